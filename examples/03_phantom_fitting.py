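"""Generate a synthetic DWI phantom, fit it voxel-wise, classify estimates.

The phantom is a nested-shell geometry (CSF core, GM shell, WM exterior)
with literature tissue parameters, noised at the scanner's b0 SNR of 20.
A per-voxel grid-search fit then shows the wide single-voxel f spread and
the boundary saturation of D*, while ROI-averaged fitting recovers tissue
values.
"""

import numpy as np

import ivimsim as iv

spec = iv.PhantomSpec(shape=(24, 24, 12), snr=20.0, seed=7)
volume, labels = iv.make_phantom(spec)
print(f"phantom {spec.shape}, labels: "
      + ", ".join(f"{k}={np.sum(labels == v)}" for k, v in iv.phantom.LABEL_CODES.items()))

maps = iv.fit_volume(volume, method="grid_search")
gm = labels == 2
truth = spec.compartments["gm"]
print(f"\nGM truth:              f={truth.f:.3f}  D*={truth.d_star:.4f}  D={truth.d:.5f}")
print(
    f"GM voxel-median fit:   f={np.nanmedian(maps.maps['f'][gm]):.3f}  "
    f"D*={np.nanmedian(maps.maps['d_star'][gm]):.4f}  "
    f"D={np.nanmedian(maps.maps['d'][gm]):.5f}"
)

roi_signal = iv.roi_average_signal(volume, labels, 2)
res = iv.fit_grid_segmented(roi_signal, spec.scheme)
print(
    f"GM ROI-averaged fit:   f={res.params.f:.3f}  "
    f"D*={res.params.d_star:.4f}  D={res.params.d:.5f}"
)

report = iv.classify_estimates(maps.maps["f"], maps.maps["d_star"], labels > 0)
print(
    f"\nclassification over {report.n_total} tissue voxels: "
    f"{report.pct_f_outliers:.1f}% near-zero f outliers, "
    f"{report.pct_f_in_range:.1f}% with f in [0.02, 0.25], "
    f"{report.pct_dstar_in_range:.1f}% with D* in [0.006, 0.05)"
)
print(
    "\nReading: single-voxel estimates scatter widely at SNR 20, and because"
    "\nthe GM pseudo-diffusion (D*~0.0036) decays slowly, stage 1 of the"
    "\nsegmented fit absorbs part of the fast component and f comes out low."
    "\nROI pooling removes the scatter but not that truncation bias."
)
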