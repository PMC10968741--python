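"""Estimate a per-voxel SNR map from repeated b0 volumes.

Builds a 5-volume b0 series at a known construction SNR of 20 and recovers
it with the mean/std quotient used on real scans, illustrating the small
upward bias of the 5-sample standard deviation.
"""

import ivimsim as iv

volume = iv.make_b0_series(n_volumes=5, true_signal=1.0, snr=20.0, shape=(32, 32, 16), seed=1)
summary = iv.snr_map(volume)

print(f"b0 series: {volume.data.shape[:3]} voxels x {volume.scheme.total_measurements} volumes")
print(
    f"SNR map over {summary.n_voxels} voxels: average={summary.average:.2f}, "
    f"median={summary.median:.2f}, min={summary.minimum:.2f}, max={summary.maximum:.2f}"
)
print(
    "\nReading: the construction SNR is 20; the median map value sits a few"
    "\npercent high because the 5-sample standard deviation underestimates"
    "\nsigma (and the ratio distribution is right-skewed, hence the large"
    "\nmaximum). The same estimator applied to a real scan defines the"
    "\nscanner's working SNR."
)
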