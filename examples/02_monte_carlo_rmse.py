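"""Scaled-down Monte-Carlo accuracy study at the scanner's working SNR.

Simulates 1,728 Rician-noised realizations at SNR 20, fits all three
estimators single-voxel and after 8/27/64-fold realization averaging, and
prints the relative-RMSE table (the full-scale study uses 17,280
realizations per SNR level; Monte-Carlo standard errors quantify the
scale-down).
"""

import ivimsim as iv

config = iv.SimulationConfig(
    snr_levels=[20.0],
    n_realizations=1728,  # divisible by 8, 27 and 64
    averaging_factors=[1, 8, 27, 64],
    methods=["grid_search", "segmented", "one_step"],
    seed=42,
)
table = iv.run_study(config)
_, text = iv.export_table(table, 20.0)
print(text)
cell = table.data[
    (table.data.method == "grid_search")
    & (table.data.parameter == "f")
    & (table.data.averaging == 1)
]
print(
    f"grid-search single-voxel f error: {cell.rmse.iloc[0]:.1f}% "
    f"(MC standard error {cell.mc_se.iloc[0]:.1f} points)\n"
)
print(
    "Reading: at SNR 20 a single 1x1x2 mm voxel gives ~70-90% relative error\n"
    "on the perfusion fraction; averaging 27 neighbouring voxels brings it\n"
    "below ~20%, which is why ROI-pooled estimation is recommended."
)
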