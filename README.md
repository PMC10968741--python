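# ivimsim

Simulation and estimation toolkit for **intravoxel incoherent motion (IVIM)**
diffusion MRI, built to answer a practical question: how accurately can the
IVIM perfusion parameters be estimated from a *quick, high-resolution,
whole-brain* protocol (1 × 1 × 2 mm voxels, 35 measurements, scanner SNR ≈ 20),
and how much does voxel averaging or the choice of estimator buy you?

It is aimed at diffusion-MRI methodologists and sequence designers who want
to evaluate fitting strategies and SNR requirements before (or instead of)
burning scanner time.

## The model

The diffusion-weighted signal of perfused tissue follows the bi-exponential
IVIM model

```
S(b) = S0 · ( f · e^(−D*·b) + (1 − f) · e^(−D·b) )
```

with perfusion fraction `f`, pseudo-diffusion coefficient `D*` (capillary
blood, ~10× tissue diffusivity) and tissue diffusion coefficient `D`
(mm²/s; b in s/mm²). Magnitude images carry Rician noise:
`S_noised = sqrt((S + N_r)² + N_i²)` with `N_r, N_i ~ N(0, σ²)` and
`σ = S0 / SNR`.

Three estimators are implemented:

* **segmented grid search** — exhaustive two-stage least squares: fit
  `(S0_slow, D)` on b > 250 s/mm², subtract, fit `(S0_fast, D*)` on the
  low-b residual over a Cartesian grid; `f = S0_fast / (S0_fast + S0_slow)`;
* **segmented curve fit** — the same two stages via bounded trust-region
  nonlinear least squares;
* **one-step curve fit** — all four parameters simultaneously.

A Monte-Carlo driver sweeps SNR levels and realization-averaging factors
(8 = 2×2×2, 27 = 3×3×3, 64 = 4×4×4 pooled voxels) and reports relative RMSE
per parameter. Volume-level tools compute per-voxel SNR maps from repeated
b0 scans, fit 4D NIfTI volumes voxel-wise or per ROI, and classify estimate
maps; a synthetic nested-shell phantom generator provides test data with
GM/WM/CSF contrasts.

## Worked example

```python
import ivimsim as iv

config = iv.SimulationConfig(
    snr_levels=[20.0],
    n_realizations=1728,
    averaging_factors=[1, 8, 27, 64],
    methods=["grid_search", "segmented", "one_step"],
    seed=42,
)
table = iv.run_study(config)
print(iv.export_table(table, 20.0)[1])
```

prints (excerpt):

```
Relative RMSE (%) per estimation method, SNR 20

Single voxel
               grid_search     segmented      one_step
  S0                  3.00          3.08          1.84
  f                  72.25         71.29        185.31
  D*                 89.54        590.40        313.79
  D                  14.63         14.63         32.06

3 x 3 x 3
               grid_search     segmented      one_step
  S0                  0.41          0.36          0.35
  f                  14.98         14.81         17.73
  D*                 24.38         23.80         21.53
  D                   3.17          3.07          3.60
```

Reading: at the scanner's working SNR of 20, a single high-resolution voxel
gives ~70 % relative error on the perfusion fraction `f` and the curve-fit
methods saturate their `D*` bounds (hundreds of percent error); averaging 27
neighbouring voxels (a 3 × 3 × 6 mm region) brings `f` below ~15 % and makes
the three methods comparable. `S0` and `D`, which are dominated by the
well-conditioned high-b decay, are accurate throughout. The `examples/`
directory holds narrative scripts for the signal model, the Monte-Carlo
study, phantom fitting + classification, and SNR mapping; the command line
(`ivimsim simulate|fit|snr-map|phantom|classify|report`) exposes the same
operations on NIfTI/bval/bvec files.

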