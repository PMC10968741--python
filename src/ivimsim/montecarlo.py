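"""Monte-Carlo evaluation of the IVIM estimators: SNR sweep x methods x averaging.

For each SNR level, `n_realizations` Rician-noised copies of the ground-truth
signal are generated, optionally averaged in disjoint groups (emulating
neighbouring-voxel pooling), fitted with each configured estimator, and
summarized as relative RMSE per parameter:

    relative RMSE = 100 * sqrt(mean((estimate - truth)^2)) / truth   [%]

Every cell also carries a delta-method Monte-Carlo standard error so that
scaled-down runs (reduced `n_realizations`) can be compared against
full-scale results with honest uncertainty.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import (
    FitBounds,
    GridSpec,
    SPLIT_THRESHOLD,
    fit_curve_segmented,
    fit_grid_segmented_batch,
    fit_onestep,
)
from .model import AcquisitionScheme, IVIMParameters, default_acquisition_scheme
from .noise import NoiseSpec, add_rician_noise, average_realizations, derive_rng, make_signal_set, sigma_for_snr

__all__ = [
    "SimulationConfig",
    "RMSETable",
    "relative_rmse",
    "run_study",
    "export_table",
    "plot_rmse_vs_snr",
    "METHODS",
    "PARAMETERS",
]

logger = logging.getLogger(__name__)

METHODS = ("grid_search", "segmented", "one_step")
PARAMETERS = ("s0", "f", "d_star", "d")

#: Ground truth of the reference simulation: a grey-matter-like voxel.
DEFAULT_GROUND_TRUTH = IVIMParameters(s0=1.0, f=0.12, d_star=0.01, d=0.001)

#: Realization count of the full-scale study (divisible by 8, 27 and 64).
DEFAULT_N_REALIZATIONS = 17280


def relative_rmse(estimates, truth: float) -> float:
    """Root-mean-square error relative to a nonzero truth, in percent."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("estimates must be non-empty")
    if truth == 0:
        raise ValueError("relative RMSE is undefined for truth = 0")
    return float(100.0 * np.sqrt(np.mean((estimates - truth) ** 2)) / truth)


def _rmse_mc_se(estimates: np.ndarray, truth: float) -> float:
    """Delta-method standard error of the relative RMSE, in percentage points."""
    e2 = (np.asarray(estimates, dtype=float) - truth) ** 2
    n = e2.size
    if n < 2:
        return float("nan")
    m2 = e2.mean()
    if m2 == 0:
        return 0.0
    se_m2 = e2.std(ddof=1) / np.sqrt(n)
    return float(100.0 * se_m2 / (2.0 * np.sqrt(m2)) / abs(truth))


@dataclass
class SimulationConfig:
    """Full specification of one Monte-Carlo study run.

    Defaults reproduce the reference study conditions: ground truth
    (S0=1, f=0.12, D*=0.01, D=0.001), the 35-measurement scheme, SNR levels
    15..50 in unit steps, 17,280 realizations per level, and averaging
    factors 1/8/27/64.
    """

    ground_truth: IVIMParameters = field(default_factory=lambda: DEFAULT_GROUND_TRUTH)
    scheme: AcquisitionScheme = field(default_factory=default_acquisition_scheme)
    snr_levels: tuple = tuple(range(15, 51))
    n_realizations: int = DEFAULT_N_REALIZATIONS
    averaging_factors: tuple = (1, 8, 27, 64)
    methods: tuple = METHODS
    seed: int = 0
    grids: GridSpec = field(default_factory=GridSpec.default)
    bounds: FitBounds = field(default_factory=FitBounds.default)
    split_threshold: float = SPLIT_THRESHOLD
    average_directions: bool = False

    def __post_init__(self) -> None:
        self.snr_levels = tuple(float(s) for s in self.snr_levels)
        self.averaging_factors = tuple(int(a) for a in self.averaging_factors)
        self.methods = tuple(self.methods)
        if not self.snr_levels or any(s <= 0 for s in self.snr_levels):
            raise ValueError("snr_levels must be a non-empty list of positive values")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}; choose from {METHODS}")
        if not self.methods:
            raise ValueError("at least one method must be configured")
        for a in self.averaging_factors:
            if a < 1 or self.n_realizations % a != 0:
                raise ValueError(
                    f"n_realizations={self.n_realizations} must be divisible by every "
                    f"averaging factor; offending factor: {a}"
                )


@dataclass
class RMSETable:
    """Relative RMSE (%) indexed by (method, parameter, snr, averaging).

    `data` is a tidy DataFrame with columns: method, parameter, snr,
    averaging, rmse, mc_se, n_effective, n_converged, rmse_converged.
    """

    data: pd.DataFrame

    def get(self, method: str, parameter: str, snr: float, averaging: int = 1) -> float:
        sel = self.data[
            (self.data.method == method)
            & (self.data.parameter == parameter)
            & (self.data.snr == snr)
            & (self.data.averaging == averaging)
        ]
        if sel.empty:
            raise KeyError(f"no entry for ({method}, {parameter}, snr={snr}, averaging={averaging})")
        return float(sel.rmse.iloc[0])

    @property
    def snr_levels(self) -> list:
        return sorted(self.data.snr.unique())

    @property
    def averaging_factors(self) -> list:
        return sorted(int(a) for a in self.data.averaging.unique())

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.data.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path) -> "RMSETable":
        return cls(pd.read_csv(path))


def _average_directions(values: np.ndarray, scheme: AcquisitionScheme):
    """Average the repeats of each nonzero b-value; keep b0 repeats separate."""
    cols = []
    entries = []
    start = 0
    for b, r in scheme.entries:
        block = values[:, start : start + r]
        if b == 0.0:
            cols.append(block)
            entries.append((b, r))
        else:
            cols.append(block.mean(axis=1, keepdims=True))
            entries.append((b, 1))
        start += r
    return np.hstack(cols), AcquisitionScheme(entries=tuple(entries))


def _fit_block(values: np.ndarray, scheme: AcquisitionScheme, method: str, config: SimulationConfig):
    """Fit every row of `values`; return dict param -> estimates, plus converged mask."""
    if method == "grid_search":
        out = fit_grid_segmented_batch(values, scheme, config.grids, config.split_threshold)
        est = {p: out[p] for p in PARAMETERS}
        return est, np.ones(values.shape[0], dtype=bool)
    fit = {
        "segmented": lambda row: fit_curve_segmented(row, scheme, config.bounds, config.split_threshold),
        "one_step": lambda row: fit_onestep(row, scheme, config.bounds),
    }[method]
    n = values.shape[0]
    est = {p: np.empty(n) for p in PARAMETERS}
    converged = np.empty(n, dtype=bool)
    for i in range(n):
        r = fit(values[i])
        est["s0"][i] = r.params.s0
        est["f"][i] = r.params.f
        est["d_star"][i] = r.params.d_star
        est["d"][i] = r.params.d
        converged[i] = r.converged
    return est, converged


def run_study(config: SimulationConfig) -> RMSETable:
    """Run the full simulation study and return the relative-RMSE table.

    Deterministic given ``config.seed``: each SNR level draws its noise from
    an independent substream keyed by the level's index, so a re-run of a
    subset of levels reproduces the full run's numbers exactly.
    """
    truth = {p: getattr(config.ground_truth, p) for p in PARAMETERS}
    clean = make_signal_set(config.ground_truth, config.scheme, config.n_realizations)
    rows = []
    for i_snr, snr in enumerate(config.snr_levels):
        spec = NoiseSpec.for_snr(snr, s0_reference=config.ground_truth.s0, seed=config.seed)
        noised = add_rician_noise(clean, spec, rng=derive_rng(config.seed, i_snr))
        for factor in config.averaging_factors:
            block = average_realizations(noised, factor)
            values, scheme = block.values, block.scheme
            if config.average_directions:
                values, scheme = _average_directions(values, scheme)
            for method in config.methods:
                t0 = time.perf_counter()
                est, converged = _fit_block(values, scheme, method, config)
                for p in PARAMETERS:
                    e = est[p]
                    row = {
                        "method": method,
                        "parameter": p,
                        "snr": snr,
                        "averaging": factor,
                        "rmse": relative_rmse(e, truth[p]),
                        "mc_se": _rmse_mc_se(e, truth[p]),
                        "n_effective": e.size,
                        "n_converged": int(converged.sum()),
                        "rmse_converged": relative_rmse(e[converged], truth[p])
                        if converged.any()
                        else float("nan"),
                    }
                    rows.append(row)
                logger.info(
                    "snr=%g averaging=%d method=%s n_effective=%d wall=%.2fs",
                    snr, factor, method, values.shape[0], time.perf_counter() - t0,
                )
    return RMSETable(pd.DataFrame(rows))


_AVERAGING_LABELS = {1: "Single voxel", 8: "2 x 2 x 2", 27: "3 x 3 x 3", 64: "4 x 4 x 4"}
_PARAM_LABELS = {"s0": "S0", "f": "f", "d_star": "D*", "d": "D"}


def export_table(table: RMSETable, snr: float, out_csv=None):
    """Format one SNR level as averaging-blocks x parameters x methods.

    Returns ``(frame, text)``: a tidy pivot DataFrame and a printable text
    rendering (one block per averaging factor, rows S0/f/D*/D, one column
    per method).  Optionally writes the pivot as CSV.
    """
    df = table.data
    if df.empty:
        raise ValueError("empty RMSE table")
    if snr not in set(df.snr):
        raise ValueError(f"snr {snr} not present; available levels: {sorted(set(df.snr))}")
    sub = df[df.snr == snr]
    methods = [m for m in METHODS if m in set(sub.method)]
    pivot = sub.pivot_table(index=["averaging", "parameter"], columns="method", values="rmse")
    pivot = pivot.reindex(
        pd.MultiIndex.from_product(
            [sorted(set(sub.averaging)), PARAMETERS], names=["averaging", "parameter"]
        )
    )[methods]

    lines = [f"Relative RMSE (%) per estimation method, SNR {snr:g}", ""]
    header = f"{'':12s}" + "".join(f"{m:>14s}" for m in methods)
    for factor in sorted(set(sub.averaging)):
        lines.append(_AVERAGING_LABELS.get(int(factor), f"averaged x{int(factor)}"))
        lines.append(header)
        for p in PARAMETERS:
            cells = "".join(f"{pivot.loc[(factor, p), m]:14.2f}" for m in methods)
            lines.append(f"  {_PARAM_LABELS[p]:10s}{cells}")
        lines.append("")
    text = "\n".join(lines)
    if out_csv is not None:
        pivot.to_csv(Path(out_csv))
    return pivot, text


def plot_rmse_vs_snr(table: RMSETable, averaging_factor: int = 1, path=None):
    """Four panels (one per parameter), one RMSE-vs-SNR curve per method."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    df = table.data
    if averaging_factor not in set(df.averaging):
        raise ValueError(
            f"averaging factor {averaging_factor} not present; available: "
            f"{sorted(set(df.averaging))}"
        )
    sub = df[df.averaging == averaging_factor]
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    for ax, p in zip(axes.ravel(), PARAMETERS):
        for method in [m for m in METHODS if m in set(sub.method)]:
            cell = sub[(sub.parameter == p) & (sub.method == method)].sort_values("snr")
            ax.plot(cell.snr, cell.rmse, marker="o", ms=3, label=method)
        ax.set_title(_PARAM_LABELS[p])
        ax.set_ylabel("relative RMSE [%]")
        ax.grid(alpha=0.3)
    for ax in axes[1]:
        ax.set_xlabel("SNR")
    axes[0, 0].legend(fontsize=8)
    label = _AVERAGING_LABELS.get(int(averaging_factor), f"x{averaging_factor}")
    fig.suptitle(f"Estimator error vs SNR ({label})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return Path(path)
    return fig
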