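"""The three IVIM parameter estimators.

All three methods minimize a sum-of-squares objective against the measured
magnitude signal:

* ``grid_search`` -- segmented two-stage exhaustive search.  Stage 1 fits a
  mono-exponential (S0_slow, D) to the b > threshold measurements by
  evaluating every pair on a Cartesian grid; stage 2 subtracts the fitted
  slow curve from the b < threshold measurements and grid-fits the residual
  with (S0_fast, D*).  The perfusion fraction is composed as
  ``f = S0_fast / (S0_fast + S0_slow)`` and ``S0 = S0_fast + S0_slow``.
* ``segmented`` -- the same two-stage decomposition, but each stage is a
  bounded trust-region nonlinear least-squares fit (2 parameters per stage).
* ``one_step`` -- bounded trust-region least squares of the full
  bi-exponential model in all four parameters simultaneously.

The split threshold (default 250 s/mm^2) exploits the near-complete decay of
the perfusion component above it.  "MLE" for the grid search is least
squares, i.e. maximum likelihood under Gaussian residuals; a Rician
likelihood objective is reserved behind the ``objective`` flag but not
implemented (magnitude residuals after stage-1 subtraction may be negative,
where the Rician density is undefined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.optimize import least_squares

from .model import AcquisitionScheme, IVIMParameters

__all__ = [
    "GridAxis",
    "GridSpec",
    "ParamBounds",
    "FitBounds",
    "FitResult",
    "split_scheme",
    "grid_fit_monoexp",
    "fit_grid_segmented",
    "fit_grid_segmented_batch",
    "fit_curve_segmented",
    "fit_onestep",
    "SPLIT_THRESHOLD",
]

#: Default b-value (s/mm^2) separating the slow-only regime from the mixed one.
SPLIT_THRESHOLD = 250.0

#: Relative tolerance within which a curve-fit estimate counts as on-boundary.
_BOUNDARY_RTOL = 1e-6

PARAM_NAMES = ("s0", "f", "d_star", "d")


@dataclass(frozen=True)
class GridAxis:
    """One grid dimension: `count` candidates from `start` to `stop`."""

    start: float
    stop: float
    count: int
    spacing: str = "linear"

    def __post_init__(self) -> None:
        if self.count < 2:
            raise ValueError("grid count must be >= 2")
        if not self.start < self.stop:
            raise ValueError(f"grid must be increasing, got [{self.start}, {self.stop}]")
        if self.spacing not in ("linear", "log"):
            raise ValueError(f"spacing must be 'linear' or 'log', got {self.spacing!r}")
        if self.spacing == "log" and self.start <= 0:
            raise ValueError("log spacing requires a positive start")

    @cached_property
    def values(self) -> np.ndarray:
        if self.spacing == "log":
            return np.logspace(math.log10(self.start), math.log10(self.stop), self.count)
        return np.linspace(self.start, self.stop, self.count)


@dataclass(frozen=True)
class GridSpec:
    """Candidate grids for the two stages of the segmented grid search.

    The pseudo-diffusion axis is by far the most influential setting: its
    upper limit caps the error of realizations whose stage-2 residual is
    noise-dominated, so the reported D* RMSE scales with it (see
    docs/methods.md).
    """

    s0_slow: GridAxis = field(default_factory=lambda: GridAxis(0.3, 1.5, 121))
    d: GridAxis = field(default_factory=lambda: GridAxis(1e-4, 3e-3, 117))
    s0_fast: GridAxis = field(default_factory=lambda: GridAxis(0.0, 0.6, 121))
    d_star: GridAxis = field(default_factory=lambda: GridAxis(3e-3, 3e-2, 151, "log"))

    @classmethod
    def default(cls) -> "GridSpec":
        return cls()


@dataclass(frozen=True)
class ParamBounds:
    lower: float
    upper: float
    initial: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"lower {self.lower} must be < upper {self.upper}")
        if not self.lower <= self.initial <= self.upper:
            raise ValueError(f"initial {self.initial} outside [{self.lower}, {self.upper}]")


@dataclass(frozen=True)
class FitBounds:
    """Box bounds and fixed initial values for the curve-fit methods.

    Defaults bracket literature human-brain IVIM ranges with headroom; the
    initial point is fixed and documented (no data-dependent randomness).
    """

    s0: ParamBounds = field(default_factory=lambda: ParamBounds(1e-6, 2.0, 1.0))
    f: ParamBounds = field(default_factory=lambda: ParamBounds(0.0, 1.0, 0.1))
    d_star: ParamBounds = field(default_factory=lambda: ParamBounds(1e-4, 0.15, 1e-2))
    d: ParamBounds = field(default_factory=lambda: ParamBounds(1e-5, 5e-3, 1e-3))

    @classmethod
    def default(cls) -> "FitBounds":
        return cls()


@dataclass
class FitResult:
    """Estimated parameters plus method tag and fit diagnostics."""

    params: IVIMParameters
    method: str
    converged: bool
    boundary_flags: dict
    residual_norm: float

    def at_boundary(self) -> bool:
        return any(self.boundary_flags.values())


def split_scheme(scheme: AcquisitionScheme, threshold: float = SPLIT_THRESHOLD):
    """Indices of the high-b (> threshold) and low-b (< threshold) measurements.

    b = 0 belongs to the low set.  Raises if either set is empty, in which
    case the scheme cannot support segmented fitting.
    """
    b = scheme.b_values
    high = np.flatnonzero(b > threshold)
    low = np.flatnonzero(b < threshold)
    if high.size == 0:
        raise ValueError(f"no measurements with b > {threshold}; scheme unusable for segmented fitting")
    if low.size == 0:
        raise ValueError(f"no measurements with b < {threshold}; scheme unusable for segmented fitting")
    return high, low


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


def _grid_fit_batch(signals: np.ndarray, b: np.ndarray, s0_grid: np.ndarray, d_grid: np.ndarray, chunk: int = 512):
    """Vectorized exhaustive mono-exponential grid fit over rows of `signals`.

    For candidate (s0, d) the SSE expands to
    ``y.y - 2 s0 (E_d . y) + s0^2 (E_d . E_d)`` with ``E_d = exp(-d b)``;
    only the last two terms depend on the candidate, so the argmin is found
    without materializing residuals.  The SSE cube is laid out (d, s0) and
    flattened, so NumPy's first-occurrence argmin implements the tie-break
    "smallest d, then smallest s0".

    Returns integer index arrays (s0_idx, d_idx) plus the exact SSE of the
    winners, recomputed in residual form.
    """
    E = np.exp(-np.outer(d_grid, b))  # (n_d, n_b)
    C = signals @ E.T  # (n, n_d)
    G = np.einsum("ij,ij->i", E, E)  # (n_d,)
    n = signals.shape[0]
    n_s0 = s0_grid.size
    s0_idx = np.empty(n, dtype=np.intp)
    d_idx = np.empty(n, dtype=np.intp)
    s0_sq = s0_grid**2
    for i0 in range(0, n, chunk):
        c = C[i0 : i0 + chunk]  # (m, n_d)
        # partial SSE, shape (m, n_d, n_s0)
        sse = s0_sq[None, None, :] * G[None, :, None] - 2.0 * c[:, :, None] * s0_grid[None, None, :]
        flat_idx = sse.reshape(c.shape[0], -1).argmin(axis=1)
        d_idx[i0 : i0 + chunk] = flat_idx // n_s0
        s0_idx[i0 : i0 + chunk] = flat_idx % n_s0
    # exact SSE of winners, residual form
    model = s0_grid[s0_idx, None] * np.exp(-d_grid[d_idx, None] * b[None, :])
    sse_win = ((signals - model) ** 2).sum(axis=1)
    return s0_idx, d_idx, sse_win


def grid_fit_monoexp(signal, b, s0_grid, d_grid):
    """Exhaustive least-squares mono-exponential fit over a Cartesian grid.

    Evaluates every (s0, d) pair and returns the minimizer of
    ``sum((signal - s0 exp(-d b))^2)``; ties are broken toward the smallest
    d, then the smallest s0.  Equivalent to maximum likelihood under
    Gaussian residuals.

    Returns ``(s0_hat, d_hat, sse, boundary_flags)`` where `boundary_flags`
    maps 's0' and 'd' to True when the estimate sits on a grid endpoint.
    """
    signal = np.asarray(signal, dtype=float)
    b = np.asarray(b, dtype=float)
    s0_grid = np.asarray(s0_grid, dtype=float)
    d_grid = np.asarray(d_grid, dtype=float)
    if signal.ndim != 1 or signal.size != b.size:
        raise ValueError("signal and b must be 1-D vectors of equal length")
    if signal.size < 2:
        raise ValueError("at least two measurements are required")
    s0_idx, d_idx, sse = _grid_fit_batch(signal[None, :], b, s0_grid, d_grid)
    i, j = int(s0_idx[0]), int(d_idx[0])
    flags = {
        "s0": i in (0, s0_grid.size - 1),
        "d": j in (0, d_grid.size - 1),
    }
    return float(s0_grid[i]), float(d_grid[j]), float(sse[0]), flags


def fit_grid_segmented_batch(
    signals: np.ndarray,
    scheme: AcquisitionScheme,
    grids: GridSpec | None = None,
    threshold: float = SPLIT_THRESHOLD,
    objective: str = "ls",
) -> dict:
    """Segmented grid search applied to every row of `signals`.

    Returns a dict of per-row arrays: the four parameter estimates, the
    stage SSE totals, and boundary-hit masks.  This is the vectorized core
    behind :func:`fit_grid_segmented`, :mod:`ivimsim.montecarlo` and
    :mod:`ivimsim.volume`.
    """
    if objective != "ls":
        raise NotImplementedError(
            "only the least-squares (Gaussian MLE) objective is implemented; "
            "a Rician-likelihood objective is reserved under objective='rician'"
        )
    grids = grids or GridSpec.default()
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    b = scheme.b_values
    high, low = split_scheme(scheme, threshold)

    s0s_grid, d_grid = grids.s0_slow.values, grids.d.values
    s0f_grid, ds_grid = grids.s0_fast.values, grids.d_star.values

    # stage 1: slow compartment from the high-b subset
    i1, j1, sse1 = _grid_fit_batch(signals[:, high], b[high], s0s_grid, d_grid)
    s0_slow = s0s_grid[i1]
    d_hat = d_grid[j1]

    # stage 2: fast compartment from the low-b residual (negatives kept as-is)
    residual = signals[:, low] - s0_slow[:, None] * np.exp(-d_hat[:, None] * b[low][None, :])
    i2, j2, sse2 = _grid_fit_batch(residual, b[low], s0f_grid, ds_grid)
    s0_fast = s0f_grid[i2]
    d_star_hat = ds_grid[j2]

    total = s0_fast + s0_slow
    with np.errstate(invalid="ignore", divide="ignore"):
        f_hat = np.where(total > 0, s0_fast / np.where(total > 0, total, 1.0), 0.0)

    n1, nd = s0s_grid.size, d_grid.size
    n2, nds = s0f_grid.size, ds_grid.size
    slow_edge = (i1 == 0) | (i1 == n1 - 1)
    fast_edge = (i2 == 0) | (i2 == n2 - 1)
    return {
        "s0": total,
        "f": f_hat,
        "d_star": d_star_hat,
        "d": d_hat,
        "s0_slow": s0_slow,
        "s0_fast": s0_fast,
        "sse": sse1 + sse2,
        "boundary_s0": slow_edge | fast_edge,
        "boundary_f": fast_edge | (total <= 0),
        "boundary_d": (j1 == 0) | (j1 == nd - 1),
        "boundary_d_star": (j2 == 0) | (j2 == nds - 1),
    }


def fit_grid_segmented(
    signal,
    scheme: AcquisitionScheme,
    grids: GridSpec | None = None,
    threshold: float = SPLIT_THRESHOLD,
) -> FitResult:
    """Two-stage exhaustive grid search on a single measurement vector."""
    out = fit_grid_segmented_batch(np.asarray(signal, dtype=float)[None, :], scheme, grids, threshold)
    s0 = float(out["s0"][0])
    params = IVIMParameters(
        s0=max(s0, 1e-12),  # degenerate all-zero amplitude still yields a valid record
        f=float(out["f"][0]),
        d_star=float(out["d_star"][0]),
        d=float(out["d"][0]),
    )
    flags = {p: bool(out[f"boundary_{p}"][0]) for p in PARAM_NAMES}
    return FitResult(
        params=params,
        method="grid_search",
        converged=True,
        boundary_flags=flags,
        residual_norm=float(out["sse"][0]),
    )


# ---------------------------------------------------------------------------
# Trust-region curve fits
# ---------------------------------------------------------------------------

_LSQ_OPTS = dict(method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)


def _near(value: float, bound: float) -> bool:
    return abs(value - bound) <= _BOUNDARY_RTOL * max(abs(bound), 1.0)


def _fit_monoexp_curve(signal, b, s0_bounds: ParamBounds, d_bounds: ParamBounds):
    """Bounded trust-region LS fit of s0*exp(-d b); negatives in `signal` allowed."""

    def resid(p):
        return p[0] * np.exp(-p[1] * b) - signal

    res = least_squares(
        resid,
        x0=[s0_bounds.initial, d_bounds.initial],
        bounds=([s0_bounds.lower, d_bounds.lower], [s0_bounds.upper, d_bounds.upper]),
        x_scale=[max(s0_bounds.initial, 1e-3), max(d_bounds.initial, 1e-6)],
        **_LSQ_OPTS,
    )
    return res


def fit_curve_segmented(
    signal,
    scheme: AcquisitionScheme,
    bounds: FitBounds | None = None,
    threshold: float = SPLIT_THRESHOLD,
    stage2: str = "residual",
) -> FitResult:
    """Segmented two-stage trust-region curve fit.

    Stage 1 fits (S0_slow, D) to the b > threshold subset; stage 2, in the
    default ``stage2='residual'`` variant, fits (S0_fast, D*) to the low-b
    residual after subtracting the stage-1 curve, mirroring the grid search.
    The alternative ``stage2='fixed_slow'`` fits (f, D*) to the full low-b
    signal with the stage-1 slow curve held fixed.
    """
    bounds = bounds or FitBounds.default()
    signal = np.asarray(signal, dtype=float)
    b = scheme.b_values
    high, low = split_scheme(scheme, threshold)

    # stage 1: slow compartment on high-b data; amplitude bounded like s0
    s1 = _fit_monoexp_curve(signal[high], b[high], bounds.s0, bounds.d)
    s0_slow, d_hat = s1.x

    if stage2 == "residual":
        residual = signal[low] - s0_slow * np.exp(-d_hat * b[low])
        fast_amp = ParamBounds(0.0, bounds.s0.upper, bounds.f.initial * bounds.s0.initial)
        s2 = _fit_monoexp_curve(residual, b[low], fast_amp, bounds.d_star)
        s0_fast, d_star_hat = s2.x
        total = s0_fast + s0_slow
        f_hat = s0_fast / total if total > 0 else 0.0
        s0_hat = total if total > 0 else s0_slow
        fast_lo, fast_hi = fast_amp.lower, fast_amp.upper
        f_boundary = _near(s0_fast, fast_lo) or _near(s0_fast, fast_hi) or total <= 0
    elif stage2 == "fixed_slow":
        # fit (f, D*) to the full low-b signal with the stage-1 slow curve fixed:
        # model = s0_slow/(1-f) * (f exp(-D* b) + (1-f) exp(-D b))
        f_cap = min(bounds.f.upper, 0.999)  # keep s0_slow/(1-f) finite

        def resid(p):
            f, d_star = p
            return s0_slow / (1.0 - f) * (
                f * np.exp(-d_star * b[low]) + (1.0 - f) * np.exp(-d_hat * b[low])
            ) - signal[low]

        s2 = least_squares(
            resid,
            x0=[bounds.f.initial, bounds.d_star.initial],
            bounds=([bounds.f.lower, bounds.d_star.lower], [f_cap, bounds.d_star.upper]),
            x_scale=[0.1, max(bounds.d_star.initial, 1e-6)],
            **_LSQ_OPTS,
        )
        f_hat, d_star_hat = s2.x
        s0_hat = s0_slow / (1.0 - f_hat)
        f_boundary = _near(f_hat, bounds.f.lower) or _near(f_hat, f_cap)
    else:
        raise ValueError(f"unknown stage2 variant {stage2!r}")

    converged = bool(s1.status > 0 and s2.status > 0)
    flags = {
        "s0": _near(s0_slow, bounds.s0.lower) or _near(s0_slow, bounds.s0.upper),
        "f": bool(f_boundary),
        "d_star": _near(d_star_hat, bounds.d_star.lower) or _near(d_star_hat, bounds.d_star.upper),
        "d": _near(d_hat, bounds.d.lower) or _near(d_hat, bounds.d.upper),
    }
    params = IVIMParameters(
        s0=float(max(s0_hat, 1e-12)),
        f=float(np.clip(f_hat, 0.0, 1.0)),
        d_star=float(d_star_hat),
        d=float(d_hat),
    )
    return FitResult(
        params=params,
        method="segmented",
        converged=converged,
        boundary_flags=flags,
        residual_norm=float(2.0 * (s1.cost + s2.cost)),
    )


def fit_onestep(signal, scheme: AcquisitionScheme, bounds: FitBounds | None = None) -> FitResult:
    """Simultaneous 4-parameter bounded trust-region fit of the full model."""
    bounds = bounds or FitBounds.default()
    signal = np.asarray(signal, dtype=float)
    b = scheme.b_values

    def resid(p):
        s0, f, d_star, d = p
        return s0 * (f * np.exp(-d_star * b) + (1.0 - f) * np.exp(-d * b)) - signal

    lower = [bounds.s0.lower, bounds.f.lower, bounds.d_star.lower, bounds.d.lower]
    upper = [bounds.s0.upper, bounds.f.upper, bounds.d_star.upper, bounds.d.upper]
    x0 = [bounds.s0.initial, bounds.f.initial, bounds.d_star.initial, bounds.d.initial]
    res = least_squares(
        resid,
        x0=x0,
        bounds=(lower, upper),
        x_scale=[1.0, 0.1, max(bounds.d_star.initial, 1e-6), max(bounds.d.initial, 1e-6)],
        **_LSQ_OPTS,
    )
    s0_hat, f_hat, d_star_hat, d_hat = res.x
    flags = {
        "s0": _near(s0_hat, bounds.s0.lower) or _near(s0_hat, bounds.s0.upper),
        "f": _near(f_hat, bounds.f.lower) or _near(f_hat, bounds.f.upper),
        "d_star": _near(d_star_hat, bounds.d_star.lower) or _near(d_star_hat, bounds.d_star.upper),
        "d": _near(d_hat, bounds.d.lower) or _near(d_hat, bounds.d.upper),
    }
    params = IVIMParameters(s0=float(s0_hat), f=float(f_hat), d_star=float(d_star_hat), d=float(d_hat))
    return FitResult(
        params=params,
        method="one_step",
        converged=bool(res.status > 0),
        boundary_flags=flags,
        residual_norm=float(2.0 * res.cost),
    )
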