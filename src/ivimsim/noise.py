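"""Rician noise generation and realization averaging.

Magnitude MR images are Rician distributed: independent zero-mean Gaussian
noise corrupts the real and imaginary channels, and the magnitude operation

    S_noised = sqrt((S + N_r)^2 + N_i^2),   N_r, N_i ~ N(0, sigma^2)

leaves the signal non-negative and biased upward, increasingly so at low
SNR.  SNR is referenced to the b = 0 signal: ``sigma = s0_reference / snr``,
constant across b-values, matching how scanner SNR is measured from repeated
b0 volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import AcquisitionScheme, IVIMParameters, ivim_signal

__all__ = [
    "NoiseSpec",
    "SignalSet",
    "sigma_for_snr",
    "add_rician_noise",
    "average_realizations",
    "make_signal_set",
    "derive_rng",
]


def sigma_for_snr(s0_reference: float, snr: float) -> float:
    """Gaussian channel standard deviation giving a target b0 SNR.

    Defined as ``s0_reference / snr``; at high SNR the magnitude-image noise
    standard deviation equals the per-channel sigma, so the b0 mean/std
    quotient measured from repeated volumes recovers `snr`.
    """
    if not (np.isfinite(s0_reference) and s0_reference > 0):
        raise ValueError(f"s0_reference must be positive, got {s0_reference}")
    if not (np.isfinite(snr) and snr > 0):
        raise ValueError(f"snr must be positive, got {snr}")
    return s0_reference / snr


@dataclass(frozen=True)
class NoiseSpec:
    """Target SNR, the implied channel sigma, and the random seed."""

    snr: float
    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.snr) and self.snr > 0):
            raise ValueError(f"snr must be positive, got {self.snr}")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @classmethod
    def for_snr(cls, snr: float, s0_reference: float = 1.0, seed: int = 0) -> "NoiseSpec":
        return cls(snr=float(snr), sigma=sigma_for_snr(s0_reference, snr), seed=seed)


@dataclass
class SignalSet:
    """Matrix of signal realizations (rows) by measurements (columns).

    `provenance` records whether the rows are noiseless model evaluations,
    Rician-noised realizations, or group averages of noised realizations.
    """

    values: np.ndarray
    scheme: AcquisitionScheme
    provenance: str = "noiseless"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.scheme.total_measurements:
            raise ValueError(
                f"column count {self.values.shape[1]} does not match "
                f"scheme.total_measurements {self.scheme.total_measurements}"
            )
        if self.provenance not in ("noiseless", "noised", "averaged"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def n_realizations(self) -> int:
        return self.values.shape[0]


def make_signal_set(
    params: IVIMParameters, scheme: AcquisitionScheme, n_realizations: int = 1
) -> SignalSet:
    """Tile the noiseless IVIM signal into `n_realizations` identical rows."""
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    row = ivim_signal(params, scheme)
    return SignalSet(np.tile(row, (n_realizations, 1)), scheme, "noiseless")


def derive_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream generator for (master seed, integer key path).

    Distinct key paths yield statistically independent streams, so partial
    re-runs (one SNR level, one realization block) reproduce exactly the
    draws they would receive inside a full run.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


def add_rician_noise(
    clean: SignalSet, spec: NoiseSpec, rng: np.random.Generator | None = None
) -> SignalSet:
    """Replace every element S by ``sqrt((S + N_r)^2 + N_i^2)``.

    N_r and N_i are independent N(0, spec.sigma^2) draws, independent across
    measurements and realizations.  Deterministic given ``spec.seed`` (or the
    supplied generator).
    """
    if clean.provenance != "noiseless":
        raise ValueError(f"expected a noiseless SignalSet, got {clean.provenance!r}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    shape = clean.values.shape
    nr = rng.normal(0.0, spec.sigma, shape)
    ni = rng.normal(0.0, spec.sigma, shape)
    noised = np.sqrt((clean.values + nr) ** 2 + ni**2)
    return replace(clean, values=noised, provenance="noised")


def average_realizations(noised: SignalSet, group_size: int) -> SignalSet:
    """Column-wise mean over consecutive disjoint groups of `group_size` rows.

    Emulates averaging the signal of `group_size` neighbouring voxels before
    fitting (2x2x2 = 8, 3x3x3 = 27, 4x4x4 = 64).  The realization count must
    be divisible by `group_size`.
    """
    group_size = int(group_size)
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    n = noised.n_realizations
    if n % group_size != 0:
        raise ValueError(
            f"n_realizations={n} is not divisible by group_size={group_size}; "
            f"choose a realization count divisible by every averaging factor "
            f"(e.g. a multiple of {group_size})"
        )
    if group_size == 1:
        return noised
    mean = noised.values.reshape(n // group_size, group_size, -1).mean(axis=1)
    return replace(noised, values=mean, provenance="averaged")
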