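"""Bi-exponential IVIM signal model and diffusion acquisition schemes.

The intravoxel incoherent motion (IVIM) model describes the diffusion-weighted
MR signal of perfused tissue as the sum of a fast pseudo-diffusion component
(capillary blood, fraction ``f``, coefficient ``D*``) and a slow tissue
component (fraction ``1 - f``, coefficient ``D``)::

    S(b) = S0 * (f * exp(-D* . b) + (1 - f) * exp(-D . b))

b-values are carried in s/mm^2 and diffusivities in mm^2/s so that ``D * b``
is dimensionless.  The model is isotropic: acquisitions along different
gradient directions at the same b-value are represented as repeats with
identical expectation (each repeat receives independent noise downstream).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "IVIMParameters",
    "AcquisitionScheme",
    "default_acquisition_scheme",
    "ivim_signal",
    "monoexp_signal",
]

#: b-values (s/mm^2) of the reference whole-brain protocol, ascending.
DEFAULT_NONZERO_B = (10.0, 20.0, 50.0, 80.0, 120.0, 200.0, 500.0, 700.0, 1000.0, 1200.0)
DEFAULT_N_B0 = 5
DEFAULT_N_DIRECTIONS = 3


@dataclass(frozen=True)
class IVIMParameters:
    """The four IVIM parameters, used both as ground truth and as fit output.

    Attributes
    ----------
    s0 : float
        Baseline signal intensity at b = 0 (arbitrary units, > 0).
    f : float
        Perfusion (blood) fraction, in [0, 1].
    d_star : float
        Pseudo-diffusion coefficient of the vascular compartment, mm^2/s.
    d : float
        Tissue diffusion coefficient, mm^2/s.
    """

    s0: float
    f: float
    d_star: float
    d: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.s0) or self.s0 <= 0:
            raise ValueError(f"s0 must be positive and finite, got {self.s0}")
        if not np.isfinite(self.f) or not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must lie in [0, 1], got {self.f}")
        if not np.isfinite(self.d_star) or self.d_star < 0:
            raise ValueError(f"d_star must be non-negative, got {self.d_star}")
        if not np.isfinite(self.d) or self.d < 0:
            raise ValueError(f"d must be non-negative, got {self.d}")

    def as_array(self) -> np.ndarray:
        """Return (s0, f, d_star, d) as a float array."""
        return np.array([self.s0, self.f, self.d_star, self.d], dtype=float)

    @classmethod
    def from_array(cls, values) -> "IVIMParameters":
        s0, f, d_star, d = (float(v) for v in values)
        return cls(s0=s0, f=f, d_star=d_star, d=d)


@dataclass(frozen=True)
class AcquisitionScheme:
    """Ordered list of (b-value, repeats) defining one measurement vector.

    Entries are stored sorted by ascending b with repeats contiguous; this is
    the canonical measurement order used throughout the package.
    """

    entries: tuple

    def __post_init__(self) -> None:
        entries = tuple((float(b), int(r)) for b, r in self.entries)
        if not entries:
            raise ValueError("scheme must contain at least one entry")
        bs = [b for b, _ in entries]
        if any(b < 0 or not np.isfinite(b) for b in bs):
            raise ValueError(f"b-values must be non-negative and finite, got {bs}")
        if len(set(bs)) != len(bs):
            raise ValueError(f"b-values must be unique within entries, got {bs}")
        if any(r < 1 for _, r in entries):
            raise ValueError("repeat counts must be positive")
        object.__setattr__(self, "entries", tuple(sorted(entries)))

    @property
    def b_values(self) -> np.ndarray:
        """Expanded per-measurement b-value vector (ascending, repeats contiguous)."""
        return np.repeat([b for b, _ in self.entries], [r for _, r in self.entries]).astype(float)

    @property
    def total_measurements(self) -> int:
        return sum(r for _, r in self.entries)

    @property
    def n_b0(self) -> int:
        """Number of measurements acquired without diffusion weighting."""
        return sum(r for b, r in self.entries if b == 0.0)

    @property
    def nonzero_b(self) -> tuple:
        return tuple(b for b, _ in self.entries if b > 0)

    # ---- FSL-style sidecar serialization -------------------------------

    def to_bval(self, path) -> Path:
        """Write a single-line, space-separated FSL bval file."""
        path = Path(path)
        path.write_text(" ".join(f"{b:g}" for b in self.b_values) + "\n")
        return path

    def to_bvec(self, path) -> Path:
        """Write a 3-line FSL bvec file.

        The model is isotropic, so repeats of a nonzero b-value are assigned
        the unit axes x, y, z in rotation; b0 measurements get zero vectors.
        """
        axes = np.eye(3)
        vecs = []
        for b, r in self.entries:
            if b == 0.0:
                vecs.extend([np.zeros(3)] * r)
            else:
                vecs.extend(axes[i % 3] for i in range(r))
        arr = np.array(vecs).T  # 3 x total_measurements
        path = Path(path)
        path.write_text("\n".join(" ".join(f"{v:g}" for v in row) for row in arr) + "\n")
        return path

    @classmethod
    def from_bval(cls, path, tolerance: float = 1.0) -> "AcquisitionScheme":
        """Reconstruct a scheme from an FSL bval file.

        b-values within `tolerance` (s/mm^2) of each other are grouped into
        the same shell (scanner bval files jitter); the shell is represented
        by the rounded mean of its members.
        """
        raw = np.loadtxt(Path(path), ndmin=1).ravel()
        return cls.from_b_values(raw, tolerance=tolerance)

    @classmethod
    def from_b_values(cls, b_values, tolerance: float = 1.0) -> "AcquisitionScheme":
        """Group a per-measurement b-value vector into (b, repeats) entries."""
        raw = np.asarray(b_values, dtype=float).ravel()
        if raw.size == 0:
            raise ValueError("empty b-value list")
        order = np.sort(raw)
        groups = [[order[0]]]
        for b in order[1:]:
            if b - groups[-1][-1] <= tolerance:
                groups[-1].append(b)
            else:
                groups.append([b])
        entries = []
        for g in groups:
            b = float(np.round(np.mean(g), 6))
            entries.append((0.0 if b <= tolerance and g[0] == 0.0 else b, len(g)))
        return cls(entries=tuple(entries))


def default_acquisition_scheme() -> AcquisitionScheme:
    """The study protocol: 5 b0 plus 10 nonzero b-values in 3 directions (35 total)."""
    entries = [(0.0, DEFAULT_N_B0)] + [(b, DEFAULT_N_DIRECTIONS) for b in DEFAULT_NONZERO_B]
    return AcquisitionScheme(entries=tuple(entries))


def ivim_signal(params: IVIMParameters, scheme: AcquisitionScheme) -> np.ndarray:
    """Noiseless bi-exponential IVIM signal for every measurement in `scheme`.

    Returns a vector of length ``scheme.total_measurements`` in canonical
    order (ascending b, repeats contiguous).  At b = 0 the signal equals
    ``s0`` exactly; with ``f = 0`` it reduces to a mono-exponential with
    coefficient ``d``, and with ``f = 1`` to one with ``d_star``.
    """
    if not isinstance(params, IVIMParameters):
        params = IVIMParameters(*params)
    b = scheme.b_values
    return params.s0 * (
        params.f * np.exp(-params.d_star * b) + (1.0 - params.f) * np.exp(-params.d * b)
    )


def monoexp_signal(s0_component: float, d_coeff: float, b) -> np.ndarray:
    """Mono-exponential decay ``s0_component * exp(-d_coeff * b)``.

    This is the component model used by both stages of the segmented
    estimators.  `b` may be an :class:`AcquisitionScheme` or an array of
    b-values.
    """
    if s0_component < 0:
        raise ValueError(f"s0_component must be non-negative, got {s0_component}")
    if d_coeff < 0:
        raise ValueError(f"d_coeff must be non-negative, got {d_coeff}")
    if isinstance(b, AcquisitionScheme):
        b = b.b_values
    b = np.asarray(b, dtype=float)
    return s0_component * np.exp(-d_coeff * b)
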