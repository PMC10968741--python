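"""Synthetic DWI phantoms with the statistical structure of the study data.

The phantom is a deterministic nested-shell geometry -- CSF core, grey-matter
shell, white-matter exterior -- on a 1 x 1 x 2 mm voxel grid.  Each voxel's
noiseless signal follows the bi-exponential IVIM model with its
compartment's parameters; Rician noise at a target b0 SNR is applied on top.
Compartment defaults for GM and WM are the study's fitted in-vivo values
(grid-search column); the CSF parameters are conventional placeholders, as
no CSF fit was reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import AcquisitionScheme, IVIMParameters, default_acquisition_scheme, ivim_signal
from .noise import NoiseSpec, SignalSet, add_rician_noise, derive_rng, sigma_for_snr
from .volume import DWIVolume

__all__ = ["PhantomSpec", "make_phantom", "make_b0_series", "LABEL_CODES"]

#: Integer label codes in the emitted label map.
LABEL_CODES = {"background": 0, "csf": 1, "gm": 2, "wm": 3}

#: Mirrors the study's 1 x 1 x 2 mm acquisition voxels.
DEFAULT_AFFINE = np.diag([1.0, 1.0, 2.0, 1.0])

DEFAULT_COMPARTMENTS = {
    "csf": IVIMParameters(s0=1.0, f=0.05, d_star=0.01, d=0.003),
    "gm": IVIMParameters(s0=1.0, f=0.09, d_star=0.0036, d=0.00065),
    "wm": IVIMParameters(s0=1.0, f=0.16, d_star=0.00517, d=0.00079),
}

#: Normalized-radius shell edges of the nested geometry.
_SHELLS = {"csf": 0.25, "gm": 0.55, "wm": 0.90}


@dataclass
class PhantomSpec:
    """Geometry, tissue parameters, acquisition and noise of one phantom."""

    shape: tuple = (32, 32, 16)
    compartments: dict = field(default_factory=lambda: dict(DEFAULT_COMPARTMENTS))
    snr: float | None = 20.0
    seed: int = 0
    scheme: AcquisitionScheme = field(default_factory=default_acquisition_scheme)
    mixing: bool = False
    mixing_width: float = 0.05

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 4 for s in self.shape):
            raise ValueError(f"shape must be 3-D with every dimension >= 4, got {self.shape}")
        if any(s > 64 for s in self.shape):
            raise ValueError(f"phantom shape {self.shape} exceeds the desk-scale limit of 64^3")
        missing = set(_SHELLS) - set(self.compartments)
        if missing:
            raise ValueError(f"compartments missing tissue(s): {sorted(missing)}")
        for name, p in self.compartments.items():
            if not isinstance(p, IVIMParameters):
                raise ValueError(f"compartment {name!r} must be IVIMParameters, got {type(p)}")
        if self.snr is not None and self.snr <= 0:
            raise ValueError(f"snr must be positive or None (noiseless), got {self.snr}")


def _normalized_radius(shape) -> np.ndarray:
    """Radial coordinate scaled so the volume edge midpoints sit at r = 1."""
    axes = [(np.arange(s) - (s - 1) / 2.0) / (s / 2.0) for s in shape]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(x**2 + y**2 + z**2)


def make_label_map(shape) -> np.ndarray:
    """Nested-shell integer label map: CSF core, GM shell, WM exterior."""
    r = _normalized_radius(shape)
    labels = np.zeros(shape, dtype=np.int16)
    labels[r < _SHELLS["wm"]] = LABEL_CODES["wm"]
    labels[r < _SHELLS["gm"]] = LABEL_CODES["gm"]
    labels[r < _SHELLS["csf"]] = LABEL_CODES["csf"]
    return labels


def make_phantom(spec: PhantomSpec, out_dir=None) -> tuple:
    """Build a noised 4D DWI phantom, its label map, and optional files.

    Returns ``(volume, labels)`` where `volume` is a :class:`DWIVolume`
    whose mask covers the three tissue shells.  With `out_dir` set, also
    writes dwi.nii.gz, labels.nii.gz, dwi.bval and dwi.bvec.

    The per-voxel noiseless signal is the compartment's bi-exponential
    curve; with ``spec.mixing`` enabled, voxels within ``mixing_width`` of a
    shell interface mix the two adjacent compartments linearly (partial
    volume).  Rician noise at ``spec.snr`` (referenced to S0) is applied
    independently per voxel and measurement; deterministic given
    ``spec.seed``.
    """
    labels = make_label_map(spec.shape)
    b = spec.scheme.b_values
    n_meas = b.size
    signals = {name: ivim_signal(p, spec.scheme) for name, p in spec.compartments.items()}

    data = np.zeros(spec.shape + (n_meas,), dtype=float)
    for name, code in LABEL_CODES.items():
        if name == "background":
            continue
        data[labels == code] = signals[name]

    if spec.mixing:
        r = _normalized_radius(spec.shape)
        for inner, outer, edge in (("csf", "gm", _SHELLS["csf"]), ("gm", "wm", _SHELLS["gm"])):
            zone = np.abs(r - edge) < spec.mixing_width
            w = np.clip((r[zone] - (edge - spec.mixing_width)) / (2 * spec.mixing_width), 0, 1)
            data[zone] = (1 - w[:, None]) * signals[inner] + w[:, None] * signals[outer]

    mask = labels > 0
    if spec.snr is not None:
        s0_ref = max(p.s0 for p in spec.compartments.values())
        noise = NoiseSpec.for_snr(spec.snr, s0_reference=s0_ref, seed=spec.seed)
        flat = SignalSet(data.reshape(-1, n_meas), spec.scheme, "noiseless")
        noised = add_rician_noise(flat, noise, rng=derive_rng(spec.seed, 0))
        data = noised.values.reshape(spec.shape + (n_meas,))

    volume = DWIVolume(data=data, scheme=spec.scheme, affine=DEFAULT_AFFINE.copy(), mask=mask)

    if out_dir is not None:
        from . import io  # local import: nibabel only needed when writing

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        io.write_dwi(volume, out_dir / "dwi.nii.gz")
        io.write_labels(labels, volume.affine, out_dir / "labels.nii.gz")
        spec.scheme.to_bval(out_dir / "dwi.bval")
        spec.scheme.to_bvec(out_dir / "dwi.bvec")
    return volume, labels


def make_b0_series(
    n_volumes: int = 5,
    true_signal: float = 1.0,
    snr: float = 20.0,
    shape=(16, 16, 16),
    seed: int = 0,
) -> DWIVolume:
    """Rician-noised repeats of a constant 3D signal, for SNR-map testing.

    Returns a :class:`DWIVolume` whose scheme is a single b = 0 entry with
    `n_volumes` repeats.  With ``snr=None`` the copies are noiseless (the
    SNR map is then undefined everywhere).
    """
    n_volumes = int(n_volumes)
    if n_volumes < 2:
        raise ValueError(f"need at least 2 b0 volumes, got {n_volumes}")
    if true_signal <= 0:
        raise ValueError("true_signal must be positive")
    shape = tuple(int(s) for s in shape)
    scheme = AcquisitionScheme(entries=((0.0, n_volumes),))
    data = np.full(shape + (n_volumes,), float(true_signal))
    if snr is not None:
        spec = NoiseSpec(snr=float(snr), sigma=sigma_for_snr(true_signal, snr), seed=seed)
        flat = SignalSet(data.reshape(-1, n_volumes), scheme, "noiseless")
        noised = add_rician_noise(flat, spec, rng=derive_rng(seed, 1))
        data = noised.values.reshape(shape + (n_volumes,))
    return DWIVolume(data=data, scheme=scheme, affine=DEFAULT_AFFINE.copy())
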