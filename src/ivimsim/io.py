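"""Readers and writers for every on-disk format the pipeline touches.

NIfTI-1 volumes go through nibabel; acquisition schemes use FSL-style
bval/bvec sidecars; study configuration is YAML; tabular outputs are CSV and
classification reports JSON.  Every writer's output round-trips through the
corresponding reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .estimators import FitBounds, GridAxis, GridSpec, ParamBounds
from .model import AcquisitionScheme, IVIMParameters
from .montecarlo import SimulationConfig
from .phantom import PhantomSpec
from .volume import ClassificationReport, DWIVolume, ParameterMaps

__all__ = [
    "read_dwi",
    "write_dwi",
    "write_labels",
    "read_labels",
    "write_maps",
    "read_map",
    "write_classification",
    "fit_results_to_frame",
    "StudyConfig",
]


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def read_dwi(nifti_path, bval_path, bvec_path=None, mask_path=None) -> DWIVolume:
    """Load a 4D DWI volume and reconstruct its scheme from the bval sidecar.

    The 4th axis is re-sorted into canonical order (ascending b, repeats
    contiguous, stable within equal b).  `bvec_path` is accepted for
    interface completeness; the isotropic model ignores directions.
    """
    nifti_path = Path(nifti_path)
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{nifti_path}: expected a 4-D volume, got shape {data.shape}")
    bvals = np.loadtxt(Path(bval_path), ndmin=1).ravel()
    if bvals.size != data.shape[3]:
        raise ValueError(
            f"bval count {bvals.size} does not match 4th-axis length {data.shape[3]}"
        )
    order = np.argsort(bvals, kind="stable")
    data = data[..., order]
    scheme = AcquisitionScheme.from_b_values(bvals[order])
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    return DWIVolume(data=data, scheme=scheme, affine=img.affine, mask=mask)


def write_dwi(volume: DWIVolume, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), volume.affine), str(path))
    return path


def write_labels(labels: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine), str(path))
    return path


def read_labels(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(np.int16)


def write_maps(maps, affine, out_dir) -> list:
    """Write each named 3D map as a float32 NIfTI file ``<name>.nii.gz``.

    `maps` is a dict name -> 3D array or a :class:`ParameterMaps`.
    """
    if isinstance(maps, ParameterMaps):
        affine = maps.affine
        maps = maps.maps
    if not maps:
        raise ValueError("no maps to write")
    shapes = {m.shape for m in maps.values()}
    if len(shapes) != 1:
        raise ValueError(f"maps must share one shape, got {sorted(shapes)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, arr in maps.items():
        p = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), str(p))
        written.append(p)
    return written


def read_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


# ---------------------------------------------------------------------------
# Tabular / report output
# ---------------------------------------------------------------------------


def fit_results_to_frame(results) -> pd.DataFrame:
    """Serialize FitResult records to a flat table."""
    rows = []
    for r in results:
        rows.append(
            {
                "method": r.method,
                "s0": r.params.s0,
                "f": r.params.f,
                "d_star": r.params.d_star,
                "d": r.params.d,
                "converged": r.converged,
                "boundary_s0": r.boundary_flags["s0"],
                "boundary_f": r.boundary_flags["f"],
                "boundary_d_star": r.boundary_flags["d_star"],
                "boundary_d": r.boundary_flags["d"],
                "sse": r.residual_norm,
            }
        )
    return pd.DataFrame(rows)


def write_classification(report: ClassificationReport, json_path, csv_path=None) -> Path:
    json_path = Path(json_path)
    json_path.write_text(json.dumps(report.as_dict(), indent=2) + "\n")
    if csv_path is not None:
        pd.DataFrame([report.as_dict()]).to_csv(Path(csv_path), index=False)
    return json_path


# ---------------------------------------------------------------------------
# YAML study configuration
# ---------------------------------------------------------------------------


def _reject_unknown(section: dict, allowed, where: str) -> None:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config section '{where}'")


def _parse_axis(d: dict, where: str) -> GridAxis:
    _reject_unknown(d, {"min", "max", "count", "spacing"}, where)
    return GridAxis(
        start=float(d["min"]),
        stop=float(d["max"]),
        count=int(d["count"]),
        spacing=d.get("spacing", "linear"),
    )


def _parse_grids(d: dict) -> GridSpec:
    _reject_unknown(d, {"s0_slow", "d", "s0_fast", "d_star"}, "grids")
    default = GridSpec.default()
    kw = {}
    for name in ("s0_slow", "d", "s0_fast", "d_star"):
        kw[name] = _parse_axis(d[name], f"grids.{name}") if name in d else getattr(default, name)
    return GridSpec(**kw)


def _parse_bounds(d: dict) -> FitBounds:
    _reject_unknown(d, {"s0", "f", "d_star", "d"}, "bounds")
    default = FitBounds.default()
    kw = {}
    for name in ("s0", "f", "d_star", "d"):
        if name in d:
            sec = d[name]
            _reject_unknown(sec, {"lower", "upper", "initial"}, f"bounds.{name}")
            kw[name] = ParamBounds(float(sec["lower"]), float(sec["upper"]), float(sec["initial"]))
        else:
            kw[name] = getattr(default, name)
    return FitBounds(**kw)


def _parse_ground_truth(d: dict) -> IVIMParameters:
    _reject_unknown(d, {"s0", "f", "d_star", "d"}, "simulation.ground_truth")
    return IVIMParameters(
        s0=float(d.get("s0", 1.0)),
        f=float(d.get("f", 0.12)),
        d_star=float(d.get("d_star", 0.01)),
        d=float(d.get("d", 0.001)),
    )


_SIM_KEYS = {
    "ground_truth",
    "snr_levels",
    "snr_min",
    "snr_max",
    "snr_step",
    "n_realizations",
    "averaging_factors",
    "methods",
    "seed",
    "split_threshold",
    "average_directions",
}


def _parse_simulation(d: dict, grids: GridSpec, bounds: FitBounds) -> SimulationConfig:
    _reject_unknown(d, _SIM_KEYS, "simulation")
    if "snr_levels" in d:
        snr_levels = tuple(float(s) for s in d["snr_levels"])
    else:
        lo = float(d.get("snr_min", 15))
        hi = float(d.get("snr_max", 50))
        step = float(d.get("snr_step", 1))
        snr_levels = tuple(np.arange(lo, hi + step / 2, step))
    kw = dict(
        snr_levels=snr_levels,
        n_realizations=int(d.get("n_realizations", SimulationConfig.n_realizations)),
        averaging_factors=tuple(d.get("averaging_factors", (1, 8, 27, 64))),
        methods=tuple(d.get("methods", ("grid_search", "segmented", "one_step"))),
        seed=int(d.get("seed", 0)),
        split_threshold=float(d.get("split_threshold", 250.0)),
        average_directions=bool(d.get("average_directions", False)),
        grids=grids,
        bounds=bounds,
    )
    if "ground_truth" in d:
        kw["ground_truth"] = _parse_ground_truth(d["ground_truth"])
    return SimulationConfig(**kw)


def _parse_phantom(d: dict) -> PhantomSpec:
    _reject_unknown(d, {"shape", "snr", "seed", "compartments", "mixing", "mixing_width"}, "phantom")
    kw = {}
    if "shape" in d:
        kw["shape"] = tuple(int(s) for s in d["shape"])
    if "snr" in d:
        kw["snr"] = None if d["snr"] in (None, "none") else float(d["snr"])
    if "seed" in d:
        kw["seed"] = int(d["seed"])
    if "mixing" in d:
        kw["mixing"] = bool(d["mixing"])
    if "mixing_width" in d:
        kw["mixing_width"] = float(d["mixing_width"])
    if "compartments" in d:
        comps = {}
        for name, sec in d["compartments"].items():
            _reject_unknown(sec, {"s0", "f", "d_star", "d"}, f"phantom.compartments.{name}")
            comps[name] = IVIMParameters(
                s0=float(sec.get("s0", 1.0)),
                f=float(sec["f"]),
                d_star=float(sec["d_star"]),
                d=float(sec["d"]),
            )
        kw["compartments"] = comps
    return PhantomSpec(**kw)


@dataclass
class StudyConfig:
    """Validated top-level configuration assembled from a YAML file.

    Sections: ``simulation``, ``grids``, ``bounds``, ``phantom``,
    ``output`` (dir), ``log_level``.  Unknown keys anywhere are rejected
    before any computation starts.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    grids: GridSpec = field(default_factory=GridSpec.default)
    bounds: FitBounds = field(default_factory=FitBounds.default)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    output_dir: Path = Path("results")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: top level of the config must be a mapping")
        _reject_unknown(raw, {"simulation", "grids", "bounds", "phantom", "output", "log_level"}, "<top>")
        grids = _parse_grids(raw.get("grids", {}))
        bounds = _parse_bounds(raw.get("bounds", {}))
        sim = _parse_simulation(raw.get("simulation", {}), grids, bounds)
        phantom = _parse_phantom(raw.get("phantom", {}))
        out = raw.get("output", {})
        if out:
            _reject_unknown(out, {"dir"}, "output")
        return cls(
            simulation=sim,
            grids=grids,
            bounds=bounds,
            phantom=phantom,
            output_dir=Path(out.get("dir", "results")),
            log_level=str(raw.get("log_level", "INFO")),
        )

    def echo(self) -> str:
        """YAML rendering of the effective configuration, for logging."""

        def axis(a: GridAxis) -> dict:
            return {"min": a.start, "max": a.stop, "count": a.count, "spacing": a.spacing}

        doc = {
            "simulation": {
                "ground_truth": {
                    f.name: getattr(self.simulation.ground_truth, f.name)
                    for f in fields(IVIMParameters)
                },
                "snr_levels": list(self.simulation.snr_levels),
                "n_realizations": self.simulation.n_realizations,
                "averaging_factors": list(self.simulation.averaging_factors),
                "methods": list(self.simulation.methods),
                "seed": self.simulation.seed,
                "split_threshold": self.simulation.split_threshold,
                "average_directions": self.simulation.average_directions,
            },
            "grids": {n: axis(getattr(self.grids, n)) for n in ("s0_slow", "d", "s0_fast", "d_star")},
            "bounds": {
                n: {
                    "lower": getattr(self.bounds, n).lower,
                    "upper": getattr(self.bounds, n).upper,
                    "initial": getattr(self.bounds, n).initial,
                }
                for n in ("s0", "f", "d_star", "d")
            },
            "phantom": {
                "shape": list(self.phantom.shape),
                "snr": self.phantom.snr,
                "seed": self.phantom.seed,
                "mixing": self.phantom.mixing,
                "mixing_width": self.phantom.mixing_width,
                "compartments": {
                    name: {f.name: getattr(p, f.name) for f in fields(IVIMParameters)}
                    for name, p in self.phantom.compartments.items()
                },
            },
            "output": {"dir": str(self.output_dir)},
            "log_level": self.log_level,
        }
        return yaml.safe_dump(doc, sort_keys=False)
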