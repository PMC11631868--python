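"""Shared readers and writers: NIfTI volumes, CSV tables, run configuration.

Also exposes the bundled published volume-of-activation summary tables
(per-region group means, SEs, p-values and omega-squared for negative and
positive BOLD voxel counts across a 173-region atlas), used by the
significance-ranking stage and the reproduction scripts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import AtlasLabels, Bold4D, Window

__all__ = [
    "read_bold_nifti",
    "write_bold_nifti",
    "read_atlas_nifti",
    "write_atlas_nifti",
    "read_table",
    "write_table",
    "RunConfig",
    "load_reference_voa",
    "write_manifest",
]


def read_bold_nifti(path: str | Path, tr: float | None = None,
                    subject_id: str = "", group: str = "") -> Bold4D:
    """Load a 4D BOLD NIfTI-1 volume.

    The repetition time is taken from the header pixdim when not supplied.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got {data.ndim}D")
    if tr is None:
        tr = float(img.header.get_zooms()[3]) or 1.0
    return Bold4D(data, tr, subject_id or Path(path).stem, group)


def write_bold_nifti(bold: Bold4D, path: str | Path) -> None:
    img = nib.Nifti1Image(bold.data.astype(np.float64), affine=np.eye(4))
    zooms = list(img.header.get_zooms())
    zooms[3] = bold.tr
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_atlas_nifti(label_path: str | Path, region_table_path: str | Path) -> AtlasLabels:
    """Load an integer label volume plus its region lookup CSV."""
    img = nib.load(str(label_path))
    labels = np.asarray(img.dataobj)
    if not np.allclose(labels, np.round(labels)):
        raise ValueError(f"{label_path}: label volume is not integer-valued")
    regions = read_table(region_table_path, required=("id", "name"))
    return AtlasLabels(labels.astype(np.int32), regions)


def write_atlas_nifti(atlas: AtlasLabels, label_path: str | Path,
                      region_table_path: str | Path) -> None:
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int32), affine=np.eye(4)), str(label_path))
    write_table(atlas.regions, region_table_path)


def read_table(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a CSV table with a header row; validate required columns."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty input file")
    frame = pd.read_csv(path)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return frame


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a CSV deterministically (stable column order, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Pipeline thresholds and windows; defaults are the published settings."""

    baseline_window: Window = (5, 45)
    response_window: Window = (150, 200)
    q: float = 0.2
    c_v: float = 1.0
    threshold_pct: float = 1.0
    zcut: float = 2.3
    band: tuple[float, float] = (0.01, 0.1)
    alpha: float = 0.05
    knn_k: int = 5
    n_required: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.q <= 1:
            raise ValueError("q must lie in (0, 1]")
        if self.c_v <= 0:
            raise ValueError("c(V) must be positive")
        if self.threshold_pct < 0 or self.zcut < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("band must satisfy 0 < low < high")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("baseline_window", "response_window", "band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_reference_voa(sign: str = "negative") -> pd.DataFrame:
    """Load the bundled per-region volume-of-activation summary table.

    ``sign`` selects the negative- or positive-BOLD table.  Columns: region,
    per-group mean and SE (vehicle, 3, 10, 30 mg/kg), p_value, omega_sq.
    """
    if sign not in ("negative", "positive"):
        raise ValueError("sign must be 'negative' or 'positive'")
    ref = resources.files("phmrikit.data") / f"{sign}_voa.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def write_manifest(out_dir: str | Path, config: RunConfig, extra: dict | None = None) -> Path:
    """Write a JSON provenance manifest (config hash, seed, package version)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=list))
    return path
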