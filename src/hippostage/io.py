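"""Format readers/writers and run configuration.

Cohort tables travel as plain CSV (small, human-auditable); volumes and
masks as NIfTI with voxel spacing taken from the header; results as
JSON/CSV with the resolved run configuration embedded for provenance.
All writes are atomic (write to a temp file in the target directory,
then rename), so an interrupted run never leaves a truncated artifact.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import COHORT_COLUMNS, CSF_COLUMNS, LABELS
from .preproc import SegmentationMask, Volume3D

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "read_nifti",
    "write_nifti",
    "RunConfig",
    "atomic_write_text",
    "write_results_json",
]

logger = logging.getLogger(__name__)

_MANDATORY = ("subject_id", "label", "vol_left_mm3", "vol_right_mm3", "vol_total_mm3")


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text atomically: temp file in the same directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV; missing CSF panels become empty cells."""
    out = cohort[list(COHORT_COLUMNS)]
    atomic_write_text(path, out.to_csv(index=False))


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Empty CSF cells mean a missing panel.  Rows with missing mandatory
    fields, unknown labels, or non-positive volumes are rejected with a
    row-numbered error (row numbers are 1-based and count the header).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing_cols = [c for c in _MANDATORY if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing mandatory columns {missing_cols}")
    for c in CSF_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    for row_pos, (_, row) in enumerate(df.iterrows(), start=2):
        for c in _MANDATORY:
            if pd.isna(row[c]):
                raise ValueError(f"{path}:{row_pos}: missing value in column {c!r}")
        if row["label"] not in LABELS:
            raise ValueError(
                f"{path}:{row_pos}: unknown label {row['label']!r} (expected one of {LABELS})"
            )
        for c in ("vol_left_mm3", "vol_right_mm3", "vol_total_mm3"):
            v = row[c]
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{path}:{row_pos}: non-positive volume {c}={v}")
        csf = [row[c] for c in CSF_COLUMNS]
        if any(pd.isna(v) for v in csf) and not all(pd.isna(v) for v in csf):
            raise ValueError(f"{path}:{row_pos}: partially missing CSF panel")
        for c, v in zip(CSF_COLUMNS, csf):
            if not pd.isna(v) and v <= 0:
                raise ValueError(f"{path}:{row_pos}: non-positive CSF value {c}={v}")
    n_missing = int(df[list(CSF_COLUMNS)].isna().all(axis=1).sum())
    if n_missing:
        logger.info("%s: %d of %d records lack a CSF panel", path, n_missing, len(df))
    return df[list(COHORT_COLUMNS)]


# ---------------------------------------------------------------------------
# NIfTI


def write_nifti(vol: Volume3D, path: str | Path) -> None:
    """Write a volume/mask as NIfTI; spacing goes into the header zooms."""
    import nibabel as nib

    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.grid.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def read_nifti(path: str | Path, as_mask: bool = False) -> Volume3D:
    """Read a 3D NIfTI into a :class:`Volume3D` (or validated mask).

    Spacing comes from the header zooms; non-3D images are rejected, and
    masks must hold probabilities in [0, 1].
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid voxel spacing {zooms}")
    spacing = tuple(float(z) for z in zooms)
    if as_mask:
        return SegmentationMask(data, spacing)
    return Volume3D(data, spacing)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Resolved run settings, embedded into every results artifact."""

    variant: str = "hlm1"
    stage1_model: str = "extra_tree"
    stage2_model: str = "extra_tree"
    m: float = 2.0
    fuzz_mode: str = "univariate"
    ratio_tag: str = "ptau_over_abeta"
    train_fraction: float = 0.7
    stratified: bool = True
    augment_angles: list = field(default_factory=lambda: [-15.0, -10.0, -5.0, 5.0, 10.0, 15.0])
    augment_axis: str = "h"
    seed: int = 0
    verbosity: str = "info"

    @classmethod
    def from_mapping(cls, data: dict, overrides: dict | None = None) -> "RunConfig":
        """Build from a config mapping (YAML/JSON) with explicit-flag overrides.

        Unknown keys are rejected; ``overrides`` entries that are not
        None take precedence over the file values.
        """
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(data)
        for k, v in (overrides or {}).items():
            if v is not None:
                if k not in known:
                    raise ValueError(f"unknown config key {k!r}")
                merged[k] = v
        cfg = cls(**merged)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.variant not in ("hlm1", "hlm2"):
            raise ValueError(f"variant must be hlm1 or hlm2, got {self.variant!r}")
        if not 0 < self.train_fraction < 1:
            raise ValueError(f"train_fraction must be in (0,1), got {self.train_fraction}")
        if self.m <= 1:
            raise ValueError(f"fuzziness m must be > 1, got {self.m}")
        if self.fuzz_mode not in ("univariate", "multivariate"):
            raise ValueError(f"unknown fuzz_mode {self.fuzz_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def write_results_json(path: str | Path, results: dict, config: RunConfig | None = None) -> None:
    """Write a results artifact with embedded config and package version."""
    payload = {
        "package": "hippostage",
        "version": __version__,
        "config": config.to_dict() if config else None,
        "results": results,
    }
    atomic_write_text(path, json.dumps(payload, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
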