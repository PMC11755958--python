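"""Seeded synthetic cohort generator.

The real cohort behind this kind of staging study (ADNI) is
access-restricted, so the package ships a generator that reproduces the
*statistical structure* the cascade assumes rather than any real
measurements: three diagnostic groups (NC, MCI, AD) with hippocampal
volume falling and CSF amyloid-beta 42 falling, total tau and
phosphorylated tau rising, from NC through MCI to AD.  Default group
sizes are 215 AD / 204 NC / 211 MCI (630 subjects), with a fraction of
subjects missing the CSF panel so that about 500 complete panels remain.

All marker values are drawn from truncated-at-zero Gaussians (volumes in
mm^3 and CSF concentrations in pg/mL are strictly positive); the two tau
markers are drawn jointly with a positive correlation.  The numeric
default means are synthetic configuration values chosen to sit in a
plausible clinical range with adjacent-group overlap of roughly 1-2 SD
per feature; they are not measurements from any cohort.

Cohorts are plain pandas DataFrames with columns::

    subject_id, label, vol_left_mm3, vol_right_mm3, vol_total_mm3,
    abeta_pg_ml, t_tau_pg_ml, p_tau_pg_ml

where empty / NaN CSF cells mean the panel is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "GroupParams",
    "CohortSpec",
    "generate_cohort",
    "generate_volume_phantom",
    "COHORT_COLUMNS",
    "CSF_COLUMNS",
    "LABELS",
]

LABELS = ("NC", "MCI", "AD")
CSF_COLUMNS = ("abeta_pg_ml", "t_tau_pg_ml", "p_tau_pg_ml")
COHORT_COLUMNS = (
    "subject_id",
    "label",
    "vol_left_mm3",
    "vol_right_mm3",
    "vol_total_mm3",
    "abeta_pg_ml",
    "t_tau_pg_ml",
    "p_tau_pg_ml",
)


@dataclass
class GroupParams:
    """Per-group marker means and SDs (volumes mm^3, CSF pg/mL)."""

    vol_left_mean: float
    vol_right_mean: float
    vol_sd: float
    abeta_mean: float
    abeta_sd: float
    t_tau_mean: float
    t_tau_sd: float
    p_tau_mean: float
    p_tau_sd: float


#: Synthetic defaults.  Hippocampal volume shrinks NC -> MCI -> AD with the
#: NC/MCI gap wider than the MCI/AD gap (early atrophy separates controls
#: from the symptomatic pool); abeta falls while the taus rise.
DEFAULT_GROUPS: dict[str, GroupParams] = {
    "NC": GroupParams(3700.0, 3600.0, 215.0, 1100.0, 170.0, 240.0, 55.0, 22.0, 5.5),
    "MCI": GroupParams(3075.0, 2975.0, 215.0, 850.0, 170.0, 320.0, 55.0, 30.0, 5.5),
    "AD": GroupParams(2700.0, 2600.0, 215.0, 600.0, 170.0, 400.0, 55.0, 38.0, 5.5),
}


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort.

    Defaults reproduce the study conditions emulated here: group sizes
    (NC 204, MCI 211, AD 215; 630 total), about 500 of 630 subjects with
    a complete CSF panel, and the canonical marker orderings.
    """

    n_nc: int = 204
    n_mci: int = 211
    n_ad: int = 215
    groups: dict[str, GroupParams] = field(
        default_factory=lambda: {k: GroupParams(**asdict(v)) for k, v in DEFAULT_GROUPS.items()}
    )
    tau_correlation: float = 0.7
    csf_missing_rate: float = 130.0 / 630.0
    seed: int = 0

    def validate(self) -> None:
        for name, n in (("n_nc", self.n_nc), ("n_mci", self.n_mci), ("n_ad", self.n_ad)):
            if n < 0 or int(n) != n:
                raise ValueError(f"{name} must be a nonnegative integer, got {n}")
        if not 0.0 <= self.csf_missing_rate <= 1.0:
            raise ValueError(f"csf_missing_rate must be in [0, 1], got {self.csf_missing_rate}")
        if not -1.0 < self.tau_correlation < 1.0:
            raise ValueError(f"tau_correlation must be in (-1, 1), got {self.tau_correlation}")
        for label in LABELS:
            if label not in self.groups:
                raise ValueError(f"missing group parameters for {label}")
            g = self.groups[label]
            for fname, val in asdict(g).items():
                if fname.endswith("_sd") and val <= 0:
                    raise ValueError(f"{label}.{fname} must be > 0, got {val}")
                if fname.endswith("_mean") and val <= 0:
                    raise ValueError(f"{label}.{fname} must be > 0, got {val}")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Gaussian truncated at zero by resampling (means sit many SDs above 0)."""
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def _truncated_bivariate(
    rng: np.random.Generator,
    means: tuple[float, float],
    sds: tuple[float, float],
    corr: float,
    n: int,
) -> np.ndarray:
    cov = np.array(
        [
            [sds[0] ** 2, corr * sds[0] * sds[1]],
            [corr * sds[0] * sds[1], sds[1] ** 2],
        ]
    )
    L = np.linalg.cholesky(cov)
    out = np.asarray(means) + rng.standard_normal((n, 2)) @ L.T
    bad = (out <= 0).any(axis=1)
    while bad.any():
        k = int(bad.sum())
        out[bad] = np.asarray(means) + rng.standard_normal((k, 2)) @ L.T
        bad = (out <= 0).any(axis=1)
    return out


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Generate a synthetic cohort table from ``spec``.

    Deterministic in ``spec.seed``: the same spec yields a bit-identical
    table across runs.  Subjects with a missing CSF panel carry NaN in
    all three CSF columns.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    frames = []
    sizes = {"NC": spec.n_nc, "MCI": spec.n_mci, "AD": spec.n_ad}
    for label in LABELS:
        n = sizes[label]
        g = spec.groups[label]
        left = _truncated_normal(rng, g.vol_left_mean, g.vol_sd, n)
        right = _truncated_normal(rng, g.vol_right_mean, g.vol_sd, n)
        abeta = _truncated_normal(rng, g.abeta_mean, g.abeta_sd, n)
        taus = _truncated_bivariate(
            rng,
            (g.t_tau_mean, g.p_tau_mean),
            (g.t_tau_sd, g.p_tau_sd),
            spec.tau_correlation,
            n,
        )
        missing = rng.random(n) < spec.csf_missing_rate
        abeta[missing] = np.nan
        taus[missing] = np.nan
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{label}_{i:04d}" for i in range(n)],
                    "label": label,
                    "vol_left_mm3": left,
                    "vol_right_mm3": right,
                    "vol_total_mm3": left + right,
                    "abeta_pg_ml": abeta,
                    "t_tau_pg_ml": taus[:, 0],
                    "p_tau_pg_ml": taus[:, 1],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=list(COHORT_COLUMNS))
    table = pd.concat(frames, ignore_index=True)
    return table


# ---------------------------------------------------------------------------
# volume phantoms


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return (acc <= 1.0).astype(float)


#: phantom hippocampus size scale per diagnostic group (NC > MCI > AD)
_PHANTOM_SCALE = {"NC": 1.0, "MCI": 0.85, "AD": 0.72}


def generate_volume_phantom(
    label: str,
    dims: tuple[int, int, int] = (32, 32, 32),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
):
    """Build a toy 3D image with two ellipsoidal "hippocampi" plus masks.

    Returns ``(volume, left_mask, right_mask)`` as
    :class:`~hippostage.preproc.Volume3D` / ``SegmentationMask``.  The
    ellipsoid sizes scale NC > MCI > AD, the masks are binary probability
    grids exactly covering the blobs, so mask-derived volumetry equals
    blob voxel count times the voxel volume by construction.
    """
    from .preproc import Volume3D, SegmentationMask  # avoid circular import

    if label not in _PHANTOM_SCALE:
        raise ValueError(f"label must be one of {sorted(_PHANTOM_SCALE)}, got {label!r}")
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or any(d < 8 for d in dims):
        raise ValueError(f"dims must be a triple with every entry >= 8, got {dims}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive, got {spacing}")

    rng = np.random.default_rng(seed)
    scale = _PHANTOM_SCALE[label]
    semi = tuple(max(1.0, 0.18 * d * scale) for d in dims)
    center_r = (dims[0] - 1) / 2.0
    center_h = (dims[2] - 1) / 2.0
    left_c = (dims[1] - 1) * 0.28
    right_c = (dims[1] - 1) * 0.72
    left = _ellipsoid_mask(dims, (center_r, left_c, center_h), semi)
    right = _ellipsoid_mask(dims, (center_r, right_c, center_h), semi)
    if left.sum() == 0 or right.sum() == 0:
        raise ValueError(f"dims {dims} too small to contain the phantom blobs")
    if (left * right).any():
        raise ValueError(f"dims {dims} too small: left/right blobs overlap")
    background = 0.05 * rng.random(dims)
    image = background + 0.9 * (left + right)
    return (
        Volume3D(image, spacing),
        SegmentationMask(left, spacing),
        SegmentationMask(right, spacing),
    )
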