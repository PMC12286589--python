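"""Skeletal mass tables and the fraction arithmetic built on them.

The dosimetric model is anchored to the JM-103 reference-voxel-phantom mass
bookkeeping for the cervical vertebrae: how much of a bone site is red bone
marrow (RBM), how much blood that marrow holds, and what share of the marrow
blood sits in the wide sinusoidal capillaries where the haematopoietic
stem-cell (HSC) layer is assumed to live.  Three small pieces of arithmetic
feed the rest of the pipeline:

* the sinusoid share of marrow blood, from vessel morphometry (segment counts
  and mean diameters per vessel class),
* the fraction of whole-body blood resident in RBM (blood mass x RBM share of
  bone blood / RBM mass),
* the share of whole-body-blood decays apportioned to the cervical RBM blood
  pool (site RBM-blood mass / total blood mass).

All report values are rounded half-away-from-zero to the precision customary
in the printed tables (percentages to 1 or 2 decimals); full precision is kept
internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_away

__all__ = [
    "BoneSiteMasses",
    "VesselClassRow",
    "vessel_cross_sections",
    "blood_in_rbm_fraction",
    "rbm_blood_share",
    "site_percentages",
    "load_site_masses",
    "load_cervical_masses",
    "load_vessel_classes",
    "cervical_totals",
    "read_mass_table",
    "write_mass_table",
    "read_vessel_table",
    "write_vessel_table",
    "RBM_BLOOD_DECAY_FRACTION",
]

#: Default apportionment of whole-body-blood decays to cervical RBM blood
#: (6.1 g cervical RBM blood / 3410 g total blood = 0.18%).
RBM_BLOOD_DECAY_FRACTION = 0.0018

_MASS_COLUMNS = [
    "site",
    "body_tissue_g",
    "rbm_g",
    "cortical_g",
    "trabecular_g",
    "soft_g",
    "blood_g",
]
_VESSEL_COLUMNS = ["class", "n_segments", "mean_diameter_um"]


@dataclass(frozen=True)
class BoneSiteMasses:
    """Masses (g) of one skeletal site's tissues and blood."""

    site_name: str
    body_tissue_g: float
    rbm_g: float
    cortical_g: float = 0.0
    trabecular_g: float = 0.0
    soft_g: float = 0.0
    blood_g: float = 0.0

    def __post_init__(self) -> None:
        for field in (
            "body_tissue_g",
            "rbm_g",
            "cortical_g",
            "trabecular_g",
            "soft_g",
            "blood_g",
        ):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be >= 0, got {getattr(self, field)}")


@dataclass(frozen=True)
class VesselClassRow:
    """One marrow vessel class: segment count and mean diameter (um)."""

    class_name: str
    n_segments: int
    mean_diameter_um: float

    def __post_init__(self) -> None:
        if self.n_segments < 0:
            raise ValueError("n_segments must be >= 0")
        if self.mean_diameter_um <= 0:
            raise ValueError("mean_diameter_um must be > 0")


def vessel_cross_sections(
    rows: Sequence[VesselClassRow], pi_value: float = 3.14
) -> pd.DataFrame:
    """Cross-sectional-area bookkeeping per vessel class.

    Per-vessel area is (d/2)^2 * ``pi_value``; the class total is that times
    the segment count; the share column is each class total as a percentage of
    the grand total.  ``pi_value`` defaults to 3.14 so the published
    morphometry table is reproduced digit for digit; pass ``math.pi`` for
    full-precision work.

    Returns a DataFrame with rounded report columns (1 decimal) plus
    ``*_exact`` columns at full precision; the grand total is stored in
    ``df.attrs["total_area_um2"]``.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("vessel_cross_sections requires at least one vessel class")
    if pi_value <= 0:
        raise ValueError("pi_value must be > 0")
    d = np.array([r.mean_diameter_um for r in rows], dtype=float)
    n = np.array([r.n_segments for r in rows], dtype=float)
    per_vessel = (d / 2.0) ** 2 * pi_value
    class_total = per_vessel * n
    total = float(class_total.sum())
    if total == 0.0:
        raise ZeroDivisionError("total cross-sectional area is zero")
    share = class_total / total * 100.0
    df = pd.DataFrame(
        {
            "class": [r.class_name for r in rows],
            "n_segments": n.astype(int),
            "mean_diameter_um": d,
            "per_vessel_area_um2": [round_half_away(v, 1) for v in per_vessel],
            "class_total_area_um2": [round_half_away(v, 1) for v in class_total],
            "share_pct": [round_half_away(v, 1) for v in share],
            "per_vessel_area_um2_exact": per_vessel,
            "class_total_area_um2_exact": class_total,
            "share_pct_exact": share,
        }
    )
    df.attrs["total_area_um2"] = total
    return df


def blood_in_rbm_fraction(
    total_blood_g: float, rbm_g: float, rbm_share_of_bone_blood: float
) -> float:
    """Percent of red-bone-marrow mass that is blood.

    ``total_blood_g x rbm_share_of_bone_blood / rbm_g x 100``, reported to one
    decimal.  The reference-share argument is the RBM portion of the skeletal
    blood pool (4/7 in the ICRP 89 bookkeeping: 7% of blood in bone tissue, of
    which 4 points are in RBM).
    """
    if rbm_g <= 0:
        raise ValueError("rbm_g must be > 0")
    if total_blood_g < 0:
        raise ValueError("total_blood_g must be >= 0")
    if not 0.0 <= rbm_share_of_bone_blood <= 1.0:
        raise ValueError("rbm_share_of_bone_blood must be in [0, 1]")
    return round_half_away(total_blood_g * rbm_share_of_bone_blood / rbm_g * 100.0, 1)


def rbm_blood_share(site_rbm_blood_g: float, whole_body_blood_g: float) -> float:
    """Site RBM-blood mass as a percentage of whole-body blood, to 2 decimals."""
    if whole_body_blood_g <= 0:
        raise ValueError("whole_body_blood_g must be > 0")
    if site_rbm_blood_g < 0:
        raise ValueError("site_rbm_blood_g must be >= 0")
    return round_half_away(site_rbm_blood_g / whole_body_blood_g * 100.0, 2)


def site_percentages(site: BoneSiteMasses) -> tuple[float, float]:
    """(RBM/body-tissue %, blood/body-tissue %) for a site, to 1 decimal each."""
    if site.body_tissue_g <= 0:
        raise ValueError("body_tissue_g must be > 0")
    rbm_pct = site.rbm_g / site.body_tissue_g * 100.0
    blood_pct = site.blood_g / site.body_tissue_g * 100.0
    return round_half_away(rbm_pct, 1), round_half_away(blood_pct, 1)


# ---------------------------------------------------------------------------
# Packaged tables and CSV round-trip


def _data_path(name: str):
    return resources.files("marrowdose.data").joinpath(name)


def load_site_masses() -> pd.DataFrame:
    """JM-103 whole-skeleton site masses (g), one row per anatomical site."""
    with resources.as_file(_data_path("jm103_site_masses.csv")) as p:
        return read_mass_table(p)


def load_cervical_masses() -> pd.DataFrame:
    """JM-103 cervical vertebra rows, including the blood-in-RBM column.

    Missing entries in the source table are NaN.  Totals are intentionally not
    included: the published totals differ from the row sums by up to 0.1 g
    (rounded-row arithmetic), so use :func:`cervical_totals` to recompute them.
    """
    with resources.as_file(_data_path("jm103_cervical_masses.csv")) as p:
        return pd.read_csv(p, encoding="utf-8")


def cervical_totals(df: pd.DataFrame | None = None) -> pd.Series:
    """Column sums of the cervical table recomputed from the packaged rows."""
    if df is None:
        df = load_cervical_masses()
    return df.drop(columns=["site"]).sum(skipna=True)


def load_vessel_classes() -> list[VesselClassRow]:
    """Mouse marrow vessel morphometry rows (per-class counts and diameters)."""
    with resources.as_file(_data_path("mouse_vessel_classes.csv")) as p:
        return read_vessel_table(p)


def read_mass_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in _MASS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mass table missing required columns: {missing}")
    return df[_MASS_COLUMNS]


def write_mass_table(df: pd.DataFrame, path: str | Path) -> None:
    df[_MASS_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def read_vessel_table(path: str | Path) -> list[VesselClassRow]:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in _VESSEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"vessel table missing required columns: {missing}")
    return [
        VesselClassRow(str(r["class"]), int(r["n_segments"]), float(r["mean_diameter_um"]))
        for _, r in df.iterrows()
    ]


def write_vessel_table(rows: Iterable[VesselClassRow], path: str | Path) -> None:
    pd.DataFrame(
        {
            "class": [r.class_name for r in rows],
            "n_segments": [r.n_segments for r in rows],
            "mean_diameter_um": [r.mean_diameter_um for r in rows],
        }
    ).to_csv(path, index=False, encoding="utf-8")


def mass_table_rows(df: pd.DataFrame) -> list[BoneSiteMasses]:
    """Convert a mass-table DataFrame to typed rows."""
    return [
        BoneSiteMasses(
            site_name=str(r["site"]),
            body_tissue_g=float(r["body_tissue_g"]),
            rbm_g=float(r["rbm_g"]),
            cortical_g=float(r["cortical_g"]),
            trabecular_g=float(r["trabecular_g"]),
            soft_g=float(r["soft_g"]),
            blood_g=float(r["blood_g"]),
        )
        for _, r in df.iterrows()
    ]
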