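"""First-order linear biokinetic compartment models with radioactive decay.

A unit intake (1 Bq, i.e. N0 = 1/lambda_s atoms) enters one compartment of a
first-order transfer network.  With M the transfer-rate matrix (entry (i, j)
is the j -> i flow, per day; diagonal the negative outflow sums) and lambda
the physical decay constant, the atom inventory obeys

    dN/dt = (M − lambda I) N,     N(0) = N0 e_intake,

and the number of decays in compartment i over [0, T] is
lambda ∫0..T N_i dt.  The integral is computed in closed form through the
augmented matrix exponential

    exp([[A, I], [0, 0]] T) = [[e^{AT}, ∫ e^{As} ds], [0, I]],  A = M − lambda I,

with a stiff adaptive ODE quadrature as fallback for pathological matrices.

Transfer matrices are user-supplied (edge-list CSV: ``from,to,rate_per_day``);
the package ships only synthetic fixtures, including a schematic radon-like
inhalation system used for noble gases.  For xenon and krypton the radon
system is reused with the lung -> blood transfer scaled by the relative
blood solubility (1/2 for Xe, 1/4 for Kr) and the gas's own decay constant.

Integration horizons follow the study convention: 15,800,000 min for
long-lived nuclides, 10,000 min for short-lived ones, with "long-lived"
meaning half-life >= 30 days (per-nuclide override available).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .nuclides import NuclideData

__all__ = [
    "CompartmentSystem",
    "DecayTally",
    "solve_decays",
    "noble_gas_from_radon",
    "rbm_blood_decays",
    "classify_horizon",
    "read_compartments_csv",
    "write_compartments_csv",
    "load_radon_demo_system",
    "LONG_HORIZON_MIN",
    "SHORT_HORIZON_MIN",
    "RBM_BLOOD_DECAY_FRACTION",
]

LONG_HORIZON_MIN = 15_800_000.0
SHORT_HORIZON_MIN = 10_000.0
LONG_LIVED_THRESHOLD_DAYS = 30.0

#: Share of whole-body-blood decays assigned to the cervical RBM blood pool
#: (6.1 g / 3410 g).
RBM_BLOOD_DECAY_FRACTION = 0.0018


@dataclass(frozen=True)
class CompartmentSystem:
    """A validated compartment network plus decay constant and intake."""

    names: tuple[str, ...]
    matrix: np.ndarray  # (i, j) = rate j -> i, per day; diagonal = -outflows
    decay_constant_per_day: float
    intake_compartment: str
    intake_bq: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.names)
        if m.shape != (n, n):
            raise ValueError("matrix shape must match the compartment list")
        off = m.copy()
        np.fill_diagonal(off, 0.0)
        if (off < 0).any():
            raise ValueError("off-diagonal transfer rates must be >= 0")
        if not np.allclose(np.diag(m), -off.sum(axis=0), rtol=1e-9, atol=1e-12):
            raise ValueError("diagonal must equal minus the column outflow sums")
        if self.decay_constant_per_day <= 0:
            raise ValueError("decay constant must be > 0")
        if self.intake_compartment not in self.names:
            raise ValueError(f"unknown intake compartment {self.intake_compartment!r}")
        if self.intake_bq < 0:
            raise ValueError("intake_bq must be >= 0")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def rate(self, frm: str, to: str) -> float:
        return float(self.matrix[self.index(to), self.index(frm)])

    def with_rate(self, frm: str, to: str, rate: float) -> "CompartmentSystem":
        """Copy with one edge rate replaced (diagonal rebalanced)."""
        m = self.matrix.copy()
        i, j = self.index(to), self.index(frm)
        m[i, j] = rate
        np.fill_diagonal(m, 0.0)
        np.fill_diagonal(m, -m.sum(axis=0))
        return replace(self, matrix=m)

    @classmethod
    def from_edges(
        cls,
        names: Sequence[str],
        edges: Sequence[tuple[str, str, float]],
        decay_constant_per_day: float,
        intake_compartment: str,
        intake_bq: float = 1.0,
    ) -> "CompartmentSystem":
        names = tuple(names)
        n = len(names)
        m = np.zeros((n, n))
        idx = {nm: i for i, nm in enumerate(names)}
        for frm, to, rate in edges:
            if frm not in idx or to not in idx:
                raise ValueError(f"edge ({frm} -> {to}) references unknown compartment")
            if rate < 0:
                raise ValueError("transfer rates must be >= 0")
            m[idx[to], idx[frm]] += rate
        np.fill_diagonal(m, -m.sum(axis=0))
        return cls(names, m, decay_constant_per_day, intake_compartment, intake_bq)


@dataclass(frozen=True)
class DecayTally:
    """Decays per compartment over [0, T] for the configured intake."""

    names: tuple[str, ...]
    decays: np.ndarray
    horizon_min: float
    residual_atoms: np.ndarray
    intake_bq: float

    def __getitem__(self, name: str) -> float:
        return float(self.decays[self.names.index(name)])

    @property
    def total_decays(self) -> float:
        return float(self.decays.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.decays, index=list(self.names), name="decays")


def _initial_atoms(system: CompartmentSystem) -> np.ndarray:
    lam_s = system.decay_constant_per_day / 86400.0
    n0 = np.zeros(system.n)
    n0[system.index(system.intake_compartment)] = system.intake_bq / lam_s
    return n0


def solve_decays(system: CompartmentSystem, horizon_min: float) -> DecayTally:
    """Decays per compartment over [0, horizon] via the augmented expm.

    Falls back to stiff adaptive quadrature (``solve_ivp`` on the augmented
    state) if the exponential evaluates to a non-finite result.
    """
    if horizon_min <= 0:
        raise ValueError("horizon must be > 0")
    t_days = horizon_min / 1440.0
    lam = system.decay_constant_per_day
    a = system.matrix - lam * np.eye(system.n)
    n0 = _initial_atoms(system)

    big = np.zeros((2 * system.n, 2 * system.n))
    big[: system.n, : system.n] = a
    big[: system.n, system.n :] = np.eye(system.n)
    try:
        e = expm(big * t_days)
        phi = e[: system.n, : system.n]
        integ = e[: system.n, system.n :]
        if not (np.isfinite(phi).all() and np.isfinite(integ).all()):
            raise FloatingPointError("non-finite matrix exponential")
        n_t = phi @ n0
        int_n = integ @ n0  # atom-days per compartment
    except (FloatingPointError, ValueError):
        n_t, int_n = _quadrature_fallback(a, n0, t_days)

    decays = lam * int_n
    return DecayTally(
        names=system.names,
        decays=np.maximum(decays, 0.0),
        horizon_min=horizon_min,
        residual_atoms=np.maximum(n_t, 0.0),
        intake_bq=system.intake_bq,
    )


def _quadrature_fallback(a, n0, t_days):
    n = len(n0)

    def rhs(_, y):
        return np.concatenate([a @ y[:n], y[:n]])

    sol = solve_ivp(
        rhs,
        (0.0, t_days),
        np.concatenate([n0, np.zeros(n)]),
        method="LSODA",
        rtol=1e-10,
        atol=1e-6 * max(n0.max(), 1.0),
    )
    if not sol.success:
        raise RuntimeError(f"fallback quadrature failed: {sol.message}")
    return sol.y[:n, -1], sol.y[n:, -1]


def noble_gas_from_radon(
    radon_system: CompartmentSystem,
    gas: str,
    half_life_s: float,
    *,
    lung: str = "lung",
    blood: str = "blood",
) -> CompartmentSystem:
    """Derive a noble-gas system from the radon one by solubility scaling.

    The lung -> blood transfer is multiplied by 1/2 for xenon or 1/4 for
    krypton (relative blood solubilities), and the decay constant is replaced
    by the gas's own.  Everything else is copied unchanged.
    """
    factors = {"xe": 0.5, "kr": 0.25}
    key = gas.strip().lower()[:2]
    if key not in factors:
        raise ValueError(f"gas must be Xe or Kr, got {gas!r}")
    if half_life_s <= 0:
        raise ValueError("half_life_s must be > 0")
    if lung not in radon_system.names or blood not in radon_system.names:
        raise ValueError("radon system must contain lung and blood compartments")
    base = radon_system.rate(lung, blood)
    if base <= 0:
        raise ValueError("radon system has no lung -> blood transfer")
    out = radon_system.with_rate(lung, blood, base * factors[key])
    return replace(out, decay_constant_per_day=np.log(2.0) / half_life_s * 86400.0)


def rbm_blood_decays(
    whole_blood_decays: float, fraction: float = RBM_BLOOD_DECAY_FRACTION
) -> float:
    """Decays in the cervical RBM blood pool from whole-body-blood decays."""
    if whole_blood_decays < 0:
        raise ValueError("decay count must be >= 0")
    return fraction * whole_blood_decays


def classify_horizon(
    nuclide: NuclideData | float,
    *,
    threshold_days: float = LONG_LIVED_THRESHOLD_DAYS,
    override: Mapping[str, float] | None = None,
) -> float:
    """Integration horizon (minutes) for a nuclide or bare half-life (s).

    Half-life >= ``threshold_days`` selects the long horizon.  ``override``
    maps nuclide names to explicit horizons for cases where the convention is
    ambiguous (e.g. an 8-day nuclide analysed on the long horizon).
    """
    if isinstance(nuclide, NuclideData):
        if override and nuclide.name in override:
            return float(override[nuclide.name])
        half_life_s = nuclide.half_life_s
    else:
        half_life_s = float(nuclide)
    if half_life_s <= 0:
        raise ValueError("half-life must be > 0")
    return (
        LONG_HORIZON_MIN
        if half_life_s >= threshold_days * 86400.0
        else SHORT_HORIZON_MIN
    )


# ---------------------------------------------------------------------------
# CSV interchange


def read_compartments_csv(
    path: str | Path,
    decay_constant_per_day: float,
    intake_compartment: str,
    intake_bq: float = 1.0,
) -> CompartmentSystem:
    """Build a system from an edge-list CSV with columns from,to,rate_per_day."""
    df = pd.read_csv(path, comment="#")
    need = ["from", "to", "rate_per_day"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"compartment CSV missing columns: {missing}")
    names: list[str] = []
    for nm in pd.concat([df["from"], df["to"]]):
        if nm not in names:
            names.append(str(nm))
    edges = [
        (str(r["from"]), str(r["to"]), float(r["rate_per_day"]))
        for _, r in df.iterrows()
    ]
    return CompartmentSystem.from_edges(
        names, edges, decay_constant_per_day, intake_compartment, intake_bq
    )


def write_compartments_csv(system: CompartmentSystem, path: str | Path) -> None:
    rows = []
    for j, frm in enumerate(system.names):
        for i, to in enumerate(system.names):
            if i != j and system.matrix[i, j] > 0:
                rows.append({"from": frm, "to": to, "rate_per_day": system.matrix[i, j]})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_radon_demo_system(
    decay_constant_per_day: float | None = None, intake_bq: float = 1.0
) -> CompartmentSystem:
    """The packaged schematic radon-like inhalation system (synthetic rates).

    Compartments: lung, blood, fat, soft_tissue and an excreta sink.  The
    rates are plausible in ordering (fast alveolar exchange, preferential fat
    partitioning, exhalation dominating) but are synthetic placeholders, not
    a fitted or reference model.  Defaults to the radon decay constant.
    """
    if decay_constant_per_day is None:
        decay_constant_per_day = np.log(2.0) / 330350.0 * 86400.0  # Rn-222
    with resources.as_file(
        resources.files("marrowdose.data").joinpath("compartments_radon_synthetic.csv")
    ) as p:
        return read_compartments_csv(
            p, decay_constant_per_day, intake_compartment="lung", intake_bq=intake_bq
        )
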