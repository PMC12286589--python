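"""Generators for self-contained fixtures: compartment systems, toy nuclides,
toy SAF tables and reduced geometry specs.

The statistical structure the pipeline relies on is deliberately minimal —
first-order linear kinetics with radioactive decay, and uniform source
sampling inside geometric regions — and the fixtures emulate exactly that:

* :func:`gen_compartments` draws random Metzler-structured transfer matrices
  with an intake compartment and an excreta sink, and returns an independent
  eigendecomposition-based solution record alongside, so the matrix-
  exponential solver can be checked against closed-form arithmetic.
* :func:`gen_toy_nuclide` emits schema-valid single/few-line nuclides.
* :func:`gen_reduced_geometry` shrinks the vessel lattice while preserving
  every invariant, so Monte Carlo tests finish in seconds.

All generators are deterministic under a fixed seed; :func:`write_fixture_set`
writes a directory of fixtures plus a manifest with seeds and content hashes.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np

from .biokinetics import CompartmentSystem, write_compartments_csv
from .geometry import GeometrySpec
from .nuclides import NuclideData
from .geometry import RegionLabel

__all__ = [
    "gen_compartments",
    "analytic_decays",
    "gen_toy_nuclide",
    "gen_saf_table",
    "gen_reduced_geometry",
    "write_fixture_set",
]


def gen_compartments(
    n: int,
    connectivity: float = 0.5,
    seed: int = 0,
    *,
    half_life_s: float = 86400.0,
    intake_bq: float = 1.0,
    horizon_min: float = 10_000.0,
) -> tuple[CompartmentSystem, dict]:
    """Random ``n``-compartment system (plus excreta sink) with analytic record.

    Off-diagonal rates are lognormal, present with probability
    ``connectivity``; every compartment gets a small excretion pathway so the
    chain is never trapped.  Regenerates (next substream) until the intake
    compartment reaches at least one other compartment when ``n > 1``.

    Returns ``(system, record)`` where ``record`` holds the eigendecomposition
    solution of the decay counts at ``horizon_min`` — an arithmetic route
    independent of the matrix-exponential solver.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= connectivity <= 1.0:
        raise ValueError("connectivity must be in [0, 1]")
    lam = math.log(2.0) / half_life_s * 86400.0
    for attempt in range(64):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        names = tuple(f"c{i}" for i in range(n)) + ("excreta",)
        m = np.zeros((n + 1, n + 1))
        for j in range(n):
            for i in range(n):
                if i != j and rng.random() < connectivity:
                    m[i, j] = rng.lognormal(mean=-0.7, sigma=1.0)
            m[n, j] = rng.lognormal(mean=-2.0, sigma=0.5)  # excretion
        np.fill_diagonal(m, -m.sum(axis=0))
        reachable = _reachable_from(m, 0)
        if n == 1 or len(reachable & set(range(1, n))) > 0:
            system = CompartmentSystem(names, m, lam, "c0", intake_bq)
            record = {
                "seed": seed,
                "attempt": attempt,
                "horizon_min": horizon_min,
                "decays": analytic_decays(system, horizon_min).tolist(),
                "method": "eigendecomposition",
            }
            return system, record
    raise RuntimeError("could not generate a connected system")


def _reachable_from(m: np.ndarray, start: int) -> set[int]:
    n = m.shape[0]
    seen = {start}
    stack = [start]
    while stack:
        j = stack.pop()
        for i in range(n):
            if i != j and m[i, j] > 0 and i not in seen:
                seen.add(i)
                stack.append(i)
    return seen


def analytic_decays(system: CompartmentSystem, horizon_min: float) -> np.ndarray:
    """Decay counts via dense eigendecomposition (closed-form time integral).

    ``decays = lambda V diag((e^{mu T} - 1)/mu) V^{-1} N0`` with
    ``mu`` the eigenvalues of ``M - lambda I`` (all nonzero because of the
    decay shift).  Used as an independent arithmetic route in tests.
    """
    t = horizon_min / 1440.0
    lam = system.decay_constant_per_day
    a = system.matrix - lam * np.eye(system.n)
    lam_s = lam / 86400.0
    n0 = np.zeros(system.n)
    n0[system.index(system.intake_compartment)] = system.intake_bq / lam_s
    mu, v = np.linalg.eig(a)
    coef = np.linalg.solve(v, n0.astype(complex))
    integral = v @ (coef * (np.exp(mu * t) - 1.0) / mu)
    return np.maximum((lam * integral).real, 0.0)


def gen_toy_nuclide(mode: str, energy_scale: float = 1.0, seed: int = 0) -> NuclideData:
    """Schema-valid toy nuclide with 1–3 emissions, yields summing to <= 1.2."""
    if mode not in ("alpha", "beta"):
        raise ValueError("mode must be 'alpha' or 'beta'")
    if energy_scale <= 0:
        raise ValueError("energy_scale must be > 0")
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, 4))
    yields = rng.dirichlet(np.ones(k)) * float(rng.uniform(0.8, 1.2))
    half_life = float(rng.uniform(3600.0, 3.2e8))
    if mode == "alpha":
        energies = np.sort(rng.uniform(3.5, 6.5, size=k))[::-1] * energy_scale
        return NuclideData(
            name=f"toy-alpha-{seed}",
            half_life_s=half_life,
            mode="alpha",
            alpha_lines=tuple((float(e), float(y)) for e, y in zip(energies, yields)),
        )
    endpoints = np.sort(rng.uniform(0.2, 2.3, size=k))[::-1] * energy_scale
    z = int(rng.integers(30, 90))
    return NuclideData(
        name=f"toy-beta-{seed}",
        half_life_s=half_life,
        mode="beta",
        beta_branches=tuple(
            (float(e), float(y), z) for e, y in zip(endpoints, yields)
        ),
    )


def gen_saf_table(seed: int = 0) -> dict[RegionLabel, float]:
    """Toy SAF table (1/kg) over all source regions, lognormal magnitudes."""
    rng = np.random.default_rng(seed)
    return {r: float(rng.lognormal(mean=0.0, sigma=1.0)) for r in RegionLabel}


def gen_reduced_geometry(scale_factor: float) -> GeometrySpec:
    """Desk-scale lattice: same cell dimensions, fewer vessels and cells.

    ``scale_factor = 1`` reproduces the full default configuration (1600
    cells, 40,000 vessels, 3x3 modeled block of 25-vessel cells).  Smaller
    factors shrink the vessel grid side and modeled block while keeping every
    spec invariant (perfect-square counts, consistent totals, non-overlapping
    shells); total volume scales linearly with the cell count by construction.
    """
    if not 0.0 < scale_factor <= 1.0:
        raise ValueError("scale_factor must be in (0, 1]")
    m = max(1, round(5 * scale_factor))
    g = max(1, round(3 * scale_factor))
    vessels_per_cell = m * m
    modeled = g * g
    n_cells = max(modeled, round(1600 * scale_factor**3))
    return GeometrySpec(
        vessels_per_cell=vessels_per_cell,
        modeled_grids=modeled,
        n_cells_total=n_cells,
        total_vessels=n_cells * vessels_per_cell,
    )


def write_fixture_set(outdir: str | Path, seed: int = 0) -> dict:
    """Write a directory of fixtures plus a manifest (seeds and SHA-256 hashes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    system, record = gen_compartments(5, 0.5, seed)
    write_compartments_csv(system, outdir / "compartments.csv")
    (outdir / "compartments_solution.json").write_text(
        json.dumps(record, indent=2), encoding="utf-8"
    )
    gen_toy_nuclide("alpha", seed=seed).to_json(outdir / "toy_alpha.json")
    gen_toy_nuclide("beta", seed=seed).to_json(outdir / "toy_beta.json")
    gen_reduced_geometry(0.2).to_json(outdir / "geometry_reduced.json")
    saf = {r.name: v for r, v in gen_saf_table(seed).items()}
    (outdir / "saf_toy.json").write_text(json.dumps(saf, indent=2), encoding="utf-8")

    for p in sorted(outdir.iterdir()):
        if p.name != "manifest.json":
            files[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {"seed": seed, "files": files}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8"
    )
    return manifest
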