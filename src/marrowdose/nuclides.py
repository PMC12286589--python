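"""Decay data for the study nuclides and emission sampling for transport.

Each nuclide carries a half-life, a particle mode (``alpha``, ``beta`` or
``noble_gas_beta``), discrete alpha lines, beta branches (endpoint energy,
yield, daughter atomic number) and discrete electron lines (conversion/Auger
electrons).  Beta energies are drawn from the allowed-transition spectrum

    N(E) dE  ∝  p W (Q − E)^2 F(Z, W) dE,

with ``W = E + m_e c^2`` the total energy, ``p`` the momentum and ``F`` the
non-relativistic Fermi function ``F = 2πη / (1 − e^{−2πη})``,
``η = αZW/(pc)`` for β⁻ decay.  Noble gases are transported as beta emitters.

The packaged files under ``data/nuclides_synthetic/`` are *synthetic
approximations* assembled from commonly quoted line energies and yields; they
are fixtures with the right structure and rough magnitudes, not an evaluated
decay library.  Users needing evaluated data can supply their own JSON files
with the same schema::

    {"name": ..., "half_life_s": ..., "mode": "alpha|beta|noble_gas_beta",
     "alpha_lines": [[E_MeV, yield], ...],
     "beta_branches": [[E_endpoint_MeV, yield, Z_daughter], ...],
     "electron_lines": [[E_MeV, yield], ...]}
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "NuclideData",
    "NuclideSchemaError",
    "load_nuclide",
    "load_packaged_nuclide",
    "packaged_nuclide_names",
    "beta_spectrum_density",
    "sample_beta_energy",
    "sample_emission",
]

_ELECTRON_MASS_MEV = 0.51099895
_ALPHA_FS = 1.0 / 137.035999  # fine-structure constant

_MODES = ("alpha", "beta", "noble_gas_beta")


class NuclideSchemaError(ValueError):
    """A nuclide record violates the schema; the message names the field."""


@dataclass(frozen=True)
class NuclideData:
    """Validated decay properties of one nuclide."""

    name: str
    half_life_s: float
    mode: str
    alpha_lines: tuple[tuple[float, float], ...] = ()
    beta_branches: tuple[tuple[float, float, int], ...] = ()
    electron_lines: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.half_life_s <= 0:
            raise NuclideSchemaError("half_life_s: must be > 0")
        if self.mode not in _MODES:
            raise NuclideSchemaError(f"mode: must be one of {_MODES}")
        for i, (e, y) in enumerate(self.alpha_lines):
            if e <= 0:
                raise NuclideSchemaError(f"alpha_lines[{i}][0]: energy must be > 0")
            if y < 0:
                raise NuclideSchemaError(f"alpha_lines[{i}][1]: yield must be >= 0")
        for i, (e, y, z) in enumerate(self.beta_branches):
            if e <= 0:
                raise NuclideSchemaError(
                    f"beta_branches[{i}][0]: endpoint must be > 0"
                )
            if y < 0:
                raise NuclideSchemaError(f"beta_branches[{i}][1]: yield must be >= 0")
            if not 1 <= int(z) <= 120:
                raise NuclideSchemaError(
                    f"beta_branches[{i}][2]: daughter Z out of range"
                )
        for i, (e, y) in enumerate(self.electron_lines):
            if e <= 0:
                raise NuclideSchemaError(
                    f"electron_lines[{i}][0]: energy must be > 0"
                )
            if y < 0:
                raise NuclideSchemaError(f"electron_lines[{i}][1]: yield must be >= 0")
        if self.mode == "alpha" and not self.alpha_lines:
            raise NuclideSchemaError("alpha_lines: alpha nuclide has no alpha lines")
        if self.mode in ("beta", "noble_gas_beta") and not (
            self.beta_branches or self.electron_lines
        ):
            raise NuclideSchemaError(
                "beta_branches: beta-mode nuclide has no electron emissions"
            )

    @property
    def decay_constant_per_s(self) -> float:
        return math.log(2.0) / self.half_life_s

    @property
    def decay_constant_per_day(self) -> float:
        return self.decay_constant_per_s * 86400.0

    def emissions(self, kind: str | None = None):
        """Flat (kind, payload, yield) emission list; kind in {alpha, beta, electron}."""
        out = []
        for e, y in self.alpha_lines:
            out.append(("alpha", (e,), y))
        for e, y, z in self.beta_branches:
            out.append(("beta", (e, int(z)), y))
        for e, y in self.electron_lines:
            out.append(("electron", (e,), y))
        if kind == "alpha":
            out = [x for x in out if x[0] == "alpha"]
        elif kind == "electron":
            out = [x for x in out if x[0] in ("beta", "electron")]
        return out

    def mean_energy_per_decay_mev(self) -> float:
        """Yield-weighted mean emitted energy per decay (MeV), betas by quadrature."""
        total = 0.0
        for kind, payload, y in self.emissions():
            if kind == "beta":
                total += y * mean_beta_energy(payload[0], payload[1])
            else:
                total += y * payload[0]
        return total

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "half_life_s": self.half_life_s,
            "mode": self.mode,
            "alpha_lines": [list(x) for x in self.alpha_lines],
            "beta_branches": [list(x) for x in self.beta_branches],
            "electron_lines": [list(x) for x in self.electron_lines],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")


def _parse(payload: dict, origin: str) -> NuclideData:
    for req in ("name", "half_life_s", "mode"):
        if req not in payload:
            raise NuclideSchemaError(f"{origin}: missing required field '{req}'")
    try:
        return NuclideData(
            name=str(payload["name"]),
            half_life_s=float(payload["half_life_s"]),
            mode=str(payload["mode"]),
            alpha_lines=tuple(
                (float(e), float(y)) for e, y in payload.get("alpha_lines", [])
            ),
            beta_branches=tuple(
                (float(e), float(y), int(z))
                for e, y, z in payload.get("beta_branches", [])
            ),
            electron_lines=tuple(
                (float(e), float(y)) for e, y in payload.get("electron_lines", [])
            ),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, NuclideSchemaError):
            raise
        raise NuclideSchemaError(f"{origin}: malformed emission table ({exc})") from exc


def load_nuclide(path: str | Path) -> NuclideData:
    """Load and validate a nuclide JSON file."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise NuclideSchemaError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(payload, dict):
        raise NuclideSchemaError(f"{path}: top level must be a JSON object")
    return _parse(payload, str(path))


def packaged_nuclide_names() -> list[str]:
    root = resources.files("marrowdose.data").joinpath("nuclides_synthetic")
    return sorted(p.name[: -len(".json")] for p in root.iterdir() if p.name.endswith(".json"))


def load_packaged_nuclide(name: str) -> NuclideData:
    """Load one of the packaged synthetic nuclide fixtures, e.g. ``"cs137"``."""
    key = name.lower().replace("-", "")
    ref = resources.files("marrowdose.data").joinpath(
        f"nuclides_synthetic/{key}.json"
    )
    if not ref.is_file():
        raise KeyError(
            f"no packaged nuclide {name!r}; available: {packaged_nuclide_names()}"
        )
    payload = json.loads(ref.read_text(encoding="utf-8"))
    return _parse(payload, f"packaged:{key}")


# ---------------------------------------------------------------------------
# Beta spectrum


def beta_spectrum_density(endpoint_mev: float, z_daughter: int, e):
    """Relative allowed-shape beta spectrum density at kinetic energy ``e`` (MeV).

    Zero outside the open interval (0, endpoint).  Unnormalised; callers
    integrate or rejection-sample as needed.
    """
    if endpoint_mev <= 0:
        raise ValueError("endpoint must be > 0")
    e = np.asarray(e, dtype=float)
    scalar = e.ndim == 0
    e = np.atleast_1d(e)
    out = np.zeros_like(e)
    ok = (e > 0.0) & (e < endpoint_mev)
    if ok.any():
        w = e[ok] + _ELECTRON_MASS_MEV
        p = np.sqrt(np.maximum(w * w - _ELECTRON_MASS_MEV**2, 0.0))
        eta = _ALPHA_FS * z_daughter * w / np.maximum(p, 1e-12)
        x = 2.0 * np.pi * eta
        fermi = x / (1.0 - np.exp(-np.clip(x, None, 700.0)))
        out[ok] = p * w * (endpoint_mev - e[ok]) ** 2 * fermi
    return float(out[0]) if scalar else out


@lru_cache(maxsize=256)
def _spectrum_envelope(endpoint_mev: float, z_daughter: int) -> float:
    grid = np.linspace(0.0, endpoint_mev, 512)[1:-1]
    return 1.05 * float(np.max(beta_spectrum_density(endpoint_mev, z_daughter, grid)))


@lru_cache(maxsize=256)
def mean_beta_energy(endpoint_mev: float, z_daughter: int) -> float:
    """Spectrum-mean kinetic energy of one beta branch (MeV), by quadrature."""
    grid = np.linspace(0.0, endpoint_mev, 4001)
    dens = beta_spectrum_density(endpoint_mev, z_daughter, grid)
    norm = np.trapezoid(dens, grid)
    return float(np.trapezoid(grid * dens, grid) / norm)


def sample_beta_energy(
    endpoint_mev: float, z_daughter: int, rng: np.random.Generator, n: int = 1
) -> np.ndarray:
    """Rejection-sample ``n`` beta kinetic energies from the allowed spectrum."""
    env = _spectrum_envelope(endpoint_mev, z_daughter)
    out = np.empty(0)
    while len(out) < n:
        draw = max(2 * (n - len(out)), 16)
        e = rng.random(draw) * endpoint_mev
        u = rng.random(draw) * env
        acc = u < beta_spectrum_density(endpoint_mev, z_daughter, e)
        out = np.concatenate([out, e[acc]])
    return out[:n]


def sample_emission(
    nuclide: NuclideData, rng: np.random.Generator, kind: str | None = None
) -> tuple[str, float]:
    """Draw one (particle type, energy MeV) emission, weighted by yield.

    ``kind`` restricts to ``"alpha"`` or ``"electron"`` emissions (beta
    branches count as electrons).  Returned particle type is ``"alpha"`` or
    ``"electron"``.
    """
    table = nuclide.emissions(kind)
    yields = np.array([y for _, _, y in table], dtype=float)
    if not len(table) or yields.sum() <= 0:
        raise ValueError(
            f"{nuclide.name}: no emissions with positive yield (kind={kind!r})"
        )
    i = rng.choice(len(table), p=yields / yields.sum())
    k, payload, _ = table[i]
    if k == "alpha":
        return "alpha", payload[0]
    if k == "electron":
        return "electron", payload[0]
    return "electron", float(sample_beta_energy(payload[0], payload[1], rng, 1)[0])


def sample_emissions(
    nuclide: NuclideData, rng: np.random.Generator, n: int, kind: str | None = None
) -> np.ndarray:
    """Vectorised energies of ``n`` emissions of ``kind`` (yield-weighted)."""
    table = nuclide.emissions(kind)
    yields = np.array([y for _, _, y in table], dtype=float)
    if not len(table) or yields.sum() <= 0:
        raise ValueError(
            f"{nuclide.name}: no emissions with positive yield (kind={kind!r})"
        )
    idx = rng.choice(len(table), size=n, p=yields / yields.sum())
    energies = np.empty(n)
    for i, (k, payload, _) in enumerate(table):
        sel = idx == i
        m = int(sel.sum())
        if not m:
            continue
        if k == "beta":
            energies[sel] = sample_beta_energy(payload[0], payload[1], rng, m)
        else:
            energies[sel] = payload[0]
    return energies
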