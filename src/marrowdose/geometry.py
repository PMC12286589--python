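"""Parametric trabecular-bone / marrow lattice with embedded sinusoidal vessels.

The cervical-vertebra spongiosa is idealised as a periodic tiling of cubic
cells: a marrow cavity of inner dimension 600 um surrounded by trabecular bone
plates, giving an outer cell dimension of 630 um (15 um half-wall per face, a
30 um plate between neighbouring cavities).  Each cavity holds a square grid
of parallel sinusoid cylinders (radius 20 um, axes along z, spanning the
cavity), spaced cavity-width / grid-side apart.  With the defaults, 25 vessels
per cell and a 3 x 3 block of modeled cells give 225 modeled vessels standing
in for the 40,000 vessels of the full site (1600 cells); the ratio
40,000 / 225 is carried on the model as ``vessel_scale``.

Space partitions into five regions:

* ``BLOOD`` — inside a vessel (r < 20 um from the nearest axis),
* ``PERIVASCULAR_HSC`` — the 10 um shell around the vessel wall
  (20 <= r < 30 um), the dosimetric target where haematopoietic stem cells
  concentrate,
* ``RED_BONE_MARROW`` — the rest of the cavity,
* ``TRABECULAR_SURFACE`` — bone within 10 um of a bone–marrow interface,
* ``TRABECULAR_VOLUME`` — the remaining (deeper) bone.

Coordinates are continuous, in um, with the modeled block spanning
``[0, grid_side * 630]`` in x and y and ``[0, 630]`` in z.  Particles leaving
the block are considered escaped.  Boundary ties resolve to the inner region
(half-open shells), which matters only on sets of measure zero but keeps
classification deterministic.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionLabel",
    "GeometryError",
    "GeometrySpec",
    "LatticeModel",
    "build_lattice",
    "MARROW_REGIONS",
    "BONE_REGIONS",
]


class RegionLabel(enum.IntEnum):
    BLOOD = 0
    PERIVASCULAR_HSC = 1
    RED_BONE_MARROW = 2
    TRABECULAR_SURFACE = 3
    TRABECULAR_VOLUME = 4


MARROW_REGIONS = (
    RegionLabel.BLOOD,
    RegionLabel.PERIVASCULAR_HSC,
    RegionLabel.RED_BONE_MARROW,
)
BONE_REGIONS = (RegionLabel.TRABECULAR_SURFACE, RegionLabel.TRABECULAR_VOLUME)

_TOL = 1e-9


class GeometryError(ValueError):
    """Invalid geometry configuration or out-of-domain query."""


@dataclass(frozen=True)
class GeometrySpec:
    """Dimensions and counts defining the lattice.

    Defaults are the full cervical-vertebra configuration; use
    :func:`marrowdose.synthetic.gen_reduced_geometry` for desk-scale variants.
    ``vessels_per_cell`` and ``modeled_grids`` must be perfect squares (square
    vessel grid inside each cell, square block of modeled cells).
    """

    cell_inner_um: float = 600.0
    cell_outer_um: float = 630.0
    n_cells_total: int = 1600
    vessels_per_cell: int = 25
    modeled_grids: int = 9
    vessel_radius_um: float = 20.0
    hsc_shell_thickness_um: float = 10.0
    trab_surface_thickness_um: float = 10.0
    total_vessels: int = 40000
    density_bone_g_cm3: float = 1.765
    density_soft_g_cm3: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.cell_inner_um < self.cell_outer_um:
            raise GeometryError("need 0 < cell_inner_um < cell_outer_um")
        if self.vessels_per_cell < 1 or self.modeled_grids < 1:
            raise GeometryError("vessels_per_cell and modeled_grids must be >= 1")
        m = math.isqrt(self.vessels_per_cell)
        if m * m != self.vessels_per_cell:
            raise GeometryError("vessels_per_cell must be a perfect square")
        g = math.isqrt(self.modeled_grids)
        if g * g != self.modeled_grids:
            raise GeometryError("modeled_grids must be a perfect square")
        if self.vessel_radius_um <= 0 or self.hsc_shell_thickness_um <= 0:
            raise GeometryError("vessel radius and shell thickness must be > 0")
        if self.trab_surface_thickness_um <= 0:
            raise GeometryError("trab_surface_thickness_um must be > 0")
        if self.trab_surface_thickness_um > self.half_wall_um:
            raise GeometryError(
                "trabecular surface layer thicker than the bone half-wall"
            )
        if self.density_bone_g_cm3 <= 0 or self.density_soft_g_cm3 <= 0:
            raise GeometryError("densities must be > 0")
        # HSC shells must not overlap between neighbouring vessels...
        if self.shell_outer_um >= self.vessel_spacing_um / 2.0:
            raise GeometryError("HSC shells of neighbouring vessels overlap")
        # ...nor protrude into the bone wall.
        max_offset = (m - 1) / 2.0 * self.vessel_spacing_um
        if max_offset + self.shell_outer_um >= self.cell_inner_um / 2.0:
            raise GeometryError("outer vessels' HSC shells reach the bone wall")
        if self.n_cells_total * self.vessels_per_cell != self.total_vessels:
            raise GeometryError(
                "total_vessels must equal n_cells_total * vessels_per_cell"
            )
        if self.n_cells_total < self.modeled_grids:
            raise GeometryError("n_cells_total must be >= modeled_grids")

    # -- derived quantities ------------------------------------------------
    @property
    def vessels_side(self) -> int:
        return math.isqrt(self.vessels_per_cell)

    @property
    def grid_side(self) -> int:
        return math.isqrt(self.modeled_grids)

    @property
    def vessel_spacing_um(self) -> float:
        return self.cell_inner_um / self.vessels_side

    @property
    def half_inner_um(self) -> float:
        return self.cell_inner_um / 2.0

    @property
    def half_wall_um(self) -> float:
        return (self.cell_outer_um - self.cell_inner_um) / 2.0

    @property
    def shell_outer_um(self) -> float:
        return self.vessel_radius_um + self.hsc_shell_thickness_um

    @property
    def modeled_vessels(self) -> int:
        return self.modeled_grids * self.vessels_per_cell

    @property
    def vessel_scale(self) -> float:
        """Whole-site vessels per modeled vessel (40,000 / 225 by default)."""
        return self.total_vessels / self.modeled_vessels

    # -- (de)serialisation -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeometrySpec":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))

    def with_(self, **kw) -> "GeometrySpec":
        return replace(self, **kw)


class LatticeModel:
    """Built lattice: vessel axes, region volumes/masses, classification, tracing.

    Construct via :func:`build_lattice`.  All lengths um, volumes um^3,
    masses g.  The build is deterministic.
    """

    def __init__(self, spec: GeometrySpec):
        self.spec = spec
        s = spec
        g = s.grid_side
        m = s.vessels_side
        pitch = s.cell_outer_um
        self.pitch = pitch
        self.block_min = np.zeros(3)
        self.block_max = np.array([g * pitch, g * pitch, pitch])

        centers_1d = (np.arange(g) + 0.5) * pitch
        cx, cy = np.meshgrid(centers_1d, centers_1d, indexing="ij")
        self.cell_centers_xy = np.column_stack([cx.ravel(), cy.ravel()])
        self.cell_center_z = pitch / 2.0

        off = (np.arange(m) - (m - 1) / 2.0) * s.vessel_spacing_um
        ox, oy = np.meshgrid(off, off, indexing="ij")
        offsets = np.column_stack([ox.ravel(), oy.ravel()])
        self.vessel_axes_xy = (
            self.cell_centers_xy[:, None, :] + offsets[None, :, :]
        ).reshape(-1, 2)
        self._vessel_offsets = offsets
        self._offset_max = (m - 1) / 2.0 * s.vessel_spacing_um

        hi = s.half_inner_um
        ts = s.trab_surface_thickness_um
        # Breakpoint planes per axis: cavity walls, surface-layer offset, cell faces.
        px = sorted(
            {
                round(c + sgn * v, 9)
                for c in centers_1d
                for sgn in (-1.0, 1.0)
                for v in (hi, hi + ts, pitch / 2.0)
            }
        )
        self._planes = [
            np.array(px),
            np.array(px),
            np.array(
                sorted(
                    {
                        round(self.cell_center_z + sgn * v, 9)
                        for sgn in (-1.0, 1.0)
                        for v in (hi, hi + ts, pitch / 2.0)
                    }
                )
            ),
        ]
        # Surface-layer edge cylinders (radius ts) and corner spheres around
        # each cavity cube — the curved parts of the bone-depth-10um surface.
        corners_2d = np.array([[-hi, -hi], [-hi, hi], [hi, -hi], [hi, hi]])
        cz = self.cell_center_z
        # z-parallel edges: (x, y) at cavity xy-corners
        self._edges_z = (
            self.cell_centers_xy[:, None, :] + corners_2d[None, :, :]
        ).reshape(-1, 2)
        # x-parallel edges: (y, z); y from cells, z = cz +- hi
        ys = np.unique(self.cell_centers_xy[:, 1])
        self._edges_x = np.array(
            [[y + sy, cz + sz] for y in ys for sy in (-hi, hi) for sz in (-hi, hi)]
        ).reshape(-1, 2)
        xs = np.unique(self.cell_centers_xy[:, 0])
        self._edges_y = np.array(
            [[x + sx, cz + sz] for x in xs for sx in (-hi, hi) for sz in (-hi, hi)]
        ).reshape(-1, 2)
        self._corners = np.array(
            [
                [c[0] + sx, c[1] + sy, cz + sz]
                for c in self.cell_centers_xy
                for sx in (-hi, hi)
                for sy in (-hi, hi)
                for sz in (-hi, hi)
            ]
        )

        self._volumes = self._analytic_volumes()
        self._masses = {
            r: v * 1e-12 * self.density(r) for r, v in self._volumes.items()
        }

    # -- volumes and masses ------------------------------------------------
    def _analytic_volumes(self) -> dict[RegionLabel, float]:
        s = self.spec
        n_cells = s.modeled_grids
        inner = s.cell_inner_um
        ts = s.trab_surface_thickness_um
        r_in, r_out = s.vessel_radius_um, s.shell_outer_um
        v_blood = n_cells * s.vessels_per_cell * math.pi * r_in**2 * inner
        v_hsc = (
            n_cells * s.vessels_per_cell * math.pi * (r_out**2 - r_in**2) * inner
        )
        v_cavity = n_cells * inner**3
        v_bone = n_cells * (s.cell_outer_um**3 - inner**3)
        # 10 um shell around a cube: 6 face slabs + 12 quarter-cylinder edges
        # + 8 octant-sphere corners (fits inside the 15 um half-wall).
        v_ts = n_cells * (
            6 * inner**2 * ts
            + 12 * (math.pi * ts**2 / 4.0) * inner
            + (4.0 / 3.0) * math.pi * ts**3
        )
        return {
            RegionLabel.BLOOD: v_blood,
            RegionLabel.PERIVASCULAR_HSC: v_hsc,
            RegionLabel.RED_BONE_MARROW: v_cavity - v_blood - v_hsc,
            RegionLabel.TRABECULAR_SURFACE: v_ts,
            RegionLabel.TRABECULAR_VOLUME: v_bone - v_ts,
        }

    def density(self, region: RegionLabel) -> float:
        """Mass density of a region, g/cm^3."""
        if region in BONE_REGIONS:
            return self.spec.density_bone_g_cm3
        return self.spec.density_soft_g_cm3

    def region_volume(self, region: RegionLabel) -> tuple[float, float]:
        """(volume um^3, mass g) of ``region`` summed over the modeled block."""
        return self._volumes[region], self._masses[region]

    def region_mass_g(self, region: RegionLabel) -> float:
        return self._masses[region]

    @property
    def total_volume_um3(self) -> float:
        return float(np.prod(self.block_max - self.block_min))

    def region_report(self) -> pd.DataFrame:
        """Per-region volume/mass/density table for the modeled block."""
        rows = []
        for r in RegionLabel:
            v, mass = self.region_volume(r)
            rows.append(
                {
                    "region": r.name,
                    "volume_um3": v,
                    "mass_g": mass,
                    "density_g_cm3": self.density(r),
                }
            )
        return pd.DataFrame(rows)

    # -- classification ----------------------------------------------------
    def _local(self, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell-local coordinates (lx, ly, lz) of points inside the block."""
        s = self.spec
        idx = np.clip(np.floor(p[:, :2] / self.pitch), 0, s.grid_side - 1)
        lxy = p[:, :2] - (idx + 0.5) * self.pitch
        lz = p[:, 2] - self.cell_center_z
        return lxy, lz

    def classify_points(self, pts: np.ndarray) -> np.ndarray:
        """Vectorised region labels (int8 array of RegionLabel values)."""
        p = np.atleast_2d(np.asarray(pts, dtype=float))
        if p.shape[1] != 3:
            raise GeometryError("points must be (n, 3)")
        if (p < self.block_min - _TOL).any() or (p > self.block_max + _TOL).any():
            raise GeometryError("point outside the modeled block")
        s = self.spec
        hi = s.half_inner_um
        lxy, lz = self._local(p)
        a = np.abs(np.column_stack([lxy, lz]))
        in_cavity = a.max(axis=1) <= hi

        labels = np.empty(len(p), dtype=np.int8)
        # bone: Euclidean depth from the cavity surface
        d = np.clip(a - hi, 0.0, None)
        depth = np.sqrt((d * d).sum(axis=1))
        bone = ~in_cavity
        labels[bone] = np.where(
            depth[bone] <= s.trab_surface_thickness_um,
            RegionLabel.TRABECULAR_SURFACE,
            RegionLabel.TRABECULAR_VOLUME,
        )
        # cavity: radial distance to the nearest vessel axis
        sp = s.vessel_spacing_um
        om = self._offset_max
        k = np.clip(np.round((lxy + om) / sp), 0, s.vessels_side - 1)
        v = k * sp - om
        r = np.hypot(lxy[:, 0] - v[:, 0], lxy[:, 1] - v[:, 1])
        labels[in_cavity] = np.where(
            r[in_cavity] < s.vessel_radius_um,
            RegionLabel.BLOOD,
            np.where(
                r[in_cavity] < s.shell_outer_um,
                RegionLabel.PERIVASCULAR_HSC,
                RegionLabel.RED_BONE_MARROW,
            ),
        )
        return labels

    def classify_point(self, p: Sequence[float]) -> RegionLabel:
        return RegionLabel(int(self.classify_points(np.asarray(p))[0]))

    # -- sampling ----------------------------------------------------------
    def sample_points(
        self,
        region: RegionLabel,
        n: int,
        rng: np.random.Generator,
        *,
        marrow_includes_shell: bool = False,
    ) -> np.ndarray:
        """``n`` points uniform in ``region`` (rejection from bounding shapes).

        With ``marrow_includes_shell`` and ``region=RED_BONE_MARROW`` the HSC
        shell is included in the sampled source (marrow tissue as a source is
        whole-marrow in the reference bookkeeping); classification labels are
        unaffected.
        """
        if n <= 0:
            raise ValueError("n must be > 0")
        s = self.spec
        if region in (RegionLabel.BLOOD, RegionLabel.PERIVASCULAR_HSC):
            return self._sample_vessel_shell(region, n, rng)
        if region == RegionLabel.RED_BONE_MARROW:
            r_min = (
                s.vessel_radius_um if marrow_includes_shell else s.shell_outer_um
            )
            return self._sample_cavity(n, rng, r_min)
        if region in BONE_REGIONS:
            return self._sample_bone(region, n, rng)
        raise ValueError(f"unknown region {region!r}")

    def sample_point(
        self, region: RegionLabel, rng: np.random.Generator, **kw
    ) -> np.ndarray:
        return self.sample_points(region, 1, rng, **kw)[0]

    def _random_cells(self, n: int, rng) -> np.ndarray:
        idx = rng.integers(0, self.spec.modeled_grids, size=n)
        return self.cell_centers_xy[idx]

    def _sample_vessel_shell(self, region, n, rng) -> np.ndarray:
        s = self.spec
        cells = self._random_cells(n, rng)
        voff = self._vessel_offsets[rng.integers(0, s.vessels_per_cell, size=n)]
        if region == RegionLabel.BLOOD:
            r = s.vessel_radius_um * np.sqrt(rng.random(n))
        else:
            r2 = s.vessel_radius_um**2 + (
                s.shell_outer_um**2 - s.vessel_radius_um**2
            ) * rng.random(n)
            r = np.sqrt(r2)
        th = rng.random(n) * 2 * np.pi
        x = cells[:, 0] + voff[:, 0] + r * np.cos(th)
        y = cells[:, 1] + voff[:, 1] + r * np.sin(th)
        z = self.cell_center_z + (rng.random(n) - 0.5) * s.cell_inner_um
        return np.column_stack([x, y, z])

    def _sample_cavity(self, n, rng, r_min) -> np.ndarray:
        s = self.spec
        out = np.empty((0, 3))
        while len(out) < n:
            draw = max(n, int(1.5 * (n - len(out))) + 8)
            cells = self._random_cells(draw, rng)
            l = (rng.random((draw, 3)) - 0.5) * s.cell_inner_um
            sp, om = s.vessel_spacing_um, self._offset_max
            k = np.clip(np.round((l[:, :2] + om) / sp), 0, s.vessels_side - 1)
            v = k * sp - om
            r = np.hypot(l[:, 0] - v[:, 0], l[:, 1] - v[:, 1])
            keep = r >= r_min
            pts = np.column_stack(
                [
                    cells[keep, 0] + l[keep, 0],
                    cells[keep, 1] + l[keep, 1],
                    self.cell_center_z + l[keep, 2],
                ]
            )
            out = np.vstack([out, pts])
        return out[:n]

    def _sample_bone(self, region, n, rng) -> np.ndarray:
        s = self.spec
        hi, ho = s.half_inner_um, s.cell_outer_um / 2.0
        out = np.empty((0, 3))
        target = int(region)
        while len(out) < n:
            draw = max(4 * n, 64)
            cells = self._random_cells(draw, rng)
            l = (rng.random((draw, 3)) - 0.5) * s.cell_outer_um
            a = np.abs(l)
            in_bone = a.max(axis=1) > hi
            pts = np.column_stack(
                [
                    cells[in_bone, 0] + l[in_bone, 0],
                    cells[in_bone, 1] + l[in_bone, 1],
                    self.cell_center_z + l[in_bone, 2],
                ]
            )
            if len(pts):
                pts = np.clip(pts, self.block_min + _TOL, self.block_max - _TOL)
                keep = self.classify_points(pts) == target
                out = np.vstack([out, pts[keep]])
        return out[:n]

    # -- ray tracing -------------------------------------------------------
    def trace_segments(
        self, origin: Sequence[float], direction: Sequence[float], length: float
    ) -> list[tuple[RegionLabel, float]]:
        """Ordered (region, segment length um) along a straight ray.

        Segments are delimited by exact intersections with every region
        boundary surface (cell/cavity/offset planes, vessel and shell
        cylinders, and the quarter-cylinder/octant-sphere pieces of the
        bone-surface layer), then merged where consecutive labels agree.
        Lengths sum to ``min(length, distance to the block boundary)``.
        """
        o = np.asarray(origin, dtype=float)
        d = np.asarray(direction, dtype=float)
        nd = np.linalg.norm(d)
        if nd == 0:
            raise GeometryError("direction vector must be non-zero")
        if abs(nd - 1.0) > 1e-9:
            d = d / nd
        self.classify_points(o)  # bounds check
        if length <= 0:
            return []

        t_exit = np.inf
        for k in range(3):
            if abs(d[k]) > 1e-14:
                t1 = (self.block_min[k] - o[k]) / d[k]
                t2 = (self.block_max[k] - o[k]) / d[k]
                t_exit = min(t_exit, max(t1, t2))
        L = float(min(length, t_exit))
        if L <= _TOL:
            return []

        cand = [self._plane_ts(o, d), self._curved_ts(o, d)]
        ts = np.concatenate(cand) if cand else np.empty(0)
        ts = ts[(ts > _TOL) & (ts < L - _TOL)]
        bp = np.unique(np.concatenate([[0.0], ts, [L]]))
        if len(bp) > 2:
            keep = np.concatenate([[True], np.diff(bp) > _TOL])
            bp = bp[keep]
        bp[-1] = L

        mids = o[None, :] + d[None, :] * ((bp[:-1] + bp[1:]) / 2.0)[:, None]
        mids = np.clip(mids, self.block_min + _TOL, self.block_max - _TOL)
        labels = self.classify_points(mids)
        seg_len = np.diff(bp)

        out: list[tuple[RegionLabel, float]] = []
        for lab, sl in zip(labels, seg_len):
            if out and out[-1][0] == lab:
                out[-1] = (out[-1][0], out[-1][1] + float(sl))
            else:
                out.append((RegionLabel(int(lab)), float(sl)))
        return out

    def _plane_ts(self, o, d) -> np.ndarray:
        ts = []
        for k in range(3):
            if abs(d[k]) > 1e-14:
                ts.append((self._planes[k] - o[k]) / d[k])
        return np.concatenate(ts) if ts else np.empty(0)

    def _curved_ts(self, o, d) -> np.ndarray:
        s = self.spec
        ts_r = s.trab_surface_thickness_um
        parts = [
            _cylinder_ts(o[[0, 1]], d[[0, 1]], self.vessel_axes_xy, s.vessel_radius_um),
            _cylinder_ts(o[[0, 1]], d[[0, 1]], self.vessel_axes_xy, s.shell_outer_um),
            _cylinder_ts(o[[0, 1]], d[[0, 1]], self._edges_z, ts_r),
            _cylinder_ts(o[[1, 2]], d[[1, 2]], self._edges_x, ts_r),
            _cylinder_ts(o[[0, 2]], d[[0, 2]], self._edges_y, ts_r),
            _sphere_ts(o, d, self._corners, ts_r),
        ]
        return np.concatenate(parts)


def _quad_ts(a, b, c) -> np.ndarray:
    """Positive real roots of a t^2 + b t + c = 0 (vectorised)."""
    disc = b * b - 4.0 * a * c
    ok = (disc > 0) & (a > 1e-20)
    if not ok.any():
        return np.empty(0)
    sq = np.sqrt(disc[ok])
    a2 = 2.0 * a[ok]
    return np.concatenate([(-b[ok] - sq) / a2, (-b[ok] + sq) / a2])


def _cylinder_ts(o2, d2, centers, radius) -> np.ndarray:
    a = float(d2 @ d2)
    if a < 1e-20 or len(centers) == 0:
        return np.empty(0)
    rel = o2[None, :] - centers
    aa = np.full(len(centers), a)
    bb = 2.0 * rel @ d2
    cc = (rel * rel).sum(axis=1) - radius * radius
    return _quad_ts(aa, bb, cc)


def _sphere_ts(o, d, centers, radius) -> np.ndarray:
    if len(centers) == 0:
        return np.empty(0)
    rel = o[None, :] - centers
    aa = np.ones(len(centers))
    bb = 2.0 * rel @ d
    cc = (rel * rel).sum(axis=1) - radius * radius
    return _quad_ts(aa, bb, cc)


def build_lattice(spec: GeometrySpec) -> LatticeModel:
    """Build the deterministic lattice model for ``spec``."""
    return LatticeModel(spec)
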