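"""Stopping powers, CSDA ranges, Monte Carlo engines and dose conversion."""

import math

import numpy as np
import pytest

from marrowdose.geometry import RegionLabel as R
from marrowdose.nuclides import load_packaged_nuclide
from marrowdose.transport import (
    EnergyTally,
    TransportConfig,
    csda_range,
    make_tissue_stopping_table,
    tally_to_dose,
    transport_alpha,
    transport_electron,
)


class TestStoppingTable:
    def test_packaged_matches_generator(self, stopping_table):
        gen = make_tissue_stopping_table()
        assert np.allclose(stopping_table.energy_mev, gen.energy_mev)
        assert np.allclose(
            stopping_table.mass_stopping("alpha", [1.0, 5.0]),
            gen.mass_stopping("alpha", [1.0, 5.0]),
            rtol=1e-5,
        )

    def test_range_monotone_in_energy(self, stopping_table):
        e = np.geomspace(0.01, 8.0, 50)
        r = stopping_table.mass_range("alpha", e)
        assert (np.diff(r) > 0).all()
        r = stopping_table.mass_range("electron", e)
        assert (np.diff(r) > 0).all()

    def test_density_scaling(self, stopping_table):
        r1 = csda_range(stopping_table, "alpha", 5.0, 1.0)
        rb = csda_range(stopping_table, "alpha", 5.0, 1.765)
        assert rb == pytest.approx(r1 / 1.765, rel=1e-12)

    def test_range_matches_independent_quadrature(self, stopping_table):
        """R(5 MeV alpha) agrees with trapezoid quadrature of 1/S on an
        independent fine grid within 0.5%."""
        e_lo = stopping_table.e_min
        grid = np.geomspace(e_lo, 5.0, 20_000)
        inv = 1.0 / stopping_table.mass_stopping("alpha", grid)
        oracle = np.trapezoid(inv, grid) + e_lo * inv[0]
        mine = stopping_table.mass_range("alpha", 5.0)
        assert mine == pytest.approx(oracle, rel=5e-3)

    def test_below_support_rejected(self, stopping_table):
        with pytest.raises(ValueError):
            stopping_table.mass_stopping("alpha", 1e-5)


class TestTallyToDose:
    def _tally(self, mev, n=1):
        t = EnergyTally()
        dep = np.zeros((n, len(R)))
        dep[:, int(R.PERIVASCULAR_HSC)] = mev
        t.add_batch(dep, np.zeros(n), np.full(n, mev))
        return t

    def test_unit_conversion(self):
        """1 MeV mean deposit in 1 kg is 1.602e-13 Gy; in 1 g, 1.602e-10 Gy."""
        t = self._tally(1.0)
        assert tally_to_dose(t, R.PERIVASCULAR_HSC, 1000.0) == pytest.approx(
            1.602176634e-13, rel=1e-9
        )
        assert tally_to_dose(t, R.PERIVASCULAR_HSC, 1.0) == pytest.approx(
            1.602176634e-10, rel=1e-9
        )

    def test_mass_linearity_and_scale(self):
        t = self._tally(2.0)
        d1 = tally_to_dose(t, R.PERIVASCULAR_HSC, 1.0)
        assert tally_to_dose(t, R.PERIVASCULAR_HSC, 2.0) == pytest.approx(d1 / 2)
        assert tally_to_dose(
            t, R.PERIVASCULAR_HSC, 1.0, vessel_scale=40000 / 225
        ) == pytest.approx(d1 * 177.7778, rel=1e-4)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            tally_to_dose(self._tally(1.0), R.PERIVASCULAR_HSC, 0.0)


class TestAlphaTransport:
    def test_energy_conservation_per_run(self, reduced_model, rng):
        nuc = load_packaged_nuclide("ra223")
        cfg = TransportConfig(max_histories=400, min_histories=100, seed=0)
        t = transport_alpha(reduced_model, R.BLOOD, nuc, cfg, rng)
        assert t.total_deposited_mev + t.escaped_mev == pytest.approx(
            t.emitted_mev, rel=1e-9
        )

    def test_contained_point_source_all_in_shell(self, single_vessel_model, stopping_table):
        """An alpha whose range is shorter than the shell half-extent, emitted
        mid-shell, deposits 100% of its energy in the shell."""
        m = single_vessel_model
        c = m.vessel_axes_xy[0]
        src = [c[0] + 25.0, c[1], m.cell_center_z]
        e = 0.15  # MeV
        assert csda_range(stopping_table, "alpha", e) < 5.0
        cfg = TransportConfig(max_histories=200, min_histories=100, seed=1)
        t = transport_alpha(
            m, R.PERIVASCULAR_HSC, None, cfg, np.random.default_rng(1),
            source_point=src, energy_mev=e,
        )
        assert t.deposited(R.PERIVASCULAR_HSC) == pytest.approx(t.emitted_mev, rel=1e-12)

    def test_bone_source_beyond_range_misses_shell(self, single_vessel_model):
        """With 270 um bone-to-shell separation, far beyond any alpha range,
        essentially no energy from a trabecular source reaches the shell."""
        nuc = load_packaged_nuclide("pu239")
        cfg = TransportConfig(max_histories=2000, min_histories=500, seed=2)
        t = transport_alpha(
            single_vessel_model, R.TRABECULAR_VOLUME, nuc, cfg, np.random.default_rng(2)
        )
        assert t.deposited(R.PERIVASCULAR_HSC) / t.emitted_mev < 1e-3

    def test_blood_source_favours_adjacent_shell(self, reduced_model, rng):
        """From a blood source the adjacent HSC shell receives more dose than
        the distant trabecular bone."""
        nuc = load_packaged_nuclide("ra223")
        cfg = TransportConfig(max_histories=1200, min_histories=400, seed=3)
        t = transport_alpha(reduced_model, R.BLOOD, nuc, cfg, rng)
        d_hsc = tally_to_dose(
            t, R.PERIVASCULAR_HSC, reduced_model.region_mass_g(R.PERIVASCULAR_HSC)
        )
        d_tv = tally_to_dose(
            t, R.TRABECULAR_VOLUME, reduced_model.region_mass_g(R.TRABECULAR_VOLUME)
        )
        assert d_hsc > d_tv

    def test_se_estimator_vs_independent_seeds(self, reduced_model):
        """The reported relative SE is consistent with the spread of the mean
        across 10 independent runs."""
        nuc = load_packaged_nuclide("rn222")
        means, ses = [], []
        for seed in range(10):
            cfg = TransportConfig(
                max_histories=300, min_histories=300, target_rel_se=1e-6, seed=seed
            )
            t = transport_alpha(
                reduced_model, R.BLOOD, nuc, cfg, np.random.default_rng(seed)
            )
            means.append(t.mean_deposit(R.PERIVASCULAR_HSC))
            ses.append(t.rel_se(R.PERIVASCULAR_HSC) * means[-1])
        spread = np.std(means, ddof=1)
        typical_se = np.median(ses)
        assert 0.3 < spread / typical_se < 3.0


class TestElectronTransport:
    def test_energy_conservation_and_determinism(self, reduced_model):
        nuc = load_packaged_nuclide("cs137")
        cfg = TransportConfig(max_histories=120, min_histories=60, seed=5)
        a = transport_electron(reduced_model, R.BLOOD, nuc, cfg, np.random.default_rng(5))
        assert a.total_deposited_mev + a.escaped_mev == pytest.approx(
            a.emitted_mev, rel=1e-9
        )
        b = transport_electron(reduced_model, R.BLOOD, nuc, cfg, np.random.default_rng(5))
        assert a.deposited(R.PERIVASCULAR_HSC) == b.deposited(R.PERIVASCULAR_HSC)
        assert a.escaped_mev == b.escaped_mev

    def test_endpoint_displacement_bounded_by_csda_range(
        self, reduced_model, stopping_table
    ):
        """100 keV electrons from a point source never end farther than the
        CSDA range (displacement <= path length)."""
        m = reduced_model
        c = m.cell_centers_xy[0]
        src = np.array([c[0], c[1], m.cell_center_z])
        cfg = TransportConfig(max_histories=150, min_histories=100, seed=6)
        t = transport_electron(
            m, R.RED_BONE_MARROW, None, cfg, np.random.default_rng(6),
            source_point=src, energy_mev=0.1, collect_endpoints=True,
        )
        disp = np.linalg.norm(t.endpoints - src[None, :], axis=1)
        r_max = csda_range(stopping_table, "electron", 0.1)
        assert disp.max() <= r_max * (1 + 1e-9)
        assert disp.mean() < r_max


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"cutoff_keV": 0.0},
            {"target_rel_se": 0.0},
            {"target_rel_se": 1.5},
            {"electron_step_fraction": 0.0},
        ],
    )
    def test_bad_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            TransportConfig(**kw)
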