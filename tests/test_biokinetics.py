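"""Compartment solves: closed forms, conservation, noble-gas derivation."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from marrowdose.biokinetics import (
    LONG_HORIZON_MIN,
    SHORT_HORIZON_MIN,
    CompartmentSystem,
    classify_horizon,
    load_radon_demo_system,
    noble_gas_from_radon,
    rbm_blood_decays,
    read_compartments_csv,
    solve_decays,
    write_compartments_csv,
)
from marrowdose.nuclides import load_packaged_nuclide
from marrowdose.synthetic import gen_compartments


def ode_oracle(system, horizon_min, rtol=1e-11):
    """Independent adaptive-ODE quadrature of the decay counts."""
    t = horizon_min / 1440.0
    lam = system.decay_constant_per_day
    a = system.matrix - lam * np.eye(system.n)
    n0 = np.zeros(system.n)
    n0[system.index(system.intake_compartment)] = system.intake_bq / (lam / 86400.0)

    def rhs(_, y):
        n = system.n
        return np.concatenate([a @ y[:n], y[:n]])

    sol = solve_ivp(
        rhs,
        (0.0, t),
        np.concatenate([n0, np.zeros(system.n)]),
        method="LSODA",
        rtol=rtol,
        atol=1e-12 * max(n0.max(), 1.0),
    )
    assert sol.success
    return lam * sol.y[system.n :, -1]


class TestSolveDecays:
    def test_single_compartment_closed_form(self):
        """With no transfers, decays over [0,T] are N0 (1 - e^{-lambda T})."""
        lam = math.log(2.0)  # 1-day half-life
        system = CompartmentSystem(("pool",), np.zeros((1, 1)), lam, "pool", 1.0)
        t_min = 2.5 * 1440.0
        tally = solve_decays(system, t_min)
        n0 = 1.0 / (lam / 86400.0)
        expect = n0 * (1.0 - math.exp(-lam * t_min / 1440.0))
        assert tally.decays[0] == pytest.approx(expect, rel=1e-12)

    def test_total_decays_conserved(self):
        """Summed decays equal N0 (1 - e^{-lambda T}) for any flow-conserving
        network (transfers move atoms, only decay removes them)."""
        system, _ = gen_compartments(6, 0.6, seed=9)
        tally = solve_decays(system, 20_000.0)
        lam = system.decay_constant_per_day
        n0 = system.intake_bq / (lam / 86400.0)
        expect = n0 * (1.0 - math.exp(-lam * 20_000.0 / 1440.0))
        assert tally.total_decays == pytest.approx(expect, rel=1e-10)
        assert tally.total_decays + tally.residual_atoms.sum() == pytest.approx(
            n0, rel=1e-10
        )

    def test_matches_ode_oracle_on_random_fixture(self):
        system, _ = gen_compartments(5, 0.5, seed=42)
        tally = solve_decays(system, 10_000.0)
        oracle = ode_oracle(system, 10_000.0)
        rel = np.abs(tally.decays - oracle) / np.maximum(oracle, 1e-9 * oracle.sum())
        assert rel.max() < 1e-6

    def test_non_negative_inventories(self):
        system, _ = gen_compartments(4, 0.8, seed=1)
        for horizon in (10.0, 1000.0, 100_000.0):
            tally = solve_decays(system, horizon)
            assert (tally.decays >= 0).all()
            assert (tally.residual_atoms >= 0).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            CompartmentSystem(
                ("a", "b"), np.array([[0.0, 1.0], [-1.0, -1.0]]), 1.0, "a"
            )
        system, _ = gen_compartments(2, 1.0, seed=0)
        with pytest.raises(ValueError):
            solve_decays(system, -5.0)


class TestNobleGasDerivation:
    def test_xenon_halves_lung_to_blood(self):
        radon = load_radon_demo_system()
        xe = noble_gas_from_radon(radon, "Xe", 453_400.0)
        assert xe.rate("lung", "blood") == pytest.approx(
            0.5 * radon.rate("lung", "blood")
        )
        assert xe.decay_constant_per_day == pytest.approx(
            math.log(2.0) / 453_400.0 * 86400.0
        )

    def test_krypton_quarters_lung_to_blood(self):
        radon = load_radon_demo_system()
        kr = noble_gas_from_radon(radon, "Kr", 3.394e8)
        assert kr.rate("lung", "blood") == pytest.approx(
            0.25 * radon.rate("lung", "blood")
        )

    def test_identity_factor_preserves_system(self):
        radon = load_radon_demo_system()
        same = radon.with_rate("lung", "blood", radon.rate("lung", "blood"))
        assert np.allclose(same.matrix, radon.matrix)

    def test_missing_edge_rejected(self):
        system = CompartmentSystem.from_edges(
            ("lung", "blood"), [("blood", "lung", 1.0)], 1.0, "lung"
        )
        with pytest.raises(ValueError, match="lung -> blood"):
            noble_gas_from_radon(system, "Xe", 1000.0)


class TestApportionmentAndHorizon:
    def test_rbm_blood_rule(self):
        assert rbm_blood_decays(1e6) == pytest.approx(1.8e3)
        assert rbm_blood_decays(0.0) == 0.0

    def test_rbm_blood_linearity(self):
        a, b = 123.0, 456.0
        assert rbm_blood_decays(a + b) == pytest.approx(
            rbm_blood_decays(a) + rbm_blood_decays(b)
        )

    def test_horizons_per_nuclide(self):
        assert classify_horizon(load_packaged_nuclide("cs137")) == LONG_HORIZON_MIN
        assert classify_horizon(load_packaged_nuclide("xe135")) == SHORT_HORIZON_MIN
        # threshold boundary: exactly 30 days is long-lived
        assert classify_horizon(30.0 * 86400.0) == LONG_HORIZON_MIN
        assert classify_horizon(30.0 * 86400.0 - 1.0) == SHORT_HORIZON_MIN

    def test_horizon_override(self):
        i131 = load_packaged_nuclide("i131")
        assert classify_horizon(i131) == SHORT_HORIZON_MIN
        assert (
            classify_horizon(i131, override={"I-131": LONG_HORIZON_MIN})
            == LONG_HORIZON_MIN
        )


class TestCsvInterchange:
    def test_roundtrip(self, tmp_path):
        system, _ = gen_compartments(4, 0.7, seed=3)
        p = tmp_path / "edges.csv"
        write_compartments_csv(system, p)
        back = read_compartments_csv(
            p, system.decay_constant_per_day, system.intake_compartment
        )
        for frm in system.names:
            for to in system.names:
                if frm != to:
                    assert back.rate(frm, to) == pytest.approx(system.rate(frm, to))

    def test_demo_system_solves(self):
        radon = load_radon_demo_system()
        tally = solve_decays(radon, SHORT_HORIZON_MIN)
        assert tally["blood"] > 0
        assert tally["excreta"] > tally["blood"]  # exhalation dominates
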