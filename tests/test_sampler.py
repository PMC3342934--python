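"""Move operations, the Metropolis rule, and the chain driver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bouquetmc.chain import (
    EnergyModel,
    NuclearGeometry,
    TetherSpec,
    build_chromosome_spec,
    initialize_conformation,
)
from bouquetmc.energy import bending_energy, clustering_energy
from bouquetmc.oracles import discrete_wlc_r2
from bouquetmc.sampler import (
    SamplerSchedule,
    arm_rotation_move,
    crankshaft_move,
    metropolis_accept,
    metropolis_step,
    rigid_rotation_move,
    run_chain,
)


@pytest.fixture(scope="module")
def conf20():
    spec = build_chromosome_spec(100_000, 40_000, 20)
    model = EnergyModel(spec=spec, persistence_length_nm=300.0)
    return spec, model, initialize_conformation(spec, model, 4)


class TestMoves:
    def test_crankshaft_zero_angle_is_identity(self, conf20):
        _, _, conf = conf20
        np.testing.assert_allclose(crankshaft_move(conf, 3, 11, 0.0), conf)

    def test_crankshaft_full_turn_is_identity(self, conf20):
        _, _, conf = conf20
        np.testing.assert_allclose(
            crankshaft_move(conf, 3, 11, 2 * math.pi), conf, atol=1e-9
        )

    @given(
        i=st.integers(min_value=0, max_value=17),
        span=st.integers(min_value=2, max_value=19),
        angle=st.floats(min_value=-math.pi, max_value=math.pi),
    )
    @settings(max_examples=60, deadline=None)
    def test_crankshaft_preserves_endpoints_and_rods(self, conf20, i, span, angle):
        spec, _, conf = conf20
        j = min(i + span, 19)
        if j - i < 2:
            return
        out = crankshaft_move(conf, i, j, angle)
        np.testing.assert_array_equal(out[: i + 1], conf[: i + 1])
        np.testing.assert_array_equal(out[j:], conf[j:])
        rods = np.linalg.norm(np.diff(out, axis=0), axis=1)
        np.testing.assert_allclose(rods, spec.bond_length_nm, rtol=1e-9)

    def test_degenerate_crankshaft_axis_is_noop(self, conf20):
        _, _, conf = conf20
        bent = conf.copy()
        bent[5] = bent[1]  # coincident axis endpoints
        out = crankshaft_move(bent, 1, 5, 1.0)
        np.testing.assert_array_equal(out, bent)

    def test_pivot_at_penultimate_locus_moves_only_terminus(self, conf20):
        from bouquetmc.sampler import pivot_move

        _, _, conf = conf20
        out = pivot_move(conf, 18, np.array([0.0, 0.0, 1.0]), 1.0, "tail")
        np.testing.assert_array_equal(out[:19], conf[:19])
        assert not np.allclose(out[19], conf[19])

    def test_arm_rotation_preserves_all_moved_norms(self, conf20):
        _, _, conf = conf20
        out = arm_rotation_move(conf, 7, 1.3, "head")
        np.testing.assert_allclose(
            np.linalg.norm(out[:7], axis=1),
            np.linalg.norm(conf[:7], axis=1),
            rtol=1e-12,
        )
        np.testing.assert_array_equal(out[7:], conf[7:])
        rods = np.diff(out, axis=0)
        np.testing.assert_allclose(
            np.linalg.norm(rods, axis=1),
            np.linalg.norm(np.diff(conf, axis=0), axis=1),
            rtol=1e-9,
        )

    def test_rigid_rotation_preserves_norms_and_bending(self, conf20):
        _, model, conf = conf20
        out = rigid_rotation_move(conf, np.array([1.0, 2.0, -1.0]), 0.9)
        np.testing.assert_allclose(
            np.linalg.norm(out, axis=1), np.linalg.norm(conf, axis=1), rtol=1e-12
        )
        assert bending_energy(out, model) == pytest.approx(
            bending_energy(conf, model), rel=1e-9
        )

    def test_rigid_rotation_to_antipode_costs_two_nu_per_locus(self):
        spec = build_chromosome_spec(100_000, 0, 5)
        model = EnergyModel(
            spec=spec, tether=TetherSpec(mode="telomeres", nu=50.0)
        )
        R = model.geometry.radius_nm
        b = spec.bond_length_nm
        # both telomeres at the SPB pole is unphysical for a straight chain,
        # so park telomere 0 at +z and build the chain along a meridian
        conf = np.array(
            [[0, 0, R], [0, b, R - 1], [0, 2 * b, R - 2], [0, b, R - 3], [0, 0, R]],
            float,
        )
        conf[-1] = conf[-1] / np.linalg.norm(conf[-1]) * R
        e0 = clustering_energy(conf, model)
        flipped = rigid_rotation_move(conf, np.array([1.0, 0.0, 0.0]), math.pi)
        e1 = clustering_energy(flipped, model)
        # both tethered loci move from cos ~ +1 to cos ~ -1: +2 nu each
        assert e1 - e0 == pytest.approx(2 * 50.0 * 2, rel=1e-3)


class TestMetropolisRule:
    def test_zero_delta_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(0.0, rng) for _ in range(1000))

    def test_infeasible_always_rejected(self):
        rng = np.random.default_rng(0)
        assert not any(metropolis_accept(math.inf, rng) for _ in range(1000))

    def test_unit_delta_accepted_at_exp_minus_one(self):
        """dE = +1 kT proposals accept at rate e^-1 (binomial 3 SE check)."""
        rng = np.random.default_rng(12345)
        n = 100_000
        hits = sum(metropolis_accept(1.0, rng) for _ in range(n))
        p = math.exp(-1.0)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_step_never_returns_infeasible(self, conf20):
        spec, model, conf = conf20
        sched = SamplerSchedule(1000, 100, thin=10, seed=0)
        rng = np.random.default_rng(8)
        for _ in range(300):
            conf, _ = metropolis_step(conf, model, sched, rng)
            assert np.all(
                np.linalg.norm(conf, axis=1) <= model.geometry.radius_nm + 1e-6
            )


class TestSchedule:
    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            SamplerSchedule(100, 100)
        with pytest.raises(ValueError):
            SamplerSchedule(100, 10, thin=0)
        with pytest.raises(ValueError):
            SamplerSchedule(100, 10, move_mix=(0.5, 0.2, 0.2))
        with pytest.raises(ValueError):
            SamplerSchedule(100, 10, max_step_angle_rad=0.0)

    def test_retained_count_bookkeeping(self):
        assert SamplerSchedule(10_000_000, 3_000_000, thin=40).retained_count == 175_000
        assert SamplerSchedule(1_000_000, 300_000, thin=40).retained_count == 17_500


class TestRunChain:
    def test_same_seed_bit_identical(self, chrI_spec):
        model = EnergyModel(
            spec=chrI_spec, tether=TetherSpec(mode="telomeres", nu=5.0),
            persistence_length_nm=200.0,
        )
        sched = SamplerSchedule(30_000, 5_000, thin=50, seed=21)
        a = run_chain(chrI_spec, model, sched)
        b = run_chain(chrI_spec, model, sched)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert a.acceptance_rate == b.acceptance_rate

    def test_minimal_schedule_retains_one_sample(self, chrI_spec):
        model = EnergyModel(spec=chrI_spec, persistence_length_nm=200.0)
        sched = SamplerSchedule(140, 100, thin=40, seed=2, tune_during_burnin=False)
        ens = run_chain(chrI_spec, model, sched)
        assert ens.retained_count == 1

    @pytest.mark.parametrize("mode,nu", [("none", 0.0), ("centromere", 50.0),
                                         ("telomeres", 50.0)])
    def test_every_retained_sample_is_valid(self, chrI_spec, mode, nu):
        model = EnergyModel(
            spec=chrI_spec, tether=TetherSpec(mode=mode, nu=nu),
            persistence_length_nm=200.0,
        )
        sched = SamplerSchedule(60_000, 10_000, thin=100, seed=5)
        ens = run_chain(chrI_spec, model, sched)
        assert ens.retained_count == 500
        rep = ens.validate()
        assert rep.ok, rep

    def test_acceptance_rate_recorded_in_unit_interval(self, chrI_flex_pairs):
        for pair in chrI_flex_pairs.values():
            for ens in pair:
                assert 0.05 < ens.acceptance_rate < 0.95

    def test_unconfined_flexible_matches_kratky_porod_within_5pc(self):
        """Spec-level oracle: without confinement the sampler reproduces the
        discrete Kratky-Porod mean squared end-to-end distance."""
        n_loci = 60
        spec = build_chromosome_spec(240_000, 151_000, n_loci)
        model = EnergyModel(
            spec=spec, geometry=NuclearGeometry(radius_nm=1e6),
            persistence_length_nm=200.0,
        )
        sched = SamplerSchedule(250_000, 50_000, thin=20, seed=77)
        ens = run_chain(spec, model, sched)
        r2 = np.sum((ens.positions[:, -1] - ens.positions[:, 0]) ** 2, axis=1)
        pred = discrete_wlc_r2(n_loci - 1, spec.bond_length_nm,
                               model.bending_modulus_kT)
        assert r2.mean() == pytest.approx(pred.mean_sq_end_to_end_nm2, rel=0.05)

    def test_excluded_volume_run_respects_hard_sphere(self):
        spec = build_chromosome_spec(240_000, 151_000, 60)  # bond ~34.6 nm
        model = EnergyModel(
            spec=spec, persistence_length_nm=200.0, excluded_volume_enabled=True
        )
        sched = SamplerSchedule(20_000, 4_000, thin=40, seed=9)
        ens = run_chain(spec, model, sched)
        w = model.ev_adjacency_window
        for conf in ens.positions[::4]:
            d = np.linalg.norm(conf[:, None, :] - conf[None, :, :], axis=2)
            idx = np.arange(spec.n_loci)
            mask = np.abs(idx[:, None] - idx[None, :]) > w
            assert d[mask].min() >= model.ev_min_dist_nm - 1e-9
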