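"""Energy terms: bending, hard-core confinement, vMF clustering, excluded
volume, and their symmetries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from bouquetmc.chain import (
    EnergyModel,
    NuclearGeometry,
    TetherSpec,
    build_chromosome_spec,
    initialize_conformation,
)
from bouquetmc.energy import (
    INFEASIBLE,
    bending_energy,
    clustering_energy,
    confinement_energy,
    excluded_volume_energy,
    total_energy,
)
from bouquetmc.sampler import crankshaft_move, local_bending_delta, pivot_move


def small_spec(n_loci=10, bond=50.0):
    length_bp = int(round(bond * (n_loci - 1) * 40 / 0.34))
    return build_chromosome_spec(length_bp, 0, n_loci)


def straight_chain(n_loci, bond, origin=(0.0, 0.0, 0.0), direction=(1.0, 0.0, 0.0)):
    d = np.asarray(direction, float)
    return np.asarray(origin, float) + bond * np.arange(n_loci)[:, None] * d


class TestBending:
    def test_straight_chain_zero(self):
        spec = small_spec()
        model = EnergyModel(spec=spec, persistence_length_nm=200.0)
        conf = straight_chain(10, spec.bond_length_nm)
        assert bending_energy(conf, model) == pytest.approx(0.0, abs=1e-12)

    def test_all_perpendicular_joints(self):
        spec = small_spec(n_loci=6)
        model = EnergyModel(spec=spec, persistence_length_nm=200.0)
        b = spec.bond_length_nm
        # staircase: +x, +y, +x, +y, ... every consecutive rod pair orthogonal
        steps = [(b, 0, 0), (0, b, 0)] * 3
        conf = np.vstack([[0, 0, 0], np.cumsum(steps[:5], axis=0)])
        g = model.bending_modulus_kT
        assert bending_energy(conf, model) == pytest.approx(g * (6 - 2))

    def test_single_reversal_costs_two_g(self):
        spec = small_spec(n_loci=4)
        model = EnergyModel(spec=spec, persistence_length_nm=200.0)
        b = spec.bond_length_nm
        conf = np.array([[0, 0, 0], [b, 0, 0], [2 * b, 0, 0], [b, 0, 0]], float)
        assert bending_energy(conf, model) == pytest.approx(
            2 * model.bending_modulus_kT
        )

    def test_locus_count_mismatch_rejected(self):
        spec = small_spec()
        model = EnergyModel(spec=spec)
        with pytest.raises(ValueError):
            bending_energy(np.zeros((5, 3)), model)


class TestConfinement:
    geom = NuclearGeometry(radius_nm=1000.0)

    def test_inside_is_zero(self):
        conf = straight_chain(5, 50.0)
        assert confinement_energy(conf, self.geom) == 0.0

    def test_marginally_outside_is_infeasible(self):
        conf = straight_chain(5, 50.0)
        conf[2] = [1000.001, 0.0, 0.0]
        assert confinement_energy(conf, self.geom) == INFEASIBLE

    def test_boundary_is_allowed(self):
        conf = straight_chain(5, 50.0)
        conf[0] = [1000.0, 0.0, 0.0]
        assert confinement_energy(conf, self.geom) == 0.0


class TestClustering:
    def model(self, mode, nu, n_loci=10):
        spec = small_spec(n_loci=n_loci)
        return EnergyModel(spec=spec, tether=TetherSpec(mode=mode, nu=nu))

    def test_nu_zero_is_zero(self):
        model = self.model("telomeres", 0.0)
        conf = straight_chain(10, model.spec.bond_length_nm)
        assert clustering_energy(conf, model) == 0.0

    def test_centromere_at_spb_gives_minus_nu(self):
        model = self.model("centromere", 50.0)
        conf = straight_chain(10, model.spec.bond_length_nm)
        conf[model.spec.centromere_index] = [0.0, 0.0, 1000.0]
        assert clustering_energy(conf, model) == pytest.approx(-50.0)

    def test_antipodal_telomeres_give_plus_two_nu(self):
        model = self.model("telomeres", 50.0)
        conf = straight_chain(10, model.spec.bond_length_nm)
        conf[0] = [0.0, 0.0, -1000.0]
        conf[-1] = [0.0, 0.0, -1000.0]
        assert clustering_energy(conf, model) == pytest.approx(100.0)

    def test_mode_none_raises(self):
        model = self.model("none", 0.0)
        conf = straight_chain(10, model.spec.bond_length_nm)
        with pytest.raises(ValueError):
            clustering_energy(conf, model)


class TestExcludedVolume:
    def test_close_interior_pair_is_infeasible(self):
        spec = small_spec(n_loci=12, bond=50.0)
        model = EnergyModel(spec=spec, excluded_volume_enabled=True)
        conf = straight_chain(12, 50.0)
        conf[9] = conf[2] + [0.0, 39.0, 0.0]  # |i-j| = 7 > window, 39 nm apart
        assert excluded_volume_energy(conf, model) == INFEASIBLE

    def test_straight_chain_short_bond_is_feasible(self):
        # bond 6.8 nm: every pair within 40 nm is a contour neighbour covered
        # by the adjacency window (brute-force pair scan over the full chain)
        spec = build_chromosome_spec(240_000, 151_000, 300)
        model = EnergyModel(spec=spec, excluded_volume_enabled=True)
        conf = straight_chain(300, spec.bond_length_nm, origin=(-1000, 0, 0))
        assert excluded_volume_energy(conf, model) == 0.0

    def test_disabled_flag_always_zero(self):
        spec = small_spec(n_loci=12, bond=50.0)
        model = EnergyModel(spec=spec, excluded_volume_enabled=False)
        conf = straight_chain(12, 50.0)
        conf[9] = conf[2] + [0.0, 1.0, 0.0]
        assert excluded_volume_energy(conf, model) == 0.0


class TestTotalEnergy:
    def test_straight_centred_untethered_is_zero(self):
        spec = small_spec(n_loci=9, bond=50.0)
        model = EnergyModel(spec=spec, persistence_length_nm=200.0)
        conf = straight_chain(9, 50.0, origin=(-200.0, 0.0, 0.0))
        e = total_energy(conf, model)
        assert e.total_kT == pytest.approx(0.0, abs=1e-12)
        assert e.feasible

    def test_escaped_locus_makes_total_infeasible(self):
        spec = small_spec(n_loci=9, bond=50.0)
        model = EnergyModel(spec=spec)
        conf = straight_chain(9, 50.0)
        conf[4] = [0.0, 0.0, 2000.0]
        assert total_energy(conf, model).total_kT == INFEASIBLE

    def test_breakdown_matches_naive_recomputation(self, chrI_spec):
        model = EnergyModel(
            spec=chrI_spec,
            tether=TetherSpec(mode="telomeres", nu=50.0),
            persistence_length_nm=200.0,
        )
        conf = initialize_conformation(chrI_spec, model, 17)
        e = total_energy(conf, model)
        # naive loops, independent of the vectorised implementation
        g = model.bending_modulus_kT
        bend = 0.0
        for k in range(1, chrI_spec.n_loci - 1):
            t1 = conf[k] - conf[k - 1]
            t2 = conf[k + 1] - conf[k]
            bend += g * (1 - np.dot(t1, t2) / np.linalg.norm(t1) / np.linalg.norm(t2))
        mu = model.tether.mu_vec
        clust = sum(
            -50.0 * float(np.dot(mu, conf[i]) / np.linalg.norm(conf[i]))
            for i in (0, chrI_spec.n_loci - 1)
        )
        assert e.bending_kT == pytest.approx(bend, rel=1e-10)
        assert e.clustering_kT == pytest.approx(clust, rel=1e-10)
        assert e.total_kT == pytest.approx(bend + clust, rel=1e-10)


class TestSymmetries:
    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_untethered_energy_rotation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        spec = small_spec(n_loci=20, bond=40.0)
        model = EnergyModel(spec=spec, persistence_length_nm=300.0)
        conf = initialize_conformation(spec, model, seed)
        axis = rng.normal(size=3)
        rot = Rotation.from_rotvec(
            axis / np.linalg.norm(axis) * rng.uniform(-np.pi, np.pi)
        ).as_matrix()
        e0 = total_energy(conf, model)
        e1 = total_energy(conf @ rot.T, model)
        assert e1.bending_kT == pytest.approx(e0.bending_kT, rel=1e-9)
        assert e1.confinement_kT == e0.confinement_kT == 0.0

    @given(seed=st.integers(min_value=0, max_value=10_000),
           angle=st.floats(min_value=-3.0, max_value=3.0))
    @settings(max_examples=25, deadline=None)
    def test_spb_axis_rotation_preserves_clustering(self, seed, angle):
        spec = small_spec(n_loci=20, bond=40.0)
        model = EnergyModel(
            spec=spec, tether=TetherSpec(mode="telomeres", nu=50.0),
            persistence_length_nm=300.0,
        )
        conf = initialize_conformation(spec, model, seed)
        rot = Rotation.from_rotvec([0.0, 0.0, angle]).as_matrix()
        e0 = clustering_energy(conf, model)
        e1 = clustering_energy(conf @ rot.T, model)
        assert e1 == pytest.approx(e0, abs=1e-9)


class TestIncrementalDeltas:
    def test_local_joint_delta_equals_full_recompute(self, chrI_spec):
        """The sampler updates bending energy from the affected joints only;
        over 10,000 random crankshaft/pivot proposals this must agree with a
        full recomputation to 1e-8 kT."""
        model = EnergyModel(spec=chrI_spec, persistence_length_nm=200.0)
        g = model.bending_modulus_kT
        rng = np.random.default_rng(99)
        conf = initialize_conformation(chrI_spec, model, 99)
        n = chrI_spec.n_loci
        worst = 0.0
        for trial in range(10_000):
            if trial % 2 == 0:
                i = int(rng.integers(0, n - 2))
                j = int(rng.integers(i + 2, n))
                prop = crankshaft_move(conf, i, j, float(rng.uniform(-2, 2)))
                joints = [k for k in (i, j) if 1 <= k <= n - 2]
            else:
                k = int(rng.integers(1, n - 1))
                side = "head" if rng.integers(2) == 0 else "tail"
                prop = pivot_move(conf, k, rng.normal(size=3),
                                  float(rng.uniform(-2, 2)), side)
                joints = [k]
            full = bending_energy(prop, model) - bending_energy(conf, model)
            local = local_bending_delta(conf, prop, joints, g)
            worst = max(worst, abs(full - local))
            if trial % 20 == 0:  # random walk so deltas stay generic
                conf = prop
        assert worst < 1e-8
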