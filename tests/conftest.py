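"""Shared fixtures: chromosome specs, tiny schedules, and the moderately
sized homologue-pair ensembles reused across the statistical tests."""

from __future__ import annotations

import numpy as np
import pytest

from bouquetmc.chain import (
    EnergyModel,
    NuclearGeometry,
    TetherSpec,
    build_chromosome_spec,
)
from bouquetmc.sampler import SamplerSchedule, run_chain
from bouquetmc.scenarios import _subseed, make_condition

#: schedule used by the statistical checks: 13,000 retained per chain
STAT_SCHEDULE = (700_000, 180_000, 40)
#: tiny schedule for shape/determinism tests: 400 retained
TINY_SCHEDULE = (20_000, 4_000, 40)


@pytest.fixture(scope="session")
def chrI_spec():
    return build_chromosome_spec(240_000, 151_000, n_loci=300, name="chrI")


@pytest.fixture(scope="session")
def chrI_model(chrI_spec):
    return EnergyModel(spec=chrI_spec, persistence_length_nm=200.0)


def simulate_pair(condition, chromosome, persistence_nm, seed, schedule=STAT_SCHEDULE):
    """Two independent chains of one condition, sub-seeded from ``seed``."""
    out = []
    for copy_idx in range(2):
        spec, model, sched = make_condition(
            condition,
            chromosome,
            persistence_nm,
            scale="desk",
            seed=_subseed(seed, copy_idx),
            schedule_override=schedule,
        )
        out.append(run_chain(spec, model, sched))
    return out


@pytest.fixture(scope="session")
def chrI_flex_pairs():
    """chrI homologue pairs (l_p 200 nm) for the condition grid, one seed each."""
    conditions = {
        "no_tether": 201,
        "rabl": 202,
        "telomeres_tethered": 203,
        "early_bouquet": 204,
        "loose_bouquet": 205,
        "tight_bouquet": 206,
    }
    return {
        cond: simulate_pair(cond, "chrI", 200.0, seed)
        for cond, seed in conditions.items()
    }


@pytest.fixture(scope="session")
def unconfined_runs():
    """Untethered chains in an effectively unbounded sphere at three
    stiffness levels, for comparison against the discrete Kratky-Porod
    closed forms."""
    runs = {}
    for g_beta, seed in ((0.0, 31), (5.0, 32), (29.3, 33)):
        n_rods = 50
        bond = 10.0
        spec = build_chromosome_spec(
            # genomic length chosen so the derived bond length is exactly 10 nm
            int(round(bond * n_rods * 40 / 0.34)),
            0,
            n_loci=n_rods + 1,
            name=f"wlc{g_beta}",
        )
        model = EnergyModel(
            spec=spec,
            geometry=NuclearGeometry(radius_nm=1e6),
            tether=TetherSpec(mode="none"),
            persistence_length_nm=g_beta * spec.bond_length_nm,
        )
        sched = SamplerSchedule(400_000, 80_000, thin=20, seed=seed)
        runs[g_beta] = run_chain(spec, model, sched)
    return runs


def batch_mean_se(series: np.ndarray, n_batches: int = 40) -> float:
    """Standard error of the mean of an autocorrelated series (batch means)."""
    series = np.asarray(series, dtype=float)
    usable = (series.size // n_batches) * n_batches
    batches = series[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))
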