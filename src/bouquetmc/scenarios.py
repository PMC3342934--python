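"""Named presets for the experimental grid and drivers producing full
analytics bundles.

Conditions map onto tether mode and clustering strength nu:

==================  ===========  ====
condition           tether mode  nu
==================  ===========  ====
no_tether           none         --
rabl                centromere   50
telomeres_tethered  telomeres    0
early_bouquet       telomeres    5
loose_bouquet       telomeres    10
tight_bouquet       telomeres    50
==================  ===========  ====

Chromosomes are modelled on S. cerevisiae chromosome I (~240 kb), XVI
(~950 kb) and IV (~1530 kb); centromere genomic positions use documented
approximate values and are recorded in every bundle.  Persistence length is
200 nm (flexible, interphase-like) or 2000 nm (rigid).

Two schedule scales: ``paper`` replays the production bookkeeping
(10M samples, 3M burn-in, thin 40 -> 175,000 retained); ``desk`` is the
same schedule scaled for a single workstation (1M, 300k, 40 -> 17,500
retained), sized so each condition runs in minutes while retaining
>= 10,000 conformations per chain.

Homologues (and heterologue partners) are simulated independently with
sub-seeds derived from the run seed by fixed offsets; the k-th retained
sample of each chain is treated as one nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import (
    ConditionComparison,
    DistanceMap,
    RankScoreCurve,
    allelic_profile,
    compare_conditions,
    ectopic_means,
    inter_ldm,
    intra_ldm,
    rank_scores,
    telomere_cloud,
)
from .chain import (
    ChromosomeSpec,
    EnergyModel,
    NuclearGeometry,
    TetherSpec,
    build_chromosome_spec,
)
from .sampler import DESK_SCHEDULE, PAPER_SCHEDULE, Ensemble, SamplerSchedule, run_chain

__all__ = [
    "CHROMOSOMES",
    "CONDITIONS",
    "SCALES",
    "TIMECOURSE_ORDER",
    "ConditionPreset",
    "ExperimentBundle",
    "make_condition",
    "run_homologue_experiment",
    "run_heterologue_experiment",
    "run_timecourse",
]

#: (genomic length bp, centromere position bp)
CHROMOSOMES: dict[str, tuple[int, int]] = {
    "chrI": (240_000, 151_000),
    "chrXVI": (950_000, 556_000),
    "chrIV": (1_530_000, 450_000),
}

#: condition -> (tether mode, nu)
CONDITIONS: dict[str, tuple[str, float]] = {
    "no_tether": ("none", 0.0),
    "rabl": ("centromere", 50.0),
    "telomeres_tethered": ("telomeres", 0.0),
    "early_bouquet": ("telomeres", 5.0),
    "loose_bouquet": ("telomeres", 10.0),
    "tight_bouquet": ("telomeres", 50.0),
}

SCALES: dict[str, tuple[int, int, int]] = {
    "paper": PAPER_SCHEDULE,
    "desk": DESK_SCHEDULE,
}

TIMECOURSE_ORDER = [
    "no_tether",
    "rabl",
    "telomeres_tethered",
    "early_bouquet",
    "loose_bouquet",
    "tight_bouquet",
]

PERSISTENCE_CHOICES_NM = (200.0, 2000.0)


@dataclass(frozen=True)
class ConditionPreset:
    """One cell of the experimental grid."""

    condition: str
    chromosome: str
    persistence_nm: float = 200.0
    scale: str = "desk"
    nu_override: float | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; choose from {sorted(CONDITIONS)}"
            )
        if self.chromosome not in CHROMOSOMES:
            raise ValueError(
                f"unknown chromosome {self.chromosome!r}; choose from {sorted(CHROMOSOMES)}"
            )
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; choose from {sorted(SCALES)}")


@dataclass
class ExperimentBundle:
    """Simulated ensembles plus the full analytics for one preset."""

    preset: ConditionPreset
    seed: int
    ensembles: list[Ensemble]
    homologue_map: DistanceMap | None = None
    heterologue_map: DistanceMap | None = None
    allelic: np.ndarray | None = None
    allelic_sd: np.ndarray | None = None
    rank_allelic: RankScoreCurve | None = None
    rank_ectopic: RankScoreCurve | None = None
    intra_maps: list[DistanceMap] = field(default_factory=list)
    telomere_clouds: list[np.ndarray] = field(default_factory=list)
    comparisons: dict[str, ConditionComparison] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def _subseed(seed: int, index: int) -> int:
    """Deterministic sub-seed for chain ``index`` of run ``seed`` (< 2^31)."""
    return int(np.random.SeedSequence([int(seed), int(index)]).generate_state(1)[0] % (2**31))


def make_condition(
    condition: str,
    chromosome: str,
    persistence_nm: float,
    scale: str = "desk",
    seed: int = 0,
    n_loci: int = 300,
    nu_override: float | None = None,
    diameter_nm: float = 2000.0,
    excluded_volume: bool = False,
    schedule_override: tuple[int, int, int] | None = None,
) -> tuple[ChromosomeSpec, EnergyModel, SamplerSchedule]:
    """Resolve a named condition into a fully specified (spec, model, schedule).

    Pure and deterministic over the declared vocabularies; ``nu_override``
    exposes the intermediate clustering level (nu = 20) that the named
    presets do not use.
    """
    preset = ConditionPreset(condition, chromosome, persistence_nm, scale, nu_override)
    length_bp, cen_bp = CHROMOSOMES[chromosome]
    mode, nu = CONDITIONS[condition]
    if nu_override is not None:
        if mode == "none":
            raise ValueError("nu_override is meaningless without a tether")
        nu = float(nu_override)
    spec = build_chromosome_spec(length_bp, cen_bp, n_loci=n_loci, name=chromosome)
    geometry = NuclearGeometry(radius_nm=diameter_nm / 2.0)
    tether = TetherSpec(mode=mode, nu=nu, mu=geometry.spb_direction)
    model = EnergyModel(
        spec=spec,
        geometry=geometry,
        tether=tether,
        persistence_length_nm=float(persistence_nm),
        excluded_volume_enabled=excluded_volume,
    )
    n_total, n_burn, thin = (
        schedule_override if schedule_override is not None else SCALES[scale]
    )
    schedule = SamplerSchedule(n_total=n_total, n_burn_in=n_burn, thin=thin, seed=int(seed))
    del preset
    return spec, model, schedule


def _simulate_pair(
    preset: ConditionPreset, seed: int, schedule_override=None
) -> list[Ensemble]:
    out = []
    for copy_idx in range(2):
        spec, model, schedule = make_condition(
            preset.condition,
            preset.chromosome,
            preset.persistence_nm,
            preset.scale,
            seed=_subseed(seed, copy_idx),
            nu_override=preset.nu_override,
            schedule_override=schedule_override,
        )
        out.append(run_chain(spec, model, schedule))
    return out


def run_homologue_experiment(
    preset: ConditionPreset,
    seed: int,
    schedule_override: tuple[int, int, int] | None = None,
    n_cloud_cells: int = 500,
) -> ExperimentBundle:
    """Two independent homologue ensembles and the derived analytics.

    Produces the homologue LDM, the allelic profile with per-locus SD, the
    allelic and ectopic rank-score curves and a telomere cloud.
    """
    ensembles = _simulate_pair(preset, seed, schedule_override)
    homologue = inter_ldm(ensembles[0], ensembles[1])
    profile, sd = allelic_profile(homologue)
    ect = ectopic_means(homologue)
    n = homologue.n_loci
    rank_a = rank_scores(profile, n)
    rank_e = rank_scores(ect, n - 1)  # N^2 - N values in N - 1 bins of N
    clouds = [
        telomere_cloud(e, min(n_cloud_cells, e.retained_count)) for e in ensembles
    ]
    return ExperimentBundle(
        preset=preset,
        seed=seed,
        ensembles=ensembles,
        homologue_map=homologue,
        allelic=profile,
        allelic_sd=sd,
        rank_allelic=rank_a,
        rank_ectopic=rank_e,
        telomere_clouds=clouds,
        metadata=_provenance(preset, seed, ensembles),
    )


def run_heterologue_experiment(
    preset_a: ConditionPreset,
    preset_b: ConditionPreset,
    seed: int,
    schedule_override: tuple[int, int, int] | None = None,
) -> ExperimentBundle:
    """Cross-chromosome distance map between two independently simulated
    chains sharing the condition, persistence and SPB direction."""
    for attr in ("condition", "persistence_nm", "scale"):
        if getattr(preset_a, attr) != getattr(preset_b, attr):
            raise ValueError(f"presets differ in {attr}; heterologue pairing undefined")
    ensembles = []
    for copy_idx, preset in enumerate((preset_a, preset_b)):
        spec, model, schedule = make_condition(
            preset.condition,
            preset.chromosome,
            preset.persistence_nm,
            preset.scale,
            seed=_subseed(seed, copy_idx),
            nu_override=preset.nu_override,
            schedule_override=schedule_override,
        )
        ensembles.append(run_chain(spec, model, schedule))
    het = inter_ldm(ensembles[0], ensembles[1])
    n_means = het.values.size
    rank = rank_scores(het.values.ravel(), het.n_loci)
    bundle = ExperimentBundle(
        preset=preset_a,
        seed=seed,
        ensembles=ensembles,
        heterologue_map=het,
        rank_ectopic=rank,
        metadata=_provenance(preset_a, seed, ensembles),
    )
    bundle.metadata["chromosome_b"] = preset_b.chromosome
    bundle.metadata["n_heterologue_means"] = int(n_means)
    return bundle


def run_timecourse(
    chromosome: str,
    persistence_nm: float,
    scale: str = "desk",
    seed: int = 0,
    schedule_override: tuple[int, int, int] | None = None,
) -> dict[str, ExperimentBundle]:
    """Ordered bundles for the Rabl -> bouquet time course.

    Six stationary conditions mimic time-course sampling of the continuous
    reorganisation; each non-baseline condition is compared against
    ``no_tether`` with KS and Wilcoxon rank-sum tests on the intra-chain
    mean-distance vectors (all N x N means of the first homologue).
    """
    bundles: dict[str, ExperimentBundle] = {}
    for cond_idx, condition in enumerate(TIMECOURSE_ORDER):
        preset = ConditionPreset(condition, chromosome, persistence_nm, scale)
        bundle = run_homologue_experiment(
            preset, _subseed(seed, 100 + cond_idx), schedule_override
        )
        bundle.intra_maps = [intra_ldm(e) for e in bundle.ensembles]
        bundles[condition] = bundle
    base = bundles["no_tether"].intra_maps[0].values.ravel()
    for condition, bundle in bundles.items():
        if condition == "no_tether":
            continue
        bundle.comparisons["no_tether"] = compare_conditions(
            bundle.intra_maps[0].values.ravel(), base
        )
    return bundles


def _provenance(preset: ConditionPreset, seed: int, ensembles: list[Ensemble]) -> dict:
    spec = ensembles[0].spec
    model = ensembles[0].model
    sched = ensembles[0].schedule
    return {
        "condition": preset.condition,
        "chromosome": preset.chromosome,
        "length_bp": spec.length_bp,
        "centromere_bp": spec.centromere_bp,
        "centromere_index": spec.centromere_index,
        "n_loci": spec.n_loci,
        "persistence_nm": model.persistence_length_nm,
        "tether_mode": model.tether.mode,
        "nu": model.tether.nu,
        "scale": preset.scale,
        "schedule": [sched.n_total, sched.n_burn_in, sched.thin],
        "seed": int(seed),
        "sub_seeds": [e.schedule.seed for e in ensembles],
        "retained_counts": [e.retained_count for e in ensembles],
        "acceptance_rates": [e.acceptance_rate for e in ensembles],
    }
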