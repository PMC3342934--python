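"""Ensemble analytics: locus distance maps, rank scores, allelic profiles,
telomere clouds, and two-sample condition comparisons.

A locus distance map (LDM) is the N x N matrix of ensemble-mean pairwise
locus distances expressed as fractions of the nuclear diameter (ND, 2 um by
default).  Intra maps average distances within one chain; homologue and
heterologue maps pair the k-th retained sample of two independently
simulated chains as one nucleus, so correlation between the two chains
arises only through the shared SPB direction.  The diagonal of a homologue
map holds the allelic (same-locus) distances; everything off the diagonal
is ectopic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import _kernel
from .sampler import Ensemble

__all__ = [
    "DistanceMap",
    "RankScoreCurve",
    "ConditionComparison",
    "intra_ldm",
    "inter_ldm",
    "allelic_profile",
    "rank_scores",
    "ectopic_means",
    "compare_conditions",
    "telomere_cloud",
]

#: below this many pooled observations the rank-sum test uses the exact null
EXACT_RANKSUM_MAX_N = 50


@dataclass
class DistanceMap:
    """Mean pairwise locus distances in ND fractions, with per-entry SD."""

    values: np.ndarray  # (N, N) ND fractions
    sd: np.ndarray  # (N, N) ND fractions, SD across samples
    kind: str  # intra | homologue | heterologue
    n_samples: int
    nd_nm: float  # normalisation constant (nuclear diameter, nm)
    specs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("intra", "homologue", "heterologue"):
            raise ValueError(f"unknown map kind {self.kind!r}")
        lo, hi = float(np.min(self.values)), float(np.max(self.values))
        # two points in the sphere are at most one diameter apart
        if lo < 0.0 or hi > 1.0 + 1e-9:
            raise ValueError(f"LDM entries outside [0, 1]: min={lo}, max={hi}")

    @property
    def values_nm(self) -> np.ndarray:
        return self.values * self.nd_nm

    @property
    def n_loci(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class RankScoreCurve:
    """Ranked means averaged within equal consecutive bins (non-decreasing)."""

    binned_means: np.ndarray
    bin_size: int
    n_input_means: int


@dataclass(frozen=True)
class ConditionComparison:
    """Two-sided two-sample KS and Wilcoxon rank-sum results."""

    ks_statistic: float
    ks_p: float
    wilcoxon_statistic: float
    wilcoxon_p: float
    n_a: int
    n_b: int


def _check_pairing(a: Ensemble, b: Ensemble) -> None:
    if a.retained_count != b.retained_count:
        raise ValueError(
            f"retained counts differ ({a.retained_count} vs {b.retained_count}); "
            "index pairing requires equal counts"
        )
    if a.model.geometry != b.model.geometry:
        raise ValueError("ensembles were simulated in different nuclear geometries")


def intra_ldm(ensemble: Ensemble) -> DistanceMap:
    """Mean intra-chain distances; symmetric with zero diagonal."""
    if ensemble.retained_count == 0:
        raise ValueError("empty ensemble")
    nd = ensemble.model.geometry.diameter_nm
    mean, sd = _kernel.pair_stats_intra(ensemble.positions)
    return DistanceMap(
        values=mean / nd,
        sd=sd / nd,
        kind="intra",
        n_samples=ensemble.retained_count,
        nd_nm=nd,
        specs={"a": ensemble.spec.name},
    )


def inter_ldm(ensemble_a: Ensemble, ensemble_b: Ensemble) -> DistanceMap:
    """Mean distances between index-paired samples of two chains.

    The map kind is ``homologue`` when the two chains share a chromosome
    spec (diagonal = allelic distances) and ``heterologue`` otherwise.
    """
    if ensemble_a.retained_count == 0:
        raise ValueError("empty ensemble")
    _check_pairing(ensemble_a, ensemble_b)
    nd = ensemble_a.model.geometry.diameter_nm
    mean, sd = _kernel.pair_stats_inter(ensemble_a.positions, ensemble_b.positions)
    homologous = (
        ensemble_a.spec.length_bp == ensemble_b.spec.length_bp
        and ensemble_a.spec.n_loci == ensemble_b.spec.n_loci
    )
    return DistanceMap(
        values=mean / nd,
        sd=sd / nd,
        kind="homologue" if homologous else "heterologue",
        n_samples=ensemble_a.retained_count,
        nd_nm=nd,
        specs={"a": ensemble_a.spec.name, "b": ensemble_b.spec.name},
    )


def allelic_profile(homologue_map: DistanceMap) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal of a homologue map (telomere to telomere) with per-locus SD.

    The SD is the per-locus standard deviation of the allelic distance
    across retained samples.
    """
    if homologue_map.kind != "homologue":
        raise ValueError(f"allelic profile requires a homologue map, got {homologue_map.kind!r}")
    return np.diag(homologue_map.values).copy(), np.diag(homologue_map.sd).copy()


def ectopic_means(homologue_map: DistanceMap) -> np.ndarray:
    """All off-diagonal entries of a homologue map (N^2 - N values)."""
    if homologue_map.kind != "homologue":
        raise ValueError(f"ectopic means require a homologue map, got {homologue_map.kind!r}")
    v = homologue_map.values
    mask = ~np.eye(v.shape[0], dtype=bool)
    return v[mask]


def rank_scores(means: np.ndarray, n_bins: int) -> RankScoreCurve:
    """Sort ascending (stable), split into equal consecutive bins, average.

    Inputs are constructed to divide evenly (300 allelic means into 300
    bins, 90,000 intra means into 300 bins of 300, 89,700 ectopic means
    into 299 bins of 300); any other size is an error, not a silent
    truncation.
    """
    means = np.asarray(means, dtype=float).ravel()
    if means.size == 0:
        raise ValueError("empty input")
    if n_bins < 1 or means.size % n_bins != 0:
        raise ValueError(
            f"{means.size} means do not divide evenly into {n_bins} bins"
        )
    bin_size = means.size // n_bins
    ranked = np.sort(means, kind="stable")
    binned = ranked.reshape(n_bins, bin_size).mean(axis=1)
    return RankScoreCurve(binned_means=binned, bin_size=bin_size, n_input_means=means.size)


def compare_conditions(means_a: np.ndarray, means_b: np.ndarray) -> ConditionComparison:
    """Two-sided two-sample KS and Wilcoxon rank-sum tests on mean vectors.

    The rank-sum test uses the normal approximation with tie and continuity
    corrections, switching to the exact null distribution when the pooled
    sample is small.  Degenerate all-tied inputs are well defined under the
    tie correction (the KS statistic is then 0 and the rank-sum p is 1).
    """
    a = np.asarray(means_a, dtype=float).ravel()
    b = np.asarray(means_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both inputs must be non-empty")
    ks = stats.ks_2samp(a, b, alternative="two-sided")
    if np.array_equal(a, b) or (np.all(a == a[0]) and np.all(b == a[0])):
        # identical samples: rank-sum is exactly its null mean
        w_stat, w_p = float(a.size * (a.size + b.size + 1) / 2.0), 1.0
    else:
        method = "exact" if a.size + b.size < EXACT_RANKSUM_MAX_N else "asymptotic"
        try:
            mw = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        except ValueError:
            mw = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        w_stat, w_p = float(mw.statistic), float(mw.pvalue)
    return ConditionComparison(
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
        wilcoxon_statistic=w_stat,
        wilcoxon_p=min(1.0, w_p),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def telomere_cloud(ensemble: Ensemble, n_cells: int) -> np.ndarray:
    """Telomere position pairs from evenly spaced retained samples.

    Returns an ``(n_cells, 2, 3)`` array of the first- and last-locus
    positions, mirroring the red-dot telomere distributions drawn from 500
    sampled nuclei.
    """
    s = ensemble.retained_count
    if n_cells > s:
        raise ValueError(f"requested {n_cells} cells but only {s} retained samples")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    # floor(k * s / n_cells) is strictly increasing whenever n_cells <= s
    idx = (np.arange(n_cells) * s // n_cells).astype(int)
    return ensemble.positions[idx][:, [0, -1], :].copy()
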