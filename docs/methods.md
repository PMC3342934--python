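# Methods

## Model

Each chromosome is a discretised worm-like chain: `N` point loci joined by
`N − 1` inextensible rods of equal length `b`, confined to a hard sphere of
radius `R` (default 1000 nm; all distances are reported as fractions of the
nuclear diameter ND = 2R).  The genomic-to-physical mapping assumes a
uniform fibre: contour length `L_c = L_bp × rise / compaction` with
rise = 0.34 nm/bp (B-DNA) and compaction = 40 (30-nm fibre); both are
exposed as parameters.  The centromere locus index is
`round(cen_bp / L_bp × (N − 1))`.

Equilibrium conformations follow a Boltzmann distribution over

* **bending** `gβ Σ (1 − t̂_i · t̂_{i+1})` with the small-angle
  discrete-WLC correspondence `gβ = l_p / b`.  This mapping is validated in
  the test suite against the exact discrete Kratky–Porod relations
  `⟨cos θ⟩ = coth(gβ) − 1/gβ` and the closed-form `⟨R²⟩`, sampled by a
  direct (non-MCMC) chain grower that shares no code with the sampler.
* **confinement**: hard-core — zero inside the sphere (boundary included,
  tethered loci live there), infeasible outside.  Infeasibility is an exact
  `inf` sentinel, never a large float, so accept/reject logic is exact.
* **clustering**: each tethered locus contributes `−ν μ̂ · x̂`, the
  log-density of a von Mises–Fisher distribution on the sphere with mean
  direction `μ` (the SPB, +z) and concentration `ν`.  vMF normalising
  constants are dropped: ν is constant within a run, so they cancel in
  every Metropolis ratio; utilities that need a true log-density must add
  `log(ν / (4π sinh ν))` back.
* **excluded volume** (optional, off by default): hard-sphere rejection of
  locus pairs closer than 40 nm.  Pairs with contour separation
  `|i − j| ≤ ceil(40 nm / b)` are exempt, because contour neighbours
  necessarily violate the hard sphere whenever `b < 40 nm`; the exemption
  window is recorded in run metadata.  With `l_p ≥ 200 nm` the term has a
  negligible effect on distance statistics and is therefore not part of the
  named presets.

Tethering is a hard constraint, not a penalty: tethered loci are placed on
the sphere at initialisation and moved only by norm-preserving rotations.

## Sampling

One "sample" is one attempted Metropolis step.  The production bookkeeping
is 10 M samples, 3 M burn-in, thinning 40 (175,000 retained); the `desk`
preset is the same schedule at one tenth (1 M / 300 k / 40 → 17,500
retained), chosen so one condition runs in seconds-to-minutes on a single
CPU while keeping ≥ 10,000 retained conformations per chain.  Proposals
(all with symmetric densities, angles uniform in ±amplitude):

* **crankshaft** (weight 0.7): rotate the loci strictly between two chain
  points about the axis through them.  Rods in the segment rotate rigidly,
  so only the two boundary joints change bending energy; proposals spanning
  a tethered centromere are counted as rejected.
* **pivot / arm rotation** (0.15): rotate one terminal segment.  On sides
  free of tethered loci this is a pivot about a random axis through the
  hinge locus.  In telomere mode the segment instead rotates about the axis
  through the origin and the hinge locus, which preserves every norm — the
  moved telomere stays exactly on the sphere.  This move is load-bearing:
  crankshafts fix both endpoints and rigid rotations preserve relative
  geometry, so without it the telomere–telomere angle would never change
  and the chain would not be ergodic.
* **rigid rotation** (0.15): whole-chain rotation about the nucleus centre;
  only the clustering energy can change.  This is how a tethered centromere
  explores the sphere surface.

Energy differences are computed incrementally from the affected joints and
loci (verified against full recomputation to < 1e−8 kT over 10⁴ random
moves); hard-constraint violations reject before any Metropolis draw.
Proposal amplitudes start at π/2 and are auto-tuned during burn-in only
(multiplicative 15% steps toward a 30–50% acceptance window, frozen at the
end of burn-in to preserve stationarity).  Floating-point drift from
composed rotations is capped by rebuilding the chain from its anchor with
exact rod lengths every 2¹⁶ steps; retained samples satisfy the rod
(1e−9 relative), confinement and tether (1e−6 nm) tolerances throughout.

Initialisation grows the chain as a persistent random walk (rod directions
vMF-distributed about the previous direction with concentration `gβ`, the
exact unconfined equilibrium), rejecting out-of-sphere placements.  Tether
points are drawn from the clustering vMF; for telomere tethering the walk
is steered outward near the far end (enforcing `|x| ≥ R − m·b` with `m`
rods remaining) so the final locus closes onto the sphere exactly.  Any
feasible start suffices given the 30% burn-in; infeasible geometries (e.g.
a rod longer than the nuclear diameter) raise an explicit error after a
bounded retry budget.

Each chain has its own seed; experiment drivers derive per-chain sub-seeds
from one run seed with `numpy` `SeedSequence`, so homologues are
independent but a whole bundle is reproducible from a single integer.

## Analytics

Locus distance maps average pairwise locus distances over retained samples,
in ND fractions: intra-chain (symmetric, zero diagonal), homologue (the
k-th retained samples of two independently simulated chains form one
nucleus; the diagonal holds the 300 allelic distances) and heterologue
(all 300 × 300 cross-chromosome pairs).  Because the model has no
inter-chromosome energy terms, correlation between paired chains arises
only through the shared SPB direction — pairing by sample index is
therefore exact, not an approximation.  Every map carries a per-entry SD
across samples; allelic profiles are reported with that per-locus SD (an
SD across nuclei, not a standard error).  Raw nanometre matrices are kept
alongside the ND-normalised ones.

Rank-score curves sort means ascending (stable sort) and average equal
consecutive bins; sizes must divide exactly (300 allelic means → 300 bins,
90,000 intra or heterologue means → 300 bins of 300, 89,700 ectopic means →
299 bins of 300) — any other size is an error rather than a silent
truncation.  Condition comparisons use the two-sided two-sample
Kolmogorov–Smirnov test and the Wilcoxon rank-sum test (normal
approximation with tie and continuity corrections; exact null below 50
pooled observations; all-tied inputs return KS = 0, p = 1).

## Parameters that matter

| parameter | default | why |
|---|---|---|
| nuclear diameter | 2 µm | published haploid/diploid yeast estimates |
| N (loci per chain) | 300 | converged vs the continuous WLC (see below); ~40 nm segments for the longest chromosome |
| compaction | 40× | 30-nm fibre vs dsDNA |
| l_p | 200 / 2000 nm | interphase-like flexible vs near-pachytene rigid |
| ν levels | 0, 5, 10, 20, 50 | uniform → weak → intermediate → strong clustering; the named bouquet presets use 5/10/50, ν = 20 stays available as an override |
| schedule | 10M/3M/40 (paper), 1M/300k/40 (desk) | desk keeps ≥ 10k retained samples per chain |

The discretisation-convergence scan (`oracles.convergence_scan`) holds
contour and persistence length fixed while `b` shrinks with N, and shows
the mean pairwise locus distance plateauing: beyond N ≈ 75 further
refinement changes the statistic by under ~2%, and N = 150 agrees with
N = 300 within Monte Carlo error (~0.5–1% at 50,000 retained samples).

## What the simulations do and do not emulate

The generator reproduces equilibrium ensembles of isolated chains in a
spherical nucleus: chromosome-length and rigidity dependence of
intra-chain spread, homologue juxtaposition and allelic-vs-ectopic
competition under the Rabl → bouquet conditions.  It does **not** include
inter-chromosomal excluded volume, the nucleolus or other prohibited
subnuclear regions, rapid prophase movements, homology-dependent pairing
forces, or sister chromatids — so passing tests demonstrate properties of
the architectural model, not quantitative predictions for crowded real
nuclei, where absolute distances would shift.

## Numerical and design choices

* Units: nanometres and k_BT with β = 1; temperature never enters
  independently of `gβ`.
* Centromere genomic positions are not uniquely defined by coarse
  published maps; the presets use ~151/240 kb (chrI), ~556/950 kb (chrXVI),
  ~450/1530 kb (chrIV), configurable and recorded in every bundle.
* Degenerate crankshaft axes (coincident endpoints) are counted as
  rejected proposals; pivot sides containing a tethered locus are never
  proposed.
* The homologue pairing convention, sub-seed offsets, retained counts and
  acceptance rates are written into every bundle's metadata; ensembles
  round-trip bit-exactly through the `.npz` container and the 17-digit
  text export.
* Heatmap rendering (fixed 0→1 ND red→blue scale) is presentation-only and
  excluded from all numeric checks.

## Known limitations

* Soft (finite) confinement walls are not modelled; the boundary is hard.
* Simultaneous centromere **and** telomere tethering is out of scope.
* Extreme-value map statistics (the maximum over ~90,000 mean entries)
  carry more Monte Carlo uncertainty than profile means; desk-scale runs
  resolve them to roughly ±0.01 ND.
* At very short persistence lengths (≲ 30 nm) the neglected excluded
  volume would become important; the defaults stay well above that regime.
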