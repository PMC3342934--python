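"""Domain types and conformation construction for confined worm-like chains.

A chromosome is coarse-grained into ``n_loci`` point loci joined by
``n_loci - 1`` inextensible rods of equal length *b*.  The fibre contour
length derives from the genomic length assuming a fixed dsDNA helical rise
(0.34 nm/bp for B-DNA) compressed by a compaction factor (40-fold for a
30-nm fibre).  All positions are in nanometres, measured from the nuclear
centre; the nucleus is a hard sphere of radius ``radius_nm`` (default
1000 nm, i.e. a 2 um nucleus) and the spindle pole body (SPB) sits on the
positive z axis.

Tethering modes:

``none``
    The chain is only confined to the sphere.
``centromere``
    The centromere locus is constrained to lie exactly on the sphere
    surface, optionally pulled toward the SPB by a von Mises-Fisher (vMF)
    clustering potential of concentration ``nu`` (the Rabl configuration
    uses ``nu = 50``).
``telomeres``
    Both end loci are constrained to the sphere surface, each subject to an
    independent vMF clustering potential (the bouquet conditions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DEFAULT_COMPACTION",
    "DEFAULT_RISE_NM_PER_BP",
    "ChromosomeSpec",
    "NuclearGeometry",
    "TetherSpec",
    "EnergyModel",
    "ValidationReport",
    "InitializationError",
    "build_chromosome_spec",
    "initialize_conformation",
    "validate_conformation",
    "sample_uniform_sphere",
    "sample_vmf",
]

DEFAULT_COMPACTION = 40.0
DEFAULT_RISE_NM_PER_BP = 0.34

#: Relative tolerance on rod lengths (inextensibility).
ROD_RTOL = 1e-9
#: Absolute tolerance (nm) on tethered loci lying on the sphere surface.
TETHER_ATOL_NM = 1e-6
#: Absolute tolerance (nm) on the hard-core confinement boundary.
CONFINE_ATOL_NM = 1e-6


@dataclass(frozen=True)
class ChromosomeSpec:
    """Discretisation of one chromosome into an inextensible-rod chain.

    Derived quantities are exposed as properties so the invariants
    (contour length, rod length, centromere index) hold by construction.
    """

    name: str
    length_bp: int
    centromere_bp: int
    n_loci: int = 300
    compaction_factor: float = DEFAULT_COMPACTION
    rise_nm_per_bp: float = DEFAULT_RISE_NM_PER_BP

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"length_bp must be positive, got {self.length_bp}")
        if not (0 <= self.centromere_bp <= self.length_bp):
            raise ValueError(
                f"centromere_bp={self.centromere_bp} outside chromosome "
                f"[0, {self.length_bp}]"
            )
        if self.n_loci < 2:
            raise ValueError(f"n_loci must be >= 2, got {self.n_loci}")
        if self.compaction_factor <= 0 or self.rise_nm_per_bp <= 0:
            raise ValueError("compaction_factor and rise_nm_per_bp must be positive")

    @property
    def contour_length_nm(self) -> float:
        return self.length_bp * self.rise_nm_per_bp / self.compaction_factor

    @property
    def bond_length_nm(self) -> float:
        return self.contour_length_nm / (self.n_loci - 1)

    @property
    def centromere_index(self) -> int:
        return int(round(self.centromere_bp / self.length_bp * (self.n_loci - 1)))


def build_chromosome_spec(
    length_bp: int,
    centromere_bp: int,
    n_loci: int = 300,
    compaction_factor: float = DEFAULT_COMPACTION,
    rise_nm_per_bp: float = DEFAULT_RISE_NM_PER_BP,
    name: str = "chr",
) -> ChromosomeSpec:
    """Validate arguments and build a :class:`ChromosomeSpec`."""
    return ChromosomeSpec(
        name=name,
        length_bp=int(length_bp),
        centromere_bp=int(centromere_bp),
        n_loci=int(n_loci),
        compaction_factor=float(compaction_factor),
        rise_nm_per_bp=float(rise_nm_per_bp),
    )


@dataclass(frozen=True)
class NuclearGeometry:
    """Spherical nucleus: radius and the SPB direction (unit vector)."""

    radius_nm: float = 1000.0
    spb_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("radius_nm must be positive")
        n = math.sqrt(sum(c * c for c in self.spb_direction))
        if abs(n - 1.0) > 1e-12:
            raise ValueError(f"spb_direction must be a unit vector, |v| = {n!r}")

    @property
    def diameter_nm(self) -> float:
        return 2.0 * self.radius_nm

    @property
    def spb(self) -> np.ndarray:
        return np.asarray(self.spb_direction, dtype=float)


@dataclass(frozen=True)
class TetherSpec:
    """Tether mode plus the vMF clustering parameters (nu, mu)."""

    mode: str = "none"
    nu: float = 0.0
    mu: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.mode not in ("none", "centromere", "telomeres"):
            raise ValueError(f"unknown tether mode {self.mode!r}")
        if self.nu < 0:
            raise ValueError("nu must be >= 0")
        n = math.sqrt(sum(c * c for c in self.mu))
        if abs(n - 1.0) > 1e-12:
            raise ValueError("mu must be a unit vector")

    @property
    def mu_vec(self) -> np.ndarray:
        return np.asarray(self.mu, dtype=float)


@dataclass(frozen=True)
class EnergyModel:
    """All parameters entering the Boltzmann energy (units of kT, beta = 1).

    The per-joint bending modulus is the standard small-angle discrete-WLC
    correspondence g*beta = l_p / b (persistence length over rod length).
    """

    spec: ChromosomeSpec
    geometry: NuclearGeometry = field(default_factory=NuclearGeometry)
    tether: TetherSpec = field(default_factory=TetherSpec)
    persistence_length_nm: float = 200.0
    beta: float = 1.0
    excluded_volume_enabled: bool = False
    ev_min_dist_nm: float = 40.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.persistence_length_nm < 0:
            raise ValueError("persistence_length_nm must be >= 0")
        if self.ev_min_dist_nm <= 0:
            raise ValueError("ev_min_dist_nm must be positive")

    @property
    def bending_modulus_kT(self) -> float:
        return self.persistence_length_nm / self.spec.bond_length_nm

    @property
    def ev_adjacency_window(self) -> int:
        """Contour neighbours |i-j| <= window exempt from the hard-sphere check.

        Neighbours closer than ``ev_min_dist_nm`` along the contour would
        violate the hard sphere by construction whenever b < ev_min_dist_nm.
        """
        return int(math.ceil(self.ev_min_dist_nm / self.spec.bond_length_nm))

    def with_tether(self, tether: TetherSpec) -> "EnergyModel":
        return replace(self, tether=tether)


class InitializationError(RuntimeError):
    """Raised when no feasible starting conformation could be constructed."""


# ---------------------------------------------------------------------------
# Directional sampling helpers (also used by the validation oracles)
# ---------------------------------------------------------------------------


def sample_uniform_sphere(rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Uniform unit vectors on the 2-sphere."""
    n = 1 if size is None else size
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v[0] if size is None else v


def sample_vmf(mu: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """One draw from the von Mises-Fisher distribution on the 2-sphere.

    Uses the closed-form inverse-CDF for the cosine w = mu . x:
    w = 1 + log(u + (1 - u) exp(-2 kappa)) / kappa, with kappa = 0 reducing
    to the uniform distribution.
    """
    mu = np.asarray(mu, dtype=float)
    if kappa < 1e-12:
        return sample_uniform_sphere(rng)
    u = rng.random()
    # exp(-2k) underflows harmlessly to 0 for large kappa
    w = 1.0 + np.log(u + (1.0 - u) * math.exp(-2.0 * kappa)) / kappa
    w = min(1.0, max(-1.0, w))
    phi = 2.0 * math.pi * rng.random()
    e1, e2 = _orthonormal_basis(mu)
    s = math.sqrt(max(0.0, 1.0 - w * w))
    return w * mu + s * (math.cos(phi) * e1 + math.sin(phi) * e2)


def _orthonormal_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to u (|u| = 1)."""
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


# ---------------------------------------------------------------------------
# Conformation construction
# ---------------------------------------------------------------------------


def initialize_conformation(
    spec: ChromosomeSpec,
    model: EnergyModel,
    rng: np.random.Generator | int,
    max_retries: int = 200,
) -> np.ndarray:
    """Construct a feasible starting conformation (shape ``(n_loci, 3)``).

    The chain is grown as a persistent random walk (new rod directions
    drawn from a vMF around the previous direction with concentration
    g*beta, the exact unconfined discrete-WLC statistics), rejecting
    out-of-sphere placements.  Tethered loci are placed exactly on the
    sphere: the tether point is drawn from the clustering vMF, and for
    telomere tethering the walk is steered outward near the far end so the
    final locus can be closed onto the sphere exactly.

    Any feasible start suffices: the sampler discards a burn-in prefix.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if spec.n_loci != model.spec.n_loci or spec.bond_length_nm != model.spec.bond_length_nm:
        raise ValueError("model.spec inconsistent with spec")
    mode = model.tether.mode
    for _ in range(max_retries):
        try:
            if mode == "none":
                conf = _grow_free(spec, model, rng)
            elif mode == "centromere":
                conf = _grow_centromere(spec, model, rng)
            else:
                conf = _grow_telomeres(spec, model, rng)
        except _GrowthFailure:
            continue
        if validate_conformation(conf, model).ok:
            return conf
    raise InitializationError(
        f"could not construct a feasible {mode!r} conformation after "
        f"{max_retries} attempts (contour {spec.contour_length_nm:.0f} nm, "
        f"radius {model.geometry.radius_nm:.0f} nm)"
    )


class _GrowthFailure(Exception):
    pass


def _grow_segment(
    start: np.ndarray,
    n_steps: int,
    b: float,
    g_beta: float,
    radius: float,
    rng: np.random.Generator,
    lower_bounds: np.ndarray | None = None,
    first_dir: np.ndarray | None = None,
) -> np.ndarray:
    """Grow ``n_steps`` rods from ``start`` inside the sphere.

    ``lower_bounds[k]`` optionally forces ``|x| >= lower_bounds[k]`` after
    step k (used to steer telomere-tethered chains back to the surface).
    """
    pts = np.empty((n_steps + 1, 3))
    pts[0] = start
    d = first_dir if first_dir is not None else sample_uniform_sphere(rng)
    x = start.copy()
    for k in range(n_steps):
        lo = 0.0 if lower_bounds is None else lower_bounds[k]
        placed = False
        for _ in range(60):
            cand = x + b * d
            r = np.linalg.norm(cand)
            if r <= radius and r >= lo:
                placed = True
                break
            d = sample_vmf(d, g_beta, rng) if g_beta > 0 else sample_uniform_sphere(rng)
        if not placed:
            # deterministic fallback: step toward a feasible target norm
            cand = _steered_step(x, b, lo, radius, rng)
            d = (cand - x) / b
        x = cand
        pts[k + 1] = x
        d = sample_vmf(d, g_beta, rng) if g_beta > 0 else sample_uniform_sphere(rng)
    return pts


def _steered_step(
    x: np.ndarray, b: float, lo: float, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Step of length b from x landing at a norm clamped into [lo, radius]."""
    dnorm = np.linalg.norm(x)
    if dnorm < 1e-9:
        return x + b * sample_uniform_sphere(rng)
    target = min(radius, max(lo, dnorm))
    # choose the polar angle (relative to the outward radial direction)
    # landing exactly at |x'| = target when reachable
    cospsi = (target * target - dnorm * dnorm - b * b) / (2.0 * b * dnorm)
    cospsi = min(1.0, max(-1.0, cospsi))
    sinpsi = math.sqrt(max(0.0, 1.0 - cospsi * cospsi))
    xhat = x / dnorm
    e1, e2 = _orthonormal_basis(xhat)
    phi = 2.0 * math.pi * rng.random()
    step_dir = cospsi * xhat + sinpsi * (math.cos(phi) * e1 + math.sin(phi) * e2)
    return x + b * step_dir


def _grow_free(
    spec: ChromosomeSpec, model: EnergyModel, rng: np.random.Generator
) -> np.ndarray:
    R = model.geometry.radius_nm
    start = 0.5 * R * rng.random() ** (1 / 3) * sample_uniform_sphere(rng)
    return _grow_segment(
        start, spec.n_loci - 1, spec.bond_length_nm, model.bending_modulus_kT, R, rng
    )


def _grow_centromere(
    spec: ChromosomeSpec, model: EnergyModel, rng: np.random.Generator
) -> np.ndarray:
    R = model.geometry.radius_nm
    b = spec.bond_length_nm
    g = model.bending_modulus_kT
    cen = spec.centromere_index
    anchor = R * sample_vmf(model.tether.mu_vec, model.tether.nu, rng)
    inward = -anchor / R
    conf = np.empty((spec.n_loci, 3))
    conf[cen] = anchor
    if cen < spec.n_loci - 1:
        seg = _grow_segment(anchor, spec.n_loci - 1 - cen, b, g, R, rng, first_dir=inward)
        conf[cen:] = seg
    if cen > 0:
        seg = _grow_segment(anchor, cen, b, g, R, rng, first_dir=inward)
        conf[cen::-1] = seg
    return conf


def _grow_telomeres(
    spec: ChromosomeSpec, model: EnergyModel, rng: np.random.Generator
) -> np.ndarray:
    R = model.geometry.radius_nm
    b = spec.bond_length_nm
    g = model.bending_modulus_kT
    N = spec.n_loci
    anchor = R * sample_vmf(model.tether.mu_vec, model.tether.nu, rng)
    # after rod k (landing at locus k+1), N-2-k rods remain before the last
    # locus; the last locus must be reachable from the sphere: |x| >= R - m*b
    # where m is the number of rods still available.
    lower = np.maximum(0.0, R - b * (N - 2 - np.arange(N - 2)))
    seg = _grow_segment(anchor, N - 2, b, g, R, rng,
                        lower_bounds=lower, first_dir=-anchor / R)
    conf = np.empty((N, 3))
    conf[: N - 1] = seg
    conf[N - 1] = _close_onto_sphere(seg[-1], b, R, rng)
    return conf


def _close_onto_sphere(
    p: np.ndarray, b: float, R: float, rng: np.random.Generator
) -> np.ndarray:
    """Point q with |q| = R and |q - p| = b (random point on the circle)."""
    d = np.linalg.norm(p)
    if d < 1e-12:
        raise _GrowthFailure
    t = (d * d + R * R - b * b) / (2.0 * d * R)
    if not -1.0 <= t <= 1.0 + 1e-12:
        raise _GrowthFailure
    t = min(1.0, t)
    phat = p / d
    e1, e2 = _orthonormal_basis(phat)
    phi = 2.0 * math.pi * rng.random()
    s = math.sqrt(max(0.0, 1.0 - t * t))
    return R * (t * phat + s * (math.cos(phi) * e1 + math.sin(phi) * e2))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationReport:
    """Pass/fail per invariant with maximum violation magnitudes."""

    ok: bool
    rod_max_rel_err: float
    confinement_max_excess_nm: float
    tether_max_err_nm: float
    checks: dict[str, bool]

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def validate_conformation(conf: np.ndarray, model: EnergyModel) -> ValidationReport:
    """Check rod lengths, confinement and tether constraints (pure function)."""
    conf = np.asarray(conf, dtype=float)
    spec = model.spec
    b = spec.bond_length_nm
    R = model.geometry.radius_nm
    checks: dict[str, bool] = {}

    shape_ok = conf.shape == (spec.n_loci, 3)
    checks["shape"] = shape_ok
    if not shape_ok:
        return ValidationReport(False, math.inf, math.inf, math.inf, checks)

    rods = np.diff(conf, axis=0)
    rod_err = float(np.max(np.abs(np.linalg.norm(rods, axis=1) - b)) / b)
    checks["rod_lengths"] = rod_err <= ROD_RTOL

    norms = np.linalg.norm(conf, axis=1)
    excess = float(max(0.0, np.max(norms) - R))
    checks["confinement"] = excess <= CONFINE_ATOL_NM

    tether_err = 0.0
    mode = model.tether.mode
    if mode == "centromere":
        tether_err = float(abs(norms[spec.centromere_index] - R))
    elif mode == "telomeres":
        tether_err = float(max(abs(norms[0] - R), abs(norms[-1] - R)))
    checks["tether"] = tether_err <= TETHER_ATOL_NM

    return ValidationReport(
        ok=all(checks.values()),
        rod_max_rel_err=rod_err,
        confinement_max_excess_nm=excess,
        tether_max_err_nm=tether_err,
        checks=checks,
    )
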