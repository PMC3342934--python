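"""Metropolis MCMC over chain conformations under the Boltzmann distribution.

The move set is constraint-exact: tethered loci are touched only by
norm-preserving rotations, so on-sphere tethering is maintained by
construction rather than by a penalty.

* :func:`crankshaft_move` -- interior segment rotation, valid under every
  tether mode (proposals spanning a tethered centromere are skipped).
* :func:`pivot_move` -- terminal-segment rotation about a random axis
  through the hinge locus; only for sides containing no tethered locus.
* :func:`arm_rotation_move` -- terminal-segment rotation about the axis
  through the origin and the hinge locus.  This preserves the norm of every
  moved locus, so it is the move that lets a tethered telomere explore the
  sphere surface; without it the telomere-telomere angle would be frozen
  (crankshafts fix both endpoints and rigid rotations preserve relative
  geometry).
* :func:`rigid_rotation_move` -- whole-chain rotation about the origin.

One "sample" is one attempted Metropolis step; schedules follow the
total/burn-in/thinning bookkeeping (the production schedule is 10M steps,
3M burn-in, thin 40).

:func:`metropolis_step` is a straightforward single-step reference
implementation (full energy recomputation); :func:`run_chain` drives the
compiled kernel in :mod:`bouquetmc._kernel`, which computes energy
differences incrementally from the affected joints only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from . import _kernel
from .chain import (
    ChromosomeSpec,
    EnergyModel,
    ValidationReport,
    initialize_conformation,
    validate_conformation,
)
from .energy import total_energy

__all__ = [
    "SamplerSchedule",
    "Ensemble",
    "crankshaft_move",
    "pivot_move",
    "arm_rotation_move",
    "rigid_rotation_move",
    "metropolis_step",
    "metropolis_accept",
    "run_chain",
    "local_bending_delta",
]

#: schedules from the production runs and a single-workstation default
PAPER_SCHEDULE = (10_000_000, 3_000_000, 40)
DESK_SCHEDULE = (1_000_000, 300_000, 40)


@dataclass(frozen=True)
class SamplerSchedule:
    """Sampling schedule: step counts, thinning, seed and proposal mix."""

    n_total: int
    n_burn_in: int
    thin: int = 40
    seed: int = 0
    move_mix: tuple[float, float, float] = (0.7, 0.15, 0.15)  # crank, pivot, rigid
    max_step_angle_rad: float = math.pi / 2
    tune_during_burnin: bool = True
    tune_interval: int = 5_000
    target_acceptance: tuple[float, float] = (0.3, 0.5)
    renorm_interval: int = 65_536

    def __post_init__(self) -> None:
        if not (0 <= self.n_burn_in < self.n_total):
            raise ValueError("require 0 <= n_burn_in < n_total")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if abs(sum(self.move_mix) - 1.0) > 1e-9 or min(self.move_mix) < 0:
            raise ValueError("move_mix must be non-negative and sum to 1")
        if not (0.0 < self.max_step_angle_rad <= math.pi):
            raise ValueError("max_step_angle_rad must be in (0, pi]")

    @property
    def retained_count(self) -> int:
        return (self.n_total - self.n_burn_in) // self.thin


@dataclass
class Ensemble:
    """Retained thinned samples of one chain plus provenance."""

    positions: np.ndarray  # (retained_count, n_loci, 3), nm
    spec: ChromosomeSpec
    model: EnergyModel
    schedule: SamplerSchedule
    acceptance_rate: float
    final_step_angles: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def retained_count(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_loci(self) -> int:
        return int(self.positions.shape[1])

    def validate(self) -> ValidationReport:
        """Validate the worst member (max violation across all samples)."""
        worst = None
        for conf in self.positions:
            rep = validate_conformation(conf, self.model)
            if worst is None or (not rep.ok and worst.ok):
                worst = rep
            if not rep.ok:
                return rep
        return worst


# ---------------------------------------------------------------------------
# Pure move operations (reference implementations; the kernel mirrors them)
# ---------------------------------------------------------------------------


def _rotmat(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("degenerate rotation axis")
    return Rotation.from_rotvec(axis / n * angle).as_matrix()


def crankshaft_move(conf: np.ndarray, i: int, j: int, angle: float) -> np.ndarray:
    """Rotate loci strictly between i and j about the axis through them.

    Endpoints and everything outside (i, j) are unchanged; rod lengths are
    preserved exactly.  A degenerate axis (coincident endpoints) returns
    the conformation unchanged (the proposal counts as rejected).
    """
    if not (0 <= i < j <= conf.shape[0] - 1) or j - i < 2:
        raise ValueError(f"invalid crankshaft indices ({i}, {j})")
    out = np.array(conf, dtype=float, copy=True)
    axis = conf[j] - conf[i]
    if np.linalg.norm(axis) < 1e-9:
        return out
    rot = _rotmat(axis, angle)
    out[i + 1 : j] = conf[i] + (conf[i + 1 : j] - conf[i]) @ rot.T
    return out


def pivot_move(
    conf: np.ndarray, i: int, axis: np.ndarray, angle: float, side: str
) -> np.ndarray:
    """Rotate one side of the chain about an axis through locus i.

    ``side`` is ``"head"`` (loci 0..i-1) or ``"tail"`` (loci i+1..end).
    The caller is responsible for only pivoting sides free of tethered loci.
    """
    out = np.array(conf, dtype=float, copy=True)
    rot = _rotmat(axis, angle)
    if side == "head":
        sel = slice(0, i)
    elif side == "tail":
        sel = slice(i + 1, conf.shape[0])
    else:
        raise ValueError("side must be 'head' or 'tail'")
    out[sel] = conf[i] + (conf[sel] - conf[i]) @ rot.T
    return out


def arm_rotation_move(conf: np.ndarray, i: int, angle: float, side: str) -> np.ndarray:
    """Rotate one terminal segment about the origin axis through locus i.

    Preserves the norm of every moved locus and every rod length, so a
    tethered telomere in the moved segment stays exactly on the sphere.
    """
    out = np.array(conf, dtype=float, copy=True)
    rot = _rotmat(conf[i], angle)
    if side == "head":
        sel = slice(0, i)
    elif side == "tail":
        sel = slice(i + 1, conf.shape[0])
    else:
        raise ValueError("side must be 'head' or 'tail'")
    out[sel] = conf[sel] @ rot.T
    return out


def rigid_rotation_move(
    conf: np.ndarray, axis_through_origin: np.ndarray, angle: float
) -> np.ndarray:
    """Rotate the whole conformation about an axis through the nucleus centre."""
    rot = _rotmat(axis_through_origin, angle)
    return np.asarray(conf, dtype=float) @ rot.T


def local_bending_delta(
    conf_old: np.ndarray, conf_new: np.ndarray, joints: list[int], g_beta: float
) -> float:
    """Bending-energy difference from the listed joints only.

    Joint k couples rods k-1 and k (valid for 1 <= k <= n_loci - 2).  Used
    to verify that the kernel's incremental updates equal full recomputes.
    """

    def joint_e(conf: np.ndarray, k: int) -> float:
        t1 = conf[k] - conf[k - 1]
        t2 = conf[k + 1] - conf[k]
        c = float(np.dot(t1, t2) / (np.linalg.norm(t1) * np.linalg.norm(t2)))
        return g_beta * (1.0 - c)

    return sum(joint_e(conf_new, k) - joint_e(conf_old, k) for k in joints)


# ---------------------------------------------------------------------------
# Metropolis step (reference path) and the production driver
# ---------------------------------------------------------------------------


def _propose(
    conf: np.ndarray,
    model: EnergyModel,
    schedule: SamplerSchedule,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Draw one symmetric proposal; None when the draw is a structural no-op."""
    n = conf.shape[0]
    mode = model.tether.mode
    cen = model.spec.centromere_index
    p_crank, p_pivot, _ = schedule.move_mix
    u = rng.random()
    amp = schedule.max_step_angle_rad
    angle = (2.0 * rng.random() - 1.0) * amp
    if u < p_crank:
        i = int(rng.integers(0, n - 2))
        j = int(rng.integers(i + 2, n))
        if mode == "centromere" and i < cen < j:
            return None
        return crankshaft_move(conf, i, j, angle)
    if u < p_crank + p_pivot:
        side = "head" if rng.integers(2) == 0 else "tail"
        if mode == "telomeres":
            k = int(rng.integers(1, n)) if side == "head" else int(rng.integers(0, n - 1))
            if np.linalg.norm(conf[k]) < 1e-9:
                return None
            return arm_rotation_move(conf, k, angle, side)
        if mode == "centromere":
            if side == "head":
                if cen < 1:
                    return None
                k = int(rng.integers(1, cen + 1))
            else:
                if cen > n - 2:
                    return None
                k = int(rng.integers(cen, n - 1))
        else:
            k = int(rng.integers(1, n)) if side == "head" else int(rng.integers(0, n - 1))
        axis = rng.normal(size=3)
        return pivot_move(conf, k, axis, angle, side)
    axis = rng.normal(size=3)
    return rigid_rotation_move(conf, axis, angle)


def metropolis_step(
    conf: np.ndarray,
    model: EnergyModel,
    schedule: SamplerSchedule,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """One attempted Metropolis step with full energy recomputation.

    Infeasible proposals (confinement or excluded-volume violations) are
    always rejected; finite energy differences are accepted with
    probability min(1, exp(-beta dE)).
    """
    proposal = _propose(conf, model, schedule, rng)
    if proposal is None:
        return conf, False
    e_old = total_energy(conf, model).total_kT
    e_new = total_energy(proposal, model).total_kT
    if math.isinf(e_new):
        return conf, False
    if metropolis_accept(model.beta * (e_new - e_old), rng):
        return proposal, True
    return conf, False


def metropolis_accept(de_kT: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-dE)); infeasible dE = inf never."""
    if math.isinf(de_kT) and de_kT > 0:
        return False
    return de_kT <= 0.0 or rng.random() < math.exp(-de_kT)


def run_chain(
    spec: ChromosomeSpec,
    model: EnergyModel,
    schedule: SamplerSchedule,
    initial: np.ndarray | None = None,
) -> Ensemble:
    """Run one MCMC chain and return the thinned, burned-in ensemble.

    Deterministic for a given schedule seed.  The initial conformation is
    grown from the same seed unless supplied explicitly.
    """
    mode_code = {"none": 0, "centromere": 1, "telomeres": 2}[model.tether.mode]
    rng = np.random.default_rng(schedule.seed)
    if initial is None:
        x = initialize_conformation(spec, model, rng)
    else:
        x = np.array(initial, dtype=float, copy=True)
    rep = validate_conformation(x, model)
    if not rep.ok:
        raise ValueError(f"infeasible initial conformation: {rep}")
    kernel_seed = int(np.random.SeedSequence([schedule.seed, 0xB0C]).generate_state(1)[0] % (2**31))
    mu = model.tether.mu_vec
    p_crank, p_pivot, _ = schedule.move_mix
    out, acc, att, amps, acc_post, att_post = _kernel.run_mcmc(
        x,
        float(model.beta * model.bending_modulus_kT),
        float(model.geometry.radius_nm),
        mode_code,
        int(spec.centromere_index),
        float(model.tether.nu if model.tether.mode != "none" else 0.0),
        float(mu[0]),
        float(mu[1]),
        float(mu[2]),
        int(schedule.n_total),
        int(schedule.n_burn_in),
        int(schedule.thin),
        kernel_seed,
        float(p_crank),
        float(p_pivot),
        float(schedule.max_step_angle_rad),
        bool(schedule.tune_during_burnin),
        int(schedule.tune_interval),
        float(schedule.target_acceptance[0]),
        float(schedule.target_acceptance[1]),
        bool(model.excluded_volume_enabled),
        float(model.ev_min_dist_nm),
        int(model.ev_adjacency_window),
        int(schedule.renorm_interval),
        float(spec.bond_length_nm),
    )
    acceptance = float(acc_post / att_post) if att_post else float(acc.sum() / att.sum())
    return Ensemble(
        positions=out,
        spec=spec,
        model=model,
        schedule=schedule,
        acceptance_rate=acceptance,
        final_step_angles=tuple(float(a) for a in amps),
    )
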