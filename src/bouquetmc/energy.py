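"""Boltzmann energy terms for confined, tethered, clustered chains.

Four terms, all in units of kT (beta = 1):

* bending: ``g*beta * sum_i (1 - t_i . t_{i+1})`` over consecutive unit rod
  vectors -- the discretised worm-like-chain stiffness;
* confinement: hard-core, 0 inside the nuclear sphere, infeasible outside;
* clustering: ``-nu * (mu . x_hat)`` per tethered locus, the log-density of
  a von Mises-Fisher distribution on the sphere surface (normalising
  constants are dropped: nu is fixed within a run, so they cancel in every
  Metropolis ratio);
* excluded volume (optional): hard-sphere rejection of non-adjacent locus
  pairs closer than ``ev_min_dist_nm``.

Infeasible configurations are flagged with the exact sentinel
:data:`INFEASIBLE` (``math.inf``), never a large finite float, so the
sampler's accept/reject logic is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .chain import EnergyModel, NuclearGeometry

__all__ = [
    "INFEASIBLE",
    "EnergyBreakdown",
    "bending_energy",
    "confinement_energy",
    "clustering_energy",
    "excluded_volume_energy",
    "total_energy",
]

INFEASIBLE = math.inf


@dataclass(frozen=True)
class EnergyBreakdown:
    bending_kT: float
    confinement_kT: float
    clustering_kT: float
    excluded_volume_kT: float

    @property
    def total_kT(self) -> float:
        return (
            self.bending_kT
            + self.confinement_kT
            + self.clustering_kT
            + self.excluded_volume_kT
        )

    @property
    def feasible(self) -> bool:
        return math.isfinite(self.total_kT)


def bending_energy(conf: np.ndarray, model: EnergyModel) -> float:
    """g*beta * sum over joints of (1 - cos of the joint angle); >= 0."""
    conf = np.asarray(conf, dtype=float)
    if conf.shape != (model.spec.n_loci, 3):
        raise ValueError(
            f"conformation has {conf.shape[0]} loci, spec expects {model.spec.n_loci}"
        )
    rods = np.diff(conf, axis=0)
    t = rods / np.linalg.norm(rods, axis=1, keepdims=True)
    dots = np.einsum("ij,ij->i", t[:-1], t[1:])
    return float(model.beta * model.bending_modulus_kT * np.sum(1.0 - dots))


def confinement_energy(conf: np.ndarray, geometry: NuclearGeometry) -> float:
    """0 if every locus lies within the sphere (boundary allowed), else inf."""
    norms = np.linalg.norm(np.asarray(conf, dtype=float), axis=1)
    if np.max(norms) > geometry.radius_nm + 1e-6:
        return INFEASIBLE
    return 0.0


def clustering_energy(conf: np.ndarray, model: EnergyModel) -> float:
    """vMF clustering log-density term, -nu * (mu . x_hat) per tethered locus."""
    tether = model.tether
    if tether.mode == "none":
        raise ValueError("clustering_energy undefined for tether mode 'none'")
    if tether.nu == 0.0:
        return 0.0
    mu = tether.mu_vec
    conf = np.asarray(conf, dtype=float)
    if tether.mode == "centromere":
        loci = [model.spec.centromere_index]
    else:
        loci = [0, model.spec.n_loci - 1]
    e = 0.0
    for i in loci:
        x = conf[i]
        e -= tether.nu * float(np.dot(mu, x) / np.linalg.norm(x))
    return e


def excluded_volume_energy(conf: np.ndarray, model: EnergyModel) -> float:
    """Hard-sphere check over non-adjacent locus pairs.

    Pairs with contour separation ``|i - j| <= ev_adjacency_window`` are
    exempt: when the rod length is shorter than the hard-sphere distance,
    contour neighbours violate it by construction.
    """
    if not model.excluded_volume_enabled:
        return 0.0
    conf = np.asarray(conf, dtype=float)
    n = conf.shape[0]
    d = squareform(pdist(conf))
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    mask = sep > model.ev_adjacency_window
    if np.any(d[mask] < model.ev_min_dist_nm):
        return INFEASIBLE
    return 0.0


def total_energy(conf: np.ndarray, model: EnergyModel) -> EnergyBreakdown:
    """Componentwise energy of a conformation."""
    bend = bending_energy(conf, model)
    confine = confinement_energy(conf, model.geometry)
    clust = 0.0 if model.tether.mode == "none" else clustering_energy(conf, model)
    ev = excluded_volume_energy(conf, model)
    return EnergyBreakdown(bend, confine, clust, ev)
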