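"""Independent closed-form and brute-force oracles for the test suite.

These deliberately share no sampling code with the MCMC path: the direct
chain grower draws successive rod directions from the exact unconfined
discrete-WLC equilibrium (independent vMF joint angles), and the closed
forms are the discrete Kratky-Porod relations.

Discrete chain of n rods of length b with per-joint stiffness g = g*beta:

* mean joint cosine  p = <cos theta> = coth(g) - 1/g  (p = 0 at g = 0);
* mean squared end-to-end distance
  <R^2> = b^2 [ n (1+p)/(1-p) - 2 p (1 - p^n) / (1-p)^2 ].

The same Langevin function gives the mean resultant length of a von
Mises-Fisher distribution on the 2-sphere, coth(nu) - 1/nu, used to check
the clustering machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chain import sample_uniform_sphere, sample_vmf

__all__ = [
    "WlcPrediction",
    "discrete_wlc_r2",
    "vmf_mean_resultant",
    "grow_unconfined_chain",
    "unconfined_r2_samples",
    "convergence_scan",
]


@dataclass(frozen=True)
class WlcPrediction:
    """Closed-form unconfined discrete-WLC statistics."""

    mean_sq_end_to_end_nm2: float
    mean_cos_theta: float
    n_rods: int
    bond_nm: float
    g_beta: float


def _langevin(g: float) -> float:
    """coth(g) - 1/g, with the g -> 0 limit handled exactly."""
    if g == 0.0:
        return 0.0
    if g < 1e-4:
        # series: g/3 - g^3/45
        return g / 3.0 - g**3 / 45.0
    if g > 350.0:
        return 1.0 - 1.0 / g
    return 1.0 / math.tanh(g) - 1.0 / g


def discrete_wlc_r2(n_rods: int, bond_nm: float, g_beta: float) -> WlcPrediction:
    """Exact discrete Kratky-Porod mean squared end-to-end distance."""
    if n_rods < 1 or bond_nm <= 0 or g_beta < 0:
        raise ValueError("require n_rods >= 1, bond_nm > 0, g_beta >= 0")
    p = _langevin(g_beta)
    if p == 0.0:
        r2 = n_rods * bond_nm**2
    else:
        q = 1.0 - p
        r2 = bond_nm**2 * (n_rods * (1.0 + p) / q - 2.0 * p * (1.0 - p**n_rods) / q**2)
    return WlcPrediction(
        mean_sq_end_to_end_nm2=float(r2),
        mean_cos_theta=float(p),
        n_rods=n_rods,
        bond_nm=bond_nm,
        g_beta=g_beta,
    )


def vmf_mean_resultant(nu: float) -> float:
    """Mean resultant length of a vMF distribution on the 2-sphere.

    0 at nu = 0 (uniform) rising to 1 as nu -> inf; e.g. ~0.98 at nu = 50.
    """
    if nu < 0:
        raise ValueError("nu must be >= 0")
    return _langevin(nu)


def grow_unconfined_chain(
    n_rods: int, bond_nm: float, g_beta: float, rng: np.random.Generator
) -> np.ndarray:
    """One exact draw from the unconfined discrete-WLC equilibrium.

    Joint angles are independent with density proportional to
    exp(g_beta cos theta), i.e. each rod direction is a vMF draw around the
    previous one.  Direct (non-MCMC) sampling, used as the brute-force
    oracle for the Metropolis sampler.
    """
    pts = np.zeros((n_rods + 1, 3))
    d = sample_uniform_sphere(rng)
    for k in range(n_rods):
        pts[k + 1] = pts[k] + bond_nm * d
        d = sample_vmf(d, g_beta, rng) if g_beta > 0 else sample_uniform_sphere(rng)
    return pts


def unconfined_r2_samples(
    n_rods: int, bond_nm: float, g_beta: float, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Squared end-to-end distances of independent direct draws."""
    out = np.empty(n_samples)
    for s in range(n_samples):
        pts = grow_unconfined_chain(n_rods, bond_nm, g_beta, rng)
        out[s] = float(np.sum((pts[-1] - pts[0]) ** 2))
    return out


def convergence_scan(
    chromosome: str,
    persistence_nm: float,
    condition: str,
    n_list: list[int],
    n_samples: int = 1000,
    seed: int = 0,
    thin: int = 40,
    n_burn_in: int = 100_000,
) -> pd.DataFrame:
    """Mean pairwise intra-chain distance as a function of discretisation N.

    Contour length and persistence length are held fixed while the rod
    length shrinks with N; the statistic plateaus once N exceeds ~75,
    indicating convergence to the continuous worm-like chain.  Averages are
    over all same-chain locus pairs and ``n_samples`` retained trajectories.
    """
    from .analysis import intra_ldm
    from .scenarios import make_condition
    from .sampler import run_chain

    rows = []
    for n_loci in n_list:
        if n_loci < 2:
            raise ValueError(f"invalid locus count {n_loci}")
        spec, model, schedule = make_condition(
            condition,
            chromosome,
            persistence_nm,
            scale="desk",
            seed=seed,
            n_loci=int(n_loci),
        )
        schedule = type(schedule)(
            n_total=n_burn_in + n_samples * thin,
            n_burn_in=n_burn_in,
            thin=thin,
            seed=schedule.seed,
        )
        ens = run_chain(spec, model, schedule)
        dm = intra_ldm(ens)
        iu = np.triu_indices(dm.n_loci, k=1)
        rows.append(
            {
                "n_loci": int(n_loci),
                "mean_pairwise_nd": float(dm.values[iu].mean()),
                "n_samples": int(ens.retained_count),
                "seed": int(seed),
            }
        )
    return pd.DataFrame(rows)
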