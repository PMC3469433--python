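"""Exact null distributions for the constrained placement model.

For a fixed focus size ``g``, each of a stretch's constrained foci is an
independent uniform centre draw, so its hit indicator is Bernoulli with
probability ``p_hit = domain-union measure / legal-centre measure`` and
the total hit count across stretches follows a Poisson-binomial law,
computed here exactly by convolving per-stretch binomial pmfs. The outer
size-resampling loop of the Monte Carlo engine is marginalized by
averaging tails over the empirical size atoms (or quadrature nodes for a
parametric size law). These closed forms are the independent oracle
against which the simulation engine is validated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import (
    BoundaryPolicy,
    Mode,
    SizeDistribution,
    Stretch,
    StretchSet,
    legal_center_range,
    stretch_domain,
)

__all__ = [
    "HitProbability",
    "hit_probability",
    "exact_count_distribution",
    "tail_probability",
    "size_marginal_tail",
    "shared_size_mc_se",
]


@dataclass(frozen=True)
class HitProbability:
    stretch_id: str
    g: float
    mode: Mode
    p_hit: float


def hit_probability(
    stretch: Stretch,
    g: float,
    mode: Mode | str,
    boundary_policy: BoundaryPolicy | str = BoundaryPolicy.CONTAINED,
) -> HitProbability:
    """Probability that one uniformly placed focus of size ``g`` scores a
    hit on ``stretch`` under ``mode``."""
    mode = Mode(mode)
    lo, hi = legal_center_range(g, stretch.length, boundary_policy)
    if lo >= hi:
        raise ValueError(
            f"stretch {stretch.id!r}: focus size {g} µm leaves no legal "
            f"centre positions on a {stretch.length} µm stretch"
        )
    dom = stretch_domain(stretch, g, mode, boundary_policy)
    return HitProbability(stretch.id, g, mode, dom.total_measure / dom.allowed_measure)


def exact_count_distribution(
    data: StretchSet,
    g: float,
    mode: Mode | str,
    boundary_policy: BoundaryPolicy | str = BoundaryPolicy.CONTAINED,
) -> np.ndarray:
    """Exact pmf of the total hit count at fixed focus size ``g``.

    The count is the sum over stretches of Binomial(n_i, p_hit_i)
    variables; the pmf (length ``n_total + 1``) is their convolution.
    """
    pmf = np.ones(1)
    for s in data:
        n = s.n_gfp_constraint
        if n == 0:
            continue
        p = hit_probability(s, g, mode, boundary_policy).p_hit
        pmf = np.convolve(pmf, stats.binom.pmf(np.arange(n + 1), n, p))
    n_tot = data.n_gfp_constraint_total
    out = np.zeros(n_tot + 1)
    out[: pmf.size] = pmf
    return out


def tail_probability(pmf: np.ndarray, k: int) -> float:
    """P(count >= k) for a pmf over 0..n (clipped against convolution
    round-off)."""
    k = max(0, k)
    return float(min(1.0, max(0.0, pmf[k:].sum())))


def _per_size_tails(
    data: StretchSet,
    size_dist,
    mode: Mode | str,
    k: int,
    boundary_policy: BoundaryPolicy | str,
    n_quadrature: int,
) -> tuple[np.ndarray, np.ndarray]:
    """(weights, tails) of P(count >= k | g) over the size atoms or
    quadrature nodes of ``size_dist``."""
    if isinstance(size_dist, SizeDistribution):
        atoms, counts = np.unique(size_dist.as_array(), return_counts=True)
        weights = counts / counts.sum()
    else:
        lo, hi = size_dist.support
        edges = np.linspace(lo, hi, n_quadrature + 1)
        atoms = 0.5 * (edges[:-1] + edges[1:])
        weights = size_dist.pdf(atoms)
        weights = weights / weights.sum()
    tails = np.array(
        [
            tail_probability(
                exact_count_distribution(data, g, mode, boundary_policy), k
            )
            for g in atoms
        ]
    )
    return weights, tails


def size_marginal_tail(
    data: StretchSet,
    size_dist,
    mode: Mode | str,
    k: int,
    boundary_policy: BoundaryPolicy | str = BoundaryPolicy.CONTAINED,
    n_quadrature: int = 256,
) -> float:
    """Mean over focus sizes of the exact tail P(count >= k | g).

    This is the expectation estimated by the shared-size Monte Carlo
    p-value. ``size_dist`` is either a :class:`SizeDistribution` (averaged
    over its empirical atoms, weighted by multiplicity) or a parametric
    law exposing ``support`` and ``pdf`` (midpoint quadrature).
    """
    weights, tails = _per_size_tails(
        data, size_dist, mode, k, boundary_policy, n_quadrature
    )
    return float(np.dot(weights, tails))


def shared_size_mc_se(
    data: StretchSet,
    size_dist,
    mode: Mode | str,
    k: int,
    n_size_draws: int,
    n_placements_per_size: int,
    boundary_policy: BoundaryPolicy | str = BoundaryPolicy.CONTAINED,
    n_quadrature: int = 256,
) -> float:
    """Exact standard error of the shared-size Monte Carlo p-value.

    Iterations inside one size block share the size draw, so the naive
    binomial SE sqrt(p(1-p)/N) understates the error whenever the tail
    varies with g; the correct variance has a between-block term
    Var_g(tail)/n_size_draws plus the within-block binomial term.
    """
    weights, tails = _per_size_tails(
        data, size_dist, mode, k, boundary_policy, n_quadrature
    )
    mean_tail = float(np.dot(weights, tails))
    between = float(np.dot(weights, (tails - mean_tail) ** 2)) / n_size_draws
    within = float(np.dot(weights, tails * (1 - tails))) / (
        n_size_draws * n_placements_per_size
    )
    return float(np.sqrt(between + within))
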