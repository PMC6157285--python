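"""Bootstrap model averaging: edge strength, direction, and thresholding.

The best-fit network found by hill-climbing is a point estimate; its
stability is assessed by refitting on ``B`` nonparametric bootstrap
resamples of the cohort (1000 by default). The *strength* of an edge is
the fraction of replicates in which it appears in either direction; the
*direction* probability of an orientation is the fraction of those
replicates in which it points that way. Direction values near 0.5 flag
relationships whose orientation the data cannot resolve; whitelisted
edges appear in every replicate with their fixed orientation, so their
strength and direction are exactly 1.

The significance cutoff on strengths is estimated by the L1/ECDF rule:
the ideal averaged network has only strength-0 (noise) and strength-1
(real) edges, so the cutoff is the observed strength value whose ECDF
level best approximates the empirical strength distribution in L1 norm.
Edges with strength strictly greater than the cutoff are retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bn import ConstraintSet, Dag, Node, hill_climb
from .cohort import CohortTable, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "AverageNetwork",
    "bootstrap_networks",
    "edge_statistics",
    "strength_threshold",
    "filter_average",
]


@dataclass
class AverageNetwork:
    """Per-pair strength and per-orientation direction probabilities.

    ``strength`` is keyed by the sorted (A, B) pair; ``direction`` by the
    ordered (parent, child) pair, present only for pairs observed in at
    least one replicate (pairs never seen have strength 0 and *missing*
    direction, not 0.5). Directions of the two orientations of a pair sum
    to 1.
    """

    nodes: list[Node]
    strength: dict[tuple[str, str], float]
    direction: dict[tuple[str, str], float]
    n_replicates: int
    threshold: float | None = None

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self.strength)

    def retained(self, cutoff: float | None = None) -> list[tuple[str, str]]:
        """Unordered pairs with strength strictly above ``cutoff``."""
        cutoff = self.threshold if cutoff is None else cutoff
        if cutoff is None:
            raise ValueError("no cutoff given and no threshold set")
        return sorted(p for p, s in self.strength.items() if s > cutoff)

    def oriented_edges(self, cutoff: float | None = None) -> list[tuple[str, str]]:
        """Majority orientation of each retained pair."""
        out = []
        for a, b in self.retained(cutoff):
            out.append((a, b) if self.direction.get((a, b), 0.0) >= 0.5 else (b, a))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long table: from, to, strength, direction, retained (one row per orientation)."""
        rows = []
        for a, b in self.pairs():
            s = self.strength[(a, b)]
            kept = int(self.threshold is not None and s > self.threshold)
            for u, v in ((a, b), (b, a)):
                if (u, v) in self.direction:
                    rows.append(
                        {"from": u, "to": v, "strength": s,
                         "direction": self.direction[(u, v)], "retained": kept}
                    )
        return pd.DataFrame(rows, columns=["from", "to", "strength", "direction", "retained"])


def bootstrap_networks(
    cohort: CohortTable,
    constraints: ConstraintSet | None = None,
    B: int = 1000,
    rng: np.random.Generator | None = None,
    restarts: int = 10,
    genotype_as: str = "discrete",
) -> list[Dag]:
    """Refit the best network on ``B`` bootstrap resamples of the cohort.

    Each replicate resamples the n rows with replacement and reruns the
    constrained hill-climb (with its full restart schedule unless
    ``restarts`` is lowered); every returned DAG satisfies the constraint
    set. Deterministic given ``rng``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    constraints = constraints or ConstraintSet.empty()
    rng = rng if rng is not None else np.random.default_rng()
    dags = []
    for _ in range(B):
        resampled = cohort.resample(rng)
        net = hill_climb(resampled, constraints, restarts=restarts, rng=rng,
                         genotype_as=genotype_as)
        dags.append(net.dag)
    return dags


def edge_statistics(dags: list[Dag]) -> AverageNetwork:
    """Strength and direction tables from a list of replicate DAGs.

    strength{A,B} = #(replicates with A->B or B->A) / B;
    direction(A->B) = #(A->B) / #(either direction).
    """
    if not dags:
        raise ValueError("need at least one network")
    names0 = set(dags[0].kind)
    for d in dags[1:]:
        if set(d.kind) != names0:
            raise SchemaError("replicate networks have mismatched node sets")
    B = len(dags)
    count: dict[tuple[str, str], int] = {}
    for d in dags:
        for u, v in d.edges():
            count[(u, v)] = count.get((u, v), 0) + 1
    strength: dict[tuple[str, str], float] = {}
    direction: dict[tuple[str, str], float] = {}
    seen_pairs = {tuple(sorted(e)) for e in count}
    for a, b in seen_pairs:
        fwd = count.get((a, b), 0)
        bwd = count.get((b, a), 0)
        present = fwd + bwd
        strength[(a, b)] = present / B
        direction[(a, b)] = fwd / present
        direction[(b, a)] = bwd / present
    return AverageNetwork(
        nodes=dags[0].nodes, strength=strength, direction=direction, n_replicates=B
    )


def strength_threshold(strengths) -> float:
    """L1/ECDF estimate of the significance cutoff on edge strengths.

    The ideal two-level strength distribution puts every non-significant
    edge at 0 and every significant edge at 1; its CDF is flat at some
    level c on [0, 1). The estimator picks, by brute force over the
    observed strength values (and 0), the candidate cutoff t whose ECDF
    level c = F(t) minimizes the L1 distance between the empirical CDF of
    the strengths and that flat level over [0, 1). Edges with strength
    strictly greater than the returned cutoff are the significant ones.
    """
    s = np.asarray(list(strengths), dtype=float)
    if s.size == 0:
        raise ValueError("empty strength vector")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("strengths must lie in [0, 1]")
    values, counts = np.unique(s, return_counts=True)
    ecdf = np.cumsum(counts) / s.size
    # piecewise-constant empirical CDF over [0, 1]: level[i] on [knots[i], knots[i+1])
    if values[0] > 0:
        knots = np.r_[0.0, values, 1.0]
        levels = np.r_[0.0, ecdf]
    else:
        knots = np.r_[values, 1.0]
        levels = ecdf
    widths = np.diff(knots)

    def ecdf_at(t: float) -> float:
        i = int(np.searchsorted(values, t, side="right")) - 1
        return float(ecdf[i]) if i >= 0 else 0.0

    candidates = [0.0] + [float(v) for v in values]
    best_t, best_cost = 0.0, math.inf
    for t in candidates:
        cost = float(np.sum(np.abs(levels - ecdf_at(t)) * widths))
        if cost < best_cost - 1e-12:
            best_t, best_cost = t, cost
    return best_t


def filter_average(avg: AverageNetwork, cutoff: float) -> AverageNetwork:
    """Averaged network restricted to pairs with strength > ``cutoff``.

    Strengths and direction probabilities are unchanged; the retained
    pairs' majority orientations are available via ``oriented_edges``.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    keep = {p for p, s in avg.strength.items() if s > cutoff}
    return replace(
        avg,
        strength={p: s for p, s in avg.strength.items() if p in keep},
        direction={
            (u, v): d
            for (u, v), d in avg.direction.items()
            if tuple(sorted((u, v))) in keep
        },
        threshold=cutoff,
    )
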