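"""Conditional-Gaussian Bayesian networks: scoring, constraints, search.

The model is the conditional-Gaussian (CG) network for mixed data:
discrete nodes (sex, center, optionally genotype dosage as a 3-level
factor) may only have discrete parents; a continuous node follows, for
every configuration of its discrete parents, a Gaussian linear regression
on its continuous parents. The network score is the decomposable BIC

    score(G) = sum_v [ logLik(v | parents(v)) - (k_v / 2) * ln n ]

with higher values better; k_v counts an intercept, the continuous-parent
slopes and a variance per discrete-parent configuration for a continuous
node, and (levels - 1) * prod(parent levels) cell probabilities for a
discrete node. Structure search is greedy hill-climbing over single-edge
operations (add / delete / reverse) honouring whitelist, blacklist and
no-parent constraints, with random restarts from perturbed local optima.
An exhaustive enumerator over small node sets serves as an oracle.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import CohortTable, SchemaError

logger = logging.getLogger(__name__)

SCORE_TOL = 1e-9  # two scores closer than this are treated as tied

__all__ = [
    "Node",
    "Dag",
    "ConstraintSet",
    "ScoredNetwork",
    "Scorer",
    "validate",
    "neighbors",
    "hill_climb",
    "enumerate_dags",
    "exhaustive_best",
    "drug_trial_constraints",
    "ConstraintError",
    "SizeLimitError",
]


class ConstraintError(ValueError):
    """A graph or operation breaks the CG restriction or a constraint rule."""


class SizeLimitError(ValueError):
    """Exhaustive enumeration requested over too many nodes."""


@dataclass(frozen=True)
class Node:
    name: str
    kind: str  # "continuous" | "discrete"
    levels: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "discrete"):
            raise SchemaError(f"node {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "discrete" and self.levels is not None and len(self.levels) < 2:
            raise SchemaError(f"discrete node {self.name!r} needs >= 2 levels")


class Dag:
    """Directed acyclic graph over typed nodes.

    Maintains parent sets per node; edge insertion enforces acyclicity and
    the CG restriction (a discrete node never has a continuous parent).
    """

    def __init__(self, nodes: list[Node], edges: list[tuple[str, str]] = ()):  # type: ignore[assignment]
        names = [n.name for n in nodes]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate node names")
        self.nodes: list[Node] = list(nodes)
        self.kind: dict[str, str] = {n.name: n.kind for n in nodes}
        self._parents: dict[str, set[str]] = {n.name: set() for n in nodes}
        for u, v in edges:
            self.add_edge(u, v)

    # -- mutation --------------------------------------------------------

    def add_edge(self, u: str, v: str, unchecked: bool = False) -> None:
        if not unchecked:
            if u not in self._parents or v not in self._parents:
                raise SchemaError(f"edge ({u}, {v}): unknown node")
            if u == v:
                raise ConstraintError(f"self-loop {u}")
            if u in self._parents[v]:
                raise ConstraintError(f"duplicate edge {u}->{v}")
            if self.kind[v] == "discrete" and self.kind[u] == "continuous":
                raise ConstraintError(
                    f"CG restriction: continuous {u} cannot parent discrete {v}"
                )
            if self.has_path(v, u):
                raise ConstraintError(f"edge {u}->{v} would create a cycle")
        self._parents[v].add(u)

    def remove_edge(self, u: str, v: str) -> None:
        self._parents[v].discard(u)

    def copy(self) -> "Dag":
        g = Dag.__new__(Dag)
        g.nodes = self.nodes
        g.kind = self.kind
        g._parents = {k: set(v) for k, v in self._parents.items()}
        return g

    # -- queries ---------------------------------------------------------

    def parents(self, name: str) -> frozenset[str]:
        return frozenset(self._parents[name])

    def has_edge(self, u: str, v: str) -> bool:
        return u in self._parents[v]

    def edges(self) -> list[tuple[str, str]]:
        return sorted((u, v) for v, ps in self._parents.items() for u in ps)

    @property
    def n_edges(self) -> int:
        return sum(len(ps) for ps in self._parents.values())

    def has_path(self, src: str, dst: str) -> bool:
        """True if dst is reachable from src along directed edges."""
        if src == dst:
            return True
        children: dict[str, list[str]] = {n.name: [] for n in self.nodes}
        for v, ps in self._parents.items():
            for u in ps:
                children[u].append(v)
        stack, seen = [src], {src}
        while stack:
            for w in children[stack.pop()]:
                if w == dst:
                    return True
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.name, kind=n.kind)
        g.add_edges_from(self.edges())
        return g

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Dag)
            and self.kind == other.kind
            and self._parents == {k: set(v) for k, v in other._parents.items()}
        )

    def __repr__(self) -> str:
        return f"Dag({len(self.nodes)} nodes, edges={self.edges()})"


@dataclass(frozen=True)
class ConstraintSet:
    """Whitelist / blacklist / no-parent structural rules.

    Whitelisted edges must be present with fixed direction in every graph;
    blacklisted directed edges may never appear; no-parent nodes (SNPs and
    the categorical covariates in the drug-trial analysis) admit no
    incoming edges.
    """

    whitelist: frozenset = frozenset()
    blacklist: frozenset = frozenset()
    no_parent_nodes: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "whitelist", frozenset(tuple(e) for e in self.whitelist))
        object.__setattr__(self, "blacklist", frozenset(tuple(e) for e in self.blacklist))
        object.__setattr__(self, "no_parent_nodes", frozenset(self.no_parent_nodes))
        overlap = self.whitelist & self.blacklist
        if overlap:
            raise ConstraintError(f"edges both whitelisted and blacklisted: {sorted(overlap)}")
        into_np = [e for e in self.whitelist if e[1] in self.no_parent_nodes]
        if into_np:
            raise ConstraintError(f"whitelist edges into no-parent nodes: {into_np}")
        g = nx.DiGraph(list(self.whitelist))
        if not nx.is_directed_acyclic_graph(g):
            raise ConstraintError("whitelist edges form a cycle")

    @classmethod
    def empty(cls) -> "ConstraintSet":
        return cls()


def drug_trial_constraints(
    snps: list[str],
    cpgs: list[str],
    tg2: str = "TG2",
    tg4: str = "TG4",
    categorical: tuple[str, ...] = ("sex", "center"),
) -> ConstraintSet:
    """The standard constraint set for the drug-response change analysis.

    TG2 is forced to be a parent of TG4 so the network models change in
    TG; SNPs and the categorical covariates have no parents; post-treatment
    CpG measurements cannot be parents of the pre-treatment TG level.
    """
    return ConstraintSet(
        whitelist=frozenset({(tg2, tg4)}),
        blacklist=frozenset((c, tg2) for c in cpgs),
        no_parent_nodes=frozenset(list(snps) + list(categorical)),
    )


# ---------------------------------------------------------------------------
# validation


def validate(dag: Dag, constraints: ConstraintSet) -> list[str]:
    """All rule violations of ``dag``; an empty list means valid."""
    out: list[str] = []
    g = dag.to_networkx()
    if not nx.is_directed_acyclic_graph(g):
        out.append("cycle: graph is not acyclic")
    for u, v in dag.edges():
        if dag.kind[v] == "discrete" and dag.kind[u] == "continuous":
            out.append(f"CG restriction violated: continuous {u} -> discrete {v}")
        if (u, v) in constraints.blacklist:
            out.append(f"blacklisted edge present: {u} -> {v}")
        if v in constraints.no_parent_nodes:
            out.append(f"no-parent node {v} has parent {u}")
    for u, v in sorted(constraints.whitelist):
        if not dag.has_edge(u, v):
            out.append(f"missing whitelist edge: {u} -> {v}")
    return out


# ---------------------------------------------------------------------------
# scoring


class Scorer:
    """Cached decomposable BIC local scores over one cohort.

    Column kinds map to node types: continuous stays continuous, discrete
    becomes a factor with its observed levels, genotype becomes either a
    3-level factor {0,1,2} (default, consistent with no-parent SNPs) or a
    continuous dosage (``genotype_as="continuous"``). Missing data are
    handled complete-case per local-score computation.
    """

    _degenerate_reported = False

    def __init__(self, cohort: CohortTable, genotype_as: str = "discrete"):
        if genotype_as not in ("discrete", "continuous"):
            raise SchemaError(f"genotype_as must be discrete|continuous, got {genotype_as}")
        self.n_rows = cohort.n
        self.nodes: list[Node] = []
        self._cont: dict[str, np.ndarray] = {}
        self._codes: dict[str, np.ndarray] = {}  # int codes, -1 = missing
        self._nlev: dict[str, int] = {}
        self._cache: dict[tuple[str, frozenset], float] = {}
        for col in cohort.columns:
            kind = cohort.kinds[col]
            series = cohort.data[col]
            if kind == "continuous" or (kind == "genotype" and genotype_as == "continuous"):
                self.nodes.append(Node(col, "continuous"))
                self._cont[col] = series.to_numpy(dtype=float)
            elif kind == "genotype":
                self.nodes.append(Node(col, "discrete", levels=("0", "1", "2")))
                vals = series.to_numpy(dtype=float)
                codes = np.where(np.isnan(vals), -1, vals).astype(int)
                self._codes[col] = codes
                self._nlev[col] = 3
            else:
                cat = series.astype("category")
                levels = tuple(str(level) for level in cat.cat.categories)
                if len(levels) < 2:
                    raise SchemaError(f"discrete column {col!r} has < 2 observed levels")
                self.nodes.append(Node(col, "discrete", levels=levels))
                self._codes[col] = cat.cat.codes.to_numpy().astype(int)
                self._nlev[col] = len(levels)
        self.kind = {n.name: n.kind for n in self.nodes}

    # -- helpers ---------------------------------------------------------

    def node_list(self) -> list[Node]:
        return list(self.nodes)

    def _complete_mask(self, cols: list[str]) -> np.ndarray:
        mask = np.ones(self.n_rows, dtype=bool)
        for c in cols:
            if c in self._cont:
                mask &= ~np.isnan(self._cont[c])
            else:
                mask &= self._codes[c] >= 0
        return mask

    def _config_ids(self, disc: list[str], mask: np.ndarray) -> np.ndarray:
        ids = np.zeros(int(mask.sum()), dtype=np.int64)
        for c in disc:
            ids = ids * self._nlev[c] + self._codes[c][mask]
        return ids

    def _warn_degenerate(self, child: str, note: str) -> None:
        # warn once per process; repeats (common across bootstrap refits) at DEBUG
        if not Scorer._degenerate_reported:
            logger.warning("degenerate configuration while scoring %s: %s "
                           "(further occurrences logged at DEBUG)", child, note)
            Scorer._degenerate_reported = True
        else:
            logger.debug("degenerate configuration while scoring %s: %s", child, note)

    # -- the local score -------------------------------------------------

    def local_score(self, child: str, parents: frozenset | set | list = frozenset()) -> float:
        """BIC local score of ``child`` given ``parents`` (log scale, higher better)."""
        parents = frozenset(parents)
        key = (child, parents)
        if key in self._cache:
            return self._cache[key]
        if child in parents:
            raise ConstraintError(f"{child} cannot be its own parent")
        cont_par = sorted(p for p in parents if self.kind[p] == "continuous")
        disc_par = sorted(p for p in parents if self.kind[p] == "discrete")
        if self.kind[child] == "discrete" and cont_par:
            raise ConstraintError(
                f"CG restriction: discrete {child} with continuous parents {cont_par}"
            )
        cols = [child] + cont_par + disc_par
        mask = self._complete_mask(cols)
        n = int(mask.sum())
        if n < 2:
            raise SchemaError(f"fewer than 2 complete rows for scoring {child}")
        if self.kind[child] == "continuous":
            score = self._gaussian_score(child, cont_par, disc_par, mask, n)
        else:
            score = self._multinomial_score(child, disc_par, mask, n)
        self._cache[key] = score
        return score

    def _gaussian_score(self, child, cont_par, disc_par, mask, n) -> float:
        y = self._cont[child][mask]
        X = np.column_stack([np.ones(n)] + [self._cont[p][mask] for p in cont_par])
        p_params = X.shape[1]  # intercept + slopes
        if disc_par:
            ids = self._config_ids(disc_par, mask)
            order = np.argsort(ids, kind="stable")
            ids_sorted = ids[order]
            bounds = np.flatnonzero(np.r_[True, ids_sorted[1:] != ids_sorted[:-1], True])
            groups = [order[bounds[i]:bounds[i + 1]] for i in range(len(bounds) - 1)]
        else:
            groups = [np.arange(n)]
        loglik = 0.0
        for idx in groups:
            nc = idx.size
            if nc <= p_params:
                self._warn_degenerate(child, f"{nc} rows for {p_params} regression parameters")
                continue
            yc, Xc = y[idx], X[idx]
            beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
            rss = float(np.sum((yc - Xc @ beta) ** 2))
            sigma2 = rss / nc
            if sigma2 < 1e-12:
                self._warn_degenerate(child, "zero residual variance")
                continue
            loglik += -0.5 * nc * (math.log(2.0 * math.pi * sigma2) + 1.0)
        k = len(groups) * (p_params + 1)  # intercept+slopes+variance per observed config
        return loglik - 0.5 * k * math.log(n)

    def _multinomial_score(self, child, disc_par, mask, n) -> float:
        codes = self._codes[child][mask]
        nlev = self._nlev[child]
        if disc_par:
            ids = self._config_ids(disc_par, mask)
        else:
            ids = np.zeros(n, dtype=np.int64)
        combo = ids * nlev + codes
        counts = np.bincount(combo)
        counts = counts[counts > 0].astype(float)
        # per-cell n*log(n) minus per-config n*log(n)
        cfg_counts = np.bincount(ids).astype(float)
        cfg_counts = cfg_counts[cfg_counts > 0]
        loglik = float(np.sum(counts * np.log(counts)) - np.sum(cfg_counts * np.log(cfg_counts)))
        n_configs = 1
        for p in disc_par:
            n_configs *= self._nlev[p]
        k = (nlev - 1) * n_configs
        return loglik - 0.5 * k * math.log(n)


@dataclass
class ScoredNetwork:
    """A DAG with its per-node local scores, their exact sum, and (for search
    results) the trace of total scores across accepted moves."""

    dag: Dag
    local_scores: dict[str, float]
    total: float
    trace: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# neighborhood enumeration


_OP_RANK = {"add": 0, "delete": 1, "reverse": 2}


def neighbors(dag: Dag, constraints: ConstraintSet) -> list[tuple[str, str, str]]:
    """All single-edge operations (kind, parent, child) yielding a valid DAG.

    Deterministic order: adds, then deletes, then reverses, each sorted
    lexicographically by node names. Whitelist edges are never deleted or
    reversed; every returned operation preserves acyclicity, the CG
    restriction, and the constraint set.
    """
    names = sorted(n.name for n in dag.nodes)
    ops: list[tuple[str, str, str]] = []
    for u in names:
        for v in names:
            if u == v:
                continue
            if dag.has_edge(u, v):
                continue
            if (u, v) in constraints.blacklist or v in constraints.no_parent_nodes:
                continue
            if dag.kind[v] == "discrete" and dag.kind[u] == "continuous":
                continue
            if dag.has_edge(v, u) or dag.has_path(v, u):
                continue
            ops.append(("add", u, v))
    for u, v in dag.edges():
        if (u, v) in constraints.whitelist:
            continue
        ops.append(("delete", u, v))
    for u, v in dag.edges():
        if (u, v) in constraints.whitelist:
            continue
        if (v, u) in constraints.blacklist or u in constraints.no_parent_nodes:
            continue
        if dag.kind[u] == "discrete" and dag.kind[v] == "continuous":
            continue
        # reversal is acyclic iff the only u->v path is the edge itself
        tmp = dag.copy()
        tmp.remove_edge(u, v)
        if tmp.has_path(u, v):
            continue
        ops.append(("reverse", u, v))
    ops.sort(key=lambda op: (_OP_RANK[op[0]], op[1], op[2]))
    return ops


def apply_op(dag: Dag, op: tuple[str, str, str]) -> None:
    kind, u, v = op
    if kind == "add":
        dag.add_edge(u, v, unchecked=True)
    elif kind == "delete":
        dag.remove_edge(u, v)
    else:
        dag.remove_edge(u, v)
        dag.add_edge(v, u, unchecked=True)


# ---------------------------------------------------------------------------
# hill-climbing search


def _as_scorer(data, genotype_as: str) -> Scorer:
    if isinstance(data, Scorer):
        return data
    if isinstance(data, CohortTable):
        return Scorer(data, genotype_as=genotype_as)
    raise SchemaError(f"expected CohortTable or Scorer, got {type(data).__name__}")


def _whitelist_start(scorer: Scorer, constraints: ConstraintSet) -> Dag:
    names = {n.name for n in scorer.nodes}
    for u, v in constraints.whitelist:
        if u not in names or v not in names:
            raise SchemaError(f"constraint references unknown column {u!r} or {v!r}")
    for name in constraints.no_parent_nodes:
        if name not in names:
            raise SchemaError(f"no-parent constraint references unknown column {name!r}")
    return Dag(scorer.node_list(), sorted(constraints.whitelist))


def _op_delta(scorer: Scorer, dag: Dag, op, local: dict[str, float]) -> float:
    kind, u, v = op
    if kind == "add":
        return scorer.local_score(v, dag.parents(v) | {u}) - local[v]
    if kind == "delete":
        return scorer.local_score(v, dag.parents(v) - {u}) - local[v]
    d = scorer.local_score(v, dag.parents(v) - {u}) - local[v]
    d += scorer.local_score(u, dag.parents(u) | {v}) - local[u]
    return d


def _climb(scorer: Scorer, constraints: ConstraintSet, dag: Dag,
           rng: np.random.Generator) -> ScoredNetwork:
    local = {n.name: scorer.local_score(n.name, dag.parents(n.name)) for n in dag.nodes}
    trace = [sum(local.values())]
    while True:
        ops = neighbors(dag, constraints)
        if not ops:
            break
        deltas = np.array([_op_delta(scorer, dag, op, local) for op in ops])
        best = float(deltas.max()) if deltas.size else -np.inf
        if best <= SCORE_TOL:
            break
        tied = np.flatnonzero(deltas >= best - SCORE_TOL)
        op = ops[int(tied[int(rng.integers(tied.size))])]
        kind, u, v = op
        apply_op(dag, op)
        local[v] = scorer.local_score(v, dag.parents(v))
        if kind == "reverse":
            local[u] = scorer.local_score(u, dag.parents(u))
        trace.append(sum(local.values()))
    return ScoredNetwork(dag=dag, local_scores=local, total=sum(local.values()), trace=trace)


def _perturb(dag: Dag, constraints: ConstraintSet, r: int, rng: np.random.Generator) -> Dag:
    g = dag.copy()
    for _ in range(r):
        ops = [op for op in neighbors(g, constraints) if op[0] in ("add", "delete")]
        if not ops:
            break
        apply_op(g, ops[int(rng.integers(len(ops)))])
    return g


def hill_climb(
    data: CohortTable | Scorer,
    constraints: ConstraintSet | None = None,
    restarts: int = 10,
    rng: np.random.Generator | None = None,
    perturbation: int | None = None,
    genotype_as: str = "discrete",
) -> ScoredNetwork:
    """Greedy BIC hill-climbing with random restarts.

    Starts from the whitelist-only graph and repeatedly applies the best
    strictly-improving single-edge operation; score ties (within 1e-9)
    are broken uniformly at random so that score-equivalent orientations
    are sampled evenly across bootstrap replicates. Each restart perturbs
    the incumbent local optimum by ``perturbation`` random valid edge
    additions/deletions (default 2x the node count) and re-climbs; the
    best network seen is returned and always satisfies :func:`validate`.
    """
    if restarts < 0:
        raise ValueError("restarts must be >= 0")
    scorer = _as_scorer(data, genotype_as)
    constraints = constraints or ConstraintSet.empty()
    rng = rng if rng is not None else np.random.default_rng()
    r = perturbation if perturbation is not None else 2 * len(scorer.nodes)
    best = _climb(scorer, constraints, _whitelist_start(scorer, constraints), rng)
    for _ in range(restarts):
        cand = _climb(scorer, constraints, _perturb(best.dag, constraints, r, rng), rng)
        if cand.total > best.total + SCORE_TOL:
            best = cand
    return best


# ---------------------------------------------------------------------------
# exhaustive oracle


MAX_EXHAUSTIVE_NODES = 5


def enumerate_dags(nodes: list[Node], constraints: ConstraintSet | None = None):
    """Yield every valid DAG over ``nodes`` (<= 5 nodes).

    Enumerates the three states (absent, forward, backward) of every
    unordered node pair, filtering by constraints, the CG restriction and
    acyclicity; duplicate-free by construction.
    """
    constraints = constraints or ConstraintSet.empty()
    if len(nodes) > MAX_EXHAUSTIVE_NODES:
        raise SizeLimitError(
            f"exhaustive enumeration limited to {MAX_EXHAUSTIVE_NODES} nodes, got {len(nodes)}"
        )
    kind = {n.name: n.kind for n in nodes}
    names = sorted(kind)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]

    def edge_ok(u: str, v: str) -> bool:
        if (u, v) in constraints.blacklist or v in constraints.no_parent_nodes:
            return False
        if kind[v] == "discrete" and kind[u] == "continuous":
            return False
        return True

    states_per_pair = []
    for a, b in pairs:
        states: list[tuple[tuple[str, str], ...]] = []
        if (a, b) not in constraints.whitelist and (b, a) not in constraints.whitelist:
            states.append(())
        if edge_ok(a, b) and (b, a) not in constraints.whitelist:
            states.append(((a, b),))
        if edge_ok(b, a) and (a, b) not in constraints.whitelist:
            states.append(((b, a),))
        if not states:
            return  # contradictory constraints: no valid graphs
        states_per_pair.append(states)

    for combo in itertools.product(*states_per_pair):
        edges = [e for state in combo for e in state]
        if _edges_acyclic(names, edges):
            yield Dag(nodes, edges)


def _edges_acyclic(names: list[str], edges: list[tuple[str, str]]) -> bool:
    indeg = dict.fromkeys(names, 0)
    children: dict[str, list[str]] = {n: [] for n in names}
    for u, v in edges:
        indeg[v] += 1
        children[u].append(v)
    stack = [n for n in names if indeg[n] == 0]
    seen = 0
    while stack:
        seen += 1
        for w in children[stack.pop()]:
            indeg[w] -= 1
            if indeg[w] == 0:
                stack.append(w)
    return seen == len(names)


def exhaustive_best(
    data: CohortTable | Scorer,
    constraints: ConstraintSet | None = None,
    genotype_as: str = "discrete",
) -> ScoredNetwork:
    """Argmax of the total BIC over all valid DAGs (<= 5 nodes).

    Deterministic: on ties (within 1e-9) the first DAG in enumeration
    order wins. Shares its local-score cache with hill-climbing when both
    are handed the same :class:`Scorer`.
    """
    scorer = _as_scorer(data, genotype_as)
    constraints = constraints or ConstraintSet.empty()
    best: ScoredNetwork | None = None
    for dag in enumerate_dags(scorer.node_list(), constraints):
        local = {n.name: scorer.local_score(n.name, dag.parents(n.name)) for n in dag.nodes}
        total = sum(local.values())
        if best is None or total > best.total + SCORE_TOL:
            best = ScoredNetwork(dag=dag, local_scores=local, total=total)
    if best is None:
        raise ConstraintError("constraints admit no valid DAG")
    return best
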