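"""Virtual-resection search: candidate edges, simulated annealing, strategies.

The candidate connections of a virtual resection are exactly the binarized
edges from a hypothesized-EZ node to a node outside the EZ -- the
connections an actual surgery would sever.  Choosing the best k of them is
a combinatorial problem; it is solved here per size k with simulated
annealing on the eigenvector-centrality surrogate objective (minimize the
negative EC difference of the seed), with an exhaustive enumerator as an
oracle for small instances.  The best-effect-per-size curve is strongly
concave in practice, so the smallest size reaching 90% of the
full-disconnection effect (the "optimal size" k*) spares substantially
more than 10% of the connections.

Comparison strategies pick the same number of edges by static network
measures (edge betweenness; or EC, degree, betweenness of the non-seed
endpoint) or uniformly at random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix

from ._fast import csr_power_iteration
from .centrality import (
    CentralityBundle,
    Edge,
    ResectionEffect,
    centrality_suite,
    ec_difference,
    eigenvector_centrality,
    full_disconnection_edges,
)
from .connectome import ConnectomeMatrix, SeedSet
from .errors import ParameterError

__all__ = [
    "SAParams",
    "ResectionPlan",
    "EffectCurve",
    "candidate_edges",
    "sa_optimize",
    "brute_force_optimize",
    "effect_curve",
    "select_optimal_size",
    "strategy_select",
    "STRATEGIES",
]

STRATEGIES = ("edge_bc", "neighbor_ec", "neighbor_degree", "neighbor_bc", "random")

_POWER_TOL = 1e-10
_POWER_MAX_ITER = 200_000


@dataclass(frozen=True)
class SAParams:
    """Annealing schedule (defaults follow the generic annealer convention).

    Temperature starts at ``t_initial``, is multiplied by ``cooling`` after
    each temperature stage, and the anneal stops at ``t_stop`` or after
    ``max_consecutive_rejections`` rejected moves in a row.  A stage ends
    after ``max_tries_per_temperature`` proposals or
    ``max_successes_per_temperature`` acceptances.  ``restarts``
    independent anneals are run and the best state kept.
    """

    t_initial: float = 1.0
    t_stop: float = 1e-8
    cooling: float = 0.8
    max_consecutive_rejections: int = 1000
    max_tries_per_temperature: int = 300
    max_successes_per_temperature: int = 20
    restarts: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.cooling < 1:
            raise ParameterError("cooling factor must be in (0, 1)")
        if not self.t_stop < self.t_initial:
            raise ParameterError("t_stop must be below t_initial")
        if self.restarts < 1:
            raise ParameterError("restarts must be >= 1")


@dataclass(frozen=True)
class ResectionPlan:
    """A selected edge subset with its surrogate (and optionally SIR) effect."""

    edges: tuple[Edge, ...]
    k: int
    strategy: str
    effect: ResectionEffect | None = None
    propagation: float | None = None  # normalized I(t0) reduction

    def __post_init__(self) -> None:
        if len(self.edges) != self.k:
            raise ParameterError(f"plan has {len(self.edges)} edges but k={self.k}")
        if len(set(self.edges)) != len(self.edges):
            raise ParameterError("plan contains duplicate edges")


@dataclass(frozen=True)
class EffectCurve:
    """Best EC difference per resection size, and the 90%-effect size k*."""

    sizes: tuple[int, ...]
    best_ec_diff: tuple[float, ...]  # raw EC difference per size
    best_plans: tuple[ResectionPlan, ...]
    k_star: int
    effect_fraction: float

    @property
    def full_effect(self) -> float:
        return self.best_ec_diff[-1]

    @property
    def normalized(self) -> tuple[float, ...]:
        return tuple(v / self.full_effect for v in self.best_ec_diff)

    @property
    def k_star_plan(self) -> ResectionPlan:
        return self.best_plans[self.k_star - 1]

    @property
    def spared_fraction(self) -> float:
        return 1.0 - self.k_star / self.sizes[-1]


def candidate_edges(
    adjacency: ConnectomeMatrix | np.ndarray, seed: SeedSet
) -> list[Edge]:
    """Edges from seed nodes to non-seed neighbors, lexicographically ordered.

    Edges internal to the seed are excluded: they are part of the resected
    tissue itself, not of its disconnection from the rest of the brain.
    """
    return full_disconnection_edges(adjacency, seed)


class _SeedECEvaluator:
    """Cached fast evaluation of the seed's mean EC after removing a
    subset of candidate edges.

    Uses warm-started sparse power iteration (see :mod:`virtres._fast`);
    values are cached by candidate-index subset so annealing restarts and
    neighboring sizes share work.  Accuracy is ~1e-10 on the seed EC, which
    is ample for ranking moves; returned plans are always re-scored with
    the exact dense eigensolver.
    """

    def __init__(
        self,
        adjacency: ConnectomeMatrix,
        seed: SeedSet,
        candidates: Sequence[Edge],
    ) -> None:
        a = adjacency.values
        sp = csr_matrix(a)
        self.indptr = sp.indptr.astype(np.int64)
        self.indices = sp.indices.astype(np.int64)
        self.data = sp.data.astype(np.float64)
        self.seed_idx = np.array(seed.node_indices, dtype=np.int64)
        self.positions = [
            (self._nnz_pos(i, j), self._nnz_pos(j, i)) for i, j in candidates
        ]
        ec = eigenvector_centrality(a)
        base = ec + 1e-3
        self.base_x = base / np.linalg.norm(base)
        self.cache: dict[frozenset[int], float] = {}

    def _nnz_pos(self, i: int, j: int) -> int:
        lo, hi = self.indptr[i], self.indptr[i + 1]
        p = lo + np.searchsorted(self.indices[lo:hi], j)
        if p >= hi or self.indices[p] != j:
            raise ParameterError(f"edge ({i}, {j}) not present in adjacency")
        return int(p)

    def _compute(self, subset: frozenset[int], warm: np.ndarray | None) -> np.ndarray:
        data = self.data.copy()
        for idx in subset:
            p, q = self.positions[idx]
            data[p] = 0.0
            data[q] = 0.0
        if not data.any():  # removal emptied the graph (tiny instances)
            return np.zeros_like(self.base_x)
        x0 = (self.base_x if warm is None else warm) + 1e-12
        return csr_power_iteration(
            self.indptr, self.indices, data, x0, _POWER_TOL, _POWER_MAX_ITER
        )

    def ec_after(
        self,
        subset: frozenset[int],
        warm: np.ndarray | None = None,
        need_vector: bool = False,
    ) -> tuple[float, np.ndarray | None]:
        if not need_vector and subset in self.cache:
            return self.cache[subset], None
        vec = self._compute(subset, warm)
        val = float(vec[self.seed_idx].mean())
        self.cache[subset] = val
        return val, vec


def _exact_plan(
    adjacency: ConnectomeMatrix,
    seed: SeedSet,
    candidates: Sequence[Edge],
    subset: frozenset[int],
    strategy: str,
) -> ResectionPlan:
    edges = tuple(sorted(candidates[i] for i in subset))
    return ResectionPlan(
        edges=edges,
        k=len(edges),
        strategy=strategy,
        effect=ec_difference(adjacency, seed, edges),
    )


def sa_optimize(
    adjacency: ConnectomeMatrix,
    seed: SeedSet,
    k: int,
    sa: SAParams,
    rng: np.random.Generator,
    *,
    candidates: Sequence[Edge] | None = None,
    _evaluator: "_SeedECEvaluator | None" = None,
) -> ResectionPlan:
    """Simulated-annealing search for the k-edge removal maximizing the
    seed's EC difference.

    The state is a k-subset of the candidate edges; a neighboring state
    swaps one selected edge for one unselected candidate (both chosen
    uniformly).  Moves are Metropolis-accepted on the objective
    ``-EC difference`` at the current temperature.  The best state over
    all restarts is returned, re-scored exactly.
    """
    if candidates is None:
        candidates = candidate_edges(adjacency, seed)
    n_cand = len(candidates)
    if n_cand == 0:
        raise ParameterError("seed has no candidate edges")
    if not 1 <= k <= n_cand:
        raise ParameterError(f"k must be in [1, {n_cand}], got {k}")
    ev = _evaluator or _SeedECEvaluator(adjacency, seed, candidates)

    if k == n_cand:  # only one subset exists
        return _exact_plan(adjacency, seed, candidates, frozenset(range(k)), "optimal")

    best_obj = math.inf
    best_subset: frozenset[int] = frozenset()
    for _ in range(sa.restarts):
        perm = rng.permutation(n_cand).tolist()
        state, others = perm[:k], perm[k:]  # selected / unselected candidates
        in_state = frozenset(state)
        obj, vec = ev.ec_after(in_state, need_vector=True)
        if obj < best_obj:
            best_obj, best_subset = obj, in_state
        temp = sa.t_initial
        consecutive_rejections = 0
        stopped = False
        while temp >= sa.t_stop and not stopped:
            tries = successes = 0
            while (
                tries < sa.max_tries_per_temperature
                and successes < sa.max_successes_per_temperature
            ):
                tries += 1
                pos = int(rng.integers(k))
                opos = int(rng.integers(len(others)))
                proposal = in_state - {state[pos]} | {others[opos]}
                new_obj, new_vec = ev.ec_after(proposal, warm=vec)
                delta = new_obj - obj
                if delta < 0 or rng.random() < math.exp(-delta / temp):
                    state[pos], others[opos] = others[opos], state[pos]
                    in_state = proposal
                    obj = new_obj
                    if new_vec is None:  # accepted a cached value: refresh vector
                        _, new_vec = ev.ec_after(proposal, warm=vec, need_vector=True)
                    vec = new_vec
                    successes += 1
                    consecutive_rejections = 0
                    if obj < best_obj:
                        best_obj, best_subset = obj, in_state
                else:
                    consecutive_rejections += 1
                    if consecutive_rejections >= sa.max_consecutive_rejections:
                        stopped = True
                        break
            temp *= sa.cooling
    return _exact_plan(adjacency, seed, candidates, best_subset, "optimal")


def brute_force_optimize(
    adjacency: ConnectomeMatrix,
    seed: SeedSet,
    k: int,
    *,
    candidates: Sequence[Edge] | None = None,
    max_subsets: int = 500_000,
) -> ResectionPlan:
    """Exact maximizer of the EC difference over all k-subsets.

    Enumeration oracle for validating the annealer on small instances;
    ties are broken by lexicographic edge order.  Uses the exact dense
    eigensolver throughout, i.e. a code path independent of the annealer's
    fast objective.
    """
    if candidates is None:
        candidates = candidate_edges(adjacency, seed)
    n_cand = len(candidates)
    if not 1 <= k <= n_cand:
        raise ParameterError(f"k must be in [1, {n_cand}], got {k}")
    n_subsets = math.comb(n_cand, k)
    if n_subsets > max_subsets:
        raise ParameterError(
            f"C({n_cand}, {k}) = {n_subsets} exceeds the {max_subsets} subset cap"
        )
    a = adjacency.values
    seed_idx = list(seed.node_indices)
    best_after = math.inf
    best_combo: tuple[int, ...] = ()
    for combo in combinations(range(n_cand), k):
        cut = a.copy()
        for idx in combo:
            i, j = candidates[idx]
            cut[i, j] = 0.0
            cut[j, i] = 0.0
        if not cut.any():
            after = 0.0
        else:
            vals, vecs = np.linalg.eigh(cut)
            v = vecs[:, -1]
            if v.sum() < 0:
                v = -v
            v = np.clip(v, 0.0, None)
            v /= np.linalg.norm(v)
            after = float(v[seed_idx].mean())
        if after < best_after - 1e-15:  # strict improvement keeps first (lex) best
            best_after = after
            best_combo = combo
    plan = _exact_plan(
        adjacency, seed, candidates, frozenset(best_combo), "brute_force"
    )
    return plan


def select_optimal_size(curve: EffectCurve, fraction: float = 0.9) -> int:
    """Smallest resection size whose EC difference reaches ``fraction`` of
    the full-resection effect (the full resection always qualifies)."""
    if not 0 < fraction <= 1:
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    full = curve.best_ec_diff[-1]
    for size, diff in zip(curve.sizes, curve.best_ec_diff):
        if diff >= fraction * full:
            return size
    return curve.sizes[-1]


def effect_curve(
    adjacency: ConnectomeMatrix,
    seed: SeedSet,
    sa: SAParams,
    rng: np.random.Generator,
    *,
    effect_fraction: float = 0.9,
) -> EffectCurve:
    """Best EC difference for every resection size 1..K, plus k*.

    Each size is annealed independently; in addition, the previous size's
    best plan augmented with its single best extra candidate is evaluated,
    and the better of the two kept.  This greedy guard never lowers a
    size's best effect and makes the curve monotone in practice.
    """
    candidates = candidate_edges(adjacency, seed)
    n_cand = len(candidates)
    if n_cand == 0:
        raise ParameterError("seed has no candidate edges")
    ev = _SeedECEvaluator(adjacency, seed, candidates)
    plans: list[ResectionPlan] = []
    prev_subset: frozenset[int] = frozenset()
    for k in range(1, n_cand + 1):
        plan = sa_optimize(
            adjacency, seed, k, sa, rng, candidates=candidates, _evaluator=ev
        )
        chosen = frozenset(candidates.index(e) for e in plan.edges)
        if k > 1 and prev_subset:
            additions = [c for c in range(n_cand) if c not in prev_subset]
            scored = [(ev.ec_after(prev_subset | {c})[0], c) for c in additions]
            best_aug = prev_subset | {min(scored)[1]}
            if best_aug != chosen:
                aug_plan = _exact_plan(adjacency, seed, candidates, best_aug, "optimal")
                if aug_plan.effect.ec_diff > plan.effect.ec_diff:
                    plan, chosen = aug_plan, best_aug
        plans.append(plan)
        prev_subset = chosen
    sizes = tuple(range(1, n_cand + 1))
    diffs = tuple(p.effect.ec_diff for p in plans)
    provisional = EffectCurve(
        sizes=sizes,
        best_ec_diff=diffs,
        best_plans=tuple(plans),
        k_star=n_cand,
        effect_fraction=effect_fraction,
    )
    k_star = select_optimal_size(provisional, effect_fraction)
    return EffectCurve(
        sizes=sizes,
        best_ec_diff=diffs,
        best_plans=tuple(plans),
        k_star=k_star,
        effect_fraction=effect_fraction,
    )


def _ranked_plans(
    adjacency: ConnectomeMatrix,
    seed: SeedSet,
    candidates: Sequence[Edge],
    k: int,
    strategy: str,
    bundle: CentralityBundle,
) -> ResectionPlan:
    if strategy == "edge_bc":
        keys = [bundle.edge_bc[(min(i, j), max(i, j))] for i, j in candidates]
    elif strategy == "neighbor_ec":
        keys = [bundle.ec[j] for _, j in candidates]
    elif strategy == "neighbor_degree":
        keys = [float(bundle.degree[j]) for _, j in candidates]
    elif strategy == "neighbor_bc":
        keys = [bundle.node_bc[j] for _, j in candidates]
    else:  # pragma: no cover - guarded by caller
        raise ParameterError(f"unknown strategy {strategy!r}")
    # sort by metric descending; stable sort keeps lexicographic candidate
    # order among ties
    order = sorted(range(len(candidates)), key=lambda c: -keys[c])
    subset = frozenset(order[:k])
    plan = _exact_plan(adjacency, seed, candidates, subset, strategy)
    return plan


def strategy_select(
    adjacency: ConnectomeMatrix,
    seed: SeedSet,
    k: int,
    strategy: str,
    rng: np.random.Generator | None = None,
    *,
    candidates: Sequence[Edge] | None = None,
    bundle: CentralityBundle | None = None,
    n_random: int = 100,
) -> ResectionPlan | list[ResectionPlan]:
    """Pick k candidate edges by a static network measure or at random.

    Deterministic strategies rank the candidates by edge betweenness or by
    the EC / degree / betweenness of the non-seed endpoint (ties broken by
    lexicographic edge order).  ``strategy="random"`` returns ``n_random``
    independent uniform k-subsets (the random baseline).
    """
    if candidates is None:
        candidates = candidate_edges(adjacency, seed)
    n_cand = len(candidates)
    if not 1 <= k <= n_cand:
        raise ParameterError(f"k must be in [1, {n_cand}], got {k}")
    if strategy == "random":
        if rng is None:
            raise ParameterError("random strategy requires an rng")
        plans = []
        for _ in range(n_random):
            subset = frozenset(rng.choice(n_cand, size=k, replace=False).tolist())
            plans.append(_exact_plan(adjacency, seed, candidates, subset, "random"))
        return plans
    if strategy not in STRATEGIES:
        raise ParameterError(
            f"unknown strategy {strategy!r}; expected one of {STRATEGIES}"
        )
    if bundle is None:
        bundle = centrality_suite(adjacency)
    return _ranked_plans(adjacency, seed, candidates, k, strategy, bundle)
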