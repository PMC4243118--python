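"""Cohesiveness-based detection of (possibly overlapping) protein complexes.

The detector follows the greedy three-step scheme popularized by ClusterONE:

1. **Growth** — from each seed protein, greedily grow a group by the single
   best addition of an external neighbor or removal of a member that strictly
   increases the group's *cohesiveness*

       f(V) = w_in / (w_in + w_bound + penalty * |V|),

   where ``w_in`` is the total weight of edges inside V and ``w_bound`` the
   total weight of edges crossing the boundary.  The per-member penalty
   models unobserved interactions and discourages sprawling groups.
2. **Merging** — pairs of locally optimal groups whose overlap score
   omega = |A ∩ B|^2 / (|A| |B|) reaches the merge threshold are merged,
   highest-omega pair first, until all pairwise overlaps are below it.
3. **Filtering** — candidates with fewer than ``min_size`` proteins or with
   density below the density threshold are discarded.  On unweighted
   networks the threshold can be resolved automatically from the network's
   transitivity: sparse, star-heavy networks (low transitivity) get the
   stricter 0.6, others 0.5.

No claim of numeric parity with the original ClusterONE binary is made: the
seeding order, tie-breaking and merge schedule here are chosen for
determinism and are all exposed as parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

from .complexes import ComplexSet
from .evaluation import overlap_score
from .network import PPINetwork, density, transitivity

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionParams",
    "CandidateGroup",
    "cohesiveness",
    "grow_from_seed",
    "merge_overlapping",
    "detect_complexes",
    "register_detector",
    "get_detector",
    "list_detectors",
]


@dataclass
class DetectionParams:
    """Tunable knobs of the detection pipeline.

    penalty
        Cohesiveness boundary penalty per member (>= 0).  Default 2.0.
    density_threshold
        Minimum complex density, in [0, 1], or ``"auto"`` to resolve from the
        network: 0.5 for weighted networks; for unweighted networks 0.6 when
        the transitivity falls below ``transitivity_cutoff``, else 0.5.
    min_size
        Minimum complex size (default 3).
    merge_overlap
        Overlap score at or above which two grown groups merge, in (0, 1].
    transitivity_cutoff
        Transitivity below which an unweighted network is considered
        star-heavy and gets the stricter 0.6 density threshold.
    max_moves_factor
        Growth terminates after ``max_moves_factor * |V(net)|`` moves even if
        improving moves remain (a safety bound; steepest ascent on a bounded
        score normally stops long before).
    """

    penalty: float = 2.0
    density_threshold: float | str = "auto"
    min_size: int = 3
    merge_overlap: float = 0.8
    seed_order: str = "degree"
    transitivity_cutoff: float = 0.3
    max_moves_factor: int = 10

    def __post_init__(self):
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if not (0 < self.merge_overlap <= 1):
            raise ValueError("merge_overlap must lie in (0, 1]")
        if self.density_threshold != "auto" and not (0 <= float(self.density_threshold) <= 1):
            raise ValueError("density_threshold must be in [0, 1] or 'auto'")

    def resolve_density_threshold(self, net: PPINetwork) -> float:
        """Resolve ``"auto"`` against a concrete network."""
        if self.density_threshold != "auto":
            return float(self.density_threshold)
        if net.weighted:
            return 0.5
        t = transitivity(net)
        chosen = 0.6 if t < self.transitivity_cutoff else 0.5
        logger.info("auto density threshold: transitivity=%.3f -> %.1f", t, chosen)
        return chosen


@dataclass(frozen=True)
class CandidateGroup:
    """A grown group of proteins together with its cohesiveness score."""

    members: frozenset[str]
    cohesiveness: float


def _in_bound_weights(net: PPINetwork, members: frozenset[str] | set[str]) -> tuple[float, float]:
    """Total internal edge weight and boundary edge weight of a member set."""
    g = net.graph
    w_in = 0.0
    w_bound = 0.0
    for u in members:
        for v, data in g.adj[u].items():
            if v == u:
                continue  # self-loops are neither internal nor boundary
            w = data.get("weight", 1.0)
            if v in members:
                w_in += w / 2  # counted from both endpoints
            else:
                w_bound += w
    return w_in, w_bound


def cohesiveness(net: PPINetwork, members, penalty: float = 2.0) -> float:
    """f(V) = w_in / (w_in + w_bound + penalty * |V|); in [0, 1].

    Equals 1 exactly when the group has internal edges, no boundary edges and
    no penalty.  A single protein has w_in = 0 and hence cohesiveness 0.
    """
    members = frozenset(members)
    if not members:
        raise ValueError("cohesiveness is undefined for an empty member set")
    w_in, w_bound = _in_bound_weights(net, members)
    denom = w_in + w_bound + penalty * len(members)
    return w_in / denom if denom > 0 else 0.0


def grow_from_seed(net: PPINetwork, seed: str, params: DetectionParams | None = None) -> CandidateGroup:
    """Grow a locally optimal cohesive group from a seed protein.

    Steepest-ascent local search on the cohesiveness score: at each step the
    single best move — adding an external neighbor of the group or removing a
    member other than the seed — is applied if it strictly increases
    cohesiveness; the search stops at a local optimum.  Ties between equally
    good moves break on the lexicographically smallest protein identifier, so
    the result is deterministic.
    """
    params = params or DetectionParams()
    g = net.graph
    if seed not in g:
        raise KeyError(f"seed protein {seed!r} not in network")

    members: set[str] = {seed}
    w_in, w_bound = _in_bound_weights(net, members)
    penalty = params.penalty

    def score(wi: float, wb: float, size: int) -> float:
        denom = wi + wb + penalty * size
        return wi / denom if denom > 0 else 0.0

    current = score(w_in, w_bound, 1)
    max_moves = params.max_moves_factor * max(1, net.n_proteins)

    for _ in range(max_moves):
        best: tuple[float, str, str] | None = None  # (new_score, node, kind)

        # candidate additions: external nodes adjacent to the group
        frontier: set[str] = set()
        for u in members:
            frontier.update(v for v in g.adj[u] if v not in members and v != u)
        for v in sorted(frontier):
            w_to_group = sum(
                d.get("weight", 1.0) for nb, d in g.adj[v].items() if nb in members
            )
            w_outside = sum(
                d.get("weight", 1.0)
                for nb, d in g.adj[v].items()
                if nb not in members and nb != v
            )
            new = score(w_in + w_to_group, w_bound - w_to_group + w_outside, len(members) + 1)
            if best is None or new > best[0] + 1e-15:
                best = (new, v, "add")

        # candidate removals: any member except the seed
        for v in sorted(members - {seed}):
            w_to_group = sum(
                d.get("weight", 1.0)
                for nb, d in g.adj[v].items()
                if nb in members and nb != v
            )
            w_outside = sum(
                d.get("weight", 1.0)
                for nb, d in g.adj[v].items()
                if nb not in members and nb != v
            )
            new = score(w_in - w_to_group, w_bound + w_to_group - w_outside, len(members) - 1)
            if best is None or new > best[0] + 1e-15:
                best = (new, v, "remove")

        if best is None or best[0] <= current + 1e-12:
            break
        new_score, node, kind = best
        w_to_group = sum(d.get("weight", 1.0) for nb, d in g.adj[node].items() if nb in members and nb != node)
        w_outside = sum(d.get("weight", 1.0) for nb, d in g.adj[node].items() if nb not in members and nb != node)
        if kind == "add":
            members.add(node)
            w_in += w_to_group
            w_bound += w_outside - w_to_group
        else:
            members.remove(node)
            w_in -= w_to_group
            w_bound += w_to_group - w_outside
        current = new_score

    return CandidateGroup(members=frozenset(members), cohesiveness=current)


def merge_overlapping(
    groups: list[CandidateGroup],
    merge_overlap: float = 0.8,
    net: PPINetwork | None = None,
    penalty: float = 2.0,
) -> list[CandidateGroup]:
    """Merge highly overlapping groups until all pairwise overlaps are small.

    While some pair of groups has overlap score omega >= ``merge_overlap``,
    the pair with the largest omega is replaced by its union (ties break on
    the lexicographically smallest combined member tuple).  When ``net`` is
    given, merged groups get their cohesiveness recomputed; otherwise it is
    reported as NaN.
    """
    pool = list(groups)
    # deduplicate identical member sets up front (omega would be 1 anyway)
    seen: dict[frozenset[str], CandidateGroup] = {}
    for grp in pool:
        seen.setdefault(grp.members, grp)
    pool = list(seen.values())

    while True:
        best = None  # (omega, sort_key, i, j)
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                om = overlap_score(pool[i].members, pool[j].members)
                if om >= merge_overlap:
                    key = tuple(sorted(pool[i].members | pool[j].members))
                    if best is None or om > best[0] or (om == best[0] and key < best[1]):
                        best = (om, key, i, j)
        if best is None:
            break
        _, _, i, j = best
        union = pool[i].members | pool[j].members
        if net is not None:
            coh = cohesiveness(net, union, penalty=penalty)
        else:
            coh = float("nan")
        merged = CandidateGroup(members=union, cohesiveness=coh)
        pool = [grp for k, grp in enumerate(pool) if k not in (i, j)]
        pool.append(merged)
    return pool


def detect_complexes(net: PPINetwork, params: DetectionParams | None = None) -> ComplexSet:
    """Run the full grow / merge / filter pipeline on a network.

    Seeds are taken in decreasing degree order (ties on the smaller protein
    identifier); a protein already covered by a previously grown group is not
    used as a seed.  After merging, groups smaller than ``min_size`` or with
    density below the resolved threshold are discarded.  The surviving
    complexes may overlap.
    """
    params = params or DetectionParams()
    if net.n_proteins == 0:
        return ComplexSet()

    order = sorted(net.graph.degree(), key=lambda kv: (-kv[1], kv[0]))
    covered: set[str] = set()
    grown: list[CandidateGroup] = []
    for protein, deg in order:
        if protein in covered or deg == 0:
            continue
        grp = grow_from_seed(net, protein, params)
        grown.append(grp)
        covered |= grp.members

    merged = merge_overlapping(
        grown, merge_overlap=params.merge_overlap, net=net, penalty=params.penalty
    )

    thr = params.resolve_density_threshold(net)
    kept = []
    for grp in sorted(merged, key=lambda g: tuple(sorted(g.members))):
        if len(grp.members) < params.min_size:
            continue
        if density(net, grp.members) < thr:
            continue
        kept.append(grp.members)
    logger.info(
        "detect_complexes: %d seeds grown, %d after merge, %d kept (threshold %.2f)",
        len(grown), len(merged), len(kept), thr,
    )
    return ComplexSet.from_sets(kept)


# -- pluggable detector registry ---------------------------------------------

Detector = Callable[[PPINetwork, DetectionParams], ComplexSet]

_REGISTRY: dict[str, Detector] = {}


def register_detector(name: str, fn: Detector) -> None:
    """Register a detection algorithm under a name for the pipeline to use."""
    _REGISTRY[name] = fn


def get_detector(name: str) -> Detector:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"no detector named {name!r}; available: {sorted(_REGISTRY)}") from None


def list_detectors() -> list[str]:
    return sorted(_REGISTRY)


def _unimplemented(which: str) -> Detector:
    def fn(net: PPINetwork, params: DetectionParams) -> ComplexSet:
        raise NotImplementedError(
            f"the {which} detector slot is reserved but not implemented; "
            "register your own via register_detector()"
        )
    return fn


register_detector("clusterone", detect_complexes)
register_detector("cmc", _unimplemented("CMC"))
register_detector("coach", _unimplemented("COACH"))
register_detector("rrw", _unimplemented("RRW"))
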