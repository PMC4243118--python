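"""Planted-complex benchmark generator.

Emulates the full experimental setting end-to-end without external data: a
yeast-like PPI network with planted, possibly overlapping complexes; a stream
of literature-extracted interaction records whose confidence scores separate
held-out true edges from spurious pairs; an alias table mapping common names
to systematic-style ORF identifiers; and a (possibly thinned) gold standard.

The generative model:

* ``n_complexes`` complexes with sizes uniform in ``size_range`` are planted
  over disjoint protein sets; a fraction ``overlap_fraction`` of them swap
  one or two members for proteins of an earlier complex, producing overlap.
* every within-complex pair becomes a *true* edge with probability ``p_in``;
  every remaining pair becomes background noise with probability ``p_noise``.
* on weighted networks, edge weights are ``clip01(base + N(0, sd))`` with a
  higher base for true intra-complex edges than for noise edges, mimicking
  reliability-scored TAP data.
* a fraction ``holdout_fraction`` of the true edges is withheld from the
  network and emitted as literature records (under the proteins' common
  names) with confidence drawn from the true-edge score model;
  ``n_false_lit`` spurious pairs are emitted with confidence from the
  false-edge model.  With the default models — true scores N(0.8, 0.1),
  false scores N(-0.8, 0.1) — the score cleanly ranks true above false
  records, which is the calibration assumption behind the threshold sweep.

All randomness flows from the single integer ``seed`` through one
``numpy.random.Generator``; a fixed seed reproduces the outputs exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .complexes import ComplexSet
from .literature import AliasTable, LiteraturePPI
from .network import PPINetwork

__all__ = ["ScoreModel", "SyntheticConfig", "SyntheticTruth", "generate", "perturb_gold"]


@dataclass(frozen=True)
class ScoreModel:
    """Gaussian confidence-score model for true and spurious literature records."""

    true_mean: float = 0.8
    true_sd: float = 0.1
    false_mean: float = -0.8
    false_sd: float = 0.1


@dataclass
class SyntheticConfig:
    """Parameters of the planted-complex benchmark.

    Defaults describe a mid-sized benchmark: a dozen complexes of 4–9
    proteins, fully wired internally, light background noise, one fifth of
    the true edges withheld as literature records, and three hundred spurious
    literature pairs — enough that an ill-chosen confidence threshold visibly
    degrades detection.
    """

    n_complexes: int = 12
    size_range: tuple[int, int] = (4, 9)
    p_in: float = 1.0
    p_noise: float = 0.02
    overlap_fraction: float = 0.25
    holdout_fraction: float = 0.2
    n_false_lit: int = 300
    score_model: ScoreModel = field(default_factory=ScoreModel)
    weighted: bool = True
    weight_base_true: float = 0.8
    weight_base_noise: float = 0.3
    weight_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("p_in", "p_noise", "overlap_fraction", "holdout_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.size_range
        if lo < 3 or hi < lo:
            raise ValueError("size_range must satisfy 3 <= min <= max")
        if self.n_complexes < 1:
            raise ValueError("need at least one complex")


@dataclass
class SyntheticTruth:
    """Everything the generator knows: network, truth, records, aliases, gold."""

    network: PPINetwork
    complexes: ComplexSet
    literature: list[LiteraturePPI]
    aliases: AliasTable
    gold: ComplexSet
    true_pairs: set[tuple[str, str]]
    heldout_pairs: set[tuple[str, str]]

    def write(self, outdir: str | Path) -> None:
        """Write network.tsv, literature.tsv, aliases.tsv and gold.tsv."""
        from .literature import write_literature
        from .network import write_network

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_network(self.network, outdir / "network.tsv")
        write_literature(self.literature, outdir / "literature.tsv")
        self.aliases.write(outdir / "aliases.tsv")
        self.gold.write(outdir / "gold.tsv")


def _systematic_name(i: int) -> str:
    """Synthetic systematic-style ORF id (Y-prefixed, like yeast nomenclature)."""
    return f"Y{i:04d}{'C' if i % 2 else 'W'}"


def _common_name(i: int) -> str:
    return f"gene{i}"


def generate(config: SyntheticConfig) -> SyntheticTruth:
    """Draw one planted-complex benchmark instance.

    Deterministic given ``config.seed``.  Raises on infeasible configurations
    (e.g. a size range that cannot be satisfied).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_complexes)

    # assign proteins: fresh ids per complex, then swap in members of earlier
    # complexes for the overlapping share
    next_id = 0
    complex_members: list[set[int]] = []
    for k, size in enumerate(sizes):
        members = set(range(next_id, next_id + int(size)))
        next_id += int(size)
        complex_members.append(members)
    overlapping = [
        k for k in range(1, config.n_complexes)
        if rng.random() < config.overlap_fraction
    ]
    for k in overlapping:
        donor = int(rng.integers(0, k))
        n_shared = int(rng.integers(1, 3))  # share one or two proteins
        donor_pool = sorted(complex_members[donor] - complex_members[k])
        own = sorted(complex_members[k])
        for shared in rng.choice(donor_pool, size=min(n_shared, len(donor_pool)), replace=False):
            if len(own) <= 3:
                break
            drop = own.pop(int(rng.integers(0, len(own))))
            complex_members[k].discard(drop)
            complex_members[k].add(int(shared))

    ids = sorted(set().union(*complex_members))
    names = {i: _systematic_name(i) for i in ids}

    # true intra-complex pairs, each realized with probability p_in
    candidate_true: set[tuple[int, int]] = set()
    for members in complex_members:
        ms = sorted(members)
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                candidate_true.add((ms[i], ms[j]))
    true_pairs = {p for p in sorted(candidate_true) if rng.random() < config.p_in}

    # background noise among all remaining pairs
    noise_pairs: set[tuple[int, int]] = set()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            pair = (ids[i], ids[j])
            if pair not in candidate_true and rng.random() < config.p_noise:
                noise_pairs.add(pair)

    # withhold part of the true edges as literature records
    true_sorted = sorted(true_pairs)
    n_holdout = int(round(config.holdout_fraction * len(true_sorted)))
    holdout_idx = set(
        rng.choice(len(true_sorted), size=n_holdout, replace=False).tolist()
    ) if n_holdout else set()
    heldout = {true_sorted[i] for i in holdout_idx}
    kept_true = true_pairs - heldout

    def weight_for(base: float) -> float:
        return float(np.clip(base + rng.normal(0.0, config.weight_noise_sd), 0.0, 1.0))

    edges = []
    for a, b in sorted(kept_true):
        if config.weighted:
            edges.append((names[a], names[b], weight_for(config.weight_base_true)))
        else:
            edges.append((names[a], names[b]))
    for a, b in sorted(noise_pairs):
        if config.weighted:
            edges.append((names[a], names[b], weight_for(config.weight_base_noise)))
        else:
            edges.append((names[a], names[b]))
    network = PPINetwork.from_edges(
        edges, weighted=config.weighted, proteins=[names[i] for i in ids]
    )

    # literature stream: held-out true edges plus spurious pairs, under common names
    sm = config.score_model
    aliases = AliasTable({_common_name(i): names[i] for i in ids})
    literature: list[LiteraturePPI] = []
    for a, b in sorted(heldout):
        score = float(rng.normal(sm.true_mean, sm.true_sd))
        literature.append(LiteraturePPI(_common_name(a), _common_name(b), score))
    n_ids = len(ids)
    attempts = 0
    false_pairs: set[tuple[int, int]] = set()
    while len(false_pairs) < config.n_false_lit and attempts < 50 * config.n_false_lit:
        attempts += 1
        i, j = rng.integers(0, n_ids, size=2)
        a, b = ids[int(min(i, j))], ids[int(max(i, j))]
        if a == b:
            continue
        pair = (a, b)
        if pair in candidate_true or pair in false_pairs:
            continue
        false_pairs.add(pair)
    for a, b in sorted(false_pairs):
        score = float(rng.normal(sm.false_mean, sm.false_sd))
        literature.append(LiteraturePPI(_common_name(a), _common_name(b), score))

    complexes = ComplexSet(
        (f"planted{k + 1}", frozenset(names[i] for i in members))
        for k, members in enumerate(complex_members)
    )
    named_true = {(names[a], names[b]) for a, b in true_pairs}
    named_held = {(names[a], names[b]) for a, b in heldout}
    return SyntheticTruth(
        network=network,
        complexes=complexes,
        literature=literature,
        aliases=aliases,
        gold=complexes,
        true_pairs=named_true,
        heldout_pairs=named_held,
    )


def perturb_gold(complexes: ComplexSet, drop_fraction: float, seed: int) -> ComplexSet:
    """Thin a gold standard by dropping a random fraction of its complexes.

    Emulates the incompleteness of curated catalogs.  Deterministic per seed;
    ``drop_fraction`` must lie in [0, 1).
    """
    if not (0.0 <= drop_fraction < 1.0):
        raise ValueError("drop_fraction must lie in [0, 1)")
    n = len(complexes)
    n_drop = int(round(drop_fraction * n))
    if n_drop == 0:
        return ComplexSet(iter(complexes))
    rng = np.random.default_rng(seed)
    drop = set(rng.choice(n, size=n_drop, replace=False).tolist())
    return ComplexSet(
        (cid, members) for k, (cid, members) in enumerate(complexes) if k not in drop
    )
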