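"""Integration of literature-extracted PPIs into experimental PPI networks.

Text-mining systems emit candidate interactions as pairs of protein names with
a real-valued confidence score.  Before such records can supplement an
experimental network they are (i) normalized to systematic ORF names through
an alias table, (ii) gated by a confidence threshold, and (iii) added only
when both endpoints already occur in the target network — the network's
protein universe is never extended.  On weighted networks the literature
scores, which live on the extractor's own scale, are rescaled onto the range
of the native edge weights so the merged network stays comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .network import PPINetwork, canonical_pair

logger = logging.getLogger(__name__)

__all__ = [
    "LiteraturePPI",
    "AliasTable",
    "IntegrationReport",
    "read_literature",
    "normalize_names",
    "filter_by_threshold",
    "rescale_weights",
    "integrate",
    "sweep_counts",
]


@dataclass(frozen=True)
class LiteraturePPI:
    """A candidate interaction extracted from text: two names and a confidence score."""

    name_a: str
    name_b: str
    score: float

    def __post_init__(self):
        if not self.name_a or not self.name_b:
            raise ValueError("protein names must be non-empty")
        if not (self.score == self.score and abs(self.score) != float("inf")):
            raise ValueError("score must be finite")

    @property
    def pair(self) -> tuple[str, str]:
        return canonical_pair(self.name_a, self.name_b)


class AliasTable:
    """Case-insensitive mapping from common protein names to systematic IDs.

    Lookup trims surrounding whitespace and ignores case; each alias maps to
    exactly one systematic name (later duplicate aliases are rejected unless
    they agree).
    """

    def __init__(self, mapping: dict[str, str] | None = None):
        self._map: dict[str, str] = {}
        for alias, target in (mapping or {}).items():
            self.add(alias, target)

    @staticmethod
    def _key(alias: str) -> str:
        return alias.strip().lower()

    def add(self, alias: str, systematic: str) -> None:
        key = self._key(alias)
        if not key:
            raise ValueError("alias must be non-empty")
        existing = self._map.get(key)
        if existing is not None and existing != systematic:
            raise ValueError(f"alias {alias!r} maps to both {existing} and {systematic}")
        self._map[key] = systematic

    def get(self, name: str) -> str | None:
        return self._map.get(self._key(name))

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, name: str) -> bool:
        return self._key(name) in self._map

    @classmethod
    def read(cls, path: str | Path) -> "AliasTable":
        """Read a two-column TSV ``alias<TAB>systematic_name``."""
        table = cls()
        with Path(path).open() as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                table.add(fields[0].strip(), fields[1].strip())
        return table

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for alias in sorted(self._map):
                fh.write(f"{alias}\t{self._map[alias]}\n")


@dataclass
class IntegrationReport:
    """Bookkeeping for one integration pass at a fixed confidence threshold.

    ``n_candidates`` counts the input records, ``n_normalized`` the records
    surviving the threshold gate (the candidates actually considered for
    addition); the remaining counters partition those into added edges,
    records with an endpoint missing from the network, and records whose pair
    the network already contains.
    """

    threshold: float
    n_candidates: int = 0
    n_normalized: int = 0
    n_added: int = 0
    n_skipped_unknown_protein: int = 0
    n_skipped_duplicate: int = 0

    def __post_init__(self):
        counts = (
            self.n_candidates,
            self.n_normalized,
            self.n_added,
            self.n_skipped_unknown_protein,
            self.n_skipped_duplicate,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.n_added + self.n_skipped_unknown_protein + self.n_skipped_duplicate > self.n_candidates:
            raise ValueError("outcome counts exceed candidate count")


def read_literature(path: str | Path) -> list[LiteraturePPI]:
    """Read literature records from a TSV ``name_a<TAB>name_b<TAB>score``."""
    records = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            try:
                score = float(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: score {fields[2]!r} is not a number") from None
            records.append(LiteraturePPI(fields[0].strip(), fields[1].strip(), score))
    return records


def write_literature(records: Iterable[LiteraturePPI], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(f"{rec.name_a}\t{rec.name_b}\t{rec.score:g}\n")


def normalize_names(
    records: Sequence[LiteraturePPI], aliases: AliasTable
) -> list[LiteraturePPI]:
    """Map both protein names of each record through the alias table.

    A name found in the table (case-insensitively, after trimming) is replaced
    by its systematic target; an unknown name is left unchanged and counted —
    the endpoint-exists rule at integration time is the actual gate.
    """
    out = []
    n_unmatched = 0
    for rec in records:
        a = aliases.get(rec.name_a)
        b = aliases.get(rec.name_b)
        if a is None:
            n_unmatched += 1
            a = rec.name_a
        if b is None:
            n_unmatched += 1
            b = rec.name_b
        out.append(replace(rec, name_a=a, name_b=b))
    if n_unmatched:
        logger.info("normalize_names: %d names had no alias entry and were kept as-is", n_unmatched)
    return out


def filter_by_threshold(
    records: Sequence[LiteraturePPI], threshold: float
) -> list[LiteraturePPI]:
    """Keep records whose confidence is greater than or equal to the threshold.

    The comparison is inclusive and the input order is preserved.
    """
    return [rec for rec in records if rec.score >= threshold]


def rescale_weights(
    records: Sequence[LiteraturePPI],
    net: PPINetwork,
    strategy: str = "minmax",
) -> list[LiteraturePPI]:
    """Map literature confidence scores onto the network's native weight scale.

    strategy:
      * ``minmax`` — affine map sending [min record score, max record score]
        onto [min edge weight, max edge weight]; order-preserving.  If all
        record scores coincide the records get the network's mean edge weight.
      * ``mean``   — every record gets the mean native edge weight.
      * ``none``   — scores pass through unchanged.

    Raises
    ------
    ValueError
        If the network is unweighted or has no edges (no target scale exists).
    """
    if strategy == "none":
        return list(records)
    if not net.weighted:
        raise ValueError("rescale_weights requires a weighted network")
    if net.n_edges == 0:
        raise ValueError("rescale_weights requires a network with at least one edge")
    if not records:
        return []
    weights = [w for _, _, w in net.edges()]
    w_lo, w_hi = min(weights), max(weights)
    w_mean = sum(weights) / len(weights)
    if strategy == "mean":
        return [replace(r, score=w_mean) for r in records]
    if strategy != "minmax":
        raise ValueError(f"unknown rescaling strategy {strategy!r}")
    s_lo = min(r.score for r in records)
    s_hi = max(r.score for r in records)
    if s_hi == s_lo:
        return [replace(r, score=w_mean) for r in records]
    slope = (w_hi - w_lo) / (s_hi - s_lo)
    return [replace(r, score=w_lo + (r.score - s_lo) * slope) for r in records]


def integrate(
    net: PPINetwork,
    records: Sequence[LiteraturePPI],
    threshold: float,
    rescale: str = "minmax",
) -> tuple[PPINetwork, IntegrationReport]:
    """Add above-threshold literature PPIs to a network under the endpoint rule.

    Records are assumed already normalized to systematic names.  The pipeline:
    threshold gate (score >= threshold) -> drop records with either endpoint
    absent from the network -> drop records whose unordered pair the network
    already contains (the native edge and weight are kept, never overwritten)
    -> on weighted networks, rescale the surviving scores onto the native
    weight range and attach them as edge weights; on unweighted networks the
    scores are discarded -> add the edges.  No proteins are ever added.

    Returns the merged network (the input is untouched) and an
    :class:`IntegrationReport`.
    """
    report = IntegrationReport(threshold=threshold, n_candidates=len(records))
    kept = filter_by_threshold(records, threshold)
    report.n_normalized = len(kept)

    merged = net.copy()
    survivors: list[LiteraturePPI] = []
    seen_pairs: set[tuple[str, str]] = set()
    for rec in kept:
        a, b = rec.pair
        if a == b or a not in merged.proteins or b not in merged.proteins:
            report.n_skipped_unknown_protein += 1
            continue
        if merged.graph.has_edge(a, b) or (a, b) in seen_pairs:
            report.n_skipped_duplicate += 1
            continue
        seen_pairs.add((a, b))
        survivors.append(rec)

    if net.weighted and survivors:
        survivors = rescale_weights(survivors, net, strategy=rescale)
    for rec in survivors:
        a, b = rec.pair
        if net.weighted:
            merged.graph.add_edge(a, b, weight=float(rec.score))
        else:
            merged.graph.add_edge(a, b)
        report.n_added += 1
    logger.info(
        "integrate(threshold=%.3g): %d candidates, %d passed threshold, %d added, "
        "%d unknown-endpoint, %d duplicate",
        threshold,
        report.n_candidates,
        report.n_normalized,
        report.n_added,
        report.n_skipped_unknown_protein,
        report.n_skipped_duplicate,
    )
    return merged, report


def sweep_counts(
    net: PPINetwork,
    records: Sequence[LiteraturePPI],
    thresholds: Sequence[float],
    rescale: str = "minmax",
) -> list[IntegrationReport]:
    """One integration report per threshold, each restarted from the original network."""
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    return [integrate(net, records, t, rescale=rescale)[1] for t in thresholds]
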