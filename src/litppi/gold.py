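"""Reference complex catalogs: MIPS-style category filtering and GO-derived complexes.

Two kinds of gold standards are supported.  A MIPS-style catalog assigns
proteins to dotted hierarchical category codes (``510.190.10``); categories
with 3–100 members are taken as complexes, excluding category 550 and its
descendants (computationally predicted, unconfirmed complexes).  A GO-derived
standard takes every descendant term of the ``protein complex`` term
(GO:0043234) and collects the proteins annotated to it, ignoring annotations
carrying a ``NOT`` or ``colocalizes_with`` qualifier and protein–term pairs
whose only supporting evidence is the computational IEA code.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

from .complexes import ComplexSet

logger = logging.getLogger(__name__)

__all__ = [
    "CatalogEntry",
    "GoAnnotation",
    "GoldStandardSummary",
    "read_catalog",
    "read_annotations",
    "load_ontology",
    "go_descendants",
    "filter_mips",
    "filter_sgd",
    "summarize",
]

PROTEIN_COMPLEX_ROOT = "GO:0043234"
_GO_RE = re.compile(r"GO:\d{7}$")
_EXCLUDED_QUALIFIERS = {"not", "colocalizes_with"}


@dataclass(frozen=True)
class CatalogEntry:
    """One MIPS-style catalog category and its member proteins."""

    category_code: str
    members: frozenset[str]

    def __post_init__(self):
        parts = self.category_code.split(".")
        if not all(parts):
            raise ValueError(f"malformed category code {self.category_code!r}")


@dataclass(frozen=True)
class GoAnnotation:
    """One GO annotation row: protein, term, optional qualifier, evidence code."""

    protein: str
    term: str
    qualifier: str = ""
    evidence: str = ""

    def __post_init__(self):
        if not _GO_RE.match(self.term):
            raise ValueError(f"term {self.term!r} does not match GO:NNNNNNN")


@dataclass(frozen=True)
class GoldStandardSummary:
    """Catalog-level size statistics (count, max/min/mean complex size)."""

    n_complexes: int
    max_size: int
    min_size: int
    mean_size: float


def read_catalog(path: str | Path) -> list[CatalogEntry]:
    """Read a membership TSV ``category_code<TAB>protein_id``, one row per membership."""
    members: dict[str, set[str]] = defaultdict(set)
    order: list[str] = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            code, protein = fields[0].strip(), fields[1].strip()
            if code not in members:
                order.append(code)
            members[code].add(protein)
    return [CatalogEntry(code, frozenset(members[code])) for code in order]


def read_annotations(path: str | Path) -> list[GoAnnotation]:
    """Read a GAF-inspired TSV ``protein<TAB>GO id<TAB>qualifier<TAB>evidence``."""
    out = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            out.append(
                GoAnnotation(
                    protein=fields[0].strip(),
                    term=fields[1].strip(),
                    qualifier=fields[2].strip(),
                    evidence=fields[3].strip(),
                )
            )
    return out


def load_ontology(path: str | Path) -> dict[str, set[str]]:
    """Load a term hierarchy as a child -> parents mapping.

    Accepts either an OBO file (``.obo``; only ``id``, ``is_a`` and
    ``relationship: part_of`` fields are used — full OBO semantics are out of
    proportion to the filtering rule) or a two-column TSV ``child<TAB>parent``.
    """
    path = Path(path)
    parents: dict[str, set[str]] = defaultdict(set)
    if path.suffix.lower() == ".obo":
        import obonet

        graph = obonet.read_obo(path)
        # obonet edges point child -> parent for is_a and relationship edges
        for child, parent, key in graph.edges(keys=True):
            if key in ("is_a", "part_of"):
                parents[child].add(parent)
        for node in graph.nodes:
            parents.setdefault(node, set())
    else:
        with path.open() as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                child, parent = fields[0].strip(), fields[1].strip()
                parents[child].add(parent)
                parents.setdefault(parent, set())
    return dict(parents)


def go_descendants(parents: dict[str, set[str]], root: str) -> set[str]:
    """All terms reachable to ``root`` via is_a/part_of, excluding the root itself."""
    if root not in parents and not any(root in ps for ps in parents.values()):
        raise KeyError(f"root term {root!r} not present in ontology")
    children: dict[str, set[str]] = defaultdict(set)
    for child, ps in parents.items():
        for p in ps:
            children[p].add(child)
    out: set[str] = set()
    stack = [root]
    while stack:
        term = stack.pop()
        for child in children.get(term, ()):
            if child not in out:
                out.add(child)
                stack.append(child)
    return out


def _is_excluded_category(code: str, excluded_root: str = "550") -> bool:
    """Component-wise dotted-prefix test: '550' and '550.*' hit, '5500' does not."""
    parts = code.split(".")
    root_parts = excluded_root.split(".")
    return parts[: len(root_parts)] == root_parts


def filter_mips(
    catalog: list[CatalogEntry],
    min_size: int = 3,
    max_size: int = 100,
    excluded_category: str = "550",
) -> ComplexSet:
    """Apply the MIPS gold-standard filters and return the surviving complexes.

    Keeps categories with ``min_size <= |members| <= max_size`` (both bounds
    inclusive) whose code is neither the excluded category nor one of its
    dotted descendants.
    """
    kept = [
        (entry.category_code, entry.members)
        for entry in catalog
        if min_size <= len(entry.members) <= max_size
        and not _is_excluded_category(entry.category_code, excluded_category)
    ]
    logger.info("filter_mips: kept %d of %d categories", len(kept), len(catalog))
    return ComplexSet(kept)


def filter_sgd(
    annotations: list[GoAnnotation],
    ontology: dict[str, set[str]],
    root: str = PROTEIN_COMPLEX_ROOT,
    closure: bool = False,
) -> ComplexSet:
    """Derive one reference complex per descendant term of the protein-complex root.

    Annotation rows with a ``NOT`` or ``colocalizes_with`` qualifier are
    dropped first.  A protein–term pair supported only by IEA evidence is
    dropped; a pair with IEA plus any other code survives.  Each descendant
    term of ``root`` (the root itself excluded) yields a complex containing
    its annotated proteins; with ``closure=True`` the proteins of a term's own
    descendants are folded in as well.  Terms left without members are
    omitted.  No minimum-size gate is applied — GO-derived complexes may be
    singletons.
    """
    descendants = go_descendants(ontology, root)

    evidence: dict[tuple[str, str], set[str]] = defaultdict(set)
    for ann in annotations:
        if ann.qualifier.strip().lower() in _EXCLUDED_QUALIFIERS:
            continue
        evidence[(ann.protein, ann.term)].add(ann.evidence.strip().upper())

    term_members: dict[str, set[str]] = defaultdict(set)
    for (protein, term), codes in evidence.items():
        if codes and codes != {"IEA"}:
            term_members[term].add(protein)

    complexes = []
    for term in sorted(descendants):
        members = set(term_members.get(term, ()))
        if closure:
            for sub in go_descendants(ontology, term):
                members |= term_members.get(sub, set())
        if members:
            complexes.append((term, frozenset(members)))
    logger.info("filter_sgd: %d complexes from %d descendant terms", len(complexes), len(descendants))
    return ComplexSet(complexes)


def summarize(gold: ComplexSet) -> GoldStandardSummary:
    """Count complexes and report max/min/mean size (mean to one decimal)."""
    if len(gold) == 0:
        raise ValueError("cannot summarize an empty gold standard")
    sizes = gold.sizes()
    return GoldStandardSummary(
        n_complexes=len(sizes),
        max_size=max(sizes),
        min_size=min(sizes),
        mean_size=round(sum(sizes) / len(sizes), 1),
    )
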