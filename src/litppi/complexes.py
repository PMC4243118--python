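"""Collections of protein complexes, used for predictions and gold standards."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator


class ComplexSet:
    """An ordered collection of uniquely-identified protein sets.

    The same protein may belong to many complexes (both predicted complexes
    and GO-derived reference complexes overlap); member sets are non-empty
    and ids unique.
    """

    def __init__(self, complexes: Iterable[tuple[str, Iterable[str]]] = ()):
        self._ids: list[str] = []
        self._members: list[frozenset[str]] = []
        seen = set()
        for cid, members in complexes:
            members = frozenset(members)
            if not members:
                raise ValueError(f"complex {cid!r} has no members")
            if cid in seen:
                raise ValueError(f"duplicate complex id {cid!r}")
            seen.add(cid)
            self._ids.append(cid)
            self._members.append(members)

    @classmethod
    def from_sets(cls, sets: Iterable[Iterable[str]], prefix: str = "C") -> "ComplexSet":
        """Wrap bare member sets, assigning ids ``C1, C2, ...``."""
        return cls((f"{prefix}{i}", s) for i, s in enumerate(sets, start=1))

    @property
    def ids(self) -> list[str]:
        return list(self._ids)

    @property
    def members(self) -> list[frozenset[str]]:
        return list(self._members)

    def sizes(self) -> list[int]:
        return [len(m) for m in self._members]

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for m in self._members:
            out |= m
        return out

    def __len__(self) -> int:
        return len(self._ids)

    def __iter__(self) -> Iterator[tuple[str, frozenset[str]]]:
        return iter(zip(self._ids, self._members))

    def __getitem__(self, i: int) -> tuple[str, frozenset[str]]:
        return self._ids[i], self._members[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ComplexSet):
            return NotImplemented
        return set(self._members) == set(other._members)

    def __repr__(self) -> str:
        return f"<ComplexSet: {len(self)} complexes>"

    # -- I/O: the common "cluster file" convention, one complex per line ------

    @classmethod
    def read(cls, path: str | Path) -> "ComplexSet":
        """Read a cluster file: one complex per line, tab-separated members."""
        sets = []
        with Path(path).open() as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                members = [tok for tok in line.split("\t") if tok.strip()]
                sets.append(members)
        return cls.from_sets(sets)

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for members in self._members:
                fh.write("\t".join(sorted(members)) + "\n")
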