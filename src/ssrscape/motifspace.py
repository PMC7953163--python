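"""Canonical microsatellite motif classes.

A microsatellite repeat unit of length 1-6 bp is *primitive* when it is not
itself an exact repetition of a shorter unit (``ACAC`` is two copies of
``AC`` and therefore excluded).  Because tandem arrays can be read starting
at any phase and on either strand, primitive units related by circular
rotation and/or reverse complementation describe the same repeat locus.
Grouping the 5356 primitive 1-6 bp units under that equivalence yields 501
canonical *standard motif classes*; each class is named by its
lexicographically smallest member (A < C < G < T), which matches the usual
``(AC)n`` / ``(AAT)n`` notation used in comparative repeat studies.

The full class table is tiny (5460 strings) and is built once on first use
rather than shipped as a data file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Iterator

MAX_UNIT = 6
ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class MotifError(ValueError):
    """Raised for motifs outside the supported 1-6 bp ACGT space."""


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate(motif: str) -> None:
    if not motif or len(motif) > MAX_UNIT:
        raise MotifError(
            f"motif {motif!r} has length {len(motif)}; expected 1-{MAX_UNIT}"
        )
    if any(c not in ALPHABET for c in motif):
        raise MotifError(f"motif {motif!r} contains characters outside ACGT")


def is_primitive(motif: str) -> bool:
    """True if *motif* is not k >= 2 exact copies of a shorter unit.

    >>> is_primitive("AAT")
    True
    >>> is_primitive("ACAC")
    False
    """
    _validate(motif)
    n = len(motif)
    return not any(n % d == 0 and motif == motif[:d] * (n // d) for d in range(1, n))


def primitive_root(motif: str) -> str:
    """Shortest unit whose exact repetition equals *motif* (the motif itself
    when primitive).  Helper for scanners that may probe non-primitive units."""
    _validate(motif)
    n = len(motif)
    for d in range(1, n + 1):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return motif[:d]
    raise AssertionError("unreachable")


def _closure(motif: str) -> frozenset[str]:
    """All rotations of motif and of its reverse complement."""
    members = set()
    for s in (motif, revcomp(motif)):
        for r in range(len(s)):
            members.add(s[r:] + s[:r])
    return frozenset(members)


@lru_cache(maxsize=None)
def canonical_class(motif: str) -> str:
    """Canonical representative of *motif*'s class: the lexicographically
    smallest string among all rotations of the motif and of its reverse
    complement.  Idempotent; identical for every member of a class.

    >>> canonical_class("GT")
    'AC'
    >>> canonical_class("T")
    'A'
    """
    _validate(motif)
    if not is_primitive(motif):
        raise MotifError(
            f"motif {motif!r} is not primitive; reduce it with primitive_root() "
            "or screen with is_primitive()"
        )
    return min(_closure(motif))


@dataclass(frozen=True)
class MotifClass:
    """One canonical equivalence class of primitive repeat units."""

    representative: str
    members: frozenset[str] = field(repr=False)

    @property
    def unit_length(self) -> int:
        return len(self.representative)


@lru_cache(maxsize=1)
def enumerate_motif_space() -> tuple[MotifClass, ...]:
    """Enumerate all canonical classes of primitive 1-6 bp motifs.

    Exhausts the 5460 ACGT strings of length 1-6, keeps the 5356 primitive
    ones, and partitions them into 501 classes.  Returned sorted by
    (unit_length, representative); the tuple is cached.
    """
    by_rep: dict[str, frozenset[str]] = {}
    for k in range(1, MAX_UNIT + 1):
        for tup in product(ALPHABET, repeat=k):
            motif = "".join(tup)
            if not is_primitive(motif):
                continue
            members = _closure(motif)
            by_rep.setdefault(min(members), members)
    classes = [MotifClass(rep, mem) for rep, mem in by_rep.items()]
    classes.sort(key=lambda c: (c.unit_length, c.representative))
    return tuple(classes)


@lru_cache(maxsize=1)
def _rep_index() -> dict[str, MotifClass]:
    return {c.representative: c for c in enumerate_motif_space()}


def class_members(representative: str) -> frozenset[str]:
    """All primitive motifs belonging to the class named *representative*.

    >>> sorted(class_members("A"))
    ['A', 'T']
    """
    try:
        return _rep_index()[representative].members
    except KeyError:
        raise KeyError(
            f"{representative!r} is not a canonical class representative"
        ) from None


def class_order() -> list[str]:
    """Fixed column order used throughout: unit_length, then representative."""
    return [c.representative for c in enumerate_motif_space()]


def iter_export_rows() -> Iterator[tuple[str, int, str, int]]:
    """Rows (representative, unit_length, members comma-joined, n_members)
    in deterministic order, for the TSV export."""
    for c in enumerate_motif_space():
        yield c.representative, c.unit_length, ",".join(sorted(c.members)), len(c.members)


def export_tsv(path) -> None:
    """Write the class table to *path* as TSV."""
    with open(path, "w") as fh:
        fh.write("representative\tunit_length\tmembers\tn_members\n")
        for rep, k, members, n in iter_export_rows():
            fh.write(f"{rep}\t{k}\t{members}\t{n}\n")
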