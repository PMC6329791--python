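"""Degenerate (IUPAC) recognition-motif algebra.

A methylated motif is a short IUPAC pattern with one designated methylated
base — e.g. ``GANTC`` methylated at the A (written ``GmANTC`` in files and
``G(m6A)NTC`` in reports).  This module implements the set
algebra the methylome pipeline needs: degenerate matching on both strands,
reverse complementation, position-wise compatibility, merging of
complementary (double-strand) motif pairs and of near-duplicate motifs, and
novelty assessment against a reference table of known recognition sequences.

Coordinates are 0-based half-open throughout; occurrence positions are
forward-strand coordinates of the pattern start on either strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import networkx as nx

__all__ = [
    "IUPAC",
    "IupacMotif",
    "MotifGroup",
    "expand",
    "iupac_code",
    "reverse_complement",
    "occurrences",
    "positionwise_intersection",
    "rc_compatible",
    "similarity_mergeable",
    "dedupe_and_group",
]

#: IUPAC degenerate nucleotide codes.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC.items()}

_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "S": "S", "W": "W", "N": "N",
}

MOD_TYPES = ("m6A", "m4C", "m5C", "unknown")


def expand(code: str) -> frozenset[str]:
    """Base set denoted by one IUPAC code (e.g. W -> {A, T})."""
    try:
        return IUPAC[code]
    except KeyError:
        raise ValueError(f"invalid IUPAC code: {code!r}") from None


def iupac_code(bases: Iterable[str]) -> str:
    """Minimal IUPAC code for a non-empty base set (inverse of expand)."""
    key = frozenset(bases)
    try:
        return _SET_TO_CODE[key]
    except KeyError:
        raise ValueError(f"no IUPAC code for base set {sorted(key)}") from None


@dataclass(frozen=True, order=True)
class IupacMotif:
    """A degenerate recognition sequence with one methylated position.

    Parameters
    ----------
    pattern : str
        IUPAC string, e.g. ``"GAANNNNTTC"``.
    meth_offset : int
        0-based index into *pattern* of the methylated base.
    mod_type : str
        One of ``m6A``, ``m4C``, ``m5C``, ``unknown``.
    """

    pattern: str
    meth_offset: int
    mod_type: str = "unknown"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        for c in self.pattern:
            if c not in IUPAC:
                raise ValueError(f"invalid IUPAC code {c!r} in {self.pattern!r}")
        if not 0 <= self.meth_offset < len(self.pattern):
            raise ValueError(
                f"meth_offset {self.meth_offset} out of range for {self.pattern!r}"
            )
        if self.mod_type not in MOD_TYPES:
            raise ValueError(f"invalid mod_type {self.mod_type!r}")
        # the methylated position must hold the modifiable base, or its
        # complement when the motif describes the site from the opposite
        # strand (as reverse_complement produces)
        base = expand(self.pattern[self.meth_offset])
        if self.mod_type == "m6A" and not base & {"A", "T"}:
            raise ValueError(f"m6A motif {self.pattern!r} lacks A at offset {self.meth_offset}")
        if self.mod_type in ("m4C", "m5C") and not base & {"C", "G"}:
            raise ValueError(
                f"{self.mod_type} motif {self.pattern!r} lacks C at offset {self.meth_offset}"
            )

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def meth_base(self) -> str:
        return self.pattern[self.meth_offset]

    def is_palindromic(self) -> bool:
        """True if the pattern equals its own reverse complement."""
        return rc_pattern(self.pattern) == self.pattern

    def __str__(self) -> str:  # GANTC@1(m6A)
        return f"{self.pattern}@{self.meth_offset}({self.mod_type})"


def rc_pattern(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern string."""
    return "".join(_COMPLEMENT[c] for c in reversed(pattern))


def reverse_complement(m: IupacMotif) -> IupacMotif:
    """Motif describing the same duplex site read from the opposite strand.

    The methylated offset maps to ``len - 1 - meth_offset``; the modification
    type is preserved.  This operation is an involution.
    """
    return IupacMotif(rc_pattern(m.pattern), len(m.pattern) - 1 - m.meth_offset, m.mod_type)


def _pattern_regex(pattern: str) -> re.Pattern[str]:
    # lookahead makes overlapping matches visible
    body = "".join(
        c if len(IUPAC[c]) == 1 else "[" + "".join(sorted(IUPAC[c])) + "]"
        for c in pattern
    )
    return re.compile(rf"(?=({body}))")


def occurrences(m: IupacMotif, seq: str) -> list[tuple[int, str]]:
    """All strand-specific matches of a motif in a nucleotide sequence.

    Returns ``(position, strand)`` pairs where *position* is the 0-based
    forward-strand coordinate of the pattern start: for ``-`` entries it is
    the start of the reverse-complement pattern on the forward strand.  Both
    strands are counted separately, so a palindromic motif yields two entries
    per duplex site.  Non-ACGT characters in *seq* never match.
    """
    seq = seq.upper()
    hits: list[tuple[int, str]] = []
    for match in _pattern_regex(m.pattern).finditer(seq):
        hits.append((match.start(), "+"))
    rc = rc_pattern(m.pattern)
    for match in _pattern_regex(rc).finditer(seq):
        hits.append((match.start(), "-"))
    hits.sort()
    return hits


def methylated_position(m: IupacMotif, pos: int, strand: str) -> int:
    """Forward-strand coordinate of the methylated base for one occurrence."""
    if strand == "+":
        return pos + m.meth_offset
    return pos + len(m.pattern) - 1 - m.meth_offset


@dataclass(frozen=True)
class AlignedColumn:
    """One column of a pairwise motif alignment.

    ``i1``/``i2`` are pattern indices (None marks an overhang on that side);
    ``bases`` is the intersection of the two expanded codes, or None for
    overhang columns.
    """

    i1: Optional[int]
    i2: Optional[int]
    bases: Optional[frozenset[str]]

    @property
    def is_overhang(self) -> bool:
        return self.i1 is None or self.i2 is None

    @property
    def is_conflict(self) -> bool:
        return self.bases is not None and len(self.bases) == 0


def positionwise_intersection(m1: IupacMotif, m2: IupacMotif) -> list[AlignedColumn]:
    """Per-position base-set intersections with the methylated bases aligned.

    The two patterns are shifted so that their methylated offsets coincide;
    positions present in only one pattern are returned as overhang columns.
    """
    shift = m1.meth_offset - m2.meth_offset  # i1 = i2 + shift
    lo = min(0, shift)
    hi = max(len(m1.pattern), len(m2.pattern) + shift)
    cols: list[AlignedColumn] = []
    for i1 in range(lo, hi):
        i2 = i1 - shift
        in1 = 0 <= i1 < len(m1.pattern)
        in2 = 0 <= i2 < len(m2.pattern)
        if in1 and in2:
            cols.append(
                AlignedColumn(i1, i2, expand(m1.pattern[i1]) & expand(m2.pattern[i2]))
            )
        elif in1:
            cols.append(AlignedColumn(i1, None, None))
        elif in2:
            cols.append(AlignedColumn(None, i2, None))
    return cols


def _mod_class(mod_type: str) -> str:
    # m4C and m5C are both cytosine modifications; a duplex pair must agree
    # at this level only.
    return "A" if mod_type == "m6A" else "C" if mod_type in ("m4C", "m5C") else "?"


def rc_compatible(m1: IupacMotif, m2: IupacMotif, max_len_diff: int = 1) -> bool:
    """True if the two motifs can describe the two strands of one duplex site.

    The reverse complement of *m1* is slid over *m2* with the shorter pattern
    fully contained in the longer (equal lengths: start-aligned); the pair is
    compatible if some placement has a non-empty base-set intersection at
    every overlapping position and the modification types are both adenine or
    both cytosine modifications.  The footprints must agree to within
    ``max_len_diff`` bases — duplex partners describe the same site, and
    without this cap any short motif slides compatibly into another motif's
    N spacer.
    """
    if _mod_class(m1.mod_type) != _mod_class(m2.mod_type):
        return False
    if abs(len(m1.pattern) - len(m2.pattern)) > max_len_diff:
        return False
    p1, p2 = rc_pattern(m1.pattern), m2.pattern
    if len(p1) > len(p2):
        p1, p2 = p2, p1
    for off in range(len(p2) - len(p1) + 1):
        if all(expand(a) & expand(b) for a, b in zip(p1, p2[off : off + len(p1)])):
            return True
    return False


def similarity_mergeable(m1: IupacMotif, m2: IupacMotif, max_overhang: int = 1) -> bool:
    """True if the motifs look like incomplete detections of one motif.

    Requires identical modification type and, with the methylated bases
    aligned, at most one conflicting (empty-intersection) position and at
    most ``max_overhang`` unpaired end positions in total.  The overhang cap
    keeps the rule from linking motifs that barely overlap around their
    methylated base.
    """
    if m1.mod_type != m2.mod_type:
        return False
    cols = positionwise_intersection(m1, m2)
    if sum(c.is_overhang for c in cols) > max_overhang:
        return False
    return sum(c.is_conflict for c in cols) <= 1


@dataclass
class MotifGroup:
    """A deduplicated motif (or merged set of motifs) across genomes.

    ``kind`` is ``single``, ``rc_pair`` (two distinct patterns describing
    double-strand methylation of one duplex site) or ``similarity_cluster``.
    """

    members: list[tuple[str, IupacMotif]]
    kind: str
    reference_known: bool
    patterns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty motif group")
        if not self.patterns:
            self.patterns = sorted({m.pattern for _, m in self.members})


def dedupe_and_group(
    motifs: Sequence[tuple[str, IupacMotif]],
    reference: Iterable[IupacMotif] | Iterable[str] = (),
) -> tuple[list[MotifGroup], int, int]:
    """Deduplicate motifs across genomes and merge related novel motifs.

    1. Deduplicate by exact pattern string (``n_distinct`` unique patterns).
    2. Mark a distinct motif reference-known iff its pattern, or its reverse
       complement, exactly equals a reference pattern (degenerate subsumption
       does not confer known status).
    3. Among the unknown motifs, link reverse-complement-compatible pairs and
       at-most-one-conflict similar motifs; single-linkage connected
       components are the novel groups (``n_novel_groups``).

    Returns ``(groups, n_distinct, n_novel_groups)``; *groups* covers known
    motifs (one group each) and novel components, ordered by lexicographically
    smallest member pattern.
    """
    if not motifs:
        raise ValueError("dedupe_and_group: empty motif list")
    ref_patterns: set[str] = set()
    for r in reference:
        p = r.pattern if isinstance(r, IupacMotif) else str(r)
        ref_patterns.add(p)
        ref_patterns.add(rc_pattern(p))

    by_pattern: dict[str, list[tuple[str, IupacMotif]]] = {}
    for genome_id, m in motifs:
        by_pattern.setdefault(m.pattern, []).append((genome_id, m))
    n_distinct = len(by_pattern)
    # deterministic representative per pattern: smallest genome_id
    reps = {p: sorted(members)[0][1] for p, members in by_pattern.items()}

    known = {p for p in by_pattern if p in ref_patterns}
    novel = sorted(p for p in by_pattern if p not in known)

    graph = nx.Graph()
    graph.add_nodes_from(novel)
    for i, p1 in enumerate(novel):
        for p2 in novel[i + 1 :]:
            a, b = reps[p1], reps[p2]
            if rc_compatible(a, b) or similarity_mergeable(a, b):
                graph.add_edge(p1, p2)

    groups: list[MotifGroup] = []
    for p in sorted(known):
        groups.append(MotifGroup(members=sorted(by_pattern[p]), kind="single", reference_known=True))
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    for comp in components:
        patterns = sorted(comp)
        members = sorted(m for p in patterns for m in by_pattern[p])
        if len(patterns) == 1:
            kind = "single"
        elif len(patterns) == 2 and rc_compatible(reps[patterns[0]], reps[patterns[1]]):
            kind = "rc_pair"
        else:
            kind = "similarity_cluster"
        groups.append(MotifGroup(members=members, kind=kind, reference_known=False))
    groups.sort(key=lambda g: g.patterns[0])
    n_novel_groups = len(components)
    return groups, n_distinct, n_novel_groups
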