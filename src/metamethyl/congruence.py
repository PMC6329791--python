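"""MTase-motif congruence, RM-system detection, and orphan pairing.

Annotated methyltransferase (M) genes carry the recognition motif of their
closest database match.  A record is *congruent* when that motif equals a
motif actually detected in the same genome (up to reverse complement) with
agreeing modification type; otherwise *incongruent*.  M genes flanked by a
restriction-endonuclease (R) gene constitute candidate restriction-
modification (RM) systems; Type I systems may show a specificity-subunit
(S) gene instead, and some proteins fuse both activities in one chain.
Finally, incongruent MTases and detected-but-unexplained motifs of the same
genome are paired: a unique modification-type match is proposed directly,
and ties are broken by a neighbouring REase whose cleavage target equals
the motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .motifs import IupacMotif, rc_pattern

__all__ = [
    "MTaseRecord",
    "CongruenceCall",
    "congruence",
    "detect_rm_systems",
    "propose_orphans",
    "genome_congruence",
]

_ROLES = ("M", "R", "S")
_RM_TYPES = ("I", "II", "III", "unknown")


@dataclass(frozen=True)
class MTaseRecord:
    """One annotated gene of a restriction-modification neighbourhood.

    ``gene_index`` is the ordinal position of the gene along its contig;
    ``fused_re`` marks proteins with both MTase and REase activity.
    For R records, ``closest_match_motif`` holds the cleavage target.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    gene_index: int
    role: str
    rm_type: str = "unknown"
    closest_match_motif: Optional[IupacMotif] = None
    closest_mod_type: str = "unknown"
    fused_re: bool = False

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")
        if self.rm_type not in _RM_TYPES:
            raise ValueError(f"rm_type must be one of {_RM_TYPES}, got {self.rm_type!r}")


@dataclass
class CongruenceCall:
    """Outcome for one M record: congruent / incongruent / proposed / unresolved."""

    gene_id: str
    status: str
    matched_motif: Optional[IupacMotif] = None
    rm_system: bool = False

    def __post_init__(self) -> None:
        if self.status in ("congruent", "proposed") and self.matched_motif is None:
            raise ValueError(f"status {self.status} requires a matched motif")


def _patterns_equal_up_to_rc(p1: str, p2: str) -> bool:
    return p1 == p2 or rc_pattern(p1) == p2


def congruence(record: MTaseRecord, detected: Sequence[IupacMotif]) -> CongruenceCall:
    """Compare an M record's closest-match motif against detected motifs.

    Congruent iff the closest-match motif pattern equals a detected motif of
    the same genome up to reverse complement AND the modification types
    agree exactly (a nonspecific closest match never counts as congruent).
    A record with no usable closest-match motif is unresolved.
    """
    if record.role != "M":
        raise ValueError(f"congruence is defined for M records, got role {record.role!r}")
    if record.closest_match_motif is None and record.closest_mod_type != "nonspecific":
        return CongruenceCall(record.gene_id, "unresolved")
    if record.closest_mod_type == "nonspecific" or record.closest_match_motif is None:
        return CongruenceCall(record.gene_id, "incongruent")
    for d in detected:
        if (
            _patterns_equal_up_to_rc(record.closest_match_motif.pattern, d.pattern)
            and record.closest_mod_type == d.mod_type
        ):
            return CongruenceCall(record.gene_id, "congruent", matched_motif=d)
    return CongruenceCall(record.gene_id, "incongruent")


def detect_rm_systems(
    records: Sequence[MTaseRecord],
    window: int = 5,
) -> dict[str, bool]:
    """Flag M records that plausibly sit in an RM system.

    An M record is flagged iff (a) an R record lies within ``window`` gene
    indices on the same contig, or (b) it is a fused restriction-methylation
    protein, or (c) it belongs to a Type I system and an S record lies
    within the window (Type I REase subunits are often unannotated while
    the specificity subunit is).
    """
    by_contig: dict[str, list[MTaseRecord]] = {}
    for r in records:
        by_contig.setdefault(r.contig_id, []).append(r)
    flags: dict[str, bool] = {}
    for r in records:
        if r.role != "M":
            continue
        if r.fused_re:
            flags[r.gene_id] = True
            continue
        neighbours = by_contig[r.contig_id]
        has_r = any(
            o.role == "R" and abs(o.gene_index - r.gene_index) <= window
            for o in neighbours
        )
        has_s = any(
            o.role == "S" and abs(o.gene_index - r.gene_index) <= window
            for o in neighbours
        )
        flags[r.gene_id] = has_r or (r.rm_type == "I" and has_s)
    return flags


def _mod_compatible_for_proposal(mtase_type: str, motif_type: str) -> bool:
    # a nonspecific closest match constrains nothing during proposal
    return mtase_type == "nonspecific" or mtase_type == motif_type


def propose_orphans(
    incongruent: Sequence[MTaseRecord],
    unexplained: Sequence[IupacMotif],
    all_records: Sequence[MTaseRecord] = (),
    window: int = 5,
) -> list[CongruenceCall]:
    """Pair unexplained detected motifs with incongruent MTases of one genome.

    For each motif: if exactly one incongruent MTase has a compatible
    modification type, propose the pair; if several, prefer the MTase with a
    neighbouring R gene whose cleavage target equals the motif (up to
    reverse complement); otherwise leave the motif unresolved.
    """
    by_contig: dict[str, list[MTaseRecord]] = {}
    for r in all_records:
        by_contig.setdefault(r.contig_id, []).append(r)

    def neighbouring_re_targets(m: MTaseRecord) -> list[str]:
        out = []
        for o in by_contig.get(m.contig_id, ()):
            if (
                o.role == "R"
                and abs(o.gene_index - m.gene_index) <= window
                and o.closest_match_motif is not None
            ):
                out.append(o.closest_match_motif.pattern)
        return out

    calls: list[CongruenceCall] = []
    claimed: set[str] = set()
    for motif in unexplained:
        candidates = [
            m
            for m in incongruent
            if m.gene_id not in claimed
            and _mod_compatible_for_proposal(m.closest_mod_type, motif.mod_type)
        ]
        if len(candidates) == 1:
            claimed.add(candidates[0].gene_id)
            calls.append(
                CongruenceCall(candidates[0].gene_id, "proposed", matched_motif=motif)
            )
            continue
        if len(candidates) > 1:
            tied = [
                m
                for m in candidates
                if any(
                    _patterns_equal_up_to_rc(t, motif.pattern)
                    for t in neighbouring_re_targets(m)
                )
            ]
            if len(tied) == 1:
                claimed.add(tied[0].gene_id)
                calls.append(
                    CongruenceCall(tied[0].gene_id, "proposed", matched_motif=motif)
                )
                continue
        # no unique assignment for this motif
    return calls


def genome_congruence(
    records: Sequence[MTaseRecord],
    detected_by_genome: dict[str, Sequence[IupacMotif]],
    window: int = 5,
) -> dict[str, CongruenceCall]:
    """Full congruence analysis over all genomes.

    Every M record receives exactly one status; proposals upgrade
    incongruent records where a genome's leftover motifs can be uniquely
    assigned.  RM-system flags are attached to every call.
    """
    rm_flags = detect_rm_systems(records, window=window)
    calls: dict[str, CongruenceCall] = {}
    genomes = sorted({r.genome_id for r in records})
    for genome in genomes:
        genome_records = [r for r in records if r.genome_id == genome]
        m_records = [r for r in genome_records if r.role == "M"]
        detected = list(detected_by_genome.get(genome, ()))
        explained: set[str] = set()
        incongruent: list[MTaseRecord] = []
        for r in m_records:
            call = congruence(r, detected)
            calls[r.gene_id] = call
            if call.status == "congruent":
                explained.add(call.matched_motif.pattern)
            elif call.status == "incongruent":
                incongruent.append(r)
        unexplained = [d for d in detected if d.pattern not in explained]
        for call in propose_orphans(incongruent, unexplained, genome_records, window=window):
            calls[call.gene_id] = call
    for gene_id, call in calls.items():
        call.rm_system = rm_flags.get(gene_id, False)
    return calls
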