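"""Degenerate methylated-motif discovery from called sites.

Discovery works per draft genome (bin).  Each called site contributes a
short sequence context centred on the methylated base (reverse-complemented
for minus-strand calls).  Candidate motifs are extracted greedily: the most
enriched (offset, base) column seeds a candidate, which is refined by
information-content offset selection and minimal-IUPAC-code construction
until it reaches a fixed point; matching contexts are then removed and the
search repeats.  Interior offsets that never pass the information-content
cutoff stay N, so bipartite spacer motifs (e.g. GAANNNNTTC) arise naturally.

Candidates are summarised against the genome (strand-specific occurrence
and methylated-site counts) and filtered by the standard exclusion rule:
motifs with fewer than 50 occurrences or a methylation fraction below 1%
in the genome are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import IupacMotif, iupac_code, occurrences, methylated_position, rc_pattern

__all__ = [
    "MotifSummary",
    "extract_contexts",
    "discover",
    "summarize",
    "filter_motifs",
    "discover_genome_motifs",
]

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class MotifSummary:
    """Per-genome statistics of one detected motif.

    ``ratio_pct`` uses all occurrences as denominator (the convention of
    published motif tables, which underestimates the true fraction when
    coverage limits detection); ``frac_est`` restricts the denominator to
    occurrences whose methylated position passes the caller's coverage
    floor and is therefore comparable to the true methylated fraction.
    """

    genome_id: str
    motif: IupacMotif
    n_meth_sites: int
    n_motif_sites: int
    ratio_pct: float
    mean_qv: float
    mean_subread_cov: float
    in_reference: bool = False
    n_assessable_sites: int = 0
    frac_est: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_motif_sites <= 0:
            raise ValueError("motif with zero occurrences cannot be summarised")
        if not 0 <= self.n_meth_sites <= self.n_motif_sites:
            raise ValueError("n_meth_sites out of range")


def extract_contexts(
    sites: pd.DataFrame,
    contigs: Mapping[str, str],
    flank: int = 10,
    qv_min: float | None = None,
) -> list[str]:
    """Centred +/-flank sequence contexts of called sites, on the called strand.

    Minus-strand contexts are reverse complements of the forward window, so
    the methylated base is always at the centre.  Windows truncated by a
    contig end are dropped.  ``qv_min`` optionally keeps only
    high-confidence sites.
    """
    out: list[str] = []
    if sites.empty:
        return out
    if qv_min is not None:
        sites = sites.loc[sites["qv"] >= qv_min]
    for row in sites.itertuples():
        seq = contigs.get(row.contig_id)
        if seq is None:
            raise ValueError(f"site on unknown contig {row.contig_id!r}")
        pos = int(row.position)
        if not 0 <= pos < len(seq):
            raise ValueError(f"site position {pos} outside contig {row.contig_id!r}")
        lo, hi = pos - flank, pos + flank + 1
        if lo < 0 or hi > len(seq):
            continue
        window = seq[lo:hi]
        if row.strand == "-":
            window = window.translate(_COMP)[::-1]
        out.append(window)
    return out


def _context_matrix(contexts: Sequence[str]) -> np.ndarray:
    arr = np.frombuffer("".join(contexts).encode(), dtype="S1").reshape(len(contexts), -1)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        codes[arr == b.encode()] = i
    return codes


def _column_freqs(mat: np.ndarray) -> np.ndarray:
    """(L, 4) base frequencies per column, ignoring non-ACGT."""
    n, L = mat.shape
    freqs = np.zeros((L, 4))
    for i in range(4):
        freqs[:, i] = (mat == i).sum(axis=0)
    totals = freqs.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1
    return freqs / totals


def _info_content(freq_row: np.ndarray) -> float:
    p = freq_row[freq_row > 0]
    return 2.0 + float(np.sum(p * np.log2(p)))


def _min_cover_code(freq_row: np.ndarray, eps: float) -> str:
    """Smallest IUPAC code whose bases cover >= 1-eps of contexts."""
    order = sorted(range(4), key=lambda i: (-freq_row[i], "ACGT"[i]))
    chosen: list[str] = []
    cum = 0.0
    for i in order:
        chosen.append("ACGT"[i])
        cum += freq_row[i]
        if cum >= 1.0 - eps:
            break
    return iupac_code(chosen)


def _match_mask(mat: np.ndarray, pattern: str, start_col: int) -> np.ndarray:
    """Rows of the context matrix matching *pattern* placed at *start_col*."""
    from .motifs import IUPAC

    mask = np.ones(mat.shape[0], dtype=bool)
    for j, code in enumerate(pattern):
        if code == "N":
            continue
        col = mat[:, start_col + j]
        allowed = np.zeros(5, dtype=bool)
        for b in IUPAC[code]:
            allowed[_BASE_INDEX[b]] = True
        mask &= allowed[col]
    return mask


def discover(
    contexts: Sequence[str],
    max_motifs: int = 20,
    ic_min: float = 0.5,
    eps: float = 0.05,
    min_sites: int = 20,
    enrich_min: float = 0.15,
    mod_type_map: Mapping[str, str] = {"A": "m6A", "C": "m4C"},
) -> list[IupacMotif]:
    """Greedy iterative motif extraction from methylated-site contexts.

    Returns motifs in discovery order.  Deterministic given input order;
    column ties break by offset magnitude then base.  An empty or
    structureless context set yields an empty list.
    """
    if len(contexts) < min_sites:
        return []
    lengths = {len(c) for c in contexts}
    if len(lengths) != 1:
        raise ValueError("contexts must share one length")
    L = lengths.pop()
    if L % 2 == 0:
        raise ValueError("context length must be odd (centred)")
    flank = L // 2

    mat = _context_matrix(contexts)
    used_seeds: set[tuple[int, int]] = set()
    found: list[IupacMotif] = []

    while mat.shape[0] >= min_sites and len(found) < max_motifs:
        freqs = _column_freqs(mat)
        # rank candidate seed columns: enrichment desc, |offset|, offset, base
        seeds = []
        for col in range(L):
            if col == flank:
                continue
            for b in range(4):
                if (col, b) in used_seeds:
                    continue
                seeds.append((-freqs[col, b], abs(col - flank), col - flank, b, col))
        seeds.sort()
        if not seeds or -seeds[0][0] - 0.25 < enrich_min:
            break
        _, _, _, b, col = seeds[0]
        used_seeds.add((col, b))

        subset = mat[mat[:, col] == b]
        if subset.shape[0] < min_sites:
            continue
        # force the centre to the majority methylatable base of the subset
        center_counts = np.bincount(subset[:, flank], minlength=5)
        center = "A" if center_counts[0] >= center_counts[1] else "C"
        subset = subset[subset[:, flank] == _BASE_INDEX[center]]
        if subset.shape[0] < min_sites:
            continue

        pattern, start = _refine(subset, mat, flank, center, ic_min, eps, min_sites)
        if pattern is None:
            continue
        motif = IupacMotif(pattern, flank - start, mod_type_map[center])
        if motif.pattern in {m.pattern for m in found}:
            continue
        found.append(motif)
        mat = mat[~_match_mask(mat, pattern, start)]
    return found


def _consensus(
    subset: np.ndarray, flank: int, center: str, ic_min: float, eps: float
) -> tuple[str | None, int]:
    """Pattern over offsets whose information content reaches ic_min."""
    L = subset.shape[1]
    freqs = _column_freqs(subset)
    selected = [
        col for col in range(L) if col != flank and _info_content(freqs[col]) >= ic_min
    ]
    if not selected:
        return None, flank
    lo = min(min(selected), flank)
    hi = max(max(selected), flank)
    chars = []
    for col in range(lo, hi + 1):
        if col == flank:
            chars.append(center)
        elif col in selected:
            chars.append(_min_cover_code(freqs[col], eps))
        else:
            chars.append("N")
    return "".join(chars), lo


def _refine(
    subset: np.ndarray,
    mat: np.ndarray,
    flank: int,
    center: str,
    ic_min: float,
    eps: float,
    min_sites: int,
    eps_coarse: float = 0.3,
):
    """Iterate consensus-building until the pattern reaches a fixed point.

    Intermediate rounds use a coarse covering code (eps_coarse) so that
    contexts of a second motif caught in the seed subset are shed rather
    than absorbed into degenerate codes; the final code on the converged
    subset uses the tight eps.
    """
    pattern_prev = None
    for _ in range(10):
        pattern, start = _consensus(subset, flank, center, ic_min, eps_coarse)
        if pattern is None:
            return None, None
        if pattern == pattern_prev:
            break
        pattern_prev = pattern
        new_subset = mat[
            _match_mask(mat, pattern, start) & (mat[:, flank] == _BASE_INDEX[center])
        ]
        if new_subset.shape[0] < min_sites:
            return None, None
        subset = new_subset
    pattern, start = _consensus(subset, flank, center, ic_min, eps)
    if pattern is None or set(pattern) <= {"N", center}:
        # no informative flanking position survived refinement
        return None, None
    return pattern, start


def summarize(
    motif: IupacMotif,
    sites: pd.DataFrame,
    contigs: Mapping[str, str],
    kinetics: pd.DataFrame | None = None,
    genome_id: str = "",
    min_cov: int = 25,
    reference_patterns: Iterable[str] = (),
) -> MotifSummary:
    """Genome-level statistics for one motif.

    ``n_motif_sites`` counts strand-specific occurrences over all contigs;
    ``n_meth_sites`` counts occurrences whose methylated position was called
    on the matching strand.  If a kinetics table is given, occurrences whose
    methylated position reaches the coverage floor are counted as assessable
    and ``frac_est`` is the methylated fraction among those.
    """
    called: set[tuple[str, str, int]] = set()
    qv_of: dict[tuple[str, str, int], tuple[float, float]] = {}
    for row in sites.itertuples():
        key = (row.contig_id, row.strand, int(row.position))
        called.add(key)
        qv_of[key] = (float(row.qv), float(row.coverage))

    cov_arr: dict[tuple[str, str], np.ndarray] = {}
    if kinetics is not None and not kinetics.empty:
        for (cid, strand), grp in kinetics.groupby(["contig_id", "strand"], sort=False):
            arr = np.zeros(len(contigs[cid]), dtype=np.int64)
            arr[grp["position"].to_numpy()] = grp["coverage"].to_numpy()
            cov_arr[(cid, strand)] = arr

    n_occ = n_meth = n_assessable = 0
    qvs: list[float] = []
    covs: list[float] = []
    for cid in sorted(contigs):
        seq = contigs[cid]
        for pos, strand in occurrences(motif, seq):
            n_occ += 1
            mp = methylated_position(motif, pos, strand)
            key = (cid, strand, mp)
            if cov_arr:
                arr = cov_arr.get((cid, strand))
                if arr is not None and arr[mp] >= min_cov:
                    n_assessable += 1
            if key in called:
                n_meth += 1
                qv, cov = qv_of[key]
                qvs.append(qv)
                covs.append(cov)
    if n_occ == 0:
        raise ValueError(f"motif {motif} has no occurrences in genome {genome_id!r}")

    ref = set(reference_patterns)
    in_ref = motif.pattern in ref or rc_pattern(motif.pattern) in ref
    return MotifSummary(
        genome_id=genome_id,
        motif=motif,
        n_meth_sites=n_meth,
        n_motif_sites=n_occ,
        ratio_pct=round(100.0 * n_meth / n_occ, 1),
        mean_qv=float(np.mean(qvs)) if qvs else 0.0,
        mean_subread_cov=float(np.mean(covs)) if covs else 0.0,
        in_reference=in_ref,
        n_assessable_sites=n_assessable,
        frac_est=(n_meth / n_assessable) if n_assessable else float("nan"),
    )


def filter_motifs(
    summaries: Iterable[MotifSummary],
    min_occurrences: int = 50,
    min_ratio_pct: float = 1.0,
) -> list[MotifSummary]:
    """Drop motifs with infrequent occurrences (<50) or very low methylation
    fractions (<1%); boundary values are retained."""
    return [
        s
        for s in summaries
        if s.n_motif_sites >= min_occurrences and s.ratio_pct >= min_ratio_pct
    ]


def discover_genome_motifs(
    sites: pd.DataFrame,
    contigs: Mapping[str, str],
    kinetics: pd.DataFrame | None = None,
    genome_id: str = "",
    flank: int = 10,
    qv_context_min: float = 30.0,
    reference_patterns: Iterable[str] = (),
    min_cov: int = 25,
    **discover_kwargs,
) -> list[MotifSummary]:
    """End-to-end per-genome discovery: contexts -> motifs -> summaries -> filter.

    ``qv_context_min`` restricts context extraction to high-confidence calls
    so that the expected ~1% of borderline false calls at the caller's
    default cutoff does not swamp the column statistics; summaries still
    count every called site.
    """
    contexts = extract_contexts(sites, contigs, flank=flank, qv_min=qv_context_min)
    motifs = discover(contexts, **discover_kwargs)
    summaries = []
    for m in motifs:
        try:
            summaries.append(
                summarize(
                    m,
                    sites,
                    contigs,
                    kinetics,
                    genome_id=genome_id,
                    min_cov=min_cov,
                    reference_patterns=reference_patterns,
                )
            )
        except ValueError:
            continue
    return filter_motifs(summaries)
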