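"""Per-contig methylation profiles and a binning-congruence score.

Contigs from the same organism share a methylation pattern, so per-contig
methylated fractions over the detected motif panel can corroborate (or
question) a genome binning.  The congruence score is a mean silhouette over
contigs, using L1 distance restricted to profile entries defined on both
contigs; entries are undefined where a contig carries too few occurrences
of a motif to estimate a fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import IupacMotif, occurrences, methylated_position

__all__ = ["ContigProfile", "contig_profiles", "profile_matrix", "bin_congruence"]


@dataclass
class ContigProfile:
    """Per-motif methylated fractions on one contig (NaN = undefined)."""

    contig_id: str
    bin_id: str | None
    ratios: np.ndarray  # length = motif panel size, NaN where < min_occ occurrences

    def __post_init__(self) -> None:
        r = self.ratios[~np.isnan(self.ratios)]
        if len(r) and (r.min() < 0 or r.max() > 1):
            raise ValueError("defined profile entries must lie in [0, 1]")


def contig_profiles(
    contigs: Mapping[str, str],
    panel: Sequence[IupacMotif],
    sites: pd.DataFrame,
    bin_of: Mapping[str, str] | None = None,
    min_occ: int = 10,
    kinetics: pd.DataFrame | None = None,
    min_cov: int = 25,
) -> list[ContigProfile]:
    """Methylated fraction of each panel motif on each contig.

    The fraction is methylated occurrences / occurrences, strand-specific;
    a motif with fewer than ``min_occ`` occurrences on a contig yields an
    undefined (NaN) entry.  When a kinetics table is supplied, only
    occurrences whose methylated position reaches the ``min_cov`` subread
    floor count towards the denominator — a contig too thinly covered to
    assess methylation is undefined, not unmethylated.
    """
    if not panel:
        raise ValueError("empty motif panel")
    called: set[tuple[str, str, int]] = {
        (r.contig_id, r.strand, int(r.position)) for r in sites.itertuples()
    }
    cov_arr: dict[tuple[str, str], np.ndarray] = {}
    if kinetics is not None and not kinetics.empty:
        for (cid, strand), grp in kinetics.groupby(["contig_id", "strand"], sort=False):
            arr = np.zeros(len(contigs[cid]), dtype=np.int64)
            arr[grp["position"].to_numpy()] = grp["coverage"].to_numpy()
            cov_arr[(cid, strand)] = arr
    profiles = []
    for cid in sorted(contigs):
        seq = contigs[cid]
        ratios = np.full(len(panel), np.nan)
        for j, motif in enumerate(panel):
            occ = occurrences(motif, seq)
            if kinetics is not None:
                occ = [
                    (pos, strand)
                    for pos, strand in occ
                    if (arr := cov_arr.get((cid, strand))) is not None
                    and arr[methylated_position(motif, pos, strand)] >= min_cov
                ]
            if len(occ) < min_occ:
                continue
            meth = sum(
                (cid, strand, methylated_position(motif, pos, strand)) in called
                for pos, strand in occ
            )
            ratios[j] = meth / len(occ)
        profiles.append(
            ContigProfile(cid, bin_of.get(cid) if bin_of else None, ratios)
        )
    return profiles


def profile_matrix(profiles: Sequence[ContigProfile], panel: Sequence[IupacMotif]) -> pd.DataFrame:
    """Profiles as a DataFrame (rows contigs, columns motif patterns)."""
    return pd.DataFrame(
        [p.ratios for p in profiles],
        index=[p.contig_id for p in profiles],
        columns=[m.pattern for m in panel],
    )


def _pairwise_l1(ratios: np.ndarray, min_shared: int) -> np.ndarray:
    """Mean absolute difference over shared defined entries; NaN if too few."""
    n = ratios.shape[0]
    defined = ~np.isnan(ratios)
    dist = np.full((n, n), np.nan)
    for i in range(n):
        both = defined[i] & defined
        diff = np.abs(ratios - ratios[i])
        with np.errstate(invalid="ignore"):
            shared = both.sum(axis=1)
            vals = np.where(both, diff, 0.0).sum(axis=1)
        ok = shared >= min_shared
        dist[i, ok] = vals[ok] / shared[ok]
    np.fill_diagonal(dist, 0.0)
    return dist


def bin_congruence(
    profiles: Sequence[ContigProfile],
    min_shared: int = 3,
) -> float:
    """Mean silhouette of contig methylation profiles under their bin labels.

    Distances are L1 on pairwise-defined entries; pairs sharing fewer than
    ``min_shared`` defined entries are undefined and excluded from the means.
    Contigs whose own-bin or nearest-other-bin mean distance is undefined
    are skipped.  Requires >= 2 bins with >= 2 contigs each; raises if every
    distance is undefined.
    """
    labeled = [p for p in profiles if p.bin_id is not None]
    bins: dict[str, list[int]] = {}
    for i, p in enumerate(labeled):
        bins.setdefault(p.bin_id, []).append(i)
    if len(bins) < 2 or any(len(v) < 2 for v in bins.values()):
        raise ValueError("bin_congruence needs >= 2 bins with >= 2 contigs each")

    ratios = np.array([p.ratios for p in labeled])
    dist = _pairwise_l1(ratios, min_shared)

    scores = []
    for i, p in enumerate(labeled):
        own = [j for j in bins[p.bin_id] if j != i]
        a_vals = dist[i, own]
        a_vals = a_vals[~np.isnan(a_vals)]
        if not len(a_vals):
            continue
        a = a_vals.mean()
        b = np.inf
        for bin_id, members in bins.items():
            if bin_id == p.bin_id:
                continue
            vals = dist[i, members]
            vals = vals[~np.isnan(vals)]
            if len(vals):
                b = min(b, vals.mean())
        if not np.isfinite(b):
            continue
        denom = max(a, b)
        scores.append(0.0 if denom == 0 else (b - a) / denom)
    if not scores:
        raise ValueError("all profile distances undefined; cannot score binning")
    return float(np.mean(scores))
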