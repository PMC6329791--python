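"""Per-site, per-strand DNA-modification calling from kinetic summaries.

A site's evidence for modification is a one-sided, one-sample location test
of its mean log2 interpulse-duration ratio against 0: with n subreads,

    t = mean * sqrt(n) / max(sd, sd_floor),      p = P(T_{n-1} >= t),

reported as a Phred-scaled modification QV = -10*log10(p), capped.  Sites
are emitted when they pass both the per-strand subread-coverage floor
(25x per strand is the standard detection-power guidance) and the QV cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ModifiedSite", "site_qv", "call_sites", "SD_FLOOR", "QV_CAP"]

SD_FLOOR = 0.1
QV_CAP = 1000.0


@dataclass(frozen=True)
class ModifiedSite:
    """A called modification with its Phred-scaled score."""

    contig_id: str
    position: int
    strand: str
    qv: float
    coverage: int
    effect: float  # mean log2 IPD ratio


def site_qv(
    mean: float | np.ndarray,
    sd: float | np.ndarray,
    coverage: int | np.ndarray,
    sd_floor: float = SD_FLOOR,
    qv_cap: float = QV_CAP,
):
    """Phred-scaled modification QV for one site (vectorised).

    Raises for coverage < 2 (no within-site variance estimate) or negative sd.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    coverage = np.asarray(coverage)
    if np.any(coverage < 2):
        raise ValueError("site_qv requires coverage >= 2")
    if np.any(sd < 0) or not np.all(np.isfinite(sd)):
        raise ValueError("sd must be finite and non-negative")
    t = mean * np.sqrt(coverage) / np.maximum(sd, sd_floor)
    # survival function of Student's t with coverage-1 degrees of freedom
    p = stats.t.sf(t, df=coverage - 1)
    with np.errstate(divide="ignore"):
        qv = -10.0 * np.log10(p)
    qv = np.minimum(qv, qv_cap)
    qv = np.maximum(qv, 0.0)
    return qv if qv.shape else float(qv)


def call_sites(
    kinetics: pd.DataFrame,
    min_cov_per_strand: int = 25,
    qv_min: float = 20.0,
    sd_floor: float = SD_FLOOR,
    qv_cap: float = QV_CAP,
) -> pd.DataFrame:
    """Call modified sites from a kinetics table.

    Only sites with ``coverage >= min_cov_per_strand`` are tested; of those,
    sites with ``qv >= qv_min`` are returned as a table with columns
    contig_id, position, strand, qv, coverage, effect.  An empty input yields
    an empty table.
    """
    cols = ["contig_id", "position", "strand", "qv", "coverage", "effect"]
    if kinetics.empty:
        return pd.DataFrame(columns=cols)
    ok = kinetics["coverage"] >= max(min_cov_per_strand, 2)
    sub = kinetics.loc[ok]
    if sub.empty:
        return pd.DataFrame(columns=cols)
    qv = site_qv(
        sub["mean_log2_ipd_ratio"].to_numpy(),
        sub["sd_log2_ipd_ratio"].to_numpy(),
        sub["coverage"].to_numpy(),
        sd_floor=sd_floor,
        qv_cap=qv_cap,
    )
    out = pd.DataFrame(
        {
            "contig_id": sub["contig_id"].to_numpy(),
            "position": sub["position"].to_numpy(),
            "strand": sub["strand"].to_numpy(),
            "qv": qv,
            "coverage": sub["coverage"].to_numpy(),
            "effect": sub["mean_log2_ipd_ratio"].to_numpy(),
        }
    )
    out = out.loc[out["qv"] >= qv_min].reset_index(drop=True)
    return out[cols]
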