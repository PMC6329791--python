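"""Readers and writers for the pipeline's file formats.

Motif text syntax in files: the methylated base is marked by a lowercase
``m`` immediately before it, e.g. ``GmANTC`` for GANTC methylated at the A.
All tables are plain TSV via pandas; sequences are FASTA via Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import IupacMotif

KINETICS_COLUMNS = ["contig_id", "position", "strand", "coverage",
                    "mean_log2_ipd_ratio", "sd_log2_ipd_ratio"]
SITES_COLUMNS = ["contig_id", "position", "strand", "qv", "coverage", "effect"]


def format_motif(m: IupacMotif) -> str:
    """Render a motif in m-anchor syntax (``GmANTC``)."""
    p = m.pattern
    return p[: m.meth_offset] + "m" + p[m.meth_offset :]


def parse_motif(text: str, mod_type: str = "unknown") -> IupacMotif:
    """Parse m-anchor syntax; a string without ``m`` is rejected."""
    idx = text.find("m")
    if idx < 0:
        raise ValueError(f"no methylated-base anchor 'm' in {text!r}")
    pattern = text[:idx] + text[idx + 1 :]
    return IupacMotif(pattern.upper(), idx, mod_type)


def write_fasta(contigs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_kinetics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(KINETICS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"kinetics table missing columns: {sorted(missing)}")
    return df


def read_sites(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SITES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"modified-sites table missing columns: {sorted(missing)}")
    return df


def sites_to_bed(sites: pd.DataFrame) -> pd.DataFrame:
    """BED6-like browser track of called modified sites (scores capped at 1000)."""
    return pd.DataFrame(
        {
            "chrom": sites["contig_id"],
            "chromStart": sites["position"],
            "chromEnd": sites["position"] + 1,
            "name": "modified_base",
            "score": sites["qv"].clip(upper=1000).round().astype(int),
            "strand": sites["strand"],
        }
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
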