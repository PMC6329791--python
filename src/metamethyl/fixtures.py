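"""Packaged example tables from a freshwater-lake metaepigenomic survey.

Three small TSVs ship with the package:

``survey_motifs.tsv``
    29 methylated motifs detected in 10 draft genomes, with site/occurrence
    counts, methylation ratio, mean modification QV, mean subread coverage
    and whether the motif is a known recognition sequence.
``survey_mtases.tsv``
    28 methyltransferase (M), restriction-endonuclease (R) and
    specificity-subunit (S) genes from the same genomes, with the recognition
    motif of each gene's closest database match.
``reference_motifs.tsv``
    Known recognition sequences used for novelty assessment of discovered
    motifs on synthetic runs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .congruence import MTaseRecord
from .io import parse_motif
from .motifs import IupacMotif

__all__ = [
    "load_survey_motifs",
    "load_survey_mtases",
    "load_reference_motifs",
    "survey_motif_list",
    "survey_reference_patterns",
    "survey_mtase_records",
]


def _data_path(name: str):
    return resources.files("metamethyl.data").joinpath(name)


def load_survey_motifs() -> pd.DataFrame:
    """The detected-motif table (one row per genome × motif)."""
    with resources.as_file(_data_path("survey_motifs.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_survey_mtases() -> pd.DataFrame:
    """The MTase/REase/S-subunit gene table."""
    with resources.as_file(_data_path("survey_mtases.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_reference_motifs() -> list[IupacMotif]:
    """Known recognition sequences for novelty assessment."""
    with resources.as_file(_data_path("reference_motifs.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return [parse_motif(r.motif, r.mod_type) for r in df.itertuples()]


def survey_motif_list(df: pd.DataFrame | None = None) -> list[tuple[str, IupacMotif]]:
    """(genome_id, IupacMotif) pairs from the detected-motif table."""
    if df is None:
        df = load_survey_motifs()
    return [
        (r.genome_id, IupacMotif(r.motif, int(r.meth_offset), r.mod_type))
        for r in df.itertuples()
    ]


def survey_reference_patterns(df: pd.DataFrame | None = None) -> list[str]:
    """Patterns flagged as known recognition sequences in the motif table."""
    if df is None:
        df = load_survey_motifs()
    return sorted(df.loc[df["in_rebase"].eq("Yes"), "motif"].unique())


def survey_mtase_records(df: pd.DataFrame | None = None) -> list[MTaseRecord]:
    """MTaseRecord objects for every row of the gene table."""
    if df is None:
        df = load_survey_mtases()
    records = []
    for r in df.itertuples():
        motif = None
        if r.motif not in ("?", "nonspecific"):
            if "m" in r.motif:
                motif = parse_motif(r.motif, r.mod_type)
            else:
                # REase cleavage targets carry no methylated-base anchor
                motif = IupacMotif(r.motif, 0, "unknown")
        records.append(
            MTaseRecord(
                gene_id=r.gene_id,
                genome_id=r.genome_id,
                contig_id=r.contig_id,
                gene_index=int(r.gene_index),
                role=r.role,
                rm_type=str(r.rm_type),
                closest_match_motif=motif,
                closest_mod_type=("nonspecific" if r.motif == "nonspecific" else r.mod_type),
                fused_re=bool(r.fused_re),
            )
        )
    return records
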