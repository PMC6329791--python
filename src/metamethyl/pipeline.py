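"""Pipeline orchestration: simulate -> call -> discover -> profile -> congruence.

A run is a pure function of its configuration (including the seed): stage
outputs land in a run directory together with the serialized config and a
log recording the config hash, and identical re-runs are byte-identical.
A fixtures-only analysis reproduces the survey tallies (distinct motifs,
novel groups, congruent MTases) from the packaged tables without any
simulation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import fixtures as fx
from .calling import call_sites
from .congruence import genome_congruence
from .discovery import discover_genome_motifs
from .io import format_motif, sites_to_bed, write_fasta, write_json, write_tsv
from .motifs import IupacMotif, dedupe_and_group
from .profiles import bin_congruence, contig_profiles, profile_matrix
from .simulate import CommunitySpec, default_spec, generate_community, generate_gene_table

__all__ = ["RunConfig", "run", "fixture_analysis"]


@dataclass
class RunConfig:
    """Stage toggles and parameters for one pipeline run."""

    seed: int = 0
    out_dir: str = "metamethyl_run"
    stages: tuple[str, ...] = ("simulate", "call", "discover", "profile", "congruence")
    # caller
    min_cov_per_strand: int = 25
    qv_min: float = 20.0
    # discovery
    flank: int = 10
    qv_context_min: float = 30.0
    max_motifs: int = 20
    min_occurrences: int = 50
    # profiles
    min_occ_per_contig: int = 10
    # congruence
    window: int = 5
    community: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        # out_dir is a location, not a parameter: equal-parameter runs into
        # different directories must hash identically
        params = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(params, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _spec_from_config(config: RunConfig) -> CommunitySpec:
    return default_spec(seed=config.seed, **config.community)


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the summary dict.

    Raises a configuration error if an enabled stage's upstream output is
    missing (stages must be enabled as a prefix of the full chain).
    """
    order = ("simulate", "call", "discover", "profile", "congruence")
    enabled = [s for s in order if s in config.stages]
    for i, stage in enumerate(enabled):
        if order.index(stage) != i:
            raise ValueError(
                f"stage {stage!r} enabled without its upstream stages; "
                f"enable a prefix of {order}"
            )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    (out / "run.log").write_text(
        f"metamethyl run\nconfig_hash: {config.config_hash()}\nstages: {enabled}\n"
    )
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    spec = _spec_from_config(config)
    contigs = truth = kinetics = sites = None
    reference = [m.pattern for m in fx.load_reference_motifs()]

    if "simulate" in enabled:
        contigs, truth, kinetics = generate_community(spec)
        write_fasta(contigs, out / "contigs.fasta")
        write_json(truth.to_jsonable(), out / "truth.json")
        write_tsv(kinetics, out / "kinetics.tsv")
        gene_table = generate_gene_table(spec, truth)
        write_tsv(gene_table, out / "genes.tsv")
        summary["n_contigs"] = len(contigs)
        summary["n_genomes"] = spec.n_genomes

    if "call" in enabled:
        sites = call_sites(
            kinetics, min_cov_per_strand=config.min_cov_per_strand, qv_min=config.qv_min
        )
        write_tsv(sites, out / "modified_sites.tsv")
        write_tsv(sites_to_bed(sites), out / "modified_sites.bed")
        summary["n_called_sites"] = int(len(sites))

    summaries_by_genome: dict[str, list] = {}
    if "discover" in enabled:
        genome_of = truth.contig_genome
        for gid in sorted(set(genome_of.values())):
            g_contigs = {c: s for c, s in contigs.items() if genome_of[c] == gid}
            g_sites = sites[sites["contig_id"].isin(g_contigs)]
            g_kin = kinetics[kinetics["contig_id"].isin(g_contigs)]
            summaries_by_genome[gid] = discover_genome_motifs(
                g_sites,
                g_contigs,
                g_kin,
                genome_id=gid,
                flank=config.flank,
                qv_context_min=config.qv_context_min,
                reference_patterns=reference,
                min_cov=config.min_cov_per_strand,
                max_motifs=config.max_motifs,
            )
        motif_rows = [
            {
                "genome_id": s.genome_id,
                "motif": s.motif.pattern,
                "meth_offset": s.motif.meth_offset,
                "mod_type": s.motif.mod_type,
                "in_rebase": "Yes" if s.in_reference else "No",
                "n_meth_sites": s.n_meth_sites,
                "n_motif_sites": s.n_motif_sites,
                "ratio_pct": s.ratio_pct,
                "mean_qv": round(s.mean_qv, 1),
                "mean_subread_cov": round(s.mean_subread_cov, 1),
            }
            for ss in summaries_by_genome.values()
            for s in ss
        ]
        write_tsv(pd.DataFrame(motif_rows), out / "motifs.tsv")
        all_motifs = [
            (s.genome_id, s.motif) for ss in summaries_by_genome.values() for s in ss
        ]
        if all_motifs:
            _, n_distinct, n_novel = dedupe_and_group(all_motifs, reference)
        else:
            n_distinct = n_novel = 0
        summary["n_motifs"] = len(all_motifs)
        summary["n_distinct_motifs"] = n_distinct
        summary["n_novel_groups"] = n_novel
        if truth is not None:
            planted = {
                (g, s.motif.pattern, s.motif.meth_offset)
                for g, systems in truth.systems.items()
                for s in systems
            }
            recovered = {
                (s.genome_id, s.motif.pattern, s.motif.meth_offset)
                for ss in summaries_by_genome.values()
                for s in ss
            }
            summary["recovery"] = {
                "n_planted": len(planted),
                "n_recovered_exact": len(planted & recovered),
                "n_spurious": len(recovered - planted),
            }

    if "profile" in enabled:
        panel = sorted(
            {s.motif for ss in summaries_by_genome.values() for s in ss},
            key=lambda m: m.pattern,
        )
        if panel:
            profiles = contig_profiles(
                contigs,
                panel,
                sites,
                bin_of=truth.contig_genome,
                min_occ=config.min_occ_per_contig,
                kinetics=kinetics,
                min_cov=config.min_cov_per_strand,
            )
            matrix = profile_matrix(profiles, panel)
            matrix.to_csv(out / "profiles.tsv", sep="\t")
            try:
                score = bin_congruence(profiles)
            except ValueError:
                score = None
            summary["bin_congruence"] = score
            write_json({"bin_congruence": score}, out / "congruence_score.json")

    if "congruence" in enabled:
        gene_table = pd.read_csv(out / "genes.tsv", sep="\t")
        records = fx.survey_mtase_records(gene_table)
        detected = {
            gid: [s.motif for s in ss] for gid, ss in summaries_by_genome.items()
        }
        calls = genome_congruence(records, detected, window=config.window)
        rows = [
            {
                "gene_id": gid,
                "status": c.status,
                "matched_motif": format_motif(c.matched_motif) if c.matched_motif else "-",
                "rm_system": "Yes" if c.rm_system else "No",
            }
            for gid, c in sorted(calls.items())
        ]
        write_tsv(pd.DataFrame(rows), out / "congruence.tsv")
        summary["congruence_tally"] = {
            status: sum(c.status == status for c in calls.values())
            for status in ("congruent", "incongruent", "proposed", "unresolved")
        }

    write_json(summary, out / "summary.json")
    return summary


def fixture_analysis() -> dict:
    """Reproduce the survey tallies from the packaged tables (no simulation).

    Returns row counts, the distinct-motif and novel-group counts from motif
    deduplication and merging, and the MTase congruence tally.
    """
    motif_df = fx.load_survey_motifs()
    motif_list = fx.survey_motif_list(motif_df)
    reference = fx.survey_reference_patterns(motif_df)
    groups, n_distinct, n_novel = dedupe_and_group(motif_list, reference)

    records = fx.survey_mtase_records()
    detected_by_genome: dict[str, list[IupacMotif]] = {}
    for gid, motif in motif_list:
        detected_by_genome.setdefault(gid, []).append(motif)
    calls = genome_congruence(records, detected_by_genome)
    tally = {
        status: sum(c.status == status for c in calls.values())
        for status in ("congruent", "incongruent", "proposed", "unresolved")
    }
    ratios_ok = int(
        (
            (100.0 * motif_df["n_meth_sites"] / motif_df["n_motif_sites"]).round(1)
            == motif_df["ratio_pct"]
        ).sum()
    )
    return {
        "n_motif_rows": int(len(motif_df)),
        "n_genomes": int(motif_df["genome_id"].nunique()),
        "n_distinct_motifs": n_distinct,
        "n_novel_groups": n_novel,
        "n_groups_total": len(groups),
        "congruence_tally": tally,
        "n_m_records": sum(r.role == "M" for r in records),
        "n_rm_systems": sum(
            c.rm_system for c in calls.values()
        ),
        "n_ratio_rows_consistent": ratios_ok,
    }
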