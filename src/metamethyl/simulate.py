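"""Seeded synthetic microbial community with planted methylation systems.

The generator emulates the inputs a single-molecule metaepigenomic study
works from, at desk scale: a handful of genomes with distinct nucleotide
composition and uneven abundances, fragmented into contigs; sequence-specific
methylation systems planted at partial methylation fractions; and per-site,
per-strand subread kinetic summaries whose effect size depends on the
modification type (m6A > m4C > m5C, mirroring the detectability ordering of
single-molecule kinetics).

Kinetics are emitted as per-site summary statistics (subread coverage, mean
and sd of the log2 interpulse-duration ratio) rather than raw per-subread
values; these are sufficient statistics for the downstream caller's test.
All outputs are pure functions of the spec and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import IupacMotif, occurrences, methylated_position

__all__ = [
    "PlantedSystem",
    "CommunitySpec",
    "TruthTable",
    "generate_genomes",
    "plant_methylation",
    "simulate_kinetics",
    "generate_gene_table",
    "generate_community",
    "default_spec",
]

#: per-subread log2 IPD-ratio shift by modification type (null sd = 1.0)
DEFAULT_DELTAS: dict[str, float] = {"m6A": 1.3, "m4C": 0.8, "m5C": 0.25}

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedSystem:
    """One methylation system: a motif methylated at a partial fraction."""

    motif: IupacMotif
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("methylation fraction must lie in [0, 1]")


@dataclass
class CommunitySpec:
    """Full description of a synthetic community.

    ``coverage_mean`` is the community-wide mean subread coverage per strand;
    each genome's coverage is scaled by its abundance relative to the mean
    abundance, so uneven communities show rare-genome dropout below the
    caller's coverage floor.
    """

    n_genomes: int
    genome_length_bp: Sequence[int]
    gc_content: Sequence[float]
    abundance: Sequence[float]
    systems: Sequence[Sequence[PlantedSystem]]
    markov_order: int = 1
    coverage_mean: float = 30.0
    sigma_log2: float = 1.0
    deltas: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DELTAS))
    contig_mu_log: float = np.log(20_000.0)
    contig_sigma_log: float = 0.5
    min_contig_bp: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_genomes
        for name in ("genome_length_bp", "gc_content", "abundance", "systems"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per genome")
        if not 0 <= self.markov_order <= 3:
            raise ValueError("markov_order must be in 0..3")
        if self.sigma_log2 <= 0:
            raise ValueError("sigma_log2 must be positive")
        if any(d < 0 for d in self.deltas.values()):
            raise ValueError("kinetic deltas must be non-negative")
        if any(a <= 0 for a in self.abundance):
            raise ValueError("abundances must be positive")
        for length, systems in zip(self.genome_length_bp, self.systems):
            for s in systems:
                if length < len(s.motif):
                    raise ValueError("genome shorter than a planted motif")

    def genome_ids(self) -> list[str]:
        return [f"g{i + 1}" for i in range(self.n_genomes)]

    def genome_coverage(self) -> np.ndarray:
        a = np.asarray(self.abundance, dtype=float)
        return self.coverage_mean * a / a.mean()


@dataclass
class TruthTable:
    """Ground truth of a simulated community.

    ``methylated`` maps contig_id to a dict ``strand -> set of methylated
    forward-strand positions``; every such position is the methylated base of
    an occurrence of a planted motif.
    """

    contig_genome: dict[str, str]
    systems: dict[str, list[PlantedSystem]]
    methylated: dict[str, dict[str, set[int]]]

    def to_jsonable(self) -> dict:
        return {
            "contig_genome": self.contig_genome,
            "systems": {
                g: [
                    {
                        "pattern": s.motif.pattern,
                        "meth_offset": s.motif.meth_offset,
                        "mod_type": s.motif.mod_type,
                        "fraction": s.fraction,
                    }
                    for s in systems
                ]
                for g, systems in self.systems.items()
            },
            "methylated": {
                c: {strand: sorted(pos) for strand, pos in strands.items()}
                for c, strands in self.methylated.items()
            },
        }


def _sample_sequence(rng: np.random.Generator, length: int, gc: float, order: int) -> str:
    """Markov-chain nucleotide sequence with stationary GC close to *gc*."""
    p0 = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    if order == 0:
        idx = rng.choice(4, size=length, p=p0)
        return "".join(BASES[idx])
    # context-dependent jitter around the base composition gives each genome
    # a distinct oligonucleotide signature while preserving GC
    n_ctx = 4**order
    jitter = rng.dirichlet(np.full(4, 40.0), size=n_ctx)
    trans = 0.6 * p0 + 0.4 * jitter * (p0 * 4)
    trans /= trans.sum(axis=1, keepdims=True)
    cum = np.cumsum(trans, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    ctx = 0
    mask = n_ctx - 1
    for i in range(length):
        row = cum[ctx]
        b = int(np.searchsorted(row, u[i], side="right"))
        b = min(b, 3)
        out[i] = b
        ctx = ((ctx << 2) | b) & mask
    return "".join(BASES[out])


def _fragment(rng: np.random.Generator, genome_id: str, seq: str, spec: CommunitySpec) -> dict[str, str]:
    """Cut a genome into log-normal length contigs (min length enforced)."""
    contigs: dict[str, str] = {}
    pos, k = 0, 1
    n = len(seq)
    while pos < n:
        length = int(rng.lognormal(spec.contig_mu_log, spec.contig_sigma_log))
        length = max(length, spec.min_contig_bp)
        if n - (pos + length) < spec.min_contig_bp:
            length = n - pos
        contigs[f"{genome_id}_c{k}"] = seq[pos : pos + length]
        pos += length
        k += 1
    return contigs


def generate_genomes(spec: CommunitySpec) -> tuple[dict[str, str], TruthTable]:
    """Sample genomes, fragment into contigs, and plant methylation.

    Returns the contig dict and a TruthTable; byte-identical for equal seeds.
    """
    root = np.random.SeedSequence(spec.seed)
    seq_ss, frag_ss, meth_ss = root.spawn(3)
    seq_rngs = [np.random.default_rng(s) for s in seq_ss.spawn(spec.n_genomes)]
    frag_rng = np.random.default_rng(frag_ss)

    contigs: dict[str, str] = {}
    contig_genome: dict[str, str] = {}
    for gid, rng, length, gc in zip(
        spec.genome_ids(), seq_rngs, spec.genome_length_bp, spec.gc_content
    ):
        seq = _sample_sequence(rng, int(length), float(gc), spec.markov_order)
        for cid, cseq in _fragment(frag_rng, gid, seq, spec).items():
            contigs[cid] = cseq
            contig_genome[cid] = gid

    systems = dict(zip(spec.genome_ids(), [list(s) for s in spec.systems]))
    truth = plant_methylation(contigs, contig_genome, systems, np.random.default_rng(meth_ss))
    return contigs, truth


def plant_methylation(
    contigs: Mapping[str, str],
    contig_genome: Mapping[str, str],
    systems: Mapping[str, Sequence[PlantedSystem]],
    rng: np.random.Generator,
) -> TruthTable:
    """Methylate each strand-specific motif occurrence independently.

    Each occurrence of each planted motif is methylated with probability
    equal to the system's methylation fraction.  Occurrences are
    strand-specific, so the two strands of a palindromic duplex site are
    methylated independently.
    """
    methylated: dict[str, dict[str, set[int]]] = {
        c: {"+": set(), "-": set()} for c in contigs
    }
    for cid in sorted(contigs):
        seq = contigs[cid]
        for system in systems.get(contig_genome[cid], ()):
            occ = occurrences(system.motif, seq)
            if not occ:
                continue
            keep = rng.random(len(occ)) < system.fraction
            for (pos, strand), methyl in zip(occ, keep):
                if methyl:
                    methylated[cid][strand].add(
                        methylated_position(system.motif, pos, strand)
                    )
    return TruthTable(
        contig_genome=dict(contig_genome),
        systems={g: list(s) for g, s in systems.items()},
        methylated=methylated,
    )


def simulate_kinetics(
    contigs: Mapping[str, str],
    truth: TruthTable,
    spec: CommunitySpec,
) -> pd.DataFrame:
    """Per-site, per-strand subread kinetic summaries for every position.

    Coverage is Poisson with a genome-specific mean (abundance-scaled);
    per-subread log2 IPD ratios are Normal(0, sigma) at unmethylated and
    Normal(delta_modtype, sigma) at methylated sites, summarised per site as
    (coverage, sample mean, sample sd).  Sites with zero coverage are
    omitted; coverage-1 sites report sd 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(4)[3])
    cov_by_genome = dict(zip(spec.genome_ids(), spec.genome_coverage()))
    sigma = spec.sigma_log2

    frames: list[pd.DataFrame] = []
    for cid in sorted(contigs):
        gid = truth.contig_genome[cid]
        n = len(contigs[cid])
        # map methylated positions to the mod type of the system that planted them
        mod_type_of: dict[tuple[str, int], str] = {}
        for system in truth.systems.get(gid, ()):
            occ = occurrences(system.motif, contigs[cid])
            for pos, strand in occ:
                mp = methylated_position(system.motif, pos, strand)
                if mp in truth.methylated[cid][strand]:
                    mod_type_of[(strand, mp)] = system.motif.mod_type

        for strand in "+-":
            cov = rng.poisson(cov_by_genome[gid], size=n)
            keep = cov > 0
            positions = np.nonzero(keep)[0]
            cov = cov[keep]
            mu = np.zeros(len(positions))
            meth_pos = truth.methylated[cid][strand]
            if meth_pos:
                deltas = np.array(
                    [
                        spec.deltas.get(mod_type_of.get((strand, int(p)), ""), 0.0)
                        if int(p) in meth_pos
                        else 0.0
                        for p in positions
                    ]
                )
                mu = deltas
            mean = rng.normal(mu, sigma / np.sqrt(cov))
            sd = np.zeros(len(positions))
            df_ = cov - 1
            pos_df = df_ > 0
            sd[pos_df] = sigma * np.sqrt(rng.chisquare(df_[pos_df]) / df_[pos_df])
            frames.append(
                pd.DataFrame(
                    {
                        "contig_id": cid,
                        "position": positions,
                        "strand": strand,
                        "coverage": cov,
                        "mean_log2_ipd_ratio": mean,
                        "sd_log2_ipd_ratio": sd,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out


def generate_gene_table(spec: CommunitySpec, truth: TruthTable) -> pd.DataFrame:
    """A minimal gene table pairing each planted system with an MTase gene.

    One M gene per planted system (closest-match motif = the planted motif)
    and, for the first system of each genome, an adjacent R gene targeting
    the same sequence, so synthetic runs exercise RM-system detection.
    """
    rows = []
    first_contig = {}
    for cid, gid in sorted(truth.contig_genome.items()):
        first_contig.setdefault(gid, cid)
    for gid in sorted(truth.systems):
        for k, system in enumerate(truth.systems[gid]):
            m = system.motif
            motif_txt = m.pattern[: m.meth_offset] + "m" + m.pattern[m.meth_offset :]
            rows.append(
                {
                    "genome_id": gid,
                    "gene_id": f"{gid}_M{k + 1}",
                    "contig_id": first_contig[gid],
                    "gene_index": 10 * (k + 1),
                    "role": "M",
                    "rebase_hit": "synthetic",
                    "identity_pct": 100.0,
                    "motif": motif_txt,
                    "mod_type": m.mod_type,
                    "rm_type": "II",
                    "fused_re": 0,
                }
            )
            if k == 0:
                rows.append(
                    {
                        "genome_id": gid,
                        "gene_id": f"{gid}_R{k + 1}",
                        "contig_id": first_contig[gid],
                        "gene_index": 10 * (k + 1) + 1,
                        "role": "R",
                        "rebase_hit": "synthetic",
                        "identity_pct": 100.0,
                        "motif": m.pattern,
                        "mod_type": "unknown",
                        "rm_type": "II",
                        "fused_re": 0,
                    }
                )
    return pd.DataFrame(rows)


def generate_community(spec: CommunitySpec):
    """Convenience: genomes + truth + kinetics in one call."""
    contigs, truth = generate_genomes(spec)
    kinetics = simulate_kinetics(contigs, truth, spec)
    return contigs, truth, kinetics


def default_spec(seed: int = 0, **overrides) -> CommunitySpec:
    """The default desk-scale community.

    Four genomes of 200 kb with abundances 8:4:2:1 and community coverage
    mean 30 per strand, so the two abundant genomes exceed the 25x-per-strand
    detection guidance while the rare two drop below it.  Each genome carries
    its own common prokaryotic methylation systems at partial fractions.
    """
    def sysm(pattern: str, off: int, mod: str, frac: float) -> PlantedSystem:
        return PlantedSystem(IupacMotif(pattern, off, mod), frac)

    params = dict(
        n_genomes=4,
        genome_length_bp=[200_000] * 4,
        gc_content=[0.42, 0.55, 0.48, 0.62],
        abundance=[8.0, 4.0, 2.0, 1.0],
        systems=[
            [sysm("GANTC", 1, "m6A", 0.95), sysm("GCWGC", 1, "m4C", 0.85)],
            [sysm("GATC", 1, "m6A", 0.98), sysm("TTAA", 3, "m6A", 0.90)],
            [sysm("GAANNNNTTC", 1, "m6A", 0.90)],
            [sysm("AGCT", 2, "m4C", 0.80)],
        ],
        markov_order=1,
        coverage_mean=30.0,
        seed=seed,
    )
    params.update(overrides)
    return CommunitySpec(**params)
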