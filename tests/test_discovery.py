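"""Motif discovery: contexts, greedy extraction, filtering, summaries."""

import numpy as np
import pandas as pd
import pytest

from metamethyl.calling import call_sites
from metamethyl.discovery import (
    MotifSummary,
    discover,
    discover_genome_motifs,
    extract_contexts,
    filter_motifs,
    summarize,
)
from metamethyl.motifs import IupacMotif
from metamethyl.simulate import CommunitySpec, PlantedSystem, generate_community
from conftest import random_seq


def sites_frame(rows):
    return pd.DataFrame(
        rows, columns=["contig_id", "position", "strand", "qv", "coverage", "effect"]
    )


# ------------------------------------------------------------- contexts

def test_context_at_contig_edge_dropped():
    contigs = {"c": "ACGT" * 20}
    sites = sites_frame([("c", 0, "+", 50, 30, 1.0), ("c", 40, "+", 50, 30, 1.0)])
    ctx = extract_contexts(sites, contigs, flank=10)
    assert len(ctx) == 1
    assert len(ctx[0]) == 21


def test_minus_strand_context_is_reverse_complement():
    seq = "".join(np.array(list("ACGT"))[np.random.default_rng(0).integers(0, 4, 60)])
    contigs = {"c": seq}
    plus = extract_contexts(sites_frame([("c", 30, "+", 50, 30, 1)]), contigs, flank=5)[0]
    minus = extract_contexts(sites_frame([("c", 30, "-", 50, 30, 1)]), contigs, flank=5)[0]
    comp = str.maketrans("ACGT", "TGCA")
    assert minus == plus.translate(comp)[::-1]


def test_site_off_contig_rejected():
    with pytest.raises(ValueError):
        extract_contexts(sites_frame([("c", 99, "+", 50, 30, 1)]), {"c": "ACGT"}, flank=1)
    with pytest.raises(ValueError):
        extract_contexts(sites_frame([("zzz", 1, "+", 50, 30, 1)]), {"c": "ACGT"}, flank=1)


def test_planted_contexts_carry_motif_bases(small_community):
    """Contexts of called GANTC sites show G, T, C at offsets -1, +2, +3."""
    truth = small_community["truth"]
    contigs = {
        c: s for c, s in small_community["contigs"].items()
        if truth.contig_genome[c] == "g1"
    }
    sites = small_community["sites"]
    sites = sites[sites["contig_id"].isin(contigs)]
    ctx = extract_contexts(sites, contigs, flank=10, qv_min=30)
    assert len(ctx) > 100
    match = sum(
        c[9] == "G" and c[10] == "A" and c[12] == "T" and c[13] == "C" for c in ctx
    )
    # true GANTC contexts dominate; the remainder are borderline false calls
    # (random contexts match G.TC by chance ~1.5% of the time)
    assert match / len(ctx) > 0.7


# ------------------------------------------------------------- discover

def run_genome(spec):
    contigs, truth, kin = generate_community(spec)
    sites = call_sites(kin)
    return contigs, truth, kin, sites


def one_genome_spec(systems, seed, length=150_000):
    return CommunitySpec(
        n_genomes=1, genome_length_bp=[length], gc_content=[0.5],
        abundance=[1.0], systems=[systems], coverage_mean=30.0, seed=seed,
    )


def test_single_system_recovered_exactly():
    spec = one_genome_spec([PlantedSystem(IupacMotif("GANTC", 1, "m6A"), 0.95)], seed=21)
    contigs, truth, kin, sites = run_genome(spec)
    summ = discover_genome_motifs(sites, contigs, kin, genome_id="g1")
    assert [(s.motif.pattern, s.motif.meth_offset, s.motif.mod_type) for s in summ] == [
        ("GANTC", 1, "m6A")
    ]


def test_two_systems_recovered_without_spurious_motifs():
    spec = one_genome_spec(
        [
            PlantedSystem(IupacMotif("TTAA", 3, "m6A"), 0.9),
            PlantedSystem(IupacMotif("GATC", 1, "m6A"), 0.95),
        ],
        seed=22,
    )
    contigs, truth, kin, sites = run_genome(spec)
    summ = discover_genome_motifs(sites, contigs, kin, genome_id="g1")
    found = {(s.motif.pattern, s.motif.meth_offset) for s in summ}
    assert found == {("TTAA", 3), ("GATC", 1)}


def test_unmethylated_genome_yields_no_motifs():
    spec = one_genome_spec([], seed=23, length=100_000)
    contigs, truth, kin, sites = run_genome(spec)
    assert discover_genome_motifs(sites, contigs, kin, genome_id="g1") == []


def test_random_contexts_yield_no_motifs():
    rng = np.random.default_rng(5)
    contexts = [random_seq(rng, 21) for _ in range(2000)]
    assert discover(contexts) == []


def test_discover_rejects_mixed_length_contexts():
    with pytest.raises(ValueError):
        discover(["ACGTA", "ACG"] * 20)


# --------------------------------------------------------------- filter

def make_summary(n_occ, ratio_pct):
    n_meth = int(round(ratio_pct / 100 * n_occ))
    return MotifSummary(
        genome_id="g", motif=IupacMotif("GATC", 1, "m6A"),
        n_meth_sites=n_meth, n_motif_sites=n_occ,
        ratio_pct=ratio_pct, mean_qv=50.0, mean_subread_cov=30.0,
    )


@pytest.mark.parametrize(
    "n_occ,ratio,kept",
    [
        (49, 90.0, False),   # infrequent occurrences
        (5000, 0.5, False),  # very low methylation fraction
        (50, 1.0, True),     # both boundaries retained
        (50, 90.0, True),
        (5000, 1.0, True),
    ],
)
def test_filter_boundaries(n_occ, ratio, kept):
    out = filter_motifs([make_summary(n_occ, ratio)])
    assert (len(out) == 1) is kept


# ------------------------------------------------------------ summarize

@pytest.mark.parametrize(
    "n_meth,n_occ,expected",
    [(1813, 2070, 87.6), (72730, 77932, 93.3), (0, 100, 0.0)],
)
def test_ratio_definition(n_meth, n_occ, expected):
    s = MotifSummary(
        genome_id="g", motif=IupacMotif("GANTC", 1, "m6A"),
        n_meth_sites=n_meth, n_motif_sites=n_occ,
        ratio_pct=round(100.0 * n_meth / n_occ, 1),
        mean_qv=0.0, mean_subread_cov=0.0,
    )
    assert s.ratio_pct == expected


def test_summarize_counts_against_truth(small_community):
    truth = small_community["truth"]
    contigs = {
        c: s for c, s in small_community["contigs"].items()
        if truth.contig_genome[c] == "g1"
    }
    sites = small_community["sites"]
    sites = sites[sites["contig_id"].isin(contigs)]
    kin = small_community["kinetics"]
    kin = kin[kin["contig_id"].isin(contigs)]
    m = IupacMotif("GANTC", 1, "m6A")
    s = summarize(m, sites, contigs, kin, genome_id="g1", reference_patterns=["GANTC"])
    assert s.in_reference
    assert 0 < s.n_meth_sites <= s.n_motif_sites
    assert s.ratio_pct == round(100 * s.n_meth_sites / s.n_motif_sites, 1)
    # detection-adjusted fraction close to the planted 0.95
    assert abs(s.frac_est - 0.95) < 0.05


def test_summarize_zero_occurrences_is_error():
    m = IupacMotif("GGCGCC", 2, "m4C")
    with pytest.raises(ValueError):
        summarize(m, sites_frame([]), {"c": "ATATATAT" * 50}, genome_id="g1")


def test_summarize_additive_under_contig_splitting(small_community):
    """Splitting contigs does not change genome-level counts (junction-free)."""
    truth = small_community["truth"]
    contigs = {
        c: s for c, s in small_community["contigs"].items()
        if truth.contig_genome[c] == "g1"
    }
    sites = small_community["sites"]
    sites = sites[sites["contig_id"].isin(contigs)]
    m = IupacMotif("GANTC", 1, "m6A")
    whole = summarize(m, sites, contigs, genome_id="g1")

    # split each contig at a junction no GANTC occurrence spans, and remap
    # site coordinates
    from metamethyl.motifs import occurrences as occ_fn

    def spans_cut(seq, cut):
        lo = max(0, cut - 4)
        window = seq[lo : cut + 4]
        return any(lo + pos < cut < lo + pos + 5 for pos, _ in occ_fn(m, window))

    split_contigs = {}
    rows = []
    for cid, seq in contigs.items():
        cut = len(seq) // 2
        while spans_cut(seq, cut):
            cut += 1
        split_contigs[cid + ".a"] = seq[:cut]
        split_contigs[cid + ".b"] = seq[cut:]
        for r in sites[sites["contig_id"] == cid].itertuples():
            if r.position < cut:
                rows.append((cid + ".a", r.position, r.strand, r.qv, r.coverage, r.effect))
            else:
                rows.append((cid + ".b", r.position - cut, r.strand, r.qv, r.coverage, r.effect))
    split = summarize(m, sites_frame(rows), split_contigs, genome_id="g1")
    # motifs spanning a junction are lost from the occurrence count only if
    # the junction cuts one; junctions were chosen GANTC-free
    assert split.n_motif_sites == whole.n_motif_sites
    assert split.n_meth_sites == whole.n_meth_sites
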