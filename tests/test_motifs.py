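"""IUPAC motif algebra: expansion, reverse complement, matching, merging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metamethyl.motifs import (
    IUPAC,
    IupacMotif,
    dedupe_and_group,
    expand,
    occurrences,
    positionwise_intersection,
    rc_compatible,
    reverse_complement,
    similarity_mergeable,
)
from conftest import brute_occurrences, random_seq


def motif(pattern, off=None, mod=None):
    if off is None:
        off = pattern.index("A") if "A" in pattern else pattern.index("C")
    if mod is None:
        mod = "m6A" if "A" in expand(pattern[off]) else "m4C"
    return IupacMotif(pattern, off, mod)


# ---------------------------------------------------------------- expand

@pytest.mark.parametrize(
    "code,bases",
    [("W", {"A", "T"}), ("N", {"A", "C", "G", "T"}), ("A", {"A"}),
     ("H", {"A", "C", "T"}), ("B", {"C", "G", "T"}), ("D", {"A", "G", "T"})],
)
def test_expand_defined_sets(code, bases):
    assert expand(code) == bases


def test_expand_rejects_unknown_code():
    with pytest.raises(ValueError):
        expand("X")


# ---------------------------------------------------- motif construction

def test_motif_invariants_enforced():
    with pytest.raises(ValueError):
        IupacMotif("GANTC", 5, "m6A")  # offset out of range
    with pytest.raises(ValueError):
        IupacMotif("GANTC", 0, "m6A")  # G cannot carry m6A
    with pytest.raises(ValueError):
        IupacMotif("GAXTC", 1, "m6A")  # invalid letter
    with pytest.raises(ValueError):
        IupacMotif("GANTC", 1, "m7G")  # unknown modification type


# ----------------------------------------------------- reverse complement

def test_reverse_complement_duplex_pair():
    m = IupacMotif("AGCNNNNNNCAT", 0, "m6A")
    rc = reverse_complement(m)
    assert rc.pattern == "ATGNNNNNNGCT"
    assert rc.meth_offset == 11
    assert rc.mod_type == "m6A"


def test_reverse_complement_self_complementary():
    assert reverse_complement(IupacMotif("GANTC", 1, "m6A")).pattern == "GANTC"


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    pattern=st.text(alphabet=sorted(IUPAC), min_size=1, max_size=16),
    data=st.data(),
)
def test_reverse_complement_involution(pattern, data):
    off = data.draw(st.integers(0, len(pattern) - 1))
    m = IupacMotif(pattern, off, "unknown")
    assert reverse_complement(reverse_complement(m)) == m


# ----------------------------------------------------------- occurrences

def test_palindrome_counts_both_strands():
    hits = occurrences(IupacMotif("GATC", 1, "m6A"), "GGATCC")
    assert hits == [(1, "+"), (1, "-")]


def test_overlapping_degenerate_matches():
    m = IupacMotif("GCWGC", 1, "m4C")
    assert occurrences(m, "GCAGCTGC") == brute_occurrences(m, "GCAGCTGC")
    assert (0, "+") in occurrences(m, "GCAGCTGC")


def test_reverse_strand_only_match():
    hits = occurrences(IupacMotif("ACGAG", 3, "m6A"), "CTCGT")
    assert hits == [(0, "-")]


def test_empty_and_dirty_sequences():
    m = IupacMotif("GATC", 1, "m6A")
    assert occurrences(m, "") == []
    assert occurrences(m, "GAXC" * 5) == []


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**31 - 1),
    pattern=st.text(alphabet=sorted(IUPAC), min_size=2, max_size=16),
)
def test_occurrences_match_brute_force(seed, pattern):
    rng = np.random.default_rng(seed)
    seq = random_seq(rng, 300)
    m = IupacMotif(pattern, 0, "unknown")
    assert occurrences(m, seq) == brute_occurrences(m, seq)


def test_occurrences_match_brute_force_10kb(survey_motif_list):
    """Window oracle agreement for real survey motifs on a 10 kb sequence."""
    rng = np.random.default_rng(7)
    seq = random_seq(rng, 10_000)
    for _, m in survey_motif_list[:12]:
        assert occurrences(m, seq) == brute_occurrences(m, seq)


def test_palindromic_motif_equal_strand_counts():
    rng = np.random.default_rng(3)
    seq = random_seq(rng, 5_000)
    for m in (IupacMotif("GATC", 1, "m6A"), IupacMotif("TTAA", 3, "m6A"),
              IupacMotif("GAANNNNTTC", 1, "m6A")):
        hits = occurrences(m, seq)
        fwd = sum(s == "+" for _, s in hits)
        assert fwd == len(hits) - fwd


# --------------------------------------------- positionwise intersection

def test_intersection_single_conflict():
    cols = positionwise_intersection(motif("GMAGCTKC", 4), motif("HCAGCTKC", 4))
    assert sum(c.is_conflict for c in cols) == 1
    assert cols[0].is_conflict  # G vs H at the first aligned position
    assert not any(c.is_overhang for c in cols)


def test_intersection_identity():
    m = motif("GMAGCTKC", 4)
    cols = positionwise_intersection(m, m)
    assert not any(c.is_conflict or c.is_overhang for c in cols)


def test_intersection_with_overhang():
    cols = positionwise_intersection(motif("GMAGCTKC", 4), motif("BGMAGCTGD", 5))
    assert sum(c.is_conflict for c in cols) == 1  # C vs D
    assert sum(c.is_overhang for c in cols) == 1  # leading B


# --------------------------------------------------------- rc_compatible

@pytest.mark.parametrize(
    "p1,o1,p2,o2,expected",
    [
        ("AGCNNNNNNCAT", 0, "ATGNNNNNNGCT", 0, True),
        ("CAANNNNNNNNCTTG", 2, "CAAGNNNNNNNDTTG", 2, True),
        ("GYTANNNNNNNTTRG", 3, "CYAANNNNNNNTAVCH", 3, True),
        ("GANTC", 1, "TTAA", 3, False),
        ("AGCNNNNNNCAT", 0, "AGCNNNNNNGTG", 0, False),
    ],
)
def test_rc_compatible_pairs(p1, o1, p2, o2, expected):
    assert rc_compatible(IupacMotif(p1, o1, "m6A"), IupacMotif(p2, o2, "m6A")) is expected


def test_rc_compatible_requires_same_mod_class():
    m1 = IupacMotif("GATC", 1, "m6A")
    assert not rc_compatible(m1, IupacMotif("GATC", 0, "m4C"))


# -------------------------------------------------- similarity_mergeable

@pytest.mark.parametrize(
    "p1,o1,p2,o2,expected",
    [
        ("GMAGCTKC", 4, "HCAGCTKC", 4, True),   # one conflict
        ("GMAGCTKC", 4, "BGMAGCTGD", 5, True),  # one conflict + 1-base overhang
        ("AGCNNNNNNCAT", 0, "AGCNNNNNNGTG", 0, False),
        ("AGGNNNNNRTTT", 0, "AGGNNNNNCTAA", 0, False),
    ],
)
def test_similarity_mergeable_pairs(p1, o1, p2, o2, expected):
    mod = "m4C" if "C" in (p1[o1], p2[o2]) and p1[o1] == "C" else "m6A"
    m1 = IupacMotif(p1, o1, mod)
    m2 = IupacMotif(p2, o2, mod)
    assert similarity_mergeable(m1, m2) is expected


def test_similarity_requires_same_mod_type():
    assert not similarity_mergeable(
        IupacMotif("GMAGCTKC", 4, "m4C"), IupacMotif("GMAGCTKC", 4, "m5C")
    )


# ------------------------------------------------------ dedupe_and_group

def test_dedupe_survey_counts(survey_motif_list, survey_motifs_df):
    reference = survey_motifs_df.loc[
        survey_motifs_df["in_rebase"].eq("Yes"), "motif"
    ].unique()
    groups, n_distinct, n_novel = dedupe_and_group(survey_motif_list, reference)
    assert n_distinct == 22
    assert n_novel == 9
    kinds = {}
    for g in groups:
        if not g.reference_known:
            kinds[g.kind] = kinds.get(g.kind, 0) + 1
    # five complementary pairs, one near-duplicate trio, three singletons
    assert kinds == {"rc_pair": 5, "similarity_cluster": 1, "single": 3}


def test_dedupe_shared_known_motif():
    m = IupacMotif("GANTC", 1, "m6A")
    groups, n_distinct, n_novel = dedupe_and_group(
        [("g1", m), ("g2", m), ("g3", m)], ["GANTC"]
    )
    assert (n_distinct, n_novel) == (1, 0)
    assert groups[0].reference_known


def test_dedupe_novel_rc_pair():
    m1 = IupacMotif("AGCNNNNNNCAT", 0, "m6A")
    m2 = IupacMotif("ATGNNNNNNGCT", 0, "m6A")
    _, n_distinct, n_novel = dedupe_and_group([("g1", m1), ("g1", m2)], ["GANTC"])
    assert (n_distinct, n_novel) == (2, 1)


def test_dedupe_is_order_invariant(survey_motif_list, survey_motifs_df):
    reference = survey_motifs_df.loc[
        survey_motifs_df["in_rebase"].eq("Yes"), "motif"
    ].unique()
    rng = np.random.default_rng(0)
    base = dedupe_and_group(survey_motif_list, reference)
    for _ in range(3):
        shuffled = list(survey_motif_list)
        rng.shuffle(shuffled)
        groups, n_distinct, n_novel = dedupe_and_group(shuffled, reference)
        assert (n_distinct, n_novel) == (base[1], base[2])
        assert [g.patterns for g in groups] == [g.patterns for g in base[0]]


def test_dedupe_rejects_empty_input():
    with pytest.raises(ValueError):
        dedupe_and_group([], [])


def test_subsumption_does_not_confer_known_status():
    # GANTC is degenerate-subsumed by GANTC's generalisation GNNTC, but only
    # exact equality (up to rc) counts as known
    m = IupacMotif("GANTC", 1, "m6A")
    _, _, n_novel = dedupe_and_group([("g1", m)], ["GNNTC"])
    assert n_novel == 1
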