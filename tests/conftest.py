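import numpy as np
import pytest

from metamethyl.calling import call_sites
from metamethyl.motifs import IUPAC, IupacMotif, rc_pattern
from metamethyl.simulate import CommunitySpec, PlantedSystem, generate_community
from metamethyl import fixtures as fx


def brute_occurrences(m: IupacMotif, seq: str) -> list[tuple[int, str]]:
    """Window-by-window occurrence oracle, independent of the regex path."""
    hits = []
    k = len(m.pattern)
    seq = seq.upper()
    for strand, pat in (("+", m.pattern), ("-", rc_pattern(m.pattern))):
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if all(c in "ACGT" for c in w) and all(
                w[j] in IUPAC[pat[j]] for j in range(k)
            ):
                hits.append((i, strand))
    return sorted(hits)


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


@pytest.fixture(scope="session")
def survey_motifs_df():
    return fx.load_survey_motifs()


@pytest.fixture(scope="session")
def survey_motif_list(survey_motifs_df):
    return fx.survey_motif_list(survey_motifs_df)


@pytest.fixture(scope="session")
def survey_records():
    return fx.survey_mtase_records()


@pytest.fixture(scope="session")
def small_spec():
    """Two 60 kb genomes at flat 30x/strand with one m6A system each."""
    return CommunitySpec(
        n_genomes=2,
        genome_length_bp=[60_000, 60_000],
        gc_content=[0.45, 0.55],
        abundance=[1.0, 1.0],
        systems=[
            [PlantedSystem(IupacMotif("GANTC", 1, "m6A"), 0.95)],
            [PlantedSystem(IupacMotif("GATC", 1, "m6A"), 0.90)],
        ],
        coverage_mean=30.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_community(small_spec):
    contigs, truth, kinetics = generate_community(small_spec)
    sites = call_sites(kinetics)
    return {
        "spec": small_spec,
        "contigs": contigs,
        "truth": truth,
        "kinetics": kinetics,
        "sites": sites,
    }
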