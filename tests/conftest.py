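import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from te_karyoscan.annotations_io import (
    CountMatrix,
    GeneModel,
    GeneSet,
    GenomicInterval,
    RepeatCopy,
    RepeatCopySet,
    SampleSheet,
)
from te_karyoscan.synthetic_data import SimDesign, simulate_counts, simulate_genome


def make_copies(spec):
    """Build a RepeatCopySet from (chrom, start, end, strand, subfamily) tuples."""
    return RepeatCopySet(
        [
            RepeatCopy(f"c{i}", GenomicInterval(ch, s, e, st), sub)
            for i, (ch, s, e, st, sub) in enumerate(spec)
        ]
    )


def make_genes(spec):
    """Build a GeneSet from (gene_id, chrom, start, end, strand) tuples."""
    return GeneSet(
        [GeneModel(g, GenomicInterval(ch, s, e, st)) for g, ch, s, e, st in spec]
    )


def make_counts(data: dict, kind="gene", normalized=False):
    """Build a CountMatrix from {feature: {sample: count}} nested dicts."""
    df = pd.DataFrame(data).T.astype(float if normalized else int)
    return CountMatrix(df, feature_kind=kind, normalized=normalized)


@pytest.fixture(scope="session")
def small_design():
    return SimDesign(
        n_genes=60,
        n_subfamilies=30,
        copies_per_subfamily=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_design):
    genome = simulate_genome(small_design)
    counts = simulate_counts(small_design, genome)
    return genome, counts


@pytest.fixture(scope="session")
def study_sim():
    """A study-scale simulation (6/6/8/4 cohort, defaults)."""
    design = SimDesign(seed=2024)
    genome = simulate_genome(design)
    counts = simulate_counts(design, genome)
    return design, genome, counts


def two_group_sheet(n_a, n_b, group_a="XX", group_b="XY"):
    sex = {"XX": "female", "XY": "male", "XXY": "male", "XYY": "male"}
    ids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    karyo = [group_a] * n_a + [group_b] * n_b
    return SampleSheet(
        pd.DataFrame(
            {"karyotype": karyo, "sex": [sex[k] for k in karyo]},
            index=pd.Index(ids, name="sample_id"),
        )
    )
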