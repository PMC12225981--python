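"""Chromosome-enrichment classification of TE subfamilies.

For each subfamily, the share of its genomic copies on a focal chromosome
(the Y, by default) is compared with the chromosome's length share of the
genome using a two-sided exact binomial test (minimum-likelihood two-sided
method). After BH adjustment across all tested subfamilies, subfamilies are
partitioned into enriched / depleted / neither, alongside three predicate
groups (no copies on Y, no copies on X, no copies on either) that are
independent of the test.

Default lengths are the printed kb values: Y = 57,200 kb out of a
3,088,200 kb genome, giving the 1.85% expectation (57200/3088200).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotations_io import AnnotationError, RepeatCopySet
from .differential_expression import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "ChromLengths",
    "EnrichmentRecord",
    "expected_proportion",
    "binomial_two_sided_p",
    "binomial_focal_test",
    "classify_all",
    "enriched_share_test",
]

DEFAULT_LENGTHS_KB: dict[str, float] = {"chrY": 57_200.0, "chrX": 156_040.0}
DEFAULT_TOTAL_KB = 3_088_200.0


@dataclass(frozen=True)
class ChromLengths:
    """Chromosome lengths (kb) and the genome total used for the expectation."""

    lengths: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LENGTHS_KB))
    total: float = DEFAULT_TOTAL_KB

    def __post_init__(self) -> None:
        if self.total <= 0 or any(v <= 0 for v in self.lengths.values()):
            raise AnnotationError("chromosome lengths must be positive")
        if any(v > self.total for v in self.lengths.values()):
            raise AnnotationError("chromosome length cannot exceed the genome total")


@dataclass
class EnrichmentRecord:
    subfamily: str
    n_total: int
    n_on_focal: int
    expected_prop: float
    p: float
    padj: float
    status: str  # enriched | depleted | neither


def expected_proportion(lengths: ChromLengths, focal: str) -> float:
    """Length share of the focal chromosome: length(focal) / genome total."""
    if focal not in lengths.lengths:
        raise AnnotationError(f"chromosome {focal!r} not in length table")
    return lengths.lengths[focal] / lengths.total


def binomial_two_sided_p(k: int, n: int, p0: float, method: str = "minlike") -> float:
    """Two-sided exact binomial p-value.

    ``minlike`` sums the probabilities of all outcomes no more likely than
    the observed one (the default of R's binom.test); ``double`` doubles the
    smaller one-sided tail. Both are capped at 1.
    """
    if not (0 <= k <= n) or n < 1:
        raise AnnotationError(f"invalid binomial observation k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise AnnotationError("expected proportion must be in (0, 1)")
    if method == "minlike":
        return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)
    if method == "double":
        lower = stats.binom.cdf(k, n, p0)
        upper = stats.binom.sf(k - 1, n, p0)
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise AnnotationError(f"unknown two-sided method {method!r}")


def binomial_focal_test(
    copies: RepeatCopySet,
    subfamily: str,
    expected: float,
    focal: str = "chrY",
    method: str = "minlike",
) -> EnrichmentRecord:
    """Exact binomial test of one subfamily's copy share on the focal chromosome."""
    members = [c for c in copies if c.subfamily == subfamily]
    if not members:
        raise AnnotationError(f"subfamily {subfamily!r} has no copies; not testable")
    n = len(members)
    k = sum(1 for c in members if c.interval.chrom == focal)
    p = binomial_two_sided_p(k, n, expected, method=method)
    return EnrichmentRecord(subfamily, n, k, expected, p, np.nan, "neither")


def classify_all(
    copies: RepeatCopySet,
    lengths: ChromLengths | None = None,
    focal: str = "chrY",
    other: str = "chrX",
    alpha: float = 0.05,
    method: str = "minlike",
) -> tuple[list[EnrichmentRecord], dict[str, set[str]]]:
    """Classify every subfamily with ≥1 copy and build the six groups.

    Returns the BH-adjusted records plus a partition dictionary with keys
    ``enriched`` / ``depleted`` / ``neither`` (disjoint, covering all tested
    subfamilies) and the membership predicates ``no_focal_copies`` /
    ``no_other_copies`` / ``no_focal_and_no_other_copies`` which may overlap
    the test-based groups.
    """
    if lengths is None:
        lengths = ChromLengths()
    chroms = copies.chromosomes()
    if chroms and focal not in chroms:
        logger.warning("no copies on focal chromosome %s in the annotation", focal)
    expected = expected_proportion(lengths, focal)
    subfamilies = sorted({c.subfamily for c in copies})
    records = [
        binomial_focal_test(copies, sub, expected, focal=focal, method=method)
        for sub in subfamilies
    ]
    adj = bh_adjust([r.p for r in records])
    for rec, padj in zip(records, adj):
        rec.padj = padj
        observed = rec.n_on_focal / rec.n_total
        if padj < alpha and observed > rec.expected_prop:
            rec.status = "enriched"
        elif padj < alpha and observed < rec.expected_prop:
            rec.status = "depleted"
        else:
            rec.status = "neither"

    on_other: dict[str, int] = {s: 0 for s in subfamilies}
    for c in copies:
        if c.interval.chrom == other:
            on_other[c.subfamily] += 1
    groups = {
        "enriched": {r.subfamily for r in records if r.status == "enriched"},
        "depleted": {r.subfamily for r in records if r.status == "depleted"},
        "neither": {r.subfamily for r in records if r.status == "neither"},
        "no_focal_copies": {r.subfamily for r in records if r.n_on_focal == 0},
        "no_other_copies": {s for s in subfamilies if on_other[s] == 0},
    }
    groups["no_focal_and_no_other_copies"] = (
        groups["no_focal_copies"] & groups["no_other_copies"]
    )
    return records, groups


def enriched_share_test(
    selected_subfamilies: set[str],
    records: list[EnrichmentRecord],
    background_share: float,
) -> float:
    """One-sided binomial test: are enriched subfamilies over-represented?

    Tests whether the number of focal-enriched subfamilies among a selected
    set (e.g. the significantly upregulated ones) exceeds what the
    background share of enriched subfamilies predicts.
    """
    if not selected_subfamilies:
        raise AnnotationError("empty selection")
    by_name = {r.subfamily: r for r in records}
    missing = selected_subfamilies - set(by_name)
    if missing:
        raise AnnotationError(f"selected subfamilies without records: {sorted(missing)[:5]}")
    n = len(selected_subfamilies)
    k = sum(1 for s in selected_subfamilies if by_name[s].status == "enriched")
    return float(stats.binomtest(k, n, background_share, alternative="greater").pvalue)


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subfamily": [r.subfamily for r in records],
            "n_total": [r.n_total for r in records],
            "n_on_focal": [r.n_on_focal for r in records],
            "expected_prop": [r.expected_prop for r in records],
            "p": [r.p for r in records],
            "padj": [r.padj for r in records],
            "status": [r.status for r in records],
        }
    )
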