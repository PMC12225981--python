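"""Global TE-expression proportion and the group comparison tests.

The headline statistic is, per sample, the sum of normalized TE-subfamily
counts divided by the total normalized counts over genes plus all TE
subfamilies. The denominator always includes every TE subfamily, even when
the numerator is restricted to a class (LTR, SINE, ...) or a named group
(HERVK, AluY, ...), so subset proportions are additive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .annotations_io import AnnotationError, CountMatrix, RosettaMap, SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "TeSubset",
    "GroupComparisonResult",
    "DEFAULT_GROUP_PREFIXES",
    "build_te_subsets",
    "global_te_proportion",
    "pairwise_group_test",
    "multi_group_test",
    "adjusted_sex_effect_test",
    "flag_aneuploidy_suspects",
]

#: Name-prefix rules assigning subfamilies to the transcriptionally active
#: human TE groups; editable by callers that ship their own rule table.
DEFAULT_GROUP_PREFIXES: dict[str, tuple[str, ...]] = {
    "HERVK": ("HERVK", "HERV-K", "LTR5"),
    "AluS": ("AluS",),
    "AluY": ("AluY",),
    "L1": ("L1",),
    "SVA": ("SVA",),
}


@dataclass(frozen=True)
class TeSubset:
    """A named set of TE subfamilies (a class, superfamily, or group)."""

    name: str
    members: frozenset[str] = field(default_factory=frozenset)
    is_all: bool = False

    @classmethod
    def all(cls) -> "TeSubset":
        return cls("ALL", frozenset(), is_all=True)


@dataclass
class GroupComparisonResult:
    subset: str
    test: str
    values: pd.Series  # per-sample statistic
    groups: pd.Series  # per-sample group labels
    pairwise_p: dict[tuple[str, str], float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subset": self.subset, "group_a": a, "group_b": b, "test": self.test, "p": p}
            for (a, b), p in sorted(self.pairwise_p.items())
        ]
        return pd.DataFrame(rows)


def build_te_subsets(
    rosetta: RosettaMap,
    group_prefixes: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, TeSubset]:
    """Derive the standard subsets from rosetta lineage plus name prefixes.

    Classes/superfamilies (LTR, SINE, LINE, SVA, DNA) come from the lineage
    column; named active groups (HERVK, AluS, L1, AluY) are assigned by
    subfamily-name prefix, mirroring how repeat libraries name them.
    """
    if group_prefixes is None:
        group_prefixes = DEFAULT_GROUP_PREFIXES
    subsets = {"ALL": TeSubset.all()}
    for te_class in ("LTR", "SINE", "LINE", "SVA", "DNA"):
        members = rosetta.members_of_class(te_class)
        subsets[te_class] = TeSubset(te_class, frozenset(members))
    known = rosetta.subfamilies
    for group, prefixes in group_prefixes.items():
        members = {s for s in known if s.startswith(tuple(prefixes))}
        if group in subsets:  # SVA appears as both a class and a group
            members |= subsets[group].members
        subsets[group] = TeSubset(group, frozenset(members))
    return subsets


def global_te_proportion(
    normalized: CountMatrix, subset: TeSubset | None = None
) -> pd.Series:
    """Per-sample share of (subset) TE counts among all normalized counts.

    The denominator is genes + all TE subfamilies regardless of the subset.
    """
    if not normalized.normalized:
        raise AnnotationError("global TE proportion requires a normalized matrix")
    kinds = normalized.kinds()
    te_rows = normalized.data.loc[kinds == "te_subfamily"]
    gene_rows = normalized.data.loc[kinds == "gene"]
    if te_rows.empty or gene_rows.empty:
        raise AnnotationError("matrix must contain both gene and te_subfamily rows")
    total = gene_rows.sum(axis=0) + te_rows.sum(axis=0)
    if (total <= 0).any():
        bad = list(total.index[total <= 0])
        raise AnnotationError(f"zero total normalized count for samples {bad[:5]}")
    if subset is None or subset.is_all:
        numer = te_rows.sum(axis=0)
    else:
        members = [s for s in te_rows.index if s in subset.members]
        numer = te_rows.loc[members].sum(axis=0) if members else pd.Series(0.0, index=te_rows.columns)
    return numer / total


def _rank_sum_p(x: np.ndarray, y: np.ndarray, exact_max: int = 8) -> float:
    """Two-sided Wilcoxon rank-sum p.

    Exact enumeration when both groups have ≤ ``exact_max`` observations and
    there are no ties; otherwise the normal approximation with tie
    correction (and continuity correction), matching common practice.
    """
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= exact_max and len(y) <= exact_max and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def pairwise_group_test(
    values: pd.Series, groups: pd.Series, subset_name: str = "ALL"
) -> GroupComparisonResult:
    """Two-sided rank-sum test for every unordered pair of groups."""
    groups = groups.reindex(values.index)
    if groups.isna().any():
        raise AnnotationError("group labels missing for some samples")
    level_order = list(dict.fromkeys(groups))
    sizes = groups.value_counts()
    small = sizes[sizes < 2]
    if len(level_order) < 2:
        raise AnnotationError("need at least two groups")
    if not small.empty:
        raise AnnotationError(f"groups with <2 samples: {list(small.index)}")
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in combinations(level_order, 2):
        xa = values[groups == a].to_numpy(dtype=float)
        xb = values[groups == b].to_numpy(dtype=float)
        pairwise[(a, b)] = _rank_sum_p(xa, xb)
    return GroupComparisonResult(subset_name, "wilcoxon_rank_sum", values, groups, pairwise)


def multi_group_test(values: pd.Series, groups: pd.Series) -> float:
    """Kruskal–Wallis chi-square p across ≥2 groups (tie-corrected)."""
    groups = groups.reindex(values.index)
    samples = [values[groups == g].to_numpy(dtype=float) for g in pd.unique(groups)]
    if len(samples) < 2:
        raise AnnotationError("need at least two groups")
    flat = values.to_numpy(dtype=float)
    if np.all(flat == flat[0]):
        logger.info("multi_group_test: all values identical; degenerate p = 1")
        return 1.0
    return float(stats.kruskal(*samples).pvalue)


def adjusted_sex_effect_test(values: pd.Series, sheet: SampleSheet) -> float:
    """p-value for a sex effect adjusted on age group (linear model).

    Least-squares fit of ``value ~ sex + age_group``; returns the two-sided
    t-test p on the sex coefficient. When age_group is constant this
    collapses to a two-sample t-test on sex.
    """
    import statsmodels.api as sm

    sex = sheet.column("sex").reindex(values.index)
    age = sheet.column("age_group").reindex(values.index)
    if sex.isna().any() or age.isna().any():
        raise AnnotationError("sex/age_group missing for some samples")
    if sex.nunique() < 2:
        raise AnnotationError("both sexes must be present")
    sex_dummy = (sex == "male").astype(float)
    parts = [pd.Series(1.0, index=values.index, name="intercept"), sex_dummy.rename("sex_male")]
    if age.nunique() > 1:
        age_dummies = pd.get_dummies(age, prefix="age", drop_first=True, dtype=float)
        parts.append(age_dummies)
    X = pd.concat(parts, axis=1)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise AnnotationError("rank-deficient design (sex confounded with age group?)")
    fit = sm.OLS(values.astype(float), X).fit()
    return float(fit.pvalues["sex_male"])


def flag_aneuploidy_suspects(
    gene_counts: CountMatrix,
    sheet: SampleSheet,
    marker_x: str,
    marker_y: str,
    x_fraction: float = 0.5,
    y_min: float = 1.0,
) -> pd.Series:
    """Flag males whose X/Y marker-gene expression suggests aneuploidy.

    A male is flagged when the X-inactivation marker (e.g. XIST) exceeds
    ``x_fraction`` of the female median — i.e. it is expressed like a
    two-X individual — while the Y marker (e.g. USP9Y) is still expressed
    (≥ ``y_min``), indicating a retained Y. Females are never flagged.
    """
    for marker in (marker_x, marker_y):
        if marker not in gene_counts.data.index:
            raise AnnotationError(f"marker gene {marker!r} absent from matrix")
    sex = sheet.column("sex").reindex(gene_counts.sample_ids)
    if sex.isna().any():
        raise AnnotationError("sex missing for some samples")
    x_expr = gene_counts.data.loc[marker_x]
    y_expr = gene_counts.data.loc[marker_y]
    females = sex == "female"
    if not females.any():
        raise AnnotationError("no female samples to anchor the X-marker threshold")
    female_median = float(x_expr[females].median())
    threshold = x_fraction * female_median
    flags = (sex == "male") & (x_expr > threshold) & (y_expr >= y_min)
    return flags.astype(bool)
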