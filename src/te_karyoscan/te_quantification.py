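"""Copy → subfamily aggregation and the non-TE repeat exclusion filter.

Per-copy read counts are regrouped into per-subfamily counts through the
rosetta lookup; this is purely additive, so total counts per sample are
conserved. A default exclusion list removes the 24 repeat subfamilies that
are not transposable elements (snRNA, scRNA, satellite and rRNA repeats),
taking a 1,270-subfamily repeat library down to the 1,246 TE subfamilies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .annotations_io import AnnotationError, CountMatrix, RosettaMap

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_EXCLUDED_SUBFAMILIES",
    "ExclusionList",
    "aggregate_copy_counts",
    "filter_subfamilies",
    "drop_all_zero_features",
]

#: Repeat subfamilies that are snRNA, snpRNA, scRNA, satellite or rRNA
#: repeats rather than transposable elements. "5S" is kept as a single name.
DEFAULT_EXCLUDED_SUBFAMILIES: tuple[str, ...] = (
    "7SLRNA",
    "7SK",
    "LSAU",
    "D20S16",
    "REP522",
    "SATR1",
    "SATR2",
    "ACRO1",
    "ALR/Alpha",
    "BSR/Beta",
    "CER",
    "6kbHsap",
    "TAR1",
    "SST1",
    "MSR1",
    "SAR",
    "GA-rich",
    "G-rich",
    "A-rich",
    "HY1",
    "HY3",
    "HY4",
    "HY5",
    "5S",
)


@dataclass(frozen=True)
class ExclusionList:
    """A set of subfamily names to drop before TE-level analysis."""

    names: frozenset[str] = field(
        default_factory=lambda: frozenset(DEFAULT_EXCLUDED_SUBFAMILIES)
    )

    @classmethod
    def from_iterable(cls, names: Iterable[str]) -> "ExclusionList":
        return cls(frozenset(names))

    @classmethod
    def from_file(cls, path) -> "ExclusionList":
        with open(path) as fh:
            names = [line.strip() for line in fh if line.strip()]
        return cls.from_iterable(names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.names)


def aggregate_copy_counts(
    copy_counts: CountMatrix, rosetta: RosettaMap
) -> CountMatrix:
    """Regroup per-copy counts into per-subfamily counts.

    Every copy id in the matrix must be present in the rosetta map; the
    subfamily count is the per-sample sum over its member copies. Subfamilies
    with no copy present in the matrix do not appear in the output.
    """
    if copy_counts.feature_kind != "te_copy":
        raise AnnotationError(
            f"expected a te_copy matrix, got {copy_counts.feature_kind}"
        )
    unmapped = [c for c in copy_counts.feature_ids if c not in rosetta.copy_to_subfamily]
    if unmapped:
        raise AnnotationError(
            f"{len(unmapped)} copy ids missing from rosetta map: {unmapped[:10]}"
        )
    groups = pd.Series(
        [rosetta.copy_to_subfamily[c] for c in copy_counts.feature_ids],
        index=copy_counts.data.index,
    )
    agg = copy_counts.data.groupby(groups, sort=True).sum()
    agg.index.name = None
    return CountMatrix(agg, feature_kind="te_subfamily", normalized=copy_counts.normalized)


def filter_subfamilies(
    subfamily_counts: CountMatrix, exclude: ExclusionList | None = None
) -> CountMatrix:
    """Drop rows whose subfamily name is on the exclusion list.

    Excluding a name absent from the matrix is a no-op (logged).
    """
    if exclude is None:
        exclude = ExclusionList()
    present = set(subfamily_counts.feature_ids)
    absent = sorted(exclude.names - present)
    if absent:
        logger.info("exclusion list: %d names not present (no-op): %s",
                    len(absent), absent[:5])
    keep = [f for f in subfamily_counts.feature_ids if f not in exclude]
    return subfamily_counts.replace_data(subfamily_counts.data.loc[keep])


def drop_all_zero_features(matrix: CountMatrix) -> CountMatrix:
    """Remove features with zero counts in every sample."""
    mask = (matrix.data.to_numpy() > 0).any(axis=1) if len(matrix.data) else np.array([], bool)
    keep = matrix.data.index[mask]
    return matrix.replace_data(matrix.data.loc[keep])
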