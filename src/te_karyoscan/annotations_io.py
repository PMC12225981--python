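"""Readers, writers, and the shared genomic data model.

All intervals are held internally as 0-based half-open (BED-style)
coordinates regardless of the on-disk dialect; converters live at the file
boundary so the downstream overlap arithmetic never mixes conventions.
Chromosome names are taken verbatim — no ``chr``-prefix normalisation — and
a mismatch between files surfaces as an explicit validation error rather
than a silently empty overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "RepeatCopy",
    "RepeatCopySet",
    "GeneModel",
    "GeneSet",
    "RosettaMap",
    "CountMatrix",
    "SampleSheet",
    "read_repeat_annotation",
    "read_gene_annotation",
    "read_count_matrix",
    "write_count_matrix",
    "read_rosetta",
    "write_rosetta",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_bed",
]

VALID_KARYOTYPES = ("XX", "XY", "XXY", "XYY")
#: karyotype → expected phenotypic sex (XX female; any Y male)
KARYOTYPE_SEX = {"XX": "female", "XY": "male", "XXY": "male", "XYY": "male"}
TE_CLASSES = ("LTR", "SINE", "LINE", "SVA", "DNA", "other")


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AnnotationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share ≥1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class RepeatCopy:
    """One genomic insertion copy of a repeat subfamily."""

    copy_id: str
    interval: GenomicInterval
    subfamily: str

    def __post_init__(self) -> None:
        if not self.subfamily:
            raise AnnotationError(f"copy {self.copy_id}: subfamily must be non-empty")


@dataclass
class RepeatCopySet:
    """A collection of repeat copies with unique identifiers."""

    copies: list[RepeatCopy]

    def __post_init__(self) -> None:
        ids = [c.copy_id for c in self.copies]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AnnotationError(f"duplicate copy ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.copies)

    def __iter__(self):
        return iter(self.copies)

    def subset(self, subfamilies: Iterable[str]) -> "RepeatCopySet":
        wanted = set(subfamilies)
        return RepeatCopySet([c for c in self.copies if c.subfamily in wanted])

    def chromosomes(self) -> set[str]:
        return {c.interval.chrom for c in self.copies}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [c.interval.chrom for c in self.copies],
                "start": [c.interval.start for c in self.copies],
                "end": [c.interval.end for c in self.copies],
                "copy_id": [c.copy_id for c in self.copies],
                "strand": [c.interval.strand for c in self.copies],
                "subfamily": [c.subfamily for c in self.copies],
            }
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene body interval; strand is mandatory so the TSS is defined."""

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id}: strand {self.interval.strand!r} — TSS undefined"
            )

    @property
    def tss(self) -> int:
        """Transcription start site: interval start on +, interval end on −."""
        return self.interval.start if self.interval.strand == "+" else self.interval.end


@dataclass
class GeneSet:
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AnnotationError(f"duplicate gene ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def subset(self, gene_ids: Iterable[str]) -> "GeneSet":
        wanted = set(gene_ids)
        missing = wanted - {g.gene_id for g in self.genes}
        if missing:
            raise AnnotationError(f"unknown gene ids: {sorted(missing)[:5]}")
        return GeneSet([g for g in self.genes if g.gene_id in wanted])

    def chromosomes(self) -> set[str]:
        return {g.interval.chrom for g in self.genes}


@dataclass
class RosettaMap:
    """Copy-identifier → subfamily lookup plus subfamily lineage labels.

    ``subfamily_lineage`` maps each subfamily to a ``(class, family)`` pair
    where class is drawn from the controlled vocabulary LTR / SINE / LINE /
    SVA / DNA / other. ``excluded`` flags non-TE repeat subfamilies (snRNA,
    satellites, rRNA, ...) that the quantification filter removes.
    """

    copy_to_subfamily: dict[str, str]
    subfamily_lineage: dict[str, tuple[str, str]] = field(default_factory=dict)
    excluded: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for sub, (cls, _fam) in self.subfamily_lineage.items():
            if cls not in TE_CLASSES:
                raise AnnotationError(
                    f"subfamily {sub}: class {cls!r} not in {TE_CLASSES}"
                )

    @property
    def subfamilies(self) -> set[str]:
        return set(self.copy_to_subfamily.values()) | set(self.subfamily_lineage)

    def class_of(self, subfamily: str) -> str:
        return self.subfamily_lineage.get(subfamily, ("other", ""))[0]

    def members_of_class(self, te_class: str) -> set[str]:
        return {s for s, (c, _f) in self.subfamily_lineage.items() if c == te_class}


@dataclass
class CountMatrix:
    """A features × samples count table.

    ``feature_kind`` labels the rows (``gene``, ``te_copy``,
    ``te_subfamily``) or is ``mixed`` for stacked matrices, in which case
    ``row_kinds`` carries the per-row label. Raw matrices are integer
    valued; normalized ones are real valued with ``normalized=True``.
    """

    data: pd.DataFrame
    feature_kind: str
    normalized: bool = False
    row_kinds: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.feature_kind not in ("gene", "te_copy", "te_subfamily", "mixed"):
            raise AnnotationError(f"unknown feature_kind {self.feature_kind!r}")
        if self.feature_kind == "mixed" and self.row_kinds is None:
            raise AnnotationError("mixed matrix requires row_kinds")
        if self.row_kinds is not None and not self.row_kinds.index.equals(
            self.data.index
        ):
            raise AnnotationError("row_kinds index must match feature ids")
        if self.data.index.has_duplicates:
            raise AnnotationError("duplicate feature ids")
        if self.data.columns.has_duplicates:
            raise AnnotationError("duplicate sample ids")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise AnnotationError("counts must be numeric")
        if values.size and (values < 0).any():
            raise AnnotationError("counts must be non-negative")
        if not self.normalized and values.size:
            if not np.allclose(values, np.round(values)):
                raise AnnotationError("raw counts must be integer-valued")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def kinds(self) -> pd.Series:
        """Per-row kind labels (constant series for non-mixed matrices)."""
        if self.row_kinds is not None:
            return self.row_kinds
        return pd.Series(self.feature_kind, index=self.data.index)

    def rows_of_kind(self, kind: str) -> pd.DataFrame:
        return self.data.loc[self.kinds() == kind]

    def replace_data(self, data: pd.DataFrame, **kwargs) -> "CountMatrix":
        fields = dict(
            feature_kind=self.feature_kind,
            normalized=self.normalized,
            row_kinds=None if self.row_kinds is None else self.row_kinds.loc[data.index],
        )
        fields.update(kwargs)
        return CountMatrix(data=data, **fields)


@dataclass
class SampleSheet:
    """Per-sample metadata: karyotype, sex, age group, batch, cohort."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise AnnotationError("duplicate sample ids in sample sheet")
        if "karyotype" in t.columns:
            bad = set(t["karyotype"]) - set(VALID_KARYOTYPES)
            if bad:
                raise AnnotationError(f"unknown karyotypes: {sorted(bad)}")
            if "sex" in t.columns:
                for sid, row in t.iterrows():
                    expect = KARYOTYPE_SEX[row["karyotype"]]
                    if row["sex"] != expect:
                        raise AnnotationError(
                            f"sample {sid}: karyotype {row['karyotype']} "
                            f"inconsistent with sex {row['sex']!r}"
                        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def column(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise AnnotationError(f"sample sheet has no column {name!r}")
        return self.table[name]


# ---------------------------------------------------------------------------
# file readers / writers
# ---------------------------------------------------------------------------


def _parse_bed6(path: Path) -> list[tuple[str, int, int, str, str]]:
    """Yield (chrom, start, end, name, strand) tuples from a BED file."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise AnnotationError(f"{path}:{lineno}: expected ≥4 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = parts[5] if len(parts) >= 6 else "."
            if start >= end:
                raise AnnotationError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            rows.append((parts[0], start, end, parts[3], strand))
    return rows


def _parse_rmsk_out(path: Path) -> list[tuple[str, int, int, str, str, str]]:
    """Parse a RepeatMasker ``.out`` table.

    Returns (chrom, start0, end, strand, subfamily, class_family) with
    coordinates converted from 1-based inclusive to 0-based half-open.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            # header block: "SW perc ..." banner lines
            if stripped.startswith(("SW", "score")):
                continue
            parts = stripped.split()
            if len(parts) < 11:
                raise AnnotationError(f"{path}:{lineno}: expected ≥11 rmsk columns")
            try:
                begin, end = int(parts[5]), int(parts[6])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinate") from exc
            if begin < 1 or begin > end:
                raise AnnotationError(f"{path}:{lineno}: bad span {begin}..{end}")
            strand = "+" if parts[8] == "+" else "-"  # rmsk uses 'C' for reverse
            rows.append((parts[4], begin - 1, end, strand, parts[9], parts[10]))
    return rows


def read_repeat_annotation(path: str | Path, dialect: str = "bed") -> RepeatCopySet:
    """Read repeat-copy locations from BED6 or a RepeatMasker ``.out`` table.

    BED name fields of the form ``subfamily`` or ``copyid;subfamily`` are
    both accepted; for plain-subfamily names a positional copy id is
    synthesised. rmsk rows get positional ids ``<subfamily>_<n>``.
    """
    path = Path(path)
    copies: list[RepeatCopy] = []
    if dialect == "bed":
        for i, (chrom, start, end, name, strand) in enumerate(_parse_bed6(path)):
            if ";" in name:
                copy_id, subfamily = name.split(";", 1)
            else:
                copy_id, subfamily = f"{name}_{i}", name
            copies.append(
                RepeatCopy(copy_id, GenomicInterval(chrom, start, end, strand), subfamily)
            )
    elif dialect == "rmsk_out":
        seen: dict[str, int] = {}
        for chrom, start, end, strand, subfamily, _cf in _parse_rmsk_out(path):
            n = seen.get(subfamily, 0)
            seen[subfamily] = n + 1
            copies.append(
                RepeatCopy(
                    f"{subfamily}_{n}",
                    GenomicInterval(chrom, start, end, strand),
                    subfamily,
                )
            )
    else:
        raise AnnotationError(f"unknown repeat dialect {dialect!r}")
    return RepeatCopySet(copies)


def read_gene_annotation(path: str | Path, dialect: str = "bed") -> GeneSet:
    """Read gene bodies from BED6 or a GTF-lite file (``gene`` rows only).

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Unstranded records are rejected because the TSS would be undefined.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    if dialect == "bed":
        for chrom, start, end, name, strand in _parse_bed6(path):
            genes.append(GeneModel(name, GenomicInterval(chrom, start, end, strand)))
    elif dialect == "gtf_lite":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 9:
                    raise AnnotationError(f"{path}:{lineno}: expected 9 GTF columns")
                if parts[2] != "gene":
                    continue
                try:
                    start1, end1 = int(parts[3]), int(parts[4])
                except ValueError as exc:
                    raise AnnotationError(
                        f"{path}:{lineno}: non-integer coordinate"
                    ) from exc
                gene_id = _gtf_attribute(parts[8], "gene_id")
                if gene_id is None:
                    raise AnnotationError(f"{path}:{lineno}: missing gene_id attribute")
                genes.append(
                    GeneModel(
                        gene_id,
                        GenomicInterval(parts[0], start1 - 1, end1, parts[6]),
                    )
                )
    else:
        raise AnnotationError(f"unknown gene dialect {dialect!r}")
    return GeneSet(genes)


def _gtf_attribute(attr_field: str, key: str) -> str | None:
    for chunk in attr_field.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key + " "):
            return chunk[len(key):].strip().strip('"')
    return None


def read_count_matrix(
    path: str | Path, feature_kind: str, normalized: bool = False
) -> CountMatrix:
    """Read a TSV count matrix (first column feature ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).rename(None)
    df.columns = df.columns.astype(str)
    if df.shape[1] == 0:
        raise AnnotationError(f"{path}: no sample columns")
    values = df.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise AnnotationError(f"{path}: non-numeric cells present")
    return CountMatrix(df, feature_kind=feature_kind, normalized=normalized)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    df = matrix.data
    if not matrix.normalized:
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_rosetta(path: str | Path) -> RosettaMap:
    """Read the copy→subfamily "rosetta" TSV.

    Expected columns: copy_id, subfamily, class, family (class/family may be
    blank). An optional ``excluded`` column (0/1) flags non-TE subfamilies.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"copy_id", "subfamily"}
    if not required <= set(df.columns):
        raise AnnotationError(f"{path}: rosetta needs columns {sorted(required)}")
    if df["copy_id"].duplicated().any():
        dupes = df.loc[df["copy_id"].duplicated(), "copy_id"].tolist()
        raise AnnotationError(f"{path}: duplicate copy ids {dupes[:5]}")
    copy_to_sub = dict(zip(df["copy_id"], df["subfamily"]))
    lineage: dict[str, tuple[str, str]] = {}
    if "class" in df.columns:
        fam = df["family"] if "family" in df.columns else df["class"]
        for sub, cls, f in zip(df["subfamily"], df["class"], fam):
            if cls:
                lineage[sub] = (cls, f)
    excluded: set[str] = set()
    if "excluded" in df.columns:
        excluded = set(df.loc[df["excluded"].isin(("1", "true", "True")), "subfamily"])
    return RosettaMap(copy_to_sub, lineage, excluded)


def write_rosetta(rosetta: RosettaMap, path: str | Path) -> None:
    rows = []
    for copy_id, sub in rosetta.copy_to_subfamily.items():
        cls, fam = rosetta.subfamily_lineage.get(sub, ("", ""))
        rows.append(
            {
                "copy_id": copy_id,
                "subfamily": sub,
                "class": cls,
                "family": fam,
                "excluded": int(sub in rosetta.excluded),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise AnnotationError(f"{path}: sample sheet needs a sample_id column")
    return SampleSheet(df.set_index("sample_id"))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index_label="sample_id")


def write_bed(
    intervals: Mapping[str, GenomicInterval] | Sequence[RepeatCopy],
    path: str | Path,
) -> None:
    """Write named intervals (or repeat copies) as BED6."""
    with open(path, "w") as fh:
        if isinstance(intervals, Mapping):
            items = [(name, iv) for name, iv in intervals.items()]
        else:
            items = [(f"{c.copy_id};{c.subfamily}", c.interval) for c in intervals]
        for name, iv in items:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


def check_shared_chromosomes(a: set[str], b: set[str], context: str) -> None:
    """Fail loudly when two annotation sources share no chromosome names."""
    if a and b and not (a & b):
        raise AnnotationError(
            f"{context}: no chromosome names in common "
            f"({sorted(a)[:3]} vs {sorted(b)[:3]}) — check naming conventions"
        )
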