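"""Synthetic genomes, annotations and karyotype-structured count matrices.

The generator emulates the structure of a blood RNA-seq study of
sex-chromosome aneuploidy: four karyotype groups (46,XX / 46,XY / 47,XXY /
47,XYY) with the study's cohort sizes (6/6/8/4) by default, a toy genome
with one large autosome plus X and Y at their real relative kb lengths,
TE subfamilies whose copies are placed either proportionally to chromosome
length or preferentially on the Y, and negative-binomially distributed
counts with library-size variation and a two-level batch effect.

Dosage model: a copy on the Y contributes nothing in XX, its base mean with
one Y, and ``y_dosage_effect`` times that per extra Y (the supplementary Y
is assumed fully active); a copy on the X is scaled by ``x_dosage_effect``
per extra X (default close to 1, modelling X inactivation). Everything is a
pure function of the design, seed included.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotations_io import (
    AnnotationError,
    CountMatrix,
    GeneModel,
    GeneSet,
    GenomicInterval,
    RepeatCopy,
    RepeatCopySet,
    RosettaMap,
    SampleSheet,
    write_bed,
    write_count_matrix,
    write_rosetta,
    write_sample_sheet,
)
from .te_quantification import DEFAULT_EXCLUDED_SUBFAMILIES
from .y_enrichment import ChromLengths

__all__ = [
    "SimDesign",
    "GenomeSim",
    "SimTruth",
    "CountsSim",
    "simulate_genome",
    "simulate_counts",
    "simulate_de_matrix",
    "write_fixture_bundle",
    "load_design",
]

#: chromosome copy numbers per karyotype
N_X = {"XX": 2, "XY": 1, "XXY": 2, "XYY": 1}
N_Y = {"XX": 0, "XY": 1, "XXY": 1, "XYY": 2}
KARYOTYPE_SEX = {"XX": "female", "XY": "male", "XXY": "male", "XYY": "male"}

#: (name prefix, TE class) cycle used to name simulated subfamilies so the
#: class- and prefix-based subsets (LTR, SINE, HERVK, AluY, ...) are populated
_PREFIX_CYCLE = (
    ("HERVK", "LTR"),
    ("LTR", "LTR"),
    ("AluS", "SINE"),
    ("AluY", "SINE"),
    ("MIR", "SINE"),
    ("L1", "LINE"),
    ("L2", "LINE"),
    ("SVA", "SVA"),
    ("hAT", "DNA"),
    ("TcMar", "DNA"),
)

AGE_BINS = ((20, 30), (30, 40), (40, 50), (50, 60), (60, 70))


def _age_group(age: float) -> str:
    """Decade bins [20–30], ]30–40], ]40–50], ]50–60], ]60–70].

    The first bin is closed on both sides (a boundary age of exactly 30
    belongs to 20–30); later bins are left-open.
    """
    if not 20 <= age <= 70:
        raise AnnotationError(f"age {age} outside [20, 70]")
    if age <= 30:
        return "20-30"
    for lo, hi in AGE_BINS[1:]:
        if lo < age <= hi:
            return f"{lo}-{hi}"
    raise AnnotationError(f"age {age} outside [20, 70]")  # pragma: no cover


@dataclass(frozen=True)
class SimDesign:
    """Ground-truth parameters of one simulated study."""

    n_per_karyotype: dict[str, int] = field(
        default_factory=lambda: {"XX": 6, "XY": 6, "XXY": 8, "XYY": 4}
    )
    n_genes: int = 200
    n_subfamilies: int = 100
    copies_per_subfamily: int = 50
    y_enriched_fraction: float = 0.1
    y_placement_prob: float = 0.5
    y_dosage_effect: float = 2.0
    x_dosage_effect: float = 1.1
    dispersion: float = 0.05
    libsize_log_sd: float = 0.2
    batch_effect_sd: float = 0.1
    gene_base_mean: float = 2000.0
    copy_base_mean: float = 20.0
    base_log_sd: float = 0.6
    gene_length: int = 2000
    copy_length: int = 300
    chrom_lengths_kb: dict[str, float] = field(
        default_factory=lambda: {"chrA": 2_874_960.0, "chrX": 156_040.0, "chrY": 57_200.0}
    )
    include_excluded_subfamilies: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, frac in (
            ("y_enriched_fraction", self.y_enriched_fraction),
            ("y_placement_prob", self.y_placement_prob),
        ):
            if not 0.0 <= frac <= 1.0:
                raise AnnotationError(f"{name} must be in [0, 1]")
        for name, val in (
            ("y_dosage_effect", self.y_dosage_effect),
            ("x_dosage_effect", self.x_dosage_effect),
            ("dispersion", self.dispersion),
        ):
            if val <= 0:
                raise AnnotationError(f"{name} must be > 0")
        unknown = set(self.n_per_karyotype) - set(N_X)
        if unknown:
            raise AnnotationError(f"unknown karyotypes in design: {sorted(unknown)}")
        if self.seed is None:
            raise AnnotationError("seed is mandatory")


@dataclass
class GenomeSim:
    chrom_lengths: ChromLengths
    copies: RepeatCopySet
    genes: GeneSet
    rosetta: RosettaMap
    y_enriched_subfamilies: frozenset[str]


@dataclass
class SimTruth:
    """Everything needed to check any pipeline stage against ground truth."""

    y_enriched_subfamilies: frozenset[str]
    copy_base_mean: pd.Series  # per copy_id
    copy_chrom: pd.Series
    gene_base_mean: pd.Series
    gene_chrom: pd.Series
    library_factors: pd.Series  # per sample
    batch_multiplier: pd.Series  # per feature, applied to second batch

    def expected_copy_means(self, karyotype: str, design: SimDesign) -> pd.Series:
        """Noise-free per-copy mean for one karyotype (library factor 1)."""
        nx, ny = N_X[karyotype], N_Y[karyotype]
        dosage = pd.Series(1.0, index=self.copy_base_mean.index)
        on_y = self.copy_chrom == "chrY"
        on_x = self.copy_chrom == "chrX"
        dosage[on_y] = 0.0 if ny == 0 else design.y_dosage_effect ** (ny - 1)
        dosage[on_x] = design.x_dosage_effect ** (nx - 1)
        return self.copy_base_mean * dosage

    def to_jsonable(self) -> dict:
        return {
            "y_enriched_subfamilies": sorted(self.y_enriched_subfamilies),
            "copy_base_mean": self.copy_base_mean.round(6).to_dict(),
            "copy_chrom": self.copy_chrom.to_dict(),
            "gene_base_mean": self.gene_base_mean.round(6).to_dict(),
            "gene_chrom": self.gene_chrom.to_dict(),
            "library_factors": self.library_factors.round(6).to_dict(),
            "batch_multiplier": self.batch_multiplier.round(6).to_dict(),
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "SimTruth":
        return cls(
            frozenset(d["y_enriched_subfamilies"]),
            pd.Series(d["copy_base_mean"], dtype=float),
            pd.Series(d["copy_chrom"], dtype=str),
            pd.Series(d["gene_base_mean"], dtype=float),
            pd.Series(d["gene_chrom"], dtype=str),
            pd.Series(d["library_factors"], dtype=float),
            pd.Series(d["batch_multiplier"], dtype=float),
        )


@dataclass
class CountsSim:
    gene_counts: CountMatrix
    copy_counts: CountMatrix
    sheet: SampleSheet
    truth: SimTruth


def _subfamily_names(design: SimDesign) -> list[tuple[str, str, str]]:
    """(name, class, family) for each simulated subfamily."""
    out = []
    for i in range(design.n_subfamilies):
        prefix, cls = _PREFIX_CYCLE[i % len(_PREFIX_CYCLE)]
        out.append((f"{prefix}-s{i:04d}", cls, prefix))
    if design.include_excluded_subfamilies:
        out.extend((name, "other", "non_te") for name in DEFAULT_EXCLUDED_SUBFAMILIES)
    return out


def simulate_genome(design: SimDesign) -> GenomeSim:
    """Place TE copies and genes on a toy genome with X and Y chromosomes.

    Chromosome coordinates are in bp (kb lengths × 1000). Copies of
    Y-enriched subfamilies land on the Y with probability
    ``y_placement_prob``; all other placement is proportional to chromosome
    length. Genes are placed uniformly, on both strands.
    """
    rng = np.random.default_rng(design.seed)
    chrom_names = list(design.chrom_lengths_kb)
    lengths_bp = {c: int(kb * 1000) for c, kb in design.chrom_lengths_kb.items()}
    if "chrY" not in lengths_bp or "chrX" not in lengths_bp:
        raise AnnotationError("design must include chrX and chrY")
    total_bp = sum(lengths_bp.values())
    probs = np.array([lengths_bp[c] / total_bp for c in chrom_names])

    names = _subfamily_names(design)
    te_names = [n for n, cls, _f in names if cls != "other"]
    n_enriched = int(round(design.y_enriched_fraction * len(te_names)))
    enriched = frozenset(te_names[:n_enriched])  # deterministic bookkeeping

    if any(lengths_bp[c] <= design.copy_length for c in chrom_names):
        raise AnnotationError(
            f"copy length {design.copy_length} exceeds a chromosome length"
        )
    copies: list[RepeatCopy] = []
    per_chrom_copies = {c: 0 for c in chrom_names}
    y_index = chrom_names.index("chrY")
    for sub, _cls, _fam in names:
        n_copies = design.copies_per_subfamily
        chrom_idx = rng.choice(len(chrom_names), size=n_copies, p=probs)
        if sub in enriched:
            on_y = rng.random(n_copies) < design.y_placement_prob
            chrom_idx[on_y] = y_index
        fracs = rng.random(n_copies)
        strands = rng.random(n_copies) < 0.5
        for j in range(n_copies):
            chrom = chrom_names[chrom_idx[j]]
            per_chrom_copies[chrom] += 1
            start = int(fracs[j] * (lengths_bp[chrom] - design.copy_length))
            copies.append(
                RepeatCopy(
                    f"{sub}|c{j:04d}",
                    GenomicInterval(
                        chrom, start, start + design.copy_length,
                        "+" if strands[j] else "-",
                    ),
                    sub,
                )
            )
    for chrom, n in per_chrom_copies.items():
        if n * design.copy_length > lengths_bp[chrom]:
            raise AnnotationError(
                f"infeasible placement: {n} copies of length {design.copy_length} "
                f"exceed {chrom} ({lengths_bp[chrom]} bp)"
            )

    genes: list[GeneModel] = []
    for i in range(design.n_genes):
        chrom = chrom_names[rng.choice(len(chrom_names), p=probs)]
        space = lengths_bp[chrom] - design.gene_length
        if space <= 0:
            raise AnnotationError(f"gene length exceeds {chrom} length")
        start = int(rng.integers(0, space))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                f"gene{i:05d}",
                GenomicInterval(chrom, start, start + design.gene_length, strand),
            )
        )

    rosetta = RosettaMap(
        copy_to_subfamily={c.copy_id: c.subfamily for c in copies},
        subfamily_lineage={
            n: (cls if cls != "other" else "other", fam) for n, cls, fam in names
        },
        excluded={n for n, cls, _f in names if cls == "other"},
    )
    kb = dict(design.chrom_lengths_kb)
    chrom_lengths = ChromLengths(
        lengths={c: kb[c] for c in ("chrX", "chrY")}, total=sum(kb.values())
    )
    return GenomeSim(chrom_lengths, RepeatCopySet(copies), GeneSet(genes), rosetta, enriched)


def simulate_counts(design: SimDesign, genome: GenomeSim) -> CountsSim:
    """Draw NB counts for genes and TE copies under the dosage model."""
    rng = np.random.default_rng(design.seed + 1)  # distinct stream from placement

    samples: list[tuple[str, str]] = []
    i = 0
    for karyo in ("XX", "XY", "XXY", "XYY"):
        for _ in range(design.n_per_karyotype.get(karyo, 0)):
            samples.append((f"s{i:03d}", karyo))
            i += 1
    if not samples:
        raise AnnotationError("design has no samples")
    sample_ids = [s for s, _k in samples]
    karyos = [k for _s, k in samples]

    copy_ids = [c.copy_id for c in genome.copies]
    copy_chrom = pd.Series({c.copy_id: c.interval.chrom for c in genome.copies})
    gene_ids = [g.gene_id for g in genome.genes]
    gene_chrom = pd.Series({g.gene_id: g.interval.chrom for g in genome.genes})

    copy_base = pd.Series(
        design.copy_base_mean
        * np.exp(rng.normal(0.0, design.base_log_sd, size=len(copy_ids))),
        index=copy_ids,
    )
    gene_base = pd.Series(
        design.gene_base_mean
        * np.exp(rng.normal(0.0, design.base_log_sd, size=len(gene_ids))),
        index=gene_ids,
    )
    lib = pd.Series(
        np.exp(rng.normal(0.0, design.libsize_log_sd, size=len(sample_ids))),
        index=sample_ids,
    )
    # two-level batch: a random half of samples gets a per-feature multiplier
    order = rng.permutation(len(sample_ids))
    second_batch = set(np.array(sample_ids)[order[: len(sample_ids) // 2]])
    batch = pd.Series(
        ["b2" if s in second_batch else "b1" for s in sample_ids], index=sample_ids
    )
    all_features = gene_ids + copy_ids
    batch_mult = pd.Series(
        np.exp(rng.normal(0.0, design.batch_effect_sd, size=len(all_features))),
        index=all_features,
    )
    ages = rng.uniform(20.0, 70.0, size=len(sample_ids))

    truth = SimTruth(
        genome.y_enriched_subfamilies,
        copy_base,
        copy_chrom,
        gene_base,
        gene_chrom,
        lib,
        batch_mult,
    )

    def dosage_vector(chrom: pd.Series, karyo: str) -> np.ndarray:
        nx, ny = N_X[karyo], N_Y[karyo]
        d = np.ones(len(chrom))
        d[(chrom == "chrY").to_numpy()] = (
            0.0 if ny == 0 else design.y_dosage_effect ** (ny - 1)
        )
        d[(chrom == "chrX").to_numpy()] = design.x_dosage_effect ** (nx - 1)
        return d

    def nb_draw(mean: np.ndarray) -> np.ndarray:
        out = np.zeros(mean.shape, dtype=np.int64)
        pos = mean > 0
        if pos.any():
            shape = 1.0 / design.dispersion
            lam = rng.gamma(shape, mean[pos] * design.dispersion)
            out[pos] = rng.poisson(lam)
        return out

    gene_mat = np.zeros((len(gene_ids), len(sample_ids)), dtype=np.int64)
    copy_mat = np.zeros((len(copy_ids), len(sample_ids)), dtype=np.int64)
    for j, (sid, karyo) in enumerate(samples):
        bmult_g = batch_mult[gene_ids].to_numpy() if batch[sid] == "b2" else 1.0
        bmult_c = batch_mult[copy_ids].to_numpy() if batch[sid] == "b2" else 1.0
        mu_g = gene_base.to_numpy() * dosage_vector(gene_chrom, karyo) * lib[sid] * bmult_g
        mu_c = copy_base.to_numpy() * dosage_vector(copy_chrom, karyo) * lib[sid] * bmult_c
        gene_mat[:, j] = nb_draw(mu_g)
        copy_mat[:, j] = nb_draw(mu_c)

    sheet = SampleSheet(
        pd.DataFrame(
            {
                "karyotype": karyos,
                "sex": [KARYOTYPE_SEX[k] for k in karyos],
                "age_group": [_age_group(a) for a in ages],
                "batch": batch.tolist(),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    gene_counts = CountMatrix(
        pd.DataFrame(gene_mat, index=gene_ids, columns=sample_ids), feature_kind="gene"
    )
    copy_counts = CountMatrix(
        pd.DataFrame(copy_mat, index=copy_ids, columns=sample_ids),
        feature_kind="te_copy",
    )
    return CountsSim(gene_counts, copy_counts, sheet, truth)


def simulate_de_matrix(
    n_features: int,
    n_per_group: tuple[int, int],
    fold_change: float,
    n_planted: int = 0,
    base_mean: float = 100.0,
    dispersion: float = 0.05,
    libsize_log_sd: float = 0.0,
    seed: int = 0,
) -> tuple[CountMatrix, SampleSheet, list[str]]:
    """Two-group NB count matrix with ``n_planted`` true fold changes.

    Used for differential-expression calibration (``n_planted=0`` gives a
    pure null) and recovery checks. Groups are labelled as XX (reference)
    and XY. Planted effects alternate direction (up, down, up, ...) so the
    signal does not bias the median-of-ratios size factors, as in real
    data where DE runs both ways. Returns (counts, sheet, planted ids).
    """
    rng = np.random.default_rng(seed)
    n_a, n_b = n_per_group
    sample_ids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    groups = ["XX"] * n_a + ["XY"] * n_b
    features = [f"f{i:05d}" for i in range(n_features)]
    planted = features[:n_planted]
    lib = np.exp(rng.normal(0.0, libsize_log_sd, size=len(sample_ids)))
    mat = np.zeros((n_features, len(sample_ids)), dtype=np.int64)
    shape = 1.0 / dispersion
    planted_set = set(planted)
    for i, fid in enumerate(features):
        mu = np.full(len(sample_ids), base_mean, dtype=float)
        if fid in planted_set:
            mu[n_a:] *= fold_change if i % 2 == 0 else 1.0 / fold_change
        mu *= lib
        mat[i] = rng.poisson(rng.gamma(shape, mu * dispersion))
    counts = CountMatrix(
        pd.DataFrame(mat, index=features, columns=sample_ids), feature_kind="gene"
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "karyotype": groups,
                "sex": [KARYOTYPE_SEX[g] for g in groups],
                "batch": ["b1"] * len(sample_ids),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return counts, sheet, planted


def write_fixture_bundle(out_dir: str | Path, design: SimDesign) -> Path:
    """Emit a complete file bundle readable through the IO layer.

    Files: copies.bed, genes.gtf, rosetta.tsv, gene_counts.tsv,
    te_copy_counts.tsv, samples.tsv, chrom_lengths.tsv, truth.json,
    MANIFEST.yaml (the design).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(design)
    sim = simulate_counts(design, genome)

    write_bed(list(genome.copies), out / "copies.bed")
    with open(out / "genes.gtf", "w") as fh:
        for g in genome.genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tsim\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )
    write_rosetta(genome.rosetta, out / "rosetta.tsv")
    write_count_matrix(sim.gene_counts, out / "gene_counts.tsv")
    write_count_matrix(sim.copy_counts, out / "te_copy_counts.tsv")
    write_sample_sheet(sim.sheet, out / "samples.tsv")
    pd.Series(design.chrom_lengths_kb, name="length_kb").to_csv(
        out / "chrom_lengths.tsv", sep="\t", index_label="chrom"
    )
    with open(out / "truth.json", "w") as fh:
        json.dump(sim.truth.to_jsonable(), fh, indent=1, sort_keys=True)
    with open(out / "MANIFEST.yaml", "w") as fh:
        yaml.safe_dump({"design": asdict(design)}, fh, sort_keys=True)
    return out


def load_design(path: str | Path) -> SimDesign:
    """Read a SimDesign back from YAML (a MANIFEST or a design config)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if "design" in doc:
        doc = doc["design"]
    return SimDesign(**doc)
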