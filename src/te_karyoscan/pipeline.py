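"""Configuration-driven orchestration of the full analysis.

Stage order: quantify (copy → subfamily aggregation, exclusion filter,
zero-row removal) → normalize (gene-anchored size factors, joint scaling)
→ global TE statistics (per-subset proportions, pairwise rank-sum tests)
→ differential expression (NB GLM over TE subfamilies and genes) →
Y-chromosome enrichment classification → region enrichment (upstream
permutation test and intragenic binomial test). Each stage writes TSVs
into its own subdirectory and contributes to a single JSON summary, which
is the machine-readable surface of a run. Given the same config and seeds
the summary is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotations_io as aio
from .annotations_io import AnnotationError
from .differential_expression import (
    DesignSpec,
    fit_nb_de,
    median_log2fc_test,
    rank_top_features,
    results_to_frame,
)
from .global_expression import (
    build_te_subsets,
    global_te_proportion,
    multi_group_test,
    pairwise_group_test,
)
from .normalization import normalize_joint, size_factors_from_genes
from .region_enrichment import (
    intragenic_overlap_test,
    permutation_enrichment,
    upstream_regions,
)
from .te_quantification import (
    ExclusionList,
    aggregate_copy_counts,
    drop_all_zero_features,
    filter_subfamilies,
)
from .y_enrichment import ChromLengths, classify_all, enriched_share_test, records_to_frame

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All inputs and parameters of one pipeline run."""

    copies_bed: str
    genes_file: str
    rosetta_tsv: str
    gene_counts_tsv: str
    te_copy_counts_tsv: str
    sample_sheet_tsv: str
    out_dir: str
    genes_dialect: str = "gtf_lite"
    chrom_lengths_tsv: str | None = None
    exclusion_list: str | None = None  # newline-delimited; default embedded list
    span: int = 3000
    n_perm: int = 5000
    alpha: float = 0.05
    seed: int = 0
    top_k: int = 15
    primary_factor: str = "karyotype"
    covariates: tuple[str, ...] = ("batch",)
    focal_chrom: str = "chrY"
    other_chrom: str = "chrX"
    run_region_stage: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "covariates" in doc and isinstance(doc["covariates"], list):
            doc["covariates"] = tuple(doc["covariates"])
        return cls(**doc)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems: list[str] = []
    for name in (
        "copies_bed",
        "genes_file",
        "rosetta_tsv",
        "gene_counts_tsv",
        "te_copy_counts_tsv",
        "sample_sheet_tsv",
    ):
        path = getattr(config, name)
        if not path or not Path(path).exists():
            problems.append(f"{name}: file not found: {path}")
    if config.span <= 0:
        problems.append("span must be positive")
    if config.n_perm < 1:
        problems.append("n_perm must be ≥1")
    if not (0 < config.alpha < 1):
        problems.append("alpha must be in (0, 1)")
    if Path(config.sample_sheet_tsv).exists():
        try:
            aio.read_sample_sheet(config.sample_sheet_tsv)
        except AnnotationError as exc:
            problems.append(f"sample sheet: {exc}")
    return problems


def _round_floats(obj, ndigits=10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage; return (and write) the JSON summary."""
    problems = validate_config(config)
    if problems:
        raise AnnotationError("invalid config:\n" + "\n".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": _round_floats(dataclasses.asdict(config))}

    def stage_dir(name: str) -> Path:
        d = out / name
        d.mkdir(exist_ok=True)
        return d

    try:
        # ---- inputs ------------------------------------------------------
        copies = aio.read_repeat_annotation(config.copies_bed, dialect="bed")
        genes = aio.read_gene_annotation(config.genes_file, dialect=config.genes_dialect)
        rosetta = aio.read_rosetta(config.rosetta_tsv)
        gene_counts = aio.read_count_matrix(config.gene_counts_tsv, "gene")
        copy_counts = aio.read_count_matrix(config.te_copy_counts_tsv, "te_copy")
        sheet = aio.read_sample_sheet(config.sample_sheet_tsv)
        if config.chrom_lengths_tsv:
            lk = pd.read_csv(config.chrom_lengths_tsv, sep="\t", index_col=0)["length_kb"]
            lengths = ChromLengths(
                lengths={
                    c: float(lk[c]) for c in (config.focal_chrom, config.other_chrom)
                },
                total=float(lk.sum()),
            )
        else:
            lengths = ChromLengths()
        logger.info(
            "inputs: %d copies, %d genes, %d gene rows, %d copy rows, %d samples",
            len(copies), len(genes), len(gene_counts.data),
            len(copy_counts.data), len(sheet.sample_ids),
        )

        # ---- quantify ----------------------------------------------------
        current = "quantify"
        d = stage_dir(current)
        exclusion = (
            ExclusionList.from_file(config.exclusion_list)
            if config.exclusion_list
            else ExclusionList()
        )
        subfam = aggregate_copy_counts(copy_counts, rosetta)
        subfam = filter_subfamilies(subfam, exclusion)
        subfam = drop_all_zero_features(subfam)
        gene_counts_nz = drop_all_zero_features(gene_counts)
        aio.write_count_matrix(subfam, d / "te_subfamily_counts.tsv")
        summary["quantify"] = {
            "n_te_subfamilies": len(subfam.data),
            "n_genes": len(gene_counts_nz.data),
        }
        logger.info("quantify: %d subfamilies, %d genes after filters",
                    len(subfam.data), len(gene_counts_nz.data))

        # ---- normalize ---------------------------------------------------
        current = "normalize"
        d = stage_dir(current)
        factors = size_factors_from_genes(gene_counts_nz)
        normalized = normalize_joint(gene_counts_nz, subfam, factors)
        factors.to_tsv(d / "size_factors.tsv")
        summary["normalize"] = {
            "size_factors": _round_floats(factors.factors.to_dict())
        }

        # ---- global TE statistics ---------------------------------------
        current = "global_te"
        d = stage_dir(current)
        subsets = build_te_subsets(rosetta)
        karyo = sheet.column(config.primary_factor).reindex(normalized.sample_ids)
        global_stats: dict = {}
        rows = []
        for name, subset in subsets.items():
            prop = global_te_proportion(normalized, subset)
            comparison = pairwise_group_test(prop, karyo, subset_name=name)
            kw_p = multi_group_test(prop, karyo)
            global_stats[name] = {
                "median_by_group": _round_floats(
                    prop.groupby(karyo).median().to_dict()
                ),
                "pairwise_p": {
                    f"{a}_vs_{b}": round(float(p), 10)
                    for (a, b), p in sorted(comparison.pairwise_p.items())
                },
                "kruskal_wallis_p": round(float(kw_p), 10),
            }
            rows.append(comparison.to_frame())
        pd.concat(rows).to_csv(d / "group_tests.tsv", sep="\t", index=False)
        summary["global_te"] = global_stats

        # ---- differential expression ------------------------------------
        current = "differential_expression"
        d = stage_dir(current)
        design = DesignSpec(
            primary=config.primary_factor,
            covariates=tuple(config.covariates),
            reference={config.primary_factor: "XX"},
        )
        te_results = fit_nb_de(subfam, factors, design, sheet)
        gene_results = fit_nb_de(gene_counts_nz, factors, design, sheet)
        te_frame = results_to_frame(te_results)
        gene_frame = results_to_frame(gene_results)
        te_frame.to_csv(d / "te_subfamily_de.tsv", sep="\t", index=False)
        gene_frame.to_csv(d / "gene_de.tsv", sep="\t", index=False)
        contrasts = sorted(
            c for c in te_frame["contrast"].unique() if c != "omnibus"
        )
        median_fc = {}
        for contrast in contrasts:
            sub_res = [r for r in te_results if r.contrast == contrast]
            med, p = median_log2fc_test(sub_res)
            median_fc[contrast] = {"median_log2fc": round(med, 10), "p": round(p, 10)}
        top = rank_top_features(te_results, config.top_k)
        de_counts = {
            contrast: int(
                (
                    (te_frame["contrast"] == contrast)
                    & (te_frame["padj"] < config.alpha)
                ).sum()
            )
            for contrast in contrasts
        }
        gene_de_counts = {
            contrast: int(
                (
                    (gene_frame["contrast"] == contrast)
                    & (gene_frame["padj"] < config.alpha)
                ).sum()
            )
            for contrast in contrasts
        }
        summary["differential_expression"] = {
            "n_te_significant": de_counts,
            "n_gene_significant": gene_de_counts,
            "median_log2fc": median_fc,
            "top_te_subfamilies": top,
        }

        # ---- Y enrichment -----------------------------------------------
        current = "y_enrichment"
        d = stage_dir(current)
        records, groups = classify_all(
            copies, lengths, focal=config.focal_chrom,
            other=config.other_chrom, alpha=config.alpha,
        )
        records_to_frame(records).to_csv(d / "enrichment.tsv", sep="\t", index=False)
        n_tested = len(records)
        background = len(groups["enriched"]) / n_tested if n_tested else 0.0
        top_in_records = {t for t in top if any(r.subfamily == t for r in records)}
        share_p = (
            enriched_share_test(top_in_records, records, background)
            if top_in_records and background > 0
            else None
        )
        summary["y_enrichment"] = {
            "n_tested": n_tested,
            "group_sizes": {k: len(v) for k, v in sorted(groups.items())},
            "background_enriched_share": round(background, 10),
            "top_subfamilies_enriched_share_p": (
                round(float(share_p), 10) if share_p is not None else None
            ),
        }

        # ---- region enrichment ------------------------------------------
        if config.run_region_stage:
            current = "region_enrichment"
            d = stage_dir(current)
            universe = upstream_regions(genes, span=config.span)
            region_summary: dict = {}
            for contrast in contrasts:
                gsub = gene_frame[gene_frame["contrast"] == contrast]
                up_genes = set(
                    gsub.loc[
                        (gsub["padj"] < config.alpha) & (gsub["log2fc"] > 0),
                        "feature_id",
                    ]
                )
                tsub = te_frame[te_frame["contrast"] == contrast]
                up_subfams = set(
                    tsub.loc[
                        (tsub["padj"] < config.alpha) & (tsub["log2fc"] > 0),
                        "feature_id",
                    ]
                )
                entry: dict = {
                    "n_upregulated_genes": len(up_genes),
                    "n_upregulated_te_subfamilies": len(up_subfams),
                }
                selectable = up_genes & set(universe.regions)
                if selectable and up_subfams:
                    sel = universe.subset(selectable)
                    de_copies = copies.subset(up_subfams)
                    perm = permutation_enrichment(
                        sel, universe, de_copies,
                        n_perm=config.n_perm, seed=config.seed,
                    )
                    entry["upstream_permutation"] = {
                        "observed": perm.observed,
                        "null_mean": round(perm.null_mean, 10),
                        "alternative": perm.alternative,
                        "p": round(perm.p_empirical, 10),
                    }
                    intr = intragenic_overlap_test(
                        genes.subset(up_genes), de_copies, genes
                    )
                    entry["intragenic_overlap"] = {
                        "observed_prop": round(intr.observed_prop, 10),
                        "expected_prop": round(intr.expected_prop, 10),
                        "p": (
                            round(float(intr.p), 10) if intr.p is not None else None
                        ),
                        "status": intr.status,
                    }
                region_summary[contrast] = entry
            summary["region_enrichment"] = region_summary
            with open(d / "region_enrichment.json", "w") as fh:
                json.dump(region_summary, fh, indent=1, sort_keys=True)

    except Exception as exc:
        (out / "FAILED").write_text(f"stage {current}: {exc}\n")
        raise AnnotationError(f"pipeline failed at stage {current!r}: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
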