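"""End-to-end orchestration of the spectral-count analysis.

Stage order mirrors how such studies report their results: NSAF
quantification, replicate-presence filtering, per-comparison differential
calls, PCA with loading-sum summaries, proportion-profile k-means,
functional categorization, GO enrichment of the up/down lists, and Venn
partitions of protein sets and of enriched terms.  Every stage's table is
written to the output directory and the headline numbers are collected in
a summary dict (and ``summary.json``); percentages in the summary are
always recomputed from their own counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, enrichment, filtering, io, multivariate, quantify
from .differential import DEConfig, round_half_away
from .filtering import FilterConfig
from .io import Annotation, CountMatrix

__all__ = ["PipelineConfig", "run_pipeline", "quality_ratios"]

logger = logging.getLogger("spectranote")

#: Reference-vs-treatment pairs of the pollen study, as (reference, interest).
DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("P-C", "P-HS"),
    ("P-HS", "P-E-HS"),
    ("P-C", "P-E-C"),
    ("P-C", "P-E-HS"),
)


@dataclasses.dataclass
class PipelineConfig:
    """Everything the pipeline needs: inputs, thresholds and a master seed.

    Inputs may be given either as paths (``counts_path`` + ``design_path``,
    optional ``annotations_path``) or as in-memory objects (``counts``,
    ``annotations``).  ``comparisons`` are (reference, interest) treatment
    pairs.  All stage seeds derive deterministically from ``seed``.
    """

    counts: CountMatrix | None = None
    annotations: Mapping[str, Annotation] | None = None
    counts_path: str | Path | None = None
    design_path: str | Path | None = None
    annotations_path: str | Path | None = None
    comparisons: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS
    out_dir: str | Path = "spectranote_out"
    scale_factor: float = quantify.DEFAULT_SCALE
    de: DEConfig = dataclasses.field(default_factory=DEConfig)
    filter: FilterConfig = dataclasses.field(default_factory=FilterConfig)
    k: int = 30
    n_restarts: int = 50
    loading_top_n: int = 100
    enrichment_fdr: float = 0.05
    background: str = "annotations"  # or "detected"
    seed: int = 0


def _load_counts(cfg: PipelineConfig) -> CountMatrix:
    if cfg.counts is not None:
        return cfg.counts
    if cfg.counts_path is None or cfg.design_path is None:
        raise ValueError("provide counts or counts_path + design_path")
    return io.read_counts(cfg.counts_path, cfg.design_path)


def _comp_tag(a: str, b: str) -> str:
    return f"{b}_vs_{a}".replace(" ", "_")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the report bundle.

    The returned dict holds the summary plus the in-memory stage results
    (NSAF matrix, DE tables, PCA and cluster models, enrichment tables).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = _load_counts(cfg)
    for a, b in cfg.comparisons:
        for t in (a, b):
            if t not in counts.treatments:
                raise ValueError(f"comparison references unknown treatment {t!r}")
    annotations: Mapping[str, Annotation] = cfg.annotations or (
        io.read_annotations(cfg.annotations_path) if cfg.annotations_path else {}
    )
    logger.info("pipeline start: %d proteins, %d samples, seed=%d",
                len(counts.accessions), len(counts.samples), cfg.seed)

    # -- quantify --------------------------------------------------------
    nsafm = quantify.nsaf(counts, scale_factor=cfg.scale_factor)
    nsaf_table = nsafm.values.copy()
    nsaf_table.insert(0, "accession", nsaf_table.index)
    io.write_table(nsaf_table.reset_index(drop=True), out / "nsaf.tsv")

    # -- filter ----------------------------------------------------------
    presence = filtering.presence_filter(counts, cfg.filter)
    retained = presence.retained
    det_sets = filtering.detection_sets(counts)
    logger.info("presence filter: %d of %d proteins retained",
                len(retained), len(counts.accessions))
    io.write_table(
        pd.DataFrame({"accession": sorted(retained)}), out / "retained.tsv"
    )
    protein_venn = enrichment.venn({t: det_sets[t] for t in counts.treatments})
    io.write_table(protein_venn.to_frame(), out / "venn_proteins.tsv")

    # -- differential ----------------------------------------------------
    de_tables: dict[str, pd.DataFrame] = {}
    de_summaries: dict[str, dict] = {}
    for a, b in cfg.comparisons:
        tag = _comp_tag(a, b)
        res = differential.de_call(nsafm, a, b, retained, cfg.de)
        de_tables[tag] = res
        de_summaries[tag] = differential.updown_summary(res)
        io.write_table(res, out / f"de_{tag}.tsv")
        logger.info("DE %s: %s", tag, de_summaries[tag])
    anova = differential.anova_scan(nsafm, retained)
    io.write_table(anova, out / "anova.tsv")

    # -- multivariate ----------------------------------------------------
    pca = multivariate.pca_fit(nsafm, retained)
    scores = pca.scores.copy()
    scores.insert(0, "sample_id", scores.index)
    scores["rank"] = np.arange(1, len(scores) + 1)  # preserve sample order
    io.write_table(scores.reset_index(drop=True), out / "pca_scores.tsv")
    n_load = min(cfg.loading_top_n, len(retained))
    loading_sums = pd.DataFrame(
        {
            f"{side}_{pc}": multivariate.loading_sum_profile(
                pca, nsafm, component=pc, n=n_load, side=side
            )
            for pc in ("PC1", "PC3" if "PC3" in pca.components else "PC1")
            for side in ("high", "low")
        }
    )
    loading_sums.insert(0, "treatment", loading_sums.index)
    loading_sums["rank"] = np.arange(1, len(loading_sums) + 1)
    io.write_table(loading_sums.reset_index(drop=True), out / "pca_loading_sums.tsv")

    # treatment-group centroids on PC1: which condition stands apart
    pc1 = pca.scores["PC1"]
    design = nsafm.design.set_index("sample_id")
    centroids = pc1.groupby(design["treatment"]).mean()
    pc1_extreme = centroids.abs().idxmax()

    means = quantify.treatment_means(nsafm).loc[retained]
    profiles = multivariate.profile_normalize(means)
    k = min(cfg.k, len(profiles))
    cluster = multivariate.kmeans_fit(
        profiles, k=k, seed=cfg.seed, n_restarts=cfg.n_restarts
    )
    cl_table = cluster.assignments.rename("cluster").rename_axis("accession").reset_index()
    io.write_table(cl_table, out / "clusters.tsv")
    io.write_table(
        multivariate.cluster_profile_plot_data(cluster), out / "cluster_profiles.tsv"
    )

    # -- categorization & enrichment -------------------------------------
    enrich_tables: dict[str, pd.DataFrame] = {}
    enriched_terms: dict[str, set[str]] = {}
    if annotations:
        background = (
            set(annotations) if cfg.background == "annotations"
            else set().union(*det_sets.values())
        )
        for tag, res in de_tables.items():
            called = res[res["call"]]
            for direction, sub in (
                ("up", called[called["fold"] > 0]),
                ("down", called[called["fold"] < 0]),
            ):
                fg = set(sub["accession"]) & background
                cats = enrichment.categorize(sub["accession"], annotations)
                io.write_table(cats, out / f"bins_{tag}_{direction}.tsv")
                if fg:
                    enr = enrichment.go_enrich(
                        fg, background, annotations, fdr=cfg.enrichment_fdr
                    )
                else:
                    enr = enrichment.go_enrich(
                        set(), background, annotations, fdr=cfg.enrichment_fdr
                    )
                enrich_tables[f"{tag}_{direction}"] = enr
                enriched_terms[f"{tag}_{direction}"] = set(
                    enr.loc[enr["enriched"], "term"]
                )
                io.write_table(enr, out / f"enrich_{tag}_{direction}.tsv")
        if len(enriched_terms) >= 2:
            uniq, term_part = enrichment.unique_terms(enriched_terms)
            rows = [
                {"comparison": lab, "n_unique": len(s), "terms": ";".join(sorted(s))}
                for lab, s in uniq.items()
            ]
            io.write_table(
                pd.DataFrame(rows, columns=["comparison", "n_unique", "terms"]),
                out / "unique_terms.tsv",
            )

    # -- summary ---------------------------------------------------------
    union_all = set().union(*det_sets.values())
    core_key = tuple(counts.treatments)
    summary = {
        "seed": cfg.seed,
        "n_proteins_total": len(counts.accessions),
        "n_identified_union": len(union_all),
        "n_identified_per_treatment": {t: len(det_sets[t]) for t in counts.treatments},
        "n_retained": len(retained),
        "core_common_n": protein_venn.size(*core_key),
        "core_common_pct": (
            protein_venn.percent(*core_key) if union_all else None
        ),
        "de": de_summaries,
        "pc1_extreme_treatment": pc1_extreme,
        "pc1_group_centroids": {t: float(v) for t, v in centroids.items()},
        "kmeans_k": k,
        "kmeans_inertia": cluster.inertia,
        "n_enriched_terms": {k_: len(v) for k_, v in enriched_terms.items()},
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline done: summary written to %s", out / "summary.json")
    return {
        "summary": summary,
        "nsaf": nsafm,
        "presence": presence,
        "detection_sets": det_sets,
        "de": de_tables,
        "pca": pca,
        "loading_sums": loading_sums,
        "cluster": cluster,
        "enrichment": enrich_tables,
        "protein_venn": protein_venn,
    }


def quality_ratios(
    per_flower_counts: Mapping[str, float],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Fold ratios between per-flower pollen counts of treatment pairs.

    Each (numerator, denominator) pair yields the unrounded ratio plus a
    1-decimal display value.  Defaults to all ordered pairs.
    """
    labels = list(per_flower_counts)
    if pairs is None:
        pairs = [(a, b) for a in labels for b in labels if a != b]
    rows = []
    for num, den in pairs:
        d = per_flower_counts[den]
        if d == 0:
            raise ZeroDivisionError(f"zero denominator count for {den!r}")
        r = per_flower_counts[num] / d
        rows.append(
            {"numerator": num, "denominator": den, "ratio": r,
             "display": round_half_away(10 * r) / 10}
        )
    df = pd.DataFrame(rows, columns=["numerator", "denominator", "ratio", "display"])
    df["rank"] = np.arange(1, len(df) + 1)
    return df
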