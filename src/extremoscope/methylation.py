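"""Promoter DNA-methylation association with expression outliers.

For genes with at least two extreme outliers of one direction, the
β-values of every CpG in the gene's promoter region (1500 bp upstream
of its transcription start sites, strand-aware) are compared between
outlier samples and the remaining samples with a Wilcoxon rank-sum
test; Benjamini–Hochberg FDR values are computed across all tested
(gene, CpG) pairs of the direction.  A CpG is differentially
methylated when FDR < 0.05 *and* the β-median rule holds.

The rule's default direction follows the cohort-level findings —
underexpression with promoter hypermethylation (outlier median β >
0.80, others < 0.20) and overexpression with hypomethylation (outlier
median β < 0.20, others > 0.80); ``beta_rule_direction="methods"``
swaps the two, reproducing the alternative written convention.

CpGs are annotated against CpG islands: shores are the 2 kb flanks of
an island, shelves the next 2 kb outwards, open sea the rest; where
flanks of nearby islands collide, the island-proximal class wins.
Genes whose underexpression is methylation-associated are further
tested for enrichment of CIMP-positive samples (CIMP-H ∪ CIMP-L) among
their outliers with an upper-tail hypergeometric test, BH-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_data import GeneAnnotation, SampleAnnotation
from .outliers import OutlierAtlas

__all__ = [
    "BetaMatrix",
    "CgiSegmentation",
    "load_beta_matrix",
    "load_cpg_manifest",
    "load_cgi_bed",
    "segment_cgi_regions",
    "map_cpgs_to_promoters",
    "wilcoxon_rank_sum",
    "benjamini_hochberg",
    "test_promoter_association",
    "compare_context_distribution",
    "cimp_enrichment",
]

logger = logging.getLogger(__name__)

SHORE_BP = 2000
SHELF_BP = 2000
PROMOTER_BP = 1500
FDR_LEVEL = 0.05
BETA_HIGH = 0.80
BETA_LOW = 0.20
MIN_GROUP_VALUES = 3
EXACT_MAX_N = 10


@dataclass
class BetaMatrix:
    """CpG × sample methylation β-values in [0, 1]; missing allowed."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("β-values must lie in [0, 1]")

    @property
    def cpgs(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def load_beta_matrix(path: str | Path) -> BetaMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return BetaMatrix(df.astype(float))


def load_cpg_manifest(path: str | Path) -> pd.DataFrame:
    """CpG manifest TSV: cpg_id, chrom, pos (0-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"cpg_id": str, "chrom": str, "pos": int})
    return df.set_index("cpg_id")


def load_cgi_bed(path: str | Path) -> pd.DataFrame:
    """CpG-island BED (0-based half-open); extra columns ignored."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={"chrom": str},
    )
    if (df["end"] <= df["start"]).any():
        raise ValueError("malformed BED: interval end must exceed start")
    return df


class CgiSegmentation:
    """Genome partition into island / shore / shelf / open sea.

    Built from merged island intervals per chromosome; a position's
    class is decided by its distance to the nearest island (0 → island,
    ≤2 kb → shore, ≤4 kb → shelf, else open sea), which resolves
    colliding flanks island-proximally by construction.
    """

    def __init__(self, islands: pd.DataFrame):
        self._islands: dict[str, np.ndarray] = {}
        for chrom, grp in islands.groupby("chrom"):
            iv = grp[["start", "end"]].sort_values("start").to_numpy()
            merged: list[list[int]] = []
            for s, e in iv:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([int(s), int(e)])
            self._islands[chrom] = np.asarray(merged, dtype=np.int64)

    def classify(self, chrom: str, pos: int) -> str:
        """Region class of a single 0-based position."""
        return self.classify_many(chrom, np.asarray([pos]))[0]

    def classify_many(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=np.int64)
        iv = self._islands.get(chrom)
        out = np.full(pos.shape, "open_sea", dtype=object)
        if iv is None or iv.size == 0:
            return out
        starts, ends = iv[:, 0], iv[:, 1]
        # distance to nearest island: 0 inside, else gap size in bases
        idx = np.searchsorted(starts, pos, side="right") - 1
        dist = np.full(pos.shape, np.iinfo(np.int64).max)
        has_left = idx >= 0
        inside = has_left & (pos < ends[np.clip(idx, 0, None)])
        dist[inside] = 0
        left_gap = np.where(has_left & ~inside, pos - ends[np.clip(idx, 0, None)] + 1, dist)
        dist = np.minimum(dist, left_gap)
        nxt = idx + 1
        has_right = nxt < len(starts)
        right_gap = np.where(has_right, starts[np.clip(nxt, None, len(starts) - 1)] - pos, dist)
        dist = np.minimum(dist, np.where(has_right, right_gap, dist))
        out[dist == 0] = "island"
        out[(dist >= 1) & (dist <= SHORE_BP)] = "shore"
        out[(dist > SHORE_BP) & (dist <= SHORE_BP + SHELF_BP)] = "shelf"
        return out


def segment_cgi_regions(cgi_track: pd.DataFrame) -> CgiSegmentation:
    """Build the island/shore/shelf/open-sea classifier from a CGI track."""
    return CgiSegmentation(cgi_track)


def map_cpgs_to_promoters(
    manifest: pd.DataFrame,
    ann: GeneAnnotation,
    window: int = PROMOTER_BP,
    segmentation: CgiSegmentation | None = None,
) -> pd.DataFrame:
    """CpG → promoter-gene mapping with region-class annotation.

    Promoters are strand-aware, upstream-only windows around each
    transcript TSS (1-based in the annotation): for + strand genes the
    0-based window [TSS−1−window, TSS−1), for − strand (TSS−1,
    TSS−1+window].  A CpG may map to several genes; per gene the union
    over all its TSSs is used.  Returns one row per (cpg, gene) pair
    with columns chrom, pos, region_class, gene_id.
    """
    if window <= 0:
        raise ValueError("promoter window must be positive")
    rows = []
    by_chrom = {c: g for c, g in manifest.groupby("chrom")}
    for gene_id, rec in ann.table.iterrows():
        if len(rec["tss_list"]) == 0:
            logger.warning("gene %s has no transcript TSSs; skipped", gene_id)
            continue
        grp = by_chrom.get(rec["chromosome"])
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        hit = np.zeros(pos.shape, dtype=bool)
        for tss in rec["tss_list"]:
            t0 = tss - 1  # 0-based TSS
            if rec["strand"] == "+":
                hit |= (pos >= t0 - window) & (pos < t0)
            else:
                hit |= (pos > t0) & (pos <= t0 + window)
        for cpg, p in zip(grp.index[hit], pos[hit]):
            rows.append({"cpg_id": cpg, "chrom": rec["chromosome"], "pos": int(p), "gene_id": gene_id})
    ctx = pd.DataFrame(rows, columns=["cpg_id", "chrom", "pos", "gene_id"])
    if segmentation is not None and len(ctx):
        classes = np.empty(len(ctx), dtype=object)
        for chrom, grp in ctx.groupby("chrom"):
            classes[grp.index.to_numpy()] = segmentation.classify_many(
                chrom, grp["pos"].to_numpy()
            )
        ctx["region_class"] = classes
    else:
        ctx["region_class"] = pd.NA
    return ctx


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both groups have ≤ 10 values and no ties
    across the pooled data; otherwise the normal approximation with tie
    correction.  Missing values are dropped; an empty group or a fully
    tied pooled sample yields p = 1 (no evidence of a shift).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        return np.nan
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    ok = ~np.isnan(p)
    out = np.full(p.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _beta_rule(direction: str, med_out: float, med_other: float, rule: str) -> bool:
    """β-median rule: which group must be hyper-methylated.

    ``rule="results"`` (default elsewhere): negative outliers
    hypermethylated, positive outliers hypomethylated; ``"methods"``
    is the mirrored convention.
    """
    hyper_in_outliers = med_out > BETA_HIGH and med_other < BETA_LOW
    hypo_in_outliers = med_out < BETA_LOW and med_other > BETA_HIGH
    if rule == "results":
        return hyper_in_outliers if direction == "negative" else hypo_in_outliers
    if rule == "methods":
        return hyper_in_outliers if direction == "positive" else hypo_in_outliers
    raise ValueError(f"unknown beta_rule_direction {rule!r}")


def test_promoter_association(
    atlas: OutlierAtlas,
    beta: BetaMatrix,
    ctx: pd.DataFrame,
    min_outliers: int = 2,
    fdr_level: float = FDR_LEVEL,
    beta_rule_direction: Literal["results", "methods"] = "results",
) -> pd.DataFrame:
    """Per-(gene, CpG) Wilcoxon association of promoter methylation.

    Only genes with ≥ ``min_outliers`` extreme outliers in a direction
    are tested; "other samples" are all cohort samples (of the β
    matrix) that are not extreme outliers of that gene/direction.  BH
    runs across all tested pairs within each direction.  ``significant``
    requires FDR < ``fdr_level`` and the β-median rule.
    """
    results = []
    cohort = beta.samples
    cpgs_by_gene = ctx.groupby("gene_id")
    for direction in ("positive", "negative"):
        ext = atlas.extreme(direction)
        for gene_id, grp in ext.groupby("gene_id"):
            out_samples = [s for s in grp["sample_id"] if s in cohort]
            if len(out_samples) < min_outliers:
                continue
            try:
                gene_ctx = cpgs_by_gene.get_group(gene_id)
            except KeyError:
                logger.info("gene %s has no promoter CpGs; omitted", gene_id)
                continue
            others = cohort.difference(out_samples)
            for _, row in gene_ctx.iterrows():
                cpg = row["cpg_id"]
                if cpg not in beta.cpgs:
                    continue
                a = beta.values.loc[cpg, out_samples].to_numpy(dtype=float)
                b = beta.values.loc[cpg, others].to_numpy(dtype=float)
                a = a[~np.isnan(a)]
                b = b[~np.isnan(b)]
                if a.size < MIN_GROUP_VALUES or b.size < MIN_GROUP_VALUES:
                    continue
                results.append(
                    {
                        "gene_id": gene_id,
                        "cpg_id": cpg,
                        "region_class": row.get("region_class", pd.NA),
                        "direction": direction,
                        "n_outliers": a.size,
                        "p_value": wilcoxon_rank_sum(a, b),
                        "median_beta_outliers": float(np.median(a)),
                        "median_beta_others": float(np.median(b)),
                    }
                )
    cols = [
        "gene_id", "cpg_id", "region_class", "direction", "n_outliers",
        "p_value", "median_beta_outliers", "median_beta_others",
    ]
    df = pd.DataFrame(results, columns=cols)
    df["fdr"] = np.nan
    for direction in ("positive", "negative"):
        mask = df["direction"] == direction
        df.loc[mask, "fdr"] = benjamini_hochberg(df.loc[mask, "p_value"].to_numpy())
    df["median_rule"] = [
        _beta_rule(d, mo, mot, beta_rule_direction)
        for d, mo, mot in zip(
            df["direction"], df["median_beta_outliers"], df["median_beta_others"]
        )
    ]
    df["significant"] = (df["fdr"] < fdr_level) & df["median_rule"]
    return df


def summarize_methylation_genes(assoc: pd.DataFrame) -> pd.DataFrame:
    """Genes with ≥1 significant promoter CpG, per direction.

    Negative-direction hits are hypermethylation-associated silencing,
    positive-direction hits hypomethylation-associated overexpression
    (under the default rule direction).
    """
    return (
        assoc.groupby(["gene_id", "direction"])["significant"]
        .any()
        .rename("methylation_associated")
        .reset_index()
    )


def compare_context_distribution(assoc: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """Region-class distribution of significant vs non-significant CpGs.

    Returns (2 × classes contingency table, chi-square statistic,
    p-value); Pearson chi-square without continuity correction.  A
    degenerate table yields NaN statistics with a warning.
    """
    tab = pd.crosstab(assoc["significant"], assoc["region_class"])
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        logger.warning("degenerate context table %s; chi-square undefined", tab.shape)
        return tab, np.nan, np.nan
    chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    return tab, float(chi2), float(p)


def cimp_enrichment(
    atlas: OutlierAtlas,
    samples: SampleAnnotation,
    genes: pd.Index | None = None,
    fdr_level: float = FDR_LEVEL,
) -> pd.DataFrame:
    """CIMP enrichment among extreme negative outliers, per gene.

    Population = samples with a CIMP label; successes = CIMP-positive
    samples (CIMP-H ∪ CIMP-L); draws = the gene's extreme negative
    outliers within the population.  Upper-tail hypergeometric
    P(X ≥ observed), BH across the tested genes; ``cimp_associated``
    iff FDR < ``fdr_level``.  ``genes`` restricts testing (typically to
    genes with significant promoter hypermethylation).
    """
    labeled = samples.labeled_samples()
    if len(labeled) == 0:
        raise ValueError("no samples with CIMP labels")
    positive = set(samples.cimp_positive_samples())
    ext = atlas.extreme("negative")
    rows = []
    for gene_id, grp in ext.groupby("gene_id"):
        if genes is not None and gene_id not in genes:
            continue
        draws = [s for s in grp["sample_id"] if s in set(labeled)]
        if not draws:
            continue
        n_pos = sum(s in positive for s in draws)
        # P(X >= n_pos) under Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(n_pos - 1, len(labeled), len(positive), len(draws)))
        rows.append(
            {
                "gene_id": gene_id,
                "n_outliers": len(draws),
                "n_outliers_cimp_positive": n_pos,
                "cohort_size": len(labeled),
                "cohort_cimp_positive": len(positive),
                "p_value": p,
            }
        )
    cols = [
        "gene_id", "n_outliers", "n_outliers_cimp_positive",
        "cohort_size", "cohort_cimp_positive", "p_value",
    ]
    df = pd.DataFrame(rows, columns=cols)
    df["fdr"] = benjamini_hochberg(df["p_value"].to_numpy())
    df["cimp_associated"] = df["fdr"] < fdr_level
    return df
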