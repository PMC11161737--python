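"""Reference-free copy-number estimation from WES gene-level read depth.

Matched normal samples are usually unavailable for cell-line cohorts,
so a "metanormal" reference is built from the cohort itself:

1. per sample, gene copy-number (CN) values are the ratio between the
   gene's median read depth and the median read depth over all genes;
2. samples are clustered (PCA then k-means on the leading components)
   to group models sequenced with the same capture chemistry;
3. each cluster's metanormal takes, per gene, the median CN across the
   cluster's samples; genes whose metanormal falls below 0.1 in any
   cluster are excluded (not captured by the WES probes);
4. the log2 CNV of a gene in a sample is log2(sample CN / metanormal CN
   of the sample's cluster); calls are amplified when log2 CNV > 2 and
   deleted when log2 CNV < −2 (strict).

This corrects systematic gene-to-gene depth differences that reflect
probe affinity rather than copy number.  A matched-normal mode
(log2(tumor CN / normal CN)) is provided for validation, with the
per-sample Pearson correlation between the two CNV profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .outliers import OutlierAtlas

__all__ = [
    "DepthMatrix",
    "CnMatrix",
    "CnvResult",
    "load_depth_matrix",
    "compute_gene_cn",
    "cluster_samples",
    "build_metanormals",
    "compute_cnv",
    "cnv_with_matched_normal",
    "metanormal_vs_matched_correlation",
    "join_cnv_to_atlas",
    "run_cnv_pipeline",
]

AMP_THRESHOLD = 2.0
DEL_THRESHOLD = -2.0


@dataclass
class DepthMatrix:
    """Gene × sample median WES read depth (dense, non-negative)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any() or (arr < 0).any():
            raise ValueError("depth matrix must be dense and non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class CnMatrix:
    """Gene CN values: depth normalised to the per-sample median depth."""

    values: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def load_depth_matrix(path: str | Path) -> DepthMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return DepthMatrix(df.astype(float))


def compute_gene_cn(d: DepthMatrix) -> CnMatrix:
    """CN = gene depth / per-sample median depth over all genes."""
    med = d.values.median(axis=0)
    if (med == 0).any():
        bad = med.index[med == 0].tolist()
        raise ValueError(f"sample(s) with zero overall median depth: {bad[:10]}")
    return CnMatrix(d.values / med)


def cluster_samples(
    cn: CnMatrix,
    n_clusters: int = 3,
    n_components: int = 10,
    seed: int = 0,
    n_init: int = 25,
) -> pd.Series:
    """Cluster samples on their gene-CN profiles.

    PCA (centering only) on samples × genes, then k-means with
    ``n_init`` restarts on the first ``n_components`` components.
    Deterministic for a fixed seed.
    """
    X = cn.values.to_numpy(dtype=float).T  # samples × genes
    n_samples = X.shape[0]
    if n_clusters > n_samples:
        raise ValueError(f"n_clusters={n_clusters} exceeds {n_samples} samples")
    if n_clusters == 1:
        return pd.Series(0, index=cn.samples, name="cluster")
    k = min(n_components, n_samples, X.shape[1])
    pcs = PCA(n_components=k, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    labels = km.fit_predict(pcs)
    return pd.Series(labels, index=cn.samples, name="cluster")


def build_metanormals(
    cn: CnMatrix,
    clusters: pd.Series,
    min_cn: float = 0.1,
) -> tuple[pd.DataFrame, pd.Index]:
    """Per-cluster metanormal profiles and the excluded-gene list.

    The metanormal of a cluster is the per-gene median CN across its
    samples.  Genes with metanormal CN < ``min_cn`` in at least one
    cluster are excluded everywhere (probes absent from that capture
    kit).  Returns (genes × clusters metanormal table, excluded genes).
    """
    metanormals = {}
    for c in sorted(clusters.unique()):
        members = clusters.index[clusters == c]
        if len(members) == 0:
            raise ValueError(f"cluster {c} is empty")
        metanormals[c] = cn.values[members].median(axis=1)
    table = pd.DataFrame(metanormals)
    excluded = table.index[(table < min_cn).any(axis=1)]
    return table, excluded


def _call(log2cnv: pd.DataFrame) -> pd.DataFrame:
    call = pd.DataFrame("neutral", index=log2cnv.index, columns=log2cnv.columns)
    call = call.mask(log2cnv > AMP_THRESHOLD, "amplified")
    call = call.mask(log2cnv < DEL_THRESHOLD, "deleted")
    return call


@dataclass
class CnvResult:
    """log2 CNV values with amp/del/neutral calls and provenance."""

    log2: pd.DataFrame
    calls: pd.DataFrame
    clusters: pd.Series | None = None
    metanormals: pd.DataFrame | None = None
    excluded_genes: pd.Index | None = None

    def to_long(self) -> pd.DataFrame:
        long = self.log2.stack().rename("log2_cnv").reset_index()
        long.columns = ["gene_id", "sample_id", "log2_cnv"]
        long["call"] = self.calls.stack().to_numpy()
        return long


def compute_cnv(
    cn: CnMatrix,
    metanormals: pd.DataFrame,
    clusters: pd.Series,
) -> CnvResult:
    """log2(sample CN / cluster metanormal CN) with strict ±2 calls.

    Genes still present with a zero metanormal in their cluster are a
    contract violation (they should have been excluded) and raise.
    """
    ref = metanormals[clusters.loc[cn.samples].to_numpy()].to_numpy()  # genes × samples
    if (ref <= 0).any():
        raise ValueError("zero/negative metanormal CN for a retained gene")
    with np.errstate(divide="ignore"):
        log2 = pd.DataFrame(
            np.log2(cn.values.to_numpy() / ref), index=cn.genes, columns=cn.samples
        )
    return CnvResult(
        log2=log2, calls=_call(log2), clusters=clusters, metanormals=metanormals
    )


def cnv_with_matched_normal(cn_tumor: CnMatrix, cn_normal: CnMatrix) -> CnvResult:
    """Validation mode: log2(tumor CN / matched-normal CN) per sample."""
    if not cn_tumor.values.shape == cn_normal.values.shape:
        raise ValueError("tumor and normal CN matrices differ in shape")
    if not (cn_tumor.genes.equals(cn_normal.genes) and cn_tumor.samples.equals(cn_normal.samples)):
        raise ValueError("tumor and normal CN matrices must share genes and samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = pd.DataFrame(
            np.log2(cn_tumor.values.to_numpy() / cn_normal.values.to_numpy()),
            index=cn_tumor.genes,
            columns=cn_tumor.samples,
        )
    return CnvResult(log2=log2, calls=_call(log2))


def metanormal_vs_matched_correlation(
    meta: CnvResult, matched: CnvResult
) -> pd.Series:
    """Per-sample Pearson r between metanormal and matched-normal log2 CNV.

    Computed over the genes shared by both results, pairwise-complete
    (non-finite log2 values dropped per sample).
    """
    genes = meta.log2.index.intersection(matched.log2.index)
    out = {}
    for s in meta.log2.columns:
        a = meta.log2.loc[genes, s].to_numpy()
        b = matched.log2.loc[genes, s].to_numpy()
        ok = np.isfinite(a) & np.isfinite(b)
        out[s] = float(np.corrcoef(a[ok], b[ok])[0, 1]) if ok.sum() > 2 else np.nan
    return pd.Series(out, name="pearson_r")


def join_cnv_to_atlas(atlas: OutlierAtlas, cnv: CnvResult) -> pd.DataFrame:
    """Annotate extreme calls with their CNV status.

    Adds ``log2_cnv`` and ``cnv_call`` per extreme call (NA when the
    gene was excluded from CNV) and a ``cnv_associated`` flag: positive
    call + amplified, or negative call + deleted.
    """
    ext = atlas.extreme().copy()
    log2 = []
    call = []
    for g, s in zip(ext["gene_id"], ext["sample_id"]):
        if g in cnv.log2.index and s in cnv.log2.columns:
            log2.append(cnv.log2.at[g, s])
            call.append(cnv.calls.at[g, s])
        else:
            log2.append(np.nan)
            call.append("NA")
    ext["log2_cnv"] = log2
    ext["cnv_call"] = call
    ext["cnv_associated"] = (
        ((ext["direction"] == "positive") & (ext["cnv_call"] == "amplified"))
        | ((ext["direction"] == "negative") & (ext["cnv_call"] == "deleted"))
    )
    return ext


def summarize_cnv_association(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per gene/direction: does ≥1 extreme call carry the matching CNV?"""
    return (
        annotated.groupby(["gene_id", "direction"])["cnv_associated"]
        .any()
        .rename("any_cnv_associated")
        .reset_index()
    )


def run_cnv_pipeline(
    d: DepthMatrix,
    n_clusters: int = 3,
    n_components: int = 10,
    seed: int = 0,
    min_cn: float = 0.1,
) -> CnvResult:
    """Depth → CN → clusters → metanormals → log2 CNV, end to end."""
    cn = compute_gene_cn(d)
    clusters = cluster_samples(cn, n_clusters=n_clusters, n_components=n_components, seed=seed)
    metanormals, excluded = build_metanormals(cn, clusters, min_cn=min_cn)
    retained = cn.genes.difference(excluded)
    cn_kept = CnMatrix(cn.values.loc[retained])
    res = compute_cnv(cn_kept, metanormals.loc[retained], clusters)
    res.excluded_genes = excluded
    return res
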