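"""Transcriptome-wide extreme expression-outlier calling.

The workflow has two parts.  First, Tukey's rule is applied per gene to
log2-transformed FPKM values: with Q1/Q3 the first/third quartiles and
IQR = Q3 − Q1, samples strictly above Q3 + k·IQR (k = 1.5) are positive
outliers and samples strictly below Q1 − k·IQR are negative outliers.
Second, a funnel of filters keeps only the strongest events:

1. *furthest* selection — among a gene's positive outliers, keep those
   at least as close (in log2 space) to the maximum expression value as
   to the highest non-outlier value; mirrored for negative outliers
   against the minimum and the lowest non-outlier value.  Ties are kept
   and the extremum itself always survives.
2. *differential* filter — the log2 fold change versus the cohort
   median, log2((FPKM+1)/(median+1)), must exceed 3 in absolute value.
3. *absolute* filter — positive outliers need FPKM > 10, negative
   outliers FPKM < 1.

Calls surviving all three are "extreme" outliers.  Every threshold
comparison is strict, exactly as defined.

Per-sample outlier burdens normalise the number of extreme calls by the
number of genes at which the sample was eligible (FPKM > 10 for the
positive burden, FPKM < 1 for the negative), times 1000.

``calibrate_thresholds`` re-tunes the differential thresholds for a new
cohort (e.g. tissue instead of cell lines) so that the fraction of
Tukey-stage genes surviving to the extreme stage matches a reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core_data import ExpressionMatrix, GeneAnnotation

__all__ = [
    "TukeyFences",
    "ExtremeThresholds",
    "OutlierAtlas",
    "tukey_fences",
    "call_tukey_outliers",
    "select_furthest",
    "differential_expression",
    "apply_extreme_filters",
    "call_extreme_outliers",
    "compute_burden",
    "calibrate_thresholds",
]

logger = logging.getLogger(__name__)

MIN_COHORT_SIZE = 4

ATLAS_COLUMNS = [
    "gene_id",
    "symbol",
    "sample_id",
    "direction",
    "stage",
    "fpkm",
    "median_fpkm",
    "log2fc",
]

STAGE_ORDER = {"tukey": 0, "furthest": 1, "extreme": 2}


@dataclass(frozen=True)
class TukeyFences:
    """Quartiles and outlier fences of one gene's log2 expression."""

    gene_id: str
    q1: float
    q3: float
    k: float = 1.5

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lower_fence(self) -> float:
        return self.q1 - self.k * self.iqr

    @property
    def upper_fence(self) -> float:
        return self.q3 + self.k * self.iqr


@dataclass(frozen=True)
class ExtremeThresholds:
    """Thresholds of the outlier funnel (all comparisons strict).

    tukey_k     fence multiplier on the IQR
    diff_pos    minimum log2 fold change for extreme positive outliers
    diff_neg    minimum |log2 fold change| for extreme negative outliers
    abs_pos     FPKM floor for extreme positive outliers
    abs_neg     FPKM ceiling for extreme negative outliers
    """

    tukey_k: float = 1.5
    diff_pos: float = 3.0
    diff_neg: float = 3.0
    abs_pos: float = 10.0
    abs_neg: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tukey_k", "diff_pos", "diff_neg", "abs_pos", "abs_neg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be > 0")


def _log2_transform(values: np.ndarray, mode: str) -> np.ndarray:
    """Transform FPKM to the log2 space used for fences and distances."""
    if mode == "log2p1":
        return np.log2(values + 1.0)
    if mode == "log2_dropzero":
        out = np.full_like(values, np.nan, dtype=float)
        nz = values > 0
        out[nz] = np.log2(values[nz])
        return out
    if mode == "none":
        return np.asarray(values, dtype=float)
    raise ValueError(f"unknown transform mode {mode!r}")


def tukey_fences(
    values: Sequence[float],
    k: float = 1.5,
    *,
    gene_id: str = "",
    transform: str = "log2p1",
) -> TukeyFences:
    """Tukey fences for one gene.

    ``values`` are FPKM (transformed to log2(FPKM+1) by default) or,
    with ``transform="none"``, values already on the log2 scale.
    Quartiles use linear interpolation between order statistics (the
    type-7 convention).  At least 4 observations are required.
    """
    x = _log2_transform(np.asarray(values, dtype=float), transform)
    x = x[~np.isnan(x)]
    if x.size < MIN_COHORT_SIZE:
        raise ValueError(
            f"need at least {MIN_COHORT_SIZE} values to place quartile fences, got {x.size}"
        )
    q1, q3 = np.quantile(x, [0.25, 0.75])
    return TukeyFences(gene_id=gene_id, q1=float(q1), q3=float(q3), k=k)


def differential_expression(fpkm, median_fpkm):
    """log2 fold change versus the cohort median: log2((FPKM+1)/(median+1))."""
    return np.log2((np.asarray(fpkm, dtype=float) + 1.0) / (np.asarray(median_fpkm, dtype=float) + 1.0))


class OutlierAtlas:
    """All outlier calls of a cohort with the last funnel stage each survived.

    One row per (gene, sample, direction); ``stage`` is the deepest
    stage the call reached (tukey → furthest → extreme), so per-stage
    call sets are recovered as ``stage >= s`` in funnel order.
    """

    def __init__(self, calls: pd.DataFrame):
        missing = [c for c in ATLAS_COLUMNS if c not in calls.columns]
        if missing:
            raise ValueError(f"atlas table missing columns {missing}")
        self.calls = calls.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.calls)

    def at_stage(self, stage: str, direction: str | None = None) -> pd.DataFrame:
        """Calls that survived at least *stage*, optionally one direction."""
        rank = STAGE_ORDER[stage]
        df = self.calls[self.calls["stage"].map(STAGE_ORDER) >= rank]
        if direction is not None:
            df = df[df["direction"] == direction]
        return df

    def extreme(self, direction: str | None = None) -> pd.DataFrame:
        return self.at_stage("extreme", direction)

    def genes_at_stage(self, stage: str, direction: str) -> pd.Index:
        return pd.Index(self.at_stage(stage, direction)["gene_id"].unique())

    def stage_funnel(self) -> pd.DataFrame:
        """Genes with ≥1 call per stage and direction (the cohort funnel)."""
        rows = []
        for direction in ("positive", "negative"):
            for stage in ("tukey", "furthest", "extreme"):
                sub = self.at_stage(stage, direction)
                rows.append(
                    {
                        "direction": direction,
                        "stage": stage,
                        "n_genes": sub["gene_id"].nunique(),
                        "n_calls": len(sub),
                    }
                )
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.calls.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "OutlierAtlas":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str, "sample_id": str})
        return cls(df)


def _chain_masks(
    values: np.ndarray,
    th: ExtremeThresholds,
    transform: str,
) -> dict[str, np.ndarray]:
    """Vectorised funnel over a genes × samples FPKM array.

    Returns boolean (G, S) masks for every stage/direction plus the
    log2 fold-change matrix.
    """
    X = _log2_transform(values, transform)
    if np.isnan(X).any():
        # log2_dropzero leaves NaN at zero FPKM; NaNs never become calls
        q1 = np.nanquantile(X, 0.25, axis=1)
        q3 = np.nanquantile(X, 0.75, axis=1)
    else:
        q1, q3 = np.quantile(X, [0.25, 0.75], axis=1)
    iqr = q3 - q1
    upper = q3 + th.tukey_k * iqr
    lower = q1 - th.tukey_k * iqr

    with np.errstate(invalid="ignore"):
        pos = X > upper[:, None]
        neg = X < lower[:, None]

    # furthest selection, in the same log2 space as the fences
    neg_inf = np.float64(-np.inf)
    pos_inf = np.float64(np.inf)
    Xp = np.where(np.isnan(X), neg_inf, X)
    Xn = np.where(np.isnan(X), pos_inf, X)
    M = Xp.max(axis=1)
    m_ = Xn.min(axis=1)
    highest_non_out = np.where(pos, neg_inf, Xp).max(axis=1)
    lowest_non_out = np.where(neg, pos_inf, Xn).min(axis=1)
    with np.errstate(invalid="ignore"):
        furth_pos = pos & (2.0 * X >= (M + highest_non_out)[:, None])
        furth_neg = neg & (2.0 * X <= (m_ + lowest_non_out)[:, None])

    med = np.median(values, axis=1)
    log2fc = np.log2((values + 1.0) / (med + 1.0)[:, None])

    ext_pos = furth_pos & (log2fc > th.diff_pos) & (values > th.abs_pos)
    ext_neg = furth_neg & (-log2fc > th.diff_neg) & (values < th.abs_neg)

    return {
        "tukey_pos": pos,
        "tukey_neg": neg,
        "furthest_pos": furth_pos,
        "furthest_neg": furth_neg,
        "extreme_pos": ext_pos,
        "extreme_neg": ext_neg,
        "log2fc": log2fc,
        "median": med,
        "upper": upper,
        "lower": lower,
    }


def call_tukey_outliers(
    m: ExpressionMatrix,
    k: float = 1.5,
    *,
    transform: str = "log2p1",
) -> OutlierAtlas:
    """Tukey-stage calls only (no funnel filters applied)."""
    th = ExtremeThresholds(tukey_k=k)
    atlas = call_extreme_outliers(m, thresholds=th, transform=transform)
    calls = atlas.calls.copy()
    calls["stage"] = "tukey"
    return OutlierAtlas(calls)


def select_furthest(
    calls: pd.DataFrame,
    values: Sequence[float],
    *,
    transform: str = "log2p1",
) -> pd.DataFrame:
    """Furthest-outlier selection for the calls of a single gene/direction.

    ``calls`` carries Tukey-stage calls of one gene and one direction
    (column ``sample_index`` into *values*); ``values`` is the gene's
    full FPKM vector.  Returns the subset kept by the distance rule,
    ties inclusive.
    """
    if calls.empty:
        return calls
    directions = calls["direction"].unique()
    if len(directions) != 1:
        raise ValueError("select_furthest expects calls of a single direction")
    direction = directions[0]
    x = _log2_transform(np.asarray(values, dtype=float), transform)
    idx = calls["sample_index"].to_numpy()
    out_mask = np.zeros(x.size, dtype=bool)
    out_mask[idx] = True
    xi = x[idx]
    if direction == "positive":
        non_out = x[~out_mask]
        ref = non_out.max() if non_out.size else -np.inf
        keep = (x.max() - xi) <= (xi - ref)
    else:
        non_out = x[~out_mask]
        ref = non_out.min() if non_out.size else np.inf
        keep = (xi - x.min()) <= (ref - xi)
    return calls[keep]


def apply_extreme_filters(
    calls: pd.DataFrame,
    th: ExtremeThresholds = ExtremeThresholds(),
) -> pd.DataFrame:
    """Differential + absolute filters on furthest-stage calls.

    Expects columns ``direction``, ``fpkm`` and ``log2fc``; keeps
    positive calls with log2fc > diff_pos and FPKM > abs_pos, negative
    calls with −log2fc > diff_neg and FPKM < abs_neg (all strict).
    """
    pos = calls["direction"] == "positive"
    keep = np.where(
        pos,
        (calls["log2fc"] > th.diff_pos) & (calls["fpkm"] > th.abs_pos),
        (-calls["log2fc"] > th.diff_neg) & (calls["fpkm"] < th.abs_neg),
    )
    return calls[keep]


def call_extreme_outliers(
    m: ExpressionMatrix,
    ann: GeneAnnotation | None = None,
    thresholds: ExtremeThresholds = ExtremeThresholds(),
    *,
    transform: str = "log2p1",
) -> OutlierAtlas:
    """Run the full funnel (Tukey → furthest → extreme) on a cohort matrix.

    The matrix is expected to have passed the cohort filters and sex-
    chromosome exclusion.  Every Tukey-stage call is recorded with the
    deepest stage it survived.
    """
    if m.shape[1] < MIN_COHORT_SIZE:
        raise ValueError(
            f"cohort has {m.shape[1]} samples; at least {MIN_COHORT_SIZE} required"
        )
    V = m.values.to_numpy(dtype=float)
    masks = _chain_masks(V, thresholds, transform)

    symbols = None
    if ann is not None:
        symbols = ann.require(m.genes)["symbol"]

    frames = []
    for direction in ("positive", "negative"):
        suffix = "pos" if direction == "positive" else "neg"
        tk = masks[f"tukey_{suffix}"]
        fr = masks[f"furthest_{suffix}"]
        ex = masks[f"extreme_{suffix}"]
        gi, si = np.nonzero(tk)
        if gi.size == 0:
            continue
        stage = np.where(ex[gi, si], "extreme", np.where(fr[gi, si], "furthest", "tukey"))
        genes = m.genes.to_numpy()[gi]
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "symbol": symbols.loc[genes].to_numpy() if symbols is not None else genes,
                    "sample_id": m.samples.to_numpy()[si],
                    "direction": direction,
                    "stage": stage,
                    "fpkm": V[gi, si],
                    "median_fpkm": masks["median"][gi],
                    "log2fc": masks["log2fc"][gi, si],
                }
            )
        )
    if frames:
        calls = pd.concat(frames, ignore_index=True)
        calls = calls.sort_values(["gene_id", "direction", "sample_id"], kind="stable")
    else:
        calls = pd.DataFrame(columns=ATLAS_COLUMNS)
    return OutlierAtlas(calls)


def compute_burden(
    atlas: OutlierAtlas,
    m: ExpressionMatrix,
    th: ExtremeThresholds = ExtremeThresholds(),
) -> pd.DataFrame:
    """Per-sample outlier burdens.

    positive burden = 1000 · (# extreme positive calls) / (# genes with
    FPKM > abs_pos in the sample); negative burden mirrored with
    FPKM < abs_neg.  A zero denominator yields a missing burden, and
    the total burden is the sum of the two (missing treated as 0 only
    when the other part exists).
    """
    V = m.values.to_numpy(dtype=float)
    denom_pos = pd.Series((V > th.abs_pos).sum(axis=0), index=m.samples, dtype=float)
    denom_neg = pd.Series((V < th.abs_neg).sum(axis=0), index=m.samples, dtype=float)
    ext = atlas.extreme()
    n_over = ext[ext["direction"] == "positive"].groupby("sample_id").size()
    n_under = ext[ext["direction"] == "negative"].groupby("sample_id").size()
    out = pd.DataFrame(index=m.samples)
    out.index.name = "sample_id"
    out["n_over"] = n_over.reindex(m.samples).fillna(0).astype(int)
    out["n_under"] = n_under.reindex(m.samples).fillna(0).astype(int)
    out["denom_pos"] = denom_pos.astype(int)
    out["denom_neg"] = denom_neg.astype(int)
    out["pos_burden"] = 1000.0 * out["n_over"] / denom_pos.replace(0, np.nan)
    out["neg_burden"] = 1000.0 * out["n_under"] / denom_neg.replace(0, np.nan)
    out["total_burden"] = out["pos_burden"].fillna(0) + out["neg_burden"].fillna(0)
    both_missing = out["pos_burden"].isna() & out["neg_burden"].isna()
    out.loc[both_missing, "total_burden"] = np.nan
    return out


def achieved_fractions(
    m: ExpressionMatrix,
    th: ExtremeThresholds,
    *,
    transform: str = "log2p1",
) -> tuple[float, float]:
    """Fraction of Tukey-stage genes retaining ≥1 extreme call, per direction."""
    masks = _chain_masks(m.values.to_numpy(dtype=float), th, transform)
    out = []
    for suffix in ("pos", "neg"):
        n_tukey = int(masks[f"tukey_{suffix}"].any(axis=1).sum())
        n_ext = int(masks[f"extreme_{suffix}"].any(axis=1).sum())
        out.append(n_ext / n_tukey if n_tukey else np.nan)
    return out[0], out[1]


def calibrate_thresholds(
    m_target: ExpressionMatrix,
    reference_fractions: tuple[float, float],
    search_grid: Sequence[float] | None = None,
    base: ExtremeThresholds = ExtremeThresholds(),
    *,
    transform: str = "log2p1",
) -> ExtremeThresholds:
    """Re-tune the differential thresholds for a new cohort.

    For each direction, every grid candidate replaces the differential
    threshold (absolute-expression thresholds stay fixed) and the
    achieved fraction — genes with ≥1 extreme call over genes with ≥1
    Tukey call — is compared to the reference fraction; the candidate
    minimising the absolute gap wins (ties broken toward the smaller
    threshold, deterministically).
    """
    if search_grid is None:
        search_grid = np.arange(0.5, 4.0 + 1e-9, 0.25)
    grid = sorted(float(g) for g in search_grid)
    if not grid:
        raise ValueError("empty calibration search grid")

    V = m_target.values.to_numpy(dtype=float)
    masks = _chain_masks(V, base, transform)
    log2fc = masks["log2fc"]
    ref_pos, ref_neg = reference_fractions

    def achieved(direction: str, diff: float) -> float:
        if direction == "positive":
            furth = masks["furthest_pos"]
            n_tukey = int(masks["tukey_pos"].any(axis=1).sum())
            ext = furth & (log2fc > diff) & (V > base.abs_pos)
        else:
            furth = masks["furthest_neg"]
            n_tukey = int(masks["tukey_neg"].any(axis=1).sum())
            ext = furth & (-log2fc > diff) & (V < base.abs_neg)
        if n_tukey == 0:
            return np.nan
        return ext.any(axis=1).sum() / n_tukey

    def best(direction: str, ref: float) -> float:
        gaps = [(abs(achieved(direction, g) - ref), g) for g in grid]
        return min(gaps, key=lambda t: (t[0], t[1]))[1]

    return ExtremeThresholds(
        tukey_k=base.tukey_k,
        diff_pos=best("positive", ref_pos),
        diff_neg=best("negative", ref_neg),
        abs_pos=base.abs_pos,
        abs_neg=base.abs_neg,
    )
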