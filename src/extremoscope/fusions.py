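"""Fusion-transcript harmonisation and matching to overexpression.

Calls from two callers are intersected at the gene level: caller-A
calls are kept when their read support exceeds FFPM > 0.1, they are
not flagged as likely artifacts ("red herrings"), and caller B reports
the same ordered (5′ gene, 3′ gene) pair in the same sample.  Fusions
whose 3′ partner gene is amplified in the carrier sample are excluded,
since such fusions are typically a by-product of chromosomal
instability rather than a regulatory event.  Surviving fusions are
matched against the outlier atlas: a fusion is "matched" when its
carrier sample is an extreme positive outlier for the 3′ partner gene
(the fusion putting the 3′ gene under a stronger promoter).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import CnvResult
from .outliers import OutlierAtlas

__all__ = [
    "load_fusion_calls",
    "filter_and_intersect",
    "exclude_amplification_associated",
    "match_to_outliers",
]

FFPM_CUTOFF = 0.1

FUSION_COLUMNS = ["sample_id", "gene5", "gene3"]


def load_fusion_calls(path: str | Path) -> pd.DataFrame:
    """Fusion TSV with columns sample_id, gene5, gene3 [, ffpm, red_herring]."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene5": str, "gene3": str})
    if "red_herring" in df.columns:
        df["red_herring"] = (
            df["red_herring"].astype(str).str.lower().isin(["true", "1", "yes"])
        )
    if (df["gene5"] == df["gene3"]).any():
        raise ValueError("fusion with identical 5' and 3' partner")
    return df


def filter_and_intersect(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    ffpm_cutoff: float = FFPM_CUTOFF,
) -> pd.DataFrame:
    """Support/annotation filters on caller A, then the caller-B intersection.

    Keeps caller-A calls with ffpm > cutoff (strict), red_herring
    false, and a caller-B call with the same ordered gene pair in the
    same sample.  Output rows are a subset of caller-A rows.
    """
    a = calls_a.copy()
    if "ffpm" in a.columns:
        a = a[a["ffpm"] > ffpm_cutoff]
    if "red_herring" in a.columns:
        a = a[~a["red_herring"].astype(bool)]
    b_keys = set(zip(calls_b["sample_id"], calls_b["gene5"], calls_b["gene3"]))
    in_b = [
        (s, g5, g3) in b_keys
        for s, g5, g3 in zip(a["sample_id"], a["gene5"], a["gene3"])
    ]
    return a[np.asarray(in_b, dtype=bool)].reset_index(drop=True)


def exclude_amplification_associated(
    fusions: pd.DataFrame,
    cnv: CnvResult | None,
) -> pd.DataFrame:
    """Drop fusions whose 3′ gene is amplified in the carrier sample.

    Fusions for genes/samples without CNV data are kept (conservative)
    and flagged ``cnv_available=False``.
    """
    out = fusions.copy()
    if cnv is None:
        out["cnv_available"] = False
        return out
    available = []
    amplified = []
    for s, g3 in zip(out["sample_id"], out["gene3"]):
        if g3 in cnv.calls.index and s in cnv.calls.columns:
            available.append(True)
            amplified.append(cnv.calls.at[g3, s] == "amplified")
        else:
            available.append(False)
            amplified.append(False)
    out["cnv_available"] = available
    return out[~np.asarray(amplified, dtype=bool)].reset_index(drop=True)


def match_to_outliers(
    fusions: pd.DataFrame,
    atlas: OutlierAtlas,
    median_fpkm: pd.Series | None = None,
) -> pd.DataFrame:
    """Match each fusion to 3′-partner overexpression.

    Adds ``matched`` (carrier sample is an extreme positive outlier for
    gene3) and, when per-gene median FPKM is supplied,
    ``gene3_unexpressed_cohort`` (median FPKM < 1 — the 3′ partner is
    silent in most models and only expressed in fusion carriers).
    """
    ext = atlas.extreme("positive")
    key = set(zip(ext["gene_id"], ext["sample_id"]))
    # the atlas records symbols too; accept a match on either identifier
    key |= set(zip(ext["symbol"], ext["sample_id"]))
    out = fusions.copy()
    out["matched"] = [
        (g3, s) in key for s, g3 in zip(out["sample_id"], out["gene3"])
    ]
    if median_fpkm is not None:
        out["gene3_unexpressed_cohort"] = [
            bool(median_fpkm.get(g3, np.nan) < 1.0) for g3 in out["gene3"]
        ]
    return out
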