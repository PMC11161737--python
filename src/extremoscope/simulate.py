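"""Synthetic cohort generators with planted, serialisable ground truth.

Every pipeline input (FPKM matrix, gene annotation, WES depth matrix,
β-matrix + CpG manifest + CGI track, dual-caller fusion tables, sample
annotations) can be generated here with known planted events, so each
downstream stage's sensitivity and false-call rate can be measured
without any external data.  All generators are pure functions of their
parameters and seed.

Models emulated (and deliberately simplified):

* expression — per-gene baseline log2(FPKM+1) uniform in [2, 8] with
  Gaussian sample noise (σ = 0.3 in log2 space); overexpression plants
  add a +6 log2 shift to one sample of a gene, underexpression plants
  zero out the FPKM of a well-expressed gene (baseline median ≥ ~9
  FPKM) so the differential filter is attainable;
* WES depth — per-cluster probe-affinity profiles (capture-chemistry
  bias) times a per-sample library scale, with planted ratio-8
  amplifications and ratio-1/8 deletions and optional log2-Gaussian
  multiplicative noise; a matched-normal depth matrix shares the
  affinities and scale but carries no plants;
* methylation — β-values from Beta distributions concentrated at 0.1
  (unmethylated) and 0.9 (methylated); planted genes switch their
  outlier samples' promoter CpGs to the opposite state;
* fusions — surviving fusions appear in both callers with clean flags
  and FFPM > 0.1; each decoy violates exactly one filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import CnvResult, DepthMatrix
from .core_data import ExpressionMatrix, GeneAnnotation, SampleAnnotation
from .methylation import BetaMatrix

__all__ = [
    "SyntheticTruth",
    "simulate_expression",
    "simulate_depth",
    "simulate_methylation",
    "simulate_fusions",
    "simulate_sample_annotation",
]

AUTOSOMES = [f"chr{i}" for i in range(1, 23)]


@dataclass
class SyntheticTruth:
    """Planted events of a simulated cohort, serialisable to JSON."""

    seed: int
    planted_outliers: pd.DataFrame | None = None
    planted_cnv: pd.DataFrame | None = None
    clusters: pd.Series | None = None
    planted_meth: pd.DataFrame | None = None
    planted_fusions: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        payload: dict = {"seed": self.seed}
        for name in ("planted_outliers", "planted_cnv", "planted_meth", "planted_fusions"):
            df = getattr(self, name)
            payload[name] = df.to_dict(orient="records") if df is not None else None
        payload["clusters"] = (
            self.clusters.astype(int).to_dict() if self.clusters is not None else None
        )
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        kw: dict = {"seed": payload["seed"]}
        for name in ("planted_outliers", "planted_cnv", "planted_meth", "planted_fusions"):
            rec = payload.get(name)
            kw[name] = pd.DataFrame(rec) if rec is not None else None
        if payload.get("clusters") is not None:
            kw["clusters"] = pd.Series(payload["clusters"], name="cluster")
        return cls(**kw)


def _gene_ids(n: int, prefix: str = "ENSG9") -> list[str]:
    return [f"{prefix}{i:08d}" for i in range(1, n + 1)]


def _sample_ids(n: int) -> list[str]:
    return [f"CL{i:04d}" for i in range(1, n + 1)]


def make_gene_annotation(
    gene_ids: list[str],
    chromosomes: list[str] | None = None,
    biotypes: list[str] | None = None,
) -> GeneAnnotation:
    """Deterministic toy annotation: round-robin autosomes, spaced TSSs."""
    n = len(gene_ids)
    rows = {
        "symbol": [f"SYM{i+1}" for i in range(n)],
        "chromosome": chromosomes or [AUTOSOMES[i % len(AUTOSOMES)] for i in range(n)],
        "strand": ["+" if i % 2 == 0 else "-" for i in range(n)],
        "tss_list": [(1_000_000 + (i // 22) * 100_000,) for i in range(n)],
        "biotype": biotypes or ["protein_coding"] * n,
        "par_y": [False] * n,
    }
    return GeneAnnotation(pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene_id")))


def simulate_expression(
    n_genes: int = 2000,
    n_samples: int = 200,
    n_positive: int = 100,
    n_negative: int = 100,
    pos_shift: float = 6.0,
    noise_sigma: float = 0.3,
    baseline_range: tuple[float, float] = (2.0, 8.0),
    pos_per_gene: int = 1,
    neg_per_gene: int = 1,
    seed: int = 42,
) -> tuple[ExpressionMatrix, GeneAnnotation, SyntheticTruth]:
    """FPKM cohort with planted extreme outliers.

    ``n_positive`` / ``n_negative`` count planted *genes*; each gets
    ``pos_per_gene`` / ``neg_per_gene`` planted samples.  Positive
    plants add ``pos_shift`` (log2) to the chosen samples of a gene;
    negative plants set their FPKM to 0 on genes with baseline mean
    log2(FPKM+1) ≥ 3.33 (median FPKM ≈ 9), so both directions clear
    every funnel filter by construction.  A gene carries plants of at
    most one direction.
    """
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    samples = _sample_ids(n_samples)
    lo, hi = baseline_range
    mu = rng.uniform(lo, hi, size=n_genes)
    X = mu[:, None] + rng.normal(0.0, noise_sigma, size=(n_genes, n_samples))

    neg_eligible = np.flatnonzero(mu >= 3.33)
    if n_negative > neg_eligible.size:
        raise ValueError(
            f"only {neg_eligible.size} genes have a high enough baseline for "
            f"negative plants; requested {n_negative}"
        )
    if n_positive + n_negative > n_genes:
        raise ValueError("more plants than genes")
    neg_genes = rng.choice(neg_eligible, size=n_negative, replace=False)
    pos_pool = np.setdiff1d(np.arange(n_genes), neg_genes)
    pos_genes = rng.choice(pos_pool, size=n_positive, replace=False)

    events = []
    for gi in pos_genes:
        for si in rng.choice(n_samples, size=pos_per_gene, replace=False):
            X[gi, si] = mu[gi] + pos_shift
            events.append(
                {"gene_id": genes[gi], "sample_id": samples[si], "direction": "positive",
                 "log2_shift": pos_shift}
            )
    fpkm = np.maximum(np.exp2(X) - 1.0, 0.0)
    for gi in neg_genes:
        for si in rng.choice(n_samples, size=neg_per_gene, replace=False):
            fpkm[gi, si] = 0.0
            events.append(
                {"gene_id": genes[gi], "sample_id": samples[si], "direction": "negative",
                 "log2_shift": -float(mu[gi])}
            )

    m = ExpressionMatrix(pd.DataFrame(fpkm, index=pd.Index(genes, name="gene_id"), columns=samples))
    ann = make_gene_annotation(genes)
    truth = SyntheticTruth(seed=seed, planted_outliers=pd.DataFrame(events))
    return m, ann, truth


def simulate_calibration_cohort(
    n_genes: int = 2000,
    n_samples: int = 150,
    n_positive: int = 150,
    n_negative: int = 150,
    noise_sigma: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, GeneAnnotation, SyntheticTruth]:
    """Cohort with a *spread* of planted effect sizes for threshold tuning.

    Unlike :func:`simulate_expression`, whose plants all clear the
    default filters by a wide margin, positive plants here draw their
    log2 fold change uniformly from [1, 5] and negative plants leave a
    residual FPKM so that |log2fc| varies continuously across the
    calibration grid — the achieved extreme/Tukey gene fraction then
    changes at (essentially) every candidate threshold.
    """
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes, prefix="ENSG7")
    samples = _sample_ids(n_samples)
    mu = rng.uniform(1.2, 7.0, size=n_genes)
    X = mu[:, None] + rng.normal(0.0, noise_sigma, size=(n_genes, n_samples))
    fpkm = np.maximum(np.exp2(X) - 1.0, 0.0)
    med = np.exp2(mu) - 1.0  # design median, close to the realised one

    if n_positive + n_negative > n_genes:
        raise ValueError("more plants than genes")
    order = rng.permutation(n_genes)
    pos_genes, neg_pool = order[:n_positive], order[n_positive:]
    neg_genes = neg_pool[mu[neg_pool] >= 1.3][:n_negative]

    events = []
    for gi in pos_genes:
        si = int(rng.integers(n_samples))
        d = float(rng.uniform(1.0, 5.0))
        fpkm[gi, si] = (med[gi] + 1.0) * np.exp2(d) - 1.0
        events.append({"gene_id": genes[gi], "sample_id": samples[si],
                       "direction": "positive", "log2_shift": d})
    for gi in neg_genes:
        si = int(rng.integers(n_samples))
        # residual expression below 1 FPKM: |log2fc| = mu - u, u in (0, 1)
        d = float(mu[gi] - rng.uniform(0.05, 0.95))
        fpkm[gi, si] = max((med[gi] + 1.0) / np.exp2(d) - 1.0, 0.0)
        events.append({"gene_id": genes[gi], "sample_id": samples[si],
                       "direction": "negative", "log2_shift": -d})

    m = ExpressionMatrix(pd.DataFrame(fpkm, index=pd.Index(genes, name="gene_id"), columns=samples))
    truth = SyntheticTruth(seed=seed, planted_outliers=pd.DataFrame(events))
    return m, make_gene_annotation(genes), truth


def simulate_depth(
    n_genes: int = 1001,
    n_samples: int = 30,
    n_clusters: int = 3,
    n_amp: int = 30,
    n_del: int = 30,
    amp_ratio: float = 8.0,
    del_ratio: float = 0.125,
    noise_sigma: float = 0.0,
    mean_depth: float = 100.0,
    gene_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
    seed: int = 7,
) -> tuple[DepthMatrix, DepthMatrix, SyntheticTruth]:
    """WES depth cohort with cluster-specific probe-affinity bias.

    Each cluster gets its own per-gene capture-affinity profile (shared
    base × cluster-specific log2-Gaussian factor), each sample a random
    library scale.  Planted amplifications multiply one (gene, sample)
    depth by ``amp_ratio``; deletions by ``del_ratio``.  ``noise_sigma``
    is the SD of log2-space multiplicative noise.  Returns the tumor
    depth matrix, a plant-free matched-normal matrix sharing affinity
    and scale, and the truth (plants + cluster labels).

    Amplifications are planted on genes with above-cluster-median
    affinity and deletions on below-median genes (with the gene count
    odd); the per-sample median depth is then provably unchanged by the
    plants, so in the noiseless case the log2 CNV of a planted cell is
    exactly log2 of its ratio.
    """
    rng = np.random.default_rng(seed)
    genes = gene_ids if gene_ids is not None else _gene_ids(n_genes, prefix="ENSG8")
    samples = sample_ids if sample_ids is not None else _sample_ids(n_samples)
    if len(genes) != n_genes or len(samples) != n_samples:
        raise ValueError("gene_ids/sample_ids lengths must match n_genes/n_samples")
    base = np.exp2(rng.normal(0.0, 1.0, size=n_genes))
    affinity = base[None, :] * np.exp2(rng.normal(0.0, 0.5, size=(n_clusters, n_genes)))
    labels = np.arange(n_samples) % n_clusters
    rng.shuffle(labels)
    scale = np.exp2(rng.normal(0.0, 0.25, size=n_samples))

    clean = affinity[labels, :].T * scale[None, :]  # genes × samples

    # avoid planting on genes near the metanormal exclusion threshold
    rel = affinity / np.median(affinity, axis=1, keepdims=True)
    robust = (rel >= 0.2).all(axis=0)

    events = []
    used: set[int] = set()
    # spread events over samples so every model carries some CNVs
    sample_cycle = rng.permutation(n_samples)
    cycle_pos = 0

    def plant(n: int, ratio: float, side: str) -> None:
        nonlocal cycle_pos
        for _ in range(n):
            si = int(sample_cycle[cycle_pos % n_samples])
            cycle_pos += 1
            c = labels[si]
            med = np.median(affinity[c])
            # moderate-affinity genes only: keeps the per-sample median
            # provably unmoved and the planted spike small relative to
            # the cluster-to-cluster affinity separation
            if side == "amp":
                elig = np.flatnonzero(
                    (affinity[c] > med) & (affinity[c] <= 1.5 * med) & robust
                )
            else:
                elig = np.flatnonzero(
                    (affinity[c] < med) & (affinity[c] >= 0.5 * med) & robust
                )
            elig = np.setdiff1d(elig, np.fromiter(used, dtype=int, count=len(used)))
            gi = int(rng.choice(elig))
            used.add(gi)
            clean[gi, si] *= ratio
            events.append(
                {"gene_id": genes[gi], "sample_id": samples[si], "ratio": ratio}
            )

    plant(n_amp, amp_ratio, "amp")
    plant(n_del, del_ratio, "del")

    def noisy(arr: np.ndarray) -> np.ndarray:
        if noise_sigma > 0:
            return arr * np.exp2(rng.normal(0.0, noise_sigma, size=arr.shape))
        return arr.copy()

    tumor = noisy(clean) * mean_depth
    normal_clean = affinity[labels, :].T * scale[None, :]
    normal = noisy(normal_clean) * mean_depth

    gindex = pd.Index(genes, name="gene_id")
    truth = SyntheticTruth(
        seed=seed,
        planted_cnv=pd.DataFrame(events),
        clusters=pd.Series(labels, index=pd.Index(samples), name="cluster"),
    )
    return (
        DepthMatrix(pd.DataFrame(tumor, index=gindex, columns=samples)),
        DepthMatrix(pd.DataFrame(normal, index=gindex, columns=samples)),
        truth,
    )


def simulate_methylation(
    ann: GeneAnnotation,
    silenced: dict[str, list[str]],
    samples: list[str],
    overexpressed: dict[str, list[str]] | None = None,
    n_cpg_per_gene: int = 5,
    beta_levels: tuple[float, float] = (0.1, 0.9),
    beta_concentration: float = 150.0,
    seed: int = 3,
) -> tuple[BetaMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """β-matrix + CpG manifest + CGI track with planted promoter switches.

    ``silenced`` maps gene → outlier samples whose promoter CpGs are
    methylated (β ≈ 0.9) while the rest of the cohort stays
    unmethylated (β ≈ 0.1); ``overexpressed`` plants the mirror image
    (outliers unmethylated, others methylated).  CpGs are placed every
    100 bp inside each gene's promoter window, and every promoter is
    covered by a CpG island in the generated track, so planted CpGs
    annotate as island-class.
    """
    if not (0 <= beta_levels[0] <= 1 and 0 <= beta_levels[1] <= 1):
        raise ValueError("beta levels must lie in [0, 1]")
    overexpressed = overexpressed or {}
    rng = np.random.default_rng(seed)
    low, high = beta_levels
    c = beta_concentration

    def draw(level: float, size) -> np.ndarray:
        return rng.beta(level * c, (1 - level) * c, size=size)

    manifest_rows = []
    cgi_rows = []
    beta_rows = {}
    sample_index = pd.Index(samples)
    for gene_id, rec in ann.table.iterrows():
        tss = rec["tss_list"][0]
        t0 = tss - 1
        if rec["strand"] == "+":
            positions = [t0 - 100 * (j + 1) for j in range(n_cpg_per_gene)]
            cgi = (t0 - 100 * (n_cpg_per_gene + 2), t0)
        else:
            positions = [t0 + 100 * (j + 1) for j in range(n_cpg_per_gene)]
            cgi = (t0 + 1, t0 + 100 * (n_cpg_per_gene + 2))
        cgi_rows.append({"chrom": rec["chromosome"], "start": cgi[0], "end": cgi[1]})
        for j, p in enumerate(positions):
            cpg = f"cg_{gene_id}_{j}"
            manifest_rows.append({"cpg_id": cpg, "chrom": rec["chromosome"], "pos": p})
            values = draw(low, len(samples))
            if gene_id in silenced:
                idx = sample_index.get_indexer(silenced[gene_id])
                values[idx] = draw(high, len(idx))
            elif gene_id in overexpressed:
                values = draw(high, len(samples))
                idx = sample_index.get_indexer(overexpressed[gene_id])
                values[idx] = draw(low, len(idx))
            beta_rows[cpg] = values

    beta = BetaMatrix(pd.DataFrame.from_dict(beta_rows, orient="index", columns=samples))
    manifest = pd.DataFrame(manifest_rows).set_index("cpg_id")
    cgi = pd.DataFrame(cgi_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    meth_events = [
        {"gene_id": g, "outlier_beta": high, "background_beta": low, "kind": "silenced"}
        for g in silenced
    ] + [
        {"gene_id": g, "outlier_beta": low, "background_beta": high, "kind": "overexpressed"}
        for g in overexpressed
    ]
    truth = SyntheticTruth(seed=seed, planted_meth=pd.DataFrame(meth_events))
    return beta, manifest, cgi, truth


def simulate_fusions(
    positive_outliers: pd.DataFrame,
    gene_symbols: list[str],
    n_surviving: int = 1,
    n_decoys: int = 4,
    seed: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, CnvResult, SyntheticTruth]:
    """Dual-caller fusion tables with one filter-violating decoy class each.

    ``positive_outliers`` carries planted (gene_id or symbol, sample_id)
    overexpression events; each surviving fusion uses such a gene as 3′
    partner in its outlier sample, appears in both callers with
    FFPM > 0.1 and a clean annotation flag.  Decoys cycle through the
    four violation classes: low FFPM, missing from caller B, red-herring
    flag, and 3′-partner amplification (recorded in the returned CNV
    calls).  Returns (caller-A table, caller-B table, CNV result
    covering the fusion genes, truth).
    """
    rng = np.random.default_rng(seed)
    decoy_classes = ["low_ffpm", "single_caller", "red_herring", "amplified_3prime"]
    rows_a, rows_b, truth_rows = [], [], []
    po = positive_outliers.reset_index(drop=True)
    if n_surviving > len(po):
        raise ValueError("not enough planted positive outliers for surviving fusions")
    partners = [g for g in gene_symbols]

    def pick_gene5(exclude: str) -> str:
        g = exclude
        while g == exclude:
            g = partners[int(rng.integers(len(partners)))]
        return g

    chosen = rng.choice(len(po), size=n_surviving, replace=False)
    for i in chosen:
        g3 = po.loc[i, "gene_id"]
        s = po.loc[i, "sample_id"]
        g5 = pick_gene5(g3)
        ffpm = float(rng.uniform(0.3, 2.0))
        rows_a.append({"sample_id": s, "gene5": g5, "gene3": g3, "ffpm": ffpm, "red_herring": False})
        rows_b.append({"sample_id": s, "gene5": g5, "gene3": g3})
        truth_rows.append({"sample_id": s, "gene5": g5, "gene3": g3,
                           "should_survive": True, "decoy_class": "none"})

    amp_cells = []
    used_pairs = {(r["sample_id"], r["gene3"]) for r in rows_a}
    for j in range(n_decoys):
        cls = decoy_classes[j % len(decoy_classes)]
        i = int(rng.integers(len(po)))
        s = po.loc[i, "sample_id"]
        g3 = partners[int(rng.integers(len(partners)))]
        while (s, g3) in used_pairs:
            g3 = partners[int(rng.integers(len(partners)))]
        used_pairs.add((s, g3))
        g5 = pick_gene5(g3)
        ffpm = 0.05 if cls == "low_ffpm" else float(rng.uniform(0.3, 2.0))
        rows_a.append({"sample_id": s, "gene5": g5, "gene3": g3, "ffpm": ffpm,
                       "red_herring": cls == "red_herring"})
        if cls != "single_caller":
            rows_b.append({"sample_id": s, "gene5": g5, "gene3": g3})
        if cls == "amplified_3prime":
            amp_cells.append((g3, s))
        truth_rows.append({"sample_id": s, "gene5": g5, "gene3": g3,
                           "should_survive": False, "decoy_class": cls})

    calls_a = pd.DataFrame(rows_a, columns=["sample_id", "gene5", "gene3", "ffpm", "red_herring"])
    calls_b = pd.DataFrame(rows_b, columns=["sample_id", "gene5", "gene3"])

    fusion_genes = sorted({r["gene3"] for r in rows_a})
    fusion_samples = sorted({r["sample_id"] for r in rows_a})
    log2 = pd.DataFrame(0.0, index=pd.Index(fusion_genes, name="gene_id"), columns=fusion_samples)
    for g, s in amp_cells:
        log2.at[g, s] = 3.0
    calls = pd.DataFrame("neutral", index=log2.index, columns=log2.columns)
    for g, s in amp_cells:
        calls.at[g, s] = "amplified"
    cnv = CnvResult(log2=log2, calls=calls)
    truth = SyntheticTruth(seed=seed, planted_fusions=pd.DataFrame(truth_rows))
    return calls_a, calls_b, cnv, truth


def simulate_sample_annotation(
    samples: list[str],
    cimp_positive: list[str],
    seed: int = 0,
) -> SampleAnnotation:
    """Toy CIMP/MSI labels: the given samples CIMP-H, the rest CIMP3/CIMP4."""
    rng = np.random.default_rng(seed)
    pos = set(cimp_positive)
    cimp = ["CIMP-H" if s in pos else ("CIMP3" if rng.random() < 0.5 else "CIMP4") for s in samples]
    msi = ["MSI" if rng.random() < 0.2 else "MSS" for s in samples]
    return SampleAnnotation(
        pd.DataFrame(
            {"cimp_class": cimp, "msi_status": msi},
            index=pd.Index(samples, name="sample_id"),
        )
    )
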