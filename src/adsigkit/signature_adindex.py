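"""Cross-species signature assembly, the AD-index severity score and its
clinical correlates.

A signed signature is built by intersecting direction-concordant DEGs: genes
dysregulated the same way in both murine models are mapped to their human
orthologs and intersected with genes dysregulated concordantly in the human
discovery cohorts; the human direction supplies the weight (+1 up, -1 down).
The AD index of a sample is the weighted sum of per-gene z-scores,

    AD = sum_i w_i * (e_i - mu_i) / tau_i,

with mu_i and tau_i the mean and sample standard deviation (n-1 denominator)
of gene i across the scored sample set.  Higher index = more severe disease.
Severity validation is the Pearson correlation of the index with the SCORAD
clinical score, and treatment response is a paired t-test on per-subject
index changes between timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .deg import called
from .io_model import (ExpressionMatrix, OrthologMap, RunReport,
                       SignatureTable, ValidationError)


@dataclass
class GenePool:
    """Direction-weighted candidate gene set used for resampling draws."""

    weights: pd.Series  # human symbol -> +1/-1
    pool_id: str = ""

    def __post_init__(self) -> None:
        if self.weights.index.has_duplicates:
            raise ValidationError("gene pool has duplicate genes")
        if not set(np.unique(self.weights)) <= {-1, 1}:
            raise ValidationError("pool weights must be +1 or -1")
        self.weights = self.weights.astype(int)

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def genes(self) -> pd.Index:
        return self.weights.index


@dataclass
class StandardizationStats:
    """Per-gene mean and standard deviation used to z-score expression."""

    mu: pd.Series
    tau: pd.Series
    excluded: list = field(default_factory=list)  # genes with tau == 0


@dataclass
class ADIndexVector:
    """Per-sample AD index plus the standardization used to compute it."""

    index: pd.Series  # sample -> score
    n_genes_used: int
    excluded_genes: list
    stats: StandardizationStats
    samples: pd.DataFrame = None  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# concordant intersections
# ---------------------------------------------------------------------------


def _concordant(tables: list) -> pd.Series:
    """Genes called the same direction in every table; +1/-1 weights."""
    if not tables:
        raise ValidationError("no DEG tables supplied")
    up = set(called(tables[0], "up"))
    down = set(called(tables[0], "down"))
    for t in tables[1:]:
        up &= set(called(t, "up"))
        down &= set(called(t, "down"))
    w = {g: 1 for g in up}
    w.update({g: -1 for g in down})
    return pd.Series(w, dtype=int).sort_index()


def build_gene_pool(human_degs: list, mouse_degs: list | None = None,
                    om: OrthologMap | None = None, pool_id: str = "Human",
                    report: RunReport | None = None) -> GenePool:
    """Direction-concordant DEG intersection across cohorts (and models).

    The pool holds genes called with the same direction in every human
    discovery cohort; when mouse DEG tables are supplied, each gene must
    additionally have an ortholog called with the same direction in every
    mouse table.  Weights are the human direction.
    """
    human_w = _concordant(human_degs)
    sizes = [f"human_concordant={len(human_w)}"]
    if mouse_degs:
        if om is None:
            raise ValidationError("ortholog map required with mouse DEG tables")
        mouse_w = _concordant(mouse_degs)
        mapped = om.to_human(mouse_w.index, report)
        mouse_human = pd.Series(mouse_w.to_numpy()[
            [i for i, g in enumerate(mouse_w.index) if g in mapped.index]],
            index=[mapped[g] for g in mouse_w.index if g in mapped.index])
        sizes.append(f"mouse_concordant_mapped={len(mouse_human)}")
        shared = human_w.index.intersection(mouse_human.index)
        shared = [g for g in shared if human_w[g] == mouse_human[g]]
        human_w = human_w.loc[shared].sort_index()
        sizes.append(f"cross_species_concordant={len(human_w)}")
    if len(human_w) == 0:
        raise ValidationError(
            "empty gene pool; intersection sizes: " + ", ".join(sizes))
    if report is not None:
        report.count(f"pool_{pool_id}_size", len(human_w))
    return GenePool(human_w, pool_id=pool_id)


def build_signature(mouse_degs: list, human_degs: list, om: OrthologMap,
                    report: RunReport | None = None) -> SignatureTable:
    """Signed signature from the cross-species concordant intersection.

    Mouse tables must already be thresholded at the mouse cutoffs and human
    tables at the human cutoffs; genes dysregulated in opposite directions
    in the two mouse models never enter the candidate set.
    """
    pool = build_gene_pool(human_degs, mouse_degs, om,
                           pool_id="signature", report=report)
    sig = SignatureTable(pool.weights)
    if report is not None:
        report.count("signature_size", len(sig))
    return sig


# ---------------------------------------------------------------------------
# AD index
# ---------------------------------------------------------------------------


def ad_index(m: ExpressionMatrix, sig: SignatureTable,
             stats_in: StandardizationStats | None = None,
             report: RunReport | None = None) -> ADIndexVector:
    """Weighted z-score sum over signature genes, per sample.

    mu and tau default to the mean and n-1 standard deviation across the
    scored sample set; pass ``stats_in`` to reuse a standardization fitted
    elsewhere (e.g. to score held-out samples).  Signature genes missing
    from the matrix, or with zero variance, are excluded and reported.
    """
    present = [g for g in sig.genes if g in m.gene_ids]
    missing = [g for g in sig.genes if g not in m.gene_ids]
    if missing and report is not None:
        report.warn(f"ad_index: {len(missing)} signature genes absent from "
                    f"matrix: {missing[:10]}")
    if not present:
        raise ValidationError("no signature genes present in the matrix")
    if len(m.sample_ids) < 2 and stats_in is None:
        raise ValidationError("need >= 2 samples to estimate tau")
    x = m.values.loc[present]
    if stats_in is None:
        mu = x.mean(axis=1)
        tau = x.std(axis=1, ddof=1)
    else:
        mu = stats_in.mu.reindex(present)
        tau = stats_in.tau.reindex(present)
        if mu.isna().any() or tau.isna().any():
            raise ValidationError("standardization stats missing some "
                                  "signature genes")
    zero_tau = list(tau.index[~(tau > 0)])
    usable = [g for g in present if g not in zero_tau]
    if zero_tau and report is not None:
        report.warn(f"ad_index: excluded {len(zero_tau)} zero-variance genes")
    if not usable:
        raise ValidationError("no usable signature genes (all zero variance)")
    z = (x.loc[usable].sub(mu[usable], axis=0)).div(tau[usable], axis=0)
    w = sig.weights[usable]
    idx = z.mul(w, axis=0).sum(axis=0)
    st = StandardizationStats(mu[usable], tau[usable], excluded=zero_tau)
    return ADIndexVector(index=idx, n_genes_used=len(usable),
                         excluded_genes=missing + zero_tau, stats=st,
                         samples=m.samples.copy())


def severity_correlation(idx: ADIndexVector, scorad: pd.Series):
    """Pearson correlation of the AD index with SCORAD.

    Returns (r, two-sided p, n) over samples with both values; requires at
    least 3 complete pairs.
    """
    paired = pd.DataFrame({"index": idx.index,
                           "scorad": pd.to_numeric(
                               scorad.reindex(idx.index.index),
                               errors="coerce")}).dropna()
    if len(paired) < 3:
        raise ValidationError(f"need >= 3 paired values, got {len(paired)}")
    r, p = stats.pearsonr(paired["index"], paired["scorad"])
    return float(r), float(p), int(len(paired))


def paired_timepoint_test(idx: ADIndexVector, t0: str = "baseline",
                          t1: str = "week2", lesional: str = "lesional",
                          report: RunReport | None = None):
    """Paired t-test of per-subject AD-index change t1 - t0 for one tissue.

    Subjects missing either timepoint are excluded and counted; returns
    (mean_change, p, n_pairs).
    """
    ann = idx.samples
    if ann is None:
        raise ValidationError("index vector carries no sample annotations")
    sel = ann[(ann["lesional"] == lesional) &
              (ann["timepoint"].isin([t0, t1]))]
    wide = {}
    for sid, row in sel.iterrows():
        wide.setdefault(row["subject"], {})[row["timepoint"]] = idx.index[sid]
    complete = {s: v for s, v in wide.items()
                if t0 in v and t1 in v and pd.notna(s)}
    n_excluded = len(wide) - len(complete)
    if n_excluded and report is not None:
        report.count(f"paired_{t1}_vs_{t0}_{lesional}_excluded_subjects",
                     n_excluded)
    if len(complete) < 2:
        raise ValidationError(
            f"need >= 2 complete subject pairs, got {len(complete)}")
    diffs = np.array([v[t1] - v[t0] for v in complete.values()])
    if np.std(diffs, ddof=1) == 0:
        # degenerate: all subjects changed by the same amount
        p = 1.0 if np.allclose(diffs, 0) else 0.0
        return float(diffs.mean()), p, int(len(diffs))
    t, p = stats.ttest_1samp(diffs, 0.0)
    return float(diffs.mean()), float(p), int(len(diffs))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_ad_index(idx: ADIndexVector, path) -> None:
    out = pd.DataFrame({"index": idx.index,
                        "n_genes_used": idx.n_genes_used})
    out.sort_index().to_csv(path, sep="\t", float_format="%.6g",
                            index_label="sample")


def write_gene_pool(pool: GenePool, path) -> None:
    pool.weights.sort_index().to_csv(path, sep="\t", header=False)


def read_gene_pool(path, pool_id: str = "") -> GenePool:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["gene", "weight"], dtype={"gene": str})
    return GenePool(pd.Series(df["weight"].to_numpy(),
                              index=df["gene"].to_numpy()), pool_id=pool_id)
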