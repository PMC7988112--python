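"""Rank-weighted single-sample pathway scores and pathway-level contrasts.

Each sample's transcriptome is converted to pathway-level scores by ranking
genes by descending expression (average ranks on ties), weighting each gene
by exp(-decay * rank / N), and taking, for every gene set, the mean weight
of its member genes minus the mean weight of the non-members.  A higher
score means the set sits higher in that sample's expression ranking.  The
weighting is an exponential rank-decay family with a configurable decay
constant; it is deterministic and invariant under monotone transforms of a
sample's expression values.

Pathway dysregulation between two groups is a per-pathway equal-variance
Student t-test on the scores (BH-corrected), and cross-contrast concordance
is the Pearson correlation of the two t-statistic vectors over shared
pathways.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .deg import adjust_bh
from .io_model import (ExpressionMatrix, GeneSetCollection, RunReport,
                       ValidationError)

#: cap applied to the t statistic when a pathway has zero pooled variance
#: but unequal group means (the degenerate column flags these rows).
T_CAP = 1e12


@dataclass
class FAIMEConfig:
    tie_method: str = "average_rank"
    weight_decay: float = 1.0

    def __post_init__(self) -> None:
        if self.tie_method != "average_rank":
            raise ValidationError("only average_rank tie handling is supported")
        if self.weight_decay <= 0:
            raise ValidationError("weight_decay must be positive")


@dataclass
class PathwayScoreMatrix:
    """Pathway x sample score matrix plus provenance."""

    scores: pd.DataFrame
    collection_id: str = ""
    config: FAIMEConfig = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValidationError("pathway scores must be finite")
        if self.config is None:
            self.config = FAIMEConfig()


def faime_scores(m: ExpressionMatrix, gs: GeneSetCollection,
                 cfg: FAIMEConfig | None = None,
                 report: RunReport | None = None) -> PathwayScoreMatrix:
    """Per-sample rank-weighted scores for every gene set with expressed
    members.

    Sets with no member present in the matrix, or covering every gene (empty
    complement), are dropped and reported.
    """
    cfg = cfg or FAIMEConfig()
    n_genes = len(m.gene_ids)
    if n_genes < 2:
        raise ValidationError("need at least 2 genes to rank")
    x = m.values.to_numpy(dtype=float)
    # 1-based descending average ranks, per sample
    ranks = np.apply_along_axis(stats.rankdata, 0, -x)
    weights = np.exp(-cfg.weight_decay * ranks / n_genes)
    gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
    rows, names, dropped = [], [], []
    for name in gs.names():
        members = [gene_pos[g] for g in gs.members(name) if g in gene_pos]
        if not members or len(members) == n_genes:
            dropped.append(name)
            continue
        inside = np.zeros(n_genes, dtype=bool)
        inside[members] = True
        rows.append(weights[inside].mean(axis=0) - weights[~inside].mean(axis=0))
        names.append(name)
    if dropped and report is not None:
        report.count("pathways_dropped", len(dropped))
        report.warn(f"dropped {len(dropped)} pathways with no expressed member "
                    f"or empty complement: {dropped[:5]}...")
    scores = pd.DataFrame(np.array(rows), index=names, columns=m.sample_ids)
    out = PathwayScoreMatrix(scores, collection_id=f"{len(gs)} sets", config=cfg)
    out.samples = m.samples.copy()
    return out


def pathway_contrast(ps: PathwayScoreMatrix, group_a: str,
                     group_b: str) -> pd.DataFrame:
    """Equal-variance t-test per pathway, group_b minus group_a.

    Positive t means the pathway is upregulated in group_b.  Rows with zero
    pooled variance get t = 0 / p = 1 when means are equal, otherwise a
    capped t with p = 0 and ``degenerate = True``.
    """
    samples = getattr(ps, "samples", None)
    if samples is None:
        raise ValidationError("score matrix carries no sample annotations")
    ids_a = list(samples.index[samples["group"] == group_a])
    ids_b = list(samples.index[samples["group"] == group_b])
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValidationError("each group needs at least 2 samples")
    a = ps.scores[ids_a].to_numpy(dtype=float)
    b = ps.scores[ids_b].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)
    df = n_a + n_b - 2
    pooled = ss / df
    se = np.sqrt(pooled * (1 / n_a + 1 / n_b))
    diff = mean_b - mean_a
    t = np.zeros(len(diff))
    p = np.ones(len(diff))
    degenerate = np.zeros(len(diff), dtype=bool)
    ok = se > 0
    t[ok] = diff[ok] / se[ok]
    p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df)
    zero_var_unequal = (~ok) & (diff != 0)
    t[zero_var_unequal] = np.sign(diff[zero_var_unequal]) * T_CAP
    p[zero_var_unequal] = 0.0
    degenerate[zero_var_unequal] = True
    table = pd.DataFrame({
        "t": t, "p": p, "p_corrected": adjust_bh(p),
        "direction": np.sign(t).astype(int), "degenerate": degenerate,
    }, index=ps.scores.index)
    return table


def contrast_correlation(a: pd.DataFrame, b: pd.DataFrame):
    """Pearson correlation of two pathway t-statistic vectors.

    Returns (r, two-sided p, number of shared pathways); requires at least
    3 shared pathways.
    """
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValidationError(
            f"need >= 3 shared pathways, got {len(shared)}")
    r, p = stats.pearsonr(a.loc[shared, "t"], b.loc[shared, "t"])
    return float(r), float(p), int(len(shared))


def contrast_long_format(contrasts: dict) -> pd.DataFrame:
    """Stack named contrast tables into a long (pathway, contrast, t) table,
    the heatmap-ready layer for cross-cohort comparison figures."""
    frames = []
    for label, table in contrasts.items():
        frames.append(pd.DataFrame({
            "pathway": table.index, "contrast": label,
            "t": table["t"].to_numpy()}))
    return pd.concat(frames, ignore_index=True).sort_values(
        ["pathway", "contrast"]).reset_index(drop=True)


def write_pathway_scores(ps: PathwayScoreMatrix, path) -> None:
    ps.scores.sort_index(axis=0).sort_index(axis=1).to_csv(
        path, sep="\t", float_format="%.6g", index_label="pathway")


def write_pathway_contrast(table: pd.DataFrame, path) -> None:
    table.sort_index().to_csv(path, sep="\t", float_format="%.6g",
                              index_label="pathway")
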