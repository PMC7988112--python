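"""Differential-expression statistics for the two data modalities.

Mouse RNA-seq counts go through a TPM expression filter, TMM library
normalization and a two-group negative-binomial exact test with a common
dispersion (the classic count-based exact-test construction: library sizes
are equalized to their geometric mean, counts are converted to pseudo-counts,
and the two-sided p-value sums the conditional probabilities of all splits of
a gene's total that are no more likely than the observed one).

Human microarray log2 intensities go through the SAM permutation statistic
d = (mean difference)/(s + s0) with the fudge constant s0 chosen by the
coefficient-of-variation percentile rule, permutation p-values, and Storey
q-values for FDR control.

DEG tables are plain DataFrames indexed by gene with columns
``log2fc, statistic, p, fdr, call`` (call in {up, down, none}).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import ExpressionMatrix, RunReport, ValidationError

DEG_COLUMNS = ["log2fc", "statistic", "p", "fdr", "call"]

#: prior count added to normalized group means before the log2 ratio,
#: the usual small-count offset that keeps fold-changes finite.
LOG2FC_PRIOR = 0.125

DEFAULT_SEED = 17


@dataclass
class NBConfig:
    """Tuning constants for TMM normalization and the NB exact test.

    trim_m / trim_a are the two-sided trim fractions applied to the log
    ratios (M) and average log expression (A) before the weighted mean;
    dispersion is the common negative-binomial dispersion phi (variance
    mu + phi*mu^2), estimated from the data when left unset.
    """

    trim_m: float = 0.30
    trim_a: float = 0.05
    dispersion: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.trim_m < 0.5 and 0 <= self.trim_a < 0.5):
            raise ValidationError("trim fractions must be in [0, 0.5)")
        if self.dispersion is not None and self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")


@dataclass
class SAMConfig:
    n_perm: int = 1000
    s0: float | str = "auto"
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if self.s0 != "auto" and float(self.s0) < 0:
            raise ValidationError("s0 must be >= 0 or 'auto'")


# ---------------------------------------------------------------------------
# expression filtering
# ---------------------------------------------------------------------------


def filter_by_tpm(counts: ExpressionMatrix, tpm: ExpressionMatrix,
                  min_mean_tpm: float = 1.0,
                  report: RunReport | None = None) -> ExpressionMatrix:
    """Keep genes whose mean TPM across samples strictly exceeds the cutoff."""
    if not counts.gene_ids.equals(tpm.gene_ids) or \
            not counts.sample_ids.equals(tpm.sample_ids):
        raise ValidationError("counts and tpm matrices must share gene and "
                              "sample ids in identical order")
    keep = tpm.values.mean(axis=1) > min_mean_tpm
    out = ExpressionMatrix(counts.values.loc[keep], counts.value_kind,
                           counts.samples.copy())
    if report is not None:
        report.count("genes_before_tpm_filter", len(counts.gene_ids))
        report.count("genes_after_tpm_filter", len(out.gene_ids))
    return out


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, trim_m: float,
              trim_a: float) -> float:
    """Trimmed weighted mean of M-values of one sample against the reference."""
    n_obs, n_ref = obs.sum(), ref.sum()
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok].astype(float), ref[ok].astype(float)
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # inverse asymptotic variance of M as precision weight
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = len(m)
    if n == 0:
        return 1.0
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & \
           (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() == 0 or w[keep].sum() == 0:
        return 1.0
    log2f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(log2f):
        return 1.0
    return float(2.0 ** log2f)


def tmm_factors(counts: ExpressionMatrix, ref_sample: str = "auto",
                cfg: NBConfig | None = None) -> pd.Series:
    """Per-sample TMM normalization factors, scaled to geometric mean 1.

    The reference sample, when ``auto``, is the one whose upper-quartile
    count fraction is closest to the across-sample mean.  Genes with a zero
    count in either the sample or the reference are excluded from the
    trimmed mean.
    """
    cfg = cfg or NBConfig()
    y = counts.values.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if np.any(lib <= 0):
        bad = counts.sample_ids[lib <= 0]
        raise ValidationError(f"all-zero samples: {list(bad)}")
    if ref_sample == "auto":
        uq = np.array([np.quantile(y[:, j] / lib[j], 0.75)
                       for j in range(y.shape[1])])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        if ref_sample not in counts.sample_ids:
            raise ValidationError(f"unknown reference sample {ref_sample!r}")
        ref_idx = int(counts.sample_ids.get_loc(ref_sample))
    factors = np.array([
        1.0 if j == ref_idx else
        _tmm_pair(y[:, j], y[:, ref_idx], cfg.trim_m, cfg.trim_a)
        for j in range(y.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids)


# ---------------------------------------------------------------------------
# NB exact test
# ---------------------------------------------------------------------------


def _round_half_even(x: np.ndarray) -> np.ndarray:
    # numpy's rint implements banker's rounding (ties to even)
    return np.rint(x)


def _estimate_common_dispersion(pseudo: np.ndarray, idx_a: np.ndarray,
                                idx_b: np.ndarray) -> float:
    """Moment-matching common dispersion on library-equalized pseudo-counts.

    Per gene, the within-group residual variance is compared with the mean;
    phi_g = (s2 - mean)/mean^2, and the common value is the mean of the
    per-gene estimates (clipped at zero).  Matching moments on equalized
    counts is the quantile-adjusted analogue of the usual CML fit and keeps
    the estimator closed-form.
    """
    ests = []
    for idx in (idx_a, idx_b):
        sub = pseudo[:, idx]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        ok = m > 0
        ests.append(((s2[ok] - m[ok]) / m[ok] ** 2))
    if not ests:
        return 0.0
    allv = np.concatenate(ests)
    if allv.size == 0:
        return 0.0
    return float(max(0.0, np.mean(allv)))


def _exact_nb_pvalue(y_a: int, total: int, n_a: int, n_b: int,
                     phi: float) -> float:
    """Two-sided conditional exact p for one gene.

    Group sums are NB with means n*mu and dispersions phi/n; conditional on
    the total, the p-value sums P(a | total) over all splits whose
    probability does not exceed the observed one.  phi = 0 reduces to the
    binomial split of a Poisson total.
    """
    if total == 0:
        return 1.0
    a = np.arange(total + 1)
    mu = total / (n_a + n_b)
    if phi <= 0:
        logp = stats.binom.logpmf(a, total, n_a / (n_a + n_b))
    else:
        r_a, r_b = n_a / phi, n_b / phi
        mean_a, mean_b = n_a * mu, n_b * mu
        p_a = r_a / (r_a + mean_a)
        p_b = r_b / (r_b + mean_b)
        logp = (stats.nbinom.logpmf(a, r_a, p_a)
                + stats.nbinom.logpmf(total - a, r_b, p_b))
        logp -= logsumexp_stable(logp)
    obs = logp[y_a]
    # tolerance guards against ties broken by floating-point noise
    p = np.exp(logp[logp <= obs + 1e-10]).sum()
    return float(min(1.0, p))


def logsumexp_stable(logp: np.ndarray) -> float:
    m = np.max(logp)
    return float(m + np.log(np.sum(np.exp(logp - m))))


def nb_exact_test(counts: ExpressionMatrix, group_a: str, group_b: str,
                  cfg: NBConfig | None = None,
                  report: RunReport | None = None) -> pd.DataFrame:
    """Negative-binomial exact test of group_b versus group_a.

    Returns a DEG table (log2fc is b relative to a) with BH-adjusted FDR and
    calls left as ``none`` (use :func:`call_degs` to threshold).
    """
    cfg = cfg or NBConfig()
    samples_a = counts.samples_in_group(group_a)
    samples_b = counts.samples_in_group(group_b)
    if not samples_a or not samples_b:
        raise ValidationError(
            f"both groups must be present; got {group_a!r}: {len(samples_a)} "
            f"samples, {group_b!r}: {len(samples_b)} samples")
    sub = counts.subset_samples(samples_a + samples_b)
    factors = tmm_factors(sub, cfg=cfg)
    y = sub.values.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    eff = lib * factors.to_numpy()
    n_star = np.exp(np.mean(np.log(eff)))
    pseudo = _round_half_even(y * (n_star / eff))
    idx_a = np.arange(len(samples_a))
    idx_b = np.arange(len(samples_a), len(samples_a) + len(samples_b))
    phi = cfg.dispersion
    if phi is None:
        phi = _estimate_common_dispersion(pseudo, idx_a, idx_b)
    n_a, n_b = len(samples_a), len(samples_b)
    sum_a = pseudo[:, idx_a].sum(axis=1).astype(int)
    sum_b = pseudo[:, idx_b].sum(axis=1).astype(int)
    totals = sum_a + sum_b
    pvals = np.array([
        _exact_nb_pvalue(int(sa), int(t), n_a, n_b, phi)
        for sa, t in zip(sum_a, totals)
    ])
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    log2fc = np.log2((mean_b + LOG2FC_PRIOR) / (mean_a + LOG2FC_PRIOR))
    fdr = adjust_bh(pvals)
    stat = np.sign(log2fc) * stats.norm.isf(np.clip(pvals, 1e-300, 1.0) / 2)
    table = pd.DataFrame({
        "log2fc": log2fc, "statistic": stat, "p": pvals, "fdr": fdr,
        "call": "none"}, index=sub.gene_ids)
    if report is not None:
        report.count(f"nb_exact_genes_{group_b}_vs_{group_a}", len(table))
        report.counts[f"nb_dispersion_{group_b}_vs_{group_a}"] = float(phi)
    return table


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def _sam_d_components(x: np.ndarray, mask_b: np.ndarray):
    """Mean difference and pooled standard error for every gene.

    mask_b may be 1-D (one labelling) or 2-D (samples x permutations).
    """
    mask_b = np.atleast_2d(mask_b.T).T.astype(float)  # samples x P
    mask_a = 1.0 - mask_b
    n_b = mask_b.sum(axis=0)
    n_a = mask_a.sum(axis=0)
    sum_b = x @ mask_b
    sum_a = x @ mask_a
    mean_b = sum_b / n_b
    mean_a = sum_a / n_a
    x2 = x ** 2
    ss_b = x2 @ mask_b - n_b * mean_b ** 2
    ss_a = x2 @ mask_a - n_a * mean_a ** 2
    pooled = (ss_a + ss_b) / (n_a + n_b - 2)
    pooled = np.maximum(pooled, 0.0)  # guard fp negatives
    s = np.sqrt((1.0 / n_a + 1.0 / n_b) * pooled)
    return mean_b - mean_a, s


def _choose_s0(diff: np.ndarray, s: np.ndarray) -> float:
    """Percentile rule for the SAM fudge constant.

    Candidate s0 values are the percentiles of s; for each candidate the
    genes are binned into 100 windows of s and the coefficient of variation
    of the within-window median absolute deviations of d is computed; the
    candidate minimizing that CV is chosen.
    """
    s = s.ravel()
    diff = diff.ravel()
    qs = np.percentile(s, np.arange(0, 101, 5))
    # window assignment by s-percentile, shared across candidates
    edges = np.percentile(s, np.arange(0, 101, 1))
    bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, 99)
    best_s0, best_cv = 0.0, np.inf
    for s0 in np.unique(qs):
        d = diff / (s + s0)
        mads = []
        for b in range(100):
            sel = bins == b
            if sel.sum() >= 2:
                db = d[sel]
                mads.append(np.median(np.abs(db - np.median(db))) / 0.64)
        mads = np.array(mads)
        if len(mads) < 2 or np.mean(mads) == 0:
            continue
        cv = np.std(mads, ddof=1) / np.mean(mads)
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _distinct_label_masks(n_a: int, n_b: int) -> np.ndarray:
    """All C(n_a+n_b, n_b) assignments of group-b labels, as a mask matrix."""
    n = n_a + n_b
    combos = list(itertools.combinations(range(n), n_b))
    masks = np.zeros((n, len(combos)))
    for j, combo in enumerate(combos):
        masks[list(combo), j] = 1.0
    return masks


def sam_test(m: ExpressionMatrix, group_a: str, group_b: str,
             cfg: SAMConfig | None = None,
             report: RunReport | None = None) -> pd.DataFrame:
    """SAM permutation test of group_b versus group_a on log2 intensities.

    The observed statistic is d = (mean_b - mean_a)/(s + s0); the null is
    built by permuting group labels — every distinct assignment when their
    number does not exceed ``n_perm`` (giving exact k/B p-values), otherwise
    ``n_perm`` seeded random draws with add-one smoothing.  FDR uses Storey
    q-values.
    """
    cfg = cfg or SAMConfig()
    samples_a = m.samples_in_group(group_a)
    samples_b = m.samples_in_group(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError("each group needs at least 2 samples")
    sub = m.subset_samples(samples_a + samples_b)
    x = sub.values.to_numpy(dtype=float)
    n_a, n_b = len(samples_a), len(samples_b)
    mask_obs = np.zeros(n_a + n_b)
    mask_obs[n_a:] = 1.0
    diff, s = _sam_d_components(x, mask_obs)
    diff, s = diff.ravel(), s.ravel()
    s0 = _choose_s0(diff, s) if cfg.s0 == "auto" else float(cfg.s0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_obs = diff / (s + s0)
    d_obs = np.nan_to_num(d_obs, nan=0.0, posinf=np.inf, neginf=-np.inf)

    n_distinct = math.comb(n_a + n_b, n_b)
    if n_distinct <= cfg.n_perm:
        masks = _distinct_label_masks(n_a, n_b)
        exact = True
    else:
        rng = np.random.default_rng(cfg.seed)
        masks = np.zeros((n_a + n_b, cfg.n_perm))
        for j in range(cfg.n_perm):
            masks[rng.choice(n_a + n_b, n_b, replace=False), j] = 1.0
        exact = False
    diff_p, s_p = _sam_d_components(x, masks)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_perm = diff_p / (s_p + s0)
    d_perm = np.nan_to_num(d_perm, nan=0.0, posinf=np.inf, neginf=-np.inf)
    n_extreme = (np.abs(d_perm) >= np.abs(d_obs)[:, None] - 1e-12).sum(axis=1)
    b = masks.shape[1]
    if exact:
        pvals = n_extreme / b
    else:
        pvals = (1 + n_extreme) / (1 + b)
    pvals = np.clip(pvals, 0.0, 1.0)
    fdr = qvalues(pvals)
    log2fc = diff  # input is log2 scale, so the mean difference is log2FC
    table = pd.DataFrame({
        "log2fc": log2fc, "statistic": d_obs, "p": pvals, "fdr": fdr,
        "call": "none"}, index=sub.gene_ids)
    if report is not None:
        report.count(f"sam_genes_{group_b}_vs_{group_a}", len(table))
        report.counts[f"sam_s0_{group_b}_vs_{group_a}"] = float(s0)
        report.seeds[f"sam_{group_b}_vs_{group_a}"] = cfg.seed
    return table


# ---------------------------------------------------------------------------
# multiple-testing control
# ---------------------------------------------------------------------------


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method="fdr_bh")[1]


def qvalues(p, lambda_grid=None) -> np.ndarray:
    """Storey q-values with pi0 estimated on a lambda grid.

    For fewer than 100 p-values the grid estimate is unstable, so the
    conservative fallback pi0 = min(1, 2*mean(p)) is used instead of the
    smoothed grid estimate.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.96, 0.05)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if m < 100:
        pi0 = min(1.0, 2.0 * float(np.mean(p)))
    else:
        pi0_l = np.array([np.mean(p > lam) / (1 - lam) for lam in lambda_grid])
        # smooth by cubic polynomial in lambda, evaluated at the grid max
        coef = np.polyfit(lambda_grid, pi0_l, 3)
        pi0 = float(np.polyval(coef, lambda_grid.max()))
        pi0 = min(1.0, max(pi0, 1e-8))
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    ranked = p[order] * pi0 * m / (np.arange(m) + 1)
    q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    return np.minimum(q, 1.0)


# ---------------------------------------------------------------------------
# DEG calling
# ---------------------------------------------------------------------------


def call_degs(table: pd.DataFrame, max_fdr: float, min_fc: float) -> pd.DataFrame:
    """Threshold a DEG table: FDR strictly below max_fdr and |FC| strictly
    above min_fc (natural scale; FC > 2 means |log2fc| > 1)."""
    if max_fdr <= 0 or min_fc <= 0:
        raise ValidationError("thresholds must be positive")
    out = table.copy()
    lfc_cut = np.log2(min_fc)
    sig = out["fdr"] < max_fdr
    out["call"] = "none"
    out.loc[sig & (out["log2fc"] > lfc_cut), "call"] = "up"
    out.loc[sig & (out["log2fc"] < -lfc_cut), "call"] = "down"
    return out


def called(table: pd.DataFrame, direction: str | None = None) -> pd.Index:
    """Genes with a non-none call (optionally restricted to one direction)."""
    if direction is None:
        return table.index[table["call"] != "none"]
    return table.index[table["call"] == direction]


# ---------------------------------------------------------------------------
# DEG table I/O
# ---------------------------------------------------------------------------


def read_deg_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    missing = [c for c in DEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"DEG table missing columns: {missing}")
    return df[DEG_COLUMNS]


def write_deg_table(table: pd.DataFrame, path) -> None:
    table[DEG_COLUMNS].sort_index().to_csv(
        path, sep="\t", float_format="%.6g", index_label="gene")
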