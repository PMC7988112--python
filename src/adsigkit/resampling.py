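"""Random-signature benchmarking of severity prediction.

Following the random-signature scheme of Venet et al., B size-matched
signatures are drawn uniformly without replacement from a direction-weighted
gene pool; each resampled signature is scored with the AD index on the same
expression matrix, its Pearson correlation with SCORAD is recorded, and a
candidate signature's observed correlation is placed in that null
distribution with an add-one-smoothed tail p-value,

    p_right = (1 + #{r_b >= r_obs}) / (B + 1).

Pools are compared by an equal-variance t-test on their two correlation
distributions.  Draws use per-signature child seed streams spawned from one
master seed, so increasing B extends the draw list without reshuffling
earlier signatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import ExpressionMatrix, RunReport, SignatureTable, ValidationError
from .signature_adindex import GenePool, ad_index, severity_correlation

TAILS = ("right", "left")


@dataclass
class ResamplingConfig:
    B: int = 1000
    size: int | None = None  # default: candidate signature size
    seed: int = 17
    tail: str = "right"
    exclude: tuple = ()  # genes never drawn (off by default)

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValidationError("B must be >= 1")
        if self.tail not in TAILS:
            raise ValidationError(f"tail must be one of {TAILS}")


@dataclass
class ResamplingResult:
    resampled_r: np.ndarray
    pool_id: str
    config: ResamplingConfig
    observed_r: float | None = None
    empirical_p: float | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# draws
# ---------------------------------------------------------------------------


def _pool_after_exclusion(pool: GenePool, cfg: ResamplingConfig) -> pd.Series:
    w = pool.weights
    if cfg.exclude:
        w = w.drop(index=[g for g in cfg.exclude if g in w.index])
    return w


def _draw_indices(n_pool: int, size: int, B: int, seed: int) -> np.ndarray:
    """B x size index matrix; draw b depends only on (seed, b)."""
    children = np.random.SeedSequence(seed).spawn(B)
    out = np.empty((B, size), dtype=np.int64)
    for b, child in enumerate(children):
        rng = np.random.default_rng(child)
        out[b] = rng.choice(n_pool, size=size, replace=False)
    return out


def draw_random_signatures(pool: GenePool,
                           cfg: ResamplingConfig) -> list:
    """B signatures of ``cfg.size`` genes sampled uniformly without
    replacement from the pool, carrying the pool's direction weights."""
    w = _pool_after_exclusion(pool, cfg)
    size = cfg.size if cfg.size is not None else len(w)
    if not 1 <= size <= len(w):
        raise ValidationError(
            f"signature size {size} must be in [1, pool size {len(w)}]")
    idx = _draw_indices(len(w), size, cfg.B, cfg.seed)
    genes = w.index.to_numpy()
    vals = w.to_numpy()
    return [SignatureTable(pd.Series(vals[row], index=genes[row]))
            for row in idx]


# ---------------------------------------------------------------------------
# resampled correlation distribution
# ---------------------------------------------------------------------------


def _usable_zscores(pool_weights: pd.Series, m: ExpressionMatrix):
    """Per-gene z-score rows for pool genes present with nonzero variance.

    The AD index of any signature drawn from the pool is the weighted sum of
    these rows, so they are computed once and reused across the B draws;
    per-draw results are identical to calling :func:`ad_index` directly.
    """
    # name-sorted so summation order (and hence floating point) is the same
    # whether genes arrive in pool order or signature order
    present = sorted(g for g in pool_weights.index if g in m.gene_ids)
    if not present:
        raise ValidationError("no pool genes present in the matrix")
    x = m.values.loc[present]
    mu = x.mean(axis=1)
    tau = x.std(axis=1, ddof=1)
    usable = tau > 0
    z = x[usable.to_numpy()].sub(mu[usable], axis=0).div(tau[usable], axis=0)
    return z, pool_weights[z.index]


def resampling_distribution(pool: GenePool, m: ExpressionMatrix,
                            scorad: pd.Series,
                            cfg: ResamplingConfig,
                            report: RunReport | None = None) -> ResamplingResult:
    """Correlation-with-SCORAD distribution over B random pool signatures."""
    w = _pool_after_exclusion(pool, cfg)
    size = cfg.size if cfg.size is not None else len(w)
    if not 1 <= size <= len(w):
        raise ValidationError(
            f"signature size {size} must be in [1, pool size {len(w)}]")
    z, w_usable = _usable_zscores(w, m)
    sc = pd.to_numeric(scorad.reindex(m.sample_ids), errors="coerce")
    ok = sc.notna().to_numpy()
    if ok.sum() < 3:
        raise ValidationError("need >= 3 samples with SCORAD")
    idx = _draw_indices(len(w), size, cfg.B, cfg.seed)
    genes = w.index.to_numpy()
    # weighted z rows for drawn genes; draws may include genes dropped as
    # unusable (absent / zero variance), exactly as ad_index would drop them
    usable_pos = {g: i for i, g in enumerate(z.index)}
    zw = z.mul(w_usable, axis=0).to_numpy()[:, ok]
    y = sc.to_numpy()[ok]
    y = y - y.mean()
    y_ss = np.sqrt((y ** 2).sum())
    rs = np.empty(cfg.B)
    for b in range(cfg.B):
        rows = sorted(usable_pos[g] for g in genes[idx[b]]
                      if g in usable_pos)
        if not rows:
            raise ValidationError("a resampled signature has no usable genes")
        score = zw[rows].sum(axis=0)
        score = score - score.mean()
        denom = np.sqrt((score ** 2).sum()) * y_ss
        rs[b] = float(score @ y / denom) if denom > 0 else 0.0
    if report is not None:
        report.count(f"resampling_B_{pool.pool_id}", cfg.B)
        report.seeds[f"resampling_{pool.pool_id}"] = cfg.seed
    return ResamplingResult(resampled_r=rs, pool_id=pool.pool_id, config=cfg)


def _observed_r(sig: SignatureTable, m: ExpressionMatrix,
                scorad: pd.Series) -> tuple:
    """Candidate correlation through the same kernel as the resamples.

    Numerically identical to ad_index + severity_correlation (same z-scores,
    same Pearson formula), so an observed signature equal to a resampled one
    yields exactly the same r.
    """
    z, w = _usable_zscores(sig.weights, m)
    sc = pd.to_numeric(scorad.reindex(m.sample_ids), errors="coerce")
    ok = sc.notna().to_numpy()
    if ok.sum() < 3:
        raise ValidationError("need >= 3 samples with SCORAD")
    score = z.mul(w, axis=0).to_numpy()[:, ok].sum(axis=0)
    y = sc.to_numpy()[ok]
    y = y - y.mean()
    y_ss = np.sqrt((y ** 2).sum())
    score = score - score.mean()
    denom = np.sqrt((score ** 2).sum()) * y_ss
    r = float(score @ y / denom) if denom > 0 else 0.0
    return r, int(ok.sum())


def empirical_p(observed_r: float, resampled_r, tail: str = "right") -> float:
    """Add-one-smoothed tail probability of the observed correlation."""
    rs = np.asarray(resampled_r, dtype=float)
    if rs.size == 0:
        raise ValidationError("resampled correlation list is empty")
    if tail == "right":
        k = int(np.sum(rs >= observed_r))
    elif tail == "left":
        k = int(np.sum(rs <= observed_r))
    else:
        raise ValidationError(f"tail must be one of {TAILS}")
    return (1 + k) / (len(rs) + 1)


def benchmark_signature(candidate: SignatureTable, pool: GenePool,
                        m: ExpressionMatrix, scorad: pd.Series,
                        cfg: ResamplingConfig,
                        report: RunReport | None = None) -> ResamplingResult:
    """Observed candidate correlation versus the pool's random-signature
    distribution, with the configured tail p-value."""
    cfg_eff = ResamplingConfig(B=cfg.B, seed=cfg.seed, tail=cfg.tail,
                               exclude=cfg.exclude,
                               size=cfg.size if cfg.size is not None
                               else len(candidate))
    result = resampling_distribution(pool, m, scorad, cfg_eff, report)
    r, n = _observed_r(candidate, m, scorad)
    result.observed_r = r
    result.empirical_p = empirical_p(r, result.resampled_r, cfg_eff.tail)
    result.extra["n_samples"] = n
    return result


def compare_pools(a: ResamplingResult, b: ResamplingResult):
    """Equal-variance two-sample t-test on two correlation distributions.

    Returns (t, two-sided p, mean difference a - b)."""
    ra, rb = np.asarray(a.resampled_r), np.asarray(b.resampled_r)
    if ra.size < 2 or rb.size < 2:
        raise ValidationError("each distribution needs >= 2 correlations")
    if np.array_equal(ra, rb):
        return 0.0, 1.0, 0.0
    dmean = float(ra.mean() - rb.mean())
    if ra.std(ddof=1) == 0 and rb.std(ddof=1) == 0:
        # both distributions degenerate (e.g. pool size == signature size)
        return (0.0, 1.0, 0.0) if dmean == 0 else \
            (math.copysign(np.inf, dmean), 0.0, dmean)
    t, p = stats.ttest_ind(ra, rb, equal_var=True)
    return float(t), float(p), dmean


def compare_to_reference_signature(candidate: SignatureTable,
                                   reference: SignatureTable,
                                   m: ExpressionMatrix, scorad: pd.Series,
                                   cfg: ResamplingConfig,
                                   report: RunReport | None = None
                                   ) -> ResamplingResult:
    """Benchmark an external reference signature against size-matched random
    subsets of the candidate signature.

    The candidate acts as the sampling pool; the resample size is the
    reference signature's size; the reference's observed correlation is
    evaluated in the resampled distribution with the configured tail.
    """
    if len(reference) > len(candidate):
        raise ValidationError("reference signature larger than candidate")
    pool = GenePool(candidate.weights.copy(), pool_id="candidate_subsets")
    cfg_eff = ResamplingConfig(B=cfg.B, seed=cfg.seed, tail=cfg.tail,
                               exclude=cfg.exclude, size=len(reference))
    result = resampling_distribution(pool, m, scorad, cfg_eff, report)
    r, n = _observed_r(reference, m, scorad)
    result.observed_r = r
    result.empirical_p = empirical_p(r, result.resampled_r, cfg_eff.tail)
    result.extra["n_samples"] = n
    return result


def write_resampling_result(res: ResamplingResult, tsv_path) -> dict:
    """Write the B correlations as TSV and return a JSON-ready summary."""
    pd.DataFrame({"r": res.resampled_r}).to_csv(
        tsv_path, sep="\t", index=False, float_format="%.6g")
    return {
        "pool_id": res.pool_id,
        "observed_r": res.observed_r,
        "empirical_p": res.empirical_p,
        "tail": res.config.tail,
        "B": int(res.config.B),
        "resampled_mean": float(np.mean(res.resampled_r)),
        "resampled_sd": float(np.std(res.resampled_r, ddof=1))
        if len(res.resampled_r) > 1 else 0.0,
    }
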