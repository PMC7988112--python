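"""Synthetic cross-species AD studies with known ground truth.

The generator emulates the study design end to end: two murine models with
their own controls (negative-binomial RNA-seq counts with planted shared,
model-specific and discordant DEGs), two human discovery cohorts
(log-normal microarray intensities with lesional effects concordant across
cohorts), a validation cohort with subjects, lesional/non-lesional biopsies,
three treatment timepoints and a SCORAD score generated as a noisy linear
function of the planted-signature expression, plus a mouse-to-human
ortholog map (a bijection with decoy ambiguous pairs) and a pathway GMT
seeded with the planted genes.

Every planted quantity is recorded in a :class:`GroundTruth` so recovery and
calibration can be checked at each stage, and all outputs are reproducible
from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import (ExpressionMatrix, GeneSetCollection, OrthologMap,
                       SignatureTable, ValidationError,
                       naive_mouse_to_human_symbols)

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class MouseSimConfig:
    """Murine RNA-seq arm: four groups (VT, CHS, NT, SSS), NB counts."""

    samples_per_group: int = 4
    dispersion: float = 0.1
    baseline_range: tuple = (5.0, 500.0)   # log-uniform NB mean
    n_shared_per_direction: int = 30       # DEGs planted in both models
    n_model_specific: int = 50             # per model, split up/down
    n_discordant: int = 10                 # opposite directions in the models
    effect_log2fc: float = 2.0
    library_factor_range: tuple = (0.7, 1.3)
    n_low_expressed: int = 200             # genes below the TPM filter
    low_baseline_range: tuple = (0.02, 0.3)


@dataclass
class HumanSimConfig:
    """Two discovery cohorts of log2 microarray intensities."""

    de_controls: int = 14
    de_lesional: int = 12
    se_controls: int = 10
    se_lesional: int = 10
    noise_sd: float = 0.4
    effect_log2: float = 1.2
    # images of this many planted shared mouse DEGs (per direction) are also
    # dysregulated in the human cohorts; their intersection with the mouse
    # shared set is the true signature
    n_signature_per_direction: int = 15
    n_human_only_per_direction: int = 20
    baseline_range: tuple = (6.0, 12.0)


@dataclass
class ValidationSimConfig:
    """US2-style validation cohort: paired tissues and treatment timepoints."""

    n_subjects: int = 19
    attenuation: dict = field(default_factory=lambda: {
        "baseline": 1.0, "week2": 0.6, "week12": 0.45})
    # severity latent is positive on average so multiplicative treatment
    # attenuation lowers it; SD 1 sets the scale of between-subject spread
    severity_mean: float = 2.0
    rho: float = 0.8                 # designed index-SCORAD correlation
    noise_sd: float = 0.4
    effect_scale: float = 1.0        # log2 units per severity SD
    nonlesional_coupling: float = 0.5
    scorad_mean: float = 40.0
    scorad_sd: float = 12.0
    baseline_range: tuple = (6.0, 12.0)


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    n_pathways: int = 50
    pathway_size_range: tuple = (10, 100)
    n_ambiguous_orthologs: int = 20
    mouse: MouseSimConfig = field(default_factory=MouseSimConfig)
    human: HumanSimConfig = field(default_factory=HumanSimConfig)
    validation: ValidationSimConfig = field(default_factory=ValidationSimConfig)
    seed: int = 17

    def __post_init__(self) -> None:
        m = self.mouse
        needed = (2 * m.n_shared_per_direction + 2 * m.n_model_specific
                  + m.n_discordant
                  + 2 * self.human.n_human_only_per_direction
                  + m.n_low_expressed)
        if needed > self.n_genes:
            raise ValidationError(
                f"planted sets ({needed} genes) exceed n_genes ({self.n_genes})")
        if not 0 < self.validation.rho < 1:
            raise ValidationError("rho must be in (0, 1)")


@dataclass
class GroundTruth:
    """Planted effects, by gene symbol, plus the implied true signature."""

    mouse_shared_up: list
    mouse_shared_down: list
    model_specific: dict          # model -> {"up": [...], "down": [...]}
    discordant: list              # opposite direction in the two models
    human_concordant: pd.Series   # human symbol -> +1/-1
    true_signature: SignatureTable
    designed_rho: float
    low_expressed: list


@dataclass
class StudyBundle:
    """Everything one synthetic study produces."""

    mouse_counts: ExpressionMatrix
    mouse_tpm: ExpressionMatrix
    human_cohorts: dict           # cohort id -> ExpressionMatrix
    validation: ExpressionMatrix
    orthologs: OrthologMap
    gene_sets_human: GeneSetCollection
    gene_sets_mouse: GeneSetCollection
    truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# gene bookkeeping
# ---------------------------------------------------------------------------


def _mouse_symbols(n: int) -> list:
    return [f"Gene{i + 1:04d}" for i in range(n)]


def _layout(cfg: SimulationConfig) -> dict:
    """Deterministic block layout of planted gene roles along the genome."""
    m, h = cfg.mouse, cfg.human
    genes = _mouse_symbols(cfg.n_genes)
    pos = 0

    def take(k):
        nonlocal pos
        block = genes[pos:pos + k]
        pos += k
        return block

    layout = {
        "shared_up": take(m.n_shared_per_direction),
        "shared_down": take(m.n_shared_per_direction),
        "chs_up": take(m.n_model_specific // 2),
        "chs_down": take(m.n_model_specific - m.n_model_specific // 2),
        "sss_up": take(m.n_model_specific // 2),
        "sss_down": take(m.n_model_specific - m.n_model_specific // 2),
        "discordant": take(m.n_discordant),
        "human_only_up": take(h.n_human_only_per_direction),
        "human_only_down": take(h.n_human_only_per_direction),
    }
    layout["low"] = genes[cfg.n_genes - m.n_low_expressed:]
    layout["genes"] = genes
    return layout


def _ground_truth(cfg: SimulationConfig, layout: dict) -> GroundTruth:
    h = cfg.human
    to_human = naive_mouse_to_human_symbols(layout["genes"])
    sig_up = layout["shared_up"][: h.n_signature_per_direction]
    sig_down = layout["shared_down"][: h.n_signature_per_direction]
    concordant = {}
    for g in sig_up + layout["human_only_up"]:
        concordant[to_human[g]] = 1
    for g in sig_down + layout["human_only_down"]:
        concordant[to_human[g]] = -1
    truth_sig = SignatureTable(pd.Series(
        {to_human[g]: 1 for g in sig_up} | {to_human[g]: -1 for g in sig_down}
    ).sort_index())
    return GroundTruth(
        mouse_shared_up=list(layout["shared_up"]),
        mouse_shared_down=list(layout["shared_down"]),
        model_specific={
            "CHS": {"up": layout["chs_up"], "down": layout["chs_down"]},
            "SSS": {"up": layout["sss_up"], "down": layout["sss_down"]},
        },
        discordant=list(layout["discordant"]),
        human_concordant=pd.Series(concordant).sort_index().astype(int),
        true_signature=truth_sig,
        designed_rho=cfg.validation.rho,
        low_expressed=list(layout["low"]),
    )


# ---------------------------------------------------------------------------
# mouse arm
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             phi: float) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_mouse_study(cfg: SimulationConfig, seed: int | None = None):
    """NB counts for VT/CHS/NT/SSS plus TPM (unit gene lengths) and truth."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    layout = _layout(cfg)
    truth = _ground_truth(cfg, layout)
    m = cfg.mouse
    genes = layout["genes"]
    n = cfg.n_genes
    lo, hi = m.baseline_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    low_idx = [genes.index(g) for g in layout["low"]]
    base[low_idx] = np.exp(rng.uniform(*np.log(m.low_baseline_range),
                                       size=len(low_idx)))

    # per-model signed log2 effects
    eff = {"CHS": np.zeros(n), "SSS": np.zeros(n)}
    gi = {g: i for i, g in enumerate(genes)}

    def bump(model, gene_list, sign):
        for g in gene_list:
            eff[model][gi[g]] = sign * m.effect_log2fc

    bump("CHS", layout["shared_up"], +1)
    bump("SSS", layout["shared_up"], +1)
    bump("CHS", layout["shared_down"], -1)
    bump("SSS", layout["shared_down"], -1)
    bump("CHS", layout["chs_up"], +1)
    bump("CHS", layout["chs_down"], -1)
    bump("SSS", layout["sss_up"], +1)
    bump("SSS", layout["sss_down"], -1)
    half = len(layout["discordant"]) // 2
    bump("CHS", layout["discordant"][:half], +1)
    bump("SSS", layout["discordant"][:half], -1)
    bump("CHS", layout["discordant"][half:], -1)
    bump("SSS", layout["discordant"][half:], +1)

    groups = ["VT", "CHS", "NT", "SSS"]
    cols, data, ann_rows = [], [], []
    for grp in groups:
        mult = 2.0 ** eff.get(grp, np.zeros(n))
        for k in range(m.samples_per_group):
            lib = np.exp(rng.uniform(*np.log(m.library_factor_range)))
            mu = base * mult * lib
            data.append(_nb_draw(rng, mu, m.dispersion))
            sid = f"{grp}{k + 1}"
            cols.append(sid)
            ann_rows.append({"sample": sid, "group": grp})
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    ann = pd.DataFrame(ann_rows).set_index("sample")
    counts_m = ExpressionMatrix(counts, "counts", ann)
    tpm_vals = counts / counts.sum(axis=0) * 1e6
    tpm_m = ExpressionMatrix(tpm_vals, "tpm", ann)
    return counts_m, tpm_m, truth


# ---------------------------------------------------------------------------
# human discovery cohorts
# ---------------------------------------------------------------------------


def simulate_human_cohorts(cfg: SimulationConfig, seed: int | None = None):
    """DE-like and SE-like log2-intensity cohorts with concordant planted
    lesional effects; returns ({cohort: matrix}, truth)."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    layout = _layout(cfg)
    truth = _ground_truth(cfg, layout)
    h = cfg.human
    human_genes = sorted(naive_mouse_to_human_symbols(layout["genes"]).values())
    n = len(human_genes)
    delta = truth.human_concordant.reindex(human_genes).fillna(0).to_numpy()
    cohorts = {}
    for cid, n_ctrl, n_les in (("DE", h.de_controls, h.de_lesional),
                               ("SE", h.se_controls, h.se_lesional)):
        base = rng.uniform(*h.baseline_range, size=n)
        cols, data, ann_rows = [], [], []
        for status, count in (("control", n_ctrl), ("lesional", n_les)):
            shift = delta * h.effect_log2 if status == "lesional" else 0.0
            for k in range(count):
                vals = base + shift + rng.normal(0, h.noise_sd, size=n)
                sid = f"{cid}_{status[:3]}{k + 1}"
                cols.append(sid)
                data.append(vals)
                ann_rows.append({"sample": sid, "group": status,
                                 "lesional": status})
        dfm = pd.DataFrame(np.column_stack(data), index=human_genes,
                           columns=cols)
        ann = pd.DataFrame(ann_rows).set_index("sample")
        cohorts[cid] = ExpressionMatrix(dfm, "log_intensity", ann)
    return cohorts, truth


def make_probe_level(m: ExpressionMatrix, probes_per_gene: tuple = (2, 3),
                     jitter_sd: float = 0.1, seed: int = 17):
    """Expand a gene-level log2 matrix to probe level (2-3 probes per gene
    with additive jitter) plus the probe-to-gene map, for exercising the
    probe-collapsing path."""
    from .io_model import ProbeMap
    rng = np.random.default_rng(seed)
    rows, probe_ids, gene_of = [], [], []
    x = m.values.to_numpy()
    for i, g in enumerate(m.gene_ids):
        k = rng.integers(probes_per_gene[0], probes_per_gene[1] + 1)
        for j in range(k):
            rows.append(x[i] + rng.normal(0, jitter_sd, size=x.shape[1]))
            probe_ids.append(f"{g}_p{j + 1}")
            gene_of.append(g)
    probes = pd.DataFrame(np.array(rows), index=probe_ids,
                          columns=m.sample_ids)
    pm = ProbeMap(pd.Series(gene_of, index=probe_ids))
    return ExpressionMatrix(probes, m.value_kind, m.samples.copy()), pm


# ---------------------------------------------------------------------------
# validation cohort
# ---------------------------------------------------------------------------


def simulate_validation_cohort(cfg: SimulationConfig,
                               sig: SignatureTable | None = None,
                               seed: int | None = None) -> ExpressionMatrix:
    """US2-style cohort: per subject, lesional and non-lesional biopsies at
    baseline/week2/week12; SCORAD is a noisy linear function of the planted
    signature's mean z-score, calibrated so the within-tissue correlation is
    the designed rho; treatment attenuates the severity factor at later
    timepoints."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    v = cfg.validation
    layout = _layout(cfg)
    if sig is None:
        sig = _ground_truth(cfg, layout).true_signature
    if len(sig) == 0:
        raise ValidationError("signature is empty")
    human_genes = sorted(naive_mouse_to_human_symbols(layout["genes"]).values())
    n = len(human_genes)
    w = sig.weights.reindex(human_genes).fillna(0).to_numpy()
    base = rng.uniform(*v.baseline_range, size=n)
    severity = rng.normal(v.severity_mean, 1.0, size=v.n_subjects)

    cols, data, ann_rows, sev_of_sample, tissue_of_sample = [], [], [], [], []
    for s in range(v.n_subjects):
        subj = f"S{s + 1:02d}"
        for tp, atten in v.attenuation.items():
            for tissue, coupling in (("lesional", 1.0),
                                     ("nonlesional", v.nonlesional_coupling)):
                sev = severity[s] * atten * coupling
                vals = base + w * v.effect_scale * sev \
                    + rng.normal(0, v.noise_sd, size=n)
                sid = f"{subj}_{tp}_{'L' if tissue == 'lesional' else 'NL'}"
                cols.append(sid)
                data.append(vals)
                sev_of_sample.append(sev)
                tissue_of_sample.append(tissue)
                ann_rows.append({"sample": sid, "group": tissue,
                                 "lesional": tissue, "subject": subj,
                                 "timepoint": tp})
    dfm = pd.DataFrame(np.column_stack(data), index=human_genes, columns=cols)
    ann = pd.DataFrame(ann_rows).set_index("sample")

    # SCORAD from the realized mean signature z-score, noise calibrated
    # per tissue: corr(t + eta, t) = 1/sqrt(1 + var(eta)) = rho
    sig_rows = w != 0
    x_sig = dfm.to_numpy()[sig_rows]
    mu = x_sig.mean(axis=1, keepdims=True)
    tau = x_sig.std(axis=1, ddof=1, keepdims=True)
    z = (x_sig - mu) / tau
    s_score = (w[sig_rows, None] * z).mean(axis=0)
    eta_sd = np.sqrt(1.0 / v.rho ** 2 - 1.0)
    tissue_arr = np.array(tissue_of_sample)
    scorad = np.empty(len(cols))
    for tissue in ("lesional", "nonlesional"):
        sel = tissue_arr == tissue
        t_std = (s_score[sel] - s_score[sel].mean()) / s_score[sel].std(ddof=1)
        noisy = t_std + rng.normal(0, eta_sd, size=sel.sum())
        scorad[sel] = v.scorad_mean + v.scorad_sd * noisy
    ann["scorad"] = np.maximum(scorad, 0.0)
    return ExpressionMatrix(dfm, "log_intensity", ann)


# ---------------------------------------------------------------------------
# fixtures: orthologs and pathways
# ---------------------------------------------------------------------------


def simulate_ortholog_map(cfg: SimulationConfig,
                          seed: int | None = None) -> OrthologMap:
    """Bijective mouse->human map plus decoy one-to-many pairs planted on
    non-DEG genes to exercise the ambiguity-drop path."""
    seed = cfg.seed if seed is None else seed
    layout = _layout(cfg)
    genes = layout["genes"]
    to_human = naive_mouse_to_human_symbols(genes)
    pairs = [(g, to_human[g]) for g in genes]
    planted = set()
    for key in ("shared_up", "shared_down", "chs_up", "chs_down", "sss_up",
                "sss_down", "discordant", "human_only_up", "human_only_down"):
        planted.update(layout[key])
    neutral = [g for g in genes if g not in planted]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    decoys = rng.choice(len(neutral), size=min(cfg.n_ambiguous_orthologs,
                                               len(neutral)), replace=False)
    for d in decoys:
        g = neutral[d]
        pairs.append((g, f"{to_human[g]}ALT"))  # makes g one-to-many
    return OrthologMap(pd.DataFrame(pairs, columns=["mouse", "human"]))


def simulate_gene_sets(cfg: SimulationConfig, seed: int | None = None):
    """Random pathway collection (human and mouse symbol versions).

    The first two sets are seeded with the planted up- and down-regulated
    genes so pathway-level contrasts carry real cross-species signal; the
    rest are uniform draws in the configured size range."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    layout = _layout(cfg)
    genes = layout["genes"]
    lo, hi = cfg.pathway_size_range
    sets_mouse = {}
    seeded = [("PATHWAY_UP_SEEDED", layout["shared_up"] + layout["chs_up"]),
              ("PATHWAY_DOWN_SEEDED", layout["shared_down"] + layout["chs_down"])]
    for name, core in seeded[: min(2, cfg.n_pathways)]:
        extra = rng.choice(len(genes), size=lo, replace=False)
        members = list(dict.fromkeys(list(core) + [genes[i] for i in extra]))
        sets_mouse[name] = ("synthetic seeded pathway", tuple(members))
    for k in range(len(sets_mouse), cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        sets_mouse[f"PATHWAY_{k + 1:03d}"] = (
            "synthetic random pathway",
            tuple(genes[i] for i in sorted(members)))
    gs_mouse = GeneSetCollection(sets_mouse)
    to_human = naive_mouse_to_human_symbols(genes)
    gs_human = gs_mouse.map_symbols(to_human)
    return gs_human, gs_mouse


# ---------------------------------------------------------------------------
# whole study
# ---------------------------------------------------------------------------


def simulate_study(cfg: SimulationConfig | None = None,
                   seed: int | None = None) -> StudyBundle:
    """One complete synthetic study: mouse arm, human discovery cohorts,
    validation cohort scored on the true signature, ortholog map and
    pathway sets, plus the ground truth."""
    cfg = cfg or SimulationConfig()
    seed = cfg.seed if seed is None else seed
    counts, tpm, truth = simulate_mouse_study(cfg, seed)
    cohorts, _ = simulate_human_cohorts(cfg, seed)
    validation = simulate_validation_cohort(cfg, truth.true_signature, seed)
    om = simulate_ortholog_map(cfg, seed)
    gs_human, gs_mouse = simulate_gene_sets(cfg, seed)
    return StudyBundle(mouse_counts=counts, mouse_tpm=tpm,
                       human_cohorts=cohorts, validation=validation,
                       orthologs=om, gene_sets_human=gs_human,
                       gene_sets_mouse=gs_mouse, truth=truth, config=cfg)


def write_study(bundle: StudyBundle, outdir) -> dict:
    """Write every study file in the pipeline's input formats; returns the
    path map."""
    from pathlib import Path

    from .io_model import (write_expression_matrix, write_gene_sets,
                           write_ortholog_map, write_signature)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def emit(name, writer, *args):
        path = outdir / name
        writer(*args, path)
        paths[name] = str(path)

    emit("mouse_counts.tsv", write_expression_matrix, bundle.mouse_counts)
    write_expression_matrix(bundle.mouse_counts, outdir / "mouse_counts.tsv",
                            outdir / "mouse_annotations.tsv")
    paths["mouse_annotations.tsv"] = str(outdir / "mouse_annotations.tsv")
    emit("mouse_tpm.tsv", write_expression_matrix, bundle.mouse_tpm)
    for cid, m in bundle.human_cohorts.items():
        write_expression_matrix(m, outdir / f"human_{cid}.tsv",
                                outdir / f"human_{cid}_annotations.tsv")
        paths[f"human_{cid}.tsv"] = str(outdir / f"human_{cid}.tsv")
        paths[f"human_{cid}_annotations.tsv"] = str(
            outdir / f"human_{cid}_annotations.tsv")
    write_expression_matrix(bundle.validation, outdir / "validation.tsv",
                            outdir / "validation_annotations.tsv")
    paths["validation.tsv"] = str(outdir / "validation.tsv")
    paths["validation_annotations.tsv"] = str(
        outdir / "validation_annotations.tsv")
    emit("orthologs.tsv", write_ortholog_map, bundle.orthologs)
    emit("pathways_human.gmt", write_gene_sets, bundle.gene_sets_human)
    emit("pathways_mouse.gmt", write_gene_sets, bundle.gene_sets_mouse)
    emit("true_signature.tsv", write_signature, bundle.truth.true_signature)
    return paths
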