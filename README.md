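# adsigkit

Cross-species discovery and validation of gene-expression severity
signatures for atopic dermatitis (AD).

Murine AD models only partially recapitulate human disease, so a signature
built from one species alone tends to predict clinical severity poorly.
`adsigkit` implements a pipeline that integrates mouse RNA-seq and human
microarray transcriptomes: genes dysregulated concordantly in two murine
models (hapten-induced contact hypersensitivity, CHS, and brush-induced
skin-scratching stimulation, SSS) are mapped to human orthologs and
intersected with genes dysregulated in human AD lesional skin, yielding a
signed gene signature whose per-sample score tracks the clinical SCORAD
severity index.  The package is aimed at computational biologists building
or benchmarking cross-species disease signatures; every stage is exposed as
a library function, a CLI subcommand, and is testable against a synthetic
study generator with known ground truth.

## The statistics at its core

* **Mouse differential expression** — genes with mean expression > 1 TPM
  enter a two-group negative-binomial exact test with TMM-normalized,
  geometric-mean-equalized library sizes and a common dispersion
  φ (variance μ + φμ²).  DEGs: FDR < 5 % (Benjamini–Hochberg) and fold
  change > 2.
* **Human differential expression** — SAM statistic
  d<sub>i</sub> = (x̄₂ − x̄₁)/(s<sub>i</sub> + s₀) on log2 intensities with
  permutation p-values and Storey q-values; DEGs: FDR < 10 %, FC > 1.5.
* **Pathway scores (FAIME)** — per sample, genes are ranked by descending
  expression and weighted exp(−rank/N); a gene set's score is the mean
  weight of members minus non-members.  Pathway dysregulation is a Student
  t-test on scores, and cross-species concordance is the Pearson
  correlation of the per-pathway t-statistics.
* **AD index** — for a signature with weights w<sub>i</sub> ∈ {+1, −1},

      AD = Σᵢ wᵢ (eᵢ − μᵢ) / τᵢ

  where μᵢ, τᵢ are the mean and SD of gene i across the scored samples.
  A higher index means more severe disease; it is validated by its Pearson
  correlation with SCORAD and by paired t-tests across treatment
  timepoints.
* **Resampling benchmark** (Venet-style) — B random signatures of matched
  size are drawn from a direction-weighted gene pool; the candidate's
  correlation with SCORAD is placed in the resampled distribution with the
  add-one tail probability p = (1 + #{r_b ≥ r_obs})/(B + 1), and pools are
  compared by a t-test on their correlation distributions.

The packaged 36-gene AD signature (27 genes weighted +1, 9 weighted −1) is
available via `adsigkit.load_ad36_signature()`.

## Worked example

A complete synthetic study (two mouse models with 4 replicates per group,
DE-like and SE-like human cohorts of 14/12 and 10/10 control/lesional
samples, and a 19-subject validation cohort with three treatment
timepoints) is generated, analysed end to end, and scored:

```python
import adsigkit as k
from adsigkit.deg import SAMConfig
from adsigkit.resampling import ResamplingConfig
from adsigkit.synthetic_data import SimulationConfig, simulate_study

bundle = simulate_study(SimulationConfig(seed=17))
filtered = k.filter_by_tpm(bundle.mouse_counts, bundle.mouse_tpm, 1.0)
mouse = [k.call_degs(k.nb_exact_test(filtered, c, m), 0.05, 2.0)
         for m, c in (("CHS", "VT"), ("SSS", "NT"))]
human = [k.call_degs(k.sam_test(mm, "control", "lesional", SAMConfig(seed=17)),
                     0.10, 1.5) for mm in bundle.human_cohorts.values()]
sig = k.build_signature(mouse, human, bundle.orthologs)

val = bundle.validation
les = val.subset_samples(list(val.samples.index[val.samples["lesional"] == "lesional"]))
idx = k.ad_index(les, sig)
r, p, n = k.severity_correlation(idx, les.samples["scorad"])

pool = k.build_gene_pool(human, pool_id="Human")
res = k.benchmark_signature(sig, pool, les, les.samples["scorad"],
                            ResamplingConfig(B=1000, seed=17))
```

which prints:

```
signature size: 25
lesional AD index vs SCORAD: r = 0.817, p = 8.69e-15, n = 57
week2 - baseline mean index change: -21.57 (paired p = 4.94e-07, 19 subjects)
resampling vs Human pool: observed r = 0.817, right-tail p = 0.074
```

Reading: 25 of the 30 planted cross-species signature genes survive the
full DEG chain; their AD index explains most of the SCORAD variation in
lesional skin (r = 0.82 over 57 samples); two weeks of simulated treatment
lowers the index sharply; and the signature sits in the right tail of the
1,000 random same-size signatures drawn from the human-only DEG pool.

## Command line

```bash
adsigkit simulate --seed 17 --out study/           # write a synthetic study
adsigkit run --config run.yaml                     # full pipeline
adsigkit deg --mode counts --expr study/mouse_counts.tsv \
    --annotations study/mouse_annotations.tsv \
    --tpm study/mouse_tpm.tsv --groups VT,CHS --out chs.tsv
```

`run.yaml` lists the input paths plus thresholds
(`mouse_fdr: 0.05, mouse_fc: 2, human_fdr: 0.10, human_fc: 1.5` by
default), SAM/NB/FAIME/resampling settings, a master seed and an output
directory; every stage writes sorted, byte-stable TSVs and a
`report.json` with per-stage gene counts, seeds and warnings.  See
`tests/test_cli.py::_run_config` for a complete config.

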