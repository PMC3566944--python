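# stimmod

Stimulus-derived gene modules for aggressive B-cell lymphoma expression
analysis.

## The problem

Aggressive Non-Hodgkin lymphomas arise from germinal-centre B cells and
differ widely in which oncogenic signalling pathways are active. One way to
read pathway activity off a tumour's transcriptome is to stimulate a
transformed germinal-centre B-cell line in vitro (BCR crosslinking with
αIgM, CD40L, IL21, BAFF, LPS), record which genes respond, and then ask how
strongly each patient's tumour expresses that response signature. `stimmod`
implements this analysis end to end for bulk microarray-style data:

1. **Normalization** — per-array robust affine calibration plus a
   generalized-log (glog) transform
   `h(x) = log2((z + √(z² + b²))/2)`, `z = (x − a_j)/s_j`,
   which stabilizes variance under additive + multiplicative intensity
   noise; multi-probeset genes collapse to the probeset with the largest
   absolute fold change.
2. **Paired moderated differential expression** — per gene, replicate-paired
   differences give `log2FC_g` and a sample variance `s²_g`; an
   empirical-Bayes prior (d₀, s₀²), estimated by moment-matching
   `log s²_g` via digamma/trigamma inversion, shrinks the variances:
   `s̃²_g = (d₀ s₀² + d_g s²_g)/(d₀ + d_g)`,
   `t_g = log2FC_g / √(s̃²_g / n)` on `d₀ + d_g` df, with
   Benjamini–Hochberg FDR control.
3. **Module selection** — among genes passing the FDR gate, the TOP-N
   (default 100) by `|log2FC|` form a signed *gene module* per stimulus.
4. **Ordered-list overlap** — two stimuli are compared as ranked lists:
   `O(n) = |top_n(A) ∩ top_n(B)| + |bottom_n(A) ∩ bottom_n(B)|`, with
   analytic null mean `E[O(n)] = 2n²/G`, permutation probability bands, an
   exponentially weighted score `S = Σ e^{−λn} O(n)` and a permutation
   p-value.
5. **Module projection** — a module's genes are extracted from a cohort
   matrix, median-centered, sign-oriented (down-genes flipped), and fitted
   with Tukey's median polish
   `x_gs = overall + gene_g + sample_s + residual_gs`;
   the per-sample column effects are **module activation scores** that
   order the cohort, split it into low/intermediate/high tertiles, and feed
   rank tests against sample labels (molecular diagnosis, ABC/GCB, MYC
   break).

The package ships the five published TOP100 stimulus modules and the
per-stimulus differential-expression count table as plain-text fixtures,
plus simulators that generate paired stimulation experiments and patient
cohorts with known ground truth, so the whole pipeline is testable offline.

## Worked example

```python
from scipy import stats
from stimmod import (load_published_modules, simulate_cohort, CohortSimConfig,
                     ModuleProjector, group_tests, label_association)

modules, counts = load_published_modules()
aigm = modules["aIgM"]          # 99 genes; RGS1 +5.476 ... CYP26A1 -2.752

cfg = CohortSimConfig(n_samples=120, beta_scale=1.0, sigma_resid=0.1, seed=0)
expr, annot, u = simulate_cohort(cfg, aigm)   # u = latent activation truth

proj = ModuleProjector(k=3).fit(expr, module=aigm)
print(stats.spearmanr(proj.scores_[u.index], u).statistic)
print(group_tests(proj.scores_, proj.groups_)["kruskal_p"])
print(label_association(proj.scores_, annot["myc_break"]))
```

prints

```
0.9992                      # activation scores recover the planted gradient
1.07e-23                    # tertiles differ (Kruskal-Wallis, 40/40/40 samples)
{'p': 5.05e-06, 'direction': 'lower', ...}   # MYC-break cases score low
```

i.e. the median-polish score reconstructs the simulated per-sample
activation gradient almost perfectly, the three activation groups separate
sharply, and samples carrying a planted MYC translocation sit at low
module activation — the qualitative behaviour expected of the real cohort
analysis.

The same stages are scriptable from the shell (`stimmod
simulate-experiment | normalize | de | module | overlap | project | run`);
`stimmod run --seed 9 --out-dir out/` writes every intermediate artifact
and a deterministic `summary.json`.

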