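# Methods

This note documents the statistical models implemented in `stimmod`, the
defaults and why, what the simulators emulate, and the package's known
limitations.

## Normalization: affine calibration + glog

Raw probe intensities are modelled with a two-component error:

    y = a_bg + s_j · µ · e^η + ε,   η ~ N(0, σ_mult),  ε ~ N(0, σ_add),

so replicate noise is additive for dim probes and proportional for bright
ones. Arrays are put on a common scale by matching each array's median and
MAD to a reference array (the reference keeps offset 0, scale 1); this
robust affine calibration stands in for a full maximum-likelihood
variance-stabilizing fit, which would estimate the same affine parameters
jointly with the transform. The generalized log

    h(x) = log2((z + √(z² + b²))/2),   z = (x − a_j)/s_j,

is plain log2 for z ≫ b and flattens near zero. The variance-stabilizing
width is b ≈ σ_add/σ_mult; `calibrate_arrays` defaults to a cheap heuristic
(MAD of the reference's lowest intensity decile, floored at 1e-6) that
tracks the additive noise scale but **not** the ratio σ_add/σ_mult, so it
under-stabilizes when multiplicative noise is weak. When the noise
components are known or estimated (as in simulations), pass `width`
explicitly; the stabilization test verifies that at the model-optimal
width the replicate sd of h varies by < 25% between the lowest and highest
intensity quintiles.

Multi-probeset genes collapse to the "best responding" probeset — argmax
of |log2FC| between control and stimulation, ties broken by probeset id.
The absolute value matters: strongly down-regulated genes would be
discarded by a signed maximum. Collapsing happens after probe-level
statistics are computed, because the selection criterion is itself a fold
change.

## Paired moderated t

With n replicate pairs, gene-wise differences d_gi = stim − ctrl give
log2FC_g = mean(d_g), s²_g = var(d_g) on d_g = n − 1 df. The hierarchical
model s²_g | σ²_g ~ σ²_g χ²_{d_g}/d_g, 1/σ²_g ~ χ²_{d₀}/(d₀ s₀²) yields
the posterior s̃²_g = (d₀ s₀² + d_g s²_g)/(d₀ + d_g) and a Student-t null
with d₀ + d_g df for t_g = log2FC_g/√(s̃²_g/n). (d₀, s₀²) are estimated by
moment-matching z_g = log s²_g: Var(z) = ψ′(d_g/2) + ψ′(d₀/2), inverted by
Newton iteration on the trigamma function. When the observed dispersion of
z does not exceed the sampling term ψ′(d_g/2) the prior df is capped at
1e6 (total shrinkage) and s₀² falls back to the plain mean of the sample
variances, which is unbiased in that limit; the log-moment formula is not.
Genes with s²_g = 0 are excluded from hyperparameter estimation but still
shrunk. Multiple testing uses Benjamini–Hochberg step-up (capped,
monotone), delegated to statsmodels and cross-checked in the tests against
a brute-force implementation of the step-up definition.

Two FDR gates coexist in practice: 0.05 for describing per-stimulus DE
counts and 0.1 for building projection modules. Both are exposed
(`fdr_max`); the module default is 0.1. The ranking key inside the FDR
gate is |log2FC| (ties: smaller q, then symbol) — the selection aims at
the largest expression changes, not the smallest p-values.

## Ordered-list overlap

Ranked lists order a common universe of G genes by signed log2FC
descending (ties broken by symbol, for reproducibility). The overlap curve
counts the joint membership of top-n and bottom-n segments; under a
uniformly random relative ordering each segment overlap is hypergeometric
with mean n²/G, giving E[O(n)] = 2n²/G for n ≤ G/2. Probability bands are
empirical 2.5/97.5 percentiles over permutations of one list. The weighted
score S = Σ_{n≤nmax} e^{−λn} O(n) concentrates evidence at the list
extremes; its significance uses an add-one permutation estimator,
p = (1 + #{S_perm ≥ S_obs})/(1 + n_perm), which can never return 0.

Defaults: nmax = 750 (overlap plots of this kind span a few hundred
genes), λ = 0.006 so that e^{−λ·nmax} ≈ 0.01 — depths beyond nmax would
contribute negligibly anyway. Neither value is canonical; both are config
options, and conclusions in the tests are insensitive to them because the
planted-signal separation is large.

## Module projection and stratification

Projection subsets the cohort matrix to the module genes (missing symbols
— a platform reality — are dropped and reported, never imputed; fewer than
10 present genes is an error), centers each gene row at median 0, and
flips rows of down-regulated module genes so all rows increase with
activation. Tukey's median polish then fits the additive two-way model by
alternating row/column median sweeps (tol 1e-6, max 20 sweeps; effects
re-centered into the overall term each sweep). The decomposition
reconstructs the input exactly by construction; the median-based fit is
robust to a minority of aberrant genes or samples. The per-sample column
effect is the activation score: 0 means expression at the cohort-typical
level, positive means the sample expresses the module like stimulated
cells. Down-gene orientation is a deliberate design choice — without it,
up- and down-regulated module halves cancel and the column effect loses
its monotone meaning.

Samples are ordered by ascending score (ties by sample id) and stratified
into rank-based tertiles (remainder samples go to the lowest groups
first); rank-based cuts avoid any claim about absolute score scales.
Group differences use Kruskal–Wallis plus pairwise two-sided rank-sum
tests with BH across the pairs; binary label associations (e.g. MYC
break) use a two-sided rank-sum with the direction reported as the sign
of the median score difference. Note that testing the activation scores
between score-derived tertiles is intentionally circular (it describes
the gradient's spread, not an independent finding); pass any independent
per-sample summary to `group_tests` for a non-circular comparison.

## Simulators

`simulate_stimulation_experiment` emulates the paired design: n_pairs = 3
control/stimulated biological replicates (the design of the in vitro
experiments), 1–3 probesets per gene (weights 0.5/0.3/0.2), baseline log2
abundances uniform on [6, 13], per-array scale factors uniform on
[0.8, 1.25], and the two-component noise above (defaults a_bg = 50,
σ_add = 20, σ_mult = 0.1, plus a per-pair shared biological jitter
σ_bio = 0.1 log2 that cancels in paired differences). Planted effects are
signed log2FC with magnitude uniform on [1, 3]; each probeset of a
multi-probeset gene responds with an attenuation factor uniform on
[0.3, 1], making best-probeset selection non-degenerate, while
single-probeset genes respond fully so that noise-free data recover the
planted effect exactly. The full whole-genome array scale (≈50k probesets)
is not simulated; tests run at 10²–10³ genes, which exercises every code
path at a fraction of the cost.

`simulate_cohort` plants a latent activation u_s ~ U(0,1) per sample:
module gene g has expression baseline_g + beta_scale · log2FC_g · u_s +
N(0, σ_resid) (defaults beta_scale = 1, σ_resid = 0.1, baselines
N(8, 1)), background genes are independent of u. Labels are drawn from
smooth probability curves in u: Burkitt-like diagnoses and MYC breaks
concentrate at low activation (P(mBL) = 0.75(1−u)³ + 0.05,
P(MYC) = 0.45(1−u)⁴ + 0.02), ABC/GCB is independent of u (0.5), mirroring
the observed association structure. What the simulators deliberately omit:
probe sequence effects, cross-hybridization, batch structure, censored or
missing annotations, and any realistic gene–gene correlation beyond the
planted gradient. Passing tests therefore demonstrate correctness of the
procedures and their calibration under the stated model, not performance
on real arrays.

`simulate_shared_signal_lists` builds two ranked lists over G = 10,000
genes from one latent effect vector (standard normal with ±2 planted in
300 + 300 genes) observed twice as 0.8·shared + 0.6·independent noise — a
minimal model of two stimuli with overlapping transcriptional response,
used to benchmark the overlap statistic.

## Numerical choices and degenerate inputs

- Trigamma inversion: Newton iteration, relative tol 1e-10, ≤50 steps.
- t statistics with zero posterior variance: ±∞ (0 if the fold change is
  also 0), p ∈ {0, 1}, flagged `degenerate`.
- Constant arrays (MAD 0) abort calibration; all-zero variance vectors
  abort moderation; empty module selections return a warning object so
  batch pipelines continue.
- All randomness flows through `numpy.random.default_rng` seeds; the
  pipeline expands one global seed into per-stage substreams by hashing
  the stage name (CRC-32 into a `SeedSequence`), so stages are
  reproducible in isolation and summaries are byte-identical across runs.
- Ties: ranked lists break log2FC ties by symbol; module selection breaks
  |log2FC| ties by smaller q then symbol; sample ordering breaks score
  ties by sample id.

## Known limitations

- The glog width heuristic is a stand-in for a likelihood fit; see above.
- The DE model supports exactly the paired two-group contrast — no general
  design matrices, array weights, or trend on the prior variance.
- Whether probeset collapsing should precede or follow model fitting is
  ambiguous in practice; this package computes probe-level statistics
  first and collapses afterwards, and records that as its own choice.
- Platform translation between array generations is by gene symbol only;
  unmatched module genes are dropped.
- The packaged DE-count table reproduces its source verbatim; two of the
  five printed per-stimulus totals (CD40L, BAFF) do not equal the sum of
  their printed up/down counts, an inconsistency internal to the source
  that the fixtures preserve rather than resolve.
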