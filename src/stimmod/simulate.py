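"""Synthetic stimulation experiments and patient cohorts with known truth.

Two generators make every downstream stage testable without external data:

* :func:`simulate_stimulation_experiment` emulates the design of the in
  vitro experiments — paired control/stimulated arrays from three
  independent biological replicates, probe-level intensities with
  multi-probeset genes — under a two-component (additive + multiplicative)
  noise model,

      y = a_bg + scale_j * mu * exp(eta) + eps,
      eta ~ N(0, sigma_mult), eps ~ N(0, sigma_add),

  the model under which the glog transform stabilizes variance. Truly
  affected genes carry a known signed log2 fold change on their stimulated
  columns, attenuated per probeset by a responsiveness factor so that
  "best responding probeset" selection is non-degenerate.

* :func:`simulate_cohort` emulates a lymphoma cohort carrying a latent
  per-sample activation gradient u_s ~ Uniform(0, 1): each module gene g
  contributes ``beta_scale * log2fc_g * u_s`` on top of its baseline, and
  subgroup labels (molecular diagnosis, ABC/GCB, MYC break) are drawn from
  configurable probability curves in u_s — by default Burkitt-like
  diagnoses and MYC breaks concentrate at low activation.

:func:`load_published_modules` returns the five packaged TOP100 stimulus
modules and the differential-expression count table shipped with the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .modules import GeneModule, read_module_tsv
from . import io as _io

__all__ = [
    "NoiseModel",
    "StimSimConfig",
    "ProbeMatrix",
    "simulate_stimulation_experiment",
    "LabelModel",
    "CohortSimConfig",
    "simulate_cohort",
    "load_published_modules",
    "FIXTURE_STIMULI",
]

FIXTURE_STIMULI = ["aIgM", "CD40L", "IL21", "BAFF", "LPS"]
_STIMULUS_ALIASES = {"αIgM": "aIgM", "anti-IgM": "aIgM", "a-IgM": "aIgM"}


@dataclass(frozen=True)
class NoiseModel:
    """Two-component intensity noise.

    ``a_bg`` additive background mean (intensity units); ``sigma_add`` sd of
    the additive component; ``sigma_mult`` sd of the multiplicative
    log-noise; ``sigma_bio`` sd (log2) of per-pair biological baseline
    jitter shared by both arrays of a replicate pair (cancels in paired
    differences).
    """

    a_bg: float = 50.0
    sigma_add: float = 20.0
    sigma_mult: float = 0.1
    sigma_bio: float = 0.1

    def __post_init__(self):
        for name in ("sigma_add", "sigma_mult", "sigma_bio"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"noise.{name} must be >= 0")


@dataclass(frozen=True)
class StimSimConfig:
    """Configuration of a simulated paired stimulation experiment.

    ``probesets_per_gene`` maps probeset count (1-3) to probability.
    ``effect_range`` is the magnitude range of the planted signed log2 fold
    changes (sign up with probability ``p_up``). ``responsiveness_range``
    attenuates each probeset of a multi-probeset gene; single-probeset
    genes respond fully. ``abundance_log2_range`` spans baseline log2
    abundances of expressed transcripts.
    """

    n_genes: int = 2000
    probesets_per_gene: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2}
    )
    n_pairs: int = 3
    n_de: int = 200
    effect_range: tuple[float, float] = (1.0, 3.0)
    p_up: float = 0.5
    noise: NoiseModel = field(default_factory=NoiseModel)
    array_scale_range: tuple[float, float] = (0.8, 1.25)
    abundance_log2_range: tuple[float, float] = (6.0, 13.0)
    responsiveness_range: tuple[float, float] = (0.3, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if not 0 <= self.n_de <= self.n_genes:
            raise ConfigurationError("n_de must satisfy 0 <= n_de <= n_genes")
        if self.n_pairs < 2:
            raise ConfigurationError("n_pairs must be >= 2")
        probs = self.probesets_per_gene
        if set(probs) - {1, 2, 3} or any(v < 0 for v in probs.values()):
            raise ConfigurationError("probesets_per_gene must map {1,2,3} to >=0 weights")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("probesets_per_gene probabilities must sum to 1")
        if not 0 <= self.p_up <= 1:
            raise ConfigurationError("p_up must lie in [0, 1]")
        for name in ("effect_range", "array_scale_range", "abundance_log2_range",
                     "responsiveness_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} must be (low, high) with low <= high")
        if self.array_scale_range[0] <= 0:
            raise ConfigurationError("array_scale_range must be positive")
        if not 0 < self.responsiveness_range[0] <= self.responsiveness_range[1] <= 1:
            raise ConfigurationError("responsiveness_range must lie in (0, 1]")


@dataclass
class ProbeMatrix:
    """Probe-level intensities with the probe->gene map and sample design."""

    values: pd.DataFrame
    probe_map: pd.Series  # probeset id -> gene symbol
    sample_sheet: pd.DataFrame  # sample, condition, pair

    @property
    def pairs(self) -> list[tuple[str, str]]:
        """(stimulated, control) column pairs from the sample sheet."""
        sheet = self.sample_sheet
        out = []
        for pair_id, block in sheet.groupby("pair", sort=True):
            stim = block.loc[block["condition"] == "stimulated", "sample"].item()
            ctrl = block.loc[block["condition"] == "control", "sample"].item()
            out.append((stim, ctrl))
        return out


def simulate_stimulation_experiment(
    cfg: StimSimConfig,
    true_log2fc: pd.Series | None = None,
) -> tuple[ProbeMatrix, pd.DataFrame]:
    """Simulate paired control/stimulated probe intensities with known truth.

    Returns a :class:`ProbeMatrix` and the truth table (gene, true_log2fc,
    is_de). Deterministic given ``cfg.seed``. Passing ``true_log2fc``
    (indexed by gene name ``G00001``...) plants those effects instead of
    drawing them — used to construct stimuli with shared response.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    k_options = np.array(sorted(cfg.probesets_per_gene))
    k_probs = np.array([cfg.probesets_per_gene[k] for k in k_options], dtype=float)
    n_ps = rng.choice(k_options, size=cfg.n_genes, p=k_probs)

    if true_log2fc is None:
        de_idx = rng.choice(cfg.n_genes, size=cfg.n_de, replace=False)
        true_fc = np.zeros(cfg.n_genes)
        lo, hi = cfg.effect_range
        magnitudes = rng.uniform(lo, hi, size=cfg.n_de)
        signs = np.where(rng.random(cfg.n_de) < cfg.p_up, 1.0, -1.0)
        true_fc[de_idx] = signs * magnitudes
        is_de = np.zeros(cfg.n_genes, dtype=bool)
        is_de[de_idx] = True
    else:
        true_fc = true_log2fc.reindex(genes).fillna(0.0).to_numpy(dtype=float)
        is_de = true_fc != 0
    truth = pd.DataFrame(
        {"true_log2fc": true_fc, "is_de": is_de},
        index=pd.Index(genes, name="gene"),
    )

    base_lo, base_hi = cfg.abundance_log2_range
    gene_base = rng.uniform(base_lo, base_hi, size=cfg.n_genes)

    probe_ids: list[str] = []
    probe_gene: list[str] = []
    probe_base: list[float] = []
    probe_fc: list[float] = []
    r_lo, r_hi = cfg.responsiveness_range
    for gi, gene in enumerate(genes):
        for pi in range(n_ps[gi]):
            probe_ids.append(f"{gene}_ps{pi + 1}")
            probe_gene.append(gene)
            # probesets of one gene differ in affinity around the gene baseline
            probe_base.append(gene_base[gi] + (rng.normal(0.0, 0.5) if n_ps[gi] > 1 else 0.0))
            resp = 1.0 if n_ps[gi] == 1 else rng.uniform(r_lo, r_hi)
            probe_fc.append(resp * true_fc[gi])
    n_probes = len(probe_ids)
    probe_base_arr = np.asarray(probe_base)
    probe_fc_arr = np.asarray(probe_fc)

    samples, conditions, pair_ids = [], [], []
    for p in range(1, cfg.n_pairs + 1):
        samples += [f"ctrl_{p}", f"stim_{p}"]
        conditions += ["control", "stimulated"]
        pair_ids += [p, p]
    sheet = pd.DataFrame({"sample": samples, "condition": conditions, "pair": pair_ids})

    noise = cfg.noise
    s_lo, s_hi = cfg.array_scale_range
    scales = rng.uniform(s_lo, s_hi, size=len(samples))
    columns = {}
    for p in range(cfg.n_pairs):
        bio = rng.normal(0.0, noise.sigma_bio, size=n_probes) if noise.sigma_bio > 0 else 0.0
        for cond_offset, cond in enumerate(["ctrl", "stim"]):
            j = 2 * p + cond_offset
            log2_signal = probe_base_arr + bio
            if cond == "stim":
                log2_signal = log2_signal + probe_fc_arr
            mu = np.exp2(log2_signal)
            eta = rng.normal(0.0, noise.sigma_mult, size=n_probes) if noise.sigma_mult > 0 else 0.0
            eps = rng.normal(0.0, noise.sigma_add, size=n_probes) if noise.sigma_add > 0 else 0.0
            columns[f"{cond}_{p + 1}"] = noise.a_bg + scales[j] * mu * np.exp(eta) + eps
    values = pd.DataFrame(columns, index=pd.Index(probe_ids, name="probeset"))[samples]
    probe_map = pd.Series(probe_gene, index=values.index, name="symbol")
    return ProbeMatrix(values=values, probe_map=probe_map, sample_sheet=sheet), truth


def _default_p_mbl(u: np.ndarray) -> np.ndarray:
    return 0.75 * (1.0 - u) ** 3 + 0.05


def _default_p_non_mbl(u: np.ndarray) -> np.ndarray:
    return 0.75 * u**3 + 0.05


def _default_p_abc(u: np.ndarray) -> np.ndarray:
    # ABC/GCB shows no direct association with module activation
    return np.full_like(np.asarray(u, dtype=float), 0.5)


def _default_p_myc(u: np.ndarray) -> np.ndarray:
    # MYC-translocated cases concentrate at low module activation
    return 0.45 * (1.0 - u) ** 4 + 0.02


@dataclass(frozen=True)
class LabelModel:
    """Label probabilities as functions of the activation gradient u in [0,1].

    ``p_mbl`` and ``p_non_mbl`` must sum to <= 1 pointwise; the remainder is
    the intermediate diagnosis. ``p_abc`` is P(ABC) vs GCB and ``p_myc`` is
    P(MYC break).
    """

    p_mbl: Callable[[np.ndarray], np.ndarray] = _default_p_mbl
    p_non_mbl: Callable[[np.ndarray], np.ndarray] = _default_p_non_mbl
    p_abc: Callable[[np.ndarray], np.ndarray] = _default_p_abc
    p_myc: Callable[[np.ndarray], np.ndarray] = _default_p_myc

    def validate(self) -> None:
        u = np.linspace(0.0, 1.0, 101)
        for name in ("p_mbl", "p_non_mbl", "p_abc", "p_myc"):
            p = np.asarray(getattr(self, name)(u), dtype=float)
            if (p < 0).any() or (p > 1).any():
                raise ConfigurationError(f"label_model.{name} leaves [0, 1]")
        total = np.asarray(self.p_mbl(u)) + np.asarray(self.p_non_mbl(u))
        if (total > 1 + 1e-9).any():
            raise ConfigurationError("label_model: p_mbl + p_non_mbl exceeds 1")


@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration of a simulated patient cohort.

    ``beta_scale`` links each module gene's log2fc to the latent activation
    u_s (expression slope in log2 units per unit u); ``sigma_resid`` is the
    residual sd; ``n_background_genes`` independent genes pad the matrix.
    """

    n_samples: int = 120
    beta_scale: float = 1.0
    sigma_resid: float = 0.1
    n_background_genes: int = 500
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    label_model: LabelModel = field(default_factory=LabelModel)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 9:
            raise ConfigurationError("n_samples must be >= 9")
        if self.sigma_resid < 0:
            raise ConfigurationError("sigma_resid must be >= 0")
        if self.n_background_genes < 0:
            raise ConfigurationError("n_background_genes must be >= 0")
        self.label_model.validate()


def simulate_cohort(
    cfg: CohortSimConfig, module: GeneModule
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate a gene-level cohort carrying a planted activation gradient.

    Returns ``(expression, annotations, u)``: a gene x sample table holding
    the module genes plus background genes, per-sample labels drawn from
    the label model, and the latent truth u_s. Deterministic given
    ``cfg.seed``.
    """
    if len(module) == 0:
        raise ConfigurationError("module must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    u = pd.Series(rng.uniform(0.0, 1.0, size=cfg.n_samples), index=samples, name="u")

    mod_fc = module.log2fc
    baselines = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(mod_fc))
    signal = baselines[:, None] + cfg.beta_scale * np.outer(mod_fc.to_numpy(), u.to_numpy())
    signal = signal + rng.normal(0.0, cfg.sigma_resid, size=signal.shape)
    rows = [pd.DataFrame(signal, index=mod_fc.index, columns=samples)]

    if cfg.n_background_genes:
        bg_names = [f"BG{i + 1:05d}" for i in range(cfg.n_background_genes)]
        bg_base = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_background_genes)
        bg = bg_base[:, None] + rng.normal(
            0.0, max(cfg.sigma_resid, 0.3), size=(cfg.n_background_genes, cfg.n_samples)
        )
        rows.append(pd.DataFrame(bg, index=pd.Index(bg_names), columns=samples))
    expr = pd.concat(rows)
    expr.index.name = "symbol"

    lm = cfg.label_model
    uu = u.to_numpy()
    p_mbl = np.asarray(lm.p_mbl(uu), dtype=float)
    p_non = np.asarray(lm.p_non_mbl(uu), dtype=float)
    draw = rng.random(cfg.n_samples)
    diagnosis = np.where(
        draw < p_mbl, "mBL", np.where(draw < p_mbl + p_non, "non-mBL", "intermediate")
    )
    abc = np.where(rng.random(cfg.n_samples) < np.asarray(lm.p_abc(uu)), "ABC", "GCB")
    myc = (rng.random(cfg.n_samples) < np.asarray(lm.p_myc(uu))).astype(int)
    annot = pd.DataFrame(
        {
            "sample": samples,
            "molecular_diagnosis": diagnosis,
            "abc_gcb": abc,
            "myc_break": myc,
        }
    ).set_index("sample")
    return expr, annot, u


def simulate_shared_signal_lists(
    n_genes: int = 10_000,
    n_up: int = 300,
    n_down: int = 300,
    effect: float = 2.0,
    shared_weight: float = 0.8,
    noise_weight: float = 0.6,
    seed: int = 42,
) -> tuple[list[str], list[str]]:
    """Two ranked gene lists sharing differential signal at both extremes.

    A latent effect vector (standard normal, plus +-``effect`` planted in
    ``n_up`` up- and ``n_down`` down-genes) is observed twice with
    independent noise: effect_i = shared_weight * shared + noise_weight *
    N(0, 1). Both observations are ranked by effect descending. Emulates
    two stimuli driving an overlapping transcriptional response.
    """
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal(n_genes)
    shared[:n_up] += effect
    shared[n_up : n_up + n_down] -= effect
    genes = np.array([f"g{i + 1:05d}" for i in range(n_genes)])
    lists = []
    for _ in range(2):
        eff = shared_weight * shared + noise_weight * rng.standard_normal(n_genes)
        lists.append(list(genes[np.argsort(-eff, kind="stable")]))
    return lists[0], lists[1]


def load_published_modules() -> tuple[dict[str, GeneModule], pd.DataFrame]:
    """Packaged TOP100 stimulus modules and the DE-count table.

    Returns ``(modules, counts)``: modules keyed aIgM / CD40L / IL21 /
    BAFF / LPS (Greek-alpha spellings accepted as aliases) and a DataFrame
    of up/down/total differentially expressed gene counts per stimulus, as
    printed.
    """
    data = resources.files("stimmod") / "data"
    with resources.as_file(data / "modules.tsv") as path:
        modules = read_module_tsv(path, n_max=100, fdr_max=0.1)
    for alias, target in _STIMULUS_ALIASES.items():
        if target in modules:
            modules[alias] = modules[target]
    with resources.as_file(data / "de_counts.json") as path:
        counts_raw = _io.read_json(path)
    counts = pd.DataFrame.from_dict(counts_raw, orient="index").loc[FIXTURE_STIMULI]
    counts.index.name = "stimulus"
    return modules, counts[["up", "down", "total"]]
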