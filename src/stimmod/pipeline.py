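"""End-to-end orchestration of the synthetic analysis.

One call wires the stages together: simulate paired stimulation
experiments for two stimuli with partially shared truth, variance-
stabilize, run paired moderated DE at probe level, collapse probesets,
select TOP-N modules, compare the two responses by the ordered-list
statistic, project the first module onto a simulated cohort, stratify and
test. A single global seed is expanded into per-stage substreams (hashed
by stage name) so each stage is independently reproducible; the JSON
summary is byte-deterministic given config + seed.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _sps

from . import io as _io
from .diffexpr import run_paired_moderated_de, select_top_module
from .exceptions import ConfigurationError, StimmodError
from .modules import write_module_tsv, write_modules_gmt
from .ordered_list import compare_ranked_lists, ranked_list
from .preprocess import calibrate_arrays, collapse_probesets, glog_transform
from .projection import ModuleProjector, group_tests, label_association
from .simulate import CohortSimConfig, StimSimConfig, simulate_stimulation_experiment, simulate_cohort

__all__ = ["PipelineConfig", "stage_seed", "run_pipeline"]

logger = logging.getLogger("stimmod")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode("utf-8"))])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class PipelineConfig:
    """Tunable parameters of the end-to-end synthetic run."""

    seed: int = 0
    # stimulation experiments
    n_genes: int = 2000
    n_de: int = 200
    n_pairs: int = 3
    shared_fraction: float = 0.5  # fraction of stimulus A's DE genes shared by B
    # module selection
    n_max: int = 100
    fdr_max: float = 0.1
    # ordered-list comparison
    lam: float = 0.006
    overlap_nmax: int | None = None
    n_perm: int = 1000
    # cohort projection
    n_samples: int = 120
    beta_scale: float = 1.0
    sigma_resid: float = 0.1
    k_groups: int = 3
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0 <= self.shared_fraction <= 1:
            raise ConfigurationError("shared_fraction must lie in [0, 1]")
        if not 0 < self.fdr_max <= 1:
            raise ConfigurationError("fdr_max must lie in (0, 1]")
        if self.n_perm < 100:
            raise ConfigurationError("n_perm must be >= 100")
        if self.k_groups < 2:
            raise ConfigurationError("k_groups must be >= 2")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _run_de(probe_matrix, n_max, fdr_max, stimulus):
    """normalize -> probe DE -> collapse -> gene DE -> module, for one experiment."""
    params = calibrate_arrays(probe_matrix.values)
    transformed = glog_transform(probe_matrix.values, params)
    pairs = probe_matrix.pairs
    probe_de, _ = run_paired_moderated_de(transformed, pairs)
    probe_stats = pd.DataFrame(
        {"symbol": probe_matrix.probe_map, "log2fc": probe_de["log2fc"]}
    )
    gene_table, report = collapse_probesets(transformed, probe_stats)
    gene_de, prior = run_paired_moderated_de(gene_table, pairs)
    module = select_top_module(gene_de, stimulus, n_max=n_max, fdr_max=fdr_max)
    return transformed, gene_de, report, module, prior


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic analysis; returns (and optionally writes) the summary.

    When ``out_dir`` is given, all intermediate artifacts (expression TSVs,
    DE tables, module GMT/TSV, overlap curves, projection scores) plus
    ``summary.json`` are written there.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    base = StimSimConfig(
        n_genes=config.n_genes,
        n_de=config.n_de,
        n_pairs=config.n_pairs,
        seed=stage_seed(config.seed, "simulate-A"),
    )
    logger.info("simulating stimulus A (%d genes, %d DE)", base.n_genes, base.n_de)
    pm_a, truth_a = simulate_stimulation_experiment(base)

    # stimulus B shares a fraction of A's affected genes, same sign
    rng_b = np.random.default_rng(stage_seed(config.seed, "simulate-B-truth"))
    de_a = truth_a.index[truth_a["is_de"]]
    n_shared = int(round(config.shared_fraction * len(de_a)))
    shared = rng_b.choice(de_a, size=n_shared, replace=False)
    null_genes = truth_a.index[~truth_a["is_de"]]
    fresh = rng_b.choice(null_genes, size=len(de_a) - n_shared, replace=False)
    fc_b = pd.Series(0.0, index=truth_a.index)
    fc_b[shared] = truth_a.loc[shared, "true_log2fc"]
    lo, hi = base.effect_range
    fc_b[fresh] = rng_b.uniform(lo, hi, size=len(fresh)) * np.where(
        rng_b.random(len(fresh)) < base.p_up, 1.0, -1.0
    )
    cfg_b = dataclasses.replace(base, seed=stage_seed(config.seed, "simulate-B"))
    pm_b, truth_b = simulate_stimulation_experiment(cfg_b, true_log2fc=fc_b)

    logger.info("normalizing and testing")
    _, de_a_tbl, report_a, module_a, prior_a = _run_de(
        pm_a, config.n_max, config.fdr_max, "stimA"
    )
    _, de_b_tbl, _, module_b, _ = _run_de(pm_b, config.n_max, config.fdr_max, "stimB")

    logger.info("ordered-list comparison")
    ol = compare_ranked_lists(
        ranked_list(de_a_tbl),
        ranked_list(de_b_tbl),
        lam=config.lam,
        nmax=config.overlap_nmax,
        n_perm=config.n_perm,
        seed=stage_seed(config.seed, "overlap"),
        labels=("stimA", "stimB"),
    )

    logger.info("cohort projection")
    cohort_cfg = CohortSimConfig(
        n_samples=config.n_samples,
        beta_scale=config.beta_scale,
        sigma_resid=config.sigma_resid,
        seed=stage_seed(config.seed, "cohort"),
    )
    expr, annot, u = simulate_cohort(cohort_cfg, module_a)
    projector = ModuleProjector(k=config.k_groups).fit(expr, module=module_a)
    rho = float(_sps.spearmanr(projector.scores_[u.index], u).statistic)
    gtests = group_tests(projector.scores_, projector.groups_)
    myc = label_association(projector.scores_, annot["myc_break"])

    recall_a = _recall(de_a_tbl, truth_a, config.fdr_max)
    summary = {
        "config": config.to_dict(),
        "stimA": {
            "n_de_true": int(truth_a["is_de"].sum()),
            "n_called": int((de_a_tbl["q"] <= config.fdr_max).sum()),
            "recall": recall_a,
            "module_size": len(module_a),
            "prior_d0": prior_a.d0,
            "prior_s0_sq": prior_a.s0_sq,
        },
        "stimB": {
            "n_de_true": int(truth_b["is_de"].sum()),
            "n_called": int((de_b_tbl["q"] <= config.fdr_max).sum()),
            "module_size": len(module_b),
        },
        "overlap": ol.summary(),
        "projection": {
            "spearman_u": rho,
            "kruskal_p": gtests["kruskal_p"],
            "pairwise": gtests["pairwise"],
            "myc_p": myc["p"],
            "myc_direction": myc["direction"],
            "dropped_genes": len(projector.dropped_genes_),
            "group_sizes": projector.groups_.value_counts().sort_index().to_dict(),
        },
    }

    if out is not None:
        _io.write_expression_tsv(pm_a.values, out / "stimA_probes.tsv")
        _io.write_expression_tsv(pm_b.values, out / "stimB_probes.tsv")
        de_a_tbl.to_csv(out / "stimA_de.tsv", sep="\t")
        de_b_tbl.to_csv(out / "stimB_de.tsv", sep="\t")
        report_a.to_csv(out / "stimA_collapse_report.tsv", sep="\t")
        write_module_tsv([module_a, module_b], out / "modules.tsv")
        write_modules_gmt([module_a, module_b], out / "modules.gmt")
        ol.to_frame().to_csv(out / "overlap_curves.tsv", sep="\t", index=False)
        _io.write_expression_tsv(expr, out / "cohort_expression.tsv")
        annot.to_csv(out / "cohort_annotations.tsv", sep="\t")
        scores = projector.scores_.to_frame()
        scores["group"] = projector.groups_
        scores["u_true"] = u
        scores.to_csv(out / "projection_scores.tsv", sep="\t")
        _io.write_json(summary, out / "summary.json")
    return summary


def _recall(de_table: pd.DataFrame, truth: pd.DataFrame, fdr_max: float) -> float:
    called = set(de_table.index[de_table["q"] <= fdr_max])
    true_de = set(truth.index[truth["is_de"]])
    if not true_de:
        return float("nan")
    return len(called & true_de) / len(true_de)
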