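"""Projecting a signed gene module onto a cohort.

The module's genes are extracted from the cohort matrix, each gene row is
median-centered, and rows of down-regulated module genes (negative module
log2fc) are sign-flipped so that every row increases with pathway
activation. Tukey's median polish then fits the additive model

    x_gs = overall + gene_g + sample_s + residual_gs

by alternating row- and column-median sweeps; the per-sample column
effects are the module activation scores. Because medians (not means) are
swept, a handful of aberrant genes cannot drag a sample's score. Samples
are ordered by ascending score, split into rank-based tertiles (low /
intermediate / high activation) and the groups compared by rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .diffexpr import bh_adjust
from .exceptions import ProjectionError, StimmodError
from .modules import GeneModule

__all__ = [
    "PolishFit",
    "median_polish",
    "orient_module_matrix",
    "score_samples",
    "stratify",
    "group_tests",
    "label_association",
    "ModuleProjection",
    "ModuleProjector",
]


@dataclass
class PolishFit:
    """Additive fit: input == overall + row + column + residual, exactly."""

    overall: float
    row_effects: pd.Series
    col_effects: pd.Series
    residuals: pd.DataFrame
    n_iter: int
    converged: bool

    def reconstruct(self) -> pd.DataFrame:
        return (
            self.residuals.add(self.row_effects, axis=0)
            .add(self.col_effects, axis=1)
            + self.overall
        )


def median_polish(
    matrix: pd.DataFrame, tol: float = 1e-6, max_iter: int = 20
) -> PolishFit:
    """Tukey's median polish of a two-way table.

    Alternates row-median and column-median sweeps, accumulating effects,
    until the largest single adjustment in a full sweep drops below ``tol``
    or ``max_iter`` sweeps have run. After each sweep the medians of the
    row and column effects are absorbed into the overall term, so effects
    are centered (median 0). The decomposition reconstructs the input
    exactly by construction.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ProjectionError(f"need a >=2 x >=2 matrix, got {matrix.shape}")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ProjectionError("matrix contains non-finite entries")
    resid = values.copy()
    overall = 0.0
    row = np.zeros(matrix.shape[0])
    col = np.zeros(matrix.shape[1])
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        delta = 0.0
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row += rmed
        delta = max(delta, np.abs(rmed).max())
        cmed_of_col = np.median(col)
        overall += cmed_of_col
        col -= cmed_of_col
        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col += cmed
        delta = max(delta, np.abs(cmed).max())
        rmed_of_row = np.median(row)
        overall += rmed_of_row
        row -= rmed_of_row
        if delta < tol:
            converged = True
            break
    return PolishFit(
        overall=float(overall),
        row_effects=pd.Series(row, index=matrix.index, name="row_effect"),
        col_effects=pd.Series(col, index=matrix.columns, name="col_effect"),
        residuals=pd.DataFrame(resid, index=matrix.index, columns=matrix.columns),
        n_iter=n_iter,
        converged=converged,
    )


def orient_module_matrix(
    cohort: pd.DataFrame, module: GeneModule, min_genes: int = 10
) -> tuple[pd.DataFrame, list[str]]:
    """Extract, center and sign-orient the module submatrix of a cohort.

    Genes absent from the cohort (platform differences) are dropped and
    reported, never imputed. Each present gene row is centered to median 0
    across samples; rows of genes the module lists with negative log2fc are
    negated, so every oriented row increases with module activation.

    Raises
    ------
    ProjectionError
        If fewer than ``min_genes`` module genes are present.
    """
    if len(module) == 0:
        raise ProjectionError(f"module {module.stimulus!r} is empty")
    present = [s for s in module.symbols if s in cohort.index]
    dropped = [s for s in module.symbols if s not in cohort.index]
    if len(present) < min_genes:
        raise ProjectionError(
            f"only {len(present)} of {len(module)} module genes present in cohort "
            f"(need >= {min_genes})"
        )
    sub = cohort.loc[present].astype(float)
    centered = sub.sub(sub.median(axis=1), axis=0)
    signs = pd.Series(
        [1.0 if fc >= 0 else -1.0 for _, fc in module.entries], index=module.symbols
    )
    oriented = centered.mul(signs.loc[present], axis=0)
    return oriented, dropped


@dataclass
class ModuleProjection:
    """Per-sample activation scores and stratification for one module."""

    scores: pd.Series
    order: list[str]
    groups: pd.Series
    dropped_genes: list[str]
    fit: PolishFit

    def heatmap_matrix(self, cohort: pd.DataFrame, module: GeneModule) -> pd.DataFrame:
        """Centered module submatrix with genes by module log2fc and samples by score."""
        present = [s for s in module.symbols if s in cohort.index]
        sub = cohort.loc[present, self.order].astype(float)
        return sub.sub(sub.median(axis=1), axis=0)


def score_samples(
    oriented: pd.DataFrame, tol: float = 1e-6, max_iter: int = 20, k: int = 3
) -> ModuleProjection:
    """Activation scores = column effects of the median polish fit.

    Samples are ordered by ascending score (ties broken by sample id) and
    stratified into ``k`` rank-based groups.
    """
    fit = median_polish(oriented, tol=tol, max_iter=max_iter)
    scores = fit.col_effects.rename("activation_score")
    order = sorted(scores.index, key=lambda s: (scores[s], str(s)))
    groups = stratify(scores, k=k)
    return ModuleProjection(
        scores=scores, order=order, groups=groups, dropped_genes=[], fit=fit
    )


_TERTILE_NAMES = ["low", "intermediate", "high"]


def stratify(scores: pd.Series, k: int = 3) -> pd.Series:
    """Rank-based equal-size groups of ascending activation.

    With n = qk + r samples the lowest r groups get the extra sample each,
    so cut points depend only on ranks, never on score magnitudes. For
    k = 3 the labels are low / intermediate / high; otherwise g1..gk.
    """
    if k < 2:
        raise StimmodError(f"k must be >= 2, got {k}")
    n = len(scores)
    if n < k:
        raise StimmodError(f"need >= {k} samples to form {k} groups, got {n}")
    names = _TERTILE_NAMES if k == 3 else [f"g{i + 1}" for i in range(k)]
    order = sorted(scores.index, key=lambda s: (scores[s], str(s)))
    base, rem = divmod(n, k)
    labels = {}
    start = 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        for s in order[start : start + size]:
            labels[s] = names[i]
        start += size
    return pd.Series(labels, name="group").reindex(scores.index)


def group_tests(values: pd.Series, groups: pd.Series) -> dict:
    """Omnibus Kruskal-Wallis plus BH-adjusted pairwise rank-sum tests.

    ``values`` is any per-sample statistic (activation scores or an
    independent expression summary); ``groups`` assigns each sample a
    label. Each group needs >= 2 samples.
    """
    groups = groups.reindex(values.index)
    by_group = {g: values[groups == g].to_numpy(float) for g in groups.dropna().unique()}
    if len(by_group) < 2:
        raise StimmodError(f"need >= 2 groups, got {len(by_group)}")
    small = [g for g, v in by_group.items() if v.size < 2]
    if small:
        raise StimmodError(f"groups with < 2 samples: {small}")
    names = sorted(by_group, key=str)
    kw_stat, kw_p = stats.kruskal(*[by_group[g] for g in names])
    pair_names = []
    pair_p = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            u = stats.mannwhitneyu(
                by_group[names[i]], by_group[names[j]], alternative="two-sided"
            )
            pair_names.append((names[i], names[j]))
            pair_p.append(float(u.pvalue))
    adj = bh_adjust(np.asarray(pair_p)) if pair_p else np.array([])
    return {
        "kruskal_stat": float(kw_stat),
        "kruskal_p": float(kw_p),
        "pairwise": [
            {"groups": list(pair), "p": p, "q": float(q)}
            for pair, p, q in zip(pair_names, pair_p, adj)
        ],
    }


def label_association(scores: pd.Series, labels: pd.Series) -> dict:
    """Two-sided rank-sum association between scores and a binary label.

    Returns the p-value and the direction of the labeled (truthy) group
    relative to the rest: ``"lower"`` / ``"higher"`` / ``"equal"`` by sign
    of the median score difference. Samples with missing labels are
    dropped.
    """
    labels = labels.reindex(scores.index)
    mask = labels.notna()
    scores, labels = scores[mask], labels[mask].astype(bool)
    pos = scores[labels].to_numpy(float)
    neg = scores[~labels].to_numpy(float)
    if pos.size == 0 or neg.size == 0:
        raise StimmodError("both label values must be present")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided")
    diff = float(np.median(pos) - np.median(neg))
    direction = "equal" if diff == 0 else ("lower" if diff < 0 else "higher")
    return {"p": float(u.pvalue), "direction": direction, "median_diff": diff}


class ModuleProjector(BaseEstimator):
    """Gene-module activation scoring with a scikit-learn interface.

    ``fit(cohort, module=...)`` orients the module submatrix, fits the
    median polish and stratifies the samples; fitted attributes expose the
    projection. ``transform`` of new samples is intentionally absent: the
    polish is a joint fit, and scores for new samples require refitting.

    Parameters
    ----------
    k : int, default 3
        Number of rank-based activation groups.
    min_genes : int, default 10
        Minimum module genes that must be present in the cohort.
    tol, max_iter
        Median polish convergence controls.

    Attributes
    ----------
    scores_ : Series           per-sample activation score (column effect)
    order_ : list[str]         sample ids by ascending score
    groups_ : Series           low/intermediate/high (k = 3) labels
    dropped_genes_ : list[str] module symbols absent from the cohort
    fit_ : PolishFit           full additive decomposition
    """

    def __init__(
        self,
        k: int = 3,
        min_genes: int = 10,
        tol: float = 1e-6,
        max_iter: int = 20,
    ):
        self.k = k
        self.min_genes = min_genes
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, y=None, *, module: GeneModule):
        oriented, dropped = orient_module_matrix(X, module, min_genes=self.min_genes)
        proj = score_samples(oriented, tol=self.tol, max_iter=self.max_iter, k=self.k)
        self.module_ = module
        self.scores_ = proj.scores
        self.order_ = proj.order
        self.groups_ = proj.groups
        self.dropped_genes_ = dropped
        self.fit_ = proj.fit
        return self

    def projection_(self) -> ModuleProjection:
        if not hasattr(self, "fit_"):
            raise StimmodError("ModuleProjector is not fitted")
        return ModuleProjection(
            scores=self.scores_,
            order=self.order_,
            groups=self.groups_,
            dropped_genes=self.dropped_genes_,
            fit=self.fit_,
        )
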