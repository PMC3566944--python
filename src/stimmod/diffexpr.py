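"""Paired moderated differential expression and module selection.

Per gene g, replicate-paired differences d_gi = stim_gi - ctrl_gi give the
fold change (their mean, in log2 units) and a sample variance s2_g on
dg = n_pairs - 1 degrees of freedom. With only a handful of replicate
pairs, per-gene variances are noisy; an empirical-Bayes hierarchical model
shrinks them toward a pooled prior. Assuming

    s2_g | sigma2_g ~ sigma2_g * chi2_dg / dg,
    1 / sigma2_g    ~ chi2_d0 / (d0 * s0^2),

the posterior variance is the precision-weighted blend

    s2_tilde_g = (d0 * s0^2 + dg * s2_g) / (d0 + dg)

and t_g = log2fc_g / sqrt(s2_tilde_g / n_pairs) follows a Student t with
d0 + dg degrees of freedom under the null. The hyperparameters (d0, s0^2)
are estimated by moment-matching the log sample variances: the mean and
variance of log s2_g have closed forms in digamma/trigamma functions, and
inverting the trigamma equation yields d0.

p-values are converted to q-values by the Benjamini-Hochberg step-up.
The TOP-N module for a stimulus keeps, among genes passing the FDR gate,
the N with the largest absolute fold change, reported sorted by signed
fold change ascending.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .exceptions import DesignError, ModerationError, StimmodError
from .modules import GeneModule

__all__ = [
    "paired_differences",
    "ModerationParams",
    "moderate_variances",
    "moderated_t_test",
    "bh_adjust",
    "select_top_module",
    "delta_delta_ct",
    "PairedModeratedT",
]

#: prior degrees of freedom used when the trigamma equation has no positive
#: root (log-variance dispersion at or below the sampling floor); at this
#: value shrinkage is total and s2_tilde == s0^2 to ~1e-6 relative.
D0_CAP = 1e6


def paired_differences(
    table: pd.DataFrame, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Per-gene paired statistics from a gene x sample table.

    ``pairs`` lists ``(stimulated_column, control_column)`` tuples, one per
    biological replicate. Returns a DataFrame indexed by gene with columns
    ``log2fc`` (mean difference), ``s2`` (unbiased variance of differences)
    and ``dg`` (= n_pairs - 1).
    """
    if len(pairs) < 2:
        raise DesignError(f"need >=2 replicate pairs, got {len(pairs)}")
    flat = [c for pair in pairs for c in pair]
    missing = [c for c in flat if c not in table.columns]
    if missing:
        raise DesignError(f"columns not in table: {missing}")
    if len(set(flat)) != len(flat):
        raise DesignError("a sample column appears in more than one pair")
    diffs = np.column_stack(
        [table[stim].to_numpy(float) - table[ctrl].to_numpy(float) for stim, ctrl in pairs]
    )
    return pd.DataFrame(
        {
            "log2fc": diffs.mean(axis=1),
            "s2": diffs.var(axis=1, ddof=1),
            "dg": len(pairs) - 1,
        },
        index=table.index,
    )


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes prior: degrees of freedom d0 and variance s0^2."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 > 0 and self.s0_sq > 0):
            raise ModerationError(f"invalid prior (d0={self.d0}, s0_sq={self.s0_sq})")


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ModerationError(f"trigamma inverse undefined for y={y}")
    # large y -> small x: trigamma(x) ~ 1/x^2 + 1/x ; small y: trigamma(x) ~ 1/x
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def moderate_variances(
    s2: np.ndarray | pd.Series, dg: int
) -> tuple[ModerationParams, np.ndarray]:
    """Estimate the variance prior and return posterior variances.

    Moment-matching on z_g = log(s2_g): under the hierarchical model,
    Var(z) = trigamma(dg/2) + trigamma(d0/2) and E(z) determines s0^2 once
    d0 is known. If the observed dispersion of z does not exceed the
    sampling term trigamma(dg/2), d0 is capped at ``D0_CAP`` (effectively
    infinite prior df). Genes with s2 == 0 are excluded from estimation but
    still shrunk in the returned posterior vector.
    """
    s2 = np.asarray(s2, dtype=float)
    if dg < 1:
        raise ModerationError(f"dg must be >= 1, got {dg}")
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ModerationError("all sample variances are zero; nothing to moderate")
    if positive.size < 10:
        raise ModerationError(
            f"need >=10 genes with positive variance, got {positive.size}"
        )
    z = np.log(positive)
    # center the sampling distribution of log s2 given sigma2
    e = z - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    resid = evar - float(special.polygamma(1, dg / 2.0))
    capped = resid <= 0
    if not capped:
        try:
            d0 = min(2.0 * _trigamma_inverse(resid), D0_CAP)
        except ModerationError:
            capped = True
    if capped:
        warnings.warn(
            "log-variance dispersion at or below the sampling floor; "
            f"capping prior df at {D0_CAP:g}",
            stacklevel=2,
        )
        d0 = D0_CAP
        # infinite-prior limit: total shrinkage, prior = plain mean variance
        s0_sq = float(positive.mean())
    else:
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    params = ModerationParams(d0=d0, s0_sq=s0_sq)
    posterior = (d0 * s0_sq + dg * s2) / (d0 + dg)
    return params, posterior


def moderated_t_test(
    log2fc: np.ndarray | pd.Series,
    s2_tilde: np.ndarray,
    n_pairs: int,
    df_total: float,
) -> pd.DataFrame:
    """Moderated t statistics and two-sided p-values.

    ``t = log2fc / sqrt(s2_tilde / n_pairs)`` on ``df_total = d0 + dg``
    degrees of freedom. Genes with zero posterior variance get t = +-inf
    (0 where the fold change is also 0), p = 0, and are flagged in the
    ``degenerate`` column.
    """
    index = log2fc.index if isinstance(log2fc, pd.Series) else None
    fc = np.asarray(log2fc, dtype=float)
    s2_tilde = np.asarray(s2_tilde, dtype=float)
    se = np.sqrt(s2_tilde / n_pairs)
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, np.sign(fc) * np.inf, fc / np.where(degenerate, 1, se))
    t = np.where(degenerate & (fc == 0), 0.0, t)
    p = np.where(
        degenerate,
        np.where(fc == 0, 1.0, 0.0),
        2.0 * stats.t.sf(np.abs(np.where(degenerate, 0.0, t)), df=df_total),
    )
    return pd.DataFrame(
        {"t_mod": t, "df_total": df_total, "p": p, "degenerate": degenerate},
        index=index,
    )


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return p if isinstance(p, pd.Series) else arr
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise StimmodError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    if isinstance(p, pd.Series):
        return pd.Series(q, index=p.index, name="q")
    return q


def run_paired_moderated_de(
    table: pd.DataFrame, pairs: Sequence[tuple[str, str]]
) -> tuple[pd.DataFrame, ModerationParams]:
    """Full paired moderated DE: differences -> moderation -> t -> BH.

    Returns the DE table (gene, log2fc, s2, t_mod, df_total, p, q) and the
    fitted moderation prior.
    """
    base = paired_differences(table, pairs)
    dg = int(base["dg"].iloc[0])
    params, s2_tilde = moderate_variances(base["s2"], dg)
    tt = moderated_t_test(base["log2fc"], s2_tilde, len(pairs), params.d0 + dg)
    result = base.join(tt)
    result["q"] = bh_adjust(result["p"])
    return result, params


def select_top_module(
    de_table: pd.DataFrame,
    stimulus: str,
    n_max: int = 100,
    fdr_max: float = 0.1,
) -> GeneModule:
    """TOP-N module: FDR gate, then largest |log2fc|.

    Genes with q <= ``fdr_max`` are ranked by absolute fold change
    (descending; ties by smaller q, then symbol) and the first ``n_max``
    kept. The module lists them by signed log2fc ascending. An empty
    selection returns an empty module carrying a warning rather than
    raising.
    """
    if "q" not in de_table.columns:
        raise StimmodError("DE table has no q column; run bh_adjust first")
    passed = de_table[de_table["q"] <= fdr_max].copy()
    if passed.empty:
        msg = f"no genes pass FDR <= {fdr_max} for {stimulus!r}"
        warnings.warn(msg, stacklevel=2)
        return GeneModule(stimulus=stimulus, entries=(), n_max=n_max, fdr_max=fdr_max, warning=msg)
    passed["absfc"] = passed["log2fc"].abs()
    passed["symbol"] = list(passed.index.astype(str))
    passed = passed.reset_index(drop=True)
    top = passed.sort_values(
        ["absfc", "q", "symbol"], ascending=[False, True, True]
    ).head(n_max)
    top = top.sort_values(["log2fc", "symbol"])
    return GeneModule(
        stimulus=stimulus,
        entries=tuple(zip(top["symbol"], top["log2fc"].astype(float))),
        n_max=n_max,
        fdr_max=fdr_max,
    )


def delta_delta_ct(
    ct_target_stim: float,
    ct_hk_stim: float,
    ct_target_ctrl: float | None,
    ct_hk_ctrl: float,
    not_expressed_delta: float = 10.0,
) -> dict:
    """qRT-PCR relative quantification against a housekeeper.

    ddCt = (Ct_target,stim - Ct_hk,stim) - (Ct_target,ctrl - Ct_hk,ctrl);
    the fold change is 2^(-ddCt). When the target is undetectable in the
    unstimulated control (``ct_target_ctrl`` is None, or the basal
    dCt = Ct_target,ctrl - Ct_hk,ctrl exceeds ``not_expressed_delta``
    cycles), no ratio to baseline is meaningful and the stimulated dCt is
    returned instead (``mode == "delta_ct"``).
    """
    for name, val in [("ct_hk_stim", ct_hk_stim), ("ct_hk_ctrl", ct_hk_ctrl)]:
        if val is None or not np.isfinite(val):
            raise StimmodError(f"missing housekeeper Ct: {name}")
    if ct_target_stim is None or not np.isfinite(ct_target_stim):
        raise StimmodError("missing stimulated target Ct")
    dct_stim = ct_target_stim - ct_hk_stim
    basal_undetectable = ct_target_ctrl is None or not np.isfinite(ct_target_ctrl)
    if not basal_undetectable:
        dct_ctrl = ct_target_ctrl - ct_hk_ctrl
        basal_undetectable = dct_ctrl > not_expressed_delta
    if basal_undetectable:
        return {"mode": "delta_ct", "delta_ct": dct_stim, "fold": None}
    ddct = dct_stim - dct_ctrl
    return {"mode": "ddct", "delta_delta_ct": ddct, "fold": float(2.0 ** (-ddct))}


class PairedModeratedT(BaseEstimator):
    """Paired moderated differential expression as an estimator.

    ``fit(X, pairs=...)`` consumes a gene x sample DataFrame and the
    replicate pairing and exposes the full DE table plus the fitted
    empirical-Bayes prior as attributes.

    Parameters
    ----------
    n_max, fdr_max
        Module selection size and FDR gate used by :meth:`top_module`.

    Attributes
    ----------
    results_ : DataFrame
        gene, log2fc, s2, dg, t_mod, df_total, p, q.
    prior_ : ModerationParams
        Estimated (d0, s0^2).
    """

    def __init__(self, n_max: int = 100, fdr_max: float = 0.1):
        self.n_max = n_max
        self.fdr_max = fdr_max

    def fit(self, X: pd.DataFrame, y=None, *, pairs: Sequence[tuple[str, str]]):
        self.results_, self.prior_ = run_paired_moderated_de(X, pairs)
        return self

    def top_module(self, stimulus: str) -> GeneModule:
        if not hasattr(self, "results_"):
            raise StimmodError("PairedModeratedT is not fitted")
        return select_top_module(
            self.results_, stimulus, n_max=self.n_max, fdr_max=self.fdr_max
        )
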