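"""Ranked-gene-list overlap statistics.

Two stimulus responses are compared as ranked lists over a common gene
universe: rank 1 is the strongest up-regulation, rank G the strongest
down-regulation. For each depth n the overlap

    O(n) = |top_n(A) & top_n(B)| + |bottom_n(A) & bottom_n(B)|

counts genes responding in the same direction at both list extremes; the
"reversed" orientation reverses list B first and so counts anti-correlated
response. Under a random-order null, each segment overlap is
hypergeometric with mean n^2/G, so E[O(n)] = 2 n^2 / G; probability bands
come from random permutations of one list. Depths are aggregated into an
exponentially weighted score

    S = sum_{n=1..nmax} exp(-lambda * n) * O(n)

whose significance is assessed by the permutation distribution of S with
an add-one estimator, p = (1 + #{S_perm >= S_obs}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import StimmodError

__all__ = [
    "ranked_list",
    "overlap_curve",
    "expected_overlap",
    "expected_and_band",
    "weighted_score",
    "overlap_pvalue",
    "compare_ranked_lists",
    "OrderedListResult",
    "DEFAULT_LAMBDA",
    "DEFAULT_NMAX",
]

#: default depth limit; printed overlap plots extend to a few hundred genes.
DEFAULT_NMAX = 750
#: default weight decay, chosen so exp(-lambda * DEFAULT_NMAX) ~ 0.01.
DEFAULT_LAMBDA = 0.006


def ranked_list(de_table: pd.DataFrame) -> list[str]:
    """Rank genes by signed log2fc descending; ties break by symbol.

    Rank 1 is the strongest up-regulated gene. Accepts any DataFrame with a
    ``log2fc`` column indexed by gene symbol.
    """
    tbl = pd.DataFrame(
        {"symbol": list(de_table.index.astype(str)), "log2fc": de_table["log2fc"].to_numpy()}
    )
    tbl = tbl.sort_values(["log2fc", "symbol"], ascending=[False, True])
    return list(tbl["symbol"])


def _check_universe(a: list[str], b: list[str]) -> int:
    sa, sb = set(a), set(b)
    if len(sa) != len(a) or len(sb) != len(b):
        raise StimmodError("ranked lists must not contain duplicates")
    if sa != sb:
        raise StimmodError(
            f"gene universes differ (symmetric difference of {len(sa ^ sb)} symbols)"
        )
    return len(a)


def _rank_arrays(a: list[str], b: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """1-based rank of every gene in A and B, in a fixed gene order."""
    pos_b = {g: i + 1 for i, g in enumerate(b)}
    rank_a = np.arange(1, len(a) + 1)
    rank_b = np.array([pos_b[g] for g in a])
    return rank_a, rank_b


def _curve_from_ranks(rank_a: np.ndarray, rank_b: np.ndarray, nmax: int) -> np.ndarray:
    """O(n) for n=1..nmax given 1-based rank vectors over G genes."""
    G = rank_a.size
    top = np.maximum(rank_a, rank_b)
    bottom = np.maximum(G + 1 - rank_a, G + 1 - rank_b)
    curve = np.zeros(nmax, dtype=np.int64)
    np.add.at(curve, top[top <= nmax] - 1, 1)
    np.add.at(curve, bottom[bottom <= nmax] - 1, 1)
    return np.cumsum(curve)


def overlap_curve(
    a: list[str], b: list[str], orientation: str = "same", nmax: int | None = None
) -> np.ndarray:
    """Integer overlap curve O(n), n = 1..nmax.

    ``orientation="reversed"`` reverses B before comparing, measuring
    anti-correlated ranking. ``nmax`` defaults to G // 2 (beyond which top
    and bottom segments of one list overlap each other).
    """
    G = _check_universe(a, b)
    if orientation not in ("same", "reversed"):
        raise StimmodError(f"orientation must be 'same' or 'reversed', got {orientation!r}")
    if orientation == "reversed":
        b = list(reversed(b))
    if nmax is None:
        nmax = G // 2
    if not (1 <= nmax <= G // 2):
        raise StimmodError(f"nmax must lie in [1, G//2] = [1, {G // 2}], got {nmax}")
    rank_a, rank_b = _rank_arrays(a, b)
    return _curve_from_ranks(rank_a, rank_b, nmax)


def expected_overlap(G: int, nmax: int) -> np.ndarray:
    """Analytic null mean E[O(n)] = 2 n^2 / G (two hypergeometric segments)."""
    n = np.arange(1, nmax + 1, dtype=float)
    return 2.0 * n * n / G


def _null_curves(
    G: int, nmax: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """O(n) curves for n_perm random orderings of one list (shape n_perm x nmax)."""
    rank_a = np.arange(1, G + 1)
    curves = np.empty((n_perm, nmax), dtype=np.int64)
    for k in range(n_perm):
        rank_b = rng.permutation(G) + 1
        curves[k] = _curve_from_ranks(rank_a, rank_b, nmax)
    return curves


def expected_and_band(
    G: int, nmax: int, n_perm: int = 1000, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Null expectation and 95% probability band of the overlap curve.

    Returns ``(E, band_low, band_high)`` where E is analytic and the band
    holds the empirical 2.5/97.5 percentiles over ``n_perm`` permutations.
    """
    if n_perm < 100:
        raise StimmodError(f"n_perm must be >= 100, got {n_perm}")
    if not (1 <= nmax <= G // 2):
        raise StimmodError(f"nmax must lie in [1, G//2] = [1, {G // 2}], got {nmax}")
    rng = np.random.default_rng(seed)
    curves = _null_curves(G, nmax, n_perm, rng)
    low, high = np.percentile(curves, [2.5, 97.5], axis=0)
    return expected_overlap(G, nmax), low, high


def weighted_score(
    curve: np.ndarray, lam: float = DEFAULT_LAMBDA, nmax: int | None = None
) -> float:
    """Exponentially weighted overlap score S = sum exp(-lam n) O(n)."""
    if lam <= 0:
        raise StimmodError(f"lambda must be > 0, got {lam}")
    curve = np.asarray(curve, dtype=float)
    if nmax is not None:
        curve = curve[:nmax]
    n = np.arange(1, curve.size + 1, dtype=float)
    return float(np.sum(np.exp(-lam * n) * curve))


def overlap_pvalue(
    a: list[str],
    b: list[str],
    lam: float = DEFAULT_LAMBDA,
    nmax: int | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, np.ndarray]:
    """Permutation p-value of the weighted overlap score.

    B's order is permuted ``n_perm`` times; p uses the add-one estimator so
    it is never 0. Returns ``(p, S_obs, S_perm)``.
    """
    if n_perm < 100:
        raise StimmodError(f"n_perm must be >= 100, got {n_perm}")
    G = _check_universe(a, b)
    if nmax is None:
        nmax = min(DEFAULT_NMAX, G // 2)
    obs = overlap_curve(a, b, "same", nmax)
    s_obs = weighted_score(obs, lam)
    rng = np.random.default_rng(seed)
    curves = _null_curves(G, nmax, n_perm, rng)
    weights = np.exp(-lam * np.arange(1, nmax + 1))
    s_perm = curves @ weights
    p = (1.0 + np.count_nonzero(s_perm >= s_obs)) / (1.0 + n_perm)
    return float(p), s_obs, s_perm


@dataclass
class OrderedListResult:
    """Full comparison of two ranked lists (curves, null, score, p)."""

    nmax: int
    lam: float
    o_same: np.ndarray
    o_reversed: np.ndarray
    expected: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    score: float
    p_perm: float
    n_perm: int
    seed: int | None = None
    labels: tuple[str, str] = field(default=("A", "B"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": np.arange(1, self.nmax + 1),
                "overlap_same": self.o_same,
                "overlap_reversed": self.o_reversed,
                "expected": self.expected,
                "band_low": self.band_low,
                "band_high": self.band_high,
            }
        )

    def summary(self) -> dict:
        return {
            "labels": list(self.labels),
            "nmax": self.nmax,
            "lambda": self.lam,
            "score": self.score,
            "p_perm": self.p_perm,
            "n_perm": self.n_perm,
            "max_overlap_same": int(self.o_same.max()),
            "max_overlap_reversed": int(self.o_reversed.max()),
        }

    def plot(self, ax=None):
        """Overlap curves with the null expectation and 95% band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        n = np.arange(1, self.nmax + 1)
        ax.fill_between(n, self.band_low, self.band_high, color="orange", alpha=0.3,
                        label="95% random band")
        ax.plot(n, self.expected, color="orange", label="expected random")
        ax.plot(n, self.o_same, color="tab:blue", label="same orientation")
        ax.plot(n, self.o_reversed, color="tab:green", label="reversed orientation")
        ax.set_xlabel("top/bottom n genes")
        ax.set_ylabel("overlap size")
        ax.set_title(f"{self.labels[0]} vs {self.labels[1]} (p = {self.p_perm:.3g})")
        ax.legend()
        return ax


def compare_ranked_lists(
    a: list[str],
    b: list[str],
    lam: float = DEFAULT_LAMBDA,
    nmax: int | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    labels: tuple[str, str] = ("A", "B"),
) -> OrderedListResult:
    """One-call comparison: both orientation curves, null band, score, p."""
    G = _check_universe(a, b)
    if nmax is None:
        nmax = min(DEFAULT_NMAX, G // 2)
    o_same = overlap_curve(a, b, "same", nmax)
    o_rev = overlap_curve(a, b, "reversed", nmax)
    rng = np.random.default_rng(seed)
    curves = _null_curves(G, nmax, n_perm, rng)
    low, high = np.percentile(curves, [2.5, 97.5], axis=0)
    weights = np.exp(-lam * np.arange(1, nmax + 1))
    s_obs = float(np.sum(weights * o_same))
    s_perm = curves @ weights
    p = (1.0 + np.count_nonzero(s_perm >= s_obs)) / (1.0 + n_perm)
    return OrderedListResult(
        nmax=nmax,
        lam=lam,
        o_same=o_same,
        o_reversed=o_rev,
        expected=expected_overlap(G, nmax),
        band_low=low,
        band_high=high,
        score=s_obs,
        p_perm=float(p),
        n_perm=n_perm,
        seed=seed if isinstance(seed, int) else None,
        labels=labels,
    )
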