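"""Median polish, module orientation, scoring, stratification and tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stimmod import (
    CohortSimConfig,
    GeneModule,
    ModuleProjector,
    group_tests,
    label_association,
    median_polish,
    orient_module_matrix,
    score_samples,
    simulate_cohort,
    stratify,
)
from stimmod.exceptions import ProjectionError, StimmodError


def polish_oracle(x, tol=1e-6, max_iter=20):
    """Independent augmented-matrix sweep implementation (loops, no numpy
    vectorization over effects)."""
    x = np.asarray(x, dtype=float)
    nr, nc = x.shape
    aug = np.zeros((nr + 1, nc + 1))
    aug[1:, 1:] = x.copy()
    for _ in range(max_iter):
        delta = 0.0
        for i in range(1, nr + 1):
            m = float(np.median(aug[i, 1:]))
            aug[i, 1:] -= m
            aug[i, 0] += m
            delta = max(delta, abs(m))
        m = float(np.median(aug[0, 1:]))
        aug[0, 1:] -= m
        aug[0, 0] += m
        for j in range(1, nc + 1):
            m = float(np.median(aug[1:, j]))
            aug[1:, j] -= m
            aug[0, j] += m
            delta = max(delta, abs(m))
        m = float(np.median(aug[1:, 0]))
        aug[1:, 0] -= m
        aug[0, 0] += m
        if delta < tol:
            break
    return aug[0, 0], aug[1:, 0], aug[0, 1:], aug[1:, 1:]


def _df(x):
    x = np.asarray(x, dtype=float)
    return pd.DataFrame(
        x,
        index=[f"r{i}" for i in range(x.shape[0])],
        columns=[f"c{j}" for j in range(x.shape[1])],
    )


def test_exactly_additive_matrix():
    fit = median_polish(_df([[3, 5], [7, 9]]))
    assert fit.overall == pytest.approx(6.0)
    np.testing.assert_allclose(fit.row_effects, [-2.0, 2.0])
    np.testing.assert_allclose(fit.col_effects, [-1.0, 1.0])
    np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)
    assert fit.converged


def test_shift_equivariance(rng):
    x = _df(rng.normal(size=(5, 7)))
    base = median_polish(x)
    shifted = median_polish(x + 11.5)
    assert shifted.overall == pytest.approx(base.overall + 11.5)
    np.testing.assert_allclose(shifted.row_effects, base.row_effects, atol=1e-10)
    np.testing.assert_allclose(shifted.col_effects, base.col_effects, atol=1e-10)


def test_reconstruction_identity_and_oracle_agreement(rng):
    for _ in range(100):
        nr = rng.integers(2, 8)
        nc = rng.integers(2, 8)
        x = _df(rng.normal(0, 3, size=(nr, nc)))
        fit = median_polish(x, tol=1e-6)
        np.testing.assert_allclose(
            fit.reconstruct().to_numpy(), x.to_numpy(), atol=1e-10
        )
        overall, row, col, resid = polish_oracle(x.to_numpy(), tol=1e-6)
        assert fit.overall == pytest.approx(overall, abs=1e-6)
        np.testing.assert_allclose(fit.row_effects, row, atol=1e-6)
        np.testing.assert_allclose(fit.col_effects, col, atol=1e-6)
        np.testing.assert_allclose(fit.residuals, resid, atol=1e-6)
        if fit.converged:
            assert np.abs(np.median(fit.residuals, axis=1)).max() <= 2e-6
            assert np.abs(np.median(fit.residuals, axis=0)).max() <= 2e-6


def test_polish_input_validation():
    with pytest.raises(ProjectionError):
        median_polish(_df([[1, 2]]))
    with pytest.raises(ProjectionError):
        median_polish(_df([[1, np.nan], [2, 3]]))


# ---- orientation ---------------------------------------------------------


def _module(entries):
    return GeneModule("m", tuple(sorted(entries, key=lambda e: e[1])))


def test_orientation_flips_down_genes_only(rng):
    module = _module([("UP1", 2.0), ("UP2", 0.5), ("BCL6", -2.03)])
    cohort = _df(rng.normal(8, 1, size=(3, 12)))
    cohort.index = ["UP1", "UP2", "BCL6"]
    oriented, dropped = orient_module_matrix(cohort, module, min_genes=2)
    assert dropped == []
    centered = cohort.sub(cohort.median(axis=1), axis=0)
    np.testing.assert_allclose(oriented.loc["UP1"], centered.loc["UP1"])
    np.testing.assert_allclose(oriented.loc["BCL6"], -centered.loc["BCL6"])
    assert np.abs(oriented.median(axis=1)).max() < 1e-12


def test_missing_genes_are_reported_never_imputed(rng, published_fixtures):
    module = published_fixtures[0]["aIgM"]
    present = module.symbols[:93]
    cohort = _df(rng.normal(size=(93, 20)))
    cohort.index = present
    oriented, dropped = orient_module_matrix(cohort, module)
    assert len(oriented) == 93
    assert sorted(dropped) == sorted(set(module.symbols) - set(present))
    with pytest.raises(ProjectionError, match="insufficient|present"):
        orient_module_matrix(cohort.iloc[:5], module)


# ---- scoring -------------------------------------------------------------


@pytest.fixture(scope="module")
def aigm():
    from stimmod import load_published_modules

    return load_published_modules()[0]["aIgM"]


def test_scores_recover_planted_gradient(aigm):
    cfg = CohortSimConfig(n_samples=60, beta_scale=1.0, sigma_resid=0.1, seed=4)
    expr, _, u = simulate_cohort(cfg, aigm)
    proj = ModuleProjector().fit(expr, module=aigm)
    assert stats.spearmanr(proj.scores_[u.index], u).statistic > 0.95
    assert proj.order_ == sorted(proj.scores_.index, key=lambda s: (proj.scores_[s], s))


def test_score_permutation_equivariance(rng, aigm):
    cfg = CohortSimConfig(n_samples=30, n_background_genes=0, seed=9)
    expr, _, _ = simulate_cohort(cfg, aigm)
    oriented, _ = orient_module_matrix(expr, aigm)
    base = score_samples(oriented)
    shuffled = oriented[list(rng.permutation(oriented.columns))]
    perm = score_samples(shuffled)
    pd.testing.assert_series_equal(
        base.scores.sort_index(), perm.scores.sort_index(), atol=1e-9, rtol=0
    )


def test_duplicated_samples_get_equal_adjacent_scores(rng):
    x = _df(rng.normal(size=(12, 5)))
    x["c5"] = x["c2"]
    fit_proj = score_samples(x)
    assert fit_proj.scores["c5"] == pytest.approx(fit_proj.scores["c2"], abs=1e-12)
    i2, i5 = fit_proj.order.index("c2"), fit_proj.order.index("c5")
    assert abs(i2 - i5) == 1


def test_row_shift_does_not_reorder_samples(rng, aigm):
    cfg = CohortSimConfig(n_samples=24, n_background_genes=0, seed=2)
    expr, _, _ = simulate_cohort(cfg, aigm)
    oriented, _ = orient_module_matrix(expr, aigm)
    base = score_samples(oriented)
    bumped = oriented.copy()
    bumped.iloc[0] += 5.0
    again = score_samples(bumped)
    assert again.order == base.order


# ---- stratification ------------------------------------------------------


def test_tertile_sizes():
    s9 = pd.Series(np.arange(9.0), index=[f"s{i}" for i in range(9)])
    g = stratify(s9)
    assert g.value_counts().to_dict() == {"low": 3, "intermediate": 3, "high": 3}
    s10 = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
    g10 = stratify(s10)
    assert g10.value_counts()[["low", "intermediate", "high"]].tolist() == [4, 3, 3]


def test_group_means_increase_with_activation(rng):
    scores = pd.Series(rng.normal(size=31), index=[f"s{i}" for i in range(31)])
    groups = stratify(scores)
    means = scores.groupby(groups).mean()
    assert means["low"] < means["intermediate"] < means["high"]


def test_stratify_guardrails():
    s = pd.Series([1.0, 2.0], index=["a", "b"])
    with pytest.raises(StimmodError):
        stratify(s, k=1)
    with pytest.raises(StimmodError):
        stratify(s, k=3)


# ---- group tests and label association -----------------------------------


def test_group_tests_null_calibration():
    rng = np.random.default_rng(0)
    hits = 0
    groups = pd.Series(
        ["a"] * 15 + ["b"] * 15 + ["c"] * 15, index=[f"s{i}" for i in range(45)]
    )
    for _ in range(200):
        vals = pd.Series(rng.normal(size=45), index=groups.index)
        hits += group_tests(vals, groups)["kruskal_p"] < 0.05
    assert abs(hits / 200 - 0.05) < 0.05


def test_group_tests_detect_planted_shift():
    rng = np.random.default_rng(1)
    vals = pd.Series(
        np.concatenate(
            [rng.normal(0, 1, 30), rng.normal(2, 1, 30), rng.normal(4, 1, 30)]
        ),
        index=[f"s{i}" for i in range(90)],
    )
    groups = pd.Series(
        ["low"] * 30 + ["mid"] * 30 + ["high"] * 30, index=vals.index
    )
    res = group_tests(vals, groups)
    assert res["kruskal_p"] < 1e-10
    assert all(pair["p"] < 0.001 for pair in res["pairwise"])
    assert len(res["pairwise"]) == 3


def test_group_tests_require_two_groups():
    vals = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
    groups = pd.Series(["g"] * 3, index=list("abc"))
    with pytest.raises(StimmodError):
        group_tests(vals, groups)


def test_label_association_null_and_power():
    rng = np.random.default_rng(2)
    null_ps = []
    for _ in range(100):
        scores = pd.Series(rng.normal(size=40), index=[f"s{i}" for i in range(40)])
        labels = pd.Series(rng.integers(0, 2, 40), index=scores.index)
        if labels.sum() in (0, 40):
            continue
        null_ps.append(label_association(scores, labels)["p"])
    # roughly uniform: mean near 0.5, no excess of tiny p
    assert 0.4 < np.mean(null_ps) < 0.6
    assert np.mean(np.asarray(null_ps) < 0.05) < 0.12

    scores = pd.Series(np.arange(40.0), index=[f"s{i}" for i in range(40)])
    labels = pd.Series([1] * 10 + [0] * 30, index=scores.index)  # low scores labeled
    res = label_association(scores, labels)
    assert res["p"] < 1e-4 and res["direction"] == "lower"


def test_label_association_needs_both_labels():
    scores = pd.Series([1.0, 2.0], index=list("ab"))
    with pytest.raises(StimmodError):
        label_association(scores, pd.Series([1, 1], index=list("ab")))


def test_projector_reports_dropped_genes(rng, aigm):
    cfg = CohortSimConfig(n_samples=30, n_background_genes=0, seed=6)
    expr, _, _ = simulate_cohort(cfg, aigm)
    expr_missing = expr.drop(index=aigm.symbols[:7])
    proj = ModuleProjector().fit(expr_missing, module=aigm)
    assert len(proj.dropped_genes_) == 7
    assert len(proj.scores_) == 30
    recon = proj.fit_.reconstruct()
    oriented, _ = orient_module_matrix(expr_missing, aigm)
    np.testing.assert_allclose(recon.to_numpy(), oriented.to_numpy(), atol=1e-10)
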