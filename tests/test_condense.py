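"""Outcome summaries, agglomerative condensation, ranking, and disparity stats."""

import numpy as np
import pandas as pd
import pytest

import econclusters as ec
from econclusters.condense import scale_outcome_means, weighted_ttest
from helpers import build_table, naive_agglomerative


def summary_frame(means, settings=None):
    """Build an outcome-summary frame from (haz, literacy, deceased) rows."""
    means = np.asarray(means, dtype=float)
    frame = pd.DataFrame(
        means, columns=["haz_mean", "literacy_mean", "deceased_mean"],
        index=[f"c{i}" for i in range(1, len(means) + 1)],
    )
    frame["setting"] = settings if settings is not None else "rural"
    for o in ("haz", "literacy", "deceased"):
        frame[f"{o}_se"] = 0.1
        frame[f"{o}_n"] = 10
    return frame


# --- outcome summaries ------------------------------------------------------

def test_deceased_proportion_formula_and_exclusion():
    from econclusters.condense import deceased_proportion

    assert deceased_proportion(1, 1, 4) == 0.5
    with pytest.raises(ec.EconClustersError):
        deceased_proportion(0, 0, 0)


def test_weighted_outcome_mean_closed_form():
    levels = {"setting": ["rural", "urban"]}
    table = build_table({"setting": ["rural", "rural"]}, levels, ids=["a", "b"])
    women = ec.WomanTable(
        data=pd.DataFrame(
            {
                "household_id": ["a", "b", "a"],
                "weight": [1.0, 3.0, 1.0],
                "literacy": [0, 1, 2],
                "sons_died": [0, 1, 0],
                "daughters_died": [0, 1, 0],
                "children_ever_born": [4, 4, 0],  # last woman excluded (0 born)
            }
        )
    )
    labels = pd.Series({"a": 1, "b": 1})
    summary = ec.outcome_summary(labels, table, women=women)
    # deceased: proportions 0.0 (w=1) and 0.5 (w=3) -> 0.375
    assert summary.loc[1, "deceased_mean"] == pytest.approx(0.375)
    assert summary.loc[1, "deceased_n"] == 2
    # literacy over all three women: (0*1 + 1*3 + 2*1) / 5
    assert summary.loc[1, "literacy_mean"] == pytest.approx(1.0)


def test_group_without_individuals_warns_and_is_nan():
    levels = {"setting": ["rural", "urban"]}
    table = build_table({"setting": ["rural", "urban"]}, levels, ids=["a", "b"])
    children = ec.ChildTable(
        data=pd.DataFrame({"household_id": ["a"], "weight": [1.0], "haz": [-1.0]})
    )
    labels = pd.Series({"a": 1, "b": 2})
    with pytest.warns(UserWarning, match="no individuals"):
        summary = ec.outcome_summary(labels, table, children=children)
    assert np.isnan(summary.loc[2, "haz_mean"])


# --- survey-weighted means and SEs ------------------------------------------

def test_equal_weight_se_reduces_to_classical():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    mean, se, n = ec.survey_mean_se(y, np.ones(4))
    assert mean == pytest.approx(2.5)
    assert se == pytest.approx(y.std(ddof=1) / 2)  # s / sqrt(n)


def test_design_se_collapses_within_psu():
    # two PSUs with identical totals -> zero between-PSU variance
    y = np.array([1.0, 3.0, 1.0, 3.0])
    strat = np.array(["s1"] * 4)
    psu = np.array(["p1", "p1", "p2", "p2"])
    _, se, _ = ec.survey_mean_se(y, np.ones(4), strat, psu)
    assert se == pytest.approx(0.0)


# --- condensation -----------------------------------------------------------

def test_scaled_matrix_is_standardized():
    frame = summary_frame([[-2, 0.2, 0.15], [-1, 0.8, 0.10], [0, 1.5, 0.05]])
    X, dropped = scale_outcome_means(frame)
    assert dropped == []
    np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(X.std(axis=0, ddof=1), 1.0)


def test_identical_clusters_merge_first_at_height_zero():
    frame = summary_frame(
        [[-2, 0.2, 0.15], [-2, 0.2, 0.15], [0, 1.5, 0.05], [1, 1.8, 0.02]]
    )
    condensed = ec.condense_clusters(frame, target_groups=(3, 3))
    Z = condensed.linkages["rural"]
    assert Z[0, 2] == pytest.approx(0.0)
    assert condensed.mapping["c1"] == condensed.mapping["c2"]
    assert len(set(condensed.mapping.values())) == 3


@pytest.mark.parametrize("method", ["complete", "average"])
def test_linkage_matches_independent_oracle(method):
    """Merge heights and topology agree with a naive O(n^3) agglomerative
    implementation on random 8-cluster instances."""
    rng = np.random.default_rng(12)
    for _ in range(5):
        X = rng.normal(size=(8, 3))
        from scipy.cluster.hierarchy import linkage

        Z = linkage(X, method=method)
        oracle = naive_agglomerative(X, method=method)
        # reconstruct scipy's merge sequence as leaf sets
        sets = {i: frozenset([i]) for i in range(8)}
        for step, (a, b, h, _) in enumerate(Z):
            sa, sb = sets[int(a)], sets[int(b)]
            oa, ob, oh = oracle[step]
            assert {sa, sb} == {oa, ob}
            assert h == pytest.approx(oh)
            sets[8 + step] = sa | sb


def test_condense_runs_separately_per_stratum():
    frame = summary_frame(
        [[-2, 0.2, 0.15], [-1.8, 0.3, 0.14], [-1, 0.8, 0.10],
         [0, 1.5, 0.05], [0.2, 1.6, 0.04], [1, 1.9, 0.01]],
        settings=["rural"] * 3 + ["urban"] * 3,
    )
    condensed = ec.condense_clusters(frame, target_groups=(4, 4))
    groups = set(condensed.mapping.values())
    assert len(groups) == 4
    # no group mixes strata
    for g in groups:
        members = [c for c, gg in condensed.mapping.items() if gg == g]
        assert frame.loc[members, "setting"].nunique() == 1


def test_single_cluster_stratum_passes_through():
    frame = summary_frame(
        [[-2, 0.2, 0.15], [0, 1.5, 0.05], [1, 1.8, 0.02]],
        settings=["rural", "urban", "urban"],
    )
    condensed = ec.condense_clusters(frame, target_groups=(3, 3))
    assert condensed.linkages["rural"] is None
    assert len(set(condensed.mapping.values())) == 3


def test_force_separate_splits_merged_group():
    frame = summary_frame(
        [[-2, 0.2, 0.15], [-1.99, 0.21, 0.15], [0, 1.5, 0.05], [1, 1.8, 0.02]]
    )
    merged = ec.condense_clusters(frame, target_groups=(3, 3))
    assert merged.mapping["c1"] == merged.mapping["c2"]
    forced = ec.condense_clusters(frame, target_groups=(3, 3),
                                  force_separate=[["c1"]])
    assert forced.mapping["c1"] != forced.mapping["c2"]


def test_condensation_invariant_to_cluster_relabeling():
    frame = summary_frame(
        [[-2, 0.2, 0.15], [-1, 0.8, 0.10], [0, 1.5, 0.05], [1, 1.8, 0.02]]
    )
    condensed = ec.condense_clusters(frame, target_groups=(2, 2))
    renamed = frame.rename(index={"c1": "x1", "c2": "x2", "c3": "x3", "c4": "x4"})
    condensed2 = ec.condense_clusters(renamed, target_groups=(2, 2))
    part1 = {frozenset(c for c in frame.index if condensed.mapping[c] == g)
             for g in set(condensed.mapping.values())}
    part2 = {frozenset(c.replace("x", "c") for c in renamed.index
                       if condensed2.mapping[c] == g)
             for g in set(condensed2.mapping.values())}
    assert part1 == part2


# --- ranking ----------------------------------------------------------------

def test_comonotone_outcomes_rank_conflict_free():
    frame = summary_frame(
        [[-2, 0.2, 0.15], [-1, 0.8, 0.10], [0, 1.5, 0.05]]
    )
    ranked, conflicts = ec.rank_groups(frame)
    assert conflicts == []
    assert ranked["rank"].tolist() == [1, 2, 3]


def test_disagreeing_indicator_is_flagged_not_resolved():
    # literacy says c1 < c2 but HAZ says the opposite
    frame = summary_frame([[0.0, 0.2, 0.15], [-1.0, 0.8, 0.10]])
    ranked, conflicts = ec.rank_groups(frame)
    assert ranked["rank"].tolist() == [1, 2]  # still ranked by literacy
    assert any(c["indicator"] == "haz" for c in conflicts)


def test_planted_wealth_gradient_is_recovered(small_model, small_sim):
    model = small_model.selected
    labels = pd.Series(model.assignment)
    summary = ec.outcome_summary(labels, small_sim.households,
                                 small_sim.children, small_sim.women)
    ranked, conflicts = ec.rank_groups(summary)
    assert conflicts == []
    # within each setting, rank order matches the planted poor < wealthy order
    name_of = {}
    for cluster in summary.index:
        members = [h for h, c in model.assignment.items() if c == cluster]
        name_of[cluster] = small_sim.labels.loc[members].mode()[0]
    for stratum in ("rural", "urban"):
        sub = ranked[ranked["setting"] == stratum].sort_values("rank")
        assert [name_of[c] for c in sub.index] == \
            [f"{stratum}_poor", f"{stratum}_wealthy"]


# --- validation statistics ---------------------------------------------------

def test_eta_squared_degenerate_cases():
    y = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0])
    g = np.array([1, 1, 2, 2, 3, 3])
    assert ec.eta_squared(y, np.ones(6), g) == pytest.approx(0.0)
    y2 = np.array([1.0, 1.0, 2.0, 2.0, 5.0, 5.0])  # constant within groups
    assert ec.eta_squared(y2, np.ones(6), g) == pytest.approx(1.0)


def test_eta_squared_matches_hand_computed_toy():
    """Three groups [1,2,3], [2,3,4], [4,5,6]: BSS=14, TSS=20, eta^2=0.7."""
    y = np.array([1, 2, 3, 2, 3, 4, 4, 5, 6], dtype=float)
    g = np.repeat(["A", "B", "C"], 3)
    w = np.ones(9)
    assert ec.eta_squared(y, w, g) == pytest.approx(0.7)
    report = ec.validation_stats(g, y, w, order=["A", "B", "C"])
    assert report.eta_squared == pytest.approx(0.7)
    # adjacent t for A vs B: means 2 vs 3, s^2=1, n=3 -> t = -1/sqrt(2/3)
    t_ab = report.adjacent.iloc[0]["t"]
    assert t_ab == pytest.approx(-np.sqrt(1.5))
    assert report.anova_p < 0.05


def test_eta_squared_invariant_to_affine_rescaling():
    rng = np.random.default_rng(4)
    y = rng.normal(size=30)
    w = rng.uniform(0.5, 2, 30)
    g = rng.integers(0, 3, 30)
    base = ec.eta_squared(y, w, g)
    assert ec.eta_squared(3.5 * y - 7, w, g) == pytest.approx(base)


def test_merging_groups_cannot_increase_between_ss():
    rng = np.random.default_rng(6)
    y = rng.normal(size=40)
    w = rng.uniform(0.5, 2, 40)
    g = rng.integers(0, 4, 40)
    merged = np.where(g == 3, 2, g)
    assert ec.eta_squared(y, w, merged) <= ec.eta_squared(y, w, g) + 1e-12


def test_weighted_ttest_zero_variance_is_nan():
    t, df, p = weighted_ttest(1.0, 0.0, 3, 1.0, 0.0, 3)
    assert np.isnan(t)


def test_validation_stats_excludes_degenerate_groups():
    y = np.array([1.0, 2.0, 3.0, 5.0, 6.0, 9.0])
    g = np.array(["a", "a", "a", "b", "b", "c"])  # group c has a single observation
    with pytest.warns(UserWarning, match="degenerate"):
        report = ec.validation_stats(g, y, np.ones(6), order=["a", "b", "c"])
    assert np.isfinite(report.anova_f)
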