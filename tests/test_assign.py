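"""The medoid-matching assignment rule and its two-stage tie-break."""

import numpy as np
import pandas as pd
import pytest

import econclusters as ec
from helpers import build_table

VARS = ["setting", "phone", "fuel", "land", "radio"]
LEVELS = {
    "setting": ["rural", "urban"],
    "phone": ["no", "yes"],
    "fuel": ["wood", "charcoal", "LPG"],
    "land": ["no", "yes"],
    "radio": ["no", "yes"],
}

MEDOIDS = [
    {"setting": "rural", "phone": "no", "fuel": "wood", "land": "yes", "radio": "no"},
    {"setting": "rural", "phone": "yes", "fuel": "charcoal", "land": "yes", "radio": "yes"},
    {"setting": "urban", "phone": "no", "fuel": "charcoal", "land": "no", "radio": "yes"},
    {"setting": "urban", "phone": "yes", "fuel": "LPG", "land": "no", "radio": "no"},
]


def reference_table(rows, clusters):
    cols = {v: [r[v] for r in rows] for v in VARS}
    table = build_table(cols, LEVELS)
    return table, {hid: c for hid, c in zip(table.data.index, clusters)}


def toy_model(rows=None, clusters=None):
    rows = rows if rows is not None else list(MEDOIDS)
    clusters = clusters if clusters is not None else [1, 2, 3, 4]
    table, assignment = reference_table(rows, clusters)
    model = ec.ClusterModel(
        asset_names=VARS,
        levels=LEVELS,
        k=4,
        medoids=[dict(m) for m in MEDOIDS],
        assignment=assignment,
        profile_assignment=[
            {"profile": dict(r), "cluster": c, "weight": 1.0}
            for r, c in zip(rows, clusters)
        ],
        asw=0.9,
        config=ec.SearchConfig(n_assets=5, k_range=(4, 4), min_prevalence=0.0),
        provenance=table.fingerprint(),
    )
    return model, table


def test_exact_medoid_answers_assign_directly():
    model, table = toy_model()
    res = ec.assign_participant("p", dict(MEDOIDS[2]), model, table)
    assert (res.cluster, res.match_count, res.method) == (3, 5, "medoid_match")


def test_tie_resolved_by_unanimous_reference_households():
    # participant agrees 3/5 with medoids 2 and 4, less with the others
    answers = {"setting": "urban", "phone": "yes", "fuel": "charcoal",
               "land": "yes", "radio": "no"}
    model, _ = toy_model()
    med = np.array([[sum(answers[v] == m[v] for v in VARS)] for m in MEDOIDS]).ravel()
    assert list(med) == [2, 3, 2, 3]
    # reference: the maximally similar households all sit in cluster 4
    extra = dict(answers)
    rows = list(MEDOIDS) + [extra]
    model, table = toy_model(rows, [1, 2, 3, 4, 4])
    res = ec.assign_participant("p", answers, model, table)
    assert (res.cluster, res.method) == (4, "reference_tiebreak")


def test_tie_spanning_clusters_is_unassigned():
    answers = {"setting": "urban", "phone": "yes", "fuel": "charcoal",
               "land": "yes", "radio": "no"}
    extra2, extra4 = dict(answers), dict(answers)
    rows = list(MEDOIDS) + [extra2, extra4]
    model, table = toy_model(rows, [1, 2, 3, 4, 2, 4])  # equally similar in 2 and 4
    res = ec.assign_participant("p", answers, model, table)
    assert res.cluster is None and res.method == "unassigned"


def test_all_missing_answers_are_unassigned():
    model, table = toy_model()
    res = ec.assign_participant("p", {}, model, table)
    assert res.method == "unassigned" and res.match_count == 0


def test_agreement_counted_over_observed_answers_only():
    model, table = toy_model()
    res = ec.assign_participant(
        "p", {"setting": "urban", "phone": "yes", "fuel": "LPG"}, model, table
    )
    assert (res.cluster, res.match_count) == (4, 3)


def test_unknown_variable_errors():
    model, table = toy_model()
    with pytest.raises(ec.EconClustersError, match="absent"):
        ec.assign_participant("p", {"bicycle": "yes"}, model, table)


def test_undeclared_level_errors():
    model, table = toy_model()
    with pytest.raises(ec.TableValidationError):
        ec.assign_participant("p", {"fuel": "lpg"}, model, table)


def test_feedback_assignment_reproduces_model_clusters(small_model, small_sim):
    """Every fitted household fed back as a participant lands in its own
    model cluster (stage 2 is unanimous for identical profiles)."""
    model = small_model.selected
    table = small_sim.households
    part = table.data.reset_index().rename(columns={"household_id": "participant_id"})
    results = ec.assign_table(part, model, table)
    fitted = results[results["participant_id"].isin(model.assignment)]
    assert (fitted["cluster"].notna()).all()
    expected = fitted["participant_id"].map(model.assignment)
    assert (fitted["cluster"].astype(int).to_numpy() == expected.to_numpy()).all()


def test_irrelevant_reference_households_never_change_assignment():
    answers = {"setting": "urban", "phone": "yes", "fuel": "charcoal",
               "land": "yes", "radio": "no"}
    rows = list(MEDOIDS) + [dict(answers)]
    model, table = toy_model(rows, [1, 2, 3, 4, 4])
    before = ec.assign_participant("p", answers, model, table)
    # add a household disagreeing with the participant on everything
    stranger = {"setting": "rural", "phone": "no", "fuel": "LPG",
                "land": "no", "radio": "yes"}
    rows2 = rows + [stranger]
    model2, table2 = toy_model(rows2, [1, 2, 3, 4, 4, 1])
    after = ec.assign_participant("p", answers, model2, table2)
    assert (before.cluster, before.method) == (after.cluster, after.method)


def test_assignment_independent_of_participant_order():
    model, table = toy_model()
    part = pd.DataFrame(
        [{"participant_id": f"p{i}", **m} for i, m in enumerate(MEDOIDS)]
    )
    a = ec.assign_table(part, model, table)
    b = ec.assign_table(part.iloc[::-1].reset_index(drop=True), model, table)
    merged = a.merge(b, on="participant_id", suffixes=("_a", "_b"))
    assert (merged["cluster_a"] == merged["cluster_b"]).all()


def test_distribution_identity_on_reference_households(small_model, small_sim):
    model = small_model.selected
    table = small_sim.households
    part = table.data.reset_index().rename(columns={"household_id": "participant_id"})
    results = ec.assign_table(part, model, table)
    dist = ec.assignment_distribution(results, model)
    # unweighted new-data shares equal the reference's unweighted shares
    counts = pd.Series(model.assignment).value_counts(normalize=True).sort_index()
    np.testing.assert_allclose(dist["new_share"].to_numpy(), counts.to_numpy(), atol=1e-12)
    assert dist.attrs["n_unassigned"] == 0


def test_distribution_with_all_unassigned():
    model, _ = toy_model()
    results = pd.DataFrame(
        {"participant_id": ["a", "b"], "cluster": [None, None],
         "match_count": [0, 0], "method": ["unassigned"] * 2}
    )
    dist = ec.assignment_distribution(results, model)
    assert dist.attrs["n_unassigned"] == 2
    assert dist["new_count"].sum() == 0
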