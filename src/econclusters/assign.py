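"""Assigning new survey/registry participants to a fitted model's clusters.

A participant answers (possibly with gaps) the model's few asset
questions.  Stage 1 counts agreements between the participant's
non-missing answers and each cluster medoid; a unique best-matching medoid
decides the cluster.  On a tie, stage 2 compares the participant to every
reference (survey) household: if all households with the maximal agreement
count sit in one cluster, the participant joins that cluster; otherwise
the participant is explicitly UNASSIGNED — there is no random tie-breaking
anywhere, and missing data or rare asset combinations can legitimately
leave a participant without a cluster.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    ClusterModel,
    EconClustersError,
    HouseholdTable,
    TableValidationError,
)

UNASSIGNED = "unassigned"
MEDOID_MATCH = "medoid_match"
REFERENCE_TIEBREAK = "reference_tiebreak"


@dataclass(frozen=True)
class AssignmentResult:
    participant_id: str
    cluster: int | None           # 1..k, or None when unassigned
    match_count: int              # agreements with the winning medoid(s)
    method: str                   # medoid_match | reference_tiebreak | unassigned


class _ReferenceIndex:
    """Encoded reference households restricted to the model's variables."""

    def __init__(self, model: ClusterModel, reference: HouseholdTable):
        fp = reference.fingerprint()
        expected = model.provenance
        if (fp.get("n_households") != expected.get("n_households")
                or fp.get("id_hash") != expected.get("id_hash")):
            _warnings.warn(
                "reference table fingerprint does not match the one the model "
                "was fitted on; stage-2 tie-breaks may differ from the "
                "original fit",
                stacklevel=3,
            )
        sub = reference.data
        mask = sub[model.asset_names].notna().all(axis=1).to_numpy()
        ids = sub.index.astype(str).to_numpy()[mask]
        in_model = np.array([hid in model.assignment for hid in ids])
        ids = ids[in_model]
        codes = np.column_stack(
            [
                pd.Categorical(
                    sub.loc[mask, v][in_model], categories=model.levels[v]
                ).codes
                for v in model.asset_names
            ]
        )
        self.codes = codes
        self.clusters = np.array([model.assignment[hid] for hid in ids])


def _encode_answers(
    answers: Mapping[str, str | None], model: ClusterModel
) -> np.ndarray:
    """Participant answers as level codes; -1 marks missing."""
    unknown = [v for v in answers if v not in model.levels]
    if unknown:
        raise EconClustersError(
            f"participant answers variables absent from the model: {unknown}"
        )
    codes = np.full(len(model.asset_names), -1, dtype=int)
    for j, v in enumerate(model.asset_names):
        val = answers.get(v)
        if val is None or (isinstance(val, float) and np.isnan(val)) or val is pd.NA:
            continue
        if val == "" or val == "NA":
            continue
        if val not in model.levels[v]:
            raise TableValidationError(
                f"answer {val!r} for {v!r} not in declared levels {model.levels[v]}"
            )
        codes[j] = model.levels[v].index(val)
    return codes


def _medoid_codes(model: ClusterModel) -> np.ndarray:
    return np.column_stack(
        [
            [model.levels[v].index(m[v]) for m in model.medoids]
            for v in model.asset_names
        ]
    )


def assign_participant(
    participant_id: str,
    answers: Mapping[str, str | None],
    model: ClusterModel,
    reference: HouseholdTable | None = None,
    _ref_index: "_ReferenceIndex | None" = None,
) -> AssignmentResult:
    """Assign one participant by the medoid-matching rule with tie-break.

    ``reference`` is only consulted on a stage-1 tie; omitting it turns
    every tie into UNASSIGNED.
    """
    codes = _encode_answers(answers, model)
    observed = codes >= 0
    if not observed.any():
        return AssignmentResult(participant_id, None, 0, UNASSIGNED)

    med = _medoid_codes(model)
    agree = (med[:, observed] == codes[observed]).sum(axis=1)
    best = int(agree.max())
    winners = np.flatnonzero(agree == best)
    if len(winners) == 1:
        return AssignmentResult(participant_id, int(winners[0]) + 1, best, MEDOID_MATCH)

    # stage 2: unanimity among the most similar reference households
    if _ref_index is None:
        if reference is None:
            return AssignmentResult(participant_id, None, best, UNASSIGNED)
        _ref_index = _ReferenceIndex(model, reference)
    ref_agree = (_ref_index.codes[:, observed] == codes[observed]).sum(axis=1)
    if len(ref_agree) == 0:
        return AssignmentResult(participant_id, None, best, UNASSIGNED)
    top = _ref_index.clusters[ref_agree == ref_agree.max()]
    unique = np.unique(top)
    if len(unique) == 1:
        return AssignmentResult(participant_id, int(unique[0]), best, REFERENCE_TIEBREAK)
    return AssignmentResult(participant_id, None, best, UNASSIGNED)


def assign_table(
    participants: pd.DataFrame,
    model: ClusterModel,
    reference: HouseholdTable | None = None,
    id_column: str = "participant_id",
) -> pd.DataFrame:
    """Assign every row of a participants table.

    ``participants`` needs an id column plus one column per model variable
    (missing answers as empty strings or NA).  Returns a frame with
    ``participant_id, cluster, match_count, method``; unassigned rows keep
    an empty cluster.  Deterministic and independent of row order.
    """
    if id_column not in participants.columns:
        raise EconClustersError(f"participants table lacks {id_column!r}")
    ref_index = _ReferenceIndex(model, reference) if reference is not None else None
    results = []
    for _, row in participants.iterrows():
        answers = {
            v: (None if pd.isna(row[v]) else str(row[v]))
            for v in model.asset_names
            if v in participants.columns
        }
        results.append(
            assign_participant(str(row[id_column]), answers, model, _ref_index=ref_index)
        )
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in results],
            "cluster": [r.cluster for r in results],
            "match_count": [r.match_count for r in results],
            "method": [r.method for r in results],
        }
    )


def assignment_distribution(
    results: pd.DataFrame, model: ClusterModel
) -> pd.DataFrame:
    """Cluster shares in newly assigned data versus the reference survey.

    The new-data shares are unweighted proportions among assigned
    participants; the reference shares are survey-weighted, taken from the
    profile weights stored in the model.  Unassigned participants are
    reported separately in the frame's ``attrs``.
    """
    assigned = results[results["cluster"].notna()]
    ref_weight = np.zeros(model.k)
    for entry in model.profile_assignment:
        ref_weight[int(entry["cluster"]) - 1] += float(entry["weight"])
    out = pd.DataFrame(
        {
            "cluster": np.arange(1, model.k + 1),
            "reference_share": ref_weight / ref_weight.sum(),
            "new_count": [
                int((assigned["cluster"] == c).sum()) for c in range(1, model.k + 1)
            ],
        }
    )
    n_assigned = len(assigned)
    out["new_share"] = out["new_count"] / n_assigned if n_assigned else np.nan
    out.attrs["n_unassigned"] = int(len(results) - n_assigned)
    return out
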