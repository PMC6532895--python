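"""Exhaustive model search: asset subsets x cluster counts, scored by ASW.

The search enumerates every subset of ``n_assets`` candidate variables that
contains the forced variables (by default the rural/urban setting), crossed
with every cluster count in ``k_range``.  Each candidate is scored through
the fixed pipeline

    aggregate_profiles -> gower_matrix -> weighted_pam -> weighted_asw

and the final model is chosen either as the global ASW argmax
(``mode="max_asw"``) or, for a model with few interpretable groups, by the
threshold rule: the smallest K whose best ASW reaches the threshold
(default 0.70), then the asset subset with the highest ASW at that K
(``mode="threshold"``).  All ties are broken deterministically
(lexicographically first subset, then smaller K), so the outcome is
independent of evaluation order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .clustering import weighted_asw, weighted_pam
from .core_data import (
    ClusterModel,
    CompleteCaseReport,
    EconClustersError,
    HouseholdTable,
    SearchConfig,
    complete_case_filter,
)
from .dissimilarity import ProfileTable, aggregate_profiles, gower_matrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateScore:
    """Score of one (asset subset, k) candidate; ``feasible=False`` records
    candidates with fewer distinct profiles than clusters."""

    assets: tuple[str, ...]
    k: int
    asw: float | None
    n_profiles: int
    total_cost: float | None
    feasible: bool = True


@dataclass
class SearchResult:
    scores: list[CandidateScore]
    selected: ClusterModel
    selection_rule: str
    warnings: list[str]
    complete_case: CompleteCaseReport

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "assets": ["+".join(s.assets) for s in self.scores],
                "k": [s.k for s in self.scores],
                "asw": [s.asw for s in self.scores],
                "n_profiles": [s.n_profiles for s in self.scores],
                "total_cost": [s.total_cost for s in self.scores],
                "feasible": [s.feasible for s in self.scores],
            }
        )


def _resolve_forced(table: HouseholdTable, config: SearchConfig) -> tuple[str, ...]:
    forced = config.forced_variables
    if forced is None:
        forced = (table.setting,)
    missing = [v for v in forced if v not in table.levels]
    if missing:
        raise EconClustersError(f"forced variables absent from table: {missing}")
    return tuple(forced)


def eligible_variables(
    table: HouseholdTable,
    min_prevalence: float,
    forced: Sequence[str] = (),
) -> list[str]:
    """Candidate variables after the rare-asset prevalence filter.

    A two-level (ownership) variable is eligible iff the survey-weighted
    share of its positive level — the *second* declared level, by the
    ``[no, yes]`` convention — is at least ``min_prevalence`` among
    households answering it.  Multi-level variables and forced variables
    are always eligible.
    """
    out = []
    for var in table.variables:
        if var in forced:
            out.append(var)
            continue
        levels = table.levels[var]
        if len(levels) != 2:
            out.append(var)
            continue
        col = table.data[var]
        mask = col.notna().to_numpy()
        if not mask.any():
            continue
        w = table.weights[mask]
        prevalence = float(w[(col[mask] == levels[1]).to_numpy()].sum() / w.sum())
        if prevalence >= min_prevalence:
            out.append(var)
        else:
            log.info("dropping rare asset %r (weighted prevalence %.3f)", var, prevalence)
    return out


def enumerate_candidates(
    eligible: Sequence[str], config: SearchConfig, forced: Sequence[str] = ()
) -> Iterator[tuple[tuple[str, ...], int]]:
    """Yield every (asset subset, k) candidate in deterministic order.

    Subsets are the forced variables plus every lexicographic combination
    of the remaining eligible variables; each is crossed with every k in
    ``k_range`` ascending.
    """
    forced = tuple(forced)
    free = sorted(v for v in eligible if v not in forced)
    n_free = config.n_assets - len(forced)
    if n_free < 0:
        raise EconClustersError("more forced variables than n_assets")
    if n_free > len(free):
        raise EconClustersError(
            f"n_assets={config.n_assets} exceeds the {len(free) + len(forced)} "
            "eligible variables"
        )
    lo, hi = config.k_range
    for combo in itertools.combinations(free, n_free):
        assets = forced + combo
        for k in range(lo, hi + 1):
            yield assets, k


def score_candidate(
    table: HouseholdTable, subset: Sequence[str], k: int
) -> CandidateScore:
    """Score one candidate; infeasible (k > #profiles) is recorded, not fatal."""
    profiles = aggregate_profiles(table, subset)
    return _score_from_profiles(profiles, tuple(subset), k)


def _score_from_profiles(
    profiles: ProfileTable, assets: tuple[str, ...], k: int,
    d: np.ndarray | None = None,
) -> CandidateScore:
    if k > profiles.n_profiles or profiles.n_profiles < 2:
        return CandidateScore(assets=assets, k=k, asw=None,
                              n_profiles=profiles.n_profiles,
                              total_cost=None, feasible=False)
    if d is None:
        d = gower_matrix(profiles)
    pam = weighted_pam(d, profiles.weights, k)
    if len(np.unique(pam.labels)) < 2:
        return CandidateScore(assets=assets, k=k, asw=None,
                              n_profiles=profiles.n_profiles,
                              total_cost=pam.total_cost, feasible=False)
    sil = weighted_asw(d, profiles.weights, pam.labels)
    return CandidateScore(assets=assets, k=k, asw=sil.asw,
                          n_profiles=profiles.n_profiles,
                          total_cost=pam.total_cost)


def select_model(
    scores: Iterable[CandidateScore], config: SearchConfig
) -> tuple[CandidateScore, list[str]]:
    """Apply the selection rule to a score table.

    ``max_asw``: global ASW argmax.  ``threshold``: smallest k whose best
    ASW reaches ``config.asw_threshold``, then the ASW argmax at that k; if
    no k qualifies, fall back to max-ASW with an explicit warning.  Ties on
    ASW break to the lexicographically first subset, then the smaller k.
    """
    feasible = [s for s in scores if s.feasible and s.asw is not None]
    if not feasible:
        raise EconClustersError("no feasible (subset, k) candidate to select from")
    warnings: list[str] = []

    def best(cands: list[CandidateScore]) -> CandidateScore:
        return min(cands, key=lambda s: (-s.asw, s.assets, s.k))

    if config.mode == "max_asw":
        return best(feasible), warnings

    for k in sorted({s.k for s in feasible}):
        at_k = [s for s in feasible if s.k == k]
        champion = best(at_k)
        if champion.asw >= config.asw_threshold:
            return champion, warnings
    warnings.append(
        f"no k in {config.k_range} reached ASW threshold "
        f"{config.asw_threshold}; falling back to the max-ASW model"
    )
    return best(feasible), warnings


def build_model(
    table: HouseholdTable,
    assets: Sequence[str],
    k: int,
    config: SearchConfig,
    provenance: dict | None = None,
) -> ClusterModel:
    """Fit the final model for a chosen subset and k on a complete-case table."""
    profiles = aggregate_profiles(table, assets)
    d = gower_matrix(profiles)
    pam = weighted_pam(d, profiles.weights, k)
    sil = weighted_asw(d, profiles.weights, pam.labels)
    medoids = [profiles.profile(int(m)) for m in pam.medoid_indices]
    assignment: dict[str, int] = {}
    profile_assignment = []
    for i in range(profiles.n_profiles):
        cluster = int(pam.labels[i]) + 1
        profile_assignment.append(
            {
                "profile": profiles.profile(i),
                "cluster": cluster,
                "weight": float(profiles.weights[i]),
            }
        )
        for hid in profiles.members[i]:
            assignment[hid] = cluster
    model = ClusterModel(
        asset_names=list(assets),
        levels={v: list(table.levels[v]) for v in assets},
        k=k,
        medoids=medoids,
        assignment=assignment,
        profile_assignment=profile_assignment,
        asw=sil.asw,
        config=config,
        provenance=provenance or table.fingerprint(),
    )
    model.validate()
    return model


def search(table: HouseholdTable, config: SearchConfig) -> SearchResult:
    """Run the full exhaustive search and return scores plus the fitted model.

    Households are complete-case filtered once over the whole eligible
    candidate set (so every candidate is scored on the same population),
    profiles and dissimilarities are computed once per subset, and the
    winning candidate is refitted into a full :class:`ClusterModel`.
    """
    forced = _resolve_forced(table, config)
    eligible = eligible_variables(table, config.min_prevalence, forced)
    cc_table, cc_report = complete_case_filter(table, eligible)
    provenance = table.fingerprint()
    provenance["n_complete_cases"] = cc_report.n_retained

    scores: list[CandidateScore] = []
    lo, hi = config.k_range
    current_subset: tuple[str, ...] | None = None
    profiles = None
    d = None
    for assets, k in enumerate_candidates(eligible, config, forced):
        if assets != current_subset:
            current_subset = assets
            profiles = aggregate_profiles(cc_table, assets)
            d = gower_matrix(profiles) if profiles.n_profiles >= 2 else None
        score = _score_from_profiles(profiles, assets, k, d)
        if not score.feasible:
            log.info("candidate %s k=%d infeasible (%d profiles)",
                     "+".join(assets), k, score.n_profiles)
        scores.append(score)

    chosen, warnings = select_model(scores, config)
    model = build_model(cc_table, chosen.assets, chosen.k, config, provenance)
    return SearchResult(
        scores=scores,
        selected=model,
        selection_rule=config.mode,
        warnings=warnings,
        complete_case=cc_report,
    )
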