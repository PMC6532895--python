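"""Profile aggregation and Gower dissimilarity on categorical asset answers.

Households answering a handful of categorical questions collapse onto a
small number of distinct answer *profiles* (bounded by the product of the
level-set sizes), so all clustering runs at the profile level with the
summed survey weights as case weights.  The contract is exact equivalence
with household-level computation with duplicate rows collapsed — tested,
not assumed.

For purely nominal variables Gower's coefficient reduces to simple
matching: the dissimilarity between two profiles is the fraction of
variables on which they disagree, so every entry lies on the grid
``{0, 1/m, ..., 1}`` for ``m`` variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import EconClustersError, HouseholdTable


@dataclass
class ProfileTable:
    """Distinct asset-answer profiles with aggregated weights.

    ``codes`` holds one row per profile, with each variable encoded as the
    index of its level in the declared level order; rows are sorted
    lexicographically, which makes profile order deterministic.
    """

    variables: list[str]
    levels: dict[str, list[str]]
    codes: np.ndarray          # (n_profiles, n_variables) int
    weights: np.ndarray        # (n_profiles,) float, summed household weights
    members: list[list[str]]   # household ids per profile

    @property
    def n_profiles(self) -> int:
        return len(self.codes)

    def profile(self, i: int) -> dict[str, str]:
        """Decode profile ``i`` back to a {variable: level} dict."""
        return {
            v: self.levels[v][c] for v, c in zip(self.variables, self.codes[i])
        }

    def profiles(self) -> list[dict[str, str]]:
        return [self.profile(i) for i in range(self.n_profiles)]


def encode_variables(table: HouseholdTable, variables: Sequence[str]) -> np.ndarray:
    """Encode the selected variables as level indices; -1 marks missing."""
    cols = []
    for v in variables:
        if v not in table.levels:
            raise EconClustersError(f"unknown variable {v!r}")
        cat = pd.Categorical(table.data[v], categories=table.levels[v])
        cols.append(cat.codes)
    return np.column_stack(cols).astype(np.int64)


def aggregate_profiles(table: HouseholdTable, variables: Sequence[str]) -> ProfileTable:
    """Collapse households into distinct answer profiles over ``variables``.

    Requires the table to be complete on ``variables``; weights are summed
    per profile and member household-id lists are preserved.
    """
    if table.n_households == 0:
        raise EconClustersError("cannot aggregate an empty table")
    variables = list(variables)
    codes = encode_variables(table, variables)
    if (codes < 0).any():
        bad = [variables[j] for j in np.unique(np.nonzero(codes < 0)[1])]
        raise EconClustersError(
            f"table has missing values on {bad}; run complete_case_filter first"
        )
    uniq, inverse = np.unique(codes, axis=0, return_inverse=True)
    weights = np.bincount(inverse, weights=table.weights, minlength=len(uniq))
    ids = table.data.index.astype(str).to_numpy()
    members: list[list[str]] = [[] for _ in range(len(uniq))]
    for hid, g in zip(ids, inverse):
        members[g].append(hid)
    return ProfileTable(
        variables=variables,
        levels={v: list(table.levels[v]) for v in variables},
        codes=uniq,
        weights=weights.astype(float),
        members=members,
    )


def gower_matrix(profiles: ProfileTable) -> np.ndarray:
    """Pairwise Gower (simple-matching) dissimilarity between profiles.

    ``d(i, j)`` is the proportion of variables on which profiles i and j
    give different answers: symmetric, zero diagonal, entries in [0, 1].
    """
    if profiles.n_profiles < 2:
        raise EconClustersError("need at least two profiles for a dissimilarity matrix")
    codes = profiles.codes
    d = (codes[:, None, :] != codes[None, :, :]).mean(axis=2)
    return np.ascontiguousarray(d, dtype=float)


def matrix_to_csv(d: np.ndarray, path) -> None:
    """Debug dump of a dissimilarity matrix."""
    pd.DataFrame(d).to_csv(path, index=False)
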