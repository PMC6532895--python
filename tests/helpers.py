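"""Shared builders and independent oracles used across the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from econclusters import HouseholdTable


def build_table(
    columns: dict[str, list],
    levels: dict[str, list[str]],
    weights=None,
    ids=None,
    setting: str = "setting",
    stratum=None,
    psu=None,
) -> HouseholdTable:
    """Construct a validated HouseholdTable from plain lists.

    ``columns`` maps every variable in ``levels`` to its values (None for
    missing).  Weights default to 1.
    """
    n = len(next(iter(columns.values())))
    if ids is None:
        ids = [f"H{i:03d}" for i in range(1, n + 1)]
    data = pd.DataFrame(index=pd.Index(ids, name="household_id"))
    data["weight"] = np.asarray(weights if weights is not None else np.ones(n), dtype=float)
    for var in levels:
        data[var] = pd.array(
            [None if v is None else str(v) for v in columns[var]], dtype="string"
        )
    stratum_col = psu_col = None
    if stratum is not None:
        data["stratum"] = stratum
        stratum_col = "stratum"
    if psu is not None:
        data["psu"] = psu
        psu_col = "psu"
    table = HouseholdTable(
        data=data, levels={k: list(v) for k, v in levels.items()},
        setting=setting, stratum=stratum_col, psu=psu_col,
    )
    table.validate()
    return table


def full_grid_table(level_sizes=(2, 2, 2, 3, 3), weights=None) -> HouseholdTable:
    """One household per combination of the given categorical level grid."""
    names = [f"v{i}" for i in range(len(level_sizes))]
    levels = {"setting": ["rural", "urban"]}
    levels.update({n: [f"L{j}" for j in range(s)] for n, s in zip(names, level_sizes)})
    combos = list(itertools.product(*[levels[n] for n in names]))
    columns = {"setting": ["rural"] * len(combos)}
    for j, n in enumerate(names):
        columns[n] = [c[j] for c in combos]
    return build_table(columns, levels, weights=weights)


def brute_force_pam_cost(d: np.ndarray, w: np.ndarray, k: int) -> float:
    """Global optimum of the weighted k-medoids cost by exhaustive enumeration."""
    n = d.shape[0]
    best = np.inf
    for subset in itertools.combinations(range(n), k):
        cost = float(w @ d[:, subset].min(axis=1))
        best = min(best, cost)
    return best


def naive_silhouette(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Textbook unweighted silhouette widths, computed with plain loops."""
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own <= 1:
            continue
        a = d[i, own].sum() / (n_own - 1)
        b = min(
            d[i, labels == c].mean()
            for c in np.unique(labels)
            if c != labels[i]
        )
        if max(a, b) > 0:
            s[i] = (b - a) / max(a, b)
    return s


def naive_agglomerative(X: np.ndarray, method: str = "complete"):
    """Independent bottom-up agglomerative clustering on Euclidean points.

    Returns the merge sequence as a list of ``(frozenset_a, frozenset_b,
    height)`` tuples, merging the closest active pair at each step under
    complete or average linkage.
    """
    n = len(X)
    pair_d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    active = {i: frozenset([i]) for i in range(n)}
    merges = []
    while len(active) > 1:
        best = None
        keys = sorted(active)
        for ai, bi in itertools.combinations(keys, 2):
            pairs = [(x, y) for x in active[ai] for y in active[bi]]
            dist = [pair_d[x, y] for x, y in pairs]
            h = max(dist) if method == "complete" else float(np.mean(dist))
            if best is None or h < best[0]:
                best = (h, ai, bi)
        h, ai, bi = best
        merges.append((active[ai], active[bi], h))
        active[ai] = active[ai] | active[bi]
        del active[bi]
    return merges
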