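"""Condensing clusters into ranked economic groups and validating them.

A fitted model may contain more clusters than are practical for policy
work.  This module (1) summarizes each cluster by the survey-weighted means
of three wealth-graded outcomes — child height-for-age Z-score (HAZ),
women's 0-2 literacy score, and the proportion of a woman's children who
are deceased — (2) condenses clusters by agglomerative hierarchical
clustering of the standardized outcome means, run separately for rural and
urban clusters (wealth manifests as different assets in the two settings),
(3) ordinally ranks the resulting groups, and (4) computes the disparity
statistics used to compare groupings: survey-weighted one-way ANOVA
(a design-based Wald test on group means), eta squared from weighted sums
of squares, and adjacent-group two-sample t-tests with unequal variances.

Standard errors are Taylor-linearized design-based estimates when stratum
and PSU columns are available (with-replacement PSU approximation) and
precision-weight estimates otherwise; with equal weights and no design
columns they reduce to the classical s/sqrt(n).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist

from .core_data import ChildTable, EconClustersError, HouseholdTable, WomanTable

OUTCOMES = ("haz", "literacy", "deceased")


# ---------------------------------------------------------------------------
# survey-weighted means, SEs, and test statistics


def survey_mean_se(
    y: np.ndarray,
    w: np.ndarray,
    stratum: np.ndarray | None = None,
    psu: np.ndarray | None = None,
) -> tuple[float, float, int]:
    """Weighted mean with a design-based (linearized) standard error.

    Each observation is its own PSU when no PSU column is given; strata
    with a single PSU contribute no variance (with a warning-free grand
    mean centering, the usual with-replacement approximation).
    Returns ``(mean, se, n)``.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    n = len(y)
    if n == 0:
        return np.nan, np.nan, 0
    W = w.sum()
    mean = float((w * y).sum() / W)
    if n == 1:
        return mean, 0.0, 1
    # linearized scores
    z = w * (y - mean) / W
    if psu is None:
        psu = np.arange(n)
    if stratum is None:
        stratum = np.zeros(n)
    frame = pd.DataFrame({"z": z, "stratum": stratum, "psu": psu})
    totals = frame.groupby(["stratum", "psu"], sort=True)["z"].sum()
    var = 0.0
    for _, t in totals.groupby(level="stratum"):
        n_h = len(t)
        if n_h < 2:
            continue
        var += n_h / (n_h - 1) * float(((t - t.mean()) ** 2).sum())
    return mean, float(np.sqrt(var)), n


def _design_df(stratum, psu, n: int) -> float:
    """Degrees of freedom: PSUs minus strata under a design, else n - 1."""
    if psu is None:
        return n - 1
    frame = pd.DataFrame(
        {
            "stratum": stratum if stratum is not None else np.zeros(n),
            "psu": psu,
        }
    )
    n_psu = len(frame.drop_duplicates())
    n_strata = frame["stratum"].nunique()
    return max(n_psu - n_strata, 1)


def eta_squared(y: np.ndarray, w: np.ndarray, groups: np.ndarray) -> float:
    """Weighted between-group sum of squares over weighted total sum of squares."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    groups = np.asarray(groups)
    grand = (w * y).sum() / w.sum()
    tss = float((w * (y - grand) ** 2).sum())
    if tss == 0:
        return 0.0
    bss = 0.0
    for g in np.unique(groups):
        m = groups == g
        W_g = w[m].sum()
        mean_g = (w[m] * y[m]).sum() / W_g
        bss += W_g * (mean_g - grand) ** 2
    return float(bss / tss)


@dataclass
class OutcomeValidation:
    outcome: str
    groups: pd.DataFrame          # index: group; columns mean, se, n
    anova_f: float
    anova_df: tuple[float, float]
    anova_p: float
    eta_squared: float
    adjacent: pd.DataFrame        # adjacent-pair t-tests


@dataclass
class ValidationReport:
    """Per grouping variable: ANOVA, eta squared, and adjacent-pair t-tests."""

    outcomes: dict[str, OutcomeValidation] = field(default_factory=dict)


def _sig_stars(p: float) -> str:
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def weighted_ttest(
    mean1: float, se1: float, n1: int, mean2: float, se2: float, n2: int
) -> tuple[float, float, float]:
    """Welch-style two-sample t-test on design-based means and SEs."""
    v1, v2 = se1**2, se2**2
    se = np.sqrt(v1 + v2)
    if se == 0:
        return np.nan, np.nan, np.nan
    t = (mean1 - mean2) / se
    df = (v1 + v2) ** 2 / (
        (v1**2 / max(n1 - 1, 1)) + (v2**2 / max(n2 - 1, 1)) + 1e-300
    )
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def validation_stats(
    groups: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    stratum: np.ndarray | None = None,
    psu: np.ndarray | None = None,
    order: Sequence | None = None,
    outcome: str = "outcome",
) -> OutcomeValidation:
    """Disparity statistics of one outcome across a grouping.

    The ANOVA is a design-based Wald test of equal group means: with
    independent design-based mean variances ``v_g``, the statistic is the
    quadratic form of the G-1 mean contrasts, divided by G-1 and referred
    to an F distribution with design degrees of freedom.  ``order`` fixes
    which group pairs count as adjacent for the pairwise t-tests (defaults
    to sorted group labels).
    """
    groups = np.asarray(groups)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    labels = list(order) if order is not None else sorted(pd.unique(groups).tolist())
    stats_rows = {}
    for g in labels:
        m = groups == g
        sub_str = stratum[m] if stratum is not None else None
        sub_psu = psu[m] if psu is not None else None
        mean, se, n = survey_mean_se(y[m], w[m], sub_str, sub_psu)
        stats_rows[g] = {"mean": mean, "se": se, "n": n}
    gframe = pd.DataFrame(stats_rows).T

    usable = gframe[(gframe["n"] >= 2) & (gframe["se"] > 0)]
    if len(usable) < 2:
        raise EconClustersError("need at least two groups with >=2 observations")
    if len(usable) < len(gframe):
        _warnings.warn(
            f"degenerate groups excluded from the Wald test: "
            f"{sorted(set(gframe.index) - set(usable.index))}"
        )

    means = usable["mean"].to_numpy()
    variances = usable["se"].to_numpy() ** 2
    G = len(means)
    contrasts = means[:-1] - means[-1]
    # covariance of contrasts for independent group means
    V = np.diag(variances[:-1]) + variances[-1]
    wald = float(contrasts @ np.linalg.solve(V, contrasts))
    df1 = G - 1
    df2 = _design_df(stratum, psu, len(y)) - df1 + 1
    df2 = max(df2, 1)
    f_stat = wald / df1
    p = float(sps.f.sf(f_stat, df1, df2))

    pairs = []
    for a, b in zip(labels[:-1], labels[1:]):
        ra, rb = gframe.loc[a], gframe.loc[b]
        if ra["n"] < 2 or rb["n"] < 2 or (ra["se"] == 0 and rb["se"] == 0):
            _warnings.warn(f"adjacent pair ({a}, {b}) skipped: degenerate group")
            continue
        t, df, pv = weighted_ttest(ra["mean"], ra["se"], int(ra["n"]),
                                   rb["mean"], rb["se"], int(rb["n"]))
        pairs.append({"group_a": a, "group_b": b, "t": t, "df": df,
                      "p": pv, "sig": _sig_stars(pv)})
    return OutcomeValidation(
        outcome=outcome,
        groups=gframe,
        anova_f=f_stat,
        anova_df=(float(df1), float(df2)),
        anova_p=p,
        eta_squared=eta_squared(y, w, groups),
        adjacent=pd.DataFrame(pairs, columns=["group_a", "group_b", "t", "df", "p", "sig"]),
    )


# ---------------------------------------------------------------------------
# outcome summaries per cluster / group


def _linked_outcomes(
    labels: pd.Series,
    households: HouseholdTable,
    children: ChildTable | None,
    women: WomanTable | None,
) -> dict[str, pd.DataFrame]:
    """Individual-level outcome frames with group labels and design columns."""
    lab = labels.copy()
    lab.index = lab.index.astype(str)
    design = pd.DataFrame(index=households.data.index.astype(str))
    design["stratum"] = (
        households.data[households.stratum].to_numpy() if households.stratum else None
    )
    design["psu"] = (
        households.data[households.psu].to_numpy() if households.psu else None
    )
    out: dict[str, pd.DataFrame] = {}

    def link(frame: pd.DataFrame, value_col: str) -> pd.DataFrame:
        f = frame.copy()
        f["household_id"] = f["household_id"].astype(str)
        f["group"] = f["household_id"].map(lab)
        f = f[f["group"].notna()]
        f["stratum"] = f["household_id"].map(design["stratum"])
        f["psu"] = f["household_id"].map(design["psu"])
        return f[["group", value_col, "weight", "stratum", "psu"]].rename(
            columns={value_col: "y"}
        )

    if children is not None:
        out["haz"] = link(children.data, "haz")
    if women is not None:
        wd = women.data
        out["literacy"] = link(wd.assign(literacy=wd["literacy"].astype(float)), "literacy")
        mort = wd[wd["children_ever_born"] > 0].copy()
        mort["deceased"] = (
            mort["sons_died"] + mort["daughters_died"]
        ) / mort["children_ever_born"]
        out["deceased"] = link(mort, "deceased")
    return out


def deceased_proportion(sons_died: int, daughters_died: int, children_ever_born: int) -> float:
    """Proportion of a woman's children who are deceased; undefined at 0 born."""
    if children_ever_born <= 0:
        raise EconClustersError("woman with zero children ever born is excluded")
    return (sons_died + daughters_died) / children_ever_born


def outcome_summary(
    labels: pd.Series,
    households: HouseholdTable,
    children: ChildTable | None = None,
    women: WomanTable | None = None,
) -> pd.DataFrame:
    """Per-group weighted outcome means, SEs and counts, plus majority setting.

    ``labels`` maps household id to a cluster index or group label.  Women
    with zero children ever born are excluded from the deceased-children
    outcome; a group without linked individuals for an outcome gets an
    undefined (NaN) mean with a warning.
    """
    lab = labels.copy()
    lab.index = lab.index.astype(str)
    groups = sorted(pd.unique(lab.dropna()).tolist())
    linked = _linked_outcomes(lab, households, children, women)

    rows = {}
    hh = households.data
    hh_groups = pd.Series(hh.index.astype(str), index=hh.index).map(lab)
    for g in groups:
        row: dict[str, float] = {}
        m = (hh_groups == g).to_numpy()
        setting_w = (
            pd.Series(households.weights[m]).groupby(
                pd.Series(hh[households.setting].to_numpy()[m])
            ).sum()
        )
        row["setting"] = setting_w.idxmax() if len(setting_w) else np.nan
        for name in OUTCOMES:
            if name not in linked:
                continue
            sub = linked[name][linked[name]["group"] == g]
            if len(sub) == 0:
                _warnings.warn(f"group {g!r}: no individuals for outcome {name!r}")
                row[f"{name}_mean"] = np.nan
                row[f"{name}_se"] = np.nan
                row[f"{name}_n"] = 0
                continue
            stratum = sub["stratum"].to_numpy() if sub["stratum"].notna().any() else None
            psu = sub["psu"].to_numpy() if sub["psu"].notna().any() else None
            mean, se, n = survey_mean_se(
                sub["y"].to_numpy(), sub["weight"].to_numpy(), stratum, psu
            )
            row[f"{name}_mean"] = mean
            row[f"{name}_se"] = se
            row[f"{name}_n"] = n
        rows[g] = row
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# agglomerative condensation


@dataclass
class CondensedModel:
    """Mapping of original clusters to condensed, rankable groups."""

    mapping: dict                              # original cluster -> group label
    linkages: dict[str, np.ndarray]            # stratum -> scipy linkage matrix
    leaf_order: dict[str, list]                # stratum -> clusters in matrix order
    cut_height: float
    warnings: list[str] = field(default_factory=list)

    def groups(self) -> list:
        return sorted(set(self.mapping.values()))

    def merge_list(self) -> dict:
        """JSON-friendly dendrogram description (leaves + merge steps)."""
        out = {}
        for stratum, Z in self.linkages.items():
            out[stratum] = {
                "leaves": [str(c) for c in self.leaf_order[stratum]],
                "merges": [
                    {"left": int(a), "right": int(b), "height": float(h), "size": int(s)}
                    for a, b, h, s in Z
                ] if Z is not None else [],
            }
        return out

    def newick(self) -> dict[str, str]:
        out = {}
        for stratum, Z in self.linkages.items():
            leaves = [str(c) for c in self.leaf_order[stratum]]
            if Z is None:
                out[stratum] = f"({leaves[0]});" if len(leaves) == 1 else "();"
                continue
            tree = to_tree(Z)

            def render(node) -> str:
                if node.is_leaf():
                    return leaves[node.id]
                left, right = node.left, node.right
                return (
                    f"({render(left)}:{node.dist - left.dist:.6g},"
                    f"{render(right)}:{node.dist - right.dist:.6g})"
                )

            out[stratum] = render(tree) + ";"
        return out


def scale_outcome_means(frame: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Standardize cluster outcome means to zero mean, unit sd per column.

    The objects being clustered are the cluster means themselves, so the
    standardization is unweighted across clusters (sd with one delta
    degree of freedom, matching the conventional ``scale`` behaviour).
    Zero-variance columns are dropped with a note.
    """
    cols = [f"{o}_mean" for o in OUTCOMES]
    X = frame[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise EconClustersError("all three outcome means must be defined per cluster")
    sd = X.std(axis=0, ddof=1) if len(X) > 1 else np.ones(X.shape[1])
    keep = sd > 0
    dropped = [cols[j] for j in np.flatnonzero(~keep)]
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return X, dropped


def condense_clusters(
    summary: pd.DataFrame,
    target_groups: tuple[int, int] = (5, 10),
    method: str = "complete",
    force_separate: Sequence[Sequence] = (),
) -> CondensedModel:
    """Merge clusters into broad economic groups, separately per setting.

    Within each setting stratum the three outcome means are standardized
    across that stratum's clusters, Euclidean distances are computed on the
    scaled vectors, and agglomerative clustering (default complete linkage)
    builds a dendrogram.  Both dendrograms are cut at the greatest common
    height whose total group count across strata falls in
    ``target_groups``; a stratum with a single cluster passes through
    uncut.  ``force_separate`` lists sets of clusters to keep apart from
    all clusters outside the set, applied after the cut.
    """
    lo, hi = target_groups
    if lo < 1 or hi < lo:
        raise EconClustersError(f"invalid target_groups {target_groups}")
    warnings_list: list[str] = []
    strata = sorted(pd.unique(summary["setting"]).tolist())
    linkages: dict[str, np.ndarray] = {}
    leaf_order: dict[str, list] = {}
    for stratum in strata:
        sub = summary[summary["setting"] == stratum]
        leaf_order[stratum] = list(sub.index)
        if len(sub) == 1:
            linkages[stratum] = None
            continue
        X, dropped = scale_outcome_means(sub)
        if dropped:
            warnings_list.append(
                f"stratum {stratum!r}: zero-variance outcomes dropped from scaling: {dropped}"
            )
        linkages[stratum] = linkage(pdist(X), method=method)

    heights = sorted(
        {float(h) for Z in linkages.values() if Z is not None for h in Z[:, 2]},
        reverse=True,
    )

    def cut_at(t: float) -> dict:
        mapping = {}
        for stratum in strata:
            leaves = leaf_order[stratum]
            Z = linkages[stratum]
            if Z is None:
                mapping[leaves[0]] = f"{stratum}-1"
                continue
            labs = fcluster(Z, t=t, criterion="distance")
            for cluster, g in zip(leaves, labs):
                mapping[cluster] = f"{stratum}-{int(g)}"
        return mapping

    chosen_t = None
    n_single = sum(1 for Z in linkages.values() if Z is None)
    candidates = [heights[0] + 1.0] if heights else [0.0]
    candidates += [h - 1e-9 for h in heights]
    for t in candidates:
        total = len(set(cut_at(t).values()))
        if total >= lo:
            chosen_t = t
            if total > hi:
                warnings_list.append(
                    f"smallest achievable total group count {total} exceeds "
                    f"target range {target_groups}"
                )
            break
    if chosen_t is None:  # even cutting every merge stays below lo
        chosen_t = -1.0
        warnings_list.append(
            f"maximum total group count below target minimum {lo}; "
            "every cluster kept separate"
        )
    mapping = cut_at(chosen_t)

    for fs in force_separate:
        fs = set(fs)
        group_of = {}
        for cluster, g in mapping.items():
            group_of.setdefault(g, set()).add(cluster)
        for g, members in group_of.items():
            inside = members & fs
            if inside and members - fs:
                for cluster in inside:
                    mapping[cluster] = f"{g}s"
                warnings_list.append(
                    f"force_separate split group {g}: {sorted(inside)} set apart"
                )

    return CondensedModel(
        mapping=mapping,
        linkages=linkages,
        leaf_order=leaf_order,
        cut_height=float(chosen_t),
        warnings=warnings_list,
    )


# ---------------------------------------------------------------------------
# ordinal ranking


def rank_groups(summary: pd.DataFrame) -> tuple[pd.DataFrame, list[dict]]:
    """Ordinally rank condensed groups within each setting stratum.

    The primary key is mean women's literacy ascending (rank 1 = poorest);
    for each adjacent pair the two corroborating indicators — HAZ ascending
    and deceased-children proportion descending — are checked and any
    disagreement is recorded as a conflict rather than silently resolved.
    Exact literacy ties break by HAZ, then by deceased proportion, and are
    flagged.
    """
    conflicts: list[dict] = []
    ranked = summary.copy()
    ranked["rank"] = 0
    for stratum in sorted(pd.unique(summary["setting"]).tolist()):
        sub = summary[summary["setting"] == stratum]
        order = sub.sort_values(
            ["literacy_mean", "haz_mean", "deceased_mean"],
            ascending=[True, True, False],
            kind="mergesort",
        ).index.tolist()
        for r, g in enumerate(order, start=1):
            ranked.loc[g, "rank"] = r
        for a, b in zip(order[:-1], order[1:]):
            if summary.loc[a, "literacy_mean"] == summary.loc[b, "literacy_mean"]:
                conflicts.append(
                    {"stratum": stratum, "groups": (a, b), "indicator": "literacy_tie"}
                )
            if not summary.loc[a, "haz_mean"] <= summary.loc[b, "haz_mean"]:
                conflicts.append(
                    {"stratum": stratum, "groups": (a, b), "indicator": "haz"}
                )
            if not summary.loc[a, "deceased_mean"] >= summary.loc[b, "deceased_mean"]:
                conflicts.append(
                    {"stratum": stratum, "groups": (a, b), "indicator": "deceased"}
                )
    return ranked, conflicts


def validate_grouping(
    labels: pd.Series,
    households: HouseholdTable,
    children: ChildTable | None = None,
    women: WomanTable | None = None,
    order: Sequence | None = None,
) -> ValidationReport:
    """Full validation report (ANOVA, eta squared, adjacent t-tests) for a
    household grouping against the three wealth-graded outcomes."""
    lab = labels.copy()
    lab.index = lab.index.astype(str)
    linked = _linked_outcomes(lab, households, children, women)
    report = ValidationReport()
    for name, frame in linked.items():
        stratum = frame["stratum"].to_numpy() if frame["stratum"].notna().any() else None
        psu = frame["psu"].to_numpy() if frame["psu"].notna().any() else None
        report.outcomes[name] = validation_stats(
            frame["group"].to_numpy(),
            frame["y"].to_numpy(),
            frame["weight"].to_numpy(),
            stratum,
            psu,
            order=order,
            outcome=name,
        )
    return report
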