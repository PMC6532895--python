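"""Synthetic household surveys with planted economic groups.

The generator emulates the structure the clustering method assumes in a
DHS-style survey: a population partitioned into a few latent economic
groups, each with a characteristic asset-answer signature (binary
ownership items plus multi-level items such as cooking fuel and home
financing), positive survey weights, uninformative "noise" assets, and
group-graded outcome distributions (child HAZ, women's literacy, child
deaths).  Asset answers equal the group signature except for independent
per-variable corruption to a random other level; the rural/urban setting
is a fixed attribute of each group and is never corrupted.

Everything is reproducible from the spec's single seed.  Outcome effects
are attached at the group level — the construct the method measures — with
no household-level confounding; this is a deliberate limitation of the
fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_data import (
    ChildTable,
    ClusterModel,
    EconClustersError,
    HouseholdTable,
    WomanTable,
)

#: default informative asset variables, mirroring common DHS wealth items
DEFAULT_ASSET_LEVELS: dict[str, list[str]] = {
    "agricultural_land": ["no", "yes"],
    "cellphone": ["no", "yes"],
    "radio": ["no", "yes"],
    "cooking_fuel": ["wood", "charcoal", "LPG"],
    "home_financing": ["own", "rent", "free"],
}


@dataclass(frozen=True)
class GroupSpec:
    """One planted economic group.

    ``signature`` fixes the modal answer to every informative asset;
    ``corruption_rate`` is the per-variable probability that a household's
    answer is flipped to a uniformly random other level.  Outcome
    parameters encode the group's position on the wealth gradient.
    """

    name: str
    share: float
    setting: str                       # "rural" | "urban"
    signature: Mapping[str, str]
    corruption_rate: float = 0.0
    haz_mean: float = -1.0
    haz_sd: float = 1.1
    literacy_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    death_prob: float = 0.05


@dataclass(frozen=True)
class SimSpec:
    """Full description of a synthetic survey population."""

    n_households: int
    groups: tuple[GroupSpec, ...]
    asset_levels: Mapping[str, Sequence[str]]
    n_noise_assets: int = 5
    weight_distribution: str = "lognormal"   # "constant" | "lognormal"
    weight_sigma: float = 0.5
    mean_children_under5: float = 0.8
    mean_children_ever_born: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_households < 1:
            raise EconClustersError("n_households must be positive")
        shares = [g.share for g in self.groups]
        if not np.isclose(sum(shares), 1.0):
            raise EconClustersError(f"group shares must sum to 1, got {sum(shares)}")
        if any(not (0 < s < 1) for s in shares):
            raise EconClustersError("each group share must lie in (0, 1)")
        if self.weight_distribution not in ("constant", "lognormal"):
            raise EconClustersError(
                f"unknown weight_distribution {self.weight_distribution!r}"
            )
        for g in self.groups:
            if g.setting not in ("rural", "urban"):
                raise EconClustersError(f"group {g.name}: setting must be rural/urban")
            if not (0 <= g.corruption_rate < 1):
                raise EconClustersError(f"group {g.name}: bad corruption rate")
            if not np.isclose(sum(g.literacy_probs), 1.0):
                raise EconClustersError(f"group {g.name}: literacy probs must sum to 1")
            if not (0 <= g.death_prob <= 1):
                raise EconClustersError(f"group {g.name}: bad death probability")
            for var, level in g.signature.items():
                if var not in self.asset_levels:
                    raise EconClustersError(f"group {g.name}: unknown asset {var!r}")
                if level not in self.asset_levels[var]:
                    raise EconClustersError(
                        f"group {g.name}: level {level!r} not in {var!r} levels"
                    )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["groups"] = [asdict(g) | {"signature": dict(g.signature),
                                    "literacy_probs": list(g.literacy_probs)}
                       for g in self.groups]
        d["asset_levels"] = {k: list(v) for k, v in self.asset_levels.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def default_spec(
    n_households: int = 5000,
    corruption: float = 0.02,
    n_noise_assets: int = 5,
    seed: int = 0,
) -> SimSpec:
    """The canonical four-group study population.

    Two rural and two urban groups with pairwise well-separated signatures
    (every pair disagrees on at least three of the five informative assets)
    and a monotone wealth gradient within each setting: within rural and
    within urban, the poorer group has lower mean child HAZ, lower literacy,
    and a higher proportion of deceased children.
    """
    groups = (
        GroupSpec(
            name="rural_poor", share=0.30, setting="rural",
            signature={"agricultural_land": "yes", "cellphone": "no",
                       "radio": "no", "cooking_fuel": "wood",
                       "home_financing": "own"},
            corruption_rate=corruption,
            haz_mean=-1.8, literacy_probs=(0.70, 0.20, 0.10), death_prob=0.15,
        ),
        GroupSpec(
            name="rural_wealthy", share=0.25, setting="rural",
            signature={"agricultural_land": "yes", "cellphone": "yes",
                       "radio": "yes", "cooking_fuel": "charcoal",
                       "home_financing": "own"},
            corruption_rate=corruption,
            haz_mean=-1.2, literacy_probs=(0.45, 0.30, 0.25), death_prob=0.10,
        ),
        GroupSpec(
            name="urban_poor", share=0.25, setting="urban",
            signature={"agricultural_land": "no", "cellphone": "no",
                       "radio": "yes", "cooking_fuel": "charcoal",
                       "home_financing": "rent"},
            corruption_rate=corruption,
            haz_mean=-0.8, literacy_probs=(0.30, 0.30, 0.40), death_prob=0.06,
        ),
        GroupSpec(
            name="urban_wealthy", share=0.20, setting="urban",
            signature={"agricultural_land": "no", "cellphone": "yes",
                       "radio": "no", "cooking_fuel": "LPG",
                       "home_financing": "rent"},
            corruption_rate=corruption,
            haz_mean=-0.2, literacy_probs=(0.10, 0.20, 0.70), death_prob=0.03,
        ),
    )
    return SimSpec(
        n_households=n_households,
        groups=groups,
        asset_levels=dict(DEFAULT_ASSET_LEVELS),
        n_noise_assets=n_noise_assets,
        seed=seed,
    )


@dataclass
class SimulatedSurvey:
    households: HouseholdTable
    children: ChildTable
    women: WomanTable
    labels: pd.Series          # household id -> planted group name
    spec: SimSpec


def _noise_levels(j: int) -> list[str]:
    # alternate binary and three-level noise assets
    return ["no", "yes"] if j % 2 == 0 else ["low", "mid", "high"]


def _noise_probs(j: int) -> np.ndarray:
    if j % 2 == 0:
        p = [0.55, 0.45] if j % 4 == 0 else [0.7, 0.3]
    else:
        p = [0.5, 0.3, 0.2]
    return np.array(p)


def simulate_survey(spec: SimSpec) -> SimulatedSurvey:
    """Draw a complete survey (households, children, women, planted labels)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_households
    shares = np.array([g.share for g in spec.groups])
    gidx = rng.choice(len(spec.groups), size=n, p=shares)
    ids = np.array([f"H{i:06d}" for i in range(1, n + 1)])

    if spec.weight_distribution == "constant":
        weights = np.ones(n)
    else:
        weights = rng.lognormal(mean=0.0, sigma=spec.weight_sigma, size=n)
        weights /= weights.mean()

    levels = {"setting": ["rural", "urban"]}
    levels.update({k: list(v) for k, v in spec.asset_levels.items()})
    data = pd.DataFrame(index=pd.Index(ids, name="household_id"))
    data["weight"] = weights
    data["setting"] = pd.array(
        [spec.groups[g].setting for g in gidx], dtype="string"
    )

    for var, lv in spec.asset_levels.items():
        lv = list(lv)
        codes = np.array(
            [lv.index(spec.groups[g].signature[var]) for g in gidx]
        )
        corrupt = rng.random(n) < np.array([spec.groups[g].corruption_rate for g in gidx])
        if corrupt.any():
            shift = rng.integers(1, len(lv), size=int(corrupt.sum()))
            codes[corrupt] = (codes[corrupt] + shift) % len(lv)
        data[var] = pd.array([lv[c] for c in codes], dtype="string")

    for j in range(spec.n_noise_assets):
        lv = _noise_levels(j)
        name = f"noise_{j + 1}"
        levels[name] = lv
        codes = rng.choice(len(lv), size=n, p=_noise_probs(j))
        data[name] = pd.array([lv[c] for c in codes], dtype="string")

    households = HouseholdTable(data=data, levels=levels, setting="setting")
    households.validate()

    # children under five with HAZ
    n_children = rng.poisson(spec.mean_children_under5, size=n)
    child_rows = []
    for hid, g, w, m in zip(ids, gidx, weights, n_children):
        gs = spec.groups[g]
        for _ in range(m):
            child_rows.append((hid, w, rng.normal(gs.haz_mean, gs.haz_sd)))
    children = ChildTable(
        data=pd.DataFrame(child_rows, columns=["household_id", "weight", "haz"])
    )

    # one woman per household
    lit = np.empty(n, dtype=int)
    cbe = rng.poisson(spec.mean_children_ever_born, size=n)
    deaths = np.empty(n, dtype=int)
    for g in range(len(spec.groups)):
        m = gidx == g
        gs = spec.groups[g]
        lit[m] = rng.choice(3, size=int(m.sum()), p=np.array(gs.literacy_probs))
        deaths[m] = rng.binomial(cbe[m], gs.death_prob)
    sons = rng.binomial(deaths, 0.5)
    women = WomanTable(
        data=pd.DataFrame(
            {
                "household_id": ids,
                "weight": weights,
                "literacy": lit,
                "sons_died": sons,
                "daughters_died": deaths - sons,
                "children_ever_born": cbe,
            }
        )
    )

    labels = pd.Series(
        [spec.groups[g].name for g in gidx], index=pd.Index(ids, name="household_id")
    )
    return SimulatedSurvey(households, children, women, labels, spec)


def recovery_metrics(
    planted: pd.Series, model: ClusterModel
) -> tuple[float, pd.DataFrame]:
    """Adjusted Rand index and confusion table between planted groups and a
    fitted model's assignment (over the households present in both)."""
    from sklearn.metrics import adjusted_rand_score

    planted = planted.copy()
    planted.index = planted.index.astype(str)
    common = [hid for hid in planted.index if hid in model.assignment]
    if not common:
        raise EconClustersError("planted labels and model assignment share no ids")
    truth = planted.loc[common].to_numpy()
    fitted = np.array([model.assignment[hid] for hid in common])
    ari = float(adjusted_rand_score(truth, fitted))
    confusion = pd.crosstab(
        pd.Series(truth, name="planted"), pd.Series(fitted, name="cluster")
    )
    return ari, confusion
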