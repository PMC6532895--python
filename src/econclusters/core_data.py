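"""Core data containers, validated CSV readers, and model serialization.

The package works on DHS-style household surveys: one row per household
carrying a survey weight (the inverse probability of household selection),
a rural/urban setting indicator, and a set of categorical asset questions
(binary ownership items such as "owns a cell phone", or multi-level items
such as cooking fuel with levels wood/charcoal/LPG).  Optional child- and
woman-level tables carry the outcome variables used for validation and
ranking: child height-for-age Z-score (HAZ), women's literacy on a 0-2
scale, and the counts needed to form each woman's proportion of deceased
children.

Design rules enforced here:

* Asset levels are case-sensitive strings declared up front in the column
  mapping; the readers never recode values silently.  A value outside the
  declared level set is an error that names the offending values and rows.
* Missing values (empty cells or the literal ``NA``) are explicit missing
  markers, never a level of their own.
* Model files are versioned JSON and store a fingerprint of the source
  table so that assignment against a mismatched reference table can warn.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

SCHEMA_VERSION = 1

#: cell values treated as explicit missing markers in input CSVs
MISSING_TOKENS = ("", "NA")


class EconClustersError(Exception):
    """Base class for all errors raised by this package."""


class TableValidationError(EconClustersError):
    """An input table violates a declared invariant (bad weight, level, ...)."""


class ModelSchemaError(EconClustersError):
    """A model file cannot be parsed or has an incompatible schema version."""


def _as_level(value) -> str:
    # YAML parses bare yes/no/true/false as booleans; coerce them back to the
    # conventional string levels instead of erroring on a common config slip.
    if isinstance(value, bool):
        return "yes" if value else "no"
    return str(value)


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from CSV columns to the survey schema.

    ``assets`` maps each asset variable name to its declared, ordered level
    set.  The declared order fixes the lexicographic ordering used for
    deterministic profile enumeration.  The rural/urban ``setting`` column is
    itself a two-level categorical variable and is treated as one more model
    variable (the one forced into every candidate subset by default).
    """

    household_id: str
    weight: str
    setting: str
    assets: Mapping[str, Sequence[str]]
    setting_levels: tuple[str, str] = ("rural", "urban")
    stratum: str | None = None
    psu: str | None = None

    def __post_init__(self):
        if len(set(self.setting_levels)) != 2:
            raise TableValidationError(
                "setting must have exactly two distinct levels, got "
                f"{self.setting_levels!r}"
            )
        for name, levels in self.assets.items():
            if len(levels) < 2:
                raise TableValidationError(
                    f"asset {name!r} declares fewer than two levels"
                )
            if len(set(levels)) != len(levels):
                raise TableValidationError(f"asset {name!r} declares duplicate levels")
        if self.setting in self.assets:
            raise TableValidationError(
                f"setting column {self.setting!r} also declared as an asset"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "ColumnMap":
        setting = d["setting"]
        if isinstance(setting, Mapping):
            setting_col = setting["column"]
            setting_levels = tuple(_as_level(v) for v in setting.get("levels", ("rural", "urban")))
        else:
            setting_col = setting
            setting_levels = ("rural", "urban")
        assets = {
            str(name): [_as_level(v) for v in levels]
            for name, levels in d["assets"].items()
        }
        return cls(
            household_id=d["household_id"],
            weight=d["weight"],
            setting=setting_col,
            assets=assets,
            setting_levels=setting_levels,  # type: ignore[arg-type]
            stratum=d.get("stratum"),
            psu=d.get("psu"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnMap":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = {
            "household_id": self.household_id,
            "weight": self.weight,
            "setting": {"column": self.setting, "levels": list(self.setting_levels)},
            "assets": {k: list(v) for k, v in self.assets.items()},
        }
        if self.stratum:
            d["stratum"] = self.stratum
        if self.psu:
            d["psu"] = self.psu
        return d


@dataclass
class HouseholdTable:
    """A validated household survey table.

    ``data`` is indexed by household id and holds a float ``weight`` column,
    optional ``stratum``/``psu`` columns, and one string column per model
    variable (the setting variable plus every asset), with ``pd.NA`` marking
    missing answers.  ``levels`` maps every model variable, including the
    setting, to its declared ordered level set.
    """

    data: pd.DataFrame
    levels: dict[str, list[str]]
    setting: str
    stratum: str | None = None
    psu: str | None = None

    @property
    def variables(self) -> list[str]:
        """All candidate model variables (setting first, then assets)."""
        return list(self.levels)

    @property
    def n_households(self) -> int:
        return len(self.data)

    @property
    def weights(self) -> np.ndarray:
        return self.data["weight"].to_numpy(dtype=float)

    def fingerprint(self) -> dict:
        """Row count plus a hash of the sorted household ids."""
        ids = sorted(str(i) for i in self.data.index)
        digest = hashlib.sha256("\n".join(ids).encode()).hexdigest()[:16]
        return {"n_households": len(ids), "id_hash": digest}

    def validate(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate household ids: {dupes[:5]}")
        w = self.data["weight"].to_numpy(dtype=float)
        bad = ~np.isfinite(w) | (w <= 0)
        if bad.any():
            rows = list(self.data.index[bad][:5])
            raise TableValidationError(
                f"non-positive or non-finite weights for households {rows}"
            )
        for var, levels in self.levels.items():
            col = self.data[var]
            offending = col.dropna()[~col.dropna().isin(levels)]
            if len(offending):
                raise TableValidationError(
                    f"variable {var!r}: values {sorted(set(offending))} not in "
                    f"declared levels {levels}"
                )
        if len(self.levels[self.setting]) != 2:
            raise TableValidationError("setting variable must have two levels")


@dataclass(frozen=True)
class CompleteCaseReport:
    n_input: int
    n_retained: int
    n_dropped: int
    variables: tuple[str, ...]


@dataclass
class ChildTable:
    """Child-level rows: household id, survey weight, height-for-age Z-score."""

    data: pd.DataFrame  # columns: household_id, weight, haz


@dataclass
class WomanTable:
    """Woman-level rows carrying literacy and child-survival counts.

    ``literacy`` is the DHS 0-2 reading scale (0 = cannot read at all,
    2 = reads a whole sentence).  The proportion of a woman's children who
    are deceased is derived downstream as
    ``(sons_died + daughters_died) / children_ever_born``.
    """

    data: pd.DataFrame  # columns: household_id, weight, literacy,
    #                     sons_died, daughters_died, children_ever_born


@dataclass(frozen=True)
class SearchConfig:
    """Configuration of the exhaustive asset-subset / cluster-count search.

    Parameters
    ----------
    n_assets:
        Total number of model variables, including forced ones (default 5,
        the five-question survey module the method targets).
    k_range:
        Inclusive range of cluster counts to evaluate.
    mode:
        ``"max_asw"`` picks the global ASW argmax; ``"threshold"`` picks the
        smallest K whose best ASW reaches ``asw_threshold`` (0.70, the
        classical cutoff for a strong cluster structure), then the best
        asset subset at that K.
    min_prevalence:
        Binary ownership assets owned by less than this weighted share of
        the population are dropped from the candidate pool (0.10 by
        default); multi-level variables always stay eligible.
    forced_variables:
        Variables included in every candidate subset.  ``None`` means "the
        table's rural/urban setting variable".
    """

    n_assets: int = 5
    k_range: tuple[int, int] = (5, 20)
    mode: str = "threshold"
    asw_threshold: float = 0.70
    min_prevalence: float = 0.10
    forced_variables: tuple[str, ...] | None = None
    random_seed: int = 0

    def __post_init__(self):
        if self.n_assets < 2:
            raise EconClustersError("n_assets must be at least 2")
        lo, hi = self.k_range
        if lo < 2 or hi < lo:
            raise EconClustersError(f"invalid k_range {self.k_range}")
        if self.mode not in ("max_asw", "threshold"):
            raise EconClustersError(f"unknown selection mode {self.mode!r}")
        if not (0 < self.asw_threshold <= 1):
            raise EconClustersError("asw_threshold must lie in (0, 1]")
        if not (0 <= self.min_prevalence < 1):
            raise EconClustersError("min_prevalence must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        if self.forced_variables is not None:
            d["forced_variables"] = list(self.forced_variables)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SearchConfig":
        d = dict(d)
        d["k_range"] = tuple(d["k_range"])
        if d.get("forced_variables") is not None:
            d["forced_variables"] = tuple(d["forced_variables"])
        return cls(**d)


@dataclass
class ClusterModel:
    """A fitted economic-cluster model.

    ``medoids`` are actual asset-answer profiles from the data, one per
    cluster; clusters are numbered 1..k in medoid order.  ``assignment``
    maps every complete-case household id to its cluster, and
    ``profile_assignment`` records the distinct profiles with their summed
    weights and cluster labels (the unit at which clustering was run).
    """

    asset_names: list[str]
    levels: dict[str, list[str]]
    k: int
    medoids: list[dict[str, str]]
    assignment: dict[str, int]
    profile_assignment: list[dict]
    asw: float
    config: SearchConfig
    provenance: dict

    def validate(self) -> None:
        if len(self.medoids) != self.k:
            raise EconClustersError("number of medoids differs from k")
        clusters = set(self.assignment.values())
        if not clusters <= set(range(1, self.k + 1)):
            raise EconClustersError("assignment contains out-of-range clusters")


def read_household_table(path: str | Path, mapping: ColumnMap) -> HouseholdTable:
    """Read and validate a household CSV against a column mapping.

    Raises :class:`TableValidationError` naming the offending CSV lines
    (line 1 is the header) for duplicate ids, non-positive weights, or asset
    values outside their declared level set.  Missing asset values (empty
    cells or ``NA``) are preserved as explicit missing markers.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    needed = [mapping.household_id, mapping.weight, mapping.setting, *mapping.assets]
    for col in (mapping.stratum, mapping.psu):
        if col:
            needed.append(col)
    absent = [c for c in needed if c not in raw.columns]
    if absent:
        raise TableValidationError(f"{path}: missing columns {absent}")

    lines = np.arange(2, len(raw) + 2)  # CSV line numbers of the data rows

    ids = raw[mapping.household_id]
    dup = ids.duplicated(keep=False)
    if dup.any():
        raise TableValidationError(
            f"duplicate household ids {sorted(set(ids[dup]))[:5]} "
            f"on lines {lines[dup][:10].tolist()}"
        )

    weight = pd.to_numeric(raw[mapping.weight], errors="coerce")
    bad_w = ~np.isfinite(weight.to_numpy()) | (weight.to_numpy() <= 0)
    if bad_w.any():
        raise TableValidationError(
            f"non-positive, missing, or non-numeric weights on lines "
            f"{lines[bad_w][:10].tolist()}"
        )

    levels = {mapping.setting: list(mapping.setting_levels)}
    levels.update({name: list(lv) for name, lv in mapping.assets.items()})

    data = pd.DataFrame(index=pd.Index(ids, name="household_id"))
    data["weight"] = weight.to_numpy()
    errors = []
    for var, lv in levels.items():
        col = raw[var].where(~raw[var].isin(MISSING_TOKENS), other=pd.NA)
        outside = col.notna() & ~col.isin(lv)
        if outside.any():
            vals = sorted(set(col[outside.to_numpy()]))
            errors.append(
                f"variable {var!r}: undeclared values {vals} on lines "
                f"{lines[outside.to_numpy()][:10].tolist()}"
            )
        data[var] = pd.array(col.to_numpy(), dtype="string")
    if errors:
        raise TableValidationError("; ".join(errors))

    stratum = psu = None
    if mapping.stratum:
        data["stratum"] = raw[mapping.stratum].to_numpy()
        stratum = "stratum"
    if mapping.psu:
        data["psu"] = raw[mapping.psu].to_numpy()
        psu = "psu"

    table = HouseholdTable(data=data, levels=levels, setting=mapping.setting,
                           stratum=stratum, psu=psu)
    table.validate()
    return table


def write_household_table(table: HouseholdTable, path: str | Path) -> None:
    out = table.data.copy()
    out.insert(0, "household_id", out.index.astype(str))
    out.to_csv(path, index=False)


def complete_case_filter(
    table: HouseholdTable, variables: Sequence[str]
) -> tuple[HouseholdTable, CompleteCaseReport]:
    """Keep only households with no missing value among ``variables``.

    Mirrors the complete-case counts a survey analysis reports before
    clustering.  Idempotent; raises if no household survives.
    """
    unknown = [v for v in variables if v not in table.levels]
    if unknown:
        raise EconClustersError(f"variables not in table: {unknown}")
    mask = table.data[list(variables)].notna().all(axis=1).to_numpy()
    n_keep = int(mask.sum())
    if n_keep == 0:
        raise TableValidationError(
            f"no household has complete data on {list(variables)}"
        )
    filtered = HouseholdTable(
        data=table.data.loc[mask].copy(),
        levels=dict(table.levels),
        setting=table.setting,
        stratum=table.stratum,
        psu=table.psu,
    )
    report = CompleteCaseReport(
        n_input=table.n_households,
        n_retained=n_keep,
        n_dropped=table.n_households - n_keep,
        variables=tuple(variables),
    )
    return filtered, report


def _read_simple_table(path, mapping, numeric_cols, defaults=None):
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    mapping = dict(mapping)
    absent = [c for c in mapping.values() if c not in raw.columns]
    if absent:
        raise TableValidationError(f"{path}: missing columns {absent}")
    lines = np.arange(2, len(raw) + 2)
    out = pd.DataFrame()
    for name, col in mapping.items():
        if name in numeric_cols:
            out[name] = pd.to_numeric(
                raw[col].where(~raw[col].isin(MISSING_TOKENS)), errors="coerce"
            )
        else:
            out[name] = raw[col]
    return out, lines


_CHILD_MAPPING = {"household_id": "household_id", "weight": "weight", "haz": "haz"}
_WOMAN_MAPPING = {
    "household_id": "household_id",
    "weight": "weight",
    "literacy": "literacy",
    "sons_died": "sons_died",
    "daughters_died": "daughters_died",
    "children_ever_born": "children_ever_born",
}


def read_child_table(path: str | Path, mapping: Mapping[str, str] | None = None) -> ChildTable:
    """Read the child table (household id, weight, height-for-age Z-score)."""
    out, lines = _read_simple_table(path, mapping or _CHILD_MAPPING, {"weight", "haz"})
    bad = ~np.isfinite(out["haz"].to_numpy(dtype=float)) | \
        ~np.isfinite(out["weight"].to_numpy(dtype=float)) | (out["weight"].to_numpy(dtype=float) <= 0)
    if bad.any():
        raise TableValidationError(
            f"child rows with missing/invalid haz or weight on lines {lines[bad][:10].tolist()}"
        )
    return ChildTable(data=out)


def read_woman_table(path: str | Path, mapping: Mapping[str, str] | None = None) -> WomanTable:
    """Read the woman table and check literacy/child-count invariants."""
    numeric = {"weight", "literacy", "sons_died", "daughters_died", "children_ever_born"}
    out, lines = _read_simple_table(path, mapping or _WOMAN_MAPPING, numeric)
    arr = out[list(numeric)].to_numpy(dtype=float)
    bad = ~np.isfinite(arr).all(axis=1) | (out["weight"].to_numpy(dtype=float) <= 0)
    bad |= ~out["literacy"].isin([0, 1, 2]).to_numpy()
    bad |= (
        out["sons_died"].to_numpy(dtype=float) + out["daughters_died"].to_numpy(dtype=float)
        > out["children_ever_born"].to_numpy(dtype=float)
    )
    bad |= (out[["sons_died", "daughters_died", "children_ever_born"]].to_numpy(dtype=float) < 0).any(axis=1)
    if bad.any():
        raise TableValidationError(
            f"invalid woman rows on lines {lines[bad][:10].tolist()} "
            "(literacy must be 0/1/2, deaths must not exceed children ever born)"
        )
    for c in ("literacy", "sons_died", "daughters_died", "children_ever_born"):
        out[c] = out[c].astype(int)
    return WomanTable(data=out)


# ---------------------------------------------------------------------------
# model serialization


def serialize_model(model: ClusterModel, path: str | Path) -> None:
    """Write a model as versioned, deterministically ordered JSON."""
    model.validate()
    payload = {
        "schema_version": SCHEMA_VERSION,
        "asset_names": model.asset_names,
        "levels": model.levels,
        "k": model.k,
        "medoids": model.medoids,
        "assignment": model.assignment,
        "profile_assignment": model.profile_assignment,
        "asw": model.asw,
        "config": model.config.to_dict(),
        "provenance": model.provenance,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def deserialize_model(path: str | Path) -> ClusterModel:
    """Load a model JSON; errors on truncation or schema-version mismatch."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelSchemaError(f"{path}: not valid model JSON ({exc})") from exc
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ModelSchemaError(
            f"{path}: schema version {version!r} not supported (expected {SCHEMA_VERSION})"
        )
    return ClusterModel(
        asset_names=list(payload["asset_names"]),
        levels={k: list(v) for k, v in payload["levels"].items()},
        k=int(payload["k"]),
        medoids=[dict(m) for m in payload["medoids"]],
        assignment={str(k): int(v) for k, v in payload["assignment"].items()},
        profile_assignment=[dict(p) for p in payload["profile_assignment"]],
        asw=float(payload["asw"]),
        config=SearchConfig.from_dict(payload["config"]),
        provenance=dict(payload["provenance"]),
    )
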