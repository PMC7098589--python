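"""Readers and writers for the CSV/YAML interchange formats.

Food system: CSV with columns ``food_id, group_id, price_per_100g,
grams_per_day, kj_per_100g`` plus one column per nutrient (g per 100 g).
PE matrix: square CSV with a header row and index column of food ids.
EE vector: two-column CSV (``food_id, eta``).  Disaggregation scheme: CSV
with ``group_id, sub_food_id, within_group_share``.  Policy: YAML mapping
with ``nutrient_taxes``, ``ad_valorem`` and ``name``.

All files are UTF-8, comma-delimited with '.' decimals; writers round-trip
through their readers at full float precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .demand import ExpenditureVector, FoodSystem, PEMatrix, PolicySpec
from .disaggregation import DisaggregationScheme

__all__ = [
    "load_food_table", "save_food_table",
    "load_pe_matrix", "save_pe_matrix",
    "load_ee_vector", "save_ee_vector",
    "load_scheme", "save_scheme",
    "load_policy", "save_policy",
    "write_result_json",
]

RESERVED_COLUMNS = ["food_id", "group_id", "price_per_100g", "grams_per_day",
                    "kj_per_100g"]
_FLOAT_FMT = "%.17g"


def load_food_table(path: str | Path) -> FoodSystem:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    dupes = df["food_id"][df["food_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate food_id {dupes}")
    bad = df.index[df["price_per_100g"] <= 0].tolist()
    if bad:
        raise ValueError(f"{path}: non-positive price in rows {bad}")
    nutrients = [c for c in df.columns if c not in RESERVED_COLUMNS]
    return FoodSystem(
        food_id=df["food_id"].astype(str).tolist(),
        group_id=df["group_id"].astype(str).tolist(),
        q_b=df["grams_per_day"].to_numpy(float),
        p_b=df["price_per_100g"].to_numpy(float),
        energy_density=df["kj_per_100g"].to_numpy(float),
        nutrient_content={c: df[c].to_numpy(float) for c in nutrients},
    )


def save_food_table(system: FoodSystem, path: str | Path) -> None:
    df = pd.DataFrame({
        "food_id": system.food_id,
        "group_id": system.group_id,
        "price_per_100g": system.p_b,
        "grams_per_day": system.q_b,
        "kj_per_100g": system.energy_density,
    })
    for nut, arr in system.nutrient_content.items():
        df[nut] = arr
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_pe_matrix(path: str | Path) -> PEMatrix:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: PE matrix row/column labels differ")
    return PEMatrix(epsilon=df.to_numpy(float),
                    food_id=list(df.columns.astype(str)))


def save_pe_matrix(pe: PEMatrix, path: str | Path) -> None:
    labels = pe.food_id or [f"f{i}" for i in range(pe.n)]
    pd.DataFrame(pe.epsilon, index=labels, columns=labels).to_csv(
        path, float_format=_FLOAT_FMT)


def load_ee_vector(path: str | Path) -> tuple[list[str], ExpenditureVector]:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"food_id", "eta"}.issubset(df.columns):
        raise ValueError(f"{path}: EE file needs columns food_id, eta")
    return (df["food_id"].astype(str).tolist(),
            ExpenditureVector(eta=df["eta"].to_numpy(float)))


def save_ee_vector(food_id: list[str], ee: ExpenditureVector,
                   path: str | Path) -> None:
    pd.DataFrame({"food_id": food_id, "eta": ee.eta}).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def load_scheme(path: str | Path, s: float = 0.025,
                sd_s: float = 0.0125) -> DisaggregationScheme:
    df = pd.read_csv(path, float_precision="round_trip")
    need = {"group_id", "sub_food_id", "within_group_share"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: scheme file needs columns {sorted(need)}")
    groups: dict[str, list[tuple[str, float]]] = {}
    for _, row in df.iterrows():
        groups.setdefault(str(row["group_id"]), []).append(
            (str(row["sub_food_id"]), float(row["within_group_share"])))
    return DisaggregationScheme(groups=groups, s=s, sd_s=sd_s)


def save_scheme(scheme: DisaggregationScheme, path: str | Path) -> None:
    rows = [
        {"group_id": gid, "sub_food_id": sid, "within_group_share": share}
        for gid, members in scheme.groups.items()
        for sid, share in members
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_policy(path: str | Path) -> PolicySpec:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return PolicySpec(
        nutrient_taxes={str(k): float(v)
                        for k, v in (raw.get("nutrient_taxes") or {}).items()},
        ad_valorem={str(k): float(v)
                    for k, v in (raw.get("ad_valorem") or {}).items()},
        name=str(raw.get("name", "policy")),
    )


def save_policy(policy: PolicySpec, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {"name": policy.name,
             "nutrient_taxes": dict(policy.nutrient_taxes),
             "ad_valorem": dict(policy.ad_valorem)},
            fh, sort_keys=True)


def provenance(config: dict, seed: int | None = None) -> dict:
    """Provenance block for output artifacts: config hash, seed, version."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "version": __version__,
    }


def write_result_json(payload: dict, path: str | Path,
                      config: dict | None = None,
                      seed: int | None = None) -> None:
    out = dict(payload)
    out["provenance"] = provenance(config or {}, seed)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
        fh.write("\n")
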