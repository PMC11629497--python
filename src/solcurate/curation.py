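"""Cleaning, weighting and cross-set merging of solubility record tables.

Two levels of curation are implemented, mirroring how compiled solubility
sets are usually processed before modelling:

**Cleaning** (per set): drop unparseable structures; drop records measured
under non-standard conditions (outside temperature 25 ± 5 °C or pH 7 ± 1
when that metadata is present — records without metadata pass); collapse
duplicates, i.e. records of the same connectivity whose values differ by
less than 0.01 log units; remove metal-containing and single-heavy-atom
species; and assign each record an intra-set weight of 1/(records per
molecule) so every molecule carries total weight 1. Every removal is
counted in a :class:`CurationReport` whose accounting always closes:
``input = output + Σ removals``.

**Cross-set curation** (between sets): each record first carries a
source-quality weight supplied by the user (quality is judged externally,
never inferred here); each analyzed set is extended with records for the
same molecule found in the other sets; within a molecule, records whose
values agree to within ``d`` (default 0.5 log units, the usual estimate of
experimental accuracy for solubility) are merged into one record whose
value is the weight-weighted mean of the members. Records further apart
stay separate with their own weights. Merging is greedy from the
highest-weight record, which makes the outcome deterministic and
order-insensitive.

All operations take and return pandas DataFrames with the standardized
columns produced by :func:`solcurate.standardize.standardize_table`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .standardize import standardize_table

__all__ = [
    "CurationReport",
    "CuratedDataset",
    "filter_conditions",
    "deduplicate",
    "remove_nonorganic",
    "assign_intra_weights",
    "remove_parse_failures",
    "clean_pipeline",
    "curate_across_sets",
    "cross_source_duplicate_report",
    "duplicate_excess",
]

REMOVAL_RULES = (
    "parse_failure",
    "condition_filter",
    "exact_duplicate",
    "near_duplicate",
    "metal",
    "single_heavy_atom",
)


@dataclass
class CurationReport:
    """Record accounting for one cleaning stage (or a whole pipeline)."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    n_output: int = 0

    def __post_init__(self):
        self.check()

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    def check(self) -> None:
        if self.n_input != self.n_output + self.n_removed:
            raise ValueError(
                f"accounting does not close: {self.n_input} != "
                f"{self.n_output} + {self.n_removed}"
            )

    def merge(self, other: "CurationReport") -> "CurationReport":
        """Chain two stage reports (this stage's output fed the other)."""
        if self.n_output != other.n_input:
            raise ValueError("reports are not consecutive stages")
        removed = dict(self.removed)
        for rule, count in other.removed.items():
            removed[rule] = removed.get(rule, 0) + count
        return CurationReport(self.n_input, removed, other.n_output)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed": dict(self.removed),
            "n_output": self.n_output,
        }


@dataclass
class CuratedDataset:
    """A cross-set curated table plus its merge log."""

    name: str
    records: pd.DataFrame
    merge_log: list[dict] = field(default_factory=list)

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / f"cured_{self.name}.csv", index=False)
        with open(outdir / f"merge_log_{self.name}.jsonl", "w") as fh:
            for entry in self.merge_log:
                fh.write(json.dumps(entry) + "\n")


def _report(df_in, df_out, removed: dict[str, int]) -> CurationReport:
    return CurationReport(len(df_in), removed, len(df_out))


def remove_parse_failures(df: pd.DataFrame) -> tuple[pd.DataFrame, CurationReport]:
    """Drop rows flagged ``parse_failed`` by standardization."""
    keep = ~df["parse_failed"].to_numpy(dtype=bool)
    out = df.loc[keep].reset_index(drop=True)
    return out, _report(df, out, {"parse_failure": int((~keep).sum())})


def filter_conditions(
    df: pd.DataFrame,
    temperature_center: float = 25.0,
    temperature_tol: float = 5.0,
    pH_center: float = 7.0,
    pH_tol: float = 1.0,
) -> tuple[pd.DataFrame, CurationReport]:
    """Remove records measured outside the standard condition windows.

    A record is removed when its temperature or pH is *present* and falls
    outside ``center ± tol``. Missing metadata passes — most compiled
    records carry none, and discarding them would empty the set.
    """
    keep = np.ones(len(df), dtype=bool)
    if "temperature" in df.columns:
        t = pd.to_numeric(df["temperature"], errors="coerce")
        keep &= t.isna() | ((t - temperature_center).abs() <= temperature_tol)
    if "pH" in df.columns:
        p = pd.to_numeric(df["pH"], errors="coerce")
        keep &= p.isna() | ((p - pH_center).abs() <= pH_tol)
    out = df.loc[keep].reset_index(drop=True)
    return out, _report(df, out, {"condition_filter": int((~keep).sum())})


def deduplicate(
    df: pd.DataFrame, precision: float = 0.01, value_col: str = "logS"
) -> tuple[pd.DataFrame, CurationReport]:
    """Collapse same-molecule records whose values differ by < ``precision``.

    Within each connectivity-key group, records are scanned in stable input
    order; a record is dropped when an already-kept record of the group has
    a value less than ``precision`` away (the earlier record survives).
    Groups whose values are all at least ``precision`` apart keep every
    member. Removals are counted as ``exact_duplicate`` when the raw values
    are identical and ``near_duplicate`` otherwise.
    """
    if precision <= 0:
        raise ValueError(f"precision must be > 0, got {precision}")
    keep = np.ones(len(df), dtype=bool)
    n_exact = n_near = 0
    values = df[value_col].to_numpy(dtype=float)
    for _, idx in df.groupby("connectivity_key", sort=False).indices.items():
        kept_values: list[float] = []
        for i in idx:
            v = values[i]
            clash = next((kv for kv in kept_values if abs(v - kv) < precision), None)
            if clash is None:
                kept_values.append(v)
            else:
                keep[i] = False
                if v == clash:
                    n_exact += 1
                else:
                    n_near += 1
    out = df.loc[keep].reset_index(drop=True)
    return out, _report(df, out, {"exact_duplicate": n_exact, "near_duplicate": n_near})


def remove_nonorganic(df: pd.DataFrame) -> tuple[pd.DataFrame, CurationReport]:
    """Remove metal-containing and single-heavy-atom records, counted apart.

    Mirrors :func:`solcurate.standardize.classify_organic`: a multi-fragment
    inorganic complex whose surviving fragment is a metal counts as metal,
    not as a single-atom species.
    """
    metal_flag = df["contains_metal"].to_numpy(dtype=bool)
    multi_frag = df["n_fragments_before_desalt"].to_numpy(dtype=int) > 1
    single = df["is_single_heavy_atom"].to_numpy(dtype=bool) & ~(metal_flag & multi_frag)
    metal = metal_flag & ~single
    keep = ~(single | metal)
    out = df.loc[keep].reset_index(drop=True)
    return out, _report(
        df, out, {"metal": int(metal.sum()), "single_heavy_atom": int(single.sum())}
    )


def assign_intra_weights(df: pd.DataFrame) -> pd.DataFrame:
    """Weight every record by 1/(records per molecule).

    After this, each molecule (connectivity key) carries total weight
    exactly 1, so molecules measured many times do not dominate training —
    the "inter-dataset curation" weighting.
    """
    out = df.copy()
    counts = out.groupby("connectivity_key", sort=False)["connectivity_key"].transform("size")
    out["weight"] = 1.0 / counts.to_numpy(dtype=float)
    return out


def clean_pipeline(
    df: pd.DataFrame,
    precision: float = 0.01,
    neutralize: bool = False,
    temperature_center: float = 25.0,
    temperature_tol: float = 5.0,
    pH_center: float = 7.0,
    pH_tol: float = 1.0,
) -> tuple[pd.DataFrame, CurationReport]:
    """Full per-set cleaning: standardize, filter, deduplicate, weight.

    Stages, in order: structure standardization (adding identity keys),
    parse-failure removal, condition filter, duplicate collapse at
    ``precision``, metal/single-atom removal, intra-set weight assignment.
    Returns the cleaned table and the chained accounting report.
    """
    if "connectivity_key" not in df.columns:
        df = standardize_table(df, neutralize=neutralize)
    df = df.reset_index(drop=True)
    out, report = remove_parse_failures(df)
    out, r = filter_conditions(
        out, temperature_center, temperature_tol, pH_center, pH_tol
    )
    report = report.merge(r)
    out, r = deduplicate(out, precision=precision)
    report = report.merge(r)
    out, r = remove_nonorganic(out)
    report = report.merge(r)
    out = assign_intra_weights(out)
    return out, report


# --------------------------------------------------------------------------
# Cross-set curation


def _merge_group(
    group: pd.DataFrame, d: float, weight_update: str
) -> tuple[list[dict], list[dict]]:
    """Greedy merge of one molecule's cross-set record group.

    Records are seeded in descending weight order (ties: value, then record
    id); the current seed absorbs every unmerged record whose value lies
    within ``d`` of the seed's value. Transitive chains beyond ``d`` from
    the seed start a new merged record — the tie-break is documented, not
    physical.
    """
    rows = group.sort_values(
        by=["weight", "logS", "record_id"], ascending=[False, True, True]
    ).to_dict("records")
    merged_rows: list[dict] = []
    log: list[dict] = []
    used = [False] * len(rows)
    for i, seed_row in enumerate(rows):
        if used[i]:
            continue
        members = [seed_row]
        used[i] = True
        for j in range(i + 1, len(rows)):
            if used[j]:
                continue
            if abs(rows[j]["logS"] - seed_row["logS"]) < d:
                members.append(rows[j])
                used[j] = True
        if len(members) == 1:
            merged_rows.append(dict(seed_row))
            continue
        weights = np.array([m["weight"] for m in members], dtype=float)
        vals = np.array([m["logS"] for m in members], dtype=float)
        if weights.sum() > 0:
            value = float(np.average(vals, weights=weights))
        else:
            value = float(vals.mean())
        if weight_update == "max":
            w = float(min(1.0, weights.max()))
        elif weight_update == "sum_capped":
            w = float(min(1.0, weights.sum()))
        elif weight_update == "mean":
            w = float(weights.mean())
        else:
            raise ValueError(f"unknown weight_update rule: {weight_update!r}")
        new = dict(seed_row)
        new["logS"] = value
        new["weight"] = w
        new["record_id"] = f"merged-{seed_row['record_id']}"
        merged_rows.append(new)
        log.append(
            {
                "connectivity_key": seed_row["connectivity_key"],
                "merged_record_id": new["record_id"],
                "member_record_ids": [m["record_id"] for m in members],
                "member_values": [float(v) for v in vals],
                "member_weights": [float(w_) for w_ in weights],
                "merged_value": value,
                "merged_weight": w,
            }
        )
    return merged_rows, log


def curate_across_sets(
    sets: dict[str, pd.DataFrame],
    quality: dict[str, float],
    d: float = 0.5,
    weight_update: str = "max",
) -> dict[str, CuratedDataset]:
    """Cross-set curation: quality weights, extension, value merging.

    For each analyzed set: every record (from this set and, for molecules
    the set contains, from all other sets) carries its source's quality
    weight; per molecule, records within ``d`` log units of the
    highest-weight record are merged (weighted-mean value); the rest keep
    their own weights. ``weight_update`` controls the merged record's
    weight: ``"max"`` (default) keeps the best member's weight,
    ``"sum_capped"`` sums member weights capping at 1, ``"mean"`` averages.

    Raises ``KeyError`` when a source in ``sets`` has no quality weight.
    """
    for name in sets:
        if name not in quality:
            raise KeyError(f"no quality weight configured for source {name!r}")
    for name, w in quality.items():
        if not (0.0 < w <= 1.0):
            raise ValueError(f"quality weight for {name!r} must be in (0, 1], got {w}")

    weighted = {
        name: df.assign(weight=quality[name]).reset_index(drop=True)
        for name, df in sets.items()
    }
    out: dict[str, CuratedDataset] = {}
    for name, base in weighted.items():
        keys = set(base["connectivity_key"])
        pool = [base]
        for other, df in weighted.items():
            if other == name:
                continue
            ext = df[df["connectivity_key"].isin(keys)]
            if len(ext):
                pool.append(ext)
        combined = pd.concat(pool, ignore_index=True)
        merged_rows: list[dict] = []
        merge_log: list[dict] = []
        for _, group in combined.groupby("connectivity_key", sort=False):
            rows, log = _merge_group(group, d=d, weight_update=weight_update)
            merged_rows.extend(rows)
            merge_log.extend(log)
        records = pd.DataFrame(merged_rows).reset_index(drop=True)
        out[name] = CuratedDataset(name=name, records=records, merge_log=merge_log)
    return out


# --------------------------------------------------------------------------
# Cross-source duplicate reporting


def _classify_variant(smiles_a: str, smiles_b: str) -> str:
    """Classify how two texts of the same (connectivity, value) pair differ."""
    if smiles_a == smiles_b:
        return "verbatim"
    mol_a = Chem.MolFromSmiles(smiles_a)
    mol_b = Chem.MolFromSmiles(smiles_b)
    if mol_a is None or mol_b is None:
        return "other"
    if Chem.MolToSmiles(mol_a) == Chem.MolToSmiles(mol_b):
        return "verbatim"
    n_frags_a = len(Chem.GetMolFrags(mol_a))
    n_frags_b = len(Chem.GetMolFrags(mol_b))
    if n_frags_a != n_frags_b:
        return "salt"
    charge_a = sum(a.GetFormalCharge() for a in mol_a.GetAtoms())
    charge_b = sum(a.GetFormalCharge() for a in mol_b.GetAtoms())
    if charge_a != charge_b:
        return "ionization"
    Chem.RemoveStereochemistry(mol_a)
    Chem.RemoveStereochemistry(mol_b)
    if Chem.MolToSmiles(mol_a) == Chem.MolToSmiles(mol_b):
        return "stereo"
    return "other"


def cross_source_duplicate_report(sets: dict[str, pd.DataFrame]) -> dict:
    """Count records sharing (connectivity key, identical value) across sources.

    Returns a dict with ``n_duplicate_records`` (records that repeat an
    earlier record's key-value pair, overall), ``by_source_pair`` counts of
    duplicate pairs, and ``pairs``: one entry per (earlier, later) record
    pair sharing connectivity and value, classified by how the raw texts
    differ (verbatim / salt / ionization / stereo / other).
    """
    combined = pd.concat(sets.values(), ignore_index=True)
    pairs: list[dict] = []
    pair_counts: dict[tuple[str, str], int] = {}
    n_dup_records = 0
    for _, group in combined.groupby("connectivity_key", sort=False):
        rows = group.to_dict("records")
        for j in range(1, len(rows)):
            is_dup = False
            for i in range(j):
                if rows[i]["logS"] == rows[j]["logS"]:
                    is_dup = True
                    kind = _classify_variant(rows[i]["smiles"], rows[j]["smiles"])
                    key = tuple(sorted((rows[i]["source"], rows[j]["source"])))
                    pair_counts[key] = pair_counts.get(key, 0) + 1
                    pairs.append(
                        {
                            "record_id_a": rows[i]["record_id"],
                            "record_id_b": rows[j]["record_id"],
                            "source_a": rows[i]["source"],
                            "source_b": rows[j]["source"],
                            "value": float(rows[j]["logS"]),
                            "variant": kind,
                        }
                    )
            if is_dup:
                n_dup_records += 1
    return {
        "n_duplicate_records": n_dup_records,
        "by_source_pair": {f"{a}|{b}": c for (a, b), c in sorted(pair_counts.items())},
        "pairs": pairs,
    }


def duplicate_excess(n_deduplicated: int, n_primary: int) -> int:
    """Bookkeeping identity for re-imported assay data.

    When a compilation aggregates one primary assay together with processed
    copies of the same measurements from secondary publications, the record
    count that survives value-level deduplication still exceeds the primary
    assay's size; the excess is exactly the number of disguised duplicate
    records (variant structures or re-rounded values that defeated the
    duplicate key).
    """
    return n_deduplicated - n_primary
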