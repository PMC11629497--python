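"""Synthetic multi-source solubility compilations with known ground truth.

Real solubility compilations are aggregates of heterogeneous sources that
share molecules, disagree in noise level and calibration, and — crucially —
contain the same measurement re-imported several times under different
structure texts (salt forms, ionized vs. neutral species, stereo markers
present or stripped). This module generates such compilations from scratch
so that every downstream stage (standardization, deduplication, weighting,
merging, split policies, leakage experiments) can be tested against an
exact generation log instead of an unknowable real provenance.

The design, briefly:

* a *universe* of distinct organic molecules is assembled from a built-in
  fragment library (SMILES concatenation, validity checked with RDKit,
  uniqueness enforced on the connectivity key);
* each molecule's *true* log-solubility is a fixed linear function of five
  physicochemical descriptors (heavy atoms, aromatic rings, H-bond donors,
  H-bond acceptors, heteroatom fraction) — not real physics, but a smooth
  learnable signal with a known noise floor;
* each *source* samples molecules with replacement (so molecules recur
  across sources), adds its own Gaussian noise and calibration bias,
  rounds values to a configured precision (0.01 log units by default,
  matching how databases index property values), and then replaces a
  configured fraction of its records with representation-variant copies of
  existing records: same value, different structure text;
* a small fraction of records may be metal/inorganic/single-heavy-atom
  species drawn from a built-in fixture list — the kind of entry that
  graph-based models cannot process and curation must remove.

Every record that is a duplicate carries a pointer to its original in the
returned table and in the generation log, which downstream tests use as
the oracle for duplicate detection.

All randomness flows from one ``numpy`` generator seeded per call; no
global state. Identical (specs, seed) reproduce identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .baseline_model import featurize
from .standardize import StandardizationError, round_half_even, standardize_structure

__all__ = [
    "SourceSpec",
    "GroundTruth",
    "GenerationLogEntry",
    "DEFAULT_COEFFICIENTS",
    "FRAGMENT_SCAFFOLDS",
    "FRAGMENT_SUBSTITUENTS",
    "INORGANIC_FIXTURES",
    "VARIANT_KINDS",
    "generate_universe",
    "true_solubility",
    "build_ground_truth",
    "generate_sources",
    "write_sources",
]

# --------------------------------------------------------------------------
# Fragment library: valid stand-alone SMILES chains (rings closed, first and
# last atoms with spare valence) so that plain string concatenation of
# scaffold + substituents yields a parseable molecule. Validity is checked
# with RDKit anyway; invalid combinations are simply re-drawn.

FRAGMENT_SCAFFOLDS: tuple[str, ...] = (
    "c1ccccc1",        # benzene
    "c1ccncc1",        # pyridine
    "c1ccsc1",         # thiophene
    "c1ccoc1",         # furan
    "c1cc[nH]c1",      # pyrrole
    "C1CCCCC1",        # cyclohexane
    "C1CCNCC1",        # piperidine
    "C1CCOCC1",        # tetrahydropyran
    "C1CCCC1",         # cyclopentane
    "c1ccc2ccccc2c1",  # naphthalene
    "CCCC",            # butane chain
    "CCOCC",           # diethyl ether chain
    "CC(C)C",          # isobutane
    "CCSCC",           # thioether chain
)

FRAGMENT_SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "O", "OC", "OCC", "N", "NC",
    "Cl", "F", "Br", "C(=O)O", "C(=O)N", "C(=O)OC", "C#N",
    "CO", "CN", "C(C)O", "S", "C(F)(F)F", "C=C", "CCO",
)

#: Metal / inorganic / single-heavy-atom fixtures of the kind found in
#: compiled solubility sets (graph models fail on them; curation drops them).
INORGANIC_FIXTURES: tuple[str, ...] = (
    "[Mo]",
    "[Re]",
    "[Mg+2]",
    "C",                            # methane: one heavy atom
    "[H+].[F-]",
    "[O-2].[O-2].[Mg+2].[Ca+2]",
    "[Al+3].[Cl-].[Cl-].[Cl-]",
    "[Na+].[Cl-]",
    "[K+].[Br-]",
    "[Fe+2].[Cl-].[Cl-]",
)

VARIANT_KINDS: tuple[str, ...] = ("salt", "ionize", "stereo_strip", "stereo_add")

_COUNTERIONS: tuple[str, ...] = ("[Na+]", "[Cl-]", "[K+]")

#: Coefficients of the linear truth model over the five descriptors
#: (heavy atoms, aromatic rings, HBD, HBA, heteroatom fraction). Chosen so
#: generated true values span roughly -8..0 log mol/L: solubility falls with
#: size and aromaticity and rises with hydrogen bonding and polarity.
DEFAULT_COEFFICIENTS: tuple[float, ...] = (-0.30, -0.40, 0.35, 0.25, 2.0)


@dataclass(frozen=True)
class SourceSpec:
    """Parameters of one simulated data source.

    ``noise_sd`` and ``bias`` are in log units; ``dup_fraction`` is the
    share of records that are representation-variant copies of an existing
    record (same value, different SMILES); ``value_precision`` is the
    rounding step applied to every recorded value; ``frac_inorganic`` is
    the share of metal/single-heavy-atom fixture records. The default
    ``noise_sd`` of 0.5 log units matches the commonly quoted experimental
    accuracy of solubility measurements.
    """

    name: str
    n_records: int
    noise_sd: float = 0.5
    bias: float = 0.0
    dup_fraction: float = 0.0
    variant_kinds: tuple[str, ...] = VARIANT_KINDS
    value_precision: float = 0.01
    frac_inorganic: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.dup_fraction < 1.0):
            raise ValueError(f"dup_fraction must be in [0, 1), got {self.dup_fraction}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.value_precision <= 0:
            raise ValueError(f"value_precision must be > 0, got {self.value_precision}")
        if not (0.0 <= self.frac_inorganic <= 1.0):
            raise ValueError(f"frac_inorganic must be in [0, 1], got {self.frac_inorganic}")
        if self.n_records < 1:
            raise ValueError(f"n_records must be >= 1, got {self.n_records}")
        unknown = set(self.variant_kinds) - set(VARIANT_KINDS)
        if unknown:
            raise ValueError(f"unknown variant kinds: {sorted(unknown)}")


@dataclass(frozen=True)
class GroundTruth:
    """True log-solubility per unique connectivity in the universe."""

    smiles_by_key: dict[str, str]
    true_logS: dict[str, float]
    coefficients: tuple[float, ...]


@dataclass(frozen=True)
class GenerationLogEntry:
    record_id: str
    source: str
    kind: str                      # original | duplicate | inorganic
    duplicate_of: str = ""
    variant: str = ""              # salt | ionize | stereo_strip | stereo_add | verbatim
    note: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "record_id": self.record_id,
                "source": self.source,
                "kind": self.kind,
                "duplicate_of": self.duplicate_of,
                "variant": self.variant,
                "note": self.note,
            }
        )


# --------------------------------------------------------------------------
# Universe and truth


def generate_universe(n_molecules: int, seed: int) -> list[str]:
    """Assemble ``n_molecules`` distinct organic SMILES from the fragment library.

    Molecules are built by concatenating one scaffold with 0-3 substituent
    chains; candidates that fail to parse or repeat an already-emitted
    connectivity key are re-drawn. Deterministic for a fixed seed.
    """
    if n_molecules < 1:
        raise ValueError(f"n_molecules must be >= 1, got {n_molecules}")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    max_attempts = 2000 * n_molecules + 10_000
    while len(out) < n_molecules:
        attempts += 1
        if attempts > max_attempts:  # pragma: no cover - library is ample
            raise RuntimeError(
                f"could not assemble {n_molecules} distinct molecules "
                f"after {attempts} attempts"
            )
        n_sub = int(rng.integers(0, 4))
        parts = [str(rng.choice(FRAGMENT_SCAFFOLDS))]
        parts += [str(rng.choice(FRAGMENT_SUBSTITUENTS)) for _ in range(n_sub)]
        candidate = "".join(parts)
        mol = Chem.MolFromSmiles(candidate)
        if mol is None:
            continue
        try:
            std = standardize_structure(candidate)
        except StandardizationError:
            continue
        if std.connectivity_key in seen:
            continue
        seen.add(std.connectivity_key)
        out.append(std.canonical_smiles)
    return out


def true_solubility(
    smiles: str, coefficients: Sequence[float] = DEFAULT_COEFFICIENTS
) -> float:
    """Deterministic linear truth: descriptor vector dotted with coefficients."""
    vec = featurize(smiles)
    coeff = np.asarray(coefficients, dtype=float)
    if coeff.shape != vec.shape:
        raise ValueError(f"expected {vec.shape[0]} coefficients, got {coeff.shape[0]}")
    return float(vec @ coeff)


def build_ground_truth(
    universe: Sequence[str], coefficients: Sequence[float] = DEFAULT_COEFFICIENTS
) -> GroundTruth:
    smiles_by_key: dict[str, str] = {}
    values: dict[str, float] = {}
    for smi in universe:
        std = standardize_structure(smi)
        if std.connectivity_key in smiles_by_key:
            raise ValueError(f"universe has repeated connectivity: {smi!r}")
        smiles_by_key[std.connectivity_key] = std.canonical_smiles
        values[std.connectivity_key] = true_solubility(smi, coefficients)
    return GroundTruth(smiles_by_key, values, tuple(float(c) for c in coefficients))


# --------------------------------------------------------------------------
# Representation variants


def _variant_salt(smiles: str, rng: np.random.Generator) -> str | None:
    if "." in smiles:
        return None
    return smiles + "." + str(rng.choice(_COUNTERIONS))


def _variant_ionize(smiles: str, rng: np.random.Generator) -> str | None:
    """Toggle carboxylic-acid or primary/secondary-amine protonation."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    acid = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
    amine = Chem.MolFromSmarts("[NX3;H2,H1;+0;!$(NC=O)]")
    matches = mol.GetSubstructMatches(acid)
    if matches:
        idx = matches[0][2]  # the hydroxyl oxygen
        edit = Chem.RWMol(mol)
        atom = edit.GetAtomWithIdx(idx)
        atom.SetFormalCharge(-1)
        atom.SetNumExplicitHs(0)
        try:
            Chem.SanitizeMol(edit)
        except Exception:
            return None
        return Chem.MolToSmiles(edit)
    matches = mol.GetSubstructMatches(amine)
    if matches:
        idx = matches[0][0]
        edit = Chem.RWMol(mol)
        atom = edit.GetAtomWithIdx(idx)
        atom.SetFormalCharge(1)
        atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
        try:
            Chem.SanitizeMol(edit)
        except Exception:
            return None
        return Chem.MolToSmiles(edit)
    return None


def _variant_stereo_strip(smiles: str, rng: np.random.Generator) -> str | None:
    if not any(ch in smiles for ch in "@/\\"):
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def _variant_stereo_add(smiles: str, rng: np.random.Generator) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    centers = Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    unassigned = [idx for idx, tag in centers if tag == "?"]
    if not unassigned:
        return None
    idx = int(rng.choice(unassigned))
    tag = (
        Chem.ChiralType.CHI_TETRAHEDRAL_CW
        if rng.random() < 0.5
        else Chem.ChiralType.CHI_TETRAHEDRAL_CCW
    )
    mol.GetAtomWithIdx(idx).SetChiralTag(tag)
    return Chem.MolToSmiles(mol)


_VARIANT_FUNCS = {
    "salt": _variant_salt,
    "ionize": _variant_ionize,
    "stereo_strip": _variant_stereo_strip,
    "stereo_add": _variant_stereo_add,
}


def make_variant(
    smiles: str, kinds: Sequence[str], rng: np.random.Generator
) -> tuple[str, str]:
    """Produce a representation-variant SMILES with the same connectivity.

    Kinds are tried in a seeded random order; a kind that does not apply to
    this structure (no stereocenter to strip, nothing to ionize, ...) is
    skipped. When nothing applies the text is copied verbatim — still a
    duplicate record, just not a disguised one — and reported as such.

    Returns ``(variant_smiles, kind_used)`` where kind is ``"verbatim"`` on
    fallback.
    """
    order = list(kinds)
    rng.shuffle(order)
    for kind in order:
        variant = _VARIANT_FUNCS[kind](smiles, rng)
        if variant is None:
            continue
        check = Chem.MolFromSmiles(variant)
        if check is None:
            continue
        return variant, kind
    return smiles, "verbatim"


# --------------------------------------------------------------------------
# Source generation


def generate_sources(
    universe: Sequence[str],
    truth: GroundTruth,
    specs: Sequence[SourceSpec],
    seed: int,
) -> tuple[dict[str, pd.DataFrame], list[GenerationLogEntry]]:
    """Generate one record table per source plus the generation log.

    Each source samples molecules from the universe with replacement (also
    across sources, so molecules recur between sources), records
    ``true_logS + bias + Normal(0, noise_sd)`` rounded to
    ``value_precision``, then converts a ``dup_fraction`` share of its
    records into representation-variant copies of records generated so far
    — same value, variant structure text. ``round(dup_fraction *
    n_records)`` records are flagged as duplicates, exactly.

    Tables carry columns ``smiles, logS, source, record_id,
    is_duplicate_of`` (empty string for originals). The log is the oracle
    for duplicate bookkeeping: entry ``kind`` is one of ``original``,
    ``duplicate``, ``inorganic``.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    key_cache: dict[str, str] = {v: k for k, v in truth.smiles_by_key.items()}
    log: list[GenerationLogEntry] = []
    tables: dict[str, pd.DataFrame] = {}
    # duplicate targets: organic original records from any source so far
    dup_pool: list[tuple[str, str, float]] = []  # (record_id, smiles, value)

    for spec in specs:
        n = spec.n_records
        n_dup = int(round(spec.dup_fraction * n))
        n_inorg = int(round(spec.frac_inorganic * n))
        n_inorg = min(n_inorg, n - n_dup)
        n_org = n - n_dup - n_inorg
        rows = []
        counter = 0

        def next_id() -> str:
            nonlocal counter
            rid = f"{spec.name}-{counter:05d}"
            counter += 1
            return rid

        for _ in range(n_org):
            smi = universe[int(rng.integers(0, len(universe)))]
            key = key_cache.get(smi)
            if key is None:
                key = standardize_structure(smi).connectivity_key
                key_cache[smi] = key
            value = truth.true_logS[key] + spec.bias + rng.normal(0.0, spec.noise_sd)
            value = round_half_even(value, spec.value_precision)
            rid = next_id()
            rows.append((rid, smi, value, ""))
            dup_pool.append((rid, smi, value))
            log.append(GenerationLogEntry(rid, spec.name, "original"))

        for _ in range(n_inorg):
            smi = str(rng.choice(INORGANIC_FIXTURES))
            # no linear truth for these; a broad plausible range
            value = round_half_even(rng.normal(-1.0, 1.5), spec.value_precision)
            rid = next_id()
            rows.append((rid, smi, value, ""))
            log.append(GenerationLogEntry(rid, spec.name, "inorganic"))

        for _ in range(n_dup):
            if not dup_pool:
                raise ValueError(
                    f"source {spec.name!r} requests duplicates but no original "
                    "records exist yet"
                )
            target_id, target_smi, target_value = dup_pool[
                int(rng.integers(0, len(dup_pool)))
            ]
            variant, kind = make_variant(target_smi, spec.variant_kinds, rng)
            rid = next_id()
            rows.append((rid, variant, target_value, target_id))
            note = "variant generation fell back to verbatim copy" if kind == "verbatim" else ""
            log.append(
                GenerationLogEntry(rid, spec.name, "duplicate", target_id, kind, note)
            )

        df = pd.DataFrame(rows, columns=["record_id", "smiles", "logS", "is_duplicate_of"])
        df.insert(2, "source", spec.name)
        tables[spec.name] = df

    return tables, log


def write_sources(
    tables: dict[str, pd.DataFrame],
    log: list[GenerationLogEntry],
    outdir,
) -> None:
    """Write one CSV per source and the generation log as JSON lines."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"source_{name}.csv", index=False)
    with open(outdir / "generation_log.jsonl", "w") as fh:
        for entry in log:
            fh.write(entry.to_json() + "\n")
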