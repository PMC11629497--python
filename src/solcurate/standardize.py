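"""Chemical structure standardization and identity keys.

Multi-source solubility compilations contain the same compound written as
different SMILES strings: salt forms, ionized vs. neutral species, records
with and without stereochemistry. Deduplication and molecule-aware data
splitting therefore operate on identity keys computed *after* a fixed
standardization sequence:

1. parse and sanitize the SMILES (RDKit);
2. de-salt, keeping the fragment with the most heavy atoms (ties broken by
   the lexicographically smallest canonical SMILES);
3. optionally neutralize formal charges (off by default — graph featurizers
   downstream tolerate charged species, and neutralization occasionally
   produces unparseable molecules);
4. emit the canonical SMILES, the standard InChIKey (``full_key``) and its
   first 14-character block (``connectivity_key``).

The connectivity key encodes the molecular skeleton without stereochemistry
or protonation state, so stereoisomers and acid/base forms of one compound
collapse onto one key. That is the identity used both for duplicate removal
and for splitting data into cross-validation folds by molecule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "StandardizationError",
    "StandardizedMolecule",
    "DuplicateKey",
    "standardize_structure",
    "classify_organic",
    "duplicate_key",
    "round_half_even",
    "ORGANIC_ATOMIC_NUMBERS",
]


class StandardizationError(ValueError):
    """Raised when a structure text cannot be parsed or processed."""


#: Elements allowed in an "organic" record. Everything else counts as a metal
#: (lanthanides, transition metals, alkali/alkaline-earth, metalloids other
#: than B/Si, ...). H, B, C, N, O, Si, P, S, Se, the halogens and the noble
#: gases are exempt; the set is configurable via `classify_organic`.
ORGANIC_ATOMIC_NUMBERS: frozenset[int] = frozenset(
    [1, 5, 6, 7, 8, 14, 15, 16, 34]  # H B C N O Si P S Se
    + [9, 17, 35, 53, 85]  # halogens
    + [2, 10, 18, 36, 54, 86]  # noble gases
)


@dataclass(frozen=True)
class StandardizedMolecule:
    """A structure after the fixed standardization sequence.

    Attributes
    ----------
    input_smiles : str
        The text as received.
    canonical_smiles : str
        RDKit canonical SMILES of the de-salted (and possibly neutralized)
        structure.
    full_key : str
        Standard InChIKey — stereo- and protonation-aware.
    connectivity_key : str
        First 14-character block of the InChIKey; identical for
        stereoisomers and protonation states of one skeleton.
    n_heavy_atoms : int
        Heavy-atom count of the surviving fragment.
    n_fragments_before_desalt : int
        Fragment count of the input (>1 indicates a salt/mixture record).
    contains_metal : bool
        True when any atom of the surviving fragment falls outside the
        organic element set.
    is_single_heavy_atom : bool
        True when the surviving fragment has at most one heavy atom.
    neutralization_failed : bool
        True when neutralization was requested but raised; the molecule is
        then kept un-neutralized and the event logged.
    """

    input_smiles: str
    canonical_smiles: str
    full_key: str
    connectivity_key: str
    n_heavy_atoms: int
    n_fragments_before_desalt: int
    contains_metal: bool
    is_single_heavy_atom: bool
    neutralization_failed: bool = False


@dataclass(frozen=True)
class DuplicateKey:
    """Identity used for exact-duplicate detection.

    Two records collide when they share a connectivity key and their values
    agree after rounding to ``precision`` (default 0.01 log units,
    round-half-to-even on the decimal representation). The precision is part
    of the key's identity.
    """

    connectivity_key: str
    rounded_value: float
    precision: float = 0.01


def round_half_even(value: float, precision: float) -> float:
    """Round ``value`` to the nearest multiple of ``precision``, ties to even.

    Performed on the decimal representation so results are reproducible
    across platforms (binary-float `round` can surprise at exact ties).
    """
    if precision <= 0:
        raise ValueError(f"precision must be positive, got {precision}")
    step = Decimal(str(precision))
    quotient = (Decimal(str(value)) / step).to_integral_value(rounding=ROUND_HALF_EVEN)
    return float(quotient * step)


# SMARTS from the standard charge-neutralization recipe: atoms with a formal
# charge that is not balanced by an adjacent opposite charge (so zwitterionic
# quaternary ammonium etc. are left alone).
_NEUTRALIZE_PATTERN = Chem.MolFromSmarts(
    "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
)


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    mol = Chem.Mol(mol)
    matches = mol.GetSubstructMatches(_NEUTRALIZE_PATTERN)
    for (idx,) in matches:
        atom = mol.GetAtomWithIdx(idx)
        charge = atom.GetFormalCharge()
        h_count = atom.GetTotalNumHs()
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(max(0, h_count - charge))
        atom.UpdatePropertyCache()
    Chem.SanitizeMol(mol)
    return mol


def _largest_fragment(mol: Chem.Mol) -> tuple[Chem.Mol, int]:
    """Keep the fragment with the most heavy atoms.

    Ties go to the lexicographically smallest canonical SMILES so the
    choice is deterministic regardless of fragment order in the input.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    n_frags = len(frags)
    if n_frags == 1:
        return mol, 1
    best = min(frags, key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
    return best, n_frags


def standardize_structure(smiles: str, neutralize: bool = False) -> StandardizedMolecule:
    """Standardize a SMILES and compute its identity keys.

    Parameters
    ----------
    smiles : str
        Input structure text.
    neutralize : bool
        Attempt to neutralize formal charges after de-salting. On failure
        the molecule is kept un-neutralized, flagged and logged rather than
        dropped.

    Raises
    ------
    StandardizationError
        If the text cannot be parsed, carrying the parser diagnostic.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        # re-parse without sanitization to recover a diagnostic
        probe = Chem.MolFromSmiles(smiles, sanitize=False)
        if probe is None:
            raise StandardizationError(f"unparseable SMILES: {smiles!r}")
        try:
            Chem.SanitizeMol(probe)
        except Exception as exc:  # pragma: no cover - message path
            raise StandardizationError(f"sanitization failed for {smiles!r}: {exc}")
        raise StandardizationError(f"unparseable SMILES: {smiles!r}")

    mol, n_frags = _largest_fragment(mol)

    neutralization_failed = False
    if neutralize:
        try:
            mol = _neutralize(mol)
        except Exception as exc:
            neutralization_failed = True
            logger.warning("neutralization failed for %r: %s; kept as-is", smiles, exc)
            mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))

    canonical = Chem.MolToSmiles(mol)
    try:
        full_key = Chem.MolToInchiKey(mol)
    except Exception as exc:
        raise StandardizationError(f"InChI generation failed for {smiles!r}: {exc}")
    if not full_key:
        raise StandardizationError(f"InChI generation failed for {smiles!r}")

    n_heavy = mol.GetNumHeavyAtoms()
    contains_metal = any(
        atom.GetAtomicNum() not in ORGANIC_ATOMIC_NUMBERS for atom in mol.GetAtoms()
    )
    return StandardizedMolecule(
        input_smiles=smiles,
        canonical_smiles=canonical,
        full_key=full_key,
        connectivity_key=full_key[:14],
        n_heavy_atoms=n_heavy,
        n_fragments_before_desalt=n_frags,
        contains_metal=contains_metal,
        is_single_heavy_atom=n_heavy <= 1,
        neutralization_failed=neutralization_failed,
    )


def classify_organic(
    mol: StandardizedMolecule,
    organic_elements: Iterable[int] = ORGANIC_ATOMIC_NUMBERS,
) -> str:
    """Classify a standardized molecule for the non-organic filter.

    Returns one of ``"single_heavy_atom"``, ``"metal_containing"`` or
    ``"organic"``. Single-heavy-atom species (e.g. ``[Mo]``, ``[CH4]``) are
    reported as such even when the atom is a metal: graph models fail on
    them for the same reason — there is no bond between heavy atoms. A
    multi-fragment input whose surviving fragment is a metal (an inorganic
    complex such as an aluminium chloride) is ``metal_containing`` even
    though the fragment is a single atom.
    """
    if mol.is_single_heavy_atom and not (
        mol.contains_metal and mol.n_fragments_before_desalt > 1
    ):
        return "single_heavy_atom"
    organic = frozenset(organic_elements)
    if organic is ORGANIC_ATOMIC_NUMBERS or organic == ORGANIC_ATOMIC_NUMBERS:
        metal = mol.contains_metal
    else:
        parsed = Chem.MolFromSmiles(mol.canonical_smiles)
        metal = any(a.GetAtomicNum() not in organic for a in parsed.GetAtoms())
    if metal:
        return "metal_containing"
    return "organic"


def duplicate_key(
    mol: StandardizedMolecule, value: float, precision: float = 0.01
) -> DuplicateKey:
    """Build the (connectivity, rounded value) key used for exact duplicates."""
    return DuplicateKey(
        connectivity_key=mol.connectivity_key,
        rounded_value=round_half_even(value, precision),
        precision=precision,
    )


# Convenience used by table-level code ---------------------------------------


def standardize_table(df, smiles_col: str = "smiles", neutralize: bool = False):
    """Standardize every row of a record table.

    Returns a copy of ``df`` with columns ``canonical_smiles``, ``full_key``,
    ``connectivity_key``, ``n_heavy_atoms``, ``n_fragments_before_desalt``,
    ``contains_metal``, ``is_single_heavy_atom`` and ``parse_failed`` added. Unparseable rows get
    ``parse_failed=True`` and empty keys instead of raising, so the cleaning
    stage can count them.
    """
    import pandas as pd

    records = []
    cache: dict[str, StandardizedMolecule | None] = {}
    for smi in df[smiles_col]:
        if smi in cache:
            std = cache[smi]
        else:
            try:
                std = standardize_structure(smi, neutralize=neutralize)
            except StandardizationError:
                std = None
            cache[smi] = std
        if std is None:
            records.append(
                {
                    "canonical_smiles": "",
                    "full_key": "",
                    "connectivity_key": "",
                    "n_heavy_atoms": 0,
                    "n_fragments_before_desalt": 0,
                    "contains_metal": False,
                    "is_single_heavy_atom": False,
                    "parse_failed": True,
                }
            )
        else:
            records.append(
                {
                    "canonical_smiles": std.canonical_smiles,
                    "full_key": std.full_key,
                    "connectivity_key": std.connectivity_key,
                    "n_heavy_atoms": std.n_heavy_atoms,
                    "n_fragments_before_desalt": std.n_fragments_before_desalt,
                    "contains_metal": std.contains_metal,
                    "is_single_heavy_atom": std.is_single_heavy_atom,
                    "parse_failed": False,
                }
            )
    out = df.copy().reset_index(drop=True)
    extra = pd.DataFrame.from_records(records)
    return pd.concat([out, extra], axis=1)
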