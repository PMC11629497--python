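"""Desk-scale baseline predictors.

The evaluation machinery in this package (cross-validation, bootstrap,
paired comparisons, nested validation) is model-agnostic: it consumes a
*predictor factory* — a callable ``factory(train_df, early_stop_df) ->
predictor`` where the predictor exposes ``predict(df) -> ndarray``. Large
graph/transformer models plug into the same contract; the predictors here
are deliberately small so the full pipeline runs in seconds on one CPU:

``fit_ridge``
    L2-penalized linear regression on five physicochemical descriptors,
    penalty selected on the early-stopping subset only, with optional
    per-record sample weights (so weighted training on curated data is
    testable).
``memorizer``
    Returns the (weighted mean) training value for an exact
    connectivity-key match and the global weighted training mean otherwise.
    It exists purely to expose duplicate leakage: when the same molecule
    straddles training and evaluation partitions, the memorizer scores a
    perfect prediction it has not earned.
``oracle``
    Predicts the generator's true value — used to verify that measured
    cross-validation error recovers the injected noise level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors
from sklearn.linear_model import Ridge

from .standardize import StandardizationError, standardize_structure

logger = logging.getLogger(__name__)

__all__ = [
    "DESCRIPTOR_NAMES",
    "featurize",
    "featurize_table",
    "fit_ridge",
    "ridge_factory",
    "memorizer",
    "memorizer_factory",
    "oracle",
    "oracle_factory",
]

#: The fixed descriptor vector. Computed on the de-salted standardized
#: structure, so salt forms and stereoisomers of one skeleton share a vector.
DESCRIPTOR_NAMES = (
    "n_heavy_atoms",
    "n_aromatic_rings",
    "n_hbd",
    "n_hba",
    "heteroatom_fraction",
)

DEFAULT_PENALTY_GRID = (1e-8, 1e-4, 1e-2, 0.1, 1.0, 10.0, 100.0)


_FEATURE_CACHE: dict[str, np.ndarray] = {}


def featurize(smiles: str) -> np.ndarray:
    """Compute the five-descriptor vector for one structure.

    Descriptors: heavy-atom count, aromatic-ring count, H-bond donor count,
    H-bond acceptor count, heteroatom fraction (non-carbon heavy atoms over
    heavy atoms). Deterministic; raises :class:`StandardizationError` on
    parse failure. Results are cached per input text (the function is pure).
    """
    cached = _FEATURE_CACHE.get(smiles)
    if cached is not None:
        return cached.copy()
    std = standardize_structure(smiles)
    mol = Chem.MolFromSmiles(std.canonical_smiles)
    n_heavy = mol.GetNumHeavyAtoms()
    n_hetero = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6))
    vec = np.array(
        [
            float(n_heavy),
            float(rdMolDescriptors.CalcNumAromaticRings(mol)),
            float(rdMolDescriptors.CalcNumHBD(mol)),
            float(rdMolDescriptors.CalcNumHBA(mol)),
            n_hetero / n_heavy if n_heavy else 0.0,
        ]
    )
    _FEATURE_CACHE[smiles] = vec
    return vec.copy()


def featurize_table(df: pd.DataFrame, smiles_col: str = "smiles") -> np.ndarray:
    """Descriptor matrix for a record table."""
    rows = [featurize(smi) for smi in df[smiles_col]]
    return np.vstack(rows) if rows else np.empty((0, len(DESCRIPTOR_NAMES)))


@dataclass
class RidgePredictor:
    model: Ridge | None
    fallback_mean: float
    alpha: float
    intercept_only: bool = False

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        if self.intercept_only or self.model is None:
            return np.full(len(df), self.fallback_mean)
        return self.model.predict(featurize_table(df))


def _weighted_mean(values: np.ndarray, weights: np.ndarray | None) -> float:
    if weights is None or not np.any(weights > 0):
        return float(np.mean(values))
    return float(np.average(values, weights=weights))


def fit_ridge(
    train: pd.DataFrame,
    early_stop: pd.DataFrame | None = None,
    penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID,
    use_weights: bool = False,
    value_col: str = "logS",
) -> RidgePredictor:
    """Fit ridge regression, choosing the penalty on the early-stop subset.

    The grid is scanned with the model fitted on ``train`` only; the alpha
    with the lowest early-stop RMSE wins (ties to the larger, i.e. more
    regularized, alpha). When ``early_stop`` is ``None`` or empty the first
    grid value is used. With ``use_weights`` the ``weight`` column of
    ``train`` enters as per-record sample weights. A degenerate design
    (constant columns only, or fewer than two records) falls back to an
    intercept-only predictor, logged.
    """
    if len(train) < 2:
        raise ValueError(f"need at least 2 training records, got {len(train)}")
    X = featurize_table(train)
    y = train[value_col].to_numpy(dtype=float)
    w = None
    if use_weights and "weight" in train.columns:
        w = train["weight"].to_numpy(dtype=float)
    mean = _weighted_mean(y, w)

    if np.allclose(X.std(axis=0), 0.0):
        logger.warning("degenerate design (all-constant descriptors); intercept-only fit")
        return RidgePredictor(None, mean, alpha=float("nan"), intercept_only=True)

    candidates: list[tuple[float, Ridge]] = []
    for alpha in penalty_grid:
        model = Ridge(alpha=alpha)
        model.fit(X, y, sample_weight=w)
        candidates.append((alpha, model))

    if early_stop is None or len(early_stop) == 0:
        alpha, model = candidates[0]
    else:
        X_es = featurize_table(early_stop)
        y_es = early_stop[value_col].to_numpy(dtype=float)
        scores = [
            (float(np.sqrt(np.mean((m.predict(X_es) - y_es) ** 2))), -a, a, m)
            for a, m in candidates
        ]
        _, _, alpha, model = min(scores, key=lambda t: (t[0], t[1]))
    return RidgePredictor(model, mean, alpha=alpha)


def ridge_factory(
    penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID, use_weights: bool = False
):
    """Predictor factory wrapping :func:`fit_ridge` for cross-validation."""

    def factory(train: pd.DataFrame, early_stop: pd.DataFrame) -> RidgePredictor:
        return fit_ridge(train, early_stop, penalty_grid=penalty_grid, use_weights=use_weights)

    return factory


@dataclass
class MemorizerPredictor:
    table: dict[str, float] = field(default_factory=dict)
    fallback_mean: float = 0.0

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        keys = df["connectivity_key"]
        return np.array([self.table.get(k, self.fallback_mean) for k in keys])


def memorizer(train: pd.DataFrame, value_col: str = "logS") -> MemorizerPredictor:
    """Look-up-table predictor keyed on the connectivity key.

    Requires a ``connectivity_key`` column (i.e. standardized records). A
    key seen several times in training maps to the weighted mean of its
    training values; unseen keys map to the global weighted training mean.
    """
    w = (
        train["weight"].to_numpy(dtype=float)
        if "weight" in train.columns
        else np.ones(len(train))
    )
    y = train[value_col].to_numpy(dtype=float)
    table: dict[str, float] = {}
    for key, grp in train.assign(_y=y, _w=w).groupby("connectivity_key", sort=False):
        table[key] = _weighted_mean(grp["_y"].to_numpy(), grp["_w"].to_numpy())
    return MemorizerPredictor(table, _weighted_mean(y, w))


def memorizer_factory():
    def factory(train: pd.DataFrame, early_stop: pd.DataFrame) -> MemorizerPredictor:
        # early-stop data deliberately unused: the memorizer has no knobs
        return memorizer(train)

    return factory


@dataclass
class OraclePredictor:
    """Predicts the generator's true value; the noise-floor reference."""

    truth_by_key: dict[str, float]

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return np.array([self.truth_by_key[k] for k in df["connectivity_key"]])


def oracle(truth) -> OraclePredictor:
    """Build the oracle from a :class:`~solcurate.synthetic_data.GroundTruth`."""
    return OraclePredictor(dict(truth.true_logS))


def oracle_factory(truth):
    def factory(train: pd.DataFrame, early_stop: pd.DataFrame) -> OraclePredictor:
        return oracle(truth)

    return factory
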