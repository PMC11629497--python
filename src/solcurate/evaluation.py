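"""Weighted error metrics, molecule-aware cross-validation, and model comparison.

Metrics
-------
For predictions ȳ_i, observations y_i and record weights w_i over n records:

    RMSE   = sqrt( Σ (ȳ_i − y_i)² / n )
    cuRMSE = sqrt( Σ (w_i · (ȳ_i − y_i))² / n )

In the weighted variant the record weight scales the *error* of the record,
and the divisor is the record count n, **not** Σw — that is how the
"curated RMSE" behaves where it is used: a molecule split into two records
at weight ½ each, both off by 0.6, scores cuRMSE 0.3 where its RMSE is 0.6
— the error is artificially halved. This is exactly why cuRMSE is not
comparable to RMSE whenever weights fall below 1, and why the two metrics
are kept strictly apart, in separate labelled columns, in every report this
package writes.

``challenge_score`` maps an RMSE onto the 1000000·(2 − RMSE) scale some
blind prediction challenges use for ranking.

Cross-validation
----------------
``assign_folds`` partitions records into n outer folds either *by record*
or *by molecule* (all records sharing a connectivity key travel together —
stereoisomers and representation variants land in one fold, which is what
prevents duplicate leakage). Fold membership is derived from a stable
platform-independent hash of the record/molecule key and the seed: records
are ordered by hash and dealt into folds of equal size, so the assignment
is deterministic and insensitive to input order, and fold sizes are
balanced. Within each outer fold's training portion, a further hash-based
split sets aside 10% for early stopping, giving the familiar
0.81/0.09/0.10 train/early-stop/evaluation partition of the full table.

One :class:`FoldAssignment` can be reused across models, so different
algorithms are compared on exactly the same splits.

``bootstrap_ci`` resamples evaluated records with replacement to put a
percentile confidence interval on either metric; ``compare_models`` runs a
paired two-sided t-test on per-record squared errors of two prediction
tables over the identical record set.

``nested_validation`` implements the two-step protocol against
hyperparameter overfitting: the final model is built once on all data, but
its accuracy is estimated by re-running the *entire* development procedure
(including any tuning) inside each of n outer subsets and pooling the
held-out predictions. A tuner that peeks at its evaluation fold will score
better under a naive protocol than under this one — that gap is the
overfitting the protocol exists to expose.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FoldAssignment",
    "EvaluationResult",
    "ComparisonResult",
    "rmse",
    "curmse",
    "challenge_score",
    "assign_folds",
    "cross_validate",
    "bootstrap_ci",
    "compare_models",
    "nested_validation",
]


# --------------------------------------------------------------------------
# Metrics


def _errors(table: pd.DataFrame) -> np.ndarray:
    if len(table) == 0:
        raise ValueError("empty prediction table")
    return table["y_pred"].to_numpy(dtype=float) - table["y_obs"].to_numpy(dtype=float)


def rmse(table: pd.DataFrame) -> float:
    """Unweighted root-mean-squared error; weights are ignored."""
    e = _errors(table)
    return float(np.sqrt(np.mean(e**2)))


def curmse(table: pd.DataFrame) -> float:
    """Weighted RMSE with divisor n: sqrt(Σ (w_i e_i)² / n).

    The weight scales the record's error linearly, so a molecule whose k
    records each carry weight 1/k contributes a k-fold smaller error on the
    RMSE scale than the same molecule measured once. Reduces to
    :func:`rmse` when all weights are 1; monotone non-decreasing in every
    weight. Negative weights are rejected.
    """
    e = _errors(table)
    w = table["weight"].to_numpy(dtype=float)
    if np.any(w < 0):
        raise ValueError("negative record weight")
    return float(np.sqrt(np.sum((w * e) ** 2) / len(e)))


_METRICS: dict[str, Callable[[pd.DataFrame], float]] = {"rmse": rmse, "curmse": curmse}


def challenge_score(rmse_value: float) -> float:
    """Challenge ranking scale: 1000000 · (2 − RMSE)."""
    return 1_000_000.0 * (2.0 - rmse_value)


# --------------------------------------------------------------------------
# Fold assignment


def _stable_hash(text: str) -> int:
    """Platform-independent 64-bit hash (first 8 bytes of SHA-256)."""
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:8], "big")


@dataclass
class FoldAssignment:
    """Outer-fold indices plus inner train/early-stop roles per fold.

    ``folds`` maps record_id → outer fold in 0..n_folds−1. Under the
    ``by_molecule`` policy every record sharing a connectivity key carries
    the same outer fold. ``roles(k)`` partitions all record ids into the
    evaluation fold k, an early-stopping slice (10% of the remainder, by
    hash order) and the training rest — fractions ≈ 0.81/0.09/0.10.
    """

    folds: dict[str, int]
    n_folds: int
    policy: str
    seed: int
    _keys: dict[str, str]  # record_id -> hashing key (molecule or record)

    def fold_of(self, record_id: str) -> int:
        return self.folds[record_id]

    def roles(self, k: int) -> dict[str, list[str]]:
        if not (0 <= k < self.n_folds):
            raise ValueError(f"fold index {k} out of range 0..{self.n_folds - 1}")
        eval_ids = [r for r, f in self.folds.items() if f == k]
        pool = [r for r, f in self.folds.items() if f != k]
        # hash-ordered, molecule-aware inner split: 10% early stopping
        pool_keys = sorted(
            {self._keys[r] for r in pool},
            key=lambda key: (_stable_hash(f"{key}|{self.seed}|inner{k}"), key),
        )
        n_es_keys = int(round(0.1 * len(pool_keys)))
        es_keys = set(pool_keys[:n_es_keys])
        early = [r for r in pool if self._keys[r] in es_keys]
        train = [r for r in pool if self._keys[r] not in es_keys]
        return {"train": train, "early_stop": early, "eval": eval_ids}


def assign_folds(
    records: pd.DataFrame,
    n_folds: int = 10,
    policy: Literal["by_molecule", "by_record"] = "by_molecule",
    seed: int = 0,
) -> FoldAssignment:
    """Deterministic, order-insensitive n-fold partition of a record table.

    Keys (connectivity keys under ``by_molecule``, record ids under
    ``by_record``) are ordered by a stable hash of (key, seed) and dealt
    into ``n_folds`` contiguous blocks, so fold sizes differ by at most one
    key. Records inherit their molecule's fold under ``by_molecule`` —
    stereo variants of one skeleton can never straddle folds.
    """
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2, got {n_folds}")
    ids = records["record_id"].tolist()
    if policy == "by_molecule":
        if "connectivity_key" not in records.columns:
            raise ValueError("by_molecule policy requires standardized records")
        keys = dict(zip(ids, records["connectivity_key"].tolist()))
    elif policy == "by_record":
        keys = {r: r for r in ids}
    else:
        raise ValueError(f"unknown split policy {policy!r}")

    distinct = sorted(set(keys.values()))
    if len(distinct) < n_folds:
        raise ValueError(
            f"{len(distinct)} distinct {policy[3:]} keys < {n_folds} folds"
        )
    ordered = sorted(distinct, key=lambda key: (_stable_hash(f"{key}|{seed}"), key))
    n = len(ordered)
    fold_of_key = {key: (i * n_folds) // n for i, key in enumerate(ordered)}
    folds = {r: fold_of_key[keys[r]] for r in ids}
    return FoldAssignment(folds=folds, n_folds=n_folds, policy=policy, seed=seed, _keys=keys)


# --------------------------------------------------------------------------
# Cross-validation


def cross_validate(
    records: pd.DataFrame,
    model_factory: Callable[[pd.DataFrame, pd.DataFrame], object],
    folds: FoldAssignment,
    value_col: str = "logS",
) -> pd.DataFrame:
    """Out-of-fold predictions for every record.

    For each outer fold the factory is called with that fold's train and
    early-stop tables and the fitted predictor scores the evaluation fold.
    The concatenated table has one row per record with columns
    ``record_id, y_pred, y_obs, weight, fold`` and can be reused across
    models (identical folds → directly comparable results).
    """
    indexed = records.set_index("record_id", drop=False)
    parts = []
    for k in range(folds.n_folds):
        roles = folds.roles(k)
        train = indexed.loc[roles["train"]]
        early = indexed.loc[roles["early_stop"]]
        eval_df = indexed.loc[roles["eval"]]
        try:
            model = model_factory(train, early)
            preds = np.asarray(model.predict(eval_df), dtype=float)
        except Exception as exc:
            raise RuntimeError(f"model failed on fold {k}: {exc}") from exc
        parts.append(
            pd.DataFrame(
                {
                    "record_id": eval_df["record_id"].to_numpy(),
                    "y_pred": preds,
                    "y_obs": eval_df[value_col].to_numpy(dtype=float),
                    "weight": (
                        eval_df["weight"].to_numpy(dtype=float)
                        if "weight" in eval_df.columns
                        else np.ones(len(eval_df))
                    ),
                    "fold": k,
                }
            )
        )
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values("record_id", kind="stable").reset_index(drop=True)


# --------------------------------------------------------------------------
# Bootstrap and comparison


@dataclass(frozen=True)
class EvaluationResult:
    metric: str
    point: float
    ci_low: float
    ci_high: float
    level: float
    n_records: int
    n_replicates: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "n_records": self.n_records,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
        }


def bootstrap_ci(
    table: pd.DataFrame,
    metric: str = "rmse",
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> EvaluationResult:
    """Percentile bootstrap CI for a metric over a prediction table.

    Records (not molecules) are resampled with replacement B times; the
    interval is the empirical (1±level)/2 percentile pair. Deterministic
    per seed.
    """
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    fn = _METRICS[metric]
    point = fn(table)
    rng = np.random.default_rng(seed)
    n = len(table)
    e = table["y_pred"].to_numpy(dtype=float) - table["y_obs"].to_numpy(dtype=float)
    w = table["weight"].to_numpy(dtype=float) if metric == "curmse" else np.ones(n)
    we2 = (w * e) ** 2
    reps = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        reps[b] = np.sqrt(np.sum(we2[idx]) / n)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return EvaluationResult(metric, point, float(lo), float(hi), level, n, B, seed)


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    value_a: float
    value_b: float
    delta: float            # value_a - value_b
    p_value: float
    better: str             # "A", "B" or "tie"
    significant: bool       # p < 0.05

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "value_a": self.value_a,
            "value_b": self.value_b,
            "delta": self.delta,
            "p_value": self.p_value,
            "better": self.better,
            "significant": self.significant,
        }


def compare_models(
    table_a: pd.DataFrame, table_b: pd.DataFrame, metric: str = "rmse"
) -> ComparisonResult:
    """Paired two-sided t-test on per-record squared errors.

    Both tables must cover the identical record ids (same CV folds); rows
    are aligned by record id. A zero-variance difference is handled
    explicitly: all-equal errors give p = 1 (no evidence either way); a
    constant non-zero shift gives p = 0.
    """
    a = table_a.set_index("record_id").sort_index()
    b = table_b.set_index("record_id").sort_index()
    if not a.index.equals(b.index):
        raise ValueError("prediction tables cover different record sets")
    e2a = (a["y_pred"] - a["y_obs"]).to_numpy(dtype=float) ** 2
    e2b = (b["y_pred"] - b["y_obs"]).to_numpy(dtype=float) ** 2
    diff = e2a - e2b
    if np.allclose(diff.std(), 0.0):
        p = 1.0 if np.allclose(diff, 0.0) else 0.0
    else:
        p = float(stats.ttest_rel(e2a, e2b).pvalue)
    fn = _METRICS[metric]
    va, vb = fn(table_a), fn(table_b)
    if va < vb:
        better = "A"
    elif vb < va:
        better = "B"
    else:
        better = "tie"
    return ComparisonResult(metric, va, vb, va - vb, p, better, p < 0.05)


# --------------------------------------------------------------------------
# Nested validation


def nested_validation(
    records: pd.DataFrame,
    model_builder: Callable[[pd.DataFrame], object],
    n_subsets: int = 5,
    policy: Literal["by_molecule", "by_record"] = "by_molecule",
    seed: int = 0,
    metric: str = "rmse",
    bootstrap_B: int = 1000,
    value_col: str = "logS",
) -> tuple[EvaluationResult, pd.DataFrame]:
    """Two-step protocol: develop once on all data, validate by full re-runs.

    ``model_builder`` must encapsulate the *entire* development procedure —
    internal splits, early stopping, hyperparameter selection, everything —
    taking a record table and returning a fitted predictor. The data are
    divided into ``n_subsets``; for each, a model is developed from scratch
    on the other n−1 subsets and applied to the held-out one; the pooled
    held-out predictions estimate the accuracy of the model built on all
    data. Returns the pooled metric with a bootstrap CI and the pooled
    prediction table.
    """
    if n_subsets < 2:
        raise ValueError(f"n_subsets must be >= 2, got {n_subsets}")
    folds = assign_folds(records, n_folds=n_subsets, policy=policy, seed=seed)
    indexed = records.set_index("record_id", drop=False)
    parts = []
    for k in range(n_subsets):
        roles = folds.roles(k)
        dev = indexed.loc[roles["train"] + roles["early_stop"]]
        held = indexed.loc[roles["eval"]]
        model = model_builder(dev)
        preds = np.asarray(model.predict(held), dtype=float)
        parts.append(
            pd.DataFrame(
                {
                    "record_id": held["record_id"].to_numpy(),
                    "y_pred": preds,
                    "y_obs": held[value_col].to_numpy(dtype=float),
                    "weight": (
                        held["weight"].to_numpy(dtype=float)
                        if "weight" in held.columns
                        else np.ones(len(held))
                    ),
                    "fold": k,
                }
            )
        )
    table = pd.concat(parts, ignore_index=True).sort_values(
        "record_id", kind="stable"
    ).reset_index(drop=True)
    result = bootstrap_ci(table, metric=metric, B=bootstrap_B, seed=seed)
    return result, table
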