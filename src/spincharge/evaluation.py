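"""Model evaluation: per-atom/per-spin error metrics and spin-difference stats.

Metrics per (atom, spin) over held-out frames, with errors
e_i = predicted - reference:

* MAE  = mean |e_i|
* RMSE = sqrt(mean e_i^2)
* error std = sample standard deviation (n-1) of the signed errors
* Pearson r between predicted and reference charges

plus per-spin means over atoms (the "Mean" row of a performance table).
Spin-difference statistics summarise the per-atom distributions of
D31 = q_triplet - q_singlet and D53 = q_quintuplet - q_triplet with
histograms whose bins are centered on integer multiples of the bin width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ConfigError, DataError, UndefinedCorrelationError
from .forest import (
    FeaturizerSpec,
    ForestConfig,
    TrainedChargeModel,
    predict_frames,
    split_dataset,
    train_all,
)
from .structure import ATOM_NAMES, SPIN_STATES, ChargeTable, Dataset, SpinState


class Metrics(NamedTuple):
    mae: float
    rmse: float
    error_std: float
    pearson_r: float


def metrics(pred: Sequence[float], ref: Sequence[float]) -> Metrics:
    """MAE, RMSE, sample error std, and Pearson r of predicted vs reference."""
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise DataError("pred and ref must be 1-D of equal length")
    if p.size < 2:
        raise DataError("need at least 2 values")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(r))):
        raise DataError("non-finite values in metrics input")
    e = p - r
    mae = float(np.mean(np.abs(e)))
    rmse = float(np.sqrt(np.mean(e**2)))
    error_std = float(np.std(e, ddof=1))
    if np.std(p) == 0.0 or np.std(r) == 0.0:
        raise UndefinedCorrelationError(
            "Pearson correlation undefined for zero-variance input"
        )
    pearson = float(stats.pearsonr(p, r).statistic)
    return Metrics(mae, rmse, error_std, pearson)


@dataclass
class EvaluationReport:
    """Per-(atom, spin) metrics plus per-spin means and run metadata."""

    per_atom: pd.DataFrame  # columns: atom_index, atom, spin, mae, rmse, error_std, pearson_r
    per_spin: pd.DataFrame  # columns: spin, mean_mae, mean_rmse, mean_error_std, mean_pearson
    n_test: int
    scheme: str = ""

    def cell(self, atom: int, spin: SpinState) -> pd.Series:
        df = self.per_atom
        return df[(df.atom_index == atom) & (df.spin == spin.label)].iloc[0]

    def spin_mean(self, spin: SpinState, column: str = "mean_mae") -> float:
        df = self.per_spin
        return float(df[df.spin == spin.label][column].iloc[0])

    def to_csv(self, path) -> None:
        self.per_atom.to_csv(path, index=False, float_format="%.12g")


def evaluate_predictions(
    predictions: np.ndarray,
    references: np.ndarray,
    atom_index: np.ndarray,
    elements: Sequence[str] | None = None,
    scheme: str = "",
) -> EvaluationReport:
    """Build a report from stacked (n_frames, n_atoms, 3) charge arrays."""
    if predictions.shape != references.shape:
        raise DataError("prediction/reference shape mismatch")
    rows = []
    for a_pos, atom in enumerate(atom_index):
        name = (
            elements[a_pos]
            if elements is not None
            else ATOM_NAMES.get(int(atom), str(atom))
        )
        for s_i, spin in enumerate(SPIN_STATES):
            m = metrics(predictions[:, a_pos, s_i], references[:, a_pos, s_i])
            rows.append(
                {
                    "atom_index": int(atom),
                    "atom": ATOM_NAMES.get(int(atom), name),
                    "spin": spin.label,
                    "mae": m.mae,
                    "rmse": m.rmse,
                    "error_std": m.error_std,
                    "pearson_r": m.pearson_r,
                }
            )
    per_atom = pd.DataFrame(rows)
    per_spin = (
        per_atom.groupby("spin", sort=False)
        .agg(
            mean_mae=("mae", "mean"),
            mean_rmse=("rmse", "mean"),
            mean_error_std=("error_std", "mean"),
            mean_pearson=("pearson_r", "mean"),
        )
        .reset_index()
    )
    return EvaluationReport(
        per_atom=per_atom,
        per_spin=per_spin,
        n_test=predictions.shape[0],
        scheme=scheme,
    )


def evaluate_model(
    model: TrainedChargeModel, test: Dataset, scheme: str | None = None
) -> EvaluationReport:
    """Evaluate a trained model on held-out frames with reference charges."""
    if not test.tables:
        raise AlignmentError("test dataset carries no reference charges")
    if len(test) < 1:
        raise DataError("empty test set")
    preds = predict_frames(model, test.structures)
    atom_index = np.array(model.atom_indices)
    pred_arr = np.stack([p.q_mean for p in preds])
    ref_arr = np.stack(
        [
            t.charges[np.searchsorted(t.atom_index, atom_index)]
            for t in test.tables
        ]
    )
    return evaluate_predictions(
        pred_arr,
        ref_arr,
        atom_index,
        scheme=scheme if scheme is not None else model.featurizer.scheme,
    )


@dataclass
class SpinDifferenceStats:
    """Per-atom histograms and summaries of spin-to-spin charge differences."""

    bin_width: float
    per_atom: dict[int, dict[str, dict]]  # atom -> {"d31": {...}, "d53": {...}}

    def mode_center(self, atom: int, which: str) -> float:
        return self.per_atom[atom][which]["mode_center"]

    def mean(self, atom: int, which: str) -> float:
        return self.per_atom[atom][which]["mean"]

    def histogram(self, atom: int, which: str) -> pd.DataFrame:
        h = self.per_atom[atom][which]
        return pd.DataFrame(
            {
                "bin_left": h["edges"][:-1],
                "bin_right": h["edges"][1:],
                "count": h["counts"],
            }
        )


def _centered_histogram(x: np.ndarray, width: float):
    """Histogram with bin centers at integer multiples of ``width``."""
    k_lo = math.floor(x.min() / width + 0.5)
    k_hi = math.floor(x.max() / width + 0.5)
    edges = (np.arange(k_lo, k_hi + 2) - 0.5) * width
    counts, edges = np.histogram(x, bins=edges)
    mode_bin = int(np.argmax(counts))
    return {
        "edges": edges,
        "counts": counts,
        "mean": float(x.mean()),
        "mode_center": float((k_lo + mode_bin) * width),
    }


def spin_differences(
    tables: Iterable[ChargeTable], bin_width: float = 0.02
) -> SpinDifferenceStats:
    """Distributions of D31 = q_T - q_S and D53 = q_Q - q_T per atom."""
    if bin_width <= 0:
        raise ConfigError("bin_width must be positive")
    tables = list(tables)
    if not tables:
        raise DataError("no charge tables given")
    stacked = np.stack([t.charges for t in tables])  # (F, A, 3)
    atom_index = tables[0].atom_index
    per_atom: dict[int, dict[str, dict]] = {}
    for a_pos, atom in enumerate(atom_index):
        d31 = stacked[:, a_pos, 1] - stacked[:, a_pos, 0]
        d53 = stacked[:, a_pos, 2] - stacked[:, a_pos, 1]
        per_atom[int(atom)] = {
            "d31": _centered_histogram(d31, bin_width),
            "d53": _centered_histogram(d53, bin_width),
        }
    return SpinDifferenceStats(bin_width=bin_width, per_atom=per_atom)


def compare_descriptors(
    dataset: Dataset,
    schemes: Sequence[FeaturizerSpec],
    config: ForestConfig = ForestConfig(),
) -> tuple[dict[str, EvaluationReport], pd.DataFrame]:
    """Train and evaluate several featurization schemes on one identical split.

    Returns per-scheme reports plus a side-by-side RMSE table with the
    improvement of each scheme over the first one (positive delta = lower
    RMSE than the baseline scheme).
    """
    if len(schemes) < 2:
        raise ConfigError("need at least two schemes to compare")
    train, test = split_dataset(dataset, config.split_fraction, config.seed)
    reports: dict[str, EvaluationReport] = {}
    names = []
    for spec in schemes:
        name = spec.scheme
        if name in reports:
            name = f"{name}_{len(reports)}"
        model = train_all(train, spec, config)
        reports[name] = evaluate_model(model, test, scheme=name)
        names.append(name)
    base = names[0]
    wide = reports[base].per_atom[["atom_index", "atom", "spin", "rmse"]].rename(
        columns={"rmse": f"rmse_{base}"}
    )
    for name in names[1:]:
        other = reports[name].per_atom[["atom_index", "spin", "rmse"]].rename(
            columns={"rmse": f"rmse_{name}"}
        )
        wide = wide.merge(other, on=["atom_index", "spin"])
        wide[f"improvement_{name}"] = wide[f"rmse_{base}"] - wide[f"rmse_{name}"]
    return reports, wide


def sweep_m(
    dataset: Dataset,
    m_values: Sequence,
    featurizer: FeaturizerSpec,
    config: ForestConfig = ForestConfig(),
    atom: int = 0,
) -> pd.DataFrame:
    """Pearson r of one atom's predictions for a sweep of m specifications.

    Only the chosen atom's three spin models are retrained per m value;
    the split and all seeds are held fixed across the sweep.
    """
    from dataclasses import replace as _replace

    from .forest import _sub_seed, train_forest

    train, test = split_dataset(dataset, config.split_fraction, config.seed)
    feats_train = featurizer.features(train.structures)
    feats_test = featurizer.features(test.structures)
    a_pos = int(np.nonzero(train.tables[0].atom_index == atom)[0][0])
    X_train = featurizer.atom_features(feats_train, atom)
    X_test = featurizer.atom_features(feats_test, atom)
    rows = []
    for m_spec in m_values:
        cfg = _replace(config, m_spec=m_spec)
        rs = []
        for s_i, spin in enumerate(SPIN_STATES):
            y_train = np.array([t.charges[a_pos, s_i] for t in train.tables])
            y_test = np.array([t.charges[a_pos, s_i] for t in test.tables])
            forest = train_forest(
                X_train, y_train, cfg, seed=_sub_seed(cfg.seed, atom, spin)
            )
            pred = forest.predict(X_test)
            rs.append(metrics(pred, y_test).pearson_r)
        rows.append(
            {
                "m": str(m_spec),
                "pearson_singlet": rs[0],
                "pearson_triplet": rs[1],
                "pearson_quintuplet": rs[2],
                "pearson_mean": float(np.mean(rs)),
            }
        )
    return pd.DataFrame(rows)

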