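"""Microbiota maturity scoring and disease-state classification with random forests.

A random-forest regression trained on control samples predicts "microbiota
age" from composition. Microbial maturity (MM) is the predicted age minus
the median predicted age of control samples of similar age (same sampled
week by default); MAZ is MM divided by the standard deviation of control
predictions in that bin. Control predictions entering the bin statistics are
out-of-bag, so a control's own trees never score it.

Disease outcome (NAFLD or elevated HOMA-IR development) is classified per
week by random forests on rarefied counts with leave-one-out error and
permutation importance on the held-out predictions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .compositions import rarefy
from .io import OtuTable

log = logging.getLogger(__name__)


@dataclass
class AgeModel:
    forest: RandomForestRegressor
    oob_prediction: np.ndarray   # per training (control) sample
    train_index: np.ndarray      # indices of training samples in the source table

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forest.predict(np.asarray(X, dtype=float))


@dataclass
class MazResult:
    """Per-sample predicted age, microbial maturity, and MAZ."""

    predicted_age: np.ndarray
    mm: np.ndarray
    maz: np.ndarray
    bin_id: np.ndarray
    valid: np.ndarray            # False where the bin had no usable controls / zero SD

    def to_frame(self, sample_ids=None) -> pd.DataFrame:
        df = pd.DataFrame({"predicted_age": self.predicted_age, "MM": self.mm,
                           "MAZ": self.maz, "bin": self.bin_id, "valid": self.valid})
        if sample_ids is not None:
            df.index = list(sample_ids)
        return df


@dataclass
class RfReport:
    """Leave-one-out random-forest disease classification summary."""

    errors: pd.DataFrame        # trial x week LOO error
    importance: pd.DataFrame    # OTU x week mean increase error (%)
    n_trees: int
    mtry: int
    n_trials: int
    depth: int

    @property
    def mean_error(self) -> pd.Series:
        return self.errors.mean(axis=0)


def _mtry(d: int) -> int:
    return max(1, math.ceil(d / 3))


def fit_age_model(counts_controls: np.ndarray, ages, n_trees: int = 1000,
                  seed: int | None = 0) -> AgeModel:
    """Random-forest regression of age on control-sample composition.

    mtry is ceil(d/3) features per split; out-of-bag predictions for the
    training controls are retained for the MAZ reference statistics.
    """
    X = np.asarray(counts_controls, dtype=float)
    y = np.asarray(ages, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("training ages are constant; age is unlearnable")
    rf = RandomForestRegressor(n_estimators=n_trees, max_features=_mtry(X.shape[1]),
                               oob_score=True, bootstrap=True, random_state=seed,
                               n_jobs=1)
    rf.fit(X, y)
    return AgeModel(rf, rf.oob_prediction_, np.arange(X.shape[0]))


def maz_scores(model: AgeModel, counts_all: np.ndarray, ages,
               control_mask, bins=None) -> MazResult:
    """MM and MAZ for every sample against same-bin control references.

    ``bins`` defaults to the sampled age value itself (discrete weeks); pass
    a precomputed array for custom binning. Controls' own predicted ages are
    out-of-bag; other samples use the full forest.
    """
    X = np.asarray(counts_all, dtype=float)
    ages = np.asarray(ages, dtype=float)
    control_mask = np.asarray(control_mask, dtype=bool)
    n = X.shape[0]
    if bins is None:
        bins = ages.copy()
    bins = np.asarray(bins)

    pred = model.predict(X)
    # overwrite control predictions with their out-of-bag values
    ctrl_idx = np.where(control_mask)[0]
    if len(ctrl_idx) != len(model.oob_prediction):
        raise ValueError("control_mask does not match the model's training set")
    pred[ctrl_idx] = model.oob_prediction

    mm = np.full(n, np.nan)
    maz = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for b in np.unique(bins):
        in_bin = bins == b
        ctrl = in_bin & control_mask
        if ctrl.sum() < 2:
            log.warning("bin %r has <2 controls; samples flagged invalid", b)
            continue
        med = np.median(pred[ctrl])
        sd = pred[ctrl].std(ddof=1)
        mm[in_bin] = pred[in_bin] - med
        if sd == 0:
            log.warning("bin %r has zero control SD; MAZ undefined", b)
            continue
        maz[in_bin] = mm[in_bin] / sd
        valid[in_bin] = True
    return MazResult(pred, mm, maz, bins, valid)


def _loo_predictions(X: np.ndarray, y: np.ndarray, n_trees: int, seed,
                     rng) -> tuple[np.ndarray, list]:
    """Leave-one-out predicted labels and the per-fold fitted forests."""
    n = len(y)
    preds = np.empty(n, dtype=y.dtype)
    models = []
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        rf = RandomForestClassifier(n_estimators=n_trees,
                                    max_features=_mtry(X.shape[1]),
                                    random_state=seed, n_jobs=1)
        rf.fit(X[mask], y[mask])
        preds[i] = rf.predict(X[i][None])[0]
        models.append(rf)
        mask[i] = True
    return preds, models


def classify_disease(table: OtuTable, labels, weeks, n_trees: int = 1000,
                     depth: int = 1000, n_trials: int = 10,
                     seed: int | None = 0,
                     importance: bool = True) -> RfReport:
    """Per-week disease classification with LOO error over rarefaction trials.

    Each trial rarefies the table to ``depth`` reads per sample, then fits a
    leave-one-out random forest per sampled week. OTU importance is the mean
    increase in LOO error (%) when that OTU's held-out values are permuted.
    """
    labels = pd.Series(np.asarray(labels), index=table.sample_ids)
    weeks = pd.Series(np.asarray(weeks), index=table.sample_ids)
    rng = np.random.default_rng(seed)
    week_values = sorted(pd.unique(weeks))
    err_rows = []
    imp_acc = pd.DataFrame(0.0, index=table.otu_ids, columns=week_values)
    imp_n = pd.Series(0, index=week_values)
    for trial in range(n_trials):
        tseed = int(rng.integers(2 ** 31 - 1))
        sub = rarefy(table, depth=depth, seed=tseed)
        row = {}
        for w in week_values:
            ids = [s for s in sub.sample_ids if weeks[s] == w]
            yw = labels[ids].to_numpy()
            if len(np.unique(yw)) < 2:
                log.warning("week %s has a single class in trial %d; skipped", w, trial)
                continue
            Xw = sub.select_samples(np.isin(sub.sample_ids, ids)).counts.astype(float)
            preds, models = _loo_predictions(Xw, yw, n_trees, tseed, rng)
            row[w] = float(np.mean(preds != yw))
            if importance:
                d = Xw.shape[1]
                # one permutation per OTU, shared across folds
                perms = np.column_stack([rng.permutation(Xw[:, j])
                                         for j in range(d)])
                wrong = np.zeros(d)
                for i in range(len(yw)):
                    batch = np.tile(Xw[i], (d, 1))
                    batch[np.arange(d), np.arange(d)] = perms[i]
                    wrong += models[i].predict(batch) != yw[i]
                inc = wrong / len(yw) - row[w]
                imp_acc.loc[sub.otu_ids, w] += 100.0 * inc
                imp_n[w] += 1
        err_rows.append(row)
    errors = pd.DataFrame(err_rows)
    imp = imp_acc.div(imp_n.replace(0, np.nan), axis=1)
    return RfReport(errors, imp, n_trees, _mtry(table.n_otus), n_trials, depth)
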