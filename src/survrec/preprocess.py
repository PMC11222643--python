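"""Covariate encoding and train / test / external-test splitting.

Encoding rule: binary categoricals become a single 0/1 column; categoricals
with three or more levels are one-hot encoded — full dummies for the neural
models, reference-level-dropped for linear / propensity models (to avoid
collinearity).  Continuous covariates are standardized with statistics
computed on the fitting rows only, so no information leaks from test data.

The split mimics a registry study with a concealed external cohort: all
patients from one diagnosis year form the external test set; the remainder
is split 70/30 into training and testing (stratified by treatment and
event to stabilize small cohorts), and the training set is partitioned
into five cross-validation folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .cohort import CATEGORICAL_LEVELS

__all__ = ["DesignMatrix", "SplitPlan", "encode_covariates", "split_cohort"]

CONTINUOUS_COVARIATES = ["age", "tumor_size_mm", "positive_nodes"]
#: grade is ordinal 1-4 but enters the models as a 4-level categorical
CATEGORICAL_COVARIATES = ["grade", "histology", "location", "laterality",
                          "race", "marriage", "income"]


@dataclass
class DesignMatrix:
    """Encoded covariates plus everything needed to re-apply the encoding."""

    matrix: np.ndarray
    feature_names: list[str]
    encoding_map: dict                      # column -> list of (level, feature) pairs
    centers: dict                           # continuous column -> center
    scales: dict                            # continuous column -> scale
    scheme: str                             # "onehot_full" | "onehot_drop"

    def transform(self, cohort: pd.DataFrame) -> np.ndarray:
        """Apply the stored encoding to new rows (bit-identical on the
        fitting data).  Unseen category levels raise a ValueError naming
        the column and level."""
        cols = []
        for col in CONTINUOUS_COVARIATES:
            x = cohort[col].to_numpy(float)
            cols.append((x - self.centers[col]) / self.scales[col])
        for col in CATEGORICAL_COVARIATES:
            levels_here = set(map(str, cohort[col].unique()))
            known = {lev for lev, _ in self.encoding_map[col]}
            if col in self._dropped:
                known = known | {self._dropped[col]}
            unseen = levels_here - known
            if unseen:
                raise ValueError(
                    f"unseen category level(s) {sorted(unseen)} in column {col!r}")
            vals = cohort[col].astype(str).to_numpy()
            for lev, _feat in self.encoding_map[col]:
                cols.append((vals == lev).astype(float))
        return np.column_stack(cols) if cols else np.empty((len(cohort), 0))

    @property
    def _dropped(self) -> dict:
        return self.__dict__.setdefault("_dropped_levels", {})


def encode_covariates(cohort: pd.DataFrame, fit_on=None,
                      scheme: str = "onehot_full") -> DesignMatrix:
    """Fit the encoding on ``fit_on`` rows (positional indices; default all)
    and return the encoded matrix for the whole ``cohort``.

    scheme="onehot_full": indicator per level for >=3-level categoricals
    (neural models); scheme="onehot_drop": first level dropped as reference
    (linear and propensity models).  Binary categoricals always map to one
    0/1 column for the second level.
    """
    if scheme not in ("onehot_full", "onehot_drop"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if fit_on is None:
        fit_on = np.arange(len(cohort))
    fit_on = np.asarray(fit_on)
    if len(fit_on) == 0:
        raise ValueError("fit_on must be non-empty")
    fit_rows = cohort.iloc[fit_on]

    centers, scales = {}, {}
    for col in CONTINUOUS_COVARIATES:
        x = fit_rows[col].to_numpy(float)
        centers[col] = float(x.mean())
        s = float(x.std(ddof=1)) if len(x) > 1 else 0.0
        scales[col] = s if s > 0 else 1.0

    encoding_map: dict[str, list] = {}
    dropped: dict[str, str] = {}
    feature_names = list(CONTINUOUS_COVARIATES)
    for col in CATEGORICAL_COVARIATES:
        if col == "grade":
            levels = ["1", "2", "3", "4"]    # fixed histologic-grade codebook
        else:
            levels = [lev for lev in CATEGORICAL_LEVELS[col]
                      if lev in set(fit_rows[col].astype(str))]
        if len(levels) <= 1:
            encoding_map[col] = []           # constant column carries no signal
            if levels:
                dropped[col] = levels[0]
            continue
        if len(levels) == 2 or scheme == "onehot_drop":
            kept = levels[1:] if len(levels) == 2 else levels[1:]
            dropped[col] = levels[0]
        else:
            kept = levels
        encoding_map[col] = [(lev, f"{col}={lev}") for lev in kept]
        feature_names.extend(f for _, f in encoding_map[col])

    dm = DesignMatrix(matrix=np.empty((0, 0)), feature_names=feature_names,
                      encoding_map=encoding_map, centers=centers,
                      scales=scales, scheme=scheme)
    dm.__dict__["_dropped_levels"] = dropped
    dm.matrix = dm.transform(cohort)
    return dm


@dataclass
class SplitPlan:
    """Disjoint, exhaustive index sets (positional into the cohort)."""

    external: np.ndarray
    train: np.ndarray
    test: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]  # (fit_idx, val_idx) within train
    seed: int

    def to_json(self, cohort: pd.DataFrame) -> str:
        pid = cohort["patient_id"].to_numpy()
        payload = {
            "seed": self.seed,
            "external": pid[self.external].tolist(),
            "train": pid[self.train].tolist(),
            "test": pid[self.test].tolist(),
            "folds": [{"fit": pid[self.train[f]].tolist(),
                       "val": pid[self.train[v]].tolist()}
                      for f, v in self.folds],
        }
        return json.dumps(payload)


def split_cohort(cohort: pd.DataFrame, external_year: int, seed: int = 0,
                 test_fraction: float = 0.3, n_folds: int = 5) -> SplitPlan:
    """External set = all rows diagnosed in ``external_year``; remainder is
    split 70/30 (stratified by treatment x event); five CV folds partition
    the training set.  Deterministic given ``seed``."""
    years = cohort["diagnosis_year"].to_numpy(int)
    external = np.flatnonzero(years == external_year)
    rest = np.flatnonzero(years != external_year)
    if len(external) == 0:
        warnings.warn(f"no patients diagnosed in {external_year}; "
                      "external test set is empty", stacklevel=2)
    if len(rest) < 10:
        raise ValueError("fewer than 10 non-external patients; cannot split")

    strata = (cohort["treatment"].to_numpy(int)[rest] * 2
              + cohort["event"].to_numpy(int)[rest])
    # degenerate strata (fewer than 2 members) fall back to unstratified
    counts = np.bincount(strata, minlength=4)
    strat = strata if counts[counts > 0].min() >= 2 else None
    train, test = train_test_split(rest, test_size=test_fraction,
                                   random_state=seed, stratify=strat)
    train, test = np.sort(train), np.sort(test)

    fold_strata = (cohort["treatment"].to_numpy(int)[train] * 2
                   + cohort["event"].to_numpy(int)[train])
    fc = np.bincount(fold_strata, minlength=4)
    if fc[fc > 0].min() >= n_folds:
        kf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        fold_iter = kf.split(np.zeros(len(train)), fold_strata)
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(train))
        chunks = np.array_split(perm, n_folds)
        fold_iter = [(np.setdiff1d(np.arange(len(train)), c), np.sort(c))
                     for c in chunks]
    folds = [(np.asarray(f), np.asarray(v)) for f, v in fold_iter]
    return SplitPlan(external=external, train=train, test=test,
                     folds=folds, seed=seed)
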