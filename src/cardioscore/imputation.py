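"""Chained-equation multiple imputation (minimal MICE).

Mirrors the configuration used for clinical predictor tables with low
(percent-level) missingness: m completed datasets, a fixed number of chained
sweeps per dataset, predictive mean matching for continuous columns,
logistic regression for binary columns and polytomous (multinomial)
regression for categoricals, with the outcome entering every imputation
model as the Nelson-Aalen cumulative hazard at the subject's own follow-up
time together with the event indicator.

The table must be numeric (booleans as 0/1, categoricals integer-coded).
Columns imputed polytomously are one-hot encoded when they appear as
predictors.  Observed cells are never altered; a fixed seed makes the whole
procedure deterministic.  The default analysis downstream uses a single
randomly selected completed dataset; Rubin pooling across the m datasets is
a reporting option, not the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_model import OutcomeRecord
from .survival_stats import nelson_aalen

logger = logging.getLogger("cardioscore")

METHODS = ("pmm", "logistic", "polytomous")


@dataclass
class ImputationSpec:
    """MICE configuration: m datasets, sweeps per dataset, per-column methods."""

    methods: dict[str, str]
    m: int = 5
    iterations: int = 5
    seed: int = 0
    pmm_donors: int = 5

    def validate(self, df: pd.DataFrame) -> None:
        if self.m < 1 or self.iterations < 1:
            raise ValueError("m and iterations must be >= 1")
        for col, method in self.methods.items():
            if method not in METHODS:
                raise ValueError(f"unknown imputation method {method!r} for {col!r}")
        for col in df.columns:
            frac = df[col].isna().mean()
            if frac >= 0.5:
                raise ValueError(f"column {col!r} is >= 50% missing")
            if 0 < frac and col not in self.methods:
                raise ValueError(f"incomplete column {col!r} has no method assigned")


def nelson_aalen_outcome_covariate(outcomes: Sequence[OutcomeRecord]) -> np.ndarray:
    """Cumulative hazard of the event evaluated at each subject's own time.

    Used (with the event indicator) as the outcome's representation in every
    imputation model; order-equivariant with the input.
    """
    times = np.array([o.time for o in outcomes], dtype=float)
    events = np.array([o.status == 1 for o in outcomes], dtype=int)
    if events.sum() == 0:
        return np.zeros(len(outcomes))
    H = nelson_aalen(times, events)
    return np.array([H.at(t) for t in times])


def _one_hot(values: np.ndarray, levels: np.ndarray) -> np.ndarray:
    # drop-first coding to avoid collinearity with the intercept
    return (values[:, None] == levels[None, 1:]).astype(float)


def _design(df: pd.DataFrame, target: str, methods: dict[str, str]) -> np.ndarray:
    cols = []
    for col in df.columns:
        if col == target:
            continue
        v = df[col].to_numpy(dtype=float)
        if methods.get(col) == "polytomous":
            cols.append(_one_hot(v, np.unique(v)))
        else:
            cols.append(v[:, None])
    X = np.hstack(cols) if cols else np.empty((len(df), 0))
    # drop degenerate predictor columns to keep the inner fits well posed
    keep = np.ptp(X, axis=0) > 0
    return X[:, keep]


def _impute_pmm(y_obs, X_obs, X_mis, k, rng):
    Xo = np.column_stack([np.ones(len(X_obs)), X_obs])
    Xm = np.column_stack([np.ones(len(X_mis)), X_mis])
    beta, *_ = np.linalg.lstsq(Xo, y_obs, rcond=None)
    pred_obs = Xo @ beta
    pred_mis = Xm @ beta
    out = np.empty(len(X_mis))
    for i, pm in enumerate(pred_mis):
        dist = np.abs(pred_obs - pm)
        donors = np.argsort(dist, kind="stable")[: min(k, len(y_obs))]
        out[i] = y_obs[donors[rng.integers(0, len(donors))]]
    return out


def _impute_logistic(y_obs, X_obs, X_mis, rng, multinomial=False):
    from sklearn.linear_model import LogisticRegression

    classes = np.unique(y_obs)
    if classes.size < 2:
        raise ValueError("cannot fit a classifier on a single observed class")
    model = LogisticRegression(max_iter=500)
    model.fit(X_obs, y_obs)
    probs = model.predict_proba(X_mis)
    draws = np.array([rng.choice(model.classes_, p=p) for p in probs])
    return draws


def mice_impute(
    df: pd.DataFrame, spec: ImputationSpec
) -> tuple[list[pd.DataFrame], dict]:
    """Run chained-equation imputation; returns m completed tables + diagnostics.

    Columns are visited in ascending-missingness order within each sweep.
    Diagnostics hold per-iteration column means of the imputed cells, one
    trace per chain, for visual convergence assessment.
    """
    spec.validate(df)
    missing_mask = df.isna()
    incomplete = [c for c in df.columns if missing_mask[c].any()]
    for col in incomplete:
        obs = df[col].dropna()
        if obs.nunique() < 2:
            raise ValueError(f"column {col!r} has a single observed value")
    # visit order: ascending missingness
    incomplete.sort(key=lambda c: missing_mask[c].mean())

    rng = np.random.default_rng(spec.seed)
    completed: list[pd.DataFrame] = []
    traces: dict[str, list[list[float]]] = {c: [] for c in incomplete}

    for _chain in range(spec.m):
        work = df.copy()
        # initial fill: random draws from the observed values
        for col in incomplete:
            obs_vals = df[col].dropna().to_numpy()
            idx = missing_mask[col]
            work.loc[idx, col] = rng.choice(obs_vals, size=int(idx.sum()))
        chain_trace: dict[str, list[float]] = {c: [] for c in incomplete}
        for _sweep in range(spec.iterations):
            for col in incomplete:
                method = spec.methods[col]
                obs_rows = (~missing_mask[col]).to_numpy()
                mis_rows = missing_mask[col].to_numpy()
                X = _design(work, col, spec.methods)
                y_obs = df.loc[obs_rows, col].to_numpy(dtype=float)
                if method == "pmm":
                    imputed = _impute_pmm(y_obs, X[obs_rows], X[mis_rows],
                                          spec.pmm_donors, rng)
                else:
                    imputed = _impute_logistic(y_obs, X[obs_rows], X[mis_rows], rng,
                                               multinomial=(method == "polytomous"))
                work.loc[mis_rows, col] = imputed
                chain_trace[col].append(float(work.loc[mis_rows, col].mean()))
        for col in incomplete:
            traces[col].append(chain_trace[col])
        completed.append(work)

    diagnostics = {
        "imputed_cell_means": traces,  # col -> [chain][iteration]
        "n_missing": {c: int(missing_mask[c].sum()) for c in incomplete},
        "visit_order": incomplete,
    }
    return completed, diagnostics


def select_single_dataset(
    tables: Sequence[pd.DataFrame], seed: int
) -> tuple[pd.DataFrame, int]:
    """Uniform seeded choice of one completed dataset; the index is returned
    and logged."""
    if len(tables) == 0:
        raise ValueError("no completed datasets to select from")
    idx = int(np.random.default_rng(seed).integers(0, len(tables)))
    logger.info("selected imputed dataset %d of %d", idx, len(tables))
    return tables[idx], idx
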