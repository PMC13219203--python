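"""Case/control cohort construction and non-genetic feature preparation.

Cases are split by comparing the earliest target-disease diagnosis against a
per-participant baseline time (pre-baseline and self-reported cases train,
incident cases test); controls are sampled uniformly from participants never
diagnosed with the target. Feature preparation covers train-learned
imputation, a missingness filter, and univariable logistic screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sequence_io import EventSequence

__all__ = [
    "Participant",
    "CohortSplit",
    "assign_case_split",
    "build_control_pool",
    "sample_controls",
    "impute_features",
    "filter_missingness",
    "screen_candidates",
    "build_cohort",
]


@dataclass
class Participant:
    sample_id: str
    baseline_time: float
    self_report_target: bool
    sequence: EventSequence
    features: dict = field(default_factory=dict)
    prs: float = 0.0


@dataclass
class CohortSplit:
    train_cases: list[str]
    test_cases: list[str]
    train_controls: list[str] = field(default_factory=list)
    test_controls: list[str] = field(default_factory=list)
    control_pool: list[str] = field(default_factory=list)

    def all_ids(self) -> list[str]:
        return (
            self.train_cases + self.train_controls
            + self.test_cases + self.test_controls
        )

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(i, "train", "case") for i in self.train_cases]
            + [(i, "train", "control") for i in self.train_controls]
            + [(i, "test", "case") for i in self.test_cases]
            + [(i, "test", "control") for i in self.test_controls]
        )
        return pd.DataFrame(rows, columns=["sample_id", "split", "role"])


def first_diagnosis_time(seq: EventSequence, target_code: str) -> float | None:
    for ev in seq.events:
        if ev.code == target_code:
            return ev.time
    return None


def assign_case_split(participant: Participant, target_code: str) -> str:
    """Route a participant to "train", "test" or "not-case".

    Earliest target diagnosis before baseline -> train; at or after baseline
    -> test; a self-report of the target disease -> train regardless.
    """
    if participant.self_report_target:
        return "train"
    t = first_diagnosis_time(participant.sequence, target_code)
    if t is None:
        return "not-case"
    return "train" if t < participant.baseline_time else "test"


def build_control_pool(
    participants: Iterable[Participant], target_code: str
) -> list[str]:
    """Ids never diagnosed with (and never self-reporting) the target."""
    return [
        p.sample_id
        for p in participants
        if not p.self_report_target
        and first_diagnosis_time(p.sequence, target_code) is None
    ]


def sample_controls(
    pool: Sequence[str], n_train: int, n_test: int, seed: int
) -> tuple[list[str], list[str]]:
    """Uniform sampling without replacement into disjoint train/test controls."""
    if len(pool) < n_train + n_test:
        raise ValueError(
            f"control pool has {len(pool)} samples, need {n_train + n_test} "
            f"(shortfall {n_train + n_test - len(pool)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(sorted(pool), size=n_train + n_test, replace=False)
    return list(chosen[:n_train]), list(chosen[n_train:])


def build_cohort(
    participants: Iterable[Participant], target_code: str, seed: int
) -> CohortSplit:
    """Full split: case assignment, control pool and matched control sampling."""
    train_cases, test_cases = [], []
    plist = list(participants)
    for p in plist:
        where = assign_case_split(p, target_code)
        if where == "train":
            train_cases.append(p.sample_id)
        elif where == "test":
            test_cases.append(p.sample_id)
    pool = build_control_pool(plist, target_code)
    train_controls, test_controls = sample_controls(
        pool, len(train_cases), len(test_cases), seed
    )
    return CohortSplit(
        train_cases=train_cases,
        test_cases=test_cases,
        train_controls=train_controls,
        test_controls=test_controls,
        control_pool=pool,
    )


def filter_missingness(table: pd.DataFrame, max_rate: float = 0.05) -> pd.DataFrame:
    """Drop feature columns whose missing fraction exceeds ``max_rate``.

    The boundary rate is kept (the rule is "more than"); computed before
    any imputation.
    """
    rates = table.isna().mean()
    keep = [c for c in table.columns if rates[c] <= max_rate]
    return table[keep]


def impute_features(
    table: pd.DataFrame,
    schema: Mapping[str, str],
    train_mask: np.ndarray | pd.Series,
) -> tuple[pd.DataFrame, dict]:
    """Fill missing values with train-split mode (categorical) / median (numeric).

    Imputation values are learned on training rows only and applied
    everywhere; observed values are never altered. Columns entirely missing
    in the training rows are dropped with a warning. Returns the imputed
    table and the learned fill values.
    """
    train_mask = np.asarray(train_mask, dtype=bool)
    out = table.copy()
    fills: dict = {}
    for col, kind in schema.items():
        if col not in out.columns:
            continue
        train_vals = out.loc[train_mask, col].dropna()
        if train_vals.empty:
            warnings.warn(f"feature {col!r} entirely missing in train; dropped",
                          stacklevel=2)
            out = out.drop(columns=[col])
            continue
        if kind == "categorical":
            fill = train_vals.mode(dropna=True).iloc[0]
        elif kind == "numeric":
            fill = float(train_vals.astype(float).median())
        else:
            raise ValueError(f"unknown column type {kind!r} for {col!r}")
        fills[col] = fill
        out[col] = out[col].fillna(fill)
    return out, fills


def _logistic_pvalue(x: pd.Series, y: np.ndarray, kind: str) -> float:
    """Univariable logistic p-value for one feature.

    Numeric features: Wald p of the slope from a statsmodels Logit fit.
    Categorical features: likelihood-ratio test of the one-hot model against
    the intercept-only model. Falls back to a rank / contingency test when
    the fit does not converge (e.g. perfect separation).
    """
    import statsmodels.api as sm

    if kind == "categorical":
        X = pd.get_dummies(x.astype(str), drop_first=True, dtype=float)
        if X.shape[1] == 0:
            raise ValueError("constant feature")
    else:
        xv = x.astype(float)
        if xv.nunique() < 2:
            raise ValueError("constant feature")
        X = pd.DataFrame({"x": (xv - xv.mean()) / (xv.std() or 1.0)})
    Xc = sm.add_constant(X.to_numpy())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if kind == "categorical":
            p = float(fit.llr_pvalue)
        else:
            p = float(fit.pvalues[1])
        if np.isfinite(p):
            return p
    except Exception:
        pass
    # fallback: separation-robust tests
    if kind == "categorical":
        tab = pd.crosstab(x.astype(str), y)
        return float(stats.chi2_contingency(tab)[1])
    a = x.astype(float)[y == 1]
    b = x.astype(float)[y == 0]
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def screen_candidates(
    table: pd.DataFrame,
    labels: Sequence[int],
    schema: Mapping[str, str],
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Univariable logistic screening on the training split only.

    Keeps features with p <= ``alpha`` (boundary kept: the exclusion rule is
    "p > alpha"). Non-testable features (constant, unfittable) are excluded
    with a reason. Returns (kept feature names, per-feature report).
    """
    y = np.asarray(labels, dtype=int)
    kept, rows = [], []
    for col in table.columns:
        kind = schema.get(col, "numeric")
        try:
            p = _logistic_pvalue(table[col], y, kind)
        except Exception as exc:
            rows.append({"feature": col, "pval": np.nan, "kept": False,
                         "reason": f"untestable: {exc}"})
            continue
        keep = p <= alpha
        if keep:
            kept.append(col)
        rows.append({"feature": col, "pval": p, "kept": keep, "reason": ""})
    return kept, pd.DataFrame(rows)
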