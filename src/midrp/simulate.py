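"""Synthetic generators with exported ground truth for every pipeline stage.

Three families of inputs are produced: (1) comorbidity-structured diagnosis
sequences from a first-order Markov chain with exponential waiting times and
planted precursor -> target transition enrichment; (2) a liability-model
cohort with known genetic and non-genetic effects (plus a generator that
samples directly from the integrator's own model family); (3) exposure /
outcome GWAS summary-statistic pairs with planted causal effects, LD
structure, allele flips and palindromic variants. Every generator is
bit-reproducible under a fixed seed and exports the quantities needed for
oracle-based tests (transition matrix, true effects, Bayes scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mr import GWAS_COLUMNS

__all__ = [
    "SequenceSimConfig",
    "CohortSimConfig",
    "GwasSimConfig",
    "simulate_event_sequences",
    "simulate_cohort",
    "simulate_gwas_pair",
    "simulate_midrp_records",
    "markov_bayes_accuracy",
]


def _code_names(n: int) -> list[str]:
    return [f"{chr(ord('A') + i // 100)}{i % 100:02d}" for i in range(n)]


@dataclass
class SequenceSimConfig:
    seed: int = 0
    n_samples: int = 500
    n_codes: int = 20
    min_len: int = 3
    max_len: int = 30
    mean_gap_days: float = 30.0
    dominance: float = 0.6          # weight of each row's preferred next code
    dirichlet_conc: float = 1.0
    target_code: str | None = None  # defaults to the last code
    comorbidity_boost: float = 1.0  # multiplier on precursor -> target transitions
    n_precursors: int = 0


@dataclass
class CohortSimConfig:
    seed: int = 0
    intercept: float = -1.0
    prs_effect: float = 1.0
    feature_effects: tuple = (0.5, -0.5)
    precursor_effect: float = 0.0
    n_categorical: int = 1
    categorical_effect: float = 0.5
    missing_rate: float = 0.02
    self_report_rate: float = 0.02


@dataclass
class GwasSimConfig:
    seed: int = 0
    n_instruments: int = 50
    true_effect: float = 0.3
    se_x: float = 0.005
    se_y: float = 0.02
    beta_x_low: float = 0.05
    beta_x_high: float = 0.2
    n_weak: int = 10            # null variants that fail the p-value filter
    n_palindromic: int = 2
    n_flipped: int = 3          # outcome rows stored on swapped alleles
    n_ld_pairs: int = 1         # planted in-window high-r2 duplicates
    ld_r2: float = 0.9
    maf_low: float = 0.1
    maf_high: float = 0.5


# ---------------------------------------------------------------------------
# event sequences
# ---------------------------------------------------------------------------

def _build_transition_matrix(cfg: SequenceSimConfig, rng: np.random.Generator):
    n = cfg.n_codes
    base = rng.dirichlet(np.full(n, cfg.dirichlet_conc), size=n)
    preferred = rng.permutation(n)
    P = (1.0 - cfg.dominance) * base
    P[np.arange(n), preferred] += cfg.dominance
    codes = _code_names(n)
    target = cfg.target_code or codes[-1]
    t_idx = codes.index(target)
    precursors = []
    if cfg.n_precursors > 0 and cfg.comorbidity_boost != 1.0:
        candidates = [i for i in range(n) if i != t_idx]
        precursors = list(rng.choice(candidates, size=cfg.n_precursors, replace=False))
        for i in precursors:
            P[i, t_idx] *= cfg.comorbidity_boost
    P /= P.sum(axis=1, keepdims=True)
    return P, codes, target, [codes[i] for i in precursors]


def simulate_event_sequences(cfg: SequenceSimConfig):
    """Markov diagnosis sequences with exponential waiting times.

    Returns ``(events_df, truth)`` where the events table uses the pipeline's
    TSV dialect (sample_id, icd10, admission_time in days) and ``truth``
    carries the realized transition matrix, initial distribution, code list,
    target code and planted precursor codes.
    """
    rng = np.random.default_rng(cfg.seed)
    P, codes, target, precursors = _build_transition_matrix(cfg, rng)
    init = np.full(cfg.n_codes, 1.0 / cfg.n_codes)
    rows = []
    for s in range(cfg.n_samples):
        sid = f"S{s:06d}"
        length = int(rng.integers(cfg.min_len, cfg.max_len + 1))
        state = rng.choice(cfg.n_codes, p=init)
        t = 0.0
        for i in range(length):
            rows.append((sid, codes[state], t))
            t += float(rng.exponential(cfg.mean_gap_days))
            state = rng.choice(cfg.n_codes, p=P[state])
    events = pd.DataFrame(rows, columns=["sample_id", "icd10", "admission_time"])
    truth = {
        "codes": codes,
        "transition_matrix": P,
        "initial_distribution": init,
        "target_code": target,
        "precursor_codes": precursors,
        "config": cfg,
    }
    return events, truth


def markov_bayes_accuracy(prev_states: np.ndarray, P: np.ndarray) -> float:
    """Analytic Bayes next-event accuracy over the given predecessor states.

    An oracle that knows the chain predicts the argmax of each transition
    row; its expected accuracy is the mean row maximum.
    """
    return float(np.mean(P[np.asarray(prev_states)].max(axis=1)))


# ---------------------------------------------------------------------------
# liability-model cohort
# ---------------------------------------------------------------------------

def simulate_cohort(cfg: CohortSimConfig, events: pd.DataFrame, truth: dict):
    """Participants with PRS, features, labels and baseline times.

    Labels follow a logistic liability over the PRS, numeric/categorical
    features and a planted-precursor indicator; per-sample true logits are
    exported as ``bayes_logit`` for oracle comparisons. Baselines are drawn
    uniformly over each sample's observed time span so pre- and
    post-baseline first diagnoses both occur.
    """
    rng = np.random.default_rng(cfg.seed)
    grouped = events.groupby("sample_id")
    sids = sorted(grouped.groups)
    n = len(sids)
    span = grouped["admission_time"].max().reindex(sids).to_numpy(dtype=float)
    precursors = set(truth.get("precursor_codes", []))
    has_pre = (
        events[events["icd10"].isin(precursors)].groupby("sample_id").size()
        .reindex(sids).fillna(0).to_numpy()
        > 0
    ).astype(float)

    prs = rng.standard_normal(n)
    k_num = len(cfg.feature_effects)
    numeric = rng.standard_normal((n, k_num))
    logit = (
        cfg.intercept
        + cfg.prs_effect * prs
        + numeric @ np.asarray(cfg.feature_effects)
        + cfg.precursor_effect * has_pre
    )
    cat_cols = {}
    for c in range(cfg.n_categorical):
        levels = rng.choice(["A", "B", "C"], size=n)
        cat_cols[f"cat{c}"] = levels
        logit = logit + cfg.categorical_effect * (levels == "A").astype(float)
    label = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    baseline = rng.uniform(0.0, np.maximum(span, 1.0) * 1.2)
    self_report = (rng.random(n) < cfg.self_report_rate) & label

    table = pd.DataFrame(
        {
            "sample_id": sids,
            "baseline_time": baseline,
            "self_report": self_report.astype(bool),
            "prs": prs,
            "label": label.astype(int),
            "bayes_logit": logit,
        }
    )
    for j in range(k_num):
        table[f"num{j}"] = numeric[:, j]
    for name, vals in cat_cols.items():
        table[name] = vals
    # inject missingness into the feature columns only
    feat_cols = [f"num{j}" for j in range(k_num)] + list(cat_cols)
    for col in feat_cols:
        hole = rng.random(n) < cfg.missing_rate
        table.loc[hole, col] = np.nan
    cohort_truth = {"config": cfg, "feature_columns": feat_cols}
    return table, cohort_truth


def simulate_midrp_records(
    n: int,
    factor_dims: Sequence[int],
    w_s: float,
    gamma: np.ndarray,
    W: Sequence[np.ndarray] | None = None,
    b_s: float = 0.0,
    seed: int = 0,
):
    """Sample labelled records directly from the integrator's model family.

    ``y ~ Bernoulli(sigmoid(R_true))`` with the risk score of the known
    parameters; returns ``(x_s, factors, y, truth)`` where
    ``truth["bayes_score"]`` holds the per-sample true risk (the
    Bayes-optimal ranking score).
    """
    from . import integrator

    rng = np.random.default_rng(seed)
    gamma = np.asarray(gamma, dtype=float)
    if W is None:
        W = [rng.normal(0.0, 1.0, size=(d, 2)) for d in factor_dims]
    params = {"w_s": np.array(float(w_s)), "b_s": np.array(float(b_s)),
              "W": [np.asarray(w, dtype=float) for w in W], "gamma": gamma}
    x_s = rng.standard_normal(n)
    factors = [rng.standard_normal((n, d)) for d in factor_dims]
    score = np.asarray(integrator.risk_score(x_s, factors, params))
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-score))).astype(int)
    truth = {"params": params, "bayes_score": score}
    return x_s, factors, y, truth


# ---------------------------------------------------------------------------
# GWAS pairs
# ---------------------------------------------------------------------------

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A")]


def simulate_gwas_pair(cfg: GwasSimConfig):
    """Exposure GWAS, two independent outcome GWAS, LD matrix and positions.

    Instrument exposure betas are strong and common; the two outcome tables
    share the causal signal ``true_effect * beta_x`` but carry independent
    noise at ``se_y``. Weak null variants, allele-swapped outcome rows,
    palindromic variants and near-duplicate high-r² pairs are injected to
    exercise filtering, harmonization and clumping.
    """
    rng = np.random.default_rng(cfg.seed)
    n_main = cfg.n_instruments
    ids = [f"rs{i:06d}" for i in range(n_main + cfg.n_weak + cfg.n_ld_pairs
                                       + cfg.n_palindromic)]
    n_total = len(ids)

    sign = rng.choice([-1.0, 1.0], size=n_total)
    beta_true = sign * rng.uniform(cfg.beta_x_low, cfg.beta_x_high, size=n_total)
    beta_true[n_main: n_main + cfg.n_weak] = 0.0  # weak variants: no signal
    ld_src = rng.choice(n_main, size=cfg.n_ld_pairs, replace=False)
    for k, src in enumerate(ld_src):
        beta_true[n_main + cfg.n_weak + k] = beta_true[src]  # LD proxies

    eaf = rng.uniform(cfg.maf_low, cfg.maf_high, size=n_total)
    alleles = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(n_total)]
    for k in range(cfg.n_palindromic):
        alleles[n_total - 1 - k] = ("A", "T")
        beta_true[n_total - 1 - k] = sign[n_total - 1 - k] * cfg.beta_x_high

    beta_x = beta_true + rng.normal(0.0, cfg.se_x, size=n_total)
    pval_x = np.maximum(2.0 * stats.norm.sf(np.abs(beta_x / cfg.se_x)), 1e-300)
    exposure = pd.DataFrame(
        {
            "variant_id": ids,
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "eaf": eaf,
            "beta": beta_x,
            "se": cfg.se_x,
            "pval": pval_x,
        }
    )[list(GWAS_COLUMNS)]

    outcomes = []
    flip_idx = set(rng.choice(n_main, size=min(cfg.n_flipped, n_main),
                              replace=False).tolist())
    for rep in range(2):
        beta_y = cfg.true_effect * beta_true + rng.normal(0.0, cfg.se_y,
                                                          size=n_total)
        ea = [a for a, _ in alleles]
        oa = [b for _, b in alleles]
        eaf_y = eaf.copy()
        by = beta_y.copy()
        if rep == 1:  # second study stores some variants on the swapped allele
            for i in flip_idx:
                ea[i], oa[i] = oa[i], ea[i]
                by[i] = -by[i]
                eaf_y[i] = 1.0 - eaf_y[i]
        pv = np.maximum(2.0 * stats.norm.sf(np.abs(by / cfg.se_y)), 1e-300)
        outcomes.append(
            pd.DataFrame(
                {
                    "variant_id": ids,
                    "effect_allele": ea,
                    "other_allele": oa,
                    "eaf": eaf_y,
                    "beta": by,
                    "se": cfg.se_y,
                    "pval": pv,
                }
            )[list(GWAS_COLUMNS)]
        )

    # positions: spaced 20 Mb apart (outside any 10 Mb clump window), with the
    # planted LD proxies placed adjacent to their source variants
    pos = 20_000_000 * (1 + np.arange(n_total, dtype=float))
    ld_rows = []
    for k, src in enumerate(ld_src):
        dup = n_main + cfg.n_weak + k
        pos[dup] = pos[src] + 1000.0
        ld_rows.append((ids[src], ids[dup], cfg.ld_r2))
    positions = pd.DataFrame({"variant_id": ids, "chrom": 1, "pos": pos})
    ld = pd.DataFrame(ld_rows, columns=["variant_id_1", "variant_id_2", "r2"])

    truth = {
        "true_effect": cfg.true_effect,
        "instrument_ids": ids[:n_main],
        "ld_pairs": [(ids[s], ids[n_main + cfg.n_weak + k])
                     for k, s in enumerate(ld_src)],
        "config": cfg,
    }
    return exposure, outcomes[0], outcomes[1], ld, positions, truth
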