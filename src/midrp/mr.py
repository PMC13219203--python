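"""Two-sample Mendelian randomization feature selection.

For every candidate lifestyle/physical exposure: filter GWAS rows into
strong, common instruments; drop user-listed confounder SNPs; LD-clump;
harmonize against each of two outcome GWAS; run inverse-variance-weighted
MR on each pair; pool the two estimates with a fixed-effect meta-analysis;
and apply a four-part decision rule (fixed-effect p, I-squared, Cochran-Q
heterogeneity p, and a confidence interval excluding zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MrEstimate",
    "MetaResult",
    "EstimationError",
    "GWAS_COLUMNS",
    "read_gwas",
    "filter_instruments",
    "exclude_confounder_snps",
    "ld_clump",
    "harmonize",
    "ivw",
    "fixed_effect_meta",
    "decide_causal",
    "select_causal_features",
]

GWAS_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
)

_PALINDROMIC = {frozenset({"A", "T"}), frozenset({"C", "G"})}


class EstimationError(ValueError):
    """No usable instruments for an MR estimate."""


@dataclass(frozen=True)
class MrEstimate:
    beta: float
    se: float
    pval: float


@dataclass(frozen=True)
class MetaResult:
    pooled_beta: float
    pooled_se: float
    fixed_p: float
    ci_low: float
    ci_high: float
    Q: float
    het_p: float
    I2: float


def read_gwas(path) -> pd.DataFrame:
    """Read a summary-statistics TSV with the seven canonical columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS table {path} is missing columns: {missing}")
    if df["variant_id"].duplicated().any():
        dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValueError(f"duplicate variant_id {dup!r} in {path}")
    if (df["se"] <= 0).any():
        raise ValueError(f"non-positive standard errors in {path}")
    return df


def filter_instruments(
    exposure: pd.DataFrame, p_max: float = 1e-5, maf_min: float = 0.01
) -> pd.DataFrame:
    """Keep strongly associated, common variants.

    Rows survive iff ``pval <= p_max`` and ``min(eaf, 1 - eaf) >= maf_min``.
    """
    maf = np.minimum(exposure["eaf"], 1.0 - exposure["eaf"])
    kept = exposure[(exposure["pval"] <= p_max) & (maf >= maf_min)].reset_index(drop=True)
    if kept.empty:
        warnings.warn("no instruments survive the p-value/MAF filter", stacklevel=2)
    return kept


def exclude_confounder_snps(
    instruments: pd.DataFrame, exclusion_list: Iterable[str]
) -> pd.DataFrame:
    """Drop variants named on a (user-supplied) confounder exclusion list."""
    excl = set(exclusion_list)
    kept = instruments[~instruments["variant_id"].isin(excl)].reset_index(drop=True)
    if kept.empty and not instruments.empty:
        warnings.warn("exclusion list removed every instrument", stacklevel=2)
    return kept


def _ld_lookup(ld: pd.DataFrame | None) -> dict[frozenset, float]:
    table: dict[frozenset, float] = {}
    if ld is not None:
        for row in ld.itertuples():
            table[frozenset({row.variant_id_1, row.variant_id_2})] = float(row.r2)
    return table


def ld_clump(
    instruments: pd.DataFrame,
    ld: pd.DataFrame | None = None,
    positions: pd.DataFrame | None = None,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
) -> pd.DataFrame:
    """Greedy LD pruning by ascending exposure p-value.

    A variant is kept unless its r² with an already-kept variant inside
    ``window_kb`` exceeds ``r2_max``. ``ld`` is a long-format table
    (variant_id_1, variant_id_2, r2); ``positions`` maps variant_id to
    (chrom, pos). Missing r² for an in-window pair is treated as 1
    (unverifiable independence is never assumed); without a position table
    every pair counts as in-window.
    """
    if instruments.empty:
        return instruments
    table = _ld_lookup(ld)
    pos: dict[str, tuple] = {}
    if positions is not None:
        for row in positions.itertuples():
            chrom = getattr(row, "chrom", 0)
            pos[row.variant_id] = (chrom, float(row.pos))
    ordered = instruments.sort_values("pval", kind="stable")
    kept_ids: list[str] = []
    for row in ordered.itertuples():
        vid = row.variant_id
        ok = True
        for other in kept_ids:
            if pos:
                a, b = pos.get(vid), pos.get(other)
                in_window = (
                    a is not None
                    and b is not None
                    and a[0] == b[0]
                    and abs(a[1] - b[1]) <= window_kb * 1000.0
                )
            else:
                in_window = True
            if not in_window:
                continue
            r2 = table.get(frozenset({vid, other}), 1.0)
            if r2 > r2_max:
                ok = False
                break
        if ok:
            kept_ids.append(vid)
    keep = instruments["variant_id"].isin(kept_ids)
    return instruments[keep].reset_index(drop=True)


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Align outcome effects to the exposure effect allele.

    Inner join on variant id; when the outcome's effect allele equals the
    exposure's other allele the outcome beta is sign-flipped (and eaf
    mirrored). Palindromic (A/T, C/G) and irreconcilable variants are
    dropped. Returns the harmonized instrument set with columns
    ``variant_id, beta_x, se_x, beta_y, se_y``.
    """
    merged = exposure.merge(
        outcome, on="variant_id", suffixes=("_x", "_y"), how="inner"
    )
    rows = []
    for row in merged.itertuples():
        ea_x, oa_x = str(row.effect_allele_x).upper(), str(row.other_allele_x).upper()
        ea_y, oa_y = str(row.effect_allele_y).upper(), str(row.other_allele_y).upper()
        if frozenset({ea_x, oa_x}) in _PALINDROMIC:
            continue
        if (ea_y, oa_y) == (ea_x, oa_x):
            beta_y = row.beta_y
        elif (ea_y, oa_y) == (oa_x, ea_x):
            beta_y = -row.beta_y
        else:
            continue
        rows.append(
            {
                "variant_id": row.variant_id,
                "beta_x": float(row.beta_x),
                "se_x": float(row.se_x),
                "beta_y": float(beta_y),
                "se_y": float(row.se_y),
            }
        )
    return pd.DataFrame(rows, columns=["variant_id", "beta_x", "se_x", "beta_y", "se_y"])


def ivw(instruments: pd.DataFrame) -> MrEstimate:
    """Inverse-variance-weighted pooling of per-variant Wald ratios.

    Ratio ``beta_y / beta_x`` with first-order variance ``se_y^2 / beta_x^2``
    (exposure-side uncertainty ignored, the standard IVW simplification).
    """
    usable = instruments[instruments["beta_x"] != 0.0]
    if len(usable) < len(instruments):
        warnings.warn(
            f"excluded {len(instruments) - len(usable)} instruments with zero "
            "exposure beta",
            stacklevel=2,
        )
    if usable.empty:
        raise EstimationError("no usable instruments for IVW")
    ratio = usable["beta_y"].to_numpy() / usable["beta_x"].to_numpy()
    var = usable["se_y"].to_numpy() ** 2 / usable["beta_x"].to_numpy() ** 2
    w = 1.0 / var
    beta = float(np.sum(ratio * w) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    pval = float(2.0 * stats.norm.sf(abs(beta / se)))
    return MrEstimate(beta=beta, se=se, pval=pval)


def fixed_effect_meta(
    est1: MrEstimate, est2: MrEstimate, alpha: float = 0.05
) -> MetaResult:
    """Fixed-effect pooling of two estimates with Cochran's Q and I².

    ``I² = max(0, (Q - df) / Q)`` with df = 1 for two studies, reported on
    the [0, 1] fraction scale.
    """
    betas = np.array([est1.beta, est2.beta])
    ses = np.array([est1.se, est2.se])
    if not (np.all(np.isfinite(betas)) and np.all(np.isfinite(ses))):
        raise ValueError("meta-analysis inputs must be finite")
    w = 1.0 / ses**2
    pooled = float(np.sum(w * betas) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    fixed_p = float(2.0 * stats.norm.sf(abs(pooled / pooled_se)))
    Q = float(np.sum(w * (betas - pooled) ** 2))
    het_p = float(stats.chi2.sf(Q, df=1))
    I2 = float(max(0.0, (Q - 1.0) / Q)) if Q > 0 else 0.0
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))
    return MetaResult(
        pooled_beta=pooled,
        pooled_se=pooled_se,
        fixed_p=fixed_p,
        ci_low=pooled - z * pooled_se,
        ci_high=pooled + z * pooled_se,
        Q=Q,
        het_p=het_p,
        I2=I2,
    )


DECISION_CRITERIA = ("fixed_p", "i2", "het_p", "ci_spans_zero")


def decide_causal(
    meta: MetaResult,
    fixed_p_max: float = 0.05,
    i2_max: float = 0.05,
    het_p_min: float = 0.05,
) -> tuple[bool, list[str]]:
    """Four-part causal call; returns (decision, failing criterion codes).

    Causal iff fixed-effect p < 0.05, I² < 0.05, heterogeneity p > 0.05 and
    the confidence interval lies strictly on one side of zero.
    """
    reasons = []
    if not meta.fixed_p < fixed_p_max:
        reasons.append("fixed_p")
    if not meta.I2 < i2_max:
        reasons.append("i2")
    if not meta.het_p > het_p_min:
        reasons.append("het_p")
    if not (meta.ci_high < 0.0 or meta.ci_low > 0.0):
        reasons.append("ci_spans_zero")
    return (not reasons, reasons)


def select_causal_features(
    exposures: Mapping[str, pd.DataFrame],
    outcome1: pd.DataFrame,
    outcome2: pd.DataFrame,
    ld: pd.DataFrame | None = None,
    positions: pd.DataFrame | None = None,
    exclusion_list: Iterable[str] = (),
    p_max: float = 1e-5,
    maf_min: float = 0.01,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
) -> pd.DataFrame:
    """Run the full instrument pipeline and decision rule per exposure.

    Returns one report row per feature with all intermediate statistics and
    a decision in {"causal", "not_causal", "untestable"}; features with no
    surviving instruments are never called causal.
    """
    exclusion = set(exclusion_list)
    rows = []
    for name, gwas in exposures.items():
        rec: dict = {"feature": name}
        inst = filter_instruments(gwas, p_max=p_max, maf_min=maf_min)
        inst = exclude_confounder_snps(inst, exclusion)
        inst = ld_clump(inst, ld=ld, positions=positions, r2_max=r2_max,
                        window_kb=window_kb)
        rec["n_instruments"] = len(inst)
        try:
            pair1 = harmonize(inst, outcome1)
            pair2 = harmonize(inst, outcome2)
            est1, est2 = ivw(pair1), ivw(pair2)
        except EstimationError:
            rec.update(decision="untestable", reasons="no_instruments")
            rows.append(rec)
            continue
        meta = fixed_effect_meta(est1, est2)
        causal, reasons = decide_causal(meta)
        rec.update(
            n_harmonized_1=len(pair1),
            n_harmonized_2=len(pair2),
            beta_1=est1.beta, se_1=est1.se, pval_1=est1.pval,
            beta_2=est2.beta, se_2=est2.se, pval_2=est2.pval,
            pooled_beta=meta.pooled_beta, pooled_se=meta.pooled_se,
            fixed_p=meta.fixed_p, ci_low=meta.ci_low, ci_high=meta.ci_high,
            Q=meta.Q, het_p=meta.het_p, I2=meta.I2,
            decision="causal" if causal else "not_causal",
            reasons=";".join(reasons),
        )
        rows.append(rec)
    return pd.DataFrame(rows)
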