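"""Longitudinal repeated-measures summaries and inter-rater agreement.

This is a thin statistical stage: the marginal models are generalized
estimating equations (GEE) fitted by statsmodels with an exchangeable
working correlation, with Wald chi-square tests per factor and
Bonferroni-adjusted pairwise level contrasts. Counts use a Poisson/log
family; durations, frequencies, and coherence use Gaussian/identity.

Cohen's κ is the chance-corrected frame-level agreement between two coders'
rattling annotations, rasterized at video rate (25 fps by default).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import AnnotationTrack, Tier, ValidationError
from .sync import binarize_annotations

__all__ = [
    "EffectReport",
    "PairwiseComparison",
    "build_longitudinal_table",
    "fit_repeated_effects",
    "cohens_kappa",
    "TIMEPOINTS",
]

TIMEPOINTS = ["T1", "T2", "T3", "T4"]

#: Metric name → GEE family ("poisson" for counts, "gaussian" otherwise).
_COUNT_METRICS = {"n_rattling_episodes", "n_rattling_movements"}


@dataclass
class PairwiseComparison:
    factor: str
    level_a: str
    level_b: str
    estimate: float
    p_raw: float
    p_adj: float  # Bonferroni: min(1, p_raw · m)


@dataclass
class EffectReport:
    metric: str
    effects: dict  # factor -> {"wald_chi2", "df", "p"}
    pairwise: list[PairwiseComparison]


def build_longitudinal_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Long-format table: subject_id, timepoint, condition, metric, value.

    Enforces at most one value per (subject, timepoint, condition, metric)
    and the T1..T4 timepoint ordering.
    """
    df = pd.DataFrame(list(rows))
    required = {"subject_id", "timepoint", "condition", "metric", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"longitudinal rows lack fields {sorted(missing)}")
    bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValidationError(f"unknown timepoints {sorted(bad_tp)}")
    keys = ["subject_id", "timepoint", "condition", "metric"]
    if df.duplicated(keys).any():
        dup = df[df.duplicated(keys, keep=False)].iloc[0]
        raise ValidationError(
            f"duplicate cell: subject {dup['subject_id']} {dup['timepoint']} "
            f"{dup['condition']} {dup['metric']}"
        )
    df["timepoint"] = pd.Categorical(df["timepoint"], TIMEPOINTS, ordered=True)
    return df.sort_values(keys).reset_index(drop=True)


def _family_for(metric: str, family: str) -> sm.families.Family:
    if family == "auto":
        family = "poisson" if metric in _COUNT_METRICS else "gaussian"
    if family == "poisson":
        return sm.families.Poisson()
    if family == "gaussian":
        return sm.families.Gaussian()
    raise ValidationError(f"unknown family {family!r}")


def fit_repeated_effects(
    table: pd.DataFrame,
    metric: str,
    factors: Sequence[str] = ("timepoint",),
    family: str = "auto",
    cov_struct: str = "exchangeable",
    interaction: bool = True,
) -> EffectReport:
    """GEE marginal model for one metric with repeated measures per subject.

    Fits ``value ~ C(f1) [+ C(f2) + C(f1):C(f2)]`` with subject clusters and
    the requested working correlation; reports a Wald chi-square per factor
    (and the interaction when two factors are given) plus all pairwise level
    contrasts of each factor with Bonferroni adjustment.
    """
    sub = table[table["metric"] == metric].copy()
    if sub.empty:
        raise ValidationError(f"no rows for metric {metric!r}")
    sub["timepoint"] = sub["timepoint"].astype(str)
    for f in factors:
        levels = sub[f].dropna().unique()
        if len(levels) < 2:
            raise ValidationError(f"factor {f!r} has fewer than 2 observed levels")
        counts = sub.groupby(f, observed=True)["value"].count()
        empty = [lv for lv in levels if counts.get(lv, 0) == 0]
        if empty:
            raise ValidationError(f"factor {f!r} level {empty[0]!r} has no data")
    n_per_subject = sub.groupby("subject_id")["value"].count()
    if (n_per_subject >= 2).sum() < 2:
        raise ValidationError("need ≥ 2 subjects with ≥ 2 repeated measurements")

    terms = [f"C({f})" for f in factors]
    if interaction and len(factors) == 2:
        terms.append(f"C({factors[0]}):C({factors[1]})")
    formula = "value ~ " + " + ".join(terms)
    cov = {
        "exchangeable": sm.cov_struct.Exchangeable,
        "independence": sm.cov_struct.Independence,
        "ar1": sm.cov_struct.Autoregressive,
    }[cov_struct]()
    model = sm.GEE.from_formula(
        formula, groups="subject_id", data=sub,
        family=_family_for(metric, family), cov_struct=cov,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
        wald = res.wald_test_terms(scalar=True)

    effects: dict[str, dict] = {}
    for term, row in wald.table.iterrows():
        if term == "Intercept":
            continue
        name = term
        for f in factors:
            name = name.replace(f"C({f})", f)
        effects[name] = {
            "wald_chi2": float(row["statistic"]),
            "df": int(row["df_constraint"]),
            "p": float(row["pvalue"]),
        }

    pairwise: list[PairwiseComparison] = []
    params = res.params
    cov_params = res.cov_params()
    from scipy.stats import norm

    for f in factors:
        levels = sorted(sub[f].astype(str).unique())
        pairs = list(itertools.combinations(levels, 2))
        m = len(pairs)
        for a, b in pairs:
            # treatment coding: effect of level L vs reference is the
            # C(f)[T.L] coefficient (0 for the reference level)
            vec = pd.Series(0.0, index=params.index)
            est = 0.0
            for lv, sign in ((b, 1.0), (a, -1.0)):
                name = f"C({f})[T.{lv}]"
                if name in vec.index:
                    vec[name] += sign
            est = float(vec @ params)
            se = float(np.sqrt(vec @ cov_params @ vec))
            if se == 0.0:
                p_raw = 1.0
            else:
                z = est / se
                p_raw = float(2.0 * norm.sf(abs(z)))
            pairwise.append(
                PairwiseComparison(f, a, b, est, p_raw, min(1.0, p_raw * m))
            )
    return EffectReport(metric, effects, pairwise)


def cohens_kappa(
    track_a: AnnotationTrack,
    track_b: AnnotationTrack,
    fs: float = 25.0,
    tier: Tier = Tier.RATTLING,
    extent_s: Optional[float] = None,
) -> float:
    """Frame-level Cohen's κ between two coders' annotation tracks.

    Both tracks are rasterized to binary frames (inside/outside the tier's
    intervals) at ``fs`` over a shared extent; κ = (p_o − p_e) / (1 − p_e)
    with p_o the observed frame agreement and p_e the chance agreement from
    the marginal label frequencies. Returns NaN (with a warning) when both
    raters are constant with the same label (p_e = 1, κ undefined).
    """
    if extent_s is None:
        extent_s = max(
            (iv.offset_s for tr in (track_a, track_b) for iv in tr.intervals),
            default=0.0,
        )
    if extent_s <= 0:
        raise ValidationError("empty tracks: extent undefined")
    a = binarize_annotations(track_a, tier, fs, extent_s).astype(bool)
    b = binarize_annotations(track_b, tier, fs, extent_s).astype(bool)
    po = float(np.mean(a == b))
    pa1, pb1 = float(a.mean()), float(b.mean())
    pe = pa1 * pb1 + (1.0 - pa1) * (1.0 - pb1)
    if pe >= 1.0 - 1e-15:
        warnings.warn("both raters constant with the same label: kappa undefined")
        return float("nan")
    return (po - pe) / (1.0 - pe)
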