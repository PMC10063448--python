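"""Bulk-cohort signature scoring, survival and response association.

Samples are scored with a self-contained rank-percentile enrichment: the
mean within-sample rank percentile of the signature genes. The score is
invariant to any strictly increasing per-sample transform of expression,
so cohorts normalized differently remain comparable. Scores are then
median-split for Kaplan–Meier survival analysis (truncated to a 5-year
horizon) with a log-rank test, or compared between responders (CR/PR)
and non-responders (SD/PD) with a Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from gdtcr._errors import UndefinedInputError
from gdtcr._stats import rank_sum_test

CLINICAL_COLUMNS = {"time", "event", "response", "arm", "signature_fraction"}


def _gene_columns(cohort: pd.DataFrame) -> list[str]:
    return [c for c in cohort.columns if c not in CLINICAL_COLUMNS]


def sample_signature_score(
    cohort: pd.DataFrame, signature_genes: list[str]
) -> pd.Series:
    """Rank-percentile enrichment score per sample.

    Within each sample, all genes are ranked (average ties); the score is
    the mean rank percentile (rank / n_genes) of the signature genes.
    """
    genes = _gene_columns(cohort)
    overlap = [g for g in signature_genes if g in genes]
    if not overlap:
        raise UndefinedInputError("signature has empty overlap with cohort genes")
    if len(overlap) < len(signature_genes):
        warnings.warn(
            f"signature overlap {len(overlap)}/{len(signature_genes)} genes"
        )
    expr = cohort[genes].to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, expr) / len(genes)
    cols = [genes.index(g) for g in overlap]
    return pd.Series(
        ranks[:, cols].mean(axis=1), index=cohort.index, name="signature_score"
    )


def median_split(scores: pd.Series) -> pd.Series:
    """Label samples high/low by the cohort median score.

    Strictly above the median → ``high``; at or below → ``low`` (the
    declared tie convention, so an odd cohort's median sample is low).
    All-equal scores degenerate to all ``low`` with a warning.
    """
    scores = pd.Series(scores)
    if len(scores) < 2:
        raise UndefinedInputError("median split needs at least 2 samples")
    med = scores.median()
    labels = pd.Series(
        np.where(scores > med, "high", "low"), index=scores.index, name="score_group"
    )
    if (labels == "low").all():
        warnings.warn("degenerate median split: no sample above the median")
    return labels


@dataclass
class SurvivalFit:
    """Product-limit estimate for one group."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        mask = self.event_times <= t
        return float(self.survival[mask][-1]) if mask.any() else 1.0


def truncate_survival(
    times, events, horizon: float = 60.0
) -> tuple[np.ndarray, np.ndarray]:
    """Administratively censor follow-up at ``horizon`` months."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    over = t > horizon
    return np.where(over, horizon, t), np.where(over, 0, e)


def kaplan_meier(times, events) -> SurvivalFit:
    """Kaplan–Meier product-limit estimator (events before censorings at
    equal times, the estimator's standard convention)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise UndefinedInputError("empty survival input")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(timeline).to_numpy(dtype=float)
    keep = timeline > 0
    return SurvivalFit(
        event_times=timeline[keep],
        survival=surv[keep],
        at_risk=at_risk[keep],
        n=int(t.size),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> dict:
    """Two-group log-rank test: chi-square statistic on 1 df, two-sided p."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    if ta.size == 0 or tb.size == 0:
        raise UndefinedInputError("both groups must be non-empty")
    res = _ll_logrank(ta, tb, event_observed_A=events_a, event_observed_B=events_b)
    return dict(statistic=float(res.test_statistic), pvalue=float(res.p_value))


def survival_analysis(
    cohort: pd.DataFrame,
    scores: pd.Series,
    horizon: float = 60.0,
) -> dict:
    """Median-split Kaplan–Meier comparison of a scored cohort.

    Follow-up is truncated at ``horizon`` months (5-year analysis) before
    fitting; returns per-group fits and the log-rank result.
    """
    groups = median_split(scores)
    t, e = truncate_survival(cohort["time"], cohort["event"], horizon)
    hi = (groups == "high").to_numpy()
    lo = ~hi
    if hi.sum() == 0 or lo.sum() == 0:
        raise UndefinedInputError("median split produced an empty group")
    return dict(
        groups=groups,
        fit_high=kaplan_meier(t[hi], e[hi]),
        fit_low=kaplan_meier(t[lo], e[lo]),
        logrank=logrank_test(t[hi], e[hi], t[lo], e[lo]),
    )


def response_association(scores: pd.Series, response_labels) -> dict:
    """Rank-sum comparison of signature scores by clinical response.

    Responders are CR/PR, non-responders SD/PD; both classes must be
    present. Returns the two-sided p plus per-class medians and quartiles
    for box-plot-style reporting.
    """
    labels = pd.Series(response_labels, index=scores.index).astype(str)
    resp = scores[labels == "CR/PR"]
    nonresp = scores[labels == "SD/PD"]
    if resp.empty or nonresp.empty:
        raise UndefinedInputError("both response classes must be present")
    stat, p = rank_sum_test(resp.to_numpy(), nonresp.to_numpy())

    def _summary(s: pd.Series) -> dict:
        q1, med, q3 = np.percentile(s, [25, 50, 75])
        return dict(n=len(s), q1=float(q1), median=float(med), q3=float(q3))

    return dict(
        statistic=stat,
        pvalue=p,
        responders=_summary(resp),
        nonresponders=_summary(nonresp),
    )
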