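"""Regression metrics at four aggregation levels and responder
discrimination statistics.

Levels: ``a`` pools every prediction; ``d`` groups by drug across tissues;
``t`` by tissue across drugs; ``dt`` computes metrics per drug-tissue pair
and summarises them as mean ± 95% CI across pairs.  Correlations on
constant vectors are undefined and reported as NaN, and excluded (with a
logged count) from dt averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: SCC^dt above this is flagged as high predictive performance
HIGH_PERFORMANCE_SCC = 0.5


@dataclass
class MetricReport:
    level: str           # one of {"a", "d", "t", "dt"}
    group: str           # drug id, tissue, "drug|tissue" pair, or "all"
    mse: float
    mae: float
    pcc: float
    scc: float
    n: int
    ci95: tuple[float, float] | None = None  # for dt summaries (on SCC)


@dataclass
class GroupComparison:
    effect_size: float   # rank-biserial correlation, 2*AUC - 1
    p_value: float       # Mann-Whitney U, two-sided
    roc_auc: float


def compute_metrics(predictions, labels) -> tuple[float, float, float, float]:
    """(MSE, MAE, PCC, SCC); correlations NaN when undefined (n < 2 or constant)."""
    y_pred = np.asarray(predictions, dtype=np.float64)
    y_true = np.asarray(labels, dtype=np.float64)
    if y_pred.shape != y_true.shape:
        raise ValueError("prediction/label length mismatch")
    err = y_pred - y_true
    mse = float(np.mean(err ** 2))
    mae = float(np.mean(np.abs(err)))
    pcc = scc = float("nan")
    if y_pred.size >= 2 and np.ptp(y_pred) > 0 and np.ptp(y_true) > 0:
        pcc = float(stats.pearsonr(y_pred, y_true).statistic)
        scc = float(stats.spearmanr(y_pred, y_true).statistic)
    return mse, mae, pcc, scc


def _report(level: str, group: str, sub: pd.DataFrame) -> MetricReport:
    mse, mae, pcc, scc = compute_metrics(sub["y_pred"], sub["y_true"])
    return MetricReport(level=level, group=group, mse=mse, mae=mae,
                        pcc=pcc, scc=scc, n=len(sub))


def aggregate_levels(records: pd.DataFrame) -> list[MetricReport]:
    """Metric reports at all four levels.

    ``records`` needs columns drug_id, tissue, y_pred, y_true.  The dt level
    emits one report per pair plus a summary row (group "dt_mean") whose
    metrics are means across pairs and whose ``ci95`` is the normal-
    approximation 95% CI of SCC^dt.
    """
    reports = [_report("a", "all", records)]
    for drug, sub in records.groupby("drug_id", sort=True):
        reports.append(_report("d", str(drug), sub))
    for tissue, sub in records.groupby("tissue", sort=True):
        reports.append(_report("t", str(tissue), sub))
    pair_reports = []
    for (drug, tissue), sub in records.groupby(["drug_id", "tissue"], sort=True):
        pair_reports.append(_report("dt", f"{drug}|{tissue}", sub))
    reports.extend(pair_reports)
    sccs = np.array([r.scc for r in pair_reports], dtype=np.float64)
    n_undef = int(np.isnan(sccs).sum())
    if n_undef:
        logger.warning("%d drug-tissue pairs with undefined SCC excluded "
                       "from dt summary", n_undef)
    valid = sccs[~np.isnan(sccs)]
    if valid.size:
        mean = float(valid.mean())
        se = float(valid.std(ddof=1) / np.sqrt(valid.size)) if valid.size > 1 else 0.0
        summary = MetricReport(
            level="dt", group="dt_mean",
            mse=float(np.mean([r.mse for r in pair_reports])),
            mae=float(np.mean([r.mae for r in pair_reports])),
            pcc=float(np.nanmean([r.pcc for r in pair_reports])),
            scc=mean, n=len(pair_reports),
            ci95=(mean - 1.96 * se, mean + 1.96 * se))
        reports.append(summary)
    return reports


def reports_frame(reports: list[MetricReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {"level": r.level, "group": r.group, "mse": r.mse, "mae": r.mae,
               "pcc": r.pcc, "scc": r.scc, "n": r.n}
        if r.ci95 is not None:
            row["scc_ci_low"], row["scc_ci_high"] = r.ci95
        rows.append(row)
    return pd.DataFrame(rows)


def responder_discrimination(scores, responder_flags,
                             higher_is_sensitive: bool = False) -> GroupComparison:
    """Mann-Whitney separation of responders vs non-responders.

    By default ``scores`` are predicted LN_IC50 values: lower means more
    sensitive, so the discrimination score is the *negated* prediction
    (responders are expected to score higher).  Pass
    ``higher_is_sensitive=True`` for scores already oriented as
    sensitivity.  AUC = U / (n1 n0); effect size is the rank-biserial
    correlation 2*AUC - 1.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if not higher_is_sensitive:
        scores = -scores
    flags = np.asarray(responder_flags, dtype=bool)
    pos, neg = scores[flags], scores[~flags]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both responder classes must be nonempty")
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided")
    auc = float(res.statistic / (pos.size * neg.size))
    return GroupComparison(effect_size=2.0 * auc - 1.0,
                           p_value=float(res.pvalue), roc_auc=auc)
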