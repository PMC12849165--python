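"""Summary statistics, paired tests and experiment reports.

Conventions used repo-wide: percentiles (median, quartiles) use linear
interpolation between order statistics; the two-sided Wilcoxon signed-rank
test drops zero differences (Wilcoxon's original proposal), uses the exact
null distribution for small samples without ties and a normal approximation
with continuity correction otherwise; the Holm step-down correction is
applied per family.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation_sim import ScenarioSpec, WorkloadSummary

_EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class SummaryStat:
    median: float
    iqr_lo: float
    iqr_hi: float
    n: int

    def __post_init__(self):
        if not self.iqr_lo <= self.median <= self.iqr_hi:
            raise ValueError(f"quartiles must bracket the median: {self}")


def summarize(values: Sequence[float]) -> SummaryStat:
    """Median and 25th/75th percentiles of a nonempty sample."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty sample")
    lo, med, hi = np.percentile(values, [25, 50, 75])
    return SummaryStat(median=float(med), iqr_lo=float(lo), iqr_hi=float(hi),
                       n=int(values.size))


def paired_wilcoxon(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped; if all differences are zero the test is
    undefined and p = 1.0 is returned with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("paired samples must be equal-length nonempty 1D sequences")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p-value reported as 1.0")
        return 1.0
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    if nonzero.size <= _EXACT_WILCOXON_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                         correction=(method == "approx"), method=method)
    return float(res.pvalue)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvalues, method="holm")[1]


def workload_report(
    summaries: Mapping[str, tuple[ScenarioSpec, WorkloadSummary]]
) -> pd.DataFrame:
    """Tabulate acceptance/correction proportions per scenario."""
    if len(summaries) == 0:
        raise ValueError("at least one scenario summary is required")
    rows = []
    for name, (scenario, summary) in summaries.items():
        rows.append({
            "scenario": name,
            "tau_dsc": scenario.tau_dsc,
            "tau_nsd": scenario.tau_nsd,
            "total_instance_slices": summary.total_instance_slices,
            "proportion_accepted": summary.proportion_accepted,
            "proportion_corrected": summary.proportion_corrected,
        })
    return pd.DataFrame(rows)


def write_report(report: pd.DataFrame, out_base: str | Path) -> None:
    """Emit a report as JSON (full precision) and CSV (4 significant figures)."""
    out_base = Path(out_base)
    out_base.parent.mkdir(parents=True, exist_ok=True)
    with open(out_base.with_suffix(".json"), "w") as fh:
        json.dump(report.to_dict(orient="records"), fh, indent=2)
        fh.write("\n")
    rounded = report.copy()
    for col in rounded.columns:
        if pd.api.types.is_float_dtype(rounded[col]):
            rounded[col] = rounded[col].map(lambda v: float(f"{v:.4g}"))
    rounded.to_csv(out_base.with_suffix(".csv"), index=False)
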