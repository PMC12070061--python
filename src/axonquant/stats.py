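"""Group comparison and summary reporting for pipeline outputs.

Thin plumbing over scipy/statsmodels: paired or unpaired two-group tests
(parametric or rank-based, with an automatic choice via a Shapiro–Wilk
normality pre-check), Holm–Šídák multiple-comparison adjustment, and
mean ± s.e.m. summaries with plot-ready exports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ComparisonSpec", "compare_groups", "adjust_pvalues", "summarize"]


@dataclass
class ComparisonSpec:
    """How to compare two samples.

    ``design``: 'paired' or 'unpaired'.  ``test``: 't', 'wilcoxon',
    'mannwhitney' or 'auto' (Shapiro–Wilk at alpha 0.05 per group chooses
    parametric vs rank).  ``mcp``: 'none' or 'holm_sidak', recorded for the
    reporting layer.
    """

    design: str = "unpaired"
    test: str = "auto"
    mcp: str = "none"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.design not in ("paired", "unpaired"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.test not in ("t", "wilcoxon", "mannwhitney", "auto"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.mcp not in ("none", "holm_sidak"):
            raise ValueError(f"unknown mcp {self.mcp!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def _normalish(x: np.ndarray, alpha: float) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue > alpha


def compare_groups(a, b, spec: ComparisonSpec | None = None) -> dict:
    """Two-group comparison; returns estimate, statistic, p and group info.

    The estimate is ``mean(a) - mean(b)`` (for paired designs, the mean of
    the paired differences — the same number).  Degenerate inputs (zero
    variance everywhere for a t-test, or all-zero paired differences for
    the signed-rank test) are reported with ``degenerate=True`` rather than
    raising.
    """
    spec = spec or ComparisonSpec()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    if spec.design == "paired" and len(a) != len(b):
        raise ValueError("paired design requires equal-length samples")
    test = spec.test
    if test == "auto":
        if spec.design == "paired":
            test = "t" if _normalish(a - b, 0.05) else "wilcoxon"
        else:
            test = (
                "t"
                if _normalish(a, 0.05) and _normalish(b, 0.05)
                else "mannwhitney"
            )
    if spec.design == "paired" and test == "mannwhitney":
        raise ValueError("Mann-Whitney is an unpaired test")
    if spec.design == "unpaired" and test == "wilcoxon":
        raise ValueError("the signed-rank test requires a paired design")

    estimate = float(a.mean() - b.mean())
    degenerate = False
    if test == "t":
        if spec.design == "paired":
            d = a - b
            if np.ptp(d) == 0:
                degenerate = True
                stat, p = np.nan, (1.0 if np.allclose(d, 0) else 0.0)
            else:
                res = sps.ttest_rel(a, b)
                stat, p = float(res.statistic), float(res.pvalue)
        else:
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                degenerate = True
                stat, p = np.nan, (1.0 if a.mean() == b.mean() else 0.0)
            else:
                res = sps.ttest_ind(a, b)
                stat, p = float(res.statistic), float(res.pvalue)
    elif test == "wilcoxon":
        d = a - b
        if np.all(d == 0):
            degenerate = True
            stat, p = np.nan, 1.0
        else:
            res = sps.wilcoxon(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
    else:  # mannwhitney
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    return {
        "test": test,
        "design": spec.design,
        "estimate": estimate,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "statistic": stat,
        "p": float(p),
        "n": (len(a), len(b)),
        "degenerate": degenerate,
    }


def adjust_pvalues(pvals, method: str = "holm_sidak") -> np.ndarray:
    """Holm–Šídák step-down adjusted p-values (monotone, >= raw).

    ``method='none'`` returns the inputs unchanged.
    """
    pvals = np.asarray(pvals, dtype=float)
    if method == "none":
        return pvals.copy()
    if method != "holm_sidak":
        raise ValueError(f"unknown adjustment {method!r}")
    from statsmodels.stats.multitest import multipletests

    if len(pvals) == 0:
        return pvals.copy()
    with np.errstate(divide="ignore"):  # p = 1 hits log1p(-1) internally
        _, adj, _, _ = multipletests(pvals, method="holm-sidak")
    return np.maximum(adj, pvals)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean, s.e.m. and n for a replicate × condition table.

    Rows are replicates, columns conditions.  ``sem`` is NaN when a
    condition has a single replicate.  The input column values double as
    plot-ready distribution data (e.g. for violin plots).
    """
    table = pd.DataFrame(table)
    out = pd.DataFrame(
        {
            "mean": table.mean(axis=0),
            "sem": table.sem(axis=0, ddof=1),
            "n": table.count(axis=0).astype(int),
        }
    )
    out.index.name = "condition"
    return out


def violin_export(table: pd.DataFrame) -> pd.DataFrame:
    """Long-form (condition, value) table for distribution plots."""
    return (
        pd.DataFrame(table)
        .melt(var_name="condition", value_name="value")
        .dropna()
        .reset_index(drop=True)
    )
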