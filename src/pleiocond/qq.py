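"""Conditional Q-Q enrichment diagnostics.

A conditional Q-Q plot shows the quantiles of one trait's p-values within
nested strata of SNPs selected by their significance in a second,
conditional trait. Successive leftward/upward deflection of the curves as
the conditional threshold tightens indicates cross-trait polygenic
enrichment, which the conditional FDR then exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import SumStats

#: conditional p-value cutoffs used throughout (1.0 = unconditional curve)
DEFAULT_QQ_THRESHOLDS = (1.0, 0.1, 0.01, 0.001)


@dataclass
class QqStrata:
    """Conditional Q-Q curves: one stratum per conditional threshold.

    ``table`` is long-format with columns (threshold, expected, observed):
    expected is -log10 of the uniform plotting position rank/(k+1) and
    observed the matching empirical -log10 p of the primary trait. Strata
    smaller than ``min_stratum`` SNPs keep their count but contribute no
    curve and are listed in ``flagged``.
    """

    thresholds: tuple
    table: pd.DataFrame
    counts: dict = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)
    flagged: list = field(default_factory=list)
    summary_quantile: float = 0.1

    def summary_series(self) -> pd.Series:
        """Enrichment summary per stratum, ordered loosest to strictest."""
        return pd.Series(
            {t: self.summaries.get(t, np.nan) for t in self.thresholds}
        )


def conditional_qq(
    primary: SumStats,
    conditional: SumStats,
    thresholds=DEFAULT_QQ_THRESHOLDS,
    min_stratum: int = 100,
    summary_quantile: float = 0.1,
) -> QqStrata:
    """Stratified Q-Q of the primary trait's p-values.

    For each conditional cutoff t the stratum is {SNPs with p_cond <= t};
    within it the sorted -log10 primary p-values are paired with
    -log10(rank/(k+1)) uniform plotting positions. The scalar enrichment
    summary per stratum is the observed -log10 p at the upper
    ``summary_quantile`` tail (default: the 0.1 empirical quantile, i.e.
    the 90th percentile of -log10 p).

    Inputs must be harmonized (same SNPs, same order). The reverse analysis
    is the same call with the arguments exchanged.
    """
    if len(primary) != len(conditional) or not primary.snp.equals(conditional.snp):
        raise ValueError("inputs must be harmonized to the same SNP order")
    thresholds = tuple(sorted(set(thresholds), reverse=True))
    if any(t <= 0 or t > 1 for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")

    p1 = primary.p
    p2 = conditional.p
    rows = []
    counts, summaries, flagged = {}, {}, []
    for t in thresholds:
        stratum = np.sort(p1[p2 <= t])
        k = stratum.size
        counts[t] = int(k)
        if k < min_stratum:
            flagged.append(t)
            continue
        obs = -np.log10(stratum[::-1])  # ascending expected order
        exp = -np.log10(np.arange(k, 0, -1) / (k + 1.0))
        rows.append(
            pd.DataFrame({"threshold": t, "expected": exp, "observed": obs})
        )
        neglog = -np.log10(stratum)
        summaries[t] = float(np.quantile(neglog, 1.0 - summary_quantile))

    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["threshold", "expected", "observed"])
    )
    return QqStrata(
        thresholds=thresholds,
        table=table,
        counts=counts,
        summaries=summaries,
        flagged=flagged,
        summary_quantile=summary_quantile,
    )


def plot_conditional_qq(strata: QqStrata, ax=None, title: str | None = None):
    """Render the stratified curves with the null (y = x) reference line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    for t in strata.thresholds:
        sub = strata.table[strata.table["threshold"] == t]
        if len(sub):
            ax.plot(sub["expected"], sub["observed"], label=f"p_cond <= {t:g}")
    lim = max(strata.table["expected"].max(), 1.0) if len(strata.table) else 1.0
    ax.plot([0, lim], [0, lim], "k--", lw=0.8, label="null")
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax
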