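"""Within-subject agreement of paired measurements from two algorithms.

Agreement is quantified by Lin's concordance correlation coefficient

    pc = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2),

which penalises both scatter about and systematic departure from the line
of identity, classified on the descriptive scale: poor (< 0.90), moderate
(0.90 <= pc <= 0.95), substantial (0.95 < pc <= 0.99), almost perfect
(pc > 0.99). Moments use denominator n (Lin's original estimator); with an
n-1 convention pc shifts slightly at small n, which matters when quoting
values near a class boundary.

Systematic within-subject differences are tested with the two-sided
Wilcoxon signed-rank test: exact null distribution (tie-aware, via
dynamic programming over midranks) up to n = 25 non-zero differences,
normal approximation with tie and continuity corrections above. Zero
differences are discarded before ranking, classic Wilcoxon treatment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AgreementResult",
    "WilcoxonResult",
    "concordance_correlation",
    "classify_agreement",
    "wilcoxon_signed_rank",
    "median_iqr",
    "compare_algorithms",
]


def concordance_correlation(x, y) -> float:
    """Lin's concordance correlation coefficient between paired series.

    Raises
    ------
    ValueError
        If fewer than 3 pairs, unequal lengths, or both series are
        constant with equal means (pc undefined).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise ValueError("pc undefined: both series constant with equal means")
    return float(2.0 * sxy / denom)


_AGREEMENT_SCALE = (
    (0.90, "poor"),        # pc < 0.90
    (0.95, "moderate"),    # 0.90 <= pc <= 0.95
    (0.99, "substantial"), # 0.95 < pc <= 0.99
)


def classify_agreement(pc: float) -> str:
    """Descriptive agreement class of a concordance coefficient."""
    if not (-1.0 - 1e-12 <= pc <= 1.0 + 1e-12):
        raise ValueError(f"pc = {pc} outside [-1, 1]")
    if pc < 0.90:
        return "poor"
    if pc <= 0.95:
        return "moderate"
    if pc <= 0.99:
        return "substantial"
    return "almost perfect"


@dataclass
class WilcoxonResult:
    statistic: float      # smaller of the signed rank sums
    p_value: float
    n_used: int           # pairs after zero-difference removal
    n_zero: int
    degenerate: bool      # all differences were zero
    method: str           # "exact" or "normal"


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank sum via DP over sign flips.

    Midranks are doubled to integers so tied ranks are handled exactly;
    the distribution of W+ is then the convolution of fair coin flips over
    the doubled ranks.
    """
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for dr in doubled:
        counts[dr:] += counts[: total + 1 - dr]
    counts /= counts.sum()
    w2 = int(round(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(x, y) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired series.

    Returns the smaller signed-rank sum as the statistic. All-zero
    differences are a degenerate case reported with p = 1 and a flag
    rather than an error, so cohort tables can include measures identical
    under both algorithms.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    d = x - y
    nonzero = d != 0.0
    n_zero = int(np.count_nonzero(~nonzero))
    d = d[nonzero]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, n_zero, True, "degenerate")
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)
    if n <= 25:
        p = _exact_signed_rank_p(ranks, w_plus)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        if var <= 0:
            return WilcoxonResult(statistic, 1.0, n, n_zero, False, "normal")
        dev = w_plus - mu
        # continuity correction toward the null
        z = (dev - 0.5 * np.sign(dev)) / math.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        method = "normal"
    return WilcoxonResult(statistic, p, n, n_zero, False, method)


def median_iqr(values) -> tuple[float, float, float]:
    """Median with 25th/75th percentiles (linear interpolation, same
    convention as the densitometry percentile)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty series")
    q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0])
    return float(med), float(q1), float(q3)


@dataclass
class AgreementResult:
    measure: str
    pc: float | None
    agreement_class: str | None
    wilcoxon_stat: float
    wilcoxon_p: float
    wilcoxon_degenerate: bool
    median_A: float
    q1_A: float
    q3_A: float
    median_B: float
    q1_B: float
    q3_B: float
    abs_diff_median: float
    abs_diff_q1: float
    abs_diff_q3: float
    n: int

    def as_row(self) -> dict:
        return {
            "measure": self.measure,
            "pc": self.pc,
            "agreement_class": self.agreement_class,
            "wilcoxon_stat": self.wilcoxon_stat,
            "wilcoxon_p": self.wilcoxon_p,
            "wilcoxon_degenerate": self.wilcoxon_degenerate,
            "median_A": self.median_A,
            "iqr_A": f"{self.q1_A:.6g}..{self.q3_A:.6g}",
            "median_B": self.median_B,
            "iqr_B": f"{self.q1_B:.6g}..{self.q3_B:.6g}",
            "abs_diff_median": self.abs_diff_median,
            "abs_diff_iqr": f"{self.abs_diff_q1:.6g}..{self.abs_diff_q3:.6g}",
            "n": self.n,
        }


def compare_algorithms(
    measures: pd.DataFrame,
    algo_a: str = "FBP",
    algo_b: str = "IR",
    measure_order: list[str] | None = None,
) -> tuple[pd.DataFrame, list[AgreementResult]]:
    """Per-measure agreement table between two reconstruction algorithms.

    Parameters
    ----------
    measures
        Long-format frame with columns ``subject``, ``recon``, ``measure``,
        ``value`` — one row per subject, reconstruction and measure.

    Subjects missing either reconstruction for a measure are dropped from
    that measure's comparison (logged). Returns the table as a DataFrame
    plus the underlying :class:`AgreementResult` objects.
    """
    required = {"subject", "recon", "measure", "value"}
    if not required.issubset(measures.columns):
        raise ValueError(f"measures frame must have columns {sorted(required)}")
    results: list[AgreementResult] = []
    names = measure_order or list(dict.fromkeys(measures["measure"]))
    for name in names:
        sub = measures[measures["measure"] == name]
        wide = sub.pivot_table(index="subject", columns="recon", values="value")
        if algo_a not in wide.columns or algo_b not in wide.columns:
            logger.warning("measure %s missing one algorithm entirely; skipped", name)
            continue
        paired = wide[[algo_a, algo_b]].dropna()
        dropped = len(wide) - len(paired)
        if dropped:
            logger.warning("measure %s: dropped %d unpaired subjects", name, dropped)
        a = paired[algo_a].to_numpy()
        b = paired[algo_b].to_numpy()
        if a.size < 3:
            logger.warning("measure %s: fewer than 3 complete pairs; skipped", name)
            continue
        try:
            pc = concordance_correlation(a, b)
            agreement_class = classify_agreement(min(1.0, max(-1.0, pc)))
        except ValueError:
            pc, agreement_class = None, None
        try:
            wres = wilcoxon_signed_rank(a, b)
        except ValueError:
            # < 5 non-zero differences: too few to test, report untested.
            wres = WilcoxonResult(float("nan"), float("nan"), a.size, 0, False, "insufficient")
        med_a, q1_a, q3_a = median_iqr(a)
        med_b, q1_b, q3_b = median_iqr(b)
        med_d, q1_d, q3_d = median_iqr(np.abs(a - b))
        results.append(
            AgreementResult(
                measure=name,
                pc=pc,
                agreement_class=agreement_class,
                wilcoxon_stat=wres.statistic,
                wilcoxon_p=wres.p_value,
                wilcoxon_degenerate=wres.degenerate,
                median_A=med_a, q1_A=q1_a, q3_A=q3_a,
                median_B=med_b, q1_B=q1_b, q3_B=q3_b,
                abs_diff_median=med_d, abs_diff_q1=q1_d, abs_diff_q3=q3_d,
                n=int(a.size),
            )
        )
    table = pd.DataFrame([r.as_row() for r in results])
    return table, results
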