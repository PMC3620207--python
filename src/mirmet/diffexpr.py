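"""Two-library differential expression for miRNA counts.

Expression is normalised to reads per million clean reads; miRNAs whose
normalised value is below 1 in both libraries are removed, surviving zeros
are floored to 0.01, and the fold change is log2(treatment/control).
Significance comes from the Audic–Claverie exact test: conditional on
observing ``x`` counts in a library of ``N1`` total clean reads, the
probability of ``y`` counts in a library of ``N2`` reads is

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1 + N2/N1)^(x+y+1) )

and the two-sided p-value doubles the smaller tail (ties at the observed
``y`` included in both tails), capped at 1.  A miRNA is called up-regulated
when log2 fold change > 2 with p < 0.05, down-regulated when < −2 with
p < 0.05 (strict inequalities; thresholds configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

UP = "up-regulated"
DOWN = "down-regulated"
NS = "not-significant"
FILTERED = "filtered"

ZERO_FLOOR = 0.01


@dataclass(frozen=True)
class CountPair:
    """Counts for one feature in two libraries with their clean-read totals."""

    x: int   # control library count
    y: int   # treatment library count
    N1: int  # control library total clean reads
    N2: int  # treatment library total clean reads

    def __post_init__(self) -> None:
        for name in ("x", "y", "N1", "N2"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.N1 <= 0 or self.N2 <= 0:
            raise ValueError("library totals must be positive")
        if self.x > self.N1 or self.y > self.N2:
            raise ValueError("count exceeds its library total")


def normalize(count: int, total_clean: int) -> float:
    """Reads-per-million normalisation: count / total_clean * 1e6."""
    if total_clean <= 0:
        raise ValueError("total_clean must be positive")
    if not 0 <= count <= total_clean:
        raise ValueError("count must lie in [0, total_clean]")
    return count / total_clean * 1e6


def floor_and_filter(
    norm_pairs: dict[str, tuple[float, float]], mode: str = "both"
) -> tuple[dict[str, tuple[float, float]], list[str]]:
    """Drop low-expression miRNAs and floor exact zeros to 0.01.

    ``mode='both'`` removes a miRNA only when BOTH libraries are < 1 (the
    default: an 'either' rule would delete miRNAs expressed in only one
    condition, which are exactly the strongly differential ones);
    ``mode='either'`` removes when at least one library is < 1.

    Returns (retained mapping with floored values, removed names).
    """
    if mode not in ("both", "either"):
        raise ValueError("mode must be 'both' or 'either'")
    kept: dict[str, tuple[float, float]] = {}
    removed: list[str] = []
    for name, (a, b) in norm_pairs.items():
        if a < 0 or b < 0:
            raise ValueError("normalized values must be nonnegative")
        low = (a < 1 and b < 1) if mode == "both" else (a < 1 or b < 1)
        if low:
            removed.append(name)
        else:
            kept[name] = (a if a != 0 else ZERO_FLOOR, b if b != 0 else ZERO_FLOOR)
    return kept, removed


def fold_change(norm_control: float, norm_treatment: float) -> float:
    """log2(treatment / control); inputs must be positive (post-floor)."""
    if norm_control <= 0 or norm_treatment <= 0:
        raise ValueError("fold change requires positive values; apply the floor first")
    return math.log2(norm_treatment / norm_control)


def ac_log_pmf(x: int, y: int, n1: int, n2: int) -> float:
    """log p(y|x) of the Audic–Claverie conditional distribution."""
    logq = math.log(n2) - math.log(n1)
    log1pq = math.log1p(n2 / n1)
    return float(
        y * logq + gammaln(x + y + 1) - gammaln(x + 1) - gammaln(y + 1)
        - (x + y + 1) * log1pq
    )


def count_test_pvalue(pair: CountPair) -> float:
    """Two-sided Audic–Claverie p-value for a CountPair, in log space.

    The lower tail sums p(y'|x) for y' ≤ y with compensated summation; the
    upper tail is its complement plus the observed term, so ties count in
    both tails.  The doubled smaller tail is capped at 1.
    """
    x, y, n1, n2 = pair.x, pair.y, pair.N1, pair.N2
    logq = math.log(n2) - math.log(n1)
    log1pq = math.log1p(n2 / n1)
    yy = np.arange(0, y + 1)
    logp = (
        yy * logq
        + gammaln(x + yy + 1)
        - gammaln(x + 1)
        - gammaln(yy + 1)
        - (x + yy + 1) * log1pq
    )
    terms = np.exp(logp)
    lower = math.fsum(terms)
    p_obs = float(terms[-1])
    upper = max(p_obs, 1.0 - lower + p_obs)
    lower = min(lower, 1.0)
    return min(1.0, 2.0 * min(lower, upper))


def call_de(
    counts: pd.DataFrame,
    total_control: int,
    total_treatment: int,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    filter_mode: str = "both",
) -> pd.DataFrame:
    """Full differential-expression call for a two-library count table.

    ``counts`` needs columns ``mir_name``, ``count_control``,
    ``count_treatment``.  Returns a table with one row per input miRNA:
    normalised expressions, log2 fold change, Audic–Claverie p-value and
    status, sorted ascending by fold change (filtered rows last).
    """
    required = {"mir_name", "count_control", "count_treatment"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")
    norm_pairs = {
        str(r.mir_name): (
            normalize(int(r.count_control), total_control),
            normalize(int(r.count_treatment), total_treatment),
        )
        for r in counts.itertuples()
    }
    kept, removed = floor_and_filter(norm_pairs, mode=filter_mode)
    raw = {
        str(r.mir_name): (int(r.count_control), int(r.count_treatment))
        for r in counts.itertuples()
    }
    rows = []
    for name, (nc, nt) in kept.items():
        fc = fold_change(nc, nt)
        p = count_test_pvalue(
            CountPair(raw[name][0], raw[name][1], total_control, total_treatment)
        )
        rows.append((name, nc, nt, fc, p, classify_status(fc, p, fc_threshold, alpha)))
    out = pd.DataFrame(
        rows,
        columns=["mir_name", "norm_control", "norm_treatment",
                 "fold_change", "p_value", "status"],
    ).sort_values("fold_change", kind="mergesort").reset_index(drop=True)
    if removed:
        out = pd.concat(
            [out, pd.DataFrame({
                "mir_name": removed,
                "norm_control": np.nan, "norm_treatment": np.nan,
                "fold_change": np.nan, "p_value": np.nan,
                "status": FILTERED,
            })],
            ignore_index=True,
        )
    return out


def classify_status(
    fc: float, p: float, fc_threshold: float = 2.0, alpha: float = 0.05
) -> str:
    """Status from a (log2 fold change, p-value) pair under strict thresholds."""
    if fc > fc_threshold and p < alpha:
        return UP
    if fc < -fc_threshold and p < alpha:
        return DOWN
    return NS
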