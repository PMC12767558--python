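"""Nonparametric inference layer.

Implements the tests used for the study's per-animal paired outcomes:

* **Wilcoxon signed-rank** on paired samples, statistic
  ``W = min(T⁺, T⁻)`` after dropping zero differences and midranking ties.
  The asymptotic p-value uses the normal approximation *without* continuity
  correction (``z = (W − n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 − Σ(t³−t)/48)``);
  this is the variant that yields the familiar p = 0.028 for six uniformly
  signed pairs.  The exact p-value enumerates the null distribution of the
  rank sum over all ``2ⁿ`` sign assignments (computed by subset-sum
  convolution, which is identical to full enumeration when no magnitudes
  tie).
* **Friedman test** across repeated conditions with midranks and the
  standard tie correction; the statistic is referred to χ² with k−1 df.
* **Family-wise α splitting** (Bonferroni, ``α/m``) and the z-approximation
  sample-size formula for two-sample or paired designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class InsufficientDataError(ValueError):
    """Fewer than two informative pairs after zero-difference removal."""


@dataclass
class StatResult:
    """Outcome of one hypothesis test."""

    statistic: float
    p_two_sided: float
    method: str
    n_effective: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


def _signed_ranks(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks of |d| and the sign pattern, zeros already removed."""
    ranks = sps.rankdata(np.abs(d))
    return ranks, np.sign(d)


def exact_rank_sum_distribution(ranks: np.ndarray) -> dict[float, int]:
    """Null counts of the positive rank sum over all sign assignments.

    With distinct magnitudes the ranks are 1..n and this subset-sum
    convolution enumerates exactly the ``2ⁿ`` equally likely sign vectors.
    Ranks are scaled by 2 internally so midranks (halves) stay integral.
    """
    scaled = np.round(np.asarray(ranks) * 2).astype(int)
    total = int(scaled.sum())
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in scaled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return {s / 2.0: int(c) for s, c in enumerate(counts) if c}


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray, mode: str = "asymptotic"
) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    ``mode='asymptotic'`` uses the normal approximation without continuity
    correction and with the tie-correction term in the variance;
    ``mode='exact'`` enumerates the exact null distribution and is only
    valid without tied magnitudes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise InsufficientDataError("need at least 2 pairs")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n < 2:
        raise InsufficientDataError(
            "fewer than 2 nonzero differences; test undefined"
        )
    ranks, signs = _signed_ranks(d)
    t_plus = float(ranks[signs > 0].sum())
    t_minus = float(ranks[signs < 0].sum())
    w = min(t_plus, t_minus)

    if mode == "asymptotic":
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        if var <= 0:
            raise InsufficientDataError(
                "all differences tie; asymptotic variance is zero"
            )
        z = (w - mu) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
        return StatResult(
            statistic=w, p_two_sided=min(p, 1.0),
            method="wilcoxon_asymptotic", n_effective=n,
        )
    if mode == "exact":
        if np.unique(np.abs(d)).size != n:
            raise ValueError(
                "exact mode requires untied difference magnitudes"
            )
        dist = exact_rank_sum_distribution(ranks)
        total = 2.0**n
        # two-sided: double the tail probability of the smaller rank sum
        p = 2.0 * sum(c for s, c in dist.items() if s <= w) / total
        return StatResult(
            statistic=w, p_two_sided=min(p, 1.0),
            method="wilcoxon_exact", n_effective=n,
        )
    raise ValueError("mode must be 'asymptotic' or 'exact'")


def friedman(data: np.ndarray) -> StatResult:
    """Friedman test on a units × conditions matrix (midranks, tie-corrected).

    Uses the χ² form ``T = (k−1) · Σ_j (R_j − n(k+1)/2)² / (A − C)`` with
    ``A = Σ r_ij²`` and ``C = nk(k+1)²/4``, which reduces to the classic
    statistic without ties.  If every row is constant the statistic is 0
    and p = 1.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D units × conditions matrix")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 units and 2 conditions")
    r = np.apply_along_axis(sps.rankdata, 1, data)
    col_sums = r.sum(axis=0)
    a = float(np.sum(r**2))
    c = n * k * (k + 1) ** 2 / 4.0
    if a == c:  # every row constant: no information
        return StatResult(0.0, 1.0, "friedman", n)
    stat = (k - 1) * float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2)) / (
        a - c
    )
    p = float(sps.chi2.sf(stat, k - 1))
    return StatResult(stat, p, "friedman", n)


def familywise_alpha(fwer: float, m: int) -> float:
    """Bonferroni per-comparison level ``fwer / m``."""
    if not 0.0 < fwer < 1.0:
        raise ValueError("fwer must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return fwer / m


def sample_size_z(
    delta: float,
    sigma: float,
    alpha: float = 0.05,
    power: float = 0.80,
    design: str = "two_sample",
) -> int:
    """Per-group sample size from the z-approximation.

    ``two_sample``: ``n = ceil(2 (z_{1−α/2} + z_power)² (σ/δ)²)``;
    ``paired`` drops the factor 2.
    """
    if delta <= 0 or sigma <= 0:
        raise ValueError("delta and sigma must be > 0")
    if not 0.0 < alpha < 1.0 or not 0.0 < power < 1.0:
        raise ValueError("alpha and power must lie in (0, 1)")
    if power <= alpha / 2.0:
        raise ValueError("power must exceed alpha/2")
    z_a = sps.norm.ppf(1.0 - alpha / 2.0)
    z_b = sps.norm.ppf(power)
    core = (z_a + z_b) ** 2 * (sigma / delta) ** 2
    if design == "two_sample":
        core *= 2.0
    elif design != "paired":
        raise ValueError("design must be 'two_sample' or 'paired'")
    return int(math.ceil(core))


def pairwise_wilcoxon_matrix(
    table: pd.DataFrame, mode: str = "asymptotic"
) -> pd.DataFrame:
    """Lower-triangular matrix of pairwise Wilcoxon p-values.

    ``table`` holds one row per unit and one column per condition (the
    per-disc summary layout).  Entry ``(i, j)`` with ``i > j`` is the
    two-sided p for conditions i vs j; the upper triangle and diagonal are
    NaN.  Values are rounded to 3 decimals, the precision used in reports.
    """
    conds = list(table.columns)
    out = pd.DataFrame(
        np.full((len(conds), len(conds)), np.nan), index=conds, columns=conds
    )
    for i, ci in enumerate(conds):
        for j in range(i):
            res = wilcoxon_signed_rank(
                table[ci].to_numpy(), table[conds[j]].to_numpy(), mode=mode
            )
            out.iloc[i, j] = round(res.p_two_sided, 3)
    return out
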