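"""Statistical primitives for small-cohort nonparametric comparisons.

The cohorts in dorsal-subiculum tracing studies are small (8–12 animals per
group, 3–7 per sex-stratified subgroup), so asymptotic rank-test p-values are
unreliable and the smallest attainable p is a combinatorial floor (e.g.
2/252 ≈ 0.0079 for a 5-vs-5 comparison). This module therefore computes the
*exact* null distribution of the Wilcoxon rank-sum statistic — with midranks
for ties — whenever the number of group assignments C(n1+n2, n1) is small
enough, and of the Wilcoxon signed-rank statistic for tie-free paired
differences. Benjamini–Hochberg FDR adjustment and a two-group
random-intercept linear mixed-effects fit (for repeated within-animal
measurements) round out the battery.

Exact nulls are computed by a subset-sum dynamic program over midranks
doubled to integers; the result is identical to complete enumeration of all
group assignments (or sign patterns) but runs in polynomial time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "LMEFit",
    "rank_sum_test",
    "signed_rank_test",
    "bh_adjust",
    "star_level",
    "fit_lme_two_group",
]

#: Largest number of group assignments for which the rank-sum null is exact.
#: C(22, 10) = 646,646 — the 10-vs-12 comparison of the largest cohorts —
#: falls under this cap, so every cohort-sized p-value is exact.
MAX_EXACT_ASSIGNMENTS = 700_000

#: Largest post-zero-drop n for which the signed-rank null is exact
#: (requires tie-free absolute differences).
MAX_EXACT_SIGNED_N = 30

_STAR_LADDER = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided nonparametric test."""

    test: str
    statistic: float
    n: tuple[int, ...]
    p_two_sided: float
    method: str  # exact_enumeration | normal_approx_tie_corrected | zero_difference_degenerate
    direction: int  # sign of the location difference (a vs b); 0 when equal

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "n": list(self.n),
            "p_two_sided": self.p_two_sided,
            "method": self.method,
            "direction": self.direction,
        }


@dataclass(frozen=True)
class LMEFit:
    """Two-group random-intercept mixed-model fit summary."""

    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    sigma2_u: float  # between-animal (random intercept) variance
    sigma2: float  # residual variance
    p_beta1: float  # Wald z p-value for the group effect
    n_animals: int
    n_measurements: int
    converged: bool
    reference_level: str = ""
    effect_level: str = ""

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _direction(x: np.ndarray, y: np.ndarray) -> int:
    return int(np.sign(np.median(x) - np.median(y)))


def _doubled_midranks(values: np.ndarray) -> np.ndarray:
    """Midranks scaled by 2 so that ties land on exact integers."""
    r2 = 2.0 * sps.rankdata(values, method="average")
    out = np.rint(r2).astype(np.int64)
    if not np.allclose(r2, out):  # pragma: no cover - midranks are half-integers
        raise AssertionError("doubled midranks must be integral")
    return out


def _subset_sum_counts(weights: np.ndarray, k: int) -> np.ndarray:
    """count[s] = number of k-subsets of ``weights`` with element sum s.

    Equivalent to enumerating all C(n, k) assignments; used for the exact
    rank-sum null over (doubled) midranks.
    """
    total = int(weights.sum())
    dp = np.zeros((k + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for w in weights:
        w = int(w)
        # iterate subset sizes implicitly via the slice; rows update bottom-up
        dp[1:, w:] = dp[1:, w:] + dp[:-1, : total + 1 - w]
    return dp[k]


def _sign_sum_counts(weights: np.ndarray) -> np.ndarray:
    """count[s] = number of sign patterns whose positive-part sum is s.

    The signed-rank null: each of the n (doubled) ranks independently enters
    the positive sum or not; 2^n patterns in total.
    """
    total = int(weights.sum())
    dp = np.zeros(total + 1, dtype=np.float64)
    dp[0] = 1.0
    for w in weights:
        w = int(w)
        nxt = dp.copy()
        nxt[w:] += dp[: total + 1 - w]
        dp = nxt
    return dp


def _two_sided_from_counts(counts: np.ndarray, stat2: int) -> float:
    """Two-sided p from an exact integer-support null: 2·min(tails), capped."""
    total = counts.sum()
    lower = counts[: stat2 + 1].sum() / total
    upper = counts[stat2:].sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def rank_sum_test(
    x,
    y,
    *,
    max_exact_assignments: int = MAX_EXACT_ASSIGNMENTS,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Uses the exact permutation null over all C(n1+n2, n1) group assignments
    (midranks for ties) whenever that count is at most
    ``max_exact_assignments``; otherwise a tie- and continuity-corrected
    normal approximation. The statistic reported is the rank sum of ``x``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks2 = _doubled_midranks(pooled)
    w2 = int(ranks2[:n1].sum())  # doubled rank sum of x

    if math.comb(n, n1) <= max_exact_assignments:
        counts = _subset_sum_counts(ranks2, n1)
        p = _two_sided_from_counts(counts, w2)
        method = "exact_enumeration"
    else:
        mean2 = n1 * (n + 1)  # doubled scale
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        var2 = 4.0 * n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var2 <= 0:
            p = 1.0
        else:
            sd2 = math.sqrt(var2)
            lower = sps.norm.cdf((w2 - mean2 + 1.0) / sd2)  # continuity: 0.5 on raw scale
            upper = sps.norm.sf((w2 - mean2 - 1.0) / sd2)
            p = float(min(1.0, 2.0 * min(lower, upper)))
        method = "normal_approx_tie_corrected"

    return TestResult(
        test="wilcoxon_rank_sum",
        statistic=w2 / 2.0,
        n=(n1, n2),
        p_two_sided=p,
        method=method,
        direction=_direction(x, y),
    )


def signed_rank_test(
    d,
    *,
    max_exact_n: int = MAX_EXACT_SIGNED_N,
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon convention). The exact null over
    all 2^n sign patterns is used when the remaining n is at most
    ``max_exact_n`` — midranks keep the enumeration exact under ties among
    the absolute differences; beyond that a tie-corrected normal
    approximation. All-zero input is a degenerate case with p = 1.
    """
    d = np.asarray(d, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("signed_rank_test requires at least one difference")
    direction = int(np.sign(np.median(d)))
    nz = d[d != 0.0]
    if nz.size == 0:
        return TestResult(
            test="wilcoxon_signed_rank", statistic=0.0, n=(0,), p_two_sided=1.0,
            method="zero_difference_degenerate", direction=0,
        )
    n = nz.size
    absd = np.abs(nz)
    ranks2 = _doubled_midranks(absd)
    wpos2 = int(ranks2[nz > 0].sum())

    if n <= max_exact_n:
        counts = _sign_sum_counts(ranks2)
        p = _two_sided_from_counts(counts, wpos2)
        method = "exact_enumeration"
    else:
        mean2 = n * (n + 1) / 2.0
        _, tie_counts = np.unique(absd, return_counts=True)
        var2 = 4.0 * (n * (n + 1) * (2 * n + 1) / 24.0
                      - (tie_counts**3 - tie_counts).sum() / 48.0)
        if var2 <= 0:
            p = 1.0
        else:
            sd2 = math.sqrt(var2)
            lower = sps.norm.cdf((wpos2 - mean2 + 1.0) / sd2)
            upper = sps.norm.sf((wpos2 - mean2 - 1.0) / sd2)
            p = float(min(1.0, 2.0 * min(lower, upper)))
        method = "normal_approx_tie_corrected"

    return TestResult(
        test="wilcoxon_signed_rank",
        statistic=wpos2 / 2.0,
        n=(n,),
        p_two_sided=p,
        method=method,
        direction=direction,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order.

    q_(i) = p_(i)·m/i with a running minimum enforced from the largest rank
    down, capped at 1.
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def star_level(p: float) -> str:
    """Map a p-value to the conventional significance-star ladder."""
    if not (0 <= p <= 1):
        raise ValueError("p must lie in [0, 1]")
    for threshold, stars in _STAR_LADDER:
        if p <= threshold:
            return stars
    return "ns"


def fit_lme_two_group(values, animal_ids, group_labels) -> LMEFit:
    """Fit value_ij = β₀ + β₁·[group_i = B] + u_i + ε_ij by REML.

    u_i ~ N(0, σ²_u) is a per-animal random intercept absorbing within-animal
    correlation of repeated measurements; ε_ij ~ N(0, σ²). The group effect
    β₁ is tested with a Wald z statistic. The effect level B is the second
    of the sorted unique group labels.
    """
    import statsmodels.api as sm

    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "animal": np.asarray(animal_ids),
        "group": np.asarray(group_labels),
    })
    levels = sorted(df["group"].unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two group levels required, got {levels}")
    for lvl in levels:
        if df.loc[df["group"] == lvl, "animal"].nunique() < 2:
            raise ValueError(f"group {lvl!r} has fewer than 2 animals")
    if float(np.var(df["value"])) == 0.0:
        raise ValueError("degenerate data: zero total variance")

    ref, eff = levels
    exog = sm.add_constant((df["group"] == eff).astype(float).to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(df["value"].to_numpy(), exog, groups=df["animal"].to_numpy())
        # gradient optimizers can diverge when sigma2_u sits on the zero
        # boundary; keep the best converged fit with finite standard errors
        res, best = None, None
        for method in (None, "powell"):
            try:
                fit = model.fit(reml=True) if method is None else model.fit(reml=True, method=method)
            except Exception:
                continue
            ok = (bool(getattr(fit, "converged", False))
                  and np.all(np.isfinite(fit.bse[:2]))
                  and float(np.max(fit.bse[:2])) < 1e6 * (1.0 + abs(float(fit.params[0]))))
            if ok:
                res = fit
                break
            score = float(fit.llf) if np.isfinite(fit.llf) else -np.inf
            if best is None or score > best[0]:
                best = (score, fit)
        if res is None:
            if best is None:
                raise RuntimeError("mixed-model fit failed under all optimizers")
            res = best[1]
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    z = params[1] / bse[1]
    return LMEFit(
        beta0=float(params[0]),
        beta1=float(params[1]),
        se_beta0=float(bse[0]),
        se_beta1=float(bse[1]),
        sigma2_u=float(np.asarray(res.cov_re)[0, 0]),
        sigma2=float(res.scale),
        p_beta1=float(2.0 * sps.norm.sf(abs(z))),
        n_animals=int(df["animal"].nunique()),
        n_measurements=int(len(df)),
        converged=bool(getattr(res, "converged", True)),
        reference_level=str(ref),
        effect_level=str(eff),
    )
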