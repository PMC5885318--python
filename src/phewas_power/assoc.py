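"""Single-SNP additive association tests.

Binary traits use maximum-likelihood logistic regression of case status on
the minor-allele count (logit P(case) = b0 + b1*g); quantitative traits use
ordinary least squares with an intercept, tested with the exact t statistic
on n-2 df.

The logistic slope is tested with the likelihood-ratio statistic (reported
as the signed likelihood root, sign(b1) * sqrt(deviance), so ``stat`` stays
on a z-like scale).  The Wald z = b1/se is deliberately not used for the
p-value: at PheWAS-typical strata (tens to hundreds of cases, minor allele
frequencies of a few percent) the Wald statistic's far tail is strongly
deflated — the standard error inflates with |b1| (the Hauck-Donner effect),
so rejections at thresholds like 2.5e-4 become several-fold too rare and
Type I error is no longer nominal.  The LRT tail is calibrated at these
sizes.  ``beta`` and ``se`` (the Wald SE) are still reported for effect
interpretation.

Because the additive genotype takes only three values, the logistic
likelihood depends on the data only through the 2x3 genotype-by-status
table; the fit therefore runs Newton iterations on aggregated counts, which
makes a power run (tens of thousands of fits) cheap.  Degenerate inputs —
constant genotype, single-class status, complete separation — yield a
non-converged result with an undefined (NaN) p-value rather than an
exception, so a Monte-Carlo power run never aborts mid-grid; the power
engine counts such tests as non-significant and tallies them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import stdtr

__all__ = ["AssocResult", "fit_logistic_additive", "fit_logistic_counts", "fit_linear_additive"]

_MAX_ITER = 50
_LL_TOL = 1e-8
# |log-odds per allele| beyond this is numerically infinite for any realistic
# cohort: treat as (quasi-)complete separation
_SEPARATION_BETA = 30.0
_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class AssocResult:
    """One association test: per-allele effect, its SE, statistic, p-value.

    ``beta`` is the log-odds per minor allele (logistic) or trait units per
    minor allele (linear).  ``stat`` is the signed likelihood-root (logistic)
    or the t statistic on ``df`` = n-2 degrees of freedom (linear).  When
    ``converged`` is False the remaining fields are NaN.
    """

    beta: float
    se: float
    stat: float
    pvalue: float
    converged: bool
    n: int
    df: int | None = None

    @staticmethod
    def failed(n: int, df: int | None = None) -> "AssocResult":
        return AssocResult(math.nan, math.nan, math.nan, math.nan, False, n, df)


def _norm_sf2(z: float) -> float:
    """Two-sided standard-normal tail probability."""
    return math.erfc(abs(z) / _SQRT2)


def _loglik(n: tuple, y: tuple, b0: float, b1: float) -> float:
    ll = 0.0
    for g in (0, 1, 2):
        ng = n[g]
        if ng == 0:
            continue
        eta = b0 + b1 * g
        # log(1 + e^eta), overflow-safe
        if eta > 0:
            lse = eta + math.log1p(math.exp(-eta))
        else:
            lse = math.log1p(math.exp(eta))
        ll += y[g] * eta - ng * lse
    return ll


def fit_logistic_counts(genotype_counts, case_counts) -> AssocResult:
    """Additive logistic fit from the aggregated 2x3 table.

    Parameters
    ----------
    genotype_counts
        Individuals with genotype 0, 1, 2 (length-3).
    case_counts
        Cases among them (length-3).

    Newton iterations on the exact binomial log-likelihood, tolerance 1e-8 on
    the log-likelihood change, at most 50 iterations with step halving.  The
    p-value is the two-sided likelihood-ratio test of slope = 0.
    """
    n = tuple(int(v) for v in genotype_counts)
    y = tuple(int(v) for v in case_counts)
    total = sum(n)
    total_y = sum(y)
    if any(yg < 0 or yg > ng for yg, ng in zip(y, n)):
        raise ValueError("case_counts must satisfy 0 <= cases <= individuals per genotype")
    present = [g for g in (0, 1, 2) if n[g] > 0]
    if len(present) < 2 or total_y == 0 or total_y == total:
        # constant genotype, or no variation in status: slope not identifiable
        return AssocResult.failed(total)

    rate = total_y / total
    b0 = math.log(rate / (1.0 - rate))
    b1 = 0.0
    ll = _loglik(n, y, b0, b1)
    i00 = i01 = i11 = 0.0
    converged = False
    for _ in range(_MAX_ITER):
        g0 = g1 = 0.0
        i00 = i01 = i11 = 0.0
        for g in present:
            eta = b0 + b1 * g
            p = 1.0 / (1.0 + math.exp(-eta)) if eta > -700 else 0.0
            w = n[g] * p * (1.0 - p)
            r = y[g] - n[g] * p
            g0 += r
            g1 += r * g
            i00 += w
            i01 += w * g
            i11 += w * g * g
        det = i00 * i11 - i01 * i01
        if det <= 1e-300:
            return AssocResult.failed(total)
        d0 = (i11 * g0 - i01 * g1) / det
        d1 = (-i01 * g0 + i00 * g1) / det
        step = 1.0
        for _ in range(16):
            nb0, nb1 = b0 + step * d0, b1 + step * d1
            nll = _loglik(n, y, nb0, nb1)
            if nll >= ll:
                break
            step *= 0.5
        else:
            nb0, nb1, nll = b0, b1, ll
        delta = nll - ll
        b0, b1, ll = nb0, nb1, nll
        if abs(delta) < _LL_TOL:
            converged = True
            break
    if not converged or abs(b1) > _SEPARATION_BETA:
        return AssocResult.failed(total)
    det = i00 * i11 - i01 * i01
    se = math.sqrt(i00 / det)
    # signed likelihood-root: sign(b1) * sqrt(2 * (ll_full - ll_null))
    ll0 = total_y * math.log(rate) + (total - total_y) * math.log(1.0 - rate)
    deviance = max(2.0 * (ll - ll0), 0.0)
    stat = math.copysign(math.sqrt(deviance), b1)
    return AssocResult(
        beta=b1, se=se, stat=stat, pvalue=_norm_sf2(stat), converged=True, n=total
    )


def fit_logistic_additive(genotypes, status) -> AssocResult:
    """Additive logistic regression of 0/1 status on minor-allele count."""
    g = np.asarray(genotypes)
    s = np.asarray(status)
    if g.shape != s.shape or g.ndim != 1:
        raise ValueError("genotypes and status must be 1-D of equal length")
    if not np.isin(s, (0, 1)).all():
        raise ValueError("status must be binary 0/1")
    n = [int((g == k).sum()) for k in (0, 1, 2)]
    y = [int(s[g == k].sum()) for k in (0, 1, 2)]
    return fit_logistic_counts(n, y)


def fit_linear_additive(genotypes, trait) -> AssocResult:
    """Ordinary least squares of a quantitative trait on minor-allele count.

    Two-sided t-test on the slope with n-2 residual degrees of freedom.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(trait, dtype=float)
    if g.shape != y.shape or g.ndim != 1:
        raise ValueError("genotypes and trait must be 1-D of equal length")
    nobs = g.size
    if nobs < 3:
        raise ValueError(f"need n >= 3 observations, got {nobs}")
    df = nobs - 2
    gm = g.mean()
    sxx = float(np.dot(g, g) - nobs * gm * gm)
    if sxx <= 0.0:
        return AssocResult.failed(nobs, df)
    ym = y.mean()
    sxy = float(np.dot(g, y) - nobs * gm * ym)
    yc = y - ym
    syy = float(np.dot(yc, yc))
    if syy <= 1e-24 * nobs * (ym * ym + 1.0):
        # trait numerically constant: zero slope, no evidence
        return AssocResult(0.0, 0.0, 0.0, 1.0, True, nobs, df)
    slope = sxy / sxx
    rss = syy - slope * sxy
    if rss <= 0.0:
        # numerically exact fit: zero residual variance
        if slope == 0.0:
            return AssocResult(0.0, 0.0, 0.0, 1.0, True, nobs, df)
        return AssocResult(slope, 0.0, math.inf, 0.0, True, nobs, df)
    se = math.sqrt(rss / df / sxx)
    t = slope / se
    pvalue = 2.0 * float(stdtr(df, -abs(t)))
    return AssocResult(beta=slope, se=se, stat=t, pvalue=pvalue, converged=True, n=nobs, df=df)
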