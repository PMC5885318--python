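"""Penetrance-model phenotype simulation.

Binary traits
-------------
Disease risk is parameterised by a penetrance function (f0, f1, f2): the
probability of being a case given 0/1/2 copies of the minor (risk) allele.
The baseline f0 is the disease prevalence among non-carriers (0.1 by
default), the scalar "penetrance" of a simulation cell is the homozygote
risk f2, and f1 is the midpoint — additive on the risk scale.  Cohorts are
sampled retrospectively: individuals are drawn genotype-first from HWE, their
status from Bernoulli(f(g)), and accepted into the case or control stratum
until both quotas fill.  Consequently the case genotype distribution is
proportional to HWE(g)*f(g) and the control distribution to HWE(g)*(1-f(g)).

Quantitative traits
-------------------
The same penetrance function is mapped onto a liability-threshold model:
trait = beta*g + N(0,1) with beta chosen so that the probability of exceeding
the population threshold Phi^-1(1-f0) is f0 for non-carriers and f2 for
minor-allele homozygotes.  Genotypes are thereby enriched in the tails of the
trait distribution, and beta has the closed form
(Phi^-1(1-f0) - Phi^-1(1-f2)) / 2.

Noise phenotypes are independent of every genotype: a random permutation of
the case/control labels (binary) or fresh standard-normal draws
(quantitative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .genotype import SNPSpec, draw_genotypes, hwe_genotype_probs

__all__ = [
    "PenetranceFunction",
    "BinaryCohort",
    "QuantCohort",
    "penetrance_table",
    "sample_case_control",
    "expected_case_genotype_dist",
    "expected_control_genotype_dist",
    "expected_prevalence",
    "liability_effect_size",
    "sample_quantitative",
    "make_noise_phenotype",
]

DEFAULT_DRAW_CAP = 10**7


@dataclass(frozen=True)
class PenetranceFunction:
    """P(case | genotype) for minor-allele counts 0, 1, 2.

    Risk is monotone in the minor-allele count (the risk allele is always the
    minor allele; protective coding is not modelled).
    """

    f0: float
    f1: float
    f2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f0 <= self.f1 <= self.f2 <= 1.0):
            raise ValueError(
                f"penetrances must satisfy 0 <= f0 <= f1 <= f2 <= 1, got "
                f"({self.f0}, {self.f1}, {self.f2})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.f0, self.f1, self.f2], dtype=float)

    def __call__(self, g: int) -> float:
        return (self.f0, self.f1, self.f2)[g]


@dataclass(frozen=True)
class BinaryCohort:
    """Case/control cohort: genotypes plus 0/1 status, cases first."""

    genotypes: np.ndarray
    status: np.ndarray
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if len(self.genotypes) != len(self.status):
            raise ValueError("genotypes and status must have equal length")
        if int(self.status.sum()) != self.n_cases:
            raise ValueError("status does not sum to n_cases")
        if len(self.status) != self.n_cases + self.n_controls:
            raise ValueError("cohort length != n_cases + n_controls")


@dataclass(frozen=True)
class QuantCohort:
    """Quantitative cohort: genotypes plus real-valued trait."""

    genotypes: np.ndarray
    trait: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genotypes) != len(self.trait):
            raise ValueError("genotypes and trait must have equal length")
        if not np.all(np.isfinite(self.trait)):
            raise ValueError("trait values must be finite")


def penetrance_table(
    baseline: float, penetrance: float, mode: str = "additive_risk"
) -> PenetranceFunction:
    """Build the penetrance triple from a baseline prevalence and a scalar
    homozygote penetrance.

    Under ``additive_risk`` the heterozygote risk is the midpoint
    (f0 + f2) / 2, i.e. risk is additive per allele on the probability scale.
    """
    if mode != "additive_risk":
        raise ValueError(f"unknown mode {mode!r}; only 'additive_risk' is supported")
    if not (0.0 < baseline <= 1.0):
        raise ValueError(f"baseline must lie in (0, 1], got {baseline}")
    if not (baseline <= penetrance <= 1.0):
        raise ValueError(
            f"penetrance must lie in [baseline, 1]; got penetrance={penetrance}, "
            f"baseline={baseline} (protective coding is not modelled)"
        )
    return PenetranceFunction(baseline, (baseline + penetrance) / 2.0, penetrance)


def expected_prevalence(pf: PenetranceFunction, maf: float) -> float:
    """Marginal P(case) = sum_g HWE(g) * f(g)."""
    probs = hwe_genotype_probs(maf)
    f = pf.as_array()
    return float(np.dot(probs, f))


def expected_case_genotype_dist(pf: PenetranceFunction, maf: float) -> tuple[float, float, float]:
    """Genotype distribution among cases under retrospective sampling.

    Bayes: P(g | case) = HWE(g) * f(g) / sum_g HWE(g) * f(g).
    """
    probs = np.asarray(hwe_genotype_probs(maf))
    w = probs * pf.as_array()
    total = w.sum()
    if total <= 0.0:
        raise ValueError("penetrance function assigns zero case probability everywhere")
    return tuple(w / total)


def expected_control_genotype_dist(pf: PenetranceFunction, maf: float) -> tuple[float, float, float]:
    """Genotype distribution among controls: P(g | control) ∝ HWE(g) * (1 - f(g))."""
    probs = np.asarray(hwe_genotype_probs(maf))
    w = probs * (1.0 - pf.as_array())
    total = w.sum()
    if total <= 0.0:
        raise ValueError("penetrance function assigns zero control probability everywhere")
    return tuple(w / total)


def sample_case_control(
    pf: PenetranceFunction,
    maf: float,
    n_cases: int,
    ratio: float,
    rng: np.random.Generator,
    draw_cap: int = DEFAULT_DRAW_CAP,
) -> BinaryCohort:
    """Retrospectively sample a case/control cohort.

    Individuals are generated genotype-first (HWE at ``maf``), then assigned
    case status with probability f(genotype), and accepted into the case or
    control stratum until both quotas are filled; surplus draws beyond a
    filled quota are discarded.  ``ratio`` is controls per case ("1:2" -> 2);
    non-integer ratios are rounded to the nearest integer control count.

    Raises after ``draw_cap`` population draws if a quota cannot fill
    (degenerate penetrance: all-zero requesting cases, all-one requesting
    controls).
    """
    if n_cases < 1:
        raise ValueError(f"n_cases must be >= 1, got {n_cases}")
    if ratio < 1:
        raise ValueError(f"ratio (controls per case) must be >= 1, got {ratio}")
    n_controls = int(round(n_cases * ratio))

    probs = hwe_genotype_probs(maf)
    f = pf.as_array()
    p_case = expected_prevalence(pf, maf)

    case_parts: list[np.ndarray] = []
    ctrl_parts: list[np.ndarray] = []
    got_cases = got_ctrls = 0
    drawn = 0
    while got_cases < n_cases or got_ctrls < n_controls:
        # size batches by the expected number of draws needed for the
        # binding stratum, padded to keep the loop count small
        need_c = n_cases - got_cases
        need_k = n_controls - got_ctrls
        exp_draws = 0.0
        if need_c > 0:
            exp_draws = max(exp_draws, need_c / max(p_case, 1e-12))
        if need_k > 0:
            exp_draws = max(exp_draws, need_k / max(1.0 - p_case, 1e-12))
        batch = int(min(max(2.0 * exp_draws, 256.0), max(draw_cap - drawn, 0)))
        if batch <= 0:
            raise RuntimeError(
                f"draw cap {draw_cap} exhausted with {got_cases}/{n_cases} cases and "
                f"{got_ctrls}/{n_controls} controls; penetrance function is degenerate "
                "for the requested stratum"
            )
        u = rng.random(batch)
        g = np.empty(batch, dtype=np.int8)
        g[:] = 2
        g[u < probs[0] + probs[1]] = 1
        g[u < probs[0]] = 0
        is_case = rng.random(batch) < f[g]
        drawn += batch
        if got_cases < n_cases:
            new = g[is_case][: n_cases - got_cases]
            if new.size:
                case_parts.append(new)
                got_cases += new.size
        if got_ctrls < n_controls:
            new = g[~is_case][: n_controls - got_ctrls]
            if new.size:
                ctrl_parts.append(new)
                got_ctrls += new.size

    genotypes = np.concatenate(case_parts + ctrl_parts)
    status = np.zeros(n_cases + n_controls, dtype=np.int8)
    status[:n_cases] = 1
    return BinaryCohort(genotypes=genotypes, status=status, n_cases=n_cases, n_controls=n_controls)


def liability_effect_size(baseline: float, penetrance: float) -> float:
    """Per-allele mean shift beta of the liability-calibrated trait model.

    With trait Y | g ~ Normal(beta * g, 1) and threshold T = Phi^-1(1 - baseline),
    beta = (Phi^-1(1-baseline) - Phi^-1(1-penetrance)) / 2 makes
    P(Y > T | g=0) = baseline and P(Y > T | g=2) = penetrance.  Zero iff
    penetrance equals baseline (the null model).
    """
    if not (0.0 < baseline < 1.0):
        raise ValueError(f"baseline must lie in (0, 1), got {baseline}")
    if not (baseline <= penetrance < 1.0):
        raise ValueError(
            f"penetrance must lie in [baseline, 1), got {penetrance} with baseline {baseline}"
        )
    return float(norm.ppf(1.0 - baseline) - norm.ppf(1.0 - penetrance)) / 2.0


def sample_quantitative(
    beta: float, maf: float, n: int, rng: np.random.Generator
) -> QuantCohort:
    """Sample a quantitative cohort: genotype ~ HWE(maf), trait = beta*g + N(0,1)."""
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    g = draw_genotypes(SNPSpec(maf=maf, label="signal"), n, rng)
    trait = beta * g.astype(float) + rng.standard_normal(n)
    return QuantCohort(genotypes=g, trait=trait)


def make_noise_phenotype(
    template: BinaryCohort | QuantCohort, rng: np.random.Generator
) -> np.ndarray:
    """Phenotype vector independent of every genotype.

    Binary: a uniformly random permutation of a status vector with the
    template's case/control counts.  Quantitative: fresh N(0,1) draws of the
    template's length.
    """
    if isinstance(template, BinaryCohort):
        if len(template.status) == 0:
            raise ValueError("template cohort is empty")
        return rng.permutation(template.status)
    if isinstance(template, QuantCohort):
        if len(template.trait) == 0:
            raise ValueError("template cohort is empty")
        return rng.standard_normal(len(template.trait))
    raise TypeError(f"unsupported template type {type(template).__name__}")
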