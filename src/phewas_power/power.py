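"""Replicate assembly and Monte-Carlo power / Type-I-error estimation.

A simulation *cell* fixes the trait type, effect parameters (MAF, baseline
prevalence, homozygote penetrance), and the sampling design (cases and
controls-per-case, or total n).  Each replicate dataset follows the standard
PheWAS layout: 4 SNPs x 10 phenotypes for binary traits (40 tests) or
4 SNPs x 1 phenotype for quantitative traits (4 tests), with exactly one
signal SNP-phenotype pair; the 3 remaining SNPs are noise drawn at the same
MAF, and the 9 remaining binary phenotypes are label permutations with the
same case/control counts.

Power is the fraction of replicates in which the signal pair attains
p < alpha; Type I error is the fraction of noise-pair tests attaining
p < alpha.  The default per-test thresholds are 0.00025 for the 40-test
binary battery (a Bonferroni split of a 0.01 family level) and 0.004 for the
4-test quantitative battery.  Non-converged fits count as non-significant
and are tallied separately — conservative at extreme cells (e.g. 10 cases at
MAF 0.01, where the minor-homozygote stratum is usually empty).

Determinism: every replicate draws from an independent substream seeded by
(master_seed, cell_index, replicate_index), so a grid run returns identical
results regardless of worker count or execution order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .assoc import fit_linear_additive, fit_logistic_counts
from .genotype import draw_noise_genotypes
from .phenotype import (
    expected_case_genotype_dist,
    expected_control_genotype_dist,
    liability_effect_size,
    make_noise_phenotype,
    penetrance_table,
    sample_case_control,
    sample_quantitative,
)

__all__ = [
    "SimDesign",
    "ReplicateDataset",
    "PowerEstimate",
    "alpha_threshold",
    "assemble_replicate",
    "run_cell",
    "run_grid",
    "analytic_power_linear",
    "analytic_power_binary",
    "DEFAULT_FAMILY_LEVEL",
    "DEFAULT_ALPHA_BINARY",
    "DEFAULT_ALPHA_QUANT",
]

logger = logging.getLogger(__name__)

DEFAULT_FAMILY_LEVEL = 0.01
#: Default per-test thresholds: binary is a Bonferroni split of the 0.01
#: family level over the 40-test battery.  The quantitative default is the
#: conventional published operating threshold for the 4-test battery, fixed
#: as a constant rather than derived (a strict 0.01/4 split would give
#: 0.0025; results are insensitive to the difference).
DEFAULT_ALPHA_BINARY = 0.00025
DEFAULT_ALPHA_QUANT = 0.004
_N_SNPS = 4
_N_PHENO_BINARY = 10
_N_PHENO_QUANT = 1


def alpha_threshold(family_level: float, n_tests: int) -> float:
    """Bonferroni-style per-test significance threshold: family_level / n_tests."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if not (0.0 < family_level < 1.0):
        raise ValueError(f"family_level must lie in (0, 1), got {family_level}")
    return family_level / n_tests


@dataclass(frozen=True)
class SimDesign:
    """One grid cell of the simulation.

    Binary designs need ``n_cases`` and ``ratio`` (controls per case);
    quantitative designs need ``n``.  ``penetrance`` is the minor-homozygote
    disease risk f2; ``baseline`` is the non-carrier prevalence f0.  If
    ``alpha`` is None the Bonferroni default family_level / n_tests applies.
    """

    trait: str
    maf: float
    penetrance: float
    baseline: float = 0.1
    n_cases: int | None = None
    ratio: float | None = None
    n: int | None = None
    replicates: int = 1000
    alpha: float | None = None
    family_level: float | None = None
    n_snps: int = _N_SNPS

    def __post_init__(self) -> None:
        if self.trait not in ("binary", "quantitative"):
            raise ValueError(f"trait must be 'binary' or 'quantitative', got {self.trait!r}")
        if self.trait == "binary":
            if self.n_cases is None or self.ratio is None:
                raise ValueError("binary designs require n_cases and ratio")
        else:
            if self.n is None:
                raise ValueError("quantitative designs require n")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.alpha is not None and not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")

    @property
    def n_phenotypes(self) -> int:
        return _N_PHENO_BINARY if self.trait == "binary" else _N_PHENO_QUANT

    @property
    def n_tests(self) -> int:
        return self.n_snps * self.n_phenotypes

    @property
    def effective_alpha(self) -> float:
        """Per-test threshold: explicit ``alpha`` wins, then a Bonferroni
        split of an explicit ``family_level``, then the trait default."""
        if self.alpha is not None:
            return self.alpha
        if self.family_level is not None:
            return alpha_threshold(self.family_level, self.n_tests)
        return DEFAULT_ALPHA_BINARY if self.trait == "binary" else DEFAULT_ALPHA_QUANT


@dataclass(frozen=True)
class ReplicateDataset:
    """One simulated dataset: genotype matrix (n x n_snps), phenotype matrix
    (n x n_phenotypes); column 0 of each is the signal pair."""

    genotypes: np.ndarray
    phenotypes: np.ndarray
    trait: str
    signal_snp: int = 0
    signal_phenotype: int = 0
    snp_labels: tuple = ()
    phenotype_labels: tuple = ()

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    def test_pairs(self) -> list[tuple[int, int]]:
        """All (snp, phenotype) index pairs in the association battery."""
        return [
            (s, p)
            for s in range(self.genotypes.shape[1])
            for p in range(self.phenotypes.shape[1])
        ]


@dataclass(frozen=True)
class PowerEstimate:
    """Monte-Carlo power and Type-I estimate for one design cell."""

    design: SimDesign
    power: float
    type1: float
    n_signal_tests: int
    n_noise_tests: int
    power_se: float
    type1_se: float
    n_nonconverged: int
    alpha: float


def _binomial_se(p: float, n: int) -> float:
    return math.sqrt(p * (1.0 - p) / n) if n > 0 else math.nan


def _replicate_rng(master_seed: int, cell_index: int, rep: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(cell_index), int(rep)))
    return np.random.default_rng(ss)


def assemble_replicate(design: SimDesign, rng: np.random.Generator) -> ReplicateDataset:
    """Build one replicate dataset for a design cell.

    One signal SNP tied to one signal phenotype through the penetrance model;
    ``n_snps - 1`` noise SNPs at the same MAF; for binary traits, 9 noise
    phenotypes that are label permutations with identical case/control counts.
    """
    pf = penetrance_table(design.baseline, design.penetrance)
    n_noise_snps = design.n_snps - 1
    if design.trait == "binary":
        cohort = sample_case_control(pf, design.maf, design.n_cases, design.ratio, rng)
        n = len(cohort.status)
        phenotypes = np.empty((n, _N_PHENO_BINARY), dtype=np.int8)
        phenotypes[:, 0] = cohort.status
        for j in range(1, _N_PHENO_BINARY):
            phenotypes[:, j] = make_noise_phenotype(cohort, rng)
        genotypes = np.empty((n, design.n_snps), dtype=np.int8)
        genotypes[:, 0] = cohort.genotypes
    else:
        beta = liability_effect_size(design.baseline, design.penetrance)
        cohort = sample_quantitative(beta, design.maf, design.n, rng)
        n = len(cohort.trait)
        phenotypes = cohort.trait.reshape(-1, 1)
        genotypes = np.empty((n, design.n_snps), dtype=np.int8)
        genotypes[:, 0] = cohort.genotypes
    for s in range(1, design.n_snps):
        genotypes[:, s] = draw_noise_genotypes(design.maf, n, rng)
    snp_labels = ("snp1_signal",) + tuple(f"snp{s + 1}_noise" for s in range(1, design.n_snps))
    if design.trait == "binary":
        pheno_labels = ("pheno1_signal",) + tuple(
            f"pheno{j + 1}_noise" for j in range(1, _N_PHENO_BINARY)
        )
    else:
        pheno_labels = ("pheno1_signal",)
    return ReplicateDataset(
        genotypes=genotypes,
        phenotypes=phenotypes,
        trait=design.trait,
        snp_labels=snp_labels,
        phenotype_labels=pheno_labels,
    )


def _battery_binary(dataset: ReplicateDataset, alpha: float) -> tuple[int, int, int]:
    """Run all snp x phenotype logistic tests on one binary replicate.

    Returns (signal_hits in {0,1}, noise_hits, n_nonconverged).  Tests are
    aggregated to 2x3 tables per pair; a whole phenotype column against one
    SNP needs only three masked column sums.
    """
    g = dataset.genotypes
    ph = dataset.phenotypes
    signal_hit = 0
    noise_hits = 0
    nonconv = 0
    for s in range(g.shape[1]):
        col = g[:, s]
        masks = [col == k for k in (0, 1, 2)]
        n_g = [int(m.sum()) for m in masks]
        # case counts per genotype for every phenotype at once
        y_g = np.stack([ph[m].sum(axis=0) for m in masks])  # (3, n_pheno)
        for p in range(ph.shape[1]):
            res = fit_logistic_counts(n_g, y_g[:, p])
            if not res.converged:
                nonconv += 1
                continue
            hit = res.pvalue < alpha
            if s == dataset.signal_snp and p == dataset.signal_phenotype:
                signal_hit = int(hit)
            elif hit:
                noise_hits += 1
    return signal_hit, noise_hits, nonconv


def _battery_quant(dataset: ReplicateDataset, alpha: float) -> tuple[int, int, int]:
    signal_hit = 0
    noise_hits = 0
    nonconv = 0
    trait = dataset.phenotypes[:, 0]
    for s in range(dataset.genotypes.shape[1]):
        res = fit_linear_additive(dataset.genotypes[:, s], trait)
        if not res.converged:
            nonconv += 1
            continue
        hit = res.pvalue < alpha
        if s == dataset.signal_snp:
            signal_hit = int(hit)
        elif hit:
            noise_hits += 1
    return signal_hit, noise_hits, nonconv


def run_cell(design: SimDesign, master_seed: int, cell_index: int = 0) -> PowerEstimate:
    """Monte-Carlo power and Type I error for one design cell.

    Runs ``design.replicates`` independent replicates, each from its own
    seed substream, and counts signal-pair and noise-pair rejections at the
    cell's per-test alpha.
    """
    alpha = design.effective_alpha
    battery = _battery_binary if design.trait == "binary" else _battery_quant
    signal_hits = 0
    noise_hits = 0
    nonconv = 0
    for rep in range(design.replicates):
        rng = _replicate_rng(master_seed, cell_index, rep)
        dataset = assemble_replicate(design, rng)
        s_hit, n_hits, n_nc = battery(dataset, alpha)
        signal_hits += s_hit
        noise_hits += n_hits
        nonconv += n_nc
    n_signal = design.replicates
    n_noise = design.replicates * (design.n_tests - 1)
    power = signal_hits / n_signal
    type1 = noise_hits / n_noise if n_noise else math.nan
    return PowerEstimate(
        design=design,
        power=power,
        type1=type1,
        n_signal_tests=n_signal,
        n_noise_tests=n_noise,
        power_se=_binomial_se(power, n_signal),
        type1_se=_binomial_se(type1, n_noise) if n_noise else math.nan,
        n_nonconverged=nonconv,
        alpha=alpha,
    )


def _cell_worker(args) -> PowerEstimate | Exception:
    design, master_seed, cell_index = args
    try:
        est = run_cell(design, master_seed, cell_index)
    except Exception as exc:  # a failed cell must not abort the grid
        logger.error("cell %d failed: %s", cell_index, exc)
        return exc
    logger.info(
        "cell %d done: trait=%s maf=%g pen=%g power=%.4f type1=%.5f nonconv=%d",
        cell_index, design.trait, design.maf, design.penetrance,
        est.power, est.type1, est.n_nonconverged,
    )
    return est


def run_grid(
    grid: list[SimDesign], master_seed: int, workers: int = 1
) -> pd.DataFrame:
    """Run every cell of a grid; returns one row per cell.

    Per-cell seed substreams derive from (master_seed, cell index), so the
    output is identical for any worker count.
    """
    if not grid:
        raise ValueError("grid must contain at least one design")
    tasks = [(design, master_seed, i) for i, design in enumerate(grid)]
    if workers > 1:
        from joblib import Parallel, delayed

        estimates = Parallel(n_jobs=workers)(delayed(_cell_worker)(t) for t in tasks)
    else:
        estimates = [_cell_worker(t) for t in tasks]
    rows = []
    for i, est in enumerate(estimates):
        if isinstance(est, Exception):
            d = grid[i]
            rows.append(
                {
                    "cell": i, "trait": d.trait, "n_cases": d.n_cases, "ratio": d.ratio,
                    "n": d.n, "maf": d.maf, "penetrance": d.penetrance,
                    "baseline": d.baseline, "replicates": d.replicates,
                    "alpha": d.effective_alpha, "power": math.nan, "type1": math.nan,
                    "power_se": math.nan, "type1_se": math.nan,
                    "n_noise_tests": 0, "n_nonconverged": 0, "error": str(est),
                }
            )
            continue
        d = est.design
        rows.append(
            {
                "cell": i,
                "trait": d.trait,
                "n_cases": d.n_cases,
                "ratio": d.ratio,
                "n": d.n if d.trait == "quantitative" else d.n_cases + int(round(d.n_cases * d.ratio)),
                "maf": d.maf,
                "penetrance": d.penetrance,
                "baseline": d.baseline,
                "replicates": d.replicates,
                "alpha": est.alpha,
                "power": est.power,
                "type1": est.type1,
                "power_se": est.power_se,
                "type1_se": est.type1_se,
                "n_noise_tests": est.n_noise_tests,
                "n_nonconverged": est.n_nonconverged,
            }
        )
    return pd.DataFrame(rows)


def analytic_power_linear(beta: float, maf: float, n: int, alpha: float) -> float:
    """Closed-form normal-approximation power for the quantitative model.

    With trait = beta*g + N(0,1) and g ~ HWE(maf), the slope estimate has
    variance ~ 1 / (n * 2*maf*(1-maf)); power of the two-sided level-alpha
    test is Phi(-z_{1-a/2} + delta) + Phi(-z_{1-a/2} - delta) with
    delta = beta * sqrt(n * 2*maf*(1-maf)).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    z = norm.ppf(1.0 - alpha / 2.0)
    delta = beta * math.sqrt(n * 2.0 * maf * (1.0 - maf))
    return float(norm.cdf(-z + delta) + norm.cdf(-z - delta))


def analytic_power_binary(
    pf, maf: float, n_cases: int, n_controls: int, alpha: float
) -> float:
    """Two-proportion normal-approximation power for the binary design.

    Contrasts the minor-allele frequency among cases and controls implied by
    retrospective sampling (Bayes on HWE x penetrance) with 2*n alleles per
    stratum.  An approximation to the logistic trend test, adequate away
    from very sparse strata.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    d_case = expected_case_genotype_dist(pf, maf)
    d_ctrl = expected_control_genotype_dist(pf, maf)
    p1 = (d_case[1] + 2.0 * d_case[2]) / 2.0
    p2 = (d_ctrl[1] + 2.0 * d_ctrl[2]) / 2.0
    var = p1 * (1.0 - p1) / (2.0 * n_cases) + p2 * (1.0 - p2) / (2.0 * n_controls)
    delta = (p1 - p2) / math.sqrt(var)
    z = norm.ppf(1.0 - alpha / 2.0)
    return float(norm.cdf(-z + delta) + norm.cdf(-z - delta))
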