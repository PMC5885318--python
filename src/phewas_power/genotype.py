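"""Biallelic SNP genotype simulation under Hardy-Weinberg equilibrium.

Genotypes are coded additively as minor-allele counts 0/1/2.  Each individual
is an i.i.d. multinomial draw from the HWE genotype probabilities
((1-q)^2, 2q(1-q), q^2) at minor allele frequency q; under HWE this is
equivalent to drawing the two alleles independently.  SNPs are drawn
independently of each other (no linkage disequilibrium) and of any phenotype
unless a penetrance model ties them together downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SNPSpec", "hwe_genotype_probs", "draw_genotypes", "draw_noise_genotypes"]

_ROLES = frozenset({"signal", "noise"})


@dataclass(frozen=True)
class SNPSpec:
    """A single simulated SNP: minor allele frequency, role, and label.

    ``maf`` must lie in [0, 0.5]: the minor allele is by definition the less
    common one, and maf=0 is allowed only as a degenerate (monomorphic) case
    for testing.
    """

    maf: float
    role: str = "signal"
    label: str = "snp"

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"maf must lie in [0, 0.5], got {self.maf}")
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {sorted(_ROLES)}, got {self.role!r}")


def hwe_genotype_probs(maf: float) -> tuple[float, float, float]:
    """Genotype probabilities (P(g=0), P(g=1), P(g=2)) under Hardy-Weinberg.

    Parameters
    ----------
    maf
        Minor allele frequency, in [0, 0.5].

    Returns
    -------
    tuple of three floats summing to 1: ((1-q)^2, 2q(1-q), q^2).
    """
    if not (0.0 <= maf <= 0.5):
        raise ValueError(f"maf must lie in [0, 0.5], got {maf}")
    q = float(maf)
    p = 1.0 - q
    return (p * p, 2.0 * p * q, q * q)


def draw_genotypes(spec: SNPSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` additive-coded genotypes for ``spec`` under HWE.

    Returns an int8 array of minor-allele counts in {0, 1, 2}.  The draw is
    deterministic given the generator state.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    p0, p1, _ = hwe_genotype_probs(spec.maf)
    u = rng.random(n)
    # inverse-CDF draw: cheaper than rng.choice with explicit probabilities
    g = np.empty(n, dtype=np.int8)
    g[:] = 2
    g[u < p0 + p1] = 1
    g[u < p0] = 0
    return g


def draw_noise_genotypes(maf: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw genotypes for a noise SNP: same MAF as the signal SNP, independent
    of every phenotype (it is never passed through a penetrance function)."""
    return draw_genotypes(SNPSpec(maf=maf, role="noise", label="noise"), n, rng)
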