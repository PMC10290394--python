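"""Selfing segregation, ALT-locus classification and mutation-rate estimation.

A heterozygous locus subjected to g successive self-fertilizations stays
heterozygous with probability (1/2)^g; the remaining probability splits
evenly between the two homozygous classes. After two selfings the
expected REF:HET:ALT ratio is therefore 3:2:3.

In a clone, homozygous-alternative calls are unexpected (somatic
mutations arise heterozygous); classifying which classes co-occur with
ALT at a locus distinguishes loss-of-heterozygosity conversion
(HET -> ALT in one sample, the rest still HET) from other explanations.

Somatic mutation rates are point-estimated as mu = m / (L * T) for m
observed mutations over L surveyed bases and T elapsed years, with an
exact (Garwood) Poisson interval on m propagated to the rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Mapping

import numpy as np
from scipy import stats

from . import genotypes as gt
from .matrix import GenotypeMatrix

__all__ = [
    "SelfingDistribution",
    "selfing_distribution",
    "AltLocusClassification",
    "classify_alt_loci",
    "MutationRateEstimate",
    "estimate_mutation_rate",
    "convert_per_generation_rate",
    "per_sample_rates",
    "round_sig",
]


@dataclass(frozen=True)
class SelfingDistribution:
    """Genotype distribution of a founder-HET locus after g selfings."""

    g: int
    p_ref: float
    p_het: float
    p_alt: float
    ratio: tuple[int, int, int]

    def as_probs(self) -> tuple[float, float, float]:
        return (self.p_ref, self.p_het, self.p_alt)


def selfing_distribution(g: int) -> SelfingDistribution:
    """Closed-form genotype distribution after ``g`` selfing generations.

    p_HET = (1/2)^g, p_REF = p_ALT = (1 - (1/2)^g) / 2. The ratio triple
    is REF:HET:ALT reduced to smallest integers; g=1 gives 1:2:1 and g=2
    gives 3:2:3.
    """
    if g < 0:
        raise ValueError(f"selfing generations must be >= 0, got {g}")
    p_het = 0.5**g
    p_hom = (1.0 - p_het) / 2.0
    # exact integers over the common denominator 2^(g+1)
    num_ref = 2**g - 1
    num_het = 2
    num_alt = 2**g - 1
    d = math.gcd(math.gcd(num_ref, num_het), num_alt)
    ratio = (num_ref // d, num_het // d, num_alt // d)
    return SelfingDistribution(g, p_hom, p_het, p_hom, ratio)


@dataclass(frozen=True)
class AltLocusClassification:
    """Counts of ALT-containing loci by which classes co-occur with ALT.

    The four categories (ALT only; ALT with HET but no REF; ALT with REF
    but no HET; all three classes) partition the ALT-containing loci.
    ``single_alt_rest_het`` additionally counts loci with exactly one ALT
    sample and every other non-missing sample HET — the signature of a
    single HET -> ALT conversion within a clone.
    """

    alt_only: int
    alt_het: int
    alt_ref: int
    alt_het_ref: int
    single_alt_rest_het: int

    @property
    def total(self) -> int:
        return self.alt_only + self.alt_het + self.alt_ref + self.alt_het_ref


def classify_alt_loci(matrix: GenotypeMatrix) -> AltLocusClassification:
    """Classify each ALT-containing locus by co-occurring classes.

    OTHER and MISSING calls are ignored when deciding which classes are
    present at a locus.
    """
    codes = matrix.codes
    has_alt = (codes == gt.CODE[gt.ALT]).any(axis=1)
    counts = {"alt_only": 0, "alt_het": 0, "alt_ref": 0, "alt_het_ref": 0}
    single = 0
    for i in np.nonzero(has_alt)[0]:
        row = codes[i]
        n_alt = int((row == gt.CODE[gt.ALT]).sum())
        has_het = bool((row == gt.CODE[gt.HET]).any())
        has_ref = bool((row == gt.CODE[gt.REF]).any())
        if has_het and has_ref:
            counts["alt_het_ref"] += 1
        elif has_het:
            counts["alt_het"] += 1
        elif has_ref:
            counts["alt_ref"] += 1
        else:
            counts["alt_only"] += 1
        informative = row[(row == gt.CODE[gt.ALT]) | (row == gt.CODE[gt.HET]) | (row == gt.CODE[gt.REF])]
        if n_alt == 1 and len(informative) > 1 and np.all(
            informative[informative != gt.CODE[gt.ALT]] == gt.CODE[gt.HET]
        ):
            single += 1
    return AltLocusClassification(single_alt_rest_het=single, **counts)


@dataclass(frozen=True)
class MutationRateEstimate:
    """Point rate m/(L*T) with an exact Poisson 95% interval on m."""

    m: int
    bases: float
    years: float
    rate: float
    ci_low: float
    ci_high: float

    def rounded(self, sig: int = 1) -> float:
        return round_sig(self.rate, sig)


def estimate_mutation_rate(m: int, bases: float, years: float) -> MutationRateEstimate:
    """Estimate a somatic mutation rate per base per year.

    ``m`` observed mutations over ``bases`` surveyed base pairs and
    ``years`` elapsed years give mu = m / (bases * years). The 95%
    interval is the exact (Garwood) Poisson interval on the count,
    divided by bases * years; m = 0 yields a one-sided interval with a
    zero lower bound.
    """
    if bases <= 0 or years <= 0:
        raise ValueError("bases and years must be positive")
    if m < 0:
        raise ValueError("mutation count must be >= 0")
    denom = bases * years
    rate = m / denom
    low = 0.0 if m == 0 else float(stats.chi2.ppf(0.025, 2 * m) / 2) / denom
    high = float(stats.chi2.ppf(0.975, 2 * m + 2) / 2) / denom
    return MutationRateEstimate(m, bases, years, rate, low, high)


def convert_per_generation_rate(r_gen: float, gen_time: float) -> float:
    """Convert a per-generation mutation rate to a per-year rate.

    E.g. 8.51e-8 per base per generation with a 67-year generation time
    gives 1.3e-9 per base per year (2 significant figures).
    """
    if gen_time <= 0:
        raise ValueError("generation time must be positive")
    if r_gen < 0:
        raise ValueError("rate must be >= 0")
    return r_gen / gen_time


def per_sample_rates(
    counts: Mapping[str, int], bases: float, years: float
) -> dict[str, MutationRateEstimate]:
    """Per-sample rate estimates from per-sample mutation counts."""
    return {s: estimate_mutation_rate(m, bases, years) for s, m in counts.items()}


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
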