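"""Exact set-intersection (UpSet) analysis of shared genotype classes.

The core idea: in a clonally propagating lineage, somatic mutations are
heterozygous and are shared by exactly the descendants of the branch on
which they arose. Counting, for every locus, the exact set of samples
that carry a given genotype class partitions the loci into sample
combinations; combinations with far more loci than others of the same
degree mark clades.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import genotypes as gt
from .matrix import GenotypeMatrix

__all__ = [
    "CombinationRow",
    "CombinationTable",
    "ElevatedSet",
    "combination_counts",
    "prune_uninformative",
    "condition_on_focal",
    "detect_elevated",
]


@dataclass(frozen=True)
class CombinationRow:
    """One exact sample combination: the samples, its size, its locus count."""

    samples: tuple[str, ...]
    degree: int
    count: int


@dataclass
class CombinationTable:
    """Exact partition of class-carrying loci by sample combination.

    Rows are sorted by degree (descending), then count (descending), then
    lexicographically on the sorted sample names, so output is byte-stable.
    """

    cls: str
    rows: list[CombinationRow]
    total_class_loci: int
    sample_names: tuple[str, ...]

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def rows_at_degree(self, degree: int) -> list[CombinationRow]:
        return [r for r in self.rows if r.degree == degree]

    def to_rows(self) -> list[dict]:
        return [
            {"samples": ",".join(r.samples), "degree": r.degree, "count": r.count}
            for r in self.rows
        ]


@dataclass(frozen=True)
class ElevatedSet:
    """A sample combination whose locus count is an outlier at its degree."""

    samples: tuple[str, ...]
    degree: int
    count: int
    zscore: float
    z_cut: float
    degree_median: float
    degree_mad: float
    n_combinations: int
    zeros_included: bool


def combination_counts(matrix: GenotypeMatrix, cls: str) -> CombinationTable:
    """Count loci by the exact set of samples carrying class ``cls``.

    Every locus with at least one sample of the class contributes exactly
    one count, to the row of its exact sample set; loci with no sample of
    the class are excluded. The counts over rows therefore sum to the
    number of class-carrying loci (partition property).
    """
    if matrix.n_loci == 0 or matrix.n_samples == 0:
        return CombinationTable(cls, [], 0, tuple(matrix.samples))
    mask = matrix.class_mask(cls)
    any_cls = mask.any(axis=1)
    sub = mask[any_cls]
    total = int(any_cls.sum())
    rows: list[CombinationRow] = []
    if total:
        patterns, counts = np.unique(sub, axis=0, return_counts=True)
        order = np.array(matrix.samples, dtype=object)
        for pat, cnt in zip(patterns, counts):
            members = tuple(sorted(order[pat]))
            rows.append(CombinationRow(members, len(members), int(cnt)))
    rows.sort(key=lambda r: (-r.degree, -r.count, r.samples))
    return CombinationTable(cls, rows, total, tuple(matrix.samples))


def prune_uninformative(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, dict]:
    """Drop loci that carry no phylogenetic signal among the samples.

    Two rules, applied in order:

    * monomorphic — the non-missing classes are identical across samples
      (e.g. heterozygous in every sample: a variant against the reference
      but not a polymorphism among samples);
    * singleton — exactly one sample is HET and every other non-missing
      sample is REF, or exactly one sample is ALT and every other
      non-missing sample shares a single class.

    Returns the pruned matrix and a report dict with per-rule counts.
    """
    codes = matrix.codes
    miss = gt.CODE[gt.MISSING]
    monomorphic = np.zeros(matrix.n_loci, dtype=bool)
    singleton = np.zeros(matrix.n_loci, dtype=bool)
    for i in range(matrix.n_loci):
        row = codes[i]
        present = row[row != miss]
        uniq = np.unique(present)
        if len(uniq) <= 1:
            monomorphic[i] = True
            continue
        n_het = int((present == gt.CODE[gt.HET]).sum())
        n_alt = int((present == gt.CODE[gt.ALT]).sum())
        if n_het == 1 and np.all(present[present != gt.CODE[gt.HET]] == gt.CODE[gt.REF]):
            singleton[i] = True
        elif n_alt == 1 and len(np.unique(present[present != gt.CODE[gt.ALT]])) == 1:
            singleton[i] = True
    keep = ~(monomorphic | singleton)
    report = {
        "monomorphic": int(monomorphic.sum()),
        "singleton": int(singleton.sum()),
        "kept": int(keep.sum()),
    }
    return matrix.subset_loci(keep), report


def condition_on_focal(matrix: GenotypeMatrix, focal: str) -> GenotypeMatrix:
    """Retain only loci where the focal sample is heterozygous."""
    j = matrix.sample_index(focal)
    return matrix.subset_loci(matrix.codes[:, j] == gt.CODE[gt.HET])


def detect_elevated(
    table: CombinationTable,
    min_degree: int = 2,
    z_cut: float = 3.5,
    enumeration_bound: int = 10**6,
) -> list[ElevatedSet]:
    """Flag sample combinations with outlier locus counts at their degree.

    For each degree d >= ``min_degree``, a robust z-score is computed for
    every observed combination against all same-degree combinations:
    z = (count - median) / (1.4826 * MAD). When the full combination space
    C(n_samples, d) is no larger than ``enumeration_bound``, unobserved
    combinations enter the statistics as zero counts; otherwise only
    observed combinations are used (recorded per set via
    ``zeros_included``). Combinations with z >= ``z_cut`` are returned.
    A degree with fewer than 3 combinations cannot be assessed and is
    skipped with a warning.

    Sparse degrees routinely have both median and MAD equal to zero
    (almost all same-degree combinations carry no loci). The scale then
    falls back to 1.4826 times the mean absolute deviation from the
    median, which is positive whenever any count differs from the
    median; if every count is identical the z-score is 0 and nothing is
    flagged. This keeps the statistic finite, deterministic and
    scale-free in the degenerate case.
    """
    out: list[ElevatedSet] = []
    degrees = sorted({r.degree for r in table.rows if r.degree >= min_degree}, reverse=True)
    for d in degrees:
        rows = table.rows_at_degree(d)
        counts = np.array([r.count for r in rows], dtype=float)
        space = math.comb(table.n_samples, d)
        zeros_included = space <= enumeration_bound
        if zeros_included:
            n_zero = space - len(rows)
            values = np.concatenate([counts, np.zeros(n_zero)])
        else:
            values = counts
        if len(values) < 3:
            warnings.warn(
                f"degree {d}: only {len(values)} combination(s); no flagging",
                stacklevel=2,
            )
            continue
        med = float(np.median(values))
        mad = float(np.median(np.abs(values - med)))
        scale = 1.4826 * mad
        if scale == 0:
            scale = 1.4826 * float(np.mean(np.abs(values - med)))
        for r, c in zip(rows, counts):
            z = (c - med) / scale if scale > 0 else 0.0
            if z >= z_cut:
                out.append(
                    ElevatedSet(
                        r.samples, d, r.count, z, z_cut, med, mad, len(values), zeros_included
                    )
                )
    return out
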