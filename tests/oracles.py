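"""Independent brute-force oracles used only by the tests.

Deliberately slow and structure-free, so they share no code path with
the implementations they check.
"""

from fractions import Fraction

from clonehet.matrix import GenotypeMatrix

_GAMETES = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def enumerate_selfing(g: int) -> dict[int, Fraction]:
    """Exact genotype distribution after g selfings of a heterozygote.

    Enumerates every gamete-combination path with exact rational
    probabilities; genotypes are alternative-allele dosages 0/1/2.
    """
    dist: dict[int, Fraction] = {1: Fraction(1)}
    for _ in range(g):
        nxt: dict[int, Fraction] = {}
        for dose, p in dist.items():
            for a in _GAMETES[dose]:
                for b in _GAMETES[dose]:
                    nxt[a + b] = nxt.get(a + b, Fraction(0)) + p * Fraction(1, 4)
        dist = nxt
    return dist


def brute_force_combinations(matrix: GenotypeMatrix, cls: str) -> dict[tuple, int]:
    """Per-locus subset tally of which samples carry ``cls``."""
    frame = matrix.to_frame()
    tallies: dict[tuple, int] = {}
    for _, row in frame.iterrows():
        members = tuple(sorted(s for s in frame.columns if row[s] == cls))
        if members:
            tallies[members] = tallies.get(members, 0) + 1
    return tallies
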