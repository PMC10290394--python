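"""Divergence-order inference and clustering/PCA baselines.

Elevated sample combinations that contain a focal sample, when nested,
define a divergence chain: if S1 > S2 > ... > Sk (all containing the
focal sample), the samples in S_i \\ S_{i+1} diverged from the focal
lineage before the interior of S_{i+1}. The chain is the set-intersection
analogue of reading a phylogeny along the focal path.

The module also provides the conventional baselines the chain is compared
against: Ward hierarchical clustering (Ward.D2 convention) with ordinary
bootstrap support over locus resamples, and a deterministic PCA, both on
the 0 / 0.5 / 1 genotype encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from . import genotypes as gt
from .intersections import ElevatedSet
from .matrix import GenotypeMatrix

__all__ = [
    "DivergenceChain",
    "Dendrogram",
    "infer_divergence_chain",
    "encode_numeric",
    "bootstrap_cluster",
    "pca_scores",
    "select_representatives",
]


@dataclass
class DivergenceChain:
    """Maximal nested chain of elevated sets containing the focal sample."""

    focal: str
    sets: list[ElevatedSet]
    residuals: list[ElevatedSet] = field(default_factory=list)
    diagnostic: str | None = None

    def subsets(self) -> list[frozenset[str]]:
        return [frozenset(e.samples) for e in self.sets]

    def divergence_groups(self) -> list[tuple[str, ...]]:
        """Sample groups in divergence order, outermost first.

        Group i is S_i \\ S_{i+1}; the last group is the innermost set.
        """
        groups: list[tuple[str, ...]] = []
        subs = self.subsets()
        for a, b in zip(subs, subs[1:]):
            groups.append(tuple(sorted(a - b)))
        if subs:
            groups.append(tuple(sorted(subs[-1])))
        return groups

    def to_dict(self) -> dict:
        return {
            "focal": self.focal,
            "chain": [
                {"samples": list(e.samples), "degree": e.degree, "count": e.count}
                for e in self.sets
            ],
            "residuals": [
                {"samples": list(e.samples), "degree": e.degree, "count": e.count}
                for e in self.residuals
            ],
            "diagnostic": self.diagnostic,
        }


def infer_divergence_chain(elevated: list[ElevatedSet], focal: str) -> DivergenceChain:
    """Extract the maximal nested chain of elevated sets containing ``focal``.

    Candidates are ordered by degree (descending), count (descending),
    then lexicographically on the sample tuple, and greedily appended
    when strictly contained in the current innermost set. Elevated sets
    that do not nest with the chain are reported as residuals, never
    silently dropped. An empty candidate list yields an empty chain with
    a diagnostic message.
    """
    cands = [e for e in elevated if focal in e.samples]
    if not cands:
        return DivergenceChain(
            focal, [], list(elevated), diagnostic=f"no elevated set contains {focal!r}"
        )
    cands.sort(key=lambda e: (-e.degree, -e.count, e.samples))
    chain = [cands[0]]
    residuals = [e for e in elevated if focal not in e.samples]
    for e in cands[1:]:
        if set(e.samples) < set(chain[-1].samples):
            chain.append(e)
        else:
            residuals.append(e)
    return DivergenceChain(focal, chain, residuals)


def encode_numeric(
    matrix: GenotypeMatrix, drop_other: bool = False, drop_missing: bool = False
) -> pd.DataFrame:
    """Encode genotype classes numerically: REF=0, HET=0.5, ALT=1.

    Returns a samples x loci DataFrame (rows are observations for
    clustering/PCA). OTHER or MISSING calls raise unless the matching
    ``drop_*`` flag is set, in which case the offending loci are dropped.
    """
    m = matrix
    for cls, flag, name in ((gt.OTHER, drop_other, "OTHER"), (gt.MISSING, drop_missing, "MISSING")):
        bad = m.class_mask(cls).any(axis=1)
        if bad.any():
            if not flag:
                raise ValueError(
                    f"{int(bad.sum())} loci contain {name} calls; "
                    f"drop them explicitly or clean the matrix first"
                )
            m = m.subset_loci(~bad)
    values = np.empty(m.codes.shape, dtype=float)
    values[m.codes == gt.CODE[gt.REF]] = 0.0
    values[m.codes == gt.CODE[gt.HET]] = 0.5
    values[m.codes == gt.CODE[gt.ALT]] = 1.0
    cols = pd.MultiIndex.from_tuples(m.loci, names=["scaffold", "pos"])
    return pd.DataFrame(values.T, index=m.samples, columns=cols)


@dataclass
class Dendrogram:
    """Agglomerative merge tree with optional bootstrap support per node."""

    linkage: np.ndarray  # scipy linkage matrix
    leaves: list[str]
    support: dict[frozenset, float] | None = None

    def clades(self) -> list[frozenset[str]]:
        """Leaf set of each internal node, in merge order."""
        n = len(self.leaves)
        sets: list[frozenset[str]] = [frozenset([s]) for s in self.leaves]
        out = []
        for a, b, *_ in self.linkage:
            merged = sets[int(a)] | sets[int(b)]
            sets.append(merged)
            out.append(merged)
        return out

    def smallest_clade_containing(self, sample: str) -> frozenset[str]:
        for clade in self.clades():
            if sample in clade:
                return clade
        raise KeyError(sample)


def bootstrap_cluster(
    numeric: pd.DataFrame, nboot: int = 1000, seed: int = 0
) -> Dendrogram:
    """Ward clustering (Ward.D2 convention) with bootstrap clade support.

    ``numeric`` is samples x loci (as produced by :func:`encode_numeric`).
    SciPy's ward linkage on the observation matrix minimizes the Ward
    variance criterion over Euclidean distances, matching the Ward.D2
    convention (squared distances inside the criterion). Support for each
    internal node is the fraction of ``nboot`` locus resamples (with
    replacement) whose ward tree contains the same leaf set; this is an
    ordinary bootstrap proportion, not a multiscale-bootstrap p-value.
    ``nboot=0`` returns the dendrogram without support values.
    """
    if numeric.shape[0] < 3:
        raise ValueError("need at least 3 samples to cluster")
    X = numeric.to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        raise ValueError("no variation among samples")
    leaves = list(numeric.index)
    Z = linkage(X, method="ward")
    dend = Dendrogram(Z, leaves)
    if nboot <= 0:
        return dend
    targets = dend.clades()
    hits = {c: 0 for c in targets}
    rng = np.random.default_rng(seed)
    n_loci = X.shape[1]
    for _ in range(nboot):
        idx = rng.integers(0, n_loci, n_loci)
        Xb = X[:, idx]
        if np.allclose(Xb, Xb[0]):
            continue  # uninformative resample supports no clade
        Zb = linkage(Xb, method="ward")
        for clade in Dendrogram(Zb, leaves).clades():
            if clade in hits:
                hits[clade] += 1
    dend.support = {c: hits[c] / nboot for c in targets}
    return dend


def pca_scores(numeric: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-centred SVD scores with a deterministic sign convention.

    Returns (scores, variance_explained_percent). For each component the
    loading with the largest magnitude is made positive, so signs are
    stable across runs and platforms. Duplicated sample rows receive
    identical scores.
    """
    if numeric.shape[0] < 2 or numeric.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 loci")
    X = numeric.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("rank-0 input: no variation after centring")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(len(S)):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U * S
    var = S**2
    var_explained = 100.0 * var / var.sum()
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=numeric.index, columns=cols), var_explained


def select_representatives(
    scores: pd.DataFrame, region_of: Mapping[str, str]
) -> dict[str, str]:
    """Pick one representative sample per region from PC coordinates.

    For each region the componentwise median of (PC1, PC2, PC3) over its
    samples is computed and the sample with the smallest Euclidean
    distance to that median is selected; ties go to the lexicographically
    first sample name.
    """
    if scores.shape[1] < 3:
        raise ValueError("need at least 3 principal components")
    regions: dict[str, list[str]] = {}
    # a sample missing from the map is a hard error: silent exclusion
    # would bias the medians
    for sample in scores.index:
        if sample not in region_of:
            raise KeyError(f"sample {sample!r} has no region label")
        regions.setdefault(region_of[sample], []).append(sample)
    out: dict[str, str] = {}
    for region, samples in sorted(regions.items()):
        if not samples:
            raise ValueError(f"region {region!r} has no samples")
        pcs = scores.loc[samples, ["PC1", "PC2", "PC3"]].to_numpy()
        median = np.median(pcs, axis=0)
        dist = np.linalg.norm(pcs - median, axis=1)
        best = min(zip(dist, samples), key=lambda t: (t[0], t[1]))[1]
        out[region] = best
    return out
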