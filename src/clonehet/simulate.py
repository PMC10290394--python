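"""Forward simulator of a vegetatively propagating diploid lineage.

The generative model mirrors what the analysis assumes about a clonal
bamboo lineage:

* a **founder** whose genome is a block mosaic of heterozygous and
  homozygous regions — modelled as the selfed descendant (g0 generations)
  of an F1 between two haplotypes diverged at density ``d``, with meiotic
  recombination (Poisson crossover counts per scaffold, uniform
  positions, no interference);
* **clonal propagation** along a dated tree: on a branch of length t
  years, new heterozygous somatic mutations arise as a Poisson process
  with rate mu per base per year at reference-state sites, and each
  existing heterozygous site converts to homozygous-alternative
  (loss of heterozygosity) with probability 1 - exp(-rho * t);
* **selfed seedlings** obtained from the founder by g rounds of
  self-fertilization with recombination, whose founder-HET loci segregate
  with the closed-form selfing distribution;
* an **observation layer**: negative-binomial read depth (DP = 0 means a
  missing call), depth-dependent miscalls of heterozygotes, and, in
  GRAS-Di (random-amplicon genotyping) mode, restriction to an amplicon
  panel, per-allele amplification dropout and PCR false heterozygotes.
  Site annotations (MQ, QD, FS, rank sums, QUAL, GQ/RGQ) are emitted so
  that error-free sites pass the package's filter ladders while a
  configurable fraction of artifact sites fail them.

Identical config (including the seed) gives bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from collections.abc import Sequence

import numpy as np

from . import genotypes as gt
from .matrix import GenotypeMatrix
from .records import SNP, LocusRecord, SampleCall

__all__ = [
    "SimConfig",
    "CloneNode",
    "CloneTree",
    "MutEvent",
    "TruthSet",
    "generate_founder",
    "propagate_clones",
    "simulate_selfed_seedlings",
    "apply_observation_model",
]

_BASES = np.array(["A", "C", "G", "T"], dtype=object)

HET_GAIN = "het_gain"
CONVERSION = "conversion"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the forward simulation.

    Units: ``genome_length`` in bp; ``divergence_density`` in heterozygous
    sites per bp between the parental haplotypes; ``somatic_rate`` in
    mutations per bp per year; ``conversion_rate`` in HET->ALT events per
    heterozygous locus per year; ``map_length`` in Morgans per scaffold.
    ``dropout_prob``, ``pcr_error_prob`` and ``amplicon_fraction`` only
    act in GRAS-Di mode. ``artifact_fail_frac`` is the fraction of
    artifact sites emitted with annotations that fail the hard filters.
    ``depth_cap`` truncates the depth draw (the DP < 100 analysis gate
    targets repeat pileups, which this simulator does not model).
    """

    genome_length: int = 1_000_000
    n_scaffolds: int = 2
    divergence_density: float = 0.003
    founder_selfings: int = 2
    somatic_rate: float = 5e-9
    conversion_rate: float = 7e-8
    map_length: float = 2.0
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0
    dropout_prob: float = 0.1
    pcr_error_prob: float = 1e-6
    amplicon_fraction: float = 0.005
    artifact_fail_frac: float = 0.9
    depth_cap: int = 99
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be > 0")
        if self.n_scaffolds < 1 or self.n_scaffolds > self.genome_length:
            raise ValueError("invalid n_scaffolds")
        if not 0 <= self.divergence_density <= 1:
            raise ValueError("divergence_density must be in [0, 1]")
        if self.founder_selfings < 0:
            raise ValueError("founder_selfings must be >= 0")
        if self.somatic_rate < 0 or self.conversion_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.map_length < 0 or self.depth_mean < 0 or self.depth_dispersion <= 0:
            raise ValueError("invalid map/depth parameters")
        for p in (self.dropout_prob, self.pcr_error_prob, self.amplicon_fraction,
                  self.artifact_fail_frac):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")

    def scaffold_lengths(self) -> list[int]:
        base = self.genome_length // self.n_scaffolds
        lengths = [base] * self.n_scaffolds
        lengths[-1] += self.genome_length - base * self.n_scaffolds
        return lengths

    def scaffold_names(self) -> list[str]:
        return [f"scaffold{i + 1}" for i in range(self.n_scaffolds)]


# ---------------------------------------------------------------------------
# dated clone tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CloneNode:
    id: str
    parent: str | None
    length: float  # years on the branch above this node


class CloneTree:
    """Dated tree of clonal propagation; leaves are sample names."""

    def __init__(self, nodes: Sequence[CloneNode]) -> None:
        self.nodes: dict[str, CloneNode] = {}
        for n in nodes:
            if n.id in self.nodes:
                raise ValueError(f"duplicate node id {n.id!r}")
            if n.length < 0:
                raise ValueError(f"negative branch length at {n.id!r}")
            self.nodes[n.id] = n
        roots = [n.id for n in nodes if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._children: dict[str, list[str]] = {n.id: [] for n in nodes}
        for n in nodes:
            if n.parent is not None:
                if n.parent not in self.nodes:
                    raise ValueError(f"unknown parent {n.parent!r} of {n.id!r}")
                self._children[n.parent].append(n.id)

    def children(self, node_id: str) -> list[str]:
        return self._children[node_id]

    def leaves(self) -> list[str]:
        return [i for i, c in self._children.items() if not c]

    def path(self, leaf: str) -> list[str]:
        """Node ids from the root down to ``leaf`` (inclusive)."""
        out = []
        cur: str | None = leaf
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        return out[::-1]

    def leaf_set_below(self, node_id: str) -> frozenset[str]:
        stack, out = [node_id], []
        while stack:
            n = stack.pop()
            kids = self._children[n]
            if kids:
                stack.extend(kids)
            else:
                out.append(n)
        return frozenset(out)

    @classmethod
    def caterpillar(cls, leaf_names: Sequence[str], branch_length: float) -> "CloneTree":
        """Fully pectinate tree: leaf i diverges at step i from the spine."""
        names = list(leaf_names)
        if len(names) < 2:
            raise ValueError("need >= 2 leaves")
        nodes = [CloneNode("root", None, 0.0)]
        parent = "root"
        for i, name in enumerate(names[:-1]):
            nodes.append(CloneNode(name, parent, branch_length))
            if i < len(names) - 2:
                inner = f"n{i + 1}"
                nodes.append(CloneNode(inner, parent, branch_length))
                parent = inner
        nodes.append(CloneNode(names[-1], parent, branch_length))
        return cls(nodes)

    def to_newick(self) -> str:
        def fmt(node_id: str) -> str:
            kids = self._children[node_id]
            n = self.nodes[node_id]
            label = node_id if not kids else ""
            inner = "" if not kids else "(" + ",".join(fmt(k) for k in kids) + ")"
            length = f":{n.length:g}" if n.parent is not None else ""
            return f"{inner}{label}{length}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "CloneTree":
        import dendropy

        tree = dendropy.Tree.get(data=text, schema="newick")
        nodes: list[CloneNode] = []
        ids: dict[int, str] = {}
        counter = 0
        for nd in tree.preorder_node_iter():
            if nd.taxon is not None:
                name = nd.taxon.label
            elif nd.parent_node is None:
                name = "root"
            else:
                counter += 1
                name = f"n{counter}"
            ids[id(nd)] = name
            parent = ids[id(nd.parent_node)] if nd.parent_node is not None else None
            length = float(nd.edge.length or 0.0)
            nodes.append(CloneNode(name, parent, length))
        return cls(nodes)


# ---------------------------------------------------------------------------
# truth set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutEvent:
    """A somatic event: HET gain at a reference-state site, or HET->ALT."""

    branch: str
    pos: int  # global 0-based
    kind: str  # HET_GAIN or CONVERSION


@dataclass
class TruthSet:
    """Ground truth of one simulation run.

    Positions are global 0-based offsets over the concatenated scaffolds
    internally; VCF output converts to per-scaffold 1-based coordinates.
    """

    config: SimConfig
    div_positions: np.ndarray  # founder divergent sites, sorted
    founder_haps: np.ndarray  # (2, n_div) int8; 1 = alternative allele
    tree: CloneTree | None = None
    events: list[MutEvent] = field(default_factory=list)
    clone_classes: dict[str, dict[int, str]] = field(default_factory=dict)
    seedling_classes: dict[str, dict[int, str]] = field(default_factory=dict)
    collision_redraws: int = 0

    # -- coordinates --------------------------------------------------------

    def locate(self, pos: int) -> tuple[str, int]:
        """Global 0-based position -> (scaffold name, 1-based position)."""
        offset = 0
        for name, length in zip(self.config.scaffold_names(), self.config.scaffold_lengths()):
            if pos < offset + length:
                return name, pos - offset + 1
            offset += length
        raise ValueError(f"position {pos} beyond genome")

    # -- founder ------------------------------------------------------------

    def founder_class_codes(self) -> np.ndarray:
        """Genotype class code at each divergent site (REF/HET/ALT)."""
        dosage = self.founder_haps.sum(axis=0)
        codes = np.full(dosage.shape, gt.CODE[gt.REF], dtype=np.int8)
        codes[dosage == 1] = gt.CODE[gt.HET]
        codes[dosage == 2] = gt.CODE[gt.ALT]
        return codes

    def founder_het_positions(self) -> np.ndarray:
        return self.div_positions[self.founder_haps[0] != self.founder_haps[1]]

    def founder_class_at(self, pos: int) -> str:
        idx = np.searchsorted(self.div_positions, pos)
        if idx < len(self.div_positions) and self.div_positions[idx] == pos:
            return str(gt.NAMES[self.founder_class_codes()[idx]])
        return gt.REF

    # -- tracked sites and matrices -----------------------------------------

    def tracked_positions(self) -> np.ndarray:
        """All sites the simulation touched: divergent plus somatic."""
        somatic = {e.pos for e in self.events if e.kind == HET_GAIN}
        return np.array(sorted(set(self.div_positions.tolist()) | somatic), dtype=np.int64)

    def _matrix(self, per_sample: dict[str, dict[int, str]]) -> GenotypeMatrix:
        positions = self.tracked_positions()
        samples = list(per_sample)
        founder_codes = {
            int(p): int(c)
            for p, c in zip(self.div_positions, self.founder_class_codes())
        }
        codes = np.empty((len(positions), len(samples)), dtype=np.int8)
        for i, p in enumerate(positions):
            base = founder_codes.get(int(p), gt.CODE[gt.REF])
            for j, s in enumerate(samples):
                cls = per_sample[s].get(int(p))
                codes[i, j] = gt.CODE[cls] if cls is not None else base
        loci = [self.locate(int(p)) for p in positions]
        return GenotypeMatrix(codes, loci, samples)

    def clone_matrix(self) -> GenotypeMatrix:
        """Truth genotype classes of the clonal leaves at tracked sites."""
        if not self.clone_classes:
            raise ValueError("no clones simulated")
        return self._matrix(self.clone_classes)

    def seedling_matrix(self) -> GenotypeMatrix:
        if not self.seedling_classes:
            raise ValueError("no seedlings simulated")
        return self._matrix(self.seedling_classes)

    def event_leafset(self, event: MutEvent) -> frozenset[str]:
        """Exact leaf set that inherits an event (the branch's clade)."""
        if self.tree is None:
            raise ValueError("no tree attached")
        return self.tree.leaf_set_below(event.branch)

    def replay_leaf(self, leaf: str) -> dict[int, str]:
        """Reconstruct a leaf's non-reference sites from the event log.

        Independent replay of the founder state plus the root-to-leaf
        events; used to verify the stored leaf genotypes.
        """
        if self.tree is None:
            raise ValueError("no tree attached")
        state: dict[int, str] = {}
        codes = self.founder_class_codes()
        for p, c in zip(self.div_positions, codes):
            name = str(gt.NAMES[c])
            if name != gt.REF:
                state[int(p)] = name
        on_path = set(self.tree.path(leaf))
        for ev in self.events:  # events are logged in root->leaf traversal order
            if ev.branch not in on_path:
                continue
            if ev.kind == HET_GAIN:
                state[ev.pos] = gt.HET
            else:
                state[ev.pos] = gt.ALT
        return state


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _scaffold_offsets(config: SimConfig) -> list[tuple[int, int]]:
    out, offset = [], 0
    for length in config.scaffold_lengths():
        out.append((offset, length))
        offset += length
    return out


def _gamete(
    haps: np.ndarray,
    positions: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete from a diplotype over ``positions``.

    Crossover counts per scaffold are Poisson(map_length) with uniform
    positions (no interference); the starting haplotype of each scaffold
    is chosen at random.
    """
    choice = np.empty(len(positions), dtype=np.int64)
    for offset, length in _scaffold_offsets(config):
        lo = np.searchsorted(positions, offset)
        hi = np.searchsorted(positions, offset + length)
        k = rng.poisson(config.map_length)
        breaks = np.sort(rng.uniform(0, length, k)) + offset
        first = int(rng.integers(2))
        seg = np.searchsorted(breaks, positions[lo:hi], side="right")
        choice[lo:hi] = (first + seg) % 2
    return haps[choice, np.arange(len(positions))]


def _self_once(
    haps: np.ndarray,
    positions: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    g1 = _gamete(haps, positions, config, rng)
    g2 = _gamete(haps, positions, config, rng)
    return np.stack([g1, g2])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def generate_founder(config: SimConfig) -> TruthSet:
    """Simulate the founder: an F1 of two diverged haplotypes, selfed g0 times.

    The two parental haplotypes differ at ~Binomial(L, d) sites; each
    selfing generation applies meiosis with recombination to both
    gametes. The resulting founder is heterozygous at a fraction
    ~(1/2)^g0 of the divergent sites, in contiguous blocks separated by
    homozygous blocks (fixed to either parental allele).
    """
    rng = np.random.default_rng([config.seed, 0])
    L, d = config.genome_length, config.divergence_density
    if 0 < d * L < 1:
        warnings.warn(f"expected divergent sites d*L = {d * L:.3g} < 1", stacklevel=2)
    n_div = int(rng.binomial(L, d))
    positions = np.sort(rng.choice(L, size=n_div, replace=False)).astype(np.int64)
    haps = np.zeros((2, n_div), dtype=np.int8)
    haps[1] = 1  # F1: parental haplotype 2 carries the alternative allele
    for _ in range(config.founder_selfings):
        haps = _self_once(haps, positions, config, rng)
    return TruthSet(config=config, div_positions=positions, founder_haps=haps)


def propagate_clones(founder: TruthSet, tree: CloneTree, config: SimConfig) -> TruthSet:
    """Propagate the founder along a dated clone tree.

    On each branch of length t years, heterozygous somatic gains arrive
    as Poisson(mu * L * t) at uniformly chosen sites that are currently
    reference-state on that lineage; collisions with segregating sites or
    with any previously mutated site anywhere in the tree are redrawn and
    counted (infinite-sites convention, which guarantees that the exact
    leaf set sharing a somatic mutation is the clade of its branch), and
    every existing
    heterozygous site converts to homozygous-alternative with probability
    1 - exp(-rho * t). Leaf genotypes and the full event log are stored
    on the returned truth set.
    """
    rng = np.random.default_rng([config.seed, 1])
    truth = replace(founder, tree=tree)
    truth.events = []
    truth.clone_classes = {}
    truth.collision_redraws = 0
    L = config.genome_length
    div_set = set(int(p) for p in truth.div_positions)

    founder_state: dict[int, str] = {}
    for p, c in zip(truth.div_positions, truth.founder_class_codes()):
        name = str(gt.NAMES[c])
        if name != gt.REF:
            founder_state[int(p)] = name

    used_anywhere: set[int] = set()

    def visit(node_id: str, state: dict[int, str]) -> None:
        node = tree.nodes[node_id]
        t = node.length
        if node.parent is not None and t > 0:
            # HET -> ALT conversions (memoryless per year)
            p_conv = 1.0 - np.exp(-config.conversion_rate * t)
            if p_conv > 0:
                het_sites = sorted(p for p, c in state.items() if c == gt.HET)
                conv = rng.random(len(het_sites)) < p_conv
                for p, flag in zip(het_sites, conv):
                    if flag:
                        state[p] = gt.ALT
                        truth.events.append(MutEvent(node_id, p, CONVERSION))
            # heterozygous somatic gains at reference-state sites
            n_gain = rng.poisson(config.somatic_rate * L * t)
            for _ in range(n_gain):
                while True:
                    pos = int(rng.integers(L))
                    if pos in used_anywhere or pos in div_set:
                        truth.collision_redraws += 1
                        continue
                    break
                state[pos] = gt.HET
                used_anywhere.add(pos)
                truth.events.append(MutEvent(node_id, pos, HET_GAIN))
        kids = tree.children(node_id)
        if not kids:
            truth.clone_classes[node_id] = dict(state)
            return
        for kid in kids:
            visit(kid, dict(state))

    visit(tree.root, dict(founder_state))
    return truth


def simulate_selfed_seedlings(
    founder: TruthSet, g: int, n: int, config: SimConfig
) -> TruthSet:
    """Simulate ``n`` seedlings, each by ``g`` selfings of the founder.

    Meiosis uses the same recombination model as founder construction.
    Across many seedlings, each founder-HET locus segregates with the
    closed-form selfing distribution (1:2:1 after one selfing, 3:2:3
    after two).
    """
    if g < 1 or n < 1:
        raise ValueError("need g >= 1 and n >= 1")
    rng = np.random.default_rng([config.seed, 2])
    truth = replace(founder)
    truth.seedling_classes = {}
    width = len(str(n))
    for i in range(n):
        haps = founder.founder_haps
        for _ in range(g):
            haps = _self_once(haps, founder.div_positions, config, rng)
        dosage = haps.sum(axis=0)
        state: dict[int, str] = {}
        for p, dose in zip(founder.div_positions, dosage):
            if dose == 1:
                state[int(p)] = gt.HET
            elif dose == 2:
                state[int(p)] = gt.ALT
        truth.seedling_classes[f"seedling{i + 1:0{width}d}"] = state
    return truth


# ---------------------------------------------------------------------------
# observation layer
# ---------------------------------------------------------------------------

def _depths(rng: np.random.Generator, config: SimConfig, size: int) -> np.ndarray:
    m, k = config.depth_mean, config.depth_dispersion
    if m == 0:
        return np.zeros(size, dtype=np.int64)
    draws = rng.negative_binomial(k, k / (k + m), size=size)
    return np.minimum(draws, config.depth_cap)


def apply_observation_model(
    truth: TruthSet, config: SimConfig, mode: str = "wgs"
) -> list[LocusRecord]:
    """Emit noisy observed locus records for the clonal samples.

    Per sample and site: read depth is negative-binomial with mean
    ``depth_mean`` (DP = 0 gives a MISSING call); a true heterozygote
    with depth dp is miscalled homozygous with probability 2 * (1/2)^dp
    (all reads sampling one allele). In ``grasdi`` mode only an amplicon
    panel covering ``amplicon_fraction`` of the genome is observable,
    each allele of a heterozygote independently fails to amplify with
    probability ``dropout_prob`` (one failure gives a confidently
    miscalled homozygote, two give a missing call), and panel sites that
    are reference in all samples acquire per-sample false heterozygous
    calls with probability ``pcr_error_prob``.

    Error-free sites are annotated to pass the filter ladders (MQ = 60,
    high GQ/QUAL); a fraction ``artifact_fail_frac`` of PCR-artifact
    sites is emitted with degraded annotations (MQ < 40, QD < 2) so the
    hard filters can catch them.
    """
    if mode not in ("wgs", "grasdi"):
        raise ValueError(f"unknown mode {mode!r}")
    if not truth.clone_classes:
        raise ValueError("no clones to observe; run propagate_clones first")
    rng = np.random.default_rng([config.seed, 3])
    L = config.genome_length
    samples = list(truth.clone_classes)
    tracked = truth.tracked_positions()
    tracked_set = set(int(p) for p in tracked)

    if mode == "grasdi":
        n_panel = int(round(config.amplicon_fraction * L))
        panel = np.sort(rng.choice(L, size=n_panel, replace=False)).astype(np.int64)
        panel_set = set(int(p) for p in panel)
        site_positions = [p for p in tracked.tolist() if p in panel_set]
        # PCR false heterozygotes on panel sites outside the tracked set
        background = np.array(sorted(panel_set - tracked_set), dtype=np.int64)
        false_het: dict[int, set[str]] = {}
        for s in samples:
            hits = background[rng.random(len(background)) < config.pcr_error_prob]
            for p in hits.tolist():
                false_het.setdefault(int(p), set()).add(s)
        site_positions = sorted(set(site_positions) | set(false_het))
    else:
        site_positions = tracked.tolist()
        false_het = {}

    founder_codes = {
        int(p): int(c) for p, c in zip(truth.div_positions, truth.founder_class_codes())
    }

    records: list[LocusRecord] = []
    for pos in site_positions:
        base_cls = str(gt.NAMES[founder_codes.get(pos, gt.CODE[gt.REF])])
        is_artifact = pos in false_het
        ref, alt = rng.choice(4, size=2, replace=False)
        scaffold, vcf_pos = truth.locate(pos)
        depths = _depths(rng, config, len(samples))
        calls: dict[str, SampleCall] = {}
        for s, dp in zip(samples, depths.tolist()):
            true_cls = truth.clone_classes[s].get(pos, base_cls)
            if pos in false_het and s in false_het[pos]:
                true_cls = gt.HET
            obs = true_cls
            if mode == "grasdi" and obs == gt.HET and config.dropout_prob > 0:
                drop_ref = rng.random() < config.dropout_prob
                drop_alt = rng.random() < config.dropout_prob
                if drop_ref and drop_alt:
                    dp = 0
                elif drop_alt:
                    obs = gt.REF
                elif drop_ref:
                    obs = gt.ALT
            if dp == 0:
                calls[s] = SampleCall(gt.MISSING, 0)
                continue
            if obs == gt.HET and rng.random() < 2 * 0.5**dp:
                obs = gt.REF if rng.random() < 0.5 else gt.ALT
            if obs == gt.REF and mode == "wgs":
                calls[s] = SampleCall(gt.REF, dp, rgq=int(rng.integers(30, 100)))
            elif obs == gt.REF:
                calls[s] = SampleCall(gt.REF, dp, gq=int(rng.integers(30, 100)))
            else:
                calls[s] = SampleCall(obs, dp, gq=int(rng.integers(90, 100)))
        degrade = is_artifact and rng.random() < config.artifact_fail_frac
        if degrade:
            info = {
                "MQ": float(np.round(rng.uniform(20, 39.9), 2)),
                "QD": float(np.round(rng.uniform(0.2, 1.9), 2)),
                "FS": float(np.round(rng.uniform(0, 3), 2)),
                "MQRankSum": float(np.round(rng.uniform(-2, 2), 2)),
                "ReadPosRankSum": float(np.round(rng.uniform(-2, 2), 2)),
            }
        else:
            info = {
                "MQ": 60.0,
                "QD": float(np.round(rng.uniform(20, 35), 2)),
                "FS": float(np.round(rng.uniform(0, 3), 2)),
                "MQRankSum": float(np.round(rng.uniform(-2, 2), 2)),
                "ReadPosRankSum": float(np.round(rng.uniform(-2, 2), 2)),
            }
        qual = float(np.round(rng.uniform(200, 2000), 2))
        records.append(
            LocusRecord(
                scaffold=scaffold,
                pos=vcf_pos,
                ref=str(_BASES[ref]),
                alts=(str(_BASES[alt]),),
                variant_type=SNP,
                qual=qual,
                info=info,
                calls=calls,
            )
        )
    # site_positions is in global order, so records are already sorted
    # per scaffold in scaffold index order
    return records
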