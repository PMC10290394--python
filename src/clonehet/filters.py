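"""Genotype-quality filter ladders.

Two ladders are implemented:

* the whole-genome-sequencing (WGS) high-quality-SNP ladder — per-sample
  depth/quality gates, a per-sample depth ceiling, exclusion of loci where
  the reference individual's own reads called a variant, exclusion of
  all-reference loci, and a final mapping-quality gate (MQ exactly 60,
  SNPs only);
* the GRAS-Di (genotyping by random amplicon sequencing) ladder — hard
  annotation filters, extraction of newly generated heterozygous loci
  (some samples HET, all others REF), and a second, genotype-quality /
  grove-structure filter.

Each ladder returns the surviving records together with a
:class:`FilterReport` giving stage-by-stage in/out counts and per-reason
tallies, so a run is auditable and exactly reproducible.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

from . import genotypes as gt
from .records import INDEL, SNP, LocusRecord, SampleCall

__all__ = [
    "classify_genotype",
    "apply_wgs_ladder",
    "apply_grasdi_filters",
    "FilterReport",
    "FilterStage",
    "RefControlSet",
]


# ---------------------------------------------------------------------------
# genotype classification
# ---------------------------------------------------------------------------

def classify_genotype(
    genotype: str | tuple[int | None, int | None],
    dp: int,
    gq: int | None = None,
    rgq: int | None = None,
) -> SampleCall:
    """Reduce a raw diploid call to a genotype class.

    ``genotype`` is either a VCF GT string (``"0/1"``, ``"0|0"``, ``"./."``)
    or a pair of allele indices with ``None`` for a no-call allele.
    Classification: 0/0 -> REF; 0/x -> HET; x/x (same x>0) -> ALT; no-call
    or DP=0 -> MISSING; any other diploid call (e.g. two distinct
    non-reference alleles) -> OTHER.

    Raises ``ValueError`` for haploid or polyploid calls.
    """
    if dp < 0:
        raise ValueError(f"negative DP {dp}")
    if isinstance(genotype, str):
        sep = "|" if "|" in genotype else "/"
        parts = genotype.split(sep)
        alleles: list[int | None] = [None if p in (".", "") else int(p) for p in parts]
    else:
        alleles = list(genotype)
    if len(alleles) != 2:
        raise ValueError(
            f"expected a diploid genotype, got {genotype!r} ({len(alleles)} allele(s))"
        )
    if dp == 0 or any(a is None for a in alleles):
        return SampleCall(gt.MISSING, 0 if dp == 0 else dp, None, None)
    a, b = sorted(alleles)  # type: ignore[type-var]
    if a == 0 and b == 0:
        cls = gt.REF
    elif a == 0:
        cls = gt.HET
    elif a == b:
        cls = gt.ALT
    else:
        cls = gt.OTHER
    return SampleCall(cls, dp, gq, rgq)


# ---------------------------------------------------------------------------
# filter report plumbing
# ---------------------------------------------------------------------------

@dataclass
class FilterStage:
    name: str
    n_in: int
    n_out: int
    reasons: Counter = field(default_factory=Counter)

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out


@dataclass
class FilterReport:
    """Ordered stage-by-stage record of a filter ladder run."""

    stages: list[FilterStage] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int, reasons: Counter | None = None) -> None:
        if n_out > n_in:
            raise ValueError("stage output larger than input")
        if self.stages and self.stages[-1].n_out != n_in:
            raise ValueError("stage input does not match previous stage output")
        self.stages.append(FilterStage(name, n_in, n_out, reasons or Counter()))

    def survivors(self) -> int:
        return self.stages[-1].n_out if self.stages else 0

    def counts(self) -> list[tuple[str, int, int]]:
        return [(s.name, s.n_in, s.n_out) for s in self.stages]

    def to_rows(self) -> list[dict]:
        return [
            {
                "stage": s.name,
                "loci_in": s.n_in,
                "loci_out": s.n_out,
                "removed": s.n_removed,
                "reasons": dict(sorted(s.reasons.items())),
            }
            for s in self.stages
        ]


#: Loci where re-sequencing reads of the reference individual were called
#: homozygous-alternative or Other; these are excluded as possible
#: reference-assembly errors. Keys are (scaffold, 1-based position).
RefControlSet = frozenset


def _stage(records: list[LocusRecord], keep_fn, report: FilterReport, name: str):
    """Apply a per-locus predicate, tallying removal reasons."""
    survivors: list[LocusRecord] = []
    reasons: Counter = Counter()
    for rec in records:
        ok, reason = keep_fn(rec)
        if ok:
            survivors.append(rec)
        else:
            reasons[reason] += 1
    report.add(name, len(records), len(survivors), reasons)
    return survivors


# ---------------------------------------------------------------------------
# WGS high-quality-SNP ladder
# ---------------------------------------------------------------------------

def _wgs_sample_gate(call: SampleCall) -> bool:
    """[DP>4 and RGQ>0] or [DP>4 and GQ>0] or [DP=0]."""
    if call.dp == 0:
        return True
    if call.dp > 4:
        if call.rgq is not None and call.rgq > 0:
            return True
        if call.gq is not None and call.gq > 0:
            return True
    return False


def apply_wgs_ladder(
    records: Iterable[LocusRecord],
    ref_control: frozenset[tuple[str, int]] = frozenset(),
) -> tuple[list[LocusRecord], FilterReport]:
    """Run the WGS high-quality-SNP ladder.

    Stages, in order:

    1. ``sample_dp_gq_gate`` — every sample satisfies [DP>4 and RGQ>0] or
       [DP>4 and GQ>0] or [DP=0];
    2. ``sample_dp_lt_100`` — every sample has DP < 100;
    3. ``ref_control`` — drop loci in ``ref_control`` (sites where the
       reference individual's own reads were called variant);
    4. ``all_ref`` — drop loci where every sample is exactly REF;
    5. ``mq60_snp`` — keep SNPs whose site MQ is exactly 60; InDels and
       records with absent MQ are dropped (tallied separately).
    """
    recs = list(records)
    report = FilterReport()

    recs = _stage(
        recs,
        lambda r: (all(_wgs_sample_gate(c) for c in r.calls.values()), "sample DP/GQ gate"),
        report,
        "sample_dp_gq_gate",
    )
    recs = _stage(
        recs,
        lambda r: (all(c.dp < 100 for c in r.calls.values()), "DP >= 100"),
        report,
        "sample_dp_lt_100",
    )
    recs = _stage(
        recs,
        lambda r: (r.key not in ref_control, "reference-read control"),
        report,
        "ref_control",
    )
    recs = _stage(
        recs,
        lambda r: (
            not all(c.cls == gt.REF for c in r.calls.values()),
            "all samples REF",
        ),
        report,
        "all_ref",
    )

    def _mq60(r: LocusRecord) -> tuple[bool, str]:
        if r.variant_type != SNP:
            return False, "not a SNP"
        mq = r.annotation("MQ")
        if mq is None:
            return False, "MQ absent"
        return (mq == 60, "MQ != 60")

    recs = _stage(recs, _mq60, report, "mq60_snp")
    return recs, report


# ---------------------------------------------------------------------------
# GRAS-Di ladder
# ---------------------------------------------------------------------------

_SNP_HARD = (
    ("QD", lambda v: v < 2.0),
    ("FS", lambda v: v > 60.0),
    ("MQ", lambda v: v < 40.0),
    ("MQRankSum", lambda v: v < -12.5),
    ("ReadPosRankSum", lambda v: v < -8.0),
)
_INDEL_HARD = (
    ("QD", lambda v: v < 2.0),
    ("FS", lambda v: v > 200.0),
    ("ReadPosRankSum", lambda v: v < -20.0),
)


def _hard_filter(rec: LocusRecord) -> tuple[bool, str]:
    rules = _SNP_HARD if rec.variant_type == SNP else _INDEL_HARD
    for key, fails in rules:
        v = rec.annotation(key)
        if v is None:
            # absent annotation is treated as failing the gate that needs it
            return False, f"{key} absent"
        if fails(v):
            return False, f"{key} hard filter"
    return True, ""


def _filter2_quality_ok(rec: LocusRecord) -> bool:
    """Every non-REF sample has [20<=GQ<90 and QUAL>=160] or [GQ>=90]."""
    qual = rec.qual
    for call in rec.calls.values():
        if call.cls == gt.REF:
            continue
        gq = call.gq
        if gq is None:
            return False
        if gq >= 90:
            continue
        if 20 <= gq < 90 and qual is not None and qual >= 160:
            continue
        return False
    return True


def apply_grasdi_filters(
    records: Iterable[LocusRecord],
    grove_of: Mapping[str, str],
    filter2_literal: bool = False,
    grove_rule: str = "whole-groves",
) -> tuple[list[LocusRecord], FilterReport]:
    """Run the GRAS-Di ladder.

    Stages, in order:

    1. ``filter1_dp_gq`` — drop loci where any sample has DP < 10 or a
       missing GQ;
    2. ``filter1_hard`` — hard annotation filters: SNPs fail on
       QD<2.0 || FS>60.0 || MQ<40.0 || MQRankSum<-12.5 || ReadPosRankSum<-8.0,
       InDels on QD<2.0 || FS>200.0 || ReadPosRankSum<-20.0; absent
       annotations fail the gate that needs them;
    3. ``new_het`` — keep only loci where at least one sample is HET and
       every remaining sample is REF (newly generated heterozygous loci);
    4. ``filter2_quality`` — genotype-quality condition; by default a locus
       is kept when every HET sample has [20<=GQ<90 and QUAL>=160] or
       [GQ>=90] (``filter2_literal=True`` inverts this, removing such loci,
       i.e. the verbatim reading of the protocol);
    5. ``filter2_grove`` — drop loci whose HET samples form exactly one,
       two or three complete groves (grove_rule="whole-groves"), or, with
       grove_rule="count-only", loci whose HET count is 4, 8 or 12.

    ``grove_of`` maps every sample name to its grove label; a sample
    absent from the map is an error.
    """
    recs = list(records)
    if grove_rule not in ("whole-groves", "count-only"):
        raise ValueError(f"unknown grove_rule {grove_rule!r}")
    for rec in recs:
        for s in rec.calls:
            if s not in grove_of:
                raise KeyError(f"sample {s!r} missing from grove map")
    report = FilterReport()

    def _dp_gq(r: LocusRecord) -> tuple[bool, str]:
        for c in r.calls.values():
            if c.dp < 10:
                return False, "DP < 10"
            if c.gq is None:
                return False, "GQ missing"
        return True, ""

    recs = _stage(recs, _dp_gq, report, "filter1_dp_gq")
    recs = _stage(recs, _hard_filter, report, "filter1_hard")

    def _new_het(r: LocusRecord) -> tuple[bool, str]:
        classes = [c.cls for c in r.calls.values()]
        n_het = sum(c == gt.HET for c in classes)
        if n_het == 0:
            return False, "no HET sample"
        if any(c not in (gt.HET, gt.REF) for c in classes):
            return False, "non-REF non-HET sample present"
        return True, ""

    recs = _stage(recs, _new_het, report, "new_het")

    def _f2_quality(r: LocusRecord) -> tuple[bool, str]:
        ok = _filter2_quality_ok(r)
        if filter2_literal:
            ok = not ok
        return ok, "GQ/QUAL condition"

    recs = _stage(recs, _f2_quality, report, "filter2_quality")

    groves: dict[str, set[str]] = {}
    for sample, grove in grove_of.items():
        groves.setdefault(grove, set()).add(sample)

    def _grove(r: LocusRecord) -> tuple[bool, str]:
        het = {s for s, c in r.calls.items() if c.cls == gt.HET}
        if grove_rule == "count-only":
            return len(het) not in (4, 8, 12), "HET count 4/8/12"
        het_groves = {grove_of[s] for s in het}
        whole_union = set().union(*(groves[g] for g in het_groves)) == het
        if whole_union and 1 <= len(het_groves) <= 3:
            return False, "HET set is 1-3 whole groves"
        return True, ""

    recs = _stage(recs, _grove, report, "filter2_grove")
    return recs, report
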