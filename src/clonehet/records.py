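"""Variant-site records: one locus with its annotations and per-sample calls."""

from __future__ import annotations

from dataclasses import dataclass, field

SNP = "SNP"
INDEL = "InDel"

#: Site-level annotations the filter ladders consult.
ANNOTATION_KEYS = ("MQ", "QD", "FS", "MQRankSum", "ReadPosRankSum")


@dataclass(frozen=True)
class SampleCall:
    """One sample's genotype call at one locus.

    Exactly one of ``gq`` (variant call) or ``rgq`` (reference-block call)
    is expected to be present unless the call is MISSING.
    """

    cls: str
    dp: int
    gq: int | None = None
    rgq: int | None = None

    def quality(self) -> int | None:
        """GQ if present, else RGQ, else None."""
        return self.gq if self.gq is not None else self.rgq


@dataclass
class LocusRecord:
    """One variant site: coordinates, alleles, annotations, per-sample calls.

    Positions are 1-based (VCF convention). ``info`` holds the site
    annotations that may be absent; an absent annotation is stored as None
    (or simply not present), never silently defaulted to a number.
    """

    scaffold: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    variant_type: str = SNP
    qual: float | None = None
    info: dict[str, float | None] = field(default_factory=dict)
    calls: dict[str, SampleCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.variant_type not in (SNP, INDEL):
            raise ValueError(f"unknown variant_type {self.variant_type!r}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.scaffold, self.pos)

    def annotation(self, name: str) -> float | None:
        """Annotation value or None when absent."""
        return self.info.get(name)
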