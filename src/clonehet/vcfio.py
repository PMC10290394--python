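"""VCF reading (cyvcf2) and deterministic VCF writing.

Reading accepts any VCF 4.x with GT and DP; GQ/RGQ and the site
annotations are optional and an absent annotation stays absent (None) —
it is never defaulted to a number. Writing emits a minimal VCF 4.2
dialect with INFO MQ, QD, FS, MQRankSum, ReadPosRankSum and FORMAT
GT:DP:GQ:RGQ (GQ at variant calls, RGQ at reference calls), with fixed
float formatting so identical inputs produce byte-identical files.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

from . import genotypes as gt
from .filters import classify_genotype
from .matrix import GenotypeMatrix
from .records import ANNOTATION_KEYS, INDEL, SNP, LocusRecord, SampleCall

__all__ = ["load_vcf", "write_vcf", "records_to_matrix"]


def _fmt_float(v: float | None) -> str:
    return "." if v is None else f"{v:g}"


def _is_snp(ref: str, alts: Sequence[str]) -> bool:
    return len(ref) == 1 and all(len(a) == 1 and a.isalpha() for a in alts)


def load_vcf(path) -> tuple[list[LocusRecord], GenotypeMatrix]:
    """Read a VCF into locus records and a genotype matrix.

    Malformed records raise with the 1-based record number; haploid or
    polyploid genotypes raise naming the offending site.
    """
    from cyvcf2 import VCF

    reader = VCF(str(path))
    samples = list(reader.samples)
    records: list[LocusRecord] = []
    for idx, v in enumerate(reader, start=1):
        try:
            alts = tuple(v.ALT or ())
            info: dict[str, float | None] = {}
            for key in ANNOTATION_KEYS:
                val = v.INFO.get(key)
                info[key] = float(val) if val is not None else None
            dp = _format_ints(v, "DP", len(samples))
            gq = _format_ints(v, "GQ", len(samples))
            rgq = _format_ints(v, "RGQ", len(samples))
            calls: dict[str, SampleCall] = {}
            for j, s in enumerate(samples):
                geno = v.genotypes[j]
                alleles = tuple(None if a < 0 else int(a) for a in geno[:-1])
                calls[s] = classify_genotype(
                    alleles, dp[j] or 0, gq=gq[j], rgq=rgq[j]
                )
            records.append(
                LocusRecord(
                    scaffold=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alts=alts,
                    variant_type=SNP if _is_snp(v.REF, alts) else INDEL,
                    qual=float(v.QUAL) if v.QUAL is not None else None,
                    info=info,
                    calls=calls,
                )
            )
        except ValueError as exc:
            raise ValueError(f"record {idx} ({v.CHROM}:{v.POS}): {exc}") from exc
    return records, GenotypeMatrix.from_records(records)


def _format_ints(variant, key: str, n: int) -> list[int | None]:
    """Per-sample integer FORMAT values, None when absent."""
    try:
        arr = variant.format(key)
    except KeyError:
        arr = None
    if arr is None:
        return [None] * n
    out: list[int | None] = []
    for row in arr:
        val = int(row[0])
        out.append(None if val < 0 else val)
    return out


_GT_BY_CLASS = {gt.REF: "0/0", gt.HET: "0/1", gt.ALT: "1/1", gt.MISSING: "./."}

_HEADER_LINES = [
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    '##FORMAT=<ID=RGQ,Number=1,Type=Integer,Description="Genotype quality at reference sites">',
]


def write_vcf(
    records: Iterable[LocusRecord],
    path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write locus records as a minimal VCF 4.2 text file."""
    records = list(records)
    samples: list[str] = list(records[0].calls) if records else []
    lines = ["##fileformat=VCFv4.2"]
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    else:
        seen: dict[str, None] = {}
        for r in records:
            seen.setdefault(r.scaffold)
        for name in seen:
            lines.append(f"##contig=<ID={name}>")
    lines.extend(_HEADER_LINES)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for r in records:
        if list(r.calls) != samples:
            raise ValueError(f"inconsistent sample set at {r.scaffold}:{r.pos}")
        info_parts = [
            f"{k}={_fmt_float(v)}" for k, v in r.info.items() if v is not None
        ]
        fields = [
            r.scaffold,
            str(r.pos),
            ".",
            r.ref,
            ",".join(r.alts) if r.alts else ".",
            _fmt_float(r.qual),
            ".",
            ";".join(info_parts) if info_parts else ".",
            "GT:DP:GQ:RGQ",
        ]
        for s in samples:
            c = r.calls[s]
            if c.cls == gt.OTHER:
                if len(r.alts) < 2:
                    raise ValueError(
                        f"OTHER call at {r.scaffold}:{r.pos} needs >= 2 alt alleles"
                    )
                gt_str = "1/2"
            else:
                gt_str = _GT_BY_CLASS[c.cls]
            gq = "." if c.gq is None else str(c.gq)
            rgq = "." if c.rgq is None else str(c.rgq)
            fields.append(f"{gt_str}:{c.dp}:{gq}:{rgq}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def records_to_matrix(
    records: Iterable[LocusRecord], metadata: Mapping[str, str] | None = None
) -> GenotypeMatrix:
    """Convenience wrapper over :meth:`GenotypeMatrix.from_records`."""
    return GenotypeMatrix.from_records(records, metadata)
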