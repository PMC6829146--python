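"""VCF reading and writing via pysam.

The pipeline consumes per-sample VCFs (one genotyped sample each) carrying
DP/AD/GT in FORMAT and the caller annotations QD, FS, MQ, MQRankSum and
ReadPosRankSum in INFO, plus a sites-only strain-catalog VCF.  Multi-allelic
records are split into one VariantRecord per ALT allele.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pysam

from .filtering import VariantRecord

ANNOTATION_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

_HEADER_LINES = [
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant confidence normalized by depth">',
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand-bias Fisher exact p">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping-quality rank-sum z">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read-position rank-sum z">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
]

_GT_CODES = {"het": (0, 1), "hom_alt": (1, 1), "hom_ref": (0, 0)}


def _genotype_label(gt: Optional[tuple]) -> str:
    if gt is None or all(a is None for a in gt):
        return "het"
    alleles = [a for a in gt if a is not None]
    if all(a == 0 for a in alleles):
        return "hom_ref"
    if all(a and a > 0 for a in alleles):
        return "hom_alt"
    return "het"


def read_vcf(path, sample_id: Optional[str] = None, caller: str = "gatk") -> list[VariantRecord]:
    """Read a VCF into VariantRecords (one per ALT allele).

    ``sample_id`` overrides the sample name stored in the header; sites-only
    files (e.g. a strain catalog) yield records with zero depths.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        header_samples = list(vcf.header.samples)
        default_sample = sample_id or (header_samples[0] if header_samples else "")
        for rec in vcf:
            if not rec.alts:
                continue
            annotations = {
                k: float(rec.info[k]) for k in ANNOTATION_KEYS if k in rec.info
            }
            if header_samples:
                fmt = rec.samples[header_samples[0]]
                dp = fmt.get("DP")
                ad = fmt.get("AD")
                genotype = _genotype_label(fmt.get("GT"))
            else:
                try:
                    dp = rec.info.get("DP")
                except ValueError:  # DP not declared in this header
                    dp = None
                ad, genotype = None, "het"
            for alt_index, alt in enumerate(rec.alts):
                if alt is None or alt in (".", "*", "<NON_REF>"):
                    continue
                if ad is not None and len(ad) > alt_index + 1:
                    depths = (int(ad[0] or 0), int(ad[alt_index + 1] or 0))
                else:
                    depths = (0, 0)
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        total_depth=int(dp) if dp is not None else None,
                        qual=float(rec.qual) if rec.qual is not None else 0.0,
                        allele_depths=depths,
                        genotype=genotype,
                        annotations=annotations,
                        sample_id=default_sample,
                        caller=caller,
                    )
                )
    return records


def _build_header(contigs: Mapping[str, int], sample_id: Optional[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for line in _HEADER_LINES:
        header.add_line(line)
    if sample_id is not None:
        header.add_sample(sample_id)
    return header


def write_vcf(
    path,
    records: Sequence[VariantRecord],
    contigs: Mapping[str, int],
    sample_id: Optional[str] = None,
) -> None:
    """Write records as an uncompressed single-sample (or sites-only) VCF 4.2.

    Records are sorted by (chrom, pos, alleles) to keep output deterministic.
    """
    header = _build_header(contigs, sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in sorted(records, key=lambda v: (v.chrom, v.pos, v.ref_allele, v.alt_allele)):
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                alleles=(r.ref_allele, r.alt_allele),
                qual=round(float(r.qual), 2),
            )
            for k in ANNOTATION_KEYS:
                if k in r.annotations:
                    rec.info[k] = round(float(r.annotations[k]), 3)
            if sample_id is not None:
                fmt = rec.samples[sample_id]
                fmt["GT"] = _GT_CODES.get(r.genotype, (0, 1))
                fmt["AD"] = (int(r.allele_depths[0]), int(r.allele_depths[1]))
                if r.total_depth is not None:
                    fmt["DP"] = int(r.total_depth)
            out.write(rec)
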