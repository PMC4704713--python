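"""Minimal VCF 4.2 emission and pysam-backed reading of haploid call sets.

Emission writes one single-sample uncompressed VCF per MA line with GT, DP
and AD fields — enough for the support filters (read depth and fraction of
reads backing the alternate allele) to be exercised downstream.  Reading
goes through :class:`pysam.VariantFile` so anything a standard caller emits
is accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pysam

log = logging.getLogger(__name__)


@dataclass
class VcfRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int = 50
    alt_reads: int | None = None  # defaults to depth (alt fraction 1.0)

    @property
    def alt_fraction(self) -> float:
        ar = self.depth if self.alt_reads is None else self.alt_reads
        return ar / self.depth if self.depth else 0.0


def write_vcf(path, contigs: dict[str, int], records, sample: str = "sample") -> None:
    """Write records (iterable of VcfRecord) as a single-sample VCF."""
    records = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref,alt)">\n'
        )
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for r in records:
            alt_reads = r.depth if r.alt_reads is None else r.alt_reads
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                f"GT:DP:AD\t1:{r.depth}:{r.depth - alt_reads},{alt_reads}\n"
            )


def read_vcf_records(vcf_path):
    """Yield (chrom, pos, ref, alt, depth, alt_fraction) per alternate allele.

    Multi-allelic sites are split into one record per alternate.  Records with
    no usable depth yield depth None (the caller decides how to handle them).
    """
    with pysam.VariantFile(str(vcf_path)) as vf:
        sample_names = list(vf.header.samples)
        for rec in vf.fetch() if vf.index is not None else vf:
            alts = rec.alts or ()
            depth = None
            ad = None
            if sample_names:
                fmt = rec.samples[sample_names[0]]
                depth = fmt.get("DP")
                ad = fmt.get("AD")
            if depth is None:
                try:
                    depth = rec.info.get("DP")
                except ValueError:  # DP not declared in header
                    depth = None
            for i, alt in enumerate(alts):
                if alt is None or alt == "*":
                    continue
                if depth is None:
                    yield rec.chrom, rec.pos, rec.ref, alt, None, None
                    continue
                if ad is not None and len(ad) > i + 1 and ad[i + 1] is not None:
                    frac = ad[i + 1] / depth if depth else 0.0
                else:
                    frac = 1.0  # haploid call without AD: assume full support
                yield rec.chrom, rec.pos, rec.ref, alt, int(depth), float(frac)
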