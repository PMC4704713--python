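"""Reference genome handling and genome-side denominators.

Loads a FASTA reference plus an exclusion BED (centromere/telomere-like
regions that are untrustworthy for short-read variant calling), and exposes
the denominators every downstream rate needs: analyzed length, A/T vs G/C
base composition, the 32-class strand-collapsed trinucleotide census,
non-overlapping G/C windows, and a per-position feature map
(coding / intron / noncoding).

Coordinates are 1-based inclusive internally (VCF convention).  BED input is
0-based half-open and converted on load.  Ambiguous bases (anything outside
ACGT) are excluded from all denominators; a position whose trinucleotide
window touches an excluded or ambiguous base is dropped from the census.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ReferenceGenome",
    "BaseComposition",
    "TrinucleotideCensus",
    "FeatureMap",
    "GCWindowTable",
    "load_reference",
    "base_composition",
    "trinucleotide_census",
    "gc_windows",
    "load_annotation",
    "collapse_trinucleotide",
    "trinuc_class_label",
    "TRINUC_CLASSES",
    "encode_sequence",
    "decode_sequence",
]

# base encoding: A=0 C=1 G=2 T=3, ambiguous=4
BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def revcomp(seq: str) -> str:
    return decode_sequence(_COMP[encode_sequence(seq)][::-1])


def collapse_trinucleotide(tri: str) -> str:
    """Strand-collapsed representative: lexicographic min of (tri, revcomp)."""
    rc = revcomp(tri)
    return min(tri.upper(), rc)


def trinuc_class_label(tri: str) -> str:
    """Field-style label with flanks lowercased, center capitalized: aCa."""
    rep = collapse_trinucleotide(tri)
    return rep[0].lower() + rep[1] + rep[2].lower()


def _build_collapse_tables():
    tris = ["".join((a, b, c)) for a in BASES for b in BASES for c in BASES]
    reps = sorted({collapse_trinucleotide(t) for t in tris})
    rep_index = {r: i for i, r in enumerate(reps)}
    code_map = np.empty(64, dtype=np.int16)
    for t in tris:
        code = _tri_code(t)
        code_map[code] = rep_index[collapse_trinucleotide(t)]
    return reps, code_map


def _tri_code(tri: str) -> int:
    c = encode_sequence(tri)
    return int(c[0]) * 16 + int(c[1]) * 4 + int(c[2])


#: the 32 strand-collapse class representatives, sorted lexicographically
TRINUC_CLASSES, _TRI_COLLAPSE = _build_collapse_tables()
TRINUC_CLASS_LABELS = [r[0].lower() + r[1] + r[2].lower() for r in TRINUC_CLASSES]

#: index of classes by center base of the representative
GC_CENTER_CLASSES = [i for i, r in enumerate(TRINUC_CLASSES) if r[1] in "CG"]
AT_CENTER_CLASSES = [i for i, r in enumerate(TRINUC_CLASSES) if r[1] in "AT"]


@dataclass
class ReferenceGenome:
    """Chromosome sequences plus the analyzed-position mask.

    ``seqs`` maps chromosome name to a uint8 code array; ``mask`` maps it to a
    boolean array, True where the position is analyzed (not excluded).
    """

    names: list[str]
    seqs: dict[str, np.ndarray]
    mask: dict[str, np.ndarray]

    @property
    def chromosome_lengths(self) -> dict[str, int]:
        return {n: len(self.seqs[n]) for n in self.names}

    @property
    def total_length_bp(self) -> int:
        return int(sum(len(s) for s in self.seqs.values()))

    @property
    def analyzed_length_bp(self) -> int:
        """L: count of mask-true positions."""
        return int(sum(m.sum() for m in self.mask.values()))

    def base_at(self, chrom: str, pos: int) -> str:
        """1-based base lookup."""
        return "ACGTN"[self.seqs[chrom][pos - 1]]

    def context_at(self, chrom: str, pos: int) -> str | None:
        """Trinucleotide (5'->3' reference strand) centered at 1-based pos.

        Returns None at chromosome ends or if any of the three bases is
        ambiguous or excluded.
        """
        seq = self.seqs[chrom]
        if pos < 2 or pos > len(seq) - 1:
            return None
        codes = seq[pos - 2 : pos + 1]
        if (codes >= 4).any() or not self.mask[chrom][pos - 2 : pos + 1].all():
            return None
        return decode_sequence(codes)


@dataclass
class BaseComposition:
    at_sites: int
    gc_sites: int
    ambiguous_sites: int = 0

    @property
    def gc_fraction(self) -> float:
        tot = self.at_sites + self.gc_sites
        return self.gc_sites / tot if tot else float("nan")


@dataclass
class TrinucleotideCensus:
    """Included center-position counts for the 32 strand-collapsed classes."""

    class_sites: dict[str, int]

    @property
    def total(self) -> int:
        return int(sum(self.class_sites.values()))

    def as_array(self) -> np.ndarray:
        return np.array([self.class_sites[r] for r in TRINUC_CLASSES], dtype=float)


@dataclass
class FeatureMap:
    """Per-position feature labels with precedence coding > intron > noncoding."""

    labels: dict[str, np.ndarray]  # int8: 0 noncoding, 1 coding, 2 intron
    genome: ReferenceGenome

    CODES = {"noncoding": 0, "coding": 1, "intron": 2}
    NAMES = {v: k for k, v in CODES.items()}

    @property
    def fractions(self) -> dict[str, float]:
        counts = {k: 0 for k in self.CODES}
        total = 0
        for chrom in self.genome.names:
            lab = self.labels[chrom][self.genome.mask[chrom]]
            total += lab.size
            for name, code in self.CODES.items():
                counts[name] += int((lab == code).sum())
        return {k: v / total for k, v in counts.items()}

    def label_at(self, chrom: str, pos: int) -> str:
        return self.NAMES[int(self.labels[chrom][pos - 1])]

    def bp(self, label: str) -> int:
        code = self.CODES[label]
        return int(
            sum(
                ((self.labels[c] == code) & self.genome.mask[c]).sum()
                for c in self.genome.names
            )
        )


@dataclass
class GCWindowTable:
    """Non-overlapping fixed-width windows with floored G/C percent bins."""

    windows: pd.DataFrame  # chrom, start, end, included_bp, at_bp, gc_bp, gc_percent, gc_bin, short
    window_bp: int

    def full_windows(self) -> pd.DataFrame:
        return self.windows[~self.windows["short"]]


def _read_bed(bed_path, genome: ReferenceGenome) -> list[tuple[str, int, int]]:
    """Parse 0-based half-open BED into 1-based inclusive intervals."""
    intervals = []
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{bed_path}: line {ln}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if chrom not in genome.seqs:
                raise ValueError(
                    f"{bed_path}: line {ln}: unknown chromosome {chrom!r}"
                )
            if start < 0 or end > len(genome.seqs[chrom]) or start >= end:
                raise ValueError(
                    f"{bed_path}: line {ln}: interval {start}-{end} outside "
                    f"chromosome {chrom} bounds"
                )
            intervals.append((chrom, start + 1, end))
    return intervals


def load_reference(fasta_path, exclusion_bed_path=None) -> ReferenceGenome:
    """Load a FASTA reference and mask out excluded BED intervals."""
    names, seqs, mask = [], {}, {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        names.append(rec.id)
        codes = encode_sequence(str(rec.seq))
        seqs[rec.id] = codes
        mask[rec.id] = np.ones(len(codes), dtype=bool)
    if not names:
        raise ValueError(f"no FASTA records parsed from {fasta_path}")
    genome = ReferenceGenome(names=names, seqs=seqs, mask=mask)
    if exclusion_bed_path is not None:
        for chrom, start, end in _read_bed(exclusion_bed_path, genome):
            mask[chrom][start - 1 : end] = False
    return genome


def base_composition(genome: ReferenceGenome) -> BaseComposition:
    at = gc = amb = 0
    for chrom in genome.names:
        codes = genome.seqs[chrom][genome.mask[chrom]]
        counts = np.bincount(codes, minlength=5)
        at += int(counts[0] + counts[3])
        gc += int(counts[1] + counts[2])
        amb += int(counts[4])
    return BaseComposition(at_sites=at, gc_sites=gc, ambiguous_sites=amb)


def context_class_codes(genome: ReferenceGenome) -> dict[str, np.ndarray]:
    """Per-position collapsed trinucleotide class index (-1 = unassignable).

    Shared by the census, context annotation and the simulator so all three
    agree exactly on which positions carry which class.
    """
    out = {}
    for chrom in genome.names:
        codes = genome.seqs[chrom].astype(np.int16)
        m = genome.mask[chrom]
        n = len(codes)
        cls = np.full(n, -1, dtype=np.int16)
        if n >= 3:
            left, center, right = codes[:-2], codes[1:-1], codes[2:]
            valid = (left < 4) & (center < 4) & (right < 4)
            valid &= m[:-2] & m[1:-1] & m[2:]
            tri = left * 16 + center * 4 + right
            cls[1:-1][valid] = _TRI_COLLAPSE[tri[valid]]
        out[chrom] = cls
    return out


def trinucleotide_census(genome: ReferenceGenome) -> TrinucleotideCensus:
    totals = np.zeros(32, dtype=np.int64)
    for cls in context_class_codes(genome).values():
        valid = cls >= 0
        totals += np.bincount(cls[valid], minlength=32)
    return TrinucleotideCensus(
        class_sites={rep: int(totals[i]) for i, rep in enumerate(TRINUC_CLASSES)}
    )


def gc_windows(genome: ReferenceGenome, window_bp: int = 10_000) -> GCWindowTable:
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows = []
    for chrom in genome.names:
        codes = genome.seqs[chrom]
        m = genome.mask[chrom]
        n = len(codes)
        for start0 in range(0, n, window_bp):
            end0 = min(start0 + window_bp, n)
            win = codes[start0:end0]
            wm = m[start0:end0]
            counts = np.bincount(win[wm], minlength=5)
            at_bp = int(counts[0] + counts[3])
            gc_bp = int(counts[1] + counts[2])
            inc = at_bp + gc_bp
            pct = 100.0 * gc_bp / inc if inc else float("nan")
            rows.append(
                {
                    "chrom": chrom,
                    "start": start0 + 1,
                    "end": end0,
                    "included_bp": inc,
                    "at_bp": at_bp,
                    "gc_bp": gc_bp,
                    "gc_percent": pct,
                    "gc_bin": int(np.floor(pct)) if inc else -1,
                    "short": end0 - start0 < window_bp,
                }
            )
    return GCWindowTable(windows=pd.DataFrame(rows), window_bp=window_bp)


def load_annotation(annotation_path, genome: ReferenceGenome) -> FeatureMap:
    """Read feature intervals into a per-position map.

    Accepts a 4-column TSV (chrom, start, end, label; 1-based inclusive) or
    GFF3 (feature types CDS -> coding, intron -> intron; others ignored).
    Overlaps resolve by precedence coding > intron > noncoding.
    """
    path = Path(annotation_path)
    intervals: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 9:  # GFF3
                chrom, ftype, start, end = parts[0], parts[2], parts[3], parts[4]
                label = {"CDS": "coding", "intron": "intron"}.get(ftype)
                if label is None:
                    continue
            elif len(parts) >= 4:
                chrom, start, end, label = parts[0], parts[1], parts[2], parts[3]
            else:
                raise ValueError(f"{path}: line {ln}: unrecognized annotation row")
            if label not in FeatureMap.CODES:
                raise ValueError(f"{path}: line {ln}: unknown feature label {label!r}")
            start, end = int(start), int(end)
            if chrom not in genome.seqs:
                raise ValueError(f"{path}: line {ln}: unknown chromosome {chrom!r}")
            if start < 1 or end > len(genome.seqs[chrom]) or start > end:
                raise ValueError(
                    f"{path}: line {ln}: interval {start}-{end} outside {chrom}"
                )
            intervals.append((chrom, start, end, label))
    return feature_map_from_intervals(intervals, genome)


def feature_map_from_intervals(intervals, genome: ReferenceGenome) -> FeatureMap:
    labels = {c: np.zeros(len(genome.seqs[c]), dtype=np.int8) for c in genome.names}
    # apply in increasing precedence so coding wins over intron
    for wanted in ("intron", "coding"):
        code = FeatureMap.CODES[wanted]
        for chrom, start, end, label in intervals:
            if label == wanted:
                labels[chrom][start - 1 : end] = code
    return FeatureMap(labels=labels, genome=genome)
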