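"""Synthetic MA experiment generator with fully known ground truth.

Generates a reference genome (target G/C content, gene/intron annotation,
exclusion regions, replication-origin and expression tables) and per-line
variant call sets that emulate what a variant-calling pipeline would hand to
the downstream analysis: new SNMs drawn from a six-class conditional
spectrum with optional trinucleotide-context multipliers, small indels with
an insertion bias, clustered double/complex events, ancestral marker
differences present in every line (with per-class detection dropout for
false-negative accounting), and low-quality spike-in records that the
support filters must remove.

Default parameters mirror the fission-yeast MA experiment the package
models: 79 lines, 1952 generations, SNM rate 1.70e-10 per base per
generation with negative-binomial line-to-line overdispersion k = 2.06, a
6.13-fold insertion bias, and 80/120/42 ancestral SNM/insertion/deletion
markers.  Mutations are placed in one generative pass (per-generation
linearity makes forward simulation unnecessary for effectively single
lineages).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .catalog import VariantCall
from .enrichment import GeneModel
from .genome import (
    BASES,
    ReferenceGenome,
    TRINUC_CLASSES,
    FeatureMap,
    context_class_codes,
    decode_sequence,
    feature_map_from_intervals,
)
from .rates import SNM_CLASSES, snm_class_of
from .vcfio import VcfRecord, write_vcf

__all__ = [
    "SimulationConfig",
    "SyntheticGenome",
    "SyntheticTruth",
    "SimulatedExperiment",
    "generate_genome",
    "simulate_lines",
    "recovery_report",
    "write_genome_files",
    "write_experiment_vcfs",
    "DEFAULT_SNM_SPECTRUM",
]

# Six-class count proportions consistent with the printed biases of the
# modeled experiment (Ts/Tv 0.72; within-transition G:C->A:T fold 2.02;
# within-transversion G:C->T:A fold 4.55; overall G/C->A/T fold 2.97 at
# G/C fraction 0.3606).  The G:C<->C:G vs A:T<->T:A split is not printed;
# it is fixed by equating those two conditional rates.
DEFAULT_SNM_SPECTRUM = {
    "GC>AT_ts": 0.22295,
    "AT>GC_ts": 0.19568,
    "GC>TA_tv": 0.30194,
    "AT>CG_tv": 0.11766,
    "GC>CG_tv": 0.05828,
    "AT>TA_tv": 0.10349,
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# directed changes per strand-collapsed class, keyed by source base
_DIRECTED = {}
for _ref in BASES:
    for _alt in BASES:
        if _ref != _alt:
            _DIRECTED.setdefault(_ref, {})[_alt] = snm_class_of(_ref, _alt)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment; defaults are the study scale."""

    genome_length_bp: int = 12_470_000
    n_chromosomes: int = 3
    chromosome_weights: tuple = (0.4475, 0.3641, 0.1884)
    gc_fraction: float = 0.3606
    coding_fraction: float = 0.57
    intron_fraction: float = 0.03
    excluded_fraction: float = 0.038
    n_lines: int = 79
    generations: float = 1952.0
    #: denominator length for expected counts; None = analyzed genome length.
    #: Setting it above the genome length lets a small genome carry
    #: study-scale event counts.
    rate_denominator_bp: float | None = None
    snm_rate: float = 1.70e-10
    snm_spectrum: dict = field(default_factory=lambda: dict(DEFAULT_SNM_SPECTRUM))
    insertion_rate: float = 0.174e-9 * 288 / 335   # 6.13-fold insertion bias
    deletion_rate: float = 0.174e-9 * 47 / 335
    double_rate: float = 8.84e-12
    complex_rate: float = 8.32e-12
    dispersion_k: float | None = 2.06  # NB overdispersion of per-line SNM counts
    insertion_mean_bp: float = 1.6
    deletion_mean_bp: float = 3.1
    context_multipliers: dict = field(default_factory=dict)
    dropout: dict = field(
        default_factory=lambda: {"SNM": 1e-4, "insertion": 0.011, "deletion": 0.017}
    )
    n_markers: dict = field(
        default_factory=lambda: {"SNM": 80, "insertion": 120, "deletion": 42}
    )
    n_low_quality_per_line: int = 3
    oris_per_mb: float = 32.0
    ori_minute_range: tuple = (68, 85)
    expression_zero_fraction: float = 0.3
    expression_replicates: int = 10
    cluster_distance: int = 50

    def __post_init__(self):
        if self.genome_length_bp < 10_000:
            raise ValueError("genome_length_bp must be at least 10 kb")
        if self.coding_fraction + self.intron_fraction > 1:
            raise ValueError("feature fractions exceed 1")
        for name in ("snm_rate", "insertion_rate", "deletion_rate",
                     "double_rate", "complex_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        s = sum(self.snm_spectrum.values())
        if s > 0:
            self.snm_spectrum = {k: v / s for k, v in self.snm_spectrum.items()}


@dataclass
class SyntheticGenome:
    genome: ReferenceGenome
    feature_map: FeatureMap
    feature_intervals: list
    genes: list
    exclusions: list  # (chrom, start0, end0) BED-style half-open
    ori_table: pd.DataFrame
    expression_table: pd.DataFrame
    realized: dict


@dataclass
class SyntheticTruth:
    config: SimulationConfig
    events: pd.DataFrame           # one row per planted event
    per_line_snm_counts: pd.Series
    markers: pd.DataFrame          # marker_id, class, chrom, pos, ref, alt
    dropout: pd.DataFrame          # marker_id x line 0/1 detected
    collisions: list               # event-id pairs within cluster distance
    filtered_spikes: pd.DataFrame  # planted low-quality records


@dataclass
class SimulatedExperiment:
    line_variants: dict            # line_id -> list[VariantCall]
    ancestor_variants: list
    truth: SyntheticTruth


def _rng_of(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ----------------------------------------------------------------------------
# genome generation
# ----------------------------------------------------------------------------


def generate_genome(config: SimulationConfig, seed=0) -> SyntheticGenome:
    rng = _rng_of(seed)
    gc, at = config.gc_fraction, 1.0 - config.gc_fraction
    weights = np.asarray(config.chromosome_weights[: config.n_chromosomes], float)
    weights = weights / weights.sum()
    lengths = np.maximum((weights * config.genome_length_bp).astype(int), 3000)

    names, seqs, mask = [], {}, {}
    for i, n in enumerate(lengths):
        name = f"chr{'I' * (i + 1)}" if i < 3 else f"chr{i + 1}"
        names.append(name)
        # first-order Markov chain with identical rows (stationary = target):
        # equivalent to i.i.d. draws, which vectorizes
        seqs[name] = rng.choice(
            4, size=int(n), p=[at / 2, gc / 2, gc / 2, at / 2]
        ).astype(np.uint8)
        mask[name] = np.ones(int(n), dtype=bool)
    genome = ReferenceGenome(names=names, seqs=seqs, mask=mask)

    # exclusions: telomere-like ends plus a centromere-like middle block
    exclusions = []
    f = config.excluded_fraction
    for name in names:
        n = len(seqs[name])
        end_len = max(int(n * f / 4), 0)
        mid_len = max(int(n * f / 2), 0)
        if end_len:
            exclusions.append((name, 0, end_len))
            exclusions.append((name, n - end_len, n))
        if mid_len:
            mid = n // 2
            exclusions.append((name, mid - mid_len // 2, mid + (mid_len + 1) // 2))
    for chrom, s0, e0 in exclusions:
        mask[chrom][s0:e0] = False

    genes, feature_intervals = _generate_annotation(genome, config, rng)
    feature_map = feature_map_from_intervals(feature_intervals, genome)

    ori_rows = []
    lo, hi = config.ori_minute_range
    for name in names:
        n_oris = max(int(round(config.oris_per_mb * len(seqs[name]) / 1e6)), 1)
        positions = np.sort(rng.integers(1, len(seqs[name]) + 1, size=n_oris))
        for p in positions:
            ori_rows.append(
                {"chrom": name, "position": int(p),
                 "minute": int(rng.integers(lo, hi + 1))}
            )
    ori_table = pd.DataFrame(ori_rows)

    expr_rows = []
    for g in genes:
        if rng.random() < config.expression_zero_fraction:
            vals = np.zeros(config.expression_replicates)
        else:
            base = min(max(rng.normal(1.5, 0.8), 0.01), 3.5)
            vals = np.clip(base + rng.normal(0, 0.05, config.expression_replicates),
                           0.0, 3.5)
        row = {"transcript_id": g.gene_id, "chrom": g.chrom,
               "start": g.exons[0][0], "end": g.exons[-1][1]}
        row.update({f"log10_fpkm_{i + 1}": v for i, v in enumerate(vals)})
        expr_rows.append(row)
    expression_table = pd.DataFrame(expr_rows)

    realized = {
        "gc_fraction_target": gc,
        "feature_fractions": feature_map.fractions,
        "analyzed_length_bp": genome.analyzed_length_bp,
    }
    return SyntheticGenome(
        genome=genome, feature_map=feature_map,
        feature_intervals=feature_intervals, genes=genes,
        exclusions=exclusions, ori_table=ori_table,
        expression_table=expression_table, realized=realized,
    )


def _generate_annotation(genome, config, rng):
    """Place genes (CDS blocks, occasional introns) to hit target fractions."""
    genes, intervals = [], []
    coding_f, intron_f = config.coding_fraction, config.intron_fraction
    if coding_f <= 0:
        return genes, intervals
    mean_cds = 1350.0
    mean_intron_total = mean_cds * intron_f / coding_f
    genic_f = coding_f + intron_f
    mean_gap = (mean_cds + mean_intron_total) * (1.0 - genic_f) / genic_f
    gid = 0
    for chrom in genome.names:
        n = len(genome.seqs[chrom])
        cursor = 1
        while True:
            gap = int(rng.exponential(mean_gap)) if mean_gap > 0 else 0
            cds_len = 3 * int(rng.integers(100, 801))  # 300-2400 bp CDS
            n_introns = int(rng.poisson(mean_intron_total / 90.0)) if intron_f else 0
            intron_lens = [int(40 + rng.exponential(50)) for _ in range(n_introns)]
            span = cds_len + sum(intron_lens)
            start = cursor + gap
            if start + span - 1 > n:
                break
            # split the CDS into n_introns+1 exon blocks
            cuts = sorted(
                rng.choice(np.arange(3, cds_len - 2, 3), size=n_introns,
                           replace=False)
            ) if n_introns else []
            exon_lens = np.diff([0, *cuts, cds_len])
            exons = []
            pos = start
            for i, el in enumerate(exon_lens):
                exons.append((pos, pos + int(el) - 1))
                pos += int(el)
                if i < len(intron_lens):
                    pos += intron_lens[i]
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(gene_id=f"gene{gid:05d}", chrom=chrom,
                                   strand=strand, exons=exons))
            for s, e in exons:
                intervals.append((chrom, s, e, "coding"))
            for s, e in GeneModel(f"tmp", chrom, strand, exons).introns:
                intervals.append((chrom, s, e, "intron"))
            cursor = start + span
    return genes, intervals


# ----------------------------------------------------------------------------
# line simulation
# ----------------------------------------------------------------------------


class _SitePicker:
    """Weighted sampling of included unambiguous sites by source base set.

    Weights apply per trinucleotide class (context multipliers); sites with
    unassignable context get weight 1.
    """

    def __init__(self, bundle: SyntheticGenome, config: SimulationConfig):
        genome = bundle.genome
        ctx = context_class_codes(genome)
        mult = np.ones(33)
        for cls, m in config.context_multipliers.items():
            mult[TRINUC_CLASSES.index(cls)] = m
        self.chrom_names = list(genome.names)
        chrom_idx, pos, base, weight = [], [], [], []
        for ci, chrom in enumerate(self.chrom_names):
            codes = genome.seqs[chrom]
            m = genome.mask[chrom]
            ok = m & (codes < 4)
            idx = np.nonzero(ok)[0]
            cls = ctx[chrom][idx]
            w = mult[np.where(cls >= 0, cls, 32)]
            chrom_idx.append(np.full(len(idx), ci, dtype=np.int32))
            pos.append(idx + 1)
            base.append(codes[idx])
            weight.append(w)
        self.chrom_idx = np.concatenate(chrom_idx)
        self.pos = np.concatenate(pos).astype(np.int64)
        self.base = np.concatenate(base)
        self.weight = np.concatenate(weight)
        self.is_gc = (self.base == 1) | (self.base == 2)
        self._cum = {}
        for key, sel in (("GC", self.is_gc), ("AT", ~self.is_gc), ("any", None)):
            sel_idx = np.arange(len(self.pos)) if sel is None else np.nonzero(sel)[0]
            cum = np.cumsum(self.weight[sel_idx])
            self._cum[key] = (sel_idx, cum)

    def sample(self, rng, source: str, n: int = 1):
        """Sample n site indices from the 'GC', 'AT' or 'any' pool."""
        sel_idx, cum = self._cum[source]
        u = rng.random(n) * cum[-1]
        return sel_idx[np.searchsorted(cum, u)]

    def site(self, i):
        return (
            self.chrom_names[self.chrom_idx[i]],
            int(self.pos[i]),
            "ACGT"[self.base[i]],
        )


def _direction_weights(config):
    """P(alt | ref base) proportional to conditional class rates."""
    # class conditional rates ~ proportion / source fraction
    gc, at = config.gc_fraction, 1 - config.gc_fraction
    rate = {
        c: config.snm_spectrum[c] / (gc if c.startswith("GC") else at)
        for c in SNM_CLASSES
    }
    out = {}
    for ref in BASES:
        alts = [a for a in BASES if a != ref]
        w = np.array([rate[_DIRECTED[ref][a]] for a in alts])
        out[ref] = (alts, w / w.sum())
    return out


def _geometric_size(rng, mean):
    return int(rng.geometric(min(1.0, 1.0 / mean)))


def simulate_lines(bundle: SyntheticGenome, config: SimulationConfig,
                   seed=0, picker: "_SitePicker | None" = None
                   ) -> SimulatedExperiment:
    """Simulate per-line call sets plus the ancestor, with full truth.

    ``picker`` (from :class:`_SitePicker`) can be passed in to amortize the
    per-genome site-weight tables over many replicate simulations.
    """
    rng = _rng_of(seed)
    genome = bundle.genome
    if picker is None:
        picker = _SitePicker(bundle, config)
    dir_w = _direction_weights(config)
    L = config.rate_denominator_bp or genome.analyzed_length_bp
    G = config.generations
    gc, at = config.gc_fraction, 1 - config.gc_fraction
    gc_share = sum(v for k, v in config.snm_spectrum.items() if k.startswith("GC"))

    line_ids = [f"line{(i + 1):03d}" for i in range(config.n_lines)]

    # --- ancestor markers (spaced so each is its own event) ------------------
    markers = _place_markers(bundle, config, picker, dir_w, rng)

    events_rows, spikes_rows = [], []
    line_variants = {}
    per_line_snm = {}
    collisions = []
    dropout_mat = pd.DataFrame(
        1, index=markers["marker_id"], columns=line_ids, dtype=int
    ) if len(markers) else pd.DataFrame(index=pd.Index([], name="marker_id"))
    event_id = 0

    mean_snm = config.snm_rate * G * L
    class_probs = np.array([config.snm_spectrum[c] for c in SNM_CLASSES])

    for line_id in line_ids:
        used: set = set()
        variants: list[VariantCall] = []
        line_events = []

        def add_snm(source, cls=None):
            nonlocal event_id
            for _ in range(200):
                i = int(picker.sample(rng, source)[0])
                chrom, pos, ref = picker.site(i)
                if (chrom, pos) not in used:
                    break
            used.add((chrom, pos))
            if cls is None:
                alts, w = dir_w[ref]
                alt = alts[int(rng.choice(len(alts), p=w))]
            else:
                alts = [a for a in BASES if a != ref and _DIRECTED[ref][a] == cls]
                alt = alts[int(rng.integers(len(alts)))]
            return chrom, pos, ref, alt

        # SNMs: NB-overdispersed per-line total, multinomial over classes
        if config.dispersion_k is None or math.isinf(config.dispersion_k):
            n_snm = int(rng.poisson(mean_snm)) if mean_snm > 0 else 0
        elif mean_snm > 0:
            k = config.dispersion_k
            n_snm = int(rng.negative_binomial(k, k / (k + mean_snm)))
        else:
            n_snm = 0
        per_line_snm[line_id] = n_snm
        n_per_class = rng.multinomial(n_snm, class_probs)
        for cls, n_c in zip(SNM_CLASSES, n_per_class):
            source = "GC" if cls.startswith("GC") else "AT"
            for _ in range(int(n_c)):
                chrom, pos, ref, alt = add_snm(source, cls)
                event_id += 1
                line_events.append((event_id, "SNM", chrom, pos))
                events_rows.append(
                    {"line_id": line_id, "event_id": event_id, "class": "SNM",
                     "snm_class": cls, "chrom": chrom, "pos": pos,
                     "ref": ref, "alt": alt}
                )
                variants.append(VariantCall(line_id, chrom, pos, ref, alt))

        # indels
        for kind, rate, mean_sz in (
            ("insertion", config.insertion_rate, config.insertion_mean_bp),
            ("deletion", config.deletion_rate, config.deletion_mean_bp),
        ):
            n_k = int(rng.poisson(rate * G * L)) if rate > 0 else 0
            for _ in range(n_k):
                size = _geometric_size(rng, mean_sz)
                for _ in range(200):
                    i = int(picker.sample(rng, "any")[0])
                    chrom, pos, ref = picker.site(i)
                    seq = genome.seqs[chrom]
                    if (chrom, pos) in used:
                        continue
                    if kind == "deletion":
                        if pos + size > len(seq) or (seq[pos : pos + size] >= 4).any():
                            continue
                    break
                used.add((chrom, pos))
                if kind == "insertion":
                    ins = "".join(
                        "ACGT"[b] for b in rng.choice(
                            4, size, p=[at / 2, gc / 2, gc / 2, at / 2])
                    )
                    ref_a, alt_a = ref, ref + ins
                else:
                    ref_a = ref + decode_sequence(seq[pos : pos + size])
                    alt_a = ref
                event_id += 1
                line_events.append((event_id, kind, chrom, pos))
                events_rows.append(
                    {"line_id": line_id, "event_id": event_id, "class": kind,
                     "snm_class": None, "chrom": chrom, "pos": pos,
                     "ref": ref_a, "alt": alt_a}
                )
                variants.append(VariantCall(line_id, chrom, pos, ref_a, alt_a))

        # clustered events
        for kind, rate in (("double_SNM", config.double_rate),
                           ("complex", config.complex_rate)):
            n_k = int(rng.poisson(rate * G * L)) if rate > 0 else 0
            for _ in range(n_k):
                members = _make_cluster(kind, genome, picker, dir_w, config,
                                        rng, used)
                if members is None:
                    continue
                event_id += 1
                line_events.append((event_id, kind, members[0][0], members[0][1]))
                for chrom, pos, ref_a, alt_a in members:
                    events_rows.append(
                        {"line_id": line_id, "event_id": event_id, "class": kind,
                         "snm_class": None, "chrom": chrom, "pos": pos,
                         "ref": ref_a, "alt": alt_a}
                    )
                    variants.append(VariantCall(line_id, chrom, pos, ref_a, alt_a))

        # collisions: independent events within the cluster distance merge
        # downstream; record them so recovery tests can account for it
        by_chrom: dict[str, list] = {}
        for eid, cls, chrom, pos in line_events:
            by_chrom.setdefault(chrom, []).append((pos, eid))
        for chrom, items in by_chrom.items():
            items.sort()
            for (p1, e1), (p2, e2) in zip(items, items[1:]):
                if e1 != e2 and p2 - p1 <= config.cluster_distance:
                    collisions.append((line_id, e1, e2))

        # ancestor markers, with per-class detection dropout
        detected_markers = []
        for row in markers.itertuples():
            p_drop = config.dropout.get(row.cls, 0.0)
            if p_drop > 0 and rng.random() < p_drop:
                dropout_mat.loc[row.marker_id, line_id] = 0
                continue
            detected_markers.append(
                VariantCall(line_id, row.chrom, row.pos, row.ref, row.alt)
            )
        line_variants[line_id] = variants + detected_markers

        # low-quality spike-ins (fail depth or allele-fraction filters)
        for _ in range(config.n_low_quality_per_line):
            i = int(picker.sample(rng, "any")[0])
            chrom, pos, ref = picker.site(i)
            alts = [a for a in BASES if a != ref]
            alt = alts[int(rng.integers(3))]
            if rng.random() < 0.5:
                depth, frac = 3, 1.0
            else:
                depth, frac = 50, 0.5
            spikes_rows.append(
                {"line_id": line_id, "chrom": chrom, "pos": pos, "ref": ref,
                 "alt": alt, "depth": depth, "alt_fraction": frac}
            )

    ancestor_variants = [
        VariantCall("ancestor", r.chrom, r.pos, r.ref, r.alt)
        for r in markers.itertuples()
    ]
    truth = SyntheticTruth(
        config=config,
        events=pd.DataFrame(
            events_rows,
            columns=["line_id", "event_id", "class", "snm_class", "chrom",
                     "pos", "ref", "alt"],
        ),
        per_line_snm_counts=pd.Series(per_line_snm),
        markers=markers,
        dropout=dropout_mat,
        collisions=collisions,
        filtered_spikes=pd.DataFrame(
            spikes_rows,
            columns=["line_id", "chrom", "pos", "ref", "alt", "depth",
                     "alt_fraction"],
        ),
    )
    return SimulatedExperiment(
        line_variants=line_variants,
        ancestor_variants=ancestor_variants,
        truth=truth,
    )


def _place_markers(bundle, config, picker, dir_w, rng) -> pd.DataFrame:
    """Ancestral markers spaced > cluster distance apart, one event each."""
    genome = bundle.genome
    gc, at = config.gc_fraction, 1 - config.gc_fraction
    taken: list[tuple[str, int]] = []
    rows = []
    mid = 0
    spacing = config.cluster_distance + 10
    for cls, n in config.n_markers.items():
        for _ in range(int(n)):
            for _ in range(500):
                i = int(picker.sample(rng, "any")[0])
                chrom, pos, ref = picker.site(i)
                if all(c != chrom or abs(p - pos) > spacing for c, p in taken):
                    break
            taken.append((chrom, pos))
            if cls == "SNM":
                alts, w = dir_w[ref]
                alt = alts[int(rng.choice(len(alts), p=w))]
                ref_a, alt_a = ref, alt
            elif cls == "insertion":
                size = _geometric_size(rng, config.insertion_mean_bp)
                ins = "".join("ACGT"[b] for b in rng.choice(
                    4, size, p=[at / 2, gc / 2, gc / 2, at / 2]))
                ref_a, alt_a = ref, ref + ins
            else:
                size = _geometric_size(rng, config.deletion_mean_bp)
                seq = genome.seqs[chrom]
                if pos + size > len(seq) or (seq[pos : pos + size] >= 4).any():
                    size = 1
                if pos + size > len(seq):
                    continue
                ref_a = ref + decode_sequence(seq[pos : pos + size])
                alt_a = ref
            mid += 1
            rows.append({"marker_id": f"m{mid:04d}", "cls": cls, "chrom": chrom,
                         "pos": pos, "ref": ref_a, "alt": alt_a})
    return pd.DataFrame(rows, columns=["marker_id", "cls", "chrom", "pos",
                                       "ref", "alt"])


def _make_cluster(kind, genome, picker, dir_w, config, rng, used):
    """Build member variants for a double-SNM or complex event."""
    for _ in range(100):
        i = int(picker.sample(rng, "any")[0])
        chrom, pos, ref = picker.site(i)
        seq = genome.seqs[chrom]
        if kind == "double_SNM":
            n_members, with_indel = 2, False
        else:
            n_members = int(rng.integers(3, 6))
            with_indel = bool(rng.random() < 0.5)
        offsets = [0]
        while len(offsets) < n_members:
            o = int(rng.integers(1, config.cluster_distance + 1))
            if o not in offsets:
                offsets.append(o)
        offsets.sort()
        positions = [pos + o for o in offsets]
        if positions[-1] > len(seq):
            continue
        if any((chrom, p) in used for p in positions):
            continue
        if any(seq[p - 1] >= 4 or not genome.mask[chrom][p - 1] for p in positions):
            continue
        members = []
        indel_slot = int(rng.integers(n_members)) if with_indel else -1
        for j, p in enumerate(positions):
            base = "ACGT"[seq[p - 1]]
            if j == indel_slot:
                members.append((chrom, p, base, base + "A"))  # 1-bp insertion
            else:
                alts, w = dir_w[base]
                alt = alts[int(rng.choice(len(alts), p=w))]
                members.append((chrom, p, base, alt))
        for p in positions:
            used.add((chrom, p))
        return members
    return None


# ----------------------------------------------------------------------------
# emission and recovery
# ----------------------------------------------------------------------------


def write_genome_files(bundle: SyntheticGenome, outdir) -> dict:
    """Write FASTA, exclusion BED, annotation TSV, ori and expression tables."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "reference.fa",
        "exclusions": outdir / "exclusions.bed",
        "annotation": outdir / "annotation.tsv",
        "oris": outdir / "oris.tsv",
        "expression": outdir / "expression.tsv",
        "genes": outdir / "genes.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        for name in bundle.genome.names:
            fh.write(f">{name}\n")
            s = decode_sequence(bundle.genome.seqs[name])
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")
    with open(paths["exclusions"], "w") as fh:
        for chrom, s0, e0 in bundle.exclusions:
            fh.write(f"{chrom}\t{s0}\t{e0}\n")
    with open(paths["annotation"], "w") as fh:
        fh.write("# chrom\tstart\tend\tlabel (1-based inclusive)\n")
        for chrom, s, e, label in bundle.feature_intervals:
            fh.write(f"{chrom}\t{s}\t{e}\t{label}\n")
    bundle.ori_table.to_csv(paths["oris"], sep="\t", index=False)
    bundle.expression_table.to_csv(paths["expression"], sep="\t", index=False)
    with open(paths["genes"], "w") as fh:
        fh.write("gene_id\tchrom\tstrand\texons\n")
        for g in bundle.genes:
            blocks = ";".join(f"{s}-{e}" for s, e in g.exons)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{blocks}\n")
    return paths


def write_experiment_vcfs(exp: SimulatedExperiment, bundle: SyntheticGenome,
                          outdir) -> dict:
    """Emit per-line and ancestor VCFs (depth 50, full support; spike-ins
    carry their planted low depth / fraction)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = bundle.genome.chromosome_lengths
    spikes = exp.truth.filtered_spikes
    paths = {}
    for line_id, variants in exp.line_variants.items():
        recs = [VcfRecord(v.chromosome, v.position, v.ref_allele, v.alt_allele)
                for v in variants]
        for row in spikes[spikes["line_id"] == line_id].itertuples():
            recs.append(VcfRecord(row.chrom, row.pos, row.ref, row.alt,
                                  depth=row.depth,
                                  alt_reads=int(round(row.depth * row.alt_fraction))))
        path = outdir / f"{line_id}.vcf"
        write_vcf(path, contigs, recs, sample=line_id)
        paths[line_id] = path
    anc = outdir / "ancestor.vcf"
    write_vcf(
        anc, contigs,
        [VcfRecord(v.chromosome, v.position, v.ref_allele, v.alt_allele)
         for v in exp.ancestor_variants],
        sample="ancestor",
    )
    paths["ancestor"] = anc
    return paths


def recovery_report(truth: SyntheticTruth, estimates: dict) -> pd.DataFrame:
    """Compare estimates {name: (truth_key or value, estimate, se)} to truth.

    Each row gets a z-score (estimate - truth)/se and a |z| <= 2 pass flag
    (a per-parameter check; with many parameters some |z| > 2 are expected
    by chance).
    """
    rows = []
    for name, (true_value, estimate, se) in estimates.items():
        z = (estimate - true_value) / se if se > 0 else float("nan")
        rows.append({"parameter": name, "truth": true_value,
                     "estimate": estimate, "se": se, "z": z,
                     "pass": bool(abs(z) <= 2) if se > 0 else None})
    return pd.DataFrame(rows)
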