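"""Feature enrichment, coding consequences, error rates, and design statistics.

Covers the quality-control side of an MA analysis: are mutations placed at
random with respect to features and chromosomes (they should be, if
selection was ineffective during bottlenecked passaging); what do coding
SNMs do to proteins; how often does the caller miss a known mutation
(false-negative rate from ancestral markers); and how strong can selection
have been given the within-line effective population size of a colony grown
from a single cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from scipy import stats

from .genome import FeatureMap, ReferenceGenome
from .rates import SNM_CLASSES, SpectrumTable, snm_class_of

__all__ = [
    "EnrichmentResult",
    "GeneModel",
    "MarkerMatrix",
    "feature_enrichment",
    "chromosome_distribution_test",
    "consequence_summary",
    "expected_syn_mis_ratio",
    "enumerate_codon_substitution_ratio",
    "false_negative_rate",
    "marker_mutation_probability",
    "generations_from_cells",
    "within_line_ne",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


# ----------------------------------------------------------------------------
# feature / chromosome enrichment
# ----------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    event_class: str
    feature: str
    observed: int
    expected: float
    p: float


def feature_enrichment(events, feature_map: FeatureMap,
                       event_class: str | None = None) -> list[EnrichmentResult]:
    """Fisher's exact test of events in/out of each feature vs bp in/out.

    Expected counts are n_events x genome fraction, so they sum to n_events
    across the three labels.
    """
    if event_class is not None:
        events = [e for e in events if e.event_class == event_class]
    fractions = feature_map.fractions
    bp = {label: feature_map.bp(label) for label in fractions}
    total_bp = sum(bp.values())
    observed = {label: 0 for label in fractions}
    for e in events:
        observed[feature_map.label_at(e.chromosome, e.start)] += 1
    n = sum(observed.values())
    results = []
    for label in ("coding", "intron", "noncoding"):
        obs_in = observed[label]
        table = [
            [obs_in, n - obs_in],
            [bp[label] - obs_in, (total_bp - bp[label]) - (n - obs_in)],
        ]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        results.append(
            EnrichmentResult(
                event_class=event_class or "all",
                feature=label,
                observed=obs_in,
                expected=n * fractions[label],
                p=float(p),
            )
        )
    return results


def chromosome_distribution_test(events, chromosome_lengths: dict,
                                 subset=None) -> dict:
    """Chi-square of per-chromosome event counts vs length-proportional
    expectation; ``subset`` optionally restricts to some chromosomes."""
    chroms = list(subset) if subset else list(chromosome_lengths)
    if len(chroms) < 2:
        raise ValueError("need at least 2 chromosomes")
    counts = {c: 0 for c in chroms}
    for e in events:
        if e.chromosome in counts:
            counts[e.chromosome] += 1
    obs = np.array([counts[c] for c in chroms], dtype=float)
    lengths = np.array([chromosome_lengths[c] for c in chroms], dtype=float)
    expected = obs.sum() * lengths / lengths.sum()
    if (expected < 1).any():
        import warnings

        warnings.warn("expected count below 1 in chromosome test")
    chi2, p = stats.chisquare(obs, expected)
    return {
        "chi2": float(chi2),
        "df": len(chroms) - 1,
        "p": float(p),
        "observed": {c: int(counts[c]) for c in chroms},
        "expected": {c: float(e) for c, e in zip(chroms, expected)},
    }


# ----------------------------------------------------------------------------
# coding consequences
# ----------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A protein-coding gene: ordered CDS exon blocks on one strand.

    ``exons`` are (start, end) 1-based inclusive genomic intervals in
    genomic order; total CDS length must be a multiple of 3.  Introns are
    the gaps between consecutive exons.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def coding_positions(self) -> list[int]:
        """Genomic positions in translation order (reversed on '-')."""
        pos = [p for s, e in self.exons for p in range(s, e + 1)]
        return pos[::-1] if self.strand == "-" else pos


CONSEQUENCE_CLASSES = [
    "synonymous", "missense", "nonsense", "stop_retained", "splice",
]
SPLICE_SITE_NT = 2


def _coding_base(genome: ReferenceGenome, gene: GeneModel, pos: int) -> str:
    b = genome.base_at(gene.chrom, pos)
    return _COMP[b] if gene.strand == "-" else b


def classify_coding_snm(genome: ReferenceGenome, gene: GeneModel,
                        pos: int, ref: str, alt: str) -> str:
    """Consequence of a single-base substitution inside a gene's CDS span."""
    for istart, iend in gene.introns:
        if istart <= pos <= iend:
            if pos - istart < SPLICE_SITE_NT or iend - pos < SPLICE_SITE_NT:
                return "splice"
            return "intronic"
    coding = gene.coding_positions()
    try:
        idx = coding.index(pos)
    except ValueError:
        return "unclassified"
    codon_i = idx // 3
    codon_pos = coding[codon_i * 3 : codon_i * 3 + 3]
    old = "".join(_coding_base(genome, gene, p) for p in codon_pos)
    alt_c = _COMP[alt] if gene.strand == "-" else alt
    ref_c = _COMP[ref] if gene.strand == "-" else ref
    offset = codon_pos.index(pos)
    if old[offset] != ref_c:
        return "unclassified"  # reference mismatch: ambiguous frame/model
    new = old[:offset] + alt_c + old[offset + 1 :]
    old_is_stop = old in STANDARD_TABLE.stop_codons
    new_is_stop = new in STANDARD_TABLE.stop_codons
    if old_is_stop and new_is_stop:
        return "stop_retained"
    if new_is_stop:
        return "nonsense"
    if old_is_stop:
        return "stop_lost"
    if str(Seq(old).translate()) == str(Seq(new).translate()):
        return "synonymous"
    return "missense"


def consequence_summary(events, genes: list[GeneModel],
                        genome: ReferenceGenome) -> dict:
    """Consequence counts for lone-SNM events, plus indel frame classes.

    SNMs: synonymous / missense / nonsense / stop_retained / splice (plus
    intronic, stop_lost, unclassified, and noncoding for events outside any
    gene).  Indels inside CDS: frameshift vs in_frame by length change mod 3.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    def find_gene(chrom, pos):
        for g in by_chrom.get(chrom, []):
            if g.exons[0][0] <= pos <= g.exons[-1][1]:
                return g
        return None

    counts = {c: 0 for c in CONSEQUENCE_CLASSES}
    counts.update({"intronic": 0, "stop_lost": 0, "unclassified": 0,
                   "noncoding": 0, "frameshift": 0, "in_frame": 0})
    for e in events:
        if e.event_class == "SNM":
            v = e.member_variants[0]
            g = find_gene(v.chromosome, v.position)
            if g is None:
                counts["noncoding"] += 1
            else:
                counts[
                    classify_coding_snm(
                        genome, g, v.position, v.ref_allele, v.alt_allele
                    )
                ] += 1
        elif e.event_class in ("insertion", "deletion"):
            v = e.member_variants[0]
            g = find_gene(v.chromosome, v.position)
            if g is None:
                counts["noncoding"] += 1
            elif any(s <= v.position <= en for s, en in g.introns):
                counts["intronic"] += 1
            elif abs(v.length_change) % 3 == 0:
                counts["in_frame"] += 1
            else:
                counts["frameshift"] += 1
    return counts


# ----------------------------------------------------------------------------
# expected synonymous/missense ratio under the observed spectrum
# ----------------------------------------------------------------------------


def _substitution_weights(spectrum: SpectrumTable) -> dict[tuple[str, str], float]:
    """Per-site weight of each of the 12 base changes from conditional rates.

    Each strand-collapsed class covers two directed changes; each gets the
    class's conditional per-site rate.
    """
    w = {}
    for ref in "ACGT":
        for alt in "ACGT":
            if ref == alt:
                continue
            w[(ref, alt)] = spectrum.conditional_rates[snm_class_of(ref, alt)]
    return w


def enumerate_codon_substitution_ratio(codon_freqs: dict,
                                       spectrum: SpectrumTable) -> dict:
    """Exact expected syn/mis ratio by enumerating all single-base changes
    over all codons, weighted by codon frequency and substitution rates."""
    w = _substitution_weights(spectrum)
    tallies = {"synonymous": 0.0, "missense": 0.0, "nonsense": 0.0,
               "stop_lost": 0.0, "stop_retained": 0.0}
    total_freq = sum(codon_freqs.values())
    for codon, freq in codon_freqs.items():
        freq = freq / total_freq
        for i, ref in enumerate(codon):
            for alt in "ACGT":
                if alt == ref:
                    continue
                new = codon[:i] + alt + codon[i + 1 :]
                weight = freq * w[(ref, alt)]
                old_stop = codon in STANDARD_TABLE.stop_codons
                new_stop = new in STANDARD_TABLE.stop_codons
                if old_stop and new_stop:
                    tallies["stop_retained"] += weight
                elif old_stop:
                    tallies["stop_lost"] += weight
                elif new_stop:
                    tallies["nonsense"] += weight
                elif str(Seq(codon).translate()) == str(Seq(new).translate()):
                    tallies["synonymous"] += weight
                else:
                    tallies["missense"] += weight
    tallies["ratio"] = tallies["synonymous"] / tallies["missense"]
    return tallies


def expected_syn_mis_ratio(codon_freqs: dict, spectrum: SpectrumTable,
                           n_sequences: int, seed: int,
                           codons_per_sequence: int = 300,
                           observed_ratio: float | None = None,
                           n_observed: int | None = None) -> dict:
    """Monte-Carlo expected synonymous/missense ratio under the spectrum.

    Generates ``n_sequences`` random coding sequences from ``codon_freqs``
    (stop codons excluded as sense codons), applies one substitution drawn
    with per-site weights from the conditional spectrum, and tallies the
    consequence.  With ``observed_ratio`` (and the observed syn+mis count
    ``n_observed``) a one-sample two-proportion z-test against the expected
    syn fraction is reported.
    """
    if n_sequences < 100:
        raise ValueError("n_sequences must be at least 100")
    rng = np.random.default_rng(seed)
    codons = [c for c in codon_freqs if c not in STANDARD_TABLE.stop_codons]
    probs = np.array([codon_freqs[c] for c in codons], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("degenerate codon source")
    probs /= probs.sum()
    w = _substitution_weights(spectrum)
    base_out = {b: sum(w[(b, a)] for a in "ACGT" if a != b) for b in "ACGT"}
    if all(v == 0 for v in base_out.values()):
        raise ValueError("degenerate spectrum")
    syn = mis = other = 0
    for _ in range(n_sequences):
        seq = "".join(codons[i] for i in rng.choice(len(codons), codons_per_sequence,
                                                    p=probs))
        site_w = np.array([base_out[b] for b in seq])
        site = int(rng.choice(len(seq), p=site_w / site_w.sum()))
        ref = seq[site]
        alts = [a for a in "ACGT" if a != ref]
        aw = np.array([w[(ref, a)] for a in alts])
        alt = alts[int(rng.choice(3, p=aw / aw.sum()))]
        ci = site // 3
        old = seq[ci * 3 : ci * 3 + 3]
        new = old[: site % 3] + alt + old[site % 3 + 1 :]
        if new in STANDARD_TABLE.stop_codons:
            other += 1
        elif str(Seq(old).translate()) == str(Seq(new).translate()):
            syn += 1
        else:
            mis += 1
    ratio = syn / mis if mis else float("inf")
    p_exp = syn / (syn + mis)
    se_mc = math.sqrt(p_exp * (1 - p_exp) / (syn + mis))
    out = {"syn": syn, "mis": mis, "other": other, "ratio": ratio,
           "syn_fraction": p_exp, "mc_se": se_mc}
    if observed_ratio is not None and n_observed is not None:
        p_obs = observed_ratio / (1.0 + observed_ratio)
        z = (p_obs - p_exp) / math.sqrt(p_exp * (1 - p_exp) / n_observed)
        out["z"] = float(z)
        out["p"] = float(2 * stats.norm.sf(abs(z)))
    return out


# ----------------------------------------------------------------------------
# false negatives and design statistics
# ----------------------------------------------------------------------------


@dataclass
class MarkerMatrix:
    """Detection of each ancestral marker (rows) in each line (columns)."""

    detected: pd.DataFrame  # 0/1, index marker_id, columns line ids
    marker_class: pd.Series  # index marker_id -> class name

    @property
    def n_lines(self) -> int:
        return self.detected.shape[1]


def false_negative_rate(matrix: MarkerMatrix, by_class: bool = True) -> dict:
    """Missed-marker fraction: misses / (markers_of_class x lines)."""
    out = {}
    det = matrix.detected
    if by_class:
        for cls in sorted(matrix.marker_class.unique()):
            sub = det.loc[matrix.marker_class == cls]
            total = sub.size
            out[cls] = float((total - sub.values.sum()) / total) if total else 0.0
    out["all"] = float((det.size - det.values.sum()) / det.size) if det.size else 0.0
    return out


def marker_mutation_probability(n_markers: int, n_lines: int, generations: float,
                                mu: float) -> float:
    """Linear-approximation probability that any marker site mutates again
    in any line during the experiment: markers x lines x G x mu."""
    if min(n_markers, n_lines) <= 0 or generations <= 0 or mu < 0:
        raise ValueError("inputs must be positive")
    p = n_markers * n_lines * generations * mu
    if p > 0.1:
        import warnings

        warnings.warn("linear approximation degrades for probability > 0.1")
    return p


def generations_from_cells(colony_cells, transfers: int) -> dict:
    """Total generations from colony cell counts: 2^g cells after g doublings.

    ``colony_cells`` is a sequence (or per-transfer mapping) of cells-per-
    colony measurements; g per transfer is log2(mean cells), and the total is
    mean g x transfers.
    """
    if isinstance(colony_cells, dict):
        gs = []
        for cells in colony_cells.values():
            cells = np.asarray(cells, dtype=float)
            if (cells < 1).any():
                raise ValueError("cells per colony must be >= 1")
            gs.append(math.log2(cells.mean()))
        g = float(np.mean(gs))
    else:
        cells = np.asarray(colony_cells, dtype=float)
        if (cells < 1).any():
            raise ValueError("cells per colony must be >= 1")
        g = math.log2(cells.mean())
    return {"generations_per_transfer": g, "total_generations": g * transfers}


def within_line_ne(g: float) -> dict:
    """Within-line effective size of a colony grown from one cell.

    Harmonic mean of census sizes 2^0 ... 2^(g-1) over one growth cycle:
    Ne = g / sum_{i=0}^{ceil(g)-1} 2^-i.  The reciprocal is the selection-
    coefficient magnitude below which drift dominates.
    """
    if g <= 0:
        raise ValueError("g must be positive")
    ne = g / sum(2.0 ** (-i) for i in range(math.ceil(g)))
    return {"ne": ne, "selection_threshold": 1.0 / ne}
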