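"""Feature/chromosome enrichment, consequences, error rates, design stats."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from maspect.catalog import VariantCall, cluster_and_classify
from maspect.enrichment import (
    GeneModel,
    MarkerMatrix,
    STANDARD_TABLE,
    chromosome_distribution_test,
    classify_coding_snm,
    consequence_summary,
    enumerate_codon_substitution_ratio,
    expected_syn_mis_ratio,
    false_negative_rate,
    feature_enrichment,
    generations_from_cells,
    marker_mutation_probability,
    within_line_ne,
)
from maspect.genome import feature_map_from_intervals
from maspect.rates import SNM_CLASSES, spectrum_from_counts
from conftest import genome_from_seqs


def make_events(positions, ref="A", alt="AT", chrom="c"):
    calls = [VariantCall("L1", chrom, int(p), ref, alt) for p in positions]
    return cluster_and_classify(calls)


class TestFeatureEnrichment:
    @pytest.fixture()
    def fmap(self):
        g = genome_from_seqs({"c": "A" * 100_000})
        intervals = [("c", 1, 57_000, "coding"), ("c", 57_001, 60_000, "intron")]
        return feature_map_from_intervals(intervals, g)

    def test_expected_counts_from_fractions(self, fmap):
        rng = np.random.default_rng(1)
        # 33 indels in coding, 21 in intron, rest noncoding: 335 total
        pos = (
            list(rng.choice(np.arange(1, 57_000, 60), 33, replace=False))
            + list(rng.choice(np.arange(57_001, 60_000, 60), 21, replace=False))
            + list(rng.choice(np.arange(60_001, 100_000, 60), 281, replace=False))
        )
        events = make_events(sorted(pos))
        results = {r.feature: r for r in feature_enrichment(events, fmap)}
        assert results["coding"].expected == pytest.approx(335 * 0.57)
        assert round(results["coding"].expected) == 191
        assert results["intron"].expected == pytest.approx(335 * 0.03)
        assert round(results["intron"].expected) == 10
        assert sum(r.expected for r in results.values()) == pytest.approx(335)
        assert results["coding"].p < 0.001       # 33 observed vs 191 expected
        assert results["noncoding"].p < 0.001

    def test_uniform_placement_not_significant(self, fmap):
        rng = np.random.default_rng(2)
        pos = rng.choice(np.arange(1, 100_000, 60), 300, replace=False)
        events = make_events(sorted(pos))
        results = feature_enrichment(events, fmap)
        assert all(r.p > 0.001 for r in results)

    def test_null_p_calibrated(self, fmap):
        """Under uniform placement the coding-feature Fisher p is not
        anti-conservative: across replicates, p < 0.05 in < 15%."""
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(60):
            pos = rng.choice(np.arange(1, 100_000, 60), 120, replace=False)
            res = {r.feature: r for r in
                   feature_enrichment(make_events(sorted(pos)), fmap)}
            hits += res["coding"].p < 0.05
        assert hits <= 9


class TestChromosomeDistribution:
    LENGTHS = {"cI": 5_580_000, "cII": 4_540_000, "cIII": 2_350_000}

    def test_proportional_counts_give_zero(self):
        events = []
        for chrom, n in (("cI", 558), ("cII", 454), ("cIII", 235)):
            events.extend(make_events(range(100, 100 + 61 * n, 61), chrom=chrom))
        res = chromosome_distribution_test(events, self.LENGTHS)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-9)
        assert res["df"] == 2

    def test_study_scale_insertion_excess(self):
        # 120 insertions, 68 on the 5.58-Mb chromosome of a 12.47-Mb genome
        events = (make_events(range(100, 100 + 61 * 68, 61), chrom="cI")
                  + make_events(range(100, 100 + 61 * 30, 61), chrom="cII")
                  + make_events(range(100, 100 + 61 * 22, 61), chrom="cIII"))
        res = chromosome_distribution_test(events, self.LENGTHS)
        assert res["expected"]["cI"] == pytest.approx(53.7, abs=0.1)
        assert res["p"] < 0.05

    def test_planted_excess_detected(self):
        events = (make_events(range(100, 100 + 61 * 120, 61), chrom="cI")
                  + make_events(range(100, 100 + 61 * 30, 61), chrom="cII")
                  + make_events(range(100, 100 + 61 * 15, 61), chrom="cIII"))
        assert chromosome_distribution_test(events, self.LENGTHS)["p"] < 0.001

    def test_needs_two_chromosomes(self):
        with pytest.raises(ValueError):
            chromosome_distribution_test([], {"c": 100})


def all_sense_codon_gene():
    codons = [c for c in STANDARD_TABLE.forward_table] + \
             list(STANDARD_TABLE.stop_codons)
    seq = "".join(codons)
    genome = genome_from_seqs({"c": seq})
    gene = GeneModel("g1", "c", "+", [(1, len(seq))])
    return genome, gene, codons


class TestConsequences:
    def test_synonymous_third_position(self):
        genome = genome_from_seqs({"c": "CTTAAA"})
        gene = GeneModel("g", "c", "+", [(1, 6)])
        assert classify_coding_snm(genome, gene, 3, "T", "C") == "synonymous"

    def test_missense_and_nonsense(self):
        genome = genome_from_seqs({"c": "CTTAAA"})
        gene = GeneModel("g", "c", "+", [(1, 6)])
        assert classify_coding_snm(genome, gene, 2, "T", "A") == "missense"
        # AAA -> TAA creates a stop
        assert classify_coding_snm(genome, gene, 4, "A", "T") == "nonsense"

    def test_stop_retained(self):
        genome = genome_from_seqs({"c": "ATGTAA"})
        gene = GeneModel("g", "c", "+", [(1, 6)])
        # TAA -> TAG
        assert classify_coding_snm(genome, gene, 6, "A", "G") == "stop_retained"

    def test_splice_site(self):
        genome = genome_from_seqs({"c": "ATGGTAAGTATGTAA"})
        gene = GeneModel("g", "c", "+", [(1, 3), (10, 15)])
        assert classify_coding_snm(genome, gene, 4, "G", "A") == "splice"
        assert classify_coding_snm(genome, gene, 9, "T", "C") == "splice"
        assert classify_coding_snm(genome, gene, 6, "A", "T") == "intronic"

    def test_matches_translation_oracle_forward(self):
        """Every single-base change in every codon agrees with a direct
        six-frame-free translation comparison."""
        genome, gene, codons = all_sense_codon_gene()
        for ci, codon in enumerate(codons):
            for offset, alt in itertools.product(range(3), "ACGT"):
                ref = codon[offset]
                if ref == alt:
                    continue
                pos = ci * 3 + offset + 1
                got = classify_coding_snm(genome, gene, pos, ref, alt)
                new = codon[:offset] + alt + codon[offset + 1 :]
                old_stop = codon in STANDARD_TABLE.stop_codons
                new_stop = new in STANDARD_TABLE.stop_codons
                if old_stop and new_stop:
                    expected = "stop_retained"
                elif old_stop:
                    expected = "stop_lost"
                elif new_stop:
                    expected = "nonsense"
                elif Seq(codon).translate() == Seq(new).translate():
                    expected = "synonymous"
                else:
                    expected = "missense"
                assert got == expected, (codon, offset, alt)

    def test_reverse_strand_agrees_with_forward(self):
        from maspect.genome import revcomp

        fwd_seq = "ATGCTTCCGTAA"
        rev_genome = genome_from_seqs({"c": revcomp(fwd_seq)})
        fwd_genome = genome_from_seqs({"c": fwd_seq})
        n = len(fwd_seq)
        fwd_gene = GeneModel("g", "c", "+", [(1, n)])
        rev_gene = GeneModel("g", "c", "-", [(1, n)])
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for pos in range(1, n + 1):
            ref = fwd_seq[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                f = classify_coding_snm(fwd_genome, fwd_gene, pos, ref, alt)
                r = classify_coding_snm(rev_genome, rev_gene, n - pos + 1,
                                        comp[ref], comp[alt])
                assert f == r

    def test_summary_with_indel_frames(self):
        genome = genome_from_seqs({"c": "ATGCTT" + "A" * 144 + "TAG" + "A" * 150})
        gene = GeneModel("g", "c", "+", [(1, 153)])
        events = cluster_and_classify([
            VariantCall("L", "c", 5, "T", "C"),          # coding SNM
            VariantCall("L", "c", 70, "A", "ATTTTTT"),   # 6-bp in-frame ins
            VariantCall("L", "c", 130, "A", "AT"),       # coding frameshift
            VariantCall("L", "c", 250, "A", "AT"),       # noncoding insertion
        ])
        counts = consequence_summary(events, [gene], genome)
        assert counts["in_frame"] == 1
        assert counts["frameshift"] == 1
        assert counts["noncoding"] == 1
        assert counts["missense"] + counts["synonymous"] == 1


@pytest.fixture(scope="module")
def uniform_spectrum():
    return spectrum_from_counts(dict.fromkeys(SNM_CLASSES, 10), 0.5)


class TestExpectedSynMisRatio:

    def test_mc_matches_enumeration(self, uniform_spectrum):
        freqs = {c: 1.0 for c in STANDARD_TABLE.forward_table}
        exact = enumerate_codon_substitution_ratio(freqs, uniform_spectrum)
        mc = expected_syn_mis_ratio(freqs, uniform_spectrum,
                                    n_sequences=2000, seed=5)
        p_exact = exact["synonymous"] / (exact["synonymous"] + exact["missense"])
        assert mc["syn_fraction"] == pytest.approx(p_exact, abs=4 * mc["mc_se"])

    def test_biased_spectrum_shifts_ratio(self):
        counts = dict.fromkeys(SNM_CLASSES, 0)
        counts["GC>AT_ts"] = 100  # transitions only: more synonymous changes
        ts_only = spectrum_from_counts(counts, 0.5)
        freqs = {c: 1.0 for c in STANDARD_TABLE.forward_table}
        uniform = spectrum_from_counts(dict.fromkeys(SNM_CLASSES, 10), 0.5)
        r_ts = enumerate_codon_substitution_ratio(freqs, ts_only)["ratio"]
        r_uni = enumerate_codon_substitution_ratio(freqs, uniform)["ratio"]
        assert r_ts > r_uni

    def test_study_scale_z_not_significant(self, uniform_spectrum):
        freqs = {c: 1.0 for c in STANDARD_TABLE.forward_table}
        out = expected_syn_mis_ratio(
            freqs, uniform_spectrum, n_sequences=200, seed=1,
            observed_ratio=0.398, n_observed=166,
        )
        assert "z" in out and "p" in out

    def test_degenerate_spectrum_error(self):
        spec = spectrum_from_counts(dict.fromkeys(SNM_CLASSES, 0), 0.5)
        freqs = {c: 1.0 for c in STANDARD_TABLE.forward_table}
        with pytest.raises(ValueError):
            expected_syn_mis_ratio(freqs, spec, n_sequences=100, seed=0)


class TestFalseNegatives:
    def make_matrix(self, n_markers, n_lines, misses):
        det = pd.DataFrame(1, index=[f"m{i}" for i in range(n_markers)],
                           columns=[f"L{j}" for j in range(n_lines)])
        for mi, lj in misses:
            det.iloc[mi, lj] = 0
        cls = pd.Series(["SNM"] * n_markers, index=det.index)
        return MarkerMatrix(detected=det, marker_class=cls)

    def test_no_misses_zero(self):
        m = self.make_matrix(10, 5, [])
        assert false_negative_rate(m)["SNM"] == 0.0

    def test_one_miss_study_scale(self):
        m = self.make_matrix(80, 79, [(3, 7)])
        assert false_negative_rate(m)["SNM"] == pytest.approx(1 / (80 * 79))
        assert false_negative_rate(m)["SNM"] == pytest.approx(1.6e-4, abs=2e-5)

    def test_scale_free(self):
        m1 = self.make_matrix(10, 10, [(0, 0)])
        m2 = self.make_matrix(20, 10, [(0, 0), (11, 5)])
        assert (false_negative_rate(m1)["SNM"]
                == pytest.approx(false_negative_rate(m2)["SNM"]))

    def test_planted_dropout_recovered(self, qc_experiment, qc_config):
        truth = qc_experiment.truth
        det = truth.dropout
        for cls, planted in qc_config.dropout.items():
            sub = det.loc[truth.markers.set_index("marker_id")["cls"] == cls]
            observed = 1 - sub.values.mean()
            n = sub.size
            se = math.sqrt(planted * (1 - planted) / n)
            assert abs(observed - planted) <= 3 * se + 1e-9


class TestDesignStatistics:
    def test_marker_mutation_probability_study_scale(self):
        p = marker_mutation_probability(272, 79, 1952, 1.70e-10)
        assert p == pytest.approx(0.007, abs=2e-4)

    def test_zero_mu(self):
        assert marker_mutation_probability(272, 79, 1952, 0.0) == 0.0

    def test_agrees_with_exact_complement_form(self):
        n, lines, g, mu = 272, 79, 1952, 1.70e-10
        linear = marker_mutation_probability(n, lines, g, mu)
        exact = 1 - (1 - mu) ** (n * lines * g)
        assert linear == pytest.approx(exact, rel=0.01)

    def test_generations_from_cells(self):
        out = generations_from_cells([2 ** 19.52], transfers=100)
        assert out["total_generations"] == pytest.approx(1952.0)
        assert generations_from_cells([1.0], 100)["total_generations"] == 0.0
        out = generations_from_cells([1024.0], 10)
        assert out["generations_per_transfer"] == 10.0

    def test_zero_cells_error(self):
        with pytest.raises(ValueError):
            generations_from_cells([0.5], 10)

    def test_within_line_ne(self):
        assert within_line_ne(1.0)["ne"] == pytest.approx(1.0)
        out = within_line_ne(19.52)
        assert out["ne"] == pytest.approx(9.76, abs=0.01)
        # the study's printed 10.26-cell Ne is consumed as data downstream:
        assert 1 / 10.26 == pytest.approx(0.0975, abs=2e-4)
        assert out["selection_threshold"] == pytest.approx(1 / out["ne"])
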