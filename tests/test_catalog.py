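"""Variant filtering, ancestor subtraction, clustering, classification."""

import numpy as np
import networkx as nx
import pytest

from maspect.catalog import (
    VariantCall,
    annotate_context,
    catalog_summary,
    cluster_and_classify,
    detect_cross_contamination,
    read_variants,
    subtract_ancestor,
)
from maspect.genome import collapse_trinucleotide
from maspect.vcfio import VcfRecord, write_vcf
from conftest import genome_from_seqs


def snm(pos, line="L1", chrom="c", ref="A", alt="G"):
    return VariantCall(line, chrom, pos, ref, alt)


class TestReadVariants:
    @pytest.fixture()
    def vcf(self, tmp_path):
        path = tmp_path / "line.vcf"
        write_vcf(
            path,
            {"chr1": 1000},
            [
                VcfRecord("chr1", 10, "A", "G", depth=3),            # low depth
                VcfRecord("chr1", 20, "A", "G", depth=4, alt_reads=3),  # 0.75
                VcfRecord("chr1", 30, "A", "G", depth=10, alt_reads=7),  # 0.70
                VcfRecord("chr1", 40, "C", "T", depth=50),
                VcfRecord("chr1", 900, "C", "T", depth=50),  # excluded region
            ],
            sample="L1",
        )
        return path

    def test_depth_and_fraction_thresholds_inclusive(self, vcf):
        calls = read_variants(vcf, "L1")
        assert [v.position for v in calls] == [20, 40, 900]

    def test_excluded_region_dropped(self, vcf):
        genome = genome_from_seqs(
            {"chr1": "A" * 1000}, exclude={"chr1": [(850, 1000)]}
        )
        calls = read_variants(vcf, "L1", genome=genome)
        assert [v.position for v in calls] == [20, 40]

    def test_multiallelic_site_split(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
            "##contig=<ID=chr1,length=100>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tL1\n"
            "chr1\t5\t.\tA\tG,T\t.\tPASS\t.\tGT:DP\t1:20\n"
        )
        calls = read_variants(path, "L1")
        assert {(v.position, v.alt_allele) for v in calls} == {(5, "G"), (5, "T")}

    def test_missing_depth_rejected_with_warning(self, tmp_path, caplog):
        path = tmp_path / "nodp.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "##contig=<ID=chr1,length=100>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tL1\n"
            "chr1\t5\t.\tA\tG\t.\tPASS\t.\tGT\t1\n"
        )
        with caplog.at_level("WARNING"):
            calls = read_variants(path, "L1")
        assert calls == []
        assert "no depth" in caplog.text


class TestSubtractAncestor:
    def test_identical_lists_empty(self):
        vs = [snm(10), snm(20)]
        assert subtract_ancestor(vs, vs) == []

    def test_disjoint_lists_unchanged(self):
        line, anc = [snm(10)], [snm(20)]
        assert subtract_ancestor(line, anc) == line

    def test_same_position_different_allele_kept(self):
        line = [snm(10, alt="G")]
        anc = [snm(10, alt="T")]
        assert subtract_ancestor(line, anc) == line

    def test_planted_new_mutations_recovered(self, clean_experiment, qc_experiment):
        exp = qc_experiment
        line_id = sorted(exp.line_variants)[0]
        new = subtract_ancestor(exp.line_variants[line_id], exp.ancestor_variants)
        truth = exp.truth.events[exp.truth.events["line_id"] == line_id]
        assert {(v.chromosome, v.position) for v in new} == set(
            zip(truth["chrom"], truth["pos"])
        )


class TestClusterAndClassify:
    def test_two_snms_within_50_are_double(self):
        events = cluster_and_classify([snm(100), snm(149)])
        assert [e.event_class for e in events] == ["double_SNM"]

    def test_two_snms_beyond_50_are_independent(self):
        events = cluster_and_classify([snm(100), snm(151)])
        assert [e.event_class for e in events] == ["SNM", "SNM"]

    def test_chained_cluster_of_three_is_complex(self):
        vs = [snm(100), VariantCall("L1", "c", 140, "A", "AT"), snm(180)]
        events = cluster_and_classify(vs)
        assert [e.event_class for e in events] == ["complex"]
        assert events[0].n_members == 3

    def test_snm_indel_pair_classified_independently(self):
        vs = [snm(100), VariantCall("L1", "c", 120, "A", "AT")]
        classes = sorted(e.event_class for e in cluster_and_classify(vs))
        assert classes == ["SNM", "insertion"]

    @pytest.mark.parametrize(
        "ref_len,expected", [(2, "deletion"), (50, "medium_deletion"),
                             (51, "medium_deletion"), (1002, "deletion")]
    )
    def test_deletion_size_classes(self, ref_len, expected):
        v = VariantCall("L1", "c", 100, "A" * (ref_len + 1), "A")
        events = cluster_and_classify([v])
        assert events[0].event_class == expected

    def test_medium_deletion_escapes_clustering(self):
        vs = [VariantCall("L1", "c", 100, "A" * 101, "A"), snm(120), snm(130)]
        classes = sorted(e.event_class for e in cluster_and_classify(vs))
        assert classes == ["double_SNM", "medium_deletion"]

    def test_mnp_decomposed_before_clustering(self):
        v = VariantCall("L1", "c", 100, "AC", "GT")
        events = cluster_and_classify([v])
        assert [e.event_class for e in events] == ["double_SNM"]
        assert events[0].snm_changes == [("A", "G"), ("C", "T")]

    def test_order_independence(self):
        rng = np.random.default_rng(3)
        vs = [snm(int(p)) for p in rng.choice(2000, 60, replace=False)]
        ref = cluster_and_classify(vs)
        for _ in range(5):
            rng.shuffle(vs)
            again = cluster_and_classify(list(vs))
            assert [(e.event_class, e.start, e.end) for e in again] == [
                (e.event_class, e.start, e.end) for e in ref
            ]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_connected_components_oracle(self, seed):
        """Single-linkage chaining equals graph connected components with
        edges between same-chromosome variants at distance <= 50."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        positions = rng.choice(5000, size=n, replace=False)
        chroms = rng.choice(["c1", "c2"], size=n)
        vs = [snm(int(p), chrom=c) for p, c in zip(positions, chroms)]
        events = cluster_and_classify(vs)
        g = nx.Graph()
        g.add_nodes_from((v.chromosome, v.position) for v in vs)
        for a in vs:
            for b in vs:
                if a.chromosome == b.chromosome and abs(a.position - b.position) <= 50:
                    g.add_edge((a.chromosome, a.position), (b.chromosome, b.position))
        expected = {
            frozenset(comp) for comp in nx.connected_components(g)
        }
        observed = {
            frozenset((v.chromosome, v.position) for v in e.member_variants)
            for e in events
        }
        assert observed == expected

    def test_every_variant_in_exactly_one_event(self):
        rng = np.random.default_rng(9)
        vs = [snm(int(p)) for p in rng.choice(3000, 100, replace=False)]
        events = cluster_and_classify(vs)
        members = [v for e in events for v in e.member_variants]
        assert sorted(v.position for v in members) == sorted(v.position for v in vs)


class TestAnnotateContext:
    def test_cpg_flag_center_c(self):
        g = genome_from_seqs({"c": "ATCGA"})
        [e] = cluster_and_classify([VariantCall("L1", "c", 3, "C", "A")])
        annotate_context(e, g)
        assert e.contexts == ["CGA"] and e.cpg_flags == [True]
        assert collapse_trinucleotide("TCG") == "CGA"

    def test_cpg_flag_center_g_with_5prime_c(self):
        g = genome_from_seqs({"c": "ATCGA"})
        [e] = cluster_and_classify([VariantCall("L1", "c", 4, "G", "T")])
        annotate_context(e, g)
        assert e.cpg_flags == [True]

    def test_non_cpg(self):
        g = genome_from_seqs({"c": "AACAA"})
        [e] = cluster_and_classify([VariantCall("L1", "c", 3, "C", "T")])
        annotate_context(e, g)
        assert e.contexts == [collapse_trinucleotide("ACA")]
        assert e.cpg_flags == [False]

    def test_chromosome_end_unassigned(self):
        g = genome_from_seqs({"c": "ACGTA"})
        [e] = cluster_and_classify([VariantCall("L1", "c", 1, "A", "G")])
        annotate_context(e, g)
        assert e.contexts == [None]

    def test_flags_match_independent_substring_scan(self, clean_bundle,
                                                    clean_experiment):
        genome = clean_bundle.genome
        truth = clean_experiment.truth.events
        snms = truth[truth["class"] == "SNM"].head(200)
        from maspect.genome import decode_sequence

        checked = 0
        for row in snms.itertuples():
            [e] = cluster_and_classify(
                [VariantCall(row.line_id, row.chrom, row.pos, row.ref, row.alt)]
            )
            annotate_context(e, genome)
            seq = decode_sequence(genome.seqs[row.chrom][row.pos - 2 : row.pos + 1])
            if e.cpg_flags[0] is None:
                continue
            expected = (seq[1] == "C" and seq[2] == "G") or (
                seq[1] == "G" and seq[0] == "C"
            )
            assert e.cpg_flags[0] == expected
            checked += 1
        assert checked > 100


class TestContamination:
    def test_no_shared_mutations_all_retained(self):
        lines = {"a": [snm(10)], "b": [snm(20)]}
        reports, retained = detect_cross_contamination(lines)
        assert retained == {"a", "b"} and reports == []

    def test_one_shared_mutation_drops_one(self):
        lines = {"a": [snm(10, line="a")], "b": [snm(10, line="b")]}
        reports, retained = detect_cross_contamination(lines)
        assert len(retained) == 1
        assert reports[0]["n_shared"] == 1
        assert reports[0]["dropped"] not in retained

    def test_seeded_and_reproducible(self):
        lines = {"a": [snm(10, line="a")], "b": [snm(10, line="b")]}
        _, r1 = detect_cross_contamination(lines, seed=7)
        _, r2 = detect_cross_contamination(lines, seed=7)
        assert r1 == r2

    def test_planted_contaminated_pairs_each_lose_one_line(self):
        rng = np.random.default_rng(0)
        lines = {
            f"L{i:02d}": [snm(int(p), line=f"L{i:02d}")]
            for i, p in enumerate(rng.choice(10000, 24, replace=False))
        }
        # plant sharing in 11 disjoint pairs: contaminate L01 from L00, etc.
        for k in range(11):
            a, b = f"L{2 * k:02d}", f"L{2 * k + 1:02d}"
            lines[b] = [VariantCall(b, "c", lines[a][0].position, "A", "G")]
        reports, retained = detect_cross_contamination(lines)
        assert len(lines) - len(retained) == 11


class TestCatalogSummary:
    def test_empty_catalog_all_zero(self):
        table = catalog_summary([])
        assert (table.to_numpy() == 0).all()

    def test_totals_match_truth(self, clean_experiment):
        exp = clean_experiment
        events = []
        for line_id, vs in exp.line_variants.items():
            events.extend(cluster_and_classify(vs))
        table = catalog_summary(events)
        truth_events = exp.truth.events.drop_duplicates(["line_id", "event_id"])
        collided = {e for _, a, b in exp.truth.collisions for e in (a, b)}
        if not collided:
            truth_counts = truth_events["class"].value_counts()
            for cls in ("SNM", "insertion", "deletion", "double_SNM", "complex"):
                assert table.loc["total", cls] == truth_counts.get(cls, 0)
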