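import io

import numpy as np
import pytest

from varq import QueryEngine, VariantType, query_coverage, query_variants
from varq import fixtures as fx
from varq.importers import (
    AlleleCounts,
    PileupFormatError,
    SortOrderError,
    LoaderConflictError,
    call_variants,
    count_alleles,
    known_formats,
    load_bed_features,
    load_gff_features,
    load_consequences_kv,
    load_pileup,
    load_with_plugin,
    parse_pileup_line,
    register_loader,
    unregister_loader,
)
from conftest import truth_key, variant_key


class TestParseLine:
    def test_basic_fields(self):
        rec = parse_pileup_line("chr1\t100\tA\t5\t..,,.\tIIIII")
        assert (rec.contig, rec.position, rec.ref_base, rec.depth) == ("chr1", 100, "A", 5)
        assert rec.read_bases == "..,,."

    def test_crlf_equals_lf(self):
        a = parse_pileup_line("chr1\t100\tA\t1\t.\tI\r\n")
        b = parse_pileup_line("chr1\t100\tA\t1\t.\tI\n")
        assert a == b

    @pytest.mark.parametrize(
        "line",
        [
            "chr1\t100\tA\t5\t..,,.",  # 5 columns
            "chr1\t100\tA\t5\t..,,.\tIIIII\textra",  # 7 columns (mpileup-style)
            "chr1\tx\tA\t5\t..,,.\tIIIII",
            "chr1\t100\tA\tfive\t..,,.\tIIIII",
        ],
    )
    def test_malformed_lines_rejected(self, line):
        with pytest.raises(PileupFormatError):
            parse_pileup_line(line, line_no=3)


class TestCountAlleles:
    def run(self, bases, ref="A", depth=None):
        depth = depth if depth is not None else len(bases)
        return count_alleles(
            parse_pileup_line(f"chr1\t10\t{ref}\t{depth}\t{bases}\tI" )
        )

    def test_all_ref_marks(self):
        c = self.run("..,,.", depth=5)
        assert c.ref_count == 5 and not c.snv_counts

    def test_caret_consumes_quality_and_case_merges(self):
        # "^~" consumes "~"; the final "." is a ref call; C and c merge
        c = self.run(".C,c.^~.", depth=6)
        assert c.ref_count == 4
        assert dict(c.snv_counts) == {"C": 2}

    def test_indels_attach_to_preceding_call(self):
        c = self.run(".+2AT.,-1c", ref="G", depth=3)
        assert c.ref_count == 3
        assert dict(c.insertion_counts) == {"AT": 1}
        assert dict(c.deletion_counts) == {"c": 1}

    def test_star_occupies_a_read_slot(self):
        c = self.run("..*", depth=3)
        assert c.ref_count == 2 and c.deletion_placeholders == 1
        assert c.tokens == 3

    def test_conservation_violation_names_the_line(self):
        with pytest.raises(PileupFormatError, match="line 7"):
            count_alleles(parse_pileup_line("chr1\t10\tA\t5\t...\tIII", 7), 7)

    def test_fuzz_conservation_over_grammar_valid_strings(self):
        # tokens consumed == depth for 2,000 random grammar-valid strings
        rng = np.random.default_rng(21)
        for _ in range(2000):
            depth = int(rng.integers(1, 40))
            bases = fx.random_read_bases(rng, depth)
            rec = parse_pileup_line(f"chrF\t5\tA\t{depth}\t{bases}\t{'I' * depth}")
            assert count_alleles(rec).tokens == depth


class TestCallVariants:
    def rec(self, depth):
        return parse_pileup_line(f"chr1\t100\tA\t{depth}\t{'.' * depth}\tI")

    def counts(self, **kw):
        c = AlleleCounts()
        for base, n in kw.pop("snv", {}).items():
            c.snv_counts[base] = n
        for s, n in kw.pop("ins", {}).items():
            c.insertion_counts[s] = n
        for s, n in kw.pop("dele", {}).items():
            c.deletion_counts[s] = n
        return c

    def test_threshold_met(self):
        out = call_variants(self.rec(6), self.counts(snv={"C": 2}), 1, "g1")
        assert len(out) == 1
        v = out[0]
        assert (v.ref_allele, v.alt_allele, v.observation_count) == ("A", "C", 2)
        assert v.locus.position == 99  # 1-based file -> 0-based internal

    def test_threshold_unmet(self):
        assert call_variants(self.rec(6), self.counts(snv={"C": 2}), 3, "g1") == []

    def test_colocated_version_order(self):
        out = call_variants(self.rec(6), self.counts(snv={"C": 2, "T": 1}), 1, "g1")
        assert [(v.alt_allele, v.version) for v in out] == [("C", 1), ("T", 2)]

    def test_type_order_snv_insertion_deletion(self):
        out = call_variants(
            self.rec(9),
            self.counts(snv={"G": 1}, ins={"TT": 1}, dele={"ca": 1}),
            1,
            "g1",
        )
        kinds = [v.variant_type for v in out]
        assert kinds == [VariantType.SNV, VariantType.INSERTION, VariantType.DELETION]
        ins, dele = out[1], out[2]
        assert (ins.locus.position, ins.alt_allele) == (99, "TT")
        # deletion starts at the first deleted base; sequence upper-cased
        assert (dele.locus.position, dele.stop, dele.ref_allele) == (100, 102, "CA")

    def test_n_calls_never_become_variants(self):
        assert call_variants(self.rec(3), self.counts(snv={"N": 3}), 1, "g1") == []


class TestLoadPileup:
    def test_empty_stream(self, engine):
        rep = load_pileup(engine, [], "g1")
        assert (rep.lines_read, rep.variants_written, rep.blocks_written) == (0, 0, 0)

    def test_truth_round_trip(self, small_pileup_load):
        engine, truth, report, _ = small_pileup_load
        recovered = {variant_key(v) for v in query_variants(engine, "g1")}
        assert recovered == {truth_key(t) for t in truth.variants}
        assert report.variants_written == len(truth.variants)

    def test_every_covered_base_lands_in_one_block(self, small_pileup_load):
        # brute-force per-base depth oracle from the generator
        engine, truth, _, _ = small_pileup_load
        got = dict(query_coverage(engine, "g1", "chrT:0-5000"))
        assert got == truth.depth_map["chrT"]

    def test_unsorted_input_rejected(self, engine):
        lines = ["chr1\t10\tA\t1\t.\tI", "chr1\t9\tA\t1\t.\tI"]
        with pytest.raises(SortOrderError, match="line 2"):
            load_pileup(engine, lines, "g1")

    def test_reappearing_contig_rejected(self, engine):
        lines = [
            "chr1\t1\tA\t1\t.\tI",
            "chr2\t1\tA\t1\t.\tI",
            "chr1\t2\tA\t1\t.\tI",
        ]
        with pytest.raises(SortOrderError):
            load_pileup(engine, lines, "g1")

    def test_deletion_shares_locus_with_next_line_snv(self, engine):
        # a deletion recorded at line p lands at p+1, where the next line
        # may call an SNV — versions must keep both retrievable
        lines = [
            "chr1\t100\tG\t3\t.-1a..\tIII",
            "chr1\t101\tA\t3\tCC.\tIII",
        ]
        load_pileup(engine, lines, "g1")
        vs = list(query_variants(engine, "g1"))
        at_100 = [v for v in vs if v.locus.position == 100]
        assert {v.variant_type for v in at_100} == {
            VariantType.DELETION,
            VariantType.SNV,
        }
        assert sorted(v.version for v in at_100) == [1, 2]


class TestAnnotationLoaders:
    def test_bed_basic_and_headers_skipped(self, engine):
        stream = [
            "track name=test",
            "browser position chr1",
            "chr1\t10\t20\tpromoter",
            "chr1\t30\t40\tenhancer\t5.5\t-",
        ]
        assert load_bed_features(engine, stream, "g1") == 2
        feats = list(engine.scan_objects("feature", "g1"))
        assert feats[0].locus.position == 10 and feats[0].stop == 20
        assert feats[0].name == "promoter"
        assert feats[1].score == 5.5 and feats[1].strand.value == "-"

    def test_bed_bad_coordinates(self, engine):
        with pytest.raises(ValueError):
            load_bed_features(engine, ["chr1\tten\t20"], "g1")

    def test_gff_coordinate_conversion_and_attributes(self, engine):
        stream = [
            "# a comment",
            "chr1\tsrc\tgene\t1\t1\t.\t+\t.\tID=x;Note=y",
        ]
        assert load_gff_features(engine, stream, "g1") == 1
        f = next(engine.scan_objects("feature", "g1"))
        assert (f.locus.position, f.stop) == (0, 1)
        assert f.tags == {"ID": "x", "Note": "y"}

    def test_gff_wrong_column_count(self, engine):
        with pytest.raises(ValueError, match="line 1"):
            load_gff_features(engine, ["chr1\tsrc\tgene\t1\t10"], "g1")

    def test_consequence_loader_links_to_variant(self, engine):
        load_pileup(engine, ["chr1\t100\tA\t4\tCCcc\tIIII"], "g1")
        n = load_consequences_kv(
            engine, ["chr1\t100\t1\tmissense\tTP53\timpact=high"], "g1"
        )
        assert n == 1
        from varq import query_consequences

        pairs = list(query_consequences(engine, "g1"))
        assert len(pairs) == 1
        c, v = pairs[0]
        assert c.effect == "missense" and v.alt_allele == "C"

    def test_consequence_to_missing_variant_rejected(self, engine):
        engine.store.register_label("g1")
        with pytest.raises(Exception, match="no variant"):
            load_consequences_kv(engine, ["chr1\t100\t1\tmissense\t."], "g1")


class TestPluginRegistry:
    def test_builtins_known(self):
        assert {"pileup", "bed", "gff", "consequence-kv"} <= set(known_formats())

    def test_unknown_format_lists_known(self, engine):
        with pytest.raises(LookupError, match="pileup"):
            load_with_plugin("nope", engine, [], "g1")

    def test_duplicate_registration_conflicts(self):
        with pytest.raises(LoaderConflictError):
            register_loader("bed", lambda e, s, g: 0)

    def test_custom_plugin_round_trips(self, engine):
        # a 5-line custom tab format: contig, pos, name
        from varq.datamodel import Feature, ReferenceLocus

        def load_custom(eng, stream, label):
            n = 0
            for line in stream:
                contig, pos, name = line.split("\t")
                eng.write_feature(
                    Feature(
                        locus=ReferenceLocus(contig, int(pos)),
                        stop=int(pos) + 1,
                        name=name.strip(),
                        genome_label=label,
                    )
                )
                n += 1
            return n

        register_loader("custom-tab", load_custom)
        try:
            lines = [f"chrC\t{i * 10}\tsite{i}\n" for i in range(5)]
            assert load_with_plugin("custom-tab", engine, lines, "g1") == 5
            names = [f.name for f in engine.scan_objects("feature", "g1")]
            assert names == [f"site{i}" for i in range(5)]
        finally:
            unregister_loader("custom-tab")
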