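import io

import numpy as np
import pytest

from varq import (
    ReferenceLocus,
    UnknownGenomeError,
    Variant,
    VariantFilter,
    VariantType,
    export_bed,
    export_wig,
    nonredundant_tags,
    query_consequences,
    query_coverage,
    query_variants,
)
from varq.datamodel import Consequence, CoverageBlock
from varq.importers import load_bed_features
from varq.query_export import RegionParseError, parse_region


def brute_force(written, contig=None, start=None, stop=None, filt=None):
    """In-memory reference implementation of a region+filter query."""
    filt = filt or VariantFilter()
    out = [
        v
        for v in written
        if (contig is None or v.locus.contig == contig)
        and (start is None or start <= v.locus.position < stop)
        and filt.passes(v)
    ]
    out.sort(key=lambda v: (v.locus.contig, v.locus.position, v.version))
    return [v.key for v in out]


def random_filter(rng):
    kw = {}
    if rng.random() < 0.5:
        kw["min_observations"] = int(rng.integers(1, 30))
    if rng.random() < 0.4:
        kw["min_depth"] = int(rng.integers(1, 60))
    if rng.random() < 0.3:
        kw["max_p_value"] = float(rng.random())
    if rng.random() < 0.3:
        kw["variant_types"] = frozenset({VariantType.SNV})
    if rng.random() < 0.4:
        kw["tag"] = ["dbSNP", "genic", "gene", "rare"][int(rng.integers(0, 4))]
        if kw["tag"] == "gene" and rng.random() < 0.5:
            kw["tag_value"] = "TP53"
    return VariantFilter(**kw)


class TestRegionParsing:
    @pytest.mark.parametrize(
        "s,expected",
        [
            ("chr1", ("chr1", None, None)),
            ("chr1:0-100", ("chr1", 0, 100)),
            ("HLA:A-1:5-10", ("HLA:A-1", 5, 10)),
        ],
    )
    def test_valid(self, s, expected):
        assert parse_region(s) == expected

    def test_one_based_conversion(self):
        assert parse_region("chr1:1-100", one_based=True) == ("chr1", 0, 100)

    @pytest.mark.parametrize("s", ["", "chr1:", "chr1:5", "chr1:b-c", "chr1:9-2"])
    def test_malformed(self, s):
        with pytest.raises(RegionParseError):
            parse_region(s)


class TestQueryVariants:
    def test_empty_filter_returns_everything_in_order(self, populated):
        engine, written = populated
        got = [v.key for v in query_variants(engine, "g1")]
        assert got == brute_force(written)

    def test_unknown_genome(self, populated):
        engine, _ = populated
        with pytest.raises(UnknownGenomeError):
            list(query_variants(engine, "genome99"))

    def test_fifty_seeded_random_queries_match_oracle(self, populated):
        engine, written = populated
        rng = np.random.default_rng(77)
        for _ in range(50):
            contig = ["chrA", "chrB"][int(rng.integers(0, 2))]
            a, b = sorted(
                int(x) for x in rng.integers(0, 2_000_000, size=2)
            )
            filt = random_filter(rng)
            region = None if rng.random() < 0.15 else f"{contig}:{a}-{b}"
            got = [v.key for v in query_variants(engine, "g1", region, filt)]
            want = brute_force(
                written,
                contig if region else None,
                a if region else None,
                b if region else None,
                filt,
            )
            assert got == want

    def test_tag_and_field_conjunction_equals_set_intersection(self, populated):
        engine, written = populated
        filt = VariantFilter(tag="dbSNP", min_depth=10)
        got = {v.key for v in query_variants(engine, "g1", filt=filt)}
        tag_only = {v.key for v in written if "dbSNP" in v.tags}
        depth_only = {v.key for v in written if v.depth >= 10}
        assert got == tag_only & depth_only

    def test_tag_routed_equals_scan_routed(self, populated):
        engine, written = populated
        filt = VariantFilter(tag="genic", min_observations=5)
        routed = [v.key for v in query_variants(engine, "g1", filt=filt)]
        # scan route: same clauses applied to a plain scan
        scan = [
            v.key
            for v in query_variants(engine, "g1")
            if filt.passes(v)
        ]
        assert routed == scan


class TestQueryConsequences:
    def test_join_filter_and_dangling(self, engine, caplog):
        from varq.importers import load_pileup

        load_pileup(engine, ["chr1\t50\tA\t10\tCCCCC.....\t" + "I" * 10], "g1")
        locus = ReferenceLocus("chr1", 49)
        engine.write_consequence(
            Consequence(locus, (locus, "g1", 1), "missense", "g1", gene="X")
        )
        dangle = ReferenceLocus("chr1", 60)
        engine.write_consequence(
            Consequence(dangle, (dangle, "g1", 4), "nonsense", "g1")
        )
        pairs = list(query_consequences(engine, "g1"))
        assert len(pairs) == 1  # dangling back-reference skipped with a warning
        assert "dangling" in caplog.text
        # join-then-filter: the variant has obs 5; a stricter filter suppresses
        assert (
            list(
                query_consequences(
                    engine, "g1", filt=VariantFilter(min_observations=6)
                )
            )
            == []
        )


class TestQueryCoverage:
    def seed_blocks(self, engine):
        engine.store.register_label("g1")
        for start, depths in [(0, {97: 2, 98: 4, 99: 6}), (100, {0: 8, 50: 3})]:
            engine.write_coverage_block(
                CoverageBlock(ReferenceLocus("chr1", start), 100, depths, "g1")
            )

    def test_region_straddling_two_blocks(self, engine):
        self.seed_blocks(engine)
        got = list(query_coverage(engine, "g1", "chr1:95-150"))
        assert got == [(97, 2), (98, 4), (99, 6), (100, 8)]

    def test_clipping_and_uncovered_region(self, engine):
        self.seed_blocks(engine)
        assert list(query_coverage(engine, "g1", "chr1:0-50")) == []
        for pos, _ in query_coverage(engine, "g1", "chr1:98-101"):
            assert 98 <= pos < 101

    def test_region_required(self, engine):
        engine.store.register_label("g1")
        with pytest.raises(RegionParseError):
            list(query_coverage(engine, "g1", "chr1"))


class TestExportBed:
    def make_snv(self):
        return Variant(
            locus=ReferenceLocus("chr1", 99),
            stop=100,
            variant_type=VariantType.SNV,
            ref_allele="A",
            alt_allele="C",
            observation_count=2,
            depth=6,
            genome_label="g1",
        )

    def test_coordinates_and_shape(self):
        buf = io.StringIO()
        assert export_bed([self.make_snv()], buf) == 1
        line = buf.getvalue().rstrip("\n")
        cols = line.split("\t")
        assert cols[:3] == ["chr1", "99", "100"]
        assert "A>C" in cols[3] and "obs=2" in cols[3] and "depth=6" in cols[3]

    def test_empty_iterator(self):
        buf = io.StringIO()
        assert export_bed([], buf) == 0
        assert buf.getvalue() == ""

    def test_reimport_round_trips_positions(self, populated, engine):
        src, written = populated
        buf = io.StringIO()
        export_bed(query_variants(src, "g1", "chrA:0-50000"), buf)
        n = load_bed_features(engine, io.StringIO(buf.getvalue()), "g1")
        feats = list(engine.scan_objects("feature", "g1"))
        assert n == len(feats) > 0
        got = sorted((f.locus.position, f.stop) for f in feats)
        want = sorted(
            (v.locus.position, v.stop)
            for v in written
            if v.locus.contig == "chrA" and v.locus.position < 50000
        )
        assert got == want

    def test_deterministic_bytes(self, populated):
        engine, _ = populated
        out = []
        for _ in range(2):
            buf = io.StringIO()
            export_bed(query_variants(engine, "g1", "chrA:0-100000"), buf)
            out.append(buf.getvalue())
        assert out[0] == out[1]


class TestExportWig:
    def test_block_mean_of_2_4_6_is_4(self):
        buf = io.StringIO()
        export_wig(
            [(0, 2), (1, 4), (2, 6)], buf, "chr1", mode="block_average", block_size=3
        )
        header, value = buf.getvalue().splitlines()
        assert header == "fixedStep chrom=chr1 start=1 step=3 span=3"
        assert float(value) == 4.0

    def test_per_base_positions_are_one_based(self):
        buf = io.StringIO()
        export_wig([(10, 5), (11, 7)], buf, "chrZ", mode="per_base")
        lines = buf.getvalue().splitlines()
        assert lines[0] == "fixedStep chrom=chrZ start=11 step=1"
        assert lines[1:] == ["5", "7"]

    def test_gap_starts_new_section(self):
        buf = io.StringIO()
        export_wig([(0, 1), (5, 2)], buf, "c", mode="per_base")
        assert buf.getvalue().count("fixedStep") == 2

    def test_block_average_matches_per_base_mean_oracle(self, small_pileup_load):
        engine, truth, _, _ = small_pileup_load
        bs = engine.store.block_size
        buf = io.StringIO()
        export_wig(
            query_coverage(engine, "g1", "chrT:0-5000"),
            buf, "chrT", mode="block_average", block_size=bs,
        )
        # independent per-base pass over the generator's truth depths
        per_block = {}
        for pos, d in truth.depth_map["chrT"].items():
            per_block.setdefault(pos // bs * bs, []).append(d)
        got = []
        for line in buf.getvalue().splitlines():
            if line.startswith("fixedStep"):
                start = int(dict(p.split("=") for p in line.split()[1:])["start"]) - 1
                step = bs
                nxt = start
            else:
                got.append((nxt, float(line)))
                nxt += step
        want = [
            (b, sum(ds) / len(ds)) for b, ds in sorted(per_block.items())
        ]
        assert len(got) == len(want)
        for (gb, gv), (wb, wv) in zip(got, want):
            assert gb == wb and gv == pytest.approx(wv, abs=5e-6)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            export_wig([(5, 1), (4, 1)], io.StringIO(), "c", mode="per_base")


class TestNonredundantTags:
    def test_union_and_sort(self, populated):
        engine, written = populated
        got = nonredundant_tags(query_variants(engine, "g1"))
        want = sorted({(k, v) for var in written for k, v in var.tags.items()})
        assert got == want

    def test_empty_result(self):
        assert nonredundant_tags([]) == []
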