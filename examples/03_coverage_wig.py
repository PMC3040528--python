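"""Per-base coverage blocks and WIG export.

Coverage is stored sparsely: fixed-width blocks holding only covered
bases.  Queries reconstruct per-base depths for a region; WIG export emits
either one value per base or one mean per block (averaged over covered
bases only — uncovered bases are absent, not zero).
"""

import io
import tempfile

from varq import QueryEngine, export_wig, query_coverage
from varq import fixtures
from varq.importers import load_pileup

ref = fixtures.generate_reference([("chr1", 5_000)], seed=7)
lines, truth = fixtures.generate_pileup(ref, mean_depth=12, snv_rate=0, seed=7)
engine = QueryEngine.create(tempfile.mkdtemp(), "example-ref", block_size=500)
load_pileup(engine, lines, "s1")

cov = list(query_coverage(engine, "s1", "chr1:1000-1010"))
print("depths over chr1:1000-1010 (position, reads):", cov)

buf = io.StringIO()
export_wig(query_coverage(engine, "s1", "chr1:1000-1010"), buf, "chr1")
print("\nper-base WIG (fixedStep starts are 1-based):")
print(buf.getvalue(), end="")

buf = io.StringIO()
export_wig(query_coverage(engine, "s1", "chr1:0-2000"), buf, "chr1",
           mode="block_average", block_size=500)
print("\nblock-averaged WIG, one mean depth per 500 bp block:")
print(buf.getvalue(), end="")
engine.close()
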