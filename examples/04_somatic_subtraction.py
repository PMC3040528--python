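"""Tumor/normal somatic mutation subtraction.

Both genomes load into the same table, so identical variants share a row
and the comparison is row-local: a tumor variant is a putative somatic
mutation when it passes quality thresholds, no normal variant matches it,
and the normal genome was covered deeply enough at the locus to trust the
absence.
"""

import tempfile

from varq import QueryEngine, SomaticCriteria, detect_somatic
from varq import fixtures
from varq.importers import load_pileup

ref = fixtures.generate_reference([("chr9", 50_000)], seed=11)
normal, tumor, truth = fixtures.generate_tumor_normal(
    ref, germline_n=80, somatic_n=20, depth=20, seed=11
)
engine = QueryEngine.create(tempfile.mkdtemp(), "example-ref")
load_pileup(engine, normal, "blood")
load_pileup(engine, tumor, "tumor")

criteria = SomaticCriteria(
    min_tumor_observations=4, min_tumor_fraction=0.1, min_normal_coverage=10
)
calls = list(detect_somatic(engine, "tumor", "blood", criteria))
called = {(c.variant.locus.position, c.variant.alt_allele) for c in calls}
planted = {(t.position, t.alt) for t in truth.somatic_subset}
print(f"planted somatic: {len(planted)}, germline: {len(truth.germline_subset)}")
print(f"called somatic:  {len(called)}  "
      f"(recall {len(called & planted) / len(planted):.2f}, "
      f"precision {len(called & planted) / len(called):.2f})")
c = calls[0]
print(f"example call: chr9:{c.variant.locus.position} "
      f"{c.variant.ref_allele}>{c.variant.alt_allele} "
      f"obs {c.variant.observation_count}/{c.variant.depth}, "
      f"normal depth {c.normal_depth_at_locus} -> {c.status.value}")
engine.close()
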