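import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from varq import QueryEngine, ReferenceLocus, Variant, VariantType
from varq import fixtures as fx

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

TAG_POOL = [("dbSNP", ""), ("genic", ""), ("gene", "TP53"), ("gene", "EGFR"), ("rare", "")]


@pytest.fixture
def engine(tmp_path):
    eng = QueryEngine.create(tmp_path / "store", "test-ref", block_size=100)
    yield eng
    eng.close()


def _random_variant(rng, contigs, label="g1") -> Variant:
    contig, length = contigs[int(rng.integers(0, len(contigs)))]
    pos = int(rng.integers(0, length))
    bases = "ACGT"
    ref = bases[int(rng.integers(0, 4))]
    alt = bases[(bases.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
    r = rng.random()
    if r < 0.8:
        vt, stop, ra, aa = VariantType.SNV, pos + 1, ref, alt
    elif r < 0.9:
        vt, stop, ra, aa = VariantType.INSERTION, pos + 1, "", alt * int(rng.integers(1, 4))
    else:
        vt, stop, ra, aa = VariantType.DELETION, pos + 2, ref + alt, ""
    depth = int(rng.integers(1, 80))
    tags = {}
    for k, v in TAG_POOL:
        if rng.random() < 0.25:
            tags[k] = v
    return Variant(
        locus=ReferenceLocus(contig, pos),
        stop=stop,
        variant_type=vt,
        ref_allele=ra,
        alt_allele=aa,
        observation_count=int(rng.integers(1, depth + 1)),
        depth=depth,
        p_value=None if rng.random() < 0.3 else float(np.round(rng.random(), 6)),
        tags=tags,
        genome_label=label,
    )


@pytest.fixture(scope="session")
def populated(tmp_path_factory):
    """A store holding 10,000 randomly generated variants (two contigs,
    mixed types, random tags/fields) plus the in-memory list of exactly
    what was written — the brute-force oracle universe."""
    root = tmp_path_factory.mktemp("populated")
    eng = QueryEngine.create(root / "store", "oracle-ref", block_size=1000)
    rng = np.random.default_rng(123)
    contigs = [("chrA", 2_000_000), ("chrB", 1_000_000)]
    for name, _ in contigs:
        eng.store.register_contig(name)
    written = []
    with eng.store.bulk():
        for _ in range(10_000):
            v = _random_variant(rng, contigs)
            written.append(eng.write_variant(v))
    yield eng, written
    eng.close()


@pytest.fixture(scope="session")
def small_pileup_load(tmp_path_factory):
    """A 5 kb genome generated at depth 10 with SNVs and indels, loaded at
    threshold 1, together with its truth set."""
    ref = fx.generate_reference([("chrT", 5000)], seed=42)
    lines, truth = fx.generate_pileup(
        ref, mean_depth=10, snv_rate=2e-3, indel_rate=1e-3, seed=42
    )
    eng = QueryEngine.create(
        tmp_path_factory.mktemp("pileup") / "store", "mini-ref", block_size=100
    )
    from varq.importers import load_pileup

    report = load_pileup(eng, lines, "g1")
    yield eng, truth, report, ref
    eng.close()


@pytest.fixture
def wsgi_get():
    def get(app, path, qs=""):
        status = []
        env = {"REQUEST_METHOD": "GET", "PATH_INFO": path, "QUERY_STRING": qs}
        body = b"".join(app(env, lambda s, h: status.append(s)))
        return int(status[0][:3]), body

    return get


def variant_key(v: Variant):
    """Identity of a recovered variant for truth-set comparisons."""
    return (
        v.locus.contig,
        v.locus.position,
        v.variant_type.value,
        v.ref_allele,
        v.alt_allele,
        v.observation_count,
    )


def truth_key(t: fx.TruthVariant):
    return (t.contig, t.position, t.variant_type, t.ref, t.alt, t.observation_count)
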