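# Methods

This note documents the model behind `varq`, the parameters that matter,
the numerical and representational choices made where the design was
genuinely open, what the synthetic-data generator does and does not
emulate, and known limitations.

## Storage model

The engine emulates a BigTable-style table — rows, column families fixed
at creation, dynamic per-genome labels, integer versions per cell — on a
single embedded ordered map. The physical cell key is

    row_key(12 bytes) ∥ family byte ∥ label ∥ NUL ∥ version (u32 BE)

with `row_key = contig_index (u32 BE) ∥ position (u64 BE)`. Because the
row key is fixed-width, the family byte is small, and labels are NUL-free,
bytewise order over these flattened keys equals `(contig, position,
family, label, version)` order, so one B-tree range scan implements region
queries, and a full scan walks the genome in coordinate order. sqlite3
(a `WITHOUT ROWID` table clustered on the key, memcmp BLOB comparison)
provides the ordered map; the store contract documents single-writer use.

Contig names map to dense indices through a dictionary persisted in the
store, in registration order (reference declaration order, or first
appearance during a load). This is the total order on contigs that a
fixed-width key requires; nothing else in the system depends on which
order it is, only that it is stable.

Values are versioned, self-describing JSON; the store treats them as
opaque bytes. All version retention is indefinite — versions are identity
(co-located variants), not history, so nothing is ever garbage-collected.

**Version numbering.** Versions start at 1 and increment in load order per
(locus, genome, family). Pileup calling orders co-located alleles
deterministically — SNVs by base, then insertions, then deletions, each
lexicographic — and the writer re-checks the store at write time, which
matters in one corner: a deletion recorded on line *p* lands at locus
*p+1*, where the next line may independently call an SNV; both survive
under distinct versions.

## Coordinates and alleles

Internal coordinates are 0-based half-open everywhere. Conversions happen
only at I/O boundaries: pileup and WIG are 1-based, BED is already
0-based half-open, GFF is 1-based inclusive. Insertions anchor at the base
they follow (`stop = position + 1`, empty reference allele); deletions are
located at the first deleted base (`stop = position + length`, empty
alternate allele). SNV base calls from reads are merged case-insensitively
(case encodes strand, not identity); indel sequences are tallied verbatim
during tokenization and case-normalized when variants are formed. `N`
calls are tallied (they occupy read slots) but never emitted as variants.

The pileup tokenizer enforces read conservation per line: reference marks
+ mismatch calls + `*` deletion placeholders must equal the depth column
(`^q` and `$` are markers, indels ride on the preceding call). A `*`
occupies a read slot but produces no variant — the deletion it belongs to
was recorded on its anchoring line.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `min_observations` (load) | 1 | reads | load everything observed at least once; filter at query time, not load time |
| `block_size` | 1000 | bases | coverage-block width; storage/lookup granularity trade-off, persisted per store |
| `min_tumor_observations` | 4 | reads | somatic quality floor; explicit stand-in, user-specified by design |
| `min_tumor_fraction` | 0.1 | fraction | alt reads / depth in the tumor |
| `min_normal_coverage` | 10 | reads | minimum normal depth for "absent from normal" to be trusted |
| `max_p_value` | unset | probability | optional call-quality bound; a variant with no recorded p-value fails the bound (unknown cannot certify) |

All four somatic thresholds are exposed on the CLI; they are defaults, not
recommendations — the subtraction is deliberately parameter-driven.

## Queries

Filter clauses combine by conjunction. A tag clause routes execution
through the secondary index (prefix scan on `tag ∥ NUL`), then resolves
locators against the primary table and applies the remaining clauses
client-side; the index keys only on tag *keys*, so tag-value filtering is
always client-side. Index-routed and scan-routed execution are required to
return identical results (tested). Locators whose object has been deleted
are skipped with a warning, not an error — deletion support is minimal.

Coverage block averages are means over **covered bases only**. Uncovered
bases are unstored; dividing by the block width instead would silently
change values wherever coverage has gaps, so the choice is stated here
prominently.

The map-reduce traversal is an in-process contract, not a runtime: pure
map over `(row_key, cells)`, grouping by emitted key with values in
emission order, pure reduce per key, result independent of how the row
stream is partitioned. The property tests pin exactly this contract,
including order-sensitive reduce functions.

## Somatic subtraction

"Present in the normal" means a normal-genome variant with the same type,
alleles and span at the same locus, at **any** observation count — the
normal loads unfiltered precisely so that single-read germline evidence
can veto a call. The reduce phase checks normal coverage at each surviving
locus from the coverage blocks and only reports calls where that depth
reaches `min_normal_coverage`; rejected candidates carry one of three
rejection statuses and are reported only on request.

Translocations are stored one record per breakend, the mate named in a
`mate` tag; the two-breakend-one-record alternative would break the
position-keyed row model.

## Synthetic data

The generator emits per-position evidence, not reads: depths are Poisson
around `mean_depth` (zero-depth positions absent, as in real pileup;
planted positions floored at 2 so the allele is observable), planted
alleles get roughly heterozygous support (binomial, floored at the
requested minimum), error alleles are injected per read slot at
`error_rate`, drawn uniformly from the non-reference (and non-planted)
bases, and logged allele-by-allele. Read start/end markers are sprinkled
in to exercise the grammar. Everything derives from one seeded numpy
generator, so output is byte-identical for fixed (parameters, seed).

Tumor/normal pairs plant `germline_n` SNVs in both genomes and
`somatic_n` SNVs in the tumor only, at separated loci, with tumor support
forced over the default detector thresholds and normal depth at somatic
loci forced to `normal_depth_floor` (default 10) — so on noise-free pairs
detector precision and recall against the planted set are exactly 1.0 by
construction, which is what makes the subtraction testable end to end.

What this does **not** emulate: read lengths and read-level correlation,
mapping ambiguity, strand bias, quality-score/error correlation, indel
realignment artifacts, contamination, or copy number. Passing tests
demonstrate that storage, indexing, querying and subtraction are exact
over the data model; they say nothing about calling accuracy on real
sequencing data, which depends on upstream alignment and calling.

## Problem sizes

The shipped checks run at deliberate desk scale: a 100 kb genome at mean
depth 20 (~100 planted variants) for round-trip and coverage fidelity; a
10,000-variant two-contig store for query/oracle and index checks; a
200-germline / 50-somatic pair for the subtraction; 10,000 fuzz lines for
grammar conservation; and a one-million-variant bulk load plus full-table
export as the capacity pass, which exercises the same linear-scan export
path at three orders of magnitude above the fixtures.

## Known limitations

- Single process, single writer; no compaction, replication or sharding.
- Consequences are loaded (pre-computed annotations), never predicted.
- No VCF import/export; no BAM/SAM parsing (pileup text only, classic
  6-column single-sample — mpileup multi-sample rows are rejected).
- The tag index is key-only; numeric fields filter by scan.
- Base qualities are stored with records but unused by calling; filtering
  is a query-time concern.
- HTTP service: localhost, no auth, offset/limit paging only; the XML
  schema is minimal and versioned, not standardized.
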