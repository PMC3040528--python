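# varq — a desk-scale genomic variant query engine

`varq` stores and searches sequence-derived data — variants (SNVs, indels,
structural variants, translocations), per-base coverage, generic genomic
features, and coding consequences — for many genomes at once, and answers
region, field and annotation queries over them. It is aimed at people who
have per-position variant evidence for a handful of genomes (for example a
tumor/normal pair called "everything observed once or more") and want a
queryable database, BED/WIG tracks, and cross-genome analyses without
setting up any database server.

## The data model

The store is a BigTable-style column-family key-value table, flattened onto
an embedded ordered map (sqlite3 B-tree over byte keys):

- **Row key** — an order-preserving fixed-width encoding of
  *(contig index, 0-based position)*, so a bytewise range scan is a genomic
  region scan and a full scan is a whole-genome walk in coordinate order.
- **Column families** — `variant`, `coverage`, `feature`, `consequence`,
  fixed at table creation.
- **Labels** — one per genome (e.g. `variant:genome7`), added as genomes
  load. Identical variants of different genomes therefore share a row,
  which makes cross-genome comparison a row-local operation.
- **Versions** — integers ≥ 1 distinguishing co-located values at one
  row/family/label, i.e. several variant alleles of one genome at one
  locus.
- **Secondary tag index** — a per-genome table keyed by
  `tag ∥ NUL ∥ object-id` whose values locate primary-table rows, so
  tag queries (dbSNP membership, gene names, …) never scan the main table.

Per-base depths are packed into fixed-width **coverage blocks** (sparse
maps over a window, default 1000 bases); uncovered bases are absent, never
stored as zero.

On top of this sit: a classic SAMtools pileup loader (full base-string
grammar: `. , ACGTN ^q $ +n⟨seq⟩ -n⟨seq⟩ *`, with a read-conservation
check per line), BED/GFF/key-value loaders behind a plugin registry,
filtered queries with BED/WIG export, a map-reduce-style traversal used by
the variant-type counter and the tumor/normal somatic detector, and a
stateless HTTP interface where every query is a bookmarkable URL.

A tumor variant is reported as a **putative somatic mutation** when it
passes the user's quality thresholds (supporting reads, allele fraction,
optional p-value), no normal-genome variant with the same type and alleles
exists at the locus, and the normal genome's coverage there reaches a
minimum — so "absent from the normal" is only trusted where it was
observable.

## Worked example

```sh
$ varq fixtures make --out fx --contigs chr20:20000 --mean-depth 20 \
      --snv-rate 0.002 --seed 42
$ varq load pileup fx/sample.pileup --store db --genome sampleA
lines=20000 variants=44 blocks=20
$ varq query variants --store db --genome sampleA \
      --region chr20:0-20000 --filter minObs=5 --format bed | head -3
chr20	740	741	SNV:T>A:obs=9:depth=22:v=1
chr20	743	744	SNV:C>G:obs=11:depth=25:v=1
chr20	1158	1159	SNV:C>G:obs=7:depth=21:v=1
```

Each BED line is a variant: chromosome, 0-based half-open span, then
type, ref>alt alleles, supporting reads / total depth, and the version
that separates co-located calls. The same query over HTTP
(`varq serve --store db` then
`GET /genomes/sampleA/variants?region=chr20:0-20000&filter.minObs=5&format=bed`)
returns byte-identical output.

Somatic subtraction on a synthetic pair (from
`examples/04_somatic_subtraction.py`):

```
planted somatic: 20, germline: 80
called somatic:  20  (recall 1.00, precision 1.00)
example call: chr9:1432 G>T obs 11/19, normal depth 18 -> PUTATIVE_SOMATIC
```

The `examples/` directory has one short script per capability: loading and
querying, the tag index, coverage/WIG export, somatic subtraction, and the
web service.

## Scope notes

Single-process, single-writer, desk scale: no sharding, replication or
cluster runtime — the schema and traversal semantics are what scale-out
systems provide, pinned down here in an embedded form. No alignment, no
genotype-likelihood models, no VCF import; see `docs/methods.md` for the
model, parameter and design details.
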