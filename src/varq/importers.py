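"""Load pileup, BED, GFF and key-value annotation files into the store.

The workhorse is the classic 6-column single-sample pileup (chrom, 1-based
position, reference base, depth, read-bases string, base qualities).  The
read-bases string is a small grammar:

    . ,            match to the reference (forward / reverse strand)
    ACGTN acgtn    mismatch — an alternate base call
    ^q             start of a read segment; the next character is the
                   mapping quality and is consumed, not a base call
    $              end of a read segment, consumed
    +n<seq> -n<seq> an insertion / deletion of n bases attached to the
                   immediately preceding base call
    *              placeholder within a deletion span (the deletion itself
                   was recorded on the anchoring base's line)

Tokenizing must conserve reads: base calls consumed == the depth column,
which is the consistency check applied to every line.

Every variant observed at least ``min_observations`` times (default 1 —
load everything, sequencing errors included, and filter at query time) is
written through the generic store interface and tag-indexed; per-base
depths are packed into fixed-width coverage blocks.

A plugin registry lets new annotation formats be added without touching
this module; the built-in loaders register themselves under "pileup",
"bed", "gff" and "consequence-kv".
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, TextIO

from .datamodel import (
    Consequence,
    ContractError,
    CoverageBlock,
    Feature,
    ReferenceLocus,
    Strand,
    Variant,
    VariantType,
)
from .engine import QueryEngine

log = logging.getLogger(__name__)


class PileupFormatError(ValueError):
    """A line that does not parse as classic 6-column pileup."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        where = f" (line {line_no})" if line_no is not None else ""
        super().__init__(message + where)


class TokenConservationError(PileupFormatError):
    """Base calls tokenized from read_bases disagree with the depth column."""


class SortOrderError(ValueError):
    """Pileup input not sorted by (contig, position)."""


@dataclass
class PileupRecord:
    contig: str
    position: int  # 1-based, as in the file
    ref_base: str
    depth: int
    read_bases: str
    base_qualities: str


@dataclass
class AlleleCounts:
    """Per-allele observation counts for one pileup line.

    SNV calls are merged case-insensitively (case only encodes read strand);
    indel sequences are kept exactly as written.  ``deletion_placeholders``
    counts ``*`` tokens, which occupy a read slot inside a deletion span but
    carry no allele of their own, so read conservation is
    ``ref_count + sum(snv_counts) + deletion_placeholders == depth``.
    """

    ref_count: int = 0
    snv_counts: Counter = field(default_factory=Counter)
    insertion_counts: Counter = field(default_factory=Counter)
    deletion_counts: Counter = field(default_factory=Counter)
    deletion_placeholders: int = 0

    @property
    def tokens(self) -> int:
        return self.ref_count + sum(self.snv_counts.values()) + self.deletion_placeholders


def parse_pileup_line(line: str, line_no: int | None = None) -> PileupRecord:
    """Split one classic pileup line into its six raw columns."""
    fields = line.rstrip("\r\n").split("\t")
    if len(fields) != 6:
        raise PileupFormatError(
            f"expected 6 tab-separated pileup columns, got {len(fields)}", line_no
        )
    contig, pos_s, ref, depth_s, bases, quals = fields
    try:
        position = int(pos_s)
    except ValueError:
        raise PileupFormatError(f"non-integer position {pos_s!r}", line_no) from None
    try:
        depth = int(depth_s)
    except ValueError:
        raise PileupFormatError(f"non-integer depth {depth_s!r}", line_no) from None
    if len(ref) != 1:
        raise PileupFormatError(f"reference column must be one base, got {ref!r}", line_no)
    if position < 1:
        raise PileupFormatError(f"pileup positions are 1-based, got {position}", line_no)
    return PileupRecord(contig, position, ref, depth, bases, quals)


_SNV_CHARS = set("ACGTNacgtn")


def count_alleles(rec: PileupRecord, line_no: int | None = None) -> AlleleCounts:
    """Tokenize the read-bases string and tally observations per allele."""
    s = rec.read_bases
    counts = AlleleCounts()
    i, n = 0, len(s)
    while i < n:
        c = s[i]
        if c == "^":
            if i + 1 >= n:
                raise PileupFormatError("'^' at end of read-bases string", line_no)
            i += 2  # '^' plus the mapping-quality character
        elif c == "$":
            i += 1
        elif c in ".,":
            counts.ref_count += 1
            i += 1
        elif c in _SNV_CHARS:
            counts.snv_counts[c.upper()] += 1
            i += 1
        elif c == "*":
            counts.deletion_placeholders += 1
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and s[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupFormatError(f"indel marker {c!r} without a length", line_no)
            length = int(s[i + 1 : j])
            seq = s[j : j + length]
            if len(seq) < length:
                raise PileupFormatError("truncated indel sequence", line_no)
            if c == "+":
                counts.insertion_counts[seq] += 1
            else:
                counts.deletion_counts[seq] += 1
            i = j + length
        else:
            raise PileupFormatError(f"unexpected character {c!r} in read bases", line_no)
    if counts.tokens != rec.depth:
        raise TokenConservationError(
            f"tokenized {counts.tokens} base calls but depth column says {rec.depth}",
            line_no,
        )
    return counts


def _merge_upper(counter: Counter) -> dict[str, int]:
    merged: Counter = Counter()
    for seq, cnt in counter.items():
        merged[seq.upper()] += cnt
    return dict(merged)


def call_variants(
    rec: PileupRecord,
    counts: AlleleCounts,
    min_observations: int = 1,
    genome_label: str = "genome",
) -> list[Variant]:
    """Turn allele counts into Variant records (1-based file position becomes
    the internal 0-based locus).

    One variant per alternate allele meeting the observation threshold, in
    deterministic order — SNVs by base, then insertions, then deletions,
    each lexicographic — with versions numbered per locus in that order.
    Insertions anchor at the pileup base; deletions start at the following
    base (the first base actually deleted).  Indel allele sequences are
    upper-cased (strand-case merged) at this point; 'N' calls are tallied
    but never emitted as variants.
    """
    pos0 = rec.position - 1
    ref = rec.ref_base.upper()
    out: list[Variant] = []
    versions: Counter = Counter()

    def nxt(locus: ReferenceLocus) -> int:
        versions[locus] += 1
        return versions[locus]

    for base in sorted(counts.snv_counts):
        obs = counts.snv_counts[base]
        if base == "N" or base == ref or obs < min_observations:
            continue
        locus = ReferenceLocus(rec.contig, pos0)
        out.append(
            Variant(
                locus=locus,
                stop=pos0 + 1,
                variant_type=VariantType.SNV,
                ref_allele=ref,
                alt_allele=base,
                observation_count=obs,
                depth=rec.depth,
                genome_label=genome_label,
                version=nxt(locus),
            )
        )
    for seq, obs in sorted(_merge_upper(counts.insertion_counts).items()):
        if obs < min_observations:
            continue
        locus = ReferenceLocus(rec.contig, pos0)
        out.append(
            Variant(
                locus=locus,
                stop=pos0 + 1,
                variant_type=VariantType.INSERTION,
                ref_allele="",
                alt_allele=seq,
                observation_count=obs,
                depth=rec.depth,
                genome_label=genome_label,
                version=nxt(locus),
            )
        )
    for seq, obs in sorted(_merge_upper(counts.deletion_counts).items()):
        if obs < min_observations:
            continue
        locus = ReferenceLocus(rec.contig, pos0 + 1)
        out.append(
            Variant(
                locus=locus,
                stop=pos0 + 1 + len(seq),
                variant_type=VariantType.DELETION,
                ref_allele=seq,
                alt_allele="",
                observation_count=obs,
                depth=rec.depth,
                genome_label=genome_label,
                version=nxt(locus),
            )
        )
    return out


@dataclass
class LoadReport:
    lines_read: int = 0
    variants_written: int = 0
    blocks_written: int = 0


def load_pileup(
    engine: QueryEngine,
    stream: Iterable[str],
    genome_label: str,
    min_observations: int = 1,
    block_size: int | None = None,
) -> LoadReport:
    """Stream a sorted pileup file into the store.

    Variants go to the variant family (tag-indexed, versions assigned at
    write time so they stay correct when an earlier line's deletion already
    occupies a locus); every base with depth >= 1 lands in exactly one
    coverage block.  Input must be sorted by (contig, position); the first
    out-of-order line aborts the load.
    """
    bs = block_size or engine.store.block_size
    report = LoadReport()
    seen_contigs: set[str] = set()
    cur_contig: str | None = None
    last_pos = -1
    blk_start = -1
    blk_depths: dict[int, int] = {}

    def flush_block() -> None:
        nonlocal blk_depths
        if blk_depths and cur_contig is not None:
            engine.write_coverage_block(
                CoverageBlock(
                    locus=ReferenceLocus(cur_contig, blk_start),
                    block_size=bs,
                    depths=blk_depths,
                    genome_label=genome_label,
                )
            )
            report.blocks_written += 1
        blk_depths = {}

    with engine.store.bulk():
        for line_no, line in enumerate(stream, start=1):
            if not line.strip():
                continue
            report.lines_read += 1
            rec = parse_pileup_line(line, line_no)
            if rec.contig != cur_contig:
                if rec.contig in seen_contigs:
                    raise SortOrderError(
                        f"contig {rec.contig!r} reappears out of order at line {line_no}"
                    )
                flush_block()
                seen_contigs.add(rec.contig)
                cur_contig = rec.contig
                last_pos = -1
                blk_start = -1
            pos0 = rec.position - 1
            if pos0 <= last_pos:
                raise SortOrderError(
                    f"position {rec.position} at line {line_no} not after previous"
                )
            last_pos = pos0
            counts = count_alleles(rec, line_no)
            for v in call_variants(rec, counts, min_observations, genome_label):
                engine.write_variant(v, assign_version=True)
                report.variants_written += 1
            if rec.depth >= 1:
                start = (pos0 // bs) * bs
                if start != blk_start:
                    flush_block()
                    blk_start = start
                blk_depths[pos0 - start] = rec.depth
        flush_block()
    return report


# -- annotation loaders ----------------------------------------------------


def load_bed_features(
    engine: QueryEngine, stream: Iterable[str], genome_label: str
) -> int:
    """Load BED3+ lines as features (BED is already 0-based half-open).

    ``track``/``browser`` headers and comments are skipped; the name column,
    when present, also becomes a tag so features are findable by name
    through the secondary index.
    """
    count = 0
    with engine.store.bulk():
        for line_no, line in enumerate(stream, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"BED line {line_no}: fewer than 3 columns")
            try:
                start, stop = int(cols[1]), int(cols[2])
            except ValueError:
                raise ValueError(
                    f"BED line {line_no}: non-integer coordinates {cols[1]!r}/{cols[2]!r}"
                ) from None
            name = cols[3] if len(cols) > 3 else f"feature{line_no}"
            score = None
            if len(cols) > 4 and cols[4] not in (".", ""):
                score = float(cols[4])
            strand = Strand.UNKNOWN
            if len(cols) > 5 and cols[5] in ("+", "-"):
                strand = Strand(cols[5])
            tags = {name: ""} if len(cols) > 3 else {}
            engine.write_feature(
                Feature(
                    locus=ReferenceLocus(cols[0], start),
                    stop=stop,
                    name=name,
                    score=score,
                    strand=strand,
                    tags=tags,
                    genome_label=genome_label,
                )
            )
            count += 1
    return count


def load_gff_features(
    engine: QueryEngine, stream: Iterable[str], genome_label: str
) -> int:
    """Load 9-column GFF; 1-based inclusive coordinates become 0-based
    half-open, and the attributes column becomes the tag map."""
    count = 0
    with engine.store.bulk():
        for line_no, line in enumerate(stream, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"GFF line {line_no}: expected 9 tab-separated columns, got {len(cols)}"
                )
            seqid, _source, ftype, start_s, end_s, score_s, strand_s, _frame, attrs = cols
            start = int(start_s) - 1
            stop = int(end_s)  # inclusive end == half-open stop
            tags: dict[str, str] = {}
            for item in attrs.split(";"):
                item = item.strip()
                if not item:
                    continue
                if "=" in item:
                    k, _, v = item.partition("=")
                elif " " in item:
                    k, _, v = item.partition(" ")
                    v = v.strip('"')
                else:
                    k, v = item, ""
                tags[k.strip()] = v
            engine.write_feature(
                Feature(
                    locus=ReferenceLocus(seqid, start),
                    stop=stop,
                    name=tags.get("ID", ftype),
                    score=None if score_s == "." else float(score_s),
                    strand=Strand(strand_s) if strand_s in ("+", "-") else Strand.UNKNOWN,
                    tags=tags,
                    genome_label=genome_label,
                )
            )
            count += 1
    return count


def load_consequences_kv(
    engine: QueryEngine, stream: Iterable[str], genome_label: str
) -> int:
    """Simple key-value consequence loader.

    Tab-separated: contig, 1-based position, variant version, effect, gene
    ('.' for none), then optional ``key=value`` tag columns.  Each line must
    back-reference a variant already stored for the genome; consequence
    *prediction* is out of scope — this loads pre-computed annotations.
    """
    count = 0
    with engine.store.bulk():
        for line_no, line in enumerate(stream, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ValueError(f"consequence line {line_no}: need >= 5 columns")
            contig, pos_s, ver_s, effect, gene = cols[:5]
            locus = ReferenceLocus(contig, int(pos_s) - 1)
            ref = (locus, genome_label, int(ver_s))
            if engine.resolve_variant(ref) is None:
                raise ContractError(
                    f"consequence line {line_no}: no variant at "
                    f"{contig}:{pos_s} version {ver_s} in {genome_label!r}"
                )
            tags: dict[str, str] = {}
            for item in cols[5:]:
                k, _, v = item.partition("=")
                tags[k] = v
            engine.write_consequence(
                Consequence(
                    locus=locus,
                    variant_ref=ref,
                    effect=effect,
                    gene=None if gene == "." else gene,
                    tags=tags,
                    genome_label=genome_label,
                )
            )
            count += 1
    return count


# -- plugin registry -------------------------------------------------------

Loader = Callable[[QueryEngine, Iterable[str], str], object]

_LOADERS: dict[str, Loader] = {}


class LoaderConflictError(ValueError):
    """A format name registered twice."""


def register_loader(format_name: str, loader: Loader) -> None:
    """Make a loader discoverable by name.  The loader contract: callable
    (engine, text stream, genome_label) -> summary (count or report), all
    persistence via the generic store interface."""
    if format_name in _LOADERS:
        raise LoaderConflictError(f"loader {format_name!r} already registered")
    _LOADERS[format_name] = loader


def unregister_loader(format_name: str) -> None:
    _LOADERS.pop(format_name, None)


def known_formats() -> list[str]:
    return sorted(_LOADERS)


def load_with_plugin(
    format_name: str, engine: QueryEngine, stream: Iterable[str], genome_label: str
):
    try:
        loader = _LOADERS[format_name]
    except KeyError:
        raise LookupError(
            f"unknown format {format_name!r}; known formats: {known_formats()}"
        ) from None
    return loader(engine, stream, genome_label)


register_loader("pileup", load_pileup)
register_loader("bed", load_bed_features)
register_loader("gff", load_gff_features)
register_loader("consequence-kv", load_consequences_kv)
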