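"""Region/field/tag queries over the store and BED/WIG serialization.

Queries are expressed as a region (``contig:start-stop``, half-open, or a
bare contig, or whole-genome), a genome label, and a :class:`VariantFilter`
whose clauses combine by conjunction.  Plain queries run as ordered range
scans; a tag clause routes through the secondary index first and applies
the remaining clauses client-side — both routes return identical results.

Exports: BED for variants (0-based half-open, metadata packed into the name
field), WIG for coverage (1-based fixedStep), per-base or averaged per
coverage block.  Block averages are over *covered* bases only — uncovered
bases are unstored, not zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

from . import tag_index
from .codec import decode_object
from .datamodel import Consequence, Variant, VariantType, variant_id
from .engine import QueryEngine

log = logging.getLogger(__name__)


class RegionParseError(ValueError):
    pass


def parse_region(region: str, one_based: bool = False) -> tuple[str, int | None, int | None]:
    """Parse ``contig`` or ``contig:start-stop`` (internally 0-based
    half-open; with ``one_based`` the string is 1-based inclusive, the
    browser convention, and is converted)."""
    if not region:
        raise RegionParseError("empty region string")
    if ":" not in region:
        return region, None, None
    contig, _, span = region.rpartition(":")
    if not contig or "-" not in span:
        raise RegionParseError(f"malformed region {region!r}")
    start_s, _, stop_s = span.partition("-")
    try:
        start, stop = int(start_s), int(stop_s)
    except ValueError:
        raise RegionParseError(f"non-integer bounds in region {region!r}") from None
    if one_based:
        start -= 1
    if start < 0 or stop < start:
        raise RegionParseError(f"invalid bounds in region {region!r}")
    return contig, start, stop


@dataclass
class VariantFilter:
    """Conjunction of optional per-field constraints; empty filter passes all.

    When ``max_p_value`` is set, variants with no recorded p-value fail the
    clause (an unknown p-value cannot certify the bound).
    """

    min_observations: int | None = None
    min_depth: int | None = None
    max_p_value: float | None = None
    variant_types: frozenset[VariantType] | None = None
    tag: str | None = None
    tag_value: str | None = None

    def passes(self, v: Variant) -> bool:
        if self.min_observations is not None and v.observation_count < self.min_observations:
            return False
        if self.min_depth is not None and v.depth < self.min_depth:
            return False
        if self.max_p_value is not None and (
            v.p_value is None or v.p_value > self.max_p_value
        ):
            return False
        if self.variant_types is not None and v.variant_type not in self.variant_types:
            return False
        if self.tag is not None:
            if self.tag not in v.tags:
                return False
            if self.tag_value is not None and v.tags[self.tag] != self.tag_value:
                return False
        return True


EMPTY_FILTER = VariantFilter()


def query_variants(
    engine: QueryEngine,
    genome_label: str,
    region: str | None = None,
    filt: VariantFilter | None = None,
    one_based: bool = False,
) -> Iterator[Variant]:
    """Stored variants of one genome in (contig, position, version) order,
    restricted to the region and passing every filter clause."""
    filt = filt or EMPTY_FILTER
    engine.store.require_label(genome_label)
    contig = start = stop = None
    if region is not None:
        contig, start, stop = parse_region(region, one_based)
    if filt.tag is not None:
        yield from _query_variants_by_tag(engine, genome_label, contig, start, stop, filt)
        return
    for v in engine.scan_objects("variant", genome_label, contig, start, stop):
        if filt.passes(v):
            yield v


def _query_variants_by_tag(
    engine: QueryEngine,
    genome_label: str,
    contig: str | None,
    start: int | None,
    stop: int | None,
    filt: VariantFilter,
) -> Iterator[Variant]:
    """Index-routed execution: prefix-scan the tag table, resolve locators
    to variants, then apply region and remaining clauses."""
    assert filt.tag is not None
    hits: list[Variant] = []
    seen: set[tuple] = set()
    for _table, row_key, object_id in tag_index.lookup_by_tag(
        engine.store, filt.tag, genome_label
    ):
        for _lab, _ver, value in engine.store.get_cells(
            engine.table, row_key, "variant", genome_label
        ):
            v = decode_object(value)
            # the index covers all families; keep only the variant whose
            # identity matches this locator
            if variant_id(v) != object_id or v.key in seen:
                continue
            seen.add(v.key)
            if contig is not None:
                if v.locus.contig != contig:
                    continue
                if start is not None and not (start <= v.locus.position < stop):
                    continue
            if filt.passes(v):
                hits.append(v)
    ci = engine.store.contig_dict()
    hits.sort(key=lambda v: (ci[v.locus.contig], v.locus.position, v.version))
    yield from hits


def query_consequences(
    engine: QueryEngine,
    genome_label: str,
    region: str | None = None,
    filt: VariantFilter | None = None,
) -> Iterator[tuple[Consequence, Variant]]:
    """Consequences joined to their back-referenced variants; pairs whose
    variant fails the filter are suppressed, dangling references are logged
    and skipped."""
    filt = filt or EMPTY_FILTER
    engine.store.require_label(genome_label)
    contig = start = stop = None
    if region is not None:
        contig, start, stop = parse_region(region)
    for c in engine.scan_objects("consequence", genome_label, contig, start, stop):
        v = engine.resolve_variant(c.variant_ref)
        if v is None:
            log.warning(
                "dangling consequence back-reference %s in %s; skipped",
                c.variant_ref, genome_label,
            )
            continue
        if filt.passes(v):
            yield c, v


def query_coverage(
    engine: QueryEngine, genome_label: str, region: str
) -> Iterator[tuple[int, int]]:
    """Per-base (position, depth) over a required region, ascending,
    reconstructed from the overlapping coverage blocks and clipped to the
    region; uncovered bases are omitted."""
    engine.store.require_label(genome_label)
    contig, start, stop = parse_region(region)
    if start is None:
        raise RegionParseError("coverage queries need an explicit contig:start-stop region")
    bs = engine.store.block_size
    block_lo = (start // bs) * bs
    for block in engine.scan_objects("coverage", genome_label, contig, block_lo, stop):
        base = block.locus.position
        for off in sorted(block.depths):
            pos = base + off
            if start <= pos < stop:
                yield pos, block.depths[off]


# -- serialization ---------------------------------------------------------


def _bed_name(v: Variant) -> str:
    ref = v.ref_allele or "-"
    alt = v.alt_allele or "-"
    return f"{v.variant_type.value}:{ref}>{alt}:obs={v.observation_count}:depth={v.depth}:v={v.version}"


def export_bed(variants: Iterable[Variant], stream: IO[str]) -> int:
    """Write variants as BED4 (chrom, 0-based start, exclusive end, name);
    byte-for-byte deterministic for a fixed input order."""
    n = 0
    for v in variants:
        stream.write(
            f"{v.locus.contig}\t{v.locus.position}\t{v.stop}\t{_bed_name(v)}\n"
        )
        n += 1
    return n


def export_tsv(variants: Iterable[Variant], stream: IO[str]) -> int:
    """Flat tab-separated dump of variant fields (one header line)."""
    stream.write(
        "contig\tstart\tstop\ttype\tref\talt\tobs\tdepth\tp_value\tversion\ttags\n"
    )
    n = 0
    for v in variants:
        tags = ",".join(f"{k}={val}" if val else k for k, val in sorted(v.tags.items()))
        p = "" if v.p_value is None else repr(v.p_value)
        stream.write(
            f"{v.locus.contig}\t{v.locus.position}\t{v.stop}\t{v.variant_type.value}\t"
            f"{v.ref_allele}\t{v.alt_allele}\t{v.observation_count}\t{v.depth}\t"
            f"{p}\t{v.version}\t{tags}\n"
        )
        n += 1
    return n


def export_wig(
    coverage: Iterable[tuple[int, int]],
    stream: IO[str],
    contig: str,
    mode: str = "per_base",
    block_size: int | None = None,
) -> int:
    """Serialize coverage as WIG fixedStep (1-based starts).

    ``per_base`` emits each contiguous covered run as a step-1 section;
    ``block_average`` emits one value per coverage block — the arithmetic
    mean of depths over the covered bases of the block — as step/span =
    block_size sections.  Input positions must ascend.
    """
    if mode not in ("per_base", "block_average"):
        raise ValueError(f"unknown WIG mode {mode!r}")
    if mode == "block_average" and not block_size:
        raise ValueError("block_average mode requires block_size")
    lines = 0
    if mode == "per_base":
        prev = None
        for pos, depth in coverage:
            if prev is not None and pos <= prev:
                raise ValueError(f"coverage positions not ascending at {pos}")
            if prev is None or pos != prev + 1:
                stream.write(f"fixedStep chrom={contig} start={pos + 1} step=1\n")
                lines += 1
            stream.write(f"{depth}\n")
            lines += 1
            prev = pos
        return lines

    bs = block_size
    sums: dict[int, int] = {}
    counts: dict[int, int] = {}
    prev = None
    for pos, depth in coverage:
        if prev is not None and pos <= prev:
            raise ValueError(f"coverage positions not ascending at {pos}")
        prev = pos
        b = (pos // bs) * bs
        sums[b] = sums.get(b, 0) + depth
        counts[b] = counts.get(b, 0) + 1
    prev_block = None
    for b in sorted(sums):
        if prev_block is None or b != prev_block + bs:
            stream.write(
                f"fixedStep chrom={contig} start={b + 1} step={bs} span={bs}\n"
            )
            lines += 1
        mean = sums[b] / counts[b]
        stream.write(f"{mean:.10g}\n")
        lines += 1
        prev_block = b
    return lines


def nonredundant_tags(variants: Iterable[Variant]) -> list[tuple[str, str]]:
    """The set union of (tag, value) pairs across a result set, sorted."""
    seen: set[tuple[str, str]] = set()
    for v in variants:
        seen.update(v.tags.items())
    return sorted(seen)
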