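"""Map-reduce-style traversal of the primary table plus the two analysis
tools built on it: variant-type counting and tumor/normal somatic
mutation subtraction.

The traversal contract is in-process, not a distributed runtime: scan every
row once in genomic order, apply a pure map function to each (row_key,
cells), group the emitted (key, value) pairs by key, and apply a pure
reduce function per key.  Grouping is by key with values kept in emission
order, and the result is independent of how the scan is partitioned — the
properties a cluster implementation would also have to honor.

Somatic detection exploits the schema directly: identical variants of
different genomes share a row, so the tumor-vs-normal comparison is local
to each row in the map phase.  The reduce phase then checks normal coverage
at each candidate locus, so a "somatic" call is only reported where the
normal genome was actually sequenced deeply enough to have revealed a
germline allele.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator

from .codec import decode_object
from .datamodel import Variant, VariantType
from .engine import QueryEngine
from .kvstore import Cell, Store


class MapReduceError(RuntimeError):
    """A user map/reduce function raised; carries the row key in context."""


def map_reduce(
    store: Store,
    table: str,
    map_fn: Callable[[bytes, list[Cell]], Iterable[tuple]],
    reduce_fn: Callable[[object, list], object],
    partitions: int = 1,
) -> dict:
    """Scan all rows, map each, group emissions by key, reduce per key.

    ``partitions`` splits the row stream into that many contiguous chunks
    processed independently before a single merge — the result must not
    depend on it (property-tested), mirroring how a sharded scan behaves.
    """
    if partitions < 1:
        raise ValueError("partitions must be >= 1")
    rows = list(store.scan_all(table))
    chunk = max(1, -(-len(rows) // partitions))
    grouped: dict = {}
    for p in range(0, len(rows), chunk):
        for row_key, cells in rows[p : p + chunk]:
            try:
                emitted = list(map_fn(row_key, cells))
            except Exception as e:
                raise MapReduceError(
                    f"map function failed at row {row_key.hex()}"
                ) from e
            for key, value in emitted:
                grouped.setdefault(key, []).append(value)
    result = {}
    for key in sorted(grouped):
        try:
            result[key] = reduce_fn(key, grouped[key])
        except Exception as e:
            raise MapReduceError(f"reduce function failed for key {key!r}") from e
    return result


def count_variant_types(engine: QueryEngine, genome_label: str) -> dict[VariantType, int]:
    """Count stored variants of one genome by type via a full traversal."""
    engine.store.require_label(genome_label)

    def map_fn(row_key: bytes, cells: list[Cell]):
        for cell in cells:
            if cell.family == "variant" and cell.label == genome_label:
                v = decode_object(cell.value)
                yield v.variant_type, 1

    def reduce_fn(key, values):
        return sum(values)

    return map_reduce(engine.store, engine.table, map_fn, reduce_fn)


class SomaticStatus(str, enum.Enum):
    PUTATIVE_SOMATIC = "PUTATIVE_SOMATIC"
    REJECTED_PRESENT_IN_NORMAL = "REJECTED_PRESENT_IN_NORMAL"
    REJECTED_LOW_NORMAL_COVERAGE = "REJECTED_LOW_NORMAL_COVERAGE"
    REJECTED_QUALITY = "REJECTED_QUALITY"


@dataclass
class SomaticCriteria:
    """User-specified quality criteria applied to tumor variants in the map
    step.  ``min_tumor_fraction`` is observation_count/depth.  The defaults
    are explicit stand-ins (the thresholds are inherently user-specified);
    all are exposed on the command line."""

    min_tumor_observations: int = 4
    min_tumor_fraction: float = 0.1
    min_normal_coverage: int = 10
    max_p_value: float | None = None


@dataclass
class SomaticCall:
    variant: Variant
    normal_depth_at_locus: int
    status: SomaticStatus


def _passes_quality(v: Variant, criteria: SomaticCriteria) -> bool:
    if v.observation_count < criteria.min_tumor_observations:
        return False
    if v.depth > 0 and v.observation_count / v.depth < criteria.min_tumor_fraction:
        return False
    if criteria.max_p_value is not None and (
        v.p_value is None or v.p_value > criteria.max_p_value
    ):
        return False
    return True


def _same_call(a: Variant, b: Variant) -> bool:
    """Same event: type, alleles and span — any normal evidence (>= 1
    observation) vetoes a somatic call."""
    return (
        a.variant_type == b.variant_type
        and a.ref_allele == b.ref_allele
        and a.alt_allele == b.alt_allele
        and a.stop == b.stop
    )


def detect_somatic(
    engine: QueryEngine,
    tumor_label: str,
    normal_label: str,
    criteria: SomaticCriteria | None = None,
    report_rejected: bool = False,
) -> Iterator[SomaticCall]:
    """Tumor-minus-normal subtraction as a map-reduce job.

    Map: each tumor variant is checked against the quality criteria and
    against the co-located normal variants in the same row.  Reduce: normal
    coverage at each surviving locus is looked up from the coverage blocks;
    a call is PUTATIVE_SOMATIC iff that depth reaches
    ``min_normal_coverage``.  Rejected calls are yielded with their
    rejection status only when ``report_rejected`` is set.
    """
    criteria = criteria or SomaticCriteria()
    engine.store.require_label(tumor_label)
    engine.store.require_label(normal_label)

    def map_fn(row_key: bytes, cells: list[Cell]):
        tumor = []
        normal = []
        for cell in cells:
            if cell.family != "variant":
                continue
            if cell.label == tumor_label:
                tumor.append(decode_object(cell.value))
            elif cell.label == normal_label:
                normal.append(decode_object(cell.value))
        for v in tumor:
            if not _passes_quality(v, criteria):
                yield (v.locus.contig, v.locus.position, v.version), (
                    v, SomaticStatus.REJECTED_QUALITY,
                )
            elif any(_same_call(v, n) for n in normal):
                yield (v.locus.contig, v.locus.position, v.version), (
                    v, SomaticStatus.REJECTED_PRESENT_IN_NORMAL,
                )
            else:
                yield (v.locus.contig, v.locus.position, v.version), (v, None)

    def reduce_fn(key, values):
        out = []
        for v, status in values:
            if status is None:
                depth = engine.depth_at(v.locus.contig, v.locus.position, normal_label)
                status = (
                    SomaticStatus.PUTATIVE_SOMATIC
                    if depth >= criteria.min_normal_coverage
                    else SomaticStatus.REJECTED_LOW_NORMAL_COVERAGE
                )
            else:
                depth = engine.depth_at(v.locus.contig, v.locus.position, normal_label)
            out.append(SomaticCall(v, depth, status))
        return out

    grouped = map_reduce(engine.store, engine.table, map_fn, reduce_fn)
    ci = engine.store.contig_dict()
    for key in sorted(grouped, key=lambda k: (ci[k[0]], k[1], k[2])):
        for call in grouped[key]:
            if report_rejected or call.status is SomaticStatus.PUTATIVE_SOMATIC:
                yield call
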