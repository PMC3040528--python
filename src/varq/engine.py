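"""The generic store interface: typed read/write of every data type.

Import and export tools never touch cell bytes directly — they go through
this object-mapping layer, which assigns row keys from loci, assigns
versions to co-located objects, serializes values, and keeps the secondary
tag index in step with primary-table writes.  Backends are swappable below
this line; everything above it is backend-agnostic.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

from . import codec, tag_index
from .datamodel import (
    Consequence,
    CoverageBlock,
    Feature,
    ReferenceLocus,
    Variant,
    variant_id,
)
from .kvstore import CellAddress, Store, encode_row_key

_MAX_POS = 2**63 - 1


class QueryEngine:
    """An open store plus the object persistence layer over it."""

    def __init__(self, store: Store):
        self.store = store
        self.table = store.reference_name

    @classmethod
    def create(
        cls,
        path: str | Path,
        reference_name: str = "reference",
        block_size: int = 1000,
        contigs: Iterable[str] = (),
    ) -> "QueryEngine":
        return cls(Store.create(path, reference_name, block_size, contigs))

    @classmethod
    def open(cls, path: str | Path) -> "QueryEngine":
        return cls(Store.open(path))

    def close(self) -> None:
        self.store.close()

    def __enter__(self) -> "QueryEngine":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- writes ------------------------------------------------------------

    def write_variant(self, v: Variant, assign_version: bool = True) -> Variant:
        """Persist a variant and its tag-index entries.

        With ``assign_version`` the version becomes 1 + the count already
        stored at (locus, genome, variant family) — load-order numbering for
        co-located variants.
        """
        row = self.store.row_key_for(v.locus.contig, v.locus.position, register=True)
        if assign_version:
            v.version = self.store.next_version(self.table, row, "variant", v.genome_label)
        self.store.put_cell(
            CellAddress(self.table, row, "variant", v.genome_label, v.version),
            codec.encode_object(v),
        )
        self.store.register_label(v.genome_label)
        tag_index.index_object(
            self.store, v.tags, variant_id(v), self.table, row, v.genome_label
        )
        return v

    def write_variants_bulk(
        self, variants: Iterable[Variant], chunk: int = 50_000
    ) -> int:
        """High-throughput variant load: versions are taken from the records
        as given (the caller guarantees uniqueness of the identifying
        triple), writes are batched into large transactions, and tag-index
        entries are still maintained for tagged records."""
        n = 0
        labels: set[str] = set()
        buf: list[tuple[bytes, str, str, int, bytes]] = []
        with self.store.bulk():
            for v in variants:
                row = self.store.row_key_for(
                    v.locus.contig, v.locus.position, register=True
                )
                buf.append(
                    (row, "variant", v.genome_label, v.version, codec.encode_object(v))
                )
                labels.add(v.genome_label)
                if v.tags:
                    tag_index.index_object(
                        self.store, v.tags, variant_id(v), self.table, row, v.genome_label
                    )
                n += 1
                if len(buf) >= chunk:
                    self.store.put_cells(self.table, buf)
                    buf = []
            if buf:
                self.store.put_cells(self.table, buf)
            for label in labels:
                self.store.register_label(label)
        return n

    def write_coverage_block(self, block: CoverageBlock) -> None:
        """Persist one coverage block (one cell per block start; re-writing
        a block replaces it)."""
        row = self.store.row_key_for(
            block.locus.contig, block.locus.position, register=True
        )
        self.store.put_cell(
            CellAddress(self.table, row, "coverage", block.genome_label, 1),
            codec.encode_object(block),
        )
        self.store.register_label(block.genome_label)

    def write_feature(self, f: Feature) -> Feature:
        row = self.store.row_key_for(f.locus.contig, f.locus.position, register=True)
        version = self.store.next_version(self.table, row, "feature", f.genome_label)
        self.store.put_cell(
            CellAddress(self.table, row, "feature", f.genome_label, version),
            codec.encode_object(f),
        )
        self.store.register_label(f.genome_label)
        oid = row + b"feature" + version.to_bytes(4, "big")
        tag_index.index_object(self.store, f.tags, oid, self.table, row, f.genome_label)
        return f

    def write_consequence(self, c: Consequence) -> Consequence:
        row = self.store.row_key_for(c.locus.contig, c.locus.position, register=True)
        version = self.store.next_version(self.table, row, "consequence", c.genome_label)
        self.store.put_cell(
            CellAddress(self.table, row, "consequence", c.genome_label, version),
            codec.encode_object(c),
        )
        self.store.register_label(c.genome_label)
        oid = row + b"consequence" + version.to_bytes(4, "big")
        tag_index.index_object(self.store, c.tags, oid, self.table, row, c.genome_label)
        return c

    # -- reads -------------------------------------------------------------

    def variants_at(
        self, locus: ReferenceLocus, genome_label: str | None = None
    ) -> list[Variant]:
        """All variant versions stored at one locus, (label, version) order."""
        try:
            row = self.store.row_key_for(locus.contig, locus.position)
        except Exception:
            return []
        cells = self.store.get_cells(self.table, row, "variant", genome_label)
        return [codec.decode_object(value) for _, _, value in cells]

    def resolve_variant(
        self, ref: tuple[ReferenceLocus, str, int]
    ) -> Variant | None:
        """Resolve a (locus, genome_label, version) back-reference, or None."""
        locus, label, version = ref
        for v in self.variants_at(locus, label):
            if v.version == version:
                return v
        return None

    def coverage_block_at(
        self, contig: str, block_start: int, genome_label: str
    ) -> CoverageBlock | None:
        try:
            row = self.store.row_key_for(contig, block_start)
        except Exception:
            return None
        cells = self.store.get_cells(self.table, row, "coverage", genome_label)
        return codec.decode_object(cells[-1][2]) if cells else None

    def _region_keys(
        self, contig: str | None, start: int | None, stop: int | None
    ) -> tuple[bytes, bytes]:
        if contig is None:
            return b"", b"\xff" * 13
        ci = self.store.contig_index(contig)
        lo = encode_row_key(ci, start or 0)
        if stop is None:
            hi = encode_row_key(ci, _MAX_POS) + b"\xff"
        else:
            hi = encode_row_key(ci, stop)
        return lo, hi

    def scan_objects(
        self,
        family: str,
        genome_label: str | None = None,
        contig: str | None = None,
        start: int | None = None,
        stop: int | None = None,
    ) -> Iterator:
        """Decoded objects of one family in genomic (row, label, version) order."""
        lo, hi = self._region_keys(contig, start, stop)
        for _row, cells in self.store.scan_range(self.table, lo, hi):
            for cell in cells:
                if cell.family != family:
                    continue
                if genome_label is not None and cell.label != genome_label:
                    continue
                yield codec.decode_object(cell.value)

    def depth_at(self, contig: str, position: int, genome_label: str) -> int:
        """Per-base depth reconstructed from the enclosing coverage block."""
        bs = self.store.block_size
        block = self.coverage_block_at(contig, (position // bs) * bs, genome_label)
        if block is None:
            return 0
        return block.depths.get(position % bs, 0)
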