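"""Embedded byte-ordered key-value store with a column-family cell model.

This is the single-process stand-in for a BigTable-style backend: one
logical table per reference genome build, rows keyed by an order-preserving
encoding of (contig, position), and cells addressed by
(row, family, label, version).  Column families are fixed when a table is
created; labels (one per genome, e.g. ``variant:genome7``) can be added at
any time; versions distinguish multiple values at one row/family/label —
the mechanism that lets co-located variants of one genome coexist.

Physically everything flattens onto a single ordered map (a sqlite3 B-tree
over BLOB keys, which sqlite compares by memcmp, i.e. bytewise): the cell
key is ``row_key || family_byte || label || NUL || version``.  Because the
row key is fixed-width and the label is NUL-free, a bytewise range scan over
``[start_row, end_row)`` visits exactly the cells of those rows in genomic
order, which is what makes region queries and full-table traversal linear.

Contig names map to dense integer indices through a contig dictionary
persisted in the store; row keys embed the index, so contig order is the
registration order (normally reference declaration order).

Single-writer contract: one process writes at a time; readers may share.
"""

from __future__ import annotations

import json
import sqlite3
import struct
from contextlib import contextmanager
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

ROW_KEY_WIDTH = 12  # u32 contig index + u64 position, both big-endian

PRIMARY_FAMILIES = ("variant", "coverage", "feature", "consequence")
INDEX_FAMILIES = ("index",)

_FAMILY_BYTE = {
    "variant": 0x01,
    "coverage": 0x02,
    "feature": 0x03,
    "consequence": 0x04,
    "index": 0x05,
}
_BYTE_FAMILY = {v: k for k, v in _FAMILY_BYTE.items()}


class StoreError(Exception):
    """Base class for store-level failures."""


class SchemaError(StoreError):
    """Unknown table, or a family not declared for the table."""


class KeyRangeError(StoreError):
    """Row-key component outside its encodable range, or start > end."""


class KeyFormatError(StoreError):
    """A byte string is not a validly encoded key."""


class UnknownGenomeError(StoreError):
    """A genome label that was never loaded."""


def encode_row_key(contig_index: int, position: int) -> bytes:
    """Fixed-width row key whose bytewise order equals (contig, position) order."""
    if not 0 <= contig_index < 2**32:
        raise KeyRangeError(f"contig index {contig_index} outside [0, 2^32)")
    if not 0 <= position < 2**63:
        raise KeyRangeError(f"position {position} outside [0, 2^63)")
    return struct.pack(">IQ", contig_index, position)


def decode_row_key(key: bytes) -> tuple[int, int]:
    """Inverse of :func:`encode_row_key`."""
    if len(key) != ROW_KEY_WIDTH:
        raise KeyFormatError(f"row key must be {ROW_KEY_WIDTH} bytes, got {len(key)}")
    contig_index, position = struct.unpack(">IQ", key)
    return contig_index, position


class CellAddress(NamedTuple):
    table: str
    row_key: bytes
    family: str
    label: str
    version: int


class Cell(NamedTuple):
    family: str
    label: str
    version: int
    value: bytes


def _cell_key(row_key: bytes, family: str, label: str, version: int) -> bytes:
    if family not in _FAMILY_BYTE:
        raise SchemaError(f"unknown column family {family!r}")
    if "\x00" in label:
        raise KeyFormatError(f"label contains NUL: {label!r}")
    if version < 1:
        raise KeyRangeError("cell versions start at 1")
    return (
        row_key
        + bytes([_FAMILY_BYTE[family]])
        + label.encode("utf-8")
        + b"\x00"
        + struct.pack(">I", version)
    )


def _parse_cell_key(key: bytes) -> tuple[bytes, str, str, int]:
    row_key = key[:ROW_KEY_WIDTH]
    family = _BYTE_FAMILY[key[ROW_KEY_WIDTH]]
    body = key[ROW_KEY_WIDTH + 1 :]
    if len(body) < 5 or body[-5] != 0:
        raise KeyFormatError("malformed cell key")
    label = body[:-5].decode("utf-8")
    version = struct.unpack(">I", body[-4:])[0]
    return row_key, family, label, version


class Store:
    """An open store directory: one sqlite3 file plus persisted schema.

    Config keys carried in the store: ``reference_name`` (names the primary
    table), ``block_size`` (coverage block width in bases).
    """

    def __init__(self, path: str | Path, conn: sqlite3.Connection):
        self.path = Path(path)
        self._conn = conn
        self._contig_cache: dict[str, int] | None = None

    # -- lifecycle ---------------------------------------------------------

    @classmethod
    def create(
        cls,
        path: str | Path,
        reference_name: str = "reference",
        block_size: int = 1000,
        contigs: Iterable[str] = (),
    ) -> "Store":
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        db = path / "store.sqlite3"
        if db.exists():
            raise StoreError(f"store already exists at {path}")
        conn = cls._connect(db)
        with conn:
            conn.execute("CREATE TABLE meta (k TEXT PRIMARY KEY, v TEXT NOT NULL)")
            conn.execute(
                "CREATE TABLE contigs (name TEXT PRIMARY KEY, idx INTEGER UNIQUE NOT NULL)"
            )
            conn.execute(
                "CREATE TABLE tabledefs (name TEXT PRIMARY KEY, families TEXT NOT NULL)"
            )
            conn.execute("CREATE TABLE labels (label TEXT PRIMARY KEY)")
            conn.execute(
                "CREATE TABLE cells (tbl TEXT NOT NULL, key BLOB NOT NULL,"
                " value BLOB NOT NULL, PRIMARY KEY (tbl, key)) WITHOUT ROWID"
            )
            conn.execute(
                "INSERT INTO meta VALUES ('reference_name', ?), ('block_size', ?)",
                (reference_name, str(block_size)),
            )
        store = cls(path, conn)
        store.create_table(reference_name, PRIMARY_FAMILIES)
        for name in contigs:
            store.register_contig(name)
        return store

    @classmethod
    def open(cls, path: str | Path) -> "Store":
        db = Path(path) / "store.sqlite3"
        if not db.exists():
            raise StoreError(f"no store at {path}")
        return cls(path, cls._connect(db))

    @staticmethod
    def _connect(db: Path) -> sqlite3.Connection:
        conn = sqlite3.connect(db, isolation_level=None)
        conn.execute("PRAGMA synchronous=OFF")
        conn.execute("PRAGMA cache_size=-65536")
        return conn

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @contextmanager
    def bulk(self):
        """Group many writes into one transaction (load-time throughput)."""
        self._conn.execute("BEGIN")
        try:
            yield self
        except BaseException:
            self._conn.execute("ROLLBACK")
            raise
        self._conn.execute("COMMIT")

    # -- config & dictionaries ---------------------------------------------

    @property
    def reference_name(self) -> str:
        return self._meta("reference_name")

    @property
    def block_size(self) -> int:
        return int(self._meta("block_size"))

    def _meta(self, k: str) -> str:
        row = self._conn.execute("SELECT v FROM meta WHERE k=?", (k,)).fetchone()
        if row is None:
            raise StoreError(f"missing config key {k}")
        return row[0]

    def register_contig(self, name: str) -> int:
        """Map a contig to its dense index, registering on first sight."""
        idx = self.contig_dict().get(name)
        if idx is not None:
            return idx
        idx = len(self._contig_cache)  # type: ignore[arg-type]
        self._conn.execute("INSERT INTO contigs VALUES (?, ?)", (name, idx))
        self._contig_cache[name] = idx  # type: ignore[index]
        return idx

    def contig_dict(self) -> dict[str, int]:
        if self._contig_cache is None:
            rows = self._conn.execute("SELECT name, idx FROM contigs").fetchall()
            self._contig_cache = {n: i for n, i in rows}
        return self._contig_cache

    def contig_index(self, name: str) -> int:
        try:
            return self.contig_dict()[name]
        except KeyError:
            raise KeyRangeError(f"unknown contig {name!r}") from None

    def contig_names(self) -> list[str]:
        return [n for n, _ in sorted(self.contig_dict().items(), key=lambda kv: kv[1])]

    def contig_name(self, idx: int) -> str:
        names = self.contig_names()
        if not 0 <= idx < len(names):
            raise KeyRangeError(f"contig index {idx} not registered")
        return names[idx]

    def register_label(self, label: str) -> None:
        self._conn.execute("INSERT OR IGNORE INTO labels VALUES (?)", (label,))

    def labels(self) -> list[str]:
        return [r[0] for r in self._conn.execute("SELECT label FROM labels ORDER BY label")]

    def require_label(self, label: str) -> None:
        row = self._conn.execute("SELECT 1 FROM labels WHERE label=?", (label,)).fetchone()
        if row is None:
            raise UnknownGenomeError(
                f"unknown genome {label!r}; loaded genomes: {self.labels()}"
            )

    # -- tables ------------------------------------------------------------

    def create_table(self, name: str, families: Iterable[str]) -> None:
        fams = tuple(families)
        for f in fams:
            if f not in _FAMILY_BYTE:
                raise SchemaError(f"unknown column family {f!r}")
        self._conn.execute(
            "INSERT OR IGNORE INTO tabledefs VALUES (?, ?)", (name, json.dumps(fams))
        )

    def table_families(self, table: str) -> tuple[str, ...]:
        row = self._conn.execute(
            "SELECT families FROM tabledefs WHERE name=?", (table,)
        ).fetchone()
        if row is None:
            raise SchemaError(f"unknown table {table!r}")
        return tuple(json.loads(row[0]))

    def tables(self) -> list[str]:
        return [r[0] for r in self._conn.execute("SELECT name FROM tabledefs ORDER BY name")]

    # -- cells -------------------------------------------------------------

    def put_cell(self, addr: CellAddress, value: bytes) -> None:
        """Write one cell; re-writing an existing address replaces its value."""
        if addr.family not in self.table_families(addr.table):
            raise SchemaError(
                f"family {addr.family!r} not in table {addr.table!r} "
                f"(has {self.table_families(addr.table)})"
            )
        key = _cell_key(addr.row_key, addr.family, addr.label, addr.version)
        self._conn.execute(
            "INSERT OR REPLACE INTO cells VALUES (?, ?, ?)", (addr.table, key, value)
        )

    def put_cells(self, table: str, items: Iterable[tuple[bytes, str, str, int, bytes]]) -> None:
        """Batch write of (row_key, family, label, version, value) tuples."""
        fams = self.table_families(table)
        rows = []
        for row_key, family, label, version, value in items:
            if family not in fams:
                raise SchemaError(f"family {family!r} not in table {table!r}")
            rows.append((table, _cell_key(row_key, family, label, version), value))
        self._conn.executemany("INSERT OR REPLACE INTO cells VALUES (?, ?, ?)", rows)

    def get_cells(
        self, table: str, row_key: bytes, family: str, label: str | None = None
    ) -> list[tuple[str, int, bytes]]:
        """All cells at (row, family), optionally one label; ordered by (label, version)."""
        if family not in self.table_families(table):
            raise SchemaError(f"family {family!r} not in table {table!r}")
        prefix = row_key + bytes([_FAMILY_BYTE[family]])
        if label is not None:
            prefix += label.encode("utf-8") + b"\x00"
        out = []
        for key, value in self._conn.execute(
            "SELECT key, value FROM cells WHERE tbl=? AND key>=? AND key<? ORDER BY key",
            (table, prefix, prefix + b"\xff" * 5),
        ):
            _, _, lab, ver = _parse_cell_key(key)
            out.append((lab, ver, value))
        return out

    def put_raw(self, table: str, key: bytes, value: bytes) -> None:
        """Write an uninterpreted key (secondary-index tables, whose keys are
        tag-based rather than row-key-based)."""
        self.table_families(table)
        self._conn.execute(
            "INSERT OR REPLACE INTO cells VALUES (?, ?, ?)", (table, key, value)
        )

    def delete_raw(self, table: str, key: bytes) -> None:
        self._conn.execute("DELETE FROM cells WHERE tbl=? AND key=?", (table, key))

    def delete_cell(self, addr: CellAddress) -> None:
        key = _cell_key(addr.row_key, addr.family, addr.label, addr.version)
        self._conn.execute("DELETE FROM cells WHERE tbl=? AND key=?", (addr.table, key))

    def next_version(self, table: str, row_key: bytes, family: str, label: str) -> int:
        """1 + the highest version stored at (row, family, label)."""
        cells = self.get_cells(table, row_key, family, label)
        return 1 + max((v for _, v, _ in cells), default=0)

    # -- scans -------------------------------------------------------------

    def scan_range(
        self, table: str, start_key: bytes, end_key: bytes
    ) -> Iterator[tuple[bytes, list[Cell]]]:
        """Yield each row with start <= row_key < end once, in byte order.

        A row's cells come back ordered by (family, label, version), which
        is the physical order of the flattened cell keys.
        """
        if start_key > end_key:
            raise KeyRangeError("scan start key exceeds end key")
        self.table_families(table)  # existence check
        cur = self._conn.execute(
            "SELECT key, value FROM cells WHERE tbl=? AND key>=? AND key<? ORDER BY key",
            (table, start_key, end_key),
        )
        current_row: bytes | None = None
        cells: list[Cell] = []
        for key, value in cur:
            row_key, family, label, version = _parse_cell_key(key)
            if row_key != current_row:
                if current_row is not None:
                    yield current_row, cells
                current_row, cells = row_key, []
            cells.append(Cell(family, label, version, value))
        if current_row is not None:
            yield current_row, cells

    def scan_all(self, table: str) -> Iterator[tuple[bytes, list[Cell]]]:
        """Full-table scan in row-key (genomic) order."""
        return self.scan_range(table, b"", b"\xff" * (ROW_KEY_WIDTH + 1))

    def prefix_scan(self, table: str, prefix: bytes) -> Iterator[tuple[bytes, bytes]]:
        """Raw (key, value) pairs whose key starts with ``prefix`` (index tables)."""
        self.table_families(table)
        end = prefix + b"\xff" * 16
        yield from self._conn.execute(
            "SELECT key, value FROM cells WHERE tbl=? AND key>=? AND key<? ORDER BY key",
            (table, prefix, end),
        )

    def row_key_for(self, contig: str, position: int, register: bool = False) -> bytes:
        """Row key for a locus, optionally registering a new contig."""
        idx = self.register_contig(contig) if register else self.contig_index(contig)
        return encode_row_key(idx, position)
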