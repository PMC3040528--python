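"""Secondary tag index: find tagged objects without a primary-table scan.

One index table per genome.  The index key is ``tag || NUL || object_id``
and the value locates the primary-table row (table name + row key), so a
prefix scan on ``tag || NUL`` yields every object carrying the tag in
object-id order.  The NUL separator keeps tag "a" from matching objects
tagged "ab".  The index keys only on the tag *key*; tag-value filtering
happens client-side after lookup.

All four families are indexed uniformly — anything written with tags gets
index entries.
"""

from __future__ import annotations

import json
import logging
from typing import Iterator, NamedTuple

from .kvstore import INDEX_FAMILIES, KeyFormatError, Store

log = logging.getLogger(__name__)

SEP = b"\x00"


class TagIndexEntry(NamedTuple):
    tag: str
    object_id: bytes
    target_table: str
    target_row_key: bytes


def index_table_name(genome_label: str) -> str:
    return f"tags:{genome_label}"


def ensure_index_table(store: Store, genome_label: str) -> str:
    name = index_table_name(genome_label)
    store.create_table(name, INDEX_FAMILIES)
    return name


def index_object(
    store: Store,
    tags: dict[str, str],
    object_id: bytes,
    target_table: str,
    target_row_key: bytes,
    genome_label: str,
) -> int:
    """Write one index entry per tag key; returns the number written.

    The object must already be in the primary table — the index stores
    locators, not data.
    """
    if not tags:
        return 0
    table = ensure_index_table(store, genome_label)
    for tag in tags:
        if "\x00" in tag:
            raise KeyFormatError(f"tag contains NUL byte: {tag!r}")
        key = tag.encode("utf-8") + SEP + object_id
        value = json.dumps(
            {"table": target_table, "row": target_row_key.hex()}
        ).encode("utf-8")
        store.put_raw(table, key, value)
    return len(tags)


def lookup_by_tag(
    store: Store, tag: str, genome_label: str
) -> Iterator[tuple[str, bytes, bytes]]:
    """Yield (target_table, target_row_key, object_id) for every object
    carrying the tag, in object-id order."""
    store.require_label(genome_label)
    table = ensure_index_table(store, genome_label)
    prefix = tag.encode("utf-8") + SEP
    for key, value in store.prefix_scan(table, prefix):
        object_id = key[len(prefix) :]
        d = json.loads(value.decode("utf-8"))
        yield d["table"], bytes.fromhex(d["row"]), object_id


def remove_object(
    store: Store, tags: dict[str, str], object_id: bytes, genome_label: str
) -> None:
    """Minimal deletion support: drop the entries for one object."""
    table = index_table_name(genome_label)
    for tag in tags:
        store.delete_raw(table, tag.encode("utf-8") + SEP + object_id)
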