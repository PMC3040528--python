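"""Versioned, self-describing JSON serialization of the domain objects.

The store treats cell values as opaque bytes; this codec is the single place
that turns domain objects into those bytes and back.  Every payload carries
a ``_t`` type tag and a ``_v`` schema version so future layouts can coexist
with old stores.
"""

from __future__ import annotations

import json

from .datamodel import (
    Consequence,
    CoverageBlock,
    Feature,
    ReferenceLocus,
    Strand,
    Variant,
    VariantType,
)

SCHEMA_VERSION = 1


def _locus(obj: ReferenceLocus) -> list:
    return [obj.contig, obj.position]


def encode_object(obj) -> bytes:
    if isinstance(obj, Variant):
        d = {
            "_t": "Variant",
            "locus": _locus(obj.locus),
            "stop": obj.stop,
            "type": obj.variant_type.value,
            "ref": obj.ref_allele,
            "alt": obj.alt_allele,
            "obs": obj.observation_count,
            "depth": obj.depth,
            "p": obj.p_value,
            "tags": obj.tags,
            "label": obj.genome_label,
            "version": obj.version,
        }
    elif isinstance(obj, CoverageBlock):
        d = {
            "_t": "CoverageBlock",
            "locus": _locus(obj.locus),
            "block_size": obj.block_size,
            # JSON object keys are strings; offsets are re-int'd on decode
            "depths": obj.depths,
            "label": obj.genome_label,
        }
    elif isinstance(obj, Feature):
        d = {
            "_t": "Feature",
            "locus": _locus(obj.locus),
            "stop": obj.stop,
            "name": obj.name,
            "score": obj.score,
            "strand": obj.strand.value,
            "tags": obj.tags,
            "label": obj.genome_label,
        }
    elif isinstance(obj, Consequence):
        ref_locus, ref_label, ref_version = obj.variant_ref
        d = {
            "_t": "Consequence",
            "locus": _locus(obj.locus),
            "ref": [_locus(ref_locus), ref_label, ref_version],
            "effect": obj.effect,
            "gene": obj.gene,
            "tags": obj.tags,
            "label": obj.genome_label,
        }
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    d["_v"] = SCHEMA_VERSION
    return json.dumps(d, separators=(",", ":"), sort_keys=True).encode("utf-8")


def decode_object(data: bytes):
    d = json.loads(data.decode("utf-8"))
    t = d["_t"]
    locus = ReferenceLocus(*d["locus"])
    if t == "Variant":
        return Variant(
            locus=locus,
            stop=d["stop"],
            variant_type=VariantType(d["type"]),
            ref_allele=d["ref"],
            alt_allele=d["alt"],
            observation_count=d["obs"],
            depth=d["depth"],
            p_value=d["p"],
            tags=d["tags"],
            genome_label=d["label"],
            version=d["version"],
        )
    if t == "CoverageBlock":
        return CoverageBlock(
            locus=locus,
            block_size=d["block_size"],
            depths={int(k): v for k, v in d["depths"].items()},
            genome_label=d["label"],
        )
    if t == "Feature":
        return Feature(
            locus=locus,
            stop=d["stop"],
            name=d["name"],
            score=d["score"],
            strand=Strand(d["strand"]),
            tags=d["tags"],
            genome_label=d["label"],
        )
    if t == "Consequence":
        (rl, ref_label, ref_version) = d["ref"]
        return Consequence(
            locus=locus,
            variant_ref=(ReferenceLocus(*rl), ref_label, ref_version),
            effect=d["effect"],
            gene=d["gene"],
            tags=d["tags"],
            genome_label=d["label"],
        )
    raise ValueError(f"unknown serialized type {t!r}")
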