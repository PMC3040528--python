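"""Domain types shared by every layer of the query engine.

The engine stores four kinds of position-keyed objects for many genomes in
one table: variants (SNVs, indels, SVs, translocations), per-base coverage
packed into fixed-width blocks, generic location-based features, and coding
consequences that link back to the variant they annotate.  All internal
coordinates are 0-based, half-open; pileup (1-based), GFF (1-based
inclusive) and WIG (1-based) are converted at the I/O boundary.

Objects carry a free-form tag map (string key -> string value, value may be
empty for a bare tag) which drives the secondary index.
"""

from __future__ import annotations

import enum
import struct
from dataclasses import dataclass, field


class ContractError(ValueError):
    """A type invariant or operation precondition was violated."""


class VariantType(str, enum.Enum):
    SNV = "SNV"
    INSERTION = "INSERTION"
    DELETION = "DELETION"
    SV = "SV"
    TRANSLOCATION = "TRANSLOCATION"


class Strand(str, enum.Enum):
    FORWARD = "+"
    REVERSE = "-"
    UNKNOWN = "."


def _check_tags(tags: dict) -> dict:
    for k, v in tags.items():
        if not isinstance(k, str) or not k:
            raise ContractError(f"tag keys must be non-empty strings, got {k!r}")
        if "\x00" in k:
            raise ContractError(f"tag key contains NUL byte: {k!r}")
        if v is None:
            tags[k] = ""
        elif not isinstance(v, str):
            raise ContractError(f"tag values must be strings, got {v!r}")
    return tags


@dataclass(frozen=True, order=True)
class ReferenceLocus:
    """A contig name plus 0-based base offset; the source of every row key."""

    contig: str
    position: int

    def __post_init__(self) -> None:
        if not self.contig:
            raise ContractError("contig name must be non-empty")
        if "\t" in self.contig or "\x00" in self.contig:
            raise ContractError(f"contig name contains tab/NUL: {self.contig!r}")
        if self.position < 0:
            raise ContractError(f"position must be >= 0, got {self.position}")


@dataclass
class Variant:
    """A typed sequence variant called in one genome.

    ``observation_count`` is the number of reads supporting the alternate
    allele; ``depth`` the total reads at the locus.  ``version`` (>= 1)
    distinguishes co-located variants within one genome, mirroring the
    per-cell version a column-family store attaches at one row/family/label.
    """

    locus: ReferenceLocus
    stop: int
    variant_type: VariantType
    ref_allele: str
    alt_allele: str
    observation_count: int
    depth: int
    genome_label: str
    version: int = 1
    p_value: float | None = None
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.variant_type = VariantType(self.variant_type)
        if self.observation_count < 0:
            raise ContractError("observation_count must be >= 0")
        if self.depth < self.observation_count:
            raise ContractError(
                f"depth ({self.depth}) < observation_count ({self.observation_count})"
            )
        if self.version < 1:
            raise ContractError("version numbering starts at 1")
        if not self.genome_label or "\x00" in self.genome_label:
            raise ContractError(f"bad genome label {self.genome_label!r}")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ContractError(f"p_value outside [0,1]: {self.p_value}")
        if self.variant_type is VariantType.SNV:
            if self.stop != self.locus.position + 1:
                raise ContractError("SNV must span exactly one base")
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ContractError("SNV alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ContractError("SNV alt allele equals reference")
        elif self.stop <= self.locus.position and self.variant_type is not VariantType.INSERTION:
            raise ContractError("stop must exceed start for ranged variant types")
        _check_tags(self.tags)

    @property
    def key(self) -> tuple[ReferenceLocus, str, int]:
        """The (locus, genome_label, version) triple that uniquely identifies
        this variant in the store."""
        return (self.locus, self.genome_label, self.version)


@dataclass
class CoverageBlock:
    """Sparse per-base read depths over one fixed-width genomic window.

    The block starts on a multiple of ``block_size``; ``depths`` maps in-block
    offsets to depths >= 1.  Uncovered bases are simply absent — never stored
    as zero — which keeps storage proportional to covered bases.
    """

    locus: ReferenceLocus
    block_size: int
    depths: dict[int, int]
    genome_label: str

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ContractError("block_size must be >= 1")
        if self.locus.position % self.block_size != 0:
            raise ContractError(
                f"block start {self.locus.position} not a multiple of {self.block_size}"
            )
        for off, d in self.depths.items():
            if not 0 <= off < self.block_size:
                raise ContractError(f"offset {off} outside block of {self.block_size}")
            if d < 1:
                raise ContractError("zero/negative depths must be omitted, not stored")


@dataclass
class Feature:
    """Any location-based annotation on the genome (BED/GFF records land here)."""

    locus: ReferenceLocus
    stop: int
    name: str
    genome_label: str
    score: float | None = None
    strand: Strand = Strand.UNKNOWN
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.strand = Strand(self.strand)
        if self.stop <= self.locus.position:
            raise ContractError("feature stop must exceed start")
        _check_tags(self.tags)


@dataclass
class Consequence:
    """A coding-consequence annotation holding a back-reference to its variant.

    ``variant_ref`` is the (locus, genome_label, version) triple of the
    annotated variant; it must resolve within the same genome label.
    """

    locus: ReferenceLocus
    variant_ref: tuple[ReferenceLocus, str, int]
    effect: str
    genome_label: str
    gene: str | None = None
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ref_locus, ref_label, ref_version = self.variant_ref
        if ref_label != self.genome_label:
            raise ContractError("consequence must reference a variant in its own genome")
        if ref_version < 1:
            raise ContractError("referenced version must be >= 1")
        _check_tags(self.tags)


def variant_id(v: Variant) -> bytes:
    """Deterministic, injective identifier over (locus, genome_label, version).

    Layout: contig utf-8 || NUL || position u64-BE || label utf-8 || NUL ||
    version u32-BE.  Contig and label are NUL-free by construction, so the
    encoding is prefix-unambiguous and stable across runs and platforms.
    """
    if v.locus is None or not v.genome_label or v.version is None:
        raise ContractError("variant_id requires locus, genome_label and version")
    return (
        v.locus.contig.encode("utf-8")
        + b"\x00"
        + struct.pack(">Q", v.locus.position)
        + v.genome_label.encode("utf-8")
        + b"\x00"
        + struct.pack(">I", v.version)
    )


def triple_id(locus: ReferenceLocus, genome_label: str, version: int) -> bytes:
    """``variant_id`` computed from a bare identifying triple."""
    return (
        locus.contig.encode("utf-8")
        + b"\x00"
        + struct.pack(">Q", locus.position)
        + genome_label.encode("utf-8")
        + b"\x00"
        + struct.pack(">I", version)
    )
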