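"""Deterministic synthetic data: references, pileup streams, tumor/normal
pairs — each with a machine-readable truth set.

The generator emulates the load regime the engine is built for: unfiltered
per-position variant evidence ("observed once or more"), so every planted
allele and every injected sequencing-error allele is recoverable at
threshold 1 and recorded in the truth set.  It emits positions, depths and
per-read base calls, not reads: there are no read lengths, mapping
qualities or alignment artifacts, which is exactly what keeps truth sets
exact.

Everything is driven by one ``numpy`` generator seeded from the caller, so
output is byte-identical across runs for fixed (parameters, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

BASES = "ACGT"


@dataclass(frozen=True)
class TruthVariant:
    """One planted (or injected-error) allele, in the loader's coordinates:
    0-based position, deletions located at the first deleted base,
    insertions at their anchor base, empty allele strings for the absent
    side of an indel."""

    contig: str
    position: int
    variant_type: str  # SNV / INSERTION / DELETION
    ref: str
    alt: str
    observation_count: int

    @property
    def key(self) -> tuple:
        return (self.contig, self.position, self.variant_type, self.ref, self.alt)


@dataclass
class TruthSet:
    variants: list[TruthVariant] = field(default_factory=list)
    depth_map: dict[str, dict[int, int]] = field(default_factory=dict)
    somatic_subset: list[TruthVariant] = field(default_factory=list)
    germline_subset: list[TruthVariant] = field(default_factory=list)
    error_log: list[TruthVariant] = field(default_factory=list)
    normal_depth_map: dict[str, dict[int, int]] = field(default_factory=dict)

    def keys(self, min_observations: int = 1) -> set[tuple]:
        return {
            t.key for t in self.variants if t.observation_count >= min_observations
        }

    def to_json(self) -> str:
        def enc(lst):
            return [t.__dict__ for t in lst]

        return json.dumps(
            {
                "variants": enc(self.variants),
                "somatic_subset": enc(self.somatic_subset),
                "germline_subset": enc(self.germline_subset),
                "error_log": enc(self.error_log),
                "depth_map": {c: m for c, m in self.depth_map.items()},
            },
            indent=None,
            sort_keys=True,
        )


def generate_reference(
    contigs: Iterable[tuple[str, int]], seed: int
) -> dict[str, str]:
    """Uniform-ACGT contig sequences, deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    out = {}
    for name, length in contigs:
        if length < 1:
            raise ValueError(f"contig {name!r} length must be >= 1")
        idx = rng.integers(0, 4, size=length)
        out[name] = "".join(BASES[i] for i in idx)
    return out


def _quals(rng, n: int) -> str:
    return "".join(chr(33 + int(q)) for q in rng.integers(0, 40, size=n))


def _decorate(rng, token: str) -> str:
    """Randomly wrap a base call with read start/end markers to exercise
    the full pileup grammar."""
    if rng.random() < 0.05:
        token = "^" + chr(33 + int(rng.integers(0, 60))) + token
    if rng.random() < 0.05:
        token = token + "$"
    return token


def _case(rng, base: str) -> str:
    return base if rng.random() < 0.5 else base.lower()


@dataclass
class _Planted:
    kind: str  # snv / ins / del
    alt: str  # alt base, inserted seq, or deleted seq (upper case)
    obs: int = 0


def _plan_events(
    rng, seq: str, snv_rate: float, indel_rate: float
) -> dict[int, _Planted]:
    """Choose planted events, at most one per position, indel spans kept
    clear of later events so truth loci never collide."""
    events: dict[int, _Planted] = {}
    skip_until = -1
    L = len(seq)
    for pos in range(L):
        if pos < skip_until:
            continue
        r = rng.random()
        if r < snv_rate:
            ref = seq[pos]
            alt = BASES[(BASES.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
            events[pos] = _Planted("snv", alt)
            skip_until = pos + 2
        elif r < snv_rate + indel_rate and pos < L - 5:
            length = 1 + int(rng.integers(0, 3))
            if rng.random() < 0.5:
                ins = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
                events[pos] = _Planted("ins", ins)
                skip_until = pos + 2
            else:
                events[pos] = _Planted("del", seq[pos + 1 : pos + 1 + length])
                skip_until = pos + 1 + length + 1
    return events


def _emit_line(
    rng,
    contig: str,
    pos: int,
    ref: str,
    depth: int,
    planted: _Planted | None,
    error_rate: float,
    truth: TruthSet,
    min_obs: int = 1,
) -> str:
    """Build one grammar-valid pileup line and record its truth."""
    tokens: list[str] = []
    alt_obs = 0
    if planted is not None:
        if planted.kind == "snv":
            alt_obs = max(min_obs, int(rng.binomial(depth, 0.5)))
            alt_obs = min(alt_obs, depth)
            tokens += [_case(rng, planted.alt) for _ in range(alt_obs)]
        else:
            alt_obs = max(min_obs, int(rng.binomial(depth, 0.5)))
            alt_obs = min(alt_obs, depth)
            indel = ("+" if planted.kind == "ins" else "-") + str(
                len(planted.alt)
            ) + planted.alt
            tokens += ["." + indel] * alt_obs
        planted.obs = alt_obs
    # indel carrier tokens above already hold their ref call
    n_plain = depth - len(tokens)
    err_counts: dict[str, int] = {}
    if error_rate > 0 and n_plain > 0:
        n_err = int(rng.binomial(n_plain, error_rate))
        excluded = {ref}
        if planted is not None and planted.kind == "snv":
            excluded.add(planted.alt)
        choices = [b for b in BASES if b not in excluded]
        for _ in range(n_err):
            b = choices[int(rng.integers(0, len(choices)))]
            err_counts[b] = err_counts.get(b, 0) + 1
            tokens.append(_case(rng, b))
    while len(tokens) < depth:
        tokens.append("." if rng.random() < 0.5 else ",")
    rng.shuffle(tokens)
    bases = "".join(_decorate(rng, t) for t in tokens)
    # truth bookkeeping
    if planted is not None and planted.obs >= 1:
        if planted.kind == "snv":
            tv = TruthVariant(contig, pos, "SNV", ref, planted.alt, planted.obs)
        elif planted.kind == "ins":
            tv = TruthVariant(contig, pos, "INSERTION", "", planted.alt, planted.obs)
        else:
            tv = TruthVariant(contig, pos + 1, "DELETION", planted.alt, "", planted.obs)
        truth.variants.append(tv)
    for b, cnt in sorted(err_counts.items()):
        ev = TruthVariant(contig, pos, "SNV", ref, b, cnt)
        truth.error_log.append(ev)
        truth.variants.append(ev)
    truth.depth_map.setdefault(contig, {})[pos] = depth
    return f"{contig}\t{pos + 1}\t{ref}\t{depth}\t{bases}\t{_quals(rng, depth)}"


def generate_pileup(
    reference: dict[str, str],
    mean_depth: float = 20,
    snv_rate: float = 1e-3,
    indel_rate: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[str], TruthSet]:
    """One genome's sorted pileup stream plus its exact truth set.

    Depths are Poisson around ``mean_depth`` (zero-depth positions are
    simply absent, as in real pileup); positions hosting a planted event
    get depth >= 2 so the allele is observable.  Error alleles are drawn
    uniformly from the non-reference, non-planted bases and logged.
    """
    rng = np.random.default_rng(seed)
    truth = TruthSet()
    lines: list[str] = []
    for contig in reference:
        seq = reference[contig]
        events = _plan_events(rng, seq, snv_rate, indel_rate)
        depths = rng.poisson(mean_depth, size=len(seq))
        for pos in range(len(seq)):
            depth = int(depths[pos])
            planted = events.get(pos)
            if planted is not None:
                depth = max(depth, 2)
            if depth == 0:
                continue
            lines.append(
                _emit_line(
                    rng, contig, pos, seq[pos], depth, planted, error_rate, truth
                )
            )
    return lines, truth


def generate_tumor_normal(
    reference: dict[str, str],
    germline_n: int = 200,
    somatic_n: int = 50,
    depth: float = 20,
    seed: int = 0,
    error_rate: float = 0.0,
    normal_depth_floor: int = 10,
    min_tumor_obs: int = 4,
    min_tumor_fraction: float = 0.1,
) -> tuple[list[str], list[str], TruthSet]:
    """A matched pair: germline SNVs in both genomes, somatic SNVs only in
    the tumor, with guarantees that make detector completeness testable —
    tumor alt counts reach ``min_tumor_obs`` and ``min_tumor_fraction``,
    and normal depth at somatic loci reaches ``normal_depth_floor``.

    Returns (normal pileup lines, tumor pileup lines, truth).  The truth
    set's ``depth_map`` is the tumor's; the normal's is in
    ``normal_depth_map``.
    """
    rng = np.random.default_rng(seed)
    total = germline_n + somatic_n
    loci: list[tuple[str, int]] = []
    for contig, seq in reference.items():
        loci += [(contig, p) for p in range(1, len(seq) - 2)]
    if total > len(loci) // 4:
        raise ValueError("reference too small for the requested variant counts")
    order = {c: i for i, c in enumerate(reference)}
    picks = rng.choice(len(loci), size=total, replace=False)
    chosen = sorted(
        (loci[int(i)] for i in picks), key=lambda cp: (order[cp[0]], cp[1])
    )
    # drop adjacent picks to keep one event per position cleanly separated
    filtered: list[tuple[str, int]] = []
    for c, p in chosen:
        if filtered and filtered[-1][0] == c and p - filtered[-1][1] < 2:
            continue
        filtered.append((c, p))
    while len(filtered) < total:  # extremely unlikely at sane densities
        c, p = loci[int(rng.integers(0, len(loci)))]
        if all(not (c == fc and abs(p - fp) < 2) for fc, fp in filtered):
            filtered.append((c, p))
    filtered = filtered[:total]
    flags = np.zeros(total, dtype=bool)
    flags[rng.choice(total, size=somatic_n, replace=False)] = True
    somatic_loci = {filtered[i] for i in range(total) if flags[i]}
    germline_loci = {filtered[i] for i in range(total) if not flags[i]}

    def alt_for(ref: str) -> str:
        return BASES[(BASES.index(ref) + 1 + int(rng.integers(0, 3))) % 4]

    plan: dict[tuple[str, int], str] = {}
    for c, p in sorted(somatic_loci | germline_loci, key=lambda cp: (order[cp[0]], cp[1])):
        plan[(c, p)] = alt_for(reference[c][p])

    truth = TruthSet()

    def emit_genome(planted_loci: set, depth_map_out: dict, record_truth: bool):
        sub = TruthSet()
        lines: list[str] = []
        for contig, seq in reference.items():
            depths = rng.poisson(depth, size=len(seq))
            for pos in range(len(seq)):
                d = int(depths[pos])
                key = (contig, pos)
                planted = None
                if key in planted_loci:
                    d = max(d, int(math.ceil(min_tumor_obs / 0.4)), 2)
                    planted = _Planted("snv", plan[key])
                elif key in somatic_loci:
                    # normal genome at a somatic locus: force assessable depth
                    d = max(d, normal_depth_floor)
                if d == 0:
                    continue
                min_obs = 1
                if planted is not None:
                    min_obs = max(min_tumor_obs, int(math.ceil(min_tumor_fraction * d)))
                lines.append(
                    _emit_line(
                        rng, contig, pos, seq[pos], d, planted, error_rate, sub, min_obs
                    )
                )
        depth_map_out.update(sub.depth_map)
        if record_truth:
            truth.variants.extend(sub.variants)
        truth.error_log.extend(sub.error_log)
        return lines

    normal_lines = emit_genome(germline_loci, truth.normal_depth_map, False)
    tumor_lines = emit_genome(
        germline_loci | somatic_loci, truth.depth_map, True
    )
    by_key = {t.key: t for t in truth.variants if not _is_error(t, truth)}
    for c, p in sorted(somatic_loci, key=lambda cp: (order[cp[0]], cp[1])):
        tv = by_key[(c, p, "SNV", reference[c][p], plan[(c, p)])]
        truth.somatic_subset.append(tv)
    for c, p in sorted(germline_loci, key=lambda cp: (order[cp[0]], cp[1])):
        tv = by_key[(c, p, "SNV", reference[c][p], plan[(c, p)])]
        truth.germline_subset.append(tv)
    return normal_lines, tumor_lines, truth


def _is_error(tv: TruthVariant, truth: TruthSet) -> bool:
    return any(e is tv for e in truth.error_log)


def generate_variant_stream(
    contig_lengths: dict[str, int],
    n: int,
    genome_label: str,
    seed: int,
):
    """Yield ``n`` synthetic SNV records at distinct loci (capacity testing:
    the records are valid but carry no planted biology or tags).

    Positions are laid out deterministically — contigs round-robin, strided
    so loci never collide — and alleles/counts come from the seeded RNG.
    """
    from .datamodel import ReferenceLocus, Variant, VariantType

    rng = np.random.default_rng(seed)
    names = list(contig_lengths)
    per = -(-n // len(names))
    alts = rng.integers(0, 3, size=n)
    refs = rng.integers(0, 4, size=n)
    depths = rng.integers(5, 60, size=n)
    k = 0
    for contig in names:
        stride = max(1, contig_lengths[contig] // per)
        for i in range(per):
            if k >= n:
                return
            ref = BASES[refs[k]]
            alt = BASES[(refs[k] + 1 + alts[k]) % 4]
            depth = int(depths[k])
            yield Variant(
                locus=ReferenceLocus(contig, i * stride),
                stop=i * stride + 1,
                variant_type=VariantType.SNV,
                ref_allele=ref,
                alt_allele=alt,
                observation_count=max(1, depth // 3),
                depth=depth,
                genome_label=genome_label,
            )
            k += 1


def random_read_bases(rng, depth: int) -> str:
    """A random grammar-valid read-bases string with exactly ``depth`` base
    calls — the fuzzer behind the tokenizer-conservation property."""
    tokens = []
    for _ in range(depth):
        r = rng.random()
        if r < 0.55:
            t = "." if rng.random() < 0.5 else ","
        elif r < 0.8:
            t = _case(rng, BASES[int(rng.integers(0, 4))])
        elif r < 0.87:
            t = "*"
        else:
            length = 1 + int(rng.integers(0, 4))
            seq = "".join(
                _case(rng, BASES[int(rng.integers(0, 4))]) for _ in range(length)
            )
            t = ("." if rng.random() < 0.5 else ",") + (
                "+" if rng.random() < 0.5 else "-"
            ) + str(length) + seq
        tokens.append(_decorate(rng, t))
    return "".join(tokens)
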