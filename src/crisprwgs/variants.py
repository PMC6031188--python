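"""Variant representation, normalization, VCF I/O and multi-caller consensus.

Variants use the VCF convention throughout: 1-based positions, explicit REF and
ALT alleles with an anchor base for indels. All set operations (caller
intersection, control subtraction, replicate overlap) are defined on the
*normalized* key ``(chrom, pos, ref, alt)``: left-aligned, with any shared
suffix removed and at most one shared leading (anchor) base for indels. Two
VCF records that describe the same physical edit therefore always collide to
one key, which is what makes a strict multi-caller intersection meaningful.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Variant",
    "VariantCall",
    "SampleVariantSet",
    "LedgerEntry",
    "normalize_variant",
    "read_vcf",
    "write_vcf",
    "intersect_callers",
    "af_filter",
    "subtract_controls",
]


@dataclass(frozen=True, order=True)
class Variant:
    """A normalized genomic change in VCF coordinates (1-based ``pos``)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("empty allele; VCF alleles require an anchor base")

    @property
    def kind(self) -> str:
        """One of ``SNV``, ``INS``, ``DEL`` (complex substitutions count by net length)."""
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def interval(self) -> tuple[int, int]:
        """0-based half-open reference interval affected by this variant."""
        start = self.pos - 1
        return (start, start + len(self.ref))


@dataclass(frozen=True)
class VariantCall:
    """A variant observed in one sample by one caller, with AF and depth."""

    variant: Variant
    sample_id: str
    caller_id: str
    af: float
    depth: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.af <= 1.0:
            raise ValueError(f"allele frequency {self.af} outside [0, 1]")
        if self.depth < 0:
            raise ValueError(f"negative depth {self.depth}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.variant.key


@dataclass
class SampleVariantSet:
    """All calls for one sample, keyed by normalized variant identity.

    ``group`` optionally records the cohort group the sample belongs to
    (e.g. ``TC_only``); control subtraction uses it to tag absorbed variants.
    """

    sample_id: str
    calls: dict[tuple[str, int, str, str], VariantCall] = field(default_factory=dict)
    group: str | None = None

    def add(self, call: VariantCall) -> None:
        if call.sample_id != self.sample_id:
            raise ValueError(
                f"call for sample {call.sample_id!r} added to set {self.sample_id!r}"
            )
        self.calls[call.key] = call

    def __len__(self) -> int:
        return len(self.calls)

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self.calls

    def __iter__(self):
        return iter(self.calls.values())

    def keys(self):
        return self.calls.keys()

    def sorted_calls(self) -> list[VariantCall]:
        return [self.calls[k] for k in sorted(self.calls)]


@dataclass(frozen=True)
class LedgerEntry:
    """A variant removed by control subtraction, with the absorbing group."""

    call: VariantCall
    absorbed_by_group: str


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_variant(v: Variant, genome) -> Variant:
    """Left-align and minimalize a variant against the reference.

    Implements the standard normalization loop: while both alleles end with
    the same base, truncate it (left-extending with the preceding reference
    base whenever an allele would become empty), then strip shared leading
    bases down to a single anchor. Idempotent; raises ``ValueError`` when
    the REF allele does not match the reference sequence.
    """
    seq = genome.sequences[v.chrom]
    pos, ref, alt = v.pos, v.ref, v.alt
    if seq[pos - 1 : pos - 1 + len(ref)] != ref:
        raise ValueError(
            f"REF mismatch at {v.chrom}:{pos}: variant says {ref!r}, "
            f"reference has {seq[pos - 1 : pos - 1 + len(ref)]!r}"
        )
    while ref[-1] == alt[-1]:
        if len(ref) == 1 or len(alt) == 1:
            if pos == 1:
                break
            prev = seq[pos - 2]
            ref, alt, pos = prev + ref, prev + alt, pos - 1
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return Variant(v.chrom, pos, ref, alt)


def normalize_set(s: SampleVariantSet, genome) -> SampleVariantSet:
    """Normalize every call in a sample set; collisions keep the higher-AF call."""
    out = SampleVariantSet(s.sample_id, group=s.group)
    for call in s:
        norm = normalize_variant(call.variant, genome)
        key = norm.key
        cand = replace(call, variant=norm)
        if key in out.calls and out.calls[key].af >= cand.af:
            continue
        out.calls[key] = cand
    return out


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    sample_id: str,
    caller_id: str,
    genome=None,
    require_af: bool = True,
) -> SampleVariantSet:
    """Read one caller's VCF into a :class:`SampleVariantSet`.

    AF and DP are taken from FORMAT when present, falling back to INFO; AF is
    imputed from AD (alt / total) when only AD is available. Multi-allelic
    records are split into one call per ALT. When ``genome`` is given, calls
    are normalized on the way in.
    """
    from cyvcf2 import VCF

    out = SampleVariantSet(sample_id)
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            afs = _record_afs(rec, require_af)
            dp = _record_dp(rec)
            for i, alt in enumerate(rec.ALT):
                if alt is None or alt in {".", "*"} or "<" in alt:
                    continue
                v = Variant(rec.CHROM, rec.POS, rec.REF, alt)
                if genome is not None:
                    v = normalize_variant(v, genome)
                af = afs[i] if i < len(afs) else afs[-1]
                out.add(VariantCall(v, sample_id, caller_id, af, dp))
    finally:
        vcf.close()
    return out


def _fmt(rec, field):
    try:
        return rec.format(field)
    except KeyError:  # field absent from the header FORMAT definitions
        return None


def _record_afs(rec, require_af: bool) -> list[float]:
    n_alt = len(rec.ALT)
    af = _fmt(rec, "AF")
    if af is not None:
        vals = [float(x) for x in af[0][:n_alt]]
        if vals:
            return vals
    ad = _fmt(rec, "AD")
    if ad is not None:
        counts = [float(x) for x in ad[0]]
        total = sum(c for c in counts if c >= 0)
        if total > 0:
            return [max(0.0, counts[i + 1]) / total for i in range(n_alt)]
    info_af = rec.INFO.get("AF")
    if info_af is not None:
        if isinstance(info_af, (tuple, list)):
            return [float(x) for x in info_af]
        return [float(info_af)] * n_alt
    if require_af:
        raise ValueError(f"no AF, AD or INFO/AF at {rec.CHROM}:{rec.POS}")
    return [0.0] * n_alt


def _record_dp(rec) -> int:
    dp = _fmt(rec, "DP")
    if dp is not None and int(dp[0][0]) >= 0:
        return int(dp[0][0])
    info_dp = rec.INFO.get("DP")
    return int(info_dp) if info_dp is not None else 0


def write_vcf(path: str | Path, s: SampleVariantSet, genome) -> None:
    """Write a sample set as a sorted single-sample VCF 4.2 with FORMAT DP/AF."""
    import pysam

    header = pysam.VariantHeader()
    for name, length in genome.lengths.items():
        header.contigs.add(name, length=length)
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AF", "A", "Float", "Allele frequency")
    header.add_sample(s.sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in s.sorted_calls():
            v = call.variant
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                alleles=(v.ref, v.alt),
            )
            rec.samples[s.sample_id]["DP"] = call.depth
            rec.samples[s.sample_id]["AF"] = call.af
            out.write(rec)


# ---------------------------------------------------------------------------
# Consensus and filtering
# ---------------------------------------------------------------------------

def intersect_callers(sets: Sequence[SampleVariantSet]) -> SampleVariantSet:
    """Strict intersection across callers for one sample.

    A variant is retained only when its normalized key appears in *every*
    caller set; the consensus call carries the median AF and median depth
    across callers (robust to a single outlier caller).
    """
    if len(sets) < 2:
        raise ValueError("consensus requires at least two caller sets")
    sample_ids = {s.sample_id for s in sets}
    if len(sample_ids) != 1:
        raise ValueError(f"mixed sample_ids in consensus input: {sorted(sample_ids)}")
    shared = set(sets[0].keys())
    for s in sets[1:]:
        shared &= set(s.keys())
    out = SampleVariantSet(sets[0].sample_id, group=sets[0].group)
    for key in shared:
        calls = [s.calls[key] for s in sets]
        out.calls[key] = VariantCall(
            variant=calls[0].variant,
            sample_id=out.sample_id,
            caller_id="consensus",
            af=float(statistics.median(c.af for c in calls)),
            depth=int(statistics.median(c.depth for c in calls)),
        )
    return out


def af_filter(s: SampleVariantSet, min_af: float = 0.10) -> SampleVariantSet:
    """Drop calls whose allele frequency falls below ``min_af``.

    The floor is inclusive: a call at exactly ``min_af`` is retained; only
    frequencies strictly below it are treated as possible sequencing noise.
    """
    if not 0.0 <= min_af <= 1.0:
        raise ValueError(f"min_af {min_af} outside [0, 1]")
    out = SampleVariantSet(s.sample_id, group=s.group)
    for call in s:
        if call.af >= min_af:
            out.calls[call.key] = call
    return out


def subtract_controls(
    s: SampleVariantSet,
    controls: Sequence[SampleVariantSet],
) -> tuple[SampleVariantSet, list[LedgerEntry]]:
    """Remove variants present in any control set.

    Returns the surviving set plus a ledger of removed calls, each tagged with
    the group (falling back to the sample id) of the first control that
    contains it. Conservation: ``len(s) == len(kept) + len(ledger)``.
    """
    kept = SampleVariantSet(s.sample_id, group=s.group)
    ledger: list[LedgerEntry] = []
    for call in s:
        absorbed = None
        for ctrl in controls:
            if call.key in ctrl:
                absorbed = ctrl.group or ctrl.sample_id
                break
        if absorbed is None:
            kept.calls[call.key] = call
        else:
            ledger.append(LedgerEntry(call, absorbed))
    return kept, ledger
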