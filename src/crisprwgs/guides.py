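"""Protospacer + PAM genome scanning with seed and bulge rules.

Finds every genomic site matching a guide's protospacer within a mismatch
budget, subject to an exact IUPAC PAM match (Cas-OFFinder-style exhaustive
scan, vectorized with numpy), counts mismatches falling in the PAM-proximal
seed, aligns mutation flanks to the guide allowing a single 1-nt bulge, and
applies the seed-based guide-safety rule: a guide is considered safe when
every potential off-target site within a 3-mismatch budget carries at least
2 mismatches in the seed.

Coordinates are 0-based half-open internally; report writers convert to
1-based. Cas9 PAMs sit 3' of the protospacer (NGG, optionally NAG), Cpf1
PAMs 5' (TTTV). Ambiguous reference bases (N) never match a protospacer
position, and PAM IUPAC codes treat reference N pessimistically (no match).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GuideSpec",
    "SiteMatch",
    "FlankHit",
    "GuideSafety",
    "find_sites",
    "count_seed_mismatches",
    "flank_align",
    "guide_specificity",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}  # N -> 0: never matches

DEFAULT_PAMS = {"Cas9": ("NGG",), "Cpf1": ("TTTV",)}
PROTOSPACER_LEN = {"Cas9": 20, "Cpf1": 23}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GuideSpec:
    """A guide RNA: protospacer sequence, nuclease, and PAM rule.

    ``pam_patterns`` are IUPAC strings in the orientation fixed by the
    nuclease (3' of the protospacer for Cas9, 5' for Cpf1); the first
    pattern is the canonical PAM.
    """

    guide_id: str
    protospacer: str
    nuclease: str = "Cas9"
    pam_patterns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.nuclease not in ("Cas9", "Cpf1"):
            raise ValueError(f"unknown nuclease {self.nuclease!r}")
        if set(self.protospacer) - set("ACGT"):
            raise ValueError(f"protospacer contains non-ACGT: {self.protospacer!r}")
        if not self.pam_patterns:
            object.__setattr__(self, "pam_patterns", DEFAULT_PAMS[self.nuclease])
        for pat in self.pam_patterns:
            if set(pat) - set(IUPAC):
                raise ValueError(f"invalid IUPAC PAM pattern {pat!r}")

    @property
    def pam_is_5prime(self) -> bool:
        return self.nuclease == "Cpf1"

    @property
    def pam_len(self) -> int:
        return len(self.pam_patterns[0])

    @property
    def site_len(self) -> int:
        return len(self.protospacer) + self.pam_len


@dataclass(frozen=True)
class SiteMatch:
    """A genomic locus matching a guide within the mismatch budget.

    ``start``/``end`` are the 0-based half-open interval of protospacer+PAM
    on the reference; ``mismatch_positions`` are 1-based distances from the
    PAM of each mismatched protospacer position (position 1 = adjacent to
    the PAM), so seed mismatches at any seed length can be recounted.
    """

    chrom: str
    start: int
    end: int
    strand: str
    guide_id: str
    n_mismatch: int
    seed_mismatch: int
    pam_observed: str
    pam_canonical: bool
    mismatch_positions: tuple[int, ...] = ()

    def protospacer_interval(self, guide: GuideSpec) -> tuple[int, int]:
        """Reference interval of the protospacer part of this site."""
        plen = guide.pam_len
        pam_at_left = guide.pam_is_5prime if self.strand == "+" else not guide.pam_is_5prime
        if pam_at_left:
            return (self.start + plen, self.end)
        return (self.start, self.end - plen)

    def cut_position(self, guide: GuideSpec) -> int:
        """Predicted nuclease cut coordinate (0-based, within the protospacer).

        Cas9 cuts bluntly 3 bp from the PAM; Cpf1 cuts in a staggered
        fashion ~18 bp from the PAM (PAM-distal part of the protospacer).
        """
        ps, pe = self.protospacer_interval(guide)
        # distance of the cut from the PAM-proximal protospacer end
        offset = 3 if guide.nuclease == "Cas9" else 18
        pam_proximal_right = (self.strand == "+") != guide.pam_is_5prime
        return pe - offset if pam_proximal_right else ps + offset


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _bits(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for base, bit in _BASE_BITS.items():
        lut[ord(base)] = bit
    return lut[arr]


def _pam_mask(pattern: str) -> list[int]:
    return [sum(_BASE_BITS[b] for b in IUPAC[c]) for c in pattern]


def _scan_strand(
    bits: np.ndarray, guide: GuideSpec, max_mismatch: int
) -> Iterable[tuple[int, int]]:
    """Yield (window_start, n_mismatch) on the scanned (forward-frame) sequence."""
    proto = guide.protospacer
    w = guide.site_len
    n = len(bits) - w + 1
    if n <= 0:
        return
    if guide.pam_is_5prime:
        pam_off, proto_off = 0, guide.pam_len
    else:
        pam_off, proto_off = len(proto), 0
    pam_ok = np.zeros(n, dtype=bool)
    for pattern in guide.pam_patterns:
        ok = np.ones(n, dtype=bool)
        for j, mask in enumerate(_pam_mask(pattern)):
            ok &= (bits[pam_off + j : pam_off + j + n] & mask) != 0
        pam_ok |= ok
    mm = np.zeros(n, dtype=np.int16)
    for k, base in enumerate(proto):
        mm += (bits[proto_off + k : proto_off + k + n] & _BASE_BITS[base]) == 0
    hits = np.nonzero(pam_ok & (mm <= max_mismatch))[0]
    for i in hits:
        yield int(i), int(mm[i])


def _matches_iupac(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in IUPAC[c] for b, c in zip(seq, pattern)
    )


def _mismatch_positions_from_pam(window_proto: str, proto: str, pam_proximal_right: bool) -> tuple[int, ...]:
    """1-based distances from the PAM of mismatched protospacer positions."""
    L = len(proto)
    out = []
    for k in range(L):
        if window_proto[k] != proto[k]:
            out.append(L - k if pam_proximal_right else k + 1)
    return tuple(sorted(out))


def find_sites(
    genome,
    guide: GuideSpec,
    max_mismatch: int,
    seed_len: int = 18,
) -> list[SiteMatch]:
    """Exhaustive both-strand scan for guide matches under the PAM rule.

    Reports every window where one of the guide's PAM patterns matches
    exactly (IUPAC-expanded) and the protospacer Hamming distance is at most
    ``max_mismatch``; overlapping matches are kept independently. Sorted by
    (chrom, start, strand).
    """
    if max_mismatch > len(guide.protospacer):
        raise ValueError("max_mismatch exceeds protospacer length")
    sites: list[SiteMatch] = []
    w = guide.site_len
    for chrom in sorted(genome.sequences):
        seq = genome.sequences[chrom]
        L = len(seq)
        for strand, frame in (("+", seq), ("-", reverse_complement(seq))):
            bits = _bits(frame)
            for i, n_mm in _scan_strand(bits, guide, max_mismatch):
                start = i if strand == "+" else L - i - w
                window = frame[i : i + w]
                if guide.pam_is_5prime:
                    pam, proto_seq = window[: guide.pam_len], window[guide.pam_len :]
                else:
                    pam, proto_seq = window[len(guide.protospacer) :], window[: len(guide.protospacer)]
                # PAM-proximal end of the protospacer in scan frame: right for
                # 3'-PAM nucleases, left for 5'-PAM.
                mm_pos = _mismatch_positions_from_pam(
                    proto_seq, guide.protospacer, pam_proximal_right=not guide.pam_is_5prime
                )
                sites.append(
                    SiteMatch(
                        chrom=chrom,
                        start=start,
                        end=start + w,
                        strand=strand,
                        guide_id=guide.guide_id,
                        n_mismatch=n_mm,
                        seed_mismatch=sum(1 for p in mm_pos if p <= seed_len),
                        pam_observed=pam,
                        pam_canonical=_matches_iupac(pam, guide.pam_patterns[0]),
                        mismatch_positions=mm_pos,
                    )
                )
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


def count_seed_mismatches(site: SiteMatch, guide: GuideSpec, seed_len: int = 18) -> int:
    """Mismatches within the ``seed_len`` PAM-proximal protospacer positions."""
    if seed_len > len(guide.protospacer):
        raise ValueError("seed_len exceeds protospacer length")
    return sum(1 for p in site.mismatch_positions if p <= seed_len)


# ---------------------------------------------------------------------------
# Flank alignment (bulge-aware)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlankHit:
    """A local alignment of the protospacer against a mutation flank."""

    strand: str
    flank_start: int
    flank_end: int
    matches: int
    mismatches: int
    bulges: int
    bulge_type: str | None  # "dna": extra base in the DNA; "rna": base missing from DNA
    score: float


_GAP_PENALTY = 1.5  # one bulge outranks two mismatches (match=1, mismatch=0)


def flank_align(flank: str, guide: GuideSpec, min_match: int = 15) -> list[FlankHit]:
    """Align the protospacer to a mutation-flanking sequence, both strands.

    Enumerates every ungapped offset plus every placement of a single 1-nt
    bulge: an extra base in the DNA (skipped flank base) or a base missing
    from the DNA (skipped guide base). Hits with fewer than ``min_match``
    matching bases are suppressed; surviving hits are culled greedily by
    score so overlapping shadows of a better alignment are not reported.
    """
    flank = flank.upper()
    proto = guide.protospacer
    P = len(proto)
    raw: list[FlankHit] = []
    for strand, query in (("+", proto), ("-", reverse_complement(proto))):
        F = len(flank)
        # ungapped
        for off in range(F - P + 1):
            m = sum(1 for a, b in zip(flank[off : off + P], query) if a == b)
            raw.append(FlankHit(strand, off, off + P, m, P - m, 0, None, float(m)))
        # DNA bulge: alignment spans P+1 flank bases, one interior flank base unpaired
        for off in range(F - P):
            window = flank[off : off + P + 1]
            for g in range(1, P):  # skipped flank index within window
                aligned = window[:g] + window[g + 1 :]
                m = sum(1 for a, b in zip(aligned, query) if a == b)
                raw.append(
                    FlankHit(strand, off, off + P + 1, m, P - m, 1, "dna", m - _GAP_PENALTY)
                )
        # RNA bulge: one interior guide base unpaired, alignment spans P-1 flank bases
        for off in range(F - (P - 1) + 1):
            window = flank[off : off + P - 1]
            for g in range(1, P - 1):  # skipped guide index
                q = query[:g] + query[g + 1 :]
                m = sum(1 for a, b in zip(window, q) if a == b)
                raw.append(
                    FlankHit(strand, off, off + P - 1, m, (P - 1) - m, 1, "rna", m - _GAP_PENALTY)
                )
    raw = [h for h in raw if h.matches >= min_match]
    raw.sort(key=lambda h: (-h.score, h.bulges, h.flank_start, h.strand))
    kept: list[FlankHit] = []
    for h in raw:
        if any(
            k.strand == h.strand and h.flank_start < k.flank_end and k.flank_start < h.flank_end
            for k in kept
        ):
            continue
        kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# Guide safety
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuideSafety:
    safe: bool
    best_offtarget: SiteMatch | None
    n_offtarget_sites: int


def guide_specificity(
    genome,
    guide: GuideSpec,
    seed_len: int = 18,
    max_mismatch: int = 3,
    extra_pams: Sequence[str] = (),
) -> GuideSafety:
    """Seed-based guide-safety check.

    Scans for every site within ``max_mismatch`` of the protospacer, removes
    one perfect-match site as the intended target, and declares the guide
    safe only when every remaining site carries at least 2 mismatches in the
    ``seed_len`` PAM-proximal positions. Alternative PAMs (e.g. NAG) are off
    by default for design-time safety checks; pass them via ``extra_pams``.
    """
    g = guide
    if extra_pams:
        g = GuideSpec(
            guide.guide_id, guide.protospacer, guide.nuclease,
            tuple(guide.pam_patterns) + tuple(extra_pams),
        )
    sites = find_sites(genome, g, max_mismatch, seed_len=seed_len)
    perfect = [s for s in sites if s.n_mismatch == 0 and s.pam_canonical]
    on_target = perfect[0] if perfect else None
    off = [s for s in sites if s is not on_target]
    unsafe_sites = [s for s in off if s.seed_mismatch < 2]
    best = None
    if off:
        best = min(off, key=lambda s: (s.seed_mismatch, s.n_mismatch, s.chrom, s.start))
    return GuideSafety(safe=not unsafe_sites, best_offtarget=best, n_offtarget_sites=len(off))
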