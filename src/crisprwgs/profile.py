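"""Mutation rates, SNV spectra, allele-frequency bins and feature enrichment.

Per-generation mutation rates are expressed per site per diploid genome, i.e.
``n / (2L x generations)`` — the convention under which 41 spontaneous
mutations on the ~374-Mb rice genome correspond to a rate of ~5.4e-8.
SNV spectra are folded onto the pyrimidine strand (six classes), so G:C>A:T
transitions accumulate under C>T. Allele-frequency bins separate
somatic-like (AF <= 0.25), heterozygous-like and homozygous-like
(AF >= 0.75) mutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variants import Variant, VariantCall

__all__ = [
    "RateEstimate",
    "AFBins",
    "FeatureTrack",
    "SpectrumResult",
    "mutation_rate",
    "snv_spectrum",
    "af_bins",
    "feature_enrichment",
    "RICE_GENOME_BP",
    "FEATURE_PRECEDENCE",
]

# Nipponbare (TIGR7 assembly) nuclear genome size in bp
RICE_GENOME_BP = 374_000_000

# overlapping annotations resolve to the highest-precedence category
FEATURE_PRECEDENCE = ("CDS", "UTR", "intron", "TE", "repeat", "intergenic")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_TRANSITIONS = {"C>T", "T>C"}


@dataclass(frozen=True)
class RateEstimate:
    """A per-site per-diploid-genome per-generation mutation rate."""

    n_mutations: int
    diploid_sites: float
    n_generations: int
    rate: float


def mutation_rate(
    n_mutations: int,
    genome_length_bp: float,
    n_generations: int = 1,
    diploid: bool = True,
) -> RateEstimate:
    """Mutation rate per site per (diploid) genome per generation."""
    if genome_length_bp <= 0:
        raise ValueError("genome length must be positive")
    if n_generations <= 0:
        raise ValueError("generation count must be positive")
    if n_mutations < 0:
        raise ValueError("mutation count must be non-negative")
    sites = (2 if diploid else 1) * float(genome_length_bp)
    return RateEstimate(
        n_mutations=n_mutations,
        diploid_sites=sites,
        n_generations=n_generations,
        rate=n_mutations / (sites * n_generations),
    )


@dataclass(frozen=True)
class SpectrumResult:
    counts: dict[str, int]
    ts_tv: float | None
    gc_to_at_fraction: float | None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def snv_spectrum(variants: Iterable[Variant]) -> SpectrumResult:
    """Six-class pyrimidine-folded SNV spectrum with Ts/Tv ratio.

    Purine-reference changes are complemented onto the pyrimidine strand, so
    a G>A change counts as C>T (a G:C>A:T transition). Raises on non-SNV
    input. Ts/Tv is None for empty input or when no transversions exist.
    """
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for v in variants:
        if v.kind != "SNV":
            raise ValueError(f"non-SNV in spectrum input: {v}")
        ref, alt = v.ref, v.alt
        if ref in "AG":
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts[f"{ref}>{alt}"] += 1
    total = sum(counts.values())
    ts = sum(counts[c] for c in _TRANSITIONS)
    tv = total - ts
    return SpectrumResult(
        counts=counts,
        ts_tv=(ts / tv) if tv > 0 else None,
        gc_to_at_fraction=(counts["C>T"] / total) if total else None,
    )


@dataclass(frozen=True)
class AFBins:
    """Allele-frequency classification of a call set.

    ``somatic_like``: AF in [0, 0.25]; ``heterozygous_like``: (0.25, 0.75);
    ``homozygous_like``: [0.75, 1.0]. Boundaries assign 0.25 downward and
    0.75 upward; counts sum to the input size.
    """

    somatic_like: int
    heterozygous_like: int
    homozygous_like: int

    @property
    def total(self) -> int:
        return self.somatic_like + self.heterozygous_like + self.homozygous_like


def af_bins(calls: Iterable[VariantCall | float]) -> AFBins:
    """Bin calls (or raw AF values) into somatic/heterozygous/homozygous-like."""
    som = het = hom = 0
    for c in calls:
        af = c.af if hasattr(c, "af") else float(c)
        if not 0.0 <= af <= 1.0:
            raise ValueError(f"allele frequency {af} outside [0, 1]")
        if af <= 0.25:
            som += 1
        elif af < 0.75:
            het += 1
        else:
            hom += 1
    return AFBins(som, het, hom)


@dataclass
class FeatureTrack:
    """Genome annotation with per-category genomic fractions.

    Intervals are 0-based half-open ``(chrom, start, end, category)``.
    Overlaps resolve by :data:`FEATURE_PRECEDENCE` (CDS wins over UTR, etc.);
    uncovered sequence counts as intergenic.
    """

    intervals: list[tuple[str, int, int, str]]
    genome_lengths: dict[str, int]
    genomic_fraction: dict[str, float]
    _paint: dict[str, np.ndarray]

    @classmethod
    def from_intervals(
        cls,
        intervals: Sequence[tuple[str, int, int, str]],
        genome_lengths: Mapping[str, int],
    ) -> "FeatureTrack":
        rank = {c: i for i, c in enumerate(FEATURE_PRECEDENCE)}
        paint = {
            chrom: np.full(length, rank["intergenic"], dtype=np.int8)
            for chrom, length in genome_lengths.items()
        }
        # paint from lowest precedence upward so higher categories overwrite
        for chrom, start, end, cat in sorted(
            intervals, key=lambda iv: -rank.get(iv[3], len(rank))
        ):
            if cat not in rank:
                raise ValueError(f"unknown feature category {cat!r}")
            if chrom in paint:
                arr = paint[chrom]
                arr[max(0, start) : min(len(arr), end)] = np.minimum(
                    arr[max(0, start) : min(len(arr), end)], rank[cat]
                )
        total = sum(genome_lengths.values())
        fraction = {
            cat: sum(int((arr == rank[cat]).sum()) for arr in paint.values()) / total
            for cat in FEATURE_PRECEDENCE
        }
        return cls(list(intervals), dict(genome_lengths), fraction, paint)

    @classmethod
    def from_bed(cls, path, genome_lengths: Mapping[str, int]) -> "FeatureTrack":
        """BED with the category in the name (4th) column."""
        intervals = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, start, end, cat = line.split()[:4]
                intervals.append((chrom, int(start), int(end), cat))
        return cls.from_intervals(intervals, genome_lengths)

    @classmethod
    def from_gff3(cls, path, genome_lengths: Mapping[str, int]) -> "FeatureTrack":
        """GFF3 whose feature types map onto the track categories.

        Recognizes CDS, five_prime_UTR/three_prime_UTR (UTR), intron,
        transposable_element* (TE) and *repeat* types; others are ignored.
        """
        type_map = {
            "CDS": "CDS",
            "five_prime_UTR": "UTR",
            "three_prime_UTR": "UTR",
            "intron": "intron",
        }
        intervals = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 5:
                    continue
                chrom, _, ftype, start, end = parts[:5]
                cat = type_map.get(ftype)
                if cat is None:
                    low = ftype.lower()
                    if "transposable" in low or low == "te":
                        cat = "TE"
                    elif "repeat" in low:
                        cat = "repeat"
                if cat is not None:
                    intervals.append((chrom, int(start) - 1, int(end), cat))
        return cls.from_intervals(intervals, genome_lengths)

    def category_at(self, chrom: str, pos0: int) -> str:
        arr = self._paint.get(chrom)
        if arr is None or not 0 <= pos0 < len(arr):
            return "intergenic"
        return FEATURE_PRECEDENCE[int(arr[pos0])]


def feature_enrichment(
    variants: Iterable[Variant],
    track: FeatureTrack,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Observed vs expected variant counts per feature category.

    Expected counts follow the genomic fraction of each category; p-values
    come from a two-sided binomial test, Benjamini-Hochberg corrected across
    the categories. Variants are located by their leftmost affected base.
    """
    from statsmodels.stats.multitest import multipletests

    observed = {c: 0 for c in FEATURE_PRECEDENCE}
    n = 0
    for v in variants:
        observed[track.category_at(v.chrom, v.pos - 1)] += 1
        n += 1
    rows = []
    for cat in FEATURE_PRECEDENCE:
        frac = track.genomic_fraction[cat]
        exp = n * frac
        obs = observed[cat]
        if n == 0:
            p = np.nan
        elif frac in (0.0, 1.0):
            p = 1.0 if obs == exp else 0.0
        else:
            p = stats.binomtest(obs, n, frac).pvalue
        rows.append(
            {
                "category": cat,
                "observed": obs,
                "expected": exp,
                "enrichment": (obs / exp) if exp > 0 else np.nan,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows).set_index("category")
    mask = df["p_value"].notna()
    df["p_adjusted"] = np.nan
    if mask.any():
        df.loc[mask, "p_adjusted"] = multipletests(
            df.loc[mask, "p_value"], alpha=alpha, method="fdr_bh"
        )[1]
    return df
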