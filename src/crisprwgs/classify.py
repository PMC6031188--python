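"""Provenance classification of post-subtraction variants.

Assigns each variant one of six classes using three orthogonal lines of
evidence: membership in a control cohort (pre-existing or culture-induced
background), overlap with a guide-homologous genomic site, and behaviour
across independently edited replicate lines. The key biological signal is
allele identity: a locus edited independently in two lines carries distinct
indel alleles with high probability, whereas an inherited mutation is
identical in both — so shared-identical-allele variants with poor guide
homology are adjudicated as pre-existing, and site-assigned indels with
distinct alleles across lines as true off-target edits.

Off-target validation is deliberately restricted to indels: nuclease repair
products at verified off-target loci are overwhelmingly indels, and an excess
of SNVs at a candidate locus argues against nuclease origin. SNVs overlapping
a site are reported as candidates with a warning tag, never validated.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .guides import GuideSpec, SiteMatch
from .variants import LedgerEntry, SampleVariantSet, VariantCall

__all__ = [
    "ClassifiedVariant",
    "ReplicatePair",
    "OverlapResult",
    "assign_to_sites",
    "replicate_overlap",
    "classify",
    "summarize_guides",
]

CLASSES = (
    "pre_existing",
    "background",
    "spontaneous",
    "on_target",
    "off_target_candidate",
    "off_target_validated",
)

# control groups whose absorption implies inherited rather than induced origin
PEDIGREE_GROUPS = {"WT_G1", "WT_G2", "WT_G3", "parent"}


@dataclass(frozen=True)
class ClassifiedVariant:
    call: VariantCall
    klass: str
    site: SiteMatch | None
    evidence: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.klass not in CLASSES:
            raise ValueError(f"unknown class {self.klass!r}")
        if self.klass in ("on_target", "off_target_candidate", "off_target_validated"):
            if self.site is None:
                raise ValueError(f"class {self.klass} requires a site")
        if not self.evidence:
            raise ValueError("evidence trail must be non-empty")


@dataclass
class ReplicatePair:
    """Two post-subtraction variant sets from independent lines, same guide."""

    sample_a: SampleVariantSet
    sample_b: SampleVariantSet
    guide_id: str

    def __post_init__(self) -> None:
        if self.sample_a.sample_id == self.sample_b.sample_id:
            raise ValueError("replicate pair requires two distinct samples")


@dataclass
class OverlapResult:
    shared: set
    unique_a: set
    unique_b: set
    shared_loci: list[tuple[SiteMatch, tuple, tuple]] = field(default_factory=list)


def _site_key(site: SiteMatch) -> tuple:
    return (site.chrom, site.start, site.end, site.strand)


def assign_to_sites(
    variants: SampleVariantSet,
    sites: Sequence[SiteMatch],
    window: int = 5,
) -> dict[tuple, SiteMatch | None]:
    """Map each variant to the best overlapping guide site, or None.

    A variant is assigned when its affected reference interval intersects a
    site's protospacer+PAM interval expanded by ``window`` bp on each side.
    Ties between overlapping sites break toward lowest mismatch count, then
    lowest seed-mismatch count, then leftmost position.
    """
    by_chrom: dict[str, list[SiteMatch]] = defaultdict(list)
    for s in sites:
        by_chrom[s.chrom].append(s)
    out: dict[tuple, SiteMatch | None] = {}
    for call in variants:
        v = call.variant
        vs, ve = v.interval()
        hits = [
            s for s in by_chrom.get(v.chrom, ())
            if vs < s.end + window and s.start - window < ve
        ]
        if hits:
            best = min(hits, key=lambda s: (s.n_mismatch, s.seed_mismatch, s.start))
            out[v.key] = best
        else:
            out[v.key] = None
    return out


def replicate_overlap(
    pair: ReplicatePair,
    site_map_a: Mapping[tuple, SiteMatch | None] | None = None,
    site_map_b: Mapping[tuple, SiteMatch | None] | None = None,
) -> OverlapResult:
    """Partition two replicate variant sets by exact normalized key.

    When site assignments are supplied, loci edited in both lines with
    *different* alleles (same site, no shared key) are reported separately in
    ``shared_loci`` — the replicate signature of genuine nuclease activity.
    """
    keys_a, keys_b = set(pair.sample_a.keys()), set(pair.sample_b.keys())
    res = OverlapResult(
        shared=keys_a & keys_b,
        unique_a=keys_a - keys_b,
        unique_b=keys_b - keys_a,
    )
    if site_map_a and site_map_b:
        sites_a: dict[tuple, list] = defaultdict(list)
        sites_b: dict[tuple, list] = defaultdict(list)
        for k in res.unique_a:
            s = site_map_a.get(k)
            if s is not None:
                sites_a[_site_key(s)].append(k)
        for k in res.unique_b:
            s = site_map_b.get(k)
            if s is not None:
                sites_b[_site_key(s)].append(k)
        for sk in sorted(set(sites_a) & set(sites_b)):
            site = next(
                s for m in (site_map_a, site_map_b) for s in m.values()
                if s is not None and _site_key(s) == sk
            )
            res.shared_loci.append(
                (site, tuple(sorted(sites_a[sk])), tuple(sorted(sites_b[sk])))
            )
    return res


def classify(
    variants: SampleVariantSet,
    site_map: Mapping[tuple, SiteMatch | None],
    target_site: SiteMatch | None,
    controls_ledger: Sequence[LedgerEntry] = (),
    replicate: SampleVariantSet | None = None,
    replicate_site_map: Mapping[tuple, SiteMatch | None] | None = None,
    homology_budget: int = 6,
    validation_homology: int = 3,
) -> list[ClassifiedVariant]:
    """Assign a provenance class to every variant of one sample.

    Decision order:

    1. variants absorbed by a control (from the subtraction ledger) are
       ``pre_existing`` when the absorbing group is a wild-type/pedigree
       sample, else ``background``;
    2. variants assigned to the declared target site are ``on_target``;
    3. indels assigned to another guide-homologous site become
       ``off_target_candidate``, promoted to ``off_target_validated`` when
       the same site is edited in the independent replicate with a distinct
       allele, or when the site homology is within ``validation_homology``
       mismatches (the empirical envelope of confirmed off-target loci) and
       the variant survived every control and pedigree subtraction;
    4. variants shared with an identical allele by the independent replicate
       but lacking a site within the homology budget are ``pre_existing``
       (inherited from a common parental line);
    5. everything else is ``spontaneous``.

    The subtraction-ledger entries for the sample are themselves returned as
    classified variants, so class counts over the output sum to the sample's
    pre-subtraction variant count.
    """
    out: list[ClassifiedVariant] = []
    for entry in controls_ledger:
        if entry.call.sample_id != variants.sample_id:
            continue
        pre = entry.absorbed_by_group in PEDIGREE_GROUPS
        out.append(
            ClassifiedVariant(
                entry.call,
                "pre_existing" if pre else "background",
                None,
                (f"in_control:{entry.absorbed_by_group}",),
            )
        )
    target_key = _site_key(target_site) if target_site is not None else None

    rep_keys = set(replicate.keys()) if replicate is not None else set()
    rep_site_alleles: dict[tuple, set] = defaultdict(set)
    if replicate is not None and replicate_site_map is not None:
        for k in replicate.keys():
            s = replicate_site_map.get(k)
            if s is not None:
                rep_site_alleles[_site_key(s)].add(k)

    for call in variants:
        key = call.variant.key
        site = site_map.get(key)
        evidence: list[str] = []
        if site is not None and target_key is not None and _site_key(site) == target_key:
            out.append(ClassifiedVariant(call, "on_target", site, ("target_site_overlap",)))
            continue
        if site is not None and site.n_mismatch <= homology_budget:
            evidence.append(f"site_assigned:mm={site.n_mismatch}")
            if call.variant.kind in ("INS", "DEL"):
                klass = "off_target_candidate"
                rep_alleles = rep_site_alleles.get(_site_key(site), set())
                if rep_alleles and rep_alleles != {key}:
                    klass = "off_target_validated"
                    evidence.append("replicate_distinct_allele")
                elif site.n_mismatch <= validation_homology:
                    klass = "off_target_validated"
                    evidence.append("high_homology_absent_from_controls")
                out.append(ClassifiedVariant(call, klass, site, tuple(evidence)))
                continue
            evidence.append("snv_at_site_warning")
            out.append(ClassifiedVariant(call, "off_target_candidate", site, tuple(evidence)))
            continue
        if key in rep_keys:
            out.append(
                ClassifiedVariant(
                    call, "pre_existing", None,
                    ("shared_identical_allele", "poor_site_homology"),
                )
            )
            continue
        out.append(ClassifiedVariant(call, "spontaneous", None, ("no_site_evidence",)))
    return out


def summarize_guides(
    classified: Mapping[str, Sequence[ClassifiedVariant]],
    sample_guides: Mapping[str, str | None],
) -> dict[str, dict]:
    """Aggregate per-guide off-target evidence across the cohort.

    ``classified`` maps sample_id to that sample's classified variants and
    ``sample_guides`` maps sample_id to its guide (or None for controls).
    A guide is flagged unsafe when at least one off-target locus was
    validated in any of its lines. Counts are locus-level (distinct sites).
    """
    report: dict[str, dict] = {}
    for sid, items in classified.items():
        gid = sample_guides.get(sid)
        if gid is None:
            continue
        rep = report.setdefault(
            gid,
            {
                "guide_id": gid,
                "validated_loci": set(),
                "candidate_loci": set(),
                "n_on_target": 0,
                "n_validated_variants": 0,
                "samples": [],
            },
        )
        if sid not in rep["samples"]:
            rep["samples"].append(sid)
        for cv in items:
            if cv.klass == "on_target":
                rep["n_on_target"] += 1
            elif cv.klass == "off_target_validated":
                rep["validated_loci"].add(_site_key(cv.site))
                rep["n_validated_variants"] += 1
            elif cv.klass == "off_target_candidate":
                rep["candidate_loci"].add(_site_key(cv.site))
    for rep in report.values():
        rep["candidate_loci"] -= rep["validated_loci"]
        rep["n_validated_offtarget_loci"] = len(rep.pop("validated_loci"))
        rep["n_candidate_loci"] = len(rep.pop("candidate_loci"))
        rep["unsafe"] = rep["n_validated_offtarget_loci"] > 0
    return report
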