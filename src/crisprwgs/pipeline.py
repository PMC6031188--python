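"""End-to-end orchestration: consensus -> subtraction -> scan -> classify -> profile.

:func:`analyze_cohort` runs the whole adjudication on in-memory objects (the
form the simulator produces and the tests use); :func:`run_pipeline` is the
file-based wrapper behind the CLI, reading a cohort directory written by the
simulator (or assembled by hand in the same layout) and writing the report
bundle. Every stage logs machine-parsable JSON lines with input/output counts
to stderr.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

from .classify import (
    ClassifiedVariant,
    ReplicatePair,
    assign_to_sites,
    classify,
    replicate_overlap,
    summarize_guides,
)
from .guides import GuideSpec, SiteMatch, find_sites
from .profile import af_bins, mutation_rate, snv_spectrum
from .simulate import BACKGROUND_GROUPS, WT_GROUPS, CohortDesign, ReferenceGenome
from .variants import (
    LedgerEntry,
    SampleVariantSet,
    af_filter,
    intersect_callers,
    normalize_set,
    read_vcf,
    subtract_controls,
)

__all__ = ["PipelineConfig", "CohortResult", "validate_config", "analyze_cohort", "run_pipeline"]

log = logging.getLogger("crisprwgs")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def _stage(stage: str, **counts) -> None:
    log.info(json.dumps({"stage": stage, **counts}, sort_keys=True))


@dataclass
class PipelineConfig:
    """Paths and thresholds for a file-based pipeline run."""

    input_dir: str
    output_dir: str
    min_af: float = 0.10
    homology_budget: int = 6
    validation_homology: int = 3
    seed_len: int = 18
    window: int = 5
    features: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems; empty iff the pipeline can run."""
    problems: list[str] = []
    if not 0.0 <= config.min_af <= 1.0:
        problems.append("min_af out of range [0, 1]")
    if not 0 <= config.validation_homology <= config.homology_budget:
        problems.append("validation_homology must lie in [0, homology_budget]")
    if config.window < 0:
        problems.append("window must be >= 0")
    if config.seed_len < 1:
        problems.append("seed_len must be >= 1")
    indir = Path(config.input_dir)
    for name in ("genome.fa", "design.tsv", "guides.tsv"):
        if not (indir / name).exists():
            problems.append(f"missing input file: {indir / name}")
    if (indir / "vcf").exists():
        if not any((indir / "vcf").glob("*.vcf")):
            problems.append("vcf directory contains no .vcf files")
    else:
        problems.append(f"missing input directory: {indir / 'vcf'}")
    if config.features and not Path(config.features).exists():
        problems.append(f"missing features file: {config.features}")
    return problems


@dataclass
class CohortResult:
    """Everything the adjudication computed for one cohort."""

    consensus: dict[str, SampleVariantSet]
    post_subtraction: dict[str, SampleVariantSet]
    ledgers: dict[str, list[LedgerEntry]]
    sites: dict[str, list[SiteMatch]]
    classified: dict[str, list[ClassifiedVariant]]
    guide_report: dict[str, dict]
    spontaneous_rate: float | None
    sample_profiles: "object"  # pandas DataFrame

    def class_counts(self, sample_id: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for cv in self.classified.get(sample_id, ()):
            out[cv.klass] = out.get(cv.klass, 0) + 1
        return out


def _ancestors(design: CohortDesign, sample_id: str) -> list[str]:
    out = []
    cur = design.by_id(sample_id).parent_id
    while cur is not None:
        out.append(cur)
        cur = design.by_id(cur).parent_id
    return out


def analyze_cohort(
    genome: ReferenceGenome,
    design: CohortDesign,
    guides: Mapping[str, GuideSpec],
    calls: Mapping[str, Sequence[SampleVariantSet]],
    target_sites: Mapping[str, tuple[str, int, str]] | None = None,
    sites: Mapping[str, list[SiteMatch]] | None = None,
    min_af: float = 0.10,
    homology_budget: int = 6,
    validation_homology: int = 3,
    seed_len: int = 18,
    window: int = 5,
) -> CohortResult:
    """Run consensus, subtraction, scanning, classification and profiling.

    ``calls`` maps sample_id to its per-caller variant sets. ``target_sites``
    optionally pins each guide's declared target locus ``(chrom, start,
    strand)``; without it, the perfect-match canonical-PAM site that sorts
    first is taken as the target.
    """
    import pandas as pd

    # --- consensus + AF floor -------------------------------------------------
    consensus: dict[str, SampleVariantSet] = {}
    for spec in design:
        sets = [normalize_set(s, genome) for s in calls[spec.sample_id]]
        cons = af_filter(intersect_callers(sets), min_af)
        cons.group = spec.group
        consensus[spec.sample_id] = cons
        _stage("consensus", sample=spec.sample_id,
               n_in=max(len(s) for s in sets), n_out=len(cons))

    # --- control subtraction --------------------------------------------------
    wt_controls = [consensus[s.sample_id] for s in design if s.group in WT_GROUPS]
    bg_controls = [consensus[s.sample_id] for s in design if s.group in BACKGROUND_GROUPS]
    post: dict[str, SampleVariantSet] = {}
    ledgers: dict[str, list[LedgerEntry]] = {}
    for spec in design:
        if spec.group.startswith("Edited"):
            pedigree = []
            for anc in _ancestors(design, spec.sample_id):
                anc_set = consensus[anc]
                ped = SampleVariantSet(anc_set.sample_id, dict(anc_set.calls), group="parent")
                pedigree.append(ped)
            controls = pedigree + wt_controls + bg_controls
        elif spec.group in WT_GROUPS and spec.parent_id is not None:
            controls = [consensus[a] for a in _ancestors(design, spec.sample_id)]
        else:
            controls = []
        kept, ledger = subtract_controls(consensus[spec.sample_id], controls)
        post[spec.sample_id] = kept
        ledgers[spec.sample_id] = ledger
        _stage("subtract", sample=spec.sample_id,
               n_in=len(consensus[spec.sample_id]), n_out=len(kept), n_absorbed=len(ledger))

    # --- guide scanning -------------------------------------------------------
    if sites is None:
        sites = {
            gid: find_sites(genome, g, homology_budget, seed_len=seed_len)
            for gid, g in guides.items()
        }
    targets: dict[str, SiteMatch] = {}
    for gid, site_list in sites.items():
        _stage("scan", guide=gid, n_sites=len(site_list))
        pinned = (target_sites or {}).get(gid)
        if pinned is not None:
            targets[gid] = next(
                s for s in site_list if (s.chrom, s.start, s.strand) == tuple(pinned)
            )
        else:
            perfect = [s for s in site_list if s.n_mismatch == 0 and s.pam_canonical]
            if not perfect:
                raise ValueError(f"guide {gid}: no perfect-match target site in genome")
            targets[gid] = perfect[0]

    # --- classification -------------------------------------------------------
    replicate_of = {s.sample_id: s.replicate_of for s in design}
    site_maps: dict[str, dict] = {}
    for spec in design:
        if spec.group.startswith("Edited") and spec.guide_id:
            site_maps[spec.sample_id] = assign_to_sites(
                post[spec.sample_id], sites[spec.guide_id], window
            )
    classified: dict[str, list[ClassifiedVariant]] = {}
    for spec in design:
        if not (spec.group.startswith("Edited") and spec.guide_id):
            continue
        rep_id = replicate_of.get(spec.sample_id)
        rep = post.get(rep_id) if rep_id else None
        classified[spec.sample_id] = classify(
            post[spec.sample_id],
            site_maps[spec.sample_id],
            targets[spec.guide_id],
            ledgers[spec.sample_id],
            replicate=rep,
            replicate_site_map=site_maps.get(rep_id) if rep_id else None,
            homology_budget=homology_budget,
            validation_homology=validation_homology,
        )
        _stage("classify", sample=spec.sample_id, n=len(classified[spec.sample_id]))

    sample_guides = {s.sample_id: s.guide_id for s in design}
    guide_report = summarize_guides(classified, sample_guides)

    # --- profiling ------------------------------------------------------------
    rows = []
    for spec in design:
        cons = consensus[spec.sample_id]
        snvs = [c.variant for c in cons if c.variant.kind == "SNV"]
        spec_res = snv_spectrum(snvs)
        bins = af_bins(cons)
        rows.append(
            {
                "sample_id": spec.sample_id,
                "group": spec.group,
                "n_snv": len(snvs),
                "n_indel": len(cons) - len(snvs),
                "ts_tv": spec_res.ts_tv,
                "gc_to_at_fraction": spec_res.gc_to_at_fraction,
                "af_somatic_like": bins.somatic_like,
                "af_heterozygous_like": bins.heterozygous_like,
                "af_homozygous_like": bins.homozygous_like,
            }
        )
    profiles = pd.DataFrame(rows).set_index("sample_id")

    # spontaneous rate from WT parent->child links (new = post-subtraction set)
    link_counts = [
        len(post[s.sample_id]) for s in design
        if s.group in WT_GROUPS and s.parent_id is not None
    ]
    rate = None
    if link_counts:
        total = sum(link_counts)
        rate = mutation_rate(total, genome.total_length, n_generations=len(link_counts)).rate
    _stage("profile", n_samples=len(rows), spontaneous_rate=rate)

    return CohortResult(
        consensus=consensus,
        post_subtraction=post,
        ledgers=ledgers,
        sites=dict(sites),
        classified=classified,
        guide_report=guide_report,
        spontaneous_rate=rate,
        sample_profiles=profiles,
    )


# ---------------------------------------------------------------------------
# File-based wrapper
# ---------------------------------------------------------------------------

def _read_guides_tsv(path: Path) -> tuple[dict[str, GuideSpec], dict[str, tuple[str, int, str]]]:
    guides: dict[str, GuideSpec] = {}
    targets: dict[str, tuple[str, int, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            gid = parts[idx["guide_id"]]
            guides[gid] = GuideSpec(
                gid,
                parts[idx["protospacer"]],
                parts[idx["nuclease"]],
                tuple(parts[idx["pam_patterns"]].split(",")),
            )
            if "target_chrom" in idx and parts[idx["target_chrom"]] not in (".", ""):
                targets[gid] = (
                    parts[idx["target_chrom"]],
                    int(parts[idx["target_start"]]),
                    parts[idx["target_strand"]],
                )
    return guides, targets


def run_pipeline(config: PipelineConfig) -> CohortResult:
    """Run the full pipeline from a cohort directory and write the report bundle.

    Expects ``genome.fa``, ``design.tsv``, ``guides.tsv`` and
    ``vcf/<sample>.<caller>.vcf`` under ``config.input_dir``. Writes per-sample
    classification TSVs, the subtraction ledger, a per-guide JSON summary, a
    per-sample profile TSV and a Markdown summary under ``config.output_dir``.
    Deterministic: identical inputs and config give byte-identical outputs.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid pipeline config: " + "; ".join(problems))
    indir, outdir = Path(config.input_dir), Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = ReferenceGenome.from_fasta(indir / "genome.fa")
    design = CohortDesign.from_tsv(indir / "design.tsv")
    guides, targets = _read_guides_tsv(indir / "guides.tsv")

    calls: dict[str, list[SampleVariantSet]] = {}
    for spec in design:
        paths = sorted((indir / "vcf").glob(f"{spec.sample_id}.*.vcf"))
        if not paths:
            raise FileNotFoundError(f"no caller VCFs for sample {spec.sample_id}")
        calls[spec.sample_id] = [
            read_vcf(p, spec.sample_id, p.stem.split(".")[-1], genome) for p in paths
        ]

    result = analyze_cohort(
        genome, design, guides, calls,
        target_sites=targets or None,
        min_af=config.min_af,
        homology_budget=config.homology_budget,
        validation_homology=config.validation_homology,
        seed_len=config.seed_len,
        window=config.window,
    )
    write_report_bundle(result, outdir)
    return result


def write_report_bundle(result: CohortResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with open(outdir / "classification.tsv", "w") as fh:
        fh.write(
            "sample_id\tchrom\tpos\tref\talt\tkind\tclass\tguide_id\t"
            "site_chrom\tsite_start\tn_mismatch\tseed_mismatch\tpam_observed\tevidence\n"
        )
        for sid in sorted(result.classified):
            for cv in sorted(result.classified[sid], key=lambda c: c.call.variant.key):
                v = cv.call.variant
                s = cv.site
                fh.write(
                    "\t".join(
                        [
                            sid, v.chrom, str(v.pos), v.ref, v.alt, v.kind, cv.klass,
                            s.guide_id if s else ".",
                            s.chrom if s else ".",
                            str(s.start + 1) if s else ".",
                            str(s.n_mismatch) if s else ".",
                            str(s.seed_mismatch) if s else ".",
                            s.pam_observed if s else ".",
                            ",".join(cv.evidence),
                        ]
                    )
                    + "\n"
                )

    with open(outdir / "subtraction_ledger.tsv", "w") as fh:
        fh.write("sample_id\tchrom\tpos\tref\talt\tabsorbed_by_group\n")
        for sid in sorted(result.ledgers):
            for e in sorted(result.ledgers[sid], key=lambda e: e.call.variant.key):
                v = e.call.variant
                fh.write(f"{sid}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{e.absorbed_by_group}\n")

    guide_json = {
        gid: {k: v for k, v in rep.items()}
        for gid, rep in sorted(result.guide_report.items())
    }
    with open(outdir / "guide_summary.json", "w") as fh:
        json.dump(guide_json, fh, indent=2, sort_keys=True)
        fh.write("\n")

    result.sample_profiles.sort_index().to_csv(outdir / "sample_profiles.tsv", sep="\t")

    with open(outdir / "summary.md", "w") as fh:
        fh.write("# Off-target adjudication summary\n\n")
        if result.spontaneous_rate is not None:
            fh.write(
                f"Spontaneous mutation rate: {result.spontaneous_rate:.3g} "
                "per site per diploid genome per generation\n\n"
            )
        fh.write("| guide | validated off-target loci | candidate loci | unsafe |\n")
        fh.write("|---|---|---|---|\n")
        for gid in sorted(result.guide_report):
            rep = result.guide_report[gid]
            fh.write(
                f"| {gid} | {rep['n_validated_offtarget_loci']} | "
                f"{rep['n_candidate_loci']} | {'yes' if rep['unsafe'] else 'no'} |\n"
            )
        total = sum(len(v) for v in result.classified.values())
        fh.write(f"\nClassified variants across edited samples: {total}\n")
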