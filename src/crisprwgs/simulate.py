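"""Synthetic cohorts for whole-genome off-target adjudication.

Generates reference genomes, planted guide targets and off-target sites,
per-sample truth variant sets with the background structure observed in
tissue-culture-regenerated rice (class-specific SNV/indel loads,
heterozygous-like allele frequencies), and noisy per-caller views of each
truth set standing in for independent variant callers.

Randomness is organized as a counter-based stream hierarchy: one top-level
integer seed, with every purpose and every sample drawing from its own
``numpy`` ``SeedSequence`` derived from ``(seed, crc32(tag))``. Adding a
sample to a design therefore never perturbs the variants simulated for
existing samples.

Default mutation loads reflect the cohort the generator emulates: tissue
culture contributes on average 114 SNVs and 36 indels per regenerated plant,
seed propagation 23 SNVs and 18 indels per generation, and Agrobacterium
infection a further ~15-41 indels (modelled as a configurable mean, default
the midpoint 28).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .guides import DEFAULT_PAMS, PROTOSPACER_LEN, GuideSpec, SiteMatch, find_sites, reverse_complement
from .variants import SampleVariantSet, Variant, VariantCall, normalize_variant

__all__ = [
    "ReferenceGenome",
    "MutationLoadModel",
    "CallerEmulationModel",
    "SampleSpec",
    "CohortDesign",
    "TruthVariant",
    "CohortSimulation",
    "simulate_reference",
    "simulate_truth_set",
    "plant_guide_edits",
    "emulate_callers",
    "default_cohort_design",
    "simulate_cohort",
]

BASES = np.array(list("ACGT"))

# groups whose presence in a control set marks a variant as culture/transformation
# background rather than inherited
BACKGROUND_GROUPS = {"TC_only", "Agro", "Cas9_backbone", "Cpf1_backbone"}
WT_GROUPS = {"WT_G1", "WT_G2", "WT_G3"}
VALID_GROUPS = WT_GROUPS | BACKGROUND_GROUPS | {"Edited_T0", "Edited_T1"}

MEAN_DEPTH = 70  # emulated sequencing depth, within the 45-105x cohort range


def _stream(seed: int, *tags) -> np.random.Generator:
    """Independent RNG stream for (seed, tags); stable under cohort growth."""
    keys = [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + keys))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ReferenceGenome:
    """In-memory reference: contig name -> uppercase A/C/G/T string."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if set(seq) - set("ACGTN"):
                raise ValueError(f"contig {name} contains non-ACGTN characters")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.sequences):
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})


@dataclass(frozen=True)
class MutationLoadModel:
    """Expected per-sample mutation load for one cohort class."""

    mean_snv: float
    mean_indel: float
    af_mode: str = "heterozygous"  # heterozygous | somatic | homozygous
    indel_size_range: tuple[int, int] = (1, 15)

    def __post_init__(self) -> None:
        if self.mean_snv < 0 or self.mean_indel < 0:
            raise ValueError("mutation load means must be >= 0")
        lo, hi = self.indel_size_range
        if not (1 <= lo <= hi <= 50):
            raise ValueError("indel_size_range must lie within [1, 50]")
        if self.af_mode not in ("heterozygous", "somatic", "homozygous"):
            raise ValueError(f"unknown af_mode {self.af_mode!r}")


@dataclass(frozen=True)
class CallerEmulationModel:
    """Noise model for emulated variant callers (three by default)."""

    n_callers: int = 3
    fp_rate: float = 1e-5  # false calls per bp per caller
    fn_rate: float = 0.02  # per-caller probability of missing a true variant
    af_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_callers < 2:
            raise ValueError("need at least 2 callers for a consensus")
        for r in (self.fp_rate, self.fn_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


DEFAULT_LOADS: dict[str, MutationLoadModel] = {
    "spontaneous": MutationLoadModel(23, 18),
    "tissue_culture": MutationLoadModel(114, 36),
    "agro_extra": MutationLoadModel(0, 28),
    "founder": MutationLoadModel(50, 15),
}


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    group: str
    guide_id: str | None = None
    replicate_of: str | None = None
    parent_id: str | None = None


@dataclass
class CohortDesign:
    """Sample sheet: groups, replicate links and pedigree links."""

    samples: list[SampleSpec]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("sample_ids are not unique")
        known = set(ids)
        for s in self.samples:
            if s.group not in VALID_GROUPS:
                raise ValueError(f"unknown group {s.group!r} for {s.sample_id}")
            if s.group.startswith("Edited") and not s.guide_id:
                raise ValueError(f"edited sample {s.sample_id} lacks a guide_id")
            if s.parent_id is not None and s.parent_id not in known:
                raise ValueError(f"{s.sample_id}: unknown parent {s.parent_id}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parent = {s.sample_id: s.parent_id for s in self.samples}
        for sid in parent:
            seen = set()
            cur = sid
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"pedigree cycle involving {sid}")
                seen.add(cur)
                cur = parent.get(cur)

    def __iter__(self):
        return iter(self.samples)

    def by_id(self, sample_id: str) -> SampleSpec:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def topological(self) -> list[SampleSpec]:
        """Samples ordered so every parent precedes its descendants."""
        done: dict[str, SampleSpec] = {}
        by_id = {s.sample_id: s for s in self.samples}
        def visit(s: SampleSpec):
            if s.sample_id in done:
                return
            if s.parent_id is not None:
                visit(by_id[s.parent_id])
            done[s.sample_id] = s
        for s in self.samples:
            visit(s)
        return list(done.values())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tgroup\tguide_id\treplicate_of\tparent_id\n")
            for s in self.samples:
                fh.write(
                    f"{s.sample_id}\t{s.group}\t{s.guide_id or '.'}\t"
                    f"{s.replicate_of or '.'}\t{s.parent_id or '.'}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortDesign":
        samples = []
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                sid, group, gid, rep, par = line.rstrip("\n").split("\t")
                samples.append(
                    SampleSpec(
                        sid, group,
                        None if gid == "." else gid,
                        None if rep == "." else rep,
                        None if par == "." else par,
                    )
                )
        return cls(samples)


@dataclass(frozen=True)
class TruthVariant:
    """A simulated true mutation with its provenance class and true AF."""

    variant: Variant
    true_af: float
    klass: str  # pre_existing | tissue_culture | agro | spontaneous | on_target | off_target

    @property
    def key(self):
        return self.variant.key


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------

def simulate_reference(
    n_contigs: int, contig_length: int, gc: float = 0.43, seed: int = 0
) -> ReferenceGenome:
    """IID reference genome with the requested GC content.

    The default GC of 0.43 matches the rice nuclear genome.
    """
    if contig_length < 1000:
        raise ValueError("contig_length must be >= 1000")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie strictly between 0 and 1")
    rng = _stream(seed, "reference")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for i in range(n_contigs):
        draw = rng.choice(4, size=contig_length, p=p)
        seqs[f"chr{i + 1}"] = codes[draw].tobytes().decode("ascii")
    return ReferenceGenome(seqs)


# ---------------------------------------------------------------------------
# Truth sets
# ---------------------------------------------------------------------------

class _Occupied:
    """Tracks reference bp already affected by a simulated variant."""

    def __init__(self) -> None:
        self._used: dict[str, set[int]] = {}

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        used = self._used.get(chrom)
        return used is not None and any(p in used for p in range(start, end))

    def add(self, chrom: str, start: int, end: int) -> None:
        self._used.setdefault(chrom, set()).update(range(start, end))

    def add_variant(self, v: Variant) -> None:
        s, e = v.interval()
        self.add(v.chrom, s, e)


def _draw_af(mode: str, rng: np.random.Generator) -> float:
    if mode == "heterozygous":
        return 0.5
    if mode == "homozygous":
        return 1.0
    return float(rng.uniform(0.0, 0.25))  # somatic


def _random_position(
    genome: ReferenceGenome, rng: np.random.Generator, span: int,
    occupied: _Occupied, exclude: "_Occupied | None",
) -> tuple[str, int]:
    contigs = sorted(genome.sequences)
    lengths = np.array([genome.lengths[c] for c in contigs], dtype=float)
    probs = lengths / lengths.sum()
    for _ in range(10_000):
        chrom = contigs[int(rng.choice(len(contigs), p=probs))]
        L = genome.lengths[chrom]
        if L < span + 2:
            continue
        pos0 = int(rng.integers(1, L - span - 1))  # keep an anchor base to the left
        if occupied.overlaps(chrom, pos0 - 1, pos0 + span + 1):
            continue
        if exclude is not None and exclude.overlaps(chrom, pos0 - 1, pos0 + span + 1):
            continue
        return chrom, pos0
    raise ValueError("could not place variant: genome capacity exceeded")


def _other_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(3))]


def simulate_truth_set(
    genome: ReferenceGenome,
    model: MutationLoadModel,
    seed: int | np.random.Generator = 0,
    klass: str = "spontaneous",
    occupied: _Occupied | None = None,
    exclude: _Occupied | None = None,
) -> list[TruthVariant]:
    """Draw one sample's worth of mutations under a load model.

    SNV and indel counts are Poisson with the model means; positions are
    uniform over the genome without collision (affected intervals never
    overlap, resampled otherwise) and outside any ``exclude`` regions.
    """
    if not genome.sequences:
        raise ValueError("empty genome")
    rng = seed if isinstance(seed, np.random.Generator) else _stream(seed, "truth", klass)
    occupied = occupied if occupied is not None else _Occupied()
    capacity = genome.total_length / 4
    if model.mean_snv + model.mean_indel * 16 > capacity:
        raise ValueError("mutation load exceeds genome capacity")
    out: list[TruthVariant] = []
    n_snv = int(rng.poisson(model.mean_snv))
    n_indel = int(rng.poisson(model.mean_indel))
    for _ in range(n_snv):
        chrom, p0 = _random_position(genome, rng, 1, occupied, exclude)
        ref = genome.sequences[chrom][p0]
        v = Variant(chrom, p0 + 1, ref, _other_base(ref, rng))
        occupied.add_variant(v)
        out.append(TruthVariant(v, _draw_af(model.af_mode, rng), klass))
    lo, hi = model.indel_size_range
    for _ in range(n_indel):
        size = int(rng.integers(lo, hi + 1))
        if rng.random() < 0.5:  # deletion
            chrom, p0 = _random_position(genome, rng, size + 1, occupied, exclude)
            seq = genome.sequences[chrom]
            v = Variant(chrom, p0, seq[p0 - 1 : p0 + size], seq[p0 - 1])
        else:  # insertion
            chrom, p0 = _random_position(genome, rng, 1, occupied, exclude)
            anchor = genome.sequences[chrom][p0]
            ins = "".join(BASES[rng.integers(0, 4, size=min(size, 10))])
            v = Variant(chrom, p0 + 1, anchor, anchor + ins)
        v = normalize_variant(v, genome)
        occupied.add_variant(v)
        out.append(TruthVariant(v, _draw_af(model.af_mode, rng), klass))
    return out


# ---------------------------------------------------------------------------
# Guide edits
# ---------------------------------------------------------------------------

def _allele_catalog(
    genome: ReferenceGenome, guide: GuideSpec, site: SiteMatch,
    del_sizes: range = range(1, 16), ins_sizes: range = range(1, 11),
) -> list[Variant]:
    """Fixed per-site catalog of candidate edit alleles at the cut position.

    Deterministic given the site (insertion fill bases seeded from the site
    coordinates), so allele-identity comparisons between independently edited
    replicates are well defined.
    """
    cut = site.cut_position(guide)
    seq = genome.sequences[site.chrom]
    cat_rng = _stream(0, "allele_catalog", site.chrom, site.start, site.strand)
    catalog: list[Variant] = []
    for size in del_sizes:
        start = max(1, cut - size // 2)
        if start + size >= len(seq):
            continue
        v = Variant(site.chrom, start, seq[start - 1 : start + size], seq[start - 1])
        catalog.append(normalize_variant(v, genome))
    for size in ins_sizes:
        anchor = seq[cut - 1]
        ins = "".join(BASES[cat_rng.integers(0, 4, size=size)])
        if ins == seq[cut : cut + size]:  # would normalize into a no-op-like shift
            ins = ins[:-1] + _other_base(ins[-1], cat_rng)
        v = Variant(site.chrom, cut, anchor, anchor + ins)
        catalog.append(normalize_variant(v, genome))
    # normalization can make distinct raw alleles collide; keep unique keys
    seen, unique = set(), []
    for v in catalog:
        if v.key not in seen:
            seen.add(v.key)
            unique.append(v)
    return unique


def plant_guide_edits(
    genome: ReferenceGenome,
    guide: GuideSpec,
    sites: Sequence[SiteMatch],
    efficiency: float,
    n_replicates: int,
    seed: int | np.random.Generator = 0,
    af: float = 0.5,
    klass: str = "off_target",
) -> list[list[TruthVariant]]:
    """Independently edit each replicate at each site with the given efficiency.

    Each replicate draws its allele uniformly from the site's fixed indel
    catalog, independently of the other replicates, so independent lines
    carry distinct alleles with high probability — the signature that
    separates true nuclease activity from inherited mutations.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else _stream(seed, "edits", guide.guide_id)
    replicates: list[list[TruthVariant]] = []
    for _ in range(n_replicates):
        edits: list[TruthVariant] = []
        for site in sites:
            if rng.random() >= efficiency:
                continue
            catalog = _allele_catalog(genome, guide, site)
            allele = catalog[int(rng.integers(len(catalog)))]
            edits.append(TruthVariant(allele, af, klass))
        replicates.append(edits)
    return replicates


# ---------------------------------------------------------------------------
# Caller emulation
# ---------------------------------------------------------------------------

def emulate_callers(
    truth: Sequence[TruthVariant],
    model: CallerEmulationModel,
    genome: ReferenceGenome,
    seed: int | np.random.Generator = 0,
    sample_id: str = "sample",
) -> list[SampleVariantSet]:
    """Produce one noisy call set per emulated caller.

    Each caller independently misses each true variant with probability
    ``fn_rate``, adds Poisson(fp_rate x genome length) false SNVs at uniform
    positions never coinciding with a truth position, and perturbs reported
    allele frequencies with truncated Gaussian noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else _stream(seed, "callers", sample_id)
    truth_keys = {t.key for t in truth}
    truth_pos = {(t.variant.chrom, t.variant.pos) for t in truth}
    out: list[SampleVariantSet] = []
    for c in range(model.n_callers):
        caller_id = f"caller{c + 1}"
        s = SampleVariantSet(sample_id)
        for t in truth:
            if rng.random() < model.fn_rate:
                continue
            af = float(np.clip(t.true_af + rng.normal(0, model.af_noise_sd), 0.0, 1.0)) \
                if model.af_noise_sd > 0 else t.true_af
            s.add(VariantCall(t.variant, sample_id, caller_id, af, int(rng.poisson(MEAN_DEPTH))))
        n_fp = int(rng.poisson(model.fp_rate * genome.total_length))
        contigs = sorted(genome.sequences)
        for _ in range(n_fp):
            for _ in range(1000):
                chrom = contigs[int(rng.integers(len(contigs)))]
                p0 = int(rng.integers(1, genome.lengths[chrom] - 1))
                if (chrom, p0 + 1) in truth_pos:
                    continue
                ref = genome.sequences[chrom][p0]
                v = Variant(chrom, p0 + 1, ref, _other_base(ref, rng))
                if v.key in s.calls:
                    continue
                s.add(VariantCall(v, sample_id, caller_id, float(rng.uniform(0, 1)),
                                  int(rng.poisson(MEAN_DEPTH))))
                break
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# Whole-cohort simulation
# ---------------------------------------------------------------------------

def default_cohort_design(
    n_cas9: int = 12,
    n_cpf1: int = 3,
    unsafe_guide: str = "Cas9-10",
    n_t1: int = 2,
) -> CohortDesign:
    """The control + edited cohort layout the pipeline is designed around.

    Three generations of wild-type plants (pedigree-linked), two samples each
    of the four tissue-culture-related control types, two independent T0
    lines per guide, and a small T1 family from one T0 line.
    """
    samples: list[SampleSpec] = [
        SampleSpec("WT_G1_1", "WT_G1"),
        SampleSpec("WT_G2_1", "WT_G2", parent_id="WT_G1_1"),
        SampleSpec("WT_G2_2", "WT_G2", parent_id="WT_G1_1"),
        SampleSpec("WT_G3_1", "WT_G3", parent_id="WT_G2_1"),
        SampleSpec("WT_G3_2", "WT_G3", parent_id="WT_G2_1"),
    ]
    for group in ("TC_only", "Agro", "Cas9_backbone", "Cpf1_backbone"):
        for i in (1, 2):
            samples.append(SampleSpec(f"{group}_{i}", group))
    guide_ids = [f"Cas9-{i + 1:02d}" for i in range(n_cas9)] + [
        f"Cpf1-{i + 1:02d}" for i in range(n_cpf1)
    ]
    if unsafe_guide not in guide_ids:
        raise ValueError(f"unsafe guide {unsafe_guide!r} not among {guide_ids}")
    for gid in guide_ids:
        a, b = f"{gid}_T0_1", f"{gid}_T0_2"
        samples.append(SampleSpec(a, "Edited_T0", guide_id=gid, replicate_of=b))
        samples.append(SampleSpec(b, "Edited_T0", guide_id=gid, replicate_of=a))
    for i in range(n_t1):
        samples.append(
            SampleSpec(f"{guide_ids[0]}_T1_{i + 1}", "Edited_T1",
                       guide_id=guide_ids[0], parent_id=f"{guide_ids[0]}_T0_1")
        )
    return CohortDesign(samples)


@dataclass
class CohortSimulation:
    """Everything the simulator produced for one cohort."""

    genome: ReferenceGenome
    design: CohortDesign
    guides: dict[str, GuideSpec]
    on_target: dict[str, SiteMatch]
    planted_offtargets: dict[str, list[SiteMatch]]
    sites: dict[str, list[SiteMatch]]  # scan results per guide (classification budget)
    truth: dict[str, list[TruthVariant]]
    calls: dict[str, list[SampleVariantSet]]
    unsafe_guide: str

    def write(self, outdir: str | Path) -> None:
        """Write the cohort as plain-text inputs for the pipeline."""
        from .variants import write_vcf

        outdir = Path(outdir)
        (outdir / "vcf").mkdir(parents=True, exist_ok=True)
        self.genome.write_fasta(outdir / "genome.fa")
        self.design.to_tsv(outdir / "design.tsv")
        with open(outdir / "guides.tsv", "w") as fh:
            fh.write("guide_id\tprotospacer\tnuclease\tpam_patterns\t"
                     "target_chrom\ttarget_start\ttarget_strand\n")
            for gid in sorted(self.guides):
                g = self.guides[gid]
                t = self.on_target[gid]
                fh.write(f"{g.guide_id}\t{g.protospacer}\t{g.nuclease}\t"
                         f"{','.join(g.pam_patterns)}\t{t.chrom}\t{t.start}\t{t.strand}\n")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("sample_id\tchrom\tpos\tref\talt\tclass\ttrue_af\n")
            for sid in sorted(self.truth):
                for t in self.truth[sid]:
                    v = t.variant
                    fh.write(f"{sid}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{t.klass}\t{t.true_af}\n")
        for sid, caller_sets in self.calls.items():
            for s in caller_sets:
                caller = next(iter(s.calls.values())).caller_id if s.calls else "caller"
                write_vcf(outdir / "vcf" / f"{sid}.{caller}.vcf", s, self.genome)

    def write_caller_vcfs(self, outdir: str | Path) -> dict[str, list[Path]]:
        from .variants import write_vcf

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, list[Path]] = {}
        for sid, caller_sets in self.calls.items():
            paths[sid] = []
            for i, s in enumerate(caller_sets):
                p = outdir / f"{sid}.caller{i + 1}.vcf"
                write_vcf(p, s, self.genome)
                paths[sid].append(p)
        return paths


def _random_protospacer(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate_protospacer(
    proto: str, positions_from_pam: Sequence[int], pam_is_5prime: bool,
    rng: np.random.Generator,
) -> str:
    """Substitute bases at the given 1-based PAM-distances of a protospacer."""
    s = list(proto)
    L = len(proto)
    for p in positions_from_pam:
        idx = (p - 1) if pam_is_5prime else (L - p)
        s[idx] = _other_base(s[idx], rng)
    return "".join(s)


def _plant_sequence(sequences: dict[str, str], chrom: str, start: int, payload: str) -> None:
    seq = sequences[chrom]
    sequences[chrom] = seq[:start] + payload + seq[start + len(payload):]


def simulate_cohort(
    seed: int,
    design: CohortDesign | None = None,
    genome_bp: int = 1_000_000,
    n_contigs: int = 2,
    gc: float = 0.43,
    loads: Mapping[str, MutationLoadModel] | None = None,
    caller_model: CallerEmulationModel | None = None,
    unsafe_guide: str = "Cas9-10",
    n_offtarget_sites: int = 12,
    efficiency: float = 1.0,
    homology_budget: int = 6,
    validation_homology: int = 3,
    assignment_window: int = 5,
) -> CohortSimulation:
    """Simulate a full control + edited cohort on one synthetic genome.

    One guide (``unsafe_guide``) receives ``n_offtarget_sites`` planted
    homologous loci: one perfect protospacer under an alternative canonical
    PAM, most with a single PAM-distal mismatch, one with two mismatches
    (at most one in the seed) and one under a non-canonical NAG PAM —
    mirroring the empirically validated off-target site structure. All other
    guides have a single exact target.

    Background and spontaneous mutations are never placed inside the
    assignment window of a high-homology (within ``validation_homology``
    mismatches) guide site: such a placement would be indistinguishable from
    a true off-target edit even in principle, which would make the truth
    labels ill-defined.
    """
    design = design if design is not None else default_cohort_design(unsafe_guide=unsafe_guide)
    loads = dict(DEFAULT_LOADS, **(loads or {}))
    caller_model = caller_model if caller_model is not None else CallerEmulationModel()
    genome = simulate_reference(n_contigs, genome_bp // n_contigs, gc, seed)
    sequences = dict(genome.sequences)
    grng = _stream(seed, "guides")

    guide_ids = sorted({s.guide_id for s in design if s.guide_id})
    guides: dict[str, GuideSpec] = {}
    planted: dict[str, list[tuple[str, int, str]]] = {}  # guide -> (chrom, start, strand)
    target_pos: dict[str, tuple[str, int, str]] = {}

    reserved = _Occupied()
    contigs = sorted(sequences)

    def place(width: int) -> tuple[str, int]:
        for _ in range(10_000):
            chrom = contigs[int(grng.integers(len(contigs)))]
            start = int(grng.integers(100, len(sequences[chrom]) - width - 100))
            if not reserved.overlaps(chrom, start - 60, start + width + 60):
                reserved.add(chrom, start - 60, start + width + 60)
                return chrom, start
        raise ValueError("could not place guide site")

    for gid in guide_ids:
        nuclease = "Cpf1" if gid.startswith("Cpf1") else "Cas9"
        proto = _random_protospacer(grng, PROTOSPACER_LEN[nuclease])
        pams = ("NGG", "NAG") if nuclease == "Cas9" else ("TTTV",)
        guide = GuideSpec(gid, proto, nuclease, pams)
        guides[gid] = guide
        canonical_pam = "AGG" if nuclease == "Cas9" else "TTTC"
        payload = (canonical_pam + proto) if guide.pam_is_5prime else (proto + canonical_pam)
        chrom, start = place(len(payload))
        strand = "+" if grng.random() < 0.5 else "-"
        _plant_sequence(sequences, chrom, start,
                        payload if strand == "+" else reverse_complement(payload))
        target_pos[gid] = (chrom, start, strand)
        planted[gid] = []
        if gid == unsafe_guide:
            # composition of the planted off-target family: one exact copy under
            # a different canonical NGG, one NAG-PAM copy, one 2-mismatch copy
            # (<=1 in seed), remainder single PAM-distal mismatches
            specs: list[tuple[Sequence[int], str]] = [((), "CGG"), ((19,), "CAG"), ((20, 10), "TGG")]
            while len(specs) < n_offtarget_sites:
                specs.append(((20,), "GGG"))
            for mm_positions, pam in specs[:n_offtarget_sites]:
                mutated = _mutate_protospacer(proto, mm_positions, guide.pam_is_5prime, grng)
                pl = mutated + pam
                c, s0 = place(len(pl))
                st = "+" if grng.random() < 0.5 else "-"
                _plant_sequence(sequences, c, s0, pl if st == "+" else reverse_complement(pl))
                planted[gid].append((c, s0, st))

    genome = ReferenceGenome(sequences)

    # scan once per guide at the classification budget; recover planted sites
    sites: dict[str, list[SiteMatch]] = {}
    on_target: dict[str, SiteMatch] = {}
    planted_sites: dict[str, list[SiteMatch]] = {}
    exclude = _Occupied()
    pad = assignment_window + 20  # window plus indel reach
    for gid, guide in guides.items():
        found = find_sites(genome, guide, homology_budget)
        sites[gid] = found
        by_pos = {(s.chrom, s.start, s.strand): s for s in found}
        tchrom, tstart, tstrand = target_pos[gid]
        on_target[gid] = by_pos[(tchrom, tstart, tstrand)]
        planted_sites[gid] = [by_pos[p] for p in planted[gid]]
        for s in found:
            if s.n_mismatch <= validation_homology:
                exclude.add(s.chrom, s.start - pad, s.end + pad)

    # truth assembly, parents before children
    truth: dict[str, list[TruthVariant]] = {}
    founder = simulate_truth_set(
        genome, loads["founder"], _stream(seed, "founder"), klass="pre_existing",
        exclude=exclude,
    )
    edits_by_guide: dict[str, list[list[TruthVariant]]] = {}
    t0_index: dict[str, dict[str, int]] = {}
    for gid, guide in guides.items():
        t0s = [s.sample_id for s in design
               if s.group == "Edited_T0" and s.guide_id == gid]
        t0_index[gid] = {sid: i for i, sid in enumerate(sorted(t0s))}
        all_sites = [on_target[gid]] + planted_sites[gid]
        reps = plant_guide_edits(
            genome, guide, all_sites, efficiency, len(t0s),
            _stream(seed, "edits", gid),
        )
        # first entry of each replicate targets the declared site -> on_target class
        fixed = []
        for rep in reps:
            rep_fixed = []
            for tv in rep:
                k = "on_target" if _variant_at_site(tv.variant, on_target[gid], assignment_window) else "off_target"
                rep_fixed.append(TruthVariant(tv.variant, tv.true_af, k))
            fixed.append(rep_fixed)
        edits_by_guide[gid] = fixed

    group_class = {"TC_only": "tissue_culture", "Agro": "agro",
                   "Cas9_backbone": "agro", "Cpf1_backbone": "agro"}
    for spec in design.topological():
        occ = _Occupied()
        for t in founder:
            occ.add_variant(t.variant)
        own: list[TruthVariant] = []
        inherited: list[TruthVariant] = []
        if spec.parent_id is not None:
            for t in truth[spec.parent_id]:
                inherited.append(TruthVariant(t.variant, t.true_af, t.klass))
                occ.add_variant(t.variant)
        srng = _stream(seed, "sample", spec.sample_id)
        if spec.group in WT_GROUPS:
            if spec.parent_id is not None:
                own += simulate_truth_set(genome, loads["spontaneous"], srng,
                                          "spontaneous", occ, exclude)
        elif spec.group in BACKGROUND_GROUPS:
            own += simulate_truth_set(genome, loads["tissue_culture"], srng,
                                      "tissue_culture", occ, exclude)
            if spec.group != "TC_only":
                own += simulate_truth_set(genome, loads["agro_extra"], srng,
                                          "agro", occ, exclude)
        elif spec.group == "Edited_T0":
            own += simulate_truth_set(genome, loads["tissue_culture"], srng,
                                      "tissue_culture", occ, exclude)
            own += simulate_truth_set(genome, loads["agro_extra"], srng,
                                      "agro", occ, exclude)
            own += edits_by_guide[spec.guide_id][t0_index[spec.guide_id][spec.sample_id]]
        elif spec.group == "Edited_T1":
            own += simulate_truth_set(genome, loads["spontaneous"], srng,
                                      "spontaneous", occ, exclude)
        truth[spec.sample_id] = founder + inherited + own

    calls = {
        spec.sample_id: emulate_callers(
            truth[spec.sample_id], caller_model, genome,
            _stream(seed, "callers", spec.sample_id), spec.sample_id,
        )
        for spec in design
    }
    return CohortSimulation(
        genome=genome, design=design, guides=guides, on_target=on_target,
        planted_offtargets=planted_sites, sites=sites, truth=truth, calls=calls,
        unsafe_guide=unsafe_guide,
    )


def _variant_at_site(v: Variant, site: SiteMatch, window: int) -> bool:
    if v.chrom != site.chrom:
        return False
    s, e = v.interval()
    return s < site.end + window and site.start - window < e
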