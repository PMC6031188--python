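# Methods

## The adjudication model

The pipeline treats every variant in an edited plant as arising from one of
six sources: standing variation inherited from the parental line
(`pre_existing`), mutations induced by tissue culture or *Agrobacterium*
transformation (`background`), per-generation spontaneous mutations
(`spontaneous`), the intended edit (`on_target`), and nuclease activity at a
guide-homologous locus (`off_target_candidate` / `off_target_validated`).
Classification uses three orthogonal signals:

* **Cohort membership.** A variant found in any wild-type, pedigree or
  transformation control cannot be a nuclease product. Subtraction is exact
  on the normalized variant key; absorbed variants are retained in a ledger
  tagged with the absorbing group, so class counts are conserved end to end.
* **Sequence homology.** Nuclease activity requires a protospacer-like
  sequence next to a PAM. Variants are assigned to scanned sites when their
  affected reference interval overlaps the site ± a window (default 5 bp,
  covering resection around the cut); ties break toward the lower-mismatch
  site, then lower seed-mismatch, then leftmost.
* **Replicate allele identity.** Independently regenerated lines repair
  independent cuts, so a truly cut locus carries *distinct* indel alleles
  across lines, whereas inherited variants are identical. This asymmetry is
  the decisive evidence: distinct alleles at a shared site validate an
  off-target locus; identical shared alleles with poor homology mark
  inheritance.

Off-target validation is restricted to indels. Repair products at verified
off-target loci are overwhelmingly indels, and SNV dominance at a candidate
locus is evidence against nuclease origin; SNVs overlapping a site are
therefore reported as candidates with a warning tag and never validated.

A candidate observed in only one line is validated only when its site lies
within 3 protospacer mismatches (the empirical envelope of confirmed
off-target loci — most carry a single mismatch, none more than three) and the
variant survived every control and pedigree subtraction. Without the
homology gate, single-line promotion would validate any background indel
that happens to land near a low-homology site; with it, the probability of a
random 20-mer match within 3 mismatches is ~10⁻⁸ per window, so false
validations are structurally rare. Sites with 4–6 mismatches can still be
validated through the replicate-distinct-allele route; beyond the mapping
budget (default 6, configurable) a variant counts as having no site.

## Guide scanning

`find_sites` is an exhaustive Cas-OFFinder-style scan: both strands, every
window, exact IUPAC PAM match and protospacer Hamming distance within the
budget, vectorized with numpy bit masks (A/C/G/T → one bit; ambiguous
reference bases never match, and pattern codes meet reference `N`
pessimistically). Overlapping matches are reported independently.
Coordinates are 0-based half-open internally and converted to 1-based in
reports. Mismatch positions are stored as 1-based distances from the PAM, so
seed mismatches can be recounted for any seed length (default 18, the
PAM-proximal stretch where mismatches most strongly abolish cleavage;
10–12 is also common in the literature and available via `seed_len`).

Cut positions follow canonical nuclease biology: Cas9 cuts bluntly 3 bp from
the PAM; Cpf1 cuts in a staggered fashion ~18 bp from its 5′ PAM. The flank
aligner enumerates every ungapped offset and every placement of a single
1-nt bulge (extra base in the DNA, or DNA base missing against the guide) on
both strands; the gap penalty (1.5 at match = 1, mismatch = 0) makes one
bulge outrank two mismatches, and overlapping shadows of a better alignment
are culled greedily by score.

The guide-safety rule declares a guide safe when every non-target site
within 3 mismatches carries at least 2 mismatches in the seed. NAG PAMs are
included by default when classifying observed mutations (a non-canonical NAG
site can be a true off-target) but excluded by default in design-time safety
checks, where they would be needlessly conservative.

## The synthetic cohort

The generator emulates the structure of a tissue-culture-regenerated rice
cohort; its defaults are the study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| tissue-culture load | 114 SNVs + 36 indels | somaclonal mutations per regenerated plant |
| spontaneous load | 23 SNVs + 18 indels | per seed generation |
| *Agrobacterium* excess | 28 indels (mean) | midpoint of the observed ~15–41 range, configurable |
| founder load | 50 SNVs + 15 indels | standing variation shared by the whole pedigree |
| allele frequency | heterozygous (0.5) | culture-derived mutations look heterozygous |
| callers | 3; FN 0.02, FP 10⁻⁵/bp, AF noise sd 0.05 | independent noisy views of each truth set |
| genome | 2 × 500 kb, GC 0.43 | IID sequence at rice GC content |
| depth | Poisson(70) | within the 45–105× cohort range |

Counts are Poisson; positions are uniform without interval collisions.
One guide of fifteen receives 12 planted homologous loci (one exact copy
under an alternative canonical NGG, one NAG-PAM copy, one 2-mismatch copy
with at most one seed mismatch, the rest single PAM-distal mismatches);
edited replicates draw indel alleles independently from a fixed per-site
catalog (deletions 1–15 bp, insertions 1–10 bp), so two lines pick the same
allele with probability ~1/25. Randomness is a counter-based stream
hierarchy keyed by `(seed, purpose, sample_id)`: adding samples to a design
never perturbs existing ones.

Background and spontaneous mutations are never placed inside the assignment
window of a high-homology (≤3-mismatch) guide site. A background indel there
would be indistinguishable from a true off-target edit even in principle, so
admitting them would make the truth labels — and any sensitivity/false-
validation measurement — ill-defined. This is a property of truth
construction, not of the classifier, which receives no truth information.

What the generator does **not** model: read-level errors and alignment
artifacts (caller noise is drawn directly), mosaicism, structural variants
and T-DNA integrations, repetitive sequence (IID genomes underestimate
mapping ambiguity and homopolymer normalization shifts), and linkage between
mutations. Passing tests therefore demonstrate the adjudication logic under
clean statistical conditions, not robustness to alignment pathology on real
repetitive genomes.

## Numerical and interface choices

* Variant keys are normalized (left-aligned, minimal, one anchor base) with
  the standard truncate/extend loop; normalization is idempotent and checked
  against a whole-sequence diffing oracle in the tests. Multi-allelic
  records are split before normalization; exact-allele keys are required for
  consensus and replicate comparison because allele identity carries the
  inheritance signal — near-miss indels at the same locus deliberately do
  not match.
* The AF floor is inclusive: AF ≥ 0.10 is kept, applied post-intersection on
  the consensus (median) AF; `min_af` is configurable.
* Consensus AF/DP use the median across callers, robust to one outlier.
* AF bins assign 0.25 downward (somatic-like) and 0.75 upward
  (homozygous-like); only the outer bins are externally defined, the
  boundary direction is a convention.
* Feature precedence for overlapping annotations is CDS > UTR > intron >
  TE > repeat > intergenic (TEs overlap genes in rice); uncovered sequence
  is intergenic. Enrichment p-values are two-sided binomial with BH
  correction across the six categories (α = 0.05).
* Mutation rates use the diploid denominator 2L by default (haploid via
  flag); multi-generation chains divide by the number of parent→child links.
* Degenerate inputs: empty spectra report Ts/Tv as `None`; zero-length
  genomes, out-of-range AFs and rates, pedigree cycles and duplicate sample
  ids raise `ValueError` with named fields.

## Problem sizes

The test and acceptance studies run at desk scale, chosen so the statistical
assertions have the intended power: 50-kb genomes for scanner–oracle
equivalence (100 genomes across the three PAM configurations), a 1-Mb genome
× 100 seeds for consensus robustness, 1-Mb two-contig genomes × 50 seeds for
cohort recovery, and 10-Mb genomes × 50 seeds for rate-estimator recovery.
Sensitivity for planted off-target loci is measured at locus level (a locus
is recovered if validated in either replicate line), mirroring site-level
reporting of off-target findings.

## Known limitations

* Single-line validation encodes one defensible reading of an
  under-determined decision rule (high homology + absence from all
  controls); the evidence trail tags which route promoted each variant so
  downstream users can re-adjudicate.
* The scanner is exhaustive and memory-light but linear in genome size per
  guide; it is intended for desk-scale and chromosome-scale scans, not
  indexed gigabase screening.
* Bulge-aware alignment allows at most one 1-nt bulge, matching the
  short-word alignment step it replaces; larger bulges are out of scope.
* T1 analysis is limited to pedigree subtraction; germline-transmission
  dynamics and mosaicism deconvolution are not modelled.
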