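# Methods

This note records the models, conventions, and numerical choices behind
`capsforge`, in the order the pipeline runs.

## Coordinates, genotypes, formats

Internal coordinates are 0-based half-open; everything that crosses an I/O
boundary (VCF records, SNP identifiers `<contig>_<pos>_<ref>_<alt>`,
report tables) is 1-based. Genotypes are stored as reference-allele dosage
(2 = ref-hom, 1 = het, 0 = alt-hom, −1 = missing); ploidy is fixed at two
and any other GT arity is a format error. FASTA is read/written through
Biopython, VCF is read through pysam (plain or bgzipped); VCF *writing* is
a deterministic plain-text writer so that identical simulator inputs give
byte-identical files. A missing DP is treated as unknown and passes no
depth threshold (conservative for the tier rule).

## Filtering cascade

`basic_filter` retains biallelic SNPs that are not fixed for the alternate
allele (alt frequency ≤ 0.999 over typed samples), genotyped in at least
`min_typed` samples (default 15 of 22), with MAF ≥ 0.20. MAF is computed
over typed samples only; boundaries are inclusive (MAF exactly 0.20 and
exactly `min_typed` samples are kept). Each rejected site carries the
first failing reason.

`hwe_exact` is the conditional exact test of Hardy–Weinberg proportions:
given n typed diploids and m minor-allele copies, the heterozygote count h
has support {m mod 2, …, min(m, 2n − m)} in steps of 2 with weights
∝ 2^h / [((m−h)/2)! h! ((2n−m−h)/2)!], evaluated in log space with
`gammaln`. The two-sided p-value sums all configurations no more probable
than the observed one (plain tails, no mid-p); `p_deficit` = P(h ≤ obs),
`p_excess` = P(h ≥ obs). A monomorphic site has a single configuration, so
all three p-values are 1. Results are cached per (n, m) — at 22 samples
the whole genome touches only a few hundred distinct configurations.

The excess screen **retains** sites with `p_excess ≥ 0.5` (inclusive).
Any lean toward excess heterozygosity is treated as a duplication
artifact, not genotypic structure; the direction and threshold are
configurable. Retention tiers: n_typed ≥ 17 kept outright; n_typed = 16
kept only if `p_deficit < p_excess` (the selfing signature); n_typed = 15
additionally requires DP ≥ 2 in ≥ 11 samples, and a tier-C site without
any depth data is rejected with an explicit reason. No multiple-testing
correction is applied to the HWE screen (none is appropriate: it is a
directional filter, not an inference).

**Calibration.** The exact test is discrete and conservative: at n = 22
its attained size at the nominal 5 % level is ≈ 2–3 %, so "5 % rejections
under the null" is not attainable and would be the wrong check. The
type-I test instead compares the observed rejection count against the
exact attained size Σᵢ P(p_hwe < 0.05 | nᵢ, mᵢ), computed from the null
distribution by enumeration, within 3 standard errors — plus a one-sided
validity bound at the nominal level.

`inbreeding_estimate` is the multilocus moment estimator
F̂ = 1 − Σ obs-het / Σ 2 p̂ q̂ n_typed, pooling all polymorphic sites. It
carries a small negative bias of order (1 + F)/(2n) (from plugging in p̂),
≈ 0.02 at n = 22 — well inside the ±0.05 recovery tolerance used in tests
— and is left uncorrected for transparency.

## Flanks

`extract_flanks` builds, per sample, a consensus sequence over the
reference window (default 1000 bp each side of the SNP): homozygous
substitutions applied, heterozygous substitutions written as the IUPAC
two-base code, untyped positions as N. Heterozygous or untyped indels are
masked with N over their REF span — one sequence per sample is kept, and
primer design must never sit on an uncertain position; homozygous-
alternate indels are applied literally (per-reference-position cells track
the coordinate shift). Windows crossing a contig edge are clipped and the
clip recorded, not raised.

## Duplicate screening

Spurious SNPs arise when reads from two near-identical genomic copies
co-map to one locus; the screen asks whether the sequence around a
candidate occurs more than once. Two windows centered on the SNP (41 bp
and 201 bp — a short window for local duplications, a long one for
context) are searched against both strands of every supplied genome (the
marker's own reference is required; additional assemblies optional) by
seed-and-extend: exact k-mer seeds (k = 11 for the short window, 16 for
the long), extended by banded local alignment with megablast-like scoring
(match +1, mismatch −2, gap open −2.5, gap extend −0.5) via Biopython's
PairwiseAligner. Overlapping alignments at one locus are merged.

Each hit records two identities: the BLAST-convention **column identity**
(matches / alignment columns, gaps included) and the **query identity**
(matches / full query length). The verdict qualifies a hit on query
identity ≥ 0.90 plus SNP coverage, and fails a candidate when any single
genome holds more than one qualifying hit (the self-hit is the first).
Query identity is used because a local alignment happily trims a degraded
copy (or a chance 11-mer seed) down to a short high-column-identity
fragment; "90 % identical to the query" must mean the query as a whole.
Reverse-strand search reverse-complements the query, so the odd window's
center index is strand-invariant and the verdict is strand-symmetric.

## Enzyme selection and primer design

The enzyme catalog is data, not code: a REBASE-style TSV (recognition
sequence in IUPAC, top/bottom cut offsets from the recognition start, a
provenance column) shipping with the 17 enzymes of the published marker
panel, including offset cutters (MnlI: CCTC(7/6)). Degeneracy is honored
on the pattern side only — N or an IUPAC code in the *subject* never
matches, since an uncertain base cannot certify a site. Reverse-strand
matches are reported in forward coordinates; palindromic sites once. The
sense-strand cut coordinate of a reverse-strand match mirrors the top
offset (`pos + site_len − cut_top`), giving every match a single
well-defined cut position for fragment arithmetic.

A candidate marker is a SNP where exactly one allele version of the flank
has a recognition match overlapping the SNP and the other has none
(`allele_specific_sites`), with no constitutive match of the same enzyme
within 150 bp (`uniqueness_check`), and — after primer design — no
constitutive match anywhere in the amplicon (`nontarget_site_check`).

Primer search is exhaustive within constraints: all windows of 15–25 bp
lying fully in conserved positions (identical, unambiguous base in the
reference and every sample flank), with the forward primer ending and the
reverse-primer site starting 150–600 bp from the recognition site. Pairs
must give an amplicon of 590–1000 bp with both digest fragments ≥ 100 bp,
primer GC in [0.20, 0.80], Tm in [57, 63] °C, ΔTm ≤ 3 °C. Melting
temperature is nearest-neighbor (unified 1998 parameter set, 50 mM
monovalent cation, 250 nM primer, Biopython implementation); conditions
are fixed in one place so reported Tm values are comparable. Ranking
score: |Tm_f − 60| + |Tm_r − 60| + |ΔTm| + 0.01·|amplicon − 750|, ties
broken by coordinates — fully deterministic. One computational cap: only
the 100 primers per side closest to the optimal Tm enter the quadratic
pairing (`max_per_side`); the score is Tm-dominated, so top-ranked pairs
are unaffected while fully conserved flanks (millions of raw pairs) stay
fast. Published marker tables occasionally bend the amplicon bound, so
`MarkerSpec` stores plain data and the constraints are enforced at design
time, not construction time.

## Digest model and assay scoring

`predict_digest`: digest-homozygote → {fragment_up, fragment_down};
other-homozygote → {amplicon}; heterozygote → all three; missing → no
bands. `genotype_from_bands` inverts this by multiset matching within a
per-band tolerance, defaulting to 5 % of the predicted size as a
gel-resolution proxy (gels are scored visually; exact sizes exist only in
silico); anything matching no pattern is `unreadable` — a value, not an
error. Panel summaries use readable calls only; a 50:50 allele tie
reports MAF 0.5 with both alleles listed; the SD uses the n − 1
denominator and summaries are reported at two decimals (raw values are
retained in machine output).

## The synthetic-data generator

The generator emulates the study conditions the filters assume — and only
those:

- **Genotype model**: independent sites; P(ref-hom) = p² + Fpq,
  P(het) = 2pq(1 − F), P(alt-hom) = q² + Fpq, with defaults n = 22
  samples, F = 0.41.
- **Depth model**: per-call DP ~ Poisson(mean 3.5); a call is missing iff
  DP = 0. This is an assumption standing in for the unobservable
  low-coverage missingness mechanism, chosen as the simplest model whose
  DP thresholds the tier rule can exercise.
- **Base composition**: i.i.d. at the configured GC fraction (default
  0.40) — no incidental repeats, so duplicate screening sees only what is
  planted.
- **Planted CAPS sites**: a concrete realization of the enzyme's
  recognition sequence is written with the cut allele at the SNP; the
  uncut allele must break the match. The surrounding ±680 bp (the maximal
  reach of any amplicon) is scrubbed of every other match of that enzyme
  under either allele, so planted markers pass the uniqueness and
  non-target checks by construction and any failure indicates a pipeline
  defect, not bad luck.
- **Duplicate decoys**: the 201 bp SNP-centered window of a planted
  marker is copied elsewhere with an exact substitution count
  round((1 − identity)·len) (realized identity within rounding of the
  request; default 0.95).
- **Linked decoys**: a second planted marker on the same contig copies
  its partner's genotype vector with one flipped call and two extra
  missing calls, so r² ≫ 0.2 and pruning must drop exactly the decoy
  under the more-missing-data rule.
- **Controlled layout**: every planted unit lives on its own contig;
  background SNPs (MAF ~ Uniform(0.05, 0.5)) live on separate background
  contigs. Because the linkage window never spans contigs, pruning sees
  only the planted positive controls — with 22 samples, truly unlinked
  dosage vectors exceed r² = 0.2 by chance a few percent of the time, and
  at desk-scale contig sizes every same-contig pair is inside the window;
  linkage, like duplication, must be controlled rather than incidental.
- **Planted-site conditioning**: genotype draws at planted sites are
  redrawn until the realized site is well-typed (≥ 19/22 after
  missingness), has realized MAF ≥ 0.25, and leans toward heterozygote
  deficit. Planted markers are the ground truth of recovery tests; a
  marker whose sample happened to fall below the MAF filter would be
  *correctly* filtered, which tests nothing.

What the generator does **not** emulate: read-level errors, genotype-
likelihood uncertainty, linkage decay along chromosomes, demographic
history, repeat families, or indel-rich regions. Passing recovery tests
therefore demonstrates the correctness of the pipeline's logic under its
own assumptions, not robustness to real sequencing artifacts beyond the
planted ones.

Determinism: every random choice flows from one `numpy` Generator seeded
by the configuration, and identical configurations produce byte-identical
FASTA/VCF/truth files.

## Pipeline driver and problem sizes

`run_pipeline` chains the stages in the order basic filters → excess
screen → tiers → flanks → duplicate screen → enzyme selection → linkage
pruning → primer design, logging a per-stage funnel (monotone
non-increasing after the load stage), a reason for every dropped site,
and a JSON manifest of thresholds. The default test/verification problem
sizes — 211 SNPs across ~13 contigs (≈ 0.3 Mb genome), 22 samples, 10⁴
sites for test calibration, 2000 × 22 for F̂ recovery — were chosen so the
whole suite and the acceptance script each complete in well under a
minute while keeping every statistical check at ≥ 3-standard-error
resolution.

The command-line interface is a thin layer over these functions
(`simulate`, `filter`, `dupscreen`, `prune`, `design`, `run`); flank
export and assay scoring are reached through the library surface and the
`design`/`run` outputs.

## Known limitations

- The duplicate screen's seed-and-extend search can in principle miss a
  ≥ 90 %-identity copy whose differences are spaced so that no exact
  k-mer survives; at the default k and window sizes this requires an
  adversarial mutation pattern (tests include a brute-force all-offsets
  oracle cross-check).
- Greedy pair-at-a-time linkage pruning is not a maximum independent set;
  on small candidate sets it is within one site of the exhaustive optimum
  (property-tested), matching common practice.
- Primer thermodynamics ignore secondary structure, dimers, and
  mispriming elsewhere in the genome; dCAPS (mismatch-primer) designs are
  out of scope.
- The enzyme catalog ships only the 17 panel enzymes; extend the TSV for
  broader scans. One catalog entry (BstCI, recorded as the HaeIII
  isoschizomer GG^CC) has thinner public documentation than the rest, as
  flagged in its provenance column.
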