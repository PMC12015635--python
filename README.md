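# capsforge

**CAPS / PCR-RFLP genotyping-marker design from a reference genome and a
multi-sample VCF.**

Population studies of selfing plants (outcrossing rates from progeny
arrays, parentage, fine-scale structure) need a handful of codominant,
cheaply scorable markers with high minor-allele frequencies — not
whole-genome data. A CAPS (cleaved amplified polymorphic sequence, a.k.a.
PCR-RFLP) marker delivers exactly that: a SNP sits inside a restriction
enzyme's recognition site, so after PCR and digestion one allele yields two
fragments, the other a single uncut band, and heterozygotes all three.

`capsforge` turns a reference genome plus a population VCF into complete
CAPS marker specifications, reproducing the whole in-silico development
funnel:

1. **Basic variant filters** — biallelic SNPs only, not fixed, minor allele
   frequency ≥ 0.20, genotyped in ≥ 15 of 22 samples.
2. **Exact Hardy–Weinberg screen** — the conditional exact test with
   one-tailed p-values. In an inbred population true SNPs lean toward
   heterozygote *deficit* (at inbreeding coefficient *F*, expected
   heterozygosity is 2*pq*(1 − *F*)); heterozygote *excess* is the
   signature of reads from duplicated regions co-mapping to one locus
   ("pseudo-SNPs"), so excess-leaning sites (p_excess < 0.5) are removed.
3. **Retention tiers** by genotyping completeness, with a read-depth rule
   (≥ 11 samples at DP ≥ 2) for the thinnest tier.
4. **Consensus flanks** — per-sample sequences 1000 bp either side of each
   SNP with IUPAC codes at heterozygous positions and N where untyped.
5. **Duplicate screening** — seed-and-extend local alignment of 41 bp and
   201 bp SNP-centered windows against whole genomes; a candidate fails
   when any genome holds a second ≥ 90 %-identity hit covering the SNP.
6. **Enzyme selection** — a recognition site completed by exactly one
   allele, with no second constitutive site within 150 bp.
7. **Linkage pruning** — pairwise r² of 0/1/2 genotype dosages within a
   1000 kbp window; for r² > 0.2 the site with more missing data is
   dropped.
8. **Primer design** — exhaustive search over conserved flank positions:
   primers 15–25 bp, GC 20–80 %, Tm 57–63 °C (ΔTm ≤ 3 °C), amplicon
   590–1000 bp, digest fragments ≥ 100 bp, no non-target digest site in
   the amplicon.

A first-class synthetic-data module simulates the study conditions the
pipeline assumes — a ~22-sample population under partial selfing
(*F* ≈ 0.41), mean sequencing depth 3.5× driving missing genotypes, planted
CAPS-able SNPs, near-identical duplicated decoy segments, and linked-pair
decoys — so the entire pipeline is testable at desk scale, offline.

## Worked example

```python
import tempfile
from capsforge.synthetic_data import SimulationConfig, simulate_study, write_simulation
from capsforge.assay_report import PipelineConfig, run_pipeline, marker_report_rows

sim = simulate_study(SimulationConfig(seed=1))          # 11 planted + 200 background SNPs
with tempfile.TemporaryDirectory() as d:
    paths = write_simulation(sim.genome, sim.matrix, sim.truth, d)
    result = run_pipeline(PipelineConfig(vcf=paths["vcf"], fasta=paths["fasta"]))

for stage, n in result.funnel:
    print(f"{stage}\t{n}")
print(marker_report_rows(result.markers)[0])
```

prints

```
loaded          211
basic_filter    140
excess_screen   138
tier_filter     138
flanks          138
duplicate_screen        136
enzyme_selection        20
linkage_prune   15
primer_design   13
{'locus': 1, 'snp_id': 'chr_m01_1201_G_A', 'primer_f': 'ATTTGCGAGGCTTGTAAGAACTGC',
 'primer_r': 'CCAATCGGTTCAGAGAAGTGCCTA', 'tm_f': 60.0, 'tm_r': 60.0, 'size': 747,
 'enzyme': 'NdeI', 'digest_allele': 'G', 'size_up': 371, 'size_down': 376}
```

The funnel shows each stage's surviving site count: 211 simulated SNPs
shrink to 13 final markers. The report row is a complete assay: amplify
`chr_m01` with the given primer pair (both Tm 60.0 °C), digest the 747 bp
product with NdeI — G-homozygotes cut into 371 + 376 bp, A-homozygotes stay
uncut at 747 bp, heterozygotes show all three bands. All seven planted
true markers are among the 13; both duplicated decoys and both linked
decoys were rejected.

The same stages are available from the shell:

```bash
capsforge simulate --config sim.yaml --out simdir --seed 1
capsforge filter --vcf simdir/variants.vcf --fasta simdir/reference.fa --out sites.tsv
capsforge design --vcf simdir/variants.vcf --fasta simdir/reference.fa --out markers/
```

## Scoring real gels

`capsforge.assay_report.genotype_from_bands` inverts the digest model
(band multiset → genotype, with a ±5 % gel-resolution tolerance), and
`maf_from_genotypes` / `summarize_markers` compute the per-locus and
panel-level minor-allele-frequency summaries used to judge a marker panel.
The package ships the specifications and per-locus MAFs of a published
17-marker panel (`capsforge.caps_design.load_marker_panel` /
`load_panel_maf`) as fixtures for these report surfaces.

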