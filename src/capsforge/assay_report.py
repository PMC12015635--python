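"""Assay scoring, marker summaries, and the end-to-end pipeline driver.

:func:`genotype_from_bands` inverts the digest model (gel band pattern ->
genotype); :func:`maf_from_genotypes` and :func:`summarize_markers`
produce the per-locus and aggregate minor-allele-frequency summaries a
marker panel is judged by; :func:`run_pipeline` chains every stage of
marker development — basic variant filters, the Hardy–Weinberg excess
screen, retention tiers, flank construction, duplicate screening,
allele-specific enzyme-site selection, linkage pruning and primer design —
with a per-stage funnel log and a machine-readable run manifest.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from . import caps_design as cd
from .flanks_duplicates import (
    FlankSet,
    build_seed_index,
    duplicate_scan,
    duplicate_verdict,
    extract_flanks,
)
from .linkage import prune
from .popgen_filters import (
    FilterParams,
    basic_filter,
    excess_screen,
    hwe_for_matrix,
    tier_filter,
)
from .variant_io import (
    GenotypeMatrix,
    read_fasta,
    read_vcf,
    snp_id,
    write_candidate_table,
)

__all__ = [
    "AssayResult",
    "MarkerSummary",
    "PipelineConfig",
    "PipelineResult",
    "genotype_from_bands",
    "maf_from_genotypes",
    "summarize_markers",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# band-pattern scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssayResult:
    marker: cd.MarkerSpec
    sample: str
    bands: tuple[int, ...]
    genotype: str  # digest-hom | other-hom | het | unreadable


def _bands_match(observed, expected, tol_of) -> bool:
    if len(observed) != len(expected):
        return False
    for o, e in zip(sorted(observed), sorted(expected)):
        if abs(o - e) > tol_of(e):
            return False
    return True


def genotype_from_bands(
    bands,
    marker: cd.MarkerSpec,
    tolerance: float | None = None,
) -> str:
    """Genotype call from a multiset of gel band sizes.

    Band sizes are matched against the three predicted patterns within a
    per-band tolerance — *tolerance* bp if given, otherwise 5 % of the
    predicted fragment size (a gel-resolution proxy).  A pattern that
    matches none of the three is ``unreadable`` (a value, not an error).
    """
    if tolerance is None:
        tol_of = lambda e: 0.05 * e
    else:
        tol_of = lambda e: tolerance
    bands = sorted(bands)
    for genotype in cd.GENOTYPES:
        if _bands_match(bands, cd.predict_digest(marker, genotype), tol_of):
            return genotype
    return "unreadable"


def maf_from_genotypes(
    genotypes, digest_allele: str, other_allele: str
) -> tuple[float, str]:
    """Minor-allele frequency from readable assay genotypes.

    Counts alleles over readable calls only; a 50:50 tie reports MAF 0.5
    with both alleles listed as ``"X/Y"``.
    """
    n_digest = 0
    n_other = 0
    for g in genotypes:
        if g == "digest-hom":
            n_digest += 2
        elif g == "other-hom":
            n_other += 2
        elif g == "het":
            n_digest += 1
            n_other += 1
    total = n_digest + n_other
    if total == 0:
        raise ValueError("no readable genotypes: MAF undefined")
    if n_digest == n_other:
        return 0.5, f"{digest_allele}/{other_allele}"
    if n_digest < n_other:
        return n_digest / total, digest_allele
    return n_other / total, other_allele


@dataclass(frozen=True)
class MarkerSummary:
    """Aggregate MAF summary over a marker panel (sample SD, n-1)."""

    n_loci: int
    mean_maf: float
    sd_maf: float
    min_maf: float
    threshold: float
    n_at_or_above_threshold: int
    sd_defined: bool


def summarize_markers(mafs, threshold: float = 0.30) -> MarkerSummary:
    mafs = list(map(float, mafs))
    if not mafs:
        raise ValueError("at least one locus required")
    arr = np.asarray(mafs)
    sd_defined = arr.size > 1
    return MarkerSummary(
        n_loci=arr.size,
        mean_maf=float(arr.mean()),
        sd_maf=float(arr.std(ddof=1)) if sd_defined else 0.0,
        min_maf=float(arr.min()),
        threshold=threshold,
        n_at_or_above_threshold=int((arr >= threshold).sum()),
        sd_defined=sd_defined,
    )


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Inputs and thresholds for a full marker-development run."""

    vcf: str
    fasta: str
    extra_fastas: list[str] = field(default_factory=list)
    enzyme_catalog: str | None = None  # None -> packaged catalog
    filter_params: FilterParams = field(default_factory=FilterParams)
    design: cd.DesignConstraints = field(default_factory=cd.DesignConstraints)
    flank_radius: int = 1000
    duplicate_identity_min: float = 0.90
    uniqueness_radius: int = 150
    r2_max: float = 0.2
    linkage_window: int = 1_000_000
    out_dir: str | None = None


@dataclass
class PipelineResult:
    markers: list[cd.MarkerSpec]
    funnel: list[tuple[str, int]]
    dropped: list[tuple[str, str, str]]  # (stage, snp_id, reason)
    manifest: dict

    def funnel_counts(self) -> list[int]:
        return [n for _, n in self.funnel]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every marker-development stage in order.

    Stage order: load -> basic filters -> heterozygote-excess screen ->
    retention tiers -> flank construction -> duplicate screen ->
    allele-specific enzyme sites (with the local-uniqueness rule) ->
    linkage pruning -> primer design with the non-target digest check ->
    report.  Per-stage counts are recorded (the funnel is monotone
    non-increasing after the load stage) and every dropped site carries a
    reason.
    """
    genome = read_fasta(config.fasta)
    extra = [read_fasta(p) for p in config.extra_fastas]
    matrix = read_vcf(config.vcf, genome=genome)
    catalog = (
        cd.load_enzyme_catalog(config.enzyme_catalog)
        if config.enzyme_catalog
        else cd.default_enzyme_catalog()
    )
    funnel: list[tuple[str, int]] = [("loaded", matrix.n_sites)]
    dropped: list[tuple[str, str, str]] = []

    matrix, rejected = basic_filter(matrix, config.filter_params)
    dropped += [("basic_filter", sid, why) for sid, why in rejected]
    funnel.append(("basic_filter", matrix.n_sites))

    hwe = hwe_for_matrix(matrix)
    matrix, hwe, rejected = excess_screen(matrix, hwe, config.filter_params)
    dropped += [("excess_screen", sid, why) for sid, why in rejected]
    funnel.append(("excess_screen", matrix.n_sites))

    tiers = tier_filter(matrix, hwe, config.filter_params)
    dropped += [("tier_filter", sid, why) for sid, why in tiers.rejected]
    matrix = tiers.matrix
    funnel.append(("tier_filter", matrix.n_sites))

    flanks: list[FlankSet] = [
        extract_flanks(genome, matrix, site, config.flank_radius)
        for site in matrix.sites
    ]
    funnel.append(("flanks", len(flanks)))

    genomes = [genome] + extra
    seed_index = build_seed_index(genomes)
    survivors: list[int] = []
    for i, flank in enumerate(flanks):
        hits = duplicate_scan(
            flank,
            genomes,
            identity_min=config.duplicate_identity_min,
            index=seed_index,
        )
        ok, reason = duplicate_verdict(hits, config.duplicate_identity_min)
        if ok:
            survivors.append(i)
        else:
            sid = _sid(matrix, i)
            dropped.append(("duplicate_screen", sid, reason))
    flanks = [flanks[i] for i in survivors]
    matrix = matrix.subset(survivors)
    funnel.append(("duplicate_screen", matrix.n_sites))

    candidates: list[list[cd.CandidateCaps]] = []
    survivors = []
    for i, flank in enumerate(flanks):
        cands = [
            c
            for c in cd.allele_specific_sites(flank, catalog)
            if cd.uniqueness_check(flank, c, config.uniqueness_radius)
        ]
        if cands:
            survivors.append(i)
            candidates.append(cands)
        else:
            dropped.append(("enzyme_selection", _sid(matrix, i), "no_allele_specific_site"))
    flanks = [flanks[i] for i in survivors]
    matrix = matrix.subset(survivors)
    funnel.append(("enzyme_selection", matrix.n_sites))

    pruned = prune(matrix, r2_max=config.r2_max, window=config.linkage_window)
    dropped += [
        ("linkage_prune", sid, f"linked_to:{other} ({rule})")
        for sid, other, rule in pruned.dropped
    ]
    flanks = [flanks[i] for i in pruned.kept]
    candidates = [candidates[i] for i in pruned.kept]
    matrix = matrix.subset(pruned.kept)
    funnel.append(("linkage_prune", matrix.n_sites))

    markers: list[cd.MarkerSpec] = []
    for i, (flank, cands) in enumerate(zip(flanks, candidates)):
        best: cd.MarkerSpec | None = None
        for cand in cands:
            specs, _tally = cd.design_primers(flank, cand, config.design)
            for spec in specs:
                if cd.nontarget_site_check(spec, flank):
                    best = spec
                    break
            if best is not None:
                break
        if best is None:
            dropped.append(("primer_design", _sid(matrix, i), "no_feasible_primers"))
        else:
            markers.append(best)
    funnel.append(("primer_design", len(markers)))

    manifest = {
        "n_samples": matrix.n_samples,
        "funnel": funnel,
        "filter_params": asdict(config.filter_params),
        "design_constraints": asdict(config.design),
        "flank_radius": config.flank_radius,
        "duplicate_identity_min": config.duplicate_identity_min,
        "uniqueness_radius": config.uniqueness_radius,
        "r2_max": config.r2_max,
        "linkage_window": config.linkage_window,
    }
    result = PipelineResult(markers=markers, funnel=funnel, dropped=dropped, manifest=manifest)
    if config.out_dir:
        _write_outputs(result, config)
    return result


def _sid(matrix: GenotypeMatrix, i: int) -> str:
    s = matrix.sites[i]
    return snp_id(s.contig, s.pos, s.ref, s.alts[0])


def marker_report_rows(markers: list[cd.MarkerSpec]) -> list[dict]:
    """Report rows mirroring the validated-marker table layout."""
    rows = []
    for k, m in enumerate(markers, start=1):
        pp = m.primer_pair
        rows.append(
            {
                "locus": k,
                "snp_id": m.snp_id,
                "primer_f": pp.forward if pp else "",
                "primer_r": pp.reverse if pp else "",
                "tm_f": round(pp.tm_forward, 1) if pp else "",
                "tm_r": round(pp.tm_reverse, 1) if pp else "",
                "size": m.amplicon_length,
                "enzyme": m.enzyme.name,
                "digest_allele": m.digest_allele,
                "size_up": m.fragment_up,
                "size_down": m.fragment_down,
            }
        )
    return rows


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    os.makedirs(config.out_dir, exist_ok=True)
    write_candidate_table(
        marker_report_rows(result.markers),
        os.path.join(config.out_dir, "markers.tsv"),
    )
    write_candidate_table(
        [{"stage": s, "snp_id": sid, "reason": r} for s, sid, r in result.dropped],
        os.path.join(config.out_dir, "dropped.tsv"),
        columns=["stage", "snp_id", "reason"],
    )
    with open(os.path.join(config.out_dir, "funnel.tsv"), "w") as fh:
        fh.write("stage\tn_sites\n")
        for stage, n in result.funnel:
            fh.write(f"{stage}\t{n}\n")
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
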