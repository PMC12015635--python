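"""Synthetic genomes and partial-selfing populations with planted CAPS markers.

The generator emulates the study conditions the marker pipeline is built
for: a ~22-sample diploid population under partial selfing (inbreeding
coefficient F ~ 0.41), low mean sequencing depth (~3.5x) driving missing
genotypes, biallelic SNPs over a spectrum of minor-allele frequencies,
and reference genomes that contain (a) SNPs planted inside restriction
recognition sites and (b) near-identical duplicated segments as decoys.
Everything is written as standard FASTA/VCF plus a machine-readable truth
table, so every downstream stage is testable without external data.

Genotypes at each site are drawn independently from the inbreeding model

    P(ref-hom) = p^2 + F p q,   P(het) = 2 p q (1 - F),   P(alt-hom) = q^2 + F p q,

and per-call read depth is Poisson with the configured mean; a call with
zero reads is missing (the DP = 0 <=> missing rule is the model's
assumption for low-coverage data, not an observed mechanism).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .caps_design import IUPAC, Enzyme, default_enzyme_catalog, match_recognition, revcomp
from .variant_io import (
    MISSING,
    GenotypeMatrix,
    ReferenceGenome,
    VariantSite,
    write_fasta,
    write_vcf,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "PlantedMarker",
    "PlantedDuplicate",
    "PlantingError",
    "generate_reference",
    "plant_caps_site",
    "plant_duplicate",
    "simulate_genotypes",
    "simulate_depth_missingness",
    "simulate_study",
    "write_simulation",
]


class PlantingError(RuntimeError):
    """A requested marker or duplicate could not be planted cleanly."""


@dataclass
class SimulationConfig:
    """Study-condition parameters for one simulated dataset.

    Defaults reproduce the target population design: 22 samples at
    inbreeding F = 0.41 with mean depth 3.5x.  ``maf_distribution`` is a
    named spec ``("uniform", low, high)`` for background-site minor-allele
    frequencies; planted markers draw from ``marker_maf`` (>= 0.3 so they
    clear the MAF filter decisively).
    """

    n_contigs: int = 1
    contig_length: int = 50_000
    gc_content: float = 0.40
    n_samples: int = 22
    inbreeding_f: float = 0.41
    n_sites: int = 200
    maf_distribution: tuple = ("uniform", 0.05, 0.5)
    mean_depth: float = 3.5
    seed: int = 0
    n_caps_markers: int = 5
    n_duplicate_decoys: int = 2
    n_linked_pairs: int = 2
    duplicate_identity: float = 0.95
    marker_maf: tuple[float, float] = (0.30, 0.45)
    flank_radius: int = 1000
    # planted-site realization conditions (see simulate_study docstring)
    marker_min_typed: int = 19
    marker_min_realized_maf: float = 0.25

    def __post_init__(self) -> None:
        for name in ("n_contigs", "contig_length", "n_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("n_sites", "n_caps_markers", "n_duplicate_decoys", "n_linked_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("gc_content", "inbreeding_f"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth <= 0:
            raise ValueError(f"mean_depth must be > 0, got {self.mean_depth}")
        if self.contig_length < 2 * self.flank_radius + 1 and (
            self.n_caps_markers or self.n_duplicate_decoys or self.n_linked_pairs
        ):
            raise ValueError(
                "contig_length must be >= 2*flank_radius + 1 to host planted sites"
            )
        if not 0.0 < self.duplicate_identity <= 1.0:
            raise ValueError("duplicate_identity must be in (0, 1]")


@dataclass
class PlantedMarker:
    contig: str
    pos: int  # 1-based
    ref: str  # cut allele (written into the reference)
    alt: str  # uncut allele
    enzyme: str
    cut_allele: str
    kind: str = "clean"  # clean | duplicate_decoy | linked_decoy | linked_partner


@dataclass
class PlantedDuplicate:
    src_contig: str
    src_start: int  # 0-based half-open
    src_end: int
    dest_contig: str
    dest_start: int
    requested_identity: float
    realized_identity: float


@dataclass
class SimulationTruth:
    """Ground truth for recovery tests."""

    planted_markers: list[PlantedMarker] = field(default_factory=list)
    planted_duplicates: list[PlantedDuplicate] = field(default_factory=list)
    true_freqs: dict = field(default_factory=dict)  # (contig, pos) -> alt freq
    true_f: float = 0.0
    seed: int = 0

    def expected_recovered(self) -> list[PlantedMarker]:
        return [m for m in self.planted_markers if m.kind in ("clean", "linked_partner")]

    def expected_rejected(self) -> list[PlantedMarker]:
        return [
            m
            for m in self.planted_markers
            if m.kind in ("duplicate_decoy", "linked_decoy")
        ]


# ---------------------------------------------------------------------------
# reference genome
# ---------------------------------------------------------------------------


def generate_reference(config: SimulationConfig) -> ReferenceGenome:
    """I.i.d. random contigs at the requested GC fraction (deterministic)."""
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    contigs = {}
    for i in range(config.n_contigs):
        seq = rng.choice(bases, size=config.contig_length, p=probs)
        contigs[f"contig{i + 1}"] = "".join(seq)
    return ReferenceGenome(contigs)


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------


def planting_options(enzyme: Enzyme) -> list[tuple[int, str, str]]:
    """(offset, cut_base, uncut_base) choices that break the site cleanly."""
    out = []
    for o, sym in enumerate(enzyme.recognition):
        allowed = IUPAC[sym]
        for cut in sorted(allowed):
            for uncut in sorted(set("ACGT") - allowed):
                out.append((o, cut, uncut))
    return out


def _break_base(pattern_sets, col: int, current: str, rng) -> str:
    """A base that defeats the pattern column, different from *current*."""
    choices = sorted(set("ACGT") - pattern_sets[col] - {current})
    if not choices:  # N column: any change keeps the match; pick any other base
        choices = sorted(set("ACGT") - {current})
    return choices[rng.integers(len(choices))]


def plant_caps_site(
    genome: ReferenceGenome,
    contig: str,
    position: int,
    enzyme: Enzyme,
    cut_allele: str,
    uncut_allele: str,
    offset: int | None = None,
    rng: np.random.Generator | None = None,
    clean_radius: int = 680,
) -> tuple[ReferenceGenome, PlantedMarker]:
    """Edit the genome so the SNP at *position* (1-based) is CAPS-able.

    A concrete realization of the enzyme's recognition site is written with
    the SNP at recognition *offset* carrying *cut_allele*; substituting
    *uncut_allele* there must destroy the match.  The neighborhood (up to
    *clean_radius* bp either side — wide enough to cover any later
    amplicon) is then scrubbed of every other match of this enzyme under
    both alleles, so the planted marker passes the local-uniqueness and
    non-target-digest checks by construction.
    """
    rng = rng or np.random.default_rng(0)
    L = enzyme.size
    opts = [
        (o, c, u)
        for o, c, u in planting_options(enzyme)
        if c == cut_allele.upper() and u == uncut_allele.upper()
    ]
    if offset is not None:
        opts = [t for t in opts if t[0] == offset]
    if not opts:
        raise PlantingError(
            f"{enzyme.name}: site {enzyme.recognition} cannot be broken by "
            f"{cut_allele}->{uncut_allele}"
            + (f" at offset {offset}" if offset is not None else "")
        )
    o = opts[0][0]
    pos0 = position - 1
    s0 = pos0 - o  # recognition start in the contig
    if s0 < 0 or s0 + L > genome.length(contig):
        raise PlantingError("recognition site does not fit inside the contig")

    seq = list(genome[contig])
    # concrete realization of the recognition site, cut allele at the SNP
    for i, sym in enumerate(enzyme.recognition):
        if i == o:
            seq[s0 + i] = cut_allele.upper()
        else:
            allowed = sorted(IUPAC[sym])
            seq[s0 + i] = allowed[rng.integers(len(allowed))]

    w_lo = max(0, s0 - clean_radius)
    w_hi = min(len(seq), s0 + L + clean_radius)
    pat_sets = tuple(IUPAC[c] for c in enzyme.recognition)
    rc_sets = tuple(IUPAC[c] for c in revcomp(enzyme.recognition))

    for _round in range(500):
        window = "".join(seq[w_lo:w_hi])
        offending = []
        for allele in (cut_allele, uncut_allele):
            view = list(window)
            view[pos0 - w_lo] = allele.upper()
            for p, strand in match_recognition("".join(view), enzyme):
                if allele == cut_allele and p + w_lo == s0 and strand == "+":
                    continue  # the intended match
                offending.append((p + w_lo, strand))
        if not offending:
            break
        p, strand = offending[0]
        span = [
            b
            for b in range(p, p + L)
            if not (s0 <= b < s0 + L) and b != pos0 and 0 <= b < len(seq)
        ]
        if not span:
            raise PlantingError(
                f"{enzyme.name}: cannot break unintended match at {p} "
                "without touching the planted site"
            )
        b = span[rng.integers(len(span))]
        sets = pat_sets if strand == "+" else rc_sets
        seq[b] = _break_base(sets, b - p, seq[b], rng)
    else:
        raise PlantingError(f"{enzyme.name}: neighborhood would not come clean")

    new_genome = genome.with_sequence(contig, "".join(seq))
    marker = PlantedMarker(
        contig=contig,
        pos=position,
        ref=cut_allele.upper(),
        alt=uncut_allele.upper(),
        enzyme=enzyme.name,
        cut_allele=cut_allele.upper(),
    )
    return new_genome, marker


def plant_duplicate(
    genome: ReferenceGenome,
    src_contig: str,
    src_start: int,
    src_end: int,
    dest_contig: str,
    dest_start: int,
    identity: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[ReferenceGenome, PlantedDuplicate]:
    """Write a degraded copy of a source segment at a destination locus.

    The number of substitutions is fixed at ``round((1 - identity) * len)``
    (positions drawn without replacement), so the realized identity is
    within rounding of the request.  Source and destination intervals must
    not overlap.
    """
    rng = rng or np.random.default_rng(0)
    if not 0.0 < identity <= 1.0:
        raise ValueError(f"identity must be in (0, 1], got {identity}")
    length = src_end - src_start
    if length <= 0:
        raise ValueError("empty source interval")
    if src_start < 0 or src_end > genome.length(src_contig):
        raise ValueError("source interval outside contig bounds")
    dest_end = dest_start + length
    if dest_start < 0 or dest_end > genome.length(dest_contig):
        raise ValueError("destination interval outside contig bounds")
    if src_contig == dest_contig and src_start < dest_end and dest_start < src_end:
        raise ValueError("source and destination intervals overlap")

    segment = list(genome[src_contig][src_start:src_end])
    n_mut = round((1.0 - identity) * length)
    for b in rng.choice(length, size=n_mut, replace=False):
        others = sorted(set("ACGT") - {segment[b]})
        segment[b] = others[rng.integers(len(others))]
    realized = 1.0 - n_mut / length

    dest_seq = genome[dest_contig]
    new_seq = dest_seq[:dest_start] + "".join(segment) + dest_seq[dest_end:]
    new_genome = genome.with_sequence(dest_contig, new_seq)
    return new_genome, PlantedDuplicate(
        src_contig=src_contig,
        src_start=src_start,
        src_end=src_end,
        dest_contig=dest_contig,
        dest_start=dest_start,
        requested_identity=identity,
        realized_identity=realized,
    )


# ---------------------------------------------------------------------------
# genotypes, depth, missingness
# ---------------------------------------------------------------------------


def simulate_genotypes(
    true_freqs,
    inbreeding_f: float,
    n_samples: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw per-site genotypes from the inbreeding (mixed-mating) model.

    *true_freqs* are alternate-allele frequencies in (0, 1); the returned
    array holds reference-allele dosages (2/1/0) of shape
    ``(n_sites, n_samples)``.  Sites are independent.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    q = np.asarray(true_freqs, dtype=float)
    if ((q <= 0) | (q >= 1)).any():
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    if not 0.0 <= inbreeding_f <= 1.0:
        raise ValueError("inbreeding_f must be in [0, 1]")
    p = 1.0 - q
    f = inbreeding_f
    probs = np.stack(
        [q * q + f * p * q, 2 * p * q * (1 - f), p * p + f * p * q], axis=1
    )  # columns: dosage 0, 1, 2
    u = rng.random((q.size, n_samples))
    cum = probs.cumsum(axis=1)
    dosage = (u[:, :, None] >= cum[:, None, :]).sum(axis=2).astype(np.int8)
    return dosage


def simulate_depth_missingness(
    dosage: np.ndarray,
    mean_depth: float,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson per-call depth; calls with zero reads become missing."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    dp = rng.poisson(mean_depth, size=dosage.shape).astype(np.int32)
    out = dosage.copy()
    out[dp == 0] = MISSING
    return out, dp


# ---------------------------------------------------------------------------
# full study simulation
# ---------------------------------------------------------------------------

#: enzymes with robust planting options, cycled over planted markers
_PLANT_ENZYMES = ("NdeI", "AseI", "Bsu36I", "SacII", "AflIII", "NsiI", "BclI-HF", "MseI")


@dataclass
class SimulationResult:
    genome: ReferenceGenome
    matrix: GenotypeMatrix
    truth: SimulationTruth


def _draw_planted_site(
    q: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype + depth vector for a planted site, conditioned to be usable.

    Planted markers are the ground truth of recovery tests: they must
    actually satisfy the conditions they are planted to represent, so the
    realization is redrawn until the site is well-typed
    (``marker_min_typed`` samples after depth-driven missingness), has a
    realized MAF of at least ``marker_min_realized_maf``, and leans toward
    heterozygote deficit (the selfing signature) rather than excess.
    """
    from .popgen_filters import hwe_exact, site_stats

    min_typed = min(config.marker_min_typed, config.n_samples)
    for _ in range(1000):
        row = simulate_genotypes([q], config.inbreeding_f, config.n_samples, rng)[0]
        row, dp = simulate_depth_missingness(row, config.mean_depth, rng)
        typed = row[row != MISSING]
        if typed.size < min_typed:
            continue
        stats = site_stats(row)
        if stats.maf < config.marker_min_realized_maf:
            continue
        hwe = hwe_exact(stats.n_ref_hom, stats.n_het, stats.n_alt_hom)
        if not hwe.p_deficit < hwe.p_excess:
            continue
        return row, dp
    raise PlantingError(
        "could not realize a planted site satisfying the marker conditions; "
        "check n_samples / mean_depth / marker_maf"
    )


def _random_contig(length: int, gc: float, rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.random.default_rng(rng.integers(2**31)).choice(
        np.array(list("ACGT")), size=length, p=probs
    ))


def simulate_study(config: SimulationConfig) -> SimulationResult:
    """Generate a complete study dataset under one configuration.

    Layout: every planted unit gets its own contig — ``n_caps_markers``
    clean CAPS SNPs, ``n_duplicate_decoys`` CAPS SNPs whose SNP-centered
    201 bp window is additionally copied (at ``duplicate_identity``) into
    a reserved region of an auxiliary contig, and ``n_linked_pairs``
    contigs each holding a pair of CAPS SNPs with nearly identical
    genotype vectors, the noisier of which carries extra missing calls so
    linkage pruning must drop exactly it.  ``n_sites`` unlinked background
    SNPs live on ``n_contigs`` separate background contigs: since the
    linkage window never spans contigs, linkage tests see only the planted
    positive controls, never chance correlations with background sites —
    linkage, like duplication, is controlled rather than incidental.
    Planted flanks carry no background variation, so primer design sees
    fully conserved sequence, and planted-site genotype draws are
    conditioned on the marker conditions (see :func:`_draw_planted_site`).
    """
    rng = np.random.default_rng(config.seed)
    truth = SimulationTruth(true_f=config.inbreeding_f, seed=config.seed)
    catalog = {e.name: e for e in default_enzyme_catalog()}
    radius = config.flank_radius

    # --- genome layout -----------------------------------------------------
    unit_len = 2 * radius + 401
    pair_len = 4 * radius + 501
    snp_at = radius + 201  # 1-based position of a unit's (first) SNP
    contigs: dict[str, str] = {}
    units: list[tuple[str, str, list[int]]] = []  # (kind, contig, positions)
    k = 0
    for _ in range(config.n_caps_markers):
        k += 1
        name = f"chr_m{k:02d}"
        contigs[name] = _random_contig(unit_len, config.gc_content, rng)
        units.append(("clean", name, [snp_at]))
    for _ in range(config.n_duplicate_decoys):
        k += 1
        name = f"chr_m{k:02d}"
        contigs[name] = _random_contig(unit_len, config.gc_content, rng)
        units.append(("duplicate_decoy", name, [snp_at]))
    for _ in range(config.n_linked_pairs):
        k += 1
        name = f"chr_m{k:02d}"
        contigs[name] = _random_contig(pair_len, config.gc_content, rng)
        units.append(("linked_pair", name, [snp_at, snp_at + 2 * radius + 100]))
    for b in range(config.n_contigs if config.n_sites else 0):
        name = f"chr_z{b + 1:02d}"  # background contigs sort after planted ones
        contigs[name] = _random_contig(config.contig_length, config.gc_content, rng)
    if config.n_duplicate_decoys and not any(n.startswith("chr_z") for n in contigs):
        contigs["chr_z01"] = _random_contig(
            max(config.contig_length, 300 * config.n_duplicate_decoys),
            config.gc_content,
            rng,
        )
    genome = ReferenceGenome(contigs)

    # --- plant markers -----------------------------------------------------
    enzyme_cycle = [catalog[n] for n in _PLANT_ENZYMES]
    planted: list[PlantedMarker] = []
    idx = 0

    def plant(kind: str, contig: str, pos: int) -> PlantedMarker:
        nonlocal genome, idx
        enzyme = enzyme_cycle[idx % len(enzyme_cycle)]
        idx += 1
        options = planting_options(enzyme)
        last_err: PlantingError | None = None
        for _attempt in range(10):
            o, cut, uncut = options[rng.integers(len(options))]
            try:
                genome, marker = plant_caps_site(
                    genome, contig, pos, enzyme, cut, uncut, offset=o, rng=rng
                )
            except PlantingError as err:
                last_err = err
                continue
            marker.kind = kind
            planted.append(marker)
            return marker
        raise last_err  # pragma: no cover - planting is overwhelmingly feasible

    linked_pairs: list[tuple[PlantedMarker, PlantedMarker]] = []
    decoy_markers: list[PlantedMarker] = []
    for kind, contig, positions in units:
        if kind == "linked_pair":
            a = plant("linked_partner", contig, positions[0])
            b = plant("linked_decoy", contig, positions[1])
            linked_pairs.append((a, b))
        elif kind == "duplicate_decoy":
            decoy_markers.append(plant(kind, contig, positions[0]))
        else:
            plant(kind, contig, positions[0])

    # duplicate each decoy's SNP-centered 201 bp window into the reserved
    # tail of the last auxiliary contig
    dup_reserved: list[tuple[str, int, int]] = []
    if decoy_markers:
        aux = sorted(n for n in genome.names() if n.startswith("chr_z"))[-1]
        dest = genome.length(aux)
        for m in decoy_markers:
            dest -= 250
            genome, dup = plant_duplicate(
                genome,
                m.contig,
                (m.pos - 1) - 100,
                (m.pos - 1) + 101,
                aux,
                dest,
                identity=config.duplicate_identity,
                rng=rng,
            )
            truth.planted_duplicates.append(dup)
            dup_reserved.append((aux, dest - 50, dest + 251))

    # --- background sites (on background contigs only) ---------------------
    dist_name, lo, hi = config.maf_distribution
    if dist_name != "uniform":
        raise ValueError(f"unknown maf_distribution {dist_name!r}")
    bg_contigs = sorted(n for n in genome.names() if n.startswith("chr_z"))
    background: list[tuple[str, int, str, str, float]] = []
    used: set[tuple[str, int]] = set()
    attempts = 0
    while len(background) < config.n_sites and attempts < config.n_sites * 50 + 100:
        attempts += 1
        contig = bg_contigs[int(rng.integers(len(bg_contigs)))]
        pos0 = int(rng.integers(genome.length(contig)))
        if (contig, pos0) in used or any(
            c == contig and s <= pos0 < e for c, s, e in dup_reserved
        ):
            continue
        ref = genome.base(contig, pos0 + 1)
        if ref not in "ACGT":
            continue
        used.add((contig, pos0))
        alt = sorted(set("ACGT") - {ref})[rng.integers(3)]
        background.append((contig, pos0 + 1, ref, alt, float(rng.uniform(lo, hi))))
    if len(background) < config.n_sites:
        raise PlantingError("could not place all background sites")

    # --- genotypes ---------------------------------------------------------
    entries: list[tuple[str, int, str, str, float, PlantedMarker | None]] = []
    for m in planted:
        entries.append(
            (m.contig, m.pos, m.ref, m.alt, float(rng.uniform(*config.marker_maf)), m)
        )
    for contig, pos, ref, alt, maf in background:
        entries.append((contig, pos, ref, alt, maf, None))
    entries.sort(key=lambda e: (e[0], e[1]))

    sites = [VariantSite(c, p, r, (a,)) for c, p, r, a, _, _ in entries]
    truth.true_freqs = {(c, p): f for (c, p, _, _, f, _) in entries}
    index = {(s.contig, s.pos): i for i, s in enumerate(sites)}

    n = config.n_samples
    dosage = np.full((len(sites), n), MISSING, dtype=np.int8)
    dp = np.zeros((len(sites), n), dtype=np.int32)

    bg_idx = [i for i, e in enumerate(entries) if e[5] is None]
    if bg_idx:
        freqs = np.array([entries[i][4] for i in bg_idx])
        bg_dos = simulate_genotypes(freqs, config.inbreeding_f, n, rng)
        bg_dos, bg_dp = simulate_depth_missingness(bg_dos, config.mean_depth, rng)
        dosage[bg_idx] = bg_dos
        dp[bg_idx] = bg_dp

    partner_rows: dict[tuple[str, int], int] = {}
    for i, (c, p, _, _, q, m) in enumerate(entries):
        if m is None:
            continue
        if m.kind == "linked_decoy":
            continue  # filled from the partner below
        dosage[i], dp[i] = _draw_planted_site(q, config, rng)

    for a, b in linked_pairs:
        ia, ib = index[(a.contig, a.pos)], index[(b.contig, b.pos)]
        dosage[ib] = dosage[ia]
        dp[ib] = dp[ia]
        truth.true_freqs[(b.contig, b.pos)] = truth.true_freqs[(a.contig, a.pos)]
        typed = [j for j in range(n) if dosage[ib, j] != MISSING]
        # light genotype noise (keeps r2 high but < 1) ...
        flip = typed[int(rng.integers(len(typed)))]
        dosage[ib, flip] = {0: 1, 1: 0, 2: 1}[int(dosage[ib, flip])]
        # ... and strictly more missing data, so pruning drops the decoy
        typed.remove(flip)
        for j in rng.choice(typed, size=2, replace=False):
            dosage[ib, j] = MISSING
            dp[ib, j] = 0

    samples = [f"S{j + 1:02d}" for j in range(n)]
    matrix = GenotypeMatrix.from_dosage(sites, samples, dosage, dp)
    truth.planted_markers = planted
    return SimulationResult(genome=genome, matrix=matrix, truth=truth)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_simulation(
    genome: ReferenceGenome,
    matrix: GenotypeMatrix,
    truth: SimulationTruth,
    out_dir,
) -> dict[str, str]:
    """Write FASTA + VCF + truth tables; returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "fasta": os.path.join(out_dir, "reference.fa"),
        "vcf": os.path.join(out_dir, "variants.vcf"),
        "truth": os.path.join(out_dir, "truth_markers.tsv"),
        "duplicates": os.path.join(out_dir, "truth_duplicates.tsv"),
    }
    try:
        write_fasta(genome, paths["fasta"])
        write_vcf(matrix, genome, paths["vcf"])
        with open(paths["truth"], "w") as fh:
            fh.write(
                "contig\tpos\tref\talt\tenzyme\tcut_allele\tkind\ttrue_alt_freq\ttrue_f\tseed\n"
            )
            marker_index = {(m.contig, m.pos): m for m in truth.planted_markers}
            for site in matrix.sites:
                key = (site.contig, site.pos)
                m = marker_index.get(key)
                freq = truth.true_freqs.get(key, float("nan"))
                fh.write(
                    "\t".join(
                        [
                            site.contig,
                            str(site.pos),
                            site.ref,
                            site.alts[0],
                            m.enzyme if m else ".",
                            m.cut_allele if m else ".",
                            m.kind if m else "background",
                            f"{freq:.6g}",
                            f"{truth.true_f:.6g}",
                            str(truth.seed),
                        ]
                    )
                    + "\n"
                )
        with open(paths["duplicates"], "w") as fh:
            fh.write(
                "src_contig\tsrc_start\tsrc_end\tdest_contig\tdest_start\t"
                "requested_identity\trealized_identity\n"
            )
            for d in truth.planted_duplicates:
                fh.write(
                    f"{d.src_contig}\t{d.src_start}\t{d.src_end}\t{d.dest_contig}\t"
                    f"{d.dest_start}\t{d.requested_identity:.4f}\t{d.realized_identity:.4f}\n"
                )
    except OSError as exc:
        raise OSError(f"writing simulation to {out_dir}: {exc}") from exc
    return paths
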