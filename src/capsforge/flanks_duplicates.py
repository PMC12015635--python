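"""Per-sample consensus flanks around candidate SNPs and duplicate screening.

Each candidate SNP gets a :class:`FlankSet`: the reference sequence 1000 bp
either side of the SNP plus one consensus sequence per sample, in which
heterozygous substitutions are written as IUPAC two-base codes and untyped
positions as N.  Spurious SNPs caused by reads from duplicated regions
co-mapping to one locus are screened by a seed-and-extend local-alignment
search (:func:`duplicate_scan`) of short windows centered on the SNP
against whole genomes: a candidate fails (:func:`duplicate_verdict`) when
any single genome contains more than one >= 90 %-identity hit covering the
SNP position — the locus itself plus at least one near-identical copy.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .caps_design import AMBIG_FOR_PAIR, revcomp
from .variant_io import GenotypeMatrix, ReferenceGenome, VariantSite

__all__ = [
    "FlankSet",
    "SequenceHit",
    "extract_flanks",
    "duplicate_scan",
    "duplicate_verdict",
    "write_flank_fasta",
]


@dataclass
class FlankSet:
    """Reference and per-sample consensus sequences around one SNP.

    ``sample_cells`` maps each sample to a list of per-reference-position
    strings ("cells"): a substitution or IUPAC/N symbol occupies one cell;
    a homozygous deletion leaves empty cells; a homozygous insertion puts
    more than one base in a cell.  ``sample_flanks`` joins the cells, so
    sequences may differ in length when indels were applied literally.
    """

    site: VariantSite
    radius: int
    contig_start: int  # 0-based start of the flank on the contig
    reference_flank: str
    sample_cells: dict[str, list[str]]
    snp_offset: int  # 0-based index of the SNP in the reference flank
    clipped: tuple[int, int] = (0, 0)  # bp lost at the left/right contig edge

    @property
    def sample_flanks(self) -> dict[str, str]:
        return {name: "".join(cells) for name, cells in self.sample_cells.items()}


def extract_flanks(
    genome: ReferenceGenome,
    matrix: GenotypeMatrix,
    site: VariantSite,
    radius: int = 1000,
) -> FlankSet:
    """Build the consensus flank set for one candidate SNP.

    For every sample the reference flank is edited with that sample's
    calls at every matrix site inside the window: homozygous-alternate
    substitutions are applied, heterozygous substitutions become the IUPAC
    code of the two alleles, untyped positions become N.  Heterozygous or
    untyped indels are masked with N over their REF span (primers must
    never sit on an uncertain position); homozygous-alternate indels are
    applied literally.  A window crossing a contig edge is clipped, and
    the clip is recorded rather than raised.
    """
    contig_len = genome.length(site.contig)
    pos0 = site.pos - 1
    start = pos0 - radius
    end = pos0 + radius + 1
    clip_left = max(0, -start)
    clip_right = max(0, end - contig_len)
    start += clip_left
    end -= clip_right
    ref_flank = genome.slice(site.contig, start, end)
    snp_offset = pos0 - start

    cells = {
        name: list(ref_flank) for name in matrix.samples
    }  # one cell per reference position
    for i, vsite in enumerate(matrix.sites):
        if vsite.contig != site.contig:
            continue
        v0 = vsite.pos - 1
        span = len(vsite.ref)
        if v0 + span <= start or v0 >= end:
            continue
        for j, name in enumerate(matrix.samples):
            a1, a2 = matrix.gt[i, j]
            _apply_call(cells[name], vsite, v0 - start, span, a1, a2, len(ref_flank))
    return FlankSet(
        site=site,
        radius=radius,
        contig_start=start,
        reference_flank=ref_flank,
        sample_cells=cells,
        snp_offset=snp_offset,
        clipped=(clip_left, clip_right),
    )


def _apply_call(cells, vsite, offset, span, a1, a2, flank_len) -> None:
    """Edit one sample's cells for one variant call (in-place)."""
    missing = a1 < 0 or a2 < 0
    if not missing and a1 == 0 and a2 == 0:
        return  # homozygous reference: flank already correct
    alleles = None if missing else sorted({int(a1), int(a2)})
    is_indel = len(vsite.ref) != 1 or any(len(a) != 1 for a in vsite.alts)

    def mask_span() -> None:
        for k in range(span):
            if 0 <= offset + k < flank_len:
                cells[offset + k] = "N"

    if is_indel:
        if missing or len(alleles) > 1:
            mask_span()
            return
        # homozygous alternate indel: apply literally
        alt = vsite.alts[alleles[0] - 1]
        if 0 <= offset < flank_len:
            cells[offset] = alt
        for k in range(1, span):
            if 0 <= offset + k < flank_len:
                cells[offset + k] = ""
        return
    # single-base site
    if not 0 <= offset < flank_len:
        return
    if missing:
        cells[offset] = "N"
    elif len(alleles) == 1:
        cells[offset] = ([vsite.ref] + list(vsite.alts))[alleles[0]]
    else:
        bases = frozenset(([vsite.ref] + list(vsite.alts))[a] for a in alleles)
        cells[offset] = AMBIG_FOR_PAIR.get(bases, "N")


def write_flank_fasta(flank: FlankSet, path) -> None:
    """One FASTA per candidate: reference flank plus every sample flank."""
    sid = f"{flank.site.contig}_{flank.site.pos}_{flank.site.ref}_{flank.site.alts[0]}"
    with open(path, "w") as fh:
        fh.write(f">reference {sid}\n")
        for i in range(0, len(flank.reference_flank), 60):
            fh.write(flank.reference_flank[i : i + 60] + "\n")
        for name, seq in flank.sample_flanks.items():
            fh.write(f">{name} {sid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# duplicate screening
# ---------------------------------------------------------------------------


@dataclass
class SequenceHit:
    """One local-alignment hit of a SNP-centered query window."""

    query_id: str
    genome_index: int
    contig: str
    start: int  # 0-based half-open target interval
    end: int
    strand: str
    identity: float  # matches / alignment columns (BLAST convention)
    overlaps_snp: bool
    query_identity: float = 1.0  # matches / full query length


_aligner = Align.PairwiseAligner(
    mode="local",
    match_score=1,
    mismatch_score=-2,
    open_gap_score=-2.5,
    extend_gap_score=-0.5,
)


def _align_identity(query: str, target: str):
    """Best local alignment of query vs target.

    Returns (column identity, match count, query range, target range).
    """
    alignments = _aligner.align(target, query)
    try:
        aln = alignments[0]
    except IndexError:
        return None
    counts = aln.counts()
    columns = aln.shape[1]
    identity = counts.identities / columns if columns else 0.0
    t_rng = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
    q_rng = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
    return identity, counts.identities, q_rng, t_rng


def _seed_positions(query: str, target: str, k: int) -> list[tuple[int, int]]:
    """Exact k-mer seed matches (target_pos, query_pos) via str.find."""
    seeds = []
    kmers: dict[str, list[int]] = {}
    for q in range(len(query) - k + 1):
        kmers.setdefault(query[q : q + k], []).append(q)
    for kmer, qpos_list in kmers.items():
        t = target.find(kmer)
        while t != -1:
            for q in qpos_list:
                seeds.append((t, q))
            t = target.find(kmer, t + 1)
    return seeds


def build_seed_index(
    genomes: list[ReferenceGenome], ks: tuple[int, ...] = (11, 16)
) -> dict[int, dict[str, list[tuple[int, str, int]]]]:
    """Forward-strand k-mer location index over a set of genomes.

    Maps k -> kmer -> [(genome_index, contig, position)].  Building it once
    per run makes scanning many candidates cheap; :func:`duplicate_scan`
    accepts it through its *index* argument.
    """
    index: dict[int, dict[str, list[tuple[int, str, int]]]] = {k: {} for k in ks}
    for gi, genome in enumerate(genomes):
        for contig in genome.names():
            seq = genome[contig]
            for k in ks:
                sub = index[k]
                for p in range(len(seq) - k + 1):
                    sub.setdefault(seq[p : p + k], []).append((gi, contig, p))
    return index


def duplicate_scan(
    flank: FlankSet,
    genomes: list[ReferenceGenome],
    window_small: int = 41,
    window_large: int = 201,
    identity_min: float = 0.90,
    seed_k_small: int = 11,
    seed_k_large: int = 16,
    index: dict | None = None,
) -> list[SequenceHit]:
    """Seed-and-extend search of SNP-centered windows against whole genomes.

    Two windows (default 41 and 201 bp, both centered on the SNP) are
    searched against both strands of every genome; exact k-mer seeds
    (k = 11 / 16) are extended by banded local alignment with
    megablast-like scoring.  Overlapping hits at one locus are merged,
    keeping the best identity; ``overlaps_snp`` is true when the alignment
    covers the window center.  The marker's own reference genome should be
    first in *genomes* so the self-hit is always present.  When screening
    many candidates, pass a prebuilt :func:`build_seed_index` of the same
    *genomes* as *index*.
    """
    if not genomes:
        raise ValueError("at least one genome (the marker's own) is required")
    if index is None:
        index = build_seed_index(genomes, (seed_k_small, seed_k_large))
    sid = f"{flank.site.contig}_{flank.site.pos}_{flank.site.ref}_{flank.site.alts[0]}"
    hits: list[SequenceHit] = []
    for window, k in ((window_small, seed_k_small), (window_large, seed_k_large)):
        if window > len(flank.reference_flank):
            raise ValueError(f"window {window} larger than flank")
        half = window // 2
        q_start = flank.snp_offset - half
        q_end = flank.snp_offset + half + 1
        if q_start < 0 or q_end > len(flank.reference_flank):
            continue  # clipped flank: window would leave the contig
        sub = index[k]
        pad = max(10, window // 10)
        for strand in ("+", "-"):
            # search the reverse strand by reverse-complementing the query;
            # the window is odd, so its center index is strand-invariant
            query = flank.reference_flank[q_start:q_end]
            if strand == "-":
                query = revcomp(query)
            center = half
            grouped: dict[tuple[int, str], list[tuple[int, int]]] = {}
            for q in range(len(query) - k + 1):
                for gi, contig, t in sub.get(query[q : q + k], ()):
                    grouped.setdefault((gi, contig), []).append((t, q))
            for (gi, contig), seeds in sorted(grouped.items()):
                target = genomes[gi][contig]
                found: list[tuple] = []
                seen_spans: list[tuple[int, int]] = []
                for t, q in sorted(seeds):
                    t0 = max(0, t - q - pad)
                    t1 = min(len(target), t - q + window + pad)
                    if any(s <= t0 and t1 <= e for s, e in seen_spans):
                        continue
                    res = _align_identity(query, target[t0:t1])
                    if res is None:
                        continue
                    identity, n_match, q_rng, t_rng = res
                    found.append(
                        (
                            t0 + t_rng[0],
                            t0 + t_rng[1],
                            identity,
                            q_rng[0] <= center < q_rng[1],
                            n_match / len(query),
                        )
                    )
                    seen_spans.append((t0, t1))
                for s, e, ident, over, cov in _merge_intervals(found):
                    hits.append(
                        SequenceHit(
                            query_id=sid,
                            genome_index=gi,
                            contig=contig,
                            start=s,
                            end=e,
                            strand=strand,
                            identity=ident,
                            overlaps_snp=over,
                            query_identity=cov,
                        )
                    )
    return _dedupe_hits(hits)


def _merge_intervals(found):
    """Merge overlapping alignment intervals, keeping the best identity."""
    merged: list[list] = []
    for s, e, ident, over, cov in sorted(found):
        for m in merged:
            if s < m[1] and e > m[0]:  # overlap
                m[0] = min(m[0], s)
                m[1] = max(m[1], e)
                if ident > m[2]:
                    m[2] = ident
                m[3] = m[3] or over
                m[4] = max(m[4], cov)
                break
        else:
            merged.append([s, e, ident, over, cov])
    return [tuple(m) for m in merged]


def _dedupe_hits(hits: list[SequenceHit]) -> list[SequenceHit]:
    """Collapse the same target locus found through both windows/strands."""
    out: list[SequenceHit] = []
    for h in sorted(
        hits, key=lambda h: (h.genome_index, h.contig, h.start, -h.identity)
    ):
        for o in out:
            if (
                o.genome_index == h.genome_index
                and o.contig == h.contig
                and h.start < o.end
                and h.end > o.start
            ):
                if h.identity > o.identity:
                    o.identity = h.identity
                o.overlaps_snp = o.overlaps_snp or h.overlaps_snp
                o.query_identity = max(o.query_identity, h.query_identity)
                o.start = min(o.start, h.start)
                o.end = max(o.end, h.end)
                break
        else:
            out.append(h)
    return out


def duplicate_verdict(
    hits: list[SequenceHit], identity_min: float = 0.90
) -> tuple[bool, str]:
    """Pass/fail for one candidate from its duplicate-scan hits.

    A hit qualifies when it covers the SNP and its *query_identity*
    (matches over the full query length — the "identical to the query
    sequence" criterion) reaches *identity_min*; this also discards the
    very short high-identity local alignments a chance seed produces.
    Fails iff any single genome holds more than one qualifying hit; the
    self-hit counts as the first occurrence.  Returns (passed, reason).
    """
    per_genome: dict[int, int] = {}
    for h in hits:
        if h.query_identity >= identity_min and h.overlaps_snp:
            per_genome[h.genome_index] = per_genome.get(h.genome_index, 0) + 1
    for gi, n in sorted(per_genome.items()):
        if n > 1:
            return False, f"{n} qualifying hits in genome {gi}"
    return True, "unique"
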