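"""Reading and writing the standard formats the marker pipeline touches.

FASTA and VCF are handled through Biopython and pysam respectively; this
module adds the pipeline's in-memory containers (:class:`ReferenceGenome`,
:class:`VariantSite`, :class:`GenotypeMatrix`) and fixes the coordinate
conventions once: internal coordinates are 0-based half-open, everything
that crosses an I/O boundary (VCF, reports, SNP IDs) is 1-based.

Genotypes are stored as ref-allele dosage: 2 = reference homozygote,
1 = heterozygote, 0 = alternate homozygote, -1 = missing. Ploidy is fixed
at two; any other GT arity is a format error.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = -1  #: sentinel for a missing genotype call or unknown depth

__all__ = [
    "MISSING",
    "ReferenceGenome",
    "VariantSite",
    "GenotypeMatrix",
    "snp_id",
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "write_candidate_table",
]


class FormatError(ValueError):
    """A file violated the format contract (missing GT, bad ploidy, ...)."""


class ConsistencyError(ValueError):
    """Cross-file inconsistency, e.g. VCF REF not matching the genome."""


# ---------------------------------------------------------------------------
# reference genome
# ---------------------------------------------------------------------------


@dataclass
class ReferenceGenome:
    """Ordered collection of uppercase contig sequences.

    Parameters
    ----------
    contigs:
        Mapping contig name -> sequence (A/C/G/T/N, uppercase). Insertion
        order is the file order and is preserved on write.
    headers:
        Full FASTA headers keyed by contig name (name = first whitespace
        token of the header).
    """

    contigs: dict[str, str]
    headers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"contig {name!r} has an empty sequence")
        self.contigs = {n: s.upper() for n, s in self.contigs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def names(self) -> list[str]:
        return list(self.contigs)

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    def base(self, contig: str, pos: int) -> str:
        """Base at a 1-based position (the VCF convention)."""
        return self.contigs[contig][pos - 1]

    def slice(self, contig: str, start: int, end: int) -> str:
        """0-based half-open slice, clipped to the contig bounds."""
        seq = self.contigs[contig]
        return seq[max(start, 0) : min(end, len(seq))]

    def with_sequence(self, contig: str, seq: str) -> "ReferenceGenome":
        """Copy of the genome with one contig's sequence replaced."""
        new = dict(self.contigs)
        new[contig] = seq.upper()
        return ReferenceGenome(new, dict(self.headers))


# ---------------------------------------------------------------------------
# variant sites and the genotype matrix
# ---------------------------------------------------------------------------

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class VariantSite:
    """One VCF record: position, alleles. Calls live in the matrix."""

    contig: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        if not self.ref:
            raise FormatError("REF allele must be non-empty")
        if not self.alts:
            raise FormatError("at least one ALT allele required")

    @property
    def is_snp(self) -> bool:
        return (
            len(self.ref) == 1
            and self.ref in _ACGT
            and all(len(a) == 1 and a in _ACGT for a in self.alts)
        )

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1


def snp_id(contig: str, pos: int, ref: str, alt: str) -> str:
    """Candidate-table SNP identifier: ``<contig>_<pos>_<ref>_<alt>``."""
    return f"{contig}_{pos}_{ref}_{alt}"


class GenotypeMatrix:
    """Per-site, per-sample diploid calls with read depth.

    Attributes
    ----------
    sites:
        ``list[VariantSite]`` in input order.
    samples:
        ordered sample names.
    gt:
        int8 array of shape (n_sites, n_samples, 2); allele indices
        (0 = REF, 1 = first ALT, ...), ``MISSING`` for uncalled alleles.
    depth:
        int32 array (n_sites, n_samples); ``MISSING`` where DP is unknown.
    dosage:
        int8 array (n_sites, n_samples): reference-allele count per call
        (2 ref-hom / 1 het / 0 alt-hom), ``MISSING`` for missing calls.
    """

    def __init__(
        self,
        sites: list[VariantSite],
        samples: list[str],
        gt: np.ndarray,
        depth: np.ndarray | None = None,
    ) -> None:
        gt = np.asarray(gt, dtype=np.int8)
        if gt.shape != (len(sites), len(samples), 2):
            raise ValueError(
                f"gt shape {gt.shape} inconsistent with "
                f"{len(sites)} sites x {len(samples)} samples"
            )
        if depth is None:
            depth = np.full((len(sites), len(samples)), MISSING, dtype=np.int32)
        depth = np.asarray(depth, dtype=np.int32)
        if depth.shape != (len(sites), len(samples)):
            raise ValueError("depth shape inconsistent with gt")
        self.sites = list(sites)
        self.samples = list(samples)
        self.gt = gt
        self.depth = depth
        missing = (gt < 0).any(axis=2)
        dos = (gt == 0).sum(axis=2).astype(np.int8)
        dos[missing] = MISSING
        self.dosage = dos

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, indices) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (kept in order)."""
        idx = list(indices)
        return GenotypeMatrix(
            [self.sites[i] for i in idx],
            self.samples,
            self.gt[idx],
            self.depth[idx],
        )

    def site_index(self) -> dict[tuple[str, int], int]:
        return {(s.contig, s.pos): i for i, s in enumerate(self.sites)}

    @classmethod
    def from_dosage(
        cls,
        sites: list[VariantSite],
        samples: list[str],
        dosage: np.ndarray,
        depth: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Build a matrix from 0/1/2/MISSING ref-allele dosages (biallelic)."""
        dosage = np.asarray(dosage)
        gt = np.empty((*dosage.shape, 2), dtype=np.int8)
        gt[..., 0] = np.select(
            [dosage == 2, dosage == 1, dosage == 0], [0, 0, 1], default=MISSING
        )
        gt[..., 1] = np.select(
            [dosage == 2, dosage == 1, dosage == 0], [0, 1, 1], default=MISSING
        )
        return cls(sites, samples, gt, depth)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> ReferenceGenome:
    """Load a FASTA file into a :class:`ReferenceGenome` (uppercased)."""
    contigs: dict[str, str] = {}
    headers: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise FormatError(f"{path}: duplicate contig name {rec.id!r}")
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: empty record {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper()
        headers[rec.id] = rec.description
    if not contigs:
        raise FormatError(f"{path}: no FASTA records found")
    return ReferenceGenome(contigs, headers)


def write_fasta(genome: ReferenceGenome, path: str | os.PathLike) -> None:
    """Write contigs in order, wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description=genome.headers.get(name, name))
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(
    path: str | os.PathLike, genome: ReferenceGenome | None = None
) -> GenotypeMatrix:
    """Load every record of a VCF (plain or bgzipped) with GT and optional DP.

    If *genome* is given, each record's REF is cross-checked against it and
    a :class:`ConsistencyError` names the first offending site.
    """
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if "GT" not in vf.header.formats:
            raise FormatError(f"{path}: VCF has no GT FORMAT field")
        sites: list[VariantSite] = []
        gt_rows: list[np.ndarray] = []
        dp_rows: list[np.ndarray] = []
        for rec in vf:
            alts = tuple(rec.alts or ())
            if not alts:
                continue  # monomorphic reference record: nothing to genotype
            site = VariantSite(rec.contig, rec.pos, rec.ref, alts)
            if genome is not None and site.is_snp:
                if site.contig not in genome or site.pos > genome.length(site.contig):
                    raise ConsistencyError(
                        f"{path}: site {site.contig}:{site.pos} outside genome"
                    )
                base = genome.base(site.contig, site.pos)
                if base != site.ref:
                    raise ConsistencyError(
                        f"{path}: REF mismatch at {site.contig}:{site.pos} "
                        f"(VCF {site.ref!r}, genome {base!r})"
                    )
            grow = np.full((len(samples), 2), MISSING, dtype=np.int8)
            drow = np.full(len(samples), MISSING, dtype=np.int32)
            for j, name in enumerate(samples):
                call = rec.samples[name]
                alleles = call.get("GT")
                if alleles is None:
                    raise FormatError(
                        f"{path}: no GT for sample {name} at {rec.contig}:{rec.pos}"
                    )
                alleles = tuple(alleles)
                if len(alleles) != 2:
                    raise FormatError(
                        f"{path}: ploidy {len(alleles)} != 2 for sample {name} "
                        f"at {rec.contig}:{rec.pos}"
                    )
                grow[j] = [MISSING if a is None else a for a in alleles]
                dp = call.get("DP")
                if dp is not None:
                    drow[j] = dp
            sites.append(site)
            gt_rows.append(grow)
            dp_rows.append(drow)
    gt = (
        np.stack(gt_rows)
        if gt_rows
        else np.empty((0, len(samples), 2), dtype=np.int8)
    )
    dp = (
        np.stack(dp_rows)
        if dp_rows
        else np.empty((0, len(samples)), dtype=np.int32)
    )
    return GenotypeMatrix(sites, samples, gt, dp)


def write_vcf(matrix: GenotypeMatrix, genome: ReferenceGenome, path) -> None:
    """Write a minimal, deterministic VCF v4.2 with GT:DP per call.

    A plain-text writer is used so that identical inputs produce
    byte-identical files (a contract the simulator relies on).
    """
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=capsforge\n")
    for name in genome.names():
        buf.write(f"##contig=<ID={name},length={genome.length(name)}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples)
        + "\n"
    )
    for i, site in enumerate(matrix.sites):
        fields = [
            site.contig,
            str(site.pos),
            ".",
            site.ref,
            ",".join(site.alts),
            ".",
            "PASS",
            ".",
            "GT:DP",
        ]
        for j in range(matrix.n_samples):
            a1, a2 = matrix.gt[i, j]
            gt_str = (
                "./."
                if a1 < 0 or a2 < 0
                else f"{a1}/{a2}"
            )
            dp = matrix.depth[i, j]
            fields.append(f"{gt_str}:{'.' if dp < 0 else dp}")
        buf.write("\t".join(fields) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# candidate tables
# ---------------------------------------------------------------------------


def write_candidate_table(records, path, columns: list[str] | None = None) -> None:
    """Write candidate rows as TSV with stable column order.

    *records* is an iterable of dicts; a ``snp_id`` key is expected (build it
    with :func:`snp_id`). An empty iterable yields a header-only file.
    """
    import pandas as pd

    rows = list(records)
    if columns is None:
        columns = list(rows[0]) if rows else ["snp_id"]
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, sep="\t", index=False)
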