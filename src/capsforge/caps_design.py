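"""CAPS / PCR-RFLP marker design.

A CAPS (cleaved amplified polymorphic sequence) marker is a SNP that sits
inside a restriction-enzyme recognition site: one allele completes the
site (the *digest allele* — the amplicon is cut into two fragments), the
other destroys it (single uncut band); heterozygotes show all three bands.

This module provides the enzyme catalog, IUPAC-aware recognition-site
matching, discovery of allele-specific sites around a candidate SNP, a
local-uniqueness rule (no second constitutive site near the SNP),
constraint-based primer design restricted to conserved flank regions, and
in-silico amplicon digestion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "IUPAC",
    "AMBIG_FOR_PAIR",
    "revcomp",
    "Enzyme",
    "CandidateCaps",
    "PrimerPair",
    "MarkerSpec",
    "DesignConstraints",
    "load_enzyme_catalog",
    "default_enzyme_catalog",
    "load_marker_panel",
    "load_panel_maf",
    "match_recognition",
    "allele_specific_sites",
    "uniqueness_check",
    "melting_temperature",
    "conserved_mask",
    "design_primers",
    "nontarget_site_check",
    "predict_digest",
]

# ---------------------------------------------------------------------------
# IUPAC alphabet
# ---------------------------------------------------------------------------

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: two-base ambiguity code for a heterozygous call, e.g. {"A","G"} -> "R"
AMBIG_FOR_PAIR: dict[frozenset[str], str] = {
    bases: code for code, bases in IUPAC.items() if len(bases) == 2
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# enzymes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition sequence and cut offsets.

    ``cut_top`` / ``cut_bottom`` are measured in bp from the 5' start of
    the recognition sequence on the strand carrying it; for offset cutters
    (MnlI-type) they may lie outside the recognition span.
    """

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int
    source: str = ""

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError(f"enzyme {self.name}: empty recognition sequence")
        bad = set(self.recognition.upper()) - set(IUPAC)
        if bad:
            raise ValueError(
                f"enzyme {self.name}: non-IUPAC symbol(s) {sorted(bad)} "
                f"in recognition sequence {self.recognition!r}"
            )
        object.__setattr__(self, "recognition", self.recognition.upper())

    @property
    def size(self) -> int:
        return len(self.recognition)

    @property
    def palindromic(self) -> bool:
        return revcomp(self.recognition) == self.recognition


def load_enzyme_catalog(path) -> list[Enzyme]:
    """Load a REBASE-like TSV (name, recognition, cut_top, cut_bottom[, source])."""
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty enzyme catalog")
        return []
    if table.empty:
        warnings.warn(f"{path}: empty enzyme catalog")
        return []
    enzymes = []
    for _, row in table.iterrows():
        enzymes.append(
            Enzyme(
                name=row["name"],
                recognition=row["recognition"],
                cut_top=int(row["cut_top"]),
                cut_bottom=int(row["cut_bottom"]),
                source=str(row.get("source", "")),
            )
        )
    return enzymes


def _data_path(name: str):
    return resources.files("capsforge.data").joinpath(name)


def default_enzyme_catalog() -> list[Enzyme]:
    """The packaged catalog of the 17 validated-marker enzymes."""
    with resources.as_file(_data_path("enzymes.tsv")) as p:
        return load_enzyme_catalog(p)


def load_marker_panel() -> pd.DataFrame:
    """Packaged specifications of the 17 validated markers (report fixture)."""
    with resources.as_file(_data_path("marker_panel.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_panel_maf() -> pd.DataFrame:
    """Packaged per-locus minor-allele frequencies of the validated markers."""
    with resources.as_file(_data_path("panel_maf.tsv")) as p:
        return pd.read_csv(p, sep="\t")


# ---------------------------------------------------------------------------
# recognition-site matching
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4096)
def _pattern_regex(pattern: str):
    import re

    # lookahead so overlapping matches are all reported
    body = "".join(
        c if len(IUPAC[c]) == 1 else "[" + "".join(sorted(IUPAC[c])) + "]"
        for c in pattern
    )
    return re.compile(f"(?=({body}))")


def _scan(sequence: str, pattern: str) -> list[int]:
    """All start offsets where the IUPAC *pattern* matches *sequence*.

    Degeneracy is honored on the pattern side only: an ambiguous or N base
    in the sequence never matches (an uncertain base cannot certify a
    recognition site).
    """
    return [m.start() for m in _pattern_regex(pattern).finditer(sequence)]


def match_recognition(
    sequence: str, enzyme: Enzyme, both_strands: bool = True
) -> list[tuple[int, str]]:
    """Positions (0-based start, strand) of recognition-site matches.

    Reverse-strand matches are reported in forward coordinates (start of
    the matched span on the given sequence).  Palindromic enzymes are
    reported once, on the forward strand.
    """
    sequence = sequence.upper()
    hits = [(p, "+") for p in _scan(sequence, enzyme.recognition)]
    if both_strands and not enzyme.palindromic:
        hits += [(p, "-") for p in _scan(sequence, revcomp(enzyme.recognition))]
    return sorted(hits)


def cut_position(match_pos: int, strand: str, enzyme: Enzyme) -> int:
    """Top(sense)-strand cut coordinate of a recognition match.

    Measured from the start of the sequence the match was found on; for a
    reverse-strand match the enzyme's top-strand offset is mirrored.
    """
    if strand == "+":
        return match_pos + enzyme.cut_top
    return match_pos + enzyme.size - enzyme.cut_top


# ---------------------------------------------------------------------------
# allele-specific site discovery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateCaps:
    """A SNP embedded in an allele-specific recognition site."""

    snp_id: str
    enzyme: Enzyme
    digest_allele: str  # allele whose sequence completes the site
    other_allele: str
    match_offset: int  # recognition start relative to the SNP (<= 0)
    strand: str


def _allele_versions(flank, site) -> tuple[str, str, str, str]:
    """Reference flank with each allele substituted at the SNP."""
    ref_allele = site.ref
    alt_allele = site.alts[0]
    seq = flank.reference_flank
    off = flank.snp_offset
    ref_seq = seq[:off] + ref_allele + seq[off + 1 :]
    alt_seq = seq[:off] + alt_allele + seq[off + 1 :]
    return ref_allele, alt_allele, ref_seq, alt_seq


def _overlapping(matches: list[tuple[int, str]], snp_offset: int, size: int):
    return [(p, s) for p, s in matches if p <= snp_offset < p + size]


def allele_specific_sites(flank, catalog: list[Enzyme]) -> list[CandidateCaps]:
    """Find enzymes whose recognition site is completed by exactly one allele.

    Both allele versions of the reference flank are scanned in a window of
    one recognition length either side of the SNP; a candidate is emitted
    iff one allele version has at least one match overlapping the SNP and
    the other has none there.
    """
    site = flank.site
    ref_allele, alt_allele, ref_seq, alt_seq = _allele_versions(flank, site)
    off = flank.snp_offset
    out: list[CandidateCaps] = []
    for enzyme in catalog:
        lo = max(0, off - enzyme.size + 1)
        hi = min(len(ref_seq), off + enzyme.size)
        window_ref = ref_seq[lo:hi]
        window_alt = alt_seq[lo:hi]
        snp_in_window = off - lo
        m_ref = _overlapping(
            match_recognition(window_ref, enzyme), snp_in_window, enzyme.size
        )
        m_alt = _overlapping(
            match_recognition(window_alt, enzyme), snp_in_window, enzyme.size
        )
        if bool(m_ref) == bool(m_alt):
            continue  # constitutive or absent: no allele specificity
        digest, other = (ref_allele, alt_allele) if m_ref else (alt_allele, ref_allele)
        pos, strand = (m_ref or m_alt)[0]
        out.append(
            CandidateCaps(
                snp_id=f"{site.contig}_{site.pos}_{site.ref}_{site.alts[0]}",
                enzyme=enzyme,
                digest_allele=digest,
                other_allele=other,
                match_offset=(pos + lo) - off,
                strand=strand,
            )
        )
    return out


def constitutive_matches(flank, enzyme: Enzyme) -> list[tuple[int, str]]:
    """Recognition matches present for both alleles of the flank's SNP."""
    _, _, ref_seq, alt_seq = _allele_versions(flank, flank.site)
    ref_m = set(match_recognition(ref_seq, enzyme))
    alt_m = set(match_recognition(alt_seq, enzyme))
    return sorted(ref_m & alt_m)


def uniqueness_check(
    flank, candidate: CandidateCaps, exclusion_radius: int = 150
) -> bool:
    """True iff no constitutive site of the candidate's enzyme lies within
    *exclusion_radius* bp either side of the SNP (span overlap counts)."""
    off = flank.snp_offset
    lo = off - exclusion_radius
    hi = off + exclusion_radius
    size = candidate.enzyme.size
    for pos, _strand in constitutive_matches(flank, candidate.enzyme):
        if pos + size - 1 >= lo and pos <= hi:
            return False
    return True


# ---------------------------------------------------------------------------
# melting temperature
# ---------------------------------------------------------------------------


def melting_temperature(primer: str) -> float:
    """Nearest-neighbor duplex melting temperature in deg C.

    Uses the unified 1998 nearest-neighbor parameter set at 50 mM
    monovalent cation and 250 nM primer (no divalent corrections).
    """
    primer = primer.upper()
    if len(primer) < 8:
        raise ValueError("primer shorter than 8 bases")
    if set(primer) - set("ACGT"):
        raise ValueError(f"ambiguity codes in primer {primer!r}")
    return float(
        _mt.Tm_NN(primer, check=False, nn_table=_mt.DNA_NN3, Na=50, dnac1=250, dnac2=0)
    )


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


# ---------------------------------------------------------------------------
# primer design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str  # 5'->3' on the minus strand
    forward_start: int  # 0-based on the reference flank
    reverse_start: int  # 0-based start of the reverse-primer site (plus strand)
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float

    @property
    def tm_diff(self) -> float:
        return abs(self.tm_forward - self.tm_reverse)


@dataclass
class MarkerSpec:
    """A complete designed marker.

    Plain data: geometric consistency can be asserted with :meth:`check`,
    but construction itself does not enforce the design constraints so that
    published marker tables (which occasionally bend them) can be
    represented as-is.
    """

    locus_id: str
    snp_id: str
    primer_pair: PrimerPair | None
    amplicon_length: int
    cut_position: int  # bp from the amplicon 5' end
    enzyme: Enzyme
    digest_allele: str

    @property
    def fragment_up(self) -> int:
        return self.cut_position

    @property
    def fragment_down(self) -> int:
        return self.amplicon_length - self.cut_position

    def check(self, constraints: "DesignConstraints") -> bool:
        return (
            self.fragment_up + self.fragment_down == self.amplicon_length
            and min(self.fragment_up, self.fragment_down) >= constraints.fragment_min
            and constraints.amplicon_min
            <= self.amplicon_length
            <= constraints.amplicon_max
        )


@dataclass
class DesignConstraints:
    """Primer/amplicon design constraints.

    Defaults: primers 15-25 bp, GC 20-80 %, Tm 57-63 deg C with at most
    3 deg C difference, amplicon 590-1000 bp, digest fragments >= 100 bp,
    primers placed 150-600 bp from the recognition site in conserved
    sequence.  Ranking: ``|Tm_f-60| + |Tm_r-60| + |dTm| +
    amplicon_weight*|amplicon-750|``.
    """

    primer_len_min: int = 15
    primer_len_max: int = 25
    gc_min: float = 0.20
    gc_max: float = 0.80
    tm_min: float = 57.0
    tm_max: float = 63.0
    tm_diff_max: float = 3.0
    amplicon_min: int = 590
    amplicon_max: int = 1000
    fragment_min: int = 100
    site_dist_min: int = 150
    site_dist_max: int = 600
    tm_opt: float = 60.0
    amplicon_opt: int = 750
    amplicon_weight: float = 0.01
    # pairing is quadratic; per side, only the max_per_side primers closest
    # to tm_opt are paired (the score is Tm-dominated, so the top-ranked
    # pairs are unaffected at any realistic setting)
    max_per_side: int = 100


def conserved_mask(flank) -> list[bool]:
    """Per reference-flank position: invariant and unambiguous in all samples.

    A position is conserved iff every sample flank carries exactly the
    reference base there (no IUPAC code, no N, no indel edit).
    """
    ref = flank.reference_flank
    mask = [b in "ACGT" for b in ref]
    for cells in flank.sample_cells.values():
        for i, cell in enumerate(cells):
            if cell != ref[i]:
                mask[i] = False
    return mask


def _feasible_primers(seq, mask, lo, hi, constraints, reverse):
    """Enumerate constraint-satisfying primers with 3' ends in [lo, hi)."""
    out = []
    for start in range(max(lo - constraints.primer_len_max, 0), hi):
        for length in range(constraints.primer_len_min, constraints.primer_len_max + 1):
            end = start + length
            if end > len(seq):
                break
            # distance band: forward primers are bounded by their 3' end,
            # reverse primers by the 5' edge of their binding site
            if not (lo <= (start if reverse else end) < hi):
                continue
            if not all(mask[start:end]):
                continue
            primer_site = seq[start:end]
            primer = revcomp(primer_site) if reverse else primer_site
            gc = gc_fraction(primer)
            if not constraints.gc_min <= gc <= constraints.gc_max:
                continue
            tm = melting_temperature(primer)
            if not constraints.tm_min <= tm <= constraints.tm_max:
                continue
            out.append((start, end, primer, tm, gc))
    return out


def design_primers(
    flank,
    candidate: CandidateCaps,
    constraints: DesignConstraints | None = None,
    max_results: int = 20,
) -> tuple[list[MarkerSpec], dict[str, int]]:
    """Exhaustive constraint-based primer search for one CAPS candidate.

    Primer windows (15-25 bp) fully inside conserved regions, with the
    forward primer ending 150-600 bp upstream of the recognition site and
    the reverse-primer site starting 150-600 bp downstream of it, are
    paired subject to the amplicon-size, fragment-size and Tm constraints,
    then ranked by the documented score.  Returns the ranked markers and a
    per-constraint failure tally (which constraint pruned most pairs).
    """
    constraints = constraints or DesignConstraints()
    seq = flank.reference_flank
    mask = conserved_mask(flank)
    site_start = flank.snp_offset + candidate.match_offset
    site_end = site_start + candidate.enzyme.size
    cut_abs = cut_position(site_start, candidate.strand, candidate.enzyme)

    tally: dict[str, int] = {
        "conserved_or_gc_or_tm": 0,
        "amplicon_size": 0,
        "fragment_size": 0,
        "tm_diff": 0,
    }
    # forward: 3' end in [site_start - dist_max, site_start - dist_min]
    f_lo = max(site_start - constraints.site_dist_max, 0)
    f_hi = max(site_start - constraints.site_dist_min + 1, 0)
    forwards = _feasible_primers(seq, mask, f_lo, f_hi, constraints, reverse=False)
    # reverse: site start in [site_end + dist_min, site_end + dist_max]
    r_lo = min(site_end + constraints.site_dist_min, len(seq))
    r_hi = min(site_end + constraints.site_dist_max + 1, len(seq))
    reverses = _feasible_primers(seq, mask, r_lo, r_hi, constraints, reverse=True)
    key = lambda t: (abs(t[3] - constraints.tm_opt), t[0])
    forwards = sorted(forwards, key=key)[: constraints.max_per_side]
    reverses = sorted(reverses, key=key)[: constraints.max_per_side]
    if not forwards or not reverses:
        tally["conserved_or_gc_or_tm"] += 1
        return [], tally

    scored = []
    for f_start, f_end, f_primer, f_tm, f_gc in forwards:
        for r_start, r_end, r_primer, r_tm, r_gc in reverses:
            amplicon = r_end - f_start
            if not constraints.amplicon_min <= amplicon <= constraints.amplicon_max:
                tally["amplicon_size"] += 1
                continue
            cut_rel = cut_abs - f_start
            if min(cut_rel, amplicon - cut_rel) < constraints.fragment_min:
                tally["fragment_size"] += 1
                continue
            if abs(f_tm - r_tm) > constraints.tm_diff_max:
                tally["tm_diff"] += 1
                continue
            score = (
                abs(f_tm - constraints.tm_opt)
                + abs(r_tm - constraints.tm_opt)
                + abs(f_tm - r_tm)
                + constraints.amplicon_weight * abs(amplicon - constraints.amplicon_opt)
            )
            pair = PrimerPair(
                forward=f_primer,
                reverse=r_primer,
                forward_start=f_start,
                reverse_start=r_start,
                tm_forward=f_tm,
                tm_reverse=r_tm,
                gc_forward=f_gc,
                gc_reverse=r_gc,
            )
            spec = MarkerSpec(
                locus_id=candidate.snp_id,
                snp_id=candidate.snp_id,
                primer_pair=pair,
                amplicon_length=amplicon,
                cut_position=cut_rel,
                enzyme=candidate.enzyme,
                digest_allele=candidate.digest_allele,
            )
            scored.append((score, f_start, r_start, spec))
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    return [spec for _, _, _, spec in scored[:max_results]], tally


def nontarget_site_check(marker: MarkerSpec, flank) -> bool:
    """True iff the amplicon contains no constitutive site of the marker's
    enzyme besides the allele-specific one."""
    if marker.primer_pair is None:
        raise ValueError("marker has no primer coordinates")
    a_start = marker.primer_pair.forward_start
    a_end = a_start + marker.amplicon_length
    size = marker.enzyme.size
    for pos, _strand in constitutive_matches(flank, marker.enzyme):
        if pos >= a_start and pos + size <= a_end:
            return False
    return True


# ---------------------------------------------------------------------------
# in-silico digestion
# ---------------------------------------------------------------------------

GENOTYPES = ("digest-hom", "other-hom", "het")


def predict_digest(marker: MarkerSpec, genotype: str) -> list[int]:
    """Predicted gel band sizes (bp) for one genotype at a marker.

    digest-hom -> both cut fragments; other-hom -> the uncut amplicon;
    het -> all three bands; missing -> no bands.
    """
    up, down = marker.fragment_up, marker.fragment_down
    if genotype == "digest-hom":
        return sorted([up, down])
    if genotype == "other-hom":
        return [marker.amplicon_length]
    if genotype == "het":
        return sorted([up, down, marker.amplicon_length])
    if genotype == "missing":
        return []
    raise ValueError(f"unknown genotype {genotype!r}")
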