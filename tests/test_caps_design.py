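"""Enzyme catalog, recognition matching, primer design, digest prediction."""

import numpy as np
import pytest

from capsforge.caps_design import (
    DesignConstraints,
    Enzyme,
    MarkerSpec,
    allele_specific_sites,
    conserved_mask,
    cut_position,
    default_enzyme_catalog,
    design_primers,
    load_enzyme_catalog,
    load_marker_panel,
    match_recognition,
    melting_temperature,
    nontarget_site_check,
    predict_digest,
    revcomp,
    uniqueness_check,
)
from capsforge.flanks_duplicates import extract_flanks
from capsforge.variant_io import GenotypeMatrix, ReferenceGenome, VariantSite

CATALOG = {e.name: e for e in default_enzyme_catalog()}


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------


def test_catalog_covers_all_validated_marker_enzymes():
    table = load_marker_panel()
    assert set(table["enzyme"]) <= set(CATALOG)


def test_ndei_entry():
    ndei = CATALOG["NdeI"]
    assert ndei.recognition == "CATATG"
    assert (ndei.cut_top, ndei.cut_bottom) == (2, 4)
    assert ndei.palindromic


def test_catalog_rejects_bad_symbol(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("name\trecognition\tcut_top\tcut_bottom\nBadI\tACZGT\t1\t1\n")
    with pytest.raises(ValueError, match="BadI"):
        load_enzyme_catalog(path)


def test_catalog_empty_file_warns(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("")
    with pytest.warns(UserWarning):
        assert load_enzyme_catalog(path) == []


# ---------------------------------------------------------------------------
# recognition matching
# ---------------------------------------------------------------------------


def test_match_simple_site():
    msei = CATALOG["MseI"]
    assert match_recognition("GGTTAACC", msei) == [(2, "+")]


def test_match_degenerate_n():
    ddei = CATALOG["DdeI"]  # CTNAG
    assert match_recognition("ACTGAGT", ddei) == [(1, "+")]


def test_sequence_ambiguity_never_matches():
    msei = CATALOG["MseI"]
    assert match_recognition("GGTNAACC", msei) == []
    assert match_recognition("GGWTAACC", msei) == []


def test_reverse_strand_reported_in_forward_coordinates():
    mnli = CATALOG["MnlI"]  # CCTC, non-palindromic
    seq = "AAGAGGAA"  # revcomp(CCTC) = GAGG at offset 2
    assert match_recognition(seq, mnli) == [(2, "-")]
    assert match_recognition(seq, mnli, both_strands=False) == []


def test_palindromic_reported_once():
    ndei = CATALOG["NdeI"]
    assert match_recognition("ACATATGA", ndei) == [(1, "+")]


def test_cut_position_strand_mirroring():
    ndei = CATALOG["NdeI"]
    assert cut_position(10, "+", ndei) == 12
    assert cut_position(10, "-", ndei) == 14


# ---------------------------------------------------------------------------
# allele-specific discovery on a hand-built flank
# ---------------------------------------------------------------------------


def _flank(seq, pos, ref, alt, dosages=((2,),)):
    genome = ReferenceGenome({"c1": seq})
    site = VariantSite("c1", pos, ref, (alt,))
    n = len(dosages[0])
    m = GenotypeMatrix.from_dosage(
        [site], [f"S{i}" for i in range(n)], np.array(dosages, dtype=np.int8)
    )
    return extract_flanks(genome, m, site, radius=len(seq))


def test_allele_specific_site_discovery():
    #        0123456789
    seq = "GGGGTTAAGGGG"  # MseI site TTAA at 4; SNP at offset 4 (pos 5, T)
    flank = _flank(seq, 5, "T", "G")
    cands = allele_specific_sites(flank, [CATALOG["MseI"]])
    assert len(cands) == 1
    c = cands[0]
    assert c.enzyme.name == "MseI"
    assert c.digest_allele == "T" and c.other_allele == "G"
    assert c.match_offset == 0 and c.strand == "+"


def test_no_candidate_when_both_alleles_match():
    # DdeI CTNAG: N position tolerates both alleles
    seq = "GGGCTTAGGGG"
    flank = _flank(seq, 6, "T", "A")  # the N slot of CTNAG at offset 3
    cands = allele_specific_sites(flank, [CATALOG["DdeI"]])
    assert cands == []


def test_uniqueness_check_rejects_nearby_constitutive_site():
    # planted MseI site at 100 (SNP there) and a constitutive TTAA 100 bp away
    seq = ["G", "C"] * 200
    seq[100:104] = list("TTAA")
    seq[200:204] = list("TTAA")
    seq = "".join(seq)
    flank = _flank(seq, 101, "T", "G")
    cands = allele_specific_sites(flank, [CATALOG["MseI"]])
    assert len(cands) == 1
    assert not uniqueness_check(flank, cands[0], exclusion_radius=150)
    assert uniqueness_check(flank, cands[0], exclusion_radius=50)


# ---------------------------------------------------------------------------
# melting temperature
# ---------------------------------------------------------------------------


def test_tm_monotone_in_gc_and_strand_symmetric():
    at = melting_temperature("ATATATATATATATATATAT")
    gc = melting_temperature("GCGCGCGCGCGCGCGCGCGC")
    assert at < gc
    primer = "CGTTCAAAAGCGTGTCCTGTG"
    assert 50.0 <= melting_temperature(primer) <= 70.0
    assert melting_temperature(revcomp(primer)) == pytest.approx(
        melting_temperature(primer), abs=0.3
    )


def test_tm_rejects_ambiguity_and_short_input():
    with pytest.raises(ValueError):
        melting_temperature("ACGTNACGTACGT")
    with pytest.raises(ValueError):
        melting_temperature("ACGT")


# ---------------------------------------------------------------------------
# primer design on planted flanks
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def planted_flank_and_candidate(study):
    from capsforge.caps_design import allele_specific_sites

    marker = study.truth.planted_markers[0]
    site = next(
        s
        for s in study.matrix.sites
        if (s.contig, s.pos) == (marker.contig, marker.pos)
    )
    flank = extract_flanks(study.genome, study.matrix, site, 1000)
    cands = [
        c
        for c in allele_specific_sites(flank, list(CATALOG.values()))
        if c.enzyme.name == marker.enzyme
    ]
    assert cands, "planted enzyme site must be recoverable"
    return flank, cands[0]


def test_design_primers_satisfies_all_constraints(planted_flank_and_candidate):
    flank, cand = planted_flank_and_candidate
    constraints = DesignConstraints()
    specs, tally = design_primers(flank, cand, constraints)
    assert specs, tally
    for spec in specs:
        pp = spec.primer_pair
        assert spec.check(constraints)
        for primer, tm, gc in (
            (pp.forward, pp.tm_forward, pp.gc_forward),
            (pp.reverse, pp.tm_reverse, pp.gc_reverse),
        ):
            assert 15 <= len(primer) <= 25
            assert 0.20 <= gc <= 0.80
            assert 57.0 <= tm <= 63.0
        assert pp.tm_diff <= 3.0
        assert min(spec.fragment_up, spec.fragment_down) >= 100
        assert 590 <= spec.amplicon_length <= 1000
    # deterministic ordering
    specs2, _ = design_primers(flank, cand, constraints)
    assert [(s.amplicon_length, s.primer_pair.forward) for s in specs] == [
        (s.amplicon_length, s.primer_pair.forward) for s in specs2
    ]


def test_design_primers_respects_conserved_regions(planted_flank_and_candidate):
    flank, cand = planted_flank_and_candidate
    mask = conserved_mask(flank)
    specs, _ = design_primers(flank, cand)
    pp = specs[0].primer_pair
    f_start = pp.forward_start
    assert all(mask[f_start : f_start + len(pp.forward)])
    r_start = pp.reverse_start
    assert all(mask[r_start : r_start + len(pp.reverse)])
    assert pp.forward == flank.reference_flank[f_start : f_start + len(pp.forward)]
    assert pp.reverse == revcomp(
        flank.reference_flank[r_start : r_start + len(pp.reverse)]
    )


def test_design_primers_empty_when_nothing_conserved(planted_flank_and_candidate):
    flank, cand = planted_flank_and_candidate
    import copy

    ruined = copy.deepcopy(flank)
    name = next(iter(ruined.sample_cells))
    ruined.sample_cells[name] = ["N"] * len(ruined.reference_flank)
    specs, tally = design_primers(ruined, cand)
    assert specs == []
    assert tally["conserved_or_gc_or_tm"] >= 1


def test_amplicon_bounds_enforced(planted_flank_and_candidate):
    flank, cand = planted_flank_and_candidate
    tight = DesignConstraints(site_dist_max=250)  # max amplicon ~ 550 < 590
    specs, tally = design_primers(flank, cand, tight)
    assert specs == []
    assert tally["amplicon_size"] > 0


def test_nontarget_site_check(planted_flank_and_candidate):
    flank, cand = planted_flank_and_candidate
    specs, _ = design_primers(flank, cand)
    spec = specs[0]
    assert nontarget_site_check(spec, flank)  # scrubbed by construction
    # inject a constitutive site inside the amplicon -> fail
    import copy

    bad = copy.deepcopy(flank)
    enz = cand.enzyme
    concrete = "".join(
        sorted(__import__("capsforge.caps_design", fromlist=["IUPAC"]).IUPAC[c])[0]
        for c in enz.recognition
    )
    ins = spec.primer_pair.forward_start + 30
    bad.reference_flank = (
        bad.reference_flank[:ins]
        + concrete
        + bad.reference_flank[ins + len(concrete) :]
    )
    assert not nontarget_site_check(spec, bad)


# ---------------------------------------------------------------------------
# digest prediction (validated-marker table fixtures)
# ---------------------------------------------------------------------------


def _fixture_marker(row):
    return MarkerSpec(
        locus_id=str(row["locus"]),
        snp_id=row["snp_id"],
        primer_pair=None,
        amplicon_length=int(row["size"]),
        cut_position=int(row["size_up"]),
        enzyme=CATALOG[row["enzyme"]],
        digest_allele=row["digest_allele"],
    )


def test_predict_digest_locus1_patterns():
    row = load_marker_panel().iloc[0]
    marker = _fixture_marker(row)
    assert predict_digest(marker, "digest-hom") == [200, 442]
    assert predict_digest(marker, "other-hom") == [642]
    assert predict_digest(marker, "het") == [200, 442, 642]
    assert predict_digest(marker, "missing") == []
    with pytest.raises(ValueError):
        predict_digest(marker, "bogus")


def test_fixture_fragment_arithmetic_consistent_except_erratum():
    """Fragments sum to the amplicon for 16 of 17 loci; locus 3 is the
    documented inconsistent row."""
    table = load_marker_panel()
    bad = []
    for _, row in table.iterrows():
        if int(row["size_up"]) + int(row["size_down"]) != int(row["size"]):
            bad.append(int(row["locus"]))
    assert bad == [3]
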