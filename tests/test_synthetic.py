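"""Generators: composition targets, ground-truth bookkeeping, determinism."""

import numpy as np
import pytest

from vntrkit._seq import revcomp
from vntrkit import gel
from vntrkit.synthetic import (DEFAULT_CASSETTES, GenerationError, LocusSpec,
                               PedigreeSpec, SpeciesPairSpec, make_background,
                               make_locus, make_pedigree, make_species_pair,
                               make_amplicon_template, write_fasta,
                               write_pedigree_tsv)

SMALL = dict(unit_length=900, copy_number=5, flank_length=2000,
             cassette_positions=((100, "tRNA-Gly-1", "+"),
                                 (400, "tRNA-Glu", "-")),
             motif_offset=700)


class TestBackground:
    def test_pure_gc(self):
        s = make_background(1000, 1.0, seed=0)
        assert len(s) == 1000 and set(s) <= {"G", "C"}

    def test_zero_length(self):
        assert make_background(0, 0.5, seed=0) == ""

    def test_gc_fraction_concentrates(self):
        s = make_background(10000, 0.642, seed=7)
        gc = (s.count("G") + s.count("C")) / len(s)
        assert gc == pytest.approx(0.642, abs=0.02)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            make_background(-1, 0.5, seed=0)


class TestLocus:
    def test_length_is_exactly_flanks_plus_units(self, big_locus):
        spec, seq, _ = big_locus
        assert len(seq) == 2 * spec.flank_length + spec.copy_number * spec.unit_length

    def test_truth_counts_by_construction(self, big_locus):
        spec, seq, truth = big_locus
        assert len(truth.of_class("cassette")) == 8 * 5
        assert len(truth.of_class("motif")) == 8
        assert len(truth.of_class("unit-boundary")) == 8
        assert len(truth.of_class("LTR-like")) == 2
        truth.validate(len(seq))

    def test_no_forbidden_site_in_array_on_either_strand(self, big_locus):
        spec, seq, _ = big_locus
        array = seq[spec.flank_length:
                    spec.flank_length + spec.copy_number * spec.unit_length]
        assert "TCTAGA" not in array
        assert "TCTAGA" not in revcomp(array)

    def test_zero_divergence_units_identical(self):
        spec = LocusSpec(divergence=0.0, seed=3, **SMALL)
        seq, truth = make_locus(spec)
        units = [seq[s:e] for s, e, lab, _ in truth.intervals
                 if lab == "unit-boundary"]
        assert len(set(units)) == 1

    def test_same_seed_byte_identical(self):
        a = make_locus(LocusSpec(seed=9, **SMALL))
        b = make_locus(LocusSpec(seed=9, **SMALL))
        assert a[0] == b[0]
        assert a[1].intervals == b[1].intervals

    def test_pairwise_unit_identity_within_binomial_bounds(self):
        # substitution-only model: expected pairwise identity ~ 1 - 2d
        d = 0.01
        spec = LocusSpec(unit_length=6000, copy_number=3, divergence=d,
                         flank_length=0, cassette_positions=(),
                         motif_offset=None, seed=5)
        seq, truth = make_locus(spec)
        units = [seq[s:e] for s, e, lab, _ in truth.intervals
                 if lab == "unit-boundary"]
        idents = []
        for i in range(3):
            for j in range(i + 1, 3):
                same = sum(x == y for x, y in zip(units[i], units[j]))
                idents.append(same / 6000)
        mean = np.mean(idents)
        assert 1 - 2 * d - 0.01 <= mean <= 1 - d + 0.01

    def test_cassettes_and_motif_copied_undiverged(self):
        spec = LocusSpec(divergence=0.05, seed=4, **SMALL)
        seq, truth = make_locus(spec)
        cass = DEFAULT_CASSETTES["tRNA-Glu"]
        for s, e, lab, strand in truth.intervals:
            if lab == "cassette" and strand == "-":
                assert seq[s:e] == revcomp(cass)

    def test_unknown_cassette_id_rejected(self):
        spec = LocusSpec(cassette_positions=((10, "nope", "+"),),
                         motif_offset=None, unit_length=500, flank_length=0)
        with pytest.raises(ValueError, match="nope"):
            make_locus(spec)

    def test_forbidden_site_inside_protected_element_fails(self):
        lib = {"bad": "GGGTCTAGAGGGAAACCCGGGTTT"}
        spec = LocusSpec(unit_length=500, copy_number=3, flank_length=100,
                         cassette_positions=((50, "bad", "+"),),
                         motif_offset=None, divergence=0.0, seed=0)
        with pytest.raises(GenerationError):
            make_locus(spec, cassette_library=lib)

    def test_overlapping_elements_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            LocusSpec(unit_length=900,
                      cassette_positions=((100, "tRNA-Gly-1", "+"),
                                          (120, "tRNA-Glu", "-")),
                      motif_offset=None)


PED_MEMBERS = (
    ("gm", None, None), ("gf", None, None),
    ("mo", "gm", "gf"), ("fa", None, None),
    ("c1", "mo", "fa"), ("c2", "mo", "fa"),
)
FOUNDERS = {"gm": (10, 20), "gf": (15, 30), "fa": (25, 40)}


class TestPedigree:
    def test_mendelian_children_carry_parental_bands(self):
        ped = make_pedigree(PedigreeSpec(members=PED_MEMBERS,
                                         founder_alleles=FOUNDERS, seed=2),
                            unit_bp=7200)
        for m in ped.members.values():
            if m.mother is None:
                continue
            parental = ped.members[m.mother].bands + ped.members[m.father].bands
            assert all(b in parental for b in m.bands)

    def test_mitotic_event_gives_three_bands(self):
        spec = PedigreeSpec(members=PED_MEMBERS, founder_alleles=FOUNDERS,
                            mitotic_event=("gf", 35), seed=2)
        ped = make_pedigree(spec, unit_bp=7200)
        assert len(ped.members["gf"].bands) == 3

    def test_meiotic_event_changes_transmitted_copies(self):
        base = make_pedigree(PedigreeSpec(members=PED_MEMBERS,
                                          founder_alleles=FOUNDERS, seed=2),
                             unit_bp=7200)
        spec = PedigreeSpec(members=PED_MEMBERS, founder_alleles=FOUNDERS,
                            meiotic_event=(("mo", "c1"), +7), seed=2)
        ped = make_pedigree(spec, unit_bp=7200)
        # same RNG stream: exactly the altered transmission differs, by 7 units
        diff = sorted(set(ped.members["c1"].bands) - set(base.members["c1"].bands))
        assert len(diff) == 1
        assert diff[0] - min(set(base.members["c1"].bands)
                             - set(ped.members["c1"].bands)) == 7 * 7200

    def test_same_seed_reproducible(self):
        spec = PedigreeSpec(members=PED_MEMBERS, founder_alleles=FOUNDERS, seed=6)
        p1 = make_pedigree(spec, unit_bp=7200)
        p2 = make_pedigree(spec, unit_bp=7200)
        assert all(p1.members[k].bands == p2.members[k].bands for k in p1.members)

    def test_event_referencing_unknown_member_rejected(self):
        spec = PedigreeSpec(members=PED_MEMBERS, founder_alleles=FOUNDERS,
                            mitotic_event=("nobody", 12))
        with pytest.raises(ValueError):
            make_pedigree(spec, unit_bp=7200)

    def test_cyclic_parent_links_rejected(self):
        with pytest.raises(ValueError, match="cyclic|unknown"):
            PedigreeSpec(members=(("a", "b", "b"), ("b", "a", "a")),
                         founder_alleles={})


class TestSpeciesPair:
    def test_six_shared_elements_in_truth(self):
        a, b, (ta, tb) = make_species_pair(SpeciesPairSpec(seed=11))
        assert len(ta.intervals) == 6
        assert len(tb.intervals) == 6
        assert len(a) == 7380 and len(b) == 7600
        # cassettes identical, motifs the two printed variants
        for (sa, ea, lab, _), (sb, eb, lab2, _) in zip(ta.intervals, tb.intervals):
            if lab == "cassette":
                assert a[sa:ea] == b[sb:eb]

    def test_no_shared_elements(self):
        spec = SpeciesPairSpec(shared_cassettes=(), shared_motif_a=None,
                               shared_motif_b=None, seed=0)
        a, b, (ta, tb) = make_species_pair(spec)
        assert ta.intervals == [] and tb.intervals == []

    def test_deterministic(self):
        r1 = make_species_pair(SpeciesPairSpec(seed=4))
        r2 = make_species_pair(SpeciesPairSpec(seed=4))
        assert r1[0] == r2[0] and r1[1] == r2[1]

    def test_elements_too_big_rejected(self):
        with pytest.raises(GenerationError):
            make_species_pair(SpeciesPairSpec(
                unit_length_a=300, unit_length_b=300,
                shared_cassettes=tuple(DEFAULT_CASSETTES.values())))


class TestAmpliconTemplate:
    def test_product_at_printed_spacing(self):
        t = make_amplicon_template(seed=3)
        products = gel.insilico_pcr(
            t, "CCGCGACCCTCTACCAATTG", "TGCTCAGCGGTCAGAAGTTG")
        assert len(products) == 1
        assert products[0].length == 519


class TestWriters:
    def test_fasta_wrapped_at_60(self, tmp_path):
        path = tmp_path / "x.fa"
        write_fasta(path, {"s": "ACGT" * 50})
        lines = path.read_text().splitlines()
        assert lines[0] == ">s"
        assert all(len(l) <= 60 for l in lines[1:])
        assert "".join(lines[1:]) == "ACGT" * 50

    def test_bed_roundtrip(self, tmp_path):
        from vntrkit.pipeline import read_bed
        spec = LocusSpec(seed=1, **SMALL)
        _, truth = make_locus(spec)
        path = tmp_path / "t.bed"
        truth.to_bed(path)
        back = read_bed(path)
        assert [(s, e, lab, strand) for s, e, lab, strand in back] == truth.intervals

    def test_pedigree_tsv_roundtrip(self, tmp_path):
        ped = make_pedigree(PedigreeSpec(members=PED_MEMBERS,
                                         founder_alleles=FOUNDERS, seed=2),
                            unit_bp=7200)
        path = tmp_path / "p.tsv"
        write_pedigree_tsv(path, ped)
        back = dict(gel.read_band_table(path, size_unit="bp"))
        assert set(back) == set(ped.members)
        assert back["c1"] == ped.members["c1"].bands
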