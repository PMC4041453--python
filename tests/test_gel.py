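"""Digestion, in-silico PCR, band sizing, copy-number calls, pedigrees."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vntrkit.gel import (BUILTIN_ENZYMES, Enzyme, InstabilityEvent, Member,
                         Pedigree, bands_match, call_copies, classify_pedigree,
                         digest, fragment_sizes, insilico_pcr,
                         predict_allele_size, simulate_band)
from vntrkit.synthetic import (PROBE_FWD_PRIMER, PROBE_REV_PRIMER, PedigreeSpec,
                               make_background, make_pedigree)
from vntrkit._seq import revcomp

XBAI = BUILTIN_ENZYMES["XbaI"]


class TestDigest:
    def test_no_site_single_fragment(self):
        assert digest("AAAACCCCGGGG", XBAI) == [(0, 12)]

    def test_xbai_cut_position(self):
        # cut after the T of TCTAGA: site at 3 -> cut at 4
        assert fragment_sizes("AAATCTAGAAAA", XBAI) == [4, 8]

    def test_ecorv_blunt_cut(self):
        assert fragment_sizes("AAGATATCAA", BUILTIN_ENZYMES["EcoRV"]) == [5, 5]

    def test_non_palindromic_site_cut_on_both_strands(self):
        enz = Enzyme("BsaI-like", "GGTCTC", 1)
        # site on top strand at 2 -> cut 3; bottom-strand site (GAGACC on top)
        # at 12 -> cut at 12 + (6-1) = 17
        seq = "AAGGTCTCAAAAGAGACCAAAA"
        frags = digest(seq, enz)
        assert [e - s for s, e in frags] == [3, 14, 5]

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_fragments_partition_random_sequences(self, seed):
        seq = make_background(200 + (seed % 97), 0.45, seed=seed)
        frags = digest(seq, XBAI)
        assert sum(e - s for s, e in frags) == len(seq)
        assert frags[0][0] == 0 and frags[-1][1] == len(seq)
        assert all(f1[1] == f2[0] for f1, f2 in zip(frags, frags[1:]))


class TestInsilicoPcr:
    def test_primers_absent_no_product(self):
        assert insilico_pcr("ACGT" * 30, PROBE_FWD_PRIMER, PROBE_REV_PRIMER) == []

    def test_adjacent_primers_product_length_is_sum(self):
        template = PROBE_FWD_PRIMER + revcomp(PROBE_REV_PRIMER)
        products = insilico_pcr(template, PROBE_FWD_PRIMER, PROBE_REV_PRIMER)
        assert len(products) == 1
        assert products[0].length == len(PROBE_FWD_PRIMER) + len(PROBE_REV_PRIMER)

    def test_product_on_reverse_strand_template(self):
        spacer = make_background(100, 0.5, seed=1)
        template = PROBE_FWD_PRIMER + spacer + revcomp(PROBE_REV_PRIMER)
        flipped = revcomp(template)
        products = insilico_pcr(flipped, PROBE_FWD_PRIMER, PROBE_REV_PRIMER)
        assert len(products) == 1
        assert products[0].strand == "-"
        assert products[0].length == len(template)

    def test_three_prime_anchor_must_match(self):
        spacer = make_background(60, 0.5, seed=2)
        fwd_bad3 = PROBE_FWD_PRIMER[:-1] + ("A" if PROBE_FWD_PRIMER[-1] != "A" else "C")
        template = PROBE_FWD_PRIMER + spacer + revcomp(PROBE_REV_PRIMER)
        assert insilico_pcr(template, fwd_bad3, PROBE_REV_PRIMER, max_mm=1) == []
        fwd_bad_mid = PROBE_FWD_PRIMER[:5] + "A" + PROBE_FWD_PRIMER[6:]
        if fwd_bad_mid != PROBE_FWD_PRIMER:
            assert len(insilico_pcr(template, fwd_bad_mid, PROBE_REV_PRIMER,
                                    max_mm=1)) == 1

    def test_short_primers_rejected(self):
        with pytest.raises(ValueError):
            insilico_pcr("ACGT" * 30, "ACGTACGT", PROBE_REV_PRIMER)


class TestSimulateBand:
    def test_zero_cv_identity(self):
        assert simulate_band(70000, 0.0, seed=5) == 70000

    def test_reproducible(self):
        assert simulate_band(70000, 0.02, seed=5) == simulate_band(70000, 0.02, seed=5)

    def test_empirical_cv_matches_nominal(self):
        draws = np.array([simulate_band(100000, 0.02, seed=s) for s in range(1000)])
        assert draws.std() / draws.mean() == pytest.approx(0.02, abs=0.005)


class TestCopyNumber:
    @pytest.mark.parametrize("frag,expect", [
        (70000, 9), (200000, 27), (310000, 43), (7200, 1),
    ])
    def test_published_convention_calls(self, frag, expect):
        assert call_copies(frag, unit_bp=7200, flank_bp=0) == expect

    def test_fragment_below_flank_rejected(self):
        with pytest.raises(ValueError):
            call_copies(5000, unit_bp=7200, flank_bp=6000)

    def test_nondecreasing_in_fragment_size(self):
        calls = [call_copies(f, 7200, 0) for f in range(7200, 400000, 1777)]
        assert all(a <= b for a, b in zip(calls, calls[1:]))

    def test_predict_allele_size(self):
        assert predict_allele_size(9, 7200, 0) == 64800

    def test_predict_call_roundtrip(self):
        for n in range(1, 51):
            size = predict_allele_size(n, 7200, 0)
            assert call_copies(size + 7200 - 1, 7200, 0) == n
            assert call_copies(size, 7200, 0) == n


PED_MEMBERS = (
    ("gm", None, None), ("gf", None, None),
    ("mo", "gm", "gf"), ("fa", None, None),
    ("c1", "mo", "fa"), ("c2", "mo", "fa"),
)


def _mendelian_pedigree(seed):
    rng = np.random.default_rng(seed)
    # founder alleles at least 5 copies apart, from a 6-spaced grid
    grid = list(range(9, 45, 6))
    picks = rng.choice(len(grid), size=6, replace=False)
    vals = [grid[i] for i in picks]
    spec = PedigreeSpec(
        members=PED_MEMBERS,
        founder_alleles={"gm": (vals[0], vals[1]), "gf": (vals[2], vals[3]),
                         "fa": (vals[4], vals[5])},
        seed=int(seed))
    return make_pedigree(spec, unit_bp=7200)


def _blot_noise(ped, cv, blot_seed):
    """Apply PFGE sizing noise; within one blot the calibration error is
    shared, so equal true sizes measure identically."""
    out = {}
    for m in ped.members.values():
        bands = [simulate_band(b, cv, seed=(blot_seed * 1009 + int(b)) % 2**31)
                 for b in m.bands]
        out[m.id] = Member(m.id, m.mother, m.father, bands)
    return Pedigree(out)


class TestClassifyPedigree:
    def test_mendelian_pedigree_clean(self):
        ped = _mendelian_pedigree(0)
        assert classify_pedigree(ped) == []

    def test_three_bands_flagged_mitotic(self):
        ped = _mendelian_pedigree(1)
        ped.members["gf"].bands.append(33.5 * 7200)
        events = classify_pedigree(ped)
        assert len(events) == 1
        assert events[0].kind == "mitotic" and events[0].member_id == "gf"

    def test_child_band_matching_no_parent_flagged_meiotic(self):
        ped = _mendelian_pedigree(2)
        c1 = ped.members["c1"]
        c1.bands[0] = c1.bands[0] * 1.08  # 8% size shift, beyond 3% tolerance
        events = classify_pedigree(ped, rel_tol=0.03)
        assert [e.kind for e in events] == ["meiotic"]
        assert events[0].member_id == "c1"

    def test_meiotic_only_for_members_with_typed_parents(self):
        ped = _mendelian_pedigree(3)
        ped.members["fa"].bands[0] *= 1.2  # founder: no parents to compare
        events = classify_pedigree(ped)
        assert all(e.kind != "meiotic" or e.member_id != "fa" for e in events)

    def test_somatic_band_excluded_from_transmission_matching(self):
        # child of a 3-band mother must match her germline bands only
        ped = _mendelian_pedigree(4)
        mo = ped.members["mo"]
        extra = mo.bands[0] * 1.5
        mo.bands.append(extra)
        events = classify_pedigree(ped)
        assert [e.kind for e in events] == ["mitotic"]

    def test_member_without_bands_rejected(self):
        ped = Pedigree({"x": Member("x", None, None, [])})
        with pytest.raises(ValueError):
            classify_pedigree(ped)

    def test_rel_tol_validated(self):
        ped = _mendelian_pedigree(5)
        with pytest.raises(ValueError):
            classify_pedigree(ped, rel_tol=0.5)

    def test_no_false_events_on_100_noisy_mendelian_pedigrees(self):
        for seed in range(100):
            ped = _blot_noise(_mendelian_pedigree(seed), cv=0.02, blot_seed=seed)
            events = classify_pedigree(ped, rel_tol=0.03)
            assert events == [], f"blot seed {seed}: {events}"


def test_bands_match_relative_tolerance():
    assert bands_match(100000, 102900, 0.03)
    assert not bands_match(100000, 104000, 0.03)
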