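"""Dis_pH scoring: windowed hydrophobicity, pH scans, profiles, regions."""

import numpy as np
import pytest

from disphred import (
    CAPPED_TERMINI,
    DEFAULT_BOUNDARY,
    UVERSKY_BOUNDARY,
    PhGrid,
    ch_coordinates,
    classify,
    classify_regions,
    disph_score,
    get_scale,
    mean_hydrophobicity,
    residue_profile,
    scan_ph,
    window_ncpr,
)
from disphred.charge import WindowBoundsError
from disphred.predictor import binary_label

from conftest import random_sequence

SCALE = get_scale("ph_default")


def brute_force_mean_h(seq, ph, window):
    """Independent double-loop oracle for the windowed mean hydrophobicity."""
    h = [SCALE.value(r, ph) for r in seq]
    win_means = []
    for i in range(len(seq) - window + 1):
        acc = 0.0
        for j in range(i, i + window):
            acc += h[j]
        win_means.append(acc / window)
    return sum(win_means) / len(win_means)


class TestMeanHydrophobicity:
    def test_homopolymer_any_window(self):
        for window in (1, 3, 7):
            value = mean_hydrophobicity("A" * 20, 7.0, window)
            assert value == pytest.approx(SCALE.value("A", 7.0), abs=1e-12)

    def test_window_equal_to_length_is_simple_mean(self):
        seq = "AKELIVDPW"
        windowed = mean_hydrophobicity(seq, 7.0, window=9)
        simple = mean_hydrophobicity(seq, 7.0, window=9, windowed=False)
        assert windowed == pytest.approx(simple, abs=1e-15)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            seq = random_sequence(rng, 60)
            got = mean_hydrophobicity(seq, 6.0, window=7)
            assert got == pytest.approx(brute_force_mean_h(seq, 6.0, 7), abs=1e-12)

    def test_short_sequence_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="falling back"):
            value = mean_hydrophobicity("AKE", 7.0, window=7)
        assert value == pytest.approx(
            mean_hydrophobicity("AKE", 7.0, window=3, windowed=False), abs=1e-15
        )

    def test_even_window_incremented_with_warning(self):
        with pytest.warns(UserWarning, match="odd"):
            even = mean_hydrophobicity("A" * 30, 7.0, window=6)
        odd = mean_hydrophobicity("A" * 30, 7.0, window=7)
        assert even == pytest.approx(odd, abs=1e-15)

    def test_static_scale_is_ph_invariant(self):
        kd = get_scale("kyte_doolittle")
        seq = "AKEDLIV"
        v2 = mean_hydrophobicity(seq, 2.0, window=3, scale=kd)
        v12 = mean_hydrophobicity(seq, 12.0, window=3, scale=kd)
        assert v2 == v12


class TestDisphScore:
    def test_boundary_point_is_zero(self):
        assert disph_score(1.118 / 2.775, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_direct_substitution(self):
        assert disph_score(0.5, 0.1) == pytest.approx(0.1695, abs=1e-12)

    def test_uversky_preset(self):
        assert disph_score(0.5, 0.1, UVERSKY_BOUNDARY) == pytest.approx(
            0.1415, abs=1e-12
        )

    def test_monotone_in_both_arguments(self):
        base = disph_score(0.5, 0.2)
        assert disph_score(0.6, 0.2) > base
        assert disph_score(0.5, 0.3) < base


class TestClassify:
    @pytest.mark.parametrize(
        "score,expected",
        [(0.5, "folded"), (-0.5, "disordered"), (0.01, "within-margin"),
         (-0.015, "within-margin"), (0.021, "folded")],
    )
    def test_three_way(self, score, expected):
        assert classify(score, margin=0.02) == expected

    def test_zero_margin_never_within_margin(self):
        for score in (-0.01, 0.0, 0.01):
            assert classify(score, margin=0.0) in ("folded", "disordered")

    def test_binary_label_matches_sign(self):
        assert binary_label(0.01) == "folded"
        assert binary_label(-0.01) == "disordered"


class TestScanPh:
    def test_poly_ala_constant_across_ph(self):
        rows = scan_ph("A" * 60, PhGrid(1, 13, 2.0), window=7,
                       termini=CAPPED_TERMINI)
        scores = {round(r.disph, 12) for r in rows}
        assert len(scores) == 1

    def test_row_invariant(self):
        rows = scan_ph("A" * 30 + "E" * 30, PhGrid(2, 10, 2.0), window=7)
        for row in rows:
            assert row.disph == pytest.approx(
                DEFAULT_BOUNDARY.a * row.mean_h - row.ncpr_abs - DEFAULT_BOUNDARY.b,
                abs=1e-12,
            )
            assert row.ncpr_abs == abs(row.ncpr)

    def test_model_peptide_folds_at_high_ph(self, capped_peptide):
        rows = scan_ph(capped_peptide.residues, PhGrid(7, 13, 1.0), window=7,
                       termini=capped_peptide.termini)
        by_ph = {r.ph: r for r in rows}
        assert by_ph[7.0].disph < 0  # disordered at neutral pH
        assert by_ph[12.0].disph > 0  # folded side once Lys deprotonates
        assert by_ph[13.0].disph > 0

    def test_glu_rich_gains_order_at_low_ph(self):
        seq = ("E" * 3 + "LIA" * 2) * 8  # Glu-rich with hydrophobic filler
        rows = scan_ph(seq, PhGrid(2, 7, 1.0), window=7)
        by_ph = {r.ph: r for r in rows}
        assert by_ph[2.0].disph > by_ph[4.0].disph > by_ph[7.0].disph


class TestPhGrid:
    def test_inclusive_endpoint(self):
        assert PhGrid(1.0, 13.0, 0.5).points()[-1] == 13.0
        assert len(PhGrid(1.0, 13.0, 0.5).points()) == 25

    def test_single(self):
        assert list(PhGrid.single(7.4).points()) == [7.4]

    def test_validation(self):
        with pytest.raises(ValueError):
            PhGrid(8.0, 2.0, 0.5)
        with pytest.raises(ValueError):
            PhGrid(2.0, 8.0, -1.0)


class TestResidueProfile:
    def test_homopolymer_all_positions_equal(self):
        prof = residue_profile("A" * 30, 7.0, window=7, termini=CAPPED_TERMINI)
        assert len(prof.scores) == 24
        assert prof.start == 4
        assert np.allclose(prof.scores, prof.scores[0], atol=1e-12)

    def test_hydrophobic_vs_charged_halves(self):
        seq = "ILVFA" * 8 + "EKEKD" * 8
        prof = residue_profile(seq, 7.0, window=7)
        n = len(prof.scores)
        assert (prof.scores[: n // 3] > 0).all()
        assert (prof.scores[-n // 3 :] < 0).all()

    def test_matches_brute_force_windows(self):
        rng = np.random.default_rng(3)
        seq = random_sequence(rng, 40)
        window = 7
        prof = residue_profile(seq, 5.0, window=window)
        for i, score in enumerate(prof.scores):
            h = sum(SCALE.value(r, 5.0) for r in seq[i : i + window]) / window
            q = window_ncpr(seq, 5.0, i, window)
            expected = DEFAULT_BOUNDARY.a * h - abs(q) - DEFAULT_BOUNDARY.b
            assert score == pytest.approx(expected, abs=1e-12)

    def test_window_larger_than_sequence(self):
        with pytest.raises(WindowBoundsError):
            residue_profile("AKE", 7.0, window=7)


class TestClassifyRegions:
    def test_single_ph_no_conditional_regions(self):
        prof = residue_profile("ILVFA" * 8 + "EKEKD" * 8, 7.0, window=7)
        regions = classify_regions([prof])
        assert all(r.cls != "conditionally_disordered" for r in regions)

    def test_homopolymer_single_region(self):
        profs = [residue_profile("A" * 30, ph, window=7) for ph in (3.0, 7.0, 11.0)]
        regions = classify_regions(profs)
        assert len(regions) == 1
        assert regions[0].start == 4 and regions[0].end == 27

    def test_regions_tile_scored_positions(self):
        seq = "ILVFA" * 6 + "EEEEE" * 6
        profs = [residue_profile(seq, ph, window=7) for ph in (2.0, 4.0, 7.0)]
        regions = classify_regions(profs)
        covered = []
        for r in regions:
            assert r.start <= r.end
            covered.extend(range(r.start, r.end + 1))
        assert covered == list(profs[0].positions)

    def test_glu_stretch_is_conditionally_disordered(self):
        # Glu-rich block folds at pH 2 and unfolds at pH 7
        seq = "ILVFA" * 6 + "EELEA" * 8
        profs = [residue_profile(seq, ph, window=7) for ph in (2.0, 4.5, 7.0)]
        regions = classify_regions(profs)
        classes = {r.cls for r in regions}
        assert "conditionally_disordered" in classes


class TestChCoordinates:
    def test_freeze_h_mode_keeps_charge_titrating(self):
        seq = "E" * 20 + "ILA" * 10
        h_frozen_2, q_2 = ch_coordinates(seq, 2.0, window=7, freeze_h_at=7.0)
        h_frozen_7, q_7 = ch_coordinates(seq, 7.0, window=7, freeze_h_at=7.0)
        assert h_frozen_2 == h_frozen_7  # hydrophobicity pinned at pH 7
        assert abs(q_2) != pytest.approx(abs(q_7))  # charge still titrates
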