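import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from fennelpop.rflp_densitometry import (
    AmbiguousBandError,
    Band,
    CalibrationError,
    DensitometryError,
    GelLane,
    ITSProfile,
    calibrate_ladder,
    detect_bands,
    digest_sequence,
    its_allele_fractions,
    match_diagnostic_bands,
    profile_from_match,
    read_band_table,
    replicate_reproducibility,
    validate_pattern,
)
from fennelpop.synthetic_data import LADDER_SIZES, make_ladder_lane, migration_of_size


def reference_calibration():
    return calibrate_ladder(make_ladder_lane(), list(LADDER_SIZES))


class TestDigest:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAATTT", [6]),
            ("AACCGGTT", [3, 5]),
            ("CCGGCCGG", [1, 4, 3]),
            ("CCGG", [1, 3]),
        ],
    )
    def test_fragment_lengths(self, seq, expected):
        assert digest_sequence(seq, "CCGG", 1) == expected

    def test_invalid_characters_rejected(self):
        with pytest.raises(DensitometryError):
            digest_sequence("ACGTN")

    def test_empty_sequence_rejected(self):
        with pytest.raises(DensitometryError):
            digest_sequence("")

    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=200),
        st.text(alphabet="ACGT", min_size=1, max_size=4),
        st.data(),
    )
    def test_length_conservation(self, seq, site, data):
        offset = data.draw(st.integers(min_value=0, max_value=len(site)))
        fragments = digest_sequence(seq, site, offset)
        assert sum(fragments) == len(seq)
        assert all(f > 0 for f in fragments)

    def test_matches_biopython_restriction_enzyme(self, rng):
        """Independent oracle: MspI fragment sets from Bio.Restriction."""
        from Bio.Restriction import MspI
        from Bio.Seq import Seq

        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=rng.integers(10, 300)))
            mine = digest_sequence(seq, "CCGG", 1)
            cuts = MspI.search(Seq(seq))  # 1-based position after which MspI cuts? (5' cut coordinates)
            bounds = [0] + [c - 1 for c in cuts] + [len(seq)]
            oracle = [b - a for a, b in zip(bounds[:-1], bounds[1:]) if b > a]
            assert mine == oracle


class TestDetectBands:
    def test_flat_trace_yields_no_bands(self):
        assert detect_bands(np.zeros(100)) == []

    def test_single_gaussian_area(self):
        positions = np.linspace(0, 60, 2000)
        trace = 100.0 * norm.pdf(positions, loc=30.0, scale=1.0)
        bands = detect_bands(trace, positions=positions, baseline_quantile=0.0)
        assert len(bands) == 1
        assert bands[0].migration == pytest.approx(30.0, abs=0.1)
        assert bands[0].area == pytest.approx(100.0, rel=0.02)

    def test_two_bumps_recover_area_ratio(self):
        positions = np.linspace(0, 60, 3000)
        trace = 60.0 * norm.pdf(positions, 20.0, 1.0) + 40.0 * norm.pdf(positions, 40.0, 1.0)
        bands = detect_bands(trace, positions=positions, baseline_quantile=0.0)
        assert len(bands) == 2
        ratio = bands[0].area / bands[1].area
        assert ratio == pytest.approx(60.0 / 40.0, rel=0.02)

    def test_short_or_negative_traces_rejected(self):
        with pytest.raises(DensitometryError):
            detect_bands(np.array([1.0, 2.0]))
        with pytest.raises(DensitometryError):
            detect_bands(np.array([1.0, -2.0, 1.0]))


class TestLadderCalibration:
    def test_identity_at_anchors(self):
        cal = reference_calibration()
        for size in LADDER_SIZES:
            estimate = cal.size_at(migration_of_size(size))
            assert estimate.size_bp == pytest.approx(size, rel=1e-9)
            assert not estimate.extrapolated

    def test_log_linear_midpoint_is_geometric_mean(self):
        ladder = GelLane(
            "lad",
            [Band(migration=10.0, area=1.0), Band(migration=30.0, area=1.0)],
            is_ladder=True,
        )
        cal = calibrate_ladder(ladder, [400, 100])
        assert cal.size_at(20.0).size_bp == pytest.approx(math.sqrt(400 * 100))

    def test_extrapolation_is_flagged(self):
        cal = reference_calibration()
        low = cal.size_at(cal.migrations[0] - 5.0)
        high = cal.size_at(cal.migrations[-1] + 5.0)
        assert low.extrapolated and high.extrapolated
        assert low.size_bp > 1000 and high.size_bp < 100

    def test_non_monotonic_ladder_rejected(self):
        ladder = GelLane(
            "lad",
            [Band(migration=10.0, area=1.0), Band(migration=20.0, area=1.0)],
            is_ladder=True,
        )
        with pytest.raises(CalibrationError, match="anchor"):
            calibrate_ladder(ladder, [100, 400])  # sizes increase with migration

    def test_band_count_mismatch_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_ladder(make_ladder_lane(), [500, 100])

    def test_inverse_query_round_trip(self):
        cal = reference_calibration()
        assert cal.size_at(cal.migration_for(250.0)).size_bp == pytest.approx(250.0)


class TestDiagnosticMatching:
    def test_near_diagnostic_sizes_are_assigned(self):
        cal = reference_calibration()
        lane = GelLane(
            "s1",
            [
                Band(migration=cal.migration_for(683.0), area=30.0),
                Band(migration=cal.migration_for(531.0), area=60.0),
                Band(migration=cal.migration_for(152.0), area=10.0),
            ],
        )
        match = match_diagnostic_bands(lane, cal)
        assert match.assigned[684] is not None
        assert match.assigned[529] is not None
        assert match.assigned[153] is not None
        assert match.assigned[344] is None and match.assigned[185] is None
        assert match.unassigned == []

    def test_empty_lane_all_absent(self):
        match = match_diagnostic_bands(GelLane("empty", []), reference_calibration())
        assert all(band is None for band in match.assigned.values())

    def test_band_outside_tolerance_is_unassigned(self):
        cal = reference_calibration()
        lane = GelLane("s", [Band(migration=cal.migration_for(450.0), area=5.0)])
        match = match_diagnostic_bands(lane, cal, tolerance_frac=0.05)
        assert all(band is None for band in match.assigned.values())
        assert len(match.unassigned) == 1

    def test_two_bands_competing_for_one_size_raise(self):
        cal = reference_calibration()
        lane = GelLane(
            "dup",
            [
                Band(migration=cal.migration_for(525.0), area=5.0),
                Band(migration=cal.migration_for(533.0), area=5.0),
            ],
        )
        with pytest.raises(AmbiguousBandError, match="529"):
            match_diagnostic_bands(lane, cal)


class TestAlleleFractions:
    def test_two_band_pattern(self):
        profile = its_allele_fractions(35.9, 64.1, 0.0)
        assert profile.itsA == pytest.approx(0.359)
        assert profile.itsB == pytest.approx(0.641)
        assert profile.itsC == 0.0

    def test_equal_areas_split_evenly(self):
        profile = its_allele_fractions(5.0, 5.0, 5.0)
        assert profile.as_array() == pytest.approx([1 / 3, 1 / 3, 1 / 3])

    def test_renormalizes_rounding_excess(self):
        # printed percentages summing to 100.1
        profile = its_allele_fractions(36.0, 56.7, 7.4)
        assert profile.as_array() == pytest.approx(
            np.array([36.0, 56.7, 7.4]) / 100.1
        )
        assert profile.itsA + profile.itsB + profile.itsC == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(DensitometryError):
            its_allele_fractions(0.0, 0.0, 0.0)

    @given(
        st.tuples(
            st.floats(min_value=0.01, max_value=1e3),
            st.floats(min_value=0.01, max_value=1e3),
            st.floats(min_value=0.0, max_value=1e3),
        ),
        st.floats(min_value=1e-3, max_value=1e4),
    )
    def test_scale_invariance_and_unit_sum(self, areas, scale):
        base = its_allele_fractions(*areas)
        scaled = its_allele_fractions(*(a * scale for a in areas))
        assert base.as_array() == pytest.approx(scaled.as_array())
        assert float(base.as_array().sum()) == pytest.approx(1.0)


class TestPatternValidation:
    def test_secondary_fragments_reconstruct_parent(self):
        report = validate_pattern([529, 344, 185, 684, 153])
        assert report.consistent

    def test_pure_itsA_pattern_is_consistent(self):
        assert validate_pattern([684]).consistent

    def test_missing_companion_fragment_warns(self):
        report = validate_pattern([684, 529, 344, 153])
        assert any("185" in w for w in report.warnings)

    def test_inconsistent_lengths_warn_without_correcting(self):
        report = validate_pattern({344: Band(10.0, 1.0, size_bp=344.0),
                                   185: Band(12.0, 1.0, size_bp=160.0),
                                   529: Band(8.0, 1.0, size_bp=529.0)})
        assert any("expected" in w for w in report.warnings)


class TestReproducibility:
    def test_identical_replicates_have_zero_sd(self):
        profile = ITSProfile("s", 0.3, 0.6, 0.1)
        table = replicate_reproducibility({"s": [profile] * 4})
        assert (table["sd_pct"] == 0.0).all()

    def test_two_replicates_hand_arithmetic(self):
        reps = [ITSProfile("s", 0.30, 0.70, 0.0), ITSProfile("s", 0.40, 0.60, 0.0)]
        table = replicate_reproducibility({"s": reps}).set_index("band")
        assert table.loc["itsA", "mean_pct"] == pytest.approx(35.0)
        assert table.loc["itsA", "sd_pct"] == pytest.approx(7.0710678, rel=1e-6)

    def test_single_replicate_rejected(self):
        with pytest.raises(DensitometryError, match="replicates"):
            replicate_reproducibility({"s": [ITSProfile("s", 0.5, 0.5, 0.0)]})


def test_band_table_reader_groups_lanes(tmp_path):
    path = tmp_path / "bands.csv"
    path.write_text(
        "lane_id,plant_id,migration,area,is_ladder\n"
        "L1,p1,14.8,30,False\nL1,p1,19.3,60,False\n"
        "M,,8.2,50,True\nM,,11.0,50,True\n"
    )
    lanes = read_band_table(path)
    assert len(lanes) == 2
    sample = next(l for l in lanes if not l.is_ladder)
    assert sample.plant_id == "p1" and len(sample.bands) == 2
    assert sample.bands[0].migration < sample.bands[1].migration


def test_full_lane_round_trip_recovers_profile(rng):
    """detect -> calibrate -> match -> fractions on rendered traces."""
    from fennelpop.synthetic_data import render_gel_lane, render_trace

    truth = ITSProfile("p9", 0.35, 0.50, 0.15)
    lane, ladder = render_gel_lane(truth, noise_cv_band=0.0, rng=rng)
    lpos, ltrace = render_trace(ladder)
    lbands = detect_bands(ltrace, positions=lpos, baseline_quantile=0.0)
    cal = calibrate_ladder(GelLane("lad", lbands, is_ladder=True), list(LADDER_SIZES))
    pos, trace = render_trace(lane)
    bands = detect_bands(trace, positions=pos, baseline_quantile=0.0)
    match = match_diagnostic_bands(GelLane("s", bands, plant_id="p9"), cal)
    recovered = profile_from_match(match, "p9")
    assert recovered.as_array() == pytest.approx(truth.as_array(), abs=1e-3)
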