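"""Synthetic-data generators: determinism, truth consistency, trace shape."""

import dataclasses
import io

import numpy as np
import pandas as pd
import pytest

from sulfoscreen import simulate as sim
from sulfoscreen.kinetics import NoiseModel

from conftest import make_profile


class TestScreenSimulation:
    def test_all_inactive_zero_noise_equals_controls(self):
        cfg = sim.ScreenConfig(n_plates=1, class_frequencies={"inactive": 1.0},
                               noise=NoiseModel(), seed=0)
        ds, truth = sim.simulate_screen(cfg)
        assert ds.data["rfu"].nunique() == 1  # everyone reads pure baseline
        assert (truth["true_class"] == "inactive").all()

    def test_truth_table_bookkeeping(self, mini_screen):
        ds, truth = mini_screen
        wells = ds.data.groupby(["plate", "well"]).size()
        assert len(truth) == len(wells)
        assert set(wells.values) == {len(sim.DEFAULT_TIMEPOINTS)}
        n_controls = (truth["role"] == "control").sum()
        assert n_controls == 3 * 16

    def test_full_scale_preset_dimensions(self):
        cfg = sim.full_scale_config(seed=5)
        n_clones = cfg.n_plates * (cfg.wells_per_plate - cfg.controls_per_plate)
        assert n_clones == 11520
        assert cfg.timepoints == (1.0, 3.0, 6.0, 24.0, 30.0, 48.0)

    def test_deterministic_under_seed(self):
        cfg = sim.ScreenConfig(n_plates=2, seed=77)
        a, ta = sim.simulate_screen(cfg)
        b, tb = sim.simulate_screen(cfg)
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_frame_equal(ta, tb)
        buf_a, buf_b = io.StringIO(), io.StringIO()
        a.data.to_csv(buf_a, index=False)
        b.data.to_csv(buf_b, index=False)
        assert buf_a.getvalue() == buf_b.getvalue()

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sim.ScreenConfig(class_frequencies={"inactive": 0.9})
        with pytest.raises(ValueError, match="unknown classes"):
            sim.ScreenConfig(class_frequencies={"inactive": 0.5, "bogus": 0.5})

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError):
            sim.ScreenConfig(controls_per_plate=1)


class TestTruthConsistency:
    @pytest.mark.parametrize("cls", sim.CLASSES)
    def test_class_rate_map_round_trips(self, cls):
        # nonzero planted rates exactly mirror the class label
        profile = make_profile(cls)
        has = (profile.sulfatase_rate > 0, profile.generic_sulfatase,
               profile.hex_sulfated_rate > 0, profile.hex_asulfated_rate > 0,
               profile.autofluor_rate > 0)
        assert has == sim.CLASS_RATE_MAP[cls]

    def test_inconsistent_profile_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            sim.WellProfile("w", "clone", "inactive", sulfatase_rate=1.0)
        with pytest.raises(ValueError, match="control"):
            sim.WellProfile("w", "control", "sulfo_specific_sulfatase",
                            sulfatase_rate=1.0)

    def test_screen_truth_consistent_everywhere(self, mini_screen):
        _, truth = mini_screen
        for r in truth.to_dict("records"):
            has = (r["sulfatase_rate"] > 0, bool(r["generic_sulfatase"]),
                   r["hex_sulfated_rate"] > 0, r["hex_asulfated_rate"] > 0,
                   r["autofluor_rate"] > 0)
            assert has == sim.CLASS_RATE_MAP[r["true_class"]]


class TestPanelSimulation:
    def test_sulfo_specific_signal_only_in_coupled(self):
        pan = sim.simulate_panel(make_profile("sulfo_specific_sulfatase"), seed=1)
        background = pan.rfu["no_substrate"]
        assert pan.rfu["coupled"] > background + 100
        for cond in ("direct", "asulfated", "generic_sulfate"):
            assert pan.rfu[cond] == pytest.approx(background, abs=1.0)

    def test_autofluorescent_signal_everywhere(self):
        pan = sim.simulate_panel(make_profile("autofluorescent_false_positive"), seed=1)
        base = sim.AssayConstants().baseline
        for cond in sim.PANEL_CONDITIONS:
            assert pan.rfu[cond] > base + 100  # including no-substrate

    def test_inactive_all_background(self):
        pan = sim.simulate_panel(make_profile("inactive"), seed=1)
        base = sim.AssayConstants().baseline
        for cond in sim.PANEL_CONDITIONS:
            assert pan.rfu[cond] == pytest.approx(base)

    def test_sulfate_dependent_hex_direct_but_not_asulfated(self):
        pan = sim.simulate_panel(make_profile("sulfate_dependent_hexosaminidase"), seed=1)
        base = sim.AssayConstants().baseline
        assert pan.rfu["direct"] > base + 100
        assert pan.rfu["asulfated"] == pytest.approx(base, abs=1.0)


class TestTraceSimulation:
    def test_identity_warp_apex_at_reference(self):
        spec = sim.TraceSpec(components=(sim.TraceComponent("FA2G0-SO4", 150.0, 100.0),),
                             noise_sd=0.0)
        trace, truth = sim.simulate_trace(spec)
        apex = trace.times[np.argmax(
            np.where(np.abs(trace.times - 150) < 20, trace.intensities, 0))]
        assert apex == pytest.approx(150.0, abs=spec.grid_step / 2)
        assert truth["FA2G0-SO4"]["raw_time"] == pytest.approx(150.0)

    def test_affine_warp_moves_apex(self):
        spec = sim.TraceSpec(components=(sim.TraceComponent("FA2G0-SO4", 150.0, 100.0),),
                             warp_slope=2.0, warp_intercept=500.0, noise_sd=0.0)
        _, truth = sim.simulate_trace(spec)
        assert truth["FA2G0-SO4"]["raw_time"] == pytest.approx(800.0)

    def test_fixed_seed_bit_identical(self):
        spec = sim.TraceSpec(components=(sim.TraceComponent("M3", 178.0, 50.0),), seed=3)
        a, _ = sim.simulate_trace(spec)
        b, _ = sim.simulate_trace(spec)
        assert np.array_equal(a.intensities, b.intensities)

    def test_standards_must_bracket_analytes(self):
        with pytest.raises(ValueError, match="bracket"):
            sim.TraceSpec(components=(sim.TraceComponent("x", 400.0, 10.0),))

    def test_warp_slope_must_be_positive(self):
        with pytest.raises(ValueError, match="slope"):
            sim.TraceSpec(components=(), warp_slope=-1.0)

    def test_noiseless_trace_area_matches_planted_peaks(self):
        comps = (sim.TraceComponent("FA2G0-SO4", 150.0, 100.0),
                 sim.TraceComponent("FA1G0", 245.0, 60.0))
        spec = sim.TraceSpec(components=comps, noise_sd=0.0)
        trace, _ = sim.simulate_trace(spec)
        area = np.trapezoid(trace.intensities, trace.times)
        expected = sum(h * spec.peak_width * np.sqrt(2 * np.pi)
                       for h in (100.0, 60.0, spec.std_height, spec.std_height))
        assert area == pytest.approx(expected, rel=0.005)


class TestGlycanLibrary:
    def test_reference_positions(self, glycan_library):
        by_name = {e.name: e.mtu for e in glycan_library}
        assert by_name["FA2G0-SO4"] == 150.0
        assert by_name["M3"] == 178.0
        assert by_name["FM3"] == 207.0
        assert by_name["FA1G0"] == 245.0

    def test_names_unique_and_positions_valid(self, glycan_library):
        names = [e.name for e in glycan_library]
        assert len(set(names)) == len(names)
        assert all(e.mtu > 0 and np.isfinite(e.mtu) for e in glycan_library)

    def test_library_tsv_round_trip(self, glycan_library, tmp_path):
        path = tmp_path / "lib.tsv"
        sim.write_glycan_library_tsv(glycan_library, path)
        back = sim.read_glycan_library_tsv(path)
        assert [(e.name, e.mtu) for e in back] == \
               [(e.name, e.mtu) for e in glycan_library]


class TestDigestPairSimulation:
    def test_complete_conversion_moves_all_substrate(self, enzymes, glycan_library):
        spec = sim.TraceSpec(components=(), noise_sd=0.0)
        pre, post = sim.simulate_digest_pair({"FA2G0-SO4": 50.0}, enzymes["F1_SULFATASE"],
                                             spec, glycan_library)
        # post apex must sit at FA2G0's fixture position, not at 150
        in_band = lambda tr, mtu: tr.intensities[np.abs(tr.times - mtu) < 5].max()
        assert in_band(pre, 150.0) > 40
        assert in_band(post, 150.0) < 1
        assert in_band(post, 265.0) > 40

    def test_binding_mode_depletes_without_product(self, enzymes, glycan_library):
        spec = sim.TraceSpec(components=(), noise_sd=0.0)
        pre, post = sim.simulate_digest_pair({"FA2G0-SO4": 50.0, "FA2G0": 20.0},
                                             enzymes["F1_APO_BINDING"], spec,
                                             glycan_library)
        in_band = lambda tr, mtu: tr.intensities[np.abs(tr.times - mtu) < 5].max()
        assert in_band(post, 150.0) == pytest.approx(
            in_band(pre, 150.0) * 0.4, rel=0.05)  # 60% depleted
        assert in_band(post, 265.0) == pytest.approx(in_band(pre, 265.0), rel=0.05)

    def test_unknown_pool_glycan_rejected(self, enzymes, glycan_library):
        with pytest.raises(ValueError, match="not in library"):
            sim.simulate_digest_pair({"nope": 1.0}, enzymes["F1_SULFATASE"],
                                     sim.TraceSpec(components=()), glycan_library)


class TestTraceIO:
    def test_trace_csv_round_trip(self, tmp_path):
        spec = sim.TraceSpec(components=(sim.TraceComponent("M3", 178.0, 50.0),), seed=8)
        trace, _ = sim.simulate_trace(spec)
        path = tmp_path / "trace.csv"
        sim.write_trace_csv(trace, path)
        back = sim.read_trace_csv(path)
        assert np.allclose(back.times, trace.times)
        assert np.allclose(back.intensities, trace.intensities)
        assert [s.name for s in back.standards] == ["STD-LOW", "STD-HIGH"]

    def test_empty_trace_file_errors(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("time,intensity\n")
        with pytest.raises(ValueError, match="empty"):
            sim.read_trace_csv(path)
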