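"""Event functions, timing conversion, RDP classes, and script I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdspeech import (
    RDP,
    Event,
    UtteranceScript,
    builtin_rdp,
    event_function,
    read_script,
    time_to_samples,
    write_script,
)
from rdspeech.events import ScriptSchemaError
from rdspeech.fixtures import sentence1, sentence2


def make_event(t_p=0.5, t_w=0.1, t_h=0.0, mu=0.5):
    return Event("x", RDP(-1, 1, 1), mu, t_p, t_w, t_h)


def script_for(ev, duration=1.2):
    return UtteranceScript([ev], duration)


class TestEventFunction:
    def test_peak_amplitude_is_exactly_one(self):
        ev = make_event()
        e = event_function(ev, script_for(ev))
        n_p = time_to_samples(ev.t_p)
        assert e[n_p - 1] == 1.0

    def test_half_amplitude_at_half_width(self):
        ev = make_event(t_p=100 / 146.0, t_w=20 / 146.0)
        e = event_function(ev, script_for(ev))
        # n = N_p +/- N_w/2 sits at amplitude 0.5 by construction
        assert e[100 + 10 - 1] == pytest.approx(0.5)
        assert e[100 - 10 - 1] == pytest.approx(0.5)

    def test_one_sixteenth_at_full_width(self):
        ev = make_event(t_p=100 / 146.0, t_w=20 / 146.0)
        e = event_function(ev, script_for(ev))
        assert e[100 + 20 - 1] == pytest.approx(1.0 / 16.0)

    def test_bounded_and_symmetric_without_hold(self):
        ev = make_event(t_p=0.6)
        e = event_function(ev, script_for(ev))
        assert np.all((e >= 0) & (e <= 1))
        n_p = time_to_samples(ev.t_p)
        for k in range(1, 20):
            assert e[n_p - 1 + k] == pytest.approx(e[n_p - 1 - k])

    def test_sampled_fwhm_matches_width_parameter(self):
        ev = make_event(t_p=0.6, t_w=0.15)
        e = event_function(ev, script_for(ev))
        n_w = time_to_samples(ev.t_w)
        fwhm = int(np.sum(e >= 0.5))
        assert abs(fwhm - n_w) <= 1

    def test_hold_inserts_unit_plateau_centered_on_peak(self):
        ev = make_event(t_p=0.6, t_w=0.1, t_h=0.1)
        e = event_function(ev, script_for(ev))
        n_p = time_to_samples(ev.t_p)
        half = time_to_samples(ev.t_h) // 2
        plateau = e[n_p - 1 - half : n_p + half]
        np.testing.assert_array_equal(plateau, np.ones_like(plateau))
        # flanks decay like the held-free Gaussian shifted by the half-hold
        assert e[n_p - 1 + half + 5] < 1.0

    @given(
        st.floats(0.2, 1.0),
        st.floats(0.05, 0.3),
        st.floats(0.0, 0.1),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_amplitude_always_in_unit_interval(self, t_p, t_w, t_h):
        ev = make_event(t_p=t_p, t_w=t_w, t_h=t_h)
        e = event_function(ev, script_for(ev, duration=1.5))
        assert np.all((e >= 0) & (e <= 1))
        assert e.max() == 1.0


class TestTimeToSamples:
    @pytest.mark.parametrize(
        "t,expected", [(0.14, 20), (0.0, 0), (1.0, 146)]
    )
    def test_rounding(self, t, expected):
        assert time_to_samples(t, 146) == expected

    def test_negative_time_rejected(self):
        with pytest.raises(ScriptSchemaError):
            time_to_samples(-0.1)

    def test_inverse_mapping_within_half_frame(self):
        n = time_to_samples(0.37, 146)
        assert abs(n / 146 - 0.37) <= 0.5 / 146


class TestBuiltinRDP:
    def test_bilabial_deflects_all_three_down(self):
        r = builtin_rdp("bilabial")
        assert (r.delta1, r.delta2, r.delta3) == (-1, -1, -1)

    def test_alveolar_first_down_second_third_up(self):
        r = builtin_rdp("alveolar")
        assert (r.delta1, r.delta2, r.delta3) == (-1, 1, 1)

    def test_velar_first_down_second_up_third_down(self):
        r = builtin_rdp("velar")
        assert (r.delta1, r.delta2, r.delta3) == (-1, 1, -1)

    def test_unknown_class_rejected(self):
        with pytest.raises(ScriptSchemaError):
            builtin_rdp("uvular")


class TestScriptIO:
    def test_round_trip_identity(self, tmp_path):
        s = sentence2()
        path = tmp_path / "s.json"
        write_script(s, path)
        back = read_script(path)
        assert back.events == s.events
        assert back.duration == s.duration
        assert back.f0_contour == s.f0_contour
        assert back.abduction_intervals == s.abduction_intervals

    def test_delta_out_of_range_names_event(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(
            '{"duration": 1.0, "events": [{"label": "x", '
            '"delta": [0, 1.5, 0], "mu": 0.5, "tp": 0.3, "tw": 0.1}]}'
        )
        with pytest.raises(ScriptSchemaError, match="event 0"):
            read_script(path)

    def test_non_positive_width_rejected(self):
        with pytest.raises(ScriptSchemaError):
            make_event(t_w=0.0)

    def test_rdp_range_enforced(self):
        with pytest.raises(ScriptSchemaError):
            RDP(0.0, -1.2, 0.0)


class TestSentenceFixtures:
    def test_sentence1_events(self):
        s = sentence1()
        assert [ev.label for ev in s.events] == [
            "d", "ao", "g", "eh", "ih", "t", "b", "ah", "g",
        ]
        assert s.events[2].t_p == 0.55 and s.events[2].t_h == 0.03

    def test_sentence2_events(self):
        s = sentence2()
        assert len(s.events) == 11
        first = s.events[0]
        assert (first.label, first.t_p, first.t_w, first.t_h) == ("f", 0.10, 0.10, 0.03)

    def test_fricative_nearly_occludes_with_hold(self):
        s = sentence2()
        for ev in s.events:
            if ev.label == "f":
                assert ev.mu == 0.98 and ev.t_h == 0.03

    def test_liquid_deflections(self):
        s = sentence2()
        r = next(ev for ev in s.events if ev.label == "r")
        l = next(ev for ev in s.events if ev.label == "l")
        assert (r.rdp.delta1, r.rdp.delta2, r.rdp.delta3) == (-0.3, 0.0, -1.0)
        assert (l.rdp.delta1, l.rdp.delta2, l.rdp.delta3) == (-0.3, 0.0, 1.0)
        assert r.mu == 0.8 and l.mu == 0.9

    def test_shared_symbols_have_identical_rdps_across_sentences(self):
        s1 = {ev.label: ev.rdp for ev in sentence1().events}
        s2 = {ev.label: ev.rdp for ev in sentence2().events}
        for sym in set(s1) & set(s2):
            assert s1[sym] == s2[sym]
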