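import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylomap.splicing import (
    call_delta_psi,
    call_events,
    central_motif_enrichment,
    compute_psi,
    concordance_analysis,
    expressed_filter,
    fpkm,
    summarize_events,
)
from .oracles import binom_tail_oracle


class TestComputePsi:
    def test_symmetric_counts(self):
        assert compute_psi(50, 50, 1, 1) == pytest.approx(0.5)

    def test_length_normalization(self):
        assert compute_psi(30, 10, 2, 1) == pytest.approx(0.6)  # 15/(15+10)

    def test_zero_counts_absent(self):
        assert math.isnan(compute_psi(0, 0, 1, 1, min_total=0))

    def test_below_min_total_absent(self):
        assert math.isnan(compute_psi(4, 5, 1, 1, min_total=10))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_psi(-1, 5, 1, 1)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            compute_psi(1, 5, 0, 1)

    @given(
        inc=st.integers(0, 5000),
        skip=st.integers(0, 5000),
    )
    @settings(max_examples=200, deadline=None)
    def test_equal_length_limit_is_isoform_ratio(self, inc, skip):
        psi = compute_psi(inc, skip, 3.0, 3.0, min_total=0)
        if inc + skip == 0:
            assert math.isnan(psi)
        else:
            assert psi == pytest.approx(inc / (inc + skip))
            assert 0.0 <= psi <= 1.0

    @given(
        inc=st.integers(0, 500),
        skip=st.integers(10, 500),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_inclusion_count(self, inc, skip):
        lo = compute_psi(inc, skip, 2, 1, min_total=0)
        hi = compute_psi(inc + 1, skip, 2, 1, min_total=0)
        assert hi >= lo


class TestDeltaPsi:
    def test_strong_skipping_call(self):
        call = call_delta_psi(0.9, 0.2)
        assert call.delta_psi == pytest.approx(0.7)
        assert call.differential and call.direction == "ES"

    def test_small_change_not_differential(self):
        call = call_delta_psi(0.4, 0.6)
        assert call.delta_psi == pytest.approx(-0.2)
        assert not call.differential and call.direction == "none"

    def test_boundary_inclusive(self):
        call = call_delta_psi(1.0, 0.5)
        assert call.differential  # |dPSI| = 0.5 counts

    def test_absent_psi_gives_no_call(self):
        assert call_delta_psi(float("nan"), 0.5) is None

    @given(
        a=st.floats(0, 1),
        b=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry_under_condition_swap(self, a, b):
        fwd = call_delta_psi(a, b)
        rev = call_delta_psi(b, a)
        assert fwd.delta_psi == pytest.approx(-rev.delta_psi)
        assert fwd.differential == rev.differential
        if fwd.differential and a != b:
            assert {fwd.direction, rev.direction} == {"EI", "ES"}


def _counts_row(event_id, etype, cond, inc, skip, il=1.0, sl=1.0):
    return {
        "event_id": event_id,
        "event_type": etype,
        "condition": cond,
        "inc_count": inc,
        "skip_count": skip,
        "inc_len": il,
        "skip_len": sl,
    }


class TestCallEvents:
    def test_calls_and_untestable_reported(self):
        counts = pd.DataFrame(
            [
                _counts_row("E1", "SE", "ctl", 90, 10),
                _counts_row("E1", "SE", "kd", 10, 90),
                _counts_row("E2", "IR", "ctl", 3, 2),  # below coverage
                _counts_row("E2", "IR", "kd", 50, 50),
            ]
        )
        calls = call_events(counts, "ctl", "kd")
        e1 = calls[calls["event_id"] == "E1"].iloc[0]
        assert e1["differential"] and e1["direction"] == "ES"
        e2 = calls[calls["event_id"] == "E2"].iloc[0]
        assert not e2["testable"] and not e2["differential"]

    def test_missing_condition_rejected(self):
        counts = pd.DataFrame([_counts_row("E1", "SE", "ctl", 9, 1)])
        with pytest.raises(ValueError, match="missing"):
            call_events(counts, "ctl", "kd")

    def test_summary_counts(self):
        counts = pd.DataFrame(
            [
                _counts_row("E1", "SE", "ctl", 95, 5),
                _counts_row("E1", "SE", "kd", 5, 95),
                _counts_row("E2", "SE", "ctl", 90, 10),
                _counts_row("E2", "SE", "kd", 10, 90),
                _counts_row("E3", "SE", "ctl", 80, 20),
                _counts_row("E3", "SE", "kd", 15, 85),
                _counts_row("E4", "IR", "ctl", 10, 90),
                _counts_row("E4", "IR", "kd", 95, 5),
                _counts_row("E5", "MXE", "ctl", 50, 50),
                _counts_row("E5", "MXE", "kd", 55, 45),
            ]
        )
        summary = summarize_events(call_events(counts, "ctl", "kd"))
        assert summary["SE"] == {"EI": 0, "ES": 3, "differential": 3}
        assert summary["IR"] == {"EI": 1, "ES": 0, "differential": 1}
        assert summary["MXE"]["differential"] == 0
        assert summary["total"]["differential"] == 4


class TestConcordance:
    def _calls(self, rows):
        return pd.DataFrame(
            [
                {
                    "event_id": eid,
                    "event_type": "SE",
                    "psi_ctl": 0.9,
                    "psi_kd": 0.2,
                    "delta_psi": 0.7,
                    "differential": direction != "none",
                    "direction": direction,
                    "testable": True,
                }
                for eid, direction in rows
            ]
        )

    def test_all_same_direction_concordant(self):
        calls = {
            lab: self._calls([("E1", "ES"), ("E2", "none")])
            for lab in ("PRMT4", "PRMT5", "PRMT7")
        }
        conc = concordance_analysis(calls)
        assert conc.class_counts[3] == 1
        assert conc.concordance_fraction == 1.0

    def test_mixed_directions_discordant(self):
        calls = {
            "A": self._calls([("E1", "EI")]),
            "B": self._calls([("E1", "ES")]),
            "C": self._calls([("E1", "none")]),
        }
        conc = concordance_analysis(calls)
        assert conc.class_counts[2] == 1
        assert conc.n_discordant == 1

    def test_universe_mismatch_rejected(self):
        calls = {
            "A": self._calls([("E1", "EI")]),
            "B": self._calls([("E2", "ES")]),
        }
        with pytest.raises(ValueError, match="universes differ"):
            concordance_analysis(calls)


class TestFpkm:
    def test_reference_value(self):
        assert fpkm(100, 1000, 1_000_000) == pytest.approx(100.0)

    def test_scale_invariance(self):
        assert fpkm(200, 1000, 2_000_000) == pytest.approx(
            fpkm(100, 1000, 1_000_000)
        )

    def test_threshold_strictly_greater(self):
        # FPKM exactly 0.5 in every condition -> excluded
        vals = {"ctl": 0.5, "kd": 0.5}
        assert not expressed_filter(vals, keep_threshold=0.5)
        assert expressed_filter({"ctl": 0.5, "kd": 0.51}, keep_threshold=0.5)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            fpkm(10, 0, 1e6)


class TestCentralMotif:
    def test_central_matches_highly_significant(self):
        rng = np.random.default_rng(0)
        seqs = []
        for _ in range(50):
            s = rng.choice(list("ACGT"), size=575)
            mid = 575 // 2
            for start in (mid - 10, mid, mid + 10):
                s[start : start + 4] = list("TAGG")
            seqs.append("".join(s))
        res = central_motif_enrichment(seqs, "TAGG", center_window=50)
        assert res.p_value < 1e-10
        # cross-check against the exact binomial tail
        oracle = binom_tail_oracle(
            res.n_in_window, res.n_matches, Fraction(res.p0).limit_denominator(10**9)
        )
        assert res.p_value == pytest.approx(oracle, rel=1e-6)

    def test_zero_matches_p_one(self):
        seqs = ["A" * 100, "C" * 100]
        res = central_motif_enrichment(seqs, "TAGG", center_window=20)
        assert res.n_matches == 0 and res.p_value == 1.0

    def test_iupac_degenerate_symbols(self):
        res = central_motif_enrichment(["AATAGGGTAA"], "TAGGGW", center_window=10)
        assert res.n_matches == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            central_motif_enrichment([], "TAGG")

    def test_uniform_matches_not_significant(self):
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list("ACGT"), size=575)) for _ in range(60)]
        res = central_motif_enrichment(seqs, "TAGG", center_window=100)
        assert res.p_value > 0.001  # no planted central preference
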