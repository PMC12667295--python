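"""Per-well assay arithmetic: Papp, efflux ratio, recovery, TEER, batch QC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from bbbscreen import (
    BLQ,
    CellLine,
    Direction,
    QCPolicy,
    SinkConditionWarning,
    TeerMeasurement,
    TransportRecord,
    ValidationError,
    compute_efflux_ratio,
    compute_papp,
    compute_recovery,
    compute_teer,
    is_blq,
    run_qc,
    summarize_permeability,
)
from bbbscreen.assay import format_er, format_papp, round_sig
from bbbscreen.simulate import AssayTruth, simulate_transport_assay


def make_record(**kw):
    defaults = dict(
        compound_id="X",
        cell_line=CellLine.MOCK,
        direction=Direction.AtoB,
        c0_donor=2.0,
        c_donor_final=1.9,
        receiver_amount=0.02,
        duration=7200.0,
    )
    defaults.update(kw)
    return TransportRecord(**defaults)


def ode_endpoint(papp_1e6, c0, vd, vr, area, duration, trapping=0.0):
    """Independent numerical oracle for the two-compartment endpoint."""
    p = papp_1e6 * 1e-6

    def rhs(_t, y):
        qd, qr, _qc = y
        flux = p * area * (qd / vd - qr / vr)
        return [-flux, (1 - trapping) * flux, trapping * flux]

    sol = solve_ivp(rhs, (0.0, duration), [c0 * vd, 0.0, 0.0],
                    rtol=1e-11, atol=1e-14)
    return sol.y[:, -1]


class TestComputePapp:
    def test_zero_receiver_amount_gives_zero(self):
        assert compute_papp(make_record(receiver_amount=0.0)) == 0.0

    def test_blq_receiver_gives_blq_not_zero(self):
        result = compute_papp(make_record(receiver_amount=BLQ))
        assert is_blq(result)
        assert result != 0.0

    def test_halves_when_duration_doubles(self):
        p1 = compute_papp(make_record(duration=3600.0))
        p2 = compute_papp(make_record(duration=7200.0))
        assert p2 == pytest.approx(p1 / 2)

    def test_recovers_true_permeability_in_sink_regime(self):
        """Endpoint estimate vs the ODE oracle: <2% bias at a 30-min sink run."""
        truth = AssayTruth("S", papp_true=10.0, noise_cv=0.0)
        recs = simulate_transport_assay(truth, duration=1800.0)
        rec = next(r for r in recs
                   if r.cell_line is CellLine.MOCK and r.direction is Direction.AtoB)
        _qd, qr, _qc = ode_endpoint(10.0, rec.c0_donor, rec.v_donor,
                                    rec.v_receiver, rec.area, rec.duration)
        assert rec.receiver_amount == pytest.approx(qr, rel=1e-9)
        assert compute_papp(rec) == pytest.approx(10.0, rel=0.02)

    def test_bias_grows_with_receiver_accumulation(self):
        """The endpoint estimator under-reads more the further from sink."""
        truth = AssayTruth("S", papp_true=10.0, noise_cv=0.0)
        errors = []
        for duration in (900.0, 3600.0, 14400.0, 43200.0):
            recs = simulate_transport_assay(truth, duration=duration)
            rec = next(r for r in recs if r.cell_line is CellLine.MOCK
                       and r.direction is Direction.AtoB)
            errors.append(10.0 - compute_papp(rec))
        assert all(e >= 0 for e in errors)
        assert errors == sorted(errors)

    def test_sink_violation_warns(self):
        rec = make_record(c_donor_final=1.0, receiver_amount=0.5, v_receiver=0.85)
        with pytest.warns(SinkConditionWarning):
            compute_papp(rec, policy=QCPolicy())

    @pytest.mark.parametrize("field,value", [
        ("c0_donor", 0.0), ("duration", -1.0), ("area", 0.0),
    ])
    def test_nonpositive_inputs_rejected(self, field, value):
        with pytest.raises(ValidationError):
            make_record(**{field: value})

    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           amount=st.floats(min_value=1e-6, max_value=0.3),
           c0=st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_consistent_unit_rescaling(self, scale, amount, c0):
        """Rescaling the amount unit (nmol<->umol with matching uM<->mM) is a no-op."""
        base = make_record(c0_donor=c0, c_donor_final=None, receiver_amount=amount)
        scaled = make_record(c0_donor=c0 * scale, c_donor_final=None,
                             receiver_amount=amount * scale)
        assert compute_papp(scaled) == pytest.approx(compute_papp(base), rel=1e-12)


class TestEffluxRatio:
    @pytest.mark.parametrize("ba,ab,expected", [
        (42.9, 2.48, 17.3),   # strongly effluxed substrate
        (47.5, 9.45, 5.03),   # substrate with retained permeability
        (33.9, 1.32, 25.7),   # low-permeability substrate
    ])
    def test_reported_table_values(self, ba, ab, expected):
        assert round_sig(compute_efflux_ratio(ab, ba), 3) == pytest.approx(expected)

    @given(x=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_symmetric_transport_gives_unity(self, x):
        assert compute_efflux_ratio(x, x) == pytest.approx(1.0)

    def test_undefined_when_ab_blq_or_zero(self):
        assert compute_efflux_ratio(BLQ, 1.0) is None
        assert compute_efflux_ratio(0.0, 1.0) is None
        assert format_er(None) == "\\"

    def test_er_from_papps_matches_er_from_amounts(self):
        """Unit handling: Papp-ratio equals raw amount-ratio at shared t, A, C0."""
        ab = make_record(receiver_amount=0.01)
        ba = make_record(direction=Direction.BtoA, receiver_amount=0.17)
        er = compute_efflux_ratio(compute_papp(ab), compute_papp(ba))
        assert er == pytest.approx(0.17 / 0.01)


class TestRecovery:
    def test_nothing_moved_nothing_lost(self):
        rec = make_record(c_donor_final=2.0, receiver_amount=0.0)
        assert compute_recovery(rec) == pytest.approx(100.0)

    def test_all_mass_in_receiver(self):
        rec = make_record(c_donor_final=0.0, receiver_amount=0.4, v_donor=0.2)
        assert compute_recovery(rec) == pytest.approx(100.0)

    def test_trapped_mass_recovered_through_lysate(self):
        """30% of initial mass in the cell layer: 70% without, 100% with lysate."""
        rec = make_record(v_donor=0.2, c0_donor=2.0,          # 0.4 nmol dosed
                          c_donor_final=1.0,                  # 0.2 nmol left
                          receiver_amount=0.08,
                          lysate_amount=0.12)                 # 30% of 0.4
        assert compute_recovery(rec) == pytest.approx(70.0)
        assert compute_recovery(rec, include_lysate=True) == pytest.approx(100.0)

    def test_lysate_requested_but_missing(self):
        with pytest.raises(ValidationError, match="lysate"):
            compute_recovery(make_record(lysate_amount=None), include_lysate=True)

    def test_noiseless_untrapped_simulation_conserves_mass(self):
        truth = AssayTruth("M", papp_true=15.0, noise_cv=0.0)
        for rec in simulate_transport_assay(truth):
            assert compute_recovery(rec) == pytest.approx(100.0, abs=1e-9)


class TestTeer:
    def test_blank_corrected_value(self):
        assert compute_teer(TeerMeasurement(300.0, 100.0, 0.33)) == pytest.approx(66.0)

    def test_equal_resistances_give_zero(self):
        assert compute_teer(TeerMeasurement(150.0, 150.0)) == 0.0

    def test_linear_in_area(self):
        t1 = compute_teer(TeerMeasurement(300.0, 100.0, 0.33))
        t2 = compute_teer(TeerMeasurement(300.0, 100.0, 0.66))
        assert t2 == pytest.approx(2 * t1)

    def test_blank_above_total_warns_and_surfaces_negative(self):
        with pytest.warns(UserWarning, match="negative TEER"):
            assert compute_teer(TeerMeasurement(90.0, 100.0, 0.33)) < 0


class TestRunQC:
    CONTROLS = {"atenolol": [0.27, 0.28, 0.26], "metoprolol": [30.0, 31.0, 29.5]}

    def test_tight_monolayer_passes(self):
        qc = run_qc(batch_id="b1", ly_papp=0.46, teer=89.0,
                    control_papp_ab=self.CONTROLS)
        assert qc.passed and qc.reasons == []

    def test_leaky_monolayer_fails_with_reason(self):
        qc = run_qc(batch_id="b2", ly_papp=5.0, teer=89.0,
                    control_papp_ab=self.CONTROLS)
        assert not qc.passed
        assert "paracellular leak" in qc.reasons

    def test_zero_cv_controls_pass(self):
        qc = run_qc(batch_id="b3", ly_papp=0.5, teer=132.0,
                    control_papp_ab={"digoxin": [20.0, 20.0, 20.0]})
        assert qc.passed and qc.control_cv["digoxin"] == 0.0

    def test_high_control_cv_fails(self):
        qc = run_qc(batch_id="b4", ly_papp=0.5, teer=132.0,
                    control_papp_ab={"digoxin": [10.0, 20.0, 30.0]})
        assert not qc.passed

    def test_low_teer_fails(self):
        qc = run_qc(batch_id="b5", ly_papp=0.5, teer=50.0,
                    control_papp_ab=self.CONTROLS)
        assert not qc.passed

    def test_empty_batch_rejected(self):
        with pytest.raises(ValidationError):
            run_qc(batch_id="b6", ly_papp=0.5, teer=100.0, control_papp_ab={})


class TestSummarize:
    def test_er_uses_direction_means(self):
        truth = AssayTruth("E", papp_true=5.0, efflux_multiplier=4.0, noise_cv=0.05,
                           seed=7)
        recs = [r for r in simulate_transport_assay(truth, duration=1800.0)
                if r.cell_line is CellLine.MDR1]
        s = summarize_permeability(recs)
        assert s.n_replicates == 3
        assert s.er == pytest.approx(s.papp_ba / s.papp_ab)
        assert s.papp_ab_sd > 0

    def test_blq_direction_propagates(self):
        recs = [make_record(receiver_amount=BLQ, replicate_id=i) for i in (1, 2, 3)]
        recs += [make_record(direction=Direction.BtoA, receiver_amount=0.01,
                             replicate_id=i) for i in (1, 2, 3)]
        s = summarize_permeability(recs)
        assert is_blq(s.papp_ab)
        assert s.er is None
        assert format_papp(s.papp_ab) == "BLQ"

    def test_mixed_compounds_rejected(self):
        with pytest.raises(ValidationError):
            summarize_permeability([make_record(), make_record(compound_id="Y")])
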