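import dataclasses

import numpy as np
import pandas as pd
import pytest

from ncounter_reject.qc import (
    EmptyCohortError,
    QCThresholds,
    filter_samples,
    lane_qc,
    limit_of_detection,
    pos_control_linearity,
    technical_norm_factor,
)
from ncounter_reject._utils import geomean

from conftest import make_lane, matrix_from_lanes, toy_panel


def _counts(panel, pos=None, neg=None, content=100):
    out = {}
    pos_ids = panel.positive_concentrations().index
    for i, pid in enumerate(pos_ids):
        out[pid] = pos[i] if pos is not None else 100
    for i, pid in enumerate(panel.ids_of("Negative")):
        out[pid] = neg[i] if neg is not None else 5
    for pid in panel.ids_of("Endogenous") + panel.ids_of("Housekeeping"):
        out[pid] = content
    return out


class TestPosControlLinearity:
    def test_exact_power_law_gives_r2_one(self, panel):
        # counts proportional to concentration**1 on the standard 6-point series
        counts = _counts(panel, pos=[1024, 256, 64, 16, 4, 1])
        assert pos_control_linearity(counts, panel) == pytest.approx(1.0)

    def test_proportional_counts_give_r2_one(self, panel):
        counts = _counts(panel, pos=[12800, 3200, 800, 200, 50, 13])
        assert pos_control_linearity(counts, panel) > 0.999

    def test_constant_positives_degenerate_r2_zero(self, panel):
        counts = _counts(panel, pos=[50] * 6)
        assert pos_control_linearity(counts, panel) == 0.0


class TestLimitOfDetection:
    def test_passes_two_sd_above_negatives(self):
        # negatives mean 8, sample SD 3.1623 -> cutoff 14.3246; 0.5 fM probe at 20
        big_panel = toy_panel(n_neg=5)
        counts = _counts(big_panel, pos=[1000, 500, 100, 50, 20, 5],
                         neg=[4, 6, 8, 10, 12])
        assert limit_of_detection(counts, big_panel)

    def test_zero_negatives_any_positive_passes(self, panel):
        counts = _counts(panel, pos=[1000, 500, 100, 50, 1, 0], neg=[0, 0, 0, 0])
        assert limit_of_detection(counts, panel)

    def test_below_mean_fails(self, panel):
        counts = _counts(panel, pos=[1000, 500, 100, 50, 9, 5], neg=[10, 10, 10, 10])
        assert not limit_of_detection(counts, panel)


class TestTechnicalNormFactor:
    def test_identical_lanes_give_unit_factors(self, panel):
        lanes = [make_lane(panel, sample_id=f"S{i}") for i in range(3)]
        matrix = matrix_from_lanes(panel, lanes)
        factors = technical_norm_factor(matrix)
        assert np.allclose(factors, 1.0)

    def test_doubled_sample_factors(self, panel):
        lane1 = make_lane(panel, sample_id="S1")
        doubled = {pid: 2 * c for pid, c in lane1.counts.items()}
        lane2 = dataclasses.replace(lane1, sample_id="S2", counts=doubled)
        matrix = matrix_from_lanes(panel, [lane1, lane2])
        factors = technical_norm_factor(matrix)
        # geomeans (g, 2g) -> mean 1.5g -> factors (1.5, 0.75)
        assert factors["S1"] == pytest.approx(1.5)
        assert factors["S2"] == pytest.approx(0.75)

    def test_mean_geomean_conserved_after_scaling(self, panel):
        lanes = [
            make_lane(panel, sample_id=f"S{i}", base=80 + 17 * i) for i in range(4)
        ]
        matrix = matrix_from_lanes(panel, lanes)
        factors = technical_norm_factor(matrix)
        pos_ids = matrix.panel.ids_of("Positive")
        gms = np.array(
            [geomean(matrix.values.loc[pos_ids, s]) for s in matrix.values.columns]
        )
        scaled = gms * factors.values
        assert np.allclose(scaled, gms.mean())
        assert np.allclose(scaled, scaled[0])


class TestLaneQC:
    def _cohort(self, panel, special_lane):
        clean = [make_lane(panel, sample_id=f"C{i}") for i in range(3)]
        return matrix_from_lanes(panel, clean + [special_lane])

    def test_clean_lane_unflagged(self, panel):
        matrix = self._cohort(panel, make_lane(panel, sample_id="X"))
        report = lane_qc(matrix)
        assert not report.table["excluded"].any()
        assert all(not report.flags[s] for s in report.table.index)

    def test_binding_density_exception_flags_but_keeps(self, panel):
        lane = make_lane(panel, sample_id="X", binding_density=2.5)
        report = lane_qc(self._cohort(panel, lane))
        assert "binding_density" in report.flags["X"]
        assert not report.table.loc["X", "excluded"]

    def test_binding_density_with_bad_linearity_excludes(self, panel):
        lane = make_lane(panel, sample_id="X", binding_density=2.5)
        flat = {pid: 50 for pid in panel.ids_of("Positive")}
        lane = dataclasses.replace(lane, counts={**lane.counts, **flat})
        report = lane_qc(self._cohort(panel, lane))
        assert report.table.loc["X", "excluded"]
        assert any("binding density" in r for r in report.reasons["X"])

    def test_low_reference_geomean_excludes(self, panel):
        lane = make_lane(panel, sample_id="X",
                         overrides={"H1": 25, "H2": 25})
        report = lane_qc(self._cohort(panel, lane))
        assert report.table.loc["X", "excluded"]
        assert any("geomean" in r for r in report.reasons["X"])

    def test_low_fov_excludes(self, panel):
        lane = make_lane(panel, sample_id="X", fov=(490, 200))
        report = lane_qc(self._cohort(panel, lane))
        assert report.table.loc["X", "excluded"]

    def test_exclusion_reason_invariant_holds(self, panel):
        lane = make_lane(panel, sample_id="X", fov=(490, 200))
        report = lane_qc(self._cohort(panel, lane))
        for sid in report.table.index:
            assert report.table.loc[sid, "excluded"] == bool(report.reasons[sid])

    def test_decisions_invariant_to_sample_order(self, panel):
        lanes = [make_lane(panel, sample_id=f"S{i}", base=70 + 11 * i) for i in range(4)]
        lanes[2] = dataclasses.replace(lanes[2], binding_density=2.5)
        a = lane_qc(matrix_from_lanes(panel, lanes))
        b = lane_qc(matrix_from_lanes(panel, lanes[::-1]))
        for sid in a.table.index:
            assert a.table.loc[sid, "excluded"] == b.table.loc[sid, "excluded"]


class TestFilterSamples:
    def test_excluded_columns_removed_order_preserved(self, panel):
        lanes = [make_lane(panel, sample_id=f"S{i}") for i in range(5)]
        lanes[1] = dataclasses.replace(lanes[1], fov_counted=100)
        matrix = matrix_from_lanes(panel, lanes)
        kept = filter_samples(matrix, lane_qc(matrix))
        assert list(kept.values.columns) == ["S0", "S2", "S3", "S4"]

    def test_no_exclusions_is_identity(self, panel):
        matrix = matrix_from_lanes(
            panel, [make_lane(panel, sample_id=f"S{i}") for i in range(3)]
        )
        kept = filter_samples(matrix, lane_qc(matrix))
        assert kept.values.equals(matrix.values)

    def test_all_excluded_raises(self, panel):
        lanes = [
            dataclasses.replace(make_lane(panel, sample_id=f"S{i}"), fov_counted=10)
            for i in range(3)
        ]
        matrix = matrix_from_lanes(panel, lanes)
        with pytest.raises(EmptyCohortError):
            filter_samples(matrix, lane_qc(matrix))
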