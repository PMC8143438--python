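"""Quadrant classification, motile fraction, histograms, aggregation, density."""

import numpy as np
import pytest
from scipy.stats import binomtest

from dermtrack.behaviour import (
    BehaviourSummary,
    Thresholds,
    cell_density,
    classify,
    motile_fraction,
    quadrant_percentages,
    summarize_behaviour,
    velocity_distribution,
)
from dermtrack.errors import ComputationError, ValidationError
from dermtrack.motility import TrackMetrics, metrics_table
from dermtrack.synthetic import SyntheticConfig, simulate_cohort


def metric(velocity, confinement, track_id="t", **metadata):
    path = 10.0
    return TrackMetrics(
        track_id=track_id,
        duration=path / velocity if velocity > 0 else 30.0,
        path_length=path,
        displacement=confinement * path,
        mean_velocity=velocity,
        confinement=confinement,
        n_points=31,
        metadata=metadata,
    )


class TestClassify:
    @pytest.mark.parametrize(
        "velocity,confinement,expected",
        [
            (1.0, 0.1, "Q1"),
            (1.0, 0.5, "Q2"),
            (3.0, 0.5, "Q3"),
            (3.0, 0.1, "Q4"),
            (2.0, 0.2, "Q3"),   # boundary values count as 'high'
            (2.0, 0.1, "Q4"),
            (1.99, 0.2, "Q2"),
        ],
    )
    def test_quadrant_assignment(self, velocity, confinement, expected):
        assert classify(metric(velocity, confinement)) == expected

    def test_partition_every_track_gets_exactly_one_label(self, rng):
        ms = [metric(v, c) for v, c in rng.uniform(0, 1, size=(200, 2)) * [8, 1]]
        pct = quadrant_percentages(ms)
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-6)
        assert all(p >= 0 for p in pct.values())

    def test_motile_fraction_equals_q3_plus_q4(self, rng):
        ms = [metric(v, c) for v, c in rng.uniform(0, 1, size=(150, 2)) * [6, 1]]
        pct = quadrant_percentages(ms)
        assert motile_fraction(ms) == pytest.approx(pct["Q3"] + pct["Q4"])

    def test_raising_velocity_is_monotone(self):
        # Q1 -> Q4 and Q2 -> Q3 are the only velocity-driven moves
        assert classify(metric(1.0, 0.1)) == "Q1"
        assert classify(metric(5.0, 0.1)) == "Q4"
        assert classify(metric(1.0, 0.5)) == "Q2"
        assert classify(metric(5.0, 0.5)) == "Q3"

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValidationError):
            Thresholds(velocity_threshold=-1.0)


class TestMotileFraction:
    def test_half_motile(self):
        ms = [metric(v, 0.5) for v in (1, 1, 3, 3)]
        assert motile_fraction(ms) == pytest.approx(50.0)

    def test_all_static(self):
        ms = [metric(0.0, 0.0) for _ in range(5)]
        assert motile_fraction(ms) == 0.0

    def test_empty_collection_errors(self):
        with pytest.raises(ComputationError):
            motile_fraction([])

    def test_recovers_simulated_mixture_weight(self):
        """A half-motile cohort estimate falls in the exact binomial interval."""
        config = SyntheticConfig(
            mixture_weights={"static": 0.5, "intermittent": 0.0,
                             "continuous": 0.5, "fast_confined": 0.0},
            n_tracks_per_fov=50, n_fov_per_mouse=2, n_mice=2, seed=11,
        )
        metrics, _ = metrics_table(simulate_cohort(config))
        assert len(metrics) == 200
        k = round(motile_fraction(metrics) / 100 * len(metrics))
        ci = binomtest(k, len(metrics)).proportion_ci(0.95, method="exact")
        assert ci.low <= 0.5 <= ci.high


class TestVelocityDistribution:
    def test_three_bins(self):
        ms = [metric(v, 0.5) for v in (0.5, 1.5, 2.5)]
        hist, median = velocity_distribution(ms, bin_width=1.0)
        np.testing.assert_allclose(hist["rel_freq"], [1 / 3, 1 / 3, 1 / 3])
        np.testing.assert_allclose(hist["bin_left"], [0, 1, 2])
        assert median == pytest.approx(1.5)

    def test_single_value(self):
        hist, median = velocity_distribution([metric(3.2, 0.5)], bin_width=0.5)
        assert hist["rel_freq"].sum() == pytest.approx(1.0)
        assert hist.loc[hist["rel_freq"] > 0, "bin_left"].tolist() == [3.0]
        assert median == pytest.approx(3.2)

    def test_matches_direct_counting_oracle(self, rng):
        v = rng.uniform(0, 10, size=1000)
        ms = [metric(x, 0.5) for x in v]
        hist, median = velocity_distribution(ms, bin_width=0.5)
        for _, row in hist.iterrows():
            expected = np.sum((v >= row.bin_left) & (v < row.bin_right)) / 1000
            assert row.rel_freq == pytest.approx(expected, abs=0)
        assert hist["rel_freq"].sum() == pytest.approx(1.0)
        assert median == pytest.approx(np.median(v))

    def test_empty_errors(self):
        with pytest.raises(ComputationError):
            velocity_distribution([])


class TestSummarizeBehaviour:
    def test_single_fov_percentages(self):
        ms = [
            metric(1, 0.1, mouse="m1", fov="f1"),
            metric(1, 0.1, mouse="m1", fov="f1"),
            metric(3, 0.5, mouse="m1", fov="f1"),
            metric(3, 0.1, mouse="m1", fov="f1"),
        ]
        (s,) = summarize_behaviour(ms, level="fov")
        assert s.quadrant_pct == pytest.approx(
            {"Q1": 50.0, "Q2": 0.0, "Q3": 25.0, "Q4": 25.0})
        assert s.motile_fraction == pytest.approx(50.0)

    def test_fov_to_mouse_averaging_order(self):
        ms = [metric(1, 0.1, mouse="m1", fov="f1") for _ in range(3)]
        ms += [metric(3, 0.5, mouse="m1", fov="f2")]
        (s,) = summarize_behaviour(ms, level="mouse")
        # fovs average with equal weight regardless of track counts
        assert s.quadrant_pct == pytest.approx(
            {"Q1": 50.0, "Q2": 0.0, "Q3": 50.0, "Q4": 0.0})

    def test_fov_level_then_manual_average_equals_mouse_level(self, rng):
        ms = []
        for fov in ("f1", "f2", "f3"):
            for i in range(10):
                v, c = rng.uniform(0, 6), rng.uniform(0, 1)
                ms.append(metric(v, c, track_id=f"{fov}{i}", mouse="m1", fov=fov))
        fov_summaries = summarize_behaviour(ms, level="fov")
        (mouse_summary,) = summarize_behaviour(ms, level="mouse")
        for q in ("Q1", "Q2", "Q3", "Q4"):
            manual = np.mean([s.quadrant_pct[q] for s in fov_summaries])
            assert mouse_summary.quadrant_pct[q] == pytest.approx(manual)

    def test_missing_metadata_names_track(self):
        ms = [metric(1, 0.1, track_id="orphan")]
        with pytest.raises(ValidationError, match="orphan"):
            summarize_behaviour(ms, level="mouse")

    def test_group_sem_over_mice(self):
        ms = []
        for mouse, v in (("m1", 3.0), ("m2", 1.0)):
            for i in range(4):
                ms.append(metric(v, 0.5, track_id=f"{mouse}{i}",
                                 mouse=mouse, fov="f1", group="g"))
        (s,) = summarize_behaviour(ms, level="group")
        # mice are 100% Q3 and 100% Q2: mean 50, SD 70.71, SEM 50
        assert s.quadrant_pct["Q3"] == pytest.approx(50.0)
        assert s.quadrant_sem["Q3"] == pytest.approx(50.0)
        assert s.n_units == 2

    def test_recovers_generative_phenotype_weights(self):
        """Group-level quadrant means recover the designed mixture weights."""
        weights = {"static": 0.2, "intermittent": 0.2,
                   "continuous": 0.4, "fast_confined": 0.2}
        config = SyntheticConfig(mixture_weights=weights, n_tracks_per_fov=25,
                                 n_fov_per_mouse=3, n_mice=4, seed=21)
        metrics, _ = metrics_table(simulate_cohort(config))
        (s,) = summarize_behaviour(metrics, level="group")
        # static -> Q1, continuous -> Q3, fast_confined -> Q4; intermittent
        # straddles Q1/Q2 so only its designed side is bounded loosely
        for q, w in (("Q1", 0.2), ("Q3", 0.4), ("Q4", 0.2)):
            sem = max(s.quadrant_sem[q], 1.0)
            assert abs(s.quadrant_pct[q] - 100 * w) <= 3 * sem + 10


class TestCellDensity:
    def test_unit_arithmetic(self):
        # 9 cells in 300x300x100 µm = 9e6 µm³ -> 1000 cells/mm³
        assert cell_density([9], 300 * 300 * 100) == pytest.approx(1000.0)

    def test_zero_cells(self):
        assert cell_density([0], 1e6) == 0.0

    def test_mean_over_regions(self):
        v = 1e7
        expected = np.mean([10 / v, 20 / v]) * 1e9
        assert cell_density([10, 20], v) == pytest.approx(expected)

    def test_invalid_volume(self):
        with pytest.raises(ValueError):
            cell_density([1], 0.0)
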