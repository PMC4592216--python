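"""Tests for the Information Space metrics, binned surfaces and rank statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hostswitch.analysis import (
    information_space,
    max_individual_distance,
    phase_diagram,
    population_metrics,
    spearman_partial,
    success_curve,
)


def _events(rows):
    """Event table from (generation, IS, distance, size, outcome) tuples."""
    return pd.DataFrame(
        [
            {
                "generation": g,
                "pre_switch_IS": i,
                "standardized_distance": d,
                "pre_switch_size": s,
                "outcome": o,
            }
            for g, i, d, s, o in rows
        ]
    )


class TestInformationSpace:
    def test_single_individual_has_no_amplitude(self):
        assert information_space([5.0], 0.5) == 0.0

    def test_known_value(self):
        assert information_space([4.5, 5.0, 5.5], 0.5) == pytest.approx(2.0)

    def test_translation_invariance(self):
        phen = np.array([4.1, 5.3, 6.0])
        assert information_space(phen + 7.0, 0.5) == pytest.approx(
            information_space(phen, 0.5)
        )

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            information_space([], 0.5)

    def test_scale_equivariance(self):
        phen = np.array([4.0, 5.0, 6.5])
        assert information_space(phen * 2, 1.0) == pytest.approx(
            information_space(phen, 0.5)
        )


class TestPopulationMetrics:
    def test_symmetric_population_centred_on_optimum(self):
        m = population_metrics([4.0, 6.0], 5.0, 0.5)
        assert (m.IS, m.midpoint_distance, m.max_distance) == (4.0, 0.0, 2.0)

    def test_hand_computed_asymmetric_case(self):
        m = population_metrics([5.2, 5.6, 6.0], 5.0, 0.5)
        assert m.IS == pytest.approx(1.6)
        assert m.midpoint_distance == pytest.approx(1.2)
        assert m.max_distance == pytest.approx(2.0)

    def test_translation_invariance(self):
        phen = np.array([4.7, 5.1, 5.9])
        a = population_metrics(phen, 5.0, 0.5)
        b = population_metrics(phen + 3.0, 8.0, 0.5)
        assert (a.IS, a.midpoint_distance, a.max_distance) == pytest.approx(
            (b.IS, b.midpoint_distance, b.max_distance)
        )

    def test_farthest_individual_variant(self):
        # p_max-based distance and farthest-individual distance differ
        # when the far tail lies below the optimum
        phen = [3.0, 5.2]
        assert population_metrics(phen, 5.0, 0.5).max_distance == pytest.approx(0.4)
        assert max_individual_distance(phen, 5.0, 0.5) == pytest.approx(4.0)


class TestSuccessCurve:
    def test_all_successes_give_unit_probability(self):
        ev = _events([(100, 0.5, d, 50, "success") for d in (0.1, 0.5, 1.2)])
        surface = success_curve(ev, "standardized_distance", 0.5, burn_in=50)
        probs = surface.probability[surface.attempts > 0]
        assert np.all(probs == 1.0)

    def test_counts_match_brute_force_tally(self):
        rows = [
            (60, 0.2, 0.05, 10, "success"),
            (70, 0.3, 0.12, 20, "failure"),
            (80, 0.8, 0.55, 30, "success"),
            (90, 1.2, 0.58, 40, "success"),
            (100, 2.0, 1.95, 50, "failure"),
            (40, 0.1, 0.07, 5, "success"),  # burn-in: excluded
        ]
        surface = success_curve(
            _events(rows), "standardized_distance", 0.5, burn_in=50
        )
        # brute-force recount over the kept events
        kept = [r for r in rows if r[0] > 50]
        for k, (lo, hi) in enumerate(
            zip(surface.bin_edges[0][:-1], surface.bin_edges[0][1:])
        ):
            in_bin = [r for r in kept if lo <= r[2] < hi]
            assert surface.attempts[k] == len(in_bin)
            assert surface.successes[k] == sum(r[4] == "success" for r in in_bin)
        assert surface.attempts.sum() == len(kept)

    def test_empty_bins_are_flagged_not_zero(self):
        ev = _events([(100, 0.5, 1.9, 50, "success")])
        surface = success_curve(ev, "standardized_distance", 0.5, burn_in=50)
        assert np.isnan(surface.probability[surface.attempts == 0]).all()

    def test_single_wide_bin_recovers_overall_fraction(self):
        rows = [(60 + i, 0.5, 0.3, 10, "success" if i % 3 else "failure")
                for i in range(12)]
        surface = success_curve(
            _events(rows), "standardized_distance", 1e9, burn_in=50
        )
        assert surface.probability[0] == pytest.approx(8 / 12)

    def test_pending_events_rejected(self):
        ev = _events([(100, 0.5, 0.3, 10, "pending")])
        with pytest.raises(ValueError, match="pending"):
            success_curve(ev, "standardized_distance", 0.5, burn_in=50)


class TestPhaseDiagram:
    def test_single_event_occupies_one_cell(self):
        ev = _events([(100, 0.35, 1.45, 10, "failure")])
        surface = phase_diagram(
            ev, "pre_switch_IS", "standardized_distance", (0.1, 0.1), burn_in=50
        )
        assert surface.attempts.sum() == 1
        occupied = surface.probability[surface.attempts > 0]
        assert occupied.shape == (1,) and occupied[0] == 0.0

    def test_cell_counts_match_brute_force(self):
        rng = np.random.default_rng(0)
        n = 400
        ev = pd.DataFrame(
            {
                "generation": rng.integers(51, 1000, n),
                "pre_switch_IS": rng.uniform(0, 3, n),
                "standardized_distance": rng.uniform(0, 3, n),
                "pre_switch_size": rng.integers(1, 500, n),
                "outcome": rng.choice(["success", "failure"], n),
            }
        )
        surface = phase_diagram(
            ev, "pre_switch_IS", "standardized_distance", (0.5, 0.5), burn_in=50
        )
        xe, ye = surface.bin_edges
        for i in range(len(xe) - 1):
            for j in range(len(ye) - 1):
                m = (
                    (ev.pre_switch_IS >= xe[i])
                    & (ev.pre_switch_IS < xe[i + 1])
                    & (ev.standardized_distance >= ye[j])
                    & (ev.standardized_distance < ye[j + 1])
                )
                assert surface.attempts[i, j] == m.sum()
                assert surface.successes[i, j] == (ev.outcome[m] == "success").sum()
        # totals conserved: every kept event lands in exactly one cell
        assert surface.attempts.sum() == len(ev)

    def test_long_format_table_roundtrip(self):
        ev = _events(
            [(100, 0.35, 1.45, 10, "failure"), (110, 0.8, 0.2, 20, "success")]
        )
        surface = phase_diagram(
            ev, "pre_switch_IS", "standardized_distance", (0.5, 0.5), burn_in=50
        )
        frame = surface.to_frame()
        assert frame["attempts"].sum() == 2
        assert set(frame.columns) >= {"attempts", "successes", "probability"}


class TestSpearmanPartial:
    def test_perfect_monotone_association(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 200)
        y = np.exp(x)  # strictly increasing transform
        z = rng.normal(size=200)
        assert spearman_partial(x, y, z) == pytest.approx(1.0, abs=0.05)

    def test_symmetry_in_first_two_arguments(self):
        rng = np.random.default_rng(2)
        x, y, z = rng.normal(size=(3, 50))
        assert spearman_partial(x, y, z) == pytest.approx(
            spearman_partial(y, x, z), abs=1e-12
        )

    def test_matches_rank_residual_regression_oracle(self):
        # independent route: regress rank(x) and rank(y) on rank(z),
        # then correlate the residuals
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3, 5.8])
        y = np.array([2.7, 1.8, 2.8, 1.2, 8.1, 2.9, 4.5, 9.0])
        z = np.array([1.0, 2.0, 1.5, 3.0, 2.5, 0.5, 4.0, 3.5])

        def residuals(a, b):
            ra, rb = stats.rankdata(a), stats.rankdata(b)
            slope = np.cov(ra, rb, bias=True)[0, 1] / np.var(rb)
            return ra - (ra.mean() + slope * (rb - rb.mean()))

        expected = np.corrcoef(residuals(x, z), residuals(y, z))[0, 1]
        assert spearman_partial(x, y, z) == pytest.approx(expected, abs=1e-12)

    def test_matches_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        z = rng.normal(size=120)
        x = z + rng.normal(size=120)
        y = 0.5 * z + rng.normal(size=120)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        assert spearman_partial(x, y, z) == pytest.approx(
            float(ref["r"].iloc[0]), abs=1e-10
        )

    def test_reduces_to_plain_spearman_without_confounding(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=500)
        y = x + rng.normal(size=500)
        z = rng.normal(size=500)  # independent of both
        plain = stats.spearmanr(x, y).statistic
        assert spearman_partial(x, y, z) == pytest.approx(plain, abs=0.05)

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_partial([1, 2, 3, 4], [1, 1, 1, 1], [4, 3, 2, 1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal-length"):
            spearman_partial([1, 2, 3], [1, 2], [1, 2, 3])
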