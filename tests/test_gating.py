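import numpy as np
import pandas as pd
import pytest

from dfmflow.gating import (
    COMBINED_CLASSES,
    GatingConfig,
    assign_colours,
    assign_combined,
    gate_bacteria,
    gate_singlets,
    run_gating,
    score_assignments,
)
from dfmflow.synthetic_data import (
    CHANNEL_BLUE,
    CHANNEL_RED,
    CHANNEL_YELLOW,
    simulate_events,
    simulate_mixture,
)

SEED = 3841


def chain_oracle(events, cfg):
    """Independent per-event evaluation of the stated gating predicates.

    Pure-Python, event by event, no vectorisation -- used to cross-check the
    production chain on small fixtures.  Assumes every event is in the
    bacteria gate (callers use density_fraction=1.0 with positive scatter).
    """
    results = []
    for _, ev in events.data.iterrows():
        singlet = ev["fsc"] > cfg.singlet_fsc_min and ev["ar_ssc"] > cfg.singlet_ar_min
        if not singlet:
            results.append("NotSinglet")
            continue
        r = ev[CHANNEL_RED] > 550.0
        y = ev[CHANNEL_YELLOW] > 500.0
        b = ev[CHANNEL_BLUE] > 450.0
        label = ("R" if r else "") + ("Y" if y else "") + ("B" if b else "")
        if label not in COMBINED_CLASSES:
            label = "Unassigned"
        results.append(label)
    return results


class TestGateBacteria:
    def test_fraction_one_retains_all(self, noise, spec_by_id):
        events = simulate_events(spec_by_id["R"], 2_000, noise=noise)
        labels = gate_bacteria(events, GatingConfig(density_fraction=1.0))
        assert labels["in_bacteria"].all()

    def test_two_cluster_separation(self, rng, tiny_table_factory):
        """95% tight 'cells' + 5% dispersed 'debris': the density gate keeps
        the cells and drops most of the debris."""
        n_cells, n_debris = 9_500, 500
        gen = np.random.default_rng(7)
        cells_fsc = gen.lognormal(np.log(2e4), np.log(1.05), n_cells)
        cells_ssc = gen.lognormal(np.log(1.5e4), np.log(1.05), n_cells)
        debris_fsc = gen.lognormal(np.log(100), np.log(3.0), n_debris)
        debris_ssc = gen.lognormal(np.log(100), np.log(3.0), n_debris)
        table = tiny_table_factory(
            {
                "fsc": np.concatenate([cells_fsc, debris_fsc]),
                "ssc": np.concatenate([cells_ssc, debris_ssc]),
                "ar_ssc": np.full(n_cells + n_debris, 0.8),
            }
        )
        labels = gate_bacteria(table, GatingConfig(density_fraction=0.95))
        kept = labels["in_bacteria"].to_numpy()
        assert kept[:n_cells].mean() >= 0.99
        assert kept[n_cells:].mean() <= 0.50

    def test_polygon_covering_range_equals_fraction_one(self, noise, spec_by_id):
        events = simulate_events(spec_by_id["Y"], 1_000, noise=noise)
        full = gate_bacteria(events, GatingConfig(density_fraction=1.0))
        poly = GatingConfig(
            bacteria_mode="polygon",
            polygon=[(-10, -10), (-10, 10), (10, 10), (10, -10)],
        )
        boxed = gate_bacteria(events, poly)
        assert (full["in_bacteria"] == boxed["in_bacteria"]).all()

    def test_nonpositive_scatter_warns_and_excludes(self, tiny_table_factory):
        table = tiny_table_factory(
            {"fsc": [0.0, 100.0, 200.0], "ssc": [10.0, 10.0, 10.0]}
        )
        with pytest.warns(UserWarning, match="non-positive"):
            labels = gate_bacteria(table, GatingConfig(density_fraction=1.0))
        assert not labels["in_bacteria"].iloc[0]
        assert labels["in_bacteria"].iloc[1:].all()

    def test_empty_input_rejected(self, tiny_table_factory):
        table = tiny_table_factory({"fsc": [], "ssc": [], "ar_ssc": []})
        with pytest.raises(ValueError, match="empty"):
            gate_bacteria(table)

    def test_invalid_density_fraction(self):
        with pytest.raises(ValueError):
            GatingConfig(density_fraction=0.0)


class TestGateSinglets:
    @pytest.mark.parametrize("ar, fsc, expected", [
        (0.4, 1.0, False),   # boundary: strict inequality on the 0.4 cut
        (0.41, 1.0, True),
        (0.8, 0.0, False),   # FSC threshold is strict > 0
    ])
    def test_boundaries(self, tiny_table_factory, ar, fsc, expected):
        table = tiny_table_factory({"fsc": [fsc], "ssc": [10.0], "ar_ssc": [ar]})
        labels = pd.DataFrame(
            {
                "in_bacteria": [True],  # isolate the singlet predicate
                "in_singlets": [False],
                "red": [False],
                "yellow": [False],
                "blue": [False],
                "combined": ["NotSinglet"],
            }
        )
        labels = gate_singlets(table, labels)
        assert labels["in_singlets"].iloc[0] == expected

    def test_doublets_excluded(self, spec_by_id):
        from dfmflow.synthetic_data import NoiseModel

        noise = NoiseModel(doublet_rate=0.3, debris_rate=0.0, seed=SEED)
        events = simulate_events(spec_by_id["R"], 2_000, noise=noise)
        labels = run_gating(events, GatingConfig(density_fraction=1.0))
        # every simulated doublet has ar_ssc < 0.4 and must be excluded
        doublet_like = events.data["ar_ssc"] < 0.4
        assert not labels.loc[doublet_like, "in_singlets"].any()
        assert doublet_like.mean() > 0.2


class TestAssignColours:
    def make_single_event(self, factory, red=0.0, yellow=0.0, blue=0.0):
        table = factory(
            {
                "fsc": [100.0],
                "ssc": [100.0],
                "ar_ssc": [0.9],
                CHANNEL_RED: [red],
                CHANNEL_YELLOW: [yellow],
                CHANNEL_BLUE: [blue],
            }
        )
        labels = gate_bacteria(table, GatingConfig(density_fraction=1.0))
        labels = gate_singlets(table, labels)
        return table, labels

    def test_above_threshold_positive(self, tiny_table_factory):
        table, labels = self.make_single_event(tiny_table_factory, red=600.0)
        labels = assign_colours(table, labels)
        assert labels["red"].iloc[0]

    def test_exact_threshold_negative(self, tiny_table_factory):
        table, labels = self.make_single_event(tiny_table_factory, red=550.0)
        labels = assign_colours(table, labels)
        assert not labels["red"].iloc[0]

    def test_mixed_intensities(self, tiny_table_factory):
        table, labels = self.make_single_event(
            tiny_table_factory, red=0.0, yellow=501.0, blue=451.0
        )
        labels = assign_colours(table, labels)
        assert not labels["red"].iloc[0]
        assert labels["yellow"].iloc[0]
        assert labels["blue"].iloc[0]

    def test_missing_channel_is_hard_error(self, tiny_table_factory):
        table, labels = self.make_single_event(tiny_table_factory)
        cfg = GatingConfig(
            colour_thresholds={"Red": ("999-999/99", 550.0)}
        )
        with pytest.raises(KeyError, match="999-999/99"):
            assign_colours(table, labels, cfg)


class TestAssignCombined:
    @pytest.mark.parametrize("flags, expected", [
        ((True, False, False), "R"),
        ((False, True, False), "Y"),
        ((False, False, True), "B"),
        ((True, True, False), "RY"),
        ((True, False, True), "RB"),
        ((False, True, True), "YB"),
        ((False, False, False), "Unassigned"),
        ((True, True, True), "Unassigned"),
    ])
    def test_all_eight_combinations(self, flags, expected):
        labels = pd.DataFrame(
            {
                "in_bacteria": [True],
                "in_singlets": [True],
                "red": [flags[0]],
                "yellow": [flags[1]],
                "blue": [flags[2]],
                "combined": ["NotSinglet"],
            }
        )
        assert assign_combined(labels)["combined"].iloc[0] == expected

    def test_non_singlet_untouched(self):
        labels = pd.DataFrame(
            {
                "in_bacteria": [True],
                "in_singlets": [False],
                "red": [False],
                "yellow": [False],
                "blue": [False],
                "combined": ["NotSinglet"],
            }
        )
        assert assign_combined(labels)["combined"].iloc[0] == "NotSinglet"


class TestScoreAssignments:
    def test_zero_noise_gives_perfect_accuracy(self, specs, quiet_noise):
        for spec in specs:
            events = simulate_events(spec, 500, noise=quiet_noise)
            labels = run_gating(events, GatingConfig(density_fraction=1.0))
            summary = score_assignments(labels, events.data["truth"])
            assert summary.overall_accuracy == 1.0
            assert summary.per_class_accuracy[spec.strain_id] == 1.0

    def test_hand_built_confusion_matrix(self, tiny_table_factory):
        """12 events with hand-chosen flags against a hand-counted matrix."""
        hi = {"R": 600.0, "Y": 600.0, "B": 600.0}
        rows = {
            "fsc": [100.0] * 12,
            "ssc": [100.0] * 12,
            "ar_ssc": [0.9] * 12,
            # truth R: 3 correct; 1 with stray blue -> RB
            # truth Y: 2 correct; 1 dark -> Unassigned
            # truth RB: 4 correct; 1 missing red -> B
            CHANNEL_RED: [hi["R"]] * 4 + [0.0] * 3 + [hi["R"]] * 4 + [0.0],
            CHANNEL_YELLOW: [0.0] * 4 + [hi["Y"]] * 2 + [0.0] * 6,
            CHANNEL_BLUE: [0.0] * 3 + [hi["B"]] + [0.0] * 3 + [hi["B"]] * 5,
        }
        truth = ["R"] * 4 + ["Y"] * 3 + ["RB"] * 5
        table = tiny_table_factory(rows, truth=truth)
        labels = run_gating(table, GatingConfig(density_fraction=1.0))
        summary = score_assignments(labels, truth)

        assert summary.matrix.loc["R", "R"] == 3
        assert summary.matrix.loc["R", "RB"] == 1
        assert summary.matrix.loc["Y", "Y"] == 2
        assert summary.matrix.loc["Y", "Unassigned"] == 1
        assert summary.matrix.loc["RB", "RB"] == 4
        assert summary.matrix.loc["RB", "B"] == 1
        assert summary.matrix.to_numpy().sum() == 12
        assert summary.per_class_accuracy["R"] == pytest.approx(3 / 4)
        assert summary.per_class_accuracy["RB"] == pytest.approx(4 / 5)
        assert summary.overall_accuracy == pytest.approx(9 / 12)

    def test_length_mismatch_rejected(self, specs, quiet_noise):
        events = simulate_events(specs[0], 10, noise=quiet_noise)
        labels = run_gating(events, GatingConfig(density_fraction=1.0))
        with pytest.raises(ValueError, match="truth"):
            score_assignments(labels, ["R"] * 5)


class TestChainInvariants:
    @pytest.fixture(scope="class")
    @staticmethod
    def mixture(specs):
        from dfmflow.synthetic_data import default_noise

        return simulate_mixture(
            specs, [1 / 6] * 6, 6_000, noise=default_noise(seed=SEED)
        )

    def test_partition(self, mixture):
        labels = run_gating(mixture)
        singlets = int(labels["in_singlets"].sum())
        assigned = labels.loc[labels["in_singlets"], "combined"]
        total = sum((assigned == c).sum() for c in COMBINED_CLASSES)
        total += (assigned == "Unassigned").sum()
        assert total == singlets

    def test_threshold_monotonicity(self, mixture):
        sizes = []
        for thr in (300.0, 450.0, 550.0, 700.0, 1_000.0):
            cfg = GatingConfig()
            cfg.colour_thresholds = dict(cfg.colour_thresholds)
            cfg.colour_thresholds["Red"] = (CHANNEL_RED, thr)
            labels = run_gating(mixture, cfg)
            sizes.append(int(labels["red"].sum()))
        assert sizes == sorted(sizes, reverse=True)

    def test_idempotence(self, mixture):
        a = run_gating(mixture)
        b = run_gating(mixture)
        pd.testing.assert_frame_equal(a, b)

    def test_oracle_equivalence_on_small_fixture(self, rng, tiny_table_factory):
        n = 20
        gen = np.random.default_rng(11)
        table = tiny_table_factory(
            {
                "fsc": gen.uniform(0.0, 1_000.0, n),
                "ssc": gen.uniform(1.0, 1_000.0, n),
                "ar_ssc": gen.uniform(0.0, 1.0, n),
                CHANNEL_RED: gen.uniform(0.0, 1_200.0, n),
                CHANNEL_YELLOW: gen.uniform(0.0, 1_200.0, n),
                CHANNEL_BLUE: gen.uniform(0.0, 1_200.0, n),
            }
        )
        cfg = GatingConfig(density_fraction=1.0)
        got = run_gating(table, cfg)["combined"].tolist()
        assert got == chain_oracle(table, cfg)
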