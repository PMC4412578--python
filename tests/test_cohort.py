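"""Cohort analytics: capacity, density, regions, stratification."""

import numpy as np
import pandas as pd
import pytest

from orbitpanel import (
    BinaryPanel,
    CompletenessError,
    DimensionError,
    Region,
    StratificationError,
    SubjectSeries,
    admissible_successors,
    capacity_table,
    density_table,
    encode_orbit,
    encode_panel,
    find_clusters,
    find_holes,
    fitness_label,
    group_proportion_by_fitness,
    index_to_state,
    population_change_frequencies,
    region_percentages,
    stratify,
    unfavourable_percentages,
)
from orbitpanel.simulate import PanelSpec, generate_panel

from conftest import random_panel


def panel_of(series_list) -> BinaryPanel:
    values = np.stack([s.answers for s in series_list])
    p, nt = series_list[0].answers.shape
    return BinaryPanel(
        values,
        [s.subject_id for s in series_list],
        [f"Q{i}" for i in range(p)],
        list(range(nt)),
    )


class TestCapacity:
    def test_single_orbit(self, demo):
        cap = capacity_table([encode_orbit(demo)])
        assert cap.counts.loc[24, 0] == 1
        assert cap.counts[0].sum() == 1
        assert cap.accumulated().to_dict() == {23: 2, 24: 3, 29: 1, 30: 2}
        assert cap.accumulated().sum() == 8  # n * (T+1)

    def test_conservation(self):
        rng = np.random.default_rng(5)
        orbits = encode_panel(random_panel(rng, n=40, p=4, T=7))
        cap = capacity_table(orbits)
        assert (cap.counts.sum(axis=0) == 40).all()

    def test_constant_ones_cohort_occupies_state_48(self):
        series = [
            SubjectSeries(f"s{i}", np.ones((3, 5), dtype=int)) for i in range(100)
        ]
        cap = capacity_table(encode_panel(panel_of(series)))
        assert (cap.counts.loc[48] == 100).all()
        assert cap.counts.shape == (1, 5)

    def test_mixed_dimensions_rejected(self, demo, trio):
        with pytest.raises(DimensionError):
            capacity_table([encode_orbit(demo), encode_orbit(trio["trio_a"])])

    def test_reporting_filter_leaves_table(self, demo):
        cap = capacity_table([encode_orbit(demo)])
        assert set(cap.filtered(1).index) == {23, 24, 29, 30}
        assert cap.filtered(2).empty  # one orbit: c[s, t] <= 1 everywhere
        assert cap.counts.shape == (4, 8)  # stored table untouched


class TestDensity:
    def test_single_orbit_counts(self, demo):
        den = density_table([encode_orbit(demo)])
        d = {
            (r.from_index, r.to_index): r.count for r in den.edges.itertuples()
        }
        assert d == {
            (24, 24): 1, (24, 23): 2, (23, 29): 1,
            (29, 30): 1, (30, 30): 1, (30, 24): 1,
        }
        assert den.total == 7  # n * T

    def test_empty_cohort(self):
        assert density_table([]).edges.empty

    def test_conservation_and_admissibility(self):
        rng = np.random.default_rng(11)
        orbits = encode_panel(random_panel(rng, n=25, p=3, T=6))
        den = density_table(orbits)
        assert den.total == 25 * 6
        for r in den.edges.itertuples():
            s = index_to_state(r.from_index, 3)
            succ = {x.index for x in admissible_successors(s)}
            assert r.to_index in succ

    def test_idle_edges_are_blue(self, demo):
        den = density_table([encode_orbit(demo)])
        idle = den.edges[den.edges.from_index == den.edges.to_index]
        assert set(idle["color"]) == {"blue"}


class TestRegionPercentages:
    def test_depth1_sums_to_100(self):
        rng = np.random.default_rng(3)
        orbits = encode_panel(random_panel(rng, n=30, p=4, T=5))
        table = region_percentages(orbits, depth=1)
        assert table["percent"].sum() == pytest.approx(100.0)
        assert len(table) == 2 * 4

    def test_depth2_nests_in_depth1(self):
        rng = np.random.default_rng(4)
        orbits = encode_panel(random_panel(rng, n=20, p=3, T=6))
        d1 = region_percentages(orbits, depth=1)
        d2 = region_percentages(orbits, depth=2)
        for r in d1.itertuples():
            nested = d2[
                d2["sig_prefix"].str.startswith(r.sig_prefix)
                & d2["fit_prefix"].str.startswith(r.fit_prefix)
            ]
            assert nested["percent"].sum() == pytest.approx(r.percent)

    def test_single_constant_subject(self):
        s = SubjectSeries("c", np.ones((3, 4), dtype=int))
        table = region_percentages([encode_orbit(s)], depth=1)
        hit = table[table["visits"] > 0]
        assert len(hit) == 1
        assert hit["percent"].iloc[0] == pytest.approx(100.0)

    def test_depth_beyond_p(self, demo):
        with pytest.raises(DimensionError):
            region_percentages([encode_orbit(demo)], depth=4)


class TestHolesAndClusters:
    def test_always_flipping_variable_makes_holes(self):
        """A variable that changes every step never leads the order
        (unless every variable changes at once), so both of its depth-1
        regions are holes."""
        rng = np.random.default_rng(9)
        values = np.empty((50, 3, 7), dtype=int)
        values[:, :, 0] = rng.integers(0, 2, size=(50, 3))
        flip0 = rng.random((50, 6)) < 0.3
        flip1 = (rng.random((50, 6)) < 0.3) & ~flip0  # never both at once
        for t in range(6):
            values[:, 0, t + 1] = values[:, 0, t] ^ flip0[:, t]
            values[:, 1, t + 1] = values[:, 1, t] ^ flip1[:, t]
        values[:, 2, :] = np.arange(7) % 2  # variable 2 alternates
        panel = BinaryPanel(
            values, [f"s{i}" for i in range(50)], ["Q0", "Q1", "Q2"], list(range(7))
        )
        holes = find_holes(encode_panel(panel))
        assert Region((2,), (0,)) in holes
        assert Region((2,), (1,)) in holes

    def test_single_constant_subject_one_full_cluster(self):
        s = SubjectSeries("c", np.zeros((3, 5), dtype=int))
        clusters = find_clusters([encode_orbit(s)])
        assert clusters == {Region((0,), (0,)): pytest.approx(1.0)}

    def test_planted_stable_favourable_cluster(self):
        spec = PanelSpec(
            n=150, p=4, T=6, pi=(1.0, 0.5, 0.5, 0.5), phi=(0.0, 0.3, 0.3, 0.5), seed=21
        )
        panel, _ = generate_panel(spec)
        clusters = find_clusters(encode_panel(panel), min_share=0.10)
        assert set(clusters) == {Region((0,), (1,))}
        assert clusters[Region((0,), (1,))] == pytest.approx(1.0)


class TestPanelSummaries:
    def test_unfavourable_demo(self, demo):
        panel = panel_of([demo])
        pct = unfavourable_percentages(panel)
        assert pct["Q0"] == pytest.approx(62.5)  # 5 zeros of 8
        assert pct["Q1"] == pytest.approx(0.0)

    def test_all_ones(self):
        panel = panel_of([SubjectSeries("a", np.ones((2, 3), dtype=int))])
        assert (unfavourable_percentages(panel) == 0).all()

    def test_population_frequencies_two_copies(self, demo):
        twin = SubjectSeries("demo2", demo.answers.copy())
        panel = panel_of([demo, twin])
        assert population_change_frequencies(panel).tolist() == [6, 0, 4]

    def test_invariant_under_subject_reordering(self):
        rng = np.random.default_rng(7)
        panel = random_panel(rng, n=12, p=3, T=4)
        shuffled = panel.subset(list(reversed(panel.subject_ids)))
        pd.testing.assert_series_equal(
            unfavourable_percentages(panel), unfavourable_percentages(shuffled)
        )
        pd.testing.assert_series_equal(
            population_change_frequencies(panel),
            population_change_frequencies(shuffled),
        )


class TestStratify:
    def test_planted_split(self):
        rng = np.random.default_rng(13)
        panel = random_panel(rng, n=100, p=3, T=4)
        labels = {
            sid: ("north" if i < 60 else "south")
            for i, sid in enumerate(panel.subject_ids)
        }
        strata = stratify(panel, labels)
        assert {k: v.n for k, v in strata.items()} == {"north": 60, "south": 40}
        assert sum(s.n for s in strata.values()) == panel.n

    def test_single_stratum_identity(self):
        rng = np.random.default_rng(14)
        panel = random_panel(rng, n=5, p=2, T=3)
        strata = stratify(panel, {s: "all" for s in panel.subject_ids})
        assert list(strata) == ["all"]
        assert np.array_equal(strata["all"].values, panel.values)

    def test_multi_attribute_labels(self):
        rng = np.random.default_rng(15)
        panel = random_panel(rng, n=4, p=2, T=2)
        frame = pd.DataFrame(
            {"nation": ["SA", "SA", "MOZ", "MOZ"], "rich": [1, 0, 1, 0]},
            index=pd.Index(panel.subject_ids, name="subject_id"),
        )
        strata = stratify(panel, frame)
        assert set(strata) == {"SA/1", "SA/0", "MOZ/1", "MOZ/0"}

    def test_unlabelled_subject_rejected(self):
        rng = np.random.default_rng(16)
        panel = random_panel(rng, n=3, p=2, T=2)
        with pytest.raises(StratificationError):
            stratify(panel, {panel.subject_ids[0]: "x"})


class TestFitnessLabels:
    @pytest.mark.parametrize(
        "bits, label",
        [((0, 0, 0, 0, 0), 1), ((0, 0, 1, 1, 1), 8), ((1, 1, 1, 1, 1), 32)],
    )
    def test_labels(self, bits, label):
        assert fitness_label(bits) == label


class TestGroupProportions:
    def test_all_flagged(self):
        rng = np.random.default_rng(17)
        panel = random_panel(rng, n=10, p=3, T=3)
        table = group_proportion_by_fitness(panel, {s: 1 for s in panel.subject_ids})
        occupied = table.to_numpy()[~np.isnan(table.to_numpy())]
        assert (occupied == 1.0).all()

    def test_absent_cells_are_nan(self):
        panel = panel_of([SubjectSeries("a", np.ones((2, 2), dtype=int))])
        table = group_proportion_by_fitness(panel, {"a": 1})
        assert list(table.index) == [4]  # only label 4 = (1,1) occupied
        assert not table.isna().any().any()

    def test_planted_mix_recovered(self):
        rng = np.random.default_rng(18)
        n = 400
        values = np.ones((n, 3, 2), dtype=int)
        flags = {f"s{i}": int(rng.random() < 0.7) for i in range(n)}
        panel = BinaryPanel(
            values, list(flags), ["Q0", "Q1", "Q2"], [0, 1]
        )
        table = group_proportion_by_fitness(panel, flags)
        expected = np.mean(list(flags.values()))
        assert table.loc[8, 0] == pytest.approx(expected)
        assert abs(table.loc[8, 0] - 0.7) < 3 * np.sqrt(0.7 * 0.3 / n)

    def test_flag_missing_subject(self):
        panel = panel_of([SubjectSeries("a", np.ones((2, 2), dtype=int))])
        with pytest.raises(CompletenessError):
            group_proportion_by_fitness(panel, {})
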