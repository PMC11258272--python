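"""Double-positive detection, region densities, heat maps and voxel tests."""

import numpy as np
import pandas as pd
import pytest

from sleepmap import cellmap as cm
from sleepmap import synthetic as syn


def simple_ontology(extra=None):
    rows = [
        {"acronym": "root", "parent": "", "volume_mm3": 0.0},
        {"acronym": "ISO", "parent": "root", "volume_mm3": 1.0},
        {"acronym": "CB", "parent": "root", "volume_mm3": 1.0},
    ]
    if extra:
        rows += extra
    return cm.Ontology(pd.DataFrame(rows))


def brain_from_points(points, brain_id="b0", group="S", ontology=None):
    """points: list of (x, y, z, channel, region)."""
    cells = pd.DataFrame(
        [
            {"x_um": x, "y_um": y, "z_um": z, "intensity": 1.0,
             "channel": ch, "region": reg}
            for x, y, z, ch, reg in points
        ],
        columns=cm.CELL_COLUMNS,
    )
    return cm.BrainCellTable(
        cells=cells, brain_id=brain_id, group=group,
        ontology=ontology or simple_ontology(),
    )


class TestDoublePositive:
    @pytest.mark.parametrize("bx, expected", [(10.0, True), (20.0, False)])
    def test_distance_threshold(self, bx, expected):
        brain = brain_from_points(
            [(0, 0, 0, "A", "ISO"), (bx, 0, 0, "B", "ISO")]
        )
        out = cm.double_positive(brain, "A", "B", cm.ColocParams(radius_um=16.0))
        assert bool(out["double_positive"].iloc[0]) is expected

    def test_empty_reference_valid_zero_flags(self):
        brain = brain_from_points([(0, 0, 0, "A", "ISO")])
        out = cm.double_positive(brain, "A", "B")
        assert len(out) == 1 and not out["double_positive"].any()

    def test_excluded_regions_dropped_first(self):
        brain = brain_from_points(
            [(0, 0, 0, "A", "CB"), (5, 0, 0, "B", "CB"), (100, 0, 0, "A", "ISO")]
        )
        out = cm.double_positive(brain, "A", "B")
        assert list(out["region"]) == ["ISO"]
        assert not out["double_positive"].any()

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(5):
            q = rng.uniform(0, 500, (400, 3))
            r = rng.uniform(0, 500, (400, 3))
            flags = cm._grid_radius_flags(q, r, 16.0)
            d2 = ((q[:, None, :] - r[None, :, :]) ** 2).sum(-1)
            brute = (d2 <= 16.0**2).any(axis=1)
            assert np.array_equal(flags, brute)

    def test_flag_set_nondecreasing_in_radius(self, rng):
        q = rng.uniform(0, 300, (300, 3))
        r = rng.uniform(0, 300, (300, 3))
        previous = np.zeros(len(q), dtype=bool)
        for radius in (5.0, 10.0, 16.0, 40.0):
            flags = cm._grid_radius_flags(q, r, radius)
            assert np.all(flags | ~previous)  # previous set contained in new
            previous = flags

    def test_self_comparison_flags_everything(self, rng):
        pts = [(x, y, z, "A", "ISO") for x, y, z in rng.uniform(0, 100, (50, 3))]
        brain = brain_from_points(pts)
        out = cm.double_positive(brain, "A", "A", cm.ColocParams(radius_um=0.5))
        assert out["double_positive"].all()


class TestNativeRadius:
    def test_values(self):
        assert cm.native_radius(cm.ColocParams(16.0, 1.0)) == pytest.approx(16.0)
        assert cm.native_radius(cm.ColocParams(16.0, 1.5)) == pytest.approx(10.67, abs=0.01)
        assert cm.native_radius(cm.ColocParams(15.0, 1.5)) == pytest.approx(10.0)

    def test_factor_below_one_rejected(self):
        with pytest.raises(ValueError):
            cm.ColocParams(16.0, 0.9)


class TestRegionDensity:
    def test_count_over_volume(self, rng):
        pts = [(x, y, z, "A", "ISO") for x, y, z in rng.uniform(0, 100, (100, 3))]
        ontology = simple_ontology()
        ontology.table.loc[ontology.table["acronym"] == "ISO", "volume_mm3"] = 0.5
        brain = brain_from_points(pts, ontology=cm.Ontology(ontology.table))
        assert cm.region_density(brain, "A", ["ISO"])["ISO"] == pytest.approx(200.0)

    def test_empty_region_zero(self):
        brain = brain_from_points([(0, 0, 0, "A", "ISO")])
        assert cm.region_density(brain, "A", ["CB"])["CB"] == 0.0

    def test_ontology_closure_child_counts_sum_to_parent(self, rng):
        extra = [
            {"acronym": "ISO-a", "parent": "ISO", "volume_mm3": 0.5},
            {"acronym": "ISO-b", "parent": "ISO", "volume_mm3": 0.5},
        ]
        ontology = simple_ontology(extra)
        pts = [
            (x, y, z, "A", rng.choice(["ISO-a", "ISO-b", "ISO"]))
            for x, y, z in rng.uniform(0, 100, (60, 3))
        ]
        brain = brain_from_points(pts, ontology=ontology)
        counts = cm.region_counts(brain, "A")
        leaf = brain.cells["region"].value_counts()
        assert counts["ISO"] == leaf.get("ISO", 0) + leaf.get("ISO-a", 0) + leaf.get("ISO-b", 0)
        assert counts["root"] == len(brain.cells)


class TestNormalizedGroupDensity:
    def test_planted_increase_recovered(self):
        scen = syn.CellMapScenario(
            regions=[syn.RegionSpec("ISO", 2.0, {"PV": 2000.0})],
            coloc_channels=None,
        )
        control, _ = syn.simulate_cell_map_group(scen, n_brains=6, seed=41, group="S")
        boosted = syn.CellMapScenario(
            regions=[syn.RegionSpec("ISO", 2.0, {"PV": 2000.0})],
            coloc_channels=None,
            density_multipliers={"ISO": 1.5},
        )
        test, _ = syn.simulate_cell_map_group(boosted, n_brains=6, seed=42, group="SD")
        ratios = cm.normalized_group_density(test, control, "PV", ["ISO"])
        assert ratios.loc["ISO"].mean() == pytest.approx(1.5, abs=0.1)

    def test_equal_groups_near_one(self):
        scen = syn.CellMapScenario(
            regions=[syn.RegionSpec("ISO", 2.0, {"PV": 2000.0})],
            coloc_channels=None,
        )
        a, _ = syn.simulate_cell_map_group(scen, n_brains=6, seed=43)
        b, _ = syn.simulate_cell_map_group(scen, n_brains=6, seed=44)
        ratios = cm.normalized_group_density(b, a, "PV", ["ISO"])
        assert ratios.loc["ISO"].mean() == pytest.approx(1.0, abs=0.1)


class TestRatesAndPPV:
    def test_rate_arithmetic(self):
        # 2 A-cells, one near a B-cell; 3 B-cells
        brain = brain_from_points(
            [
                (0, 0, 0, "A", "ISO"),
                (1000, 0, 0, "A", "ISO"),
                (5, 0, 0, "B", "ISO"),
                (2000, 0, 0, "B", "ISO"),
                (3000, 0, 0, "B", "ISO"),
            ]
        )
        rates = cm.double_positive_rates(brain, "A", "B")
        overall = rates.loc["overall"]
        assert overall["rate_in_query"] == pytest.approx(0.5)
        assert overall["rate_in_ref"] == pytest.approx(1 / 3)

    def test_disjoint_channels_zero(self):
        brain = brain_from_points(
            [(0, 0, 0, "A", "ISO"), (10000, 0, 0, "B", "ISO")]
        )
        rates = cm.double_positive_rates(brain, "A", "B")
        assert rates.loc["overall", "rate_in_query"] == 0.0

    def test_empty_denominator_nan(self):
        brain = brain_from_points([(0, 0, 0, "B", "ISO")])
        rates = cm.double_positive_rates(brain, "A", "B")
        assert np.isnan(rates.loc["overall", "rate_in_query"])

    def test_ppv_identical_point_sets(self, rng):
        pts = rng.uniform(0, 200, (40, 3))
        points = [(x, y, z, "mCherry", "ISO") for x, y, z in pts]
        points += [(x, y, z, "PV", "ISO") for x, y, z in pts]
        brain = brain_from_points(points)
        assert cm.ppv(brain, "mCherry", "PV") == pytest.approx(1.0)

    def test_ppv_no_labeled_cells_nan(self):
        brain = brain_from_points([(0, 0, 0, "PV", "ISO")])
        assert np.isnan(cm.ppv(brain, "mCherry", "PV"))


class TestRegionHeatmap:
    @staticmethod
    def _groups(multiplier, seed_a=51, seed_b=52):
        scen = syn.CellMapScenario(
            regions=[
                syn.RegionSpec("ISO-a", 1.0, {"PV": 3000.0}),
                syn.RegionSpec("ISO-b", 1.0, {"PV": 3000.0}),
            ],
            coloc_channels=None,
        )
        planted = syn.CellMapScenario(
            regions=scen.regions,
            coloc_channels=None,
            density_multipliers={"ISO-b": multiplier},
        )
        a, _ = syn.simulate_cell_map_group(scen, n_brains=6, seed=seed_a, group="A")
        b, _ = syn.simulate_cell_map_group(planted, n_brains=6, seed=seed_b, group="B")
        return a, b

    def test_identical_groups_ratio_one(self):
        a, b = self._groups(1.0)
        heat = cm.region_heatmap(a, b, "PV", ["ISO-a", "ISO-b"])
        assert np.allclose(heat["ratio"], 1.0, atol=0.1)

    def test_planted_doubling_flagged(self):
        a, b = self._groups(2.0)
        heat = cm.region_heatmap(a, b, "PV", ["ISO-a", "ISO-b"])
        assert heat.loc["ISO-b", "ratio"] == pytest.approx(2.0, abs=0.25)
        assert heat.loc["ISO-b", "significant"]
        assert not heat.loc["ISO-a", "significant"]

    def test_ratios_invariant_to_brain_order(self):
        a, b = self._groups(2.0)
        heat1 = cm.region_heatmap(a, b, "PV", ["ISO-b"])
        heat2 = cm.region_heatmap(a[::-1], b[::-1], "PV", ["ISO-b"])
        assert heat1.loc["ISO-b", "ratio"] == heat2.loc["ISO-b", "ratio"]

    def test_single_brain_groups_refuse_significance(self):
        a, b = self._groups(2.0)
        heat = cm.region_heatmap(a[:1], b[:1], "PV", ["ISO-a"])
        assert np.isfinite(heat.loc["ISO-a", "ratio"])
        assert np.isnan(heat.loc["ISO-a", "p_value"])


class TestVoxelwise:
    def test_planted_focal_drop_flagged_decrease(self, rng):
        side = 600.0
        ontology = simple_ontology()

        def brain(drop, brain_id, seed):
            r = np.random.default_rng(seed)
            pts = r.uniform(0, side, (4000, 3))
            if drop:
                # empty out the voxel-aligned cube [150, 300)^3
                inside = np.all((pts >= 150.0) & (pts < 300.0), axis=1)
                pts = pts[~inside]
            return brain_from_points(
                [(x, y, z, "A", "ISO") for x, y, z in pts],
                brain_id=brain_id, ontology=ontology,
            )

        group_a = [brain(False, f"a{i}", 100 + i) for i in range(4)]
        group_b = [brain(True, f"b{i}", 200 + i) for i in range(4)]
        res = cm.voxelwise_test(group_a, group_b, "A", voxel_um=150.0)
        assert res.direction[1, 1, 1] == -1

    def test_identical_groups_all_masked(self, rng):
        pts = rng.uniform(0, 500, (1000, 3))
        points = [(x, y, z, "A", "ISO") for x, y, z in pts]
        a = [brain_from_points(points, brain_id=f"a{i}") for i in range(3)]
        b = [brain_from_points(points, brain_id=f"b{i}") for i in range(3)]
        res = cm.voxelwise_test(a, b, "A", voxel_um=100.0)
        assert not res.valid.any()

    def test_fdr_switch_never_lowers_pvalues(self, rng):
        def brain(brain_id, seed):
            r = np.random.default_rng(seed)
            pts = r.uniform(0, 500, (2000, 3))
            return brain_from_points(
                [(x, y, z, "A", "ISO") for x, y, z in pts], brain_id=brain_id
            )

        a = [brain(f"a{i}", 300 + i) for i in range(3)]
        b = [brain(f"b{i}", 400 + i) for i in range(3)]
        raw = cm.voxelwise_test(a, b, "A", voxel_um=100.0)
        adj = cm.voxelwise_test(a, b, "A", voxel_um=100.0, fdr=True)
        sel = raw.valid
        assert np.all(adj.p_value[sel] >= raw.p_value[sel] - 1e-12)

    def test_too_few_brains_rejected(self):
        brain = brain_from_points([(0, 0, 0, "A", "ISO")])
        with pytest.raises(ValueError):
            cm.voxelwise_test([brain], [brain, brain], "A")
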