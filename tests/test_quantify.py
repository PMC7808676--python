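import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytoshell.io_config import CellRecord, VoxelGrid3D
from cytoshell.quantify import (
    NoSignalError,
    PunctaMask,
    manders_overlap,
    nearest_rank_threshold,
    quantify_cell,
    regional_enrichment,
    threshold_puncta,
    ventral_dorsal_ratio,
)
from cytoshell.regionalize import REGION_NAMES, RegionPartition, split_halves
from cytoshell.segmentation import CellMask
from cytoshell.synthetic_data import SimulationSpec, simulate_cell


def make_partition(label_1d, shape=None):
    """RegionPartition from a flat list of codes (0=bg, 1..3=shells)."""
    label = np.asarray(label_1d, dtype=np.uint8)
    if shape is None:
        shape = (1, 1, label.size)
    return RegionPartition(label=label.reshape(shape), boundaries=(1.0, 3.0), spacing=(1, 1, 1))


def puncta_from(flags, partition, name="a"):
    member = np.asarray(flags, bool).reshape(partition.label.shape)
    return PunctaMask(member=member, spacing=partition.spacing, source_channel=name)


def random_config(rng, n=200):
    """Random partition + nested puncta masks for property checks."""
    label = rng.integers(1, 4, size=n).astype(np.uint8)
    label[rng.random(n) < 0.2] = 0
    if not (label > 0).any():
        label[0] = 1
    part = make_partition(label)
    cell = label > 0
    a = cell & (rng.random(n) < 0.4).reshape(part.label.shape).ravel()
    b = cell & (rng.random(n) < 0.4).reshape(part.label.shape).ravel()
    return part, puncta_from(a, part), puncta_from(b, part)


class TestNearestRankThreshold:
    def test_count_oracle_distinct_values(self, rng):
        values = rng.permutation(10_000).astype(float)
        t = nearest_rank_threshold(values, 95.0)
        # oracle: threshold is the ceil(0.95 n)-th order statistic,
        # strictly-above count is n - that rank
        assert t == sorted(values)[math.ceil(0.95 * 10_000) - 1]
        assert (values > t).sum() == 10_000 - math.ceil(0.95 * 10_000)

    @given(n=st.integers(2, 500), pct=st.floats(1.0, 99.0))
    @settings(max_examples=50, deadline=None)
    def test_matches_sorted_rank(self, n, pct):
        rng = np.random.default_rng(n)
        values = rng.random(n)
        assert nearest_rank_threshold(values, pct) == sorted(values)[
            max(1, math.ceil(pct / 100 * n)) - 1
        ]

    def test_bad_percentile(self):
        with pytest.raises(ValueError):
            nearest_rank_threshold(np.arange(5.0), 0.0)
        with pytest.raises(ValueError):
            nearest_rank_threshold(np.arange(5.0), 100.0)


class TestThresholdPuncta:
    def _cell(self, values, spacing=(1.0, 1.0, 1.0)):
        grid = VoxelGrid3D(values, spacing)
        return grid, CellMask(np.ones(grid.shape, bool), spacing)

    def test_puncta_fraction_95(self, rng):
        values = rng.permutation(10_000).astype(float).reshape(10, 100, 10)
        grid, mask = self._cell(values)
        puncta = threshold_puncta(grid, mask, sigma_um=0.0, percentile=95.0)
        assert abs(puncta.count - 500) <= 1

    def test_constant_intensity_empty_with_warning(self):
        grid, mask = self._cell(np.full((4, 4, 4), 9.0))
        puncta = threshold_puncta(grid, mask, sigma_um=0.0)
        assert puncta.count == 0

    def test_no_smoothing_delta_spike(self):
        values = np.zeros((4, 6, 6))
        values[2, 3, 3] = 50.0
        grid, mask = self._cell(values)
        puncta = threshold_puncta(grid, mask, sigma_um=0.0, percentile=95.0)
        assert puncta.count == 1 and puncta.member[2, 3, 3]

    def test_restricted_to_mask(self, rng):
        values = rng.random((4, 6, 6)) * 100
        grid = VoxelGrid3D(values, (1, 1, 1))
        member = np.zeros(grid.shape, bool)
        member[1:3, 1:5, 1:5] = True
        mask = CellMask(member, (1, 1, 1))
        puncta = threshold_puncta(grid, mask, sigma_um=0.0)
        assert not puncta.member[~member].any()

    def test_empty_mask_errors(self):
        grid = VoxelGrid3D(np.ones((3, 3, 3)), (1, 1, 1))
        with pytest.raises(ValueError):
            threshold_puncta(grid, CellMask(np.zeros((3, 3, 3), bool), (1, 1, 1)))


class TestRegionalEnrichment:
    def test_uniform_density_is_one(self):
        part = make_partition([1] * 20 + [2] * 30 + [3] * 50)
        # one punctum per 10 voxels in every region
        flags = ([True] + [False] * 9) * 10
        res = regional_enrichment(puncta_from(flags, part), part)
        for name in REGION_NAMES:
            assert res.enrichment[name] == pytest.approx(1.0)

    def test_printed_formula_arithmetic(self):
        # V_cell=1000, V_region=(200,300,500), V_in_region=(30,10,10)
        label = [1] * 200 + [2] * 300 + [3] * 500
        flags = [True] * 30 + [False] * 170 + [True] * 10 + [False] * 290 + [True] * 10 + [False] * 490
        res = regional_enrichment(puncta_from(flags, make_partition(label)), make_partition(label))
        assert res.enrichment["membrane"] == pytest.approx(3.0)
        assert res.enrichment["peripheral"] == pytest.approx(10 / 300 / (50 / 1000))
        assert res.enrichment["deep"] == pytest.approx(0.4)

    def test_all_in_membrane_shell(self):
        label = [1] * 20 + [2] * 30 + [3] * 50
        flags = [True] * 20 + [False] * 80
        res = regional_enrichment(puncta_from(flags, make_partition(label)), make_partition(label))
        assert res.enrichment["membrane"] == pytest.approx(5.0)
        assert res.enrichment["peripheral"] == 0.0
        assert res.enrichment["deep"] == 0.0

    def test_no_signal_errors(self):
        part = make_partition([1, 2, 3])
        with pytest.raises(NoSignalError):
            regional_enrichment(puncta_from([False] * 3, part), part)

    def test_empty_region_is_nan(self):
        part = make_partition([1, 1, 2, 2])  # no deep voxels
        res = regional_enrichment(puncta_from([True, False, False, False], part), part)
        assert math.isnan(res.enrichment["deep"])

    def test_puncta_outside_cell_rejected(self):
        part = make_partition([1, 1, 0, 0])
        with pytest.raises(ValueError):
            regional_enrichment(puncta_from([True, False, True, False], part), part)

    def test_conservation_property(self):
        # sum_region E * V_region == V_cell (100 random configurations)
        rng = np.random.default_rng(77)
        for _ in range(100):
            part, a, _ = random_config(rng)
            if a.count == 0:
                continue
            res = regional_enrichment(a, part)
            total = sum(
                res.enrichment[name] * res.region_counts[name]
                for name in REGION_NAMES
                if res.region_counts[name] > 0
            )
            assert total == pytest.approx(res.cell_count, rel=1e-9)

    def test_whole_cell_enrichment_is_one(self, rng):
        part = make_partition([1] * 50)
        flags = rng.random(50) < 0.3
        if not flags.any():
            flags[0] = True
        res = regional_enrichment(puncta_from(flags, part), part)
        assert res.enrichment["membrane"] == pytest.approx(1.0)


class TestMandersOverlap:
    def test_identity(self, rng):
        part, a, _ = random_config(rng)
        res = manders_overlap(a, a, part)
        assert res.moc_cell == pytest.approx(1.0)
        for name in REGION_NAMES:
            if res.a_counts[name] > 0:
                assert res.moc_region[name] == pytest.approx(1.0)

    def test_disjoint(self):
        part = make_partition([1] * 10 + [2] * 10 + [3] * 10)
        a = puncta_from([True] * 5 + [False] * 25, part)
        b = puncta_from([False] * 5 + [True] * 5 + [False] * 20, part)
        res = manders_overlap(a, b, part)
        assert res.moc_cell == 0.0

    def test_asymmetry(self):
        part = make_partition([1] * 200)
        a = puncta_from([True] * 100 + [False] * 100, part)
        b = puncta_from([False] * 75 + [True] * 50 + [False] * 75, part)
        assert manders_overlap(a, b, part).moc_cell == pytest.approx(0.25)
        assert manders_overlap(b, a, part).moc_cell == pytest.approx(0.5)

    def test_empty_denominator_flagged_nan(self):
        part = make_partition([1, 2, 3])
        a = puncta_from([True, False, False], part)
        b = puncta_from([True, True, False], part)
        res = manders_overlap(a, b, part)
        assert math.isnan(res.moc_region["peripheral"])

    def test_decomposition_property(self):
        # moc_cell == sum_region (V_A,region / V_A,cell) * moc_region
        rng = np.random.default_rng(88)
        checked = 0
        for _ in range(150):
            part, a, b = random_config(rng)
            if a.count == 0:
                continue
            res = manders_overlap(a, b, part)
            total = sum(
                (res.a_counts[name] / res.a_count_cell) * res.moc_region[name]
                for name in REGION_NAMES
                if res.a_counts[name] > 0
            )
            assert total == pytest.approx(res.moc_cell, abs=1e-12)
            checked += 1
        assert checked >= 100


class TestVentralDorsalRatio:
    def _split(self, member, spacing=(1, 1, 1), axis="+x"):
        return split_halves(CellMask(np.asarray(member, bool), spacing), axis)

    def test_symmetric_puncta_ratio_one(self):
        member = np.ones((2, 2, 10), bool)
        split = self._split(member)
        flags = np.zeros((2, 2, 10), bool)
        flags[:, :, [1, 8]] = True  # mirror pair about the bisection plane
        res = ventral_dorsal_ratio(PunctaMask(flags, (1, 1, 1)), split)
        assert res.vd_ratio == pytest.approx(1.0)

    def test_arithmetic(self):
        member = np.ones((2, 2, 10), bool)
        split = self._split(member)
        flags = np.zeros((2, 2, 10), bool)
        flags[:, :, 5:8] = True  # 12 ventral
        flags[0, :, 1:5] = True  # 8 dorsal
        res = ventral_dorsal_ratio(PunctaMask(flags, (1, 1, 1)), split)
        assert res.vd_ratio == pytest.approx(1.5)

    def test_zero_dorsal_flagged_not_raised(self):
        member = np.ones((2, 2, 10), bool)
        split = self._split(member)
        flags = np.zeros((2, 2, 10), bool)
        flags[:, :, 7] = True
        res = ventral_dorsal_ratio(PunctaMask(flags, (1, 1, 1)), split)
        assert not res.defined and math.isnan(res.vd_ratio)


class TestQuantifyCell:
    def test_synthetic_image_tier_row(self):
        spec = SimulationSpec(tier="image", seed=11)
        channels, truth = simulate_cell(spec)
        record = CellRecord("c1", stage="metaphase", ventral_axis="+y")
        row = quantify_cell(channels, record)
        assert row["cell_id"] == "c1"
        assert row["cell_volume_um3"] == pytest.approx(
            truth.mask.volume_um3, rel=0.15
        )
        assert 0.0 <= row["moc_cell"] <= 1.0

    def test_missing_marker_channel_gives_nan_moc(self):
        spec = SimulationSpec(tier="image", seed=11)
        channels, _ = simulate_cell(spec)
        row = quantify_cell({"receptor": channels["receptor"]}, CellRecord("c1"))
        assert math.isnan(row["moc_cell"])
        assert row["E_membrane"] > 0

    def test_deterministic(self):
        spec = SimulationSpec(tier="image", seed=42)
        row1 = quantify_cell(simulate_cell(spec)[0], CellRecord("c1"))
        row2 = quantify_cell(simulate_cell(spec)[0], CellRecord("c1"))
        assert row1 == row2

    def test_missing_receptor_channel_errors(self):
        spec = SimulationSpec(tier="image", seed=11)
        channels, _ = simulate_cell(spec)
        with pytest.raises(KeyError):
            quantify_cell({"rab": channels["rab"]}, CellRecord("c1"))
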