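import numpy as np
import pytest

import kbpadvisor as k
from kbpadvisor.cohort_miner import (
    DegenerateTestError,
    MissingROIError,
    RECTUM_VX_LEVELS_GY,
)
from kbpadvisor.dose_geometry import EmptyMaskError

from conftest import make_grid
from oracles import brute_ring_voxels, paired_oracle_less, welch_oracle


def make_record(patient_id, delta, **overrides):
    base = dict(
        patient_id=patient_id,
        risk_group="HR",
        d_px=74.0,
        fractions=37,
        overlap_frac=0.2,
        mean_rectum=40.0,
        mean_bladder=22.0,
        ptv3_d99=72.4,
        ptv3_d1=75.1,
        ptv2_d99=67.6,
        ptv1_d99=59.3,
        total_mu=430.0,
        ci_56_2=0.69,
        ci_40_0=0.37,
        rectum_vx={30.0: 0.7, 40.0: 0.5, 50.0: 0.35, 60.0: 0.2, 65.0: 0.12, 70.0: 0.07},
        delta=delta,
        ring1cm_mean=25.0,
    )
    base.update(overrides)
    return k.PlanRecord(**base)


def simple_plan(uniform_dose=None):
    """Tiny hand-built plan: concentric boxes for PTVs, a separate rectum bar."""
    grid = make_grid((20, 20, 12), spacing=2.0)
    occ = lambda: np.zeros(grid.shape, dtype=bool)  # noqa: E731

    ptv3 = occ(); ptv3[8:12, 10:14, 4:8] = True
    ptv2 = occ(); ptv2[7:13, 9:15, 3:9] = True
    ptv1 = occ(); ptv1[6:14, 8:16, 2:10] = True
    rectum = occ(); rectum[8:12, 2:7, 3:9] = True
    bladder = occ(); bladder[8:12, 16:19, 3:9] = True

    structures = {
        name: k.ROIMask(grid, arr, name)
        for name, arr in [
            ("ptv3", ptv3), ("ptv2", ptv2), ("ptv1", ptv1),
            ("rectum", rectum), ("bladder", bladder),
        ]
    }
    if uniform_dose is None:
        dose_arr = np.full(grid.shape, 8.0)
        dose_arr[ptv1] = 50.0
        dose_arr[ptv2] = 65.0
        dose_arr[ptv3] = 74.0
        dose_arr[rectum] = 30.0
    else:
        dose_arr = np.full(grid.shape, uniform_dose)
    dose = k.DoseGrid(grid, dose_arr)
    meta = {"patient_id": "P1", "risk_group": "HR", "d_px_gy": 74.0, "fractions": 37, "total_mu": 410.0}
    return structures, dose, meta


@pytest.fixture(scope="module")
def pair():
    return k.ModelPair(
        oard=k.SparingModel(0.33, 0.5, -2.3), mard=k.SparingModel(0.38, 0.5, -2.3)
    )


class TestExtractRecord:
    def test_uniform_dose_gives_flat_ptv_metrics(self, pair):
        structures, dose, meta = simple_plan(uniform_dose=74.0)
        rec = k.extract_record(structures, dose, meta, pair)
        assert rec.ptv3_d99 == pytest.approx(74.0, abs=0.1)
        assert rec.ptv3_d1 == pytest.approx(74.0, abs=0.1)

    def test_disjoint_rectum_has_zero_overlap(self, pair):
        structures, dose, meta = simple_plan()
        rec = k.extract_record(structures, dose, meta, pair)
        assert rec.overlap_frac == 0.0
        assert rec.mean_rectum == pytest.approx(30.0)

    def test_missing_mandatory_roi_listed(self, pair):
        structures, dose, meta = simple_plan()
        del structures["bladder"]
        del structures["ptv2"]
        with pytest.raises(MissingROIError) as exc:
            k.extract_record(structures, dose, meta, pair)
        assert set(exc.value.missing) == {"bladder", "ptv2"}

    def test_optional_organs_marked_absent(self, pair):
        structures, dose, meta = simple_plan()
        rec = k.extract_record(structures, dose, meta, pair)
        assert rec.mean_bowel is None
        assert rec.femhead_d50_L is None

    def test_extraction_is_pure(self, pair):
        structures, dose, meta = simple_plan()
        assert k.extract_record(structures, dose, meta, pair) == k.extract_record(
            structures, dose, meta, pair
        )

    def test_rectum_vx_non_increasing(self, pair, phantom_plan):
        structures, dose, meta = phantom_plan
        rec = k.extract_record(structures, dose, meta, pair)
        vals = [rec.rectum_vx[lvl] for lvl in RECTUM_VX_LEVELS_GY]
        assert np.all(np.diff(vals) <= 1e-12)

    def test_generator_round_trip_recovers_delta(self, pair, phantom_plan):
        structures, dose, meta = phantom_plan
        rec = k.extract_record(structures, dose, meta, pair)
        assert rec.delta == pytest.approx(0.1, abs=0.02)


class TestRingMeanDose:
    def test_uniform_field_ring_mean_is_uniform_value(self):
        structures, dose, _ = simple_plan(uniform_dose=40.0)
        assert k.ring_mean_dose(dose, structures["rectum"]) == pytest.approx(40.0)

    def test_zero_dose_outside_organ_gives_zero(self):
        structures, _, _ = simple_plan()
        rectum = structures["rectum"]
        dose_arr = np.zeros(rectum.grid.shape)
        dose_arr[rectum.occupancy] = 30.0
        dose = k.DoseGrid(rectum.grid, dose_arr)
        assert k.ring_mean_dose(dose, rectum) == 0.0

    def test_gradient_field_matches_distance_oracle(self):
        grid = make_grid((10, 10, 8), spacing=2.0)
        occ = np.zeros(grid.shape, dtype=bool)
        occ[4:6, 4:6, 3:5] = True
        mask = k.ROIMask(grid, occ, "organ")
        xs = grid.axis_coords(0)[:, None, None]
        dose = k.DoseGrid(grid, 30.0 + xs + np.zeros(grid.shape))
        ring = brute_ring_voxels(occ, grid.spacing, 6.0)
        expected = dose.dose[ring].mean()
        assert k.ring_mean_dose(dose, mask, margin_mm=6.0) == pytest.approx(expected)

    def test_organ_filling_grid_raises(self):
        grid = make_grid((4, 4, 4))
        full = k.ROIMask(grid, np.ones(grid.shape, dtype=bool))
        dose = k.DoseGrid(grid, np.full(grid.shape, 10.0))
        with pytest.raises(EmptyMaskError):
            k.ring_mean_dose(dose, full)


class TestSelectExtremes:
    def test_high_and_near_zero_selection(self):
        table = k.CohortTable(
            records=[
                make_record("a", 0.3),
                make_record("b", 0.2),
                make_record("c", 0.0),
                make_record("d", -0.01),
            ]
        )
        high, low = k.select_extremes(table, 1, 1)
        assert high == ["a"]
        assert low == ["c"]

    def test_ties_break_by_patient_id(self):
        table = k.CohortTable(records=[make_record(pid, 0.1) for pid in "dcba"])
        high, low = k.select_extremes(table, 2, 2)
        assert high == ["a", "b"]
        assert low == ["c", "d"]

    def test_matches_sort_oracle_and_permutation_invariant(self):
        rng = np.random.default_rng(8)
        deltas = rng.normal(0.05, 0.1, size=20)
        records = [make_record(f"p{i:02d}", float(d)) for i, d in enumerate(deltas)]
        table = k.CohortTable(records=records)
        high, low = k.select_extremes(table, 5, 5)

        order = sorted(range(20), key=lambda i: (-deltas[i], f"p{i:02d}"))
        assert high == [f"p{i:02d}" for i in order[:5]]
        rest = order[5:]
        rest.sort(key=lambda i: (abs(deltas[i]), f"p{i:02d}"))
        assert low == [f"p{i:02d}" for i in rest[:5]]

        shuffled = k.CohortTable(records=[records[i] for i in rng.permutation(20)])
        assert k.select_extremes(shuffled, 5, 5) == (high, low)

    def test_table_too_small_rejected(self):
        table = k.CohortTable(records=[make_record("a", 0.1)])
        with pytest.raises(ValueError):
            k.select_extremes(table, 1, 1)


class TestPairedTest:
    def test_identical_vectors_are_degenerate(self):
        with pytest.raises(DegenerateTestError):
            k.paired_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])

    def test_matches_hand_computed_oracle(self):
        clinical = [0.21, 0.15, 0.30, 0.25, 0.18]
        replan = [0.12, 0.11, 0.20, 0.22, 0.10]
        t, p = k.paired_test(clinical, replan)
        t_ref, p_ref = paired_oracle_less(replan, clinical)
        assert t == pytest.approx(t_ref, abs=1e-6)
        assert p == pytest.approx(p_ref, abs=1e-6)

    def test_systematic_improvement_is_significant(self):
        rng = np.random.default_rng(3)
        clinical = rng.uniform(0.1, 0.3, size=8)
        replan = clinical - 0.08 + rng.normal(0, 0.01, size=8)
        _, p = k.paired_test(clinical, replan)
        assert p < 0.05

    def test_matches_oracle_on_random_samples(self):
        rng = np.random.default_rng(44)
        for _ in range(50):
            n = int(rng.integers(3, 12))
            a = rng.normal(0.1, 0.05, size=n)
            b = a + rng.normal(-0.02, 0.05, size=n)
            t, p = k.paired_test(a, b)
            t_ref, p_ref = paired_oracle_less(b, a)
            assert t == pytest.approx(t_ref, abs=1e-9)
            assert p == pytest.approx(p_ref, abs=1e-9)


class TestCompareCohorts:
    def test_identical_cohorts_not_significant(self):
        records = [make_record(f"p{i}", 0.1, mean_rectum=35 + i) for i in range(6)]
        pre = k.CohortTable(records=records, label="pre")
        post = k.CohortTable(records=list(records), label="post")
        row = k.compare_cohorts(pre, post, "mean_rectum")
        assert row.p_value == pytest.approx(1.0)

    def test_matches_hand_welch_computation(self):
        pre = k.CohortTable(
            records=[make_record(f"a{i}", 0.1, mean_rectum=v) for i, v in enumerate([40.1, 42.3, 44.0])]
        )
        post = k.CohortTable(
            records=[make_record(f"b{i}", 0.1, mean_rectum=v) for i, v in enumerate([35.2, 36.8, 37.4])]
        )
        row = k.compare_cohorts(pre, post, "mean_rectum")
        t_ref, p_ref = welch_oracle([40.1, 42.3, 44.0], [35.2, 36.8, 37.4])
        assert row.p_value == pytest.approx(p_ref, abs=1e-6)

    def test_scale_invariance_of_p_value(self):
        rng = np.random.default_rng(10)
        a = rng.normal(40, 4, size=8)
        b = rng.normal(36, 4, size=9)
        make = lambda vals, tag: k.CohortTable(  # noqa: E731
            records=[make_record(f"{tag}{i}", 0.1, mean_rectum=float(v)) for i, v in enumerate(vals)]
        )
        p1 = k.compare_cohorts(make(a, "a"), make(b, "b"), "mean_rectum").p_value
        p2 = k.compare_cohorts(make(3 * a, "a"), make(3 * b, "b"), "mean_rectum").p_value
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_oracle_on_random_samples(self):
        rng = np.random.default_rng(45)
        for _ in range(50):
            a = rng.normal(40, 4, size=int(rng.integers(3, 10)))
            b = rng.normal(38, 5, size=int(rng.integers(3, 10)))
            make = lambda vals, tag: k.CohortTable(  # noqa: E731
                records=[
                    make_record(f"{tag}{i}", 0.1, mean_rectum=float(v))
                    for i, v in enumerate(vals)
                ]
            )
            row = k.compare_cohorts(make(a, "a"), make(b, "b"), "mean_rectum")
            _, p_ref = welch_oracle(a, b)
            assert row.p_value == pytest.approx(p_ref, abs=1e-9)

    def test_missing_metric_and_absent_values(self):
        pre = k.CohortTable(records=[make_record("a", 0.1)])
        post = k.CohortTable(records=[make_record("b", 0.1)])
        with pytest.raises(KeyError):
            k.compare_cohorts(pre, post, "nonexistent")
        # optional organ absent everywhere -> no values to compare
        with pytest.raises(ValueError):
            k.compare_cohorts(pre, post, "mean_bowel")


class TestCohortTable:
    def test_duplicate_patient_ids_rejected(self):
        with pytest.raises(ValueError):
            k.CohortTable(records=[make_record("a", 0.1), make_record("a", 0.2)])

    def test_csv_round_trip(self, tmp_path):
        records = [
            make_record("a", 0.12),
            make_record("b", -0.03, mean_bowel=14.1, femhead_d50_L=21.7, femhead_d50_R=21.6),
        ]
        table = k.CohortTable(records=records, label="pre")
        path = tmp_path / "cohort.csv"
        table.to_csv(path)
        back = k.CohortTable.from_csv(path, label="pre")
        assert back.records[0] == records[0]
        assert back.records[1].femhead_d50_L == pytest.approx(21.7)
        assert back.records[0].mean_bowel is None

    def test_delta_reference_toggle(self, pair):
        rec = make_record("a", 0.0, overlap_frac=0.2, mean_rectum=40.0)
        table = k.CohortTable(records=[rec])
        mard_ref = table.with_delta_reference(pair, "mard").records[0]
        expected = k.relative_excess(40.0, k.predict_dose(pair.mard, 0.2, 74.0))
        assert mard_ref.delta == pytest.approx(expected)
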