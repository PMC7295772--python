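"""Detection and filtering of oocytes in synthetic whole-mount micrographs."""

import numpy as np
import pytest

from ultrametric.config import DetectionConfig
from ultrametric.detection import (
    Micrograph,
    OocyteRecord,
    detect_objects,
    filter_oocytes,
    merge_fish_detections,
)
from ultrametric.errors import InputFormatError
from ultrametric.synthetic import SceneSpec, render_micrograph


def _passing_record(**overrides):
    base = dict(
        diameter_um=400.0, major_um=420.0, minor_um=381.0, area_um2=1.26e5,
        roundness=0.9, ellipticity=0.95, mean_grey=80.0, centroid=(10.0, 10.0),
    )
    base.update(overrides)
    return OocyteRecord(**base)


def _match_truth(records, truth, tol_px=20.0):
    """Pair passed detections with ground-truth objects by centroid."""
    cents = np.array([t.centroid for t in truth])
    pairs = []
    for r in records:
        d2 = ((cents - np.array(r.centroid)) ** 2).sum(axis=1)
        j = int(np.argmin(d2))
        if d2[j] < tol_px**2:
            pairs.append((r, truth[j]))
    return pairs


class TestDetectObjects:
    def test_blank_image_yields_no_objects(self):
        micro = Micrograph(np.full((256, 256), 255, dtype=np.uint8))
        assert detect_objects(micro) == []

    def test_rejects_non_2d_input(self):
        with pytest.raises(InputFormatError):
            Micrograph(np.zeros((4, 4, 3), dtype=np.uint8))
        with pytest.raises(InputFormatError):
            Micrograph(np.zeros((0, 4), dtype=np.uint8))
        with pytest.raises(InputFormatError):
            Micrograph(np.full((4, 4), 300, dtype=np.int32))

    def test_recovers_known_diameters_within_two_percent(self, rendered_three):
        micro, truth = rendered_three
        records = detect_objects(micro)
        assert len(records) == 3
        pairs = _match_truth(records, truth)
        assert len(pairs) == 3
        for rec, t in pairs:
            assert rec.diameter_um == pytest.approx(t.diameter_um, rel=0.02)

    def test_circle_has_roundness_near_one(self):
        scene = SceneSpec(shape_px=(512, 512), axis_ratio_range=(1.0, 1.0), seed=3)
        micro, truth, _ = render_micrograph([400.0], scene, np.random.default_rng(3))
        (rec,) = detect_objects(micro)
        assert rec.roundness == pytest.approx(1.0, abs=0.02)
        assert rec.ellipticity >= 0.95

    def test_border_touching_objects_are_discarded(self):
        img = np.full((200, 200), 230, dtype=np.uint8)
        img[0:40, 80:120] = 60  # touches the top border
        img[90:130, 90:130] = 60  # interior
        micro = Micrograph(img)
        records = detect_objects(micro)
        assert len(records) == 1
        assert 90 < records[0].centroid[0] < 130


class TestFilterOocytes:
    def test_undersized_record_rejected_for_size(self):
        (rec,) = filter_oocytes([_passing_record(diameter_um=90.0)])
        assert not rec.passed_filter
        assert rec.rejection_reason == "size"

    def test_bounds_inclusive_except_grey(self):
        (rec,) = filter_oocytes(
            [_passing_record(diameter_um=100.0, mean_grey=110.0,
                             roundness=0.8, ellipticity=0.91)]
        )
        assert rec.passed_filter
        (rec,) = filter_oocytes([_passing_record(mean_grey=111.0)])
        assert not rec.passed_filter and rec.rejection_reason == "grey"

    @pytest.mark.parametrize(
        "overrides,reason",
        [
            ({"diameter_um": 1601.0}, "size"),
            ({"mean_grey": 140.0}, "grey"),
            ({"roundness": 0.79}, "roundness"),
            ({"ellipticity": 0.90}, "ellipticity"),
        ],
    )
    def test_rejection_reason_identifies_failed_criterion(self, overrides, reason):
        (rec,) = filter_oocytes([_passing_record(**overrides)])
        assert not rec.passed_filter
        assert rec.rejection_reason == reason

    def test_empty_input_gives_empty_output(self):
        assert filter_oocytes([]) == []

    def test_filtering_is_idempotent(self, rendered_three):
        micro, _ = rendered_three
        once = filter_oocytes(detect_objects(micro))
        twice = filter_oocytes(once)
        assert [r.passed_filter for r in once] == [r.passed_filter for r in twice]
        assert [r.diameter_um for r in once] == [r.diameter_um for r in twice]

    def test_order_preserved(self, rendered_three):
        micro, _ = rendered_three
        records = detect_objects(micro)
        filtered = filter_oocytes(records)
        assert [r.centroid for r in records] == [r.centroid for r in filtered]


class TestResolutionEquivariance:
    def test_double_resolution_same_decisions(self):
        diams = [150.0, 400.0, 700.0]
        for res in (0.1803, 0.3606):
            scene = SceneSpec(shape_px=(1024, 1024), resolution_px_per_um=res, seed=5)
            cfg = DetectionConfig(resolution_px_per_um=res)
            micro, truth, left = render_micrograph(
                diams, scene, np.random.default_rng(5)
            )
            assert left.size == 0
            recs = filter_oocytes(detect_objects(micro, cfg), cfg)
            assert sum(r.passed_filter for r in recs) == 3
            got = sorted(r.diameter_um for r in recs)
            for g, want in zip(got, sorted(diams)):
                assert g == pytest.approx(want, rel=0.01)


class TestMergeFishDetections:
    def _passed(self, n):
        return [_passing_record(passed_filter=True) for _ in range(n)]

    def test_pooled_count_without_flags(self):
        diams, flags = merge_fish_detections(
            [("m1", self._passed(80)), ("m2", self._passed(70)), ("m3", self._passed(60))]
        )
        assert len(diams) == 210
        assert flags == []

    def test_low_count_flag(self):
        _, flags = merge_fish_detections(
            [("m1", self._passed(50)), ("m2", self._passed(50)), ("m3", self._passed(50))]
        )
        assert flags == ["low_count"]

    def test_few_micrographs_flag_only(self):
        _, flags = merge_fish_detections([("m1", self._passed(250))])
        assert flags == ["few_micrographs"]

    def test_rejected_records_not_pooled(self):
        recs = self._passed(3) + [_passing_record(passed_filter=False)]
        diams, _ = merge_fish_detections([("m1", recs)])
        assert len(diams) == 3

    def test_requires_at_least_one_micrograph(self):
        with pytest.raises(ValueError):
            merge_fish_detections([])


class TestDetectionBenchmark:
    def test_recall_precision_and_mae_on_synthetic_benchmark(self):
        """Non-overlapping oocytes with some debris: near-perfect detection."""
        from ultrametric.synthetic import CohortSpec, simulate_cohort

        rng = np.random.default_rng(42)
        tp = fp = fn = 0
        errs = []
        for seed in range(3):
            draw = simulate_cohort(CohortSpec(seed=seed), rng=rng, multinomial_n=120)
            scene = SceneSpec(shape_px=(1280, 1280), debris_count=5, seed=seed)
            micro, truth, _ = render_micrograph(draw.diameters_um, scene, rng)
            passed = [r for r in filter_oocytes(detect_objects(micro)) if r.passed_filter]
            pairs = _match_truth(passed, truth)
            tp += len(pairs)
            fp += len(passed) - len(pairs)
            fn += len(truth) - len(pairs)
            errs += [abs(r.diameter_um - t.diameter_um) / t.diameter_um for r, t in pairs]
        recall = tp / (tp + fn)
        precision = tp / (tp + fp)
        assert recall >= 0.95
        assert precision >= 0.95
        assert np.mean(errs) <= 0.02
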