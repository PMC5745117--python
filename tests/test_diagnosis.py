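"""Two-round segment diagnosis, splitting and the sample-level call."""

import numpy as np
import pytest

from msh.diagnosis import (
    DX_BCC,
    DX_DERMIS,
    DX_TISSUE,
    DiagnosisImage,
    STATUS_NEEDS_ROUND2,
    STATUS_SINGLE,
    STATUS_SPLIT,
    STATUS_UNCLASSIFIED,
    assemble_diagnosis,
    diagnose_segment_round1,
    nearest_neighbour_split,
    run_round2,
    sample_decision,
)
from msh.segmentation import SegmentMap
from msh.synthetic import generate_spectrum


def strip_segment(width=30):
    """One 4 x width strip segment with pixels and a SegmentMap."""
    labels = np.zeros((8, width), dtype=np.int32)
    labels[2:6, :] = 1
    pixels = np.nonzero(labels == 1)
    sm = SegmentMap(labels, 0.0, 40.0, np.array([4 * width]), np.array([1.0]),
                    np.array([[3.5, width / 2]]))
    return sm, pixels


def spectra_of(models, classes, snr=60.0, seed0=0):
    return [
        generate_spectrum(models[c], snr, seed=seed0 + i)
        for i, c in enumerate(classes)
    ]


def junk_spectrum(models, seed):
    """Tissue spectrum far below the diagnosis SNR threshold."""
    return generate_spectrum(models["dermis"], 1.0, seed=seed)


def dead_spectrum():
    """Deterministic signal-free spectrum: alternating noise, no CH2 band."""
    from msh.preprocessing import STANDARD_GRID, Spectrum

    y = np.where(np.arange(701) % 2 == 0, 1.0, -1.0)
    return Spectrum(STANDARD_GRID, y)


def points_on(pixels, n):
    coords = np.column_stack(pixels)
    idx = np.linspace(0, len(coords) - 1, n).astype(int)
    return coords[idx]


class TestRound1Rules:
    def test_unanimous_class_labels_segment(self, models, trained_model):
        _, pix = strip_segment()
        pts = points_on(pix, 5)
        d = diagnose_segment_round1(1, pix, pts, spectra_of(models, ["dermis"] * 5),
                                    trained_model)
        assert d.status == STATUS_SINGLE and d.label == "dermis"

    def test_single_bcc_spectrum_ignored(self, models, trained_model):
        _, pix = strip_segment()
        pts = points_on(pix, 5)
        d = diagnose_segment_round1(
            1, pix, pts, spectra_of(models, ["BCC"] + ["dermis"] * 4), trained_model
        )
        assert d.status == STATUS_SINGLE and d.label == "dermis"
        assert "ignored" in d.notes

    def test_all_bcc_exceeds_majority(self, models, trained_model):
        _, pix = strip_segment()
        pts = points_on(pix, 5)
        d = diagnose_segment_round1(1, pix, pts, spectra_of(models, ["BCC"] * 5),
                                    trained_model)
        assert d.status == STATUS_SINGLE and d.label == "BCC"

    def test_exactly_80_percent_triggers_round2(self, models, trained_model):
        # 4/5 = 80% is NOT "more than 80%": the strict boundary
        _, pix = strip_segment()
        pts = points_on(pix, 5)
        d = diagnose_segment_round1(
            1, pix, pts, spectra_of(models, ["BCC"] * 4 + ["dermis"]), trained_model
        )
        assert d.status == STATUS_NEEDS_ROUND2

    def test_mixed_non_bcc_classes_split(self, models, trained_model):
        _, pix = strip_segment()
        pts = points_on(pix, 6)
        d = diagnose_segment_round1(
            1, pix, pts, spectra_of(models, ["dermis"] * 3 + ["fat"] * 3), trained_model
        )
        assert d.status == STATUS_SPLIT
        assert set(d.pixel_labels) == {"dermis", "fat"}

    def test_discard_majority_gives_unclassified(self, models, trained_model):
        _, pix = strip_segment()
        pts = points_on(pix, 5)
        spectra = [junk_spectrum(models, s) for s in range(5)]
        d = diagnose_segment_round1(1, pix, pts, spectra, trained_model)
        assert d.status == STATUS_UNCLASSIFIED
        assert d.n_discarded == 5

    def test_no_spectra_rejected(self, trained_model):
        _, pix = strip_segment()
        with pytest.raises(ValueError):
            diagnose_segment_round1(1, pix, np.zeros((0, 2)), [], trained_model)


class TestNearestNeighbourSplit:
    def test_single_point_takes_whole_segment(self):
        _, pix = strip_segment()
        out = nearest_neighbour_split(pix, np.array([[3, 10]]), ["fat"])
        assert set(out) == {"fat"}
        assert len(out) == len(pix[0])

    def test_two_points_split_at_bisector(self):
        _, pix = strip_segment(width=20)
        pts = np.array([[3, 2], [3, 17]])
        out = nearest_neighbour_split(pix, pts, ["dermis", "BCC"])
        coords = np.column_stack(pix)
        for (r, c), lab in zip(coords, out):
            d0 = np.hypot(r - 3, c - 2)
            d1 = np.hypot(r - 3, c - 17)
            expected = "dermis" if d0 < d1 or (d0 == d1) else "BCC"
            assert lab == expected

    def test_partition_property(self):
        _, pix = strip_segment()
        rng = np.random.default_rng(0)
        coords = np.column_stack(pix)
        pts = coords[rng.choice(len(coords), 6, replace=False)]
        out = nearest_neighbour_split(pix, pts, list("abcdef"))
        assert len(out) == len(coords)  # every pixel exactly one label

    def test_no_points_rejected(self):
        _, pix = strip_segment()
        with pytest.raises(ValueError):
            nearest_neighbour_split(pix, np.zeros((0, 2)), [])


class TestRound2:
    def _ambiguous(self, models, trained_model):
        _, pix = strip_segment()
        pts = points_on(pix, 5)
        d1 = diagnose_segment_round1(
            1, pix, pts, spectra_of(models, ["BCC"] * 4 + ["dermis"]), trained_model
        )
        assert d1.status == STATUS_NEEDS_ROUND2
        return pix, pts, d1

    def test_requests_equal_count_at_new_locations(self, models, trained_model):
        pix, pts, d1 = self._ambiguous(models, trained_model)
        calls = []

        def measure(r, c):
            calls.append((r, c))
            return generate_spectrum(models["BCC"], 60.0, seed=len(calls))

        d2 = run_round2(pix, d1, pts, measure, trained_model, seed=1)
        assert len(calls) == 5  # equal to the round-1 count
        round1_set = {tuple(p) for p in pts}
        assert all(loc not in round1_set for loc in calls)
        assert d2.status == STATUS_SPLIT

    def test_all_bcc_rounds_label_everything_bcc(self, models, trained_model):
        _, pix = strip_segment()
        pts = points_on(pix, 5)
        d1 = diagnose_segment_round1(
            1, pix, pts, spectra_of(models, ["BCC"] * 4 + ["dermis"]), trained_model
        )

        def measure(r, c):
            return generate_spectrum(models["BCC"], 60.0, seed=r * 100 + c)

        d2 = run_round2(pix, d1, pts, measure, trained_model, seed=2)
        # 10 joined points: 9 BCC, the round-1 dermis cell survives the split
        assert len(d2.point_labels) == 10
        assert (d2.point_labels == "BCC").sum() == 9
        assert set(d2.pixel_labels) <= {"BCC", "dermis"}

    def test_failed_round2_finalises_with_round1(self, models, trained_model):
        pix, pts, d1 = self._ambiguous(models, trained_model)
        from msh.preprocessing import compute_snr

        assert compute_snr(dead_spectrum()) < 4.0

        def measure(r, c):
            return dead_spectrum()

        d2 = run_round2(pix, d1, pts, measure, trained_model, seed=3)
        assert d2.status == STATUS_SPLIT
        assert "no retained spectra" in d2.notes
        assert len(d2.points) == len(d1.points)


class TestAssembleAndDecision:
    def _three_segment_map(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[1:4, 1:4] = 1
        labels[1:4, 10:13] = 2
        labels[10:13, 1:4] = 3
        areas = np.array([9, 9, 9])
        cents = np.array([[2, 2], [2, 11], [11, 2]])
        sm = SegmentMap(labels, 0.0, 40.0, areas, np.zeros(3), cents)
        return sm, np.ones((20, 20), bool)

    def _single(self, sid, label):
        from msh.diagnosis import SegmentDiagnosis

        return SegmentDiagnosis(segment_id=sid, status=STATUS_SINGLE, label=label)

    def test_no_bcc_segments(self):
        sm, mask = self._three_segment_map()
        img = assemble_diagnosis([self._single(i, "dermis") for i in (1, 2, 3)], sm, mask)
        assert img.n_bcc == 0
        assert sample_decision(img, 1) == "BCC-negative"

    def test_three_disjoint_bcc_regions(self):
        sm, mask = self._three_segment_map()
        img = assemble_diagnosis([self._single(i, "BCC") for i in (1, 2, 3)], sm, mask)
        assert img.n_bcc == 3

    def test_split_subregions_counted_separately(self):
        from msh.diagnosis import SegmentDiagnosis

        sm, mask = self._three_segment_map()
        pix1 = sm.segment_pixels(1)
        # segment 1 split: BCC at both ends, dermis between -> 2 BCC regions
        cols = pix1[1]
        patch = np.where(cols == 1, "BCC", np.where(cols == 3, "BCC", "dermis"))
        split = SegmentDiagnosis(segment_id=1, status=STATUS_SPLIT,
                                 pixel_labels=patch.astype(object))
        img = assemble_diagnosis(
            [split, self._single(2, "BCC"), self._single(3, "dermis")], sm, mask
        )
        assert img.n_bcc == 3

    def test_unsegmented_tissue_keeps_tissue_code(self):
        sm, mask = self._three_segment_map()
        img = assemble_diagnosis([self._single(1, "dermis")], sm, mask)
        assert img.codes[15, 15] == DX_TISSUE
        assert (img.codes[sm.labels == 1] == DX_DERMIS).all()

    @pytest.mark.parametrize("n_bcc,n_th,expected", [
        (7, 8, "BCC-negative"),
        (8, 8, "BCC-positive"),
        (0, 1, "BCC-negative"),
        (5, 5, "BCC-positive"),
    ])
    def test_threshold_boundary(self, n_bcc, n_th, expected):
        img = DiagnosisImage(np.zeros((2, 2), dtype=np.uint8), n_bcc)
        assert sample_decision(img, n_th) == expected

    def test_rgb_rendering_uses_legend(self):
        codes = np.array([[DX_BCC, DX_TISSUE]], dtype=np.uint8)
        img = DiagnosisImage(codes, 1)
        rgb = img.to_rgb()
        assert tuple(rgb[0, 0]) == (220, 30, 30)
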