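import numpy as np
import pytest

from meniscometry import (
    Footprint2D,
    compute_indices,
    indices_from_lengths,
    lm_ratio_from_lengths,
    project_axial,
)
from meniscometry.errors import EmptyFootprintError, LabelAbsentError
from meniscometry.morphometry import (
    ap_extent,
    body_min_width,
    horn_coverage,
    max_diameter_column,
    ml_max_width,
)

from conftest import make_volume

SP = 0.35  # in-plane spacing used throughout


def fp_from_mask(mask, dx=SP, dy=SP):
    mask = np.asarray(mask, dtype=bool)
    return Footprint2D(
        occupancy=mask,
        x_coords=np.arange(mask.shape[0]) * dx,
        y_coords=np.arange(mask.shape[1]) * dy,
    )


# ---------------------------------------------------------------------------
# Brute-force per-pixel oracles (independent loop implementations)
# ---------------------------------------------------------------------------


def brute_ap_extent(fp):
    ys = [j for j in range(fp.occupancy.shape[1]) if fp.occupancy[:, j].any()]
    return (max(ys) - min(ys) + 1) * fp.dy


def brute_ml_max_width(fp):
    best = 0
    for j in range(fp.occupancy.shape[1]):
        xs = [i for i in range(fp.occupancy.shape[0]) if fp.occupancy[i, j]]
        if xs:
            best = max(best, max(xs) - min(xs) + 1)
    return best * fp.dx


def _brute_runs(col):
    runs, start = [], None
    for i, v in enumerate(col):
        if v and start is None:
            start = i
        if not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(col)))
    return runs


def brute_body_min_width(fp, side_sign=1, body_fraction=1 / 3):
    ys = [j for j in range(fp.occupancy.shape[1]) if fp.occupancy[:, j].any()]
    y_lo_edge = fp.y_coords[min(ys)] - fp.dy / 2
    span = (max(ys) - min(ys) + 1) * fp.dy
    lo = y_lo_edge + span * (0.5 - body_fraction / 2)
    hi = y_lo_edge + span * (0.5 + body_fraction / 2)
    widths = []
    for j in ys:
        if not (lo <= fp.y_coords[j] <= hi):
            continue
        runs = _brute_runs(fp.occupancy[:, j])
        if runs:
            s, e = runs[-1] if side_sign > 0 else runs[0]
            widths.append(e - s)
    if not widths:
        raise EmptyFootprintError("empty body region (oracle)")
    return min(widths) * fp.dx


def brute_max_diameter_column(fp, side_sign=1):
    spans = {}
    for i in range(fp.occupancy.shape[0]):
        ys = [j for j in range(fp.occupancy.shape[1]) if fp.occupancy[i, j]]
        if ys:
            spans[i] = max(ys) - min(ys) + 1
    best = max(spans.values())
    ties = sorted(i for i, s in spans.items() if s == best)
    ix = ties[len(ties) // 2] if side_sign > 0 else ties[(len(ties) - 1) // 2]
    return fp.x_coords[ix], best * fp.dy


def brute_horn_coverage(fp, x_star):
    ix = min(range(len(fp.x_coords)), key=lambda i: abs(fp.x_coords[i] - x_star))
    runs = _brute_runs(fp.occupancy[ix, :])
    covered = sum(e - s for s, e in runs) * fp.dy
    if len(runs) == 1:
        return covered / 2, covered / 2, covered
    c = (runs[-1][1] - runs[-1][0]) * fp.dy
    d = (runs[0][1] - runs[0][0]) * fp.dy
    return c, d, covered


def random_blob(rng, shape=(40, 40)):
    # union of a few random filled ellipses; occasionally sparse noise
    occ = np.zeros(shape, dtype=bool)
    xx, yy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    for _ in range(rng.integers(1, 4)):
        cx, cy = rng.uniform(5, shape[0] - 5), rng.uniform(5, shape[1] - 5)
        rx, ry = rng.uniform(2, 12), rng.uniform(2, 12)
        occ |= ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1
    if rng.random() < 0.3:
        occ &= rng.random(shape) < 0.8
    return occ


# ---------------------------------------------------------------------------
# project_axial
# ---------------------------------------------------------------------------


class TestProjectAxial:
    def test_single_voxel(self):
        voxels = np.zeros((4, 5, 6), dtype=np.int16)
        voxels[2, 3, 4] = 2
        vol = make_volume(voxels, spacing=(0.35, 0.35, 0.7))
        fp = project_axial(vol, 2)
        assert fp.occupancy.sum() == 1
        assert fp.occupancy[2, 3]
        assert fp.x_coords[2] == pytest.approx(0.7)

    def test_empty_label_errors(self):
        vol = make_volume(np.zeros((3, 3, 3), dtype=np.int16))
        with pytest.raises(LabelAbsentError):
            project_axial(vol, 1)

    def test_matches_triple_loop(self, rng):
        voxels = rng.integers(0, 4, size=(30, 30, 30)).astype(np.int16)
        vol = make_volume(voxels, spacing=(0.5, 0.5, 1.0))
        for label in (1, 2, 3):
            fp = project_axial(vol, label)
            expected = np.zeros((30, 30), dtype=bool)
            for i in range(30):
                for j in range(30):
                    for k in range(30):
                        if voxels[i, j, k] == label:
                            expected[i, j] = True
            np.testing.assert_array_equal(fp.occupancy, expected)


# ---------------------------------------------------------------------------
# extent / width operators
# ---------------------------------------------------------------------------


class TestExtents:
    def test_single_cell(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        fp = fp_from_mask(mask)
        assert ap_extent(fp) == pytest.approx(SP)
        assert ml_max_width(fp) == pytest.approx(SP)

    def test_voxelized_bar(self):
        # 30 mm bar along y voxelized at 0.35 mm: within one spacing of truth
        n = int(round(30 / SP))
        mask = np.zeros((5, n + 10), dtype=bool)
        mask[2, 5 : 5 + n] = True
        assert abs(ap_extent(fp_from_mask(mask)) - 30.0) <= SP
        assert abs(ml_max_width(fp_from_mask(mask.T)) - 30.0) <= SP

    def test_crescent_ap_extent_vs_truth(self, non_dlm_knee):
        vol, truth, spec = non_dlm_knee
        fp = project_axial(vol, 2)
        assert abs(ap_extent(fp) - 2 * spec.lateral.r_out_ap) <= 2 * SP

    def test_tibia_ml_width_vs_truth(self, non_dlm_knee):
        vol, truth, spec = non_dlm_knee
        fp = project_axial(vol, 3)
        assert abs(ml_max_width(fp) - 2 * spec.tibia_ml_semi) <= 2 * SP

    def test_empty_errors(self):
        fp = fp_from_mask(np.zeros((3, 3)))
        for op in (ap_extent, ml_max_width, body_min_width, max_diameter_column):
            with pytest.raises(EmptyFootprintError):
                op(fp)


class TestBodyMinWidth:
    def test_full_disc(self):
        # disc of diameter D: central-third rows are single runs >= 0.94 D
        D = 20.0
        r = D / 2
        n = int(D / SP) + 6
        coords = (np.arange(n) - n / 2) * SP
        xx, yy = np.meshgrid(coords, coords, indexing="ij")
        fp = fp_from_mask(xx**2 + yy**2 <= r**2)
        assert body_min_width(fp) >= 0.94 * D

    def test_crescent_vs_ground_truth(self, non_dlm_knee):
        vol, truth, _ = non_dlm_knee
        fp = project_axial(vol, 2)
        assert abs(body_min_width(fp, side_sign=1) - truth.a_mm) <= 2 * SP

    def test_disjoint_blobs_empty_center(self):
        mask = np.zeros((10, 30), dtype=bool)
        mask[:, :3] = True
        mask[:, -3:] = True
        with pytest.raises(EmptyFootprintError):
            body_min_width(fp_from_mask(mask))


class TestMaxDiameterColumn:
    def test_full_disc_center(self):
        n = 61
        coords = (np.arange(n) - n // 2) * SP
        xx, yy = np.meshgrid(coords, coords, indexing="ij")
        fp = Footprint2D(occupancy=xx**2 + yy**2 <= 9.0**2, x_coords=coords, y_coords=coords)
        x_star, e = max_diameter_column(fp)
        assert abs(x_star) <= SP
        assert abs(e - 18.0) <= SP

    def test_two_column_tie_returns_peripheral(self):
        mask = np.zeros((6, 8), dtype=bool)
        mask[2, 1:6] = True
        mask[3, 2:7] = True
        fp = fp_from_mask(mask)
        x_plus, _ = max_diameter_column(fp, side_sign=1)
        x_minus, _ = max_diameter_column(fp, side_sign=-1)
        assert x_plus == pytest.approx(fp.x_coords[3])
        assert x_minus == pytest.approx(fp.x_coords[2])

    def test_crescent_vs_truth(self, non_dlm_knee):
        vol, truth, _ = non_dlm_knee
        _, e = max_diameter_column(project_axial(vol, 2))
        assert abs(e - truth.e_mm) <= 2 * SP


class TestHornCoverage:
    def test_single_full_span_run(self):
        mask = np.zeros((3, 20), dtype=bool)
        mask[1, 2:18] = True
        fp = fp_from_mask(mask)
        x_star, e = max_diameter_column(fp)
        c, d, covered = horn_coverage(fp, x_star)
        assert c + d == pytest.approx(e)
        assert covered / e == 1.0

    def test_constructed_two_runs(self):
        # two 8-voxel runs separated by a 10-voxel gap at 0.35 mm
        col = np.zeros(30, dtype=bool)
        col[2:10] = True
        col[20:28] = True
        mask = col[None, :]
        fp = fp_from_mask(mask)
        c, d, covered = horn_coverage(fp, fp.x_coords[0])
        assert c == pytest.approx(2.8)
        assert d == pytest.approx(2.8)
        assert covered == pytest.approx(5.6)

    def test_crescent_vs_truth(self, non_dlm_knee):
        vol, truth, _ = non_dlm_knee
        fp = project_axial(vol, 2)
        x_star, _ = max_diameter_column(fp)
        c, d, _ = horn_coverage(fp, x_star)
        assert abs(c - truth.c_mm) <= 2 * SP
        assert abs(d - truth.d_mm) <= 2 * SP

    def test_empty_column(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 1] = True
        fp = fp_from_mask(mask)
        with pytest.raises(EmptyFootprintError):
            horn_coverage(fp, fp.x_coords[3])


# ---------------------------------------------------------------------------
# compute_indices
# ---------------------------------------------------------------------------


class TestComputeIndices:
    def test_sizing_study_lm_example(self):
        # published median AP diameters: lateral 35.8 mm, medial 47.2 mm
        assert lm_ratio_from_lengths(35.8, 47.2) == pytest.approx(0.7585, abs=1e-4)

    def test_cadaveric_lm_example(self):
        assert lm_ratio_from_lengths(34.0, 43.0) == pytest.approx(0.7907, abs=1e-4)

    def test_indices_from_lengths_consistency(self):
        res = indices_from_lengths(a=7.5, b=75.0, c=8.7, d=8.8, e=35.0, L=34.9, M=47.2)
        assert res.rmt == pytest.approx(0.1)
        assert res.pcm == pytest.approx(17.5 / 35.0)
        assert res.lm_ratio == pytest.approx(34.9 / 47.2)

    def test_identical_menisci_unity_ratio(self, rng):
        # medial and lateral blocks with identical AP extents -> L/M = 1 exactly
        voxels = np.zeros((40, 40, 6), dtype=np.int16)
        voxels[5:15, 10:30, 2:4] = 1
        voxels[25:35, 10:30, 2:4] = 2
        voxels[2:38, 8:32, 0:2] = 3
        vol = make_volume(voxels, spacing=(0.35, 0.35, 0.7))
        res = compute_indices(vol)
        assert res.lm_ratio == 1.0

    def test_full_knee_vs_truth(self, non_dlm_knee):
        vol, truth, _ = non_dlm_knee
        res = compute_indices(vol)
        assert res.rmt == pytest.approx(truth.rmt, abs=0.03)
        assert res.pcm == pytest.approx(truth.pcm, abs=0.03)
        assert res.lm_ratio == pytest.approx(truth.lm_ratio, abs=0.03)
        assert res.reliable

    def test_missing_label(self):
        voxels = np.zeros((5, 5, 5), dtype=np.int16)
        voxels[1, 1, 1] = 1
        vol = make_volume(voxels)
        with pytest.raises(LabelAbsentError):
            compute_indices(vol)


# ---------------------------------------------------------------------------
# oracle equivalence and properties
# ---------------------------------------------------------------------------


class TestBruteForceEquivalence:
    def test_random_footprints_match_oracle(self, rng):
        for _ in range(100):
            occ = random_blob(rng)
            if not occ.any():
                continue
            fp = fp_from_mask(occ)
            assert ap_extent(fp) == pytest.approx(brute_ap_extent(fp))
            assert ml_max_width(fp) == pytest.approx(brute_ml_max_width(fp))
            for sign in (1, -1):
                try:
                    got = body_min_width(fp, side_sign=sign)
                except EmptyFootprintError:
                    with pytest.raises(EmptyFootprintError):
                        brute_body_min_width(fp, side_sign=sign)
                else:
                    assert got == pytest.approx(brute_body_min_width(fp, side_sign=sign))
                x_got, e_got = max_diameter_column(fp, side_sign=sign)
                x_exp, e_exp = brute_max_diameter_column(fp, side_sign=sign)
                assert (x_got, e_got) == pytest.approx((x_exp, e_exp))
                assert horn_coverage(fp, x_got) == pytest.approx(brute_horn_coverage(fp, x_got))

    def test_pcm_bounded_on_random_footprints(self, rng):
        for _ in range(50):
            occ = random_blob(rng)
            if not occ.any():
                continue
            fp = fp_from_mask(occ)
            x_star, e = max_diameter_column(fp)
            _, _, covered = horn_coverage(fp, x_star)
            assert 0 < covered / e <= 1.0
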