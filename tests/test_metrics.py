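"""Metrics against exhaustive brute-force oracles and closed-form examples."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from fundusseg.metrics import (
    asd,
    boundary_points,
    bootstrap_ci,
    confusion_counts,
    directional_h95,
    dsc,
    evaluate_dataset,
    hd95,
    mean_foreground_dsc,
    regions_from_labels,
)


# ---------------------------------------------------------------------------
# brute-force oracles (no KD-trees, no library percentiles)
# ---------------------------------------------------------------------------

def brute_dsc(pred, gt):
    tp = np.sum(pred & gt)
    denom = 2 * tp + np.sum(pred & ~gt) + np.sum(~pred & gt)
    return 1.0 if denom == 0 else 2.0 * tp / denom


def brute_boundary(region):
    pts = []
    h, w = region.shape
    for r in range(h):
        for c in range(w):
            if not region[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not region[rr, cc]:
                    pts.append((r, c))
                    break
    return np.array(pts, dtype=float).reshape(-1, 2)


def brute_directional(pa, pb, q=0.95):
    mins = np.sort(cdist(pa, pb).min(axis=1))
    rank = int(np.ceil(q * mins.size))
    return mins[max(rank, 1) - 1]


def brute_hd95(pred, gt):
    pa, pb = brute_boundary(pred), brute_boundary(gt)
    return max(brute_directional(pa, pb), brute_directional(pb, pa))


def brute_asd(pred, gt):
    pa, pb = brute_boundary(pred), brute_boundary(gt)
    return cdist(pa, pb).min(axis=1).mean()


def random_region(rng, h, w):
    """Random blobby region: union of a few rectangles and discs."""
    m = np.zeros((h, w), dtype=bool)
    for _ in range(rng.integers(1, 4)):
        if rng.random() < 0.5:
            r0, c0 = rng.integers(0, h), rng.integers(0, w)
            m[r0:r0 + rng.integers(2, h // 2 + 1), c0:c0 + rng.integers(2, w // 2 + 1)] = True
        else:
            rr, cc = np.mgrid[0:h, 0:w]
            cy, cx = rng.integers(0, h), rng.integers(0, w)
            m |= (rr - cy) ** 2 + (cc - cx) ** 2 <= rng.integers(2, (min(h, w) // 3) ** 2 + 3)
    return m


def test_metrics_match_brute_force_oracles_exactly():
    rng = np.random.default_rng(20240917)
    n_nonempty = 0
    for _ in range(200):
        h, w = rng.integers(8, 65), rng.integers(8, 65)
        a, b = random_region(rng, h, w), random_region(rng, h, w)
        assert dsc(a, b) == pytest.approx(brute_dsc(a, b), abs=0)
        if a.any() and b.any():
            n_nonempty += 1
            assert hd95(a, b) == pytest.approx(brute_hd95(a, b), abs=1e-9)
            assert asd(a, b) == pytest.approx(brute_asd(a, b), abs=1e-9)
    assert n_nonempty >= 150  # the oracle actually exercised the distances


# ---------------------------------------------------------------------------
# closed-form examples
# ---------------------------------------------------------------------------

def test_dsc_half_overlap_rows():
    pred = np.zeros((4, 4), bool)
    gt = np.zeros((4, 4), bool)
    pred[0:2] = True   # rows 0,1 -> 8 px
    gt[1:3] = True     # rows 1,2 -> 8 px
    assert confusion_counts(pred, gt)[:3] == (4, 4, 4)
    assert dsc(pred, gt) == pytest.approx(0.5)


def test_dsc_conventions_and_symmetry():
    a = np.zeros((5, 5), bool)
    b = np.zeros((5, 5), bool)
    assert dsc(a, b) == 1.0          # both empty
    a[0, 0] = True
    assert dsc(a, b) == 0.0          # one empty
    b[4, 4] = True
    assert dsc(a, b) == 0.0          # disjoint nonempty
    assert dsc(a, b) == dsc(b, a)
    with pytest.raises(ValueError):
        dsc(a, np.zeros((4, 4), bool))


def test_single_point_distance_is_euclidean():
    a = np.zeros((6, 6), bool)
    b = np.zeros((6, 6), bool)
    a[0, 0] = True
    b[3, 4] = True
    assert hd95(a, b) == pytest.approx(5.0)
    assert asd(a, b) == pytest.approx(5.0)
    assert directional_h95(np.array([[0, 0]]), np.array([[3, 4]])) == pytest.approx(5.0)


def test_directional_h95_nearest_rank_with_outlier():
    # 20 points at distance 1 and one at distance 100: ceil(0.95*21)=20th
    # order statistic -> the outlier is excluded.
    a = np.array([[i, 1] for i in range(20)] + [[100, 100]], dtype=float)
    b = np.array([[i, 0] for i in range(20)] + [[100, 0]], dtype=float)
    assert directional_h95(a, b) == pytest.approx(1.0)


def test_hd95_symmetric_asd_directional():
    a = np.zeros((16, 16), bool)
    b = np.zeros((16, 16), bool)
    a[4:12, 4:12] = True
    b[4:12, 4:6] = True  # thin slab inside a
    assert hd95(a, b) == pytest.approx(hd95(b, a))
    assert asd(a, b) != pytest.approx(asd(b, a))  # Eq.-style ASD is one-directional
    sym = asd(a, b, symmetric=True)
    assert min(asd(a, b), asd(b, a)) <= sym <= max(asd(a, b), asd(b, a))


def test_identical_regions_are_zero_distance_unit_dsc():
    rng = np.random.default_rng(3)
    m = random_region(rng, 32, 32)
    assert dsc(m, m) == 1.0
    assert hd95(m, m) == 0.0
    assert asd(m, m) == 0.0


def test_empty_region_sentinel_is_image_diagonal():
    a = np.zeros((30, 40), bool)
    b = np.zeros((30, 40), bool)
    b[10:15, 10:15] = True
    val, flag = hd95(a, b, return_flag=True)
    assert flag and val == pytest.approx(np.hypot(30, 40))
    val, flag = hd95(a, np.zeros((30, 40), bool), return_flag=True)
    assert not flag and val == 0.0


def test_dsc_translation_invariance():
    rng = np.random.default_rng(5)
    a = random_region(rng, 20, 20)
    b = random_region(rng, 20, 20)
    pa = np.zeros((30, 30), bool)
    pb = np.zeros((30, 30), bool)
    pa[2:22, 3:23], pb[2:22, 3:23] = a, b
    qa = np.zeros((30, 30), bool)
    qb = np.zeros((30, 30), bool)
    qa[7:27, 5:25], qb[7:27, 5:25] = a, b
    assert dsc(pa, pb) == pytest.approx(dsc(qa, qb))


def test_boundary_points_match_brute_force():
    rng = np.random.default_rng(11)
    for _ in range(20):
        m = random_region(rng, 15, 17)
        got = {tuple(p) for p in boundary_points(m)}
        exp = {tuple(map(int, p)) for p in brute_boundary(m)}
        assert got == exp


# ---------------------------------------------------------------------------
# bootstrap CI
# ---------------------------------------------------------------------------

def test_bootstrap_ci_degenerate_deterministic_and_bounded():
    lo, hi = bootstrap_ci([0.9] * 10, seed=1)
    assert (lo, hi) == (0.9, 0.9)

    vals = [0.0, 1.0] * 12 + [1.0]
    lo, hi = bootstrap_ci(vals, reps=10_000, seed=7)
    assert 0.0 < lo < np.mean(vals) < hi < 1.0

    a = bootstrap_ci(np.linspace(0.7, 1.0, 25), reps=10_000, seed=42)
    b = bootstrap_ci(np.linspace(0.7, 1.0, 25), reps=10_000, seed=42)
    assert a == b

    with pytest.raises(ValueError):
        bootstrap_ci([])


# ---------------------------------------------------------------------------
# dataset-level evaluation
# ---------------------------------------------------------------------------

def _phantom_masks(n=5, size=48, seed=0):
    rng = np.random.default_rng(seed)
    masks = []
    for _ in range(n):
        m = np.zeros((size, size), np.uint8)
        rr, cc = np.mgrid[0:size, 0:size]
        cy, cx = rng.integers(16, size - 16, 2)
        r = rng.integers(8, 14)
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        m[d2 <= r * r] = 1
        m[d2 <= (r // 2) ** 2] = 2
        masks.append(m)
    return masks


def test_evaluate_dataset_perfect_predictions():
    masks = _phantom_masks()
    rep = evaluate_dataset(masks, masks, num_classes=3, reps=200, seed=0)
    for region in ("OD", "OC"):
        entry = rep.summary["regions"][region]
        assert entry["dsc_mean"] == 1.0
        assert entry["dsc_ci95"] == [1.0, 1.0]
        assert entry["hd95_mean"] == 0.0
        assert entry["asd_mean"] == 0.0


def test_evaluate_dataset_single_image_degenerate_ci():
    masks = _phantom_masks(n=1)
    pred = [np.roll(masks[0], 1, axis=0)]
    rep = evaluate_dataset(pred, masks, num_classes=3, reps=500, seed=0)
    od = rep.summary["regions"]["OD"]
    assert od["dsc_ci95"][0] == pytest.approx(od["dsc_mean"])
    assert od["dsc_ci95"][1] == pytest.approx(od["dsc_mean"])


def test_evaluate_dataset_dilated_masks_match_independent_recount():
    from scipy.ndimage import binary_dilation

    masks = _phantom_masks(n=6, seed=3)
    preds = []
    for m in masks:
        od = binary_dilation(m >= 1)
        oc = binary_dilation(m == 2)
        p = np.zeros_like(m)
        p[od] = 1
        p[oc] = 2
        preds.append(p)
    rep = evaluate_dataset(preds, masks, num_classes=3, reps=100, seed=0,
                           with_distances=False)
    expected_od = np.mean([brute_dsc(p >= 1, g >= 1) for p, g in zip(preds, masks)])
    expected_oc = np.mean([brute_dsc(p == 2, g == 2) for p, g in zip(preds, masks)])
    assert rep.summary["regions"]["OD"]["dsc_mean"] == pytest.approx(expected_od, abs=0)
    assert rep.summary["regions"]["OC"]["dsc_mean"] == pytest.approx(expected_oc, abs=0)
    assert mean_foreground_dsc(preds, masks, 3) == pytest.approx(
        np.mean([expected_od, expected_oc]), abs=1e-12)


def test_evaluate_dataset_errors_and_regions():
    masks = _phantom_masks(n=2)
    with pytest.raises(ValueError):
        evaluate_dataset(masks, masks[:1], num_classes=3)
    regions = regions_from_labels(masks[0], 3)
    assert set(regions) == {"OD", "OC"}
    assert (regions["OC"] <= regions["OD"]).all()
    assert set(regions_from_labels(masks[0], 2)) == {"OD"}


def test_report_files_roundtrip(tmp_path):
    masks = _phantom_masks(n=3)
    rep = evaluate_dataset(masks, masks, num_classes=3, reps=50, seed=0)
    path = rep.to_files(tmp_path)
    assert path.exists()
    assert (tmp_path / "metrics_per_image.csv").exists()
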