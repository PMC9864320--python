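"""Metric correctness against brute-force oracles and printed conventions."""

import math

import numpy as np
import pytest

import lesionseg as ls
from lesionseg.errors import ValidationError
from lesionseg.metrics import ContourSet


# ---------------------------------------------------------------------
# brute-force oracles (deliberately naive)

def _confusion_loop(pred, gt):
    tp = fp = fn = tn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, g = pred[i, j], gt[i, j]
            if p and g:
                tp += 1
            elif p and not g:
                fp += 1
            elif not p and g:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def _contour_loop(mask):
    h, w = mask.shape
    pts = set()
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not mask[ni, nj]:
                    pts.add((i, j))
                    break
    return pts


def _hausdorff_loop(a_pts, b_pts, symmetric):
    def directed(src, dst):
        return max(min(math.dist(p, q) for q in dst) for p in src)

    fwd = directed(a_pts, b_pts)
    return max(fwd, directed(b_pts, a_pts)) if symmetric else fwd


# ---------------------------------------------------------------------

class TestConfusion:
    def test_all_ones(self):
        ones = np.ones((4, 4), dtype=np.uint8)
        c = ls.confusion(ones, ones)
        assert (c.tp, c.fp, c.fn, c.tn) == (16, 0, 0, 0)

    def test_complement(self, checkerboard_mask):
        c = ls.confusion(1 - checkerboard_mask, checkerboard_mask)
        assert c.tp == 0 and c.tn == 0

    def test_matches_loop_oracle(self, rng):
        p = rng.integers(0, 2, (16, 16)).astype(np.uint8)
        g = rng.integers(0, 2, (16, 16)).astype(np.uint8)
        c = ls.confusion(p, g)
        assert (c.tp, c.fp, c.fn, c.tn) == _confusion_loop(p, g)
        assert c.total == 256

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError):
            ls.confusion(np.full((4, 4), 2), np.zeros((4, 4)))


class TestOverlapMetrics:
    def test_printed_example(self):
        dsc, iou, pre, rec = ls.overlap_metrics(
            ls.ConfusionCounts(tp=2, fp=1, fn=1, tn=12))
        assert dsc == pytest.approx(400 / 6, abs=1e-9)
        assert iou == pytest.approx(50.0, abs=1e-9)
        assert pre == pytest.approx(400 / 6, abs=1e-9)
        assert rec == pytest.approx(400 / 6, abs=1e-9)

    def test_perfect_prediction_all_hundred(self, checkerboard_mask):
        c = ls.confusion(checkerboard_mask, checkerboard_mask)
        assert ls.overlap_metrics(c) == (100.0,) * 4

    def test_dsc_iou_identity(self, rng):
        for _ in range(20):
            p = rng.integers(0, 2, (12, 12)).astype(np.uint8)
            g = rng.integers(0, 2, (12, 12)).astype(np.uint8)
            dsc, iou, _, _ = ls.overlap_metrics(ls.confusion(p, g))
            assert dsc == pytest.approx(200 * iou / (100 + iou), abs=1e-9)
            assert iou <= dsc + 1e-12

    def test_zero_denominator_conventions(self):
        empty = np.zeros((4, 4), dtype=np.uint8)
        full = np.ones((4, 4), dtype=np.uint8)
        assert ls.overlap_metrics(ls.confusion(empty, empty)) == (100.0,) * 4
        dsc, iou, pre, rec = ls.overlap_metrics(ls.confusion(empty, full))
        assert (dsc, iou, pre, rec) == (0.0, 0.0, 0.0, 0.0)
        dsc, iou, pre, rec = ls.overlap_metrics(ls.confusion(full, empty))
        assert (dsc, iou, pre, rec) == (0.0, 0.0, 0.0, 0.0)


class TestContour:
    def test_solid_square_boundary(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[1:4, 1:4] = 1
        pts = {tuple(p) for p in ls.extract_contour(mask).points}
        assert len(pts) == 8 and (2, 2) not in pts

    def test_single_pixel(self):
        mask = np.zeros((3, 3), dtype=np.uint8)
        mask[1, 1] = 1
        assert {tuple(p) for p in ls.extract_contour(mask).points} == {(1, 1)}

    def test_full_frame_border_counts_as_background(self):
        mask = np.ones((4, 5), dtype=np.uint8)
        pts = {tuple(p) for p in ls.extract_contour(mask).points}
        border = {(i, j) for i in range(4) for j in range(5)
                  if i in (0, 3) or j in (0, 4)}
        assert pts == border

    def test_matches_loop_oracle(self, rng):
        mask = (rng.uniform(size=(12, 12)) < 0.4).astype(np.uint8)
        pts = {tuple(p) for p in ls.extract_contour(mask).points}
        assert pts == _contour_loop(mask)

    def test_empty_mask_flagged(self):
        cs = ls.extract_contour(np.zeros((4, 4), dtype=np.uint8))
        assert cs.is_empty


class TestHausdorff:
    def test_identical_sets_zero(self, rng):
        pts = rng.integers(0, 10, (7, 2))
        cs = ContourSet(points=pts)
        assert ls.hausdorff(cs, cs) == 0.0

    def test_three_four_five(self):
        a = ContourSet(points=np.array([[0, 0]]))
        b = ContourSet(points=np.array([[3, 4]]))
        assert ls.hausdorff(a, b, symmetric=False) == pytest.approx(5.0)
        assert ls.hausdorff(a, b, symmetric=True) == pytest.approx(5.0)

    def test_matches_all_pairs_oracle(self, rng):
        a = ContourSet(points=rng.integers(0, 20, (20, 2)))
        b = ContourSet(points=rng.integers(0, 20, (20, 2)))
        a_pts = [tuple(p) for p in a.points]
        b_pts = [tuple(p) for p in b.points]
        for sym in (True, False):
            assert ls.hausdorff(a, b, symmetric=sym) == pytest.approx(
                _hausdorff_loop(a_pts, b_pts, sym), abs=1e-9)

    def test_symmetric_is_symmetric_directed_is_not(self, rng):
        # b covers a, so HD(a->b) = 0 while HD(b->a) = 10
        a = ContourSet(points=np.array([[0, 0]]))
        b = ContourSet(points=np.array([[0, 0], [10, 0]]))
        assert ls.hausdorff(a, b) == ls.hausdorff(b, a)
        assert ls.hausdorff(a, b, symmetric=False) != \
            ls.hausdorff(b, a, symmetric=False)

    def test_empty_contour_is_nan(self):
        a = ContourSet(points=np.empty((0, 2), dtype=int))
        b = ContourSet(points=np.array([[1, 1]]))
        assert math.isnan(ls.hausdorff(a, b))


class TestRotationInvariance:
    def test_all_metrics_invariant_under_rot90(self, rng):
        p = (rng.uniform(size=(14, 14)) < 0.3).astype(np.uint8)
        g = (rng.uniform(size=(14, 14)) < 0.3).astype(np.uint8)
        p[3:6, 3:6] = 1
        g[4:7, 4:7] = 1

        def all_five(pm, gm):
            c = ls.confusion(pm, gm)
            hd = ls.hausdorff(ls.extract_contour(pm), ls.extract_contour(gm))
            return (*ls.overlap_metrics(c), hd)

        base = all_five(p, g)
        rot = all_five(np.rot90(p).copy(), np.rot90(g).copy())
        assert base == pytest.approx(rot, abs=1e-9)


class TestEvaluate:
    def test_single_perfect_image(self, checkerboard_mask):
        rep = ls.evaluate([checkerboard_mask], [checkerboard_mask], ["a"])
        agg = rep.aggregate
        for name in ("dsc", "iou", "pre", "rec"):
            assert agg[name] == (100.0, 0.0)
        assert agg["hdist"] == (0.0, 0.0)

    def test_identical_rows_have_zero_sd(self, rng):
        p = (rng.uniform(size=(10, 10)) < 0.4).astype(np.uint8)
        p[4:6, 4:6] = 1
        g = np.roll(p, 1, axis=0)
        rep = ls.evaluate([p, p], [g, g])
        for name, (_, sd) in rep.aggregate.items():
            assert sd == 0.0

    def test_aggregate_recomputable_from_rows(self, rng):
        preds = [(rng.uniform(size=(10, 10)) < 0.4).astype(np.uint8)
                 for _ in range(5)]
        gts = [(rng.uniform(size=(10, 10)) < 0.4).astype(np.uint8)
               for _ in range(5)]
        rep = ls.evaluate(preds, gts)
        df = rep.to_dataframe()
        for name in ("dsc", "iou", "pre", "rec"):
            col = df[name].to_numpy()
            assert rep.aggregate[name][0] == pytest.approx(col.mean())
            assert rep.aggregate[name][1] == pytest.approx(col.std(ddof=1))

    def test_accepts_prediction_maps(self, rng):
        mask = (rng.uniform(size=(8, 8)) < 0.5).astype(np.uint8)
        pm = ls.PredictionMap(probs=ls.mask_to_map(mask) * 0.98 + 0.01)
        rep = ls.evaluate([pm], [mask])
        assert rep.aggregate["dsc"][0] == 100.0

    def test_undefined_hausdorff_excluded_and_noted(self):
        empty = np.zeros((6, 6), dtype=np.uint8)
        some = np.zeros((6, 6), dtype=np.uint8)
        some[2:4, 2:4] = 1
        rep = ls.evaluate([empty, some], [some, some])
        assert math.isnan(rep.per_image[0]["hdist"])
        assert rep.aggregate["hdist"][0] == pytest.approx(0.0)
        assert any("undefined" in n for n in rep.notes)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            ls.evaluate([np.zeros((4, 4), dtype=np.uint8)], [])

    def test_csv_json_round_trip(self, tmp_path, rng):
        import json
        import pandas as pd
        p = (rng.uniform(size=(8, 8)) < 0.4).astype(np.uint8)
        rep = ls.evaluate([p], [p])
        rep.write(tmp_path / "per_image.csv", tmp_path / "agg.json")
        df = pd.read_csv(tmp_path / "per_image.csv")
        assert list(df["dsc"]) == [100.0]
        agg = json.loads((tmp_path / "agg.json").read_text())
        assert agg["dsc"]["mean"] == 100.0


# ---------------------------------------------------------------------
# property-based invariants

from hypothesis import given, settings, strategies as st  # noqa: E402


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_metric_invariants_on_random_masks(seed):
    """IoU <= DSC, DSC = 2*IoU/(1+IoU), symmetric Hausdorff symmetry."""
    r = np.random.default_rng(seed)
    p = (r.uniform(size=(10, 10)) < r.uniform(0.05, 0.95)).astype(np.uint8)
    g = (r.uniform(size=(10, 10)) < r.uniform(0.05, 0.95)).astype(np.uint8)
    dsc, iou, pre, rec = ls.overlap_metrics(ls.confusion(p, g))
    assert iou <= dsc + 1e-12
    assert dsc == pytest.approx(200 * iou / (100 + iou), abs=1e-9)
    assert 0.0 <= min(pre, rec) and max(pre, rec) <= 100.0
    cp, cg = ls.extract_contour(p), ls.extract_contour(g)
    if not (cp.is_empty or cg.is_empty):
        assert ls.hausdorff(cp, cg) == ls.hausdorff(cg, cp)
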