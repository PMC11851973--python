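"""Dispersion fixation detector and AOI assignment."""

import numpy as np
import pandas as pd
import pytest

from emosearch.gaze import (DispersionParams, assign_aoi, detect_fixations,
                            detect_session_fixations)


def naive_dispersion(t, x, y, valid, radius=2.5, min_dur=100.0, max_gap=75.0):
    """Plain re-statement of the rule, kept deliberately simple: grow a
    candidate while the next valid sample is within ``radius`` of the mean
    of the candidate's samples; emit on violation if duration > min_dur."""
    out = []
    cand = []  # list of (t, x, y)

    def flush():
        if cand and cand[-1][0] - cand[0][0] > min_dur:
            xs = [c[1] for c in cand]
            ys = [c[2] for c in cand]
            out.append((cand[0][0], cand[-1][0],
                        sum(xs) / len(xs), sum(ys) / len(ys), len(cand)))

    for ti, xi, yi, vi in zip(t, x, y, valid):
        if not vi:
            continue
        if cand and ti - cand[-1][0] > max_gap:
            flush()
            cand = []
        if not cand:
            cand = [(ti, xi, yi)]
            continue
        mx = sum(c[1] for c in cand) / len(cand)
        my = sum(c[2] for c in cand) / len(cand)
        if ((xi - mx) ** 2 + (yi - my) ** 2) ** 0.5 <= radius:
            cand.append((ti, xi, yi))
        else:
            flush()
            cand = [(ti, xi, yi)]
    flush()
    return out


def as_tuples(fixations):
    return [(f.start_ms, f.end_ms, f.x, f.y, f.n_samples) for f in fixations]


def cluster(t0, n, x, y, dt=1000.0 / 300.0):
    t = t0 + np.arange(n) * dt
    return t, np.full(n, float(x)), np.full(n, float(y))


def test_single_stationary_cluster_is_one_fixation():
    t, x, y = cluster(0.0, 61, 3.0, -2.0)  # spans 200 ms
    fx = detect_fixations((t, x, y, np.ones_like(t, bool)))
    assert len(fx) == 1
    assert fx[0].x == pytest.approx(3.0) and fx[0].y == pytest.approx(-2.0)
    assert fx[0].duration_ms == pytest.approx(200.0)


def test_two_clusters_with_invalid_gap():
    t1, x1, y1 = cluster(0.0, 46, 0.0, 0.0)      # 150 ms
    t_inv = t1[-1] + np.arange(1, 4) * (1000 / 300)
    t2, x2, y2 = cluster(t_inv[-1] + 1000 / 300, 46, 10.0, 0.0)
    t = np.concatenate([t1, t_inv, t2])
    x = np.concatenate([x1, np.zeros(3), x2])
    y = np.concatenate([y1, np.zeros(3), y2])
    valid = np.concatenate([np.ones(46), np.zeros(3), np.ones(46)]) > 0
    fx = detect_fixations((t, x, y, valid))
    assert len(fx) == 2
    assert fx[0].x == pytest.approx(0.0)
    assert fx[1].x == pytest.approx(10.0)


def test_short_cluster_discarded():
    t, x, y = cluster(0.0, 28, 1.0, 1.0)  # 90 ms span
    fx = detect_fixations((t, x, y, np.ones_like(t, bool)))
    assert fx == []


def test_empty_stream():
    assert detect_fixations((np.array([]),) * 4) == []


def test_unsorted_stream_rejected():
    with pytest.raises(ValueError, match="time-sorted"):
        detect_fixations((np.array([1.0, 0.5]), np.zeros(2), np.zeros(2),
                          np.ones(2, bool)))


def random_stream(rng, n=120):
    t = np.cumsum(rng.uniform(2.0, 5.0, n))
    # jumpy gaze: cluster centers with occasional saccades
    x = np.cumsum(rng.choice([0, 0, 0, 0, 5], n) * rng.choice([-1, 1], n)
                  + rng.normal(0, 0.4, n)).astype(float)
    y = np.cumsum(rng.choice([0, 0, 0, 0, 4], n) * rng.choice([-1, 1], n)
                  + rng.normal(0, 0.4, n)).astype(float)
    valid = rng.random(n) > 0.1
    return t, x, y, valid


def test_matches_naive_oracle_on_random_streams(rng):
    for _ in range(200):
        t, x, y, valid = random_stream(rng)
        got = as_tuples(detect_fixations((t, x, y, valid)))
        want = naive_dispersion(t, x, y, valid)
        assert len(got) == len(want)
        for g, w in zip(got, want):
            assert g[0] == pytest.approx(w[0]) and g[1] == pytest.approx(w[1])
            assert g[2] == pytest.approx(w[2]) and g[3] == pytest.approx(w[3])
            assert g[4] == w[4]


def test_invariant_to_surrounding_invalid_samples(rng):
    t, x, y, valid = random_stream(rng, n=80)
    base = as_tuples(detect_fixations((t, x, y, valid)))
    t2 = np.concatenate([t[:1] - 10, t, t[-1:] + 10])
    x2 = np.concatenate([[99.0], x, [99.0]])
    y2 = np.concatenate([[99.0], y, [99.0]])
    v2 = np.concatenate([[False], valid, [False]])
    assert as_tuples(detect_fixations((t2, x2, y2, v2))) == base


def test_scaling_coordinates_and_radius_together(rng):
    t, x, y, valid = random_stream(rng, n=100)
    k = 3.7
    a = detect_fixations((t, x, y, valid))
    b = detect_fixations((t, k * x, k * y, valid),
                         DispersionParams(radius_deg=2.5 * k))
    assert [(f.start_ms, f.end_ms, f.n_samples) for f in a] == \
        [(f.start_ms, f.end_ms, f.n_samples) for f in b]


class TestAoi:
    layout = [dict(x_deg=0.0, y_deg=0.0, slot=0, role="target",
                   image_id="t0"),
              dict(x_deg=7.0, y_deg=0.0, slot=1, role="distractor",
                   image_id="d1")]

    def make_fix(self, x, y):
        t, xs, ys = cluster(0.0, 61, x, y)
        return detect_fixations((t, xs, ys, np.ones(61, bool)))

    def test_centroid_on_target(self):
        fx = assign_aoi(self.make_fix(0.1, 0.2), self.layout)
        assert fx[0].aoi_slot == 0 and fx[0].aoi_role == "target"

    def test_centroid_outside_all_items(self):
        fx = assign_aoi(self.make_fix(3.5, 8.0), self.layout)
        assert fx[0].aoi_slot is None

    def test_padding_expands_hit_region(self):
        fx = assign_aoi(self.make_fix(1.5, 0.0), self.layout)
        assert fx[0].aoi_slot is None  # half-width is 1.25
        fx = assign_aoi(self.make_fix(1.5, 0.0), self.layout,
                        padding_deg=0.5)
        assert fx[0].aoi_slot == 0


def test_planted_visits_recovered_from_rendered_session(small_session):
    """Generator/analyzer round trip: planted item fixations are found with
    >= 99% mean interval overlap and the right AOI."""
    sd = small_session
    fx = detect_session_fixations(sd.gaze, sd.layouts)
    overlaps, aoi_hits = [], []
    for truth in sd.ground_truth["trials"]:
        sub = fx[fx.trial == truth["trial"]]
        for f in truth["fixations"]:
            if f["slot"] is None:
                continue
            best, best_slot = 0.0, None
            for r in sub.itertuples():
                inter = (min(f["end_ms"], r.end_ms)
                         - max(f["start_ms"], r.start_ms))
                frac = inter / (f["end_ms"] - f["start_ms"])
                if frac > best:
                    best, best_slot = frac, r.aoi_slot
            overlaps.append(best)
            aoi_hits.append(best_slot == f["slot"])
    assert np.mean(overlaps) >= 0.99
    assert np.mean(aoi_hits) >= 0.99
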