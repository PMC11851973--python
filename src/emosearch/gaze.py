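"""Dispersion-based fixation detection and area-of-interest assignment.

The detector is a greedy left-to-right pass over a time-sorted gaze stream:
a candidate fixation grows while the next valid sample lies within a fixed
radius of the running centroid of the samples already in the candidate.
When a sample violates the radius, the candidate is emitted if its duration
strictly exceeds the minimum and a new candidate starts at the violating
sample.  Invalid samples (blinks, tracking loss) are skipped without
terminating a candidate unless the gap they create exceeds ``max_gap_ms``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synth import ITEM_HEIGHT_DEG, ITEM_WIDTH_DEG


@dataclass(frozen=True)
class DispersionParams:
    """Dispersion-detector thresholds.

    radius_deg: maximum distance (degrees) of a sample from the running
        centroid for it to join the candidate.
    min_duration_ms: a candidate becomes a fixation only if its duration is
        strictly greater than this.
    max_gap_ms: a run of consecutive invalid samples longer than this
        terminates the candidate (blink handling).
    """

    radius_deg: float = 2.5
    min_duration_ms: float = 100.0
    max_gap_ms: float = 75.0

    def __post_init__(self):
        if self.radius_deg <= 0 or self.min_duration_ms <= 0:
            raise ValueError("radius and minimum duration must be positive")


@dataclass
class Fixation:
    start_ms: float
    end_ms: float
    x: float
    y: float
    n_samples: int
    aoi_slot: int | None = None
    aoi_role: str | None = None
    image_id: str | None = None

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


def _as_arrays(samples):
    if isinstance(samples, pd.DataFrame):
        t = samples["t_ms"].to_numpy(dtype=float)
        x = samples["x_deg"].to_numpy(dtype=float)
        y = samples["y_deg"].to_numpy(dtype=float)
        if "validity" in samples.columns:
            v = samples["validity"].to_numpy()
            valid = (v == "valid") if v.dtype.kind in "OU" else v.astype(bool)
        else:
            valid = np.ones(len(t), dtype=bool)
    else:
        t, x, y, valid = (np.asarray(a) for a in samples)
        t = t.astype(float)
        valid = valid.astype(bool)
    if np.any(np.diff(t) < 0):
        raise ValueError("gaze samples must be time-sorted")
    return t, x, y, valid


def detect_fixations(samples, params: DispersionParams | None = None):
    """Segment a gaze stream into fixations with the dispersion rule.

    ``samples`` is either a DataFrame with columns ``t_ms, x_deg, y_deg,
    validity`` or a tuple of arrays ``(t, x, y, valid)``.  Returns a list of
    :class:`Fixation` ordered in time; an empty stream yields an empty list.
    """
    params = params or DispersionParams()
    t, x, y, valid = _as_arrays(samples)
    fixations: list[Fixation] = []

    sum_x = sum_y = 0.0
    n = 0
    start = last = np.nan

    def close():
        nonlocal sum_x, sum_y, n, start, last
        if n > 0 and (last - start) > params.min_duration_ms:
            fixations.append(Fixation(start_ms=float(start),
                                      end_ms=float(last),
                                      x=sum_x / n, y=sum_y / n, n_samples=n))
        sum_x = sum_y = 0.0
        n = 0
        start = last = np.nan

    for i in range(len(t)):
        if not valid[i]:
            continue
        if n > 0 and (t[i] - last) > params.max_gap_ms:
            close()
        if n == 0:
            sum_x, sum_y, n = x[i], y[i], 1
            start = last = t[i]
            continue
        cx, cy = sum_x / n, sum_y / n
        if np.hypot(x[i] - cx, y[i] - cy) <= params.radius_deg:
            sum_x += x[i]
            sum_y += y[i]
            n += 1
            last = t[i]
        else:
            close()
            sum_x, sum_y, n = x[i], y[i], 1
            start = last = t[i]
    close()
    return fixations


def assign_aoi(fixations, layout_items, item_width_deg: float = ITEM_WIDTH_DEG,
               item_height_deg: float = ITEM_HEIGHT_DEG,
               padding_deg: float = 0.0):
    """Attribute each fixation to the display item whose rectangle contains
    its centroid.

    ``layout_items`` is an iterable of objects/rows with ``x_deg, y_deg,
    slot, role`` and optionally ``image_id`` (e.g. :class:`DisplayLayout`
    items or rows of the synth layout table).  The hit region is the drawn
    image rectangle (width x height) centered on the item, expanded by
    ``padding_deg`` on every side.  Fixations outside all rectangles keep
    ``aoi_slot=None``.  Returns a new list.
    """
    hw = item_width_deg / 2.0 + padding_deg
    hh = item_height_deg / 2.0 + padding_deg
    items = []
    for it in layout_items:
        get = (it.get if isinstance(it, dict)
               else lambda k, _it=it: getattr(_it, k, None))
        items.append((float(get("x_deg")), float(get("y_deg")),
                      int(get("slot")), get("role"), get("image_id")))
    out = []
    for f in fixations:
        hit = None
        for x, y, slot, role, image_id in items:
            if abs(f.x - x) <= hw and abs(f.y - y) <= hh:
                hit = (slot, role, image_id)
                break
        if hit is None:
            out.append(replace(f, aoi_slot=None, aoi_role=None,
                               image_id=None))
        else:
            out.append(replace(f, aoi_slot=hit[0], aoi_role=hit[1],
                               image_id=hit[2]))
    return out


def fixations_frame(fixations, **extra) -> pd.DataFrame:
    """Tabulate fixations; ``extra`` columns (participant, trial, ...) are
    broadcast to every row."""
    rows = [dict(start_ms=f.start_ms, end_ms=f.end_ms, x=f.x, y=f.y,
                 n_samples=f.n_samples, aoi_slot=f.aoi_slot,
                 aoi_role=f.aoi_role, image_id=f.image_id, **extra)
            for f in fixations]
    return pd.DataFrame(rows)


def detect_session_fixations(gaze: pd.DataFrame, layouts: pd.DataFrame,
                             params: DispersionParams | None = None,
                             **aoi_kwargs) -> pd.DataFrame:
    """Run detection + AOI assignment over every trial of a session table."""
    frames = []
    for (p, tr), g in gaze.groupby(["participant", "trial"], sort=True):
        fx = detect_fixations(g, params)
        lay = layouts[(layouts.participant == p) & (layouts.trial == tr)]
        fx = assign_aoi(fx, lay.to_dict("records"), **aoi_kwargs)
        if fx:
            frames.append(fixations_frame(fx, participant=p, trial=tr))
    if not frames:
        return pd.DataFrame(columns=["start_ms", "end_ms", "x", "y",
                                     "n_samples", "aoi_slot", "aoi_role",
                                     "image_id", "participant", "trial"])
    return pd.concat(frames, ignore_index=True)
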