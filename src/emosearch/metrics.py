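"""Per-trial decomposition of search behavior and sequential trial exclusion.

Each correct trial is decomposed into:

* RT  -- display onset to button press,
* ST  -- onset to the start of the first target fixation (attentional part),
* TIT -- first target fixation to the press (perceptual part),
* DS  -- number of distractor visits before the target is first fixated,
* DRT -- mean dwell on those pre-target distractor visits,
* FFT -- whether the first item fixated was the target.

Consecutive fixations on the same item are merged into a single visit before
counting, so micro-refixations are not double-counted; dwell is the summed
duration of a merged visit.  A trial is correct only if a button press
occurred and the item fixated at press time is the target (gaze-determined
correctness); trials without a press within the 5 s deadline are incorrect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import RESPONSE_DEADLINE_MS


@dataclass
class TrialMetrics:
    rt_ms: float
    st_ms: float
    tit_ms: float
    ds: float
    drt_ms: float
    fft: bool
    correct: bool


@dataclass
class Visit:
    """A merged run of consecutive fixations on the same item."""

    start_ms: float
    end_ms: float
    dwell_ms: float  # summed fixation durations within the visit
    aoi_slot: int | None
    aoi_role: str | None
    image_id: str | None


def merge_visits(fixations) -> list:
    """Collapse consecutive same-item fixations into visits.

    ``fixations`` is an iterable of objects or dict-like rows with
    ``start_ms, end_ms, aoi_slot, aoi_role, image_id``, time-ordered.
    Fixations not on any item (aoi_slot is None/NaN) are kept as their own
    visits and never merged.
    """
    visits: list[Visit] = []
    for f in fixations:
        get = (f.get if isinstance(f, dict)
               else lambda k, _f=f: getattr(_f, k, None))
        slot = get("aoi_slot")
        if slot is not None and not (isinstance(slot, float) and math.isnan(slot)):
            slot = int(slot)
        else:
            slot = None
        start, end = float(get("start_ms")), float(get("end_ms"))
        if (visits and slot is not None and visits[-1].aoi_slot == slot):
            last = visits[-1]
            last.end_ms = end
            last.dwell_ms += end - start
        else:
            visits.append(Visit(start_ms=start, end_ms=end,
                                dwell_ms=end - start, aoi_slot=slot,
                                aoi_role=get("aoi_role"),
                                image_id=get("image_id")))
    return visits


def compute_trial_metrics(press_ms, fixations,
                          deadline_ms: float = RESPONSE_DEADLINE_MS,
                          ) -> TrialMetrics:
    """Score one trial from its button-press time and AOI-annotated fixations.

    ``press_ms`` may be NaN/None for a timeout.  Only item visits (fixations
    landing on a target or distractor) enter DS/FFT/DRT; the initial central
    fixation and background fixations are ignored, so "first fixation" means
    the first fixation on any display item.
    """
    visits = merge_visits(fixations)
    item_visits = [v for v in visits if v.aoi_role in ("target", "distractor")]

    no_press = (press_ms is None
                or (isinstance(press_ms, float) and math.isnan(press_ms))
                or press_ms > deadline_ms)

    target_visit = next((v for v in item_visits if v.aoi_role == "target"),
                        None)

    correct = True
    if no_press or target_visit is None:
        correct = False
    else:
        # gaze-determined correctness: the item looked at when the button
        # was pressed must be the target
        at_press = None
        for v in item_visits:
            if v.start_ms <= press_ms:
                at_press = v
            else:
                break
        correct = at_press is not None and at_press.aoi_role == "target"

    if not correct:
        return TrialMetrics(rt_ms=float(press_ms) if not no_press else np.nan,
                            st_ms=np.nan, tit_ms=np.nan, ds=np.nan,
                            drt_ms=np.nan,
                            fft=bool(item_visits
                                     and item_visits[0].aoi_role == "target"),
                            correct=False)

    pre_target = []
    for v in item_visits:
        if v is target_visit:
            break
        if v.aoi_role == "distractor":
            pre_target.append(v)
    ds = len(pre_target)
    st = target_visit.start_ms
    rt = float(press_ms)
    return TrialMetrics(
        rt_ms=rt, st_ms=st, tit_ms=rt - st, ds=ds,
        drt_ms=float(np.mean([v.dwell_ms for v in pre_target]))
        if ds > 0 else np.nan,
        fft=(ds == 0), correct=True)


def compute_metrics_table(trials: pd.DataFrame, fixations: pd.DataFrame,
                          ) -> pd.DataFrame:
    """Score every trial of a session; returns one row per trial with the
    six measures plus the trial's condition/emotion factors."""
    fx_by_trial = dict(tuple(fixations.groupby(["participant", "trial"])))
    rows = []
    for tr in trials.itertuples():
        key = (tr.participant, tr.trial)
        fx = fx_by_trial.get(key)
        fx_rows = (fx.sort_values("start_ms").to_dict("records")
                   if fx is not None else [])
        m = compute_trial_metrics(tr.press_ms, fx_rows)
        rows.append(dict(participant=tr.participant, trial=tr.trial,
                         block=tr.block, condition=tr.condition,
                         target_emotion=tr.target_emotion,
                         rt_ms=m.rt_ms, st_ms=m.st_ms, tit_ms=m.tit_ms,
                         ds=m.ds, drt_ms=m.drt_ms, fft=m.fft,
                         correct=m.correct))
    return pd.DataFrame(rows)


def apply_exclusions(metrics: pd.DataFrame, sd_multiplier: float = 2.0,
                     rt_floor_ms: float = 100.0,
                     ) -> tuple[pd.DataFrame, dict]:
    """Apply the sequential trial-exclusion procedure.

    Stages, in order: (1) drop incorrect trials; (2) drop trials with
    RT < ``rt_floor_ms`` or RT more than ``sd_multiplier`` SDs from the
    participant's mean RT; (3) the same mean/SD rule on ST over the trials
    surviving stage 2; (4) the same on TIT.  Each stage recomputes the
    per-participant mean and SD over the trials that survived the previous
    stage only, so the procedure is deliberately order-dependent and not
    idempotent.  SD uses the n-1 denominator; participants with fewer than
    3 surviving trials skip the SD rule at that stage (logged).

    Returns ``(surviving trials, exclusion log)``.
    """
    log: dict = {"n_input": int(len(metrics)), "sd_denominator": "n-1",
                 "warnings": []}
    df = metrics[metrics["correct"].astype(bool)].copy()
    log["n_incorrect"] = int(len(metrics) - len(df))

    def sd_stage(df: pd.DataFrame, col: str, floor: float | None):
        keep = pd.Series(True, index=df.index)
        if floor is not None:
            keep &= df[col] >= floor
        for p, grp in df.groupby("participant"):
            if len(grp) < 3:
                log["warnings"].append(
                    f"participant {p}: <3 trials at stage '{col}', "
                    f"SD rule skipped")
                continue
            m, s = grp[col].mean(), grp[col].std(ddof=1)
            keep.loc[grp.index] &= (grp[col] - m).abs() <= sd_multiplier * s
        return df[keep]

    for col, floor, key in (("rt_ms", rt_floor_ms, "n_rt"),
                            ("st_ms", None, "n_st"),
                            ("tit_ms", None, "n_tit")):
        before = len(df)
        df = sd_stage(df, col, floor)
        log[key] = before - len(df)
    log["n_surviving"] = int(len(df))
    return df, log
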