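"""Per-image behavioral metrics, standardized within task condition.

Trial-level gaze behavior is aggregated over all participants and trials
into three metrics per distractor image and task condition:

* ``fem``       -- first eye movements received / times presented,
* ``selection`` -- later visits received (excluding a first eye movement) /
                   times presented,
* ``decision``  -- mean dwell time (ms) over merged visits.

Only images fixated at least once within a task enter the table.  Metrics
are z-scored separately per task, and each is also cut into quartile labels
(1 = lowest) for the classification arm of the decoding stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import merge_visits


def quartile_labels(values) -> np.ndarray:
    """Rank-based quartile labels 1..4 (1 = lowest quartile).

    Groups are as equal as possible (sizes differ by at most one; any
    remainder goes to the lower quartiles).  Ties are broken by stable input
    order, so the labeling is deterministic and permutation-equivariant up
    to tie order.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 4:
        raise ValueError("need at least 4 values to form quartiles")
    order = np.argsort(v, kind="stable")
    sizes = [n // 4 + (1 if i < n % 4 else 0) for i in range(4)]
    labels = np.empty(n, dtype=int)
    pos = 0
    for q, size in enumerate(sizes, start=1):
        labels[order[pos:pos + size]] = q
        pos += size
    return labels


def aggregate_image_behavior(fixations: pd.DataFrame, trials: pd.DataFrame,
                             layouts: pd.DataFrame,
                             roles: tuple = ("distractor",),
                             standardize: bool = True) -> pd.DataFrame:
    """Build the per-image x task behavior table from AOI-annotated fixations.

    ``fixations`` must carry participant/trial/start_ms/end_ms/aoi_role/
    image_id columns; ``layouts`` supplies how often each image was presented
    per task.  Aggregation pools all participants and trials.  Returns one
    row per (image_id, condition) with raw, z-scored and quartile columns.
    """
    cond_by_trial = trials.set_index(["participant", "trial"])["condition"]

    pres = (layouts[layouts.role.isin(roles)]
            .groupby(["condition", "image_id"]).size()
            .rename("n_presentations"))

    stats: dict = {}

    def rec(cond, image_id):
        return stats.setdefault((cond, image_id),
                                {"fem": 0, "later": 0, "dwells": []})

    for (p, tr), fx in fixations.groupby(["participant", "trial"]):
        cond = cond_by_trial.get((p, tr))
        if cond is None:
            continue
        visits = merge_visits(fx.sort_values("start_ms").to_dict("records"))
        item_visits = [v for v in visits
                       if v.aoi_role in ("target", "distractor")]
        for i, v in enumerate(item_visits):
            if v.aoi_role not in roles:
                continue
            r = rec(cond, v.image_id)
            if i == 0:
                r["fem"] += 1
            else:
                r["later"] += 1
            r["dwells"].append(v.dwell_ms)

    rows = []
    for (cond, image_id), r in stats.items():
        if not r["dwells"]:
            continue
        n_pres = int(pres.get((cond, image_id), 0))
        if n_pres == 0:
            continue
        rows.append(dict(
            image_id=image_id, condition=cond, n_presentations=n_pres,
            fem=r["fem"] / n_pres, selection=r["later"] / n_pres,
            decision=float(np.mean(r["dwells"]))))
    df = pd.DataFrame(rows)
    if df.empty or not standardize:
        return df
    return standardize_image_behavior(df)


def standardize_image_behavior(df: pd.DataFrame) -> pd.DataFrame:
    """Add task-wise z-scores and quartile labels for the three metrics."""
    df = df.copy()
    for metric in ("fem", "selection", "decision"):
        zcol, qcol = f"z_{metric}", f"quartile_{metric}"
        df[zcol] = np.nan
        df[qcol] = -1
        for cond, grp in df.groupby("condition"):
            v = grp[metric].to_numpy(dtype=float)
            if v.size < 2 or np.std(v) == 0:
                raise ValueError(
                    f"cannot z-score metric '{metric}' in task '{cond}': "
                    f"fewer than 2 distinct values")
            df.loc[grp.index, zcol] = (v - v.mean()) / v.std()
            df.loc[grp.index, qcol] = quartile_labels(v)
    return df
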