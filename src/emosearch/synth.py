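"""Synthetic stimuli, displays, and eye-tracked search sessions.

The generator emulates a three-condition visual-search experiment: on every
trial eight face-like items (one target, seven distractors) are shown on a
16-position grid inside a 28 x 22 degree display, the participant scans
distractors until the target is fixated and then presses a button.  Sessions
are blocked (12 blocks of 32 trials) with a mirrored, counterbalanced
condition order.  All planted quantities -- task and emotion multipliers on
identification and dwell times, and linear feature-to-behavior mappings --
are recorded as ground truth so downstream stages can be validated against
them.

Two rendering levels are available: ``simulate_session(render_gaze=True)``
emits a 300 Hz gaze stream built from the latent scanpath, while
``render_gaze=False`` returns only the latent per-trial timing (the same
draws the gaze stream would be rendered from), which is what large
parameter-recovery simulations consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import N_FEATURES, N_FREQ_BANDS, N_ORIENT_BANDS, bin_masks

# ---------------------------------------------------------------------------
# display geometry
# ---------------------------------------------------------------------------

DISPLAY_WIDTH_DEG = 28.0
DISPLAY_HEIGHT_DEG = 22.0
N_POSITIONS = 16  # 4 main quadrants x 4 sub-quadrants
N_ITEMS = 8  # 1 target + 7 distractors
JITTER_X_DEG = 1.0
JITTER_Y_DEG = 0.23
ITEM_WIDTH_DEG = 2.5
ITEM_HEIGHT_DEG = 4.5
RESPONSE_DEADLINE_MS = 5000.0

CONDITIONS = ("find_angry", "find_happy", "find_both")
DISPLAY_EMOTIONS = ("angry", "happy", "calm", "neutral",
                    "disgust", "fear", "sad", "surprise")
BLEND_EMOTIONS = ("anger", "calm", "disgust", "fear", "neutral",
                  "sad", "surprise")

#: Per-participant completed-trial counts of the reference cohort
#: (27 complete 384-trial sessions plus two partial sessions).
PARTICIPANT_TRIAL_COUNTS = (384,) * 27 + (306, 256)


def cohort_trial_count(counts=PARTICIPANT_TRIAL_COUNTS) -> int:
    """Total trials contributed by a cohort of per-participant counts."""
    return int(sum(counts))


def stimulus_pool_size(actors_per_combination: int = 254,
                       n_genders: int = 2,
                       n_emotions: int = len(BLEND_EMOTIONS)) -> int:
    """Number of unique blended stimuli: actor pairings x gender x emotion."""
    return int(actors_per_combination * n_genders * n_emotions)


def subquadrant_centers() -> np.ndarray:
    """Centers (x, y in degrees, screen-centered) of the 16 sub-quadrants.

    The display rectangle is split into 4 main quadrants, each split again
    into 4 sub-quadrants, giving a 4 x 4 grid.  Index = row * 4 + col with
    row 0 at the top.
    """
    xs = (np.arange(4) - 1.5) * (DISPLAY_WIDTH_DEG / 4.0)
    ys = (1.5 - np.arange(4)) * (DISPLAY_HEIGHT_DEG / 4.0)
    centers = np.array([(xs[c], ys[r]) for r in range(4) for c in range(4)])
    return centers


def main_quadrant(sub_quadrant: int) -> int:
    """Main quadrant (0..3) containing a sub-quadrant index (0..15)."""
    if not 0 <= sub_quadrant < N_POSITIONS:
        raise ValueError("sub-quadrant index out of range")
    row, col = divmod(sub_quadrant, 4)
    return (row // 2) * 2 + (col // 2)


def mirrored_block_order(conditions=CONDITIONS, counterbalance: int = 0,
                         ) -> tuple[str, ...]:
    """The palindromic block order X-Y-Z-X-Y-Z-Z-Y-X-Z-Y-X.

    ``counterbalance`` (0..5) selects which condition plays X, Y and Z.
    """
    from itertools import permutations

    perms = list(permutations(range(3)))
    assignment = perms[counterbalance % 6]
    pattern = [0, 1, 2, 0, 1, 2, 2, 1, 0, 2, 1, 0]
    return tuple(conditions[assignment[i]] for i in pattern)


# ---------------------------------------------------------------------------
# texture images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageSpec:
    """Recipe for a synthetic texture with prescribed band energies.

    ``band_energy_targets`` maps (frequency_band 0..23, orientation_band
    0..15) to a nonnegative target for the summed Fourier magnitude in that
    bin.  The texture is a sum of oriented sinusoidal gratings, one per
    requested bin, with seeded random phases.
    """

    width_px: int
    height_px: int
    band_energy_targets: dict = field(default_factory=dict)
    mean_luminance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        for (fb, ob), e in self.band_energy_targets.items():
            if not (0 <= fb < N_FREQ_BANDS and 0 <= ob < N_ORIENT_BANDS):
                raise ValueError(f"bin ({fb}, {ob}) out of range")
            if not np.isfinite(e) or e < 0:
                raise ValueError("band energies must be finite and >= 0")


def _bin_representatives(height: int, width: int) -> dict:
    """Pick, for each feature bin, an integer wavevector inside the bin.

    Preference goes to the coefficient nearest the bin's log-frequency /
    orientation center; wavevectors on the Nyquist lines are avoided so a
    real cosine always has a clean conjugate pair.
    """
    freq_band, orient_band, edges = bin_masks(height, width)
    ky = np.fft.fftfreq(height, d=1.0 / height)
    kx = np.fft.fftfreq(width, d=1.0 / width)
    KX, KY = np.meshgrid(kx, ky)
    radius = np.hypot(KX, KY)
    theta = np.degrees(np.arctan2(KY, KX)) % 180.0

    ok = (np.abs(KX) < width / 2.0 - 0.5) & (np.abs(KY) < height / 2.0 - 0.5)
    ok &= freq_band >= 0
    centers_f = np.sqrt(edges[:-1] * edges[1:])  # geometric band centers
    reps: dict[tuple[int, int], tuple[int, int]] = {}
    fb_f = freq_band[ok].ravel()
    ob_f = orient_band[ok].ravel()
    r_f = radius[ok].ravel()
    t_f = theta[ok].ravel()
    kx_f = KX[ok].ravel().astype(int)
    ky_f = KY[ok].ravel().astype(int)
    for fb in range(N_FREQ_BANDS):
        sel = fb_f == fb
        if not np.any(sel):
            continue
        for ob in np.unique(ob_f[sel]):
            s = sel & (ob_f == ob)
            t_center = (ob * 180.0 / N_ORIENT_BANDS)
            dt = np.abs((t_f[s] - t_center + 90.0) % 180.0 - 90.0)
            cost = np.abs(np.log(r_f[s] / centers_f[fb])) + dt / 90.0
            j = int(np.argmin(cost))
            reps[(fb, int(ob))] = (kx_f[s][j], ky_f[s][j])
    return reps


def make_texture_image(spec: ImageSpec) -> np.ndarray:
    """Render a grayscale texture whose binned Fourier energies approximate
    ``spec.band_energy_targets``; deterministic given ``spec.seed``.

    Each requested bin contributes one grating at an integer wavevector
    inside the bin, so the planted energy lands exactly in the intended
    feature.  A cosine of amplitude A contributes A * W * H of summed
    magnitude to its bin (both conjugate coefficients included).
    """
    h, w = spec.height_px, spec.width_px
    rng = np.random.default_rng(spec.seed)
    y, x = np.mgrid[0:h, 0:w]
    img = np.full((h, w), float(spec.mean_luminance))
    if spec.band_energy_targets:
        reps = _bin_representatives(h, w)
        for (fb, ob), energy in sorted(spec.band_energy_targets.items()):
            if energy == 0:
                continue
            if (fb, ob) not in reps:
                raise ValueError(
                    f"bin ({fb}, {ob}) has no representable wavevector at "
                    f"{w}x{h}")
            kx, ky = reps[(fb, ob)]
            phase = rng.uniform(0, 2 * np.pi)
            amp = energy / (w * h)
            img += amp * np.cos(2 * np.pi * (kx * x / w + ky * y / h) + phase)
    return img


def blend_halves(image_a, image_b, match_luminance: bool = True) -> np.ndarray:
    """Merge the top of one image into the bottom of another with a vertical
    cosine ramp.

    The ramp weight w(row) = 0.5 * (1 + cos(pi * row / (H - 1))) runs from 1
    at the top row to 0 at the bottom; the output row is
    ``w * a + (1 - w) * b`` after both inputs are rescaled to their common
    mean luminance (unless ``match_luminance`` is disabled).  Row weights sum
    to 1 everywhere, so the output mean equals the matched mean.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("inputs must be 2-D images of identical shape")
    if match_luminance:
        target = 0.5 * (a.mean() + b.mean())
        a = a * (target / a.mean()) if a.mean() != 0 else a + target
        b = b * (target / b.mean()) if b.mean() != 0 else b + target
    h = a.shape[0]
    rows = np.arange(h, dtype=float)
    w = 0.5 * (1.0 + np.cos(np.pi * rows / (h - 1))) if h > 1 else np.ones(1)
    w = w[:, None]
    return w * a + (1.0 - w) * b


# ---------------------------------------------------------------------------
# display layouts
# ---------------------------------------------------------------------------


@dataclass
class ItemPlacement:
    slot: int  # 0 = target, 1..7 distractors
    sub_quadrant: int
    x_deg: float
    y_deg: float
    role: str  # "target" | "distractor"
    emotion: str
    image_id: str


@dataclass
class DisplayLayout:
    items: list

    def __post_init__(self):
        roles = [it.role for it in self.items]
        if roles.count("target") != 1 or roles.count("distractor") != 7:
            raise ValueError("layout needs exactly 1 target and 7 distractors")
        subs = [it.sub_quadrant for it in self.items]
        if len(set(subs)) != len(subs):
            raise ValueError("two items share a sub-quadrant")
        tq = main_quadrant(self.target.sub_quadrant)
        dq = {main_quadrant(it.sub_quadrant) for it in self.distractors}
        if tq in dq:
            raise ValueError("distractor placed in the target's main quadrant")

    @property
    def target(self) -> ItemPlacement:
        return next(it for it in self.items if it.role == "target")

    @property
    def distractors(self) -> list:
        return [it for it in self.items if it.role == "distractor"]


class BlockSchedule:
    """Tracks remaining target positions within a block so that every one of
    the 16 positions serves as target position equally often."""

    def __init__(self, trials_per_block: int = 32):
        if trials_per_block % N_POSITIONS != 0:
            raise ValueError("trials per block must be a multiple of 16")
        per = trials_per_block // N_POSITIONS
        self.remaining = [p for p in range(N_POSITIONS) for _ in range(per)]

    def draw(self, rng: np.random.Generator) -> int:
        if not self.remaining:
            raise ValueError("block schedule exhausted")
        i = int(rng.integers(len(self.remaining)))
        return self.remaining.pop(i)


def make_layout(schedule: BlockSchedule, rng: np.random.Generator,
                target_emotion: str = "angry",
                distractor_emotions=None,
                image_ids=None) -> DisplayLayout:
    """Place one target and seven distractors on the 16-position grid.

    The target's sub-quadrant is drawn from the block schedule; the seven
    distractors are split {3, 2, 2} over the three non-target main quadrants
    and assigned distinct sub-quadrants within each.  Positions get uniform
    jitter of +-1 degree in x and +-0.23 degrees in y around the
    sub-quadrant centers.
    """
    centers = subquadrant_centers()
    target_sub = schedule.draw(rng)
    tq = main_quadrant(target_sub)
    other_quads = [q for q in range(4) if q != tq]
    sizes = [3, 2, 2]
    rng.shuffle(other_quads)

    if distractor_emotions is None:
        distractor_emotions = [e for e in DISPLAY_EMOTIONS
                               if e not in ("angry", "happy")]
    if image_ids is None:
        image_ids = [f"img{i:04d}" for i in range(N_ITEMS)]

    items = []

    def place(slot, sub, role, emotion, image_id):
        cx, cy = centers[sub]
        x = cx + rng.uniform(-JITTER_X_DEG, JITTER_X_DEG)
        y = cy + rng.uniform(-JITTER_Y_DEG, JITTER_Y_DEG)
        items.append(ItemPlacement(slot=slot, sub_quadrant=int(sub),
                                   x_deg=float(x), y_deg=float(y), role=role,
                                   emotion=emotion, image_id=image_id))

    place(0, target_sub, "target", target_emotion, image_ids[0])
    slot = 1
    for quad, size in zip(other_quads, sizes):
        subs_in_quad = [s for s in range(N_POSITIONS)
                        if main_quadrant(s) == quad]
        chosen = rng.choice(subs_in_quad, size=size, replace=False)
        for sub in chosen:
            emotion = distractor_emotions[int(rng.integers(len(distractor_emotions)))]
            place(slot, sub, "distractor", emotion, image_ids[slot])
            slot += 1
    return DisplayLayout(items=items)


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------


@dataclass
class PlantedEffects:
    """Ground-truth effect sizes injected into a simulated session.

    Ratios are multiplicative on the relevant mean: ``emotion_tit_ratio``
    scales target-identification time when the target is happy,
    ``emotion_drt_ratio`` scales distractor dwell when the target is happy,
    and ``task_ratio`` scales both when the task names a specific emotion
    (reference: find-both).  The two 384-vectors couple an image's band
    energies to its selection priority and its dwell time.
    """

    emotion_tit_ratio: float = 1.0
    emotion_drt_ratio: float = 1.0
    task_ratio: float = 1.0
    feature_selection_betas: np.ndarray | None = None
    feature_dwell_betas: np.ndarray | None = None

    def __post_init__(self):
        for name in ("feature_selection_betas", "feature_dwell_betas"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (N_FEATURES,):
                    raise ValueError(f"{name} must have length {N_FEATURES}")
                setattr(self, name, v)


@dataclass
class SessionConfig:
    """Parameters of a simulated blocked search session.

    Timing parameters are in milliseconds.  ``participant_sd`` is the SD of
    a log-normal participant effect that multiplies both dwell and
    identification means (a random intercept on the log scale).
    """

    n_blocks: int = 12
    trials_per_block: int = 32
    conditions: tuple = CONDITIONS
    counterbalance: int = 0
    planted: PlantedEffects = field(default_factory=PlantedEffects)
    n_images_per_emotion: int = 40
    base_tit_ms: float = 550.0
    base_dwell_ms: float = 250.0
    initial_latency_ms: float = 200.0
    saccade_ms: float = 25.0
    tit_shape: float = 10.0
    dwell_shape: float = 10.0
    min_dwell_ms: float = 110.0
    participant_sd: float = 0.10
    selection_noise_sd: float = 1.0
    error_rate: float = 0.08
    gaze_noise_sd_deg: float = 0.30
    sampling_hz: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks <= 0 or self.trials_per_block <= 0:
            raise ValueError("block structure must be positive")
        if len(self.conditions) != 3:
            raise ValueError("exactly three task conditions are required")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def condition_order(self) -> tuple:
        return mirrored_block_order(self.conditions, self.counterbalance)


@dataclass
class SessionData:
    """Output bundle of ``simulate_session``."""

    trials: pd.DataFrame
    layouts: pd.DataFrame
    gaze: pd.DataFrame | None
    ground_truth: dict
    image_features: pd.DataFrame


def _make_image_pool(cfg: SessionConfig, rng: np.random.Generator):
    """Feature vectors for the session's image pool (one per image id).

    Band energies are i.i.d. standard normal in feature space; real stimuli
    would be run through ``features.fourier_features`` instead -- the
    planted feature-to-behavior couplings only require the vectors, not the
    pixels.
    """
    emotions = DISPLAY_EMOTIONS
    ids, rows, emo = [], [], []
    for e in emotions:
        for i in range(cfg.n_images_per_emotion):
            ids.append(f"{e}_{i:03d}")
            emo.append(e)
            rows.append(rng.standard_normal(N_FEATURES))
    df = pd.DataFrame(rows, columns=[f"f{i:03d}" for i in range(N_FEATURES)])
    df.insert(0, "image_id", ids)
    df.insert(1, "emotion", emo)
    return df


def _plackett_luce_order(scores: np.ndarray, rng: np.random.Generator):
    """Sample a visiting order over items by softmax of their scores
    (Gumbel-max trick)."""
    g = rng.gumbel(size=scores.shape)
    return np.argsort(-(scores + g), kind="stable")


def simulate_session(cfg: SessionConfig, participant: int = 0,
                     render_gaze: bool = True) -> SessionData:
    """Simulate one participant's blocked search session.

    Per trial the latent scanpath is drawn first: a visiting order over the
    seven distractors (softmax over planted selection scores), the number of
    distractors inspected before the target, per-distractor dwells (gamma,
    log-mean shifted by the planted dwell betas and task/emotion
    multipliers), and the target-identification time (gamma, scaled by the
    planted emotion/task ratios).  The button press ends the trial; trials
    exceeding the 5 s deadline are scored as timeouts.  When ``render_gaze``
    is set, a 300 Hz gaze stream is rendered from the latent path with
    isotropic Gaussian noise around each fixation centroid.
    """
    root = np.random.SeedSequence([cfg.seed, participant])
    rng_layout, rng_path, rng_gaze, rng_pool = (
        np.random.default_rng(s) for s in root.spawn(4))

    pool = _make_image_pool(cfg, rng_pool)
    feat_cols = [f"f{i:03d}" for i in range(N_FEATURES)]
    feat_matrix = pool[feat_cols].to_numpy(dtype=float)
    pool_features = {img_id: feat_matrix[i]
                     for i, img_id in enumerate(pool["image_id"])}
    pool_by_emotion = {e: list(pool.loc[pool.emotion == e, "image_id"])
                       for e in DISPLAY_EMOTIONS}

    p_effect = float(np.exp(rng_path.normal(0.0, cfg.participant_sd)))
    planted = cfg.planted
    sel_beta = planted.feature_selection_betas
    dwell_beta = planted.feature_dwell_betas

    dt_ms = 1000.0 / cfg.sampling_hz
    trial_rows, layout_rows, gaze_rows = [], [], []
    truth_trials = []
    order = cfg.condition_order
    distractor_emotions = [e for e in DISPLAY_EMOTIONS
                           if e not in ("angry", "happy")]

    trial_no = 0
    for block in range(cfg.n_blocks):
        condition = order[block % len(order)]
        schedule = BlockSchedule(cfg.trials_per_block)
        for _ in range(cfg.trials_per_block):
            if condition == "find_angry":
                target_emotion = "angry"
            elif condition == "find_happy":
                target_emotion = "happy"
            else:
                target_emotion = ("angry", "happy")[int(rng_layout.integers(2))]
            d_imgs = [pool_by_emotion[e][int(rng_layout.integers(
                len(pool_by_emotion[e])))]
                for e in rng_layout.choice(distractor_emotions, size=7)]
            t_img = pool_by_emotion[target_emotion][
                int(rng_layout.integers(len(pool_by_emotion[target_emotion])))]
            layout = make_layout(
                schedule, rng_layout, target_emotion=target_emotion,
                distractor_emotions=distractor_emotions,
                image_ids=[t_img] + d_imgs)

            # latent scanpath ------------------------------------------------
            distractors = layout.distractors
            feats = np.array([pool_features[it.image_id]
                              for it in distractors])
            scores = (feats @ sel_beta if sel_beta is not None
                      else np.zeros(len(distractors)))
            scores = scores + rng_path.normal(
                0.0, cfg.selection_noise_sd, size=len(distractors))
            visit_order = _plackett_luce_order(scores, rng_path)

            is_error = rng_path.random() < cfg.error_rate
            if is_error:
                n_visited = int(rng_path.integers(1, 8))
            else:
                n_visited = int(rng_path.integers(0, 8))
            visited = [distractors[i] for i in visit_order[:n_visited]]

            task_mult = (planted.task_ratio
                         if condition in ("find_angry", "find_happy") else 1.0)
            emo_dwell = (planted.emotion_drt_ratio
                         if target_emotion == "happy" else 1.0)
            emo_tit = (planted.emotion_tit_ratio
                       if target_emotion == "happy" else 1.0)

            dwells = []
            for it in visited:
                mu = cfg.base_dwell_ms * task_mult * emo_dwell * p_effect
                if dwell_beta is not None:
                    mu *= float(np.exp(
                        pool_features[it.image_id] @ dwell_beta))
                d = rng_path.gamma(cfg.dwell_shape, mu / cfg.dwell_shape)
                dwells.append(max(d, cfg.min_dwell_ms))

            tit = rng_path.gamma(
                cfg.tit_shape,
                cfg.base_tit_ms * emo_tit * task_mult * p_effect
                / cfg.tit_shape)
            tit = max(tit, cfg.min_dwell_ms)

            # assemble timeline ---------------------------------------------
            path_items, path_durs = [], []
            t_cursor = cfg.initial_latency_ms
            for it, d in zip(visited, dwells):
                path_items.append(it)
                path_durs.append(d)
            press_ms = np.nan
            target_start = np.nan
            if is_error:
                # press while fixating the last distractor; target never seen
                starts = []
                for d in path_durs:
                    t_cursor += cfg.saccade_ms
                    starts.append(t_cursor)
                    t_cursor += d
                press_ms = starts[-1] + path_durs[-1] * 0.8
                correct = False
            else:
                starts = []
                for d in path_durs:
                    t_cursor += cfg.saccade_ms
                    starts.append(t_cursor)
                    t_cursor += d
                t_cursor += cfg.saccade_ms
                target_start = t_cursor
                press_ms = target_start + tit
                correct = press_ms <= RESPONSE_DEADLINE_MS
                if not correct:
                    press_ms = np.nan  # timeout: no response recorded

            st_true = target_start
            tit_true = press_ms - target_start if correct else np.nan
            ds_true = len(visited) if not is_error else np.nan
            drt_true = float(np.mean(dwells)) if (dwells and not is_error) else np.nan

            trial_rows.append(dict(
                participant=participant, trial=trial_no, block=block,
                condition=condition, target_emotion=target_emotion,
                press_ms=press_ms, correct=bool(correct),
                st_true=st_true, tit_true=tit_true, ds_true=ds_true,
                drt_true=drt_true,
                fft_true=(not is_error and n_visited == 0)))
            for it in layout.items:
                layout_rows.append(dict(
                    participant=participant, trial=trial_no, block=block,
                    condition=condition, slot=it.slot,
                    sub_quadrant=it.sub_quadrant, x_deg=it.x_deg,
                    y_deg=it.y_deg, role=it.role, emotion=it.emotion,
                    image_id=it.image_id))

            fix_intervals = [(0.0, starts[0] - cfg.saccade_ms if starts
                              else (target_start - cfg.saccade_ms
                                    if not is_error else press_ms),
                              0.0, 0.0, None)]
            for it, s, d in zip(path_items, starts, path_durs):
                fix_intervals.append((s, s + d, it.x_deg, it.y_deg, it.slot))
            if not is_error and correct:
                fix_intervals.append((target_start, press_ms,
                                      layout.target.x_deg,
                                      layout.target.y_deg, 0))
            truth_trials.append(dict(
                trial=trial_no,
                visit_slots=[it.slot for it in path_items],
                fixations=[dict(start_ms=s, end_ms=e, x=x, y=y, slot=sl)
                           for s, e, x, y, sl in fix_intervals
                           if e - s > 0]))

            if render_gaze:
                end_t = press_ms if np.isfinite(press_ms) else RESPONSE_DEADLINE_MS
                t = 0.0
                prev = (0.0, 0.0)
                segments = []
                for s, e, x, y, _slot in fix_intervals:
                    if s > t:
                        segments.append(("saccade", t, s, prev, (x, y)))
                    segments.append(("fix", s, e, (x, y), (x, y)))
                    prev = (x, y)
                    t = e
                for kind, s, e, p0, p1 in segments:
                    ts = np.arange(s, min(e, end_t), dt_ms)
                    if ts.size == 0:
                        continue
                    frac = ((ts - s) / (e - s)) if e > s else np.zeros_like(ts)
                    gx = p0[0] + frac * (p1[0] - p0[0])
                    gy = p0[1] + frac * (p1[1] - p0[1])
                    if kind == "fix":
                        gx = gx + rng_gaze.normal(0, cfg.gaze_noise_sd_deg,
                                                  ts.size)
                        gy = gy + rng_gaze.normal(0, cfg.gaze_noise_sd_deg,
                                                  ts.size)
                    for tt, xx, yy in zip(ts, gx, gy):
                        gaze_rows.append((participant, trial_no, block,
                                          condition, target_emotion,
                                          float(tt), float(xx), float(yy),
                                          "valid"))
            trial_no += 1

    trials = pd.DataFrame(trial_rows)
    layouts = pd.DataFrame(layout_rows)
    gaze = None
    if render_gaze:
        gaze = pd.DataFrame(
            gaze_rows,
            columns=["participant", "trial", "block", "condition",
                     "target_emotion", "t_ms", "x_deg", "y_deg", "validity"])
    truth = dict(
        participant=participant,
        participant_effect=p_effect,
        planted=dict(
            emotion_tit_ratio=planted.emotion_tit_ratio,
            emotion_drt_ratio=planted.emotion_drt_ratio,
            task_ratio=planted.task_ratio,
            feature_selection_betas=(
                None if sel_beta is None else sel_beta.tolist()),
            feature_dwell_betas=(
                None if dwell_beta is None else dwell_beta.tolist())),
        trials=truth_trials)
    return SessionData(trials=trials, layouts=layouts, gaze=gaze,
                       ground_truth=truth, image_features=pool)


def simulate_cohort_metrics(cfg: SessionConfig, n_participants: int,
                            ) -> pd.DataFrame:
    """Latent trial metrics for several participants (no gaze rendering).

    Returns one table in the shape the stats stage consumes: participant,
    condition, target_emotion, correct, rt/st/tit/ds/drt/fft columns.
    """
    frames = []
    for p in range(n_participants):
        sd = simulate_session(cfg, participant=p, render_gaze=False)
        t = sd.trials
        t = t.assign(rt_ms=t.press_ms, st_ms=t.st_true, tit_ms=t.tit_true,
                     ds=t.ds_true, drt_ms=t.drt_true, fft=t.fft_true)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# image-level datasets for the decoding stage
# ---------------------------------------------------------------------------


def make_feature_behavior_dataset(n_images: int, betas=None, snr: float = 2.0,
                                  seed: int = 0, n_signal_features: int = 5,
                                  beta_scale: float = 1.0):
    """Features plus a behavioral score carrying a planted linear signal.

    ``snr`` is the ratio var(X @ betas) / var(noise); ``snr = 0`` (or all-zero
    betas) yields a pure-noise score.  Returns ``(X, y, betas)``.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_images, N_FEATURES))
    if betas is None:
        betas = np.zeros(N_FEATURES)
        idx = rng.choice(N_FEATURES, size=n_signal_features, replace=False)
        betas[idx] = rng.normal(0, beta_scale, size=n_signal_features)
    betas = np.asarray(betas, dtype=float)
    signal = X @ betas
    if snr > 0 and np.any(betas != 0):
        noise_sd = np.std(signal) / np.sqrt(snr)
    else:
        signal = np.zeros(n_images)
        noise_sd = 1.0
    y = signal + rng.normal(0, noise_sd, size=n_images)
    return X, y, betas


def make_labeled_image_set(n_per_class: int, n_classes: int = 8,
                           signature_scale: float = 1.0, seed: int = 0):
    """Feature vectors with class-specific band signatures and a two-level
    grouping factor (for leakage-free group-held-out decoding).

    ``signature_scale = 0`` removes the class signal.  Returns
    ``(X, labels, groups)``.
    """
    rng = np.random.default_rng(seed)
    signatures = rng.standard_normal((n_classes, N_FEATURES)) * signature_scale
    X, labels, groups = [], [], []
    for g in range(2):
        for c in range(n_classes):
            X.append(signatures[c] + rng.standard_normal(
                (n_per_class, N_FEATURES)))
            labels.extend([c] * n_per_class)
            groups.extend([g] * n_per_class)
    return np.vstack(X), np.asarray(labels), np.asarray(groups)
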