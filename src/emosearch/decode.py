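"""Predicting per-image search behavior from band-energy features.

Two coupled approaches run over the same cross-validation splits:

1. *Regression*: on each of 10 iterations, a random third of the images is
   held out, a bidirectional stepwise linear model selects features on the
   remaining two thirds, and the held-out predictions are Spearman-correlated
   with the true scores.  A permutation null re-correlates the predictions
   against shuffled true scores.
2. *Classification*: the per-iteration stepwise-selected features feed a
   linear discriminant analysis predicting the quartile (1..4) of the metric;
   the null shuffles the held-out quartile labels.

Nulls are pooled over iterations; the observed mean performance is converted
to a z-score against the pooled null and to a one-sided normal-tail p-value.
A prediction counts as significant only if *both* arms beat ``alpha_joint``
(default 0.001).

Cross-condition transfer re-uses the iteration-averaged betas/intercept (and,
for classification, the features selected in more than one iteration) from a
source condition to predict a different condition's data, with the null built
by shuffling the target condition's data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .features import N_FEATURES

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class DecodingConfig:
    n_cv_iterations: int = 10
    holdout_fraction: float = 1.0 / 3.0
    n_perm_regression: int = 1000
    n_perm_decode: int = 10000
    entry_p: float = 0.05
    stay_p: float = 0.10
    max_features: int = 30
    alpha_joint: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.n_perm_regression < 100 or self.n_perm_decode < 100:
            raise ValueError("permutation counts must be >= 100")


@dataclass
class DecodingResult:
    """Pooled outcome of the cross-validated regression/decoding procedure.

    ``rho`` / ``frac_correct`` are means over CV iterations; ``null_*``
    summarize the pooled permutation distributions; the ``significant`` flag
    applies the joint rule (both p-values below ``alpha_joint``).  Fields of
    an arm that was not run stay None.
    """

    rho: float | None = None
    z_rho: float | None = None
    p_rho: float | None = None
    null_rho_mean: float | None = None
    null_rho_sd: float | None = None
    frac_correct: float | None = None
    z_decode: float | None = None
    p_decode: float | None = None
    null_decode_mean: float | None = None
    null_decode_sd: float | None = None
    alpha_joint: float = 0.001
    selected_features: list = field(default_factory=list)
    mean_betas: np.ndarray | None = None
    mean_intercept: float | None = None
    per_iteration_rho: list = field(default_factory=list)
    per_iteration_acc: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return (self.p_rho is not None and self.p_decode is not None
                and self.p_rho < self.alpha_joint
                and self.p_decode < self.alpha_joint)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["mean_betas"] = (None if self.mean_betas is None
                           else np.asarray(self.mean_betas).tolist())
        d["selected_features"] = [list(map(int, s))
                                  for s in self.selected_features]
        d["significant"] = self.significant
        return d


# ---------------------------------------------------------------------------
# stepwise regression
# ---------------------------------------------------------------------------


def stepwise_select(X: np.ndarray, y: np.ndarray, entry_p: float = 0.05,
                    stay_p: float = 0.10, max_features: int = 30,
                    ) -> list[int]:
    """Bidirectional stepwise feature selection for a linear model.

    Forward step: among features not in the model, enter the one with the
    smallest partial-F p-value if it is <= ``entry_p``.  Backward step: drop
    the in-model feature with the largest t-test p-value if it is >
    ``stay_p``.  Iterates until no change, revisiting a previous model
    state, or ``max_features`` is reached.
    """
    n = len(y)
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    selected: list[int] = []
    seen_states: set = set()
    while True:
        state = tuple(sorted(selected))
        if state in seen_states:
            break
        seen_states.add(state)
        changed = False

        # backward: t-tests on current coefficients
        if selected:
            Xs = Xc[:, selected]
            beta, res = _ols(Xs, yc)
            dfres = n - len(selected) - 1
            if dfres > 0:
                XtX_inv = np.linalg.pinv(Xs.T @ Xs)
                s2 = (res @ res) / dfres
                se = np.sqrt(np.clip(np.diag(XtX_inv) * s2, 1e-300, None))
                pvals = 2 * sps.t.sf(np.abs(beta / se), dfres)
                worst = int(np.argmax(pvals))
                if pvals[worst] > stay_p:
                    selected.pop(worst)
                    changed = True
                    continue

        # forward: partial F for every candidate
        if len(selected) < max_features:
            dfres = n - len(selected) - 2
            if dfres > 0:
                if selected:
                    Q, _ = np.linalg.qr(np.column_stack(
                        [np.ones(n), Xc[:, selected]]))
                else:
                    Q = np.ones((n, 1)) / np.sqrt(n)
                y_res = yc - Q @ (Q.T @ yc)
                X_res = Xc - Q @ (Q.T @ Xc)
                ssx = np.einsum("ij,ij->j", X_res, X_res)
                ssy = y_res @ y_res
                if ssy <= 1e-12:
                    break
                with np.errstate(divide="ignore", invalid="ignore"):
                    r2 = (X_res.T @ y_res) ** 2 / np.where(
                        ssx > 1e-12, ssx * ssy, np.inf)
                r2[np.asarray(selected, dtype=int)] = 0.0
                r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
                F = r2 / (1.0 - r2) * dfres
                best = int(np.argmax(F))
                p_best = sps.f.sf(F[best], 1, dfres)
                if p_best <= entry_p and best not in selected:
                    selected.append(best)
                    changed = True
        if not changed:
            break
    return selected


def _ols(X: np.ndarray, y: np.ndarray):
    """Least squares on centered data; returns (beta, residuals)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta, y - X @ beta


def _fit_linear(X: np.ndarray, y: np.ndarray, idx: list[int]):
    """Fit y ~ X[:, idx] with intercept; returns (dense beta vector,
    intercept)."""
    beta_full = np.zeros(X.shape[1])
    if not idx:
        return beta_full, float(y.mean())
    Xs = X[:, idx]
    A = np.column_stack([np.ones(len(y)), Xs])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    beta_full[idx] = coef[1:]
    return beta_full, float(coef[0])


def _iteration_splits(n: int, cfg: DecodingConfig):
    """Deterministic per-iteration (train, holdout) index pairs.

    Splits are drawn independently per iteration from the config seed, so a
    regression run and a decoding run with the same config, seed and sample
    size see identical splits and can share selected feature sets.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, n]))
    n_hold = max(1, int(round(n * cfg.holdout_fraction)))
    splits = []
    for _ in range(cfg.n_cv_iterations):
        hold = rng.choice(n, size=n_hold, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[hold] = False
        splits.append((np.where(mask)[0], np.sort(hold)))
    return splits, rng


def _spearman_null(pred: np.ndarray, true: np.ndarray, n_perm: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Spearman correlations of ``pred`` against shuffles of ``true``."""
    rp = sps.rankdata(pred)
    rt = sps.rankdata(true)
    rp = (rp - rp.mean())
    denom = np.sqrt((rp @ rp))
    perms = rng.permuted(np.tile(rt, (n_perm, 1)), axis=1)
    perms = perms - perms.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        out = (perms @ rp) / (denom * np.sqrt(
            np.einsum("ij,ij->i", perms, perms)))
    return out


def _z_p(observed: float, null: np.ndarray):
    null = np.asarray(null, dtype=float)
    null = null[np.isfinite(null)]
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0:
        return 0.0, 1.0, mu, sd
    z = (observed - mu) / sd
    p = float(np.clip(sps.norm.sf(z), _P_FLOOR, 1.0))
    return float(z), p, mu, sd


def stepwise_cv_fit(X, y, cfg: DecodingConfig | None = None) -> DecodingResult:
    """Cross-validated stepwise regression of a behavioral score on the 384
    band-energy features, with a permutation null on the held-out Spearman
    correlation.
    """
    cfg = cfg or DecodingConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features and target must be row-aligned")
    if np.std(y) == 0:
        raise ValueError("target is constant; nothing to fit")

    splits, rng = _iteration_splits(len(y), cfg)
    perm_per_iter = max(1, cfg.n_perm_regression // cfg.n_cv_iterations)

    res = DecodingResult(alpha_joint=cfg.alpha_joint)
    betas, intercepts, nulls = [], [], []
    for it, (train, hold) in enumerate(splits):
        sel = stepwise_select(X[train], y[train], cfg.entry_p, cfg.stay_p,
                              cfg.max_features)
        res.selected_features.append(sel)
        beta, b0 = _fit_linear(X[train], y[train], sel)
        betas.append(beta)
        intercepts.append(b0)
        pred = X[hold] @ beta + b0
        if not sel:
            res.flags.append(f"iteration {it}: no feature entered; "
                             f"rho recorded at null level")
            res.per_iteration_rho.append(0.0)
            continue
        rho = sps.spearmanr(pred, y[hold]).statistic
        res.per_iteration_rho.append(float(rho))
        nulls.append(_spearman_null(pred, y[hold], perm_per_iter, rng))

    res.mean_betas = np.mean(betas, axis=0)
    res.mean_intercept = float(np.mean(intercepts))
    res.rho = float(np.mean(res.per_iteration_rho))
    if nulls:
        pooled = np.concatenate(nulls)
        res.z_rho, res.p_rho, res.null_rho_mean, res.null_rho_sd = _z_p(
            res.rho, pooled)
    else:
        res.z_rho, res.p_rho = 0.0, 1.0
        res.flags.append("no iteration selected any feature")
    return res


# ---------------------------------------------------------------------------
# LDA quartile decoding
# ---------------------------------------------------------------------------


def _train_lda(X: np.ndarray, labels: np.ndarray):
    """LDA with the svd solver, which tolerates the collinear feature
    subsets stepwise selection can produce."""
    clf = LinearDiscriminantAnalysis(solver="svd")
    clf.fit(X, labels)
    return clf


def lda_quartile_decode(X, labels, selected_sets, cfg: DecodingConfig | None = None,
                        result: DecodingResult | None = None,
                        ) -> DecodingResult:
    """Cross-validated quartile classification on stepwise-selected features.

    ``selected_sets`` holds one feature-index list per CV iteration (from
    :func:`stepwise_cv_fit` run with the same config/seed/sample size, so the
    splits line up).  Iterations whose training split misses a quartile are
    re-drawn (logged).  Results are written into ``result`` when given (so
    one :class:`DecodingResult` can carry both arms), else a fresh one.
    """
    cfg = cfg or DecodingConfig()
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    splits, rng = _iteration_splits(len(labels), cfg)
    classes = np.unique(labels)
    perm_per_iter = max(1, cfg.n_perm_decode // cfg.n_cv_iterations)

    res = result if result is not None else DecodingResult(
        alpha_joint=cfg.alpha_joint)
    nulls = []
    n_hold = len(splits[0][1])
    for it, (train, hold) in enumerate(splits):
        for _retry in range(100):
            if np.isin(classes, labels[train]).all():
                break
            res.flags.append(f"iteration {it}: quartile missing from "
                             f"training split; resampled")
            hold = rng.choice(len(labels), size=n_hold, replace=False)
            mask = np.ones(len(labels), dtype=bool)
            mask[hold] = False
            train, hold = np.where(mask)[0], np.sort(hold)
        sel = selected_sets[it] if it < len(selected_sets) else []
        if not sel:
            res.flags.append(f"iteration {it}: empty feature set; "
                             f"accuracy recorded at chance")
            res.per_iteration_acc.append(1.0 / len(classes))
            continue
        clf = _train_lda(X[train][:, sel], labels[train])
        pred = clf.predict(X[hold][:, sel])
        res.per_iteration_acc.append(float(np.mean(pred == labels[hold])))
        perms = rng.permuted(np.tile(labels[hold], (perm_per_iter, 1)),
                             axis=1)
        nulls.append((perms == pred).mean(axis=1))

    res.frac_correct = float(np.mean(res.per_iteration_acc))
    if nulls:
        pooled = np.concatenate(nulls)
        res.z_decode, res.p_decode, res.null_decode_mean, \
            res.null_decode_sd = _z_p(res.frac_correct, pooled)
    else:
        res.z_decode, res.p_decode = 0.0, 1.0
        res.flags.append("no iteration had usable features for decoding")
    return res


def decode_metric(X, y, quartiles=None, cfg: DecodingConfig | None = None,
                  ) -> DecodingResult:
    """Run both arms (stepwise regression + LDA quartile decoding) on one
    behavioral metric and merge them into a single result."""
    from .imagebehavior import quartile_labels

    cfg = cfg or DecodingConfig()
    res = stepwise_cv_fit(X, y, cfg)
    if quartiles is None:
        quartiles = quartile_labels(y)
    return lda_quartile_decode(X, quartiles, res.selected_features, cfg,
                               result=res)


# ---------------------------------------------------------------------------
# cross-condition transfer
# ---------------------------------------------------------------------------


def cross_condition_transfer(result_a: DecodingResult, features_a, labels_a,
                             features_b, target_b, labels_b,
                             cfg: DecodingConfig | None = None,
                             ) -> DecodingResult:
    """Apply a condition-A model to condition-B data.

    Regression arm: condition A's iteration-averaged betas/intercept predict
    condition B's scores; Spearman rho against the observed B scores with a
    null from shuffled B scores.  Classification arm: an LDA trained on all
    of condition A's data, restricted to the features A selected in more
    than one iteration, predicts condition B's quartiles against a shuffled-
    label null.  If no feature was selected more than once the
    classification arm is skipped with an explicit flag.
    """
    cfg = cfg or DecodingConfig()
    if result_a.mean_betas is None:
        raise ValueError("source result carries no averaged model")
    Xb = np.asarray(features_b, dtype=float)
    yb = np.asarray(target_b, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, len(yb), 7]))

    res = DecodingResult(alpha_joint=cfg.alpha_joint,
                         selected_features=result_a.selected_features,
                         mean_betas=result_a.mean_betas,
                         mean_intercept=result_a.mean_intercept)
    pred = Xb @ result_a.mean_betas + result_a.mean_intercept
    if np.std(pred) == 0:
        res.flags.append("averaged model is constant; rho at null level")
        res.rho, res.z_rho, res.p_rho = 0.0, 0.0, 1.0
    else:
        res.rho = float(sps.spearmanr(pred, yb).statistic)
        null = _spearman_null(pred, yb, cfg.n_perm_regression, rng)
        res.z_rho, res.p_rho, res.null_rho_mean, res.null_rho_sd = _z_p(
            res.rho, null)

    counts = np.bincount(
        np.concatenate([np.asarray(s, dtype=int)
                        for s in result_a.selected_features if len(s)])
        if any(len(s) for s in result_a.selected_features)
        else np.array([], dtype=int),
        minlength=N_FEATURES)
    stable = np.where(counts > 1)[0]
    if stable.size == 0:
        res.flags.append("classification transfer skipped: no feature "
                         "selected in more than one iteration")
        return res

    Xa = np.asarray(features_a, dtype=float)
    la = np.asarray(labels_a)
    lb = np.asarray(labels_b)
    clf = _train_lda(Xa[:, stable], la)
    pred_q = clf.predict(Xb[:, stable])
    res.frac_correct = float(np.mean(pred_q == lb))
    perms = rng.permuted(np.tile(lb, (cfg.n_perm_decode, 1)), axis=1)
    null = (perms == pred_q).mean(axis=1)
    res.z_decode, res.p_decode, res.null_decode_mean, res.null_decode_sd = \
        _z_p(res.frac_correct, null)
    return res


def decode_image_labels(X, labels, groups, cfg: DecodingConfig | None = None,
                        ) -> DecodingResult:
    """Classify categorical image labels with group-held-out validation.

    Each level of ``groups`` (e.g. a gender factor that partitions how the
    stimuli were constructed) serves once as the test set while the other
    levels train the LDA, avoiding leakage through shared image parts.
    Accuracy is averaged over the group folds; the null shuffles each fold's
    test labels.
    """
    cfg = cfg or DecodingConfig()
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, len(labels),
                                                        13]))
    res = DecodingResult(alpha_joint=cfg.alpha_joint)
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("need at least two groups for held-out validation")
    perm_per_fold = max(1, cfg.n_perm_decode // levels.size)
    accs, nulls = [], []
    for g in levels:
        test = groups == g
        train = ~test
        if np.unique(labels[train]).size < 2:
            raise ValueError(f"training groups for fold {g!r} contain a "
                             f"single class")
        clf = _train_lda(X[train], labels[train])
        pred = clf.predict(X[test])
        accs.append(float(np.mean(pred == labels[test])))
        perms = rng.permuted(np.tile(labels[test], (perm_per_fold, 1)),
                             axis=1)
        nulls.append((perms == pred).mean(axis=1))
    res.frac_correct = float(np.mean(accs))
    res.per_iteration_acc = accs
    pooled = np.concatenate(nulls)
    res.z_decode, res.p_decode, res.null_decode_mean, res.null_decode_sd = \
        _z_p(res.frac_correct, pooled)
    return res
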