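"""2 x 2 generalized linear mixed models for the six search measures.

Each measure is modeled with target emotion (happy vs. angry; reference
angry) and search task (find-specific vs. find-both; reference find-both)
as crossed fixed factors plus their interaction, and a random intercept per
participant:

* RT, ST, TIT, DRT -- gamma family, inverse link (in seconds);
* DS               -- Poisson family, log link;
* FFT              -- binomial family, logit link.

Fitting is delegated to glmmTMB through ``Rscript`` (no frequentist gamma
GLMM exists in the scientific Python stack); the gamma/inverse fit falls
back to a log link only on documented non-convergence, flagged in the
summary.  Effect estimates are reported multiplicatively: for Poisson and
binomial models as exp(coefficient) (incidence-rate / odds ratios), and for
gamma models as ratios of back-transformed cell means, so a generator that
plants a multiplicative effect on the mean is recovered on the same scale
regardless of the link.  Because the 2 x 2 fixed part is saturated, the
four cell means are link-invariant.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit, polygamma

RESPONSES = ("rt", "st", "tit", "drt", "ds", "fft")
_FAMILY = {"rt": ("gamma", "inverse"), "st": ("gamma", "inverse"),
           "tit": ("gamma", "inverse"), "drt": ("gamma", "inverse"),
           "ds": ("poisson", "log"), "fft": ("binomial", "logit")}
_COLUMN = {"rt": "rt_ms", "st": "st_ms", "tit": "tit_ms", "drt": "drt_ms",
           "ds": "ds", "fft": "fft"}
_CELLS = [(0, 0), (1, 0), (0, 1), (1, 1)]  # (emotion, task) indicator pairs


class ModelFitError(RuntimeError):
    """Raised when the mixed-model backend fails to converge; carries the
    backend's diagnostics."""


@dataclass(frozen=True)
class ModelSpec:
    """Which measure to model; family and link follow from the response."""

    response: str
    ref_emotion: str = "angry"
    ref_task: str = "find_both"

    def __post_init__(self):
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}")

    @property
    def family(self) -> str:
        return _FAMILY[self.response][0]

    @property
    def link(self) -> str:
        return _FAMILY[self.response][1]


@dataclass
class ModelSummary:
    """Table-shaped summary of one fitted 2 x 2 mixed model.

    ``terms`` maps intercept/emotion/task/interaction to multiplicative
    estimates with Wald 95% CIs and p-values; ``cell_means`` holds the
    back-transformed marginal means (response scale) with delta-method SEs
    for the four design cells keyed by (emotion_level, task_level)
    indicators.  ``icc`` and the R² values use latent-scale
    distribution-specific residual variances (log-normal/trigamma style
    approximations) and are descriptive.
    """

    response: str
    family: str
    link: str
    terms: dict
    coefficients: dict
    vcov: np.ndarray
    cell_means: dict
    sigma2: float
    tau00: float
    icc: float
    r2_marginal: float
    r2_conditional: float
    n_subjects: int
    n_observations: int
    link_fallback: bool = False
    flags: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(term=t, **v) for t, v in self.terms.items()]
        return pd.DataFrame(rows)


def _rscript_path() -> str:
    exe = shutil.which("Rscript")
    if exe is None:
        raise ModelFitError("Rscript not found on PATH; the mixed-model "
                            "backend requires R with glmmTMB")
    return exe


def _prepare_frame(metrics: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    col = _COLUMN[spec.response]
    required = {"participant", "target_emotion", "condition", col}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table lacks columns {sorted(missing)}")
    df = metrics.copy()
    # search task factor: find-specific vs find-both
    df["task"] = np.where(df["condition"] == "find_both",
                          "find_both", "find_specific")
    df = df[df["target_emotion"].isin(["angry", "happy"])]
    y = df[col]
    if spec.response in ("rt", "st", "tit", "drt"):
        y = y / 1000.0  # milliseconds -> seconds for the gamma models
    if spec.response == "fft":
        y = y.astype(float)
    out = pd.DataFrame(dict(y=y, participant=df["participant"],
                            emotion=df["target_emotion"], task=df["task"]))
    out = out.dropna(subset=["y"])
    if spec.response in ("rt", "st", "tit", "drt"):
        out = out[out["y"] > 0]
    for f in ("emotion", "task"):
        if out[f].nunique() < 2:
            raise ValueError(f"factor '{f}' has a single level")
    levels = out.groupby("participant")[["emotion", "task"]].nunique()
    if ((levels["emotion"] >= 2) & (levels["task"] >= 2)).sum() < 2:
        raise ValueError("need both factor levels for at least 2 participants")
    return out


def _run_backend(jobs: list[dict]) -> list[dict]:
    script = resources.files("emosearch").joinpath("glmm_fit.R")
    with tempfile.TemporaryDirectory() as td:
        jobfile = Path(td) / "jobs.json"
        outfile = Path(td) / "out.json"
        jobfile.write_text(json.dumps(jobs))
        with resources.as_file(script) as sp:
            proc = subprocess.run(
                [_rscript_path(), str(sp), str(jobfile), str(outfile)],
                capture_output=True, text=True)
        if proc.returncode != 0 or not outfile.exists():
            raise ModelFitError(
                f"mixed-model backend failed:\n{proc.stderr[-4000:]}")
        return json.loads(outfile.read_text())


def _linpred(coef: np.ndarray, e: int, t: int) -> np.ndarray:
    """Design row for cell (emotion indicator e, task indicator t)."""
    return np.array([1.0, e, t, e * t])


def _invlink(link: str):
    if link == "inverse":
        return lambda eta: 1.0 / eta, lambda eta: -1.0 / eta ** 2
    if link == "log":
        return np.exp, np.exp
    if link == "logit":
        return expit, lambda eta: expit(eta) * (1 - expit(eta))
    raise ValueError(link)


def _summarize(raw: dict, spec: ModelSpec, data: pd.DataFrame) -> ModelSummary:
    coef = np.asarray(raw["coef"], dtype=float)
    se = np.asarray(raw["se"], dtype=float)
    pvals = np.asarray(raw["p"], dtype=float)
    vcov = np.asarray(raw["vcov"], dtype=float)
    link = raw["link"]
    inv, dinv = _invlink(link)

    term_names = ["intercept", "emotion", "task", "interaction"]

    cell_means = {}
    for e, t in _CELLS:
        x = _linpred(coef, e, t)
        eta = float(x @ coef)
        se_eta = float(np.sqrt(x @ vcov @ x))
        cell_means[(e, t)] = dict(mean=float(inv(eta)),
                                  se=abs(float(dinv(eta))) * se_eta,
                                  eta=eta)

    terms = {}
    if spec.family in ("poisson", "binomial"):
        # exp(coef): incidence-rate ratios / odds ratios
        for i, name in enumerate(term_names):
            lo, hi = coef[i] - 1.96 * se[i], coef[i] + 1.96 * se[i]
            terms[name] = dict(estimate=float(np.exp(coef[i])),
                               ci_low=float(np.exp(lo)),
                               ci_high=float(np.exp(hi)),
                               p=float(pvals[i]))
    else:
        # ratios of back-transformed cell means, delta-method CIs on the
        # log-ratio scale; p-values are the Wald tests of the raw terms
        def log_ratio_and_grad(weights):
            def f(b):
                tot = 0.0
                for (e, t), w in weights:
                    tot += w * np.log(inv(float(_linpred(b, e, t) @ b)))
                return tot
            eps = 1e-6
            grad = np.zeros_like(coef)
            for i in range(len(coef)):
                bp, bm = coef.copy(), coef.copy()
                bp[i] += eps
                bm[i] -= eps
                grad[i] = (f(bp) - f(bm)) / (2 * eps)
            return f(coef), grad

        contrasts = {
            "intercept": [((0, 0), 1.0)],
            "emotion": [((1, 0), 1.0), ((0, 0), -1.0)],
            "task": [((0, 1), 1.0), ((0, 0), -1.0)],
            "interaction": [((1, 1), 1.0), ((0, 1), -1.0),
                            ((1, 0), -1.0), ((0, 0), 1.0)],
        }
        for i, name in enumerate(term_names):
            lr, grad = log_ratio_and_grad(contrasts[name])
            se_lr = float(np.sqrt(grad @ vcov @ grad))
            terms[name] = dict(estimate=float(np.exp(lr)),
                               ci_low=float(np.exp(lr - 1.96 * se_lr)),
                               ci_high=float(np.exp(lr + 1.96 * se_lr)),
                               p=float(pvals[i]))

    tau00 = float(raw["tau00"])
    sigma = float(raw["sigma"])
    # latent-scale residual variance (distribution-specific approximations)
    if spec.family == "gamma":
        shape = 1.0 / sigma ** 2
        var_resid = float(polygamma(1, shape))
        sigma2 = sigma ** 2
    elif spec.family == "poisson":
        lam = float(np.exp(np.log(max(cell_means[(0, 0)]["mean"], 1e-9))
                           + tau00 / 2.0))
        var_resid = float(np.log1p(1.0 / lam))
        sigma2 = var_resid
    else:
        var_resid = float(np.pi ** 2 / 3.0)
        sigma2 = var_resid

    e_ind = (data["emotion"] != spec.ref_emotion).to_numpy(int)
    t_ind = (data["task"] != spec.ref_task).to_numpy(int)
    Xd = np.column_stack([np.ones(len(data)), e_ind, t_ind, e_ind * t_ind])
    var_fixed = float(np.var(Xd @ coef))
    denom = var_fixed + tau00 + var_resid
    icc = tau00 / (tau00 + var_resid) if (tau00 + var_resid) > 0 else 0.0

    return ModelSummary(
        response=spec.response, family=spec.family, link=link,
        terms=terms,
        coefficients=dict(zip(raw["coef_names"], coef.tolist())),
        vcov=vcov, cell_means=cell_means, sigma2=sigma2, tau00=tau00,
        icc=float(np.clip(icc, 0.0, 1.0)),
        r2_marginal=var_fixed / denom if denom > 0 else 0.0,
        r2_conditional=(var_fixed + tau00) / denom if denom > 0 else 0.0,
        n_subjects=int(raw["n_subjects"]),
        n_observations=int(raw["n_obs"]),
        link_fallback=bool(raw.get("link_fallback", False)),
        flags=(["gamma/inverse fit did not converge; refit with log link"]
               if raw.get("link_fallback") else []))


def fit_condition_models(tables_and_specs) -> list[ModelSummary]:
    """Fit several 2 x 2 mixed models in a single backend invocation.

    ``tables_and_specs`` is a sequence of ``(metrics_table, ModelSpec)``
    pairs; R startup cost is paid once for the whole batch.
    """
    prepared = [( _prepare_frame(tbl, spec), spec)
                for tbl, spec in tables_and_specs]
    with tempfile.TemporaryDirectory() as td:
        jobs = []
        for i, (df, spec) in enumerate(prepared):
            path = Path(td) / f"job{i}.csv"
            df.to_csv(path, index=False)
            jobs.append(dict(data=str(path), family=spec.family,
                             link=spec.link, ref_emotion=spec.ref_emotion,
                             ref_task=("find_both" if spec.ref_task
                                       == "find_both" else spec.ref_task)))
        raws = _run_backend(jobs)
    out = []
    for raw, (df, spec) in zip(raws, prepared):
        if not raw.get("ok"):
            raise ModelFitError(raw.get("error", "unknown backend failure"))
        out.append(_summarize(raw, spec, df))
    return out


def fit_condition_model(metrics: pd.DataFrame, spec: ModelSpec,
                        ) -> ModelSummary:
    """Fit one 2 x 2 generalized linear mixed model (see module docstring).

    For the DRT model, trials with undefined dwell (direct hits, DS = 0)
    are excluded by the NaN filter, matching the smaller N of dwell models.
    """
    return fit_condition_models([(metrics, spec)])[0]


def fit_all_measures(metrics: pd.DataFrame) -> dict:
    """Fit the six standard models in one batch; returns
    {response: ModelSummary}."""
    pairs = [(metrics, ModelSpec(response=r)) for r in RESPONSES]
    return dict(zip(RESPONSES, fit_condition_models(pairs)))
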