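"""Contrast-coded linear mixed models with crossed random intercepts.

Fixed effects use +-1/2 contrast coding so each coefficient estimates a named
difference of condition means: in the 2x2 experiment ``Task``
(Guess_Time - Free_Viewing), ``Body`` (Standing - Chin_Rest) and their
interaction (difference of differences); in the 4-posture experiment ``C1``
(standing postures - sitting postures), ``C2`` (Sitting - Chin_Rest) and
``C3`` (Balancing - Standing).  Models are estimated by maximum likelihood
with crossed random intercepts for subjects and images (optionally an
uncorrelated random slope by image); inference is Wald t = estimate / SE,
with |t| > 2 reported as significant by convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: Contrast codes per experiment: column -> {level: code}.
EXP1_CONTRASTS = {
    "Task": {"Free_Viewing": -0.5, "Guess_Time": +0.5},
    "Body": {"Chin_Rest": -0.5, "Standing": +0.5},
}
EXP2_CONTRASTS = {
    "C1": {"Chin_Rest": -0.5, "Sitting": -0.5,
           "Standing": +0.5, "Balancing": +0.5},
    "C2": {"Chin_Rest": -0.5, "Sitting": +0.5,
           "Standing": 0.0, "Balancing": 0.0},
    "C3": {"Chin_Rest": 0.0, "Sitting": 0.0,
           "Standing": -0.5, "Balancing": +0.5},
}

T_SIGNIFICANCE = 2.0   # reporting convention: |t| above 2 is significant


class ConvergenceError(RuntimeError):
    """Mixed-model optimizer failed to converge; carries the trace."""


def build_contrasts(experiment: int, trial_table: pd.DataFrame) -> pd.DataFrame:
    """Design matrix (Intercept + orthogonal contrast columns) for a table.

    Experiment 1 expects ``task_level`` and ``posture_level`` columns and
    yields ``Intercept, Task, Body, Task:Body``; Experiment 2 expects
    ``posture_level`` and yields ``Intercept, C1, C2, C3``.  On a balanced
    design the contrast columns are mutually orthogonal and each coefficient
    equals its named difference of condition means.
    """
    n = len(trial_table)
    out = pd.DataFrame({"Intercept": np.ones(n)}, index=trial_table.index)
    if experiment == 1:
        task = _code(trial_table["task_level"], EXP1_CONTRASTS["Task"], "Task")
        body = _code(trial_table["posture_level"], EXP1_CONTRASTS["Body"],
                     "Body")
        out["Task"] = task
        out["Body"] = body
        out["Task:Body"] = task * body
    elif experiment == 2:
        for col, codes in EXP2_CONTRASTS.items():
            out[col] = _code(trial_table["posture_level"], codes, col)
    else:
        raise ValueError(f"unknown experiment {experiment}; valid: 1, 2")
    return out


def _code(levels: pd.Series, codes: dict[str, float], name: str) -> np.ndarray:
    unknown = set(levels.unique()) - set(codes)
    if unknown:
        raise ValueError(
            f"unknown level(s) {sorted(unknown)} for contrast {name}; "
            f"valid levels: {sorted(codes)}"
        )
    return levels.map(codes).to_numpy(dtype=float)


def cfb_covariates(
    table: pd.DataFrame,
    start_distance_col: str = "start_distance_deg",
    sample_col: str = "sample",
) -> pd.DataFrame:
    """Standardized covariates of the central-fixation-bias model.

    ``start_distance`` is the fixation-cross distance from the image center,
    centered at its dataset mean and scaled by its SD; ``log_sample`` is the
    standardized natural log of the within-trial fixation ordinal (controls
    for the logarithmic time trend of the bias).  Standardization statistics
    come from the analysis subset passed in.
    """
    sd0 = table[start_distance_col].to_numpy(dtype=float)
    ls = np.log(table[sample_col].to_numpy(dtype=float))
    out = pd.DataFrame(index=table.index)
    out["start_distance"] = (sd0 - sd0.mean()) / sd0.std(ddof=1)
    out["log_sample"] = (ls - ls.mean()) / ls.std(ddof=1)
    return out


@dataclass
class LMMFit:
    """Fitted mixed model: fixed effects, variance components, diagnostics."""

    terms: list[str]
    estimates: np.ndarray
    se: np.ndarray
    vc_sd: dict[str, float]
    residual_sd: float
    loglik: float
    converged: bool
    boundary: set[str] = field(default_factory=set)
    optimizer: str = ""
    n_obs: int = 0

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.estimates / self.se

    def fixed_effects(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.terms, "estimate": self.estimates, "se": self.se,
             "t": self.tvalues}
        )

    def to_dict(self) -> dict:
        return {
            "fixed_effects": self.fixed_effects().to_dict(orient="records"),
            "variance_components_sd": self.vc_sd,
            "residual_sd": self.residual_sd,
            "loglik": self.loglik,
            "converged": self.converged,
            "boundary": sorted(self.boundary),
            "optimizer": self.optimizer,
            "n_obs": self.n_obs,
        }


def fit_lmm(
    response: np.ndarray,
    fixed: pd.DataFrame,
    subject_ids: np.ndarray | None = None,
    image_ids: np.ndarray | None = None,
    image_slope: str | None = None,
    maxiter: int = 500,
) -> LMMFit:
    """Maximum-likelihood LMM with crossed subject/image random intercepts.

    ``fixed`` is the design matrix (include an Intercept column);
    ``image_slope`` optionally names a fixed column whose coefficient also
    varies by image, with no intercept-slope correlation (the ``||`` random
    structure).  Grouping factors with fewer than two levels are dropped to
    the boundary (SD 0) rather than erroring, matching the degenerate-fit
    contract.  Raises :class:`ConvergenceError` when no optimizer converges.
    """
    y = np.asarray(response, dtype=float)
    if np.isnan(y).any() or fixed.isna().any().any():
        raise ValueError("missing values in response or fixed-effect matrix")
    n = len(y)
    if len(fixed) != n:
        raise ValueError("response and fixed matrix lengths differ")

    df = pd.DataFrame(
        {f"x{i}": fixed.iloc[:, i].to_numpy(dtype=float)
         for i in range(fixed.shape[1])}
    )
    df["y"] = y
    boundary: set[str] = set()
    vc_formula: dict[str, str] = {}
    if subject_ids is not None:
        df["subj"] = np.asarray(subject_ids)
        if df["subj"].nunique() >= 2:
            vc_formula["subject"] = "0 + C(subj)"
        else:
            boundary.add("subject")
    if image_ids is not None:
        df["img"] = np.asarray(image_ids)
        if df["img"].nunique() >= 2:
            vc_formula["image"] = "0 + C(img)"
            if image_slope is not None:
                j = list(fixed.columns).index(image_slope)
                vc_formula["image_slope"] = f"0 + C(img):x{j}"
        else:
            boundary.add("image")

    terms = list(fixed.columns)
    formula = "y ~ 0 + " + " + ".join(f"x{i}" for i in range(fixed.shape[1]))

    if not vc_formula:
        # no random structure left: ordinary least squares is the ML fit
        res = sm.OLS(df["y"], df[[f"x{i}" for i in range(fixed.shape[1])]]).fit()
        return LMMFit(
            terms=terms, estimates=res.params.to_numpy(),
            se=res.bse.to_numpy(), vc_sd={}, residual_sd=float(np.sqrt(res.scale)),
            loglik=float(res.llf), converged=True, boundary=boundary,
            optimizer="ols", n_obs=n,
        )

    df["_group"] = 1
    model = sm.MixedLM.from_formula(
        formula, groups="_group", vc_formula=vc_formula, data=df,
    )
    trace = []
    result = None
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            with warnings.catch_warnings():
                # optimizer retries are expected; failures land in the trace
                warnings.simplefilter("ignore")
                candidate = model.fit(reml=False, method=method,
                                      maxiter=maxiter)
        except Exception as exc:   # noqa: BLE001 - collected into the trace
            trace.append(f"{method}: raised {exc!r}")
            continue
        if candidate.converged:
            result = candidate
            break
        trace.append(f"{method}: did not converge")
    if result is None:
        raise ConvergenceError(
            "mixed-model optimization failed to converge; trace: "
            + "; ".join(trace)
        )

    vc_sd = {}
    for name, var in zip(model.exog_vc.names, np.atleast_1d(result.vcomp)):
        var = float(max(var, 0.0))
        sd = float(np.sqrt(var))
        vc_sd[name] = sd
        if sd < 1e-6:
            boundary.add(name)
    return LMMFit(
        terms=terms,
        estimates=np.asarray(result.fe_params, dtype=float),
        se=np.asarray(result.bse_fe, dtype=float),
        vc_sd=vc_sd,
        residual_sd=float(np.sqrt(result.scale)),
        loglik=float(result.llf),
        converged=True,
        boundary=boundary,
        optimizer=result.method if isinstance(result.method, str) else "mixedlm",
        n_obs=n,
    )


def significance_report(fit: LMMFit) -> pd.DataFrame:
    """Fixed-effect table flagging |t| > 2 (the reporting convention).

    t exactly 2 is not flagged; a zero SE yields an undefined t flagged as
    degenerate.  The criterion column records that the threshold is a
    field convention, not a derived p-value.
    """
    tab = fit.fixed_effects()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = tab["estimate"] / tab["se"]
    degenerate = ~np.isfinite(t)
    tab["significant"] = np.where(degenerate, False,
                                  np.abs(t) > T_SIGNIFICANCE)
    tab["degenerate"] = degenerate
    tab.attrs["criterion"] = (
        f"|t| > {T_SIGNIFICANCE} by convention (no degrees-of-freedom "
        "correction)"
    )
    return tab
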