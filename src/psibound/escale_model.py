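"""Boundary-effect-scaled effect size epsilon and the E prediction model.

At migration-drift equilibrium the mean |psi| in a finite meta-population is
proportional to its overall genetic structuring, so the boundary-effect
normalized asymmetry is ``epsilon = mean|psi| / F_ST`` with the mean pairwise
F_ST censored below at 0.001.  With ``epsilon_eq`` the value the same
meta-population attains at equilibrium, the range-expansion effect size is
``E = epsilon / epsilon_eq``; ``E > 1`` indicates asymmetry beyond what
boundary effects alone produce.  Because ``epsilon_eq`` is unknowable in
empirical data, E is predicted from the observables via the weighted linear
model

    E = b0 + b_eps * epsilon + b_tau * tau + b_int * epsilon * tau + resid,

fitted to simulated calibration records with observation weights 1/epsilon
(the residual spread grows with epsilon).  A data set supports a range
expansion when the lower prediction bound for E at confidence alpha exceeds 1.
This decision heuristic is *not* a calibrated hypothesis test: the boundary
depends on the simulation suite behind the fit, and unmodeled features of real
data (asymmetric gene flow, non-clinal Ne variation) shift epsilon_eq.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EpsilonRecord",
    "EModel",
    "epsilon",
    "fit_E_model",
    "predict_E",
    "classify_records",
]


def epsilon(mean_abs_psi, mean_fst, censor_min=0.001) -> float:
    """epsilon = mean|psi| / max(mean F_ST, censor_min)."""
    if not np.isfinite(mean_abs_psi) or not np.isfinite(mean_fst):
        raise ValueError("inputs must be finite")
    if mean_abs_psi < 0:
        raise ValueError("mean_abs_psi must be >= 0")
    return float(mean_abs_psi / max(mean_fst, censor_min))


@dataclasses.dataclass
class EpsilonRecord:
    """One data set's epsilon, tau and (when known) equilibrium reference.

    ``epsilon_eq`` is the epsilon of the same simulation replicate at its final
    sampling time; ``E_true = epsilon / epsilon_eq`` is defined only for
    simulated records.  ``source`` tags the simulation family ("RE", "DE",
    "panmictic", ...) and ``cycle`` the sampling time, both used by
    :func:`classify_records`.
    """

    mean_abs_psi: float
    fst_censored: float
    tau: float
    epsilon_eq: Optional[float] = None
    source: str = "unknown"
    cycle: Optional[float] = None
    label: str = "unknown"

    @property
    def epsilon(self) -> float:
        return self.mean_abs_psi / self.fst_censored

    @property
    def E_true(self) -> Optional[float]:
        if self.epsilon_eq is None or self.epsilon_eq <= 0:
            return None
        return self.epsilon / self.epsilon_eq


@dataclasses.dataclass
class EModel:
    """Fitted weighted model E ~ epsilon * tau with prediction machinery."""

    beta: np.ndarray                  # (b0, b_eps, b_tau, b_int)
    cov_beta: np.ndarray
    scale: float                      # weighted residual variance
    df_resid: float
    r2: float
    n_obs: int
    n_excluded_zero_eps: int = 0
    eps_range: tuple = (np.nan, np.nan)
    tau_range: tuple = (np.nan, np.nan)

    def design_row(self, eps, tau):
        return np.array([1.0, eps, tau, eps * tau])

    def predict(self, eps, tau) -> float:
        return float(self.design_row(eps, tau) @ self.beta)

    def lower_bound(self, eps, tau, alpha=0.05) -> float:
        """One-sided lower prediction bound at confidence level alpha.

        The prediction variance at a new point follows the weighted-regression
        convention: Var = x' Cov(beta) x + scale * eps (a new observation with
        weight 1/eps has residual variance scale * eps).
        """
        x = self.design_row(eps, tau)
        var = float(x @ self.cov_beta @ x) + self.scale * max(eps, 0.0)
        t = stats.t.ppf(1 - alpha, self.df_resid)
        return self.predict(eps, tau) - t * np.sqrt(var)

    def extrapolates(self, eps, tau) -> bool:
        lo_e, hi_e = self.eps_range
        lo_t, hi_t = self.tau_range
        return not (lo_e <= eps <= hi_e and lo_t <= tau <= hi_t)

    # -- persistence -------------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "beta": list(map(float, self.beta)),
            "cov_beta": [list(map(float, row)) for row in self.cov_beta],
            "scale": self.scale,
            "df_resid": self.df_resid,
            "r2": self.r2,
            "n_obs": self.n_obs,
            "n_excluded_zero_eps": self.n_excluded_zero_eps,
            "eps_range": list(self.eps_range),
            "tau_range": list(self.tau_range),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "EModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            beta=np.array(payload["beta"], float),
            cov_beta=np.array(payload["cov_beta"], float),
            scale=float(payload["scale"]),
            df_resid=float(payload["df_resid"]),
            r2=float(payload["r2"]),
            n_obs=int(payload["n_obs"]),
            n_excluded_zero_eps=int(payload.get("n_excluded_zero_eps", 0)),
            eps_range=tuple(payload.get("eps_range", (np.nan, np.nan))),
            tau_range=tuple(payload.get("tau_range", (np.nan, np.nan))),
        )

    @classmethod
    def from_coefficients(cls, beta, scale=0.0, df_resid=np.inf, r2=np.nan):
        """Model from externally supplied coefficients, without interval machinery."""
        beta = np.asarray(beta, float)
        return cls(beta=beta, cov_beta=np.zeros((4, 4)), scale=scale,
                   df_resid=df_resid, r2=r2, n_obs=0,
                   eps_range=(-np.inf, np.inf), tau_range=(-np.inf, np.inf))


def fit_E_model(records: Sequence[EpsilonRecord], terms="full") -> EModel:
    """Weighted least squares of E_true on (epsilon, tau, epsilon*tau).

    Observation weights are 1/epsilon; records with epsilon == 0 are excluded
    (and counted).  ``terms`` selects nested designs for model comparison:
    "full" (default), "eps", "tau", or "psi" (mean |psi| as sole predictor).
    """
    import statsmodels.api as sm

    recs = [r for r in records if r.E_true is not None]
    if len(recs) < 10:
        raise ValueError("need at least 10 records with known E_true")
    eps_v = np.array([r.epsilon for r in recs])
    tau_v = np.array([r.tau for r in recs])
    psi_v = np.array([r.mean_abs_psi for r in recs])
    E = np.array([r.E_true for r in recs])
    keep = eps_v > 0
    n_excluded = int((~keep).sum())
    eps_v, tau_v, psi_v, E = eps_v[keep], tau_v[keep], psi_v[keep], E[keep]
    if eps_v.size < 10 or np.ptp(eps_v) == 0:
        raise ValueError("records must span a nonzero epsilon range")

    if terms == "full":
        X = np.column_stack([np.ones_like(eps_v), eps_v, tau_v, eps_v * tau_v])
        names = ["const", "eps", "tau", "eps:tau"]
    elif terms == "eps":
        X = np.column_stack([np.ones_like(eps_v), eps_v])
        names = ["const", "eps"]
    elif terms == "tau":
        X = np.column_stack([np.ones_like(eps_v), tau_v])
        names = ["const", "tau"]
    elif terms == "psi":
        X = np.column_stack([np.ones_like(eps_v), psi_v])
        names = ["const", "psi"]
    else:
        raise ValueError(f"unknown terms: {terms!r}")

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the collinear columns for the error message
        bad = []
        for k in range(1, X.shape[1]):
            sub = np.delete(X, k, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(names[k])
        raise ValueError(f"rank-deficient design; collinear columns: {bad or names}")

    w = 1.0 / eps_v
    res = sm.WLS(E, X, weights=w).fit()
    beta = np.zeros(4)
    cov = np.zeros((4, 4))
    if terms == "full":
        beta = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
    else:
        idx = {"eps": [0, 1], "tau": [0, 2], "psi": [0, 1]}[terms]
        for a, ia in enumerate(idx):
            beta[ia] = res.params[a]
            for b, ib in enumerate(idx):
                cov[ia, ib] = res.cov_params()[a, b]
    return EModel(
        beta=beta,
        cov_beta=cov,
        scale=float(res.scale),
        df_resid=float(res.df_resid),
        r2=float(res.rsquared),
        n_obs=int(res.nobs),
        n_excluded_zero_eps=n_excluded,
        eps_range=(float(eps_v.min()), float(eps_v.max())),
        tau_range=(float(tau_v.min()), float(tau_v.max())),
    )


def predict_E(model: EModel, eps, tau, alpha=0.05):
    """Point prediction, lower bound and decision for one data set.

    Returns a dict with ``E_hat``, ``lower_bound``, ``re_supported``
    (lower bound > 1) and an ``extrapolation`` flag when (eps, tau) falls
    outside the fitted range.
    """
    E_hat = model.predict(eps, tau)
    lb = model.lower_bound(eps, tau, alpha=alpha)
    return {
        "E_hat": E_hat,
        "lower_bound": lb,
        "alpha": alpha,
        "re_supported": bool(lb > 1.0),
        "extrapolation": model.extrapolates(eps, tau),
    }


def classify_records(records: Sequence[EpsilonRecord], model: Optional[EModel] = None,
                     threshold=1.2, alpha=0.05):
    """Label records equilibrium/nonequilibrium and summarize power and FPR.

    A record from an RE simulation is *nonequilibrium* (true positive class)
    when ``epsilon / epsilon_eq > threshold``; records from DE or panmictic
    simulations, and RE records at or below the threshold (late sampling
    times), are *equilibrium*.  Records with unknown epsilon_eq are labeled
    unknown and excluded from the summaries.  When a model is supplied, power
    is the fraction of nonequilibrium records whose lower prediction bound
    exceeds 1 at ``alpha``, and the false positive rate is the same fraction
    among equilibrium records.
    """
    labeled = []
    for r in records:
        if r.E_true is None:
            r.label = "unknown"
        elif r.source.upper().startswith("RE") or r.source in ("1D", "2D"):
            r.label = "nonequilibrium" if r.E_true > threshold else "equilibrium"
        else:
            r.label = "equilibrium"
        labeled.append(r)
    summary = {"n_unknown": sum(r.label == "unknown" for r in labeled),
               "n_equilibrium": sum(r.label == "equilibrium" for r in labeled),
               "n_nonequilibrium": sum(r.label == "nonequilibrium" for r in labeled)}
    if model is not None:
        def exceed(rs):
            hits = [model.lower_bound(r.epsilon, r.tau, alpha=alpha) > 1 for r in rs]
            return float(np.mean(hits)) if hits else np.nan
        summary["power"] = exceed([r for r in labeled if r.label == "nonequilibrium"])
        summary["fpr"] = exceed([r for r in labeled if r.label == "equilibrium"])
    return labeled, summary
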