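"""Cox proportional-hazards fitting by Newton-Raphson on the partial likelihood.

Features are standardized (center, scale) before optimization; reported
coefficients live on the standardized scale with the standardization constants
carried alongside, so the linear predictor is

    eta_i = sum_k beta_k * (x_ik - center_k) / scale_k  .

Ties are handled by Breslow's approximation by default (Efron available via
``ties="efron"``).  Breslow has the useful exact invariance that duplicating
every patient leaves the maximizer unchanged.

Monotone likelihood (perfect separation) is detected as unbounded coefficient
growth and reported as :class:`~mmrisk.errors.ConvergenceError` rather than
returned as a huge finite estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConvergenceError, DegenerateFeatureError

__all__ = ["FittedRiskModel", "fit_cox"]

_MAX_ABS_BETA = 25.0  # on the standardized scale; beyond this we call separation


@dataclass
class FittedRiskModel:
    """A fitted proportional-hazards risk score.

    ``coefficients`` are per standardized feature (log-hazard units per SD for
    continuous features); ``standardization`` maps feature -> (center, scale).
    """

    feature_names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    standardization: dict[str, tuple[float, float]]
    model_form: str = "cox"
    log_likelihood: float = float("nan")
    n: int = 0
    n_events: int = 0
    n_iter: int = 0
    converged: bool = False
    ties: str = "breslow"

    @property
    def coefficients_original(self) -> np.ndarray:
        """Coefficients per unit of the raw (unstandardized) feature."""
        scales = np.array([self.standardization[f][1] for f in self.feature_names])
        return self.coefficients / scales

    def linear_predictor(self, features: pd.DataFrame) -> pd.Series:
        """Continuous risk score (higher = higher hazard) for new patients."""
        eta = np.zeros(len(features))
        for k, name in enumerate(self.feature_names):
            center, scale = self.standardization[name]
            eta += self.coefficients[k] * (features[name].to_numpy(float) - center) / scale
        return pd.Series(eta, index=features.index)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "coefficients": self.coefficients.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "standardization": {k: list(v) for k, v in self.standardization.items()},
            "model_form": self.model_form,
            "log_likelihood": self.log_likelihood,
            "n": self.n,
            "n_events": self.n_events,
            "ties": self.ties,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FittedRiskModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=d["feature_names"],
            coefficients=np.asarray(d["coefficients"], float),
            standard_errors=np.asarray(d["standard_errors"], float),
            standardization={k: (v[0], v[1]) for k, v in d["standardization"].items()},
            model_form=d.get("model_form", "cox"),
            log_likelihood=d.get("log_likelihood", float("nan")),
            n=d.get("n", 0),
            n_events=d.get("n_events", 0),
            converged=True,
            ties=d.get("ties", "breslow"),
        )


def _neg_partial_loglik(beta, X, times, events, ties):
    """Log partial likelihood, gradient and information at ``beta``.

    Rows must be sorted by time ascending.  Returns (ll, grad, info).
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # guard exp overflow; cancels in every ratio and in ll up
    w = np.exp(eta)
    xw = X * w[:, None]
    xxw = np.einsum("ij,ik,i->ijk", X, X, w)

    # suffix sums over the risk set {j : t_j >= t}; with ascending sort the
    # risk set at sorted index i is rows i..n-1 (ties share the block start)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(xw[::-1], axis=0)[::-1]
    S2 = np.cumsum(xxw[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    event_times = np.unique(times[events == 1])
    starts = np.searchsorted(times, event_times, side="left")
    for t_k, i0 in zip(event_times, starts):
        in_block = (times == t_k) & (events == 1)
        d = int(in_block.sum())
        eta_sum = eta[in_block].sum()
        x_sum = X[in_block].sum(axis=0)
        ll += eta_sum
        grad += x_sum
        if ties == "breslow":
            s0, s1, s2 = S0[i0], S1[i0], S2[i0]
            ll -= d * np.log(s0)
            grad -= d * s1 / s0
            info += d * (s2 / s0 - np.outer(s1 / s0, s1 / s0))
        else:  # efron
            w_d = w[in_block].sum()
            s1_d = xw[in_block].sum(axis=0)
            s2_d = xxw[in_block].sum(axis=0)
            for ell in range(d):
                f = ell / d
                s0 = S0[i0] - f * w_d
                s1 = S1[i0] - f * s1_d
                s2 = S2[i0] - f * s2_d
                ll -= np.log(s0)
                grad -= s1 / s0
                info += s2 / s0 - np.outer(s1 / s0, s1 / s0)
    return ll, grad, info


def fit_cox(
    features: pd.DataFrame,
    survival: pd.DataFrame,
    *,
    time_col: str = "pfs_months",
    event_col: str = "pfs_event",
    ties: str = "breslow",
    model_form: str = "cox",
    max_iter: int = 100,
    tol: float = 1e-9,
) -> FittedRiskModel:
    """Maximize the Cox partial likelihood on standardized features.

    ``features`` and ``survival`` must share their patient index (row order is
    irrelevant; alignment is by index).  Deterministic given input order.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie handling {ties!r}")
    surv = survival.loc[features.index]
    times = surv[time_col].to_numpy(float)
    events = surv[event_col].to_numpy(int)
    if (times < 0).any():
        raise ValueError("negative survival times")
    n_events = int(events.sum())
    if n_events < 2:
        raise DegenerateFeatureError(f"need >= 2 events, got {n_events}")

    names = list(features.columns)
    X_raw = features.to_numpy(float)
    if not np.isfinite(X_raw).all():
        raise ValueError("non-finite feature values")
    centers = X_raw.mean(axis=0)
    scales = X_raw.std(axis=0, ddof=0)
    for name, s in zip(names, scales):
        if s == 0 or not np.isfinite(s):
            raise DegenerateFeatureError(
                f"feature {name!r} is constant across patients"
            )
    X = (X_raw - centers) / scales

    order = np.argsort(times, kind="stable")
    Xs, ts, es = X[order], times[order], events[order]

    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, grad, info = _neg_partial_loglik(beta, Xs, ts, es, ties)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                "singular information matrix",
                {"iteration": n_iter, "log_likelihood": ll},
            ) from exc
        # step-halving if the update does not improve the likelihood
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new = _neg_partial_loglik(cand, Xs, ts, es, ties)[0]
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        if np.max(np.abs(beta)) > _MAX_ABS_BETA:
            raise ConvergenceError(
                "coefficients diverging: monotone likelihood "
                "(perfect separation) suspected",
                {"iteration": n_iter, "max_abs_beta": float(np.max(np.abs(beta))),
                 "log_likelihood": float(ll_new)},
            )
        if abs(ll_new - ll_old) < tol * (abs(ll_old) + 1.0):
            ll_old = ll_new
            break
        ll_old = ll_new
    else:
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations",
            {"iteration": max_iter, "log_likelihood": float(ll_old),
             "max_abs_beta": float(np.max(np.abs(beta)))},
        )

    ll, grad, info = _neg_partial_loglik(beta, Xs, ts, es, ties)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return FittedRiskModel(
        feature_names=names,
        coefficients=beta,
        standard_errors=se,
        standardization={k: (float(c), float(s))
                         for k, c, s in zip(names, centers, scales)},
        model_form=model_form,
        log_likelihood=float(ll),
        n=len(times),
        n_events=n_events,
        n_iter=n_iter,
        converged=True,
        ties=ties,
    )
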