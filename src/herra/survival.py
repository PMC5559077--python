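"""Inverse-probability-of-censoring weighting for age-at-onset outcomes.

Under a log-normal accelerated failure time model the observed data are
Y = min(Y0, C) on the log scale with event indicator delta = I(Y0 <= C).
Censoring is handled by weighting each *event* observation by
W_i = delta_i / Sc(Y_i-), where Sc is the Kaplan-Meier estimator of the
censoring survival function (censorings play the role of events in that
estimator).  The left-limit evaluation means an event at time t uses only
censoring information from strictly before t; ties between an event and a
censoring at the same time are resolved event-first.  Censored
observations get weight zero, so weighted regression steps see an
unbiased reweighting of the complete-data problem.

The weighted total-variance estimator is
    sigma2_Y0 = V1 * sum_i W_i (Y_i - Ybar_w)^2 / (V1^2 - V2),
with V1 = sum W_i, V2 = sum W_i^2 and Ybar_w the weighted mean.  At unit
weights V1^2 - V2 = n(n-1) and the expression reduces exactly to the
ordinary n-1 sample variance, which is what pins down this denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class CensoringError(ValueError):
    """Degenerate censoring pattern (no events, or zero survival mass)."""


@dataclass
class CensoringSurvival:
    """Kaplan-Meier step function for the censoring distribution.

    ``times``/``surv`` are the right-continuous knots: surv[k] is the value
    of Sc on [times[k], times[k+1]).  Sc is 1 before the first knot.
    """

    times: np.ndarray
    surv: np.ndarray

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.times, t, side="right") - 1
        vals = np.concatenate([[1.0], self.surv])
        return vals[idx + 1]

    def evaluate_left(self, t: np.ndarray) -> np.ndarray:
        """Sc(t-): the value just before t."""
        idx = np.searchsorted(self.times, t, side="left") - 1
        vals = np.concatenate([[1.0], self.surv])
        return vals[idx + 1]


@dataclass
class IPCWWeights:
    """Per-observation censoring weights plus their summary moments."""

    weights: np.ndarray
    censoring_survival: CensoringSurvival
    v1: float
    v2: float
    y_bar_w: float


def km_censoring_survival(y: np.ndarray, event: np.ndarray,
                          case_weights: np.ndarray | None = None
                          ) -> CensoringSurvival:
    """Product-limit estimator treating censorings (event == 0) as the
    terminal events and true failures as censored.

    The risk set for a censoring at time t excludes failures occurring at
    exactly t (event-first tie convention).  ``case_weights`` allows a
    weighted-bootstrap version (weighted counts in both numerator and
    risk set).
    """
    y = np.asarray(y, dtype=float)
    event = np.asarray(event, dtype=float)
    if len(y) == 0:
        raise CensoringError("empty survival input")
    w = np.ones(len(y)) if case_weights is None else np.asarray(case_weights,
                                                                dtype=float)
    cens = event == 0
    ctimes = np.unique(y[cens])
    if len(ctimes) == 0:
        return CensoringSurvival(times=np.zeros(0), surv=np.zeros(0))
    # weighted counts: d_k censorings at t_k; risk set = mass with y >= t_k
    # minus failures at exactly t_k
    d = np.array([w[cens & (y == t)].sum() for t in ctimes])
    at_risk = np.array([w[y >= t].sum() - w[(~cens) & (y == t)].sum()
                        for t in ctimes])
    surv = np.cumprod(1.0 - d / at_risk)
    return CensoringSurvival(times=ctimes, surv=surv)


def ipcw_weights(y: np.ndarray, event: np.ndarray,
                 case_weights: np.ndarray | None = None) -> IPCWWeights:
    """W_i = delta_i / Sc(Y_i-); censored observations get weight zero."""
    y = np.asarray(y, dtype=float)
    event = np.asarray(event, dtype=float)
    if event.sum() == 0:
        raise CensoringError("all observations censored; weights undefined")
    sc = km_censoring_survival(y, event, case_weights)
    sc_left = sc.evaluate_left(y)
    is_event = event == 1
    if np.any(sc_left[is_event] <= 0.0):
        raise CensoringError("censoring survival reaches 0 before an event; "
                             "IPCW weight would be infinite")
    weights = np.zeros(len(y))
    weights[is_event] = 1.0 / sc_left[is_event]
    v1 = float(weights.sum())
    v2 = float(weights @ weights)
    if v1 <= 0:
        raise CensoringError("all observations censored")
    y_bar_w = float((weights @ y) / v1)
    return IPCWWeights(weights=weights, censoring_survival=sc,
                       v1=v1, v2=v2, y_bar_w=y_bar_w)


def weighted_outcome_variance(w: IPCWWeights, y: np.ndarray) -> float:
    """V1 * sum W_i (Y_i - Ybar_w)^2 / (V1^2 - V2)."""
    y = np.asarray(y, dtype=float)
    if w.v1 <= 0 or w.v1**2 <= w.v2:
        raise CensoringError("degenerate weights: V1^2 <= V2")
    y_bar_w = (w.weights @ y) / w.v1
    ss = w.weights @ (y - y_bar_w) ** 2
    return float(w.v1 * ss / (w.v1**2 - w.v2))
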