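"""Negative log Cox partial likelihood (Breslow ties) and the Breslow
baseline cumulative-hazard estimator.

These are the shared primitives behind every risk model in the package:
the linear per-arm Cox fits, the neural per-arm fits, and the two-head
balanced networks all minimize the same partial likelihood, and all
predicted survival curves are assembled from the same Breslow baseline:

    S_a(t | x) = exp(-H0_a(t) * exp(g_a(x)))
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["cox_partial_loss", "cox_partial_loss_grad", "breslow_baseline",
           "StepFunction"]


def _order_desc(times: np.ndarray) -> np.ndarray:
    # descending time so the risk set at an event is a prefix sum
    return np.argsort(-times, kind="stable")


def cox_partial_loss(log_risks, times, events) -> float:
    """Negative log Cox partial likelihood, Breslow tie convention,
    averaged over events.  Undefined (raises) when there are no events."""
    loss, _ = cox_partial_loss_grad(np.asarray(log_risks, float),
                                    np.asarray(times, float),
                                    np.asarray(events, int))
    return loss


def cox_partial_loss_grad(log_risks: np.ndarray, times: np.ndarray,
                          events: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to ``log_risks``.

    With subjects sorted by descending time, the risk set of an event at
    t_i is everyone with time >= t_i; ties share one risk set (Breslow).
    The gradient is computed analytically via cumulative sums, so the same
    code backs both the hand-checkable loss values and neural training.
    """
    log_risks = np.asarray(log_risks, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    n_events = int(events.sum())
    if n_events == 0:
        raise ValueError("Cox partial likelihood is undefined with zero events")

    order = _order_desc(times)
    r = log_risks[order]
    t = times[order]
    e = events[order]

    # numerically stable cumulative sum of exp(r) over the risk set
    exp_r = np.exp(r - r.max())
    cum = np.cumsum(exp_r)
    # ties: every subject with the same time shares the full tied risk set
    _, inv, counts = np.unique(-t, return_inverse=True, return_counts=True)
    last_of_group = np.cumsum(counts)[inv] - 1   # index of last member of tie group
    risk_sum = cum[last_of_group]
    log_risk_sum = np.log(risk_sum) + r.max()

    loss = -(r[e == 1].sum() - log_risk_sum[e == 1].sum()) / n_events

    # d loss / d r_k = -(1/D) [e_k - exp(r_k) * sum_{events i with t_i <= t_k} 1/S_i]
    inv_s = np.where(e == 1, 1.0 / risk_sum, 0.0)
    # collect tied events' 1/S contributions at each tie group's last index,
    # then a reverse cumulative sum gives the sum over events with t_i <= t_k
    rep = np.zeros_like(inv_s)
    first_idx = np.r_[0, np.cumsum(counts)[:-1]]
    totals = np.add.reduceat(inv_s, first_idx)
    rep[np.cumsum(counts) - 1] = totals
    rev_cum = np.cumsum(rep[::-1])[::-1]
    grad_sorted = -(e - exp_r * rev_cum) / n_events

    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return float(loss), grad


class StepFunction:
    """Right-continuous nondecreasing step function with H(0) = 0."""

    def __init__(self, knots: np.ndarray, values: np.ndarray):
        self.knots = np.asarray(knots, float)
        self.values = np.asarray(values, float)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        idx = np.searchsorted(self.knots, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 0.0)
        return out

    def to_dict(self) -> dict:
        return {"knots": self.knots.tolist(), "values": self.values.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "StepFunction":
        return cls(np.asarray(d["knots"]), np.asarray(d["values"]))


def breslow_baseline(times, events, log_risks) -> StepFunction:
    """Breslow estimator of the baseline cumulative hazard:

        H0(t) = sum_{event times t_i <= t} d_i / sum_{j at risk at t_i} exp(r_j)

    With no events the baseline is identically zero (warned, not fatal).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    log_risks = np.asarray(log_risks, float)
    if not np.all(np.isfinite(log_risks)):
        raise ValueError("log_risks must be finite")
    if events.sum() == 0:
        warnings.warn("no events: baseline cumulative hazard is identically 0",
                      stacklevel=2)
        return StepFunction(np.array([0.0]), np.array([0.0]))

    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    w = np.exp(log_risks[order] - log_risks.max())
    # at-risk sum at time t = total - sum of w for subjects with time < t
    total = w.sum()
    uniq, first = np.unique(t, return_index=True)
    cum_before = np.r_[0.0, np.cumsum(w)][first]       # w-mass strictly before each unique time
    at_risk = (total - cum_before) * np.exp(log_risks.max())
    d = np.add.reduceat(e.astype(float), first)
    increments = np.where(d > 0, d / at_risk, 0.0)
    H = np.cumsum(increments)
    keep = d > 0
    return StepFunction(uniq[keep], H[keep])
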