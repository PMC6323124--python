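"""Weighted Breslow partial-likelihood machinery with delayed entry.

Everything is computed from prefix/suffix sums over sorted event times, so
all per-subject and per-event quantities are O(n log n):

* ``S0_k`` — weighted risk mass at each event time,
* ``S1_k`` / ``S2_k`` — weighted first and second moments of covariates over
  the risk set,
* per-subject accumulations ``A_i = sum_k c_k / S0_k``, ``B_i = sum_k c_k /
  S0_k^2`` and ``D_i = sum_k c_k xbar_k / S0_k`` taken over the event times
  the subject is at risk for (entry_i < t_k <= exit_i).

These are the ingredients for the gradient and Hessian of the weighted
log partial likelihood in the linear predictor, used by the shared-frailty
fitter and by the scaled-Schoenfeld proportional-hazards test.
"""

from __future__ import annotations

import numpy as np


class BreslowWorkspace:
    """Risk-set sums for fixed data (entry, exit, event, weights, X)."""

    def __init__(self, entry, exit_, event, weights, X):
        self.entry = np.asarray(entry, dtype=float)
        self.exit = np.asarray(exit_, dtype=float)
        self.event = np.asarray(event, dtype=bool)
        self.w = np.asarray(weights, dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.n, self.p = self.X.shape
        if not np.all(self.entry < self.exit):
            raise ValueError("every row must satisfy entry < exit")
        if not self.event.any():
            raise ValueError("at least one event is required")
        ev = np.flatnonzero(self.event)
        order = ev[np.argsort(self.exit[ev], kind="stable")]
        self.event_idx = order                 # event rows, ascending time
        self.t_events = self.exit[order]
        self.c = self.w[order]                 # event weights
        self.m = len(order)
        self._exit_order = np.argsort(self.exit, kind="stable")
        self._entry_order = np.argsort(self.entry, kind="stable")

    # -- core sums -----------------------------------------------------------

    def _suffix_sum_at_events(self, values, times_sorted_idx, times):
        """sum of values[i] over rows with sorted-key >= each event time."""
        v = values[times_sorted_idx]
        suff = np.concatenate([np.cumsum(v[::-1])[::-1], [0.0]]) if v.ndim == 1 else \
            np.vstack([np.cumsum(v[::-1], axis=0)[::-1], np.zeros((1, v.shape[1]))])
        pos = np.searchsorted(times, self.t_events, side="left")
        return suff[pos]

    def risk_sums(self, r, Xr=None):
        """S0 (and optionally S1 columns) at each event time for risk weights r."""
        texit = self.exit[self._exit_order]
        tentry = self.entry[self._entry_order]
        S0 = (self._suffix_sum_at_events(r, self._exit_order, texit)
              - self._suffix_sum_at_events(r, self._entry_order, tentry))
        if Xr is None:
            return S0
        S1 = (self._suffix_sum_at_events(Xr, self._exit_order, texit)
              - self._suffix_sum_at_events(Xr, self._entry_order, tentry))
        return S0, S1

    def _per_subject_accumulate(self, event_values):
        """A_i = sum of event_values over event times with entry_i < t_k <= exit_i."""
        cs = np.cumsum(event_values, axis=0)
        cs = np.vstack([np.zeros((1,) + event_values.shape[1:]), cs]) if event_values.ndim > 1 \
            else np.concatenate([[0.0], cs])
        hi = np.searchsorted(self.t_events, self.exit, side="right")
        lo = np.searchsorted(self.t_events, self.entry, side="right")
        return cs[hi] - cs[lo]

    def quantities(self, eta):
        """All gradient/Hessian ingredients at linear predictor eta."""
        r = self.w * np.exp(eta - np.max(eta))   # stabilised; S0 ratios unaffected
        scale = np.exp(np.max(eta))
        Xr = self.X * r[:, None]
        S0, S1 = self.risk_sums(r, Xr)
        if np.any(S0 <= 0):
            raise FloatingPointError("empty risk set at an event time")
        xbar = S1 / S0[:, None]
        invS0 = self.c / S0
        A = self._per_subject_accumulate(invS0)
        B = self._per_subject_accumulate(self.c / S0**2)
        D = self._per_subject_accumulate(invS0[:, None] * xbar)
        loglik = float(np.sum(self.c * (eta[self.event_idx] - np.log(S0) - np.log(scale))))
        return {
            "r": r, "S0": S0, "S1": S1, "xbar": xbar,
            "A": A, "B": B, "D": D, "loglik": loglik,
        }

    def loglik(self, eta):
        r = self.w * np.exp(eta - np.max(eta))
        S0 = self.risk_sums(r)
        return float(np.sum(self.c * (eta[self.event_idx] - np.log(S0) - np.max(eta))))

    def grad_eta(self, q):
        """Gradient of the log partial likelihood in eta (per subject)."""
        g = -q["r"] * q["A"]
        g[self.event_idx] += self.c
        return g

    def hess_beta(self, q):
        """Exact negative Hessian (information) in beta: sum_k c_k (S2/S0 - xbar xbar')."""
        # S2/S0 term via per-event suffix sums of r x x'
        r = q["r"]
        iu = np.triu_indices(self.p)
        Xpairs = self.X[:, iu[0]] * self.X[:, iu[1]] * r[:, None]
        texit = self.exit[self._exit_order]
        tentry = self.entry[self._entry_order]
        S2u = (self._suffix_sum_at_events(Xpairs, self._exit_order, texit)
               - self._suffix_sum_at_events(Xpairs, self._entry_order, tentry))
        ratio = S2u / q["S0"][:, None]
        term1 = np.zeros((self.p, self.p))
        vals = (self.c[:, None] * ratio).sum(axis=0)
        term1[iu] = vals
        term1[(iu[1], iu[0])] = vals
        xb = q["xbar"] * np.sqrt(self.c)[:, None]
        return term1 - xb.T @ xb

    def schoenfeld(self, q):
        """Per-event weighted Schoenfeld residuals c_k (x_(k) - xbar_k)."""
        return self.c[:, None] * (self.X[self.event_idx] - q["xbar"])
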