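"""Closed-form algebra for sums of ``(a + b*t) * exp(lam*t)`` terms.

Everything the one-tissue compartment simulator needs — convolution of the
plasma input with the tissue impulse response, and exact frame averaging of
the resulting curve — stays inside this family of functions, so time-activity
curves are computed analytically rather than by numerical quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ExpSum"]

# Exponents closer together than this are nudged apart before convolving so
# the partial-fraction formulas stay finite; the perturbation is far below
# any tolerance used downstream.
_DEGENERACY_EPS = 1e-9


@dataclass(frozen=True)
class ExpSum:
    """f(t) = sum_i (a_i + b_i * t) * exp(lam_i * t), defined for t >= 0."""

    a: np.ndarray
    b: np.ndarray
    lam: np.ndarray

    @classmethod
    def from_terms(cls, terms) -> "ExpSum":
        """Build from an iterable of ``(a, b, lam)`` triples."""
        arr = np.atleast_2d(np.asarray(list(terms), dtype=float))
        if arr.size == 0:
            arr = np.zeros((0, 3))
        return cls(arr[:, 0].copy(), arr[:, 1].copy(), arr[:, 2].copy())

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape)
        for a, b, lam in zip(self.a, self.b, self.lam):
            out += (a + b * t) * np.exp(lam * t)
        return out

    def scale(self, c: float) -> "ExpSum":
        return ExpSum(self.a * c, self.b * c, self.lam.copy())

    def __add__(self, other: "ExpSum") -> "ExpSum":
        return ExpSum(
            np.concatenate([self.a, other.a]),
            np.concatenate([self.b, other.b]),
            np.concatenate([self.lam, other.lam]),
        )

    def convolve_exp(self, beta: float) -> "ExpSum":
        """Convolve with the kernel ``exp(-beta * t)`` on [0, t].

        For one term ``(a + b s) e^{lam s}`` and mu = lam + beta != 0::

            conv(t) = (a/mu - b/mu^2) e^{lam t} + (b/mu) t e^{lam t}
                      + (b/mu^2 - a/mu) e^{-beta t}
        """
        a_out, b_out, lam_out = [], [], []
        for a, b, lam in zip(self.a, self.b, self.lam):
            mu = lam + beta
            if abs(mu) < _DEGENERACY_EPS:
                mu = _DEGENERACY_EPS if mu >= 0 else -_DEGENERACY_EPS
            a_out += [a / mu - b / mu**2, b / mu**2 - a / mu]
            b_out += [b / mu, 0.0]
            lam_out += [lam, -beta]
        return ExpSum(np.array(a_out), np.array(b_out), np.array(lam_out))

    def antiderivative(self, t):
        """F(t) with F(0) = 0, vectorized over t."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape)
        for a, b, lam in zip(self.a, self.b, self.lam):
            # near-zero exponents take the polynomial limit: the exact form
            # divides by lam and cancels catastrophically
            if abs(lam) < 1e-8:
                out += a * t + 0.5 * b * t**2
            else:
                # int (a + b s) e^{lam s} ds = e^{lam s}((a + b s)/lam - b/lam^2)
                prim = np.exp(lam * t) * ((a + b * t) / lam - b / lam**2)
                prim0 = a / lam - b / lam**2
                out += prim - prim0
        return out

    def frame_means(self, starts, ends):
        """Average value over each frame [start, end]."""
        starts = np.asarray(starts, dtype=float)
        ends = np.asarray(ends, dtype=float)
        return (self.antiderivative(ends) - self.antiderivative(starts)) / (
            ends - starts
        )
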