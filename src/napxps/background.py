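"""Inelastic-scattering backgrounds for core-level regions.

The Shirley background models the step under a photoemission peak as
proportional to the integrated net peak intensity at lower binding energy
(electrons that lost energy appear at higher apparent binding energy).  On
an ascending BE grid with endpoint intensities ``I_lo`` (low-BE side) and
``I_hi`` (high-BE side) the classic fixed point is

    B(E) = I_hi + (I_lo - I_hi) * A_above(E) / A_total

with ``A_above(E)`` the net (signal minus background) area at binding
energies above E, iterated to convergence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .spectra import Spectrum

__all__ = ["shirley_background", "linear_background", "ShirleyResult"]

log = logging.getLogger(__name__)


@dataclass
class ShirleyResult:
    """Background curve plus iteration diagnostics."""

    background: np.ndarray
    n_iterations: int
    converged: bool
    max_rel_change: float

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.background, dtype=dtype)


def _endpoint_means(y: np.ndarray, n_edge: int) -> tuple[float, float]:
    n_edge = min(n_edge, y.size // 2)
    return float(np.mean(y[:n_edge])), float(np.mean(y[-n_edge:]))


def shirley_background(
    s: Spectrum | None = None,
    *,
    x: np.ndarray | None = None,
    y: np.ndarray | None = None,
    n_edge_points: int = 5,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> ShirleyResult:
    """Iterative Shirley background of one region scan.

    Accepts either a :class:`Spectrum` or raw ``x``/``y`` arrays (ascending
    binding energy).  Region endpoints are defined as means over the
    outermost ``n_edge_points`` points on each side.  Iteration stops when
    the maximum relative change of the background drops below ``tol`` or
    after ``max_iter`` sweeps (the result records which).
    """
    if s is not None:
        x = s.binding_energy
        y = s.counts
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_edge_points < 1:
        raise ValueError("n_edge_points must be >= 1")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input to shirley_background")

    i_lo, i_hi = _endpoint_means(y, n_edge_points)
    if np.allclose(y, y[0]):
        # constant spectrum: the fixed point is the constant itself
        return ShirleyResult(np.full_like(y, i_lo), 0, True, 0.0)

    bg = np.linspace(i_lo, i_hi, x.size)
    max_rel = np.inf
    it = 0
    scale = max(abs(i_lo), abs(i_hi), 1e-300)
    for it in range(1, max_iter + 1):
        net = y - bg
        # negative net signal is clipped to zero for the area integrals
        n_neg = int(np.sum(net < 0))
        net = np.clip(net, 0.0, None)
        cum = cumulative_trapezoid(net, x, initial=0.0)
        total = cum[-1]
        if total <= 0:
            new_bg = np.full_like(y, 0.5 * (i_lo + i_hi))
            new_bg[:] = np.linspace(i_lo, i_hi, x.size)
        else:
            a_above = total - cum
            new_bg = i_hi + (i_lo - i_hi) * a_above / total
        max_rel = float(np.max(np.abs(new_bg - bg)) / scale)
        bg = new_bg
        if max_rel < tol:
            break
    converged = max_rel < tol
    if not converged:
        log.warning(
            "Shirley background did not converge in %d iterations "
            "(max relative change %.3g)", max_iter, max_rel,
        )
    if it > 1 and n_neg:
        log.debug("Shirley: clipped %d negative net-signal points", n_neg)
    return ShirleyResult(bg, it, converged, max_rel)


def linear_background(
    s: Spectrum | None = None,
    *,
    x: np.ndarray | None = None,
    y: np.ndarray | None = None,
    n_edge_points: int = 5,
) -> ShirleyResult:
    """Straight line between the endpoint means (fallback background)."""
    if s is not None:
        x = s.binding_energy
        y = s.counts
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    i_lo, i_hi = _endpoint_means(y, n_edge_points)
    frac = (x - x[0]) / (x[-1] - x[0])
    return ShirleyResult(i_lo + (i_hi - i_lo) * frac, 0, True, 0.0)
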