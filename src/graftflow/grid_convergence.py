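"""Richardson extrapolation and the grid convergence index (GCI).

Given solution values on three (or more) systematically refined grids,
the observed order of accuracy ``p`` solves

    eps32 / eps21 = r21^p (r32^p - s) / (r21^p - s),   s = sign(eps32/eps21)

with ``eps21 = f2 - f1``, ``eps32 = f3 - f2`` (1 = finest), solved by
fixed-point iteration for unequal refinement ratios. The GCI for a grid
pair is ``fs * |relative error| / (r^p - 1) * 100`` with safety factor
``fs = 1.25`` for three-grid studies. A study is in the asymptotic range
when ``gci32 / (r21^p * gci21)`` is close to one.

Oscillatory (non-monotone) convergence — the medium-grid value lying
outside the fine/coarse bracket, equivalently ``eps32/eps21 < 0`` — is
flagged rather than silently reported; the effective order is then
computed from the error-magnitude ratio and may be negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridStudy",
    "OrderEstimate",
    "GCIResult",
    "observed_order",
    "gci",
    "asymptotic_check",
    "gci_study",
]

DEFAULT_SAFETY_FACTOR = 1.25


@dataclass
class GridStudy:
    """Representative cell sizes (fine -> coarse) and solution values."""

    h: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.h.size != self.f.size or self.h.size < 3:
            raise ValueError("need matching h and f with at least three grids")
        if np.any(np.diff(self.h) <= 0):
            raise ValueError("h must be strictly increasing (fine to coarse)")


@dataclass(frozen=True)
class OrderEstimate:
    """Observed order with a monotone-convergence flag."""

    p: float
    monotone: bool


@dataclass
class GCIResult:
    p: float
    monotone: bool
    f_ext: float
    E: tuple[float, float]  # (eps21, eps32)
    gci: tuple[float, float]  # (gci21, gci32), percent
    asymptotic_ratio: float


def observed_order(
    f1: float,
    f2: float,
    f3: float,
    r21: float,
    r32: float,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> OrderEstimate:
    """Observed order of accuracy from a three-grid triplet (1 = finest)."""
    if r21 <= 1 or r32 <= 1:
        raise ValueError("refinement ratios must exceed 1")
    eps21 = f2 - f1
    eps32 = f3 - f2
    if eps21 == 0 or eps32 == 0:
        raise ValueError(
            "degenerate convergence: identical solutions on adjacent grids"
        )
    ratio = eps32 / eps21
    monotone = ratio > 0
    if not monotone:
        # oscillatory: report the effective order from error magnitudes
        p_eff = np.log(abs(ratio)) / np.log(0.5 * (r21 + r32))
        return OrderEstimate(p=float(p_eff), monotone=False)
    if abs(r21 - r32) < 1e-14:
        return OrderEstimate(p=float(np.log(ratio) / np.log(r21)), monotone=True)

    # unequal ratios: eps32/eps21 = r21^p (r32^p - 1)/(r21^p - 1), a strictly
    # increasing function of p — solved by bisection-safe root bracketing
    from scipy.optimize import brentq

    def residual(p):
        return (
            p * np.log(r21) + np.log(r32**p - 1.0) - np.log(r21**p - 1.0)
            - np.log(ratio)
        )

    lo, hi = 1e-8, 1.0
    while residual(hi) < 0 and hi < 64.0:
        hi *= 2.0
    if residual(lo) > 0 or residual(hi) < 0:
        raise ValueError("no admissible order p in (0, 64] for this triplet")
    p = brentq(residual, lo, hi, xtol=tol, maxiter=max_iter)
    return OrderEstimate(p=float(p), monotone=True)


def gci(
    f_fine: float,
    f_coarse: float,
    r: float,
    p: float,
    fs: float = DEFAULT_SAFETY_FACTOR,
) -> float:
    """Grid convergence index for one grid pair, percent."""
    if r <= 1:
        raise ValueError("refinement ratio must exceed 1")
    if not np.isfinite(p):
        raise ValueError("order p must be finite")
    denom = r**p - 1.0
    if denom == 0:
        raise ValueError("r^p == 1: GCI undefined")
    if f_fine == 0:
        raise ValueError("fine-grid value is zero: relative error undefined")
    e_rel = abs((f_coarse - f_fine) / f_fine)
    return fs * e_rel / denom * 100.0


def asymptotic_check(gci21: float, gci32: float, r21: float, p: float) -> float:
    """Asymptotic-range ratio ``gci32 / (r21^p * gci21)``; ~1 is asymptotic."""
    if not (np.isfinite(gci21) and np.isfinite(gci32) and np.isfinite(p)):
        raise ValueError("inputs must be finite")
    if gci21 == 0:
        raise ValueError("gci21 is zero: asymptotic ratio undefined")
    return gci32 / (r21**p * gci21)


def richardson_extrapolate(f1: float, f2: float, r21: float, p: float) -> float:
    """Zero-spacing estimate from the finest pair."""
    return f1 + (f1 - f2) / (r21**p - 1.0)


def gci_study(study: GridStudy, fs: float = DEFAULT_SAFETY_FACTOR) -> GCIResult:
    """Full three-grid analysis of the finest triplet of a study."""
    f1, f2, f3 = study.f[:3]
    h1, h2, h3 = study.h[:3]
    r21 = h2 / h1
    r32 = h3 / h2
    est = observed_order(f1, f2, f3, r21, r32)
    g21 = gci(f1, f2, r21, est.p, fs)
    g32 = gci(f2, f3, r32, est.p, fs)
    return GCIResult(
        p=est.p,
        monotone=est.monotone,
        f_ext=richardson_extrapolate(f1, f2, r21, est.p),
        E=(float(f2 - f1), float(f3 - f2)),
        gci=(g21, g32),
        asymptotic_ratio=asymptotic_check(g21, g32, r21, est.p),
    )
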