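"""Elliptic Fourier analysis of closed outlines.

A closed outline defines periodic coordinate functions x(t), y(t) over one
traversal, and harmonic n contributes

    x_n(t) = a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T)
    y_n(t) = c_n cos(2 pi n t / T) + d_n sin(2 pi n t / T)

with the quadruples (a_n, b_n, c_n, d_n) as shape descriptors. The curve
parameter advances by one unit per vertex (the sampling parameter), and the
projections are integrated exactly over the piecewise-linear chain. On
outlines resampled to equidistant vertices — which the pipeline always does
before the transform — the sampling parameter IS arc length, so this matches
the classical chain-code (Kuhl & Giardina) coefficients there, while a curve
supplied with its own parameterization (e.g. an ellipse sampled at equal
angle steps) keeps that parameterization's coefficients.

Harmonic power (a^2+b^2+c^2+d^2)/2 decays with n; an analysis keeps the
smallest harmonic count whose cumulative power reaches a threshold (99% by
default) across the whole dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .outline import OutlinePolygon

__all__ = [
    "EFTCoefficients",
    "eft_forward",
    "eft_inverse",
    "normalize_phase",
    "harmonic_power",
    "choose_n_harmonics",
    "coefficient_matrix",
]


@dataclass(frozen=True)
class EFTCoefficients:
    """Elliptic Fourier coefficients of one outline.

    ``harmonics`` has one row (a_n, b_n, c_n, d_n) per harmonic; ``dc`` is
    the parametric mean point (A0, C0); ``perimeter`` the period of the
    parameterization.
    """

    dc: tuple
    harmonics: np.ndarray = field(repr=False)
    perimeter: float = 1.0

    def __post_init__(self) -> None:
        h = np.asarray(self.harmonics, dtype=float)
        if h.ndim != 2 or h.shape[1] != 4 or h.shape[0] < 1:
            raise ValueError("harmonics must be (n_harmonics, 4) with n >= 1")
        if not (np.all(np.isfinite(h)) and np.all(np.isfinite(self.dc))):
            raise ValueError("non-finite coefficients")
        if self.perimeter <= 0:
            raise ValueError("perimeter must be positive")
        object.__setattr__(self, "harmonics", h)
        self.harmonics.setflags(write=False)

    @property
    def n_harmonics(self) -> int:
        return self.harmonics.shape[0]

    def truncated(self, n: int) -> "EFTCoefficients":
        if not 1 <= n <= self.n_harmonics:
            raise ValueError(f"cannot truncate to {n} of {self.n_harmonics} harmonics")
        return EFTCoefficients(self.dc, self.harmonics[:n].copy(), self.perimeter)


def eft_forward(poly: OutlinePolygon, n_harmonics: int) -> EFTCoefficients:
    """Elliptic Fourier coefficients of a polygonal outline.

    Exact integration of the Fourier projections over the piecewise-linear
    contour; ``n_harmonics`` may not exceed the Nyquist bound of half the
    vertex count.
    """
    n_harmonics = int(n_harmonics)
    if n_harmonics < 1:
        raise ValueError("need at least 1 harmonic")
    if n_harmonics > len(poly) // 2:
        raise ValueError(
            f"{n_harmonics} harmonics exceeds the Nyquist bound {len(poly) // 2} "
            f"for {len(poly)} vertices"
        )
    v = poly.vertices
    d = np.roll(v, -1, axis=0) - v  # edge vectors
    dt = np.ones(len(v))  # unit parameter step per vertex
    big_t = dt.sum()
    t1 = np.arange(len(v), dtype=float)  # edge start times
    t2 = t1 + dt

    n = np.arange(1, n_harmonics + 1, dtype=float)
    w = 2.0 * np.pi * n[:, None] / big_t  # (H, 1) angular frequencies
    dcos = np.cos(w * t2) - np.cos(w * t1)  # (H, E)
    dsin = np.sin(w * t2) - np.sin(w * t1)
    slope = d / dt[:, None]  # dx/dt, dy/dt per edge
    coef = big_t / (2.0 * np.pi**2 * n**2)  # (H,)
    a = coef * (dcos @ slope[:, 0])
    b = coef * (dsin @ slope[:, 0])
    c = coef * (dcos @ slope[:, 1])
    dcf = coef * (dsin @ slope[:, 1])
    harmonics = np.column_stack((a, b, c, dcf))

    # DC component: time average of the piecewise-linear x(t), y(t)
    mid = v + 0.5 * d  # edge midpoints = average position on each edge
    a0 = float((mid[:, 0] * dt).sum() / big_t)
    c0 = float((mid[:, 1] * dt).sum() / big_t)
    return EFTCoefficients(dc=(a0, c0), harmonics=harmonics, perimeter=float(big_t))


def eft_inverse(coef: EFTCoefficients, n_points: int,
                n_harmonics: int | None = None) -> OutlinePolygon:
    """Reconstruct an outline from (possibly truncated) Fourier coefficients."""
    if n_points < 3:
        raise ValueError("need n_points >= 3")
    h = coef.harmonics if n_harmonics is None else coef.truncated(n_harmonics).harmonics
    t = np.arange(n_points) / n_points  # t / T in [0, 1)
    n = np.arange(1, len(h) + 1)[:, None]
    phase = 2.0 * np.pi * n * t[None, :]
    cosp, sinp = np.cos(phase), np.sin(phase)
    x = coef.dc[0] + h[:, 0] @ cosp + h[:, 1] @ sinp
    y = coef.dc[1] + h[:, 2] @ cosp + h[:, 3] @ sinp
    return OutlinePolygon(np.column_stack((x, y)))


def shift_start(coef: EFTCoefficients, phi1: float) -> EFTCoefficients:
    """Coefficients of the same curve with the parameter origin advanced.

    ``phi1`` is the first-harmonic phase advance (2 pi * arc fraction);
    harmonic n is rotated in its (cos, sin) basis by ``n * phi1``. The
    geometry is unchanged — only where t = 0 sits on the outline.
    """
    h = coef.harmonics
    n = np.arange(1, coef.n_harmonics + 1)
    phi = n * phi1
    cosp, sinp = np.cos(phi), np.sin(phi)
    a = h[:, 0] * cosp + h[:, 1] * sinp
    b = -h[:, 0] * sinp + h[:, 1] * cosp
    c = h[:, 2] * cosp + h[:, 3] * sinp
    d = -h[:, 2] * sinp + h[:, 3] * cosp
    return EFTCoefficients(coef.dc, np.column_stack((a, b, c, d)), coef.perimeter)


def normalize_phase(coef: EFTCoefficients) -> EFTCoefficients:
    """Move the starting point to the nearer end of the first-harmonic ellipse.

    The raw starting vertex of a traced outline wanders along flat margins
    under digitization noise, which scrambles the (cos, sin) split of every
    harmonic. The classical remedy re-parameterizes so t = 0 sits where the
    first-harmonic ellipse crosses its major axis; of the two such crossings
    the one closest to the current (anatomically anchored) start is chosen,
    so the anterior-first convention survives while its jitter is removed.
    Orientation is NOT normalized — acquisition orientation is preserved.
    """
    a1, b1, c1, d1 = coef.harmonics[0]
    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1),
                             a1**2 + c1**2 - b1**2 - d1**2)
    # candidates theta + k*pi/... the major-axis crossings are pi apart
    candidates = [theta, theta + np.pi, theta - np.pi]
    phi1 = min(candidates, key=abs)
    return shift_start(coef, phi1)


def harmonic_power(coef: EFTCoefficients):
    """Per-harmonic power (a^2+b^2+c^2+d^2)/2 and cumulative fractions."""
    h = coef.harmonics
    power = 0.5 * (h**2).sum(axis=1)
    total = power.sum()
    if total <= 0:
        raise ValueError("outline has zero harmonic power (degenerate)")
    return power, np.cumsum(power) / total


def choose_n_harmonics(cumulative_fractions, threshold: float = 0.99) -> int:
    """Smallest harmonic count whose cumulative power reaches ``threshold``.

    Accepts one outline's cumulative-fraction vector or a list of them (one
    per outline of a dataset); a dataset gets the maximum over outlines, so a
    single shared harmonic count serves the whole analysis.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    fracs = cumulative_fractions
    if np.ndim(fracs[0]) == 0:  # one outline's vector
        arrs = [np.asarray(fracs, float)]
    else:  # a dataset: one vector per outline
        arrs = [np.asarray(f, float) for f in fracs]
    best = 1
    for f in arrs:
        if np.any(np.diff(f) < -1e-9):
            raise ValueError("cumulative fractions must be non-decreasing")
        idx = np.flatnonzero(f >= threshold - 1e-12)
        n = int(idx[0]) + 1 if idx.size else len(f)
        best = max(best, n)
    return best


def coefficient_matrix(coefs, n_harmonics: int) -> np.ndarray:
    """Stack per-outline coefficients into a (shapes, 4*n_harmonics) matrix.

    Row layout (a1, b1, c1, d1, a2, ...). DC terms are excluded: outlines are
    expected to be centered (normalize_outline) before the forward transform,
    which makes them ~0.
    """
    rows = []
    for i, c in enumerate(coefs):
        if c.n_harmonics < n_harmonics:
            raise ValueError(
                f"outline {i} has {c.n_harmonics} harmonics, need {n_harmonics}"
            )
        rows.append(c.harmonics[:n_harmonics].ravel())
    return np.stack(rows)


def eft_header(n_harmonics: int) -> list[str]:
    """CSV column names a1,b1,c1,d1,a2,... for a coefficient matrix."""
    return [f"{letter}{n}" for n in range(1, n_harmonics + 1) for letter in "abcd"]


def save_calibration_report(path, per_outline_n, chosen_n, threshold) -> None:
    Path(path).write_text(json.dumps({
        "threshold": threshold,
        "per_outline_harmonics": list(map(int, per_outline_n)),
        "chosen_n_harmonics": int(chosen_n),
    }, indent=2), encoding="utf-8")
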