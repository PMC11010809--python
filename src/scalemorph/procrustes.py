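"""Ordinary and generalized Procrustes superimposition of 2-D configurations.

Partial Procrustes scheme: every configuration is centered and scaled to unit
centroid size once, then iteratively rotated onto the running consensus (the
pointwise mean), which removes position, scale and rotation while leaving
shape. Optional bending-energy sliding lets semilandmarks move along their
local tangent to minimize thin-plate-spline bending energy against the
consensus — the treatment geomorph applies by default — while the default
keeps them fixed at their equidistant positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .landmarks import LandmarkedShape
from .outline import centroid_size

__all__ = ["AlignedShapeSet", "centroid_size", "opa_align", "gpa", "tps_bending_energy"]


def _center_scale(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    return c / np.sqrt((c**2).sum())


def _optimal_rotation(shape: np.ndarray, reference: np.ndarray,
                      allow_reflection: bool) -> np.ndarray:
    """Rotation R (applied as ``shape @ R``) minimizing ||shape @ R - reference||."""
    m = shape.T @ reference
    u, _s, vt = np.linalg.svd(m)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def opa_align(shape, reference, allow_reflection: bool = False):
    """Ordinary Procrustes: rotate ``shape`` onto ``reference``.

    Both configurations are centered and scaled to unit centroid size
    internally. Returns ``(aligned, angle, residual)`` where ``angle`` is the
    counterclockwise rotation applied and ``residual`` the root-sum-of-squares
    coordinate difference (partial Procrustes distance). Reflections are only
    permitted when ``allow_reflection`` — scales are imaged in a standard
    orientation, so an improper fit usually signals a digitization error.
    """
    shape = np.asarray(shape, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if shape.shape != reference.shape:
        raise ValueError(f"point counts differ: {shape.shape} vs {reference.shape}")
    sc = _center_scale(shape)
    rc = _center_scale(reference)
    r = _optimal_rotation(sc, rc, allow_reflection)
    aligned = sc @ r
    angle = float(np.arctan2(r[0, 1], r[0, 0]))
    residual = float(np.sqrt(((aligned - rc) ** 2).sum()))
    return aligned, angle, residual


def tps_bending_energy_matrix(reference: np.ndarray, ridge: float = 1e-10) -> np.ndarray:
    """Thin-plate-spline bending energy matrix of a 2-D reference configuration.

    Returns the k x k matrix B such that a displacement field taking the
    reference points to targets ``y`` (per coordinate) has bending energy
    ``y^T B y``; affine displacement fields have zero energy.
    """
    ref = np.asarray(reference, dtype=float)
    k = len(ref)
    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        kmat = np.where(d2 > 0, d2 * np.log(d2), 0.0)
    q = np.column_stack((np.ones(k), ref))
    ell = np.zeros((k + 3, k + 3))
    ell[:k, :k] = kmat + ridge * np.eye(k)
    ell[:k, k:] = q
    ell[k:, :k] = q.T
    binv = np.linalg.inv(ell)[:k, :k]
    return (binv + binv.T) / 2.0


def tps_bending_energy(reference: np.ndarray, target: np.ndarray) -> float:
    """Bending energy of the TPS mapping reference -> target (both k x 2)."""
    b = tps_bending_energy_matrix(reference)
    t = np.asarray(target, dtype=float)
    return float(t[:, 0] @ b @ t[:, 0] + t[:, 1] @ b @ t[:, 1])


def _chain_tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangents of the closed chain through the configuration points."""
    fwd = np.roll(points, -1, axis=0) - np.roll(points, 1, axis=0)
    norms = np.linalg.norm(fwd, axis=1, keepdims=True)
    return fwd / np.where(norms > 0, norms, 1.0)


def _project_to_chain(points: np.ndarray, chain: np.ndarray) -> np.ndarray:
    """Project each point onto the closed polyline through ``chain``."""
    a = chain
    b = np.roll(chain, -1, axis=0)
    ab = b - a
    denom = (ab**2).sum(axis=1)
    out = np.empty_like(points)
    for i, p in enumerate(points):
        t = np.clip(((p - a) * ab).sum(axis=1) / np.where(denom > 0, denom, 1.0), 0, 1)
        proj = a + t[:, None] * ab
        out[i] = proj[np.argmin(((proj - p) ** 2).sum(axis=1))]
    return out


def _slide_semilandmarks(points: np.ndarray, consensus: np.ndarray,
                         semi_mask: np.ndarray) -> np.ndarray:
    """One bending-energy sliding step of ``points`` against ``consensus``.

    Semilandmarks move along the local tangent of their own chain to minimize
    TPS bending energy relative to the consensus, then are re-projected onto
    the original chain so they stay on the outline polyline. Fixed landmarks
    never move.
    """
    k = len(points)
    semi_idx = np.flatnonzero(semi_mask)
    if semi_idx.size == 0:
        return points
    b = tps_bending_energy_matrix(consensus)
    tangents = _chain_tangents(points)
    # stacked-coordinate quadratic form: E(z) = zx^T B zx + zy^T B zy
    u = tangents[semi_idx]  # (m, 2)
    # gradient/Hessian of E w.r.t. slide parameters t (points + t * u)
    bx = b @ points[:, 0]
    by = b @ points[:, 1]
    g = u[:, 0] * bx[semi_idx] + u[:, 1] * by[semi_idx]
    bsub = b[np.ix_(semi_idx, semi_idx)]
    h = (u[:, 0:1] * bsub * u[:, 0:1].T) + (u[:, 1:2] * bsub * u[:, 1:2].T)
    h += 1e-12 * np.eye(len(semi_idx)) * max(1.0, np.abs(h).max())
    t = np.linalg.solve(h, -g)
    slid = points.copy()
    slid[semi_idx] += t[:, None] * u
    slid[semi_idx] = _project_to_chain(slid[semi_idx], points)
    return slid


@dataclass
class AlignedShapeSet:
    """Procrustes-superimposed configurations plus their consensus.

    ``shapes`` hold aligned coordinates (centroid at origin, unit centroid
    size); ``consensus`` is their pointwise mean; ``centroid_sizes`` are the
    pre-alignment sizes in input units (millimetres when calibration was
    applied at load).
    """

    shapes: list
    consensus: LandmarkedShape
    centroid_sizes: np.ndarray
    iterations_used: int
    converged: bool
    slide: str = "none"
    residuals: np.ndarray = field(default=None)

    @property
    def coordinate_matrix(self) -> np.ndarray:
        """(n_shapes, 2k) matrix of aligned coordinates, rows (x1,y1,x2,y2,...)."""
        return np.stack([s.points.ravel() for s in self.shapes])

    def summary(self) -> str:
        lines = [
            "Generalized Procrustes alignment",
            f"  shapes:          {len(self.shapes)}",
            f"  points/shape:    {len(self.consensus)}"
            f" ({self.consensus.n_fixed} fixed)",
            f"  slide mode:      {self.slide}",
            f"  iterations:      {self.iterations_used}"
            f" ({'converged' if self.converged else 'NOT converged'})",
            f"  centroid size:   mean {self.centroid_sizes.mean():.4g},"
            f" range [{self.centroid_sizes.min():.4g}, {self.centroid_sizes.max():.4g}]",
            f"  mean residual:   {self.residuals.mean():.4g}",
        ]
        return "\n".join(lines)

    def report(self) -> dict:
        return {
            "n_shapes": len(self.shapes),
            "n_points": len(self.consensus),
            "slide": self.slide,
            "iterations_used": self.iterations_used,
            "converged": bool(self.converged),
            "centroid_sizes": self.centroid_sizes.tolist(),
            "residuals": self.residuals.tolist(),
        }

    def save_report(self, path) -> None:
        Path(path).write_text(json.dumps(self.report(), indent=2), encoding="utf-8")


def _as_shape_list(shapes) -> list[LandmarkedShape]:
    out = []
    for s in shapes:
        if isinstance(s, LandmarkedShape):
            out.append(s)
        else:
            out.append(LandmarkedShape.from_matrix(np.asarray(s, dtype=float)))
    return out


def gpa(shapes, slide: str = "none", tol: float = 1e-8, max_iter: int = 100,
        slide_iters: int = 5, allow_reflection: bool = False) -> AlignedShapeSet:
    """Generalized Procrustes analysis of two or more configurations.

    Iterates rotation-to-consensus and consensus update until the root-mean-
    square consensus change drops below ``tol``. ``slide="bending_energy"``
    additionally slides semilandmarks along their tangent to minimize
    thin-plate-spline bending energy against the consensus (fixed landmarks
    never move); the default leaves all points fixed. Sliding runs during the
    first ``slide_iters`` rounds only, so the align-slide-reproject loop
    cannot cycle below the convergence tolerance once positions stabilize.

    After convergence the consensus (and every aligned shape with it) is
    rotated so the landmark 1 -> landmark 4 chord — anterior tip to
    mid-posterior — is horizontal, removing the rotational indeterminacy of
    the superimposition; configurations without labeled landmarks are gauged
    by the consensus principal axis instead.
    """
    if slide not in ("none", "bending_energy"):
        raise ValueError(f"unknown slide mode {slide!r}")
    shp = _as_shape_list(shapes)
    if len(shp) < 2:
        raise ValueError("need at least 2 shapes")
    k = len(shp[0])
    for s in shp[1:]:
        if len(s) != k or s.roles != shp[0].roles:
            raise ValueError("all shapes must share point count and role structure")

    sizes = np.array([centroid_size(s.points) for s in shp])
    coords = [_center_scale(s.points.copy()) for s in shp]
    semi_mask = shp[0].is_semi if slide == "bending_energy" else np.zeros(k, bool)

    consensus = coords[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i, x in enumerate(coords):
            r = _optimal_rotation(x, consensus, allow_reflection)
            coords[i] = x @ r
        if semi_mask.any() and iterations <= slide_iters:
            for i, x in enumerate(coords):
                coords[i] = _center_scale(_slide_semilandmarks(x, consensus, semi_mask))
        new_consensus = np.mean(coords, axis=0)
        new_consensus = _center_scale(new_consensus)
        change = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn(f"GPA did not converge in {max_iter} iterations", stacklevel=2)

    # final pass so every shape is aligned to the final consensus
    for i, x in enumerate(coords):
        coords[i] = x @ _optimal_rotation(x, consensus, allow_reflection)
    mean = np.mean(coords, axis=0)

    # orientation gauge, removing GPA's rotational indeterminacy: landmark
    # 1 -> 4 chord horizontal when landmarks are labeled, otherwise the
    # consensus principal axis along x (sign fixed by the most extreme point)
    lmi = shp[0].landmark_index
    ang = None
    if 1 in lmi and 4 in lmi:
        chord = mean[lmi[4]] - mean[lmi[1]]
        ang = np.arctan2(chord[1], chord[0])
    else:
        cov = mean.T @ mean
        evals, evecs = np.linalg.eigh(cov)
        if evals[1] - evals[0] > 1e-12 * evals[1]:
            ang = np.arctan2(evecs[1, 1], evecs[0, 1])
    if ang is not None:
        c, s_ = np.cos(-ang), np.sin(-ang)
        rot = np.array([[c, s_], [-s_, c]])  # row-vector rotation by -ang
        rotated = mean @ rot
        if rotated[np.argmax(np.abs(rotated[:, 0])), 0] < 0:
            rot = -rot  # resolve the pi ambiguity of the axis
        coords = [x @ rot for x in coords]
        mean = mean @ rot

    aligned = [shp[i].with_points(coords[i]) for i in range(len(shp))]
    residuals = np.array([np.sqrt(((x - mean) ** 2).sum()) for x in coords])
    return AlignedShapeSet(
        shapes=aligned,
        consensus=shp[0].with_points(mean),
        centroid_sizes=sizes,
        iterations_used=iterations,
        converged=converged,
        slide=slide,
        residuals=residuals,
    )
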