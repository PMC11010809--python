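"""End-to-end analysis pipelines.

Chains the toolkit modules into the two standard experiments:

* landmark route (``analyze_lm``): snap digitized landmarks to the traced
  outline, place the 5 + 80 configuration, generalized Procrustes
  superimposition, PCA, pairwise PERMANOVA on the aligned coordinates,
  Welch tests on centroid size and the shape-on-size allometry regression;
* outline route (``analyze_ol``): equidistant resampling, normalization,
  elliptic Fourier transform calibrated to 99% cumulative harmonic power
  over the dataset, PCA and pairwise PERMANOVA on the coefficient matrix.

Studies come from disk (``load_study``: masks + TPS + metadata, with pixel
coordinates converted to millimetres via each scale's calibration) or
directly from the synthetic generator (``study_from_synthetic``).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .eft import (choose_n_harmonics, coefficient_matrix, eft_forward, eft_header,
                  harmonic_power)
from .io import read_mask, read_metadata, read_tps
from .landmarks import DEFAULT_SEGMENT_PLAN, build_configuration, snap_landmarks
from .outline import (OutlinePolygon, anterior_ray_start, normalize_outline,
                      resample_equidistant, trace_boundary)
from .procrustes import AlignedShapeSet, gpa
from .stats import (PCAModel, RegressionResult, pairwise_permanova, pca_fit,
                    shape_size_regression, significance_stars, size_group_tests)

logger = logging.getLogger(__name__)

__all__ = [
    "Study", "load_study", "study_from_synthetic",
    "LMResult", "OLResult", "analyze_lm", "analyze_ol",
    "write_lm_outputs", "write_ol_outputs",
]


@dataclass
class Study:
    """In-memory dataset: outlines in mm, optional landmarks, metadata."""

    scale_ids: list
    polygons: dict
    records: dict
    landmarks: dict = field(default_factory=dict)

    def groups(self, column: str = "species") -> np.ndarray:
        vals = [getattr(self.records[sid], column) for sid in self.scale_ids]
        if any(v is None for v in vals):
            missing = [s for s, v in zip(self.scale_ids, vals) if v is None]
            raise ValueError(f"grouping column {column!r} missing for: {missing[:5]} ...")
        return np.asarray(vals)


def load_study(masks_dir, tps_path, metadata_path, *, flip_y: bool = False) -> Study:
    """Load a study from disk, converting pixel coordinates to millimetres.

    Every metadata scale_id must have a mask ``<masks_dir>/<scale_id>.png``
    (or .tif/.tiff) and, when ``tps_path`` is given, a TPS record with the
    same id; mismatches are listed exhaustively before aborting.
    """
    masks_dir = Path(masks_dir)
    records = {r.scale_id: r for r in read_metadata(metadata_path)}
    tps = {}
    if tps_path is not None:
        tps = {rec.shape_id: rec for rec in read_tps(tps_path, flip_y=flip_y)}

    problems = []
    mask_paths = {}
    for sid in records:
        for ext in (".png", ".tif", ".tiff"):
            p = masks_dir / f"{sid}{ext}"
            if p.exists():
                mask_paths[sid] = p
                break
        else:
            problems.append(f"no mask image for scale_id {sid!r}")
    if tps:
        for sid in records:
            if sid not in tps:
                problems.append(f"no TPS record for scale_id {sid!r}")
        for sid in tps:
            if sid not in records:
                problems.append(f"TPS record {sid!r} has no metadata row")
    if problems:
        raise ValueError("dataset inconsistencies:\n  " + "\n  ".join(problems))

    polygons, landmarks = {}, {}
    for sid, rec in records.items():
        mask = read_mask(mask_paths[sid])
        poly = trace_boundary(mask)
        polygons[sid] = OutlinePolygon(poly.vertices / rec.pixels_per_mm)
        if tps:
            landmarks[sid] = tps[sid].points / rec.pixels_per_mm
    logger.info("loaded %d scales from %s", len(records), masks_dir)
    return Study(scale_ids=list(records), polygons=polygons, records=records,
                 landmarks=landmarks)


def study_from_synthetic(ds) -> Study:
    """Wrap a SyntheticDataset (already in mm) as a Study, no rasterization."""
    return Study(scale_ids=[r.scale_id for r in ds.records],
                 polygons=dict(ds.polygons),
                 records={r.scale_id: r for r in ds.records},
                 landmarks=dict(ds.landmarks))


# ----------------------------------------------------------------- LM route

@dataclass
class LMResult:
    """Landmark-route outputs: alignment, ordination and inference tables."""

    aligned: AlignedShapeSet
    pca: PCAModel
    pairwise: list               # (a, b, PermanovaResult)
    size_tests: list             # (a, b, p, mean_a, mean_b)
    allometry: RegressionResult
    grouping: str
    scale_ids: list
    seed: int

    def pairwise_table(self) -> pd.DataFrame:
        return _pairwise_frame(self.pairwise)

    def summary(self) -> str:
        parts = [f"Landmark-based analysis ({len(self.scale_ids)} scales, "
                 f"grouping by {self.grouping})",
                 self.aligned.summary(), self.pca.summary(),
                 self.allometry.summary(),
                 _pairwise_frame(self.pairwise).to_string(index=False)]
        return "\n\n".join(parts)


def analyze_lm(study: Study, grouping: str = "species",
               counts=DEFAULT_SEGMENT_PLAN, slide: str = "none",
               n_permutations: int = 999, seed: int = 0,
               adjust: str = "bonferroni") -> LMResult:
    """Run the landmark route on a study with digitized landmarks."""
    if not study.landmarks:
        raise ValueError("study has no landmarks; the landmark route needs TPS input")
    shapes = []
    for sid in study.scale_ids:
        poly = study.polygons[sid]
        positions, poly_t, _rev = snap_landmarks(poly, study.landmarks[sid])
        shapes.append(build_configuration(poly_t, positions, counts))
    aligned = gpa(shapes, slide=slide)
    groups = study.groups(grouping)
    coords = aligned.coordinate_matrix
    pca = pca_fit(coords)
    pairwise = pairwise_permanova(coords, groups, n_permutations=n_permutations,
                                  seed=seed, adjust=adjust)
    sizes = aligned.centroid_sizes
    size_tab = size_group_tests(sizes, groups)
    allometry = shape_size_regression(aligned, sizes, n_permutations=n_permutations,
                                      seed=seed + 1)
    logger.info("LM route: %d scales, %d points each, %d pairs tested",
                len(shapes), len(shapes[0]), len(pairwise))
    return LMResult(aligned=aligned, pca=pca, pairwise=pairwise,
                    size_tests=size_tab, allometry=allometry,
                    grouping=grouping, scale_ids=list(study.scale_ids), seed=seed)


# ----------------------------------------------------------------- OL route

@dataclass
class OLResult:
    """Outline-route outputs: calibration, coefficients, ordination, tests."""

    n_harmonics: int
    per_outline_harmonics: list
    coefficients: np.ndarray
    pca: PCAModel
    pairwise: list
    grouping: str
    scale_ids: list
    n_points: int
    seed: int

    def pairwise_table(self) -> pd.DataFrame:
        return _pairwise_frame(self.pairwise)

    def summary(self) -> str:
        parts = [f"Outline-based analysis ({len(self.scale_ids)} scales, "
                 f"grouping by {self.grouping})",
                 f"harmonics kept: {self.n_harmonics} "
                 f"(99% power over dataset; outlines resampled to {self.n_points})",
                 self.pca.summary(),
                 _pairwise_frame(self.pairwise).to_string(index=False)]
        return "\n\n".join(parts)


def analyze_ol(study: Study, grouping: str = "species", n_points: int = 360,
               power_threshold: float = 0.99, max_harmonics: int = 32,
               n_permutations: int = 999, seed: int = 0,
               adjust: str = "bonferroni") -> OLResult:
    """Run the outline route: resample, normalize, EFT at 99% power, test."""
    coefs, per_n = [], []
    nyquist = n_points // 2
    n_max = min(max_harmonics, nyquist)
    for sid in study.scale_ids:
        raw = study.polygons[sid]
        poly = normalize_outline(
            resample_equidistant(raw, n_points, start_arc=anterior_ray_start(raw)))
        coef = eft_forward(poly, n_max)
        _, cum = harmonic_power(coef)
        per_n.append(choose_n_harmonics(cum, power_threshold))
        coefs.append(coef)
    n_h = min(max(per_n), n_max)
    matrix = coefficient_matrix(coefs, n_h)
    groups = study.groups(grouping)
    pca = pca_fit(matrix)
    pairwise = pairwise_permanova(matrix, groups, n_permutations=n_permutations,
                                  seed=seed, adjust=adjust)
    logger.info("OL route: %d outlines, %d harmonics kept (max needed %d)",
                len(coefs), n_h, max(per_n))
    return OLResult(n_harmonics=n_h, per_outline_harmonics=per_n,
                    coefficients=matrix, pca=pca, pairwise=pairwise,
                    grouping=grouping, scale_ids=list(study.scale_ids),
                    n_points=n_points, seed=seed)


# ----------------------------------------------------------------- outputs

def _pairwise_frame(pairwise) -> pd.DataFrame:
    rows = []
    for a, b, r in pairwise:
        rows.append({
            "pair": f"{a} vs {b}", "R2": round(r.R2, 4),
            "pseudo_F": round(r.pseudo_F, 4), "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "signif": significance_stars(r.p_adjusted
                                         if r.p_adjusted is not None else r.p_raw),
        })
    return pd.DataFrame(rows)


def _provenance(seed: int, config: dict) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {"software": "scalemorph", "version": __version__, "seed": seed,
            "config": config, "config_sha256": hashlib.sha256(blob).hexdigest()}


def write_lm_outputs(result: LMResult, outdir, config: dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.pairwise_table().to_csv(outdir / "lm_permanova_pairwise.csv", index=False)
    k = len(result.aligned.consensus)
    cols = [f"{ax}{i + 1}" for i in range(k) for ax in "xy"]
    pd.DataFrame(result.aligned.coordinate_matrix, index=result.scale_ids,
                 columns=cols).to_csv(outdir / "lm_aligned_coords.csv")
    pd.DataFrame(result.pca.scores, index=result.scale_ids,
                 columns=[f"PC{i + 1}" for i in range(result.pca.n_components)]
                 ).to_csv(outdir / "lm_pca_scores.csv")
    pd.DataFrame(result.size_tests,
                 columns=["group_a", "group_b", "p_welch", "mean_a", "mean_b"]
                 ).to_csv(outdir / "lm_size_tests.csv", index=False)
    report = {
        "n_points": k, "n_fixed": result.aligned.consensus.n_fixed,
        "slide": result.aligned.slide,
        "gpa": result.aligned.report(),
        "allometry": {"R2": result.allometry.R2, "p_perm": result.allometry.p_perm},
        "provenance": _provenance(result.seed, config or {}),
    }
    (outdir / "lm_report.json").write_text(json.dumps(report, indent=2), encoding="utf-8")


def write_ol_outputs(result: OLResult, outdir, config: dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.pairwise_table().to_csv(outdir / "ol_permanova_pairwise.csv", index=False)
    pd.DataFrame(result.coefficients, index=result.scale_ids,
                 columns=eft_header(result.n_harmonics)
                 ).to_csv(outdir / "ol_eft_coefficients.csv")
    pd.DataFrame(result.pca.scores, index=result.scale_ids,
                 columns=[f"PC{i + 1}" for i in range(result.pca.n_components)]
                 ).to_csv(outdir / "ol_pca_scores.csv")
    report = {
        "n_harmonics": result.n_harmonics,
        "per_outline_harmonics": result.per_outline_harmonics,
        "n_points": result.n_points,
        "provenance": _provenance(result.seed, config or {}),
    }
    (outdir / "ol_report.json").write_text(json.dumps(report, indent=2), encoding="utf-8")
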