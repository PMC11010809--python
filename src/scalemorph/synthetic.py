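"""Synthetic scale-shape generator.

Emulates single-scale silhouettes of the kind both pipelines consume:
rounded-quadrilateral elasmoid scale outlines, anterior margin at -x and
dorsal margin at +y, with the anterior margin carrying the species-diagnostic
oscillation style — smooth, striated (many shallow ripples), waved
(sinusoidal lobes) or dentate (triangular teeth). Five true landmarks sit at
the four margin junctions and the middle of the posterior margin, known by
construction, so the generator exercises every downstream stage with exact
ground truth.

Per-specimen biological variation is a smooth random radial field (low-order
Fourier perturbation of the radius function), which cannot self-intersect a
star-shaped outline and spans the same descriptor space as the elliptic
Fourier pipeline. Group-level effects perturb the template the same way,
scaled by an effect size delta. Everything is deterministic under a seed, and
datasets can be written to disk in exactly the formats the I/O layer reads
(PNG masks, TPS landmarks, CSV metadata).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import BinaryMask, LandmarkFileRecord, ScaleRecord, write_mask, write_metadata, write_tps
from .outline import OutlinePolygon

__all__ = [
    "ScaleTemplate",
    "SpecimenSample",
    "SyntheticDataset",
    "make_template",
    "sample_specimen",
    "rasterize",
    "generate_dataset",
    "species_templates",
    "STUDY_GROUP_SIZES",
]

MARGIN_STYLES = ("smooth", "striated", "waved", "dentate")

STUDY_GROUP_SIZES = {
    "dentate_sp": 35,   # mullet-like
    "striated_sp": 29,  # seabass-like
    "smooth_sp": 11,    # sardine-like
    "waved_sp": 81,     # seabream-like
    "smooth_small_sp": 28,  # zebrafish-like
}
"""Scales per species in the study design this generator emulates."""

_STYLE_DEFAULTS = {
    "smooth": (0.0, 0),
    "striated": (0.012, 24),
    "waved": (0.05, 6),
    "dentate": (0.07, 8),
}

# landmark angular stations on the unit parameter circle, counterclockwise:
# 1 dorsal-anterior, 2 ventral-anterior, 3 ventral-posterior, 4 mid-posterior,
# 5 dorsal-posterior.  Margin 1->2 (anterior) faces -x.
_LM_THETA_OFFSETS = (0.0, np.pi / 2, np.pi, 5 * np.pi / 4, 3 * np.pi / 2)
_THETA0 = 3 * np.pi / 4


@dataclass(frozen=True)
class ScaleTemplate:
    """Deterministic species-level scale outline with known landmarks."""

    name: str
    margin_style: str
    aspect_ratio: float
    oscillation_amplitude: float
    oscillation_count: int
    base_outline: OutlinePolygon = field(repr=False)
    true_landmarks: np.ndarray = field(repr=False)  # 5 arc positions
    radius_mm: float = 1.0
    squareness: float = 4.0

    @property
    def landmark_points(self) -> np.ndarray:
        return self.base_outline.point_at(self.true_landmarks)


def _radius_profile(theta: np.ndarray, aspect_ratio: float, squareness: float,
                    amplitude: float, count: int, style: str) -> np.ndarray:
    """Radius function of the template: superellipse plus anterior oscillation."""
    p = squareness
    base = (np.abs(np.cos(theta) / aspect_ratio) ** p + np.abs(np.sin(theta)) ** p) ** (-1.0 / p)
    if amplitude > 0 and count > 0:
        # anterior margin: theta in (3pi/4, 5pi/4); u in (0, 1) across it
        rel = np.mod(theta - _THETA0, 2 * np.pi)
        u = rel / (np.pi / 2)
        on_ant = (u > 0) & (u < 1)
        window = np.sin(np.pi * np.clip(u, 0, 1)) ** 2
        if style == "dentate":
            # triangle teeth peaking at the half-integer stations, so all
            # `count` teeth sit strictly inside the margin window
            wave = 4.0 * np.abs(((count * u + 0.5) % 1.0) - 0.5) - 1.0
        else:
            wave = -np.cos(2 * np.pi * count * u)
        base = base * (1.0 + amplitude * window * wave * on_ant)
    return base


def make_template(margin_style: str, aspect_ratio: float = 1.2,
                  oscillation_amplitude: float | None = None,
                  oscillation_count: int | None = None,
                  radius_mm: float = 1.0, squareness: float = 4.0,
                  n_vertices: int = 720, name: str | None = None) -> ScaleTemplate:
    """Build a species template with the requested anterior-margin style.

    The base outline is a rounded quadrilateral (superellipse of exponent
    ``squareness``) with semi-axes ``radius_mm * aspect_ratio`` along x and
    ``radius_mm`` along y; the anterior margin between landmarks 1 and 2 is
    modulated by the style's oscillation. Amplitude is a fraction of the
    local radius; styles default to (smooth 0, striated 0.012 x 24,
    waved 0.05 x 6, dentate 0.07 x 8).
    """
    if margin_style not in MARGIN_STYLES:
        raise ValueError(f"margin_style must be one of {MARGIN_STYLES}")
    amp_d, cnt_d = _STYLE_DEFAULTS[margin_style]
    amplitude = amp_d if oscillation_amplitude is None else float(oscillation_amplitude)
    count = cnt_d if oscillation_count is None else int(oscillation_count)
    if margin_style == "smooth" and amplitude != 0:
        raise ValueError("smooth margins have zero oscillation amplitude")
    if amplitude < 0 or count < 0:
        raise ValueError("oscillation parameters must be non-negative")
    if amplitude >= 0.5:
        raise ValueError("oscillation amplitude >= 0.5 would self-intersect the outline")
    if n_vertices % 8 or n_vertices < 80:
        raise ValueError("n_vertices must be a multiple of 8 and >= 80")

    theta = _THETA0 + 2 * np.pi * np.arange(n_vertices) / n_vertices
    r = radius_mm * _radius_profile(theta, aspect_ratio, squareness, amplitude,
                                    count, margin_style)
    if np.any(r <= 0):
        raise ValueError("oscillation drives the radius non-positive")
    verts = np.column_stack((r * np.cos(theta), r * np.sin(theta)))
    poly = OutlinePolygon(verts)
    lm_idx = [int(round(off / (2 * np.pi) * n_vertices)) for off in _LM_THETA_OFFSETS]
    lm_arc = poly.arc_positions[lm_idx]
    return ScaleTemplate(
        name=name or f"{margin_style}_template",
        margin_style=margin_style, aspect_ratio=float(aspect_ratio),
        oscillation_amplitude=amplitude, oscillation_count=count,
        base_outline=poly, true_landmarks=np.asarray(lm_arc, float),
        radius_mm=float(radius_mm), squareness=float(squareness),
    )


def _perturb_template(template: ScaleTemplate, coeffs: np.ndarray) -> ScaleTemplate:
    """Apply a radial Fourier field (rows (alpha_j, beta_j)) to the template."""
    poly = template.base_outline
    v = poly.vertices
    theta = np.arctan2(v[:, 1], v[:, 0])
    factor = np.ones(len(v))
    for j, (a, b) in enumerate(coeffs, start=1):
        factor += a * np.cos(j * theta) + b * np.sin(j * theta)
    if np.any(factor <= 0):
        raise ValueError("perturbation drives the radius non-positive")
    new_poly = OutlinePolygon(v * factor[:, None])
    lm_idx = [int(round(off / (2 * np.pi) * len(v))) for off in _LM_THETA_OFFSETS]
    return replace(template, base_outline=new_poly,
                   true_landmarks=new_poly.arc_positions[lm_idx])


@dataclass(frozen=True)
class SpecimenSample:
    """One sampled specimen: outline, true landmarks, optional raster mask."""

    polygon: OutlinePolygon = field(repr=False)
    landmarks: np.ndarray = field(repr=False)  # 5 x 2, same frame as polygon
    mask: BinaryMask | None = field(default=None, repr=False)
    pixels_per_mm: float | None = None
    mask_origin: tuple | None = None


def sample_specimen(template: ScaleTemplate, noise_sd: float, seed,
                    n_radial_orders: int = 6, rotation_jitter_sd: float = 0.02,
                    scale_jitter_sd: float = 0.03,
                    pixels_per_mm: float | None = None,
                    max_retries: int = 10) -> SpecimenSample:
    """Draw one specimen from a template.

    The outline radius is modulated by a low-order random Fourier field with
    coefficients ~ Normal(0, noise_sd^2) over ``n_radial_orders`` orders, plus
    small random rotation and scale jitter (removed downstream by
    normalization / superimposition). ``noise_sd = 0`` reproduces the
    template exactly. With ``pixels_per_mm`` set, the outline is also
    rasterized to a silhouette mask.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:  # exact template reproduction
        rotation_jitter_sd = scale_jitter_sd = 0.0
    rng = np.random.default_rng(seed)
    poly = template.base_outline
    v = poly.vertices
    theta = np.arctan2(v[:, 1], v[:, 0])
    lm_pts = template.landmark_points

    for attempt in range(max_retries):
        coeffs = rng.normal(0.0, noise_sd, size=(n_radial_orders, 2)) if noise_sd > 0 \
            else np.zeros((n_radial_orders, 2))
        orders = np.arange(1, n_radial_orders + 1)[:, None]
        factor = 1.0 + (coeffs[:, 0:1] * np.cos(orders * theta)
                        + coeffs[:, 1:2] * np.sin(orders * theta)).sum(axis=0)
        if np.all(factor > 0.05):
            break
    else:
        raise ValueError(f"self-intersecting deformation after {max_retries} retries")

    rot = rng.normal(0.0, rotation_jitter_sd) if rotation_jitter_sd > 0 else 0.0
    scale = float(np.exp(rng.normal(0.0, scale_jitter_sd))) if scale_jitter_sd > 0 else 1.0
    c, s = np.cos(rot), np.sin(rot)
    rmat = np.array([[c, s], [-s, c]])  # row-vector rotation by rot

    def deform(points: np.ndarray) -> np.ndarray:
        th = np.arctan2(points[:, 1], points[:, 0])
        f = 1.0 + (coeffs[:, 0:1] * np.cos(orders * th)
                   + coeffs[:, 1:2] * np.sin(orders * th)).sum(axis=0)
        return scale * (points * f[:, None]) @ rmat

    new_poly = OutlinePolygon(deform(v))
    new_lms = deform(lm_pts)
    mask = origin = None
    ppm = None
    if pixels_per_mm is not None:
        mask, origin = rasterize(new_poly, pixels_per_mm)
        ppm = float(pixels_per_mm)
    return SpecimenSample(polygon=new_poly, landmarks=new_lms, mask=mask,
                          pixels_per_mm=ppm, mask_origin=origin)


def rasterize(poly: OutlinePolygon, pixels_per_mm: float, pad: int = 2):
    """Rasterize an outline (mm units) to a silhouette mask.

    Returns ``(mask, origin)`` where ``origin`` is the mm coordinate of the
    pixel-grid point that maps to column 0 / bottom row, so that a traced
    contour can be mapped back: mm = origin + trace_xy / pixels_per_mm.
    """
    if pixels_per_mm <= 0:
        raise ValueError("pixels_per_mm must be positive")
    v = poly.vertices
    x0 = v[:, 0].min() - pad / pixels_per_mm
    y0 = v[:, 1].min() - pad / pixels_per_mm
    cols = (v[:, 0] - x0) * pixels_per_mm
    ys = (v[:, 1] - y0) * pixels_per_mm
    height = int(np.ceil(ys.max())) + 1 + pad
    width = int(np.ceil(cols.max())) + 1 + pad
    rows = (height - 1) - ys
    # scanline fill: a pixel center is foreground when the horizontal ray
    # through it crosses the polygon an odd number of times (vectorized
    # even-odd rule over all rows at once)
    r0, r1 = rows, np.roll(rows, -1)
    c0, c1 = cols, np.roll(cols, -1)
    scan = np.arange(height, dtype=float)[:, None]
    crosses = (r0[None, :] <= scan) != (r1[None, :] <= scan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (scan - r0[None, :]) / (r1 - r0)[None, :]
    xs = c0[None, :] + t * (c1 - c0)[None, :]
    row_idx, edge_idx = np.nonzero(crosses)
    xvals = xs[row_idx, edge_idx]
    order = np.lexsort((xvals, row_idx))
    row_s, x_s = row_idx[order], xvals[order]
    # crossings per row come in pairs bounding foreground spans
    left, right = x_s[0::2], x_s[1::2]
    span_row = row_s[0::2]
    c_start = np.ceil(left).astype(int)
    c_end = np.floor(right).astype(int)
    ok = c_end >= c_start
    diff = np.zeros((height, width + 1), dtype=np.int32)
    np.add.at(diff, (span_row[ok], np.clip(c_start[ok], 0, width)), 1)
    np.add.at(diff, (span_row[ok], np.clip(c_end[ok] + 1, 0, width)), -1)
    grid = (np.cumsum(diff, axis=1)[:, :width] > 0).astype(np.uint8)
    return BinaryMask(grid), (float(x0), float(y0))


@dataclass
class SyntheticDataset:
    """A generated study: per-specimen outlines, landmarks, metadata, truth."""

    records: list
    polygons: dict
    landmarks: dict
    truth: dict

    @property
    def groups(self) -> list:
        return sorted({r.species for r in self.records})

    def group_of(self, scale_id: str) -> str:
        return next(r.species for r in self.records if r.scale_id == scale_id)

    def write(self, outdir, pixels_per_mm: float = 371.0) -> None:
        """Write masks/, landmarks.tps, metadata.csv and manifest.json.

        Masks are rasterized at ``pixels_per_mm``; TPS landmarks are written
        in the mask's pixel frame (x rightward, y upward from the bottom
        row), matching what the loaders reconstruct, and metadata carries the
        calibration so loads come back in millimetres.
        """
        outdir = Path(outdir)
        (outdir / "masks").mkdir(parents=True, exist_ok=True)
        tps_records = []
        records = []
        for rec in self.records:
            poly = self.polygons[rec.scale_id]
            lms = self.landmarks[rec.scale_id]
            mask, (x0, y0) = rasterize(poly, pixels_per_mm)
            write_mask(mask, outdir / "masks" / f"{rec.scale_id}.png")
            px_lms = (lms - np.array([x0, y0])) * pixels_per_mm
            tps_records.append(LandmarkFileRecord(
                shape_id=rec.scale_id, points=px_lms,
                image=f"masks/{rec.scale_id}.png"))
            records.append(ScaleRecord(
                scale_id=rec.scale_id, species=rec.species,
                specimen_id=rec.specimen_id, body_area=rec.body_area,
                group=rec.group, pixels_per_mm=pixels_per_mm))
        write_tps(tps_records, outdir / "landmarks.tps")
        write_metadata(records, outdir / "metadata.csv")
        manifest = dict(self.truth)
        manifest["pixels_per_mm"] = pixels_per_mm
        manifest["n_scales"] = len(records)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")


def generate_dataset(templates: dict, n_per_group: dict, effect_delta: float = 0.0,
                     noise_sd: float = 0.015, seed: int = 0,
                     landmark_jitter_sd: float = 0.0,
                     body_area: str = "D") -> SyntheticDataset:
    """Generate a grouped dataset of synthetic scales.

    ``templates`` maps group name -> ScaleTemplate; groups may share one
    template. ``effect_delta`` scales a fixed per-group radial perturbation of
    the template (delta = 0 leaves all groups at their given templates, the
    null construction when templates coincide). ``noise_sd`` is the
    per-specimen radial Fourier coefficient scale and ``landmark_jitter_sd``
    adds Normal operator error (mm) to the emitted landmarks. Deterministic
    under ``seed``.
    """
    if set(templates) != set(n_per_group):
        raise ValueError("templates and n_per_group must cover the same groups")
    if any(n < 2 for n in n_per_group.values()):
        raise ValueError("every group needs at least 2 specimens")
    if effect_delta < 0:
        raise ValueError("effect_delta must be >= 0")
    records, polygons, landmarks = [], {}, {}
    for gi, group in enumerate(sorted(templates)):
        # fixed per-group effect direction, scaled by delta
        g_rng = np.random.default_rng([seed % (2**31), 1000 + gi])
        direction = g_rng.normal(0.0, 1.0, size=(4, 2))
        direction /= np.linalg.norm(direction)
        tpl = templates[group]
        if effect_delta > 0:
            tpl = _perturb_template(tpl, effect_delta * direction)
        for i in range(n_per_group[group]):
            spec_seed = [seed % (2**31), 2000 + gi, i]
            sample = sample_specimen(tpl, noise_sd, spec_seed)
            scale_id = f"{group}_{i:03d}"
            lms = sample.landmarks
            if landmark_jitter_sd > 0:
                j_rng = np.random.default_rng([seed % (2**31), 3000 + gi, i])
                lms = lms + j_rng.normal(0.0, landmark_jitter_sd, size=lms.shape)
            records.append(ScaleRecord(
                scale_id=scale_id, species=group,
                specimen_id=f"{group}_spec{i // 8}", body_area=body_area,
                group=group, pixels_per_mm=1.0))
            polygons[scale_id] = sample.polygon
            landmarks[scale_id] = lms
    truth = {
        "groups": {g: {"template": templates[g].name,
                       "margin_style": templates[g].margin_style,
                       "n": n_per_group[g]} for g in sorted(templates)},
        "effect_delta": effect_delta,
        "noise_sd": noise_sd,
        "landmark_jitter_sd": landmark_jitter_sd,
        "seed": seed,
    }
    return SyntheticDataset(records=records, polygons=polygons,
                            landmarks=landmarks, truth=truth)


def species_templates() -> dict:
    """Five templates emulating the study species' scale-shape families.

    Margin styles follow the species' anterior-margin taxonomy (sardine-like
    smooth, seabass-like striated, seabream-like waved, mullet-like dentate,
    plus a smooth small-scale zebrafish-like family); radii reflect the
    gross size ordering (mullet largest, zebrafish smallest).
    """
    return {
        "dentate_sp": make_template("dentate", aspect_ratio=0.95, radius_mm=2.0,
                                    name="mullet_like"),
        "striated_sp": make_template("striated", aspect_ratio=1.05, radius_mm=1.3,
                                     name="seabass_like"),
        "smooth_sp": make_template("smooth", aspect_ratio=1.25, radius_mm=1.1,
                                   squareness=3.0, name="sardine_like"),
        "waved_sp": make_template("waved", aspect_ratio=1.15, radius_mm=1.2,
                                  name="seabream_like"),
        "smooth_small_sp": make_template("smooth", aspect_ratio=1.45, radius_mm=0.45,
                                         squareness=5.0, name="zebrafish_like"),
    }
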