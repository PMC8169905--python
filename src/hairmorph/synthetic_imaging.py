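"""Ground-truth image simulation for validating the fiber pipelines.

Two generators mirror the validation study design:

* **Arcs** — longitudinal-image stand-ins. Each image holds ``n_fragments``
  circular arcs of one known curvature ``c`` (mm⁻¹) at random orientations.
  An arc of radius ``r = 1/c`` sweeps from a start angle θ_start, drawn
  uniformly on (0, π), to ``θ_end = θ_start + π/(2 r)``, so the true arc
  length is ``r · π/(2r) = π/2`` mm for every arc regardless of curvature.
* **Ellipses** — cross-section stand-ins. The maximum diameter is drawn
  uniformly on 50–120 µm, the eccentricity uniformly on (0, 1) (which fixes
  the minimum diameter via ``2b = 2a·√(1−e²)``), and the rotation uniformly
  on 0–360°.

Both draw dark shapes on a light background as binary-contrast 8-bit images
and record the exact generating parameters in a truth table keyed by the
image filename stem.

Strokes are rasterized analytically: a pixel is foreground iff its center
lies within half the stroke width of the *continuous* arc (with round end
caps). This keeps the drawn centerline exactly on the nominal circle, so the
truth table is unbiased at every curvature, and gives stroke edges that are
clean digitizations of circles rather than ragged unions of dilated pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .io import CalibratedImage, write_csv

__all__ = [
    "ArcSpec",
    "EllipseSpec",
    "PlacementError",
    "arc_points",
    "simulate_arc_image",
    "generate_arc_dataset",
    "simulate_ellipse_image",
    "generate_ellipse_dataset",
    "DEFAULT_CURVATURE_GRID",
    "ARC_TRUTH_SCHEMA",
    "ELLIPSE_TRUTH_SCHEMA",
]

#: default curvature grid: 20 values evenly spaced over the study range (mm^-1)
DEFAULT_CURVATURE_GRID: tuple[float, ...] = tuple(np.linspace(0.1, 2.0, 20))

ARC_TRUTH_SCHEMA = ("image_id", "element_id", "curvature_per_mm", "length_mm")
ELLIPSE_TRUTH_SCHEMA = ("image_id", "min_diameter_um", "max_diameter_um", "area_um2", "eccentricity")

#: true arc length in mm, constant by construction of the sweep angle
TRUE_ARC_LENGTH_MM = math.pi / 2


class PlacementError(RuntimeError):
    """Canvas too small to place the requested fragments disjointly."""


@dataclass(frozen=True)
class ArcSpec:
    """One simulated arc: radius (mm), start angle (rad), sample count.

    The sweep is ``π/(2·radius_mm)`` so the arc length is always π/2 mm.
    """

    radius_mm: float
    theta_start: float = 0.0
    n_points: int = 25

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError(f"radius_mm must be positive, got {self.radius_mm}")
        if not (0 <= self.theta_start < math.pi):
            raise ValueError(f"theta_start must lie in [0, pi), got {self.theta_start}")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    @property
    def curvature_per_mm(self) -> float:
        return 1.0 / self.radius_mm

    @property
    def sweep(self) -> float:
        """Angular extent θ_end − θ_start in radians."""
        return math.pi / (2 * self.radius_mm)

    @property
    def length_mm(self) -> float:
        return self.radius_mm * self.sweep  # == pi/2 for every radius


@dataclass(frozen=True)
class EllipseSpec:
    """One simulated cross-section ellipse (diameters in µm)."""

    max_diameter_um: float
    eccentricity: float
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if not self.max_diameter_um > 0:
            raise ValueError("max_diameter_um must be positive")
        if not (0 <= self.eccentricity < 1):
            raise ValueError(f"eccentricity must lie in [0, 1), got {self.eccentricity}")
        if not (0 <= self.rotation_deg < 360):
            raise ValueError("rotation_deg must lie in [0, 360)")

    @property
    def min_diameter_um(self) -> float:
        return self.max_diameter_um * math.sqrt(1 - self.eccentricity**2)

    @property
    def area_um2(self) -> float:
        return math.pi * (self.max_diameter_um / 2) * (self.min_diameter_um / 2)


def arc_points(spec: ArcSpec, center: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Sample ``spec.n_points`` points on the arc, as (x, y) pairs.

    Points lie exactly on the circle of radius ``spec.radius_mm`` about
    ``center``, at angles uniformly spaced on [θ_start, θ_start + π/(2r)]:
    ``x = r·cos(θ_i)``, ``y = r·sin(θ_i)``.
    """
    r = spec.radius_mm
    theta = np.linspace(spec.theta_start, spec.theta_start + spec.sweep, spec.n_points)
    return np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)])


def _arc_bbox(r_px: float, theta0: float, sweep: float, half_w: float) -> tuple[float, float, float, float]:
    """Bounding box (xmin, xmax, ymin, ymax) of the stroked arc, relative to
    the circle center, in pixel units."""
    thetas = [theta0, theta0 + sweep]
    # include axis-crossing extrema inside the sweep
    k0 = math.ceil(theta0 / (math.pi / 2))
    k1 = math.floor((theta0 + sweep) / (math.pi / 2))
    thetas += [k * math.pi / 2 for k in range(k0, k1 + 1)]
    xs = [r_px * math.cos(t) for t in thetas]
    ys = [r_px * math.sin(t) for t in thetas]
    return (min(xs) - half_w, max(xs) + half_w, min(ys) - half_w, max(ys) + half_w)


def _rasterize_arc(
    canvas: np.ndarray,
    center_rc: tuple[float, float],
    r_px: float,
    theta0: float,
    sweep: float,
    half_w: float,
) -> None:
    """Set pixels within ``half_w`` of the continuous arc to foreground (0).

    Column maps to +x and row to +y; only the handedness of the drawing
    differs from math convention, which is immaterial for the analyses.
    """
    cy, cx = center_rc
    xmin, xmax, ymin, ymax = _arc_bbox(r_px, theta0, sweep, half_w + 1.5)
    r0 = max(0, int(math.floor(cy + ymin)))
    r1 = min(canvas.shape[0], int(math.ceil(cy + ymax)) + 1)
    c0 = max(0, int(math.floor(cx + xmin)))
    c1 = min(canvas.shape[1], int(math.ceil(cx + xmax)) + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dx = cc - cx
    dy = rr - cy
    d = np.hypot(dx, dy)
    ang = np.mod(np.arctan2(dy, dx) - theta0, 2 * math.pi)
    inside = (ang <= sweep) & (np.abs(d - r_px) <= half_w)
    for t in (theta0, theta0 + sweep):  # round end caps
        ex = cx + r_px * math.cos(t)
        ey = cy + r_px * math.sin(t)
        inside |= np.hypot(cc - ex, rr - ey) <= half_w
    canvas[r0:r1, c0:c1][inside] = 0


def simulate_arc_image(
    curvature_per_mm: float,
    n_fragments: int = 25,
    canvas_px: tuple[int, int] = (3900, 5200),
    resolution_px_per_mm: float = 132.0,
    seed: int | None = 0,
    stroke_width_px: float = 5.0,
    clearance_px: float = 10.0,
    image_id: str = "arc",
    max_attempts: int = 200,
) -> tuple[CalibratedImage, pd.DataFrame]:
    """Draw ``n_fragments`` disjoint arcs of one curvature at random
    orientations; return the image and its per-element truth table.

    Fragment placement is rejection sampling: a candidate start angle
    θ_start ~ U(0, π) and circle center are drawn, and the stroked arc's
    bounding box must fit the canvas and keep ``clearance_px`` from every
    previously placed fragment. Exhausting ``max_attempts`` for a fragment
    raises :class:`PlacementError`.
    """
    if not curvature_per_mm > 0:
        raise ValueError("curvature_per_mm must be positive")
    rng = np.random.default_rng(seed)
    h, w = canvas_px
    canvas = np.full((h, w), 255, dtype=np.uint8)
    r_mm = 1.0 / curvature_per_mm
    r_px = r_mm * resolution_px_per_mm
    sweep = math.pi / (2 * r_mm)
    half_w = stroke_width_px / 2.0
    placed: list[tuple[float, float, float, float]] = []  # (r0, r1, c0, c1)
    rows = []
    for element in range(n_fragments):
        for _ in range(max_attempts):
            theta0 = rng.uniform(0, math.pi)
            xmin, xmax, ymin, ymax = _arc_bbox(r_px, theta0, sweep, half_w)
            bb_h = ymax - ymin
            bb_w = xmax - xmin
            if bb_h + 4 > h or bb_w + 4 > w:
                raise PlacementError(
                    f"arc bounding box ({bb_h:.0f}x{bb_w:.0f} px) exceeds canvas {canvas_px}"
                )
            # circle center such that the stroked-arc bbox stays in-canvas
            cy = rng.uniform(2 - ymin, h - 2 - ymax)
            cx = rng.uniform(2 - xmin, w - 2 - xmax)
            box = (cy + ymin, cy + ymax, cx + xmin, cx + xmax)
            g = clearance_px
            if all(
                box[0] > b[1] + g or box[1] < b[0] - g or box[2] > b[3] + g or box[3] < b[2] - g
                for b in placed
            ):
                break
        else:
            raise PlacementError(
                f"could not place fragment {element + 1}/{n_fragments} after {max_attempts} attempts"
            )
        _rasterize_arc(canvas, (cy, cx), r_px, theta0, sweep, half_w)
        placed.append(box)
        rows.append(
            {
                "image_id": image_id,
                "element_id": element,
                "curvature_per_mm": curvature_per_mm,
                "length_mm": TRUE_ARC_LENGTH_MM,
            }
        )
    image = CalibratedImage(canvas, resolution=resolution_px_per_mm, unit="px/mm", image_id=image_id)
    return image, pd.DataFrame(rows, columns=list(ARC_TRUTH_SCHEMA))


def generate_arc_dataset(
    out_dir: str | Path,
    curvature_grid: "list[float] | tuple[float, ...]" = DEFAULT_CURVATURE_GRID,
    n_fragments: int = 25,
    canvas_px: tuple[int, int] = (3900, 5200),
    resolution_px_per_mm: float = 132.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Write one TIFF per grid curvature plus ``truth_arcs.csv``.

    Filenames encode the true curvature (``arc_c0.400.tiff``); the truth
    table has one row per drawn fragment, with the constant true length
    π/2 mm.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for i, curv in enumerate(curvature_grid):
        image_id = f"arc_c{curv:.3f}"
        img, truth = simulate_arc_image(
            curv,
            n_fragments=n_fragments,
            canvas_px=canvas_px,
            resolution_px_per_mm=resolution_px_per_mm,
            seed=seed + i,
            image_id=image_id,
        )
        tifffile.imwrite(out_dir / f"{image_id}.tiff", img.pixels)
        frames.append(truth)
    truth = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=list(ARC_TRUTH_SCHEMA))
    write_csv(truth, ARC_TRUTH_SCHEMA, out_dir / "truth_arcs.csv")
    return truth


def simulate_ellipse_image(
    spec: EllipseSpec | None = None,
    canvas_px: tuple[int, int] = (3900, 5200),
    resolution_px_per_um: float = 4.25,
    seed: int | None = 0,
    image_id: str = "ellipse",
) -> tuple[CalibratedImage, pd.DataFrame]:
    """Draw one filled dark ellipse centered on a light canvas.

    With ``spec=None`` the parameters are sampled: max diameter ~ U(50, 120)
    µm, eccentricity ~ U(0, 1), rotation ~ U(0°, 360°). The truth row stores
    the analytic min/max diameters, area π·a·b and eccentricity.
    """
    from skimage.draw import ellipse as draw_ellipse

    rng = np.random.default_rng(seed)
    if spec is None:
        spec = EllipseSpec(
            max_diameter_um=rng.uniform(50.0, 120.0),
            eccentricity=rng.uniform(0.0, 1.0),
            rotation_deg=rng.uniform(0.0, 360.0),
        )
    h, w = canvas_px
    a_px = spec.max_diameter_um / 2 * resolution_px_per_um
    b_px = spec.min_diameter_um / 2 * resolution_px_per_um
    if 2 * a_px >= min(h, w) - 4:
        raise ValueError(
            f"ellipse diameter {spec.max_diameter_um} um exceeds canvas {canvas_px} at "
            f"{resolution_px_per_um} px/um"
        )
    canvas = np.full((h, w), 255, dtype=np.uint8)
    rr, cc = draw_ellipse(
        h / 2, w / 2, a_px, b_px, shape=(h, w), rotation=math.radians(spec.rotation_deg)
    )
    canvas[rr, cc] = 0
    truth = pd.DataFrame(
        [
            {
                "image_id": image_id,
                "min_diameter_um": spec.min_diameter_um,
                "max_diameter_um": spec.max_diameter_um,
                "area_um2": spec.area_um2,
                "eccentricity": spec.eccentricity,
            }
        ],
        columns=list(ELLIPSE_TRUTH_SCHEMA),
    )
    image = CalibratedImage(canvas, resolution=resolution_px_per_um, unit="px/um", image_id=image_id)
    return image, truth


def generate_ellipse_dataset(
    out_dir: str | Path,
    n: int = 100,
    canvas_px: tuple[int, int] = (3900, 5200),
    resolution_px_per_um: float = 4.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Write ``n`` single-ellipse TIFFs plus ``truth_ellipses.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for i in range(n):
        image_id = f"ellipse_{i:03d}"
        img, truth = simulate_ellipse_image(
            canvas_px=canvas_px,
            resolution_px_per_um=resolution_px_per_um,
            seed=seed + i,
            image_id=image_id,
        )
        tifffile.imwrite(out_dir / f"{image_id}.tiff", img.pixels)
        frames.append(truth)
    truth = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=list(ELLIPSE_TRUTH_SCHEMA))
    write_csv(truth, ELLIPSE_TRUTH_SCHEMA, out_dir / "truth_ellipses.csv")
    return truth
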