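"""Radial histology quantification around an implant site.

Two quantifications, both radial from a manually marked implant center:

* fluorescence-intensity markers (GFAP, CD68, IgG): mean pixel intensity
  in 5-um concentric rings out to 1 mm, normalized to the 700-750 um
  background annulus, then the area under the normalized profile in
  50-um increments;
* neuron density (NeuN): manual neuron counts per area in 50-um rings out
  to 600 um, converted to percent of the 450-500 um background ring.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import DISTANCE_BINS, HISTOLOGY_VAR_OF, MARKERS
from .synthetic import SLICES_PER_ANIMAL, StudyBundle, SyntheticImage

RING_WIDTH_UM = 5.0
PROFILE_MAX_UM = 1000.0
BACKGROUND_RANGE_UM = (700.0, 750.0)
AUC_INCREMENT_UM = 50.0

NEURON_RING_UM = 50.0
NEURON_MAX_UM = 600.0
NEURON_BG_RING_UM = (450.0, 500.0)


@dataclass
class RadialProfile:
    """Ring-binned intensity profile of one section image."""

    marker: str
    animal_id: str
    ring_edges: np.ndarray            # 201 edges, 0..1000 um
    mean_intensity: np.ndarray        # 200 ring means (NaN = empty ring)
    n_pixels: np.ndarray
    normalized: np.ndarray | None = None
    auc_increments: np.ndarray | None = None   # 20 values, one per 50 um

    @property
    def ring_centers(self) -> np.ndarray:
        return 0.5 * (self.ring_edges[:-1] + self.ring_edges[1:])


@dataclass
class NeuronDensityProfile:
    """Ring-binned neuron counts, densities and percent-of-background."""

    animal_id: str
    ring_edges: np.ndarray            # 13 edges, 0..600 um
    count: np.ndarray
    area_mm2: np.ndarray              # in-image ring area
    density: np.ndarray               # neurons per mm^2
    percent_of_background: np.ndarray


# ---------------------------------------------------------------------------
# Ring binning
# ---------------------------------------------------------------------------


def _pixel_distances(image: SyntheticImage) -> np.ndarray:
    ny, nx = image.pixels.shape
    cx, cy = image.implant_center
    xs = (np.arange(nx) - cx) * image.um_per_pixel
    ys = (np.arange(ny) - cy) * image.um_per_pixel
    return np.sqrt(xs[None, :] ** 2 + ys[:, None] ** 2)


def _edge_margin_um(image: SyntheticImage) -> float:
    """Distance from the implant center to the nearest image border."""
    ny, nx = image.pixels.shape
    cx, cy = image.implant_center
    return float(min(cx, nx - 1 - cx, cy, ny - 1 - cy) * image.um_per_pixel)


def bin_radial_intensity(image: SyntheticImage,
                         marker: str = "",
                         animal_id: str = "",
                         r_max: float = PROFILE_MAX_UM,
                         ring_width: float = RING_WIDTH_UM) -> RadialProfile:
    """Mean intensity in half-open concentric rings [r, r + ring_width).

    Each pixel is assigned to the ring containing its center's distance to
    the implant center; rings with no pixels are flagged NaN. The image
    must fully contain the background annulus.
    """
    margin = _edge_margin_um(image)
    if margin < BACKGROUND_RANGE_UM[1]:
        raise ValueError(
            "background annulus clipped by the image edge: need at least "
            f"{BACKGROUND_RANGE_UM[1]:.0f} um around the implant center, "
            f"have {margin:.0f} um")
    d = _pixel_distances(image)
    n_rings = int(round(r_max / ring_width))
    idx = np.floor(d / ring_width).astype(int)
    inside = idx < n_rings
    counts = np.bincount(idx[inside], minlength=n_rings)
    sums = np.bincount(idx[inside], weights=image.pixels[inside],
                       minlength=n_rings)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    edges = np.arange(n_rings + 1) * ring_width
    return RadialProfile(marker=marker or image.marker, animal_id=animal_id,
                         ring_edges=edges, mean_intensity=means,
                         n_pixels=counts)


def _band_integral(centers: np.ndarray, values: np.ndarray,
                   lo: float, hi: float) -> float:
    """Trapezoidal integral of the piecewise-linear profile over [lo, hi]."""
    xs = [lo] + [float(c) for c in centers if lo < c < hi] + [hi]
    ys = np.interp(xs, centers, values)
    return float(np.trapezoid(ys, xs))


def normalize_profile(profile: RadialProfile,
                      background_range: tuple[float, float] = BACKGROUND_RANGE_UM,
                      increment: float = AUC_INCREMENT_UM) -> RadialProfile:
    """Divide by the background-annulus mean and integrate 50-um increments.

    The background is the mean raw intensity over the rings spanning
    700-750 um. AUC increments are trapezoidal integrals of the
    normalized profile (interpolated at ring centers) over each 50-um
    band from 0 to 1 mm. Normalizing twice is the identity.
    """
    lo, hi = background_range
    centers = profile.ring_centers
    bg_sel = (centers >= lo) & (centers < hi)
    bg_vals = profile.mean_intensity[bg_sel]
    if np.any(np.isnan(bg_vals)):
        raise ValueError("background rings (700-750 um) contain empty rings")
    bg = float(bg_vals.mean())
    if bg <= 0:
        raise ValueError(f"background mean must be positive, got {bg:.3g}")
    normalized = profile.mean_intensity / bg
    valid = ~np.isnan(normalized)
    n_inc = int(round(profile.ring_edges[-1] / increment))
    auc = np.array([
        _band_integral(centers[valid], normalized[valid],
                       k * increment, (k + 1) * increment)
        for k in range(n_inc)])
    return replace(profile, mean_intensity=normalized.copy(),
                   normalized=normalized, auc_increments=auc)


# ---------------------------------------------------------------------------
# Neuron density
# ---------------------------------------------------------------------------


def neuron_density(points: np.ndarray,
                   implant_center: tuple[float, float],
                   image_shape: tuple[int, int],
                   um_per_pixel: float,
                   animal_id: str = "",
                   r_max: float = NEURON_MAX_UM,
                   ring_width: float = NEURON_RING_UM) -> NeuronDensityProfile:
    """Neuron counts per in-image ring area, as percent of background.

    ``points`` are (x, y) pixel coordinates of counted neurons. Ring
    areas are measured by counting in-image pixel centers (so rings
    clipped by the image edge are handled exactly as the counts are).
    The background is the 450-500 um ring, set to 100% by construction.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    cx, cy = implant_center
    n_rings = int(round(r_max / ring_width))
    edges = np.arange(n_rings + 1) * ring_width

    d_pts = np.sqrt(((points[:, 0] - cx) * um_per_pixel) ** 2
                    + ((points[:, 1] - cy) * um_per_pixel) ** 2)
    idx = np.floor(d_pts / ring_width).astype(int)
    count = np.bincount(idx[idx < n_rings], minlength=n_rings)

    ny, nx = image_shape
    xs = (np.arange(nx) - cx) * um_per_pixel
    ys = (np.arange(ny) - cy) * um_per_pixel
    d_px = np.sqrt(xs[None, :] ** 2 + ys[:, None] ** 2)
    pix_idx = np.floor(d_px / ring_width).astype(int)
    px_area_mm2 = (um_per_pixel / 1000.0) ** 2
    area = np.bincount(pix_idx[pix_idx < n_rings],
                       minlength=n_rings) * px_area_mm2

    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(area > 0, count / np.maximum(area, 1e-300), np.nan)
    bg_ring = int(NEURON_BG_RING_UM[0] // ring_width)
    if count[bg_ring] == 0:
        raise ValueError(
            "no neurons in the 450-500 um background ring; percent of "
            "background is undefined")
    percent = 100.0 * density / density[bg_ring]
    return NeuronDensityProfile(animal_id=animal_id, ring_edges=edges,
                                count=count, area_mm2=area, density=density,
                                percent_of_background=percent)


# ---------------------------------------------------------------------------
# Per-animal analysis values
# ---------------------------------------------------------------------------


def image_analysis_values(image: SyntheticImage, marker: str,
                          animal_id: str = "") -> dict[str, float]:
    """The two per-bin analysis values of one section image.

    Intensity markers: the 0-50 and 50-100 um AUC increments of the
    normalized profile. NeuN: percent-of-background of the first two
    50-um rings.
    """
    if marker == "NeuN":
        prof = neuron_density(image.neuron_points, image.implant_center,
                              image.pixels.shape, image.um_per_pixel,
                              animal_id=animal_id)
        return {"0-50": float(prof.percent_of_background[0]),
                "50-100": float(prof.percent_of_background[1])}
    prof = normalize_profile(bin_radial_intensity(
        image, marker=marker, animal_id=animal_id))
    return {"0-50": float(prof.auc_increments[0]),
            "50-100": float(prof.auc_increments[1])}


def quantify_study_histology(bundle: StudyBundle,
                             slices_per_animal: int = SLICES_PER_ANIMAL,
                             ) -> pd.DataFrame:
    """Image-pipeline histology table: one value per animal/marker/bin.

    Renders each section image, quantifies it, and averages the section
    values per animal (2 slides x 3 sections by default) — the value
    that enters the correlation network and regressions.
    """
    rows = []
    for a in bundle.config.animals:
        for marker in MARKERS:
            per_bin = {b: [] for b in DISTANCE_BINS}
            for s in range(slices_per_animal):
                img = bundle.histology_image(a, marker, s)
                vals = image_analysis_values(img, marker, animal_id=a)
                for b in DISTANCE_BINS:
                    per_bin[b].append(vals[b])
            for b in DISTANCE_BINS:
                rows.append((a, marker, b, float(np.mean(per_bin[b]))))
    return pd.DataFrame(rows, columns=["animal_id", "marker", "distance_bin",
                                       "value"])


def histology_to_variables(histology: pd.DataFrame) -> pd.DataFrame:
    """Tidy (animal_id, variable, value) table using registry names."""
    out = histology.copy()
    out["variable"] = [HISTOLOGY_VAR_OF[(m, b)] for m, b in
                       zip(out.marker, out.distance_bin)]
    return out[["animal_id", "variable", "value"]]
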