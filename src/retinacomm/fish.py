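"""RNAscope dot quantification on fluorescence intensity images.

Discrete hybridization puncta ("dots") are segmented as 8-connected
components of pixels at or above a detection threshold.  From a
representative region containing a countable number of dots, the
background-corrected average intensity of a single dot is

    avg_per_dot = (sum of integrated dot intensities
                   - background_mean * sum of dot areas) / n_dots

and the dot content of any other region follows from its bulk intensity:

    total_dots = (region total intensity
                  - background_mean * region area) / avg_per_dot.

Both quantities are linear in above-background signal, so a region of
pure background evaluates to zero dots.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from .synthetic import DotField


def read_image(path) -> np.ndarray:
    """Single-channel TIFF/PNG as a float array."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:  # collapse an accidental channel axis
        img = img.mean(axis=-1)
    return img


def default_threshold(background_mean: float, background_sd: float) -> float:
    """Conventional detection threshold: background mean + 3 SD."""
    return background_mean + 3.0 * background_sd


def estimate_background(image: np.ndarray, threshold: float) -> tuple[float, float]:
    """Mean and SD of sub-threshold pixels (the background estimate when
    none is supplied)."""
    below = np.asarray(image, dtype=float)[np.asarray(image) < threshold]
    if below.size == 0:
        return 0.0, 0.0
    return float(below.mean()), float(below.std())


def calibrate_threshold(image: np.ndarray, background_region: tuple[slice, slice]) -> DotField:
    """Build a DotField from a user-chosen pure-background region: its
    mean/SD set the background estimate and the mean+3SD threshold."""
    patch = np.asarray(image, dtype=float)[background_region]
    bg, sd = float(patch.mean()), float(patch.std())
    return DotField(
        intensity=np.asarray(image, dtype=float),
        background_mean=bg,
        detect_threshold=default_threshold(bg, sd),
    )


def detect_dots(field: DotField) -> list[tuple[int, float]]:
    """8-connected components of pixels >= threshold, as
    (area px^2, integrated intensity) tuples, in label order."""
    img = field.intensity
    mask = img >= field.detect_threshold
    labels = measure.label(mask, connectivity=2)
    out = []
    for region in measure.regionprops(labels, intensity_image=img):
        out.append((int(region.area), float(region.image_intensity.sum())))
    return out


def avg_intensity_per_dot(dots: list[tuple[int, float]], background_mean: float) -> float:
    """Background-corrected mean integrated intensity of a single dot."""
    if not dots:
        raise ValueError("need at least one detected dot")
    total_area = sum(a for a, _ in dots)
    total_intensity = sum(i for _, i in dots)
    return (total_intensity - background_mean * total_area) / len(dots)


def total_dot_number(
    region_total_intensity: float,
    background_mean: float,
    region_area: float,
    avg_per_dot: float,
) -> float:
    """Dot content of a region from its bulk background-corrected
    intensity divided by the single-dot average."""
    if avg_per_dot <= 0:
        raise ValueError("avg_per_dot must be positive")
    return (region_total_intensity - background_mean * region_area) / avg_per_dot


def quantify_field(field: DotField) -> dict:
    """End-to-end quantification of one field: detect dots, derive the
    single-dot average from them, then estimate the field's dot count from
    bulk intensity."""
    dots = detect_dots(field)
    if not dots:
        return {"n_dots_detected": 0, "avg_per_dot": float("nan"),
                "total_dot_estimate": 0.0}
    avg = avg_intensity_per_dot(dots, field.background_mean)
    total = total_dot_number(
        float(field.intensity.sum()),
        field.background_mean,
        float(field.intensity.size),
        avg,
    )
    return {
        "n_dots_detected": len(dots),
        "avg_per_dot": avg,
        "total_dot_estimate": total,
    }
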