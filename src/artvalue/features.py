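"""The low-level visual feature bank.

Per-segment statistics (size, HSV means, spatial moments, entropy, mirror
symmetry, mean R) and whole-image statistics (intensity-bin fractions, HSV
modes, aspect ratio, entropy, blur) that together form the candidate set for
the linear feature-summation value model.  All formulas operate on a
:class:`~artvalue.raster.RasterImage` plus, for the segment features, a
:class:`~artvalue.segmentation.Segmentation`.

Conventions pinned here:

* coordinates are 0-based, x = column, y = row;
* grayscale uses ITU-R BT.601 luma on the 0-255 scale;
* hue statistics are plain (non-circular) means on [0, 1) by default, with a
  circular variant behind a flag;
* the skew moment is the raw third central coordinate moment divided by the
  segment area (not standardised by variance^1.5);
* blur is computed from the unnormalised DFT power of the 0-255 luminance,
  thresholded at power > 4.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .raster import LUMA_601, RasterImage
from .segmentation import Segmentation

MISSING = float("nan")  # sentinel for features of an absent segment


# ---------------------------------------------------------------------------
# Blur


def compute_blur(
    image: RasterImage,
    power_threshold: float = 4.0,
    luma=LUMA_601,
) -> float:
    """Blur score: the highest retained spatial frequency, in [0, 1].

    A blurred image is modelled as a sharp image smoothed by a Gaussian of
    unknown width sigma; the extent of the power spectrum is then
    proportional to 1/sigma.  The score is
    max over frequency components with power > threshold of max(|k_x|, |k_y|)
    where k_x = 2(x - n_x/2)/n_x and k_y = 2(y - n_y/2)/n_y index the centred
    spectrum.  Power is the squared modulus of the unnormalised DFT of the
    0-255 luminance.  Returns 0.0 if no component passes the threshold.
    """
    gray = image.grayscale_255(luma)
    ny, nx = gray.shape
    power = np.abs(np.fft.fftshift(np.fft.fft2(gray))) ** 2
    kx = 2.0 * (np.arange(nx) - nx / 2.0) / nx
    ky = 2.0 * (np.arange(ny) - ny / 2.0) / ny
    kmax = np.maximum(np.abs(kx)[None, :], np.abs(ky)[:, None])
    mask = power > power_threshold
    if not mask.any():
        return 0.0
    return float(kmax[mask].max())


# ---------------------------------------------------------------------------
# Entropy


def intensity_entropy(gray255: np.ndarray, n_bins: int = 256) -> float:
    """Shannon entropy (bits) of the normalised intensity histogram."""
    counts, _ = np.histogram(gray255, bins=n_bins, range=(0.0, 255.0))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# Segment features


def _circular_mean(hue: np.ndarray) -> float:
    ang = hue * 2.0 * np.pi
    return float((np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * np.pi)) % 1.0)


def compute_segment_features(
    image: RasterImage,
    seg: Segmentation,
    segment_index: int,
    *,
    normalize_coords: bool = True,
    circular_hue: bool = False,
    entropy_bins: int = 256,
    luma=LUMA_601,
) -> dict[str, float]:
    """Statistics of one segment (0 = largest, 1 = second largest).

    Returns segment size (area fraction), HSV means, mean lightness and mean
    R, the centre of mass, the second and third central coordinate moments,
    intensity entropy, and horizontal/vertical mirror-symmetry MSEs computed
    on the image cropped to the segment's bounding box.

    With ``normalize_coords`` the centre of mass is expressed as a fraction
    of image width/height and the moment sums use those fractional
    coordinates, which makes the values comparable across image sizes.
    If the requested segment does not exist, every value is the NaN sentinel.
    """
    names = [
        "segment_size", "mean_hue", "mean_saturation", "mean_value",
        "mean_lightness", "mean_r", "com_x", "com_y", "variance", "skew",
        "entropy", "h_symmetry", "v_symmetry",
    ]
    if segment_index >= seg.n_segments:
        return {k: MISSING for k in names}
    mask = seg.segment_mask(segment_index)
    area = int(mask.sum())
    total = mask.size

    hsv = image.hsv()
    hue = hsv[:, :, 0][mask]
    mean_hue = _circular_mean(hue) if circular_hue else float(hue.mean())
    rgb = image.pixels
    mx = rgb.max(axis=2)[mask]
    mn = rgb.min(axis=2)[mask]

    ys, xs = np.nonzero(mask)
    xs = xs.astype(float)
    ys = ys.astype(float)
    if normalize_coords:
        xs = xs / image.width
        ys = ys / image.height
    xbar = xs.sum() / area
    ybar = ys.sum() / area
    dx = xs - xbar
    dy = ys - ybar
    variance = float(((dx**2) + (dy**2)).sum() / area)
    skew = float(((dx**3) + (dy**3)).sum() / area)

    gray = image.grayscale_255(luma)
    entropy = intensity_entropy(gray[mask], n_bins=entropy_bins)

    # Mirror symmetry on the bounding-box crop of the (luminance) image.
    sl = ndimage.find_objects(mask.astype(int))[0]
    crop = image.luminance(luma)[sl]
    h_sym = float(((crop - crop[:, ::-1]) ** 2).mean())
    v_sym = float(((crop - crop[::-1, :]) ** 2).mean())

    return {
        "segment_size": area / total,
        "mean_hue": mean_hue,
        "mean_saturation": float(hsv[:, :, 1][mask].mean()),
        "mean_value": float(hsv[:, :, 2][mask].mean()),
        "mean_lightness": float(((mx + mn) / 2.0).mean()),
        "mean_r": float(rgb[:, :, 0][mask].mean()),
        "com_x": float(xbar),
        "com_y": float(ybar),
        "variance": variance,
        "skew": skew,
        "entropy": entropy,
        "h_symmetry": h_sym,
        "v_symmetry": v_sym,
    }


# ---------------------------------------------------------------------------
# Global features


def intensity_bin_fractions(image: RasterImage, n_bins: int = 5, luma=LUMA_601) -> np.ndarray:
    """Area fraction of pixels in each of ``n_bins`` equal intensity bins.

    The 0-255 grayscale range is tiled by equally sized bins (255 itself
    falls in the last bin); the fractions sum to 1.
    """
    gray = image.grayscale_255(luma)
    counts, _ = np.histogram(gray, bins=n_bins, range=(0.0, 255.0))
    return counts / gray.size


def hsv_modes(image: RasterImage, n_bins: int = 64) -> tuple[float, float, float]:
    """Modes of hue, saturation and value over the whole image.

    Each channel is histogrammed into ``n_bins`` bins on [0, 1]; the mode is
    the centre of the fullest bin (ties resolved toward the lower bin).
    """
    hsv = image.hsv()
    out = []
    for c in range(3):
        counts, edges = np.histogram(hsv[:, :, c], bins=n_bins, range=(0.0, 1.0))
        i = int(np.argmax(counts))
        out.append(float((edges[i] + edges[i + 1]) / 2.0))
    return tuple(out)  # type: ignore[return-value]


def _colorfulness(rgb: np.ndarray) -> float:
    # Hasler & Suesstrunk opponent-channel statistic, on the [0,1] scale.
    rg = rgb[:, :, 0] - rgb[:, :, 1]
    yb = 0.5 * (rgb[:, :, 0] + rgb[:, :, 1]) - rgb[:, :, 2]
    return float(
        np.sqrt(rg.std() ** 2 + yb.std() ** 2)
        + 0.3 * np.sqrt(rg.mean() ** 2 + yb.mean() ** 2)
    )


def compute_global_features(
    image: RasterImage,
    *,
    n_intensity_bins: int = 5,
    mode_bins: int = 64,
    entropy_bins: int = 256,
    circular_hue: bool = False,
    luma=LUMA_601,
) -> dict[str, float]:
    """Whole-image features: colour statistics, intensity bins, modes,
    aspect ratio, entropy, blur, edge density and colorfulness."""
    hsv = image.hsv()
    gray = image.grayscale_255(luma)
    rgb = image.pixels
    mx = rgb.max(axis=2)
    mn = rgb.min(axis=2)

    hue = hsv[:, :, 0].ravel()
    mean_hue = _circular_mean(hue) if circular_hue else float(hue.mean())

    sob = ndimage.sobel(gray / 255.0, axis=0) ** 2 + ndimage.sobel(gray / 255.0, axis=1) ** 2
    edge_density = float(np.sqrt(sob).mean())

    out = {
        "global_mean_hue": mean_hue,
        "global_mean_saturation": float(hsv[:, :, 1].mean()),
        "global_mean_value": float(hsv[:, :, 2].mean()),
        "global_mean_lightness": float(((mx + mn) / 2.0).mean()),
        "global_intensity_mean": float(gray.mean()) / 255.0,
        "global_intensity_contrast": float(gray.std()) / 255.0,
        "global_blur": compute_blur(image, luma=luma),
        "global_edge_density": edge_density,
        "global_colorfulness": _colorfulness(rgb),
        "global_hue_std": float(hsv[:, :, 0].std()),
        "global_saturation_std": float(hsv[:, :, 1].std()),
        "global_value_std": float(hsv[:, :, 2].std()),
        "aspect_ratio": image.width / image.height,
        "global_entropy": intensity_entropy(gray, n_bins=entropy_bins),
    }
    fracs = intensity_bin_fractions(image, n_bins=n_intensity_bins, luma=luma)
    for i, f in enumerate(fracs, start=1):
        out[f"intensity_bin_{i}"] = float(f)
    mh, ms, mv = hsv_modes(image, n_bins=mode_bins)
    out["global_mode_hue"] = mh
    out["global_mode_saturation"] = ms
    out["global_mode_value"] = mv
    return out
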