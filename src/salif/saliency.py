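"""Bottom-up saliency front-end (classic center-surround recipe).

Produces the spatial input to the temporal LIF/WTA layer, decoupled
from it: maps are computed once per image and contain no noise.  The
pipeline is the classic one — a dyadic Gaussian pyramid; intensity,
red-green / blue-yellow opponency and four Gabor orientation channels;
rectified across-scale center-surround differences; peak-promoting
normalization; equally weighted conspicuity maps — with the final map
linearly rescaled so its maximum equals ``map_range`` (order 1e-9, the
scale the LIF layer expects).

Simplifications relative to the full published recipes are noted
inline: opponency maps are rectified per level before the
center-surround step, and orientation channels are Gabor energy on
de-meaned intensity levels (which keeps the whole pipeline exactly
invariant to adding a constant to all image channels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import gabor
from skimage.transform import pyramid_reduce, resize

from salif.synthetic import SaliencyMap

log = logging.getLogger(__name__)

__all__ = [
    "SaliencyConfig",
    "FeatureMapSet",
    "compute_saliency",
    "center_surround",
    "normalize_map",
    "build_pyramid",
    "write_map_csv",
    "read_map_csv",
]


@dataclass(frozen=True)
class SaliencyConfig:
    """Constants of the front-end (classic values)."""

    n_levels: int = 9                      # dyadic pyramid depth
    center_scales: tuple[int, ...] = (2, 3, 4)
    surround_deltas: tuple[int, ...] = (3, 4)
    map_level: int = 4                     # map scale = 1/16 of the input
    orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    gabor_frequency: float = 0.2           # cycles / pixel at each level
    normalization: str = "max"             # "max" | "iterative"


@dataclass
class FeatureMapSet:
    """Center-surround feature maps resampled to the map scale,
    indexed by (center, surround) scale pair."""

    intensity: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    color: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    orientation: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)


def build_pyramid(channel: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Dyadic Gaussian pyramid; stops early when a level gets < 2 px."""
    levels = [channel.astype(np.float64)]
    for _ in range(1, n_levels):
        if min(levels[-1].shape) < 4:
            break
        levels.append(pyramid_reduce(levels[-1], downscale=2))
    return levels


def center_surround(
    pyramid: list[np.ndarray],
    center_scales: tuple[int, ...],
    surround_deltas: tuple[int, ...],
    map_shape: tuple[int, int] | None = None,
) -> dict[tuple[int, int], np.ndarray]:
    """Rectified across-scale differences |center - upsampled surround|,
    resampled to ``map_shape`` (default: the coarsest center level)."""
    out: dict[tuple[int, int], np.ndarray] = {}
    if map_shape is None:
        map_shape = pyramid[min(max(center_scales), len(pyramid) - 1)].shape
    for c in center_scales:
        if c >= len(pyramid):
            raise IndexError(f"center scale {c} out of range for "
                             f"{len(pyramid)}-level pyramid")
        for d in surround_deltas:
            s = c + d
            if s >= len(pyramid):
                raise IndexError(f"surround scale {s} out of range for "
                                 f"{len(pyramid)}-level pyramid")
            surround = resize(pyramid[s], pyramid[c].shape, order=1,
                              anti_aliasing=False)
            diff = np.abs(pyramid[c] - surround)
            out[(c, s)] = resize(diff, map_shape, order=1,
                                 anti_aliasing=False)
    return out


def normalize_map(m: np.ndarray, method: str = "max") -> np.ndarray:
    """Rescale to [0, 1] and promote maps with one dominant peak.

    ``max``: weight by (M - mbar)^2 where M is the global maximum (1
    after rescaling) and mbar the mean of the other local maxima — a
    map with many equal peaks is suppressed relative to a single-peak
    map.  ``iterative``: a few difference-of-Gaussians competition
    steps achieving the same effect.
    """
    m = np.asarray(m, dtype=np.float64)
    peak = m.max()
    if peak <= 1e-12:  # numerically featureless (e.g. uniform input)
        return np.zeros_like(m)
    m = m / peak
    if method == "max":
        size = max(3, min(m.shape) // 8)
        # tolerant local-maximum detection: exact == comparisons would
        # make the weight a discontinuous function of ulp-level noise
        is_max = (m >= ndimage.maximum_filter(m, size=size) - 1e-9) & (m > 0.01)
        vals = np.sort(m[is_max])[::-1]
        # mean of local maxima other than (one instance of) the global
        mbar = float(vals[1:].mean()) if vals.size > 1 else 0.0
        return m * (1.0 - mbar) ** 2
    if method == "iterative":
        sig_ex = max(1.0, 0.02 * max(m.shape))
        sig_in = max(2.0, 0.25 * max(m.shape))
        for _ in range(3):
            exc = 0.5 * ndimage.gaussian_filter(m, sig_ex)
            inh = 1.5 * ndimage.gaussian_filter(m, sig_in)
            m = np.clip(m + exc - inh - 0.02, 0.0, None)
        return m / m.max() if m.max() > 0 else m
    raise ValueError(f"unknown normalization {method!r}")


def _validate_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    if min(img.shape[:2]) < 32:
        raise ValueError("image too small for the pyramid (need >= 32 px)")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def compute_feature_maps(image: np.ndarray,
                         config: SaliencyConfig = SaliencyConfig()
                         ) -> FeatureMapSet:
    """Center-surround feature maps for intensity, color and orientation."""
    img = _validate_image(image)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    intensity = img.mean(axis=2)

    int_pyr = build_pyramid(intensity, config.n_levels)
    n_avail = len(int_pyr)
    # clamp the scale recipe to the achievable pyramid depth: centers
    # need at least one coarser level to act as surround
    centers = tuple(c for c in config.center_scales if c < n_avail - 1)
    if not centers:
        centers = (max(n_avail - 2, 0),)
    max_c = max(centers)
    deltas = tuple(d for d in config.surround_deltas if max_c + d < n_avail)
    if not deltas:
        deltas = (n_avail - 1 - max_c,)
    map_level = min(config.map_level, max_c)
    map_shape = int_pyr[map_level].shape

    fs = FeatureMapSet()
    fs.intensity = center_surround(int_pyr, centers, deltas, map_shape)

    # color opponency, rectified per level before the across-scale step
    R = np.clip(r - (g + b) / 2.0, 0.0, None)
    G = np.clip(g - (r + b) / 2.0, 0.0, None)
    B = np.clip(b - (r + g) / 2.0, 0.0, None)
    Y = np.clip((r + g) / 2.0 - np.abs(r - g) / 2.0 - b, 0.0, None)
    rg_pyr = build_pyramid(np.abs(R - G), config.n_levels)
    by_pyr = build_pyramid(np.abs(B - Y), config.n_levels)
    cs_rg = center_surround(rg_pyr, centers, deltas, map_shape)
    cs_by = center_surround(by_pyr, centers, deltas, map_shape)
    fs.color = {k: cs_rg[k] + cs_by[k] for k in cs_rg}

    # orientation: Gabor energy on de-meaned intensity levels (the
    # de-meaning makes the channel exactly invariant to global offsets);
    # each orientation keeps its own maps so that the peak-promoting
    # normalization can single out an odd-one-out orientation
    fs.orientation = {}
    for theta_deg in config.orientations:
        theta = np.deg2rad(theta_deg)
        o_pyr = []
        for lev in int_pyr:
            zero_mean = lev - lev.mean()
            re, im = gabor(zero_mean, frequency=config.gabor_frequency,
                           theta=theta)
            o_pyr.append(np.hypot(re, im))
        cs = center_surround(o_pyr, centers, deltas, map_shape)
        for (c, s), v in cs.items():
            fs.orientation[(theta_deg, c, s)] = v
    return fs


def compute_saliency(image: np.ndarray, map_range: float = 1e-9,
                     config: SaliencyConfig = SaliencyConfig()) -> SaliencyMap:
    """Saliency map of an RGB image, rescaled so max == ``map_range``.

    Deterministic (no noise at this stage); a uniform image yields an
    all-zero map.
    """
    fs = compute_feature_maps(image, config)
    norm = lambda m: normalize_map(m, config.normalization)  # noqa: E731
    conspicuity = []
    for channel_maps in (fs.intensity, fs.color, fs.orientation):
        summed = sum(norm(m) for m in channel_maps.values())
        conspicuity.append(norm(summed))
    sal = sum(conspicuity) / 3.0
    peak = sal.max()
    if peak > 0:
        sal = sal / peak * map_range
    scale = int(round(image.shape[0] / sal.shape[0]))
    return SaliencyMap(sal, map_scale=max(1, scale), value_range=map_range)


def write_map_csv(smap: SaliencyMap, path) -> None:
    np.savetxt(path, smap.values, delimiter=",",
               header=f"map_scale={smap.map_scale},value_range={smap.value_range}")


def read_map_csv(path, map_scale: int = 16,
                 value_range: float = 1e-9) -> SaliencyMap:
    values = np.loadtxt(path, delimiter=",")
    return SaliencyMap(np.atleast_2d(values), map_scale, value_range)
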