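"""Synthetic human-like fixation data, saliency maps and pop-out images.

The eye-tracking data this analysis targets (18 participants searching
natural indoor scenes, first-fixation latencies pooled per image) is
emulated here.  First-fixation latencies follow the conventional
reaction-time family: an ex-Gaussian (normal(mu, sigma) + exponential
(tau)) main component, a per-image shift of mu capturing between-image
differences, and a small uniform long-tail component beyond the 1500 ms
outlier threshold.  Defaults are calibrated so the retained (sub-1500
ms) sample has mean 190.8 ms and SD 77.7 ms:

    mean = mu + tau                    = 120.8 + 70  = 190.8 ms
    SD   = sqrt(sigma^2 + tau^2 + shift_sd^2)
         = sqrt(30.204^2 + 70^2 + 15^2)              = 77.7 ms

tau sits at the high end of the typical RT range so that per-image
samples of ~17 latencies are positively skewed for nearly all images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "SaliencyMap",
    "FixationRecord",
    "FixationDataset",
    "LatencyGeneratorConfig",
    "dataset1_config",
    "dataset2_config",
    "generate_first_fixation_dataset",
    "generate_all_fixation_dataset",
    "generate_synthetic_saliency_map",
    "random_map_set",
    "PopOutSpec",
    "PopOutImage",
    "generate_synthetic_image",
    "write_fixation_csv",
    "read_fixation_csv",
]

FIXATION_COLUMNS = [
    "participant_id", "image_id", "trial_index", "fixation_index",
    "onset_ms", "offset_ms", "duration_ms", "x", "y",
]

#: duration below which a generated fixation is redrawn (physiological floor)
MIN_DURATION_MS = 20.0


@dataclass(frozen=True)
class SaliencyMap:
    """Nonnegative 2D conspicuity field at reduced (map) resolution.

    ``map_scale`` is the downsampling factor relative to the input
    image; ``value_range`` the nominal maximum after rescaling (maps
    the LIF layer expects are of order 1e-9).
    """

    values: np.ndarray
    map_scale: int = 16
    value_range: float = 1e-9

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("saliency map must be 2D")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("saliency map must be finite and nonnegative")
        object.__setattr__(self, "values", v)

    @property
    def argmax(self) -> tuple[int, int]:
        idx = int(np.argmax(self.values))
        return idx // self.values.shape[1], idx % self.values.shape[1]


@dataclass(frozen=True)
class FixationRecord:
    """One fixation within a trial (times in ms from trial start)."""

    participant_id: int
    image_id: int
    trial_index: int
    fixation_index: int
    onset: float
    offset: float
    duration: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError("offset must exceed onset")
        if abs(self.duration - (self.offset - self.onset)) > 1e-9:
            raise ValueError("duration must equal offset - onset")


@dataclass
class FixationDataset:
    """Fixation records plus the (uniform) presentation window per trial.

    The image appears ``image_onset`` ms after trial start and stays for
    8000 ms; all trials share the same window in the synthetic design.
    """

    records: pd.DataFrame
    image_onset: float = 1000.0
    image_offset: float = 9000.0
    config_label: str = ""

    def __post_init__(self) -> None:
        missing = set(FIXATION_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")

    @property
    def n_images(self) -> int:
        return int(self.records["image_id"].nunique())


@dataclass(frozen=True)
class LatencyGeneratorConfig:
    """Parameters of the synthetic latency generator (times in ms)."""

    mu: float = 120.8
    sigma: float = 30.204
    tau: float = 70.0
    outlier_weight: float = 0.01
    outlier_range: tuple[float, float] = (1500.0, 6000.0)
    per_image_shift_sd: float = 15.0
    n_images: int = 44
    first_fix_per_image: tuple[int, int] = (16, 19)
    all_fix_per_image: tuple[int, int] = (542, 794)
    total_first_fixations: int = 782
    total_all_fixations: int = 29528
    n_participants: int = 18
    seed: int = 0
    label: str = "dataset1"

    def __post_init__(self) -> None:
        if min(self.mu, self.sigma, self.tau) <= 0:
            raise ValueError("mu, sigma, tau must be > 0")
        if not 0 <= self.outlier_weight < 1:
            raise ValueError("outlier_weight must be in [0, 1)")
        if self.outlier_range[0] < 1500:
            raise ValueError("outlier_range must start at or above 1500 ms")
        if self.outlier_range[1] <= self.outlier_range[0]:
            raise ValueError("outlier_range must be increasing")
        lo, hi = self.first_fix_per_image
        if not lo * self.n_images <= self.total_first_fixations <= hi * self.n_images:
            raise ValueError(
                f"total_first_fixations={self.total_first_fixations} infeasible "
                f"for {self.n_images} images with per-image range [{lo}, {hi}]"
            )
        lo, hi = self.all_fix_per_image
        if not lo * self.n_images <= self.total_all_fixations <= hi * self.n_images:
            raise ValueError(
                f"total_all_fixations={self.total_all_fixations} infeasible "
                f"for {self.n_images} images with per-image range [{lo}, {hi}]"
            )


def dataset1_config(seed: int = 0) -> LatencyGeneratorConfig:
    """44 images, 782 first fixations (29,528 in all), ~1% outlier tail."""
    return LatencyGeneratorConfig(seed=seed)


def dataset2_config(seed: int = 0) -> LatencyGeneratorConfig:
    """91 images, 1593 first fixations (60,186 in all), ~3% outlier tail."""
    return LatencyGeneratorConfig(
        outlier_weight=0.03,
        n_images=91,
        total_first_fixations=1593,
        total_all_fixations=60186,
        seed=seed,
        label="dataset2",
    )


def _draw_counts(rng: np.random.Generator, n: int, lo: int, hi: int,
                 total: int) -> np.ndarray:
    """Per-image counts in [lo, hi] summing exactly to ``total``."""
    counts = rng.integers(lo, hi + 1, size=n)
    while counts.sum() != total:
        i = int(rng.integers(n))
        if counts.sum() < total and counts[i] < hi:
            counts[i] += 1
        elif counts.sum() > total and counts[i] > lo:
            counts[i] -= 1
    return counts


def _n_outliers(cfg: LatencyGeneratorConfig, retained: int) -> int:
    w = cfg.outlier_weight
    return int(round(w / (1.0 - w) * retained)) if w > 0 else 0


def _exgauss(rng: np.random.Generator, mu: float, sigma: float, tau: float,
             size: int) -> np.ndarray:
    """Ex-Gaussian draws, redrawing the rare values below the floor."""
    out = mu + sigma * rng.standard_normal(size) + rng.exponential(tau, size)
    bad = out < MIN_DURATION_MS
    while np.any(bad):
        k = int(bad.sum())
        out[bad] = mu + sigma * rng.standard_normal(k) + rng.exponential(tau, k)
        bad = out < MIN_DURATION_MS
    return out


def generate_first_fixation_dataset(cfg: LatencyGeneratorConfig) -> FixationDataset:
    """One first-fixation record per trial, pooled over images.

    Produces ``total_first_fixations`` retained records (latency below
    the 1500 ms outlier threshold, ex-Gaussian with a per-image mu
    shift) plus the outlier records implied by ``outlier_weight``, so
    the post-exclusion count matches the configured total exactly and
    the pre-exclusion tail fraction matches the configured weight.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.first_fix_per_image
    counts = _draw_counts(rng, cfg.n_images, lo, hi, cfg.total_first_fixations)
    shifts = rng.normal(0.0, cfg.per_image_shift_sd, size=cfg.n_images)

    n_out = _n_outliers(cfg, cfg.total_first_fixations)
    outlier_images = rng.choice(cfg.n_images, size=n_out,
                                replace=n_out > cfg.n_images)

    image_onset, image_offset = 1000.0, 9000.0
    rows: list[tuple] = []
    participant_trial = np.zeros(cfg.n_participants, dtype=int)
    pid_cycle = 0

    def add_record(image_id: int, duration: float, srt: float) -> None:
        nonlocal pid_cycle
        pid = pid_cycle % cfg.n_participants
        pid_cycle += 1
        participant_trial[pid] += 1
        onset = image_onset + srt
        rows.append((pid, image_id, int(participant_trial[pid]), 1,
                     onset, onset + duration, duration,
                     rng.uniform(0, 800), rng.uniform(0, 600)))

    for img in range(cfg.n_images):
        lat = _exgauss(rng, cfg.mu + shifts[img], cfg.sigma, cfg.tau,
                       int(counts[img]))
        # retained records must survive the outlier rule by construction
        over = lat > 1500.0
        while np.any(over):
            k = int(over.sum())
            lat[over] = _exgauss(rng, cfg.mu + shifts[img], cfg.sigma,
                                 cfg.tau, k)
            over = lat > 1500.0
        for d in lat:
            add_record(img, float(d), rng.uniform(150.0, 250.0))
    for img in outlier_images:
        dur = rng.uniform(*cfg.outlier_range)
        add_record(int(img), float(dur), rng.uniform(100.0, 200.0))

    records = pd.DataFrame(rows, columns=FIXATION_COLUMNS)
    log.info("generated %d first-fixation records (%d outliers) for %s",
             len(records), n_out, cfg.label)
    return FixationDataset(records, image_onset, image_offset, cfg.label)


def generate_all_fixation_dataset(cfg: LatencyGeneratorConfig) -> FixationDataset:
    """Full ordered fixation sequences within the 8000 ms window.

    Per image, the trial count follows ``first_fix_per_image`` and the
    fixation count ``all_fix_per_image`` (totals exact).  Durations come
    from the same latency mixture; sequences that would overrun the
    window are uniformly compressed to fit, so late-trial durations are
    slightly shrunk relative to the first-fixation calibration.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    trials = _draw_counts(rng, cfg.n_images, *cfg.first_fix_per_image,
                          cfg.total_first_fixations)
    fix_counts = _draw_counts(rng, cfg.n_images, *cfg.all_fix_per_image,
                              cfg.total_all_fixations)
    shifts = rng.normal(0.0, cfg.per_image_shift_sd, size=cfg.n_images)
    image_onset, image_offset = 1000.0, 9000.0
    window = image_offset - image_onset

    cols: dict[str, list[np.ndarray]] = {c: [] for c in FIXATION_COLUMNS}
    participant_trial = np.zeros(cfg.n_participants, dtype=int)
    pid_cycle = 0
    for img in range(cfg.n_images):
        t_i, n_i = int(trials[img]), int(fix_counts[img])
        base, extra = divmod(n_i, t_i)
        for j in range(t_i):
            k = base + (1 if j < extra else 0)
            pid = pid_cycle % cfg.n_participants
            pid_cycle += 1
            participant_trial[pid] += 1
            srt = rng.uniform(100.0, 300.0)
            gaps = rng.uniform(20.0, 50.0, size=k)
            dur = _exgauss(rng, cfg.mu + shifts[img], cfg.sigma, cfg.tau, k)
            if cfg.outlier_weight > 0:
                is_out = rng.uniform(size=k) < cfg.outlier_weight
                dur[is_out] = rng.uniform(*cfg.outlier_range,
                                          size=int(is_out.sum()))
            budget = window - srt - gaps.sum()
            if dur.sum() > budget:
                dur *= 0.999 * budget / dur.sum()
            onset = image_onset + srt + np.concatenate(
                ([0.0], np.cumsum(dur + gaps)[:-1]))
            cols["participant_id"].append(np.full(k, pid))
            cols["image_id"].append(np.full(k, img))
            cols["trial_index"].append(np.full(k, participant_trial[pid]))
            cols["fixation_index"].append(np.arange(1, k + 1))
            cols["onset_ms"].append(onset)
            cols["offset_ms"].append(onset + dur)
            cols["duration_ms"].append(dur)
            cols["x"].append(rng.uniform(0, 800, size=k))
            cols["y"].append(rng.uniform(0, 600, size=k))
    records = pd.DataFrame({c: np.concatenate(v) for c, v in cols.items()})
    for c in ("participant_id", "image_id", "trial_index", "fixation_index"):
        records[c] = records[c].astype(int)
    log.info("generated %d fixations over %d images for %s",
             len(records), cfg.n_images, cfg.label)
    return FixationDataset(records, image_onset, image_offset, cfg.label)


# ---------------------------------------------------------------------------
# synthetic saliency maps and pop-out images
# ---------------------------------------------------------------------------

def generate_synthetic_saliency_map(
    height: int,
    width: int,
    peaks: list[tuple[tuple[int, int], float]],
    seed: int | None = None,
    map_range: float = 1e-9,
    peak_sigma: float | None = None,
    background_ampl: float = 0.02,
    map_scale: int = 16,
) -> SaliencyMap:
    """Gaussian-bump saliency map with values of order ``map_range``.

    ``peaks`` is a list of ((row, col), relative_height); the global
    maximum lands on the highest requested peak (a weak smooth
    background of amplitude ``background_ampl`` relative to the top
    peak adds texture).  An empty peak list yields an all-zero map.
    """
    if height < 1 or width < 1:
        raise ValueError("map dimensions must be >= 1")
    field = np.zeros((height, width), dtype=np.float64)
    if not peaks:
        return SaliencyMap(field, map_scale, map_range)
    for (r, c), _h in peaks:
        if not (0 <= r < height and 0 <= c < width):
            raise ValueError(f"peak ({r}, {c}) outside {height}x{width} grid")
    rng = np.random.default_rng(seed)
    if background_ampl > 0:
        from scipy.ndimage import gaussian_filter

        bg = gaussian_filter(rng.standard_normal((height, width)),
                             sigma=max(1.0, min(height, width) / 6.0))
        bg -= bg.min()
        if bg.max() > 0:
            bg /= bg.max()
        field += background_ampl * max(h for _, h in peaks) * bg
    sigma = peak_sigma if peak_sigma is not None else max(2.0, min(height, width) / 8.0)
    rr, cc = np.mgrid[0:height, 0:width]
    for (r, c), h in peaks:
        field += h * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2.0 * sigma**2))
    return SaliencyMap(field * map_range, map_scale, map_range)


def random_map_set(
    n_maps: int,
    shape: tuple[int, int] = (24, 32),
    seed: int | None = None,
    map_range: float = 1e-9,
    rel_height_range: tuple[float, float] = (0.35, 1.0),
) -> list[SaliencyMap]:
    """Random single-to-few-peak maps standing in for per-image saliency.

    Top-peak heights vary over ``rel_height_range`` x ``map_range`` so
    the model's first-fixation latency varies across "images" — the
    image-driven variability the temporal analysis hinges on.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    sigma = max(2.0, min(h, w) / 8.0)
    maps = []
    for i in range(n_maps):
        n_peaks = int(rng.integers(1, 5))
        top = rng.uniform(*rel_height_range)
        margin = 2
        pts: list[tuple[int, int]] = []
        # rejection-sample separated peaks; small maps may not fit all
        # requested peaks at 3 sigma separation, so give up after a
        # bounded number of attempts and keep the ones placed
        attempts = 0
        while len(pts) < n_peaks and attempts < 200:
            attempts += 1
            r = int(rng.integers(margin, h - margin))
            c = int(rng.integers(margin, w - margin))
            if all((r - r0) ** 2 + (c - c0) ** 2 >= (3 * sigma) ** 2
                   for r0, c0 in pts):
                pts.append((r, c))
        n_peaks = len(pts)
        heights = [top] + list(rng.uniform(0.1, 0.6 * top, size=n_peaks - 1))
        maps.append(generate_synthetic_saliency_map(
            h, w, list(zip(pts, heights)), seed=int(rng.integers(2**31)),
            map_range=map_range, peak_sigma=sigma))
    return maps


@dataclass(frozen=True)
class PopOutSpec:
    """A grid of distractor items with one pop-out item."""

    size: tuple[int, int] = (512, 512)
    n_items: int = 16
    item_radius: int = 24
    feature: str = "color"  # color | intensity | orientation
    background: float = 0.5
    popout_index: int = 0

    def __post_init__(self) -> None:
        if self.feature not in ("color", "intensity", "orientation"):
            raise ValueError("feature must be color, intensity or orientation")
        side = int(np.ceil(np.sqrt(self.n_items)))
        if side * 4 * self.item_radius > min(self.size):
            raise ValueError("items do not fit in the image")


@dataclass(frozen=True)
class PopOutImage:
    pixels: np.ndarray                 # H x W x 3 in [0, 1]
    popout_center: tuple[int, int]     # (row, col)
    item_radius: int


def _draw_disc(img: np.ndarray, r: int, c: int, radius: int,
               color: np.ndarray) -> None:
    rr, cc = np.mgrid[max(r - radius, 0):min(r + radius + 1, img.shape[0]),
                      max(c - radius, 0):min(c + radius + 1, img.shape[1])]
    mask = (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
    img[rr[mask], cc[mask]] = color


def _draw_bar(img: np.ndarray, r: int, c: int, half_len: int, half_wid: int,
              theta: float, color: np.ndarray) -> None:
    ext = half_len + half_wid + 1
    rr, cc = np.mgrid[max(r - ext, 0):min(r + ext + 1, img.shape[0]),
                      max(c - ext, 0):min(c + ext + 1, img.shape[1])]
    u = (cc - c) * np.cos(theta) + (rr - r) * np.sin(theta)
    v = -(cc - c) * np.sin(theta) + (rr - r) * np.cos(theta)
    mask = (np.abs(u) <= half_len) & (np.abs(v) <= half_wid)
    img[rr[mask], cc[mask]] = color


def generate_synthetic_image(spec: PopOutSpec, seed: int | None = None) -> PopOutImage:
    """RGB display whose pop-out item differs in one feature channel.

    With zero items the image is uniform background.  Fixed seed gives
    identical pixels.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.size
    img = np.full((h, w, 3), spec.background, dtype=np.float64)
    if spec.n_items == 0:
        return PopOutImage(img, (-1, -1), spec.item_radius)
    side = int(np.ceil(np.sqrt(spec.n_items)))
    ys = np.linspace(h / (side + 1), h - h / (side + 1), side)
    xs = np.linspace(w / (side + 1), w - w / (side + 1), side)
    # centers snap to the 16-px map-scale grid so identical items share
    # their pyramid sampling phase (their feature responses then match
    # and the odd item is the only asymmetry)
    grid = 16
    centers = [(int(y) // grid * grid, int(x) // grid * grid)
               for y in ys for x in xs][: spec.n_items]
    centers = [(r + grid * int(rng.integers(-1, 2)),
                c + grid * int(rng.integers(-1, 2)))
               for r, c in centers]
    gray = np.array([0.55, 0.55, 0.55])
    for i, (r, c) in enumerate(centers):
        pop = i == spec.popout_index % spec.n_items
        if spec.feature == "color":
            color = np.array([0.9, 0.1, 0.1]) if pop else gray
            _draw_disc(img, r, c, spec.item_radius, color)
        elif spec.feature == "intensity":
            color = np.full(3, 0.95) if pop else np.full(3, 0.58)
            _draw_disc(img, r, c, spec.item_radius, color)
        else:  # orientation
            theta = np.pi / 2 if pop else 0.0
            _draw_bar(img, r, c, spec.item_radius,
                      max(2, spec.item_radius // 4), theta, gray)
        if pop:
            popout_center = (r, c)
    return PopOutImage(img, popout_center, spec.item_radius)


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

def write_fixation_csv(dataset: FixationDataset, path) -> None:
    dataset.records.to_csv(path, index=False)


def read_fixation_csv(path, image_onset: float = 1000.0,
                      image_offset: float = 9000.0,
                      config_label: str = "") -> FixationDataset:
    records = pd.read_csv(path)
    return FixationDataset(records, image_onset, image_offset, config_label)
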