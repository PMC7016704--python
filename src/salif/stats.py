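"""First-fixation extraction, outlier exclusion, and distribution tests.

The comparisons mirror the study's fitness machinery: a two-sample
Kolmogorov-Smirnov test between model and ground-truth latency samples,
and a one-sample z test of the model sample's mean against the
ground-truth mean with the ground-truth SD taken as the known sigma
(the natural reading of the z test used alongside KS in this design; a
pooled two-sample variant could be swapped in through the same
interface).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from salif.synthetic import FixationDataset

log = logging.getLogger(__name__)

__all__ = [
    "LatencySample",
    "ComparisonResult",
    "extract_first_fixations",
    "filter_outliers",
    "ks_two_sample",
    "z_test",
    "compare_distributions",
    "variance_decomposition",
]

OUTLIER_THRESHOLD_MS = 1500.0


@dataclass(frozen=True)
class LatencySample:
    """A sample of fixation latencies (ms) with a source tag."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise ValueError("latency sample must be 1D")
        if np.any(v <= 0):
            raise ValueError("latencies must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def mean(self) -> float:
        return float(np.mean(self.values))

    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))


@dataclass(frozen=True)
class ComparisonResult:
    """KS and z statistics for a model-vs-ground-truth comparison."""

    D: float
    p_ks: float
    z: float
    p_z: float
    mean_model: float
    sd_model: float
    mean_truth: float
    sd_truth: float
    n_model: int
    n_truth: int


def extract_first_fixations(dataset: FixationDataset) -> LatencySample:
    """Latency per trial: duration of the earliest fixation fully inside
    the presentation window.  Trials with no such fixation contribute
    nothing."""
    rec = dataset.records
    inside = rec[(rec["onset_ms"] >= dataset.image_onset)
                 & (rec["offset_ms"] <= dataset.image_offset)]
    first = (inside.sort_values("onset_ms")
             .groupby(["participant_id", "trial_index"], sort=False)
             .first())
    return LatencySample(first["duration_ms"].to_numpy(), label="human")


def filter_outliers(sample: LatencySample,
                    threshold_ms: float = OUTLIER_THRESHOLD_MS) -> LatencySample:
    """Drop latencies strictly longer than the threshold (1500 ms rule).

    Idempotent; a value exactly at the threshold is retained.
    """
    if threshold_ms <= 0:
        raise ValueError("threshold must be > 0")
    keep = sample.values <= threshold_ms
    removed = int((~keep).sum())
    if removed:
        log.info("filter_outliers: removed %d of %d latencies > %g ms",
                 removed, sample.n, threshold_ms)
    if not np.any(keep):
        log.warning("filter_outliers: all %d latencies removed", sample.n)
    return LatencySample(sample.values[keep], label=sample.label)


def ks_two_sample(a: LatencySample, b: LatencySample) -> tuple[float, float]:
    """Two-sample KS statistic D = sup |ECDF_a - ECDF_b| with the
    asymptotic p-value (effective n = n_a n_b / (n_a + n_b))."""
    if a.n == 0 or b.n == 0:
        raise ValueError("samples must be nonempty")
    with np.errstate(divide="ignore", invalid="ignore"):
        D = float(sps.ks_2samp(a.values, b.values, method="asymp").statistic)
    # asymptotic Kolmogorov p with effective n; evaluated directly so
    # degenerate tiny-sample inputs cannot produce NaN
    n_eff = a.n * b.n / (a.n + b.n)
    p = float(sps.kstwobign.sf(np.sqrt(n_eff) * D))
    return D, min(max(p, 0.0), 1.0)


def z_test(sample: LatencySample, mu0: float, sigma0: float) -> tuple[float, float]:
    """One-sample z: (mean - mu0) / (sigma0 / sqrt(n)), two-sided p."""
    if sample.n == 0:
        raise ValueError("sample must be nonempty")
    if sigma0 <= 0:
        raise ValueError("sigma0 must be > 0")
    z = (sample.mean() - mu0) / (sigma0 / np.sqrt(sample.n))
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def compare_distributions(model: LatencySample,
                          truth: LatencySample) -> ComparisonResult:
    """Bundle KS(model, truth) and z(model vs truth mean/SD) with
    summary statistics.  Censored runs must already be excluded."""
    if model.n == 0:
        raise ValueError("no non-censored model runs to compare "
                         "(non-firing parameter set)")
    if truth.n == 0:
        raise ValueError("ground-truth sample is empty")
    D, p_ks = ks_two_sample(model, truth)
    z, p_z = z_test(model, truth.mean(), truth.sd())
    return ComparisonResult(D=D, p_ks=p_ks, z=z, p_z=p_z,
                            mean_model=model.mean(), sd_model=model.sd(),
                            mean_truth=truth.mean(), sd_truth=truth.sd(),
                            n_model=model.n, n_truth=truth.n)


def variance_decomposition(latencies: pd.DataFrame) -> tuple[float, float]:
    """(pooled within-image SD, SD of per-image mean latency).

    Expects columns ``image_id`` and ``latency_ms``; censored rows
    (NaN latency) are dropped with a warning.  Within-image SD of zero
    is the signature of a deterministic per-image model response.
    """
    df = latencies[["image_id", "latency_ms"]].dropna()
    dropped = len(latencies) - len(df)
    if dropped:
        log.warning("variance_decomposition: dropped %d censored rows", dropped)
    groups = df.groupby("image_id")["latency_ms"]
    if groups.ngroups < 2:
        raise ValueError("need >= 2 images")
    n = groups.count()
    if (n < 2).all():
        raise ValueError("need >= 2 runs per image for a within-image SD")
    var = groups.var(ddof=1)
    w = (n - 1).where(n > 1, 0)
    pooled = float(np.sqrt((var.fillna(0.0) * w).sum() / w.sum()))
    between = float(groups.mean().std(ddof=1))
    return pooled, between
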