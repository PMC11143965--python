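"""Spheroid micrograph quantification.

Mirrors a standard ImageJ workflow: Gaussian blur, global threshold,
connected components, then per-structure metrics —

* disaggregation index (DI): area of detached fragments relative to the main
  spheroid body (DI = 0 for an intact spheroid);
* raw integrated density (RawIntDen): summed pixel intensity of a channel
  over the detected structures;
* live/dead ratio: live RawIntDen / dead RawIntDen;
* nuclei counting with optional distance-transform watershed splitting;

plus the figure-level statistics (one-tailed unpaired t, Holm-Bonferroni).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage import filters, measure, morphology, segmentation
from skimage.feature import peak_local_max
from statsmodels.stats.multitest import multipletests

from .containers import SpheroidImage
from .errors import SegmentationError, TestError, ValidationError

__all__ = [
    "SegmentationResult",
    "segment_structures",
    "disaggregation_index",
    "raw_integrated_density",
    "live_dead_ratio",
    "count_nuclei",
    "holm_bonferroni",
    "unpaired_one_tailed_t",
    "spheroid_metrics",
]


@dataclass
class SegmentationResult:
    labels: np.ndarray  # 0 background, 1..n structures
    main_label: int
    areas: dict[int, int]  # px per label
    connectivity: int
    pixel_size: float | None = None

    @property
    def n_structures(self) -> int:
        return len(self.areas)

    @property
    def main_area(self) -> int:
        return self.areas[self.main_label]

    @property
    def total_area(self) -> int:
        return int(sum(self.areas.values()))

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def areas_um2(self) -> dict[int, float] | None:
        if self.pixel_size is None:
            return None
        return {lab: a * self.pixel_size**2 for lab, a in self.areas.items()}


def segment_structures(
    channel: np.ndarray,
    sigma: float = 2.0,
    threshold="otsu",
    min_area: int = 20,
    connectivity: int = 2,
    pixel_size: float | None = None,
) -> SegmentationResult:
    """Gaussian blur + global threshold + connected components.

    ``threshold`` is Otsu by default; pass a number for a manual cutoff.
    Components smaller than ``min_area`` pixels are dropped; the largest
    surviving component is the main structure.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 2:
        raise ValidationError("expected a 2D channel")
    if channel.std() == 0:
        raise SegmentationError("blank channel: zero intensity variance")
    smoothed = filters.gaussian(channel, sigma=sigma, preserve_range=True)
    thr = filters.threshold_otsu(smoothed) if threshold == "otsu" else float(threshold)
    mask = smoothed > thr
    mask = morphology.remove_small_objects(mask, max_size=min_area - 1)
    labels = measure.label(mask, connectivity=connectivity)
    if labels.max() == 0:
        raise SegmentationError("no structure survives the area filter")
    areas = {int(r.label): int(r.area) for r in measure.regionprops(labels)}
    main = max(areas, key=lambda lab: (areas[lab], -lab))
    return SegmentationResult(labels, main, areas, connectivity, pixel_size)


def disaggregation_index(seg: SegmentationResult, denominator: str = "main") -> float:
    """Fragment area normalised by spheroid area.

    ``DI = (total structure area - main area) / main area`` by default;
    ``denominator="total"`` divides by the total structure area instead.
    """
    frag = seg.total_area - seg.main_area
    if denominator == "main":
        return frag / seg.main_area
    if denominator == "total":
        return frag / seg.total_area
    raise ValidationError(f"unknown denominator {denominator!r}")


def raw_integrated_density(
    channel: np.ndarray, seg: SegmentationResult, scope: str = "structures"
) -> float:
    """Sum of channel intensities over the segmented structures (or the
    whole frame with ``scope="whole"``)."""
    channel = np.asarray(channel, dtype=float)
    if channel.shape != seg.labels.shape:
        raise ValidationError("channel shape does not match segmentation mask")
    if scope == "whole":
        return float(channel.sum())
    if scope != "structures":
        raise ValidationError(f"unknown scope {scope!r}")
    return float(channel[seg.mask].sum())


def live_dead_ratio(image: SpheroidImage, seg: SegmentationResult, scope: str = "structures") -> float:
    """Live RawIntDen divided by dead RawIntDen over the structures."""
    for role in ("live", "dead"):
        if role not in image.channels:
            raise ValidationError(f"image lacks a {role!r} channel")
    dead = raw_integrated_density(image.channels["dead"], seg, scope)
    if dead <= 0:
        raise TestError("dead-channel integrated density is zero: ratio undefined")
    return raw_integrated_density(image.channels["live"], seg, scope) / dead


def count_nuclei(
    channel: np.ndarray,
    sigma: float = 1.0,
    threshold="otsu",
    min_area: int = 15,
    split: str = "watershed",
    min_distance: int = 5,
) -> int:
    """Count nuclei in a field; blank fields count 0 rather than erroring.

    With ``split="watershed"`` touching nuclei are separated by a distance-
    transform watershed seeded at local maxima at least ``min_distance``
    pixels apart.
    """
    channel = np.asarray(channel, dtype=float)
    try:
        seg = segment_structures(channel, sigma=sigma, threshold=threshold, min_area=min_area)
    except SegmentationError:
        return 0
    if split == "none":
        return seg.n_structures
    if split != "watershed":
        raise ValidationError(f"unknown split mode {split!r}")
    mask = seg.mask
    distance = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, labels=seg.labels, min_distance=min_distance, exclude_border=False
    )
    if peaks.shape[0] == 0:
        return seg.n_structures
    markers = np.zeros_like(seg.labels)
    markers[tuple(peaks.T)] = np.arange(1, peaks.shape[0] + 1)
    ws = segmentation.watershed(-distance, markers, mask=mask)
    count = 0
    for r in measure.regionprops(ws):
        if r.area >= min_area:
            count += 1
    return count


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjustment (monotone, capped at 1); NaNs propagate."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="holm")[1]
    return out


def unpaired_one_tailed_t(
    group_a,
    group_b,
    alternative: str = "greater",
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sample t test with a one-tailed p in the stated direction.

    ``alternative="greater"`` tests mean(a) > mean(b). Pooled variance by
    default; set ``equal_var=False`` for Welch.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise TestError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise TestError("both groups have zero variance: t undefined")
    if alternative not in ("greater", "less"):
        raise TestError(f"unknown alternative {alternative!r}")
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def spheroid_metrics(
    image: SpheroidImage,
    segment_on: str = "phase",
    sigma: float = 2.0,
    threshold="otsu",
    min_area: int = 20,
    di_denominator: str = "main",
) -> dict:
    """All per-image metrics in one pass: segmentation on one channel, DI,
    per-channel RawIntDen over structures, live/dead ratio when possible."""
    image.validate()
    if segment_on not in image.channels:
        raise ValidationError(f"image lacks the {segment_on!r} channel")
    seg = segment_structures(
        image.channels[segment_on], sigma=sigma, threshold=threshold,
        min_area=min_area, pixel_size=image.pixel_size,
    )
    metrics = {
        "n_structures": seg.n_structures,
        "main_area_px": seg.main_area,
        "total_area_px": seg.total_area,
        "disaggregation_index": disaggregation_index(seg, di_denominator),
    }
    for role, ch in image.channels.items():
        metrics[f"rawintden_{role}"] = raw_integrated_density(ch, seg)
    if "live" in image.channels and "dead" in image.channels:
        try:
            metrics["live_dead_ratio"] = live_dead_ratio(image, seg)
        except TestError:
            metrics["live_dead_ratio"] = np.nan
    return metrics
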