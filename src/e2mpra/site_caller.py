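"""Functional-site calling from 6-bp window-perturbation profiles.

The per-position perturbation effect is the median pooled activity of
all window variants covering that position.  Effects are converted to
MAD scores against a reference activity (the WT activity for the
transcriptional assay; for the noisier fragment-count assays the median
of the CRE's single-nucleotide substitution activities is the
recommended reference, since WT fragment counts are anomalously deep):

    mad   = median_i |effect_i - reference|
    score = (effect - reference) / mad

Sites are then called with a one-dimensional adaptation of Canny edge
detection: Gaussian smoothing, central-difference derivative,
non-maximum suppression on |derivative|, hysteresis thresholding at the
median absolute derivative, and peak candidates taken as extrema of the
smoothed score exceeding 0.75 in magnitude.  Each peak is extended to
the nearest strong edge on each side; overlapping regions merge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .library_design import DesignElement

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateProfileError",
    "FunctionalSite",
    "PerturbationProfile",
    "positional_effect",
    "mad_score",
    "snv_median_reference",
    "canny_1d",
    "call_functional_sites",
    "profile_to_frame",
    "sites_to_frame",
]


class DegenerateProfileError(ValueError):
    """All positional effects equal the reference; MAD is zero."""


@dataclass(frozen=True)
class FunctionalSite:
    """A called functional region, 1-based inclusive coordinates."""

    start: int
    end: int
    direction: int
    cre_id: str = ""
    assay: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid site [{self.start},{self.end}]")


@dataclass
class PerturbationProfile:
    """Positional-effect profile of one CRE in one assay."""

    cre_id: str
    assay: str
    effect: np.ndarray
    reference: float
    mad: float = np.nan
    score: np.ndarray | None = None
    smoothed: np.ndarray | None = None
    derivative: np.ndarray | None = None
    coverage: np.ndarray | None = None
    sites: list[FunctionalSite] = field(default_factory=list)


# --------------------------------------------------------------------------
# positional effect and MAD score
# --------------------------------------------------------------------------

def positional_effect(activities: pd.DataFrame,
                      designs: list[DesignElement],
                      length: int | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Median pooled activity over all window variants covering each
    position.

    ``activities`` must carry pooled rows (replicate == 'pooled') for
    window elements.  Positions covered by no surviving variant are
    linearly interpolated (and logged).  Returns (effect, coverage).
    """
    windows = {d.element_id: d.window for d in designs
               if d.category == "window"}
    if not windows:
        raise ValueError("no window elements in designs")
    L = length or len(designs[0].sequence)
    act = activities[(activities["replicate"] == "pooled")
                     & (activities["element_id"].isin(windows))]
    by_pos: list[list[float]] = [[] for _ in range(L)]
    for r in act.itertuples(index=False):
        start, width, _ = windows[r.element_id]
        if not np.isnan(r.log2_activity):
            for i in range(start - 1, min(L, start - 1 + width)):
                by_pos[i].append(r.log2_activity)
    effect = np.array([np.median(v) if v else np.nan for v in by_pos])
    coverage = np.array([len(v) for v in by_pos])
    miss = np.isnan(effect)
    if miss.all():
        raise ValueError("no position has a surviving window variant")
    if miss.any():
        logger.info("positional_effect: interpolating %d uncovered positions",
                    int(miss.sum()))
        idx = np.arange(L)
        effect[miss] = np.interp(idx[miss], idx[~miss], effect[~miss])
    return effect, coverage


def snv_median_reference(snv_activities: pd.DataFrame) -> float:
    """Reference activity as the median over the CRE's single-nucleotide
    substitution pooled activities (used when the WT measurement itself
    is unreliable in fragment-count assays)."""
    pooled = snv_activities[snv_activities["replicate"] == "pooled"]
    vals = pooled["log2_activity"].dropna()
    if vals.empty:
        raise ValueError("no pooled substitution activities available")
    return float(vals.median())


def mad_score(effect: np.ndarray, reference: float
              ) -> tuple[np.ndarray, float]:
    """Deviation of each positional effect from the reference in units of
    the profile's median absolute deviation.  The reference (WT baseline)
    maps to score 0."""
    dev = np.asarray(effect, dtype=float) - reference
    mad = float(np.median(np.abs(dev)))
    if mad == 0:
        raise DegenerateProfileError(
            "degenerate profile: every position equals the reference")
    return dev / mad, mad


# --------------------------------------------------------------------------
# 1-D Canny edge detection
# --------------------------------------------------------------------------

def _local_extrema(v: np.ndarray, kind: str) -> np.ndarray:
    """Indices that are local maxima ('max') or minima ('min') of v,
    end positions compared against their single neighbour."""
    n = len(v)
    left = np.empty(n)
    right = np.empty(n)
    left[0], left[1:] = -np.inf if kind == "max" else np.inf, v[:-1]
    right[-1], right[:-1] = -np.inf if kind == "max" else np.inf, v[1:]
    if kind == "max":
        return np.flatnonzero((v >= left) & (v >= right))
    return np.flatnonzero((v <= left) & (v <= right))


def canny_1d(score: np.ndarray, sigma: float = 1.5,
             peak_threshold: float = 0.75, truncate: float = 4.0
             ) -> tuple[list[FunctionalSite], dict]:
    """Call functional-site regions on a MAD-score vector.

    Returns the merged sites (1-based inclusive) and a diagnostics dict
    with the smoothed scores, derivative, edge sets and peak candidates.
    """
    score = np.asarray(score, dtype=float)
    if len(score) < 7:
        raise ValueError("score vector too short for edge detection")
    if np.isnan(score).any():
        raise ValueError("score vector contains missing values")
    smoothed = gaussian_filter1d(score, sigma=sigma, mode="reflect",
                                 truncate=truncate)
    derivative = np.gradient(smoothed)
    absd = np.abs(derivative)

    nms = _local_extrema(absd, "max")
    med = float(np.median(absd))
    weak = set(np.flatnonzero(absd > med))
    strong = set(i for i in nms if absd[i] > med)
    # hysteresis: grow strong edges through adjacent weak positions
    frontier = list(strong)
    while frontier:
        i = frontier.pop()
        for j in (i - 1, i + 1):
            if j in weak and j not in strong:
                strong.add(j)
                frontier.append(j)
    strong_sorted = np.array(sorted(strong), dtype=int)

    peaks = [i for i in np.concatenate([_local_extrema(smoothed, "max"),
                                        _local_extrema(smoothed, "min")])
             if abs(smoothed[i]) > peak_threshold]
    peaks = sorted(set(int(i) for i in peaks))

    raw_sites = []
    for p in peaks:
        if strong_sorted.size:
            lo_candidates = strong_sorted[strong_sorted <= p]
            hi_candidates = strong_sorted[strong_sorted >= p]
            lo = int(lo_candidates[-1]) if lo_candidates.size else p
            hi = int(hi_candidates[0]) if hi_candidates.size else p
        else:
            lo = hi = p
        raw_sites.append((lo, hi, int(np.sign(smoothed[p])), abs(smoothed[p])))

    # merge overlapping regions; direction follows the strongest peak
    merged: list[list] = []  # [lo, hi, direction, mag], 0-based
    for lo, hi, direction, mag in sorted(raw_sites):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
            if mag > merged[-1][3]:
                merged[-1][2], merged[-1][3] = direction, mag
        else:
            merged.append([lo, hi, direction, mag])
    sites = [FunctionalSite(lo + 1, hi + 1, direction)
             for lo, hi, direction, _ in merged]
    diagnostics = {"smoothed": smoothed, "derivative": derivative,
                   "nms": nms, "strong_edges": strong_sorted,
                   "weak_edges": np.array(sorted(weak), dtype=int),
                   "peaks": np.array(peaks, dtype=int),
                   "median_abs_derivative": med}
    return sites, diagnostics


def call_functional_sites(profile: PerturbationProfile,
                          sigma: float = 1.5,
                          peak_threshold: float = 0.75
                          ) -> PerturbationProfile:
    """Run MAD scoring (if needed) and edge detection on a profile,
    filling in score, smoothed, derivative and sites."""
    if profile.score is None:
        profile.score, profile.mad = mad_score(profile.effect,
                                               profile.reference)
    sites, diag = canny_1d(profile.score, sigma=sigma,
                           peak_threshold=peak_threshold)
    profile.smoothed = diag["smoothed"]
    profile.derivative = diag["derivative"]
    profile.sites = [FunctionalSite(s.start, s.end, s.direction,
                                    profile.cre_id, profile.assay)
                     for s in sites]
    return profile


# --------------------------------------------------------------------------
# IO
# --------------------------------------------------------------------------

def profile_to_frame(profile: PerturbationProfile) -> pd.DataFrame:
    L = len(profile.effect)
    return pd.DataFrame({
        "cre_id": profile.cre_id, "assay": profile.assay,
        "position": np.arange(1, L + 1),
        "effect": profile.effect,
        "score": profile.score if profile.score is not None else np.nan,
        "smoothed": (profile.smoothed if profile.smoothed is not None
                     else np.nan),
        "derivative": (profile.derivative if profile.derivative is not None
                       else np.nan),
    })


def sites_to_frame(sites: list[FunctionalSite]) -> pd.DataFrame:
    """BED-like table; start/end are 1-based inclusive."""
    return pd.DataFrame([{"cre_id": s.cre_id, "assay": s.assay,
                          "start": s.start, "end": s.end,
                          "direction": s.direction} for s in sites])
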