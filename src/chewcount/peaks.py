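"""Peak detection and chew counting with speed-adaptive thresholds.

Every strict local maximum of the smoothed chewing signal is a candidate
chew.  Candidates are thresholded by a minimum peak height (MPH) set as a
fixed fraction of the mean candidate peak height (PH):

    MPH = d * mean(PH),   d = 1/2  (LPF, all speeds; DWD slow)
                          d = 1/3  (DWD normal)
                          d = 1/4  (DWD fast)

The divisor loosens for faster chewing because mandible displacement — and
hence peak height relative to noise — shrinks with speed.  Outsized
excursions caused by taking a bite are labelled separately and discounted
from the chew count.  Peak heights are measured above a running-minimum
baseline by default, making the count invariant to the arbitrary ED
baseline (face size / camera distance) and to slow drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import minimum_filter1d
from scipy.signal import peak_prominences

from .errors import NoPeaksError
from .signal import ChewSignal

__all__ = ["PeakSet", "ChewResult", "BitePolicy", "MPH_DIVISORS",
           "find_local_maxima", "compute_mph", "exclude_bites", "count_chews"]

Method = Literal["LPF", "DWD"]
Speed = Literal["slow", "normal", "fast"]

#: MPH divisor d per (method, speed): threshold = d * mean candidate height.
MPH_DIVISORS: dict[tuple[str, str], float] = {
    ("LPF", "slow"): 1 / 2, ("LPF", "normal"): 1 / 2, ("LPF", "fast"): 1 / 2,
    ("DWD", "slow"): 1 / 2, ("DWD", "normal"): 1 / 3, ("DWD", "fast"): 1 / 4,
}


@dataclass
class PeakSet:
    """Candidate local maxima with heights, labels, and the applied threshold."""

    indices: np.ndarray                  # strictly increasing sample positions
    heights: np.ndarray                  # PH: peak heights (baseline-adjusted when enabled)
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]  # 'chew' | 'bite' | 'rejected'
    mph: float | None = None
    prominences: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.labels is None:
            self.labels = np.full(len(self.indices), "candidate", dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)

    def __len__(self) -> int:
        return len(self.indices)

    def where(self, label: str) -> np.ndarray:
        return np.nonzero(self.labels == label)[0]


@dataclass(frozen=True)
class BitePolicy:
    """A peak is a bite when its prominence exceeds ``bite_factor`` times the
    median prominence of the retained (non-bite) peaks."""

    bite_factor: float = 2.5
    enabled: bool = True


@dataclass
class ChewResult:
    """Final count with provenance."""

    count: int
    method: str
    speed: str
    n_candidate_peaks: int = 0
    n_bites_excluded: int = 0
    mph: float = 0.0
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "count": int(self.count),
            "method": self.method,
            "speed": self.speed,
            "n_candidate_peaks": int(self.n_candidate_peaks),
            "n_bites_excluded": int(self.n_bites_excluded),
            "mph": float(self.mph),
            "parameters": self.parameters,
        }


def find_local_maxima(values: np.ndarray) -> PeakSet:
    """Strict local maxima: values[i] > both immediate neighbours.

    Endpoints are never peaks, and flat-topped plateaus yield none — a
    consequence of the strict two-neighbour rule.  Series shorter than 3
    samples return an empty set with a warning.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        warnings.warn("series too short for peak detection; returning no peaks", stacklevel=2)
        return PeakSet(indices=np.empty(0, int), heights=np.empty(0))
    core = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    idx = np.nonzero(core)[0] + 1
    return PeakSet(indices=idx, heights=v[idx])


def running_min_baseline(values: np.ndarray, rate_hz: float, window_s: float = 10.0) -> np.ndarray:
    """Running minimum over a centred window; the floor heights are measured from."""
    size = max(3, int(round(window_s * rate_hz)) | 1)
    return minimum_filter1d(np.asarray(values, float), size=size, mode="nearest")


def compute_mph(peak_heights: np.ndarray, method: str, speed: str) -> float:
    """Adaptive minimum peak height: divisor times the mean candidate height."""
    h = np.asarray(peak_heights, dtype=float)
    if h.size == 0:
        raise NoPeaksError("cannot derive MPH from an empty peak set")
    try:
        d = MPH_DIVISORS[(method.upper(), speed)]
    except KeyError:
        raise NoPeaksError(f"no MPH rule for method={method!r} speed={speed!r}") from None
    return d * float(h.mean())


def exclude_bites(peaks: PeakSet, values: np.ndarray, policy: BitePolicy | None = None) -> PeakSet:
    """Label outsized-prominence peaks as bites.

    Bite excursions are several-fold larger than chew cycles; a peak whose
    prominence exceeds ``bite_factor`` x the median prominence of the
    retained peaks is labelled ``bite``.  The median is recomputed after each
    removal round (fixpoint), so a couple of huge bites cannot mask each
    other.  Labels on the returned set: ``bite`` or ``candidate``.
    """
    policy = policy or BitePolicy()
    out = PeakSet(indices=peaks.indices.copy(), heights=peaks.heights.copy(),
                  labels=np.full(len(peaks), "candidate", dtype=object))
    if len(out) == 0 or not policy.enabled:
        return out
    prom = peak_prominences(np.asarray(values, float), out.indices)[0]
    out.prominences = prom
    retained = np.ones(len(out), dtype=bool)
    for _ in range(len(out)):
        med = np.median(prom[retained])
        newly = retained & (prom > policy.bite_factor * med)
        if not newly.any():
            break
        retained &= ~newly
        if not retained.any():
            break
    out.labels[~retained] = "bite"
    return out


def count_chews(
    sig: ChewSignal | np.ndarray,
    method: str,
    speed: str,
    rate_hz: float | None = None,
    bite_policy: BitePolicy | None = None,
    baseline_window_s: float | None = 10.0,
    include_bites_in_mph: bool = False,
) -> tuple[ChewResult, PeakSet]:
    """Count chews in a smoothed signal.

    Two-stage thresholding: all strict local maxima are found first, the MPH
    is computed from their (baseline-adjusted) heights, and the threshold is
    then applied.  Bites are labelled before the MPH average by default so a
    few huge excursions do not inflate the threshold.  Deterministic.

    Set ``baseline_window_s=None`` to threshold raw signal values instead of
    heights above the running minimum.
    """
    if isinstance(sig, ChewSignal):
        values, fs = sig.values, sig.fps
    else:
        values = np.asarray(sig, dtype=float)
        fs = rate_hz if rate_hz is not None else 1.0
    method = method.upper()

    peaks = find_local_maxima(values)
    params = {
        "baseline_window_s": baseline_window_s,
        "bite_factor": (bite_policy or BitePolicy()).bite_factor,
        "include_bites_in_mph": include_bites_in_mph,
        "rate_hz": fs,
    }
    if len(peaks) == 0:
        warnings.warn("no candidate peaks; chew count is 0", stacklevel=2)
        return ChewResult(0, method, speed, parameters=params), peaks

    if baseline_window_s is not None:
        baseline = running_min_baseline(values, fs, baseline_window_s)
        peaks.heights = values[peaks.indices] - baseline[peaks.indices]

    peaks = PeakSet(peaks.indices, peaks.heights)
    labeled = exclude_bites(peaks, values, bite_policy)
    is_bite = labeled.labels == "bite"

    mph_heights = labeled.heights if include_bites_in_mph else labeled.heights[~is_bite]
    if mph_heights.size == 0:
        warnings.warn("all candidate peaks labelled bites; chew count is 0", stacklevel=2)
        return ChewResult(0, method, speed, n_candidate_peaks=len(labeled),
                          n_bites_excluded=int(is_bite.sum()), parameters=params), labeled
    mph = compute_mph(mph_heights, method, speed)

    labels = labeled.labels.copy()
    accept = (~is_bite) & (labeled.heights >= mph)
    labels[accept] = "chew"
    labels[(~is_bite) & ~accept] = "rejected"
    final = PeakSet(labeled.indices, labeled.heights, labels=labels, mph=mph,
                    prominences=labeled.prominences)
    result = ChewResult(
        count=int(accept.sum()),
        method=method,
        speed=speed,
        n_candidate_peaks=len(final),
        n_bites_excluded=int(is_bite.sum()),
        mph=float(mph),
        parameters=params,
    )
    return result, final
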