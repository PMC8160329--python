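"""Event-triggered neurovascular coupling analysis.

The single-vessel pipeline: normalise a neuronal calcium trace over the
whole recording (min--max), pick putative peaks above 10% of the maximum,
re-express each peak relative to its own 5 s pre-event baseline (ΔF/F),
keep peaks more than 2 baseline SDs above the baseline mean, then ask
whether the simultaneously imaged vessel dilated (a contiguous >0.5 s run
above baseline mean + 1 SD within 5 s of the event).  The coupling index
is the dilation peak divided by the triggering calcium peak.  A shuffled
null (full random permutation of the diameter samples, repeated) gives the
chance rate of "responses".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .traces import DiameterTrace, FluorescenceTrace

__all__ = [
    "CalciumEvent",
    "ResponseRecord",
    "normalize_global",
    "normalize_baseline",
    "detect_calcium_events",
    "classify_response",
    "shuffled_null",
    "nvc_index",
    "roi_pairwise_correlation",
    "holm_bonferroni",
]


@dataclass
class CalciumEvent:
    """A detected calcium transient.

    ``peak_dff`` is the peak in baseline-relative ΔF/F units; ``window``
    holds the ΔF/F-normalised samples over ``[-pre_s, +post_s]`` around the
    peak; ``baseline_sd`` the SD of the normalised baseline.
    """

    peak_time: float  # s
    peak_dff: float
    window: np.ndarray
    frame_rate: float
    pre_s: float = 5.0
    post_s: float = 10.0
    baseline_mean: float = 0.0
    baseline_sd: float = 0.0


@dataclass
class ResponseRecord:
    """Vessel response classification for one calcium event."""

    responsive: bool
    dilation_peak: float  # fractional change from baseline diameter
    latency: float  # s from event to response onset (NaN if none)
    nvc_index: float = float("nan")
    valid: bool = True


def normalize_global(t: FluorescenceTrace) -> FluorescenceTrace:
    """Min--max normalise a trace over the entire recording to [0, 1]."""
    v = t.values
    vmin, vmax = v.min(), v.max()
    if vmax - vmin <= 0:
        raise ValueError("cannot normalise a constant trace")
    return FluorescenceTrace(values=(v - vmin) / (vmax - vmin),
                             frame_rate=t.frame_rate, roi_id=t.roi_id,
                             normalization="global")


def normalize_baseline(window: np.ndarray, baseline: np.ndarray,
                       tol: float = 1e-12) -> np.ndarray:
    """Express ``window`` as ΔF/F relative to the mean of ``baseline``.

    ΔF/F = (F − F0)/|F0| with F0 the baseline mean; the absolute value
    keeps the sign of changes meaningful when F0 is negative (possible in
    background-subtracted traces).  Raises when |F0| is below machine
    tolerance.
    """
    f0 = float(np.mean(baseline))
    if abs(f0) < tol:
        raise ValueError("baseline mean too close to zero for ΔF/F")
    return (np.asarray(window, dtype=float) - f0) / abs(f0)


def detect_calcium_events(t: FluorescenceTrace, putative_height: float = 0.10,
                          prominence: float = 0.05, min_separation_s: float = 1.0,
                          pre_s: float = 5.0, post_s: float = 10.0,
                          sd_mult: float = 2.0) -> list[CalciumEvent]:
    """Detect calcium transients in a raw fluorescence trace.

    Putative events are local maxima of the globally normalised trace
    exceeding ``putative_height`` (fraction of the recording's maximum),
    with a minimum prominence and separation.  Each is re-expressed as
    ΔF/F against its own ``pre_s``-second baseline and kept only if the
    peak exceeds the baseline mean by ``sd_mult`` baseline SDs.  Peaks too
    close to the recording edges for a full window are dropped.
    """
    if t.duration < pre_s + post_s:
        raise ValueError("recording shorter than one event window")
    rate = t.frame_rate
    g = normalize_global(t).values
    distance = max(1, int(round(min_separation_s * rate)))
    peaks, _ = find_peaks(g, height=putative_height, prominence=prominence,
                          distance=distance)
    n_pre = int(round(pre_s * rate))
    n_post = int(round(post_s * rate))
    events = []
    for p in peaks:
        if p - n_pre < 0 or p + n_post >= t.values.size:
            continue  # windows are clipped, not padded: drop edge events
        raw = t.values[p - n_pre:p + n_post + 1]
        baseline_raw = t.values[p - n_pre:p]
        try:
            dff = normalize_baseline(raw, baseline_raw)
        except ValueError:
            continue
        base_dff = dff[:n_pre]
        mu, sd = float(base_dff.mean()), float(base_dff.std())
        peak_dff = float(dff[n_pre])
        if peak_dff <= mu + sd_mult * sd:
            continue
        events.append(CalciumEvent(peak_time=p / rate, peak_dff=peak_dff,
                                   window=dff, frame_rate=rate, pre_s=pre_s,
                                   post_s=post_s, baseline_mean=mu,
                                   baseline_sd=sd))
    return events


def classify_response(diam_window: np.ndarray, rate: float,
                      pre_s: float = 5.0, response_s: float = 5.0,
                      min_duration_s: float = 0.5, sd_mult: float = 1.0,
                      calcium_peak: float | None = None,
                      max_missing_frac: float = 0.2) -> ResponseRecord:
    """Classify a diameter window around one calcium event as responsive or not.

    ``diam_window`` must span ``[-pre_s, ...]`` seconds around the event at
    sampling ``rate``.  The pre-event seconds give the baseline mean and
    SD; the trace is responsive iff a contiguous run longer than
    ``min_duration_s`` within ``(0, response_s]`` exceeds baseline mean +
    ``sd_mult``·SD.  The dilation peak is the maximum of the response
    window as a fraction of the baseline diameter; with ``calcium_peak``
    given, the record carries the per-event coupling index.
    """
    d = np.asarray(diam_window, dtype=float)
    missing = ~np.isfinite(d)
    if missing.mean() > max_missing_frac:
        return ResponseRecord(responsive=False, dilation_peak=float("nan"),
                              latency=float("nan"), valid=False)
    n_pre = int(round(pre_s * rate))
    n_resp = int(round(response_s * rate))
    base = d[:n_pre]
    base = base[np.isfinite(base)]
    if base.size < 2:
        return ResponseRecord(responsive=False, dilation_peak=float("nan"),
                              latency=float("nan"), valid=False)
    mu, sd = base.mean(), base.std()
    resp = d[n_pre + 1:n_pre + 1 + n_resp]
    above = np.isfinite(resp) & (resp > mu + sd_mult * sd)
    # smallest sample count whose duration strictly exceeds min_duration_s
    min_run = int(np.floor(min_duration_s * rate)) + 1
    responsive = False
    latency = float("nan")
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= min_run:
            responsive = True
            latency = (i - run + 2) / rate
            break
    finite_resp = resp[np.isfinite(resp)]
    peak = float(np.max(normalize_baseline(finite_resp, base))) if finite_resp.size else float("nan")
    rec = ResponseRecord(responsive=responsive, dilation_peak=peak, latency=latency)
    if calcium_peak is not None:
        try:
            rec.nvc_index = nvc_index(peak, calcium_peak)
        except ValueError:
            rec.valid = False
    return rec


def shuffled_null(diam: DiameterTrace, event_times, n_iter: int = 100,
                  seed: int = 0, mode: str = "permute", **classify_kw) -> float:
    """Chance rate of "responsive" classifications under temporal shuffling.

    Each iteration destroys the alignment between diameter and calcium —
    ``mode="permute"`` draws a full random permutation of the diameter
    samples, ``mode="roll"`` a random circular shift — and every event is
    re-classified on the shuffled trace.  Returns the fraction of event ×
    iteration pairs classified responsive.
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("need at least one event")
    rng = np.random.default_rng(seed)
    rate = diam.rate
    pre_s = classify_kw.get("pre_s", 5.0)
    post_s = classify_kw.pop("post_s", 10.0)
    n_pre = int(round(pre_s * rate))
    n_post = int(round(post_s * rate))
    idx = np.round(event_times * rate).astype(int)
    idx = idx[(idx - n_pre >= 0) & (idx + n_post < diam.values.size)]
    if idx.size == 0:
        raise ValueError("no event window fits inside the recording")
    hits = 0
    total = 0
    for _ in range(n_iter):
        if mode == "permute":
            shuf = rng.permutation(diam.values)
        elif mode == "roll":
            shuf = np.roll(diam.values, rng.integers(1, diam.values.size))
        else:
            raise ValueError(f"unknown shuffle mode {mode!r}")
        for i in idx:
            rec = classify_response(shuf[i - n_pre:i + n_post + 1], rate, **classify_kw)
            if rec.valid:
                hits += rec.responsive
                total += 1
    if total == 0:
        raise ValueError("no valid shuffled classifications")
    return hits / total


def nvc_index(dilation_peak: float, calcium_peak: float) -> float:
    """Single-vessel coupling index: dilation peak / calcium peak.

    Both inputs are baseline-relative fractional peaks, making the index
    scale-free.  A non-positive calcium peak leaves the index undefined.
    """
    if not calcium_peak > 0:
        raise ValueError("calcium peak must be positive")
    return dilation_peak / calcium_peak


def roi_pairwise_correlation(traces) -> tuple[np.ndarray, float]:
    """Pearson correlation matrix across ROI traces and its mean off-diagonal.

    ``traces`` is (n_rois, n_samples) or a DataFrame with one column per
    ROI.  Constant traces yield NaN rows/columns and are excluded from the
    summary mean.
    """
    arr = np.asarray(traces, dtype=float)
    if hasattr(traces, "columns"):
        arr = arr.T  # DataFrame: columns are ROIs
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two ROI traces of equal length")
    sd = arr.std(axis=1)
    r = np.full((arr.shape[0], arr.shape[0]), np.nan)
    ok = sd > 0
    if ok.sum() >= 1:
        sub = np.corrcoef(arr[ok])
        r[np.ix_(ok, ok)] = sub
    np.fill_diagonal(r, np.where(ok, 1.0, np.nan))
    off = r[~np.eye(r.shape[0], dtype=bool)]
    mean_off = float(np.nanmean(off)) if np.isfinite(off).any() else float("nan")
    return r, mean_off


def holm_bonferroni(pvals) -> np.ndarray:
    """Holm's step-down adjusted p values.

    Ascending p values are multiplied by (m, m−1, …, 1); running maxima
    enforce monotonicity and results are capped at 1, which encodes the
    stop-at-first-nonsignificant semantics as adjusted values.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
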