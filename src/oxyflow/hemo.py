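"""Oxy-CBF probe analysis: derived channels, rest segmentation, CMRO2 events.

A combined laser-doppler flowmetry / haemoglobin spectroscopy probe samples
blood flow (flux), speed, oxygenated (HbO) and deoxygenated (Hbr)
haemoglobin at 40 Hz, in arbitrary units.  Derived channels are total
haemoglobin Hbt = HbO + Hbr, saturation SO2 = HbO/Hbt (as %), and the
oxygen consumption estimate

    CMRO2(t) = CBF(t) · Hbr(t) / Hbt(t)

Metabolic events are CMRO2 peaks more than two baseline SDs above their
preceding baseline (the same peak machinery as the calcium pipeline);
each event's regional coupling index relates the blood-volume (Hbt)
excursion to the CMRO2 excursion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nvc
from .traces import FluorescenceTrace

__all__ = [
    "HemoTrace",
    "MetabolicEvent",
    "derive_channels",
    "segment_rest",
    "baseline_summary",
    "detect_metabolic_events",
    "regional_nvc_index",
]

RATE = 40.0  # Hz


@dataclass
class HemoTrace:
    """One oxy-CBF probe session at 40 Hz.

    ``flux`` is the laser-doppler CBF signal; derived channels are None
    until :func:`derive_channels` fills them.  ``stimulus`` is a boolean
    screen-on mask, ``locomotion`` treadmill speed in cm/s.
    """

    t: np.ndarray
    flux: np.ndarray
    speed: np.ndarray
    hbo: np.ndarray
    hbr: np.ndarray
    locomotion: np.ndarray
    stimulus: np.ndarray
    hbt: np.ndarray | None = None
    so2: np.ndarray | None = None
    cmro2: np.ndarray | None = None

    def __post_init__(self) -> None:
        arrays = [self.t, self.flux, self.speed, self.hbo, self.hbr,
                  self.locomotion, self.stimulus]
        n = {np.asarray(a).size for a in arrays}
        if len(n) != 1:
            raise ValueError("all channels must have equal length")
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(dt, 1.0 / RATE, rtol=1e-3):
                raise ValueError("probe traces must be sampled at 40 Hz")
        if np.any(np.asarray(self.hbo) < 0) or np.any(np.asarray(self.hbr) < 0):
            raise ValueError("HbO and Hbr must be non-negative")
        self.stimulus = np.asarray(self.stimulus, dtype=bool)

    @property
    def rate(self) -> float:
        return RATE

    @property
    def duration(self) -> float:
        return self.t.size / RATE


@dataclass
class MetabolicEvent:
    """A CMRO2 peak with its aligned blood-volume excursion."""

    peak_time: float
    cmro2_peak: float  # baseline-normalised
    hbt_peak: float  # baseline-normalised excursion within the response window
    nvc_index: float = float("nan")


def derive_channels(h: HemoTrace) -> HemoTrace:
    """Fill Hbt, SO2 [%] and CMRO2 samplewise; CMRO2 is NaN where Hbt = 0."""
    hbo = np.asarray(h.hbo, dtype=float)
    hbr = np.asarray(h.hbr, dtype=float)
    flux = np.asarray(h.flux, dtype=float)
    hbt = hbo + hbr
    with np.errstate(divide="ignore", invalid="ignore"):
        so2 = np.where(hbt > 0, 100.0 * hbo / hbt, np.nan)
        cmro2 = np.where(hbt > 0, flux * hbr / hbt, np.nan)
    h.hbt = hbt
    h.so2 = so2
    h.cmro2 = cmro2
    return h


def segment_rest(h: HemoTrace, speed_thresh: float = 0.25,
                 pad_s: float = 1.0) -> np.ndarray:
    """Boolean mask of resting samples: immobile and in the dark.

    True where |locomotion| < ``speed_thresh`` cm/s and the stimulus is
    off, with ``pad_s`` seconds of exclusion added around every locomotion
    bout (movement-evoked haemodynamics outlast the movement).
    """
    moving = np.abs(np.asarray(h.locomotion, dtype=float)) >= speed_thresh
    pad = int(round(pad_s * RATE))
    if pad > 0 and moving.any():
        kernel = np.ones(2 * pad + 1, dtype=bool)
        moving = np.convolve(moving, kernel, mode="same") > 0
    return ~moving & ~h.stimulus


def baseline_summary(sessions, masks, channels=("flux", "speed", "hbt", "so2",
                                                "cmro2", "hbo", "hbr")):
    """Resting-state channel means per session, aggregated to one row ("animal").

    ``sessions`` is a list of derived :class:`HemoTrace`; ``masks`` the
    matching rest masks.  Each mask must cover at least 10 s.  Returns a
    pandas DataFrame of per-session means plus an ``"animal"`` row holding
    the across-session mean of each channel.
    """
    import pandas as pd

    if len(sessions) != len(masks) or not sessions:
        raise ValueError("need one mask per session")
    rows = {}
    for i, (h, mask) in enumerate(zip(sessions, masks)):
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() < 10 * RATE:
            raise ValueError(f"session {i}: rest mask covers <10 s")
        row = {}
        for ch in channels:
            vals = getattr(h, ch)
            if vals is None:
                raise ValueError(f"channel {ch!r} not derived; run derive_channels")
            row[ch] = float(np.nanmean(np.asarray(vals)[mask]))
        rows[f"session{i}"] = row
    df = pd.DataFrame(rows).T
    df.loc["animal"] = df.mean(axis=0)
    return df


def detect_metabolic_events(h: HemoTrace, response_s: float = 5.0,
                            **detect_kw) -> list[MetabolicEvent]:
    """CMRO2 peaks >2 SD above their preceding baseline, with Hbt excursions.

    Runs the calcium-event detector on the CMRO2 channel (one shared code
    path), then extracts the baseline-normalised Hbt window at the same
    times; the per-event regional coupling index is the Hbt excursion peak
    within ``response_s`` seconds divided by the CMRO2 peak.
    """
    if h.cmro2 is None or h.hbt is None:
        raise ValueError("derive_channels must run first")
    trace = FluorescenceTrace(values=np.nan_to_num(h.cmro2, nan=0.0),
                              frame_rate=RATE, roi_id="cmro2")
    cal_events = nvc.detect_calcium_events(trace, **detect_kw)
    events = []
    for ev in cal_events:
        p = int(round(ev.peak_time * RATE))
        n_pre = int(round(ev.pre_s * RATE))
        n_resp = int(round(response_s * RATE))
        hbt_base = h.hbt[p - n_pre:p]
        hbt_resp = h.hbt[p:p + n_resp + 1]
        try:
            hbt_dff = nvc.normalize_baseline(hbt_resp, hbt_base)
        except ValueError:
            continue
        hbt_peak = float(np.max(hbt_dff))
        me = MetabolicEvent(peak_time=ev.peak_time, cmro2_peak=ev.peak_dff,
                            hbt_peak=hbt_peak)
        try:
            me.nvc_index = regional_nvc_index(me)
        except ValueError:
            pass
        events.append(me)
    return events


def regional_nvc_index(event: MetabolicEvent,
                       direction: str = "hbt_over_cmro2") -> float:
    """Regional coupling index for one metabolic event.

    Default is blood-volume excursion per unit metabolic excursion
    (Hbt/CMRO2), the regional analogue of dilation-per-calcium;
    ``direction="cmro2_over_hbt"`` gives the reciprocal convention.
    """
    if not event.cmro2_peak > 0:
        raise ValueError("CMRO2 peak must be positive")
    if direction == "hbt_over_cmro2":
        return event.hbt_peak / event.cmro2_peak
    if direction == "cmro2_over_hbt":
        if event.hbt_peak == 0:
            raise ValueError("Hbt excursion is zero")
        return event.cmro2_peak / event.hbt_peak
    raise ValueError(f"unknown direction {direction!r}")
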