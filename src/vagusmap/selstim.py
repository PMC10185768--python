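"""Selective-stimulation readouts and angular localization.

Cycling a stimulation pulse train through the 14 longitudinal electrode
pairs elicits organ-specific physiological responses: a heart-rate drop
(cardiac), a breathing-rate change measured on EtCO2 (pulmonary), or a
laryngeal-EMG RMS increase (recurrent laryngeal).  For each organ, the pair
with the maximal response and all pairs reaching at least 50% of it are
selected; their circular-mean angle, at a fixed radius of 2/3 of the nerve
radius (selective stimulation steers angle but resolves no depth), is the
organ's selective-stimulation center of mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .geometry import N_ELECTRODES
from .phantom import PhysioSignals
from .reconstruct import CoMRecord
from .sigproc import detect_triggers


class ResponseError(RuntimeError):
    pass


@dataclass
class PairSelection:
    best_pair: int
    selected: list[int]
    selectivity_ok: bool
    n_significant: int


Window = tuple[float, float]


def _events_in(times: np.ndarray, windows: list[Window]) -> np.ndarray:
    m = np.zeros(times.size, dtype=bool)
    for a, b in windows:
        m |= (times >= a) & (times < b)
    return m


def _rate_from_events(times: np.ndarray, windows: list[Window]) -> float:
    """Events/min from mean inter-event interval within the windows."""
    sel = times[_events_in(times, windows)]
    if sel.size < 2:
        return np.nan
    iv = np.diff(sel)
    iv = iv[iv < 3.0 * np.median(iv)]    # drop across-window gaps
    if iv.size == 0:
        return np.nan
    return 60.0 / iv.mean()


def hr_drop(physio: PhysioSignals, stim_windows: list[Window],
            rest_windows: list[Window], pair: int = -1) -> dict:
    """Percent heart-rate change during stimulation vs baseline.

    Heart rate is measured from blood-pressure beat intervals (systolic
    peaks).  Returns a StimResponseTable row dict; an unmeasurable rate in
    either window marks the row missing (NaN response).
    """
    beats = detect_triggers(physio, "bp_peak").times
    hr_base = _rate_from_events(beats, rest_windows)
    hr_stim = _rate_from_events(beats, stim_windows)
    resp = 100.0 * (hr_stim - hr_base) / hr_base if hr_base else np.nan
    return dict(pair=pair, metric="hr_drop_pct", baseline=hr_base,
                value=hr_stim, response=resp,
                missing=bool(np.isnan(resp)))


def breath_change(physio: PhysioSignals, stim_windows: list[Window],
                  rest_windows: list[Window], pair: int = -1) -> dict:
    """Percent breathing-rate change, from EtCO2 cycle counting.

    Apnea during stimulation (no complete cycles) is reported as -100%.
    """
    mids = detect_triggers(physio, "etco2_midpoint").times
    base = _rate_from_events(mids, rest_windows)
    stim = _rate_from_events(mids, stim_windows)
    if np.isnan(base):
        return dict(pair=pair, metric="breath_change_pct", baseline=np.nan,
                    value=np.nan, response=np.nan, missing=True)
    if np.isnan(stim):
        n_in = int(_events_in(mids, stim_windows).sum())
        if n_in == 0:
            stim, resp = 0.0, -100.0
        else:
            return dict(pair=pair, metric="breath_change_pct", baseline=base,
                        value=np.nan, response=np.nan, missing=True)
    else:
        resp = 100.0 * (stim - base) / base
    return dict(pair=pair, metric="breath_change_pct", baseline=base,
                value=stim, response=resp, missing=False)


def emg_rms_ratio(physio: PhysioSignals, stim_windows: list[Window],
                  rest_windows: list[Window], pair: int = -1,
                  band: tuple[float, float] = (5.0, 2000.0),
                  rms_window: float = 1.0) -> dict:
    """Ratio of stimulation-window EMG RMS to baseline RMS.

    The EMG is band-pass filtered (5-2000 Hz; the upper edge is truncated
    with a warning if the sampling rate is too low) and converted to a
    moving RMS with a 1 s window before window averaging.
    """
    fs = physio.sampling_rate
    lo, hi = band
    if fs < 2.5 * hi:
        import warnings
        hi = fs / 2.5
        warnings.warn(f"EMG band truncated to {hi:.0f} Hz for fs={fs:.0f} Hz")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, np.asarray(physio.emg, dtype=float))
    from scipy.ndimage import uniform_filter1d
    ms = uniform_filter1d(filt * filt, int(round(rms_window * fs)),
                          mode="nearest")
    rms = np.sqrt(np.maximum(ms, 0.0))
    t = np.arange(rms.size) / fs

    def mean_in(windows: list[Window]) -> float:
        # contract each window by half the RMS window so boundary smearing
        # between train and rest does not bias either average
        h = 0.5 * rms_window
        shrunk = [(a + h, b - h) for a, b in windows if b - a > 2.5 * h]
        m = _events_in(t, shrunk or windows)
        return float(rms[m].mean()) if m.any() else np.nan

    base = mean_in(rest_windows)
    stim = mean_in(stim_windows)
    floor = 1e-9 * max(float(np.abs(physio.emg).max()), 1e-30)
    if np.isnan(base) or base <= floor:
        raise ResponseError("zero baseline EMG RMS (band removes DC); "
                            "cannot form a ratio")
    ratio = stim / base
    return dict(pair=pair, metric="emg_rms_ratio", baseline=1.0, value=ratio,
                response=ratio - 1.0, missing=bool(np.isnan(ratio)))


def select_pairs(table: pd.DataFrame, significance_factor: float = 3.0
                 ) -> PairSelection:
    """Apply the maximal-response / 50% rule to one organ's response table.

    A pair responds significantly when |response| exceeds
    ``significance_factor`` times the baseline fluctuation scale
    (``baseline_sd`` column).  Spatial selectivity requires fewer than half
    the pairs (7 of 14) to respond significantly.
    """
    if table.pair.nunique() != N_ELECTRODES:
        raise ValueError(f"expected {N_ELECTRODES} pairs, got {table.pair.nunique()}")
    resp = table.set_index("pair").response
    mag = resp.abs()
    if not (mag > 0).any():
        raise ResponseError("all responses are zero; nothing to select")
    best = int(mag.idxmax())
    selected = sorted(int(p) for p in mag.index[mag >= 0.5 * mag[best]])
    if "baseline_sd" in table.columns:
        sd = table.set_index("pair").baseline_sd
        n_sig = int((mag > significance_factor * sd).sum())
    else:
        n_sig = len(selected)
    return PairSelection(best_pair=best, selected=selected,
                         selectivity_ok=n_sig < N_ELECTRODES // 2,
                         n_significant=n_sig)


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Circular mean of angles in degrees; raises if the resultant vanishes
    (e.g. an antipodal two-pair selection has no defined mean)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    v = np.array([np.cos(a).mean(), np.sin(a).mean()])
    if np.hypot(*v) < 1e-9:
        raise ResponseError(
            "circular mean undefined (antipodal selection); review the pair "
            "selection or stimulation amplitude")
    return float(np.degrees(np.arctan2(v[1], v[0])) % 360.0)


def ss_com(selection: PairSelection, electrode_angles: np.ndarray,
           nerve_radius_um: float, organ: str = "", animal: str = ""
           ) -> CoMRecord:
    """Selective-stimulation CoM: circular mean angle of the selected pairs
    at a fixed radius of two thirds of the nerve radius."""
    if not selection.selected:
        raise ResponseError("empty pair selection")
    ang = circular_mean_deg(np.asarray(electrode_angles)[selection.selected])
    return CoMRecord.from_polar(radius_um=2.0 * nerve_radius_um / 3.0,
                                angle_deg=ang, organ=organ, technique="ss",
                                animal=animal)
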