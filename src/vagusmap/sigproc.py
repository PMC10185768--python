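"""Carrier demodulation, coherent averaging, quality control and SNR.

The raw EIT measurement is a 6 kHz carrier whose amplitude is modulated by
fascicular impedance changes.  The processing chain is: zero-phase 5th-order
Butterworth band-pass around the carrier (+-1 kHz evoked laryngeal,
+-2 kHz spontaneous), Hilbert-transform envelope demodulation (dV), and
coherent averaging on a trigger series (stimulus times, blood-pressure
peaks, or EtCO2 breath midpoints).  Spontaneous traces are additionally
high-pass filtered at 250 Hz and converted to a moving-window RMS signal
(dV-RMS) at the original 20 us step.

Quality control applies the per-trace exclusion criteria (amplitude,
derivative, ensemble 3-SD deviation, and the same test on the residual
after keeping only the first principal component of the 196-trace
ensemble), and reports the retained fraction.

Voltages in DemodTrace / RMSTrace are expressed in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


class ProcessingError(RuntimeError):
    pass


@dataclass
class DemodTrace:
    """Demodulated voltage trace (dV) for one (injection pair, electrode)."""

    values: np.ndarray        # microvolts
    dt: float                 # seconds per sample
    pair: int = -1
    electrode: int = -1
    kept: bool = True
    exclusion_reasons: list[str] = field(default_factory=list)


@dataclass
class RMSTrace:
    """Moving-window RMS of the high-passed dV signal (dV-RMS)."""

    values: np.ndarray        # microvolts, nonnegative before baseline subtraction
    dt: float
    window: float             # RMS moving-average window, s
    highpass_fc: float = 250.0
    baseline_value: float = 0.0
    pair: int = -1
    electrode: int = -1


@dataclass
class TriggerSeries:
    times: np.ndarray         # seconds, strictly increasing
    source: str               # stimulus | bp_peak | etco2_midpoint

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("trigger times must be strictly increasing")


@dataclass
class SNRReport:
    snr: float
    peak_value: float         # microvolts
    baseline_noise: float     # microvolts (SD of the baseline window)


def bandpass_carrier(trace: np.ndarray, fs: float, center: float = 6000.0,
                     halfwidth: float = 1000.0, order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth band-pass around the carrier frequency."""
    lo, hi = center - halfwidth, center + halfwidth
    if not 0 < lo < hi or fs <= 2 * hi:
        raise ValueError(
            f"invalid band [{lo}, {hi}] Hz for sampling rate {fs} Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=float))


def demodulate(filtered: np.ndarray, fs: float, pair: int = -1,
               electrode: int = -1) -> DemodTrace:
    """Analytic-signal envelope via the Hilbert transform.

    Input in volts; the returned DemodTrace is in microvolts.
    """
    x = np.asarray(filtered, dtype=float)
    env = np.abs(signal.hilbert(x))
    return DemodTrace(values=env * 1e6, dt=1.0 / fs, pair=pair, electrode=electrode)


def detect_triggers(physio, source: str) -> TriggerSeries:
    """Extract trigger events from the auxiliary physiological channels.

    - ``bp_peak``: systolic local maxima of arterial blood pressure, one per
      heartbeat.
    - ``etco2_midpoint``: midpoint between the rising and falling half-level
      crossing of the EtCO2 waveform for each breathing cycle.
    - ``stimulus``: passthrough of the recorded stimulus event times.
    """
    if source == "stimulus":
        if physio.stim_times is None or len(physio.stim_times) == 0:
            raise ProcessingError("no stimulus times recorded")
        return TriggerSeries(times=np.asarray(physio.stim_times), source=source)
    fs = physio.sampling_rate
    if source == "bp_peak":
        x = np.asarray(physio.bp, dtype=float)
        ptp = np.ptp(x)
        if ptp <= 1e-9 * max(1.0, np.abs(x).max()):
            raise ProcessingError("blood pressure channel is flat; no beats")
        peaks, _ = signal.find_peaks(x, prominence=0.3 * ptp)
        if peaks.size < 1:
            raise ProcessingError("no blood-pressure peaks detected")
        return TriggerSeries(times=peaks / fs, source=source)
    if source == "etco2_midpoint":
        x = np.asarray(physio.etco2, dtype=float)
        ptp = np.ptp(x)
        if ptp <= 1e-9 * max(1.0, np.abs(x).max()):
            raise ProcessingError("EtCO2 channel is flat; no breaths")
        level = 0.5 * (x.max() + x.min())
        above = x > level
        cross = np.flatnonzero(np.diff(above.astype(np.int8)))
        rising = cross[~above[cross]]
        falling = cross[above[cross]]
        mids = []
        for r in rising:
            nxt = falling[falling > r]
            if nxt.size:
                mids.append(0.5 * (r + nxt[0]) / fs)
        if not mids:
            raise ProcessingError("no complete EtCO2 breathing cycles")
        return TriggerSeries(times=np.asarray(mids), source=source)
    raise ValueError(f"unknown trigger source {source!r}")


def coherent_average(values: np.ndarray, dt: float, triggers: TriggerSeries,
                     window_before: float, window_after: float
                     ) -> tuple[np.ndarray, np.ndarray, int]:
    """Average trigger-aligned epochs of a trace.

    Epochs extending past the recording bounds are dropped.  Returns
    (averaged epoch, epoch time axis relative to trigger, number of epochs).
    """
    x = np.asarray(values, dtype=float)
    n_before = int(round(window_before / dt))
    n_after = int(round(window_after / dt))
    n_ep = n_before + n_after
    epochs = []
    for t in triggers.times:
        i0 = int(round(t / dt)) - n_before
        if i0 < 0 or i0 + n_ep > x.size:
            continue
        epochs.append(x[i0:i0 + n_ep])
    if not epochs:
        raise ProcessingError("all epochs fall outside the recording")
    avg = np.mean(epochs, axis=0)
    taxis = (np.arange(n_ep) - n_before) * dt
    return avg, taxis, len(epochs)


def rms_convert(trace: DemodTrace, fc: float = 250.0,
                window: float = 0.1) -> RMSTrace:
    """High-pass at ``fc`` then moving-window RMS, preserving the sample step.

    The moving average uses nearest-edge padding so the output has the same
    number of samples as the input.
    """
    fs = 1.0 / trace.dt
    n = trace.values.size
    if window >= n * trace.dt:
        raise ValueError("RMS window must be shorter than the trace")
    sos = signal.butter(5, fc, btype="highpass", fs=fs, output="sos")
    hp = signal.sosfiltfilt(sos, trace.values)
    nwin = max(1, int(round(window / trace.dt)))
    from scipy.ndimage import uniform_filter1d
    ms = uniform_filter1d(hp * hp, size=nwin, mode="nearest")
    return RMSTrace(values=np.sqrt(np.maximum(ms, 0.0)), dt=trace.dt,
                    window=window, highpass_fc=fc,
                    pair=trace.pair, electrode=trace.electrode)


def default_baseline_window(ensemble_mean: np.ndarray, dt: float,
                            fraction: float = 0.1) -> tuple[int, int]:
    """Baseline window: ``fraction`` of the epoch centered on the minimum of
    the ensemble-mean trace (a time of low or absent neural traffic)."""
    n = ensemble_mean.size
    half = max(1, int(round(0.5 * fraction * n)))
    i = int(np.argmin(ensemble_mean))
    lo = min(max(0, i - half), n - 2 * half)
    return lo, lo + 2 * half


def baseline_subtract(values: np.ndarray, baseline: tuple[int, int]) -> np.ndarray:
    """Subtract the mean over the baseline sample window."""
    lo, hi = baseline
    x = np.asarray(values, dtype=float)
    if not 0 <= lo < hi <= x.size:
        raise ValueError("baseline window outside epoch")
    return x - x[lo:hi].mean()


@dataclass
class ExclusionReport:
    kept: np.ndarray                    # (n,) bool
    reasons: list[list[str]]            # per trace
    counts: dict[str, int]

    @property
    def kept_fraction(self) -> float:
        return float(self.kept.mean())


def exclude_evoked(traces: np.ndarray, baseline: tuple[int, int],
                   noise_thresh: float = 1.0, mean_thresh: float = 2.0,
                   max_thresh: float = 4.0,
                   carrier_amplitudes: np.ndarray | None = None,
                   carrier_min: float = 300.0) -> ExclusionReport:
    """Quality control for evoked (averaged) dV traces.

    A trace is excluded if its pre-stimulus noise level (baseline-window SD)
    exceeds ``noise_thresh`` or its mean/max absolute amplitude after
    baseline subtraction exceeds ``mean_thresh``/``max_thresh``.  Thresholds
    are in microvolts; defaults are the strict ends of the 1-4 / 2-6 / 4-8 uV
    working ranges.

    If per-trace baseline carrier amplitudes (the mean demodulated envelope,
    uV) are supplied, channels below ``carrier_min`` are also excluded: with
    no appreciable carrier the envelope is noise-dominated and the recovered
    dV sign is meaningless (poor contact, or a measurement electrode at a
    null of the injection pattern).
    """
    if min(noise_thresh, mean_thresh, max_thresh) <= 0:
        raise ValueError("thresholds must be positive")
    X = np.atleast_2d(np.asarray(traces, dtype=float))
    reasons: list[list[str]] = []
    counts = {"noise": 0, "mean_amplitude": 0, "max_amplitude": 0,
              "low_carrier": 0}
    for i, row in enumerate(X):
        x = baseline_subtract(row, baseline)
        r = []
        if x[baseline[0]:baseline[1]].std() > noise_thresh:
            r.append("noise")
        if np.abs(x).mean() > mean_thresh:
            r.append("mean_amplitude")
        if np.abs(x).max() > max_thresh:
            r.append("max_amplitude")
        if carrier_amplitudes is not None and carrier_amplitudes[i] < carrier_min:
            r.append("low_carrier")
        for k in r:
            counts[k] += 1
        reasons.append(r)
    kept = np.array([not r for r in reasons])
    if not kept.any():
        raise ProcessingError(
            "all evoked traces excluded; review thresholds "
            f"(noise={noise_thresh}, mean={mean_thresh}, max={max_thresh} uV)")
    return ExclusionReport(kept=kept, reasons=reasons, counts=counts)


def exclude_spontaneous(traces: np.ndarray, dt: float,
                        amplitude_thresh: float = 0.2,
                        derivative_thresh: float = 50.0,
                        n_sd: float = 3.0,
                        exceed_fraction: float = 0.05,
                        pc1_residual: bool = True,
                        manual: list[int] | None = None) -> ExclusionReport:
    """Quality control for spontaneous dV-RMS traces.

    Criteria, each evaluated against the full ensemble (flags are unioned,
    not applied sequentially):

    1. amplitude: max |trace - trace mean| > ``amplitude_thresh`` uV;
    2. derivative: max |first difference| / dt > ``derivative_thresh`` uV/s;
    3. ensemble deviation: |trace - ensemble mean| exceeds ``n_sd`` ensemble
       SDs in more than ``exceed_fraction`` of time points;
    4. the same pointwise test applied to the residual after reconstructing
       each trace from only the first principal component of the ensemble
       (set ``pc1_residual=False`` to test the PC1 reconstruction itself);
    5. manual override list.

    Because pointwise 3-SD tests on finite ensembles flag isolated samples by
    chance, a trace must exceed the threshold in a fraction of time points
    (default 5%) to be excluded by criteria 3-4.
    """
    X = np.atleast_2d(np.asarray(traces, dtype=float))
    n = X.shape[0]
    if n < 10:
        raise ValueError("need >= 10 traces for ensemble statistics")
    reasons: list[list[str]] = [[] for _ in range(n)]
    counts = {"amplitude": 0, "derivative": 0, "ensemble_sd": 0,
              "pca_sd": 0, "manual": 0}

    amp = np.abs(X - X.mean(axis=1, keepdims=True)).max(axis=1)
    deriv = np.abs(np.diff(X, axis=1)).max(axis=1) / dt
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, np.inf)
    frac3 = (np.abs(X - mu) > n_sd * sd).mean(axis=1)

    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    pc1 = np.outer(U[:, 0] * s[0], Vt[0])
    resid = Xc - pc1
    target = resid if pc1_residual else mu + pc1
    tm = target.mean(axis=0)
    tsd = target.std(axis=0)
    tsd = np.where(tsd > 0, tsd, np.inf)
    frac4 = (np.abs(target - tm) > n_sd * tsd).mean(axis=1)

    manual = set(manual or [])
    for i in range(n):
        if amp[i] > amplitude_thresh:
            reasons[i].append("amplitude")
        if deriv[i] > derivative_thresh:
            reasons[i].append("derivative")
        if frac3[i] > exceed_fraction:
            reasons[i].append("ensemble_sd")
        if frac4[i] > exceed_fraction:
            reasons[i].append("pca_sd")
        if i in manual:
            reasons[i].append("manual")
        for k in reasons[i]:
            counts[k] += 1
    kept = np.array([not r for r in reasons])
    return ExclusionReport(kept=kept, reasons=reasons, counts=counts)


def compute_snr(values: np.ndarray, peak_window: tuple[int, int],
                baseline_window: tuple[int, int]) -> SNRReport:
    """SNR of an averaged trace: |peak mean - baseline mean| / baseline SD."""
    p0, p1 = peak_window
    b0, b1 = baseline_window
    if max(p0, b0) < min(p1, b1):
        raise ValueError("peak and baseline windows must be disjoint")
    x = np.asarray(values, dtype=float)
    noise = x[b0:b1].std()
    if noise <= 0:
        raise ProcessingError("baseline window has zero variance")
    peak = x[p0:p1].mean() - x[b0:b1].mean()
    return SNRReport(snr=float(abs(peak) / noise), peak_value=float(abs(peak)),
                     baseline_noise=float(noise))
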