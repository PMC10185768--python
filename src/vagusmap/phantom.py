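"""Synthetic nerves, physiology, EIT recordings and stimulation responses.

The phantom realizes the organotopic layout observed in the pig cervical
vagus nerve: laryngeal fascicles ventrolateral (3 o'clock, 0 deg math
convention), pulmonary dorsomedial (8 o'clock, 210 deg), cardiac
ventromedial (12 o'clock, 90 deg), on a 3 mm circular cross-section.
Everything downstream of the generators is a pure function of
(configuration, seed).

Neural traffic is modeled as a fractional conductivity decrease of the
active group's fascicles: an impulse at a conduction latency after each
stimulus for evoked activity, or a cycle-locked burst envelope multiplying
band-limited (300-1500 Hz) activity for cardiac/pulmonary-gated traffic —
the burst carries the high-frequency content that survives the 250 Hz
high-pass of the dV-RMS chain.  Raw recordings are the baseline transfer
voltage carrier, amplitude-modulated by J . dsigma, plus white noise;
traces are synthesized lazily per injection pair to keep memory flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .forward import JacobianMatrix, VoxelGrid
from .geometry import N_ELECTRODES, PROTOCOL_SKIP, NerveGeometry, clock_to_deg


class PlacementError(RuntimeError):
    """Fascicle placement failed after the allowed number of attempts."""


ORGANS = ("laryngeal", "pulmonary", "cardiac")

#: SS readout metric per organ
ORGAN_METRIC = {
    "cardiac": "hr_drop_pct",
    "pulmonary": "breath_change_pct",
    "laryngeal": "emg_rms_ratio",
}


@dataclass(frozen=True)
class FascicleGroupSpec:
    """One organ's fascicle group on the cross-section.

    Angles are degrees counterclockwise from 3 o'clock; the center sits at
    ``center_radius_fraction`` of the nerve radius.  ``perturbation_amplitude``
    is the fractional conductivity change during firing (e.g. -0.01 = -1%).
    """

    organ: str
    center_angle: float
    center_radius_fraction: float = 0.6
    n_fascicles: int = 10
    fascicle_radius: float = 130e-6
    perturbation_amplitude: float = -0.01
    angle_spread_deg: float = 22.0
    radius_spread_fraction: float = 0.12

    def __post_init__(self) -> None:
        if not 0 <= self.center_radius_fraction < 1:
            raise ValueError("center_radius_fraction must be in [0, 1)")
        if self.n_fascicles < 0 or self.fascicle_radius <= 0:
            raise ValueError("invalid fascicle count/radius")


def default_groups() -> list[FascicleGroupSpec]:
    """The three-organ layout: laryngeal at 3, pulmonary at 8, cardiac at 12
    o'clock, with fascicle counts in the ratio observed in microCT tracing
    (laryngeal ~15, pulmonary ~18, cardiac 1-2 per nerve)."""
    return [
        FascicleGroupSpec("laryngeal", clock_to_deg(3), 0.60, 15, 100e-6,
                          angle_spread_deg=26.0, radius_spread_fraction=0.15),
        FascicleGroupSpec("pulmonary", clock_to_deg(8), 0.60, 18, 100e-6,
                          angle_spread_deg=26.0, radius_spread_fraction=0.15),
        FascicleGroupSpec("cardiac", clock_to_deg(12), 0.65, 1, 110e-6,
                          angle_spread_deg=8.0, radius_spread_fraction=0.05),
    ]


@dataclass
class Phantom:
    geometry: NerveGeometry
    groups: list[FascicleGroupSpec]
    fascicles: pd.DataFrame          # columns x, y (m), radius (m), organ
    seed: int

    def group(self, organ: str) -> FascicleGroupSpec:
        for g in self.groups:
            if g.organ == organ:
                return g
        raise KeyError(f"no fascicle group for organ {organ!r}")

    def group_center(self, organ: str) -> tuple[float, float]:
        """True mean fascicle-center location of one organ, meters."""
        sub = self.fascicles[self.fascicles.organ == organ]
        if sub.empty:
            raise KeyError(f"no fascicles for organ {organ!r}")
        return float(sub.x.mean()), float(sub.y.mean())

    def voxel_perturbation(self, grid: VoxelGrid, organ: str,
                           subsamples: int = 4) -> np.ndarray:
        """Per-voxel fractional-conductivity perturbation pattern (at unit
        traffic), i.e. amplitude times the covered fraction of each voxel."""
        g = self.group(organ)
        sub = self.fascicles[self.fascicles.organ == organ]
        h = grid.voxel_size
        off = (np.arange(subsamples) + 0.5) / subsamples - 0.5
        ox, oy = np.meshgrid(off * h, off * h)
        pts = grid.centers[:, None, :] + np.column_stack([ox.ravel(), oy.ravel()])[None]
        covered = np.zeros(pts.shape[:2], dtype=bool)
        for _, f in sub.iterrows():
            covered |= np.hypot(pts[..., 0] - f.x, pts[..., 1] - f.y) <= f.radius
        return g.perturbation_amplitude * covered.mean(axis=1)


def make_phantom(geometry: NerveGeometry | None = None,
                 groups: list[FascicleGroupSpec] | None = None,
                 seed: int = 0, max_attempts: int = 1000) -> Phantom:
    """Realize fascicle disks for each organ group, deterministically.

    Fascicle centers scatter around the group center (Gaussian in angle and
    radius); disks must lie strictly inside the nerve and not overlap.
    """
    geometry = geometry or NerveGeometry()
    groups = default_groups() if groups is None else groups
    organs = [g.organ for g in groups]
    if len(set(organs)) != len(organs):
        raise ValueError("organ labels must be unique")
    rng = np.random.default_rng(seed)
    R = geometry.nerve_radius
    placed_x, placed_y, placed_r, placed_org = [], [], [], []
    for g in groups:
        r0 = g.center_radius_fraction * R
        for _ in range(g.n_fascicles):
            for attempt in range(max_attempts):
                ang = np.radians(g.center_angle + rng.normal(0, g.angle_spread_deg))
                rad = r0 + rng.normal(0, g.radius_spread_fraction * R)
                x, y = rad * np.cos(ang), rad * np.sin(ang)
                if np.hypot(x, y) + g.fascicle_radius >= 0.97 * R:
                    continue
                ok = all(np.hypot(x - px, y - py) > g.fascicle_radius + pr
                         for px, py, pr in zip(placed_x, placed_y, placed_r))
                if ok:
                    placed_x.append(x); placed_y.append(y)
                    placed_r.append(g.fascicle_radius); placed_org.append(g.organ)
                    break
            else:
                raise PlacementError(
                    f"could not place fascicle of group {g.organ!r} without "
                    f"overlap (colliding with {sorted(set(placed_org))}) after "
                    f"{max_attempts} attempts")
    fascicles = pd.DataFrame({
        "x": placed_x, "y": placed_y, "radius": placed_r, "organ": placed_org})
    return Phantom(geometry=geometry, groups=list(groups),
                   fascicles=fascicles, seed=seed)


# ---------------------------------------------------------------------------
# Physiology


@dataclass
class PhysioSignals:
    """Auxiliary physiological channels with generator ground truth."""

    sampling_rate: float
    bp: np.ndarray            # mmHg
    etco2: np.ndarray         # mmHg
    ecg: np.ndarray           # mV
    emg: np.ndarray           # mV
    heart_rate: float         # bpm
    breath_rate: float        # breaths/min
    beat_times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    breath_midpoints: np.ndarray = field(default_factory=lambda: np.zeros(0))
    stim_times: np.ndarray | None = None

    @property
    def duration(self) -> float:
        return self.bp.size / self.sampling_rate


def _bp_waveform(t: np.ndarray, beat_times: np.ndarray, period: float,
                 diastolic: float = 80.0, pulse: float = 40.0) -> np.ndarray:
    bp = np.full_like(t, diastolic)
    rise, fall = 0.10 * period, 0.22 * period
    for tb in beat_times:
        d = t - tb
        m = (d > -4 * rise) & (d < 4 * fall)
        s = np.where(d[m] < 0, rise, fall)
        bp[m] += pulse * np.exp(-0.5 * (d[m] / s) ** 2)
    return bp


def _etco2_waveform(t: np.ndarray, onsets: np.ndarray, period: float,
                    lo: float = 5.0, hi: float = 40.0) -> np.ndarray:
    """Plateau-shaped capnogram: logistic rising edge at breath onset,
    falling edge half a cycle later."""
    from scipy.special import expit

    x = np.full_like(t, lo)
    w = 0.03 * period
    for tb in onsets:
        up = expit((t - tb) / w)
        down = expit((t - (tb + 0.5 * period)) / w)
        x += (hi - lo) * (up - down)
    return np.clip(x, lo, hi)


def simulate_physio(duration: float, heart_rate: float = 100.0,
                    breath_rate: float = 12.0, seed: int = 0,
                    sampling_rate: float = 50000.0,
                    hr_jitter: float = 0.02, rr_jitter: float = 0.03,
                    ) -> PhysioSignals:
    """Generate BP, EtCO2, ECG and (quiescent) EMG channels.

    BP peaks and EtCO2 edge midpoints are exactly at the stored ground-truth
    times; cycle-to-cycle interval jitter is seeded.  The channels are
    clean monitoring signals (no additive noise) so trigger detection is
    exact to within one sample.
    """
    if duration <= 0 or heart_rate <= 0 or breath_rate <= 0:
        raise ValueError("duration and rates must be positive")
    if duration < max(60.0 / heart_rate, 60.0 / breath_rate):
        raise ValueError("duration shorter than one physiological cycle")
    rng = np.random.default_rng(seed)
    fs = sampling_rate
    t = np.arange(int(round(duration * fs))) / fs

    Tb = 60.0 / heart_rate
    n_beats = int(np.ceil(duration / Tb)) + 2
    intervals = Tb * (1.0 + hr_jitter * rng.standard_normal(n_beats))
    beats = 0.35 * Tb + np.concatenate([[0.0], np.cumsum(intervals)])
    beats = beats[(beats > 0.1 * Tb) & (beats < duration - 0.1 * Tb)]
    bp = _bp_waveform(t, beats, Tb)

    Tr = 60.0 / breath_rate
    n_breaths = int(np.ceil(duration / Tr)) + 2
    rints = Tr * (1.0 + rr_jitter * rng.standard_normal(n_breaths))
    onsets = 0.15 * Tr + np.concatenate([[0.0], np.cumsum(rints)])
    onsets = onsets[onsets < duration - 0.55 * Tr]
    etco2 = _etco2_waveform(t, onsets, Tr)
    midpoints = onsets + 0.25 * Tr

    ecg = np.zeros_like(t)
    for tb in beats:
        d = t - (tb - 0.15 * Tb)      # R wave precedes the systolic BP peak
        m = np.abs(d) < 0.05
        ecg[m] += 1.2 * np.exp(-0.5 * (d[m] / 0.008) ** 2)
    emg = 0.002 * rng.standard_normal(t.size)

    return PhysioSignals(sampling_rate=fs, bp=bp, etco2=etco2, ecg=ecg,
                         emg=emg, heart_rate=heart_rate,
                         breath_rate=breath_rate, beat_times=beats,
                         breath_midpoints=midpoints)


# ---------------------------------------------------------------------------
# Stimulation protocol


@dataclass(frozen=True)
class StimProtocol:
    """Pulse-train stimulation protocol; rest duration equals train duration."""

    pulse_rate: float = 20.0
    pulse_width: float = 50e-6
    amplitude: float = 400e-6
    train_duration: float = 5.0
    rest_duration: float = 5.0

    def __post_init__(self) -> None:
        if self.rest_duration != self.train_duration:
            raise ValueError("rest_duration must equal train_duration")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    @classmethod
    def for_organ(cls, organ: str) -> "StimProtocol":
        table = {
            "pulmonary": dict(pulse_width=50e-6, amplitude=400e-6,
                              train_duration=15.0, rest_duration=15.0),
            "cardiac": dict(pulse_width=1e-3, amplitude=1000e-6,
                            train_duration=15.0, rest_duration=15.0),
            "laryngeal": dict(pulse_width=50e-6, amplitude=100e-6,
                              train_duration=5.0, rest_duration=5.0),
        }
        return cls(**table[organ])


# ---------------------------------------------------------------------------
# Neural traffic


@dataclass
class NeuralTraffic:
    """Fractional conductivity-change time course per fascicle group."""

    sampling_rate: float
    values: dict[str, np.ndarray]     # organ -> dsigma/sigma per sample
    mode: str
    trigger_times: np.ndarray

    @property
    def n_samples(self) -> int:
        return next(iter(self.values.values())).size


#: default cross-sectional traffic scale per mode.  The 2D cross-sectional
#: forward model concentrates all injected current in the imaging plane, so
#: a full-depth fractional conductivity change would produce boundary-voltage
#: changes far above the microvolt regime the recording chain (thresholds,
#: noise-correction amplitudes) is built for; these factors model the
#: longitudinal current spreading and partial fiber recruitment of the real
#: cylindrical geometry.  Spontaneous gated activity recruits a smaller
#: synchronous fiber fraction per cycle than an evoked compound volley.
TRAFFIC_DILUTION = {
    "evoked": 5e-3,
    "cardiac_gated": 5e-3,
    "pulmonary_gated": 5e-4,
}


def _band_noise(n: int, fs: float, lo: float, hi: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited noise (the fast component of a firing burst)."""
    x = rng.standard_normal(n)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfilt(sos, x)
    return y / max(y.std(), 1e-30)


def simulate_neural_traffic(
    phantom: Phantom,
    mode: str,
    duration: float,
    physio: PhysioSignals | None = None,
    stim_protocol: StimProtocol | None = None,
    stim_times: np.ndarray | None = None,
    conduction_velocity: float = 40.0,
    travel_distance: float = 0.4,
    sampling_rate: float = 50000.0,
    seed: int = 0,
    evoked_width: float = 1e-3,
    cardiac_phase: float = 0.150,
    cardiac_width: float = 0.030,
    pulmonary_width: float = 0.5,
    burst_band: tuple[float, float] = (300.0, 1500.0),
    dilution: float | None = None,
    cycle_cv: float = 0.3,
) -> NeuralTraffic:
    """Conductivity-perturbation time course for the active group.

    - ``evoked``: a Gaussian impulse of width ``evoked_width`` peaking
      ``travel_distance / conduction_velocity`` after each stimulus.
    - ``cardiac_gated``: a burst envelope peaking ``cardiac_phase`` seconds
      after each blood-pressure peak.
    - ``pulmonary_gated``: a burst envelope at each EtCO2 breath midpoint.

    Gated envelopes multiply unit-RMS 300-1500 Hz activity so the burst has
    the high-frequency content the dV-RMS chain measures, and each cycle's
    burst amplitude varies with coefficient of variation ``cycle_cv``
    (physiological cycle-to-cycle variability).  Only the target organ's
    group is perturbed; other organs carry zeros.  The final amplitude is
    the group's perturbation amplitude times ``dilution`` (per-mode default
    from ``TRAFFIC_DILUTION``).
    """
    fs = sampling_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    values = {g.organ: np.zeros(n) for g in phantom.groups}

    if mode == "evoked":
        organ = "laryngeal"
        if stim_times is None:
            if stim_protocol is None:
                raise ValueError("evoked mode requires stim_protocol or stim_times")
            stim_times = np.arange(0.05, duration - 0.05, 1.0 / stim_protocol.pulse_rate)
        latency = travel_distance / conduction_velocity
        x = np.zeros(n)
        for ts in np.asarray(stim_times):
            d = t - (ts + latency)
            m = np.abs(d) < 5 * evoked_width
            x[m] += np.exp(-0.5 * (d[m] / evoked_width) ** 2)
        values[organ] = np.clip(x, 0, 1.0)
        triggers = np.asarray(stim_times)
    elif mode in ("cardiac_gated", "pulmonary_gated"):
        if physio is None:
            raise ValueError(f"{mode} requires physiological signals")
        organ = "cardiac" if mode == "cardiac_gated" else "pulmonary"
        if organ not in values:
            raise KeyError(f"phantom has no {organ} group")
        if mode == "cardiac_gated":
            centers = physio.beat_times + cardiac_phase
            width = cardiac_width
        else:
            centers = physio.breath_midpoints
            width = pulmonary_width
        env = np.zeros(n)
        gains = np.maximum(1.0 + cycle_cv * rng.standard_normal(len(centers)), 0.1)
        for tc, gain in zip(centers, gains):
            d = t - tc
            m = np.abs(d) < 4 * width
            env[m] += gain * np.exp(-0.5 * (d[m] / width) ** 2)
        values[organ] = env * _band_noise(n, fs, *burst_band, rng)
        triggers = np.asarray(centers)
    else:
        raise ValueError(f"unknown traffic mode {mode!r}")

    # scale by the group's perturbation amplitude and the mode's dilution
    if dilution is None:
        dilution = TRAFFIC_DILUTION[mode]
    amp = phantom.group(organ).perturbation_amplitude * dilution
    values[organ] = amp * values[organ]
    return NeuralTraffic(sampling_rate=fs, values=values, mode=mode,
                         trigger_times=triggers)


# ---------------------------------------------------------------------------
# Raw recording synthesis


@dataclass
class RawEITRecording:
    """Multichannel carrier recording for the full skip-4 protocol.

    Traces are synthesized lazily per injection pair (deterministic in the
    seed) so the 196 x duration x 50 kS/s ensemble never has to sit in
    memory at once.  ``pair_traces(k)`` returns a (14, n_samples) array in
    volts.
    """

    sampling_rate: float
    carrier_frequency: float
    carrier_amplitude: float
    n_samples: int
    injection_pairs: list[tuple[int, int]]
    baseline_voltages: np.ndarray          # (196,) volts, pair-major
    modulation: np.ndarray                 # (196, n_organs) volts per unit traffic
    traffic: NeuralTraffic
    noise_rms: float
    seed: int
    physio: PhysioSignals | None = None
    trigger_times: np.ndarray | None = None
    electrode_count: int = N_ELECTRODES
    skip: int = PROTOCOL_SKIP
    corruption: dict[tuple[int, int], tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.injection_pairs) != self.electrode_count:
            raise ValueError("one injection pair per electrode position required")
        for a, b in self.injection_pairs:
            if (b - a) % self.electrode_count not in (self.skip,
                                                      self.electrode_count - self.skip):
                raise ValueError("injection pair does not respect the skip")

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def _organ_traffic_matrix(self) -> np.ndarray:
        organs = list(self.traffic.values)
        return np.stack([self.traffic.values[o] for o in organs])

    def delta_v(self, k: int) -> np.ndarray:
        """Noise-free envelope modulation dV (14, n) in volts for pair k."""
        rows = slice(14 * k, 14 * (k + 1))
        T = self._organ_traffic_matrix()
        return self.modulation[rows] @ T

    def pair_traces(self, k: int) -> np.ndarray:
        """Synthesize the 14 electrode-voltage traces of injection pair k."""
        if not 0 <= k < len(self.injection_pairs):
            raise IndexError(f"injection pair {k} out of range")
        if self.traffic.n_samples != self.n_samples:
            raise ValueError("traffic is not sampled on the recording clock")
        fs = self.sampling_rate
        t = np.arange(self.n_samples) / fs
        carrier = np.sin(2 * np.pi * self.carrier_frequency * t)
        rows = slice(14 * k, 14 * (k + 1))
        amp = self.baseline_voltages[rows, None] + self.delta_v(k)
        traces = amp * carrier[None, :]
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, k]))
        if self.noise_rms > 0:
            traces = traces + self.noise_rms * rng.standard_normal(traces.shape)
        for (pk, e), (kind, value) in self.corruption.items():
            if pk != k:
                continue
            traces[e] = traces[e] + self._artifact(kind, value, t, carrier, rng)
        return traces

    def _artifact(self, kind: str, value: float, t: np.ndarray,
                  carrier: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """In-band artifact components; ``value`` is in volts (or V/s)."""
        if kind == "amplitude":
            # fluctuating burst activity of RMS ~ value: large dV-RMS amplitude
            burst = _band_noise(t.size, self.sampling_rate, 300.0, 1500.0, rng)
            env = 1.0 + 0.9 * np.sin(2 * np.pi * 0.25 * t)
            return value * env * burst * carrier
        if kind == "derivative":
            # burst-RMS ramp: dV-RMS derivative ~ value V/s
            burst = _band_noise(t.size, self.sampling_rate, 300.0, 1500.0, rng)
            return value * t * burst * carrier
        if kind == "noise":
            # broadband in-band noise: raises post-demodulation noise level
            return value * rng.standard_normal(t.size)
        if kind == "drift":
            # off-ensemble slow-burst drift (criterion-3/4 class)
            burst = _band_noise(t.size, self.sampling_rate, 300.0, 1500.0, rng)
            env = 0.5 * (1 + np.sin(2 * np.pi * 0.1 * t))
            return value * env * burst * carrier
        raise ValueError(f"unknown artifact class {kind!r}")


def synthesize_recording(
    phantom: Phantom,
    jacobian: JacobianMatrix,
    baseline_voltages: np.ndarray,
    traffic: NeuralTraffic,
    noise_rms: float = 0.0,
    seed: int = 0,
    carrier_frequency: float = 6000.0,
    carrier_amplitude: float = 200e-6,
    physio: PhysioSignals | None = None,
) -> RawEITRecording:
    """Assemble a raw recording from the forward model and a traffic course.

    The measurement for trace m is (V0_m + sum_g J_m . p_g traffic_g(t))
    times the carrier, plus white noise; p_g is organ g's voxel perturbation
    pattern at unit traffic.
    """
    if noise_rms < 0:
        raise ValueError("noise_rms must be >= 0")
    if jacobian.grid is None:
        raise ValueError("voxelized Jacobian required")
    organs = list(traffic.values)
    P = np.column_stack([
        phantom.voxel_perturbation(jacobian.grid, o) /
        (phantom.group(o).perturbation_amplitude or 1.0)
        for o in organs
    ])
    modulation = jacobian.matrix @ P     # volts per unit traffic value
    pairs = [(k, (k + PROTOCOL_SKIP) % N_ELECTRODES) for k in range(N_ELECTRODES)]
    return RawEITRecording(
        sampling_rate=traffic.sampling_rate,
        carrier_frequency=carrier_frequency,
        carrier_amplitude=carrier_amplitude,
        n_samples=traffic.n_samples,
        injection_pairs=pairs,
        baseline_voltages=np.asarray(baseline_voltages, dtype=float),
        modulation=modulation,
        traffic=traffic,
        noise_rms=noise_rms,
        seed=seed,
        physio=physio,
        trigger_times=traffic.trigger_times,
    )


def corrupt_traces(recording: RawEITRecording,
                   plan: dict[tuple[int, int], tuple[str, float]]
                   ) -> RawEITRecording:
    """Return a recording with artifact components injected on selected
    (pair, electrode) traces.  An empty plan returns an identical recording."""
    for (k, e) in plan:
        if not (0 <= k < len(recording.injection_pairs) and
                0 <= e < recording.electrode_count):
            raise ValueError(f"corruption plan index ({k}, {e}) out of range")
    merged = dict(recording.corruption)
    merged.update(plan)
    return replace(recording, corruption=merged)


# ---------------------------------------------------------------------------
# Selective-stimulation responses


def angular_kernel(delta_deg: np.ndarray, spread_deg: float = 26.0) -> np.ndarray:
    """Von Mises-shaped selectivity kernel; half-width at half maximum equals
    ``spread_deg / 2`` so the full angular spread matches the focused
    stimulation characterization."""
    if spread_deg <= 0:
        raise ValueError("spread_deg must be positive")
    kappa = np.log(2.0) / (1.0 - np.cos(np.radians(spread_deg / 2.0)))
    return np.exp(kappa * (np.cos(np.radians(delta_deg)) - 1.0))


#: peak physiological effect at the best-aligned pair, per organ
DEFAULT_SS_AMPLITUDE = {
    "cardiac": -10.1,        # % HR change
    "pulmonary": -38.6,      # % breathing-rate change
    "laryngeal": 12.0,       # EMG RMS ratio at peak (>10x baseline)
}

DEFAULT_SS_BASELINE = {
    "cardiac": 100.0,        # bpm
    "pulmonary": 12.0,       # breaths/min
    "laryngeal": 1.0,        # RMS ratio
}


def simulate_ss_responses(
    phantom: Phantom,
    electrode_angles: np.ndarray,
    spread_deg: float = 26.0,
    seed: int = 0,
    amplitudes: dict[str, float] | None = None,
    noise_sd: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-electrode-pair physiological responses to selective stimulation.

    The response of pair p to organ g follows the angular selectivity kernel
    of the angular distance between the pair angle and g's fascicle-group
    center, scaled to the organ's peak effect, plus seeded measurement noise.
    Returns a StimResponseTable: one row per (organ, pair) with the metric,
    baseline, value during stimulation, response (change from baseline) and
    the baseline fluctuation scale.
    """
    amplitudes = {**DEFAULT_SS_AMPLITUDE, **(amplitudes or {})}
    noise_sd = {**{"cardiac": 0.8, "pulmonary": 3.0, "laryngeal": 0.15},
                **(noise_sd or {})}
    rng = np.random.default_rng(seed)
    rows = []
    for g in phantom.groups:
        metric = ORGAN_METRIC[g.organ]
        base = DEFAULT_SS_BASELINE[g.organ]
        amp = amplitudes[g.organ]
        sd = noise_sd[g.organ]
        cx, cy = phantom.group_center(g.organ)
        center_angle = np.degrees(np.arctan2(cy, cx))
        delta = (np.asarray(electrode_angles) - center_angle + 180.0) % 360.0 - 180.0
        kern = angular_kernel(delta, spread_deg)
        # the organ amplitude is defined as the peak effect observed at the
        # most effective pair, whatever its alignment with the group center
        kern = kern / kern.max()
        if metric == "emg_rms_ratio":
            resp = (amp - 1.0) * kern + sd * rng.standard_normal(kern.size)
            value = 1.0 + resp
        else:
            resp = amp * kern + sd * rng.standard_normal(kern.size)
            value = base * (1.0 + resp / 100.0)
        for p in range(kern.size):
            rows.append(dict(organ=g.organ, metric=metric, pair=p,
                             baseline=base, value=value[p],
                             response=resp[p], baseline_sd=sd))
    return pd.DataFrame(rows)


def simulate_stim_session(
    metric: str,
    response: float,
    protocol: StimProtocol,
    n_trains: int = 3,
    seed: int = 0,
    heart_rate: float = 100.0,
    breath_rate: float = 12.0,
    sampling_rate: float = 10000.0,
    emg_baseline_rms: float = 0.01,
) -> tuple[PhysioSignals, list[tuple[float, float]], list[tuple[float, float]]]:
    """One pair's stimulation session: physiology modulated during trains.

    ``response`` is the percent change (hr/breath metrics) or the RMS ratio
    (EMG metric) during stimulation.  Returns (physio, stim windows, rest
    windows); the session alternates rest and train periods of equal length,
    starting and ending at rest.
    """
    T = protocol.train_duration
    windows_s = [((2 * i + 1) * T, (2 * i + 2) * T) for i in range(n_trains)]
    windows_r = [((2 * i) * T, (2 * i + 1) * T) for i in range(n_trains + 1)]
    duration = (2 * n_trains + 1) * T
    rng = np.random.default_rng(seed)
    fs = sampling_rate
    t = np.arange(int(round(duration * fs))) / fs

    def in_stim(x: float) -> bool:
        return any(a <= x < b for a, b in windows_s)

    if metric == "hr_drop_pct":
        rate0 = heart_rate
        beats, tc = [], 0.3
        while tc < duration:
            rate = rate0 * (1.0 + response / 100.0) if in_stim(tc) else rate0
            beats.append(tc)
            tc += 60.0 / rate * (1.0 + 0.01 * rng.standard_normal())
        beats = np.asarray(beats)
        bp = _bp_waveform(t, beats, 60.0 / rate0)
        physio = PhysioSignals(fs, bp, np.zeros_like(t), np.zeros_like(t),
                               np.zeros_like(t), heart_rate, breath_rate,
                               beat_times=beats)
    elif metric == "breath_change_pct":
        rate0 = breath_rate
        onsets, tc = [], 0.3
        while tc < duration:
            rate = rate0 * (1.0 + response / 100.0) if in_stim(tc) else rate0
            onsets.append(tc)
            tc += 60.0 / max(rate, 1e-6) * (1.0 + 0.02 * rng.standard_normal())
        onsets = np.asarray(onsets)
        etco2 = _etco2_waveform(t, onsets, 60.0 / rate0)
        physio = PhysioSignals(fs, np.zeros_like(t), etco2, np.zeros_like(t),
                               np.zeros_like(t), heart_rate, breath_rate,
                               breath_midpoints=onsets + 0.25 * 60.0 / rate0)
    elif metric == "emg_rms_ratio":
        sos = signal.butter(4, [20.0, 2000.0], btype="bandpass", fs=fs,
                            output="sos")
        base = signal.sosfilt(sos, rng.standard_normal(t.size))
        base *= emg_baseline_rms / base.std()
        gain = np.ones_like(t)
        for a, b in windows_s:
            gain[(t >= a) & (t < b)] = response
        physio = PhysioSignals(fs, np.zeros_like(t), np.zeros_like(t),
                               np.zeros_like(t), base * gain,
                               heart_rate, breath_rate)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return physio, windows_s, windows_r


# ---------------------------------------------------------------------------
# microCT fascicle tables


def simulate_microct_fascicles(
    phantom: Phantom,
    ellipse_ratio: float = 1.2,
    rotation_deg: float = 0.0,
    jitter_um: float = 30.0,
    seed: int = 0,
    animal: str = "animal0",
    level: str = "caudal_cuff",
):
    """MicroCT-style fascicle center table on a deformed cross-section.

    The imaged nerve is the circular phantom rotated by ``rotation_deg``
    (cuff orientation in the image) and then elongated/shortened along the
    image X/Y axes by sqrt(ellipse_ratio) (area-preserving), plus Gaussian
    segmentation jitter.  Returns a FascicleTable whose outline is the
    deformed nerve ellipse and whose recorded cuff-opening angle is the
    image angle of the deformed 90-degree (opening) direction.
    """
    from .coregister import EllipseOutline, FascicleTable

    if ellipse_ratio <= 0:
        raise ValueError("ellipse_ratio must be positive")
    rng = np.random.default_rng(seed)
    R = phantom.geometry.nerve_radius
    s = np.sqrt(ellipse_ratio)
    th = np.radians(rotation_deg)
    Rm = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    S = np.diag([s, 1.0 / s])
    pts = phantom.fascicles[["x", "y"]].to_numpy()
    obs = (S @ Rm @ pts.T).T * 1e6
    obs = obs + jitter_um * rng.standard_normal(obs.shape)
    opening = S @ Rm @ np.array([0.0, 1.0])
    opening_deg = float(np.degrees(np.arctan2(opening[1], opening[0])) % 360.0)
    df = pd.DataFrame({
        "x_um": obs[:, 0], "y_um": obs[:, 1],
        "organ": phantom.fascicles.organ.to_numpy(),
        "animal": animal, "level": level,
    })
    outline = EllipseOutline(cx=0.0, cy=0.0, a=R * 1e6 * s, b=R * 1e6 / s,
                             phi_deg=0.0)
    return FascicleTable(table=df, outline=outline,
                         cuff_opening_deg=opening_deg,
                         nerve_radius_um=R * 1e6)
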