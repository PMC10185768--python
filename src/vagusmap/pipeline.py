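"""End-to-end orchestration: simulate -> process -> reconstruct -> localize
-> co-register, for one animal or a cohort, reproducibly from one seed.

The default configuration is the synthetic analog of the in vivo study
conditions: four animals, three organs (laryngeal / pulmonary / cardiac),
three localization techniques (fast-neural EIT, selective stimulation,
microCT at two cuff levels).  Recording durations are desk-scale (seconds
rather than minutes); every random draw descends from the single run seed.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coregister as cg
from . import forward as fw
from . import phantom as ph
from . import reconstruct as rc
from . import selstim as ss
from . import sigproc as sp
from .geometry import NerveGeometry, electrode_angles_deg


@dataclass
class RunConfig:
    """Tunable study conditions for a synthetic cohort run."""

    seed: int = 7
    n_animals: int = 4
    target_elements: int = 5000
    voxel_size: float = 150e-6
    # recordings
    evoked_duration: float = 8.0
    cardiac_duration: float = 12.0
    pulmonary_duration: float = 24.0
    heart_rate: float = 120.0
    breath_rate: float = 13.0
    noise_evoked: float = 15e-6          # raw-channel white noise RMS, V
    noise_spont: float = 1e-7
    corrupt_fraction: float = 0.05       # bad-contact channels per recording
    edge_guard: float = 1.5              # s of recording edge excluded
    # processing
    evoked_halfwidth: float = 1000.0
    spont_halfwidth: float = 2000.0
    rms_window_cardiac: float = 0.1
    rms_window_pulmonary: float = 2.0
    evoked_thresholds: tuple[float, float, float] = (1.0, 2.0, 4.0)
    carrier_min_uv: float = 300.0        # minimum usable carrier amplitude
    # search window for the evoked response peak, s after the stimulus
    # (conduction latency 10 ms = 0.4 m at 40 m/s, +- dispersion)
    evoked_peak_window: tuple[float, float] = (0.007, 0.016)
    # reconstruction
    eps_evoked: float = 1e-6
    eps_spont: float = 10e-9
    top_k: int = 16
    # dV-RMS measurements are magnitudes; invert them with |J| by default
    rectified_inversion: bool = True
    # regularization strength relative to the spectral base rule
    # lambda = eps * s1 / s_mean.  The default puts lambda above the top
    # singular value: the image becomes noise-normalized sensitivity
    # backprojection, the robust regime for top-k center-of-mass
    # localization at the SNR of coherently averaged recordings
    lambda_scale: float = 20000.0
    # selective stimulation
    ss_spread_deg: float = 26.0
    # microCT
    microct_jitter_um: float = 30.0
    # per-animal cuff-orientation scatter (deg) and group-angle jitter (deg)
    animal_rotation_range: float = 60.0
    group_angle_jitter: float = 10.0

    def validate(self) -> None:
        errors = []
        if self.n_animals < 1:
            errors.append("n_animals must be >= 1")
        for name in ("evoked_duration", "cardiac_duration", "pulmonary_duration",
                     "heart_rate", "breath_rate", "eps_evoked", "eps_spont"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        if not 0 <= self.corrupt_fraction < 1:
            errors.append("corrupt_fraction must be in [0, 1)")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in data.items()})
        cfg.validate()
        return cfg


@dataclass
class ForwardBundle:
    """Mesh, baseline voltages and voxelized Jacobian for one geometry."""

    mesh: fw.Mesh
    sigma: np.ndarray
    baseline_voltages: np.ndarray
    jacobian: fw.JacobianMatrix


def build_forward(geometry: NerveGeometry | None = None,
                  target_elements: int = 5000,
                  voxel_size: float = 150e-6) -> ForwardBundle:
    geometry = geometry or NerveGeometry()
    mesh = fw.build_mesh(geometry, target_elements=target_elements)
    sigma = mesh.base_conductivity(geometry)
    V0, _ = fw.protocol_voltages(mesh, sigma)
    J = fw.voxelize_jacobian(fw.assemble_jacobian(mesh, sigma), mesh,
                             voxel_size=voxel_size)
    return ForwardBundle(mesh=mesh, sigma=sigma, baseline_voltages=V0,
                         jacobian=J)


def demodulate_recording(recording, halfwidth: float,
                         edge_trim: float = 0.5) -> tuple[np.ndarray, float]:
    """Demodulate all 196 traces of a recording into a (196, n) uV matrix.

    ``edge_trim`` seconds are cut from both record ends between filtering
    and envelope extraction: the band-pass edge transients otherwise leak
    through the analytic-signal transform as an envelope ripple proportional
    to each trace's carrier amplitude, swamping nanovolt dV-RMS signals.
    Returns (matrix, time offset of sample 0 relative to the recording).
    """
    fs = recording.sampling_rate
    ntrim = int(round(edge_trim * fs))
    out = []
    for k in range(len(recording.injection_pairs)):
        traces = recording.pair_traces(k)
        filt = sp.bandpass_carrier(traces, fs, halfwidth=halfwidth)
        if ntrim:
            filt = filt[..., ntrim:-ntrim]
        out.append(sp.demodulate(filt, fs).values)
    return np.vstack(out), ntrim / fs


def _guarded_triggers(triggers: sp.TriggerSeries, before: float, after: float,
                      duration: float, guard: float) -> sp.TriggerSeries:
    t = triggers.times
    keep = (t > before + guard) & (t < duration - after - guard)
    if not keep.any():
        raise sp.ProcessingError("no triggers inside the guarded recording span")
    return sp.TriggerSeries(times=t[keep], source=triggers.source)


@dataclass
class BranchResult:
    """Processed EIT outcome for one organ branch of one animal."""

    organ: str
    epochs: np.ndarray            # (196, T) baseline-subtracted averages, uV
    epoch_times: np.ndarray
    kept: np.ndarray
    exclusion: sp.ExclusionReport
    n_epochs: int
    image: rc.EITImage
    com: rc.CoMRecord
    peak_time: float
    snr: float


def _reconstruct_branch(J: fw.JacobianMatrix, X: np.ndarray, taxis: np.ndarray,
                        kept: np.ndarray, eps: float, top_k: int, organ: str,
                        peak_window: tuple[float, float],
                        time_decimation: int = 50,
                        signs: np.ndarray | None = None,
                        rectify: bool = False,
                        lambda_scale: float = 1.0
                        ) -> tuple[rc.EITImage, rc.CoMRecord, float]:
    """Invert the averaged traces and localize the activity peak.

    ``signs`` restores the sign the envelope demodulation strips: the
    Hilbert envelope measures |V0 + dV|, so the baseline-subtracted dV of a
    trace carries the sign of its baseline transfer voltage (evoked path).
    ``rectify`` inverts with the element-wise |J| instead of J: a dV-RMS
    measurement is the magnitude of the trace's fast content, |J . p| per
    row for a compact source, which |J| maps linearly while the signed J
    does not.
    """
    X = X if signs is None else X * np.sign(signs)[:, None]
    if rectify:
        J = fw.JacobianMatrix(matrix=np.abs(J.matrix), index=J.index,
                              grid=J.grid)
    inv = rc.TikhonovInverter(
        J, kept=kept, config=rc.ReconstructionConfig(
            noise_amplitude=eps, top_k=top_k, lambda_scale=lambda_scale))
    dec = slice(0, X.shape[1], time_decimation)
    zseq = inv.z_score(inv.invert(X[kept][:, dec].astype(float) * 1e-6))
    t_peak = rc.find_peak_time(zseq, taxis[dec], window=peak_window)
    ipk = int(np.argmin(np.abs(taxis - t_peak)))
    z = inv.z_score(inv.invert(X[kept][:, ipk] * 1e-6))
    image = rc.EITImage(z=z, grid=J.grid.centers, peak_time=t_peak,
                        branch=organ)
    com = rc.com_top_voxels(image, k=top_k)
    return image, com, t_peak


def _branch_snr(X: np.ndarray, kept: np.ndarray, taxis: np.ndarray,
                t_peak: float, baseline: tuple[int, int],
                half: float = 0.01) -> float:
    """Branch SNR: best kept trace's peak-to-baseline-noise ratio."""
    ipk = int(np.argmin(np.abs(taxis - t_peak)))
    dt = taxis[1] - taxis[0]
    h = max(1, int(round(half / dt)))
    pw = (max(0, ipk - h), min(len(taxis), ipk + h))
    snrs = []
    for x in X[kept]:
        try:
            snrs.append(sp.compute_snr(x, pw, baseline).snr)
        except (sp.ProcessingError, ValueError):
            continue
    return float(np.max(snrs)) if snrs else float("nan")


def _default_corruption(rng: np.random.Generator, fraction: float,
                        mode: str) -> dict[tuple[int, int], tuple[str, float]]:
    """Bad-contact / artifact channels for one recording."""
    n_bad = rng.binomial(196, fraction)
    chans = rng.choice(196, size=n_bad, replace=False)
    plan: dict[tuple[int, int], tuple[str, float]] = {}
    for i, c in enumerate(chans):
        k, e = divmod(int(c), 14)
        if mode == "evoked":
            plan[(k, e)] = ("noise", 120e-6)
        else:
            kind = ("amplitude", "derivative", "drift")[i % 3]
            value = {"amplitude": 5e-6, "derivative": 200e-6,
                     "drift": 3e-6}[kind]
            plan[(k, e)] = (kind, value)
    return plan


def run_evoked_branch(config: RunConfig, bundle: ForwardBundle,
                      phantom: ph.Phantom, seed: int) -> BranchResult:
    """Evoked laryngeal EIT: stimulate at 20 Hz, average dV on stimulus
    triggers, exclude outliers, reconstruct at the response peak."""
    rng = np.random.default_rng(seed)
    dur = config.evoked_duration
    protocol = ph.StimProtocol.for_organ("laryngeal")
    traffic = ph.simulate_neural_traffic(
        phantom, "evoked", dur, stim_protocol=protocol,
        seed=int(rng.integers(2**31)))
    rec = ph.synthesize_recording(
        phantom, bundle.jacobian, bundle.baseline_voltages, traffic,
        noise_rms=config.noise_evoked, seed=int(rng.integers(2**31)))
    rec = ph.corrupt_traces(rec, _default_corruption(
        rng, config.corrupt_fraction, "evoked"))
    before, after = 0.005, 0.030
    triggers = _guarded_triggers(
        sp.TriggerSeries(times=traffic.trigger_times, source="stimulus"),
        before, after, dur, 0.7)
    fs = rec.sampling_rate
    ntrim = int(round(0.5 * fs))
    rows = []
    n_ep = 0
    for k in range(len(rec.injection_pairs)):
        traces = rec.pair_traces(k)
        filt = sp.bandpass_carrier(traces, fs,
                                   halfwidth=config.evoked_halfwidth)
        env = sp.demodulate(filt[..., ntrim:-ntrim], fs).values
        for trace in env:
            avg, taxis, n_ep = sp.coherent_average(
                trace, 1.0 / fs, sp.TriggerSeries(
                    times=triggers.times - ntrim / fs, source=triggers.source),
                before, after)
            rows.append(avg)
    X = np.asarray(rows)
    baseline = (0, int(0.004 * rec.sampling_rate))   # pre-stimulus span
    nt, mt, xt = config.evoked_thresholds
    carrier = X[:, baseline[0]:baseline[1]].mean(axis=1)
    report = sp.exclude_evoked(X, baseline, noise_thresh=nt, mean_thresh=mt,
                               max_thresh=xt, carrier_amplitudes=carrier,
                               carrier_min=config.carrier_min_uv)
    X = np.asarray([sp.baseline_subtract(x, baseline) for x in X])
    # smooth over ~0.6 ms before inversion: the compound response is ~1 ms
    # wide, while instantaneous samples carry the full post-averaging noise
    from scipy.ndimage import uniform_filter1d
    Xs = uniform_filter1d(X, size=max(1, int(6e-4 * rec.sampling_rate)),
                          axis=1, mode="nearest")
    image, com, t_peak = _reconstruct_branch(
        bundle.jacobian, Xs, taxis, report.kept, config.eps_evoked,
        config.top_k, "laryngeal", peak_window=config.evoked_peak_window,
        time_decimation=5, signs=bundle.baseline_voltages,
        lambda_scale=config.lambda_scale)
    snr = _branch_snr(X, report.kept, taxis, t_peak, baseline, half=0.002)
    return BranchResult(organ="laryngeal", epochs=X, epoch_times=taxis,
                        kept=report.kept, exclusion=report, n_epochs=n_ep,
                        image=image, com=com, peak_time=t_peak, snr=snr)


def run_spontaneous_branch(config: RunConfig, bundle: ForwardBundle,
                           phantom: ph.Phantom, organ: str,
                           seed: int) -> BranchResult:
    """Spontaneous cardiac- or pulmonary-gated EIT via the dV-RMS chain."""
    rng = np.random.default_rng(seed)
    if organ == "cardiac":
        dur, window = config.cardiac_duration, config.rms_window_cardiac
        mode, source = "cardiac_gated", "bp_peak"
        before, after = 0.1, 0.35
        peak_window = (0.05, 0.30)
    elif organ == "pulmonary":
        dur, window = config.pulmonary_duration, config.rms_window_pulmonary
        mode, source = "pulmonary_gated", "etco2_midpoint"
        before, after = 1.8, 2.0
        peak_window = (-1.0, 1.0)
    else:
        raise ValueError(f"no spontaneous mode for organ {organ!r}")
    physio = ph.simulate_physio(dur, heart_rate=config.heart_rate,
                                breath_rate=config.breath_rate,
                                seed=int(rng.integers(2**31)))
    traffic = ph.simulate_neural_traffic(phantom, mode, dur, physio=physio,
                                         seed=int(rng.integers(2**31)))
    rec = ph.synthesize_recording(
        phantom, bundle.jacobian, bundle.baseline_voltages, traffic,
        noise_rms=config.noise_spont, seed=int(rng.integers(2**31)),
        physio=physio)
    rec = ph.corrupt_traces(rec, _default_corruption(
        rng, 0.5 * config.corrupt_fraction, mode))
    triggers = _guarded_triggers(sp.detect_triggers(physio, source),
                                 before, after, dur, config.edge_guard)
    fs = rec.sampling_rate
    ntrim = int(round(0.5 * fs))
    offset = ntrim / fs
    triggers = sp.TriggerSeries(times=triggers.times - offset,
                                source=triggers.source)
    rows = []
    continuous = []            # decimated continuous dV-RMS for QC
    carriers = []              # per-trace mean envelope (carrier level), uV
    qc_dec = 20
    qc_guard = max(config.edge_guard - offset, 0.5)
    n_ep = 0
    for k in range(len(rec.injection_pairs)):
        traces = rec.pair_traces(k)
        filt = sp.bandpass_carrier(traces, fs,
                                   halfwidth=config.spont_halfwidth)
        env = sp.demodulate(filt[..., ntrim:-ntrim], fs).values
        guard = slice(int(qc_guard * fs), env.shape[1] - int(qc_guard * fs))
        for trace in env:
            carriers.append(trace[guard].mean())
            rms = sp.rms_convert(sp.DemodTrace(values=trace, dt=1.0 / fs),
                                 window=window)
            continuous.append(rms.values[guard][::qc_dec])
            avg, taxis, n_ep = sp.coherent_average(rms.values, rms.dt,
                                                   triggers, before, after)
            rows.append(avg)
    X = np.asarray(rows)
    # exclusion operates on the continuous (pre-averaging) dV-RMS traces:
    # stationary artifacts are averaged flat and would otherwise pass.
    # Low-carrier channels are retained here: the dV-RMS measurement is a
    # magnitude and needs no carrier sign, so those channels still measure
    # |J . p| validly.
    report = sp.exclude_spontaneous(np.asarray(continuous), qc_dec / fs)
    baseline = sp.default_baseline_window(X.mean(axis=0), 1.0 / fs)
    Xb = np.asarray([sp.baseline_subtract(x, baseline) for x in X])
    image, com, t_peak = _reconstruct_branch(
        bundle.jacobian, Xb, taxis, report.kept, config.eps_spont,
        config.top_k, organ, peak_window=peak_window,
        rectify=config.rectified_inversion, lambda_scale=config.lambda_scale)
    snr = _branch_snr(Xb, report.kept, taxis, t_peak, baseline,
                      half=5 * window / 10.0)
    return BranchResult(organ=organ, epochs=Xb, epoch_times=taxis,
                        kept=report.kept, exclusion=report, n_epochs=n_ep,
                        image=image, com=com, peak_time=t_peak, snr=snr)


@dataclass
class AnimalResult:
    animal: str
    phantom: ph.Phantom
    branches: dict[str, BranchResult]
    ss_table: pd.DataFrame
    ss_selections: dict[str, ss.PairSelection]
    coms: list[rc.CoMRecord]
    microct: dict[str, cg.FascicleTable]       # per level, circular frame
    timings: dict[str, float] = field(default_factory=dict)


def _animal_phantom(config: RunConfig, rng: np.random.Generator,
                    idx: int) -> tuple[ph.Phantom, float]:
    """Per-animal phantom: jittered group layout under a random cuff
    orientation (the quantity clusterization must undo)."""
    rotation = float(rng.uniform(-config.animal_rotation_range,
                                 config.animal_rotation_range))
    groups = []
    for g in ph.default_groups():
        n = g.n_fascicles
        if g.organ == "cardiac":
            n = int(rng.integers(1, 3))          # 1-2 cardiac fascicles
        else:
            n = max(3, int(rng.poisson(g.n_fascicles)))
        groups.append(dataclasses.replace(
            g,
            center_angle=(g.center_angle + rotation
                          + rng.normal(0, config.group_angle_jitter)) % 360.0,
            n_fascicles=n))
    phantom = ph.make_phantom(NerveGeometry(), groups,
                              seed=int(rng.integers(2**31)))
    return phantom, rotation


def run_animal(config: RunConfig, bundle: ForwardBundle, idx: int) -> AnimalResult:
    """All three techniques for one synthetic animal."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, idx]))
    animal = f"animal{idx}"
    phantom, _ = _animal_phantom(config, rng, idx)
    R_um = phantom.geometry.nerve_radius * 1e6
    timings: dict[str, float] = {}
    branches: dict[str, BranchResult] = {}
    coms: list[rc.CoMRecord] = []

    def _slim(br: BranchResult) -> BranchResult:
        # cohort runs keep only a decimated preview of the averaged traces;
        # the full-resolution epochs have served reconstruction already
        br.epochs = np.ascontiguousarray(br.epochs[:, ::20], dtype=np.float32)
        br.epoch_times = br.epoch_times[::20].copy()
        return br

    t0 = time.time()
    branches["laryngeal"] = _slim(run_evoked_branch(
        config, bundle, phantom, int(rng.integers(2**31))))
    timings["eit_laryngeal"] = time.time() - t0
    for organ in ("cardiac", "pulmonary"):
        t0 = time.time()
        branches[organ] = _slim(run_spontaneous_branch(
            config, bundle, phantom, organ, int(rng.integers(2**31))))
        timings[f"eit_{organ}"] = time.time() - t0
    for organ, br in branches.items():
        com = br.com
        coms.append(rc.CoMRecord(x_um=com.x_um, y_um=com.y_um, organ=organ,
                                 technique="eit", animal=animal))

    # selective stimulation
    t0 = time.time()
    angles = electrode_angles_deg()
    table = ph.simulate_ss_responses(phantom, angles,
                                     spread_deg=config.ss_spread_deg,
                                     seed=int(rng.integers(2**31)))
    selections = {}
    for organ in ("laryngeal", "pulmonary", "cardiac"):
        sub = table[table.organ == organ]
        sel = ss.select_pairs(sub)
        selections[organ] = sel
        coms.append(ss.ss_com(sel, angles, R_um, organ=organ, animal=animal))
    timings["ss"] = time.time() - t0

    # microCT at the two cuff levels, deformed then co-registered back
    t0 = time.time()
    microct = {}
    for level in ("cranial_cuff", "caudal_cuff"):
        tab = ph.simulate_microct_fascicles(
            phantom,
            ellipse_ratio=float(rng.uniform(1.1, 1.35)),
            rotation_deg=float(rng.uniform(0, 360)),
            jitter_um=config.microct_jitter_um,
            seed=int(rng.integers(2**31)),
            animal=animal, level=level)
        circ, _ = cg.ellipse_to_circle(tab)
        microct[level] = circ
        for organ in ("laryngeal", "pulmonary", "cardiac"):
            com = cg.microct_com(circ, organ, animal=animal, level=level)
            coms.append(com)
    timings["microct"] = time.time() - t0

    return AnimalResult(animal=animal, phantom=phantom, branches=branches,
                        ss_table=table, ss_selections=selections, coms=coms,
                        microct=microct, timings=timings)


@dataclass
class CohortResult:
    config: RunConfig
    animals: list[AnimalResult]
    com_table: pd.DataFrame
    errors: pd.DataFrame                  # EIT vs microCT per organ/animal
    separations: pd.DataFrame
    clusterizations: dict[str, cg.ClusterizationResult]
    dispersions: dict[str, float]
    ttests: pd.DataFrame
    summary: dict


def com_records_to_table(coms: list[rc.CoMRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(animal=c.animal, organ=c.organ, technique=c.technique,
             level=c.level, x_um=c.x_um, y_um=c.y_um,
             r_um=c.radius_um, theta_deg=c.angle_deg)
        for c in coms
    ])


#: clusterization/separation groupings: technique name -> (technique, level)
TECHNIQUE_KEYS = {
    "eit": ("eit", ""),
    "ss": ("ss", ""),
    "microct_cranial": ("microct", "cranial_cuff"),
    "microct_caudal": ("microct", "caudal_cuff"),
}


def run_cohort(config: RunConfig | None = None,
               bundle: ForwardBundle | None = None) -> CohortResult:
    """Run the full synthetic study: N animals, three organs, three
    techniques, then co-registration statistics across animals."""
    config = config or RunConfig()
    config.validate()
    bundle = bundle or build_forward(target_elements=config.target_elements,
                                     voxel_size=config.voxel_size)
    animals = [run_animal(config, bundle, i) for i in range(config.n_animals)]
    all_coms = [c for a in animals for c in a.coms]
    com_table = com_records_to_table(all_coms)

    # EIT localization error vs microCT at the EIT-cuff (caudal) level
    err_rows = []
    for a in animals:
        for organ in ("laryngeal", "pulmonary", "cardiac"):
            eit = next(c for c in a.coms
                       if c.organ == organ and c.technique == "eit")
            mct = next(c for c in a.coms if c.organ == organ
                       and c.technique == "microct" and c.level == "caudal_cuff")
            e = cg.com_error(eit, mct)
            err_rows.append(dict(animal=a.animal, organ=organ,
                                 cartesian_um=e.cartesian_um,
                                 radial_um=e.radial_um,
                                 angular_deg=e.angular_deg))
    errors = pd.DataFrame(err_rows)

    # angular separations from laryngeal, per technique and animal
    sep_rows = []
    for a in animals:
        for name, (tech, level) in TECHNIQUE_KEYS.items():
            coms = {c.organ: c for c in a.coms
                    if c.technique == tech and c.level == level}
            if len(coms) < 3:
                continue
            seps = cg.angular_separation(coms)
            for organ, val in seps.items():
                sep_rows.append(dict(animal=a.animal, technique=name,
                                     organ=organ, separation_deg=val))
    separations = pd.DataFrame(sep_rows)

    # clusterization per technique
    clusterizations = {}
    dispersions = {}
    for name, (tech, level) in TECHNIQUE_KEYS.items():
        sets = {}
        for a in animals:
            coms = {c.organ: c for c in a.coms
                    if c.technique == tech and c.level == level}
            if len(coms) == 3:
                sets[a.animal] = coms
        if len(sets) >= 2:
            result = cg.clusterize(sets)
            clusterizations[name] = result
            dispersions[name] = result.mean_dispersion_um

    # discrimination power: t-tests of separations against zero mean
    t_rows = []
    for (name, organ), sub in separations.groupby(["technique", "organ"]):
        vals = sub.separation_deg.to_numpy()
        if vals.size >= 2 and not np.allclose(vals, vals[0]):
            t, p = cg.one_sample_ttest(vals)
            t_rows.append(dict(technique=name, organ=organ, n=vals.size,
                               mean_deg=vals.mean(), sd_deg=vals.std(ddof=1),
                               t=t, p=p))
    ttests = pd.DataFrame(t_rows)

    summary = summarize(config, animals, errors, separations, dispersions,
                        clusterizations)
    return CohortResult(config=config, animals=animals, com_table=com_table,
                        errors=errors, separations=separations,
                        clusterizations=clusterizations,
                        dispersions=dispersions, ttests=ttests,
                        summary=summary)


def cluster_disjointness(result: cg.ClusterizationResult) -> float:
    """Smallest inter-centroid distance divided by the largest intra-cluster
    dispersion; > 1 means all organ clusters are disjoint."""
    organs = list(result.centroids_um)
    inter = np.inf
    for i, a in enumerate(organs):
        for b in organs[i + 1:]:
            inter = min(inter, float(np.hypot(
                *(result.centroids_um[a] - result.centroids_um[b]))))
    disp = dispersion(result)
    intra = max(disp.values())
    return inter / max(intra, 1e-9)


def dispersion(result: cg.ClusterizationResult) -> dict[str, float]:
    return cg.dispersion(result)


def summarize(config: RunConfig, animals: list[AnimalResult],
              errors: pd.DataFrame, separations: pd.DataFrame,
              dispersions: dict[str, float],
              clusterizations: dict[str, cg.ClusterizationResult]) -> dict:
    """Headline quantities of one cohort run (plain JSON-ready floats)."""
    out: dict = {"n_animals": len(animals)}
    for organ in ("laryngeal", "pulmonary", "cardiac"):
        snrs = [a.branches[organ].snr for a in animals]
        kept = [a.branches[organ].exclusion.kept_fraction for a in animals]
        out[f"snr_{organ}"] = float(np.mean(snrs))
        out[f"kept_fraction_pct_{organ}"] = float(100 * np.mean(kept))
    out["com_error_cartesian_um"] = float(errors.cartesian_um.mean())
    out["com_error_radial_um"] = float(errors.radial_um.mean())
    out["com_error_angular_deg"] = float(errors.angular_deg.mean())
    for (name, organ), sub in separations.groupby(["technique", "organ"]):
        out[f"separation_{organ}_{name}_deg"] = float(sub.separation_deg.mean())
    for name, d in dispersions.items():
        out[f"dispersion_{name}_um"] = float(d)
    for name, res in clusterizations.items():
        out[f"cluster_disjointness_{name}"] = cluster_disjointness(res)
        if "laryngeal" in res.centroids_um:
            c = res.centroids_um["laryngeal"]
            out[f"laryngeal_centroid_angle_{name}_deg"] = float(
                np.degrees(np.arctan2(c[1], c[0])) % 360.0)
    # selective-stimulation peak effects (best pair per organ, averaged)
    for organ, key in (("cardiac", "hr_drop_pct"),
                       ("pulmonary", "breath_change_pct"),
                       ("laryngeal", "emg_rms_ratio")):
        vals = []
        for a in animals:
            sub = a.ss_table[a.ss_table.organ == organ]
            best = sub.loc[sub.response.abs().idxmax()]
            vals.append(best.value if key == "emg_rms_ratio" else best.response)
        out[f"ss_{key}"] = float(np.mean(vals))
    return out


def write_outputs(result: CohortResult, outdir: str | Path) -> Path:
    """Write the cohort tables, summary JSON and manifest to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": result.config.seed,
        "config": dataclasses.asdict(result.config),
        "complete": False,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    result.com_table.to_csv(outdir / "com_table.csv", index=False)
    result.errors.to_csv(outdir / "com_errors.csv", index=False)
    result.separations.to_csv(outdir / "separations.csv", index=False)
    result.ttests.to_csv(outdir / "ttests.csv", index=False)
    (outdir / "summary.json").write_text(json.dumps(result.summary, indent=2))
    rows = []
    for a in result.animals:
        a.ss_table.assign(animal=a.animal).to_csv(
            outdir / f"ss_table_{a.animal}.csv", index=False)
        for organ, br in a.branches.items():
            rows.append(dict(animal=a.animal, organ=organ, snr=br.snr,
                             kept_fraction=br.exclusion.kept_fraction,
                             n_epochs=br.n_epochs, peak_time_s=br.peak_time))
    pd.DataFrame(rows).to_csv(outdir / "branch_summary.csv", index=False)

    # figures: clustered CoM panels and first-animal EIT images
    from . import viz
    clustered = []
    for name, res in result.clusterizations.items():
        for a, organs in res.rotated.items():
            for organ, c in organs.items():
                clustered.append(dict(animal=a, organ=organ, technique=name,
                                      x_um=c.x_um, y_um=c.y_um))
    if clustered:
        R_um = result.animals[0].phantom.geometry.nerve_radius * 1e6
        viz.plot_com_panels(pd.DataFrame(clustered), R_um,
                            outdir / "com_panels.png")
    first = result.animals[0]
    for organ, br in first.branches.items():
        viz.plot_eit_image(br.image, first.phantom.geometry.nerve_radius,
                           outdir / f"eit_{organ}_{first.animal}.png",
                           com=br.com)

    manifest["complete"] = True
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
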