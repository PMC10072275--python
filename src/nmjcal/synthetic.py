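"""Ground-truth generator for NMJ Ca²⁺ imaging data.

Produces single-ROI traces, drifting multi-bouton movies, and static
two-channel (ER marker + plasma-membrane reference) images whose every
stochastic ingredient is recorded in a :class:`SimTruth`, so each analysis
stage can be validated against a known answer.

The forward model of a trace is

    F(i) = a * (i + 1)**b * [1 + g * r(t_i) + sum_k m_k(t_i)] + eps_i

where ``a * x**b`` is the power-law photobleach of the baseline, ``r`` the
compartment-specific evoked kernel, ``g`` the genotype scale on evoked
amplitudes (1.0 for wild type; mutant presets use 0.5, i.e. responses
reduced to about half), ``m_k`` spontaneous miniature events from a
homogeneous Poisson process, and ``eps`` Gaussian read noise with optional
Poisson shot noise.

Compartment kinetics emulated:

* ``cytosol`` / ``postsynaptic`` — fast saturating rise during the train to
  the peak, then exponential decay (GCaMP-like).
* ``er`` — an immediate lumenal dip (store release) decaying with its own
  time constant, plus a slow positive uptake component that starts when the
  train ends and peaks after it (store refilling overshoot).
* ``mito`` — fast rise during the train, rapid partial decline to a plateau
  fraction of the peak, then a slow (tens of seconds) return to baseline.
"""

from __future__ import annotations


from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .datatypes import COMPARTMENTS, Movie, Roi, StimWindow, Trace

# -- configuration dataclasses ------------------------------------------------


@dataclass(frozen=True)
class KernelParams:
    """Shape parameters of the evoked-response kernel (seconds, ΔF/F units)."""

    rise_tau_s: float = 0.2
    decay_tau_s: float = 0.5
    peak_dff: float = 1.5
    dip_amp_dff: float = 0.0     # ER only: lumenal release dip amplitude
    dip_tau_s: float = 2.0       # ER only: dip recovery time constant
    plateau_fraction: float = 0.4  # mito only: post-decline plateau / peak
    slow_tau_s: float = 30.0     # mito slow return; reused as ER slow-uptake tau

    def validate(self) -> None:
        for name in ("rise_tau_s", "decay_tau_s", "dip_tau_s", "slow_tau_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.peak_dff < 0 or self.dip_amp_dff < 0:
            raise ValueError("kernel amplitudes must be >= 0")
        if not 0.0 <= self.plateau_fraction <= 1.0:
            raise ValueError("plateau_fraction must lie in [0, 1]")


#: Default kernels per compartment; amplitudes are ΔF/F for a wild-type
#: response to a strong (40-80 Hz) train.
DEFAULT_KERNELS = {
    # rise comparable to the train duration: a slow indicator integrates
    # Ca2+ over the whole train, peaking at its end
    "cytosol": KernelParams(rise_tau_s=2.0, decay_tau_s=1.0, peak_dff=1.5),
    "postsynaptic": KernelParams(rise_tau_s=0.15, decay_tau_s=0.4, peak_dff=0.5),
    "er": KernelParams(rise_tau_s=0.5, decay_tau_s=2.0, peak_dff=0.2,
                       dip_amp_dff=0.15, dip_tau_s=2.0, slow_tau_s=10.0),
    "mito": KernelParams(rise_tau_s=0.5, decay_tau_s=1.0, peak_dff=2.0,
                         plateau_fraction=0.4, slow_tau_s=30.0),
}

#: Acquisition rates used for each compartment (frames per second).
DEFAULT_FRAME_RATES = {"cytosol": 50.0, "postsynaptic": 50.0, "er": 10.0, "mito": 10.0}


@dataclass(frozen=True)
class BleachParams:
    a: float = 1000.0
    b: float = -0.05


@dataclass(frozen=True)
class NoiseParams:
    gaussian_sd: float = 0.0
    shot_noise: bool = False


@dataclass(frozen=True)
class MiniParams:
    rate_hz: float = 0.0
    amp_mean: float = 0.3
    amp_sd: float = 0.1
    decay_tau_s: float = 0.2


@dataclass(frozen=True)
class Geometry:
    n_boutons: int = 3
    bouton_radius_px: float = 5.0
    image_shape: tuple = (64, 64)
    drift_px_per_frame: tuple = (0.0, 0.0)
    background: float = 0.0
    bouton_peak_scales: Optional[tuple] = None  # per-bouton evoked-amplitude scale


@dataclass(frozen=True)
class StaticParams:
    """Parameters of the static marker/reference image pair."""

    n_puncta: int = 4
    puncta_radius_px: float = 3.0
    puncta_amp: float = 200.0    # marker intensity inside a punctum
    tubule_level: float = 10.0   # dim marker intensity on the ER tubule network
    ref_level: float = 80.0      # uniform reference (PM marker) level in the NMJ


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated recording."""

    compartment: str = "cytosol"
    genotype_scale: float = 1.0      # 1.0 = WT; mutant presets use 0.5
    frame_rate_hz: Optional[float] = None
    duration_s: float = 20.0
    stim: Optional[StimWindow] = StimWindow(5.0, 2.0, 40.0)
    bleach: BleachParams = BleachParams()
    noise: NoiseParams = NoiseParams()
    mini: MiniParams = MiniParams()
    geometry: Geometry = Geometry()
    static: StaticParams = StaticParams()
    kernel: Optional[KernelParams] = None
    seed: int = 0

    def resolved(self) -> "SimConfig":
        """Fill compartment-dependent defaults (frame rate, kernel)."""
        out = self
        if out.frame_rate_hz is None:
            out = replace(out, frame_rate_hz=DEFAULT_FRAME_RATES[self.compartment])
        if out.kernel is None:
            out = replace(out, kernel=DEFAULT_KERNELS[self.compartment])
        return out

    def validate(self) -> "SimConfig":
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r}; "
                f"expected one of {COMPARTMENTS}")
        cfg = self.resolved()
        if cfg.frame_rate_hz <= 0 or cfg.duration_s <= 0:
            raise ValueError("frame_rate_hz and duration_s must be > 0")
        if cfg.stim is not None:
            cfg.stim.validate(cfg.duration_s)
        if cfg.bleach.a <= 0:
            raise ValueError("bleach amplitude a must be > 0")
        if cfg.mini.rate_hz < 0:
            raise ValueError("mini rate must be >= 0")
        if not np.isfinite([cfg.mini.amp_mean, cfg.mini.amp_sd, cfg.genotype_scale]).all():
            raise ValueError("amplitudes must be finite")
        if cfg.geometry.n_boutons < 1:
            raise ValueError("n_boutons must be >= 1")
        cfg.kernel.validate()
        return cfg


@dataclass
class SimTruth:
    """Everything that was drawn or derived while simulating one recording."""

    kernel: KernelParams
    true_peak_dff: float
    mini_times_s: list = field(default_factory=list)
    mini_amps: list = field(default_factory=list)
    bleach_a: float = 1000.0
    bleach_b: float = -0.05
    shifts_px: list = field(default_factory=list)        # per-frame (dy, dx)
    bouton_centers_px: list = field(default_factory=list)
    clean_dff: Optional[np.ndarray] = None               # g*r(t) without minis/noise
    bouton_truths: list = field(default_factory=list)    # per-bouton SimTruth (movies)
    puncta_mask: Optional[np.ndarray] = None             # static pair ground truth

    def __post_init__(self) -> None:
        t = np.asarray(self.mini_times_s, dtype=float)
        if t.size and not np.all(np.diff(t) >= 0):
            raise ValueError("mini_times_s must be sorted ascending")


# -- evoked kernels -----------------------------------------------------------


def evoked_kernel(compartment: str, stim: StimWindow, params: KernelParams,
                  frame_rate_hz: float, duration_s: float) -> np.ndarray:
    """Dimensionless evoked response r(t) sampled at the frame rate.

    r(t) = 0 before stimulation onset; the shape after onset depends on the
    compartment (see module docstring). A zero-frequency train produces no
    response.
    """
    params.validate()
    n = int(round(duration_s * frame_rate_hz))
    t = np.arange(n) / frame_rate_hz
    return evoked_kernel_at(compartment, stim, params, t)


def evoked_kernel_at(compartment: str, stim: StimWindow, params: KernelParams,
                     t: np.ndarray) -> np.ndarray:
    """Closed-form kernel evaluated at arbitrary times ``t`` (seconds)."""
    if compartment not in COMPARTMENTS:
        raise ValueError(
            f"unknown compartment {compartment!r}; expected one of {COMPARTMENTS}")
    t = np.asarray(t, dtype=float)
    r = np.zeros_like(t)
    if stim is None or stim.frequency_hz <= 0:
        return r
    t0, te = stim.onset_s, stim.end_s
    dur = stim.duration_s
    during = (t >= t0) & (t < te)
    after = t >= te
    dt_on = t - t0
    dt_off = t - te

    if compartment in ("cytosol", "postsynaptic"):
        # saturating rise to peak_dff at train end, then exponential decay
        norm = 1.0 - np.exp(-dur / params.rise_tau_s)
        if norm > 0 and params.peak_dff > 0:
            r[during] = params.peak_dff * (
                1.0 - np.exp(-dt_on[during] / params.rise_tau_s)) / norm
            r[after] = params.peak_dff * np.exp(-dt_off[after] / params.decay_tau_s)
    elif compartment == "er":
        # immediate lumenal dip at onset + delayed slow uptake (alpha shape,
        # starts at train end so the two components do not overlap at onset)
        post = t >= t0
        r[post] -= params.dip_amp_dff * np.exp(-dt_on[post] / params.dip_tau_s)
        x = dt_off[after] / params.slow_tau_s
        r[after] += params.peak_dff * x * np.exp(1.0 - x)
    elif compartment == "mito":
        # fast rise; rapid partial decline to plateau_fraction * peak;
        # slow (>40 s including the fast phase) return to baseline
        norm = 1.0 - np.exp(-dur / params.rise_tau_s)
        if norm > 0 and params.peak_dff > 0:
            r[during] = params.peak_dff * (
                1.0 - np.exp(-dt_on[during] / params.rise_tau_s)) / norm
            c = params.plateau_fraction
            r[after] = params.peak_dff * (
                (1.0 - c) * np.exp(-dt_off[after] / params.decay_tau_s)
                + c * np.exp(-dt_off[after] / params.slow_tau_s))
    return r


def saturating_peak(base_peak_dff: float, frequency_hz: float,
                    f_half_hz: float = 20.0) -> float:
    """Frequency-dependent evoked amplitude: peak * f / (f + f_half).

    A simple saturating drive used by cohort simulations to emulate the
    monotone frequency dependence of evoked responses.
    """
    if frequency_hz <= 0:
        return 0.0
    return base_peak_dff * frequency_hz / (frequency_hz + f_half_hz)


# -- trace simulation ---------------------------------------------------------


def _draw_minis(cfg: SimConfig, rng: np.random.Generator):
    n = rng.poisson(cfg.mini.rate_hz * cfg.duration_s)
    times = np.sort(rng.uniform(0.0, cfg.duration_s, size=n))
    amps = rng.normal(cfg.mini.amp_mean, cfg.mini.amp_sd, size=n)
    # truncate at 0 by redrawing (keeps the mean close to amp_mean)
    for _ in range(100):
        bad = amps <= 0
        if not bad.any():
            break
        amps[bad] = rng.normal(cfg.mini.amp_mean, cfg.mini.amp_sd, size=bad.sum())
    amps = np.clip(amps, 1e-9, None)
    return times, amps


def _mini_waveform(times, amps, t, tau):
    """Sum of instant-rise, exponential-decay transients."""
    m = np.zeros_like(t)
    for tk, ak in zip(times, amps):
        on = t >= tk
        m[on] += ak * np.exp(-(t[on] - tk) / tau)
    return m


def simulate_trace(cfg: SimConfig, rng: Optional[np.random.Generator] = None):
    """Simulate one single-ROI trace; returns ``(Trace, SimTruth)``.

    Identical config (including seed) gives byte-identical output.
    """
    cfg = cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.frame_rate_hz))
    t = np.arange(n) / cfg.frame_rate_hz

    if cfg.stim is not None:
        r = evoked_kernel_at(cfg.compartment, cfg.stim, cfg.kernel, t)
    else:
        r = np.zeros_like(t)
    g = cfg.genotype_scale
    mini_times, mini_amps = _draw_minis(cfg, rng)
    m = _mini_waveform(mini_times, mini_amps, t, cfg.mini.decay_tau_s)

    bleach = cfg.bleach.a * np.power(np.arange(n) + 1.0, cfg.bleach.b)
    clean = bleach * (1.0 + g * r + m)
    values = clean.copy()
    if cfg.noise.shot_noise:
        values = rng.poisson(np.clip(values, 0.0, None)).astype(float)
    if cfg.noise.gaussian_sd > 0:
        values = values + rng.normal(0.0, cfg.noise.gaussian_sd, size=n)

    trace = Trace(values, cfg.frame_rate_hz, cfg.stim,
                  meta={"compartment": cfg.compartment,
                        "genotype": "WT" if g == 1.0 else "mutant",
                        "genotype_scale": g, "seed": cfg.seed})
    truth = SimTruth(kernel=cfg.kernel,
                     true_peak_dff=float(g * r.max()) if n else 0.0,
                     mini_times_s=list(mini_times), mini_amps=list(mini_amps),
                     bleach_a=cfg.bleach.a, bleach_b=cfg.bleach.b,
                     clean_dff=g * r)
    return trace, truth


# -- movie simulation ---------------------------------------------------------


def _disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _place_boutons(geom: Geometry, rng: np.random.Generator):
    """Deterministic-ish placement: boutons along a chain with jitter."""
    h, w = geom.image_shape
    margin = geom.bouton_radius_px * 3.0
    if 2 * margin >= min(h, w):
        raise ValueError("bouton footprints do not fit inside the image")
    xs = np.linspace(margin, w - margin, geom.n_boutons)
    ys = h / 2.0 + rng.uniform(-h * 0.1, h * 0.1, size=geom.n_boutons)
    centers = [(float(y), float(x)) for y, x in zip(ys, xs)]
    for y, x in centers:
        if not (margin * 0 + geom.bouton_radius_px <= y <= h - geom.bouton_radius_px
                and geom.bouton_radius_px <= x <= w - geom.bouton_radius_px):
            raise ValueError("bouton placement outside image bounds")
    return centers


def _integer_shift(frame, dy, dx, fill):
    out = np.full_like(frame, fill)
    h, w = frame.shape
    ys = slice(max(dy, 0), min(h, h + dy))
    xs = slice(max(dx, 0), min(w, w + dx))
    ys_src = slice(max(-dy, 0), min(h, h - dy))
    xs_src = slice(max(-dx, 0), min(w, w - dx))
    out[ys, xs] = frame[ys_src, xs_src]
    return out


def simulate_movie(cfg: SimConfig, rng: Optional[np.random.Generator] = None):
    """Render a drifting multi-bouton movie; returns ``(Movie, rois, SimTruth)``.

    Boutons are 2-D Gaussian spots (sigma = radius / 2) whose per-frame
    brightness follows an independently simulated trace; the whole field is
    translated by the cumulative integer drift; noise is added per pixel.
    Returned ROIs (defined on the undrifted frame) mark each bouton and the
    whole NMJ.
    """
    cfg = cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    geom = cfg.geometry
    h, w = geom.image_shape
    centers = _place_boutons(geom, rng)
    n = int(round(cfg.duration_s * cfg.frame_rate_hz))

    scales = geom.bouton_peak_scales or (1.0,) * geom.n_boutons
    if len(scales) != geom.n_boutons:
        raise ValueError("bouton_peak_scales length must equal n_boutons")

    # per-bouton noiseless traces; pixel noise is added at the movie level
    bouton_traces, bouton_truths = [], []
    child_seeds = np.random.SeedSequence(cfg.seed).spawn(geom.n_boutons)
    for k, (scale, ss) in enumerate(zip(scales, child_seeds)):
        sub = replace(cfg, noise=NoiseParams(),
                      genotype_scale=cfg.genotype_scale * scale)
        tr, truth = simulate_trace(sub, rng=np.random.default_rng(ss))
        bouton_traces.append(tr.values)
        bouton_truths.append(truth)

    yy, xx = np.mgrid[0:h, 0:w]
    sigma = geom.bouton_radius_px / 2.0
    profiles = [np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2)))
                for cy, cx in centers]

    dy_rate, dx_rate = geom.drift_px_per_frame
    shifts = [(int(round(i * dy_rate)), int(round(i * dx_rate))) for i in range(n)]

    frames = np.empty((n, h, w), dtype=float)
    for i in range(n):
        frame = np.full((h, w), geom.background, dtype=float)
        for prof, vals in zip(profiles, bouton_traces):
            frame += vals[i] * prof
        dy, dx = shifts[i]
        if dy or dx:
            frame = _integer_shift(frame, dy, dx, geom.background)
        frames[i] = frame
    if cfg.noise.shot_noise:
        frames = rng.poisson(np.clip(frames, 0.0, None)).astype(float)
    if cfg.noise.gaussian_sd > 0:
        frames = frames + rng.normal(0.0, cfg.noise.gaussian_sd, size=frames.shape)

    movie = Movie(frames, cfg.frame_rate_hz, channel_label=cfg.compartment)
    rois = [Roi(f"bouton_{k}", "bouton", _disk_mask((h, w), c, geom.bouton_radius_px))
            for k, c in enumerate(centers)]
    nmj_mask = np.zeros((h, w), dtype=bool)
    for roi in rois:
        nmj_mask |= roi.mask
    rois.append(Roi("nmj", "nmj", nmj_mask))

    truth = SimTruth(kernel=cfg.kernel,
                     true_peak_dff=bouton_truths[0].true_peak_dff,
                     bleach_a=cfg.bleach.a, bleach_b=cfg.bleach.b,
                     shifts_px=shifts, bouton_centers_px=centers,
                     bouton_truths=bouton_truths)
    return movie, rois, truth


# -- static two-channel image pair -------------------------------------------


def simulate_static_pair(cfg: SimConfig, rng: Optional[np.random.Generator] = None):
    """Static confocal-like pair: (marker, reference) images + masks.

    Channel 1 (marker, e.g. an ER lumen marker) carries a dim tubule-network
    intensity across the NMJ plus bright puncta; channel 2 (reference, e.g.
    a plasma-membrane marker) is uniform inside the NMJ. Puncta are rendered
    as uniform-intensity disks so ground-truth pixel membership is exact;
    real puncta are diffraction-blurred, which this idealization omits.

    Returns ``(marker, reference, nmj_roi, truth)`` where ``truth.puncta_mask``
    is the ground-truth puncta pixel mask.
    """
    cfg = cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    geom, st = cfg.geometry, cfg.static
    h, w = geom.image_shape
    centers = _place_boutons(geom, rng)

    nmj_mask = np.zeros((h, w), dtype=bool)
    for c in centers:
        nmj_mask |= _disk_mask((h, w), c, geom.bouton_radius_px * 2.0)

    marker = np.zeros((h, w), dtype=float)
    marker[nmj_mask] = st.tubule_level
    puncta_mask = np.zeros((h, w), dtype=bool)
    inside = np.argwhere(nmj_mask)
    for _ in range(st.n_puncta):
        cy, cx = inside[rng.integers(len(inside))]
        disk = _disk_mask((h, w), (cy, cx), st.puncta_radius_px) & nmj_mask
        puncta_mask |= disk
    marker[puncta_mask] = st.puncta_amp

    reference = np.zeros((h, w), dtype=float)
    reference[nmj_mask] = st.ref_level
    if cfg.noise.gaussian_sd > 0:
        marker = marker + rng.normal(0.0, cfg.noise.gaussian_sd, size=marker.shape)
        reference = reference + rng.normal(0.0, cfg.noise.gaussian_sd, size=reference.shape)

    nmj_roi = Roi("nmj", "nmj", nmj_mask)
    truth = SimTruth(kernel=cfg.kernel, true_peak_dff=0.0,
                     bleach_a=cfg.bleach.a, bleach_b=cfg.bleach.b,
                     bouton_centers_px=centers, puncta_mask=puncta_mask)
    return marker, reference, nmj_roi, truth


# -- cohort simulation --------------------------------------------------------


def simulate_cohort(n_larvae_per_genotype: int = 20,
                    frequencies_hz: Sequence[float] = (5.0, 20.0, 40.0, 80.0),
                    compartment: str = "cytosol",
                    genotype_scales: dict = None,
                    noise_sd_fraction: float = 0.02,
                    larva_cv: float = 0.1,
                    seed: int = 0,
                    duration_s: float = 20.0,
                    stim_onset_s: float = 5.0,
                    stim_duration_s: float = 2.0):
    """Simulate a WT-vs-mutant cohort across stimulation frequencies.

    Each larva contributes one trace per frequency. The evoked amplitude is
    the compartment default scaled by the genotype factor, a saturating
    frequency dependence, and a lognormal per-larva factor (CV
    ``larva_cv``). Gaussian noise SD is ``noise_sd_fraction`` of the
    baseline amplitude. Returns ``(traces, truths, records)`` where records
    is a list of dicts (larva_id, genotype, frequency_hz, seed, ...) aligned
    with the traces.
    """
    if genotype_scales is None:
        genotype_scales = {"WT": 1.0, "mutant": 0.5}
    base_kernel = DEFAULT_KERNELS[compartment]
    frame_rate = DEFAULT_FRAME_RATES[compartment]
    root = np.random.SeedSequence(seed)
    traces, truths, records = [], [], []
    for g_idx, (genotype, g_scale) in enumerate(sorted(genotype_scales.items())):
        for larva in range(n_larvae_per_genotype):
            larva_ss = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(g_idx, larva))
            larva_rng = np.random.default_rng(larva_ss)
            larva_factor = float(np.exp(larva_rng.normal(0.0, larva_cv)))
            for freq in frequencies_hz:
                peak = saturating_peak(base_kernel.peak_dff, freq) * larva_factor
                dip = saturating_peak(base_kernel.dip_amp_dff, freq) * larva_factor
                kernel = replace(base_kernel, peak_dff=peak, dip_amp_dff=dip)
                cfg = SimConfig(
                    compartment=compartment, genotype_scale=g_scale,
                    frame_rate_hz=frame_rate, duration_s=duration_s,
                    stim=StimWindow(stim_onset_s, stim_duration_s, freq),
                    noise=NoiseParams(gaussian_sd=noise_sd_fraction * 1000.0),
                    kernel=kernel, seed=0)
                tr, truth = simulate_trace(cfg, rng=np.random.default_rng(larva_rng))
                tr.meta.update({"larva_id": f"{genotype}_{larva}",
                                "genotype": genotype, "frequency_hz": freq})
                traces.append(tr)
                truths.append(truth)
                records.append({"larva_id": f"{genotype}_{larva}",
                                "genotype": genotype, "frequency_hz": freq,
                                "true_peak_dff": truth.true_peak_dff})
    return traces, truths, records
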