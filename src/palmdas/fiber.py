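"""Forward model of a phase-sensitive OTDR (Φ-OTDR) distributed acoustic sensor.

The interrogator launches coherent optical pulses into a single-mode fiber
laid out across a palm farm, with a short fiber loop wound around each tree
trunk.  Rayleigh backscatter from many sub-resolution scatterers interferes
coherently, so each distance bin of the backscatter trace carries a speckle
intensity.  An acoustic pressure at a tree loop strains the fiber there,
perturbing the relative optical phases of the scatterers in those bins and
hence the local trace intensity — the sensing mechanism this module
simulates.

The model is a direct-detection (intensity) one: per distance bin the field
is a coherent sum ``E_z = sum_m a_m exp(i(phi_m + theta_z(t) w_m))`` over
``M`` frozen scatterers with random amplitudes ``a_m``, phases ``phi_m`` and
fractional positions ``w_m`` inside the gauge length, and the detected
intensity is ``|E_z|^2``.  ``theta_z(t)`` is the acoustic phase perturbation
at bin ``z``.  Everything is a pure function of its inputs and a seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import signal as sps

SPEED_OF_LIGHT = 299_792_458.0  # m/s

__all__ = [
    "PulseConfig",
    "TreeSpec",
    "FiberLayout",
    "BurstSource",
    "WindModel",
    "InstrumentNoise",
    "AcousticScene",
    "ScattererState",
    "RayleighTraceSet",
    "realize_fiber",
    "synthesize_traces",
    "larvae_waveform",
    "wind_waveform",
    "wind_shaping_gain",
]


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseConfig:
    """Interrogation pulse parameters.

    Defaults mirror a conventional Φ-OTDR interrogator: a 1550-nm
    narrow-linewidth laser modulated into 50-ns pulses at a 5-kHz repetition
    rate, giving ~5-m spatial resolution and a 2.5-kHz acoustic Nyquist.
    ``laser_linewidth`` and ``launch_power`` are carried as metadata only.
    """

    wavelength: float = 1550e-9        # m
    rep_rate: float = 5000.0           # Hz, pulse repetition rate
    pulse_width: float = 50e-9         # s
    laser_linewidth: float = 100.0     # Hz (metadata)
    launch_power: float = 0.040        # W (metadata)

    def __post_init__(self) -> None:
        if self.pulse_width <= 0:
            raise ValueError("pulse_width must be positive")
        if self.rep_rate <= 0:
            raise ValueError("rep_rate must be positive")

    def spatial_resolution(self, group_index: float = 1.468) -> float:
        """Two-way spatial resolution c*tau/(2*n_g) set by the pulse width."""
        return SPEED_OF_LIGHT * self.pulse_width / (2.0 * group_index)

    def validate_against(self, layout: "FiberLayout") -> None:
        """No pulse overlap: round-trip time must fit between pulses."""
        round_trip = 2.0 * layout.fiber_length * layout.group_index / SPEED_OF_LIGHT
        if self.rep_rate * round_trip >= 1.0:
            raise ValueError(
                f"rep_rate {self.rep_rate} Hz overlaps pulses on a "
                f"{layout.fiber_length} m fiber (round trip {round_trip:.2e} s)"
            )


@dataclass(frozen=True)
class TreeSpec:
    """One tree on the farm: a fiber loop interval and a ground-truth condition."""

    tree_id: str
    start_position: float              # m from the interrogator
    loop_length: float = 5.0           # m of fiber wound around the trunk
    condition: Literal["infested", "healthy"] = "healthy"

    def __post_init__(self) -> None:
        if self.condition not in ("infested", "healthy"):
            raise ValueError(f"unknown tree condition {self.condition!r}")
        if self.loop_length <= 0 or self.start_position < 0:
            raise ValueError("tree loop must have positive length at a non-negative position")


@dataclass(frozen=True)
class FiberLayout:
    """Sensing-fiber geometry: total length, digitizer sampling, tree loops."""

    fiber_length: float = 1000.0       # m
    spatial_sampling: float = 0.5      # m per digitizer distance bin
    group_index: float = 1.468
    trees: tuple[TreeSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.spatial_sampling <= 0:
            raise ValueError("spatial_sampling must be positive")
        object.__setattr__(self, "trees", tuple(self.trees))
        ids = [t.tree_id for t in self.trees]
        if len(set(ids)) != len(ids):
            raise ValueError("tree_ids must be unique")
        spans = sorted((t.start_position, t.start_position + t.loop_length) for t in self.trees)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("tree loops must be disjoint intervals")
        if spans and spans[-1][1] > self.fiber_length:
            raise ValueError("tree loops must lie within the fiber")

    @property
    def n_bins(self) -> int:
        return int(math.floor(self.fiber_length / self.spatial_sampling))

    def tree(self, tree_id: str) -> TreeSpec:
        for t in self.trees:
            if t.tree_id == tree_id:
                return t
        raise KeyError(f"tree {tree_id!r} not in layout")

    def tree_bins(self, tree_id: str) -> np.ndarray:
        """Distance-bin indices of a tree's loop (half-open bins [i*dz, (i+1)*dz))."""
        t = self.tree(tree_id)
        first = int(round(t.start_position / self.spatial_sampling))
        count = int(round(t.loop_length / self.spatial_sampling))
        return np.arange(first, first + count)

    def all_tree_bins(self) -> np.ndarray:
        if not self.trees:
            return np.empty(0, dtype=int)
        return np.concatenate([self.tree_bins(t.tree_id) for t in self.trees])

    def points_per_tree(self, tree_id: str) -> int:
        return len(self.tree_bins(tree_id))


@dataclass(frozen=True)
class BurstSource:
    """An intermittent band-limited acoustic source attached to one tree loop.

    With the default band this is the larvae chewing model: short broadband
    bursts with dominant energy in 100–800 Hz, arriving at Poisson times and
    gated by an active/silent duty pattern so whole 100-ms windows can be
    silent.  The same type with a lower band serves as a non-larval
    disturbance (rustling, mechanical rubbing) on healthy trees.
    """

    tree_id: str
    burst_rate: float = 6.0            # mean bursts per second while active
    burst_duration: float = 0.025      # s per burst
    band: tuple[float, float] = (100.0, 800.0)   # Hz
    amplitude: float = 0.05            # strain-equivalent phase amplitude (rad RMS in bursts)
    duty_pattern: tuple[float, float] = (2.0, 2.0)  # (active, silent) episode lengths, s

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.burst_rate * self.burst_duration > 1.0:
            raise ValueError("burst_rate * burst_duration > 1: overlapping saturation")


@dataclass(frozen=True)
class WindModel:
    """Fiber-wide wind noise, dominated below ``corner_freq`` and growing with speed.

    Total acoustic power scales as ``speed_mph**3`` (a stated modeling choice,
    asserted only for monotonicity); the spectrum is flat below ``corner_freq``
    and rolls off at ``spectral_slope`` dB/decade above it, so some in-band
    (100–800 Hz) leakage always survives the band-pass filter and grows with
    speed.  Tree loops couple more strongly than loose fiber by ``tree_gain``
    (the wound fiber rides the swaying trunk).
    """

    speed_mph: float = 0.0
    corner_freq: float = 100.0         # Hz
    spectral_slope: float = 40.0       # dB/decade power roll-off above corner
    base_rms: float = 0.06             # phase RMS (rad) at 10 mph on loose fiber
    tree_gain: float = 3.0             # extra coupling at tree loops

    def __post_init__(self) -> None:
        if self.speed_mph < 0:
            raise ValueError("wind speed must be >= 0")

    def rms(self) -> float:
        """Phase RMS on loose fiber; power ∝ speed³ ⇒ amplitude ∝ speed^1.5."""
        return self.base_rms * (self.speed_mph / 10.0) ** 1.5


@dataclass(frozen=True)
class InstrumentNoise:
    """Receiver-chain noise lumped into additive intensity noise.

    ``white_floor`` is a broadband white term; ``hf_level`` an extra component
    band-limited to ``hf_band`` mimicking >800-Hz electronic/optical noise.
    Both are fractions of the median unperturbed trace intensity.
    """

    white_floor: float = 0.010
    hf_level: float = 0.008
    hf_band: tuple[float, float] = (800.0, 2500.0)


@dataclass(frozen=True)
class AcousticScene:
    """Everything that vibrates the fiber during one recording."""

    duration: float                    # s
    larvae_sources: tuple[BurstSource, ...] = ()
    disturbance_sources: tuple[BurstSource, ...] = ()
    wind: WindModel | None = None
    instrument_noise: InstrumentNoise | None = InstrumentNoise()

    def __post_init__(self) -> None:
        object.__setattr__(self, "larvae_sources", tuple(self.larvae_sources))
        object.__setattr__(self, "disturbance_sources", tuple(self.disturbance_sources))

    def validate(self, layout: FiberLayout, pulse: PulseConfig) -> None:
        nyquist = pulse.rep_rate / 2.0
        for src in self.larvae_sources + self.disturbance_sources:
            layout.tree(src.tree_id)  # KeyError if absent
            lo, hi = src.band
            if not (0 <= lo < hi <= nyquist):
                raise ValueError(f"source band {src.band} outside [0, {nyquist}] Hz")


# --------------------------------------------------------------------------
# scatterer realization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScattererState:
    """Frozen random realization of the fiber's Rayleigh scatterers.

    Per distance bin, ``M`` scatterers with Rayleigh-distributed amplitudes,
    uniform phases and uniform fractional positions ``w`` in the gauge.  The
    complex moments ``E0 = Σ a e^{iφ}``, ``B = Σ a w e^{iφ}`` and
    ``C = Σ a w² e^{iφ}`` support a fast second-order small-signal expansion
    of the perturbed field.
    """

    layout: FiberLayout
    pulse: PulseConfig
    seed: int
    amp: np.ndarray       # (n_bins, M)
    phase: np.ndarray     # (n_bins, M)
    w: np.ndarray         # (n_bins, M) fractional position in gauge
    wind_coupling: np.ndarray  # (n_bins,) per-bin wind coupling gain
    fresnel_factor: float

    @property
    def n_bins(self) -> int:
        return self.amp.shape[0]

    @property
    def field0(self) -> np.ndarray:
        return (self.amp * np.exp(1j * self.phase)).sum(axis=1)

    @property
    def moment_b(self) -> np.ndarray:
        return (self.amp * self.w * np.exp(1j * self.phase)).sum(axis=1)

    @property
    def moment_c(self) -> np.ndarray:
        return (self.amp * self.w**2 * np.exp(1j * self.phase)).sum(axis=1)

    def unperturbed_trace(self) -> np.ndarray:
        """Backscatter intensity with a quiet fiber, float32 like synthesized traces."""
        return (np.abs(self.field0) ** 2).astype(np.float32)


def realize_fiber(
    layout: FiberLayout,
    pulse: PulseConfig,
    seed: int,
    scatterers_per_gauge: int = 20,
    fresnel_factor: float = 50.0,
) -> ScattererState:
    """Draw a frozen scatterer realization for (layout, pulse, seed).

    ``fresnel_factor`` scales the intensity of the first gauge-length of bins
    to emulate the strong Fresnel reflection off the fiber's front facet
    (set to 1.0 to disable).  Raises if the gauge length set by the pulse
    width undersamples the digitizer's spatial bins.
    """
    pulse.validate_against(layout)
    gauge = pulse.spatial_resolution(layout.group_index)
    if gauge < layout.spatial_sampling:
        raise ValueError(
            f"pulse width {pulse.pulse_width:.3g} s gives a {gauge:.3g} m gauge, "
            f"shorter than one {layout.spatial_sampling} m spatial bin"
        )
    rng = np.random.default_rng(seed)
    n = layout.n_bins
    m = scatterers_per_gauge
    amp = rng.rayleigh(scale=1.0, size=(n, m))
    phase = rng.uniform(0.0, 2.0 * np.pi, size=(n, m))
    w = rng.uniform(0.0, 1.0, size=(n, m))
    # mild per-bin heterogeneity of wind pickup along the cable
    wind_coupling = rng.uniform(0.7, 1.3, size=n)
    if fresnel_factor != 1.0:
        k = max(1, int(round(gauge / layout.spatial_sampling)))
        amp = amp.copy()
        amp[:k] *= math.sqrt(fresnel_factor)
    return ScattererState(
        layout=layout, pulse=pulse, seed=int(seed),
        amp=amp, phase=phase, w=w, wind_coupling=wind_coupling,
        fresnel_factor=float(fresnel_factor),
    )


# --------------------------------------------------------------------------
# acoustic waveforms
# --------------------------------------------------------------------------

def _design_bandpass(band: tuple[float, float], fs: float, order: int = 4) -> np.ndarray:
    lo, hi = band
    nyq = fs / 2.0
    if not (0 < lo < hi <= nyq):
        raise ValueError(f"band {band} invalid for sample rate {fs}")
    if hi >= nyq:  # degenerate upper edge -> high-pass
        return sps.butter(order, lo, btype="highpass", fs=fs, output="sos")
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def larvae_waveform(
    burst_rate: float,
    burst_duration: float,
    band: tuple[float, float],
    amplitude: float,
    duration: float,
    seed: int,
    sample_rate: float = 5000.0,
    duty_pattern: tuple[float, float] = (math.inf, 0.0),
) -> np.ndarray:
    """Intermittent train of band-limited noise bursts (larvae chewing model).

    Burst onsets are Poisson with rate ``burst_rate`` during active episodes
    of the ``duty_pattern`` (active, silent) cycle; each burst is Hann-shaped
    white noise, and the assembled train is band-pass filtered to ``band`` so
    that >=90% of its energy is in band.  The result is scaled so the RMS over
    burst supports equals ``amplitude``; ``amplitude == 0`` gives exact zeros.
    """
    if burst_rate * burst_duration > 1.0:
        raise ValueError("burst_rate * burst_duration > 1: overlapping saturation")
    if band[1] > sample_rate / 2.0:
        raise ValueError("band exceeds Nyquist")
    n = int(round(duration * sample_rate))
    if amplitude == 0.0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    n_bursts = rng.poisson(burst_rate * duration)
    onsets = np.sort(rng.uniform(0.0, duration, size=n_bursts))
    active_len, silent_len = duty_pattern
    cycle = active_len + silent_len
    if math.isfinite(cycle) and cycle > 0:
        onsets = onsets[(onsets % cycle) < active_len]
    blen = max(4, int(round(burst_duration * sample_rate)))
    win = np.hanning(blen)
    for t0 in onsets:
        i0 = int(round(t0 * sample_rate))
        i1 = min(i0 + blen, n)
        if i1 > i0:
            x[i0:i1] += rng.standard_normal(i1 - i0) * win[: i1 - i0]
    if not np.any(x):
        return np.zeros(n)
    sos = _design_bandpass(band, sample_rate)
    x = sps.sosfiltfilt(sos, x)
    support = np.abs(x) > 1e-12 * np.max(np.abs(x))
    rms = math.sqrt(float(np.mean(x[support] ** 2))) if support.any() else 0.0
    if rms > 0:
        x = x * (amplitude / rms)
    return x


def wind_shaping_gain(freq: np.ndarray | float, corner_freq: float, spectral_slope: float) -> np.ndarray:
    """Amplitude response of the wind spectral shaper: flat below the corner,
    power roll-off of ``spectral_slope`` dB/decade above it."""
    p = spectral_slope / 10.0  # power-law exponent
    f = np.asarray(freq, dtype=float)
    return 1.0 / np.sqrt(1.0 + (f / corner_freq) ** p)


def wind_waveform(
    speed_mph: float,
    corner_freq: float,
    spectral_slope: float,
    duration: float,
    seed: int,
    sample_rate: float = 5000.0,
    base_rms: float = 0.06,
    gustiness: float = 0.4,
) -> np.ndarray:
    """Colored-noise wind phase waveform on loose fiber.

    White noise is shaped by :func:`wind_shaping_gain` in the frequency
    domain, modulated by a slow (~0.2 Hz) log-normal gust envelope, and scaled
    to a total RMS of ``base_rms * (speed/10)**1.5`` — i.e. power ∝ speed³,
    a modeling choice; only monotonic growth with speed is contractual.
    """
    if speed_mph < 0:
        raise ValueError("wind speed must be >= 0")
    n = int(round(duration * sample_rate))
    if speed_mph == 0.0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    shaped = np.fft.irfft(np.fft.rfft(white) * wind_shaping_gain(freqs, corner_freq, spectral_slope), n=n)
    if gustiness > 0:
        slow = rng.standard_normal(n)
        sos = sps.butter(2, 0.2, btype="lowpass", fs=sample_rate, output="sos")
        slow = sps.sosfiltfilt(sos, slow)
        sd = float(np.std(slow))
        if sd > 0:
            env = np.exp(gustiness * slow / sd)
            shaped = shaped * (env / float(np.mean(env)))
    rms = float(np.sqrt(np.mean(shaped**2)))
    target = base_rms * (speed_mph / 10.0) ** 1.5
    return shaped * (target / rms)


# --------------------------------------------------------------------------
# trace synthesis
# --------------------------------------------------------------------------

@dataclass
class RayleighTraceSet:
    """A stack of backscatter intensity traces, one per interrogation pulse."""

    traces: np.ndarray        # (n_pulses, n_bins) float32, >= 0
    distance_axis: np.ndarray  # (n_bins,) m
    time_axis: np.ndarray      # (n_pulses,) s
    seed: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_pulses(self) -> int:
        return self.traces.shape[0]

    @property
    def n_bins(self) -> int:
        return self.traces.shape[1]

    @property
    def rep_rate(self) -> float:
        return float(self.provenance.get("rep_rate", 5000.0))


def _source_phase_tracks(
    scene: AcousticScene,
    layout: FiberLayout,
    n: int,
    fs: float,
    seed: int,
) -> dict[str, np.ndarray]:
    """Per-tree summed source phase waveforms, keyed by tree_id."""
    tracks: dict[str, np.ndarray] = {}
    sources = list(scene.larvae_sources) + list(scene.disturbance_sources)
    for k, src in enumerate(sources):
        sub = int(np.random.SeedSequence((seed, 101, k)).generate_state(1)[0] % 2**31)
        wf = larvae_waveform(
            src.burst_rate, src.burst_duration, src.band, src.amplitude,
            n / fs, sub, sample_rate=fs, duty_pattern=src.duty_pattern,
        )[:n]
        tracks[src.tree_id] = tracks.get(src.tree_id, 0.0) + wf
    return tracks


def synthesize_traces(
    state: ScattererState,
    scene: AcousticScene,
    pulse: PulseConfig,
    seed: int = 0,
    method: Literal["small_signal", "exact"] = "small_signal",
    phase_coupling: float = 1.0,
    block: int = 4096,
) -> RayleighTraceSet:
    """Synthesize the pulse-by-pulse Rayleigh intensity traces for a scene.

    Source waveforms become phase perturbations confined to their tree's
    bins; wind is a fiber-wide phase track scaled by each bin's coupling
    (with extra gain at tree loops); instrument noise is additive intensity
    noise.  ``method='small_signal'`` evaluates the perturbed coherent sum
    through its second-order expansion in the phase (fast, accurate for the
    small phase amplitudes of this regime); ``method='exact'`` sums the
    scatterers directly and is used as a cross-check.
    """
    layout = state.layout
    scene.validate(layout, pulse)
    fs = pulse.rep_rate
    if scene.duration < 0.1:
        raise ValueError("scene duration must cover at least one 100-ms window")
    n_pulses = int(round(scene.duration * fs))
    n_bins = state.n_bins

    tracks = _source_phase_tracks(scene, layout, n_pulses, fs, seed)

    wind_track = None
    gain = None
    if scene.wind is not None and scene.wind.speed_mph > 0:
        wsub = int(np.random.SeedSequence((seed, 202)).generate_state(1)[0] % 2**31)
        wind_track = wind_waveform(
            scene.wind.speed_mph, scene.wind.corner_freq, scene.wind.spectral_slope,
            scene.duration, wsub, sample_rate=fs, base_rms=scene.wind.base_rms,
        )[:n_pulses]
        gain = state.wind_coupling.copy()
        tb = layout.all_tree_bins()
        gain[tb] *= scene.wind.tree_gain

    e0 = state.field0
    mb = state.moment_b
    mc = state.moment_c

    noise_rng = np.random.default_rng(np.random.SeedSequence((seed, 303)).generate_state(1))
    out = np.empty((n_pulses, n_bins), dtype=np.float32)
    median_i0 = float(np.median(np.abs(e0) ** 2))

    tree_cols = {tid: layout.tree_bins(tid) for tid in tracks}
    if wind_track is None and method == "small_signal":
        # only source columns are perturbed; everything else stays at |E0|^2
        active = (np.unique(np.concatenate(list(tree_cols.values())))
                  if tree_cols else np.empty(0, dtype=int))
    else:
        active = np.arange(n_bins)

    base = (np.abs(e0) ** 2).astype(np.float32)
    for lo in range(0, n_pulses, block):
        hi = min(lo + block, n_pulses)
        nb = hi - lo
        out[lo:hi] = base  # broadcast row-wise
        if active.size == 0:
            continue
        theta = np.zeros((nb, active.size))
        if wind_track is not None:
            theta += np.outer(wind_track[lo:hi], gain[active])
        col_of = {c: i for i, c in enumerate(active)}
        for tid, track in tracks.items():
            idx = [col_of[c] for c in tree_cols[tid]]
            theta[:, idx] += track[lo:hi, None]
        theta *= phase_coupling
        if method == "small_signal":
            fld = e0[None, active] + 1j * theta * mb[None, active] - 0.5 * theta**2 * mc[None, active]
            inten = np.abs(fld) ** 2
        elif method == "exact":
            ph = state.phase[None, active, :] + theta[:, :, None] * state.w[None, active, :]
            fld = (state.amp[None, active, :] * np.exp(1j * ph)).sum(axis=2)
            inten = np.abs(fld) ** 2
        else:
            raise ValueError(f"unknown method {method!r}")
        out[lo:hi, active] = inten.astype(np.float32)

    if scene.instrument_noise is not None:
        nz = scene.instrument_noise
        if nz.white_floor > 0:
            white = noise_rng.standard_normal(size=out.shape, dtype=np.float32)
            white *= np.float32(nz.white_floor * median_i0)
            out += white
        if nz.hf_level > 0:
            hf = noise_rng.standard_normal(size=out.shape, dtype=np.float32)
            sos = _design_bandpass(nz.hf_band, fs)
            hf = sps.sosfilt(sos, hf, axis=0).astype(np.float32)
            out += hf * np.float32(nz.hf_level * median_i0 / max(float(np.std(hf)), 1e-30))
        np.maximum(out, 0.0, out=out)

    return RayleighTraceSet(
        traces=out,
        distance_axis=np.arange(n_bins) * layout.spatial_sampling,
        time_axis=np.arange(n_pulses) / fs,
        seed=int(seed),
        provenance={
            "rep_rate": fs,
            "spatial_sampling": layout.spatial_sampling,
            "fiber_length": layout.fiber_length,
            "method": method,
            "phase_coupling": phase_coupling,
            "state_seed": state.seed,
            "trees": [dataclasses.asdict(t) for t in layout.trees],
        },
    )
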