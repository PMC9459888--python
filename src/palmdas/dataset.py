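"""CNN input images, SNR-based labeling, splits, and the synthetic dataset builder.

A tree's 5-m fiber loop spans 10 distance bins at 0.5-m sampling, and each
100-ms digitizer window holds 500 samples at the 5-kHz pulse rate, so every
(tree, window) pair yields a 10x500 temporal image and, row-by-row FFT, a
10x250 spectral image.  Labels combine the tree's ground-truth condition
with the window's SNR against quiet fiber: infested trees with SNR > 2 dB
(the minimum usable DAS SNR) are recorded as "infested"; healthy trees give
"calm" (SNR < 2 dB) or "noisy" (SNR > 2 dB) examples; infested-tree windows
at or below 2 dB — the larvae pausing — are discarded, not recorded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from . import dsp
from .fiber import (
    AcousticScene,
    BurstSource,
    FiberLayout,
    InstrumentNoise,
    PulseConfig,
    TreeSpec,
    WindModel,
    realize_fiber,
    synthesize_traces,
)

logger = logging.getLogger(__name__)

SNR_THRESHOLD_DB = 2.0

__all__ = [
    "AcousticImage",
    "LabeledExample",
    "SplitSpec",
    "form_images",
    "label_example",
    "make_split",
    "split_sizes",
    "sample_noise_bins",
    "extract_tree_examples",
    "extract_evaluation_stream",
    "GeneratorConfig",
    "generate_labeled_dataset",
    "examples_to_arrays",
    "default_farm_layout",
]


# --------------------------------------------------------------------------
# types
# --------------------------------------------------------------------------

@dataclass
class AcousticImage:
    matrix: np.ndarray                      # (rows, 500) or (rows, 250)
    tree_id: str
    window_index: int
    kind: Literal["temporal", "spectral"]


@dataclass
class LabeledExample:
    temporal: AcousticImage
    spectral: AcousticImage
    sublabel: Literal["infested", "calm", "noisy"]
    snr_db: float

    @property
    def label(self) -> str:
        return "infested" if self.sublabel == "infested" else "healthy"


@dataclass(frozen=True)
class SplitSpec:
    """Reproducible train/validation/test split, stratified by sublabel."""

    fractions: tuple[float, float, float] = (0.60, 0.20, 0.20)
    seed: int = 0
    stratify_by_sublabel: bool = True

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.fractions}")


# --------------------------------------------------------------------------
# labeling and image formation
# --------------------------------------------------------------------------

def label_example(
    tree_condition: Literal["infested", "healthy"],
    snr_db: float,
) -> str | None:
    """Apply the 2-dB recording rule; ``None`` means the window is not recorded.

    An SNR of exactly 2 dB counts as not-greater, i.e. the quiet side.
    """
    if tree_condition == "infested":
        return "infested" if snr_db > SNR_THRESHOLD_DB else None
    if tree_condition == "healthy":
        return "noisy" if snr_db > SNR_THRESHOLD_DB else "calm"
    raise ValueError(f"unknown tree condition {tree_condition!r}")


def _normalize(matrix: np.ndarray) -> np.ndarray:
    peak = float(np.max(np.abs(matrix)))
    return matrix / peak if peak > 0 else matrix


def form_images(
    filtered: np.ndarray,
    valid: np.ndarray,
    layout: FiberLayout,
    window_index: int,
    tree_id: str,
    rep_rate: float = 5000.0,
) -> tuple[AcousticImage, AcousticImage] | None:
    """Cut one tree-window image pair out of the band-passed differential stack.

    ``filtered`` is (n_pulses, n_bins) band-passed normalized-differential
    data; rows are the tree's bins in increasing distance order.  Both images
    are scaled by their own peak magnitude so CNN inputs are bounded; the
    spectral image is the row-by-row one-sided spectrum of the (normalized)
    temporal image, which keeps the pair recomputable from one another up to
    that scaling.  Returns ``None`` (logged) if any loop bin is invalid or
    the window is not fully inside the recording.
    """
    bins = layout.tree_bins(tree_id)
    if not valid[bins].all():
        logger.info("skipping %s window %d: %d invalid bin(s) in loop",
                    tree_id, window_index, int((~valid[bins]).sum()))
        return None
    wlen = dsp.window_length(rep_rate)
    lo, hi = window_index * wlen, (window_index + 1) * wlen
    if lo < 0 or hi > filtered.shape[0]:
        raise ValueError(f"window {window_index} not inside recording of {filtered.shape[0]} pulses")
    temporal = _normalize(filtered[lo:hi, bins].T.copy())
    spectral = _normalize(
        np.vstack([dsp.spectrum(row, sample_rate=rep_rate).magnitudes for row in temporal])
    )
    return (
        AcousticImage(temporal, tree_id, window_index, "temporal"),
        AcousticImage(spectral, tree_id, window_index, "spectral"),
    )


def sample_noise_bins(
    layout: FiberLayout,
    n: int = 64,
    seed: int = 0,
    guard_bins: int = 20,
) -> np.ndarray:
    """Seeded subsample of distance bins outside every tree loop.

    The first ``guard_bins`` bins are excluded (Fresnel spike region).  The
    window-wise median power over these bins is the quiet-fiber noise
    reference for SNR labeling.
    """
    excluded = set(layout.all_tree_bins().tolist())
    candidates = np.array([b for b in range(guard_bins, layout.n_bins) if b not in excluded])
    if candidates.size == 0:
        raise ValueError("no non-tree bins available for a noise reference")
    rng = np.random.default_rng(seed)
    if candidates.size <= n:
        return candidates
    return np.sort(rng.choice(candidates, size=n, replace=False))


def window_snr(
    filtered: np.ndarray,
    layout: FiberLayout,
    tree_id: str,
    window_index: int,
    noise_bins: np.ndarray,
    rep_rate: float = 5000.0,
    ref_trace: np.ndarray | None = None,
) -> float:
    """Window SNR of a tree: median loop-row power over the median noise-bin power.

    In the intensity-differential domain the additive receiver noise at bin
    ``z`` is amplified by ``1/I_ref(z)``, so deeply faded speckle bins would
    bias any cross-bin power comparison.  When ``ref_trace`` is given, bin
    powers are weighted by ``(I_ref / median I_ref)**2`` — an exact noise
    equalization for additive intensity noise — before the medians are taken.
    """
    wlen = dsp.window_length(rep_rate)
    lo, hi = window_index * wlen, (window_index + 1) * wlen
    bins = layout.tree_bins(tree_id)
    p_rows = np.mean(np.square(filtered[lo:hi, bins]), axis=0)
    p_ref = np.mean(np.square(filtered[lo:hi, noise_bins]), axis=0)
    if ref_trace is not None:
        w = np.square(np.asarray(ref_trace, dtype=np.float64) / np.median(ref_trace))
        p_rows = p_rows * w[bins]
        p_ref = p_ref * w[noise_bins]
    p_sig = float(np.median(p_rows))
    p_noise = float(np.median(p_ref))
    if p_noise <= 0:
        raise ValueError("degenerate noise reference: zero power")
    return 10.0 * math.log10(p_sig / p_noise) if p_sig > 0 else -math.inf


# --------------------------------------------------------------------------
# splits
# --------------------------------------------------------------------------

def split_sizes(n: int, fractions: Sequence[float] = (0.6, 0.2, 0.2)) -> tuple[int, int, int]:
    """Train/val/test sizes: 36,000 at 60/20/20 gives 21,600/7,200/7,200."""
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return n_train, n_val, n - n_train - n_val


def make_split(
    examples: Sequence,
    spec: SplitSpec,
    sublabels: Sequence[str] | None = None,
) -> tuple[list, list, list]:
    """Deterministic, stratified, disjoint and exhaustive 3-way split.

    ``sublabels`` defaults to each example's ``.sublabel`` attribute when
    stratifying.  Items may be any objects (e.g. :class:`LabeledExample` or
    plain indices).
    """
    if spec.stratify_by_sublabel:
        if sublabels is None:
            sublabels = [ex.sublabel for ex in examples]
        groups: dict[str, list[int]] = {}
        for i, s in enumerate(sublabels):
            groups.setdefault(s, []).append(i)
    else:
        groups = {"all": list(range(len(examples)))}
    rng = np.random.default_rng(spec.seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    test_idx: list[int] = []
    for key in sorted(groups):
        idx = np.array(groups[key])
        rng.shuffle(idx)
        n_tr, n_va, _ = split_sizes(len(idx), spec.fractions)
        train_idx += idx[:n_tr].tolist()
        val_idx += idx[n_tr:n_tr + n_va].tolist()
        test_idx += idx[n_tr + n_va:].tolist()
    return (
        [examples[i] for i in train_idx],
        [examples[i] for i in val_idx],
        [examples[i] for i in test_idx],
    )


# --------------------------------------------------------------------------
# synthetic dataset generation
# --------------------------------------------------------------------------

def default_farm_layout(
    n_infested: int = 6,
    n_healthy: int = 6,
    fiber_length: float = 1000.0,
    loop_length: float = 5.0,
    start: float = 50.0,
    spacing: float = 75.0,
) -> FiberLayout:
    """A virtual farm: trees strung along a 1-km fiber, infested first."""
    trees = []
    pos = start
    for i in range(n_infested):
        trees.append(TreeSpec(f"I{i+1}", pos, loop_length, "infested"))
        pos += spacing
    for i in range(n_healthy):
        trees.append(TreeSpec(f"H{i+1}", pos, loop_length, "healthy"))
        pos += spacing
    if pos - spacing + loop_length > fiber_length:
        raise ValueError("trees do not fit on the fiber")
    return FiberLayout(fiber_length=fiber_length, trees=tuple(trees))


def _preprocess_stack(traces, layout, noise_bins, band):
    """Differential vs first-window mean, band-pass restricted to used bins."""
    arr = traces.traces if hasattr(traces, "traces") else np.asarray(traces)
    rep_rate = traces.rep_rate if hasattr(traces, "rep_rate") else 5000.0
    ref = dsp.first_window_reference(arr, rep_rate)
    d, valid = dsp.normalized_differential(arr, reference=ref)
    cols = np.unique(np.concatenate([layout.all_tree_bins(), noise_bins]))
    cols = cols[valid[cols]]
    filtered = np.zeros_like(d)
    if cols.size:
        filtered[:, cols] = dsp.bandpass(d[:, cols], rep_rate, band=band, axis=0)
    return filtered, valid, rep_rate, ref


def extract_tree_examples(
    traces,
    layout: FiberLayout,
    noise_bins: np.ndarray | None = None,
    band: tuple[float, float] = dsp.DEFAULT_BAND,
) -> list[LabeledExample]:
    """Run the full DSP chain on a trace stack and emit labeled image pairs.

    Differential against the first window's mean trace, band-pass, then per
    (tree, window): SNR labeling under the 2-dB recording rule and image
    formation.  Infested-tree windows at or below 2 dB are discarded.
    """
    if noise_bins is None:
        noise_bins = sample_noise_bins(layout, seed=0)
    filtered, valid, rep_rate, ref = _preprocess_stack(traces, layout, noise_bins, band)
    wlen = dsp.window_length(rep_rate)
    n_windows = filtered.shape[0] // wlen
    out: list[LabeledExample] = []
    for tree in layout.trees:
        for w in range(n_windows):
            snr = window_snr(filtered, layout, tree.tree_id, w, noise_bins, rep_rate, ref_trace=ref)
            sub = label_example(tree.condition, snr)
            if sub is None:
                continue
            pair = form_images(filtered, valid, layout, w, tree.tree_id, rep_rate)
            if pair is None:
                continue
            out.append(LabeledExample(pair[0], pair[1], sub, snr))
    return out


def extract_evaluation_stream(
    traces,
    layout: FiberLayout,
    noise_bins: np.ndarray | None = None,
    band: tuple[float, float] = dsp.DEFAULT_BAND,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-tree image stacks for *every* window — the alarm-counting stream.

    Unlike training-data recording, tree classification must score each
    window, so no SNR gate is applied.  Returns
    ``{tree_id: (X_temporal, X_spectral)}``.
    """
    if noise_bins is None:
        noise_bins = sample_noise_bins(layout, seed=0)
    filtered, valid, rep_rate, _ref = _preprocess_stack(traces, layout, noise_bins, band)
    wlen = dsp.window_length(rep_rate)
    n_windows = filtered.shape[0] // wlen
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for tree in layout.trees:
        xt, xs = [], []
        for w in range(n_windows):
            pair = form_images(filtered, valid, layout, w, tree.tree_id, rep_rate)
            if pair is None:
                continue
            xt.append(pair[0].matrix)
            xs.append(pair[1].matrix)
        if xt:
            out[tree.tree_id] = (
                np.stack(xt).astype(np.float32),
                np.stack(xs).astype(np.float32),
            )
    return out


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic labeled dataset.

    The controlled-environment scene (no wind) records infested and calm
    examples from a farm of infested + healthy trees; the outdoor scene (all
    trees healthy, moderate wind plus intermittent rustling disturbances)
    supplies the noisy-healthy class.  Class budget defaults reproduce the
    design of equal infested/healthy counts with healthy split evenly
    calm/noisy.
    """

    larvae: BurstSource = field(default_factory=lambda: BurstSource(tree_id=""))
    disturbance_band: tuple[float, float] = (30.0, 400.0)
    disturbance_amplitude: float = 0.06
    noisy_wind_range: tuple[float, float] = (4.0, 10.0)
    amplitude_jitter: tuple[float, float] = (0.5, 1.5)
    chunk_seconds: float = 5.0
    max_chunks: int = 200
    scatterers_per_gauge: int = 20
    instrument_noise: InstrumentNoise = field(default_factory=InstrumentNoise)


def generate_labeled_dataset(
    n_per_class: int = 2000,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    layout: FiberLayout | None = None,
    pulse: PulseConfig | None = None,
) -> list[LabeledExample]:
    """Simulate until the class budget is met: ``n_per_class`` infested,
    ``n_per_class/2`` calm and ``n_per_class/2`` noisy examples.

    Every scene chunk uses a fresh fiber (scatterer) realization, jittered
    source amplitudes and a wind speed drawn from ``noisy_wind_range``, so
    classifiers must learn the acoustic signal structure rather than the
    speckle fingerprint of a handful of tree locations.  Deterministic in
    ``seed``; all chunk randomness comes from derived sub-seeds.
    """
    cfg = config or GeneratorConfig()
    pulse = pulse or PulseConfig()
    layout = layout or default_farm_layout()
    n_calm = n_noisy = n_per_class // 2
    budgets = {"infested": n_per_class, "calm": n_calm, "noisy": n_noisy}
    got: dict[str, list[LabeledExample]] = {k: [] for k in budgets}

    healthy_layout = FiberLayout(
        fiber_length=layout.fiber_length,
        spatial_sampling=layout.spatial_sampling,
        group_index=layout.group_index,
        trees=tuple(
            TreeSpec(t.tree_id, t.start_position, t.loop_length, "healthy") for t in layout.trees
        ),
    )
    noise_bins = sample_noise_bins(layout, seed=seed)

    infested_ids = [t.tree_id for t in layout.trees if t.condition == "infested"]
    all_ids = [t.tree_id for t in layout.trees]
    jlo, jhi = cfg.amplitude_jitter

    def controlled_scene(rng: np.random.Generator) -> AcousticScene:
        return AcousticScene(
            duration=cfg.chunk_seconds,
            larvae_sources=tuple(
                BurstSource(tid, cfg.larvae.burst_rate, cfg.larvae.burst_duration,
                            cfg.larvae.band,
                            cfg.larvae.amplitude * rng.uniform(jlo, jhi),
                            cfg.larvae.duty_pattern)
                for tid in infested_ids
            ),
            instrument_noise=cfg.instrument_noise,
        )

    def noisy_scene(rng: np.random.Generator) -> AcousticScene:
        return AcousticScene(
            duration=cfg.chunk_seconds,
            disturbance_sources=tuple(
                BurstSource(tid, burst_rate=3.0, burst_duration=0.08,
                            band=cfg.disturbance_band,
                            amplitude=cfg.disturbance_amplitude * rng.uniform(jlo, jhi),
                            duty_pattern=(3.0, 1.0))
                for tid in all_ids
            ),
            wind=WindModel(speed_mph=rng.uniform(*cfg.noisy_wind_range)),
            instrument_noise=cfg.instrument_noise,
        )

    def need(kind: str) -> bool:
        return len(got[kind]) < budgets[kind]

    for chunk in range(cfg.max_chunks):
        if not any(need(k) for k in budgets):
            break
        chunk_seed = int(np.random.SeedSequence((seed, 9, chunk)).generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(chunk_seed + 2)
        if need("infested") or need("calm"):
            state = realize_fiber(layout, pulse, seed=chunk_seed + 3,
                                  scatterers_per_gauge=cfg.scatterers_per_gauge)
            ts = synthesize_traces(state, controlled_scene(rng), pulse, seed=chunk_seed)
            for ex in extract_tree_examples(ts, layout, noise_bins):
                if need(ex.sublabel):
                    got[ex.sublabel].append(ex)
        if need("noisy"):
            healthy_state = realize_fiber(healthy_layout, pulse, seed=chunk_seed + 4,
                                          scatterers_per_gauge=cfg.scatterers_per_gauge)
            ts = synthesize_traces(healthy_state, noisy_scene(rng), pulse, seed=chunk_seed + 1)
            for ex in extract_tree_examples(ts, healthy_layout, noise_bins):
                if ex.sublabel == "noisy" and need("noisy"):
                    got["noisy"].append(ex)
    shortfall = {k: budgets[k] - len(got[k]) for k in budgets if need(k)}
    if shortfall:
        raise RuntimeError(f"dataset generation exhausted max_chunks with shortfall {shortfall}")
    examples = got["infested"] + got["calm"] + got["noisy"]
    order = np.random.default_rng(seed).permutation(len(examples))
    return [examples[i] for i in order]


def examples_to_arrays(
    examples: Iterable[LabeledExample],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack examples into (X_temporal, X_spectral, y_label, y_sublabel) arrays."""
    exs = list(examples)
    xt = np.stack([ex.temporal.matrix for ex in exs]).astype(np.float32)
    xs = np.stack([ex.spectral.matrix for ex in exs]).astype(np.float32)
    y = np.array([ex.label for ex in exs])
    sub = np.array([ex.sublabel for ex in exs])
    return xt, xs, y, sub
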