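"""Synthetic digital kidney phantoms and mixture series.

Three generators make every pipeline stage testable without scanner data:

* :func:`generate_layered_image` — a schematic kidney slice built from
  three nested elliptical layers (cortex ring, outer-medulla ring,
  inner-medulla core), each with a known true TVF and short-component T2.
  Every voxel's echo train is composed with the EPG simulator from its
  layer's two-pool parameters, plus white Gaussian noise.
* :func:`generate_mixture_series` — single-voxel signals mixing a long-T2
  (fluid-like) and short-T2 (tissue-like) decay at prescribed fractions,
  emulating a two-tube phantom whose signals are scaled and summed to
  synthesize known tubule-water fractions.
* :func:`generate_intervention_series` — a time series of layered images
  whose per-layer TVFs are scaled by a programmable effect profile
  (diuretic-like TVF increase), with independent noise per time point.

Default layer TVFs (29.8 / 42.6 / 76.4 % for cortex / outer medulla /
inner medulla) correspond to baseline values in healthy rat kidney.  The
per-layer short-component T2 defaults (38 / 35 / 30 ms) are conventions
chosen inside the physiologic 10-40 ms band of the parenchyma/blood pool;
mono-exponential composite layer T2 values reported in vivo are weighted
mixtures of both pools and deliberately not used here.  Layer geometry is
schematic, sufficient for testing voxel-wise independence and ROI medians,
and contains no partial-volume transition zones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cartography import LAYER_LABELS, MultiEchoImage, ParametricMap, ROILabels
from .epg import compose_signal
from .protocols import MESEProtocol, SHORT_TE
from .signal import CompartmentSet, DecaySignal

__all__ = [
    "LayerSpec",
    "PhantomSpec",
    "InterventionProfile",
    "generate_layered_image",
    "generate_mixture_series",
    "generate_intervention_series",
]

_LAYERS = ("cortex", "outer_medulla", "inner_medulla")


@dataclass(frozen=True)
class LayerSpec:
    """True two-pool parameters of one renal layer."""

    tvf_percent: float
    t2_short_ms: float

    def __post_init__(self) -> None:
        if not 0.0 < self.tvf_percent < 100.0:
            raise ValueError(f"layer TVF must be in (0, 100), got {self.tvf_percent}")
        if self.t2_short_ms <= 0:
            raise ValueError("t2_short_ms must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue parameters and acquisition of the digital kidney.

    The three layers are nested ellipses centred on the grid: the cortex
    is the ring between the outer and middle ellipse, the outer medulla
    the ring between the middle and inner ellipse, and the inner medulla
    the core.  Semi-axes are fractions of the half-grid size and must be
    strictly decreasing.
    """

    shape: tuple[int, int] = (64, 64)
    layer_radii: tuple[float, float, float] = (0.9, 0.62, 0.34)
    layers: dict[str, LayerSpec] = field(
        default_factory=lambda: {
            "cortex": LayerSpec(tvf_percent=29.8, t2_short_ms=38.0),
            "outer_medulla": LayerSpec(tvf_percent=42.6, t2_short_ms=35.0),
            "inner_medulla": LayerSpec(tvf_percent=76.4, t2_short_ms=30.0),
        }
    )
    t2_long_ms: float = 150.0
    t1_short_ms: float = 1500.0
    t1_long_ms: float = 2500.0
    m0: float = 1.0
    snr: float = 100.0
    protocol: MESEProtocol = SHORT_TE
    rng_seed: int = 0

    def __post_init__(self) -> None:
        r = self.layer_radii
        if not (1.0 >= r[0] > r[1] > r[2] > 0.0):
            raise ValueError("layer radii must be strictly decreasing in (0, 1]")
        if set(self.layers) != set(_LAYERS):
            raise ValueError(f"layers must be exactly {_LAYERS}")
        if self.snr <= 0:
            raise ValueError("snr must be > 0 (use numpy.inf for noiseless)")

    def layer_masks(self) -> dict[str, np.ndarray]:
        """Disjoint nested elliptical masks for the three layers."""
        rows, cols = self.shape
        y, x = np.mgrid[0:rows, 0:cols]
        cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
        ry, rx = rows / 2.0, cols / 2.0

        def ellipse(frac: float) -> np.ndarray:
            return ((y - cy) / (frac * ry)) ** 2 + ((x - cx) / (frac * rx)) ** 2 <= 1.0

        outer, mid, inner = (ellipse(f) for f in self.layer_radii)
        masks = {
            "cortex": outer & ~mid,
            "outer_medulla": mid & ~inner,
            "inner_medulla": inner,
        }
        for name, m in masks.items():
            if not m.any():
                raise ValueError(f"layer {name!r} is empty; enlarge the grid or radii")
        return masks

    def layer_pools(self, layer: str, tvf_override: float | None = None) -> CompartmentSet:
        spec = self.layers[layer]
        return CompartmentSet.two_pool(
            tvf_percent=spec.tvf_percent if tvf_override is None else tvf_override,
            t2_short_ms=spec.t2_short_ms,
            t2_long_ms=self.t2_long_ms,
            m0=self.m0,
            t1_short_ms=self.t1_short_ms,
            t1_long_ms=self.t1_long_ms,
        )


def _render(
    spec: PhantomSpec,
    tvf_by_layer: dict[str, float],
    rng: np.random.Generator,
) -> tuple[MultiEchoImage, ROILabels, dict[str, ParametricMap]]:
    """Compose the noiseless layer decays, broadcast and add noise."""
    masks = spec.layer_masks()
    rows, cols = spec.shape
    n_echoes = spec.protocol.n_echoes
    data = np.zeros((rows, cols, n_echoes))
    labels = np.zeros((rows, cols), dtype=np.int16)
    truth_tvf = np.full((rows, cols), np.nan)
    truth_t2s = np.full((rows, cols), np.nan)
    kidney = np.zeros((rows, cols), dtype=bool)
    for layer, mask in masks.items():
        clean = compose_signal(
            spec.layer_pools(layer, tvf_by_layer[layer]), spec.protocol
        ).amplitude
        data[mask] = clean
        labels[mask] = LAYER_LABELS[layer]
        truth_tvf[mask] = tvf_by_layer[layer]
        truth_t2s[mask] = spec.layers[layer].t2_short_ms
        kidney |= mask
        if np.isfinite(spec.snr):
            sigma = float(np.mean(clean)) / spec.snr
            data[mask] += rng.normal(0.0, sigma, size=(int(mask.sum()), n_echoes))
    image = MultiEchoImage(data=data, protocol=spec.protocol, mask=kidney)
    truth = {
        "tvf": ParametricMap(values=truth_tvf, valid=kidney, units="percent"),
        "t2_short": ParametricMap(values=truth_t2s, valid=kidney, units="ms"),
    }
    return image, ROILabels(labels=labels), truth


def generate_layered_image(
    spec: PhantomSpec,
    rng: "int | np.random.Generator | None" = None,
) -> tuple[MultiEchoImage, ROILabels, dict[str, ParametricMap]]:
    """Render the layered kidney phantom.

    Returns the noisy multi-echo image (masked to the kidney), the layer
    label map, and ground-truth TVF / T2_short maps for scoring.
    Deterministic for a given seed (``rng=None`` uses ``spec.rng_seed``).
    """
    if rng is None:
        rng = spec.rng_seed
    generator = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    tvfs = {layer: spec.layers[layer].tvf_percent for layer in _LAYERS}
    return _render(spec, tvfs, generator)


def generate_mixture_series(
    fractions,
    t2_pair_ms: tuple[float, float] = (150.0, 30.0),
    protocol: MESEProtocol = SHORT_TE,
    snr: float = 100.0,
    rng: "int | np.random.Generator | None" = None,
    t1_pair_ms: tuple[float, float] = (2500.0, 1500.0),
) -> tuple[list[DecaySignal], np.ndarray]:
    """Two-decay mixtures at prescribed long-component fractions.

    Each signal is ``f * long_decay + (1 - f) * short_decay`` plus noise,
    mirroring a tube-phantom experiment in which the fluid and tissue tube
    signals are rescaled and summed to synthesize a voxel of known tubule
    water fraction ``f``.  Returns the signals and the ground-truth TVF in
    percent (``100 * f``).
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.ndim != 1 or fr.size == 0:
        raise ValueError("fractions must be a nonempty 1-D sequence")
    if np.any((fr < 0) | (fr > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    generator = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    t2_long, t2_short = t2_pair_ms
    signals = []
    from .epg import add_gaussian_noise, epg_echo_amplitudes  # local import avoids cycle noise

    long_decay = epg_echo_amplitudes(t2_long, t1_pair_ms[0], protocol)
    short_decay = epg_echo_amplitudes(t2_short, t1_pair_ms[1], protocol)
    te = protocol.echo_times_ms
    for f in fr:
        clean = DecaySignal(te_ms=te, amplitude=f * long_decay + (1.0 - f) * short_decay)
        signals.append(add_gaussian_noise(clean, snr, generator) if np.isfinite(snr) else clean)
    return signals, 100.0 * fr


@dataclass(frozen=True)
class InterventionProfile:
    """Multiplicative per-layer TVF trajectory over the time series.

    ``multipliers`` maps each layer to a positive factor per time point
    (1.0 at baseline).  ``baseline_idx`` / ``interval1_idx`` /
    ``interval2_idx`` describe the experiment's phases; defaults mirror a
    bolus intervention followed by a volume-replacement infusion
    (3 baseline points, 4 first-interval points, 3 second-interval points).
    """

    multipliers: dict[str, np.ndarray]
    baseline_idx: tuple[int, ...] = (0, 1, 2)
    interval1_idx: tuple[int, ...] = (3, 4, 5, 6)
    interval2_idx: tuple[int, ...] = (7, 8, 9)

    def __post_init__(self) -> None:
        mult = {k: np.asarray(v, dtype=float) for k, v in self.multipliers.items()}
        lengths = {v.size for v in mult.values()}
        if set(mult) != set(_LAYERS):
            raise ValueError(f"multipliers must cover exactly {_LAYERS}")
        if len(lengths) != 1:
            raise ValueError("all multiplier series must have equal length")
        for k, v in mult.items():
            if np.any(v <= 0):
                raise ValueError(f"multipliers must be positive (layer {k!r})")
        object.__setattr__(self, "multipliers", mult)

    @property
    def n_timepoints(self) -> int:
        return next(iter(self.multipliers.values())).size

    @classmethod
    def step(
        cls,
        effects: dict[str, float],
        n_baseline: int = 3,
        n_interval1: int = 4,
        n_interval2: int = 3,
        effects_interval2: dict[str, float] | None = None,
    ) -> "InterventionProfile":
        """Step profile: 1.0 at baseline, then a constant factor per layer."""
        e2 = effects if effects_interval2 is None else effects_interval2
        n = n_baseline + n_interval1 + n_interval2
        mult = {}
        for layer in _LAYERS:
            series = np.ones(n)
            series[n_baseline : n_baseline + n_interval1] = effects[layer]
            series[n_baseline + n_interval1 :] = e2[layer]
            mult[layer] = series
        return cls(
            multipliers=mult,
            baseline_idx=tuple(range(n_baseline)),
            interval1_idx=tuple(range(n_baseline, n_baseline + n_interval1)),
            interval2_idx=tuple(range(n_baseline + n_interval1, n)),
        )


def generate_intervention_series(
    spec: PhantomSpec,
    profile: InterventionProfile,
    rng: "int | np.random.Generator | None" = None,
) -> tuple[list[MultiEchoImage], ROILabels, np.ndarray]:
    """Layered images over time with per-layer TVFs scaled by the profile.

    Noise is drawn independently per time point from a generator seeded by
    the master seed.  Returns the image series, the (static) label map and
    the true per-layer TVF matrix of shape ``(n_layers, n_timepoints)`` in
    the order cortex, outer medulla, inner medulla.
    """
    if rng is None:
        rng = spec.rng_seed
    generator = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    truth = np.empty((len(_LAYERS), profile.n_timepoints))
    for i, layer in enumerate(_LAYERS):
        truth[i] = spec.layers[layer].tvf_percent * profile.multipliers[layer]
    if np.any(truth >= 100.0):
        raise ValueError("a profile multiplier pushes a layer TVF to >= 100 %")
    images = []
    labels = None
    for t in range(profile.n_timepoints):
        tvfs = {layer: float(truth[i, t]) for i, layer in enumerate(_LAYERS)}
        image, labels, _ = _render(spec, tvfs, generator)
        images.append(image)
    return images, labels, truth
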