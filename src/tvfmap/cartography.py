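"""Voxel-wise parametric mapping and ROI summaries for renal MRI.

Maps of TVF (percent), T2, T2* and T2' (ms) are computed by independent
per-voxel fits of the echo dimension — there is no spatial coupling, so
mapping commutes with any voxel permutation.  ROI statistics use the
median over valid voxels per renal layer (cortex, outer medulla, inner
medulla); voxels whose fit failed propagate as missing values and are
excluded.  Time courses of layer medians are summarized as relative
changes versus the mean of the baseline time points, averaged within
post-intervention interval 1 (default 4 points) and interval 2 (default
3 points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import FitConstraints, fit_biexp_batch, fit_monoexp_batch, t2prime
from .protocols import MESEProtocol, MGEProtocol

__all__ = [
    "LAYER_LABELS",
    "MultiEchoImage",
    "ParametricMap",
    "ROILabels",
    "LayerTimeCourse",
    "map_voxelwise",
    "t2prime_map",
    "roi_median",
    "interval_summary",
]

#: Integer codes of the renal-layer label map.
LAYER_LABELS = {"background": 0, "cortex": 1, "outer_medulla": 2, "inner_medulla": 3}
_LAYERS = ("cortex", "outer_medulla", "inner_medulla")


@dataclass(frozen=True)
class MultiEchoImage:
    """A 2-D slice with an echo dimension: array indexed (row, col, echo)."""

    data: np.ndarray
    protocol: "MESEProtocol | MGEProtocol"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"data must be (rows, cols, echoes), got shape {data.shape}")
        if data.shape[-1] != self.protocol.n_echoes:
            raise ValueError(
                f"echo dimension {data.shape[-1]} does not match protocol "
                f"n_echoes {self.protocol.n_echoes}"
            )
        object.__setattr__(self, "data", data)
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != data.shape[:2]:
                raise ValueError(
                    f"mask shape {mask.shape} does not match image shape {data.shape[:2]}"
                )
            object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def effective_mask(self) -> np.ndarray:
        return np.ones(self.shape, dtype=bool) if self.mask is None else self.mask


@dataclass(frozen=True)
class ParametricMap:
    """A fitted parameter per voxel plus a validity mask and a units label."""

    values: np.ndarray
    valid: np.ndarray
    units: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        valid = np.asarray(self.valid, dtype=bool)
        if values.shape != valid.shape:
            raise ValueError("values and valid must share a shape")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid", valid)

    def masked(self) -> np.ndarray:
        """Values with invalid voxels as NaN."""
        return np.where(self.valid, self.values, np.nan)


@dataclass(frozen=True)
class ROILabels:
    """Integer label map over {background, cortex, outer_medulla, inner_medulla}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        if not np.isin(labels, list(LAYER_LABELS.values())).all():
            raise ValueError(f"labels must come from {LAYER_LABELS}")
        object.__setattr__(self, "labels", labels)

    def region(self, layer: str) -> np.ndarray:
        return self.labels == LAYER_LABELS[layer]


def map_voxelwise(
    image: MultiEchoImage,
    model: str,
    constraints: FitConstraints = FitConstraints(),
) -> dict[str, ParametricMap]:
    """Fit every in-mask voxel independently and return parametric maps.

    Parameters
    ----------
    image : MultiEchoImage
    model : {"biexp_tvf", "mono_t2", "mono_t2star"}
        ``biexp_tvf`` and ``mono_t2`` require a spin-echo (MESE) protocol,
        ``mono_t2star`` a gradient-echo (MGE) protocol.
    constraints : FitConstraints
        Used by the bi-exponential model only.

    Returns
    -------
    dict of ParametricMap
        For ``biexp_tvf``: keys ``tvf`` (percent), ``t2_short`` (ms) and
        ``residual``.  For the mono models: ``t2`` or ``t2star`` (ms),
        ``s0`` and ``residual``.  Out-of-mask and failed voxels are
        invalid.
    """
    if model in ("biexp_tvf", "mono_t2"):
        if not isinstance(image.protocol, MESEProtocol):
            raise ValueError(f"model {model!r} requires a spin-echo (MESE) protocol")
    elif model == "mono_t2star":
        if not isinstance(image.protocol, MGEProtocol):
            raise ValueError("model 'mono_t2star' requires a gradient-echo (MGE) protocol")
    else:
        raise ValueError(f"unknown model {model!r}")

    mask = image.effective_mask()
    te = image.protocol.echo_times_ms
    voxels = image.data[mask]  # (n_voxels, n_echoes)
    shape = image.shape

    def to_map(flat: np.ndarray, ok: np.ndarray, units: str) -> ParametricMap:
        values = np.full(shape, np.nan)
        valid = np.zeros(shape, dtype=bool)
        values[mask] = flat
        valid[mask] = ok
        return ParametricMap(values=values, valid=valid, units=units)

    if voxels.shape[0] == 0:
        empty = np.zeros(shape, dtype=bool)
        nanmap = ParametricMap(np.full(shape, np.nan), empty, "ms")
        return {"tvf": nanmap} if model == "biexp_tvf" else {"t2": nanmap}

    if model == "biexp_tvf":
        res = fit_biexp_batch(te, voxels, constraints)
        ok = res["valid"]
        return {
            "tvf": to_map(np.clip(res["tvf_percent"], 0.0, 100.0), ok, "percent"),
            "t2_short": to_map(res["t2_short_ms"], ok, "ms"),
            "residual": to_map(res["residual_norm"], ok, "a.u."),
        }
    res = fit_monoexp_batch(te, voxels)
    ok = res["valid"]
    key = "t2" if model == "mono_t2" else "t2star"
    return {
        key: to_map(res["t2_ms"], ok, "ms"),
        "s0": to_map(res["s0"], ok, "a.u."),
        "residual": to_map(res["residual_norm"], ok, "a.u."),
    }


def t2prime_map(t2_map: ParametricMap, t2star_map: ParametricMap) -> ParametricMap:
    """Voxel-wise T2' from aligned T2 and T2* maps (1/T2* = 1/T2 + 1/T2').

    Valid only where both inputs are valid and T2* < T2; other voxels are
    marked invalid (equality would mean infinite T2').
    """
    if t2_map.values.shape != t2star_map.values.shape:
        raise ValueError(
            f"shape mismatch: {t2_map.values.shape} vs {t2star_map.values.shape}"
        )
    both = t2_map.valid & t2star_map.valid
    with np.errstate(invalid="ignore"):
        physical = both & (t2star_map.values < t2_map.values) & (t2star_map.values > 0)
        values = np.full(t2_map.values.shape, np.nan)
        values[physical] = 1.0 / (
            1.0 / t2star_map.values[physical] - 1.0 / t2_map.values[physical]
        )
    return ParametricMap(values=values, valid=physical, units="ms")


def roi_median(pmap: ParametricMap, labels: ROILabels) -> dict[str, float]:
    """Median map value over the valid voxels of each renal layer.

    Layers without any valid voxel yield NaN.
    """
    if labels.labels.shape != pmap.values.shape:
        raise ValueError("label map and parametric map shapes differ")
    out = {}
    for layer in _LAYERS:
        sel = labels.region(layer) & pmap.valid
        out[layer] = float(np.median(pmap.values[sel])) if sel.any() else float("nan")
    return out


@dataclass(frozen=True)
class LayerTimeCourse:
    """Per-layer median values over time plus the interval structure.

    ``values`` maps a layer name to a 1-D series of per-time-point medians.
    Index sets select the baseline and the two post-intervention intervals;
    they must be disjoint and inside the series.
    """

    values: dict[str, np.ndarray]
    baseline_idx: tuple[int, ...]
    interval1_idx: tuple[int, ...]
    interval2_idx: tuple[int, ...]

    def __post_init__(self) -> None:
        values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        lengths = {v.size for v in values.values()}
        if len(lengths) != 1:
            raise ValueError("all layer series must have equal length")
        n = lengths.pop()
        sets = [set(self.baseline_idx), set(self.interval1_idx), set(self.interval2_idx)]
        if not self.baseline_idx:
            raise ValueError("baseline index set must be nonempty")
        union = set().union(*sets)
        if len(union) != sum(len(s) for s in sets):
            raise ValueError("baseline/interval index sets must be disjoint")
        if union and (min(union) < 0 or max(union) >= n):
            raise ValueError("index sets must lie within the series")
        object.__setattr__(self, "values", values)


def interval_summary(tc: LayerTimeCourse) -> dict[str, dict[str, float]]:
    """Baseline mean and mean relative change per interval, per layer.

    Each post-baseline time point is expressed as a percent change versus
    the mean of the baseline points, then averaged within each interval.
    """
    out = {}
    for layer, series in tc.values.items():
        base = series[list(tc.baseline_idx)]
        if np.any(base <= 0):
            raise ValueError(f"nonpositive baseline value in layer {layer!r}")
        base_mean = float(np.mean(base))
        summary = {"baseline_mean": base_mean}
        for name, idx in (
            ("interval1_mean_relative_change_percent", tc.interval1_idx),
            ("interval2_mean_relative_change_percent", tc.interval2_idx),
        ):
            if idx:
                vals = series[list(idx)]
                summary[name] = float(np.mean(100.0 * (vals - base_mean) / base_mean))
            else:
                summary[name] = float("nan")
        out[layer] = summary
    return out
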