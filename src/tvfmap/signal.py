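"""Core signal containers: single-voxel decay curves and voxel compartment sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DecaySignal", "Compartment", "CompartmentSet"]


@dataclass(frozen=True)
class DecaySignal:
    """A sampled decay curve for one voxel or ROI.

    Attributes
    ----------
    te_ms : ndarray
        Strictly increasing echo times in ms.
    amplitude : ndarray
        Signal amplitude at each echo time (arbitrary units).
    """

    te_ms: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        te = np.asarray(self.te_ms, dtype=float)
        amp = np.asarray(self.amplitude, dtype=float)
        if te.ndim != 1 or amp.ndim != 1:
            raise ValueError("te_ms and amplitude must be 1-D")
        if te.shape != amp.shape:
            raise ValueError(
                f"length mismatch: {te.shape[0]} echo times, {amp.shape[0]} amplitudes"
            )
        if te.size == 0:
            raise ValueError("empty signal")
        if not np.all(np.diff(te) > 0):
            raise ValueError("te_ms must be strictly increasing")
        object.__setattr__(self, "te_ms", te)
        object.__setattr__(self, "amplitude", amp)

    def __len__(self) -> int:
        return self.te_ms.size


@dataclass(frozen=True)
class Compartment:
    """One water compartment: relaxation times plus its weight in the voxel."""

    t2_ms: float
    t1_ms: float
    weight: float

    def __post_init__(self) -> None:
        if self.t2_ms <= 0:
            raise ValueError(f"t2_ms must be > 0, got {self.t2_ms}")
        if self.t1_ms <= 0:
            raise ValueError(f"t1_ms must be > 0, got {self.t1_ms}")
        if self.weight < 0:
            raise ValueError(f"weight must be >= 0, got {self.weight}")


@dataclass(frozen=True)
class CompartmentSet:
    """A multi-compartment voxel model: overall scale M0 plus compartments.

    The kidney model uses two compartments: a short-T2 pool
    (parenchyma + blood, T2 roughly 10-40 ms) and a long-T2 pool
    (tubular fluid, T2 around 150 ms). Weights are the compartment
    fractions D_j; they need not sum to one (M0 carries the overall scale).
    """

    m0: float
    compartments: tuple[Compartment, ...]

    def __post_init__(self) -> None:
        comps = tuple(self.compartments)
        if len(comps) == 0:
            raise ValueError("at least one compartment is required")
        object.__setattr__(self, "compartments", comps)

    @classmethod
    def two_pool(
        cls,
        tvf_percent: float,
        t2_short_ms: float,
        t2_long_ms: float,
        m0: float = 1.0,
        t1_short_ms: float = 1500.0,
        t1_long_ms: float = 2500.0,
    ) -> "CompartmentSet":
        """Build the standard two-pool kidney voxel.

        ``tvf_percent`` is the tubular volume fraction: the weight of the
        long-T2 (fluid) pool as a percentage of the total weight.
        """
        if not 0.0 <= tvf_percent <= 100.0:
            raise ValueError(f"tvf_percent must be in [0, 100], got {tvf_percent}")
        f = tvf_percent / 100.0
        return cls(
            m0=m0,
            compartments=(
                Compartment(t2_ms=t2_long_ms, t1_ms=t1_long_ms, weight=f),
                Compartment(t2_ms=t2_short_ms, t1_ms=t1_short_ms, weight=1.0 - f),
            ),
        )
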