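"""Extended phase graph (EPG) simulation of multi-echo spin-echo trains.

The EPG formalism tracks the magnetization of a voxel as a ladder of
configuration states ``(F+(k), F-(k), Z(k))`` indexed by the dephasing
order ``k``.  Refocusing pulses with flip angles below 180° split the
magnetization across states and create stimulated-echo pathways, so the
echo-train amplitude of a CPMG experiment deviates from the ideal
mono-exponential ``exp(-TE/T2)`` decay.  At exactly 180° the formalism
collapses to the ideal spin-echo case and the decay is mono-exponential.

Conventions
-----------
* CPMG phase convention: the excitation pulse is applied about y, the
  refocusing pulses about x, so the refocusing axis is parallel to the
  excited magnetization and echo amplitudes are real and nonnegative.
* Ideal crusher gradients: one unit of gradient dephasing per half
  inter-echo interval; no diffusion.
* Longitudinal relaxation with T1 recovery acts between pulses; it feeds
  stimulated-echo pathways.  Steady-state (TR) saturation is not modelled:
  each train starts from full longitudinal magnetization, so a uniform
  steady-state scale is absorbed into M0.

Gradient-echo (T2*) signals need no phase graph — a single excitation per
TR samples a free induction decay — and are modelled as mono-exponential.
"""

from __future__ import annotations

import numbers

import numpy as np

from .protocols import MESEProtocol, MGEProtocol
from .signal import CompartmentSet, DecaySignal

__all__ = [
    "epg_echo_amplitudes",
    "fid_echo_amplitudes",
    "compose_signal",
    "add_gaussian_noise",
]


def _rf_matrix(flip_deg: float, phase_deg: float) -> np.ndarray:
    """EPG transition matrix of an RF pulse acting on (F+(k), F-(k), Z(k))."""
    a = np.deg2rad(flip_deg)
    p = np.deg2rad(phase_deg)
    cos_half2 = np.cos(a / 2.0) ** 2
    sin_half2 = np.sin(a / 2.0) ** 2
    sina = np.sin(a)
    eip = np.exp(1j * p)
    return np.array(
        [
            [cos_half2, np.exp(2j * p) * sin_half2, -1j * eip * sina],
            [np.exp(-2j * p) * sin_half2, cos_half2, 1j * np.conj(eip) * sina],
            [-0.5j * np.conj(eip) * sina, 0.5j * eip * sina, np.cos(a)],
        ],
        dtype=complex,
    )


def epg_echo_amplitudes(
    t2_ms: float,
    t1_ms: float,
    protocol: MESEProtocol,
    n_states: int | None = None,
) -> np.ndarray:
    """Simulate unit-scale CPMG echo amplitudes for one relaxation species.

    Parameters
    ----------
    t2_ms, t1_ms : float
        Transverse and longitudinal relaxation times in ms.
    protocol : MESEProtocol
        Echo-train timing and flip angles.  Echo ``k`` is evaluated at
        ``TE_k = te_first + (k-1) * delta_te``.
    n_states : int, optional
        Number of configuration orders retained.  The default keeps every
        order a CPMG pathway can populate (``2 * n_echoes + 2``), which is
        exact for ideal crushers.

    Returns
    -------
    ndarray
        Echo amplitudes of length ``protocol.n_echoes``, each in [0, 1]
        relative to the magnetization excited at t = 0.  With a 180°
        refocusing flip this equals ``exp(-TE_k / t2_ms)`` exactly.
    """
    if not isinstance(protocol, MESEProtocol):
        raise TypeError(f"protocol must be a MESEProtocol, got {type(protocol).__name__}")
    if not (np.isfinite(t2_ms) and t2_ms > 0) and not np.isinf(t2_ms):
        raise ValueError(f"t2_ms must be > 0, got {t2_ms}")
    if t2_ms <= 0 or t1_ms <= 0:
        raise ValueError(f"relaxation times must be > 0, got t2={t2_ms}, t1={t1_ms}")

    n_echoes = protocol.n_echoes
    if n_states is None:
        n_states = 2 * n_echoes + 2
    if n_states < 2:
        raise ValueError("n_states must be >= 2")

    half_ms = protocol.delta_te_ms / 2.0
    e2 = np.exp(-half_ms / t2_ms)
    e1 = np.exp(-half_ms / t1_ms)

    fp = np.zeros(n_states, dtype=complex)
    fm = np.zeros(n_states, dtype=complex)
    z = np.zeros(n_states, dtype=complex)

    # Excitation about y from thermal equilibrium (M0 = 1).
    exc = np.deg2rad(protocol.excitation_flip_deg)
    fp[0] = np.sin(exc)
    fm[0] = np.conj(fp[0])
    z[0] = np.cos(exc)

    t_ref = _rf_matrix(protocol.refocusing_flip_deg, 0.0)

    def relax_and_shift() -> None:
        nonlocal fp, fm, z
        fp *= e2
        fm *= e2
        z *= e1
        z[0] += 1.0 - e1  # T1 recovery feeds the k = 0 longitudinal state
        fp[1:] = fp[:-1]
        fp[0] = np.conj(fm[1])
        fm[:-1] = fm[1:]
        fm[-1] = 0.0

    echoes = np.empty(n_echoes, dtype=float)
    for k in range(n_echoes):
        relax_and_shift()
        fp, fm, z = (
            t_ref[0, 0] * fp + t_ref[0, 1] * fm + t_ref[0, 2] * z,
            t_ref[1, 0] * fp + t_ref[1, 1] * fm + t_ref[1, 2] * z,
            t_ref[2, 0] * fp + t_ref[2, 1] * fm + t_ref[2, 2] * z,
        )
        relax_and_shift()
        echoes[k] = fp[0].real

    return echoes


def fid_echo_amplitudes(t2star_ms: float, protocol: MGEProtocol) -> np.ndarray:
    """Unit-scale gradient-echo amplitudes ``exp(-TE_k / T2*)``."""
    if not isinstance(protocol, MGEProtocol):
        raise TypeError(f"protocol must be an MGEProtocol, got {type(protocol).__name__}")
    if t2star_ms <= 0:
        raise ValueError(f"t2star_ms must be > 0, got {t2star_ms}")
    return np.exp(-protocol.echo_times_ms / t2star_ms)


def compose_signal(
    compartments: CompartmentSet,
    protocol: MESEProtocol | MGEProtocol,
) -> DecaySignal:
    """Compose the noiseless multi-compartment echo train.

    The voxel signal is the weighted sum of each compartment's echo-train
    amplitude, scaled by the overall magnetization M0:

        S(TE_k) = M0 * sum_j D_j * EPG(T2_j, T1_j; protocol)_k

    For a gradient-echo protocol the per-compartment amplitude is the
    mono-exponential FID decay instead of the EPG train.
    """
    te = protocol.echo_times_ms
    total = np.zeros_like(te, dtype=float)
    for comp in compartments.compartments:
        if comp.weight == 0.0:
            continue
        if isinstance(protocol, MESEProtocol):
            amp = epg_echo_amplitudes(comp.t2_ms, comp.t1_ms, protocol)
        else:
            amp = fid_echo_amplitudes(comp.t2_ms, protocol)
        total += comp.weight * amp
    return DecaySignal(te_ms=te, amplitude=compartments.m0 * total)


def add_gaussian_noise(
    signal: DecaySignal,
    snr: float,
    rng: "int | np.random.Generator | None" = None,
) -> DecaySignal:
    """Add white Gaussian noise at a prescribed signal-to-noise ratio.

    The noise level follows the magnitude-image convention
    ``SNR = mean(s) / sigma``: the standard deviation is the mean of the
    noiseless echo-train amplitudes divided by ``snr``.  Noise is additive,
    real-valued, zero-mean and independent per echo (no magnitude/Rician
    transformation).

    Parameters
    ----------
    signal : DecaySignal
        Noiseless signal.
    snr : float
        Signal-to-noise ratio (> 0).  ``numpy.inf`` returns the signal
        unchanged.
    rng : int, numpy.random.Generator, optional
        Seed or generator; a given seed yields a reproducible draw.
    """
    if not isinstance(snr, numbers.Real) or np.isnan(snr) or snr <= 0:
        raise ValueError(f"snr must be > 0, got {snr}")
    if np.isinf(snr):
        return DecaySignal(te_ms=signal.te_ms, amplitude=signal.amplitude.copy())
    generator = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sigma = float(np.mean(signal.amplitude)) / float(snr)
    noisy = signal.amplitude + generator.normal(0.0, sigma, size=signal.amplitude.shape)
    return DecaySignal(te_ms=signal.te_ms, amplitude=noisy)
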