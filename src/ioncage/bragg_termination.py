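"""Bragg termination: self-gating of diffraction by accumulating disorder.

As atomic displacements grow during the pulse, high-resolution Bragg
intensities fade — the crystal effectively gates its own diffraction.
This is modelled by an effective B-factor growing with the third power of
time, ``B_eff(t) = b_end * (t / T)**3``, applied to reference (single
pulse) intensities with the standard crystallographic Debye-Waller
convention ``exp(-2 B s**2)`` (``s = sinθ/λ``) at each of N uniformly
spaced time points and averaged:

    I_out(s) = (1/N) * sum_p I_in(s) * exp(-2 * B_eff(t_p) * s**2).

Wilson-plot fitting and the cumulative intensity distribution N(z)
(vs the ideal acentric ``1 - exp(-z)``) quantify the resulting damage
signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import ReflectionSet

__all__ = [
    "BraggConfig",
    "b_eff",
    "attenuate",
    "wilson_fit",
    "cumulative_intensity_distribution",
    "bragg_report",
]


@dataclass
class BraggConfig:
    """Cubic-in-time effective B-factor schedule.

    ``b_end`` is B_eff at the end of the ``pulse_length`` window (125 Å²
    for thaumatin, 500 Å² for the gadolinium lysozyme complex, with the
    100 fs probe window); ``n_steps`` time points are spread uniformly on
    ``[0, pulse_length]``.  The exponent is fixed cubic.
    """

    b_end: float = 125.0  # Å²
    pulse_length: float = 100.0  # fs
    n_steps: int = 100
    exponent: int = 3

    def __post_init__(self) -> None:
        if self.b_end < 0:
            raise ValueError("b_end must be non-negative")
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")
        if self.exponent != 3:
            raise ValueError("the B_eff growth law is fixed cubic")


def b_eff(t: float, config: BraggConfig) -> float:
    """Effective B-factor (Å²) at time ``t`` within the pulse window."""
    if not (0.0 <= t <= config.pulse_length):
        raise ValueError("t must lie within [0, pulse_length]")
    return config.b_end * (t / config.pulse_length) ** 3


def attenuate(reflections: ReflectionSet, config: BraggConfig) -> ReflectionSet:
    """Apply the time-averaged cubic-B damping to a reflection set.

    Never increases any intensity; the damping is monotone in both
    ``b_end`` and resolution.
    """
    t = np.linspace(0.0, config.pulse_length, config.n_steps)
    b = config.b_end * (t / config.pulse_length) ** 3
    s2 = reflections.s**2
    factor = np.exp(-2.0 * b[:, None] * s2[None, :]).mean(axis=0)
    return ReflectionSet(
        s=reflections.s.copy(),
        intensity=reflections.intensity * factor,
        hkl=None if reflections.hkl is None else reflections.hkl.copy(),
    )


def _resolution_bins(s: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin assignment with ~equal reciprocal volume per bin (uniform s³)."""
    edges = np.quantile(s**3, np.linspace(0.0, 1.0, n_bins + 1)) ** (1.0 / 3.0)
    edges[0] -= 1e-12
    edges[-1] += 1e-12
    return np.clip(np.digitize(s, edges) - 1, 0, n_bins - 1)


def wilson_fit(reflections: ReflectionSet, n_bins: int = 20):
    """Wilson-plot fit: least squares of ``ln <I>_bin`` against ``s²``.

    Returns ``(wilson_b, scale)`` with ``slope = -2 * wilson_b``.  Bins
    with no usable intensity are excluded; fewer than two usable bins is
    an error.
    """
    s = reflections.s
    intensity = reflections.intensity
    bins = _resolution_bins(s, n_bins)
    s2_mean, log_mean = [], []
    for b in range(n_bins):
        sel = bins == b
        if not np.any(sel):
            continue
        mi = intensity[sel].mean()
        if mi <= 0:
            continue
        s2_mean.append((s[sel] ** 2).mean())
        log_mean.append(np.log(mi))
    if len(log_mean) < 2:
        raise ValueError("fewer than two usable resolution bins")
    slope, icept = np.polyfit(s2_mean, log_mean, 1)
    return float(-slope / 2.0), float(np.exp(icept))


def cumulative_intensity_distribution(
    reflections: ReflectionSet, n_z: int = 50, n_bins: int = 20
):
    """Empirical cumulative distribution N(z) of normalized intensities.

    Intensities are resolution-normalized (divided by their bin mean,
    equal-volume bins) so that ``z = I / <I>``; returns ``(z, N_emp,
    N_ideal)`` with the ideal acentric curve ``1 - exp(-z)``.
    """
    s = reflections.s
    intensity = reflections.intensity.astype(float).copy()
    bins = _resolution_bins(s, n_bins)
    z_values = np.empty_like(intensity)
    for b in range(n_bins):
        sel = bins == b
        if not np.any(sel):
            continue
        mean = intensity[sel].mean()
        z_values[sel] = intensity[sel] / mean if mean > 0 else 0.0
    z_grid = np.linspace(0.0, 5.0, n_z)
    n_emp = np.searchsorted(np.sort(z_values), z_grid, side="right") / len(
        z_values
    )
    n_ideal = 1.0 - np.exp(-z_grid)
    return z_grid, n_emp, n_ideal


def bragg_report(reflections: ReflectionSet, config: BraggConfig) -> dict:
    """JSON-ready damage report: input/output Wilson B and the N(z) table."""
    damped = attenuate(reflections, config)
    b_in, _ = wilson_fit(reflections)
    b_out, _ = wilson_fit(damped)
    z, n_emp, n_ideal = cumulative_intensity_distribution(damped)
    return {
        "b_end": config.b_end,
        "wilson_b_input": b_in,
        "wilson_b_output": b_out,
        "nz": {
            "z": z.tolist(),
            "empirical": n_emp.tolist(),
            "ideal_acentric": n_ideal.tolist(),
        },
    }
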