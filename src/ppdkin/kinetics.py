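"""Forward solution of the linear hydrogenation kinetics.

The network model is linear and time-invariant, so the concentration
vector is propagated exactly by the matrix exponential,

    c(t) = expm(K·t) · c0,

evaluated incrementally over the sampling grid (one exponential per
distinct time increment).  Closed-form cross-checks are provided for the
intermediates (the Bateman solution of a first-order series A → X → products)
and for the time at which an intermediate peaks; an adaptive Runge–Kutta
integrator (:func:`ode_oracle`) exists solely as an independent test oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .network import ReactionNetwork, build_rate_matrix

__all__ = [
    "ConcentrationProfile",
    "validate_initial_state",
    "validate_times",
    "simulate",
    "bateman_intermediate",
    "time_of_maximum",
    "ode_oracle",
]

#: relative tolerance below which two rates are treated as equal in the
#: Bateman closed form (numeric-cancellation guard)
EQUAL_RATE_RTOL = 1e-12


@dataclass
class ConcentrationProfile:
    """Sampled concentration–time data for the nine species.

    ``conc`` is a (n_times × 9) array in the fixed species order
    A,B,C,D,E,F,G,H,I; times are minutes.  ``meta`` records provenance
    (simulated or loaded, seed, noise level, generating constants).
    """

    times: np.ndarray
    conc: np.ndarray
    species: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        validate_times(self.times)
        if self.conc.shape != (self.times.size, len(self.species)):
            raise ValueError(
                f"conc shape {self.conc.shape} does not match "
                f"({self.times.size}, {len(self.species)})"
            )

    @property
    def n_times(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.conc, columns=list(self.species))
        frame.insert(0, "time_min", self.times)
        return frame

    def column(self, code: str) -> np.ndarray:
        return self.conc[:, self.species.index(code)]


def validate_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if not np.all(np.isfinite(times)):
        raise ValueError("times must be finite")
    if times[0] < 0:
        raise ValueError(f"times must be >= 0; first time is {times[0]}")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return times


def validate_initial_state(c0: Sequence[float] | np.ndarray, n_species: int = 9) -> np.ndarray:
    c0 = np.asarray(c0, dtype=float)
    if c0.shape != (n_species,):
        raise ValueError(f"initial state must have shape ({n_species},), got {c0.shape}")
    if np.any(c0 < 0) or not np.all(np.isfinite(c0)):
        raise ValueError("initial concentrations must be finite and >= 0")
    if not np.any(c0 > 0):
        raise ValueError("at least one initial concentration must be positive")
    return c0


def simulate(
    network: ReactionNetwork,
    k: Sequence[float] | np.ndarray,
    c0: Sequence[float] | np.ndarray,
    times: Sequence[float] | np.ndarray,
) -> ConcentrationProfile:
    """Exact propagation c(t) = expm(K·t)·c0 at each sampling time.

    The exponential is computed per distinct time increment (scaling and
    squaring, robust to repeated eigenvalues) and reused across a uniform
    grid, so simulation cost is essentially one 9×9 ``expm`` per unique Δt.
    """
    times = validate_times(times)
    c0 = validate_initial_state(c0, len(network.species))
    K = build_rate_matrix(network, k)

    out = np.empty((times.size, c0.size))
    propagators: dict[float, np.ndarray] = {}
    c = c0
    prev_t = 0.0
    for i, t in enumerate(times):
        dt = t - prev_t
        if dt > 0:
            P = propagators.get(dt)
            if P is None:
                P = expm(K * dt)
                propagators[dt] = P
            c = P @ c
        out[i] = c
        prev_t = t
    return ConcentrationProfile(
        times=times,
        conc=out,
        species=tuple(network.species),
        meta={"source": "simulate", "k": np.asarray(k, dtype=float).tolist()},
    )


def bateman_intermediate(
    k_in: float, k_out: float, k_parent_total: float, t: float | np.ndarray, c0: float = 1.0
) -> float | np.ndarray:
    """Closed-form concentration of an intermediate fed by first-order decay.

    For the series  A --(k_in, of total k_parent_total)--> X --(k_out)-->
    the intermediate obeys

        x(t) = c0·k_in·(exp(−k_out·t) − exp(−k_parent_total·t)) / (k_parent_total − k_out)

    with the l'Hôpital limit c0·k_in·t·exp(−k_out·t) when the two rates
    coincide within :data:`EQUAL_RATE_RTOL`.
    """
    for name, rate in (("k_in", k_in), ("k_out", k_out), ("k_parent_total", k_parent_total)):
        if rate < 0:
            raise ValueError(f"{name} must be >= 0, got {rate}")
    t = np.asarray(t, dtype=float)
    if abs(k_parent_total - k_out) < EQUAL_RATE_RTOL * max(k_parent_total, k_out, 1e-300):
        result = c0 * k_in * t * np.exp(-k_out * t)
    else:
        result = (
            c0 * k_in * (np.exp(-k_out * t) - np.exp(-k_parent_total * t))
            / (k_parent_total - k_out)
        )
    return result if result.ndim else float(result)


def time_of_maximum(k_out: float, k_parent_total: float) -> float | None:
    """Time (min) at which a first-order intermediate peaks.

    Returns ``None`` when no interior maximum exists: ``k_out = 0`` means the
    species only accumulates, ``k_parent_total = 0`` means nothing forms.
    """
    if k_out < 0 or k_parent_total < 0:
        raise ValueError("rates must be >= 0")
    if k_parent_total == 0 or k_out == 0:
        return None
    if abs(k_parent_total - k_out) < EQUAL_RATE_RTOL * max(k_parent_total, k_out):
        return 1.0 / k_parent_total
    return math.log(k_parent_total / k_out) / (k_parent_total - k_out)


def ode_oracle(
    network: ReactionNetwork,
    k: Sequence[float] | np.ndarray,
    c0: Sequence[float] | np.ndarray,
    times: Sequence[float] | np.ndarray,
) -> ConcentrationProfile:
    """Brute-force adaptive integration of dc/dt = K·c (test oracle only)."""
    times = validate_times(times)
    c0 = validate_initial_state(c0, len(network.species))
    K = build_rate_matrix(network, k)
    t_span = (0.0, float(times[-1]) if times[-1] > 0 else 1.0)
    sol = solve_ivp(
        lambda _t, c: K @ c,
        t_span,
        c0,
        t_eval=times,
        method="DOP853",
        rtol=1e-12,
        atol=1e-14,
    )
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return ConcentrationProfile(
        times=times,
        conc=sol.y.T.copy(),
        species=tuple(network.species),
        meta={"source": "ode_oracle"},
    )
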