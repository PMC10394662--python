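"""Synthetic concentration datasets emulating the batch hydrogenation runs.

The real experiment samples the reactor ten times over 0–360 min starting
from pure dione; measured concentrations scatter around the kinetic model
roughly in proportion to their magnitude.  The generator reproduces that
statistical structure: an exact forward simulation on the sampling grid,
followed by per-cell multiplicative (or additive) Gaussian noise, clipped
at zero because measured concentrations cannot be negative.  Defaults are
the study conditions: 10 equally spaced times on [0, 360] min, initial
state pure A = 1 (concentrations are normalised; first-order constants are
scale-invariant), reference rate constants as the generating truth and 2%
relative noise.  Seeds are recorded in the profile metadata so every
dataset is reproducible.

Also home to the dataset CSV format (header ``time_min,A,...,I``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import ConcentrationProfile, simulate, validate_initial_state, validate_times
from .network import REFERENCE_RATE_CONSTANTS, SPECIES, ReactionNetwork, default_network

__all__ = [
    "NoiseSpec",
    "ExperimentDesign",
    "generate_dataset",
    "read_dataset",
    "write_dataset",
    "SchemaError",
]

_NOISE_KINDS = ("none", "multiplicative_gaussian", "additive_gaussian")


class SchemaError(ValueError):
    """Dataset file does not match the expected CSV schema."""


@dataclass
class NoiseSpec:
    """Measurement-noise model applied cell-wise to the simulated profile.

    ``sigma`` is a fraction of the true value for ``multiplicative_gaussian``
    and an absolute concentration for ``additive_gaussian``.
    """

    kind: str = "multiplicative_gaussian"
    sigma: float = 0.02
    seed: int = 0
    clip_negative: bool = True

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ValueError(f"noise kind must be one of {_NOISE_KINDS}, got {self.kind!r}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


def _default_times() -> np.ndarray:
    return np.linspace(0.0, 360.0, 10)


def _default_c0() -> np.ndarray:
    c0 = np.zeros(len(SPECIES))
    c0[0] = 1.0
    return c0


@dataclass
class ExperimentDesign:
    """Sampling grid, initial charge and generating rate constants."""

    times: np.ndarray = field(default_factory=_default_times)
    c0: np.ndarray = field(default_factory=_default_c0)
    k_true: np.ndarray = field(default_factory=lambda: REFERENCE_RATE_CONSTANTS.copy())

    def __post_init__(self) -> None:
        self.times = validate_times(np.asarray(self.times, dtype=float))
        self.c0 = validate_initial_state(np.asarray(self.c0, dtype=float), len(SPECIES))
        self.k_true = np.asarray(self.k_true, dtype=float)


def generate_dataset(
    design: ExperimentDesign | None = None,
    noise: NoiseSpec | None = None,
    network: ReactionNetwork | None = None,
) -> ConcentrationProfile:
    """Simulate the design and apply measurement noise cell-wise."""
    design = design or ExperimentDesign()
    noise = noise or NoiseSpec()
    network = network or default_network()

    clean = simulate(network, design.k_true, design.c0, design.times)
    conc = clean.conc.copy()
    if noise.kind != "none" and noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        draw = rng.standard_normal(conc.shape)
        if noise.kind == "multiplicative_gaussian":
            conc = conc * (1.0 + noise.sigma * draw)
        else:
            conc = conc + noise.sigma * draw
        if noise.clip_negative:
            conc = np.clip(conc, 0.0, None)
    return ConcentrationProfile(
        times=design.times,
        conc=conc,
        species=tuple(network.species),
        meta={
            "source": "generate_dataset",
            "noise_kind": noise.kind,
            "noise_sigma": noise.sigma,
            "seed": noise.seed,
            "clip_negative": noise.clip_negative,
            "k_true": design.k_true.tolist(),
        },
    )


def write_dataset(profile: ConcentrationProfile, path: str | Path) -> None:
    """Write a profile as CSV with header ``time_min,A,...,I`` (full precision)."""
    # %.17g round-trips IEEE doubles exactly
    profile.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_dataset(path: str | Path) -> ConcentrationProfile:
    """Read a dataset CSV, checking schema and time monotonicity."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("time_min", *SPECIES) if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    times = frame["time_min"].to_numpy(dtype=float)
    if times.size == 0:
        raise SchemaError(f"{path}: no data rows")
    if np.any(times < 0):
        row = int(np.flatnonzero(times < 0)[0])
        raise SchemaError(f"{path}: negative time at data row {row}")
    if np.any(np.diff(times) <= 0):
        row = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
        raise SchemaError(f"{path}: times must be strictly increasing (violated at data row {row})")
    conc = frame[list(SPECIES)].to_numpy(dtype=float)
    return ConcentrationProfile(
        times=times, conc=conc, species=SPECIES, meta={"source": f"loaded:{path}"}
    )
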