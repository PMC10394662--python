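"""Reaction network for the hydrogenation of 1-phenyl-1,2-propanedione.

Nine species take part: the prochiral dione reactant ``A``, four
half-hydrogenated hydroxyketone intermediates ``B``–``E`` (one carbonyl
reduced; B/C are the 1-hydroxy enantiomer pair, D/E the 2-hydroxy pair)
and four fully hydrogenated 1-phenyl-1,2-propanediols ``F``–``I``.
Twelve irreversible first-order steps connect them in two layers:
four parallel steps out of A, and two steps out of each hydroxyketone
into its pair of accessible diols.  Hydrogen, solvent, catalyst and the
cinchonidine modifier are not state variables — their effects are lumped
into the apparent rate constants, which carry units of min⁻¹.

The concentration vector therefore obeys the linear system

    dc/dt = K · c

where ``K`` is the 9×9 rate matrix assembled by :func:`build_rate_matrix`:
``K[target, source] = k`` for every edge, and each diagonal entry is minus
the total consumption rate of that species, so every column sums to zero
and total concentration is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "SPECIES",
    "REACTANT",
    "HYDROXYKETONES",
    "DIOLS",
    "N_SPECIES",
    "N_REACTIONS",
    "REFERENCE_RATE_CONSTANTS",
    "Species",
    "Reaction",
    "ReactionNetwork",
    "default_network",
    "build_rate_matrix",
    "validate_network",
    "validate_rate_constants",
    "load_network",
    "save_network",
]

SPECIES: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G", "H", "I")
REACTANT = "A"
HYDROXYKETONES: tuple[str, ...] = ("B", "C", "D", "E")
DIOLS: tuple[str, ...] = ("F", "G", "H", "I")

N_SPECIES = 9
N_REACTIONS = 12

#: Reference apparent rate constants (min⁻¹) for the cinchonidine-modified
#: Ir/TiO₂ system, indexed k1..k12.  k8 (E→I) and k9 (C→G) sit at the zero
#: bound: those routes are negligible on this catalyst.  Used as the default
#: generating truth of the synthetic-data module.
REFERENCE_RATE_CONSTANTS = np.array(
    [0.821, 3.175, 1.472, 2.501, 0.199, 1.776, 2.285, 0.0, 0.0, 0.241, 0.359, 0.617]
) * 1e-3


def species_role(code: str) -> str:
    """Role of a species code: ``reactant``, ``hydroxyketone`` or ``diol``."""
    if code == REACTANT:
        return "reactant"
    if code in HYDROXYKETONES:
        return "hydroxyketone"
    if code in DIOLS:
        return "diol"
    raise ValueError(f"unknown species code {code!r}; expected one of {SPECIES}")


@dataclass(frozen=True)
class Species:
    code: str

    @property
    def role(self) -> str:
        return species_role(self.code)


@dataclass(frozen=True)
class Reaction:
    """One irreversible first-order step, identified by its k-index (1..12)."""

    index: int
    source: str
    target: str

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"k{self.index}: {self.source}->{self.target}"


@dataclass(frozen=True)
class ReactionNetwork:
    """Fixed two-layer topology of 9 species and 12 unidirectional steps."""

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]

    def species_index(self, code: str) -> int:
        return self.species.index(code)

    def reaction(self, index: int) -> Reaction:
        for r in self.reactions:
            if r.index == index:
                return r
        raise KeyError(f"no reaction with index {index}")

    def outgoing(self, code: str) -> list[Reaction]:
        return [r for r in self.reactions if r.source == code]

    def incoming(self, code: str) -> list[Reaction]:
        return [r for r in self.reactions if r.target == code]


# k-index ↔ edge mapping.  The four steps out of A and the second-layer
# steps toward the major diols are pinned by which constants explain the
# observed F and H accumulation (k2/k6 feed F via B, k4/k7 feed H via C,
# k3/k11 is the alternate F route, k1/k10 the alternate H route) and by the
# two zero-valued constants k8/k9 being the E→I and C→G routes.  k5 (B→I)
# and k12 (D→G) follow by elimination; the assignment between those two is
# a declared convention, overridable through a network file.
_DEFAULT_EDGES: dict[int, tuple[str, str]] = {
    1: ("A", "E"),
    2: ("A", "B"),
    3: ("A", "D"),
    4: ("A", "C"),
    5: ("B", "I"),
    6: ("B", "F"),
    7: ("C", "H"),
    8: ("E", "I"),
    9: ("C", "G"),
    10: ("E", "H"),
    11: ("D", "F"),
    12: ("D", "G"),
}


def default_network() -> ReactionNetwork:
    """The standard 12-reaction network (k1:A→E ... k12:D→G)."""
    reactions = tuple(
        Reaction(index=i, source=s, target=t) for i, (s, t) in sorted(_DEFAULT_EDGES.items())
    )
    return ReactionNetwork(species=SPECIES, reactions=reactions)


def validate_rate_constants(k: Sequence[float] | np.ndarray) -> np.ndarray:
    """Check and coerce a 12-vector of nonnegative rate constants (min⁻¹)."""
    arr = np.asarray(k, dtype=float)
    if arr.shape != (N_REACTIONS,):
        raise ValueError(
            f"rate-constant vector must have shape ({N_REACTIONS},), got {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("rate constants must be finite")
    negative = np.flatnonzero(arr < 0)
    if negative.size:
        idx = ", ".join(f"k{i + 1}" for i in negative)
        raise ValueError(f"rate constants must be >= 0; negative entries: {idx}")
    return arr


def build_rate_matrix(network: ReactionNetwork, k: Sequence[float] | np.ndarray) -> np.ndarray:
    """Assemble the 9×9 generator K of dc/dt = K·c.

    Off-diagonal ``K[target, source]`` entries are the formation rates;
    each diagonal entry is minus the total rate of consumption of that
    species, so columns sum to zero (closed mass balance).
    """
    arr = validate_rate_constants(k)
    K = np.zeros((len(network.species), len(network.species)))
    for r in network.reactions:
        rate = arr[r.index - 1]
        s = network.species_index(r.source)
        t = network.species_index(r.target)
        K[t, s] += rate
        K[s, s] -= rate
    return K


def validate_network(network: ReactionNetwork) -> list[str]:
    """Return human-readable violations of the network invariants (empty = valid)."""
    violations: list[str] = []
    if tuple(network.species) != SPECIES:
        violations.append(
            f"species must be exactly {SPECIES} in order, got {tuple(network.species)}"
        )
        return violations

    if len(network.reactions) != N_REACTIONS:
        violations.append(f"expected {N_REACTIONS} reactions, got {len(network.reactions)}")

    indices = sorted(r.index for r in network.reactions)
    if indices != list(range(1, len(network.reactions) + 1)):
        violations.append(f"reaction indices must cover 1..{N_REACTIONS} exactly once, got {indices}")

    for r in network.reactions:
        src_role = species_role(r.source) if r.source in SPECIES else None
        tgt_role = species_role(r.target) if r.target in SPECIES else None
        if src_role is None or tgt_role is None:
            violations.append(f"reaction k{r.index} references unknown species {r.source}->{r.target}")
            continue
        if src_role == "diol":
            violations.append(f"reaction k{r.index} ({r.source}->{r.target}) has a diol as source")
        elif (src_role, tgt_role) not in {
            ("reactant", "hydroxyketone"),
            ("hydroxyketone", "diol"),
        }:
            violations.append(
                f"reaction k{r.index} ({r.source}->{r.target}) is not reactant->hydroxyketone "
                "or hydroxyketone->diol"
            )

    def _count(pred) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in network.reactions:
            code = pred(r)
            out[code] = out.get(code, 0) + 1
        return out

    out_deg = _count(lambda r: r.source)
    in_deg = _count(lambda r: r.target)
    if out_deg.get(REACTANT, 0) != 4:
        violations.append(f"A must have exactly 4 outgoing edges, has {out_deg.get('A', 0)}")
    for hk in HYDROXYKETONES:
        if out_deg.get(hk, 0) != 2:
            violations.append(f"{hk} must have exactly 2 outgoing edges, has {out_deg.get(hk, 0)}")
    for diol in DIOLS:
        if in_deg.get(diol, 0) != 2:
            violations.append(f"{diol} must have exactly 2 incoming edges, has {in_deg.get(diol, 0)}")
        if out_deg.get(diol, 0):
            violations.append(f"{diol} must have no outgoing edges, has {out_deg[diol]}")
    return violations


def save_network(network: ReactionNetwork, path: str | Path) -> None:
    payload = {
        "species": list(network.species),
        "reactions": [
            {"index": r.index, "source": r.source, "target": r.target}
            for r in network.reactions
        ],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_network(path: str | Path) -> ReactionNetwork:
    """Read a network definition (YAML with ``species:`` and ``reactions:``)."""
    payload = yaml.safe_load(Path(path).read_text())
    try:
        species = tuple(payload["species"])
        reactions = tuple(
            Reaction(index=int(r["index"]), source=str(r["source"]), target=str(r["target"]))
            for r in payload["reactions"]
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed network file {path}: {exc}") from exc
    network = ReactionNetwork(species=species, reactions=reactions)
    violations = validate_network(network)
    if violations:
        raise ValueError(f"invalid network in {path}: " + "; ".join(violations))
    return network


def bundled_network_path() -> Path:
    """Path of the YAML file shipped with the package (equals default_network())."""
    return Path(resources.files("ppdkin") / "data" / "default_network.yaml")
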