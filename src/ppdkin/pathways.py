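"""Pathway classification and derived selectivity metrics.

Each of the eight two-step routes A–X–Y (X a hydroxyketone, Y a diol) is
classified from the fitted constants alone:

* **negligible** — the route contains an edge with k ≤ ``negligible_tol``
  (default 0, i.e. a constant sitting on the lower bound);
* **preferential** — among the surviving routes, the ``top_n`` (default 2)
  ranked by their bottleneck rate min(k_first, k_second), provided the
  ranking is strict at the cut (ties at the boundary demote all tied
  routes to intermediate and are reported);
* **intermediate** — everything else.

The bottleneck rate orders routes by the slower of their two steps, which
is what limits how much diol a route can deliver over the run.

Selectivity metrics are reporting conveniences derived from a
concentration profile: regioselectivity (fraction of half-hydrogenation
occurring at the carbonyl next to the phenyl ring, giving B/C rather than
D/E) and the enantiomeric excesses of the two hydroxyketone pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import ConcentrationProfile
from .network import HYDROXYKETONES, ReactionNetwork, validate_rate_constants

__all__ = ["Route", "PathwayClassification", "classify_pathways", "selectivity_metrics"]


@dataclass(frozen=True)
class Route:
    """A two-step route A–X–Y with its k-indices and bottleneck rate."""

    intermediate: str
    diol: str
    first_index: int
    second_index: int
    bottleneck: float

    @property
    def label(self) -> str:
        return f"A-{self.intermediate}-{self.diol}"


@dataclass
class PathwayClassification:
    negligible: list[Route]
    preferential: list[Route]
    intermediate: list[Route]
    ties: list[Route] = field(default_factory=list)
    negligible_tol: float = 0.0
    top_n: int = 2

    def to_dict(self) -> dict:
        return {
            "negligible": [r.label for r in self.negligible],
            "preferential": [r.label for r in self.preferential],
            "intermediate": [r.label for r in self.intermediate],
            "ties": [r.label for r in self.ties],
            "negligible_tol": self.negligible_tol,
            "top_n": self.top_n,
        }


def _routes(network: ReactionNetwork, k: np.ndarray) -> list[Route]:
    routes = []
    first_step = {r.target: r for r in network.outgoing("A")}
    for x in HYDROXYKETONES:
        for second in network.outgoing(x):
            r1 = first_step[x]
            routes.append(
                Route(
                    intermediate=x,
                    diol=second.target,
                    first_index=r1.index,
                    second_index=second.index,
                    bottleneck=min(k[r1.index - 1], k[second.index - 1]),
                )
            )
    return routes


def classify_pathways(
    k,
    network: ReactionNetwork,
    negligible_tol: float = 0.0,
    top_n: int = 2,
) -> PathwayClassification:
    """Partition the eight A–X–Y routes into negligible / preferential / intermediate."""
    if negligible_tol < 0:
        raise ValueError("negligible_tol must be >= 0")
    if top_n < 0:
        raise ValueError("top_n must be >= 0")
    k = validate_rate_constants(k)
    routes = _routes(network, k)

    def is_negligible(route: Route) -> bool:
        return (
            k[route.first_index - 1] <= negligible_tol
            or k[route.second_index - 1] <= negligible_tol
        )

    negligible = [r for r in routes if is_negligible(r)]
    surviving = sorted(
        (r for r in routes if not is_negligible(r)),
        key=lambda r: r.bottleneck,
        reverse=True,
    )

    preferential: list[Route] = []
    ties: list[Route] = []
    if top_n and surviving:
        cut = min(top_n, len(surviving))
        if cut < len(surviving) and surviving[cut - 1].bottleneck == surviving[cut].bottleneck:
            # ambiguous cut: report the whole tied block as ties, promote none of it
            tie_value = surviving[cut - 1].bottleneck
            preferential = [r for r in surviving[:cut] if r.bottleneck > tie_value]
            ties = [r for r in surviving if r.bottleneck == tie_value]
        else:
            preferential = surviving[:cut]
    intermediate = [r for r in surviving if r not in preferential]
    return PathwayClassification(
        negligible=negligible,
        preferential=preferential,
        intermediate=intermediate,
        ties=ties,
        negligible_tol=negligible_tol,
        top_n=top_n,
    )


def selectivity_metrics(profile: ConcentrationProfile) -> pd.DataFrame:
    """Per-time regioselectivity and enantiomeric excesses.

    regioselectivity = (B+C)/(B+C+D+E); ee_BC = (B−C)/(B+C);
    ee_DE = (D−E)/(D+E).  Entries with a zero denominator are NaN.
    """
    B, C, D, E = (profile.column(s) for s in ("B", "C", "D", "E"))
    with np.errstate(divide="ignore", invalid="ignore"):
        regio = np.where(B + C + D + E > 0, (B + C) / (B + C + D + E), np.nan)
        ee_bc = np.where(B + C > 0, (B - C) / (B + C), np.nan)
        ee_de = np.where(D + E > 0, (D - E) / (D + E), np.nan)
    return pd.DataFrame(
        {
            "time_min": profile.times,
            "regioselectivity": regio,
            "ee_BC": ee_bc,
            "ee_DE": ee_de,
        }
    )
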