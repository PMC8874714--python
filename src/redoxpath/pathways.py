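"""Electron-transfer routes through the FAD→FMN→heme chain.

A *route template* is a (donor, acceptor) pair of group keys such as
("FAD1", "FMN1").  In a monomer the only chain is FAD1→FMN1→HEME1; in a
homodimer each monomer carries its own intra-monomer chain and, in addition,
the FMN of one monomer faces the heme of the partner (cross routes
FMN1→HEME2 and FMN2→HEME1).  The monomer index follows chain order in the
coordinate file; reports carry that convention because the labelling of the
two identical monomers is otherwise arbitrary.

The chain rate of a pathway is the rate of its *limiting* (longest-distance,
slowest) step — under a monotone distance-decay model one step dominates so
strongly that a series combination adds nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .et_model import ETModelParams, rate_from_distance
from .geometry import min_group_distance, residue_group_distance
from .structure_io import CofactorGroup, Structure

__all__ = [
    "ETStep",
    "ETPathway",
    "KcatComparison",
    "RouteTemplate",
    "enumerate_routes",
    "standard_pathways",
    "build_pathway",
    "naive_full_path_rate",
    "compare_with_kcat",
    "aromatic_contact_screen",
]

RouteTemplate = tuple[str, str]

LABELS = ("FAD", "FMN", "HEM")


@dataclass(frozen=True)
class ETStep:
    donor: str
    acceptor: str
    distance: float  # Å
    rate: float  # s^-1
    donor_atom: str = ""
    acceptor_atom: str = ""


@dataclass(frozen=True)
class ETPathway:
    name: str
    steps: tuple[ETStep, ...]
    limiting_step: int
    chain_rate: float
    route_kind: str  # "intra-monomer" | "cross-monomer"

    @property
    def limiting(self) -> ETStep:
        return self.steps[self.limiting_step]

    @property
    def total_distance(self) -> float:
        return sum(s.distance for s in self.steps)


@dataclass(frozen=True)
class KcatComparison:
    pathway: ETPathway
    kcat: float
    ratio: float  # k_et / k_cat
    verdict: str  # "consistent" | "et_faster" | "et_slower"


def _index_groups(groups: Iterable[CofactorGroup]) -> dict[str, CofactorGroup]:
    by_key: dict[str, CofactorGroup] = {}
    for g in groups:
        if g.key in by_key:
            raise ValueError(f"duplicate cofactor group {g.key}")
        by_key[g.key] = g
    return by_key


def enumerate_routes(
    groups: Sequence[CofactorGroup], topology: str
) -> list[RouteTemplate]:
    """Route templates for a monomer or homodimer.

    Monomer: FAD1→FMN1, FMN1→HEM1.  Homodimer: both intra-monomer chains
    plus the two FMN→heme cross routes.  Cross routes never involve FAD —
    the flavin-to-flavin step stays within a monomer.
    """
    by_key = _index_groups(groups)
    indices = sorted({g.monomer_index for g in groups})
    if topology == "monomer":
        needed = [f"{lab}1" for lab in LABELS]
        n_expected = 1
    elif topology == "homodimer":
        needed = [f"{lab}{i}" for i in (1, 2) for lab in LABELS]
        n_expected = 2
    else:
        raise ValueError(f"unsupported topology {topology!r} (monomer or homodimer)")
    if indices and max(indices) > n_expected:
        raise ValueError(
            f"unsupported topology: {len(indices)} monomers found, "
            f"{topology} expects {n_expected} (higher oligomers not supported)"
        )
    missing = [k for k in needed if k not in by_key]
    if missing:
        raise ValueError(f"missing cofactor groups for {topology}: {', '.join(missing)}")
    if topology == "monomer":
        return [("FAD1", "FMN1"), ("FMN1", "HEM1")]
    return [
        ("FAD1", "FMN1"),
        ("FMN1", "HEM1"),
        ("FAD2", "FMN2"),
        ("FMN2", "HEM2"),
        ("FMN1", "HEM2"),
        ("FMN2", "HEM1"),
    ]


def standard_pathways(topology: str) -> list[tuple[str, list[RouteTemplate], str]]:
    """Named pathway layouts: (name, templates, route_kind)."""
    if topology == "monomer":
        return [("monomer", [("FAD1", "FMN1"), ("FMN1", "HEM1")], "intra-monomer")]
    if topology == "homodimer":
        return [
            ("intra-1", [("FAD1", "FMN1"), ("FMN1", "HEM1")], "intra-monomer"),
            ("intra-2", [("FAD2", "FMN2"), ("FMN2", "HEM2")], "intra-monomer"),
            ("cross-1", [("FMN1", "HEM2")], "cross-monomer"),
            ("cross-2", [("FMN2", "HEM1")], "cross-monomer"),
        ]
    raise ValueError(f"unsupported topology {topology!r}")


def build_pathway(
    route: Sequence[RouteTemplate],
    groups: Sequence[CofactorGroup],
    model: ETModelParams,
    name: str = "pathway",
    route_kind: str = "intra-monomer",
) -> ETPathway:
    """Attach measured distances and model rates to a route.

    The limiting step is the one with the largest distance (equivalently the
    smallest rate under the monotone model); the chain rate is its rate.
    """
    by_key = _index_groups(groups)
    steps = []
    for donor, acceptor in route:
        for k in (donor, acceptor):
            if k not in by_key:
                raise ValueError(f"route references missing group {k}")
        dres = min_group_distance(by_key[donor], by_key[acceptor])
        steps.append(
            ETStep(
                donor=donor,
                acceptor=acceptor,
                distance=dres.distance,
                rate=rate_from_distance(model, dres.distance),
                donor_atom=dres.donor_atom,
                acceptor_atom=dres.acceptor_atom,
            )
        )
    if not steps:
        raise ValueError("empty route")
    limiting = max(range(len(steps)), key=lambda i: steps[i].distance)
    chain_rate = min(s.rate for s in steps)
    return ETPathway(
        name=name,
        steps=tuple(steps),
        limiting_step=limiting,
        chain_rate=chain_rate,
        route_kind=route_kind,
    )


def naive_full_path_rate(pathway: ETPathway, model: ETModelParams) -> float:
    """Single-jump rate over the summed path length.

    Evaluates the decay model at the *sum* of the step distances, i.e. treats
    the whole FAD→heme path as one tunnelling event with no intermediate
    station.  This estimate is physically rejected — it under-predicts the
    rate by orders of magnitude — and is reported only as the contrast that
    motivates the hopping (limiting-step) picture.
    """
    if not pathway.steps:
        raise ValueError("naive_full_path_rate: pathway has no steps")
    return rate_from_distance(model, pathway.total_distance)


def compare_with_kcat(
    pathway: ETPathway,
    kcat: float,
    bounds: tuple[float, float] = (1.0 / 3.0, 3.0),
) -> KcatComparison:
    """Qualitative verdict of chain k_et against experimental turnover k_cat."""
    if kcat <= 0:
        raise ValueError(f"kcat must be > 0, got {kcat}")
    lo, hi = bounds
    if not 0 < lo <= hi:
        raise ValueError(f"invalid verdict bounds {bounds}")
    ratio = pathway.chain_rate / kcat
    if ratio < lo:
        verdict = "et_slower"
    elif ratio > hi:
        verdict = "et_faster"
    else:
        verdict = "consistent"
    return KcatComparison(pathway=pathway, kcat=kcat, ratio=ratio, verdict=verdict)


def aromatic_contact_screen(
    structure: Structure,
    residues: Sequence[tuple[str, int]],
    heme: CofactorGroup,
    threshold: float = 4.0,
) -> pd.DataFrame:
    """Side-chain-to-heme distances for candidate aromatic relay residues.

    An aromatic ring packed against the heme edge (closer than ``threshold``,
    default 4 Å) can act as an ET stepping stone; the screen flags such
    contacts.  Missing residues are listed with a null distance, not raised.
    """
    rows = []
    for chain, res_seq in residues:
        try:
            d = residue_group_distance(structure, chain, res_seq, heme)
            rows.append(
                {
                    "chain": chain,
                    "res_seq": res_seq,
                    "distance": round(d, 6),
                    "contact": bool(d < threshold),
                    "note": "",
                }
            )
        except ValueError:
            rows.append(
                {
                    "chain": chain,
                    "res_seq": res_seq,
                    "distance": None,
                    "contact": False,
                    "note": "residue not found",
                }
            )
    return pd.DataFrame(rows, columns=["chain", "res_seq", "distance", "contact", "note"])
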