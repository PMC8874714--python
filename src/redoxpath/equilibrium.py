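"""Monomer ⇄ dimer mass-action equilibrium.

For self-association A + A ⇄ AA with dissociation constant
K_D = [A]² / [AA] and a total protein concentration C expressed in monomer
equivalents ([A] + 2[AA] = C), the free-monomer concentration is the
positive root of 2x²/K_D + x − C = 0:

    x = K_D (−1 + sqrt(1 + 8 C / K_D)) / 4

Trimers and higher oligomers are neglected.  The monomer fraction is
x / C (fraction of protein chains that are free monomers); at C = K_D it is
exactly 1/2, it tends to 1 at infinite dilution and falls off as
sqrt(K_D / 2C) at high concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["EquilibriumResult", "solve_equilibrium", "fraction_vs_concentration"]


@dataclass(frozen=True)
class EquilibriumResult:
    total_conc: float  # M, monomer equivalents
    kd: float  # M
    monomer_conc: float  # M
    dimer_conc: float  # M
    monomer_fraction: float  # in [0, 1]

    @property
    def dimer_fraction(self) -> float:
        return 1.0 - self.monomer_fraction


def solve_equilibrium(total_conc: float, kd: float) -> EquilibriumResult:
    """Species concentrations at a given total concentration and K_D.

    ``total_conc = 0`` returns the empty system with the monomer fraction
    defined as 1 (the dilute limit).
    """
    if total_conc < 0:
        raise ValueError(f"total concentration must be >= 0, got {total_conc}")
    if kd <= 0:
        raise ValueError(f"K_D must be > 0, got {kd}")
    if total_conc == 0:
        return EquilibriumResult(0.0, kd, 0.0, 0.0, 1.0)
    # conjugate form of kd*(-1 + sqrt(1 + 8C/kd))/4: no cancellation at C << kd
    x = 2.0 * total_conc / (1.0 + math.sqrt(1.0 + 8.0 * total_conc / kd))
    dimer = x * x / kd
    return EquilibriumResult(
        total_conc=total_conc,
        kd=kd,
        monomer_conc=x,
        dimer_conc=dimer,
        monomer_fraction=x / total_conc,
    )


def fraction_vs_concentration(kd: float, conc_grid: Sequence[float]) -> pd.DataFrame:
    """Monomer fraction across a concentration grid (strictly decreasing)."""
    rows = []
    for c in conc_grid:
        if c <= 0:
            raise ValueError(f"concentration grid must be positive, got {c}")
        r = solve_equilibrium(c, kd)
        rows.append(
            {
                "total_conc": c,
                "monomer_conc": r.monomer_conc,
                "dimer_conc": r.dimer_conc,
                "monomer_fraction": r.monomer_fraction,
            }
        )
    return pd.DataFrame(rows, columns=["total_conc", "monomer_conc", "dimer_conc", "monomer_fraction"])
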