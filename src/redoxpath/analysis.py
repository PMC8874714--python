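"""End-to-end analysis: structure in, annotated ET pathways out.

Pipeline: read PDB → extract prosthetic groups → calibrate the decay model →
enumerate and build pathways → pick the principal (fastest-chain) route →
dimer equilibrium → comparison with experimental turnover.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .equilibrium import fraction_vs_concentration
from .et_model import ETModelParams, calibrate, verify_anchor, AnchorReport
from .pathways import (
    ETPathway,
    KcatComparison,
    aromatic_contact_screen,
    build_pathway,
    compare_with_kcat,
    enumerate_routes,
    naive_full_path_rate,
    standard_pathways,
)
from .structure_io import Structure, extract_cofactors, read_pdb

__all__ = ["RunSummary", "analyze_structure", "analyze_file", "calibrated_model"]


@dataclass
class RunSummary:
    """Everything one analysis run produced, ready for reporting."""

    source: str
    topology: str
    model: ETModelParams
    anchor_report: AnchorReport
    pathways: list[ETPathway]
    principal: ETPathway
    naive_rate: float | None
    route_table: pd.DataFrame
    equilibrium_table: pd.DataFrame
    kcat_comparison: KcatComparison | None
    aromatic_table: pd.DataFrame | None
    rejected_cross_routes: list[str]
    provenance: dict = field(default_factory=dict)


def calibrated_model(config: RunConfig) -> tuple[ETModelParams, AnchorReport]:
    p1, p2 = (p.as_point() for p in config.calibration.points)
    model = calibrate(p1, p2)
    report = verify_anchor(
        model,
        config.calibration.anchor.as_point(),
        config.calibration.anchor_tolerance_factor,
    )
    return model, report


def _route_frame(pathways: list[ETPathway]) -> pd.DataFrame:
    rows = []
    for p in pathways:
        for i, s in enumerate(p.steps):
            rows.append(
                {
                    "pathway": p.name,
                    "route_kind": p.route_kind,
                    "donor": s.donor,
                    "acceptor": s.acceptor,
                    "distance_A": round(s.distance, 2),
                    "k_et_s-1": s.rate,
                    "limiting": i == p.limiting_step,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["pathway", "route_kind", "donor", "acceptor", "distance_A", "k_et_s-1", "limiting"],
    )


def analyze_structure(
    structure: Structure,
    topology: str,
    config: RunConfig,
    form: str | None = None,
) -> RunSummary:
    """Run the full pathway analysis on an in-memory structure.

    ``form`` selects the experimental k_cat from the config (e.g. "wt"); when
    omitted, the turnover comparison is skipped.
    """
    groups = extract_cofactors(structure, config.domains.residue_codes)
    if not groups:
        raise ValueError(f"{structure.source_label}: no prosthetic groups found")
    enumerate_routes(groups, topology)  # validates completeness / topology
    model, anchor_report = calibrated_model(config)

    pathways = [
        build_pathway(templates, groups, model, name=name, route_kind=kind)
        for name, templates, kind in standard_pathways(topology)
    ]
    principal = max(pathways, key=lambda p: p.chain_rate)
    rejected = [
        p.name
        for p in pathways
        if p.route_kind == "cross-monomer" and p.chain_rate < config.pathway.cross_rejection_rate
    ]

    naive = None
    intra = [p for p in pathways if p.route_kind == "intra-monomer"]
    if intra:
        naive = naive_full_path_rate(intra[0], model)

    comparison = None
    if form is not None:
        if form not in config.pathway.kcat:
            raise ValueError(
                f"unknown enzyme form {form!r}; config provides {sorted(config.pathway.kcat)}"
            )
        comparison = compare_with_kcat(
            principal, config.pathway.kcat[form], config.pathway.consistency_bounds
        )

    aromatic = None
    hem1 = next((g for g in groups if g.key == "HEM1"), None)
    if hem1 is not None and config.pathway.aromatic_residues:
        chains = structure.chains
        residues = [(chains[0], r) for r in config.pathway.aromatic_residues]
        aromatic = aromatic_contact_screen(
            structure, residues, hem1, config.pathway.aromatic_contact_threshold
        )

    equilibrium = fraction_vs_concentration(
        config.equilibrium.kd, config.equilibrium.concentrations
    )

    return RunSummary(
        source=structure.source_label,
        topology=topology,
        model=model,
        anchor_report=anchor_report,
        pathways=pathways,
        principal=principal,
        naive_rate=naive,
        route_table=_route_frame(pathways),
        equilibrium_table=equilibrium,
        kcat_comparison=comparison,
        aromatic_table=aromatic,
        rejected_cross_routes=rejected,
        provenance={"version": __version__, "form": form},
    )


def analyze_file(
    pdb_path: str | Path,
    topology: str,
    config: RunConfig,
    form: str | None = None,
) -> RunSummary:
    """Read a PDB file and analyze it; records the input hash in provenance."""
    pdb_path = Path(pdb_path)
    structure = read_pdb(pdb_path)
    summary = analyze_structure(structure, topology, config, form=form)
    summary.provenance["input"] = pdb_path.name
    summary.provenance["input_sha256"] = hashlib.sha256(pdb_path.read_bytes()).hexdigest()
    return summary
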