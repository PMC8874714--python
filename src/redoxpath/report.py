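"""Plain-text and machine-readable outputs of an analysis run.

Writers are timestamp-free: rerunning an identical analysis produces
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .analysis import RunSummary

__all__ = ["summary_dict", "write_reports", "format_summary_text"]

SCHEMA_VERSION = 1


def summary_dict(summary: RunSummary) -> dict:
    """Key-value view of a run, stable-ordered and versioned."""
    d: dict = {
        "schema_version": SCHEMA_VERSION,
        "source": summary.source,
        "topology": summary.topology,
        "model": {"beta_per_A": summary.model.beta, "A0_per_s": summary.model.A0},
        "anchor_check": {
            "passed": summary.anchor_report.passed,
            "predicted_rate_s-1": summary.anchor_report.predicted_rate,
            "anchor_distance_A": summary.anchor_report.anchor.distance,
            "anchor_rate_s-1": summary.anchor_report.anchor.rate,
        },
        "pathways": [
            {
                "name": p.name,
                "route_kind": p.route_kind,
                "chain_rate_s-1": p.chain_rate,
                "limiting_step": f"{p.limiting.donor}->{p.limiting.acceptor}",
                "limiting_distance_A": round(p.limiting.distance, 2),
                "steps": [
                    {
                        "donor": s.donor,
                        "acceptor": s.acceptor,
                        "distance_A": round(s.distance, 2),
                        "k_et_s-1": s.rate,
                    }
                    for s in p.steps
                ],
            }
            for p in summary.pathways
        ],
        "principal_pathway": summary.principal.name,
        "principal_chain_rate_s-1": summary.principal.chain_rate,
        "naive_full_path_rate_s-1": summary.naive_rate,
        "rejected_cross_routes": summary.rejected_cross_routes,
        "monomer_index_convention": "chains numbered by order of first appearance in the file",
        "equilibrium": summary.equilibrium_table.to_dict(orient="records"),
        "provenance": summary.provenance,
    }
    if summary.kcat_comparison is not None:
        c = summary.kcat_comparison
        d["kcat_comparison"] = {
            "kcat_s-1": c.kcat,
            "k_et_s-1": c.pathway.chain_rate,
            "ratio": c.ratio,
            "verdict": c.verdict,
        }
    if summary.aromatic_table is not None:
        d["aromatic_contacts"] = summary.aromatic_table.to_dict(orient="records")
    return d


def format_summary_text(summary: RunSummary) -> str:
    """Short human-readable digest (distances at 2 decimals)."""
    lines = [
        f"source: {summary.source}  topology: {summary.topology}",
        f"model: beta = {summary.model.beta:.4f} 1/A, A0 = {summary.model.A0:.3g} 1/s",
        str(summary.anchor_report),
        "routes (monomer indices follow chain order in the file):",
    ]
    for p in summary.pathways:
        for i, s in enumerate(p.steps):
            star = " *limiting*" if i == p.limiting_step else ""
            lines.append(
                f"  [{p.name:8s}] {s.donor:>4s} -> {s.acceptor:<4s} "
                f"{s.distance:6.2f} A   k_et = {s.rate:10.3g} 1/s{star}"
            )
    lines.append(
        f"principal pathway: {summary.principal.name} "
        f"(chain k_et = {summary.principal.chain_rate:.3g} 1/s)"
    )
    if summary.naive_rate is not None:
        lines.append(
            f"naive single-jump rate over the summed path: {summary.naive_rate:.3g} 1/s (rejected)"
        )
    if summary.rejected_cross_routes:
        lines.append("rejected cross routes: " + ", ".join(summary.rejected_cross_routes))
    if summary.kcat_comparison is not None:
        c = summary.kcat_comparison
        lines.append(
            f"k_et vs k_cat: {c.pathway.chain_rate:.3g} vs {c.kcat:.3g} 1/s "
            f"(ratio {c.ratio:.3g}) -> {c.verdict}"
        )
    return "\n".join(lines) + "\n"


def write_reports(summary: RunSummary, out_dir: str | Path, stem: str = "run") -> dict[str, Path]:
    """Write the route table (TSV), equilibrium table (TSV) and summary (YAML)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "routes": out_dir / f"{stem}.routes.tsv",
        "equilibrium": out_dir / f"{stem}.equilibrium.tsv",
        "summary": out_dir / f"{stem}.summary.yaml",
        "text": out_dir / f"{stem}.report.txt",
    }
    summary.route_table.to_csv(paths["routes"], sep="\t", index=False)
    summary.equilibrium_table.to_csv(paths["equilibrium"], sep="\t", index=False)
    with open(paths["summary"], "w") as fh:
        yaml.safe_dump(summary_dict(summary), fh, sort_keys=False)
    paths["text"].write_text(format_summary_text(summary))
    return paths
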