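"""Distances, rigid superposition and cofactor transfer.

Inter-group separations are always minimal heavy-atom edge-to-edge distances
(the closest pair of atoms between the two groups), not metal-center or
centroid distances.  Superposition is least-squares Kabsch with the proper
rotation enforced (det = +1); the Cα atoms provide the default atom
correspondence between two versions of a domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import AtomRecord, CofactorGroup, Structure

__all__ = [
    "DistanceResult",
    "SuperpositionResult",
    "min_group_distance",
    "kabsch_superpose",
    "apply_transform",
    "domain_rmsd",
    "transfer_cofactor",
    "residue_group_distance",
]

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class DistanceResult:
    """Minimal edge-to-edge separation between two cofactor groups."""

    donor_label: str
    acceptor_label: str
    distance: float
    donor_atom: str
    acceptor_atom: str
    donor_atom_index: int
    acceptor_atom_index: int


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid map (rotation then translation) and the resulting RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def min_group_distance(a: CofactorGroup, b: CofactorGroup) -> DistanceResult:
    """Closest heavy-atom pair between two prosthetic groups.

    Ties are broken toward the lowest (a-atom, b-atom) index pair, which is
    what a row-major argmin delivers.
    """
    if not a.atoms or not b.atoms:
        raise ValueError("min_group_distance: empty cofactor group")
    d = cdist(a.coords_array(), b.coords_array())
    i, j = np.unravel_index(int(np.argmin(d)), d.shape)
    return DistanceResult(
        donor_label=a.key,
        acceptor_label=b.key,
        distance=float(d[i, j]),
        donor_atom=a.atoms[i].name,
        acceptor_atom=b.atoms[j].name,
        donor_atom_index=int(i),
        acceptor_atom_index=int(j),
    )


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns rotation R and translation t such that ``mobile @ R.T + t``
    minimises the coordinate RMSD to ``target``.  Reflections are never
    returned: the sign of the smallest singular direction is flipped when the
    raw solution is improper.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(
            f"kabsch_superpose: shape mismatch {mobile.shape} vs {target.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"kabsch_superpose: need at least 3 atoms, got {n}")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    x = mobile - cm
    y = target - ct
    # collinear (or coincident) point sets leave the rotation about the axis
    # undetermined
    if np.linalg.matrix_rank(x, tol=1e-8) < 2 or np.linalg.matrix_rank(y, tol=1e-8) < 2:
        raise ValueError("kabsch_superpose: degenerate (collinear) point set")
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ct - rotation @ cm
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd, n_atoms=n)


def apply_transform(sup: SuperpositionResult, coords: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ sup.rotation.T + sup.translation


def _ca_pairing(s1: Structure, s2: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Matched Cα coordinates keyed by (chain, residue number)."""
    ca1 = {(a.chain_id, a.res_seq): a for a in s1.atoms if a.name == "CA"}
    ca2 = {(a.chain_id, a.res_seq): a for a in s2.atoms if a.name == "CA"}
    # when the two structures use different single chains, match on residue
    # number alone (mutant vs wild-type domain comparisons)
    if not set(ca1) & set(ca2) and len({k[0] for k in ca1}) == 1 == len({k[0] for k in ca2}):
        ca1 = {k[1]: v for k, v in ca1.items()}
        ca2 = {k[1]: v for k, v in ca2.items()}
    keys = sorted(set(ca1) & set(ca2), key=lambda k: ca1[k].serial)
    p1 = np.array([ca1[k].coords for k in keys], dtype=float).reshape(-1, 3)
    p2 = np.array([ca2[k].coords for k in keys], dtype=float).reshape(-1, 3)
    return p1, p2


def domain_rmsd(
    s1: Structure,
    s2: Structure,
    pairing: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """RMSD of two versions of a domain after optimal superposition.

    By default the correspondence is Cα atoms matched by chain and author
    residue number; an explicit coordinate pairing can be supplied instead.
    """
    if pairing is None:
        p1, p2 = _ca_pairing(s1, s2)
    else:
        p1, p2 = (np.asarray(p, dtype=float) for p in pairing)
    if len(p1) < 3:
        raise ValueError(f"domain_rmsd: only {len(p1)} matched atoms (need >= 3)")
    return kabsch_superpose(p1, p2).rmsd


def transfer_cofactor(
    reference_domain: Structure,
    predicted_domain: Structure,
    cofactor: CofactorGroup,
) -> CofactorGroup:
    """Carry a cofactor from an experimental domain into a predicted one.

    The reference domain is superposed onto the predicted domain on shared
    Cα atoms and the same rigid map is applied to the cofactor, placing e.g.
    a crystallographic heme into an apo predicted model.  Intra-cofactor
    geometry is preserved exactly (rigid map).
    """
    p_ref, p_pred = _ca_pairing(reference_domain, predicted_domain)
    if len(p_ref) < 3:
        raise ValueError(
            f"transfer_cofactor: only {len(p_ref)} shared Cα residues (need >= 3)"
        )
    sup = kabsch_superpose(p_ref, p_pred)
    moved = apply_transform(sup, cofactor.coords_array())
    atoms = [
        AtomRecord(
            serial=a.serial,
            name=a.name,
            element=a.element,
            res_name=a.res_name,
            res_seq=a.res_seq,
            chain_id=a.chain_id,
            coords=(float(x), float(y), float(z)),
            is_hetero=a.is_hetero,
        )
        for a, (x, y, z) in zip(cofactor.atoms, moved)
    ]
    return CofactorGroup(label=cofactor.label, monomer_index=cofactor.monomer_index, atoms=atoms)


def residue_group_distance(
    structure: Structure,
    chain: str,
    res_seq: int,
    group: CofactorGroup,
) -> float:
    """Minimal heavy-atom distance from a residue's side chain to a group.

    Backbone atoms (N, CA, C, O, OXT) are excluded when the residue has any
    side-chain heavy atoms; a Cα-only residue falls back to all its heavy
    atoms.
    """
    res_atoms = [
        a
        for a in structure.atoms
        if a.chain_id == chain and a.res_seq == res_seq and not a.is_hetero
    ]
    if not res_atoms:
        raise ValueError(f"residue {chain}{res_seq} not found")
    side = [a for a in res_atoms if a.name not in BACKBONE_NAMES and not a.is_hydrogen]
    if not side:
        side = [a for a in res_atoms if not a.is_hydrogen]
    p = np.array([a.coords for a in side], dtype=float)
    d = cdist(p, group.coords_array())
    return float(d.min())
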