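"""Ground-truth PDB fixtures for the analysis pipeline.

The generator writes structurally valid PDB files that *look* like predicted
multidomain P450 models — one or two chains whose Cα trace spans the heme
(2–459), FMN (460–650) and FAD (659–1049) residue ranges, each chain carrying
HEM/FMN/FAD hetero groups — while the minimal heavy-atom distance between
every constrained cofactor pair equals its target exactly.

Exactness survives the fixed 3-decimal PDB coordinate columns because every
atom is placed on the 0.001 Å grid and each constrained pair of groups gets a
dedicated *contact* pair of atoms whose integer (milli-Å) displacement vector
has squared norm exactly (1000·d)².  All other atoms are kept far enough away
(interior atoms within 1.2 Å of a group center, contact shells at 2.0 Å,
contact directions separated by >= 45°) that the designated pair is provably
the closest one.  Cofactors are multi-atom clouds, not points, so
closest-pair logic is genuinely exercised.

Fixtures emulate file structure and geometry only: the Cα traces are
serpentine synthetic walks, not real folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .structure_io import AtomRecord, Structure, read_pdb, write_pdb, extract_cofactors
from .geometry import min_group_distance, residue_group_distance

__all__ = [
    "FixtureSpec",
    "FixtureManifest",
    "FixtureFeasibilityError",
    "generate_fixture",
    "reference_scenarios",
    "SCENARIO_NAMES",
]

RHO = 2.0  # contact-shell radius of a cofactor cloud (Å)
RHO_IN = 1.2  # interior-atom radius (Å)
MIN_TARGET = 1.6  # smallest realizable minimal distance: 2*(RHO - RHO_IN)
ANGLE_MIN_DEG = 40.0  # minimal separation of contact directions at one group
_DEV_BUDGETS = (150, 300, 450)  # lattice-vector deviation budgets, milli-Å
# integer points on a sphere thin out near the coordinate axes, so layout
# directions are kept either exactly on an axis (trivially exact) or well off
_AXIS_AVOID_DEG = 8.0

MONOMER_ROUTES = ("FAD1-FMN1", "FMN1-HEM1")
DIMER_ROUTES = (
    "FAD1-FMN1",
    "FMN1-HEM1",
    "FAD2-FMN2",
    "FMN2-HEM2",
    "FMN1-HEM2",
    "FMN2-HEM1",
)

DOMAIN_RANGES = {"HEME": (2, 459), "FMN": (460, 650), "FAD": (659, 1049)}
PROBE_RES_SEQ = 262  # aromatic relay residue analogous to F262, heme domain

_COFACTOR_NAMES = {
    "HEM": [("FE", "Fe"), ("NA", "N"), ("NB", "N"), ("NC", "N"), ("ND", "N"),
            ("C1A", "C"), ("C2A", "C"), ("C3A", "C"), ("C4A", "C"), ("CHA", "C"),
            ("CHB", "C"), ("CHC", "C"), ("CHD", "C"), ("CMA", "C"), ("CMB", "C"),
            ("CMC", "C")],
    "FMN": [("N5", "N"), ("C4A", "C"), ("N10", "N"), ("C10", "C"), ("N1", "N"),
            ("C2", "C"), ("O2", "O"), ("N3", "N"), ("C4", "C"), ("O4", "O"),
            ("C5A", "C"), ("C6", "C"), ("C7", "C"), ("C8", "C"), ("C9", "C"),
            ("C9A", "C")],
    "FAD": [("N5", "N"), ("C4X", "C"), ("N10", "N"), ("PA", "P"), ("O1A", "O"),
            ("O2A", "O"), ("N1", "N"), ("C2", "C"), ("O2", "O"), ("N3", "N"),
            ("C4", "C"), ("O4", "O"), ("C6", "C"), ("C7", "C"), ("C8", "C"),
            ("C9", "C")],
}

_RES_SEQ = {"HEM": 1101, "FMN": 1102, "FAD": 1103}


class FixtureFeasibilityError(ValueError):
    """The requested distance set cannot be realized geometrically."""


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic structure."""

    topology: str  # "monomer" | "homodimer"
    target_distances: Mapping[str, float]  # route key -> minimal distance (Å)
    n_decoy_atoms_per_domain: int = 20
    aromatic_probe_distance: float | None = None  # F262-analogue -> HEM1 (Å)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in ("monomer", "homodimer"):
            raise ValueError(f"unknown topology {self.topology!r}")
        expected = MONOMER_ROUTES if self.topology == "monomer" else DIMER_ROUTES
        got = set(self.target_distances)
        if got != set(expected):
            raise ValueError(
                f"{self.topology} fixture needs routes {sorted(expected)}, got {sorted(got)}"
            )
        for key, d in self.target_distances.items():
            if not d > 0:
                raise ValueError(f"target distance {key} must be > 0, got {d}")
        if self.aromatic_probe_distance is not None and not self.aromatic_probe_distance > 0:
            raise ValueError("aromatic_probe_distance must be > 0")

    @property
    def routes(self) -> tuple[str, ...]:
        return MONOMER_ROUTES if self.topology == "monomer" else DIMER_ROUTES


@dataclass
class FixtureManifest:
    """What the generator actually wrote, re-measured from the file."""

    path: str
    topology: str
    seed: int
    target_distances: dict[str, float]
    achieved_distances: dict[str, float]
    group_atom_counts: dict[str, int]
    aromatic_probe_target: float | None = None
    aromatic_probe_achieved: float | None = None

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "schema_version": 1,
                    "path": self.path,
                    "topology": self.topology,
                    "seed": self.seed,
                    "target_distances": self.target_distances,
                    "achieved_distances": self.achieved_distances,
                    "group_atom_counts": self.group_atom_counts,
                    "aromatic_probe_target": self.aromatic_probe_target,
                    "aromatic_probe_achieved": self.aromatic_probe_achieved,
                },
                fh,
                sort_keys=True,
            )
        return path


# ---------------------------------------------------------------------------
# exact lattice placement


def _milli(d: float) -> int:
    m = round(d * 1000)
    if abs(d * 1000 - m) > 1e-6:
        raise FixtureFeasibilityError(
            f"target distance {d} is not representable at the 0.001 Å "
            "precision of PDB coordinates"
        )
    return m


def _snap(p: np.ndarray) -> np.ndarray:
    return np.rint(np.asarray(p, dtype=float) * 1000.0) / 1000.0


def _lattice_vector(d_milli: int, w: np.ndarray) -> np.ndarray:
    """Integer vector v with |v| == d_milli to < 5e-4 milli-Å, close to w.

    Two grid atoms separated by v/1000 are then d apart to better than
    1e-6 Å — far below the 1e-3 Å quantum the PDB columns carry, so the
    distance survives the file round trip unchanged at that tolerance.
    A perfect |v|^2 == d^2 match is preferred when the rounded ideal vector
    already provides one (axis-aligned contacts).
    """
    n_sq = d_milli * d_milli
    # |m - N| <= floor(d/1000) keeps | |v| - d | <= 5e-4 milli-Å
    slack = max(d_milli // 1000, 0)
    w = np.asarray(w, dtype=float)
    w = w * (d_milli / np.linalg.norm(w))
    wr = np.rint(w).astype(np.int64)
    if abs(int((wr * wr).sum()) - n_sq) <= slack:
        return wr
    order = np.argsort(np.abs(w))  # solve the largest component by rounding
    i0, i1, i2 = int(order[0]), int(order[1]), int(order[2])
    sign = 1 if w[i2] >= 0 else -1
    for budget in _DEV_BUDGETS:
        da = np.arange(-budget, budget + 1, dtype=np.int64)
        a = np.int64(round(w[i0])) + da
        b = np.int64(round(w[i1])) + da
        aa, bb = np.meshgrid(a, b, indexing="ij")
        rem = n_sq - aa * aa - bb * bb
        ok = rem >= 0
        c = np.zeros_like(rem)
        c[ok] = np.rint(np.sqrt(rem[ok].astype(float))).astype(np.int64)
        ok &= np.abs(aa * aa + bb * bb + c * c - n_sq) <= slack
        if not ok.any():
            continue
        dev2 = (aa - w[i0]) ** 2 + (bb - w[i1]) ** 2 + (sign * c - w[i2]) ** 2
        dev2 = np.where(ok, dev2, np.inf)
        k = np.unravel_index(int(np.argmin(dev2)), dev2.shape)
        if dev2[k] <= float(budget) ** 2:
            v = np.zeros(3, dtype=np.int64)
            v[i0] = aa[k]
            v[i1] = bb[k]
            v[i2] = sign * c[k]
            return v
    raise FixtureFeasibilityError(
        f"no lattice placement found for distance {d_milli / 1000} Å"
    )


# ---------------------------------------------------------------------------
# center layout


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise FixtureFeasibilityError("degenerate direction in layout")
    return v / n


def _route_groups(key: str) -> tuple[str, str]:
    a, b = key.split("-")
    return a, b


def _min_contact_angle(centers: dict[str, np.ndarray], routes: tuple[str, ...]) -> float:
    """Smallest pairwise angle (deg) between contact directions at any group."""
    dirs: dict[str, list[np.ndarray]] = {}
    for key in routes:
        g1, g2 = _route_groups(key)
        dirs.setdefault(g1, []).append(_unit(centers[g2] - centers[g1]))
        dirs.setdefault(g2, []).append(_unit(centers[g1] - centers[g2]))
    best = 180.0
    for ds in dirs.values():
        for i in range(len(ds)):
            for j in range(i + 1, len(ds)):
                cosang = float(np.clip(np.dot(ds[i], ds[j]), -1.0, 1.0))
                best = min(best, math.degrees(math.acos(cosang)))
    return best


def _axis_directions_ok(centers: dict[str, np.ndarray], routes: tuple[str, ...]) -> bool:
    """True when every route direction is exactly on, or well off, an axis."""
    for key in routes:
        g1, g2 = _route_groups(key)
        u = _unit(centers[g2] - centers[g1])
        ang = abs(math.degrees(math.atan2(u[1], u[0]))) % 90.0
        dist = min(ang, 90.0 - ang)
        if dist > 1e-9 and dist < _AXIS_AVOID_DEG:
            return False
    return True


def _place_fad(fmn: np.ndarray, partners: list[np.ndarray], length: float) -> np.ndarray:
    """Hang FAD off its FMN pointing away from the listed partner centers."""
    away = -sum(_unit(p - fmn) for p in partners)
    if np.linalg.norm(away) < 1e-6:
        away = np.array([0.0, 1.0])
    return fmn + length * _unit(away)


def _layout_monomer(lengths: dict[str, float]) -> dict[str, np.ndarray]:
    fad = np.array([0.0, 0.0])
    fmn = fad + np.array([lengths["FAD1-FMN1"], 0.0])
    hem = fmn + np.array([lengths["FMN1-HEM1"], 0.0])
    return {"FAD1": fad, "FMN1": fmn, "HEM1": hem}


def _layout_homodimer(lengths: dict[str, float]) -> dict[str, np.ndarray]:
    l_ih1 = lengths["FMN1-HEM1"]
    l_ih2 = lengths["FMN2-HEM2"]
    l_c1 = lengths["FMN1-HEM2"]
    l_c2 = lengths["FMN2-HEM1"]
    cycle = [l_ih1, l_c2, l_ih2, l_c1]
    for i, side in enumerate(cycle):
        if side >= sum(cycle) - side:
            raise FixtureFeasibilityError(
                f"cross/intra distance set not embeddable: side {side:.1f} Å "
                "exceeds the sum of the other cycle sides"
            )
    fmn1 = np.array([0.0, 0.0])
    hem1 = np.array([l_ih1, 0.0])
    best = None
    for alpha in np.arange(25.0, 156.0, 0.25):
        ar = math.radians(alpha)
        fmn2 = hem1 + l_c2 * np.array([math.cos(ar), math.sin(ar)])
        d12 = float(np.linalg.norm(fmn2 - fmn1))
        if not (abs(l_c1 - l_ih2) + 1e-6 < d12 < l_c1 + l_ih2 - 1e-6):
            continue
        ex = (fmn2 - fmn1) / d12
        ey = np.array([-ex[1], ex[0]])
        xproj = (d12 * d12 + l_c1 * l_c1 - l_ih2 * l_ih2) / (2.0 * d12)
        h_sq = l_c1 * l_c1 - xproj * xproj
        if h_sq < 1.0:
            continue
        for s in (1.0, -1.0):
            hem2 = fmn1 + xproj * ex + s * math.sqrt(h_sq) * ey
            centers = {"FMN1": fmn1, "HEM1": hem1, "FMN2": fmn2, "HEM2": hem2}
            centers["FAD1"] = _place_fad(fmn1, [hem1, hem2], lengths["FAD1-FMN1"])
            centers["FAD2"] = _place_fad(fmn2, [hem2, hem1], lengths["FAD2-FMN2"])
            pts = list(centers.values())
            sep = min(
                float(np.linalg.norm(pts[i] - pts[j]))
                for i in range(len(pts))
                for j in range(i + 1, len(pts))
            )
            if sep < 2.0 * (RHO + 0.5) + 1.0:
                continue
            if not _axis_directions_ok(centers, DIMER_ROUTES):
                continue
            score = _min_contact_angle(centers, DIMER_ROUTES)
            if best is None or score > best[0]:
                best = (score, centers)
    if best is None or best[0] < ANGLE_MIN_DEG:
        got = "none" if best is None else f"{best[0]:.1f} deg"
        raise FixtureFeasibilityError(
            f"homodimer layout infeasible: best contact-direction separation {got} "
            f"(need >= {ANGLE_MIN_DEG} deg)"
        )
    return best[1]


# ---------------------------------------------------------------------------
# atom cloud assembly


def _build_cofactor_atoms(
    spec: FixtureSpec,
    centers3: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[dict[str, list[tuple[str, str, np.ndarray]]], np.ndarray | None]:
    """Per-group (name, element, position) lists plus the probe CZ position."""
    atoms: dict[str, list[tuple[str, str, np.ndarray]]] = {k: [] for k in centers3}
    used: dict[str, int] = {k: 0 for k in centers3}

    def next_name(gkey: str) -> tuple[str, str]:
        label = gkey[:3]
        names = _COFACTOR_NAMES[label]
        i = used[gkey]
        if i >= len(names):
            raise RuntimeError(f"name pool exhausted for {gkey}")
        used[gkey] += 1
        return names[i]

    # center atom
    for gkey, c in centers3.items():
        nm, el = next_name(gkey)
        atoms[gkey].append((nm, el, _snap(c)))

    # designated contact pairs, exact on the milli-Å grid
    for key in spec.routes:
        g1, g2 = _route_groups(key)
        c1, c2 = centers3[g1], centers3[g2]
        u = _unit(c2 - c1)
        p1 = _snap(c1 + RHO * u)
        d_milli = _milli(spec.target_distances[key])
        w = ((c2 - RHO * u) - p1) * 1000.0
        v = _lattice_vector(d_milli, w)
        p2 = p1 + v.astype(float) / 1000.0
        nm1, el1 = next_name(g1)
        nm2, el2 = next_name(g2)
        atoms[g1].append((nm1, el1, p1))
        atoms[g2].append((nm2, el2, p2))

    # aromatic probe: dedicated heme contact atom straight up the z axis
    probe_cz = None
    if spec.aromatic_probe_distance is not None:
        d = spec.aromatic_probe_distance
        c = centers3["HEM1"]
        p_h = _snap(c + np.array([0.0, 0.0, RHO]))
        probe_cz = p_h + np.array([0.0, 0.0, _milli(d) / 1000.0])
        nm, el = next_name("HEM1")
        atoms["HEM1"].append((nm, el, p_h))

    # interior filler atoms: strictly inside RHO_IN of the center
    for gkey, c in centers3.items():
        n_interior = max(0, 13 - len(atoms[gkey]) - 0)
        for _ in range(n_interior):
            if used[gkey] >= len(_COFACTOR_NAMES[gkey[:3]]):
                break
            vec = rng.normal(size=3)
            r = (RHO_IN - 0.05) * rng.random() ** (1.0 / 3.0)
            pos = _snap(c + r * vec / np.linalg.norm(vec))
            nm, el = next_name(gkey)
            atoms[gkey].append((nm, el, pos))
    return atoms, probe_cz


def _build_chain_trace(
    chain_id: str,
    y_offset: float,
    spec: FixtureSpec,
    rng: np.random.Generator,
    probe: tuple[np.ndarray, np.ndarray] | None,
) -> list[tuple[str, int, str, str, np.ndarray]]:
    """Serpentine Cα walk spanning all three domain ranges.

    Returns (res_name, res_seq, atom_name, element, pos).  The trace lives in
    a slab at z >= 13.5 Å while cofactor atoms stay below z ~ 7.5 Å, so decoy
    atoms can never undercut a target minimum.  ``probe`` carries the
    (CA, CZ) anchor positions of the aromatic relay residue.
    """
    rows: list[tuple[str, int, str, str, np.ndarray]] = []
    lo = min(r[0] for r in DOMAIN_RANGES.values())
    hi = max(r[1] for r in DOMAIN_RANGES.values())
    decoy_res: set[int] = set()
    for start, end in DOMAIN_RANGES.values():
        pool = np.arange(start, end + 1)
        pool = pool[pool != PROBE_RES_SEQ]
        n = min(spec.n_decoy_atoms_per_domain, len(pool))
        decoy_res.update(int(r) for r in rng.choice(pool, size=n, replace=False))
    for res_seq in range(lo, hi + 1):
        i = res_seq - lo
        row, col = divmod(i, 80)
        x = -60.0 + 1.5 * col if row % 2 == 0 else 58.5 - 1.5 * col
        y = y_offset + 6.0 * row
        z = 16.0 + 1.2 * math.sin(0.7 * res_seq)
        ca = _snap(np.array([x, y, z]))
        if probe is not None and res_seq == PROBE_RES_SEQ:
            p_ca, p_cz = probe
            base = np.array([p_cz[0], p_cz[1], 0.0])
            rows.append(("PHE", res_seq, "N", "N", _snap(p_ca + [0.8, 0.0, 0.5])))
            rows.append(("PHE", res_seq, "CA", "C", _snap(p_ca)))
            rows.append(("PHE", res_seq, "C", "C", _snap(p_ca + [-0.8, 0.6, 0.4])))
            rows.append(("PHE", res_seq, "O", "O", _snap(p_ca + [-1.2, 1.2, 0.9])))
            rows.append(("PHE", res_seq, "CB", "C", _snap(base + [0.0, 0.0, 13.0])))
            rows.append(("PHE", res_seq, "CG", "C", _snap(base + [0.0, 0.0, 10.8])))
            rows.append(("PHE", res_seq, "CZ", "C", _snap(p_cz)))
            continue
        rows.append(("GLY", res_seq, "CA", "C", ca))
        if res_seq in decoy_res:
            off = rng.normal(scale=0.8, size=3) + np.array([0.0, 0.0, 1.5])
            rows.append(("GLY", res_seq, "CB", "C", _snap(ca + off)))
    return rows


# ---------------------------------------------------------------------------
# public API


def generate_fixture(
    spec: FixtureSpec,
    out_dir: str | Path,
    name: str = "fixture",
) -> tuple[Path, FixtureManifest]:
    """Write ``<name>.pdb`` and ``<name>.manifest.yaml`` under ``out_dir``.

    Deterministic per (spec, seed): identical inputs give byte-identical
    files.  The manifest's achieved distances are re-measured from the
    written file, so they certify the round trip through the fixed-width
    format.
    """
    for key, d in spec.target_distances.items():
        if d < MIN_TARGET:
            raise FixtureFeasibilityError(
                f"target {key} = {d} Å < {MIN_TARGET} Å: interior atoms of the two "
                "clouds would clash with the designated minimum"
            )
    if spec.aromatic_probe_distance is not None and spec.aromatic_probe_distance < MIN_TARGET:
        raise FixtureFeasibilityError("aromatic probe distance too small to realize")

    lengths = {k: v + 2.0 * RHO for k, v in spec.target_distances.items()}
    if spec.topology == "monomer":
        centers2 = _layout_monomer(lengths)
    else:
        centers2 = _layout_homodimer(lengths)
    centers3 = {k: np.array([c[0], c[1], 0.0]) for k, c in centers2.items()}

    rng = np.random.default_rng(spec.seed)
    cof_atoms, probe_cz = _build_cofactor_atoms(spec, centers3, rng)

    probe = None
    if probe_cz is not None:
        c = centers3["HEM1"]
        probe = (np.array([c[0], c[1], 16.0]), probe_cz)

    chain_of_index = {1: "A", 2: "B"}
    records: list[AtomRecord] = []
    serial = 0

    def add(name_, element, res_name, res_seq, chain_id, pos, het):
        nonlocal serial
        serial += 1
        records.append(
            AtomRecord(
                serial=serial,
                name=name_,
                element=element,
                res_name=res_name,
                res_seq=res_seq,
                chain_id=chain_id,
                coords=(float(pos[0]), float(pos[1]), float(pos[2])),
                is_hetero=het,
            )
        )

    n_chains = 1 if spec.topology == "monomer" else 2
    for idx in range(1, n_chains + 1):
        chain_id = chain_of_index[idx]
        y_off = -150.0 if idx == 1 else 110.0
        trace = _build_chain_trace(chain_id, y_off, spec, rng, probe if idx == 1 else None)
        for res_name, res_seq, atom_name, element, pos in trace:
            add(atom_name, element, res_name, res_seq, chain_id, pos, het=False)
        for label in ("HEM", "FMN", "FAD"):
            gkey = f"{label}{idx}"
            for atom_name, element, pos in cof_atoms[gkey]:
                add(atom_name, element, label, _RES_SEQ[label], chain_id, pos, het=True)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_path = out_dir / f"{name}.pdb"
    write_pdb(Structure(atoms=records, source_label=name), pdb_path)

    # re-measure from the written file: the round trip is the ground truth
    reread = read_pdb(pdb_path)
    groups = {g.key: g for g in extract_cofactors(reread)}
    achieved: dict[str, float] = {}
    for key in spec.routes:
        g1, g2 = _route_groups(key)
        achieved[key] = min_group_distance(groups[g1], groups[g2]).distance
        if abs(achieved[key] - spec.target_distances[key]) > 1e-6:
            raise RuntimeError(
                f"fixture self-check failed: {key} achieved {achieved[key]!r} "
                f"vs target {spec.target_distances[key]!r}"
            )
    probe_achieved = None
    if spec.aromatic_probe_distance is not None:
        probe_achieved = residue_group_distance(reread, "A", PROBE_RES_SEQ, groups["HEM1"])
        if abs(probe_achieved - spec.aromatic_probe_distance) > 1e-6:
            raise RuntimeError("fixture self-check failed on the aromatic probe distance")

    manifest = FixtureManifest(
        path=str(pdb_path),
        topology=spec.topology,
        seed=spec.seed,
        target_distances=dict(spec.target_distances),
        achieved_distances=achieved,
        group_atom_counts={k: len(g.atoms) for k, g in sorted(groups.items())},
        aromatic_probe_target=spec.aromatic_probe_distance,
        aromatic_probe_achieved=probe_achieved,
    )
    manifest.write(out_dir / f"{name}.manifest.yaml")
    return pdb_path, manifest


#: The six CYP102A1 cases: wild type and the A83F/A83I point mutants, each as
#: isolated monomer and as homodimer.  Limiting distances are the measured
#: values for each form; distances never reported for a form (the non-limiting
#: partner steps) are filled with shorter, non-limiting values so the stated
#: step stays the limiting one.
SCENARIO_NAMES = (
    "wt-monomer",
    "wt-dimer",
    "a83i-monomer",
    "a83i-dimer",
    "a83f-monomer",
    "a83f-dimer",
)


def reference_scenarios(seed: int = 0) -> dict[str, FixtureSpec]:
    """Fixture specs for the six canonical CYP102A1 forms."""
    base = int(seed)
    return {
        "wt-monomer": FixtureSpec(
            topology="monomer",
            target_distances={"FAD1-FMN1": 28.0, "FMN1-HEM1": 11.0},
            seed=base + 0,
        ),
        "wt-dimer": FixtureSpec(
            topology="homodimer",
            target_distances={
                "FAD1-FMN1": 15.0,
                "FMN1-HEM1": 30.0,
                "FAD2-FMN2": 15.0,
                "FMN2-HEM2": 30.0,
                "FMN1-HEM2": 47.0,
                "FMN2-HEM1": 48.0,
            },
            seed=base + 1,
        ),
        "a83i-monomer": FixtureSpec(
            topology="monomer",
            target_distances={"FAD1-FMN1": 32.0, "FMN1-HEM1": 11.0},
            seed=base + 2,
        ),
        "a83i-dimer": FixtureSpec(
            topology="homodimer",
            target_distances={
                "FAD1-FMN1": 15.0,
                "FMN1-HEM1": 20.0,
                "FAD2-FMN2": 15.0,
                "FMN2-HEM2": 20.0,
                "FMN1-HEM2": 43.0,
                "FMN2-HEM1": 45.0,
            },
            seed=base + 3,
        ),
        "a83f-monomer": FixtureSpec(
            topology="monomer",
            target_distances={"FAD1-FMN1": 40.0, "FMN1-HEM1": 11.0},
            aromatic_probe_distance=5.0,
            seed=base + 4,
        ),
        "a83f-dimer": FixtureSpec(
            topology="homodimer",
            target_distances={
                "FAD1-FMN1": 15.0,
                "FMN1-HEM1": 44.0,
                "FAD2-FMN2": 15.0,
                "FMN2-HEM2": 42.0,
                "FMN1-HEM2": 34.0,
                "FMN2-HEM1": 44.0,
            },
            aromatic_probe_distance=3.0,
            seed=base + 5,
        ),
    }
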