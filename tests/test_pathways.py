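"""Route enumeration, limiting-step logic and turnover comparison."""

import numpy as np
import pytest

from redoxpath.pathways import (
    aromatic_contact_screen,
    build_pathway,
    compare_with_kcat,
    enumerate_routes,
    naive_full_path_rate,
    standard_pathways,
)
from redoxpath.structure_io import AtomRecord, CofactorGroup, Structure


def _group(label, idx, center):
    # small cross-shaped cloud around the center
    offsets = [(0, 0, 0), (0.5, 0, 0), (-0.5, 0, 0), (0, 0.5, 0), (0, 0, 0.5)]
    atoms = [
        AtomRecord(i + 1, f"C{i}", "C", label, 1101, "ABCD"[idx - 1],
                   tuple(np.add(center, o).astype(float)), True)
        for i, o in enumerate(offsets)
    ]
    return CofactorGroup(label=label, monomer_index=idx, atoms=atoms)


def _monomer_groups(d_fad_fmn=28.0, d_fmn_hem=11.0):
    # centers on a line; clouds extend 0.5 either side, so edge-to-edge
    # separation is center gap minus 1.0
    fad = _group("FAD", 1, (0.0, 0.0, 0.0))
    fmn = _group("FMN", 1, (d_fad_fmn + 1.0, 0.0, 0.0))
    hem = _group("HEM", 1, (d_fad_fmn + d_fmn_hem + 2.0, 0.0, 0.0))
    return [fad, fmn, hem]


class TestEnumerateRoutes:
    def test_monomer_two_steps(self):
        routes = enumerate_routes(_monomer_groups(), "monomer")
        assert routes == [("FAD1", "FMN1"), ("FMN1", "HEM1")]

    def test_homodimer_intra_plus_cross(self):
        groups = _monomer_groups() + [
            _group("FAD", 2, (0, 50, 0)),
            _group("FMN", 2, (29, 50, 0)),
            _group("HEM", 2, (41, 50, 0)),
        ]
        routes = enumerate_routes(groups, "homodimer")
        assert len(routes) == 6
        assert ("FMN1", "HEM2") in routes and ("FMN2", "HEM1") in routes
        # FAD never crosses monomers
        assert all(not (d.startswith("FAD") and d[-1] != a[-1]) for d, a in routes)

    def test_missing_group_listed(self):
        groups = _monomer_groups()[:2]  # no heme
        with pytest.raises(ValueError, match="HEM1"):
            enumerate_routes(groups, "monomer")

    def test_trimer_rejected(self):
        groups = _monomer_groups() + [
            _group(lab, i, (0, 50 * (i - 1), 0))
            for i in (2, 3)
            for lab in ("FAD", "FMN", "HEM")
        ]
        with pytest.raises(ValueError, match="topology"):
            enumerate_routes(groups, "homodimer")


class TestBuildPathway:
    def test_wt_monomer_limiting_step(self, model):
        groups = _monomer_groups(28.0, 11.0)
        p = build_pathway([("FAD1", "FMN1"), ("FMN1", "HEM1")], groups, model)
        assert p.limiting.donor == "FAD1"
        assert p.steps[0].distance == pytest.approx(28.0, abs=1e-9)
        assert p.chain_rate == pytest.approx(p.steps[0].rate, rel=1e-12)
        assert p.chain_rate == pytest.approx(0.26, rel=0.01)

    def test_single_step_route(self, model):
        groups = _monomer_groups()
        p = build_pathway([("FMN1", "HEM1")], groups, model)
        assert p.limiting_step == 0 and p.chain_rate == p.steps[0].rate

    def test_limiting_is_min_rate_and_max_distance(self, model, rng):
        groups = _monomer_groups(rng.uniform(10, 40), rng.uniform(10, 40))
        p = build_pathway([("FAD1", "FMN1"), ("FMN1", "HEM1")], groups, model)
        assert p.chain_rate == min(s.rate for s in p.steps)
        assert p.limiting.distance == max(s.distance for s in p.steps)

    def test_adding_step_never_raises_chain_rate(self, model):
        groups = _monomer_groups(28.0, 11.0)
        one = build_pathway([("FAD1", "FMN1")], groups, model)
        two = build_pathway([("FAD1", "FMN1"), ("FMN1", "HEM1")], groups, model)
        assert two.chain_rate <= one.chain_rate


class TestNaiveFullPath:
    def test_summed_path_rate(self, model):
        groups = _monomer_groups(28.0, 11.0)
        p = build_pathway([("FAD1", "FMN1"), ("FMN1", "HEM1")], groups, model)
        naive = naive_full_path_rate(p, model)
        # 39 Å single jump: orders of magnitude below the limiting-step rate
        assert naive == pytest.approx(2.2e-6, rel=0.05)
        assert naive < p.chain_rate / 1e4

    def test_single_step_equals_rate(self, model):
        groups = _monomer_groups()
        p = build_pathway([("FMN1", "HEM1")], groups, model)
        assert naive_full_path_rate(p, model) == pytest.approx(p.steps[0].rate, rel=1e-12)


class TestKcatComparison:
    @pytest.mark.parametrize(
        "chain_rate,kcat,verdict",
        [(0.03, 0.03, "consistent"), (0.004, 0.19, "et_slower"), (1e3, 0.19, "et_faster")],
    )
    def test_verdicts(self, model, chain_rate, kcat, verdict):
        from redoxpath.et_model import distance_from_rate

        d = distance_from_rate(model, chain_rate)
        groups = _monomer_groups(d, 5.0)
        p = build_pathway([("FAD1", "FMN1")], groups, model)
        c = compare_with_kcat(p, kcat)
        assert c.verdict == verdict
        assert c.ratio == pytest.approx(p.chain_rate / kcat, rel=1e-12)

    def test_invalid_kcat(self, model):
        p = build_pathway([("FMN1", "HEM1")], _monomer_groups(), model)
        with pytest.raises(ValueError):
            compare_with_kcat(p, 0.0)


class TestAromaticScreen:
    def _structure_with_probe(self, z):
        heme = _group("HEM", 1, (0.0, 0.0, 0.0))
        atoms = [
            AtomRecord(1, "CA", "C", "PHE", 262, "A", (0.0, 0.0, z + 10.0), False),
            AtomRecord(2, "CZ", "C", "PHE", 262, "A", (0.0, 0.0, z + 0.5), False),
        ]
        return Structure(atoms=atoms, source_label="probe"), heme

    def test_contact_flagged_below_threshold(self):
        s, heme = self._structure_with_probe(3.0)
        table = aromatic_contact_screen(s, [("A", 262)], heme)
        assert table.loc[0, "distance"] == pytest.approx(3.0)
        assert bool(table.loc[0, "contact"])

    def test_five_angstrom_not_flagged_at_default(self):
        s, heme = self._structure_with_probe(5.0)
        table = aromatic_contact_screen(s, [("A", 262)], heme)
        assert not bool(table.loc[0, "contact"])

    def test_missing_residue_reported_not_fatal(self):
        s, heme = self._structure_with_probe(3.0)
        table = aromatic_contact_screen(s, [("A", 262), ("A", 500)], heme)
        assert table.loc[1, "note"] == "residue not found"
        assert table.loc[1, "distance"] is None or np.isnan(table.loc[1, "distance"])

    def test_empty_residue_list(self):
        s, heme = self._structure_with_probe(3.0)
        assert len(aromatic_contact_screen(s, [], heme)) == 0


def test_standard_pathways_shapes():
    assert [n for n, _, _ in standard_pathways("monomer")] == ["monomer"]
    names = [n for n, _, _ in standard_pathways("homodimer")]
    assert names == ["intra-1", "intra-2", "cross-1", "cross-2"]
    with pytest.raises(ValueError):
        standard_pathways("trimer")
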