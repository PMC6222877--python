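import json

import numpy as np
import pytest

from tunnelflex.geometry import Axis
from tunnelflex.model_io import (
    BONDI_RADII,
    AtomSphere,
    RadiusTable,
    UnknownElementError,
    assign_radii,
    partition_residue,
    read_pdb,
    read_tunnel,
    write_tunnel,
)
from tunnelflex.tunnel import TunnelProfile


def pdb_line(serial, name, resname, chain, resseq, x, y, z, element,
             altloc=" ", occ=1.0, record="ATOM"):
    name_f = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:5d} {name_f:4s}{altloc:1s}{resname:>3s} "
        f"{chain:1s}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.00:6.2f}          {element:>2s}"
    )


ALA_LINES = [
    pdb_line(1, "N", "ALA", "A", 1, 0.0, 1.4, 0.0, "N"),
    pdb_line(2, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
    pdb_line(3, "C", "ALA", "A", 1, 1.4, -0.6, 0.0, "C"),
    pdb_line(4, "O", "ALA", "A", 1, 2.3, 0.2, 0.0, "O"),
    pdb_line(5, "CB", "ALA", "A", 1, -1.0, -0.5, 1.0, "C"),
]


def write_pdb(tmp_path, lines, name="m.pdb"):
    p = tmp_path / name
    p.write_text("\n".join(lines + ["END"]) + "\n")
    return p


class TestReadPdb:
    def test_single_ala(self, tmp_path):
        mol = read_pdb(write_pdb(tmp_path, ALA_LINES))
        assert len(mol.residues) == 1
        res = mol.residues[0]
        assert len(res.main_chain) == 4 and len(res.side_chain) == 1
        assert res.type == "ALA" and not res.rotatable
        assert res.axis is not None  # CA and CB both present

    def test_hydrogens_ignored(self, tmp_path):
        with_h = ALA_LINES + [
            pdb_line(6, "H", "ALA", "A", 1, 0.5, 2.0, 0.0, "H"),
            pdb_line(7, "HB1", "ALA", "A", 1, -1.5, -1.2, 1.2, "H"),
        ]
        mol_h = read_pdb(write_pdb(tmp_path, with_h, "h.pdb"))
        mol = read_pdb(write_pdb(tmp_path, ALA_LINES, "noh.pdb"))
        names = lambda m: sorted(a.name for a in m.residues[0].atoms)
        assert names(mol_h) == names(mol)

    def test_waters_dropped_heteros_kept(self, tmp_path):
        lines = ALA_LINES + [
            pdb_line(10, "O", "HOH", "A", 90, 9.0, 9.0, 9.0, "O", record="HETATM"),
            pdb_line(11, "FE", "HEM", "A", 91, 5.0, 5.0, 5.0, "FE", record="HETATM"),
        ]
        mol = read_pdb(write_pdb(tmp_path, lines))
        assert len(mol.residues) == 1
        assert [a.element for a in mol.hetero_atoms] == ["FE"]
        mol_no_het = read_pdb(write_pdb(tmp_path, lines), include_hetero=False)
        assert mol_no_het.hetero_atoms == ()

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        lines = list(ALA_LINES)
        # CB in two altlocs; B has higher occupancy and must win
        lines[4] = pdb_line(5, "CB", "ALA", "A", 1, -1.0, -0.5, 1.0, "C",
                            altloc="A", occ=0.4)
        lines.append(pdb_line(6, "CB", "ALA", "A", 1, -1.1, -0.6, 1.1, "C",
                              altloc="B", occ=0.6))
        mol = read_pdb(write_pdb(tmp_path, lines))
        cbs = [a for a in mol.residues[0].side_chain if a.name == "CB"]
        assert len(cbs) == 1
        assert np.allclose(cbs[0].center, [-1.1, -0.6, 1.1])

    def test_altloc_tie_prefers_a(self, tmp_path):
        lines = list(ALA_LINES)
        lines[4] = pdb_line(5, "CB", "ALA", "A", 1, -1.0, -0.5, 1.0, "C",
                            altloc="A", occ=0.5)
        lines.append(pdb_line(6, "CB", "ALA", "A", 1, -1.1, -0.6, 1.1, "C",
                              altloc="B", occ=0.5))
        mol = read_pdb(write_pdb(tmp_path, lines))
        (cb,) = [a for a in mol.residues[0].side_chain if a.name == "CB"]
        assert np.allclose(cb.center, [-1.0, -0.5, 1.0])

    def test_record_order_permutation_invariant(self, tmp_path):
        mol1 = read_pdb(write_pdb(tmp_path, ALA_LINES, "a.pdb"))
        mol2 = read_pdb(write_pdb(tmp_path, ALA_LINES[::-1], "b.pdb"))
        for r1, r2 in zip(mol1.residues, mol2.residues):
            a1 = sorted((a.name, tuple(a.center)) for a in r1.atoms)
            a2 = sorted((a.name, tuple(a.center)) for a in r2.atoms)
            assert a1 == a2

    def test_no_atoms_is_an_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER    EMPTY\nEND\n")
        with pytest.raises(ValueError):
            read_pdb(p)

    def test_unknown_element_names_offender(self, tmp_path):
        lines = ALA_LINES + [
            pdb_line(6, "XX", "ALA", "A", 1, 3.0, 3.0, 3.0, "XQ"),
        ]
        with pytest.raises(UnknownElementError, match="XX"):
            read_pdb(write_pdb(tmp_path, lines))

    def test_chain_filter(self, tmp_path):
        lines = ALA_LINES + [
            pdb_line(6, "N", "GLY", "B", 1, 8.0, 8.0, 8.0, "N"),
            pdb_line(7, "CA", "GLY", "B", 1, 8.0, 9.4, 8.0, "C"),
            pdb_line(8, "C", "GLY", "B", 1, 9.4, 9.9, 8.0, "C"),
            pdb_line(9, "O", "GLY", "B", 1, 10.3, 9.1, 8.0, "O"),
        ]
        mol = read_pdb(write_pdb(tmp_path, lines), chains=["B"])
        assert [r.key[0] for r in mol.residues] == ["B"]


def _atom(name, xyz, key=("A", 1, ""), element="C", radius=1.7, serial=1):
    return AtomSphere(serial=serial, name=name, element=element,
                      center=np.array(xyz, float), radius=radius,
                      residue_key=key)


class TestPartition:
    def test_gly_not_rotatable(self):
        atoms = [_atom(n, (i, 0, 0), serial=i)
                 for i, n in enumerate(["N", "CA", "C", "O"])]
        res = partition_residue(atoms, "GLY")
        assert res.side_chain == () and not res.rotatable and res.axis is None

    def test_ala_cb_on_axis_not_rotatable(self):
        atoms = [_atom(n, (i, 0, 0), serial=i)
                 for i, n in enumerate(["N", "CA", "C", "O", "CB"])]
        res = partition_residue(atoms, "ALA")
        assert [a.name for a in res.side_chain] == ["CB"]
        assert not res.rotatable and res.axis is not None

    def test_leu_rotatable_with_ca_cb_axis(self):
        names = ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"]
        atoms = [_atom(n, (i, 0, 0), serial=i) for i, n in enumerate(names)]
        res = partition_residue(atoms, "LEU")
        assert sorted(a.name for a in res.side_chain) == ["CB", "CD1", "CD2", "CG"]
        assert res.rotatable
        assert np.allclose(res.axis.point_a, (1, 0, 0))
        assert np.allclose(res.axis.point_b, (4, 0, 0))

    def test_duplicate_atom_names_rejected(self):
        atoms = [_atom("CA", (0, 0, 0)), _atom("CA", (1, 0, 0), serial=2)]
        with pytest.raises(ValueError, match="duplicate"):
            partition_residue(atoms, "GLY")


class TestRadii:
    def test_bundled_carbon_value(self):
        assert BONDI_RADII["C"] == 1.70
        assert BONDI_RADII["c"] == 1.70  # case-insensitive

    def test_assign_custom_table(self, tmp_path):
        mol = read_pdb(write_pdb(tmp_path, ALA_LINES))
        custom = RadiusTable({"C": 2.0, "N": 2.0, "O": 2.0}, name="fat")
        out = assign_radii(mol, custom)
        assert all(a.radius == 2.0 for a in out.residues[0].atoms)

    def test_missing_element_named(self, tmp_path):
        mol = read_pdb(write_pdb(tmp_path, ALA_LINES))
        with pytest.raises(UnknownElementError, match="'N'"):
            assign_radii(mol, RadiusTable({"C": 2.0, "O": 1.5}))


class TestTunnelIO:
    def test_tsv_parse(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("t x y z r\n0 0 0 0 1.5\n0.5 1 0 0 1.0\n1 2 0 0 2.0\n")
        tun = read_tunnel(p)
        assert len(tun) == 3
        assert tun.radii[1] == 1.0

    def test_json_parse(self, tmp_path):
        p = tmp_path / "t.json"
        rows = [{"t": 0, "x": 0, "y": 0, "z": 0, "r": 1},
                {"t": 1, "x": 3, "y": 0, "z": 0, "r": 2}]
        p.write_text(json.dumps(rows))
        tun = read_tunnel(p)
        assert len(tun) == 2 and tun.centers[1][0] == 3

    @pytest.mark.parametrize(
        "body", [
            "t x y z r\n0 0 0 0 1\n0 1 0 0 1\n",  # duplicate t
            "t x y z r\n0 0 0 0 1\n0.5 1 0 0 0\n1 0 0 0 1\n",  # zero radius
            "t x y z r\n0 0 0 0 1\n",  # single sample
        ],
    )
    def test_invalid_tunnels_rejected(self, tmp_path, body):
        p = tmp_path / "bad.tsv"
        p.write_text(body)
        with pytest.raises(ValueError):
            read_tunnel(p)

    def test_round_trip_bit_exact(self, tmp_path):
        tun = TunnelProfile(
            t=np.array([0.0, 0.37, 1.0]),
            centers=np.array([[0.1, 0.2, 0.3], [1.1, -2.2, 3.3], [4, 5, 6]]),
            radii=np.array([1.234567891234, 0.5, 2.0]),
        )
        p = tmp_path / "rt.tsv"
        write_tunnel(tun, p)
        back = read_tunnel(p)
        assert np.array_equal(back.t, tun.t)
        assert np.array_equal(back.centers, tun.centers)
        assert np.array_equal(back.radii, tun.radii)
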