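"""Trajectory model, GRO/XYZ I/O and periodic geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micellekit import (Atom, Frame, Trajectory, SpeciesMap, assign_species,
                        minimum_image, read_gro, read_xyz, write_gro)
from micellekit.synthetic import MicelleSpec, build_micelle
from micellekit.trajectory import (ConfigurationError, ParseError,
                                   UnsupportedFormatError, infer_mass)

from .oracles import minimum_image_ref


def small_traj(n_frames=1):
    atoms = [
        Atom(index=0, atom_name="S1", residue_name="SDS", residue_id=1, mass=32.06),
        Atom(index=1, atom_name="C1", residue_name="SDS", residue_id=1, mass=12.011),
        Atom(index=2, atom_name="OW", residue_name="SOL", residue_id=2, mass=15.999),
    ]
    frames = [Frame(coords=np.array([[1.0, 2.0, 3.0], [1.1, 2.1, 3.1],
                                     [4.0, 4.0, 4.0]]) + 0.01 * k,
                    box=np.array([8.0, 8.0, 8.0]), time=float(k))
              for k in range(n_frames)]
    return Trajectory(topology=atoms, frames=frames)


class TestGroRoundTrip:
    def test_single_frame(self, tmp_path):
        traj = small_traj()
        path = tmp_path / "one.gro"
        write_gro(traj, path)
        back = read_gro(path)
        assert back.n_atoms == 3 and back.n_frames == 1
        assert [a.atom_name for a in back.topology] == ["S1", "C1", "OW"]
        assert [a.residue_id for a in back.topology] == [1, 1, 2]
        np.testing.assert_allclose(back.frames[0].coords, traj.frames[0].coords,
                                   atol=1e-3)
        np.testing.assert_allclose(back.frames[0].box, traj.frames[0].box)

    def test_multi_frame_times(self, tmp_path):
        path = tmp_path / "two.gro"
        write_gro(small_traj(n_frames=2), path)
        back = read_gro(path)
        assert back.n_frames == 2
        np.testing.assert_allclose(back.times, [0.0, 1.0])

    def test_position_formatting(self, tmp_path):
        atoms = [Atom(index=0, atom_name="C1", residue_name="MOL", residue_id=1,
                      mass=12.011)]
        traj = Trajectory(topology=atoms,
                          frames=[Frame(coords=[[1.234567, 0.0, 0.0]],
                                        box=[5.0, 5.0, 5.0])])
        path = tmp_path / "fmt.gro"
        write_gro(traj, path)
        assert "1.235" in path.read_text()

    def test_micelle_round_trip_against_mdtraj(self, tmp_path):
        """Our GRO dialect must be readable by an independent reader."""
        mdtraj = pytest.importorskip("mdtraj")
        traj = build_micelle(MicelleSpec(n_surfactants=8, jitter=0.0))
        path = tmp_path / "mic.gro"
        write_gro(traj, path)
        ref = mdtraj.load(str(path))
        np.testing.assert_allclose(ref.xyz[0], traj.frames[0].coords, atol=1e-3)
        np.testing.assert_allclose(np.diag(ref.unitcell_vectors[0]),
                                   traj.frames[0].box, atol=1e-4)


class TestGroErrors:
    def test_atom_count_mismatch(self, tmp_path):
        path = tmp_path / "bad.gro"
        path.write_text("hdr\n    5\n" + "".join(
            f"    1MOL    C{i + 1:>2d}{i + 1:5d}{0.1 * i:8.3f}{0.0:8.3f}{0.0:8.3f}\n"
            for i in range(4)) + "   8.0   8.0   8.0\n")
        with pytest.raises(ParseError):
            read_gro(path)

    def test_truncated_frame_names_line(self, tmp_path):
        path = tmp_path / "trunc.gro"
        path.write_text("hdr\n    3\n    1MOL   C1    1   0.000   0.000   0.000\n")
        with pytest.raises(ParseError, match="line"):
            read_gro(path)

    def test_triclinic_rejected(self, tmp_path):
        path = tmp_path / "tri.gro"
        write_gro(small_traj(), path)
        lines = path.read_text().splitlines()
        lines[-1] = "   8.0   8.0   8.0   0.0   0.0   1.0   0.0   0.0   0.0"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(UnsupportedFormatError):
            read_gro(path)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(topology=[], frames=[])


class TestXyz:
    def test_angstrom_to_nm(self, tmp_path):
        path = tmp_path / "a.xyz"
        path.write_text("2\nt= 5.0\nC 1.0 2.0 3.0\nO 4.0 5.0 6.0\n")
        traj = read_xyz(path, box=(5.0, 5.0, 5.0))
        np.testing.assert_allclose(traj.frames[0].coords,
                                   [[0.1, 0.2, 0.3], [0.4, 0.5, 0.6]])
        assert traj.frames[0].time == 5.0

    def test_count_mismatch(self, tmp_path):
        path = tmp_path / "b.xyz"
        path.write_text("3\ncomment\nC 1 2 3\nO 4 5 6\n")
        with pytest.raises(ParseError):
            read_xyz(path)


class TestMinimumImage:
    @pytest.mark.parametrize("a, b, box, expected", [
        ((0.1, 0, 0), (7.6, 0, 0), (7.7, 7.7, 7.7), (-0.2, 0, 0)),
        ((0.3, 0.4, 0.5), (0.3, 0.4, 0.5), (8, 8, 8), (0, 0, 0)),
        ((0, 0, 0), (3.85, 0, 0), (7.7, 7.7, 7.7), (3.85, 0, 0)),  # +L/2 boundary
    ])
    def test_examples(self, a, b, box, expected):
        np.testing.assert_allclose(minimum_image(a, b, np.array(box)), expected,
                                   atol=1e-12)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=6, max_size=6),
           st.floats(0.5, 20))
    def test_antisymmetry_and_bound(self, vals, edge):
        a, b = np.array(vals[:3]), np.array(vals[3:])
        box = np.full(3, edge)
        d_ab = minimum_image(a, b, box)
        d_ba = minimum_image(b, a, box)
        # antisymmetric except exactly on the +L/2 boundary
        on_boundary = np.isclose(np.abs(d_ab), edge / 2)
        np.testing.assert_allclose(d_ab[~on_boundary], -d_ba[~on_boundary],
                                   atol=1e-9)
        assert np.linalg.norm(d_ab) <= np.sqrt(3) / 2 * edge + 1e-9
        np.testing.assert_allclose(d_ab, minimum_image_ref(a, b, box), atol=1e-9)


class TestSpecies:
    def smap(self):
        return SpeciesMap(rules={
            "SDS": {"S1": {"species": "Surf", "site_role": "head", "mass": 32.06},
                    "*": {"species": "Surf", "site_role": "none", "mass": None}},
            "SOL": {"OW": {"species": "HBD", "site_role": "acceptor", "mass": None}},
        })

    def test_mapped_atoms_labeled(self):
        traj = assign_species(small_traj(), self.smap())
        assert traj.topology[0].species == "Surf"
        assert traj.topology[0].site_role == "head"
        assert traj.topology[1].species == "Surf"      # via wildcard
        assert traj.topology[2].species == "HBD"

    def test_unmapped_strict_names_offender(self):
        traj = small_traj()
        traj.topology[2] = Atom(index=2, atom_name="XX", residue_name="XYZ",
                                residue_id=2, mass=1.0)
        with pytest.raises(ConfigurationError, match="XYZ"):
            assign_species(traj, self.smap())

    def test_unmapped_permissive_becomes_other(self):
        traj = small_traj()
        traj.topology[2] = Atom(index=2, atom_name="XX", residue_name="XYZ",
                                residue_id=2, mass=1.0)
        out = assign_species(traj, self.smap(), permissive=True)
        assert out.topology[2].species == "Other"

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "map.yaml"
        self.smap().to_yaml(path)
        back = SpeciesMap.from_yaml(path)
        assert back.lookup("SDS", "S1")["species"] == "Surf"
        assert back.lookup("SDS", "C7")["species"] == "Surf"  # wildcard survives
        assert back.mass_override("SDS", "S1") == 32.06

    def test_mass_inference(self):
        assert infer_mass("C12") == 12.011
        assert infer_mass("HY") == 1.008
        assert infer_mass("1H") == 1.008
        with pytest.raises(ConfigurationError):
            infer_mass("Qq")
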