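import numpy as np
import pytest

from qebss import traj_io
from qebss.exceptions import (
    EmptyTrajectoryError,
    FormatError,
    MissingAmideHydrogenError,
)

from conftest import default_peptide_coords, make_multimodel_pdb


class TestLoadTrajectory:
    def test_all_frames_retained_without_skip(self, peptide_pdb):
        traj = traj_io.load_trajectory(peptide_pdb, frame_spacing=10.0)
        assert traj.frame_count == 11
        assert traj.frame_spacing == 10.0
        assert [r[1] for r in traj.residues] == ["ALA", "GLY", "LEU"]

    def test_skip_time_counts_frames_at_or_after_cutoff(self, peptide_pdb):
        # frames at 0,10,...,100 ps; t >= 50 keeps 50..100
        traj = traj_io.load_trajectory(peptide_pdb, skip_time=50.0,
                                       frame_spacing=10.0)
        assert traj.frame_count == 6
        assert traj.times[0] == 50.0

    def test_equilibration_skip_of_microsecond_run(self, tmp_path):
        # 10 frames spanning 1 us at 100 ns spacing; dropping the first
        # 300 ns equilibration retains 70% of the frames
        resnames = ["ALA", "GLY"]
        frames = [default_peptide_coords(resnames) for _ in range(10)]
        p = tmp_path / "long.pdb"
        p.write_text(make_multimodel_pdb(resnames, frames))
        traj = traj_io.load_trajectory(p, skip_time=300_000.0,
                                       frame_spacing=100_000.0)
        assert traj.frame_count == 7
        assert traj.frame_count / 10 == 0.7

    def test_skip_beyond_duration_raises(self, peptide_pdb):
        with pytest.raises(EmptyTrajectoryError):
            traj_io.load_trajectory(peptide_pdb, skip_time=1e9,
                                    frame_spacing=10.0)

    def test_missing_file_raises_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            traj_io.load_trajectory(tmp_path / "nope.pdb")

    def test_skipping_preserves_retained_frame_values(self, peptide_pdb):
        full = traj_io.load_trajectory(peptide_pdb, frame_spacing=10.0)
        part = traj_io.load_trajectory(peptide_pdb, skip_time=30.0,
                                       frame_spacing=10.0)
        v_full = traj_io.extract_nh_vectors(full)
        v_part = traj_io.extract_nh_vectors(part)
        np.testing.assert_allclose(v_full[0].vectors[3:], v_part[0].vectors)


class TestExtractNHVectors:
    def test_first_residue_dropped_by_default(self, peptide_pdb):
        traj = traj_io.load_trajectory(peptide_pdb, frame_spacing=10.0)
        series = traj_io.extract_nh_vectors(traj)
        assert [s.residue_id for s in series] == [2, 3]

    def test_proline_absent_from_output(self, proline_pdb):
        traj = traj_io.load_trajectory(proline_pdb, frame_spacing=10.0)
        series = traj_io.extract_nh_vectors(traj)
        assert [s.residue_id for s in series] == [3, 4]

    def test_explicit_proline_request_raises(self, proline_pdb):
        traj = traj_io.load_trajectory(proline_pdb, frame_spacing=10.0)
        with pytest.raises(MissingAmideHydrogenError, match="2"):
            traj_io.extract_nh_vectors(traj, residue_ids=[2, 3])

    def test_vectors_are_normalized_along_nh_bond(self, peptide_pdb):
        # geometry: H is 1.02 A along +z from N, so the unit vector is e_z
        traj = traj_io.load_trajectory(peptide_pdb, frame_spacing=10.0)
        series = traj_io.extract_nh_vectors(traj)
        for s in series:
            np.testing.assert_allclose(s.vectors, [[0.0, 0.0, 1.0]] * 11,
                                       atol=1e-6)

    def test_translation_invariance_and_rotation_equivariance(self, tmp_path):
        resnames = ["ALA", "GLY", "LEU"]
        base = default_peptide_coords(resnames)
        shifted = default_peptide_coords(resnames, displacement=(7.0, -3.0, 2.0))
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ])
        rot = rot @ np.array([[1, 0, 0], [0, 0, -1.0], [0, 1, 0]])
        rotated = {k: tuple(rot @ np.array(v)) for k, v in base.items()}

        def vectors(coords):
            p = tmp_path / f"v{len(list(tmp_path.iterdir()))}.pdb"
            p.write_text(make_multimodel_pdb(resnames, [coords] * 2))
            traj = traj_io.load_trajectory(p, frame_spacing=10.0)
            return np.array([s.vectors for s in traj_io.extract_nh_vectors(traj)])

        v0, v_shift, v_rot = vectors(base), vectors(shifted), vectors(rotated)
        np.testing.assert_allclose(v_shift, v0, atol=1e-5)
        np.testing.assert_allclose(v_rot, v0 @ rot.T, atol=1e-5)


class TestRelaxationTables:
    def test_csv_with_noe_alias(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("res,T1,T2,NOE\n2,0.5,0.1,0.7\n3,0.6,0.12,0.75\n4,0.55,0.11,0.72\n")
        prof = traj_io.read_relaxation_table(p)
        assert len(prof.residue_ids) == 3
        np.testing.assert_allclose(prof.t1, [0.5, 0.6, 0.55])

    def test_missing_cell_is_nan_not_zero(self, tmp_path):
        p = tmp_path / "gap.csv"
        p.write_text("res,T1,T2,NOE\n6,0.5,0.1,0.7\n7,,0.1,0.7\n8,0.5,0.1,0.7\n")
        prof = traj_io.read_relaxation_table(p)
        assert np.isnan(prof.t1[1])
        assert np.isfinite(prof.t2[1])

    def test_millisecond_dialect_converts_to_seconds(self, tmp_path):
        p = tmp_path / "ms.csv"
        p.write_text("res,T1,T2,NOE\n2,500,100,0.7\n")
        prof = traj_io.read_relaxation_table(p, dialect="ms")
        assert prof.t1[0] == pytest.approx(0.5)
        assert prof.t2[0] == pytest.approx(0.1)

    def test_bracket_units_in_header(self, tmp_path):
        p = tmp_path / "u.txt"
        p.write_text("# residue T1[ms] T2[ms] hetNOE\n2 500 100 0.7\n")
        prof = traj_io.read_relaxation_table(p)
        assert prof.t1[0] == pytest.approx(0.5)

    def test_duplicate_residues_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("res,T1,T2,NOE\n2,0.5,0.1,0.7\n2,0.6,0.1,0.7\n")
        with pytest.raises(FormatError, match="duplicate"):
            traj_io.read_relaxation_table(p)

    def test_unparseable_unit_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("# residue T1[fortnights] T2[s] hetNOE\n2 1 0.1 0.7\n")
        with pytest.raises(FormatError, match="unit"):
            traj_io.read_relaxation_table(p)

    def test_write_read_round_trip_lossless(self, tmp_path):
        prof = traj_io.RelaxationProfile(
            residue_ids=[2, 3, 5],
            t1=[0.512345678901234, 0.6, np.nan],
            t2=[0.1, np.nan, 0.12],
            hetnoe=[0.7, -0.3, 0.78],
            field_mhz=850.0,
        )
        p = tmp_path / "rt.tsv"
        traj_io.write_relaxation_table(prof, p)
        back = traj_io.read_relaxation_table(p)
        np.testing.assert_array_equal(back.residue_ids, prof.residue_ids)
        for name in ("t1", "t2", "hetnoe"):
            np.testing.assert_allclose(
                back.observable(name), prof.observable(name),
                rtol=1e-12, equal_nan=True,
            )
        assert back.field_mhz == 850.0


class TestXvg:
    def test_headers_skipped(self, tmp_path):
        p = tmp_path / "a.xvg"
        p.write_text('@ title "x"\n@ xaxis label "t"\n@ yaxis label "g"\n'
                     "0 1.0\n10 0.9\n20 0.8\n30 0.7\n")
        t, v = traj_io.read_xvg_acf(p)
        assert t.size == 4
        np.testing.assert_allclose(v, [1.0, 0.9, 0.8, 0.7])

    def test_constant_acf(self, tmp_path):
        p = tmp_path / "c.xvg"
        p.write_text("\n".join(f"{10*i} 1.0" for i in range(5)) + "\n")
        _, v = traj_io.read_xvg_acf(p)
        np.testing.assert_array_equal(v, 1.0)

    def test_round_trip_lossless(self, tmp_path):
        t = 10.0 * np.arange(50)
        v = np.exp(-t / 123.456789)
        p = tmp_path / "rt.xvg"
        traj_io.write_xvg(p, t, v)
        t2, v2 = traj_io.read_xvg_acf(p)
        np.testing.assert_allclose(t2, t, rtol=1e-12)
        np.testing.assert_allclose(v2, v, rtol=1e-12)

    def test_non_monotonic_times_rejected(self, tmp_path):
        p = tmp_path / "bad.xvg"
        p.write_text("0 1.0\n20 0.9\n10 0.8\n")
        with pytest.raises(FormatError, match="increasing"):
            traj_io.read_xvg_acf(p)
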