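import numpy as np
import pytest


def _pdb_atom_line(serial, name, resname, resid, xyz, element):
    x, y, z = xyz
    return (
        f"ATOM  {serial:>5d} {name:^4s} {resname:<3s} A{resid:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
    )


def make_multimodel_pdb(resnames, frames):
    """Multi-model PDB text for a toy peptide.

    ``frames`` is a list of dicts mapping (residue_index, atom_name) to an
    (x, y, z) tuple in Angstrom.  Prolines get no amide H.
    """
    lines = []
    for m, coords in enumerate(frames, start=1):
        lines.append(f"MODEL     {m:>4d}")
        serial = 1
        for i, resname in enumerate(resnames):
            atom_names = ["N", "CA"] if resname == "PRO" else ["N", "H", "CA"]
            for name in atom_names:
                xyz = coords[(i, name)]
                element = name[0]
                lines.append(
                    _pdb_atom_line(serial, name, resname, i + 1, xyz, element)
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def default_peptide_coords(resnames, displacement=(0.0, 0.0, 0.0)):
    """Fixed toy geometry: residue i offset by 4 Å along x; N-H along z."""
    dx, dy, dz = displacement
    coords = {}
    for i, resname in enumerate(resnames):
        base = np.array([4.0 * i + dx, dy, dz])
        coords[(i, "N")] = tuple(base)
        coords[(i, "H")] = tuple(base + [0.0, 0.0, 1.02])
        coords[(i, "CA")] = tuple(base + [1.5, 0.8, 0.0])
    return coords


@pytest.fixture
def peptide_pdb(tmp_path):
    """11-frame multi-model PDB of a 3-residue peptide with fixed geometry."""
    resnames = ["ALA", "GLY", "LEU"]
    frames = [default_peptide_coords(resnames) for _ in range(11)]
    path = tmp_path / "peptide.pdb"
    path.write_text(make_multimodel_pdb(resnames, frames))
    return path


@pytest.fixture
def proline_pdb(tmp_path):
    resnames = ["ALA", "PRO", "LEU", "GLY"]
    frames = [default_peptide_coords(resnames) for _ in range(3)]
    path = tmp_path / "pro_peptide.pdb"
    path.write_text(make_multimodel_pdb(resnames, frames))
    return path
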