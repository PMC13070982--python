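"""Shared fixtures: programmatic PDB text and small NOE graphs."""

from __future__ import annotations

import numpy as np
import pytest

from methylwalk import NOEGraph


def pdb_text(residues, model_blocks=None) -> str:
    """Render minimal PDB ATOM records.

    ``residues`` is a list of ``(chain, resnum, resname, {atom: (x, y, z)})``.
    ``model_blocks`` — a list of such lists — renders a multi-MODEL file.
    """
    blocks = model_blocks if model_blocks is not None else [residues]
    lines = []
    serial = 1
    multi = len(blocks) > 1
    for num, block in enumerate(blocks, start=1):
        if multi:
            lines.append(f"MODEL     {num:4d}")
        for chain, resnum, resname, atoms in block:
            for name, xyz in atoms.items():
                x, y, z = xyz
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} {chain}"
                    f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                    f"           C"
                )
                serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def four_residue_pdb(tmp_path):
    """1 Met, 1 Ile, 2 Leu with full methyl carbons, spread out in space."""
    residues = [
        ("A", 1, "MET", {"CE": (0.0, 0.0, 0.0)}),
        ("A", 2, "ILE", {"CD1": (5.0, 0.0, 0.0)}),
        ("A", 3, "LEU", {"CD1": (0.0, 5.0, 0.0), "CD2": (1.5, 5.0, 0.0)}),
        ("A", 4, "LEU", {"CD1": (5.0, 5.0, 0.0), "CD2": (6.5, 5.0, 0.0)}),
    ]
    path = tmp_path / "four.pdb"
    path.write_text(pdb_text(residues))
    return path


def peaklist(rows, header="auto_peak_id\tauto_aa_type\tcross_peak_id\tcross_aa_type") -> str:
    return header + "\n" + "\n".join(rows) + "\n"


def simple_noe(edges, types) -> NOEGraph:
    """Build an NOEGraph from (auto, cross) pairs and a type map."""
    g = NOEGraph()
    for res, t in types.items():
        g.add_resonance(res, t)
    for a, b in edges:
        g.add_contact(a, b)
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
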