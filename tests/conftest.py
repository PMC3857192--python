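"""Shared fixtures: a hand-written fixed-column PDB builder kept independent
of the package's own serializer so parser tests are not self-referential."""

from __future__ import annotations

import numpy as np
import pytest


def atom_line(serial, name, resname, chain, resnum, x, y, z,
              altloc=" ", icode=" ", occupancy=1.0, bfactor=0.0,
              element=None, record="ATOM  ") -> str:
    """Compose one fixed-column coordinate line (wwPDB v3.3 layout)."""
    if element is None:
        element = name.strip()[0]
    if len(name) >= 4:
        name_field = name[:4]
    else:
        name_field = f" {name:<3s}"
    return (f"{record:<6s}{serial:5d} {name_field}{altloc:1s}{resname:>3s} "
            f"{chain:1s}{resnum:4d}{icode:1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{bfactor:6.2f}"
            f"          {element:>2s}")


def simple_residue_lines(chain, resnum, resname, cb_xyz, serial_start=1,
                         with_cb=True):
    """N/CA/C(/CB) lines for one residue, backbone offset from the CB."""
    x, y, z = cb_xyz
    lines = [
        atom_line(serial_start, "N", resname, chain, resnum,
                  x - 0.7, y + 1.2, z + 1.8),
        atom_line(serial_start + 1, "CA", resname, chain, resnum,
                  x, y, z + 1.5),
        atom_line(serial_start + 2, "C", resname, chain, resnum,
                  x + 0.8, y + 1.1, z + 1.3),
    ]
    if with_cb:
        lines.append(atom_line(serial_start + 3, "CB", resname, chain,
                               resnum, x, y, z))
    return lines


def build_pdb(chains):
    """chains: {chain_id: [(resnum, resname, (x, y, z)), ...]} -> PDB text."""
    lines = []
    serial = 1
    for chain_id, residues in chains.items():
        for resnum, resname, xyz in residues:
            with_cb = resname != "GLY"
            res_lines = simple_residue_lines(chain_id, resnum, resname, xyz,
                                             serial_start=serial,
                                             with_cb=with_cb)
            serial += len(res_lines)
            lines.extend(res_lines)
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def two_chain_pdb_text():
    """Chains A (10 residues) and B (8 residues), single conformer."""
    chains = {
        "A": [(i, "ALA", (4.0 * i, 0.0, 0.0)) for i in range(1, 11)],
        "B": [(i, "VAL", (4.0 * i, 15.0, 0.0)) for i in range(1, 9)],
    }
    return build_pdb(chains)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
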