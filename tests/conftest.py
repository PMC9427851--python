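import numpy as np
import pytest

import pcsgrid as pg


@pytest.fixture(scope="session")
def default_spec():
    return pg.SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def structure(default_spec):
    return pg.make_toy_structure(default_spec)


@pytest.fixture(scope="session")
def tensor(default_spec):
    return pg.planted_tensor(default_spec)


@pytest.fixture(scope="session")
def noiseless_table(structure, tensor):
    table, truth = pg.simulate_pcs(structure, tensor, noise_sd=0.0, seed=11)
    return table, truth


def _pdb_line(serial, name, resname, resseq, x, y, z, record="ATOM", element=" C"):
    return (
        f"{record:<6s}{serial:>5d} {name:<4s}{resname:>4s} A{resseq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element}"
    )


@pytest.fixture(scope="session")
def toy_pdb_text():
    """Three-residue toy: one Ala, one Val, a pivot Gly, and a Dy ion."""
    lines = [
        _pdb_line(1, "CB", "ALA", 70, 10.0, 0.0, 0.0),
        _pdb_line(2, "CA", "VAL", 170, 0.0, 0.0, 0.0),
        _pdb_line(3, "CG1", "VAL", 170, 1.0, 2.0, 3.0),
        _pdb_line(4, "CG2", "VAL", 170, -1.0, 2.0, 3.0),
        _pdb_line(5, "CA", "GLY", 165, 5.0, 5.0, 5.0),
        _pdb_line(6, "DY", "DY", 300, 0.0, 0.0, 20.0, record="HETATM", element="DY"),
        "END",
    ]
    return "\n".join(lines) + "\n"
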