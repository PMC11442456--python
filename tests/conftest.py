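import numpy as np
import pytest

from amyloidsim import chemshift, model_io, synthetic

TWO_ATOM_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def two_atom_pdb(tmp_path):
    p = tmp_path / "two_atom.pdb"
    p.write_text(TWO_ATOM_PDB)
    return p


@pytest.fixture
def five_chain_pdb(tmp_path):
    lines = []
    serial = 1
    for i, chain in enumerate("ABCDE"):
        for name, x in (("N", 0.0), ("CA", 1.458)):
            lines.append(
                f"ATOM  {serial:>5}  {name:<3}ALA {chain}   1    "
                f"{x:8.3f}{i * 10.0:8.3f}{0.0:8.3f}  1.00  0.00           {name[0]:>1}"
            )
            serial += 1
    p = tmp_path / "five_chain.pdb"
    p.write_text("\n".join(lines) + "\nEND\n")
    return p


@pytest.fixture
def one_residue_structure():
    """Single Ala with CA and CB 1.53 Å apart."""
    return model_io.Structure(
        atoms=[
            model_io.Atom("A", 1, "ALA", "CA", "C", (0.0, 0.0, 0.0)),
            model_io.Atom("A", 1, "ALA", "CB", "C", (1.53, 0.0, 0.0)),
        ],
        model_label="toy",
    )


@pytest.fixture
def toy_shifts():
    return chemshift.ShiftTable(
        entries=[
            chemshift.ShiftEntry(1, "ALA", "CA", "C13", 55.1),
            chemshift.ShiftEntry(1, "ALA", "CB", "C13", 18.6),
        ]
    )


@pytest.fixture(scope="session")
def helix12():
    return synthetic.generate_helix(12)


@pytest.fixture(scope="session")
def ala_stack5():
    return synthetic.generate_beta_stack("A" * 20, n_layers=5)


@pytest.fixture(scope="session")
def strand_shifts20():
    ssmap = model_io.SecondaryStructureMap([model_io.Span(1, 20, "strand", "s")])
    return chemshift.predict_shifts("A" * 20, ssmap)


def brute_force_cc_pairs(model, shifts, cutoff, filter="all", source_chains=None):
    """Independent O(n^2) all-pairs enumeration of CC cross-peak positions.

    Returns the multiset of (omega1, omega2) ordered-pair positions before any
    merging, for carbons with shifts, pairs within cutoff passing the filter,
    and (if given) at least one atom in source_chains.
    """
    carbons = [
        a
        for a in model.atoms
        if (a.element == "C" or (not a.element and a.atom_name.startswith("C")))
        and shifts.get(a.residue_number, a.atom_name) is not None
    ]
    out = []
    for i, ai in enumerate(carbons):
        for j, aj in enumerate(carbons):
            if i == j:
                continue
            if source_chains is not None and not (
                ai.chain_id in source_chains or aj.chain_id in source_chains
            ):
                continue
            d = np.linalg.norm(np.subtract(ai.xyz, aj.xyz))
            if d > cutoff:
                continue
            intra = ai.chain_id == aj.chain_id and ai.residue_number == aj.residue_number
            if filter == "intra_residue_only" and not intra:
                continue
            if filter == "inter_residue_only" and intra:
                continue
            out.append(
                (
                    shifts.get(ai.residue_number, ai.atom_name),
                    shifts.get(aj.residue_number, aj.atom_name),
                )
            )
    return out
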