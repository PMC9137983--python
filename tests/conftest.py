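"""Shared fixtures: small synthetic structures, alignments and a PDB file.

Everything is generated programmatically; the session scope keeps the
expensive detection fixtures to a single run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from pocketcons import seqcons, sitefind, synthdata

TEST_SPACING = 0.7  # A; desk-scale grid (production default is 0.35)


@pytest.fixture(scope="session")
def cavity_spec():
    return synthdata.SyntheticStructureSpec(
        shell_radius=12.0, cavity_radius=4.0, mouth_fraction=0.0,
        residue_count=90, seed=11)


@pytest.fixture(scope="session")
def cavity_structure(cavity_spec):
    return synthdata.generate_structure(cavity_spec)


@pytest.fixture(scope="session")
def rate_class_alignment():
    """8-leaf, 400-column alignment with planted slow/fast rate classes."""
    tree = synthdata.balanced_tree(8, 0.3)
    spec = synthdata.SyntheticAlignmentSpec(
        tree=tree, n_columns=400, rate_classes=((0.1, 0.5), (5.0, 0.5)), seed=3)
    aln, truth = synthdata.evolve_alignment(spec)
    return aln, truth


@pytest.fixture(scope="session")
def scored_profile(rate_class_alignment):
    aln, truth = rate_class_alignment
    tree = seqcons.build_nj_tree(seqcons.pairwise_distance(aln))
    profile = seqcons.assign_grades(seqcons.score_conservation(aln, tree))
    return profile, truth


# ---------------------------------------------------------------------------
# hand-written PDB fixture for ingest tests


def _atom(record, serial, name, resname, chain, resnum, x, y, z,
          element, altloc=" ", bfac=20.0):
    nm = name if len(name) >= 4 else f" {name:<3}"
    return (f"{record:<6}{serial:>5} {nm:<4}{altloc}{resname:>3} {chain}"
            f"{resnum:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{bfac:6.2f}"
            f"          {element:>2}")


@pytest.fixture()
def two_chain_pdb(tmp_path):
    """Chains A and B, waters, an NAD ligand, an Mg ion and an MSE residue."""
    lines = [
        "HEADER    TEST PROTEIN                            01-JAN-20   XXXX",
        "REMARK   2 RESOLUTION.    1.80 ANGSTROMS.",
        "REMARK 465   M RES C SSSEQI",
        "REMARK 465     ALA A     99",
        "HELIX    1   1 ALA A    1  GLY A    2  1                               2",
        "SHEET    1 S1  1 TRP A   3  TRP A   3  0",
    ]
    serial = 1
    # chain A: ALA-GLY-TRP-MSE, CA + one side-chain atom each
    rows = [("ALA", 1, "C"), ("GLY", 2, "C"), ("TRP", 3, "C"), ("MSE", 4, "SE")]
    for resname, num, el in rows:
        record = "HETATM" if resname == "MSE" else "ATOM"
        lines.append(_atom(record, serial, "CA", resname, "A", num,
                           float(num) * 3.0, 0.0, 0.0, "C"))
        serial += 1
        side = "SE" if resname == "MSE" else "CB"
        lines.append(_atom(record, serial, side, resname, "A", num,
                           float(num) * 3.0, 1.5, 0.0, el))
        serial += 1
    # altloc pair on residue 1 — only altloc A must be kept
    lines.append(_atom("ATOM", serial, "CG", "ALA", "A", 1, 3.0, 2.8, 0.0,
                       "C", altloc="A"))
    serial += 1
    lines.append(_atom("ATOM", serial, "CG", "ALA", "A", 1, 3.2, 2.8, 0.0,
                       "C", altloc="B"))
    serial += 1
    # chain B
    lines.append(_atom("ATOM", serial, "CA", "VAL", "B", 1, 0.0, 8.0, 0.0, "C"))
    serial += 1
    # heteroatoms on chain A: waters, an NAD and a magnesium
    for i in range(3):
        lines.append(_atom("HETATM", serial, "O", "HOH", "A", 500 + i,
                           10.0 + i, 10.0, 0.0, "O"))
        serial += 1
    lines.append(_atom("HETATM", serial, "C1", "NAD", "A", 600, 5.0, 5.0, 5.0, "C"))
    serial += 1
    lines.append(_atom("HETATM", serial, "MG", "MG", "A", 700, 6.0, 6.0, 6.0, "MG"))
    serial += 1
    lines.append("END")
    path = tmp_path / "fixture.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def detected_sites(cavity_structure):
    """Sites detected on the enclosed-cavity structure at test spacing."""
    return sitefind.find_sites(cavity_structure, spacing=TEST_SPACING, margin=4.0)


def halfspace_atoms():
    """Dense slab of carbon atoms filling z <= 0 (half-space fixture)."""
    xs = np.arange(-12.0, 12.01, 1.5)
    zs = np.array([0.0, -1.5, -3.0, -4.5, -6.0])
    pts = np.array([[x, y, z] for x in xs for y in xs for z in zs])
    return pts, np.full(len(pts), 1.7)
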