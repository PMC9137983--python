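"""PDB ingest, cleanup, superposition and conformational clustering.

Ingest follows the monomer-analysis convention: a single chain is retained
(chain A unless told otherwise), ligands, waters and other co-crystallised
molecules are stripped, a magnesium cofactor is kept when present, and
selenomethionine is read as methionine.  Pairwise structural comparison is a
least-squares (Kabsch) superposition on common C-alpha atoms; ensembles are
clustered with k-means on a classical-MDS embedding of the RMSD matrix and one
representative per cluster is chosen by resolution, completeness and B-factor.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.PDB import PDBParser
from Bio.SVDSuperimposer import SVDSuperimposer
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .config import VDW_DEFAULT, VDW_RADII

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items() if k != "MSE"}

WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureError(ValueError):
    """Raised for unusable structure input (missing chain, empty file...)."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) A
    bfactor: float = 0.0

    @property
    def vdw(self) -> float:
        return VDW_RADII.get(self.element.upper(), VDW_DEFAULT)


@dataclass
class Residue:
    number: int
    name: str  # 3-letter code
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.name, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    """A single-chain protein structure with optional cofactor/ligand atoms."""

    chain_id: str
    residues: list[Residue]
    cofactor_atoms: list[Atom] = field(default_factory=list)
    ligand_atoms: list[Atom] = field(default_factory=list)
    ss: dict[int, str] = field(default_factory=dict)  # residue number -> H/E
    metadata: dict = field(default_factory=dict)
    label: str = ""

    # ---- derived arrays (polymer + cofactor = "protein heavy atoms") ----

    def _protein_atoms(self) -> list[tuple[int, Atom]]:
        out = []
        for ri, res in enumerate(self.residues):
            for a in res.atoms:
                out.append((ri, a))
        for a in self.cofactor_atoms:
            out.append((-1, a))
        return out

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for _, a in self._protein_atoms()], float).reshape(-1, 3)

    @property
    def elements(self) -> list[str]:
        return [a.element.upper() for _, a in self._protein_atoms()]

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw for _, a in self._protein_atoms()], float)

    @property
    def atom_residue_index(self) -> np.ndarray:
        """Residue index per protein atom; -1 for cofactor atoms."""
        return np.array([ri for ri, _ in self._protein_atoms()], int)

    def ca_coords(self) -> dict[int, np.ndarray]:
        out = {}
        for res in self.residues:
            ca = res.atom("CA")
            if ca is not None:
                out[res.number] = ca.coord
        return out

    def ss_class(self, resnum: int) -> str:
        """'helix' / 'sheet' / 'loop' for a residue number."""
        kind = self.ss.get(resnum)
        return {"H": "helix", "E": "sheet"}.get(kind, "loop")

    def __len__(self) -> int:
        return len(self.residues)

    def to_pdb(self, path: str | Path | None = None) -> str:
        """Serialise to PDB v3.3 text (deterministic byte layout)."""
        lines = []
        # group contiguous SS runs into HELIX/SHEET records
        runs: list[tuple[str, int, int]] = []
        for num in sorted(self.ss):
            kind = self.ss[num]
            if runs and runs[-1][0] == kind and runs[-1][2] == num - 1:
                runs[-1] = (kind, runs[-1][1], num)
            else:
                runs.append((kind, num, num))
        h_idx = e_idx = 0
        for kind, start, end in runs:
            if kind == "H":
                h_idx += 1
                lines.append(
                    f"HELIX  {h_idx:>3} {h_idx:>3} "
                    f"{'ALA':>3} {self.chain_id}{start:>5}  "
                    f"{'ALA':>3} {self.chain_id}{end:>5}  1"
                    f"{'':>30}{end - start + 1:>6}"
                )
            else:
                e_idx += 1
                lines.append(
                    f"SHEET  {e_idx:>3} S{e_idx:<2} 1 "
                    f"{'ALA':>3} {self.chain_id}{start:>4}  "
                    f"{'ALA':>3} {self.chain_id}{end:>4}  0"
                )
        serial = 1
        for res in self.residues:
            for a in res.atoms:
                lines.append(_pdb_atom_line("ATOM", serial, a, res.name,
                                            self.chain_id, res.number))
                serial += 1
        last_res = self.residues[-1].number if self.residues else 0
        lines.append(f"TER   {serial:>5}      {'ALA':>3} {self.chain_id}{last_res:>4}")
        serial += 1
        for a in self.cofactor_atoms:
            lines.append(_pdb_atom_line("HETATM", serial, a, "MG", self.chain_id, 9001))
            serial += 1
        for a in self.ligand_atoms:
            lines.append(_pdb_atom_line("HETATM", serial, a, "LIG", self.chain_id, 9101))
            serial += 1
        lines.append("END")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def _pdb_atom_line(record: str, serial: int, a: Atom, resname: str,
                   chain: str, resnum: int) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3}"
    x, y, z = (float(v) for v in a.coord)
    return (f"{record:<6}{serial:>5} {name:<4} {resname:>3} {chain}"
            f"{resnum:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{a.bfactor:6.2f}"
            f"          {a.element.upper():>2}")


# ---------------------------------------------------------------------------
# ingest


def load_structure(source: str | Path, chain: str = "A") -> Structure:
    """Read one chain of a PDB file, stripped for pocket analysis.

    Keeps the first MODEL, altloc 'A'/blank atoms and the requested chain's
    polymer heavy atoms; MSE is read as methionine; HETATMs are dropped except
    magnesium, which is kept as a cofactor.  HELIX/SHEET records become
    per-residue secondary-structure annotations, and resolution / missing
    residue counts are pulled from the header when present.
    """
    path = Path(source)
    text = path.read_text()
    if not text.strip():
        raise StructureError(f"empty PDB file: {source}")

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = next(parser.get_structure("s", io.StringIO(text)).get_models())
    chains = [c.id for c in model]
    if chain not in chains:
        raise StructureError(
            f"chain {chain!r} not found in {source}; available chains: {sorted(chains)}")

    residues: list[Residue] = []
    cofactors: list[Atom] = []
    for bres in model[chain]:
        het, resnum, icode = bres.id
        resname = bres.get_resname().strip()
        if resname in WATER_NAMES:
            continue
        is_polymer = (het == " ") or resname == "MSE"
        if not is_polymer:
            if resname == "MG":
                for ba in bres:
                    cofactors.append(_atom_from_biopdb(ba))
            continue
        name = "MET" if resname == "MSE" else resname
        atoms = []
        for ba in bres.get_unpacked_list():
            if ba.get_altloc() not in (" ", "A"):
                continue
            atom = _atom_from_biopdb(ba)
            if atom.element == "H":
                continue
            if resname == "MSE" and atom.name == "SE":
                atom.name, atom.element = "SD", "S"
            atoms.append(atom)
        if atoms:
            residues.append(Residue(resnum, name, atoms, icode.strip()))

    ss: dict[int, str] = {}
    n_missing = 0
    resolution = None
    for line in text.splitlines():
        rec = line[:6]
        if rec == "HELIX " and len(line) >= 38 and line[19] == chain:
            try:
                a, b = int(line[21:25]), int(line[33:37])
                for n in range(a, b + 1):
                    ss[n] = "H"
            except ValueError:
                pass
        elif rec == "SHEET " and len(line) >= 38 and line[21] == chain:
            try:
                a, b = int(line[22:26]), int(line[33:37])
                for n in range(a, b + 1):
                    ss[n] = "E"
            except ValueError:
                pass
        elif line.startswith("REMARK 465") and len(line.split()) == 5:
            parts = line.split()
            if parts[3] == chain and parts[2] in AA3_TO_1:
                n_missing += 1
        elif line.startswith("REMARK   2 RESOLUTION"):
            for tok in line.split()[3:]:
                try:
                    resolution = float(tok)
                    break
                except ValueError:
                    continue

    bvals = [a.bfactor for r in residues for a in r.atoms]
    meta = {
        "resolution": resolution,
        "missing_residues": n_missing,
        "mean_bfactor": float(np.mean(bvals)) if bvals else 0.0,
    }
    return Structure(chain, residues, cofactor_atoms=cofactors, ss=ss,
                     metadata=meta, label=path.stem)


def _atom_from_biopdb(ba) -> Atom:
    element = (ba.element or "").strip().upper() or ba.get_name().strip()[0]
    return Atom(ba.get_name().strip(), element,
                np.asarray(ba.coord, float), float(ba.get_bfactor()))


def extract_sequence(s: Structure):
    """One-letter sequence in residue order; nonstandard residues become 'X'."""
    from .seqcons import SequenceRecord

    seq = "".join(res.one_letter for res in s.residues)
    if not seq:
        warnings.warn(f"structure {s.label or s.chain_id!r} has no polymer residues")
    return SequenceRecord(id=s.label or "structure", organism="", residues=seq)


# ---------------------------------------------------------------------------
# superposition and RMSD


def superpose(a: Structure, b: Structure) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares superposition of b onto a over common C-alpha atoms.

    Atoms are matched by author residue number; when fewer than 30 positions
    are shared that way (numbering offsets) the match falls back to a global
    sequence alignment of the extracted sequences.  Returns (rotation,
    translation, rmsd) with a proper rotation (det = +1) such that
    ``b @ R.T + t`` superposes onto a.
    """
    ca_a, ca_b = a.ca_coords(), b.ca_coords()
    common = sorted(set(ca_a) & set(ca_b))
    n_full = min(len(ca_a), len(ca_b))
    if len(common) >= min(30, n_full) and len(common) >= 3:
        xa = np.array([ca_a[n] for n in common])
        xb = np.array([ca_b[n] for n in common])
    else:
        xa, xb = _aligned_ca_pairs(a, b)
    if len(xa) < 3:
        raise StructureError(
            f"fewer than 3 common C-alpha atoms between {a.label!r} and {b.label!r}")
    sup = SVDSuperimposer()
    sup.set(xa, xb)
    sup.run()
    rot, tran = sup.get_rotran()
    return rot.T.copy(), np.asarray(tran, float), float(sup.get_rms())


def _aligned_ca_pairs(a: Structure, b: Structure):
    seq_a = "".join(r.one_letter for r in a.residues)
    seq_b = "".join(r.one_letter for r in b.residues)
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score, aligner.extend_gap_score = -11.0, -1.0
    aligner.mode = "global"
    aln = aligner.align(seq_a.replace("X", "A"), seq_b.replace("X", "A"))[0]
    xa, xb = [], []
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            caa = a.residues[i].atom("CA")
            cab = b.residues[j].atom("CA")
            if caa is not None and cab is not None:
                xa.append(caa.coord)
                xb.append(cab.coord)
    return np.array(xa).reshape(-1, 3), np.array(xb).reshape(-1, 3)


@dataclass
class RMSDMatrix:
    labels: list[str]
    values: np.ndarray  # (n, n) A

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if not np.allclose(v, v.T, atol=1e-9, equal_nan=True):
            raise ValueError("RMSD matrix must be symmetric")
        self.values = v


def rmsd_matrix(structures: list[Structure]) -> RMSDMatrix:
    """All-pairs best-fit C-alpha RMSD matrix."""
    n = len(structures)
    if n < 2:
        raise StructureError("need at least 2 structures for an RMSD matrix")
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                _, _, r = superpose(structures[i], structures[j])
            except StructureError as exc:
                raise StructureError(
                    f"superposition failed for pair "
                    f"({structures[i].label!r}, {structures[j].label!r}): {exc}") from exc
            m[i, j] = m[j, i] = r
    labels = [s.label or f"structure_{i}" for i, s in enumerate(structures)]
    return RMSDMatrix(labels, m)


# ---------------------------------------------------------------------------
# k-means representative selection


@dataclass
class ClusterAssignment:
    labels: list[str]
    cluster: np.ndarray            # (n,) cluster index per structure
    representatives: dict[int, str]  # cluster index -> representative label
    rationale: dict[int, str]


def _classical_mds(d: np.ndarray, n_components: int) -> np.ndarray:
    """Torgerson MDS: embed a distance matrix into Euclidean coordinates."""
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:n_components]
    w = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(w)


def cluster_representatives(m: RMSDMatrix, k: int = 6,
                            metadata: list[dict] | None = None,
                            seed: int = 0) -> ClusterAssignment:
    """k-means conformational clustering with per-cluster representatives.

    The RMSD matrix is embedded with classical MDS into min(8, n-1)
    dimensions, then clustered with seeded k-means (k capped at the number of
    structures).  Within a cluster, the representative is the structure with
    the best resolution, then the fewest missing residues, then the lowest
    mean B-factor, then the lexicographically smallest label.
    """
    d = np.asarray(m.values, float)
    if not np.all(np.isfinite(d)):
        raise ValueError("RMSD matrix contains non-finite entries")
    n = d.shape[0]
    k_eff = max(1, min(k, n))
    x = _classical_mds(d, min(8, n - 1)) if n > 1 else np.zeros((n, 1))
    km = KMeans(n_clusters=k_eff, n_init=10, random_state=seed)
    labels = km.fit_predict(x)

    meta = metadata if metadata is not None else [{} for _ in m.labels]
    reps: dict[int, str] = {}
    rationale: dict[int, str] = {}
    for c in range(k_eff):
        members = [i for i in range(n) if labels[i] == c]

        def sort_key(i: int):
            md = meta[i]
            res = md.get("resolution")
            return (res if res is not None else np.inf,
                    md.get("missing_residues", 0),
                    md.get("mean_bfactor", 0.0),
                    m.labels[i])

        best = min(members, key=sort_key)
        reps[c] = m.labels[best]
        md = meta[best]
        rationale[c] = (f"resolution={md.get('resolution')}, "
                        f"missing={md.get('missing_residues', 0)}, "
                        f"meanB={md.get('mean_bfactor', 0.0):.2f}")
    return ClusterAssignment(list(m.labels), labels.astype(int), reps, rationale)
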