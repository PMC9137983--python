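"""Synthetic inputs for every pipeline stage.

The generators build the four kinds of fixture the analysis needs without any
downloads: (a) shell "proteins" with an engineered spherical cavity whose
size, mouth opening and lining chemistry are controlled exactly, (b) gap-free
alignments evolved along a known tree under discrete site-rate classes,
(c) structure ensembles with a planted family partition, and (d) candidate-site
descriptor tables spanning the combined filter's thresholds.

Pseudo-residues are a C-alpha plus a single side-chain proxy atom typed by
residue class (carbon for hydrophobic, oxygen for polar, nitrogen/oxygen for
charged); this is enough for the burial, polarity and charge descriptors
downstream, which never look at real side-chain geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
from Bio.Align import substitution_matrices
from scipy.linalg import expm

from .structio import AA1_TO_3, Atom, Residue, Structure

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

HYDROPHOBIC = "AVLIFMW"
POLAR = "STNQYG"
CHARGED = "DEKR"

#: side-chain proxy element by residue class
_PROXY_ELEMENT = {**{a: "C" for a in HYDROPHOBIC},
                  **{a: "O" for a in POLAR},
                  "D": "O", "E": "O", "K": "N", "R": "N",
                  "C": "S", "H": "N", "P": "C"}


class SpecError(ValueError):
    """Invalid synthetic-data specification."""


# ---------------------------------------------------------------------------
# structures with engineered cavities


@dataclass(frozen=True)
class SyntheticStructureSpec:
    """An engineered-cavity shell protein.

    The cavity void of radius ``cavity_radius`` sits at the origin, lined by
    ``lining_count`` residues whose innermost atoms touch the void surface;
    the remaining residues sit on the outer shell at ``shell_radius``.  A
    mouth is carved by deleting every residue inside a spherical cap around
    +z covering ``mouth_fraction`` of the full solid angle.
    """

    shell_radius: float = 14.0
    cavity_radius: float = 4.5
    mouth_fraction: float = 0.0
    lining_composition: dict[str, float] = field(
        default_factory=lambda: {"hydrophobic": 0.5, "polar": 0.3, "charged": 0.2})
    residue_count: int = 120
    plant_ligand: bool = False
    seed: int = 0
    lining_count: int | None = None  # default: 60% of residue_count

    def __post_init__(self):
        if self.cavity_radius >= self.shell_radius:
            raise SpecError("cavity_radius must be smaller than shell_radius")
        if not 0.0 <= self.mouth_fraction <= 1.0:
            raise SpecError("mouth_fraction must lie in [0, 1]")
        total = sum(self.lining_composition.values())
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"lining_composition fractions sum to {total}, not 1")
        if self.residue_count < 1:
            raise SpecError("residue_count must be positive")

    @property
    def n_lining(self) -> int:
        if self.lining_count is not None:
            return min(self.lining_count, self.residue_count)
        return max(1, round(0.6 * self.residue_count))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


_CLASS_LETTERS = {
    "hydrophobic": "LIVFA",
    "polar": "STNQY",
    "charged": "DEKR",
}


def _composition_counts(composition: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n residues over classes."""
    keys = sorted(composition)
    raw = {k: composition[k] * n for k in keys}
    counts = {k: int(math.floor(raw[k])) for k in keys}
    short = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))[:short]:
        counts[k] += 1
    return counts


def generate_structure(spec: SyntheticStructureSpec) -> Structure:
    """Build the engineered-cavity structure described by ``spec``.

    Deterministic for a fixed seed; ``Structure.metadata`` records the cavity
    centroid, the planted lining residue numbers and the true void radius.
    """
    rng = np.random.default_rng(spec.seed)
    n_lin = spec.n_lining
    n_outer = spec.residue_count - n_lin

    counts = _composition_counts(spec.lining_composition, n_lin)
    letters: list[str] = []
    for klass in sorted(counts):
        pool = _CLASS_LETTERS[klass]
        letters.extend(pool[i % len(pool)] for i in range(counts[klass]))
    order = rng.permutation(n_lin)
    lining_letters = [letters[i] for i in order]

    cos_cap = 1.0 - 2.0 * spec.mouth_fraction  # mouth cap: z/|r| > cos_cap

    residues: list[Residue] = []
    num = 1
    lining_numbers: list[int] = []
    # lining layer: proxy atom exactly on the void surface, CA 1.5 A outside
    for u, letter in zip(_fibonacci_sphere(n_lin), lining_letters):
        if spec.mouth_fraction > 0 and u[2] > cos_cap:
            continue
        ca = u * (spec.cavity_radius + 1.5)
        proxy = u * spec.cavity_radius
        residues.append(Residue(num, AA1_TO_3[letter], [
            Atom("CA", "C", ca.copy()),
            Atom("CB", _PROXY_ELEMENT[letter], proxy.copy()),
        ]))
        lining_numbers.append(num)
        num += 1
    # outer shell layer: alanines on the shell surface, proxy pointing inward
    outer_letters = ["A", "G", "S", "L"]
    for k, u in enumerate(_fibonacci_sphere(max(n_outer, 1))[:n_outer]):
        if spec.mouth_fraction > 0 and u[2] > cos_cap:
            continue
        letter = outer_letters[k % len(outer_letters)]
        ca = u * spec.shell_radius
        proxy = u * (spec.shell_radius - 1.5)
        residues.append(Residue(num, AA1_TO_3[letter], [
            Atom("CA", "C", ca.copy()),
            Atom("CB", _PROXY_ELEMENT[letter], proxy.copy()),
        ]))
        num += 1

    ligand = [Atom("C1", "C", np.zeros(3))] if spec.plant_ligand else []
    meta = {
        "cavity_centroid": [0.0, 0.0, 0.0],
        "cavity_radius": spec.cavity_radius,
        "mouth_fraction": spec.mouth_fraction,
        "lining_residues": lining_numbers,
        "resolution": 2.0,
        "missing_residues": 0,
        "mean_bfactor": 0.0,
    }
    return Structure("A", residues, ligand_atoms=ligand, metadata=meta,
                     label=f"synthetic_cavity_seed{spec.seed}")


def generate_ensemble(base: SyntheticStructureSpec, families: int,
                      members_per_family: int, within_noise: float,
                      between_shift: float, seed: int = 0) -> tuple[list[Structure], np.ndarray]:
    """Structure ensemble with a planted conformational family partition.

    Family f's centroid conformation is the base structure with a coherent
    random deformation of magnitude >= ``between_shift`` (RMSD sense); each
    member adds i.i.d. coordinate noise of scale ``within_noise``.  Returns
    the structures and the true family label per structure.
    """
    if families < 1 or members_per_family < 1:
        raise SpecError("families and members_per_family must be >= 1")
    rng = np.random.default_rng(seed)
    ref = generate_structure(base)
    ref_coords = np.array([a.coord for r in ref.residues for a in r.atoms])
    n_atoms = len(ref_coords)

    structures: list[Structure] = []
    labels = []
    for f in range(families):
        if f == 0:
            centroid = ref_coords.copy()
        else:
            defo = rng.normal(size=ref_coords.shape)
            defo -= defo.mean(axis=0)          # remove net translation
            defo *= between_shift / np.sqrt((defo ** 2).sum(axis=1).mean())
            centroid = ref_coords + defo
        for m in range(members_per_family):
            noise = (rng.normal(scale=within_noise, size=ref_coords.shape)
                     if within_noise > 0 else np.zeros_like(ref_coords))
            coords = centroid + noise
            s = _with_coords(ref, coords)
            s.label = f"fam{f}_member{m}"
            s.metadata = dict(ref.metadata, family=f,
                              resolution=round(1.5 + 0.1 * ((f * members_per_family + m) % 10), 2))
            structures.append(s)
            labels.append(f)
    return structures, np.array(labels)


def _with_coords(ref: Structure, coords: np.ndarray) -> Structure:
    out_res = []
    k = 0
    for res in ref.residues:
        atoms = []
        for a in res.atoms:
            atoms.append(Atom(a.name, a.element, coords[k].copy(), a.bfactor))
            k += 1
        out_res.append(Residue(res.number, res.name, atoms, res.icode))
    return Structure(ref.chain_id, out_res, ss=dict(ref.ss))


# ---------------------------------------------------------------------------
# alignments evolved along a tree


@dataclass(frozen=True)
class SyntheticAlignmentSpec:
    """Alignment evolved along ``tree`` under discrete site-rate classes.

    ``rate_classes`` is a list of (relative rate, proportion) pairs with
    proportions summing to 1; ``column_classes`` may pin the class index per
    column, and ``root_sequence`` may pin the root state (otherwise sampled
    from ``residue_frequencies``).
    """

    tree: str | dendropy.Tree
    n_columns: int = 200
    rate_classes: tuple[tuple[float, float], ...] = ((0.1, 0.5), (5.0, 0.5))
    residue_frequencies: tuple[float, ...] | None = None
    seed: int = 0
    root_sequence: str | None = None
    column_classes: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.n_columns < 1:
            raise SpecError("n_columns must be positive")
        props = [p for _, p in self.rate_classes]
        if abs(sum(props) - 1.0) > 1e-9:
            raise SpecError("rate-class proportions must sum to 1")
        if any(r < 0 for r, _ in self.rate_classes):
            raise SpecError("rates must be non-negative")
        if self.residue_frequencies is not None:
            if len(self.residue_frequencies) != 20:
                raise SpecError("residue_frequencies must have 20 entries")
            if abs(sum(self.residue_frequencies) - 1.0) > 1e-9:
                raise SpecError("residue_frequencies must sum to 1")


def _as_tree(tree: str | dendropy.Tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=tree, schema="newick")


def blosum_rate_matrix(freqs: np.ndarray) -> np.ndarray:
    """CTMC rate matrix with BLOSUM62-derived exchangeabilities.

    BLOSUM scores are half-bit log-odds, so 2**(B_ij/2) is proportional to the
    target/background frequency ratio; used as symmetric exchangeabilities
    s_ij with Q_ij = s_ij * pi_j, normalised to one expected substitution per
    site per unit time.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    n = 20
    s = np.zeros((n, n))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if i != j:
                s[i, j] = 2.0 ** (blosum[a, b] / 2.0)
    q = s * freqs[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(freqs * np.diag(q)).sum()
    return q / scale


def evolve_alignment(spec: SyntheticAlignmentSpec):
    """Evolve a gap-free alignment down the tree; returns (alignment, truth).

    ``truth`` is a dict with the per-column rate-class index and relative
    rate.  Zero-rate columns are invariant by construction.
    """
    from .seqcons import MultipleAlignment, SequenceRecord

    tree = _as_tree(spec.tree)
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise SpecError("tree must have at least 3 leaves")

    rng = np.random.default_rng(spec.seed)
    freqs = (np.asarray(spec.residue_frequencies, float)
             if spec.residue_frequencies is not None
             else np.full(20, 0.05))
    q = blosum_rate_matrix(freqs)

    rates = np.array([r for r, _ in spec.rate_classes])
    props = np.array([p for _, p in spec.rate_classes])
    if spec.column_classes is not None:
        if len(spec.column_classes) != spec.n_columns:
            raise SpecError("column_classes length must equal n_columns")
        classes = np.asarray(spec.column_classes, int)
    else:
        classes = rng.choice(len(rates), size=spec.n_columns, p=props)

    if spec.root_sequence is not None:
        if len(spec.root_sequence) != spec.n_columns:
            raise SpecError("root_sequence length must equal n_columns")
        idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
        root_states = np.array([idx.get(c, 0) for c in spec.root_sequence.upper()])
    else:
        root_states = rng.choice(20, size=spec.n_columns, p=freqs)

    # transition matrices per (branch, rate class), computed on demand
    cache: dict[tuple[float, float], np.ndarray] = {}

    def pmatrix(t: float, rate: float) -> np.ndarray:
        key = (round(t, 12), rate)
        if key not in cache:
            cache[key] = expm(q * (t * rate)) if t * rate > 0 else np.eye(20)
        return cache[key]

    states: dict[int, np.ndarray] = {id(tree.seed_node): root_states}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_states = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        child = parent_states.copy()
        for ci, rate in enumerate(rates):
            cols = np.nonzero(classes == ci)[0]
            if len(cols) == 0 or t * rate == 0:
                continue
            p = pmatrix(t, rate)
            u = rng.random(len(cols))
            cum = np.cumsum(p[parent_states[cols]], axis=1)
            child[cols] = (u[:, None] > cum).sum(axis=1)
        states[id(node)] = child

    rows = []
    for k, leaf in enumerate(leaves):
        name = (leaf.taxon.label if leaf.taxon is not None else f"leaf{k}").replace(" ", "_")
        seq = "".join(AMINO_ACIDS[i] for i in states[id(leaf)])
        rows.append(SequenceRecord(id=name, organism=name, residues=seq))
    aln = MultipleAlignment(rows)
    truth = {"class_index": classes, "rate": rates[classes]}
    return aln, truth


# ---------------------------------------------------------------------------
# candidate-site tables


CANDIDATE_COLUMNS = ["site_id", "n_points", "enclosure", "sitescore", "dscore",
                     "hydrophilic", "charged_fraction", "conserved_fraction"]


def make_candidate_sites(n_rows: int = 32, seed: int = 0):
    """Random candidate-site descriptor table straddling every filter threshold.

    The first eight rows are pinned to cover both sides of each default
    threshold (0.8 scores, 0.5 conserved fraction, 0.263 charged fraction,
    15 site points); the remainder are drawn uniformly over ranges that span
    the thresholds.
    """
    import pandas as pd

    if n_rows < 1:
        raise SpecError("n_rows must be >= 1")
    rng = np.random.default_rng(seed)
    pinned = [
        # n, enclosure, ss, ds, philic, charged, conserved
        (40, 0.9, 1.05, 1.00, 0.8, 0.10, 0.80),   # passes everything
        (40, 0.9, 0.70, 1.00, 0.8, 0.10, 0.80),   # fails SiteScore
        (40, 0.9, 1.05, 0.60, 0.8, 0.10, 0.80),   # fails DScore
        (40, 0.9, 1.05, 1.00, 0.8, 0.10, 0.30),   # fails conservation
        (40, 0.9, 1.05, 1.00, 0.8, 0.40, 0.80),   # charged flag raised
        (10, 0.9, 1.05, 1.00, 0.8, 0.10, 0.80),   # below 15 site points
        (40, 0.9, 0.80, 0.80, 0.8, 0.263, 0.50),  # exactly at thresholds
        (40, 0.2, 0.40, 0.30, 2.0, 0.50, 0.10),   # fails everything
    ]
    records = []
    for i in range(n_rows):
        if i < len(pinned):
            n, e, ss, ds, p, ch, co = pinned[i]
        else:
            n = int(rng.integers(5, 150))
            e = float(rng.uniform(0.1, 1.0))
            ss = float(rng.uniform(0.3, 1.3))
            ds = float(rng.uniform(0.3, 1.3))
            p = float(rng.uniform(0.2, 2.0))
            ch = float(rng.uniform(0.0, 0.6))
            co = float(rng.uniform(0.0, 1.0))
        records.append((f"site{i:03d}", n, e, ss, ds, p, ch, co))
    return pd.DataFrame.from_records(records, columns=CANDIDATE_COLUMNS)


# ---------------------------------------------------------------------------
# convenience tree factory for fixtures


def balanced_tree(n_leaves: int = 8, branch_length: float = 0.3,
                  seed: int | None = None) -> dendropy.Tree:
    """Balanced binary newick tree with equal (or seed-jittered) branch lengths."""
    rng = np.random.default_rng(seed) if seed is not None else None

    def bl() -> float:
        if rng is None:
            return branch_length
        return float(branch_length * rng.uniform(0.5, 1.5))

    labels = [f"t{i}" for i in range(n_leaves)]

    def build(group: list[str]) -> str:
        if len(group) == 1:
            return f"{group[0]}:{bl():.6f}"
        mid = len(group) // 2
        return f"({build(group[:mid])},{build(group[mid:])}):{bl():.6f}"

    # strip the root edge length for a clean unrooted-style tree
    newick = build(labels).rsplit(":", 1)[0] + ";"
    return dendropy.Tree.get(data=newick, schema="newick")
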