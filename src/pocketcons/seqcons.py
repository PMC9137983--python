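"""Sequence curation, BLOSUM62 distances, NJ trees and conservation grading.

The conservation score is a deterministic surrogate for empirical-Bayesian
rate estimation: a tree-weighted sum-of-pairs BLOSUM62 statistic per column,
with Gerstein-Sonnhammer-Chothia sequence weights computed from the
neighbor-joining tree so that redundant sequences do not dominate.  Scores are
standardised across columns (mean 0, sd 1; higher = more conserved) and binned
into nine equal-width grades, grade 9 being the most conserved — the scale
used for ConSurf-style visualisation and for the "conserved = grade 8 or 9"
rule downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

VALID_LETTERS = set("ARNDCQEGHILKMFPSTWYVX-")


class SequenceError(ValueError):
    pass


@dataclass
class SequenceRecord:
    id: str
    organism: str = ""
    residues: str = ""

    def __post_init__(self):
        bad = set(self.residues.upper()) - VALID_LETTERS
        if bad:
            raise SequenceError(f"{self.id}: invalid residue letters {sorted(bad)}")
        self.residues = self.residues.upper()

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class MultipleAlignment:
    rows: list[SequenceRecord]

    def __post_init__(self):
        if not self.rows:
            raise SequenceError("alignment has no rows")
        lengths = {len(r.residues) for r in self.rows}
        if len(lengths) != 1:
            raise SequenceError(f"rows have unequal aligned lengths: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].residues)

    def column(self, c: int) -> str:
        return "".join(r.residues[c] for r in self.rows)

    def row(self, row_id: str) -> SequenceRecord:
        for r in self.rows:
            if r.id == row_id:
                return r
        raise KeyError(row_id)

    @classmethod
    def read(cls, path: str | Path, fmt: str | None = None) -> "MultipleAlignment":
        """Read a FASTA or Clustal (.aln) alignment file."""
        path = Path(path)
        if fmt is None:
            fmt = "clustal" if path.suffix in {".aln", ".clustal"} else "fasta"
        aln = AlignIO.read(str(path), fmt)
        return cls([SequenceRecord(id=r.id, residues=str(r.seq)) for r in aln])

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.rows:
                fh.write(f">{r.id}\n{r.residues}\n")


# ---------------------------------------------------------------------------
# curation


def filter_length_outliers(seqs: list[SequenceRecord],
                           fraction: float = 0.6) -> list[SequenceRecord]:
    """Drop sequences shorter than ``fraction`` x the mean ungapped length.

    The boundary is exclusive: a sequence exactly at the cutoff is retained.
    """
    if not seqs:
        raise SequenceError("no sequences supplied")
    mean_len = float(np.mean([len(s.ungapped) for s in seqs]))
    cutoff = fraction * mean_len
    return [s for s in seqs if len(s.ungapped) >= cutoff]


def select_representatives(seqs: list[SequenceRecord]) -> list[SequenceRecord]:
    """One record per distinct organism: longest sequence, ties by smaller id."""
    for s in seqs:
        if not s.organism:
            raise SequenceError(f"record {s.id!r} has no organism annotation")
    best: dict[str, SequenceRecord] = {}
    for s in seqs:
        cur = best.get(s.organism)
        if cur is None or (-len(s.ungapped), s.id) < (-len(cur.ungapped), cur.id):
            best[s.organism] = s
    chosen = set(id(v) for v in best.values())
    return [s for s in seqs if id(s) in chosen]


# ---------------------------------------------------------------------------
# BLOSUM62 distances


_BLOSUM = substitution_matrices.load("BLOSUM62")


def _blosum(a: str, b: str) -> float:
    try:
        return float(_BLOSUM[a, b])
    except (KeyError, IndexError):
        return 0.0  # X / nonstandard: neutral


_ROW_MIN = {a: min(float(_BLOSUM[a, b]) for b in "ARNDCQEGHILKMFPSTWYV")
            for a in "ARNDCQEGHILKMFPSTWYV"}
_ROW_MAX = {a: float(_BLOSUM[a, a]) for a in "ARNDCQEGHILKMFPSTWYV"}


def _pair_similarity(a: str, b: str) -> float:
    """BLOSUM62 pair score rescaled to [0, 1] between the pair's extremes.

    1 for an identical pair, 0 for the worst pairing either letter can
    achieve; unknown letters (X) are neutral at 0.5.
    """
    if a not in _ROW_MAX or b not in _ROW_MAX:
        return 0.5
    hi = max(_ROW_MAX[a], _ROW_MAX[b])
    lo = max(_ROW_MIN[a], _ROW_MIN[b])
    if hi - lo < 1e-12:
        return 1.0
    return float(np.clip((_blosum(a, b) - lo) / (hi - lo), 0.0, 1.0))


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be square and symmetric")
        if np.any(v < -1e-12):
            raise ValueError("distances must be non-negative")
        np.fill_diagonal(v, 0.0)
        self.values = v


def pairwise_distance(aln: MultipleAlignment) -> DistanceMatrix:
    """1 - rescaled mean BLOSUM62 similarity over ungapped column pairs.

    For each sequence pair the raw mean score is rescaled to [0, 1] between
    the pair's own attainable extremes: per column the maximum is the larger
    self-score of the two letters and the minimum is the larger of the two
    letters' worst-case BLOSUM62 scores (so identical sequences map to
    distance 0 and a worst-scoring pairing to distance 1).
    """
    rows = aln.rows
    if len(rows) < 2:
        raise SequenceError("need at least 2 rows for a distance matrix")
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i].residues, rows[j].residues
            scores, lo, hi = [], [], []
            for x, y in zip(a, b):
                if x == "-" or y == "-":
                    continue
                scores.append(_blosum(x, y))
                hi.append(max(_ROW_MAX.get(x, 0.0), _ROW_MAX.get(y, 0.0)))
                lo.append(max(_ROW_MIN.get(x, 0.0), _ROW_MIN.get(y, 0.0)))
            if not scores:
                raise SequenceError(
                    f"rows {rows[i].id!r} and {rows[j].id!r} share no ungapped columns")
            s, smin, smax = np.mean(scores), np.mean(lo), np.mean(hi)
            sim = 1.0 if smax - smin < 1e-12 else (s - smin) / (smax - smin)
            d[i, j] = d[j, i] = 1.0 - float(np.clip(sim, 0.0, 1.0))
    return DistanceMatrix([r.id for r in rows], d)


# ---------------------------------------------------------------------------
# neighbor joining


def build_nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Q-matrix ties are broken by the smallest (i, j) label pair; negative
    branch lengths are clamped to zero.  Returns an unrooted dendropy tree
    whose leaves carry the input labels.
    """
    labels = list(d.labels)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dist = {(a, b): float(d.values[i, j])
            for i, a in enumerate(labels) for j, b in enumerate(labels)}

    taxon_ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    nodes: dict[str, dendropy.Node] = {}
    for lab in labels:
        node = dendropy.Node(taxon=taxon_ns.get_taxon(lab))
        nodes[lab] = node

    active = list(labels)
    next_id = 0
    while len(active) > 2:
        r = len(active)
        totals = {a: sum(dist[(a, b)] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            q = (r - 2) * dist[(a, b)] - totals[a] - totals[b]
            if best is None or q < best[0] - 1e-12:
                best = (q, a, b)
        _, a, b = best
        la = 0.5 * dist[(a, b)] + (totals[a] - totals[b]) / (2.0 * (r - 2))
        lb = dist[(a, b)] - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new_lab = f"__internal_{next_id}"
        next_id += 1
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        nodes[new_lab] = parent
        for c in active:
            if c in (a, b):
                continue
            nd = 0.5 * (dist[(a, c)] + dist[(b, c)] - dist[(a, b)])
            dist[(new_lab, c)] = dist[(c, new_lab)] = max(nd, 0.0)
        dist[(new_lab, new_lab)] = 0.0
        active = [c for c in active if c not in (a, b)] + [new_lab]

    a, b = active
    root = dendropy.Node()
    root.add_child(nodes[a])
    root.add_child(nodes[b])
    half = 0.5 * dist[(a, b)]
    nodes[a].edge.length = max(half, 0.0)
    nodes[b].edge.length = max(half, 0.0)
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


# ---------------------------------------------------------------------------
# conservation scoring


@dataclass
class ConservationProfile:
    scores: np.ndarray              # standardized, higher = more conserved
    grades: np.ndarray | None = None  # 1..9
    flags: np.ndarray | None = None   # True where column is gap-dominated
    alignment: MultipleAlignment | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, float)
        if self.flags is None:
            self.flags = np.zeros(len(self.scores), bool)


def gsc_weights(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    """Gerstein-Sonnhammer-Chothia sequence weights from tree branch lengths.

    Each edge's length is shared among the leaves below it in proportion to
    their current weights, accumulating from the tips rootward; degenerate
    trees (all zero branch lengths) fall back to uniform weights.  Weights
    are normalised to sum to 1.
    """
    weights = {lab: 0.0 for lab in labels}
    tree = tree.clone(depth=1)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._leafset = [node.taxon.label] if node.taxon else []
        else:
            node._leafset = [l for c in node.child_nodes() for l in c._leafset]
        length = node.edge.length or 0.0
        if length <= 0 or not node._leafset:
            continue
        below = {l: weights[l] for l in node._leafset if l in weights}
        tot = sum(below.values())
        if tot <= 0:
            share = {l: 1.0 / len(below) for l in below}
        else:
            share = {l: w / tot for l, w in below.items()}
        for l, frac in share.items():
            weights[l] += length * frac
    w = np.array([weights[lab] for lab in labels], float)
    if w.sum() <= 0:
        w = np.ones(len(labels))
    return w / w.sum()


def score_conservation(aln: MultipleAlignment,
                       tree: dendropy.Tree | None = None) -> ConservationProfile:
    """Tree-weighted sum-of-pairs BLOSUM62 conservation per column.

    Raw column score = sum_{i<j} w_i w_j b(a_i, a_j) / sum w_i w_j over
    non-gap pairs, where b is the BLOSUM62 score rescaled to [0, 1] between
    the pair's own attainable extremes (as in ``pairwise_distance``) so that
    any invariant column scores exactly 1 regardless of its residue's
    self-score.  Scores are standardised to mean 0 / sd 1 across scorable
    columns.  Columns with more than 50% gaps (or all gaps) are flagged and
    later forced to the lowest grade.
    """
    if len(aln.rows) < 3:
        raise SequenceError("conservation scoring needs at least 3 rows")
    labels = [r.id for r in aln.rows]
    if tree is not None:
        leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon}
        if leaf_labels != set(labels):
            raise SequenceError("tree leaves do not match alignment row ids")
        w = gsc_weights(tree, labels)
    else:
        w = np.ones(len(labels)) / len(labels)

    n_rows, n_cols = len(aln.rows), aln.n_columns
    raw = np.zeros(n_cols)
    flags = np.zeros(n_cols, bool)
    seqs = [r.residues for r in aln.rows]
    for c in range(n_cols):
        col = [s[c] for s in seqs]
        present = [i for i, x in enumerate(col) if x != "-"]
        if len(col) - len(present) > 0.5 * n_rows or len(present) < 2:
            flags[c] = True
            raw[c] = np.nan
            continue
        num = den = 0.0
        for ii in range(len(present)):
            for jj in range(ii + 1, len(present)):
                i, j = present[ii], present[jj]
                ww = w[i] * w[j]
                num += ww * _pair_similarity(col[i], col[j])
                den += ww
        raw[c] = num / den if den > 0 else np.nan
    flags |= ~np.isfinite(raw)

    ok = ~flags
    scores = np.zeros(n_cols)
    vals = raw[ok]
    if len(vals) and np.nanstd(vals) > 1e-12:
        scores[ok] = (vals - vals.mean()) / vals.std()
    elif len(vals):
        scores[ok] = 0.0
    scores[flags] = np.nan
    return ConservationProfile(scores=scores, flags=flags, alignment=aln)


def assign_grades(profile: ConservationProfile) -> ConservationProfile:
    """Nine equal-width grade bins over the observed score range (9 = top).

    Degenerate case (all scores equal): grade 9 when every scorable column is
    single-residue, else grade 5.  Flagged (gap-dominated) columns get grade 1.
    """
    scores, flags = profile.scores, profile.flags
    grades = np.ones(len(scores), int)
    ok = ~flags & np.isfinite(scores)
    if ok.any():
        vals = scores[ok]
        lo, hi = vals.min(), vals.max()
        if hi - lo < 1e-12:
            if profile.alignment is not None and all(
                    len(set(profile.alignment.column(c).replace("-", ""))) == 1
                    for c in np.nonzero(ok)[0]):
                grades[ok] = 9
            else:
                grades[ok] = 5
        else:
            binned = 1 + np.floor(9.0 * (vals - lo) / (hi - lo)).astype(int)
            grades[ok] = np.clip(binned, 1, 9)
    profile.grades = grades
    return profile


# ---------------------------------------------------------------------------
# projection onto a structure


@dataclass
class ResidueMap:
    """(alignment column -> structure residue number) pairs plus grades."""

    pairs: list[tuple[int, int]]
    grades: dict[int, int]          # residue number -> grade
    scores: dict[int, float]
    ungraded: list[int]             # residue numbers with no aligned column
    identity: float


def map_to_structure(profile: ConservationProfile, aln_row: SequenceRecord,
                     structure) -> ResidueMap:
    """Project column grades onto structure residues via global alignment.

    The row's ungapped sequence is globally aligned (BLOSUM62, affine gaps)
    to the structure-derived sequence; matched positions inherit the column
    grade.  An identity below 30% raises (wrong chain or protein).
    """
    if profile.grades is None:
        raise ValueError("assign grades before mapping onto a structure")
    row_seq = aln_row.ungapped
    # ungapped position -> alignment column
    cols = [c for c, x in enumerate(aln_row.residues) if x != "-"]
    struct_seq = "".join(res.one_letter for res in structure.residues)
    if not row_seq or not struct_seq:
        raise SequenceError("empty sequence in mapping")

    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score, aligner.extend_gap_score = -11.0, -1.0
    aligner.mode = "global"
    aln = aligner.align(row_seq.replace("X", "A"), struct_seq.replace("X", "A"))[0]

    pairs, grades, scores = [], {}, {}
    matched = ident = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            matched += 1
            if row_seq[i] == struct_seq[j]:
                ident += 1
            col = cols[i]
            resnum = structure.residues[j].number
            pairs.append((col, resnum))
            grades[resnum] = int(profile.grades[col])
            scores[resnum] = float(profile.scores[col]) if np.isfinite(
                profile.scores[col]) else float("nan")
    identity = ident / matched if matched else 0.0
    if identity < 0.30:
        raise SequenceError(
            f"alignment identity {identity:.0%} below 30%: wrong chain or protein?")
    mapped = set(grades)
    ungraded = [r.number for r in structure.residues if r.number not in mapped]
    return ResidueMap(pairs, grades, scores, ungraded, identity)


def write_grades_table(rmap: ResidueMap, structure, path: str | Path) -> None:
    """ConSurf-style per-residue TSV: number, residue, score, grade, flag."""
    with open(path, "w") as fh:
        fh.write("residue_number\tresidue\tscore\tgrade\tflag\n")
        for res in structure.residues:
            g = rmap.grades.get(res.number)
            s = rmap.scores.get(res.number, float("nan"))
            flag = "" if g is not None else "ungraded"
            fh.write(f"{res.number}\t{res.one_letter}\t"
                     f"{s if s == s else ''}\t{g if g is not None else ''}\t{flag}\n")
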