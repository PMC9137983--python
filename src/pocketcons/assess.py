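"""Integration: site typing, conservation fractions, the combined filter,
summaries, group statistics and the end-to-end pipeline.

A detected pocket is *retained* as a candidate target when it clears the
two-stage combined filter: SiteScore >= 0.8 and DScore >= 0.8 (ligandable and
druggable), then a conserved-lining fraction >= 0.5, where "conserved" means
conservation grade 8 or 9.  A charged-lining fraction above 26.3% raises an
additional warning flag (Perola's druggability threshold) without removing
the site.  Thresholds are inclusive at the boundary and configurable.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from . import __version__ as _pkg_version
from .config import TEST_SPACING, Thresholds
from .seqcons import ResidueMap
from .sitefind import Site
from .structio import Structure

QUADRANTS = ("LL", "LR", "UL", "UR")


@dataclass
class SiteAssessment:
    site_rank: int
    site_type: str                 # orthosteric | cofactor | other
    merged_flag: bool
    sitescore: float
    dscore: float
    conserved_fraction: float
    charged_fraction: float
    quadrant: str
    ligandable: bool
    druggable: bool
    conserved: bool
    charged_exceeds: bool
    retained: bool


def label_site_type(site: Site, ligand_atoms: np.ndarray | None,
                    cofactor_atoms: np.ndarray | None, structure: Structure,
                    cutoff: float = 4.0) -> tuple[str, bool]:
    """Type a site by proximity of its lining residues to reference atoms.

    Orthosteric when any lining residue lies within ``cutoff`` of a ligand
    atom, cofactor when within ``cutoff`` of a cofactor atom; a site near
    both is orthosteric with a merged flag (colliding substrate and cofactor
    pockets forming one large site).  Without reference atoms every site is
    "other" (with a warning).
    """
    have_lig = ligand_atoms is not None and len(ligand_atoms) > 0
    have_cof = cofactor_atoms is not None and len(cofactor_atoms) > 0
    if not have_lig and not have_cof:
        warnings.warn("no reference ligand/cofactor atoms; labelling site 'other'")
        return "other", False
    lining = set(site.lining_residues)
    res_coords = np.array([a.coord for res in structure.residues
                           if res.number in lining for a in res.atoms]).reshape(-1, 3)
    if len(res_coords) == 0:
        return "other", False

    def near(ref: np.ndarray) -> bool:
        tree = cKDTree(np.atleast_2d(np.asarray(ref, float)))
        d, _ = tree.query(res_coords)
        return bool((d <= cutoff).any())

    is_orth = have_lig and near(ligand_atoms)
    is_cof = have_cof and near(cofactor_atoms)
    if is_orth:
        return "orthosteric", bool(is_cof)
    if is_cof:
        return "cofactor", False
    return "other", False


def conserved_fraction(site: Site, grades: dict[int, int],
                       conserved_grade: int = 8) -> float:
    """Fraction of graded lining residues at grade >= ``conserved_grade``."""
    graded = [grades[r] for r in site.lining_residues if r in grades]
    if not graded:
        raise ValueError("no graded lining residues for this site")
    return sum(1 for g in graded if g >= conserved_grade) / len(graded)


def classify_quadrant(sitescore: float, dscore: float,
                      threshold: float = 0.8) -> str:
    """UR both >= t; LR SiteScore only; UL DScore only; LL neither."""
    if not (np.isfinite(sitescore) and np.isfinite(dscore)):
        raise ValueError("scores must be finite")
    s_ok, d_ok = sitescore >= threshold, dscore >= threshold
    if s_ok and d_ok:
        return "UR"
    if s_ok:
        return "LR"
    if d_ok:
        return "UL"
    return "LL"


def assess_site(site: Site, site_type: str, merged: bool,
                cons_frac: float, thr: Thresholds) -> SiteAssessment:
    lig = site.sitescore >= thr.sitescore
    drg = site.dscore >= thr.dscore
    con = cons_frac >= thr.conserved
    return SiteAssessment(
        site_rank=site.rank, site_type=site_type, merged_flag=merged,
        sitescore=site.sitescore, dscore=site.dscore,
        conserved_fraction=cons_frac,
        charged_fraction=site.descriptors.charged_fraction,
        quadrant=classify_quadrant(site.sitescore, site.dscore, thr.sitescore),
        ligandable=lig, druggable=drg, conserved=con,
        charged_exceeds=site.descriptors.charged_fraction > thr.charged,
        retained=lig and drg and con)


def apply_combined_filter(assessments: list[SiteAssessment],
                          score_thr: float = 0.8,
                          cons_thr: float = 0.5) -> tuple[list[SiteAssessment], dict]:
    """Two-stage filter: scores first, then conservation; inclusive bounds."""
    stage1 = [a for a in assessments
              if a.sitescore >= score_thr and a.dscore >= score_thr]
    stage2 = [a for a in stage1 if a.conserved_fraction >= cons_thr]
    counts = {"input": len(assessments),
              "after_scores": len(stage1),
              "after_conservation": len(stage2)}
    return stage2, counts


def filter_candidate_table(table: pd.DataFrame, thr: Thresholds | None = None
                           ) -> tuple[pd.DataFrame, dict]:
    """Combined filter applied to a candidate-site descriptor table.

    Expects the synthdata candidate-table schema (sitescore, dscore,
    conserved_fraction, charged_fraction, n_points columns).  Rows below the
    minimum site-point count are excluded up front (they would never have
    been reported as sites).
    """
    thr = thr or Thresholds()
    sized = table[table["n_points"] >= thr.min_points]
    stage1 = sized[(sized["sitescore"] >= thr.sitescore)
                   & (sized["dscore"] >= thr.dscore)]
    stage2 = stage1[stage1["conserved_fraction"] >= thr.conserved]
    out = stage2.copy()
    out["charged_exceeds"] = out["charged_fraction"] > thr.charged
    counts = {"input": len(table), "sized": len(sized),
              "after_scores": len(stage1), "after_conservation": len(stage2)}
    return out, counts


# ---------------------------------------------------------------------------
# conservation summaries


@dataclass
class ConservationSummary:
    percent_conserved: float                  # residues at grade 8-9, %
    ss_distribution: dict[str, float]         # helix/sheet/loop fractions
    n_conserved: int
    n_total: int


def conservation_summary(grades: dict[int, int], structure: Structure,
                         conserved_grade: int = 8) -> ConservationSummary:
    """Share of grade-8/9 residues and their helix/sheet/loop split."""
    graded = {n: g for n, g in grades.items()}
    n_total = len(graded)
    conserved = [n for n, g in graded.items() if g >= conserved_grade]
    counts = {"helix": 0, "sheet": 0, "loop": 0}
    for n in conserved:
        counts[structure.ss_class(n)] += 1
    total_c = len(conserved)
    dist = ({k: v / total_c for k, v in counts.items()} if total_c
            else {k: 0.0 for k in counts})
    pct = 100.0 * total_c / n_total if n_total else 0.0
    return ConservationSummary(pct, dist, total_c, n_total)


# ---------------------------------------------------------------------------
# group statistics


@dataclass
class GroupComparison:
    n1: int
    n2: int
    ks_stat: tuple[float, float]   # per-group KS-vs-normal statistic
    ks_p: tuple[float, float]
    u_stat: float
    p_value: float
    method: str                    # "exact" | "normal"
    significant: bool


def _rank_sum_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic for group a from midranks of the pooled sample."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(a)].sum()
    return float(r1 - len(a) * (len(a) + 1) / 2.0)


def exact_mannwhitney_p(a, b) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumeration (ties via midranks).

    Enumerates every assignment of the pooled midranks to the two groups and
    counts assignments whose U deviates from n1*n2/2 by at least as much as
    the observed U.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    center = n1 * n2 / 2.0
    dev = abs(u_obs - center) - 1e-12
    total = comb(n1 + n2, n1)
    count = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - center) >= dev:
            count += 1
    return u_obs, count / total


def compare_groups(a, b, alpha: float = 0.05,
                   exact_max_n: int = 8) -> GroupComparison:
    """KS normality check plus a two-sided Mann-Whitney U comparison.

    The U test is exact (full enumeration, tie-aware) when both groups have
    at most ``exact_max_n`` values, otherwise the tie-corrected normal
    approximation is used.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")

    def ks(x):
        sd = x.std(ddof=1)
        if sd <= 0:
            return 0.0, 1.0
        r = stats.kstest(x, "norm", args=(x.mean(), sd))
        return float(r.statistic), float(r.pvalue)

    ks_a, ks_b = ks(a), ks(b)
    if len(a) <= exact_max_n and len(b) <= exact_max_n:
        u, p = exact_mannwhitney_p(a, b)
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        method = "normal"
    return GroupComparison(len(a), len(b), (ks_a[0], ks_b[0]),
                           (ks_a[1], ks_b[1]), u, p, method, p < alpha)


# ---------------------------------------------------------------------------
# inhibitor-profile comparison


def compare_inhibitor_profile(pocket_donacc: dict[str, float],
                              inhibitors: pd.DataFrame) -> pd.DataFrame:
    """Median inhibitor TPSA and don/acc ratio vs pocket don/acc per enzyme.

    ``inhibitors`` columns: enzyme, compound_id, tpsa, hbd, hba.  Enzymes
    with no inhibitor rows get missing-value markers; mismatch_sign is the
    sign of (pocket don/acc - median inhibitor don/acc): positive when the
    pocket favours more donors than the known inhibitors provide.
    """
    rows = []
    for enzyme, pocket in sorted(pocket_donacc.items()):
        sub = inhibitors[inhibitors["enzyme"] == enzyme] if len(inhibitors) else inhibitors
        if len(sub) == 0:
            rows.append({"enzyme": enzyme, "n_inhibitors": 0,
                         "median_tpsa": np.nan, "median_donacc": np.nan,
                         "pocket_donacc": pocket, "mismatch": np.nan,
                         "mismatch_sign": 0, "missing": True})
            continue
        ratios = sub["hbd"] / sub["hba"].replace(0, np.nan)
        med_ratio = float(ratios.median())
        mismatch = pocket - med_ratio
        rows.append({"enzyme": enzyme, "n_inhibitors": int(len(sub)),
                     "median_tpsa": float(sub["tpsa"].median()),
                     "median_donacc": med_ratio,
                     "pocket_donacc": pocket, "mismatch": mismatch,
                     "mismatch_sign": int(np.sign(mismatch)) if np.isfinite(mismatch) else 0,
                     "missing": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class AssessmentReport:
    sites: pd.DataFrame
    assessments: pd.DataFrame
    retained: list[int]             # ranks of retained sites
    stage_counts: dict
    summary: dict
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.sites.to_csv(outdir / "sites.csv", index=False)
        self.assessments.to_csv(outdir / "assessment.csv", index=False)
        (outdir / "summary.json").write_text(
            json.dumps(self.summary, indent=2, sort_keys=True) + "\n")
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")


def run_pipeline(cfg: dict) -> AssessmentReport:
    """Execute the full synthetic or file-driven analysis.

    ``cfg`` keys: ``seed``; ``structure`` (either ``{"synthetic": {...spec
    fields...}}`` or ``{"pdb": path, "chain": id}``); ``alignment`` (either
    ``{"synthetic": {"n_leaves": .., "n_columns": optional}}`` evolved from
    the structure sequence with slow cavity-lining columns, or ``{"fasta":
    path, "tree": optional newick path}``); optional ``thresholds`` mapping;
    optional ``inhibitors`` CSV path.  Stage failures abort with the stage
    name.
    """
    from . import probemap, seqcons, sitefind, structio, synthdata

    seed = int(cfg.get("seed", 0))
    thr = Thresholds(**cfg.get("thresholds", {}))

    # --- structio: obtain the structure ---------------------------------
    scfg = cfg.get("structure")
    if not scfg:
        raise PipelineError("structio", "config has no 'structure' input")
    try:
        if "synthetic" in scfg:
            spec_kwargs = dict(scfg["synthetic"])
            spec_kwargs.setdefault("seed", seed)
            spec = synthdata.SyntheticStructureSpec(**spec_kwargs)
            structure = synthdata.generate_structure(spec)
        else:
            structure = structio.load_structure(scfg["pdb"], scfg.get("chain", "A"))
    except (KeyError, ValueError) as exc:
        raise PipelineError("structio", str(exc)) from exc

    # --- seqcons: alignment, tree, conservation -------------------------
    acfg = cfg.get("alignment")
    if not acfg:
        raise PipelineError("seqcons", "config has no 'alignment' input")
    try:
        struct_seq = structio.extract_sequence(structure)
        if "synthetic" in acfg:
            ac = dict(acfg["synthetic"])
            n_leaves = int(ac.get("n_leaves", 8))
            n_cols = len(struct_seq.residues)
            lining = set(structure.metadata.get("lining_residues", []))
            resnums = [r.number for r in structure.residues]
            classes = tuple(0 if rn in lining else 1 for rn in resnums)
            tree = synthdata.balanced_tree(n_leaves, ac.get("branch_length", 0.4),
                                           seed=seed)
            aspec = synthdata.SyntheticAlignmentSpec(
                tree=tree, n_columns=n_cols,
                rate_classes=((ac.get("slow_rate", 0.05), 0.5),
                              (ac.get("fast_rate", 3.0), 0.5)),
                seed=seed, root_sequence=struct_seq.residues,
                column_classes=classes)
            aln, _truth = synthdata.evolve_alignment(aspec)
        else:
            aln = seqcons.MultipleAlignment.read(acfg["fasta"])
        dm = seqcons.pairwise_distance(aln)
        njtree = seqcons.build_nj_tree(dm)
        profile = seqcons.assign_grades(seqcons.score_conservation(aln, njtree))
        # choose the alignment row closest to the structure sequence
        best_row = max(aln.rows, key=lambda r: _identity(r.ungapped,
                                                         struct_seq.residues))
        rmap = seqcons.map_to_structure(profile, best_row, structure)
    except (ValueError, KeyError) as exc:
        raise PipelineError("seqcons", str(exc)) from exc

    # --- sitefind: pockets ----------------------------------------------
    try:
        spacing = float(cfg.get("spacing", TEST_SPACING))
        sites = sitefind.find_sites(
            structure, spacing=spacing, margin=float(cfg.get("margin", 4.0)),
            burial_min=thr.burial_min, min_points=thr.min_points,
            max_sites=thr.max_sites, lining_cutoff=thr.lining_cutoff,
            n_transform=thr.n_transform)
    except ValueError as exc:
        raise PipelineError("sitefind", str(exc)) from exc

    # --- probemap: hotspots ---------------------------------------------
    try:
        poses = probemap.map_probes(structure, seed=seed)
        clusters = probemap.cluster_poses(poses)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            predicted = probemap.predict_binding_sites(clusters, structure)
    except ValueError as exc:
        raise PipelineError("probemap", str(exc)) from exc

    # --- assess ----------------------------------------------------------
    lig_atoms = (np.array([a.coord for a in structure.ligand_atoms])
                 if structure.ligand_atoms else None)
    cof_atoms = (np.array([a.coord for a in structure.cofactor_atoms])
                 if structure.cofactor_atoms else None)
    assessments = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for site in sites:
            stype, merged = label_site_type(site, lig_atoms, cof_atoms,
                                            structure, thr.lining_cutoff)
            try:
                cf = conserved_fraction(site, rmap.grades, thr.conserved_grade)
            except ValueError:
                cf = 0.0
            assessments.append(assess_site(site, stype, merged, cf, thr))
    retained, counts = apply_combined_filter(assessments, thr.sitescore,
                                             thr.conserved)
    cons = conservation_summary(rmap.grades, structure, thr.conserved_grade)

    site_frame = sitefind.sites_to_frame(sites)
    adf = pd.DataFrame([asdict(a) for a in assessments])
    summary = {
        "n_sites": len(sites),
        "n_probe_clusters": len(clusters),
        "n_predicted_sites": len(predicted),
        "stage_counts": counts,
        "retained_ranks": [a.site_rank for a in retained],
        "percent_conserved_residues": round(cons.percent_conserved, 3),
        "ss_distribution": {k: round(v, 4) for k, v in cons.ss_distribution.items()},
        "mapping_identity": round(rmap.identity, 4),
    }
    manifest = {
        "package": "pocketcons",
        "version": _pkg_version,
        "seed": seed,
        "spacing": spacing,
        "thresholds": thr.as_dict(),
        "structure_label": structure.label,
        "n_residues": len(structure),
    }
    return AssessmentReport(site_frame, adf, [a.site_rank for a in retained],
                            counts, summary, manifest)


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(1 for x, y in zip(a, b) if x == y) / n
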