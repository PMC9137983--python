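"""Site typing, quadrants, the combined filter, statistics and the pipeline."""

import itertools
import json

import numpy as np
import pandas as pd
import pytest

from pocketcons import assess, synthdata
from pocketcons.assess import (classify_quadrant, compare_groups,
                               compare_inhibitor_profile, conservation_summary,
                               conserved_fraction, exact_mannwhitney_p,
                               filter_candidate_table, label_site_type,
                               run_pipeline, PipelineError)
from pocketcons.config import Thresholds
from pocketcons.sitefind import Site, SiteDescriptors
from pocketcons.structio import Atom, Residue, Structure


def _site(lining, charged_fraction=0.1, sitescore=1.0, dscore=1.0, rank=1):
    desc = SiteDescriptors(n=40, volume=10.0, exposure=0.4, enclosure=0.8,
                           contact=1.0, phobic=1.0, philic=0.9, balance=1.5,
                           donacc=0.8, charged_fraction=charged_fraction)
    return Site(points=np.zeros((3, 3)), descriptors=desc,
                lining_residues=list(lining), sitescore=sitescore,
                dscore=dscore, rank=rank)


def _toy_structure():
    residues = [Residue(i, "ALA", [Atom("CA", "C", np.array([3.0 * i, 0, 0]))])
                for i in range(1, 21)]
    ss = {**{i: "H" for i in range(1, 11)}, **{i: "E" for i in range(11, 16)}}
    return Structure("A", residues, ss=ss)


class TestLabelSiteType:
    def test_ligand_contact_is_orthosteric(self):
        s = _toy_structure()
        site = _site([1, 2, 3])
        lig = np.array([[3.0, 1.0, 0.0]])
        stype, merged = label_site_type(site, lig, None, s)
        assert stype == "orthosteric" and not merged

    def test_remote_ligand_is_other(self):
        s = _toy_structure()
        site = _site([1, 2])
        lig = np.array([[100.0, 0.0, 0.0]])
        stype, _ = label_site_type(site, lig, None, s)
        assert stype == "other"

    def test_cofactor_contact(self):
        s = _toy_structure()
        site = _site([10, 11])
        cof = np.array([[30.0, 2.0, 0.0]])
        stype, merged = label_site_type(site, None, cof, s)
        assert stype == "cofactor" and not merged

    def test_collision_merges_into_orthosteric(self):
        s = _toy_structure()
        site = _site([1, 2, 3])
        lig = np.array([[3.0, 1.0, 0.0]])
        cof = np.array([[6.0, 1.0, 0.0]])
        stype, merged = label_site_type(site, lig, cof, s)
        assert stype == "orthosteric" and merged

    def test_no_reference_atoms_warns(self):
        with pytest.warns(UserWarning):
            stype, _ = label_site_type(_site([1]), None, None, _toy_structure())
        assert stype == "other"


class TestConservedFraction:
    @pytest.mark.parametrize("n_conserved, expected", [(6, 0.6), (10, 1.0), (5, 0.5)])
    def test_fraction_of_graded_lining(self, n_conserved, expected):
        lining = list(range(1, 11))
        grades = {i: (9 if i <= n_conserved else 3) for i in lining}
        assert conserved_fraction(_site(lining), grades) == pytest.approx(expected)

    def test_boundary_half_passes_retention(self):
        grades = {i: (8 if i <= 5 else 1) for i in range(1, 11)}
        cf = conserved_fraction(_site(range(1, 11)), grades)
        assert cf >= Thresholds().conserved

    def test_ungraded_lining_rejected(self):
        with pytest.raises(ValueError):
            conserved_fraction(_site([1, 2]), {})


class TestQuadrants:
    @pytest.mark.parametrize("ss, ds, expected", [
        (1.13, 1.0, "UR"),
        (0.79, 0.79, "LL"),
        (0.9, 0.7, "LR"),
        (0.7, 0.9, "UL"),
        (0.8, 0.8, "UR"),     # boundaries inclusive toward UR
    ])
    def test_partition(self, ss, ds, expected):
        assert classify_quadrant(ss, ds) == expected

    def test_every_pair_gets_exactly_one_quadrant(self):
        rng = np.random.default_rng(0)
        for ss, ds in rng.uniform(0, 1.6, size=(200, 2)):
            assert classify_quadrant(ss, ds) in {"LL", "LR", "UL", "UR"}

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_quadrant(np.nan, 1.0)


def _oracle_filter(table: pd.DataFrame, thr: Thresholds) -> set:
    """Independent brute-force re-evaluation of the combined predicate."""
    keep = set()
    for _, row in table.iterrows():
        if (row.n_points >= thr.min_points and row.sitescore >= thr.sitescore
                and row.dscore >= thr.dscore
                and row.conserved_fraction >= thr.conserved):
            keep.add(row.site_id)
    return keep


class TestCombinedFilter:
    def test_matches_bruteforce_oracle(self):
        thr = Thresholds()
        table = synthdata.make_candidate_sites(200, seed=3)
        kept, counts = filter_candidate_table(table, thr)
        assert set(kept.site_id) == _oracle_filter(table, thr)
        assert counts["after_conservation"] == len(kept)

    def test_all_below_scores_empty(self):
        table = synthdata.make_candidate_sites(30, seed=1)
        table["sitescore"] = 0.5
        kept, counts = filter_candidate_table(table)
        assert len(kept) == 0
        assert counts["after_scores"] == 0 and counts["after_conservation"] == 0

    def test_exact_boundary_retained(self):
        table = pd.DataFrame([{"site_id": "b", "n_points": 15, "enclosure": 0.8,
                               "sitescore": 0.8, "dscore": 0.8,
                               "hydrophilic": 0.8, "charged_fraction": 0.263,
                               "conserved_fraction": 0.5}])
        kept, _ = filter_candidate_table(table)
        assert list(kept.site_id) == ["b"]
        assert not kept.charged_exceeds.iloc[0]  # flag strictly greater


class TestConservationSummary:
    def test_ss_split_counts(self):
        s = _toy_structure()  # helix 1-10, sheet 11-15, loop 16-20
        grades = {i: 1 for i in range(1, 21)}
        for i in (2, 3, 12, 20):
            grades[i] = 9
        cs = conservation_summary(grades, s)
        assert cs.percent_conserved == pytest.approx(20.0)
        assert cs.ss_distribution == pytest.approx(
            {"helix": 0.5, "sheet": 0.25, "loop": 0.25})
        assert sum(cs.ss_distribution.values()) == pytest.approx(1.0)

    def test_no_conserved_residues(self):
        cs = conservation_summary({i: 3 for i in range(1, 11)}, _toy_structure())
        assert cs.percent_conserved == 0.0
        assert all(v == 0.0 for v in cs.ss_distribution.values())

    def test_all_conserved(self):
        cs = conservation_summary({i: 9 for i in range(1, 21)}, _toy_structure())
        assert cs.percent_conserved == pytest.approx(100.0)


class TestGroupComparison:
    def test_tied_identical_groups(self):
        u, p = exact_mannwhitney_p([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)
        assert p == pytest.approx(1.0)

    def test_extreme_separation(self):
        u, p = exact_mannwhitney_p([1, 2, 3], [10, 11, 12])
        assert u == pytest.approx(0.0)
        assert p == pytest.approx(0.1)

    def test_constant_groups_not_significant(self):
        gc = compare_groups([5, 5, 5], [5, 5, 5])
        assert not gc.significant
        assert gc.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_equals_enumeration(self, seed):
        """n1,n2 <= 5: p must equal the exhaustive-enumeration value."""
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 6), rng.integers(3, 6)
        a = rng.integers(0, 6, n1).astype(float)   # ties likely
        b = rng.integers(0, 6, n2).astype(float)
        u_obs, p = exact_mannwhitney_p(a, b)
        # independent enumeration via scipy rankdata on explicit assignments
        from scipy.stats import rankdata
        pooled = np.concatenate([a, b])
        ranks = rankdata(pooled)
        center = n1 * n2 / 2.0
        count = total = 0
        for idx in itertools.combinations(range(n1 + n2), int(n1)):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - center) >= abs(u_obs - center) - 1e-12:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_large_groups_use_normal_approx(self):
        rng = np.random.default_rng(1)
        gc = compare_groups(rng.normal(0, 1, 30), rng.normal(1.5, 1, 30))
        assert gc.method == "normal"
        assert gc.significant

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2], [1, 2, 3])


class TestInhibitorProfile:
    def test_median_ratio(self):
        inhib = pd.DataFrame([
            {"enzyme": "E1", "compound_id": "c1", "tpsa": 120.0, "hbd": 1, "hba": 4},
            {"enzyme": "E1", "compound_id": "c2", "tpsa": 100.0, "hbd": 2, "hba": 4},
        ])
        out = compare_inhibitor_profile({"E1": 0.76}, inhib)
        row = out.iloc[0]
        assert row.median_donacc == pytest.approx(0.375)
        assert row.median_tpsa == pytest.approx(110.0)
        assert row.mismatch_sign == 1   # pocket favours more donors

    def test_empty_table_flags_missing(self):
        out = compare_inhibitor_profile(
            {"E1": 0.8, "E2": 0.5},
            pd.DataFrame(columns=["enzyme", "compound_id", "tpsa", "hbd", "hba"]))
        assert out.missing.all()
        assert len(out) == 2


PIPE_CFG = {
    "seed": 7,
    "structure": {"synthetic": {
        "shell_radius": 12.0, "cavity_radius": 4.0, "mouth_fraction": 0.1,
        "residue_count": 90, "plant_ligand": True,
        "lining_composition": {"hydrophobic": 0.5, "polar": 0.3, "charged": 0.2}}},
    "alignment": {"synthetic": {"n_leaves": 8}},
}


class TestPipeline:
    @pytest.fixture(scope="class")
    def report(self):
        return run_pipeline(PIPE_CFG)

    def test_retained_set_matches_filter_oracle(self, report):
        adf = report.assessments
        expected = set(adf[(adf.sitescore >= 0.8) & (adf.dscore >= 0.8)
                           & (adf.conserved_fraction >= 0.5)].site_rank)
        assert set(report.retained) == expected
        assert report.retained  # the planted conserved cavity survives

    def test_planted_cavity_is_rank1_orthosteric(self, report):
        top = report.assessments.iloc[0]
        assert top.site_type == "orthosteric"
        assert top.retained

    def test_rerun_is_byte_identical(self, tmp_path, report):
        report.write(tmp_path / "a")
        run_pipeline(PIPE_CFG).write(tmp_path / "b")
        for name in ("sites.csv", "assessment.csv", "summary.json",
                     "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes(), name

    def test_missing_structure_input_aborts_with_stage(self):
        with pytest.raises(PipelineError, match="structio"):
            run_pipeline({"seed": 1, "alignment": {"synthetic": {}}})

    def test_manifest_records_thresholds_and_seed(self, report):
        assert report.manifest["seed"] == 7
        assert report.manifest["thresholds"]["sitescore"] == 0.8
        assert report.manifest["thresholds"]["charged"] == 0.263


class TestEndToEndRecovery:
    def test_only_the_conserved_cavity_is_retained_over_20_seeds(self):
        """A conserved, enclosed cavity is retained in every replicate and
        every retained site overlaps it (no spurious surface survivors)."""
        for seed in range(20):
            cfg = dict(PIPE_CFG, seed=seed)
            report = run_pipeline(cfg)
            adf = report.assessments
            assert report.retained, seed
            retained = adf[adf.site_rank.isin(report.retained)]
            assert (retained.site_type == "orthosteric").all(), seed
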