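"""ASE scoring, unit assignment, ANOVA, shuffle nulls and per-unit calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from syntad.ase import (
    ase_score,
    assign_units,
    fit_anova,
    permute_cohort,
    unit_significance,
)
from syntad.core_io import GenomicInterval, Track


def records(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "tissue", "paternal", "maternal"])


class TestAseScore:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(0, 0, 0.0), (9, 0, 1.0), (0, 99, -2.0), (5, 5, 0.0), (99, 0, 2.0)],
    )
    def test_pseudocounted_log_ratio(self, p, m, expected):
        assert ase_score(p, m) == pytest.approx(expected)

    def test_sign_encodes_parental_direction(self):
        assert ase_score(30, 3) > 0 > ase_score(3, 30)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ase_score(-1, 5)

    def test_zero_iff_balanced(self):
        p = np.arange(0, 50)
        y = ase_score(p, p)
        assert np.all(y == 0)


UNITS = Track(
    "tads",
    [GenomicInterval("chr1", 0, 1_000), GenomicInterval("chr1", 1_000, 2_000),
     GenomicInterval("chr1", 3_000, 4_000)],
)
GAPS = Track(
    "gaps",
    [GenomicInterval("chr1", 100, 500), GenomicInterval("chr1", 1_200, 1_900)],
)


class TestAssignUnits:
    def test_tad_model_assigns_containing_tad(self):
        recs = records([("chr1", 50 + i, "t", 1, 1) for i in range(5)]
                       + [("chr1", 3_100 + i, "t", 1, 1) for i in range(5)])
        asg = assign_units(recs, tads=UNITS, model="tad")
        assert asg.n_units == 2
        assert (asg.unit_of >= 0).all()

    def test_intersection_cells_in_nested_model(self):
        recs = records([("chr1", 150 + i, "t", 1, 1) for i in range(5)])
        asg = assign_units(recs, tads=UNITS, gaps=GAPS, model="tad+ctcf")
        assert asg.n_units == 1
        assert asg.unit_names[0].count("|") == 1  # (tad, gap) pair key

    def test_unit_with_fewer_than_five_snps_dropped(self):
        recs = records([("chr1", 10 + i, "t", 1, 1) for i in range(4)])
        asg = assign_units(recs, tads=UNITS, model="tad")
        assert asg.n_units == 0
        assert not asg.retained.any()

    def test_exactly_five_snps_kept(self):
        recs = records([("chr1", 10 + i, "t", 1, 1) for i in range(5)])
        asg = assign_units(recs, tads=UNITS, model="tad")
        assert asg.n_units == 1

    def test_records_outside_all_regions_unassigned(self):
        recs = records([("chr1", 2_500 + i, "t", 1, 1) for i in range(6)])
        asg = assign_units(recs, tads=UNITS, model="tad")
        assert not asg.retained.any()

    def test_nested_model_retains_no_more_snps_than_tad_model(self):
        rng = np.random.default_rng(0)
        recs = records([("chr1", int(p), "t", 1, 1) for p in rng.integers(0, 4_000, 400)])
        tad_n = assign_units(recs, tads=UNITS, model="tad").retained.sum()
        nested_n = assign_units(recs, tads=UNITS, gaps=GAPS, model="tad+ctcf").retained.sum()
        assert nested_n <= tad_n

    def test_model_requires_matching_tracks(self):
        recs = records([("chr1", 10, "t", 1, 1)])
        with pytest.raises(ValueError):
            assign_units(recs, tads=None, model="tad")
        with pytest.raises(ValueError):
            assign_units(recs, tads=UNITS, gaps=None, model="tad+ctcf")


def toy_assignment(groups):
    """Build records/scores/assignment from {unit: [scores]} on disjoint TADs."""
    tads, rows, scores = [], [], []
    for u, vals in enumerate(groups):
        tads.append(GenomicInterval("chr1", u * 1_000, (u + 1) * 1_000))
        for i, v in enumerate(vals):
            rows.append(("chr1", u * 1_000 + i, "t", 1, 1))
            scores.append(v)
    asg = assign_units(records(rows), tads=Track("t", tads), model="tad")
    return np.array(scores), asg


class TestFitAnova:
    def test_all_scores_equal_gives_zero_r2(self):
        scores, asg = toy_assignment([[1.0] * 5, [1.0] * 5])
        assert fit_anova(scores, asg).r_squared == 0.0

    def test_pure_between_unit_variance_gives_r2_one(self):
        scores, asg = toy_assignment([[1.0] * 5, [2.0] * 5])
        res = fit_anova(scores, asg)
        assert res.r_squared == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_hand_computed_fixture(self):
        # 3 units x 5 scores; SSB/SST computed by hand from the group means
        groups = [[0.1, 0.2, 0.3, 0.2, 0.2], [0.8, 0.9, 1.0, 0.9, 0.9], [-0.5, -0.4, -0.6, -0.5, -0.5]]
        scores, asg = toy_assignment(groups)
        means = [np.mean(g) for g in groups]
        grand = np.mean(scores)
        ssb = 5 * sum((m - grand) ** 2 for m in means)
        sst = sum((v - grand) ** 2 for v in scores)
        res = fit_anova(scores, asg)
        assert res.r_squared == pytest.approx(ssb / sst)

    def test_agrees_with_scipy_f_oneway(self):
        rng = np.random.default_rng(8)
        groups = [list(rng.normal(mu, 1.0, size=12)) for mu in (0.0, 0.4, -0.3, 1.0)]
        scores, asg = toy_assignment(groups)
        res = fit_anova(scores, asg)
        ref = stats.f_oneway(*groups)
        assert res.f_statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_r2_invariant_to_score_shift_and_unit_relabeling(self):
        rng = np.random.default_rng(9)
        groups = [list(rng.normal(mu, 1.0, size=8)) for mu in (0.0, 0.5, -0.5)]
        scores, asg = toy_assignment(groups)
        r2 = fit_anova(scores, asg).r_squared
        assert fit_anova(scores + 3.7, asg).r_squared == pytest.approx(r2)
        scores_rev, asg_rev = toy_assignment(list(reversed(groups)))
        assert fit_anova(scores_rev, asg_rev).r_squared == pytest.approx(r2)

    def test_requires_two_units(self):
        scores, asg = toy_assignment([[1.0, 2.0, 1.0, 2.0, 1.5]])
        with pytest.raises(ValueError):
            fit_anova(scores, asg)


class TestPermutationNull:
    def test_zero_permutations_rejected(self):
        scores, asg = toy_assignment([[1.0] * 5, [2.0] * 5])
        with pytest.raises(ValueError):
            permute_cohort(scores, asg, n_perm=0)

    def test_strong_structure_beats_every_shuffle(self):
        rng = np.random.default_rng(10)
        groups = [list(rng.normal(mu, 0.1, size=10)) for mu in (-1.0, 0.0, 1.0, 2.0)]
        scores, asg = toy_assignment(groups)
        perm = permute_cohort(scores, asg, n_perm=300, seed=1)
        assert perm.significant

    def test_null_scores_rarely_significant(self):
        # cohort-level type-I control: R^2 > all shuffles is a 1/(n_perm+1) event
        rng = np.random.default_rng(13)
        hits = 0
        for rep in range(30):
            groups = [list(rng.normal(0.0, 1.0, size=8)) for _ in range(6)]
            scores, asg = toy_assignment(groups)
            if permute_cohort(scores, asg, n_perm=200, seed=rep).significant:
                hits += 1
        assert hits <= 2

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(14)
        groups = [list(rng.normal(0.0, 1.0, size=8)) for _ in range(4)]
        scores, asg = toy_assignment(groups)
        a = permute_cohort(scores, asg, n_perm=100, seed=7)
        b = permute_cohort(scores, asg, n_perm=100, seed=7)
        assert np.array_equal(a.r2_null, b.r2_null)


class TestUnitSignificance:
    def test_all_zero_unit_not_called(self):
        scores, asg = toy_assignment([[0.0] * 6, [1.0, 1.1, 0.9, 1.0, 1.05, 0.95]])
        perm = permute_cohort(scores, asg, n_perm=400, seed=2)
        calls = unit_significance(scores, asg, perm).set_index("unit")
        zero_unit = asg.unit_names[0]
        assert not calls.loc[zero_unit, "significant"]

    def test_strongly_biased_unit_called(self):
        rng = np.random.default_rng(15)
        # delta = +3 on the log-odds scale at depth 50 (logistic(3) ~ 0.95)
        biased = [ase_score(int(p), 50 - int(p)) for p in rng.binomial(50, 0.95, 20)]
        flat = list(rng.normal(0.0, 0.05, 20))
        scores, asg = toy_assignment([biased, flat])
        perm = permute_cohort(scores, asg, n_perm=500, seed=3)
        calls = unit_significance(scores, asg, perm).set_index("unit")
        assert calls.loc[asg.unit_names[0], "significant"]
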