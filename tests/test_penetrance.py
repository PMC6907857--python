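import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from penliab.datatypes import AnalysisConfig, ScoringTable
from penliab.errors import EstimationError, ValidationError
from penliab.penetrance import (
    ContingencyTable2x2,
    PValueSet,
    adjust_pvalues,
    compare_penetrance_groups,
    estimate_penetrance,
    fisher_exact_2x2,
)


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: exhaustive hypergeometric enumeration.

    Sums the probability of every table sharing the observed margins whose
    probability is at most the observed table's (1e-7 relative tolerance).
    """
    n, r, k = a + b + c + d, a + b, a + c
    support = np.arange(max(0, r + k - n), min(r, k) + 1)
    pmf = stats.hypergeom.pmf(support, n, r, k)
    p_obs = stats.hypergeom.pmf(a, n, r, k)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def mutants_of(strain):
    return {"strain": strain, "genotype": {"mef2ca": "mut"}}


def table_from_counts(counts):
    """Build a scoring table with given (strain -> (affected, scored)) counts."""
    rows = []
    i = 0
    for strain, (k, n) in counts.items():
        for j in range(n):
            rows.append(
                {
                    "animal_id": f"x{i}",
                    "strain": strain,
                    "generation": 1,
                    "family_id": "f",
                    "mef2ca": "mut",
                    "ectopic-bone": j < k,
                }
            )
            i += 1
    df = pd.DataFrame(rows)
    df["ectopic-bone"] = df["ectopic-bone"].astype("boolean")
    return ScoringTable(df, loci=("mef2ca",), phenotypes=("ectopic-bone",))


class TestEstimatePenetrance:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(4, 101, 0.0396), (0, 25, 0.0), (18, 44, 0.4091)],
    )
    def test_reported_proportions(self, k, n, expected):
        t = table_from_counts({"s": (k, n)})
        est = estimate_penetrance(t, "ectopic-bone", {"strain": "s"})
        assert est.proportion == pytest.approx(expected, abs=5e-5)
        assert est.ci_low <= est.proportion <= est.ci_high

    def test_zero_affected_has_zero_ci_lower_bound(self):
        est = estimate_penetrance(
            table_from_counts({"s": (0, 25)}), "ectopic-bone", {"strain": "s"}
        )
        assert est.ci_low == 0.0

    def test_empty_group_is_an_error_not_zero(self, small_table):
        with pytest.raises(EstimationError):
            estimate_penetrance(small_table, "ectopic-bone", {"strain": "absent"})

    def test_invariant_to_record_order_and_unscored_rows(self, small_table):
        base = estimate_penetrance(small_table, "ectopic-bone", mutants_of("high"))
        shuffled = ScoringTable(
            small_table.data.sample(frac=1, random_state=0).reset_index(drop=True),
            loci=small_table.loci,
            phenotypes=small_table.phenotypes,
        )
        again = estimate_penetrance(shuffled, "ectopic-bone", mutants_of("high"))
        assert (base.affected, base.scored) == (again.affected, again.scored)
        # the NA-scored high mutant is in neither margin
        assert base.scored == 1


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((5, 5, 5, 5), 1.0),
            ((0, 3, 3, 0), 0.1),
            ((8, 36, 18, 26), fisher_enumeration(8, 36, 18, 26)),
        ],
    )
    def test_known_tables(self, table, expected):
        assert fisher_exact_2x2(ContingencyTable2x2(*table)) == pytest.approx(expected)

    def test_zero_margin_returns_one_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 4)) == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable2x2(-1, 2, 3, 4)

    @given(st.tuples(*(st.integers(0, 12),) * 4))
    def test_invariant_under_simultaneous_row_and_column_swap(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p1 = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            p2 = fisher_exact_2x2(ContingencyTable2x2(d, c, b, a))
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestAdjustment:
    def test_single_p_unchanged_by_either_method(self):
        for method in ("benjamini-hochberg", "hochberg"):
            out = adjust_pvalues(PValueSet(["x"], [0.03], method))
            assert out.adjusted[0] == pytest.approx(0.03)

    def test_bh_step_up_worked_example(self):
        out = adjust_pvalues(PValueSet(list("abc"), [0.01, 0.02, 0.03], "benjamini-hochberg"))
        assert out.adjusted == pytest.approx([0.03, 0.03, 0.03])

    def test_hochberg_step_up_worked_example(self):
        out = adjust_pvalues(PValueSet(list("ab"), [0.01, 0.04], "hochberg"))
        assert out.adjusted == pytest.approx([0.02, 0.04])

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            PValueSet(["x"], [1.5], "hochberg")

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=8),
        st.sampled_from(["benjamini-hochberg", "hochberg"]),
    )
    def test_adjustment_is_monotone_and_bounded(self, raw, method):
        out = adjust_pvalues(PValueSet([str(i) for i in range(len(raw))], raw, method))
        adj = out.adjusted
        assert (adj <= 1.0 + 1e-12).all()
        assert (adj >= np.asarray(raw) - 1e-12).all()
        order = np.argsort(raw)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestComparePenetranceGroups:
    def test_identical_counts_are_never_significant(self, config):
        t = table_from_counts({"low": (5, 20)})
        high = table_from_counts({"high": (5, 20)})
        merged = ScoringTable(
            pd.concat([t.data, high.data.assign(animal_id=lambda d: d.animal_id + "h")],
                      ignore_index=True),
            loci=("mef2ca",),
            phenotypes=("ectopic-bone",),
        )
        res = compare_penetrance_groups(
            merged, ["ectopic-bone"], mutants_of("low"), mutants_of("high"), config
        )
        assert (res["p_raw"] == 1.0).all()
        assert not res["significant"].any()

    def test_reproduces_overexpression_comparison(self, config):
        """Control 8/44 vs treated 18/44: significant at alpha 0.05."""
        merged = table_from_counts({"control": (8, 44), "treated": (18, 44)})
        res = compare_penetrance_groups(
            merged, ["ectopic-bone"], mutants_of("control"), mutants_of("treated"),
            config, label_a="control", label_b="treated",
        )
        row = res.iloc[0]
        assert row["p_raw"] == pytest.approx(fisher_enumeration(8, 36, 18, 26))
        assert row["p_raw"] < 0.05
        assert row["significant"]

    def test_family_adjustment_composes_with_fisher(self, config):
        """Three phenotypes with raw p (0.01,0.02,0.03) all BH-adjust to 0.03."""
        pset = adjust_pvalues(
            PValueSet(list("abc"), [0.01, 0.02, 0.03], config.multiplicity, alpha=config.alpha)
        )
        assert pset.adjusted == pytest.approx([0.03, 0.03, 0.03])
        assert pset.significant.all()

    def test_overlapping_groups_rejected(self, config, small_table):
        with pytest.raises(ValidationError, match="overlap"):
            compare_penetrance_groups(
                small_table, ["ectopic-bone"], {"strain": "low"},
                {"genotype": {"mef2ca": "mut"}}, config,
            )
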