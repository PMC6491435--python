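import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from seqmate import (
    IntegrityError,
    MatingTable,
    ParameterError,
    UndefinedStatisticError,
    bootstrap_p,
    cell_coefficients,
    fisher_combine,
    i_psi,
    ia_psi,
    pool_replicates,
    summarize_table,
    w_fitness,
)
from seqmate.mating import read_mating_csv, write_mating_csv

from ._oracles import enumerate_bootstrap_p_psi00


def table(pairs, af=(25, 25), am=(25, 25)):
    return MatingTable(["A", "S"], list(af), list(am), pairs)


random_tables = arrays(np.int64, (2, 2), elements=st.integers(0, 12)).filter(
    lambda p: p.sum() > 0
)


class TestCellCoefficients:
    def test_worked_example(self, worked_table):
        c = cell_coefficients(worked_table)
        assert np.allclose(c.e, 5.0)
        assert c.PTI[0, 0] == pytest.approx(1.6)
        assert c.PSI[0, 0] == pytest.approx(1.6)
        assert c.PSS[0, 0] == pytest.approx(1.0)

    def test_random_mating_fixed_point(self):
        c = cell_coefficients(table([[5, 5], [5, 5]]))
        for m in (c.PTI, c.PSI, c.PSS):
            assert np.allclose(m, 1.0)

    def test_zero_denominator_is_nan_not_zero(self):
        c = cell_coefficients(table([[5, 5], [0, 0]]))
        assert np.isnan(c.PSI[1, 0]) and np.isnan(c.PSI[1, 1])

    def test_empty_table_raises(self):
        with pytest.raises(ParameterError):
            cell_coefficients(table([[0, 0], [0, 0]]))

    @given(random_tables)
    def test_e_and_s_sum_to_total(self, pairs):
        c = cell_coefficients(table(pairs))
        assert c.e.sum() == pytest.approx(pairs.sum())
        assert c.s.sum() == pytest.approx(pairs.sum())

    @given(random_tables)
    def test_pti_factorizes_into_psi_times_pss(self, pairs):
        c = cell_coefficients(table(pairs))
        mask = ~(np.isnan(c.PTI) | np.isnan(c.PSI) | np.isnan(c.PSS))
        assert np.allclose(c.PTI[mask], (c.PSI * c.PSS)[mask], atol=1e-9)


class TestIPsi:
    def test_total_assortative(self):
        assert i_psi(table([[13, 0], [0, 12]])) == pytest.approx(1.0)

    def test_random_mating_zero(self):
        assert i_psi(table([[5, 5], [5, 5]])) == pytest.approx(0.0)

    def test_worked_example(self, worked_table):
        assert i_psi(worked_table) == pytest.approx(0.6)

    def test_undefined_cell_raises_with_cell(self):
        with pytest.raises(UndefinedStatisticError) as exc:
            i_psi(table([[5, 5], [0, 0]]))
        assert exc.value.cell is not None

    @given(random_tables)
    def test_bounds(self, pairs):
        try:
            v = i_psi(table(pairs))
        except UndefinedStatisticError:
            return
        assert -1.0 - 1e-12 <= v <= 1.0 + 1e-12


class TestIaPsi:
    def test_symmetric_table_no_asymmetry(self, worked_table):
        assert ia_psi(worked_table) == pytest.approx(1.0)

    def test_hand_computed_ratio_and_order(self):
        t = table([[6, 6], [2, 6]])
        assert ia_psi(t) == pytest.approx(0.75)
        swapped = [("S", "A"), ("A", "S")]
        assert ia_psi(t, swapped) == pytest.approx(1 / 0.75)

    @given(random_tables)
    def test_order_swap_inverts(self, pairs):
        # the inversion x -> 1/x requires both heterotypic PSI cells positive
        t = table(pairs)
        try:
            v = ia_psi(t)
            swapped = ia_psi(t, [("S", "A"), ("A", "S")])
        except UndefinedStatisticError:
            return
        if v == 0:
            return
        assert swapped == pytest.approx(1 / v)

    def test_zero_heterotypic_psi_raises(self):
        with pytest.raises(UndefinedStatisticError):
            ia_psi(table([[10, 0], [5, 5]]))


class TestWFitness:
    def test_equal_rates(self):
        w = w_fitness(table([[5, 5], [5, 5]]), "male")
        assert np.allclose(w, [1.0, 1.0])

    def test_hand_computed_ratio(self):
        w = w_fitness(table([[8, 4], [4, 4]]), "male")  # mated males 12 vs 8
        assert w[0] == pytest.approx(1.0)
        assert w[1] == pytest.approx(8 / 12)

    def test_availability_scale_invariance(self):
        p = [[8, 4], [4, 4]]
        w1 = w_fitness(table(p, af=(25, 25), am=(25, 25)), "female")
        w2 = w_fitness(table(p, af=(100, 100), am=(100, 100)), "female")
        assert np.allclose(w1, w2)

    def test_no_matings_raises(self):
        t = MatingTable(["A", "S"], [5, 5], [5, 5], [[0, 0], [0, 0]])
        with pytest.raises((ParameterError, UndefinedStatisticError)):
            w_fitness(t, "male")


class TestBootstrap:
    def test_degenerate_distribution_tiny_p(self):
        t = table([[13, 0], [0, 12]])
        b = bootstrap_p(t, "I_PSI", n_boot=4000, seed=1)
        assert b.p < 2 / 4000

    def test_seed_determinism(self, worked_table):
        a = bootstrap_p(worked_table, "I_PSI", n_boot=2000, seed=7)
        b = bootstrap_p(worked_table, "I_PSI", n_boot=2000, seed=7)
        assert a.p == b.p

    def test_agrees_with_exact_enumeration_at_t3(self):
        t = table([[1, 1], [1, 0]])
        exact = enumerate_bootstrap_p_psi00(t.pairs, 3)
        b = bootstrap_p(t, "PSI", cell=(0, 0), n_boot=40_000, seed=3)
        # 3 Monte-Carlo standard errors on a doubled tail fraction
        se = 2 * np.sqrt(0.25 / 40_000)
        assert abs(b.p - exact) < 3 * se + 1e-9

    def test_undefined_observed_statistic_raises(self):
        with pytest.raises(UndefinedStatisticError):
            bootstrap_p(table([[5, 5], [0, 0]]), "I_PSI", n_boot=100, seed=0)

    def test_discarded_resamples_reported(self):
        b = bootstrap_p(table([[2, 1], [1, 1]]), "I_PSI", n_boot=2000, seed=2)
        assert 0 <= b.n_discarded < 2000


class TestPoolReplicates:
    def test_zero_table_identity(self, worked_table):
        zero = MatingTable(["A", "S"], [0, 0], [0, 0], [[0, 0], [0, 0]])
        pooled = pool_replicates([worked_table, zero])
        assert (pooled.pairs == worked_table.pairs).all()
        assert (pooled.avail_females == worked_table.avail_females).all()

    def test_k_copies_scale(self, worked_table):
        pooled = pool_replicates([worked_table] * 3)
        assert (pooled.pairs == 3 * worked_table.pairs).all()

    def test_order_invariant(self, worked_table):
        other = table([[3, 1], [2, 4]])
        a = pool_replicates([worked_table, other])
        b = pool_replicates([other, worked_table])
        assert (a.pairs == b.pairs).all()

    def test_mismatched_types_raise(self, worked_table):
        other = MatingTable(["X", "Y"], [5, 5], [5, 5], [[1, 0], [0, 1]])
        with pytest.raises(IntegrityError):
            pool_replicates([worked_table, other])


class TestFisherCombine:
    def test_all_ones(self):
        fr = fisher_combine([1.0, 1.0, 1.0])
        assert fr.chi_square == 0.0 and fr.df == 6 and fr.p == pytest.approx(1.0)

    def test_three_at_005(self):
        fr = fisher_combine([0.05, 0.05, 0.05])
        assert fr.chi_square == pytest.approx(-6 * np.log(0.05), abs=1e-9)
        assert fr.chi_square == pytest.approx(17.97, abs=0.01)
        assert fr.df == 6

    def test_single_p_identity(self):
        fr = fisher_combine([0.5])
        assert fr.chi_square == pytest.approx(1.386, abs=0.001)
        assert fr.df == 2 and fr.p == pytest.approx(0.5)

    def test_empty_raises(self):
        with pytest.raises(ParameterError):
            fisher_combine([])

    def test_zero_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            fr = fisher_combine([0.0, 0.5])
        assert np.isfinite(fr.chi_square)

    def test_uniform_inputs_give_uniform_output(self):
        rng = np.random.default_rng(5)
        ps = [fisher_combine(list(rng.uniform(1e-12, 1, 4))).p for _ in range(5000)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSummaryAndIO:
    def test_summarize_worked_table(self, worked_table):
        s = summarize_table(worked_table, n_boot=1000, seed=0)
        assert s.i_psi == pytest.approx(0.6)
        assert s.ia_psi == pytest.approx(1.0)
        assert max(s.w_females) == 1.0 and max(s.w_males) == 1.0
        assert "I_PSI" in s.p_values

    def test_undefined_index_reported_as_nan(self):
        s = summarize_table(table([[10, 0], [5, 5]]), n_boot=200, seed=0)
        assert np.isnan(s.ia_psi)
        assert "IA_PSI" not in s.p_values

    def test_csv_roundtrip(self, tmp_path, worked_table):
        tables = {"t1": worked_table, "t2": table([[3, 1], [2, 4]])}
        groups = {"t1": "rep1", "t2": "rep2"}
        write_mating_csv(tables, tmp_path / "p.csv", tmp_path / "a.csv", groups)
        back, back_groups = read_mating_csv(tmp_path / "p.csv", tmp_path / "a.csv")
        assert set(back) == {"t1", "t2"}
        assert (back["t1"].pairs == worked_table.pairs).all()
        assert (back["t2"].avail_males == [25, 25]).all()
        assert back_groups == groups

    def test_malformed_csv_raises(self, tmp_path):
        (tmp_path / "p.csv").write_text("trial_id,female_type\nx,A\n")
        (tmp_path / "a.csv").write_text("trial_id,sex,type,available\nx,female,A,5\n")
        with pytest.raises(IntegrityError, match="pairs"):
            read_mating_csv(tmp_path / "p.csv", tmp_path / "a.csv")
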