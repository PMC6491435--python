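import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seqmate import (
    DEConfig,
    DesignError,
    ParameterError,
    call_de,
    group_interval,
    hierarchical_de,
    make_counts,
    noise_filter,
    offset_fold_change,
    select_reference_genes,
)

from .conftest import make_matrix

pos_floats = st.floats(0, 1e7, allow_nan=False, allow_infinity=False)


class TestOffsetFoldChange:
    def test_powers_of_two(self):
        assert offset_fold_change(1004, 236, 20) == pytest.approx(2.0)

    @pytest.mark.parametrize("x", [0, 1, 100, 1e6])
    def test_equal_inputs_zero(self, x):
        assert offset_fold_change(x, x, 20) == 0.0

    @given(pos_floats, pos_floats)
    def test_antisymmetric(self, a, b):
        assert offset_fold_change(a, b, 20) == pytest.approx(
            -offset_fold_change(b, a, 20), abs=1e-9
        )

    @given(pos_floats, pos_floats, pos_floats)
    def test_monotone_in_first_argument(self, a, b, delta):
        assert offset_fold_change(a + delta, b, 20) >= offset_fold_change(a, b, 20)

    def test_nonpositive_offset_rejected(self):
        with pytest.raises(ParameterError):
            offset_fold_change(1, 1, 0)


class TestNoiseFilter:
    def test_below_floor_everywhere_dropped(self):
        em = make_matrix({"low": [99] * 6, "hi": [150] * 6})
        kept, dropped = noise_filter(em, 100)
        assert dropped == ["low"] and list(kept.values.index) == ["hi"]

    def test_single_sample_above_floor_keeps(self):
        em = make_matrix({"edge": [99, 100, 30, 0, 1, 2]})
        kept, dropped = noise_filter(em, 100)
        assert dropped == [] and "edge" in kept.values.index

    def test_nothing_dropped_when_all_pass(self):
        em = make_matrix({"a": [200] * 6, "b": [500] * 6})
        _, dropped = noise_filter(em, 100)
        assert dropped == []

    def test_raw_state_rejected(self):
        em = make_matrix({"a": [200] * 6}, state="raw")
        with pytest.raises(ParameterError):
            noise_filter(em)


class TestGroupInterval:
    def test_min_max(self):
        assert group_interval([120, 150, 140]) == (120, 150)

    def test_single_replicate(self):
        assert group_interval([7]) == (7, 7)

    @given(st.lists(pos_floats, min_size=1, max_size=8))
    def test_permutation_invariant(self, vals):
        assert group_interval(vals) == group_interval(vals[::-1])

    def test_empty_raises(self):
        with pytest.raises(ParameterError):
            group_interval([])


class TestCallDE:
    def test_degenerate_intervals_powers_of_two(self):
        em = make_matrix({"t": [1004, 1004, 1004, 236, 236, 236]})
        (r,) = call_de(em)
        assert r.conservative_log2_ofc == pytest.approx(2.0)
        assert r.de_call and r.direction == "up_in_A"

    def test_overlapping_intervals_never_called(self):
        em = make_matrix({"t": [100, 300, 200, 250, 600, 400]})
        (r,) = call_de(em)
        assert not r.de_call and r.direction == "none"

    def test_direction_tracks_sign(self):
        em = make_matrix({"t": [236, 236, 236, 1004, 1004, 1004]})
        (r,) = call_de(em)
        assert r.conservative_log2_ofc == pytest.approx(-2.0)
        assert r.direction == "up_in_S"

    def test_threshold_monotone(self):
        em, _ = make_counts(
            300,
            [("HT", r, k) for r in ("A", "S") for k in (1, 2, 3)],
            300_000, 0.05, 0.2, 2.0, seed=0,
        )
        loose = {r.transcript_id for r in call_de(em, config=DEConfig(ofc_threshold=0.5)) if r.de_call}
        strict = {r.transcript_id for r in call_de(em, config=DEConfig(ofc_threshold=1.5)) if r.de_call}
        assert strict <= loose

    def test_requires_two_groups(self):
        em = make_matrix({"t": [1, 2, 3]}, regimes=["A", "A", "A"])
        with pytest.raises(DesignError):
            call_de(em)


class TestOperatingCharacteristics:
    """Truth-recovery on the synthetic generator at the generator's own
    dispersion (0.05) with 3 vs 3 replicates."""

    design = [("HT", r, k) for r in ("A", "S") for k in (1, 2, 3)]

    def test_null_false_positive_rate_below_one_percent(self):
        fprs = []
        for seed in range(20):
            em, _ = make_counts(2000, self.design, 2_000_000, 0.05, 0.0, 2.0, seed)
            kept, _ = noise_filter(em)
            res = call_de(kept)
            fprs.append(np.mean([r.de_call for r in res]))
        assert np.mean(fprs) <= 0.01

    def test_sensitivity_at_high_abundance(self):
        sens = []
        for seed in range(20):
            em, truth = make_counts(2000, self.design, 2_000_000, 0.05, 0.1, 2.0, seed)
            kept, _ = noise_filter(em)
            called = {r.transcript_id for r in call_de(kept) if r.de_call}
            gm = truth.group_means
            eligible = gm.index[(gm.min(axis=1) >= 500).to_numpy() & truth.de_labels]
            sens.append(np.mean([t in called for t in eligible]))
        assert np.mean(sens) >= 0.80


class TestHierarchicalDE:
    def test_tissue_specific_class(self):
        em = make_matrix(
            {
                "ab_only": [10, 10, 10, 10, 10, 10, 2000, 2000, 2000, 300, 300, 300],
                "both": [500] * 12,
            },
            tissues=["HT"] * 6 + ["Ab"] * 6,
            regimes=(["A"] * 3 + ["S"] * 3) * 2,
        )
        out = hierarchical_de(em)
        ab = {r.transcript_id: r for r in out["Ab"]}
        assert ab["ab_only"].expression_class == "tissue_specific"
        assert ab["ab_only"].de_call
        assert ab["both"].expression_class == "shared"
        assert "ab_only" not in {r.transcript_id for r in out["HT"]}

    def test_shared_listed_in_both_tissues(self):
        em = make_matrix(
            {"both": [500] * 12},
            tissues=["HT"] * 6 + ["Ab"] * 6,
            regimes=(["A"] * 3 + ["S"] * 3) * 2,
        )
        out = hierarchical_de(em)
        for t in ("HT", "Ab"):
            assert out[t][0].expression_class == "shared"

    def test_missing_regime_raises(self):
        em = make_matrix(
            {"t": [1, 2, 3, 4, 5, 6]},
            tissues=["HT"] * 3 + ["Ab"] * 3,
            regimes=["A", "A", "A", "A", "S", "S"],
        )
        with pytest.raises(DesignError):
            hierarchical_de(em)

    def test_class_labels_match_construction(self):
        design = [(t, r, k) for t in ("HT", "Ab") for r in ("A", "S") for k in (1, 2, 3)]
        em, _ = make_counts(400, design, 400_000, 0.05, 0.0, 2.0, seed=8)
        # silence half the genes in HT to make them Ab-specific
        silenced = em.values.index[:200]
        ht_cols = em.sample_meta.index[em.sample_meta["tissue"] == "HT"]
        em.values.loc[silenced, ht_cols] = 0.0
        out = hierarchical_de(em)
        ab = {r.transcript_id: r.expression_class for r in out["Ab"]}
        for t, cls in ab.items():
            assert cls == ("tissue_specific" if t in set(silenced) else "shared")


class TestReferenceGenes:
    tissues = ["HT"] * 6 + ["Ab"] * 6
    regimes = (["A"] * 3 + ["S"] * 3) * 2

    def make(self, rows):
        return make_matrix(rows, tissues=self.tissues, regimes=self.regimes)

    def test_constant_high_row_selected(self):
        em = self.make({"ref": [600_000.0] * 12})
        assert select_reference_genes(em) == ["ref"]

    def test_one_low_sample_rejected(self):
        vals = [600_000.0] * 12
        vals[4] = 400_000.0
        em = self.make({"notref": vals})
        assert select_reference_genes(em) == []

    def test_tiny_regime_shift_rejected(self):
        # 600,000 vs 600,100 between regimes: |OFC| ~ 0.00024 > 0.0001
        vals = ([600_000.0] * 3 + [600_100.0] * 3) * 2
        em = self.make({"shifted": vals})
        assert select_reference_genes(em) == []
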