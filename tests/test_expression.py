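import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lncarch.expression import (
    AnalysisConfig,
    CASCADE_STEPS,
    ExpressionTimecourse,
    correlate_pair,
    fold_change,
    is_differentially_expressed,
    kendall_tau,
    read_expression_tsv,
    run_filtration_cascade,
    write_expression_tsv,
)
from lncarch.ga_classifier import ArchitecturePair, make_ga_class

from .conftest import make_tc


def brute_force_tau(x, y):
    """Independent all-pairs Kendall tau-b oracle."""
    n = len(x)
    c = d = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        sx = np.sign(x[j] - x[i])
        sy = np.sign(y[j] - y[i])
        if sx == 0 and sy == 0:
            continue
        if sx == 0:
            tx += 1
        elif sy == 0:
            ty += 1
        elif sx == sy:
            c += 1
        else:
            d += 1
    den = np.sqrt((c + d + tx) * (c + d + ty))
    return np.nan if den == 0 else (c - d) / den


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestReadExpression:
    def write(self, tmp_path, header, rows):
        p = tmp_path / "expr.tsv"
        p.write_text("\n".join(["\t".join(header)] + rows) + "\n")
        return p

    def test_reads_matrix_per_gene(self, tmp_path):
        header = ["gene_id", "r1_t0", "r1_t6", "r1_t24", "r1_t120",
                  "r2_t0", "r2_t6", "r2_t24", "r2_t120"]
        p = self.write(tmp_path, header, ["gA\t1\t2\t3\t4\t5\t6\t7\t8", "gB\t8\t7\t6\t5\t4\t3\t2\t1"])
        tcs = read_expression_tsv(p)
        assert set(tcs) == {"gA", "gB"}
        assert tcs["gA"].values.shape == (2, 4)
        assert tcs["gA"].timepoints == (0, 6, 24, 120)
        np.testing.assert_array_equal(tcs["gA"].values, [[1, 2, 3, 4], [5, 6, 7, 8]])

    def test_shuffled_columns_give_identical_result(self, tmp_path):
        h1 = ["gene_id", "r1_t0", "r1_t6", "r2_t0", "r2_t6"]
        h2 = ["gene_id", "r2_t6", "r1_t0", "r2_t0", "r1_t6"]
        p1 = self.write(tmp_path, h1, ["g\t1\t2\t3\t4"])
        t1 = read_expression_tsv(p1)["g"]
        p2 = self.write(tmp_path, h2, ["g\t4\t1\t3\t2"])
        t2 = read_expression_tsv(p2)["g"]
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_negative_value_rejected(self, tmp_path):
        p = self.write(tmp_path, ["gene_id", "r1_t0", "r1_t6", "r2_t0", "r2_t6"], ["g\t1\t-2\t3\t4"])
        with pytest.raises(ValueError, match="negative|non-negative"):
            read_expression_tsv(p)

    def test_missing_cell_names_gene_and_column(self, tmp_path):
        p = self.write(tmp_path, ["gene_id", "r1_t0", "r1_t6", "r2_t0", "r2_t6"], ["g\t1\t\t3\t4"])
        with pytest.raises(ValueError, match="g.*r1_t6"):
            read_expression_tsv(p)

    def test_unknown_header_rejected(self, tmp_path):
        p = self.write(tmp_path, ["gene_id", "sample1", "sample2"], ["g\t1\t2"])
        with pytest.raises(ValueError, match="header"):
            read_expression_tsv(p)

    def test_round_trip(self, tmp_path):
        tc = make_tc([1, 2, 3, 4], [5, 6, 7, 8], gene_id="g")
        p = tmp_path / "rt.tsv"
        write_expression_tsv({"g": tc}, p)
        back = read_expression_tsv(p)["g"]
        np.testing.assert_array_equal(back.values, tc.values)


def test_timecourse_invariants():
    with pytest.raises(ValueError, match="replicates"):
        ExpressionTimecourse("g", (0, 6), np.array([[1.0, 2.0]]))
    with pytest.raises(ValueError, match="increasing"):
        make_tc([1, 2, 3, 4], [1, 2, 3, 4], timepoints=(0, 6, 6, 120))


# ---------------------------------------------------------------------------
# Kendall tau
# ---------------------------------------------------------------------------

class TestKendallTau:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3, 4), (2, 4, 6, 8), 1.0),
            ((1, 2, 3, 4), (4, 3, 2, 1), -1.0),
            ((1, 2, 3, 4), (1, 3, 2, 4), 2 / 3),  # 5 concordant, 1 discordant of 6
        ],
    )
    def test_worked_examples(self, x, y, expected):
        assert kendall_tau(x, y) == pytest.approx(expected)

    def test_length_contract(self):
        with pytest.raises(ValueError):
            kendall_tau([1], [2])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            n = rng.integers(2, 9)
            x = rng.integers(0, 6, n)  # small alphabet: ties exercised
            y = rng.integers(0, 6, n)
            got = kendall_tau(x, y)
            want = brute_force_tau(x, y)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.integers(-50, 50), min_size=2, max_size=8),
        st.lists(st.integers(-50, 50), min_size=2, max_size=8),
    )
    def test_symmetry_and_monotone_invariance(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n], float), np.array(ys[:n], float)
        t = kendall_tau(x, y)
        if np.isnan(t):
            return
        assert kendall_tau(y, x) == pytest.approx(t)
        # strictly increasing transform of either argument preserves tau
        assert kendall_tau(np.exp(x / 50), y) == pytest.approx(t)
        assert kendall_tau(x, 3 * y + 7) == pytest.approx(t)


# ---------------------------------------------------------------------------
# fold change and the DE rule
# ---------------------------------------------------------------------------

class TestFoldChange:
    def test_up(self):
        assert fold_change(make_tc([100, 0, 0, 150], [100, 0, 0, 150])) == pytest.approx(1.5)

    def test_down_direction_symmetric(self):
        assert fold_change(make_tc([200, 0, 0, 100], [200, 0, 0, 100])) == pytest.approx(2.0)

    def test_constant_is_one(self):
        assert fold_change(make_tc([100] * 4, [100] * 4)) == pytest.approx(1.0)

    def test_zero_endpoint_rejected(self):
        with pytest.raises(ValueError, match="fold change"):
            fold_change(make_tc([0, 1, 1, 1], [0, 1, 1, 1]))


class TestDERule:
    def test_concordant_subset_and_fc_pass(self):
        # subset {0, 24, 120} has tau=1; FC = mean(160,158)/mean(100,100) = 1.59
        res = is_differentially_expressed(make_tc([100, 150, 155, 160], [100, 160, 140, 158]))
        assert res.is_de and res.concordant
        assert res.fold_change == pytest.approx(1.59)
        assert (0, 2, 3) in res.qualifying_subsets

    def test_flat_profile_fails_on_fold_change(self):
        assert not is_differentially_expressed(make_tc([100] * 4, [100] * 4))

    def test_discordant_replicates_fail(self):
        # every 3-subset has tau = -1
        res = is_differentially_expressed(make_tc([100, 150, 155, 160], [160, 120, 110, 100]))
        assert not res.is_de and not res.concordant

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        tcs = [
            make_tc(rng.integers(50, 500, 4), rng.integers(50, 500, 4), gene_id=f"g{i}")
            for i in range(60)
        ]

        def de_set(tau, fc):
            cfg = AnalysisConfig(tau_threshold=tau, fc_threshold=fc)
            return {tc.gene_id for tc in tcs if is_differentially_expressed(tc, cfg)}

        base = de_set(0.6, 1.5)
        assert de_set(0.9, 1.5) <= base
        assert de_set(0.6, 2.5) <= base
        assert de_set(0.3, 1.2) >= base


# ---------------------------------------------------------------------------
# pair correlation
# ---------------------------------------------------------------------------

class TestCorrelatePair:
    def pair(self, lvals, pvals):
        return make_tc(lvals, lvals, "l"), make_tc(pvals, pvals, "p")

    def test_positive(self):
        l, p = self.pair([1, 2, 3, 4], [10, 20, 30, 40])
        r = correlate_pair(l, p)
        assert (r.sign, r.tau) == ("+", pytest.approx(1.0))

    def test_negative(self):
        l, p = self.pair([1, 2, 3, 4], [4, 3, 2, 1])
        r = correlate_pair(l, p)
        assert (r.sign, r.tau) == ("-", pytest.approx(-1.0))

    def test_weak_is_none(self):
        l, p = self.pair([1, 2, 3, 4], [2, 1, 4, 3])  # 4 concordant, 2 discordant
        r = correlate_pair(l, p)
        assert r.sign == "none"
        assert r.tau == pytest.approx(1 / 3)

    def test_admissible_tau_values_on_untied_points(self):
        """Over all 24 orderings of 4 untied points, |tau| >= 0.6 admits exactly {2/3, 1}."""
        base = [1.0, 2.0, 3.0, 4.0]
        taus = {
            round(kendall_tau(base, perm), 6)
            for perm in map(list, itertools.permutations(base))
        }
        assert taus == {round(v, 6) for v in
                        (-1, -2 / 3, -1 / 3, 0, 1 / 3, 2 / 3, 1)}
        admitted = {t for t in taus if abs(t) >= 0.6}
        assert admitted == {round(v, 6) for v in (-1, -2 / 3, 2 / 3, 1)}


# ---------------------------------------------------------------------------
# filtration cascade
# ---------------------------------------------------------------------------

def _planted_cascade():
    """20 paired lncRNAs: 10 DE, 5 with DE partners, 3 positively correlated."""
    DE = [100, 120, 130, 160]       # tau=1 on every subset, FC 1.6
    FLAT = [100, 100, 100, 100]     # FC 1.0: not DE
    DOWN = [160, 130, 120, 100]     # DE, opposite direction
    WEAK = [100, 160, 110, 150]     # DE (FC 1.5) but tau vs DE profile = 1/3

    pairs, expr = [], {}
    for i in range(20):
        lid, pid = f"l{i:02d}", f"p{i:02d}"
        pairs.append(
            ArchitecturePair(
                lncrna_id=lid, partner_id=pid, ga=make_ga_class("head_to_head"),
                edge_distance=0, tss_distance=0, overlap_bp=10,
            )
        )
        if i < 3:          # DE + DE partner + positive correlation
            lvals, pvals = DE, DE
        elif i < 5:        # DE + DE partner, weak correlation
            lvals, pvals = WEAK, DE
        elif i < 10:       # DE lncRNA, flat partner
            lvals, pvals = DOWN, FLAT
        else:              # not DE
            lvals, pvals = FLAT, DE
        expr[lid] = make_tc(lvals, lvals, lid)
        expr[pid] = make_tc(pvals, pvals, pid)
    return pairs, expr


def test_cascade_planted_sizes():
    pairs, expr = _planted_cascade()
    res = run_filtration_cascade(pairs, expr)
    assert res.step_sizes() == {
        "on_array": 20,
        "differentially_expressed": 10,
        "protein_associated": 10,
        "partner_differentially_expressed": 5,
        "correlated": 3,
    }
    signs = res.flags["correlation_sign"]
    assert (signs == "+").sum() == 3
    # correlation sign only set inside the partner-DE set
    assert (signs[~res.flags["partner_differentially_expressed"]] == "none").all()


def test_cascade_nesting_and_table_marginals():
    pairs, expr = _planted_cascade()
    res = run_filtration_cascade(pairs, expr)
    for prev, step in zip(CASCADE_STEPS, CASCADE_STEPS[1:]):
        assert set(res.members(step)) <= set(res.members(prev))
        for kind, table in res.tables[step].items():
            assert table.sum() == len(res.members(step))


def test_cascade_order_invariance_and_no_de_case():
    pairs, expr = _planted_cascade()
    a = run_filtration_cascade(pairs, expr)
    b = run_filtration_cascade(list(reversed(pairs)), expr)
    pd.testing.assert_frame_equal(a.flags, b.flags)

    flat = {g: make_tc([100] * 4, [100] * 4, g) for g in expr}
    res = run_filtration_cascade(pairs, flat)
    sizes = res.step_sizes()
    assert sizes["on_array"] == 20
    assert all(sizes[s] == 0 for s in CASCADE_STEPS[1:])
    assert res.tables["on_array"]["ga_class"]["head_to_head"] == 20


def test_cascade_drops_missing_expression_with_warning():
    pairs, expr = _planted_cascade()
    del expr["l00"]
    res = run_filtration_cascade(pairs, expr)
    assert res.dropped == ("l00",)
    assert res.step_sizes()["on_array"] == 19
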