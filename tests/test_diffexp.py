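import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cistrans.data_io import AMPLIFICATION, DELETION, Alteration, ExpressionMatrix, ValidationError
from cistrans.diffexp import (
    CIS_THRESHOLDS,
    DEThresholds,
    ROLE_CIS,
    ROLE_TRANS,
    _test_matrix,
    bh_fdr,
    one_sided_p,
    run_de,
    two_group_test,
)


def pooled_t_oracle(x0, x1):
    """Textbook pooled-variance two-sample t-test."""
    n0, n1 = len(x0), len(x1)
    s2 = (np.sum((x0 - np.mean(x0)) ** 2) + np.sum((x1 - np.mean(x1)) ** 2)) / (n0 + n1 - 2)
    t = (np.mean(x1) - np.mean(x0)) / math.sqrt(s2 * (1 / n0 + 1 / n1))
    p = 2 * stats.t.sf(abs(t), n0 + n1 - 2)
    return t, p


class TestTwoGroupTest:
    def test_simple_example(self):
        log2fc, t, p, df = two_group_test([1, 1, 2, 2], [0, 0, 1, 1])
        assert log2fc == pytest.approx(1.0)
        t_ref, p_ref = pooled_t_oracle(np.array([1.0, 1.0]), np.array([2.0, 2.0]))
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(p_ref)
        assert df == 2

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(25):
            x = rng.normal(size=30)
            status = np.array([0] * 14 + [1] * 16)
            _, t, p, _ = two_group_test(x, status)
            ref = stats.ttest_ind(x[status == 1], x[status == 0], equal_var=True)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_no_signal(self):
        log2fc, _, p, _ = two_group_test([3, 4, 3, 4], [0, 0, 1, 1])
        assert log2fc == 0 and p == pytest.approx(1.0)

    def test_degenerate_grouping_errors(self):
        with pytest.raises(ValidationError):
            two_group_test([1, 2, 3, 4], [0, 0, 0, 0])

    def test_flipping_status_negates_effect(self, rng):
        x = rng.normal(size=20)
        status = np.array([0] * 10 + [1] * 10)
        fc1, t1, p1, _ = two_group_test(x, status)
        fc2, t2, p2, _ = two_group_test(x, 1 - status)
        assert fc1 == pytest.approx(-fc2)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_handling(self):
        # perfect separation: flagged, p -> 0
        table = _test_matrix(np.array([[1.0, 1.0, 2.0, 2.0]]), np.array([0, 0, 1, 1]))
        assert table["degenerate"].iloc[0] and table["p_two"].iloc[0] == 0.0
        # no difference at all: p = 1
        table = _test_matrix(np.array([[1.0, 1.0, 1.0, 1.0]]), np.array([0, 0, 1, 1]))
        assert table["p_two"].iloc[0] == 1.0


class TestOneSidedP:
    def test_symmetry_at_zero(self):
        assert one_sided_p(0.0, 10, "up") == pytest.approx(0.5)

    def test_up_down_mirror(self):
        assert one_sided_p(2.5, 8, "up") == pytest.approx(one_sided_p(-2.5, 8, "down"))

    def test_matches_student_tail(self):
        assert one_sided_p(1.0, 10, "up") == pytest.approx(stats.t.sf(1.0, 10))

    def test_relation_to_two_sided(self, rng):
        # p_one = p_two/2 in the expected direction, 1 - p_two/2 otherwise
        for t in [2.0, -2.0, 0.5]:
            p_two = 2 * stats.t.sf(abs(t), 12)
            p_up = one_sided_p(t, 12, "up")
            expected = p_two / 2 if t > 0 else 1 - p_two / 2
            assert p_up == pytest.approx(expected)


def bh_bruteforce(p):
    """Literal step-up rule: q_(i) = min_{j >= i} p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        q[idx] = min(running, 1.0)
    return q


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.3]), [0.3])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(derandomize=True, max_examples=300)
    def test_matches_bruteforce_stepup(self, pvals):
        np.testing.assert_allclose(bh_fdr(pvals), bh_bruteforce(pvals), atol=1e-12)

    def test_adjusted_never_below_raw_and_monotone(self, rng):
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def _toy_alteration(n, direction=AMPLIFICATION, cis=("C1",)):
    status = np.zeros(n, dtype=np.int8)
    status[n // 2:] = 1
    return Alteration("alt", direction, status, frozenset(cis))


def _toy_expr(rows, samples):
    return ExpressionMatrix(pd.DataFrame(rows, index=samples).T)


class TestRunDe:
    def _setup(self, rng, n=60):
        samples = [f"s{i}" for i in range(n)]
        alt = _toy_alteration(n)
        status = alt.status.astype(float)
        rows = {
            "C1": 7 + 1.0 * status + rng.normal(0, 0.4, n),   # strong cis signal
            "C2": 7 + rng.normal(0, 0.4, n),                   # null cis gene
            "T1": 5 - 1.2 * status + rng.normal(0, 0.4, n),    # strong trans, down
            "T2": 5 + rng.normal(0, 0.4, n),
        }
        return _toy_expr(rows, samples), alt

    def test_planted_cis_gene_significant(self, rng):
        expr, alt = self._setup(rng)
        table = run_de(expr, alt, ["C1", "C2"], ROLE_CIS, moderation=False)
        assert "C1" in table.significant_genes
        assert "C2" not in table.significant_genes

    def test_trans_two_sided_catches_downregulation(self, rng):
        expr, alt = self._setup(rng)
        table = run_de(expr, alt, ["T1", "T2"], ROLE_TRANS, moderation=False)
        assert table.significant_genes == ["T1"]

    def test_threshold_filter(self):
        # fold 1.3 with fdr 0.2 retained under cis defaults; fold 1.1 dropped
        df = pd.DataFrame({
            "fold_change": [1.3, 1.1], "fdr": [0.2, 0.0001],
        })
        keep = (df["fold_change"] > CIS_THRESHOLDS.fc_min) & (df["fdr"] < CIS_THRESHOLDS.fdr_max)
        assert keep.tolist() == [True, False]

    def test_significance_monotone_in_thresholds(self, rng):
        expr, alt = self._setup(rng)
        strict = run_de(expr, alt, ["C1", "C2"], ROLE_CIS,
                        DEThresholds(1.5, 0.05), moderation=False)
        lenient = run_de(expr, alt, ["C1", "C2"], ROLE_CIS,
                         DEThresholds(1.1, 0.5), moderation=False)
        assert set(strict.significant_genes) <= set(lenient.significant_genes)

    def test_empty_gene_list_warns(self, rng):
        expr, alt = self._setup(rng)
        with pytest.warns(UserWarning):
            table = run_de(expr, alt, [], ROLE_CIS)
        assert len(table.table) == 0

    def test_null_trans_false_positive_rate(self, rng):
        """Permuted labels yield roughly fdr_max x genes or fewer significant calls."""
        n, g = 80, 120
        samples = [f"s{i}" for i in range(n)]
        matrix = rng.normal(7, 1, (g, n))
        expr = _toy_expr(dict(zip([f"G{i}" for i in range(g)], matrix)), samples)
        counts = []
        for perm in range(30):
            status = np.zeros(n, dtype=np.int8)
            status[rng.permutation(n)[: n // 2]] = 1
            alt = Alteration("alt", AMPLIFICATION, status, frozenset())
            table = run_de(expr, alt, list(expr.gene_ids), ROLE_TRANS, moderation=False)
            counts.append(len(table.significant_genes))
        assert np.mean(counts) <= 0.01 * g + 0.5


class TestModeratedT:
    def test_moderation_shrinks_toward_prior(self, rng):
        n, g = 20, 200
        matrix = rng.normal(0, 1, (g, n))
        matrix[0] *= 0.05  # artificially tiny variance
        status = np.array([0] * 10 + [1] * 10)
        plain = _test_matrix(matrix, status, moderation=False)
        moderated = _test_matrix(matrix, status, moderation=True)
        # the low-variance gene's |t| must shrink; df must grow
        assert abs(moderated["t"].iloc[0]) < abs(plain["t"].iloc[0])
        assert moderated["df"].iloc[0] > plain["df"].iloc[0]

    def test_matches_limma_reference(self, tmp_path, rng):
        """Cross-check the empirical-Bayes moderated t against limma."""
        n, g = 16, 80
        status = np.array([0] * 8 + [1] * 8)
        matrix = rng.normal(7, 1, (g, n)) + 0.8 * status * (rng.uniform(size=(g, 1)) > 0.7)
        df = pd.DataFrame(matrix, index=[f"G{i}" for i in range(g)],
                          columns=[f"s{i}" for i in range(n)])
        mat_path = tmp_path / "mat.tsv"
        df.to_csv(mat_path, sep="\t")
        out_path = tmp_path / "limma.tsv"
        script = tmp_path / "ref.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.table("{mat_path}", header=TRUE, row.names=1, sep="\\t"))
            status <- c({", ".join(map(str, status.tolist()))})
            fit <- eBayes(lmFit(x, cbind(1, status)))
            write.table(data.frame(t=fit$t[, 2], p=fit$p.value[, 2], df=fit$df.total),
                        "{out_path}", sep="\\t", quote=FALSE)
        """))
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(out_path, sep="\t")
        mine = _test_matrix(matrix, status, moderation=True)
        np.testing.assert_allclose(mine["t"], ref["t"], rtol=1e-5)
        np.testing.assert_allclose(mine["p_two"], ref["p"], rtol=1e-5)
        assert mine["df"].iloc[0] == pytest.approx(ref["df"].iloc[0], rel=1e-4)


def test_cis_one_sided_direction_depends_on_alteration(rng):
    n = 40
    samples = [f"s{i}" for i in range(n)]
    status = np.array([0] * 20 + [1] * 20, dtype=np.int8)
    down = 7 - 1.0 * status + rng.normal(0, 0.4, n)
    expr = _toy_expr({"C1": down}, samples)
    amp = Alteration("amp", AMPLIFICATION, status, frozenset({"C1"}))
    dele = Alteration("del", DELETION, status, frozenset({"C1"}))
    as_amp = run_de(expr, amp, ["C1"], ROLE_CIS, moderation=False)
    as_del = run_de(expr, dele, ["C1"], ROLE_CIS, moderation=False)
    # a down-shifted gene is significant for a deletion but not an amplification
    assert as_del.table["p"].iloc[0] < 1e-6
    assert as_amp.table["p"].iloc[0] > 0.5
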