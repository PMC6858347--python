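import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cistrans.data_io import AMPLIFICATION, Alteration, ExpressionMatrix, ValidationError
from cistrans.mediation import (
    assign_mediators,
    compute_wftm,
    mediation_table,
    mediation_weight,
    run_mediation,
    sobel_triplet,
)


def _expr(rows, samples):
    return ExpressionMatrix(pd.DataFrame(rows, index=samples).T)


class TestSobelTriplet:
    def test_exact_fit_orthogonal_mediator(self):
        # trans = 1 + 2*status + 1*cis with cis orthogonal to status:
        # tau = tau' = 2, delta = 0, p = 1
        res = sobel_triplet([0, 0, 1, 1], [0, 1, 0, 1], [1, 2, 3, 4])
        assert res.tau == pytest.approx(2.0)
        assert res.tau_prime == pytest.approx(2.0)
        assert res.delta_tau == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=100)
    def test_nested_ols_identity(self, seed):
        """delta_tau equals a_hat * b_hat exactly for nested OLS."""
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 40)
        status = (rng.uniform(size=n) < 0.5).astype(float)
        if status.min() == status.max():
            status[0] = 1 - status[0]
        cis = rng.normal(size=n)
        trans = rng.normal(size=n)
        res = sobel_triplet(status, cis, trans)
        assert res.delta_tau == pytest.approx(res.a_hat * res.b_hat, abs=1e-9)

    def test_planted_chain_significant_and_agrees_with_permutation(self):
        rng = np.random.default_rng(7)
        n = 200
        status = np.array([0.0] * 100 + [1.0] * 100)
        cis = 0.7 * status + rng.normal(0, 0.5, n)
        trans = 0.7 * cis + rng.normal(0, 0.5, n)
        res = sobel_triplet(status, cis, trans)
        assert res.p < 0.01
        # permutation oracle for the indirect effect: permuting the mediator
        # breaks the chain while preserving the marginals
        observed = abs(res.delta_tau)
        exceed = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = sobel_triplet(status, rng.permutation(cis), trans)
            if abs(perm.delta_tau) >= observed:
                exceed += 1
        p_perm = (exceed + 1) / (n_perm + 1)
        assert (res.p < 0.05) == (p_perm < 0.05)

    def test_null_common_cause_agrees_with_permutation(self):
        rng = np.random.default_rng(8)
        n = 200
        status = np.array([0.0] * 100 + [1.0] * 100)
        cis = 0.7 * status + rng.normal(0, 0.5, n)
        trans = 0.7 * status + rng.normal(0, 0.5, n)
        res = sobel_triplet(status, cis, trans)
        assert res.p > 0.05

    def test_collinear_mediator_flagged(self):
        status = np.array([0, 0, 1, 1, 0, 1])
        res = sobel_triplet(status, 2.0 * status, np.arange(6.0))
        assert res.degenerate

    def test_affine_invariance_of_p(self, rng):
        n = 50
        status = np.array([0.0] * 25 + [1.0] * 25)
        cis = 0.7 * status + rng.normal(0, 0.5, n)
        trans = 0.7 * cis + rng.normal(0, 0.5, n)
        base = sobel_triplet(status, cis, trans)
        scaled = sobel_triplet(status, 3.0 * cis - 5.0, -2.0 * trans + 11.0)
        assert scaled.p == pytest.approx(base.p, rel=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            sobel_triplet([0, 1, 0], [1, 2, 3], [1, 2, 3])  # n < 4
        with pytest.raises(ValidationError):
            sobel_triplet([1, 1, 1, 1], [1, 2, 3, 4], [1, 2, 3, 4])  # constant


class TestBatchAgainstScalar:
    def test_mediation_table_matches_sobel_triplet(self, rng):
        n = 40
        samples = [f"s{i}" for i in range(n)]
        status = np.zeros(n, dtype=np.int8)
        status[rng.permutation(n)[:20]] = 1
        rows = {g: rng.normal(size=n) + status * rng.uniform(0, 1)
                for g in ["c1", "c2", "t1", "t2", "t3"]}
        expr = _expr(rows, samples)
        alt = Alteration("a", AMPLIFICATION, status, frozenset({"c1", "c2"}))
        table = mediation_table(expr, alt, ["c1", "c2"], ["t1", "t2", "t3"])
        for row in table.itertuples():
            ref = sobel_triplet(status.astype(float), rows[row.cis_gene], rows[row.trans_gene])
            assert row.tau == pytest.approx(ref.tau, abs=1e-10)
            assert row.delta_tau == pytest.approx(ref.delta_tau, abs=1e-10)
            assert row.se == pytest.approx(ref.se, abs=1e-10)
            assert row.p == pytest.approx(ref.p, abs=1e-10)


class TestWeight:
    @pytest.mark.parametrize(
        "delta, tau, expected",
        [(0.5, 1.0, 0.5), (1.2, 1.0, 1.0), (-0.2, 1.0, 0.0),
         (-0.5, -1.0, 0.5), (-1.2, -1.0, 1.0)],
    )
    def test_clipping(self, delta, tau, expected):
        assert mediation_weight(delta, tau) == pytest.approx(expected)

    def test_zero_tau_undefined(self):
        assert np.isnan(mediation_weight(0.3, 0.0))


def _triplet_frame(records):
    df = pd.DataFrame(records)
    df["alt_id"] = "a"
    df["degenerate"] = False
    return df


class TestAssignment:
    def test_lowest_fdr_wins(self):
        df = _triplet_frame([
            {"cis_gene": "A", "trans_gene": "T", "fdr": 0.01, "delta_tau": 0.2, "weight": 0.2},
            {"cis_gene": "B", "trans_gene": "T", "fdr": 0.20, "delta_tau": 0.9, "weight": 0.9},
        ])
        out = assign_mediators(df).table
        assert out.loc[0, "cis_gene"] == "A" and out.loc[0, "assigned"]

    def test_fdr_tie_broken_by_larger_effect_then_name(self):
        df = _triplet_frame([
            {"cis_gene": "B", "trans_gene": "T", "fdr": 0.01, "delta_tau": 0.3, "weight": 0.3},
            {"cis_gene": "A", "trans_gene": "T", "fdr": 0.01, "delta_tau": 0.5, "weight": 0.5},
            {"cis_gene": "C", "trans_gene": "U", "fdr": 0.01, "delta_tau": 0.5, "weight": 0.5},
            {"cis_gene": "D", "trans_gene": "U", "fdr": 0.01, "delta_tau": 0.5, "weight": 0.5},
        ])
        out = assign_mediators(df).table.set_index("trans_gene")
        assert out.loc["T", "cis_gene"] == "A"   # larger |delta_tau|
        assert out.loc["U", "cis_gene"] == "C"   # lexicographic
        # each trans gene assigned to at most one cis gene
        assert out.index.is_unique

    def test_above_cutoff_unassigned(self):
        df = _triplet_frame([
            {"cis_gene": "A", "trans_gene": "T", "fdr": 0.30, "delta_tau": 0.9, "weight": 0.9},
        ])
        out = assign_mediators(df, assign_fdr_max=0.25).table
        assert not out.loc[0, "assigned"]


class TestWftm:
    def test_worked_example(self):
        df = _triplet_frame([
            {"cis_gene": "A", "trans_gene": "T1", "fdr": 0.01, "delta_tau": 0.5, "weight": 0.5},
            {"cis_gene": "A", "trans_gene": "T2", "fdr": 0.01, "delta_tau": 1.0, "weight": 1.0},
        ])
        ranking = compute_wftm(assign_mediators(df), ["A", "B"], m=4)
        assert ranking.wftm("A") == pytest.approx(0.375)
        assert ranking.wftm("B") == 0.0
        assert ranking.rank1_gene == "A"

    def test_single_dominant_gene_reaches_one(self):
        records = [
            {"cis_gene": "A", "trans_gene": f"T{i}", "fdr": 0.001,
             "delta_tau": 1.0, "weight": 1.0}
            for i in range(4)
        ]
        ranking = compute_wftm(assign_mediators(_triplet_frame(records)), ["A"], m=4)
        assert ranking.wftm("A") == pytest.approx(1.0)

    @given(seed=st.integers(0, 5000))
    @settings(derandomize=True, max_examples=60)
    def test_sum_bounded_and_matches_recount(self, seed):
        rng = np.random.default_rng(seed)
        n_cis, n_trans = rng.integers(1, 5), rng.integers(1, 8)
        records = []
        for j in range(n_trans):
            for i in range(n_cis):
                records.append({
                    "cis_gene": f"c{i}", "trans_gene": f"t{j}",
                    "fdr": float(rng.uniform()), "delta_tau": float(rng.normal()),
                    "weight": float(rng.uniform()),
                })
        assignment = assign_mediators(_triplet_frame(records))
        ranking = compute_wftm(assignment, [f"c{i}" for i in range(n_cis)], m=n_trans)
        total = ranking.table["wftm"].sum()
        manual = assignment.assigned["weight"].sum() / n_trans
        assert total == pytest.approx(manual)
        assert total <= 1.0 + 1e-12
        assert ((ranking.table["wftm"] >= 0) & (ranking.table["wftm"] <= 1)).all()


class TestRunMediation:
    def test_single_cis_gene_is_rank1(self, rng):
        n = 60
        samples = [f"s{i}" for i in range(n)]
        status = np.array([0] * 30 + [1] * 30, dtype=np.int8)
        cis = 1.0 * status + rng.normal(0, 0.4, n)
        rows = {"C": cis, "T": 0.8 * cis + rng.normal(0, 0.4, n)}
        expr = _expr(rows, samples)
        alt = Alteration("a", AMPLIFICATION, status, frozenset({"C"}))
        out = run_mediation(expr, alt, ["C"], ["T"])
        assert out.ranking.rank1_gene == "C"
        assert out.ranking.table["n_trans_mediated"].iloc[0] == 1

    def test_trans_restrict_shrinks_denominator(self, rng):
        n = 80
        samples = [f"s{i}" for i in range(n)]
        status = np.array([0] * 40 + [1] * 40, dtype=np.int8)
        cis = 1.0 * status + rng.normal(0, 0.4, n)
        rows = {"C": cis}
        trans_genes = [f"T{i}" for i in range(6)]
        for g in trans_genes:
            rows[g] = 0.8 * cis + rng.normal(0, 0.4, n)
        expr = _expr(rows, samples)
        alt = Alteration("a", AMPLIFICATION, status, frozenset({"C"}))
        full = run_mediation(expr, alt, ["C"], trans_genes)
        restricted = run_mediation(expr, alt, ["C"], trans_genes,
                                   trans_restrict={"T0", "T1", "T2"})
        assert full.ranking.m == 6
        assert restricted.ranking.m == 3
        assert len(restricted.triplets) == 3

    def test_empty_inputs_warn_without_ranking(self, rng):
        expr = _expr({"C": rng.normal(size=6)}, [f"s{i}" for i in range(6)])
        alt = Alteration("a", AMPLIFICATION, np.array([0, 0, 0, 1, 1, 1]), frozenset({"C"}))
        with pytest.warns(UserWarning):
            out = run_mediation(expr, alt, ["C"], [])
        assert out.ranking is None

    def test_planted_driver_beats_decoys(self, study, study_result):
        """End-to-end: the planted driver is Rank-1 in every alteration."""
        for alt_id, info in study.truth["alterations"].items():
            res = study_result.per_alteration[alt_id]
            assert res.mediation.ranking.rank1_gene == info["drivers"][0]


def test_sobel_conservative_under_true_negatives():
    """Fraction of null triplets with p < 0.05 stays below 0.05 + 2 SE."""
    from cistrans.simulation import SimulationConfig, evaluate_sobel

    cfg = SimulationConfig(n=200, reps_pos=1, reps_neg=1000, seed=3)
    perf = evaluate_sobel(cfg)
    limit = 0.05 + 2 * np.sqrt(0.05 * 0.95 / 1000)
    assert 1.0 - perf.specificity <= limit
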