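"""Pulldown preprocessing, imputation, S0 t-test, and iBAQ stoichiometry."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from utxsplice.interactome import (
    PulldownMatrix,
    impute,
    load_complex_annotation,
    load_pulldown_tsv,
    preprocess,
    s0_ttest,
    stoichiometry,
    write_pulldown_tsv,
)
from utxsplice.synthetic_data import MissingLogic, simulate_pulldown

GROUPS = {"GFP": ["GFP_1", "GFP_2", "GFP_3"],
          "control": ["control_1", "control_2", "control_3"]}
COLS = GROUPS["GFP"] + GROUPS["control"]


def _matrix(lfq_rows: dict, flags: dict | None = None) -> PulldownMatrix:
    lfq = pd.DataFrame.from_dict(lfq_rows, orient="index", columns=COLS)
    flags_df = pd.DataFrame(
        {
            "is_contaminant": [flags.get(p, "")[0:1] == "c" if flags else False
                               for p in lfq.index],
            "is_reverse": [flags.get(p, "") == "rev" if flags else False
                           for p in lfq.index],
            "n_replicates_identified": lfq.notna().sum(axis=1),
        },
        index=lfq.index,
    )
    return PulldownMatrix(lfq=lfq, ibaq=lfq.copy(), flags=flags_df, groups=GROUPS)


class TestPreprocess:
    def test_flagged_and_single_replicate_rows_removed(self):
        m = _matrix(
            {
                "ok": [1024.0] * 6,
                "rev": [1024.0] * 6,
                "cont": [1024.0] * 6,
                "single": [1024.0] + [np.nan] * 5,
            },
            flags={"rev": "rev", "cont": "cont"},
        )
        out = preprocess(m)
        assert list(out.proteins) == ["ok"]

    def test_lfq_log2_transformed(self):
        m = _matrix({"p": [1024.0] * 6})
        out = preprocess(m)
        assert (out.lfq.loc["p"] == 10.0).all()
        assert out.log2_scale

    def test_filter_order_invariance(self):
        """Applying the three row filters sequentially in any order matches
        the one-shot preprocessing result."""
        rng = np.random.default_rng(0)
        lfq = pd.DataFrame(rng.uniform(100, 2000, (30, 6)), columns=COLS,
                           index=[f"p{i}" for i in range(30)])
        lfq.iloc[::7, 1:] = np.nan  # some single-replicate rows
        flags = pd.DataFrame(
            {
                "is_contaminant": rng.random(30) < 0.2,
                "is_reverse": rng.random(30) < 0.2,
                "n_replicates_identified": lfq.notna().sum(axis=1),
            },
            index=lfq.index,
        )
        m = PulldownMatrix(lfq=lfq, ibaq=lfq.copy(), flags=flags, groups=GROUPS)
        expected = set(preprocess(m).proteins)
        filters = {
            "contaminant": ~flags["is_contaminant"],
            "reverse": ~flags["is_reverse"],
            "replicates": flags["n_replicates_identified"] >= 2,
        }
        import itertools

        for order in itertools.permutations(filters):
            keep = pd.Series(True, index=lfq.index)
            for name in order:
                keep &= filters[name]
            assert set(lfq.index[keep]) == expected

    def test_group_with_one_replicate_rejected(self):
        lfq = pd.DataFrame([[1.0, 2.0]], columns=["a", "b"], index=["p"])
        flags = pd.DataFrame({"is_contaminant": [False], "is_reverse": [False],
                              "n_replicates_identified": [2]}, index=["p"])
        m = PulldownMatrix(lfq=lfq, ibaq=lfq.copy(), flags=flags,
                           groups={"GFP": ["a"], "control": ["b"]})
        with pytest.raises(ValueError, match="fewer than 2 replicates"):
            preprocess(m)


class TestImpute:
    def _log2_matrix(self, values: np.ndarray) -> PulldownMatrix:
        lfq = pd.DataFrame(values, columns=COLS[: values.shape[1]],
                           index=[f"p{i}" for i in range(len(values))])
        flags = pd.DataFrame({"is_contaminant": False, "is_reverse": False,
                              "n_replicates_identified": lfq.notna().sum(axis=1)},
                             index=lfq.index)
        groups = {"GFP": list(lfq.columns[:1]), "control": list(lfq.columns[1:2])} \
            if values.shape[1] == 2 else GROUPS
        return PulldownMatrix(lfq=lfq, ibaq=lfq.copy(), flags=flags, groups=groups,
                              log2_scale=True)

    def test_complete_matrix_unchanged(self):
        m = self._log2_matrix(np.full((5, 6), 20.0))
        out = impute(m, seed=0)
        assert out.lfq.equals(m.lfq)

    def test_downshifted_gaussian_moments(self):
        """Observed mean 25, sd 2 -> imputed cells ~ N(21.4, 0.6^2) within 2%."""
        rng = np.random.default_rng(1)
        observed = rng.normal(25, 2, 5000)
        observed = (observed - observed.mean()) / observed.std(ddof=1) * 2 + 25
        col = np.concatenate([observed, np.full(10_000, np.nan)])
        values = np.column_stack([col, np.full(col.size, 20.0)])
        out = impute(self._log2_matrix(values), width=0.3, shift=1.8, seed=2)
        imputed = out.lfq.iloc[5000:, 0]
        assert imputed.mean() == pytest.approx(25 - 1.8 * 2, rel=0.02)
        assert imputed.std(ddof=1) == pytest.approx(0.3 * 2, rel=0.02)

    def test_same_seed_identical(self):
        col = np.array([20.0, 21.0, np.nan, 19.0, np.nan])
        values = np.column_stack([col, np.full(5, 20.0)])
        a = impute(self._log2_matrix(values), seed=7).lfq
        b = impute(self._log2_matrix(values), seed=7).lfq
        assert a.equals(b)

    def test_fully_missing_column_rejected(self):
        values = np.column_stack([np.full(4, np.nan), np.full(4, 20.0)])
        with pytest.raises(ValueError, match="fully missing"):
            impute(self._log2_matrix(values), seed=0)


class TestS0TTest:
    def test_s0_zero_equals_classical_t(self):
        """With s0=0 the statistic is the pooled-variance two-sample t."""
        a = [24.1, 25.3, 24.8]
        b = [20.2, 21.1, 20.7]
        lfq = pd.DataFrame([a + b], columns=COLS, index=["p"])
        flags = pd.DataFrame({"is_contaminant": [False], "is_reverse": [False],
                              "n_replicates_identified": [6]}, index=["p"])
        m = PulldownMatrix(lfq=lfq, ibaq=lfq.copy(), flags=flags, groups=GROUPS,
                           log2_scale=True)
        out = s0_ttest(m, s0=0.0, seed=0)
        expected = stats.ttest_ind(a, b, equal_var=True)
        assert out.loc["p", "statistic"] == pytest.approx(expected.statistic)
        assert out.loc["p", "p_value"] == pytest.approx(expected.pvalue)

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(2)
        half = rng.normal(25, 1, (200, 3))
        lfq = pd.DataFrame(np.hstack([half, half]), columns=COLS,
                           index=[f"p{i}" for i in range(200)])
        flags = pd.DataFrame({"is_contaminant": False, "is_reverse": False,
                              "n_replicates_identified": 6}, index=lfq.index)
        m = PulldownMatrix(lfq=lfq, ibaq=lfq.copy(), flags=flags, groups=GROUPS,
                           log2_scale=True)
        out = s0_ttest(m, seed=2)
        assert not out["significant"].any()

    def test_planted_enrichments_recovered(self):
        """20 planted 5-log2 enrichments among 1,000 nulls: >=19 recovered,
        <=1% of nulls called at q=0.01."""
        planted = {f"P{i}": (5.0, 0.5) for i in range(20)}
        matrix, truth = simulate_pulldown(n_background=1000, planted=planted,
                                          missing_logic=MissingLogic(), seed=5)
        m = impute(preprocess(matrix), seed=5)
        out = s0_ttest(m, seed=5)
        called = set(out.index[out["significant"]])
        planted_set = set(truth.loc[truth["planted"], "protein"])
        assert len(called & planted_set) >= 19
        assert len(called - planted_set) <= 10

    def test_significant_shares_sign_with_difference(self):
        planted = {"UP": (4.0, 0.5)}
        matrix, _ = simulate_pulldown(n_background=300, planted=planted, seed=6)
        out = s0_ttest(impute(preprocess(matrix), seed=6), seed=6)
        sig = out[out["significant"]]
        assert (np.sign(sig["statistic"]) == np.sign(sig["difference"])).all()

    def test_isoform_lacking_complex_interactions(self):
        """Planting only MLL3/MLL4 enrichment (MiDAC/PR-DUB left at baseline,
        as for the double-skip isoform) yields MLL subunits significant and
        no MiDAC/PR-DUB subunit significant."""
        ann = load_complex_annotation()
        mll = ann.loc[ann["complex"] == "MLL3/MLL4", "protein"]
        others = ann.loc[ann["complex"] != "MLL3/MLL4", "protein"]
        planted = {p: (5.0, 0.5) for p in mll}
        matrix, _ = simulate_pulldown(n_background=500, planted=planted, seed=7)
        # MiDAC/PR-DUB members present but unenriched (background behaviour)
        out = s0_ttest(impute(preprocess(matrix), seed=7), seed=7)
        called = set(out.index[out["significant"]])
        assert set(mll) <= called
        assert not (set(others) & called)


class TestStoichiometry:
    def _ibaq_matrix(self) -> PulldownMatrix:
        ibaq = pd.DataFrame(
            {
                "GFP_1": [620.0, 300.0, 25.0],
                "GFP_2": [620.0, 320.0, 15.0],
                "GFP_3": [620.0, 340.0, 20.0],
                "control_1": [20.0, 20.0, 20.0],
                "control_2": [20.0, 20.0, 20.0],
                "control_3": [20.0, 20.0, 20.0],
            },
            index=["PAXIP1", "PARTNER", "FLAT"],
        )
        flags = pd.DataFrame({"is_contaminant": False, "is_reverse": False,
                              "n_replicates_identified": 6}, index=ibaq.index)
        return PulldownMatrix(lfq=ibaq.copy(), ibaq=ibaq, flags=flags, groups=GROUPS)

    def test_anchor_is_one_and_hand_arithmetic(self):
        out = stoichiometry(self._ibaq_matrix())
        assert out.loc["PAXIP1", "ratio"] == 1.0
        # PARTNER: control-subtracted reps (280, 300, 320) mean 300; anchor 600
        assert out.loc["PARTNER", "ratio"] == pytest.approx(0.5)

    def test_protein_at_control_level_is_zero(self):
        out = stoichiometry(self._ibaq_matrix())
        assert out.loc["FLAT", "ratio"] == pytest.approx(0.0)

    def test_scale_invariance(self):
        m = self._ibaq_matrix()
        scaled = PulldownMatrix(lfq=m.lfq, ibaq=m.ibaq * 1e6, flags=m.flags,
                                groups=m.groups)
        assert np.allclose(stoichiometry(m)["ratio"], stoichiometry(scaled)["ratio"])

    def test_missing_anchor_rejected(self):
        m = self._ibaq_matrix()
        with pytest.raises(ValueError, match="anchor"):
            stoichiometry(m, anchor="ABSENT")


def test_maxquant_tsv_roundtrip(tmp_path):
    matrix, _ = simulate_pulldown(n_background=10, planted={"PAXIP1": (5.0, 1.0)},
                                  seed=8)
    path = tmp_path / "proteinGroups.txt"
    write_pulldown_tsv(matrix, path)
    back = load_pulldown_tsv(path)
    assert set(back.proteins) == set(matrix.proteins)
    assert np.allclose(back.lfq.loc[matrix.proteins, matrix.lfq.columns].fillna(0),
                       matrix.lfq.fillna(0))
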