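import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from scipy import stats

from sirenet.expression import (
    InsufficientReplicationError,
    QCThresholds,
    call_degs,
    differential_expression,
    discretize_measurements,
    normalize_log,
    qc_filter,
    wilcoxon_two_group,
)


def make_adata(x, conditions=None, cell_types=None, genes=None):
    x = np.asarray(x, dtype=float)
    n_cells, n_genes = x.shape
    obs = pd.DataFrame(
        {
            "condition": conditions or ["CTL"] * n_cells,
            "cell_type": cell_types or ["T"] * n_cells,
        },
        index=[f"c{i}" for i in range(n_cells)],
    )
    var = pd.DataFrame(index=genes or [f"g{i}" for i in range(n_genes)])
    return AnnData(X=x, obs=obs, var=var)


class TestQCFilter:
    def test_gene_count_boundary_at_500(self):
        x = np.zeros((2, 600))
        x[0, :499] = 1.0  # 499 genes -> removed
        x[1, :500] = 1.0  # 500 genes -> kept
        out = qc_filter(make_adata(x))
        assert list(out.obs_names) == ["c1"]

    def test_flagged_fraction_bound(self):
        # 6% of UMIs from the flagged gene -> removed; 4% -> kept
        x = np.zeros((2, 600))
        x[0, :600] = 1.0
        x[0, 0] = 36.7  # 36.7 / (36.7 + 599) ~ 0.0577
        x[1, :600] = 1.0
        x[1, 0] = 25.0  # 25 / 624 ~ 0.040
        out = qc_filter(make_adata(x), flagged_genes={"g0"})
        assert list(out.obs_names) == ["c1"]

    def test_permissive_thresholds_are_identity(self):
        x = np.array([[1.0, 0.0], [0.0, 0.0]])
        out = qc_filter(make_adata(x), QCThresholds(min_genes=0, max_flagged_fraction=1.0))
        assert out.shape == (2, 2)

    def test_unknown_flagged_gene_rejected(self):
        with pytest.raises(KeyError):
            qc_filter(make_adata(np.ones((1, 2))), flagged_genes={"nope"})


class TestNormalizeLog:
    def test_single_gene_count_nine(self):
        adata = make_adata([[9.0]])
        out = normalize_log(adata, scale=9.0)  # scale equal to the cell total
        assert out.X[0, 0] == pytest.approx(np.log(10.0))

    def test_all_zero_cell_stays_zero(self):
        out = normalize_log(make_adata([[0.0, 0.0]]), scale=1e4)
        assert np.all(out.X == 0)

    def test_proportional_cells_normalize_identically(self):
        adata = make_adata([[2.0, 4.0, 6.0], [10.0, 20.0, 30.0]])
        out = normalize_log(adata)
        np.testing.assert_allclose(out.X[0], out.X[1])


class TestDifferentialExpression:
    def test_identical_groups_zero_log2fc(self):
        x = np.tile([1.0, 2.0], (8, 1))
        adata = make_adata(x, conditions=["CTL"] * 4 + ["CASE"] * 4)
        res = differential_expression(adata, "T")
        assert np.allclose(res["log2fc"], 0.0)

    def test_constant_unit_shift_is_significant(self):
        x = np.array([[1.0]] * 4 + [[2.0]] * 4)
        adata = make_adata(x, conditions=["CTL"] * 4 + ["CASE"] * 4)
        res = differential_expression(adata, "T")
        assert res["log2fc"][0] == pytest.approx(1.0)
        assert res["p_value"][0] < 1e-6

    def test_matches_scipy_welch_on_nondegenerate_gene(self):
        rng = np.random.default_rng(0)
        case, ctl = rng.normal(1.0, 1.0, 20), rng.normal(0.0, 1.0, 25)
        x = np.concatenate([case, ctl])[:, None]
        adata = make_adata(x, conditions=["CASE"] * 20 + ["CTL"] * 25)
        res = differential_expression(adata, "T")
        ref = stats.ttest_ind(case, ctl, equal_var=False)
        assert res["p_value"][0] == pytest.approx(ref.pvalue, rel=1e-6)
        assert res["log2fc"][0] == pytest.approx(case.mean() - ctl.mean())

    def test_insufficient_replication_names_cell_type(self):
        adata = make_adata(np.ones((3, 1)), conditions=["CTL", "CTL", "CASE"])
        with pytest.raises(InsufficientReplicationError, match="'T'"):
            differential_expression(adata, "T")


class TestCallDegs:
    @pytest.mark.parametrize(
        "log2fc,p,expected",
        [
            (0.5, 0.01, 1),
            (0.30, 0.01, 0),  # strict inequality at the FC threshold
            (-0.4, 0.2, 0),
            (-0.4, 0.01, -1),
            (0.5, 0.05, 0),  # strict inequality at the p threshold
        ],
    )
    def test_threshold_rules(self, log2fc, p, expected):
        records = pd.DataFrame({"gene": ["g"], "log2fc": [log2fc], "p_value": [p]})
        assert call_degs(records)["direction"][0] == expected

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(1)
        records = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(200)],
                "log2fc": rng.normal(0, 0.5, 200),
                "p_value": rng.uniform(0, 1, 200),
            }
        )
        strict = set(records["gene"][call_degs(records, 0.3, 0.05)["direction"] != 0])
        loose = set(records["gene"][call_degs(records, 0.2, 0.10)["direction"] != 0])
        assert strict <= loose

    def test_bh_correction_never_adds_degs(self):
        rng = np.random.default_rng(2)
        records = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(100)],
                "log2fc": rng.normal(0, 1, 100),
                "p_value": rng.uniform(0, 1, 100),
            }
        )
        raw = set(records["gene"][call_degs(records)["direction"] != 0])
        bh = set(records["gene"][call_degs(records, correct="bh")["direction"] != 0])
        assert bh <= raw


class TestDiscretize:
    def test_single_deg_on_core_network(self, core_net):
        degs = pd.DataFrame({"gene": ["EIF4E"], "direction": [1]})
        m = discretize_measurements(degs, core_net.nodes)
        assert m["EIF4E"] == 1
        assert all(v == 0 for k, v in m.items() if k != "EIF4E")

    def test_empty_deg_list_all_zero(self, core_net):
        m = discretize_measurements(
            pd.DataFrame({"gene": [], "direction": []}), core_net.nodes
        )
        assert set(m.values()) == {0}

    def test_off_network_gene_ignored(self, core_net):
        degs = pd.DataFrame({"gene": ["NOTAGENE"], "direction": [1]})
        m = discretize_measurements(degs, core_net.nodes)
        assert "NOTAGENE" not in m and set(m.values()) == {0}

    def test_nonzero_count_matches_network_degs(self, core_net):
        degs = pd.DataFrame(
            {"gene": ["EIF4E", "MTOR", "XYZ"], "direction": [1, -1, 1]}
        )
        m = discretize_measurements(degs, core_net.nodes)
        assert sum(v != 0 for v in m.values()) == 2
        assert set(m.values()) <= {-1, 0, 1}


class TestWilcoxon:
    def test_identical_multisets(self):
        assert wilcoxon_two_group([1, 2, 2, 3], [3, 2, 2, 1]) == 1.0

    def test_fully_separated_groups(self):
        # exact enumeration: only 2 of C(20,10) rank splits are this extreme
        p = wilcoxon_two_group(range(1, 11), range(11, 21))
        assert p == pytest.approx(2 / 184756, rel=1e-6)

    def test_single_swap_from_identical_is_near_one(self):
        a, b = [1, 2, 3, 4, 5], [1, 2, 3, 4, 6]
        assert wilcoxon_two_group(a, b) > 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_two_group([], [1.0])
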