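import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ileumatlas import classify_signatures as cs
from ileumatlas import embed_cluster as ec


def _brute_force_classify(features_row: dict, rules: cs.RuleSet) -> str:
    """Independent per-cell evaluation with plain Python eval."""
    for label, expr in rules.steps:
        if bool(eval(expr, {"__builtins__": {}}, dict(features_row))):  # noqa: S307
            return label
    return rules.fallback


RULESET_FEATURES = {
    "cd4": ["m2", "m3", "t1", "t2", "t3"],
    "gd_cd8": ["cluster", "m1", "m3", "t1", "t2", "t3"],
    "ilc": ["cluster", "m2", "t2", "t3"],
    "b": ["cluster", "m3", "t2"],
}


class TestRuleSets:
    @pytest.mark.parametrize("name", ["cd4", "gd_cd8", "ilc", "b"])
    def test_matches_brute_force_on_random_features(self, name):
        rules = cs.RuleSet.builtin(name)
        rng = np.random.default_rng(hash(name) % 2**31)
        cols = RULESET_FEATURES[name]
        n = 2500
        feats = pd.DataFrame(rng.random((n, len(cols))), columns=cols)
        if "cluster" in cols:
            feats["cluster"] = rng.integers(0, 60, n)
        got = cs.classify_cells(feats, rules)
        for i in range(n):
            assert got.iloc[i] == _brute_force_classify(feats.iloc[i].to_dict(), rules)

    @pytest.mark.parametrize(
        "name,row,expected",
        [
            ("cd4", {"m2": 0.05, "t3": 0.45, "m3": 0, "t1": 0, "t2": 0}, "cycling"),
            ("cd4", {"m2": 0.0, "t3": 0.1, "m3": 0.10, "t2": 0.30, "t1": 0.20}, "follicular"),
            ("cd4", {"m2": 0.1, "t3": 0.4, "m3": 0.3, "t2": 0.2, "t1": 0.2}, "activated"),
            ("gd_cd8", {"cluster": 31, "m1": 0, "m3": 0, "t1": 0, "t2": 0, "t3": 0}, "cd2neg_gd"),
            ("gd_cd8", {"cluster": 51, "m1": 0, "m3": 0, "t1": 0, "t2": 0, "t3": 0}, "sellhi_gd"),
            ("gd_cd8", {"cluster": 1, "m1": 0.10, "m3": 0, "t1": 0.40, "t2": 0.05, "t3": 0}, "activated"),
            ("gd_cd8", {"cluster": 1, "m1": 0.25, "m3": 0, "t1": 0.39, "t2": 0.10, "t3": 0}, "cytotoxic"),
            # boundary: m3 = 0.11 and t3 = 0.41 both fail the strict >
            ("gd_cd8", {"cluster": 1, "m1": 0, "m3": 0.11, "t1": 0.3, "t2": 0.29, "t3": 0.41}, "cytotoxic"),
            ("ilc", {"cluster": 43, "m2": 0, "t2": 0, "t3": 0.9}, "group3"),
            ("ilc", {"cluster": 53, "m2": 0, "t2": 0, "t3": 0}, "cycling_group1"),
            ("ilc", {"cluster": 1, "m2": 0.5, "t2": 0, "t3": 0.04}, "activated_group1"),
            ("ilc", {"cluster": 1, "m2": 0.4, "t2": 0.9, "t3": 0.04}, "cytotoxic_group1"),
            ("ilc", {"cluster": 1, "m2": 0.5, "t2": 0, "t3": 0.05}, "cytotoxic_group1"),
            ("b", {"cluster": 30, "m3": 0, "t2": 0}, "resting"),
            ("b", {"cluster": 33, "m3": 0, "t2": 0}, "transitioning"),
            ("b", {"cluster": 25, "m3": 0, "t2": 0}, "asc"),
            ("b", {"cluster": 99, "m3": 0.06, "t2": 0.32}, "activated"),
            ("b", {"cluster": 99, "m3": 0.061, "t2": 0}, "cycling"),
        ],
    )
    def test_caption_rules_and_boundaries(self, name, row, expected):
        rules = cs.RuleSet.builtin(name)
        feats = pd.DataFrame([row])
        assert cs.classify_cells(feats, rules).iloc[0] == expected

    def test_every_cell_gets_exactly_one_label(self):
        rules = cs.RuleSet.builtin("cd4")
        rng = np.random.default_rng(0)
        feats = pd.DataFrame(
            rng.random((500, 5)), columns=["m2", "m3", "t1", "t2", "t3"]
        )
        labels = cs.classify_cells(feats, rules)
        assert len(labels) == 500
        assert labels.notna().all()

    def test_missing_feature_named(self):
        rules = cs.RuleSet.builtin("cd4")
        with pytest.raises(KeyError, match="t3"):
            cs.classify_cells(pd.DataFrame({"m2": [0.1]}), rules)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text(
            "name: custom\nsteps:\n  - label: hi\n    when: 'x > 0.5 and y < 0.2'\nfallback: lo\n"
        )
        rules = cs.RuleSet.from_yaml(path)
        feats = pd.DataFrame({"x": [0.9, 0.1], "y": [0.1, 0.1]})
        assert cs.classify_cells(feats, rules).tolist() == ["hi", "lo"]


class TestRatioClassify:
    def _norm(self, trdc, cd8b):
        x = np.array([[trdc, cd8b]])
        a = ad.AnnData(X=sp.csr_matrix(x))
        a.var_names = ["TRDC", "CD8B"]
        return a

    @pytest.mark.parametrize(
        "trdc,cd8b,expected",
        [
            (1.2, 0.3, "gd T"),
            (0.3, 1.2, "CD8 ab T"),
            (0.5, 0.5, "CD8 ab T"),  # ratio exactly 1: strict >
            (0.0, 0.0, "CD8 ab T"),  # 0/0
            (0.7, 0.0, "gd T"),  # x/0
        ],
    )
    def test_ratio_rule(self, trdc, cd8b, expected):
        got = cs.ratio_classify(self._norm(trdc, cd8b), "TRDC", "CD8B")
        assert got.iloc[0] == expected

    def test_missing_gene_rejected(self):
        with pytest.raises(KeyError, match="ABSENT"):
            cs.ratio_classify(self._norm(1, 1), "ABSENT", "CD8B")


class TestDeriveSignature:
    def _dataset(self, pct_t, pct_n, mean_t, mean_n, n=200):
        """One gene, two subsets with controlled detection and means."""
        x = np.zeros((2 * n, 1))
        k_t = int(round(pct_t * n))
        k_n = int(round(pct_n * n))
        if k_t:
            x[:k_t, 0] = mean_t * n / k_t
        if k_n:
            x[n : n + k_n, 0] = mean_n * n / k_n
        a = ad.AnnData(X=sp.csr_matrix(x))
        a.var_names = ["g"]
        labels = np.array(["T"] * n + ["N"] * n)
        return a, labels

    def _spec(self):
        return cs.SignatureSpec(
            candidate_genes=["g"], target_subsets=["T"], nontarget_subsets=["N"]
        )

    @pytest.mark.parametrize(
        "pct_t,pct_n,mean_t,mean_n,kept,branch",
        [
            (0.40, 0.15, 1.0, 1.0, True, 1),  # 2x detection fold
            (0.25, 0.15, 1.0, 0.4, True, 2),  # between 1x and 2x but 2x mean
            (0.25, 0.20, 0.5, 0.3, False, 0),  # neither branch
            (0.09, 0.01, 1.0, 0.1, False, 1),  # below the 10% floor
        ],
    )
    def test_branches(self, pct_t, pct_n, mean_t, mean_n, kept, branch):
        a, labels = self._dataset(pct_t, pct_n, mean_t, mean_n)
        sig, ev = cs.derive_signature(a, labels, self._spec())
        assert (len(sig) == 1) == kept
        assert ev["branch"].iloc[0] == branch

    def test_monotone_in_fold_parameters(self, two_tissue):
        _, a, b, ta, tb = two_tissue
        merged = ad.concat([a, b], merge="same")
        norm = ec.lognormalize(merged)
        labels = pd.concat([ta, tb]).apply(
            lambda r: f"{r.tissue_id}_{r.true_type}", axis=1
        ).to_numpy()
        candidates = list(a.var_names[:80])
        base = dict(
            candidate_genes=candidates,
            target_subsets=["ileum_ILC"],
            nontarget_subsets=["pbmc_ILC", "ileum_CD4_T"],
        )
        sig_loose, _ = cs.derive_signature(
            norm, labels, cs.SignatureSpec(**base, fold_pct=1.5, fold_expr=1.5)
        )
        sig_default, _ = cs.derive_signature(norm, labels, cs.SignatureSpec(**base))
        sig_tight, _ = cs.derive_signature(
            norm, labels, cs.SignatureSpec(**base, fold_pct=3.0, fold_expr=3.0)
        )
        assert set(sig_tight) <= set(sig_default) <= set(sig_loose)

    def test_planted_markers_recovered_exactly(self, two_tissue):
        _, a, b, ta, tb = two_tissue
        merged = ad.concat([a, b], merge="same")
        norm = ec.lognormalize(merged)
        labels = pd.concat([ta, tb]).apply(
            lambda r: f"{r.tissue_id}_{r.true_type}", axis=1
        ).to_numpy()
        block = [g for g in a.var_names if a.var.loc[g, "program"] == "ILC@ileum"]
        distractors = [
            g for g in a.var_names if a.var.loc[g, "program"] in ("", "cycling")
        ][:30]
        spec = cs.SignatureSpec(
            candidate_genes=block + distractors,
            target_subsets=["ileum_ILC"],
            nontarget_subsets=["pbmc_ILC", "ileum_CD4_T", "ileum_B"],
        )
        sig, _ = cs.derive_signature(norm, labels, spec)
        assert set(sig) == set(block)  # precision = recall = 1

    def test_empty_subset_rejected(self):
        a, labels = self._dataset(0.5, 0.5, 1.0, 1.0)
        spec = cs.SignatureSpec(
            candidate_genes=["g"], target_subsets=["T"], nontarget_subsets=["missing"]
        )
        with pytest.raises(ValueError, match="no cells"):
            cs.derive_signature(a, labels, spec)

    def test_overlapping_subsets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            cs.SignatureSpec(
                candidate_genes=["g"], target_subsets=["A"], nontarget_subsets=["A"]
            )
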