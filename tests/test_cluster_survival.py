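"""RPMM clustering, class labelling, Cox and Kaplan–Meier contracts."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tandem5hmc.cluster_survival import (
    cox_fit,
    km_logrank,
    label_clusters,
    top_variable_loci,
)
from tandem5hmc.exceptions import ConfigurationError, DegenerateDataError
from tandem5hmc.rpmm import rpmm_cluster
from tandem5hmc.simulate import simulate_survival, simulate_truth, simulate_annotation

from conftest import props_from_5hmc, sample_frame, small_config


def two_class_betas(n_per_class=20, n_loci=200, mean_a=0.1, mean_b=0.5, noise=60.0, seed=0):
    """Beta matrices with two planted classes of well-separated means."""
    rng = np.random.default_rng(seed)
    mus = np.r_[np.full(n_per_class, mean_a), np.full(n_per_class, mean_b)]
    x = rng.beta(mus[:, None] * noise, (1 - mus[:, None]) * noise, size=(2 * n_per_class, n_loci))
    ids = [f"S{i:03d}" for i in range(2 * n_per_class)]
    truth = np.r_[np.zeros(n_per_class), np.ones(n_per_class)]
    return pd.DataFrame(x, index=ids, columns=[f"cg{j:05d}" for j in range(n_loci)]), truth


class TestTopVariable:
    def test_full_universe(self):
        props = props_from_5hmc(np.random.default_rng(0).uniform(0, 0.4, (30, 5)))
        got = top_variable_loci(props, props.sample_ids, 30)
        assert set(got) == set(props.locus_ids)

    def test_constant_loci_excluded(self):
        h = np.vstack([np.full((5, 4), 0.2), np.random.default_rng(1).uniform(0, 0.4, (5, 4))])
        props = props_from_5hmc(h)
        got = top_variable_loci(props, props.sample_ids, 5)
        assert all(l in set(props.locus_ids[5:]) for l in got)

    def test_matches_variance_sort_oracle(self):
        rng = np.random.default_rng(2)
        h = rng.uniform(0, 0.4, (60, 6))
        props = props_from_5hmc(h)
        got = top_variable_loci(props, props.sample_ids, 10)
        var = h.var(axis=1, ddof=1)
        oracle = set(np.array(props.locus_ids)[np.argsort(-var)[:10]])
        assert set(got) == oracle

    def test_n_exceeding_universe_rejected(self):
        props = props_from_5hmc(np.random.default_rng(3).uniform(0, 0.4, (10, 4)))
        with pytest.raises(ConfigurationError):
            top_variable_loci(props, props.sample_ids, 11)


class TestRPMM:
    def test_identical_rows_single_leaf(self):
        betas = pd.DataFrame(
            np.full((12, 50), 0.3),
            index=[f"S{i}" for i in range(12)],
        )
        tree = rpmm_cluster(betas)
        assert len(tree.leaves()) == 1

    def test_separated_classes_perfectly_recovered(self):
        betas, truth = two_class_betas(seed=4)
        tree = rpmm_cluster(betas)
        assert len(tree.leaves()) == 2
        assign = tree.assignments().reindex(betas.index)
        ari = adjusted_rand_score(truth, assign.astype("category").cat.codes)
        assert ari == 1.0

    def test_null_one_class_split_rejected(self):
        """Homogeneous beta data: the BIC criterion rejects the split in at
        least 95% of seeded replicates."""
        rejected = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            betas = pd.DataFrame(
                rng.beta(2.0, 10.0, size=(20, 30)),
                index=[f"S{i:02d}" for i in range(20)],
            )
            tree = rpmm_cluster(betas)
            rejected += len(tree.leaves()) == 1
        assert rejected >= 95

    def test_invariant_to_sample_and_locus_order(self):
        betas, _ = two_class_betas(seed=5)
        tree = rpmm_cluster(betas)
        rng = np.random.default_rng(6)
        shuffled = betas.iloc[
            rng.permutation(len(betas)), rng.permutation(betas.shape[1])
        ]
        tree2 = rpmm_cluster(shuffled)
        sets1 = sorted(frozenset(l.members) for l in tree.leaves() for _ in [0])
        sets2 = sorted(frozenset(l.members) for l in tree2.leaves() for _ in [0])
        assert sets1 == sets2

    def test_leaves_partition_samples(self):
        betas, _ = two_class_betas(n_per_class=15, seed=7)
        tree = rpmm_cluster(betas)
        members = [s for leaf in tree.leaves() for s in leaf.members]
        assert sorted(members) == sorted(betas.index)


class TestLabelClusters:
    def _props_for(self, betas):
        return props_from_5hmc(betas.to_numpy().T, locus_ids=betas.columns, sample_ids=betas.index)

    def test_higher_mean_leaf_labeled_high(self):
        betas, truth = two_class_betas(seed=8)
        tree = rpmm_cluster(betas)
        labels, diag = label_clusters(tree, self._props_for(betas))
        high_ids = labels.index[labels == "high5hmC"]
        assert set(high_ids) == set(betas.index[truth == 1])
        assert diag["kruskal_p"] < 0.01

    def test_single_leaf_errors(self):
        betas = pd.DataFrame(np.full((10, 40), 0.2), index=[f"S{i}" for i in range(10)])
        tree = rpmm_cluster(betas)
        with pytest.raises(DegenerateDataError, match="2 leaves"):
            label_clusters(tree, self._props_for(betas))

    def test_class_independent_of_subtype_fisher_nonsignificant(self):
        betas, truth = two_class_betas(seed=9)
        tree = rpmm_cluster(betas)
        props = self._props_for(betas)
        rng = np.random.default_rng(10)
        samples = sample_frame(
            ["tumor"] * len(betas),
            subtypes=list(rng.choice(["glioma", "ependymoma", "embryonal"], len(betas))),
            ids=list(betas.index),
        )
        _, diag = label_clusters(tree, props, samples)
        ps = [v["p_value"] for v in diag["fisher_cluster_vs_subtype"].values()]
        assert all(p > 0.001 for p in ps)


class TestCox:
    def test_four_subject_grid_search_oracle(self):
        times = [1.0, 2.0, 3.0, 4.0]
        x = [1, 0, 1, 0]
        samples = sample_frame(
            ["tumor"] * 4, times=times, events=[1, 1, 1, 1],
            ids=[f"P{i}" for i in range(4)],
        )
        labels = pd.Series(
            ["low5hmC" if xi else "high5hmC" for xi in x],
            index=samples.sample_ids,
        )
        fit = cox_fit(samples, outcome="death", covariates=("cluster",), cluster_labels=labels)

        def neg_log_partial(beta):
            ll = 0.0
            for i in range(4):
                risk = [j for j in range(4) if times[j] >= times[i]]
                ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
            return -ll

        grid = np.arange(-4, 4, 1e-4)
        beta_star = grid[np.argmin([neg_log_partial(b) for b in grid])]
        assert fit.summary.loc["cluster_low", "coef"] == pytest.approx(beta_star, abs=1e-3)

    def test_null_cluster_effect_within_3_se(self):
        cfg = small_config(
            n_tumor=300, hazard_ratio_low=1.0, baseline_hazard=0.1, seed=31
        )
        truth = simulate_truth(cfg, simulate_annotation(cfg))
        samples = simulate_survival(truth, cfg)
        fit = cox_fit(
            samples, outcome="death", covariates=("age", "sex", "cluster"),
            cluster_labels=truth.cluster_labels,
        )
        coef = fit.summary.loc["cluster_low", "coef"]
        se = fit.summary.loc["cluster_low", "se"]
        assert abs(coef) < 3 * se

    def test_zero_events_degenerate(self):
        cfg = small_config(censor_time=0.0)
        truth = simulate_truth(cfg, simulate_annotation(cfg))
        samples = simulate_survival(truth, cfg)
        with pytest.raises(DegenerateDataError, match="events"):
            cox_fit(samples, outcome="death", covariates=("cluster",),
                    cluster_labels=truth.cluster_labels)

    def test_missing_followup_dropped_and_logged(self, caplog):
        samples = sample_frame(
            ["tumor"] * 5,
            times=[1, 2, 3, 4, np.nan],
            events=[1, 1, 0, 1, np.nan],
            ids=[f"P{i}" for i in range(5)],
        )
        labels = pd.Series(
            ["low5hmC", "high5hmC", "low5hmC", "high5hmC", "low5hmC"],
            index=samples.sample_ids,
        )
        with caplog.at_level("WARNING"):
            fit = cox_fit(samples, outcome="death", covariates=("cluster",),
                          cluster_labels=labels)
        assert fit.dropped_ids == ["P4"]
        assert fit.n_subjects == 4

    def test_hr_exponentiates_coef_and_ci_brackets(self):
        cfg = small_config(n_tumor=120, hazard_ratio_low=3.0, baseline_hazard=0.1, seed=37)
        truth = simulate_truth(cfg, simulate_annotation(cfg))
        samples = simulate_survival(truth, cfg)
        fit = cox_fit(samples, outcome="death", covariates=("cluster",),
                      cluster_labels=truth.cluster_labels)
        row = fit.summary.loc["cluster_low"]
        assert row["hr"] == pytest.approx(np.exp(row["coef"]))
        assert row["ci_low"] < row["hr"] < row["ci_high"]
        assert 0.5 <= fit.concordance <= 1.0


class TestKM:
    def test_hand_product_limit(self):
        samples = sample_frame(
            ["tumor"] * 6,
            times=[1, 2, 3, 4, 5, 6],
            events=[1, 1, 0, 1, 0, 1],
            ids=[f"P{i}" for i in range(6)],
        )
        labels = pd.Series(["A"] * 6, index=samples.sample_ids)
        labels.iloc[0] = "B"  # a second group so the test is defined
        # hand product-limit for group A (subjects P1..P5):
        # t=2: 4/5; t=4: 4/5 * 2/3; t=6: 4/5 * 2/3 * 0
        curves, _, _ = km_logrank(samples, labels, outcome="death")
        sf = curves["A"].iloc[:, 0]
        assert sf.loc[2.0] == pytest.approx(4 / 5)
        assert sf.loc[4.0] == pytest.approx(4 / 5 * 2 / 3)
        assert sf.loc[6.0] == pytest.approx(0.0)

    def test_identical_groups_p_near_one(self):
        times = [1, 2, 3, 4] * 2
        events = [1, 0, 1, 1] * 2
        samples = sample_frame(["tumor"] * 8, times=times, events=events,
                               ids=[f"P{i}" for i in range(8)])
        labels = pd.Series(["A"] * 4 + ["B"] * 4, index=samples.sample_ids)
        _, stat, p = km_logrank(samples, labels, outcome="death")
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_complete_separation_extreme_statistic(self):
        times = [1, 2, 3, 4, 10, 11, 12, 13]
        events = [1] * 8
        samples = sample_frame(["tumor"] * 8, times=times, events=events,
                               ids=[f"P{i}" for i in range(8)])
        labels = pd.Series(["A"] * 4 + ["B"] * 4, index=samples.sample_ids)
        _, stat, p = km_logrank(samples, labels, outcome="death")
        assert p < 0.01

    def test_no_events_rejected(self):
        samples = sample_frame(["tumor"] * 4, times=[1, 2, 3, 4], events=[0, 0, 0, 0],
                               ids=[f"P{i}" for i in range(4)])
        labels = pd.Series(["A", "A", "B", "B"], index=samples.sample_ids)
        with pytest.raises(DegenerateDataError):
            km_logrank(samples, labels, outcome="death")
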