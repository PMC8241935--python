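"""Micro-tumor workflows: AUC, Mann-Whitney, PLSR/PLS-DA, elimination."""

import numpy as np
import pandas as pd
import pytest

import microtumor as mt

from .oracles import auc_bruteforce, mannwhitney_exact_enumeration


class TestAuc:
    def test_perfect_ranking(self):
        assert mt.auc([0.1, 0.2, 0.9, 0.8], [0, 0, 1, 1]) == 1.0

    def test_all_scores_tied(self):
        assert mt.auc([5.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            mt.auc([1.0, 2.0], [1, 1])

    def test_matches_bruteforce_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(6, 30)
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert mt.auc(scores, labels) == auc_bruteforce(scores, labels)


class TestMannWhitney:
    def test_worked_example_8_vs_6(self):
        """U = 7 at group sizes (8, 6): exact two-sided p = 2*44/3003."""
        # tie-free samples engineered to give U1 = 7 (x beats y in 7 cross pairs)
        x = [1, 2, 3, 4, 5, 6, 8.5, 14.5]
        y = [8, 9, 10, 11, 12, 13]
        u, p = mt.mann_whitney(x, y)
        assert u == 7
        assert p == pytest.approx(2 * 44 / 3003, rel=1e-12)
        assert round(p, 2) == 0.03

    def test_exact_matches_enumeration_small_sizes(self):
        rng = np.random.default_rng(3)
        for n1 in range(1, 7):
            for n2 in range(1, 13 - n1):
                if n1 + n2 > 12:
                    continue
                x = rng.permutation(np.arange(n1 + n2, dtype=float))[:n1]
                pool = set(range(n1 + n2)) - set(int(v) for v in x)
                y = np.array(sorted(pool), dtype=float)
                u_ref, p_ref = mannwhitney_exact_enumeration(x, y)
                u, p = mt.mann_whitney(x, y)
                assert u == u_ref
                assert p == pytest.approx(p_ref, rel=1e-12)

    def test_complete_separation_two_vs_two(self):
        u, p = mt.mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert u == 0
        assert p == pytest.approx(1 / 3, rel=1e-12)

    def test_identical_samples_p_one(self):
        u, p = mt.mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            mt.mann_whitney([], [1.0])


class TestPlsrWorkflow:
    def test_planted_truth_recovery(self, processed_cohort, fast_cfg):
        labelled, truth = processed_cohort
        report = mt.plsr_workflow(labelled, "CD8A", "immune_rich", fast_cfg)
        vt = report.vip_table
        for protein, sign in truth.coef_signs.items():
            assert vt.loc[protein, "vip"] > 1.0
            assert np.sign(vt.loc[protein, "coef"]) == sign

    def test_zero_y_rois_excluded(self, processed_cohort, fast_cfg):
        labelled, _ = processed_cohort
        ds = labelled.copy()
        rich = ds.roi_meta.index[ds.roi_meta["compartment"] == "immune_rich"]
        ds.matrix.loc[rich[0], "CD8A"] = 0.0
        report = mt.plsr_workflow(ds, "CD8A", "immune_rich", fast_cfg)
        assert rich[0] in report.excluded_rois
        assert rich[0] not in report.roi_ids

    def test_constant_nonzero_y_errors(self, processed_cohort, fast_cfg):
        labelled, _ = processed_cohort
        ds = labelled.copy()
        ds.matrix["CD8A"] = 0.5
        with pytest.raises(ValueError, match="zero variance"):
            mt.plsr_workflow(ds, "CD8A", "immune_rich", fast_cfg)

    def test_too_few_rois_errors(self, processed_cohort, fast_cfg):
        labelled, _ = processed_cohort
        small = labelled.subset_rois(labelled.matrix.index[:5])
        with pytest.raises(ValueError, match="usable ROIs"):
            mt.plsr_workflow(small, "CD8A", None, fast_cfg)

    def test_report_predict_reproduces_fitted_values(self, processed_cohort, fast_cfg):
        labelled, _ = processed_cohort
        report = mt.plsr_workflow(labelled, "CD8A", "immune_rich", fast_cfg)
        densities = labelled.matrix.loc[report.roi_ids]
        np.testing.assert_allclose(report.predict(densities), report.predicted, atol=1e-10)


class TestPlsdaWorkflow:
    def test_perfectly_separating_protein_gives_auc_one(self, fast_cfg):
        ds, labels, _ = mt.gen_response_cohort(
            mt.ResponseSimConfig(n_per_class=(10, 10), delta=0.0), seed=0
        )
        panel = mt.default_panel(mt.ResponseSimConfig(n_per_class=(10, 10)).base_config())
        dens = mt.process_counts(ds, panel)
        # overwrite one protein with a perfectly separating density
        dens.matrix["P01"] = np.where(labels == 1, 10.0, 0.1)
        report = mt.plsda_workflow(dens, labels, None, fast_cfg, features=["P01"])
        assert report.auc == 1.0

    def test_permuted_labels_auc_near_half(self, fast_cfg):
        ds, labels, _ = mt.gen_response_cohort(
            mt.ResponseSimConfig(n_per_class=(20, 20), delta=0.0), seed=1
        )
        panel = mt.default_panel(mt.ResponseSimConfig(n_per_class=(20, 20)).base_config())
        dens = mt.process_counts(ds, panel)
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(100):
            perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
            report = mt.plsda_workflow(dens, perm, None, fast_cfg)
            aucs.append(report.auc)
        # in-sample PLS-DA AUC on random labels is optimistic (> 0.5), but the
        # permutation-mean must sit well below a real signal
        assert 0.5 <= np.mean(aucs) < 0.95

    def test_single_class_errors(self, fast_cfg):
        ds, labels, _ = mt.gen_response_cohort(seed=0)
        panel = mt.default_panel(mt.ResponseSimConfig().base_config())
        dens = mt.process_counts(ds, panel)
        all_ones = pd.Series(1, index=labels.index)
        with pytest.raises(ValueError, match="both classes"):
            mt.plsda_workflow(dens, all_ones, None, fast_cfg)


class TestEliminateVariables:
    @pytest.fixture(scope="class")
    def cohort(self):
        ds, labels, truth = mt.gen_response_cohort(seed=3)
        panel = mt.default_panel(mt.ResponseSimConfig().base_config())
        return mt.process_counts(ds, panel), labels, truth

    def test_recovers_planted_discriminant_set(self, cohort, fast_cfg):
        dens, labels, truth = cohort
        trace = mt.eliminate_variables(dens, labels, fast_cfg)
        assert not trace.floor_unreachable
        assert set(truth.discriminant) <= set(trace.final_features)
        assert trace.final.auc > 0.90

    def test_subsets_strictly_decreasing(self, cohort, fast_cfg):
        dens, labels, _ = cohort
        trace = mt.eliminate_variables(dens, labels, fast_cfg)
        sizes = [len(s.features) for s in trace.steps]
        assert sizes == sorted(sizes, reverse=True)
        assert len(set(map(tuple, (s.features for s in trace.steps)))) == len(sizes)

    def test_removed_proteins_were_below_both_thresholds(self, cohort, fast_cfg):
        dens, labels, _ = cohort
        trace = mt.eliminate_variables(dens, labels, fast_cfg)
        for step in trace.steps:
            for protein in step.removed:
                assert step.vip[protein] < fast_cfg.vip_drop
                assert abs(step.coef[protein]) < fast_cfg.coef_drop

    def test_refit_on_final_subset_reproduces_final_model(self, cohort, fast_cfg):
        dens, labels, _ = cohort
        trace = mt.eliminate_variables(dens, labels, fast_cfg)
        refit = mt.plsda_workflow(
            dens, labels, None, fast_cfg, features=trace.final_features
        )
        assert refit.auc == pytest.approx(trace.final.auc, abs=1e-12)
        np.testing.assert_allclose(
            refit.vip_table["vip"], trace.final.vip_table["vip"], atol=1e-10
        )

    def test_nothing_removable_gives_single_step(self, cohort, fast_cfg):
        dens, labels, truth = cohort
        # restrict to the two planted discriminant proteins: both important
        trace_cfg = mt.RunConfig(n_perm=1000)
        sub = dens.copy()
        keep = truth.discriminant + ["CD8A"]
        sub.matrix = sub.matrix[keep + sub.control_columns]
        trace = mt.eliminate_variables(sub, labels, trace_cfg)
        if not trace.floor_unreachable:
            assert all(
                set(s.removed) == set() or s is not trace.steps[-1]
                for s in trace.steps
            )

    def test_null_labels_flag_floor_unreachable(self, fast_cfg):
        ds, labels, _ = mt.gen_response_cohort(
            mt.ResponseSimConfig(delta=0.0), seed=11
        )
        panel = mt.default_panel(mt.ResponseSimConfig().base_config())
        dens = mt.process_counts(ds, panel)
        trace = mt.eliminate_variables(dens, labels, fast_cfg)
        assert trace.floor_unreachable
        assert trace.final.auc <= fast_cfg.auc_floor


class TestVolcano:
    @pytest.fixture
    def density_with_groups(self):
        ds, _ = mt.gen_roi_counts(
            mt.RoiSimConfig(n_roi=32, n_tissues=16, max_rois_per_tissue=2), seed=5
        )
        panel = mt.default_panel(mt.RoiSimConfig())
        dens = mt.process_counts(ds, panel)
        labels = pd.Series("immune_rich", index=dens.matrix.index)
        labelled = dens.with_compartments(labels)
        tissues = sorted(labelled.roi_meta["tissue_id"].unique())
        groups = pd.Series(
            ["A" if i < 8 else "B" for i in range(len(tissues))], index=tissues
        )
        return labelled, groups

    def test_identical_groups_null(self, density_with_groups):
        labelled, groups = density_with_groups
        means = mt.compartment_mean(labelled, "immune_rich")
        # duplicate group A tissues into group B positions: identical samples
        dup = labelled.copy()
        a_tissues = groups.index[groups == "A"]
        b_tissues = groups.index[groups == "B"]
        for ta, tb in zip(a_tissues, b_tissues):
            rois_a = dup.roi_meta.index[dup.roi_meta["tissue_id"] == ta]
            rois_b = dup.roi_meta.index[dup.roi_meta["tissue_id"] == tb]
            dup.matrix.loc[rois_b] = dup.matrix.loc[rois_a].to_numpy()
        table = mt.volcano(dup, groups, "immune_rich")
        np.testing.assert_allclose(table.table["effect"], 0.0, atol=1e-12)
        assert (table.table["p"] == 1.0).all()

    def test_fourfold_shift_gives_effect_two(self, density_with_groups):
        labelled, groups = density_with_groups
        shifted = labelled.copy()
        b_rois = shifted.roi_meta["tissue_id"].isin(groups.index[groups == "B"])
        shifted.matrix.loc[~b_rois.to_numpy(), "P01"] *= 4.0
        base = mt.volcano(labelled, groups, "immune_rich").table.loc["P01", "effect"]
        table = mt.volcano(shifted, groups, "immune_rich")
        assert table.table.loc["P01", "effect"] == pytest.approx(base + 2.0, abs=1e-12)

    def test_shifted_protein_significant_in_simulation(self):
        """A 2-fold shifted protein (n=8 vs 8, CV 20%) clears both p-value
        cutoffs in nearly every replicate; its effect size straddles the
        2-fold line by construction so the median effect is ~1."""
        hits_05, hits_10 = 0, 0
        effects = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.normal(1.0, 0.2, size=8).clip(0.01) * 2.0  # 2-fold shift, CV 20%
            b = rng.normal(1.0, 0.2, size=8).clip(0.01)
            _, p = mt.mann_whitney(a, b)
            effects.append(np.log2(a.mean() / b.mean()))
            hits_05 += p < 0.05
            hits_10 += p < 0.10
        assert hits_05 >= 90
        assert hits_10 >= 90
        assert np.median(effects) == pytest.approx(1.0, abs=0.15)

    def test_zero_group_mean_gives_inf_sentinel(self, density_with_groups):
        labelled, groups = density_with_groups
        ds = labelled.copy()
        ds.matrix["P01"] = 0.0
        b_rois = ds.roi_meta["tissue_id"].isin(groups.index[groups == "B"])
        ds.matrix.loc[b_rois.to_numpy(), "P01"] = 1.0
        with pytest.warns(UserWarning, match="zero group mean"):
            table = mt.volcano(ds, groups, "immune_rich")
        assert np.isneginf(table.table.loc["P01", "effect"])


class TestTissueScore:
    def test_one_roi_per_tissue_scores_equal_roi_scores(self, fast_cfg):
        ds, labels, _ = mt.gen_response_cohort(
            mt.ResponseSimConfig(n_per_class=(8, 8)), seed=2
        )
        base = mt.ResponseSimConfig(n_per_class=(8, 8)).base_config()
        dens = mt.process_counts(ds, mt.default_panel(base))
        # force one ROI per tissue
        dens.roi_meta["tissue_id"] = [f"T{i}" for i in range(dens.n_rois)]
        report = mt.plsda_workflow(dens, labels, None, fast_cfg)
        tissue_labels = pd.Series(
            labels.to_numpy(), index=dens.roi_meta["tissue_id"].to_numpy()
        )
        result = mt.tissue_score(report, dens, tissue_labels)
        roi_scores = pd.Series(report.predicted, index=report.roi_ids)
        expected = roi_scores.to_numpy()
        np.testing.assert_allclose(
            result.scores.reindex(dens.roi_meta["tissue_id"]).to_numpy(), expected
        )

    def test_tissue_means_match_manual_computation(self, fast_cfg):
        ds, labels, _ = mt.gen_response_cohort(seed=4)
        dens = mt.process_counts(ds, mt.default_panel(mt.ResponseSimConfig().base_config()))
        report = mt.plsda_workflow(dens, labels, None, fast_cfg)
        tissue_labels = labels.groupby(dens.roi_meta["tissue_id"]).first()
        result = mt.tissue_score(report, dens, tissue_labels)
        roi_scores = pd.Series(report.predicted, index=report.roi_ids)
        manual = roi_scores.groupby(dens.roi_meta.loc[report.roi_ids, "tissue_id"]).mean()
        pd.testing.assert_series_equal(result.scores, manual, check_names=False)


class TestPearsonAndSensitivity:
    def test_protein_identical_to_y_has_r_one(self, processed_cohort, fast_cfg):
        labelled, _ = processed_cohort
        ds = labelled.copy()
        ds.matrix["P10"] = ds.matrix["CD8A"]
        r = mt.pearson_per_protein(ds, "CD8A", "immune_rich", fast_cfg)
        assert r["P10"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_closed_form_covariance(self, processed_cohort, fast_cfg):
        labelled, _ = processed_cohort
        r = mt.pearson_per_protein(labelled, "CD8A", "immune_rich", fast_cfg)
        scoped = labelled.subset_rois(
            labelled.roi_meta.index[labelled.roi_meta["compartment"] == "immune_rich"]
        )
        keep = scoped.matrix["CD8A"] > 0
        x = np.log1p(scoped.matrix.loc[keep, "P01"])
        y = np.log1p(scoped.matrix.loc[keep, "CD8A"])
        expected = np.corrcoef(x, y)[0, 1]
        assert r["P01"] == pytest.approx(expected, abs=1e-12)

    def test_strong_signal_stable_across_cutoffs(self, processed_cohort, fast_cfg):
        labelled, truth = processed_cohort
        report = mt.cutoff_sensitivity(labelled, "CD8A", fast_cfg)
        assert report.stable  # identical top-VIP sets at 20/25/30% cutoffs
        for top in report.top_sets.values():
            assert len(set(top) & set(truth.informative)) >= 1

    def test_single_cutoff_trivially_stable(self, processed_cohort, fast_cfg):
        labelled, _ = processed_cohort
        report = mt.cutoff_sensitivity(labelled, "CD8A", fast_cfg, cutoffs=(0.25,))
        assert report.stable

    def test_extreme_cutoff_skipped_with_warning(self, processed_cohort, fast_cfg):
        labelled, _ = processed_cohort
        with pytest.warns(UserWarning, match="skipped"):
            report = mt.cutoff_sensitivity(
                labelled, "CD8A", fast_cfg, cutoffs=(0.25, 0.99)
            )
        assert 0.99 in report.skipped
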