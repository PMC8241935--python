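"""Count-processing chain: ERCC, isotype, area, compartments, standardize."""

import numpy as np
import pandas as pd
import pytest

import microtumor as mt
from microtumor.dataset import geometric_mean

from .conftest import make_dataset


class TestErccNormalize:
    def test_identical_ercc_leaves_matrix_unchanged(self, three_roi_raw, small_panel):
        out = mt.ercc_normalize(three_roi_raw, small_panel)
        assert out.state == "ercc_normalized"
        pd.testing.assert_frame_equal(out.matrix, three_roi_raw.matrix)

    def test_doubled_ercc_geomean_halves_counts(self, small_panel):
        # ROI2's ERCC geomean is 2x ROI1's; grand geomean = sqrt(2) * g1,
        # so f1 = 1/sqrt(2) and f2 = sqrt(2): ratio of scaled counts is 2.
        ds = make_dataset(
            {
                "A": [10.0, 10.0], "B": [4.0, 4.0], "C": [1.0, 1.0],
                "IgG1": [0.0, 0.0],
                "ERCC1": [100.0, 200.0], "ERCC2": [100.0, 200.0],
            },
            areas=[1.0, 1.0], cd45=[0.1, 0.1],
            controls=["IgG1", "ERCC1", "ERCC2"],
        )
        out = mt.ercc_normalize(ds, small_panel)
        np.testing.assert_allclose(
            out.matrix.loc["R1", "A"] / out.matrix.loc["R2", "A"], 2.0
        )
        np.testing.assert_allclose(out.matrix.loc["R1", "A"], 10.0 * np.sqrt(2))

    def test_single_roi_unchanged(self, small_panel):
        ds = make_dataset(
            {"A": [10.0], "B": [4.0], "C": [1.0], "IgG1": [0.0],
             "ERCC1": [100.0], "ERCC2": [400.0]},
            areas=[1.0], cd45=[0.1], controls=["IgG1", "ERCC1", "ERCC2"],
        )
        out = mt.ercc_normalize(ds, small_panel)
        pd.testing.assert_frame_equal(out.matrix, ds.matrix)

    def test_post_ercc_geomeans_equal_across_rois(self, small_panel, rng):
        counts = rng.uniform(10, 1000, size=(8, 6))
        ds = make_dataset(
            {c: counts[:, i] for i, c in enumerate(["A", "B", "C", "IgG1", "ERCC1", "ERCC2"])},
            areas=np.full(8, 100.0), cd45=np.full(8, 0.3),
            controls=["IgG1", "ERCC1", "ERCC2"],
        )
        out = mt.ercc_normalize(ds, small_panel)
        geo = geometric_mean(out.matrix[["ERCC1", "ERCC2"]].to_numpy(), axis=1)
        np.testing.assert_allclose(geo, geo[0], rtol=1e-9)

    def test_nonpositive_ercc_names_roi(self, three_roi_raw, small_panel):
        ds = three_roi_raw.copy()
        ds.matrix.loc["R2", "ERCC1"] = 0.0
        with pytest.raises(ValueError, match="R2"):
            mt.ercc_normalize(ds, small_panel)


class TestIsotypeSubtract:
    @pytest.mark.parametrize(
        "target_count, isotype_count, expected", [(5.0, 8.0, 0.0), (100.0, 30.0, 70.0)]
    )
    def test_subtraction_arithmetic(self, small_panel, target_count, isotype_count, expected):
        ds = make_dataset(
            {"A": [target_count] * 3, "B": [1.0] * 3, "C": [1.0] * 3,
             "IgG1": [isotype_count] * 3, "ERCC1": [100.0] * 3, "ERCC2": [100.0] * 3},
            areas=[1.0] * 3, cd45=[0.1] * 3, controls=["IgG1", "ERCC1", "ERCC2"],
        )
        out = mt.isotype_subtract(mt.ercc_normalize(ds, small_panel), small_panel)
        assert (out.matrix["A"] == expected).all()

    def test_zero_isotype_leaves_targets_unchanged(self, three_roi_raw, small_panel):
        ds = three_roi_raw.copy()
        ds.matrix["IgG1"] = 0.0
        out = mt.isotype_subtract(mt.ercc_normalize(ds, small_panel), small_panel)
        pd.testing.assert_frame_equal(
            out.matrix[["A", "B", "C"]], ds.matrix[["A", "B", "C"]]
        )

    def test_monotone_and_nonnegative(self, small_panel, rng):
        counts = rng.uniform(0, 50, size=(10, 6))
        ds = make_dataset(
            {c: counts[:, i] for i, c in enumerate(["A", "B", "C", "IgG1", "ERCC1", "ERCC2"])},
            areas=np.full(10, 1.0), cd45=np.full(10, 0.3),
            controls=["IgG1", "ERCC1", "ERCC2"],
        )
        ds.matrix[["ERCC1", "ERCC2"]] = 100.0
        normed = mt.ercc_normalize(ds, small_panel)
        out = mt.isotype_subtract(normed, small_panel)
        targets = ["A", "B", "C"]
        assert (out.matrix[targets].to_numpy() <= normed.matrix[targets].to_numpy()).all()
        assert (out.matrix[targets].to_numpy() >= 0).all()

    def test_unmapped_target_errors(self, three_roi_raw):
        with pytest.raises(ValueError, match="no isotype control mapping"):
            mt.PanelConfig(
                targets=["A", "B", "C"],
                isotype_controls=["IgG1"],
                isotype_map={"A": "IgG1", "B": "IgG1"},
                ercc_controls=["ERCC1", "ERCC2"],
            )


class TestAreaNormalize:
    def test_density_arithmetic(self, small_panel):
        ds = make_dataset(
            {"A": [50.0, 50.0, 50.0], "B": [1.0] * 3, "C": [1.0] * 3,
             "IgG1": [0.0] * 3, "ERCC1": [100.0] * 3, "ERCC2": [100.0] * 3},
            areas=[1.0, 25000.0, 1.0], cd45=[0.1] * 3,
            controls=["IgG1", "ERCC1", "ERCC2"],
        )
        out = mt.area_normalize(mt.isotype_subtract(mt.ercc_normalize(ds, small_panel), small_panel))
        assert out.state == "density"
        assert out.matrix.loc["R1", "A"] == 50.0  # area 1: unchanged
        assert out.matrix.loc["R2", "A"] == pytest.approx(0.002)

    def test_doubling_areas_halves_densities(self, three_roi_raw, small_panel):
        sub = mt.isotype_subtract(mt.ercc_normalize(three_roi_raw, small_panel), small_panel)
        doubled = sub.copy()
        doubled.roi_meta["mask_area"] *= 2
        d1 = mt.area_normalize(sub)
        d2 = mt.area_normalize(doubled)
        np.testing.assert_allclose(d2.matrix.to_numpy(), d1.matrix.to_numpy() / 2)

    def test_chain_scale_consistency(self, three_roi_raw, small_panel):
        """Scaling all counts (targets, controls, ERCC) by c scales every
        density by exactly c: the chain preserves relative structure and
        introduces no nonlinearity."""
        base = mt.process_counts(three_roi_raw, small_panel)
        scaled_raw = three_roi_raw.copy()
        scaled_raw.matrix = scaled_raw.matrix * 3.7
        scaled = mt.process_counts(scaled_raw, small_panel)
        np.testing.assert_allclose(
            scaled.matrix[["A", "B", "C"]].to_numpy(),
            3.7 * base.matrix[["A", "B", "C"]].to_numpy(),
            rtol=1e-12,
        )


class TestCompartmentMean:
    def _labelled_density(self, small_panel):
        ds = make_dataset(
            {"A": [1.0, 3.0, 10.0, 20.0], "B": [2.0, 2.0, 5.0, 7.0],
             "C": [1.0] * 4, "IgG1": [0.0] * 4,
             "ERCC1": [100.0] * 4, "ERCC2": [100.0] * 4},
            areas=[1.0] * 4, cd45=[0.5, 0.6, 0.1, 0.4],
            tissues=["T1", "T1", "T1", "T2"],
            controls=["IgG1", "ERCC1", "ERCC2"],
        )
        dens = mt.process_counts(ds, small_panel)
        labels = pd.Series(
            ["immune_rich", "immune_rich", "immune_poor", "immune_rich"],
            index=dens.matrix.index,
        )
        return dens.with_compartments(labels)

    def test_two_rois_average(self, small_panel):
        labelled = self._labelled_density(small_panel)
        means = mt.compartment_mean(labelled, "immune_rich")
        assert means.loc["T1", "A"] == pytest.approx(2.0)  # mean(1, 3)

    def test_single_roi_row_equals_that_roi(self, small_panel):
        labelled = self._labelled_density(small_panel)
        means = mt.compartment_mean(labelled, "immune_rich")
        assert means.loc["T2", "A"] == pytest.approx(20.0)

    def test_mixed_compartment_tissue_uses_only_matching(self, small_panel):
        labelled = self._labelled_density(small_panel)
        means = mt.compartment_mean(labelled, "immune_poor")
        # T1's poor compartment is ROI 3 alone; T2 omitted with warning
        assert means.loc["T1", "A"] == pytest.approx(10.0)
        assert "T2" not in means.index

    def test_unknown_compartment_errors(self, small_panel):
        labelled = self._labelled_density(small_panel)
        with pytest.raises(ValueError, match="unknown compartment"):
            mt.compartment_mean(labelled, "stroma")


class TestClassifyRois:
    def test_threshold_on_observed_fractions(self, three_roi_raw):
        # CD45+ proportions 37.1%, 50.4% and 1.7% at the 25% cutoff
        result = mt.classify_rois(three_roi_raw, method="threshold", cutoff=0.25)
        assert result.labels.tolist() == ["immune_rich", "immune_rich", "immune_poor"]

    def test_boundary_fraction_is_poor(self, small_panel):
        ds = make_dataset(
            {"A": [1.0] * 3, "B": [1.0] * 3, "C": [1.0] * 3, "IgG1": [0.0] * 3,
             "ERCC1": [1.0] * 3, "ERCC2": [1.0] * 3},
            areas=[1.0] * 3, cd45=[0.25, 0.250001, 0.2],
            controls=["IgG1", "ERCC1", "ERCC2"],
        )
        labels = mt.classify_rois(ds, cutoff=0.25).labels
        assert labels.tolist() == ["immune_poor", "immune_rich", "immune_poor"]

    def test_cluster_method_derives_midpoint_cutoff(self, small_panel):
        ds = make_dataset(
            {"A": [1.0] * 6, "B": [1.0] * 6, "C": [1.0] * 6, "IgG1": [0.0] * 6,
             "ERCC1": [1.0] * 6, "ERCC2": [1.0] * 6},
            areas=[1.0] * 6, cd45=[0.02, 0.05, 0.08, 0.45, 0.5, 0.6],
            controls=["IgG1", "ERCC1", "ERCC2"],
        )
        result = mt.classify_rois(ds, method="cluster")
        assert result.cutoff == pytest.approx((0.08 + 0.45) / 2)
        assert result.labels.tolist() == ["immune_poor"] * 3 + ["immune_rich"] * 3

    def test_cluster_identical_fractions_error(self, small_panel):
        ds = make_dataset(
            {"A": [1.0] * 4, "B": [1.0] * 4, "C": [1.0] * 4, "IgG1": [0.0] * 4,
             "ERCC1": [1.0] * 4, "ERCC2": [1.0] * 4},
            areas=[1.0] * 4, cd45=[0.3] * 4, controls=["IgG1", "ERCC1", "ERCC2"],
        )
        with pytest.raises(ValueError, match="identical"):
            mt.classify_rois(ds, method="cluster")


class TestLogStandardize:
    def test_zero_maps_to_zero_log(self):
        matrix = pd.DataFrame({"A": [0.0, np.e - 1], "B": [1.0, 2.0]})
        Z, params = mt.log_standardize(matrix)
        logged_zero = 0.0  # ln(0 + 1)
        recovered = Z["A"] * params.loc["A", "sd"] + params.loc["A", "mean"]
        assert recovered.iloc[0] == pytest.approx(logged_zero)

    def test_constant_column_dropped_with_warning(self):
        matrix = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            Z, params = mt.log_standardize(matrix)
        assert "B" not in Z.columns
        assert not params.loc["B", "kept"]

    def test_columns_standardized(self, rng):
        matrix = pd.DataFrame(rng.uniform(0, 100, size=(30, 5)),
                              columns=list("ABCDE"))
        Z, _ = mt.log_standardize(matrix)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_transformer_applies_training_params(self, rng):
        train = pd.DataFrame(rng.uniform(0, 10, size=(20, 3)), columns=list("ABC"))
        new = pd.DataFrame(rng.uniform(0, 10, size=(5, 3)), columns=list("CBA"))
        scaler = mt.LogStandardizer().fit(train)
        out = scaler.transform(new)
        p = scaler.params_
        expected = (np.log1p(new["A"]) - p.loc["A", "mean"]) / p.loc["A", "sd"]
        np.testing.assert_allclose(out["A"], expected)
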