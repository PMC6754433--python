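"""QC filtering rules, beta-mixture EM, BMIQ mapping, batch adjustment."""

import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import ks_2samp

from methylmark import (DegenerateDataError, DesignError, GeneratorConfig,
                        batch_adjust, bmiq_normalize, filter_probes,
                        fit_beta_mixture, generate_dataset)
from methylmark.errors import NoProbesRetainedError
from methylmark.preprocess import FilterThresholds

from conftest import make_dataset


class TestFilterProbes:
    def _toy(self):
        """10 probes, 20 samples; one failure of each kind among probes 0-4."""
        rng = np.random.default_rng(0)
        beta = rng.uniform(0.2, 0.8, size=(10, 20))
        det = np.full((10, 20), 0.001)
        det[0, 3] = 0.02                      # detection failure in one sample
        beads = np.full((10, 20), 12, int)
        beads[1, :5] = 2                      # low beads in 25% of samples
        chrom = ["1"] * 10
        chrom[2] = "X"
        snp = [0] * 10
        snp[3] = 1
        cross = [0] * 10
        cross[4] = 1
        return make_dataset(beta, detection_p=det, bead_count=beads,
                            chromosome=chrom, snp=snp, cross=cross)

    def test_toy_counts_one_per_rule(self):
        out, report = filter_probes(self._toy())
        assert report.removed == {"detection": 1, "beads": 1, "sex_chr": 1,
                                  "snp": 1, "cross_reactive": 1}
        assert report.retained == 5
        assert out.n_probes == 5
        assert report.retained + sum(report.removed.values()) == report.total

    def test_first_rule_attribution(self):
        """A probe failing both detection and SNP is charged to detection."""
        ds = self._toy()
        ds.annotation.iloc[0, ds.annotation.columns.get_loc("snp_flag")] = 1
        _, report = filter_probes(ds)
        assert report.removed["detection"] == 1
        assert report.removed["snp"] == 1  # probe 3 only

    def test_bead_fraction_boundary_is_strict(self):
        beta = np.full((4, 20), 0.5)
        beads = np.full((4, 20), 12, int)
        beads[0, 0] = 2                       # exactly 5% of samples -> retained
        beads[1, :2] = 2                      # 10% -> removed
        out, report = filter_probes(make_dataset(beta, bead_count=beads))
        assert report.removed["beads"] == 1
        assert "cg00000" in out.beta.index

    def test_clean_dataset_is_identity_and_idempotent(self):
        ds = make_dataset(np.full((6, 10), 0.4))
        out1, rep1 = filter_probes(ds)
        assert rep1.retained == 6 and sum(rep1.removed.values()) == 0
        out2, rep2 = filter_probes(out1)
        assert list(out2.beta.index) == list(out1.beta.index)
        assert rep2.removed == rep1.removed

    def test_all_removed_raises(self):
        det = np.full((3, 4), 0.5)
        with pytest.raises(NoProbesRetainedError):
            filter_probes(make_dataset(np.full((3, 4), 0.5), detection_p=det))

    def test_threshold_validation(self):
        from methylmark.errors import ConfigurationError
        with pytest.raises(ConfigurationError):
            filter_probes(make_dataset(np.full((3, 4), 0.5)),
                          FilterThresholds(detection_p_max=0.0))


class TestBetaMixture:
    def test_recovers_component_means(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.beta(2.0, 23.0, 2500),     # mean ~0.08
                            rng.beta(10.0, 10.0, 1000),    # mean 0.5
                            rng.beta(23.0, 2.0, 1500)])    # mean ~0.92
        fit = fit_beta_mixture(x)
        np.testing.assert_allclose(fit.means, [0.08, 0.50, 0.92], atol=0.03)
        np.testing.assert_allclose(fit.weights, [0.5, 0.2, 0.3], atol=0.05)
        assert np.all(np.diff(fit.means) > 0)

    def test_single_cluster_concentrates_weight(self):
        rng = np.random.default_rng(1)
        fit = fit_beta_mixture(rng.normal(0.1, 0.01, 1000).clip(0.01, 0.99))
        assert fit.weights[0] > 0.9

    def test_responsibilities_normalized(self):
        rng = np.random.default_rng(2)
        x = rng.beta(2, 5, 500)
        fit = fit_beta_mixture(x)
        r = fit.responsibilities(x)
        np.testing.assert_allclose(r.sum(axis=1), 1.0, atol=1e-9)

    def test_degenerate_data_raises(self):
        with pytest.raises(DegenerateDataError):
            fit_beta_mixture(np.full(100, 0.5))

    def test_too_few_values_rejected(self):
        from methylmark.errors import ConfigurationError
        with pytest.raises(ConfigurationError):
            fit_beta_mixture(np.linspace(0.1, 0.9, 20))


class TestBmiq:
    @pytest.fixture(scope="class")
    def small(self):
        cfg = GeneratorConfig(n_probes=900, n_case=6, n_control=6, seed=4,
                              batch_shift_sd=0.0)
        ds, _ = generate_dataset(cfg)
        return filter_probes(ds)[0]

    def test_identity_when_distributions_match(self):
        """Type-II values drawn from the same trimodal law as type-I map
        (approximately) onto themselves."""
        rng = np.random.default_rng(5)

        def draw(n):
            comp = rng.choice(3, size=n, p=[0.4, 0.2, 0.4])
            return np.choose(comp, [rng.beta(2, 18, n), rng.beta(8, 8, n), rng.beta(18, 2, n)])

        vals = draw(1200)
        design = ["I"] * 600 + ["II"] * 600
        ds = make_dataset(np.tile(vals[:, None], (1, 4)), design_type=design)
        out = bmiq_normalize(ds)
        before = ds.beta.to_numpy()[600:, 0]
        after = out.beta.to_numpy()[600:, 0]
        assert np.median(np.abs(after - before)) < 0.01
        assert np.quantile(np.abs(after - before), 0.9) < 0.05

    def test_ks_distance_decreases_per_sample(self, small):
        out = bmiq_normalize(small)
        is2 = (small.annotation["design_type"] == "II").to_numpy()
        for j in range(small.n_samples):
            before = ks_2samp(small.beta.to_numpy()[~is2, j], small.beta.to_numpy()[is2, j]).statistic
            after = ks_2samp(out.beta.to_numpy()[~is2, j], out.beta.to_numpy()[is2, j]).statistic
            assert after < before

    def test_type_one_bit_identical_and_type_two_monotone(self, small):
        out = bmiq_normalize(small)
        is2 = (small.annotation["design_type"] == "II").to_numpy()
        assert np.array_equal(small.beta.to_numpy()[~is2], out.beta.to_numpy()[~is2])
        for j in range(small.n_samples):
            x = small.beta.to_numpy()[is2, j]
            y = out.beta.to_numpy()[is2, j]
            order = np.argsort(x, kind="mergesort")
            assert np.all(np.diff(y[order]) >= -1e-12)
        assert out.beta.to_numpy().min() >= 0.0 and out.beta.to_numpy().max() <= 1.0

    def test_fit_failure_names_sample(self):
        ds = make_dataset(np.full((200, 4), 0.5), design_type=["I"] * 100 + ["II"] * 100)
        with pytest.raises(DegenerateDataError, match="S000"):
            bmiq_normalize(ds)


class TestBatchAdjust:
    def test_single_level_is_noop(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.uniform(0.1, 0.9, (50, 12)))
        out = batch_adjust(ds, ["batch_id"])
        np.testing.assert_allclose(out.beta.to_numpy(), ds.beta.to_numpy(), atol=1e-6)

    def test_planted_shift_removed(self):
        """A +0.5 logit shift on batch B2 is reduced below 0.02 (mean over probes)."""
        rng = np.random.default_rng(1)
        p, n = 300, 40
        m = rng.normal(0, 1, (p, n))
        batch = ["B1"] * 20 + ["B2"] * 20
        group = (["case"] * 10 + ["control"] * 10) * 2
        m[:, 20:] += 0.5
        ds = make_dataset(expit(m), batch=batch, group=group)
        out = batch_adjust(ds, ["batch_id"])
        ma = logit(np.clip(out.beta.to_numpy(), 1e-6, 1 - 1e-6))
        diff = ma[:, :20].mean(axis=1) - ma[:, 20:].mean(axis=1)
        assert abs(diff.mean()) < 0.02

    def test_group_effect_preserved(self):
        """A balanced planted Δβ = 0.10 survives batch adjustment within ±0.015."""
        cfg = GeneratorConfig(n_probes=800, n_case=40, n_control=40, seed=8,
                              batch_shift_sd=0.4, batch_count=2)
        ds, truth = generate_dataset(cfg)
        out = batch_adjust(ds, ["batch_id"])
        case = ds.group_mask("case")
        idx = [ds.beta.index.get_loc(q) for q in truth.planted_probe_ids]
        b = out.beta.to_numpy()
        diff = b[idx][:, case].mean(axis=1) - b[idx][:, ~case].mean(axis=1)
        assert abs(diff.mean() - 0.10) < 0.015

    def test_sample_reordering_commutes(self):
        rng = np.random.default_rng(3)
        ds = make_dataset(rng.uniform(0.2, 0.8, (60, 16)),
                          batch=["B1", "B2"] * 8)
        out = batch_adjust(ds, ["batch_id"])
        perm = rng.permutation(16)
        shuffled = make_dataset(ds.beta.to_numpy()[:, perm],
                                batch=list(np.asarray(ds.samples["batch_id"])[perm]),
                                group=list(np.asarray(ds.samples["group"])[perm]))
        out_shuf = batch_adjust(shuffled, ["batch_id"])
        np.testing.assert_allclose(out_shuf.beta.to_numpy(),
                                   out.beta.to_numpy()[:, perm], atol=1e-8)

    def test_singleton_batch_raises(self):
        ds = make_dataset(np.full((20, 5), 0.5) + np.arange(5) * 0.01,
                          batch=["B1", "B1", "B1", "B1", "B2"])
        with pytest.raises(DesignError, match="B2"):
            batch_adjust(ds, ["batch_id"])

    def test_perfect_confounding_raises(self):
        rng = np.random.default_rng(4)
        ds = make_dataset(rng.uniform(0.3, 0.7, (20, 8)),
                          group=["case"] * 4 + ["control"] * 4,
                          batch=["B1"] * 4 + ["B2"] * 4)
        with pytest.raises(DesignError, match="confounded"):
            batch_adjust(ds, ["batch_id"])
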