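import numpy as np
import pandas as pd
import pytest

from fmtomics.prep import prepare_counts, select_analysis_sample, SampleMeta, EARLY_POST
from fmtomics.simulate import (
    SimConfig,
    generate_cohort,
    generate_microbiome,
    generate_outcomes,
    generate_metabolome,
    simulate_all,
    write_dataset,
)


class TestConfig:
    def test_default_allocation_matches_trial(self):
        cfg = SimConfig()
        assert (cfg.n_fmt, cfg.n_placebo) == (49, 25)

    def test_small_exact_allocation(self):
        cfg = SimConfig(n_patients=3)
        assert (cfg.n_fmt, cfg.n_placebo) == (2, 1)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(arm_ratio=(0, 1))

    def test_zero_patients_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_patients=0)

    def test_planted_genus_must_anchor_one_topic(self):
        with pytest.raises(ValueError, match="planted_genus"):
            SimConfig(planted_genus="NotAnAnchor")

    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            SimConfig(engraftment_rate=1.5)


class TestCohort:
    def test_arm_counts(self):
        meta = generate_cohort(SimConfig(seed=5))
        pats = meta.patients()
        by_arm = pats.groupby("arm")["patient_id"].nunique()
        assert by_arm["FMT"] == 49 and by_arm["placebo"] == 25

    def test_same_seed_identical(self):
        m1 = generate_cohort(SimConfig(seed=9))
        m2 = generate_cohort(SimConfig(seed=9))
        pd.testing.assert_frame_equal(m1.table, m2.table)

    def test_donors_have_na_arm_and_outcome(self):
        meta = generate_cohort(SimConfig(seed=5))
        donors = meta.donors()
        assert len(donors) == 4
        assert donors["arm"].isna().all() and donors["outcome"].isna().all()

    def test_fmt_patients_have_donors(self):
        meta = generate_cohort(SimConfig(seed=6))
        pats = meta.patients()
        fmt = pats[pats["arm"] == "FMT"]
        assert fmt["donor_id"].notna().all()
        assert pats.loc[pats["arm"] == "placebo", "donor_id"].isna().all()


class TestMicrobiome:
    def test_same_seed_identical_counts(self):
        cfg = SimConfig(seed=21, n_patients=10)
        meta = generate_cohort(cfg)
        t1, _ = generate_microbiome(meta, cfg)
        t2, _ = generate_microbiome(generate_cohort(cfg), cfg)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)

    def test_counts_nonnegative_integers(self, small_dataset):
        arr = small_dataset.counts.counts.to_numpy()
        assert arr.dtype.kind in "iu" and (arr >= 0).all()

    def test_zero_engraftment_shares_no_donor_unique_asvs(self):
        cfg = SimConfig(seed=22, n_patients=12, engraftment_rate=0.0)
        meta = generate_cohort(cfg)
        counts, truth = generate_microbiome(meta, cfg)
        tbl = meta.table
        donor_unique = {
            a for s in truth.donor_asv_sets.values() for a in s if "_recip_" not in a
        }
        post = tbl[(tbl["role"] == "patient") & tbl["timepoint"].isin(["post10", "post28", "late"])]
        sub = counts.counts.loc[post.index, sorted(donor_unique)]
        assert int(sub.to_numpy().sum()) == 0

    def test_full_engraftment_deep_sequencing_carries_all_donor_asvs(self):
        cfg = SimConfig(
            seed=23, n_patients=9, engraftment_rate=1.0,
            depth_range=(200_000, 200_001), frac_shallow=0.0,
        )
        meta = generate_cohort(cfg)
        counts, truth = generate_microbiome(meta, cfg)
        tbl = meta.table
        post = tbl[
            (tbl["role"] == "patient") & (tbl["arm"] == "FMT")
            & tbl["timepoint"].isin(["post10", "post28"])
        ]
        for sid, row in post.iterrows():
            dset = sorted(truth.donor_asv_sets[row["donor_id"]])
            present = (counts.counts.loc[sid, dset] > 0)
            assert present.all()

    def test_mean_depth_matches_configuration(self):
        """Law of large numbers: mean total count approaches the log-uniform
        depth mean over many samples."""
        cfg = SimConfig(seed=24, n_patients=40, frac_shallow=0.0)
        meta = generate_cohort(cfg)
        counts, _ = generate_microbiome(meta, cfg)
        totals = counts.counts.sum(axis=1).to_numpy()
        lo, hi = cfg.depth_range
        expected = (hi - lo) / np.log(hi / lo)  # mean of log-uniform
        assert abs(totals.mean() - expected) / expected < 0.15

    def test_ground_truth_rows_stochastic(self, small_dataset):
        tt = small_dataset.truth.true_topic_term.to_numpy()
        assert np.allclose(tt.sum(axis=1), 1.0, atol=1e-9)


class TestOutcomes:
    def test_null_effect_gives_no_association(self):
        cfg = SimConfig(seed=25, n_patients=200, beta_outcome=0.0, gamma_prophylaxis=0.0)
        meta = generate_cohort(cfg)
        counts, _ = generate_microbiome(meta, cfg)
        out = generate_outcomes(meta, counts, cfg)
        from fmtomics.simulate import _early_post_risk_score
        from scipy import stats

        x = _early_post_risk_score(meta, counts, cfg)
        shared = x.index.intersection(out.index)
        rho, _ = stats.spearmanr(x[shared], out[shared])
        assert abs(rho) < 0.15

    def test_positive_effect_gives_positive_association(self):
        cfg = SimConfig(seed=26, n_patients=300)
        meta = generate_cohort(cfg)
        counts, _ = generate_microbiome(meta, cfg)
        out = generate_outcomes(meta, counts, cfg)
        from fmtomics.simulate import _early_post_risk_score
        from scipy import stats

        x = _early_post_risk_score(meta, counts, cfg)
        shared = x.index.intersection(out.index)
        rho, p = stats.spearmanr(x[shared], out[shared])
        assert rho > 0.15 and p < 0.01

    def test_event_rate_calibration(self):
        cfg = SimConfig(seed=27, n_patients=2000, event_rate=0.35)
        meta = generate_cohort(cfg)
        counts, _ = generate_microbiome(meta, cfg)
        out = generate_outcomes(meta, counts, cfg)
        assert abs(out.mean() - 0.35) <= 0.02

    def test_labels_binary(self, small_dataset):
        assert set(small_dataset.outcomes.unique()) <= {0, 1}


class TestMetabolome:
    def test_anchor_samples_duplicated_in_both_batches(self, default_dataset):
        mm = default_dataset.metabolome
        assert len(mm.anchor_pairs) == 18
        for ref, tgt in mm.anchor_pairs:
            assert mm.batch[ref] == "reference" and mm.batch[tgt] == "target"

    def test_intensities_nonnegative(self, small_dataset):
        assert (small_dataset.metabolome.intensities.to_numpy() >= 0).all()

    def test_unit_batch_factors_make_adjustment_identity(self):
        cfg = SimConfig(seed=28, n_patients=20, n_metabolites=40,
                        n_anchor_samples=6, batch_scale_range=(1.0, 1.0),
                        zero_rate=0.0, frac_poorly_detected=0.0)
        ds = simulate_all(cfg)
        from fmtomics.metabolome import batch_adjust

        adj = batch_adjust(ds.metabolome)
        assert np.allclose(
            adj.intensities.to_numpy(), ds.metabolome.intensities.to_numpy(),
            rtol=1e-9,
        )

    def test_collinear_blocks_correlate(self, default_dataset):
        from scipy import stats

        mm = default_dataset.metabolome
        block = default_dataset.truth.collinear_blocks[0]
        vals = np.log(mm.intensities[block].replace(0, np.nan))
        rho = vals.corr(method="spearman").to_numpy()
        off = rho[np.triu_indices(len(block), 1)]
        assert np.nanmedian(off) > 0.5

    def test_no_collinearity_when_disabled(self):
        cfg = SimConfig(seed=29, n_patients=30, n_metabolites=60,
                        n_anchor_samples=5, frac_collinear=0.0, zero_rate=0.0,
                        frac_poorly_detected=0.0)
        ds = simulate_all(cfg)
        vals = np.log(ds.metabolome.intensities.iloc[:, :30])
        rho = vals.corr(method="spearman").to_numpy()
        off = np.abs(rho[np.triu_indices(30, 1)])
        assert np.median(off) < 0.2

    def test_planted_metabolite_lower_in_events(self, default_dataset):
        mm = default_dataset.metabolome
        sm = default_dataset.serum_meta
        planted = default_dataset.truth.planted_metabolite
        vals = np.log(mm.intensities.loc[sm.index, planted])
        ev = sm["outcome"].astype(float)
        assert vals[ev == 1].mean() < vals[ev == 0].mean()

    def test_too_many_anchors_errors(self):
        cfg = SimConfig(seed=30, n_patients=3, n_anchor_samples=500)
        meta = generate_cohort(cfg)
        counts, _ = generate_microbiome(meta, cfg)
        out = generate_outcomes(meta, counts, cfg)
        with pytest.raises(ValueError, match="anchor"):
            generate_metabolome(meta, out, cfg)


class TestDeterminism:
    def test_full_dataset_reproducible(self, small_config):
        d1 = simulate_all(small_config)
        d2 = simulate_all(small_config)
        pd.testing.assert_frame_equal(d1.counts.counts, d2.counts.counts)
        pd.testing.assert_frame_equal(d1.metabolome.intensities, d2.metabolome.intensities)
        pd.testing.assert_series_equal(d1.outcomes, d2.outcomes)

    def test_write_dataset_round_trip(self, small_dataset, tmp_path):
        write_dataset(small_dataset, tmp_path)
        from fmtomics.io import read_count_table, read_metabolites, read_metadata

        t = read_count_table(tmp_path / "asv_counts.tsv", tmp_path / "taxonomy.tsv")
        pd.testing.assert_frame_equal(t.counts, small_dataset.counts.counts)
        meta = read_metadata(tmp_path / "sample_metadata.tsv")
        assert len(meta.table) == len(small_dataset.meta.table)
        mm = read_metabolites(tmp_path / "metabolites.tsv", tmp_path / "anchor_pairs.tsv")
        assert np.allclose(
            mm.intensities.to_numpy(), small_dataset.metabolome.intensities.to_numpy()
        )
        assert mm.anchor_pairs == small_dataset.metabolome.anchor_pairs
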