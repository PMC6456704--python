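import json

import numpy as np
import pytest
from scipy.stats import kstest

from episcan import synthetic_data as syn
from episcan.additive_scan import hwe_exact_test
from episcan.exact_epistasis import interaction_lrt, logistic_fit
from episcan.genotype_io import CohortTable, read_plink
from episcan.pair_screen import dosage_r2

from conftest import make_cohort, make_genotypes


def small_config(**kw):
    base = dict(n_cases=300, n_controls=700, n_markers=12, seed=1, n_pcs=2)
    base.update(kw)
    return syn.SimulationConfig(**base)


class TestConfigValidation:
    def test_bad_maf_range(self):
        with pytest.raises(ValueError, match="maf_range"):
            small_config(maf_range=(0.0, 0.5)).validate()

    def test_effect_index_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            small_config(additive_effects=[(99, 0.3)]).validate()

    def test_pair_members_distinct(self):
        with pytest.raises(ValueError, match="distinct"):
            small_config(
                epistatic_effects=[((1, 1), np.zeros((3, 3)))]
            ).validate()

    def test_block_lengths_bounded(self):
        with pytest.raises(ValueError, match="block lengths"):
            small_config(block_structure=[(13, 0.5)]).validate()


class TestSimulateCohort:
    def test_deterministic(self):
        a = syn.simulate_cohort(small_config())
        b = syn.simulate_cohort(small_config())
        assert np.array_equal(a[0].dosages, b[0].dosages)
        assert np.array_equal(a[1].status, b[1].status)
        np.testing.assert_array_equal(
            a[1].covariates.to_numpy(), b[1].covariates.to_numpy()
        )

    def test_seed_changes_output(self):
        a = syn.simulate_cohort(small_config(seed=1))
        b = syn.simulate_cohort(small_config(seed=2))
        assert not np.array_equal(a[0].dosages, b[0].dosages)

    def test_null_frequencies_and_hwe(self):
        cfg = syn.SimulationConfig(
            n_cases=5000, n_controls=5000, n_markers=60,
            maf_range=(0.3, 0.3), n_pcs=0, seed=42,
        )
        gm, cohort, _ = syn.simulate_cohort(cfg)
        freqs = [gm.allele2_frequency(j) for j in range(gm.n_markers)]
        assert all(abs(f - 0.3) < 0.02 for f in freqs)
        hwe_ok = 0
        for j in range(gm.n_markers):
            d = gm.dosages[:, j]
            p = hwe_exact_test(int((d == 0).sum()), int((d == 1).sum()),
                               int((d == 2).sum()))
            hwe_ok += p > 1e-3
        assert hwe_ok >= 0.99 * gm.n_markers

    def test_case_fraction_matches_target(self):
        gm, cohort, _ = syn.simulate_cohort(small_config())
        assert cohort.status.sum() == 300
        assert (cohort.status == 0).sum() == 700

    def test_ld_decays_with_distance(self):
        cfg = syn.SimulationConfig(
            n_cases=3000, n_controls=3000, n_markers=30,
            block_structure=[(10, 0.9)] * 3, maf_range=(0.3, 0.5),
            n_pcs=0, seed=9,
        )
        gm, _, _ = syn.simulate_cohort(cfg)
        r2_by_dist = {1: [], 3: [], 6: []}
        for start in (0, 10, 20):
            for dist in r2_by_dist:
                r2_by_dist[dist].append(dosage_r2(gm, start, start + dist))
        means = [np.mean(r2_by_dist[d]) for d in (1, 3, 6)]
        assert means[0] > means[1] > means[2]

    def test_multiplicative_pair_is_lrt_null(self):
        # the 4-df interaction test must be calibrated when the planted 3x3
        # matrix is purely additive in the two dosages
        M = syn.multiplicative_matrix(0.4, -0.3)
        ps = []
        for seed in range(120):
            cfg = syn.SimulationConfig(
                n_cases=600, n_controls=600, n_markers=2,
                maf_range=(0.3, 0.5), epistatic_effects=[((0, 1), M)],
                n_pcs=0, seed=seed,
            )
            gm, cohort, _ = syn.simulate_cohort(cfg)
            ps.append(interaction_lrt(gm, cohort, ("snp1", "snp2")).p)
        assert kstest(np.array(ps), "uniform").pvalue > 0.01

    def test_unachievable_case_fraction_raises(self):
        cfg = syn.SimulationConfig(
            n_cases=9000, n_controls=1000, n_markers=2,
            maf_range=(0.3, 0.3), additive_effects=[(0, -60.0)],
            n_pcs=0, seed=1,
        )
        with pytest.raises(syn.SimulationError, match="intercept|case fraction"):
            syn.simulate_cohort(cfg)

    def test_missingness_rate(self):
        gm, _, _ = syn.simulate_cohort(
            small_config(n_cases=2000, n_controls=2000, missing_rate=0.05)
        )
        frac = (gm.dosages < 0).mean()
        assert 0.03 < frac < 0.07

    def test_truth_record_roundtrip(self):
        cfg = small_config(
            additive_effects=[(0, 0.5)],
            epistatic_effects=[((1, 2), syn.interaction_only_matrix(0.3))],
            n_batches=3, batch_effect_sd=0.2,
        )
        _, _, truth = syn.simulate_cohort(cfg)
        d = json.loads(truth.to_json())
        assert d["additive"] == [["snp1", 0.5]]
        assert d["epistatic"][0][:2] == ["snp2", "snp3"]
        assert len(d["batch_labels"]) == 1000

    def test_effect_recovery_with_true_model(self):
        # fitting the generating model recovers planted log-odds
        recovered = 0
        effects = [(0, 0.35), (3, -0.3)]
        for seed in range(5):
            cfg = syn.SimulationConfig(
                n_cases=4000, n_controls=4000, n_markers=6,
                maf_range=(0.3, 0.5), additive_effects=effects,
                n_pcs=0, seed=seed + 60,
            )
            gm, cohort, _ = syn.simulate_cohort(cfg)
            X = np.column_stack([
                np.ones(gm.n_samples),
                gm.dosages[:, 0].astype(float),
                gm.dosages[:, 3].astype(float),
            ])
            fit = logistic_fit(X, cohort.status.astype(float))
            ok = all(
                abs(fit.beta[k + 1] - beta) < 3 * fit.se(k + 1)
                for k, (_, beta) in enumerate(effects)
            )
            recovered += ok
        assert recovered >= 4

    def test_subpop_divergence_shifts_frequencies(self):
        cfg = small_config(
            n_cases=2000, n_controls=2000, n_subpops=2,
            fst_like_divergence=0.2, seed=8,
        )
        gm, _, truth = syn.simulate_cohort(cfg)
        labels = np.asarray(truth.subpop_labels)
        diffs = [
            abs(gm.dosages[labels == 0, j].mean() - gm.dosages[labels == 1, j].mean())
            for j in range(gm.n_markers)
        ]
        assert max(diffs) > 0.1


class TestSplitCohort:
    def test_exact_halving(self):
        gm = make_genotypes(np.zeros((300, 1), dtype=np.int8))
        cohort = make_cohort([1] * 100 + [0] * 200)
        (g1, c1), (g2, c2) = syn.split_cohort(gm, cohort, 0.5, seed=0)
        assert c1.status.sum() == 50 and c2.status.sum() == 50
        assert (c1.status == 0).sum() == 100 and (c2.status == 0).sum() == 100

    def test_consortium_shaped_split(self):
        # 14,224 cases + 33,954 controls halved -> 7,112 cases per half
        n_cases, n_controls = 14224, 33954
        gm = make_genotypes(np.zeros((n_cases + n_controls, 1), dtype=np.int8))
        cohort = make_cohort([1] * n_cases + [0] * n_controls)
        (_, c1), (_, c2) = syn.split_cohort(gm, cohort, 0.5, seed=3,
                                            recompute_pcs_per_half=False)
        assert c1.status.sum() == 7112 and c2.status.sum() == 7112
        assert abs(int((c1.status == 0).sum()) - 16977) <= 1

    def test_disjoint_and_exhaustive(self):
        gm, cohort, _ = syn.simulate_cohort(small_config())
        (g1, c1), (g2, c2) = syn.split_cohort(gm, cohort, 0.4, seed=7)
        s1, s2 = set(c1.samples), set(c2.samples)
        assert not (s1 & s2)
        assert s1 | s2 == set(cohort.samples)

    def test_seeded_reproducible(self):
        gm, cohort, _ = syn.simulate_cohort(small_config())
        a = syn.split_cohort(gm, cohort, 0.5, seed=11)
        b = syn.split_cohort(gm, cohort, 0.5, seed=11)
        assert a[0][1].samples == b[0][1].samples

    def test_empty_stratum_raises(self):
        gm = make_genotypes(np.zeros((10, 1), dtype=np.int8))
        cohort = make_cohort([0] * 10)
        with pytest.raises(ValueError, match="case stratum"):
            syn.split_cohort(gm, cohort, 0.5, seed=0)


class TestWriteCohort:
    def test_files_written_and_readable(self, tmp_path):
        gm, cohort, truth = syn.simulate_cohort(small_config(missing_rate=0.02))
        prefix = tmp_path / "cohort"
        syn.write_cohort(prefix, gm, cohort, truth)
        gm2, fam = read_plink(prefix)
        assert np.array_equal(gm.dosages, gm2.dosages)
        assert list((fam["phenotype"] == 2).astype(int)) == list(cohort.status)
        assert (tmp_path / "cohort.covar").exists()
        json.loads((tmp_path / "cohort.truth.json").read_text())
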