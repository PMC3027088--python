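import numpy as np
import pytest

import cnvjoint as cj
from cnvjoint.exceptions import ValidationError


class TestBuildRoster:
    def test_cohort_histogram_counts(self):
        roster = cj.build_roster(cj.HYPERGEN_FAMILY_HISTOGRAM, seed=1)
        assert roster["family_id"].nunique() == 421
        assert len(roster) == 1086

    def test_single_family(self):
        roster = cj.build_roster({3: 1}, seed=0)
        assert roster["family_id"].nunique() == 1
        assert len(roster) == 3

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValidationError):
            cj.build_roster({}, seed=0)
        with pytest.raises(ValidationError):
            cj.build_roster({2: 0}, seed=0)

    def test_sex_and_center_proportions(self):
        roster = cj.build_roster({1: 3000}, seed=2, p_female=0.666)
        assert (roster["sex"] == 2).mean() == pytest.approx(0.666, abs=0.03)
        assert (roster["center"] == "AL").mean() == pytest.approx(856 / 1086, abs=0.03)


class TestSimulateGenotypes:
    def test_reproducible_from_seed(self):
        cfg = cj.SimConfig(n_markers=50, family_size_histogram={2: 10}, seed=9)
        s1 = cj.simulate_study(cfg)
        s2 = cj.simulate_study(cfg)
        assert s1.genotypes.equals(s2.genotypes)
        np.testing.assert_array_equal(s1.pheno["trait"], s2.pheno["trait"])

    def test_no_cnv_loci_means_all_diploid(self):
        cfg = cj.SimConfig(n_markers=100, family_size_histogram={2: 20},
                           cnv_locus_fraction=0.0, seed=3)
        t = cj.simulate_study(cfg).genotypes
        np.testing.assert_array_equal(t.a + t.b, 2)

    def test_duplication_kind_raises_copy_number(self):
        cfg = cj.SimConfig(n_markers=50, family_size_histogram={1: 200},
                           cnv_locus_fraction=1.0, cnv_allele_freq=0.2,
                           cnv_kind="duplication", seed=4)
        t = cj.simulate_study(cfg).genotypes
        total = t.a + t.b
        assert total.max() > 2
        assert total.min() == 2

    def test_allele_frequencies_converge(self):
        # law of large numbers at 5,000 unrelated singletons, no divergence
        cfg = cj.SimConfig(n_markers=20, family_size_histogram={1: 5000},
                           divergence=0.0, cnv_locus_fraction=0.0, seed=5)
        roster = cj.build_roster(cfg.family_size_histogram, seed=cfg.seed)
        table, partial = cj.simulate_genotypes(roster, cfg)
        p1, _ = partial["founder_freqs"]
        obs = table.b.mean(axis=1) / 2.0
        np.testing.assert_allclose(obs, p1, atol=0.02)

    def test_sibling_genotype_correlation_is_half(self):
        # full sibs share half their genome: mean per-marker dosage
        # correlation across sib pairs ~ 0.5
        cfg = cj.SimConfig(n_markers=4000, family_size_histogram={2: 150},
                           divergence=0.0, cnv_locus_fraction=0.0, seed=6)
        t = cj.simulate_study(cfg).genotypes
        d = t.b.astype(float)
        s1, s2 = d[:, 0::2], d[:, 1::2]
        s1 = s1 - s1.mean(axis=1, keepdims=True)
        s2 = s2 - s2.mean(axis=1, keepdims=True)
        num = (s1 * s2).mean(axis=1)
        den = s1.std(axis=1) * s2.std(axis=1)
        ok = den > 0
        r = (num[ok] / den[ok]).mean()
        assert r == pytest.approx(0.5, abs=0.05)

    def test_singletons_without_divergence_are_uncorrelated(self):
        cfg = cj.SimConfig(n_markers=4000, family_size_histogram={1: 300},
                           divergence=0.0, cnv_locus_fraction=0.0, seed=7)
        t = cj.simulate_study(cfg).genotypes
        d = t.b.astype(float)
        s1, s2 = d[:, 0::2], d[:, 1::2]
        s1 = s1 - s1.mean(axis=1, keepdims=True)
        s2 = s2 - s2.mean(axis=1, keepdims=True)
        den = s1.std(axis=1) * s2.std(axis=1)
        r = ((s1 * s2).mean(axis=1)[den > 0] / den[den > 0]).mean()
        assert abs(r) < 0.05

    def test_cnv_allele_is_rare(self):
        cfg = cj.SimConfig(n_markers=2000, family_size_histogram={1: 500},
                           cnv_locus_fraction=0.05, seed=8)
        study = cj.simulate_study(cfg)
        t = study.genotypes
        idx = [t.marker_index(m) for m in study.truth.cnv_marker_ids]
        total = t.a[idx] + t.b[idx]
        carrier_rate = (total != 2).mean()
        assert 0 < carrier_rate < 0.025  # 2 * allele freq 0.005, Monte-Carlo slack


class TestSimulatePheno:
    def test_degenerate_constant_trait(self):
        cfg = cj.SimConfig(
            n_markers=10, family_size_histogram={2: 5}, seed=1,
            sigma2_family=0.0, sigma2_resid=0.0, phi_age=0.0, phi_age2=0.0,
            phi_sex=0.0, phi_center=0.0, phi_ancestry=0.0,
            alpha=np.log(3.26),
        )
        study = cj.simulate_study(cfg)
        np.testing.assert_allclose(study.pheno["trait"], 3.26, rtol=1e-12)

    def test_intraclass_correlation_of_sib_pairs(self):
        cfg = cj.SimConfig(
            n_markers=5, family_size_histogram={2: 2000}, seed=2,
            sigma2_family=0.01, sigma2_resid=0.01, phi_age=0.0, phi_age2=0.0,
            phi_sex=0.0, phi_center=0.0, phi_ancestry=0.0, divergence=0.0,
        )
        study = cj.simulate_study(cfg)
        ln_y = np.log(study.pheno["trait"].to_numpy())
        r = np.corrcoef(ln_y[0::2], ln_y[1::2])[0, 1]
        assert r == pytest.approx(0.5, abs=0.05)

    def test_additive_allele_effect_is_exact(self):
        cfg = cj.SimConfig(
            n_markers=50, family_size_histogram={1: 300}, seed=3,
            n_causal=1, beta1=0.05, beta2=0.0, cnv_locus_fraction=0.0,
            sigma2_family=0.0, sigma2_resid=0.0, phi_age=0.0, phi_age2=0.0,
            phi_sex=0.0, phi_center=0.0, phi_ancestry=0.0,
        )
        study = cj.simulate_study(cfg)
        mid = study.truth.causal_markers[0][0]
        i = study.genotypes.marker_index(mid)
        contrast = (study.genotypes.a[i] - study.genotypes.b[i]).astype(float)
        ln_y = np.log(study.pheno["trait"].to_numpy())
        aa = ln_y[contrast == 2]
        bb = ln_y[contrast == -2]
        assert len(aa) and len(bb)
        # beta1 * (2 - (-2)) = 0.2 between opposite homozygotes, exactly
        assert aa.mean() - bb.mean() == pytest.approx(0.2, abs=1e-12)

    def test_causal_marker_must_exist(self):
        cfg = cj.SimConfig(n_markers=10, family_size_histogram={2: 5}, seed=4)
        study = cj.simulate_study(cfg)
        study.truth.causal_markers = [("nope", 0.1, 0.0)]
        with pytest.raises(KeyError):
            cj.simulate_phenocov(study.roster, study.genotypes, study.truth, cfg)
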