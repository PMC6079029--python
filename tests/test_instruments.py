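import numpy as np
import pytest

from ginet.core_io import (
    CovariateSet,
    DataError,
    GeneAnnotation,
    GenotypeData,
    VariantRecord,
    gene_distance,
)
from ginet.instruments import (
    GeneticInstrument,
    cis_window,
    fit_instrument,
    instrument_strength,
    neighbour_instruments,
    score_instrument,
    split_samples,
)
from ginet.synth_data import generate_genotypes

from .conftest import plain_covariates


class TestSplit:
    def test_same_seed_same_split(self):
        cov = plain_covariates(100, seed=1)
        a = split_samples(cov, seed=7)
        b = split_samples(cov, seed=7)
        assert a.train == b.train and a.test == b.test

    def test_nine_constant_samples_give_three_train(self):
        cov = CovariateSet(
            samples=[f"s{i}" for i in range(9)],
            cohort=np.array(["X"] * 9, dtype=object),
            sex=np.array(["F"] * 9, dtype=object),
            age=np.full(9, 50.0),
        )
        split = split_samples(cov, train_frac=1 / 3, seed=0)
        assert len(split.train) == 3 and len(split.test) == 6
        assert sorted(split.train + split.test) == cov.samples

    def test_large_cohort_split_is_balanced(self):
        rng = np.random.default_rng(0)
        n = 3072
        cov = CovariateSet(
            samples=[f"s{i:05d}" for i in range(n)],
            cohort=np.array(
                [f"C{i % 6}" for i in range(n)],
                dtype=object,
            ),
            sex=rng.choice(["F", "M"], n).astype(object),
            age=rng.normal(56, 14.8, n),
        )
        split = split_samples(cov, train_frac=1 / 3, seed=3)
        # about one third in train, within per-stratum rounding (12 strata)
        assert abs(len(split.train) - n / 3) <= 12
        # cohort x sex proportions match overall within 1 sample per stratum
        tr = set(split.train)
        for coh in set(cov.cohort):
            for sex in ("F", "M"):
                idx = (cov.cohort == coh) & (cov.sex == sex)
                n_str = idx.sum()
                got = sum(s in tr for s in np.asarray(cov.samples)[idx])
                assert abs(got - n_str / 3) <= 1
        # age balance: means differ by < 0.1 SD
        age = {s: a for s, a in zip(cov.samples, cov.age)}
        mu_tr = np.mean([age[s] for s in split.train])
        mu_te = np.mean([age[s] for s in split.test])
        assert abs(mu_tr - mu_te) < 0.1 * cov.age.std()

    def test_bad_fraction_rejected(self):
        cov = plain_covariates(10)
        with pytest.raises(DataError):
            split_samples(cov, train_frac=1.5)


class TestCisWindow:
    def test_flank_arithmetic(self):
        g = GeneAnnotation("g", "1", 200_000, 210_000)
        assert cis_window(g) == ("1", 100_000, 310_000)

    def test_floored_at_one(self):
        g = GeneAnnotation("g", "1", 50_000, 60_000)
        assert cis_window(g)[1] == 1

    def test_equals_union_of_body_and_flanks(self, rng):
        for _ in range(20):
            s = int(rng.integers(1, 5_000_000))
            e = s + int(rng.integers(1, 100_000))
            g = GeneAnnotation("g", "1", s, e)
            flank = 100_000
            chrom, lo, hi = cis_window(g, flank)
            # union of body, TSS flank and TES flank
            lo_u = max(1, min(s, s - flank, e - flank))
            hi_u = max(e, s + flank, e + flank)
            assert (lo, hi) == (lo_u, hi_u)


def orthovariate_fixture(n=64, p=4, seed=5):
    """Genotype data whose standardized dosages are exactly orthonormal
    (unit variance, zero mean, zero cross-products)."""
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(
        np.column_stack([np.ones(n), rng.normal(size=(n, p))])
    )
    U = Q[:, 1:] * np.sqrt(n)  # unit-variance columns orthogonal to 1
    D = 1.0 + U * (0.9 / np.abs(U).max(axis=0))  # dosages stay in [0, 2]
    variants = [VariantRecord(f"v{j}", "1", 100 + j, "A", "G") for j in range(p)]
    geno = GenotypeData(variants, [f"s{i}" for i in range(n)], D)
    cov = CovariateSet(
        samples=geno.samples,
        cohort=np.array(["X"] * n, dtype=object),
        sex=np.array(["F"] * n, dtype=object),
        age=np.full(n, 50.0),
    )
    return geno, cov


class TestFitInstrument:
    gene = GeneAnnotation("g", "1", 1, 1000)

    def test_max_penalty_returns_none(self, rng):
        geno = generate_genotypes(80, 6, seed=1)
        cov = plain_covariates(80)
        y = rng.normal(size=80)
        # the grid starts at the smallest penalty zeroing all coefficients
        Z = (geno.dosage - geno.dosage.mean(0)) / geno.dosage.std(0)
        gi = fit_instrument(
            self.gene, geno, y, cov, forced_alpha=np.abs(Z.T @ y).max() / 80 * 1.01
        )
        assert gi is None

    def test_soft_threshold_closed_form(self, rng):
        # orthonormal standardized design, no informative covariates:
        # lasso weights equal sign(b) * (|b| - lambda)+ of univariate OLS b
        geno, cov = orthovariate_fixture()
        n = geno.n_samples
        Z = (geno.dosage - geno.dosage.mean(0)) / geno.dosage.std(0)
        beta_true = np.array([1.0, -0.5, 0.25, 0.0])
        y = Z @ beta_true + 0.05 * rng.normal(size=n)
        alpha = 0.2
        gi = fit_instrument(self.gene, geno, y, cov, forced_alpha=alpha)
        b = Z.T @ y / n
        expected = np.sign(b) * np.maximum(np.abs(b) - alpha, 0.0)
        got = np.array([gi.weights.get(f"v{j}", 0.0) for j in range(4)])
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_lambda_zero_reproduces_ols(self, rng):
        geno, cov = orthovariate_fixture(seed=7)
        n = geno.n_samples
        Z = (geno.dosage - geno.dosage.mean(0)) / geno.dosage.std(0)
        y = Z @ np.array([0.8, -0.6, 0.3, 0.45]) + 0.1 * rng.normal(size=n)
        gi = fit_instrument(self.gene, geno, y, cov, forced_alpha=1e-12)
        ols = np.linalg.lstsq(Z - Z.mean(0), y - y.mean(), rcond=None)[0]
        got = np.array([gi.weights.get(f"v{j}", 0.0) for j in range(4)])
        np.testing.assert_allclose(got, ols, atol=1e-5)

    def test_causal_snp_selected_under_ld(self):
        # one causal SNP (20% variance) among 50 AR(1)-correlated SNPs
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            geno = generate_genotypes(
                500, 50, block_size=50, rho=0.5, seed=seed, maf_range=(0.1, 0.5)
            )
            cov = plain_covariates(500, seed=seed)
            causal = 25
            z = (geno.dosage[:, causal] - geno.dosage[:, causal].mean()) / geno.dosage[
                :, causal
            ].std()
            y = np.sqrt(0.2) * z + np.sqrt(0.8) * rng.normal(size=500)
            gi = fit_instrument(self.gene, geno, y, cov, seed=seed)
            if gi is not None and geno.variants[causal].id in gi.weights:
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_permutation_invariance(self, rng):
        geno = generate_genotypes(90, 8, seed=2, maf_range=(0.2, 0.5))
        cov = plain_covariates(90, seed=2)
        z = (geno.dosage[:, 3] - geno.dosage[:, 3].mean()) / geno.dosage[:, 3].std()
        y = 0.6 * z + rng.normal(size=90)
        gi1 = fit_instrument(self.gene, geno, y, cov, seed=5)
        perm = rng.permutation(90)
        gi2 = fit_instrument(
            self.gene,
            geno.subset_samples([geno.samples[i] for i in perm]),
            y[perm],
            cov.subset([cov.samples[i] for i in perm]),
            seed=5,
        )
        assert gi1 is not None and gi2 is not None
        assert gi1.weights.keys() == gi2.weights.keys()
        for v in gi1.weights:
            assert gi1.weights[v] == pytest.approx(gi2.weights[v], abs=1e-9)


class TestScoreInstrument:
    def test_single_unit_weight_is_standardized_dosage(self):
        geno = generate_genotypes(40, 3, seed=9, maf_range=(0.2, 0.5))
        v = geno.variants[1]
        mu, sd = geno.dosage[:, 1].mean(), geno.dosage[:, 1].std()
        gi = GeneticInstrument(
            gene_id="g", weights={v.id: 1.0}, variant_means={v.id: mu},
            variant_sds={v.id: sd}, lambda_=0.1, n_train=40,
        )
        np.testing.assert_allclose(
            score_instrument(gi, geno), (geno.dosage[:, 1] - mu) / sd
        )

    def test_all_zero_weights_unrepresentable(self):
        with pytest.raises(DataError):
            GeneticInstrument(
                gene_id="g", weights={"v": 0.0}, variant_means={"v": 1.0},
                variant_sds={"v": 0.5}, lambda_=0.1, n_train=10,
            )

    def test_missing_variant_named(self):
        geno = generate_genotypes(10, 2, seed=0)
        gi = GeneticInstrument(
            gene_id="g", weights={"nope": 1.0}, variant_means={"nope": 1.0},
            variant_sds={"nope": 0.5}, lambda_=0.1, n_train=10,
        )
        with pytest.raises(DataError, match="nope"):
            score_instrument(gi, geno)

    def test_training_score_matches_fit_predictor(self, rng):
        # scoring training samples reproduces Z @ beta from the fit
        geno = generate_genotypes(120, 10, seed=4, maf_range=(0.2, 0.5))
        cov = plain_covariates(120, seed=4)
        Z = (geno.dosage - geno.dosage.mean(0)) / geno.dosage.std(0)
        y = Z[:, 2] * 0.7 + Z[:, 6] * -0.4 + 0.5 * rng.normal(size=120)
        gi = fit_instrument(GeneAnnotation("g", "1", 1, 1000), geno, y, cov, seed=1)
        assert gi is not None
        beta = np.array([gi.weights.get(v.id, 0.0) for v in geno.variants])
        np.testing.assert_allclose(score_instrument(gi, geno), Z @ beta, atol=1e-10)


class TestNeighbours:
    def make_gi(self, gid):
        return GeneticInstrument(
            gene_id=gid, weights={"v": 1.0}, variant_means={"v": 1.0},
            variant_sds={"v": 0.5}, lambda_=0.1, n_train=10,
        )

    def test_gap_under_radius_is_neighbour(self):
        ann = {
            "a": GeneAnnotation("a", "1", 1, 2000),
            "b": GeneAnnotation("b", "1", 900_000, 901_000),
        }
        gis = {g: self.make_gi(g) for g in ann}
        out = neighbour_instruments(ann["a"], gis, ann)
        assert [g.gene_id for g in out] == ["b"]

    def test_different_chromosomes_never_neighbours(self):
        ann = {
            "a": GeneAnnotation("a", "1", 1, 2000),
            "b": GeneAnnotation("b", "2", 900_000, 901_000),
        }
        gis = {g: self.make_gi(g) for g in ann}
        assert neighbour_instruments(ann["a"], gis, ann) == []

    def test_matches_all_pairs_oracle(self, rng):
        ann = {}
        for i in range(20):
            chrom = "1" if i < 12 else "2"
            start = int(rng.integers(1, 4_000_000))
            ann[f"g{i}"] = GeneAnnotation(f"g{i}", chrom, start, start + 5000)
        gis = {g: self.make_gi(g) for g in ann}
        for gid, gene in ann.items():
            got = {g.gene_id for g in neighbour_instruments(gene, gis, ann)}
            expected = {
                other
                for other, o in ann.items()
                if other != gid and gene_distance(gene, o) < 1_000_000
            }
            assert got == expected


class TestInstrumentStrength:
    def test_duplicate_of_neighbour_adds_nothing(self, rng):
        n = 50
        cov = plain_covariates(n)
        gi = rng.normal(size=n)
        y = 0.5 * gi + rng.normal(size=n)
        s = instrument_strength(gi, y, cov, neighbour_values=gi.copy())
        assert s.f_statistic == pytest.approx(0.0, abs=1e-8)
        assert not s.keep

    def test_matches_normal_equations_oracle(self, rng):
        # 20-observation instance, F from explicit RSS difference
        n = 20
        cov = plain_covariates(n, seed=8)
        gi = rng.normal(size=n)
        neigh = rng.normal(size=(n, 2))
        y = 0.8 * gi + 0.3 * neigh[:, 0] + rng.normal(size=n)
        s = instrument_strength(gi, y, cov, neighbour_values=neigh)
        C, _ = cov.design()
        Xr = np.column_stack([np.ones(n), C, neigh])
        Xf = np.column_stack([Xr, gi])

        def rss(X):
            b = np.linalg.solve(X.T @ X, X.T @ y)
            r = y - X @ b
            return r @ r

        f_expected = (rss(Xr) - rss(Xf)) / (rss(Xf) / (n - Xf.shape[1]))
        assert s.f_statistic == pytest.approx(f_expected, abs=1e-10)
        assert s.df_den == n - Xf.shape[1]

    def test_keep_rule_is_strictly_greater(self, rng):
        n = 40
        cov = plain_covariates(n)
        gi = rng.normal(size=n)
        y = 0.5 * gi + rng.normal(size=n)
        s = instrument_strength(gi, y, cov)
        at_boundary = instrument_strength(gi, y, cov, threshold=s.f_statistic)
        assert not at_boundary.keep
        below = instrument_strength(gi, y, cov, threshold=s.f_statistic - 1e-9)
        assert below.keep

    def test_f_equals_squared_t(self, rng):
        # single-df identity between the ANOVA F and the GI coefficient's t
        from ginet._lm import add_intercept, ols

        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 30
            cov = plain_covariates(n, seed=seed)
            gi = r.normal(size=n)
            y = 0.4 * gi + r.normal(size=n)
            s = instrument_strength(gi, y, cov)
            C, _ = cov.design()
            fit = ols(add_intercept(C, gi), y)
            t = fit.coef[-1] / fit.se[-1]
            assert s.f_statistic == pytest.approx(t * t, rel=1e-10)

    def test_constant_gi_rejected(self, rng):
        cov = plain_covariates(20)
        with pytest.raises(DataError):
            instrument_strength(np.ones(20), rng.normal(size=20), cov)
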