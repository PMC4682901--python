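"""Expression-vs-SED correlation screen: oracles, filters, stratification."""

import numpy as np
import pandas as pd
import pytest

from tumorshape.screen import (
    ExpressionMatrix,
    gene_summary,
    pearson_with_p,
    screen,
    stratified_screen,
)


def _matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(values=pd.DataFrame(values, index=genes, columns=samples))


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10, dtype=float)
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_vectors(self):
        x = np.arange(10, dtype=float)
        gen = np.random.default_rng(0)
        y = gen.standard_normal(10)
        xc = x - x.mean()
        y = y - y.mean() - (y - y.mean()) @ xc / (xc @ xc) * xc  # orthogonalize
        r, p = pearson_with_p(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_permutation_oracle_n41(self, rng):
        # independent oracle: correlation p as the tail mass of the permutation null
        n = 41
        x = rng.standard_normal(n)
        y = 0.3 * x + rng.standard_normal(n)
        r_obs, p_t = pearson_with_p(x, y)
        n_perm = 40000
        perms = np.array([rng.permutation(y) for _ in range(n_perm)])
        xc = x - x.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        r_null = (pc @ xc) / np.sqrt((xc**2).sum() * (pc**2).sum(axis=1))
        p_perm = float((np.abs(r_null) >= abs(r_obs) - 1e-12).mean())
        assert p_t == pytest.approx(p_perm, abs=3 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 1e-3)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p([1.0, 2.0], [1.0, 2.0])


class TestGeneSummary:
    def test_constant_vector(self):
        assert gene_summary([5, 5, 5, 5]) == (5.0, 0.0, 0.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero-mean"):
            gene_summary([0.0, 0.0, 0.0])

    def test_matches_two_pass_brute_force(self, rng):
        v = rng.lognormal(3.0, 1.0, size=50)
        mean, sd, cv = gene_summary(v)
        m = sum(v) / len(v)
        s = (sum((x - m) ** 2 for x in v) / (len(v) - 1)) ** 0.5
        assert mean == pytest.approx(m, rel=1e-12)
        assert sd == pytest.approx(s, rel=1e-12)
        assert cv == pytest.approx(s / m, rel=1e-12)


class TestScreen:
    def _planted_matrix(self, rng, n_samples=41, n_null=495, n_planted=5, r=0.7):
        sed = rng.beta(5, 2, size=n_samples)
        z = (sed - sed.mean()) / sed.std()
        planted = 50 * np.exp(
            0.5 * (r * z + np.sqrt(1 - r**2) * rng.standard_normal((n_planted, n_samples)))
        )
        null = np.exp(rng.normal(3.0, 1.0, size=(n_null, 1)) + rng.standard_normal((n_null, n_samples)))
        genes = [f"PLANT{i}" for i in range(n_planted)] + [f"NULL{i}" for i in range(n_null)]
        samples = [f"S{i}" for i in range(n_samples)]
        mat = _matrix(np.vstack([planted, null]), genes, samples)
        return mat, dict(zip(samples, sed))

    def test_planted_genes_recovered(self, rng):
        mat, sed_map = self._planted_matrix(rng)
        hits = screen(mat, sed_map, mean_min=0.0, cv_min=0.0)
        recovered = {s for s in hits["symbol"] if s.startswith("PLANT")}
        assert len(recovered) == 5
        # ~1% of null genes expected past the p-filter alone
        n_null_hits = (hits["symbol"].str.startswith("NULL")).sum()
        assert n_null_hits <= 20

    def test_every_emitted_row_passes_all_filters(self, rng):
        mat, sed_map = self._planted_matrix(rng)
        hits = screen(mat, sed_map)
        assert (hits["p_value"] < 0.01).all()
        assert (hits["mean"] > 10).all()
        assert (hits["cv"] > 1).all()
        assert set(hits["symbol"]) <= set(mat.gene_ids)

    def test_mean_filter_rejects_strong_correlation(self):
        gen = np.random.default_rng(1)
        sed = gen.random(20)
        low = 5.0 + 0.1 * (sed - sed.mean()) / sed.std()  # r ~ 1, mean 5
        mat = _matrix([low * np.exp(gen.normal(0, 1e-3, 20))], ["lowmean"])
        sed_map = dict(zip(mat.sample_ids, sed))
        assert len(screen(mat, sed_map)) == 0
        assert len(screen(mat, sed_map, mean_min=1.0, cv_min=0.0)) == 1

    def test_strict_inequality_at_boundaries(self):
        # a gene with mean exactly 10 must be excluded by "mean > 10"
        gen = np.random.default_rng(2)
        sed = np.linspace(0.1, 0.9, 12)
        vals = np.exp(3 * (sed - sed.mean()) / sed.std() + gen.normal(0, 0.1, 12))
        vals = vals / vals.mean() * 10.0  # exact boundary
        mat = _matrix([vals], ["boundary"])
        hits = screen(mat, dict(zip(mat.sample_ids, sed)), cv_min=0.0)
        assert len(hits) == 0

    def test_empty_matrix(self):
        mat = _matrix(np.empty((0, 5)))
        assert len(screen(mat, {f"S{i}": 0.5 for i in range(5)})) == 0

    def test_negating_sed_flips_signs_and_partitions(self, rng):
        mat, sed_map = self._planted_matrix(rng)
        hits = screen(mat, sed_map, mean_min=0.0, cv_min=0.0)
        flipped = screen(mat, {k: -v for k, v in sed_map.items()}, mean_min=0.0, cv_min=0.0)
        merged = hits.merge(flipped, on="symbol", suffixes=("_a", "_b"))
        assert len(merged) == len(hits)
        np.testing.assert_allclose(merged["correlation_a"], -merged["correlation_b"], atol=1e-12)
        np.testing.assert_allclose(merged["p_value_a"], merged["p_value_b"], atol=1e-12)

    def test_output_ordering(self, rng):
        mat, sed_map = self._planted_matrix(rng, n_null=300)
        hits = screen(mat, sed_map, mean_min=0.0, cv_min=0.0)
        r = hits["correlation"].to_numpy()
        neg = r[r < 0]
        pos = r[r >= 0]
        assert np.all(np.diff(neg) >= 0) and np.all(np.diff(pos) >= 0)
        assert np.all(r[: neg.size] < 0)

    def test_no_overlap_rejected(self, rng):
        mat, _ = self._planted_matrix(rng, n_null=5)
        with pytest.raises(ValueError, match="overlap"):
            screen(mat, {"OTHER": 0.5})

    def test_false_positive_rate_on_pure_noise(self, rng):
        # validates the p computation: on null data ~1% of genes reach p<0.01
        n_genes, n, reps = 1000, 41, 5
        frac = []
        for _ in range(reps):
            sed = rng.beta(5, 2, size=n)
            mat = _matrix(rng.lognormal(3, 1, size=(n_genes, n)))
            hits = screen(mat, dict(zip(mat.sample_ids, sed)), mean_min=0.0, cv_min=0.0)
            frac.append(len(hits) / n_genes)
        assert np.mean(frac) == pytest.approx(0.01, abs=0.005)


class TestStratifiedScreen:
    def test_stratum_specific_signal(self, rng):
        n = 40
        sed = rng.beta(5, 2, size=n)
        hr = np.arange(n) < 20
        expr = np.where(
            hr, rng.lognormal(3, 0.5, n), 50 * np.exp(-2.0 * (sed - sed.mean()) / sed.std())
        )
        mat = _matrix([expr], ["G"])
        samples = mat.sample_ids
        res = stratified_screen(
            mat,
            dict(zip(samples, sed)),
            dict(zip(samples, hr)),
            genes=["G"],
        )
        r_pos = res.loc[res["stratum"] == "HR+", "correlation"].iloc[0]
        r_neg = res.loc[res["stratum"] == "HR-", "correlation"].iloc[0]
        pooled, _ = pearson_with_p(expr, sed)
        # the HR- subset carries the signal: stronger there than pooled,
        # and far stronger than in the noise-only HR+ subset
        assert abs(r_neg) > abs(pooled) > 0
        assert abs(r_neg) > 0.6 > abs(pooled) > abs(r_pos)

    def test_small_stratum_skipped_with_warning(self, rng):
        n = 10
        sed = rng.random(n)
        hr = np.array([True] * 8 + [False] * 2)
        mat = _matrix(rng.lognormal(3, 1, size=(2, n)))
        with pytest.warns(UserWarning, match="skipped"):
            res = stratified_screen(
                mat, dict(zip(mat.sample_ids, sed)), dict(zip(mat.sample_ids, hr))
            )
        assert set(res["stratum"]) == {"HR+"}

    def test_shared_structure_strata_agree_with_pooled(self, rng):
        n = 60
        sed = rng.beta(5, 2, size=n)
        z = (sed - sed.mean()) / sed.std()
        expr = 100 * np.exp(-0.8 * z + 0.3 * rng.standard_normal(n))
        hr = rng.random(n) < 0.5
        mat = _matrix([expr], ["G"])
        res = stratified_screen(
            mat, dict(zip(mat.sample_ids, sed)), dict(zip(mat.sample_ids, hr)), genes=["G"]
        )
        pooled, _ = pearson_with_p(expr, sed)
        for r in res["correlation"]:
            assert r == pytest.approx(pooled, abs=0.25)  # sampling error at n~30


class TestExpressionMatrix:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _matrix(np.ones((2, 3)), genes=["A", "A"])

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            _matrix([[1.0, -2.0, 3.0]])

    def test_tsv_round_trip(self, tmp_path, rng):
        mat = _matrix(rng.lognormal(2, 1, size=(4, 3)))
        path = tmp_path / "expr.tsv"
        mat.to_tsv(path)
        back = ExpressionMatrix.from_tsv(path)
        pd.testing.assert_frame_equal(mat.values, back.values, check_names=False)
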