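"""Distance operations against brute-force two-loop oracles and the printed
closed forms."""
import numpy as np
import pandas as pd
import pytest

from divpanel.distances import (
    combine_matrices,
    euclidean,
    gower,
    ibs_distance,
    jaccard_distance,
    mahalanobis,
    manhattan,
    nei_distance,
    rogers_distance,
)
from divpanel.formats_io import DistanceMatrix, GenotypeMatrix, PhenotypeTable


# ---------------------------------------------------------------------------
# independent oracles (plain loops, no shared code with the implementation)
# ---------------------------------------------------------------------------

def oracle_gower(df, kinds):
    n = len(df)
    out = np.zeros((n, n))
    ranges = {}
    for c in df.columns:
        if kinds[c] != "nominal":
            vals = df[c].dropna()
            ranges[c] = vals.max() - vals.min()
    for i in range(n):
        for j in range(n):
            num = den = 0.0
            for c in df.columns:
                xi, xj = df[c].iloc[i], df[c].iloc[j]
                if pd.isna(xi) or pd.isna(xj):
                    continue
                if kinds[c] == "nominal":
                    num += 0.0 if xi == xj else 1.0
                    den += 1.0
                else:
                    if ranges[c] == 0:
                        continue
                    num += abs(xi - xj) / ranges[c]
                    den += 1.0
            out[i, j] = num / den
    return out


def oracle_pair_metrics(X):
    n = len(X)
    eu = np.zeros((n, n))
    ma = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            eu[i, j] = np.sqrt(((X[i] - X[j]) ** 2).sum())
            ma[i, j] = np.abs(X[i] - X[j]).sum()
    return eu, ma


def oracle_geno(dosage):
    """IBS, Nei, Jaccard, Rogers from per-pair per-locus loops."""
    n, L = dosage.shape
    ibs = np.zeros((n, n))
    nei = np.zeros((n, n))
    jac = np.zeros((n, n))
    rog = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            share = sum(2 - abs(int(dosage[i, l]) - int(dosage[j, l])) for l in range(L))
            ibs[i, j] = 1.0 - share / (2.0 * L)
            jxy = jx = jy = 0.0
            rsum = 0.0
            for l in range(L):
                x, y = dosage[i, l] / 2.0, dosage[j, l] / 2.0
                jxy += x * y + (1 - x) * (1 - y)
                jx += x * x + (1 - x) ** 2
                jy += y * y + (1 - y) ** 2
                rsum += np.sqrt(0.5 * ((x - y) ** 2 + ((1 - x) - (1 - y)) ** 2))
            ratio = (jxy / L) / np.sqrt((jx / L) * (jy / L))
            nei[i, j] = np.inf if jxy == 0 else max(0.0, -np.log(ratio))
            rog[i, j] = rsum / L
            P, Q = dosage[i].astype(float), dosage[j].astype(float)
            denom = (P**2).sum() + (Q**2).sum() - (P * Q).sum()
            jac[i, j] = 0.0 if denom == 0 else 1.0 - (P * Q).sum() / denom
    return ibs, nei, jac, rog


# ---------------------------------------------------------------------------
# phenotypic measures
# ---------------------------------------------------------------------------

class TestGower:
    def test_printed_formula_cases(self):
        # endpoints of a quantitative range plus a differing nominal -> (1+1)/2
        data = pd.DataFrame({
            "q": [0.0, 10.0, 5.0],
            "n": pd.Categorical(["purple", "green", "purple"]),
        }, index=["a", "b", "c"])
        pt = PhenotypeTable(data, {"q": "quantitative", "n": "nominal"})
        d = gower(pt)
        assert d.values[0, 1] == pytest.approx(1.0)
        assert d.values[0, 0] == 0.0

    def test_missing_value_drops_term(self):
        data = pd.DataFrame({
            "q1": [0.0, 10.0],
            "q2": [np.nan, 3.0],
        }, index=["a", "b"])
        pt = PhenotypeTable(data, {"q1": "quantitative", "q2": "quantitative"})
        d = gower(pt)
        # only q1 contributes: |0-10|/10 = 1
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_no_shared_traits_is_error(self):
        data = pd.DataFrame({"q1": [1.0, np.nan], "q2": [np.nan, 2.0]}, index=["a", "b"])
        pt = PhenotypeTable(data, {"q1": "quantitative", "q2": "quantitative"})
        with pytest.raises(ValueError, match="a.*b|pair"):
            gower(pt)

    def test_matches_oracle_mixed_types(self, rng):
        n = 15
        data = pd.DataFrame({
            "q1": rng.normal(size=n),
            "q2": rng.uniform(0, 50, size=n),
            "o1": rng.integers(0, 5, size=n).astype(float),
            "n1": pd.Categorical(rng.choice(["x", "y", "z"], size=n)),
        }, index=[f"A{i}" for i in range(n)])
        data.loc[data.index[3], "q1"] = np.nan
        kinds = {"q1": "quantitative", "q2": "quantitative",
                 "o1": "ordinal", "n1": "nominal"}
        pt = PhenotypeTable(data, kinds, ordinal_levels={"o1": [0, 1, 2, 3, 4]})
        got = gower(pt).values
        want = oracle_gower(data, kinds)
        np.testing.assert_allclose(got, want, atol=1e-10)
        assert got.max() <= 1.0


class TestNumericMetrics:
    def test_pythagorean_raw(self):
        data = pd.DataFrame({"x": [0.0, 3.0], "y": [0.0, 4.0]}, index=["a", "b"])
        pt = PhenotypeTable(data, {"x": "quantitative", "y": "quantitative"})
        assert euclidean(pt, standardize=False).values[0, 1] == pytest.approx(5.0)
        assert manhattan(pt, standardize=False).values[0, 1] == pytest.approx(7.0)

    def test_matches_oracle(self, random_numeric_pheno):
        X = random_numeric_pheno.numeric_matrix()
        eu, ma = oracle_pair_metrics(X)
        np.testing.assert_allclose(euclidean(random_numeric_pheno, standardize=False).values,
                                   eu, atol=1e-10)
        np.testing.assert_allclose(manhattan(random_numeric_pheno, standardize=False).values,
                                   ma, atol=1e-10)

    def test_nominal_trait_rejected(self):
        data = pd.DataFrame({"x": [0.0, 1.0], "n": pd.Categorical(["a", "b"])},
                            index=["a", "b"])
        pt = PhenotypeTable(data, {"x": "quantitative", "n": "nominal"})
        with pytest.raises(ValueError, match="gower"):
            euclidean(pt)


class TestMahalanobis:
    def test_identity_covariance_equals_euclidean(self, rng):
        # whiten a random cloud so its sample covariance is the identity
        X = rng.normal(size=(30, 4))
        X -= X.mean(axis=0)
        S = np.cov(X, rowvar=False)
        L = np.linalg.cholesky(np.linalg.inv(S))
        Xw = X @ L
        ids = [f"A{i}" for i in range(30)]
        pt = PhenotypeTable(pd.DataFrame(Xw, index=ids, columns=list("abcd")),
                            {c: "quantitative" for c in "abcd"})
        np.testing.assert_allclose(mahalanobis(pt).values,
                                   euclidean(pt, standardize=False).values, atol=1e-8)

    def test_matches_solve_oracle(self, random_numeric_pheno):
        X = random_numeric_pheno.numeric_matrix()
        S = np.cov(X, rowvar=False)
        n = len(X)
        want = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                diff = X[i] - X[j]
                want[i, j] = np.sqrt(diff @ np.linalg.solve(S, diff))
        np.testing.assert_allclose(mahalanobis(random_numeric_pheno).values, want, atol=1e-10)

    def test_duplicate_trait_column_is_singular(self, rng):
        X = rng.normal(size=(20, 2))
        data = pd.DataFrame(np.column_stack([X, X[:, 0]]),
                            index=[f"A{i}" for i in range(20)], columns=["a", "b", "c"])
        pt = PhenotypeTable(data, {c: "quantitative" for c in "abc"})
        with pytest.raises(ValueError, match="singular|pseudo"):
            mahalanobis(pt)
        # pseudo-inverse route still yields a valid matrix
        dm = mahalanobis(pt, pseudo_inverse=True)
        assert np.isfinite(dm.values).all()


# ---------------------------------------------------------------------------
# genotypic measures
# ---------------------------------------------------------------------------

class TestGenotypicDistances:
    def test_single_locus_closed_forms(self):
        gm = GenotypeMatrix(["a", "b", "c"], ["L1"], np.array([[0], [1], [2]]))
        d = ibs_distance(gm).values
        assert d[0, 1] == pytest.approx(0.5)   # AA vs Aa share 1 of 2
        assert d[0, 2] == pytest.approx(1.0)   # opposite homozygotes share 0
        r = rogers_distance(gm).values
        assert r[0, 2] == pytest.approx(1.0)   # sqrt(0.5*(1+1)) = 1
        nei = nei_distance(gm)
        assert np.isinf(nei.values[0, 2]) and nei.has_infinite  # Jxy = 0

    def test_identical_profiles_are_zero(self, random_genotypes):
        for fn in (ibs_distance, nei_distance, jaccard_distance, rogers_distance):
            d = fn(random_genotypes).values
            assert np.allclose(np.diag(d), 0.0)

    def test_jaccard_orthogonal_vectors(self):
        gm = GenotypeMatrix(["a", "b"], ["L1", "L2"], np.array([[1, 0], [0, 2]]))
        assert jaccard_distance(gm).values[0, 1] == pytest.approx(1.0)

    def test_all_match_oracles(self, random_genotypes):
        ibs_o, nei_o, jac_o, rog_o = oracle_geno(random_genotypes.dosage)
        np.testing.assert_allclose(ibs_distance(random_genotypes).values, ibs_o, atol=1e-10)
        np.testing.assert_allclose(nei_distance(random_genotypes).values, nei_o, atol=1e-10)
        np.testing.assert_allclose(jaccard_distance(random_genotypes).values, jac_o, atol=1e-12)
        np.testing.assert_allclose(rogers_distance(random_genotypes).values, rog_o, atol=1e-12)

    def test_ibs_rogers_coincide_on_homozygotes(self, rng):
        dosage = rng.choice([0, 2], size=(10, 30)).astype(np.int8)
        gm = GenotypeMatrix([f"A{i}" for i in range(10)],
                            [f"L{j}" for j in range(30)], dosage)
        ibs_o, _, _, rog_o = oracle_geno(dosage)
        np.testing.assert_allclose(ibs_distance(gm).values, ibs_o, atol=1e-12)
        np.testing.assert_allclose(rogers_distance(gm).values, rog_o, atol=1e-12)
        np.testing.assert_allclose(ibs_distance(gm).values, rogers_distance(gm).values,
                                   atol=1e-12)

    def test_missing_dosage_rejected(self):
        gm = GenotypeMatrix(["a", "b"], ["L1"], np.array([[0], [-1]]))
        with pytest.raises(ValueError, match="missing"):
            ibs_distance(gm)

    def test_label_equivariance(self, random_genotypes, rng):
        perm = rng.permutation(random_genotypes.n_accessions)
        ids = [random_genotypes.accession_ids[i] for i in perm]
        gm_p = random_genotypes.take_accessions(ids)
        d = ibs_distance(random_genotypes)
        d_p = ibs_distance(gm_p)
        np.testing.assert_allclose(d_p.values, d.reorder(ids).values, atol=1e-12)


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

class TestCombine:
    def _pair(self, rng):
        from conftest import random_distance_matrix
        a = random_distance_matrix(rng, 6)
        b = random_distance_matrix(rng, 6, labels=a.labels)
        return a, b

    def test_weight_extremes(self, rng):
        a, b = self._pair(rng)
        np.testing.assert_allclose(combine_matrices(a, b, weight=1.0).values,
                                   a.values / a.values.max(), atol=1e-12)
        np.testing.assert_allclose(combine_matrices(a, b, weight=0.0).values,
                                   b.values / b.values.max(), atol=1e-12)

    def test_hand_computed_mean(self):
        labels = ["a", "b", "c"]
        a = DistanceMatrix(labels, np.array([[0, 2.0, 4.0], [2.0, 0, 2.0], [4.0, 2.0, 0]]))
        b = DistanceMatrix(labels, np.array([[0, 1.0, 1.0], [1.0, 0, 0.5], [1.0, 0.5, 0]]))
        got = combine_matrices(a, b, weight=0.5).values
        want = 0.5 * a.values / 4.0 + 0.5 * b.values / 1.0
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_identical_inputs_pass_through(self, rng):
        a, _ = self._pair(rng)
        np.testing.assert_allclose(combine_matrices(a, a).values,
                                   a.values / a.values.max(), atol=1e-12)

    def test_label_mismatch_reported(self, rng):
        from conftest import random_distance_matrix
        a = random_distance_matrix(rng, 4, labels=list("abcd"))
        b = random_distance_matrix(rng, 4, labels=list("abce"))
        with pytest.raises(Exception, match="mismatch"):
            combine_matrices(a, b)
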