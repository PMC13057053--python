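"""MGIDI chain against an independently coded eigen/varimax/projection oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from germqtl import (
    FactorModel,
    factor_analysis,
    mgidi_index,
    rescale_trait,
    run_mgidi,
    select_genotypes,
    selection_gain,
)
from germqtl.errors import DataWarning, InvalidInputError
from germqtl.germination import TraitTable
from germqtl.mgidi import varimax


# --------------------------------------------------------------- the oracle

def varimax_pairwise(a, n_sweeps=200, tol=1e-12):
    """Classical planar-rotation varimax (Kaiser), independent of the
    package's SVD implementation."""
    a = np.array(a, dtype=float)
    p, k = a.shape
    h = np.sqrt((a ** 2).sum(axis=1))
    h[h == 0] = 1.0
    a = a / h[:, None]

    def criterion(m):
        return sum(np.var(m[:, j] ** 2) for j in range(k))

    for _ in range(n_sweeps):
        before = criterion(a)
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = a[:, i], a[:, j]
                u = x ** 2 - y ** 2
                v = 2 * x * y
                num = 2 * (p * (u * v).sum() - u.sum() * v.sum())
                den = p * (u ** 2 - v ** 2).sum() - (u.sum() ** 2 - v.sum() ** 2)
                phi = 0.25 * math.atan2(num, den)
                c, s = math.cos(phi), math.sin(phi)
                a[:, i], a[:, j] = c * x + s * y, -s * x + c * y
        if criterion(a) - before < tol:
            break
    return a * h[:, None]


def oracle_chain(rescaled):
    """Direct eigen + score projection without any rotation.  MGIDI is
    invariant under orthogonal rotation of the factor space, so distances
    from this chain must match the rotated pipeline exactly."""
    x = rescaled.to_numpy(dtype=float)
    mu, sd = x.mean(0), x.std(0, ddof=1)
    z = (x - mu) / sd
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    f = max(int((eigval >= 1).sum()), 1)
    lam = eigvec[:, :f] * np.sqrt(eigval[:f])
    w = np.linalg.inv(corr) @ lam
    scores = z @ w
    ideo = ((100.0 - mu) / sd) @ w
    return np.sqrt(((scores - ideo) ** 2).sum(axis=1))


def fixture_5x4(seed=3):
    rng = np.random.default_rng(seed)
    base = rng.uniform(0, 100, size=(5, 2))
    x = np.column_stack([base[:, 0], base[:, 0] * 0.8 + rng.uniform(0, 8, 5),
                         base[:, 1], base[:, 1] * 0.9 + rng.uniform(0, 8, 5)])
    return pd.DataFrame(x, index=[f"G{i}" for i in range(5)],
                        columns=list("abcd"))


# -------------------------------------------------------------------- tests

class TestRescale:
    def test_increase(self):
        assert np.allclose(rescale_trait([1, 2, 3], "increase"), [0, 50, 100])

    def test_decrease(self):
        assert np.allclose(rescale_trait([1, 2, 3], "decrease"), [100, 50, 0])

    def test_idempotent(self):
        once = rescale_trait([2.0, 5.0, 11.0], "increase")
        assert np.allclose(rescale_trait(once, "increase"), once)

    def test_constant_rejected(self):
        with pytest.raises(InvalidInputError):
            rescale_trait([4.0, 4.0, 4.0], "increase")


class TestFactorAnalysis:
    def test_eigenvalue_trace_identity(self):
        fm = factor_analysis(fixture_5x4())
        assert fm.eigenvalues.sum() == pytest.approx(4.0, rel=1e-9)

    def test_duplicated_blocks_split_into_two_factors(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 100, size=20)
        b = rng.uniform(0, 100, size=20)
        df = pd.DataFrame({
            "a1": a, "a2": a + rng.normal(0, 2, 20),
            "b1": b, "b2": b + rng.normal(0, 2, 20)})
        fm = factor_analysis(df)
        assert fm.n_factors == 2
        # after rotation each block loads dominantly on its own factor
        lam = fm.loadings_rotated.abs()
        assert lam.loc["a1"].idxmax() == lam.loc["a2"].idxmax()
        assert lam.loc["b1"].idxmax() == lam.loc["b2"].idxmax()
        assert lam.loc["a1"].idxmax() != lam.loc["b1"].idxmax()

    def test_varimax_matches_pairwise_rotation_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, size=(6, 2))
        ours = varimax(a)[0]
        ref = varimax_pairwise(a)
        # align columns and signs before comparing
        perm = [int(np.argmax(np.abs(ref.T @ ours)[:, j])) for j in range(2)]
        aligned = ref[:, perm] * np.sign(np.diag(ours.T @ ref[:, perm]))
        assert np.allclose(ours, aligned, atol=1e-6)

    def test_mgidi_matches_unrotated_oracle(self):
        df = fixture_5x4()
        res = mgidi_index(factor_analysis(df))
        assert np.allclose(res.mgidi.to_numpy(), oracle_chain(df), atol=1e-8)


class TestMgidiIndex:
    def hand_model(self):
        scores = pd.DataFrame([[0.0, 0.0], [3.0, 4.0], [1.0, 1.0]],
                              index=["I", "F", "E"], columns=["FA1", "FA2"])
        ideo = pd.Series([0.0, 0.0], index=["FA1", "FA2"])
        df = pd.DataFrame(np.ones((3, 2)) * 50, index=scores.index,
                          columns=["x", "y"])
        return FactorModel(
            rescaled=df, trait_means=df.mean(), trait_sds=df.std(),
            correlation=pd.DataFrame(np.eye(2)), eigenvalues=np.array([1.0, 1.0]),
            n_factors=2, loadings_rotated=pd.DataFrame(np.eye(2)),
            scores=scores, ideotype_scores=ideo)

    def test_euclidean_distance_and_omega(self):
        with pytest.warns(DataWarning):  # genotype exactly at the ideotype
            res = mgidi_index(self.hand_model())
        assert res.mgidi["I"] == 0.0
        assert res.mgidi["F"] == pytest.approx(5.0)
        assert np.allclose(res.omega.loc["F"], [3 / 7, 4 / 7])
        assert np.allclose(res.omega.loc["E"], [0.5, 0.5])
        assert np.allclose(res.omega.loc["I"], [0.5, 0.5])  # uniform fallback
        assert np.allclose(res.omega.sum(axis=1), 1.0)

    def test_genotype_at_ideotype_has_zero_mgidi(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.uniform(10, 90, size=(8, 3)),
                          columns=["t1", "t2", "t3"])
        df.iloc[0] = 100.0  # best in every trait
        df = 100 * (df - df.min()) / (df.max() - df.min())
        res = mgidi_index(factor_analysis(df))
        assert res.mgidi.iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert res.rank.iloc[0] == 1

    def test_invariance_to_trait_and_genotype_permutation(self):
        df = fixture_5x4()
        res = mgidi_index(factor_analysis(df))
        shuffled = df[["c", "a", "d", "b"]].iloc[[3, 1, 4, 0, 2]]
        res2 = mgidi_index(factor_analysis(shuffled))
        assert np.allclose(res.mgidi.sort_index().to_numpy(),
                           res2.mgidi.sort_index().to_numpy(), atol=1e-9)

    def test_single_factor_ranking_matches_score_distance(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(0, 100, size=12)
        df = pd.DataFrame({f"t{j}": base + rng.normal(0, 3, 12)
                           for j in range(4)})
        fm = factor_analysis(df)
        assert fm.n_factors == 1
        res = mgidi_index(fm)
        dist = (fm.scores["FA1"] - fm.ideotype_scores["FA1"]).abs()
        assert (res.mgidi.rank() == dist.rank()).all()


class TestSelection:
    def series(self, values):
        mgidi = pd.Series(values, index=[f"G{i}" for i in range(len(values))])
        fm = None
        from germqtl.mgidi import MgidiResult
        return MgidiResult(mgidi=mgidi, rank=mgidi.rank(method="first").astype(int),
                           omega=pd.DataFrame(index=mgidi.index), factor_model=fm)

    def test_fifteen_percent_of_65_selects_ten(self, rng):
        res = self.series(rng.uniform(2, 9, size=65))
        selected, cut = select_genotypes(res, 0.15)
        assert len(selected) == 10
        assert cut == sorted(res.mgidi)[9]

    def test_minimal_pressure_selects_single_best(self, rng):
        res = self.series(rng.uniform(2, 9, size=20))
        selected, _ = select_genotypes(res, 1 / 20)
        assert selected == [res.mgidi.idxmin()]

    def test_ties_keep_input_order_with_warning(self):
        res = self.series([1.0] * 10)
        with pytest.warns(DataWarning):
            selected, _ = select_genotypes(res, 0.25)
        assert selected == ["G0", "G1", "G2"]

    def test_bad_pressure(self):
        with pytest.raises(InvalidInputError):
            select_genotypes(self.series([1.0, 2.0]), 1.5)


class TestSelectionGain:
    def table(self):
        df = pd.DataFrame({"up_C": [1.0, 2, 3, 4], "MGT_C": [4.0, 3, 2, 1]},
                          index=list("abcd"))
        return TraitTable(df)

    def test_all_selected_gain_zero(self):
        out = selection_gain(self.table(), list("abcd"))
        assert np.allclose(out["sg_pct"], 0.0)

    def test_top_genotype_of_monotone_trait(self):
        out = selection_gain(self.table(), ["d"])
        assert out.loc["up_C", "sg_pct"] == pytest.approx(100 * (4 - 2.5) / 2.5)
        assert out.loc["up_C", "desirable"]
        assert out.loc["MGT_C", "sg_pct"] < 0 and out.loc["MGT_C", "desirable"]

    def test_planted_superior_subset_signs(self, rng):
        # genotypes 0-4 uniformly better: gains must track trait direction
        hits = 0
        trials = 100
        for _ in range(trials):
            n = 30
            good = np.zeros(n)
            good[:5] = 1.0
            df = pd.DataFrame({
                "inc_C": good * 2 + rng.normal(0, 0.5, n) + 5,
                "MGT_C": -good * 2 + rng.normal(0, 0.5, n) + 5})
            out = selection_gain(TraitTable(df), [df.index[i] for i in range(5)])
            hits += int(out["desirable"].all())
        assert hits >= 95


class TestRunMgidi:
    def test_full_chain_on_simulated_traits(self, default_dataset):
        import germqtl

        tt = germqtl.assemble_trait_table(
            default_dataset.time_courses(), default_dataset.seedling_records())
        cols = [c for c in tt.data.columns
                if c.endswith("_D") and not c.endswith("_DN")]
        sub = TraitTable(tt.data[cols], {c: tt.directions[c] for c in cols})
        res = run_mgidi(sub, pressure=0.15)
        assert len(res.selected) == 10
        assert (res.mgidi >= 0).all()
        assert np.allclose(res.omega.sum(axis=1), 1.0)
        assert res.selection_gain["sg_pct"].notna().all()
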