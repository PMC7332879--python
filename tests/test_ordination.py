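"""Jaccard/NMDS/Ward ordination and Pareto-scaled PCA."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from residomics.align import AlignedMatrix
from residomics.ordination import (feature_count_summary, jaccard_distances,
                                   kruskal_stress, nmds, pareto_pca,
                                   pareto_scale, ward_cluster,
                                   ward_merge_heights)


class TestJaccard:
    def test_identical_zero(self):
        d = jaccard_distances({"a": {1, 2, 3}, "b": {1, 2, 3}})
        assert d.loc["a", "b"] == 0.0

    def test_disjoint_one(self):
        d = jaccard_distances({"a": {1, 2}, "b": {3, 4}})
        assert d.loc["a", "b"] == 1.0

    def test_hand_arithmetic(self):
        # |a & b| = 5, |a | b| = 20 -> d = 0.75
        a = set(range(0, 15))
        b = set(range(10, 20))
        d = jaccard_distances({"a": a, "b": b})
        assert d.loc["a", "b"] == pytest.approx(0.75)

    def test_both_empty_zero_logged(self, caplog):
        with caplog.at_level("WARNING"):
            d = jaccard_distances({"a": set(), "b": set()})
        assert d.loc["a", "b"] == 0.0
        assert "empty" in caplog.text

    def test_triangle_inequality_random_triples(self):
        rng = np.random.default_rng(2)
        universe = list(range(60))
        sets = {f"s{i}": set(rng.choice(universe, size=rng.integers(5, 40),
                                        replace=False).tolist())
                for i in range(8)}
        d = jaccard_distances(sets)
        names = list(d.index)
        for _ in range(60):
            a, b, c = rng.choice(names, 3, replace=False)
            assert d.loc[a, c] <= d.loc[a, b] + d.loc[b, c] + 1e-12


class TestNMDS:
    def dist_of(self, coords):
        names = [f"p{i}" for i in range(len(coords))]
        coords = np.asarray(coords, dtype=float)
        d = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        return pd.DataFrame(d, index=names, columns=names)

    def test_equilateral_zero_stress(self):
        d = self.dist_of([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        ordn = nmds(d, k=2, n_starts=8, seed=0)
        assert ordn.stress == pytest.approx(0.0, abs=1e-4)

    def test_duplicated_sample_near_coincident(self):
        d = self.dist_of([[0, 0], [0, 0], [3, 0], [0, 4], [3, 4]])
        ordn = nmds(d, k=2, n_starts=8, seed=0)
        c = ordn.coords.to_numpy()
        scale = np.abs(c).max()
        assert np.linalg.norm(c[0] - c[1]) < 0.05 * scale

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(size=(7, 3))
        d = self.dist_of(pts)
        o1 = nmds(d, k=2, n_starts=5, seed=42)
        o2 = nmds(d, k=2, n_starts=5, seed=42)
        np.testing.assert_array_equal(o1.coords.to_numpy(), o2.coords.to_numpy())
        assert o1.stress == o2.stress

    def test_reported_stress_matches_independent_recomputation(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(size=(8, 4))
        d = self.dist_of(pts)
        ordn = nmds(d, k=2, n_starts=5, seed=3)

        # independent stress-1: PAVA isotonic regression written inline
        coords = ordn.coords.to_numpy()
        iu = np.triu_indices(8, k=1)
        delta = d.to_numpy()[iu]
        emb = np.sqrt(((coords[iu[0]] - coords[iu[1]]) ** 2).sum(axis=1))
        order = np.argsort(delta, kind="stable")
        y = emb[order].astype(float)
        w = np.ones_like(y)
        # pool-adjacent-violators
        blocks = [[y[i], w[i]] for i in range(len(y))]
        merged = []
        for val, wt in blocks:
            merged.append([val, wt])
            while len(merged) > 1 and merged[-2][0] > merged[-1][0]:
                v2, w2 = merged.pop()
                v1, w1 = merged.pop()
                merged.append([(v1 * w1 + v2 * w2) / (w1 + w2), w1 + w2])
        fitted = np.concatenate([[v] * int(wt) for v, wt in merged])
        dhat = np.empty_like(emb)
        dhat[order] = fitted
        stress = np.sqrt(((emb - dhat) ** 2).sum() / (emb ** 2).sum())
        assert ordn.stress == pytest.approx(stress, abs=1e-6)

    def test_k_too_large_rejected(self):
        d = self.dist_of([[0, 0], [1, 1]])
        with pytest.raises(ValueError):
            nmds(d, k=2)


class TestWard:
    def test_two_well_separated_groups(self):
        pts = np.array([[0, 0], [0.1, 0], [0, 0.1], [5, 5], [5.1, 5], [5, 5.1]])
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        df = pd.DataFrame(d, index=list("abcdef"), columns=list("abcdef"))
        labels = ward_cluster(df, n_clusters=2)
        assert len(set(labels[list("abc")])) == 1
        assert len(set(labels[list("def")])) == 1
        assert labels["a"] != labels["f"]

    def test_matches_r_hclust_ward_d(self, tmp_path):
        # cross-check merge heights against R's hclust(method="ward.D")
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(8)
        pts = rng.uniform(size=(6, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        df = pd.DataFrame(d, index=[f"s{i}" for i in range(6)],
                          columns=[f"s{i}" for i in range(6)])
        csv = tmp_path / "d.csv"
        df.to_csv(csv)
        script = tmp_path / "ward.R"
        script.write_text(textwrap.dedent(f"""
            d <- as.matrix(read.csv("{csv}", row.names = 1))
            h <- hclust(as.dist(d), method = "ward.D")
            cat(sprintf("%.10f", h$height), sep = "\\n")
        """))
        res = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=120)
        assert res.returncode == 0, res.stderr
        r_heights = [float(x) for x in res.stdout.split()]
        mine = ward_merge_heights(df)
        np.testing.assert_allclose(mine, r_heights, rtol=1e-8)


def demo_matrix(n_rows=12, n_cols=5, seed=0):
    rng = np.random.default_rng(seed)
    ab = rng.lognormal(11, 1, size=(n_rows, n_cols))
    ab[rng.uniform(size=ab.shape) < 0.3] = np.nan
    ab = pd.DataFrame(ab, index=pd.RangeIndex(n_rows, name="row_id"),
                      columns=[f"r{i}" for i in range(n_cols)])
    rm = pd.DataFrame({"mz": rng.uniform(100, 1200, n_rows),
                       "rt": rng.uniform(1, 12, n_rows)}, index=ab.index)
    cm = pd.DataFrame({
        "sample": [f"s{i % 2}" for i in range(n_cols)],
        "role": ["species_ref"] * n_cols,
        "solvent": ["TA", "APW", "MTBE", "TA", "APW"][:n_cols],
        "species": ["A", "A", "A", "B", "B"][:n_cols],
    }, index=ab.columns)
    return AlignedMatrix(ab, rm, cm)


class TestParetoPCA:
    def test_post_scaling_variance_equals_pre_scaling_sd(self):
        X = demo_matrix().abundance.T.fillna(0.0)
        scaled = pareto_scale(X)
        np.testing.assert_allclose(scaled.var(axis=0, ddof=1).to_numpy(),
                                   X.std(axis=0, ddof=1).to_numpy(),
                                   rtol=0, atol=1e-9)

    def test_full_rank_variance_fractions_sum_to_one(self):
        m = demo_matrix()
        k = min(m.abundance.shape[1], m.n_rows) - 1
        ordn = pareto_pca(m, k=k)
        assert ordn.explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_samples_identical_scores(self):
        m = demo_matrix()
        m.abundance["r1"] = m.abundance["r0"]
        ordn = pareto_pca(m, k=2)
        np.testing.assert_allclose(ordn.coords.loc["r0"], ordn.coords.loc["r1"],
                                   atol=1e-9)

    def test_zero_variance_feature_dropped_with_warning(self, caplog):
        m = demo_matrix()
        m.abundance.iloc[0, :] = 7.0
        with caplog.at_level("WARNING"):
            ordn = pareto_pca(m, k=2)
        assert "zero-variance" in caplog.text
        assert 0 not in ordn.loadings.index

    def test_scores_sample_order_invariant_up_to_sign(self):
        m = demo_matrix()
        o1 = pareto_pca(m, k=2)
        perm = list(m.abundance.columns[::-1])
        m2 = AlignedMatrix(m.abundance[perm], m.row_meta,
                           m.col_meta.loc[perm], token=m.token)
        o2 = pareto_pca(m2, k=2)
        for col in o1.coords.columns:
            a = o1.coords[col].sort_index()
            b = o2.coords[col].sort_index()
            assert (np.allclose(a, b, atol=1e-8)
                    or np.allclose(a, -b, atol=1e-8))


class TestFeatureCounts:
    def test_per_run_count_is_filled_cells(self):
        m = demo_matrix()
        out = feature_count_summary(m, group_by="solvent")
        manual = m.abundance.notna().sum(axis=0)
        manual_means = manual.groupby(m.col_meta["solvent"]).mean()
        got = out.set_index("solvent")["mean"]
        for solv in manual_means.index:
            assert got[solv] == pytest.approx(manual_means[solv])

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError):
            feature_count_summary(demo_matrix(), group_by="nope")

    def test_empty_matrix(self):
        m = demo_matrix()
        empty = AlignedMatrix(m.abundance.iloc[:0], m.row_meta.iloc[:0],
                              m.col_meta, token=m.token)
        out = feature_count_summary(empty, group_by="solvent")
        assert (out["mean"] == 0).all()
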