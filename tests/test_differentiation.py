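"""Weir-Cockerham Fst, differentiation bins, selection scan, UPGMA, PCA."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from cnpop import (
    SimulationConfig,
    classify_differentiation,
    distance_tree,
    pairwise_fst_matrix,
    pca,
    selection_scan,
    simulate_dataset,
    wc_fst,
)
from cnpop.data import MISSING
from cnpop.differentiation import (
    _bipartitions,
    _linkage_to_newick,
    individual_distance_matrix,
)
from conftest import matrix_from_cn


def wc_fst_oracle(genos_a, genos_b):
    """Independent WC84 theta via the ANOVA mean-squares route (Weir 1996).

    genos_* are lists of (allele, allele) pairs. Per allele j:
    MSP = sum_i n_i (p_i - pbar)^2 / (r - 1),
    MSI = sum_i n_i (p_i(1-p_i) - h_i/4) / (sum n_i - r) * 2,
    MSG = (1/2) sum h_i n_i / sum n_i,
    with expectations E[MSG] = c, E[MSI] = c + 2b, E[MSP] = c + 2b + 2 nc a;
    components are recovered as a = (MSP - MSI)/(2 nc), b = (MSI - MSG)/2,
    c = MSG and summed over alleles.
    """
    groups = [np.asarray(genos_a), np.asarray(genos_b)]
    r = 2
    ns = np.array([len(g) for g in groups], dtype=float)
    nsum = ns.sum()
    nc = (nsum - (ns ** 2).sum() / nsum) / (r - 1)
    alleles = sorted({int(a) for g in groups for pair in g for a in pair})
    A = B = C = 0.0
    for j in alleles:
        ps = np.array([(g == j).mean() for g in groups])
        hs = np.array([((g == j).sum(axis=1) == 1).mean() for g in groups])
        pbar = (ns * ps).sum() / nsum
        if pbar in (0.0, 1.0):
            continue
        msp = 2 * (ns * (ps - pbar) ** 2).sum() / (r - 1)
        msi = (2 * ns * (ps * (1 - ps) - hs / 4)).sum() / (nsum - r)
        msg = (ns * hs).sum() / (2 * nsum)
        A += (msp - msi) / (2 * nc)
        B += (msi - msg) / 2
        C += msg
    return A / (A + B + C)


def pairs_of(cn_row):
    from cnpop.data import ALLELE_PAIRS

    return [tuple(ALLELE_PAIRS[c]) for c in cn_row]


class TestWcFst:
    def test_fixed_difference_theta_one(self):
        # pop A fixed CN 0 (allele 0), pop B fixed CN 2 (allele 1)
        cn = np.array([[0] * 20 + [2] * 20])
        gm = matrix_from_cn(cn, ["A"] * 20 + ["B"] * 20)
        assert wc_fst(gm, "A", "B").theta == pytest.approx(1.0)

    def test_all_heterozygote_theta_zero(self):
        # every individual CN 1 = (0,1): s2 = 0 and a = 0 exactly
        cn = np.array([[1] * 30])
        gm = matrix_from_cn(cn, ["A"] * 15 + ["B"] * 15)
        res = wc_fst(gm, "A", "B")
        assert res.theta == pytest.approx(0.0, abs=1e-12)

    def test_identical_tables_small_magnitude(self):
        # identical genotype tables: theta is not exactly 0 under WC84's
        # small-sample correction, but must be non-positive and small
        row = [0] * 4 + [1] * 8 + [2] * 8
        cn = np.array([row + row])
        gm = matrix_from_cn(cn, ["A"] * 20 + ["B"] * 20)
        res = wc_fst(gm, "A", "B")
        assert res.theta <= 0
        assert abs(res.theta) < 0.05

    def test_matches_anova_oracle_biallelic(self):
        rng = np.random.default_rng(3)
        cn = rng.choice([0, 1, 2], size=(25, 60), p=[0.2, 0.4, 0.4])
        gm = matrix_from_cn(cn, ["A"] * 25 + ["B"] * 35)
        res = wc_fst(gm, "A", "B")
        for l in range(25):
            exp = wc_fst_oracle(pairs_of(cn[l, :25]), pairs_of(cn[l, 25:]))
            assert res.per_locus["theta"].iloc[l] == pytest.approx(exp, abs=1e-10)

    def test_matches_anova_oracle_multiallelic(self):
        rng = np.random.default_rng(4)
        cn = rng.choice(7, size=(15, 50))
        gm = matrix_from_cn(cn, ["A"] * 20 + ["B"] * 30)
        res = wc_fst(gm, "A", "B")
        for l in range(15):
            exp = wc_fst_oracle(pairs_of(cn[l, :20]), pairs_of(cn[l, 20:]))
            assert res.per_locus["theta"].iloc[l] == pytest.approx(exp, abs=1e-10)

    def test_multilocus_is_ratio_of_sums(self):
        rng = np.random.default_rng(5)
        cn = rng.choice([0, 1, 2], size=(30, 40))
        gm = matrix_from_cn(cn, ["A"] * 20 + ["B"] * 20)
        res = wc_fst(gm, "A", "B")
        pl = res.per_locus.dropna()
        expected = pl["a"].sum() / (pl["a"] + pl["b"] + pl["c"]).sum()
        assert res.theta == pytest.approx(expected)
        assert res.theta != pytest.approx(pl["theta"].mean(), abs=1e-6)

    def test_monomorphic_locus_excluded(self):
        cn = np.array([[2] * 20, [0] * 10 + [2] * 10])
        gm = matrix_from_cn(cn, ["A"] * 10 + ["B"] * 10)
        res = wc_fst(gm, "A", "B")
        assert np.isnan(res.per_locus["theta"].iloc[0])
        assert res.n_loci_used == 1

    def test_min_per_pop_exclusion(self):
        cn = np.array([[0, MISSING, 2, 2, 0, 2]])
        gm = matrix_from_cn(cn, ["A"] * 3 + ["B"] * 3)
        assert wc_fst(gm, "A", "B", min_per_pop=3).n_loci_used == 0
        assert wc_fst(gm, "A", "B", min_per_pop=2).n_loci_used == 1

    @pytest.mark.parametrize("f,lo,hi", [(0.01, 0.0, 0.025), (0.05, 0.04, 0.06), (0.15, 0.11, 0.20)])
    def test_balding_nichols_recovery(self, f, lo, hi):
        cfg = SimulationConfig(
            n_populations=2, n_individuals=100, n_loci=500, F=f,
            architecture_mix=(0.6, 0.2, 0.2), seed=17,
        )
        gm, _ = simulate_dataset(cfg)
        theta = wc_fst(gm, "P1", "P2").theta
        assert lo <= theta <= hi

    def test_pairwise_matrix_symmetric(self, three_pop_dataset):
        gm, _ = three_pop_dataset
        mat, results = pairwise_fst_matrix(gm)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T, equal_nan=True)
        assert np.isnan(np.diag(mat)).all()
        assert len(results) == 3
        assert mat.loc["P1", "P2"] == results[("P1", "P2")].theta


class TestDifferentiationBins:
    @pytest.mark.parametrize("theta,label", [
        (0.022, "weak"), (0.083, "moderate"), (0.30, "very-high"),
        (0.05, "weak"), (0.15, "moderate"), (0.25, "high"),
        (0.0500001, "moderate"), (-0.01, "weak"), (0.16, "high"),
    ])
    def test_bins(self, theta, label):
        assert classify_differentiation(theta) == label

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_differentiation(float("nan"))


class TestSelectionScan:
    def _results_with_thetas(self, thetas, pair=("A", "B")):
        from cnpop.differentiation import FstResult

        idx = pd.Index([f"CNP{i + 1}" for i in range(len(thetas))], name="locus")
        pl = pd.DataFrame({"a": np.nan, "b": np.nan, "c": np.nan, "theta": thetas}, index=idx)
        return {pair: FstResult(pair[0], pair[1], pl, 0.1, int(np.isfinite(thetas).sum()))}

    def test_top_one_percent_of_1000(self):
        rng = np.random.default_rng(0)
        thetas = rng.uniform(0, 0.1, 1000)
        res = self._results_with_thetas(thetas)
        per_pair, union = selection_scan(res, top_fraction=0.01)
        assert len(per_pair[("A", "B")]) == 10
        order = np.argsort(thetas)[::-1][:10]
        assert set(union) == {f"CNP{i + 1}" for i in order}

    def test_fraction_one_selects_all_ranked(self):
        thetas = np.array([0.1, np.nan, 0.2, 0.05] * 30)
        res = self._results_with_thetas(thetas)
        per_pair, _ = selection_scan(res, top_fraction=1.0)
        assert len(per_pair[("A", "B")]) == 90  # NaN loci excluded

    def test_ties_break_by_locus_id(self):
        thetas = np.full(200, 0.05)
        res = self._results_with_thetas(thetas)
        per_pair, _ = selection_scan(res, top_fraction=0.01)
        assert per_pair[("A", "B")] == ["CNP1", "CNP10"]

    def test_specific_loci_added_to_union(self):
        res = self._results_with_thetas(np.linspace(0, 0.1, 100))
        _, union = selection_scan(res, top_fraction=0.01, specific_loci=["EXTRA"])
        assert "EXTRA" in union

    def test_invalid_fraction(self):
        res = self._results_with_thetas(np.linspace(0, 0.1, 100))
        with pytest.raises(ValueError):
            selection_scan(res, top_fraction=0.0)

    def test_small_family_warns(self):
        res = self._results_with_thetas(np.linspace(0, 0.1, 20))
        with pytest.warns(UserWarning, match="noisy"):
            selection_scan(res, top_fraction=0.5)


def test_designed_outlier_detected():
    """A locus with a fixed difference lands in the top 1% of the scan."""
    cfg = SimulationConfig(
        n_populations=2, n_individuals=80, n_loci=199, F=0.02,
        architecture_mix=(1.0, 0.0, 0.0), seed=29,
    )
    gm, _ = simulate_dataset(cfg)
    outlier = np.concatenate([
        np.zeros((1, 80), dtype=np.int16), np.full((1, 80), 2, np.int16)
    ], axis=1)
    loci = pd.concat([
        gm.loci,
        pd.DataFrame({"id": ["OUTLIER"], "chrom": ["chr1"], "start": [900_000_000], "end": [900_005_000]}),
    ], ignore_index=True)
    from cnpop import GenotypeMatrix

    gm2 = GenotypeMatrix(loci, gm.samples, gm.populations, np.vstack([gm.cn, outlier]))
    res = wc_fst(gm2, "P1", "P2")
    per_pair, union = selection_scan({("P1", "P2"): res}, top_fraction=0.01)
    assert "OUTLIER" in union


class TestDistances:
    def test_euclidean_no_missing(self):
        cn = np.array([[0, 2], [2, 2], [4, 2], [2, 2]])
        d = individual_distance_matrix(cn)
        # samples differ by (2,0,2,0): distance sqrt(8)
        assert d[0, 1] == pytest.approx(np.sqrt(8))
        assert d[0, 0] == 0

    def test_missing_rescaled(self):
        # 4 loci, one masked for sample 2: d^2 over 3 shared loci scaled by 4/3
        cn = np.array([[0, 2], [2, 2], [4, MISSING], [2, 0]])
        d = individual_distance_matrix(cn)
        assert d[0, 1] == pytest.approx(np.sqrt((4 + 0 + 4) * 4 / 3))

    def test_zero_shared_loci_error(self):
        cn = np.array([[0, MISSING], [MISSING, 2]])
        with pytest.raises(ValueError, match="zero genotyped loci"):
            individual_distance_matrix(cn)


class TestUpgma:
    def test_three_taxon_heights(self):
        # d(A,B)=2, d(A,C)=d(B,C)=8 -> join heights 1 then 4
        from cnpop.differentiation import _upgma

        dmat = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float)
        Z = _upgma(dmat)
        assert Z[0, 2] == pytest.approx(2)
        assert Z[1, 2] == pytest.approx(8)
        nwk = _linkage_to_newick(Z, ["A", "B", "C"])
        assert nwk == "(C:4,(A:1,B:1):3);"

    def test_four_taxon_hand_case(self):
        # d(A,B)=2, d(C,D)=4, all cross distances 10
        from cnpop.differentiation import _upgma

        dmat = np.array([
            [0, 2, 10, 10],
            [2, 0, 10, 10],
            [10, 10, 0, 4],
            [10, 10, 4, 0],
        ], dtype=float)
        Z = _upgma(dmat)
        merges = sorted(Z[:, 2].tolist())
        assert merges == pytest.approx([2, 4, 10])
        parts = _bipartitions(Z, ["A", "B", "C", "D"])
        assert frozenset({"A", "B"}) in parts
        assert frozenset({"C", "D"}) in parts

    def test_tree_is_ultrametric_and_parseable(self, three_pop_dataset):
        gm, _ = three_pop_dataset
        tree = distance_tree(gm, n_bootstrap=25, seed=1)
        # root height = max linkage distance / 2; all tips equidistant from root
        import io

        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        coph = squareform(cophenet(tree.linkage))
        # ultrametric check on the newick: parse and measure root-to-tip paths
        depths = _newick_tip_depths(tree.newick)
        assert set(depths) == set(tree.populations)
        vals = np.array(list(depths.values()))
        assert np.allclose(vals, vals[0], atol=1e-6)
        assert coph.shape == (3, 3)

    def test_designed_topology_high_support(self):
        # pops A and B identical in expectation, C far away: ((A,B),C)
        rng = np.random.default_rng(13)
        near = rng.choice([0, 1, 2], size=(120, 60), p=[0.25, 0.5, 0.25])
        far = rng.choice([2, 3, 4], size=(120, 30), p=[0.25, 0.5, 0.25])
        cn = np.hstack([near, far])
        gm = matrix_from_cn(cn, ["A"] * 30 + ["B"] * 30 + ["C"] * 30)
        tree = distance_tree(gm, n_bootstrap=200, seed=2)
        assert tree.support_for({"A", "B"}) > 0.95

    def test_bootstrap_deterministic(self, three_pop_dataset):
        gm, _ = three_pop_dataset
        t1 = distance_tree(gm, n_bootstrap=20, seed=7)
        t2 = distance_tree(gm, n_bootstrap=20, seed=7)
        assert t1.newick == t2.newick
        assert t1.bootstrap_support == t2.bootstrap_support

    def test_frequency_level(self, three_pop_dataset):
        gm, _ = three_pop_dataset
        tree = distance_tree(gm, n_bootstrap=10, seed=3, level="frequency")
        assert sorted(tree.populations) == ["P1", "P2", "P3"]
        assert tree.newick.endswith(";")


def _newick_tip_depths(newick):
    """Root-to-tip path lengths from a simple Newick string."""
    import re

    depths = {}
    depth = 0.0
    stack = []
    i = 0
    s = newick.strip().rstrip(";")
    token = re.compile(r"([A-Za-z0-9_.]+)?(?::([0-9.eE+-]+))?")
    pos = 0
    # simple recursive descent
    def parse(s, pos, depth):
        if s[pos] == "(":
            pos += 1
            while True:
                pos = _parse_child(s, pos, depth)
                if s[pos] == ",":
                    pos += 1
                    continue
                break
            assert s[pos] == ")"
            pos += 1
            # internal label/branch
            m = token.match(s, pos)
            pos = m.end()
            return pos
        return _parse_child(s, pos, depth)

    def _parse_child(s, pos, depth):
        if s[pos] == "(":
            start = pos
            level = 0
            while True:
                if s[pos] == "(":
                    level += 1
                elif s[pos] == ")":
                    level -= 1
                    if level == 0:
                        pos += 1
                        break
                pos += 1
            m = token.match(s, pos)
            label, length = m.group(1), m.group(2)
            inner = s[start + 1:pos - 1]
            d = depth + (float(length) if length else 0.0)
            # split children at top level
            parts, lvl, last = [], 0, 0
            for k, ch in enumerate(inner):
                if ch == "(":
                    lvl += 1
                elif ch == ")":
                    lvl -= 1
                elif ch == "," and lvl == 0:
                    parts.append(inner[last:k])
                    last = k + 1
            parts.append(inner[last:])
            for part in parts:
                _parse_child(part + "\x00", 0, d)
            return m.end()
        m = token.match(s, pos)
        label, length = m.group(1), m.group(2)
        depths[label] = depth + (float(length) if length else 0.0)
        return m.end()

    _parse_child(s + "\x00", 0, 0.0)
    return depths


class TestPca:
    def test_duplicated_samples_identical_coordinates(self):
        rng = np.random.default_rng(1)
        cn = rng.choice([0, 1, 2, 3, 4], size=(50, 10))
        cn = np.hstack([cn, cn[:, :1]])  # sample 11 duplicates sample 1
        gm = matrix_from_cn(cn, ["A"] * 11)
        res = pca(gm, n_components=3)
        assert np.allclose(
            res.coordinates.iloc[0].to_numpy(), res.coordinates.iloc[10].to_numpy()
        )

    def test_explained_variance_matches_svd_oracle(self):
        rng = np.random.default_rng(2)
        cn = rng.choice([0, 1, 2], size=(40, 25))
        gm = matrix_from_cn(cn, ["A"] * 25)
        res = pca(gm, n_components=5, scale=False)
        X = cn.T.astype(float)
        X = X[:, X.var(axis=0) > 0]
        X = X - X.mean(axis=0)
        sv = np.linalg.svd(X, compute_uv=False)
        evr = sv ** 2 / (sv ** 2).sum()
        assert np.allclose(res.explained_variance_ratio, evr[:5], atol=1e-10)

    def test_population_separation(self, three_pop_dataset):
        gm, _ = three_pop_dataset
        res = pca(gm, n_components=2)
        labels = pd.factorize(gm.populations)[0]
        sil = silhouette_score(res.coordinates.to_numpy(), labels)
        assert sil > 0.3  # clear 3-way separation in PC space
        km = KMeans(n_clusters=3, n_init=10, random_state=0).fit(res.coordinates)
        assert adjusted_rand_score(labels, km.labels_) > 0.9

    def test_monomorphic_rejected(self):
        gm = matrix_from_cn(np.full((5, 4), 2), ["A"] * 4)
        with pytest.raises(ValueError, match="monomorphic"):
            pca(gm)

    def test_deterministic_sign(self):
        rng = np.random.default_rng(3)
        cn = rng.choice([0, 1, 2], size=(30, 20))
        gm = matrix_from_cn(cn, ["A"] * 20)
        r1, r2 = pca(gm, n_components=3), pca(gm, n_components=3)
        assert np.allclose(r1.coordinates.to_numpy(), r2.coordinates.to_numpy())
        for k in range(3):
            col = r1.loadings[f"PC{k + 1}"].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0
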