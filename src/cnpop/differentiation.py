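"""Population differentiation: Weir-Cockerham Fst, selection scan, UPGMA, PCA.

Fst is estimated with the Weir & Cockerham (1984) method-of-moments
estimator theta, built from three variance components per locus:

* ``a`` - variance among populations,
* ``b`` - variance among individuals within populations,
* ``c`` - variance between the two allele copies within individuals,

with theta = a / (a + b + c). Multiallelic loci (the four-allele CNP
system) are handled by summing the per-allele components. The multi-locus
estimate is the ratio of summed components, not the mean of per-locus
ratios. Negative per-locus theta values are retained unclamped: they are
ordinary sampling noise around zero and keep ranks unbiased in the
selection scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import ceil

import numpy as np
import pandas as pd

from .data import MISSING, ALLELE_PAIRS, GenotypeMatrix

__all__ = [
    "FstResult",
    "wc_fst",
    "pairwise_fst_matrix",
    "classify_differentiation",
    "selection_scan",
    "DistanceTree",
    "distance_tree",
    "individual_distance_matrix",
    "pca",
    "PCAResult",
]


@dataclass
class FstResult:
    """Weir-Cockerham variance components and theta for one population pair."""

    pop_a: str
    pop_b: str
    per_locus: pd.DataFrame  # columns a, b, c, theta (NaN for excluded loci)
    theta: float  # multi-locus: sum(a) / sum(a+b+c)
    n_loci_used: int

    @property
    def differentiation(self) -> str:
        return classify_differentiation(self.theta)


def _component_arrays(gm: GenotypeMatrix, pops) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-population allele frequencies, het rates and sample sizes.

    Returns (freq[r, L, 4], het[r, L, 4], n[r, L]) where het[i, l, j] is the
    fraction of genotyped individuals in population i heterozygous for
    allele j at locus l (carrying exactly one copy of allele j).
    """
    L = gm.n_loci
    r = len(pops)
    freq = np.zeros((r, L, 4))
    het = np.zeros((r, L, 4))
    n = np.zeros((r, L))
    for i, pop in enumerate(pops):
        sub = gm.cn[:, gm.population_mask(pop)]
        ok = sub != MISSING
        n[i] = ok.sum(axis=1)
        pairs = ALLELE_PAIRS[np.where(ok, sub, 2)]  # (L, n_i, 2)
        for j in range(4):
            is_j = pairs == j
            cnt = (is_j & ok[..., None]).sum(axis=(1, 2))
            hetj = ((is_j.sum(axis=2) == 1) & ok).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                freq[i, :, j] = np.where(n[i] > 0, cnt / np.maximum(2 * n[i], 1), np.nan)
                het[i, :, j] = np.where(n[i] > 0, hetj / np.maximum(n[i], 1), np.nan)
    return freq, het, n


def wc_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str, min_per_pop: int = 2) -> FstResult:
    """Weir-Cockerham (1984) theta between two populations.

    Copy states are expanded through the four-allele encoding; per-allele
    variance components a, b, c are summed over alleles at each locus.
    Loci monomorphic across both populations, or with fewer than
    ``min_per_pop`` genotyped individuals in either population, are
    excluded (NaN in the per-locus table).
    """
    pops = [pop_a, pop_b]
    freq, het, n = _component_arrays(gm, pops)
    r = 2
    nbar = n.mean(axis=0)  # (L,)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n[:, :, None] * freq).sum(axis=0) / (r * nbar)[:, None]  # (L,4)
        s2 = (n[:, :, None] * (freq - pbar[None]) ** 2).sum(axis=0) / ((r - 1) * nbar)[:, None]
        hbar = (n[:, :, None] * het).sum(axis=0) / (r * nbar)[:, None]
        a = (nbar / nc)[:, None] * (
            s2
            - 1.0 / (nbar - 1)[:, None]
            * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
        )
        b = (nbar / (nbar - 1))[:, None] * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1)[:, None] / (4 * nbar)[:, None]
        )
        c = hbar / 2
    polymorphic = ((pbar > 0) & (pbar < 1)).any(axis=1)
    enough = (n >= min_per_pop).all(axis=0)
    usable = polymorphic & enough & np.isfinite(pbar).all(axis=1)
    # alleles absent overall contribute nothing
    allele_seen = (pbar > 0) & (pbar < 1)
    aL = np.where(allele_seen, a, 0.0).sum(axis=1)
    bL = np.where(allele_seen, b, 0.0).sum(axis=1)
    cL = np.where(allele_seen, c, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_l = np.where(usable, aL / (aL + bL + cL), np.nan)
    per_locus = pd.DataFrame(
        {
            "a": np.where(usable, aL, np.nan),
            "b": np.where(usable, bL, np.nan),
            "c": np.where(usable, cL, np.nan),
            "theta": theta_l,
        },
        index=pd.Index(gm.loci["id"], name="locus"),
    )
    denom = (aL + bL + cL)[usable].sum()
    theta = float(aL[usable].sum() / denom) if usable.any() and denom != 0 else float("nan")
    return FstResult(
        pop_a=pop_a, pop_b=pop_b, per_locus=per_locus,
        theta=theta, n_loci_used=int(usable.sum()),
    )


def pairwise_fst_matrix(gm: GenotypeMatrix, focal: str | None = None) -> tuple[pd.DataFrame, dict]:
    """Multi-locus theta for every population pair (or focal vs others).

    Returns (symmetric theta matrix with NaN diagonal, dict pair->FstResult).
    """
    pops = gm.population_names
    pairs = (
        [(focal, o) for o in pops if o != focal]
        if focal is not None
        else list(combinations(pops, 2))
    )
    mat = pd.DataFrame(np.nan, index=pops, columns=pops)
    results = {}
    for a, b in pairs:
        res = wc_fst(gm, a, b)
        results[(a, b)] = res
        mat.loc[a, b] = mat.loc[b, a] = res.theta
    return mat, results


_BINS = ((0.05, "weak"), (0.15, "moderate"), (0.25, "high"))


def classify_differentiation(theta: float) -> str:
    """Magnitude bin for a pairwise theta.

    weak (<= 0.05), moderate (<= 0.15), high (<= 0.25), very-high (> 0.25);
    boundary values fall in the lower bin, and non-positive values count as
    weak (no detectable differentiation).
    """
    if not np.isfinite(theta):
        raise ValueError("theta must be a finite number")
    for cut, label in _BINS:
        if theta <= cut:
            return label
    return "very-high"


def selection_scan(
    fst_results: dict,
    top_fraction: float = 0.01,
    specific_loci=None,
) -> tuple[dict, list]:
    """Rank loci by per-locus theta per pair and keep the top fraction.

    ``fst_results`` maps a pair key to an :class:`FstResult`. Per pair, the
    top ``ceil(top_fraction * m)`` loci by theta are selected among the m
    loci with defined theta, ties broken by locus id for determinism. The
    candidate set is the union across pairs plus any supplied
    population-specific loci.

    Returns (per-pair candidate dict, sorted union list).
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    per_pair = {}
    union = set(specific_loci or [])
    for key, res in fst_results.items():
        theta = res.per_locus["theta"].dropna()
        if theta.empty:
            raise ValueError(f"no ranked loci for pair {key}")
        m = len(theta)
        if m < 100:
            import warnings

            warnings.warn(
                f"pair {key}: only {m} ranked loci; top-fraction scan is noisy",
                stacklevel=2,
            )
        k = ceil(top_fraction * m)
        # stable sort after ordering by locus id, so ties break deterministically
        ordered = theta.loc[sorted(theta.index)].sort_values(ascending=False, kind="mergesort")
        top = ordered.index[:k].tolist()
        per_pair[key] = top
        union.update(top)
    return per_pair, sorted(union)


# ---------------------------------------------------------------------------
# Distance matrix and UPGMA tree
# ---------------------------------------------------------------------------

def individual_distance_matrix(cn: np.ndarray) -> np.ndarray:
    """Euclidean distance between copy-state vectors of all sample pairs.

    Missing loci are excluded pairwise and the squared distance rescaled by
    L / m (m = loci shared by the pair) so sparsely genotyped pairs remain
    comparable. A pair sharing zero loci is an error.
    """
    X = cn.T.astype(float)  # samples x loci
    ok = cn.T != MISSING
    Xz = np.where(ok, X, 0.0)
    sq = Xz ** 2
    # sum over shared loci of (x - y)^2, computed by masked matrix algebra
    shared = ok.astype(float) @ ok.T.astype(float)
    if (shared == 0).any():
        raise ValueError("some sample pair shares zero genotyped loci")
    cross = Xz @ Xz.T
    xx = sq @ ok.T.astype(float)
    d2 = xx + xx.T - 2 * cross
    L = cn.shape[0]
    d2 = np.maximum(d2, 0) * (L / shared)
    np.fill_diagonal(d2, 0)
    return np.sqrt(d2)


def _population_distances(dist: np.ndarray, populations, pops) -> np.ndarray:
    """Mean inter-population individual-pair distance."""
    r = len(pops)
    out = np.zeros((r, r))
    masks = [np.asarray(populations) == p for p in pops]
    for i in range(r):
        for j in range(i + 1, r):
            out[i, j] = out[j, i] = dist[np.ix_(masks[i], masks[j])].mean()
    return out


def _upgma(dmat: np.ndarray):
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    return linkage(squareform(dmat, checks=False), method="average")


def _bipartitions(linkage_matrix, labels) -> set:
    """Non-trivial clades of the rooted tree (as frozensets of tip labels)."""
    n = len(labels)
    members = {i: frozenset([labels[i]]) for i in range(n)}
    out = set()
    for k, (i, j, _, _) in enumerate(linkage_matrix):
        merged = members[int(i)] | members[int(j)]
        members[n + k] = merged
        if 1 < len(merged) < n:
            out.add(merged)
    return out


@dataclass
class DistanceTree:
    """UPGMA tree over populations with bootstrap support."""

    populations: list
    distance_matrix: pd.DataFrame
    linkage: np.ndarray
    newick: str
    bootstrap_support: dict  # frozenset clade -> support in [0, 1]
    n_bootstrap: int

    def support_for(self, group) -> float:
        return self.bootstrap_support.get(frozenset(group), 0.0)


def _linkage_to_newick(linkage_matrix, labels, supports=None) -> str:
    """Serialize a linkage matrix as a Newick string with node heights and
    optional bootstrap support as internal node labels."""
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    node = {i: labels[i] for i in range(n)}
    members = {i: frozenset([labels[i]]) for i in range(n)}
    text = dict(node)
    for k, (i, j, dist, _) in enumerate(linkage_matrix):
        i, j = int(i), int(j)
        h = dist / 2.0
        bi = text[i] + f":{h - height[i]:.6g}"
        bj = text[j] + f":{h - height[j]:.6g}"
        idx = n + k
        members[idx] = members[i] | members[j]
        label = ""
        if supports is not None and members[idx] in supports:
            label = f"{supports[members[idx]]:.3g}"
        text[idx] = f"({bi},{bj}){label}"
        height[idx] = h
    return text[2 * n - 2] + ";"


def distance_tree(
    gm: GenotypeMatrix,
    n_bootstrap: int = 1000,
    seed: int | None = None,
    level: str = "individual",
) -> DistanceTree:
    """Population UPGMA tree from copy-state Euclidean distances.

    ``level="individual"`` (default) computes individual-level distances
    and aggregates population distance as the mean over inter-population
    pairs; ``level="frequency"`` uses Euclidean distance between population
    carrier/state frequency vectors instead. Bootstrap resamples loci with
    replacement; support is the fraction of replicates reproducing each
    clade of the full-data tree.
    """
    pops = gm.population_names
    if len(pops) < 2 or gm.n_loci < 2:
        raise ValueError("need >= 2 populations and >= 2 loci")
    rng = np.random.default_rng(seed)

    def pop_dist(cn):
        if level == "individual":
            return _population_distances(individual_distance_matrix(cn), gm.populations, pops)
        if level == "frequency":
            ok = cn != MISSING
            vecs = []
            for p in pops:
                m = gm.population_mask(p)
                sub, sok = cn[:, m], ok[:, m]
                mean_state = np.where(
                    sok.any(axis=1), np.where(sok, sub, 0).sum(axis=1) / np.maximum(sok.sum(axis=1), 1), 2.0
                )
                vecs.append(mean_state)
            V = np.array(vecs)
            diff = V[:, None, :] - V[None, :, :]
            return np.sqrt((diff ** 2).sum(axis=2))
        raise ValueError("level must be 'individual' or 'frequency'")

    dmat = pop_dist(gm.cn)
    Z = _upgma(dmat)
    ref_parts = _bipartitions(Z, pops)
    counts = dict.fromkeys(ref_parts, 0)
    for _ in range(n_bootstrap):
        idx = rng.integers(0, gm.n_loci, size=gm.n_loci)
        Zb = _upgma(pop_dist(gm.cn[idx]))
        parts = _bipartitions(Zb, pops)
        for part in ref_parts:
            if part in parts:
                counts[part] += 1
    support = (
        {p: c / n_bootstrap for p, c in counts.items()} if n_bootstrap > 0 else {p: float("nan") for p in ref_parts}
    )
    newick = _linkage_to_newick(Z, pops, support if n_bootstrap > 0 else None)
    return DistanceTree(
        populations=pops,
        distance_matrix=pd.DataFrame(dmat, index=pops, columns=pops),
        linkage=Z,
        newick=newick,
        bootstrap_support=support,
        n_bootstrap=n_bootstrap,
    )


# ---------------------------------------------------------------------------
# PCA on copy-state dosages
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # loci x components
    n_loci_used: int


def pca(gm: GenotypeMatrix, n_components: int = 10, scale: bool = True) -> PCAResult:
    """Principal component analysis of the copy-state dosage matrix.

    Columns (loci) are mean-centred and, by default, scaled to unit
    variance, mirroring the classical population-genetics convention for
    dosage PCA. Zero-variance (monomorphic) loci are dropped; missing calls
    are imputed with the locus mean. The sign of each component is fixed so
    that the largest-magnitude loading is positive.
    """
    from sklearn.decomposition import PCA as SkPCA

    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    X = gm.cn.T.astype(float)  # samples x loci
    ok = gm.cn.T != MISSING
    col_mean = np.where(ok, X, 0).sum(axis=0) / np.maximum(ok.sum(axis=0), 1)
    X = np.where(ok, X, col_mean[None, :])
    var = X.var(axis=0)
    keep = var > 0
    if not keep.any():
        raise ValueError("all loci are monomorphic")
    X = X[:, keep]
    X = X - X.mean(axis=0)
    if scale:
        X = X / X.std(axis=0)
    n_components = min(n_components, min(X.shape) - 1) or 1
    model = SkPCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(X)
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(n_components):
        j = np.argmax(np.abs(model.components_[k]))
        if model.components_[k, j] < 0:
            model.components_[k] *= -1
            coords[:, k] *= -1
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=gm.samples, columns=cols),
        explained_variance_ratio=model.explained_variance_ratio_,
        loadings=pd.DataFrame(
            model.components_.T, index=gm.loci.loc[keep, "id"].to_numpy(), columns=cols
        ),
        n_loci_used=int(keep.sum()),
    )
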