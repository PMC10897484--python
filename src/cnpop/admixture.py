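"""Model-based ancestry estimation for CNP genotypes.

Implements the classical admixture model behind Bayesian population
assignment: K latent clusters, each with its own allele-frequency table;
every individual has an ancestry proportion vector q over the clusters, and
each of the two allele copies at every locus originates from one cluster
drawn according to q. Inference is by Gibbs sampling:

* z (cluster of origin of each allele copy) ~ categorical, proportional to
  q_ik * p_k,l,allele;
* q_i ~ Dirichlet(alpha + per-cluster copy counts of individual i);
* p_k,l,. ~ Dirichlet(lambda + per-cluster allele counts at locus l).

The model log-probability reported per run is the standard harmonic-style
convention used for cluster-number selection: mean of the data
log-likelihood over retained sweeps minus half its variance. The Evanno
delta-K statistic computed across replicate runs selects the number of
clusters.

:class:`AdmixtureModel` follows the scikit-learn estimator protocol
(``get_params``/``set_params``, ``fit``, fitted attributes with trailing
underscores) so it composes with sklearn model-selection utilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import MISSING, ALLELE_PAIRS, GenotypeMatrix

__all__ = [
    "AdmixtureRun",
    "AdmixtureModel",
    "fit_admixture",
    "replicate_runs",
    "evanno_delta_k",
    "align_runs",
]


@dataclass
class AdmixtureRun:
    """One fitted run: ancestry matrix Q, cluster frequencies P, lnP."""

    K: int
    q: np.ndarray  # (n_samples, K) posterior-mean ancestry
    p: np.ndarray  # (K, n_loci, 4) posterior-mean allele frequencies
    ln_prob: float
    seed: int
    burn_in: int
    n_iter: int
    samples: list | None = None

    def q_frame(self) -> pd.DataFrame:
        idx = self.samples if self.samples is not None else range(len(self.q))
        return pd.DataFrame(
            self.q, index=idx, columns=[f"q{k + 1}" for k in range(self.K)]
        )


def _flatten_alleles(gm: GenotypeMatrix):
    """Non-missing allele copies as flat (individual, locus, allele) arrays."""
    al = gm.allele_pairs()  # (L, N, 2)
    ok = al[..., 0] != MISSING
    l_idx, i_idx = np.nonzero(ok)
    l_idx = np.repeat(l_idx, 2)
    i_idx = np.repeat(i_idx, 2)
    a_idx = al[ok].reshape(-1)
    return i_idx.astype(np.int64), l_idx.astype(np.int64), a_idx.astype(np.int64)


class AdmixtureModel(BaseEstimator):
    """Gibbs-sampled admixture model over the four-allele CNP encoding.

    Parameters
    ----------
    K : int
        Number of ancestral clusters.
    alpha : float
        Symmetric Dirichlet prior on individual ancestry proportions.
    lam : float
        Symmetric Dirichlet prior on cluster allele frequencies.
    burn_in, n_iter : int
        Discarded and retained Gibbs sweeps. The convergence of the sampler
        is not monitored; the iteration budget is fixed.
    seed : int
        RNG seed; a fitted run is deterministic for a fixed seed.

    Attributes (after ``fit``)
    ----------
    Q_ : ndarray (n_samples, K) - posterior-mean ancestry proportions.
    P_ : ndarray (K, n_loci, 4) - posterior-mean cluster allele frequencies.
    ln_prob_ : float - model log-probability estimate.
    loglik_trace_ : ndarray - data log-likelihood of each retained sweep.
    """

    def __init__(self, K=3, alpha=1.0, lam=1.0, burn_in=10_000, n_iter=10_000, seed=0):
        self.K = K
        self.alpha = alpha
        self.lam = lam
        self.burn_in = burn_in
        self.n_iter = n_iter
        self.seed = seed

    def fit(self, gm: GenotypeMatrix, y=None):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.K > gm.n_samples:
            raise ValueError("K cannot exceed the number of samples")
        K = self.K
        N, L = gm.n_samples, gm.n_loci
        rng = np.random.default_rng(self.seed)
        i_idx, l_idx, a_idx = _flatten_alleles(gm)
        M = a_idx.size
        flat_pl = l_idx * 4 + a_idx

        q = np.full((N, K), 1.0 / K)
        g = rng.standard_gamma(self.lam, size=(K, L, 4))
        p = g / g.sum(axis=2, keepdims=True)

        q_sum = np.zeros((N, K))
        p_sum = np.zeros((K, L, 4))
        lls = np.empty(self.n_iter)
        for it in range(self.burn_in + self.n_iter):
            pg = p.reshape(K, -1)[:, flat_pl]  # (K, M)
            w = q[i_idx].T * pg
            tot = w.sum(axis=0)
            if K == 1:
                z = np.zeros(M, dtype=np.int64)
            else:
                u = rng.random(M) * tot
                z = (np.cumsum(w, axis=0) < u).sum(axis=0)
                np.minimum(z, K - 1, out=z)
            cq = np.bincount(i_idx * K + z, minlength=N * K).reshape(N, K)
            gq = rng.standard_gamma(self.alpha + cq)
            q = gq / gq.sum(axis=1, keepdims=True)
            cp = np.bincount((z * L + l_idx) * 4 + a_idx, minlength=K * L * 4).reshape(K, L, 4)
            gp = rng.standard_gamma(self.lam + cp)
            p = gp / gp.sum(axis=2, keepdims=True)
            if it >= self.burn_in:
                t = it - self.burn_in
                lls[t] = np.log(tot).sum()
                q_sum += q
                p_sum += p
        self.Q_ = q_sum / self.n_iter
        if K == 1:
            self.Q_ = np.ones((N, 1))
        self.P_ = p_sum / self.n_iter
        self.loglik_trace_ = lls
        self.ln_prob_ = float(lls.mean() - lls.var() / 2.0)
        self.n_features_in_ = L
        return self

    def to_run(self, gm: GenotypeMatrix | None = None) -> AdmixtureRun:
        return AdmixtureRun(
            K=self.K, q=self.Q_, p=self.P_, ln_prob=self.ln_prob_,
            seed=self.seed, burn_in=self.burn_in, n_iter=self.n_iter,
            samples=None if gm is None else list(gm.samples),
        )


def fit_admixture(
    gm: GenotypeMatrix, K: int, burn_in: int = 10_000, n_iter: int = 10_000,
    seed: int = 0, alpha: float = 1.0, lam: float = 1.0,
) -> AdmixtureRun:
    """Fit one admixture run and return its :class:`AdmixtureRun`."""
    model = AdmixtureModel(K=K, alpha=alpha, lam=lam, burn_in=burn_in, n_iter=n_iter, seed=seed)
    return model.fit(gm).to_run(gm)


def replicate_runs(
    gm: GenotypeMatrix, k_range, n_replicates: int = 3,
    burn_in: int = 10_000, n_iter: int = 10_000, seed: int = 0,
) -> dict[int, list[AdmixtureRun]]:
    """Fit ``n_replicates`` independent runs for every K in ``k_range``.

    Replicate seeds are derived from ``seed`` through a seed sequence so
    runs are independent yet reproducible.
    """
    rng = np.random.default_rng(seed)
    out: dict[int, list[AdmixtureRun]] = {}
    for K in k_range:
        out[K] = [
            fit_admixture(gm, K, burn_in, n_iter, seed=int(rng.integers(2 ** 31)))
            for _ in range(n_replicates)
        ]
    return out


def evanno_delta_k(runs: dict[int, list[AdmixtureRun]]) -> pd.DataFrame:
    """Evanno table: L(K), sd, first/second differences and delta-K.

    L(K) is the mean ln-probability over replicates; L'(K) = L(K) - L(K-1);
    |L''(K)| = |L'(K+1) - L'(K)|; delta-K = |L''(K)| / sd(K). Delta-K is
    defined only for interior K with >= 2 replicates and positive sd
    (NaN otherwise, never infinity). The attribute ``best_k`` on the
    returned frame is the argmax of the defined delta-K values.
    """
    ks = sorted(runs)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need a contiguous K range of length >= 3")
    L = {k: float(np.mean([r.ln_prob for r in runs[k]])) for k in ks}
    sd = {
        k: float(np.std([r.ln_prob for r in runs[k]], ddof=1)) if len(runs[k]) >= 2 else np.nan
        for k in ks
    }
    rows = []
    for k in ks:
        lp = L[k] - L[k - 1] if k - 1 in L else np.nan
        if k - 1 in L and k + 1 in L:
            lpp = abs((L[k + 1] - L[k]) - (L[k] - L[k - 1]))
            dk = lpp / sd[k] if np.isfinite(sd[k]) and sd[k] > 0 else np.nan
        else:
            lpp, dk = np.nan, np.nan
        rows.append((k, L[k], sd[k], len(runs[k]), lp, lpp, dk))
    df = pd.DataFrame(
        rows, columns=["K", "mean_lnP", "sd_lnP", "n_replicates", "Lprime", "Lsecond", "deltaK"]
    ).set_index("K")
    defined = df["deltaK"].dropna()
    df.attrs["best_k"] = int(defined.idxmax()) if not defined.empty else None
    return df


def align_runs(
    runs: list[AdmixtureRun], reference: AdmixtureRun
) -> tuple[list[AdmixtureRun], list[float]]:
    """Permute cluster labels of each run to best match the reference.

    Because the total disagreement sum_i sum_k |q[i, perm(k)] - ref[i, k]|
    decomposes over (run column, reference column) pairs, the optimal
    permutation is an assignment problem solved exactly by the Hungarian
    algorithm for any K. Returns relabelled runs and their disagreement
    scores (mean absolute q difference).
    """
    from scipy.optimize import linear_sum_assignment

    aligned, scores = [], []
    for run in runs:
        if run.K != reference.K:
            raise ValueError("all runs must share K with the reference")
        cost = np.abs(run.q[:, :, None] - reference.q[:, None, :]).sum(axis=0)
        rows, cols = linear_sum_assignment(cost)
        perm = np.empty(run.K, dtype=int)
        perm[cols] = rows
        aligned.append(
            AdmixtureRun(
                K=run.K, q=run.q[:, perm], p=run.p[perm], ln_prob=run.ln_prob,
                seed=run.seed, burn_in=run.burn_in, n_iter=run.n_iter,
                samples=run.samples,
            )
        )
        scores.append(float(cost[rows, cols].sum() / run.q.size))
    return aligned, scores


def brute_force_alignment(run_q: np.ndarray, ref_q: np.ndarray) -> tuple[tuple, float]:
    """Exhaustive label-permutation search (small K); used as an oracle."""
    K = run_q.shape[1]
    best, best_cost = None, np.inf
    for perm in permutations(range(K)):
        cost = np.abs(run_q[:, perm] - ref_q).sum()
        if cost < best_cost:
            best, best_cost = perm, cost
    return best, float(best_cost / run_q.size)
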