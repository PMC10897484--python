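"""Frequency characterisation and cross-population comparisons of CNP loci.

The "frequency" of a CNP is its carrier frequency: the fraction of
genotyped individuals whose copy state deviates from the normal CN=2.
Carrier frequencies are binned into the four classes [0%, 10%), [10%, 50%),
[50%, 100%) and exactly 100% (fixed). Population pairs are compared by

* a chi-square or exact (Fisher-type) test on the 2x4 class-count table,
* a Wilcoxon rank-sum test on locus lengths,
* per-locus Fisher exact tests on carrier counts,

with Benjamini-Hochberg FDR control over the requested family of tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .data import MISSING, ALLELE_PAIRS, GenotypeMatrix

__all__ = [
    "FREQUENCY_CLASSES",
    "FrequencyTable",
    "carrier_frequencies",
    "class_count_table",
    "compare_class_distributions",
    "compare_class_counts",
    "compare_size_distributions",
    "per_locus_fisher",
    "high_frequent_cnps",
    "HighFrequentResult",
    "sharing_analysis",
    "SharingResult",
    "fisher_exact_2xc",
]

FREQUENCY_CLASSES = ("[0%, 10%[", "[10%, 50%[", "[50%, 100%[", "100%")


def _frequency_class(freq: np.ndarray) -> np.ndarray:
    """Half-open carrier-frequency classes; boundaries as printed."""
    pct = freq * 100
    out = np.select(
        [pct < 10, pct < 50, pct < 100],
        FREQUENCY_CLASSES[:3],
        default=FREQUENCY_CLASSES[3],
    )
    return np.where(np.isnan(pct), None, out)


@dataclass
class FrequencyTable:
    """Per-(locus, population) carrier counts, frequencies and allele counts.

    Attributes
    ----------
    table : pandas.DataFrame
        MultiIndex (locus, population); columns ``n_genotyped``,
        ``n_carriers``, ``carrier_freq`` (NaN where no call was genotyped),
        ``freq_class`` and four-allele counts ``a0``..``a3``.
    state_tallies : pandas.DataFrame
        Per population, counts of each copy state 0..6 pooled over loci.
    populations : list of str
    """

    table: pd.DataFrame
    state_tallies: pd.DataFrame
    populations: list

    def carrier_freq_matrix(self) -> pd.DataFrame:
        """Loci x populations matrix of carrier frequencies."""
        return self.table["carrier_freq"].unstack("population")[self.populations]

    def allelic_matrix(self) -> pd.DataFrame:
        """Boolean loci x populations matrix: locus allelic (>=1 carrier)."""
        return (self.table["n_carriers"].unstack("population") > 0)[self.populations]

    def median_frequency(self, population: str, allelic_only: bool = True) -> float:
        sub = self.table.xs(population, level="population")
        f = sub["carrier_freq"].dropna()
        if allelic_only:
            f = f[f > 0]
        return float(f.median())


def carrier_frequencies(gm: GenotypeMatrix) -> FrequencyTable:
    """Count carriers (CN != 2) per locus and population.

    A population with zero genotyped calls at a locus gets carrier_freq NaN
    (undefined, flagged by the missing class label) rather than zero.
    """
    pops = gm.population_names
    cn = gm.cn
    rows = []
    tallies = {}
    for pop in pops:
        mask = gm.population_mask(pop)
        sub = cn[:, mask]
        genotyped = (sub != MISSING).sum(axis=1)
        carriers = ((sub != MISSING) & (sub != 2)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(genotyped > 0, carriers / np.maximum(genotyped, 1), np.nan)
        # four-allele counts from the copy-state encoding
        ok = sub != MISSING
        pairs = ALLELE_PAIRS[np.where(ok, sub, 2)]
        acounts = np.zeros((gm.n_loci, 4), dtype=np.int64)
        for j in range(4):
            acounts[:, j] = ((pairs == j) & ok[..., None]).sum(axis=(1, 2))
        df = pd.DataFrame({
            "locus": gm.loci["id"].to_numpy(),
            "population": pop,
            "n_genotyped": genotyped,
            "n_carriers": carriers,
            "carrier_freq": freq,
            "freq_class": _frequency_class(freq),
        })
        for j in range(4):
            df[f"a{j}"] = acounts[:, j]
        rows.append(df)
        vals = sub[ok]
        tallies[pop] = np.bincount(vals, minlength=7)
    table = pd.concat(rows).set_index(["locus", "population"]).sort_index()
    state_tallies = pd.DataFrame(tallies, index=pd.Index(range(7), name="cn")).T
    return FrequencyTable(table=table, state_tallies=state_tallies, populations=pops)


def class_count_table(ft: FrequencyTable, population: str) -> np.ndarray:
    """Counts of allelic loci per frequency class for one population."""
    sub = ft.table.xs(population, level="population")
    sub = sub[sub["n_carriers"] > 0]
    counts = sub["freq_class"].value_counts()
    return np.array([int(counts.get(c, 0)) for c in FREQUENCY_CLASSES])


# ---------------------------------------------------------------------------
# Exact Fisher-type test for 2 x c tables
# ---------------------------------------------------------------------------

_LGF = gammaln(np.arange(1, 200_002, dtype=np.float64))  # _LGF[n] = log(n!)


def _lgf(n):
    return _LGF[n]


def fisher_exact_2xc(table) -> float:
    """Exact two-sided test of independence for a 2 x c contingency table.

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more probable than the observed one
    (probability ordering, the classical two-sided Fisher convention).
    Exact and deterministic; feasible for c <= ~5 with the column margins
    of locus-class tables.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] != 2 or (table < 0).any():
        raise ValueError("a 2 x c table of non-negative counts is required")
    cols = table.sum(axis=0)
    keep = cols > 0
    table = table[:, keep]
    cols = cols[keep]
    r1 = int(table[0].sum())
    c = table.shape[1]
    if c < 2 or r1 == 0 or table[1].sum() == 0:
        return 1.0
    # enumerate first-row counts of all columns but the largest (fewest cells)
    order = np.argsort(cols)[::-1]
    cols = cols[order]
    obs = table[:, order]
    grids = np.ix_(*[np.arange(cols[j] + 1) for j in range(1, c)])
    s = np.zeros((), dtype=np.int64)
    logp = np.zeros((), dtype=np.float64)
    for j in range(1, c):
        x = grids[j - 1]
        s = s + x
        logp = logp - _lgf(x) - _lgf(cols[j] - x)
    x0 = r1 - s
    valid = (x0 >= 0) & (x0 <= cols[0])
    x0c = np.where(valid, x0, 0)
    logp = logp - _lgf(x0c) - _lgf(cols[0] - x0c)
    log_obs = -(_lgf(obs[0]).sum() + _lgf(obs[1]).sum())
    ratio = np.exp(logp - log_obs)
    ratio = np.where(valid, ratio, 0.0)
    total = ratio.sum()
    p = ratio[ratio <= 1.0 + 1e-7].sum() / total
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Class-distribution comparison (2 x 4 tables)
# ---------------------------------------------------------------------------

def _class_test(row_a, row_b, method: str) -> tuple[float, float]:
    """Return (statistic, p) for a 2 x c class-count table; empty classes in
    both rows are dropped (reducing the degrees of freedom)."""
    tbl = np.array([row_a, row_b], dtype=np.int64)
    tbl = tbl[:, tbl.sum(axis=0) > 0]
    if tbl.shape[1] < 2:
        return 0.0, 1.0
    if method == "chi2":
        res = stats.chi2_contingency(tbl, correction=False)
        return float(res.statistic), float(res.pvalue)
    if method == "fisher":
        return np.nan, fisher_exact_2xc(tbl)
    raise ValueError("method must be 'chi2' or 'fisher'")


def compare_class_distributions(
    ft: FrequencyTable,
    focal: str,
    others=None,
    method: str = "fisher",
    family: str = "all-pairs",
) -> pd.DataFrame:
    """Compare the frequency-class distribution of ``focal`` to other
    populations.

    Each comparison tests the 2 x 4 table of allelic-locus counts per
    frequency class. ``method`` selects the plain Pearson chi-square
    (``"chi2"``, no continuity correction) or the exact probability-ordered
    test (``"fisher"``). ``family`` sets the Benjamini-Hochberg FDR family:
    ``"focal"`` adjusts across the focal comparisons only, ``"all-pairs"``
    across every pairwise comparison among all populations (the convention
    that reproduces published class-comparison tables).

    Returns one row per focal comparison with raw and adjusted p-values.
    """
    counts = {p: class_count_table(ft, p) for p in ft.populations}
    return compare_class_counts(counts, focal, others, method=method, family=family)


def compare_class_counts(
    counts: dict,
    focal: str,
    others=None,
    method: str = "fisher",
    family: str = "all-pairs",
) -> pd.DataFrame:
    """Class-distribution comparison on pre-tabulated per-class counts.

    ``counts`` maps each population to its vector of allelic-locus counts
    per frequency class; see :func:`compare_class_distributions` for the
    test and family options.
    """
    pops = list(counts)
    if focal not in pops:
        raise KeyError(f"unknown focal population: {focal}")
    if others is None:
        others = [p for p in pops if p != focal]
    if family == "all-pairs":
        pairs = list(combinations(pops, 2))
    elif family == "focal":
        pairs = [(focal, o) for o in others]
    else:
        raise ValueError("family must be 'focal' or 'all-pairs'")
    stats_p = [_class_test(counts[a], counts[b], method) for a, b in pairs]
    raw = np.array([p for _, p in stats_p])
    adj = multipletests(raw, method="fdr_bh")[1]
    df = pd.DataFrame({
        "pop_a": [a for a, _ in pairs],
        "pop_b": [b for _, b in pairs],
        "test": f"class-{method}",
        "statistic": [s for s, _ in stats_p],
        "p_raw": raw,
        "p_adj": adj,
    })
    wanted = df[(df["pop_a"] == focal) | (df["pop_b"] == focal)].copy()
    wanted["population"] = np.where(
        wanted["pop_a"] == focal, wanted["pop_b"], wanted["pop_a"]
    )
    wanted = wanted.set_index("population").loc[[o for o in others]]
    return wanted[["test", "statistic", "p_raw", "p_adj"]]


def compare_size_distributions(groups: dict, comparisons=None) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests on locus lengths between groups.

    ``groups`` maps a group label to a vector of locus lengths;
    ``comparisons`` is a list of label pairs (default: all pairs).
    BH-FDR across the requested comparisons. All-tied inputs give p = 1.
    """
    if comparisons is None:
        comparisons = list(combinations(groups, 2))
    rows = []
    for a, b in comparisons:
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        if xa.size == 0 or xb.size == 0:
            raise ValueError("each group needs at least one locus")
        if np.unique(np.concatenate([xa, xb])).size == 1:
            import warnings

            warnings.warn(f"all lengths tied in {a} vs {b}", stacklevel=2)
            rows.append((a, b, 0.0, 1.0))
            continue
        method = "exact" if max(xa.size, xb.size) <= 25 else "asymptotic"
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        rows.append((a, b, float(res.statistic), float(res.pvalue)))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_raw"])
    df["test"] = "wilcoxon-rank-sum"
    df["p_adj"] = multipletests(df["p_raw"].to_numpy(), method="fdr_bh")[1]
    return df[["group_a", "group_b", "test", "statistic", "p_raw", "p_adj"]]


# ---------------------------------------------------------------------------
# Per-locus Fisher tests and high-frequent detection
# ---------------------------------------------------------------------------

def _carrier_table(ft: FrequencyTable, locus, pop_a, pop_b) -> np.ndarray | None:
    ta = ft.table.loc[(locus, pop_a)]
    tb = ft.table.loc[(locus, pop_b)]
    if ta["n_genotyped"] == 0 or tb["n_genotyped"] == 0:
        return None
    return np.array([
        [ta["n_carriers"], ta["n_genotyped"] - ta["n_carriers"]],
        [tb["n_carriers"], tb["n_genotyped"] - tb["n_carriers"]],
    ], dtype=np.int64)


def per_locus_fisher(
    ft: FrequencyTable,
    pop_a: str,
    pop_b: str,
    loci=None,
    mode: str = "carriers",
    gm: GenotypeMatrix | None = None,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-locus Fisher exact tests between two populations.

    ``mode="carriers"`` tests the 2x2 carriers / non-carriers table;
    ``mode="states"`` tests the full 2 x (observed copy states) contingency
    exactly (requires ``gm``). BH-FDR across the tested loci; loci
    ungenotyped in either population get NaN p-values, flagged not dropped.
    """
    all_loci = ft.table.index.get_level_values("locus").unique()
    loci = list(all_loci) if loci is None else list(loci)
    rows = []
    for locus in loci:
        if mode == "carriers":
            tbl = _carrier_table(ft, locus, pop_a, pop_b)
            if tbl is None:
                rows.append((locus, np.nan, np.nan))
                continue
            odds, p = stats.fisher_exact(tbl, alternative=alternative)
            rows.append((locus, float(odds), float(p)))
        elif mode == "states":
            if gm is None:
                raise ValueError("mode='states' needs the genotype matrix")
            li = gm.loci.index[gm.loci["id"] == locus][0]
            counts = []
            for pop in (pop_a, pop_b):
                sub = gm.cn[li, gm.population_mask(pop)]
                sub = sub[sub != MISSING]
                counts.append(np.bincount(sub, minlength=7))
            tbl = np.array(counts)
            rows.append((locus, np.nan, fisher_exact_2xc(tbl)))
        else:
            raise ValueError("mode must be 'carriers' or 'states'")
    df = pd.DataFrame(rows, columns=["locus", "odds_ratio", "p_raw"]).set_index("locus")
    defined = df["p_raw"].notna()
    adj = np.full(len(df), np.nan)
    if defined.any():
        adj[defined.to_numpy()] = multipletests(
            df.loc[defined, "p_raw"].to_numpy(), method="fdr_bh"
        )[1]
    df["p_adj"] = adj
    df["test"] = f"fisher-{mode}-{alternative}"
    return df


@dataclass
class HighFrequentResult:
    """High-frequent loci in the focal population, partitioned by class."""

    loci: list
    by_class: dict
    detail: pd.DataFrame  # per (locus, other population): freqs and adjusted p


def high_frequent_cnps(
    ft: FrequencyTable,
    focal: str,
    alpha: float = 0.05,
    gm: GenotypeMatrix | None = None,
    classes: pd.Series | None = None,
) -> HighFrequentResult:
    """Loci with significantly higher carrier frequency in ``focal`` than in
    every other population.

    For each locus, a one-sided (greater) Fisher exact test against each
    other population; BH-FDR within the locus across those comparisons. A
    locus qualifies iff the focal frequency is strictly greater and the
    adjusted p < ``alpha`` for every comparison. The result is partitioned
    by locus architecture (deletion / duplication / mixed), taken from
    ``classes`` or computed from ``gm``.
    """
    others = [p for p in ft.populations if p != focal]
    if not others:
        raise ValueError("need at least two populations")
    freq = ft.carrier_freq_matrix()
    ngen = ft.table["n_genotyped"].unstack("population")
    ncar = ft.table["n_carriers"].unstack("population")
    hits, detail_rows = [], []
    for locus in freq.index:
        f_focal = freq.loc[locus, focal]
        if not np.isfinite(f_focal) or f_focal == 0:
            continue
        if not all(
            np.isfinite(freq.loc[locus, o]) and f_focal > freq.loc[locus, o]
            for o in others
        ):
            continue
        ps = []
        for o in others:
            tbl = np.array([
                [ncar.loc[locus, focal], ngen.loc[locus, focal] - ncar.loc[locus, focal]],
                [ncar.loc[locus, o], ngen.loc[locus, o] - ncar.loc[locus, o]],
            ], dtype=np.int64)
            ps.append(stats.fisher_exact(tbl, alternative="greater")[1])
        adj = multipletests(np.array(ps), method="fdr_bh")[1]
        for o, p_raw, p_adj in zip(others, ps, adj):
            detail_rows.append((locus, o, f_focal, freq.loc[locus, o], p_raw, p_adj))
        if (adj < alpha).all():
            hits.append(locus)
    detail = pd.DataFrame(
        detail_rows,
        columns=["locus", "population", "freq_focal", "freq_other", "p_raw", "p_adj"],
    ).set_index(["locus", "population"])
    if classes is None:
        if gm is None:
            raise ValueError("provide gm or a per-locus class series")
        classes = gm.locus_classes()
    by_class: dict[str, list] = {}
    for locus in hits:
        by_class.setdefault(str(classes.loc[locus]), []).append(locus)
    return HighFrequentResult(loci=hits, by_class=by_class, detail=detail)


# ---------------------------------------------------------------------------
# Sharing analysis
# ---------------------------------------------------------------------------

@dataclass
class SharingResult:
    """Which populations each locus is allelic in, with summaries."""

    presence: pd.DataFrame  # loci x populations boolean
    shared_in_all: list
    population_specific: dict  # population -> loci allelic only there
    pairwise_shared: pd.DataFrame  # populations x populations shared counts

    def shared_with(self, focal: str) -> pd.Series:
        """Loci shared between ``focal`` and each other population."""
        return self.pairwise_shared.loc[focal].drop(focal)


def sharing_analysis(ft: FrequencyTable) -> SharingResult:
    """Partition loci by the set of populations where they are allelic."""
    presence = ft.allelic_matrix().fillna(False)
    pops = list(presence.columns)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    shared_all = presence.index[presence.all(axis=1)].tolist()
    n_pops_allelic = presence.sum(axis=1)
    specific = {
        pop: presence.index[(n_pops_allelic == 1) & presence[pop]].tolist()
        for pop in pops
    }
    mat = presence.to_numpy()
    pairwise = pd.DataFrame(
        (mat.T.astype(int) @ mat.astype(int)), index=pops, columns=pops
    )
    return SharingResult(
        presence=presence,
        shared_in_all=shared_all,
        population_specific=specific,
        pairwise_shared=pairwise,
    )
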