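"""Synthetic multi-population CNP genotype datasets with known ground truth.

The generator follows the Balding-Nichols drift model: each locus has an
ancestral allele-frequency vector, and every population draws its own
frequency vector from a Dirichlet distribution centred on the ancestral one
with concentration (1-F)/F, so the per-allele variance equals
F * p * (1 - p). Small F means little drift; F near 1 means populations far
apart. Diploid genotypes are two independent allele draws, and the reported
copy state is the sum of the two allele copy values.

Three locus architectures are modelled:

* ``deletion``   - alleles {0-copy, 1-copy}, copy states {0, 1, 2};
* ``duplication``- alleles {1-copy, 2-copy}, copy states {2, 3, 4};
* ``mixed``      - alleles {0-copy, 1-copy, 2-copy}, copy states {0..4};
  an optional low-frequency 3-copy amplification allele extends mixed loci
  to states 5-6, the rarest states in array-called CNP data.

Admixed individuals carry an ancestry proportion vector; each allele copy
is drawn from one ancestral population chosen by those proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_dataset",
    "STUDY_POPULATIONS",
]

#: Study-scale default: 12 populations of unrelated individuals (1093 total),
#: a North African focal population plus eleven reference panels.
STUDY_POPULATIONS = {
    "TUN": 102, "ASW": 50, "LWK": 83, "MKK": 147, "YRI": 120,
    "CEU": 115, "TSI": 83, "MEX": 56, "CHB": 89, "CHD": 85,
    "JPT": 91, "GIH": 72,
}

_ARCHS = ("deletion", "duplication", "mixed")
#: Allele copy values available per architecture (before the optional
#: amplification allele at mixed loci).
_ARCH_ALLELES = {
    "deletion": np.array([0, 1], dtype=np.int8),
    "duplication": np.array([1, 2], dtype=np.int8),
    "mixed": np.array([0, 1, 2], dtype=np.int8),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic CNP dataset.

    Parameters
    ----------
    n_populations : int
        Number of populations. Ignored when ``population_sizes`` is given.
    n_individuals : int
        Diploid individuals per population (uniform); ignored when
        ``population_sizes`` is given.
    population_sizes : dict[str, int], optional
        Explicit name -> size map; defaults to ``n_populations`` equal
        groups named P1..Pn.
    n_loci : int
        Number of CNP loci.
    architecture_mix : tuple of 3 floats
        Proportions of deletion, duplication and mixed loci; must sum to 1.
    F : float or sequence of float
        Balding-Nichols differentiation parameter in (0, 1), one global
        value or one per population.
    ancestral_freq_prior : (float, float)
        Beta shape pair for the ancestral non-normal allele frequency. The
        default Beta(0.5, 2) makes most loci rare, matching the observed
        excess of low-frequency CNPs.
    amplification_freq : float
        Ancestral frequency of the optional 3-copy allele at mixed loci
        (produces copy states 5-6); 0 disables it.
    admixture_spec : list of (str, dict[str, float]), optional
        Each entry adds a group of admixed individuals: (group name,
        {source population: ancestry proportion}). Group sizes come from
        ``admixture_sizes`` (parallel list, default 20 each).
    admixture_sizes : list of int, optional
    confidence_noise : (float, float)
        Beta shape pair for per-call confidence scores.
    missing_rate : float
        Probability a call is set to missing.
    seed : int
        RNG seed; output is bit-identical for a fixed seed.
    """

    n_populations: int = 12
    n_individuals: int = 90
    population_sizes: dict | None = None
    n_loci: int = 1279
    architecture_mix: tuple = (0.6, 0.2, 0.2)
    F: float | tuple = 0.05
    ancestral_freq_prior: tuple = (0.5, 2.0)
    amplification_freq: float = 0.02
    admixture_spec: list = field(default_factory=list)
    admixture_sizes: list = field(default_factory=list)
    confidence_noise: tuple = (8.0, 2.0)
    missing_rate: float = 0.0
    seed: int = 0

    def resolved_sizes(self) -> dict[str, int]:
        if self.population_sizes is not None:
            return dict(self.population_sizes)
        return {f"P{i + 1}": self.n_individuals for i in range(self.n_populations)}

    def validate(self) -> None:
        mix = np.asarray(self.architecture_mix, dtype=float)
        if mix.shape != (3,) or (mix < 0).any() or abs(mix.sum() - 1) > 1e-9:
            raise ValueError(
                "architecture_mix must be 3 non-negative proportions summing to 1"
            )
        fs = np.atleast_1d(np.asarray(self.F, dtype=float))
        if ((fs <= 0) | (fs >= 1)).any():
            raise ValueError("F must be strictly inside (0, 1)")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        sizes = self.resolved_sizes()
        if len(sizes) < 1 or any(n < 1 for n in sizes.values()):
            raise ValueError("every population needs at least one individual")
        if len(fs) not in (1, len(sizes)):
            raise ValueError("F must be scalar or one value per population")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.amplification_freq < 1:
            raise ValueError("amplification_freq must be in [0, 1)")
        for name, q in self.admixture_spec:
            qv = np.array(list(q.values()), dtype=float)
            if (qv < 0).any() or abs(qv.sum() - 1) > 1e-9:
                raise ValueError(f"ancestry proportions for {name} must sum to 1")
            unknown = set(q) - set(sizes)
            if unknown:
                raise ValueError(f"admixture group {name}: unknown sources {unknown}")


@dataclass
class TruthSet:
    """Ground truth recorded during simulation.

    Attributes
    ----------
    ancestral_freqs : pandas.DataFrame
        Per locus, ancestral frequency of each allele copy value (columns
        ``a0``..``a3``; alleles absent from a locus have frequency 0).
    population_freqs : pandas.DataFrame
        Realized per-population allele frequencies, indexed by
        (locus, population), same columns.
    ancestry : pandas.DataFrame
        Per-individual ancestry proportions over the source populations.
    architectures : pandas.Series
        Per-locus architecture label.
    """

    ancestral_freqs: pd.DataFrame
    population_freqs: pd.DataFrame
    ancestry: pd.DataFrame
    architectures: pd.Series


def _ancestral_vector(arch: str, rng, prior, amp_freq) -> tuple[np.ndarray, np.ndarray]:
    """Draw (allele copy values, ancestral frequency vector) for one locus."""
    a, b = prior
    alleles = _ARCH_ALLELES[arch]
    if arch == "deletion":
        p = rng.beta(a, b)
        freqs = np.array([p, 1 - p])
    elif arch == "duplication":
        p = rng.beta(a, b)
        freqs = np.array([1 - p, p])
    else:
        d = rng.beta(a, b)
        g = rng.beta(a, b) * (1 - d)  # keep d + g < 1
        freqs = np.array([d, 1 - d - g, g])
        if amp_freq > 0 and rng.random() < 0.5:
            # optional rare amplification allele extends states to 5-6
            freqs = np.append(freqs * (1 - amp_freq), amp_freq)
            alleles = np.array([0, 1, 2, 3], dtype=np.int8)
    return alleles, freqs


def simulate_dataset(config: SimulationConfig) -> tuple[GenotypeMatrix, TruthSet]:
    """Generate a multi-population CNP genotype matrix plus its ground truth.

    Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes = config.resolved_sizes()
    pop_names = list(sizes)
    n_pops = len(pop_names)
    fs = np.atleast_1d(np.asarray(config.F, dtype=float))
    if fs.size == 1:
        fs = np.repeat(fs, n_pops)

    # sample roster: source populations first, then admixed groups
    samples, labels, q_rows = [], [], []
    for p, name in enumerate(pop_names):
        for i in range(sizes[name]):
            samples.append(f"{name}_{i + 1:03d}")
            labels.append(name)
            q = np.zeros(n_pops)
            q[p] = 1.0
            q_rows.append(q)
    adm_sizes = list(config.admixture_sizes) or [20] * len(config.admixture_spec)
    for (gname, qmap), gsize in zip(config.admixture_spec, adm_sizes):
        q = np.array([qmap.get(nm, 0.0) for nm in pop_names])
        for i in range(gsize):
            samples.append(f"{gname}_{i + 1:03d}")
            labels.append(gname)
            q_rows.append(q)
    Q = np.array(q_rows)
    n_samples = len(samples)

    n_loci = config.n_loci
    arch_idx = rng.choice(3, size=n_loci, p=np.asarray(config.architecture_mix))
    archs = np.array(_ARCHS, dtype=object)[arch_idx]

    cn = np.zeros((n_loci, n_samples), dtype=np.int16)
    anc_rows = np.zeros((n_loci, 4))
    pf_rows = np.zeros((n_loci, n_pops, 4))
    for l in range(n_loci):
        alleles, anc = _ancestral_vector(
            archs[l], rng, config.ancestral_freq_prior, config.amplification_freq
        )
        k = len(alleles)
        anc_rows[l, alleles] = anc
        # per-population frequencies: Dirichlet(anc * (1-F)/F), the
        # multi-allele Balding-Nichols analogue (Beta when k = 2)
        popfreq = np.empty((n_pops, k))
        for p in range(n_pops):
            conc = np.maximum(anc, 1e-12) * (1 - fs[p]) / fs[p]
            popfreq[p] = rng.dirichlet(conc)
            pf_rows[l, p, alleles] = popfreq[p]
        # each allele copy: pick source population by ancestry, then allele
        src = (rng.random((n_samples, 2, 1)) > Q.cumsum(axis=1)[:, None, :]).sum(axis=2)
        u = rng.random((n_samples, 2))
        cum = popfreq.cumsum(axis=1)
        draw = (u[..., None] > cum[src]).sum(axis=2)
        cn[l] = alleles[draw].sum(axis=1)

    confidence = rng.beta(*config.confidence_noise, size=cn.shape)
    if config.missing_rate > 0:
        cn[rng.random(cn.shape) < config.missing_rate] = MISSING

    # locus coordinates: spread along 22 autosomes, sizes 1 kb - 200 kb
    chroms = np.array([f"chr{c}" for c in (np.arange(n_loci) % 22) + 1], dtype=object)
    lengths = np.round(np.exp(rng.uniform(np.log(1e3), np.log(2e5), size=n_loci))).astype(np.int64)
    starts = np.zeros(n_loci, dtype=np.int64)
    for c in np.unique(chroms):
        m = chroms == c
        gaps = rng.integers(10_000, 2_000_000, size=m.sum())
        starts[m] = np.cumsum(gaps + lengths[m]) - lengths[m]
    loci = pd.DataFrame({
        "id": [f"CNP{i + 1}" for i in range(n_loci)],
        "chrom": chroms,
        "start": starts,
        "end": starts + lengths,
    })

    gm = GenotypeMatrix(loci, samples, labels, cn, confidence)
    truth = TruthSet(
        ancestral_freqs=pd.DataFrame(
            anc_rows, index=loci["id"], columns=[f"a{j}" for j in range(4)]
        ),
        population_freqs=pd.DataFrame(
            pf_rows.reshape(n_loci * n_pops, 4),
            index=pd.MultiIndex.from_product(
                [loci["id"], pop_names], names=["locus", "population"]
            ),
            columns=[f"a{j}" for j in range(4)],
        ),
        ancestry=pd.DataFrame(Q, index=samples, columns=pop_names),
        architectures=pd.Series(archs, index=pd.Index(loci["id"], name="locus"), name="architecture"),
    )
    return gm, truth


def write_truth_tsv(truth: TruthSet, prefix) -> None:
    """Write the ground truth as three TSV files sharing a path prefix."""
    truth.ancestral_freqs.to_csv(f"{prefix}.ancestral_freqs.tsv", sep="\t")
    truth.population_freqs.to_csv(f"{prefix}.population_freqs.tsv", sep="\t")
    truth.ancestry.to_csv(f"{prefix}.ancestry.tsv", sep="\t", index_label="sample_id")
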