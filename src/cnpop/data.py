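"""Core data model for copy-number polymorphism (CNP) genotype matrices.

A CNP locus is a genomic segment whose diploid copy number (CN) varies
between individuals. Array-based callers report an integer copy state per
individual per locus, here restricted to 0-6 with CN=2 the normal diploid
state. The seven copy states are generated by a four-allele system of
haploid alleles carrying 0, 1, 2 or 3 segment copies: the copy state is the
sum of the two allele copy values, so CN 0..6 correspond to the unphased
genotypes 0/0, 0/1, 1/1, 1/2, 2/2, 2/3 and 3/3.

Coordinates are stored 0-based half-open internally and rendered 1-based
inclusive in text files (UCSC text convention).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "ALLELE_PAIRS",
    "CNPLocus",
    "GenotypeMatrix",
    "IntervalSet",
    "FilterReport",
    "OverlapReport",
    "encode_genotype",
    "decode_genotype",
    "classify_locus",
    "classify_loci",
    "filter_calls",
    "reciprocal_overlap",
    "reciprocal_overlap_filter",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_population_map",
    "write_population_map",
    "read_intervals_bed",
    "read_intervals_vcf",
]

#: Sentinel for a missing copy-number call.
MISSING = -1

#: Row s of this table is the allele pair encoding copy state s.
ALLELE_PAIRS = np.array(
    [(0, 0), (0, 1), (1, 1), (1, 2), (2, 2), (2, 3), (3, 3)], dtype=np.int8
)

DELETION = "deletion"
DUPLICATION = "duplication"
MIXED = "mixed"
NON_ALLELIC = "non-allelic"


def encode_genotype(cn: int) -> tuple[int, int]:
    """Map a copy state 0..6 to its unphased allele pair.

    The four-allele system assigns haploid alleles carrying 0, 1, 2 or 3
    copies of the segment; a diploid copy state is the sum of its two
    alleles, giving the fixed mapping 0->(0,0), 1->(0,1), 2->(1,1),
    3->(1,2), 4->(2,2), 5->(2,3), 6->(3,3).
    """
    if not 0 <= cn <= 6:
        raise ValueError(f"copy state must be in 0..6, got {cn}")
    a, b = ALLELE_PAIRS[int(cn)]
    return int(a), int(b)


def decode_genotype(pair: tuple[int, int]) -> int:
    """Inverse of :func:`encode_genotype`: allele pair -> copy state."""
    a, b = pair
    cn = int(a) + int(b)
    if tuple(sorted((int(a), int(b)))) != tuple(ALLELE_PAIRS[cn]):
        raise ValueError(f"{pair!r} is not a valid allele pair")
    return cn


def classify_locus(states) -> str:
    """Classify a locus from the set of copy states observed across samples.

    ``deletion`` if only states <= 2 occur with at least one below 2,
    ``duplication`` if only states >= 2 occur with at least one above 2,
    ``mixed`` if both losses and gains occur, and ``non-allelic`` if every
    individual is at the normal state CN=2.
    """
    s = {int(x) for x in states if x != MISSING}
    if not s:
        raise ValueError("empty copy-state set")
    if not s <= set(range(7)):
        raise ValueError(f"invalid copy states: {sorted(s - set(range(7)))}")
    has_loss = min(s) < 2
    has_gain = max(s) > 2
    if has_loss and has_gain:
        return MIXED
    if has_loss:
        return DELETION
    if has_gain:
        return DUPLICATION
    return NON_ALLELIC


@dataclass(frozen=True)
class CNPLocus:
    """One CNP locus: identifier, chromosome and 0-based half-open span."""

    id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"locus {self.id}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class GenotypeMatrix:
    """Integer copy-number calls for samples x loci with population labels.

    Parameters
    ----------
    loci : pandas.DataFrame
        One row per locus with columns ``id``, ``chrom``, ``start``, ``end``
        (0-based half-open).
    samples : sequence of str
        Ordered sample identifiers (columns of ``cn``).
    populations : sequence of str
        Population label per sample.
    cn : ndarray of shape (n_loci, n_samples)
        Integer copy states in 0..6, or :data:`MISSING` (-1).
    confidence : ndarray, optional
        Per-call confidence score, same shape as ``cn``.
    """

    def __init__(self, loci, samples, populations, cn, confidence=None):
        loci = pd.DataFrame(loci).reset_index(drop=True)
        required = {"id", "chrom", "start", "end"}
        if not required <= set(loci.columns):
            raise ValueError(f"loci table must have columns {sorted(required)}")
        if (loci["end"] <= loci["start"]).any():
            bad = loci.loc[loci["end"] <= loci["start"], "id"].tolist()
            raise ValueError(f"loci with non-positive length: {bad}")
        cn = np.asarray(cn, dtype=np.int16)
        samples = list(samples)
        populations = np.asarray(populations, dtype=object)
        if cn.shape != (len(loci), len(samples)):
            raise ValueError(
                f"cn shape {cn.shape} inconsistent with {len(loci)} loci x "
                f"{len(samples)} samples"
            )
        if len(populations) != len(samples):
            raise ValueError("one population label per sample required")
        valid = ((cn >= 0) & (cn <= 6)) | (cn == MISSING)
        if not valid.all():
            raise ValueError("copy states must be in 0..6 or missing (-1)")
        if confidence is not None:
            confidence = np.asarray(confidence, dtype=float)
            if confidence.shape != cn.shape:
                raise ValueError("confidence must have the same shape as cn")
        self.loci = loci
        self.samples = samples
        self.populations = populations
        self.cn = cn
        self.confidence = confidence

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def population_names(self) -> list[str]:
        seen = dict.fromkeys(self.populations)
        return list(seen)

    @property
    def lengths(self) -> np.ndarray:
        return (self.loci["end"] - self.loci["start"]).to_numpy()

    def population_mask(self, population: str) -> np.ndarray:
        mask = self.populations == population
        if not mask.any():
            raise KeyError(f"unknown population: {population}")
        return mask

    def allele_pairs(self) -> np.ndarray:
        """Encoded alleles, shape (n_loci, n_samples, 2); missing calls -1."""
        out = np.full((*self.cn.shape, 2), MISSING, dtype=np.int8)
        ok = self.cn != MISSING
        out[ok] = ALLELE_PAIRS[self.cn[ok]]
        return out

    def locus_classes(self) -> pd.Series:
        """Per-locus architecture class from all non-missing calls."""
        return classify_loci(self.cn, self.loci["id"])

    def subset_loci(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        conf = None if self.confidence is None else self.confidence[index]
        return GenotypeMatrix(
            self.loci.iloc[index], self.samples, self.populations,
            self.cn[index], conf,
        )

    def subset_samples(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            raise ValueError("sample subset requires a boolean mask")
        conf = None if self.confidence is None else self.confidence[:, mask]
        return GenotypeMatrix(
            self.loci, [s for s, m in zip(self.samples, mask) if m],
            self.populations[mask], self.cn[:, mask], conf,
        )

    def copy(self) -> "GenotypeMatrix":
        conf = None if self.confidence is None else self.confidence.copy()
        return GenotypeMatrix(
            self.loci.copy(), list(self.samples), self.populations.copy(),
            self.cn.copy(), conf,
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_loci} loci x {self.n_samples} samples, "
            f"{len(self.population_names)} populations)"
        )


def classify_loci(cn: np.ndarray, ids=None) -> pd.Series:
    """Vectorised :func:`classify_locus` over the rows of a CN matrix."""
    cn = np.asarray(cn)
    ok = cn != MISSING
    if not ok.any(axis=1).all():
        raise ValueError("every locus needs at least one non-missing call")
    masked = np.where(ok, cn, 2)
    has_loss = ((cn < 2) & ok).any(axis=1)
    has_gain = (masked > 2).any(axis=1)
    out = np.where(
        has_loss & has_gain, MIXED,
        np.where(has_loss, DELETION, np.where(has_gain, DUPLICATION, NON_ALLELIC)),
    )
    index = None if ids is None else pd.Index(ids, name="locus")
    return pd.Series(out, index=index, name="class")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Counts removed by the confidence/length filter."""

    n_calls_masked: int = 0
    n_loci_dropped: int = 0
    dropped_locus_ids: list = field(default_factory=list)


def filter_calls(
    gm: GenotypeMatrix,
    min_confidence: float = 0.1,
    min_length: int = 1000,
    comparator: str = ">",
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the call-level confidence filter and the locus-size filter.

    Calls whose confidence fails the threshold are set to missing; loci
    shorter than ``min_length`` bases are dropped entirely. The comparator
    defaults to keep-if-score>threshold and can be switched to ``">="`` or,
    for scores where small means confident, ``"<"``/``"<="``.
    """
    if min_confidence < 0 or min_length < 0:
        raise ValueError("thresholds must be non-negative")
    ops = {
        ">": np.greater, ">=": np.greater_equal,
        "<": np.less, "<=": np.less_equal,
    }
    if comparator not in ops:
        raise ValueError(f"comparator must be one of {sorted(ops)}")
    report = FilterReport()
    out = gm.copy()
    if out.confidence is not None:
        keep = ops[comparator](out.confidence, min_confidence)
        fail = ~keep & (out.cn != MISSING)
        report.n_calls_masked = int(fail.sum())
        out.cn[fail] = MISSING
    long_enough = out.lengths >= min_length
    report.n_loci_dropped = int((~long_enough).sum())
    report.dropped_locus_ids = out.loci.loc[~long_enough, "id"].tolist()
    out = out.subset_loci(np.nonzero(long_enough)[0])
    if out.n_loci == 0:
        import warnings

        warnings.warn("all loci removed by the size filter", stacklevel=2)
    return out, report


# ---------------------------------------------------------------------------
# Reciprocal-overlap filtering against a reference SV set
# ---------------------------------------------------------------------------

class IntervalSet:
    """Reference structural-variant intervals, 0-based half-open."""

    def __init__(self, intervals):
        df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["end"] <= df["start"]).any():
            raise ValueError("reference intervals must satisfy end > start")
        self._by_chrom = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            # running maximum of end along the start-sorted order lets the
            # sweep stop early when scanning leftwards
            self._by_chrom[str(chrom)] = (starts, ends, np.maximum.accumulate(ends))
        self._df = df

    def __len__(self) -> int:
        return len(self._df)

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def overlaps(self, chrom: str, start: int, end: int, min_fraction: float) -> bool:
        """True if some same-chromosome interval shares at least
        ``min_fraction`` of BOTH interval lengths (reciprocal overlap,
        ties at exactly the threshold count as overlapping)."""
        if chrom not in self._by_chrom:
            return False
        starts, ends, runmax = self._by_chrom[chrom]
        length = end - start
        need = min_fraction * length
        # candidate refs must start early enough to share >= need with the query
        hi = np.searchsorted(starts, end - need, side="right")
        i = hi - 1
        while i >= 0:
            if runmax[i] < start + need:
                break  # nothing further left can reach the required span
            shared = min(ends[i], end) - max(starts[i], start)
            if shared >= need and shared >= min_fraction * (ends[i] - starts[i]):
                return True
            i -= 1
        return False


def reciprocal_overlap(a_start, a_end, b_start, b_end, min_fraction: float) -> bool:
    """Symmetric reciprocal-overlap predicate for two intervals."""
    shared = min(a_end, b_end) - max(a_start, b_start)
    return (
        shared >= min_fraction * (a_end - a_start)
        and shared >= min_fraction * (b_end - b_start)
    )


@dataclass
class OverlapReport:
    """Outcome of the reciprocal-overlap false-positive filter."""

    overlap_status: pd.Series
    removed_locus_ids: list
    n_removed: int


def reciprocal_overlap_filter(
    loci: pd.DataFrame,
    frequencies,
    ref: IntervalSet,
    min_fraction: float = 0.5,
    freq_threshold: float = 0.9,
) -> tuple[pd.DataFrame, OverlapReport]:
    """Remove likely false-positive loci unsupported by a reference SV set.

    A locus overlapping no reference interval at >= ``min_fraction``
    reciprocal overlap while segregating above ``freq_threshold`` carrier
    frequency is removed as a potential artifact: a genuinely common variant
    is expected to have been seen before. All other loci are retained, with
    overlap status annotated.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if not 0 < freq_threshold <= 1:
        raise ValueError("freq_threshold must be in (0, 1]")
    loci = pd.DataFrame(loci).reset_index(drop=True)
    freqs = np.asarray(frequencies, dtype=float)
    if len(freqs) != len(loci):
        raise ValueError("one frequency per locus required")
    status = np.array([
        ref.overlaps(row.chrom, row.start, row.end, min_fraction)
        for row in loci.itertuples()
    ])
    remove = (freqs > freq_threshold) & ~status
    retained = loci.loc[~remove].reset_index(drop=True)
    report = OverlapReport(
        overlap_status=pd.Series(status, index=loci["id"].to_numpy(), name="overlaps_reference"),
        removed_locus_ids=loci.loc[remove, "id"].tolist(),
        n_removed=int(remove.sum()),
    )
    return retained, report


# ---------------------------------------------------------------------------
# Text I/O
# ---------------------------------------------------------------------------
# Genotype TSV: rows = loci with columns id, chrom, start, end (1-based
# inclusive) followed by one integer CN column per sample, "." = missing.
# Confidence TSV shares the layout. Population map TSV: sample_id, population.

def write_genotype_tsv(gm: GenotypeMatrix, path, confidence_path=None) -> None:
    df = gm.loci[["id", "chrom", "start", "end"]].copy()
    df["start"] = df["start"] + 1  # 1-based inclusive in text
    cn = pd.DataFrame(gm.cn, columns=gm.samples).astype(object)
    cn[gm.cn == MISSING] = "."
    pd.concat([df, cn], axis=1).to_csv(path, sep="\t", index=False)
    if confidence_path is not None and gm.confidence is not None:
        conf = pd.DataFrame(np.round(gm.confidence, 6), columns=gm.samples)
        pd.concat([df, conf], axis=1).to_csv(confidence_path, sep="\t", index=False)


def read_genotype_tsv(path, population_map, confidence_path=None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = df[["id", "chrom", "start", "end"]].copy()
    meta["start"] = meta["start"] - 1  # back to 0-based half-open
    samples = [c for c in df.columns if c not in ("id", "chrom", "start", "end")]
    cn = df[samples].replace(".", MISSING).astype(np.int16).to_numpy()
    conf = None
    if confidence_path is not None:
        cdf = pd.read_csv(confidence_path, sep="\t")
        conf = cdf[samples].to_numpy(dtype=float)
    pops = pd.Series(population_map)
    missing = [s for s in samples if s not in pops.index]
    if missing:
        raise ValueError(f"samples without population label: {missing[:5]}")
    return GenotypeMatrix(meta, samples, pops[samples].to_numpy(), cn, conf)


def read_population_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "population"} <= set(df.columns):
        raise ValueError("population map needs columns sample_id, population")
    return dict(zip(df["sample_id"], df["population"]))


def write_population_map(gm: GenotypeMatrix, path) -> None:
    pd.DataFrame({"sample_id": gm.samples, "population": gm.populations}).to_csv(
        path, sep="\t", index=False
    )


def read_intervals_bed(path) -> IntervalSet:
    """Read reference SV intervals from a BED file (3+ columns, 0-based)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            rows.append((fields[0], int(fields[1]), int(fields[2])))
    return IntervalSet(rows)


_SV_TYPES = {"DEL", "DUP", "CNV"}


def read_intervals_vcf(path, sv_types=_SV_TYPES) -> IntervalSet:
    """Read copy-number-class structural variants from a VCF.

    Uses POS and INFO/END; keeps records whose INFO/SVTYPE is one of
    ``sv_types`` (DEL, DUP, CNV by default).
    """
    import pysam

    rows = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype is None or str(svtype) not in sv_types:
                continue
            end = rec.stop  # pysam resolves INFO/END, 0-based exclusive
            rows.append((rec.chrom, rec.start, end))
    return IntervalSet(rows)
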