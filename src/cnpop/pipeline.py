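"""End-to-end orchestration of the CNP population-genetics analysis.

``run_pipeline`` executes the full analysis sequence on a genotype matrix:
filter -> encode -> frequencies -> class/size comparisons -> high-frequent
detection -> sharing -> pairwise Fst -> selection scan -> UPGMA tree ->
PCA -> admixture with Evanno model selection, writing one TSV per stage
plus a summary. Every artifact carries the configuration hash and seed in a
header comment, and all randomness flows from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import admixture as adm
from . import compare as cmp
from . import differentiation as diff
from .data import GenotypeMatrix, IntervalSet, filter_calls, reciprocal_overlap_filter

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("cnpop")


class PipelineError(RuntimeError):
    """Raised when a stage fails; carries the failing stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All thresholds and ranges of the analysis, with study defaults."""

    focal_population: str = "TUN"
    min_confidence: float = 0.1
    min_length: int = 1000
    overlap_fraction: float = 0.5
    false_positive_frequency: float = 0.9
    alpha: float = 0.05
    top_fraction: float = 0.01
    k_min: int = 2
    k_max: int = 6
    k_replicates: int = 3
    admixture_burn_in: int = 10_000
    admixture_iters: int = 10_000
    n_bootstrap: int = 1000
    seed: int = 0
    class_test_method: str = "fisher"
    class_test_family: str = "all-pairs"

    def validate(self) -> None:
        if not 0 < self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in (0, 1]")
        if not 0 < self.false_positive_frequency <= 1:
            raise ValueError("false_positive_frequency must be in (0, 1]")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("need 1 <= k_min <= k_max")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _write(df: pd.DataFrame, path: Path, config: PipelineConfig, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cnpop config={config.config_hash()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", **kwargs)


def run_pipeline(
    gm: GenotypeMatrix,
    config: PipelineConfig,
    outdir,
    reference_svs: IntervalSet | None = None,
) -> dict:
    """Run every analysis stage and write per-stage TSVs under ``outdir``.

    Returns a dict of in-memory stage results. Stage failures raise
    :class:`PipelineError` naming the stage; artifacts written before the
    failure are retained.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    focal = config.focal_population

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:  # noqa: BLE001 - report failing stage
                raise PipelineError(name, exc) from exc
            log.info("stage %-12s %6.2fs", name, time.perf_counter() - t0)
            results[name] = out
            return out

        return wrap

    gm_f, filter_report = stage("filter")(
        lambda: filter_calls(gm, config.min_confidence, config.min_length)
    )

    def _freqs():
        return cmp.carrier_frequencies(gm_f)

    ft = stage("frequencies")(_freqs)

    if reference_svs is not None:
        def _overlap():
            freqs = ft.carrier_freq_matrix().max(axis=1).reindex(gm_f.loci["id"]).fillna(0)
            retained, report = reciprocal_overlap_filter(
                gm_f.loci, freqs.to_numpy(), reference_svs,
                config.overlap_fraction, config.false_positive_frequency,
            )
            keep = gm_f.loci["id"].isin(retained["id"]).to_numpy()
            return gm_f.subset_loci(np.nonzero(keep)[0]), report

        gm_f, overlap_report = stage("overlap_filter")(_overlap)
        ft = stage("frequencies")(_freqs)

    classes = gm_f.locus_classes()
    _write(ft.table, outdir / "frequency_table.tsv", config)
    _write(ft.state_tallies, outdir / "cn_state_tallies.tsv", config)

    class_cmp = stage("class_comparison")(
        lambda: cmp.compare_class_distributions(
            ft, focal, method=config.class_test_method, family=config.class_test_family
        )
    )
    _write(class_cmp, outdir / "class_comparisons.tsv", config)

    def _sizes():
        lengths = gm_f.lengths
        groups = {
            c: lengths[(classes == c).to_numpy()]
            for c in ("deletion", "duplication", "mixed")
            if (classes == c).any()
        }
        if len(groups) < 2:
            return pd.DataFrame()
        return cmp.compare_size_distributions(groups)

    size_cmp = stage("size_comparison")(_sizes)
    _write(size_cmp, outdir / "size_comparisons.tsv", config, index=False)

    hf = stage("high_frequent")(
        lambda: cmp.high_frequent_cnps(ft, focal, config.alpha, classes=classes)
    )
    _write(hf.detail, outdir / "high_frequent_detail.tsv", config)
    pd.Series(hf.loci, name="locus").to_csv(outdir / "high_frequent_loci.tsv", sep="\t", index=False)

    share = stage("sharing")(lambda: cmp.sharing_analysis(ft))
    _write(share.presence.astype(int), outdir / "sharing_matrix.tsv", config)

    def _fst():
        mat, per_pair = diff.pairwise_fst_matrix(gm_f, focal=None)
        return mat, per_pair

    fst_mat, fst_pairs = stage("fst")(_fst)
    bins = fst_mat.map(lambda v: diff.classify_differentiation(v) if np.isfinite(v) else "")
    _write(fst_mat, outdir / "pairwise_fst.tsv", config)
    _write(bins, outdir / "pairwise_fst_bins.tsv", config)

    focal_pairs = {k: v for k, v in fst_pairs.items() if focal in k}
    scan_pairs, scan_union = stage("selection_scan")(
        lambda: diff.selection_scan(focal_pairs or fst_pairs, config.top_fraction)
    )
    pd.Series(scan_union, name="locus").to_csv(outdir / "selection_candidates.tsv", sep="\t", index=False)

    tree = stage("tree")(
        lambda: diff.distance_tree(gm_f, config.n_bootstrap, seed=config.seed)
    )
    (outdir / "upgma_tree.nwk").write_text(tree.newick + "\n")
    _write(tree.distance_matrix, outdir / "population_distances.tsv", config)

    pca_res = stage("pca")(lambda: diff.pca(gm_f))
    coords = pca_res.coordinates.copy()
    coords.insert(0, "population", gm_f.populations)
    _write(coords, outdir / "pca_coordinates.tsv", config, index_label="sample_id")

    def _admixture():
        runs = adm.replicate_runs(
            gm_f, range(config.k_min, config.k_max + 1), config.k_replicates,
            config.admixture_burn_in, config.admixture_iters, seed=config.seed,
        )
        evanno = adm.evanno_delta_k(runs)
        return runs, evanno

    runs, evanno = stage("admixture")(_admixture)
    _write(evanno, outdir / "evanno.tsv", config)
    best_k = evanno.attrs["best_k"]
    if best_k is not None:
        aligned, _ = adm.align_runs(runs[best_k], runs[best_k][0])
        qbar = np.mean([r.q for r in aligned], axis=0)
        qdf = pd.DataFrame(qbar, index=gm_f.samples, columns=[f"q{k+1}" for k in range(best_k)])
        qdf.insert(0, "population", gm_f.populations)
        _write(qdf, outdir / f"q_matrix_K{best_k}.tsv", config, index_label="sample_id")

    summary = pd.DataFrame(
        {
            "value": {
                "n_loci_input": gm.n_loci,
                "n_loci_after_filter": gm_f.n_loci,
                "n_calls_masked": filter_report.n_calls_masked,
                "n_high_frequent": len(hf.loci),
                "n_high_frequent_deletion": len(hf.by_class.get("deletion", [])),
                "n_high_frequent_duplication": len(hf.by_class.get("duplication", [])),
                "n_high_frequent_mixed": len(hf.by_class.get("mixed", [])),
                "n_shared_in_all": len(share.shared_in_all),
                "n_selection_candidates": len(scan_union),
                "best_k": best_k if best_k is not None else "NA",
            }
        }
    )
    _write(summary, outdir / "summary.tsv", config, index_label="quantity")
    results["summary"] = summary
    return results
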