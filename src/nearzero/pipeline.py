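"""End-to-end orchestration: simulate -> preprocess -> test -> cluster
-> enrich -> kinetics.

A single global seed is fanned out into stable stage-specific child
seeds, so re-running the whole pipeline (or a single stage on the
written intermediates) is byte-reproducible.  Every stage writes its
outputs as plain-text tables under the run directory; the run is
summarized in a JSON report of per-stage counts and the kinetic summary.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nzio
from .clustering import ClusteringConfig, kmeans_correlation
from .enrichment import (
    GeneSetCollection,
    Motif,
    hypergeometric_enrichment,
    motif_enrichment_factor,
    scan_motif,
)
from .kinetics import (
    RetentostatParams,
    doubling_time,
    fit_biomass_curve,
    glucose_partition,
    specific_growth_rate,
)
from .preprocess import (
    floor_and_filter,
    global_scale,
    mean_normalize_profiles,
    select_orfs,
    validate_metadata,
)
from .significance import TestConfig, call_significant, differential_expression
from .simulate import (
    DesignSpec,
    NoiseSpec,
    generate_expression,
    generate_gene_sets,
    generate_promoters,
    generate_retentostat_series,
)

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline", "stage_seed"]

log = logging.getLogger("nearzero.pipeline")

ALL_STAGES = ("simulate", "preprocess", "test", "cluster", "enrich", "kinetics")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable child seed for a stage, derived from the global seed."""
    idx = ALL_STAGES.index(stage)
    ss = np.random.SeedSequence([int(global_seed), idx])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Stage-specific settings keep their own dataclasses; ``stages``
    selects which stages run (later stages read the written
    intermediates of earlier ones when those are skipped).
    """

    outdir: Path
    seed: int = 42
    stages: tuple = ALL_STAGES
    design: DesignSpec = field(default_factory=DesignSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    n_genes_per_archetype: int = 60
    n_housekeeping: int = 6
    n_null: int = 600
    n_decoy_features: int = 150
    test: TestConfig = field(default_factory=TestConfig)
    cluster: ClusteringConfig = field(default_factory=ClusteringConfig)
    params: RetentostatParams = field(
        default_factory=lambda: RetentostatParams(D=0.025, Cs_in=50.0)
    )
    series_noise_cv: float = 0.02
    enrich_p_threshold: float = 1e-6
    motif: Motif = field(default_factory=lambda: Motif("TCGTTYAG"))
    promoter_p_background: float = 0.10
    promoter_p_planted: float = 0.40
    planted_motif_archetype: int = 6
    planted_sets: tuple = (("planted_arch2", 2, 8.0),)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")


@dataclass
class RunReport:
    """Per-stage counts and the kinetic summary of one pipeline run."""

    seed: int
    stages_run: list = field(default_factory=list)
    n_samples: int | None = None
    n_features: int | None = None
    n_after_filter: int | None = None
    n_orfs: int | None = None
    n_significant: int | None = None
    cluster_sizes: dict = field(default_factory=dict)
    n_enriched_sets: int | None = None
    motif_ef: dict = field(default_factory=dict)
    mu_final: float | None = None
    doubling_time_h: float | None = None
    frac_maintenance_final: float | None = None
    versions: dict = field(default_factory=dict)
    wall_time_s: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=float)


def _setup_logging() -> None:
    if not log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
        log.addHandler(h)
        log.setLevel(logging.INFO)


def _load_or_fail(path: Path, reader, stage: str, what: str):
    if not path.exists():
        raise PipelineError(f"stage {stage!r}: required input {what} not found at {path}")
    return reader(path)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in order; see module docstring."""
    _setup_logging()
    t0 = time.perf_counter()
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    report.versions = {
        "nearzero": _package_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }

    matrix = meta = truth = None
    clean = None
    results = None
    assignment = None

    if "simulate" in config.stages:
        log.info("simulate: generating inputs (seed %d)", config.seed)
        seed = stage_seed(config.seed, "simulate")
        noise = NoiseSpec(
            replicate_cv=config.noise.replicate_cv,
            housekeeping_cv=config.noise.housekeeping_cv,
            housekeeping_cv_max=config.noise.housekeeping_cv_max,
            seed=seed,
        )
        matrix, meta, truth = generate_expression(
            design=config.design,
            n_genes_per_archetype=config.n_genes_per_archetype,
            n_housekeeping=config.n_housekeeping,
            n_null=config.n_null,
            noise=noise,
            n_decoy_features=config.n_decoy_features,
        )
        series, series_truth = generate_retentostat_series(
            params=config.params, noise_cv=config.series_noise_cv, seed=seed + 1
        )
        collection, planted_map = generate_gene_sets(
            truth, planted=config.planted_sets, seed=seed + 2
        )
        planted_motif_genes = truth.loc[
            truth["archetype"] == config.planted_motif_archetype, "gene_id"
        ]
        promoters = generate_promoters(
            truth.loc[truth["is_orf"], "gene_id"],
            motif=config.motif,
            p_background=config.promoter_p_background,
            p_planted=config.promoter_p_planted,
            planted_genes=planted_motif_genes,
            seed=seed + 3,
        )
        nzio.write_matrix(matrix, out / "expression.tsv")
        nzio.write_metadata(meta, out / "metadata.tsv")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        nzio.write_series(series, out / "series.tsv")
        series_truth.to_csv(out / "series_truth.tsv", sep="\t", index=False)
        collection.to_gmt(out / "gene_sets.gmt")
        nzio.write_fasta(promoters, out / "promoters.fa")
        nzio.write_gene_list(truth.loc[truth["is_orf"], "gene_id"], out / "orfs.txt")
        report.stages_run.append("simulate")
        report.n_samples = matrix.shape[1]
        report.n_features = matrix.shape[0]

    if "preprocess" in config.stages:
        if matrix is None:
            matrix = _load_or_fail(out / "expression.tsv", nzio.read_matrix, "preprocess", "expression matrix")
            meta = _load_or_fail(out / "metadata.tsv", nzio.read_metadata, "preprocess", "metadata")
        try:
            validate_metadata(matrix, meta)
        except ValueError as e:
            raise PipelineError(f"stage 'preprocess': {e}") from e
        log.info("preprocess: scaling, flooring, filtering, ORF selection")
        scaled = global_scale(matrix)
        floored, removed = floor_and_filter(scaled)
        orfs = nzio.read_gene_list(out / "orfs.txt") if (out / "orfs.txt").exists() else list(floored.index)
        clean = select_orfs(floored, orfs)
        nzio.write_matrix(clean, out / "clean.tsv")
        report.stages_run.append("preprocess")
        report.n_samples = clean.shape[1]
        report.n_features = matrix.shape[0]
        report.n_after_filter = matrix.shape[0] - len(removed)
        report.n_orfs = clean.shape[0]

    if "test" in config.stages:
        if clean is None:
            clean = _load_or_fail(out / "clean.tsv", nzio.read_matrix, "test", "preprocessed matrix")
            meta = _load_or_fail(out / "metadata.tsv", nzio.read_metadata, "test", "metadata")
        tconf = TestConfig(
            df_full=config.test.df_full,
            covariate=config.test.covariate,
            n_permutations=config.test.n_permutations,
            seed=stage_seed(config.seed, "test"),
            p_threshold=config.test.p_threshold,
            q_threshold=config.test.q_threshold,
        )
        log.info("test: permutation F test, B=%d", tconf.n_permutations)
        results = differential_expression(clean, meta, tconf)
        results.to_csv(out / "test_results.tsv", sep="\t", index=False)
        report.stages_run.append("test")
        report.n_significant = int(results["significant"].sum())

    if "cluster" in config.stages:
        if results is None:
            results = _load_or_fail(
                out / "test_results.tsv", lambda p: pd.read_csv(p, sep="\t"), "cluster", "test results"
            )
        if clean is None:
            clean = _load_or_fail(out / "clean.tsv", nzio.read_matrix, "cluster", "preprocessed matrix")
            meta = _load_or_fail(out / "metadata.tsv", nzio.read_metadata, "cluster", "metadata")
        sig_genes = call_significant(results, config.test)
        if len(sig_genes) < config.cluster.k:
            raise PipelineError(
                f"stage 'cluster': only {len(sig_genes)} significant genes for k={config.cluster.k}"
            )
        profiles = mean_normalize_profiles(clean.loc[sig_genes], meta)
        cconf = ClusteringConfig(
            k=config.cluster.k,
            max_iterations=config.cluster.max_iterations,
            n_restarts=config.cluster.n_restarts,
            seed=stage_seed(config.seed, "cluster"),
        )
        log.info("cluster: k-means (1-r distance), k=%d on %d genes", cconf.k, len(sig_genes))
        assignment = kmeans_correlation(profiles, cconf)
        assignment.labels.rename_axis("gene_id").reset_index().to_csv(
            out / "clusters.tsv", sep="\t", index=False
        )
        assignment.centroids.to_csv(out / "centroids.tsv", sep="\t")
        report.stages_run.append("cluster")
        report.cluster_sizes = {int(c): int(s) for c, s in assignment.sizes().items()}

    if "enrich" in config.stages:
        if assignment is None:
            labels_df = _load_or_fail(
                out / "clusters.tsv", lambda p: pd.read_csv(p, sep="\t"), "enrich", "cluster labels"
            )
            labels = labels_df.set_index("gene_id")["cluster"]
        else:
            labels = assignment.labels
        if clean is None:
            clean = _load_or_fail(out / "clean.tsv", nzio.read_matrix, "enrich", "preprocessed matrix")
        universe = frozenset(clean.index)
        collection = GeneSetCollection.from_gmt(out / "gene_sets.gmt", universe)
        promoters = nzio.read_fasta(out / "promoters.fa")
        hits = scan_motif({g: s for g, s in promoters.items() if g in universe}, config.motif)
        log.info("enrich: %d sets, motif %s", len(collection), config.motif.pattern)
        frames = []
        for cid in sorted(labels.unique()):
            cluster_genes = frozenset(labels.index[labels == cid]) & universe
            df = hypergeometric_enrichment(cluster_genes, collection, config.enrich_p_threshold)
            df.insert(0, "cluster", cid)
            frames.append(df)
            mef = motif_enrichment_factor(cluster_genes, hits, universe)
            report.motif_ef[int(cid)] = {"ef": mef["ef"], "p": mef["p"]}
        enrich_df = pd.concat(frames, ignore_index=True)
        enrich_df.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        report.stages_run.append("enrich")
        report.n_enriched_sets = int(enrich_df["significant"].sum())

    if "kinetics" in config.stages:
        series = _load_or_fail(out / "series.tsv", nzio.read_series, "kinetics", "biomass series")
        log.info("kinetics: fitting biomass trajectory")
        fit = fit_biomass_curve(series)
        profile = specific_growth_rate(fit, series)
        part = glucose_partition(config.params, profile.Cx_viable, profile.mu)
        pd.DataFrame(
            {
                "time_h": profile.t,
                "cx_fit": profile.Cx_fit,
                "dcx_dt": profile.dCx_dt,
                "mu": profile.mu,
                "frac_maintenance": part.frac_maintenance,
                "frac_growth": part.frac_growth,
            }
        ).to_csv(out / "profile.tsv", sep="\t", index=False)
        with open(out / "fit.json", "w") as fh:
            json.dump(
                {"A": fit.A, "B": fit.B, "C": fit.C, "sse": fit.sse, "converged": fit.converged},
                fh,
                indent=2,
            )
        report.stages_run.append("kinetics")
        report.mu_final = float(profile.mu[-1])
        report.doubling_time_h = float(doubling_time(profile.mu[-1]))
        report.frac_maintenance_final = float(part.frac_maintenance[-1])

    report.wall_time_s = time.perf_counter() - t0
    report.to_json(out / "report.json")
    return report


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("nearzero")
    except Exception:
        return "unknown"
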