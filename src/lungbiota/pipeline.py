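"""End-to-end analysis pipeline: from counts (or a simulated cohort) to report.

Stage order: load/simulate -> depth summaries -> contaminant removal ->
rarefaction (controls leave the analysis here; low-yield samples are dropped)
-> alpha diversity with Holm-corrected paired site comparisons -> Bray-Curtis
-> batch correction -> PCoA + PERMANOVA (site and subject groupings) ->
batch-stratified bronchus-lung permutation test -> neutral-model immigration
fits with oral, nasal and bronchial sources. Every stage that consumes
randomness records its seed in the stage log, and a report serialized without
timings is byte-reproducible for a fixed configuration.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Any, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import community, diversity, neutral, stratified, synthetic
from .community import OtuTable, SampleMetadata

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "StageError",
    "run_pipeline",
    "load_config",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class InputPaths(BaseModel):
    otu_table: str
    metadata: str
    format: Literal["tsv", "biom_json"] = "tsv"


class PermutationSettings(BaseModel):
    max_exhaustive: int = 100_000
    n_monte_carlo: int = 10_000


class PipelineConfig(BaseModel):
    """Validated pipeline configuration.

    Exactly one of ``input`` (paths to an OTU table and metadata) or
    ``simulate`` (keyword arguments for the synthetic-cohort generator) must
    be present. Per-stage seeds are derived deterministically from ``seed``.
    """

    input: Optional[InputPaths] = None
    simulate: Optional[dict] = None
    rarefaction_depth: int = Field(default=563, ge=1)
    contaminant_threshold: float = Field(default=0.01, gt=0, lt=1)
    confidence: float = Field(default=0.95, gt=0, lt=1)
    band_method: Literal["quantile", "wilson"] = "quantile"
    neutral_sources: tuple[str, ...] = ("oral", "nasal", "bronchial")
    neutral_table: Literal["rarefied", "filtered"] = "rarefied"
    permutation: PermutationSettings = Field(default_factory=PermutationSettings)
    permanova_permutations: int = Field(default=999, ge=1)
    seed: int = 0
    out_dir: Optional[str] = None

    @model_validator(mode="after")
    def _one_source(self) -> "PipelineConfig":
        if (self.input is None) == (self.simulate is None):
            raise ValueError("exactly one of 'input' or 'simulate' must be given")
        return self

    def stage_seed(self, offset: int) -> int:
        return (self.seed + offset) % (2**31 - 1)


class StageLogEntry(BaseModel):
    stage: str
    seed: Optional[int] = None
    duration_s: Optional[float] = None
    input_shape: Optional[tuple[int, int]] = None
    output_shape: Optional[tuple[int, int]] = None
    message: str = ""


class SummaryStats(BaseModel):
    n_samples: int
    total: int
    mean: float
    median: float


class PermanovaReport(BaseModel):
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int


class PairedPermutationReport(BaseModel):
    observed: float
    p_value: float
    n_permutations: int
    mode: str
    seed: Optional[int] = None


class NeutralFitReport(BaseModel):
    source: str
    m_hat: float
    sse: float
    n_subjects: int
    N: float
    d: float
    n_otus: int
    n_consistent: int
    n_above: int
    n_below: int
    n_absent_in_source: int
    table_used: str
    band_method: str


class PipelineReport(BaseModel):
    depth_summary_subjects: SummaryStats
    depth_summary_with_controls: SummaryStats
    removed_contaminants: list[str]
    rarefaction_depth: int
    dropped_samples: list[str]
    alpha_diversity: list[dict[str, Any]]
    alpha_pairwise: dict[str, list[dict[str, Any]]]
    pcoa_proportion_explained: list[float]
    permanova_site: PermanovaReport
    permanova_subject: Optional[PermanovaReport] = None
    paired_permutation: PairedPermutationReport
    neutral_fits: list[NeutralFitReport]
    stage_log: list[StageLogEntry]

    def to_json(self, include_timings: bool = False) -> str:
        doc = self.model_dump(mode="json")
        if not include_timings:
            for entry in doc["stage_log"]:
                entry["duration_s"] = None
        return json.dumps(doc, sort_keys=True, indent=2)


def load_config(path: str | Path) -> PipelineConfig:
    import yaml

    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return PipelineConfig.model_validate(doc or {})


def _cohort_config(kwargs: dict, seed: int) -> synthetic.CohortConfig:
    kwargs = dict(kwargs)
    guilds = kwargs.pop("guild_sizes", None)
    kwargs.setdefault("seed", seed)
    cfg = synthetic.CohortConfig(**kwargs)
    if guilds is not None:
        cfg.guild_sizes = synthetic.GuildSizes(**guilds)
    return cfg


def run_pipeline(
    config: PipelineConfig,
) -> tuple[PipelineReport, dict[str, Any]]:
    """Run all stages and return the report plus in-memory artifacts.

    Artifacts include the filtered and rarefied tables, distance matrices,
    ordination, and per-taxon neutral-fit tables, keyed by stage name. When
    ``config.out_dir`` is set, tabular artifacts are also written there as
    they are produced, so a failing stage preserves completed outputs.
    """
    log: list[StageLogEntry] = []
    artifacts: dict[str, Any] = {}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name: str, fn, seed: int | None = None, **entry):
        t0 = time.perf_counter()
        try:
            result = fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc
        log.append(
            StageLogEntry(
                stage=name, seed=seed, duration_s=time.perf_counter() - t0, **entry
            )
        )
        return result

    # -- load or simulate ----------------------------------------------------
    if config.simulate is not None:
        sim_seed = config.stage_seed(0)

        def _simulate():
            cfg = _cohort_config(config.simulate, sim_seed)
            return synthetic.simulate_cohort(cfg)

        table, metadata, truth = stage("load", _simulate, seed=sim_seed, message="simulated cohort")
        artifacts["truth"] = truth
    else:
        def _load():
            t = community.read_otu_table(config.input.otu_table, format=config.input.format)
            m = community.read_metadata(config.input.metadata)
            return t, m

        table, metadata = stage("load", _load, message="read input tables")
    artifacts["full_table"] = table
    artifacts["metadata"] = metadata

    # -- depth summaries -----------------------------------------------------
    def _summaries():
        subj = community.summarize_depths(table, metadata, include_controls=False)
        both = community.summarize_depths(table, metadata, include_controls=True)
        return subj, both

    depth_subj, depth_all = stage("summarize_depths", _summaries,
                                  input_shape=(table.n_taxa, table.n_samples))

    # -- contaminant filter --------------------------------------------------
    def _filter():
        return community.remove_contaminant_taxa(
            table, metadata, abundance_threshold=config.contaminant_threshold
        )

    filtered, removed = stage("remove_contaminants", _filter)
    log[-1].output_shape = (filtered.n_taxa, filtered.n_samples)
    log[-1].message = f"removed {len(removed)} taxa"
    artifacts["filtered_table"] = filtered

    # controls exist only to drive the filter; drop them before rarefaction
    subject_samples = [s for s in filtered.sample_ids if metadata.site_of(s) != "control"]
    filtered_subjects = filtered.select_samples(subject_samples)

    # -- rarefaction ---------------------------------------------------------
    rarefy_seed = config.stage_seed(1)

    def _rarefy():
        return community.rarefy(filtered_subjects, config.rarefaction_depth, seed=rarefy_seed)

    rarefied, dropped = stage(
        "rarefy", _rarefy, seed=rarefy_seed,
        input_shape=(filtered_subjects.n_taxa, filtered_subjects.n_samples),
    )
    log[-1].output_shape = (rarefied.n_taxa, rarefied.n_samples)
    log[-1].message = f"dropped {len(dropped)} low-yield samples"
    artifacts["rarefied_table"] = rarefied
    if out_dir:
        community.write_otu_table(rarefied, out_dir / "rarefied_otu_table.tsv")

    # -- alpha diversity + paired site tests ---------------------------------
    def _alpha():
        alpha = diversity.alpha_diversity_table(rarefied)
        pairwise = {
            metric: diversity.pairwise_tests_holm(alpha[metric], metadata)
            for metric in ("shannon", "inverse_simpson")
        }
        return alpha, pairwise

    alpha, pairwise = stage("alpha_diversity", _alpha)
    if out_dir:
        alpha.to_csv(out_dir / "alpha_diversity.tsv", sep="\t")

    # -- beta diversity ------------------------------------------------------
    def _bray():
        return diversity.bray_curtis(
            community.relative_abundance(rarefied), sample_ids=rarefied.sample_ids
        )

    dm_raw = stage("bray_curtis", _bray)
    artifacts["distance_raw"] = dm_raw

    # -- batch correction ----------------------------------------------------
    def _correct():
        rel = community.relative_abundance(rarefied)
        corrected = diversity.batch_correct(rel, rarefied.sample_ids, metadata)
        return corrected, diversity.bray_curtis(corrected, sample_ids=rarefied.sample_ids)

    corrected, dm = stage("batch_correct", _correct)
    artifacts["corrected_proportions"] = corrected
    artifacts["distance_corrected"] = dm
    if out_dir:
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            out_dir / "bray_curtis_corrected.tsv", sep="\t"
        )

    # -- ordination + permanova ----------------------------------------------
    def _ordination():
        return diversity.pcoa(dm, n_axes=2)

    ordination = stage("pcoa", _ordination)
    artifacts["ordination"] = ordination
    if out_dir:
        ordination.to_frame().to_csv(out_dir / "pcoa_coordinates.tsv", sep="\t")

    site_of = {s: metadata.site_of(s) for s in dm.ids}
    subject_of = {s: metadata.subject_of(s) for s in dm.ids}
    perm_seed = config.stage_seed(2)

    def _permanova_site():
        return diversity.permanova(
            dm, site_of, n_permutations=config.permanova_permutations, seed=perm_seed
        )

    res_site = stage("permanova_site", _permanova_site, seed=perm_seed)

    def _permanova_subject():
        # subjects with a single remaining sample still form valid groups;
        # the test errors only if every sample is its own group
        try:
            return diversity.permanova(
                dm, subject_of, n_permutations=config.permanova_permutations,
                seed=perm_seed + 1,
            )
        except ValueError:
            return None

    res_subject = stage("permanova_subject", _permanova_subject, seed=perm_seed + 1)

    # -- paired bronchus-lung stratified permutation test --------------------
    permtest_seed = config.stage_seed(3)

    def _permtest():
        psm = stratified.build_paired_site_matrix(dm, metadata, "bronchial", "lung")
        return stratified.stratified_permutation_test(
            psm,
            max_exhaustive=config.permutation.max_exhaustive,
            n_monte_carlo=config.permutation.n_monte_carlo,
            seed=permtest_seed,
        )

    perm_res = stage("paired_permutation", _permtest, seed=permtest_seed)
    artifacts["paired_permutation"] = perm_res

    # -- neutral fits ---------------------------------------------------------
    neutral_input_table = rarefied if config.neutral_table == "rarefied" else filtered_subjects
    fits: list[NeutralFitReport] = []

    def _neutral():
        out = []
        for source in config.neutral_sources:
            inputs = neutral.prepare_inputs(neutral_input_table, metadata, source, "lung")
            fit = neutral.fit_immigration(
                inputs, confidence=config.confidence, band_method=config.band_method
            )
            out.append((source, fit))
        return out

    for source, fit in stage("neutral_fits", _neutral):
        counts = fit.class_counts()
        fits.append(
            NeutralFitReport(
                source=source,
                m_hat=fit.m_hat,
                sse=fit.sse,
                n_subjects=fit.n_subjects,
                N=fit.N,
                d=fit.d,
                n_otus=len(fit.otus),
                n_consistent=int(counts.get("consistent", 0)),
                n_above=int(counts.get("above", 0)),
                n_below=int(counts.get("below", 0)),
                n_absent_in_source=int(counts.get("absent_in_source", 0)),
                table_used=config.neutral_table,
                band_method=fit.band_method,
            )
        )
        artifacts[f"neutral_fit_{source}"] = fit
        if out_dir:
            fit.otus.to_csv(out_dir / f"neutral_fit_{source}.tsv", sep="\t")

    report = PipelineReport(
        depth_summary_subjects=SummaryStats(
            n_samples=depth_subj.n_samples, total=depth_subj.total,
            mean=depth_subj.mean, median=depth_subj.median,
        ),
        depth_summary_with_controls=SummaryStats(
            n_samples=depth_all.n_samples, total=depth_all.total,
            mean=depth_all.mean, median=depth_all.median,
        ),
        removed_contaminants=removed,
        rarefaction_depth=config.rarefaction_depth,
        dropped_samples=dropped,
        alpha_diversity=alpha.reset_index().to_dict(orient="records"),
        alpha_pairwise={
            metric: frame.replace({np.nan: None}).to_dict(orient="records")
            for metric, frame in pairwise.items()
        },
        pcoa_proportion_explained=[float(v) for v in ordination.proportion_explained],
        permanova_site=PermanovaReport(**vars(res_site)),
        permanova_subject=None if res_subject is None else PermanovaReport(**vars(res_subject)),
        paired_permutation=PairedPermutationReport(
            observed=perm_res.observed, p_value=perm_res.p_value,
            n_permutations=perm_res.n_permutations, mode=perm_res.mode,
            seed=perm_res.seed,
        ),
        neutral_fits=fits,
        stage_log=log,
    )
    if out_dir:
        (out_dir / "report.json").write_text(report.to_json(include_timings=True))
    return report, artifacts
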