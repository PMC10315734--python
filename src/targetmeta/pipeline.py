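"""End-to-end orchestration: ingest -> merge/batch-adjust -> target SMD
meta-analysis -> genome-wide screen -> ROC/SROC -> pathways -> immune ->
survival -> co-expression/intersection -> assay statistics -> report.

Each stage writes its tables under the output directory and appends to a
MANIFEST; a stage failure aborts with the stage name while earlier outputs
are retained.  The JSON report holds the headline summary (pooled SMD with
CI and model, SROC AUC, selected pathways, significant cell types, Cox
result, intersection members) plus run metadata.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from targetmeta import assays, diagnostics, meta, pathways, screen, survival
from targetmeta.cohorts import (
    ExpressionCohort,
    adjust_batch_location_scale,
    merge_same_platform,
    read_expression_matrix,
)
from targetmeta.immune import SignatureMatrix, correlate_gene_cells, deconvolve_samples
from targetmeta.pathways import GeneSetCatalog
from targetmeta.synthetic import (
    SyntheticStudyConfig,
    generate_ancillary,
    generate_multicohort,
)

logger = logging.getLogger(__name__)

STAGES = ["ingest", "merge", "effects", "pooling", "screen", "diagnostics",
          "pathways", "immune", "survival", "coexpression", "assays", "report"]

_DEPS = {
    "merge": ["ingest"],
    "effects": ["merge"],
    "pooling": ["effects"],
    "screen": ["merge"],
    "diagnostics": ["merge"],
    "pathways": ["ingest"],
    "immune": ["ingest"],
    "survival": ["ingest"],
    "coexpression": ["ingest", "screen", "pathways"],
    "assays": ["ingest"],
    "report": [],  # summarizes whatever stages ran
}


class PipelineError(RuntimeError):
    pass


class ValidationError(PipelineError):
    pass


class StageError(PipelineError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Run configuration: synthetic study or real input paths plus thresholds."""

    synthetic: bool = True
    synthetic_config: SyntheticStudyConfig = field(default_factory=SyntheticStudyConfig)
    cohorts: list[dict] = field(default_factory=list)   # expression/metadata/platform/study_id
    gmt_path: str | None = None
    signature_path: str | None = None
    mixture_path: str | None = None
    survival_path: str | None = None
    ihc_path: str | None = None
    qpcr_path: str | None = None
    edges_path: str | None = None
    target_gene: str = "G00001"
    alpha: float = 0.05
    outdir: str = "results"
    seed: int = 0

    def validate(self) -> None:
        if not self.synthetic and not self.cohorts:
            raise ValidationError("config has neither synthetic=true nor input cohorts")
        self.synthetic_config.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic_config", None)
        cfg = cls(**raw)
        if syn:
            allowed = {f.name for f in dataclasses.fields(SyntheticStudyConfig)}
            unknown = set(syn) - allowed
            if unknown:
                raise ValidationError(f"unknown synthetic_config fields: {sorted(unknown)}")
            if "set_size_range" in syn:
                syn["set_size_range"] = tuple(syn["set_size_range"])
            cfg.synthetic_config = SyntheticStudyConfig(**syn)
        return cfg


@dataclass
class PipelineReport:
    headline: dict
    tables: dict[str, str]   # logical name -> file path
    metadata: dict

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"headline": self.headline, "tables": self.tables,
             "metadata": self.metadata}, indent=2, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _closure(requested) -> list[str]:
    want = set(requested)
    changed = True
    while changed:
        changed = False
        for s in list(want):
            for d in _DEPS.get(s, []):
                if d not in want:
                    want.add(d)
                    changed = True
    return [s for s in STAGES if s in want]


def _merge_platforms(cohorts: list[ExpressionCohort]) -> list[ExpressionCohort]:
    by_platform: dict[str, list[ExpressionCohort]] = {}
    for c in cohorts:
        by_platform.setdefault(c.platform_id, []).append(c)
    out = []
    for platform in sorted(by_platform):
        group = by_platform[platform]
        if len(group) == 1:
            out.append(group[0])
        else:
            merged = merge_same_platform(group)
            out.append(adjust_batch_location_scale(merged))
    return out


def run_full_pipeline(config: PipelineConfig,
                      stages: list[str] | None = None) -> PipelineReport:
    """Execute the requested stages (default: all) and write the report."""
    config.validate()
    run = _closure(stages or STAGES)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "MANIFEST"
    manifest_path.write_text("")
    headline: dict = {}
    tables: dict[str, str] = {}
    state: dict = {}

    def _done(stage: str, dt: float) -> None:
        logger.info("stage %-12s done in %.2fs", stage, dt)
        with open(manifest_path, "a") as fh:
            fh.write(stage + "\n")

    def _write(name: str, frame: pd.DataFrame, fname: str) -> None:
        path = outdir / fname
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        tables[name] = str(path)

    for stage in run:
        t0 = time.perf_counter()
        try:
            if stage == "ingest":
                _stage_ingest(config, state)
            elif stage == "merge":
                state["analysis_cohorts"] = _merge_platforms(state["cohorts"])
            elif stage == "effects":
                _stage_effects(config, state, _write)
            elif stage == "pooling":
                _stage_pooling(config, state, headline)
            elif stage == "screen":
                _stage_screen(config, state, headline, _write)
            elif stage == "diagnostics":
                _stage_diagnostics(config, state, headline, _write)
            elif stage == "pathways":
                _stage_pathways(config, state, headline, _write)
            elif stage == "immune":
                _stage_immune(config, state, headline, _write)
            elif stage == "survival":
                _stage_survival(config, state, headline, _write)
            elif stage == "coexpression":
                _stage_coexpression(config, state, headline, _write)
            elif stage == "assays":
                _stage_assays(config, state, headline, _write)
            elif stage == "report":
                pass  # written below once headline is complete
        except PipelineError:
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc
        _done(stage, time.perf_counter() - t0)

    report = PipelineReport(
        headline=headline,
        tables=tables,
        metadata={"seed": config.seed, "target_gene": config.target_gene,
                  "stages": run, "package": "targetmeta"},
    )
    if "report" in run:
        report.to_json(outdir / "report.json")
    return report


# --- stage bodies -----------------------------------------------------------


def _stage_ingest(config: PipelineConfig, state: dict) -> None:
    if config.synthetic:
        cohorts, truth = generate_multicohort(config.synthetic_config, config.seed)
        catalog, signature, mixtures, surv, ihc, qpcr = generate_ancillary(
            config.synthetic_config, truth, config.seed, cohorts)
        config.target_gene = truth.target_gene
        state.update(cohorts=cohorts, truth=truth, catalog=catalog,
                     signature=signature, mixtures=mixtures, survival=surv,
                     ihc=ihc, qpcr=qpcr)
        return
    cohorts = []
    for spec in config.cohorts:
        cohorts.append(read_expression_matrix(
            spec["expression"], spec["metadata"],
            study_id=spec.get("study_id"),
            platform_id=spec.get("platform", "unknown")))
    state["cohorts"] = cohorts
    state["truth"] = None
    state["catalog"] = GeneSetCatalog.read_gmt(config.gmt_path) if config.gmt_path else None
    state["signature"] = (SignatureMatrix.read_tsv(config.signature_path)
                          if config.signature_path else None)
    state["mixtures"] = (pd.read_csv(config.mixture_path, sep="\t", index_col=0)
                         if config.mixture_path else None)
    state["survival"] = pd.read_csv(config.survival_path) if config.survival_path else None
    state["ihc"] = pd.read_csv(config.ihc_path) if config.ihc_path else None
    state["qpcr"] = pd.read_csv(config.qpcr_path) if config.qpcr_path else None


def _primary_cohort(state: dict) -> ExpressionCohort:
    return max(state["cohorts"], key=lambda c: c.n_samples)


def _stage_effects(config, state, _write) -> None:
    effects = meta.effects_per_cohort(state["analysis_cohorts"], config.target_gene)
    if len(effects) < 2:
        raise meta.MetaError("target gene estimable in fewer than 2 cohorts")
    state["effects"] = effects
    _write("effects", pd.DataFrame(
        [{"study_id": e.study_id, "g": e.g, "se": e.se,
          "ci_low": e.ci_low, "ci_high": e.ci_high} for e in effects]),
        "target_effects.tsv")


def _stage_pooling(config, state, headline) -> None:
    effects = state["effects"]
    fixed = meta.pool_fixed(effects)
    pooled = meta.pool_auto(effects)
    headline["target_smd"] = pooled.mean
    headline["target_smd_ci"] = [pooled.ci_low, pooled.ci_high]
    headline["model"] = pooled.model
    headline["I2"] = fixed.I2
    headline["p_Q"] = fixed.p_Q
    headline["tau2"] = pooled.tau2
    headline["k_studies"] = pooled.k
    if len(effects) >= 3:
        egger = meta.egger_test(effects)
        headline["egger_p"] = egger.p
        loo = meta.leave_one_out(effects)
        headline["leave_one_out_range"] = [min(p.mean for p in loo),
                                           max(p.mean for p in loo)]
    state["pooled"] = pooled


def _stage_screen(config, state, headline, _write) -> None:
    records = meta.genomewide_smd_screen(state["analysis_cohorts"])
    frame = meta.screen_to_frame(records)
    _write("screen", frame, "genomewide_screen.tsv")
    up = {r.gene for r in records if r.up_regulated}
    state["up_genes"] = up
    headline["n_screened_genes"] = len(records)
    headline["n_up_regulated"] = len(up)
    headline["target_up_regulated"] = bool(config.target_gene in up)


def _stage_diagnostics(config, state, headline, _write) -> None:
    tables = []
    rows = []
    for c in state["analysis_cohorts"]:
        if config.target_gene not in c.genes:
            continue
        scores = c.values.loc[config.target_gene].to_numpy(dtype=float)
        labels = (c.groups.to_numpy() == "tumor").astype(int)
        if labels.sum() == 0 or labels.sum() == len(labels):
            continue
        roc = diagnostics.roc_auc(scores, labels)
        cut = diagnostics.youden_cutoff(scores, labels)
        tables.append(cut)
        rows.append({"study_id": c.study_id, "auc": roc.auc, "p": roc.p,
                     "cutoff": cut.cutoff, "tp": cut.tp, "fp": cut.fp,
                     "fn": cut.fn, "tn": cut.tn,
                     "sens": cut.sens, "spec": cut.spec})
    _write("diagnostics", pd.DataFrame(rows), "per_study_roc.tsv")
    if len(tables) >= 3:
        sroc = diagnostics.sroc_moses(tables)
        headline["sroc_auc"] = sroc.auc
        headline["pooled_sens"] = sroc.pooled_sens.value
        headline["pooled_spec"] = sroc.pooled_spec.value
        headline["sroc_reliable"] = sroc.reliable
    state["confusion_tables"] = tables


def _stage_pathways(config, state, headline, _write) -> None:
    if state.get("catalog") is None:
        logger.warning("pathways: no gene-set catalog provided; stage skipped")
        headline["selected_pathways"] = []
        state["selected_pathways"] = []
        return
    cohort = _primary_cohort(state)
    records = pathways.pathway_analysis(cohort, state["catalog"],
                                        config.target_gene,
                                        sig_alpha=config.alpha)
    _write("pathways", pathways.records_to_frame(records), "pathway_records.tsv")
    selected = [r for r in records if r.selected]
    headline["selected_pathways"] = [r.pathway for r in selected]
    state["selected_pathways"] = selected
    state["pathway_records"] = records


def _stage_immune(config, state, headline, _write) -> None:
    if state.get("signature") is None or state.get("mixtures") is None:
        logger.warning("immune: no signature/mixtures provided; stage skipped")
        headline["positive_cells"] = []
        headline["negative_cells"] = []
        return
    fractions = deconvolve_samples(state["mixtures"], state["signature"])
    out = fractions.copy()
    out.insert(0, "sample_id", out.index)
    _write("fractions", out, "cell_fractions.tsv")

    cohort = _primary_cohort(state)
    target = cohort.values.loc[config.target_gene, cohort.tumor_samples].astype(float)
    shared = target.index.intersection(fractions.index)
    if len(shared) < 3:
        logger.warning("immune: mixture samples do not overlap tumor samples; "
                       "correlation skipped")
        headline["positive_cells"] = []
        headline["negative_cells"] = []
        return
    records = correlate_gene_cells(target.loc[shared], fractions.loc[shared],
                                   alpha=config.alpha)
    _write("cell_correlations", pd.DataFrame(
        [{"cell_type": r.cell_type, "r": r.r, "p": r.p, "direction": r.direction}
         for r in records]), "cell_correlations.tsv")
    headline["positive_cells"] = [r.cell_type for r in records if r.direction == "positive"]
    headline["negative_cells"] = [r.cell_type for r in records if r.direction == "negative"]

    surv = state.get("survival")
    if surv is not None:
        rows = []
        joined = surv.set_index("sample_id").join(fractions, how="inner")
        for ct in fractions.columns:
            if joined[ct].nunique() < 2 or joined["os_event"].sum() < 1:
                continue
            try:
                res = survival.cox_univariate(joined[ct], joined["os_time_months"],
                                              joined["os_event"])
            except survival.SurvivalError:
                continue
            rows.append({"cell_type": ct, "hr": res.hr, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "p_wald": res.p_wald,
                         "p_logrank": res.p_logrank, "risk_factor": res.risk_factor})
        if rows:
            _write("cell_cox", pd.DataFrame(rows), "cell_cox.tsv")


def _stage_survival(config, state, headline, _write) -> None:
    surv = state.get("survival")
    if surv is None:
        logger.warning("survival: no survival table provided; stage skipped")
        return
    cohort = _primary_cohort(state)
    target = cohort.values.loc[config.target_gene].astype(float)
    joined = surv.set_index("sample_id").join(target.rename("expr"), how="inner")
    if len(joined) < 4:
        raise survival.SurvivalError("fewer than 4 samples join survival and expression")
    groups = survival.median_split(joined["expr"])
    curves = []
    for label in ("high", "low"):
        km = survival.km_estimator(joined["os_time_months"][groups == label],
                                   joined["os_event"][groups == label])
        km.insert(0, "group", label)
        curves.append(km)
    _write("km_curves", pd.concat(curves), "km_curves.tsv")
    chi2, p_lr = survival.logrank_test(joined["os_time_months"], joined["os_event"], groups)
    res = survival.cox_univariate(joined["expr"], joined["os_time_months"],
                                  joined["os_event"])
    headline["cox"] = {"hr": res.hr, "ci": [res.ci_low, res.ci_high],
                       "beta": res.beta, "p_wald": res.p_wald,
                       "p_logrank": p_lr, "risk_factor": res.risk_factor}


def _stage_coexpression(config, state, headline, _write) -> None:
    cohort = _primary_cohort(state)
    records = screen.coexpression_screen(cohort, config.target_gene)
    _write("coexpression", screen.coexpr_to_frame(records), "coexpression.tsv")
    passing = {r.gene for r in records if r.passes}
    headline["n_coexpressed"] = len(passing)

    pathway_members: set = set()
    for rec in state.get("selected_pathways", []):
        if state.get("catalog") is not None:
            pathway_members |= set(state["catalog"].sets[rec.pathway])
    if pathway_members and state.get("up_genes"):
        inter = screen.intersect_sets({
            "up_regulated": set(state["up_genes"]),
            "coexpressed": passing,
            "pathway": pathway_members,
        })
        headline["intersection_size"] = inter.size
        headline["intersection_members"] = inter.members
        _write("intersection",
               pd.DataFrame({"gene": inter.members}), "intersection.tsv")
    if config.edges_path:
        edges = pd.read_csv(config.edges_path, sep="\t", header=None).values.tolist()
        ranking = screen.hub_rank_degree(edges, k=10)
        _write("hubs", pd.DataFrame(ranking.ranking, columns=["gene", "degree"]),
               "hub_ranking.tsv")
        headline["hub_genes"] = [g for g, _ in ranking.ranking]


def _stage_assays(config, state, headline, _write) -> None:
    ihc = state.get("ihc")
    if ihc is not None:
        scored = assays.score_ihc_table(ihc)
        _write("ihc_scored", scored, "ihc_scored.tsv")
        labels = (scored["tissue_type"] == "cancer").astype(int).to_numpy()
        p, roc = assays.ihc_group_difference(scored["composite"].to_numpy(), labels)
        headline["ihc_p"] = p
        headline["ihc_auc"] = roc.auc
    qpcr = state.get("qpcr")
    if qpcr is not None:
        fc = assays.ddct_from_table(qpcr, "target", "reference", "si-target", "CK")
        headline["knockdown_ddct"] = fc.ddct
        headline["knockdown_fold"] = fc.fold
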