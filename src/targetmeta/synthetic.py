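"""Synthetic multi-cohort expression studies with planted ground truth.

The generator emulates the data layout of an integrative single-gene
meta-analysis: K two-group cohorts of log2-scale expression in which the
target gene carries a planted standardized effect, a subset of genes is
up-regulated, a latent-factor block co-varies with the target, and each
cohort has its own additive batch shift.  Ancillary tables provide a
gene-set catalog with one active pathway, a cell-type signature with
mixture samples whose first cell type is coupled to the target, an
exponential survival table with a planted log-hazard, ordinal IHC scores
from a shifted latent normal, and qPCR Ct values with a planted knockdown.

Effects are planted in SMD units: a gene with loading lambda on the latent
factor has within-group SD sqrt(noise_sd^2 + lambda^2), and the tumor-arm
shift is delta times that SD, so the planted delta is the true
standardized mean difference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from targetmeta.cohorts import ExpressionCohort, GROUP_CONTROL, GROUP_TUMOR
from targetmeta.immune import SignatureMatrix
from targetmeta.pathways import GeneSetCatalog


class ConfigError(ValueError):
    """Invalid synthetic-study configuration; message names the field."""


@dataclass
class SyntheticStudyConfig:
    """Study conditions for the synthetic multi-cohort experiment.

    Defaults mirror the scale of the motivating integrative analysis:
    15 cohorts averaging 115 tumor vs 63 control samples, a planted
    target SMD of 1.0, a 50-gene up-regulated set, a 30-gene co-expressed
    block with latent loading 0.7, unit residual noise on the log2 scale
    and a per-cohort batch shift SD of 0.5.
    """

    n_cohorts: int = 15
    tumor_n: int | tuple[int, ...] = 115     # scalar or one size per cohort
    control_n: int | tuple[int, ...] = 63
    n_genes: int = 1000

    target_effect: float = 1.0        # SMD units
    n_up_genes: int = 50
    up_effect: float = 1.0            # SMD units
    coexpr_block_size: int = 30
    latent_loading: float = 0.7       # in (0, 1]
    batch_shift_sd: float = 0.5
    noise_sd: float = 1.0

    n_gene_sets: int = 20
    set_size_range: tuple[int, int] = (15, 60)
    active_set_name: str = "PATHWAY_ACTIVE"

    n_cell_types: int = 5
    markers_per_type: int = 10
    cell_coupling: float = 0.8        # loading of cell type 1 on the target

    baseline_hazard: float = 0.02     # events per month
    log_hazard: float = 0.7           # per SD of target expression
    censor_time: float = 60.0         # months

    ihc_n_cancer: int = 179
    ihc_n_noncancer: int = 147
    ihc_shift: float = 2.0            # latent SD units

    knockdown_ddct: float = 2.0       # planted ddCt
    mixture_noise_sd: float = 0.05
    qpcr_noise_sd: float = 0.05

    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_cohorts": self.n_cohorts, "n_genes": self.n_genes,
            "n_gene_sets": self.n_gene_sets, "n_cell_types": self.n_cell_types,
            "markers_per_type": self.markers_per_type,
            "ihc_n_cancer": self.ihc_n_cancer,
            "ihc_n_noncancer": self.ihc_n_noncancer,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigError(f"{name} must be >= 1, got {value}")
        for name in ("tumor_n", "control_n"):
            sizes = self.arm_sizes(name)
            if len(sizes) != self.n_cohorts:
                raise ConfigError(
                    f"{name} must be a scalar or one size per cohort "
                    f"(got {len(sizes)} for {self.n_cohorts} cohorts)")
            if any(v < 1 for v in sizes):
                raise ConfigError(f"{name} must be >= 1 in every cohort")
        if not np.isfinite(self.target_effect):
            raise ConfigError("target_effect must be finite")
        if self.coexpr_block_size >= self.n_genes:
            raise ConfigError("coexpr_block_size must be smaller than n_genes")
        if 1 + self.n_up_genes + self.coexpr_block_size > self.n_genes:
            raise ConfigError("n_up_genes + coexpr_block_size exceed n_genes")
        if not 0 < self.latent_loading <= 1:
            raise ConfigError("latent_loading must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.batch_shift_sd < 0:
            raise ConfigError("batch_shift_sd must be >= 0")
        if self.set_size_range[0] < 1 or self.set_size_range[0] > self.set_size_range[1]:
            raise ConfigError("set_size_range must be an increasing pair of counts >= 1")
        if self.markers_per_type * self.n_cell_types < self.n_cell_types:
            raise ConfigError("signature needs at least one marker per cell type")

    def arm_sizes(self, which: str) -> list[int]:
        """Per-cohort sizes of one arm ("tumor_n" or "control_n")."""
        value = getattr(self, which)
        if isinstance(value, (int, np.integer)):
            return [int(value)] * self.n_cohorts
        return [int(v) for v in value]

    # --- derived gene rosters (deterministic by construction) ---

    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:05d}" for i in range(self.n_genes)]

    @property
    def target_gene(self) -> str:
        return "G00001"

    def up_genes(self) -> list[str]:
        return [f"G{i + 2:05d}" for i in range(self.n_up_genes)]

    def block_genes(self) -> list[str]:
        start = 2 + self.n_up_genes
        return [f"G{start + i:05d}" for i in range(self.coexpr_block_size)]


@dataclass
class SyntheticTruth:
    """Planted values recorded by the generator.

    ``cell_fractions`` and ``survival`` are filled in by
    :func:`generate_ancillary`.
    """

    delta: pd.Series                 # per-gene true SMD
    target_gene: str
    up_genes: list[str]
    block_genes: list[str]
    active_pathway: str
    hazard_ratio: float              # per SD of target expression
    knockdown_fold: float            # 2 ** -ddct
    seed: int
    cell_fractions: pd.DataFrame | None = None
    survival: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "target_gene": self.target_gene,
            "up_genes": self.up_genes,
            "block_genes": self.block_genes,
            "active_pathway": self.active_pathway,
            "hazard_ratio": self.hazard_ratio,
            "knockdown_fold": self.knockdown_fold,
            "seed": self.seed,
            "delta": {g: float(d) for g, d in self.delta.items() if d != 0},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _rng(master: int, stream: int) -> np.random.Generator:
    # sub-streams by fixed offsets from one master seed
    return np.random.default_rng([master, stream])


def generate_multicohort(
    config: SyntheticStudyConfig, seed: int | None = None
) -> tuple[list[ExpressionCohort], SyntheticTruth]:
    """Generate K two-group cohorts plus the truth record.

    Expression = gene baseline + per-cohort batch shift + latent-factor
    block + group effect (delta_g times the gene's within-group SD) +
    Gaussian noise, all on the log2 scale.  The first three cohorts share
    one platform id so the merge path is exercised.
    """
    config.validate()
    master = config.seed if seed is None else int(seed)

    genes = config.gene_ids()
    target = config.target_gene
    up = config.up_genes()
    block = config.block_genes()

    # block genes carry both the latent loading and the up-regulation so the
    # up-set, the co-expression hits and the active pathway genuinely overlap
    delta = pd.Series(0.0, index=genes)
    delta[target] = config.target_effect
    delta[up] = config.up_effect
    delta[block] = config.up_effect
    lam = pd.Series(0.0, index=genes)
    lam[target] = config.latent_loading
    lam[block] = config.latent_loading

    base_rng = _rng(master, 0)
    baseline = base_rng.normal(7.0, 1.5, config.n_genes)

    lam_v = lam.to_numpy()
    delta_v = delta.to_numpy()
    sigma = np.sqrt(config.noise_sd**2 + lam_v**2)

    tumor_sizes = config.arm_sizes("tumor_n")
    control_sizes = config.arm_sizes("control_n")
    cohorts = []
    for i in range(config.n_cohorts):
        rng = _rng(master, i + 1)
        study = f"STUDY{i + 1:02d}"
        platform = "PLATFORM_A" if i < 3 else f"PLATFORM_{i + 1:02d}"
        n = tumor_sizes[i] + control_sizes[i]
        group = np.array([GROUP_TUMOR] * tumor_sizes[i]
                         + [GROUP_CONTROL] * control_sizes[i])
        z = (group == GROUP_TUMOR).astype(float)

        shift = rng.normal(0.0, config.batch_shift_sd, config.n_genes)
        f = rng.normal(0.0, 1.0, n)
        noise = rng.normal(0.0, config.noise_sd, (config.n_genes, n))
        X = (baseline[:, None] + shift[:, None]
             + lam_v[:, None] * f[None, :]
             + (delta_v * sigma)[:, None] * z[None, :]
             + noise)

        samples = [f"{study}_S{j + 1:03d}" for j in range(n)]
        values = pd.DataFrame(X, index=genes, columns=samples)
        clinical = pd.DataFrame(
            {
                "age": np.clip(rng.normal(62, 10, n).round(), 30, 90).astype(int),
                "sex": rng.choice(["male", "female"], n),
                "tnm_stage": rng.choice(["I", "II", "III", "IV"], n),
                "grade": rng.choice(["high", "low"], n),
            },
            index=samples,
        )
        cohorts.append(ExpressionCohort(
            study_id=study, platform_id=platform, values=values,
            groups=pd.Series(group, index=samples),
            batch=pd.Series(study, index=samples),
            clinical=clinical,
        ))

    truth = SyntheticTruth(
        delta=delta, target_gene=target, up_genes=up, block_genes=block,
        active_pathway=config.active_set_name,
        hazard_ratio=float(np.exp(config.log_hazard)),
        knockdown_fold=float(2.0 ** (-config.knockdown_ddct)),
        seed=master,
    )
    return cohorts, truth


def _standardized_target(cohort: ExpressionCohort, target: str) -> pd.Series:
    expr = cohort.values.loc[target, cohort.tumor_samples].astype(float)
    return (expr - expr.mean()) / expr.std(ddof=1)


def generate_ancillary(
    config: SyntheticStudyConfig,
    truth: SyntheticTruth,
    seed: int | None = None,
    cohorts: list[ExpressionCohort] | None = None,
):
    """Generate the gene-set catalog, signature, mixtures, survival, IHC
    and qPCR tables tied to the planted truth.

    When ``cohorts`` is given, the mixture coupling and survival hazards
    follow the standardized target expression of the first cohort's tumor
    samples (so downstream correlation and Cox stages can join on sample
    ids); otherwise a fresh latent score is drawn for synthetic subjects.

    Returns ``(catalog, signature, mixtures, survival, ihc, qpcr)``.
    """
    config.validate()
    master = config.seed if seed is None else int(seed)

    planted = set(truth.up_genes) | set(truth.block_genes) | {truth.target_gene}
    null_genes = np.array([g for g in config.gene_ids() if g not in planted])

    # --- gene-set catalog: inert sets from null genes, one active set ---
    rng = _rng(master, 101)
    lo, hi = config.set_size_range
    sets: dict[str, list[str]] = {}
    for j in range(config.n_gene_sets - 1):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(null_genes))
        members = sorted(rng.choice(null_genes, size=size, replace=False))
        sets[f"PATHWAY_{j + 1:02d}"] = [str(g) for g in members]
    sets[config.active_set_name] = sorted(set(truth.up_genes) | set(truth.block_genes))
    catalog = GeneSetCatalog(sets)

    # --- cell-type signature ---
    rng = _rng(master, 102)
    types = [f"cell_type_{t + 1}" for t in range(config.n_cell_types)]
    markers = [f"MK{t + 1:02d}_{m + 1:02d}"
               for t in range(config.n_cell_types)
               for m in range(config.markers_per_type)]
    basis = rng.uniform(0.0, 0.5, (len(markers), config.n_cell_types))
    for t in range(config.n_cell_types):
        rows = slice(t * config.markers_per_type, (t + 1) * config.markers_per_type)
        basis[rows, t] = rng.uniform(5.0, 10.0, config.markers_per_type)
    signature = SignatureMatrix(pd.DataFrame(basis, index=markers, columns=types))

    # --- subjects used for mixtures and survival ---
    if cohorts is not None:
        z = _standardized_target(cohorts[0], truth.target_gene)
        subjects = list(z.index)
        z = z.to_numpy()
    else:
        rng0 = _rng(master, 100)
        n_subjects = config.arm_sizes("tumor_n")[0]
        subjects = [f"MIX{j + 1:03d}" for j in range(n_subjects)]
        z = rng0.normal(0.0, 1.0, n_subjects)

    # --- immune mixtures: Dirichlet fractions, type 1 coupled to target ---
    rng = _rng(master, 103)
    gam = rng.gamma(1.0, 1.0, (len(subjects), config.n_cell_types))
    gam[:, 0] *= np.exp(config.cell_coupling * z)
    fractions = gam / gam.sum(axis=1, keepdims=True)
    fractions = pd.DataFrame(fractions, index=subjects, columns=types)
    mix = signature.basis.to_numpy() @ fractions.to_numpy().T
    mix = mix + rng.normal(0.0, config.mixture_noise_sd, mix.shape)
    mixtures = pd.DataFrame(mix, index=markers, columns=subjects)
    truth.cell_fractions = fractions

    # --- survival: exponential, log-hazard on standardized target ---
    rng = _rng(master, 104)
    rate = config.baseline_hazard * np.exp(config.log_hazard * z)
    t_event = rng.exponential(1.0 / rate)
    event = (t_event <= config.censor_time).astype(int)
    time = np.minimum(t_event, config.censor_time)
    survival = pd.DataFrame({
        "sample_id": subjects,
        "os_time_months": time,
        "os_event": event,
    })
    truth.survival = survival

    # --- IHC: thresholded latent normal shifted by tissue group ---
    rng = _rng(master, 105)
    n_c, n_n = config.ihc_n_cancer, config.ihc_n_noncancer
    latent = np.concatenate([
        rng.normal(config.ihc_shift, 1.0, n_c),
        rng.normal(0.0, 1.0, n_n),
    ])
    percent = 100.0 * norm.cdf(latent - 1.0)
    cuts = [-0.5, 0.5, 1.5]
    grades = np.array(["none", "light", "brown", "dark"])
    intensity = grades[np.searchsorted(cuts, latent + rng.normal(0, 0.2, len(latent)))]
    ihc = pd.DataFrame({
        "case_id": [f"IHC{j + 1:03d}" for j in range(n_c + n_n)],
        "tissue_type": ["cancer"] * n_c + ["non-cancer"] * n_n,
        "percent_positive": percent,
        "intensity": intensity,
    })

    # --- qPCR: reference + target Ct per group, planted knockdown ---
    rng = _rng(master, 106)
    rows = []
    for group in ("CK", "NC", "si-target"):
        dct = config.knockdown_ddct if group == "si-target" else 0.0
        for gene, base in (("reference", 20.0), ("target", 23.0 + dct)):
            for _ in range(3):
                rows.append({"group": group, "gene": gene,
                             "ct": base + rng.normal(0.0, config.qpcr_noise_sd)})
    qpcr = pd.DataFrame(rows)

    return catalog, signature, mixtures, survival, ihc, qpcr


def write_study(cohorts: list[ExpressionCohort], truth: SyntheticTruth,
                outdir) -> None:
    """Write cohorts as TSV + CSV pairs and the truth record as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for c in cohorts:
        c.write(outdir / f"{c.study_id}_expression.tsv",
                outdir / f"{c.study_id}_metadata.csv")
    truth.to_json(outdir / "truth.json")
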