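"""Synthetic paired expression/methylation cohorts with planted structure.

The generator emulates, at bulk resolution, the statistical structure of a
multi-subtype glioma-like cohort: S subtypes, planted modules of
co-regulated genes with subtype-specific activation on log10 expression
scale, promoter hyper-/hypo-methylation anti-correlated with expression
for a subset of modules (GCIMP-like coupling), per-gene Gaussian noise,
exponential survival with hazard tied to module activity, and age/sex/TLR
covariates.  Every downstream stage of the pipeline has a ground-truth
recovery test against the planted structure returned in
:class:`SyntheticTruth`.

A sample's module activity is the activation entry of its subtype (block
model): the cohort is analysed at bulk level, so per-cell mixtures are out
of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .matrix import OmicsMatrix, ConfigurationError, SurvivalTable
from .preprocess import promoter_window


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the standard study conditions used throughout the
    test-bench: 5,000 genes, 120 samples, 6 subtypes each activating its
    own module of 40 genes by one log10 unit, moderate gene-level noise,
    and half of the modules methylation-coupled with slope -0.3 beta per
    log10 unit.
    """

    n_genes: int = 5000
    n_samples: int = 120
    n_subtypes: int = 6
    n_modules: int = 6
    genes_per_module: int = 40
    #: module x subtype effect sizes in log10 expression units;
    #: None -> 1.0 on the module==subtype diagonal (cycled if shapes differ).
    activation: Optional[np.ndarray] = None
    coupled_fraction: float = 0.5
    coupling_slope: float = -0.3  # beta change per log10 expression unit
    noise_sd_expr: float = 0.25   # log10 units
    noise_sd_meth: float = 0.05   # beta units
    baseline_beta: float = 0.5
    #: per-module log-hazard per unit of module activity; scalar is
    #: broadcast, None -> all zero (survival independent of modules).
    hazard_beta: Optional[np.ndarray] = None
    censor_rate: float = 0.2
    cpgs_per_gene: int = 5
    #: fraction of background genes placed on chrX/chrY to exercise the
    #: sex-chromosome filter (module genes stay autosomal).
    sex_chrom_fraction: float = 0.02
    median_survival: float = 5.0  # time units, at zero module activity
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples", "n_subtypes", "n_modules",
                     "genes_per_module", "cpgs_per_gene"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.genes_per_module * self.n_modules > self.n_genes:
            raise ConfigurationError(
                "genes_per_module * n_modules exceeds n_genes")
        if not 0.0 <= self.coupled_fraction <= 1.0:
            raise ConfigurationError("coupled_fraction must lie in [0, 1]")
        if not 0.0 <= self.baseline_beta <= 1.0:
            raise ConfigurationError("baseline_beta must lie in [0, 1]")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigurationError("censor_rate must lie in [0, 1)")
        if self.noise_sd_expr < 0 or self.noise_sd_meth < 0:
            raise ConfigurationError("noise sds must be >= 0")
        if not 0.0 <= self.sex_chrom_fraction < 1.0:
            raise ConfigurationError("sex_chrom_fraction must lie in [0, 1)")
        if self.median_survival <= 0:
            raise ConfigurationError("median_survival must be > 0")

    def activation_matrix(self) -> np.ndarray:
        if self.activation is None:
            act = np.zeros((self.n_modules, self.n_subtypes))
            for m in range(self.n_modules):
                act[m, m % self.n_subtypes] = 1.0
            return act
        act = np.asarray(self.activation, dtype=float)
        if act.shape != (self.n_modules, self.n_subtypes):
            raise ConfigurationError(
                f"activation must be {self.n_modules} x {self.n_subtypes}, "
                f"got {act.shape}")
        return act

    def hazard_vector(self) -> np.ndarray:
        if self.hazard_beta is None:
            return np.zeros(self.n_modules)
        hb = np.asarray(self.hazard_beta, dtype=float)
        if hb.ndim == 0:
            return np.full(self.n_modules, float(hb))
        if hb.shape != (self.n_modules,):
            raise ConfigurationError(
                f"hazard_beta must have length {self.n_modules}")
        return hb


@dataclass
class SyntheticTruth:
    """Planted ground truth: the recovery target for all downstream tests."""

    module_members: Dict[int, List[str]]
    subtype_of_sample: Dict[str, int]
    coupled_modules: Set[int]
    hazard_beta: np.ndarray
    activation: np.ndarray

    def __post_init__(self) -> None:
        all_genes: Set[str] = set()
        for genes in self.module_members.values():
            if all_genes & set(genes):
                raise ConfigurationError("module gene sets must be disjoint")
            all_genes |= set(genes)

    def module_activity(self, subtypes: np.ndarray) -> np.ndarray:
        """module x sample activity under the block model."""
        return self.activation[:, subtypes]

    def to_json(self, path: str) -> None:
        payload = {
            "module_members": {str(k): v for k, v in self.module_members.items()},
            "subtype_of_sample": self.subtype_of_sample,
            "coupled_modules": sorted(self.coupled_modules),
            "hazard_beta": self.hazard_beta.tolist(),
            "activation": self.activation.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            module_members={int(k): v for k, v in payload["module_members"].items()},
            subtype_of_sample=payload["subtype_of_sample"],
            coupled_modules=set(payload["coupled_modules"]),
            hazard_beta=np.asarray(payload["hazard_beta"], dtype=float),
            activation=np.asarray(payload["activation"], dtype=float),
        )


def _gene_annotation(gene_ids: List[str], module_gene_mask: np.ndarray,
                     cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Round-robin autosomes chr1..chr22 for module genes; a configurable
    fraction of background genes goes to chrX/chrY."""
    n = len(gene_ids)
    autosomes = [f"chr{i}" for i in range(1, 23)]
    chroms = np.array([autosomes[i % 22] for i in range(n)], dtype=object)
    background = np.flatnonzero(~module_gene_mask)
    n_sex = int(round(cfg.sex_chrom_fraction * len(background)))
    if n_sex:
        sex_idx = rng.choice(background, size=n_sex, replace=False)
        half = n_sex // 2
        chroms[sex_idx[:half]] = "chrX"
        chroms[sex_idx[half:]] = "chrY"
    # well-separated TSS so promoter windows never overlap within a chromosome
    per_chrom_counter: Dict[str, int] = {}
    tss = np.empty(n, dtype=int)
    for i, c in enumerate(chroms):
        k = per_chrom_counter.get(c, 0)
        tss[i] = 10_000 + 10_000 * k
        per_chrom_counter[c] = k + 1
    strand = np.where(np.arange(n) % 2 == 0, "+", "-")
    return pd.DataFrame({"gene_id": gene_ids, "chromosome": chroms,
                         "tss": tss, "strand": strand})


def generate_cohort(cfg: CohortConfig):
    """Generate one paired cohort.

    Returns
    -------
    expr : OmicsMatrix (expression_log10), gene x sample
    cpgs : DataFrame CpG table (cpg_id, chromosome, position, betas...)
    ann : DataFrame gene annotation (gene_id, chromosome, tss, strand)
    pheno : DataFrame phenotype/survival table
    truth : SyntheticTruth
    """
    rng = np.random.default_rng(cfg.seed)
    act = cfg.activation_matrix()

    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    sample_ids = [f"s{j:04d}" for j in range(cfg.n_samples)]

    # subtypes cycle deterministically so every subtype is populated
    subtypes = np.arange(cfg.n_samples) % cfg.n_subtypes
    module_members = {
        m: gene_ids[m * cfg.genes_per_module:(m + 1) * cfg.genes_per_module]
        for m in range(cfg.n_modules)}
    module_of_gene = np.full(cfg.n_genes, -1, dtype=int)
    module_of_gene[:cfg.n_modules * cfg.genes_per_module] = np.repeat(
        np.arange(cfg.n_modules), cfg.genes_per_module)

    # expression: block signal + iid noise, log10 scale
    activity = act[:, subtypes]                      # module x sample
    signal = np.zeros((cfg.n_genes, cfg.n_samples))
    in_module = module_of_gene >= 0
    signal[in_module] = activity[module_of_gene[in_module]]
    expr_values = signal + rng.normal(0.0, cfg.noise_sd_expr,
                                      size=signal.shape)
    expr = OmicsMatrix(pd.DataFrame(expr_values, index=gene_ids,
                                    columns=sample_ids), "expression_log10")

    # first ceil(fraction * n_modules) modules are methylation-coupled
    n_coupled = int(round(cfg.coupled_fraction * cfg.n_modules))
    coupled = set(range(n_coupled))

    ann = _gene_annotation(gene_ids, in_module, cfg, rng)

    # CpGs uniform inside each promoter window, strand-aware
    n_cpgs = cfg.n_genes * cfg.cpgs_per_gene
    cpg_gene = np.repeat(np.arange(cfg.n_genes), cfg.cpgs_per_gene)
    lo = np.empty(cfg.n_genes, dtype=int)
    hi = np.empty(cfg.n_genes, dtype=int)
    for i, rec in enumerate(ann.itertuples(index=False)):
        lo[i], hi[i] = promoter_window(int(rec.tss), rec.strand)
    positions = rng.integers(lo[cpg_gene], hi[cpg_gene] + 1)

    # betas: coupled-module genes track module activity with negative slope
    beta_mean = np.full((cfg.n_genes, cfg.n_samples), cfg.baseline_beta)
    for m in coupled:
        rows = slice(m * cfg.genes_per_module, (m + 1) * cfg.genes_per_module)
        beta_mean[rows] = cfg.baseline_beta + cfg.coupling_slope * activity[m]
    cpg_betas = beta_mean[cpg_gene] + rng.normal(
        0.0, cfg.noise_sd_meth, size=(n_cpgs, cfg.n_samples))
    np.clip(cpg_betas, 0.0, 1.0, out=cpg_betas)

    cpgs = pd.concat(
        [pd.DataFrame({"cpg_id": [f"cg{i:06d}" for i in range(n_cpgs)],
                       "chromosome": ann["chromosome"].to_numpy()[cpg_gene],
                       "position": positions}),
         pd.DataFrame(cpg_betas, columns=sample_ids)], axis=1)

    truth = SyntheticTruth(
        module_members=module_members,
        subtype_of_sample={s: int(t) for s, t in zip(sample_ids, subtypes)},
        coupled_modules=coupled,
        hazard_beta=cfg.hazard_vector(),
        activation=act,
    )

    surv = generate_survival(truth, expr, cfg,
                             rng=np.random.default_rng(cfg.seed + 1))
    pheno = pd.DataFrame({
        "sample_id": sample_ids,
        "subtype": [f"S{t}" for t in subtypes],
        "age": np.round(rng.normal(50.0, 12.0, cfg.n_samples).clip(18, 90), 1),
        "sex": np.where(rng.random(cfg.n_samples) < 0.5, "F", "M"),
        "tlr": np.round(rng.lognormal(0.0, 0.35, cfg.n_samples), 4),
        "surv_time": surv.time,
        "surv_event": surv.event,
    })
    return expr, cpgs, ann, pheno, truth


def generate_survival(truth: SyntheticTruth, expr: OmicsMatrix,
                      cfg: CohortConfig,
                      rng: Optional[np.random.Generator] = None) -> SurvivalTable:
    """Exponential survival with log-hazard linear in module activity.

    time ~ Exp(rate = lam0 * exp(sum_m hazard_beta[m] * activity_m(s)));
    lam0 gives median survival cfg.median_survival at zero activity.
    Censoring is Uniform(0, T_c) with T_c solved numerically so the
    expected censored fraction equals cfg.censor_rate.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    sample_ids = list(expr.sample_ids)
    subtypes = np.array([truth.subtype_of_sample[s] for s in sample_ids])
    activity = truth.module_activity(subtypes)         # module x sample
    lam0 = np.log(2.0) / cfg.median_survival
    rates = lam0 * np.exp(truth.hazard_beta @ activity)
    times = rng.exponential(1.0 / rates)
    if cfg.censor_rate == 0.0:
        return SurvivalTable(pd.Index(sample_ids), times,
                             np.ones(len(times), dtype=int))

    def censored_fraction(tc: float) -> float:
        # P(C < T), C ~ U(0, tc), T ~ Exp(rate): E[min(T, tc)] / tc
        lam_tc = rates * tc
        return float(np.mean((1.0 - np.exp(-lam_tc)) / lam_tc))

    # censored_fraction decreases from 1 (tc -> 0) to 0 (tc -> inf)
    hi = 1.0
    while censored_fraction(hi) > cfg.censor_rate:
        hi *= 2.0
        if hi > 1e9:
            break
    tc = brentq(lambda t: censored_fraction(t) - cfg.censor_rate,
                1e-9, hi, xtol=1e-10)
    censor_times = rng.uniform(0.0, tc, size=len(times))
    event = (times <= censor_times).astype(int)
    observed = np.minimum(times, censor_times)
    return SurvivalTable(pd.Index(sample_ids), observed, event)
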