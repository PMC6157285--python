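"""Synthetic drug-response cohorts with SNP effects modified by paired CpGs.

Emulates the GAW20-style fenofibrate trial design: triglycerides (TG) are
log-normal, measured before treatment (visit 2) and after (visit 4); five
causal SNPs act additively on the log-TG change, each effect modulated by
the methylation level of one paired CpG; CpG beta-values share a
per-individual methylation propensity so that methylation is correlated
across the epigenome; covariates age, sex and study center are available
as network nodes. A machine-readable truth record accompanies every
cohort so that parameter-recovery tests can compare learned structure and
effect sizes against the generating model.

Heritability calibration
------------------------
Each SNP's target heritability ``h2`` is the share of log-TG-change
variance its additive effect explains when methylation plays no role
(``modification_mode="none"``). With genotype variance 2p(1-p) the raw
per-allele slope is ``s = sqrt(h2 * total_var / (2 p (1-p)))``, where
``total_var`` is the analytic variance of the change under that regime.
The modifier m(M) multiplies the SNP term, so the stored coefficient is
rescaled by 1/E[m(M)] to keep the mean effect -- and hence the
no-epigenetics heritabilities -- exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CohortTable

__all__ = [
    "SnpSpec",
    "SimConfig",
    "SimTruth",
    "default_snps",
    "simulate_genotypes",
    "simulate_methylation",
    "calibrate_effect_size",
    "total_change_variance",
    "simulate_cohort",
]

MAF_FLOOR = 0.01  # analysis floor on the minor allele frequency
MODIFICATION_MODES = ("proportional", "complement", "none")
_AGE_VARIANCE = (80.0 - 20.0) ** 2 / 12.0  # Uniform(20, 80)


class InvalidParameterError(ValueError):
    pass


@dataclass(frozen=True)
class SnpSpec:
    """One causal (or null) SNP: frequency, target heritability, paired CpG."""

    name: str
    maf: float = 0.3
    h2: float = 0.0
    paired_cpg: str | None = None

    def __post_init__(self) -> None:
        if not MAF_FLOOR < self.maf <= 0.5:
            raise InvalidParameterError(
                f"{self.name}: maf must be in ({MAF_FLOOR}, 0.5], got {self.maf}"
            )
        if not 0.0 <= self.h2 < 1.0:
            raise InvalidParameterError(f"{self.name}: h2 must be in [0, 1), got {self.h2}")


def default_snps() -> list[SnpSpec]:
    """The five causal SNP/CpG pairs of the emulated drug-response design.

    Heritabilities follow the published simulation answers for the
    GAW20-style trial; minor allele frequencies default to the common-variant
    value 0.3 (the design does not fix them).
    """
    table = [
        ("rs9661059", 0.125, "cg00000363"),
        ("rs736004", 0.075, "cg10480950"),
        ("rs1012116", 0.100, "cg18772399"),
        ("rs10828412", 0.025, "cg00045910"),
        ("rs4399565", 0.050, "cg01242676"),
    ]
    return [SnpSpec(name=s, maf=0.3, h2=h2, paired_cpg=c) for s, h2, c in table]


@dataclass
class SimConfig:
    """Full description of one simulated cohort.

    Defaults are the emulated study conditions: 1000 unrelated individuals,
    the five causal SNP/CpG pairs, 500 null CpGs, log-normal pre-treatment TG
    around exp(4.7) ~ 110 mg/dL with sd 0.5 on the log scale, a mean drug
    effect of -0.25 log units (~22% TG reduction), and a residual sd of 0.25
    on the log-TG change.
    """

    n_individuals: int = 1000
    snps: list[SnpSpec] = field(default_factory=default_snps)
    n_null_cpgs: int = 500
    methylation_propensity_sd: float = 1.0
    methylation_noise_sd: float = 1.0
    tg2_log_mean: float = 4.7
    tg2_log_sd: float = 0.5
    drug_mean_effect: float = -0.25
    residual_sd: float = 0.25
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.0, "sex": 0.0, "center": 0.0}
    )
    modification_mode: str = "proportional"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise InvalidParameterError("n_individuals must be >= 1")
        if self.n_null_cpgs < 0:
            raise InvalidParameterError("n_null_cpgs must be >= 0")
        for nm, v in (
            ("tg2_log_sd", self.tg2_log_sd),
            ("residual_sd", self.residual_sd),
            ("methylation_noise_sd", self.methylation_noise_sd),
        ):
            if v <= 0:
                raise InvalidParameterError(f"{nm} must be > 0")
        if self.methylation_propensity_sd < 0:
            raise InvalidParameterError("methylation_propensity_sd must be >= 0")
        if self.modification_mode not in MODIFICATION_MODES:
            raise InvalidParameterError(
                f"modification_mode must be one of {MODIFICATION_MODES}"
            )
        h2_sum = sum(s.h2 for s in self.snps)
        if h2_sum >= 1.0:
            raise InvalidParameterError(f"sum of SNP h2 must be < 1, got {h2_sum}")
        names = [s.name for s in self.snps]
        cpgs = [s.paired_cpg for s in self.snps if s.paired_cpg is not None]
        all_names = ["age", "sex", "center", "TG2", "TG4"] + names + cpgs
        if len(set(all_names)) != len(all_names):
            raise InvalidParameterError("duplicate variable names in configuration")
        unknown = set(self.covariate_effects) - {"age", "sex", "center"}
        if unknown:
            raise InvalidParameterError(f"unknown covariate_effects keys: {unknown}")


@dataclass
class SimTruth:
    """Record of the generating model for parameter-recovery tests.

    ``snps`` holds one row per SnpSpec with the realized per-allele
    coefficient ``beta`` (the multiplier of G * m(M) in the change model)
    and the nominal heritability. ``edges`` lists causal (parent, child,
    role) triples; every SNP with h2 > 0 contributes a SNP -> TG4 edge.
    """

    snps: pd.DataFrame
    edges: list[tuple[str, str, str]]
    total_var: float
    modification_mode: str
    seed: int

    def to_tsv(self, path: str | Path) -> None:
        lines = [
            f"# total_var={self.total_var!r}",
            f"# modification_mode={self.modification_mode}",
            f"# seed={self.seed}",
        ]
        for _, row in self.snps.iterrows():
            lines.append(
                "# snp\t" + "\t".join(f"{k}={row[k]!r}" for k in self.snps.columns)
            )
        lines.append("parent\tchild\trole")
        for p, c, role in self.edges:
            lines.append(f"{p}\t{c}\t{role}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# primitive generators


def simulate_genotypes(maf: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Minor-allele dosages 0/1/2 under Hardy-Weinberg equilibrium.

    Dosage counts follow Binomial(2, maf), i.e. genotype probabilities
    (1-p)^2, 2p(1-p), p^2. The frequency must respect the 0.01 analysis
    floor and cannot exceed 0.5 (minor allele by definition).
    """
    if not MAF_FLOOR <= maf <= 0.5:
        raise InvalidParameterError(f"maf must be in [{MAF_FLOOR}, 0.5], got {maf}")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    return rng.binomial(2, maf, size=n)


def simulate_methylation(
    n: int,
    n_cpg: int,
    propensity_sd: float,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
    baseline_logits: np.ndarray | None = None,
) -> np.ndarray:
    """CpG beta-value matrix with a shared per-individual propensity.

    value(i, j) = expit(mu_j + a_i + e_ij) with a_i ~ N(0, propensity_sd^2)
    and e_ij ~ N(0, noise_sd^2); per-CpG baselines mu_j ~ N(0, 1) unless
    supplied. The propensity term makes different CpGs positively
    correlated across individuals, mimicking the tendency of individuals
    to be globally hyper- or hypo-methylated. All cells lie strictly in
    (0, 1).
    """
    if n < 1 or n_cpg < 1:
        raise InvalidParameterError("n and n_cpg must be >= 1")
    if propensity_sd < 0:
        raise InvalidParameterError("propensity_sd must be >= 0")
    if baseline_logits is None:
        mu = rng.normal(0.0, 1.0, size=n_cpg)
    else:
        mu = np.asarray(baseline_logits, dtype=float)
        if mu.shape != (n_cpg,):
            raise InvalidParameterError("baseline_logits must have length n_cpg")
    a = rng.normal(0.0, propensity_sd, size=n)
    e = rng.normal(0.0, noise_sd, size=(n, n_cpg))
    logits = mu[None, :] + a[:, None] + e
    # clip keeps expit strictly inside (0, 1) in float64
    return expit(np.clip(logits, -30.0, 30.0))


def calibrate_effect_size(h2: float, maf: float, total_var: float) -> float:
    """Per-allele effect on log-TG change giving heritability ``h2``.

    beta = sqrt(h2 * total_var / (2 p (1-p))): with genotype variance
    2p(1-p), a slope of beta explains h2 * total_var of the response
    variance; regressing the no-epigenetics change on dosage recovers
    R^2 = h2 when total_var is the true change variance.
    """
    if not 0.0 <= h2 < 1.0:
        raise InvalidParameterError(f"h2 must be in [0, 1), got {h2}")
    var_g = 2.0 * maf * (1.0 - maf)
    if var_g <= 0:
        raise InvalidParameterError(f"genotype variance 2p(1-p) must be > 0, got maf={maf}")
    if total_var <= 0:
        raise InvalidParameterError("total_var must be > 0")
    return float(np.sqrt(h2 * total_var / var_g))


def total_change_variance(config: SimConfig) -> float:
    """Analytic variance of the log-TG change under modification_mode=none.

    Solves total = sum_k h2_k * total + var(covariate terms) + residual_sd^2
    for the total, so that each SNP's marginal R^2 equals its nominal h2.
    """
    ce = {"age": 0.0, "sex": 0.0, "center": 0.0} | config.covariate_effects
    cov_var = ce["age"] ** 2 * _AGE_VARIANCE + ce["sex"] ** 2 * 0.25 + ce["center"] ** 2 * 0.25
    h2_sum = sum(s.h2 for s in config.snps)
    return (cov_var + config.residual_sd**2) / (1.0 - h2_sum)


# ---------------------------------------------------------------------------
# full cohort


def simulate_cohort(config: SimConfig) -> tuple[CohortTable, SimTruth]:
    """Draw one cohort and its truth record from ``config``.

    Columns: age, sex, center, TG2, TG4, one dosage column per SNP, one
    beta-value column per CpG (paired causal CpGs first, then null CpGs).
    log(TG2) ~ N(tg2_log_mean, tg2_log_sd^2) and

        log(TG4) = log(TG2) + drug_mean_effect
                   + sum_k beta_k * G_k * m(M_k)
                   + covariate terms + N(0, residual_sd^2)

    with m(M) = M (proportional), 1 - M (complement) or the paired CpG's
    mean methylation as a constant (none). Identical configs (including
    the seed) produce bit-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals

    age = rng.uniform(20.0, 80.0, size=n)
    sex = rng.integers(0, 2, size=n)
    center = rng.integers(0, 2, size=n)
    log_tg2 = rng.normal(config.tg2_log_mean, config.tg2_log_sd, size=n)

    genotypes = {s.name: simulate_genotypes(s.maf, n, rng) for s in config.snps}

    causal_cpgs = [s.paired_cpg for s in config.snps if s.paired_cpg is not None]
    null_cpgs = [f"cg{90000000 + i}" for i in range(config.n_null_cpgs)]
    cpg_names = causal_cpgs + null_cpgs
    if cpg_names:
        # causal modifier CpGs sit at mid-range methylation (variable sites);
        # null CpGs draw their baseline logits at random
        baselines = np.concatenate(
            [np.zeros(len(causal_cpgs)), rng.normal(0.0, 1.0, size=len(null_cpgs))]
        )
        meth = simulate_methylation(
            n,
            len(cpg_names),
            config.methylation_propensity_sd,
            rng,
            noise_sd=config.methylation_noise_sd,
            baseline_logits=baselines,
        )
    else:
        meth = np.empty((n, 0))
    cpg_col = {name: meth[:, j] for j, name in enumerate(cpg_names)}

    total_var = total_change_variance(config)
    ce = {"age": 0.0, "sex": 0.0, "center": 0.0} | config.covariate_effects
    change = np.full(n, config.drug_mean_effect, dtype=float)
    change += ce["age"] * (age - 50.0)
    change += ce["sex"] * (sex - 0.5)
    change += ce["center"] * (center - 0.5)

    truth_rows = []
    edges: list[tuple[str, str, str]] = [("TG2", "TG4", "baseline")]
    for spec in config.snps:
        raw = calibrate_effect_size(spec.h2, spec.maf, total_var)
        g = genotypes[spec.name]
        if spec.paired_cpg is not None:
            m_col = cpg_col[spec.paired_cpg]
            mbar = float(m_col.mean())
            if config.modification_mode == "proportional":
                modifier, scale = m_col, mbar
            elif config.modification_mode == "complement":
                modifier, scale = 1.0 - m_col, 1.0 - mbar
            else:  # none: methylation plays no role, constant mean modifier
                modifier, scale = np.full(n, mbar), mbar
        else:
            modifier, scale = np.ones(n), 1.0
        beta = raw / scale if scale > 0 else 0.0
        change += beta * g * modifier
        truth_rows.append(
            {
                "name": spec.name,
                "maf": spec.maf,
                "h2": spec.h2,
                "beta": beta,
                "paired_cpg": spec.paired_cpg if spec.paired_cpg is not None else "",
            }
        )
        if spec.h2 > 0:
            edges.append((spec.name, "TG4", "snp_effect"))
            if spec.paired_cpg is not None and config.modification_mode != "none":
                edges.append((spec.paired_cpg, "TG4", "cpg_modifier"))

    change += rng.normal(0.0, config.residual_sd, size=n)
    log_tg4 = log_tg2 + change

    cols: dict[str, np.ndarray] = {
        "age": age,
        "sex": sex,
        "center": center,
        "TG2": np.exp(log_tg2),
        "TG4": np.exp(log_tg4),
    }
    cols.update(genotypes)
    cols.update({name: cpg_col[name] for name in cpg_names})
    data = pd.DataFrame(cols)
    kinds = {"age": "continuous", "sex": "discrete", "center": "discrete",
             "TG2": "continuous", "TG4": "continuous"}
    kinds.update({s.name: "genotype" for s in config.snps})
    kinds.update({name: "continuous" for name in cpg_names})

    truth = SimTruth(
        snps=pd.DataFrame(truth_rows),
        edges=edges,
        total_var=total_var,
        modification_mode=config.modification_mode,
        seed=config.seed,
    )
    return CohortTable(data, kinds), truth


def null_config(**overrides) -> SimConfig:
    """A cohort with the study layout but no genetic or epigenetic effects."""
    snps = [dataclasses.replace(s, h2=0.0) for s in default_snps()]
    defaults = dict(snps=snps, modification_mode="none", drug_mean_effect=0.0)
    defaults.update(overrides)
    return SimConfig(**defaults)
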