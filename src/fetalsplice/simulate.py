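"""Synthetic cohorts with the statistical structure of developmental splicing studies.

The generator emulates three cohort designs from brain splicing studies:

* ``development`` — healthy donors spanning prenatal to adult ages
  (post-conceptional age in days, birth at 266 days),
* ``dm1`` — adult DM1 patients vs unaffected adult controls,
* ``adult`` — a healthy adult reference cohort.

The generative model couples cassette-exon inclusion to the balance between
antagonistic splicing regulators: MBNL1/MBNL2 expression rises with age
along a logistic curve in log10(post-conceptional age) while CELF1 falls,
and a regulated event's inclusion is an inverse-logit function of the
standardized composite MBNL1 + MBNL2 - CELF1. DM1 samples have that balance
shifted back toward its fetal value by a configurable fraction, producing a
partial reversion to the fetal inclusion pattern. Junction counts add
overdispersed (beta-binomial) sampling noise on top of the true inclusion.

All randomness flows from a single seed through named substreams, so
cohorts are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "BIRTH_DPC",
    "REGULATORS",
    "CohortConfig",
    "SyntheticCohort",
    "regulator_trajectory",
    "event_psi",
    "sample_junction_counts",
    "simulate_cohort",
    "simulate_study",
]

BIRTH_DPC = 266.0  # standard human gestation, days post-conception
REGULATORS = ("CELF1", "MBNL1", "MBNL2")

# adult log2-CPM plateau per regulator (typical cortex magnitudes)
_ADULT_LEVEL = {"CELF1": 5.5, "MBNL1": 6.0, "MBNL2": 7.0}


def _default_regulator_logfc() -> Dict[str, float]:
    # developmental log2 fold change, postnatal minus prenatal
    return {"CELF1": -1.23, "MBNL1": 1.60, "MBNL2": 2.66}


def _default_dm1_regulator_logfc() -> Dict[str, float]:
    # DM1 minus unaffected, log2 scale: slight MBNL1/2 upregulation,
    # essentially unchanged CELF1
    return {"CELF1": -0.09, "MBNL1": 0.50, "MBNL2": 0.44}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``n_group_a`` / ``n_group_b`` are prenatal/postnatal for the
    developmental design, DM1/unaffected for the disease design; the adult
    design pools them into one group. ``frac_true_fetal_shift`` is the
    fraction of events coupled to the regulator balance (and hence
    fetal-shifted in DM1); their developmental inclusion change
    |prenatal - postnatal| is drawn uniformly from ``effect_range``.
    ``dm1_shift`` is the fraction of the developmental balance span reverted
    in DM1 samples. ``depth`` is the mean informative read count per event
    and sample; ``concentration`` the beta-binomial overdispersion parameter
    (larger = closer to binomial).
    """

    n_events: int = 2000
    frac_true_fetal_shift: float = 0.10
    n_group_a: int = 20
    n_group_b: int = 20
    prenatal_age_range: Tuple[float, float] = (56.0, 260.0)
    postnatal_age_range: Tuple[float, float] = (280.0, BIRTH_DPC + 40 * 365.25)
    adult_age_range: Tuple[float, float] = (
        BIRTH_DPC + 23 * 365.25,
        BIRTH_DPC + 70 * 365.25,
    )
    regulator_logfc: Dict[str, float] = field(default_factory=_default_regulator_logfc)
    dm1_regulator_logfc: Dict[str, float] = field(
        default_factory=_default_dm1_regulator_logfc
    )
    dm1_shift: float = 0.6
    depth: float = 50.0
    concentration: float = 30.0
    regulator_noise_sd: float = 0.3  # donor noise on log2 expression
    psi_logit_noise_sd: float = 0.2  # per-sample biological noise on logit(psi)
    effect_range: Tuple[float, float] = (0.3, 0.8)
    frac_fetal_up: float = 0.25  # regulated events with higher prenatal inclusion
    steepness: float = 6.0  # logistic slope per log10(age) unit
    seed: int = 0

    def validate(self) -> None:
        problems = []
        for name in ("frac_true_fetal_shift", "dm1_shift", "frac_fetal_up"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name}={v} outside [0, 1]")
        if self.n_events < 1:
            problems.append(f"n_events={self.n_events} < 1")
        if self.n_group_a < 2 or self.n_group_b < 2:
            problems.append("each group needs >= 2 samples")
        if self.depth < 1:
            problems.append(f"depth={self.depth} < 1")
        if self.concentration <= 0:
            problems.append(f"concentration={self.concentration} <= 0")
        lo, hi = self.effect_range
        if not (0 < lo <= hi < 1):
            problems.append(f"effect_range={self.effect_range} invalid")
        if problems:
            raise ValueError("invalid CohortConfig: " + "; ".join(problems))


@dataclass
class SyntheticCohort:
    """A generated cohort: metadata, regulator expression, true inclusion,
    junction counts, and per-event ground truth."""

    kind: str
    metadata: pd.DataFrame        # sample_id, donor, age_days, group, sex, subregion, dataset
    regulator_expr: pd.DataFrame  # regulators x samples, log2-CPM scale
    true_psi: pd.DataFrame        # events x samples in [0, 1]
    inclusion: pd.DataFrame       # events x samples integer counts
    exclusion: pd.DataFrame       # events x samples integer counts
    truth: pd.DataFrame           # event_id, regulated, sign, psi_prenatal, psi_postnatal, ...
    config: CohortConfig


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _log_age_grid(age_range: Tuple[float, float], n: int = 512) -> np.ndarray:
    lo, hi = np.log10(age_range[0]), np.log10(age_range[1])
    return np.linspace(lo, hi, n)


def _design_sigmoid_mean(config: CohortConfig, age_range: Tuple[float, float]) -> float:
    """Mean of the logistic age response over a log10-uniform age design."""
    g = _log_age_grid(age_range)
    return float(np.mean(_sigmoid(config.steepness * (g - np.log10(BIRTH_DPC)))))


def _trajectory_span(config: CohortConfig, gene: str) -> float:
    """Logistic span calibrated so the prenatal/postnatal group-mean difference
    equals the configured developmental logFC in expectation."""
    if gene not in config.regulator_logfc:
        raise ValueError(f"unknown regulator: {gene!r}")
    c_pre = _design_sigmoid_mean(config, config.prenatal_age_range)
    c_post = _design_sigmoid_mean(config, config.postnatal_age_range)
    return config.regulator_logfc[gene] / (c_post - c_pre)


def regulator_trajectory(
    age_days: np.ndarray | float,
    gene: str,
    config: CohortConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Expected log2 expression of a splicing regulator at a given age.

    A logistic curve in log10(post-conceptional age) with midpoint at birth:
    MBNL1/2 rise toward their adult plateau, CELF1 falls from a higher fetal
    level. If ``rng`` is given, Gaussian donor noise (sd
    ``config.regulator_noise_sd``) is added.
    """
    age = np.asarray(age_days, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age_days must be positive")
    span = _trajectory_span(config, gene)
    s = _sigmoid(config.steepness * (np.log10(age) - np.log10(BIRTH_DPC)))
    # anchor the curve at its adult plateau (sigmoid -> 1)
    expr = _ADULT_LEVEL[gene] + span * (s - 1.0)
    if rng is not None:
        expr = expr + rng.normal(0.0, config.regulator_noise_sd, size=np.shape(expr))
    return expr


def _balance(expr: pd.DataFrame | Dict[str, np.ndarray]) -> np.ndarray:
    """Raw regulator-balance composite MBNL1 + MBNL2 - CELF1."""
    if isinstance(expr, pd.DataFrame):
        return (expr.loc["MBNL1"] + expr.loc["MBNL2"] - expr.loc["CELF1"]).to_numpy()
    return np.asarray(expr["MBNL1"]) + np.asarray(expr["MBNL2"]) - np.asarray(expr["CELF1"])


def _balance_standardizer(config: CohortConfig) -> Tuple[float, float]:
    """Mean and sd of the noise-free balance over the pooled developmental
    design (equal-weight prenatal + postnatal, log10-uniform ages).
    Standardizing against this fixed reference keeps the balance scale
    identical across cohort kinds."""
    ages = np.concatenate(
        [10 ** _log_age_grid(config.prenatal_age_range),
         10 ** _log_age_grid(config.postnatal_age_range)]
    )
    expr = {g: regulator_trajectory(ages, g, config) for g in REGULATORS}
    b = _balance(expr)
    return float(np.mean(b)), float(np.std(b))


def _reference_z(config: CohortConfig, age_range: Tuple[float, float]) -> float:
    """Design-average standardized balance over one age range."""
    mu, sd = _balance_standardizer(config)
    ages = 10 ** _log_age_grid(age_range)
    expr = {g: regulator_trajectory(ages, g, config) for g in REGULATORS}
    return float((np.mean(_balance(expr)) - mu) / sd)


def event_psi(
    regulator_balance: np.ndarray | float,
    baseline: float,
    sign: int,
    sensitivity: float,
    logit_noise: np.ndarray | float = 0.0,
) -> np.ndarray:
    """True inclusion of one event given the standardized regulator balance.

    psi = inverse-logit(baseline + sign * sensitivity * balance + noise).
    Events with sensitivity 0 ignore the balance entirely.
    """
    z = np.asarray(regulator_balance, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("regulator balance must be finite")
    return np.asarray(_sigmoid(baseline + sign * sensitivity * z + logit_noise))


def sample_junction_counts(
    true_psi: np.ndarray,
    depth: float,
    concentration: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Overdispersed junction counts for given true inclusion values.

    Per cell: total ~ Poisson(depth); inclusion ~ beta-binomial(total, psi,
    concentration), i.e. p ~ Beta(psi*c, (1-psi)*c) then Binomial(total, p);
    exclusion = total - inclusion. ``concentration = inf`` gives plain
    binomial sampling.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    psi = np.asarray(true_psi, dtype=float)
    total = rng.poisson(depth, size=psi.shape)
    if np.isinf(concentration):
        p = psi
    else:
        a = np.clip(psi * concentration, 1e-12, None)
        b = np.clip((1.0 - psi) * concentration, 1e-12, None)
        p = rng.beta(a, b)
        # beta draws are degenerate at the boundaries; pin them exactly
        p = np.where(psi <= 0.0, 0.0, np.where(psi >= 1.0, 1.0, p))
    inclusion = rng.binomial(total, p)
    return inclusion, total - inclusion


def _logit(p: np.ndarray | float) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def _make_truth(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-event ground truth shared by all cohorts of a study.

    Regulated events get a prenatal and a postnatal target inclusion whose
    difference is drawn from ``effect_range``; baseline and sensitivity are
    solved so the logistic balance model hits those targets at the
    design-average prenatal/postnatal balance values.
    """
    n = config.n_events
    event_ids = [f"ev{i:05d}" for i in range(n)]
    n_reg = int(round(config.frac_true_fetal_shift * n))
    regulated = np.zeros(n, dtype=bool)
    regulated[:n_reg] = True

    # sign +1: inclusion higher postnatally (decreased in DM1); sign -1: fetal-up
    sign = np.where(rng.random(n) < config.frac_fetal_up, -1, 1)
    sign[~regulated] = 0

    delta = rng.uniform(*config.effect_range, size=n)
    center = rng.uniform(delta / 2 + 0.05, 0.95 - delta / 2)
    psi_pre = np.where(sign >= 0, center - delta / 2, center + delta / 2)
    psi_post = np.where(sign >= 0, center + delta / 2, center - delta / 2)

    base_null = _logit(rng.uniform(0.05, 0.95, size=n))

    z_pre = _reference_z(config, config.prenatal_age_range)
    z_post = _reference_z(config, config.postnatal_age_range)
    sensitivity = np.where(
        regulated,
        (_logit(psi_post) - _logit(psi_pre)) / (sign * (z_post - z_pre) + (sign == 0)),
        0.0,
    )
    baseline = np.where(
        regulated, _logit(psi_pre) - sign * sensitivity * z_pre, base_null
    )
    psi_pre = np.where(regulated, psi_pre, _sigmoid(base_null))
    psi_post = np.where(regulated, psi_post, _sigmoid(base_null))

    return pd.DataFrame(
        {
            "event_id": event_ids,
            "regulated": regulated,
            "sign": sign,
            "baseline": baseline,
            "sensitivity": sensitivity,
            "psi_prenatal": psi_pre,
            "psi_postnatal": psi_post,
            "true_delta_dev": psi_pre - psi_post,
        }
    ).set_index("event_id")


def _sample_ages(
    kind: str, config: CohortConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Ages (days post-conception) and group labels for one cohort."""

    def loguni(age_range, size):
        lo, hi = np.log10(age_range[0]), np.log10(age_range[1])
        return 10 ** rng.uniform(lo, hi, size=size)

    na, nb = config.n_group_a, config.n_group_b
    if kind == "development":
        ages = np.concatenate(
            [loguni(config.prenatal_age_range, na), loguni(config.postnatal_age_range, nb)]
        )
        groups = np.array(["prenatal"] * na + ["postnatal"] * nb)
    elif kind == "dm1":
        ages = loguni(config.adult_age_range, na + nb)
        groups = np.array(["dm1"] * na + ["unaffected"] * nb)
    elif kind == "adult":
        ages = loguni(config.adult_age_range, na + nb)
        groups = np.array(["adult"] * (na + nb))
    else:
        raise ValueError(f"unknown cohort kind: {kind!r}")
    return ages, groups


def simulate_cohort(
    config: CohortConfig,
    kind: str = "development",
    truth: Optional[pd.DataFrame] = None,
    seed_offset: int = 0,
) -> SyntheticCohort:
    """Generate one cohort. Deterministic given (config.seed, kind, seed_offset).

    Passing a ``truth`` table from a previous call generates a second cohort
    over the same events (the paired developmental/disease design).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed, spawn_key=(seed_offset,))
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("truth", "ages", "regulators", "psi_noise", "counts"), ss.spawn(5)
        )
    }
    if truth is None:
        truth = _make_truth(config, streams["truth"])

    ages, groups = _sample_ages(kind, config, streams["ages"])
    n_samples = ages.size
    sample_ids = [f"{kind}_s{i:03d}" for i in range(n_samples)]

    expr = pd.DataFrame(
        {
            sid: [
                regulator_trajectory(a, g, config)
                for g in REGULATORS
            ]
            for sid, a in zip(sample_ids, ages)
        },
        index=list(REGULATORS),
        dtype=float,
    )
    expr += streams["regulators"].normal(0.0, config.regulator_noise_sd, size=expr.shape)

    # standardized splicing-activity balance per sample, on the fixed
    # developmental scale
    mu, sd = _balance_standardizer(config)
    z = (_balance(expr) - mu) / sd
    if kind == "dm1":
        # Disease shifts the *activity* balance toward its fetal value;
        # the mild DM1 mRNA change is layered onto the measured expression
        # afterwards and deliberately does not feed back into activity
        # (mRNA levels do not rescue sequestered protein).
        z_fetal = _reference_z(config, config.prenatal_age_range)
        z_adult = _reference_z(config, config.adult_age_range)
        z = np.where(groups == "dm1", z + config.dm1_shift * (z_fetal - z_adult), z)
        for g in REGULATORS:
            expr.loc[g, groups == "dm1"] += config.dm1_regulator_logfc.get(g, 0.0)

    baseline = truth["baseline"].to_numpy()[:, None]
    sign = truth["sign"].to_numpy()[:, None]
    sens = truth["sensitivity"].to_numpy()[:, None]
    noise = streams["psi_noise"].normal(
        0.0, config.psi_logit_noise_sd, size=(len(truth), n_samples)
    )
    psi = _sigmoid(baseline + sign * sens * z[None, :] + noise)
    true_psi = pd.DataFrame(psi, index=truth.index, columns=sample_ids)

    inc, exc = sample_junction_counts(
        psi, config.depth, config.concentration, streams["counts"]
    )
    inclusion = pd.DataFrame(inc, index=truth.index, columns=sample_ids)
    exclusion = pd.DataFrame(exc, index=truth.index, columns=sample_ids)

    truth = truth.copy()
    if kind == "dm1":
        z_fetal = _reference_z(config, config.prenatal_age_range)
        z_adult = _reference_z(config, config.adult_age_range)
        z_dm1 = z_adult + config.dm1_shift * (z_fetal - z_adult)
        b, sg, se = (truth[c].to_numpy() for c in ("baseline", "sign", "sensitivity"))
        psi_un = _sigmoid(b + sg * se * z_adult)
        psi_dm1 = _sigmoid(b + sg * se * z_dm1)
        truth["true_delta_dm1"] = psi_dm1 - psi_un

    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "donor": [f"{kind}_d{i:03d}" for i in range(n_samples)],
            "age_days": ages,
            "group": groups,
            "sex": np.where(streams["ages"].random(n_samples) < 0.5, "M", "F"),
            "subregion": "frontal_cortex",
            "dataset": kind,
        }
    )
    return SyntheticCohort(
        kind=kind,
        metadata=metadata,
        regulator_expr=expr,
        true_psi=true_psi,
        inclusion=inclusion,
        exclusion=exclusion,
        truth=truth,
        config=config,
    )


def simulate_study(config: CohortConfig) -> Dict[str, SyntheticCohort]:
    """The full paired design: developmental, DM1-vs-unaffected and
    healthy-adult cohorts sharing one event truth table."""
    dev = simulate_cohort(config, "development", seed_offset=0)
    dm1 = simulate_cohort(config, "dm1", truth=dev.truth, seed_offset=1)
    adult = simulate_cohort(config, "adult", truth=dev.truth, seed_offset=2)
    return {"development": dev, "dm1": dm1, "adult": adult}


def simulate_gene_counts(
    cohort: SyntheticCohort,
    n_background_genes: int = 200,
    mean_log2_expr: float = 5.0,
    seed_offset: int = 9,
) -> pd.DataFrame:
    """Raw gene-level counts (regulators + background genes) whose TMM
    log2-CPM values track the cohort's regulator expression.

    Library sizes vary log-normally around 2e6 so normalization is
    non-trivial; counts are Poisson around the expected CPM share.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(cohort.config.seed, spawn_key=(seed_offset,))
    )
    n_samples = cohort.regulator_expr.shape[1]
    genes = list(REGULATORS) + [f"gene{i:04d}" for i in range(n_background_genes)]
    log2_expr = np.empty((len(genes), n_samples))
    log2_expr[: len(REGULATORS)] = cohort.regulator_expr.to_numpy()
    base = rng.normal(mean_log2_expr, 1.5, size=n_background_genes)
    log2_expr[len(REGULATORS):] = base[:, None] + rng.normal(
        0.0, 0.1, size=(n_background_genes, n_samples)
    )
    rel = 2.0 ** log2_expr
    rel /= rel.sum(axis=0, keepdims=True)
    lib = rng.lognormal(np.log(2e6), 0.2, size=n_samples)
    counts = rng.poisson(rel * lib[None, :])
    return pd.DataFrame(counts, index=genes, columns=cohort.regulator_expr.columns)
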