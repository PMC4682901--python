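"""Seeded synthetic cohort generator.

Emulates the statistical structure the shape analysis assumes, so every
pipeline stage can be exercised end-to-end without patient data:

* per-subtype tumor diameters: the largest diameter ``a`` is lognormal
  (truncated to (0, 10] cm, the cohort inclusion limit) and the shorter
  diameters follow ``b = a*u1``, ``c = b*u2`` with independent Beta-distributed
  ratios, so ``a >= b >= c > 0`` holds by construction.  Triple-negative
  (HR-/HER2-) tumors get Beta parameters concentrated near 1, making them
  more spherical (lower SED) than HR+ tumors;
* lymph-node metastasis: Bernoulli with a logistic model in SED and tumor
  size, so the node-positive fraction rises across SED tertiles;
* distant-metastasis-free survival: exponential event times with log-hazard
  shifts by SED tertile and subtype, independent exponential censoring and
  an administrative follow-up cap;
* expression: a gene x sample FPKM matrix with lognormal null genes spanning
  the screen's abundance/dispersion filter thresholds, plus planted genes
  whose FPKM-scale Pearson correlation with SED is calibrated to a target
  value at generation time.

All randomness flows through one :class:`numpy.random.Generator`; a fixed
seed reproduces every output exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from tumorshape.cohort import PatientRecord, SedGroup, Subtype, assign_sed_tertiles
from tumorshape.morphometry import TumorDimensions, sed_from_sorted
from tumorshape.screen import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "generate_dimensions",
    "generate_clinical",
    "generate_expression",
    "clinical_frame",
]


SUBTYPES: Tuple[Subtype, ...] = (
    Subtype.HR_POS_HER2_NEG,
    Subtype.HR_POS_HER2_POS,
    Subtype.HR_NEG_HER2_POS,
    Subtype.HR_NEG_HER2_NEG,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults target the qualitative structure of a breast-cancer surgical
    cohort: subtype mix dominated by HR+/HER2-, mean largest diameter around
    2.4 cm, triple-negative tumors most spherical, node positivity around
    40% rising with SED, and a modest SED-dependent hazard of distant
    metastasis.  Effect sizes are model assumptions, not measured values.
    """

    n_patients: int = 2250
    #: cohort mix (HR+/HER2-, HR+/HER2+, HR-/HER2+, HR-/HER2-); sums to 1
    subtype_proportions: Dict[str, float] = field(
        default_factory=lambda: {
            "HR+/HER2-": 0.58,
            "HR+/HER2+": 0.07,
            "HR-/HER2+": 0.10,
            "HR-/HER2-": 0.25,
        }
    )
    #: per-subtype (median_cm, log_sd) of the lognormal largest diameter
    diameter_scale: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "HR+/HER2-": (2.1, 0.45),
            "HR+/HER2+": (2.4, 0.45),
            "HR-/HER2+": (2.7, 0.45),
            "HR-/HER2-": (2.5, 0.45),
        }
    )
    #: per-subtype Beta(alpha, beta) for both diameter ratios b/a and c/b;
    #: mass near 1 => spherical.  Triple negative most spherical.
    eccentricity_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "HR+/HER2-": (4.0, 4.0),
            "HR+/HER2+": (4.0, 4.0),
            "HR-/HER2+": (5.0, 3.0),
            "HR-/HER2-": (8.0, 2.0),
        }
    )
    max_diameter_cm: float = 10.0
    #: logistic model for lymph-node positivity:
    #: logit p = intercept + beta_sed * SED + beta_size * a
    node_intercept: float = -2.0
    node_beta_sed: float = 1.5
    node_beta_size: float = 0.2
    #: DMFS hazard: baseline exponential rate (events/month) with log-hazard
    #: shifts by cohort SED tertile and subtype
    baseline_hazard_per_month: float = 0.0015
    hazard_coef_sed_group: Dict[str, float] = field(
        default_factory=lambda: {"Low": 0.0, "Middle": 0.4, "High": 0.8}
    )
    #: kept modest, and equal within HR-, so the SED-tertile hazard signal is
    #: identifiable instead of being cancelled by subtype confounding
    #: (triple-negative tumors sit mostly in the low-SED tertile)
    hazard_coef_subtype: Dict[str, float] = field(
        default_factory=lambda: {
            "HR+/HER2-": 0.0,
            "HR+/HER2+": 0.2,
            "HR-/HER2+": 0.3,
            "HR-/HER2-": 0.3,
        }
    )
    censoring_rate_per_month: float = 0.006
    follow_up_months: float = 150.0
    #: histologic grade distribution per subtype (P(grade 1), P(2), P(3))
    grade_probs: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: {
            "HR+/HER2-": (0.25, 0.50, 0.25),
            "HR+/HER2+": (0.10, 0.45, 0.45),
            "HR-/HER2+": (0.05, 0.35, 0.60),
            "HR-/HER2-": (0.05, 0.25, 0.70),
        }
    )
    grade_missing_rate: float = 0.02
    # --- expression block ---
    n_expression_samples: int = 41
    n_genes: int = 2000
    #: FPKM-scale Pearson targets of the planted genes (sign = direction);
    #: magnitudes span the range a 41-sample screen can plausibly detect
    planted_correlations: Tuple[float, ...] = (
        -0.54, -0.52, -0.51, -0.50, -0.48, -0.47, -0.46, -0.45,
        -0.44, -0.43, -0.42, -0.41, 0.41, 0.43, 0.45, 0.47,
        0.50, 0.52, 0.54, 0.60,
    )
    #: planted genes: FPKM mean range and log-scale sd range (keeps them
    #: above the mean>10 and CV>1 screen filters)
    planted_mean_range: Tuple[float, float] = (30.0, 2000.0)
    planted_log_sd_range: Tuple[float, float] = (0.9, 1.4)
    #: null genes: log-mean ~ N(log(null_mean_median), null_mean_log_sd^2),
    #: per-gene log-scale sd uniform in null_log_sd_range -- spans both sides
    #: of the screen's abundance (10) and CV (1) thresholds
    null_mean_median: float = 60.0
    null_mean_log_sd: float = 1.8
    null_log_sd_range: Tuple[float, float] = (0.5, 1.6)
    seed: Optional[int] = None

    def validate(self) -> None:
        props = [self.subtype_proportions.get(s.value) for s in SUBTYPES]
        if any(p is None for p in props):
            raise ConfigError("subtype_proportions must cover all four subtypes")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ConfigError(f"subtype proportions must sum to 1, got {sum(props)}")
        if any(p < 0 for p in props):
            raise ConfigError("subtype proportions must be non-negative")
        for s in SUBTYPES:
            med, lsd = self.diameter_scale[s.value]
            if med <= 0 or lsd <= 0:
                raise ConfigError(f"diameter_scale for {s.value} must be positive")
            al, be = self.eccentricity_params[s.value]
            if al <= 0 or be <= 0:
                raise ConfigError(f"eccentricity Beta parameters for {s.value} must be positive")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.baseline_hazard_per_month <= 0:
            raise ConfigError("baseline hazard must be > 0")
        if self.censoring_rate_per_month < 0:
            raise ConfigError("censoring rate must be >= 0")
        if not 0 <= self.grade_missing_rate < 1:
            raise ConfigError("grade_missing_rate must be in [0, 1)")
        if len(self.planted_correlations) > self.n_genes:
            raise ConfigError("more planted genes than total genes")
        if any(not -1.0 < r < 1.0 or r == 0.0 for r in self.planted_correlations):
            raise ConfigError("planted correlations must be nonzero and in (-1, 1)")
        if self.n_expression_samples < 3:
            raise ConfigError("need at least 3 expression samples")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "SimulationConfig":
        """The reference configuration shipped with the package."""
        from importlib import resources

        with resources.files("tumorshape.data").joinpath("default_config.yaml").open() as fh:
            import yaml

            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        cfg = cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()})
        # YAML round-trips tuples as lists inside dicts too
        for attr in ("diameter_scale", "eccentricity_params", "grade_probs"):
            val = getattr(cfg, attr)
            setattr(cfg, attr, {k: tuple(v) for k, v in val.items()})
        cfg.validate()
        return cfg


def _rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def generate_dimensions(
    config: SimulationConfig, subtype: Subtype, n: int, rng
) -> List[TumorDimensions]:
    """Draw ``n`` diameter triples for one subtype.

    ``a ~ lognormal`` truncated to (0, max_diameter]; ``b = a*u1``,
    ``c = b*u2`` with ``u1, u2 ~ Beta(subtype params)`` independently.
    """
    config.validate()
    gen = _rng(rng)
    a, b, c = _dimension_arrays(config, subtype, n, gen)
    return [TumorDimensions(a=ai, b=bi, c=ci) for ai, bi, ci in zip(a, b, c)]


def _dimension_arrays(config, subtype, n, gen):
    med, lsd = config.diameter_scale[subtype.value]
    mu = math.log(med)
    a = np.empty(n)
    filled = 0
    while filled < n:  # rejection-sample the (0, max] truncation
        draw = gen.lognormal(mean=mu, sigma=lsd, size=n - filled)
        ok = draw <= config.max_diameter_cm
        take = draw[ok]
        a[filled : filled + take.size] = take
        filled += take.size
    al, be = config.eccentricity_params[subtype.value]
    u1 = gen.beta(al, be, size=n)
    u2 = gen.beta(al, be, size=n)
    # guard against an exact 0 from floating underflow
    u1 = np.clip(u1, 1e-9, 1.0)
    u2 = np.clip(u2, 1e-9, 1.0)
    b = a * u1
    c = b * u2
    return a, b, c


def generate_clinical(config: SimulationConfig, rng) -> List[PatientRecord]:
    """Generate the full clinical cohort as validated patient records."""
    config.validate()
    gen = _rng(rng)
    n = config.n_patients

    props = np.array([config.subtype_proportions[s.value] for s in SUBTYPES])
    subtype_idx = gen.choice(len(SUBTYPES), size=n, p=props)

    a = np.empty(n)
    b = np.empty(n)
    c = np.empty(n)
    for i, s in enumerate(SUBTYPES):
        mask = subtype_idx == i
        if mask.any():
            a[mask], b[mask], c[mask] = _dimension_arrays(config, s, int(mask.sum()), gen)

    sed = sed_from_sorted(a, b, c)

    # receptor percentages consistent with the subtype label
    er = np.empty(n)
    pr = np.empty(n)
    hr_pos = subtype_idx <= 1
    n_pos = int(hr_pos.sum())
    # HR+ tumors: ER high for most, PR positive in ~70%
    er[hr_pos] = gen.uniform(10, 100, size=n_pos)
    pr[hr_pos] = np.where(
        gen.random(n_pos) < 0.7, gen.uniform(10, 100, size=n_pos), gen.uniform(0, 10, size=n_pos)
    )
    n_neg = n - n_pos
    er[~hr_pos] = gen.uniform(0, 10, size=n_neg)
    pr[~hr_pos] = gen.uniform(0, 10, size=n_neg)
    er = np.clip(er, 0, 100 - 1e-9)
    pr = np.clip(pr, 0, 100 - 1e-9)
    her2 = (subtype_idx == 1) | (subtype_idx == 2)

    # lymph-node metastasis: logistic in SED and size
    logit = config.node_intercept + config.node_beta_sed * sed + config.node_beta_size * a
    p_node = 1.0 / (1.0 + np.exp(-logit))
    ln_pos = gen.random(n) < p_node

    # histologic grade per subtype, with occasional missingness
    grade = np.empty(n, dtype=object)
    for i, s in enumerate(SUBTYPES):
        mask = subtype_idx == i
        if mask.any():
            probs = np.asarray(config.grade_probs[s.value], dtype=float)
            probs = probs / probs.sum()
            grade[mask] = gen.choice([1, 2, 3], size=int(mask.sum()), p=probs)
    grade[gen.random(n) < config.grade_missing_rate] = None

    # DMFS: exponential event times with SED-tertile and subtype log-hazard
    groups = assign_sed_tertiles(sed)
    g_coef = np.array([config.hazard_coef_sed_group[g.value] for g in groups])
    s_coef = np.array([config.hazard_coef_subtype[SUBTYPES[i].value] for i in subtype_idx])
    lam = config.baseline_hazard_per_month * np.exp(g_coef + s_coef)
    t_event = gen.exponential(1.0 / lam)
    if config.censoring_rate_per_month > 0:
        t_cens = gen.exponential(1.0 / config.censoring_rate_per_month, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, config.follow_up_months)
    dmfs_time = np.minimum(t_event, t_cens)
    dmfs_event = t_event <= t_cens

    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:05d}",
                dims=TumorDimensions(a=float(a[i]), b=float(b[i]), c=float(c[i])),
                er_percent=float(er[i]),
                pr_percent=float(pr[i]),
                her2_positive=bool(her2[i]),
                ln_positive=bool(ln_pos[i]),
                grade=None if grade[i] is None else int(grade[i]),
                dmfs_time=float(dmfs_time[i]),
                dmfs_event=bool(dmfs_event[i]),
            )
        )
    return records


def clinical_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Tabulate patient records in the canonical clinical-table schema."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "diam1": [r.dims.a for r in records],
            "diam2": [r.dims.b for r in records],
            "diam3": [r.dims.c for r in records],
            "er_percent": [r.er_percent for r in records],
            "pr_percent": [r.pr_percent for r in records],
            "her2": [int(r.her2_positive) for r in records],
            "ln_status": [int(r.ln_positive) for r in records],
            "grade": [r.grade if r.grade is not None else np.nan for r in records],
            "dmfs_months": [r.dmfs_time for r in records],
            "dmfs_event": [int(r.dmfs_event) for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Expression


def _mean_sample_r(rho: float, z: np.ndarray, sigma: float, eps_cal: np.ndarray) -> float:
    """Mean sample Pearson r between z and exp(sigma*(rho*z + sqrt(1-rho^2)*eps)).

    Averaged over the fixed calibration noise draws ``eps_cal`` (replicates x
    n).  The FPKM-scale sample correlation differs from the log-scale rho:
    exponentiation attenuates the signal while heavy-tailed noise makes the
    finite-sample r run above its population value, so calibration targets
    the expected *sample* correlation directly.
    """
    w = math.sqrt(max(1.0 - rho**2, 0.0))
    y = np.exp(sigma * (rho * z[None, :] + w * eps_cal))
    zc = z - z.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((zc**2).sum() * (yc**2).sum(axis=1))
    r = (yc @ zc) / denom
    return float(r.mean())


def _calibrate_rho(target_abs_r: float, z: np.ndarray, sigma: float, eps_cal: np.ndarray) -> float:
    """Log-scale correlation whose expected FPKM-scale sample r hits the target."""
    hi = 0.999999
    r_max = _mean_sample_r(hi, z, sigma, eps_cal)
    if target_abs_r >= r_max:
        raise ConfigError(
            f"planted |r|={target_abs_r} unattainable on the FPKM scale with "
            f"log-sd {sigma} (max {r_max:.3f})"
        )
    return brentq(
        lambda rho: _mean_sample_r(rho, z, sigma, eps_cal) - target_abs_r, 0.0, hi, xtol=1e-6
    )


def generate_expression(
    sed_values: Sequence[float],
    config: SimulationConfig,
    rng,
    sample_ids: Optional[Sequence[str]] = None,
) -> Tuple[ExpressionMatrix, List[str]]:
    """Generate the FPKM matrix; returns (matrix, planted gene symbols).

    Planted gene g with target r: on the log scale the gene is
    ``sigma*(rho*z + sqrt(1-rho^2)*noise)`` around a mean level, with rho
    calibrated once per gene (closed-form lognormal moments against the
    realized SED vector) so that the expected Pearson correlation computed on
    the FPKM scale equals the target.  Null genes are independent lognormal
    with per-gene dispersion spanning the screen's CV filter threshold.
    """
    config.validate()
    gen = _rng(rng)
    sed_arr = np.asarray(list(sed_values), dtype=float)
    n = sed_arr.size
    if n != config.n_expression_samples:
        raise ConfigError(
            f"got {n} SED values but config.n_expression_samples={config.n_expression_samples}"
        )
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    z = sed_arr - sed_arr.mean()
    sd = z.std()
    if sd == 0:
        raise ConfigError("SED values are constant; cannot plant correlated genes")
    z = z / sd

    n_planted = len(config.planted_correlations)
    n_null = config.n_genes - n_planted

    # planted genes
    lo_m, hi_m = config.planted_mean_range
    lo_s, hi_s = config.planted_log_sd_range
    planted_rows = np.empty((n_planted, n))
    planted_names = [f"PLANT{j + 1:03d}" for j in range(n_planted)]
    n_cal = 400  # calibration replicates per planted gene
    for j, target in enumerate(config.planted_correlations):
        sigma = gen.uniform(lo_s, hi_s)
        mu_fpkm = math.exp(gen.uniform(math.log(lo_m), math.log(hi_m)))
        zz = z if target > 0 else -z
        eps_cal = gen.standard_normal((n_cal, n))
        rho = _calibrate_rho(abs(target), zz, sigma, eps_cal)
        eps = gen.standard_normal(n)
        logval = sigma * (rho * zz + math.sqrt(1.0 - rho**2) * eps)
        raw = np.exp(logval)
        planted_rows[j] = mu_fpkm * raw / raw.mean()  # anchor the gene mean

    # null genes: independent lognormal, means and CVs straddling the filters
    log_means = gen.normal(math.log(config.null_mean_median), config.null_mean_log_sd, size=n_null)
    sig = gen.uniform(*config.null_log_sd_range, size=n_null)
    eps = gen.standard_normal((n_null, n))
    null_rows = np.exp(log_means[:, None] + sig[:, None] * eps - 0.5 * sig[:, None] ** 2)
    null_names = [f"NULL{j + 1:04d}" for j in range(n_null)]

    values = np.vstack([planted_rows, null_rows])
    names = planted_names + null_names
    # shuffle gene order so planted genes are not positionally identifiable
    perm = gen.permutation(config.n_genes)
    df = pd.DataFrame(values[perm], index=np.asarray(names)[perm], columns=list(sample_ids))
    return ExpressionMatrix(values=df), planted_names
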