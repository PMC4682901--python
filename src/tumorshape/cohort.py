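"""Subtype classification, SED tertiles, and association statistics.

Implements the cross-sectional association layer: four-way molecular subtype
labels from ER/PR/HER2 immunohistochemistry, cohort-wide SED tertiles
(Low/Middle/High), Pearson chi-square contingency analysis of categorical
factors across tertiles, column percentages in report style, and per-group
continuous summaries (mean +/- SD with an overall ANOVA p-value and pairwise
Welch t-tests).
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from tumorshape.morphometry import TumorDimensions

logger = logging.getLogger(__name__)

__all__ = [
    "PatientRecord",
    "Subtype",
    "SedGroup",
    "ContingencyResult",
    "GroupSummary",
    "classify_subtype",
    "assign_sed_tertiles",
    "contingency_chi2",
    "column_percentages",
    "group_continuous_summary",
    "round_half_up",
]

#: ER/PR positivity cut-off: fraction of stained cells (percent).
HR_POSITIVITY_CUTOFF = 10.0


@dataclass(frozen=True)
class PatientRecord:
    """One patient's clinical record for the shape analysis.

    ``dmfs_time`` is the months from surgery to distant metastasis or to
    censoring; ``dmfs_event`` is True for observed distant metastasis.
    ``grade`` is the histologic grade 1-3 (None when missing).
    """

    patient_id: str
    dims: TumorDimensions
    er_percent: float
    pr_percent: float
    her2_positive: bool
    ln_positive: bool
    grade: Optional[int]
    dmfs_time: float
    dmfs_event: bool

    def __post_init__(self) -> None:
        if self.dmfs_time < 0:
            raise ValueError(f"dmfs_time must be >= 0, got {self.dmfs_time}")
        for name in ("er_percent", "pr_percent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.grade is not None and self.grade not in (1, 2, 3):
            raise ValueError(f"grade must be 1-3 or None, got {self.grade}")


class Subtype(str, enum.Enum):
    """Four-way molecular subtype from hormonal-receptor and HER2 status.

    HR is positive when either ER or PR staining reaches 10% of cells.
    """

    HR_POS_HER2_NEG = "HR+/HER2-"
    HR_POS_HER2_POS = "HR+/HER2+"
    HR_NEG_HER2_POS = "HR-/HER2+"
    HR_NEG_HER2_NEG = "HR-/HER2-"  # triple negative

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SedGroup(str, enum.Enum):
    """Cohort-wide SED tertile label."""

    LOW = "Low"
    MIDDLE = "Middle"
    HIGH = "High"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


SED_GROUP_ORDER: Tuple[SedGroup, SedGroup, SedGroup] = (
    SedGroup.LOW,
    SedGroup.MIDDLE,
    SedGroup.HIGH,
)


class MissingReceptorError(ValueError):
    """ER or PR percentage missing: the record carries no subtype information."""


def classify_subtype(
    er_percent: Optional[float],
    pr_percent: Optional[float],
    her2_positive: bool,
) -> Subtype:
    """Classify one tumor into the four-way HR/HER2 subtype.

    HR+ iff ER >= 10% or PR >= 10% of stained cells.  A missing receptor
    value cannot be classified and raises :class:`MissingReceptorError`;
    ingestion excludes such records with a logged reason, mirroring the
    cohort's exclusion of patients without immunohistochemistry data.
    """
    for name, v in (("er_percent", er_percent), ("pr_percent", pr_percent)):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise MissingReceptorError(f"{name} missing; subtype undefined")
        if not 0.0 <= float(v) <= 100.0:
            raise ValueError(f"{name} must be in [0, 100], got {v!r}")
    hr_positive = er_percent >= HR_POSITIVITY_CUTOFF or pr_percent >= HR_POSITIVITY_CUTOFF
    if hr_positive:
        return Subtype.HR_POS_HER2_POS if her2_positive else Subtype.HR_POS_HER2_NEG
    return Subtype.HR_NEG_HER2_POS if her2_positive else Subtype.HR_NEG_HER2_NEG


def assign_sed_tertiles(sed_values: Sequence[float]) -> List[SedGroup]:
    """Assign each patient to the Low/Middle/High cohort SED tertile.

    Cut-points are the 1/3 and 2/3 empirical quantiles under the
    inverse-empirical-CDF convention; values tied with a cut-point go to the
    lower group.  With all-distinct values and n divisible by 3 the split is
    exactly n/3 each; ties can shift whole tie-blocks.

    Raises
    ------
    ValueError
        If fewer than 3 values are supplied.
    """
    values = np.asarray(list(sed_values), dtype=float)
    if values.ndim != 1 or values.size < 3:
        raise ValueError(f"need at least 3 SED values to form tertiles, got {values.size}")
    if np.isnan(values).any():
        raise ValueError("SED values must not contain NaN")
    c1, c2 = np.quantile(values, [1.0 / 3.0, 2.0 / 3.0], method="inverted_cdf")
    if c1 == c2:
        warnings.warn(
            "degenerate SED tertiles: 1/3 and 2/3 quantiles coincide; "
            "tied values assigned to the lower group",
            stacklevel=2,
        )
    out: List[SedGroup] = []
    for v in values:
        if v <= c1:
            out.append(SedGroup.LOW)
        elif v <= c2:
            out.append(SedGroup.MIDDLE)
        else:
            out.append(SedGroup.HIGH)
    return out


@dataclass(frozen=True)
class ContingencyResult:
    """Pearson chi-square test of independence on an r x k count table."""

    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p: float


def contingency_chi2(observed) -> ContingencyResult:
    """Pearson chi-square (no continuity correction) on a count table.

    Raises
    ------
    ValueError
        On tables smaller than 2x2, negative counts, or a zero marginal
        (expected counts undefined).
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError(f"need at least a 2x2 table, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal row/column: expected counts undefined")
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    return ContingencyResult(observed=obs, expected=expected, chi2=float(chi2), df=int(df), p=float(p))


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (report convention; banker's rounding would
    print 42.85 -> 42.8 where the source tables print 42.9)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def column_percentages(observed, decimals: int = 1) -> np.ndarray:
    """Percentage of each column total, rounded half-up for reporting.

    ``cell = 100 * count / column_sum``; each column of the result sums to
    100 up to rounding.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2:
        raise ValueError("expected a 2-D count table")
    colsums = obs.sum(axis=0)
    if (colsums == 0).any():
        raise ValueError("zero column sum: percentages undefined")
    pct = 100.0 * obs / colsums
    vec = np.vectorize(lambda v: round_half_up(v, decimals))
    return vec(pct)


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean +/- sample SD with an overall difference test.

    ``anova_p`` is the one-way ANOVA p-value across all groups (NaN and
    ``degenerate=True`` when every group is internally constant, where the F
    statistic is undefined).  ``pairwise_t`` holds two-sided Welch t-test
    p-values for each unordered pair of group labels.
    """

    means: Dict[str, float]
    sds: Dict[str, float]
    ns: Dict[str, int]
    anova_p: float
    pairwise_t: Dict[Tuple[str, str], float]
    degenerate: bool


def group_continuous_summary(groups: Dict[str, Sequence[float]]) -> GroupSummary:
    """Summarise a continuous variable per group (e.g. tumor size per tertile).

    Raises
    ------
    ValueError
        On an empty group or a group with < 2 non-missing values (sample SD
        undefined).
    """
    clean: Dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < 2:
            raise ValueError(f"group {name!r} has {arr.size} non-missing values; need >= 2")
        clean[name] = arr

    means = {k: float(v.mean()) for k, v in clean.items()}
    sds = {k: float(v.std(ddof=1)) for k, v in clean.items()}
    ns = {k: int(v.size) for k, v in clean.items()}

    arrays = list(clean.values())
    degenerate = all(s == 0.0 for s in sds.values())
    if degenerate:
        logger.warning("all groups internally constant: ANOVA p undefined")
        anova_p = float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, anova_p = stats.f_oneway(*arrays)
        anova_p = float(anova_p)

    names = list(clean)
    pairwise: Dict[Tuple[str, str], float] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = clean[names[i]], clean[names[j]]
            if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
                # identical constants give t=0/0; equal constants mean no
                # evidence of difference, unequal ones certain difference
                pval = 1.0 if a[0] == b[0] else 0.0
            else:
                _, pval = stats.ttest_ind(a, b, equal_var=False)
            pairwise[(names[i], names[j])] = float(pval)

    return GroupSummary(
        means=means, sds=sds, ns=ns, anova_p=anova_p, pairwise_t=pairwise, degenerate=degenerate
    )
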