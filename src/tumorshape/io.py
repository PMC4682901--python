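"""Clinical-table ingestion, report assembly, and the end-to-end pipeline.

The clinical table is delimited text with a header and columns
``patient_id, diam1, diam2, diam3, er_percent, pr_percent, her2, ln_status,
grade, dmfs_months, dmfs_event`` (booleans as 0/1).  Ingestion applies the
cohort exclusion rules -- tumors larger than 10 cm, records without all
three diameters, records without receptor (subtype) information -- and logs
machine-parsable per-rule exclusion counts to stderr.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from tumorshape import __version__
from tumorshape.cohort import (
    PatientRecord,
    SedGroup,
    Subtype,
    assign_sed_tertiles,
    classify_subtype,
    column_percentages,
    contingency_chi2,
    group_continuous_summary,
)
from tumorshape.morphometry import (
    DimensionError,
    normalize_dimensions,
    sed,
    volume_set,
)
from tumorshape.screen import ExpressionMatrix, screen
from tumorshape.survival import cox_fit, km_estimate, log_rank_test, pairwise_log_rank

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "IngestionResult",
    "AnalysisReport",
    "read_clinical",
    "write_clinical",
    "cohort_table",
    "run_pipeline",
]

REQUIRED_COLUMNS = (
    "patient_id",
    "diam1",
    "diam2",
    "diam3",
    "er_percent",
    "pr_percent",
    "her2",
    "ln_status",
    "grade",
    "dmfs_months",
    "dmfs_event",
)

MAX_DIAMETER_CM = 10.0


@dataclass
class IngestionResult:
    """Validated records plus per-rule exclusion accounting."""

    records: List[PatientRecord]
    exclusions: Dict[str, int]

    @property
    def n_excluded(self) -> int:
        return sum(self.exclusions.values())


def read_clinical(path, sep: Optional[str] = None, strict: bool = False) -> IngestionResult:
    """Read and validate a clinical table, applying the cohort exclusion rules.

    Dimensions are sorted into the a >= b >= c convention.  Exclusion rules
    (each counted separately, counts logged to stderr):

    * ``missing_dimensions`` — any of the three diameters absent/non-numeric
    * ``invalid_dimensions`` — non-positive or non-finite diameter
    * ``oversize_tumor`` — largest diameter > 10 cm
    * ``missing_receptor`` — ER or PR percentage absent (no subtype info)
    * ``malformed_row`` — any other per-row validation failure

    ``strict=True`` turns any malformed row into an error instead.

    Raises
    ------
    ValueError
        If a required column is missing from the header.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"clinical table missing required columns: {missing_cols}")
    return records_from_frame(df, strict=strict)


def records_from_frame(df: pd.DataFrame, strict: bool = False) -> IngestionResult:
    """Validate a clinical DataFrame into patient records (see read_clinical)."""
    exclusions = {
        "missing_dimensions": 0,
        "invalid_dimensions": 0,
        "oversize_tumor": 0,
        "missing_receptor": 0,
        "malformed_row": 0,
    }
    records: List[PatientRecord] = []
    for row in df.itertuples(index=False):
        try:
            d1, d2, d3 = row.diam1, row.diam2, row.diam3
            if any(pd.isna(v) for v in (d1, d2, d3)):
                exclusions["missing_dimensions"] += 1
                continue
            try:
                dims = normalize_dimensions(d1, d2, d3)
            except DimensionError:
                exclusions["invalid_dimensions"] += 1
                continue
            if dims.a > MAX_DIAMETER_CM:
                exclusions["oversize_tumor"] += 1
                continue
            if pd.isna(row.er_percent) or pd.isna(row.pr_percent):
                exclusions["missing_receptor"] += 1
                continue
            grade = None if pd.isna(row.grade) else int(row.grade)
            records.append(
                PatientRecord(
                    patient_id=str(row.patient_id),
                    dims=dims,
                    er_percent=float(row.er_percent),
                    pr_percent=float(row.pr_percent),
                    her2_positive=bool(int(row.her2)),
                    ln_positive=bool(int(row.ln_status)),
                    grade=grade,
                    dmfs_time=float(row.dmfs_months),
                    dmfs_event=bool(int(row.dmfs_event)),
                )
            )
        except (ValueError, TypeError) as exc:
            if strict:
                raise ValueError(f"malformed clinical row {row!r}: {exc}") from exc
            exclusions["malformed_row"] += 1
    for rule, count in exclusions.items():
        if count:
            logger.info("exclusion rule=%s count=%d", rule, count)
    return IngestionResult(records=records, exclusions=exclusions)


def write_clinical(records: Sequence[PatientRecord], path, sep: str = ",") -> None:
    """Write patient records in the canonical clinical-table schema."""
    from tumorshape.simulate import clinical_frame

    clinical_frame(records).to_csv(path, sep=sep, index=False)


def cohort_table(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Per-patient analysis table: dimensions, volumes, SED, subtype, tertile.

    This is the working DataFrame every downstream stage consumes.
    """
    rows = []
    for r in records:
        vols = volume_set(r.dims)
        s = sed(r.dims)
        subtype = classify_subtype(r.er_percent, r.pr_percent, r.her2_positive)
        rows.append(
            {
                "patient_id": r.patient_id,
                "a": r.dims.a,
                "b": r.dims.b,
                "c": r.dims.c,
                "spheroid_tv": vols.spheroid,
                "oblate_tv": vols.oblate,
                "prolate_tv": vols.prolate,
                "ellipsoid_tv": vols.ellipsoid,
                "sed": s.sed,
                "b_over_a": r.dims.b / r.dims.a,
                "c_over_a": r.dims.c / r.dims.a,
                "subtype": subtype.value,
                "ln_positive": r.ln_positive,
                "grade": r.grade,
                "dmfs_months": r.dmfs_time,
                "dmfs_event": r.dmfs_event,
            }
        )
    df = pd.DataFrame(rows)
    groups = assign_sed_tertiles(df["sed"].to_numpy())
    df["sed_group"] = [g.value for g in groups]
    return df


# ---------------------------------------------------------------------------
# Report / pipeline


@dataclass
class AnalysisReport:
    """Assembled outputs of the pipeline stages, with provenance."""

    morphometry: Optional[dict] = None
    table1: Optional[dict] = None
    survival: Optional[dict] = None
    screen: Optional[pd.DataFrame] = None
    failed_stages: Dict[str, str] = field(default_factory=dict)
    provenance: Dict[str, object] = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="records")
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            return str(o)

        return json.dumps(dataclasses.asdict(self), default=default, indent=2)


def _morphometry_block(df: pd.DataFrame) -> dict:
    out: dict = {"n": int(len(df))}
    for col in ("spheroid_tv", "oblate_tv", "prolate_tv", "ellipsoid_tv", "sed"):
        out[col] = {
            "median": float(df[col].median()),
            "mean": float(df[col].mean()),
            "sd": float(df[col].std(ddof=1)),
        }
    out["sed_by_subtype"] = {
        k: {"mean": float(v.mean()), "sd": float(v.std(ddof=1)), "n": int(v.size)}
        for k, v in df.groupby("subtype")["sed"].apply(np.asarray).items()
    }
    return out


GROUP_ORDER = ["Low", "Middle", "High"]


def _table1_block(df: pd.DataFrame) -> dict:
    """Association of tumor size and node status with SED tertiles, per subtype."""

    def one_block(sub: pd.DataFrame) -> dict:
        counts = np.zeros((2, 3))
        for j, g in enumerate(GROUP_ORDER):
            gmask = sub["sed_group"] == g
            counts[0, j] = int(((~sub["ln_positive"]) & gmask).sum())
            counts[1, j] = int((sub["ln_positive"] & gmask).sum())
        block: dict = {"ln_counts": counts.tolist()}
        try:
            block["ln_percent"] = column_percentages(counts).tolist()
            block["ln_chi2_p"] = contingency_chi2(counts).p
        except ValueError as exc:
            block["ln_error"] = str(exc)
        try:
            summary = group_continuous_summary(
                {g: sub.loc[sub["sed_group"] == g, "a"].to_numpy() for g in GROUP_ORDER}
            )
            block["size_mean"] = summary.means
            block["size_sd"] = summary.sds
            block["size_anova_p"] = summary.anova_p
        except ValueError as exc:
            block["size_error"] = str(exc)
        return block

    out = {"All": one_block(df)}
    for name, sub in df.groupby("subtype"):
        out[name] = one_block(sub)
    return out


def _survival_block(df: pd.DataFrame) -> dict:
    t = df["dmfs_months"].to_numpy(dtype=float)
    e = df["dmfs_event"].to_numpy(dtype=bool)
    g = df["sed_group"].to_numpy()
    out: dict = {}
    out["km_by_sed_group"] = {
        grp: {
            "event_times": km.event_times.tolist(),
            "survival": km.survival.tolist(),
            "at_risk": km.at_risk.tolist(),
        }
        for grp in GROUP_ORDER
        for km in [km_estimate(t[g == grp], e[g == grp])]
    }
    lr = log_rank_test(t, e, g)
    out["logrank_global"] = {"statistic": lr.statistic, "df": lr.df, "p": lr.p}
    out["logrank_vs_high"] = {
        str(k): {"statistic": v.statistic, "p": v.p}
        for k, v in pairwise_log_rank(t, e, g, reference="High").items()
    }
    # Cox: tumor size, node status, grade (complete case), SED group indicators
    cc = df.dropna(subset=["grade"])
    X = np.column_stack(
        [
            cc["a"].to_numpy(float),
            cc["ln_positive"].to_numpy(float),
            cc["grade"].to_numpy(float),
            (cc["sed_group"] == "Middle").to_numpy(float),
            (cc["sed_group"] == "High").to_numpy(float),
        ]
    )
    names = ["tumor_size_cm", "node_positive", "grade", "sed_middle_vs_low", "sed_high_vs_low"]
    fit = cox_fit(
        X, cc["dmfs_months"].to_numpy(float), cc["dmfs_event"].to_numpy(bool), covariate_names=names
    )
    out["cox_multivariate"] = {
        "covariates": names,
        "coef": fit.coefficients.tolist(),
        "hr": fit.hazard_ratios.tolist(),
        "se": fit.standard_errors.tolist(),
        "p": fit.p_values.tolist(),
        "converged": fit.converged,
        "n": int(len(cc)),
        "n_excluded_missing_grade": int(df["grade"].isna().sum()),
    }
    return out


def run_pipeline(
    records: Sequence[PatientRecord],
    expression: Optional[ExpressionMatrix] = None,
    sed_by_sample: Optional[Dict[str, float]] = None,
    stages: Sequence[str] = ("morphometry", "table1", "survival", "screen"),
    provenance: Optional[dict] = None,
) -> AnalysisReport:
    """Run the analysis stages over a validated cohort.

    ``screen`` runs only when an expression matrix is supplied;
    ``sed_by_sample`` defaults to the cohort's own SED values keyed by
    patient id.  A failing stage is recorded in ``failed_stages`` and later
    independent stages still run.
    """
    report = AnalysisReport()
    report.provenance = dict(provenance or {})
    report.provenance.setdefault("software_version", __version__)
    report.provenance.setdefault("n_records", len(records))

    df = cohort_table(records)

    for stage in stages:
        try:
            if stage == "morphometry":
                report.morphometry = _morphometry_block(df)
            elif stage == "table1":
                report.table1 = _table1_block(df)
            elif stage == "survival":
                report.survival = _survival_block(df)
            elif stage == "screen":
                if expression is None:
                    continue
                sed_map = sed_by_sample or dict(zip(df["patient_id"], df["sed"]))
                report.screen = screen(expression, sed_map)
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:  # stage isolation: later stages still run
            logger.error("stage %s failed: %s", stage, exc)
            report.failed_stages[stage] = str(exc)
    return report
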