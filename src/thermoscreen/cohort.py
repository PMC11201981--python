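"""Clinical cohort fixture and validation scoring.

The packaged table transcribes the demographic and clinical data of the
25 malignant breast tumors used to validate the detection method: age,
laterality, quadrant, mammographic density, histology, grade, actual and
thermally estimated tumor size, concomitant in-situ disease, staging,
receptor status, and MRI-measured tumor depth.  One record's depth is
missing in the source and stays missing (no imputation).

Summary statistics are computed over the 25 tumor rows, not patients:
the row-to-patient linkage of the single bilateral case is not recorded
in the table, so patient-level counts would require inventing identity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .inverse import InverseResult
from .phantom import TumorParams

__all__ = [
    "CohortFixtureError",
    "load_cohort_table",
    "summarize_cohort",
    "score_validation",
    "ValidationReport",
]

_TABLE_SHA256 = "c36cba6c8be331c19d4aa69150e5d2b702c8a0efc882f2fefb4c3c8501fbe187"

QUADRANTS = {"UOQ", "UIQ", "LOQ", "LIQ"}
DENSITIES = {"PF", "SF", "HD", "ED"}
HISTOLOGIES = {"ADH", "DCIS", "IDC", "ILC", "LCIS"}
GRADES = {"X", "1", "2", "3"}


class CohortFixtureError(RuntimeError):
    """Packaged cohort table is corrupt or fails its invariants."""


def _fixture_path():
    return resources.files("thermoscreen") / "_data" / "table1.csv"


def load_cohort_table(path=None, verify_checksum: bool = True) -> pd.DataFrame:
    """Load the 25-tumor cohort table as a DataFrame.

    Verifies the fixture checksum and the closed vocabularies; missing
    entries (em-dashes in the source) are NaN/empty.
    """
    src = _fixture_path() if path is None else path
    raw = (src.read_bytes() if hasattr(src, "read_bytes") else open(src, "rb").read())
    if verify_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _TABLE_SHA256:
            raise CohortFixtureError(
                f"cohort fixture checksum mismatch: {digest[:12]}... != "
                f"{_TABLE_SHA256[:12]}..."
            )
    import io

    df = pd.read_csv(
        io.BytesIO(raw),
        dtype={"grade": str, "er": str, "pr": str, "her2": str, "staging": str,
               "dcis_lcis": str},
    )
    if len(df) != 25:
        raise CohortFixtureError(f"expected 25 records, found {len(df)}")
    if not (df["actual_size_cm"] > 0).all() or not (df["estimated_size_cm"] > 0).all():
        raise CohortFixtureError("tumor sizes must be positive")
    for col, vocab in (
        ("quadrant", QUADRANTS),
        ("density", DENSITIES),
        ("histology", HISTOLOGIES),
        ("grade", GRADES),
        ("laterality", {"L", "R"}),
    ):
        bad = set(df[col].dropna()) - vocab
        if bad:
            raise CohortFixtureError(f"unexpected {col} values {bad}")
    return df


def summarize_cohort(records: pd.DataFrame) -> dict:
    """Cohort summary statistics over tumor rows."""
    if len(records) == 0:
        raise ValueError("empty cohort")
    size_err = (records["actual_size_cm"] - records["estimated_size_cm"]).abs()
    return {
        "n_records": int(len(records)),
        "age_median": float(records["age"].median()),
        "age_min": int(records["age"].min()),
        "age_max": int(records["age"].max()),
        "laterality_counts": records["laterality"].value_counts().to_dict(),
        "quadrant_counts": records["quadrant"].value_counts().to_dict(),
        "density_counts": records["density"].value_counts().to_dict(),
        "histology_counts": records["histology"].value_counts().to_dict(),
        "grade_counts": records["grade"].value_counts().to_dict(),
        "actual_size_min_cm": float(records["actual_size_cm"].min()),
        "actual_size_max_cm": float(records["actual_size_cm"].max()),
        "max_abs_size_error_cm": float(size_err.max()),
        "n_missing_depth": int(records["depth_mri_cm"].isna().sum()),
        "statistics_over": "tumor rows (patient linkage not recorded)",
    }


@dataclass
class ValidationReport:
    """Scored synthetic validation batch.

    Size/location errors are computed for every tumor-bearing case from
    the fitted parameters, whether or not the case was called present;
    sensitivity and specificity are percentages (None when the relevant
    class is empty).
    """

    cases: pd.DataFrame
    sensitivity: float | None
    specificity: float | None
    max_size_error_mm: float | None
    mean_size_error_mm: float | None
    max_location_error_mm: float | None
    mean_location_error_mm: float | None

    def to_dict(self) -> dict:
        return {
            "n_cases": int(len(self.cases)),
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "max_size_error_mm": self.max_size_error_mm,
            "mean_size_error_mm": self.mean_size_error_mm,
            "max_location_error_mm": self.max_location_error_mm,
            "mean_location_error_mm": self.mean_location_error_mm,
        }


def score_validation(batch) -> ValidationReport:
    """Score a batch of ``(truth, InverseResult)`` pairs.

    ``truth`` is the generating :class:`TumorParams` or ``None`` for a
    tumor-free case.  Size error is ``|D_true - D_hat|``; location error
    the Euclidean distance between true and fitted centers.  Aggregates
    are permutation-invariant.
    """
    batch = list(batch)
    if not batch:
        raise ValueError("empty validation batch")
    rows = []
    for truth, result in batch:
        if not isinstance(result, InverseResult):
            raise TypeError("batch entries must be (truth, InverseResult)")
        th = result.theta_hat
        row = {
            "true_present": truth is not None,
            "detected": bool(result.detected),
            "decision_reason": result.decision_reason,
            "d_hat_mm": th.diameter * 1e3,
        }
        if truth is not None:
            row["d_true_mm"] = truth.diameter * 1e3
            row["size_error_mm"] = abs(truth.diameter - th.diameter) * 1e3
            row["location_error_mm"] = (
                float(np.linalg.norm(np.subtract(truth.center, th.center))) * 1e3
            )
        rows.append(row)
    cases = pd.DataFrame(rows)
    present = cases[cases["true_present"]]
    absent = cases[~cases["true_present"]]
    sens = 100.0 * present["detected"].mean() if len(present) else None
    spec = 100.0 * (~absent["detected"]).mean() if len(absent) else None
    return ValidationReport(
        cases=cases,
        sensitivity=None if sens is None else float(sens),
        specificity=None if spec is None else float(spec),
        max_size_error_mm=float(present["size_error_mm"].max()) if len(present) else None,
        mean_size_error_mm=float(present["size_error_mm"].mean()) if len(present) else None,
        max_location_error_mm=(
            float(present["location_error_mm"].max()) if len(present) else None
        ),
        mean_location_error_mm=(
            float(present["location_error_mm"].mean()) if len(present) else None
        ),
    )
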