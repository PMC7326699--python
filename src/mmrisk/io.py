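"""Reading and writing cohort fixtures, signatures and predictions.

On-disk layout per cohort (all plain text, times in months):

* ``<id>_expression.tsv`` — tab-delimited, first column ``gene_id``, one
  column per patient, header row of patient ids.
* ``<id>_clinical.csv`` — columns patient_id, age, iss, sex, t414.
* ``<id>_survival.csv`` — columns patient_id, pfs_months, pfs_event,
  os_months, os_event.
* ``manifest.json`` — file list plus the generating SimulationConfig, if any.

Signature files are delimited text with columns (gene_id, direction, weight);
prediction files are comma-delimited (model_id, cohort_id, patient_id, score,
optional binary_call).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DuplicatePatientError,
    InvalidISSError,
    MissingColumnError,
    NegativeTimeError,
    NonNumericExpressionError,
    PatientMismatchError,
)
from .simulate import (
    CLINICAL_COLUMNS,
    SURVIVAL_COLUMNS,
    Cohort,
    SimulationConfig,
)

__all__ = [
    "read_cohort",
    "write_cohort",
    "write_fixture",
    "read_fixture",
    "read_signature_file",
    "read_predictions",
    "write_predictions",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"
MANIFEST_NAME = "manifest.json"


def _check_unique(ids, what: str, where: str) -> None:
    seen: set = set()
    dups = {i for i in ids if i in seen or seen.add(i)}
    if dups:
        raise DuplicatePatientError(
            f"duplicate {what} in {where}: {sorted(map(str, dups))[:5]}"
        )


def _read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise MissingColumnError(f"{path}: expression needs a gene id column "
                                 "plus at least one patient column")
    gene_col = df.columns[0]
    genes = df[gene_col].tolist()
    patients = list(df.columns[1:])
    _check_unique(patients, "patient id", str(path))
    _check_unique(genes, "gene id", str(path))
    raw = df.drop(columns=[gene_col])
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise NonNumericExpressionError(
            f"{path}: non-numeric expression value {raw.iat[r, c]!r} "
            f"for gene {genes[r]!r}, patient {patients[c]!r}"
        )
    if values.isna().to_numpy().any():
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise NonNumericExpressionError(
            f"{path}: empty expression cell for gene {genes[r]!r}, "
            f"patient {patients[c]!r}"
        )
    out = values.astype(float)
    out.index = pd.Index(genes, name="gene_id")
    out.columns = patients
    return out


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing column(s) {missing}")


def _read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("patient_id", *CLINICAL_COLUMNS), path)
    _check_unique(df["patient_id"].tolist(), "patient id", str(path))
    iss = pd.to_numeric(df["iss"], errors="coerce")
    bad_iss = ~iss.isin([1, 2, 3])
    if bad_iss.any():
        val = df.loc[bad_iss.idxmax(), "iss"]
        raise InvalidISSError(f"{path}: field 'iss' has value {val!r}, "
                              "expected one of {1, 2, 3}")
    out = df.set_index("patient_id")[list(CLINICAL_COLUMNS)].copy()
    out["age"] = pd.to_numeric(out["age"])
    out["iss"] = iss.to_numpy().astype(int)
    out["t414"] = (
        out["t414"].astype(str).str.strip().str.lower()
        .map({"true": True, "false": False, "1": True, "0": False})
    )
    if out["t414"].isna().any():
        raise MissingColumnError(f"{path}: field 't414' must be boolean (0/1)")
    return out


def _read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("patient_id", *SURVIVAL_COLUMNS), path)
    _check_unique(df["patient_id"].tolist(), "patient id", str(path))
    out = df.set_index("patient_id")[list(SURVIVAL_COLUMNS)].copy()
    for col in ("pfs_months", "os_months"):
        out[col] = pd.to_numeric(out[col])
        if (out[col] < 0).any():
            pid = out.index[out[col] < 0][0]
            raise NegativeTimeError(
                f"{path}: negative {col} for patient {pid!r}"
            )
    for col in ("pfs_event", "os_event"):
        ev = pd.to_numeric(out[col])
        if not ev.isin([0, 1]).all():
            raise MissingColumnError(f"{path}: field {col!r} must be 0/1")
        out[col] = ev.astype(int)
    return out


def read_cohort(
    expression_path: str | Path,
    clinical_path: str | Path,
    survival_path: str | Path,
    cohort_id: str | None = None,
) -> Cohort:
    """Read and cross-validate one cohort from its three files.

    Patients must agree exactly across the three files; mismatches are
    reported by id.  Column order follows the expression matrix.
    """
    expression = _read_expression(expression_path)
    clinical = _read_clinical(clinical_path)
    survival = _read_survival(survival_path)

    pids = list(expression.columns)
    for name, idx in (("clinical", clinical.index), ("survival", survival.index)):
        missing = sorted(set(pids) - set(idx))
        extra = sorted(set(idx) - set(pids))
        if missing or extra:
            raise PatientMismatchError(
                f"{name} table disagrees with expression: "
                f"missing {missing[:5]}, unexpected {extra[:5]}"
            )
    clinical = clinical.loc[pids]
    survival = survival.loc[pids]
    if cohort_id is None:
        cohort_id = Path(expression_path).stem.replace("_expression", "")
    cohort = Cohort(cohort_id, expression, clinical, survival)
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, str]:
    """Write one cohort's three files; returns relative file names."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = {
        "expression": f"{cohort.cohort_id}_expression.tsv",
        "clinical": f"{cohort.cohort_id}_clinical.csv",
        "survival": f"{cohort.cohort_id}_survival.csv",
    }
    cohort.expression.to_csv(directory / names["expression"], sep="\t",
                             float_format=_FLOAT_FMT)
    clin = cohort.clinical.copy()
    clin["t414"] = clin["t414"].astype(bool).astype(int)
    clin.to_csv(directory / names["clinical"], float_format=_FLOAT_FMT)
    cohort.survival.to_csv(directory / names["survival"], float_format=_FLOAT_FMT)
    return names


def write_fixture(
    cohorts: list[Cohort],
    directory: str | Path,
    config: SimulationConfig | None = None,
    overwrite: bool = False,
) -> dict:
    """Write cohorts plus a JSON manifest; refuses to clobber an existing
    manifest unless ``overwrite`` is set."""
    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} exists; pass overwrite=True to replace it"
        )
    entries = []
    for cohort in cohorts:
        names = write_cohort(cohort, directory)
        entries.append({"cohort_id": cohort.cohort_id, **names})
    manifest = {
        "cohorts": entries,
        "config": config.to_dict() if config is not None else None,
    }
    directory.mkdir(parents=True, exist_ok=True)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def read_fixture(directory: str | Path) -> tuple[list[Cohort], SimulationConfig | None]:
    """Read every cohort listed in a fixture manifest."""
    directory = Path(directory)
    with open(directory / MANIFEST_NAME) as fh:
        manifest = json.load(fh)
    cohorts = [
        read_cohort(
            directory / entry["expression"],
            directory / entry["clinical"],
            directory / entry["survival"],
            cohort_id=entry["cohort_id"],
        )
        for entry in manifest["cohorts"]
    ]
    config = manifest.get("config")
    return cohorts, SimulationConfig.from_dict(config) if config else None


def read_signature_file(path: str | Path, name: str | None = None):
    """Read a signature definition: columns gene_id, direction in {up, down},
    optional weight.  Returns a :class:`~mmrisk.signatures.SignatureDefinition`."""
    from .signatures import SignatureDefinition

    df = pd.read_csv(path, sep=None, engine="python")
    _require_columns(df, ("gene_id", "direction"), path)
    direction = df["direction"].astype(str).str.strip().str.lower()
    if not direction.isin(["up", "down"]).all():
        raise MissingColumnError(f"{path}: direction must be 'up' or 'down'")
    up = df.loc[direction == "up", "gene_id"].astype(str).tolist()
    down = df.loc[direction == "down", "gene_id"].astype(str).tolist()
    weights = None
    rule = "mean_difference"
    if "weight" in df.columns and df["weight"].notna().any():
        weights = dict(zip(df["gene_id"].astype(str), pd.to_numeric(df["weight"])))
        rule = "weighted_sum"
    return SignatureDefinition(
        name=name or Path(path).stem, up_genes=up, down_genes=down,
        weights=weights, rule=rule,
    )


def read_predictions(path: str | Path):
    """Read a prediction table into RiskPrediction objects, one per
    (model_id, cohort_id) pair."""
    from .evaluate import RiskPrediction

    df = pd.read_csv(path)
    _require_columns(df, ("model_id", "cohort_id", "patient_id", "score"), path)
    out = []
    for (model_id, cohort_id), grp in df.groupby(["model_id", "cohort_id"], sort=True):
        _check_unique(grp["patient_id"].tolist(), "patient id", str(path))
        scores = pd.Series(
            pd.to_numeric(grp["score"]).to_numpy(),
            index=grp["patient_id"].astype(str).to_numpy(),
        )
        calls = None
        if "binary_call" in grp.columns and grp["binary_call"].notna().all():
            calls = pd.Series(
                pd.to_numeric(grp["binary_call"]).astype(int).to_numpy(),
                index=scores.index,
            )
        out.append(RiskPrediction(str(model_id), str(cohort_id), scores, calls))
    return out


def write_predictions(predictions, path: str | Path) -> None:
    rows = []
    for pred in predictions:
        for pid, score in pred.scores.items():
            row = {
                "model_id": pred.model_id,
                "cohort_id": pred.cohort_id,
                "patient_id": pid,
                "score": score,
            }
            if pred.binary_calls is not None:
                row["binary_call"] = int(pred.binary_calls.loc[pid])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
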