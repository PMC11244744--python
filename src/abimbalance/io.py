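"""Cohort table readers/writers and machine-readable run logs.

Tables are plain CSV/TSV with a documented column dictionary; missing values
are empty cells.  Run logs are JSON and record the seed, a configuration
hash, and the software version, so every output file can be traced to the
exact invocation that produced it (no timestamps: identical invocations
produce identical bytes).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

__all__ = ["COLUMN_DICTIONARY", "read_cohort", "read_visits", "write_table", "write_run_log"]

#: column -> (kind, allowed codes or None, unit/notes)
COLUMN_DICTIONARY = {
    "subject_id": ("id", None, "unique subject identifier"),
    "visit": ("str", None, "visit label; 'baseline' expected by reference criteria"),
    "age": ("num", None, "years"),
    "sex": ("cat", {"F", "M"}, "biological sex"),
    "education_years": ("num", None, "years"),
    "apoe_e4_copies": ("cat", {0, 1, 2}, "APOE-e4 allele count"),
    "diagnosis": ("cat", {"CU", "CI"}, "cognitive status"),
    "cdr": ("num", None, "Clinical Dementia Rating"),
    "mmse": ("num", None, "Mini-Mental State Examination, 0-30"),
    "centiloid": ("num", None, "global amyloid-PET burden, Centiloid"),
    "suvr": ("num", None, "standardized uptake value ratio"),
    "pet_tracer": ("str", None, "tracer label for Centiloid calibration"),
    "csf_kit": ("str", None, "CSF assay kit label"),
    "csf_ab42": ("num", None, "CSF amyloid-beta 42, pg/mL or z"),
    "csf_ab40": ("num", None, "CSF amyloid-beta 40, pg/mL"),
    "csf_ab38": ("num", None, "CSF amyloid-beta 38, pg/mL"),
    "csf_ptau": ("num", None, "CSF phosphorylated tau, pg/mL"),
    "csf_ttau": ("num", None, "CSF total tau, pg/mL"),
    "icv_mm3": ("num", None, "total intracranial volume, mm^3"),
    "ventricle_volume_mm3": ("num", None, "ventricular volume, mm^3"),
    "ventricular_volume": ("num", None, "ventricle/ICV ratio, dimensionless"),
    "wmh_volume_mm3": ("num", None, "white-matter hyperintensity volume, mm^3"),
    "fazekas": ("cat", {0, 1, 2, 3}, "Fazekas visual rating"),
    "csf_pet_interval_days": ("num", None, "days between CSF and PET"),
    "aggregation": ("num", None, "standardized aggregation score"),
    "severity": ("num", None, "standardized severity score"),
}

MANDATORY_COLUMNS = ("subject_id", "centiloid", "csf_ab42")


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_cohort(path, column_dictionary: dict | None = None, mandatory=MANDATORY_COLUMNS):
    """Read and validate a cohort table (CSV or TSV, header row required).

    Raises ``ValueError`` naming the offending row and column for unknown
    categorical codes or non-numeric cells; returns ``(table, summary)``
    where ``summary`` reports row counts and per-column missingness.
    """
    coldict = dict(COLUMN_DICTIONARY)
    if column_dictionary:
        coldict.update(column_dictionary)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    df = df.replace({"": np.nan})
    missing_cols = [c for c in mandatory if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing mandatory column(s) {missing_cols}")

    out = {}
    for col in df.columns:
        kind, codes, _ = coldict.get(col, ("str", None, ""))
        vals = df[col]
        if kind == "num" or (kind == "cat" and codes and all(isinstance(c, int) for c in codes)):
            num = pd.to_numeric(vals, errors="coerce")
            bad = num.isna() & vals.notna()
            if bad.any():
                row = int(bad.idxmax())
                raise ValueError(
                    f"{path}: non-numeric value {vals[row]!r} in column {col!r}, row {row}"
                )
            if kind == "cat":
                ok = num.isna() | num.isin(list(codes))
                if not ok.all():
                    row = int((~ok).idxmax())
                    raise ValueError(
                        f"{path}: unknown code {vals[row]!r} in column {col!r}, row {row} "
                        f"(allowed: {sorted(codes)})"
                    )
            out[col] = num
        elif kind == "cat":
            ok = vals.isna() | vals.isin(list(codes))
            if not ok.all():
                row = int((~ok).idxmax())
                raise ValueError(
                    f"{path}: unknown code {vals[row]!r} in column {col!r}, row {row} "
                    f"(allowed: {sorted(codes)})"
                )
            out[col] = vals
        else:
            out[col] = vals
    table = pd.DataFrame(out)
    summary = {
        "path": str(path),
        "n_rows": int(len(table)),
        "missing_per_column": {c: int(table[c].isna().sum()) for c in table.columns},
    }
    return table, summary


def read_visits(path):
    """Read a longitudinal (subject, test, time, score) visit table."""
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"subject_id", "test", "time_years", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: visit table missing columns {sorted(missing)}")
    if (df["time_years"] < 0).any():
        raise ValueError(f"{path}: negative visit times")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), index=False)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_run_log(path, config: dict, seed: int, outputs: list[str]) -> None:
    log = {
        "software": {"package": "abimbalance", "version": __version__},
        "seed": int(seed),
        "config_hash": config_hash(config),
        "config": config,
        "outputs": list(outputs),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
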