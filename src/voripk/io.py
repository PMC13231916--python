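"""Dataset readers/writers and run manifests.

The interchange dialect is the NONMEM-style long format: one row per
event, columns ID, TIME, AMT, RATE, EVID, DV, MDV plus the optional
covariate columns BLQ, WT, GENO.  Dose rows (EVID=1) carry AMT (mg) and
RATE (mg/h; infusion duration = AMT/RATE); observation rows (EVID=0)
carry DV (mg/L) unless MDV=1.
"""

from __future__ import annotations

import json
import platform
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .population import GENOTYPE_CLASSES
from .study import RECORD_COLUMNS, StudyDataset

__all__ = ["read_dataset", "write_dataset", "write_truth", "run_manifest"]

REQUIRED_COLUMNS = ("ID", "TIME", "AMT", "RATE", "EVID", "DV", "MDV")


def read_dataset(path) -> StudyDataset:
    """Read a NONMEM-style CSV into a :class:`StudyDataset`.

    Validates the column set, EVID/MDV semantics, non-negative times and
    genotype levels.  DV values on MDV=1 rows are ignored (with a skip
    report); observations before a subject's first dose are kept but
    warned about.
    """
    rec = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in rec.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if (rec["TIME"] < 0).any():
        raise ValueError("negative TIME values")
    if "GENO" in rec.columns:
        bad = set(rec["GENO"].dropna().unique()) - set(GENOTYPE_CLASSES)
        if bad:
            raise ValueError(
                f"unparseable genotype value(s) {sorted(bad)}; valid levels: "
                f"{', '.join(GENOTYPE_CLASSES)}")

    doses = rec[rec["EVID"] == 1]
    if ((doses["RATE"] <= 0) & (doses["AMT"] > 0)).any():
        raise ValueError("dose row with RATE<=0 and AMT>0: bolus dosing is "
                         "not supported; infusions need RATE (mg/h)")

    n_skipped = int(((rec["EVID"] == 0) & (rec["MDV"] == 1)
                     & rec["DV"].notna()).sum())
    if n_skipped:
        warnings.warn(f"{n_skipped} observation row(s) have DV but MDV=1; "
                      "values ignored")

    first_dose = doses.groupby("ID")["TIME"].min()
    obs = rec[(rec["EVID"] == 0) & (rec["MDV"] == 0)]
    early = obs.join(first_dose.rename("first_dose"), on="ID")
    n_early = int((early["TIME"] < early["first_dose"]).sum())
    if n_early:
        warnings.warn(f"{n_early} observation(s) precede the subject's first "
                      "dose; kept")

    rec = rec.sort_values(["ID", "TIME", "EVID"], kind="stable",
                          ignore_index=True)
    return StudyDataset(records=rec)


def write_dataset(dataset: StudyDataset, path, truth_path=None) -> None:
    """Write the records as CSV (standard columns only, 6 significant digits).

    If ``truth_path`` is given and the dataset has a truth table, the
    per-subject true parameters are written alongside.
    """
    cols = [c for c in RECORD_COLUMNS if c in dataset.records.columns]
    dataset.records[cols].to_csv(path, index=False, float_format="%.6g")
    if truth_path is not None and dataset.truth is not None:
        write_truth(dataset, truth_path)


def write_truth(dataset: StudyDataset, path) -> None:
    if dataset.truth is None:
        raise ValueError("dataset has no truth table")
    dataset.truth.to_csv(path, index=False, float_format="%.8g")


def run_manifest(out_dir, command: str, seed, inputs: dict,
                 wall_time_s: float | None = None) -> Path:
    """Write a JSON manifest making the run regenerable."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "command": command,
        "seed": seed,
        "inputs": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in inputs.items()},
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if wall_time_s is not None:
        payload["wall_time_s"] = round(wall_time_s, 3)
    path = out_dir / f"manifest_{command}.json"
    path.write_text(json.dumps(payload, indent=2))
    return path
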