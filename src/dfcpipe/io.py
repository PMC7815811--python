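"""Plain-text readers and writers for pipeline artefacts.

Connectivity and dFC matrices travel as square CSV with a region-label
header row and column; subnetwork definitions as JSON or YAML files listing
labels per set; cohorts as a directory of per-subject TSV series and motion
tables plus one clinical CSV and a JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import SubnetworkSpec
from .core import MotionTrace, RegionTimeSeries
from .synthetic import CohortSubject, clinical_table

__all__ = [
    "write_matrix_csv",
    "read_matrix_csv",
    "write_subnetwork_spec",
    "read_subnetwork_spec",
    "write_cohort",
    "load_cohort_series",
]


def write_matrix_csv(path: str | Path, matrix: np.ndarray, labels: list[str]) -> None:
    df = pd.DataFrame(np.asarray(matrix, dtype=float), index=labels, columns=labels)
    df.to_csv(path)


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("matrix CSV must have matching row and column labels")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_subnetwork_spec(path: str | Path, spec: SubnetworkSpec) -> None:
    payload = {"set_a": list(spec.set_a), "set_b": list(spec.set_b), "mode": spec.mode}
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(payload, fh)
        else:
            json.dump(payload, fh, indent=2)


def read_subnetwork_spec(path: str | Path) -> SubnetworkSpec:
    path = Path(path)
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return SubnetworkSpec(
        set_a=tuple(payload["set_a"]),
        set_b=tuple(payload["set_b"]),
        mode=payload.get("mode", "between-sets-plus-within"),
    )


def write_cohort(out_dir: str | Path, cohort: list[CohortSubject]) -> Path:
    """Write a simulated cohort: TSV series + motion per subject, clinical CSV,
    ground-truth CSV and a JSON manifest. Returns the manifest path."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    (out / "motion").mkdir(exist_ok=True)
    entries = []
    truths = []
    for subj in cohort:
        sid = subj.timeseries.subject_id
        ts_path = out / "timeseries" / f"{sid}.tsv"
        mo_path = out / "motion" / f"{sid}_motion.tsv"
        subj.timeseries.to_tsv(ts_path)
        subj.motion.to_tsv(mo_path)
        entries.append(
            {
                "subject_id": sid,
                "timeseries": str(ts_path.relative_to(out)),
                "motion": str(mo_path.relative_to(out)),
                "tr_seconds": subj.timeseries.tr,
                "n_regions": subj.timeseries.n_regions,
                "n_volumes": subj.timeseries.n_volumes,
            }
        )
        gt = subj.ground_truth
        truths.append(
            {
                "subject_id": sid,
                "group_label": gt.group_label,
                "true_fatigue_driver": gt.true_fatigue_driver,
                "modulation_amplitude": gt.modulation_amplitude,
                "subnetwork_amplitude": gt.subnetwork_amplitude,
            }
        )
    clinical_table(cohort).to_csv(out / "clinical.csv", index=False)
    pd.DataFrame(truths).to_csv(out / "ground_truth.csv", index=False)
    manifest = out / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump({"subjects": entries, "clinical": "clinical.csv"}, fh, indent=2)
    return manifest


def load_cohort_series(cohort_dir: str | Path) -> list[tuple[RegionTimeSeries, MotionTrace]]:
    """Load every subject's series and motion trace from a cohort directory."""
    cohort_dir = Path(cohort_dir)
    with open(cohort_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    out = []
    for entry in manifest["subjects"]:
        ts = RegionTimeSeries.from_tsv(
            cohort_dir / entry["timeseries"],
            tr=entry["tr_seconds"],
            subject_id=entry["subject_id"],
        )
        mo = MotionTrace.from_tsv(cohort_dir / entry["motion"], entry["subject_id"])
        out.append((ts, mo))
    return out
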