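"""On-disk layout for cohorts, reports, and perturbed label tables.

A cohort directory holds ``features.h5`` (one dataset per slide plus its
witness mask), ``labels.csv`` (slide_id, patient_id, source, label columns),
and ``config.yaml``. Reports are JSON-lines; perturbed tables re-serialize in
the labels.csv layout plus a sidecar JSON with the changed slides, noise
fraction, seed, and label quality.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .labels import LabelTable
from .noise import PerturbationResult
from .synthgen import Cohort, CohortConfig, InstanceBag, ReportRecord


def save_cohort(cohort: Cohort, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with h5py.File(directory / "features.h5", "w") as fh:
        for bag in cohort.bags:
            grp = fh.create_group(bag.slide_id)
            grp.create_dataset("features", data=bag.features)
            grp.create_dataset("witness_mask", data=bag.witness_mask)
            grp.attrs["patient_id"] = bag.patient_id
            grp.attrs["source"] = bag.source
    patients = {b.slide_id: b.patient_id for b in cohort.bags}
    sources = {b.slide_id: b.source for b in cohort.bags}
    frame = cohort.labels.to_frame(
        patient_ids=[patients[s] for s in cohort.labels.slide_ids],
        sources=[sources[s] for s in cohort.labels.slide_ids],
    )
    frame.to_csv(directory / "labels.csv", index=False)
    cfg = dataclasses.asdict(cohort.config)
    cfg["class_names"] = list(cfg["class_names"])
    cfg["n_instances_range"] = list(cfg["n_instances_range"])
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    return directory


def load_cohort(directory) -> Cohort:
    directory = Path(directory)
    config = CohortConfig.from_yaml(directory / "config.yaml")
    frame = pd.read_csv(directory / "labels.csv")
    labels = LabelTable.from_frame(frame, config.scheme, config.class_names)
    bags = []
    with h5py.File(directory / "features.h5", "r") as fh:
        for slide_id in labels.slide_ids:
            grp = fh[slide_id]
            bags.append(
                InstanceBag(
                    slide_id=slide_id,
                    patient_id=grp.attrs["patient_id"],
                    source=grp.attrs["source"],
                    features=grp["features"][...],
                    witness_mask=grp["witness_mask"][...],
                )
            )
    return Cohort(bags=bags, labels=labels, config=config)


def save_reports(records, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            row = dataclasses.asdict(rec)
            if isinstance(row["truth_concepts"], np.ndarray):
                row["truth_concepts"] = row["truth_concepts"].tolist()
            fh.write(json.dumps(row) + "\n")
    return path


def load_reports(path):
    records = []
    with open(path) as fh:
        for line in fh:
            row = json.loads(line)
            truth = row["truth_concepts"]
            if isinstance(truth, list):
                truth = np.asarray(truth, dtype=np.int64)
            records.append(
                ReportRecord(
                    report_id=row["report_id"],
                    slide_id=row["slide_id"],
                    source=row["source"],
                    text=row["text"],
                    truth_concepts=truth,
                    is_wordy=bool(row["is_wordy"]),
                )
            )
    return records


def save_perturbation(result: PerturbationResult, spec, directory, stem: str) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    result.perturbed.to_frame().to_csv(directory / f"{stem}.csv", index=False)
    sidecar = {
        "changed_ids": sorted(result.changed_ids),
        "p": spec.p,
        "seed": spec.seed,
        "quality_f1": result.quality_f1,
    }
    with open(directory / f"{stem}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return directory / f"{stem}.csv"
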