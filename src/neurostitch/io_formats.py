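"""Plain-text I/O: time-series tables, phenotype tables, manifests, reports.

Time-series are stored one subject per delimited text file (TSV by
default), rows in temporal order; phenotypes as CSV with columns
``subject_id``, ``site``, ``label``; datasets as a directory of
time-series files plus a JSON manifest carrying per-file SHA-256
checksums that are verified on load; metric reports as JSON; configs as
YAML.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import RoiTimeSeries, TaskDataset


class FormatError(ValueError):
    """Malformed input file; message carries the offending line where known."""


# -- time-series tables ------------------------------------------------


def read_timeseries_table(path, delimiter: str = "\t") -> np.ndarray:
    """Parse a delimited numeric table into a T x N float matrix.

    Rows are time nodes in temporal order. Ragged rows, non-numeric cells
    and empty files raise :class:`FormatError` naming the 1-based line.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split(delimiter)
            try:
                row = [float(c) for c in cells]
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell on line {lineno}"
                ) from None
            if not all(math.isfinite(x) for x in row):
                raise FormatError(f"{path}: non-finite value on line {lineno}")
            if rows and len(row) != len(rows[0]):
                raise FormatError(
                    f"{path}: line {lineno} has {len(row)} columns, expected {len(rows[0])}"
                )
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: empty time-series file")
    return np.array(rows, dtype=float)


def write_timeseries_table(matrix: np.ndarray, path, delimiter: str = "\t") -> None:
    """Write a T x N matrix; %.17g preserves doubles across a round-trip."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError(f"matrix must be 2-D, got shape {matrix.shape}")
    np.savetxt(path, matrix, fmt="%.17g", delimiter=delimiter)


# -- phenotype tables --------------------------------------------------

PHENOTYPE_COLUMNS = ("subject_id", "site", "label")


def read_phenotype(path) -> list[tuple[str, str, int]]:
    """Read (subject_id, site, label) records from a CSV with a header row."""
    df = pd.read_csv(path, dtype={"subject_id": str, "site": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing phenotype column(s) {missing}")
    dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].unique().tolist()
    if dupes:
        raise FormatError(f"{path}: duplicated subject_id(s) {dupes}")
    labels = pd.to_numeric(df["label"], errors="coerce")
    bad = df.loc[~labels.isin([0, 1]), "label"].tolist()
    if bad:
        raise FormatError(f"{path}: labels outside {{0, 1}}: {bad}")
    return list(
        zip(df["subject_id"], df["site"], labels.astype(int), strict=True)
    )


def write_phenotype(records, path) -> None:
    pd.DataFrame(records, columns=list(PHENOTYPE_COLUMNS)).to_csv(path, index=False)


# -- length harmonization ----------------------------------------------


def harmonize_length(dataset: TaskDataset, target_T: int) -> TaskDataset:
    """Force every series to exactly ``target_T`` rows.

    Longer series are truncated from the end; shorter ones zero-padded at
    the end. Modified samples carry ``harmonized=True``.
    """
    if target_T < 2:
        raise ValueError(f"target_T must be >= 2, got {target_T}")
    out = []
    for s in dataset.samples:
        t = s.matrix.shape[0]
        if t == target_T:
            out.append(s)
            continue
        if t > target_T:
            mat = s.matrix[:target_T].copy()
        else:
            mat = np.zeros((target_T, s.matrix.shape[1]))
            mat[:t] = s.matrix
        out.append(
            RoiTimeSeries(s.subject_id, s.task_index, mat, s.label, harmonized=True)
        )
    return TaskDataset(task_index=dataset.task_index, samples=out, name=dataset.name)


# -- dataset directories with checksummed manifests --------------------


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_dataset(dataset: TaskDataset, outdir) -> Path:
    """Write one task's dataset: per-subject TSVs, phenotype CSV, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    files = {}
    for s in dataset.samples:
        fname = f"{s.subject_id}.tsv"
        write_timeseries_table(s.matrix, outdir / fname)
        files[fname] = _sha256(outdir / fname)
        records.append((s.subject_id, dataset.name or str(dataset.task_index), s.label))
    write_phenotype(records, outdir / "phenotype.csv")
    files["phenotype.csv"] = _sha256(outdir / "phenotype.csv")
    manifest = {
        "task_index": dataset.task_index,
        "name": dataset.name,
        "n_samples": len(dataset),
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir / "manifest.json"


def load_dataset(indir) -> TaskDataset:
    """Load a dataset directory, verifying every file's checksum."""
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    for fname, digest in manifest["files"].items():
        fpath = indir / fname
        if not fpath.exists():
            raise FormatError(f"{indir}: manifest lists missing file {fname}")
        actual = _sha256(fpath)
        if actual != digest:
            raise FormatError(
                f"{indir}/{fname}: checksum mismatch (expected {digest[:12]}..., "
                f"got {actual[:12]}...)"
            )
    records = read_phenotype(indir / "phenotype.csv")
    samples = [
        RoiTimeSeries(
            subject_id=sid,
            task_index=manifest["task_index"],
            matrix=read_timeseries_table(indir / f"{sid}.tsv"),
            label=label,
        )
        for sid, _site, label in records
    ]
    return TaskDataset(
        task_index=manifest["task_index"], samples=samples, name=manifest["name"]
    )


def write_datasets(datasets: list[TaskDataset], outdir) -> Path:
    """Write several task datasets under ``outdir/task{d}`` + a top index."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index = {"tasks": []}
    for ds in datasets:
        sub = f"task{ds.task_index}"
        write_dataset(ds, outdir / sub)
        index["tasks"].append({"task_index": ds.task_index, "name": ds.name, "dir": sub})
    with open(outdir / "datasets.json", "w") as fh:
        json.dump(index, fh, indent=2, sort_keys=True)
    return outdir / "datasets.json"


def load_datasets(indir) -> list[TaskDataset]:
    indir = Path(indir)
    with open(indir / "datasets.json") as fh:
        index = json.load(fh)
    return [load_dataset(indir / entry["dir"]) for entry in index["tasks"]]


# -- reports and configs ------------------------------------------------


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping, got {type(cfg).__name__}")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
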