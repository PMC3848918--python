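"""Hierarchical data store: projects > experiments > measurements.

Mirrors the three-layer organization of growth-curve studies: a *project*
holds global context, an *experiment* groups related measurements (e.g.
replicates of one condition) together with the fit results attached to them,
and a *measurement* is one annotated time series.  Measurements may carry a
third numeric column and a free-text annotation; modeling consumes only
(time, value) — the extra dimensions are stored verbatim, never interpreted.

Persistence is plain files: CSV for measurement data, JSON for metadata and
fit results, a directory per project/experiment.  Round-trips are lossless —
floats are written with ``repr`` so re-import reproduces every bit.
"""

from __future__ import annotations

import csv
import json
import re
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import CsvImportError, RepositoryError, TimeSeries, ValidationError
from .estimation import GrowthCurveResults

_ID_RE = re.compile(r"^[A-Za-z0-9][A-Za-z0-9_.-]*$")


def _check_id(kind: str, value: str) -> str:
    if not _ID_RE.match(value or ""):
        raise ValidationError(
            f"{kind} id {value!r} must match [A-Za-z0-9][A-Za-z0-9_.-]* "
            f"(it becomes a file name)"
        )
    return value


@dataclass(frozen=True)
class MeasurementRow:
    time: float
    value: float
    extra: float | None = None
    annotation: str | None = None


@dataclass(frozen=True)
class Measurement:
    """One annotated time series; times strictly increasing, values finite."""

    measurement_id: str
    name: str
    rows: tuple

    def __post_init__(self):
        _check_id("measurement", self.measurement_id)
        rows = tuple(self.rows)
        times = np.array([r.time for r in rows], dtype=float)
        values = np.array([r.value for r in rows], dtype=float)
        if times.size == 0:
            raise ValidationError("measurement needs at least one row")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(values)):
            raise ValidationError("measurement times/values must be finite")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValidationError(
                "measurement times must be strictly increasing and unique"
            )
        object.__setattr__(self, "rows", rows)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.rows], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([r.value for r in self.rows], dtype=float)

    def to_timeseries(self) -> TimeSeries:
        """The (time, value) view that all modeling operates on."""
        return TimeSeries(self.times, self.values, name=self.name)

    @classmethod
    def from_timeseries(cls, ts: TimeSeries, measurement_id: str,
                        name: str | None = None) -> "Measurement":
        rows = tuple(MeasurementRow(float(t), float(v))
                     for t, v in zip(ts.times, ts.values))
        return cls(measurement_id, ts.name if name is None else name, rows)


@dataclass
class Experiment:
    """Folder of measurements plus fit results keyed by (measurement set, model)."""

    experiment_id: str
    name: str
    measurements: list = field(default_factory=list)
    fit_results: dict = field(default_factory=dict)

    def __post_init__(self):
        _check_id("experiment", self.experiment_id)
        ids = [m.measurement_id for m in self.measurements]
        if len(set(ids)) != len(ids):
            raise ValidationError("measurement ids must be unique in an experiment")

    def add_measurement(self, m: Measurement) -> "Experiment":
        if any(x.measurement_id == m.measurement_id for x in self.measurements):
            raise ValidationError(
                f"measurement id {m.measurement_id!r} already in experiment"
            )
        self.measurements.append(m)
        return self

    def get_measurement(self, measurement_id: str) -> Measurement:
        for m in self.measurements:
            if m.measurement_id == measurement_id:
                return m
        raise KeyError(measurement_id)

    def attach_result(self, measurement_ids: Sequence[str], model_id: str,
                      result: GrowthCurveResults) -> None:
        key = (tuple(measurement_ids), model_id)
        for mid in key[0]:
            self.get_measurement(mid)  # must exist
        self.fit_results[key] = result

    def results_for_model(self, model_id: str) -> list:
        return [
            (mids, res)
            for (mids, mid_model), res in self.fit_results.items()
            if mid_model == model_id
        ]


@dataclass
class Project:
    project_id: str
    name: str
    description: str = ""
    experiments: list = field(default_factory=list)

    def __post_init__(self):
        _check_id("project", self.project_id)
        ids = [e.experiment_id for e in self.experiments]
        if len(set(ids)) != len(ids):
            raise ValidationError("experiment ids must be unique in a project")

    def add_experiment(self, e: Experiment) -> "Project":
        if any(x.experiment_id == e.experiment_id for x in self.experiments):
            raise ValidationError(
                f"experiment id {e.experiment_id!r} already in project"
            )
        self.experiments.append(e)
        return self

    def get_experiment(self, experiment_id: str) -> Experiment:
        for e in self.experiments:
            if e.experiment_id == experiment_id:
                return e
        raise KeyError(experiment_id)


@dataclass
class Repository:
    projects: list = field(default_factory=list)
    root: Path | None = field(default=None, compare=False)

    def add_project(self, p: Project) -> "Repository":
        if any(x.project_id == p.project_id for x in self.projects):
            raise ValidationError(f"project id {p.project_id!r} already present")
        self.projects.append(p)
        return self

    def get_project(self, project_id: str) -> Project:
        for p in self.projects:
            if p.project_id == project_id:
                return p
        raise KeyError(project_id)


# ---------------------------------------------------------------------------
# Measurement CSV I/O
# ---------------------------------------------------------------------------

_DELIMITERS = (",", ";", "\t")


def _sniff_delimiter(line: str) -> str:
    counts = {d: line.count(d) for d in _DELIMITERS}
    best = max(_DELIMITERS, key=lambda d: counts[d])
    return best if counts[best] > 0 else ","


def _try_float(cell: str) -> float | None:
    try:
        return float(cell)
    except (TypeError, ValueError):
        return None


def import_measurement_csv(path, *, measurement_id: str | None = None,
                           name: str | None = None,
                           delimiter: str | None = None) -> Measurement:
    """Read a measurement from CSV: time,value[,extra][,annotation].

    The decimal separator is "."; the delimiter is auto-detected among
    comma, semicolon and tab.  A single leading header line is detected (its
    first two cells do not parse as numbers) and skipped.  Rows are sorted by
    time; duplicate times are an error — replicates belong in separate
    measurements.  Unparseable rows raise CsvImportError with the 1-based
    line number.
    """
    path = Path(path)
    raw_lines = path.read_text().splitlines()
    lines = [(i + 1, ln) for i, ln in enumerate(raw_lines) if ln.strip()]
    if not lines:
        raise CsvImportError(f"{path}: file is empty")
    if delimiter is None:
        delimiter = _sniff_delimiter(lines[0][1])

    parsed: list[MeasurementRow] = []
    for pos, (lineno, line) in enumerate(lines):
        cells = next(csv.reader([line], delimiter=delimiter))
        cells = [c.strip() for c in cells]
        if len(cells) < 2:
            raise CsvImportError(
                f"{path}: line {lineno}: need at least 2 columns, got {len(cells)}"
            )
        t, v = _try_float(cells[0]), _try_float(cells[1])
        if t is None or v is None:
            if pos == 0:  # header line
                continue
            raise CsvImportError(
                f"{path}: line {lineno}: cannot parse {line!r} as numbers"
            )
        extra = None
        annotation = None
        rest = [c for c in cells[2:]]
        if rest:
            maybe = _try_float(rest[0])
            if maybe is not None:
                extra = maybe
                rest = rest[1:]
            if rest:
                annotation = delimiter.join(rest) or None
        parsed.append(MeasurementRow(t, v, extra, annotation))

    if not parsed:
        raise CsvImportError(f"{path}: no data rows")
    parsed.sort(key=lambda r: r.time)
    times = [r.time for r in parsed]
    dupes = {t for i, t in enumerate(times[1:]) if t == times[i]}
    if dupes:
        raise CsvImportError(
            f"{path}: duplicate time points {sorted(dupes)}; store replicates "
            f"as separate measurements"
        )
    mid = measurement_id if measurement_id is not None else path.stem
    return Measurement(mid, name if name is not None else path.stem, tuple(parsed))


def export_measurement_csv(measurement: Measurement, path) -> int:
    """Write a measurement back to CSV with full float precision."""
    path = Path(path)
    has_extra = any(r.extra is not None for r in measurement.rows)
    has_annot = any(r.annotation is not None for r in measurement.rows)
    header = ["time", "value"] + (["extra"] if has_extra else []) \
        + (["annotation"] if has_annot else [])
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in measurement.rows:
            row = [repr(r.time), repr(r.value)]
            if has_extra:
                row.append("" if r.extra is None else repr(r.extra))
            if has_annot:
                row.append("" if r.annotation is None else r.annotation)
            writer.writerow(row)
    return len(measurement.rows)


def export_results_csv(experiment: Experiment, model_id: str, path,
                       registry=None) -> int:
    """Write one CSV row per fit of ``model_id`` attached to the experiment.

    Header: measurement,<param1>,...,<paramK>,rmse,converged,n_points with
    parameters in the model's declared order.  Floats use ``repr`` so
    re-import reproduces the values exactly.  Returns the number of data
    rows written (0 gives a header-only file).
    """
    from .registry import get_default_registry

    reg = registry if registry is not None else get_default_registry()
    param_names = list(reg.get(model_id).param_names)
    results = experiment.results_for_model(model_id)
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["measurement", *param_names, "rmse", "converged",
                         "n_points"])
        for mids, res in results:
            names = [experiment.get_measurement(m).name for m in mids]
            writer.writerow(
                ["+".join(names)]
                + [repr(float(res.estimates[p])) for p in param_names]
                + [repr(float(res.rmse)), str(bool(res.converged)),
                   str(int(res.n_points))]
            )
    return len(results)


# ---------------------------------------------------------------------------
# Repository persistence
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_repository(repo: Repository, root) -> Path:
    """Serialize the repository to a directory tree (overwrites ``root``)."""
    root = Path(root)
    if root.exists():
        shutil.rmtree(root)
    root.mkdir(parents=True)
    (root / "repository.json").write_text(
        json.dumps(
            {"format": _FORMAT_VERSION,
             "projects": [p.project_id for p in repo.projects]},
            indent=2,
        )
    )
    for project in repo.projects:
        pdir = root / project.project_id
        pdir.mkdir()
        (pdir / "project.json").write_text(
            json.dumps(
                {
                    "project_id": project.project_id,
                    "name": project.name,
                    "description": project.description,
                    "experiments": [e.experiment_id for e in project.experiments],
                },
                indent=2,
            )
        )
        for exp in project.experiments:
            edir = pdir / exp.experiment_id
            (edir / "measurements").mkdir(parents=True)
            results_meta = []
            if exp.fit_results:
                (edir / "results").mkdir()
            for i, ((mids, model_id), res) in enumerate(exp.fit_results.items()):
                fname = f"fit_{i:04d}.json"
                (edir / "results" / fname).write_text(
                    json.dumps(
                        {"measurement_ids": list(mids), "model_id": model_id,
                         "result": res.to_dict()},
                        indent=2,
                    )
                )
                results_meta.append(fname)
            for m in exp.measurements:
                _save_measurement(m, edir / "measurements" / f"{m.measurement_id}.csv")
            (edir / "experiment.json").write_text(
                json.dumps(
                    {
                        "experiment_id": exp.experiment_id,
                        "name": exp.name,
                        "measurements": [
                            {"measurement_id": m.measurement_id, "name": m.name}
                            for m in exp.measurements
                        ],
                        "fit_results": results_meta,
                    },
                    indent=2,
                )
            )
    return root


def _save_measurement(m: Measurement, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "value", "extra", "annotation"])
        for r in m.rows:
            writer.writerow([
                repr(r.time),
                repr(r.value),
                "" if r.extra is None else repr(r.extra),
                "" if r.annotation is None else r.annotation,
            ])


def _load_measurement(path: Path, measurement_id: str, name: str) -> Measurement:
    if not path.exists():
        raise RepositoryError(f"missing measurement file: {path}")
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            next(reader)  # header
            for cells in reader:
                rows.append(
                    MeasurementRow(
                        float(cells[0]),
                        float(cells[1]),
                        float(cells[2]) if cells[2] != "" else None,
                        cells[3] if cells[3] != "" else None,
                    )
                )
        except (ValueError, IndexError, StopIteration) as exc:
            raise RepositoryError(f"corrupt measurement file {path}: {exc}") from exc
    return Measurement(measurement_id, name, tuple(rows))


def _load_json(path: Path) -> dict:
    if not path.exists():
        raise RepositoryError(f"missing file: {path}")
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise RepositoryError(f"corrupt file {path}: {exc}") from exc


def load_repository(root) -> Repository:
    """Load a repository tree written by :func:`save_repository`."""
    root = Path(root)
    meta = _load_json(root / "repository.json")
    repo = Repository(root=root)
    for pid in meta["projects"]:
        pmeta = _load_json(root / pid / "project.json")
        project = Project(pmeta["project_id"], pmeta["name"],
                          pmeta.get("description", ""))
        for eid in pmeta["experiments"]:
            edir = root / pid / eid
            emeta = _load_json(edir / "experiment.json")
            exp = Experiment(emeta["experiment_id"], emeta["name"])
            for entry in emeta["measurements"]:
                mid = entry["measurement_id"]
                exp.add_measurement(
                    _load_measurement(edir / "measurements" / f"{mid}.csv",
                                      mid, entry["name"])
                )
            for fname in emeta.get("fit_results", []):
                rec = _load_json(edir / "results" / fname)
                exp.fit_results[
                    (tuple(rec["measurement_ids"]), rec["model_id"])
                ] = GrowthCurveResults.from_dict(rec["result"])
            project.add_experiment(exp)
        repo.add_project(project)
    return repo
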