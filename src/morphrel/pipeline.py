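"""End-to-end run: inputs -> per-session metric table -> reliability report.

A run is described by a single YAML config (see :class:`RunConfig`): a
manifest of per-subject, per-session input files (label volumes, meshes, or
white/pial mesh pairs) and a list of measures to compute, each with its own
parameters.  The run writes, into the output directory:

* ``metrics.csv``    — one row per subject x session x metric x region
* ``icc_report.csv`` — ICC(1), CI, category and mean deviation per metric
* ``comparisons.csv``— pairwise Mann-Whitney tests across metrics' regional
  reliability distributions (when regional measures are present)
* ``exceedance.csv`` — proportion-of-regions-above-x curves per metric
* ``config.used.yaml`` — the resolved config, for provenance

Runs are deterministic given the config and seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import fractal, morphometry, reliability, spharm
from .io_formats import (
    CompletenessError,
    SessionMatrix,
    read_label_volume,
    read_mesh,
    read_region_lookup,
    mask_from_labels,
)

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["subject", "session", "metric", "region", "value"]
WHOLE = "all"


@dataclass
class InputEntry:
    subject: str
    session: str
    kind: str  # volume | mesh | mesh_pair
    path: str | None = None
    white: str | None = None
    pial: str | None = None

    def paths(self) -> list[Path]:
        raw = [self.path] if self.kind in ("volume", "mesh") else [self.white, self.pial]
        if any(p is None for p in raw):
            raise ValueError(f"{self.kind} input for {self.subject}/{self.session} is missing a path")
        return [Path(p) for p in raw]


@dataclass
class MeasureSpec:
    name: str
    kind: str  # fd | spharm_fd | gi | thickness | volume
    params: dict[str, Any] = field(default_factory=dict)


@dataclass
class RunConfig:
    inputs: list[InputEntry]
    measures: list[MeasureSpec]
    output_dir: str = "morphrel-out"
    seed: int = 0
    log_level: str = "INFO"
    skip_errors: bool = False

    def __post_init__(self) -> None:
        names = [m.name for m in self.measures]
        if len(set(names)) != len(names):
            raise ValueError("measure names must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        inputs = [InputEntry(**e) for e in raw.get("inputs", [])]
        measures = [
            MeasureSpec(name=m.pop("name"), kind=m.pop("kind"), params=m)
            for m in (dict(m) for m in raw.get("measures", []))
        ]
        return cls(
            inputs=inputs,
            measures=measures,
            output_dir=raw.get("output_dir", "morphrel-out"),
            seed=int(raw.get("seed", 0)),
            log_level=raw.get("log_level", "INFO"),
            skip_errors=bool(raw.get("skip_errors", False)),
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "output_dir": self.output_dir,
            "seed": self.seed,
            "log_level": self.log_level,
            "skip_errors": self.skip_errors,
            "inputs": [
                {k: v for k, v in vars(e).items() if v is not None} for e in self.inputs
            ],
            "measures": [
                {"name": m.name, "kind": m.kind, **m.params} for m in self.measures
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    def validate_files(self) -> None:
        missing = [
            str(p) for e in self.inputs for p in e.paths() if not p.exists()
        ]
        if missing:
            raise FileNotFoundError(f"manifest references missing files: {missing}")


_MEASURE_INPUT_KIND = {
    "fd": "volume",
    "volume": "volume",
    "spharm_fd": "mesh",
    "gi": "mesh",
    "thickness": "mesh_pair",
}


def _compute_measure(measure: MeasureSpec, entry: InputEntry) -> list[tuple[str, float]]:
    """Rows of (region, value) for one measure on one input file."""
    p = measure.params
    if measure.kind == "fd":
        vol = read_label_volume(entry.paths()[0])
        scales = tuple(p.get("scales", fractal.DEFAULT_SCALES))
        algorithm = p.get("algorithm", "dilation")
        variant = p.get("variant", "filled")
        if "lut" in p:
            lookup = read_region_lookup(p["lut"])
            table = fractal.regional_fd(vol, lookup, algorithm=algorithm, variant=variant, scales=scales)
            return [(row["name"], float(row["fd"])) for _, row in table.iterrows()]
        labels = set(p.get("labels", [])) or set(np.unique(vol.data[vol.data > 0]).tolist())
        mask = mask_from_labels(vol, labels)
        return [(WHOLE, fractal.fd(mask, algorithm=algorithm, variant=variant, scales=scales).fd)]
    if measure.kind == "volume":
        vol = read_label_volume(entry.paths()[0])
        labels = set(p.get("labels", [])) or set(np.unique(vol.data[vol.data > 0]).tolist())
        return [(WHOLE, morphometry.mask_volume(mask_from_labels(vol, labels)))]
    if measure.kind == "spharm_fd":
        mesh = read_mesh(entry.paths()[0])
        degrees = tuple(p.get("degrees", spharm.DEFAULT_DEGREES))
        return [(WHOLE, spharm.spharm_fd(mesh, degrees=degrees).fd)]
    if measure.kind == "gi":
        mesh = read_mesh(entry.paths()[0])
        res = morphometry.gyrification_index(
            mesh,
            hull_method=p.get("hull_method", "convex_hull"),
            closing_radius_mm=p.get("closing_radius_mm", morphometry.DEFAULT_CLOSING_RADIUS_MM),
        )
        return [(WHOLE, res.gi)]
    if measure.kind == "thickness":
        white = read_mesh(Path(entry.white))
        pial = read_mesh(Path(entry.pial))
        return [(WHOLE, float(morphometry.cortical_thickness(white, pial).mean()))]
    raise ValueError(f"unknown measure kind {measure.kind!r}")


@dataclass
class RunResult:
    metrics: pd.DataFrame
    icc_table: pd.DataFrame
    comparisons: pd.DataFrame
    exceedance: pd.DataFrame
    output_dir: Path


def run(config: RunConfig) -> RunResult:
    """Execute the full measure -> reliability workflow described by ``config``."""
    config.validate_files()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.used.yaml")
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    rows = []
    for measure in config.measures:
        wanted = _MEASURE_INPUT_KIND[measure.kind]
        t0 = time.perf_counter()
        for entry in config.inputs:
            if entry.kind != wanted:
                continue
            try:
                for region, value in _compute_measure(measure, entry):
                    rows.append((entry.subject, entry.session, measure.name, region, value))
            except Exception:
                logger.exception(
                    "measure %s failed on %s/%s", measure.name, entry.subject, entry.session
                )
                if not config.skip_errors:
                    raise
        logger.info(
            "measure %s (%s, params=%s): %.2f s",
            measure.name, measure.kind, measure.params, time.perf_counter() - t0,
        )
    metrics = pd.DataFrame(rows, columns=METRIC_COLUMNS).sort_values(
        ["metric", "region", "subject", "session"], kind="mergesort", ignore_index=True
    )
    metrics.to_csv(out / "metrics.csv", index=False, float_format="%.10g")

    # whole-structure ICC per metric
    matrices: list[SessionMatrix] = []
    regional_iccs: dict[str, list[float]] = {}
    for metric, sub in metrics.groupby("metric", sort=True):
        for region, reg in sub.groupby("region", sort=True):
            wide = reg.pivot(index="subject", columns="session", values="value")
            wide = wide.sort_index(axis=0).sort_index(axis=1)
            if wide.isna().any().any():
                raise CompletenessError(f"incomplete design for metric {metric!r} region {region!r}")
            m = SessionMatrix(
                values=wide.values,
                subject_ids=list(wide.index),
                session_ids=list(wide.columns),
                metric_name=metric if region == WHOLE else f"{metric}[{region}]",
            )
            if region == WHOLE:
                matrices.append(m)
            else:
                regional_iccs.setdefault(metric, []).append(
                    reliability.icc_oneway(m).icc
                )

    if not matrices:
        raise ValueError("run produced no whole-structure metrics to report on")
    report = reliability.reliability_report(matrices, regional_iccs=regional_iccs or None)

    report.table.to_csv(out / "icc_report.csv", index=False, float_format="%.10g")
    report.comparisons.to_csv(out / "comparisons.csv", index=False, float_format="%.10g")

    exc_rows = []
    for metric, iccs in sorted(regional_iccs.items()):
        x, prop = reliability.exceedance_cdf(iccs)
        for xi, pi in zip(x, prop):
            exc_rows.append((metric, xi, pi))
    exceedance = pd.DataFrame(exc_rows, columns=["metric", "icc", "proportion_at_least"])
    exceedance.to_csv(out / "exceedance.csv", index=False, float_format="%.10g")

    return RunResult(
        metrics=metrics,
        icc_table=report.table,
        comparisons=report.comparisons,
        exceedance=exceedance,
        output_dir=out,
    )


__all__ = ["RunConfig", "InputEntry", "MeasureSpec", "RunResult", "run", "METRIC_COLUMNS"]
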