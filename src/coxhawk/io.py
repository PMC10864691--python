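"""Readers and writers for event CSVs, domains, meshes, and fit reports."""

from __future__ import annotations

import json
import logging
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .fitresult import FitResult
from .hawkes import EventSeries
from .lgcp import PointPattern
from .multihawkes import MultiEventSeries
from .spde import Domain, Mesh

logger = logging.getLogger(__name__)

__all__ = [
    "read_events",
    "write_events",
    "read_domain",
    "read_covariates",
    "write_fit_report",
    "SchemaError",
]

REQUIRED = {
    "temporal": ["t"],
    "spatial": ["x", "y"],
    "spatiotemporal": ["t", "x", "y"],
    "multistream": ["t", "stream"],
}


class SchemaError(ValueError):
    pass


def read_events(path, kind: str, T: float | None = None):
    """Read an event CSV and return the validated container for ``kind``.

    kinds: temporal (column t, optional mark) -> EventSeries;
    spatial (x, y) / spatiotemporal (t, x, y) -> PointPattern;
    multistream (t, stream) -> MultiEventSeries.  Input is sorted by time
    if needed (with a log notice); NaNs and duplicate times are reported
    as errors.
    """
    if kind not in REQUIRED:
        raise ValueError(f"unknown events kind {kind!r}")
    df = pd.read_csv(path)
    for col in REQUIRED[kind]:
        if col not in df.columns:
            raise SchemaError(f"events file is missing required column {col!r}")
    use = [c for c in [*REQUIRED[kind], "mark"] if c in df.columns]
    bad = df[use].isna().any(axis=1)
    if bad.any():
        raise SchemaError(
            f"{int(bad.sum())} rows contain NaNs (first at row {int(np.argmax(bad.values))})"
        )
    if "t" in df.columns:
        if not df["t"].is_monotonic_increasing:
            logger.info("input times were unsorted; sorting")
            df = df.sort_values("t", kind="stable").reset_index(drop=True)
        ndup = int(df["t"].duplicated().sum())
        if ndup and kind in ("temporal", "multistream", "spatiotemporal"):
            raise SchemaError(
                f"{ndup} duplicate event times; jitter them first (--jitter)"
            )
    if kind == "temporal":
        t = df["t"].to_numpy(float)
        return EventSeries(
            times=t,
            T=T if T is not None else float(t[-1]),
            marks=df["mark"].to_numpy(float) if "mark" in df.columns else None,
        )
    if kind == "multistream":
        return MultiEventSeries(
            times=df["t"].to_numpy(float),
            streams=df["stream"].to_numpy(int),
            T=T if T is not None else float(df["t"].iloc[-1]),
        )
    locs = df[["x", "y"]].to_numpy(float)
    return PointPattern(
        locs=locs,
        times=df["t"].to_numpy(float) if "t" in df.columns else None,
        time_knot=df["knot"].to_numpy(int) if "knot" in df.columns else None,
        marks=df["mark"].to_numpy(float) if "mark" in df.columns else None,
    )


def write_events(obj, path) -> None:
    """Write an event container back to CSV (inverse of read_events)."""
    if isinstance(obj, EventSeries):
        d = {"t": obj.times}
        if obj.marks is not None:
            d["mark"] = obj.marks
    elif isinstance(obj, MultiEventSeries):
        d = {"t": obj.times, "stream": obj.streams}
    elif isinstance(obj, PointPattern):
        d = {}
        if obj.times is not None:
            d["t"] = obj.times
        d["x"] = obj.locs[:, 0]
        d["y"] = obj.locs[:, 1]
        if obj.time_knot is not None:
            d["knot"] = obj.time_knot
        if obj.marks is not None:
            d["mark"] = obj.marks
    else:
        raise TypeError(f"cannot write {type(obj).__name__}")
    pd.DataFrame(d).to_csv(path, index=False, float_format="%.17g")


def read_domain(path_or_text) -> Domain:
    """Domain polygon from GeoJSON (file or string) or WKT string."""
    text = str(path_or_text)
    if text.lstrip().upper().startswith(("POLYGON", "MULTIPOLYGON")):
        return Domain.from_wkt(text)
    return Domain.from_geojson(text)


def read_covariates(path) -> np.ndarray:
    """Node-level covariate matrix from CSV (one column per covariate)."""
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c != "node"]
    return df[cols].to_numpy(float)


def write_fit_report(fit: FitResult, path, seed=None, n_events=None, area=None) -> None:
    """JSON fit report: parameter table, loglik, convergence, provenance."""
    from . import __version__

    report = fit.to_dict()
    report["software_version"] = __version__
    report["seed"] = seed
    if n_events is not None:
        report["n_events"] = int(n_events)
    if area is not None:
        report["domain_area"] = float(area)
    report["timestamp"] = datetime.now(timezone.utc).isoformat()
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def write_mesh(mesh: Mesh, path) -> None:
    with open(path, "w") as fh:
        fh.write(mesh.to_json())


def read_mesh(path) -> Mesh:
    with open(path) as fh:
        return Mesh.from_json(fh.read())
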