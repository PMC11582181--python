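"""Readers and writers for observation tables, measurement-parameter tables
and fit results.

The canonical data layout is a wide delimited table: one row per timepoint,
one column per item, with an optional leading ``time`` column.  Ordinal
entries are integer category codes; arbitrary codings (e.g. 0-based Likert
responses) are remapped onto 1..J and the mapping is recorded rather than
silently shifted.  A long-format reader (time, item, value) is provided for
typical EMA exports.

Measurement-parameter tables follow the layout of published calibration
tables: ``item_id, state_index, alpha, beta_1..beta_{J-1}`` for
graded-response items, or ``item_id, state_index, loading, error_var`` for
linear ones.

Fit results round-trip through versioned JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from .filtering import FilterOutput
from .measurement import GRMItem, LinearItem, MeasurementModel
from .mif2 import FitResult, MIF2Config, ParameterVector
from .errors import DataError, ParameterError

__all__ = [
    "read_observations",
    "read_long_observations",
    "read_measurement_table",
    "write_observations",
    "write_fit_result",
    "read_fit_result",
]

SCHEMA_VERSION = 1


def read_observations(path, kind: str = "grm", n_categories=None, sep=None,
                      missing=("", "NA", "NaN", "nan")):
    """Read a wide observation table.

    Returns (data, item_ids, coding) where ``data`` is (T, q) int64 with
    0 = missing for the grm kind (float with NaN otherwise), ``item_ids``
    the column labels and ``coding`` the original -> 1..J category map per
    item (grm only).

    n_categories: optional int or per-item mapping declaring J; observed
    codes outside the declared range raise a schema error naming the cell.
    """
    df = pd.read_csv(path, sep=sep, engine="python", na_values=list(missing), keep_default_na=True)
    cols = list(df.columns)
    if cols and cols[0].lower() in ("time", "t"):
        tcol = df[cols[0]].to_numpy()
        if np.any(np.diff(tcol) <= 0):
            raise DataError("time column must be strictly increasing")
        df = df[cols[1:]]
    item_ids = list(df.columns)
    if kind == "linear":
        return df.to_numpy(dtype=float), item_ids, None
    data = np.zeros(df.shape, dtype=np.int64)
    coding = {}
    for j, col in enumerate(item_ids):
        vals = df[col]
        obs = vals.dropna().to_numpy()
        if obs.size and not np.allclose(obs, np.round(obs)):
            raise DataError(f"column {col!r} has non-integer category codes")
        obs = obs.astype(np.int64)
        if n_categories is not None:
            J = n_categories[col] if isinstance(n_categories, dict) else int(n_categories)
            lo = int(obs.min()) if obs.size else 1
            base = 0 if lo == 0 else 1
            bad = (obs < base) | (obs > base + J - 1)
            if bad.any():
                row = int(vals.dropna().index[np.argmax(bad)])
                raise DataError(
                    f"column {col!r}, row {row}: category {obs[np.argmax(bad)]} outside "
                    f"declared coding {base}..{base + J - 1}"
                )
            levels = np.arange(base, base + J)
        else:
            levels = np.unique(obs)
        coding[col] = {int(orig): rank + 1 for rank, orig in enumerate(levels)}
        mapped = vals.map(lambda v, m=coding[col]: m.get(int(v), 0) if pd.notna(v) else 0)
        data[:, j] = mapped.to_numpy(dtype=np.int64)
    return data, item_ids, coding


def read_long_observations(path, time_col="time", item_col="item", value_col="value", **kw):
    """Read a long-format (time, item, value) export and pivot it wide."""
    df = pd.read_csv(path)
    wide = df.pivot(index=time_col, columns=item_col, values=value_col).sort_index()
    import io as _io

    buf = _io.StringIO()
    wide.reset_index().to_csv(buf, index=False)
    buf.seek(0)
    return read_observations(buf, **kw)


def write_observations(path, data, item_ids, time_start: int = 1):
    data = np.asarray(data)
    df = pd.DataFrame(data, columns=item_ids)
    df.insert(0, "time", np.arange(time_start, time_start + data.shape[0]))
    df.to_csv(path, index=False)


def read_measurement_table(path, kind: str = "grm", sep=None) -> MeasurementModel:
    """Parse a measurement-parameter table into a MeasurementModel.

    GR rows need item_id, state_index, alpha and increasing beta_1.. columns
    (trailing blanks allowed for items with fewer categories); linear rows
    need item_id, state_index, loading, error_var.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if df["item_id"].duplicated().any():
        dup = df["item_id"][df["item_id"].duplicated()].iloc[0]
        raise DataError(f"duplicate item_id {dup!r} in measurement table")
    items = []
    if kind == "grm":
        beta_cols = sorted(
            (c for c in df.columns if c.startswith("beta_")),
            key=lambda c: int(c.split("_")[1]),
        )
        if not beta_cols:
            raise DataError("no beta_1.. columns found for a grm table")
        for _, row in df.iterrows():
            beta = row[beta_cols].dropna().to_numpy(dtype=float)
            if np.any(np.diff(beta) <= 0):
                raise DataError(
                    f"item {row['item_id']!r}: thresholds not strictly increasing: {beta.tolist()}"
                )
            items.append(
                GRMItem(str(row["item_id"]), int(row["state_index"]), float(row["alpha"]), beta)
            )
        return MeasurementModel(kind="grm", items=tuple(items))
    if kind == "linear":
        for _, row in df.iterrows():
            items.append(
                LinearItem(
                    str(row["item_id"]), int(row["state_index"]),
                    float(row["loading"]), float(row["error_var"]),
                )
            )
        return MeasurementModel(kind="linear", items=tuple(items))
    raise ParameterError(f"unknown measurement kind {kind!r}")


def _pv_to_dict(pv: ParameterVector) -> dict:
    return {
        "values": pv.values.tolist(),
        "kind": pv.kind,
        "n_cats": list(pv.n_cats),
        "q": pv.q,
        "estimate_measurement": pv.estimate_measurement,
    }


def _pv_from_dict(d: dict) -> ParameterVector:
    return ParameterVector(
        values=np.asarray(d["values"], dtype=float),
        kind=d["kind"],
        n_cats=tuple(d["n_cats"]),
        q=int(d["q"]),
        estimate_measurement=bool(d["estimate_measurement"]),
    )


def write_fit_result(result: FitResult, path):
    from . import __version__

    payload = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "config": asdict(result.config),
        "run_seeds": list(result.run_seeds),
        "center": np.asarray(result.center).tolist(),
        "per_run_estimates": [_pv_to_dict(pv) for pv in result.per_run_estimates],
        "averaged_estimate": _pv_to_dict(result.averaged_estimate),
        "loglik_traces": [np.asarray(t).tolist() for t in result.loglik_traces],
        "warnings": list(result.warnings),
        "final_filter": {
            "filtered_means": result.final_filter.filtered_means.tolist(),
            "loglik": result.final_filter.loglik,
            "ess_trace": result.final_filter.ess_trace.tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_fit_result(path) -> FitResult:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise DataError(
            f"fit-result schema version {payload.get('schema_version')} "
            f"not supported (expected {SCHEMA_VERSION})"
        )
    ff = payload["final_filter"]
    return FitResult(
        per_run_estimates=tuple(_pv_from_dict(d) for d in payload["per_run_estimates"]),
        averaged_estimate=_pv_from_dict(payload["averaged_estimate"]),
        loglik_traces=tuple(np.asarray(t) for t in payload["loglik_traces"]),
        final_filter=FilterOutput(
            filtered_means=np.asarray(ff["filtered_means"]),
            loglik=float(ff["loglik"]),
            ess_trace=np.asarray(ff["ess_trace"]),
        ),
        config=MIF2Config(**payload["config"]),
        run_seeds=tuple(payload["run_seeds"]),
        center=np.asarray(payload["center"]),
        warnings=tuple(payload["warnings"]),
    )
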