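"""Reading, validation and preprocessing of replicated expression time series.

The canonical container is :class:`RhythmDataset`: an ordered vector of
observation times (hours), a ``(n_times, n_replicates)`` matrix of relative
expression values with NaN marking missing cells, and an optional per-time-point
measurement-error variance.  Every detector in the package consumes this object.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "RhythmDataset",
    "read_timeseries",
    "write_timeseries",
    "normalize",
    "collapse_replicates",
]

MISSING_MARKERS = {"", "NA", "NaN", "nan", "na"}

#: minimum number of distinct time points required for any model fit
MIN_TIMEPOINTS = 4


@dataclass(frozen=True)
class RhythmDataset:
    """Replicated single-signal time series on an arbitrary time grid.

    Parameters
    ----------
    times
        Strictly increasing observation times in hours (stacked datasets may
        carry repeated times; see :func:`collapse_replicates`).
    values
        ``(n_times, n_replicates)`` array; NaN encodes a missing cell.
    noise_var
        Optional per-time-point measurement-error variance (e.g. squared SEM
        across technical replicates), added to the GP noise diagonal.
    label
        Free-text identifier carried through the pipeline.
    """

    times: np.ndarray
    values: np.ndarray
    noise_var: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if times.ndim != 1:
            raise ValueError("times must be a 1-D vector")
        if values.shape[0] != times.size:
            raise ValueError(
                f"values has {values.shape[0]} rows but times has {times.size} entries"
            )
        if not np.all(np.isfinite(times)):
            raise ValueError("non-finite observation time")
        if np.any(np.diff(times) < 0):
            order = np.argsort(times, kind="stable")
            times = times[order]
            values = values[order]
            if self.noise_var is not None:
                object.__setattr__(
                    self, "noise_var", np.asarray(self.noise_var, dtype=float)[order]
                )
        all_missing = np.all(np.isnan(values), axis=1)
        if np.any(all_missing):
            keep = ~all_missing
            times = times[keep]
            values = values[keep]
            if self.noise_var is not None:
                object.__setattr__(
                    self, "noise_var", np.asarray(self.noise_var, dtype=float)[keep]
                )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.noise_var is not None:
            nv = np.asarray(self.noise_var, dtype=float)
            if nv.shape != (times.size,):
                raise ValueError("noise_var must have one entry per retained time point")
            if np.any(nv < 0):
                raise ValueError("noise_var entries must be nonnegative")
            object.__setattr__(self, "noise_var", nv)

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    def observed(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flatten to per-observation (time, value, noise_var) triples,
        dropping missing cells.  Rows are ordered by time then replicate."""
        t = np.repeat(self.times, self.n_replicates)
        v = self.values.ravel()
        if self.noise_var is None:
            nv = np.zeros_like(t)
        else:
            nv = np.repeat(self.noise_var, self.n_replicates)
        keep = ~np.isnan(v)
        return t[keep], v[keep], nv[keep]

    def with_label(self, label: str) -> "RhythmDataset":
        return replace(self, label=label)


def _validate_min_points(times: np.ndarray, label: str) -> None:
    if np.unique(times).size < MIN_TIMEPOINTS:
        raise ValueError(
            f"dataset {label!r} has fewer than {MIN_TIMEPOINTS} distinct time points; "
            "too short for model fitting"
        )


def _parse_time_column(raw: pd.Series, path: str) -> np.ndarray:
    times = pd.to_numeric(raw, errors="coerce")
    bad = times.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: non-numeric time value {raw.iloc[row]!r} in data row {row}"
        )
    return times.to_numpy(dtype=float)


def read_timeseries(
    path,
    layout: str = "wide",
    sep: str | None = None,
    label: str | None = None,
) -> RhythmDataset:
    """Read a CSV/TSV time-series file into a :class:`RhythmDataset`.

    Wide layout: a ``time`` column followed by one column per replicate and an
    optional ``noise_var`` column.  Long layout: columns
    ``time, replicate, value``.  Empty cells, ``NA`` and ``NaN`` are missing.

    The delimiter is sniffed from the file extension unless ``sep`` is given.
    """
    path = str(path)
    if sep is None:
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(
        path, sep=sep, na_values=sorted(MISSING_MARKERS), keep_default_na=False,
        skipinitialspace=True, float_precision="round_trip",
    )
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns, found {df.shape[1]}")
    name = label if label is not None else path

    if layout == "wide":
        time_col = df.columns[0]
        times = _parse_time_column(df[time_col].astype(object), path)
        noise_var = None
        rep_cols = [c for c in df.columns[1:]]
        if "noise_var" in rep_cols:
            noise_var = pd.to_numeric(df["noise_var"], errors="coerce").to_numpy(float)
            rep_cols.remove("noise_var")
        if not rep_cols:
            raise ValueError(f"{path}: no replicate columns")
        values = np.empty((len(df), len(rep_cols)))
        for j, c in enumerate(rep_cols):
            col = pd.to_numeric(df[c], errors="coerce")
            if col.isna().all():
                raise ValueError(f"{path}: replicate column {c!r} is entirely missing")
            values[:, j] = col.to_numpy(dtype=float)
    elif layout == "long":
        required = {"time", "replicate", "value"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"{path}: long layout requires columns {sorted(required)}"
            )
        times_raw = _parse_time_column(df["time"].astype(object), path)
        wide = (
            pd.DataFrame(
                {
                    "time": times_raw,
                    "replicate": df["replicate"],
                    "value": pd.to_numeric(df["value"], errors="coerce"),
                }
            )
            .pivot_table(index="time", columns="replicate", values="value",
                         aggfunc="first", dropna=False)
            .sort_index()
        )
        times = wide.index.to_numpy(dtype=float)
        values = wide.to_numpy(dtype=float)
        noise_var = None
    else:
        raise ValueError(f"unknown layout {layout!r}; use 'wide' or 'long'")

    ds = RhythmDataset(times=times, values=values, noise_var=noise_var, label=name)
    if np.unique(ds.times).size != ds.times.size:
        raise ValueError(f"{path}: duplicate time points in wide layout")
    _validate_min_points(ds.times, name)
    return ds


def write_timeseries(ds: RhythmDataset, path, sep: str = ",") -> None:
    """Write the wide CSV dialect (time, rep columns, optional noise_var)."""
    cols = {"time": ds.times}
    for j in range(ds.n_replicates):
        cols[f"rep{j + 1}"] = ds.values[:, j]
    if ds.noise_var is not None:
        cols["noise_var"] = ds.noise_var
    # %.17g guarantees binary round-tripping of doubles through text
    pd.DataFrame(cols).to_csv(
        path, sep=sep, index=False, na_rep="NA", float_format="%.17g"
    )


def normalize(ds: RhythmDataset, method: str = "zscore") -> RhythmDataset:
    """Normalize all replicate values by the grand mean/sd of non-missing cells.

    ``zscore`` subtracts the grand mean and divides by the grand standard
    deviation (population convention, ``ddof=0``); ``center`` subtracts the
    grand mean only; ``none`` is the identity.  ``noise_var`` is rescaled by
    the squared divisor so measurement errors stay on the data scale.
    """
    if method == "none":
        return ds
    vals = ds.values
    finite = vals[~np.isnan(vals)]
    mean = finite.mean()
    if method == "center":
        return replace(ds, values=vals - mean)
    if method == "zscore":
        sd = finite.std(ddof=0)
        if sd == 0:
            raise ValueError(
                "zero variance: z-scoring undefined; use method='center' or 'none'"
            )
        nv = None if ds.noise_var is None else ds.noise_var / sd**2
        return replace(ds, values=(vals - mean) / sd, noise_var=nv)
    raise ValueError(f"unknown normalization method {method!r}")


def collapse_replicates(ds: RhythmDataset, mode: str = "mean_sem") -> RhythmDataset:
    """Reduce replicates either to per-time-point means or to stacked rows.

    ``mean_sem`` replaces the replicates at each time point by their mean and
    stores the squared standard error of that mean (sample sd, n-1 denominator)
    in ``noise_var``; a time point with a single surviving replicate gets
    noise_var 0 and its noise is absorbed by the learned GP noise scale.
    ``mean`` averages replicates without attaching an error estimate, leaving
    the whole noise budget to the learned GP noise scale.  ``stack`` flattens
    replicates into repeated time entries for kernels that handle duplicate
    inputs through their noise diagonal.
    """
    if mode == "mean":
        mean = np.nanmean(ds.values, axis=1)
        return RhythmDataset(
            times=ds.times, values=mean[:, None], noise_var=ds.noise_var,
            label=ds.label,
        )
    if mode == "mean_sem":
        vals = ds.values
        n_obs = np.sum(~np.isnan(vals), axis=1)
        mean = np.nanmean(vals, axis=1)
        sem2 = np.zeros(ds.n_times)
        multi = n_obs >= 2
        if np.any(multi):
            sd = np.nanstd(vals[multi], axis=1, ddof=1)
            sem2[multi] = sd**2 / n_obs[multi]
        if ds.noise_var is not None:
            sem2 = sem2 + ds.noise_var
        return RhythmDataset(
            times=ds.times, values=mean[:, None], noise_var=sem2, label=ds.label
        )
    if mode == "stack":
        t, v, nv = ds.observed()
        order = np.argsort(t, kind="stable")
        return RhythmDataset(
            times=t[order],
            values=v[order][:, None],
            noise_var=nv[order] if ds.noise_var is not None else None,
            label=ds.label,
        )
    raise ValueError(f"unknown replicate mode {mode!r}")
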