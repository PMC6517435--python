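"""Delimited-text I/O for time-series matrices and TF maps, plus preprocessing."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesSet",
    "read_matrix",
    "write_matrix",
    "impute_local_average",
    "standardize",
    "write_tf_map",
    "read_tf_map",
]

_NA_TOKENS = {"", "na", "nan", "n/a", "null", "none", "."}


@dataclass
class TimeSeriesSet:
    """An (M, n) real matrix of channels with sampling rate and missing mask."""

    data: np.ndarray
    sampling_rate: float = 1.0
    channel_labels: list[str] = field(default_factory=list)
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.data)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.data.shape:
            raise ValueError("missing mask shape mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _sniff(path) -> tuple[str, bool]:
    """Return (separator, has_header) from the first line."""
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    tokens = [t.strip() for t in first.rstrip("\n").split(sep)]

    def numeric_or_na(tok: str) -> bool:
        if tok.lower() in _NA_TOKENS:
            return True
        try:
            float(tok)
            return True
        except ValueError:
            return False

    return sep, not all(numeric_or_na(t) for t in tokens)


def read_matrix(
    path,
    orientation: str = "channels_in_columns",
    sampling_rate: float = 1.0,
) -> TimeSeriesSet:
    """Read a delimited time-series matrix (CSV or TSV).

    Default layout is one column per channel and one row per sample, with an
    optional header row of channel labels; empty cells and NA tokens become
    missing values recorded in the mask.
    """
    if orientation not in ("channels_in_columns", "channels_in_rows"):
        raise ValueError("unknown orientation")
    sep, has_header = _sniff(path)
    df = pd.read_csv(
        path,
        sep=sep,
        header=0 if has_header else None,
        na_values=list(_NA_TOKENS),
        keep_default_na=True,
        skip_blank_lines=False,
    )
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise ValueError(f"non-numeric cell in column {col!r}: {exc}") from exc
    data = df.to_numpy(dtype=float)
    labels = [str(c) for c in df.columns] if has_header else []
    if orientation == "channels_in_columns":
        data = data.T
    else:
        labels = []
    return TimeSeriesSet(data=data, sampling_rate=sampling_rate, channel_labels=labels)


def write_matrix(ts: TimeSeriesSet, path, sep: str = ",") -> None:
    """Write channels-in-columns with a header of channel labels."""
    df = pd.DataFrame(ts.data.T, columns=ts.channel_labels)
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


def impute_local_average(ts: TimeSeriesSet) -> TimeSeriesSet:
    """Fill missing values with the mean of their nearest observed neighbours.

    An isolated gap becomes the average of its two temporal neighbours; runs
    of consecutive gaps are linearly interpolated between the flanking
    observed points, and boundary gaps copy the single available neighbour.
    Observed values are untouched.
    """
    data = ts.data.copy()
    mask = ts.missing_mask.copy()
    idx = np.arange(ts.n_samples)
    for ch in range(ts.n_channels):
        miss = mask[ch]
        if not miss.any():
            continue
        if miss.all():
            raise ValueError(f"channel {ts.channel_labels[ch]!r} is entirely missing")
        data[ch, miss] = np.interp(idx[miss], idx[~miss], data[ch, ~miss])
    return TimeSeriesSet(
        data=data,
        sampling_rate=ts.sampling_rate,
        channel_labels=list(ts.channel_labels),
        missing_mask=np.zeros_like(mask),
    )


def standardize(ts: TimeSeriesSet) -> TimeSeriesSet:
    """Per-channel zero mean, unit variance (population SD)."""
    if ts.missing_mask.any():
        raise ValueError("impute missing values before standardizing")
    sd = ts.data.std(axis=1, ddof=0)
    if np.any(sd == 0):
        bad = [ts.channel_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant channel(s) cannot be standardized: {bad}")
    data = (ts.data - ts.data.mean(axis=1, keepdims=True)) / sd[:, None]
    return TimeSeriesSet(
        data=data,
        sampling_rate=ts.sampling_rate,
        channel_labels=list(ts.channel_labels),
        missing_mask=ts.missing_mask.copy(),
    )


def write_tf_map(path, values: np.ndarray, frequencies: np.ndarray, times: np.ndarray) -> None:
    """Write a TF map (rows = frequencies, columns = times) as TSV.

    A two-line comment header carries the time and frequency axes.
    """
    values = np.asarray(values)
    if values.shape != (len(frequencies), len(times)):
        raise ValueError("map shape does not match axes")
    with open(path, "w") as fh:
        fh.write("# times\t" + "\t".join(f"{t:.10g}" for t in times) + "\n")
        fh.write("# frequencies\t" + "\t".join(f"{f:.10g}" for f in frequencies) + "\n")
        np.savetxt(fh, values.astype(float), delimiter="\t", fmt="%.10g")


def read_tf_map(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a TF map written by :func:`write_tf_map`; returns (values, freqs, times)."""
    with open(path) as fh:
        t_line = fh.readline()
        f_line = fh.readline()
        if not t_line.startswith("# times") or not f_line.startswith("# frequencies"):
            raise ValueError("not a TF-map file (missing axis header)")
        times = np.array([float(v) for v in t_line.split("\t")[1:]])
        freqs = np.array([float(v) for v in f_line.split("\t")[1:]])
        values = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if values.shape != (freqs.size, times.size):
        raise ValueError("TF-map body does not match its axis header")
    return values, freqs, times
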