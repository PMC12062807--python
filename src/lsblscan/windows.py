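"""Sliding-window grids in BED-like half-open coordinates.

All windowed statistics in this package live on grids produced here:
windows of ``size`` bp advanced by ``step`` bp, starting at 0, with the
final window truncated at the chromosome end.  Tracks are plain pandas
DataFrames with columns ``chrom, start, end, n_snps, value`` so that
different statistics computed on the same grid align row-for-row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["chrom", "start", "end", "n_snps", "value"]


def window_grid(chrom_len: int, size: int, step: int) -> np.ndarray:
    """Return an array of (start, end) half-open windows covering [0, chrom_len).

    Starts are 0, step, 2*step, ...; the last start is the largest multiple of
    ``step`` strictly below ``chrom_len``.  Ends are clipped to ``chrom_len``.
    """
    if size <= 0 or step <= 0 or size < step:
        raise ValueError("require size >= step > 0")
    if chrom_len <= 0:
        raise ValueError("chrom_len must be positive")
    starts = np.arange(0, chrom_len, step, dtype=np.int64)
    ends = np.minimum(starts + size, chrom_len)
    return np.column_stack([starts, ends])


def aggregate_in_windows(
    positions0: np.ndarray,
    values: np.ndarray,
    grid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum ``values`` of sites (0-based positions, sorted) over each window.

    Returns (n_snps, sums) per window.  Sites may fall into several
    overlapping windows; each contributes to all windows containing it.
    Masked (NaN) values count toward n_snps but are summed as 0.
    """
    if positions0.size and np.any(np.diff(positions0) < 0):
        raise ValueError("positions must be sorted")
    v = np.nan_to_num(np.asarray(values, dtype=float), nan=0.0)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    lo = np.searchsorted(positions0, grid[:, 0], side="left")
    hi = np.searchsorted(positions0, grid[:, 1], side="left")
    return (hi - lo).astype(np.int64), csum[hi] - csum[lo]


def empty_track(statistic: str, window: int, step: int) -> pd.DataFrame:
    t = pd.DataFrame(columns=TRACK_COLUMNS)
    t.attrs.update(statistic=statistic, window=window, step=step)
    return t


def make_track(
    chroms: list[str],
    grids: dict[str, np.ndarray],
    n_snps: dict[str, np.ndarray],
    values: dict[str, np.ndarray],
    statistic: str,
    window: int,
    step: int,
) -> pd.DataFrame:
    """Assemble per-chromosome window arrays into one ordered track."""
    parts = []
    for chrom in chroms:
        g = grids[chrom]
        parts.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": g[:, 0],
                    "end": g[:, 1],
                    "n_snps": n_snps[chrom],
                    "value": values[chrom],
                }
            )
        )
    track = pd.concat(parts, ignore_index=True) if parts else empty_track(statistic, window, step)
    track.attrs.update(statistic=statistic, window=window, step=step)
    return track


def same_grid(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    """True when two tracks share an identical (chrom, start, end) grid."""
    if len(a) != len(b):
        return False
    return bool(
        (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
        and (a["start"].to_numpy() == b["start"].to_numpy()).all()
        and (a["end"].to_numpy() == b["end"].to_numpy()).all()
    )


def write_track(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_track(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")
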