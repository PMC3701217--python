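"""Normalization and smoothing of probe-level tiling-array log-ratio tracks.

The substrate is a two-colour MeDIP/Input promoter tiling design: each probe
carries one log2(MeDIP/Input) value per hybridised array.  Before peak calling
the sample columns are brought onto a common distribution by quantile
normalization, median-centred per column, and smoothed along the genome with a
fixed-width running mean.

Coordinates are 0-based half-open throughout the package (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: mandatory leading columns of a probe table
COORD_COLS = ("probe_id", "chrom", "start", "end")


def _infer_groups(sample_cols: Sequence[str]) -> dict[str, list[str]]:
    """Infer group membership from ``<group>_<replicate>`` column names."""
    groups: dict[str, list[str]] = {}
    for col in sample_cols:
        if "_" not in col:
            raise ValueError(
                f"sample column {col!r} does not follow the "
                "'<group>_<replicate>' naming convention"
            )
        group, _ = col.rsplit("_", 1)
        groups.setdefault(group, []).append(col)
    return groups


@dataclass
class ProbeTrack:
    """Genome-ordered probes with per-sample log2(MeDIP/Input) values.

    Parameters
    ----------
    frame:
        Table with columns ``probe_id, chrom, start, end`` followed by one
        column per sample.  Rows are sorted by ``(chrom, start)`` on
        construction; duplicate probe ids are rejected.
    groups:
        Mapping from group label (e.g. ``"treated"``) to its sample columns.
        If omitted, inferred from ``<group>_<replicate>`` column names.
    """

    frame: pd.DataFrame
    groups: Mapping[str, Sequence[str]] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in COORD_COLS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"probe table lacks required columns: {missing}")
        if self.frame["probe_id"].duplicated().any():
            dup = self.frame["probe_id"][self.frame["probe_id"].duplicated()]
            raise ValueError(f"duplicate probe ids: {sorted(set(dup))[:5]}")
        frame = self.frame
        if not frame[["chrom", "start"]].equals(
            frame[["chrom", "start"]].sort_values(["chrom", "start"])
        ):
            frame = frame.sort_values(["chrom", "start"], kind="mergesort")
        self.frame = frame.reset_index(drop=True)
        if self.groups is None:
            self.groups = _infer_groups(self.samples)
        else:
            self.groups = {g: list(cols) for g, cols in self.groups.items()}
            known = {c for cols in self.groups.values() for c in cols}
            unknown = known - set(self.samples)
            if unknown:
                raise ValueError(f"group columns not in table: {sorted(unknown)}")

    # -- accessors ---------------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return [c for c in self.frame.columns if c not in COORD_COLS]

    @property
    def n_probes(self) -> int:
        return len(self.frame)

    @property
    def values(self) -> np.ndarray:
        """Probe × sample value matrix (float64)."""
        return self.frame[self.samples].to_numpy(dtype=float)

    def group_values(self, group: str) -> np.ndarray:
        """Probe × replicate matrix for one group."""
        return self.frame[list(self.groups[group])].to_numpy(dtype=float)

    def midpoints(self) -> np.ndarray:
        return (
            self.frame["start"].to_numpy(dtype=float)
            + self.frame["end"].to_numpy(dtype=float)
        ) / 2.0

    def chrom_blocks(self) -> list[tuple[str, int, int]]:
        """Contiguous ``(chrom, lo, hi)`` row ranges (track is sorted)."""
        chroms = self.frame["chrom"].to_numpy()
        blocks = []
        lo = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[lo]:
                blocks.append((chroms[lo], lo, i))
                lo = i
        return blocks

    def with_values(self, values: np.ndarray) -> "ProbeTrack":
        """Return a copy of the track carrying ``values`` (probe × sample)."""
        frame = self.frame.copy()
        frame[self.samples] = values
        return ProbeTrack(frame, groups=self.groups)

    def swap_groups(self, a: str = "treated", b: str = "control") -> "ProbeTrack":
        """Relabel group *a* as *b* and vice versa (columns untouched)."""
        mapping = {}
        for col in self.samples:
            g, rep = col.rsplit("_", 1)
            g = {a: b, b: a}.get(g, g)
            mapping[col] = f"{g}_{rep}"
        frame = self.frame.rename(columns=mapping)
        groups = {
            {a: b, b: a}.get(g, g): [mapping.get(c, c) for c in cols]
            for g, cols in self.groups.items()
        }
        return ProbeTrack(frame, groups=groups)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ProbeTrack":
        frame = pd.read_csv(path, sep="\t", comment="#")
        return cls(frame)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def quantile_normalize(track: ProbeTrack) -> ProbeTrack:
    """Median-centring quantile normalization across sample columns.

    Every sample column is mapped onto the per-rank mean of the column-wise
    order statistics (so all columns share one value multiset); a tie group
    receives the mean of the rank-mean values over the ranks it occupies.
    Each column is then centred on its median.  On tie-free (continuous)
    data the operation is exactly idempotent.

    Raises
    ------
    ValueError
        If fewer than two sample columns are present or any value is
        non-finite.
    """
    X = track.values
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs >=2 sample columns")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in probe track")
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(mean_sorted)])
    out = np.empty_like(X, dtype=float)
    for j in range(X.shape[1]):
        # a tie group occupies ranks [r_min, r_max]; every member receives
        # the mean of the rank-mean values over that span
        r_min = stats.rankdata(X[:, j], method="min")
        r_max = stats.rankdata(X[:, j], method="max")
        out[:, j] = (csum[r_max.astype(int)] - csum[r_min.astype(int) - 1]) / (
            r_max - r_min + 1
        )
    out -= np.median(out, axis=0, keepdims=True)
    return track.with_values(out)


def linear_smooth(track: ProbeTrack, window_bp: int = 300) -> ProbeTrack:
    """Fixed-width running-mean smoothing along the genome.

    Each probe's value is replaced, per sample, by the mean over all probes on
    the same chromosome whose midpoints lie within ``window_bp / 2`` of its
    own midpoint.  Windows never cross chromosome boundaries; an isolated
    probe (no neighbours in range) keeps its value.

    Raises
    ------
    ValueError
        If ``window_bp`` is not positive.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    X = track.values
    mids = track.midpoints()
    half = window_bp / 2.0
    out = np.empty_like(X, dtype=float)
    for _, lo, hi in track.chrom_blocks():
        m = mids[lo:hi]
        left = np.searchsorted(m, m - half, side="left")
        right = np.searchsorted(m, m + half, side="right")
        csum = np.vstack([np.zeros((1, X.shape[1])), np.cumsum(X[lo:hi], axis=0)])
        counts = (right - left).astype(float)[:, None]
        out[lo:hi] = (csum[right] - csum[left]) / counts
    return track.with_values(out)
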