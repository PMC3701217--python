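"""Shared construction helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd

from medipdmr.normalize import ProbeTrack


def make_track(
    starts,
    values,
    chrom: str = "chr1",
    probe_len: int = 50,
    columns=None,
) -> ProbeTrack:
    """Build a single-chromosome ProbeTrack from start positions and a
    probe × sample value array (1-D input becomes one treated/control pair)."""
    starts = np.asarray(starts, dtype=int)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and len(starts) > 1:
        values = values.T
    if columns is None:
        columns = [f"treated_{j + 1}" for j in range(values.shape[1])]
        if values.shape[1] == 1:
            columns = ["treated_1"]
    frame = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(len(starts))],
            "chrom": chrom,
            "start": starts,
            "end": starts + probe_len,
        }
    )
    for j, c in enumerate(columns):
        frame[c] = values[:, j]
    return ProbeTrack(frame, groups={"all": list(columns)})


def make_two_group_track(starts, treated, control, chrom="chr1", probe_len=50):
    """ProbeTrack with explicit treated/control replicate matrices."""
    treated = np.atleast_2d(np.asarray(treated, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    if treated.shape[0] == 1 and len(starts) > 1:
        treated = treated.T
    if control.shape[0] == 1 and len(starts) > 1:
        control = control.T
    frame = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(len(starts))],
            "chrom": chrom,
            "start": np.asarray(starts, dtype=int),
            "end": np.asarray(starts, dtype=int) + probe_len,
        }
    )
    for j in range(treated.shape[1]):
        frame[f"treated_{j + 1}"] = treated[:, j]
    for j in range(control.shape[1]):
        frame[f"control_{j + 1}"] = control[:, j]
    return ProbeTrack(frame)


def brute_force_peaks(track, pvalues, params):
    """Independent maximal-run enumeration, straight from the definition."""
    qual = [
        i
        for i in range(track.n_probes)
        if -np.log10(pvalues[i]) >= params.probe_score_cutoff - 1e-9
    ]
    starts = track.frame["start"].to_numpy()
    ends = track.frame["end"].to_numpy()
    chroms = track.frame["chrom"].to_numpy()
    runs, run = [], []
    for i in qual:
        if run and (
            chroms[i] != chroms[run[-1]]
            or starts[i] - ends[run[-1]] > params.max_gap_bp
        ):
            runs.append(run)
            run = []
        run.append(i)
    if run:
        runs.append(run)
    return [r for r in runs if len(r) >= params.min_probes]


def brute_force_upgma(dist: np.ndarray):
    """Naive UPGMA on a full distance matrix; returns merge heights sorted.

    The merged-cluster distance is the exhaustive average of all pairwise
    leaf distances between the two clusters.
    """
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean(
                    [dist[i, j] for i in clusters[a] for j in clusters[b]]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return sorted(heights)
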