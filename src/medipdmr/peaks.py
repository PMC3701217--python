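"""Sliding-window enrichment peak detection on a per-probe score track.

The scan mirrors the vendor-style tiling-array peak finder: every probe gets a
one-sided p-value asking whether the probes inside a centred genomic window
are shifted upward relative to the track-wide score distribution, then maximal
runs of individually qualifying probes (−log10 p above a cutoff, gaps bounded)
are emitted as peaks.  The per-peak ``PeakScore`` is −log10 of the mean member
p-value, so a PeakScore of 2 means the average probe p-value was 0.01.

The per-probe test is a one-sided Wilcoxon rank-sum (Mann–Whitney) of the
window members against the rest of the track, with midranks for ties and a
continuity-corrected normal approximation; for tiny tracks the exact null
enumeration is used instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .normalize import ProbeTrack

_P_FLOOR = float(np.nextafter(0, 1))

#: combined sample sizes up to which the exact rank-sum null is enumerated
_EXACT_N = 20


@dataclass(frozen=True)
class PeakParams:
    """Sliding-window peak-calling parameters.

    Defaults follow the promoter tiling-array protocol: 750 bp window, at
    least 2 probes per peak, per-probe −log10 p cutoff of 2, and at most
    500 bp between neighbouring probes within one peak.
    """

    window_bp: int = 750
    min_probes: int = 2
    probe_score_cutoff: float = 2.0
    max_gap_bp: int = 500

    def __post_init__(self) -> None:
        for name in ("window_bp", "min_probes", "probe_score_cutoff", "max_gap_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Peak:
    """A called peak: genomic interval plus member probes and scores."""

    chrom: str
    start: int
    end: int
    probe_ids: tuple
    probe_pvalues: tuple
    peak_score: float
    probe_index: tuple = ()          # row positions in the source track
    peak_dm_value: float = math.nan  # median per-probe M' (set by dep module)
    direction: str = "gain"
    accepted: bool | None = None
    reasons: tuple = ()

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def mean_p(self) -> float:
        return float(np.mean(self.probe_pvalues))

    @property
    def name(self) -> str:
        return f"{self.direction}_{self.chrom}:{self.start}-{self.end}"


def _resolve_scores(track: ProbeTrack, score_column) -> np.ndarray:
    if isinstance(score_column, str):
        return track.frame[score_column].to_numpy(dtype=float)
    scores = np.asarray(score_column, dtype=float)
    if scores.shape != (track.n_probes,):
        raise ValueError("score vector length does not match probe count")
    return scores


def probe_pvalues(
    track: ProbeTrack, score_column, params: PeakParams | None = None
) -> np.ndarray:
    """One-sided window-shift p-value for every probe.

    For probe *i*, the window is all probes on the same chromosome whose
    midpoints lie within ``params.window_bp / 2`` of probe *i*'s midpoint.
    The returned p-value tests whether those window scores are shifted upward
    relative to the remaining probes of the whole track (Wilcoxon rank-sum,
    one-sided).  When the complement is empty (e.g. a single-probe track) the
    p-value is 1: no evidence.

    Returns p-values in ``(0, 1]`` aligned to the track's probe order.
    """
    params = params or PeakParams()
    scores = _resolve_scores(track, score_column)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite scores")
    N = len(scores)
    pvals = np.ones(N, dtype=float)
    if N < 2:
        return pvals

    mids = track.midpoints()
    half = params.window_bp / 2.0

    # window membership as contiguous [lo, hi) ranges per chromosome
    lo_idx = np.empty(N, dtype=int)
    hi_idx = np.empty(N, dtype=int)
    for _, lo, hi in track.chrom_blocks():
        m = mids[lo:hi]
        lo_idx[lo:hi] = lo + np.searchsorted(m, m - half, side="left")
        hi_idx[lo:hi] = lo + np.searchsorted(m, m + half, side="right")

    if N <= _EXACT_N:
        return _pvalues_exact(scores, lo_idx, hi_idx)

    ranks = stats.rankdata(scores)
    csum = np.concatenate([[0.0], np.cumsum(ranks)])
    m = (hi_idx - lo_idx).astype(float)
    n2 = N - m
    rank_sum = csum[hi_idx] - csum[lo_idx]
    U = rank_sum - m * (m + 1) / 2.0

    _, counts = np.unique(scores, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    var = m * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))

    ok = (m > 0) & (n2 > 0) & (var > 0)
    z = np.zeros(N)
    # continuity-corrected normal approximation, as in the asymptotic MWU test
    z[ok] = (U[ok] - m[ok] * n2[ok] / 2.0 - 0.5) / np.sqrt(var[ok])
    pvals[ok] = stats.norm.sf(z[ok])
    return np.clip(pvals, _P_FLOOR, 1.0)


def _pvalues_exact(scores: np.ndarray, lo_idx, hi_idx) -> np.ndarray:
    """Small-track fallback: per-probe exact (or tie-corrected) rank-sum."""
    N = len(scores)
    pvals = np.ones(N)
    has_ties = len(np.unique(scores)) < N
    for i in range(N):
        window = scores[lo_idx[i] : hi_idx[i]]
        rest = np.concatenate([scores[: lo_idx[i]], scores[hi_idx[i] :]])
        if len(window) == 0 or len(rest) == 0:
            continue
        method = "asymptotic" if has_ties else "exact"
        res = stats.mannwhitneyu(window, rest, alternative="greater", method=method)
        pvals[i] = res.pvalue
    return np.clip(pvals, _P_FLOOR, 1.0)


def find_peaks(
    track: ProbeTrack, pvalues: np.ndarray, params: PeakParams | None = None
) -> list[Peak]:
    """Assemble peaks from per-probe p-values.

    A probe qualifies when ``-log10(p) >= params.probe_score_cutoff``.
    Qualifying probes on one chromosome are partitioned into maximal runs,
    split wherever the gap between consecutive qualifying probes (next start
    minus previous end) exceeds ``params.max_gap_bp``; runs with fewer than
    ``params.min_probes`` members are discarded.  The returned peaks are
    sorted and disjoint; ``peak_score = -log10(mean member p)``.
    """
    params = params or PeakParams()
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.shape != (track.n_probes,):
        raise ValueError("p-value vector length does not match probe count")
    # tiny epsilon guards against -log10(10**-c) landing just below c
    qual = -np.log10(pvalues) >= params.probe_score_cutoff - 1e-9

    starts = track.frame["start"].to_numpy()
    ends = track.frame["end"].to_numpy()
    ids = track.frame["probe_id"].to_numpy()

    peaks: list[Peak] = []
    for chrom, lo, hi in track.chrom_blocks():
        members = [i for i in range(lo, hi) if qual[i]]
        run: list[int] = []
        for i in members + [None]:
            if run and (i is None or starts[i] - ends[run[-1]] > params.max_gap_bp):
                if len(run) >= params.min_probes:
                    peaks.append(_make_peak(chrom, run, starts, ends, ids, pvalues))
                run = []
            if i is not None:
                run.append(i)
    return peaks


def _make_peak(chrom, run, starts, ends, ids, pvalues) -> Peak:
    member_p = pvalues[run]
    return Peak(
        chrom=chrom,
        start=int(starts[run[0]]),
        end=int(ends[run[-1]]),
        probe_ids=tuple(ids[run]),
        probe_pvalues=tuple(float(p) for p in member_p),
        peak_score=float(-np.log10(np.mean(member_p))),
        probe_index=tuple(run),
    )


def peaks_to_frame(peaks: list[Peak]):
    """Tabular (BED6+) view of a peak list."""
    import pandas as pd

    rows = [
        {
            "chrom": p.chrom,
            "start": p.start,
            "end": p.end,
            "name": p.name,
            "score": round(p.peak_score, 6),
            "strand": ".",
            "n_probes": p.n_probes,
            "peak_dm_value": p.peak_dm_value,
            "mean_p": p.mean_p,
            "direction": p.direction,
            "accepted": p.accepted,
            "reasons": ";".join(p.reasons),
        }
        for p in peaks
    ]
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "n_probes", "peak_dm_value", "mean_p", "direction", "accepted", "reasons",
    ]
    return pd.DataFrame(rows, columns=cols)
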