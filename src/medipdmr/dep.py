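"""Differential-enrichment-peak (DEP) analysis between treated and control.

The per-probe differential statistic is

    M' = mean(log2 MeDIP/Input, treated replicates)
       - mean(log2 MeDIP/Input, control replicates)

Peaks are called on the M' track (gains on M', losses on -M', in separate
passes) and then filtered by two replicate-quality criteria:

(i)  at least one group's median log2(MeDIP/Input) within the peak is >= 0.3
     AND the median M' within the peak is positive (sign-adjusted for losses);
(ii) at least half of the member probes have a coefficient of variability
     (CV = replicate sd / |replicate mean|) <= 0.8 in BOTH groups.

A final selection step keeps peaks in BOTH the top 20% by PeakScore and the
top 20% by |PeakDMValue| (median M' within the peak); that subset feeds the
clustering heat map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalize import ProbeTrack
from .peaks import Peak, PeakParams, find_peaks, probe_pvalues

#: group means with absolute value below this get CV = +inf (undefined ratio)
_CV_MEAN_FLOOR = 1e-8


@dataclass(frozen=True)
class DEPFilterParams:
    """Thresholds for the two-stage DEP filter and the top-fraction cut."""

    median_ratio_min: float = 0.3
    cv_max: float = 0.8
    cv_probe_fraction: float = 0.5
    top_fraction: float = 0.2

    def __post_init__(self) -> None:
        for name in ("cv_probe_fraction", "top_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class MPrimeTrack:
    """Probe-aligned M' values plus per-group summaries.

    Attributes
    ----------
    track:
        The source (normalized) probe track.
    mprime:
        Per-probe M' (treated mean minus control mean).
    group_means:
        Per-group per-probe mean log2(MeDIP/Input).
    group_cv:
        Per-group per-probe CV across replicates; +inf where the group mean
        is numerically zero, 0 where only one replicate exists.
    """

    track: ProbeTrack
    mprime: np.ndarray
    group_means: dict
    group_cv: dict
    treated: str = "treated"
    control: str = "control"

    @property
    def frame(self) -> pd.DataFrame:
        out = self.track.frame[["probe_id", "chrom", "start", "end"]].copy()
        out["mprime"] = self.mprime
        for g, mu in self.group_means.items():
            out[f"mean_{g}"] = mu
        for g, cv in self.group_cv.items():
            out[f"cv_{g}"] = cv
        return out


def _group_cv(values: np.ndarray) -> np.ndarray:
    """CV = sd(ddof=1)/|mean| per probe; 0 for a single replicate."""
    mean = values.mean(axis=1)
    if values.shape[1] < 2:
        return np.zeros(len(values))
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / np.abs(mean)
    cv[np.abs(mean) < _CV_MEAN_FLOOR] = np.inf
    return cv


def compute_mprime(
    track: ProbeTrack, treated: str = "treated", control: str = "control"
) -> MPrimeTrack:
    """Per-probe M' and replicate CV for both groups.

    Raises
    ------
    ValueError
        If either group is absent or has zero replicates.
    """
    for g in (treated, control):
        if g not in track.groups or len(track.groups[g]) == 0:
            raise ValueError(f"group {g!r} has no replicates")
    vals = {g: track.group_values(g) for g in (treated, control)}
    means = {g: v.mean(axis=1) for g, v in vals.items()}
    cvs = {g: _group_cv(v) for g, v in vals.items()}
    mprime = means[treated] - means[control]
    return MPrimeTrack(
        track=track,
        mprime=mprime,
        group_means=means,
        group_cv=cvs,
        treated=treated,
        control=control,
    )


def apply_dep_filters(
    peaks: list[Peak],
    mtrack: MPrimeTrack,
    filter_params: DEPFilterParams | None = None,
) -> list[Peak]:
    """Flag each peak with the two DEP filter criteria (in place).

    Criterion (i), reason code ``"median_ratio"``: at least one group's
    median log2 ratio over member probes >= ``median_ratio_min`` and the
    median M' is positive in the peak's direction.
    Criterion (ii), reason code ``"cv"``: at least ``cv_probe_fraction`` of
    member probes have CV <= ``cv_max`` in both groups.
    """
    fp = filter_params or DEPFilterParams()
    for pk in peaks:
        idx = list(pk.probe_index)
        sign = -1.0 if pk.direction == "loss" else 1.0
        med_dm = float(np.median(mtrack.mprime[idx]))
        pk.peak_dm_value = med_dm
        reasons = []
        med_by_group = [
            float(np.median(mtrack.group_means[g][idx]))
            for g in (mtrack.treated, mtrack.control)
        ]
        if not (
            max(med_by_group) >= fp.median_ratio_min and sign * med_dm > 0
        ):
            reasons.append("median_ratio")
        cv_ok = (
            (mtrack.group_cv[mtrack.treated][idx] <= fp.cv_max)
            & (mtrack.group_cv[mtrack.control][idx] <= fp.cv_max)
        )
        if cv_ok.mean() < fp.cv_probe_fraction:
            reasons.append("cv")
        pk.reasons = tuple(reasons)
        pk.accepted = not reasons
    return peaks


def _trim_peak(pk: Peak, scores: np.ndarray, pvalues: np.ndarray,
               track: ProbeTrack, min_probes: int) -> Peak | None:
    """Refine peak boundaries to locally elevated probes.

    The window test assigns significance to a probe whenever its *window* is
    shifted, so runs of qualifying probes overhang the truly enriched
    interval by up to half a window on each side.  Trim the run inward from
    both ends at half maximum: member probes whose own score falls below
    half the peak's maximum score are dropped from the ends (interior dips
    are never removed), and the peak is discarded if fewer than
    ``min_probes`` members remain.
    """
    idx = list(pk.probe_index)
    thr = 0.5 * float(max(scores[i] for i in idx))
    while idx and scores[idx[0]] < thr:
        idx.pop(0)
    while idx and scores[idx[-1]] < thr:
        idx.pop()
    if len(idx) < min_probes:
        return None
    starts = track.frame["start"].to_numpy()
    ends = track.frame["end"].to_numpy()
    ids = track.frame["probe_id"].to_numpy()
    member_p = pvalues[idx]
    return Peak(
        chrom=pk.chrom,
        start=int(starts[idx[0]]),
        end=int(ends[idx[-1]]),
        probe_ids=tuple(ids[idx]),
        probe_pvalues=tuple(float(p) for p in member_p),
        peak_score=float(-np.log10(np.mean(member_p))),
        probe_index=tuple(idx),
        direction=pk.direction,
    )


def call_deps(
    mtrack: MPrimeTrack,
    peak_params: PeakParams | None = None,
    filter_params: DEPFilterParams | None = None,
) -> list[Peak]:
    """Call and filter differential enrichment peaks on the M' track.

    Gains are scanned on M' and losses on -M' in separate passes, so the
    reported direction preserves hyper- vs hypo-methylation.  Raw runs from
    the sliding-window scan are boundary-refined (see :func:`_trim_peak`)
    before filtering.  Every surviving peak is returned, flagged ``accepted``
    or carrying rejection reason codes.
    """
    pp = peak_params or PeakParams()
    all_peaks: list[Peak] = []
    for direction, sign in (("gain", 1.0), ("loss", -1.0)):
        scores = sign * mtrack.mprime
        pv = probe_pvalues(mtrack.track, scores, pp)
        called = find_peaks(mtrack.track, pv, pp)
        for pk in called:
            pk.direction = direction
            trimmed = _trim_peak(pk, scores, pv, mtrack.track, pp.min_probes)
            if trimmed is not None:
                all_peaks.append(trimmed)
    all_peaks.sort(key=lambda p: (p.chrom, p.start, p.direction))
    return apply_dep_filters(all_peaks, mtrack, filter_params)


def top_peak_filter(
    peaks: list[Peak], top_fraction: float = 0.2
) -> list[Peak]:
    """Peaks in BOTH the top fraction by PeakScore and by |PeakDMValue|.

    ``k = ceil(top_fraction * n)`` peaks are taken from each ranking; ties are
    broken by genomic order (chrom, start) for determinism.  Returns the
    intersection in genomic order.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    if not peaks:
        return []
    k = math.ceil(top_fraction * len(peaks))
    by_score = sorted(peaks, key=lambda p: (-p.peak_score, p.chrom, p.start))
    by_dm = sorted(peaks, key=lambda p: (-abs(p.peak_dm_value), p.chrom, p.start))
    keep = {id(p) for p in by_score[:k]} & {id(p) for p in by_dm[:k]}
    return sorted(
        (p for p in peaks if id(p) in keep), key=lambda p: (p.chrom, p.start)
    )


def peak_score_matrix(
    track: ProbeTrack,
    peaks: list[Peak],
    peak_params: PeakParams | None = None,
) -> pd.DataFrame:
    """Per-sample PeakScore matrix over a set of (filtered) DEP regions.

    For every sample column the sliding-window probe p-values are recomputed
    on that sample's own log2-ratio values; the entry for (peak, sample) is
    -log10 of the mean member-probe p-value.  Peaks without member probes
    would score 0 (cannot happen for peaks produced by :func:`find_peaks`).
    """
    pp = peak_params or PeakParams()
    if len(track.samples) < 2:
        raise ValueError("need >=2 sample columns")
    index = [p.name for p in peaks]
    mat = pd.DataFrame(0.0, index=index, columns=track.samples)
    for sample in track.samples:
        pv = probe_pvalues(track, track.frame[sample].to_numpy(dtype=float), pp)
        for pk in peaks:
            idx = list(pk.probe_index)
            if idx:
                mat.loc[pk.name, sample] = float(-np.log10(np.mean(pv[idx])))
    return mat
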