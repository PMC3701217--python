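"""Per-feature differential expression and ΔΔCt qPCR quantitation.

Expression matrices are log2 intensities (features × samples, two groups).
Each feature is tested with a one-way ANOVA across groups; the fold change is
the signed linear ratio ``2**(mean_treated - mean_control)``, reported as a
negative reciprocal when below 1 (a ratio of 1/1.24 prints as -1.24).  The
default stringency filter is |fold change| >= 1.2 at p <= 0.05, with no
multiple-testing correction (a Benjamini–Hochberg option is available and off
by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalize import _infer_groups


@dataclass
class ExpressionMatrix:
    """Features × samples log2 intensity matrix with two-group labels."""

    values: pd.DataFrame  # index = feature ids, columns = sample names
    groups: Mapping[str, Sequence[str]] | None = None

    def __post_init__(self) -> None:
        if self.groups is None:
            self.groups = _infer_groups(list(self.values.columns))
        else:
            self.groups = {g: list(c) for g, c in self.groups.items()}
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("non-finite expression values")

    @property
    def features(self) -> list:
        return list(self.values.index)

    def group_values(self, group: str) -> np.ndarray:
        return self.values[list(self.groups[group])].to_numpy(dtype=float)

    def swap_groups(self, a: str = "treated", b: str = "control") -> "ExpressionMatrix":
        mapping = {}
        for col in self.values.columns:
            g, rep = col.rsplit("_", 1)
            g = {a: b, b: a}.get(g, g)
            mapping[col] = f"{g}_{rep}"
        return ExpressionMatrix(self.values.rename(columns=mapping))

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.values.to_csv(fh, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", comment="#", index_col="feature_id")
        return cls(values)


@dataclass
class DEResult:
    """Differential-expression call for one feature."""

    feature_id: str
    fold_change: float
    p_value: float
    passes_filter: bool
    testable: bool = True


def signed_fold_change(log2_diff: float) -> float:
    """Linear fold change with the negative-reciprocal sign convention."""
    ratio = 2.0 ** log2_diff
    return float(ratio) if ratio >= 1.0 else float(-1.0 / ratio)


def differential_expression(
    matrix: ExpressionMatrix,
    fc_min: float = 1.2,
    alpha: float = 0.05,
    treated: str = "treated",
    control: str = "control",
    adjust: str | None = None,
) -> list[DEResult]:
    """One-way ANOVA + fold-change filter per feature.

    A feature passes when ``|fold_change| >= fc_min`` and its (optionally
    BH-adjusted, ``adjust="bh"``) p-value is ``<= alpha``.  If either group
    has fewer than two samples the p-value is undefined and every feature is
    flagged untestable (``passes_filter=False``).
    """
    for g in (treated, control):
        if g not in matrix.groups:
            raise ValueError(f"group {g!r} missing from matrix")
    a = matrix.group_values(treated)
    b = matrix.group_values(control)
    diff = a.mean(axis=1) - b.mean(axis=1)
    fc = np.array([signed_fold_change(d) for d in diff])

    testable = a.shape[1] >= 2 and b.shape[1] >= 2
    if testable:
        with np.errstate(divide="ignore", invalid="ignore"):
            _, pvals = stats.f_oneway(a, b, axis=1)
        pvals = np.nan_to_num(pvals, nan=1.0)  # all values identical -> no evidence
    else:
        pvals = np.full(len(diff), np.nan)

    p_for_filter = pvals
    if adjust is not None:
        if adjust.lower() not in ("bh", "fdr_bh"):
            raise ValueError(f"unknown adjustment {adjust!r}")
        if testable:
            p_for_filter = multipletests(pvals, method="fdr_bh")[1]

    results = []
    for i, fid in enumerate(matrix.features):
        ok = bool(
            testable and abs(fc[i]) >= fc_min and p_for_filter[i] <= alpha
        )
        results.append(
            DEResult(
                feature_id=str(fid),
                fold_change=float(fc[i]),
                p_value=float(pvals[i]),
                passes_filter=ok,
                testable=testable,
            )
        )
    return results


def de_results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "fold_change": r.fold_change,
                "p_value": r.p_value,
                "passes_filter": r.passes_filter,
                "testable": r.testable,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# qPCR: relative quantitation by the ddCt method
# ---------------------------------------------------------------------------

QPCR_COLUMNS = ("sample", "group", "target_ct", "control_ct")


@dataclass
class QpcrResult:
    fold_change: float
    p_value: float
    ddct: float
    delta_ct: pd.DataFrame  # per-sample mean ΔCt with group label


def ddct_fold_change(
    table: pd.DataFrame, treated: str = "treated", control: str = "control"
) -> QpcrResult:
    """Relative fold change by the ΔΔCt method.

    ``table`` holds one row per technical replicate with columns
    ``sample, group, target_ct, control_ct`` (the endogenous-control Ct).
    Technical replicates are averaged per sample first; then

        ΔCt    = mean target Ct - mean endogenous-control Ct   (per sample)
        ΔΔCt   = mean ΔCt(treated) - mean ΔCt(control)
        fold   = 2 ** (-ΔΔCt)

    and the p-value is an unpaired two-sided t-test on per-sample ΔCt.

    Raises
    ------
    ValueError
        On missing columns, non-positive Ct values, a sample lacking the
        endogenous control, or a missing group.
    """
    missing = [c for c in QPCR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"qPCR table lacks columns: {missing}")
    if (table[["target_ct", "control_ct"]].to_numpy(dtype=float) <= 0).any():
        raise ValueError("Ct values must be positive")
    if table["control_ct"].isna().any():
        bad = table.loc[table["control_ct"].isna(), "sample"].unique()
        raise ValueError(f"missing endogenous control for samples: {list(bad)}")

    per_sample = (
        table.groupby(["sample", "group"], sort=True)[["target_ct", "control_ct"]]
        .mean()
        .reset_index()
    )
    per_sample["delta_ct"] = per_sample["target_ct"] - per_sample["control_ct"]

    dct = {}
    for g in (treated, control):
        sel = per_sample.loc[per_sample["group"] == g, "delta_ct"]
        if sel.empty:
            raise ValueError(f"group {g!r} absent from qPCR table")
        dct[g] = sel.to_numpy(dtype=float)

    ddct = float(dct[treated].mean() - dct[control].mean())
    fold = float(2.0 ** (-ddct))
    if len(dct[treated]) >= 2 and len(dct[control]) >= 2:
        with warnings.catch_warnings():
            # zero-variance groups (e.g. noise-free fixtures) are handled below
            warnings.simplefilter("ignore", RuntimeWarning)
            p = float(stats.ttest_ind(dct[treated], dct[control]).pvalue)
        if np.isnan(p):  # zero variance in both groups
            p = 1.0 if ddct == 0 else 0.0
    else:
        p = float("nan")
    return QpcrResult(
        fold_change=fold,
        p_value=p,
        ddct=ddct,
        delta_ct=per_sample[["sample", "group", "delta_ct"]],
    )
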