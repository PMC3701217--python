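"""Cross-omic integration of methylation, expression and genomic annotation.

Covers the downstream steps of the analysis: pairing deregulated miRNAs with
their predicted target genes under an inverse-expression constraint,
measuring concordance between promoter differential methylation and
differential expression, mapping features into named genomic region catalogs
(imprinted regions, CTCF sites), and a permutation test for region
enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .expression import DEResult
from .peaks import Peak

CONFIDENCE_RANK = {"predicted": 0, "low": 1, "moderate": 2, "high": 3}

PAIR_COLUMNS = ("mirna_id", "gene_id", "confidence", "tissue")

FEATURE_COORD_COLUMNS = ("feature_id", "chrom", "start", "end")


@dataclass
class IntervalCatalog:
    """Named sets of genomic intervals (0-based half-open, BED semantics).

    Each set is a DataFrame with columns ``chrom, start, end, name`` and
    optionally ``score, strand``.
    """

    sets: dict = field(default_factory=dict)

    def add(self, name: str, frame: pd.DataFrame) -> None:
        frame = frame.reset_index(drop=True)
        for col in ("chrom", "start", "end", "name"):
            if col not in frame.columns:
                raise ValueError(f"interval set {name!r} lacks column {col!r}")
        if (frame["start"].to_numpy() < 0).any():
            raise ValueError("negative interval coordinates")
        if (frame["start"].to_numpy() >= frame["end"].to_numpy()).any():
            raise ValueError("empty or inverted interval (start >= end)")
        if frame["name"].duplicated().any():
            raise ValueError(f"duplicate interval names in set {name!r}")
        self.sets[name] = frame

    def get(self, name: str) -> pd.DataFrame:
        return self.sets[name]

    def names(self) -> list[str]:
        return sorted(self.sets)

    def trees(self, name: str) -> dict:
        """Per-chromosome IntervalTree for one set (data = interval name)."""
        trees: dict = {}
        for row in self.get(name).itertuples(index=False):
            trees.setdefault(row.chrom, IntervalTree()).addi(
                int(row.start), int(row.end), row.name
            )
        return trees


def _de_index(results: list[DEResult]) -> dict:
    return {r.feature_id: r for r in results}


@dataclass
class PairFilterResult:
    pairs: pd.DataFrame               # retained rows of the input table
    per_gene_counts: pd.Series        # gene_id -> number of targeting miRNAs
    skipped: list = field(default_factory=list)  # (mirna, gene, reason)


def validate_pair_table(pairs: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PAIR_COLUMNS if c not in pairs.columns]
    if missing:
        raise ValueError(f"pair table lacks columns: {missing}")
    if pairs.duplicated(subset=["mirna_id", "gene_id"]).any():
        raise ValueError("duplicate (miRNA, gene) rows in pair table")
    bad = set(pairs["confidence"]) - set(CONFIDENCE_RANK)
    if bad:
        raise ValueError(f"unknown confidence labels: {sorted(bad)}")
    return pairs


def inverse_pair_filter(
    mirna_de: list[DEResult],
    gene_de: list[DEResult],
    pairs: pd.DataFrame,
    min_confidence: str = "moderate",
    tissue: str | None = "brain",
) -> PairFilterResult:
    """Retain predicted miRNA→gene pairs with inverse expression changes.

    A pair survives when (a) its interaction confidence is at least
    ``min_confidence``, (b) its tissue label matches ``tissue`` (skip the
    check with ``tissue=None``), (c) both members pass their differential
    expression filters, and (d) the miRNA and gene fold changes have opposite
    signs.  Pairs naming a feature absent from the DE results are logged in
    ``skipped`` and dropped, not an error.
    """
    pairs = validate_pair_table(pairs)
    if min_confidence not in CONFIDENCE_RANK:
        raise ValueError(f"unknown confidence {min_confidence!r}")
    min_rank = CONFIDENCE_RANK[min_confidence]
    mirna_idx = _de_index(mirna_de)
    gene_idx = _de_index(gene_de)

    keep_rows = []
    skipped = []
    for i, row in pairs.iterrows():
        m = mirna_idx.get(row["mirna_id"])
        g = gene_idx.get(row["gene_id"])
        if m is None or g is None:
            skipped.append((row["mirna_id"], row["gene_id"], "unknown_feature"))
            continue
        if CONFIDENCE_RANK[row["confidence"]] < min_rank:
            continue
        if tissue is not None and row["tissue"] != tissue:
            continue
        if not (m.passes_filter and g.passes_filter):
            continue
        if m.fold_change * g.fold_change >= 0:
            continue
        keep_rows.append(i)

    kept = pairs.loc[keep_rows].reset_index(drop=True)
    counts = kept.groupby("gene_id")["mirna_id"].nunique().sort_index()
    return PairFilterResult(pairs=kept, per_gene_counts=counts, skipped=skipped)


@dataclass
class ConcordanceReport:
    n_de_features: int
    n_with_promoter: int
    n_missing_promoter: int
    n_overlapping: int
    fraction: float          # DE features whose promoter holds >=1 DEP
    n_deps: int
    n_deps_in_de_promoters: int
    inverse_fraction: float  # DEPs overlapping >=1 DE-feature promoter


def promoter_concordance(
    dep_calls: list[Peak],
    de_results: list[DEResult],
    promoter_catalog: IntervalCatalog,
    set_name: str = "promoters",
) -> ConcordanceReport:
    """Concordance of promoter differential methylation with expression.

    Promoter interval names are feature ids.  Only accepted DEPs count; a DE
    feature without a promoter annotation is excluded from the denominator
    and reported separately.  Overlap is >=1 bp on half-open intervals.
    """
    accepted = [p for p in dep_calls if p.accepted is not False]
    dep_trees: dict = {}
    for p in accepted:
        dep_trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)

    promoters = promoter_catalog.get(set_name)
    prom_by_feature = {
        row.name: (row.chrom, int(row.start), int(row.end))
        for row in promoters.itertuples(index=False)
    }
    de_pass = [r for r in de_results if r.passes_filter]
    n_missing = sum(1 for r in de_pass if r.feature_id not in prom_by_feature)
    with_prom = [r for r in de_pass if r.feature_id in prom_by_feature]

    n_overlap = 0
    de_prom_trees: dict = {}
    for r in with_prom:
        chrom, start, end = prom_by_feature[r.feature_id]
        de_prom_trees.setdefault(chrom, IntervalTree()).addi(start, end, r.feature_id)
        tree = dep_trees.get(chrom)
        if tree is not None and tree.overlap(start, end):
            n_overlap += 1

    n_dep_hits = 0
    for p in accepted:
        tree = de_prom_trees.get(p.chrom)
        if tree is not None and tree.overlap(p.start, p.end):
            n_dep_hits += 1

    return ConcordanceReport(
        n_de_features=len(de_pass),
        n_with_promoter=len(with_prom),
        n_missing_promoter=n_missing,
        n_overlapping=n_overlap,
        fraction=(n_overlap / len(with_prom)) if with_prom else 0.0,
        n_deps=len(accepted),
        n_deps_in_de_promoters=n_dep_hits,
        inverse_fraction=(n_dep_hits / len(accepted)) if accepted else 0.0,
    )


@dataclass
class RegionMapping:
    membership: pd.DataFrame     # feature_id, region (one row per hit)
    per_region_counts: pd.Series
    n_features: int
    n_mapped: int
    fraction_mapped: float


def map_to_regions(
    features: pd.DataFrame,
    catalog: IntervalCatalog,
    set_name: str,
) -> RegionMapping:
    """Label features with every catalog region they overlap (>=1 bp).

    ``features`` needs columns ``feature_id, chrom, start, end``.  Features
    on chromosomes absent from the catalog are simply unmapped.
    """
    missing = [c for c in FEATURE_COORD_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    trees = catalog.trees(set_name)
    rows = []
    mapped_features = set()
    for row in features.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(int(row.start), int(row.end))):
            rows.append({"feature_id": row.feature_id, "region": hit.data})
            mapped_features.add(row.feature_id)
    membership = pd.DataFrame(rows, columns=["feature_id", "region"])
    region_names = list(catalog.get(set_name)["name"])
    counts = (
        membership.groupby("region")["feature_id"].nunique()
        .reindex(region_names, fill_value=0)
    )
    n = len(features)
    return RegionMapping(
        membership=membership,
        per_region_counts=counts,
        n_features=n,
        n_mapped=len(mapped_features),
        fraction_mapped=(len(mapped_features) / n) if n else 0.0,
    )


def region_enrichment(
    features: pd.DataFrame,
    catalog: IntervalCatalog,
    set_name: str,
    universe: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for region-membership enrichment of a feature set.

    Draws ``len(features)`` features from ``universe`` without replacement
    ``n_perm`` times and counts how often the number mapping into the catalog
    set reaches the observed count:

        p = (1 + #{permutations with count >= observed}) / (n_perm + 1)

    An observed count of zero can never beat any permutation, giving p = 1.

    Raises
    ------
    ValueError
        If the feature set is larger than the universe.
    """
    if len(features) > len(universe):
        raise ValueError("feature set larger than universe")
    observed = map_to_regions(features, catalog, set_name).n_mapped
    if observed == 0:
        return 1.0
    mapped_flags = (
        universe.set_index("feature_id")
        .index.to_series()
        .isin(map_to_regions(universe, catalog, set_name).membership["feature_id"])
        .to_numpy()
    )
    rng = np.random.default_rng(seed)
    k = len(features)
    hits = 0
    for _ in range(n_perm):
        draw = rng.choice(len(mapped_flags), size=k, replace=False)
        if mapped_flags[draw].sum() >= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)
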