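"""Inverse miRNA-target pairing, concordance, region mapping, enrichment."""

import numpy as np
import pandas as pd
import pytest

from medipdmr.expression import DEResult
from medipdmr.integrate import (
    IntervalCatalog,
    inverse_pair_filter,
    map_to_regions,
    promoter_concordance,
    region_enrichment,
)
from medipdmr.peaks import Peak


def _de(fid, fc, passes=True):
    return DEResult(feature_id=fid, fold_change=fc, p_value=0.01,
                    passes_filter=passes)


def _pairs(rows):
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "confidence",
                                       "tissue"])


class TestInversePairFilter:
    MIRNA = [_de("mirA", 1.3), _de("mirB", -1.5), _de("mirC", 1.4, passes=False)]
    GENE = [_de("g1", -1.25), _de("g2", 1.25), _de("g3", -1.3)]

    @pytest.mark.parametrize(
        "row,kept",
        [
            (("mirA", "g1", "high", "brain"), True),       # inverse, retained
            (("mirA", "g2", "high", "brain"), False),      # same sign
            (("mirA", "g1", "low", "brain"), False),       # confidence too low
            (("mirA", "g1", "moderate", "brain"), True),   # moderate suffices
            (("mirA", "g1", "high", "liver"), False),      # wrong tissue
            (("mirC", "g1", "high", "brain"), False),      # miRNA fails DE
        ],
    )
    def test_single_pair_decisions(self, row, kept):
        res = inverse_pair_filter(self.MIRNA, self.GENE, _pairs([row]))
        assert (len(res.pairs) == 1) is kept

    def test_unknown_feature_logged_and_skipped(self):
        res = inverse_pair_filter(
            self.MIRNA, self.GENE, _pairs([("mirX", "g1", "high", "brain")])
        )
        assert len(res.pairs) == 0
        assert res.skipped == [("mirX", "g1", "unknown_feature")]

    def test_per_gene_mirna_counts(self):
        rows = [
            ("mirA", "g1", "high", "brain"),
            ("mirB", "g2", "high", "brain"),
            ("mirA", "g3", "moderate", "brain"),
        ]
        res = inverse_pair_filter(self.MIRNA, self.GENE, _pairs(rows))
        assert res.per_gene_counts.to_dict() == {"g1": 1, "g2": 1, "g3": 1}

    def test_output_subset_and_confidence_monotone(self):
        rng = np.random.default_rng(0)
        confs = ["predicted", "low", "moderate", "high"]
        rows = [
            (f"mir{i}", f"g{i % 3}", confs[rng.integers(4)], "brain")
            for i in range(20)
        ]
        mirna = [_de(f"mir{i}", float(rng.choice([-1.5, 1.5]))) for i in range(20)]
        gene = [_de(f"g{i}", float(rng.choice([-1.5, 1.5]))) for i in range(3)]
        table = _pairs(rows)
        sizes = []
        for mc in confs:
            res = inverse_pair_filter(mirna, gene, table, min_confidence=mc)
            sizes.append(len(res.pairs))
            merged = res.pairs.merge(table, how="left", indicator=True)
            assert (merged["_merge"] == "both").all()  # subset of the input
        assert sizes == sorted(sizes, reverse=True)

    def test_duplicate_pairs_rejected(self):
        rows = [("mirA", "g1", "high", "brain")] * 2
        with pytest.raises(ValueError, match="duplicate"):
            inverse_pair_filter(self.MIRNA, self.GENE, _pairs(rows))


def _promoters(n, span=1000):
    return pd.DataFrame(
        {
            "chrom": [f"c{i}" for i in range(n)],
            "start": 0,
            "end": span,
            "name": [f"g{i}" for i in range(n)],
        }
    )


def _dep(chrom, start, end, accepted=True):
    return Peak(chrom=chrom, start=start, end=end, probe_ids=("p",),
                probe_pvalues=(0.001,), peak_score=3.0, probe_index=(0,),
                accepted=accepted)


class TestPromoterConcordance:
    def test_no_deps_fraction_zero(self):
        catalog = IntervalCatalog()
        catalog.add("promoters", _promoters(5))
        rep = promoter_concordance([], [_de("g0", 1.5)], catalog)
        assert rep.fraction == 0.0
        assert rep.n_overlapping == 0

    def test_reported_fraction_arithmetic(self):
        """21 of 129 DE features with DEP-bearing promoters → 0.1628."""
        catalog = IntervalCatalog()
        catalog.add("promoters", _promoters(129))
        de = [_de(f"g{i}", 1.5) for i in range(129)]
        deps = [_dep(f"c{i}", 100, 300) for i in range(21)]
        rep = promoter_concordance(deps, de, catalog)
        assert rep.n_overlapping == 21
        assert round(rep.fraction, 4) == 0.1628

    def test_missing_promoter_counted_separately(self):
        catalog = IntervalCatalog()
        catalog.add("promoters", _promoters(2))
        de = [_de("g0", 1.5), _de("unannotated", -1.4)]
        rep = promoter_concordance([_dep("c0", 0, 10)], de, catalog)
        assert rep.n_missing_promoter == 1
        assert rep.n_with_promoter == 1
        assert rep.fraction == 1.0

    def test_rejected_deps_ignored(self):
        catalog = IntervalCatalog()
        catalog.add("promoters", _promoters(1))
        rep = promoter_concordance(
            [_dep("c0", 0, 10, accepted=False)], [_de("g0", 1.5)], catalog
        )
        assert rep.fraction == 0.0


def _catalog_one_region():
    cat = IntervalCatalog()
    cat.add(
        "regions",
        pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [200], "name": ["R1"]}
        ),
    )
    return cat


def _features(rows):
    return pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end"])


class TestMapToRegions:
    def test_inside_and_overlap_semantics(self):
        cat = _catalog_one_region()
        feats = _features(
            [
                ("in", "chr1", 120, 150),        # wholly inside
                ("edge", "chr1", 200, 250),      # abuts end: NOT mapped
                ("spans", "chr1", 50, 101),      # 1 bp overlap: mapped
                ("elsewhere", "chr2", 120, 150), # chromosome not in catalog
            ]
        )
        m = map_to_regions(feats, cat, "regions")
        assert set(m.membership["feature_id"]) == {"in", "spans"}
        assert m.n_mapped == 2
        assert m.per_region_counts["R1"] == 2

    def test_quarter_fraction(self):
        """8 of 32 features planted inside regions → fraction 0.25."""
        cat = _catalog_one_region()
        rows = [(f"hit{i}", "chr1", 110 + i, 111 + i) for i in range(8)]
        rows += [(f"miss{i}", "chr1", 5000 + i * 10, 5001 + i * 10)
                 for i in range(24)]
        m = map_to_regions(_features(rows), cat, "regions")
        assert m.n_features == 32
        assert m.fraction_mapped == 0.25

    def test_multi_membership_allowed(self):
        cat = IntervalCatalog()
        cat.add(
            "regions",
            pd.DataFrame(
                {
                    "chrom": ["chr1", "chr1"],
                    "start": [100, 150],
                    "end": [200, 260],
                    "name": ["R1", "R2"],
                }
            ),
        )
        m = map_to_regions(_features([("f", "chr1", 160, 170)]), cat, "regions")
        assert len(m.membership) == 2
        assert m.n_mapped == 1


class TestRegionEnrichment:
    def test_features_equal_universe_p_one(self):
        cat = _catalog_one_region()
        universe = _features([("a", "chr1", 110, 120), ("b", "chr1", 500, 510)])
        p = region_enrichment(universe, cat, "regions", universe, n_perm=99)
        assert p == 1.0

    def test_zero_observed_p_one(self):
        cat = _catalog_one_region()
        universe = _features(
            [("a", "chr1", 500, 510), ("b", "chr1", 110, 120),
             ("c", "chr1", 600, 610)]
        )
        feats = universe.iloc[[0, 2]]
        assert region_enrichment(feats, cat, "regions", universe, 99) == 1.0

    def test_planted_enrichment_detected(self):
        """A strongly enriched subset earns p <= 0.01 across seeds."""
        cat = _catalog_one_region()
        rows = [(f"in{i}", "chr1", 110 + i, 111 + i) for i in range(10)]
        rows += [(f"out{i}", "chr1", 10_000 + i * 10, 10_001 + i * 10)
                 for i in range(90)]
        universe = _features(rows)
        feats = universe.iloc[:10]  # all ten mapped
        for seed in range(20):
            p = region_enrichment(feats, cat, "regions", universe,
                                  n_perm=999, seed=seed)
            assert p <= 0.01

    def test_superuniform_under_null(self):
        """Null draws give conservative (super-uniform) p-values."""
        cat = _catalog_one_region()
        rows = [(f"in{i}", "chr1", 110 + i, 111 + i) for i in range(10)]
        rows += [(f"out{i}", "chr1", 10_000 + i * 10, 10_001 + i * 10)
                 for i in range(90)]
        universe = _features(rows)
        rng = np.random.default_rng(0)
        pvals = []
        for k in range(200):
            idx = rng.choice(100, size=15, replace=False)
            pvals.append(
                region_enrichment(universe.iloc[idx], cat, "regions",
                                  universe, n_perm=99, seed=1000 + k)
            )
        pvals = np.asarray(pvals)
        for alpha in (0.05, 0.1, 0.25):
            slack = 2.6 * np.sqrt(alpha * (1 - alpha) / len(pvals))
            assert np.mean(pvals <= alpha) <= alpha + slack

    def test_feature_set_larger_than_universe_rejected(self):
        cat = _catalog_one_region()
        universe = _features([("a", "chr1", 110, 120)])
        feats = _features([("a", "chr1", 110, 120), ("b", "chr1", 1, 2)])
        with pytest.raises(ValueError, match="universe"):
            region_enrichment(feats, cat, "regions", universe, 9)


def test_catalog_validation():
    cat = IntervalCatalog()
    with pytest.raises(ValueError, match="start >= end"):
        cat.add("bad", pd.DataFrame(
            {"chrom": ["c"], "start": [10], "end": [10], "name": ["x"]}
        ))
    with pytest.raises(ValueError, match="negative"):
        cat.add("bad", pd.DataFrame(
            {"chrom": ["c"], "start": [-1], "end": [10], "name": ["x"]}
        ))
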