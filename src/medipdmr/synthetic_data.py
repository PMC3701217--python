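"""Synthetic data generator emulating the study's array structure.

Generates, with known planted truth: promoter tiling-array probe tracks (two
groups, replicated, Gaussian log2-ratio noise, planted differentially
methylated regions), miRNA and gene expression matrices with planted inverse
miRNA→target pairs, a target-prediction table with confidence/tissue labels,
interval catalogs (promoters, three imprinted regions, CTCF sites, miRNA
loci) and qPCR Ct tables — so every downstream stage is testable without
external data.

Model sketch
------------
Each promoter occupies its own synthetic chromosome, tiled with fixed-length
probes at fixed spacing across a window spanning (by default) 8.2 kb upstream
to 3 kb downstream of the TSS.  A planted DMR is one sub-interval per
selected promoter: both groups gain a +0.5 log2 baseline plateau there (a
methylated locus is enriched over input in *both* conditions) and the treated
group additionally gains the signed differential effect.  Noise is iid
Gaussian on log2 ratios per replicate; there is no probe-affinity structure.

Expression effects are tied to the methylation truth: the gene behind each
DMR promoter is planted as differentially expressed with sign opposite to the
methylation change, and each such gene is targeted by 1–3 planted miRNAs with
fold changes inverse to the gene's.  Decoy pairs (same-direction, low
confidence, wrong tissue, null features) exercise the downstream filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .integrate import IntervalCatalog
from .normalize import ProbeTrack
from .peaks import Peak

IMPRINTED_REGIONS = (
    # synthetic stand-ins named by analogy to the murine imprinted clusters
    ("chr2", 1_000_000, 1_250_000, "Sfmbt2_region"),
    ("chr7", 3_000_000, 3_400_000, "Snrpn-Ube3a_region"),
    ("chr12", 5_000_000, 5_500_000, "Dlk1-Dio3_region"),
)

_OTHER_CHROMS = ("chr1", "chr3", "chr5", "chr9", "chr15")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults emulate the source study's design: promoter windows of about
    -8.2 kb..+3 kb around the TSS, three biological replicates per group for
    methylation and expression, and a planted differential-methylation effect
    of 1.0 log2 unit over 750 bp at noise sd 0.3.
    """

    n_promoters: int = 40
    promoter_span: tuple[int, int] = (8200, 3000)  # (upstream, downstream) bp
    probe_spacing: int = 100
    probe_length: int = 50
    n_replicates_per_group: int = 3
    dmr_fraction: float = 0.25
    dmr_effect: float = 1.0          # mean M' shift, log2 units
    dmr_width: int = 750
    noise_sd: float = 0.3            # log2 units
    seed: int = 0
    # secondary knobs (defaulted; not part of the core study conditions)
    dmr_baseline: float = 0.5        # methylated-locus enrichment, both groups
    n_mirnas: int = 150
    n_genes: int = 400
    expression_effect_range: tuple[float, float] = (0.3, 0.65)  # |log2 FC|
    mirna_imprinted_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be positive")
        if not (0.0 <= self.dmr_fraction <= 1.0):
            raise ValueError("dmr_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_replicates_per_group < 1:
            raise ValueError("need at least one replicate per group")
        if min(self.promoter_span) < 0 or sum(self.promoter_span) <= 0:
            raise ValueError("invalid promoter_span")
        if self.n_genes < self.n_promoters:
            raise ValueError("n_genes must be >= n_promoters")

    @property
    def span_total(self) -> int:
        return int(sum(self.promoter_span))

    def chrom(self, i: int) -> str:
        return f"syn{i + 1:04d}"

    def gene_id(self, i: int) -> str:
        return f"gene_{i + 1:04d}"

    def mirna_id(self, i: int) -> str:
        return f"mir_{i + 1:04d}"


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator."""

    dmr_intervals: pd.DataFrame   # chrom, start, end, effect (signed log2)
    de_features: pd.DataFrame     # feature_id, kind, true_log2fc
    inverse_pairs: pd.DataFrame   # mirna_id, gene_id


def _seeds(config: SimulationConfig) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(config.seed).spawn(4)  # design/tiling/expr/qpcr


@dataclass
class _Design:
    """Deterministic planted layout shared by all generator outputs."""

    dmr_promoters: np.ndarray     # promoter indices carrying a DMR
    dmr_starts: np.ndarray
    dmr_effects: np.ndarray       # signed
    gene_fc: dict                 # gene_id -> true log2 fold change
    mirna_fc: dict                # mirna_id -> true log2 fold change
    inverse_pairs: list           # (mirna_id, gene_id)
    decoy_pairs: list             # rows for the target table
    mirna_loci: pd.DataFrame      # feature_id, chrom, start, end
    ctcf_sites: pd.DataFrame      # chrom, start, end, name


def _build_design(config: SimulationConfig) -> _Design:
    rng = np.random.default_rng(_seeds(config)[0])
    n_dmr = int(round(config.dmr_fraction * config.n_promoters))
    dmr_promoters = np.sort(
        rng.choice(config.n_promoters, size=n_dmr, replace=False)
    )
    dmr_starts = rng.integers(
        0, max(config.span_total - config.dmr_width, 0) + 1, size=n_dmr
    )
    signs = rng.choice([-1.0, 1.0], size=n_dmr)
    dmr_effects = signs * config.dmr_effect

    lo, hi = config.expression_effect_range
    gene_fc = {}
    mirna_fc = {}
    inverse_pairs = []
    mirna_pool = list(range(config.n_mirnas))
    rng.shuffle(mirna_pool)
    for j, prom in enumerate(dmr_promoters):
        gid = config.gene_id(int(prom))
        # expression moves opposite to promoter methylation
        g_sign = -np.sign(dmr_effects[j]) or 1.0
        gene_fc[gid] = float(g_sign * rng.uniform(lo, hi))
        for _ in range(int(rng.integers(1, 4))):
            if not mirna_pool:
                break
            mid = config.mirna_id(mirna_pool.pop())
            mirna_fc[mid] = float(-g_sign * rng.uniform(lo, hi))
            inverse_pairs.append((mid, gid))

    decoys = _build_decoys(config, rng, gene_fc, mirna_fc, mirna_pool,
                           inverse_pairs)
    mirna_loci = _place_mirnas(config, rng, mirna_fc)
    ctcf = _place_ctcf(config, rng)
    return _Design(
        dmr_promoters=dmr_promoters,
        dmr_starts=dmr_starts,
        dmr_effects=dmr_effects,
        gene_fc=gene_fc,
        mirna_fc=mirna_fc,
        inverse_pairs=inverse_pairs,
        decoy_pairs=decoys,
        mirna_loci=mirna_loci,
        ctcf_sites=ctcf,
    )


def _build_decoys(config, rng, gene_fc, mirna_fc, mirna_pool, planted) -> list:
    """Target-table rows that must NOT survive the inverse-pair filter."""
    decoys = []
    de_genes = sorted(gene_fc)
    de_mirnas = sorted(mirna_fc)
    existing = set(planted)

    def fresh(m, g):
        if (m, g) in existing:
            return False
        existing.add((m, g))
        return True

    # same-direction pairs among planted DE features (high confidence, brain)
    for g in de_genes:
        same = [m for m in de_mirnas if mirna_fc[m] * gene_fc[g] > 0]
        if same:
            m = same[int(rng.integers(len(same)))]
            if fresh(m, g):
                decoys.append((m, g, "high", "brain"))
    # low-confidence but otherwise inverse pairs
    for g in de_genes[: max(1, len(de_genes) // 2)]:
        inv = [m for m in de_mirnas if mirna_fc[m] * gene_fc[g] < 0]
        if inv:
            m = inv[int(rng.integers(len(inv)))]
            if fresh(m, g):
                decoys.append((m, g, "low", "brain"))
    # wrong-tissue inverse pair
    if de_genes and de_mirnas:
        g = de_genes[0]
        inv = [m for m in de_mirnas if mirna_fc[m] * gene_fc[g] < 0]
        if inv and fresh(inv[0], f"{g}"):
            decoys.append((inv[0], g, "high", "liver"))
    # null-feature pairs (no planted change on either side)
    null_genes = [
        config.gene_id(i)
        for i in range(config.n_genes)
        if config.gene_id(i) not in gene_fc
    ]
    null_mirnas = [config.mirna_id(i) for i in mirna_pool]
    for _ in range(min(10, len(null_genes), len(null_mirnas))):
        m = null_mirnas[int(rng.integers(len(null_mirnas)))]
        g = null_genes[int(rng.integers(len(null_genes)))]
        if fresh(m, g):
            decoys.append((m, g, "high", "brain"))
    return decoys


def _place_mirnas(config, rng, mirna_fc) -> pd.DataFrame:
    """Genomic loci for every miRNA; a fraction of the DE ones fall inside
    the imprinted-region catalog, everything else lands elsewhere."""
    rows = []
    de = sorted(mirna_fc)
    n_imp = int(round(config.mirna_imprinted_fraction * len(de)))
    imprinted_set = set(de[:n_imp])  # ids are already rng-shuffled at pairing
    for i in range(config.n_mirnas):
        mid = config.mirna_id(i)
        if mid in imprinted_set:
            chrom, rstart, rend, _ = IMPRINTED_REGIONS[
                int(rng.integers(len(IMPRINTED_REGIONS)))
            ]
            start = int(rng.integers(rstart, rend - 80))
        else:
            chrom = _OTHER_CHROMS[int(rng.integers(len(_OTHER_CHROMS)))]
            start = int(rng.integers(0, 10_000_000))
        rows.append(
            {"feature_id": mid, "chrom": chrom, "start": start, "end": start + 80}
        )
    return pd.DataFrame(rows)


def _place_ctcf(config, rng) -> pd.DataFrame:
    rows = []
    for k, (chrom, rstart, rend, rname) in enumerate(IMPRINTED_REGIONS):
        pos = int((rstart + rend) // 2)
        rows.append(
            {"chrom": chrom, "start": pos, "end": pos + 20, "name": f"ctcf_imp_{k}"}
        )
    for i in range(config.n_promoters):
        if rng.random() < 0.3:
            pos = int(rng.integers(0, config.span_total - 20))
            rows.append(
                {
                    "chrom": config.chrom(i),
                    "start": pos,
                    "end": pos + 20,
                    "name": f"ctcf_syn_{i}",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _truth(config: SimulationConfig, design: _Design) -> PlantedTruth:
    dmr = pd.DataFrame(
        {
            "chrom": [config.chrom(int(i)) for i in design.dmr_promoters],
            "start": design.dmr_starts.astype(int),
            "end": (design.dmr_starts + config.dmr_width).astype(int),
            "effect": design.dmr_effects,
        }
    )
    de_rows = [
        {"feature_id": g, "kind": "gene", "true_log2fc": fc}
        for g, fc in sorted(design.gene_fc.items())
    ] + [
        {"feature_id": m, "kind": "mirna", "true_log2fc": fc}
        for m, fc in sorted(design.mirna_fc.items())
    ]
    de = pd.DataFrame(de_rows, columns=["feature_id", "kind", "true_log2fc"])
    pairs = pd.DataFrame(design.inverse_pairs, columns=["mirna_id", "gene_id"])
    return PlantedTruth(dmr_intervals=dmr, de_features=de, inverse_pairs=pairs)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def simulate_tiling(config: SimulationConfig) -> tuple[ProbeTrack, PlantedTruth]:
    """Simulate the promoter tiling MeDIP-chip probe track.

    Per-probe, per-replicate log2(MeDIP/Input) = baseline (+0.5 inside a
    planted DMR, both groups) + signed DMR effect (treated group only, inside
    the DMR) + iid N(0, noise_sd).  Probes are sorted by (chrom, start) and
    the identical config/seed is bit-reproducible.

    Raises
    ------
    ValueError
        If ``dmr_width < 2 * probe_spacing`` (a planted DMR must be able to
        contain at least two probes, the caller's minimum).
    """
    if config.dmr_width < 2 * config.probe_spacing:
        raise ValueError("dmr_width must be >= 2 * probe_spacing")
    design = _build_design(config)
    rng = np.random.default_rng(_seeds(config)[1])

    starts = np.arange(
        0, config.span_total - config.probe_length + 1, config.probe_spacing
    )
    n_pp = len(starts)
    n_probes = n_pp * config.n_promoters
    chroms = np.repeat([config.chrom(i) for i in range(config.n_promoters)], n_pp)
    all_starts = np.tile(starts, config.n_promoters)
    all_ends = all_starts + config.probe_length

    baseline = np.zeros(n_probes)
    effect = np.zeros(n_probes)
    for j, prom in enumerate(design.dmr_promoters):
        lo = int(prom) * n_pp
        s, e = int(design.dmr_starts[j]), int(design.dmr_starts[j]) + config.dmr_width
        inside = (all_starts[lo : lo + n_pp] < e) & (all_ends[lo : lo + n_pp] > s)
        baseline[lo : lo + n_pp][inside] += config.dmr_baseline
        effect[lo : lo + n_pp][inside] = design.dmr_effects[j]

    nrep = config.n_replicates_per_group
    data = {
        "probe_id": [f"p{i + 1:06d}" for i in range(n_probes)],
        "chrom": chroms,
        "start": all_starts,
        "end": all_ends,
    }
    for group, eff in (("treated", effect), ("control", 0.0)):
        for r in range(nrep):
            noise = rng.normal(0.0, config.noise_sd, size=n_probes)
            data[f"{group}_{r + 1}"] = baseline + eff + noise
    track = ProbeTrack(pd.DataFrame(data))
    return track, _truth(config, design)


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, PlantedTruth]:
    """Simulate miRNA and gene log2 expression matrices plus the target table.

    Planted fold changes are added to the treated group, so the realized
    group-mean difference equals the planted log2 FC exactly at zero noise.
    Planted inverse pairs enter the target table with confidence ``high`` and
    tissue ``brain``; decoy pairs (same-direction, low-confidence,
    wrong-tissue, null-feature) are included.
    """
    design = _build_design(config)
    rng = np.random.default_rng(_seeds(config)[2])
    nrep = config.n_replicates_per_group
    cols = [f"treated_{r + 1}" for r in range(nrep)] + [
        f"control_{r + 1}" for r in range(nrep)
    ]

    def build_matrix(ids: list, fc_map: dict) -> ExpressionMatrix:
        base = rng.normal(8.0, 1.5, size=len(ids))
        values = pd.DataFrame(index=pd.Index(ids, name="feature_id"), columns=cols,
                              dtype=float)
        for c in cols:
            noise = rng.normal(0.0, config.noise_sd, size=len(ids))
            shift = np.array(
                [fc_map.get(fid, 0.0) if c.startswith("treated") else 0.0
                 for fid in ids]
            )
            values[c] = base + shift + noise
        return ExpressionMatrix(values)

    mirna_ids = [config.mirna_id(i) for i in range(config.n_mirnas)]
    gene_ids = [config.gene_id(i) for i in range(config.n_genes)]
    mirna_mat = build_matrix(mirna_ids, design.mirna_fc)
    gene_mat = build_matrix(gene_ids, design.gene_fc)

    rows = [
        {"mirna_id": m, "gene_id": g, "confidence": "high", "tissue": "brain"}
        for m, g in design.inverse_pairs
    ] + [
        {"mirna_id": m, "gene_id": g, "confidence": conf, "tissue": tis}
        for m, g, conf, tis in design.decoy_pairs
    ]
    pair_table = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "confidence",
                                             "tissue"])
    pair_table = pair_table.drop_duplicates(subset=["mirna_id", "gene_id"])
    return mirna_mat, gene_mat, pair_table.reset_index(drop=True), _truth(
        config, design
    )


def make_catalogs(config: SimulationConfig) -> IntervalCatalog:
    """Interval catalogs: promoters, imprinted regions, CTCF sites, miRNA loci.

    All sets are 0-based half-open.  Promoter names are the gene ids of the
    corresponding expression features; the three imprinted regions sit on
    distinct chromosomes.
    """
    design = _build_design(config)
    catalog = IntervalCatalog()
    catalog.add(
        "promoters",
        pd.DataFrame(
            {
                "chrom": [config.chrom(i) for i in range(config.n_promoters)],
                "start": 0,
                "end": config.span_total,
                "name": [config.gene_id(i) for i in range(config.n_promoters)],
            }
        ),
    )
    catalog.add(
        "imprinted",
        pd.DataFrame(IMPRINTED_REGIONS, columns=["chrom", "start", "end", "name"]),
    )
    catalog.add("ctcf", design.ctcf_sites)
    loci = design.mirna_loci.rename(columns={"feature_id": "name"})
    catalog.add("mirna_loci", loci[["chrom", "start", "end", "name"]])
    return catalog


def mirna_annotation(config: SimulationConfig) -> pd.DataFrame:
    """miRNA genomic coordinates as a feature table (feature_id, chrom, ...)."""
    return _build_design(config).mirna_loci.copy()


def simulate_qpcr(
    config: SimulationConfig,
    fold_change: float = 1.45,
    n_biological: int = 6,
    n_technical: int = 3,
    ct_sd: float = 0.15,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table for one target against an endogenous control.

    Defaults emulate a single-assay validation: six biological replicates per
    group, three technical replicates averaged downstream, a planted
    ``fold_change`` (treated over control) realized as a -log2(fold) shift of
    the treated target Ct.
    """
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    rng = np.random.default_rng(_seeds(config)[3])
    rows = []
    for group in ("treated", "control"):
        for b in range(n_biological):
            control_level = rng.normal(19.0, 0.3)
            target_level = control_level + 6.0
            if group == "treated":
                target_level -= np.log2(fold_change)
            for _ in range(n_technical):
                rows.append(
                    {
                        "sample": f"{group}_{b + 1}",
                        "group": group,
                        "target_ct": target_level + rng.normal(0, ct_sd),
                        "control_ct": control_level + rng.normal(0, ct_sd),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth scoring
# ---------------------------------------------------------------------------


def score_recovery(
    peaks: list[Peak], truth: PlantedTruth
) -> dict:
    """Recovery and false-discovery of accepted DEPs against planted DMRs.

    A planted DMR counts as recovered when any accepted DEP overlaps it by at
    least 1 bp; an accepted DEP overlapping no planted DMR is a false
    discovery.
    """
    accepted = [p for p in peaks if p.accepted]
    dmrs = truth.dmr_intervals
    recovered = 0
    for row in dmrs.itertuples(index=False):
        if any(
            p.chrom == row.chrom and p.start < row.end and p.end > row.start
            for p in accepted
        ):
            recovered += 1
    false = 0
    for p in accepted:
        hit = any(
            p.chrom == row.chrom and p.start < row.end and p.end > row.start
            for row in dmrs.itertuples(index=False)
        )
        if not hit:
            false += 1
    n_dmr = len(dmrs)
    n_acc = len(accepted)
    return {
        "n_planted": n_dmr,
        "n_recovered": recovered,
        "recovery": recovered / n_dmr if n_dmr else float("nan"),
        "n_accepted": n_acc,
        "n_false": false,
        "false_discovery_rate": false / n_acc if n_acc else 0.0,
    }
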