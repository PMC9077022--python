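"""Diet metrics: relative read abundance (RRA), frequency of occurrence
(FOO), camera-based relative scaled biomass contribution (RSBC), alpha
diversity and rarefaction.

RRA is per-sample: reads are summed by taxon at a chosen rank (order or
family), parasite orders are optionally excluded, and the remainder is
renormalized to fractions.  Aggregation across samples is the two-step rule:
first a percentage per sample, then an unweighted average of those
percentages.  RSBC sums camera size multipliers by taxon per session and
normalizes.  OTUs or items unresolved at the chosen rank pool into an
explicit "unknown" taxon, which is excluded (and the profile renormalized)
before cross-method correlations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .amplicon import OtuTable
from .synthetic import PARASITE_ORDERS, CameraItem, RANKS

UNKNOWN = "unknown"


@dataclass(frozen=True)
class DietProfile:
    """Per-unit relative abundance vector at a fixed rank.

    ``basis`` records whether proportions come from reads (RRA) or from
    scaled biomass (RSBC); non-empty profiles sum to 1 within 1e-9."""

    unit_id: str
    rank: str
    proportions: dict[str, float]
    basis: str  # "reads" | "biomass"

    def __post_init__(self):
        if self.proportions:
            total = sum(self.proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.unit_id}: proportions sum to {total}, not 1"
                )


def _rank_index(rank: str) -> int:
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    return RANKS.index(rank)


def taxon_at_rank(lineage, rank: str) -> str:
    """Taxon name at ``rank``, or "unknown" when unresolved there."""
    name = lineage[_rank_index(rank)]
    return name if name else UNKNOWN


def counts_by_taxon(
    table: OtuTable, taxonomy: pd.DataFrame, rank: str
) -> pd.DataFrame:
    """Collapse an OTU table to taxon x sample read counts at ``rank``.

    OTUs missing from the taxonomy, unassigned, or blank at the rank pool
    into "unknown".  A parallel "order" annotation is carried so parasite
    exclusion works at any rank."""
    idx = _rank_index(rank)
    taxa, orders = [], []
    for otu in table.otus:
        if otu in taxonomy.index:
            row = taxonomy.loc[otu]
            lineage = [row[r] for r in RANKS]
            taxa.append(lineage[idx] if lineage[idx] else UNKNOWN)
            orders.append(lineage[3] if lineage[3] else UNKNOWN)
        else:
            taxa.append(UNKNOWN)
            orders.append(UNKNOWN)
    df = table.counts.copy()
    df["_taxon"] = taxa
    df["_order"] = orders
    grouped = df.groupby(["_taxon", "_order"]).sum()
    grouped.index.names = ["taxon", "order"]
    return grouped


def compute_rra(
    table: OtuTable,
    taxonomy: pd.DataFrame,
    rank: str,
    exclude: frozenset[str] | set[str] | None = PARASITE_ORDERS,
) -> list[DietProfile]:
    """Relative read abundance per sample at ``rank``.

    Excluded orders are dropped before renormalization; samples with no
    remaining reads yield an empty profile with a warning."""
    grouped = counts_by_taxon(table, taxonomy, rank)
    if exclude:
        keep = [o not in exclude for o in grouped.index.get_level_values("order")]
        grouped = grouped[keep]
    by_taxon = grouped.groupby(level="taxon").sum()
    profiles = []
    for sample in table.samples:
        col = by_taxon[sample]
        total = col.sum()
        if total == 0:
            warnings.warn(f"sample {sample}: no reads left after exclusions")
            profiles.append(DietProfile(sample, rank, {}, "reads"))
            continue
        props = {t: c / total for t, c in col.items() if c > 0}
        profiles.append(DietProfile(sample, rank, props, "reads"))
    return profiles


def aggregate_mean_rra(profiles: list[DietProfile]) -> pd.DataFrame:
    """Two-step mean: per-unit fractions first, then an unweighted average
    across units (absent taxa contribute 0).  Returns mean and SD per taxon."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    ranks = {p.rank for p in profiles}
    bases = {p.basis for p in profiles}
    if len(ranks) > 1 or len(bases) > 1:
        raise ValueError("profiles must share rank and basis")
    mat = profile_matrix(profiles)
    return pd.DataFrame(
        {"mean": mat.mean(axis=0), "sd": mat.std(axis=0, ddof=1) if len(mat) > 1
         else 0.0}
    )


def profile_matrix(profiles: list[DietProfile]) -> pd.DataFrame:
    """Units x taxa proportion matrix (absent taxa = 0)."""
    return (
        pd.DataFrame(
            {p.unit_id: pd.Series(p.proportions, dtype=float) for p in profiles}
        )
        .fillna(0.0)
        .T.sort_index(axis=1)
    )


def drop_unknown(profile: DietProfile) -> DietProfile:
    """Remove the "unknown" taxon and renormalize (for cross-method
    correlations, which pair named taxa only)."""
    props = {t: v for t, v in profile.proportions.items() if t != UNKNOWN}
    total = sum(props.values())
    if total > 0:
        props = {t: v / total for t, v in props.items()}
    return DietProfile(profile.unit_id, profile.rank, props, profile.basis)


def compute_foo(
    unit_counts: dict[str, dict[str, float]], min_reads: int = 1
) -> dict[str, int]:
    """Frequency of occurrence: number of units where each taxon's count is
    at least ``min_reads``."""
    taxa = sorted({t for counts in unit_counts.values() for t in counts})
    return {
        t: sum(1 for counts in unit_counts.values() if counts.get(t, 0) >= min_reads)
        for t in taxa
    }


def table_unit_counts(
    table: OtuTable, taxonomy: pd.DataFrame, rank: str,
    exclude: frozenset[str] | set[str] | None = None,
) -> dict[str, dict[str, float]]:
    """Per-sample taxon read counts at ``rank`` (FOO input)."""
    grouped = counts_by_taxon(table, taxonomy, rank)
    if exclude:
        keep = [o not in exclude for o in grouped.index.get_level_values("order")]
        grouped = grouped[keep]
    by_taxon = grouped.groupby(level="taxon").sum()
    return {
        s: {t: float(c) for t, c in by_taxon[s].items() if c > 0}
        for s in table.samples
    }


def camera_unit_counts(
    items: list[CameraItem], rank: str, weighted: bool = True,
    exclude: frozenset[str] | set[str] | None = None,
) -> dict[str, dict[str, float]]:
    """Per-session taxon totals from camera items: size-multiplier-weighted
    scaled biomass (default) or raw delivery counts."""
    out: dict[str, dict[str, float]] = {}
    for it in items:
        if exclude and taxon_at_rank(it.lineage, "order") in exclude:
            continue
        taxon = taxon_at_rank(it.lineage, rank)
        sess = out.setdefault(it.session_id, {})
        sess[taxon] = sess.get(taxon, 0.0) + (it.size_multiplier if weighted else 1.0)
    return out


def compute_rsbc(
    items: list[CameraItem],
    rank: str,
    exclude: frozenset[str] | set[str] | None = PARASITE_ORDERS,
) -> list[DietProfile]:
    """Relative scaled biomass contribution per camera session at ``rank``:
    size multipliers summed by taxon and normalized, items unresolved at the
    rank pooled as "unknown"."""
    sessions = camera_unit_counts(items, rank, weighted=True, exclude=exclude)
    profiles = []
    for sess_id in sorted(sessions):
        counts = sessions[sess_id]
        total = sum(counts.values())
        props = {t: v / total for t, v in counts.items()} if total > 0 else {}
        profiles.append(DietProfile(sess_id, rank, props, "biomass"))
    return profiles


def alpha_diversity(
    counts: dict[str, float] | np.ndarray, integerize: bool = False
) -> tuple[int, float]:
    """(richness, Shannon H) for one unit's taxon counts.

    With ``integerize`` (camera scaled biomass), counts are rounded half-up
    to integers first; all-zero units give richness 0 and H = 0."""
    vals = np.asarray(
        list(counts.values()) if isinstance(counts, dict) else counts, dtype=float
    )
    if (vals < 0).any():
        raise ValueError("counts must be >= 0")
    if integerize:
        vals = np.floor(vals + 0.5)
    vals = vals[vals > 0]
    if vals.size == 0:
        return 0, 0.0
    p = vals / vals.sum()
    return int(vals.size), float(-(p * np.log(p)).sum())


def rarefaction_curve(
    read_taxa: list[str],
    depths: list[int],
    n_rep: int = 10,
    seed: int = 0,
) -> dict[int, float]:
    """Mean number of distinct taxa found in subsamples of each depth,
    subsampling reads without replacement ``n_rep`` times."""
    total = len(read_taxa)
    if any(d > total for d in depths):
        raise ValueError("rarefaction depth exceeds total reads")
    rng = np.random.default_rng(seed)
    labels = np.asarray(read_taxa)
    out = {}
    for d in depths:
        if d == total:
            out[d] = float(len(set(read_taxa)))
            continue
        richness = [
            len(np.unique(labels[rng.choice(total, size=d, replace=False)]))
            for _ in range(n_rep)
        ]
        out[d] = float(np.mean(richness))
    return out


def read_camera_tsv(path) -> list[CameraItem]:
    """Load camera records written by the simulator / field scoring."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        CameraItem(
            session_id=row["session_id"],
            item_id=row["item_id"],
            lineage=tuple(row[r] for r in RANKS),
            size_multiplier=float(row["size_multiplier"]),
        )
        for _, row in df.iterrows()
    ]


def profiles_to_frame(profiles: list[DietProfile]) -> pd.DataFrame:
    """Tidy long format: unit_id, rank, taxon, proportion, basis."""
    rows = [
        (p.unit_id, p.rank, t, v, p.basis)
        for p in profiles
        for t, v in sorted(p.proportions.items())
    ]
    return pd.DataFrame(
        rows, columns=["unit_id", "rank", "taxon", "proportion", "basis"]
    )


def expected_rarefied_richness(taxon_counts: dict[str, int], depth: int) -> float:
    """Closed-form expected richness at ``depth`` under hypergeometric
    subsampling (the analytic counterpart of :func:`rarefaction_curve`)."""
    total = sum(taxon_counts.values())
    return float(
        sum(1.0 - hypergeom.pmf(0, total, c, depth) for c in taxon_counts.values())
    )
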