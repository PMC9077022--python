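"""Read processing: merge, truncate, expected-error filter, dereplicate,
greedy 97% OTU clustering with chimera removal, read mapping, and
negative-control subtraction.

The stages mirror a classic UPARSE-style amplicon workflow.  All
tie-breaking is deterministic: unique sequences are ordered by
(abundance desc, sequence asc) and best-hit ties go to the
earliest-created centroid, so repeated runs give identical OTU tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import global_identity, oriented_identity, revcomp


class MalformedInputError(ValueError):
    """Raised for reads whose sequence and quality lengths disagree."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadPair:
    id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: str  # Phred+33
    rev_qual: str

    def __post_init__(self):
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(
            self.rev_qual
        ):
            raise MalformedInputError(
                f"read {self.id}: sequence/quality length mismatch"
            )


@dataclass
class MergedRead:
    id: str
    seq: str
    qual: np.ndarray  # integer Phred scores, one per base
    passed_filter: bool = True

    def expected_errors(self) -> float:
        return float(np.sum(10.0 ** (-self.qual.astype(float) / 10.0)))


@dataclass(frozen=True)
class UniqueSeq:
    seq: str  # canonical orientation: lexicographically smaller of seq/revcomp
    abundance: int
    member_ids: tuple[str, ...]


@dataclass(frozen=True)
class Otu:
    otu_id: str
    centroid: str
    size: int


@dataclass
class OtuTable:
    """Integer count matrix with OTUs as rows and samples as columns."""

    counts: pd.DataFrame
    centroids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("OTU table contains negative counts")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("OTU table ids must be unique")

    @property
    def otus(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class PipelineSettings:
    """Defaults follow the published workflow: 25 bp primer truncation per
    end, 220 bp read truncation, max expected errors 0.4, 97% OTU radius and
    97% mapping identity."""

    primer_trunc: int = 25
    trunc_len: int = 220
    max_ee: float = 0.4
    otu_identity: float = 0.97
    map_identity: float = 0.97
    min_overlap: int = 16
    max_overlap_diff_rate: float = 0.1
    remove_singletons: bool = True

    def __post_init__(self):
        if not (0 < self.otu_identity <= 1 and 0 < self.map_identity <= 1):
            raise ValueError("identities must lie in (0, 1]")
        if self.max_ee <= 0:
            raise ValueError("max_ee must be > 0")
        if self.primer_trunc < 0:
            raise ValueError("primer_trunc must be >= 0")
        if self.trunc_len <= 0:
            raise ValueError("trunc_len must be > 0")
        if self.min_overlap < 1 or not (0 <= self.max_overlap_diff_rate <= 1):
            raise ValueError("invalid merge parameters")


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def _to_matrix(strings: list[str]) -> np.ndarray:
    return np.frombuffer("".join(strings).encode(), np.uint8).reshape(
        len(strings), -1
    )


def merge_pairs(
    pairs: list[ReadPair], min_overlap: int = 16, max_diff_rate: float = 0.1
) -> list[MergedRead]:
    """Merge read pairs into consensus sequences.

    The best ungapped overlap of the forward read against the reverse
    complement of the reverse read is chosen (most matching columns; ties go
    to the longer overlap).  Overlaps shorter than ``min_overlap`` or with a
    mismatch rate above ``max_diff_rate`` disqualify a pair, which is then
    dropped.  In the overlap the higher-quality base wins (forward read on
    ties) and the posterior quality is the sum of the two qualities on
    agreement and their difference on disagreement, capped at 41.  Read-
    through overhangs beyond the mate's start (adaptor segments) are removed.
    """
    merged: list[MergedRead | None] = [None] * len(pairs)
    groups: dict[tuple[int, int], list[int]] = {}
    for i, p in enumerate(pairs):
        groups.setdefault((len(p.fwd_seq), len(p.rev_seq)), []).append(i)

    for (lf, lr), idxs in groups.items():
        sub = [pairs[i] for i in idxs]
        F = _to_matrix([p.fwd_seq for p in sub])
        Fq = _to_matrix([p.fwd_qual for p in sub]).astype(np.int16) - 33
        R = _to_matrix([revcomp(p.rev_seq) for p in sub])
        Rq = (_to_matrix([p.rev_qual for p in sub]).astype(np.int16) - 33)[:, ::-1]

        n = len(sub)
        best_matches = np.full(n, -1, dtype=np.int32)
        best_shift = np.zeros(n, dtype=np.int32)

        def overlap_len(s: int) -> int:
            return min(lf, s + lr) - max(0, s)

        shifts = [
            s
            for s in range(-(lr - min_overlap), lf - min_overlap + 1)
            if overlap_len(s) >= min_overlap
        ]
        shifts.sort(key=lambda s: (-overlap_len(s), s))
        for s in shifts:
            ov = overlap_len(s)
            if ov <= best_matches.min():
                break
            fa = F[:, max(0, s) : max(0, s) + ov]
            ra = R[:, max(0, -s) : max(0, -s) + ov]
            mism = np.count_nonzero(fa != ra, axis=1)
            matches = ov - mism
            improve = (mism <= max_diff_rate * ov) & (matches > best_matches)
            best_matches[improve] = matches[improve]
            best_shift[improve] = s

        for s in np.unique(best_shift[best_matches >= 0]):
            rows = np.flatnonzero((best_shift == s) & (best_matches >= 0))
            ov = overlap_len(int(s))
            st_f, st_r = max(0, int(s)), max(0, -int(s))
            fa, qa = F[rows, st_f : st_f + ov], Fq[rows, st_f : st_f + ov]
            ra, qb = R[rows, st_r : st_r + ov], Rq[rows, st_r : st_r + ov]
            agree = fa == ra
            cons = np.where(qa >= qb, fa, ra)
            consq = np.where(agree, np.minimum(qa + qb, 41), np.abs(qa - qb))
            if s >= 0:
                left, leftq = F[rows, : int(s)], Fq[rows, : int(s)]
                if s + lr >= lf:
                    right, rightq = R[rows, ov:], Rq[rows, ov:]
                else:
                    right, rightq = F[rows, int(s) + lr :], Fq[rows, int(s) + lr :]
                seqs = np.concatenate([left, cons, right], axis=1)
                quals = np.concatenate([leftq, consq, rightq], axis=1)
            else:  # read-through: drop unaligned overhangs at both ends
                seqs, quals = cons, consq
            for k, row in enumerate(rows):
                merged[idxs[row]] = MergedRead(
                    id=sub[row].id,
                    seq=seqs[k].tobytes().decode("ascii"),
                    qual=quals[k].astype(np.int16),
                )
    return [m for m in merged if m is not None]


# ---------------------------------------------------------------------------
# Truncation and quality filtering
# ---------------------------------------------------------------------------

def truncate(
    reads: list[MergedRead], primer_trunc: int = 25, trunc_len: int = 220
) -> list[MergedRead]:
    """Remove ``primer_trunc`` bases from both ends, then keep the first
    ``trunc_len`` bases; reads ending up shorter are discarded."""
    if primer_trunc < 0:
        raise ValueError("primer_trunc must be >= 0")
    if trunc_len <= 0:
        raise ValueError("trunc_len must be > 0")
    out = []
    for r in reads:
        end = len(r.seq) - primer_trunc
        if end - primer_trunc < trunc_len:
            continue
        out.append(
            MergedRead(
                id=r.id,
                seq=r.seq[primer_trunc : primer_trunc + trunc_len],
                qual=r.qual[primer_trunc : primer_trunc + trunc_len],
                passed_filter=r.passed_filter,
            )
        )
    return out


def filter_expected_errors(
    reads: list[MergedRead], max_ee: float = 0.4
) -> tuple[list[MergedRead], list[MergedRead]]:
    """Partition reads by expected errors EE = sum_i 10^(-Q_i/10) <= max_ee."""
    retained, rejected = [], []
    for r in reads:
        if r.expected_errors() <= max_ee:
            r.passed_filter = True
            retained.append(r)
        else:
            r.passed_filter = False
            rejected.append(r)
    return retained, rejected


# ---------------------------------------------------------------------------
# Dereplication
# ---------------------------------------------------------------------------

def dereplicate(
    reads: list[MergedRead], remove_singletons: bool = True
) -> list[UniqueSeq]:
    """Collapse identical reads (including reverse-complement identity) into
    unique sequences with abundances, optionally dropping singletons.

    The canonical orientation is the lexicographically smaller of the
    sequence and its reverse complement; output is sorted by
    (abundance desc, sequence asc)."""
    if reads:
        length = len(reads[0].seq)
        if any(len(r.seq) != length for r in reads):
            raise ValueError("dereplicate requires equal-length reads")
    buckets: dict[str, list[str]] = {}
    for r in reads:
        canon = min(r.seq, revcomp(r.seq))
        buckets.setdefault(canon, []).append(r.id)
    uniques = [
        UniqueSeq(seq=s, abundance=len(ids), member_ids=tuple(ids))
        for s, ids in buckets.items()
    ]
    if remove_singletons:
        uniques = [u for u in uniques if u.abundance > 1]
    uniques.sort(key=lambda u: (-u.abundance, u.seq))
    return uniques


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def is_chimeric(
    query: UniqueSeq,
    centroids: list[Otu],
    parent_abundance_factor: float = 2.0,
    segment_identity: float = 0.99,
) -> bool:
    """Two-parent chimera model: true iff some breakpoint splits the query
    into a prefix >=99% identical to one sufficiently abundant centroid and a
    suffix >=99% identical to another, while no single centroid explains the
    whole query at >=99%."""
    if not centroids:
        return False
    if any(
        oriented_identity(query.seq, c.centroid)[0] >= segment_identity
        for c in centroids
    ):
        return False
    parents = [
        c
        for c in centroids
        if c.size >= parent_abundance_factor * query.abundance
        and len(c.centroid) == len(query.seq)
    ]
    if len(parents) < 2:
        return False
    L = len(query.seq)
    q = np.frombuffer(query.seq.encode(), np.uint8)
    # per-parent prefix mismatch counts (positional; amplicons are aligned
    # end to end after truncation, so no indel handling is needed here).
    # Each parent is first put in the orientation that matches the query
    # best, since canonical storage may hold it reverse-complemented.
    oriented = []
    for p in parents:
        a = np.frombuffer(p.centroid.encode(), np.uint8)
        b = np.frombuffer(revcomp(p.centroid).encode(), np.uint8)
        oriented.append(a if (q != a).sum() <= (q != b).sum() else b)
    mism = np.stack([np.cumsum(q != a) for a in oriented])  # (n_parents, L)
    b = np.arange(1, L)
    prefix_ok = (b - mism[:, :-1]) / b >= segment_identity
    suffix_ok = ((L - b) - (mism[:, -1:] - mism[:, :-1])) / (L - b) >= segment_identity
    hits = prefix_ok[:, None, :] & suffix_ok[None, :, :]
    hits[np.arange(len(parents)), np.arange(len(parents)), :] = False
    return bool(hits.any())


def cluster_otus(
    uniques: list[UniqueSeq], otu_identity: float = 0.97
) -> list[Otu]:
    """Greedy centroid clustering at ``otu_identity``.

    Uniques are visited in (abundance desc, sequence asc) order; each joins
    the best-identity existing centroid at or above the radius (ties to the
    earliest-created centroid), is discarded as a chimera, or founds a new
    OTU.  Sizes accumulate member abundances."""
    for a, b in zip(uniques, uniques[1:]):
        if b.abundance > a.abundance or (
            b.abundance == a.abundance and b.seq < a.seq
        ):
            raise ValueError("cluster_otus requires (abundance desc, seq asc) order")
    otus: list[Otu] = []
    sizes: list[int] = []
    for u in uniques:
        best_i, best_identity = -1, -1.0
        for i, c in enumerate(otus):
            ident, _ = oriented_identity(u.seq, c.centroid)
            if ident > best_identity:
                best_i, best_identity = i, ident
        if best_i >= 0 and best_identity >= otu_identity:
            sizes[best_i] += u.abundance
        elif is_chimeric(u, [Otu(o.otu_id, o.centroid, s) for o, s in zip(otus, sizes)]):
            continue
        else:
            otus.append(Otu(f"OTU_{len(otus) + 1}", u.seq, 0))
            sizes.append(u.abundance)
    return [Otu(o.otu_id, o.centroid, s) for o, s in zip(otus, sizes)]


# ---------------------------------------------------------------------------
# Mapping and control subtraction
# ---------------------------------------------------------------------------

def map_reads_to_otus(
    reads_per_sample: dict[str, list[MergedRead]],
    otus: list[Otu],
    map_identity: float = 0.97,
) -> tuple[OtuTable, dict[str, int]]:
    """Assign each merged+truncated read to its best-identity centroid.

    Reads below ``map_identity`` against every centroid stay unassigned and
    are counted per sample.  Quality-filter status is ignored here: mapping
    uses all merged, truncated reads."""
    import edlib

    samples = list(reads_per_sample)
    otu_ids = [o.otu_id for o in otus]
    unassigned = {s: 0 for s in samples}
    cache: dict[str, int] = {}
    centroids_rc = [revcomp(o.centroid) for o in otus]

    def assign(seq: str) -> int:
        if seq in cache:
            return cache[seq]
        # banded edit-distance screen: a centroid at >= map_identity cannot
        # be further than ~(1 - identity) * columns edits away
        kmax = int((1.0 - map_identity) * (len(seq) + 10)) + 2
        candidates = []
        for i, o in enumerate(otus):
            for target in (o.centroid, centroids_rc[i]):
                d = edlib.align(seq, target, mode="NW", task="distance", k=kmax)[
                    "editDistance"
                ]
                if d != -1:
                    candidates.append(i)
                    break
        best_i, best_identity = -1, -1.0
        for i in candidates:
            ident, _ = oriented_identity(seq, otus[i].centroid)
            if ident > best_identity:
                best_i, best_identity = i, ident
        result = best_i if best_identity >= map_identity else -1
        cache[seq] = result
        return result

    cols = {}
    for s in samples:
        col = np.zeros(len(otus), dtype=np.int64)
        for r in reads_per_sample[s]:
            i = assign(r.seq)
            if i < 0:
                unassigned[s] += 1
            else:
                col[i] += 1
        cols[s] = col
    counts = pd.DataFrame(cols, index=otu_ids, dtype=np.int64)
    centroids = {o.otu_id: o.centroid for o in otus}
    return OtuTable(counts=counts, centroids=centroids), unassigned


def subtract_negative_controls(
    table: OtuTable, control_counts: dict[str, int]
) -> OtuTable:
    """Deduct per-OTU negative-control read counts from every cell,
    flooring at zero."""
    if any(v < 0 for v in control_counts.values()):
        raise ValueError("control counts must be >= 0")
    vec = np.array([control_counts.get(o, 0) for o in table.counts.index])
    new = (table.counts.values - vec[:, None]).clip(min=0)
    return OtuTable(
        counts=pd.DataFrame(
            new, index=table.counts.index, columns=table.counts.columns
        ),
        centroids=dict(table.centroids),
    )


def control_counts_from_table(
    control_reads: list[MergedRead], otus: list[Otu], map_identity: float = 0.97
) -> dict[str, int]:
    """Map pooled negative-control reads to OTUs, yielding per-OTU counts."""
    table, _ = map_reads_to_otus({"_neg": control_reads}, otus, map_identity)
    return {o: int(c) for o, c in table.counts["_neg"].items() if c > 0}


# ---------------------------------------------------------------------------
# Convenience: full sample processing
# ---------------------------------------------------------------------------

def process_reads(
    pairs_per_sample: dict[str, list[ReadPair]],
    settings: PipelineSettings = PipelineSettings(),
) -> dict:
    """Run merge -> truncate -> EE filter per sample and return per-sample
    read lists plus per-stage counters (every input read is accounted for)."""
    out = {"samples": {}, "log": {}}
    for sid, pairs in pairs_per_sample.items():
        merged = merge_pairs(
            pairs, settings.min_overlap, settings.max_overlap_diff_rate
        )
        trunc = truncate(merged, settings.primer_trunc, settings.trunc_len)
        retained, rejected = filter_expected_errors(trunc, settings.max_ee)
        out["samples"][sid] = {"truncated": trunc, "filtered": retained}
        out["log"][sid] = {
            "input_pairs": len(pairs),
            "merged": len(merged),
            "merge_dropped": len(pairs) - len(merged),
            "truncated": len(trunc),
            "length_discarded": len(merged) - len(trunc),
            "ee_retained": len(retained),
            "ee_rejected": len(rejected),
        }
    return out


def build_otus(
    processed: dict, settings: PipelineSettings = PipelineSettings()
) -> list[Otu]:
    """Pool all EE-filtered reads, dereplicate and cluster into OTUs."""
    pooled = [
        r for s in processed["samples"].values() for r in s["filtered"]
    ]
    uniques = dereplicate(pooled, settings.remove_singletons)
    return cluster_otus(uniques, settings.otu_identity)
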