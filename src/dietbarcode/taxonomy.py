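"""Taxonomic assignment of OTU centroids against a local reference library.

Best-hit search with a 28-mer exact-word prefilter (megablast-style), a
Karlin-Altschul e-value against the library's total length, and a weighted
"grade" score combining query coverage, e-value and pairwise identity with
weights 0.5 / 0.25 / 0.25.  The grade drives a three-band reliability flag:
reliable (>=97), genus-uncertain (90-97), unreliable (<90).  Species-level
assignments are always flagged indicative-only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import infix_alignment, revcomp
from .amplicon import Otu, OtuTable

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

# ungapped nucleotide Karlin-Altschul parameters for reward +1 / penalty -2
_LAMBDA = 1.28
_K = 0.46
_MATCH, _MISMATCH, _GAP = 1, -2, -2  # linear gap cost: open == extend


@dataclass(frozen=True)
class Hit:
    otu_id: str
    accession: str
    query_coverage: float  # percent
    pairwise_identity: float  # percent
    e_value: float
    bit_score: float
    grade: float  # percent

    def __post_init__(self):
        for name in ("query_coverage", "pairwise_identity", "grade"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")


def escore(e_value: float) -> float:
    """Map an e-value to a 0-100 score, linear in -log10(e) between
    e = 1 (score 0) and e = 1e-50 (score 100)."""
    if e_value <= 0:
        return 100.0
    return float(np.clip(-math.log10(e_value) * 2.0, 0.0, 100.0))


def compute_grade(
    query_coverage: float, e_value: float, pairwise_identity: float
) -> float:
    """Weighted hit grade: 0.5*coverage + 0.25*escore(e) + 0.25*identity."""
    if not (0.0 <= query_coverage <= 100.0 and 0.0 <= pairwise_identity <= 100.0):
        raise ValueError("coverage and identity must lie in [0, 100]")
    if e_value <= 0:
        raise ValueError("e-value must be > 0")
    return 0.5 * query_coverage + 0.25 * escore(e_value) + 0.25 * pairwise_identity


def _word_matches(query: str, library, word_size: int):
    """References sharing at least one exact word of ``word_size`` bases with
    the query on either strand."""
    if len(query) < word_size:
        return []
    words = set()
    for q in (query, revcomp(query)):
        words.update(q[i : i + word_size] for i in range(len(q) - word_size + 1))
    hits = []
    for ref in library:
        seq = ref.sequence
        if any(
            seq[i : i + word_size] in words
            for i in range(len(seq) - word_size + 1)
        ):
            hits.append(ref)
    return hits


def best_hit_search(
    centroid: str,
    library,
    max_e: float = 1e-1,
    word_size: int = 28,
    otu_id: str = "",
) -> Hit | None:
    """Best reference hit for a centroid, or None.

    Candidates must share an exact ``word_size``-mer with the query; each is
    aligned (edit-distance optimal, linear gap cost) and scored.  The best
    hit has the highest grade, ties broken by bit score then accession; hits
    with e-value above ``max_e`` are discarded.
    """
    if not library:
        raise ValueError("reference library is empty")
    total_len = sum(len(r.sequence) for r in library)
    best: tuple | None = None
    candidates = sorted(
        _word_matches(centroid, library, word_size), key=lambda r: r.accession
    )
    for ref in candidates:
        # strand-aware: centroids are stored in canonical orientation and may
        # be reverse-complemented relative to the reference
        aln_f = infix_alignment(centroid, ref.sequence)
        aln_r = infix_alignment(revcomp(centroid), ref.sequence)
        aln = aln_f if aln_f["edit_distance"] <= aln_r["edit_distance"] else aln_r
        raw = (
            aln["matches"] * _MATCH
            + aln["mismatches"] * _MISMATCH
            + aln["gap_columns"] * _GAP
        )
        bit = (_LAMBDA * raw - math.log(_K)) / math.log(2.0)
        e_value = max(len(centroid) * total_len * 2.0 ** (-bit), 1e-300)
        coverage = 100.0 * min(1.0, aln["columns"] / len(centroid))
        identity = 100.0 * aln["identity"]
        grade = compute_grade(coverage, e_value, identity)
        # strict improvement keeps the first (lowest) accession on ties
        if best is None or (grade, bit) > (best[5], best[4]):
            best = (ref, coverage, identity, e_value, bit, grade)
    if best is None or best[3] > max_e:
        return None
    ref, coverage, identity, e_value, bit, grade = best
    return Hit(
        otu_id=otu_id,
        accession=ref.accession,
        query_coverage=coverage,
        pairwise_identity=identity,
        e_value=e_value,
        bit_score=bit,
        grade=grade,
    )


def reliability_flag(grade: float, thresholds: tuple[float, float] = (90.0, 97.0)) -> str:
    low, high = thresholds
    if grade >= high:
        return "reliable"
    if grade >= low:
        return "genus_uncertain"
    return "unreliable"


def assign_taxonomy(
    otus: list[Otu],
    library,
    thresholds: tuple[float, float] = (90.0, 97.0),
    max_e: float = 1e-1,
    word_size: int = 28,
) -> pd.DataFrame:
    """Assign every OTU its best hit's lineage, grade and reliability flag.

    Returns a table indexed by otu_id with accession, coverage, identity,
    e-value, grade, the 7 lineage ranks, a reliability flag ("unassigned"
    for no-hit OTUs) and a species_indicative marker (species-level calls
    are never considered confirmed).
    """
    by_acc = {r.accession: r for r in library}
    rows = []
    for otu in otus:
        hit = best_hit_search(
            otu.centroid, library, max_e=max_e, word_size=word_size, otu_id=otu.otu_id
        )
        if hit is None:
            rows.append(
                {
                    "otu_id": otu.otu_id,
                    "accession": "",
                    "query_coverage": np.nan,
                    "pairwise_identity": np.nan,
                    "e_value": np.nan,
                    "grade": np.nan,
                    **{r: "" for r in RANKS},
                    "flag": "unassigned",
                    "species_indicative": True,
                }
            )
            continue
        lineage = by_acc[hit.accession].lineage
        rows.append(
            {
                "otu_id": otu.otu_id,
                "accession": hit.accession,
                "query_coverage": hit.query_coverage,
                "pairwise_identity": hit.pairwise_identity,
                "e_value": hit.e_value,
                "grade": hit.grade,
                **dict(zip(RANKS, lineage)),
                "flag": reliability_flag(hit.grade, thresholds),
                "species_indicative": True,
            }
        )
    return pd.DataFrame(rows).set_index("otu_id")


def read_reference_library(fasta_path, taxonomy_path) -> list:
    """Load a reference library from FASTA plus a 7-rank taxonomy TSV."""
    from Bio import SeqIO

    from .synthetic import RefRecord

    tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str).fillna("")
    tax = tax.set_index("accession")
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        lineage = tuple(tax.loc[rec.id, list(RANKS)])
        records.append(
            RefRecord(accession=rec.id, lineage=lineage, sequence=str(rec.seq))
        )
    return records


def prune_to_classes(
    table: OtuTable, taxonomy: pd.DataFrame, classes: set[str]
) -> tuple[OtuTable, float]:
    """Keep only OTUs whose class is in ``classes``.

    Returns the pruned table and the fraction of reads removed."""
    missing = set(table.otus) - set(taxonomy.index)
    if missing:
        raise ValueError(f"taxonomy does not cover OTUs: {sorted(missing)[:5]}")
    keep = [o for o in table.otus if taxonomy.loc[o, "class"] in classes]
    total = table.counts.values.sum()
    pruned = table.counts.loc[keep]
    removed_fraction = 0.0 if total == 0 else 1.0 - pruned.values.sum() / total
    return (
        OtuTable(
            counts=pruned.copy(),
            centroids={o: table.centroids[o] for o in keep if o in table.centroids},
        ),
        float(removed_fraction),
    )
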