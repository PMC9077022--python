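"""Pairwise identity computations shared by clustering, mapping and taxonomy.

Identity convention used throughout the package: number of matching columns
divided by the number of alignment columns, where terminal gap columns are
excluded and internal gaps count as mismatch columns.  Alignments are
edit-distance optimal (edlib); for the equal-length amplicons this pipeline
produces after truncation, that coincides with the free-end-gap optimum.
"""

from __future__ import annotations

import re

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _identity_from_cigar(cigar: str) -> tuple[float, int, int, int, int]:
    """(identity, matches, columns, mismatches, gap_columns) with terminal
    indel runs stripped."""
    ops = _cigar_ops(cigar)
    # strip terminal gaps (I/D runs at either end)
    while ops and ops[0][1] in "ID":
        ops.pop(0)
    while ops and ops[-1][1] in "ID":
        ops.pop()
    matches = sum(n for n, op in ops if op == "=")
    mismatches = sum(n for n, op in ops if op == "X")
    gap_columns = sum(n for n, op in ops if op in "ID")
    columns = matches + mismatches + gap_columns
    if columns == 0:
        return 0.0, 0, 0, 0, 0
    return matches / columns, matches, columns, mismatches, gap_columns


def global_identity(a: str, b: str) -> float:
    """Global pairwise identity between two sequences.

    Returns matches / alignment columns over an edit-distance-optimal global
    alignment, terminal gaps excluded.
    """
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    return _identity_from_cigar(res["cigar"])[0]


def oriented_identity(a: str, b: str) -> tuple[float, bool]:
    """Best global identity of ``a`` against ``b`` in either orientation.

    Dereplication stores unique sequences in a canonical orientation, so two
    near-identical amplicons can be held as reverse complements of each
    other; strand-aware comparison is therefore required everywhere
    sequences meet centroids.  Returns (identity, reverse_complemented)."""
    fwd = global_identity(a, b)
    rev = global_identity(a, revcomp(b))
    return (fwd, False) if fwd >= rev else (rev, True)


def global_alignment_stats(a: str, b: str) -> dict:
    """Identity, matches, columns, mismatches and internal gap columns for a
    global alignment of ``a`` against ``b`` (terminal gaps excluded)."""
    res = edlib.align(a, b, mode="NW", task="path")
    identity, matches, columns, mismatches, gap_columns = _identity_from_cigar(
        res["cigar"]
    )
    return {
        "identity": identity,
        "matches": matches,
        "columns": columns,
        "mismatches": mismatches,
        "gap_columns": gap_columns,
        "edit_distance": res["editDistance"],
    }


def infix_alignment(query: str, target: str) -> dict:
    """Align ``query`` against the best-matching infix of ``target``.

    Used for searching short amplicon centroids against longer reference
    barcodes.  Returns identity, matches, columns, the matched target span,
    and the raw edit distance.
    """
    res = edlib.align(query, target, mode="HW", task="path")
    identity, matches, columns, mismatches, gap_columns = _identity_from_cigar(
        res["cigar"]
    )
    start, end = res["locations"][0]
    return {
        "identity": identity,
        "matches": matches,
        "columns": columns,
        "mismatches": mismatches,
        "gap_columns": gap_columns,
        "target_start": start,
        "target_end": end,
        "edit_distance": res["editDistance"],
    }
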