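"""Ion-library merging and quantifiable-fraction accounting.

A DIA study builds its ion library by merging the identifications of
several discovery (DDA) injections.  This module does the set
bookkeeping around that merge: proteins identified per source, the union
that forms the combined library, the all-source intersection (what a
purely DDA workflow could quantify across every sample), and the
fraction of library proteins actually quantified in every injection of
a matrix — the headline advantage of DIA over DDA quantification.

Protein identity is the accession string verbatim; isoform or gene-level
collapsing happens upstream in the search engine, not here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .quantio import QuantMatrix

__all__ = ["OverlapSummary", "merge_libraries", "quantifiable_fraction"]


@dataclass(frozen=True)
class OverlapSummary:
    per_source_counts: dict[str, int]
    union_count: int
    intersection_count: int
    quantifiable_fraction: float | None = None


def merge_libraries(libraries: dict[str, pd.DataFrame]
                    ) -> tuple[pd.DataFrame, OverlapSummary]:
    """Union of per-source ion libraries with max-confidence collapse.

    ``libraries`` maps a source name (e.g. one discovery injection) to a
    library table.  Duplicate (protein, peptide) pairs across sources
    keep the highest confidence.  The summary counts unique proteins per
    source, in the union, and common to all sources.
    """
    if not libraries:
        raise ValueError("at least one source library is required")
    frames = []
    per_source = {}
    protein_sets = []
    for source, lib in libraries.items():
        frames.append(lib)
        prots = set(lib["protein"])
        protein_sets.append(prots)
        per_source[source] = len(prots)
    combined = pd.concat(frames, ignore_index=True)
    combined = (combined.sort_values("confidence")
                        .drop_duplicates(["protein", "peptide"], keep="last")
                        .sort_values(["protein", "peptide"], kind="mergesort")
                        .reset_index(drop=True))
    union = set.union(*protein_sets)
    intersection = set.intersection(*protein_sets)
    summary = OverlapSummary(per_source_counts=per_source,
                             union_count=len(union),
                             intersection_count=len(intersection))
    return combined, summary


def quantifiable_fraction(matrix: QuantMatrix) -> float:
    """Fraction of protein rows with no missing cell — the proteins
    quantifiable across *all* injections."""
    if matrix.data.empty:
        raise ValueError("matrix is empty")
    complete = matrix.data.notna().all(axis=1).sum()
    return float(complete / matrix.data.shape[0])
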