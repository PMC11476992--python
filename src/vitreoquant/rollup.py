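"""Transition -> peptide -> protein intensity roll-up for the DIA arm.

Processing mirrors the standard label-free DIA pipeline settings: up to
10 peptides per protein and 6 transitions per peptide, a 90% peptide
confidence threshold on the ion library, summed areas at both levels.
Peptides mapping to more than one protein accession are removed before
roll-up so that every quantified signal is uniquely attributable.

The targeted (MRM-HR) arm deliberately aggregates differently — top-k
*means* with an S/N gate — and lives in :mod:`vitreoquant.mrmhr`.

Identification FDR is treated as a property of the input library (the
``confidence`` column produced upstream by the search engine); no decoy
machinery is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantio import QuantMatrix

__all__ = ["RollupConfig", "LibraryFilterStats", "filter_library",
           "rollup_peptide", "rollup_protein", "build_matrix"]


class RollupError(ValueError):
    """Roll-up cannot proceed (e.g. no data/library overlap)."""


@dataclass(frozen=True)
class RollupConfig:
    max_transitions_per_peptide: int = 6
    max_peptides_per_protein: int = 10
    min_confidence: float = 0.90
    aggregation: str = "sum"  # the DIA arm sums extracted-ion areas
    # how the per-protein supporting-peptide count is summarized across
    # injections: "any" counts peptides quantified in at least one
    # injection (the library-level reading of vendor processing), "min"
    # is the conservative per-injection minimum
    peptide_count_stat: str = "any"

    def __post_init__(self) -> None:
        if self.max_transitions_per_peptide < 1:
            raise ValueError("max_transitions_per_peptide must be >= 1")
        if self.max_peptides_per_protein < 1:
            raise ValueError("max_peptides_per_protein must be >= 1")
        if self.aggregation != "sum":
            raise ValueError("the DIA arm supports sum aggregation only")
        if self.peptide_count_stat not in ("any", "min"):
            raise ValueError("peptide_count_stat must be 'any' or 'min'")


@dataclass(frozen=True)
class LibraryFilterStats:
    n_input: int
    n_low_confidence: int
    n_shared_peptides: int   # peptides dropped for multi-protein mapping
    n_kept: int


def filter_library(library: pd.DataFrame, min_confidence: float = 0.90
                   ) -> tuple[pd.DataFrame, LibraryFilterStats]:
    """Apply the confidence threshold and drop shared peptides.

    A peptide mapping to more than one accession is removed entirely
    (all of its rows), since its signal cannot be attributed uniquely.
    """
    n_input = len(library)
    kept = library[library["confidence"] >= min_confidence]
    n_low = n_input - len(kept)
    per_pep = kept.groupby("peptide")["protein"].nunique()
    shared = set(per_pep.index[per_pep > 1])
    out = kept[~kept["peptide"].isin(shared)].reset_index(drop=True)
    stats = LibraryFilterStats(n_input, n_low, len(shared), len(out))
    return out, stats


def rollup_peptide(areas, fragment_labels=None,
                   config: RollupConfig = RollupConfig()) -> float | None:
    """Sum of the top-k transition areas for one peptide in one injection.

    Ties in area are broken by fragment label (lexical ascending) so the
    selection is deterministic.  Empty input is a *missing* peptide, not
    a zero one.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        return None
    if fragment_labels is None:
        fragment_labels = [""] * areas.size
    order = sorted(range(areas.size),
                   key=lambda i: (-areas[i], str(fragment_labels[i])))
    top = order[:config.max_transitions_per_peptide]
    return float(areas[top].sum())


def rollup_protein(peptide_areas, peptide_names=None,
                   config: RollupConfig = RollupConfig()
                   ) -> tuple[float, int] | None:
    """Sum of the top-k peptide areas for one protein in one injection.

    Returns ``(area, n_peptides)`` where ``n_peptides`` is the number of
    peptides actually contributing, i.e. min(observed, cap).  Missing on
    empty input.
    """
    areas = np.asarray(peptide_areas, dtype=float)
    areas = areas[np.isfinite(areas)]
    if areas.size == 0:
        return None
    if peptide_names is None:
        names = [""] * areas.size
    else:
        names = list(peptide_names)
    order = sorted(range(areas.size),
                   key=lambda i: (-areas[i], str(names[i])))
    top = order[:config.max_peptides_per_protein]
    return float(areas[top].sum()), len(top)


def build_matrix(transitions: pd.DataFrame, library: pd.DataFrame,
                 samples: pd.DataFrame,
                 config: RollupConfig = RollupConfig()) -> QuantMatrix:
    """Roll a long transition table up to a protein x injection matrix.

    Applies the library filter, drops transitions whose peptide is not
    in the filtered library, sums top-k transitions per peptide and
    top-k peptides per protein, and records per-protein peptide counts
    feeding the >=2-peptide filter downstream.  By default the count is
    the number of distinct peptides quantified for the protein in any
    injection (capped at the peptide limit); ``peptide_count_stat='min'``
    gives the conservative minimum over injections where the protein is
    observed.
    """
    lib, _stats = filter_library(library, config.min_confidence)
    lib_pairs = lib[["protein", "peptide"]].drop_duplicates()
    data = transitions.merge(lib_pairs, on=["protein", "peptide"],
                             how="inner")
    if data.empty:
        raise RollupError(
            "no overlap between transition data and the filtered library")

    # peptide level: top-k transitions by (area desc, fragment_label asc)
    data = data.sort_values(
        ["sample_id", "protein", "peptide", "area", "fragment_label"],
        ascending=[True, True, True, False, True], kind="mergesort")
    topt = data.groupby(["sample_id", "protein", "peptide"], sort=False) \
               .head(config.max_transitions_per_peptide)
    peptides = (topt.groupby(["sample_id", "protein", "peptide"], sort=False)
                    ["area"].sum().reset_index())

    # protein level: top-k peptides by (area desc, peptide asc)
    peptides = peptides.sort_values(
        ["sample_id", "protein", "area", "peptide"],
        ascending=[True, True, False, True], kind="mergesort")
    topp = peptides.groupby(["sample_id", "protein"], sort=False) \
                   .head(config.max_peptides_per_protein)
    agg = topp.groupby(["sample_id", "protein"], sort=False) \
              .agg(area=("area", "sum"), n=("area", "size")).reset_index()

    if samples.index.name != "sample_id":
        samples = samples.set_index("sample_id")
    grid = agg.pivot(index="protein", columns="sample_id", values="area")
    grid = grid.reindex(columns=list(samples.index))
    grid = grid.sort_index()
    if config.peptide_count_stat == "min":
        counts = (agg.pivot(index="protein", columns="sample_id", values="n")
                     .reindex(index=grid.index)
                     .min(axis=1, skipna=True).astype(int))
    else:
        counts = (topp.groupby("protein")["peptide"].nunique()
                      .clip(upper=config.max_peptides_per_protein)
                      .reindex(index=grid.index).astype(int))
    return QuantMatrix(grid, samples.copy(), counts.rename("n_peptides"))
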