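"""Bilateral-concordance differential-expression filtering.

Because the study design pools all animals of one day into one right-eye
(OD) and one left-eye (OS) sample, no per-protein variance estimate (and
hence no p-value) exists at the discovery stage.  Instead, a protein is
called differentially expressed at a day-vs-day-7 contrast when

* its fold change passes the cutoff in *both* eyes, in the *same*
  direction (UP: both >= 1.5; DOWN: both <= 0.7), and
* at least two quantified peptides support the protein.

The two independent eye pools act as built-in replication: a discordant
pair is evidence of noise, not regulation.  This is a fold-change filter,
not a hypothesis test — no multiple-testing machinery applies, and none
is added here.

The asymmetric default cutoffs (1.5 up, 0.7 down) are both configurable;
0.7 is not exactly 1/1.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantio import Direction, DepRecord, FilterConfig, QuantMatrix

__all__ = ["ContrastSpec", "eye_fold_change", "classify_direction",
           "average_fc", "find_deps", "intersect_deps", "zscore_matrix",
           "round_half_away"]


class ContrastError(ValueError):
    """Requested contrast days are absent from the matrix."""


@dataclass(frozen=True)
class ContrastSpec:
    day: int
    reference_day: int = 7

    def __post_init__(self) -> None:
        if self.day == self.reference_day:
            raise ValueError("contrast day must differ from the reference day")


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention for report tables).

    Works on the shortest decimal representation of ``x`` so that values
    like 0.315 round up to 0.32 despite their binary representation.
    """
    import decimal
    quantum = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(x)).quantize(
        quantum, rounding=decimal.ROUND_HALF_UP))


def _eye_means(matrix: QuantMatrix, day: int, eye: str,
               average: str = "mean") -> pd.Series:
    cols = matrix.columns_for(day, eye)
    if not cols:
        raise ContrastError(f"no injections at day {day} for eye {eye}")
    block = matrix.data[cols]
    return block.mean(axis=1) if average == "mean" else block.median(axis=1)


def eye_fold_change(matrix: QuantMatrix, protein: str, eye: str,
                    contrast: ContrastSpec,
                    average: str = "mean") -> float:
    """FC of one protein in one eye: replicate-mean area at the contrast
    day divided by the replicate-mean area at the reference day.

    Technical replicates are averaged arithmetically before the ratio
    (``average='median'`` is available).  Missing numerator or
    denominator (or a zero denominator) yields NaN.
    """
    num = _eye_means(matrix, contrast.day, eye, average)
    den = _eye_means(matrix, contrast.reference_day, eye, average)
    a, b = num.get(protein, np.nan), den.get(protein, np.nan)
    if not np.isfinite(a) or not np.isfinite(b) or b == 0:
        return float("nan")
    return float(a / b)


def classify_direction(fc_od: float, fc_os: float,
                       config: FilterConfig = FilterConfig()) -> Direction:
    """Bilateral concordance call: UP iff both eye FCs >= up_cutoff,
    DOWN iff both <= down_cutoff, else NONE.  A missing FC is not
    evaluable and yields NONE."""
    if not (np.isfinite(fc_od) and np.isfinite(fc_os)):
        return Direction.NONE
    if fc_od >= config.up_cutoff and fc_os >= config.up_cutoff:
        return Direction.UP
    if fc_od <= config.down_cutoff and fc_os <= config.down_cutoff:
        return Direction.DOWN
    return Direction.NONE


def average_fc(fc_od: float, fc_os: float) -> tuple[float, float]:
    """Mean and two-value sample SD of the eye fold changes.

    The sample (n-1) standard deviation of two values reduces to
    |a - b| / sqrt(2), which is how the spread column of the report
    tables is derived.
    """
    ave = (fc_od + fc_os) / 2.0
    sd = abs(fc_od - fc_os) / math.sqrt(2.0)
    return ave, sd


def find_deps(matrix: QuantMatrix, contrast: ContrastSpec,
              config: FilterConfig = FilterConfig(),
              average: str = "mean") -> list[DepRecord]:
    """All proteins passing the bilateral filter at one contrast.

    Requires a normalized matrix with peptide counts.  Output is sorted
    by accession so that runs are reproducible regardless of input row
    order.
    """
    fc = {}
    for eye in ("OD", "OS"):
        num = _eye_means(matrix, contrast.day, eye, average)
        den = _eye_means(matrix, contrast.reference_day, eye, average)
        ratio = num / den.replace(0.0, np.nan)
        fc[eye] = ratio
    records = []
    counts = matrix.peptide_counts
    for protein in sorted(matrix.data.index):
        n_pep = int(counts.get(protein, 0))
        if n_pep < config.min_peptides:
            continue
        fc_od = float(fc["OD"].get(protein, np.nan))
        fc_os = float(fc["OS"].get(protein, np.nan))
        direction = classify_direction(fc_od, fc_os, config)
        if direction is Direction.NONE:
            continue
        ave, sd = average_fc(fc_od, fc_os)
        records.append(DepRecord(
            protein=protein, day=contrast.day,
            reference_day=contrast.reference_day,
            fc_od=fc_od, fc_os=fc_os, ave_fc=ave, sd_fc=sd,
            direction=direction, n_peptides=n_pep))
    return records


def intersect_deps(dep_lists: dict[int, list[DepRecord]]
                   ) -> dict[str, dict[str, list[DepRecord]]]:
    """Proteins differentially expressed in *every* contrast with the
    same direction throughout, partitioned into UP and DOWN sets.

    Returns ``{"UP": {protein: [records...]}, "DOWN": {...}}`` with the
    per-contrast records attached.
    """
    if len(dep_lists) < 2:
        raise ValueError("intersection needs at least two contrasts")
    by_contrast = []
    for records in dep_lists.values():
        by_contrast.append({r.protein: r for r in records})
    common = set(by_contrast[0])
    for mapping in by_contrast[1:]:
        common &= set(mapping)
    out: dict[str, dict[str, list[DepRecord]]] = {"UP": {}, "DOWN": {}}
    for protein in sorted(common):
        directions = {m[protein].direction for m in by_contrast}
        if len(directions) != 1:
            continue
        direction = directions.pop()
        out[direction.value][protein] = [m[protein] for m in by_contrast]
    return out


def zscore_matrix(matrix: QuantMatrix, proteins: list[str]
                  ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-row standardization (area - row mean) / row sample SD.

    Used for heatmap display of the common DEPs.  Rows observed in fewer
    than 2 samples or with zero variance cannot be standardized: they are
    emitted as all-zero and flagged.
    """
    if not proteins:
        raise ValueError("protein subset must be non-empty")
    missing = [p for p in proteins if p not in matrix.data.index]
    if missing:
        raise KeyError(f"proteins not in matrix: {', '.join(missing)}")
    block = matrix.data.loc[proteins]
    mean = block.mean(axis=1, skipna=True)
    sd = block.std(axis=1, ddof=1, skipna=True)
    n_obs = block.notna().sum(axis=1)
    degenerate = (n_obs < 2) | (sd == 0) | ~np.isfinite(sd)
    safe_sd = sd.mask(degenerate, 1.0)
    z = block.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[degenerate] = z.loc[degenerate].where(
        block.loc[degenerate].isna(), 0.0)
    flags = pd.Series(degenerate, name="zero_variance_or_single_obs")
    return z, flags
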