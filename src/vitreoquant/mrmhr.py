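"""Targeted MRM-HR quantification and validation statistics.

The targeted arm quantifies a short panel of proteins in individual
animals (n = 4 per day at days 7 and 14) rather than pooled eyes, so an
actual hypothesis test is possible.  The processing chain is:

1. gate transitions on signal-to-noise (keep snr >= 20 by default);
2. peptide intensity = mean of the top-3 surviving transition areas;
3. protein intensity = mean of the top-3 peptide intensities;
4. divide every protein by the housekeeping protein (a GAPDH analog)
   measured in the *same* injection — this removes any per-injection
   loading scale exactly;
5. fold change = mean over day-14 animals / mean over day-7 animals;
6. unpaired two-sample t-test between the day groups on the normalized
   intensities (pooled-variance Student by default, Welch by flag).

Note the deliberate contrast with the DIA arm: means of top-k here,
sums there.  P-values are reported per protein without multiplicity
correction, matching how short targeted panels are conventionally read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MrmConfig", "TransitionListSpec", "ValidationResult",
           "build_transition_list", "peptide_intensity",
           "protein_intensity", "normalize_housekeeping",
           "group_fold_change", "unpaired_t_test", "run_validation",
           "DegenerateVarianceError", "MissingHousekeepingError"]


class DegenerateVarianceError(ValueError):
    """Pooled variance is zero; the t statistic is undefined."""


class MissingHousekeepingError(ValueError):
    """The housekeeping protein is not quantified in some injection."""


@dataclass(frozen=True)
class MrmConfig:
    min_snr: float = 20.0
    top_transitions: int = 3
    top_peptides: int = 3
    housekeeping: str = "GAPDH"
    alpha: float = 0.05
    t_test: str = "student"       # or "welch"
    snr_strict: bool = False      # True: keep snr > min_snr instead of >=

    def __post_init__(self) -> None:
        if self.min_snr < 0:
            raise ValueError("min_snr must be >= 0")
        if self.top_transitions < 1 or self.top_peptides < 1:
            raise ValueError("top-k limits must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.t_test not in ("student", "welch"):
            raise ValueError("t_test must be 'student' or 'welch'")


@dataclass(frozen=True)
class TransitionListSpec:
    """Filter settings for building a targeted acquisition list."""

    precursor_charges: tuple[int, ...] = (2, 3)
    fragment_ion_charge: int = 1
    ion_types: tuple[str, ...] = ("y", "b")
    match_tolerance_mz: float = 0.5
    top_products: int = 5


def build_transition_list(library: pd.DataFrame,
                          fragment_catalog: pd.DataFrame,
                          spec: TransitionListSpec = TransitionListSpec()
                          ) -> tuple[pd.DataFrame, list[str]]:
    """Select, per library peptide, the most intense qualifying fragments.

    ``fragment_catalog`` must carry columns peptide, ion_type,
    fragment_charge, precursor_charge, mz, intensity.  Fragments must
    match the allowed ion types and charges; the ``top_products`` most
    intense survive, ties broken by m/z ascending.  Peptides with no
    qualifying fragment are excluded and returned in the second element.
    """
    peptides = library["peptide"].drop_duplicates()
    cat = fragment_catalog[
        fragment_catalog["ion_type"].isin(spec.ion_types)
        & (fragment_catalog["fragment_charge"] == spec.fragment_ion_charge)
        & fragment_catalog["precursor_charge"].isin(spec.precursor_charges)
        & fragment_catalog["peptide"].isin(peptides)]
    cat = cat.sort_values(["peptide", "intensity", "mz"],
                          ascending=[True, False, True], kind="mergesort")
    selected = cat.groupby("peptide", sort=False).head(spec.top_products)
    covered = set(selected["peptide"])
    excluded = sorted(p for p in peptides if p not in covered)
    return selected.reset_index(drop=True), excluded


def _snr_mask(snr: np.ndarray, config: MrmConfig) -> np.ndarray:
    if config.snr_strict:
        return snr > config.min_snr
    return snr >= config.min_snr


def peptide_intensity(areas, snr, config: MrmConfig = MrmConfig()
                      ) -> float | None:
    """Mean of the top-k transition areas passing the S/N gate; missing
    when nothing survives.  Fewer than k survivors are averaged as-is."""
    areas = np.asarray(areas, dtype=float)
    snr = np.asarray(snr, dtype=float)
    keep = areas[_snr_mask(snr, config)]
    if keep.size == 0:
        return None
    top = np.sort(keep)[::-1][:config.top_transitions]
    return float(top.mean())


def protein_intensity(peptide_intensities, config: MrmConfig = MrmConfig()
                      ) -> float | None:
    """Mean of the top-k peptide intensities; missing when none exist."""
    vals = np.asarray([v for v in peptide_intensities if v is not None
                       and np.isfinite(v)], dtype=float)
    if vals.size == 0:
        return None
    top = np.sort(vals)[::-1][:config.top_peptides]
    return float(top.mean())


def normalize_housekeeping(intensities: pd.DataFrame,
                           housekeeping: str) -> pd.DataFrame:
    """Divide each protein by the housekeeping intensity of the same
    injection.  ``intensities`` is protein x sample_id.  The housekeeping
    row maps to exactly 1 everywhere; if it is missing (or zero) in any
    injection, that injection cannot be normalized and is an error."""
    if housekeeping not in intensities.index:
        raise MissingHousekeepingError(
            f"housekeeping protein {housekeeping!r} not quantified")
    hk = intensities.loc[housekeeping]
    bad = hk.index[~np.isfinite(hk.to_numpy(dtype=float)) | (hk == 0)]
    if len(bad):
        raise MissingHousekeepingError(
            f"housekeeping protein {housekeeping!r} missing in "
            f"injection(s): {', '.join(map(str, bad))}")
    out = intensities.div(hk, axis=1)
    out.loc[housekeeping] = 1.0
    return out


def group_fold_change(normalized: pd.DataFrame, protein: str,
                      samples: pd.DataFrame,
                      day_a: int = 14, day_b: int = 7) -> float:
    """Mean normalized intensity over day_a animals / mean over day_b."""
    if samples.index.name != "sample_id":
        samples = samples.set_index("sample_id")
    row = normalized.loc[protein]
    a = row[samples.index[samples["day"] == day_a]].dropna()
    b = row[samples.index[samples["day"] == day_b]].dropna()
    if a.empty or b.empty or b.mean() == 0:
        return float("nan")
    return float(a.mean() / b.mean())


def unpaired_t_test(group_a, group_b, flavor: str = "student"
                    ) -> tuple[float, float, float]:
    """Two-sample t-test; returns (t, df, two-sided p).

    ``flavor='student'`` pools the variances (df = n1 + n2 - 2);
    ``flavor='welch'`` uses the Satterthwaite approximation.  Zero pooled
    variance is degenerate and raises rather than fabricating a p-value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise DegenerateVarianceError(
            "both groups have zero variance; t statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=(flavor == "student"))
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass(frozen=True)
class ValidationResult:
    protein: str
    fold_change: float
    t: float
    df: float
    p: float
    significant: bool
    degenerate: bool = False


def _protein_injection_table(transitions: pd.DataFrame,
                             config: MrmConfig) -> pd.DataFrame:
    """Roll a targeted transition table up to protein x sample_id."""
    data = transitions[_snr_mask(transitions["snr"].to_numpy(dtype=float),
                                 config)]
    data = data.sort_values(
        ["sample_id", "protein", "peptide", "area", "fragment_label"],
        ascending=[True, True, True, False, True], kind="mergesort")
    topt = data.groupby(["sample_id", "protein", "peptide"], sort=False) \
               .head(config.top_transitions)
    peptides = (topt.groupby(["sample_id", "protein", "peptide"], sort=False)
                    ["area"].mean().reset_index())
    peptides = peptides.sort_values(
        ["sample_id", "protein", "area", "peptide"],
        ascending=[True, True, False, True], kind="mergesort")
    topp = peptides.groupby(["sample_id", "protein"], sort=False) \
                   .head(config.top_peptides)
    prot = topp.groupby(["sample_id", "protein"], sort=False)["area"] \
               .mean().reset_index()
    return prot.pivot(index="protein", columns="sample_id", values="area")


def run_validation(transitions: pd.DataFrame, samples: pd.DataFrame,
                   targets: list[str],
                   config: MrmConfig = MrmConfig(),
                   day_a: int = 14, day_b: int = 7
                   ) -> list[ValidationResult]:
    """Full targeted-arm analysis for a panel of proteins.

    Composes the S/N gate, top-3/top-3 mean roll-up, housekeeping
    normalization, day_a/day_b group fold change and the unpaired t-test
    on individual animals.  Output is ordered by the ``targets`` list.
    """
    if samples.index.name != "sample_id":
        samples = samples.set_index("sample_id")
    table = _protein_injection_table(transitions, config)
    table = table.reindex(columns=list(samples.index))
    normalized = normalize_housekeeping(table, config.housekeeping)
    cols_a = samples.index[samples["day"] == day_a]
    cols_b = samples.index[samples["day"] == day_b]
    results = []
    for protein in targets:
        if protein not in normalized.index:
            results.append(ValidationResult(protein, float("nan"),
                                            float("nan"), float("nan"),
                                            float("nan"), False, True))
            continue
        fc = group_fold_change(normalized, protein, samples, day_a, day_b)
        a = normalized.loc[protein, cols_a].dropna().to_numpy()
        b = normalized.loc[protein, cols_b].dropna().to_numpy()
        try:
            t, df, p = unpaired_t_test(a, b, config.t_test)
            results.append(ValidationResult(
                protein, fc, t, df, p, bool(p < config.alpha)))
        except (DegenerateVarianceError, ValueError):
            results.append(ValidationResult(
                protein, fc, float("nan"), float("nan"), float("nan"),
                False, True))
    return results


def validation_frame(results: list[ValidationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("protein")
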