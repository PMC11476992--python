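"""Synthetic SWATH and MRM-HR datasets with known ground truth.

The generator emulates the statistical structure of a two-arm chick
vitreous study of normal eye growth (emmetropization):

* **SWATH arm** — pooled bilateral samples (one right-eye pool, one
  left-eye pool) at each of four post-hatch days, injected in three
  technical replicates: 24 injections.  Pooling is simulated by drawing a
  single biological abundance per (protein, day, eye) that all technical
  replicates of that pool share.
* **MRM-HR arm** — individual animals (default 4 per day) at days 7 and
  14, one random eye each, with biological between-animal variation
  replacing the pooling, and a signal-to-noise ratio attached to every
  transition.

Ground truth per protein: a differential-expression flag with a per-day
log2 fold change versus day 7 shared across eyes; a *decoy* flag whose
effect has opposite sign in the two eyes (built to be rejected by the
bilateral-concordance filter); or null.  One null protein is designated
the housekeeping analog (``GAPDH``) with true fold change 1 everywhere.

Signal model for one transition area in one injection::

    area = 2 ** (baseline_p + offset_pep + effect(p, day, eye) + bias_inj)
           * fraction_t * noise

with protein baseline ~ Normal(mean, sd) in log2, a fixed per-peptide
offset ~ Normal(0, 1), fixed per-peptide transition fractions ~
Dirichlet(1, ..., 1), a per-injection loading bias ~ Uniform(range)
applied to every area of that injection (what MLR normalization must
remove), and mean-one log-normal replicate noise of the configured CV.
Peptide-level dropout is abundance dependent: an observation is removed
with probability ``logistic((midpoint - log2 area) / steepness)``.

A single master seed expands to per-component substreams so the two arms
can be regenerated independently with matched truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .quantio import TRANSITION_COLUMNS, write_quant_table, \
    write_ion_library, write_sample_sheet

__all__ = ["SynthConfig", "SynthTruth", "ConfigError",
           "generate_swath", "generate_mrmhr", "write_truth"]

HOUSEKEEPING_ACCESSION = "GAPDH"
_LN2 = np.log(2.0)


class ConfigError(ValueError):
    """Degenerate or inconsistent simulation configuration."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the simulated study.

    Defaults mirror the study design (4 days x 2 eyes x 3 technical
    replicates in the DIA arm; 4 animals per day at days 7/14 in the
    targeted arm).  Noise and missingness levels are plain config
    choices typical of label-free quant data, not estimates fitted to
    any deposited dataset.
    """

    n_proteins: int = 1000
    peptides_per_protein: tuple[int, int] = (2, 15)
    transitions_per_peptide: int = 6
    days: tuple[int, ...] = (7, 14, 21, 28)
    tech_replicates: int = 3
    animals_per_day_mrmhr: int = 4
    log2_abundance_mean: float = 17.0
    log2_abundance_sd: float = 2.0
    replicate_cv: float = 0.10
    bio_cv_mrmhr: float = 0.20
    eye_jitter_sd_log2: float = 0.10
    bias_log2_range: tuple[float, float] = (-1.0, 1.0)
    de_fraction: float = 0.10
    decoy_fraction: float = 0.05
    de_log2_fc_range: tuple[float, float] = (0.8, 2.5)
    dropout_midpoint_log2: float | None = 12.0
    dropout_steepness: float = 1.5
    low_confidence_fraction: float = 0.05
    snr_below_cutoff_fraction: float = 0.10
    snr_cutoff: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if not self.days:
            raise ConfigError("days must be non-empty")
        if self.tech_replicates < 1 or self.animals_per_day_mrmhr < 1:
            raise ConfigError("replicate counts must be >= 1")
        for frac in (self.de_fraction, self.decoy_fraction,
                     self.low_confidence_fraction,
                     self.snr_below_cutoff_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("fractions must lie in [0, 1]")
        if self.de_fraction + self.decoy_fraction > 1.0:
            raise ConfigError("de_fraction + decoy_fraction must be <= 1")
        for lo, hi in (self.peptides_per_protein, self.bias_log2_range,
                       self.de_log2_fc_range):
            if lo > hi:
                raise ConfigError("ranges must be ordered (lo <= hi)")
        if self.peptides_per_protein[0] < 1:
            raise ConfigError("need at least one peptide per protein")
        if self.transitions_per_peptide < 1:
            raise ConfigError("need at least one transition per peptide")


@dataclass
class SynthTruth:
    """Ground truth emitted alongside a simulated dataset.

    ``proteins``: DataFrame indexed by accession with is_de, is_decoy,
    is_housekeeping, baseline_log2 and n_peptides.
    ``effects``: long DataFrame (protein, day, eye) -> log2_fc versus the
    first simulated day, *including* the per-eye jitter actually applied,
    so that in the noise-free limit downstream per-eye fold changes equal
    ``2 ** log2_fc`` exactly.  Null proteins have log2_fc 0 everywhere.
    ``injection_bias_log2``: per-injection loading bias (log2).
    """

    proteins: pd.DataFrame
    effects: pd.DataFrame
    injection_bias_log2: pd.Series
    housekeeping: str = HOUSEKEEPING_ACCESSION

    def log2_fc(self, protein: str, day: int, eye: str) -> float:
        sel = self.effects[(self.effects["protein"] == protein)
                           & (self.effects["day"] == day)
                           & (self.effects["eye"] == eye)]
        if sel.empty:
            return 0.0
        return float(sel["log2_fc"].iloc[0])


# ---------------------------------------------------------------------------
# deterministic sub-structures


def _substreams(config: SynthConfig) -> dict[str, np.random.Generator]:
    names = ("structure", "truth", "library", "swath", "mrmhr")
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class _Structure:
    accessions: np.ndarray          # per protein
    baseline_log2: np.ndarray       # per protein
    n_peptides: np.ndarray          # per protein
    pep_protein_idx: np.ndarray     # per peptide -> protein index
    pep_names: np.ndarray           # per peptide
    pep_offset: np.ndarray          # per peptide, log2
    pep_charge: np.ndarray          # per peptide precursor charge
    frag_labels: np.ndarray         # per transition
    fractions: np.ndarray           # per transition, sums to 1 per peptide
    tr_pep_idx: np.ndarray          # per transition -> peptide index


def _build_structure(config: SynthConfig,
                     rng: np.random.Generator) -> _Structure:
    n = config.n_proteins
    accessions = np.array(
        [HOUSEKEEPING_ACCESSION] + [f"P{i:04d}" for i in range(1, n)])
    baseline = rng.normal(config.log2_abundance_mean,
                          config.log2_abundance_sd, size=n)
    # the housekeeping analog is by construction an abundant, stable
    # protein (that is why it is usable as an internal standard)
    baseline[0] = config.log2_abundance_mean + config.log2_abundance_sd
    lo, hi = config.peptides_per_protein
    n_pep = rng.integers(lo, hi + 1, size=n)
    pep_protein_idx = np.repeat(np.arange(n), n_pep)
    within = np.concatenate([np.arange(k) for k in n_pep])
    pep_names = np.array([f"{accessions[p]}_pep{j + 1:02d}"
                          for p, j in zip(pep_protein_idx, within)])
    n_peptides_total = int(n_pep.sum())
    pep_offset = rng.normal(0.0, 1.0, size=n_peptides_total)
    pep_charge = rng.choice([2, 3], size=n_peptides_total)

    t = config.transitions_per_peptide
    ion_types = rng.choice(["y", "b"], size=(n_peptides_total, t))
    ordinals = np.arange(3, 3 + t)
    frag_labels = np.array([f"{ion_types[i, j]}{ordinals[j]}+1"
                            for i in range(n_peptides_total)
                            for j in range(t)])
    gamma = rng.gamma(1.0, 1.0, size=(n_peptides_total, t))
    fractions = (gamma / gamma.sum(axis=1, keepdims=True)).ravel()
    tr_pep_idx = np.repeat(np.arange(n_peptides_total), t)
    return _Structure(accessions, baseline, n_pep, pep_protein_idx,
                      pep_names, pep_offset, pep_charge, frag_labels,
                      fractions, tr_pep_idx)


def _build_truth(config: SynthConfig, structure: _Structure,
                 rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = config.n_proteins
    n_de = int(np.floor(n * config.de_fraction))
    n_decoy = int(np.floor(n * config.decoy_fraction))
    candidates = rng.permutation(np.arange(1, n))  # never the housekeeping
    de_idx = np.sort(candidates[:n_de])
    decoy_idx = np.sort(candidates[n_de:n_de + n_decoy])

    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True
    is_decoy = np.zeros(n, dtype=bool)
    is_decoy[decoy_idx] = True

    proteins = pd.DataFrame({
        "is_de": is_de, "is_decoy": is_decoy,
        "is_housekeeping": np.arange(n) == 0,
        "baseline_log2": structure.baseline_log2,
        "n_peptides": structure.n_peptides,
    }, index=pd.Index(structure.accessions, name="protein"))

    reference_day = config.days[0]
    contrast_days = [d for d in config.days if d != reference_day]
    lo, hi = config.de_log2_fc_range
    rows: list[dict] = []
    for idx, discordant in [(de_idx, False), (decoy_idx, True)]:
        signs = rng.choice([-1.0, 1.0], size=len(idx))
        for day in contrast_days:
            magnitude = rng.uniform(lo, hi, size=len(idx))
            jitter = rng.normal(0.0, config.eye_jitter_sd_log2,
                                size=(len(idx), 2))
            for k, p in enumerate(idx):
                od = signs[k] * magnitude[k] + jitter[k, 0]
                if discordant:
                    os_ = -signs[k] * magnitude[k] + jitter[k, 1]
                else:
                    os_ = signs[k] * magnitude[k] + jitter[k, 1]
                rows.append({"protein": structure.accessions[p], "day": day,
                             "eye": "OD", "log2_fc": od})
                rows.append({"protein": structure.accessions[p], "day": day,
                             "eye": "OS", "log2_fc": os_})
    effects = pd.DataFrame(rows, columns=["protein", "day", "eye", "log2_fc"])
    return proteins, effects


def _effect_vector(structure: _Structure, effects: pd.DataFrame,
                   day: int, eye: str) -> np.ndarray:
    """Per-protein log2 effect at (day, eye); zero for nulls/reference."""
    out = np.zeros(len(structure.accessions))
    sel = effects[(effects["day"] == day) & (effects["eye"] == eye)]
    if not sel.empty:
        pos = {a: i for i, a in enumerate(structure.accessions)}
        out[[pos[p] for p in sel["protein"]]] = sel["log2_fc"].to_numpy()
    return out


def _lognormal_noise(rng: np.random.Generator, cv: float,
                     size: int) -> np.ndarray:
    """Mean-one multiplicative log-normal noise of the given linear CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size=size)


def _build_library(config: SynthConfig, structure: _Structure,
                   rng: np.random.Generator) -> pd.DataFrame:
    n_pep = len(structure.pep_names)
    low = rng.random(n_pep) < config.low_confidence_fraction
    confidence = np.where(low, rng.uniform(0.50, 0.90, size=n_pep),
                          rng.uniform(0.90, 1.0, size=n_pep))
    # the housekeeping analog must survive the confidence filter
    confidence[structure.pep_protein_idx == 0] = np.maximum(
        confidence[structure.pep_protein_idx == 0], 0.95)
    return pd.DataFrame({
        "protein": structure.accessions[structure.pep_protein_idx],
        "peptide": structure.pep_names,
        "confidence": np.round(confidence, 6),
        "source_injection": "IDA_combined",
    })


# ---------------------------------------------------------------------------
# arms


def generate_swath(config: SynthConfig) -> tuple[
        pd.DataFrame, pd.DataFrame, pd.DataFrame, SynthTruth]:
    """Simulate the pooled-eye DIA arm.

    Returns ``(transitions, samples, library, truth)``: a long transition
    table (snr empty, as in DIA exports), the sample sheet of
    days x {OD, OS} x technical replicates, the ion library and the
    ground truth.  Identical config (including seed) gives identical
    output.
    """
    streams = _substreams(config)
    structure = _build_structure(config, streams["structure"])
    proteins, effects = _build_truth(config, structure, streams["truth"])
    library = _build_library(config, structure, streams["library"])
    rng = streams["swath"]

    sample_rows = []
    for day in config.days:
        for eye in ("OD", "OS"):
            for rep in range(1, config.tech_replicates + 1):
                sample_rows.append({
                    "sample_id": f"SW_D{day:02d}_{eye}_R{rep}",
                    "eye": eye, "day": day, "replicate": rep,
                    "cohort": "SWATH"})
    samples = pd.DataFrame(sample_rows, columns=[
        "sample_id", "eye", "day", "replicate", "cohort"])
    lo, hi = config.bias_log2_range
    bias = rng.uniform(lo, hi, size=len(samples))
    bias_series = pd.Series(bias, index=samples["sample_id"].to_numpy(),
                            name="bias_log2")

    t = config.transitions_per_peptide
    pep_base = (structure.baseline_log2[structure.pep_protein_idx]
                + structure.pep_offset)
    chunks = []
    for j, row in enumerate(samples.itertuples(index=False)):
        effect = _effect_vector(structure, effects, row.day, row.eye)
        pep_log2 = pep_base + effect[structure.pep_protein_idx] + bias[j]
        if config.dropout_midpoint_log2 is not None:
            p_drop = 1.0 / (1.0 + np.exp(
                -(config.dropout_midpoint_log2 - pep_log2)
                / config.dropout_steepness))
            keep = rng.random(len(pep_log2)) >= p_drop
        else:
            keep = np.ones(len(pep_log2), dtype=bool)
        kept = np.flatnonzero(keep)
        if kept.size == 0:
            continue
        tr_mask = keep[structure.tr_pep_idx]
        tr_pep = structure.tr_pep_idx[tr_mask]
        noise = _lognormal_noise(rng, config.replicate_cv, tr_mask.sum())
        area = (np.exp2(pep_log2[tr_pep]) * structure.fractions[tr_mask]
                * noise)
        chunks.append(pd.DataFrame({
            "sample_id": row.sample_id, "eye": row.eye, "day": row.day,
            "replicate": row.replicate, "cohort": row.cohort,
            "protein": structure.accessions[
                structure.pep_protein_idx[tr_pep]],
            "peptide": structure.pep_names[tr_pep],
            "precursor_charge": structure.pep_charge[tr_pep],
            "fragment_label": structure.frag_labels[tr_mask],
            "area": area, "snr": np.nan}))
    transitions = pd.concat(chunks, ignore_index=True)[TRANSITION_COLUMNS] \
        if chunks else pd.DataFrame(columns=TRANSITION_COLUMNS)
    truth = SynthTruth(proteins, effects, bias_series)
    return transitions, samples, library, truth


def generate_mrmhr(config: SynthConfig, target_proteins: list[str]
                   ) -> tuple[pd.DataFrame, pd.DataFrame, SynthTruth]:
    """Simulate the individual-animal targeted arm for selected proteins.

    Emits days {7, 14} x animals_per_day injections for the targets plus
    the housekeeping analog, with per-animal biological variation
    (``bio_cv_mrmhr``) in place of pooling and an snr per transition.
    The snr scale is set so that ``snr_below_cutoff_fraction`` of the
    transitions fall below ``snr_cutoff``.
    """
    streams = _substreams(config)
    structure = _build_structure(config, streams["structure"])
    proteins, effects = _build_truth(config, structure, streams["truth"])
    rng = streams["mrmhr"]

    known = set(structure.accessions)
    unknown = [p for p in target_proteins if p not in known]
    if unknown:
        raise ConfigError(
            f"unknown target accession(s): {', '.join(sorted(unknown))}")
    panel = list(dict.fromkeys(list(target_proteins)
                               + [HOUSEKEEPING_ACCESSION]))
    pos = {a: i for i, a in enumerate(structure.accessions)}
    panel_idx = np.array([pos[p] for p in panel])
    pep_mask = np.isin(structure.pep_protein_idx, panel_idx)
    pep_idx = np.flatnonzero(pep_mask)
    tr_mask = pep_mask[structure.tr_pep_idx]
    tr_pep = structure.tr_pep_idx[tr_mask]

    days = (7, 14)
    sample_rows = []
    for day in days:
        for animal in range(1, config.animals_per_day_mrmhr + 1):
            sample_rows.append({
                "sample_id": f"MR_D{day:02d}_A{animal}",
                "eye": str(rng.choice(["OD", "OS"])),  # random eye sampled
                "day": day, "replicate": animal, "cohort": "MRMHR"})
    samples = pd.DataFrame(sample_rows, columns=[
        "sample_id", "eye", "day", "replicate", "cohort"])
    lo, hi = config.bias_log2_range
    bias = rng.uniform(lo, hi, size=len(samples))
    bias_series = pd.Series(bias, index=samples["sample_id"].to_numpy(),
                            name="bias_log2")

    sigma_bio_log2 = (np.sqrt(np.log1p(config.bio_cv_mrmhr ** 2)) / _LN2
                      if config.bio_cv_mrmhr > 0 else 0.0)
    pep_base = (structure.baseline_log2[structure.pep_protein_idx]
                + structure.pep_offset)
    chunks = []
    for j, row in enumerate(samples.itertuples(index=False)):
        effect = _effect_vector(structure, effects, row.day, row.eye)
        bio = np.zeros(len(structure.accessions))
        if sigma_bio_log2 > 0:
            draw = rng.normal(-0.5 * sigma_bio_log2 ** 2 * _LN2,
                              sigma_bio_log2, size=len(panel_idx))
            bio[panel_idx] = draw
        pep_log2 = (pep_base[pep_idx]
                    + effect[structure.pep_protein_idx[pep_idx]]
                    + bio[structure.pep_protein_idx[pep_idx]] + bias[j])
        full = np.full(len(structure.pep_names), np.nan)
        full[pep_idx] = pep_log2
        noise = _lognormal_noise(rng, config.replicate_cv, int(tr_mask.sum()))
        area = (np.exp2(full[tr_pep]) * structure.fractions[tr_mask] * noise)
        chunks.append(pd.DataFrame({
            "sample_id": row.sample_id, "eye": row.eye, "day": row.day,
            "replicate": row.replicate, "cohort": row.cohort,
            "protein": structure.accessions[
                structure.pep_protein_idx[tr_pep]],
            "peptide": structure.pep_names[tr_pep],
            "precursor_charge": structure.pep_charge[tr_pep],
            "fragment_label": structure.frag_labels[tr_mask],
            "area": area, "snr": np.nan}))
    transitions = pd.concat(chunks, ignore_index=True)[TRANSITION_COLUMNS]

    # snr proportional to area over a noise floor chosen so that the
    # configured fraction of transitions falls below the cutoff
    areas = transitions["area"].to_numpy()
    floor = np.quantile(areas, config.snr_below_cutoff_fraction) \
        / config.snr_cutoff
    transitions["snr"] = areas / floor
    truth = SynthTruth(proteins, effects, bias_series)
    return transitions, samples, truth


# ---------------------------------------------------------------------------
# on-disk truth


def write_truth(truth: SynthTruth, path: str | Path) -> None:
    """Write the per-protein truth table plus realized effects as TSV."""
    path = Path(path)
    proteins = truth.proteins.copy()
    proteins.to_csv(path, sep="\t")
    effects_path = path.with_name(path.stem + "_effects.tsv")
    truth.effects.to_csv(effects_path, sep="\t", index=False)


def write_dataset(out_dir: str | Path, transitions: pd.DataFrame,
                  samples: pd.DataFrame, truth: SynthTruth,
                  library: pd.DataFrame | None = None,
                  prefix: str = "swath") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_quant_table(transitions, out / f"{prefix}_transitions.tsv")
    write_sample_sheet(samples, out / f"{prefix}_samples.tsv")
    if library is not None:
        write_ion_library(library, out / "ion_library.tsv")
    write_truth(truth, out / f"{prefix}_truth.tsv")
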