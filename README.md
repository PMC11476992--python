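# vitreoquant

Label-free SWATH-MS quantification and MRM-HR targeted validation for
chick vitreous proteomics during emmetropization.

## What this is for

In the first month after hatching, the chick eye elongates until its
axial length matches its optical power (emmetropization), and the
vitreous humor — the gel filling most of the eyeball — changes protein
composition along the way. Profiling those changes is a two-arm
mass-spectrometry problem:

* a **discovery arm** (SWATH-MS, data-independent acquisition) on
  pooled right-eye (OD) and left-eye (OS) samples at days 7, 14, 21 and
  28 post-hatch, three technical replicates each (24 injections), and
* a **validation arm** (high-resolution MRM) on individual animals
  (n = 4 per day) at days 7 and 14.

This package implements the complete downstream analysis for both arms
as a tested Python library with a thin CLI, plus a ground-truth
simulator of the study design so that every stage can be verified
without the deposited raw data. It is aimed at proteomics analysts who
work from vendor peak-area exports (long transition tables) rather than
raw spectra.

## The statistics at its core

**Roll-up.** With $A$ the extracted transition peak areas, peptide and
protein areas in the DIA arm are top-$k$ sums (6 transitions/peptide,
10 peptides/protein, library confidence ≥ 0.90, unique-mapping peptides
only). The targeted arm instead averages: peptide intensity is the mean
of the top-3 transitions with S/N ≥ 20, protein intensity the mean of
the top-3 peptides.

**Most-likely-ratio (MLR) normalization.** Loading variation scales
every area of injection $j$ by an unknown factor $f_j$. Since most
proteins are unregulated, the per-protein log-ratios
$r_{ij} = \log_2 (A_{ij} / A_{i,\mathrm{ref}})$ concentrate at
$\log_2 f_j$; the factor is estimated as $2^{\hat m_j}$ with
$\hat m_j$ the mode of the ratio distribution (Gaussian KDE, Silverman
bandwidth, 512-point grid; median fallback under 50 shared proteins).

**Bilateral-concordance DEP filter.** Per eye,
$\mathrm{FC} = \bar A_{\mathrm{day}} / \bar A_{\mathrm{day7}}$ over
technical replicates. A protein is up-regulated when both eye FCs are
≥ 1.5, down-regulated when both are ≤ 0.7, subject to ≥ 2 supporting
peptides; the two independently processed eye pools act as built-in
replication, so no p-value exists (or is faked) at this stage. Reports
carry $\overline{\mathrm{FC}} = (\mathrm{FC}_{OD}+\mathrm{FC}_{OS})/2$
and the two-value sample SD $|\mathrm{FC}_{OD}-\mathrm{FC}_{OS}|/\sqrt2$.
Proteins called in every contrast with a consistent direction form the
cross-timepoint intersection; heatmap summaries use per-row z-scores
$(A_{ij}-\bar A_i)/s_i$.

**Targeted validation.** Protein intensities are divided by GAPDH in
the same injection, the fold change is the day-14/day-7 ratio of group
means over animals, and a pooled-variance unpaired t-test gives the
per-protein p-value (α = 0.05).

See `docs/methods.md` for assumptions, parameter meanings and
limitations, including what the simulator does and does not emulate.

## Worked example

```python
from vitreoquant import synthdata, rollup, normalize, depfilter
from vitreoquant.depfilter import ContrastSpec

cfg = synthdata.SynthConfig(n_proteins=300, seed=11)
transitions, samples, library, truth = synthdata.generate_swath(cfg)

matrix = rollup.build_matrix(transitions, library, samples)   # 300 x 24
result = normalize.normalize_dataset(matrix)                  # MLR factors

deps = {d: depfilter.find_deps(result.normalized, ContrastSpec(d))
        for d in (14, 21, 28)}
for d, r in deps.items():
    up = sum(x.direction.value == "UP" for x in r)
    print(f"day {d}/7: {len(r)} DEPs ({up} up, {len(r) - up} down)")
common = depfilter.intersect_deps(deps)
print("common:", len(common["UP"]), "up,", len(common["DOWN"]), "down")
```

prints

```
day 14/7: 31 DEPs (17 up, 14 down)
day 21/7: 30 DEPs (16 up, 14 down)
day 28/7: 30 DEPs (16 up, 14 down)
common: 16 up, 14 down
```

i.e. at every age the bilateral filter recovers the simulated
regulated proteins (this config plants 30 with concordant effects and
15 discordant decoys among 300), and the intersection keeps those
regulated the same way at all three ages. Each `DepRecord` carries the
per-eye fold changes and their summary, e.g.
`P0003  FC_OD 4.34  FC_OS 3.37  -> 3.86 ± 0.69  UP  (10 peptides)`.

The same pipeline is scriptable from the shell:

```sh
vitreoquant simulate --seed 7 --out-dir data/
vitreoquant swath-quant --transitions data/swath_transitions.tsv \
    --library data/ion_library.tsv --samples data/swath_samples.tsv \
    --out-dir quant/
vitreoquant dep --matrix quant/protein_matrix.csv \
    --samples quant/samples.tsv --counts quant/peptide_counts.tsv \
    --out-dir dep/
```

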