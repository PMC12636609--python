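# rg4fus

Quantitative analysis toolkit for studying how RNA G-quadruplexes (rG4s)
regulate liquid–liquid phase separation (LLPS) of the ALS/FTD-linked
RNA-binding protein FUS. Short, stable rG4-forming RNAs can dissolve FUS
droplets and aggregates by preferentially engaging the soluble protein pool;
this package implements the computational side of that investigation for
researchers working on RNA–protein condensates:

- **rG4 motif scanning** — QGRS-style enumeration of quadruplex motifs
  (four G-runs of length *g* ≥ 2 separated by three loops of 0–36 nt, total
  span ≤ 30 nt) with a surrogate G-score for ranking.
- **Transcriptome-interval enrichment** — bedtools-style interval overlap
  counting between scored rG4 regions and soluble/droplet-phase FUS
  interactomes, tertile stratification by "G4 Probability" (the fraction of
  reads with reverse-transcription stops in rG4-seq), per-region enrichment
  scores (soluble count / droplet count), and shuffle-based permutation
  tests with empirical p-values.
- **Binding isotherm fitting** — the quadratic ligand-depletion anisotropy
  model
  *y = a₀ + ΔA_max · [(x + L_t + K_d) − √((x + L_t + K_d)² − 4 x L_t)] / (2 L_t)*
  fitted by nonlinear least squares.
- **CD melt fitting** — means-movement smoothing, buffer subtraction, and the
  two-state van't Hoff melt model
  *Y = [(m_f X + b_f) + (m_u X + b_u)·Q] / (1 + Q)*, with
  *Q = exp((ΔH/R)(1/T_m − 1/X))* and X in Kelvin, yielding T_m and ΔH.
- **Turbidity kinetics** — buffer subtraction, control/pre-RNA normalization
  and trapezoidal AUC for LLPS inhibition, reversal and disaggregation
  assays; sedimentation fractions.
- **Condensate imaging** — droplet segmentation, per-droplet enrichment
  (mean intensity inside / mean background), phase-diagram tables, top-hat
  speckle enhancement, cytoplasmic-foci masking and Pearson colocalization
  for stress-granule recruitment.
- **Synthetic data** — seeded generators for every input (planted-enrichment
  interval sets, titrations, melts, turbidity traces, droplet and cell
  images) so the whole pipeline is testable without any downloads.

## Worked example

Fit a CD melt curve of an rG4 in potassium buffer (here generated
synthetically at the acquisition grid, 15–85 °C at 1 °C pitch with 0.1 mdeg
noise):

```python
from rg4fus.melt import Spectrum, fit_melt
from rg4fus.simulate import simulate_melt

df = simulate_melt(t_m=50.64, delta_h=180e3, sigma=0.1, seed=1)
res = fit_melt(Spectrum(df["x"].to_numpy(), df["y"].to_numpy()))
print(f"Tm = {res.model.t_m:.2f} C, dH = {res.model.delta_h/1e3:.0f} kJ/mol")
```

prints

```
Tm = 50.79 C, dH = 191 kJ/mol
```

the fitted melting temperature (within noise of the 50.64 °C ground truth)
and the van't Hoff unfolding enthalpy. The same pipeline is available from
the shell, e.g.:

```bash
rg4fus simulate curves --seed 1 -o data/
rg4fus fit-melt data/melt.tsv -o melt.json
rg4fus g4scan sequences.fasta -o scan.tsv
rg4fus permtest --a g4.bed --b soluble.bed --genome sizes.tsv --n 100 --seed 7 -o perm.json
```

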