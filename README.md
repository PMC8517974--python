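# znmt — Zn(II)–metallothionein binding analysis

Metallothionein-2 (MT2) is a 61-residue, 20-cysteine protein that buffers
cellular Zn(II) through two metal–thiolate cluster domains: a β-domain
(residues 1–30) hosting a Zn₃Cys₉ cluster with three bridging and six
terminal sulfur donors, and an α-domain (residues 31–61) hosting a Zn₄Cys₁₁
cluster with five bridging and six terminal donors.  Because partially
Zn(II)-loaded species are the biologically active ones, their composition and
energetics are probed by combining mass spectrometry (differential cysteine
labelling with iodoacetamide/N-ethylmaleimide, native MS of intact
metalloforms) with molecular simulation (steered MD pulling, well-tempered
and parallel-bias metadynamics).

`znmt` implements that computational layer as a tested, desk-scale Python
package, with a synthetic-data module providing every input with known
ground truth:

- **topology** — metal–thiolate cluster graphs; the bridging/terminal
  identity `b = c·n_M − n_L`, `t = 2·n_L − c·n_M` for `c`-coordinate metals;
  free-Cys accounting and α/β domain assignment.
- **colvars** — the rational switching function
  `s(r) = (1 − x^n)/(1 − x^m)`, `x = (r − d₀)/r₀`, the Zn–S/Zn–O
  coordination-number CVs `CN = Σⱼ s(rⱼ)` (Zn–S: n=8, m=12, r₀=0.3 Å,
  d₀=2.4 Å), the combined bound-metal count, and the distance-RMSD CV.
- **pathways** — per-frame CN matrices, metal-release detection at the
  CN < 0.9 threshold with a persistence window, pathway classification with
  empirical probabilities, and the per-species α/β occupancy ledger.
- **smd** — pulling arithmetic (t = (r_F − r₀)/v), sawtooth rupture-peak
  detection, replicate mean ± SE profiles, and the moment-based Gaussian
  rupture-force fit.
- **metad / dynamics / fes** — underdamped Langevin (BAOAB) on analytic toy
  potentials with well-tempered metadynamics
  (`h = h₀·e^{−V/k_B ΔT}`, ΔT = (γ−1)T) and parallel-bias metadynamics
  (`V_PB = −k_BT log Σⱼ e^{−Vⱼ/k_BT}`), multiple walkers, walls; FES
  estimation `F = −γ/(γ−1)·V`, umbrella-sampling-like reweighting
  (`w ∝ e^{+V/k_BT}`), block-analysis errors, and basin detection.
- **mslabel** — per-Cys NEM/IAM fraction quantification, the proteoform mass
  ledger (IAM +57.021 Da, NEM +125.048 Da, Zn −2H +61.913 Da) with species
  naming such as `Zn_4_IAM_9_MT2`, and increment-difference absorption
  spectra.
- **synthetic** — generators for scripted CN-decay trajectories, sawtooth
  force curves, Langevin toy systems, and peptide label tables; all pure
  functions of (parameters, seed).

## Worked example

Run the end-to-end demo pipeline (generate → analyze → report) from one
seed:

```bash
znmt demo --seed 1 --out demo_out
```

which prints a manifest like

```json
{
  "seed": 1,
  "pathways": {"Zn1 > Zn2": 0.7, "Zn2 > Zn1": 0.3},
  "rupture_fit_pN": {"mu": 1345.96, "sigma": 255.38},
  "metad_hills": 600,
  "label_fraction_max_error": 0.045
}
```

Reading: 10 synthetic pulling runs were scripted with two dissociation
orders in a 7:3 ratio and the pathway classifier recovered exactly those
probabilities; the Gaussian fit of 20 synthetic rupture curves recovered a
mean force consistent with their generating distribution (drawn around
1252 ± 438 pN, so a 20-curve sample mean lands within ~±100 pN); 600
well-tempered hills were deposited on a double-well toy whose free-energy
surface is written to `demo_out/fes.dat`; and the per-Cys NEM fractions
recovered from a noisy synthetic peptide table deviate from the
ground-truth occupancy vector by at most 0.045.

Library use mirrors the CLI, e.g.

```python
from znmt.topology import mt2_alpha_cluster, classify_ligands
classify_ligands(mt2_alpha_cluster())   # {'bridging': 5, 'terminal': 6}
```

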