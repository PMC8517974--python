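# Methods

This note records the models, parameter choices, and numerical decisions
behind `znmt`, and what the synthetic-data validations do and do not show
about real data.

## Cluster topology

Metal–thiolate clusters are bipartite graphs metal ↔ Cys Sγ with every metal
at its coordination number (4, tetrahedral Zn/Cd) and every sulfur serving
one metal (terminal) or two (bridging).  Those degree constraints fix the
bridging/terminal split from the composition alone:
`2b + t = c·n_M`, `b + t = n_L`.  The package carries both routes — counting
on an explicit graph and the closed form — and tests them against each other
over random valid graphs.  Residue indexing is 1-based over the 61-residue
chain; the domain intervals are β = 1–30 and α = 31–61, taken verbatim, so
the boundary linker residue 30 (Lys) belongs to β.  A metal site's domain is
the majority domain of its candidate ligands (ties resolved toward β).  The
protein sequence is an input (FASTA); the packaged fixture is the human MT2
sequence (61 aa, 20 Cys: 9 in β, 11 in α).

## Coordination-number collective variables

The switching function `s(r) = (1 − x^n)/(1 − x^m)` with `x = (r − d₀)/r₀`
is clamped to 1 for r ≤ d₀, filled with its analytic limit n/m at the
removable singularity x = 1, and cut to exactly 0 beyond an optional hard
cutoff `d_max`.  Zn–S uses n=8, m=12, r₀=0.3 Å, d₀=2.4 Å (a 0.3 Å-wide
switch placed just past the Zn–S bond length; both lengths are read as Å —
a `units` flag on the parameter object documents an nm convention for
PLUMED interoperability).  Zn–O(water) uses n=12, m=24, r₀=2.9 Å,
d_max=5 Å; its offset d₀ is not independently constrained and defaults
to 0 Å.

The combined "total bound Zn" CV filters each per-site CN through the
switching function with r₀=2.5, d₀=0.  Applied literally that filter reads
≈1 for an *unbound* site (CN≈0) and ≈0.15 for a bound one (CN=4), the
inverse of a bound count, so the default combines the complement
`b(CN) = 1 − s(CN)` — which rises from 0 (apo) toward 7 (fully loaded) and
is monotone in each site's CN; the literal variant sits behind a flag and
the two always sum to the site count.

dRMSD builds its pair list from reference distances inside 0.1–8 Å and
takes the RMS of `d_ij − d_ij^ref`; it needs no superposition and errors
out if the window selects no pair.

## Synthetic data as ground truth

The generators define the package's study conditions:

- **Dissociation trajectories.** Per-metal CN time courses are logistic
  decays from CN≈4 to ≈0 with a configurable transition width (default 5
  frames) and i.i.d. Gaussian CN noise; the scripted event frame is, by
  construction, the first frame at which the noiseless profile sits below
  the 0.9 free threshold.  Profiles are rendered as coordinates by placing
  each metal's four dedicated ligands on tetrahedral rays at the distance
  whose switching value realises CN/4 (inverted through a table uniform in
  r, accurate to ~1e−6 in CN); metal sites are spaced 200 Å apart so
  cross-site contributions are < 1e−11.  Because independently scripted
  per-metal CNs cannot be realised geometrically when a sulfur bridges two
  metals, the emitted systems use a dedicated-ligand "star" topology (≤5
  metals × 4 Cys from the 20); the bridged two-cluster Zn₇ topology remains
  the first-class object for classification and ledger logic.
- **SMD curves.** Piecewise linear-rise/sharp-drop sawtooths through
  scripted (extension, peak force) points, additive Gaussian noise, truth
  recorded on-grid.  Rupture forces for ensemble statistics are drawn from
  N(1252, 438²) pN, the scale of the real pulling campaign.
- **Langevin toys.** Underdamped dynamics on analytic double wells
  `U = a(s² − s₀²)²` (barrier a·s₀⁴) or harmonic wells, in natural units
  (energy kcal/mol, k_B in kcal/mol/K, unit mass; time is an arbitrary toy
  unit).  The default well used for metadynamics validation has a 5
  kcal/mol barrier — deliberately impassable in unbiased runs at 300 K on
  the tested timescales.
- **Peptide tables.** A simple tryptic digest (cut after K/R) of the MT2
  sequence covers all 20 Cys; each covered Cys contributes NEM/IAM rows with
  abundances `A·f`, `A·(1−f)` under multiplicative log-normal noise
  (default σ=0.2) and a replicate count emulating repeated observations.

All generators are pure functions of (parameters, seed); per-run streams
derive from `SeedSequence(seed, spawn_key=(run,))`.

What passing these validations shows: the analysis layer recovers known
truth under realistic noise.  What it does not show: anything about
force-field accuracy, solvent, cooperativity between sites, chromatographic
or ionisation biases — none of which the generators emulate.

## Pathway analysis

The CN matrix is computed for every metal over **all** 20 candidate Cys per
frame.  A metal is free at the first frame from which its CN stays below
0.9 for W consecutive frames (default W=10, configurable; W=1 reduces to
first crossing).  The persistence window is a deliberate addition — how the
original threshold handled transient recrossings is not documented — and
widening it can only remove events (tested as a monotonicity property).
Pathway identity is the metal-id order only, never the kinetics; equal-frame
ties are broken by metal id and flagged.

## SMD analysis

Pulling time is `(r_F − r₀)/v`; the study setting (36 → 205 Å at 100 Å/ns)
gives 1.69 ns, printed rounded as 1.7 ns.  Peak detection is
prominence-based (`scipy.signal.find_peaks`; defaults 150 pN prominence,
5 Å minimum separation, both exposed), since the original peak-picking
procedure is unreported.  With white synthetic noise, sub-dominant
prominence bumps can appear on the rising ramps; single-rupture analyses
therefore take the dominant peak per curve.  The Gaussian rupture fit is by
sample moments (ML), not histogram least squares — bin-free and testable
against closed-form moments; zero-variance samples warn as degenerate.
Replicate mean profiles are linear interpolations onto the common extension
overlap with SE = sd/√n.  Spring constants are accepted in kcal/mol/Å² and
converted at 69.48 pN per kcal/mol/Å.

## Metadynamics engine

The integrator is BAOAB (stable with stiff walls); a heuristic ω·dt check
rejects unstable timesteps.  Well-tempered deposition follows
`h = h₀·exp(−V/k_B ΔT)` with ΔT = (γ−1)·T (γ=18, h₀=0.6 kcal/mol, width
0.12 in the CV's native units, stride 500 — the study defaults; γ=18 at
300 K gives ΔT = 5100 K exactly).  h₀=0 is allowed and disables deposition.
Walkers share one hills log and deposit in index order each stride; results
depend only on (params, seed, n_walkers).  Walls are half-harmonic with
default κ=200 kcal/mol per CV-unit² (unreported in the original; exposed).

Dynamics forces read the bias from a grid cache holding per-node V and
dV/ds accumulated analytically per hill and interpolated with cubic
Hermite polynomials — matching direct summation to better than 1e−6
kcal/mol at the default spacing (validated in tests).  WT heights and the
recorded final bias always use direct summation over the log, so replaying
a HILLS file reproduces the engine's internal bias to round-off.

PBMetaD deposits one Gaussian per CV per stride, scaled by the conditional
weights `w_i = softmax(−V_i/k_BT)`; the bias driving the dynamics is
`V_PB = −k_BT log Σ e^{−V_j/k_BT}` (force on CV i: `w_i · dV_i/ds_i`).
Whether the original applied WT scaling per-CV (V_i) or on V_PB is
ambiguous; the default is per-CV with a flag for the alternative.

## Free-energy estimation and errors

From a WT hills log, `F(s) = −γ/(γ−1)·V(s)`, min-shifted.  Reweighting uses
the final-bias approximation `w_f ∝ exp(+V(s_f)/k_BT)` (valid
post-convergence; the original cites an umbrella-sampling-like scheme
without formulas), normalised so constant bias shifts are gauge-invariant;
an unbiased run reduces to the plain histogram estimator.  Block analysis
averages the weighted histogram block-wise and propagates the block-to-block
spread through F = −k_BT log p as k_BT·SE(p)/p per node (first-order
equivalent to the SE of per-block free energies, but defined at nodes any
block leaves empty of one label); the reported error is the mean over
populated nodes, the plateau is the first ladder size whose successor
changes by <5% (the original describes only a qualitative plateau).  Basin
detection is persistence-based flooding: a basin dies at its lowest exit
saddle and is kept if saddle − minimum ≥ min_depth.

Validation problem sizes — chosen so each stage has clearly converged on
one CPU: WT-MetaD 6×10⁵ steps × 2 walkers on the 5 kcal/mol well (observed
FES RMSE ≈ 0.15–0.2 kcal/mol inside the wells against the 0.5 criterion);
PBMetaD 8×10⁵ steps × 2 walkers on a separable (3, 4) kcal/mol double-well
pair, judged against the combined block error of the two runs; walls at
±1.45 confine the walkers so every analysis block stays inside the
histogram support.

## MS label quantification

Per-Cys fractions are abundance sums per (residue, label) normalised by the
residue's NEM+IAM total; peptides covering several Cys contribute fully to
each modified-site record; uncovered Cys are flagged, never imputed.
Masses are monoisotopic by default (IAM +57.02146, NEM +125.04767 Da;
average masses behind a flag for linear-mode MALDI comparisons).  Zn(II)
uptake by thiolates displaces two protons, so the neutral-species ledger
uses Δm(Zn) = 63.92914 − 2·1.00783 = 61.91348 Da; a flag switches to
bare-metal addition.  Species assignment scans the full
(n_metal, n_IAM, n_NEM) grid with n_IAM + n_NEM ≤ 20, reports unmatched
masses, and flags any observation with ≥2 grid points inside the tolerance
— note the grid self-overlaps at large tolerances (e.g. Zn vs IAM differ by
only 4.9 Da), which is a property of the chemistry, not the matcher.
Increment-difference spectra are `(A_i − A_{i−1})/(c·l)` on a common
wavelength grid.

## Known limitations

- The toy engine is 1–2-D and separable; no all-atom forces, constraints,
  or replica exchange, and no CV gradients w.r.t. Cartesian coordinates
  beyond the identity CVs it integrates.
- Reweighting ignores the time-dependence of the bias before convergence.
- The star-topology trajectory generator cannot script correlated
  (bridge-mediated) dissociation of two metals.
- Binary trajectory formats (DCD/XTC) are an extension point; only
  multi-model PDB and XYZ are read/written.
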