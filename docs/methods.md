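# Methods

`osteosim` couples two deterministic ODE systems across time scales to model
how the delivery order of two osteogenic cytokines — BMP-2 and IGF-1 —
shapes the fate of bone-marrow stromal cells (BMSCs) in culture: a
mass-action **molecular signaling system** (hours) and a compartmental
**cell-lineage system** (days), linked by scalar transcription-factor (TF)
readouts.

## Molecular model

Each tracked state is the phosphorylated (or receptor-complexed) form of a
protein.  For species *M* with activators *pA_j* and inhibitors *I_j*:

    d[pM]/dt = Σ_j a_j [pA_j] ([M]) − Σ_j d_j [I_j] [pM],   [M] = C_M − [pM]

The total *C_M* of each phospho/unphospho pair is conserved on the fast
signaling time scale, so the unphosphorylated pool is algebraic.
Ligand–receptor binding follows the same form with association/dissociation
rates; free + complexed receptor is constant.  Species with no explicit
inhibitor dephosphorylate against an unmodeled unit phosphatase pool.

The canonical topology has 20 dynamic species (14 conservation-paired
phospho proteins, 2 ligand–receptor complexes, 4 TF outputs), 16 algebraic
complements (36 variables) and 37 rate parameters: an a/d pair per paired
species (32), an activation rate per TF (4) and one shared TF decay rate.
Wiring: BMP-2 → receptor complex → {TAK1 → p38 MAPK, SMAD1/5} → Runx2;
IGF-1 → receptor complex → {Ras → c-Raf → MEK → ERK, PI3K → PDK1 → Akt};
Akt → {GSK3β, mTOR → {p70S6K → S6, osterix}}; ERK and S6 feed a
proliferative TF output.  Two deliberate conventions:

* **ERK ⊣ SMAD1/5.** The only modeled crosstalk between the two ligand
  arms: phospho-ERK is SMAD1/5's dephosphorylating input (its *only* decay
  channel), so early IGF-1 shuts the BMP-2 → SMAD → Runx2 axis down.
* **GSK3β / β-catenin sign convention.** Phosphorylation *inactivates*
  both: Akt phosphorylates GSK3β, and the remaining *unphosphorylated*
  GSK3β pool phosphorylates β-catenin (both phosphorylated pools are the
  degraded/inactive ones).  Consequently strong GSK3β phosphorylation marks
  β-catenin activation.
* A weak BMP-2-complex → PI3K crosstalk edge (structural weight 0.4) lets
  prior BMP-2 exposure potentiate the Akt axis, consistent with reported
  BMP-2-induced PI3K/Akt activation in osteoblast-lineage cells.  Edge
  weights are part of the topology, not fitted parameters.

Units: time in hours; concentrations in arbitrary units with all totals 1
(the assay data the model is fitted against are relative, so the absolute
scale is unidentifiable).  Dose is normalized so 50 ng/ml ↦ 1.0.  Delivered
ligand is a step input held constant after its delivery day (optional
exponential decay is available but off by default — no decay information is
available to calibrate it).  Integration: LSODA, rtol 1e-6 / atol 1e-9,
restarted at delivery times; values in [−1e-9, 0) are clipped to 0, anything
below −1e-9 is an error.

**TF readouts.** TF expression changes over days, far slower than
phosphorylation, so each TF's activity is summarized as the time-average
(over the window from first delivery to 48 h past the last) of its immediate
upstream phospho fraction: Runx2 ← mean(p-p38, p-SMAD1/5); osterix ←
p-mTOR; β-catenin ← p-GSK3β (per the sign convention above); proliferative
TF ← mean(p-ERK, p-S6).  A time-average rather than an endpoint damps
transient bursts (ERK's response to IGF-1 lasts minutes).  The untreated
control has identically zero readouts.

## Cell-lineage model

Four compartments — BMSC, preosteoblast (OBp), mature osteoblast (OBa) and
non-osteoblastic cells (MSCq):

    d[BMSC]/dt = P_MSC[BMSC] − (D_MSC + Q_MSC)[BMSC]
    d[MSCq]/dt = Q_MSC[BMSC] + Q_OBp[OBp]
    d[OBp]/dt  = P_OBp[OBp] + D_MSC[BMSC] − (D_OBp + Q_OBp)[OBp]
    d[OBa]/dt  = P_OBa[OBa] + D_OBp[OBp]

MSCq and OBa are absorbing; total mass is not conserved (the culture
proliferates).  Every rate is basal + promotion terms of the form
coefficient × TF readout × window(t), where window(t) is 1 inside
[delivery day, delivery day + t_p] of the relevant cytokine.  t_p is the
effective time a delivered cytokine (and the TFs it induces) keeps acting
on cellular rates; one shared rectangular window per delivery.  Gating
(which TF modulates which rate):

| term | rate | gate | meaning |
|------|------|------|---------|
| b_1  | D_MSC | Runx2 × BMP window | BMP-2 drives BMSC → OBp commitment |
| i_2  | D_OBp | mean(osterix, β-catenin) × IGF window | IGF-1 matures OBp → OBa |
| i_1  | P_*  | proliferative TF × IGF window | IGF-1 mitogenic boost |
| i_3  | Q_MSC | (1 − Runx2) × IGF window | without timely Runx2, IGF-1 routes BMSCs out of the lineage |

Initial condition: 100 % BMSC, mass 1, day 0.  Rates are piecewise constant
between window boundaries, so integration restarts there (LSODA, rtol 1e-9).

## Default (ground-truth) parameters

The defaults in `osteosim.defaults` define the conditions the synthetic
generator emulates.  Kinetics: trunk cascade a = 2.0, d = 0.5 h⁻¹ (settles
in a few hours at fractional activation ≈ 0.75); receptor binding a = 1.0,
d = 0.1; SMAD1/5 a = 1.0 with strong ERK-mediated d = 5.0 so that the
crosstalk is decisive; TF activation 1.5, shared decay 0.3 h⁻¹ (slower than
the kinase layer).  Lineage (day⁻¹): P0 = 0.10 for BMSC/OBp and 0.12 for
OBa (mature osteoblasts compound slightly faster, favoring early
maturation), D0 = 0.01, Q0_MSC = 0.005, Q0_OBp = 0.04 (uncommitted OBp leak
out of the lineage), b_1 = 0.40, i_1 = 0.01, i_2 = 0.40, i_3 = 0.02,
t_p = 4 days.  The cytokine coefficients were calibrated once against the
qualitative experimental picture the model is meant to reproduce — calcium
deposition ordered B1I4 > {I1B1, B1} > {I1B4, I1, control}, early
(≤ day 11) total-mass curves within 10 % across scenarios, and a day-29
osteoblast optimum at BMP-2 day 1 / IGF-1 day 4 — and are not revisited.
The resulting optimum emerges mechanistically: delivering IGF-1 too early
suppresses Runx2 (ERK ⊣ SMAD) and wastes the maturation window on a small
OBp pool; delivering it too late lets OBp leak into MSCq and leaves mature
osteoblasts less time to compound.

## Synthetic data

The generator forward-simulates all six experimental scenarios (control,
I1, B1, I1B1, I1B4, B1I4; 50 ng/ml per delivery) and emits: RPPA-like
phospho time courses for 12 proteins (p38 MAPK, SMAD1/5, ERK, GSK3β, S6,
Akt, mTOR, p70S6K, c-Raf, MEK, TAK1, PI3K) in the four RPPA scenarios,
sampled at 0–48 h offsets from the *last* delivery; dsDNA total mass at
days 1/4/8/11 (4 replicates); day-28 ARS-like osteoblast output normalized
to control (4 replicates); an ALP-like OBp fraction.  Noise is
mean-preserving multiplicative lognormal with configurable CV (default
0.1 — a typical plate-assay replicate spread); zero CV returns exact model
means.  The generator emulates assay *shape and noise*, not biological
features absent from the model (cell-cycle structure, spatial effects,
batch drift, the irregular single-protein RPPA patterns real arrays show) —
so passing recovery tests demonstrates the pipeline's correctness, not that
real data would be this well-behaved.

## Calibration

* **Molecular:** affine-invariant ensemble MCMC (emcee) over log10-rates,
  Gaussian likelihood (σ = 0.02 by default) on the per-scenario RPPA table.
  Each scenario is fitted separately; the per-scenario spread of fitted
  rates (counts below 0.02 / above 0.08) is a descriptive readout of
  treatment-specific signaling remodeling.  Not all 37 rates are
  identifiable from 12 observed species; recovery guarantees cover the
  documented identifiable subset (a/d of TAK1 and p38 under
  BMP-2-containing scenarios).  Default chains for exploratory use are
  longer; test-path chains are 14 walkers × 250 steps, which already pin
  the identifiable rates within a few percent on zero-noise data.
* **Cellular:** bounded trust-region least squares (scipy) on normalized
  total mass and control-normalized day-28 OBa jointly across scenarios,
  with deterministic multi-start.  On zero-noise data the loss at the
  optimum is below 1e-10 and b_1, i_3, D0_MSC, D0_OBp are recovered
  essentially exactly.

## Sensitivity analysis

PRCC uses scipy's Latin hypercube and rank-residual partial correlation.
eFAST is implemented in-package: driving frequency ω = (N−1)/2M for the
parameter of interest, complementary frequencies chosen as distinct odd
values ≤ ω/(2M) (decorrelating the complementary parameters along one
curve matters — consecutive small frequencies bias the total-variance
estimate), NR = 3 random-phase resample curves, M = 4 harmonics, default
N = 513 points per curve; a dummy parameter supplies the significance
floor, and the 2 % variance-share filter reproduces the usual reporting
convention.  The implementation is validated against the Ishigami
function's closed-form indices (main effects within 0.05; totals match to
similar accuracy).

## Screening

The 7 × 7 grid (delivery days 1…7 for each cytokine, 49 schedules,
containing every 0–5-day inter-delivery interval) evaluates
control-normalized OBa at day 29 per cell, one full multiscale simulation
each.  Ties within 1e-6 relative (solver round-off) break to the
lexicographically smallest (day_B, day_I).  The model *predicts* osteoblast
formation at day 29 while the calcium assay is read at day 28; both days
are exported and the one-day offset is kept as designed.

## Known limitations

No spatial structure, receptor trafficking, ligand depletion or
transcription/translation delays beyond the TF-readout abstraction; the
supplementary-only details of the original wiring (exact variable
identities, parameter indexing, MCMC settings, RPPA time points) are
replaced by the documented canonical choices above, so fitted values are
comparable in structure but not numerically to any previously reported
ones; identifiability of the full 37-rate system from 12 observed species
is not claimed.
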