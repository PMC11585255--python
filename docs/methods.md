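# Methods

This note records the models implemented in `pparbias`, the assumptions they
make, the defaults and why, and what the synthetic-data experiments do and do
not demonstrate.

## Binding equilibria

All internal concentrations are nanomolar; converters live at the I/O
boundary (`pparbias.units`).

**Two species.** With receptor total P, tracer total L₀ and tracer
dissociation constant K_d, the fraction of tracer bound is the physical root
of the mass-balance quadratic, evaluated in the cancellation-free (citardauq)
form `F = 2P / (s + sqrt(s² − 4PL₀))`, `s = P + L₀ + K_d`.

**Three species (competition).** Free receptor R solves
`R·(1 + L₀/(K_d+R) + I/(K_i+R)) = P`, a cubic in R.  The production path is
the closed-form trigonometric root with the unique solution selected in
[0, P]; if the evaluated mass-balance residual exceeds 10⁻¹³·P (cancellation
when R ≪ |a|), the root is re-bracketed with Brent's method.  A
Steffensen-accelerated fixed-point iteration
`R ← P/(1 + L₀/(K_d+R) + I/(K_i+R))` is kept as an independent numeric
oracle; the two agree to better than 10⁻¹² relative across five decades of
concentration (measured: ~3·10⁻¹³ over 1000 random systems).

**Many competitors (cellular occupancy).**  Under the trace-receptor
assumption, occupancy of the receptor by coregulator i is
`occ_i = (C_i/K_i)/(1 + Σ_j C_j/K_j)`.  The assumption is flagged (warning,
not error) when the receptor exceeds 10% of the smallest coregulator
concentration — a deliberate, conservative threshold since the source
assumption is only qualitative.  An exact variant solves the full mass
balance with coregulator depletion and is used to validate the closed form:
at 50 nM receptor against 150–1500 nM coregulators with low-micromolar Ki
values the two agree to < 0.2% absolute occupancy, because depletion of any
coregulator is ≲ 1% there even though the 10% concentration heuristic fires.

## Curve fitting and Ki

Responses are equilibrium anisotropy values; the assay incubates to
equilibrium before reading, so no kinetic correction is applied.

**4PL.**  `y = bottom + (top − bottom)/(1 + 10^((logEC50 − logC)·hill))`,
fit by least squares on log₁₀ concentration.  Initialisation: bottom/top
from the response extremes, logEC50 from the half-response crossing,
hill = −1, with five jittered restarts before a fit is flagged
non-converged (returned, never raised).  Orientation is normalised so
top > bottom.  EC₅₀ is carried on the log scale; its 95% CI is the
asymptotic t interval on logEC50.

**ROUT.**  Robust fit with Lorentzian (Cauchy) loss, the residual scale
re-estimated from the 68.27th percentile of absolute residuals (with an
n/(n−4) small-sample correction); each observation's studentised residual
receives a two-sided t p-value, screened by Benjamini-Hochberg at rate Q
(default 1%); flagged points are excluded and ordinary least squares is run
on the remainder.  Q = 0 disables removal.  All 16 observations per
concentration (2 technical × 8 dilution replicates) are pooled when a whole
plate is fit; the pipelines fit per dilution replicate, which is the unit of
replication for bias statistics.  Measured on the assay design: 100% of
10-σ displaced points flagged, 0.06% of clean points flagged, and 96.4%
coverage of the 95% EC₅₀ interval.

**EC₅₀ → Ki.**  The exact competition-assay correction (the
Huang / Nikolovska-Coleska family), parameterised by F₀ (fraction of tracer
bound at zero competitor) and L₀ (total tracer):

    PL50 = F₀L₀/2            L50 = L₀ − PL50
    P0   = K_d·F₀/(1−F₀)     P50 = K_d·F₀/(2−F₀)
    I50  = EC50 − (P_T − P50 − PL50)
    Ki   = I50 / (L50/K_d + P0/K_d + 1)

Applied to the *true* midpoint of the exact competition curve this inverts
the planted Ki to machine precision; the residual error of the full
simulate → 4PL fit → convert chain (≈1.3% at zero noise, ≈−1.5% mean over
200 noisy plates) comes from the 4PL being only an approximation to the
exact competition isotherm under receptor depletion.  A classical
Cheng–Prusoff variant is selectable (`convention="cheng_prusoff"`) for
dilute-limit comparisons.  The conversion raises a descriptive error when
the EC₅₀ is smaller than the receptor-sequestered competitor at the
midpoint (no positive Ki is consistent).

## Ligand bias from Ki

σ = log₁₀(Ki_ref_ligand/Ki_test_ligand) per coregulator and assembly
(positive = test ligand binds the coregulator more tightly);
bias = σ_coreg − σ_CBP.  The sign convention makes "favours PGC1α" positive.
σ is computed within matching dilution-replicate index (pairing removes
day-to-day effects); when replicate indices differ the sorted Ki values are
matched in order with a warning.  Group means carry Student-t 95% CIs
(n = 8); a group is significantly biased when the CI excludes zero.  Group
contrasts use a two-way (ligand × coregulator) ANOVA with Tukey HSD;
unbalanced designs fall back to Type-II sums of squares with a warning.
Bias is antisymmetric under swapping test and reference ligand and invariant
to global Ki rescaling; both are property-tested.

## Pathway bias from DE tables

σ_g = log₁₀(|LFC_ref|/|LFC_test|), so genes affected more strongly by the
reference ligand score positive regardless of direction.  Effects with
|LFC| < 0.01 are floored at 0.01 before ratioing (keeps σ finite; flagged in
the output), and a gene is scorable only if adjusted p < 0.05 for at least
one of the two ligands at that timepoint.  Gene bias subtracts the mean σ_g
over the reference pathway's scorable genes; a pathway's call derives
exactly from the t-based 95% CI of its genes' bias values (strictly positive
interval → biased toward the reference ligand, strictly negative → toward
the test ligand, otherwise unbiased; fewer than two scorable genes →
indeterminate).  The reference pathway's own mean bias is zero by
construction and it can never be called biased against itself.

**A calibration caveat the implementation makes visible.**  Because every
gene's bias shares the reference pathway's mean σ, pathway calls within one
dataset are positively correlated, and the per-direction null rate exceeds
the idealised α/2 = 2.5% by a factor ≈ the inflation of
`sqrt(1 + n_pathway/n_reference)` inside the t threshold.  The synthetic
layout therefore gives the reference pathway the largest membership (300
genes, the "most consistently affected pathway" role it plays in practice),
which keeps the measured null rate at ≈3 flagged pathways per direction
against the idealised 2.45 of 98 pathways — close, but systematically above,
and occasionally one-sided within a single dataset when the reference draw
is unlucky.  Conclusions that lean on the *count* of biased pathways should
bear this in mind.

Over-representation is the upper-tail hypergeometric test per pathway with
Benjamini-Hochberg adjustment (significant at adjusted p < 0.05).  The
selectivity index is the mean |LFC| over the antidiabetic-associated gene
set minus the mean |LFC| over the adverse-effect set — zero when both sets
are equally regulated, positive when the antidiabetic set is more strongly
regulated; the published index it stands in for is cited rather than
restated in the source literature, so the package fixes only this sign
contract and the difference form.  DE-set partitioning reports exact Venn
cells keyed by the subset of ligands calling each gene significant, plus
cross-timepoint transitions for genes unique to one ligand at the first
timepoint.

## Motif scanning

Windows of matrix width are scored as Σ log(p_base/background) with a
uniform 0.25 background and natural-log odds (matching the printed cutoff
convention of the upstream scanning tool); `N` contributes 0.  Matrices may
be supplied as JASPAR-style counts (pseudo-count 0.5) or probabilities.
Both strands are scanned; coordinates are 0-based half-open on the forward
strand; presence is ≥1 hit at or above threshold within the scanned window;
overlapping hits are all reported.  The default DR1 matrix is a synthetic
sharp matrix (0.94 on the consensus GGGTCAAAGGTCA) standing in for the
heterodimer's published motif; the exact pseudo-count/background convention
behind the cutoff 7.350619126 is internal to the original tool, so both are
exposed as parameters.  An exact single-window score distribution (dynamic
programme over positions) provides the analytic null for background hit
rates.  Upstream sequence extraction (genome + TSS → FASTA) is out of
scope; the scanner consumes pre-extracted FASTA.

## Synthetic data

* **Plates** mirror the assay: 800 nM receptor, 50 nM tracer (default
  tracer K_d 200 nM, a typical fluorescent-peptide affinity), a 24-point
  geometric competitor series spanning 0.5–185 µM final, 2 technical × 8
  dilution replicates, Gaussian anisotropy noise (σ = 0.004) on a linear
  free/bound mixing model (r_free 0.08, r_bound 0.20).  The forward model is
  the exact competition solver, so fitted-parameter errors measure the
  analysis, not the simulator.
* **DE tables** mirror the processed RNA-seq scale: 15,000 genes, 98
  pathways (20–120 genes) plus the 300-gene reference, shared base effects
  (|LFC| ≈ |N(1.2, 0.6)|, floor 0.3), LFC noise σ = 0.25 per ligand, a 10%
  ligand-specific fraction among responsive genes, and adjusted p-values
  assigned from the responsiveness label (DE model fitting is upstream of
  this pipeline and out of scope).  Planted pathway bias scales the
  reference ligand's effects by 10^σ.  Power experiments use the
  shared-effect condition (ligand-specific fraction 0), where the planted
  offset is the only systematic ligand difference.
* **Promoters** are uniform-background sequences; planted sites are exact
  consensus copies at recorded strand/offset, so recovery at plant rate 1 is
  a sharp contract rather than a stochastic one.

What passing these experiments does **not** show about real data: plate
noise is homoscedastic and Gaussian (real plates drift within rows and
saturate detectors); DE effects here are independent across genes
(co-regulation inflates pathway CI miscalibration further in real data);
pathway memberships are disjoint (KEGG pathways overlap heavily); promoter
background is uniform (real upstream regions have GC structure and repeats).

## Numerical and design choices

* Solvers target 10⁻¹³ relative; all acceptance comparisons run at 10⁻⁹.
* EC₅₀ CIs are asymptotic-t on logEC50 — adequate at n ≈ 48–384
  observations per curve, slightly anti-conservative below ~20.
* Ties in the BH screens are handled by the standard step-up rule.
* The Ki workbook importer normalises µM columns to nM on read.
* Experiment sizes (1000 systems, 200 plates, 500 simulation runs, 1000
  power replicates) were chosen so each experiment's Monte-Carlo error is
  well below the margin it is judged against while the full battery stays in
  the minutes range on a single core.

## Known limitations

Cooperative or multi-site binding, binding kinetics, RXRα heterodimer
energetics (assemblies are labels, not models), global shared-parameter
fitting across curves, DE model fitting, and live database retrieval are all
out of scope by design.
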