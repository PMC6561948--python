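# Methods

This note records the models behind each module, the tunable parameters
that matter, the numerical choices, and what the synthetic-data generators
do and do not establish.

## Collision exposure model

**Number density.** Rods are treated as cylinders at their mean dimensions
(length `L`, width `w`), so a mass concentration `c` gives
`n = c / (ρ_rod π (w/2)² L)`. With ZnO (`ρ_rod = 5606 kg m⁻³`),
`L = 312 nm`, `w = 76 nm` and `c = 1 mg/ml`, one rod weighs ~7.9 × 10⁻¹⁸ kg
and `n ≈ 1.26 × 10¹⁷ m⁻³`. The density is exactly linear in `c`.

**Hydrodynamics.** The shaken flask is characterized by the rotational
Reynolds number `Re = ρ_f N d² / μ` and the orbital tip speed
`v_tip = π d N`. Defaults: `N = 200 rpm`, `d = 5 cm` (orbit/flask scale; the
diameter is not a measured quantity and is configurable), water at 37 °C
(`ρ_f ≈ 993 kg m⁻³`, `μ ≈ 6.9 × 10⁻⁴ Pa s`), giving `Re ≈ 1.2 × 10⁴`
(turbulent) and `v_tip ≈ 0.52 m/s`. The characteristic relative-velocity
band of the collision model is 0.2–1.8 m/s; `v_tip` falls inside it.

**Collision kernel.** Encounters per cell per second follow the rectilinear
kernel `rate = n σ v` with `σ = π r_cell²`. The effective collision radius
defaults to 1 µm (a cell-scale choice, not a measured value; configurable).
No hydrodynamic screening or lubrication correction is applied — the kernel
is deliberately the textbook upper-bound form.

**Hertz impact.** A collision is modelled as a quasi-static elastic impact of
a sphere (the rod apex, radius `R`, mass `m` of the whole rod) on a
half-space with effective modulus `E*`. Energy balance of
`m δ̈ = −(4/3) E* √R δ^{3/2}` gives
`δ_max = (15 m v²/(16 √R E*))^{2/5}`, from which the maximum force, contact
radius `a = √(R δ)`, mean pressure and peak pressure `p₀ = 1.5 p_mean`
follow. Peak pressure scales as `p₀ ∝ E*^{4/5} v^{2/5} R^{−3/5} m^{1/5}`.
Hertz theory assumes small indentation; events with `δ/R > 0.1` are
returned with `hertz_valid = False` but never dropped, because soft-contact
collisions in this regime are physically real even if the pressure estimate
is then only indicative.

**Contact-stiffness bounds.** The effective modulus of a real rod–cell
contact is unknown and certainly heterogeneous (LPS brush, membrane, wall).
The ensemble therefore samples `E*` log-uniformly between two bounds:

* soft bound: the compliant-cell limit `E_cell/(1 − ν²) ≈ 33 MPa`
  (`E_cell = 25 MPa`, `ν = 0.5`), the rod being effectively rigid;
* stiff bound: calibrated, not assumed. It is fixed by requiring that the
  hardest plausible impact of the ensemble — head-on (`θ = 0`) at the
  maximum speed 1.8 m/s with the sharpest tip (`R = 1 nm`) by a heavy rod
  (dimensions 4 SD above the mean) — reaches exactly the 10 GPa ceiling of
  the modelled pressure range. This solves to `E* ≈ 7.3 GPa`
  (`calibrated_stiff_bound`). An uncalibrated "rigid contact" guess of
  10–20 GPa makes the sampled maximum overshoot the model's own stated
  ceiling for most seeds; anchoring the bound to the ceiling keeps the
  ensemble maximum in the 5.5–7 GPa range across seeds, below 10 GPa with
  seed-robust margin, while preserving the >4-decade span down to
  sub-turgor pressures.

**Monte-Carlo ensemble.** Sampling order is fixed: rod lengths and widths
(truncated normal at the population parameters; mass from the cylinder
volume), tip radii (log-uniform on [1 nm, `w_mean`/2 = 38 nm] — "log" because
apex sharpness is a scale parameter), speeds (uniform on 0.2–1.8 m/s),
obliquity angles `θ` (uniform on [0, π/2); the normal speed is `v cos θ`, so
grazing hits produce arbitrarily small pressures — this is what extends the
distribution below the turgor pressure), effective moduli (log-uniform
between the bounds). One integer seed drives a single `default_rng`; equal
seeds give bitwise-equal summaries.

## Morphometry statistics

The aspect ratio is computed per cell as length/width and then summarized
(not as a ratio of group means), matching a per-cell measurement protocol.
Group summaries use the n−1 SD. The default test is the two-sided pooled
Student t-test; "unpaired t-test" without qualification is read as Student,
with Welch available by flag. Both accept published summary statistics
(mean, SD, n) directly, so reported group values are testable without raw
data. Degenerate input (both groups constant and equal) returns t = 0,
p = 1 by convention. Significance stars: * < 0.05, ** < 0.01, *** < 0.001.

## Gram-stain index

No standard numeric index exists for cuvette-read Gram staining; the
operationalization here is the baseline-corrected peak ratio A590/A530
(crystal violet vs safranine). The baseline is the straight line through the
mean absorbance in two anchor bands (450–470 and 680–700 nm, outside both
dye bands); peaks are window maxima (± 15 nm) of the corrected curve,
floored at 0. Window maxima rather than curve fits keep the estimator
assumption-light; the cost is a small overlap bias (adjacent-peak tails
shift the in-window maximum by a few percent for σ ≈ 20 nm peaks), which the
tests quantify against the analytic two-Gaussian value. The index is exactly
invariant under uniform scaling and under addition of any straight line. The
Gram classification threshold (default 1.0 = equal dye retention, ties
positive) is a convention, required explicitly for any serious use.

## EDS density proxy

EDS acquires from a fixed specimen volume and structural biomass is mostly
carbon, so the ratio of mean carbon weight fractions
`100 × (mean C_treated / mean C_control − 1)` proxies the percent density
change of a compartment. Group means are compared (no pairing is assumed
between control and treated cells); uncertainty comes from a seeded
percentile bootstrap over cells within each group (default 2000 resamples,
95% CI).

## Variant consensus

Variant identity is `(chrom, pos, ref, alt)` after normalization:
uppercase, shared trailing then leading bases trimmed (position advanced on
leading trims), multi-allelic records split one ALT per record. Genotype,
quality and depth are ignored — the consensus rule is pure set intersection
over exactly 2 callers × 3 replicates, with `snp_only=True` (default)
restricting to 1-bp substitutions, since different callers' quality models
are precisely what the intersection is meant to neutralize. Positions are
1-based throughout (VCF and gene-model intervals, inclusive).

The effect classifier handles the three-way taxonomy
intergenic / synonymous / missense only: a SNP outside every coding interval
is intergenic; otherwise the affected codon is located by phase from the CDS
start (minus-strand CDS anchored at the interval's right end and
reverse-complemented before translation, standard genetic code), and the
before/after amino acids decide synonymous vs missense. Start/stop codons
get no special casing. Overlapping coding intervals and CDS lengths not
divisible by 3 are rejected rather than guessed at.

## Expression filtering

Benjamini–Hochberg is the step-up procedure: stable ascending sort,
`q(i) = p(i)·m/i`, cumulative minimum from the largest rank, capped at 1,
returned in input order. The DE filter is `padj < padj_max` (strict, as
thresholds of this kind are conventionally quoted) and
`baseMean ≥ basemean_min` (inclusive), with optional raw p-value cap and a
linear fold band applied to `2^|log2fc|`. `basemean_min` has deliberately no
default: "high expression" depends on depth, and a silent default would hide
the most consequential knob of the filter. Example configs use 100.

## Synthetic generators: what they emulate, what a green test shows

All generators are deterministic functions of (config, seed).

* **Morphometry**: per-cell ratios and wall thicknesses are truncated
  normals (`ratio > 1`, thickness > 0) whose *post-truncation* mean and SD
  equal the configured values — the underlying-normal parameters are solved
  for (moment matching), because reported group statistics are sample
  moments of the actual truncated population. Naive truncation of
  N(1.48, 0.32²) at 1 would bias the mean by +0.04 and defeat parameter
  recovery. Widths are truncated normal (0.9 ± 0.1 µm, a typical rod-shaped
  cell width); lengths are ratio × width so `length ≥ width` by
  construction.
* **Spectra**: two Gaussian peaks (530/590 nm, σ = 20 nm) on a linear
  baseline with optional white noise. Real dye spectra are asymmetric and
  their baselines curved; a green spectral test establishes correctness of
  the baseline/peak algebra, not robustness to arbitrary real baselines.
* **VCF sets**: planted 6/6-consensus SNPs plus three decoy classes
  (caller-only, replicate-only with 1–2 replicates, 6/6 indels), each count
  configurable; default 25 + (20 + 15 + 5). Positions are drawn on a
  spaced grid so records never collide. This exercises the consensus
  logic completely but contains no alignment artefacts, no quality
  structure and no multi-nucleotide haplotypes.
* **DE tables**: nulls draw p ~ U(0,1), alternatives p ~ Beta(0.05, 1);
  |log2fc| ~ N(2.2, 0.2) signed down with probability 0.9 (a
  down-regulation-dominated response); baseMean log-normal (median ≈ 150).
  Independence between genes is assumed, so the FDR-control test verifies
  the procedure under its own assumptions, not under real count
  correlation.
* **EDS**: element weight fractions per cell are truncated normals (C 46,
  N 12, O 25, P 3 wt%, a typical organic composition); the treated
  periplasm carbon mean is the control mean × (1 + δ/100), δ = 15 by
  default; 22 vs 22 cells.

## Pipeline

`run_pipeline` derives each stage's seed as
`SeedSequence([global_seed, stage_index]) mod 2³¹` with the stage order
fixed, so adding parameters never silently reshuffles seeds. Configs reject
unknown keys, and referenced input paths are checked before any stage runs.
Each output file is recorded with its SHA-256; the manifest of completed
stages is written even when a stage fails.

## Known limitations

* The impact model is elastic and quasi-static: no plasticity, adhesion
  (JKR/DMT), poroelastic drainage, membrane puncture mechanics, or rod
  rotation; the collision kernel ignores hydrodynamic interactions. The
  pressure distribution is therefore a modelled exposure estimate whose
  extremes are calibrated to the stated range, not an ab-initio prediction.
* The Gram index and the EDS density proxy are operationalizations; their
  absolute values are convention-dependent even though their algebraic
  invariances are exact.
* The consensus filter reproduces filtering logic only; reproducing any
  specific study's SNP counts would require its raw reads, which are not
  public. The same holds for DE gene counts.
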