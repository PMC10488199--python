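# Methods

This note documents the models, estimators and numerical choices behind
`pumplipid`, and what the synthetic data generators do and do not emulate.

## Proton-pumping kinetics from ACMA traces

Vesicle acidification by a reconstituted H+-ATPase quenches the fluorescence
of the ΔpH probe ACMA; the protonophore CCCP collapses the gradient and
restores the signal. The analysis chain is:

1. **Normalization.** Each trace is divided by the intensity of the first
   sample at or after Mg2+ addition (discrete acquisition, no
   interpolation), so the normalized signal is 1.0 at the start of pumping.
   Normalization is idempotent and rates are invariant under rescaling the
   raw trace by any positive constant.
2. **Initial rate.** The pumping rate is the negated ordinary-least-squares
   slope of the normalized fluorescence over the first 30 s after Mg2+
   addition (every sample in the window is used). The 30 s window estimates
   the initial flux while the back-leak through the growing gradient is
   still negligible. It is a biased estimator of the instantaneous initial
   slope when the quench curves noticeably within the window: for an
   exponential quench with rate constant k the bias factor is approximately
   1 − kT/2 with T = 30 s. The estimator is reported as is — it is the
   assay's standard readout — and the synthetic default rates are placed in
   the near-linear regime (kT ≤ 0.11) where the bias is well below
   replicate noise.
3. **Activity filter.** A trace is inactive when the mean signal in the 5 s
   before CCCP addition is less than 10% below the post-CCCP plateau
   (exactly 10% counts as active). The plateau is measured over the last
   5 s of the trace, required to start at least 10 s after CCCP to skip
   re-equilibration; how the post-CCCP level is measured is a package
   choice, since only the 10% rule itself is standard. Inactive traces are
   flagged in every per-trace table and excluded from rate aggregation,
   never silently dropped.
4. **Fold-changes.** Per condition, the mean of the active replicate rates
   divided by the reference (pure PC) mean. Medians and quartiles are
   reported alongside for the boxplot view.

## Detergent solubilization (Boltzmann fit)

Liposome solubilization monitored by light scattering is fitted with

    y(x) = Bottom + (Top − Bottom) / (1 + exp((x − V50)/slope))

where Top is the intact-vesicle scattering plateau, Bottom the fully
solubilized plateau and V50 the inflection (half-solubilization) detergent
concentration; y(V50) = (Top+Bottom)/2 holds identically. Fitting is
Levenberg–Marquardt least squares initialized at Top = max(y),
Bottom = min(y), V50 = x nearest the midrange response and
slope = range(x)/10, with up to five restarts from perturbed starts before
a fit-failure error carrying the attempt diagnostics. The parameterization
is symmetric under (Top↔Bottom, slope→−slope); results are canonicalized
to Top > Bottom.

## Contact statistic

The central membrane statistic is the per-residue, per-species lipid
contact probability with **nearest-lipid exclusivity**: in each frame, for
each protein residue, the distance to every lipid is the minimum over
(residue bead, lipid headgroup bead) pairs; the residue contacts the
single nearest lipid, and only if that distance is within 0.55 nm. A
nearer lipid of any species blocks a contact with a farther one — the
exclusivity is global across species, which is the literal reading of the
rule; a stricter "at least two protein beads" variant was considered and
rejected because the sentence defining the contact enumerates the members
of one bead pair. Probabilities are contact frames divided by total
frames; replicas are concatenated first and normalized once.

Geometry conventions:

* Minimum image in x and y only; z is non-periodic (bilayer geometry).
* Distance ties break to the lowest lipid molecule id (determinism).
* Contacts are evaluated in the **raw** frames; superposition changes the
  lab frame but must not change contact geometry.
* Headgroup beads are identified by the `role` column of the topology TSV.

The engine is vectorized (segment-reduced distance matrices); the test
suite proves exact set equality against an exhaustive brute-force oracle
on 200 random frames and asserts the one-contact-per-residue invariant on
every frame of every test trajectory.

## Superposition, leaflets and densities

* **Alignment.** Every frame is rigid-body superposed (Kabsch SVD, proper
  rotation enforced) onto the first frame using the protein beads; the
  transform is applied to all beads. Fewer than three or collinear protein
  beads raise an alignment error.
* **Leaflets.** The midplane is the mean z of all lipid headgroup beads in
  a frame; a lipid is in the upper leaflet iff the mean z of its headgroup
  beads exceeds it (ties to lower). Assignment is per frame.
* **2-D densities.** Per leaflet and species, the xy centroid of each
  lipid's headgroup beads is binned into half-open cells [ih, (i+1)h)
  anchored at the box corner (default h = 0.02 nm) and averaged over
  frames, giving nm^-2. The identity Σ(values)·h² = mean per-frame count
  holds exactly (coordinates are wrapped into the box before binning).
* **Enrichment.** Density divided by the uniform expectation
  N_species,leaflet/(Lx·Ly); 1 means no preference.
* **3-D densities.** All beads or headgroup-only beads of a species binned
  into voxels (default 0.1 nm), averaged, divided by voxel volume (nm^-3);
  exported as OpenDX text with the conventional isovalues 3 nm^-3
  (headgroup) and 4 nm^-3 (all beads).
* **Site calling.** The enrichment map is smoothed with a periodic
  Gaussian (σ = 2 cells); local maxima above a threshold (default 2.0) are
  found, maxima within 1 nm of a stronger one merge into it, and residues
  with contact probability ≥ 5% whose mean position lies within 1 nm of
  the centroid are attached. Sites are labelled A, B, C, … by descending
  peak enrichment. No objective criterion for delimiting sites is standard
  in the field, so all thresholds are explicit parameters. Reporting
  conventions: residues above 15% probability are "labelled", ≥ 5%
  "highlighted".

## Conservation scoring

Columns of a multiple sequence alignment are scored with an entropy
measure in the AL2CO family: score = 1 − H/ln 21, Shannon entropy over the
20 amino acids plus gap as a 21st symbol (natural log). Gap counting
penalizes gappy columns; unweighted frequencies are used (sequence
weighting variants exist, but the unweighted entropy is the simplest
member of the family and is stated as such). An invariant, gap-free column
scores exactly 1; a maximally mixed column scores 0. Residue numbers of
the ungapped reference map bijectively onto columns; the site report adds
a ±7-residue flank mean (≈15-residue patches, the granularity used when
colouring structures). The eight real pump sequences live in UniProt
(P19456, P20649, Q42932, Q7XPY2, P05030, P07038, P04191, Q4H132); no live
retrieval is performed, and the packaged alignment is a synthetic
stand-in engineered to reproduce the conservation pattern of interest
(exactly one invariant arginine column among the contact residues).

## Group statistics

One-way ANOVA (classical between/within decomposition) followed by
Tukey's HSD in the Tukey–Kramer form for unequal replication:
q = |mᵢ − mⱼ| / sqrt(MSW/2 · (1/nᵢ + 1/nⱼ)), adjusted p from the
studentized range with k groups and pooled degrees of freedom. The compact
letter display uses the insert-and-absorb algorithm (split every letter
set containing a significant pair, absorb subsets); the suite verifies
letter-sharing ⇔ non-significance by full enumeration of all significance
patterns up to 5 groups and by sampling at 6. Quartiles use linear
interpolation between order statistics; whiskers span the extremes.
Significance tiers are */**/*** at 0.05/0.01/0.001. Each measured trace is
one observation; a per-reconstitution averaging step can be applied
upstream by the caller if pseudo-replication is a concern.

## Synthetic data: what it emulates, and what it does not

**Traces.** F(t) = plateau + (1−plateau)·exp(−k(t−t_mg)) with
k = rate/(1−plateau), so the instantaneous slope at Mg2+ addition is
exactly −rate; after CCCP the signal relaxes exponentially (0.05 s^-1) to
a recovery level. Gaussian noise (default sd 0.004) is added pointwise.
Defaults: t_mg 60 s, t_cccp 900 s, t_end 1000 s, dt 0.1 s, reference rate
5×10⁻⁴ s⁻¹, plateau 0.25, recovery 0.95 — a slow pure-PC proteoliposome
recorded for ~1000 s, placing the 30 s rate window in the near-linear
regime. Condition matrices scale the rate by the observed stimulation
factors (PS 5.3, PG 2.4, PA 2.2, ternary mix 3.2, PE 1.0).

**Bilayer trajectories.** A static scaffold of 10 vertical bead columns
("helices") on a 2.3 nm circle spans the bilayer (15 residues per helix,
z from −2.1 to +2.1 nm about the midplane). Default membrane: 524 lipids
distributed symmetrically (262 per leaflet), PS:PC 10:90 (per-leaflet
counts by largest-remainder rounding: 26 PS, 236 PC; remainder ties go to
the majority species), box 13×13×10 nm. Headgroup beads sit at ±2 nm from
the midplane with three tail beads at ±1.5/±1.0/±0.5 nm sharing the
headgroup's xy. Lipids perform per-leaflet 2-D Gaussian random walks with
periodic wrapping; the default per-axis step of 0.4 nm/frame corresponds
to a lateral diffusion coefficient of ~5×10⁻⁷ cm²/s at a ~1.6 ns output
stride and lets each lipid traverse the box several times per 1000-frame
run, so time averages converge (at 0.2 nm the box-traversal time equals a
whole 2000-frame run and single-lipid occupation footprints dominate
regional statistics of the 26-copy PS species).

**Hotspots.** A planted high-affinity locus is defined by residue ids
(their mean xy is the centre; the sign of their mean z picks the leaflet),
a species, a capture radius (default 0.7 nm) and a strength s ≥ 0. Inside
the radius, proposed steps that increase the distance to the centre are
accepted with probability 1/(1+s) (Metropolis-style rejection); s = 0 is
exactly unbiased, and the stationary enrichment inside the disk is ≈ 1+s.
Initial positions pre-populate the disk at that equilibrium occupancy so
short runs are near-stationary. The documented operating point for site
recovery studies is s = 25, radius 0.7 nm: planted interface residues
reach PS contact probabilities ≥ 0.95 while the best non-planted residue
stays near the unbiased background (~0.1), and the planted set is defined
as all residues of the hotspot helix whose beads can reach the leaflet's
headgroup level within the 0.55 nm cutoff (`helix_interface_residues`).

**Determinism.** Each generator call derives independent child streams
(initial placement, dynamics) from the root seed; draw counts are fixed
regardless of hotspot settings, so configurations differing only in
strength share identical proposal and acceptance streams, a zero-strength
hotspot is bitwise identical to no hotspot, and identical config+seed
reproduces byte-identical outputs.

**Not emulated** (deliberately): force-field energetics, lipid–protein
steric exclusion, lipid flip-flop, protein conformational dynamics,
membrane curvature and order parameters. Passing tests therefore
demonstrate the correctness of the estimators and bookkeeping on data with
known ground truth — not that the biological conclusions would re-emerge
from new simulations.

## Problem sizes

The test suite and the acceptance script run the membrane analyses at the
study composition (524 lipids, 10:90 PS:PC) with 2000-frame null runs and
20×600-frame hotspot-recovery runs, kinetics matrices of 6 conditions × 9
traces at 0.1 s resolution, 50-seed Boltzmann noise sweeps, and 200-frame
brute-force contact comparisons; these sizes give the statistical margins
quoted above while keeping a full run in the minutes range on one CPU.

## Pipeline

A single YAML config drives generate-or-ingest runs of all stages
(traces → stats, solubilization, membrane, conservation). Validation
returns the complete list of violations (no fail-fast); stage failures
stop dependents but completed outputs are kept; a manifest with SHA-256
checksums is written last, and identical config+seed reproduces identical
checksums. Logging goes to `run.log` in the output directory with enough
per-stage parameters to re-run any stage in isolation. Config validation
is a hand-rolled checker (full violation list accumulation) over the YAML
mapping; CLI flags on the per-stage subcommands override nothing inside a
config — they are separate entry points over the same library functions.
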