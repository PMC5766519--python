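# Methods

## Scope and model

The assay classifies the conformational state of an ERα ligand-binding-domain
(LBD) homodimer from an existing trajectory.  The LBD's mobile helix 12
(H12) packs against H3/H5–H6/H11 in the agonist (active) conformation and
sits in the H3–H5 groove in the antagonist (inactive) one; resistance
mutations in the loop connecting H11 and H12 (residues 536–538) shift the
ensemble toward the agonist-like state even with an antagonist bound.  The
package quantifies that shift through correlated dynamics, interaction
persistence, clustering and secondary-structure content.  Running molecular
dynamics itself, force-field energetics, docking and free-energy estimates
are out of scope: the inputs are a topology and coordinate frames.

All APIs use author residue numbering (303–552 per monomer) because every
mechanistic signature in the field's literature is quoted in it (E380, H377,
D351, K529/K531, the 536–538 mutation sites).  Monomer identity is taken
from chain IDs, never inferred from geometry.

## Correlation assay

With frames superposed into a common reference (iterative fit of all frames
to their converged mean; the fit set is Cα, the transform is applied to all
atoms), the dynamic cross-correlation matrix over Cα atoms is

    C_ij = ⟨Δr_i · Δr_j⟩ / sqrt(⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩),  Δr_i = r_i − ⟨r_i⟩.

Cα-only matrices are the standard residue-level choice and match the
per-residue/per-region readouts the assay produces.  For inter-monomer
correlation blocks, the whole dimer is fitted jointly — anti-correlation
*between* monomers is meaningful only in a shared frame.  Zero-variance
residues yield NaN rows with a warning and are excluded from aggregation;
a fully static trajectory is an error.

Two aggregations are produced:

* **Region score map** (14×14 per monomer pair):
  `S(A,B) = Σ_{i∈A,j∈B} C_ij · 1[|C_ij| ≥ τ]` with τ = 0.6, self-pairs
  excluded on diagonal blocks.  Map-style outputs default to the per-pair
  mean (score divided by |A|·|B|), which keeps values in the ±0.3 display
  range familiar for such maps; the raw sum is selectable.
* **H12 profile** (per H12 residue × 13 target regions): raw thresholded
  sums, because the activation metric reaches its reference value of 4 only
  unnormalised.  Totals are column sums of the per-residue table.

The threshold is inclusive on both sides (|C_ij| = τ counts), and the
activation threshold is likewise inclusive: a monomer scoring exactly 4 is
*high* and the drug is flagged ineffective.  Tiers: high (≥ 4),
intermediate ([2, 4)), low (< 2); a drug is effective only if both monomers'
max(H12–H3, H12–H5) stay below 4.

## Interaction persistence

Hydrogen bonds use a donor–acceptor heavy-atom distance ≤ 3.3 Å together
with a D–H···A deviation from linearity ≤ 35° (angle at the hydrogen
≥ 145°).  The angular cutoff is deliberately documented as a *deviation*:
tooling in this space is ambiguous between "35°" meaning the deviation or
the angle itself, and the deviation reading matches the common acceptance
convention.  Multi-atom sites (Oδ1/Oδ2, Nδ1/Nε2, multiple amine hydrogens)
are expanded into all (donor, H, acceptor) triplets and OR-combined into one
labelled interaction.  Salt bridges use the identical geometric rule between
charged groups.  When no hydrogen is resolvable, detection raises and
suggests the flagged heavy-atom-only (distance-only) fallback rather than
silently changing the rule.

Hydrophobic contacts are present when the minimum heavy-atom cross-distance
between two groups is ≤ 4.5 Å — a geometric proxy deliberately used in
place of force-field non-bonded energies.  π-stacking requires ring-centroid
distance ≤ 5.0 Å and an acute angle ≤ 30° between best-fit ring planes
(smallest-singular-vector normals); both cutoffs are package choices exposed
as parameters.  Persistence is always 100 × (frames present)/(frames
analysed), reported per monomer and never merged across monomers.

The signature panel evaluates a fixed set of mechanistically meaningful
interactions (E380–H377; O@L536···Nδ2@N348; Oδ1/Oδ2@D351 to the 538–540
backbone and to Oγ@S537; E380 to the residue-537 side chain; K529/K531 salt
bridges toward a ligand; the L536/W383/L539/L540 hydrophobic pocket;
Y537–H377 stacking).  Rows whose atoms are absent from the given topology
(mutant-dependent side chains, missing ligand) are reported as not
applicable instead of being dropped, so panels are comparable across
isoforms.

## Conformational analysis

Superposition is the Kabsch SVD solution (proper rotation enforced via the
determinant sign); collinear selections are rejected.  Pairwise frame RMSDs
use the closed-form post-fit expression with batched 3×3 SVDs.  RMSF is
√⟨|r_i − ⟨r_i⟩|²⟩ over the analysis window on the aligned trajectory.

Equilibration detection scans start points k and accepts the earliest whose
tail's cumulative running mean stays within `tol` (default 0.5 Å) of the
tail's final mean for ≥ 95 % of tail frames.  Tails shorter than 10 frames
or 20 % of the series are not considered: a two-frame tail trivially
satisfies any tolerance, which would let monotonically drifting series
"converge" at the very end.  A series with no qualifying start returns a
not-converged sentinel (None), not an exception.

Daura clustering: compute all pairwise post-fit RMSDs; repeatedly pick the
unassigned frame with the most unassigned neighbours within the cutoff
(2.75 Å default) as a centre, remove it and its neighbours as a cluster;
report clusters by descending population.  Ties in neighbour count break to
the lowest frame index, and population ties to the lower centre index —
both choices exist purely for determinism, since the original formulation
leaves them open.  Clustering runs on per-monomer Cα coordinates, matching
the per-monomer populations the assay reports.

Helix assignment uses the α-helical i→i+4 backbone hydrogen bond:
residue i is helical in a frame when C=O(i−4)···H–N(i) (donor role) or
C=O(i)···H–N(i+4) (acceptor role) satisfies d(O,N) ≤ 3.5 Å with an N–H···O
deviation ≤ 40°.  Helical-versus-not content is all the assay needs; 3₁₀/π
helices and the full 8-class secondary-structure alphabet are out of scope.

## Study design and windowing

The default design matrix is 5 isoforms × (apo, estradiol | endoxifen,
AZD-9496, fulvestrant) = 25 systems at 500 ns each, 12.5 µs cumulative,
enumerated isoform-major with the agonist state first.  The default
analysis window keeps the last 60 % of frames — the length-relative form of
analysing the final 300 ns of a 500 ns run — and an absolute start time in
ns is available where real time metadata exists.  DCD files carry no trusted
time axis, so frame times are always `frame_index × dt_ns` with a
caller-supplied dt.

## Synthetic data: what it emulates and what it does not

The generator produces a two-chain dimer (residues 303–552 per chain) whose
backbone is a continuous ideal α-helix built from internal coordinates
(φ = −57°, ψ = −47°; extended segments use φ = −139°, ψ = 135°), with named
side-chain pseudo-atoms only for the signature residues.  Geometry is
metrically valid (minimum interatomic distance ≥ 1.0 Å) but deliberately
non-physical: no sterics, no solvent, no ligand parameterisation, and the
two "monomers" are translated copies rather than a crystallographic dimer
interface.

Planted structure, all driven by one counter-based (Philox) stream keyed by
the spec seed:

* **Correlations.**  Cα displacements are drawn per Cartesian component
  from a zero-mean multivariate normal with marginal standard deviation σ
  (default 1 Å, a realistic Cα fluctuation scale; frames default to 5000 at
  0.1 ns emulating one 500 ns production run).  A plant (A, B, ρ) is
  realised as a shared latent factor with loadings ±√|ρ| on the member
  residues, making every cross-region pair correlate at exactly ρ while
  keeping the covariance positive semi-definite for any |ρ| ≤ 1 — a
  pairwise-only covariance with identity diagonal is indefinite as soon as
  |ρ|√(n_A n_B) > 1, i.e. for every full-region plant of interest.  The side
  effect, documented deliberately: within-region pairs of a planted region
  also correlate at |ρ|.  Residual variances below zero (overlapping plants)
  raise an error asking to reduce |ρ|.
* **H-bonds.**  With probability p per frame the acceptor atom is placed
  2.8–3.1 Å from the donor with a D–H···A deviation ≤ 10°, otherwise parked
  ≥ 4.8 Å away; donor and hydrogen keep their residue's noise, so detection
  recovers the latent occupancy exactly.
* **Conformer mixtures.**  Each frame's base geometry is drawn from
  weighted rigid-shift conformers of the reference dimer, plus noise.
* **Helicity.**  A planted segment's backbone N/H/C/O follow the ideal
  helix in a Bernoulli(q) fraction of frames and a displaced extended
  strand otherwise, while the segment's Cα keep the correlated noise.  The
  extended strand is offset 8 Å so neither within-segment nor
  cross-boundary i→i+4 geometry survives, making planted content an exact
  Bernoulli fraction rather than a noisy estimate.

Consequently, passing tests demonstrate estimator correctness and pipeline
integrity under known ground truth — they do not demonstrate that real
trajectories of the receptor reproduce any particular score, persistence or
population.  Real data add correlated noise between all the planted
channels (side chains that move with secondary structure, H-bonds coupled
to correlations), which the generator intentionally isolates.

## Numerical choices

* Superposition-to-mean iterates at most 10 rounds to a 10⁻⁶ Å mean shift;
  the generator's frames already share a reference frame, so validation of
  planted correlations computes the DCCM directly on generated coordinates,
  where the latent ground truth lives.
* Exact-threshold values are included everywhere (|C| ≥ τ, score ≥ 4,
  d ≤ d_max, deviation ≤ θ_max).
* Cluster populations are forced to sum to exactly 100 % (last element
  absorbs float residue); report tables round scores to 6 decimals and carry
  no timestamps, so identical configs rewrite byte-identical files.
* DCD output fixes the header remarks string for the same reason.
* Analysis problem sizes in tests and the acceptance script (5000-frame
  correlation recoveries, 500-frame clustering, 400-frame end-to-end runs)
  were chosen as the smallest sizes at which the statistical tolerances the
  estimators warrant (3 standard errors, 99 % binomial CIs, ±3 %
  populations) are meaningful.

## Known limitations

* The DCCM's 35°-rule sibling ambiguity (deviation vs absolute angle) and
  the exact aggregation convention behind published region maps are
  documented choices, not certainties; both aggregation modes are exposed.
* Whether published per-region H12 sums run jointly over all other regions
  or per region is ambiguous; the profile stores per-region values so either
  can be reported.
* The clustering atom set (per-monomer Cα) and the DCCM atom set (Cα) are
  package choices where published methods do not state the mask.
* Multi-model PDB and CHARMM-dialect DCD are the only trajectory formats;
  PSF/GRO/XTC, insertion codes and altlocs beyond the first are not
  supported.
* Equilibration detection is a running-mean heuristic for plateau finding,
  not a statistical changepoint method.
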