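# Methods

This note records the models, the numerical choices and the design
decisions behind `multiconf`, and what the synthetic benchmark does and
does not demonstrate.

## Density model

Observed maps are treated as real-space scalar fields on orthorhombic P1
grids (voxel (i,j,k) centered at `origin + index·spacing`). Model density
is synthesized directly in real space: each atom contributes an isotropic
Gaussian

    ρ(r) = occ · A · (2πσ²)^{-3/2} · exp(−r²/2σ²),
    σ² = B/(8π²) + (0.225·d)²,

where `A` is the element's electron count in X-ray mode or a tabulated
electron-scattering amplitude (sums of the five-Gaussian scattering-factor
coefficients) in EM mode, `B` the isotropic B-factor (Å²) and `d` the map
resolution (Å). The `0.225·d` blur (config-exposed) stands in for the
finite resolution of the experiment; the profile integrates to `occ·A`, so
density is conserved across B changes, and the model is linear in
occupancy and additive over atoms — the two properties the occupancy QP
relies on. A full Fourier treatment of the resolution cutoff is
deliberately avoided in scoring: fits are local (residue footprints), and
a consistent forward model on both sides of the fit is more important than
reciprocal-space fidelity.

Footprints are the union of voxels within `rmask = 0.5 + d/3` Å (CLI
`--rmask`) of any candidate atom, in deterministic x-major order. The BIC's
`n` is the footprint size, not the whole-map voxel count: a whole-map `n`
would make the parsimony penalty negligible relative to the first term and
the selection insensitive to `k`. X-ray targets subtract a flat
bulk-solvent level of 0.3 (in map units) and floor at zero; EM targets
subtract nothing. The subtraction is applied to the raw map values — maps
on other scales can be passed through `normalize_grid` first (mean positive
density scaled to 1), which is left to the caller because the right scale
reference depends on how the map was produced.

## Samplers

All sampling is deterministic (no RNG anywhere in the module); candidate
order is fixed, so rebuilds are byte-identical.

* **Backbone**: rigid translations of the whole residue. Isotropic: 9
  candidates — the null move, ±0.2 Å along each of Cα→Cβ, C→N and their
  cross product, and ±0.3 Å along Cα→Cβ. The 9/81 counts (including the
  unperturbed input) are the contract; the exact composition is a policy
  isolated in one function each. Gly uses a tetrahedral pseudo-Cβ
  direction. Anisotropic (ANISOU on Cβ): 81 candidates — null + three
  magnitudes (0.1/0.2/0.3 Å) × 26 sign patterns over the tensor's principal
  axes + a mixed-magnitude diagonal pair.
* **Aromatic angle** (His/Tyr/Phe/Trp): the side chain beyond Cβ rotates
  rigidly about an axis through Cβ normal to the Cα-Cβ-Cγ plane, offsets
  {−7.5, −3.75, 0, +3.75, +7.5}°.
* **χ grids**: every 6° within ±24° of each idealized rotamer mean. The
  library is a compact penultimate-style table of χ means; coarse means
  suffice because the ±24° window around each is searched exhaustively.
  Two augmentations make the grid robust to imperfect input geometry:
  the input's current χ is treated as an additional rotamer (sampling can
  then never do worse than the input), and the input's deviation from its
  nearest idealized mean is carried over to the other means — a distorted
  local frame rotates the nominal χ of *every* well by roughly the same
  amount, so re-centering the windows keeps all wells reachable. With an
  on-rotamer input both augmentations collapse and the plain
  means × 9-offset grid remains.
* **Proline**: the ring is puckered by rotating Cγ about the Cβ–Cδ chord
  (preserving both ring bonds exactly); the current pucker and its mirror
  are each sampled at the 9 flap offsets.
* **Pruning**: greedy first-seen-wins; a candidate is dropped if it has an
  internal hard-sphere clash (vdW radii scaled by 0.75, 1-2/1-3 pairs from
  the chemical-component bond tables excluded) or is within 0.01 Å all-atom
  RMSD of a kept candidate. Bond topology comes from the CCD rather than
  distance inference so that distorted input geometry cannot corrupt the
  exclusion lists.
* **B-factors**: each surviving conformer is crossed with multipliers
  {0.5, 0.7, 0.9, 1.1, 1.3, 1.5} (the unscaled conformer is intentionally
  not reproduced — the multiplier set brackets it).

The residue driver additionally samples from two side-chain templates: the
raw input conformer and an ideal-geometry copy (CCD side chain regrafted on
the input backbone frame at the input's χ). Input models that were refined
have near-ideal geometry and the two collapse; for distorted inputs the
density fit decides which template explains the map.

## Occupancy optimization

QP: minimize `‖ρ_obs − Σ wᵢρᵢ‖²` s.t. `wᵢ ≥ 0`, `Σwᵢ ≤ 1` (the deficit
absorbs unmodeled disorder; occupancies are only forced to sum to 1 at the
final culling stage). Solved as non-negative least squares on an augmented
system: a slack variable turns the sum constraint into an equality that a
penalty row (10⁵ × data scale) enforces; weights below 10⁻⁴ are dropped.

MIQP adds `|selected| ≤ cardinality` (≤ 5) and `wᵢ ≥ threshold` (0.2 X-ray,
0.3 EM) for selected candidates. It is solved exactly by subset
enumeration: for every subset up to the cardinality, a threshold-shifted
NNLS on the Cholesky factor of the subset Gram matrix (cost independent of
footprint size); pools larger than 12 are first reduced to the 12 highest
QP weights (stable ordering). Ties go to the smaller subset. When no subset
is feasible, the fallback removes the later-indexed member of the closest
candidate pair (all-atom RMSD, or RMS density difference when no conformers
are attached) and retries — guaranteed to terminate.

BIC selection runs the subset search once and scores each cardinality with
`n·ln(rss/n) + k·ln(n)·0.95`, `k = 4·atoms·conformers` per residue or
`k = conformers` per segment; the 0.95 factor discounts the non-independent
coordinate parameters. `rss ≤ 0` is clamped to `eps·n` with a log warning.
Ties go to the smaller cardinality.

## Per-residue pipeline and assembly

Strip hydrogens → backbone (→ aromatic) → per χ: sample, prune, QP
reduction (keep weights ≥ 0.002, at most 15), B-factor expansion, MIQP
(≤ 5 survivors feed the next χ) → at the terminal χ, BIC selection over
cardinalities 1–5. Gly/Ala stop after backbone scoring. Selected conformers
that differ only in B (coordinate RMSD < 0.01 Å) are merged, weights
summed. Residues failing preconditions (missing backbone atoms, outside the
map, non-standard) pass through unchanged. Each residue can be scored
against a sub-grid (bounding box + 8 Å + 2·rmask margin); results equal the
full-map result, which is tested — residues are fully independent units of
work.

Segments (runs of ≥ 2-conformer residues, broken at chain discontinuities)
are re-optimized with three-residue sliding windows: all cross-products of
member conformations become fragment candidates, BIC (segment k) selects,
unused conformers are culled and each conformer's occupancy becomes the
summed weight of the selected fragments containing it — adjacent paired
backbones thereby share occupancies. Relabeling minimizes
`Σ max(0, rᵢ+rⱼ−d)²` over same-altloc (or blank) heavy-atom pairs of
different residues within 4 Å by Monte-Carlo label swaps: 10·(#multi)²
proposals, temperature annealed linearly from the initial energy to 0,
best-seen state returned (so the energy never increases), seeded and
reproducible. Segment-only mode equalizes conformer counts inside each
segment by duplication (duplicates split the parent occupancy equally, and
the duplication preserves per-residue totals exactly), then re-optimizes
and normalizes to 1. Final culling removes occupancies < 0.10 and
renormalizes to 1 (a residue whose conformers are all below the cutoff
keeps its best at 1.0). The restraint writer emits one group per (segment,
altloc) with a Phenix-style selection string.

## Synthetic benchmark

`make_toy_system` builds an extended β-strand-like peptide (φ = −140°,
ψ = 135°, B = 10 Å²) cycling through Ser/Val/Leu/Thr, with ideal CCD
side-chain geometry, and gives a seeded random subset of residues (walked
until the requested count is reached) a second conformer in a different
clash-free χ₁ well at occupancies (0.6, 0.4). Degradation emulates
resolution loss at target `d` relative to a 0.8 Å base: B-factors gain
1 Å² per 0.1 Å of loss; coordinates are shaken with isotropic Gaussian
displacements of RMS vector length 0.2·d; density is synthesized from the
*shaken* multiconformer model in a P1 box (spacing d/4, 4 Å margin, flat
0.3 solvent background in X-ray mode); signal-dependent noise
`F → F + √F·N(0,1)·d·0.5` is applied to the Fourier amplitudes of the map
(phases kept) together with a hard 1/d frequency cutoff; and the input
model is the shaken, B-inflated structure stripped to its first conformer
at unit occupancy. Applying the noise rule in reciprocal space (rather than
to real-space voxel values) keeps the noise-to-signal ratio independent of
the arbitrary real-space scale, which is where amplitude-proportional noise
is physically meaningful; the rule itself is unchanged and is verified by a
Monte-Carlo test. The benchmark builds directly from the shaken input
without an intervening refinement step, which makes it strictly harder than
a protocol that first re-refines the input against the noisy data.

What passing the benchmark shows: the full pipeline recovers planted
two-state side chains and their occupancies from degraded maps at high
resolution, and loses them as resolution worsens — with the 10-seed toy
conditions used in the acceptance suite, recovery is 80 % at 1.2 Å
(mean state-occupancy error ≈ 0.06) and 0 % at 3.0 Å. What it does not
show: behavior on real data, where the forward density model is not the
one that produced the map (no "inverse crime" protection), solvent is
structured, maps carry series-termination and phase errors, and side
chains are longer and more flexible than the toy pool. Problem sizes in
the suite (10-residue toys, 10 noise seeds, two resolutions) were chosen as
the smallest systems in which segments, relabeling and the resolution
fall-off all manifest.

## Known limitations

* Only orthorhombic P1 grids; symmetry expansion and reciprocal-space data
  (MTZ) conversion are the caller's responsibility.
* Backbone sampling is translational only — no φ/ψ or larger-scale moves,
  so alternative conformations requiring genuine backbone rearrangement
  are out of reach.
* The flat 0.3 bulk-solvent subtraction is a single constant in map units;
  structured solvent is not modeled.
* The weighted-B metric implements `occ·(4π/B)^1.5` verbatim; it is a
  relative resolvability score, not the conventional `8π²⟨u²⟩` conversion.
* No crystallographic refinement is performed; the output is the raw
  multiconformer model plus restraints for an external refinement program.
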