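# Methods

## Model

The potential quantifies where, not merely whether, amino acids sit in each
other's neighborhoods. For a center residue of type *i*, each neighbor of
type *j* within the cutoff is recorded by the spherical direction (θ, φ) of
its geometric center in *i*'s local frame, with the radial coordinate
integrated from 0 to the cutoff. The observed probability factorizes into a
type term and an angular term,

    P_obs(i, j, θ, φ) = p_ij · p_ij(θ, φ),

where p_ij = N_ij / ΣN_ij is the ordered-pair probability among all
contacts and p_ij(θ, φ) = N_ij(θ, φ) / N_ij the per-pair angular
distribution (normalized by the **per-pair** contact total, so the type
preference enters exactly once). The expected probability under no
preference is p_i · p_j for the types and the bin's solid-angle fraction for
the direction. Inverse-Boltzmann inversion with kT = 1 gives

    E(i, j, θ, φ) = −log[ (p_ij / (p_i p_j)) · p_ij(θ, φ) / w(θ, φ) ],

and the score of a structure is the plain sum of E over every ordered
contact. Because contacts are ordered, each unordered pair contributes
twice — once in each residue's frame — which is deliberate: E(i, j, ·) and
E(j, i, ·) are genuinely different functions. All 400 ordered-pair tables
are stored unsymmetrized.

Assumptions inherited by anything trained with this package: single-chain
statistics (no inter-chain contacts), first model only for multi-model
files, heavy atoms only (X-ray training structures mostly lack hydrogens,
and including them would make centers deposit-dependent), and one fixed
center definition — the unweighted mean of *all* heavy atoms (backbone +
side chain) — used both for the frame origin and for the neighbor distance
test, in both cutoff modes.

## Local frame conventions

Origin = residue center **o**; x = unit(N − o); y = the component of
(Cα − o) orthogonal to x (so Cα always has positive y); z = x × y. θ ∈
[0, π] is measured from +z (this is what makes sin θ the correct uniform
density over θ) and φ ∈ [0, 2π) from +x toward +y. Points on the polar
axis take φ = 0 by convention. Any fixed azimuth origin would do — training
and scoring share the frame — but this one is the standard physics
convention. Residues missing N or Cα, or with center/N/Cα collinear beyond
1e−6, are skipped as centers (counted and logged) but still act as
neighbors of others.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `cutoff_mode` | `fixed` | `fixed`: one universal radius; `radius_sum`: per-pair radii sum |
| `r_fixed` | 6.0 Å | the operating point that best recognizes natives across cutoffs 4–10 Å |
| `radii` | shipped table | per-type mean residue radii (Å), e.g. GLY 1.72, TRP 5.38 |
| `n_theta`, `n_phi` | 20, 20 | angular resolution; 15–30 trade feature sharpness against per-bin sampling |
| `pseudocount` | 1/(n_theta·n_phi) | per-bin additive count (one contact spread over the bins) |
| `missing_pair_energy` | 0.0 | constant for pairs never observed in contact (uninformative) |
| `include_adjacent` | True | sequence neighbors count as spatial neighbors; exposed as a switch because many potentials exclude them |
| `angular_weight` | `exact` | uniform expectation per bin; see below |

The distance test is boundary-inclusive (d ≤ cutoff); equality is
measure-zero and fixing it inclusive makes enumeration deterministic.

`estimate_radii` recomputes a radii table from a corpus using a declared
convention: per residue, the mean distance from the geometric center to its
heavy atoms, averaged over residues of the type. The shipped defaults are
kept as the reference values; the estimator's convention is stated rather
than claimed identical to how the shipped table was originally derived.

## Numerical choices

* **Angular weight.** The uniform expectation in a bin is the exact
  solid-angle fraction (cos θ_lo − cos θ_hi)/2 · (1/n_phi), the closed-form
  integral of sin θ over the bin. It sums to 1 to 1e−12 on every grid and
  has no polar singularity. The literal midpoint weight
  sin(θ_mid)·Δθ·Δφ/(4π) is available (`angular_weight="point"`) for
  comparison; it does not integrate to exactly 1.
* **Radial factor.** With r integrated to the cutoff, the r²Δr factor of
  the uniform expectation is constant within each ordered pair (the cutoff
  is per-pair even in radius-sum mode) and cancels into the normalization;
  energies therefore depend only on (pair, θ-bin, φ-bin).
* **Binning.** θ-bin = ⌊θ/Δθ⌋ clamped to the last row at θ = π; φ is
  already in [0, 2π). Every angle maps to exactly one bin.
* **Zero counts.** With pseudocount α the per-pair angular estimate is
  (h + α)/(N_ij + α·B), B = number of bins; α = 0 is refused whenever an
  observed pair has an empty bin, rather than emitting infinities. Pairs
  with no contacts at all get a constant, configurable energy.
* **Superposition.** RMSD uses closed-form Kabsch superposition (SVD with
  determinant correction, never a reflection) over the Cα atoms of residues
  common to both structures; congruent inputs recover 0 to ~1e−12 Å.
* **Ties.** Equal-energy structures in a ranking are ordered
  lexicographically by name, so reports regenerate byte-identically.

## Synthetic data: what it emulates and what it does not

The fixture generator produces deterministic, seedable PDB files from
idealized residue templates (four backbone atoms at standard-ish geometry
plus a type-specific count of pseudo side-chain atoms, giving each type a
distinct center and radius). Geometries:

* `ideal_helix` / `random_coil` — connected chains exercising parsing,
  frames, and dense contact patterns;
* `planted_contact` — isolated residue pairs whose neighbor direction falls
  inside one requested angular bin of the center's frame, the construction
  used to plant an orientation preference (emulating, e.g., the disulfide
  hotspot near θ ≈ 162°, φ ≈ 270°, i.e. bin (18, 15) of the default grid);
* `uniform_pairs` — isolated pairs with uniform-on-sphere directions and
  uniformly random residue orientations: the null model under which trained
  energies converge to zero.

Pairs sit on a 25 Å lattice so no cross-pair contact is possible under any
shipped cutoff. Decoys are made by isotropic Gaussian jitter of every atom;
RMSD to the native grows with σ in expectation. No physical plausibility is
claimed for any of this: there are no sterics, no rotamers, no secondary
structure beyond the helix trace. Consequently, passing tests demonstrate
that the statistics, inversion, and ranking machinery are correct and
self-consistent — not that the potential trained on these fixtures would
assess real proteins; that requires a real structure corpus.

Two study-condition choices deserve note. The null-model convergence check
uses a single-type corpus: the type term is then exactly 1 and, at 1e5
contacts on the 20×20 grid, per-bin occupancy (≥ ~30, typically ~250) is
large enough for the asymptotic check to be meaningful; a 20-type corpus at
the same contact budget would leave < 1 expected count per cell. The decoy
jitter schedule (0.05–0.4 Å) is matched to the geometry of the planted bin:
near the pole the bin's azimuthal arc width is r·sinθ·Δφ ≈ 0.3 Å, so this
range runs from partial retention to saturation of the planted orientation.
Much larger jitter first saturates the angular signal and then starts
breaking contacts outright, at which point the raw energy sum — which is
extensive in contact count — measures contact survival rather than
orientation quality.

## Problem sizes

The test suite trains on corpora of 6–40 chains (8–50 residues each), uses
1e5 contacts for the null-model check and 1e4–2e4 for distributional unit
checks, 100 seeded trials for the planted-preference discrimination, and
5–10 decoy sets of 32 decoys for ranking metrics. `scripts/acceptance.py`
uses the same sizes except a 2e4-contact null corpus. Everything runs in
minutes on one CPU.

## Known limitations

* No multi-layer (shell-resolved) or distance-binned energies; the
  potential is purely orientational within the first neighbor shell. The
  model container records enough metadata that a layered extension could be
  added without breaking the format.
* mmCIF input, occupancy-weighted centers, ligands, nucleic acids, and
  inter-chain interfaces are out of scope.
* The raw score is extensive: structures with more contacts have larger
  |E|. For ranking decoys of the same protein this is immaterial; comparing
  scores across proteins of different sizes would require normalization the
  package deliberately does not impose.
* Pearson energy–RMSD correlations exclude the native by default (the
  0-RMSD anchor would otherwise dominate r); a flag includes it.
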