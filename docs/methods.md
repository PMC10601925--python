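# Methods

This document describes the model implemented by `deltacg`, its parameters
and defaults, what the built-in synthetic systems do and do not emulate, the
numerical choices that matter, and the method's limitations.

## 1. Model

### 1.1 Second-order energy surface

A system of `n_p` protein-like atoms and `n_s` three-site waters is described
by a molecular-mechanics energy with harmonic bonds, harmonic angles,
Lennard-Jones, and Coulomb terms. Around a reference conformation the energy
is expanded to second order:

    V(δ) = V0 − fᵀ δ + ½ δᵀ H δ

with analytic forces `f = −∇V` and Hessian `H = ∇∇V`. Both are assembled
from per-pair closed forms and verified against central finite differences.

### 1.2 Change of variables and hydrogen elimination

Each water is re-coordinatized into the position of its oxygen (`d_s`, the
solvent-particle coordinate) and the two hydrogen displacements relative to
the oxygen (`Δ12`, six coordinates per water). Protein atoms keep their
Cartesian displacements `d_p`. This is an exact linear change of variables;
the energy in the new coordinates is reproduced term-for-term by aggregated
force/Hessian blocks (`partition.aggregate`).

The hydrogen displacements are then eliminated by stationarity: for given
particle displacements `d = (d_p, d_s)`, the hydrogen response is

    Δ12*(d) = H₁₂₁₂⁻¹ (f₁₂ − H₁₂ₚₛ d)

and substituting it back yields a reduced second-order surface over the
particles only:

    V0′ = V0 − ½ f₁₂ᵀ H₁₂₁₂⁻¹ f₁₂
    f′  = fₚₛ − Hₚₛ₁₂ H₁₂₁₂⁻¹ f₁₂
    H′  = Hₚₛₚₛ − Hₚₛ₁₂ H₁₂₁₂⁻¹ H₁₂ₚₛ   (Schur complement)

By construction the reduced surface equals the full surface evaluated at the
hydrogen response, for every `d`; this plug-in identity is the main
correctness oracle of the test suite. When all first-order forces vanish the
construction reduces to the textbook Schur-complement (normal-mode
reduction) limit.

`H₁₂₁₂` is solved by Cholesky/LU when well conditioned; if it is singular
beyond tolerance, a pseudo-inverse path drops the null directions and the
solve report records this.

### 1.3 Effective pairwise forces and springs

The all-atom pair forces are summed into unit-level (atom/solvent-particle)
matrices:

* **direct** entries `F_i←j`: sums of atomic pair forces between the two
  units — exactly antisymmetric by construction;
* **indirect** entries `dF′_i←j = −[Hₚₛ₁₂ H₁₂₁₂⁻¹ F₁₂←units]`: the force
  mediated by the eliminated hydrogen response. These are **not**
  antisymmetric — eliminating internal coordinates breaks Newton's
  third law at the pair level (a structural property asserted by the tests);
* the reported effective pair force symmetrizes the indirect part,
  `F″_{i,j} = direct_{i,j} + ½ (dF′_{i,j} − dF′_{j,i})`.

Each entry splits into five components: oxygen-site electrostatic
(`o_elec`), oxygen-site van der Waals (`o_vdw`), hydrogen-site electrostatic
(`h_elec`), hydrogen-site van der Waals (`h_vdw`), and the indirect
(hydrogen-dynamics) term (`s_indir`). The four direct components sum to the
direct part and all five to the full entry, to 1e-9 relative.

Spring blocks are split the same way; the indirect spring block is the
Schur correction `H′ − Hₚₛₚₛ`.

Scalar profiles project onto the inter-particle unit vector
`r̂ = (x_i − x_j)/r`:

    f_ij = F″_{i,j} · r̂        (positive = repulsive)
    k_ij = r̂ᵀ [H′]_{i,j} r̂     (= df_ij/dr for an isolated pair potential)

### 1.4 Ensembles, binning, and curves

Records are collected per frame over a seeded ensemble: one row per unit
pair within the record cutoff, carrying `r`, the component scalars, and
optionally the motion correlation. Rows are binned at 0.1 Å (half-open bins
centered on multiples of the width); per-bin statistics are the 5–95 %
trimmed mean and standard deviation plus the 10/25/75/90th percentiles.
Bins below `min_count` are masked.

The mean spring curve is integrated to an approximate force curve
`f̂(x) = ∫ k + g`, with the constant `g` chosen so that `f̂` averages to
zero over the 8–12 Å window; the mean force curve is integrated to a
potential `U(x) = −∫ f`, whose argmin in a search window locates the
effective pair minimum.

### 1.5 Hydrophilic degree

For an atom–solvent pair, the degree is the averaged area of the negative
(attractive) region of the mean force curve and of its spring-integrated
approximation:

    area(y) = −∫ min(y, 0) dx   over [grid min, 12 Å]
    degree  = (area(f) + area(f̂)) / 2     [kcal/mol]

interpreted as the maximum work to remove a solvent particle to 12 Å.
Atoms with degree above 0.1 kcal/mol are classified hydrophilic, otherwise
hydrophobic.

### 1.6 Motion correlations

Modes of the mass-weighted reduced Hessian `M^{−1/2} H′ M^{−1/2}` are
weighted by `1/|λ|` (thermal occupancy of a harmonic mode); the six
smallest-|λ| modes (rigid body) are excluded. The correlation of two sites
is the normalized weighted covariance (`c_ii = 1`); for a positive-definite
surface this equals the displacement correlation from the covariance matrix
`H′⁻¹`. Binned solvent–solvent correlations are summarized by the
exponential decay ratio per Å, `exp(slope)` of a least-squares line fit to
`ln c` vs `r` over 5–10 Å.

## 2. Parameters (units and defaults)

Energies kcal/mol, lengths Å, angles rad internally (deg in files), masses
amu, charges e. Coulomb constant 332.0637 kcal·Å/(mol·e²).

Water (bundled `tip3p.params`, CHARMM-style flexible TIP3P):

| parameter | value |
|---|---|
| O charge / H charge | −0.834 / +0.417 e |
| O LJ ε, rmin/2 | 0.1521 kcal/mol, 1.7682 Å |
| H LJ ε, rmin/2 | 0.0460 kcal/mol, 0.2245 Å |
| bond k_b, b0 | 450.0 kcal/mol/Å², 0.9572 Å |
| angle k_θ, θ0 | 55.0 kcal/mol/rad², 104.52° |

Nonbonded policy: `untruncated` (analysis default) or `switched` (sampling
default) with a C² quintic-smoothstep multiplier from `r_on = 7.8 Å` to
`cutoff = 12 Å`. 1–2 and 1–3 intramolecular pairs are excluded.

Sampling (`SamplerConfig`): temperature 298 K; rigid-body water moves with
max translation 0.18 Å and max rotation 0.35 rad; default 2500 sweeps,
burn-in 500, frame every 10 sweeps (201 frames); droplet radius derived
from the liquid water number density unless given, with a harmonic
restraint (2.0 kcal/mol/Å²) beyond it; all randomness from a single
integer seed (mandatory).

Analysis (`RunConfig`): record cutoff 12 Å, bin width 0.1 Å, trim (5, 95) %,
`min_count` 25, zero window (8, 12) Å, correlation fit window (5, 10) Å,
six zeroed modes, hydrophilic threshold 0.1 kcal/mol.

## 3. Synthetic data: what it does and does not emulate

The package samples small TIP3P droplets (tens of waters, optionally with a
fixed probe particle at the center) by Metropolis Monte Carlo. This
emulates: liquid-like local water structure (the O–O first peak lands near
2.8 Å), Boltzmann-weighted conformational diversity at 298 K, and the
contrast between charged (hydrophilic) and apolar (hydrophobic) probes.

It does **not** emulate: bulk solvent (a droplet has a free surface and a
finite-size rigid-mode constraint), proteins (the probe is a single
Lennard-Jones site, optionally charged), long MD trajectories, or
long-range dielectric screening. Consequences that matter:

* absolute hydrophilic degrees are comparable only within a protocol;
* binned motion correlations acquire a negative baseline of order −1/N
  (every retained mode is orthogonal to the removed rigid-body motions),
  so the correlation decay ratio measured on a desk-scale droplet falls
  well below the bulk value for the same machinery (see `scripts/acceptance.py`
  output and the README reproduction section).

`random_quadratic_system` additionally generates abstract seeded quadratic
surfaces (positive-definite, indefinite, or with a singular hydrogen block)
used purely as oracles for the linear-algebra layer.

## 4. Numerical choices

* Hessians are assembled from analytic per-pair second derivatives and
  symmetrized only by construction (no numerical symmetrization).
* The switch multiplier is C² so the analytic Hessian passes finite
  differences across the switch region.
* Angle (three-body) forces are distributed onto the three atom pairs by a
  least-squares central-force decomposition so that pairwise reassembly of
  the total force is exact.
* `bin_profile` sorts records by (bin, value) making every statistic
  bit-for-bit independent of record order; bin centers are rounded to 9
  decimals so centers that are mathematically exact multiples of the bin
  width compare cleanly.
* Curve integration uses the trapezoid rule on the 0.1 Å grid; masked holes
  inside a binned curve raise `GapError` rather than being interpolated.
* If a binned curve ends before the 8–12 Å zero window (small droplets),
  the spring-integrated force is anchored on the farthest sampled 1 Å of
  the curve instead of being left unanchored.
* The hydrogen-block solve falls back to an eigenvalue-filtered
  pseudo-inverse on singular systems and reports it.

## 5. Limitations

* Second-order (harmonic) description: valid near the reference
  conformation only; anharmonicity enters solely through ensemble
  averaging over frames.
* Water hydrogens are the only eliminated coordinates; no general
  coordinate selection is offered.
* Droplet-scale correlation statistics are biased by the finite-size mode
  baseline (Section 3); quantitative decay ratios require system sizes far
  beyond a desk-scale run.
* The Monte Carlo sampler moves waters rigidly; intramolecular flexibility
  affects the analysis stage only through the force field, not the
  sampling.
* Per-atom degrees for real proteins require an externally generated
  ensemble; the built-in probes are single-site stand-ins.
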