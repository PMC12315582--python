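# Methods

## Q-score sampling

The Q-score of an atom is the Pearson correlation between map values
sampled radially around the atom and a reference Gaussian profile. The
sampling protocol (all configurable on `SamplingProtocol`):

| parameter | default | meaning |
|---|---|---|
| `sigma_ref` | 0.6 Å | width of the reference Gaussian `v(r) = exp(−r²/2σ²)` |
| `r_max` | 2.0 Å | outermost sampling shell |
| `r_step` | 0.1 Å | shell spacing |
| `pts_per_shell` | 8 | nominal points per shell |
| `max_attempts` | 8 | re-rotations tried before accepting an empty shell |
| `seed` | 0 | base seed; each atom gets an independent stream `(seed, atom index)` |

Points on each shell are a golden-spiral spherical design rotated by a
seeded random rotation — deterministic given the seed, quasi-uniform, and
cheap. A candidate point strictly closer to a neighboring atom than to the
target atom is rejected and not replaced (the *ownership* rule); if a
rotation leaves a shell empty, fresh rotations are tried up to
`max_attempts`. The atom center (r = 0) is always included.

The reference profile uses amplitude 1 and offset 0. Pearson correlation is
invariant to positive affine rescaling of either argument, so these
constants are immaterial; the test suite asserts this directly rather than
leaving it as a claim.

Scoring eligibility: non-hydrogen atoms with occupancy > 0. Waters are
scored by default (`include_waters=False` excludes them). Altloc duplicates
are resolved at parse time to the highest-occupancy conformer (ties: first
in file). Atoms near the grid boundary are scored from in-grid points only
and flagged `low_support` when fewer than half the nominal points survive;
atoms with fewer than two distinct sampled radii, or flat density
(zero variance), are left unscored with a flag and excluded from the model
mean.

Map interpolation is trilinear; positions are Å with voxel (i, j, k)
centered at `origin + (i,j,k)·voxel_size`. On reading MRC/CCP4 the origin
is taken from the ORIGIN header fields when nonzero, else NSTART ×
voxel_size; both conventions occur in the wild and an explicit
`origin_override` is exposed. Voxel size comes from the header cell and
sampling counts, which remains correct for sub-box maps where a grid-level
spacing is undefined.

## Group aggregation

Amino-acid atoms split into backbone {N, CA, C, O, OXT} and side chain
(everything else); nucleotides into phosphate {P, OP1, OP2, OP3, O5′},
ribose {C1′–C5′, O2′, O3′, O4′} and base (the rest). O2′ is ribose in RNA
and simply absent in DNA; O3′ is assigned to the ribose of its own
nucleotide. Non-polymer components (ligands, saccharide units, waters) are
scored as one unit labeled by component name; each saccharide of a glycan
is therefore its own group. Unknown residue names fall back to the
component rule, never silently dropped. Two invariants are enforced by
test: backbone + side-chain atom counts partition each residue's scored
atoms, and the n-weighted mean of group means equals the model mean.

## Archive regression and offsets

`fit_archive` restricts rows to 1–10 Å (the archive's populated range),
fits an ordinary least-squares polynomial (degree 3 by default; degree is a
parameter and R² is reported so the degree-1…4 comparison can be made on
any table), and computes three vertical offsets from the residuals
`rᵢ = qᵢ − Q_mean(dᵢ)`:

* **o_peak** — the offset maximizing the number of residuals within a
  ±0.005 window (total width 0.01), searched on a 0.001 grid spanning the
  residual range; ties break to the smallest offset. This is a histogram-free
  mode estimate matched to the scale of Q residuals.
* **o_low / o_high** — in the default `per_side` mode, the 5th percentile of
  the below-peak residuals and the 95th percentile of the above-peak
  residuals, so that 95% of each side lies between the bound and the peak.
  An `overall` mode (plain 5th/95th percentiles of all residuals) is
  available; for skewed residuals the two differ slightly, and the per-side
  reading keeps exactly 95% of each tail's points inside its bound, which is
  the property the classification uses.

Percentiles are linear-interpolated order statistics (numpy default,
type 7). Degenerate case: identical residuals collapse all three offsets to
that value.

`rolling_percentiles` provides the non-parametric cross-check: empirical
percentiles of Q over entries within a sliding resolution window (0.5 Å
default), with grid points backed by fewer than 20 entries reported as
gaps. On residuals that do not depend on resolution the rolling 5%/95%
curves and the (overall-mode) offset curves agree to well under 0.03 RMS,
which the suite asserts on the synthetic archive; the offset curves are
smoother at the sparse resolution tails, which is why they are the default.

Entry classification is a strict comparison against Q_low_95%(d) and
Q_high_95%(d): `below_low` / `typical` / `above_high`. Resolutions outside
the fitted domain are evaluated by extrapolation with a warning.

## Relative percentiles

Strict inequality ("lower than") in the numerator; ties do not count. A
`weak` mode (≤) exists for sensitivity checks. The resolution window is
total width w (|dᵢ − d| ≤ w/2); an alternative `full` mode (|dᵢ − d| ≤ w)
is selectable since "window size" is ambiguous in common usage. A query
entry present in the table stays in the denominator: it cannot satisfy the
strict inequality, deflating all entries' percentiles symmetrically. The
default w = 0.5 Å keeps the correlation between Q_relative_resolution and
reported resolution weak in both resolution strata (the window-size scan in
`window_correlation_scan` reproduces this analysis on any table).

## B factors from Q

`B = f (1 − Q)`, clamped at 0. The linear form is the simplest transform
consistent with a single scaling parameter and the boundary condition
Q = 1 ↔ B = 0; the transform is a plain function argument away from being
swapped. f is optimized by grid scan (0–300 step 10 — the CC surface is
smooth and flat near the optimum, so a finer scan buys little), rendering a
model map per candidate and maximizing CC-mean against the experimental
map; ties break to the smallest f.

Rendering: each atom is an isotropic Gaussian with variance
σ² = σ₀² + B/8π² (the standard isotropic displacement convention),
σ₀ = 0.6 Å matching the Q-score reference width, unit integral scaled by
occupancy, truncated at 4σ. No element-specific scattering factors — a
deliberate simplification: CC-mean is invariant to overall scale, and
per-element amplitudes would only matter for mixed-element contrast at
very high resolution. CC-mean is computed over voxels within 3 Å of the
model by default (whole-grid and explicit-mask modes available), so empty
background cannot dominate the correlation.

## Synthetic data: what it emulates and what it does not

`make_toy_model` produces canonically named residues (ALA helices, SER
strands, G nucleotides, NAG saccharides) with atoms along a smooth helical
space curve at ~1.4 Å spacing plus a 0.03 Å seeded jitter. These are
chemically *labeled* pseudo-atoms, not stereochemically valid molecules:
grouping rules, neighbor-ownership sampling, rendering and scoring all
exercise the same code paths as real structures, but bond geometry,
rotamers and secondary-structure-specific density are not represented.

`simulate_map` renders the toy model (optionally with per-atom B) and adds
white Gaussian noise scaled to a fraction of the signal RMSD. Real cryo-EM
noise is neither white nor stationary and real maps carry CTF and
sharpening artifacts; passing tests on these maps demonstrates correctness
of the metric and its optimization, not performance on experimental data.

`simulate_archive` draws resolutions from a Beta(2.2, 4.5) density scaled
to 1–10 Å (unimodal, mode ≈ 3.3 Å, like the archive's resolution
histogram) and Q values from a decreasing cubic mean curve — pinned at
Q(1 Å) = 0.95, Q(3 Å) = 0.5, Q(5 Å) = 0.3, Q(10 Å) = 0.1, the qualitative
anchors of the real scatter — plus mirrored-Gumbel residuals (scale 0.05,
mean-centered), giving the long lower tail that misfitted models produce.
Values escaping [−0.1, 1.05] warn rather than clip, so the tails stay
honest. These coefficients are synthetic calibration choices, not fitted
archive values; statistics computed on real archive tables (readable via
`read_archive_csv`, including the EMDB API CSV export) will differ.

## Problem sizes and numerical choices

The test suite and acceptance script run entirely on synthetic data at
desk scale, chosen as the smallest sizes at which each statistical claim is
sharp: 10,000-entry archives for regression/offset recovery (sampling error
of a 5% tail with n ≈ 3,000–7,000 per side is ±0.3–0.5%), 1,000-row tables
× 100 queries for the exact counting checks, ≤ 48³ voxel grids and
15–30-atom models for scoring and B-factor round trips. The full pipeline
runs in seconds.

Tie-breaks are deterministic everywhere (first maximum = smallest offset or
scale factor); all random streams derive from explicit seeds, and repeated
runs are bit-identical. Q is clipped to [−1, 1] only against floating-point
overshoot of the correlation itself.

## Known limitations

* No half-map handling, FSC computation, local-resolution correlation, or
  map segmentation; reported resolution is an input, never estimated.
* No stereochemistry validation — Q-scores measure map–model agreement,
  not chemical plausibility.
* B factors derived from Q are unreliable where the model is misfitted
  (low Q inflates B for reasons unrelated to mobility), and are distinct
  from map-sharpening B factors and Rosenthal–Henderson B factors.
* Archive statistics are only as representative as the table supplied;
  the bundled generator is a statistical stand-in, not EMDB data.
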