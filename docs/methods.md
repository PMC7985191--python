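# Methods

This note documents the models, conventions and numerical choices
behind `emdamage`, and what the synthetic test-bed does and does not
establish about real data.

## Coordinate and map conventions

Maps are C-ordered `(nx, ny, nz)` arrays on orthogonal lattices; the
physical coordinate of voxel `(i, j, k)` is
`origin + (i, j, k) · voxel_size` with 0-based indices.  On reading
MRC/CCP4 volumes the axes are reordered to X, Y, Z
(`MAPC,MAPR,MAPS = 1,2,3`); the origin is taken from the `ORIGIN`
header words when any is nonzero, otherwise from `N*START` times the
voxel size.  Non-orthogonal cells are rejected — single-particle maps
are orthogonal, and this keeps all interpolation and carving exact.
Sigma (σ) always means the standard deviation over all voxels of the
map being contoured; difference maps use their own σ.

## Forward model

Atoms are isotropic 3D Gaussians: variance per axis
`(ADP + B_global)/8π²` (the crystallographic B-to-width convention, so
ADP inflation visibly flattens peaks), amplitude
`occupancy × weight / (2π·var)^{3/2}`.  Element weights are fixed
positive constants proportional to atomic number (Mn 25, Ca 20, S 16,
O 8, …).  They stand in for electron scattering factors; only relative
peak heights matter to any downstream stage, so the pipeline never
interprets absolute density.  Tails are truncated at 6σ (relative error
< 2 × 10⁻⁸).

## The toy complex

The synthetic target is a 46-atom complex in a 28.8 Å box: a
Mn₄CaO₅-type cluster (4 Mn, 1 Ca, 5 bridging O) with four ligated
waters, a 30-atom Cα-like helical scaffold at 8.5 Å radius, and one
disulfide-like S–S pair (2.05 Å) placed 8.3 Å from the cluster.
Cluster coordinates are realized from the damage-free XFEL reference
distance table by least-squares multidimensional embedding (classical
MDS on the shortest-path completion, then Levenberg–Marquardt).  Two
facts about that table matter:

* It is printed at 0.1 Å precision and is over-constrained (all ten
  metal–metal/metal–Ca distances are given for five atoms, and O5 has
  four contacts), so no 3D geometry reproduces every rounded value
  better than ~0.021 Å (verified by minimax optimization).  The
  embedding therefore accepts residuals up to the rounding half-step
  (0.05 Å) and guarantees the recomputed distances round back to the
  printed table.
* Pairs the table omits (e.g. water–water) are unconstrained; a soft
  excluded-volume term keeps them ≥ 2 Å apart so unrelated atoms do not
  collapse onto one site.

Default sampling is 0.36 Å voxels (80³ grid).  At this sampling the
cubic-spline interpolant localizes an isolated atom's density maximum
to better than 0.02 Å; at 0.45 Å voxels the bias grows to ~0.04 Å,
which is why the default is finer than the 0.822 Å pixel of typical
detectors — the simulator renders ideal Gaussian atoms, not
CTF-band-limited reconstructions, and must not let grid bias masquerade
as damage signal.

## Damage process

Damage is parameterized in absorbed dose (MGy = 3.7 × fluence at
300 kV, configurable for other voltages):

* **Occupancy** of damage-prone atoms (default: the cluster and its
  waters): `exp(−D/D_c)`, `D_c = 2200 MGy`, chosen so the full
  307 MGy exposure lands near the ~0.87 occupancy scale reported for
  beam-damaged metal clusters.
* **ADP** of every atom grows by `0.01 Å²/MGy`.
* **Drift**: Mn2 and Mn3 move apart along their axis with
  `Δ(D) = 0.2 Å · (1 − e^{−D/50 MGy})` each by default, saturating at a
  +0.4 Å pair elongation — the magnitude observed for the most
  dose-sensitive Mn–Mn distance.  The 50 MGy kinetic constant is a free
  parameter: no quantitative dose–response for metal movement is
  established, so the kinetics are a modelling choice, not a fit.
* **Disulfide**: the partner sulfur's occupancy drops to zero once the
  dose passes 18.5 MGy (5 e⁻ Å⁻²), the exposure at which the bond is
  still observed intact.
* **Noise**: independent Gaussian noise of σ = 0.15 per frame.  Each
  frame is an ensemble-averaged reconstruction in this emulation, not a
  raw micrograph, so per-frame noise is small; the level is set so that
  even a two-frame average keeps an intact disulfide above a 4σ contour,
  as the low-dose analysis requires.

Frames are rendered from the model damaged at the **mid-frame**
cumulative dose (unbiased within-frame average), so a summed map is a
dose-integrated mixture of damage states — exactly as in a real
reconstruction.  Consequently a planted saturating elongation of
+0.4 Å appears in the 50-frame dose-averaged map as roughly +0.3 Å;
recovery tests compare against the dose-averaged ground truth, which
the generator returns per frame.

## Analysis stages and their numerical choices

* **Frame sums** are plain voxelwise addition.  Per-frame dose
  weighting belongs to motion-correction/polishing pipelines and is out
  of scope; per-dose metrics are computed on the frame-averaged map so
  that, absent damage and noise, they are dose-independent.
* **Difference maps**: the subtrahend is RMS-normalized to the minuend
  (which map a published difference normalized is ambiguous; this
  choice is recorded in the output).  Low-pass filtering uses a cosine
  edge ending exactly at the cutoff, 5 Fourier voxels wide (of the
  longest box edge); the zero-frequency term is untouched.
* **Carving** zeros voxels within 0.75 Å of each metal — the literal
  reading of a "diameter of 1.5 Å"; the radius is configurable for the
  alternative reading.
* **Peaks** are 26-neighborhood maxima, ties broken by ascending grid
  index; subvoxel positions from separable 1D quadratic fits (cheap and
  adequate at these voxel sizes).  A minimum-separation filter (1.2 Å
  in assignment contexts) suppresses noise-split maxima.  The metal
  *search* threshold defaults to 10σ (the 17σ figure is a display
  contour; the searcher takes the top-k peaks in any case).
* **Metal assignment** distributes the expected element multiset
  heaviest-to-highest over the top peaks; identities (Mn1 vs Mn3, …)
  are transferred from the reference geometry by minimum-distance
  Hungarian matching within each element.
* **Bond integrity** samples every 0.1 Å along the segment and uses the
  minimum (robust to asymmetric breakage); the midpoint level is also
  reported.  On dose-integrated maps the classifier necessarily flips
  in the first dose interval after the planted break, once post-break
  frames dominate the sum — it cannot flip at the break dose itself,
  because a sum reaching dose D past the break still contains the
  intact early frames.
* **FSC** uses uniform frequency shells (half the smallest grid
  dimension by default) up to the coarsest-axis Nyquist; resolution is
  the linearly interpolated first crossing below 0.143, with flagged
  sentinels (never exceptions) for curves that never cross or start
  below threshold.
* **Refinement** maximizes `map_weight · Σ wᵢ ρ(xᵢ)` minus quadratic
  restraint penalties `((d − target)/σ_r)²`, with per-atom weights
  normalized to oxygen and scaled ×⅓ for metals (their positions come
  from the highest peaks and should dominate their own density).  ρ is
  a cubic B-spline interpolant of the map in σ units — a trilinear
  field has its maxima only at grid nodes and would quantize positions
  to the lattice (the separate `interpolate` map operation remains
  trilinear, as documented).  L-BFGS-B minimizes each macrocycle, with
  per-atom moves capped at a 0.25 Å trust radius; the restraint σ
  schedule is (0.1, 0.05), last value reused; targets are refreshed
  from the current model between macrocycles (the "modified library"
  behaviour); convergence is a maximum per-pair distance change below
  0.005 Å, so 1-decimal prints are stable.  Contacts ending below
  1.7 Å are fixed to 1.8 Å by moving the light atom along the pair
  axis, and flagged — both thresholds configurable, since only the fix
  value is documented behaviour.
* **Tables** print at 1 decimal with half-up rounding; step averages
  are the plain mean of the final four macrocycles; deltas are computed
  on the rounded values (so 3.1 − 2.7 reports +0.4).  Published tables
  are not always self-consistent between per-step values and printed
  averages (monomer averaging is the likely cause); bookkeeping checks
  use only self-consistent rows.
* **Occupancy proxy** is the metal peak-height ratio against the
  lowest-dose map, not a refined occupancy: reciprocal-space occupancy
  refinement is out of scope, and the proxy conflates occupancy loss
  with drift and ADP inflation — it is a damage indicator, not an
  occupancy estimate.

## The pipeline

`run_pipeline` simulates two independent-noise realizations of the
frame stack (one analyzed, the pair supplying half-maps for FSC), then
per dose: frame sum → FSC resolution → metal peaks → carve → light-atom
sites → restraints from initial positions → restrained refinement →
step-averaged distance table and deltas versus the damage-free
reference → bond integrity and occupancy proxies.  Reference labels for
detected sites come from the starting geometry, as in model building
from a prior structure; reference light atoms with no detected site
within 1.5 Å keep their prior position (counted in `n_light_sites`).
Everything is deterministic given the seed; rerunning a configuration
reproduces the machine-readable report byte for byte.

Default problem sizes — 80³ voxels, 50 frames, six doses — run in a few
seconds on one core; the simulations in the acceptance script (ten
recovery seeds, hundreds of regression fits) complete in well under a
minute.

## What the synthetic tests do and do not show

The generator plants every parameter the pipeline estimates (geometry,
elongations, break dose, occupancy decay, B-factor of the
resolution–particle relation), so the tests establish *estimator
correctness*: the chain recovers planted damage to ~0.003 Å median on
distances at the default SNR.  The generator does **not** emulate CTF,
projection/backprojection, alignment errors, solvent, dose-weighted
frame filtering, map sharpening, or particle-number-limited
reconstruction noise; absolute resolutions and σ-contrast values on
real maps will differ, and agreement here does not certify performance
on a real dataset.  The Rosenthal–Henderson series is simulated at the
level of the fitted relation itself, not via reconstructions.

## Known limitations

* Occupancy is measured only by the peak-height proxy (see above).
* The bond classifier's flip lags the true break dose on dose-integrated
  sums by construction; bracketing, not point identification, is the
  honest claim.
* `pair_atoms` keys on chain/residue/atom identity (altloc A only); no
  sequence alignment, so renumbered models must be pre-matched.
* Maps with permuted axes are normalized, but exotic MRC variants
  (non-orthogonal cells, unusual modes) are rejected rather than
  interpreted.
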