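# Methods

## Model

The engine is a standard 2D Cellular Potts Model on a toroidal
rectangular lattice. Each site holds a cell identity σ (0 = medium) and
a non-negative integer activity. The Hamiltonian contains Moore-pair
adhesion energies J_τ,τ′ (same-identity pairs excluded by the Kronecker
delta), a quadratic area penalty λ_Area (a_σ − A_σ)² and a quadratic
perimeter penalty λ_Perimeter (p_σ − P_σ)². The perimeter of a cell is
its number of distinct interfaces: ordered (site, Moore-neighbor) pairs
whose identities differ, so a lone site has perimeter 8. A single Moore
(8-neighbor) neighborhood is used everywhere — adhesion sums, perimeter
counting, neighbor selection in copy attempts, the activity geometric
mean, protrusion connectivity — to avoid hidden anisotropy between the
energy terms.

Dynamics: one MCS = width × height random copy attempts. Per attempt a
random site u and a random Moore neighbor v are drawn; if σ_u = σ_v the
attempt is trivial and is counted toward the MCS budget but not
evaluated (the time unit stays well defined while border-only work keeps
the cost low). Otherwise

ΔH = ΔH_adhesion + ΔH_area + ΔH_perimeter − ΔH_Act − ΔH_Chemotaxis

is computed from local information only, and the copy is accepted with
probability 1 if ΔH < 0, else e^(−ΔH/T). At ΔH = 0 the Boltzmann factor
is 1, so the attempt is accepted. The default temperature is T = 20.
Area and perimeter totals are maintained incrementally (a copy changes
the gainer's interface count by 8 − 2·n_gain and the loser's by
2·n_lose − 8, with n the like-identity neighbor counts of v) and are
audited against from-scratch recounts in the tests.

### Activity feedback

A site freshly incorporated by a cell receives the cell type's Max_Act;
a site reclaimed by the medium becomes inactive. After every MCS each
positive activity value decreases by one (a global decrement sweep,
performed after the attempt sweep). The bias term is

ΔH_Act(u→v) = λ_Act / Max_Act · (GM_Act(u) − GM_Act(v)),

subtracted from ΔH, with GM_Act the geometric mean of activity over
V(u) = {u} ∪ {same-cell Moore neighbors of u}. Conventions chosen where
the formula leaves room:

* V(u) includes u itself, so a freshly incorporated site with no active
  same-cell neighbors still carries its own activity into the feedback.
  The exclude-u variant was measured to be behaviorally
  indistinguishable on the single-cell benchmarks, so this choice is
  cosmetic in practice.
* GM_Act of a medium site is 0 (no resistance derived from activity).
* The λ_Act/Max_Act prefactor is the *source* cell type's; a medium
  source (retraction) therefore contributes no activity term. When two
  activity-driven cells meet, each attempt uses the attacker's strength
  against the defender's own neighborhood mean.
* λ_Chemotaxis is likewise the source cell's; for retractions by the
  medium the target cell's value applies, so chemotactic cells feel the
  gradient on both extension and retraction.

### Connectivity constraint

Multicellular scenarios enforce a local connectivity test on the cell
about to *lose* site v: the copy is rejected outright (before any
energy evaluation) if that cell's sites in the 8-ring around v form
more than one connected arc in cyclic order, or if v is the cell's last
site. The test is O(1) per attempt; a global flood-fill would be exact
but unaffordable per attempt, and the local arc test is the variant
commonly used for this purpose. Cells whose area reaches 0 (possible
only for non-enforced types) simply drop out of the live-cell registry.

### Randomness

All randomness flows from one seed per simulation. Per attempt the
stream is consumed in a fixed order — source row, source column,
neighbor index, then one acceptance draw only when the attempt is
non-trivial, passes connectivity, and has ΔH ≥ 0. The compiled sweep
draws from a numpy legacy stream seeded per `run()` call from the
engine's `Generator`, so identical seeds give identical trajectories.

## Measurements

Sampling is every Δt = 20 MCS after burn-in. Centroids and principal
axes come from the second moments of the cell's site coordinates,
mapped to one periodic image first (circular-mean unwrapping), so cells
straddling the wrapped boundary are handled exactly. Cell length is the
extent of site projections onto the major axis (max − min + 1) — an
unambiguous, directly testable reading of "length of the major axis".
A cell whose two principal moments coincide (e.g. a perfect square) has
no unique axis and the sample is flagged degenerate.

* Instantaneous speed: centroid displacement per MCS between samples.
  Tracks are unwrapped by minimal-image displacements, valid while a
  cell moves less than half the lattice per Δt (amply satisfied here).
* Turning angle: angle between consecutive displacement steps; samples
  with a zero step are excluded from means.
* Orientation-direction angle ∈ [0°, 90°]: acute angle between the
  (axial, sign-free) major axis and the displacement direction. The
  displacement over (t, t+Δt] is paired with the axis measured at t;
  at Δt = 20 the end-of-step pairing differs by well under the run-to-
  run spread for amoeboid cells and by ~1° for keratocytes.
* Persistence time and motility coefficient: least-squares fit of
  Fürth's equation x̄² = 2nM(t − P(1 − e^(−t/P))), n = 2, to the MSD
  computed over all overlapping windows, lags up to 10% of the track
  (longer lags carry too few independent windows), with relative
  (1/msd) weighting so the short-lag curvature that identifies P is not
  swamped; both parameters constrained positive. A secondary estimator
  (exponential fit to the direction autocorrelation) is provided as a
  cross-check. On synthetic Ornstein–Uhlenbeck persistent random walks
  with known (M, P) the fit recovers both within 15%.
* Directed speed: mean displacement component along the gradient per
  MCS. Chemotactic index: net up-gradient displacement divided by total
  path length.
* Order index: |mean unit displacement vector| over cells, divided by
  the number of cells so the documented [0, 1] range holds, evaluated
  per sampling step and averaged.
* Protrusions: 8-connected components of a cell's sites with activity
  > 0 (threshold configurable), components under 10 sites discarded;
  protrusion-gradient angle between the gradient direction and the
  cell-centroid → protrusion-centroid vector, minimal-image across the
  wrap.
* Tissue scanning: a tissue cell counts as scanned once any of its
  sites is Moore-adjacent to the migrating cell; the scanned fraction
  is cumulative. Stop durations: maximal runs of samples below a speed
  threshold (default 0.25 × the cell's median speed, configurable — the
  stationarity cutoff is a free choice of the analysis).

## Scenarios and seeding

Constants across scenarios: T = 20, λ_Area = 50, J_medium,medium = 0,
λ_Perimeter = 2 except where tissue rigidity is varied. Single-cell and
collective cells: A = 500 / P = 340 (collective: A = 200 / P = 180),
J_cell,cell = 100, J_cell,medium = 20; 200×200 wrapped lattice
(chemotaxis: 100×300 with a linear gradient of slope 0.33 along y, so
concentrations span 0–100). Collective runs vary the surface tension
γ_cell,medium = J_cell,medium − (J_cell,cell + J_medium,medium)/2 via
J_cell,cell ∈ {40, −60, −160} → γ ∈ {0, 50, 100}. The skin/tissue
scenarios use amoeboid parameters Max_Act = 20 (or 80), λ_Act = 2000,
A = 100 / P = 140 for the migrating cell and stiff, near-stationary
basic-CPM cells (A = 152 / P = 145) for the tissue, with all
cross-adhesions 20. The skin/tissue lattice (200×200) and the T-cell
count (10) are this package's defaults; coverage and tissue
λ_Perimeter are the swept knobs.

Initial placement is deliberately simple plumbing: below 95% total
coverage, cells are compact squares of roughly their target area on a
shuffled, jittered grid (an error is raised if the requested coverage
cannot be placed without overlap); at (near) full coverage the lattice
is tessellated into nearest-seed domains on the torus, which is gapless.
Activity starts at zero, and a relaxation burn-in (default 500 MCS for
single cells, 1000 for collective runs — long enough for area,
perimeter and polarization transients to settle) precedes all
measurement.

## Problem sizes and determinism in the shipped analyses

The shipped headline protocols use 5 independent runs × 10,000 MCS per
single-cell condition and 5 gradient runs × 5 chemotaxis strengths
(λ_Chemotaxis ∈ {0, 50, 100, 150, 200}, one snapshot per run after a
500 MCS burn-in plus 500 MCS) — sizes chosen so the full analysis
completes in minutes on one CPU while keeping the stochastic standard
error of the reported means around a degree / a tenth of a protrusion.
Collective-order and chemotaxis-sweep behavior at full scale (hundreds
of replicates, 5·10⁵-MCS relaxations) is represented in the test suite
by reduced-scale monotone-trend checks instead.

## What the synthetic generators do and do not show

The synthetic tracks used to validate the estimators (exact AR(1)
discretization of an Ornstein–Uhlenbeck velocity; pure Brownian and
ballistic limits) have stationary, isotropic increments and no shape
dynamics. They validate the estimator implementations — not that real
(or simulated) cells follow Fürth's equation, which for lattice cells
holds only approximately and only beyond the jiggling timescale.
Likewise the lattice model itself is phenomenological: activity is a
scalar memory, not an actin density; forces are implicit in the
Hamiltonian; and parameters map to biophysics only through calibration
against measured cell behavior.

## Known limitations

* 2D only; square lattice; no diffusing chemokine dynamics (static
  linear gradients evaluated at site centers), no secretion or
  consumption.
* The gradient lives on a wrapped lattice, so a concentration cliff
  exists at the y seam; cells are seeded mid-lattice and runs are short
  enough that the seam is rarely reached.
* The local connectivity test can miss rare global disconnections that
  an exact flood-fill would catch.
* Fragmentation of single cells (connectivity unenforced) occasionally
  sheds 1-site fragments; centroids/axes then average over all pieces.
  Measured incidence is ~6% of keratocyte samples with negligible
  moment distortion.
* The orientation-direction angle of the keratocyte-like phenotype at
  λ_Act = 200 measures ≈ 61°; lowering λ_Act toward ≈ 140 moves it
  through ≈ 55° without leaving the keratocyte regime, i.e. the exact
  value is λ_Act-sensitive while the amoeboid/keratocyte classification
  (< 40° vs > 50°) is robust.
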