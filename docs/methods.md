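# Methods

## Hydrogen-bond model

A hydrogen bond D–H⋯A is a purely geometric event: the donor–acceptor
distance d(D,A) and an angular criterion must both sit inside their cutoffs
in the same frame. Defaults are d_max = 0.35 nm and angle_max = 30°, the
standard cutoffs of GROMACS-style H-bond analysis, and both comparisons are
**inclusive** (a pair exactly at the cutoff counts). Two angle conventions
are supported because tools disagree and trajectories are analyzed with
both in the wild:

* **HDA** (default): the angle at the donor between D→H and D→A must be
  ≤ angle_max. This is the convention of the GROMACS H-bond tool.
* **DHA-deviation**: the deviation of the D–H–A angle from linearity
  (180°) must be ≤ angle_max, the VMD convention.

The two conventions genuinely disagree on off-axis geometries (the test
suite pins one such case), so the choice is an explicit field of
`HBondCriteria`, not a constant. Only N and O heavy atoms form "strong"
bonds by default; weak C-H⋯F-type contacts can be enabled by extending
`heavy_atom_elements` — they are excluded by default because they would
otherwise contaminate the occupancy statistics of every ester monomer.

One event is recorded per (donor-hydrogen, acceptor) pair, so a donor with
two hydrogens may bond twice to one acceptor through different hydrogens,
but a given (H, A) pair yields at most one event per frame. Intra-molecular
pairs are excluded by default (which also removes 1-2/1-3 bonded pairs);
the exclusion is a flag because whether intra-template bonds should count
is analysis-dependent.

### Periodic geometry and neighbor search

Distances use the minimum image convention in an orthorhombic box
(d −= L·round(d/L) per component). Triclinic boxes are rejected
explicitly — the screening protocol uses cubic boxes and silently wrong
wrapping is worse than an error. Coordinates are never wrapped on read;
all image handling lives in the geometry code, which makes detection
invariant under global translation mod box (a property test).

The production search is a cell list with bin edge ≥ d_max; boxes smaller
than 3×d_max in any direction fall back to all-pairs, because a cell list
on fewer than 3 cells per axis double-counts images. Both paths, and the
vectorized whole-trajectory path, are required to return *identical* event
sets to a deliberately naive all-pairs oracle that wraps coordinates into
the box and enumerates all 27 periodic images explicitly. This exact-set
equivalence (not a tolerance) is the core correctness guarantee.

## Screening statistics

Per frame, template–monomer events reduce to the set of bound monomer
molecules and their bond multiplicities (multiplicity 2 = "double hydrogen
bond", regardless of which sites are involved). From the series:

* **EBN** = max over frames of the bound-set size. The strict maximum is
  used because no smoothing rule is part of the definition; the fraction of
  frames attaining the maximum (`frames_at_ebn`) is always reported
  alongside so that single-frame flukes are visible rather than hidden.
  An all-empty series has EBN 0, attained in every frame.
* **HBN_Max** = max over frames of the total template–monomer bond count.
  EBN ≤ HBN_Max always (each bound monomer contributes ≥ 1 bond); the
  scorecard constructor enforces this invariant.
* **Occupancy**: the primary definition is average bonds per frame
  (total events / n_frames), which is additive over disjoint site pairs;
  the fraction of frames with ≥ 1 bond is emitted as a clearly-labelled
  secondary column since both conventions appear in published occupancy
  plots and they are not interchangeable.
* **Lifetimes**: *continuous* mode is the mean length of maximal
  uninterrupted bonded runs × dt, with an optional gap tolerance (frames)
  that bridges short unbinding blips; the default tolerance is 0 because
  any other value is an analysis decision. Runs truncated by the trajectory
  ends are included; with mean lifetimes two orders of magnitude below the
  trajectory length the censoring bias is at the percent level.
  *Intermittent* mode integrates the pooled bond-existence autocorrelation
  C(t) = ⟨h(0)h(t)⟩/⟨h(0)h(0)⟩ (FFT-based, trapezoid rule, lags up to
  n_frames/2). A pair that never bonds reports a missing lifetime, never
  zero. Monomers are ranked lexicographically by (EBN, HBN_Max,
  template–monomer occupancy), descending, with a stable sort.

## Radial distribution function

g(r) between named site sets uses plain shell normalization:
g(bin) = Σ_frames counts / (n_frames · N_ref · V_shell · ρ̄), with the exact
shell volume (4π/3)(r_hi³ − r_lo³) and ρ̄ = N_target/V_box. No
excluded-volume correction is applied — peak *positions* and relative
heights, which drive the site-accessibility comparison between carbonyl and
ester oxygens, do not depend on it, and any correction would be a modelling
choice. r_max defaults to min(box)/2 − bin_width and may never exceed
min(box)/2 (minimum-image validity). Default bin width 0.002 nm resolves
the ~0.18–0.30 nm hydrogen-bond contact peaks. Self-pairs are excluded when
reference and target sets overlap. Peaks are strict local maxima ordered by
height; a monotone profile reports none.

## Binding energies

ΔE_bind = E_complex − E_template − ΣE_monomer, converted to kJ/mol with
1 hartree = 2625.4996 kJ/mol. Negative is favorable; tables sort ascending
(strongest binder first) with a stable sort. All quantum chemistry —
geometry optimization, single-point energies, BSSE/counterpoise — is
upstream of this package; `cp_corrected` is a provenance flag only. The
kJ/mol and hartree paths agree to 1e-9 relative (tested), which bounds the
conversion round-off far below chemical significance.

## Synthetic generator

The generator emulates the *counting structure* of a pre-polymerization
box, not its physics: one template fixed at the centre of a cubic periodic
box (default 4 nm), k donor sites (N-H) and m acceptor sites (O) on
mutually orthogonal/antipodal directions at 0.35 nm radius, N monomers
(default 5) and inert C filler particles (no N/O sites, so they can never
create spurious bonds). Each monomer follows an independent two-state
Markov chain with per-ps rates k_on (default 0.01) and k_off (default
0.02), discretized as p = 1 − exp(−k·dt), capped at `max_simultaneous`
concurrently bound monomers; a binding monomer attaches in
double-hydrogen-bond geometry with probability `double_bond_prob` when the
needed second template site is free. Frames are i.i.d. conditional on the
binding state; molecules are rigid dummies.

Bound geometry is sampled safely *inside* the inclusive cutoffs: distance
uniform in 0.18–0.30 nm and donor angle uniform in [0°, 27°] (0.9 ×
angle_max), so format round-off can never flip an event. Unbound monomers
are rejection-sampled outside an exclusion sphere that keeps every one of
their sites > d_max from every template site; trailing atoms of bound
monomers point outward, and the ≥ 90° separation between template site
directions keeps any unintended site pair beyond ~0.49 nm. Together these
make the emitted ground truth (per-frame bound sets and multiplicities,
EBN, HBN_Max, per-pair occupancy, episode lengths) *exactly* recoverable by
the detection pipeline — verified frame-by-frame across seed sweeps — while
occupancy and lifetime converge to the analytic Markov values
(k_on/(k_on+k_off) and ≈ 1/k_off) at sampling accuracy.

What the generator does **not** emulate: force fields, solvent structure,
correlated dynamics between frames, monomer self-aggregation geometry,
diffusion. Passing tests therefore demonstrate that the *counting and
geometry machinery* is correct on trajectories whose truth is known, not
that any particular real monomer ranks above another; real-trajectory
conclusions inherit the MD engine's physics, not ours.

## Problem sizes and numerical choices

The validation suite runs at sizes chosen to make sampling error small
relative to the tested tolerances while keeping the whole suite fast on one
CPU: oracle equivalence on 100 frames × 200 H-bond-capable molecules in a
3 nm box; EBN/HBN recovery over max_simultaneous ∈ {0,1,2,3} ×
double_bond_prob ∈ {0, 0.5, 1} × 20 seeds at 5,000 frames (240 runs, exact
equality required in every one); occupancy/lifetime recovery on ten
independent 20,000-frame telegraph fixtures at (0.01, 0.02) ps⁻¹ — ten
fixtures put ~1,300 bond episodes behind the lifetime estimate, an order of
magnitude more than the 10 % band needs; RDF limits with 10,000 uniform
targets × 100 frames. The occupancy check uses the analytic variance of the
two-state-chain mean (autocorrelation included), not an i.i.d. formula.

Tie-breaks and degenerate inputs: events order deterministically by (donor
atom, acceptor atom, hydrogen); equal-score monomers and equal-energy
complexes keep input order; a zero-monomer selection yields an empty
scorecard rather than an error; nonuniform frame spacing reports the median
dt with a warning flag; a trajectory with a single frame takes dt from the
fixture header.

## Known limitations

* Orthorhombic boxes only; no triclinic support.
* Connectivity comes from the selection config (or the element+bond
  heuristic `infer_sites`); no topology-file (TPR/PSF) parsing and no
  bond perception from 3-D geometry.
* The intermittent lifetime estimator integrates only to n_frames/2 and
  makes no finite-size correction; for slowly-relaxing systems it is a
  lower bound.
* Ranking reports the (EBN, HBN_Max, occupancy) ordering; it makes no
  claim that this ordering predicts adsorption capacity beyond the
  screening rationale itself.
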