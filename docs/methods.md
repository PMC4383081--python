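# Methods

`mtseam` is a desk-scale re-creation of the computational machinery used
to solve kinesin-decorated microtubule structures by pseudo-helical
single-particle cryo-EM, together with the downstream analyses that such
a study performs: density-steered flexible fitting of atomic models,
rigid-body subdomain motion analysis, and stopped-flow nucleotide-release
kinetics fitting.  Everything runs on synthetic data with known ground
truth; this note records the models, the parameters that matter, the
numerical choices, and what the synthetic experiments do and do not
establish about real data.

## The lattice model

A microtubule is `n_pf` protofilaments (12–15) of alpha/beta-tubulin
dimers on a cylinder of radius 110 Å.  The defaults encode the canonical
B lattice: 40 Å monomer rise, 80 Å dimer repeat, 3-start monomer helix,
zero supertwist.  Crossing from one protofilament to the next advances
the lattice axially by `start · monomer_rise / n_pf` (8.571 Å for 14
protofilaments); a full turn accumulates 120 Å — one and a half dimer
repeats — so the lateral register necessarily breaks at one interface,
the seam.  `seam_position` selects which interface carries the break;
`polarity` (a proper 180° rotation about an axis perpendicular to the
filament) selects which end points toward +z.  One kinesin motor domain
per tubulin dimer binds radially outward of the beta subunit, giving the
decorated lattice its 80 Å axial periodicity.

The measured axial repeat of the study's own filaments is not printed
anywhere; 80.0 Å here is the textbook convention, configurable but never
calibrated.  Whether 14-protofilament filaments carry supertwist is
likewise not stated; the default of zero supertwist is an assumption
(and the search machinery does not handle supertwisted lattices).

## Rendering and the subunit shape models

Subunits are rendered as small Gaussian mixtures (3–4 blobs each, sigma
8–10 Å) rather than atomic models.  Two shape choices are deliberate and
load-bearing:

* **Alpha and beta tubulin are identical.**  An undecorated filament
  then carries only the 40 Å monomer periodicity, so the 80 Å layer line
  in a power spectrum reports motor decoration and nothing else — the
  property the layer-line diagnostic tests depend on.
* **Subunits are not mirror-symmetric along the filament axis.**  Both
  the tubulin monomer and the kinesin head carry a plus-end-ward lobe.
  Without this, a polarity-flipped seam lattice is (for identical
  alpha/beta) almost exactly another seam lattice, and filament polarity
  becomes undeterminable from single-view projections — a degenerate
  corner of the blob model, not a feature of the real molecules, which
  are strongly lobed.  The lobe magnitudes are realism choices fixed at
  design time, not fitted quantities.

A 3D Gaussian projects analytically to a 2D Gaussian, so synthetic
projections are rendered directly in 2D (fast, interpolation-free).
Density maps are band-limited with a cosine-edge low-pass whose taper
ends exactly at the cutoff frequency, so "filtered to 20 Å" means zero
power beyond 1/20 Å⁻¹.

## Imaging model

Movies are CTF-modulated projections split into `n_frames` frames with
cumulative per-frame drift and additive Gaussian noise (a Gaussian
approximation of counting noise at the stated dose; adequate at the
SNRs used here and far cheaper than full Poisson optics).  The CTF is
the standard phase function with positive underfocus and 0.07 amplitude
contrast; astigmatism and dose weighting are not modelled.  Defaults
follow the study's conditions (300 kV, 1.99 Å pixel, ~15 e⁻/Å² over 15
frames, 1–2.5 µm underfocus); the desk-scale reconstruction pipeline
runs at 5 Å pixels instead (see below).

Frame alignment correlates each frame against the leave-one-out running
average — correlating a frame against an average containing itself is
dominated by the frame's own noise autocorrelation peak at zero shift —
with three iterations and parabolic subpixel peaks.  Drifts are
reported relative to the first frame.

## Conventions

Images are indexed (row, col), 0-based; the filament axis at zero
in-plane angle lies along axis 0, and the in-plane angle is measured
from axis 0 toward axis 1.  Volumes are indexed [x, y, z] with the
filament axis along z; image axes (0, 1) correspond to (x, y) of the
rotated frame.  Orientations are ZYZ Euler angles: `R = Rz(psi) ·
Ry(tilt) · Rz(rot)` maps body to image coordinates with projection
along image z; edge-on views sit at tilt 90°, and the out-of-plane
search window is tilt ∈ [75°, 105°].

## Reconstruction

The desk-scale reconstruction box is 80 voxels at 5.0 Å — 400 Å, an
exact multiple of the 80 Å repeat.  That commensurability is what makes
the wrapped helical operators (rotation about z plus axial shift with
circular z) exact for box-spanning filaments, and it is assumed by the
symmetrization and seam machinery.

* **Projection matching.**  Reference projections are central slices of
  the reference volume's Fourier transform (trilinear complex
  interpolation), cached by quantized angles.  Scores are normalized
  cross-correlations maximized over shifts within ±8 px (FFT
  correlation, parabolic subpixel peak).  Searches run coarse-to-fine
  (4°, then 1°, 0.25° — or 2°, 0.5° in the refinement's local stage) as
  coordinate-descent sweeps on grids snapped to absolute multiples of
  the step, so segments refining near the same orientation share the
  projection cache.
* **Seam and polarity** are decided per filament by summing, over its
  segments, each segment's score against all `2·n_pf` candidates — the
  n_pf seam rotations (k applications of the helical operator) times
  two polarities.  The candidates are **transformed volumes, all
  projected at the same consensus orientation**.  This matters: an
  equivalent-looking shortcut that enumerates candidates as modified
  Euler angles through one projection library is measurably biased,
  because the central-slice interpolation error varies with projection
  angle and the decision margins (0.1–1 % of the correlation — adjacent
  seam candidates are themselves ~0.99 correlated) sit below that bias.
  Holding the projection geometry fixed makes the interpolation error
  common mode, and the comparison cancels it.  The filament consensus
  orientation is the score-weighted mean rotation of its segments'
  alignments after mapping each into a common candidate frame.
  A decision is flagged ambiguous when the top-two summed-score gap is
  below `0.004·√n_segments`, the ≈95th percentile of the gap measured
  on score tables of pure-noise segments (the gap of a noise-only
  table grows as √N).
* **Reconstruction** is direct Fourier insertion of each box's central
  slice at its orientation with shift compensation, trilinear gridding
  onto the 3D grid with overlap-weight normalization, 2× oversampled
  slice sampling (zero-padded FFTs), and division of the real-space
  result by the trilinear kernel's sinc² envelope.  Half-maps split by
  even/odd repeat index — quasi-independent given independent noise,
  though neighbouring repeats of one filament share signal, so the FSC
  of very small sets is optimistic.
* **Pseudo-helical symmetrization** averages all `n_pf` helically
  transformed copies onto one good protofilament, regenerates the
  filament with the inverse operators, and combines the copies through
  complementary soft wedge masks (cosine edges, an exact partition of
  unity).  Because the operators are applied to a seam-containing
  lattice, one of the n_pf contributions to the average is misregistered
  by half a repeat — an inherent 1/n_pf dilution of the scheme, not a
  bug — and the rebuilt map retains the seam between the last and first
  wedge.
* **Refinement** runs four rounds against references low-passed at
  20, 15, 12 and 10 Å, each round re-reconstructing, symmetrizing and
  tight-masking (threshold 0.2 of max on the 20 Å map, smoothed with a
  10 Å half-width Gaussian).  The divergence diagnostic scores all
  segments against one fixed reference (the starting reference at the
  first ladder cutoff) every round, since scores against the evolving
  references are not comparable; the mean plateaus with noise-level
  jitter (~0.005) once alignment converges, and a drop of more than
  0.05 aborts.  The full map filtered back to 20 Å can be fed into a
  second seam/alignment cycle.

The synthetic datasets place 10–50 boxed segments on each of tens of
filaments with random seam, polarity, azimuth, tilt (±8°) and in-plane
angle (±4°), segment-wise random repeat phase and lateral jitter
(whole-pixel crops from a padded rendered view — circularly shifting a
clipped projection would wrap filament ends into the box and bias seam
scoring), and Gaussian noise at SNR 0.3 (signal variance over noise
variance).  Problem sizes used by the test suite — ~200 repeats for
refinement runs, 52 filaments × 12 segments for seam-recovery rates,
96 views for noiseless phantom reconstructions — are the package's
desk-scale operating points; a real data set is orders of magnitude
larger in every direction.

What passing these tests shows: the geometry, symmetrization, seam
logic and refinement loop are self-consistent and recover known ground
truth under the stated noise model.  What they do not show: behaviour
under structured noise (ice gradients, carbon edges), imperfect CTF
estimation, supertwisted lattices, bent filaments, or partial
decoration — none of which the generator emulates.

## Flexible fitting

The fitting engine deliberately replaces all-atom solvated molecular
dynamics with coarse overdamped Langevin dynamics in reduced units
(thermal energy k_BT = 1): heavy atoms or CA-only models, local
stereochemistry maintained by harmonic springs on all short-range atom
pairs of the starting structure (default cutoff 6 Å, spring 20 in
reduced units), optional positional restraints (default 50 — the
analogue of the strong-restraint tier used for tubulin), and no
electrostatics.  What is reproduced is the protocol logic:

* the steering potential is the map low-passed to 6 Å, clamped
  non-negative and rescaled to [0, 1], with energy `−ξ·w·Φ(x)` applied
  to **backbone atoms and nucleotide ligands only** (uniform weights);
* the coupling ξ follows a **linear ramp from zero** (default 6000
  steps at dt 2×10⁻³ for the calibration fixture — the shape of the
  protocol is preserved, not its nanosecond timescales);
* convergence is monitored as backbone RMSD from the starting model per
  atom group, and the fitted frame is selected **just after the initial
  rapid transition**: the first frame whose smoothed RMSD derivative
  falls below 10 % of its peak and stays there for 10 % of the run
  (5-frame moving average with edge padding).  Flat curves return the
  start flagged; curves that never plateau are flagged as such;
* follow-up stability runs switch the steering off and positionally
  restrain a stated selection (e.g. tubulin residues 1–380, excluding
  the kinesin-binding helices), reporting backbone drift and the
  per-bond persistence of a supplied hydrogen-bond list.

The known-answer fixture (a two-helix CA model with a 15° hinge
rotation, steered by a 4 Å-sharp potential at 1.5 Å voxels with
ξ_max = 120) recovers the rotation within 2° and 0.6 Å.  The sharper-
than-6 Å potential is appropriate for CA-only models, which have no
side-chain bulk to fill a 6 Å envelope.

## Subdomain motion analysis

Superposition is closed-form least squares (Kabsch, proper rotation
enforced); axis–angle decomposition takes the angle from the rotation
trace, the axis from the antisymmetric part (eigen-analysis at 180°),
and the screw point as the least-squares point of minimal displacement.
Rotations under 0.1° leave the axis undefined and are flagged.  The
kinesin subdomain boundaries shipped in `KINESIN_SUBDOMAINS` (N-terminal
= P-loop half of the sheet with helices α1/α2/α6; upper = switch half
with L7/L8; lower = switch II cluster) are **nominal**: the published
motions were measured with calibrated fragment boundaries that are not
printed, so these defaults must be calibrated against the known
rotation magnitudes before quantitative use on real models.  Hydrogen
bonds use heavy-atom criteria (donor–acceptor ≤ 3.5 Å, antecedent angle
≥ 120°, hydrogens being absent from EM-derived models); clashes use
standard van der Waals radii with a 0.4 Å overlap threshold and a
spatial tree that exactly reproduces the all-pairs scan.

## Kinetics

Mant-ADP release traces are single exponentials,
`F(t) = offset + amplitude·e^(−k_obs t)`, and the observed rate
saturates hyperbolically with microtubule concentration,
`k_obs = k_basal + k_max·[MT]/(K_0.5 + [MT])`.  Per-trace fits use
nonlinear least squares with log-linear initial guesses; the hyperbola
is fitted unweighted with `k_basal` fixed to zero by default (the basal
release enters the source data only qualitatively).  Flags mark
unidentifiable (flat) traces, non-convergence, and designs whose
concentrations never reach the fitted `K_0.5`.  The synthetic design
used for parameter-recovery checks is 8 concentrations spanning
0.25–4× the half-saturation constant, 3 replicates, 5 % Gaussian noise
on the fluorescence amplitude — the concentration series of the source
experiment is not printed, so this grid is the package's own choice.

## Known limitations

* No supertwist, no bent filaments, no multi-filament micrograph
  crowding; segments are simulated at box level for the pipeline.
* CTF handling is phase flipping only (no Wiener weighting, no
  per-particle defocus refinement); defocus is taken as known.
* The even/odd half-split shares signal between halves for small sets.
* The fitting engine's reduced units have no calibrated mapping to
  physical energies or times, and no claim of equivalence to any
  molecular-dynamics coupling constant is made.
* The deposited-coordinate comparisons (subdomain rotation magnitudes
  between the nucleotide states; backbone RMSD against the crystal
  comparator) require coordinate files that are not redistributable in
  this repository; the corresponding tests fail with an explanatory
  message unless the files are supplied under `data/deposited/`.
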