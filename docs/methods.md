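# Methods

This note records the models, parameter choices and numerical decisions
behind `dnam`, in the order data flows through the package.

## Matrix layout and the rotation-closure constraint

A 48-cell origami matrix carries five cell roles: 16 data, 4 index,
4 orientation, 4 checksum and 20 parity cells. The central four columns
form the *message region* (data + index + orientation); the outer column
pairs hold the checks. Surface-bound origami land face-up or face-down
with arbitrary in-plane rotation, but only face-up origami emit signal
and a 6×8 grid read at 90° changes aspect ratio, so the only read
ambiguity is a half turn. The design therefore requires the *constraint
graph* — every (storage cell, covered set, function) triple — to be
closed under the point rotation (i, j) → (5−i, 7−j). Consequently all
error weights, and the overall matrix weight, are invariant under
rotation of the matrix, and error correction can run before orientation
is resolved. Orientation is then decided by a 4-bit marker pattern
(1,1,1,0) whose rotated image (0,1,1,1) differs from it.

### Parity coverage sets

Half-turn rotation pairs the 48 cells into 24 two-cell orbits with no
fixed points, so constraints come in pairs: a check over cell set S
stored at cell c forces a check over rot(S) at rot(c). The 20 parity
bits are ten such orbit pairs. Each representative covers six message
cells, every message cell is covered by exactly five parity checks, and
the family was selected by simulated annealing to maximise the minimum
weight of the induced [48, 24] linear code (no nonzero codeword below
weight ≈ 6–8) subject to exact rotation closure. Two families that were
built and rejected:

* rows/columns plus 2×2 blocks of the message region (the obvious
  "bi-level" geometry): minimum distance ≈ 4; under the greedy search
  most patterns with ≥ 4 errors miscorrect to a nearby wrong codeword;
* the extended quadratic-residue [48, 24, 12] code, embedded exactly via
  a fixed-point-free involution (y ↦ −1/y on the projective line mod 47)
  in its automorphism group: optimal distance, but its weight-11 checks
  make the cell-weight landscape nearly flat and the greedy search then
  corrects almost nothing beyond 3 errors.

Sparse five-regular checks are the working compromise between code
distance and search guidance — the same trade-off that makes LDPC codes
pair sparse parity checks with message-passing decoders. The concrete
sets live in `layout._PARITY_ORBITS`; alternative layouts can be loaded
from the JSON serialization.

### Checksums

A 4-bit value with four distinct bit functions over one covered set
cannot be stored rotation-symmetrically (the four storage cells pair
into two orbits, and paired cells must hold the same function of a
rotation-paired set). The checksum layer is therefore two 2-bit
popcounts: the number of set bits among the top-half and bottom-half
data+index cells, each mod 4, with the halves exchanged by rotation.
The low bit of each popcount is an ordinary parity; the high bit is the
one nonlinear check in the graph and catches pairs of cancelling flips
within a half.

## Error correction

Cell weights follow the two-level rule: a message cell's weight is the
number of violated checks covering it; a check cell's weight is the
number of its covered cells implicated by more than one violated check.
The overall matrix weight is the summed weight divided by the number of
matched parity bits; a matrix with no matched parity bit gets +∞ (such a
state is never preferred).

`correct_matrix` is best-first search over single-bit flips:

* children are generated only for cells implicated by a currently
  violated constraint (covered cells and the storage cell);
* the queue is keyed by (overall weight, depth, insertion order), with
  *deeper* states preferred on weight ties so the search commits to a
  descent and uses the queue for backtracking;
* a node needing more than the remaining flip budget is pruned using the
  bound that one flip repairs at most seven violated checks (the densest
  cell participation in the layout) — the bound is admissible, so
  pruning never removes a reachable solution;
* consistent matrices are collected as found and the search continues,
  restricted to strictly closer candidates, returning the consistent
  matrix at the smallest flip distance. Returning the *nearest*
  consistent matrix rather than the first one found roughly halves the
  miscorrection rate at 4–6 errors.

The flip limit is 9 per matrix. The expansion budget (queue pops)
defaults to 10,000: at that budget hard instances typically exhaust the
pruned reachable space before the budget (average expansions < budget),
so further search changes almost nothing; the budget exists to bound the
worst case. The kernel packs matrices into a 64-bit word and runs under
numba (~2 µs per expansion).

Exhaustive checks: every single-bit corruption of every reference
matrix, and of its rotated image, is corrected back to the original —
guaranteed structurally, because two distinct consistent matrices are at
least distance ~6 apart while a corrupted matrix is at distance 1.

## Fountain code

Ideal Soliton degrees (the printed p(1) = 1/k is its first term; the
robust variant is deliberately not the default since the reference
encoding used 15 droplets for 10 segments). Droplet membership is a pure
function of (set seed, k, droplet index) through an independent PCG64
stream per droplet, so a reader reconstructs membership from recovered
indexes alone. The encoder re-draws the whole droplet set (bounded
retries) until the full set and every leave-one-out subset peel
successfully; this is what makes loss of any single origami harmless.
`peel_decode_robust` additionally tolerates a few *corrupt* droplets by
discarding up to two droplets and preferring the decoding consistent
with the largest number of droplets — a wrong payload that slipped
through matrix-level correction is then treated as an erasure.

## Localization model

The likelihood of a cluster of localizations (xᵢ, yᵢ) with reported
uncertainties Δxᵢ, given site intensities I_k, grid pose (x_c, y_c, θ),
global registration variance Δx_g² and background B over cluster area A,
is a 48-component Gaussian mixture plus uniform background, times a
Poisson factor in the total count N with mean ΣI + B. Each component has
per-axis variance Δxᵢ² + Δx_g² and normalisation 2π(Δxᵢ² + Δx_g²). Two
readings fixed at implementation time: the background enters as an
additive mixture component B/A (a multiplicative uniform factor is not a
normalizable density), and the Poisson term uses mean ΣI + B (a Poisson
"of mean N" would carry no information). With that structure the log of
the total-count term cancels the mixture normalisation and the objective
reduces to (ΣI + B) − Σᵢ log(Σ_k I_k g_ik + B/A), which is minimised
with L-BFGS-B under I_k ≥ 0, B ≥ 0, Δx_g² ∈ [0, 400 nm²], using exact
analytic gradients.

Initialisation matters more than the optimiser: the θ basin is only a
few degrees wide before the fit locks onto the lattice one period off.
Starts come from the lattice structure factor — |Σ exp(2πi x′/pitch)|
over a quarter-turn scan gives θ up to 90°, and its complex argument
gives the lattice phase, from which the four phase-consistent centre
candidates nearest the centroid are enumerated (the localization
centroid itself is biased when the bit pattern is lopsided). Candidate
poses (two θ peaks × quarter-turn branches × four centres) are ranked by
a fixed-pose likelihood with histogram intensities and the best two are
refined. The residual half-turn ambiguity is resolved downstream by the
orientation bits. A readout whose true pattern leaves an entire edge row
or column empty is intrinsically ambiguous to *any* reader (two window
placements explain the data equally well); such readouts usually fail
decoding and are discarded rather than corrupting the message.

Cluster picking follows the radius/annulus rule with R = 60 nm (the
half-diagonal of the 50×70 nm grid footprint plus jitter), an inner
threshold of 50 localizations, and a 15% annulus cap; accepted clusters
closer than R to an earlier one are duplicates. The on/off intensity
threshold is the two-class Otsu valley of the pooled fitted intensities
(plateau midpoint, since the between-class variance is flat across an
empty valley); if the explained-variance ratio at the cut is below 0.75
— a single Gaussian caps it near 2/π — the distribution is deemed
unimodal and half the median is used instead, with a warning.

## Synthetic recordings

`synth_localizations` emulates one field of view: origami are placed
uniformly with a 250 nm minimum separation and uniform random rotation;
each 1-site emits Poisson(35) localizations (≈ 3 nM imager over 40,000
frames at ~3 s⁻¹) unless missed (probability 0.10); 0-sites activate
spuriously with probability 0.02; localization jitter equals the per-row
uncertainty, drawn as 4 nm × U(0.7, 1.3); background is 50 µm⁻²
uniform. The per-site miss/spurious defaults give ~3 wrong bits per
origami — within the error range the codec corrects easily, matching a
good experimental preparation rather than the worst one. Every generator
emits a ground-truth sidecar (poses, effective site bits, per-loc
labels) so tests can score without re-simulation. What the generator
does *not* model: drift, camera noise and PSF shape (localizations are
taken as given, as from an upstream localizer), repeated blinking
kinetics within a binding event, origami deformation, and face-down
origami (which simply emit nothing and are invisible).

## Recovery simulation

For each message size the planner picks the minimal index width whose
2^w indexes can address ceil(1.5·k) droplets, the widest data field that
allows (20 − w bits), encodes, and makes ten copies of each origami.
Copy corruption is an i.i.d. per-site flip process: flip counts are
Binomial(48, µ/48) at target mean µ, and curves are reported against the
realized mean. This choice (over, e.g., a uniform window of flip counts)
is the physical reading of independently missing/spurious sites and
reproduces non-integer realized means naturally; it also disperses flip
counts, which flattens the recovery decline relative to any
lower-variance schedule. An origami counts as recovered when any copy
decodes to its true index and payload (copies are decoded until the
first success — later copies cannot change any reported quantity); a
message counts as recovered when peeling reassembles every segment.

Problem sizes used by the shipped experiment configurations: message
sizes 160 and 480 bits (15 and 53 origami), 40 repetitions per error
level, ten copies per origami — a deliberate subset of the 160–12,800
bit grid chosen so a full sweep stays under ten minutes on one CPU.
Averaging over only two small sizes raises the curve at high error
levels relative to a 40-size average, because small stores are the
lucky ones near the droplet-loss threshold: this, plus the stand-in
parity sets, is why the simulated message recovery at mean 8.2 and 9.0
errors per origami runs above the published 55% and 7.5% while the 7.4
point and both droplet-subset endpoints reproduce. The ten-copy
robustness claim is checked by measuring the per-copy success curve on
the reference store, interpolating it at 63%, and running 40 full
repetitions at that corruption level.

## Known limitations

* The published parity coverage sets (supplementary material) are not
  reproduced; the shipped design satisfies every stated structural
  property but per-error-level percentages can differ by tens of points
  at the steep part of the curve.
* Ideal-Soliton peeling at 1.5× redundancy is fragile for large k;
  the robust Soliton would smooth the large-message collapse but is not
  what the reference encoding used.
* The grid fit assumes an idealized rigid lattice; an empirically
  averaged template (as the study used) would absorb systematic site
  displacement that this package treats as noise.
* Readout of designs with empty edge rows/columns is ambiguous up to a
  one-pitch window shift for any localization-only reader.
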