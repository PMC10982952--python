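# Methods

## Backbone representation and features

A chain is reduced to its backbone atoms N, CA, C, O. Each residue defines
a local frame from the raw triplet [CA→C, CA→N, CA→C × CA→N]; the columns
are orthonormalized (first normalized, second Gram–Schmidt-orthogonalized,
third their cross product) so the frame is a proper rotation. This matters
because relative orientations between residues are encoded as quaternions
of OᵢᵀOⱼ, which is only a rotation if the frames are orthonormal.
Quaternions are canonicalized to a non-negative scalar part to resolve the
q ≡ −q double cover deterministically.

Node features per residue (width 35 + d_noise):

| block | width | notes |
|---|---|---|
| dihedrals | 4 | (sin φ, cos φ, sin ψ, cos ψ); undefined terminal angles use the (0, 0) sentinel, which no real angle produces |
| secondary structure | 8 | one-hot over H, G, I, T, E, B, S, loop |
| centrality | 1 | unnormalized betweenness over unordered pairs on the contact graph |
| pre-design channel | 22 | one-hot residue constraints; all-zeros where unconstrained |
| noise | d_noise (default 16) | N(0, 1), resampled per designed sequence |

Edge features per ordered pair (width 9): Cα–Cα distance, the unit
direction to the partner expressed in the source residue's frame, the
relative-rotation quaternion, and the shortest-path hop count on the
contact graph (12 Å Cα cutoff). Unreachable pairs get a sentinel hop count
of 32 (configurable) so the value stays a bounded integer. All exported
features are invariant under rigid motion because the frames are
equivariant; the test suite verifies this at 1e−6 over 20 random
rotations+translations.

Secondary structure is assigned by an internal Kabsch–Sander
implementation (electrostatic hydrogen-bond model, −0.5 kcal/mol cutoff;
amide H placed 1 Å from N opposite the previous carbonyl; missing carbonyl
O rebuilt in the peptide plane) with the standard pattern rules: two
consecutive n-turns make a minimal helix (n = 4 → H, 3 → G, 5 → I),
parallel/antiparallel bridge patterns make B, ladders E, remaining turn
spans T, Cα pseudo-angles above 70° bend S, priority
H > E > B > G > I > T > S. Implementing it internally avoids an external
binary; tests cross-check against mdtraj's DSSP on helix and strand
fixtures. Rare classes (π-helix, isolated bridge) receive no special
class-imbalance handling.

## Encoder

Pre-LN Transformer blocks with an additive attention bias from the edge
embedding. The four edge feature groups are concatenated and passed
through a two-layer MLP whose output width equals the head count, so each
head reads one embedded edge dimension; the per-head bias is the mean of
the dimensions routed to that head (the generalization, mean over an even
split, covers other widths). The published description of this reduction
is truncated, so the mean reading is a documented interpretation.

Defaults: 6 stacked blocks with independent weights, 10 heads,
d_model = 320 (unstated in the source method; 32 per head), feed-forward
1024, ReLU, LayerNorm ε = 1e−5, dropout 0. "Six recycles" is read as a
×6 stack; a `shared_weights` flag provides the literal weight-recycling
reading. From the second block onward the edge embedding is additively
updated from projections of the two endpoint node states. Padding
positions are masked out of attention (−∞ scores) and excluded from the
loss mean, while the padding token remains one of the 22 softmax classes.

Training: Adam (lr 0.002, β = 0.9/0.999), batch 64, gradient clipping at
global norm 1.0 (added for small-batch stability), 400 epochs by default.
Per step, a per-example mask rate drawn Uniform(0, 1) selects which target
residues are revealed through the pre-design channel; the loss covers all
positions; validation always runs fully masked. Whether noise enters
training is a flag, default on. The whole network is float64 numpy with
hand-written reverse-mode gradients, verified against central finite
differences in the tests.

## Design

Sampling restricts the softmax to the 20 canonical amino acids.
Temperature defaults to 1.0 — the stated diversity mechanism is the noise
block, not temperature, but temperature scaling is exposed. `one-shot`
mode samples every position in a single pass; `iterative` mode (an
interpretation of the second prediction path, k = 3 rounds) feeds argmax
predictions back through the pre-design channel and samples on the final
round. Constrained positions are clamped in the channel and hard-clamped
in the output, so conservation is exact by construction. Outputs are a
pure function of (state, backbone, seed, n, temperature, mode).

## Metrics

Recovery and diversity are reported as fractions (the benchmark tables
print fractions). "Similar" in the diversity metric is undefined in the
source description; the default rule counts BLOSUM62 score > 0 as
similar, with a strict-identity mode available. Composition similarity is
likewise undefined and implemented as the total-variation complement
1 − ½Σ|p_a − q_a|. The substitution log-odds matrix follows the BLOSUM62
construction (symmetric pair counts, expected frequencies f_a² on the
diagonal and 2f_af_b off it, half-bit rounding, pseudocount 1 on empty
cells). RMSD superposition uses the Kabsch SVD solution with a reflection
guard.

## Screening

The funnel order mirrors the enzyme-design workflow: non-polar pocket rule
first, then folding ability (Rg below the native value, conserved-site
Kabsch RMSD < 1.5 Å, pLDDT > 80 — pLDDT is consumed from an external
predictor, never computed), then solubility. Burial n_i uses virtual Cβ
atoms rebuilt with ideal tetrahedral geometry for every residue including
glycine, distance-sigmoid midpoint m = 1 Å, orientation exponent b = 2,
a = 0.5, with φ_ij the angle between the CA→Cβ directions. m = 1 Å is
kept as printed even though comparable burial measures use ~9 Å midpoints,
which makes the distance term extremely sharp; it is a config parameter,
not a constant, and is not silently "fixed". The net-charge rule direction
is ambiguous in the source prose; the default requires net charge ≤ 0 and
is configurable, as are the hydrophobicity threshold and the non-polar
set of the pocket rule (the hydrophobicity set V/I/L/M/W/F plus A/G/C/P
by default). SAP is accepted as an external column and thresholded, never
computed. DCCM follows the standard normalized displacement covariance
(zero-variance atoms are an error, named); hydrogen-bond occupancy uses
donor–acceptor ≤ 3.0 Å (0.3 nm) and donor–H–acceptor ≥ 120°.

## Synthetic data

The generators exist so every pipeline stage is exercisable without
downloads. `build_backbone_from_dihedrals` grows ideal-geometry chains by
NeRF placement (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å,
angles 111.2°/116.2°/121.7°, carbonyl O trans to the next amide N).
`make_toy_dataset` alternates helical (φ = −57°, ψ = −47°) and
extended/loop segments with per-protein segment layouts and small torsion
jitter (σ = 0.08 rad) so backbones are mutually distinguishable, and draws
helix-segment letters from helix formers (A, L, E, K, M, Q, I, F) and loop
letters from turn formers (G, P, S, N). This plants a genuine
structure→sequence signal but is far simpler than real proteins: no side
chains, no tertiary packing constraints, disjoint residue pools, and
sequence identity within a segment class is random. Passing the
scaled-down training check therefore demonstrates that featurization,
attention, gradients and optimization work end to end — not that the model
reaches published large-corpus benchmark numbers, which require full-scale
training on tens of thousands of chains.

## Scaled-down study sizes

The overfitting study trains the `ModelConfig.small()` configuration
(d_model 96, 4 heads, 3 blocks, feed-forward 192, d_noise 8) on 5 proteins
of length 40 for 300 epochs. Batch size 1 is used for this 5-example set —
with fewer examples than the default batch of 64, full-batch epochs would
mean a single optimizer step per epoch, which is not how a practitioner
would fit a tiny corpus. Constrained-design checks sample 50 sequences; the
DCCM recovery check uses 500-frame ensembles of 8 atoms.

## Known limitations

* No multi-chain complexes, mmCIF, or side-chain atoms; altlocs resolve to
  the highest-occupancy conformer; chain breaks are recorded but the chain
  is featurized as a single sequence (the source method does not state its
  handling).
* The noise dimension and scale (16, unit variance) are choices; the
  source states only that a normally distributed matrix is added.
* No trained full-scale weights ship with the package; the full
  configuration trains, but reproducing published benchmarks needs the
  large structure corpus and GPU-scale compute.
* Structure prediction (pLDDT, predicted coordinates), SAP, docking and MD
  are external inputs by design: the screening stage books their outputs,
  it does not compute them.
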