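# Methods

`cdrloop` remodels the six complementarity-determining regions (CDRs) of an
antibody variable domain: given a model structure whose framework is trusted
but whose loops are not, it replaces the loop backbone coordinates with
predictions from an ensemble of E(n)-equivariant graph neural networks
(EGNNs) and attaches a per-loop confidence score derived from the ensemble's
internal disagreement.

## Problem setup and data model

A structure is two chains (heavy, light) of residues with Chothia-style
numbering labels.  Each residue is reduced to four backbone atoms in fixed
order — Cα, N, C, Cβ — with a virtual Cβ constructed for glycine from the
local N/Cα/C frame (1.52 Å from Cα along the tetrahedral direction), so every
node in the graph carries the same atom set.  The six CDR windows are
configuration, defaulting to the Chothia ranges H1 26–32, H2 52–56,
H3 95–102, L1 24–34, L2 50–56, L3 89–97 (insertion codes included).  Each
loop is carried with two anchor residues on either side; anchor coordinates
come from the input model, are treated as trusted, and are never altered by
prediction.

## Input geometry and features

EGNNs require a starting geometry.  Loop interiors get a deliberately
non-descriptive one: the n interior residues are evenly spaced at fractions
i/(n+1) along the straight segment between the inner anchor Cα atoms, with
all four atoms of a residue co-located.  The anchors keep their real 3-D
coordinates — this is load-bearing, not cosmetic: an equivariant update built
from relative vectors of a perfectly collinear point cloud can never leave
that line, so the off-line information enters exclusively through the anchor
geometry.  The test suite asserts both directions of this property.

Each atom node carries a 41-dimensional feature vector: amino-acid one-hot
(20), atom-class one-hot (4), loop one-hot (6), and an 11-wide sinusoidal
positional block.  The paper-style positional encoding uses
p = index/(span−1) over the anchored span (anchors included, so they receive
the endpoint embeddings) and stacks (2p−1, sin(πkp), cos(πkp)) for k = 1..5.
The 20+4+6+11 split is a convention of this package; only the total width is
externally fixed.  Features are a pure function of sequence and topology,
never of coordinates, hence rigid-motion invariant by construction.

By default all six loops' atoms form one fully connected graph (directed
edges both ways, no self-edges); a per-loop graph is a configuration switch
and is considerably cheaper when loops do not need joint context.

## Network

One network is four message-passing layers:

    m_ij = φ_e(h_i, h_j, log(1 + d²_ij))
    x_i ← x_i + (g / deg_i) · Σ_j (x_i − x_j)/(d_ij + 1) · φ_x(m_ij)
    h_i ← h_i + φ_h(h_i, mean_j m_ij)

with φ_e, φ_x, φ_h two-layer SiLU perceptrons (hidden width 64, message
width 32 by default; both configurable), an input embedding from the
41-dimensional features, and a fixed coordinate gain g = 10.  Three numerical
choices deserve justification:

- **log(1+d²) distance input.**  Raw squared distances span four orders of
  magnitude between bonded atoms (~1.3 Å) and cross-loop pairs (tens of Å);
  a bounded squashing such as d²/(1+d²) saturates above ~3 Å and destroys
  the geometric signal.  The logarithm keeps a useful dynamic range at every
  scale and is still rigid-motion invariant.
- **Distance-normalized update with a fixed gain.**  Dividing the relative
  vector by (d+1) makes the per-neighbour step order φ_x regardless of how
  far apart two loops sit, which prevents the update from exploding on wide
  graphs.  The gain g = 10 then lets a layer move an atom several Å while
  φ_x outputs — and therefore its weights, which weight decay pulls toward
  zero — stay order one.  Without the gain, fitting multi-Å displacements
  requires large φ_x weights that the optimizer reaches only slowly.
- **Mean message aggregation.**  On a fully connected graph a summed
  aggregate grows with node count and the feature stream diverges within
  four layers; the mean keeps magnitudes bounded.  The coordinate update is
  likewise degree-normalized.

Anchor atoms participate in message passing, but their coordinates are
re-pinned to the trusted input values between layers and at the output, so
every prediction carries the anchors exactly and stays conditioned on real
framework geometry.

Coordinates enter only through distances and relative vectors, so the
coordinate output is exactly equivariant under rotations and translations of
the input and the feature/confidence outputs are exactly invariant; the
acceptance suite verifies both to 1e-4 Å under 20 random rigid motions.

## Ensemble

Five networks are initialized from independent seeds and share no weights.
Their parameters are stored stacked along a leading member axis purely so a
single batched forward pass evaluates all members — an implementation detail
that leaves the members mathematically independent.  The final prediction is
the per-atom arithmetic mean of the five decoys; the decoy spread is the
confidence signal.

## Training

Gradients come from a minimal reverse-mode automatic-differentiation engine
over numpy arrays written for this package (broadcast arithmetic, matmul,
gather/segment-sum on edge lists, the few needed nonlinearities); its
gradients are verified against central finite differences in the test suite.
Optimizers (RAdam with variance rectification, Adam) are implemented on the
same arrays.

Two losses:

- **Per-network RMSD** — the mean over members of the in-frame RMSD between
  a member's loop-interior atoms and the truth.  No superposition is applied:
  predictions live in the frame pinned by the true anchors, so raw deviation
  is the trained quantity.
- **Bonded L1** — the mean absolute difference between predicted and true
  distances over the five backbone bonded-pair classes (Cαᵢ–Cαᵢ₊₁, Cαᵢ–Cβᵢ,
  Cαᵢ–Nᵢ, Cαᵢ–Cᵢ, Cᵢ–Nᵢ₊₁), computed **only on the member-averaged
  structure**.  This is the term that pushes the combined prediction toward
  physically plausible geometry.

Training is two-phase: phase 1 minimizes the per-network RMSD alone (RAdam,
lr 1e-3, weight decay 1e-3) until the validation loss stops improving by
more than 1e-3 for 20 epochs; phase 2 adds the bonded L1 with weight 1.0
(Adam, lr 1e-4) with early stopping on the validation loss, restoring the
best checkpoint.  Both losses are means (not sums) over atoms, pair
instances and members, so their scale is comparable across loop lengths.
Losses cover loop-interior atoms only — anchors are inputs, not targets —
with a flag to include them.  An optional target-loss stop ends a phase once
the validation loss falls below a threshold.

## Confidence and filtering

The per-loop confidence score is the mean in-frame RMSD over all C(5,2) = 10
unordered decoy pairs, restricted to that loop's interior atoms.  No
superposition is applied before pairing (decoys share the anchor frame); a
superposed variant and a mean-to-centroid variant are flags.  Filtering
keeps structures whose score is at or below a cutoff — 1.5 Å is the default
reporting cutoff for CDR-H3 — and, when reference structures are available,
reports the mean evaluation RMSD before and after.  On decoys constructed as
truth plus isotropic noise, the score ranks the noise scale with Spearman
ρ > 0.9 (verified over σ = 0.1…2.0 Å, 20 replicates).

## Evaluation convention

Reported per-loop RMSDs follow the benchmark convention: superpose the
predicted chain onto the reference chain over all its backbone atoms
(a framework-only fit is an option), then measure the Cα-N-C-Cβ RMSD over the
loop window with no re-fit on the loop.  This is deliberately distinct from
the training loss, which uses no superposition at all.

## Restrained relaxation

The bonded L1 keeps averaged predictions close to physical, but residual
bond-length distortions remain possible.  `relax_loops` minimizes an energy
over the backbone under harmonic positional restraints (spring constant k in
kcal·mol⁻¹·Å⁻², default 10 — the conventional unit for positional
restraints) so geometry is repaired without letting loops drift.  CDR atoms
are restrained at k; framework and anchor atoms at 100k, holding the
scaffold effectively rigid through restraints rather than hard constraints.
Two backends satisfy the same contract: a built-in restrained
bonded-geometry minimizer (scipy L-BFGS over the five bonded-pair classes at
stiffness 300 kcal·mol⁻¹·Å⁻² plus the restraints; always available) and an
openmm backend (AMBER14 force field, pdbfixer preparation, Langevin-based
minimization) used when that engine is importable.  If a requested engine is
missing the pipeline degrades cleanly and returns the structure unrelaxed
with a warning; the unrelaxed prediction is always retained alongside the
relaxed one.  Relaxation never changes residue identities or the backbone
atom set.

## Synthetic fixtures

The generator fabricates antibody-like structures with known ground truth so
every stage is testable without downloads.  Backbone chains are built by
forward kinematics with exact reference bond lengths (Cα–Cα 3.80, Cα–Cβ 1.52,
Cα–N 1.46, Cα–C 1.52, C–N 1.33 Å), a trans peptide bond, and φ/ψ torsions
sampled from an extended region (φ ∈ [−160°, −60°], ψ ∈ [90°, 170°]); the
Cα–C–N angle is solved numerically so the consecutive-Cα distance is exactly
3.80 Å.  A toy antibody is a 110-residue heavy and 105-residue light chain
numbered 1..N so the default CDR windows fall inside; the "reference" carries
the ideal loops and the "model" perturbs each CDR interior with isotropic
Gaussian noise whose scale σ is the RMS per-atom displacement in Å
(per-coordinate std σ/√3), emulating a homology model whose CDRs need
remodelling.  σ defaults to 1.0 Å, the scale of typical non-H3 loop errors
in homology models.  Framework sequence is poly-alanine with a glycine every
7th residue (exercising the virtual-Cβ path); loop interiors draw uniformly
from the 20 amino acids so loops are distinguishable by sequence.
`make_idealized_loop` builds a single anchored loop the same way and can be
rigidly aligned onto a given N-side anchor frame; the C-side anchors then
come from the same ideal chain (a single rigid transform cannot satisfy both
ends exactly, and for fixtures exact ideal geometry matters more than exact
end placement).

What the fixtures do **not** emulate: real side chains, non-ideal bond
geometry, chain–chain packing, correlated (non-isotropic) model errors,
sequence–structure dependence, and multi-conformation loops.  Passing tests
therefore demonstrate that the machinery is correct — equivariance, losses,
training dynamics, confidence semantics, I/O — not that the package attains
any particular accuracy on real antibodies, which would require training on
a curated structural corpus.

## Problem sizes used in tests and the acceptance script

The tiny-overfit check trains the 5-member ensemble at reduced widths
(hidden 32, message 16) on 10 single loops of 3–4 residues with random
sequences, phase 1 only, at most 500 epochs, stopping early once the
training-set RMSD falls below 0.45 Å; a majority of 3 seeds must end below
0.5 Å.  The held-out generalization run in the acceptance script trains on
the loops of 8 toy antibodies for 60 + 10 epochs with per-loop graphs and
remodels two unseen toy antibodies.  These sizes are the package's chosen
desk-scale study conditions; they demonstrate trainability and end-to-end
behaviour, not production accuracy.

## Known limitations

- No trained production weights ship with the package; predictions from a
  randomly initialized ensemble are placeholders for the pipeline contract.
- Renumbering is out of scope: inputs must already carry the expected
  numbering, and a clear error names missing labels.
- The confidence score is a ranking signal, not a calibrated probability.
- Loops longer than 20 residues are accepted with a warning; the graph grows
  quadratically with loop length.
- The built-in relaxation backend repairs bonded lengths only; it has no
  notion of sterics, angles or torsions (the openmm backend does).
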