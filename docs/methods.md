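# Methods

## Problem and model

Given the tertiary structures of a dimer's two monomers, their (paired)
multiple sequence alignment, and precomputed co-evolutionary features, the
package predicts the distribution of inter-chain residue-residue distances as
a distogram: for every residue pair, a categorical distribution over 42
half-open distance bins — [0, 2), forty 0.5 A bins covering [2, 22), and
[22, inf). Two heads are trained jointly with equal weight: one against the
minimum distance over all heavy-atom pairs of the two residues (the
definition behind the 8 A contact criterion), one against the Cb-Cb distance
(Ca substitutes for glycine). Exactly 22.0 A falls in the open top bin.

The input tensor has 186 channels in a fixed, self-described order
(distance, coupling scores, 144 attention maps, 40 tiled PSSM channels).
Distances enter raw in Angstrom: no clipping or scaling is applied to any
input channel, on the view that normalization is the network's job through
its RCIN blocks. Attention maps are passed through as ingested, without
symmetrization.

## Architecture

Input conv (3x3, 186 -> F) -> Maxout stage (conv to G x F channels, then max
over G consecutive channels) -> B residual blocks -> two 3x3 head convs with
per-cell softmax. Each residual block applies, in order: RCIN normalization,
conv, ELU, conv, squeeze-and-excitation channel gate, spatial attention gate,
then the skip addition. Choices the architecture description leaves open were
fixed as follows and are part of this package's contract:

- **RCIN fusion.** The row, column, and instance standardization branches
  (each: subtract mean, divide by sqrt(var + 1e-6), learnable per-channel
  affine) are concatenated to 3F channels and fused back to F by a 1x1
  convolution. A constant input map therefore produces the affine/fusion
  bias, with the epsilon guarding the zero-variance case.
- **Conv-layer counting.** The published size "156 convolutional layers,
  64 filters" is reproduced under an explicit counting rule: input conv +
  maxout conv + 2 per block + 2 head convs = 4 + 2B, so B = 76 by default.
  Auxiliary 1x1 fusion convs, SE bottleneck weights, and the spatial-gate
  conv are excluded from the tally. `DistogramNetwork.counted_conv_layers()`
  exposes the rule so the count is checkable rather than folklore.
- **Defaults.** Maxout groups G = 2, SE reduction 16, trunk kernels 3x3,
  spatial-gate kernel 7x7 (the usual convolutional block attention choice),
  ELU activations, dilation 1. Weight init is He-scaled normal from a seeded
  generator; builds are bit-reproducible per seed.

The network runs on a small reverse-mode autograd engine written on NumPy
(float32, batch size 1, (H, W, C) layout; convolution via im2col GEMM). All
backward passes are verified against central finite differences in the test
suite.

## Training

Only inter-chain cells contribute to the loss: the full L x L grid for a
homodimer (every cell crosses chains), the two off-diagonal L1 x L2 blocks
for a heterodimer. The loss is the mean over masked cells of -log p[true
bin], summed over the two heads with equal weight; masked-out cells are
exactly inert (their gradient is identically zero). The published two-phase
schedule is implemented as stated — Adam at 1e-3 for 30 epochs, then SGD from
1e-4 with a ten-fold reduction every 20 epochs for 50 more, batch size 1 —
and desk-scale runs truncate it by epoch count while keeping the same
per-epoch optimizer/learning-rate mapping. Variable-size dimers need no
padding at batch size 1. Training aborts with a diagnostic on a NaN loss;
checkpointing is per epoch, with model selection left to the caller.

## Inference conventions

- **Two-MSA ensembling**: element-wise mean of distogram volumes (a convex
  combination of distributions needs no renormalization).
- **Two-order averaging** (heterodimers): the AB run's top-right L1 x L2
  inter-chain block is averaged, bin-wise, with the spatial transpose of the
  BA run's top-right L2 x L1 block.
- **Contact conversion** uses the heavy-atom head: the 8 A threshold is a
  heavy-atom definition, and lands exactly on a bin edge, so contact
  probability is the clean sum of bins 0..12. For thresholds off an edge the
  straddling bin contributes its linear fraction.
- **Ranking**: descending probability, ties broken lexicographically by
  (i, j). For homodimers a contact and its mirror are one prediction, so
  (i, j)/(j, i) collapse to a single i <= j entry carrying the larger score
  by default; the flag is exposed because published evaluation conventions
  differ on this, and with deduplication the truth matrix is folded the same
  way to keep numerator and denominator consistent. All top-k list sizes use
  floor(L/k) with a minimum of 1.
- **Confidence**: the mean probability of the top floor(L/5) entries.

## Evaluation metrics

True contacts are strict: minimum heavy-atom distance < 8 A. Precision is
reported at top 5, 10, L/10, L/5, L/2, and L (L the monomer length, or the
shorter chain for heterodimers). Accuracy order is 1000 x (rank of the first
correct prediction) / (L1 + L2); dimers with no correct prediction return NaN
and are excluded from set means (their count is reported). Accuracy rate is
the percentage of dimers with a correct prediction in their top 10. AUC is
the rank-based (Mann-Whitney) area under the ROC over all inter-chain pairs,
ties counting one half.

## MSA pairing and depth

Heterodimer alignments are built by pairing two monomer MSAs. Organism tags
are read from UniProt `OX=` fields or a trailing bracketed binomial;
untagged rows never pair. Two strategies are provided — per-taxonomy-ID
matching and per-species best-identity matching — which coincide when each
species has one candidate row; both resolve multiple candidates by the
highest sequence identity to the query, ties to the earlier row. Sequence
identity is computed over query-aligned columns with gaps as mismatches
(a documented choice; conventions vary). Neff uses the community-standard
80% identity threshold: each row is down-weighted by the size of its
neighbourhood at that threshold.

Residues are indexed densely by order of appearance in the chain, so
structures whose author numbering has gaps still align with alignment
columns positionally; callers supplying MSAs are responsible for
query/structure agreement.

## The synthetic data generator

The generator emulates exactly the statistical structure the pipeline needs
and nothing more:

- **Geometry**: two idealized helices (2.3 A radius, 1.5 A rise, 100 deg per
  residue) facing each other across a ~10 A axis gap, with three pseudo-heavy
  atoms per residue (CA, CB, side-chain tip) so heavy-atom and Cb truths
  differ measurably. Helix phases and chain B's axial offset are randomized
  per seed so the interface patch lands at unpredictable residue positions —
  a model cannot shortcut by memorizing where interfaces sit. Chain B is
  mirrored so side chains face inward; the geometry is intentionally
  unphysical in detail (no sterics, left-handed mirror helix).
- **Planted signal**: the coupling-score channel and the first 8 attention
  channels carry `snr * signal + (1 - snr) * noise`, where the signal map is
  0.6 x contact indicator + 0.4 x Gaussian-smoothed indicator (contact cells
  stay strictly above non-contact cells, so snr = 1 separates the classes
  perfectly) and the noise is one shared symmetric uniform field per dimer.
  Sharing the noise across the signal-carrying channels is deliberate: with
  independent noise, channel averaging would recover the signal at any snr
  and signal strength would not modulate task difficulty. The remaining 136
  attention channels and all PSSM channels are pure noise, so the channel
  attention has a genuine selection task.
- **MSAs**: random queries mutated per position at a configurable rate, with
  organism tags cycling through a controllable number of species shared by
  both chains' alignments.

What passing the synthetic tests does *not* show: performance on real
dimers. The generator has no phylogenetic structure, no alignment errors, no
correlation between MSA depth and feature quality, and its geometry is far
simpler than protein interfaces. The synthetic results demonstrate that the
pipeline is wired correctly end to end — features carry the signal in, the
network can find and use it, the masking trains only inter-chain cells, and
the evaluation measures what it claims — not that any accuracy level
transfers to real data.

## Desk-scale study sizes

The end-to-end checks run a deliberately small configuration: 12 counted
conv layers, 16 filters; 40 training dimers of 24 residues per chain at
snr 0.8; 10 epochs of the Adam phase; 10 held-out dimers for the
precision-versus-baseline ratio (the analytic baseline for random ranking is
the mean interface density, i.e., true contacts over grid cells); and, for
the confidence study, 40 held-out dimers of 40 residues per chain over an
evenly spaced snr ladder from 0.2 to 0.9. The larger evaluation dimers
refine the top-L/5 granularity (k = 8 instead of 4) — the network is fully
convolutional, so train and test sizes need not match. The stratified ladder
is a designed sweep: every replicate covers the same signal-strength range,
which lowers the variance of the rank-correlation estimate relative to
random snr draws.

## Known limitations

- No mmCIF input, no multi-model NMR handling, no execution of the upstream
  tools (HHblits, PSI-BLAST, CCMpred, MSA transformer); their outputs are
  ingested or synthesized.
- The autograd engine is single-threaded NumPy; the full 156-layer model is
  buildable and runnable but training it at realistic scale is out of reach
  here by design.
- Altloc ties resolve to first occurrence; residues lacking both Cb and Ca
  are rejected rather than imputed.
- AccOrder set-averages exclude dimers with no correct prediction, which
  flatters methods that fail completely on some targets; the excluded count
  is reported alongside.
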