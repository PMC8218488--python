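# Methods

## Problem and approach

Lead optimization asks which part of a candidate molecule should be changed
to strengthen target binding. `castelo` answers a narrower, data-driven
version of that question from a single MD trajectory of the bound complex:
which *atom subtypes* of the ligand behave least like the stably bound whole
molecule? The pipeline:

1. **Contacts.** Every frame is featurized as a binary N×M ligand–protein
   contact matrix: entry (i, j) is 1 iff atoms i and j are within the
   contact cutoff (closed comparison). N is the number of ligand atoms, M
   the number of protein atoms in the chosen selection.
2. **Atom subtypes.** Ligand atoms are grouped by their force-field
   Lennard-Jones parameters: atom types whose dispersion energy ε and size
   parameter (Rmin/2) are mutually within a 10 % relative tolerance belong
   to one subtype. The pairwise test is extended by transitive closure
   (connected components of the compatibility graph), which guarantees a
   partition regardless of how chains of similarity run. Contact rows of a
   subtype's member atoms are merged by logical OR, which preserves the
   binary representation required by the reconstruction loss.
3. **Dynamism tensors.** Each frame t is paired with the absolute difference
   |c(t) − c(t−δ)| of its contacts against a lagged frame (XOR for binary
   matrices): 1 marks a contact that formed or broke over the lag window,
   independent of direction. The result is a 2-channel binary tensor per
   frame. Frames with t < δ compare against frame 0, keeping the series
   frame-aligned with the reference clustering (the comparison metrics
   require aligned time axes).
4. **CVAE ensemble.** Each subtype's tensor series is embedded by a
   convolutional variational autoencoder: four convolutional layers with f
   filters of kernel 1×7, stride 2 along the protein axis, no padding or
   pooling, ReLU activations; affine heads produce a d-dimensional latent
   mean and log-variance; the decoder mirrors the encoder with transposed
   convolutions (per-layer output lengths are read off the encoder's shape
   trace so the reconstruction matches the input exactly) and a sigmoid
   output. The loss is summed binary cross-entropy plus the KL divergence
   to a standard normal (unit weight), optimized with RMSProp at learning
   rate 0.005 for up to 600 epochs, stopping after 10 epochs without strict
   improvement of the training loss. Six architectures are trained per
   subtype — f ∈ {32, 64} × d ∈ {3, 5, 10} — and all downstream metrics are
   averaged over the ensemble; their spread (population standard deviation)
   is an agreement score.
5. **Clustering.** Latent means (not samples, for determinism) are clustered
   with HDBSCAN at minimum cluster size 50, other parameters default. The
   whole-molecule reference is a greedy quality-threshold clustering of
   ligand RMSD at a 2.0 Å cutoff after superposing each frame's protein
   atoms on frame 0; pre-computed assignments can be supplied instead, or an
   all-atom CVAE clustering can serve as reference.
6. **Comparison and ranking.** Both routes are reduced to per-frame
   cluster-size series (noise frames count as singletons — a singleton is
   the honest size of an unclustered frame, and a zero would silently drop
   cosine terms). Each subtype is compared with the reference by cosine
   similarity and by the mean per-frame size difference; both are centred by
   their mean over subtypes (nCosSim, nAvgDiff) and combined into a final
   rank (mean of the two per-metric ranks, ties broken by subtype id).
   Rank 1 is the most "malicious" subtype — the modification candidate.
   The interpretation is only valid when the reference clustering is
   *stable*: the largest cluster must persist for more than 50 ns (total
   membership time × frame interval, strictly greater). Otherwise a
   prominent warning is attached.
7. **Verification arithmetic.** For follow-up alchemical calculations, the
   package converts relative binding free energies into relative potency:
   CRS = exp(−(ΔΔF − ΔΔF_ref)/RT) with R = 1.987×10⁻³ kcal/(mol·K), and a
   free-energy change of a modification into a potency fold-change
   exp(−ΔΔF/RT). Uncertainty on log₁₀(CRS) propagates the two ΔΔF standard
   deviations in quadrature.

## Key parameters

| parameter | default | unit | notes |
|---|---|---|---|
| contact cutoff | 4.5 | Å | any-atom pairs, hydrogens included; closed boundary (= counts) |
| subtype tolerance | 0.10 | – | relative, vs the larger of each pair |
| δ (dynamism lag) | 500 | frames | 10 ns at 20 ps sampling; clamped at frame 0 |
| frame interval | 20 | ps | snapshot spacing of the source trajectory |
| f, d grids | {32, 64} × {3, 5, 10} | – | 6 ensemble members |
| learning rate / epochs / patience | 0.005 / 600 / 10 | – | RMSProp; early stop on training loss |
| batch size | 64 | frames | unstated upstream; chosen as a common default |
| HDBSCAN min cluster size | 50 | frames | other HDBSCAN parameters default |
| RMSD cutoff | 2.0 | Å | ligand-atom RMSD, protein-superposed |
| stability threshold | 50 | ns | largest cluster, strictly greater |
| temperature | 310 (CRS), 298.15 (fold) | K | see "Temperature" below |

## Numerical and design choices

* **Convolution feasibility.** Four valid stride-2 kernel-7 layers require a
  protein axis of at least 91 atoms (L' = ⌊(L−7)/2⌋ + 1 per layer); the
  model computes this minimum at build time and reports it in the error for
  narrower inputs.
* **Channel separation.** The kernel is one row tall with row stride 1, so
  convolutions never mix the contact and change channels; the two channels
  are stacked as image rows and every layer slides along the protein axis
  only. The whole-molecule reference model stacks contacts over change rows
  into a 2N×M image the same way.
* **Stable BCE.** Reconstruction loss is computed from logits
  (softplus(l) − x·l), never from saturated sigmoids; log-variances are
  clipped to ±15 before exponentiation.
* **Determinism.** All randomness (weight init, shuffling, reparameterization
  noise) flows from one seeded generator per model; ensemble member seeds
  are derived from a base seed and the grid position via `SeedSequence`.
  A fixed seed reproduces loss histories bit for bit at a fixed BLAS thread
  count.
* **Zero-ε atom types** compare as mutually compatible on ε (|0−0| ≤ t·0)
  and are separated by the size test alone. CHARMM tables provide Rmin/2
  rather than σ; because the similarity test is relative, using Rmin/2
  directly is equivalent to converting to σ (a constant factor rescales
  both sides).
* **QT clustering ties** (two frames with equally many neighbours) go to the
  lower frame index; this makes the greedy reference clustering
  reproducible on exact fixtures.
* **Degenerate density clustering.** HDBSCAN cannot rank zero-distance
  points, so an exactly constant latent cloud is returned as a single
  cluster; fewer frames than the minimum cluster size return all-noise.
* **Stability = total membership.** "Persists longer than 50 ns" is read as
  total membership time of the largest cluster, not the longest contiguous
  run, matching the cluster-size quantity the metrics consume.
* **Ranking combiner.** The two normalized metrics are combined by averaging
  their ranks; both per-metric ranks are reported so users can apply a
  different rule when the metrics disagree.

## Temperature

The CRS calculator defaults to 310 K, the temperature at which the built-in
sweetener free-energy table reproduces its published log(CRS) column; the
fold-improvement calculator defaults to 298.15 K, which reproduces the
published fold factors (57× and 600×) for the two verified modifications.
The two published sets are internally inconsistent by this ~12 K, so the
temperature is an explicit argument of both functions rather than a single
package constant.

## Synthetic data

Real bound-complex trajectories are large and typically proprietary, so the
test bed is synthetic. `generate_contact_system` plants ground truth in a
binary T×N×M contact series: the molecule occupies a sequence of global
binding regimes (default: a dominant mode of 60 ns and a minor mode of
40 ns at the generator's 100 ps sampling, so exactly one mode passes the
50 ns stability rule); *stable* subtypes hold one fixed contact pattern per
regime plus small Bernoulli flip noise (2 %/cell/frame), *flicker* subtypes
re-flip each cell per frame with probability 0.5 (a random-walk churn that
never settles — the planted malicious signal), and *switching* subtypes
alternate two patterns on their own schedule. Defaults are desk-scale:
T = 1000 frames, M = 128 pseudo-protein atoms, five subtypes (four stable,
one flicker) — large enough for the 4-layer encoder and a minimum cluster
size of 50, small enough for CPU minutes. `generate_toy_trajectory` writes
a 12-atom ligand / 120-atom pseudo-protein system as PDB files in one or
two alternating poses (>5 Å apart) for exercising file loading and the
RMSD reference clustering.

The planted-recovery experiment (10 seeded replicates, reduced grid
f = {32} × d = {3, 5}) uses a shortened training schedule (12 epochs,
patience 3, batch 125) and a lag of δ = 25 frames. The lag is kept below
the minimum cluster size deliberately: after a regime change, the δ frames
whose lag window straddles the change carry a dense change channel, and if
δ exceeded the minimum cluster size this transition band would register as
a spurious latent cluster; at δ < 50 it reads as noise. This mirrors the
production default's geometry (a 10 ns lag over a 50–100 ns trajectory,
i.e. lag ≪ mode dwell time).

What the generator does *not* emulate: force-field energetics, solvent,
correlated protein motion, or spatially correlated contact noise (cells
flip independently). Passing the recovery test therefore shows that the
pipeline's featurization, embedding, clustering and ranking recover a
planted churn signature under realistic dimensions — not that the method's
physical premises hold on real complexes.

## Known limitations

* HDBSCAN cannot emit the root of its cluster hierarchy, so a trajectory
  (or subtype) that occupies a *single* undifferentiated state throughout
  tends toward all-noise labels rather than one large cluster; the
  comparison metrics then undervalue its stability. Real and synthetic
  systems with at least two visited modes do not hit this.
* Cosine similarity of two near-constant size series is close to 1 by
  construction; the discriminating signal is AvgDiff and the time
  *co-variation* of sizes. Both metrics are therefore always reported.
* Contact features use plain Euclidean distances from the trajectory reader;
  no minimum-image correction is applied beyond what the reader provides.
* The 46-subtype table of the full CHARMM36+CGenFF force field is not
  shipped (those parameter files are distributed upstream); the subtyping
  operates on whatever parameter text it is given.
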