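# Methods

This note records the model, the numerical choices, what the synthetic
fixtures do and do not emulate, and the design decisions made where the
procedure was genuinely open.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Dataset construction

Raw homolog sequences pass a length filter (ungapped length in [20, 200])
and a composition filter (standard 20 amino acids only; anything else,
including 'X', drops the sequence).  Exact duplicates are removed on the
ungapped residue string, first occurrence kept — the behaviour of a 100 %
identity cd-hit pass.  On the alignment, a column is removed iff its gap
fraction is *strictly greater* than 0.98 ("over 98 %" read literally; a
49/50 column survives).  Encoding uses the fixed alphabet
`ACDEFGHIKLMNPQRSTVWY-` (gap at index 20) so argmax decoding is
reproducible across implementations.  The train/validation split is a
seeded uniform permutation with `floor(0.8·n)` training sequences; no
stratification (the grouping variable a stratified split would use is not
defined at this stage) and no test split — the end evaluation of generated
sequences is experimental, not held-out reconstruction.

## The MSA-VAE

Encoder `L → 128 → 128 → {μ: D, σ_log: D}` and decoder
`D → 128 → 128 → L` are fully connected with ReLU hidden activations and
biases everywhere; the decoder output is reshaped to (columns × 21) and
softmaxed per column.  Defaults: D = 16, KL weight 0.01, Adam with
β = (0.9, 0.999), ε = 10⁻⁸, no weight decay, learning rate 10⁻³, batch 8,
exactly 60 epochs, no early stopping.  For the published configuration
(186 columns, L = 3906) the parameter count is 1,043,298.

The objective is the weighted ELBO `0.01·KL + BCE` with KL averaged over
latent dimensions and an *elementwise binary* cross entropy averaged over
the flattened one-hot length.  Both conventions are kept deliberately,
including the per-D/per-L normalization mismatch: the 0.01 factor exists
precisely to compensate the implicit L/D (= 244) up-weighting of the KL
term, bringing it to 0.01·L/D = 2.44.  A per-position categorical cross
entropy would be the textbook choice; it is not what this pipeline trains.

Numerical choices:

* decoder probabilities are clamped to [10⁻⁷, 1 − 10⁻⁷] before the logs
  (softmax outputs can underflow); the clamp is treated as identity in the
  backward pass;
* reparameterization `z = μ + exp(σ_log/2)·ε`, `ε ~ N(0, I)`; σ_log is a
  log-variance;
* weight init mirrors the common fully-connected default,
  U(±1/√fan_in) for weights and biases;
* batch order is reshuffled each epoch from the run seed; training is
  bit-reproducible for a fixed seed on a fixed BLAS;
* a non-finite loss aborts with a diagnostic rather than continuing.

Decoding takes the per-column argmax over the 21 symbols; ties break to
the lowest alphabet index (documented, exercised by a constructed tie
profile), and gap winners are stripped from the emitted protein (generated
candidates are synthesized as genes, hence ungapped; the aligned form is
retained internally).  The ELBO-based sequence score is the mean weighted
loss over 200 stochastic encode/sample/decode passes (seeded).

Generation quality is measured as the Pearson correlation of amino-acid
frequencies between generated and natural sequences, gaps excluded from
numerator and denominator.  The pairwise variant pools, over every
sequence, the ordered symbol pairs at unordered column pairs i < j with
both residues non-gap, normalized to sum 1 — the pairing convention is not
canonical, so it is fixed here and applied identically to both sets, which
is all a correlation needs.  Latent-space structure is summarized by a
centered PCA (first two components) of the encoder means.

## Candidate narrowing

Both 60 % thresholds (wild-type exclusion, at ≥ 0.60 per the screening
recipe, and clustering) use the cd-hit identity convention — identical
aligned residues divided by the shorter sequence length — but computed
from an exact global alignment (match 1, mismatch 0, near-zero gap cost,
free end gaps) instead of cd-hit's word-filter heuristics: same
convention, deterministic and exact.  Greedy clustering visits sequences
by decreasing length (ties by id) and joins the first cluster whose
*representative* matches at ≥ threshold, mirroring cd-hit's incremental
algorithm.  Reported identity/similarity percentages come from a
Needleman–Wunsch alignment with BLOSUM62, gap open 10, gap extend 0.5
(a length-k gap costs 10 + 0.5k) and unpenalized end gaps — the defaults
of the EMBOSS Needle tool — with both percentages divided by the full
alignment length.  Blinding renames candidates `synMinEv1…K` in a seeded
random order; the bijective key is written separately from the scored
outputs.

## Function scoring

Secondary structure is assigned from Cα geometry alone with P-SEA-style
distance windows on d(i,i+2), d(i,i+3), d(i,i+4), with thresholds fixed
from ideal helix (2.3 Å radius, 1.5 Å rise, 100°/residue) and extended
strand (3.35 Å rise) geometry; chains shorter than the window are all
coil, and an externally computed H/E/C string can override per chain.  The
MinD-binding helix is located structurally: among the candidate's helices,
the one with the lowest mean inter-chain PAE to the partner's structured
residues (ties to the lower start index); an explicit residue-range
override exists for expert use.  A candidate with no helix at all is
flagged and assigned the PAE matrix maximum (worst case) for the MinD
score.

PAE is asymmetric and no direction is canonical, so inter-chain means
average *both* off-diagonal blocks.  Membrane binding averages the
hydrophobicity track over the N-terminal helix, falling back to the whole
N-terminal region (residue 1 up to the MinD-binding helix) when the
N-terminus is unstructured; an empty region is an error, not a silent 0.
Solubility is a pass-through of an external predictor value in [0, 1]
(values above 0.7 flag "likely soluble"); a built-in *synthetic proxy*
(polar/charged residue fraction) exists for fixture-driven testing only
and is labelled as such in logs — it is not equivalent to any published
predictor.  Hydrophobicity likewise comes from an external per-residue
table for publication-parity runs; the synthetic track generator is for
tests.

Min–max normalization maps each sub-score list to [0, 1]; MinD and
dimerization are then flipped (1 − x).  An all-equal list maps to 0.5
everywhere (logged prominently) so the sum stays defined.  Sub-scores are
summed with unit weights (a config hook allows re-weighting);
`function_score ∈ [0, 4]`, `improved_score = mind + membrane ∈ [0, 2]`.
Ranking sorts by descending score with ties broken by variant id, and the
top/bottom k (default 24 + 24) are labelled for experimental follow-up.
Residue indices are 0-based internally and 1-based in all user-facing
reports.

## Screening statistics

The Mann–Whitney U test is exact (full enumeration, via the exact-method
distribution) when n_x·n_y ≤ 400 and the pooled data are tie-free,
otherwise a normal approximation with tie and continuity correction; the
method used is always reported.  AUC uses the 0.5-per-tie convention and
equals U/(n₁n₀) — the suite checks this identity and cross-checks against
an independent ROC implementation.  Scorer comparisons are one-sided with
positives hypothesized to score higher, and *uncorrected* for multiple
testing by design (parity with the screening analysis; a Holm switch
exists and is flagged in output).  Missing outcome labels exclude a row;
absence of a label is never treated as a negative.  Welch's t test uses
the Welch–Satterthwaite degrees of freedom.

## Assay analysis

* **SEC**: K_av = (V_e − V_o)/(V_c − V_o) with V_o the Blue Dextran 2000
  elution and V_c = 23.5 mL for the Superdex 75 Increase 10/300 GL column;
  a least-squares line K_av vs log₁₀(mass/kDa) through the standards
  (158, 75, 44, 29, 13.7, 6.5 kDa); oligomer mass by inversion, with
  extrapolation outside [V_o, V_c] permitted.
* **ATPase**: least-squares slope of the NADH 340 nm absorbance over a
  *user-chosen* window — linear-range selection was manual in the source
  protocol and stays an explicit argument.  Conversion to µM ATP/min
  happens only when the caller supplies the extinction coefficient and
  path length; there are deliberately no defaults to fabricate units.
* **Kymographs**: the long axis is the first principal axis of the
  time-averaged intensity footprint; intensities are binned into 100
  positions (unstated upstream; fixed for reproducibility) and each frame
  is normalized by its row maximum (one concrete reading of "fluorescence
  was normalized").
* **Periods**: nonlinear least squares of A·sin(2πt/T + φ) + c, frequency
  initialized at the dominant rFFT peak, T bounded to [2·dt, duration] to
  exclude aliased fits.  "No oscillation" is raised for flat traces or
  when the peak amplitude is below 4× the median non-DC amplitude.
* **Phenotypes**: filamentous if any cell exceeds 25 µm (at-least-one
  reading of an observational criterion; a minimum-count knob exists),
  else minicell if the sub-µm fraction is strictly above 6.3 % (three
  times the 2.1 % wild-type baseline), else normal; filamentous takes
  precedence.
* **QCMD**: 5-point moving average, then smoothed minimum minus smoothed
  maximum (a negative drop).

## Synthetic fixtures

Every generator is bit-reproducible from its seed and returns its ground
truth.  The clustered MSA draws per-cluster column profiles from a flat
Dirichlet sharpened as p ∝ p^c (c = 5 by default — strongly conserved
columns, as in a curated domain family; c → ∞ collapses each cluster to
one sequence) with a 5 % per-position gap rate.  PAE fixtures are block
matrices with chosen intra/inter-chain means and zero-truncated Gaussian
noise, paired with Cα structures built from ideal helix/strand geometry
and seeded random-walk coil.  Kymograph signals are noisy sines; cell
populations are lognormal bodies (median 3.5 µm, the wild-type median)
with a uniform 0.3–0.95 µm minicell component; SEC standards are generated
on a known log-linear line.  Noise is Gaussian throughout, truncated at
zero where the quantity must be non-negative.

What passing on these fixtures shows — and does not.  The fixtures have
exactly the structure the methods assume: PAE blocks are homogeneous,
secondary structure is ideal, kymographs are single sinusoids, cluster
profiles are column-independent.  Real predicted complexes have
heterogeneous PAE, real chains have distorted geometry, real MSAs have
phylogenetic correlation between columns; recovering ground truth here
validates the *implementation* of each formula and the end-to-end
plumbing, not the biological accuracy of PAE-based interface confidence or
of the hydrophobicity proxy for membrane binding.

## Problem sizes

The standard training condition for the generation-quality check is a
synthetic clustered MSA of 500 sequences × 100 columns (3 clusters),
trained for the full 60 epochs, with 500 decoded prior samples compared
against the training split — a family roughly one order of magnitude
smaller than the thousands-of-homologs datasets this kind of model is
usually trained on, chosen as the package's standard desk-scale condition.
Period-recovery checks use 120 frames at 5 s spacing for periods between
30 and 174 s.

## Known limitations

* Structures are Cα-only; no side-chain or full-backbone handling.
* The secondary-structure assigner is a distance-window heuristic; for
  publication-grade runs an external DSSP-style assignment can be passed
  as an override.
* The solubility and hydrophobicity proxies are testing aids, clearly
  labelled; publication-parity runs require the external predictor values.
* Profile-HMM scoring is not re-implemented; externally computed
  per-sequence scores can be ingested into the comparison harness.
* The two published-data acceptance checks (wild-type alignment metrics,
  screening AUCs) run only when the externally distributed files are
  placed under `data/published/`.
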