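# Methods

## The scoring model

Zipper propensity is modelled as a regression from hexapeptide sequence to a
real-valued score in Rosetta Energy Units (REU). The reference network
(`fc120`) is:

    one-hot(6 × 20, flattened to 120)
      → fully connected 120 → 120
      → ReLU, f(x) = max(0, x)
      → fully connected 120 → 1

Each hidden node computes y = Σᵢ wᵢxᵢ + b. Training minimises the mean
squared error Σ(P − T)²/N between predicted (P) and reference (T) scores
with minibatch Adam. The network and its training loop are implemented
directly in numpy (forward and backward passes by hand); this keeps the
whole parameter state inspectable and the runs exactly reproducible from a
single integer seed, which governs weight initialisation, the corpus
shuffle/split, and epoch-level batch order.

Variant architectures are available through
`TrainingConfig.architecture_variant`:

- `fc_expanded` — same shape with a wider hidden layer (default 500 units);
- `fc_extra_layer` — a second 120-unit hidden layer;
- `conv1d` — a width-1 embedding convolution followed by five kernel-3
  convolutions over the six sequence positions and a final dense output.
  The channel width defaults to 32 so CPU training stays tractable; the
  layer structure, not the width, is the point of the variant.

On the additive synthetic target all variants reach held-out error within a
factor of two of `fc120` (tested), consistent with the view that the simple
fully connected net already saturates what the data supports.

Key training defaults: Adam with learning rate 1e-3, batch size 1024,
1000 epochs, split fractions 0.791/0.177/0.032 (train/validation/test,
floor-rounded, remainder to train). The output bias is initialised to the
training-target mean so early optimisation is spent on structure rather
than the global offset. Other weights are uniform, scaled by 1/√fan-in.
The package's own validation study (tests and `scripts/acceptance.py`) uses
150 epochs: on the additive target validation error plateaus far earlier
(within a few tens of epochs), and 150 epochs keeps the full study a
few-minute desk run.

### Zipper calls, proline, error bands

A hexapeptide is called a zipper when its score is ≤ −23.0 REU; the
threshold is inclusive. Proline-containing segments are scored but flagged
`reliable = False`: structure-based reference scores for prolines are
erratically high, so their predictions inherit that bias. By default
training *excludes* proline-containing pairs — and the exclusion is applied
to the whole corpus before splitting, because a model never trained on
proline inputs cannot be meaningfully evaluated on them — while scoring and
profiling *include* them, flagged. Error-band evaluation (fraction of
held-out predictions within ±b REU of truth) uses an inclusive boundary.

Confusion metrics follow the standard definitions: accuracy
(TP+TN)/(TP+TN+FP+FN), sensitivity TP/(TP+FN), specificity TN/(TN+FP).
Undefined ratios (an empty class) are reported as missing, never as 0.

## The score table

Hexapeptides map bijectively to integers in [0, 20⁶) by reading the
sequence as a base-20 number over the fixed alphabet order
`ACDEFGHIKLMNPQRSTVWY` (position 1 most significant). The alphabet order is
a package convention, recorded in every model and table header so encodings
are self-describing; reduced alphabets (e.g. 4 letters → 4096 entries) use
the same machinery and make exhaustive oracle checks cheap.

Tables are stored as little-endian float32 preceded by a small header
(magic bytes, version, alphabet string, model hash, length) and are
memory-mapped on load by default, so proteome profiling never eagerly reads
the 256 MB canonical table. Generation is batched (default 2¹⁶ sequences)
to bound memory. A `sequence,score` CSV export exists for interoperability
but is not canonical. Note that float32 matrix products depend on BLAS
summation order, so scores produced at different batch sizes agree to
single-precision round-off (~1e-4 REU at these magnitudes) rather than
bit-exactly; persistence round-trips, by contrast, are bit-exact.

## Profiles, Zif, pAD

A protein of length L yields windows at starts 1..L−5 (1-based, inclusive
coordinates everywhere in reports). Proteins containing any residue outside
the canonical alphabet are withheld from scoring and all derived metrics
and flagged unscoreable.

- **Zif** = zipper windows / total windows. The denominator is always the
  total window count; masking and reliability filters only shrink the
  numerator. Undefined (reported missing) for L < 6.
- **pAD** slides a 75-residue window (configurable, ≥ 6) across the
  protein; a zipper segment counts toward a window when all six of its
  residues lie inside it. The maximum count, the density count/75, and
  *every* tied best start are reported. For L < 75 the whole-protein count
  is reported with `whole_protein = True` and start position 1. The
  implementation is an O(L) running window over the call indicator; an
  exhaustive brute-force enumeration is kept in the test suite as the
  oracle and the two agree on thousands of random call vectors.
  Full containment was chosen so the count is a property of the window's
  own residues; published pAD ranges can also be read as spanning 76
  residues, so this containment rule is documented as the package's
  convention rather than asserted as the only possible one.

### Transmembrane masking

Every 19-mer whose mean Kyte–Doolittle hydropathy exceeds 1.6 marks a
putative transmembrane stretch; overlapping qualifying 19-mers merge into
maximal regions. A window sharing ≥ 1 residue with any region is masked.
Masking never changes scores or calls — it only controls which calls the
metrics count — so raw and masked views coexist on one profile. The masked
view underestimates genuine amyloid propensity of membrane proteins
(acknowledged false negatives); the raw view is always available.

## Physicochemical metrics

Molecular weight (average isotopic masses + one water), GRAVY and the
instability index delegate to Biopython's ProtParam implementation; the
Kyte–Doolittle scale is taken from the same source. The aliphatic index is
Ikai's mole-percent formula X_A + 2.9·X_V + 3.9·(X_I + X_L) (range 0–390).
Stability is classed `stable` strictly below instability 40 (the boundary
value is unstable). Residue-type composition uses the groups hydrophobic
{A,V,I,L,M}, aromatic {F,W,½Y}, positive {H,K,R}, negative {D,E}, polar
{N,Q,S,T,½Y}, special {C,G,P}, with tyrosine weighted 0.5/0.5 between
aromatic and polar so the six groups partition canonical sequences to
exactly 100%; β-branched {I,T,V} is an overlapping, reported-only group.
Net charge is the count convention (#H + #K + #R) − (#D + #E); histidine
counts +1 by group membership, not by pKa.

GRAVY is implemented as the Kyte–Doolittle *mean* (the ProtParam
convention); a raw-sum variant is exposed. The mean is the only convention
under which the 1.6 transmembrane cutoff is meaningful, which is why it is
the default even though "sum" phrasing circulates.

All standard deviations reported anywhere in the package are sample
standard deviations (ddof = 1); a single observation reports sd 0.

## Proteome analyses

`scan_proteome` keeps one row per input record — splice variants are
deliberately not collapsed — and unscoreable records keep flagged,
metric-free rows. Ranking sorts descending with ties broken by id for
reproducibility. Correlations are Pearson's r (scipy), with zero-variance
inputs reported as undefined.

Score-table aggregations (mean score per weighted residue-type count,
per-position per-residue means, interface-vs-solvent charge placement)
stream over the table in fixed chunks. Weighted type counts take
half-integer values because of the tyrosine split, so bins have 0.5
resolution. The interface analysis defaults to positions {2, 4, 6} facing
the dry interface — the position parity of the zipper interface is not
settled, so the set is configurable and the default is a convention. All
streamed aggregations are validated against exhaustive loops on reduced
alphabets to machine precision.

## Synthetic ground truth

The generator draws a 6 × 20 matrix of per-position, per-residue additive
energy contributions (Gaussian, centred per position, spread width/(4√6))
plus a base offset at the midpoint of a target band, default (−50, 0) REU —
the region where real zipper score distributions concentrate, which also
places the −23 threshold inside the bulk so classification tests are not
degenerate. A built-in 10,000-sample Monte-Carlo check enforces ≥ 80% of
score mass inside the band and rejects infeasible bands. Optional features:
a sparse pairwise-coupling profile (energy terms an additive network cannot
express, used to check that evaluation machinery detects irreducible
error) and Gaussian score noise.

Noise is keyed by hashing (seed, hexapeptide index) with splitmix64 and
converted by Box–Muller, so the noise a sequence receives is a fixed
property of the scorer and sequence, independent of sampling order — any
two pipelines that touch the same sequence see the same score. Sampling
draws distinct hexapeptides (with-replacement draws deduplicated and topped
up), shuffles with the seeded generator, and splits at floor-rounded
fractions with the remainder to train.

What the generator emulates: the score scale and bulk location, the
train/val/test proportions of the original corpus, and optional scoring
noise. What it does not emulate: real zipper energetics (no residue
chemistry — charge, aromaticity and β-branching have no systematic effect
unless encoded in the drawn weights), the multimodal high-positive score
populations of physically impossible models, sequence-composition bias of
user-submitted corpora, and proline pathology (available only as an
explicit option). Passing the parameter-recovery study therefore shows the
*pipeline* — encoding, optimisation, evaluation, tabulation, profiling — is
correct and converges; it says nothing about predictive accuracy on real
proteins, which is entirely inherited from real training data.

Because the additive truth is an affine function on the one-hot simplex and
an affine map is exactly representable under ReLU (shift all
pre-activations positive), the noiseless recovery target (held-out MSE
≤ 0.05 REU²) is achievable rather than aspirational; with noise sd σ = 0.5
the held-out MSE converges to ≈ σ² = 0.25.

## Validation study sizes

The acceptance script and the heavy tests use: 200,000 sampled pairs,
150 epochs, batch 1024 (noiseless and σ = 0.5 runs); 1,000 random call
vectors (lengths 6–500, windows 40 and 75) for the pAD oracle; the full
64,000,000-index bijection check; and exhaustive 4-letter-alphabet tables
for aggregation oracles. These sizes were chosen so the whole study is a
desk-scale run while every check remains exhaustive or statistically
comfortable.

## Known limitations

- No real training corpus ships with the package; models trained on the
  synthetic generator are demonstrations of mechanics only.
- Only the homozipper, single-backbone threading view of amyloid propensity
  is represented; heterozippers and other symmetry classes are out of scope.
- Transmembrane detection is the simple hydropathy rule, not a topology
  predictor; charge states are counting conventions, not titration models.
- The 75-residue pAD containment rule and the interface position set are
  documented conventions (see above), configurable where they matter.
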