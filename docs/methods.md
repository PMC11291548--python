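# Methods

This note documents the models and procedures implemented in `archetyper`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic studies do and do not demonstrate.

## The analysis problem

Shell matrix proteins of the Pif/BMSP family are defined operationally, not by
a single diagnostic domain: a protein belongs to the family because (i) its
VWA domain(s) are demonstrably homologous to a reference VWA (the pearl-oyster
Pif VWA in the original survey), and (ii) it falls inside a well-supported
clade of a VWA-domain phylogeny containing the reference proteins. Members are
then *described* by their domain architecture (tandem VWA count, chitin-binding
tiers, Sushi/CCP repeats), by the insert between the two conserved laminin-G
anchor peptides, and by the placement and composition of their low-complexity
regions. The package implements each of these operations as a separately
testable stage plus an orchestrating pipeline.

## Homology gate

Candidate VWA regions (subsequences delimited by domain hits, not whole
proteins) are aligned to the reference VWA by Smith–Waterman local alignment
with affine gaps on BLOSUM62, gap open 11 and extend 1 — the standard BLASTP
parameterization. Unknown residues (`X`) score 0 against everything.
Significance uses Karlin–Altschul statistics, `E = K·m·n·exp(−λS)`, with a
pass threshold of 1e-10.

Two calibrations are provided. `canonical` uses the published ungapped
BLOSUM62 constants (λ = 0.3176, K = 0.134) as documented constants — adequate
for the gate because passing scores sit hundreds of bits above threshold and
failing scores orders of magnitude below. `shuffle` fits a Gumbel by the
method of moments (λ = π/(σ√6), K from the location via μ = ln(K·m·n)/λ) to
scores against shuffled subjects, for alphabets or scoring schemes where the
canonical constants do not apply. The calibration in force is recorded on the
model object.

The alignment engine reports one optimal trace; among co-optimal traces the
engine's deterministic traversal decides. Only the score, spans and identity
feed downstream decisions, so co-optimal trace choice has no analysis effect.
Correctness of the optimum is checked against an exhaustive alignment-path
enumerator on short sequences (length ≤ 8) in the test suite.

## Chitin-binding tiers

Chitin-binding domains are classified purely by the independent e-value of
the CBM_14 hit: below 1e-5 the domain is a confident CBM_14; in [1e-5, 1) it
is a degenerate CBM_14L1; in [1, 1e4) a barely-recognizable CBM_14L2; at or
above 1e4 the hit is discarded. The windows are half-open and
lower-inclusive, so every non-negative e-value maps to exactly one label.
(The source ranges are quoted with "~", which does not state inclusivity;
lower-inclusive is this package's convention and is property-tested.)

## Architecture assembly

Hits on one protein are reconciled by a greedy rule: among overlapping hits
the smallest independent e-value wins, ties broken toward the longer span and
then the smaller start. The resulting element list is sorted and
non-overlapping by construction (checked on every output). The signal peptide
is an input annotation (external predictor or fixture truth); prediction is
out of scope. LG status is *complete* when both anchor peptides are present
and either a Laminin_G_3 hit lies between them or the inter-anchor gap is at
most `max_complete_gap` (default 250 residues — roughly the span a full LG
domain occupies between the anchors); *partial* with at least one anchor;
*absent* otherwise.

## LG anchors and inserts

The two conserved anchor peptides (32 and 59 residues) are located by local
alignment; a placement is accepted when aligned identity ≥ 0.5 over at least
0.8 of the anchor's columns (both configurable; the source states no
tolerance). The N-anchor is searched first and the C-anchor constrained
downstream of it. Because local alignment trims terminal mismatches, the
reported span is the anchor's full *footprint*: the aligned core extended
outward by the unaligned anchor stubs, clamped to the sequence. For
substitution-only divergence this restores the anchor's true occupancy, which
is what delimits the insert; with indels the footprint can be off by the
indel length. The insert is the region strictly between the two footprints
(possibly empty).

## Low-complexity regions

Complexity is windowed Shannon entropy over observed residue frequencies
(`X` excluded; an all-`X` window cannot be scored). Defaults follow the
standard SEG parameterization: window 12, trigger 2.2 bits, extension 2.5
bits, minimum segment length one window. Maximal runs of windows at or below
the extension threshold that contain at least one trigger window become
segments (first window start to last window end); overlapping or adjacent
segments merge.

This trigger/extend/merge scheme approximates SEG, which additionally refines
candidates by an optimal-subsegment probability minimization. Without any
replacement for that refinement the segmenter is permissive: measured on
i.i.d. background 200-mers, about 20% contain at least one marginal
single-window trigger. The package therefore adds a **core-window test**: a
segment is reported only if at least one of its windows reaches `k_core`
(default 1.5 bits) or lower. The separation is wide — background windows
essentially never reach 1.5 bits (0 of 2000 simulated 200-mers), while
biased tracts of 20+ residues with a dominant residue at 85% always contain
windows below 1.0 bit — so the test removes marginal triggers without
affecting genuine compositionally biased tracts. Setting `k_core=None`
restores the plain trigger/extend behavior.

Zones are anchored on the assembled architecture: zone 1 from the signal-
peptide end (or residue 1) to the first VWA; zone 2 the gaps between
consecutive VWA domains; zone 3 from the last VWA to the first CB-class
domain of any tier; zone 4 between the two LG anchor footprints. A segment
is assigned to the zone containing its midpoint (segments straddling a
boundary are not split; the source does not address them), `outside`
otherwise, and numbered 1..k by start within each (protein, zone). Zone 4 is
anchored on the conserved anchor peptides rather than on Laminin_G_3 hit
boundaries; the anchors are the observable that defines the insert in
partial-LG proteins.

## Support classes and clade extraction

Internal branches carry an (SH-aLRT, UFBoot) percentage pair, parsed from
IQ-TREE-style `alrt/ufboot` labels (order configurable; a lone number is
taken as UFBoot). A branch is *strong* when UFBoot ≥ 95 and SH-aLRT ≥ 85;
*medium* when UFBoot ≥ 75 and SH-aLRT ≥ 65; otherwise *weak*. A missing value
fails its comparison, and the root — which has no subtending branch — is
always weak. Two medium formulations are in circulation (with and without
the SH-aLRT clause); both are implemented and neither is guessed as
"intended": the default requires SH-aLRT ≥ 65, and `medium_ufboot_only`
switches to the UFBoot-only variant.

The family clade is the largest clade whose branch class is at least
`strong` and whose leaves include every reference; among equally large
candidates the one closest to the root wins; if none qualifies the
references' MRCA is returned flagged unsupported. Subfamilies are the
maximal supported (≥ medium, ≥ 2 leaves) proper sub-clades of the family,
chosen top-down so that a supported clade nested inside a chosen one is
absorbed — matching how non-nested subfamily boxes are drawn on a published
tree. Both operations are tested for exact agreement with brute-force
enumeration over all internal nodes on random trees.

## Composition clustering

Regions (inserts or LCRs) are summarized as 20-dimensional percent
composition vectors; `X` is excluded from the denominator. Clustering is
Ward's minimum-variance method on Euclidean distances of the raw percentage
vectors (no standardization by default — the analysis clusters composition
ratios directly and Ward assumes Euclidean geometry; a z-score option
exists). The implementation is the ward.D2 formulation: squared-distance
Lance–Williams update with heights reported on the Euclidean scale, verified
against direct error-sum-of-squares computation.

The number of clusters is the k in 2..k_max (default min(8, n−1)) maximizing
the mean silhouette `s(i) = (b_i − a_i)/max(a_i, b_i)`; ties go to the
smaller k. Rows in singleton clusters score 0, which also defines the
two-point/two-singleton edge case. A best silhouette below 0.25 sets a
`weak_structure` flag rather than suppressing the output. The silhouette is
implemented in-package (the degenerate conventions above are part of the
contract) and cross-checked against scikit-learn on non-degenerate inputs.

## PSSM scanner

For profile-free synthetic runs a position-specific scoring matrix is built
from a gapless seed alignment with background-proportional pseudocounts,
`score[a][j] = log2(((count + pc·bg_a)/(N + pc))/bg_a)` in bits. Windows are
scored by summed log-odds and calibrated by an empirical null: window scores
pooled from residue shuffles of the query protein, e-value = exceedance
probability × windows scanned. The empirical e-value floors near
1/`n_null`, so very small e-values are not reachable by this scanner; it is
a detection tool for planted synthetic profiles, not a replacement for
profile-HMM search, and the pipeline consumes precomputed hit tables
whenever they exist.

## Synthetic data: what it emulates, and what it does not

The generator emits protein families whose statistical structure matches
what the analysis assumes. Architecture templates mirror the canonical
subfamily layouts: a BMSP-like template with four tandem VWA domains; a
Pif-like template with confident + degenerate CB domains and an
Asp/Lys/Arg-rich insert (D ≈ 25%, K ≈ 18%, R ≈ 12% — pearl-oyster-like); a
PifN-like template with a long Ser/Asp-rich insert (S ≈ 25.5%, D ≈ 22% —
freshwater-mussel-like); and a PifCCP-like template with Sushi repeats
between VWA and CB. Insert lengths are drawn from the observed range
(138–1438 residues, narrowed per template). Planted hit e-values are sampled
log-uniformly strictly inside the intended tier window (margin 0.05–0.5
decades), so no draw lands on a boundary and tier recovery is exact by
construction. Anchor degradation is substitution-only at a configurable
identity (≥ 0.7). Background linkers use an average SwissProt-like
composition, hard-coded as a documented constant. Low-complexity tracts are
two-letter biased (dominant residue 85%), length 22–40, planted strictly
inside zone intervals. The support tree plants each subfamily as a clade
whose ancestor branch support is drawn from its class's range (strong:
UFBoot ∈ [95,100], SH-aLRT ∈ [85,100]; medium: UFBoot ∈ [75,94]; weak
below both medium cuts), joins subfamilies by weak spine branches so the
subfamilies are the maximal supported clades, and attaches outgroup leaves
outside the strongly supported family branch.

Deliberately not emulated: sequence evolution along the tree (sequences and
tree are generated independently; no substitution model, no indel process),
domain boundary uncertainty (hit spans are exact unless jitter is enabled),
compositional autocorrelation within real inserts, and real Pfam profiles.
Consequently, passing the synthetic studies demonstrates that the decision
logic — gating, tiering, clade partition, insert delimitation, zoning,
clustering — is implemented correctly and is recoverable under the stated
noise models; it does not certify recovery rates on real proteomes, where
domain callers, boundary noise and indels add error sources the generator
does not model. The published per-database counts (protein tallies, the 96
gated sequences, the 119 LCRs, etc.) depend on specific database versions
and are out of scope.

## Determinism and problem sizes

All randomness flows through seeded NumPy generators; no global state is
used. The pipeline writes no timestamps into result files, and its config
digest hashes analysis parameters only (not paths), so identical
(inputs, config, seed) reproduce outputs byte-identically.

The synthetic study sizes used by the acceptance script and test suite:
10,000 e-values for the tier partition; 200 random pairs (length ≤ 8) for
the alignment oracle; 100 random 12-leaf trees for the clade oracle; a
200-protein family (50 per subfamily) for architecture recovery; 100
proteins each for exact- and mutated-anchor insert recovery; 500 planted
and 500 background 200-mers for LCR rates; 100 seeded 6+28 matrices for
clustering recovery; and an 80-protein default fixture set for the
determinism check. These sizes give binomial standard errors comfortably
inside the documented pass bands while keeping a full run under a minute.

## Known limitations

- The homology gate's canonical e-values use ungapped constants with gapped
  alignments; absolute e-values are approximate (conservative near the
  threshold). Use shuffle calibration when absolute calibration matters.
- Anchor footprints assume substitution-only divergence; indels inside an
  anchor shift the reported insert boundary by the indel length.
- The LCR segmenter is an approximation of SEG; segment boundaries can
  differ from SEG's refined output even where detection agrees.
- Ward + silhouette inherits silhouette's bias toward balanced, spherical
  clusters; strongly nested composition structure may select a smaller k
  than visual inspection of the dendrogram would suggest.
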