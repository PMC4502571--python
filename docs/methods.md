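# Methods

## Composition model and confidence groups

Class-level composition is modelled as a (k−1)-order Markov chain over
nucleotides (default k = 4, i.e. tetranucleotide contexts), trained on
both strands with Laplace smoothing: P(b|c) = (n_{c,b} + α)/(n_c + 4α).
A sequence's score is the mean per-base natural-log likelihood over
positions with a full, N-free k-mer window; the first k−1 positions are
not scored. Unoriented contigs take the better of the forward and
reverse-complement scores per class; ORFs are scored on their coding
strand. Means rather than totals make scores comparable across lengths;
totals are recovered as mean × scored positions where a likelihood-ratio
test needs them.

Confidence groups are evaluated in order I → II → III → IV and the first
satisfied tier wins, so the assignment is a partition. Two numerical
choices deserve note. Zero e-values are floored at 10⁻²⁰⁰ before
order-of-magnitude arithmetic (group II), since log 0 is undefined. The
group III criterion — best NB likelihood "1.5× greater" than the
runner-up — is scale-ambiguous for log-likelihoods; we read it as a
likelihood ratio, i.e. total log-likelihood difference ≥ ln 1.5, the only
scale-free interpretation. Whether the original tooling used total,
per-base or rank-transformed likelihoods is not recoverable; the ratio
reading is configurable via `group3_ratio`.

## Discordance calling

Only ORFs in groups I–II are eligible (homology-backed classifications);
the contig may carry any group, which is recorded in the output for
downstream filtering. The 15 % improvement filter is computed on mean
per-base log-likelihoods as (s_orf − s_contig)/|s_contig|: relative,
sign-safe for negative values, and configurable (`nb_improvement`).
ORFs shorter than 3k nt are never called — below that there are too few
k-mer windows for composition to mean anything. Donor = ORF class,
recipient = contig class.

An alternative reading would demand that the ORF's homology-derived
class also equal its composition-best class before the 15 % test; we
apply the test to the score of the ORF's assigned class directly, which
subsumes the agreement case (group I) and still exercises the filter for
group II.

## Built-in alignment and its statistics

The local aligner is affine-gap Smith–Waterman (delegated to
Bio.Align.PairwiseAligner); a gap of length L costs
gap_open + (L−1)·gap_extend, with defaults +2/−3/−5/−2. E-values follow
Karlin–Altschul E = K·m·n·e^(−λS) with fixed constants K = 0.13,
λ = 0.32 rather than composition-adjusted ones: every comparison in the
package uses the same statistics on both sides, so the constants cancel
in threshold decisions that compare e-values against each other. One
visible consequence: with these constants a perfect protein self-match
reaches the 10⁻³⁰ MGE bar only above roughly 110 aa, which is why the
generator's ORFs default to 120–280 aa (typical bacterial gene sizes).
All-vs-all searches use an exact 6-mer candidate filter before aligning —
unrelated proteins essentially never share an exact hexamer — and read
mapping short-circuits through exact substring lookup (optimal for
error-free reads) with a 16-mer pair prefilter before any dynamic
programming.

Coverage is alignment columns / sequence length, gaps included, matching
tabular-search convention. The self-genome screen for equal-e-value
out-of-class hits reads its "60 % shared alignment" as coverage of the
query; the original text does not say which side, and the query side is
the one always available.

## Homology network, trees, and incongruence

Network edges require ≥ 70 % identity, ≥ 60 % query coverage and
e ≤ 10⁻⁵, all inclusive boundaries; duplicate qualifying hits keep the
best e-value; components with ≥ 2 members become clusters. The built-in
tree path computes Poisson-corrected distances d = −ln(1 − p) on aligned
(equal-length) proteins — p capped at 0.95 so saturated pairs stay
finite — and neighbor-joining topologies, with optional bootstrap
support from column resampling; negative NJ branch estimates are clamped
to zero. Unequal-length inputs are aligned with mafft when available;
the fidelity route for real data is the external adapter, which ingests
trees built elsewhere (e.g. under WAG likelihood). Poisson correction
slightly underestimates deep distances relative to the 20-state
generating process (≈ 0.49 recovered at a true 0.5), which is immaterial
at the 0.3 cutoff scale and is accounted for in the simulation margins.

Supported-subtree extraction walks from the root and emits maximal
clades with support ≥ 70 % and ≤ 200 leaves; leaves under no such clade
form a remainder that is rebuilt (via callback) and re-cut, the pass
recorded in the cluster's iteration counter. A remainder that cannot be
split — including a wholly unsupported tree after one rebuild — is
emitted whole with a warning; no rule for indivisible oversized clusters
exists in the source method, so emitting with a warning keeps the data
visible rather than silently dropped.

The 0.3 substitutions/site cutoff is applied to the **patristic**
distance between the focal leaf and its nearest neighbor (the method
computes patristic distances and then applies the cutoff); the
alternative single-branch reading is rejected. The comparison is strict
(< 0.3), so a neighbor at exactly 0.3 is tallied, not called.
Nearest-neighbor search is restricted to same-community plus reference
leaves — other communities' sequences are present in trees but never
serve as neighbors — and ties break lexicographically so runs are
deterministic. Community leaves take their **contig's** predicted class:
the recipient lineage is where the gene now resides, and this is what
makes a donor-clade placement incongruent. Calls are undirected
(partner class recorded); tree shape alone cannot orient a transfer.

## MGE screen and synthesis

The mobile-element filter keeps candidates with ≥ 1 hit at e ≤ 10⁻³⁰ to
an MGE sequence of a **different** class covering ≥ 60 % of both query
and subject; hits lacking a length are skipped with a warning. Mobility
genes are found by case-insensitive keyword match ("transposase",
"integrase") on product annotations — the source method names no
procedure, so the keyword list is configurable rather than HMM-based.
Directed exchange networks are built from discordance calls only;
phylogenetic calls form a separate undirected layer and never become
arrows. Edge witnesses stay itemized as (EC, ORF) pairs, so multiplicity
equals witness count by construction.

## Synthetic communities: what they emulate and what they don't

The generator is the package's study system. Class composition models
spread marginal base frequencies over a GC range of 30–70 % with a small
alternating purine skew — the realistic span across bacterial classes —
plus lineage-specific tetranucleotide jitter, all scaled by a
`divergence` knob (0 = identical models; the default 1 yields pairwise
Jensen–Shannon divergences of ≈ 0.13 bits between two classes).
Contig backgrounds are sampled from the chain; ORFs are sampled from the
same chain codon-by-codon with in-frame stops rejected, so coding
regions carry the class's full k-mer signature and always translate
cleanly. Planting regenerates an ORF from the donor chain rather than
lowering identity to any real gene: the unit under test is the
compositional/topological signal, not database content.

Protein families evolve under a 20-state Jukes–Cantor-like process on
two-clade class trees (clades 1.0 substitutions/site apart, within-clade
branches ~ Exp(0.08), families of 100–280 aa). In the integrated
community, each planted ORF's translation anchors its family — the
process is reversible, so simulating outward from the community leaf is
statistically equivalent to root-down simulation — grafted at 0.1
substitutions/site inside the donor clade; its protein also becomes an
MGE database record labelled with the recipient class (a plasmid-borne
homolog in the recipient lineage). Background ORFs anchor ungrafted
families inside their own clade. Reference-search hit tables are
emulated directly (best hit to the true source class, a ≥ 15-orders
weaker best hit elsewhere), reads are error-free uniform substrings of
both strands, and transfers land preferentially on long contigs,
mirroring the observation that long contigs are where transfers are
detectable.

What passing tests therefore show: the thresholds, orderings and
orientations of every rule behave exactly as specified, and both callers
recover planted signal of realistic strength with near-zero false calls
under clean conditions. What they do not show: robustness to chimeric
misassembly, sequencing error, homology-search noise, skewed class
abundances, or composition signals weaker than the inter-class
differences simulated — on real data the homology evidence itself is
noisy, whereas the generator's emulated hit tables always name the true
source class.

## Problem sizes and determinism

Defaults used by the test suite and the acceptance script: discordance
recovery on 50 contigs of 2–10 kb with 20 planted ORFs (two classes);
phylogenetic recovery on 100 families of 250 aa with 12 references + 2
community leaves each; read validation at 10× depth with 500-nt reads;
the end-to-end demo on 10 contigs with 4 plants. All generators and the
pipeline are bit-reproducible given a seed: iteration orders are sorted,
bootstrap and simulation randomness flow from explicit generators, and
repeated runs produce byte-identical artifacts.

## Known limitations

- The built-in e-value constants are not BLAST's; absolute e-values
  differ from real search output, and external hit tables should be used
  when real statistics matter.
- The built-in tree path is distance-based (Poisson/NJ); likelihood
  models and rate heterogeneity arrive only via the external adapter.
- Classification operates at class level only; within-class transfers
  are invisible by design.
- The phylogenetic caller requires the donor lineage (or a close
  relative) to be sampled; grafts far from any sampled clade drop out of
  the homology network as singletons and are never evaluated.
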