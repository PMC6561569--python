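# Methods

`duplidate` dates and classifies gene duplications from transcriptome-scale
data. This note describes the models and procedures it implements, the
defaults and why they were chosen, what the built-in simulator does and
does not emulate, and the numerical choices that affect results.

## Transcript and alignment filtering

Assembled transcripts are filtered on three criteria before any analysis:

* **Low complexity.** A DUST-style score: within a sliding window (default
  64 bases, step 32) count overlapping triplets and score
  `sum_t c_t(c_t-1)/2 / (k-1)`, where `c_t` is the count of triplet type
  `t` and `k` the number of triplets in the window; the sequence score is
  the maximum over windows. A homopolymer 64-mer scores 31; a window of
  distinct triplets scores 0. Transcripts scoring above 7 are removed.
  The triplet-count formulation is the standard BLAST-DUST construction;
  window step 32 makes the score deterministic and cheap.
* **Length** below 500 bases and **expression** below 1 TPM (transcripts
  per million; quantification is an input column, not computed here).
  Boundary semantics follow the rules' wording: length and TPM cutoffs
  are inclusive (>= 500, >= 1), complexity/gap/protein-length cutoffs are
  exclusive (> 7, > 40%, > 1,500).

Isoforms are merged by transitive closure over pairwise matches sharing
at least 100 bases at 97% identity (matches come from any upstream
aligner); each gene is represented by its most expressed transcript, with
ties broken by smallest id so reruns are reproducible.

Family protein alignments lose rows with more than 1,500 ungapped
residues, a CDS DUST score above 7, or more than 40% gaps; the gap rule
is evaluated on the input alignment in a single pass (not iteratively
after other removals shrink it — the alternative would make the result
order-dependent). All-gap columns are then dropped, and families with
fewer than two surviving rows are discarded.

Codon alignments are built by back-translation: each protein row's gaps
become `---` codons and residues take successive CDS codons. The CDS must
translate exactly to the row (standard genetic code, one trailing stop
tolerated); mismatches are hard errors naming gene and position.
Frameshift-tolerant alignment of transcript to protein is deliberately
out of scope: the pipeline controls both inputs.

## 4dTv divergence

For a pair of aligned coding sequences, 4dTv = (third-position
transversions) / (fourfold-degenerate sites). A site qualifies when both
codons are gap-free, unambiguous, in one of the eight fourfold-degenerate
codon families (CTN, GTN, TCN, CCN, ACN, GCN, CGN, GGN), **and share the
same first two positions** — the prefix condition guarantees every
third-position change is synonymous. The prefix requirement is standard
4dTv practice but is stricter than "both codons fourfold-degenerate";
it is the main comparability caveat against scripts that skip it.

Saturation correction: `corrected = -ln(1 - 2*d)/2` with `d` the raw
fraction. At `d >= 0.5` (the equilibrium transversion share) the
correction is undefined and the pair is flagged SATURATED; pairs with
fewer than `min_4d_sites` (default 10) qualifying sites are flagged
UNDEFINED rather than contributing noisy distances. Flagged pairs are
excluded from density fitting but retained in output tables. Natural
logarithms throughout; zero qualifying sites is reported as undefined,
never as distance 0.

## Reconciliation and duplication dating

Gene trees and the species tree are inputs (rooted, binary; polytomies
are rejected with an explicit error rather than resolved arbitrarily).
Each internal gene-tree node `v` is mapped to the species tree by the
parsimony LCA rule: `M(leaf)` is the leaf's species, `M(v)` the LCA of
the children's mappings; `v` is a duplication iff `M(v)` equals the
mapping of at least one child. Each duplication is assigned to the
species-tree branch above `M(v)` (branches are named by the sorted leaf
set of their child clade). By default an event emits all cross pairs
between its two child clades; a representative-pair selector (the pair
with most qualifying fourfold sites) is available.

A known artefact of likelihood-based duplication assignment is
reproduced by this rule: when duplicate copies only begin to diverge
after a later speciation (delayed rediploidization), the gene-tree
bifurcations sit inside the descendant lineages and the duplication is
assigned to the descendant branches, not to the branch carrying the
event. The simulator plants exactly this scenario (below).

## Synteny classification

Gene positions are gene-order ordinals (0-based) per scaffold — windows
are counted in genes, so ordinals are the faithful representation; a
helper converts tabular best-hit coordinates to ordinals by sorting.
Within a genome, a paralogue pair is labelled with strict precedence:

1. **NO_INFO** — either copy unlocatable, or fewer than two distinct
   annotated families among the 50 neighbouring genes on each side of
   either copy (the window spans all genes; only family-annotated genes
   count toward identification and sharing);
2. **CLOSE** — same scaffold within 50 genes (tandem-duplication
   signature; tested before synteny so tandem pairs inside duplicated
   blocks still report CLOSE);
3. **SOME_SYNTENY** — the two neighbourhoods (both sides pooled; set
   semantics, a family counts once) share at least 2 families;
4. **NO_SYNTENY** otherwise.

Per-side counting instead of pooled is available behind the config. The
consensus across genomes drops NO_INFO votes; unanimity wins and
disagreement yields CONFLICTING. Branch summaries report CLOSE /
SOME_SYNTENY / NO_SYNTENY percentages over informative pairs only, with
NO_INFO and CONFLICTING counted separately.

## Mixture-model dating

Corrected 4dTv values are fitted with a lognormal mixture: Gaussian EM on
`ln(4dTv)` (scikit-learn `GaussianMixture`, full covariance, variance
floor 1e-6 in log space) for each candidate component count (default
k = 1..4, the data sets here never support more), 10 restarts with a
fixed seed, minimum BIC wins. The fit is deterministic given (values,
seed). Identical values are rejected as a degenerate spike. "Modes" are
the local maxima of the mixture density on a grid (default 0.01–1.5,
step 0.005; plateaus contribute their midpoint); a single component's
mode is `exp(mu - sigma^2)`. Histograms use half-open 0.05-wide bins
over [0.2, 1.4) with explicit under/overflow counters. Plots normalize
both the histogram and the density curve.

## Enrichment

Per-term one-sided Fisher exact tests (upper hypergeometric tail) of a
foreground gene set against a background, Benjamini–Hochberg FDR
(via statsmodels), expected counts as `|fg| * annotated / |bg|`.
Each term is tested independently — no ontology-graph decorrelation
(no GO DAG is consumed); a two-sided option exists. The pipeline's
default foreground is the genes of the duplication events on the branch
with the most events.

## The simulator

The generator produces inputs in the exact formats the pipeline reads,
plus truth tables, so every stage is testable without external data.

* **Species tree**: any ultrametric Newick with branch lengths in time
  units (ages validated to be consistent across paths).
* **WGD events**: `(branch, age, retention, onset_offset)`. A family is
  assigned to at most one event (events tried in order with probability
  = retention, then a tandem SD with probability `tandem_rate` on a
  uniform random branch). One event per family keeps truth pair lists
  unambiguous. Divergence onset is `age - offset`; every species-tree
  edge crossing the onset time below the event branch receives an
  independent duplication node — offset 0 gives one duplication on the
  event branch, a large offset reproduces lineage-specific
  rediploidization and assignment leakage.
* **Sequences**: per gene, `n_sites` fourfold-degenerate codons; the
  prefix of each site is drawn once from the eight fourfold families and
  held fixed; third positions evolve under Jukes–Cantor with rate `mu`.
  This is deliberately not a full codon model: 4dTv only reads fourfold
  third positions, and JC gives closed forms —
  `E[raw] = (1 - exp(-4*mu*T/3))/2` and `E[corrected] = 2*mu*T/3` for
  total path length `T` — used as the analytical oracle. To plant an
  expected corrected 4dTv of `c`, choose onset age `t = 3c/(4*mu)`.
* **Genomes**: ancestral scaffolds (default 100 genes; short trailing
  chunks merge into the previous scaffold so no region is too small to
  carry a signal) interleave each WGD event's families with a
  proportional share of background families — rediploidization is
  treated as regional, so each event owns its own scaffolds. In species
  descending from the event branch the scaffold exists in two copies:
  retained families keep one gene on each copy (planted SOME_SYNTENY),
  background families keep a single gene on a random copy. Tandem copies
  are inserted adjacently (planted CLOSE). Degradation then removes each
  background gene with probability `gene_loss_frac` (truth-pair genes
  are kept so the evaluated pairs survive and degradation acts on their
  neighbourhoods) and swaps `shuffle_frac` of positions with a neighbour
  within 3 genes.

What the simulator does **not** emulate: assembly artefacts and chimeric
transcripts, indels and alignment error, rate variation across lineages
and sites, codon usage bias, gene conversion, chromosome-arm scale
rearrangement, and real gene-family size distributions. Passing tests
therefore demonstrate correctness of the pipeline's logic and its
behaviour under the planted generative model — not robustness to every
pathology of real transcriptome data.

## Validation experiments and problem sizes

`duplidate.validation` packages the planted-truth experiments run by the
test suite and by `scripts/acceptance.py`: 4dTv versus a naive
per-column recount (1,000 random pairs), Jukes–Cantor closed-form
recovery (200 pairs x 500 sites), reconciliation versus a scan-all-clades
oracle (500 random tree pairs, <= 10 leaves), planted-WGD branch
assignment (200 families), synteny recovery (500 evaluated pairs from
1,000 families, clean and at 30% loss + 10% shuffle), mixture selection
(50 seeds, 2,000 values each), FDR control under a null (100 replicates
x 200 terms), and the end-to-end two-event scenario (300 families x 500
sites; expected corrected 4dTv 0.75 on the basal branch and 0.4 on a
later branch). These sizes give stable statistics at interactive run
times; all randomness flows from explicit seeds.

## Known limitations

* Reconciliation assumes correct, rooted, binary input trees; there is
  no accounting for gene-tree uncertainty, losses, or transfers.
* The synteny classifier does not score collinear order, only shared
  gene content within the window.
* 4dTv is not calibrated to absolute time; modes are comparable between
  branches, not convertible to million-year ages.
* The classic per-term Fisher test inflates dependence between nested
  annotation terms relative to graph-aware methods.
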