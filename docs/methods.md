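# Methods

## Problem and model

`patentscape` treats a corpus of patent abstracts (the Derwent-style
*Novelty* and *Use* fields) as a document-similarity network. Each patent
is reduced to its M most frequent cleaned lemmas (default M = 5). Writing
v_i for the nonnegative frequency vector of patent i in the joint keyword
space of dimension d (one axis per distinct selected word), dissimilarity
is the normalized angle

    c_ij = (2/π) · arccos( v_i · v_j / (|v_i| |v_j|) ),

so c = 0 when two keyword lists coincide (and for a patent against
itself) and c = 1 when they share no word; nonnegative frequencies keep
the cosine in [0, 1], hence the angle in [0, π/2] and c in [0, 1].
Patents i ≠ j are linked when c_ij ≤ H; the diagonal A_ii = 0 always.
The resulting simple graph is analyzed through its largest connected
component (LCC), degree distribution, and Louvain modularity communities,
and the corpus is separately mined for dosage-form mentions by year.

## Text cleaning

Four ordered steps: (1) lowercase and strip punctuation, digits and
symbols (tokens are maximal `[a-z]` runs, with in-word hyphens preserved
so compounds like `beta-cyclodextrin` stay whole; tokens shorter than
`min_token_length` = 2 are dropped as symbol-stripping debris);
(2) stop-word removal against a bundled function-word list (overridable
by file); (3) lemmatization; (4) removal of generic patent-prose words
("contain", "enable", "method", ...; a small overridable seed list,
compared as lemmas).

The lemmatizer (`rule_en_v1`, recorded in run metadata) is a
deterministic dictionary-free rule scheme: irregular plurals, regular
noun plurals (-ies/-es/-s with -ss/-us/-is guards), then verb -ing/-ed
endings with consonant undoubling and a CVC heuristic for the dropped
final e. It is deliberately conservative; words matching no rule pass
through unchanged. Rule-based lemmatization occasionally under- or
over-stems rare forms — acceptable here because both members of a
comparison pass through the same scheme, and determinism is what the
downstream network needs.

## Keyword vectors

Words are ranked by frequency, with ties broken by first occurrence in
the text and then alphabetically — the minimal deterministic reading of
a frequency-and-position ranking; alternative positional weightings are
out of scope. The top M entries with raw counts form the patent's vector
(the similarity is scale-invariant, so re-normalization would change
nothing). Patents whose cleaned stream is empty cannot be normalized;
they are excluded from the space and matrix, and logged.

Numerics: the cosine argument is clamped into [−1, 1] before arccos.
Two exact shortcuts avoid rounding residue in the analytic identities:
a zero dot product returns c = 1 directly, and Cauchy–Schwarz equality
(detected in integer arithmetic, since frequencies are counts) returns
c = 0 for proportional vectors.

## Network construction and thresholding

Pairs with c = 0 — distinct patents with coinciding keyword lists — are
connected by default (they are maximally similar); a config toggle
`include_zero_similarity=False` gives the strict reading 0 < c ≤ H. The
default sweep grid is H ∈ {0.05, 0.10, …, 1.00}. Edge sets are nested in
H, so LCC size is non-decreasing and H = 1 joins every pair.

`choose_threshold` picks the grid value immediately before the largest
single jump in LCC size. On corpora with latent groups the curve grows
as within-group links accumulate and then jumps when weakly related
groups merge; the knee sits just below that merge. When the curve never
jumps, the smallest H attaining the maximum is returned. Field-specific
operating points (e.g. 0.75 for *Novelty*-like fields, 0.8 for
*Use*-like fields) remain a user choice informed by the sweep table.

## Degree distribution

Degrees k_i are adjacency row sums. The density ρ(k) is displayed on
logarithmic bins (edges at powers of 1.5, normalized by bin width).
The exponent of ρ(k) ∝ k^−γ is estimated by discrete maximum likelihood
on the truncated support [k_min, k_max] (defaults 1 and 100):
P(k) = k^−γ / Z(γ), Z(γ) = Σ k^−γ over the window, maximized by bounded
scalar search; the standard error is 1/√(n · Var_γ(log K)) from the
Fisher information. A log-binned least-squares slope over the same
window is attached as a diagnostic only — it is biased as an estimator
but matches how degree plots are usually eyeballed. Degenerate input
(no tail variation, or fewer than two populated bins) sets an
`degenerate` flag instead of silently returning a number. The sampler
used to validate the estimator draws by exact inverse CDF on the finite
support. Validation: at n = 10,000 the MLE recovers γ = 1.1 and γ = 2.5
within ±0.1, with mean bias below 0.05 over 50 replicates.

## Communities

Louvain is implemented from scratch on a weighted adjacency
representation (weights arise from the aggregation phase; the input
patent graph is binary). Phase one repeatedly sweeps nodes in a
seed-shuffled order, moving each to the neighboring community with the
largest modularity gain; gains within 1e−12 are ties, resolved toward
the lowest community label so runs are reproducible given the seed
(default 0, recorded in metadata). Phase two contracts communities to
super-nodes with self-loops and repeats. Resolution is fixed at 1.
Each pass is non-decreasing in Q; on all fixture graphs with ≤ 8 nodes
the result never exceeds (and on the two-clique fixtures equals) the
brute-force optimum over all partitions.

A community's keyword profile reports, for each word, the fraction of
the community's patents whose top-M list contains it — a document
proportion, not a token share (values like 0.66 then read directly as
"two thirds of the cluster's patents carry this keyword"); ties are
alphabetical. Profiles are drawn from the top-M vectors — the objects
that defined the network — rather than full cleaned text.

## Dosage-form trend mining

A lexicon maps each form (14 defaults: solution, tablet, powder, gel,
suspension, emulsion, ointment, suppository, patch, lozenge, chewing
gum, fiber, sheet, capsule, with synonym seeds such as hydrogel → gel)
to query terms. Terms and text pass through the same cleaning pipeline,
so matching is case- and inflection-insensitive; multi-word terms must
appear as consecutive cleaned lemmas and cannot straddle the
novelty/use field boundary. The common-word filter is bypassed during
matching so a user's common list cannot silently delete a query term.
A patent counts at most once per form. Records without a usable year
(missing or outside 1950–2030) contribute to per-form totals and a
separate missing-year tally, but not to the yearly series; both yearly
and cumulative series are emitted because either convention is common
for trend plots.

## Synthetic corpus generator

The generator is the test bed standing in for proprietary corpora. It
plants: disjoint per-topic vocabularies (pronounceable pseudo-words
verified to pass the cleaning pipeline unchanged, so generator
bookkeeping is an exact oracle for the cleaned streams); per-token
background mixing with probability μ; Zipf(1.2) weights within each
topic so top-M lists are stable and discriminative; uniform years;
per-form injection of real dosage-form words into the *Use* field; and
20% stop-word noise plus sentence casing and periods so the cleaning
stage does real work. Defaults define the reference study conditions:
300 patents, 5 topics, topic vocabulary 50, background vocabulary 100,
μ = 0.2, 80 tokens per field, years 2000–2020, form rates
tablet 0.15 / solution 0.15 / powder 0.10 / gel 0.08. Same seed, same
bytes.

What the generator does **not** emulate: real patent prose (syntax,
named entities, legalese), overlapping topic vocabularies, topic-size
imbalance, temporal drift of vocabulary, or duplicated near-identical
filings. Consequently, passing recovery tests show the pipeline is
correct and well-calibrated on clean planted structure; they do not
certify recovery rates on real corpora, where similarity distributions
are broader and communities fuzzier. One visible artifact: planted
topic blocks become near-cliques after thresholding, so degree
distributions of synthetic LCCs are nearly degenerate and the pipeline
correctly flags their power-law fits as unreliable — estimator quality
is therefore validated on direct power-law simulations instead.

## Pipeline and determinism

`run_pipeline` executes stages in order, writes one TSV artifact per
stage plus GraphML, and records config, seeds, scheme ids, package
versions and headline counts in `metadata.json`. Failures abort with a
stage-named error; earlier artifacts are retained. All stages are pure
functions of config + input, verified by byte-identical double runs.
Default problem sizes throughout the test suite (corpora of 40–300
documents, 10,000-draw estimator simulations, 8-node exhaustive
oracles) were chosen so the full validation runs in well under a minute
on one core while still exercising every code path at meaningful scale.

## Known limitations

- The rule lemmatizer has no part-of-speech context; a handful of
  English forms ("used", "dissolved") pass under- or over-stemmed.
- The shipped common-word and stop-word lists are seeds, not the
  curated lists a production patent study would converge on; community
  keyword profiles depend on them.
- `similarity_matrix` is dense O(N²) in time and memory — fine for
  corpora of a few thousand patents, not for millions.
- The knee rule assumes a visible merge jump; on corpora without group
  structure it degrades to "smallest H reaching the maximum LCC".
- Frequency ties in keyword ranking are resolved by text position; a
  corpus tokenized differently may rank tied words differently.
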