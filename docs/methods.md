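# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates. Notation: baits x, preys y; N(x, y) usable
read-pair counts; RS = recombination–selection (clone representation),
RIS = recombination–interaction–selection (interaction readout).

## Read model and mapping

A usable read pair has the structure *constant adapter + 3′-terminal ORF
fragment* on both mates: read 1 identifies the bait (or the RNA motif in
three-hybrid mode), read 2 the prey. Accordingly:

* **References.** Each library sequence is represented by the reverse
  complement of its last `window` = 100 nt, so reference position 0 is the
  ORF's 3′-terminal base and a correctly structured insert aligns at
  offset ≈ 0. Sequences shorter than the window yield shorter references
  (min(window, len) — the behaviour for sub-100 nt ORFs is our choice, as
  no other convention is defined).
* **Adapter filter.** Prefix-anchored matching with ≤ 2 substitutions and
  no indels; the adapter derives from a constant primer at the read start,
  so internal occurrences are not searched. Inserts shorter than 15 nt are
  discarded. Base qualities are parsed but unused: all filters are
  sequence-level.
* **Alignment.** Candidate references share at least one 7-mer with the
  insert; candidates are aligned locally (match +1, mismatch −3, gap open
  5, gap extend 2) in both orientations. The expectation value is the
  Karlin–Altschul estimate E = K·m·n·e^(−λS) with the standard ungapped
  constants for +1/−3 (λ = 1.374, K = 0.711), m the insert length and n
  the total reference length, applied to the gapped score. This is a
  monotone surrogate for full gapped statistics; it preserves the intended
  behaviour of the 1e−8 cut-off on the near-exact matches this read
  structure produces. One consequence is worth stating plainly: a bare
  15 nt exact match has E ≈ 1e−4…1e−7 for realistic reference sets and can
  never pass 1e−8 — the 15 nt minimum is a trimming filter, not a mapping
  guarantee. `min_exact_match_length` computes the shortest perfect match
  that passes for a given reference size (≈ 22–25 nt for 10²–10³ ORFs).
* **Hit filters.** Best hit by E-value (equivalently score); ties across
  distinct targets are discarded as ambiguous rather than randomly
  assigned (precision over sensitivity). Accepted hits must be
  forward-oriented with reference start offset ≤ 10 (closed threshold,
  0-based). In three-hybrid mode the RNA side uses exact, prefix-anchored
  matching of the insert against each motif's expected read-1 sequence
  (reverse complement of the cloning flanks plus motif), because some
  target RNAs are short; ambiguous matches (motifs sharing a 3′ segment)
  are dropped.

Every read pair is assigned exactly one fate (adapter reject, mapping
reject, usable) and tallied, so the per-stage counts partition the input.

## Scoring chain

Per replicate, in fixed order: frequencies F = N/ΣN for both conditions;
null F_Φ(x,y) = F_RS(x)·F_RS(y) from the RS marginals; mixture noise
filter on F_RIS; IS = F_RIS′/F_Φ. Replicates are then averaged and the
per-bait upper quartile subtracted (IS_FINAL, clamped at 0).

* **Noise filter.** A two-component univariate normal mixture is fitted by
  EM to the non-zero RIS frequencies; values with higher posterior under
  the lower-mean component are zeroed, the rest pass unchanged. Fitting is
  on raw frequencies by default (log-space behind a flag). EM is
  initialised deterministically — means at the 25th/75th percentiles,
  equal weights, pooled variance — with tolerance 1e−8 on the
  log-likelihood and at most 1000 iterations. Degenerate inputs (< 4
  non-zero values, no spread, coincident percentiles) and non-converged
  fits fall back to a warned pass-through: filtering on an unreliable fit
  is worse than not filtering.
* **Division by the null.** IS is the ratio F_RIS′/F_Φ — only a ratio
  gives scale-free scores with practical cut-offs near 1–3. Cells with
  zero null and zero signal score 0. Cells with signal but zero null
  (clones unseen under RS) are scored against the smallest positive null
  entry and flagged rather than dropped, so rarely sampled clones are not
  silently biased against. Structural zeros are averaged as zeros across
  replicates.
* **Q3 subtraction.** Q3 is the ⌈3n/4⌉-th ascending order statistic, no
  interpolation. Any row with at least ⌈3n/4⌉ zeros has Q3 = 0 and is
  unchanged; negative results are clamped to 0 because scores are only
  compared against positive cut-offs.

## QC and benchmarking

Auto-activators are flagged a priori when a bait's RIS/RS mapped-read
ratio exceeds 2.5× the mean ratio over baits (baits with RIS reads but no
RS reads are flagged with a warning; the mean is over defined ratios).
The flags are invariant to global depth rescaling of either condition.

Sample complexity is the fraction of ordered bait–prey cells observed
under RS; pair complexity the fraction of unordered ORF pairs (self-pairs
in the denominator, since the assay forms homodimer fusions) seen in at
least one orientation — meaningful when bait and prey libraries share an
ORF set.

Benchmarking treats every ordered non-homodimer cell as an evaluation
unit: its true label is membership of its unordered pair in the
user-supplied reference set (databases report unordered pairs), and a cell
is called positive iff score ≥ cutoff (closed, fixed for determinism).
Homodimer cells are excluded by default because the assay underdetects
homodimers for library-preparation reasons. F1 and MCC use the standard
formulas with 0 (warned) for vanishing denominators; the cut-off scan
reports the argmax of each with ties to the smallest cut-off; ROC-AUC is
the rank-based (Mann–Whitney) probability with ties counted ½. The
hypergeometric tail is the exact upper tail P(X ≥ k); the Wilcoxon
rank-sum comparison (used for abundance-by-layer contrasts) is a thin
wrapper over the standard two-sample rank test.

## Network and motifs

Edges connect unordered hetero-pairs whose best orientation scores at or
above the cut-off; detection in both orientations is kept as a confidence
annotation. Layers are plain breadth-first distances from the seed set on
the full network (computed whole-graph, not incrementally), reported up to
layer 3. The extended SxIP nine-mer X1‑X2‑[ST]‑X3‑[IL]‑P‑X4‑X5‑X6 matches
when at least one of X1…X4 is basic (R/H/K, read as "among positions X1
through X4"; an option extends the requirement to all six X positions) and
no X position is acidic (D/E); windows with non-standard letters are
skipped with a warning. Motif-carrier enrichment among direct (layer 1)
versus indirect (deeper) interactors delegates to the hypergeometric tail
with the direct+indirect node set as population. Mass-spectrometry
abundance scores (emPAI), when used, are joined from a user-supplied table
by id — they are never computed here.

## Simulator

The generator emulates the statistical structure the chain assumes:

* clone abundances are log-normal with unit median and spread
  `abundance_sigma` (default 1.0) — overrepresented clones without further
  distributional guidance;
* RS sampling weights ∝ a_x·a_y (fusion is interaction-blind); RIS weights
  ∝ a_x·a_y·(ε + s·1[planted] + α_x) with background ε = 1, so planted
  pairs are enriched and auto-activation acts multiplicatively on the
  bait's whole row (the row-wise signal the Q3 subtraction removes);
* counts are multinomial draws of `reads_per_condition` (default 200 000)
  pairs; reads are the mode's adapter plus a reference prefix with i.i.d.
  substitution errors (default 0.5%, an Illumina-like rate; indels are not
  modelled because no filter is indel-sensitive);
* replicate screens share the library and the planted sets but redraw the
  clone abundances, because replicates begin at the library-transformation
  stage; this is what replicate averaging exploits — a true pair buried in
  the noise bulk of one replicate by unlucky representation recovers in
  the others;
* the minimum simulated insert length is 25 nt so error-free reads always
  clear the 1e−8 E-value cut-off for libraries up to ~10³ ORFs, keeping
  error-free simulations exactly recoverable by the mapper (see the E-value
  note above).

The standard benchmark configuration (`default_benchmark_config`) is a
20 × 20 screen, ten planted interactions at strength 50, two
auto-activating baits at α = 30, three replicates — strong, sparse true
signal over realistic skew. Problem sizes in the tests and the acceptance
script (3×3 matrices for the closed-form equivalence, ~10³ read pairs for
FASTQ round-trips, 20 × 20 screens for recovery) are chosen so the whole
suite completes in well under a minute while still exercising every code
path at realistic parameter values.

What passing simulations do **not** show about real data: the generator
has no PCR chimeras, index hopping, fragment-size effects, homodimer
amplification bias, toxicity-induced dropout, or correlated errors; its
libraries are uniform random DNA with none of the shared domains or
paralogy that produce genuinely ambiguous mappings. Recovery results
certify the chain's logic under its own assumptions, not assay
performance.

## Known limitations

* The E-value surrogate is calibrated for near-exact matches; heavily
  gapped alignments are scored conservatively.
* The mixture filter assumes a noise-dominated score distribution; screens
  where most pairs truly interact violate its premise (the filter can be
  disabled).
* With a single replicate, low-abundance true pairs are frequently zeroed
  by the filter before the null can rescue them — replicate averaging is
  part of the method, not an optional extra.
* Pair complexity assumes a shared bait/prey ORF universe; with disjoint
  libraries only sample complexity is meaningful.
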