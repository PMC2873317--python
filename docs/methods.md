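# Methods

## Entropy model and calibration

A window of `w` residues is scored by the Shannon entropy of its
composition, `H = −Σ_a f_a log₂ f_a` (bits), where `f_a` is the
frequency of residue `a` within the window.  `H` ranges from 0 (a
homopolymer) to `log₂ min(20, w)`.  Entropy is computed over residue
*types*, not positions; a natural-log variant is available through the
`base` argument of `window_entropy`.  Every distinct character counts as
its own symbol, so non-standard residues (X, B, Z, U, `*`) participate
like any other; `skip_ambiguous=True` excludes windows containing them.

Because the entropy distribution shifts with window length — the mean
grows toward `log₂ 20` and the spread shrinks as windows lengthen — no
single threshold works across lengths.  Instead, for each `w` in the
scan range the empirical distribution of all window entropies in a
calibration corpus provides:

* `μ_w`, `σ_w` — sample mean and standard deviation (ddof = 1),
* `t_w` — the value bounding the lowest `α` tail (default `α = 0.005`).

`t_w` is the lower order statistic at 0-based index `⌊αn⌋`: the largest
*observed* value `v` such that the fraction of windows strictly below
`v` is at most `α`.  Flagging uses the strict comparison `H < t_w`, so
at most an `α` fraction of calibration windows is ever flagged and a
degenerate (all-identical) distribution flags nothing.  No interpolation
is used; on heavily tied (discrete) entropy values the flagged fraction
can fall below `α` by up to the mass of one tied value, which is the
granularity limit of an empirical quantile.  The calibration corpus
defaults to the scanned proteome itself; tables are serialisable
(TSV with a JSON metadata header) so a table built from a larger
reference corpus can be supplied instead.

The scan slides by 1 residue in both start and window length (any larger
stride would bias the empirical distribution).  It is implemented as a
compiled incremental-count kernel: as the window advances one residue
enters and one leaves, and the running sum `Σ_a c_a log₂ c_a` is updated
in O(1), giving amortised O(L) work per window length.  The running sum
is re-initialised at every protein boundary, which bounds accumulated
floating-point drift to ~10⁻¹³ bits; streamed values agree with direct
per-window recomputation to better than 10⁻⁹ bits (tested).

## Region selection

Every window with `H < t_w` becomes a candidate region carrying
`Z = (H − μ_w)/σ_w`.  Z standardises across window lengths so candidates
of different `w` are comparable; lower entropy relative to its length
class means a more negative Z.  Overlap resolution is greedy: repeatedly
retain the candidate with the most extreme (most negative) Z and discard
everything sharing at least one residue with it.  Ties break toward the
longer region, then the smaller start, making resolution deterministic;
the greedy solution provably coincides with lexicographic minimisation
over all maximal disjoint candidate subsets (tested against exhaustive
enumeration).  A `literal_z` flag implements the alternative reading in
which the most *positive* Z wins.  Downstream positional analyses use
only proteins with exactly one resolved region; resolution is applied
before that filter.

Coordinates are 1-based inclusive internally and 0-based half-open in
exports.  Positional metrics: `centre_norm = ((start + end)/2)/L` and
`folded = min(x, 1−x)`.  Classes use residue margins outside the region
(N-margin `start − 1`, C-margin `L − end`): *terminal* if either margin
is ≤ 25 aa, *central* if both are ≥ 50 aa (the conjunctive reading),
*intermediate* otherwise.

## Positional null and test

The null asks where a region of length `w` would sit if placed uniformly
at random in its protein of length `L`: starts are uniform on
`{1, …, L−w+1}` and only lengths matter, so re-insertion is simulated
arithmetically.  Each observed LCR contributes exactly `n_reps = 1000`
replicates, weighting LCRs equally in the pooled null.  The pooled null
is approximately flat in the folded interior and decays toward the
extremity, because a region of appreciable length cannot centre itself
arbitrarily close to an end.  Observed and null positions are folded
identically and compared with a two-sample asymptotic
Kolmogorov–Smirnov test (two-sample because the null is empirical and
length-composition-dependent; an unfolded variant is available).  At
least three observed positions are required.

## Network analyses

Edge lists are symmetrised, deduplicated and stripped of self-loops; an
optional whitelist filter on the interaction-type column (default label
`physical`) removes genetic interactions.  Proteins absent from a
network are excluded from that network's comparisons rather than
assigned degree 0.  Degree comparisons use the Mann–Whitney U test
(two-sided by default; exact null when both groups have ≤ 50 members and
no ties, tie-corrected normal approximation otherwise).  Length–degree
coupling is ordinary least squares of degree on detected LCR length with
a two-sided slope p-value.  Node-level LCR enrichment is
`(Observed − Expected)/Expected`, with Expected the node count times the
proteome-wide LCR fraction.  The pipeline runs identical analyses over
every supplied network and reports them side by side.

## Enrichment analyses

One-sided over-representation p-values are hypergeometric upper tails
`P(X ≥ k)` (equivalent to the one-sided Fisher exact test).  q-values
are Benjamini–Hochberg, computed within each ontology branch (P, F, C)
by default — a pooled correction is available via `per_branch=False` —
and the default report threshold is `q < 0.1`.  No GO-DAG ancestor
propagation is performed; annotations are taken as given.  GAF 2.x rows
with a `NOT` qualifier are dropped and duplicate gene–term pairs
collapse.

## Synthetic data: what is emulated, and what is not

`generate_bundle` plants three couplings on top of an i.i.d. background
proteome (uniform residue frequencies by default; a yeast-like preset is
included):

* **Composition**: each planted LCR is a contiguous segment drawn from a
  biased composition with 1–3 dominant residues sharing 90% of the
  probability mass — entropies of roughly 0.9–2.3 bits against a ~4.2-bit
  background.
* **Position**: with probability 0.7 the segment is placed within 25 aa
  of a uniformly chosen extremity, otherwise uniformly.
* **Connectivity**: node expected degrees are
  `4 + 0.05·(terminal LCR length)` interactions (central and
  intermediate regions get no boost), realised by Chung–Lu-style
  independent edge draws `p_ij = w_i w_j / Σw`.  This is simple,
  seedable and adequate for rank-based tests; exact degree sequences are
  not reproduced.  A 5% admixture of rows labelled `genetic` exercises
  the physical-interaction filter.
* **Annotations**: 20 terms per branch at a 5% base rate; one planted
  term per positional subset annotates its target subset at odds 8.

Default sizes are 1700 proteins of 250–700 aa with planted LCRs of
20–80 aa in 20% of proteins.  The LCR fraction is deliberately set so
that planted windows make up slightly less than the calibration tail
mass's share of all scan windows: the number of detectable regions is
capped by `α × (total windows)/(windows per region)`, and keeping the
planted mass just under that budget mirrors real proteomes, where the
0.5% tail captures the genuine low-complexity tail of the distribution.
Under these conditions detection recovers ~70% of planted regions with
essentially no false-positive proteins, leaving ~185 terminal and ~50
central single-LCR proteins per bundle — enough for every planted
contrast to be recovered in ≥ 85% of seeds.

The generator does **not** emulate: repeat periodicity or slippage-style
evolution inside LCRs, realistic interactome topology beyond first-order
degree structure (no clustering, no hubs-of-hubs), correlated GO terms
or DAG structure, or inter-protein homology.  Passing recovery tests
therefore demonstrates that the pipeline measures what it claims on data
with known structure — not that real proteomes satisfy the generator's
independence assumptions.

## Numerical and design choices

* Quantile estimator: lower order statistic, never interpolated, so
  `t_w` is always an observed entropy; strict `<` at the threshold.
* Window lengths with no windows in the corpus are marked uncalibrated
  and skipped at detection with a warning; `σ_w = 0` makes the Z-score
  undefined and that length is likewise skipped.
* The Mann–Whitney sidedness default is two-sided; one-sided
  alternatives are a parameter.
* Identifier mapping between sequence and network namespaces is the
  caller's responsibility; a two-column synonym map is supported.
* Analysis runs in this repository (tests, acceptance script) scan
  windows of 16–80 aa, matching the planted LCR length law; the 16–300
  default applies to real proteomes.
* All randomness flows through `numpy.random.default_rng` seeded from
  the configuration; identical config + seed gives byte-identical
  bundles and identical reports.

## Known limitations

* The folded KS test treats LCR positions as independent across
  proteins; paralogous families in real data violate this.
* With per-proteome calibration, the flagged fraction is `α` *by
  construction*, so the detected-LCR count scales with proteome size;
  cross-proteome comparisons should share a single calibration table.
* On heavily tied entropy distributions (short windows, small
  alphabets) the realised tail mass can undershoot `α` by one tied
  value's mass.
* The re-insertion null conditions on the detected region length, not
  on composition; positional tests conditioned on composition are out
  of scope.
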