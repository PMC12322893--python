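# Methods

`chromlink` validates hypotheses of lncRNA-mediated epigenetic regulation by
confronting two kinds of evidence: *peaks* — genomic regions of a histone
modification whose signal correlates (positively, "+", or negatively, "−")
with a lncRNA's expression across cell types — and *contacts* — loci where
that lncRNA was experimentally captured on chromatin. A peak that a contact
of the same lncRNA falls on (or near) is far more credible as a direct
regulatory site. The pipeline has four stages: reconcile the gene
annotations underlying the two resources, decide per peak whether a contact
supports it, test whether support is skewed by correlation sign, and emit
navigation URLs between the two web resources.

## Coordinate conventions

All in-memory coordinates are 0-based half-open (BED convention). Display
strings — browser-style `chr13:21045571-21046978` — are 1-based inclusive;
`parse_locus`/`format_locus` are an exact inverse pair and are the only
place conversion happens. BED-like TSV input is taken as-is; GTF-lite input
is converted on read. Overlap always means ≥ 1 shared base in half-open
arithmetic: adjacency (`end == start`) is not overlap. Strand is read and
preserved but ignored by all overlap logic, which mirrors plain coordinate
intersection.

## Gene-annotation reconciliation

Two annotation versions of "the same" genes disagree in names, identifier
versions, and coordinates. For every pair of genes from annotations A and B
that share ≥ 1 bp on the same chromosome we compute three similarity
metrics:

* **name**: case-sensitive equality of `gene_name` (no alias dictionaries —
  nothing suggests fuzzy matching helps more than it hurts here);
* **id**: equality of `gene_id` after stripping the version suffix (the
  text after the last `.`); version-insensitive comparison is the only way
  the metric is informative across releases, and can be disabled;
* **Jaccard index** J = |A∩B| / |A∪B| of the two intervals.

Pairs are grouped by their metric triple (name, id, J > threshold); the
group label is the canonical index `4·name + 2·id + 1·(J>t)`. Which
numbered group is which in the upstream resources' own figures is not
documented, so this indexing is a reconstruction — the *census* (count per
occupied triple) is what carries information.

Resolution into a per-A-gene correspondence is two-stage, with
J > 0.99 as the primary criterion:

1. An A gene with exactly one pair above the Jaccard threshold takes it
   (`method="jaccard"`). With two or more passing pairs the gene is
   recorded as ambiguous and tie-broken deterministically — larger Jaccard,
   then lexicographically smallest B gene ID. The sources do not say how
   multi-hits were resolved; a deterministic, fully reported rule is the
   reproducible choice.
2. Remaining A genes with exactly one name-matching pair take it
   (`method="name_fallback"`); everything else is reported unmatched.

The output is a function on A genes (asserted on every run). B-side
uniqueness is *not* enforced — two A genes may legitimately map to one
B gene across annotation merges — but shared B genes are flagged
(`b_shared`) and a warning is emitted.

## Peak confirmation (co-localization)

A peak is **confirmed** at extension window *w* iff at least one contact of
the *same lncRNA*, on the same chromosome, overlaps it by ≥ 1 base after
the contact interval is extended by ±*w*. Extension is applied to contacts
(experimental contact coordinates understate the true interaction
footprint); extending peaks instead gives identical verdicts — the
equivalence `confirmed(w) ⇔ overlap or gap ≤ w−1` makes both sides of the
symmetry obvious, and the test suite asserts both identities on random
fixtures. The left end clamps at 0; no right clamp is applied unless
chromosome sizes are known.

Implementation: contacts are indexed per (lncRNA, chromosome) by sorted
start with a running prefix-maximum of ends, so each peak query is one
binary search — O((n+m) log m) overall, order-independent, checked against
an O(n·m) all-pairs oracle in the tests.

The sweep reports, per lncRNA and window in {0, 1, 5, 10, 25, 50} kb, the
confirmed-peak proportion (peaks pooled over all marks — whether the
upstream analysis pooled or split by mark is unstated; pooling is the
default here and the per-mark view is available through the enrichment
stage). Proportions are non-decreasing in *w* by construction. An
lncRNA-level summary counts lncRNAs with ≥ 1 contact anywhere and, of
those, the fraction with ≥ 1 confirmed peak.

## Sign-stratified enrichment

For one lncRNA × mark at window *w* (default 25 kb) the 2×2 table is

|          | confirmed | unconfirmed |
|----------|-----------|-------------|
| "+" peaks | a         | b           |
| "−" peaks | c         | d           |

With all margins fixed, a follows the central hypergeometric law;
`fisher_one_sided` returns the exact tails P(A ≥ a) (right: "+" peaks
better supported) and P(A ≤ a) (left: "−" better supported) via
`scipy.stats.hypergeom` — exact, no normal approximation. A table with an
empty sign row is degenerate and returns p = 1. The suite checks both
tails against integer enumeration of the support (≤ 1e-12 over all 246,016
tables with sign margins ≤ 30) and the complementarity identity
P(A≥a) + P(A≤a) − P(A=a) = 1.

The scan gates on support before testing: by default an lncRNA enters when
its best mark's overall confirmed proportion exceeds 0.4, and then all its
marks are tested (`gate="lncrna"`); per-pair gating is a switch, since the
gating sentence being reproduced is ambiguous. Verdicts use raw p < 1e-3 —
deliberately reproducing the procedure under study, which applies no
multiple-testing correction; Benjamini–Hochberg-adjusted columns
(`q_right`, `q_left`) are emitted alongside so users can do better. The
binary lncRNA × mark heat matrices (one per direction) encode
verdict ∧ support-filter, mirroring the black/white summary figure.

## Navigation URLs

`build_rnachrom_url` renders the locus-mode query with fixed parameter
order (locus, name, rnaID, organism), display-form locus (start clamped at
1 after extension), and `+` for spaces in the organism — byte-matching the
published example rather than percent-encoding. The extension menu is
{1, 5, 10, 25, 50, 100} kb. Only the locus mode's schema is published; the
all-contacts and all-RNAs-at-locus modes reuse the same path and parameter
vocabulary with the irrelevant parameters omitted, and are documented as a
reconstruction. `parse_rnachrom_url` inverts the builder (round-trip
tested), with any extension already folded into the parsed locus.

## Synthetic benchmark

The generator provides the ground truth the real databases cannot.

**Annotation side.** `n_genes` (default 200) genes with log-uniform lengths
1–100 kb on non-overlapping slots (guaranteeing well-defined Jaccard
truth), round-robin over chromosomes. Annotation B renames a fraction of
gene names (default 0.1), bumps ID versions (default 0.2), and jitters each
endpoint by a *bounded* uniform offset of at most
`coord_jitter + coord_jitter_rel·length` bases. The bound matters: with
half-width b, the worst-case Jaccard of a true pair is (L−2b)/(L+2b), so
b ≤ 0.002·L keeps every pair above the 0.99 threshold and full recovery is
a theorem, not a tail event. If the configured jitter pushes > 1% of true
pairs below the threshold, the generator warns.

**Peak/contact side.** Each of `n_lncrnas` (30) × 10 marks gets
`peaks_per_pair` (60) peaks, half "+" (exact split, shuffled), 0.5–2 kb
long, uniform over a 10 × 100 Mb genome. Each pair is independently
plus-enriched (p = 0.2), minus-enriched (0.2), or null. A contact
(100 bp — short, ligation-fragment-like; no contact-length model exists
upstream) is planted uniformly within ±`window_truth` (25 kb) of a peak
with probability 0.8/0.2 by sign for plus-enriched pairs (mirrored for
minus), or 0.5 for null pairs — sign-independent, the null of the Fisher
test. Planted contacts are guaranteed to confirm their peak at
`window_truth`. 500 background contacts fall uniformly with random lncRNA
attribution. The genome size is deliberately sparse (≈ real-genome contact
density): on a toy-sized genome, contacts planted for one pair incidentally
confirm peaks of the lncRNA's other pairs and dilute the planted sign
contrast, so the configured probabilities would no longer be the effective
ones.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: chromatin-contact distance decay and
domain structure, expression-driven detection bias of all-to-all assays
(most lncRNAs being sparsely covered), correlated peaks (real peaks of one
lncRNA cluster in loci and across marks), overlapping genes and
transcript-level ambiguity in real annotations, and assembly differences
requiring liftover. Results on real databases depend on those features;
the benchmark validates the algorithms, not the biology.

## Numerical choices and degenerate inputs

* Fisher p-values clipped to [0, 1] against rounding; degenerate tables
  return 1.0 rather than raising.
* Undefined proportions (lncRNA with no peaks, summary with no
  contact-bearing lncRNA) are `None`, never NaN-silently-propagated.
* Tie-break in matching: (−Jaccard, B gene ID) — total order, so output is
  independent of input order; the enrichment scan sorts by
  (lncrna_id, mark) for the same reason.
* Determinism: every synthetic draw flows from one
  `numpy.random.default_rng(seed)` per generator call; same config ⇒
  byte-identical outputs.

## Problem sizes

Default validation runs use 200 genes, 30 lncRNAs × 10 marks × 60 peaks
(18,000 peaks, ≈ 9,500 contacts) for power, 2,000 pairs × 20 peaks for null
calibration, 100 four-lncRNA fixtures for monotonicity, and the full
246,016-table enumeration for Fisher exactness — sizes at which every
stage's behaviour is already asymptotic while the whole suite runs in
about a minute of CPU.

## Known limitations

* The six-group numbering and the name-fallback uniqueness requirement are
  reconstructions of under-specified upstream choices (documented above).
* No liftover: annotations must share a genome build.
* No per-peak co-localization significance (Genometricorr/StereoGene/
  regioneR-style tests are out of scope); the Fisher test compares signs
  *within* an lncRNA × mark pair, it does not test co-localization itself.
* Raw-p verdicts reproduce the upstream procedure; for de-novo analyses use
  the BH columns.
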