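# chromlink

Tools for cross-validating two views of lncRNA biology: databases of
**histone-modification peaks** whose signal correlates with a lncRNA's
expression ("+"/"−" peaks, suggesting the lncRNA promotes or removes the
mark), and databases of **RNA–chromatin contacts** locating the lncRNA on
the genome. A correlated peak that the lncRNA physically visits is a far
stronger regulatory hypothesis than either observation alone. `chromlink`
is for computational biologists who want that integration as a scriptable,
tested pipeline rather than a pair of web sites.

Four stages, each usable on its own:

1. **Gene matching** — reconcile the two resources' annotation versions
   into a one-to-one gene correspondence. Per coordinate-overlapping gene
   pair, three metrics: gene-name equality, version-stripped gene-ID
   equality, and the interval Jaccard index J = |A∩B|/|A∪B|; J > 0.99 is
   the primary criterion, unique name equality the fallback.
2. **Co-localization** — a peak is *confirmed* at window *w* if ≥ 1 contact
   of the same lncRNA overlaps it (≥ 1 bp) after extending contacts by
   ±*w* (menu: 0, 1, 5, 10, 25, 50 kb); per-lncRNA confirmed proportions
   are reported across the sweep.
3. **Enrichment** — per lncRNA × mark, the 2×2 table of sign × confirmation
   at *w* = 25 kb. With margins fixed, the confirmed "+" count is
   hypergeometric; right-/left-tailed exact tests ask whether "+" (resp.
   "−") peaks are better supported by contacts, after a 40% support filter,
   with verdicts at p < 10⁻³ (Benjamini–Hochberg columns included).
4. **Linkage** — the cross-database navigation URLs for any
   lncRNA–peak–gene triad, byte-compatible with the contact database's
   query schema.

A synthetic-data generator (`chromlink.synthetic`) produces annotation
pairs, signed peaks, and contacts with *planted* ground truth —
correspondences, enrichment directions, confirmation probabilities — so
every stage is validated end to end without downloading anything. See
`docs/methods.md` for the model and its assumptions.

## Worked example

Generate a benchmark, reconcile its annotations, and scan for enrichment:

```sh
$ chromlink simulate --seed 11 --out-dir sim/
wrote 200 genes x2, 18000 peaks, 9585 contacts, 122 enriched pairs to sim

$ chromlink match --genes-a sim/genes_a.bed --genes-b sim/genes_b.bed \
    --out corr.tsv --report groups.tsv
matched 200 of 200 A genes (200 jaccard, 0 name fallback); 0 unmatched, 0 ambiguous

$ chromlink enrich --peaks sim/peaks.tsv --contacts sim/contacts.tsv --out enrich.tsv
300 lncRNA x mark pairs tested: 54 plus-enriched, 62 minus-enriched (alpha=0.001)
```

`match` recovered the full planted gene correspondence via the Jaccard
criterion alone (names never needed). `enrich` tested all 300
lncRNA × mark pairs passing the support filter and flagged 116 of the 122
planted enriched pairs in the correct direction, none in the wrong one; a
typical flagged row of `enrich.tsv`:

```text
lncrna_id  mark     n_plus_confirmed  n_plus_unconfirmed  n_minus_confirmed  n_minus_unconfirmed  p_right      verdict
LNC0000    H3K27ac  26                4                   9                  21                   8.0e-06      plus_enriched
```

26/30 "+" peaks but only 9/30 "−" peaks of `LNC0000`'s H3K27ac pair are
confirmed by its contacts — the right-tailed exact test puts that at
p ≈ 8×10⁻⁶, so the lncRNA is called a likely *establisher* of H3K27ac.

The same works from Python:

```python
from chromlink import SyntheticConfig, generate_peaks_and_contacts, enrichment_scan

peaks, contacts, truth = generate_peaks_and_contacts(SyntheticConfig(seed=11))
results = enrichment_scan(peaks, contacts, w=25_000)
```

And the navigation URL for a triad:

```sh
$ chromlink link --name XIST --rna-id 227896 --locus chrX:23456-24253566 --extend 25000
https://rnachrom2.bioinf.fbb.msu.ru/basic_graphical_summary_dna_filter?locus=chrX:1-24278566&name=XIST&rnaID=227896&organism=Homo+sapiens
```

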