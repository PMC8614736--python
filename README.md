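# barcodegap

How much does an **incomplete DNA-barcode reference library** distort the
ecological assessment of transitional waters (lagoons, estuaries)?

Benthic macroinvertebrates are the workhorse biological quality element of
the EU Water Framework Directive. Replacing morphological identification
with DNA-based identification is only as good as the reference libraries
(BOLD, GenBank): a species without a barcode record is invisible to the
molecular survey. `barcodegap` simulates that gap — it restricts a species
checklist to its *reduced database* (species with ≥1 barcode record),
recomputes the standard descriptors and indices under both databases, and
quantifies how often the five-class ecological quality status (EQS) flips.

It also ships the sequence-side toolkit such a study needs: per-species
consensus sequences, Kimura 2-parameter distances, neighbor-joining tree
construction, maximum-likelihood species delimitation under the Poisson
Tree Processes model, and IUPAC-aware degenerate-primer matching — plus
synthetic-data generators so the whole pipeline is testable offline.

## The quantities computed

For each sample (site × season) under each database:

- **S** — species richness, the count of taxa with positive abundance.
- **H** — Shannon diversity, `H = −Σ pᵢ log₂ pᵢ` (log base configurable and
  recorded).
- **AMBI** — the abundance-weighted biotic coefficient over the five
  ecological groups (I sensitive … V first-order opportunists):
  `AMBI = 0·f_I + 1.5·f_II + 3·f_III + 4.5·f_IV + 6·f_V`,
  with fractions renormalized over assigned individuals and a ≤20%
  not-assigned validity rule. Azoic samples take the sentinel value 7.
- **M-AMBI** — factor analysis (PCA of the correlation matrix) of
  (AMBI, H, S) for all samples plus two reference rows; each sample is
  scored by the scalar projection of its displacement from the *bad*
  reference onto the bad→high axis, clamped to [0, 1], then classified
  High/Good/Moderate/Poor/Bad at configurable boundaries
  (default 0.77 / 0.53 / 0.39 / 0.20, boundary values belong upward).

Divergence between databases is counted on the ordinal class scale
(Bad=0 … High=4); correlations are Pearson r per season.

On the sequence side, the K2P distance is
`K = −½·ln((1−2P−Q)·√(1−2Q))` (P transitions, Q transversions, gap and
ambiguity sites excluded pairwise), trees come from Saitou–Nei neighbor
joining, and delimitation fits the two-rate PTP model (exponential branch
lengths, speciation vs within-species rate) by profile-likelihood search,
compared against a one-rate null by AIC.

## Worked example

The packaged quality-class grid of 15 Apulian transitional-water sampling
sites (fall/spring, morphological vs barcode-reduced database):

```python
from barcodegap import class_divergence, load_published_eqs_grid

summary = class_divergence(load_published_eqs_grid())
print(summary.n_comparisons, summary.n_divergent,
      summary.percent_divergent_rounded, summary.n_reduced_better)
```

prints `30 8 27 1`: of 30 paired site-season comparisons, 8 cells change
quality class under the reduced database (26.7%, displayed 27%), and in
exactly one of them (site 9, fall: Poor→Moderate) the reduced database
reports a *better* status than the full survey. Run
`python examples/03_eqs_divergence.py` for the cell-by-cell table, and see
`examples/` for the other capabilities:

```text
01_barcode_coverage.py      coverage statistics of a checklist
02_indices_and_mambi.py     S/H/AMBI/M-AMBI under both databases
03_eqs_divergence.py        the worked example above
04_species_delimitation.py  K2P → NJ → ML-PTP recovery vs simulation truth
05_primer_matching.py       Folmer/degenerate primer scans
```

`examples/04_species_delimitation.py` (seed 1) simulates 10 species × 3
accessions of 600 bp at a 20:1 rate ratio and prints
`species separated: 10/10 (100%)` — the delimitation recovers every
simulated species boundary from the sequences alone.

A thin CLI mirrors the library:
`barcodegap simulate|validate|reduce|indices|run|compare|delimit|primers`.

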