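# crisprcoev

Analysis toolkit for longitudinal phage–bacterium CRISPR coevolution:
given dated bacterial CRISPR repeat-spacer arrays, dated phage genomes
with ORF annotations, and an all-against-all infection matrix, it
reconstructs the molecular arms race between a bacterial host population
and its phages over years of sampling. It was built around the kind of
dataset produced by long-term environmental sampling of *Flavobacterium
columnare* and its dsDNA phages (two CRISPR loci — a DNA-targeting
type II-C locus "C1" and an RNA-targeting type VI-B locus "C2"), but the
machinery is generic.

## What it computes

- **Spacer catalog** (`crisprcoev.catalog`) — extracts spacers from
  repeat-spacer array sequences (Hamming-tolerant repeat detection,
  degenerate segments skipped), pools them across isolates into a global
  chronological catalog (labels `C1s1`, `C1s2`, … numbered from the
  conserved end of the oldest isolate; younger isolates only append new
  labels), and partitions labels into the conserved backbone (carried by
  every isolate) and the variable end.
- **Protospacer map** (`crisprcoev.mapping`) — finds spacer matches in
  phage genomes on both strands within a Hamming budget (default 0:
  identical matches), extracts guide-centric downstream flanks (PAM) and
  target-centric mRNA-sense flanks (PFS) from overlapping ORFs, builds
  position-count motif matrices with majority consensus, and classifies
  hits by strand, ORF/intergenic region, and genome quadrant.
- **Positional bias test** (`crisprcoev.bias`) — a one-tailed permutation
  test of terminal bias: the observed mean protospacer position on a
  length-L genome is compared against the means of `n_sim` replicates of
  n positions drawn uniformly on 1..L;
  `p = #(null means > observed) / n_sim`.
- **Time-shift analysis** (`crisprcoev.timeshift`) — per-offset
  (phage year − bacterium year) mean ± SE proportion of resistant hosts,
  past/contemporary/future aggregates, and a phage-year label-permutation
  test of the past-vs-future asymmetry.
- **Escape timeline** (`crisprcoev.timeline`) — per-spacer chronology
  across phage isolates: protospacer states *intact* (exact match),
  *mutated* (relaxed Hamming match, or flank-anchor evidence of a small
  indel at the homologous site) or *absent*; first post-appearance
  escape year, ancestral-sequence reversion year, and pre-existing
  variation flags.
- **Synthetic data** (`crisprcoev.simulate`) — a seeded generator of the
  whole system (conserved backbone + terminally biased acquisitions with
  a planted downstream PAM, a phage lineage accumulating verified escape
  SNPs/deletions, reversions and terminal expansions, and an arms-race
  infection matrix) with a replayable ground-truth log, so every stage is
  testable offline.

## Worked example

The permutation test from published summary inputs (18 and 15
protospacers on a 50,666-bp consensus genome, 100,000 replicates):

```bash
$ python examples/01_positional_bias.py
C1: n=18, observed mean 35706.61, null mean 25330.0 (sd 3449.1), p = 0.00111
C2: n=15, observed mean 33342.33, null mean 25327.2 (sd 3788.0), p = 0.01677
```

Both observed means sit ~2–3 null standard deviations above the uniform
expectation of (L+1)/2 ≈ 25,333.5: protospacers cluster toward the
terminal end of the phage genome, so spacer acquisition is positionally
biased.

A full synthetic pipeline run (`examples/04_timeshift.py`, study-scale
scenario, seed 11) prints the arms-race curve:

```
        past: 0.933 ± 0.026
contemporary: 0.185 ± 0.058
      future: 0.159 ± 0.018

past-minus-future resistance = 0.761, permutation p = 0
```

Hosts resist nearly all phages from their past but are susceptible to
contemporary and future phages — the time-shift signature of arms-race
coevolution. The remaining examples cover cataloging
(`02_simulate_and_catalog.py`), mapping and PAM recovery
(`03_map_protospacers_and_pam.py`), and escape timelines
(`05_escape_timeline.py`); each prints the numbers it computes alongside
the generator's planted truth.

A thin CLI wraps the same functions
(`crisprcoev simulate|catalog|map|bias|timeshift|timeline`); see
`crisprcoev --help`.

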