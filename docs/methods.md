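# Methods

## The analysis model

The package treats a longitudinal phage–bacterium system as three linked
observables, all dated at year granularity:

1. **CRISPR arrays.** Each bacterial isolate carries, per locus, an
   ordered repeat-spacer array written conserved-end-first. Spacer
   identity is exact string equality on the uppercased sequence; no
   clustering of near-identical spacers is attempted, because no
   biologically grounded tolerance is available and near-duplicates are
   informative (they are exactly what escape analysis looks at on the
   phage side). The global catalog is built oldest-isolate-first
   (ties broken lexicographically by isolate id so re-runs are
   deterministic), and labelling is append-only: adding a younger isolate
   can never relabel existing spacers. A label is *conserved* iff its
   sequence occurs in every isolate's array for that locus.

2. **Protospacers.** Hit discovery is Hamming-only (both strands,
   reverse-strand hits reported in forward coordinates); indels are
   deliberately excluded here and handled by the timeline's anchor rule
   instead, keeping the mapper's guarantees simple. The default mismatch
   budget is 0 because host-range annotation counts *identical* matches;
   escape detection relaxes this separately. Flanks follow the two
   effector chemistries: the DNA-targeting locus's adjacent motif (PAM)
   is guide-centric (3′ of the protospacer on the spacer-matching
   strand, window 10 nt to cover an NNNNNTAAAA-length motif); the
   RNA-targeting locus's flanking sites (PFS) are target-centric from
   the overlapping ORF's mRNA sense, and are undefined (an error) for
   intergenic or template-strand hits. Motif consensus reports a base
   only where it reaches a configurable column majority (default 0.8),
   else N. Genome quadrants use each genome's own length
   (`ceil(4·midpoint/L)`); the positional-bias test instead uses a single
   consensus length because its observed means are defined on a
   consensus coordinate system.

3. **Infections.** The plaque matrix is complete by design
   (all-against-all); a missing cell is treated as a data error, not an
   NA. Resistance is the absence of plaques.

## Positional bias test

The statistic is the mean protospacer position; the null draws n
positions per replicate uniformly on the integers 1..L (discrete because
genomic coordinates are; at L ≈ 50 kb the continuous difference is
negligible) and `p = #(null means > observed)/n_sim` with a strict
inequality and no +1 correction, so p = 0 is possible; a conservative
(r+1)/(N+1) mode is available behind a flag. The per-hit coordinate
defaults to the footprint midpoint; a start-coordinate mode exists, and
with 30–40-nt protospacers the two differ by under 20 bp against a null
sd of ~3,400–3,800 — immaterial. The null mean is near-Gaussian
(sd = L/√(12n)), which the tests exploit as an independent analytic
oracle.

## Time-shift analysis

Offsets are phage year minus bacterium year; offsets < 0 are "past"
phages relative to the host, 0 contemporary, > 0 future. The default SE
is across bacteria — each bacterium contributes one resistance
proportion per offset, and mean/SE are taken over those host
proportions — because the curve describes the "resistant host
population"; a per-pair binomial SE mode is provided since figure
conventions differ. The past-vs-future effect test is a deliberately
plain label permutation (shuffle phage years among phages; one-tailed p
on the pairwise past-minus-future resistance difference). It is *not* a
mixed-model fit and does not adjust for isolation place or enrichment
host; outputs label it as a permutation test.

## Escape timeline

Protospacer states per (spacer, phage): *intact* = exact hit;
*mutated* = hit within `relaxed_budget` substitutions (default 3), or
both `anchor_len` (default 15 nt) flanks of a known intact occurrence
co-occurring within `spacer_len + max_indel` (default 20) nt — the
anchor rule is this package's explicit operationalization of "altered
protospacer", catching deletions/insertions up to `max_indel` that
Hamming matching cannot see, and the defaults comfortably cover
mutational sites of 1–12 bp; *absent* = neither, as after a large
terminal re-organization. Absent states count toward altered-protospacer
totals.

An escape year is the first altered state strictly after both the
spacer's first appearance (earliest carrying isolate's year — comparisons
are annual, so same-year alterations are contemporaneous, not escapes)
and an observed intact state. The second condition separates true
escapes from *pre-existing variation*: a spacer circulating before its
protospacer-bearing sequence ever appears in a phage is flagged, not
counted as an escape. Reversion is the first intact state after the
escape year. A spacer never observed intact anywhere is classified by
the Hamming rules alone and flagged `no_ancestral_reference`.

## Synthetic generator

What it emulates: a conserved per-locus spacer backbone shared by all
isolates; variable-end acquisitions sampled from contemporary phage
genomes with probability `terminal_bias` (default 0.5) of coming from
the terminal genome quadrant, echoing the observation that roughly half
of DNA-locus protospacers sit in quadrant 4; a 5-nt motif (default
TAAAA) written guide-centric downstream of every DNA-locus source site;
RNA-locus sources constrained to ORF sense strands (ORFs are tiled
non-overlapping windows on alternating strands so both PFS orientations
are exercised); a single phage lineage per year accumulating escape
SNPs or 1–12-bp deletions at protospacers whose spacer is already
circulating (strictly earlier first-appearance year), reverting to the
ancestral sequence with probability `reversion_prob` and then frozen so
each site carries at most one escape–reversion episode; terminal
expansions appending novel DNA (with an extra ORF); and infection
outcomes drawn per pair from the offset category alone
(`r_past`/`r_contemporary`/`r_future`).

Every planted deletion is verified to actually abolish the exact match
(an edge-of-footprint deletion can be a sequence-level no-op when
adjacent bases repeat the deleted ones); ineffective draws fall back to
a SNP, so the truth log and the realized sequences never disagree.
Acquisitions sample candidate sites without replacement, so variable
spacers are isolate-specific and event attribution is unambiguous;
shared spacers across isolates are represented by the backbone. The
optional pre-existing-variation plant gives an early isolate a spacer
whose protospacer only enters the lineage inside a later terminal
expansion.

Defaults (chosen once as realistic study-like conditions): 6 years,
3 phages and 3 bacteria per year, 46,500-bp genome, 30-nt spacers,
backbone of 10 spacers/locus, `acquisition_rate` 0.5 per bacterium-year
per locus, `escape_prob` 0.3 and `reversion_prob` 0.15 per site-year,
`expansion_prob` 0.3 with 800-bp inserts. `make_study_scale_scenario()`
instead uses the study's design: 17 bacteria over 2007–2013, 30 phages
over 2009–2014, `acquisition_rate` 0.3, expansions of 850 bp at rate 0.5
(expected growth ≈ 46.5 → 49 kb), and resistance rates 0.95 / 0.24 /
0.18 for past / contemporary / future.

What it does **not** emulate: recombination or multiple co-circulating
phage lineages, within-year dynamics, selection coefficients or
population sizes, any coupling of infection outcomes to spacer content,
primed adaptation, or anti-CRISPR systems. Passing tests therefore show
that the pipeline recovers planted structure under the stated generative
assumptions — not that real data satisfy those assumptions.

## Numerical and interface choices

External coordinates are 1-based inclusive on the forward strand;
internal computation is 0-based half-open with conversion centralized in
one module. Metadata (isolation years, sources, roles) travels in a
sidecar TSV rather than FASTA headers, which are unreliable in public
records. All randomness flows through one `numpy` generator per
operation with the seed recorded in the result objects; simulation
outputs are byte-identical under a fixed config. Problem sizes in the
test suite (e.g., 20 timeline-recovery simulations, 200 null-calibration
reruns at 2,000 null replicates, 100,000-replicate nulls for the
headline p-values) were sized to keep the full suite under a minute on a
single CPU while leaving Monte-Carlo error far inside the asserted
tolerances.

## Known limitations

Year-granular dating cannot order same-year events, so contemporaneous
alterations are conservatively not counted as escapes. Orientation of
repeat-spacer arrays is a caller-supplied convention (conserved-end
first); the package does not infer transcription direction. The escape
detector keys on one ancestral reference occurrence per spacer; highly
duplicated protospacers in one genome would need manual review. The
permutation effect test in the time-shift module ignores blocking
structure (bacterium identity) and random factors a mixed model would
absorb.
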