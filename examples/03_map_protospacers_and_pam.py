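"""Map spacers onto phage genomes, classify hits and infer the PAM.

Takes one synthetic run, maps every variable spacer against the earliest
phage genome, tabulates hit strand/region/quadrant, and builds the
position-count consensus of the guide-centric downstream flanks of the
DNA-targeting locus — which recovers the planted NNNNNTAAAA motif.
"""

from collections import Counter

from crisprcoev.catalog import build_global_catalog, classify_conserved_variable
from crisprcoev.mapping import build_motif, classify_hit, find_protospacers
from crisprcoev.simulate import SimConfig, simulate

res = simulate(SimConfig(seed=7))
cat = classify_conserved_variable(build_global_catalog(res.isolate_arrays()))
phage0 = min(res.phages, key=lambda p: (p.isolation_year, p.id))
orfs0 = [o for o in res.orfs if o.genome_id == phage0.id]

hits, flanks = [], []
for locus in ("C1", "C2"):
    for label in sorted(cat.variable[locus]):
        for hit in find_protospacers(cat.pools[locus][label], phage0, 0):
            hit = classify_hit(hit, len(phage0), orfs0)
            hits.append((locus, hit))
            if locus == "C1":
                flanks.append(hit.downstream_flank)

print(f"{len(hits)} protospacers in {phage0.id} ({len(phage0)} bp)")
print("strand counts:", Counter(h.strand for _, h in hits))
print("region counts:", Counter(h.region for _, h in hits))
print("quadrant counts:", Counter(h.quadrant for _, h in hits))
motif = build_motif(flanks, majority_fraction=0.8)
print(f"C1 downstream-flank consensus ({motif.n_flanks} flanks): {motif.consensus}")
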