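"""Escape/reversion chronology of spacer-protospacer pairs.

Builds the per-spacer timeline across dated phage isolates: when the
spacer entered the bacterial population, when its protospacer first
appeared altered (SNP, small deletion, or missing) in later phages, and
whether the ancestral sequence later reappeared. Detected events are
compared with the generator's planted truth.
"""

from crisprcoev.catalog import build_global_catalog, classify_conserved_variable
from crisprcoev.simulate import SimConfig, simulate
from crisprcoev.timeline import build_timeline

res = simulate(SimConfig(seed=7))
cat = classify_conserved_variable(build_global_catalog(res.isolate_arrays()))
events = build_timeline(cat, res.phages)

escapes = [e for e in events if e.escape_year is not None]
reversions = [e for e in events if e.reversion_year is not None]
print(f"{len(events)} phage-targeting spacers")
print(f"{len(escapes)} with altered protospacers after spacer appearance "
      f"(truth: {len(res.truth.escape_events())})")
print(f"{len(reversions)} with ancestral-sequence reversion "
      f"(truth: {len(res.truth.reversion_events())})")

for e in escapes[:5]:
    states = "".join(
        {"intact": ".", "mutated": "m", "absent": "x"}[s] for _, _, s in e.phage_states
    )
    print(f"  {e.spacer_label}: spacer {e.spacer_first_year}, escape "
          f"{e.escape_year}, reversion {e.reversion_year or '-'}  [{states}]")
print("(one character per phage isolate, year-ordered: . intact, m mutated, x absent)")
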