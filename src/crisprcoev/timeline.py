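"""Chronology of spacer acquisition and phage protospacer escape.

For every phage-targeting spacer the timeline records when the spacer
first appeared in the bacterial population (earliest isolation year of a
carrying isolate) and the state of its protospacer in every dated phage:

* ``intact``  — an identical match exists in the genome;
* ``mutated`` — a match within a relaxed substitution budget exists, or
  both flanking anchors of a known intact occurrence co-occur at the
  right spacing (catching small deletions/insertions at the homologous
  site that Hamming matching cannot see);
* ``absent``  — neither, e.g. after a large terminal re-organization.

An escape is the first altered (mutated/absent) state observed strictly
after both the spacer's appearance and an observed intact state; a later
return to ``intact`` is a reversion to the ancestral protospacer. A
spacer whose protospacer-bearing sequence only emerges in phages after
the spacer was already circulating is flagged as pre-existing variation,
not as an escape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .catalog import SpacerCatalog
from .io import DatedSequenceRecord
from .mapping import ProtospacerHit, find_protospacers
from .sequtils import revcomp

INTACT, MUTATED, ABSENT = "intact", "mutated", "absent"


@dataclass
class EscapeEvent:
    """Per-spacer chronology across all dated phage isolates."""

    spacer_label: str
    spacer_first_year: int
    phage_states: list[tuple[str, int, str]]  # (phage_id, year, state), year-ordered
    escape_year: int | None = None
    reversion_year: int | None = None
    preexisting_variation: bool = False
    no_ancestral_reference: bool = False

    def to_dict(self) -> dict:
        return {
            "spacer_label": self.spacer_label,
            "spacer_first_year": self.spacer_first_year,
            "phage_states": [
                {"phage_id": p, "year": y, "state": s} for p, y, s in self.phage_states
            ],
            "escape_year": self.escape_year,
            "reversion_year": self.reversion_year,
            "preexisting_variation": self.preexisting_variation,
            "no_ancestral_reference": self.no_ancestral_reference,
        }


def spacer_first_appearance(catalog: SpacerCatalog) -> dict[str, int]:
    """Earliest isolation year of any isolate carrying each label."""
    first: dict[str, int] = {}
    for isolate, per_locus in catalog.arrays.items():
        year = catalog.years[isolate]
        for labels in per_locus.values():
            for label in labels:
                if label not in first or year < first[label]:
                    first[label] = year
    return first


def anchors_from_occurrence(
    genome_seq: str, hit: ProtospacerHit, anchor_len: int = 15
) -> tuple[str, str] | None:
    """Flanking anchors of an intact occurrence, in spacer orientation.

    ``left`` is immediately 5' and ``right`` immediately 3' of the
    protospacer on the strand the spacer matches. Returns None when either
    flank is truncated by the genome edge (too short to anchor)."""
    if hit.strand == "+":
        left = genome_seq[max(0, hit.start - 1 - anchor_len) : hit.start - 1]
        right = genome_seq[hit.end : hit.end + anchor_len]
    else:
        left = revcomp(genome_seq[hit.end : hit.end + anchor_len])
        right = revcomp(genome_seq[max(0, hit.start - 1 - anchor_len) : hit.start - 1])
    if len(left) < anchor_len or len(right) < anchor_len:
        return None
    return left, right


def _anchored_site_present(
    genome_seq: str, anchors: tuple[str, str], spacer_len: int, max_indel: int
) -> bool:
    """True if left and right anchors co-occur (either strand) separated by
    0..spacer_len+max_indel nt — the signature of a diverged or
    indel-bearing protospacer at the homologous position."""
    left, right = anchors
    max_gap = spacer_len + max_indel
    for seq in (genome_seq, revcomp(genome_seq)):
        i = seq.find(left)
        while i != -1:
            lo = i + len(left)
            j = seq.find(right, lo, lo + max_gap + len(right))
            if j != -1 and 0 <= j - lo <= max_gap:
                return True
            i = seq.find(left, i + 1)
    return False


def protospacer_state(
    spacer_seq: str,
    phage: DatedSequenceRecord | str,
    relaxed_budget: int = 3,
    anchor_len: int = 15,
    max_indel: int = 20,
    anchors: tuple[str, str] | None = None,
) -> str:
    """Classify one phage genome as intact / mutated / absent for a spacer.

    *anchors* are flanks of a known intact occurrence in some other phage
    (see :func:`anchors_from_occurrence`); without them only the Hamming
    routes are available.
    """
    if relaxed_budget <= 0:
        raise ValueError("relaxed_budget must be positive")
    if anchor_len < 10:
        raise ValueError("anchor_len must be at least 10")
    gseq = phage.sequence if isinstance(phage, DatedSequenceRecord) else phage
    if find_protospacers(spacer_seq, gseq, 0):
        return INTACT
    if find_protospacers(spacer_seq, gseq, relaxed_budget):
        return MUTATED
    if anchors is not None and _anchored_site_present(
        gseq, anchors, len(spacer_seq), max_indel
    ):
        return MUTATED
    return ABSENT


def build_timeline(
    catalog: SpacerCatalog,
    phages: Sequence[DatedSequenceRecord],
    relaxed_budget: int = 3,
    anchor_len: int = 15,
    max_indel: int = 20,
) -> list[EscapeEvent]:
    """One EscapeEvent per phage-targeting spacer.

    Phages are processed in (year, id) order regardless of input order.
    The anchor reference is taken from the earliest phage with an intact
    occurrence; a spacer never intact anywhere is still classified by the
    Hamming rules and flagged ``no_ancestral_reference``. Comparisons are
    annual: a same-year alteration is contemporaneous, not an escape.
    """
    ordered = sorted(phages, key=lambda p: (p.isolation_year, p.id))
    first_year = spacer_first_appearance(catalog)
    events: list[EscapeEvent] = []
    for locus in sorted(catalog.pools):
        for label, seq in catalog.pools[locus].items():
            per_phage_exact = [
                (p, find_protospacers(seq, p, 0)) for p in ordered
            ]
            if not any(h for _, h in per_phage_exact):
                continue  # not phage-targeting
            anchors = None
            for p, hits in per_phage_exact:
                if hits:
                    anchors = anchors_from_occurrence(p.sequence, hits[0], anchor_len)
                    break
            states = []
            for p, hits in per_phage_exact:
                if hits:
                    state = INTACT
                else:
                    state = protospacer_state(
                        seq, p, relaxed_budget, anchor_len, max_indel, anchors
                    )
                states.append((p.id, p.isolation_year, state))
            events.append(
                _summarize(label, first_year[label], states, anchors is None)
            )
    return events


def _summarize(
    label: str,
    first_year: int,
    states: list[tuple[str, int, str]],
    no_reference: bool,
) -> EscapeEvent:
    intact_years = [y for _, y, s in states if s == INTACT]
    first_intact = min(intact_years) if intact_years else None
    escape_year = None
    for _, year, state in states:
        if state == INTACT:
            continue
        if year <= first_year:
            continue  # spacer not yet (or only just) in the population
        if first_intact is not None and year <= first_intact:
            continue  # alteration precedes any observed ancestral state
        escape_year = year
        break
    reversion_year = None
    if escape_year is not None:
        later_intact = [y for y in intact_years if y > escape_year]
        if later_intact:
            reversion_year = min(later_intact)
    preexisting = first_intact is not None and first_year < first_intact and any(
        s == ABSENT and y < first_intact for _, y, s in states
    )
    return EscapeEvent(
        spacer_label=label,
        spacer_first_year=first_year,
        phage_states=states,
        escape_year=escape_year,
        reversion_year=reversion_year,
        preexisting_variation=preexisting,
        no_ancestral_reference=no_reference,
    )
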