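"""Repeat-spacer array extraction and the global chronological spacer catalog.

Spacers are pooled across all isolates per locus and labelled by first
appearance: the oldest isolate's spacers get labels 1..k counting from the
conserved end, and every younger isolate contributes labels only for
sequences not yet in the pool, continuing the global numbering. A spacer
sequence therefore has exactly one label per locus, shared by every
isolate that carries it, and re-running the cataloging is deterministic
(chronological ties are broken by isolate id).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .sequtils import hamming_scan, validate_dna


@dataclass(frozen=True)
class SpacerRecord:
    """One spacer occurrence: its locus, global label, sequence, carrying
    isolate and 1-based position counted from the conserved end."""

    locus: str
    label: str
    sequence: str
    isolate_id: str
    index_from_conserved_end: int


@dataclass
class SpacerCatalog:
    """Global spacer pools plus per-isolate arrays.

    ``pools[locus]`` maps label -> sequence in label order;
    ``arrays[isolate][locus]`` is the isolate's array as labels, conserved
    end first; ``conserved``/``variable`` partition each locus's labels
    after :func:`classify_conserved_variable`.
    """

    pools: dict[str, dict[str, str]] = field(default_factory=dict)
    arrays: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    years: dict[str, int] = field(default_factory=dict)
    conserved: dict[str, set[str]] = field(default_factory=dict)
    variable: dict[str, set[str]] = field(default_factory=dict)

    def label_for(self, locus: str, sequence: str) -> str | None:
        for label, seq in self.pools.get(locus, {}).items():
            if seq == sequence:
                return label
        return None

    def sequence_of(self, label: str) -> str:
        for pool in self.pools.values():
            if label in pool:
                return pool[label]
        raise KeyError(label)

    def locus_of(self, label: str) -> str:
        for locus, pool in self.pools.items():
            if label in pool:
                return locus
        raise KeyError(label)

    def isolate_labels(self, isolate_id: str) -> set[str]:
        return {l for labels in self.arrays[isolate_id].values() for l in labels}

    def records(self) -> list[SpacerRecord]:
        out = []
        for isolate, per_locus in self.arrays.items():
            for locus, labels in per_locus.items():
                for pos, label in enumerate(labels, start=1):
                    out.append(
                        SpacerRecord(locus, label, self.pools[locus][label], isolate, pos)
                    )
        return out


def extract_array(
    locus_seq: str,
    repeat: str,
    max_repeat_mismatch: int = 2,
    spacer_len_range: tuple[int, int] = (20, 50),
) -> list[str]:
    """Cut a repeat-spacer array into its spacers.

    Repeat occurrences are located by Hamming scan (budget
    *max_repeat_mismatch*), taken greedily left-to-right without overlap;
    spacers are the segments between consecutive repeats whose length falls
    in *spacer_len_range*. An inter-repeat segment outside the range —
    e.g. a stretch of degenerate repeats — is skipped with a warning and
    numbering resumes after it.

    The caller supplies the sequence conserved-end-first; no orientation
    inference happens here.
    """
    locus_seq = validate_dna(locus_seq, "locus sequence")
    repeat = validate_dna(repeat, "repeat")
    if len(repeat) < 18:
        raise ValueError("repeat must be at least 18 nt")
    occ = hamming_scan(locus_seq, repeat, max_repeat_mismatch)
    starts: list[int] = []
    for pos, _ in occ:
        if not starts or pos >= starts[-1] + len(repeat):
            starts.append(pos)
    if not starts:
        raise ValueError("no repeat occurrence found in locus sequence")
    lo, hi = spacer_len_range
    spacers = []
    for a, b in zip(starts, starts[1:]):
        seg = locus_seq[a + len(repeat) : b]
        if lo <= len(seg) <= hi:
            spacers.append(seg)
        else:
            warnings.warn(
                f"inter-repeat segment of {len(seg)} nt outside spacer length "
                f"range {spacer_len_range}; skipped",
                stacklevel=2,
            )
    return spacers


def build_global_catalog(
    isolates: Iterable[tuple[str, int, Mapping[str, Sequence[str]]]],
) -> SpacerCatalog:
    """Pool spacers across dated isolates into the global labelled catalog.

    *isolates* is an iterable of ``(isolate_id, year, {locus: [spacer, ...]})``
    with each per-locus list conserved-end-first. Isolates are processed
    oldest first (ties by isolate id); labels are ``{locus}s{k}`` with k
    continuing per locus. Adding a younger isolate never changes existing
    labels.
    """
    ordered = sorted(isolates, key=lambda t: (t[1], t[0]))
    if not ordered:
        raise ValueError("need at least one isolate")
    cat = SpacerCatalog()
    counters: dict[str, int] = {}
    seq_to_label: dict[str, dict[str, str]] = {}
    for isolate_id, year, per_locus in ordered:
        if isolate_id in cat.arrays:
            raise ValueError(f"duplicate isolate id {isolate_id!r}")
        cat.years[isolate_id] = int(year)
        cat.arrays[isolate_id] = {}
        for locus, spacers in per_locus.items():
            pool = cat.pools.setdefault(locus, {})
            lookup = seq_to_label.setdefault(locus, {})
            labels: list[str] = []
            seen_here: set[str] = set()
            for raw in spacers:
                seq = validate_dna(raw, "spacer")
                label = lookup.get(seq)
                if label is None:
                    counters[locus] = counters.get(locus, 0) + 1
                    label = f"{locus}s{counters[locus]}"
                    pool[label] = seq
                    lookup[seq] = label
                if seq in seen_here:
                    warnings.warn(
                        f"isolate {isolate_id}: spacer {label} duplicated within "
                        f"one array; both positions kept under one label",
                        stacklevel=2,
                    )
                seen_here.add(seq)
                labels.append(label)
            cat.arrays[isolate_id][locus] = labels
    return cat


def classify_conserved_variable(catalog: SpacerCatalog) -> SpacerCatalog:
    """Partition each locus's labels: conserved iff carried by every isolate.

    A spacer missing from even one isolate's array for that locus is
    variable. Updates the catalog in place and returns it.
    """
    for locus, pool in catalog.pools.items():
        conserved = set()
        for label in pool:
            if all(
                label in per_locus.get(locus, [])
                for per_locus in catalog.arrays.values()
            ):
                conserved.add(label)
        catalog.conserved[locus] = conserved
        catalog.variable[locus] = set(pool) - conserved
    return catalog
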