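"""Protospacer discovery in phage genomes, flank extraction and motifs.

A protospacer is any window of a phage genome within a configurable
Hamming distance of a spacer, on either strand (default budget 0, i.e.
identical matches; escape detection elsewhere uses a relaxed budget).
Reverse-strand hits are reported in forward coordinates with strand "-".

Flank conventions follow the two effector chemistries of the study
system: the DNA-targeting locus's adjacent motif (PAM) is read
guide-centric — the window immediately 3' of the protospacer on the
strand the spacer matches — while the RNA-targeting locus's flanking
sites (PFS) are read target-centric from the mRNA sense of the predicted
ORF that the hit lies in.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .catalog import SpacerCatalog, SpacerRecord
from .io import DatedSequenceRecord, OrfAnnotation
from .sequtils import hamming_scan, revcomp

REGION_ORF = "ORF"
REGION_INTERGENIC = "intergenic"

BASES = "ACGT"


class PfsEligibilityError(ValueError):
    """The hit does not overlap an ORF on the coding strand, so no PFS exists."""


@dataclass(frozen=True)
class ProtospacerHit:
    """One spacer match in one phage genome (1-based inclusive, forward strand)."""

    spacer_label: str
    genome_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    downstream_flank: str = ""
    orf_overlap: str | None = None
    region: str | None = None
    coding_strand_hit: bool | None = None
    quadrant: int | None = None

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class MotifMatrix:
    """Position counts over {A,C,G,T} for a set of equal-length flanks.

    ``counts`` is 4 x W (rows A, C, G, T). The consensus reports a base
    only where it reaches the majority fraction; every other column is N.
    """

    counts: np.ndarray
    consensus: str
    n_flanks: int
    majority_fraction: float

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "n_flanks": self.n_flanks,
            "majority_fraction": self.majority_fraction,
            "counts": {b: self.counts[i].tolist() for i, b in enumerate(BASES)},
            "consensus": self.consensus,
        }


def _spacer_parts(spacer: SpacerRecord | str) -> tuple[str, str]:
    if isinstance(spacer, SpacerRecord):
        return spacer.label, spacer.sequence
    return "spacer", spacer


def _genome_parts(genome: DatedSequenceRecord | str) -> tuple[str, str]:
    if isinstance(genome, DatedSequenceRecord):
        return genome.id, genome.sequence
    return "genome", genome


def find_protospacers(
    spacer: SpacerRecord | str,
    genome: DatedSequenceRecord | str,
    max_mismatch: int = 0,
    pam_window: int = 10,
) -> list[ProtospacerHit]:
    """All occurrences of *spacer* in *genome* within *max_mismatch*
    substitutions, both strands, deduplicated by (start, strand).

    Each hit carries its guide-centric downstream flank (up to
    *pam_window* nt). A genome shorter than the spacer yields an empty
    list rather than an error.
    """
    label, seq = _spacer_parts(spacer)
    gid, gseq = _genome_parts(genome)
    if len(seq) < 15:
        raise ValueError("spacer must be at least 15 nt")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    hits: dict[tuple[int, str], ProtospacerHit] = {}
    for strand, pattern in (("+", seq), ("-", revcomp(seq))):
        for pos0, mm in hamming_scan(gseq, pattern, max_mismatch):
            start, end = pos0 + 1, pos0 + len(seq)
            key = (start, strand)
            if key in hits:
                continue
            hit = ProtospacerHit(label, gid, start, end, strand, mm)
            hit = replace(hit, downstream_flank=extract_pam(hit, gseq, pam_window))
            hits[key] = hit
    return sorted(hits.values(), key=lambda h: (h.start, h.strand))


def extract_pam(hit: ProtospacerHit, genome: DatedSequenceRecord | str, window: int = 10) -> str:
    """Guide-centric downstream flank: *window* nt 3' of the protospacer on
    the strand the spacer matches (reverse-complemented for minus-strand
    hits). Truncated silently where the genome ends inside the window."""
    if window < 1:
        raise ValueError("window must be >= 1")
    _, gseq = _genome_parts(genome)
    if hit.strand == "+":
        return gseq[hit.end : hit.end + window]
    lo = max(0, hit.start - 1 - window)
    return revcomp(gseq[lo : hit.start - 1])


def extract_pfs(
    hit: ProtospacerHit,
    genome: DatedSequenceRecord | str,
    orfs: Sequence[OrfAnnotation],
    up_window: int = 10,
    down_window: int = 10,
) -> tuple[str, str]:
    """Target-centric flanks from the mRNA sense of the overlapping ORF.

    Returns ``(upstream, downstream)`` in mRNA orientation, clipped at the
    ORF boundaries. Raises :class:`PfsEligibilityError` for hits outside
    any ORF or matching the template rather than the sense strand.
    """
    _, gseq = _genome_parts(genome)
    orf = _best_orf(hit, orfs)
    if orf is None:
        raise PfsEligibilityError(
            f"hit {hit.spacer_label}@{hit.start} is intergenic; no PFS defined"
        )
    if hit.strand != orf.strand:
        raise PfsEligibilityError(
            f"hit {hit.spacer_label}@{hit.start} matches the template strand of "
            f"{orf.orf_id}; PFS is defined on the mRNA sense only"
        )
    mrna = gseq[orf.start - 1 : orf.end]
    if orf.strand == "-":
        mrna = revcomp(mrna)
        mstart = orf.end - hit.end  # 0-based within mRNA
    else:
        mstart = hit.start - orf.start
    mend = mstart + (hit.end - hit.start + 1)
    up = mrna[max(0, mstart - up_window) : max(0, mstart)]
    down = mrna[mend : mend + down_window]
    return up, down


def build_motif(flanks: Iterable[str], majority_fraction: float = 0.8) -> MotifMatrix:
    """Column-wise base counts and majority consensus for a flank set.

    Flanks shorter than the longest one (genome-boundary truncations) are
    excluded with a warning; an empty input is an error.
    """
    flanks = [f.upper() for f in flanks]
    if not flanks:
        raise ValueError("no flanks supplied")
    width = max(len(f) for f in flanks)
    kept = [f for f in flanks if len(f) == width]
    if len(kept) < len(flanks):
        warnings.warn(
            f"{len(flanks) - len(kept)} flank(s) shorter than {width} nt excluded",
            stacklevel=2,
        )
    counts = np.zeros((4, width), dtype=int)
    for f in kept:
        for j, base in enumerate(f):
            if base in BASES:
                counts[BASES.index(base), j] += 1
    consensus = []
    for j in range(width):
        total = counts[:, j].sum()
        best = int(counts[:, j].argmax())
        if total > 0 and counts[best, j] / total >= majority_fraction:
            consensus.append(BASES[best])
        else:
            consensus.append("N")
    return MotifMatrix(counts, "".join(consensus), len(kept), majority_fraction)


def _overlap(hit: ProtospacerHit, orf: OrfAnnotation) -> int:
    return max(0, min(hit.end, orf.end) - max(hit.start, orf.start) + 1)


def _best_orf(hit: ProtospacerHit, orfs: Sequence[OrfAnnotation]) -> OrfAnnotation | None:
    """The ORF with maximal overlap (ties to the lowest start), or None."""
    candidates = [
        o for o in orfs if o.genome_id == hit.genome_id and _overlap(hit, o) > 0
    ]
    if not candidates:
        return None
    return max(candidates, key=lambda o: (_overlap(hit, o), -o.start))


def classify_hit(
    hit: ProtospacerHit, genome_length: int, orfs: Sequence[OrfAnnotation]
) -> ProtospacerHit:
    """Attach region (ORF/intergenic), coding-strand flag and genome quadrant.

    A hit is in an ORF if the footprints overlap by at least 1 nt; with
    multiple overlaps the largest wins. The quadrant is
    ``ceil(4 * midpoint / genome_length)``, so quadrant 4 is the terminal
    quarter of the genome.
    """
    if genome_length < hit.end:
        raise ValueError("genome_length shorter than hit end")
    orf = _best_orf(hit, orfs)
    quadrant = min(4, max(1, math.ceil(4 * hit.midpoint / genome_length)))
    if orf is None:
        return replace(
            hit, orf_overlap=None, region=REGION_INTERGENIC,
            coding_strand_hit=False, quadrant=quadrant,
        )
    return replace(
        hit,
        orf_overlap=orf.orf_id,
        region=REGION_ORF,
        coding_strand_hit=hit.strand == orf.strand,
        quadrant=quadrant,
    )


def map_catalog(
    catalog: SpacerCatalog,
    phages: Sequence[DatedSequenceRecord],
    orfs: Sequence[OrfAnnotation] = (),
    max_mismatch: int = 0,
    labels: Iterable[str] | None = None,
) -> list[ProtospacerHit]:
    """Map every catalog spacer (or a label subset) against every phage
    genome and classify the hits."""
    orf_by_genome: dict[str, list[OrfAnnotation]] = {}
    for o in orfs:
        orf_by_genome.setdefault(o.genome_id, []).append(o)
    wanted = None if labels is None else set(labels)
    hits: list[ProtospacerHit] = []
    for locus, pool in catalog.pools.items():
        for label, seq in pool.items():
            if wanted is not None and label not in wanted:
                continue
            rec = SpacerRecord(locus, label, seq, "-", 1)
            for phage in phages:
                for hit in find_protospacers(rec, phage, max_mismatch):
                    hits.append(
                        classify_hit(hit, len(phage), orf_by_genome.get(phage.id, []))
                    )
    return hits


def phage_targeting_labels(
    catalog: SpacerCatalog, phages: Sequence[DatedSequenceRecord], max_mismatch: int = 0
) -> set[str]:
    """Labels with at least one (by default identical) protospacer in any phage."""
    targeting = set()
    for locus, pool in catalog.pools.items():
        for label, seq in pool.items():
            for phage in phages:
                if find_protospacers(seq, phage, max_mismatch):
                    targeting.add(label)
                    break
    return targeting


def match_counts(
    catalog: SpacerCatalog,
    isolate_id: str,
    phage: DatedSequenceRecord,
    targeting_labels: set[str],
) -> tuple[int, int]:
    """The pair of numbers annotating one infection-matrix cell: how many of
    this bacterium's spacers have an identical match in this particular
    phage, and how many target at least one phage in the whole dataset
    (the latter is a property of the bacterium alone)."""
    labels = catalog.isolate_labels(isolate_id)
    in_this_phage = sum(
        1
        for label in labels
        if find_protospacers(catalog.sequence_of(label), phage, 0)
    )
    return in_this_phage, len(labels & targeting_labels)
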