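"""Seeded generator of a coevolving phage-bacterium system with ground truth.

The generator emulates the statistical structure of a longitudinal
arms-race study: dated bacterial isolates carry a conserved spacer
backbone plus variable-end spacers acquired from contemporary phage
genomes (with a configurable bias toward the terminal genome quadrant and
a short adjacent motif planted downstream of every DNA-targeting source
site); a single phage lineage inherits the previous year's genome and
accumulates escape mutations (SNPs or small deletions) in protospacers
after the corresponding spacer has appeared in the bacterial population,
occasionally reverting to the ancestral sequence, and occasionally
expanding by terminal insertion of novel DNA; infection outcomes follow
an asymmetric resistance model (high resistance to past phages, low to
contemporary and future ones). Every planted event is logged in a
replayable truth object so that each pipeline stage can be validated
offline against known answers.

Deliberate simplifications: one inherited lineage per year (no
recombination, no within-year dynamics), year-granular dating, and
infection outcomes drawn from the offset category alone rather than from
spacer content.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import (
    ROLE_LOCUS,
    ROLE_PHAGE,
    DatedSequenceRecord,
    OrfAnnotation,
    write_fasta,
    write_infection_matrix_csv,
    write_json,
    write_metadata,
    write_orf_annotations,
)
from .sequtils import exact_scan, random_dna, revcomp
from .timeshift import InfectionMatrix, categorize

DEFAULT_REPEATS = {
    "C1": "GTTGTAGTTCCCTATCTCATTTCGCAGTGCTACAAT",
    "C2": "GTTGGAACTTACCTATGAGGAATTGAAAGACAACTT",
}

_SITE_MARGIN = 16  # room for an upstream PAM window and flank anchors


@dataclass
class SimConfig:
    """Tunable generative assumptions; defaults mirror the study conditions."""

    seed: int = 0
    start_year: int = 2009
    n_years: int = 6
    phages_per_year: int = 3
    bacteria_per_year: int = 3
    # explicit per-year counts override the uniform defaults above
    phage_year_counts: Optional[dict[int, int]] = None
    bacteria_year_counts: Optional[dict[int, int]] = None
    genome_length: int = 46_500
    backbone_spacers_per_locus: int = 10
    spacer_len: int = 30
    acquisition_rate: float = 0.5       # expected spacers / bacterium-year / locus
    terminal_bias: float = 0.5          # fraction of source sites in the last quadrant
    pam_motif: str = "TAAAA"
    pam_window: int = 10
    escape_prob: float = 0.3            # per targeted protospacer per year
    escape_deletion_fraction: float = 0.5
    reversion_prob: float = 0.15
    expansion_prob: float = 0.3         # terminal insertion per phage-year
    expansion_length: int = 800
    r_past: float = 0.95
    r_contemporary: float = 0.24
    r_future: float = 0.18
    loci: tuple[str, ...] = ("C1", "C2")
    repeats: Optional[dict[str, str]] = None
    orf_length: int = 600
    orf_gap: int = 50
    plant_preexisting: bool = False

    def __post_init__(self) -> None:
        for name in (
            "acquisition_rate", "terminal_bias", "escape_prob",
            "escape_deletion_fraction", "reversion_prob", "expansion_prob",
            "r_past", "r_contemporary", "r_future",
        ):
            v = getattr(self, name)
            if name == "acquisition_rate":
                if v < 0:
                    raise ValueError("acquisition_rate must be >= 0")
            elif not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.genome_length < 1_000:
            raise ValueError("genome_length must be >= 1000")
        if self.spacer_len < 15:
            raise ValueError("spacer_len must be >= 15")

    @property
    def phage_years(self) -> list[int]:
        if self.phage_year_counts:
            return sorted(self.phage_year_counts)
        return [self.start_year + i for i in range(self.n_years)]

    @property
    def bacteria_years(self) -> list[int]:
        if self.bacteria_year_counts:
            return sorted(self.bacteria_year_counts)
        return [self.start_year + i for i in range(self.n_years)]

    def phages_in(self, year: int) -> int:
        if self.phage_year_counts:
            return self.phage_year_counts[year]
        return self.phages_per_year

    def bacteria_in(self, year: int) -> int:
        if self.bacteria_year_counts:
            return self.bacteria_year_counts[year]
        return self.bacteria_per_year

    def repeat_of(self, locus: str) -> str:
        if self.repeats and locus in self.repeats:
            return self.repeats[locus]
        return DEFAULT_REPEATS[locus]


@dataclass
class SiteTruth:
    """One candidate protospacer source site and everything that happened to it."""

    site_id: str
    locus: str
    strand: str
    ancestral_start: int          # 1-based forward-strand start in the ancestral genome
    spacer_seq: str               # guide-oriented
    available_from: Optional[int] = None  # None = present in the ancestral genome
    acquired_by: Optional[str] = None
    acquisition_year: Optional[int] = None
    spacer_first_year: Optional[int] = None
    escape_year: Optional[int] = None
    escape_type: Optional[str] = None
    reversion_year: Optional[int] = None

    @property
    def midpoint(self) -> float:
        return self.ancestral_start + (len(self.spacer_seq) - 1) / 2


@dataclass
class SimTruth:
    """Replayable log of every planted feature and event."""

    seed: int
    genome_length: int
    backbone: dict[str, list[str]]
    sites: list[SiteTruth]
    expansions: list[dict] = field(default_factory=list)
    preexisting: Optional[dict] = None

    def acquired_sites(self) -> list[SiteTruth]:
        """Ancestral-genome sites acquired as spacers (the planted
        protospacers; excludes the pre-existing-variation plant, whose
        protospacer only exists in later expanded genomes)."""
        return [
            s for s in self.sites
            if s.acquired_by is not None and s.available_from is None
        ]

    def escape_events(self) -> list[SiteTruth]:
        return [s for s in self.sites if s.escape_year is not None]

    def reversion_events(self) -> list[SiteTruth]:
        return [s for s in self.sites if s.reversion_year is not None]

    def truth_positions(self) -> list[float]:
        """Ancestral midpoints of the acquired source sites (bias-test input)."""
        return [s.midpoint for s in self.acquired_sites()]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "genome_length": self.genome_length,
            "backbone": self.backbone,
            "sites": [dataclasses.asdict(s) for s in self.sites],
            "expansions": self.expansions,
            "preexisting": self.preexisting,
        }


@dataclass
class SimResult:
    config: SimConfig
    phages: list[DatedSequenceRecord]
    loci: list[DatedSequenceRecord]
    orfs: list[OrfAnnotation]
    matrix: InfectionMatrix
    truth: SimTruth
    _arrays: dict[str, dict[str, list[str]]] = field(default_factory=dict, repr=False)

    def isolate_arrays(self) -> list[tuple[str, int, dict[str, list[str]]]]:
        """Ground-truth per-isolate spacer lists, conserved end first —
        the same content the locus FASTA encodes as repeat-spacer arrays."""
        years = dict(self.matrix.bacterium_years)
        return [(b, int(years[b]), self._arrays[b]) for b in sorted(self._arrays)]

    def write(self, out_dir: str | Path) -> None:
        """Emit exactly the formats the io module reads, plus the truth JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.phages, out / "phages.fasta")
        write_fasta(self.loci, out / "loci.fasta")
        write_metadata(self.phages + self.loci, out / "metadata.tsv")
        write_orf_annotations(self.orfs, out / "orfs.gff3")
        write_infection_matrix_csv(self.matrix, out / "infection_matrix.csv")
        write_json(
            {
                "phage_years": {k: int(v) for k, v in self.matrix.phage_years.items()},
                "bacterium_years": {k: int(v) for k, v in self.matrix.bacterium_years.items()},
            },
            out / "isolate_years.json",
        )
        write_json(self.truth.to_dict(), out / "truth.json")


class _Infeasible(ValueError):
    pass


def _place_sites(
    rng: np.random.Generator,
    genome: list[str],
    cfg: SimConfig,
    orfs: list[OrfAnnotation],
    n_per_locus: int,
) -> list[SiteTruth]:
    """Sample non-overlapping candidate source sites with terminal bias.

    DNA-targeting (first-locus) sites land on either strand anywhere that
    fits; RNA-targeting (second-locus) sites must sit inside a predicted
    ORF and take its sense strand. The adjacent motif is written into the
    genome downstream (guide-centric) of every first-locus site.
    """
    L = cfg.genome_length
    m = cfg.spacer_len
    q4_lo = int(math.floor(0.75 * L)) + 1  # 0-based starts whose midpoint is in Q4
    reserved: list[tuple[int, int]] = []
    sites: list[SiteTruth] = []
    pam_locus = cfg.loci[0]
    gap = cfg.pam_window - len(cfg.pam_motif)
    if gap < 0:
        raise ValueError("pam_motif longer than pam_window")

    def overlaps(lo: int, hi: int) -> bool:
        return any(lo < b and a < hi for a, b in reserved)

    for locus in cfg.loci:
        for placed in range(n_per_locus):
            # decide the region first, then rejection-sample within it, so
            # crowding cannot skew the realized terminal fraction
            terminal = rng.random() < cfg.terminal_bias
            if terminal:
                lo, hi = q4_lo, L - m - _SITE_MARGIN
            else:
                lo, hi = _SITE_MARGIN, int(0.75 * L) - m - _SITE_MARGIN
            if hi <= lo:
                raise _Infeasible("genome too short for the configured spacer length")
            for attempt in range(1001):
                if attempt == 1000:
                    raise _Infeasible(
                        f"could not place {n_per_locus} candidate sites for {locus}; "
                        "genome too small for the requested acquisition load"
                    )
                s0 = int(rng.integers(lo, hi, endpoint=True))
                if overlaps(s0 - 12, s0 + m + 12):
                    continue
                if locus == pam_locus:
                    strand = "+" if rng.random() < 0.5 else "-"
                else:
                    orf = next(
                        (o for o in orfs if o.start - 1 <= s0 and s0 + m <= o.end), None
                    )
                    if orf is None:
                        continue
                    strand = orf.strand
                break
            reserved.append((s0 - 12, s0 + m + 12))
            if locus == pam_locus:
                if strand == "+":
                    pam0 = s0 + m + gap
                    genome[pam0 : pam0 + len(cfg.pam_motif)] = list(cfg.pam_motif)
                else:
                    pam0 = s0 - cfg.pam_window
                    rc = revcomp(cfg.pam_motif)
                    genome[pam0 : pam0 + len(rc)] = list(rc)
            fwd = "".join(genome[s0 : s0 + m])
            sites.append(
                SiteTruth(
                    site_id=f"{locus}_site{placed + 1}",
                    locus=locus,
                    strand=strand,
                    ancestral_start=s0 + 1,
                    spacer_seq=fwd if strand == "+" else revcomp(fwd),
                )
            )
    return sites


class _Lineage:
    """The phage genome as it evolves, with coordinate-tracked features."""

    def __init__(self, genome: str, sites: list[SiteTruth], orfs: list[OrfAnnotation]):
        self.seq = genome
        # dynamic per-site state: current 0-based start and current length
        self.pos = {s.site_id: s.ancestral_start - 1 for s in sites}
        self.length = {s.site_id: len(s.spacer_seq) for s in sites}
        self.escaped: set[str] = set()
        self.frozen: set[str] = set()
        # ORFs as mutable [start, end] 1-based
        self.orfs = [[o.orf_id, o.start, o.end, o.strand] for o in orfs]

    def _edit(self, pos0: int, removed: int, inserted: str) -> None:
        self.seq = self.seq[:pos0] + inserted + self.seq[pos0 + removed :]
        delta = len(inserted) - removed
        if delta == 0:
            return
        for sid in self.pos:
            if self.pos[sid] >= pos0 + removed:
                self.pos[sid] += delta
        for orf in self.orfs:
            if orf[1] - 1 >= pos0 + removed:
                orf[1] += delta
                orf[2] += delta
            elif orf[2] > pos0:  # edit inside the ORF
                orf[2] += delta

    def snp(self, site: SiteTruth, rng: np.random.Generator) -> None:
        s0, ln = self.pos[site.site_id], self.length[site.site_id]
        off = int(rng.integers(0, ln))
        old = self.seq[s0 + off]
        new = rng.choice([b for b in "ACGT" if b != old])
        self._edit(s0 + off, 1, str(new))
        self.escaped.add(site.site_id)

    def deletion(self, site: SiteTruth, rng: np.random.Generator) -> bool:
        """Delete 1-12 nt inside the protospacer, verifying the edit really
        abolishes the exact match — a deletion at the footprint edge can be
        a sequence-level no-op when the adjacent bases repeat the deleted
        ones. Returns False (no edit) if no effective deletion is found."""
        sid = site.site_id
        s0, ln = self.pos[sid], self.length[sid]
        fwd = site.spacer_seq if site.strand == "+" else revcomp(site.spacer_seq)
        for _ in range(30):
            d = int(rng.integers(1, min(12, ln - 1), endpoint=True))
            off = int(rng.integers(0, ln - d, endpoint=True))
            lo, hi = max(0, s0 - ln), min(len(self.seq), s0 + 2 * ln)
            local = self.seq[lo : s0 + off] + self.seq[s0 + off + d : hi]
            if fwd in local or revcomp(fwd) in local:
                continue
            self._edit(s0 + off, d, "")
            self.length[sid] = ln - d
            self.escaped.add(sid)
            return True
        return False

    def revert(self, site: SiteTruth) -> None:
        fwd = site.spacer_seq if site.strand == "+" else revcomp(site.spacer_seq)
        s0 = self.pos[site.site_id]
        self._edit(s0, self.length[site.site_id], fwd)
        self.length[site.site_id] = len(fwd)
        self.escaped.discard(site.site_id)
        self.frozen.add(site.site_id)

    def append(self, insert: str) -> int:
        start = len(self.seq) + 1
        self.seq = self.seq + insert
        return start


def simulate(config: SimConfig) -> SimResult:
    """Run one seeded simulation; deterministic under a fixed config."""
    rng = np.random.default_rng(config.seed)
    L, m = config.genome_length, config.spacer_len

    genome = list(random_dna(rng, L))

    # tiled ORFs on alternating strands so both PFS orientations occur
    orfs_anc: list[OrfAnnotation] = []
    pos0, k = 0, 0
    while pos0 + config.orf_length <= L:
        k += 1
        orfs_anc.append(
            OrfAnnotation("ancestral", f"orf{k}", pos0 + 1, pos0 + config.orf_length,
                          "+" if k % 2 else "-")
        )
        pos0 += config.orf_length + config.orf_gap

    # how many candidate sites the acquisition load needs, with headroom
    bact_ids: list[tuple[str, int]] = []
    for year in config.bacteria_years:
        for i in range(config.bacteria_in(year)):
            bact_ids.append((f"B{year}-{i + 1}", year))
    bact_ids.sort(key=lambda t: (t[1], t[0]))
    phage_years = config.phage_years
    acq_years = {
        b: [t for t in phage_years if t <= y] for b, y in bact_ids
    }
    expected = config.acquisition_rate * sum(len(v) for v in acq_years.values())
    n_per_locus = max(40, int(math.ceil(2.5 * expected)))
    try:
        sites = _place_sites(rng, genome, config, orfs_anc, n_per_locus)
    except _Infeasible as exc:
        raise ValueError(str(exc)) from exc
    ancestral = "".join(genome)

    # conserved backbone: random spacers verified absent from the ancestral genome
    backbone: dict[str, list[str]] = {}
    for locus in config.loci:
        pool = []
        while len(pool) < config.backbone_spacers_per_locus:
            cand = random_dna(rng, m)
            if exact_scan(ancestral, cand) or exact_scan(ancestral, revcomp(cand)):
                continue
            pool.append(cand)
        backbone[locus] = pool

    # acquisitions: one site per event, sampled without replacement,
    # contemporary with the acquisition year
    by_locus: dict[str, list[SiteTruth]] = {lc: [] for lc in config.loci}
    for s in sites:
        by_locus[s.locus].append(s)
    arrays: dict[str, dict[str, list[str]]] = {}
    for b, year in bact_ids:
        arrays[b] = {lc: list(backbone[lc]) for lc in config.loci}
        for t in acq_years[b]:
            for locus in config.loci:
                n_acq = int(rng.poisson(config.acquisition_rate))
                if n_acq == 0:
                    continue
                free = [s for s in by_locus[locus] if s.acquired_by is None]
                if len(free) < n_acq:
                    raise ValueError(
                        "infeasible config: candidate protospacer sites exhausted "
                        f"for locus {locus}"
                    )
                chosen = rng.choice(len(free), size=n_acq, replace=False)
                for idx in sorted(int(i) for i in chosen):
                    site = free[idx]
                    site.acquired_by = b
                    site.acquisition_year = t
                    site.spacer_first_year = year
                    arrays[b][locus].append(site.spacer_seq)

    # optional pre-existing-variation plant: an early bacterium already
    # carries a spacer whose protospacer only emerges later by insertion
    truth = SimTruth(config.seed, L, backbone, sites)
    pre_site: Optional[SiteTruth] = None
    pre_insert_year = None
    if config.plant_preexisting and len(phage_years) >= 3:
        b0, y0 = bact_ids[0]
        pre_seq = random_dna(rng, m)
        pre_insert_year = phage_years[-2]
        locus = config.loci[-1]
        arrays[b0][locus].append(pre_seq)
        pre_site = SiteTruth(
            site_id=f"{locus}_preexisting",
            locus=locus,
            strand="+",
            ancestral_start=0,  # not in the ancestral genome
            spacer_seq=pre_seq,
            available_from=pre_insert_year,
            acquired_by=b0,
            acquisition_year=None,
            spacer_first_year=y0,
        )
        sites.append(pre_site)
        truth.preexisting = {
            "spacer_seq": pre_seq,
            "bacterium": b0,
            "bacterium_year": y0,
            "insert_year": pre_insert_year,
            "locus": locus,
        }

    # phage lineage: inherit, mutate, expand, emit isolates
    lineage = _Lineage(ancestral, sites, orfs_anc)
    if pre_site is not None:
        lineage.frozen.add(pre_site.site_id)
    phages: list[DatedSequenceRecord] = []
    orfs_out: list[OrfAnnotation] = []
    extra_orfs = 0
    for t in phage_years:
        if t != phage_years[0]:
            # reversions of previously escaped sites
            for site in sites:
                sid = site.site_id
                if sid in lineage.escaped and sid not in lineage.frozen:
                    if rng.random() < config.reversion_prob:
                        lineage.revert(site)
                        site.reversion_year = t
            # new escapes on sites whose spacer is already circulating
            for site in sites:
                sid = site.site_id
                if (
                    site.acquired_by is not None
                    and site.escape_year is None
                    and sid not in lineage.frozen
                    and site.spacer_first_year is not None
                    and site.spacer_first_year < t
                    and site.available_from is None
                ):
                    if rng.random() < config.escape_prob:
                        if (
                            rng.random() < config.escape_deletion_fraction
                            and lineage.deletion(site, rng)
                        ):
                            site.escape_type = "deletion"
                        else:
                            lineage.snp(site, rng)
                            site.escape_type = "SNP"
                        site.escape_year = t
            # terminal expansion (forced in the pre-existing plant's year)
            force = pre_insert_year == t
            if force or rng.random() < config.expansion_prob:
                insert = random_dna(rng, config.expansion_length)
                if force and pre_site is not None:
                    insert = insert[:100] + pre_site.spacer_seq + insert[100 + m :]
                start = lineage.append(insert)
                if force and pre_site is not None:
                    lineage.pos[pre_site.site_id] = start - 1 + 100
                    lineage.length[pre_site.site_id] = m
                truth.expansions.append(
                    {"year": t, "insert_start": start, "length": len(insert)}
                )
                if config.expansion_length >= 200:
                    extra_orfs += 1
                    lineage.orfs.append(
                        [
                            f"orf_x{extra_orfs}",
                            start + 120 + (m if force else 0),
                            start + len(insert) - 20,
                            "+",
                        ]
                    )
        for j in range(config.phages_in(t)):
            pid = f"P{t}-{j + 1}"
            phages.append(DatedSequenceRecord(pid, lineage.seq, t, role=ROLE_PHAGE))
            for orf_id, a, b_, strand in lineage.orfs:
                orfs_out.append(OrfAnnotation(pid, orf_id, a, b_, strand))

    # locus amplicons: repeat-spacer concatenation, conserved end first
    loci_records: list[DatedSequenceRecord] = []
    for b, year in bact_ids:
        for locus in config.loci:
            rep = config.repeat_of(locus)
            seq = rep + "".join(sp + rep for sp in arrays[b][locus])
            loci_records.append(
                DatedSequenceRecord(f"{b}_{locus}", seq, year, role=ROLE_LOCUS)
            )

    # infection outcomes from the offset-category resistance model
    r_by_cat = {
        "past": config.r_past,
        "contemporary": config.r_contemporary,
        "future": config.r_future,
    }
    pids = [p.id for p in phages]
    pyears = {p.id: p.isolation_year for p in phages}
    byears = {b: y for b, y in bact_ids}
    outcome = np.zeros((len(pids), len(bact_ids)), dtype=int)
    for i, pid in enumerate(pids):
        for j, (b, y) in enumerate(bact_ids):
            r = r_by_cat[categorize(pyears[pid] - y)]
            outcome[i, j] = 0 if rng.random() < r else 1
    matrix = InfectionMatrix(
        outcomes=pd.DataFrame(outcome, index=pids, columns=[b for b, _ in bact_ids]),
        phage_years=pd.Series(pyears),
        bacterium_years=pd.Series(byears),
    )

    return SimResult(config, phages, loci_records, orfs_out, matrix, truth, arrays)


def make_study_scale_scenario(seed: int = 0) -> SimConfig:
    """A configuration at the scale of the original study: 17 bacterial
    isolates over 2007-2013, 30 phage isolates over 2009-2014, a ~46.5 kb
    genome growing toward ~49 kb by terminal expansion, and the published
    arms-race resistance asymmetry (0.95 past / 0.24 contemporary / 0.18
    future)."""
    return SimConfig(
        seed=seed,
        bacteria_year_counts={2007: 2, 2008: 2, 2009: 3, 2010: 3, 2011: 3, 2012: 2, 2013: 2},
        phage_year_counts={y: 5 for y in range(2009, 2015)},
        genome_length=46_500,
        acquisition_rate=0.3,
        expansion_prob=0.5,
        expansion_length=850,
        plant_preexisting=True,
        r_past=0.95,
        r_contemporary=0.24,
        r_future=0.18,
    )
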