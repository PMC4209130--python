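"""Domain types shared across the pipeline.

Coordinates are 0-based, half-open genomic intervals. Transcript offsets are
measured 5'->3' in the direction of transcription: offset ``x`` of a plus-strand
gene maps to genomic base ``start + x``, of a minus-strand gene to
``end - 1 - x`` (so a transcript interval ``[a, b)`` maps to the genomic
interval ``[end - b, end - a)``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

MIN_INTRON = 42  # shortest intron tolerated by the spliceosome in Drosophila
LENGTH_THRESHOLD = 5000  # default short/long boundary (bp)


class ConfigurationError(ValueError):
    """Raised when a generator or simulator is configured inconsistently."""


class InputError(ValueError):
    """Raised when user-supplied data violates an operation's contract."""


@dataclass(frozen=True)
class GeneModel:
    """A gene's strand-aware exon/intron structure and its origin class.

    ``exons`` are non-overlapping half-open genomic intervals sorted by
    coordinate; every gap between consecutive exons (an intron) must be at
    least ``MIN_INTRON`` bp. ``origin`` is ``"maternal"`` (deposited in the
    egg) or ``"zygotic"`` (expressed only from the zygotic genome), or None
    when unknown (e.g. a gene read from a bare GTF).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    origin: Optional[str] = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise InputError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise InputError(f"{self.gene_id}: gene must have at least one exon")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if e <= s:
                raise InputError(f"{self.gene_id}: empty exon [{s},{e})")
            if prev_end is not None:
                if s < prev_end:
                    raise InputError(f"{self.gene_id}: exons overlap or are unsorted")
                if s - prev_end < MIN_INTRON:
                    raise InputError(
                        f"{self.gene_id}: intron of {s - prev_end} bp "
                        f"is below the {MIN_INTRON} bp minimum"
                    )
            prev_end = e
        if self.origin not in (None, "maternal", "zygotic"):
            raise InputError(f"{self.gene_id}: unknown origin {self.origin!r}")

    # -- geometry ---------------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start site (0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def primary_length(self) -> int:
        """Span of the primary transcript (TSS to transcription end), introns included."""
        return self.end - self.start

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def intron_lengths(self) -> Tuple[int, ...]:
        return tuple(
            self.exons[i + 1][0] - self.exons[i][1] for i in range(len(self.exons) - 1)
        )

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def is_intronless(self) -> bool:
        return self.n_introns == 0

    # -- transcript-coordinate helpers ------------------------------------
    def exon_segments_transcript(self) -> Tuple[Tuple[int, int], ...]:
        """Exons as half-open intervals in primary-transcript coordinates, 5'->3'."""
        if self.strand == "+":
            return tuple((s - self.start, e - self.start) for s, e in self.exons)
        return tuple((self.end - e, self.end - s) for s, e in reversed(self.exons))

    def transcript_to_genomic(self, a: int, b: int) -> Tuple[int, int]:
        """Map a transcript-coordinate interval [a, b) to the genomic interval it spans."""
        if self.strand == "+":
            return self.start + a, self.start + b
        return self.end - b, self.end - a

    def exonic_prefix_length(self, offset: float) -> int:
        """Number of exonic bases within the first ``offset`` bp of the primary transcript."""
        total = 0
        for s, e in self.exon_segments_transcript():
            total += max(0, min(e, int(offset)) - s)
        return total


@dataclass(frozen=True)
class CellCycleSchedule:
    """Ordered interphase/mitosis durations of the early embryonic cycles.

    ``cycles`` is a list of (cycle_index, interphase_min, mitosis_min);
    ``zga_cycle`` is the first cycle in which zygotic initiation occurs.
    """

    cycles: Tuple[Tuple[int, float, float], ...]
    zga_cycle: int = 8

    def __post_init__(self):
        if not self.cycles:
            raise ConfigurationError("schedule must contain at least one cycle")
        idx = [c[0] for c in self.cycles]
        if any(j <= i for i, j in zip(idx, idx[1:])):
            raise ConfigurationError("cycle indices must be strictly increasing")
        if any(i <= 0 or m <= 0 for _, i, m in self.cycles):
            raise ConfigurationError("all interphase/mitosis durations must be > 0")

    @classmethod
    def drosophila_default(cls) -> "CellCycleSchedule":
        """Syncytial-blastoderm schedule: cycles 1-9 of ~9 min total, cycles
        10-13 lengthening to 17 min, then a ~60 min interphase in cycle 14.
        Interphase/mitosis splits follow syncytial embryology (interphases
        lengthening from ~6 to ~13 min over cycles 10-13, mitoses of 3-5 min)."""
        cycles = [(i, 6.0, 3.0) for i in range(1, 10)]
        cycles += [(10, 6.5, 3.5), (11, 8.0, 4.0), (12, 10.0, 4.0), (13, 13.0, 4.0)]
        cycles += [(14, 60.0, 5.0)]
        return cls(cycles=tuple(cycles), zga_cycle=8)

    def segments(self) -> list:
        """Chronological (cycle_index, phase, t_start, t_end) tuples; phase in
        {'interphase', 'mitosis'}."""
        out, t = [], 0.0
        for idx, inter, mito in self.cycles:
            out.append((idx, "interphase", t, t + inter))
            t += inter
            out.append((idx, "mitosis", t, t + mito))
            t += mito
        return out

    @property
    def total_duration(self) -> float:
        return sum(i + m for _, i, m in self.cycles)

    def longest_interphase_before(self, t: float) -> float:
        """Longest interphase that has begun by time t (minutes)."""
        best = 0.0
        for _, phase, t0, t1 in self.segments():
            if phase == "interphase" and t0 < t:
                best = max(best, min(t1, t) - t0 if t < t1 else t1 - t0)
        return best


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the abortive-transcription simulator.

    Rates are per minute; lengths in bp. ``abort_prob_at_mitosis`` is the
    probability that a nascent transcript is released and degraded when the
    chromosomes condense; the default of 1.0 models complete abortion.
    ``maternal_abundance`` is the mean number of deposited mRNA copies per
    maternal gene at t=0.

    ``sample_times`` defaults to three interphase points in cycles 11-13 and
    three during the extended 14th cycle, mirroring syncytial-stage collection
    designs. With ``independent_timepoints`` (default) each sample time is
    drawn from an independently simulated embryo pool, as when every
    collection window uses different embryos; set it False to follow a single
    stochastic embryo through time.
    """

    elongation_rate: float = 1400.0
    initiation_rate: float = 2.0
    abort_prob_at_mitosis: float = 1.0
    maternal_abundance: float = 50.0
    maternal_decay_rate: float = 0.005
    zygotic_decay_rate: float = 0.01
    library_mode: str = "total"
    read_length: int = 50
    reads_per_timepoint: int = 100_000
    sample_times: Tuple[float, ...] = (96.0, 110.0, 126.0, 145.0, 165.0, 185.0)
    independent_timepoints: bool = True
    maternal_zygotic_onset: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        for name in (
            "elongation_rate",
            "initiation_rate",
            "maternal_abundance",
            "maternal_decay_rate",
            "zygotic_decay_rate",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.abort_prob_at_mitosis <= 1.0:
            raise ConfigurationError("abort_prob_at_mitosis must be in [0, 1]")
        if self.library_mode not in ("polyA", "total"):
            raise ConfigurationError("library_mode must be 'polyA' or 'total'")
        if self.read_length < 1 or self.reads_per_timepoint < 0:
            raise ConfigurationError("invalid read settings")


@dataclass
class TranscriptPool:
    """Snapshot of the transcript population at one sample time.

    ``complete`` counts mature mRNAs per gene (after decay); ``nascent_*``
    arrays hold, for every engaged polymerase, the owning gene index and its
    current position in bp from the TSS. ``initiated``, ``completed`` and
    ``aborted`` are cumulative per-gene event counters (mass balance:
    initiated = completed + aborted + currently nascent).
    """

    time: float
    gene_ids: Tuple[str, ...]
    complete: np.ndarray
    nascent_gene_index: np.ndarray
    nascent_positions: np.ndarray
    initiated: np.ndarray
    completed: np.ndarray
    aborted: np.ndarray

    def _idx(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise InputError(f"unknown gene {gene_id!r}") from None

    def complete_count(self, gene_id: str) -> int:
        return int(self.complete[self._idx(gene_id)])

    def nascent_positions_of(self, gene_id: str) -> np.ndarray:
        return self.nascent_positions[self.nascent_gene_index == self._idx(gene_id)]

    @property
    def total_nascent(self) -> int:
        return int(len(self.nascent_positions))


@dataclass(frozen=True)
class PhylogenyConfig:
    """Star phylogeny over which orthologous intron lengths evolve.

    The first species is the reference carrying the input annotation
    (branch length 0 by default); each other species' intron log-lengths
    take an independent Gaussian step with SD sigma * branch_length,
    floored at ``min_intron``.
    """

    species: Tuple[str, ...] = (
        "melanogaster",
        "ananassae",
        "pseudoobscura",
        "virilis",
    )
    branch_lengths: Optional[Tuple[float, ...]] = None
    sigma_neutral: float = 0.5
    sigma_constrained: float = 0.05
    min_intron: int = MIN_INTRON
    seed: int = 0

    def __post_init__(self):
        if self.branch_lengths is None:
            # reference species sits at the root; divergence grows down the list
            bl = tuple(0.0 if i == 0 else 0.5 + 0.5 * i for i in range(len(self.species)))
            object.__setattr__(self, "branch_lengths", bl)
        if len(self.branch_lengths) != len(self.species):
            raise ConfigurationError("branch_lengths must match species")
        if not self.sigma_constrained < self.sigma_neutral:
            raise ConfigurationError("sigma_constrained must be < sigma_neutral")
        if self.min_intron < 1:
            raise ConfigurationError("min_intron must be >= 1")
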