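"""Shared domain types for the homoeolog structure/translation pipeline.

All coordinates are 0-based, half-open. Conversion to/from 1-based formats
(GFF3, CT, VCF) happens only inside the readers/writers in :mod:`ribostruct.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

RNA_ALPHABET = set("ACGUN")

#: deterministic nucleotide ordering used for tie-breaks (major-allele calls)
NUC_ORDER = "ACGU"


@dataclass
class TranscriptRecord:
    """A transcript's sequence, subgenome label and genic-region boundaries.

    ``utr5 = [0, cds_start)``, ``cds = [cds_start, cds_end)``,
    ``utr3 = [cds_end, length)``.
    """

    transcript_id: str
    sequence: str
    cds_start: int = 0
    cds_end: int = 0
    subgenome: str = "other"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("T", "U")
        if not self.sequence:
            raise ValueError(f"{self.transcript_id}: empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.transcript_id}: invalid characters {sorted(bad)} in sequence"
            )
        if not (0 <= self.cds_start <= self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"{self.transcript_id}: invalid CDS interval "
                f"[{self.cds_start}, {self.cds_end}) for length {len(self.sequence)}"
            )
        if self.subgenome not in ("A", "B", "other"):
            raise ValueError(f"{self.transcript_id}: bad subgenome {self.subgenome!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def utr5(self) -> Tuple[int, int]:
        return (0, self.cds_start)

    @property
    def cds(self) -> Tuple[int, int]:
        return (self.cds_start, self.cds_end)

    @property
    def utr3(self) -> Tuple[int, int]:
        return (self.cds_end, self.length)

    def region_of(self, pos: int) -> str:
        if not 0 <= pos < self.length:
            raise IndexError(f"{self.transcript_id}: position {pos} out of range")
        if pos < self.cds_start:
            return "utr5"
        if pos < self.cds_end:
            return "cds"
        return "utr3"

    @property
    def cds_sequence(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]


@dataclass
class StopCountProfile:
    """Per-nucleotide RT-stop and coverage counts for one channel/replicate."""

    transcript_id: str
    channel: str  # "plus" | "minus"
    replicate: int
    stops: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.stops = np.asarray(self.stops, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        if self.channel not in ("plus", "minus"):
            raise ValueError(f"channel must be plus/minus, got {self.channel!r}")
        if self.stops.shape != self.coverage.shape:
            raise ValueError(f"{self.transcript_id}: stops/coverage length mismatch")
        if (self.stops < 0).any() or (self.coverage < 0).any():
            raise ValueError(f"{self.transcript_id}: negative counts")
        bad = np.nonzero(self.stops > self.coverage)[0]
        if bad.size:
            raise ValueError(
                f"{self.transcript_id}: stops > coverage at position {int(bad[0])}"
            )

    @property
    def length(self) -> int:
        return int(self.stops.size)


@dataclass
class ReactivityProfile:
    """Normalized per-nucleotide SHAPE reactivity with a missing-data mask.

    ``reactivity`` holds NaN exactly where ``coverage_ok`` is False.
    """

    transcript_id: str
    reactivity: np.ndarray
    coverage_ok: np.ndarray

    def __post_init__(self) -> None:
        self.reactivity = np.asarray(self.reactivity, dtype=float)
        self.coverage_ok = np.asarray(self.coverage_ok, dtype=bool)
        if self.reactivity.shape != self.coverage_ok.shape:
            raise ValueError(f"{self.transcript_id}: mask length mismatch")
        r = self.reactivity[self.coverage_ok]
        if r.size and (np.isnan(r).any() or (r < 0).any()):
            raise ValueError(f"{self.transcript_id}: reactivity must be >= 0 where defined")
        self.reactivity = self.reactivity.copy()
        self.reactivity[~self.coverage_ok] = np.nan

    @property
    def length(self) -> int:
        return int(self.reactivity.size)

    @property
    def n_defined(self) -> int:
        return int(self.coverage_ok.sum())


@dataclass
class StructureResult:
    """Dot-bracket pairing plus per-nucleotide base-pairing probability.

    ``bpp[i]`` is the Boltzmann-ensemble probability that nucleotide *i* is
    paired to any partner (the complement of single-strandedness).
    """

    transcript_id: str
    dotbracket: str
    pairs: frozenset
    bpp: np.ndarray
    mfe: float = 0.0
    bpp_matrix_available: bool = False
    bpp_matrix: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.bpp = np.asarray(self.bpp, dtype=float)
        if len(self.dotbracket) != self.bpp.size:
            raise ValueError(f"{self.transcript_id}: dotbracket/bpp length mismatch")
        if ((self.bpp < -1e-9) | (self.bpp > 1 + 1e-9)).any():
            raise ValueError(f"{self.transcript_id}: bpp outside [0, 1]")
        self.bpp = np.clip(self.bpp, 0.0, 1.0)

    @property
    def length(self) -> int:
        return len(self.dotbracket)

    @property
    def paired_mask(self) -> np.ndarray:
        m = np.zeros(self.length, dtype=bool)
        for i, j in self.pairs:
            m[i] = True
            m[j] = True
        return m


@dataclass
class SNVRecord:
    """A mismatch column between aligned homoeologs, with riboSNitch stats."""

    pair_id: str
    pos_a: int
    pos_b: int
    allele_a: str
    allele_b: str
    mutation_class: str  # transition | transversion
    region: str = "unknown"  # by A-subgenome annotation
    region_b: str = "unknown"
    region_discordant: bool = False
    is_ribosnitch: Optional[bool] = None  # None = untested
    non_isolated: bool = False
    delta_bpp_p: float = np.nan
    delta_react_p: float = np.nan
    delta_bpp_effect: float = np.nan
    delta_react_effect: float = np.nan

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError("SNV alleles must differ")

    @property
    def snv_id(self) -> str:
        return f"{self.pair_id}:{self.pos_a}"


@dataclass
class Indel:
    start: int  # alignment column of the first gap
    length: int
    which_sequence: str  # "A" | "B" (the sequence carrying the gap)


@dataclass
class HomoeologPair:
    """An aligned homoeolog pair with its variant list and summary statistics."""

    a_id: str
    b_id: str
    aligned_a: str
    aligned_b: str
    score: float = 0.0
    snvs: List[SNVRecord] = field(default_factory=list)
    indels: List[Indel] = field(default_factory=list)
    esdc: float = np.nan

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("alignment rows must have equal length")

    @property
    def pair_id(self) -> str:
        return f"{self.a_id}|{self.b_id}"

    def ungapped(self, which: str) -> str:
        row = self.aligned_a if which == "A" else self.aligned_b
        return row.replace("-", "")


@dataclass
class PopulationTable:
    """Per-SNV-site allele counts by subpopulation.

    ``counts[site_id][subpop]`` maps nucleotide -> allele count. Missing calls
    simply do not contribute counts, so counts may sum to less than twice the
    number of accessions.
    """

    counts: Dict[str, Dict[str, Dict[str, int]]]
    n_accessions: Dict[str, int]
    n_skipped: int = 0

    @property
    def subpopulations(self) -> List[str]:
        return sorted(self.n_accessions)

    @property
    def site_ids(self) -> List[str]:
        return list(self.counts)


@dataclass
class FstResult:
    snv_id: str
    frequencies: Dict[str, float]  # per-subpop frequency of the tracked allele
    pi_bar: float
    sigma2_pi: float
    fst: float  # NaN when pi_bar in {0, 1}


@dataclass
class ConservationResult:
    transcript_id: str
    snv_class: str  # ribosnitch | non_ribosnitch
    c_major: int
    c_total: int

    @property
    def ratio(self) -> float:
        return self.c_major / self.c_total if self.c_total else float("nan")
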