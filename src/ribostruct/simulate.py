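"""Synthetic pipeline inputs with known ground truth.

Every generator is fully deterministic under the config seed: each stage
draws from its own ``numpy`` Generator seeded with ``[stream_id, seed]``
(stream ids: 0 homoeolog pairs, 1 probing, 2 expression, 3 population,
4 riboSNitch fixtures), so adding one stage never perturbs another.

What is emulated: homoeolog pairs diverged by point substitutions (default
4.58%, transition:transversion 2:1) and short indels; RT-stop counts whose
(+)-channel excess tracks single-strandedness of the true structure;
negative-binomial RNA/polysome counts with per-pair log2 TE differences;
biallelic genotypes across three subpopulations with near-fixation shared
frequencies and divergent frequencies at riboSNitch sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import StopCountProfile, StructureResult, TranscriptRecord

NUCS = np.array(list("ACGU"))
_TRANSITION = {"A": "G", "G": "A", "C": "U", "U": "C"}
_TRANSVERSIONS = {
    "A": ("C", "U"), "G": ("C", "U"), "C": ("A", "G"), "U": ("A", "G"),
}


@dataclass
class SimulationConfig:
    """Study-condition parameters for all generators."""

    seed: int
    n_pairs: int = 50
    mean_len: int = 1000
    snv_rate: float = 0.0458
    indel_rate: float = 0.002
    te_logfc_sd: float = 1.0
    nb_dispersion: float = 0.05
    mod_rate_unpaired: float = 0.10
    mod_rate_paired: float = 0.01
    background_stop_rate: float = 0.02
    coverage_mean: float = 200.0
    pop_sizes: Dict[str, int] = field(
        default_factory=lambda: {"DW": 13, "DEW": 29, "WEW": 28}
    )
    ribosnitch_fraction: float = 0.0117
    ts_tv_ratio: float = 2.0
    n_replicates_probing: int = 2
    n_replicates_expression: int = 3

    def __post_init__(self) -> None:
        for name in ("snv_rate", "indel_rate", "mod_rate_unpaired",
                     "mod_rate_paired", "background_stop_rate", "ribosnitch_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.snv_rate >= 1:
            raise ValueError("snv_rate must be < 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.mod_rate_unpaired <= self.mod_rate_paired:
            raise ValueError(
                "mod_rate_unpaired must exceed mod_rate_paired (SHAPE chemistry premise)"
            )
        if self.coverage_mean < 0:
            raise ValueError("coverage_mean must be >= 0")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, config.seed])


@dataclass
class VariantTruth:
    kind: str  # "sub" | "indel"
    pos_a: int
    pos_b: int = -1
    allele_a: str = ""
    allele_b: str = ""
    length: int = 0
    which: str = ""  # for indels: sequence carrying the gap


@dataclass
class PairSim:
    record_a: TranscriptRecord
    record_b: TranscriptRecord
    truth: List[VariantTruth]

    @property
    def pair_id(self) -> str:
        return f"{self.record_a.transcript_id}|{self.record_b.transcript_id}"


def _random_regions(rng: np.random.Generator, mean_len: int) -> Tuple[int, int, int]:
    """Transcript length and CDS boundaries (CDS divisible by 3)."""
    length = max(60, int(round(mean_len * rng.uniform(0.8, 1.2))))
    utr5 = max(10, int(round(0.15 * length)))
    cds_len = int(0.6 * length) // 3 * 3
    cds_len = max(30, cds_len)
    if utr5 + cds_len > length - 10:
        cds_len = max(30, (length - 20 - utr5) // 3 * 3)
    return length, utr5, utr5 + cds_len


def _substitute(base: str, rng: np.random.Generator, ts_tv: float) -> str:
    if rng.random() < ts_tv / (ts_tv + 1.0):
        return _TRANSITION[base]
    return _TRANSVERSIONS[base][rng.integers(2)]


def simulate_homoeolog_pairs(config: SimulationConfig) -> List[PairSim]:
    """A/B homoeolog pairs: B derives from A by iid substitutions and indels.

    Indels are 1-3 nt, kept >= 10 nt away from region boundaries; B's region
    boundaries are shifted accordingly so annotations stay valid.
    """
    rng = _rng(config, 0)
    pairs: List[PairSim] = []
    for k in range(config.n_pairs):
        length, cds_start, cds_end = _random_regions(rng, config.mean_len)
        seq_a = "".join(rng.choice(NUCS, size=length))
        truth: List[VariantTruth] = []

        sub_mask = rng.random(length) < config.snv_rate
        # indel placement: away from 0, boundaries and the end
        n_indels = rng.binomial(length, config.indel_rate)
        buffered = set()
        for bnd in (0, cds_start, cds_end, length):
            buffered.update(range(bnd - 10, bnd + 11))
        candidates = [i for i in range(length) if i not in buffered]
        indel_pos = sorted(
            rng.choice(candidates, size=min(n_indels, len(candidates)), replace=False)
        ) if n_indels and candidates else []
        indel_at = {}
        for p in indel_pos:
            ilen = int(rng.integers(1, 4))
            is_del = bool(rng.random() < 0.5)
            indel_at[p] = (ilen, is_del)

        b_chars: List[str] = []
        shift_before_cds_start = 0
        shift_before_cds_end = 0
        i = 0
        while i < length:
            if i in indel_at:
                ilen, is_del = indel_at[i]
                if is_del:  # delete ilen bases from B
                    ilen = min(ilen, length - i - 1)
                    truth.append(VariantTruth("indel", pos_a=i, length=ilen, which="B"))
                    if i < cds_start:
                        shift_before_cds_start -= ilen
                    if i < cds_end:
                        shift_before_cds_end -= ilen
                    i += ilen
                    continue
                else:  # insert ilen random bases into B before position i
                    ins = "".join(rng.choice(NUCS, size=ilen))
                    truth.append(VariantTruth("indel", pos_a=i, length=ilen, which="A"))
                    b_chars.extend(ins)
                    if i < cds_start:
                        shift_before_cds_start += ilen
                    if i < cds_end:
                        shift_before_cds_end += ilen
            base = seq_a[i]
            if sub_mask[i]:
                alt = _substitute(base, rng, config.ts_tv_ratio)
                truth.append(
                    VariantTruth("sub", pos_a=i, pos_b=len(b_chars),
                                 allele_a=base, allele_b=alt)
                )
                b_chars.append(alt)
            else:
                b_chars.append(base)
            i += 1

        seq_b = "".join(b_chars)
        rec_a = TranscriptRecord(
            transcript_id=f"pair{k:04d}_A", sequence=seq_a,
            cds_start=cds_start, cds_end=cds_end, subgenome="A",
        )
        rec_b = TranscriptRecord(
            transcript_id=f"pair{k:04d}_B", sequence=seq_b,
            cds_start=cds_start + shift_before_cds_start,
            cds_end=cds_end + shift_before_cds_end, subgenome="B",
        )
        pairs.append(PairSim(rec_a, rec_b, truth))
    return pairs


# ---------------------------------------------------------------------------
# SHAPE probing

def simulate_probing(
    record: TranscriptRecord,
    true_structure: StructureResult,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[StopCountProfile]:
    """RT-stop counts for +/- channels over replicates.

    Coverage ~ Poisson(coverage_mean) per position; (+) stops ~
    Binomial(coverage, background + mod_rate by paired status); (-) stops ~
    Binomial(coverage, background). Paired status is the ensemble-majority
    call (bpp > 0.5), so the probe sees the Boltzmann ensemble rather than
    the single MFE structure. Stops are independent per position (no
    drop-off cascade).
    """
    rng = rng if rng is not None else _rng(config, 1)
    n = record.length
    paired = true_structure.bpp > 0.5
    mod = np.where(paired, config.mod_rate_paired, config.mod_rate_unpaired)
    p_plus = np.clip(config.background_stop_rate + mod, 0.0, 1.0)
    p_minus = np.full(n, config.background_stop_rate)
    out = []
    for rep in range(1, config.n_replicates_probing + 1):
        for channel, p in (("plus", p_plus), ("minus", p_minus)):
            cov = rng.poisson(config.coverage_mean, size=n)
            stops = rng.binomial(cov, p)
            out.append(
                StopCountProfile(
                    transcript_id=record.transcript_id, channel=channel,
                    replicate=rep, stops=stops, coverage=cov,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Expression counts

def simulate_expression(
    pairs: Sequence[PairSim],
    config: SimulationConfig,
    null_fraction: float = 0.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial RNA/polysome counts with per-pair TE log-fold truth.

    Per pair: base abundance ~ LogNormal; true log2 TE difference ~
    N(0, te_logfc_sd), with ``null_fraction`` of pairs forced to zero.
    Returns (counts, truth); counts columns transcript_id, replicate,
    rna_count, polysome_count; truth columns pair_id, true_log2_te_ratio.
    """
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    rng = _rng(config, 2)
    disp = config.nb_dispersion
    nb_n = 1.0 / disp

    def draw_counts(mu: float) -> int:
        p = nb_n / (nb_n + mu)
        return int(rng.negative_binomial(nb_n, p))

    rows = []
    truth_rows = []
    for sim in pairs:
        abund = float(rng.lognormal(mean=math.log(500.0), sigma=0.8))
        fc = float(rng.normal(0.0, config.te_logfc_sd)) if config.te_logfc_sd > 0 else 0.0
        if null_fraction > 0 and rng.random() < null_fraction:
            fc = 0.0
        te_a, te_b = 2.0 ** (fc / 2.0), 2.0 ** (-fc / 2.0)
        for rec, te in ((sim.record_a, te_a), (sim.record_b, te_b)):
            for rep in range(1, config.n_replicates_expression + 1):
                rows.append(
                    (rec.transcript_id, rep, draw_counts(abund), draw_counts(abund * te))
                )
        truth_rows.append((sim.pair_id, fc))
    counts = pd.DataFrame(
        rows, columns=["transcript_id", "replicate", "rna_count", "polysome_count"]
    )
    truth = pd.DataFrame(truth_rows, columns=["pair_id", "true_log2_te_ratio"])
    return counts, truth


# ---------------------------------------------------------------------------
# Population genotypes

#: divergent reference-allele frequencies at riboSNitch sites, mirroring a
#: domestication sweep (nearly fixed in the cultivated group, intermediate in
#: the domesticated wild relative, rare in the wild group)
DIVERGENT_FREQS = (0.95, 0.28, 0.05)
#: shared sites: reference allele near fixation in every subpopulation
SHARED_FREQ_BETA = (18.0, 2.0)


@dataclass
class PopSiteTruth:
    site_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    is_ribosnitch: bool
    true_freqs: Dict[str, float]  # reference-allele frequency per subpop


def simulate_population(
    snv_sites: Sequence[Tuple[str, str, int, str, str, bool]],
    config: SimulationConfig,
) -> Tuple[List[PopSiteTruth], List[dict], List[str], Dict[str, str]]:
    """Diploid genotypes across subpopulations for a set of SNV sites.

    ``snv_sites``: (site_id, chrom, pos, ref_allele, alt_allele,
    is_ribosnitch). riboSNitch sites get the divergent frequency template
    (one value per subpopulation, in pop_sizes order); other sites share one
    near-fixation frequency across subpopulations. Returns (truth, vcf_sites,
    samples, popmap) ready for :func:`ribostruct.io.write_vcf`.
    """
    rng = _rng(config, 3)
    subpops = list(config.pop_sizes)
    samples = []
    popmap = {}
    for pop in subpops:
        for i in range(config.pop_sizes[pop]):
            name = f"{pop}_{i:03d}"
            samples.append(name)
            popmap[name] = pop
    truths: List[PopSiteTruth] = []
    vcf_sites: List[dict] = []
    for site_id, chrom, pos, ref, alt, is_rs in snv_sites:
        if is_rs:
            freqs = {p: DIVERGENT_FREQS[i % len(DIVERGENT_FREQS)]
                     for i, p in enumerate(subpops)}
        else:
            shared = float(rng.beta(*SHARED_FREQ_BETA))
            freqs = {p: shared for p in subpops}
        for f in freqs.values():
            if not 0 <= f <= 1:
                raise ValueError(f"frequency {f} outside [0, 1]")
        genotypes = []
        for s in samples:
            f = freqs[popmap[s]]
            a1 = 0 if rng.random() < f else 1
            a2 = 0 if rng.random() < f else 1
            genotypes.append((a1, a2))
        truths.append(PopSiteTruth(site_id, chrom, pos, ref, alt, is_rs, freqs))
        vcf_sites.append(
            {"chrom": chrom, "pos": pos, "id": site_id,
             "ref": ref.replace("U", "T"), "alt": alt.replace("U", "T"),
             "genotypes": genotypes}
        )
    return truths, vcf_sites, samples, popmap


# ---------------------------------------------------------------------------
# Constructed riboSNitch fixtures (bistable pseudoknot-excluded switch)

#: switch blocks, in transcript order P1 < P2 < P3 < P4. Stem S1 pairs the
#: G-run P1 with the C-run P3 (8 GC pairs); stem S2 pairs the U-run P2 with
#: the A-run P4 (10 AU pairs plus register freedom). Because P2 sits between P1 and P3 while P4
#: lies beyond P3, every S1 pair crosses every S2 pair, so the two stems are
#: strictly mutually exclusive in a pseudoknot-free ensemble: the switch
#: cannot "split" between the two helices. Filler is N, which never pairs.
_P1 = "G" * 9
_P2 = "U" * 10
_P3 = "C" * 9
_P4 = "A" * 11
#: middle G of P1; the G>A substitution breaks one GC pair of S1 and tips
#: the ensemble from S1 (-24) to S2 (-22) under default pair energies
_SNV_OFFSET_IN_P1 = 4
_SNV_FROM, _SNV_TO = "G", "A"


@dataclass
class SwitchFixture:
    record_a: TranscriptRecord
    record_b: TranscriptRecord
    snv_pos: int  # transcript coordinate (same in A and B; no indels)
    arm_positions: np.ndarray  # positions of the four switch blocks
    is_null: bool


def simulate_switch_pairs(
    config: SimulationConfig, n_pairs: int, null: bool = False
) -> List[SwitchFixture]:
    """Homoeolog pairs built around a bistable two-stem switch.

    Allele A favours stem S1 (P1-P3, 9 GC pairs, -27); the SNV (G>A in the
    middle of P1) removes one GC pair, tipping the ensemble to the crossing-
    incompatible stem S2 (P2-P4) and flipping the paired status of the four
    blocks (~38 positions).

    With ``null=True`` the construct is instead a single G/C hairpin with an
    A>U SNV in the N-filler tail: the A has no pairing partner anywhere in
    the construct and the U can only form one heavily suppressed wobble with
    the hairpin's outermost G, so the structure is unchanged by design.
    """
    rng = _rng(config, 4)
    fixtures = []
    for k in range(n_pairs):
        def filler(lo: int, hi: int) -> str:
            return "N" * int(rng.integers(lo, hi + 1))

        head = filler(25, 40)
        if null:
            gap = filler(4, 7)
            tail_a = filler(10, 14)
            tail_b = filler(70, 90)
            seq = head + _P1 + gap + _P3 + tail_a + "A" + tail_b
            p1 = len(head)
            p3 = p1 + len(_P1) + len(gap)
            arm_positions = np.concatenate(
                [np.arange(p1, p1 + len(_P1)), np.arange(p3, p3 + len(_P3))]
            )
            snv_pos = p3 + len(_P3) + len(tail_a)
            assert seq[snv_pos] == "A"
            seq_b = seq[:snv_pos] + "U" + seq[snv_pos + 1 :]
        else:
            gap12 = filler(4, 7)
            gap23 = filler(4, 7)
            gap34 = filler(4, 7)
            # the lone tail C provides a degenerate alternative partner for
            # the outermost P1 G; it is part of the validated switch margin
            tail = filler(8, 12) + "C" + filler(70, 90)
            seq = head + _P1 + gap12 + _P2 + gap23 + _P3 + gap34 + _P4 + tail
            p1 = len(head)
            p2 = p1 + len(_P1) + len(gap12)
            p3 = p2 + len(_P2) + len(gap23)
            p4 = p3 + len(_P3) + len(gap34)
            arm_positions = np.concatenate(
                [np.arange(p1, p1 + len(_P1)), np.arange(p2, p2 + len(_P2)),
                 np.arange(p3, p3 + len(_P3)), np.arange(p4, p4 + len(_P4))]
            )
            snv_pos = p1 + _SNV_OFFSET_IN_P1
            assert seq[snv_pos] == _SNV_FROM
            seq_b = seq[:snv_pos] + _SNV_TO + seq[snv_pos + 1 :]
        n = len(seq)
        cds_start, cds_end = 0, (n // 3) * 3
        rec_a = TranscriptRecord(f"switch{k:04d}_A", seq, cds_start, cds_end, "A")
        rec_b = TranscriptRecord(f"switch{k:04d}_B", seq_b, cds_start, cds_end, "B")
        fixtures.append(SwitchFixture(rec_a, rec_b, snv_pos, arm_positions, null))
    return fixtures
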