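"""Readers and writers for the pipeline's external formats.

FASTA is handled through Biopython, VCF through cyvcf2, tabular formats
through pandas. Every reader validates its input and reports the offending
file/line/field; every TSV writer prepends a commented header carrying the
package version and the parameters used.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import NUC_ORDER, PopulationTable, StopCountProfile, StructureResult, TranscriptRecord

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def _header_comment(params: Optional[dict] = None) -> str:
    parts = [f"ribostruct v{__version__}"]
    if params:
        parts += [f"{k}={v}" for k, v in sorted(params.items())]
    return "# " + " ".join(parts) + "\n"


def write_tsv(df: pd.DataFrame, path, params: Optional[dict] = None) -> None:
    """Write a DataFrame as TSV with a commented provenance header line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(params))
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> List[TranscriptRecord]:
    """Read transcript sequences; DNA ``T`` is converted to RNA ``U``.

    Region boundaries default to a zero-length CDS and are filled in by
    :func:`read_annotation` / :func:`apply_annotation`.
    """
    records: List[TranscriptRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate transcript id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: empty sequence for {rec.id!r}")
        records.append(TranscriptRecord(transcript_id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[TranscriptRecord], path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.transcript_id, description="")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Region annotation

def read_annotation(path, format: str = "tsv") -> Dict[str, Tuple[int, int]]:
    """Read per-transcript CDS boundaries.

    TSV columns: ``transcript_id  cds_start  cds_end`` (0-based half-open).
    GFF3: CDS features in transcript space (1-based closed, converted on read).
    Returns ``{transcript_id: (cds_start, cds_end)}``.
    """
    if format == "tsv":
        df = pd.read_csv(
            path, sep="\t", comment="#",
            names=["transcript_id", "cds_start", "cds_end"], header=None,
        )
        if df["transcript_id"].duplicated().any():
            dup = df["transcript_id"][df["transcript_id"].duplicated()].iloc[0]
            raise ValueError(f"{path}: overlapping region definitions for {dup!r}")
        out = {}
        for ln, row in enumerate(df.itertuples(index=False), start=1):
            try:
                s, e = int(row.cds_start), int(row.cds_end)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: line {ln}: field cds_start/cds_end not an integer"
                ) from None
            out[str(row.transcript_id)] = (s, e)
        return out
    if format == "gff3":
        spans: Dict[str, List[Tuple[int, int]]] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 9:
                    raise ValueError(f"{path}: line {ln}: field count != 9")
                seqid, _src, ftype, start, end = cols[0], cols[1], cols[2], cols[3], cols[4]
                if ftype != "CDS":
                    continue
                try:
                    s1, e1 = int(start), int(end)
                except ValueError:
                    raise ValueError(f"{path}: line {ln}: field start/end not integer") from None
                spans.setdefault(seqid, []).append((s1 - 1, e1))  # 1-based closed -> half-open
        out = {}
        for tid, parts in spans.items():
            parts.sort()
            for (s0, e0), (s1, e1) in zip(parts, parts[1:]):
                if s1 < e0:
                    raise ValueError(f"{path}: overlapping CDS features for {tid!r}")
            out[tid] = (parts[0][0], parts[-1][1])
        return out
    raise ValueError(f"unknown annotation format {format!r}")


def apply_annotation(
    records: Sequence[TranscriptRecord], regions: Dict[str, Tuple[int, int]]
) -> List[TranscriptRecord]:
    """Attach CDS boundaries to FASTA records; every annotated id must exist."""
    by_id = {r.transcript_id: r for r in records}
    for tid, (s, e) in regions.items():
        if tid not in by_id:
            raise ValueError(f"annotated transcript {tid!r} absent from FASTA")
        rec = by_id[tid]
        if e > rec.length:
            raise ValueError(
                f"{tid}: cds_end {e} exceeds transcript length {rec.length}"
            )
        by_id[tid] = TranscriptRecord(
            transcript_id=rec.transcript_id, sequence=rec.sequence,
            cds_start=s, cds_end=e, subgenome=rec.subgenome,
        )
    return [by_id[r.transcript_id] for r in records]


def read_pair_list(path) -> List[Tuple[str, str]]:
    """TSV with two columns: A-subgenome id, B-subgenome id."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["a_id", "b_id"])
    return [(str(a), str(b)) for a, b in zip(df["a_id"], df["b_id"])]


# ---------------------------------------------------------------------------
# RT-stop counts

STOP_COLUMNS = ["transcript_id", "position", "channel", "replicate", "stops", "coverage"]


def read_stop_counts(path, lengths: Dict[str, int]) -> List[StopCountProfile]:
    """Read per-nucleotide RT-stop counts (long TSV, 0-based positions).

    Positions absent from the file are filled with stops=0, coverage=0.
    ``lengths`` maps transcript id -> transcript length.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing_cols = set(STOP_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    bad = df[df["stops"] > df["coverage"]]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"{path}: stops > coverage at {row['transcript_id']} position {int(row['position'])}"
        )
    profiles = []
    for (tid, channel, rep), grp in df.groupby(
        ["transcript_id", "channel", "replicate"], sort=True
    ):
        if tid not in lengths:
            raise ValueError(f"{path}: unknown transcript id {tid!r}")
        n = lengths[tid]
        stops = np.zeros(n, dtype=np.int64)
        cov = np.zeros(n, dtype=np.int64)
        pos = grp["position"].to_numpy()
        if (pos < 0).any() or (pos >= n).any():
            raise ValueError(f"{path}: {tid}: field position out of range")
        stops[pos] = grp["stops"].to_numpy()
        cov[pos] = grp["coverage"].to_numpy()
        profiles.append(
            StopCountProfile(
                transcript_id=str(tid), channel=str(channel),
                replicate=int(rep), stops=stops, coverage=cov,
            )
        )
    return profiles


def write_stop_counts(profiles: Iterable[StopCountProfile], path, params=None) -> None:
    rows = []
    for p in profiles:
        for i in range(p.length):
            rows.append(
                (p.transcript_id, i, p.channel, p.replicate, int(p.stops[i]), int(p.coverage[i]))
            )
    df = pd.DataFrame(rows, columns=STOP_COLUMNS)
    write_tsv(df, path, params)


# ---------------------------------------------------------------------------
# VCF + population map

def read_popmap(path) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["sample", "subpop"])
    return {str(s): str(p) for s, p in zip(df["sample"], df["subpop"])}


def read_vcf_population(vcf_path, popmap_path) -> PopulationTable:
    """Build per-subpopulation allele counts from a VCF (GT only).

    Only biallelic SNV sites are used; indel and multiallelic sites are
    skipped and counted. Missing calls (./.) contribute nothing. Diploid
    genotypes contribute two allele counts.
    """
    from cyvcf2 import VCF

    popmap = read_popmap(popmap_path)
    vcf = VCF(str(vcf_path))
    for s in vcf.samples:
        if s not in popmap:
            raise ValueError(f"sample {s!r} in VCF missing from popmap")
    subpops = sorted(set(popmap.values()))
    n_acc = {p: sum(1 for s in vcf.samples if popmap[s] == p) for p in subpops}
    counts: Dict[str, Dict[str, Dict[str, int]]] = {}
    n_skipped = 0
    for v in vcf:
        alts = v.ALT
        if len(v.REF) != 1 or len(alts) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        ref = v.REF.replace("T", "U").upper()
        alt = alts[0].replace("T", "U").upper()
        site_id = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS - 1}"
        site = {p: {n: 0 for n in NUC_ORDER} for p in subpops}
        for sample, gt in zip(vcf.samples, v.genotypes):
            pop = popmap[sample]
            for allele_idx in gt[:-1]:  # last entry is phasing flag
                if allele_idx < 0:
                    continue
                site[pop][ref if allele_idx == 0 else alt] += 1
        counts[site_id] = site
    if n_skipped:
        logger.info("read_vcf_population: skipped %d non-biallelic-SNV sites", n_skipped)
    return PopulationTable(counts=counts, n_accessions=n_acc, n_skipped=n_skipped)


def write_vcf(path, sites: Sequence[dict], samples: Sequence[str]) -> None:
    """Write a minimal GT-only VCF (v4.2).

    Each site dict: ``chrom, pos`` (0-based, converted to 1-based on write),
    ``id, ref, alt, genotypes`` (list of (a1, a2) with -1 = missing).
    """
    chroms = []
    for s in sites:
        if s["chrom"] not in chroms:
            chroms.append(s["chrom"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for s in sites:
            gts = [
                "./." if a1 < 0 or a2 < 0 else f"{a1}/{a2}"
                for a1, a2 in s["genotypes"]
            ]
            fh.write(
                f"{s['chrom']}\t{s['pos'] + 1}\t{s['id']}\t{s['ref']}\t{s['alt']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Secondary structure: dot-bracket and CT

def pairs_to_dotbracket(pairs: Iterable[Tuple[int, int]], length: int) -> str:
    db = ["."] * length
    for i, j in pairs:
        if not (0 <= i < j < length):
            raise ValueError(f"pair ({i}, {j}) out of range for length {length}")
        db[i] = "("
        db[j] = ")"
    return "".join(db)


def dotbracket_to_pairs(db: str) -> frozenset:
    stack: List[int] = []
    pairs = set()
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced parentheses at position {i}")
            pairs.add((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced parentheses: unmatched '(' at position {stack[-1]}")
    return frozenset(pairs)


def write_dotbracket(structure: StructureResult, path, sequence: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        fh.write(f">{structure.transcript_id}\n")
        if sequence is not None:
            fh.write(sequence + "\n")
        fh.write(structure.dotbracket + "\n")


def read_dotbracket(path) -> Dict[str, frozenset]:
    out = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
            elif set(line) <= set("()."):
                if name is None:
                    raise ValueError(f"{path}: dot-bracket line before any '>' header")
                out[name] = dotbracket_to_pairs(line)
    return out


def write_ct(sequence: str, pairs: Iterable[Tuple[int, int]], path, title: str = "") -> None:
    """Write the de-facto 6-column CT format (1-based coordinates)."""
    n = len(sequence)
    partner = [0] * n
    for i, j in pairs:
        partner[i] = j + 1
        partner[j] = i + 1
    with open(path, "w") as fh:
        fh.write(f"{n} {title}\n")
        for i in range(n):
            fh.write(f"{i + 1} {sequence[i]} {i} {i + 2 if i + 1 < n else 0} {partner[i]} {i + 1}\n")


def read_ct(path) -> Tuple[str, frozenset]:
    """Read a CT file; returns (sequence, pairs) with 0-based pairs."""
    with open(path) as fh:
        header = fh.readline()
        try:
            n = int(header.split()[0])
        except (IndexError, ValueError):
            raise ValueError(f"{path}: line 1: bad CT header") from None
        seq = []
        pairs = set()
        for ln, line in enumerate(fh, start=2):
            cols = line.split()
            if not cols:
                continue
            if len(cols) < 6:
                raise ValueError(f"{path}: line {ln}: expected 6 CT columns")
            idx = int(cols[0]) - 1
            seq.append(cols[1])
            partner = int(cols[4])
            if partner > 0 and partner - 1 > idx:
                pairs.add((idx, partner - 1))
    if len(seq) != n:
        raise ValueError(f"{path}: CT header count {n} != {len(seq)} rows")
    return "".join(seq), frozenset(pairs)


# ---------------------------------------------------------------------------
# Reactivity / BPP tables

def write_reactivity_table(profiles, path, params=None) -> None:
    rows = []
    for p in profiles:
        for i in range(p.length):
            v = p.reactivity[i]
            rows.append((p.transcript_id, i, None if np.isnan(v) else v))
    df = pd.DataFrame(rows, columns=["transcript_id", "position", "reactivity"])
    write_tsv(df, path, params)


def read_reactivity_table(path, lengths: Dict[str, int]):
    from .types import ReactivityProfile

    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for tid, grp in df.groupby("transcript_id", sort=True):
        n = lengths[str(tid)]
        react = np.full(n, np.nan)
        react[grp["position"].to_numpy()] = grp["reactivity"].to_numpy()
        out.append(
            ReactivityProfile(
                transcript_id=str(tid), reactivity=react, coverage_ok=~np.isnan(react)
            )
        )
    return out


def write_bpp_table(structures: Iterable[StructureResult], path, params=None) -> None:
    rows = []
    for s in structures:
        for i in range(s.length):
            rows.append((s.transcript_id, i, s.bpp[i]))
    df = pd.DataFrame(rows, columns=["transcript_id", "position", "bpp"])
    write_tsv(df, path, params)
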