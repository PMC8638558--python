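"""End-to-end pipeline: simulate -> reactivity -> fold -> te -> asymmetry ->
ribosnitch -> popgen -> report.

All stage outputs are TSV/JSON files in one output directory, each carrying
the config hash in a commented header; reruns with the same config are
byte-identical. Stages can be run selectively; a stage whose upstream output
is missing fails with an error naming the missing stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .types import TranscriptRecord
from .simulate import (
    PairSim, SimulationConfig, simulate_expression, simulate_homoeolog_pairs,
    simulate_population, simulate_probing, _rng,
)
from .reactivity import reactivity_pipeline
from .folding import EnergyModel, fold_transcript, mean_bpp_by_region, ppv
from .translation import differential_te, translation_efficiency
from .asymmetry import asymmetry_summary, delta_correlation, pair_bpp_test
from .variants import (
    align_pair, call_ribosnitches, esdc, extract_variants,
    finalize_ribosnitch_calls, ribosnitch_region_ratios, snv_ratio,
)
from .popgen import class_contrast, fst_for_site

logger = logging.getLogger(__name__)

STAGES = ["simulate", "reactivity", "fold", "te", "asymmetry", "ribosnitch", "popgen", "report"]

#: valid configuration keys with defaults; ``seed`` is required and has none
CONFIG_DEFAULTS: Dict[str, object] = {
    "n_pairs": 12,
    "mean_len": 150,
    "snv_rate": 0.0458,
    "indel_rate": 0.002,
    "te_logfc_sd": 1.0,
    "nb_dispersion": 0.05,
    "mod_rate_unpaired": 0.10,
    "mod_rate_paired": 0.01,
    "background_stop_rate": 0.02,
    "coverage_mean": 200.0,
    "pop_sizes": {"DW": 13, "DEW": 29, "WEW": 28},
    "ribosnitch_fraction": 0.0117,
    "alpha": 0.05,
    "min_coverage": 50,
    "window": 50,
    "min_effect": 0.1,
    "decile": 0.10,
    "fold_window": 300,
    "fold_step": 150,
    "reference_population": "DW",
}


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def validate_config(raw: dict) -> dict:
    valid = set(CONFIG_DEFAULTS) | {"seed"}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(valid)}"
        )
    if "seed" not in raw:
        raise ValueError("config key 'seed' is required (no silent default)")
    cfg = dict(CONFIG_DEFAULTS)
    cfg.update(raw)
    cfg["seed"] = int(cfg["seed"])
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.md5(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:12]


def _sim_config(cfg: dict) -> SimulationConfig:
    return SimulationConfig(
        seed=cfg["seed"], n_pairs=cfg["n_pairs"], mean_len=cfg["mean_len"],
        snv_rate=cfg["snv_rate"], indel_rate=cfg["indel_rate"],
        te_logfc_sd=cfg["te_logfc_sd"], nb_dispersion=cfg["nb_dispersion"],
        mod_rate_unpaired=cfg["mod_rate_unpaired"],
        mod_rate_paired=cfg["mod_rate_paired"],
        background_stop_rate=cfg["background_stop_rate"],
        coverage_mean=cfg["coverage_mean"], pop_sizes=dict(cfg["pop_sizes"]),
        ribosnitch_fraction=cfg["ribosnitch_fraction"],
    )


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream output {path.name}: run stage '{stage}' first"
        )
    return path


def _read_transcripts(outdir: Path) -> List[TranscriptRecord]:
    recs = rio.read_fasta(_require(outdir / "transcripts.fa", "simulate"))
    regions = rio.read_annotation(_require(outdir / "annotation.tsv", "simulate"))
    recs = rio.apply_annotation(recs, regions)
    out = []
    for r in recs:
        sub = "A" if r.transcript_id.endswith("_A") else (
            "B" if r.transcript_id.endswith("_B") else "other")
        out.append(TranscriptRecord(r.transcript_id, r.sequence, r.cds_start,
                                    r.cds_end, sub))
    return out


class Pipeline:
    """Stage runner bound to one config and output directory."""

    def __init__(self, cfg: dict, outdir) -> None:
        self.cfg = cfg
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.hash = config_hash(cfg)
        self.params = {"config_hash": self.hash, "seed": cfg["seed"]}
        self.model = EnergyModel()

    # -- stage: simulate ----------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.cfg
        sim = _sim_config(cfg)
        pairs = simulate_homoeolog_pairs(sim)
        records = [r for p in pairs for r in (p.record_a, p.record_b)]
        rio.write_fasta(records, self.outdir / "transcripts.fa")
        ann = pd.DataFrame(
            [(r.transcript_id, r.cds_start, r.cds_end) for r in records]
        )
        ann.to_csv(self.outdir / "annotation.tsv", sep="\t", header=False, index=False)
        pd.DataFrame(
            [(p.record_a.transcript_id, p.record_b.transcript_id) for p in pairs]
        ).to_csv(self.outdir / "pairs.tsv", sep="\t", header=False, index=False)
        logger.info("simulate: %d pairs", len(pairs))

        # in-silico folds define the probing ground truth
        structures = {}
        bpp_rows = []
        for r in records:
            s = fold_transcript(r.sequence, self.model, None, r.transcript_id,
                                cfg["fold_window"], cfg["fold_step"])
            structures[r.transcript_id] = s
            bpp_rows.append(s)
        rio.write_bpp_table(bpp_rows, self.outdir / "bpp_insilico.tsv", self.params)
        with open(self.outdir / "dotbracket_insilico.db", "w") as fh:
            for r in records:
                s = structures[r.transcript_id]
                fh.write(f">{r.transcript_id}\n{s.dotbracket}\n")

        rng = _rng(sim, 1)
        stop_profiles = []
        for r in records:
            stop_profiles.extend(simulate_probing(r, structures[r.transcript_id], sim, rng))
        rio.write_stop_counts(stop_profiles, self.outdir / "stops.tsv", self.params)

        counts, te_truth = simulate_expression(pairs, sim)
        rio.write_tsv(counts, self.outdir / "counts.tsv", self.params)
        truth = {
            "te": {row.pair_id: row.true_log2_te_ratio for row in te_truth.itertuples()},
            "n_substitutions": {
                p.pair_id: sum(1 for v in p.truth if v.kind == "sub") for p in pairs
            },
        }
        with open(self.outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, sort_keys=True, indent=1)

    # -- stage: reactivity --------------------------------------------------
    def stage_reactivity(self) -> None:
        records = _read_transcripts(self.outdir)
        lengths = {r.transcript_id: r.length for r in records}
        profiles = rio.read_stop_counts(
            _require(self.outdir / "stops.tsv", "simulate"), lengths
        )
        merged, corr = reactivity_pipeline(profiles, self.cfg["min_coverage"])
        rio.write_reactivity_table(merged, self.outdir / "react.tsv", self.params)
        pd.DataFrame(sorted(corr.items()), columns=["transcript_id", "replicate_r"]).to_csv(
            self.outdir / "replicate_correlation.tsv", sep="\t", index=False
        )
        logger.info("reactivity: %d transcripts", len(merged))

    # -- stage: fold (in vivo) ----------------------------------------------
    def stage_fold(self) -> None:
        records = _read_transcripts(self.outdir)
        lengths = {r.transcript_id: r.length for r in records}
        reacts = {
            p.transcript_id: p
            for p in rio.read_reactivity_table(
                _require(self.outdir / "react.tsv", "reactivity"), lengths
            )
        }
        insilico = rio.read_dotbracket(
            _require(self.outdir / "dotbracket_insilico.db", "simulate")
        )
        structures = []
        ppv_rows = []
        for r in records:
            react = reacts[r.transcript_id].reactivity if r.transcript_id in reacts else None
            s = fold_transcript(r.sequence, self.model, react, r.transcript_id,
                                self.cfg["fold_window"], self.cfg["fold_step"])
            structures.append(s)
            ppv_rows.append(
                (r.transcript_id, ppv(s.pairs, insilico[r.transcript_id]))
            )
        rio.write_bpp_table(structures, self.outdir / "bpp_invivo.tsv", self.params)
        with open(self.outdir / "dotbracket_invivo.db", "w") as fh:
            for s in structures:
                fh.write(f">{s.transcript_id}\n{s.dotbracket}\n")
        rio.write_tsv(
            pd.DataFrame(ppv_rows, columns=["transcript_id", "ppv"]),
            self.outdir / "ppv.tsv", self.params,
        )

    # -- stage: te ------------------------------------------------------------
    def stage_te(self) -> None:
        records = _read_transcripts(self.outdir)
        lengths = {r.transcript_id: r.length for r in records}
        counts = pd.read_csv(_require(self.outdir / "counts.tsv", "simulate"),
                             sep="\t", comment="#")
        te = translation_efficiency(counts, lengths)
        pairs = rio.read_pair_list(_require(self.outdir / "pairs.tsv", "simulate"))
        diff = differential_te(pairs, te, self.cfg["alpha"])
        out = te.copy()
        out["te_rep"] = out["te_rep"].map(lambda v: ",".join(f"{x:.6g}" for x in v))
        rio.write_tsv(out, self.outdir / "te.tsv", self.params)
        rio.write_tsv(diff, self.outdir / "te_differential.tsv", self.params)

    # -- stage: asymmetry -----------------------------------------------------
    def stage_asymmetry(self) -> None:
        records = {r.transcript_id: r for r in _read_transcripts(self.outdir)}
        lengths = {t: r.length for t, r in records.items()}
        bpp = pd.read_csv(_require(self.outdir / "bpp_invivo.tsv", "fold"),
                          sep="\t", comment="#")
        bpp_map = {
            tid: grp.sort_values("position")["bpp"].to_numpy()
            for tid, grp in bpp.groupby("transcript_id")
        }
        pairs = rio.read_pair_list(self.outdir / "pairs.tsv")
        diff = pd.read_csv(_require(self.outdir / "te_differential.tsv", "te"),
                           sep="\t", comment="#")
        te_ratio = dict(zip(zip(diff["a_id"], diff["b_id"]), diff["log2_te_ratio"]))
        rows = []
        for a_id, b_id in pairs:
            if a_id not in bpp_map or b_id not in bpp_map:
                continue
            try:
                p, direction = pair_bpp_test(bpp_map[a_id], bpp_map[b_id], self.cfg["alpha"])
            except ValueError:
                continue
            d_bpp = float(np.nanmean(bpp_map[a_id]) - np.nanmean(bpp_map[b_id]))
            rows.append((f"{a_id}|{b_id}", p, direction, d_bpp,
                         te_ratio.get((a_id, b_id), np.nan)))
        df = pd.DataFrame(rows, columns=["pair_id", "p", "direction", "delta_bpp", "delta_te"])
        rio.write_tsv(df, self.outdir / "asymmetry.tsv", self.params)

    # -- stage: ribosnitch ----------------------------------------------------
    def stage_ribosnitch(self) -> None:
        records = {r.transcript_id: r for r in _read_transcripts(self.outdir)}
        lengths = {t: r.length for t, r in records.items()}
        reacts = {
            p.transcript_id: p
            for p in rio.read_reactivity_table(
                _require(self.outdir / "react.tsv", "reactivity"), lengths
            )
        }
        bpp = pd.read_csv(_require(self.outdir / "bpp_invivo.tsv", "fold"),
                          sep="\t", comment="#")
        bpp_map = {
            tid: grp.sort_values("position")["bpp"].to_numpy()
            for tid, grp in bpp.groupby("transcript_id")
        }
        pair_ids = rio.read_pair_list(self.outdir / "pairs.tsv")
        all_snvs = []
        pair_rows = []
        for a_id, b_id in pair_ids:
            ra, rb = records[a_id], records[b_id]
            pair = align_pair(ra.sequence, rb.sequence, a_id, b_id)
            extract_variants(pair, ra, rb)
            if a_id in reacts and b_id in reacts:
                pair.esdc = esdc(
                    reacts[a_id].reactivity, reacts[b_id].reactivity, pair
                )
                call_ribosnitches(
                    pair, bpp_map[a_id], bpp_map[b_id],
                    reacts[a_id].reactivity, reacts[b_id].reactivity,
                    window=self.cfg["window"],
                )
            all_snvs.extend(pair.snvs)
            pair_rows.append(
                (pair.pair_id, len(pair.snvs), len(pair.indels),
                 snv_ratio(pair), pair.esdc)
            )
        finalize_ribosnitch_calls(all_snvs, self.cfg["alpha"], self.cfg["min_effect"])
        snv_df = pd.DataFrame(
            [
                (s.pair_id, s.pos_a, s.pos_b, s.allele_a, s.allele_b,
                 s.mutation_class, s.region, s.region_discordant, s.non_isolated,
                 s.delta_bpp_p, s.delta_react_p, s.delta_bpp_effect,
                 s.delta_react_effect,
                 "NA" if s.is_ribosnitch is None else str(bool(s.is_ribosnitch)))
                for s in all_snvs
            ],
            columns=["pair_id", "pos_a", "pos_b", "allele_a", "allele_b",
                     "mutation_class", "region", "region_discordant",
                     "non_isolated", "delta_bpp_p", "delta_react_p",
                     "delta_bpp_effect", "delta_react_effect", "is_ribosnitch"],
        )
        rio.write_tsv(snv_df, self.outdir / "snv.tsv",
                      {**self.params, "window": self.cfg["window"],
                       "alpha": self.cfg["alpha"], "min_effect": self.cfg["min_effect"]})
        rio.write_tsv(
            pd.DataFrame(pair_rows, columns=["pair_id", "n_snv", "n_indel",
                                             "snv_ratio", "esdc"]),
            self.outdir / "pair_variants.tsv", self.params,
        )

    # -- stage: popgen ----------------------------------------------------------
    def stage_popgen(self) -> None:
        snv = pd.read_csv(_require(self.outdir / "snv.tsv", "ribosnitch"),
                          sep="\t", comment="#",
                          dtype={"is_ribosnitch": str}, keep_default_na=False)
        sim = _sim_config(self.cfg)
        sites = []
        for row in snv.itertuples():
            if row.is_ribosnitch == "NA":
                continue
            a_id = row.pair_id.split("|")[0]
            sites.append(
                (f"{a_id}:{row.pos_a}", a_id, int(row.pos_a),
                 row.allele_a, row.allele_b, row.is_ribosnitch == "True")
            )
        truths, vcf_sites, samples, popmap = simulate_population(sites, sim)
        rio.write_vcf(self.outdir / "population.vcf", vcf_sites, samples)
        pd.DataFrame(sorted(popmap.items())).to_csv(
            self.outdir / "popmap.tsv", sep="\t", header=False, index=False
        )
        pop_table = rio.read_vcf_population(
            self.outdir / "population.vcf", self.outdir / "popmap.tsv"
        )
        rows = []
        rs_flag = {t.site_id: t.is_ribosnitch for t in truths}
        for site_id in pop_table.site_ids:
            res = fst_for_site(pop_table, site_id)
            rows.append((site_id, rs_flag.get(site_id, False), res.pi_bar,
                         res.sigma2_pi, res.fst))
        fst_df = pd.DataFrame(
            rows, columns=["site_id", "is_ribosnitch", "pi_bar", "sigma2_pi", "fst"]
        )
        rio.write_tsv(fst_df, self.outdir / "fst.tsv", self.params)

    # -- stage: report ------------------------------------------------------------
    def stage_report(self) -> dict:
        summary: Dict[str, object] = {"config_hash": self.hash, "seed": self.cfg["seed"]}
        diff = pd.read_csv(_require(self.outdir / "te_differential.tsv", "te"),
                           sep="\t", comment="#")
        summary["n_pairs_te"] = int(len(diff))
        summary["te_significant_fraction"] = (
            float((diff["direction"] != "NSD").mean()) if len(diff) else 0.0
        )
        asym = pd.read_csv(_require(self.outdir / "asymmetry.tsv", "asymmetry"),
                           sep="\t", comment="#")
        frac = asymmetry_summary(asym["direction"])
        summary["bpp_asymmetry"] = {k: float(v) for k, v in frac.items()}
        r, p, n = delta_correlation(asym["delta_bpp"], asym["delta_te"])
        summary["delta_bpp_te_correlation"] = {"r": r, "p": p, "n": n}
        snv = pd.read_csv(self.outdir / "snv.tsv", sep="\t", comment="#",
                          dtype={"is_ribosnitch": str}, keep_default_na=False)
        tested = snv[snv["is_ribosnitch"] != "NA"]
        summary["n_snv"] = int(len(snv))
        summary["n_snv_tested"] = int(len(tested))
        summary["n_ribosnitch"] = int((tested["is_ribosnitch"] == "True").sum())
        summary["ribosnitch_ratio"] = (
            summary["n_ribosnitch"] / summary["n_snv_tested"]
            if summary["n_snv_tested"] else float("nan")
        )
        region_ratios = {}
        for region in ("utr5", "cds", "utr3"):
            sub = tested[tested["region"] == region]
            region_ratios[region] = (
                float((sub["is_ribosnitch"] == "True").mean()) if len(sub)
                else float("nan")
            )
        summary["ribosnitch_region_ratios"] = region_ratios
        pv = pd.read_csv(self.outdir / "ppv.tsv", sep="\t", comment="#")
        summary["mean_ppv_invivo_vs_insilico"] = float(pv["ppv"].mean())
        fst_df = pd.read_csv(self.outdir / "fst.tsv", sep="\t", comment="#")
        rs = fst_df[fst_df["is_ribosnitch"]]["fst"].dropna()
        non = fst_df[~fst_df["is_ribosnitch"]]["fst"].dropna()
        if len(rs) >= 3 and len(non) >= 3:
            summary["fst_contrast"] = {
                k: float(v) for k, v in class_contrast(rs, non, test="wilcoxon").items()
            }
        summary["mean_fst_ribosnitch"] = float(rs.mean()) if len(rs) else float("nan")
        summary["mean_fst_non_ribosnitch"] = float(non.mean()) if len(non) else float("nan")
        with open(self.outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, sort_keys=True, indent=1, allow_nan=True)
        (self.outdir / "report.txt").write_text(make_report(summary))
        return summary


def make_report(summary: dict) -> str:
    """Human-readable rendition of the summary JSON (numbers match exactly)."""
    lines = [
        f"ribostruct pipeline report (config {summary['config_hash']}, seed {summary['seed']})",
        "",
        f"homoeolog pairs with TE: {summary['n_pairs_te']}",
        f"significant TE asymmetry: {100 * summary['te_significant_fraction']:.1f}%",
    ]
    asym = summary.get("bpp_asymmetry", {})
    if asym:
        lines.append(
            "BPP asymmetry: A higher {:.1f}%, B higher {:.1f}%, NSD {:.1f}% (n={})".format(
                100 * asym["A_higher"], 100 * asym["B_higher"], 100 * asym["NSD"],
                int(asym["n"]),
            )
        )
    lines += [
        f"SNVs: {summary['n_snv']} (tested {summary['n_snv_tested']})",
        f"riboSNitches: {summary['n_ribosnitch']} "
        f"(ratio {100 * summary['ribosnitch_ratio']:.2f}% of tested)"
        if summary["n_snv_tested"] else "riboSNitches: none tested",
        f"mean PPV (in vivo vs in silico): {summary['mean_ppv_invivo_vs_insilico']:.3f}",
        f"mean F_ST riboSNitch: {summary['mean_fst_ribosnitch']:.4f}; "
        f"non-riboSNitch: {summary['mean_fst_non_ribosnitch']:.4f}",
    ]
    dc = summary.get("delta_bpp_te_correlation", {})
    if dc:
        lines.append(
            f"|dBPP| vs |dTE| Pearson r = {dc['r']:.3f} (p = {dc['p']:.3g}, n = {dc['n']})"
        )
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: dict, outdir, stages: Optional[Sequence[str]] = None) -> dict:
    """Run the requested stages (default: all) and return the summary dict."""
    cfg = validate_config(dict(cfg))
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
    pipe = Pipeline(cfg, outdir)
    summary: dict = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("running stage %s", stage)
        result = getattr(pipe, f"stage_{stage}")()
        if stage == "report":
            summary = result
    return summary
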