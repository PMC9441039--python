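"""End-to-end orchestration: simulate/load -> normalize -> DE -> targets ->
competing pairs -> network -> export.

A run is driven by one :class:`PipelineConfig` (usually parsed from YAML),
writes every intermediate table to the output directory, and finishes with a
summary JSON whose content is fully determined by the input data and seed.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import cerna, expression, network, simulate, targets

log = logging.getLogger("cernet")


@dataclass
class PipelineConfig:
    """Either a ``simulate`` block or explicit data paths, plus thresholds."""

    outdir: str = "cernet_run"
    simulate: dict | None = None
    # data paths (used when simulate is None)
    mrna_counts: str | None = None
    lncrna_counts: str | None = None
    mirna_counts: str | None = None
    mrna_lengths: str | None = None
    lncrna_lengths: str | None = None
    mrna_fasta: str | None = None
    lncrna_fasta: str | None = None
    mirna_fasta: str | None = None
    groups: dict[str, str] = field(default_factory=dict)
    # thresholds
    min_abs_log2fc: float = 1.0
    de_max_fdr: float = 0.05
    de_max_p: float = 0.05
    pseudocount: float = 1.0
    min_site_type: str = "7mer-A1"
    regime: str = "lenient"
    mirna_universe: str = "interacting"
    seed: int = 0

    def __post_init__(self) -> None:
        paths = [self.mrna_counts, self.lncrna_counts, self.mirna_counts]
        if self.simulate is not None and any(p is not None for p in paths):
            raise ValueError("config must give either a simulate block or data paths, not both")
        if self.simulate is None and not all(p is not None for p in paths):
            raise ValueError("config must give either a simulate block or all three count paths")
        if self.regime not in ("lenient", "strict"):
            raise ValueError(f"unknown regime {self.regime!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim_cfg = simulate.SimulationConfig(
            **{**config.simulate, "seed": config.simulate.get("seed", config.seed)}
        )
        ds = simulate.generate_dataset(sim_cfg, outdir=Path(config.outdir) / "simulated")
        return (
            ds.mrna_counts,
            ds.lncrna_counts,
            ds.mirna_counts,
            ds.mrna_seqs,
            ds.lncrna_seqs,
            ds.mirna_seqs,
            ds,
        )
    mrna = expression.read_counts(
        config.mrna_counts, "mRNA", config.groups, config.mrna_lengths
    )
    lnc = expression.read_counts(
        config.lncrna_counts, "lncRNA", config.groups, config.lncrna_lengths
    )
    mirna = expression.read_counts(config.mirna_counts, "miRNA", config.groups)
    return (
        mrna,
        lnc,
        mirna,
        targets.read_fasta(config.mrna_fasta),
        targets.read_fasta(config.lncrna_fasta),
        targets.read_fasta(config.mirna_fasta),
        None,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the summary dict written to summary.json."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> dict:
    with open(out / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    stage = "load"
    try:
        mrna, lnc, mirna, mrna_seqs, lnc_seqs, mirna_seqs, ds = _load_inputs(config)
        log.info("loaded matrices: %d mRNA, %d lncRNA, %d miRNA",
                 len(mrna.ids), len(lnc.ids), len(mirna.ids))

        stage = "normalize"
        mrna_n = expression.normalize(mrna)
        lnc_n = expression.normalize(lnc)
        mirna_n = expression.normalize(mirna)

        stage = "differential_expression"
        de_tables = {}
        de_sets = {}
        de_calls: dict[str, str] = {}
        for name, mat in (("mrna", mrna_n), ("lncrna", lnc_n), ("mirna", mirna_n)):
            t = expression.de_test(mat, pseudocount=config.pseudocount)
            t = expression.filter_de(
                t,
                mat.class_label,
                min_abs_log2fc=config.min_abs_log2fc,
                max_fdr=config.de_max_fdr,
                max_p=config.de_max_p,
            )
            expression.write_de_table(t, out / f"de_{name}.tsv")
            de_tables[name] = t
            de_sets[name] = set(t.index[t["call"] != "not_de"].astype(str))
            de_calls.update(
                {str(i): c for i, c in t["call"].items() if c != "not_de"}
            )
            log.info("DE %s: %d of %d (gates: |log2FC|>=%.2f, %s)",
                     name, len(de_sets[name]), len(t), config.min_abs_log2fc,
                     "p<%.3g" % config.de_max_p if name == "mirna"
                     else "FDR<%.3g" % config.de_max_fdr)

        stage = "target_prediction"
        de_mirna_seqs = {k: v for k, v in mirna_seqs.items() if k in de_sets["mirna"]}
        de_tr_seqs = {
            k: v
            for src in (lnc_seqs, mrna_seqs)
            for k, v in src.items()
            if k in de_sets["lncrna"] or k in de_sets["mrna"]
        }
        interactions = targets.predict_targets(
            de_mirna_seqs, de_tr_seqs, min_site_type=config.min_site_type
        )
        targets.write_interactions_tsv(interactions, out / "interactions.tsv")
        log.info("predicted %d miRNA-transcript interactions (min site %s)",
                 len(interactions), config.min_site_type)

        stage = "cerna_scoring"
        params = (
            cerna.InferenceParams.strict()
            if config.regime == "strict"
            else cerna.InferenceParams.lenient()
        )
        pairs = cerna.score_pairs(
            de_sets["lncrna"],
            de_sets["mrna"],
            de_sets["mirna"],
            interactions,
            lnc_n,
            mrna_n,
            mirna_n,
            params,
            universe=config.mirna_universe,
        )
        cerna.write_pairs_tsv(pairs, out / "cerna_pairs.tsv", regime=params.regime)
        passing = cerna.passing_pairs(pairs)
        log.info("scored %d candidate pairs, %d passed (%s regime: spearman<=%.2f, "
                 "pearson>=%.2f, p<%.3g)", len(pairs), len(passing), params.regime,
                 params.spearman_max, params.pearson_min, params.pair_p_max)

        stage = "network"
        net = network.build_network(passing, interactions, de_calls, params=asdict(params))
        network.export_network(net, out / "network.sif", "SIF")
        network.export_network(net, out / "network.graphml", "GraphML")
        network.export_network(net, out / "network_edges.tsv", "TSV")

        stage = "summary"
        summary = {
            "de_counts": {
                name: {
                    "up": int((t["call"] == "up").sum()),
                    "down": int((t["call"] == "down").sum()),
                    "total_tested": int(len(t)),
                }
                for name, t in de_tables.items()
            },
            "n_interactions": len(interactions),
            "n_scored_pairs": len(pairs),
            "n_passing_pairs": len(passing),
            "regime": params.regime,
            "network": network.network_summary(net),
            "seed": config.seed,
        }
        if ds is not None:
            truth_pairs = {(t.lncrna_id, t.mrna_id) for t in ds.truth}
            found = {(p.lncrna_id, p.mrna_id) for p in passing}
            tp = len(truth_pairs & found)
            summary["truth_recovery"] = {
                "n_planted": len(truth_pairs),
                "n_recovered": tp,
                "recall": tp / len(truth_pairs) if truth_pairs else float("nan"),
                "precision": tp / len(found) if found else float("nan"),
            }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return summary
    except Exception:
        log.exception("pipeline failed at stage %r; outputs are partial", stage)
        raise
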