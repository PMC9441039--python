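"""Synthetic two-group RNA-seq data with planted ceRNA structure.

The generator emulates a 3-vs-3 two-group whole-transcriptome study
(mRNA + lncRNA libraries and a small-RNA library) well enough to exercise
every downstream screen:

* negative-binomial counts around per-transcript log-normal baselines, with
  per-sample library-size factors;
* planted differentially expressed transcripts with a fixed fold change
  between groups;
* planted sponge triples (lncRNA, miRNA, mRNA): an exact seed-match site for
  the triple's miRNA is written into both partner transcripts, and a shared
  latent per-sample factor enters the miRNA with negative sign and both
  ceRNAs with positive sign, so that miRNA-ceRNA expression is
  anti-correlated and the two ceRNAs are positively correlated across
  samples.

Sequence composition is deliberately skewed (AT-rich transcripts, GC-rich
miRNA seeds) so that incidental seed matches are rare and the planted truth
table - not background matching - dominates recovery metrics; incidental
matches still occur and are counted as false positives when recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix
from .targets import seed_patterns

_DNA = np.array(list("ACGT"))
_RNA = np.array(list("ACGU"))

# latent-factor amplitude on the natural-log scale at corr strength 1.0;
# kept modest so within-group variance does not swamp the 3v3 DE test
_LATENT_SCALE = 0.12

# minimum G+C bases in a miRNA seed (nt 2-8); together with AT-rich
# transcripts this keeps incidental seed matches rare without forbidding them
_MIN_SEED_GC = 5


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters for one synthetic dataset."""

    n_mrna: int = 2000
    n_lncrna: int = 500
    n_mirna: int = 300
    n_planted_triples: int = 50
    n_samples_per_group: int = 3
    nb_dispersion: float = 0.002
    planted_fold_change: float = 4.0
    planted_corr_strength: float = 0.9
    seed: int = 0
    mean_expression_log_mu: float = 4.0
    mean_expression_log_sigma: float = 1.2
    # fraction of non-planted transcripts that are differentially expressed
    de_fraction_mrna: float = 0.15
    de_fraction_lncrna: float = 0.20
    de_fraction_mirna: float = 0.20
    transcript_gc: float = 0.12
    mirna_gc: float = 0.70
    min_transcript_len: int = 500
    max_transcript_len: int = 2000
    planted_expression_floor: float = 1500.0
    de_expression_floor: float = 50.0
    library_size_cv: float = 0.1
    group_a: str = "CC"
    group_b: str = "GC"

    def __post_init__(self) -> None:
        if self.n_planted_triples > min(self.n_mrna, self.n_lncrna, self.n_mirna):
            raise ValueError("more planted triples than transcripts of some class")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.planted_fold_change < 2:
            raise ValueError("planted fold change must be >= 2 to pass the DE gates")
        if not (0 < self.planted_corr_strength <= 1):
            raise ValueError("planted_corr_strength must lie in (0, 1]")
        if self.n_samples_per_group < 2:
            raise ValueError("need >= 2 samples per group")
        if not (500 <= self.min_transcript_len <= self.max_transcript_len <= 2000):
            raise ValueError("transcript lengths must lie within [500, 2000]")


@dataclass(frozen=True)
class PlantedTriple:
    """One ground-truth sponge triple with the planted 8mer site positions."""

    lncrna_id: str
    mirna_id: str
    mrna_id: str
    lnc_site_start: int = 0  # 1-based
    mrna_site_start: int = 0

    def __post_init__(self) -> None:
        ids = (self.lncrna_id, self.mirna_id, self.mrna_id)
        if len(set(ids)) != 3:
            raise ValueError(f"triple ids must be pairwise distinct: {ids}")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    mrna_counts: ExpressionMatrix
    lncrna_counts: ExpressionMatrix
    mirna_counts: ExpressionMatrix
    mrna_seqs: dict[str, str]
    lncrna_seqs: dict[str, str]
    mirna_seqs: dict[str, str]
    truth: list[PlantedTriple]
    truth_de: dict[str, str]  # id -> up | down


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i:05d}" for i in range(1, n + 1)]


def _random_seq(rng: np.random.Generator, length: int, alphabet: np.ndarray, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(alphabet, size=length, p=p))


def generate_sequences(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, str], dict[str, str], list[PlantedTriple]]:
    """miRNA, lncRNA and mRNA sequences with planted 8mer sites.

    miRNAs are 21-23 nt RNA with pairwise-distinct seeds (nt 2-8); transcripts
    are 500-2000 nt DNA.  For each planted triple the 8mer site (reverse
    complement of seed nt 2-8 plus a 3'-adjacent A on the site) overwrites a
    recorded position in both partner transcripts.  Triples pair the first
    ``n_planted_triples`` ids of each class.
    """
    rng = np.random.default_rng([config.seed, 1])
    mirna_ids = _ids("miR", config.n_mirna)
    lnc_ids = _ids("LNC", config.n_lncrna)
    mrna_ids = _ids("MR", config.n_mrna)

    mirna_seqs: dict[str, str] = {}
    seen_seeds: set[str] = set()
    for mid in mirna_ids:
        while True:
            seq = _random_seq(rng, int(rng.integers(21, 24)), _RNA, config.mirna_gc)
            seed = seq[1:8]
            gc = sum(seed.count(b) for b in "GC")
            if seed not in seen_seeds and gc >= _MIN_SEED_GC:
                seen_seeds.add(seed)
                mirna_seqs[mid] = seq
                break

    def _transcripts(ids: list[str]) -> dict[str, str]:
        return {
            tid: _random_seq(
                rng,
                int(rng.integers(config.min_transcript_len, config.max_transcript_len + 1)),
                _DNA,
                config.transcript_gc,
            )
            for tid in ids
        }

    lnc_seqs = _transcripts(lnc_ids)
    mrna_seqs = _transcripts(mrna_ids)

    triples: list[PlantedTriple] = []
    for i in range(config.n_planted_triples):
        mid, lid, rid = mirna_ids[i], lnc_ids[i], mrna_ids[i]
        site = seed_patterns(mirna_seqs[mid])["8mer"]

        def _plant(seq: str) -> tuple[str, int]:
            pos = int(rng.integers(10, len(seq) - len(site) - 10))
            return seq[:pos] + site + seq[pos + len(site) :], pos + 1

        lnc_seqs[lid], lnc_pos = _plant(lnc_seqs[lid])
        mrna_seqs[rid], mrna_pos = _plant(mrna_seqs[rid])
        triples.append(
            PlantedTriple(
                lncrna_id=lid,
                mirna_id=mid,
                mrna_id=rid,
                lnc_site_start=lnc_pos,
                mrna_site_start=mrna_pos,
            )
        )
    return mirna_seqs, lnc_seqs, mrna_seqs, triples


def _assign_de(config: SimulationConfig, rng: np.random.Generator) -> dict[str, str]:
    """Ground-truth up/down map: triple members plus random decoy DE."""
    truth_de: dict[str, str] = {}
    npl = config.n_planted_triples
    for i in range(npl):
        up = bool(rng.integers(0, 2))
        cer, mir = ("up", "down") if up else ("down", "up")
        truth_de[_ids("LNC", config.n_lncrna)[i]] = cer
        truth_de[_ids("MR", config.n_mrna)[i]] = cer
        truth_de[_ids("miR", config.n_mirna)[i]] = mir
    for prefix, n, frac in (
        ("MR", config.n_mrna, config.de_fraction_mrna),
        ("LNC", config.n_lncrna, config.de_fraction_lncrna),
        ("miR", config.n_mirna, config.de_fraction_mirna),
    ):
        ids = _ids(prefix, n)[npl:]
        n_de = int(round(frac * len(ids)))
        chosen = rng.choice(len(ids), size=n_de, replace=False)
        for j in sorted(chosen):
            truth_de[ids[j]] = "up" if rng.integers(0, 2) else "down"
    return truth_de


def generate_counts(
    config: SimulationConfig,
    truth: list[PlantedTriple],
    lengths: dict[str, dict[str, int]] | None = None,
    truth_de: dict[str, str] | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix, dict[str, str]]:
    """Negative-binomial count matrices (mRNA, lncRNA, miRNA) with planted structure.

    Per-transcript means are log-normal; DE transcripts get a symmetric
    ``planted_fold_change`` split between groups; each planted triple shares a
    latent per-sample factor (positive sign on both ceRNAs, negative on the
    miRNA) whose amplitude scales with ``planted_corr_strength``.  ``lengths``
    optionally supplies true transcript lengths per class keyed ``mrna`` /
    ``lncrna``; otherwise lengths are drawn uniformly.
    """
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    for t in truth:
        if not (
            t.lncrna_id.startswith("LNC")
            and t.mirna_id.startswith("miR")
            and t.mrna_id.startswith("MR")
        ):
            raise ValueError(f"triple inconsistent with config universe: {t}")
    rng = np.random.default_rng([config.seed, 2])
    if truth_de is None:
        truth_de = _assign_de(config, np.random.default_rng([config.seed, 3]))

    nspg = config.n_samples_per_group
    samples = [f"{config.group_a}_{i+1}" for i in range(nspg)] + [
        f"{config.group_b}_{i+1}" for i in range(nspg)
    ]
    groups = {s: s.split("_")[0] for s in samples}
    half = np.r_[np.full(nspg, -0.5), np.full(nspg, 0.5)]

    # per-triple latent factors, shared across the three classes
    latent_sd = _LATENT_SCALE * config.planted_corr_strength
    z = rng.standard_normal((config.n_planted_triples, 2 * nspg))
    lnc_of_triple = {t.lncrna_id: i for i, t in enumerate(truth)}
    mr_of_triple = {t.mrna_id: i for i, t in enumerate(truth)}
    mir_of_triple = {t.mirna_id: i for i, t in enumerate(truth)}

    def _matrix(prefix: str, n: int, class_label: str) -> ExpressionMatrix:
        ids = _ids(prefix, n)
        base = rng.lognormal(
            config.mean_expression_log_mu, config.mean_expression_log_sigma, size=n
        )
        lib = rng.lognormal(0.0, config.library_size_cv, size=2 * nspg)
        planted_members = {
            "LNC": lnc_of_triple,
            "MR": mr_of_triple,
            "miR": mir_of_triple,
        }[prefix]
        log_mu = np.log(base)[:, None] + np.zeros((n, 2 * nspg))
        for row, tid in enumerate(ids):
            call = truth_de.get(tid)
            if call is not None:
                sign = 1.0 if call == "up" else -1.0
                log_mu[row] += sign * half * np.log(config.planted_fold_change)
                # DE transcripts are drawn from the expressed stratum: a 3v3
                # design has no power for barely-detected transcripts
                floor = (
                    config.planted_expression_floor
                    if tid in planted_members
                    else config.de_expression_floor
                )
                log_mu[row] = np.maximum(
                    log_mu[row], log_mu[row] - np.log(base[row]) + np.log(floor)
                )
            if tid in planted_members:
                tri = planted_members[tid]
                sign = -1.0 if prefix == "miR" else 1.0
                log_mu[row] += sign * latent_sd * z[tri]
        mu = np.exp(log_mu) * lib[None, :]
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
        values = pd.DataFrame(counts.astype(float), index=ids, columns=samples)
        lens = None
        if class_label != "miRNA":
            key = "lncrna" if class_label == "lncRNA" else "mrna"
            if lengths is not None and key in lengths:
                lens = pd.Series({k: float(v) for k, v in lengths[key].items()})
            else:
                lens = pd.Series(
                    rng.integers(
                        config.min_transcript_len, config.max_transcript_len + 1, size=n
                    ).astype(float),
                    index=ids,
                )
        return ExpressionMatrix(
            values=values, class_label=class_label, groups=groups, lengths=lens
        )

    mrna = _matrix("MR", config.n_mrna, "mRNA")
    lnc = _matrix("LNC", config.n_lncrna, "lncRNA")
    mirna = _matrix("miR", config.n_mirna, "miRNA")
    return mrna, lnc, mirna, truth_de


def generate_dataset(
    config: SimulationConfig | None = None, outdir: str | Path | None = None
) -> SyntheticDataset:
    """Full synthetic dataset: sequences, counts, and ground truth.

    When ``outdir`` is given, FASTA, count TSVs, truth tables and a config
    echo are written there.
    """
    config = config or SimulationConfig()
    mirna_seqs, lnc_seqs, mrna_seqs, truth = generate_sequences(config)
    lengths = {
        "mrna": {k: len(v) for k, v in mrna_seqs.items()},
        "lncrna": {k: len(v) for k, v in lnc_seqs.items()},
    }
    mrna, lnc, mirna, truth_de = generate_counts(config, truth, lengths=lengths)
    ds = SyntheticDataset(
        config=config,
        mrna_counts=mrna,
        lncrna_counts=lnc,
        mirna_counts=mirna,
        mrna_seqs=mrna_seqs,
        lncrna_seqs=lnc_seqs,
        mirna_seqs=mirna_seqs,
        truth=truth,
        truth_de=truth_de,
    )
    if outdir is not None:
        write_dataset(ds, outdir)
    return ds


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_fasta(ds.mirna_seqs, out / "mirna.fasta")
    _write_fasta(ds.lncrna_seqs, out / "lncrna.fasta")
    _write_fasta(ds.mrna_seqs, out / "mrna.fasta")
    for name, m in (
        ("mrna", ds.mrna_counts),
        ("lncrna", ds.lncrna_counts),
        ("mirna", ds.mirna_counts),
    ):
        m.values.astype(int).to_csv(out / f"{name}_counts.tsv", sep="\t", index_label="id")
        if m.lengths is not None:
            m.lengths.astype(int).rename("length").to_csv(
                out / f"{name}_lengths.tsv", sep="\t", index_label="id"
            )
    pd.DataFrame([asdict(t) for t in ds.truth]).to_csv(
        out / "truth_triples.tsv", sep="\t", index=False
    )
    pd.Series(ds.truth_de, name="call").sort_index().to_csv(
        out / "truth_de.tsv", sep="\t", index_label="id"
    )
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(ds.config), fh, sort_keys=True)


def read_truth(path: str | Path) -> list[PlantedTriple]:
    df = pd.read_csv(path, sep="\t")
    return [
        PlantedTriple(
            lncrna_id=r.lncrna_id,
            mirna_id=r.mirna_id,
            mrna_id=r.mrna_id,
            lnc_site_start=int(r.lnc_site_start),
            mrna_site_start=int(r.mrna_site_start),
        )
        for r in df.itertuples()
    ]
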