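"""Competing-pair scoring: shared-miRNA hypergeometric test + correlation screens.

Two transcripts compete for a miRNA pool when they share binding sites for
the same miRNAs.  For each candidate (lncRNA, mRNA) pair the overlap of
their predicted miRNA regulator sets is tested against a hypergeometric
null (upper tail: at least the observed number shared, drawing the mRNA's
regulator set from the miRNA universe).  Sponge behaviour additionally
requires the expression signature: each evidential shared miRNA must be
anti-correlated (Spearman) with both transcripts, and the two transcripts
must be positively correlated (Pearson) with each other.

Two named threshold regimes are provided: ``lenient`` (Spearman <= -0.7,
Pearson >= 0.9, p < 0.05) for network construction and ``strict``
(Spearman <= -0.95, Pearson >= 0.95, p < 0.01) for reporting high-confidence
pairs.  Strict output is a subset of lenient output by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, bh_fdr
from .targets import TargetInteraction


@dataclass(frozen=True)
class HypergeomInput:
    """Variables of the shared-regulator overlap test.

    N: universe size (distinct miRNAs considered); K: miRNAs targeting the
    lncRNA; n: miRNAs targeting the mRNA; k: shared miRNAs.
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.k <= min(self.K, self.n)
            and self.K <= self.N
            and self.n <= self.N
            and min(self.N, self.K, self.n, self.k) >= 0
        )
        if not ok:
            raise ValueError(
                f"invalid hypergeometric input N={self.N} K={self.K} "
                f"n={self.n} k={self.k}"
            )


def hypergeom_overlap_p(h: HypergeomInput) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n); 1.0 when k = 0."""
    if h.k == 0:
        return 1.0
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(h.k - 1, h.N, h.K, h.n))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks; NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class InferenceParams:
    """Screening thresholds for competing-pair calls.

    ``spearman_max`` bounds the miRNA-ceRNA anti-correlation (both arms must
    fall at or below it), ``pearson_min`` the ceRNA-ceRNA positive
    correlation, ``pair_p_max`` the hypergeometric p, ``fdr_max`` an optional
    BH-FDR gate on the same family (None disables it).
    """

    spearman_max: float = -0.7
    pearson_min: float = 0.9
    pair_p_max: float = 0.05
    fdr_max: float | None = None
    regime: str = "lenient"
    both_arms: bool = True

    def __post_init__(self) -> None:
        if not (self.spearman_max < 0 < self.pearson_min <= 1):
            raise ValueError("require spearman_max < 0 < pearson_min <= 1")
        if not (0 < self.pair_p_max <= 1):
            raise ValueError("pair_p_max must lie in (0, 1]")

    @classmethod
    def lenient(cls) -> "InferenceParams":
        return cls()

    @classmethod
    def strict(cls) -> "InferenceParams":
        return cls(
            spearman_max=-0.95,
            pearson_min=0.95,
            pair_p_max=0.01,
            fdr_max=0.01,
            regime="strict",
        )


@dataclass(frozen=True)
class CeRNAPair:
    lncrna_id: str
    mrna_id: str
    shared_mirnas: tuple[str, ...]
    hypergeom: HypergeomInput
    hypergeom_p: float
    hypergeom_fdr: float
    pearson_r: float
    spearman_lnc: Mapping[str, float]
    spearman_mrna: Mapping[str, float]
    screening_mirnas: tuple[str, ...]
    passed: bool


def _targeting_map(
    interactions: Iterable[TargetInteraction],
) -> dict[str, set[str]]:
    """transcript id -> set of miRNA ids targeting it."""
    out: dict[str, set[str]] = {}
    for it in interactions:
        out.setdefault(it.transcript_id, set()).add(it.mirna_id)
    return out


def score_pairs(
    de_lnc: set[str],
    de_mrna: set[str],
    de_mirna: set[str],
    interactions: Sequence[TargetInteraction],
    lnc_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    params: InferenceParams | None = None,
    universe: str = "interacting",
) -> list[CeRNAPair]:
    """Score every (DE lncRNA, DE mRNA) pair sharing >= 1 DE miRNA regulator.

    The miRNA universe N is, by default (``universe="interacting"``), the
    number of distinct DE miRNAs with at least one predicted interaction
    among the DE transcripts (smallest defensible universe; regulator sets
    are subsets of it by construction); ``universe="all_de"`` uses every DE
    miRNA instead, which is more appropriate when few miRNAs have targets.
    The
    hypergeometric p is BH-adjusted across all scored pairs.  A shared miRNA
    counts as screening evidence only if its Spearman correlation with the
    lncRNA AND with the mRNA are both <= ``spearman_max`` (set
    ``both_arms=False`` for either-arm semantics).  A pair passes when
    hypergeom_p < pair_p_max, pearson_r >= pearson_min, at least one
    screening miRNA exists, and (if enabled) hypergeom_fdr <= fdr_max.
    """
    params = params or InferenceParams.lenient()
    kept = [
        it
        for it in interactions
        if it.mirna_id in de_mirna and (it.transcript_id in de_lnc or it.transcript_id in de_mrna)
    ]
    if not kept:
        warnings.warn("no interactions among DE transcripts; empty result")
        return []
    targeting = _targeting_map(kept)
    if universe == "interacting":
        n_universe = len({it.mirna_id for it in kept})
    elif universe == "all_de":
        n_universe = len(de_mirna)
    else:
        raise ValueError(f"unknown universe choice {universe!r}")

    if list(lnc_expr.values.columns) != list(mrna_expr.values.columns) or list(
        lnc_expr.values.columns
    ) != list(mirna_expr.values.columns):
        raise ValueError("expression matrices must share identical sample columns")

    def _expr(mat: ExpressionMatrix, tid: str) -> np.ndarray:
        if tid not in mat.values.index:
            raise KeyError(f"no expression profile for id {tid!r}")
        return mat.values.loc[tid].to_numpy(dtype=float)

    lnc_ids = sorted(i for i in de_lnc if i in targeting)
    mrna_ids = sorted(i for i in de_mrna if i in targeting)

    raw: list[dict] = []
    for lnc in lnc_ids:
        set_l = targeting[lnc]
        for mr in mrna_ids:
            set_m = targeting[mr]
            shared = sorted(set_l & set_m)
            if not shared:
                continue
            h = HypergeomInput(N=n_universe, K=len(set_l), n=len(set_m), k=len(shared))
            x_l = _expr(lnc_expr, lnc)
            x_m = _expr(mrna_expr, mr)
            rho_l = {mi: spearman_rho(_expr(mirna_expr, mi), x_l) for mi in shared}
            rho_m = {mi: spearman_rho(_expr(mirna_expr, mi), x_m) for mi in shared}
            raw.append(
                dict(
                    lnc=lnc,
                    mr=mr,
                    shared=tuple(shared),
                    h=h,
                    p=hypergeom_overlap_p(h),
                    r=pearson_r(x_l, x_m),
                    rho_l=rho_l,
                    rho_m=rho_m,
                )
            )
    if not raw:
        return []
    fdrs = bh_fdr([d["p"] for d in raw])

    pairs: list[CeRNAPair] = []
    for d, fdr in zip(raw, fdrs):
        if params.both_arms:
            screening = tuple(
                mi
                for mi in d["shared"]
                if d["rho_l"][mi] <= params.spearman_max
                and d["rho_m"][mi] <= params.spearman_max
            )
        else:
            screening = tuple(
                mi
                for mi in d["shared"]
                if d["rho_l"][mi] <= params.spearman_max
                or d["rho_m"][mi] <= params.spearman_max
            )
        r = d["r"]
        passed = (
            d["p"] < params.pair_p_max
            and not np.isnan(r)
            and r >= params.pearson_min
            and len(screening) > 0
            and (params.fdr_max is None or fdr <= params.fdr_max)
        )
        pairs.append(
            CeRNAPair(
                lncrna_id=d["lnc"],
                mrna_id=d["mr"],
                shared_mirnas=d["shared"],
                hypergeom=d["h"],
                hypergeom_p=d["p"],
                hypergeom_fdr=float(fdr),
                pearson_r=float(r),
                spearman_lnc=d["rho_l"],
                spearman_mrna=d["rho_m"],
                screening_mirnas=screening,
                passed=bool(passed),
            )
        )
    return pairs


def passing_pairs(pairs: Iterable[CeRNAPair]) -> list[CeRNAPair]:
    return [p for p in pairs if p.passed]


def overrepresentation_test(
    gene_set: set[str],
    term_map: Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Per-term hypergeometric over-representation with BH FDR.

    Generic enrichment for user-supplied term -> gene maps (GO/KEGG style):
    N = |universe|, K = |term genes in universe|, n = |gene_set|,
    k = |term genes in gene_set|.
    """
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    rows = []
    for term in sorted(term_map):
        genes = term_map[term] & universe
        k = len(genes & gene_set)
        h = HypergeomInput(N=len(universe), K=len(genes), n=len(gene_set), k=k)
        rows.append((term, len(genes), k, hypergeom_overlap_p(h)))
    df = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p_value"])
    df["fdr"] = bh_fdr(df["p_value"].to_numpy()) if len(df) else []
    return df.set_index("term")


def pairs_to_frame(pairs: Iterable[CeRNAPair], regime: str = "lenient") -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append(
            {
                "lncrna_id": p.lncrna_id,
                "mrna_id": p.mrna_id,
                "k": p.hypergeom.k,
                "K": p.hypergeom.K,
                "n": p.hypergeom.n,
                "N": p.hypergeom.N,
                "hypergeom_p": p.hypergeom_p,
                "hypergeom_fdr": p.hypergeom_fdr,
                "pearson_r": p.pearson_r,
                "n_screening_mirnas": len(p.screening_mirnas),
                "shared_mirnas": ";".join(p.shared_mirnas),
                "passed": p.passed,
                "regime": regime,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lncrna_id",
            "mrna_id",
            "k",
            "K",
            "n",
            "N",
            "hypergeom_p",
            "hypergeom_fdr",
            "pearson_r",
            "n_screening_mirnas",
            "shared_mirnas",
            "passed",
            "regime",
        ],
    )


def write_pairs_tsv(
    pairs: Iterable[CeRNAPair], path: str | Path, regime: str = "lenient"
) -> None:
    pairs_to_frame(pairs, regime).to_csv(path, sep="\t", index=False)
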