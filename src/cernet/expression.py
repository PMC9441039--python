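"""Expression matrices, normalization, and differential-expression gating.

Transcript abundance is handled on the scale each RNA class is conventionally
reported on: FPKM (fragments per kilobase per million mapped reads) for mRNA
and lncRNA, and tags-per-million for small-RNA (miRNA) libraries, which are
sequenced as whole molecules and need no length correction.

Differential expression uses a deliberately simple, documented test: Welch's
two-sample t on log2(normalized value + pseudocount).  The interface also
accepts externally computed (p, log2fc) tables, so output from a dedicated
count-model package can be substituted without touching downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

TRANSCRIPT_CLASSES = ("mRNA", "lncRNA", "miRNA")
VALUE_KINDS = ("counts", "FPKM", "TPM")


@dataclass
class ExpressionMatrix:
    """Transcripts x samples table with class, length, and group metadata.

    Parameters
    ----------
    values
        Non-negative matrix, rows indexed by transcript id, columns by
        sample id.
    class_label
        One of ``mRNA``, ``lncRNA``, ``miRNA``; applies to every row.
    groups
        Mapping sample id -> group label (e.g. ``CC`` / ``GC``).
    lengths
        Transcript length in bp, required for length-aware normalization
        (mRNA/lncRNA); may be omitted for miRNA.
    value_kind
        ``counts``, ``FPKM`` or ``TPM``.
    """

    values: pd.DataFrame
    class_label: str
    groups: Mapping[str, str]
    lengths: pd.Series | None = None
    value_kind: str = "counts"

    def __post_init__(self) -> None:
        if self.class_label not in TRANSCRIPT_CLASSES:
            raise ValueError(f"unknown transcript class {self.class_label!r}")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value kind {self.value_kind!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate transcript ids: {list(dups)}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        if self.lengths is not None:
            absent = self.values.index.difference(self.lengths.index)
            if len(absent):
                raise ValueError(f"missing lengths for ids: {list(absent[:5])}")
            if (self.lengths.loc[self.values.index] <= 0).any():
                raise ValueError("transcript lengths must be positive")
        elif self.class_label != "miRNA":
            raise ValueError(f"{self.class_label} matrix requires transcript lengths")

    @property
    def ids(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def group_names(self) -> list[str]:
        """Distinct group labels in column order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.groups[s], None)
        return list(seen)


def read_counts(
    path: str | Path,
    class_label: str,
    groups: Mapping[str, str],
    lengths_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a TSV count matrix (first column = transcript id, header = samples).

    ``lengths_path`` points to a two-column TSV (id, length in bp) and is
    required for mRNA/lncRNA.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty count matrix")
    try:
        df = df.astype(float)
    except ValueError as exc:
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & df.notna()
        row = bad.any(axis=1).idxmax()
        col = bad.loc[row].idxmax()
        raise ValueError(
            f"{path}: non-numeric cell at row {row!r}, column {col!r}: "
            f"{df.loc[row, col]!r}"
        ) from exc
    lengths = None
    if lengths_path is not None:
        lt = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
        lengths = lt.astype(float)
    return ExpressionMatrix(
        values=df, class_label=class_label, groups=dict(groups), lengths=lengths
    )


def fpkm_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """FPKM_is = 1e9 * C_is / (N_s * L_i), N_s = column total of counts."""
    if m.value_kind != "counts":
        raise ValueError("FPKM normalization expects raw counts")
    if m.lengths is None:
        raise ValueError("FPKM requires transcript lengths")
    totals = m.values.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero column total in samples: {bad}")
    lengths = m.lengths.loc[m.values.index].to_numpy()[:, None]
    fpkm = 1e9 * m.values / (totals.to_numpy()[None, :] * lengths)
    return replace(m, values=fpkm, value_kind="FPKM")


def tpm_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Tags-per-million for miRNA; length-normalized TPM for mRNA/lncRNA.

    miRNA: TPM_is = 1e6 * C_is / N_s.  mRNA/lncRNA: length-corrected rates
    renormalized so each column sums to 1e6.
    """
    if m.value_kind != "counts":
        raise ValueError("TPM normalization expects raw counts")
    if m.class_label == "miRNA":
        rates = m.values
    else:
        if m.lengths is None:
            raise ValueError("length-normalized TPM requires transcript lengths")
        rates = m.values.div(m.lengths.loc[m.values.index], axis=0)
    totals = rates.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero column total in samples: {bad}")
    tpm = 1e6 * rates / totals
    return replace(m, values=tpm, value_kind="TPM")


def normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Class-conventional normalization: FPKM for mRNA/lncRNA, TPM for miRNA."""
    return tpm_normalize(m) if m.class_label == "miRNA" else fpkm_normalize(m)


@dataclass(frozen=True)
class DERecord:
    id: str
    mean_a: float
    mean_b: float
    log2fc: float
    p_value: float
    fdr: float
    call: str  # up | down | not_de


def de_test(
    m: ExpressionMatrix,
    pseudocount: float = 1.0,
    group_a: str | None = None,
    group_b: str | None = None,
) -> pd.DataFrame:
    """Per-transcript Welch t-test on log2(value + pseudocount).

    Fold change is oriented B relative to A, where A defaults to the first
    group appearing in the column order.  Returns a DataFrame indexed by id
    with columns mean_a, mean_b, log2fc, p_value.

    Transcripts with zero variance in both groups and equal means get p = 1
    by convention (no evidence of change, rather than NaN).
    """
    names = m.group_names()
    if len(names) != 2:
        raise ValueError(f"exactly two groups required, found {names}")
    ga = group_a or names[0]
    gb = group_b or (names[1] if names[1] != ga else names[0])
    cols_a, cols_b = m.group_samples(ga), m.group_samples(gb)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs >= 2 samples for the DE test")

    a = m.values[cols_a].to_numpy(dtype=float)
    b = m.values[cols_b].to_numpy(dtype=float)
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    # degenerate rows: no within-group variance
    flat = (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
    same = flat & np.isclose(la.mean(axis=1), lb.mean(axis=1))
    p[same] = 1.0
    p[flat & ~same] = 0.0
    p = np.nan_to_num(p, nan=1.0)

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    return pd.DataFrame(
        {"mean_a": mean_a, "mean_b": mean_b, "log2fc": log2fc, "p_value": p},
        index=m.values.index,
    )


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def filter_de(
    table: pd.DataFrame,
    class_label: str,
    min_abs_log2fc: float = 1.0,
    max_fdr: float = 0.05,
    max_p: float = 0.05,
) -> pd.DataFrame:
    """Apply the class-specific DE gates and attach FDR and up/down calls.

    mRNA/lncRNA pass on |log2fc| >= min_abs_log2fc and BH FDR < max_fdr;
    miRNA on |log2fc| >= min_abs_log2fc and raw p < max_p (small-RNA counts
    are conventionally gated on the unadjusted p-value).
    """
    if class_label not in TRANSCRIPT_CLASSES:
        raise ValueError(f"unknown transcript class {class_label!r}")
    out = table.copy()
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    fc_ok = out["log2fc"].abs() >= min_abs_log2fc
    if class_label == "miRNA":
        sig = out["p_value"] < max_p
    else:
        sig = out["fdr"] < max_fdr
    passed = fc_ok & sig
    out["call"] = np.where(~passed, "not_de", np.where(out["log2fc"] > 0, "up", "down"))
    out["class"] = class_label
    return out


def de_records(table: pd.DataFrame) -> list[DERecord]:
    """Materialize a filtered DE table as DERecord objects."""
    return [
        DERecord(
            id=str(i),
            mean_a=float(r.mean_a),
            mean_b=float(r.mean_b),
            log2fc=float(r.log2fc),
            p_value=float(r.p_value),
            fdr=float(r.fdr),
            call=str(r.call),
        )
        for i, r in table.iterrows()
    ]


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = ["class", "mean_a", "mean_b", "log2fc", "p_value", "fdr", "call"]
    table.to_csv(path, sep="\t", index_label="id", columns=cols)
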