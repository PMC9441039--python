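"""Relative expression from qPCR cycle thresholds and RNA-seq concordance.

Implements the comparative-Ct (Livak) model: per sample
dCt = Ct(target) - Ct(reference); per target ddCt = mean dCt(test group) -
mean dCt(calibrator group); relative expression = 2^-ddCt.  Amplification
efficiency is assumed to be 100% (a doubling per cycle); technical
replicates are averaged on the Ct scale before dCt.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cerna import spearman_rho


@dataclass(frozen=True)
class QpcrRecord:
    target_id: str
    sample_id: str
    group: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, ct in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not np.isfinite(ct) or ct <= 0:
                raise ValueError(
                    f"{name} must be positive and finite "
                    f"({self.target_id}/{self.sample_id}: {ct})"
                )


def _records_frame(records: Iterable[QpcrRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            (r.target_id, r.sample_id, r.group, r.ct_target, r.ct_reference)
            for r in records
        ],
        columns=["target_id", "sample_id", "group", "ct_target", "ct_reference"],
    )
    if df.empty:
        raise ValueError("no qPCR records")
    # technical replicates: average Ct per (target, sample) before dCt
    return df.groupby(["target_id", "sample_id", "group"], as_index=False).mean()


def relative_expression(
    records: Iterable[QpcrRecord], calibrator_group: str
) -> pd.Series:
    """Per-target fold change 2^-ddCt of the test group vs the calibrator."""
    df = _records_frame(records)
    if calibrator_group not in set(df["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} absent from records")
    df["dct"] = df["ct_target"] - df["ct_reference"]
    out = {}
    for target, sub in df.groupby("target_id"):
        by_group = sub.groupby("group")["dct"].mean()
        test = [g for g in by_group.index if g != calibrator_group]
        if len(test) != 1:
            raise ValueError(
                f"target {target!r} needs exactly one test and one calibrator group, "
                f"found groups {list(by_group.index)}"
            )
        ddct = by_group[test[0]] - by_group[calibrator_group]
        out[target] = float(2.0 ** (-ddct))
    return pd.Series(out, name="fold_change").sort_index()


def read_qpcr_tsv(path: str | Path) -> list[QpcrRecord]:
    """Read records from a TSV with columns target_id, sample_id, group, ct_target, ct_reference."""
    df = pd.read_csv(path, sep="\t")
    missing = df["ct_reference"].isna()
    if missing.any():
        bad = df.loc[missing, "sample_id"].tolist()
        raise ValueError(f"missing reference Ct for samples: {bad}")
    return [
        QpcrRecord(
            target_id=str(r.target_id),
            sample_id=str(r.sample_id),
            group=str(r.group),
            ct_target=float(r.ct_target),
            ct_reference=float(r.ct_reference),
        )
        for r in df.itertuples()
    ]


def concordance(
    rnaseq_log2fc: Mapping[str, float], qpcr_fold: Mapping[str, float]
) -> tuple[pd.DataFrame, float]:
    """Sign agreement per shared id plus Spearman rho across shared ids.

    Both inputs are oriented the same way (test vs calibrator); qPCR fold
    changes are logged before comparison.
    """
    shared = sorted(set(rnaseq_log2fc) & set(qpcr_fold))
    if not shared:
        raise ValueError("no shared ids between RNA-seq and qPCR tables")
    rows = []
    for i in shared:
        seq_fc = float(rnaseq_log2fc[i])
        q_l2 = float(np.log2(qpcr_fold[i]))
        rows.append((i, seq_fc, q_l2, np.sign(seq_fc) == np.sign(q_l2)))
    table = pd.DataFrame(
        rows, columns=["id", "rnaseq_log2fc", "qpcr_log2fc", "sign_agree"]
    ).set_index("id")
    rho = float("nan")
    if len(shared) >= 3:
        rho = spearman_rho(table["rnaseq_log2fc"], table["qpcr_log2fc"])
    return table, rho
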