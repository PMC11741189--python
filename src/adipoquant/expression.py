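"""Relative gene expression by the 2^-ddCt method.

Per sample, dCt = Ct(target) - Ct(reference); ddCt subtracts the arithmetic
mean dCt of the control group for that gene; the fold change is 2^-ddCt.
Technical replicates (repeated sample x gene rows) are averaged to one Ct
before the calculation.  By construction the control group's mean ddCt is 0,
so the geometric mean of control fold changes is exactly 1.

Group summaries report mean +/- SEM on the fold-change scale (matching the
convention of "fold change +/- SEM" figure panels) and additionally on the
log2 scale, where the distribution is closer to symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CtRecord", "FoldChangeTable", "delta_delta_ct"]

REQUIRED_COLUMNS = ("sample_id", "group", "gene", "ct")


@dataclass(frozen=True)
class CtRecord:
    """One qPCR cycle-threshold measurement."""

    sample_id: str
    group: str
    gene: str
    ct: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ct):
            raise ValueError(f"Ct must be finite, got {self.ct}")
        if not self.gene or not self.group:
            raise ValueError("gene and group must be non-empty")


@dataclass
class FoldChangeTable:
    """Per-sample fold changes plus group-level summaries.

    Attributes
    ----------
    per_sample
        Columns: sample_id, group, gene, delta_ct, delta_delta_ct, fold_change.
    summary
        Columns: group, gene, mean_fold, sem_fold, mean_log2_fold,
        sem_log2_fold, n.
    errors
        One record per sample x gene that could not be computed (e.g. a
        sample missing the reference-gene Ct), with a reason.
    """

    per_sample: pd.DataFrame
    summary: pd.DataFrame
    errors: list[dict] = field(default_factory=list)


def _to_frame(records: Sequence[CtRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"Ct table is missing columns: {missing}")
        df = records.loc[:, list(REQUIRED_COLUMNS)].copy()
    else:
        df = pd.DataFrame([vars(r) for r in records])
        if df.empty:
            raise ValueError("no Ct records supplied")
    if not np.isfinite(df["ct"]).all():
        raise ValueError("all Ct values must be finite")
    return df


def delta_delta_ct(
    records: Sequence[CtRecord] | pd.DataFrame,
    reference_gene: str,
    control_group: str,
) -> FoldChangeTable:
    """Compute per-sample 2^-ddCt fold changes against a reference gene and
    control group.

    Parameters
    ----------
    records
        Ct measurements (list of :class:`CtRecord` or a DataFrame with
        columns sample_id, group, gene, ct).  Repeated sample x gene rows
        are treated as technical replicates and averaged first.
    reference_gene
        Housekeeping gene (e.g. the 18S ribosomal RNA) measured in every
        sample.
    control_group
        Group whose mean dCt calibrates ddCt, per gene.
    """
    df = _to_frame(records)
    # average technical replicates to one Ct per sample x gene
    df = df.groupby(["sample_id", "group", "gene"], as_index=False)["ct"].mean()

    ref = df[df["gene"] == reference_gene].set_index("sample_id")["ct"]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from the table")
    targets = df[df["gene"] != reference_gene].copy()
    if targets.empty:
        raise ValueError("no target genes besides the reference")

    errors: list[dict] = []
    has_ref = targets["sample_id"].isin(ref.index)
    for _, row in targets[~has_ref].iterrows():
        errors.append(
            {
                "sample_id": row["sample_id"],
                "gene": row["gene"],
                "reason": f"missing reference-gene ({reference_gene}) Ct",
            }
        )
    targets = targets[has_ref].copy()
    targets["delta_ct"] = targets["ct"].to_numpy() - ref.loc[targets["sample_id"]].to_numpy()

    out_rows = []
    for gene, sub in targets.groupby("gene"):
        ctrl = sub[sub["group"] == control_group]
        if ctrl.empty:
            raise ValueError(f"control group {control_group!r} has no samples for gene {gene!r}")
        calibrator = ctrl["delta_ct"].mean()
        ddct = sub["delta_ct"] - calibrator
        out = sub.assign(delta_delta_ct=ddct, fold_change=np.power(2.0, -ddct))
        out_rows.append(out)
    per_sample = (
        pd.concat(out_rows)
        .loc[:, ["sample_id", "group", "gene", "delta_ct", "delta_delta_ct", "fold_change"]]
        .sort_values(["gene", "group", "sample_id"])
        .reset_index(drop=True)
    )

    def _summarize(sub: pd.DataFrame) -> pd.Series:
        folds = sub["fold_change"].to_numpy()
        log2 = np.log2(folds)
        n = len(folds)
        sem = folds.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        sem_log = log2.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        return pd.Series(
            {
                "mean_fold": folds.mean(),
                "sem_fold": sem,
                "mean_log2_fold": log2.mean(),
                "sem_log2_fold": sem_log,
                "n": n,
            }
        )

    summary = (
        per_sample.groupby(["group", "gene"]).apply(_summarize, include_groups=False).reset_index()
    )
    summary["n"] = summary["n"].astype(int)
    return FoldChangeTable(per_sample, summary, errors)
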