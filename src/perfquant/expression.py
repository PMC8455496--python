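"""Relative gene expression by the 2^−ΔΔCT method with dual references.

qPCR threshold cycles (Ct) are inversely proportional to the log2
abundance of a transcript.  For each sample the target Ct is normalised
against the arithmetic mean of the reference-gene Cts (equivalent to
geometric-mean normalisation on the expression scale):

    ΔCT  = Ct_target − mean(Ct_references)
    ΔΔCT = mean ΔCT(treated) − mean ΔCT(control)
    fold = 2^−ΔΔCT

Amplification efficiency is fixed at 2 per doubling cycle (no
efficiency correction).  Statistical comparison between conditions uses
a Mann–Whitney test on the per-replicate 2^−ΔCT values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import mann_whitney

__all__ = [
    "CT_MIN",
    "CT_MAX",
    "FoldChange",
    "validate_ct_table",
    "delta_ct",
    "fold_change",
    "expression_report",
]

# Plausible qPCR cycle range; values outside are treated as data errors.
CT_MIN = 1.0
CT_MAX = 45.0

_REQUIRED_COLUMNS = ("sample", "condition", "gene", "ct")


@dataclass(frozen=True)
class FoldChange:
    """2^−ΔΔCT fold change of one gene between two conditions."""

    gene: str
    fold: float
    p_value: float
    delta_delta_ct: float
    n_treated: int
    n_control: int

    def __post_init__(self) -> None:
        if not (self.fold > 0):
            raise ValueError("fold must be positive")


def delta_ct(target_ct: float, reference_cts: Sequence[float]) -> float:
    """ΔCT = target Ct − arithmetic mean of the reference Cts."""
    refs = np.asarray(reference_cts, dtype=np.float64).ravel()
    if refs.size == 0:
        raise ValueError("at least one reference Ct is required")
    return float(target_ct - refs.mean())


def fold_change(
    delta_treated: Sequence[float],
    delta_control: Sequence[float],
    gene: str = "",
) -> FoldChange:
    """Fold = 2^−ΔΔCT from per-replicate ΔCT values of the two groups."""
    dt = np.asarray(delta_treated, dtype=np.float64).ravel()
    dc = np.asarray(delta_control, dtype=np.float64).ravel()
    if dt.size == 0 or dc.size == 0:
        raise ValueError("both groups need >= 1 replicate")
    ddct = float(dt.mean() - dc.mean())
    test = mann_whitney(2.0**-dt, 2.0**-dc)
    return FoldChange(
        gene=gene,
        fold=float(2.0**-ddct),
        p_value=test.p_value,
        delta_delta_ct=ddct,
        n_treated=int(dt.size),
        n_control=int(dc.size),
    )


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the sample/condition/gene/ct column contract and Ct range."""
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    ct = pd.to_numeric(table["ct"], errors="raise")
    bad = table[(ct < CT_MIN) | (ct > CT_MAX) | ct.isna()]
    if len(bad):
        rows = bad[["sample", "gene", "ct"]].to_dict("records")
        raise ValueError(f"Ct values outside [{CT_MIN}, {CT_MAX}]: {rows}")
    out = table.copy()
    out["ct"] = ct.astype(float)
    return out


def _sample_delta_cts(
    sub: pd.DataFrame, targets: Sequence[str], refs: Sequence[str], condition: str
) -> dict[str, list[float]]:
    """Per-sample ΔCT of every target gene within one condition."""
    per_gene: dict[str, list[float]] = {g: [] for g in targets}
    for sample, grp in sub.groupby("sample"):
        by_gene = grp.groupby("gene")["ct"].mean()
        missing_refs = [r for r in refs if r not in by_gene.index]
        if missing_refs:
            raise ValueError(
                f"sample '{sample}' ({condition}) lacks reference genes {missing_refs}"
            )
        ref_mean = float(by_gene.loc[list(refs)].mean())
        for g in targets:
            if g not in by_gene.index:
                raise ValueError(
                    f"sample '{sample}' ({condition}) lacks target gene '{g}'"
                )
            per_gene[g].append(float(by_gene.loc[g]) - ref_mean)
    return per_gene


def expression_report(
    table: pd.DataFrame | str | Path,
    targets: Sequence[str],
    refs: Sequence[str],
    control: str = "static",
    treated: str | None = None,
) -> pd.DataFrame:
    """One 2^−ΔΔCT fold change per target gene, relative to ``control``.

    ``table`` is a DataFrame (or CSV/TSV path) with columns
    sample/condition/gene/ct.  Repeated measurements of a gene within a
    sample are averaged first; ΔCT is computed per sample, ΔΔCT from the
    group means.  Returns a DataFrame with columns gene, fold, p_value,
    delta_delta_ct, n_treated, n_control.
    """
    if not isinstance(table, pd.DataFrame):
        from .image_io import read_table

        table = read_table(table)
    table = validate_ct_table(table)
    if not targets:
        raise ValueError("need >= 1 target gene")
    if not refs:
        raise ValueError("need >= 1 reference gene")

    conditions = list(dict.fromkeys(table["condition"]))
    if control not in conditions:
        raise ValueError(f"control condition '{control}' not in table ({conditions})")
    if treated is None:
        others = [c for c in conditions if c != control]
        if len(others) != 1:
            raise ValueError(
                f"cannot infer treated condition from {conditions}; pass treated="
            )
        treated = others[0]
    elif treated not in conditions:
        raise ValueError(f"treated condition '{treated}' not in table ({conditions})")

    d_control = _sample_delta_cts(
        table[table["condition"] == control], targets, refs, control
    )
    d_treated = _sample_delta_cts(
        table[table["condition"] == treated], targets, refs, treated
    )
    rows = [
        fold_change(d_treated[g], d_control[g], gene=g).__dict__ for g in targets
    ]
    return pd.DataFrame(rows)
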