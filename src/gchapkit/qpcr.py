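"""Relative expression from qPCR cycle thresholds: the Livak 2^-ΔΔCt method.

Technical replicates are averaged to one Ct per (gene, condition, timepoint,
biological replicate); ΔCt subtracts the internal reference gene measured in
the same sample; ΔΔCt subtracts the mean control ΔCt (the 0 h timepoint of
the same condition by default); the fold change is 2^-ΔΔCt per biological
replicate.  Significance stars compare treated vs control ΔCt values with a
Welch two-sample t test on the four-level grid
(**** p<0.0001, *** p<0.001, ** p<0.01, * p<0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("gene", "condition", "timepoint", "bio_rep", "tech_rep", "ct")

STAR_GRID = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass
class QpcrDataset:
    """Long-format Ct measurements plus the internal reference gene id."""

    data: pd.DataFrame
    reference_gene: str

    def __post_init__(self):
        missing = set(REQUIRED_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        ct = self.data["ct"]
        if not np.isfinite(ct).all() or (ct <= 0).any():
            raise ValueError("Ct values must be finite and positive")
        if self.reference_gene not in set(self.data["gene"]):
            raise ValueError(
                f"reference gene {self.reference_gene!r} absent from dataset"
            )


@dataclass
class FoldChange:
    gene: str
    condition: str
    timepoint: float
    control_timepoint: float
    per_rep: dict[int, float]
    mean: float
    sd: float


def _mean_ct(ds: QpcrDataset, gene, condition, timepoint) -> pd.Series:
    """Technical replicates averaged: one Ct per biological replicate."""
    sub = ds.data[
        (ds.data["gene"] == gene)
        & (ds.data["condition"] == condition)
        & (ds.data["timepoint"] == timepoint)
    ]
    return sub.groupby("bio_rep")["ct"].mean()


def delta_ct(ds: QpcrDataset, gene, condition, timepoint) -> pd.Series:
    """ΔCt = Ct_target - Ct_reference per biological replicate."""
    target = _mean_ct(ds, gene, condition, timepoint)
    reference = _mean_ct(ds, ds.reference_gene, condition, timepoint)
    if target.empty:
        raise ValueError(
            f"no measurements for {gene} / {condition} / {timepoint} h"
        )
    unmatched = set(target.index) - set(reference.index)
    if unmatched:
        raise ValueError(
            f"missing reference-gene measurement for sample(s) "
            f"{sorted(unmatched)} of {gene} / {condition} / {timepoint} h"
        )
    return target - reference.loc[target.index]


def ddct_fold_change(
    ds: QpcrDataset, gene, condition, timepoint, control_timepoint=0
) -> FoldChange:
    """Per-biological-replicate 2^-ΔΔCt fold changes vs the control timepoint."""
    treated = delta_ct(ds, gene, condition, timepoint)
    control = delta_ct(ds, gene, condition, control_timepoint)
    ddct = treated - control.mean()
    folds = np.power(2.0, -ddct)
    return FoldChange(
        gene=gene, condition=condition, timepoint=timepoint,
        control_timepoint=control_timepoint,
        per_rep=dict(folds),
        mean=float(folds.mean()),
        sd=float(folds.std(ddof=1)) if len(folds) > 1 else 0.0,
    )


def expression_significance(
    ds: QpcrDataset, gene, condition, timepoint, control_timepoint=0
) -> tuple[str, float]:
    """Star label for treated-vs-control ΔCt (Welch two-sided t test)."""
    treated = delta_ct(ds, gene, condition, timepoint)
    control = delta_ct(ds, gene, condition, control_timepoint)
    if len(treated) < 2 or len(control) < 2:
        return "nd", float("nan")
    if np.allclose(treated.values, control.values.mean()) and np.allclose(
        control.values, control.values.mean()
    ):
        return "ns", 1.0
    t = stats.ttest_ind(treated.values, control.values, equal_var=False)
    p = float(t.pvalue)
    for cutoff, label in STAR_GRID:
        if p < cutoff:
            return label, p
    return "ns", p


def timepoint_anova(ds: QpcrDataset, gene, condition) -> tuple[float, float]:
    """Optional one-way ANOVA of ΔCt across all timepoints of a condition."""
    sub = ds.data[(ds.data["gene"] == gene) & (ds.data["condition"] == condition)]
    groups = [
        delta_ct(ds, gene, condition, tp).values
        for tp in sorted(sub["timepoint"].unique())
    ]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 timepoints with >= 2 replicates")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def fold_change_table(
    ds: QpcrDataset, conditions=None, control_timepoint=0
) -> pd.DataFrame:
    """All (gene, condition, timepoint) fold changes with star labels."""
    rows = []
    data = ds.data
    genes = [g for g in data["gene"].unique() if g != ds.reference_gene]
    for gene in genes:
        for condition in conditions or data["condition"].unique():
            sub = data[(data["gene"] == gene) & (data["condition"] == condition)]
            for tp in sorted(sub["timepoint"].unique()):
                fc = ddct_fold_change(ds, gene, condition, tp, control_timepoint)
                star, p = expression_significance(
                    ds, gene, condition, tp, control_timepoint
                )
                rows.append({
                    "gene": gene, "condition": condition, "timepoint": tp,
                    "fold_change": fc.mean, "sd": fc.sd,
                    "p_value": p, "stars": star,
                })
    return pd.DataFrame(rows)
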