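"""Comparative-CT (ddCt) relative quantification.

fold = 2^-ddCt with ddCt = dCt_treatment - dCt_control and
dCt_g = mean Ct(target, g) - mean Ct(reference, g); replicate averaging is on
the Ct (cycle) scale, per the standard comparative-CT procedure, with no
outlier rejection. Only technical replicates are modeled.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

CT_COLUMNS = ("gene", "group", "replicate", "ct")


@dataclasses.dataclass(frozen=True)
class FoldChange:
    gene: str
    fold: float
    delta_ct_control: float
    delta_ct_treatment: float
    reference_gene: str
    per_replicate_folds: tuple[float, ...] | None = None


def _cell_cts(table: pd.DataFrame, gene: str, group: str) -> np.ndarray:
    cell = table[(table["gene"] == gene) & (table["group"] == group)]["ct"]
    if len(cell) == 0:
        raise ValueError(f"no Ct values for gene {gene!r} in group {group!r}")
    values = cell.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-finite Ct for gene {gene!r} in group {group!r}")
    return values


def delta_delta_ct(table: pd.DataFrame, target_gene: str, reference_gene: str,
                   control_group: str = "control",
                   treatment_group: str = "treatment",
                   per_replicate: bool = False) -> FoldChange:
    """Fold change of ``target_gene`` in treatment vs control.

    The canonical fold comes from replicate-mean Cts. With
    ``per_replicate=True`` the fold of each replicate pairing (replicate i of
    every cell) is also reported, for mean-of-folds style summaries.
    """
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    ct = {
        (gene, group): _cell_cts(table, gene, group)
        for gene in (target_gene, reference_gene)
        for group in (control_group, treatment_group)
    }
    d_control = ct[(target_gene, control_group)].mean() - ct[(reference_gene, control_group)].mean()
    d_treat = ct[(target_gene, treatment_group)].mean() - ct[(reference_gene, treatment_group)].mean()
    fold = float(2.0 ** -(d_treat - d_control))

    reps = None
    if per_replicate:
        n = min(len(v) for v in ct.values())
        reps = tuple(
            float(2.0 ** -(
                (ct[(target_gene, treatment_group)][i] - ct[(reference_gene, treatment_group)][i])
                - (ct[(target_gene, control_group)][i] - ct[(reference_gene, control_group)][i])
            ))
            for i in range(n)
        )
    return FoldChange(
        gene=target_gene,
        fold=fold,
        delta_ct_control=float(d_control),
        delta_ct_treatment=float(d_treat),
        reference_gene=reference_gene,
        per_replicate_folds=reps,
    )


def fold_changes(table: pd.DataFrame, reference_gene: str,
                 control_group: str = "control",
                 treatment_group: str = "treatment") -> pd.DataFrame:
    """ddCt fold change for every non-reference gene in the table."""
    genes = [g for g in table["gene"].unique() if g != reference_gene]
    rows = []
    for gene in genes:
        fc = delta_delta_ct(table, gene, reference_gene, control_group, treatment_group)
        rows.append({
            "gene": gene,
            "fold": fc.fold,
            "delta_ct_control": fc.delta_ct_control,
            "delta_ct_treatment": fc.delta_ct_treatment,
            "reference_gene": reference_gene,
        })
    return pd.DataFrame(rows)
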