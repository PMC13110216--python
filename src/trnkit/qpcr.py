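"""Relative expression from Ct tables via the ddCt method."""

from __future__ import annotations

import pandas as pd

__all__ = ["ddct"]


def ddct(
    table: pd.DataFrame,
    ref_gene: str = "Actb",
    ref_condition: str | None = None,
) -> pd.DataFrame:
    """Per-(gene, condition) relative expression 2**(-ddCt).

    Ct values are averaged over technical replicates per (sample, gene);
    dCt = Ct_gene - Ct_ref_gene within each sample; ddCt subtracts the mean
    dCt of the reference condition; relative expression is 2**(-ddCt) averaged
    over the condition's samples, so the reference condition normalizes to
    exactly 1. Assumes amplification efficiency 2 (no efficiency correction).
    """
    required = {"sample", "condition", "gene", "Ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if ref_condition is None:
        ref_condition = table["condition"].iloc[0]
    if ref_condition not in set(table["condition"]):
        raise ValueError(f"reference condition {ref_condition!r} absent from table")

    mean_ct = (
        table.groupby(["sample", "condition", "gene"], sort=False)["Ct"]
        .mean()
        .reset_index()
    )
    ref_ct = mean_ct[mean_ct["gene"] == ref_gene].set_index("sample")["Ct"]
    samples_missing_ref = sorted(set(mean_ct["sample"]) - set(ref_ct.index))
    if samples_missing_ref:
        raise ValueError(
            f"reference gene {ref_gene!r} missing for samples: {samples_missing_ref}"
        )

    work = mean_ct[mean_ct["gene"] != ref_gene].copy()
    work["dCt"] = work["Ct"] - work["sample"].map(ref_ct)

    ref_dct = (
        work[work["condition"] == ref_condition].groupby("gene")["dCt"].mean()
    )
    genes_missing_ref = sorted(set(work["gene"]) - set(ref_dct.index))
    if genes_missing_ref:
        raise ValueError(
            f"no reference-condition measurements for genes: {genes_missing_ref}"
        )
    work["ddCt"] = work["dCt"] - work["gene"].map(ref_dct)

    # condition-mean ddCt is exponentiated last, so the reference condition
    # comes out exactly 1
    out = (
        work.groupby(["gene", "condition"], sort=False)["ddCt"]
        .mean()
        .reset_index()
    )
    out["rel_expr"] = 2.0 ** (-out["ddCt"])
    return out[["gene", "condition", "rel_expr"]]
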