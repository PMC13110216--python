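"""Synthetic qPCR Ct tables with planted fold changes."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["simulate_qpcr"]


def simulate_qpcr(
    genes: list[str],
    conditions: list[str],
    planted_fold_changes: dict[tuple[str, str], float],
    reps: int = 3,
    seed: int = 0,
    noise_sd: float = 0.0,
    ref_gene: str = "Actb",
    ref_condition: str | None = None,
    base_ct: float = 20.0,
    n_technical: int = 3,
) -> pd.DataFrame:
    """Generate a long-format Ct table realizing the planted fold changes.

    Ct = base_ct - log2(expression) + N(0, noise_sd) per technical replicate,
    where expression of (gene, condition) is the planted fold change relative
    to `ref_condition` (default: first condition) and the reference gene sits
    at expression 1 everywhere. `reps` biological samples per condition, each
    measured in `n_technical` technical replicates.
    """
    if ref_condition is None:
        ref_condition = conditions[0]
    if ref_gene not in genes:
        genes = [ref_gene] + list(genes)
    for (g, c), fc in planted_fold_changes.items():
        if fc <= 0:
            raise ValueError(f"fold change for ({g!r}, {c!r}) must be > 0, got {fc}")

    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        for r in range(1, reps + 1):
            sample = f"{cond}_s{r}"
            for gene in genes:
                if gene == ref_gene:
                    expr = 1.0
                else:
                    expr = planted_fold_changes.get((gene, cond), 1.0)
                true_ct = base_ct - np.log2(expr)
                for t in range(1, n_technical + 1):
                    ct = true_ct + rng.normal(0.0, noise_sd) if noise_sd > 0 else true_ct
                    rows.append((sample, cond, gene, t, float(ct)))
    return pd.DataFrame(rows, columns=["sample", "condition", "gene", "replicate", "Ct"])
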