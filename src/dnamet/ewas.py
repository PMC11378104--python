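"""Per-cohort epigenome-wide association scans and CpG pre-selection.

Each scan regresses one (log + z transformed) metabolic feature on every
CpG's beta values separately within one cohort — the model is simply
``feature ~ CpG`` with no covariates.  Pre-selection keeps CpGs whose
association has a consistent sign and nominal significance in every
training cohort, enriching the elastic-net input for plausibly
predictive sites without committing to a genome-wide threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def run_ewas(target: pd.Series, betas: pd.DataFrame, cohort_labels: pd.Series | None = None,
             cohort: str | None = None) -> pd.DataFrame:
    """Univariate OLS of ``target`` on each CpG within one cohort.

    Returns a frame indexed by CpG id with columns slope, se, t, p, n.
    Zero-variance CpGs are omitted.  Implemented through the closed-form
    correlation identities (t = r sqrt((n-2)/(1-r^2))), vectorised over
    all CpGs at once.
    """
    if cohort_labels is not None and cohort is not None:
        keep = cohort_labels.loc[betas.index] == cohort
        betas = betas.loc[keep.to_numpy()]
        target = target.loc[betas.index]
    y = target.to_numpy(float)
    x = betas.to_numpy(float)
    n = len(y)
    if n < 3:
        raise ValueError("EWAS needs at least 3 samples")
    if np.isnan(y).any():
        raise ValueError("target contains missing values")

    yc = y - y.mean()
    xc = x - x.mean(0)
    sxx = (xc ** 2).sum(0)
    keep_cols = sxx > 0
    xc = xc[:, keep_cols]
    sxx = sxx[keep_cols]
    sxy = xc.T @ yc
    syy = float(yc @ yc)
    slope = sxy / sxx
    # residual SS = syy - slope * sxy
    sse = np.maximum(syy - slope * sxy, 0.0)
    dof = n - 2
    se = np.sqrt(sse / dof / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / se, np.sign(slope) * np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return pd.DataFrame({"slope": slope, "se": se, "t": t, "p": p, "n": n},
                        index=betas.columns[keep_cols])


def preselect_cpgs(ewas_tables: list[pd.DataFrame], preselect_p: float = 0.05) -> list[str]:
    """CpGs with the same slope sign and p < threshold in every table.

    Output order follows the first table's index (deterministic).
    Raises when the tables share no CpGs at all.
    """
    if len(ewas_tables) < 2:
        raise ValueError("pre-selection needs at least two cohort EWAS tables")
    common = ewas_tables[0].index
    for tbl in ewas_tables[1:]:
        common = common.intersection(tbl.index)
    if len(common) == 0:
        raise ValueError("EWAS tables have disjoint CpG universes")
    common_set = set(common)
    common = [c for c in ewas_tables[0].index if c in common_set]
    signs = np.column_stack([np.sign(t.loc[common, "slope"].to_numpy()) for t in ewas_tables])
    ps = np.column_stack([t.loc[common, "p"].to_numpy() for t in ewas_tables])
    ok = (np.abs(signs.sum(1)) == signs.shape[1]) & (ps < preselect_p).all(1)
    return [c for c, keep in zip(common, ok) if keep]
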