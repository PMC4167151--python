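"""Stem-loop qPCR relative quantification by the Livak 2^(-ddCt) method.

Per replicate dCt = Ct(miRNA) - Ct(U6); ddCt = mean dCt(treated) -
mean dCt(control); relative expression fold = 2^(-ddCt), so a negative
ddCt (fewer cycles under treatment) is up-regulation.  Group difference is
an independent two-sample t-test on the replicate dCt sets (pooled
variance by default, Welch optional), starred at p < 0.05 (*) and
p < 0.01 (**).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["mirna_id", "condition", "replicate", "ct_mirna", "ct_u6"]


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    bad = df[(df.ct_mirna <= 0) | (df.ct_mirna >= 45) | (df.ct_u6 <= 0) | (df.ct_u6 >= 45)]
    if len(bad):
        raise ValueError("Ct values outside (0, 45)")
    return df


@dataclass
class QpcrResult:
    mirna_id: str
    delta_ct_control: np.ndarray
    delta_ct_treated: np.ndarray
    ddct: float
    fold: float
    t_stat: float
    p_value: float
    stars: str

    def direction(self) -> str:
        return "up" if self.fold > 1 else "down" if self.fold < 1 else "flat"


def ddct_fold(table: pd.DataFrame, mirna_id: str, welch: bool = False) -> QpcrResult:
    """ddCt, fold and t-test for one miRNA.

    Requires at least 2 replicates in each condition.  With zero variance
    in both groups the t statistic is undefined and reported as NaN.
    """
    sub = table[table.mirna_id == mirna_id]
    dct = {}
    for cond in ("control", "treated"):
        grp = sub[sub.condition == cond]
        if len(grp) < 2:
            raise ValueError(f"{mirna_id}: need >= 2 {cond} replicates")
        dct[cond] = (grp.ct_mirna - grp.ct_u6).to_numpy(dtype=float)
    ddct = float(dct["treated"].mean() - dct["control"].mean())
    fold = 2.0 ** (-ddct)
    if dct["treated"].var(ddof=1) == 0.0 and dct["control"].var(ddof=1) == 0.0:
        t = p = float("nan")   # undefined with no within-group variance
    else:
        t, p = stats.ttest_ind(dct["treated"], dct["control"], equal_var=not welch)
        t, p = float(t), float(p)
    if math.isnan(t):
        stars = ""
    else:
        stars = "**" if p < 0.01 else "*" if p < 0.05 else ""
    return QpcrResult(mirna_id, dct["control"], dct["treated"], ddct, fold, t, p, stars)


def qpcr_table(table: pd.DataFrame, welch: bool = False) -> pd.DataFrame:
    """ddct_fold for every miRNA in a Ct table."""
    rows = []
    for mid in table.mirna_id.unique():
        r = ddct_fold(table, mid, welch=welch)
        rows.append({"mirna_id": r.mirna_id, "ddct": r.ddct, "fold": r.fold,
                     "t_stat": r.t_stat, "p_value": r.p_value, "stars": r.stars,
                     "direction": r.direction()})
    return pd.DataFrame(rows)
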