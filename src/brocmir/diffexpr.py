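"""Differential read-count analysis between two sRNA libraries.

Counts are normalised to reads per million (NC); a zero NC is replaced by
0.01 for fold-change purposes and miRNAs with both NCs below 1 are excluded
as unquantifiable.  Significance uses the Audic-Claverie statistic: under
Poisson sampling proportional to library sizes, the probability of seeing
y reads in library 2 given x in library 1 is

    p(y | x) = r^y * (x+y)! / ( x! y! (1+r)^(x+y+1) ),   r = N2/N1,

a negative-binomial mass in y that sums to one.  The lower/upper tail sums
C and D give one-sided p-values; the reported two-sided value doubles the
smaller tail (capped at 1).  The upstream study labels this quantity "FDR";
it is a per-miRNA probability, so an optional Benjamini-Hochberg adjustment
is exposed but off by default.  A miRNA is called differential when
|log2 fold change| > 1 and p < 0.01 (both strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

ZERO_NC = 0.01
MIN_NC = 1.0
_REL_TOL = 1e-15


def normalize(raw: int, total: int) -> float:
    """Reads per million: raw / total * 1e6 (before zero substitution)."""
    if total <= 0:
        raise ValueError("library total must be positive")
    return raw / total * 1e6


def fold_change(nc_control: float, nc_treated: float) -> float:
    """log2(NC_treated / NC_control), zeros already substituted by 0.01."""
    a = nc_control if nc_control > 0 else ZERO_NC
    b = nc_treated if nc_treated > 0 else ZERO_NC
    return math.log2(b / a)


def ac_point_prob(x: int, y: int, n1: int, n2: int) -> float:
    """Audic-Claverie point mass p(y | x) at library-size ratio r = N2/N1."""
    if x < 0 or y < 0 or n1 <= 0 or n2 <= 0:
        raise ValueError("counts must be >= 0 and totals > 0")
    r = n2 / n1
    if x + y <= 500:
        # exact binomial coefficient keeps full double precision
        logp = (math.log(math.comb(x + y, y)) + y * math.log(r)
                - (x + y + 1) * math.log1p(r))
    else:
        logp = (y * math.log(r)
                + gammaln(x + y + 1) - gammaln(x + 1) - gammaln(y + 1)
                - (x + y + 1) * math.log1p(r))
    return float(math.exp(logp))


def ac_tail_p(x: int, y: int, n1: int, n2: int):
    """Lower tail C = sum_{y'<=y} p(y'|x), upper tail D = sum_{y'>=y} p(y'|x),
    and the two-sided p = min(1, 2*min(C, D)).

    The lower tail is the exact finite sum over y' = 0..y (descending term
    recurrence, compensated summation); the infinite upper tail runs the
    recurrence p(y'+1) = p(y') * r (x+y'+1) / ((y'+1)(1+r)) until terms fall
    below 1e-15 of the accumulated sum.

    Returns (C, D, p_two_sided).
    """
    r = n2 / n1
    point = ac_point_prob(x, y, n1, n2)
    # lower tail: all y+1 terms, walking down from y
    lower_terms = [point]
    t = point
    for yp in range(y, 0, -1):
        t = t * yp * (1 + r) / (r * (x + yp))
        lower_terms.append(t)
    c = min(math.fsum(lower_terms), 1.0)
    # upper tail: walk up until negligible
    upper_terms = []
    t = point
    yy = y
    acc = 0.0
    while t > _REL_TOL * (acc + t) or yy < y + 10:
        upper_terms.append(t)
        acc += t
        t = t * r * (x + yy + 1) / ((yy + 1) * (1 + r))
        yy += 1
        if yy > y + 10_000_000:  # pragma: no cover - defensive
            break
    d = min(math.fsum(upper_terms), 1.0)
    return c, d, min(1.0, 2.0 * min(c, d))


@dataclass
class DifferentialRecord:
    mirna_id: str
    x: int
    y: int
    n1: int
    n2: int
    nc_control: float
    nc_treated: float
    log2fc: float
    p_point: float
    p_tail: float
    c_lower: float
    d_upper: float
    significant: bool
    direction: str
    excluded: bool = False


def differential_table(counts: pd.DataFrame, n1: int, n2: int,
                       log2fc_cut: float = 1.0, p_cut: float = 0.01,
                       bh_adjust: bool = False) -> pd.DataFrame:
    """Full differential-expression table.

    ``counts`` needs columns ``id``, ``count_control``, ``count_treated``;
    ``n1``/``n2`` are the library clean-read totals.  miRNAs with both NCs
    below 1 are marked ``excluded`` and never called significant.  With
    ``bh_adjust`` a ``p_adj`` column is added and used for the call.
    """
    recs = []
    for row in counts.itertuples():
        x, y = int(row.count_control), int(row.count_treated)
        nc_c, nc_t = normalize(x, n1), normalize(y, n2)
        excluded = nc_c < MIN_NC and nc_t < MIN_NC
        lfc = fold_change(nc_c, nc_t)
        c, d, p = ac_tail_p(x, y, n1, n2)
        recs.append({
            "id": row.id, "x": x, "y": y,
            "nc_control": nc_c, "nc_treated": nc_t, "log2fc": lfc,
            "p_point": ac_point_prob(x, y, n1, n2),
            "c_lower": c, "d_upper": d, "p_tail": p, "excluded": excluded,
        })
    df = pd.DataFrame(recs)
    if df.empty:
        return df
    pcol = "p_tail"
    if bh_adjust:
        df["p_adj"] = _bh(df["p_tail"].to_numpy())
        pcol = "p_adj"
    df["significant"] = (~df.excluded) & (df.log2fc.abs() > log2fc_cut) & (df[pcol] < p_cut)
    df["direction"] = np.where(~df.significant, "flat",
                               np.where(df.log2fc > 0, "up", "down"))
    return df


def call_differential(df: pd.DataFrame, log2fc_cut: float = 1.0,
                      p_cut: float = 0.01) -> pd.DataFrame:
    """Re-flag an existing differential table at the given cuts (strict
    inequalities on both)."""
    df = df.copy()
    df["significant"] = (~df.excluded) & (df.log2fc.abs() > log2fc_cut) & (df.p_tail < p_cut)
    df["direction"] = np.where(~df.significant, "flat",
                               np.where(df.log2fc > 0, "up", "down"))
    return df


def _bh(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        k = n - rank_from_end
        running = min(running, p[idx] * n / k)
        adj[idx] = running
    return adj
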