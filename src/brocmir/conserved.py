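"""Conserved miRNA identification.

Tags are assigned to known miRNA families when they lie within 2 edits
(substitutions and gaps at unit cost) of a family's mature or precursor
reference; against precursors the distance is the best over all windows
(infix alignment).  Each family's representative is its highest-count
member and family counts sum member reads.  Families whose representative
cannot be placed in a genomic hairpin are flagged pseudo-miRNAs.

The expression noise floor is set adaptively: a geometric noise model is
fitted to the bulk of the unique-tag count histogram and the threshold is
the smallest count at which the empirical tail departs from the fitted
conditional tail by more than the Kolmogorov-Smirnov critical value at
alpha = 0.01.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from . import hairpin as hp
from .genomemap import revcomp

MAX_EDITS = 2


def edit_distance(a: str, b: str, infix: bool = False) -> int:
    """Unit-cost Levenshtein distance; with ``infix`` the best alignment of
    ``a`` against any window of ``b``."""
    res = edlib.align(a, b, task="distance", mode="HW" if infix else "NW")
    return res["editDistance"]


@dataclass
class FamilyAssignment:
    family: str
    representative_seq: str = ""
    members: list = field(default_factory=list)   # (seq, edits)
    count_control: int = 0
    count_treated: int = 0
    is_pseudo: bool | None = None
    pseudo_reason: str | None = None


def _parse_reference_header(header: str):
    """``family|type`` headers; type is mature or precursor."""
    parts = header.split("|")
    family = parts[0]
    kind = parts[1] if len(parts) > 1 else "mature"
    return family, kind


def load_reference(path) -> list[tuple[str, str, str]]:
    """Reference FASTA -> list of (family, kind, seq), T-normalised."""
    out = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    fam, kind = _parse_reference_header(name)
                    out.append((fam, kind, "".join(chunks).upper().replace("U", "T")))
                name, chunks = line[1:], []
            elif line:
                chunks.append(line)
    if name is not None:
        fam, kind = _parse_reference_header(name)
        out.append((fam, kind, "".join(chunks).upper().replace("U", "T")))
    return out


def assign_conserved(tags: pd.DataFrame, reference, max_edits: int = MAX_EDITS
                     ) -> list[FamilyAssignment]:
    """Assign each tag to its best family within ``max_edits``.

    ``reference`` is a path or a list of (family, kind, seq).  A tag hitting
    several families goes to the smallest edit distance; ties break toward
    the family with more reference sequences, then lexicographic name.
    Returns families sorted by name; representative = highest-count member
    (ties toward the lexicographically smaller sequence).
    """
    if not isinstance(reference, list):
        reference = load_reference(reference)
    if not reference:
        return []
    fam_sizes: dict[str, int] = {}
    for fam, _, _ in reference:
        fam_sizes[fam] = fam_sizes.get(fam, 0) + 1

    assignments: dict[str, FamilyAssignment] = {}
    for row in tags.itertuples():
        best = None
        for fam, kind, seq in reference:
            d = edit_distance(row.seq, seq, infix=(kind == "precursor"))
            key = (d, -fam_sizes[fam], fam)
            if best is None or key < best[0]:
                best = (key, fam)
        (d, _, _), fam = best
        if d > max_edits:
            continue
        fa = assignments.setdefault(fam, FamilyAssignment(family=fam))
        fa.members.append((row.seq, d))
        fa.count_control += row.count_control
        fa.count_treated += row.count_treated

    counts = {r.seq: r.count_control + r.count_treated for r in tags.itertuples()}
    for fa in assignments.values():
        fa.representative_seq = min(fa.members, key=lambda m: (-counts[m[0]], m[0]))[0]
    return sorted(assignments.values(), key=lambda f: f.family)


def flag_pseudo(assignments, genome: dict[str, str], genome_index=None,
                params: hp.MireapParams | None = None):
    """Partition families into real and pseudo miRNAs.

    A family is pseudo iff no genomic locus of its representative yields a
    precursor window that folds into a stem-loop passing the hairpin
    criteria.  Unmapped representatives are pseudo with reason "no locus".
    """
    from .genomemap import GenomeIndex
    params = params or hp.MireapParams()
    idx = genome_index or GenomeIndex(genome)
    for fa in assignments:
        rep = fa.representative_seq
        hits = idx.map_tag(rep, max_mismatch=1)
        if not hits:
            fa.is_pseudo, fa.pseudo_reason = True, "no locus"
            continue
        fa.is_pseudo, fa.pseudo_reason = True, "no hairpin"
        for h in hits[:params.max_copies]:
            chrom_seq = idx.genome[h.chrom]
            for ws, we in ((h.start - params.flank, h.end + params.max_space),
                           (h.start - params.max_space, h.end + params.flank)):
                ws, we = max(1, ws), min(len(chrom_seq), we)
                sub = chrom_seq[ws - 1:we]
                if h.strand == "-":
                    sub = revcomp(sub)
                    off = we - h.end
                else:
                    off = h.start - ws
                struct = hp.fold(sub)
                if hp.evaluate_criteria(struct, off, off + len(rep) - 1, params).passed:
                    fa.is_pseudo, fa.pseudo_reason = False, None
                    break
            if not fa.is_pseudo:
                break
    real = [f for f in assignments if not f.is_pseudo]
    pseudo = [f for f in assignments if f.is_pseudo]
    return real, pseudo


# ---------------------------------------------------------------------------
# Adaptive noise threshold
# ---------------------------------------------------------------------------

@dataclass
class NoiseThreshold:
    threshold: int
    ks_statistic: float
    fitted_noise_param: float


_KS_C_ALPHA_001 = 1.628  # Kolmogorov critical coefficient at alpha = 0.01


def _truncated_geometric_mle(mean_obs: float, t: float) -> float:
    """Success probability of a geometric (support 1, 2, ...) whose
    conditional mean on {X <= t} equals ``mean_obs``."""
    from scipy.optimize import brentq

    def cond_mean(p):
        lq = math.log1p(-p)
        qt = math.exp(t * lq)
        return 1.0 / p - t * qt / (-math.expm1(t * lq))

    if mean_obs <= 1.0 + 1e-12:
        return 1.0
    if mean_obs >= (t + 1.0) / 2.0 - 1e-9:   # at or past the flat (p -> 0) limit
        return 1.0 / mean_obs
    return float(brentq(lambda p: cond_mean(p) - mean_obs, 1e-9, 1.0 - 1e-9, xtol=1e-12))


def noise_threshold(count_histogram: dict[int, int], alpha_c: float = _KS_C_ALPHA_001,
                    min_tail: int = 10) -> NoiseThreshold:
    """Adaptive expression threshold from the unique-tag count histogram.

    Fits a geometric noise model (support 1, 2, ...) by maximum likelihood
    to counts at or below their 90th percentile, then scans candidate
    thresholds c upward; the threshold is the smallest c at which the KS
    distance between the empirical distribution of counts >= c and the
    fitted conditional tail exceeds the alpha = 0.01 critical value
    ``alpha_c / sqrt(n_c)``.  If no candidate exceeds it (pure noise), the
    threshold is max(count) + 1: nothing is declared above noise.
    """
    items = sorted(count_histogram.items())
    if not items or all(c <= 0 for _, c in items):
        raise ValueError("empty count histogram")
    values = np.array([v for v, _ in items], dtype=float)
    freqs = np.array([f for _, f in items], dtype=float)
    n = freqs.sum()
    if n < 100:
        warnings.warn("fewer than 100 unique tags; threshold unreliable")
    if len(values) == 1:
        warnings.warn("degenerate count histogram; threshold set to 1")
        return NoiseThreshold(1, 0.0, 1.0)

    # geometric MLE on the bulk (counts <= 90th percentile), correcting for
    # the truncation: solve E[X | X <= T] = observed bulk mean
    cum = np.cumsum(freqs)
    p90 = values[np.searchsorted(cum, 0.9 * n)]
    bulk = values <= p90
    mean_bulk = (values[bulk] * freqs[bulk]).sum() / freqs[bulk].sum()
    p_hat = _truncated_geometric_mle(mean_bulk, float(p90))
    if p_hat >= 1.0:
        warnings.warn("degenerate count histogram; threshold set to 1")
        return NoiseThreshold(1, 0.0, float(p_hat))

    max_count = int(values[-1])
    ks_at = 0.0
    for c in range(1, max_count + 1):
        sel = values >= c
        n_c = freqs[sel].sum()
        if n_c < min_tail:
            break
        # empirical CDF of counts >= c vs geometric tail conditional on >= c
        v = values[sel]
        emp = np.cumsum(freqs[sel]) / n_c
        # P(X <= k | X >= c) = 1 - (1-p)^(k - c + 1)
        model = 1.0 - (1.0 - p_hat) ** (v - c + 1)
        ks = np.abs(emp - model).max()
        crit = alpha_c / math.sqrt(n_c)
        if ks > crit:
            return NoiseThreshold(int(c), float(ks), float(p_hat))
        ks_at = ks
    return NoiseThreshold(max_count + 1, float(ks_at), float(p_hat))
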