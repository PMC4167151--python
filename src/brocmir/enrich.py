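"""GO-style classification and hypergeometric term enrichment of predicted
target genes against a user-supplied background.

Term maps are 3-column TSV (term, namespace, gene); namespaces come from
the GO trio plus "pathway".  Enrichment is the upper-tail hypergeometric
probability of drawing at least k term-annotated genes in a target list of
size n from a background of size M containing K annotated genes; optional
Benjamini-Hochberg adjustment.  No DAG propagation: terms are flat sets.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

NAMESPACES = {"cellular_component", "biological_process", "molecular_function", "pathway"}


class TermMap:
    def __init__(self, terms: dict[str, tuple[str, set]]):
        for term, (ns, genes) in terms.items():
            if ns not in NAMESPACES:
                raise ValueError(f"unknown namespace {ns!r} for term {term!r}")
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")
        self.terms = terms

    @classmethod
    def from_tsv(cls, path):
        df = pd.read_csv(path, sep="\t", names=["term", "namespace", "gene"],
                         header=None, comment="#")
        terms = {}
        for row in df.itertuples():
            ns, genes = terms.setdefault(row.term, (row.namespace, set()))
            genes.add(row.gene)
        return cls(terms)

    def annotated_genes(self) -> set:
        out = set()
        for _, genes in self.terms.values():
            out |= genes
        return out


def classify(targets, term_map: TermMap) -> pd.DataFrame:
    """Per-term target counts (a gene may land in many terms).

    Returns a frame (term, namespace, count, genes); unannotated targets
    are tallied under the pseudo-term ``<unannotated>``.
    """
    targets = set(targets)
    rows = []
    for term, (ns, genes) in sorted(term_map.terms.items()):
        inside = targets & genes
        rows.append({"term": term, "namespace": ns, "count": len(inside),
                     "genes": ",".join(sorted(inside))})
    unann = targets - term_map.annotated_genes()
    rows.append({"term": "<unannotated>", "namespace": "", "count": len(unann),
                 "genes": ",".join(sorted(unann))})
    return pd.DataFrame(rows)


def enrich(targets, background, term_map: TermMap, bh_adjust: bool = True) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per term.

    ``targets`` must be a subset of ``background``; p = P(X >= k) with
    X ~ Hypergeom(M=|background|, K=|term ∩ background|, n=|targets|).
    """
    targets, background = set(targets), set(background)
    stray = targets - background
    if stray:
        raise ValueError(f"targets not in background: {sorted(stray)}")
    M, n = len(background), len(targets)
    rows = []
    for term, (ns, genes) in sorted(term_map.terms.items()):
        K = len(genes & background)
        k = len(genes & targets)
        p = float(hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append({"term": term, "namespace": ns, "k": k, "K": K,
                     "n": n, "M": M, "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if bh_adjust and len(df):
        from .diffexpr import _bh
        df["p_adj"] = _bh(df.p_value.to_numpy())
    return df
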