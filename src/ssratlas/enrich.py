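"""Hypergeometric over-representation analysis (ORA) with BH adjustment.

Given a selected gene set and a gene->term annotation, each term is
tested for over-representation with the upper-tail hypergeometric
probability P[X >= k] where X ~ Hypergeom(N, K, n): N genes in the
universe, K annotated to the term, n selected, k in the overlap.
P-values are adjusted across terms by Benjamini-Hochberg and flagged
significant at adjusted p < alpha (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05


@dataclass
class TermMap:
    """term id -> annotated gene set, plus the gene universe."""

    terms: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(g) for t, g in self.terms.items()}
        if not self.universe:
            u: set[str] = set()
            for g in self.terms.values():
                u |= g
            self.universe = frozenset(u)
        else:
            self.universe = frozenset(self.universe)
            for t, g in self.terms.items():
                if not g <= self.universe:
                    raise ValueError(f"term {t} annotates genes outside the universe")

    @classmethod
    def from_tsv(cls, path, universe: Optional[Iterable[str]] = None) -> "TermMap":
        """Read a two-column (gene_id, term_id) TSV with a header row."""
        df = pd.read_csv(path, sep="\t")
        gene_col, term_col = df.columns[:2]
        terms: dict[str, set[str]] = {}
        for gene, term in zip(df[gene_col].astype(str), df[term_col].astype(str)):
            terms.setdefault(term, set()).add(gene)
        return cls(
            terms={t: frozenset(g) for t, g in terms.items()},
            universe=frozenset(universe) if universe is not None else frozenset(),
        )


def hypergeom_enrichment(
    selected: Iterable[str],
    annotation: TermMap,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Test every term for over-representation in ``selected``.

    Returns a DataFrame (one row per term, sorted by adjusted then raw p,
    then term id) with columns term, overlap, term_size, selected_size,
    universe_size, p_raw, p_adj, significant.  Terms with zero overlap
    get p_raw = 1.  Selected genes must lie inside the universe.
    """
    sel = frozenset(selected)
    if not sel <= annotation.universe:
        extra = sorted(sel - annotation.universe)[:5]
        raise ValueError(f"selected genes outside universe, e.g. {extra}")
    N = len(annotation.universe)
    n = len(sel)
    rows = []
    for term, genes in sorted(annotation.terms.items()):
        K = len(genes)
        k = len(sel & genes)
        p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "overlap": k,
                "term_size": K,
                "selected_size": n,
                "universe_size": N,
                "p_raw": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p_raw"].to_numpy(), method="fdr_bh")[1]
        df["significant"] = df["p_adj"] < alpha
        df = df.sort_values(["p_adj", "p_raw", "term"], kind="stable").reset_index(
            drop=True
        )
    return df
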