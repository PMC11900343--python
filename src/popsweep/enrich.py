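"""Over-representation analysis of candidate gene lists.

A generic replacement for web-based GO/KEGG enrichment: given a user-supplied
gene→term annotation and an explicit gene universe, each term is tested with
the hypergeometric upper tail P(X ≥ k), where k of the n candidate genes fall
in a term covering K of the N universe genes.  Benjamini–Hochberg adjusted
p-values are reported alongside; the default significance filter uses the
raw p < alpha rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class TermMap:
    """term id → gene set, plus the explicit gene universe."""

    terms: dict[str, set[str]]
    universe: set[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"term {term!r} contains genes outside the universe: "
                    f"{sorted(extra)[:5]}"
                )

    @classmethod
    def from_tsv(cls, gene_term_path, universe, descriptions_path=None) -> "TermMap":
        """Build from a 2-column TSV (gene_id, term_id) and a universe
        iterable; unknown genes in the map are dropped with a warning."""
        df = pd.read_csv(gene_term_path, sep="\t", dtype=str)
        if not {"gene_id", "term_id"} <= set(df.columns):
            raise ValueError("gene→term TSV needs columns gene_id, term_id")
        universe = set(universe)
        unknown = set(df["gene_id"]) - universe
        if unknown:
            warnings.warn(
                f"{len(unknown)} annotated genes outside the universe dropped"
            )
            df = df[df["gene_id"].isin(universe)]
        terms = {t: set(sub["gene_id"]) for t, sub in df.groupby("term_id")}
        descriptions = {}
        if descriptions_path is not None:
            ddf = pd.read_csv(descriptions_path, sep="\t", dtype=str)
            descriptions = dict(zip(ddf["term_id"], ddf["description"]))
        return cls(terms=terms, universe=universe, descriptions=descriptions)


def ora_test(candidates, term_map: TermMap) -> pd.DataFrame:
    """Hypergeometric over-representation test of ``candidates`` against
    every term; rows sorted by raw p with BH-adjusted p alongside.

    Candidates outside the universe are dropped with a warning; an empty
    candidate set yields an empty result.
    """
    cand = set(candidates)
    outside = cand - term_map.universe
    if outside:
        warnings.warn(
            f"{len(outside)} candidate genes outside the universe dropped"
        )
        cand &= term_map.universe
    columns = ["term_id", "description", "k", "K", "n", "N", "p_value", "bh_adjusted_p"]
    if not cand:
        warnings.warn("empty candidate set: no enrichment computed")
        return pd.DataFrame(columns=columns)
    N = len(term_map.universe)
    n = len(cand)
    rows = []
    for term in sorted(term_map.terms):
        genes = term_map.terms[term]
        K = len(genes)
        k = len(cand & genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term,
                "description": term_map.descriptions.get(term, ""),
                "k": k, "K": K, "n": n, "N": N,
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    df["bh_adjusted_p"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)


def filter_significant(
    rows: pd.DataFrame, alpha: float = 0.05, use_adjusted: bool = False
) -> pd.DataFrame:
    """Keep terms with p strictly below ``alpha`` (raw p by default)."""
    if rows.empty:
        return rows
    col = "bh_adjusted_p" if use_adjusted else "p_value"
    return rows[rows[col] < alpha].reset_index(drop=True)
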