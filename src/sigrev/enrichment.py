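"""Over-representation analysis with combined scores and consensus lists.

Per term the test is the one-sided Fisher exact (hypergeometric upper tail)
on query/term membership within an explicit background universe.  The
combined score multiplies -ln(p) by a rank-deviation z computed against an
explicit permutation null (random query sets of matched size), emulating the
EnrichR statistic in a self-contained, seeded way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import bh_adjust


@dataclass
class GeneSetLibrary:
    name: str
    sets: dict  # term -> frozenset of genes
    universe: frozenset

    def __post_init__(self) -> None:
        self.sets = {t: frozenset(g) for t, g in self.sets.items()}
        self.universe = frozenset(self.universe)
        for term, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set {term!r}")
            if not genes <= self.universe:
                extra = sorted(genes - self.universe)
                raise ValueError(f"set {term!r} has members outside the universe: {extra[:5]}")


def overrepresentation_test(query: set, library: GeneSetLibrary) -> pd.DataFrame:
    """One-sided Fisher exact test of the query against every library term.

    Query genes outside the universe are dropped (count recorded in
    ``df.attrs['n_dropped']``).  p-values are BH-adjusted across terms.
    """
    if not library.sets:
        raise ValueError("empty library")
    query = set(query)
    inside = query & library.universe
    n_dropped = len(query) - len(inside)
    if not inside:
        raise ValueError("query has no genes in the library universe")

    m = len(library.universe)
    q = len(inside)
    rows = []
    for term in sorted(library.sets):
        genes = library.sets[term]
        k = len(inside & genes)
        # upper tail: P(overlap >= k)
        p = float(stats.hypergeom.sf(k - 1, m, len(genes), q))
        rows.append(
            {
                "term": term,
                "overlap_count": k,
                "set_size": len(genes),
                "query_size": q,
                "universe_size": m,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out.attrs["n_dropped"] = n_dropped
    return out


@dataclass
class RankNullSummary:
    """Per-term mean/sd of significance ranks under random matched queries."""

    mean_rank: pd.Series
    sd_rank: pd.Series
    n_null: int
    query_size: int


def build_rank_null(
    library: GeneSetLibrary,
    query_size: int,
    n_null: int = 200,
    rng: np.random.Generator | None = None,
) -> RankNullSummary:
    """Rank-distribution null from random query sets of matched size."""
    if n_null < 100:
        raise ValueError("need at least 100 null query sets")
    rng = rng or np.random.default_rng(0)
    universe = np.array(sorted(library.universe))
    query_size = min(query_size, len(universe))
    terms = sorted(library.sets)
    ranks = np.empty((n_null, len(terms)))
    for i in range(n_null):
        null_query = set(rng.choice(universe, size=query_size, replace=False))
        res = overrepresentation_test(null_query, library).set_index("term")
        ranks[i] = stats.rankdata(res.loc[terms, "p"].to_numpy(), method="average")
    return RankNullSummary(
        mean_rank=pd.Series(ranks.mean(axis=0), index=terms),
        sd_rank=pd.Series(ranks.std(axis=0, ddof=1), index=terms),
        n_null=n_null,
        query_size=query_size,
    )


def combined_score(records: pd.DataFrame, null_summary: RankNullSummary) -> pd.DataFrame:
    """EnrichR-style combined score: c = -ln(p) * z.

    z is the deviation of the observed significance rank from its null mean,
    in null sd units, sign-flipped so larger z = more enriched.  Terms whose
    null rank never varies get z = 0 with a warning.
    """
    out = records.copy()
    obs_rank = stats.rankdata(out["p"].to_numpy(), method="average")
    mean = null_summary.mean_rank.reindex(out["term"]).to_numpy()
    sd = null_summary.sd_rank.reindex(out["term"]).to_numpy()
    degenerate = (sd == 0) | np.isnan(sd)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} terms have zero null-rank variance; z set to 0",
            stacklevel=2,
        )
    z = np.where(degenerate, 0.0, (mean - obs_rank) / np.where(degenerate, 1.0, sd))
    with np.errstate(divide="ignore"):
        neg_log_p = -np.log(out["p"].to_numpy())
    out["z"] = z
    out["combined"] = neg_log_p * z
    return out


def enrich(
    query: set,
    library: GeneSetLibrary,
    n_null: int = 200,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """ORA + combined score in one call (convenience wrapper)."""
    records = overrepresentation_test(query, library)
    null = build_rank_null(library, query_size=records["query_size"].iloc[0], n_null=n_null, rng=rng)
    return combined_score(records, null)


@dataclass
class ConsensusList:
    library_name: str
    rows: pd.DataFrame  # term x signature combined scores + inclusion flag
    included_terms: list


def build_consensus_list(
    per_signature_results: Mapping[str, pd.DataFrame],
    k: int = 5,
    alpha: float = 0.05,
    library_name: str = "",
) -> ConsensusList:
    """Union of per-signature top-k terms, kept if padj < alpha somewhere.

    A term enters the consensus when it is among a signature's top-k by
    combined score AND reaches padj < alpha in at least one signature.
    k=20 reproduces the cell-line (CCLE-style) consensus variant.  The full
    term x signature matrix of combined scores is returned for export.
    """
    if not per_signature_results:
        raise ValueError("no per-signature results supplied")
    sig_ids = sorted(per_signature_results)
    tables = {s: t.set_index("term") for s, t in per_signature_results.items()}

    top_terms: set = set()
    for s in sig_ids:
        t = tables[s]
        top = t.sort_values(["combined", "term"], ascending=[False, True], kind="mergesort").head(k)
        top_terms |= set(top.index)

    all_terms = sorted(set().union(*(set(t.index) for t in tables.values())))
    combined_mat = pd.DataFrame(
        {s: tables[s]["combined"].reindex(all_terms) for s in sig_ids}, index=all_terms
    )
    padj_mat = pd.DataFrame(
        {s: tables[s]["padj"].reindex(all_terms) for s in sig_ids}, index=all_terms
    )
    significant_somewhere = (padj_mat < alpha).any(axis=1)
    included = sorted(t for t in top_terms if significant_somewhere.get(t, False))

    rows = combined_mat.copy()
    rows.columns = [f"combined_{s}" for s in sig_ids]
    for s in sig_ids:
        rows[f"padj_{s}"] = padj_mat[s]
    rows["included"] = [t in included for t in rows.index]
    return ConsensusList(library_name=library_name, rows=rows, included_terms=included)
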