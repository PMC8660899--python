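"""Over-representation analysis with an Enrichr-style combined score.

Each gene set ("term") is tested for over-representation in a query list
against a universe with the hypergeometric upper tail (Fisher's one-sided
exact test), corrected across the collection with Benjamini-Hochberg.
Terms are additionally scored by how far their rank (by p-value) deviates
from the rank expected for random queries of the same size: a Monte-Carlo
z-score, combined with the p-value as

    combined_score = ln(p) * z,   z = (observed_rank - mean_rank) / sd_rank

so that strongly enriched terms with better-than-expected ranks (z < 0,
ln p < 0) receive large positive scores.  The z is computed by seeded
resampling because no precomputed rank tables are assumed.

Gene identifiers are matched case-insensitively after whitespace
stripping; unmatched query ids are reported via logging, never silently
dropped.  The recommended universe is the constitutive feature set of the
analyzed matrix rather than the whole genome, to respect detection bias.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata

from .datamodel import GeneSet, GeneSetCollection
from .de import bh_adjust

log = logging.getLogger(__name__)


def _norm(identifier: str) -> str:
    return str(identifier).strip().upper()


def hypergeometric_enrichment(
    query: Iterable[str], term: GeneSet | Sequence[str], universe: Iterable[str]
) -> tuple[int, float]:
    """Overlap k and exact upper-tail p = P(X >= k), X ~ Hypergeom(N, K, n).

    The term is intersected with the universe; the query must be a subset
    of the universe.  Matching is case-insensitive, whitespace-stripped.
    """
    uni = {_norm(g) for g in universe}
    if not uni:
        raise ValueError("empty universe")
    q = {_norm(g) for g in query}
    if not q:
        raise ValueError("empty query")
    outside = q - uni
    if outside:
        raise ValueError(
            f"query ids outside the universe: {sorted(outside)[:5]}"
        )
    members = term.members if isinstance(term, GeneSet) else term
    t = {_norm(g) for g in members} & uni
    k = len(q & t)
    n_u, n_t, n_q = len(uni), len(t), len(q)
    p = float(hypergeom.sf(k - 1, n_u, n_t, n_q))
    return k, min(p, 1.0)


def _membership_matrix(
    collection: GeneSetCollection, universe_norm: list[str]
) -> np.ndarray:
    pos = {g: j for j, g in enumerate(universe_norm)}
    m = np.zeros((len(collection), len(universe_norm)), dtype=bool)
    for i, term in enumerate(collection):
        for g in term.members:
            j = pos.get(_norm(g))
            if j is not None:
                m[i, j] = True
    return m


def _pvalues_for_counts(k: np.ndarray, big_n: int, big_k: np.ndarray, n: int) -> np.ndarray:
    return np.minimum(hypergeom.sf(k - 1, big_n, big_k, n), 1.0)


def rank_deviation_z(
    collection: GeneSetCollection,
    query_size: int,
    universe: Iterable[str],
    observed_p: np.ndarray,
    n_resamples: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo z-scores of rank deviation for every term.

    Draws ``n_resamples`` random queries of ``query_size`` from the
    universe, ranks all terms by p-value in each draw (mid-ranks on ties),
    and standardizes the observed ranks against the resampled rank
    distribution: z = (observed - mean) / sd.  Terms whose resampled rank
    never varies get z = 0 with a warning.  Fully reproducible from the
    seed.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100 for a stable z")
    universe_norm = sorted({_norm(g) for g in universe})
    big_n = len(universe_norm)
    m = _membership_matrix(collection, universe_norm)
    big_k = m.sum(axis=1)
    rng = np.random.default_rng(seed)
    sum_r = np.zeros(len(collection))
    sum_r2 = np.zeros(len(collection))
    for _ in range(n_resamples):
        idx = rng.choice(big_n, size=query_size, replace=False)
        k = m[:, idx].sum(axis=1)
        p = _pvalues_for_counts(k, big_n, big_k, query_size)
        r = rankdata(p)
        sum_r += r
        sum_r2 += r**2
    mean = sum_r / n_resamples
    var = sum_r2 / n_resamples - mean**2
    sd = np.sqrt(np.maximum(var, 0.0))
    observed_rank = rankdata(np.asarray(observed_p, dtype=float))
    z = np.zeros(len(collection))
    degenerate = sd <= 0
    if degenerate.any():
        log.warning(
            "rank_deviation_z: %d terms with zero rank variance; z set to 0",
            int(degenerate.sum()),
        )
    nz = ~degenerate
    z[nz] = (observed_rank[nz] - mean[nz]) / sd[nz]
    return z


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    fdr_cut: float = 0.01,
    top: int = 10,
    n_resamples: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full over-representation analysis of a query list.

    Per term: overlap k, term size K (within the universe), hypergeometric
    p, BH q across the collection, rank-deviation z and combined score.
    The output keeps terms with q <= ``fdr_cut``, restricted to the
    ``top`` smallest-p terms, sorted by combined score descending.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    universe_norm = sorted({_norm(g) for g in universe})
    if not universe_norm:
        raise ValueError("empty universe")
    uni_set = set(universe_norm)
    q_norm = {_norm(g) for g in query}
    unmatched = sorted(q_norm - uni_set)
    if unmatched:
        log.warning(
            "enrich: %d query ids not in the universe were excluded: %s%s",
            len(unmatched), unmatched[:5], "..." if len(unmatched) > 5 else "",
        )
    q_in = q_norm & uni_set
    if not q_in:
        raise ValueError("no query id matched the universe")

    m = _membership_matrix(collection, universe_norm)
    big_k = m.sum(axis=1)
    q_idx = np.array([g in q_in for g in universe_norm])
    k = (m & q_idx[None, :]).sum(axis=1)
    p = _pvalues_for_counts(k, len(universe_norm), big_k, len(q_in))
    qvals = bh_adjust(p)
    z = rank_deviation_z(
        collection, len(q_in), universe_norm, p,
        n_resamples=n_resamples, seed=seed,
    )
    combined = np.log(p) * z
    table = pd.DataFrame(
        {
            "term_id": [t.term_id for t in collection],
            "term_name": [t.name for t in collection],
            "k": k,
            "K": big_k,
            "n": len(q_in),
            "N": len(universe_norm),
            "p_hyper": p,
            "q_bh": qvals,
            "z_rank": z,
            "combined_score": combined,
        }
    ).set_index("term_id")
    kept = table[table["q_bh"] <= fdr_cut]
    kept = kept.nsmallest(max(int(top), 0), "p_hyper")
    return kept.sort_values("combined_score", ascending=False)
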