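"""Hypergeometric gene-set overlap with Benjamini–Hochberg FDR control.

For a query list of n candidate genes and a phenotype gene set of K members
drawn from a universe of N genes, the overlap p-value is the hypergeometric
upper tail P(X >= k) — the chance of sharing at least the observed k genes
by random draw. Tail probabilities reach magnitudes around 1e-20 for strong
overlaps, so all arithmetic runs in log space.

BH adjustment is applied across the *declared family* of m tested gene sets
(typically far larger than the number of sets reported with k >= 1):
q_i = min_{j >= i} (p_(j) * m / j), capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

#: Universe size (genes eligible for overlap). Calibration constant: chosen
#: as the single N in [30000, 50000] whose upper-tail probability for a
#: 253-gene set sharing 12 of 25 query genes is 1.49e-20, and verified to
#: reproduce nine further published overlap p-values at 3 significant
#: digits. Not an externally documented collection size.
DEFAULT_UNIVERSE = 40075

#: Family size of the tested gene-set collection for FDR adjustment.
DEFAULT_FAMILY_SIZE = 4494


@dataclass(frozen=True)
class EnrichmentConfig:
    universe_size: int = DEFAULT_UNIVERSE
    family_size: int = DEFAULT_FAMILY_SIZE
    q_threshold: float = 0.05
    sig_digits: int = 3

    def __post_init__(self) -> None:
        if self.universe_size < 1 or self.family_size < 1:
            raise ValueError("universe_size and family_size must be positive")


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    description: str
    K: int            # genes in the set
    k: int            # genes in the overlap
    ratio: float      # k / K
    p: float          # hypergeometric upper tail
    q: float          # BH-adjusted over the family
    significant: bool  # q < q_threshold
    overlap_genes: tuple[str, ...]


def hypergeom_overlap(n: int, K: int, N: int, k: int) -> float:
    """Upper-tail overlap probability P(X >= k), X ~ Hypergeometric(N, K, n).

    Computed in log space; exact 1.0 at k = 0.
    """
    if k < 0 or n < 0 or K < 0:
        raise ValueError("n, K, k must be nonnegative")
    if N < max(n, K):
        raise ValueError(f"universe N={N} smaller than max(n={n}, K={K})")
    if k > min(n, K):
        raise ValueError(f"k={k} exceeds min(n={n}, K={K})")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); logsf keeps precision at ~1e-20 magnitudes
    return float(np.exp(hypergeom.logsf(k - 1, N, K, n)))


def bh_adjust(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Benjamini–Hochberg step-up q-values over a family of ``m`` tests.

    ``m`` may exceed ``len(p_values)`` when only the smallest p-values of a
    larger tested family are being adjusted (the untested remainder can only
    occupy higher ranks). Returned in input order.
    """
    p = list(p_values)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError(f"family size m={m} smaller than number of p-values {len(p)}")
    for x in p:
        if not (0.0 < x <= 1.0):
            raise ValueError(f"p-value out of (0,1]: {x}")
    order = sorted(range(len(p)), key=lambda i: p[i])
    q = [0.0] * len(p)
    running_min = 1.0
    for rank_from_top in range(len(p), 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        q[i] = min(running_min, 1.0)
    return q


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (report formatting)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{digits - 1}e}")


def compute_overlaps(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, tuple[str, frozenset[str]]],
    cfg: EnrichmentConfig = EnrichmentConfig(),
) -> list[EnrichmentRow]:
    """Test every gene set against the query list; report sets with k >= 1.

    Gene symbols are uppercased and deduplicated. Rows are sorted by p
    ascending; q-values are BH-adjusted across the configured family size,
    and ``significant`` flags q < q_threshold. The overlap ratio k/K is
    reported to 4 decimals.
    """
    query = frozenset(g.strip().upper() for g in query_genes if g.strip())
    if not query:
        raise ValueError("empty query gene list")
    if not gene_sets:
        raise ValueError("empty gene-set collection")
    n = len(query)
    hits: list[tuple[str, str, int, int, tuple[str, ...], float]] = []
    for name, (desc, members) in gene_sets.items():
        overlap = tuple(sorted(query & members))
        k = len(overlap)
        if k == 0:
            continue
        K = len(members)
        p = hypergeom_overlap(n, K, cfg.universe_size, k)
        hits.append((name, desc, K, k, overlap, p))
    if not hits:
        return []
    qs = bh_adjust([h[5] for h in hits], m=cfg.family_size)
    rows = [
        EnrichmentRow(
            set_name=name,
            description=desc,
            K=K,
            k=k,
            ratio=round(k / K, 4),
            p=p,
            q=q,
            significant=q < cfg.q_threshold,
            overlap_genes=overlap,
        )
        for (name, desc, K, k, overlap, p), q in zip(hits, qs)
    ]
    rows.sort(key=lambda r: (r.p, r.set_name))
    return rows
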