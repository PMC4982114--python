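"""Gene-set over-representation analysis against GMT pathway collections.

Per gene set, an upper-tail hypergeometric p-value on the 2x2 overlap
between the input gene list and the set, both restricted to a stated
background universe (by default the contrast's measured genes).  An optional
EASE variant reproduces DAVID's conservative modified Fisher test, which
subtracts one from the observed overlap before taking the tail.  No
multiple-testing correction is applied; significance is a raw p < 0.05 by
default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import hypergeom

from .data_model import GeneSet

__all__ = ["EnrichmentResult", "enrich", "significant_pathways"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    name: str
    count: int            # input genes in the set
    percent: float        # count / input size * 100
    p_value: float
    input_size: int
    set_size: int         # set members in the universe
    universe_size: int


def enrich(genes: set[str], sets: list[GeneSet], universe: set[str],
           ease: bool = False) -> list[EnrichmentResult]:
    """Over-representation p per gene set, sorted by ascending p.

    ``genes`` must be contained in ``universe``; sets are intersected with
    the universe first, and sets disjoint from it are skipped (logged).
    With ``ease=True`` the tail is taken at overlap-1 (DAVID's EASE score).
    """
    if not universe:
        raise ValueError("empty universe")
    if not genes <= universe:
        raise ValueError("input genes must be contained in the universe")
    n = len(genes)
    N = len(universe)
    results = []
    for s in sets:
        members = s.members & universe
        if not members:
            log.info("gene set %s disjoint from universe; skipped", s.set_id)
            continue
        if n == 0:
            continue
        k = len(genes & members)
        k_eff = max(k - 1, 0) if ease else k
        p = 1.0 if k_eff == 0 else float(hypergeom.sf(k_eff - 1, N, len(members), n))
        results.append(EnrichmentResult(
            set_id=s.set_id, name=s.name, count=k, percent=100.0 * k / n,
            p_value=p, input_size=n, set_size=len(members), universe_size=N,
        ))
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results


def significant_pathways(results: list[EnrichmentResult],
                         p_max: float = 0.05) -> list[EnrichmentResult]:
    """Strict p < p_max filter, input order preserved."""
    return [r for r in results if r.p_value < p_max]
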