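"""Cross-model response-gene set algebra.

Model-specific response genes, schedule/host comparisons, basal-expression
differentials, responsiveness-enrichment folds, and gene-panel
cross-tabulations.  Basal (untreated A vs untreated B) comparisons reuse the
ordinary DE-table representation, so one significance filter serves both
treated and basal contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from scipy.stats import hypergeom

from .data_model import DETable, GenePanel, filter_significant

__all__ = [
    "SpecificGeneRule",
    "SpecificGenes",
    "specific_response_genes",
    "common_response_genes",
    "basal_differential",
    "EnrichmentFold",
    "response_enrichment_fold",
    "CrossTab",
    "panel_crosstab",
    "response_similarity",
]


@dataclass(frozen=True)
class SpecificGeneRule:
    """Thresholds for calling a response gene specific to one model.

    ``fc_min``/``p_max`` gate significance (strict, default |FC| > 2 and
    p < 0.001; a relaxed |FC| > 1.5 variant is used for close schedule
    comparisons).  ``ratio_min`` is the between-model expression-ratio
    threshold: genes whose ratio falls inside [1/ratio_min, ratio_min]
    (inclusive) are removed as not model-specific.  Default 2; relaxed 1.33.
    """

    fc_min: float = 2.0
    p_max: float = 0.001
    ratio_min: float = 2.0

    def __post_init__(self):
        if self.fc_min < 1:
            raise ValueError(f"fc_min must be >= 1, got {self.fc_min}")
        if not (0 < self.p_max <= 1):
            raise ValueError(f"p_max must be in (0, 1], got {self.p_max}")
        if self.ratio_min <= 1:
            raise ValueError(f"ratio_min must be > 1, got {self.ratio_min}")


@dataclass
class SpecificGenes:
    """Model-A-specific response genes with the rule that admitted each."""

    genes: set[str] = field(default_factory=set)
    opposite_direction: set[str] = field(default_factory=set)  # rule 1: also specific to B
    ratio_retained: set[str] = field(default_factory=set)      # rule 2: ratio outside band
    ratio_removed: set[str] = field(default_factory=set)       # inside [1/r, r], dropped
    absent_in_b: set[str] = field(default_factory=set)         # not measured in B, retained


def specific_response_genes(a: DETable, b: DETable,
                            rule: SpecificGeneRule = SpecificGeneRule(),
                            direction: str = "up") -> SpecificGenes:
    """Response genes specific to model A in the given direction.

    Rule 1: genes significant in A in ``direction`` and significant in B in
    the opposite direction are specific to *both* models (each in its own
    direction); they are included here and reported in
    ``opposite_direction``.

    Rule 2: genes significant in A but not significant in B (either
    direction) are kept only when the between-model signed-FC ratio lies
    strictly outside the inclusive band [1/ratio_min, ratio_min]; opposite
    signs or absence from B count as maximal divergence and are kept.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    opposite = "down" if direction == "up" else "up"

    sig_a = filter_significant(a, rule.fc_min, rule.p_max, direction)
    sig_b_any = filter_significant(b, rule.fc_min, rule.p_max, "any")
    sig_b_opp = filter_significant(b, rule.fc_min, rule.p_max, opposite)

    out = SpecificGenes()
    out.opposite_direction = sig_a & sig_b_opp
    for gene in sig_a - sig_b_any:
        rec_b = b.get(gene)
        if rec_b is None:
            out.absent_in_b.add(gene)
            continue
        fc_a, fc_b = a[gene].signed_fc, rec_b.signed_fc
        if fc_a * fc_b < 0:
            out.ratio_retained.add(gene)
            continue
        ratio = fc_a / fc_b
        if 1.0 / rule.ratio_min <= ratio <= rule.ratio_min:
            out.ratio_removed.add(gene)
        else:
            out.ratio_retained.add(gene)
    out.genes = out.opposite_direction | out.ratio_retained | out.absent_in_b
    return out


def common_response_genes(a: DETable, b: DETable,
                          rule: SpecificGeneRule = SpecificGeneRule()) -> set[str]:
    """Genes significant in both tables in the same direction."""
    common = set()
    for d in ("up", "down"):
        common |= (filter_significant(a, rule.fc_min, rule.p_max, d)
                   & filter_significant(b, rule.fc_min, rule.p_max, d))
    return common


def basal_differential(comparisons: list[DETable],
                       rule: SpecificGeneRule = SpecificGeneRule()) -> tuple[set[str], set[str]]:
    """Genes with consistently higher / lower basal expression.

    Each table compares the responsive model's untreated expression against
    one unresponsive model; "higher" ("lower") is the intersection of the
    significant-up (-down) sets across all comparators.
    """
    if not comparisons:
        raise ValueError("basal_differential requires at least one comparison table")
    higher = lower = None
    for t in comparisons:
        up = filter_significant(t, rule.fc_min, rule.p_max, "up")
        dn = filter_significant(t, rule.fc_min, rule.p_max, "down")
        higher = up if higher is None else higher & up
        lower = dn if lower is None else lower & dn
    return higher, lower


@dataclass(frozen=True)
class EnrichmentFold:
    subset_fraction: float | None
    global_fraction: float
    fold: float | None
    p_value: float | None
    n_subset: int
    n_overlap: int
    n_responsive: int
    n_universe: int


def response_enrichment_fold(subset: set[str], responsive: set[str],
                             universe: set[str]) -> EnrichmentFold:
    """How over-represented responsive genes are within a gene subset.

    fold = (|subset ∩ responsive| / |subset|) / (|responsive| / |universe|),
    with an upper-tail hypergeometric p for the overlap.  An empty subset
    yields an undefined (None) fold with a warning.
    """
    if not universe:
        raise ValueError("empty universe")
    if not subset <= universe or not responsive <= universe:
        raise ValueError("subset and responsive sets must be contained in the universe")
    global_frac = len(responsive) / len(universe)
    if not subset:
        warnings.warn("response_enrichment_fold: empty subset, fold undefined", stacklevel=2)
        return EnrichmentFold(None, global_frac, None, None, 0, 0,
                              len(responsive), len(universe))
    k = len(subset & responsive)
    subset_frac = k / len(subset)
    fold = subset_frac / global_frac if global_frac > 0 else None
    p = (float(hypergeom.sf(k - 1, len(universe), len(responsive), len(subset)))
         if k > 0 else 1.0)
    return EnrichmentFold(subset_frac, global_frac, fold, p, len(subset), k,
                          len(responsive), len(universe))


@dataclass
class CrossTab:
    """Panel-gene counts per contrast and basal comparison.

    ``per_contrast``: contrast id -> {"up": set, "down": set, "not_measured": set};
    ``per_basal``: comparison id -> {"higher": set, "lower": set, "not_measured": set}.
    """

    panel: str
    per_contrast: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    per_basal: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def counts(self) -> dict[str, dict[str, int]]:
        out = {}
        for cid, d in self.per_contrast.items():
            out[cid] = {k: len(v) for k, v in d.items()}
        for cid, d in self.per_basal.items():
            out[cid] = {k: len(v) for k, v in d.items()}
        return out


def panel_crosstab(panel: GenePanel,
                   contrasts: list[DETable],
                   basal_comparisons: list[DETable] | None = None,
                   rule: SpecificGeneRule = SpecificGeneRule()) -> CrossTab:
    """Cross-tabulate a gene panel against treated and basal contrasts.

    Per treated contrast: panel genes significantly up / down regulated.
    Per basal comparison: panel genes with higher / lower basal expression.
    Panel genes outside a table's universe land in "not_measured".
    """
    ct = CrossTab(panel=panel.name)
    members = set(panel.members)
    any_measured = False
    for t in contrasts:
        up = filter_significant(t, rule.fc_min, rule.p_max, "up") & members
        dn = filter_significant(t, rule.fc_min, rule.p_max, "down") & members
        measured = members & t.universe
        any_measured = any_measured or bool(measured)
        ct.per_contrast[t.contrast_id] = {
            "up": up, "down": dn, "not_measured": members - t.universe,
        }
    for t in basal_comparisons or []:
        hi = filter_significant(t, rule.fc_min, rule.p_max, "up") & members
        lo = filter_significant(t, rule.fc_min, rule.p_max, "down") & members
        measured = members & t.universe
        any_measured = any_measured or bool(measured)
        ct.per_basal[t.contrast_id] = {
            "higher": hi, "lower": lo, "not_measured": members - t.universe,
        }
    if (contrasts or basal_comparisons) and not any_measured:
        warnings.warn(f"panel {panel.name!r} shares no genes with any table universe",
                      stacklevel=2)
    return ct


def response_similarity(a: DETable, b: DETable,
                        rule: SpecificGeneRule = SpecificGeneRule()) -> dict[str, float]:
    """Similarity of two contrasts' significant responses, two conventions.

    Returns the Jaccard index |A∩B|/|A∪B| and the overlap coefficient
    |A∩B|/min(|A|,|B|) over same-direction significant genes; which (if
    either) matches any particular published "percent similarity" figure is
    deliberately left open.
    """
    common = common_response_genes(a, b, rule)
    sig_a = filter_significant(a, rule.fc_min, rule.p_max, "any")
    sig_b = filter_significant(b, rule.fc_min, rule.p_max, "any")
    union = len(sig_a | sig_b)
    mn = min(len(sig_a), len(sig_b))
    return {
        "jaccard": len(common) / union if union else 0.0,
        "overlap_coefficient": len(common) / mn if mn else 0.0,
        "n_common": float(len(common)),
    }
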