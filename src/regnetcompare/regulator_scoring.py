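"""Upstream-regulator activation scoring.

For every regulator in a signed regulator->target network, score its evidence
of activity in one contrast's significant differential-expression response:

* ``p_overlap`` — upper-tail hypergeometric p for the overlap between the
  regulator's targets and the significant gene set, with the universe taken
  as all genes measured in the DE table;
* ``z`` — the activation Z-score, a weighted agreement statistic between
  observed target directions and the regulator's expected edge signs,

      z = sum(w * s_obs * s_exp) / sqrt(sum(w**2))

  over informative matched targets (expected sign != 0, weight > 0);
* ``z_bc`` — the bias-corrected Z-score.  With the dataset's direction bias
  d (mean observed direction over all significant genes) and the regulator's
  target-sign bias, b = d * sum(w*s_exp)/sum(w), the agreement sum x is
  recentred and rescaled to its null moments under biased coin flips:

      z_bc = (x - b*sum(w)) / sqrt(sum(w**2) * (1 - b**2))

  When |b| = 1 the observed signal is fully attributable to bias and z_bc
  is 0 by convention; when b = 0 it reduces to z exactly.

A positive Z calls the regulator "Activated", negative "Inhibited"; the
magnitude threshold is enforced separately by the stringent filter.  These
are documented stand-in definitions for the three statistics that commercial
causal-analytics software reports without formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from scipy.stats import hypergeom

from .data_model import DETable, RegulatorNetwork, filter_significant

__all__ = [
    "ActivationState",
    "MatchedTarget",
    "UPRResult",
    "overlap_pvalue",
    "activation_zscore",
    "bias_corrected_zscore",
    "dataset_bias",
    "call_state",
    "score_all",
]


class ActivationState(str, Enum):
    ACTIVATED = "Activated"
    INHIBITED = "Inhibited"
    UNDETERMINED = "Undetermined"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def sign(self) -> int:
        if self is ActivationState.ACTIVATED:
            return 1
        if self is ActivationState.INHIBITED:
            return -1
        return 0


@dataclass(frozen=True)
class MatchedTarget:
    """A network target found in the significant gene set."""

    gene: str
    observed: int          # +1 up-regulated, -1 down-regulated
    expected: int          # edge sign: +1 activation, -1 repression, 0 unknown
    weight: float = 1.0

    def __post_init__(self):
        if self.observed not in (-1, 1):
            raise ValueError(f"observed direction must be +/-1, got {self.observed}")
        if self.expected not in (-1, 0, 1):
            raise ValueError(f"expected sign must be -1, 0 or +1, got {self.expected}")
        if not (math.isfinite(self.weight) and self.weight >= 0):
            raise ValueError(f"weight must be nonnegative, got {self.weight}")


@dataclass
class UPRResult:
    """One regulator's scores against one contrast."""

    regulator: str
    n_targets: int
    p_overlap: float
    z: float | None
    z_bc: float | None
    state: ActivationState
    matched_targets: tuple[MatchedTarget, ...] = field(default_factory=tuple)
    molecule_type: str | None = None
    contrast_id: str | None = None


def overlap_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric P(X >= k), X ~ Hypergeom(N, K, n).

    N = universe size (measured genes), K = regulator targets in the universe,
    n = significant genes, k = targets among the significant genes.
    """
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}")
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts: n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def _informative(matched) -> list[MatchedTarget]:
    return [m for m in matched if m.expected != 0 and m.weight > 0]


def activation_zscore(matched) -> float | None:
    """Weighted direction-agreement Z; None when no informative target pairs."""
    inf = _informative(matched)
    if not inf:
        return None
    x = sum(m.weight * m.observed * m.expected for m in inf)
    denom = math.sqrt(sum(m.weight ** 2 for m in inf))
    return x / denom


def bias_corrected_zscore(matched, dataset_bias: float) -> float | None:
    """Z-score corrected for dataset direction bias; None when undefined.

    See the module docstring for the recentring.  Returns 0 in the fully
    bias-explained limit |b| = 1.
    """
    if not (-1.0 <= dataset_bias <= 1.0):
        raise ValueError(f"dataset_bias must lie in [-1, 1], got {dataset_bias}")
    inf = _informative(matched)
    if not inf:
        return None
    w_sum = sum(m.weight for m in inf)
    w2_sum = sum(m.weight ** 2 for m in inf)
    sign_bias = sum(m.weight * m.expected for m in inf) / w_sum
    b = dataset_bias * sign_bias
    if abs(b) >= 1.0:
        return 0.0
    x = sum(m.weight * m.observed * m.expected for m in inf)
    return (x - b * w_sum) / math.sqrt(w2_sum * (1.0 - b * b))


def dataset_bias(table: DETable, fc_min: float = 2.0, p_max: float = 0.001) -> float:
    """Mean observed direction (+/-1) over all significant genes; 0 if none."""
    sig = filter_significant(table, fc_min, p_max, "any")
    if not sig:
        return 0.0
    return sum(table[g].direction for g in sig) / len(sig)


def call_state(z: float | None) -> ActivationState:
    """Activated for z > 0, Inhibited for z < 0, Undetermined otherwise."""
    if z is None or z == 0:
        return ActivationState.UNDETERMINED
    return ActivationState.ACTIVATED if z > 0 else ActivationState.INHIBITED


def score_all(table: DETable, network: RegulatorNetwork,
              fc_min: float = 2.0, p_max: float = 0.001) -> list[UPRResult]:
    """Score every regulator with >= 1 target in the table's universe.

    Observed directions are the signs of the significant genes' fold changes;
    regulators whose targets miss the significant set entirely get
    p_overlap = 1 and undefined Z-scores (state Undetermined).
    """
    if len(network) == 0:
        raise ValueError("empty regulator network")
    universe = table.universe
    N = len(universe)
    sig = filter_significant(table, fc_min, p_max, "any")
    n = len(sig)
    bias = dataset_bias(table, fc_min, p_max)
    results: list[UPRResult] = []
    for reg in network.regulators:
        edges = network.targets_of(reg)
        in_universe = [e for t, e in edges.items() if t in universe]
        K = len(in_universe)
        if K == 0:
            continue  # regulator not represented on the platform
        matched = []
        for e in in_universe:
            if e.target in sig:
                rec = table[e.target]
                if rec.signed_fc == 0:  # unreachable given |FC| > fc_min >= 1
                    raise AssertionError("significant gene with zero fold change")
                matched.append(MatchedTarget(e.target, rec.direction,
                                             e.expected_sign, e.weight))
        matched = tuple(sorted(matched, key=lambda m: m.gene))
        k = len(matched)
        p = overlap_pvalue(k, n, K, N)
        z = activation_zscore(matched)
        z_bc = bias_corrected_zscore(matched, bias)
        ann = network.annotations.get(reg)
        results.append(UPRResult(
            regulator=reg, n_targets=k, p_overlap=p, z=z, z_bc=z_bc,
            state=call_state(z), matched_targets=matched,
            molecule_type=ann.molecule_type if ann else None,
            contrast_id=table.contrast_id,
        ))
    return results
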