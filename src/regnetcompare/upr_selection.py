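"""Exclusion/dedup rules, the stringent filter, and the cross-model
uniqueness decision tree for scored upstream regulators (UPRs).

The procedure mirrors a published tumor-model comparison workflow:

1. Drop regulators annotated as exogenous chemicals (endogenous mammalian
   chemicals are kept), drop group regulators whose constituents all appear
   individually, and among same-name duplicates (e.g. mouse vs human entries)
   keep the one with the higher activation score (|z|).
2. Keep only "stringent" UPRs: overlap p < 1e-4, more than 10 matched
   targets, and |z| and |z_bc| both > 2 (all strict).
3. Call each stringent UPR of model A unique / not-unique relative to
   model B by a fixed decision tree over B's full (post-exclusion) UPR
   table; uniqueness against several comparators is the conjunction of the
   pairwise calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

from .data_model import (
    MOLTYPE_CHEMICAL_OTHER,
    MOLTYPE_GROUP,
    RegulatorAnnotation,
)
from .regulator_scoring import ActivationState, UPRResult

__all__ = [
    "StringentCriteria",
    "Verdict",
    "Branch",
    "UniquenessVerdict",
    "MissingAnnotationError",
    "exclude_and_dedup",
    "stringent_filter",
    "classify_uniqueness",
    "unique_vs_many",
    "common_stringent",
    "CommonStringentResult",
]


class MissingAnnotationError(KeyError):
    def __init__(self, regulators):
        self.regulators = sorted(regulators)
        super().__init__(f"missing annotations for regulators: {', '.join(self.regulators)}")


@dataclass(frozen=True)
class StringentCriteria:
    """Joint thresholds defining a stringent UPR (all comparisons strict)."""

    p_overlap_max: float = 1e-4
    n_targets_min: int = 10
    z_abs_min: float = 2.0

    def __post_init__(self):
        if self.p_overlap_max <= 0 or self.n_targets_min <= 0 or self.z_abs_min <= 0:
            raise ValueError("stringent thresholds must all be positive")


class Verdict(str, Enum):
    UNIQUE_TO_A = "unique_to_A"
    NOT_UNIQUE = "not_unique"
    COMMON = "common"


class Branch(str, Enum):
    """Decision-tree branches, in evaluation order."""

    ABSENT = "absent_from_B"
    BOTH_EXCEED_OPPOSITE = "both_exceed_opposite_state"
    BOTH_EXCEED_SAME = "both_exceed_same_state"
    SINGLE_EXCEED_SAME = "single_exceedance_same_direction"
    CANDIDATE_P_GE_1E3 = "candidate_pB_ge_0.001"
    CANDIDATE_100FOLD = "candidate_pB_100fold_higher"
    CANDIDATE_P_LT_1E4 = "candidate_pB_lt_0.0001"
    CANDIDATE_RATIO_FAIL = "candidate_pB_ratio_le_100"


@dataclass(frozen=True)
class UniquenessVerdict:
    regulator: str
    model_a: str
    model_b: str
    verdict: Verdict
    branch: Branch
    evidence: dict


def exclude_and_dedup(uprs: list[UPRResult],
                      annotations: dict[str, RegulatorAnnotation]) -> list[UPRResult]:
    """Apply the chemical-exclusion, group-dedup and same-name-dedup rules.

    Every scored regulator must have an annotation; the input may contain the
    same regulator id more than once (e.g. species variants scored
    separately), in which case the entry with the larger |z| survives.
    """
    missing = {u.regulator for u in uprs} - set(annotations)
    if missing:
        raise MissingAnnotationError(missing)

    def score(u: UPRResult) -> float:
        return abs(u.z) if u.z is not None else -1.0

    # same-name dedup first so group-constituent presence is well defined
    by_name: dict[str, UPRResult] = {}
    for u in uprs:
        best = by_name.get(u.regulator)
        if best is None or score(u) > score(best):
            by_name[u.regulator] = u

    kept = [u for u in by_name.values()
            if annotations[u.regulator].molecule_type != MOLTYPE_CHEMICAL_OTHER]
    present = {u.regulator for u in kept}
    out = []
    for u in kept:
        ann = annotations[u.regulator]
        if (ann.molecule_type == MOLTYPE_GROUP and ann.constituents
                and ann.constituents <= present):
            continue  # group duplicates its individual constituents
        out.append(u)
    return out


def is_stringent(u: UPRResult, criteria: StringentCriteria = StringentCriteria()) -> bool:
    if u.z is None or u.z_bc is None:
        return False
    return (u.p_overlap < criteria.p_overlap_max
            and u.n_targets > criteria.n_targets_min
            and abs(u.z) > criteria.z_abs_min
            and abs(u.z_bc) > criteria.z_abs_min)


def stringent_filter(uprs: list[UPRResult],
                     criteria: StringentCriteria = StringentCriteria()) -> list[UPRResult]:
    """Keep UPRs passing all four stringent thresholds (strictly)."""
    return [u for u in uprs if is_stringent(u, criteria)]


def _exceeds(value: float | None, threshold: float) -> bool:
    return value is not None and abs(value) > threshold


def classify_uniqueness(upr_a: UPRResult,
                        full_b: dict[str, UPRResult],
                        model_b: str,
                        a_p: float | None = None,
                        z_abs_min: float = 2.0) -> UniquenessVerdict:
    """Call a stringent UPR of model A unique or not relative to model B.

    ``full_b`` is model B's full post-exclusion UPR table keyed by regulator;
    ``a_p`` is the UPR's overlap p in model A (defaults to ``upr_a.p_overlap``).

    Branches, in order: absent from B; both B Z-scores exceed the threshold
    (opposite activation state -> unique, same -> shared); exactly one
    exceeds in A's direction -> not unique; otherwise the p-value ladder on
    B's overlap p (>= 1e-3 unique; in [1e-4, 1e-3) unique only when more
    than 100-fold above A's p; < 1e-4 never unique).
    """
    if a_p is None:
        a_p = upr_a.p_overlap
    reg = upr_a.regulator
    model_a = upr_a.contrast_id or "A"

    def verdict(v: Verdict, branch: Branch, b: UPRResult | None) -> UniquenessVerdict:
        ev = {"a": {"z": upr_a.z, "z_bc": upr_a.z_bc, "p_overlap": a_p,
                    "state": upr_a.state.value}}
        if b is not None:
            ev["b"] = {"z": b.z, "z_bc": b.z_bc, "p_overlap": b.p_overlap,
                       "state": b.state.value}
        return UniquenessVerdict(reg, model_a, model_b, v, branch, ev)

    b = full_b.get(reg)
    if b is None or b.n_targets == 0:
        # operationalizes "absent from B's default UPR listing"
        return verdict(Verdict.UNIQUE_TO_A, Branch.ABSENT, b)

    a_sign = upr_a.state.sign
    z_ex = _exceeds(b.z, z_abs_min)
    zbc_ex = _exceeds(b.z_bc, z_abs_min)
    if z_ex and zbc_ex:
        if b.state.sign == a_sign:
            return verdict(Verdict.NOT_UNIQUE, Branch.BOTH_EXCEED_SAME, b)
        return verdict(Verdict.UNIQUE_TO_A, Branch.BOTH_EXCEED_OPPOSITE, b)
    if z_ex or zbc_ex:
        exceeding = b.z if z_ex else b.z_bc
        if exceeding is not None and a_sign != 0 and exceeding * a_sign > 0:
            return verdict(Verdict.NOT_UNIQUE, Branch.SINGLE_EXCEED_SAME, b)
        # single exceedance opposite to A: candidate, fall through to p ladder

    p_b = b.p_overlap
    if p_b >= 1e-3:
        return verdict(Verdict.UNIQUE_TO_A, Branch.CANDIDATE_P_GE_1E3, b)
    if p_b >= 1e-4:
        if p_b > 100.0 * a_p:
            return verdict(Verdict.UNIQUE_TO_A, Branch.CANDIDATE_100FOLD, b)
        return verdict(Verdict.NOT_UNIQUE, Branch.CANDIDATE_RATIO_FAIL, b)
    return verdict(Verdict.NOT_UNIQUE, Branch.CANDIDATE_P_LT_1E4, b)


def unique_vs_many(upr_a: UPRResult,
                   comparators: dict[str, dict[str, UPRResult]],
                   a_p: float | None = None,
                   z_abs_min: float = 2.0) -> tuple[bool, list[UniquenessVerdict]]:
    """Unique overall only if unique against every comparator model.

    ``comparators`` maps model label -> full post-exclusion UPR table.
    """
    if not comparators:
        warnings.warn("unique_vs_many called with zero comparator models; "
                      "verdict is vacuously unique", stacklevel=2)
        return True, []
    verdicts = [classify_uniqueness(upr_a, tbl, label, a_p, z_abs_min)
                for label, tbl in comparators.items()]
    return all(v.verdict is Verdict.UNIQUE_TO_A for v in verdicts), verdicts


@dataclass(frozen=True)
class CommonStringentResult:
    common: tuple[str, ...]          # stringent in both, same activation sign
    opposite_state: tuple[str, ...]  # stringent in both but oppositely called


def common_stringent(uprs_a: list[UPRResult], uprs_b: list[UPRResult],
                     require_same_direction: bool = True) -> CommonStringentResult:
    """Regulators stringent in both models.

    Same-direction pairs form the common set; opposite-direction pairs are
    reported separately (and folded into ``common`` when
    ``require_same_direction`` is False).
    """
    a = {u.regulator: u for u in uprs_a}
    b = {u.regulator: u for u in uprs_b}
    shared = sorted(set(a) & set(b))
    same = tuple(r for r in shared if a[r].state.sign == b[r].state.sign != 0)
    opposite = tuple(r for r in shared if a[r].state.sign * b[r].state.sign < 0)
    if not require_same_direction:
        same = tuple(sorted(same + opposite))
    return CommonStringentResult(common=same, opposite_state=opposite)
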