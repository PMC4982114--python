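"""Synthetic multi-contrast DE data with planted regulator activities.

The generator emulates the table-level structure of a five-contrast tumor
RNA-seq comparison study (three tumor models in an immunocompetent host, one
model in an immunodeficient host under two drug schedules, plus two basal
responsive-vs-unresponsive comparisons): a shared gene universe, a signed
regulator->target network, and per-contrast log2 fold changes in which a
small set of *planted* regulators shifts its targets' means while everything
else is noise.

Per contrast each gene's log2FC is Normal(mu_g, noise_sd) where mu_g sums
activity x edge-sign x effect-size over the planted regulators targeting the
gene, and equals a small ``baseline_bias`` for untargeted genes; p-values
are the two-sided normal tail of log2FC against noise_sd.  Defaults are
calibrated so roughly 12.6 % of genes respond significantly per contrast
(|FC| > 2, p < 0.001), matching the global response rate the pipeline's
thresholds were designed around.  Intensities are log-normal and independent
of fold change.  Everything is generated at 1/5 study scale: 4,000 genes,
200 regulators, 20 planted regulators per contrast.

The ground truth (who was planted where, which genes were shifted) is
returned alongside, so pipeline recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .data_model import (
    DERecord,
    DETable,
    GenePanel,
    GeneSet,
    RegulatorAnnotation,
    RegulatorEdge,
    RegulatorNetwork,
)

__all__ = [
    "ContrastSpec",
    "ScenarioConfig",
    "SyntheticTruth",
    "SyntheticScenario",
    "RecoveryReport",
    "default_scenario",
    "generate",
    "truth_eval",
]


@dataclass(frozen=True)
class ContrastSpec:
    """One contrast to simulate: planted regulator activities and effect size."""

    contrast_id: str
    planted: dict[str, int]          # regulator id -> activity sign (+1/-1)
    effect_size: float = 2.0         # mean |log2FC| shift of informative targets
    basal: bool = False              # basal (untreated A vs untreated B) comparison

    def __post_init__(self):
        for reg, sign in self.planted.items():
            if sign not in (-1, 1):
                raise ValueError(f"{self.contrast_id}: activity sign for {reg} must be +/-1")
        if self.effect_size < 0:
            raise ValueError(f"{self.contrast_id}: effect_size must be nonnegative "
                             "(0 simulates an explicit null)")


@dataclass
class ScenarioConfig:
    n_genes: int = 4000
    n_regulators: int = 200
    targets_per_regulator: tuple[int, int] = (15, 40)
    activation_sign_fraction: float = 0.75   # fraction of edges with expected_sign = +1
    zero_sign_fraction: float = 0.05         # fraction with unknown direction (sign 0)
    noise_sd: float = 0.25                   # per-gene log2FC noise
    baseline_bias: float = 0.05              # mean log2FC of untargeted genes
    contrasts: list[ContrastSpec] = field(default_factory=list)
    n_coregulated_sets: int = 10             # pathway sets built from regulator targets
    n_decoy_sets: int = 10                   # random pathway sets
    decoy_set_size: tuple[int, int] = (30, 80)
    panel_size: int = 124
    panel_responsive_overlap: float = 0.3    # fraction of panel drawn from responsive genes
    intensity_log_mean: float = 4.0          # lognormal parameters for read intensities
    intensity_log_sd: float = 1.2
    seed: int = 0


@dataclass
class SyntheticTruth:
    """Planted regulator activities and shifted-gene labels per contrast."""

    planted: dict[str, dict[str, int]]       # contrast -> regulator -> activity sign
    shifts: dict[str, dict[str, int]]        # contrast -> gene -> net shift sign

    @property
    def responsive_genes(self) -> dict[str, set[str]]:
        return {c: set(d) for c, d in self.shifts.items()}


@dataclass
class SyntheticScenario:
    config: ScenarioConfig
    network: RegulatorNetwork
    tables: dict[str, DETable]
    gene_sets: list[GeneSet]
    panel: GenePanel
    truth: SyntheticTruth

    @property
    def treated_tables(self) -> dict[str, DETable]:
        basal = {c.contrast_id for c in self.config.contrasts if c.basal}
        return {cid: t for cid, t in self.tables.items() if cid not in basal}

    @property
    def basal_tables(self) -> dict[str, DETable]:
        basal = {c.contrast_id for c in self.config.contrasts if c.basal}
        return {cid: t for cid, t in self.tables.items() if cid in basal}


def _regulator_ids(n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"R{i:0{width}d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _default_sign(i: int) -> int:
    # three activated for every inhibited, echoing the up-dominated responses
    return 1 if i % 4 != 3 else -1


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """The default study-shaped scenario.

    Five treated contrasts (three disjointly planted single-host models and
    two immunodeficient-host schedules sharing 12 of 20 planted regulators
    with identical activity signs) plus two basal comparisons of the
    responsive model against each unresponsive model.  The basal programs
    reuse half of the responsive model's planted regulators, so basally
    differential genes are enriched for treatment-responsive genes.
    """
    regs = _regulator_ids(200)

    def plant(ids):
        return {regs[i]: _default_sign(i) for i in ids}

    shared_scid = plant(range(80, 92))
    contrasts = [
        ContrastSpec("GL261B6_CPA6d", plant(range(0, 20))),
        ContrastSpec("LLC_CPA6d", plant(range(20, 40))),
        ContrastSpec("B16F10_CPA6d", plant(range(40, 60))),
        ContrastSpec("GL261scid_CPA6d", {**plant(range(60, 68)), **shared_scid}),
        ContrastSpec("GL261scid_CPA9d", {**plant(range(68, 76)), **shared_scid}),
        ContrastSpec("GL261_vs_LLC_basal",
                     {**plant(range(0, 10)), **plant(range(96, 100))}, basal=True),
        ContrastSpec("GL261_vs_B16F10_basal",
                     {**plant(range(0, 10)), **plant(range(96, 100))}, basal=True),
    ]
    return ScenarioConfig(contrasts=contrasts, seed=seed)


def _validate(config: ScenarioConfig, regulators: list[str]) -> None:
    lo, hi = config.targets_per_regulator
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid targets_per_regulator range {config.targets_per_regulator}")
    if hi > config.n_genes:
        raise ValueError(
            f"targets_per_regulator upper bound {hi} exceeds n_genes={config.n_genes}")
    for frac, name in ((config.activation_sign_fraction, "activation_sign_fraction"),
                       (config.zero_sign_fraction, "zero_sign_fraction"),
                       (config.panel_responsive_overlap, "panel_responsive_overlap")):
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {frac}")
    if config.activation_sign_fraction + config.zero_sign_fraction > 1.0:
        raise ValueError("activation_sign_fraction + zero_sign_fraction exceeds 1")
    if config.noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if config.panel_size > config.n_genes:
        raise ValueError(f"panel_size {config.panel_size} exceeds n_genes")
    if not config.contrasts:
        raise ValueError("scenario needs at least one contrast")
    ids = [c.contrast_id for c in config.contrasts]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contrast ids")
    known = set(regulators)
    for c in config.contrasts:
        unknown = set(c.planted) - known
        if unknown:
            raise ValueError(
                f"{c.contrast_id}: planted regulators not in the network: {sorted(unknown)}")
        if c.planted and 0 < c.effect_size <= config.noise_sd:
            raise ValueError(
                f"{c.contrast_id}: effect_size {c.effect_size} is below the noise floor "
                f"(noise_sd={config.noise_sd}); planted responses would be unrecoverable")


def generate(config: ScenarioConfig, seed: int | None = None) -> SyntheticScenario:
    """Generate a full scenario; identical seeds give identical output."""
    if seed is None:
        seed = config.seed
    genes = _gene_ids(config.n_genes)
    regulators = _regulator_ids(config.n_regulators)
    _validate(config, regulators)
    rng = np.random.default_rng(seed)

    # network: per-regulator target draws with signed edges
    lo, hi = config.targets_per_regulator
    p_plus = config.activation_sign_fraction
    p_zero = config.zero_sign_fraction
    p_minus = 1.0 - p_plus - p_zero
    edges: list[RegulatorEdge] = []
    annotations: dict[str, RegulatorAnnotation] = {}
    molecule_types = ["cytokine", "kinase", "transcription regulator",
                     "transmembrane receptor", "enzyme", "growth factor"]
    for i, reg in enumerate(regulators):
        n_t = int(rng.integers(lo, hi + 1))
        targets = rng.choice(config.n_genes, size=n_t, replace=False)
        signs = rng.choice([1, -1, 0], size=n_t, p=[p_plus, p_minus, p_zero])
        for t, s in zip(targets, signs):
            edges.append(RegulatorEdge(reg, genes[int(t)], int(s), 1.0))
        annotations[reg] = RegulatorAnnotation(
            reg, molecule_types[i % len(molecule_types)], "mouse")
    network = RegulatorNetwork(edges, annotations)

    # per-contrast tables
    tables: dict[str, DETable] = {}
    planted_truth: dict[str, dict[str, int]] = {}
    shift_truth: dict[str, dict[str, int]] = {}
    gene_index = {g: i for i, g in enumerate(genes)}
    for spec in config.contrasts:
        mu = np.full(config.n_genes, config.baseline_bias)
        targeted = np.zeros(config.n_genes, dtype=bool)
        shift = np.zeros(config.n_genes)
        for reg, activity in spec.planted.items():
            for tgt, edge in network.targets_of(reg).items():
                idx = gene_index[tgt]
                targeted[idx] = True
                shift[idx] += activity * edge.expected_sign * spec.effect_size
        mu[targeted] = shift[targeted]
        log2fc = rng.normal(mu, config.noise_sd)
        pvals = 2.0 * norm.sf(np.abs(log2fc) / config.noise_sd)
        intens = rng.lognormal(config.intensity_log_mean, config.intensity_log_sd,
                               size=(config.n_genes, 2))
        records = [
            DERecord(genes[i], float(log2fc[i]), float(min(pvals[i], 1.0)),
                     float(intens[i, 0]), float(intens[i, 1]))
            for i in range(config.n_genes)
        ]
        tables[spec.contrast_id] = DETable(spec.contrast_id, records)
        planted_truth[spec.contrast_id] = dict(spec.planted)
        shift_truth[spec.contrast_id] = {
            genes[i]: int(np.sign(shift[i]))
            for i in np.nonzero(targeted & (shift != 0))[0]
        }

    # pathway sets: truly co-regulated target sets plus random decoys
    gene_sets: list[GeneSet] = []
    planted_any = sorted({r for p in planted_truth.values() for r in p})
    coreg = planted_any[:config.n_coregulated_sets]
    if len(coreg) < config.n_coregulated_sets:
        coreg += [r for r in regulators if r not in coreg][
            : config.n_coregulated_sets - len(coreg)]
    for reg in coreg:
        members = frozenset(network.targets_of(reg))
        gene_sets.append(GeneSet(f"COREG_{reg}", f"targets of {reg}", members))
    dlo, dhi = config.decoy_set_size
    for j in range(config.n_decoy_sets):
        size = int(rng.integers(dlo, dhi + 1))
        members = frozenset(genes[int(i)]
                            for i in rng.choice(config.n_genes, size=size, replace=False))
        gene_sets.append(GeneSet(f"DECOY_{j:02d}", "random decoy set", members))

    # panel: labeled random subset with configurable responsive-gene overlap
    responsive_union = sorted({g for d in shift_truth.values() for g in d})
    n_resp = min(int(round(config.panel_size * config.panel_responsive_overlap)),
                 len(responsive_union))
    picked: list[str] = []
    if n_resp:
        picked += [responsive_union[int(i)] for i in
                   rng.choice(len(responsive_union), size=n_resp, replace=False)]
    rest = [g for g in genes if g not in set(picked) and g not in set(responsive_union)]
    n_rest = config.panel_size - len(picked)
    picked += [rest[int(i)] for i in rng.choice(len(rest), size=n_rest, replace=False)]
    panel = GenePanel("synthetic_negative_immune_regulators", frozenset(picked))

    truth = SyntheticTruth(planted=planted_truth, shifts=shift_truth)
    return SyntheticScenario(config, network, tables, gene_sets, panel, truth)


# ---------------------------------------------------------------------------
# Recovery scoring against the planted truth
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    stringent_sensitivity: float | None = None
    stringent_fdp: float | None = None
    per_contrast: dict[str, dict[str, float]] = field(default_factory=dict)
    uniqueness_accuracy: float | None = None
    uniqueness_evaluated: int = 0
    specific_precision: float | None = None
    specific_recall: float | None = None


def _regulator_ids_of(entries) -> set[str]:
    out = set()
    for e in entries:
        out.add(e if isinstance(e, str) else e.regulator)
    return out


def truth_eval(truth: SyntheticTruth,
               stringent: dict[str, list] | None = None,
               uniqueness: list | None = None,
               specific: dict[tuple[str, str, str], set[str]] | None = None,
               ) -> RecoveryReport:
    """Score pipeline outputs against the planted truth.

    ``stringent`` maps contrast id -> stringent UPRs (UPRResult or regulator
    ids).  ``uniqueness`` is a list of UniquenessVerdict; only verdicts for
    regulators planted in exactly one of the two models (expected unique) or
    in both (expected shared) carry a truth label and are scored.
    ``specific`` maps (model_a, model_b, direction) -> the called
    A-specific gene set, scored against the genes shifted in A in that
    direction and not identically shifted in B.
    """
    report = RecoveryReport()
    if stringent is not None:
        unknown = set(stringent) - set(truth.planted)
        if unknown:
            raise ValueError(f"stringent results for unknown contrasts: {sorted(unknown)}")
        tp = fp = fn = 0
        for cid, entries in stringent.items():
            called = _regulator_ids_of(entries)
            planted = set(truth.planted[cid])
            c_tp = len(called & planted)
            c_fp = len(called - planted)
            c_fn = len(planted - called)
            tp, fp, fn = tp + c_tp, fp + c_fp, fn + c_fn
            report.per_contrast[cid] = {
                "sensitivity": c_tp / len(planted) if planted else float("nan"),
                "fdp": c_fp / len(called) if called else 0.0,
            }
        report.stringent_sensitivity = tp / (tp + fn) if (tp + fn) else None
        report.stringent_fdp = fp / (tp + fp) if (tp + fp) else 0.0

    if uniqueness is not None:
        from .upr_selection import Verdict  # local import avoids a cycle
        correct = evaluated = 0
        for v in uniqueness:
            if v.model_a not in truth.planted or v.model_b not in truth.planted:
                raise ValueError(
                    f"uniqueness verdict references unknown contrast: {v.model_a}/{v.model_b}")
            in_a = v.regulator in truth.planted[v.model_a]
            in_b = v.regulator in truth.planted[v.model_b]
            if in_a and not in_b:
                expected = Verdict.UNIQUE_TO_A
            elif in_a and in_b:
                expected = Verdict.NOT_UNIQUE
            else:
                continue  # no truth claim for unplanted or B-only regulators
            evaluated += 1
            got_unique = v.verdict is Verdict.UNIQUE_TO_A
            if got_unique == (expected is Verdict.UNIQUE_TO_A):
                correct += 1
        report.uniqueness_evaluated = evaluated
        report.uniqueness_accuracy = correct / evaluated if evaluated else None

    if specific is not None:
        tp = fp = fn = 0
        for (a_id, b_id, direction), called in specific.items():
            if a_id not in truth.shifts or b_id not in truth.shifts:
                raise ValueError(f"specific-gene key references unknown contrast: {a_id}/{b_id}")
            want = 1 if direction == "up" else -1
            shifts_a, shifts_b = truth.shifts[a_id], truth.shifts[b_id]
            true_specific = {g for g, s in shifts_a.items()
                             if s == want and shifts_b.get(g) != want}
            tp += len(called & true_specific)
            fp += len(called - true_specific)
            fn += len(true_specific - called)
        report.specific_precision = tp / (tp + fp) if (tp + fp) else None
        report.specific_recall = tp / (tp + fn) if (tp + fn) else None
    return report
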