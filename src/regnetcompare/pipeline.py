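"""End-to-end orchestration: score -> select -> compare -> enrich -> cross-tab.

A single YAML config names the input files (contrast DE tables, network,
annotations, GMT sets, panel), the comparison plan, and the thresholds
(defaulting to the published procedure: |FC| > 2, p < 0.001, stringent
overlap p < 1e-4, > 10 targets, |Z| and |bias-corrected Z| > 2, ratio band
0.5-2, pathway p < 0.05).  The run is deterministic given its inputs and
emits per-stage TSVs, a machine-readable summary and a provenance log.
"""

from __future__ import annotations

import csv
import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import yaml

from . import __version__
from .data_model import (
    DETable,
    GenePanel,
    GeneSet,
    RegulatorNetwork,
    filter_significant,
    read_annotations,
    read_de_table,
    read_gmt,
    read_network,
    read_panel,
)
from .enrichment import EnrichmentResult, enrich, significant_pathways
from .regulator_scoring import UPRResult, score_all
from .response_sets import (
    CrossTab,
    SpecificGeneRule,
    SpecificGenes,
    common_response_genes,
    panel_crosstab,
    specific_response_genes,
)
from .upr_selection import (
    CommonStringentResult,
    StringentCriteria,
    UniquenessVerdict,
    common_stringent,
    exclude_and_dedup,
    stringent_filter,
    unique_vs_many,
)

__all__ = ["Thresholds", "RunConfig", "PipelineReport", "PipelineError",
           "run", "run_objects"]


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and the offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class Thresholds:
    fc_min: float = 2.0
    p_max: float = 0.001
    stringent_p: float = 1e-4
    stringent_n: int = 10
    stringent_z: float = 2.0
    ratio_min: float = 2.0
    enrich_p_max: float = 0.05
    ease: bool = False

    @property
    def stringent(self) -> StringentCriteria:
        return StringentCriteria(self.stringent_p, self.stringent_n, self.stringent_z)

    @property
    def specific_rule(self) -> SpecificGeneRule:
        return SpecificGeneRule(self.fc_min, self.p_max, self.ratio_min)


@dataclass
class RunConfig:
    contrasts: dict[str, str]                       # label -> DE table path
    network: str
    annotations: str
    gene_sets: str | None = None                    # GMT path
    panel: str | None = None
    basal: dict[str, str] = field(default_factory=dict)
    uniqueness: list[tuple[str, list[str]]] = field(default_factory=list)
    specific: list[tuple[str, str, str]] = field(default_factory=list)
    common: list[tuple[str, str]] = field(default_factory=list)
    thresholds: Thresholds = field(default_factory=Thresholds)
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        labels = list(self.contrasts) + list(self.basal)
        if len(set(labels)) != len(labels):
            raise PipelineError("config", "contrast/basal labels must be unique")
        for label, path in {**self.contrasts, **self.basal,
                            "network": self.network,
                            "annotations": self.annotations,
                            **({"gene_sets": self.gene_sets} if self.gene_sets else {}),
                            **({"panel": self.panel} if self.panel else {})}.items():
            if not os.path.exists(path):
                raise PipelineError("config", f"input {label!r} not found: {path}")
        known = set(labels)
        for a, bs in self.uniqueness:
            for m in [a, *bs]:
                if m not in known:
                    raise PipelineError("config", f"uniqueness plan references {m!r}")
        for a, b, direction in self.specific:
            if a not in known or b not in known:
                raise PipelineError("config", f"specific plan references {a!r}/{b!r}")
            if direction not in ("up", "down"):
                raise PipelineError("config", f"bad direction {direction!r}")
        for a, b in self.common:
            if a not in known or b not in known:
                raise PipelineError("config", f"common plan references {a!r}/{b!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise PipelineError("config", f"config {path} is not a mapping")
        base = os.path.dirname(os.path.abspath(path))

        def resolve(p):
            return p if os.path.isabs(p) else os.path.join(base, p)

        thr = Thresholds(**raw.get("thresholds", {}))
        plan = raw.get("comparisons", {})
        return cls(
            contrasts={k: resolve(v) for k, v in raw.get("contrasts", {}).items()},
            network=resolve(raw["network"]),
            annotations=resolve(raw["annotations"]),
            gene_sets=resolve(raw["gene_sets"]) if raw.get("gene_sets") else None,
            panel=resolve(raw["panel"]) if raw.get("panel") else None,
            basal={k: resolve(v) for k, v in raw.get("basal", {}).items()},
            uniqueness=[(u["model"], list(u["versus"])) for u in plan.get("uniqueness", [])],
            specific=[(s["model_a"], s["model_b"], s.get("direction", "up"))
                      for s in plan.get("specific", [])],
            common=[(c["model_a"], c["model_b"]) for c in plan.get("common", [])],
            thresholds=thr,
            out_dir=resolve(raw["out_dir"]) if raw.get("out_dir") else None,
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class PipelineReport:
    full_uprs: dict[str, list[UPRResult]] = field(default_factory=dict)
    stringent: dict[str, list[UPRResult]] = field(default_factory=dict)
    uniqueness: list[UniquenessVerdict] = field(default_factory=list)
    unique_regulators: dict[str, list[str]] = field(default_factory=dict)
    common_uprs: dict[tuple[str, str], CommonStringentResult] = field(default_factory=dict)
    specific_genes: dict[tuple[str, str, str], SpecificGenes] = field(default_factory=dict)
    common_genes: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    enrichments: dict[str, list[EnrichmentResult]] = field(default_factory=dict)
    crosstab: CrossTab | None = None
    summary: dict = field(default_factory=dict)


def run_objects(tables: dict[str, DETable],
                network: RegulatorNetwork,
                gene_sets: list[GeneSet] | None = None,
                panel: GenePanel | None = None,
                basal: dict[str, DETable] | None = None,
                uniqueness: list[tuple[str, list[str]]] | None = None,
                specific: list[tuple[str, str, str]] | None = None,
                common: list[tuple[str, str]] | None = None,
                thresholds: Thresholds = Thresholds()) -> PipelineReport:
    """Run the full analysis on in-memory objects.

    ``tables`` holds the treated contrasts; ``basal`` the basal comparison
    tables (subject to set algebra and cross-tabs but not UPR scoring).
    """
    thr = thresholds
    basal = basal or {}
    all_tables = {**tables, **basal}
    report = PipelineReport()

    def table_for(label: str) -> DETable:
        try:
            return all_tables[label]
        except KeyError:
            raise PipelineError("plan", f"unknown contrast label {label!r}") from None

    # stage 1: score + exclusions, per treated contrast
    for cid, table in tables.items():
        try:
            scored = score_all(table, network, thr.fc_min, thr.p_max)
            scored = exclude_and_dedup(scored, network.annotations)
        except Exception as exc:
            raise PipelineError("score", f"contrast {cid!r}: {exc}") from exc
        report.full_uprs[cid] = scored
        report.stringent[cid] = stringent_filter(scored, thr.stringent)

    # stage 2: uniqueness decision tree
    for model_a, versus in uniqueness or []:
        full_b = {b: {u.regulator: u for u in report.full_uprs[b]} for b in versus}
        uniques = []
        for u in report.stringent.get(model_a, []):
            is_unique, verdicts = unique_vs_many(u, full_b, z_abs_min=thr.stringent_z)
            report.uniqueness.extend(verdicts)
            if is_unique:
                uniques.append(u.regulator)
        report.unique_regulators[f"{model_a}_vs_{'+'.join(versus)}"] = uniques

    # stage 3: common stringent UPRs
    for a, b in common or []:
        report.common_uprs[(a, b)] = common_stringent(
            report.stringent.get(a, []), report.stringent.get(b, []))
        report.common_genes[(a, b)] = common_response_genes(
            table_for(a), table_for(b), thr.specific_rule)

    # stage 4: model-specific response genes + their pathway enrichment
    for a, b, direction in specific or []:
        res = specific_response_genes(table_for(a), table_for(b),
                                      thr.specific_rule, direction)
        report.specific_genes[(a, b, direction)] = res
        if gene_sets:
            universe = table_for(a).universe
            results = enrich(res.genes & universe, gene_sets, universe, thr.ease)
            report.enrichments[f"specific_{a}_vs_{b}_{direction}"] = \
                significant_pathways(results, thr.enrich_p_max)

    # stage 5: per-contrast up/down pathway enrichment
    if gene_sets:
        for cid, table in tables.items():
            for direction in ("up", "down"):
                sig = filter_significant(table, thr.fc_min, thr.p_max, direction)
                results = enrich(sig, gene_sets, table.universe, thr.ease)
                report.enrichments[f"{cid}_{direction}"] = \
                    significant_pathways(results, thr.enrich_p_max)

    # stage 6: panel cross-tabulation
    if panel is not None:
        report.crosstab = panel_crosstab(panel, list(tables.values()),
                                         list(basal.values()), thr.specific_rule)

    report.summary = _summarize(report, tables, basal, thr)
    return report


def _summarize(report: PipelineReport, tables, basal, thr: Thresholds) -> dict:
    summary: dict = {"thresholds": asdict(thr), "contrasts": {}, "comparisons": {}}
    for cid, table in {**tables, **basal}.items():
        summary["contrasts"][cid] = {
            "n_genes": len(table),
            "up": len(filter_significant(table, thr.fc_min, thr.p_max, "up")),
            "down": len(filter_significant(table, thr.fc_min, thr.p_max, "down")),
        }
        if cid in report.stringent:
            summary["contrasts"][cid]["stringent_uprs"] = len(report.stringent[cid])
    for key, regs in report.unique_regulators.items():
        summary["comparisons"][key] = {"unique_uprs": len(regs)}
    for (a, b), res in report.common_uprs.items():
        summary["comparisons"][f"{a}_and_{b}"] = {
            "common_stringent_uprs": len(res.common),
            "opposite_state_uprs": len(res.opposite_state),
            "common_response_genes": len(report.common_genes.get((a, b), set())),
        }
    for (a, b, d), res in report.specific_genes.items():
        summary["comparisons"][f"{a}_specific_vs_{b}_{d}"] = {"specific_genes": len(res.genes)}
    summary["enrichments"] = {k: len(v) for k, v in report.enrichments.items()}
    if report.crosstab is not None:
        summary["panel_crosstab"] = report.crosstab.counts()
    return summary


def run(config: RunConfig) -> PipelineReport:
    """Load all inputs named by the config, run the analysis, write outputs."""
    try:
        annotations = read_annotations(config.annotations)
        network = read_network(config.network, annotations)
    except Exception as exc:
        raise PipelineError("load", f"network/annotations: {exc}") from exc
    tables: dict[str, DETable] = {}
    for label, path in config.contrasts.items():
        try:
            tables[label] = read_de_table(path, label)
        except Exception as exc:
            raise PipelineError("load", f"contrast {label!r} ({path}): {exc}") from exc
    basal: dict[str, DETable] = {}
    for label, path in config.basal.items():
        try:
            basal[label] = read_de_table(path, label)
        except Exception as exc:
            raise PipelineError("load", f"basal {label!r} ({path}): {exc}") from exc
    gene_sets = read_gmt(config.gene_sets) if config.gene_sets else None
    panel = read_panel(config.panel, "panel") if config.panel else None

    report = run_objects(tables, network, gene_sets, panel, basal,
                         config.uniqueness, config.specific, config.common,
                         config.thresholds)
    if config.out_dir:
        _write_outputs(report, config)
    return report


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_upr_table(uprs: list[UPRResult], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["regulator", "molecule_type", "n_targets", "p_overlap",
                    "z", "z_bc", "state", "targets"])
        for u in sorted(uprs, key=lambda u: (u.p_overlap, u.regulator)):
            targets = ";".join(
                f"{m.gene}:{'+' if m.observed > 0 else '-'}" for m in u.matched_targets)
            w.writerow([u.regulator, u.molecule_type or "", u.n_targets,
                        _fmt(u.p_overlap), _fmt(u.z), _fmt(u.z_bc),
                        u.state.value, targets])


def write_verdict_table(verdicts: list[UniquenessVerdict], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["regulator", "model_a", "model_b", "verdict", "branch",
                    "z_b", "z_bc_b", "p_overlap_b"])
        for v in verdicts:
            b = v.evidence.get("b") or {}
            w.writerow([v.regulator, v.model_a, v.model_b, v.verdict.value,
                        v.branch.value, _fmt(b.get("z")), _fmt(b.get("z_bc")),
                        _fmt(b.get("p_overlap"))])


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_outputs(report: PipelineReport, config: RunConfig) -> None:
    import numpy
    import scipy

    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    for cid, uprs in report.full_uprs.items():
        write_upr_table(uprs, os.path.join(out, f"uprs_full_{cid}.tsv"))
    for cid, uprs in report.stringent.items():
        write_upr_table(uprs, os.path.join(out, f"uprs_stringent_{cid}.tsv"))
    if report.uniqueness:
        write_verdict_table(report.uniqueness, os.path.join(out, "uniqueness_verdicts.tsv"))
    for (a, b, d), res in report.specific_genes.items():
        path = os.path.join(out, f"specific_{a}_vs_{b}_{d}.tsv")
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["gene", "rule"])
            for rule_name, genes in (("opposite_direction", res.opposite_direction),
                                     ("ratio_retained", res.ratio_retained),
                                     ("absent_in_b", res.absent_in_b),
                                     ("ratio_removed", res.ratio_removed)):
                for g in sorted(genes):
                    w.writerow([g, rule_name])
    for key, results in report.enrichments.items():
        path = os.path.join(out, f"enrichment_{key}.tsv")
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["set_id", "name", "count", "percent", "p_value"])
            for r in results:
                w.writerow([r.set_id, r.name, r.count, _fmt(r.percent), _fmt(r.p_value)])
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(report.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    inputs = {**config.contrasts, **config.basal,
              "network": config.network, "annotations": config.annotations}
    if config.gene_sets:
        inputs["gene_sets"] = config.gene_sets
    if config.panel:
        inputs["panel"] = config.panel
    log = {
        "package_version": __version__,
        "numpy_version": numpy.__version__,
        "scipy_version": scipy.__version__,
        "thresholds": asdict(config.thresholds),
        "seed": config.seed,
        "input_sha256": {k: _sha256(v) for k, v in inputs.items()},
        "note": ("activation and bias-corrected Z-scores use this package's "
                 "documented stand-in formulas; see docs/methods.md"),
    }
    with open(os.path.join(out, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
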