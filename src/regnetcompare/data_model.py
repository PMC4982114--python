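"""Domain types, file dialects and the shared significance/intensity filters.

The pipeline's unit of input is one *contrast*: a treated-vs-untreated (or
responsive-vs-unresponsive) differential-expression table with one row per
measured gene carrying a log2 fold change, a nominal p-value, and optional
per-condition expression intensities (normalized read counts).

Fold changes follow the signed-linear convention used throughout tumor
transcriptomics tables: a gene 2.1-fold *down* is printed as FC = -2.1, so
``|signed_fc| = 2**|log2fc|`` and ``|signed_fc| >= 1`` always.

P-values here are nominal (unadjusted) DESeq-style p-values; the procedure
this package reproduces applies fixed cutoffs (|FC| > 2, p < 0.001) rather
than an FDR layer, and all threshold comparisons are strict.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

__all__ = [
    "DERecord",
    "DETable",
    "RegulatorEdge",
    "RegulatorAnnotation",
    "RegulatorNetwork",
    "GeneSet",
    "GenePanel",
    "DataFormatError",
    "IntensityUnavailableError",
    "signed_fc",
    "log2_from_signed_fc",
    "filter_significant",
    "filter_intensity",
    "read_de_table",
    "write_de_table",
    "read_network",
    "write_network",
    "read_annotations",
    "write_annotations",
    "read_gmt",
    "write_gmt",
    "read_panel",
    "write_panel",
]

DIRECTIONS = ("up", "down", "any")

# molecule-type labels with special meaning downstream
MOLTYPE_CHEMICAL_OTHER = "chemical-other"
MOLTYPE_CHEMICAL_ENDOGENOUS = "chemical-endogenous"
MOLTYPE_GROUP = "group"


class DataFormatError(ValueError):
    """A parse error in one of the tabular input dialects.

    Carries the offending file path and 1-based line number.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class IntensityUnavailableError(ValueError):
    """The intensity filter was requested on a table without intensity columns."""


def signed_fc(log2fc: float) -> float:
    """Convert a log2 fold change to the signed linear fold-change convention.

    ``2**log2fc`` for non-negative input, ``-2**(-log2fc)`` otherwise, so a
    halving (log2fc = -1) maps to -2.0 and no change maps to +1.0.  The result
    always has magnitude >= 1.
    """
    if not math.isfinite(log2fc):
        raise ValueError(f"log2fc must be finite, got {log2fc!r}")
    if log2fc >= 0:
        return float(2.0 ** log2fc)
    return float(-(2.0 ** (-log2fc)))


def log2_from_signed_fc(fc: float) -> float:
    """Inverse of :func:`signed_fc`; requires |fc| >= 1."""
    if not math.isfinite(fc) or abs(fc) < 1.0:
        raise ValueError(f"signed fold change must be finite with |fc| >= 1, got {fc!r}")
    if fc >= 1.0:
        return math.log2(fc)
    return -math.log2(-fc)


@dataclass(frozen=True)
class DERecord:
    """One gene's measurement in one contrast."""

    gene: str
    log2fc: float
    p_value: float
    intensity_untreated: float | None = None
    intensity_treated: float | None = None

    def __post_init__(self):
        if not math.isfinite(self.log2fc):
            raise ValueError(f"{self.gene}: log2fc must be finite")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"{self.gene}: p-value {self.p_value} outside [0, 1]")
        for label, v in (
            ("intensity_untreated", self.intensity_untreated),
            ("intensity_treated", self.intensity_treated),
        ):
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{self.gene}: {label} must be nonnegative, got {v}")

    @property
    def signed_fc(self) -> float:
        return signed_fc(self.log2fc)

    @property
    def direction(self) -> int:
        """+1 for up-regulated, -1 for down-regulated (log2fc = 0 counts as up)."""
        return 1 if self.log2fc >= 0 else -1

    @property
    def max_intensity(self) -> float | None:
        pair = [v for v in (self.intensity_untreated, self.intensity_treated) if v is not None]
        return max(pair) if pair else None


class DETable:
    """One contrast's per-gene records over a gene universe.

    Genes absent from the table are "not measured", a state distinct from
    "measured but not significant"; downstream set algebra preserves the
    distinction by always intersecting with :attr:`universe` explicitly.
    """

    def __init__(self, contrast_id: str, records: list[DERecord] | dict[str, DERecord]):
        self.contrast_id = contrast_id
        if isinstance(records, dict):
            items = records.values()
        else:
            items = records
        self.records: dict[str, DERecord] = {}
        for rec in items:
            gene = rec.gene.strip()
            if gene != rec.gene:
                rec = DERecord(gene, rec.log2fc, rec.p_value,
                               rec.intensity_untreated, rec.intensity_treated)
            if gene in self.records:
                raise ValueError(f"duplicate gene {gene!r} in contrast {contrast_id!r}")
            self.records[gene] = rec

    @property
    def universe(self) -> set[str]:
        """All measured genes."""
        return set(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene: str) -> bool:
        return gene in self.records

    def __getitem__(self, gene: str) -> DERecord:
        return self.records[gene]

    def get(self, gene: str) -> DERecord | None:
        return self.records.get(gene)

    def __eq__(self, other) -> bool:
        return (isinstance(other, DETable)
                and self.contrast_id == other.contrast_id
                and self.records == other.records)

    def __repr__(self) -> str:
        return f"DETable({self.contrast_id!r}, {len(self)} genes)"


@dataclass(frozen=True)
class RegulatorEdge:
    """A signed regulator -> target relationship.

    expected_sign: +1 the regulator activates the target, -1 represses,
    0 direction unknown (counts for overlap, not for the Z-scores).
    """

    regulator: str
    target: str
    expected_sign: int
    weight: float = 1.0

    def __post_init__(self):
        if self.expected_sign not in (-1, 0, 1):
            raise ValueError(f"expected_sign must be -1, 0 or +1, got {self.expected_sign}")
        if not (math.isfinite(self.weight) and self.weight >= 0):
            raise ValueError(f"weight must be nonnegative, got {self.weight}")


@dataclass(frozen=True)
class RegulatorAnnotation:
    regulator: str
    molecule_type: str
    species: str = ""
    constituents: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.constituents and self.molecule_type != MOLTYPE_GROUP:
            raise ValueError(
                f"{self.regulator}: constituents only allowed for molecule_type="
                f"{MOLTYPE_GROUP!r}, got {self.molecule_type!r}"
            )


class RegulatorNetwork:
    """Signed regulator->target edges plus per-regulator annotations."""

    def __init__(self, edges: list[RegulatorEdge],
                 annotations: dict[str, RegulatorAnnotation] | None = None):
        self.edges = list(edges)
        self.annotations = dict(annotations or {})
        self._by_regulator: dict[str, dict[str, RegulatorEdge]] = {}
        for e in self.edges:
            tgts = self._by_regulator.setdefault(e.regulator, {})
            if e.target in tgts:
                raise ValueError(f"duplicate edge {e.regulator!r} -> {e.target!r}")
            tgts[e.target] = e

    @property
    def regulators(self) -> list[str]:
        return list(self._by_regulator)

    def targets_of(self, regulator: str) -> dict[str, RegulatorEdge]:
        return self._by_regulator.get(regulator, {})

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")


@dataclass(frozen=True)
class GenePanel:
    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"panel {self.name!r} has no members")


# ---------------------------------------------------------------------------
# Filters shared by every stage
# ---------------------------------------------------------------------------

def filter_significant(table: DETable, fc_min: float = 2.0, p_max: float = 0.001,
                       direction: str = "any") -> set[str]:
    """Genes with |signed FC| strictly above ``fc_min`` and p strictly below ``p_max``.

    ``direction`` restricts to up- (signed FC > 0) or down-regulated genes;
    "any" is the disjoint union of the two.  Both cutoffs are strict, so a
    gene at exactly 2-fold or exactly p = 0.001 is excluded.
    """
    if fc_min < 1:
        raise ValueError(f"fc_min must be >= 1, got {fc_min}")
    if not (0 < p_max <= 1):
        raise ValueError(f"p_max must be in (0, 1], got {p_max}")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    out = set()
    for gene, rec in table.records.items():
        fc = rec.signed_fc
        if abs(fc) <= fc_min or rec.p_value >= p_max:
            continue
        if direction == "up" and fc < 0:
            continue
        if direction == "down" and fc > 0:
            continue
        out.add(gene)
    return out


def filter_intensity(table: DETable, min_intensity: float = 50.0) -> set[str]:
    """Genes whose intensity strictly exceeds ``min_intensity`` in either condition."""
    if min_intensity < 0:
        raise ValueError(f"min_intensity must be >= 0, got {min_intensity}")
    out = set()
    for gene, rec in table.records.items():
        mi = rec.max_intensity
        if mi is None:
            raise IntensityUnavailableError(
                f"contrast {table.contrast_id!r}: gene {gene!r} has no intensity values; "
                "the intensity filter requires intensity columns"
            )
        if mi > min_intensity:
            out.add(gene)
    return out


# ---------------------------------------------------------------------------
# I/O — small TSV dialects with line-numbered parse errors
# ---------------------------------------------------------------------------

DE_COLUMNS = ("gene", "log2fc", "pvalue", "intensity_untreated", "intensity_treated")


def _parse_float(value: str, what: str, path: str, line: int) -> float:
    try:
        x = float(value)
    except ValueError:
        raise DataFormatError(f"malformed {what}: {value!r}", path, line) from None
    if not math.isfinite(x):
        raise DataFormatError(f"non-finite {what}: {value!r}", path, line)
    return x


def read_de_table(path: str, contrast_id: str | None = None) -> DETable:
    """Read a DE table from TSV.

    Header ``gene  log2fc  pvalue  [intensity_untreated  intensity_treated]``;
    intensity columns are optional but must come as a pair.
    """
    path = str(path)
    with open(path, newline="") as fh:
        rows = csv.reader(fh, delimiter="\t")
        try:
            header = next(rows)
        except StopIteration:
            raise DataFormatError("empty DE table", path, 1) from None
        header = [h.strip() for h in header]
        if tuple(header) not in (DE_COLUMNS, DE_COLUMNS[:3]):
            raise DataFormatError(
                f"unexpected DE header {header!r}; expected {list(DE_COLUMNS)} "
                "(intensity columns optional)", path, 1)
        has_intensity = len(header) == 5
        records: dict[str, DERecord] = {}
        for ln, row in enumerate(rows, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise DataFormatError(f"expected {len(header)} fields, got {len(row)}", path, ln)
            gene = row[0].strip()
            if not gene:
                raise DataFormatError("empty gene symbol", path, ln)
            if gene in records:
                raise DataFormatError(f"duplicate gene row {gene!r}", path, ln)
            log2fc = _parse_float(row[1], "log2fc", path, ln)
            p = _parse_float(row[2], "p-value", path, ln)
            if not (0 <= p <= 1):
                raise DataFormatError(f"p-value {p} outside [0, 1]", path, ln)
            iu = it = None
            if has_intensity:
                iu = _parse_float(row[3], "intensity", path, ln)
                it = _parse_float(row[4], "intensity", path, ln)
            try:
                records[gene] = DERecord(gene, log2fc, p, iu, it)
            except ValueError as exc:
                raise DataFormatError(str(exc), path, ln) from None
    if contrast_id is None:
        contrast_id = path
    return DETable(contrast_id, records)


def write_de_table(table: DETable, path: str) -> None:
    has_intensity = any(r.max_intensity is not None for r in table.records.values())
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(DE_COLUMNS if has_intensity else DE_COLUMNS[:3])
        for gene in sorted(table.records):
            rec = table.records[gene]
            row = [gene, repr(rec.log2fc), repr(rec.p_value)]
            if has_intensity:
                row += [repr(rec.intensity_untreated), repr(rec.intensity_treated)]
            w.writerow(row)


NETWORK_COLUMNS = ("regulator", "target", "sign", "weight")


def read_network(path: str,
                 annotations: dict[str, RegulatorAnnotation] | None = None) -> RegulatorNetwork:
    path = str(path)
    edges: list[RegulatorEdge] = []
    with open(path, newline="") as fh:
        rows = csv.reader(fh, delimiter="\t")
        try:
            header = tuple(h.strip() for h in next(rows))
        except StopIteration:
            raise DataFormatError("empty network table", path, 1) from None
        if header != NETWORK_COLUMNS:
            raise DataFormatError(
                f"unexpected network header {list(header)!r}; expected {list(NETWORK_COLUMNS)}",
                path, 1)
        for ln, row in enumerate(rows, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise DataFormatError(f"expected 4 fields, got {len(row)}", path, ln)
            reg, tgt = row[0].strip(), row[1].strip()
            if not reg or not tgt:
                raise DataFormatError("empty regulator or target id", path, ln)
            if row[2].strip() not in ("-1", "0", "1", "+1"):
                raise DataFormatError(f"sign must be -1, 0 or 1, got {row[2]!r}", path, ln)
            sign = int(row[2])
            weight = _parse_float(row[3], "weight", path, ln)
            try:
                edges.append(RegulatorEdge(reg, tgt, sign, weight))
            except ValueError as exc:
                raise DataFormatError(str(exc), path, ln) from None
    try:
        return RegulatorNetwork(edges, annotations)
    except ValueError as exc:
        raise DataFormatError(str(exc), path) from None


def write_network(network: RegulatorNetwork, path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(NETWORK_COLUMNS)
        for e in network.edges:
            w.writerow([e.regulator, e.target, str(e.expected_sign), repr(e.weight)])


ANNOTATION_COLUMNS = ("regulator", "molecule_type", "species", "constituents")


def read_annotations(path: str) -> dict[str, RegulatorAnnotation]:
    path = str(path)
    out: dict[str, RegulatorAnnotation] = {}
    with open(path, newline="") as fh:
        rows = csv.reader(fh, delimiter="\t")
        try:
            header = tuple(h.strip() for h in next(rows))
        except StopIteration:
            raise DataFormatError("empty annotation table", path, 1) from None
        if header != ANNOTATION_COLUMNS:
            raise DataFormatError(
                f"unexpected annotation header {list(header)!r}; "
                f"expected {list(ANNOTATION_COLUMNS)}", path, 1)
        for ln, row in enumerate(rows, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise DataFormatError(f"expected 4 fields, got {len(row)}", path, ln)
            reg = row[0].strip()
            if not reg:
                raise DataFormatError("empty regulator id", path, ln)
            if reg in out:
                raise DataFormatError(f"duplicate annotation for {reg!r}", path, ln)
            constituents = frozenset(c.strip() for c in row[3].split(";") if c.strip())
            try:
                out[reg] = RegulatorAnnotation(reg, row[1].strip(), row[2].strip(), constituents)
            except ValueError as exc:
                raise DataFormatError(str(exc), path, ln) from None
    return out


def write_annotations(annotations: dict[str, RegulatorAnnotation], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ANNOTATION_COLUMNS)
        for reg in sorted(annotations):
            a = annotations[reg]
            w.writerow([a.regulator, a.molecule_type, a.species,
                        ";".join(sorted(a.constituents))])


def read_gmt(path: str) -> list[GeneSet]:
    """Read gene sets in GMT format: set id, description, then member symbols."""
    path = str(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                raise DataFormatError("empty GMT line", path, ln)
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataFormatError(
                    "GMT line needs at least set id, description and one member", path, ln)
            set_id = parts[0].strip()
            if not set_id:
                raise DataFormatError("empty set id", path, ln)
            if set_id in seen:
                raise DataFormatError(f"duplicate set id {set_id!r}", path, ln)
            seen.add(set_id)
            members = frozenset(g.strip() for g in parts[2:] if g.strip())
            if not members:
                raise DataFormatError(f"set {set_id!r} has no members", path, ln)
            sets.append(GeneSet(set_id, parts[1].strip(), members))
    return sets


def write_gmt(sets: list[GeneSet], path: str) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.members)]) + "\n")


def read_panel(path: str, name: str | None = None) -> GenePanel:
    """Read a gene panel: one symbol per line, ``#`` comments allowed."""
    path = str(path)
    members: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            sym = line.split("#", 1)[0].strip()
            if not sym:
                continue
            if sym in members:
                raise DataFormatError(f"duplicate panel gene {sym!r}", path, ln)
            members.add(sym)
    if not members:
        raise DataFormatError("panel contains no gene symbols", path)
    return GenePanel(name or path, frozenset(members))


def write_panel(panel: GenePanel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# panel: {panel.name}\n")
        for sym in sorted(panel.members):
            fh.write(sym + "\n")
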