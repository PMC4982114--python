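import pytest

from regnetcompare.data_model import (
    DERecord,
    DETable,
    RegulatorAnnotation,
    RegulatorEdge,
    RegulatorNetwork,
)
from regnetcompare.synthetic_data import ContrastSpec, ScenarioConfig


def make_table(contrast_id, rows):
    """rows: (gene, log2fc, p[, intensity_untreated, intensity_treated])."""
    return DETable(contrast_id, [DERecord(*row) for row in rows])


@pytest.fixture
def toy_network():
    """One activator (3 targets), one repressor (2), one sign-free regulator."""
    edges = [
        RegulatorEdge("ACT", "g1", 1), RegulatorEdge("ACT", "g2", 1),
        RegulatorEdge("ACT", "g3", 1),
        RegulatorEdge("REP", "g1", -1), RegulatorEdge("REP", "g4", -1),
        RegulatorEdge("UNK", "g2", 0), RegulatorEdge("UNK", "g5", 0),
    ]
    annotations = {r: RegulatorAnnotation(r, "cytokine", "mouse")
                   for r in ("ACT", "REP", "UNK")}
    return RegulatorNetwork(edges, annotations)


def small_config(seed=0, n_planted=4, effect_size=2.0):
    """A fast three-contrast scenario with disjoint planted regulators."""
    width = 3
    regs = [f"R{i:0{width}d}" for i in range(30)]

    def plant(ids):
        return {regs[i]: (1 if i % 2 == 0 else -1) for i in ids}

    contrasts = [
        ContrastSpec("modelA", plant(range(0, n_planted)), effect_size),
        ContrastSpec("modelB", plant(range(n_planted, 2 * n_planted)), effect_size),
        ContrastSpec("modelC", plant(range(2 * n_planted, 3 * n_planted)), effect_size),
    ]
    return ScenarioConfig(
        n_genes=500, n_regulators=30, targets_per_regulator=(12, 20),
        contrasts=contrasts, n_coregulated_sets=4, n_decoy_sets=4,
        decoy_set_size=(15, 30), panel_size=40, seed=seed,
    )
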