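"""Shared fixtures: tiny handcrafted references and full preset runs.

The full-depth preset runs are session-scoped so the acceptance tests and the
module tests reuse one simulation each.
"""

from __future__ import annotations

import numpy as np
import pytest

from protectseq import difftest, localization, mapping, presets, simulate


@pytest.fixture(scope="session")
def tiny_reference() -> simulate.Reference:
    """A 400-bp single-chromosome genome with one feature of several categories."""
    rng = np.random.default_rng(42)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
    features = [
        simulate.FeatureInterval("rrna1", "chr1", 10, 40, "+", "rRNA"),
        simulate.FeatureInterval("te1", "chr1", 30, 60, "+", "TE"),  # overlaps rrna1
        simulate.FeatureInterval("mir1", "chr1", 80, 101, "+", "miRNA"),
        simulate.FeatureInterval("gene1", "chr1", 120, 300, "+", "mRNA"),
        simulate.FeatureInterval("gene1.utr5", "chr1", 120, 150, "+", "mRNA", "five_utr", "gene1"),
        simulate.FeatureInterval("gene1.cds", "chr1", 150, 220, "+", "mRNA", "cds", "gene1"),
        simulate.FeatureInterval("gene1.intron", "chr1", 220, 260, "+", "mRNA", "intron", "gene1"),
        simulate.FeatureInterval("gene1.utr3", "chr1", 260, 300, "+", "mRNA", "three_utr", "gene1"),
    ]
    return simulate.Reference({"chr1": seq}, features)


def run_fig4(seed: int, depth: int = 1_000_000) -> dict:
    """Full fig4 analysis: simulate, quantify, filter, contrasts, calls."""
    cfg = presets.make_config("fig4", seed=seed, depth=depth)
    data = simulate.simulate_dataset(cfg, ("C", "R", "TR"))
    q = mapping.count_and_normalize(data["readsets"], data["reference"])
    rpm = q.rpm.drop(index=mapping.UNANNOTATED)
    counts = q.counts.drop(index=mapping.UNANNOTATED)
    retained = localization.filter_by_rpm(rpm, 1.0, comparator=">")
    contrasts = difftest.run_contrasts(counts.loc[retained], data["samplesheet"])
    calls = localization.classify_table(contrasts)
    truth = simulate.species_table(data["species"]).set_index("feature_id")["planted_class"]
    return {"data": data, "quant": q, "rpm": rpm, "counts": counts,
            "retained": retained, "contrasts": contrasts, "calls": calls, "truth": truth}


@pytest.fixture(scope="session")
def fig4_run() -> dict:
    return run_fig4(seed=1)


@pytest.fixture(scope="session")
def default_run() -> dict:
    cfg = presets.make_config("default", seed=1)
    data = simulate.simulate_dataset(cfg, ("C", "R", "TR"))
    q = mapping.count_and_normalize(data["readsets"], data["reference"])
    return {"data": data, "quant": q}


@pytest.fixture(scope="session")
def rnaser_run() -> dict:
    from protectseq import circrna

    cfg = presets.make_config("rnaser", seed=1)
    data = simulate.simulate_dataset(cfg, ("C", "RR"))
    ref = data["reference"]
    index = mapping.build_index(ref)
    lib = circrna.build_junction_library(ref.circles, ref, flank=cfg.read_length)
    return {"data": data, "reference": ref, "index": index, "junctions": lib}

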