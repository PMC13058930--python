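"""Shared test helpers: rendered fixtures and graph comparison utilities."""

import math

import networkx as nx
import numpy as np
import pytest

from ocsr import assemble, fixtures, raster

NODE_MATCH = nx.algorithms.isomorphism.categorical_node_match(
    ["element", "charge", "hcount"], ["*", 0, 0]
)
EDGE_MATCH = nx.algorithms.isomorphism.categorical_edge_match(
    ["order", "aromatic"], [1, False]
)


def graphs_isomorphic(got: assemble.MoleculeGraph, spec: fixtures.MoleculeSpec) -> bool:
    return nx.is_isomorphic(
        got.to_networkx(),
        fixtures.truth_graph(spec),
        node_match=NODE_MATCH,
        edge_match=EDGE_MATCH,
    )


def hexagon_spec(side: float = 1.0) -> fixtures.MoleculeSpec:
    atoms = [
        fixtures.AtomSpec(
            pos=(
                side * math.cos(math.radians(60 * k + 30)),
                side * math.sin(math.radians(60 * k + 30)),
            )
        )
        for k in range(6)
    ]
    bonds = [fixtures.BondSpec(k, (k + 1) % 6) for k in range(6)]
    return fixtures.MoleculeSpec(atoms=atoms, bonds=bonds)


def endpoint_error(detected, truth_pair) -> float:
    """Worst-end distance between a detected line/bond and a truth segment."""
    (t1, t2) = truth_pair
    d = math.dist
    return max(
        min(d(detected.end1, t1), d(detected.end1, t2)),
        min(d(detected.end2, t1), d(detected.end2, t2)),
    )


def truth_endpoints_in_work(fx, debug) -> tuple[float, int]:
    """Map rendered base coordinates into the pipeline's working frame.

    Returns (offset function inputs): the trim origin and upscale factor so
    that p_work = (p_base - origin) * scale + pad.
    """
    b0 = raster.binarize(np.where(fx.image.pixels, 0, 255).astype(np.uint8))
    ys, xs = np.nonzero(b0.pixels)
    core_h = ys.max() - ys.min() + 1
    scale = int(round((debug.work.height - 32) / core_h)) if debug.work else 1
    return (float(xs.min()), float(ys.min())), max(scale, 1)


@pytest.fixture(scope="session")
def stub_ocr():
    from ocsr.symbols import StubOcr

    return StubOcr()
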