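"""Shared fixtures and oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from flavodiel.likelihood import felsenstein_loglik
from flavodiel.phylo import ReferencePhylogeny, read_newick
from flavodiel.substitution import AMINO_ACIDS, SubstitutionModel


@pytest.fixture(scope="session")
def wag_gamma() -> SubstitutionModel:
    return SubstitutionModel(alpha=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def five_leaf_tree() -> ReferencePhylogeny:
    return read_newick("((A:0.1,B:0.2):0.15,(C:0.3,(D:0.05,E:0.4):0.2):0.1);")


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), length))


def random_alignment(tree: ReferencePhylogeny, rng: np.random.Generator,
                     length: int) -> dict:
    return {lab: random_peptide(rng, length) for lab in tree.leaf_labels}


def graft_query(tree: ReferencePhylogeny, edge: int, attach_fraction: float,
                pendant: float, label: str = "QUERY") -> ReferencePhylogeny:
    """Regraft a new leaf onto an edge at a fractional attachment point.

    Independent route used to cross-check the placement engine: builds an
    explicit bigger tree and leaves the likelihood to plain pruning.
    """
    parent = list(tree.parent)
    lengths = list(tree.lengths)
    labels = list(tree.labels)
    n = len(parent)
    u = n
    t = lengths[edge]
    parent.append(int(tree.parent[edge]))
    lengths.append(t * (1.0 - attach_fraction))  # parent-side piece
    labels.append(None)
    parent.append(u)
    lengths.append(pendant)
    labels.append(label)
    parent[edge] = u
    lengths[edge] = t * attach_fraction          # child-side piece
    return ReferencePhylogeny(parent=np.array(parent),
                              lengths=np.array(lengths), labels=labels)


def grid_best_edge(tree: ReferencePhylogeny, model: SubstitutionModel,
                   alignment: dict, query_seq: str,
                   attach_points=(0.125, 0.375, 0.625, 0.875),
                   pendants=(1e-4, 0.01, 0.05, 0.1, 0.2, 0.4, 0.8, 1.2, 1.8)) -> int:
    """Brute-force placement oracle: dense regraft grid, plain pruning."""
    best_edge, best_ll = None, -np.inf
    for e in tree.edges:
        for a in attach_points:
            for p in pendants:
                grafted = graft_query(tree, e, a, p)
                ll = felsenstein_loglik(grafted, model,
                                        {**alignment, "QUERY": query_seq})
                if ll > best_ll:
                    best_ll, best_edge = ll, e
    return best_edge
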