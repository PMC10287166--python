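"""Phylogenetic likelihood under a reversible model with gamma rate classes.

Felsenstein pruning over a fixed rooted tree, averaging the per-site
likelihood across the discrete gamma categories. Gap / unknown residues are
treated as missing data (conditional vector of ones), so an all-gap column
contributes exactly zero log-likelihood. Per-node, per-site rescaling keeps
partial likelihoods in floating range on large trees.
"""

from __future__ import annotations

import numpy as np

from .phylo import ReferencePhylogeny
from .substitution import N_STATES, SubstitutionModel, encode_sequence


def encode_alignment(sequences: dict) -> dict:
    """Map label -> aligned residue string into label -> integer codes."""
    enc = {k: encode_sequence(v) for k, v in sequences.items()}
    lengths = {a.size for a in enc.values()}
    if len(lengths) > 1:
        raise ValueError("aligned sequences differ in length")
    return enc


def leaf_partial(codes: np.ndarray) -> np.ndarray:
    """Conditional likelihood (20, n_sites) for observed leaf states.

    Gap codes (< 0) give a column of ones (missing data).
    """
    n = codes.size
    part = np.zeros((N_STATES, n))
    gap = codes < 0
    part[:, gap] = 1.0
    obs = np.where(~gap)[0]
    part[codes[obs], obs] = 1.0
    return part


def _scaled(arr: np.ndarray) -> tuple:
    """Rescale (K, 20, S) partials per site; return (partials, log scalers)."""
    scale = arr.max(axis=(0, 1))
    scale[scale == 0] = 1.0
    return arr / scale[None, None, :], np.log(scale)


def compute_down_partials(
    tree: ReferencePhylogeny, model: SubstitutionModel, codes: dict
) -> tuple:
    """Post-order conditional likelihoods below each node.

    Returns (partials, logscale): partials[v] has shape (K, 20, S) and
    logscale[v] shape (S,), where the true partial is
    partials[v] * exp(logscale[v]).
    """
    n_sites = next(iter(codes.values())).size
    k = model.n_categories
    partials = [None] * tree.n_nodes
    logscale = [None] * tree.n_nodes
    for v in tree.postorder():
        if tree.is_leaf(v):
            lab = tree.labels[v]
            if lab not in codes:
                raise KeyError(f"leaf {lab!r} missing from alignment")
            partials[v] = np.broadcast_to(leaf_partial(codes[lab]), (k, N_STATES, n_sites)).copy()
            logscale[v] = np.zeros(n_sites)
        else:
            acc = np.ones((k, N_STATES, n_sites))
            ls = np.zeros(n_sites)
            for c in tree.children[v]:
                pmats = model.transition_matrices(float(tree.lengths[c]))
                acc *= np.einsum("kxy,kys->kxs", pmats, partials[c])
                ls += logscale[c]
            acc, extra = _scaled(acc)
            partials[v] = acc
            logscale[v] = ls + extra
    return partials, logscale


def felsenstein_loglik(
    tree: ReferencePhylogeny, model: SubstitutionModel, alignment: dict
) -> float:
    """Log-likelihood of the alignment on the tree under the model.

    ``alignment`` maps leaf label -> aligned residue string (or integer
    codes); every leaf must be present.
    """
    codes = {
        k: (v if isinstance(v, np.ndarray) else encode_sequence(v))
        for k, v in alignment.items()
    }
    partials, logscale = compute_down_partials(tree, model, codes)
    root = tree.root
    site = np.einsum(
        "k,x,kxs->s",
        model.category_weights,
        model.frequencies,
        partials[root],
    )
    return float(np.sum(np.log(site) + logscale[root]))


def two_taxon_loglik(
    model: SubstitutionModel, codes_x: np.ndarray, codes_y: np.ndarray, b1: float, b2: float
) -> float:
    """Closed-form log-likelihood of a two-leaf tree with states x, y.

    By reversibility the likelihood per site is
    pi_x * P(b1 + b2)[x, y], averaged over gamma categories. Serves as an
    independent oracle for the pruning implementation.
    """
    total = 0.0
    pmats = model.transition_matrices(b1 + b2)
    pi = model.frequencies
    for cx, cy in zip(codes_x, codes_y):
        if cx < 0 and cy < 0:
            continue
        if cx < 0:
            site = pi[cy]
        elif cy < 0:
            site = pi[cx]
        else:
            site = pi[cx] * pmats[:, cx, cy].mean()
        total += np.log(site)
    return float(total)
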