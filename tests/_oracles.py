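"""Independent reference implementations used only to check the package.

These are deliberately naive (dict-of-edges loops, exhaustive pair counting)
and share no code with the vectorized implementations they validate.
"""

import numpy as np


def naive_dmpnn_encode(graph, params) -> np.ndarray:
    """Triple-loop directed message passing on one molecular graph."""
    W_in = np.asarray(params.W_in.data, dtype=np.float64)
    W_msg = np.asarray(params.W_msg.data, dtype=np.float64)
    W_atom = np.asarray(params.W_atom.data, dtype=np.float64)
    A = graph.atom_features
    relu = lambda v: np.maximum(v, 0.0)

    c0 = {}
    for (p, q) in graph.directed_edges:
        bond = graph.bond_features[(min(p, q), max(p, q))]
        c0[(p, q)] = relu(W_in @ np.concatenate([A[p], bond]))
    c = dict(c0)
    for _ in range(params.depth):
        new = {}
        for (p, q) in graph.directed_edges:
            incoming = np.zeros(params.hidden_dim)
            for j in graph.neighbor_index[p]:
                if j != q:
                    incoming += c[(j, p)]
            new[(p, q)] = relu(c0[(p, q)] + W_msg @ incoming)
        c = new
    dpi = np.zeros(params.hidden_dim)
    for p in range(graph.n_atoms):
        i_p = np.zeros(params.hidden_dim)
        for j in graph.neighbor_index[p]:
            i_p += c[(j, p)]
        dpi += relu(W_atom @ np.concatenate([A[p], i_p]))
    return dpi


def pair_counting_auc(scores, labels) -> float:
    """AUC as the fraction of correctly ordered positive-negative pairs,
    with half credit for ties (the Mann-Whitney statistic)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def permute_graph(graph, perm):
    """Relabel the atoms of a MolecularGraph by a permutation array."""
    from mifnn.chem_io import MolecularGraph

    perm = np.asarray(perm)
    inv = {int(old): int(new) for new, old in enumerate(perm)}
    edges = [(inv[p], inv[q]) for (p, q) in graph.directed_edges]
    nbrs = [set() for _ in range(graph.n_atoms)]
    for p, q in edges:
        nbrs[p].add(q)
    bonds = {}
    for (p, q), v in graph.bond_features.items():
        np_, nq = inv[p], inv[q]
        bonds[(min(np_, nq), max(np_, nq))] = v
    return MolecularGraph(
        smiles=graph.smiles,
        n_atoms=graph.n_atoms,
        directed_edges=edges,
        neighbor_index=nbrs,
        atom_features=graph.atom_features[perm],
        bond_features=bonds,
        mol=None,
    )
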