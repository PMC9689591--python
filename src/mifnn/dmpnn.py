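"""Directed message-passing encoder producing a 300-d molecular vector.

Messages live on *directed bonds* rather than atoms.  Each directed edge
(p, q) carries a hidden state; its update at every step sums the states of
edges arriving at p while excluding the reverse edge (q, p), which prevents
information from bouncing straight back ("totters").  A skip connection adds
the edge's initial state at every step.  The readout sums edge states into
atoms, mixes with atom features, and sum-pools atoms into one vector per
molecule — so the encoding is invariant to atom relabeling and additive over
disconnected components.

All operations run on :class:`~mifnn.autodiff.Tensor`, so the encoder trains
end-to-end with the downstream branches.  Batches of molecules are packed as
one disconnected union graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, segment_sum
from .chem_io import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, MolecularGraph

HIDDEN_DIM = 300  # width of the molecular directed-information vector
DEFAULT_DEPTH = 3  # number of message-passing steps


class DimensionMismatch(ValueError):
    pass


@dataclass
class DMPNNParams:
    """Weights of the encoder.

    ``W_in`` maps cat(atom, bond) features to the initial edge state,
    ``W_msg`` mixes incoming message sums, and ``W_atom`` maps
    cat(atom features, aggregated edge states) to the per-atom vector.
    No bias terms are used.
    """

    W_in: Tensor
    W_msg: Tensor
    W_atom: Tensor
    hidden_dim: int = HIDDEN_DIM
    depth: int = DEFAULT_DEPTH

    def tensors(self) -> list[Tensor]:
        return [self.W_in, self.W_msg, self.W_atom]


def init_params(
    rng: np.random.Generator,
    hidden_dim: int = HIDDEN_DIM,
    depth: int = DEFAULT_DEPTH,
    atom_dim: int = ATOM_FEATURE_DIM,
    bond_dim: int = BOND_FEATURE_DIM,
) -> DMPNNParams:
    """Seeded uniform initialization scaled by fan-in."""

    def u(shape):
        bound = 1.0 / np.sqrt(shape[1])
        return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)

    return DMPNNParams(
        W_in=u((hidden_dim, atom_dim + bond_dim)),
        W_msg=u((hidden_dim, hidden_dim)),
        W_atom=u((hidden_dim, atom_dim + hidden_dim)),
        hidden_dim=hidden_dim,
        depth=depth,
    )


@dataclass
class GraphBatch:
    """A list of molecular graphs packed as one disconnected union."""

    atom_features: np.ndarray  # (N, atom_dim)
    edge_bond_features: np.ndarray  # (E, bond_dim), per directed edge
    edge_src: np.ndarray  # (E,)
    edge_dst: np.ndarray  # (E,)
    rev_index: np.ndarray  # (E,) index of the reverse directed edge
    atom_mol: np.ndarray  # (N,) molecule index per atom
    n_mols: int

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_src.shape[0]


def pack_graphs(graphs: list[MolecularGraph]) -> GraphBatch:
    atom_feats, bond_feats, src, dst, atom_mol = [], [], [], [], []
    offset = 0
    for m, g in enumerate(graphs):
        if g.atom_features is None:
            raise ValueError("graphs must be featurized before packing")
        atom_feats.append(g.atom_features)
        atom_mol.extend([m] * g.n_atoms)
        for (p, q) in g.directed_edges:
            src.append(p + offset)
            dst.append(q + offset)
            bond_feats.append(g.bond_features[(min(p, q), max(p, q))])
        offset += g.n_atoms
    n_edges = len(src)
    # edges were appended in (p,q),(q,p) pairs: reverse of edge e is e XOR 1
    rev = np.arange(n_edges, dtype=np.intp) ^ 1
    return GraphBatch(
        atom_features=np.vstack(atom_feats) if atom_feats else np.zeros((0, ATOM_FEATURE_DIM)),
        edge_bond_features=(
            np.vstack(bond_feats) if bond_feats else np.zeros((0, BOND_FEATURE_DIM))
        ),
        edge_src=np.asarray(src, dtype=np.intp),
        edge_dst=np.asarray(dst, dtype=np.intp),
        rev_index=rev,
        atom_mol=np.asarray(atom_mol, dtype=np.intp),
        n_mols=len(graphs),
    )


@dataclass
class EdgeStates:
    """Per-directed-edge hidden states through the message-passing phase."""

    c0: np.ndarray  # initial states, ReLU output so entrywise >= 0
    c: np.ndarray  # current states
    i: np.ndarray | None = None  # last incoming message sums


# -- batched differentiable core -------------------------------------------

def _init_edge_states_t(batch: GraphBatch, params: DMPNNParams) -> Tensor:
    atom = Tensor(batch.atom_features)
    bond = Tensor(batch.edge_bond_features)
    cat_dim = batch.atom_features.shape[1] + batch.edge_bond_features.shape[1]
    if params.W_in.shape[1] != cat_dim:
        raise DimensionMismatch(
            f"W_in expects input dim {params.W_in.shape[1]}, cat(a_p, b_pq) has {cat_dim}"
        )
    x = concat([atom.take_rows(batch.edge_src), bond], axis=1)
    return (x @ params.W_in.T).relu()


def _message_step_t(batch: GraphBatch, c0: Tensor, c: Tensor, params: DMPNNParams) -> tuple[Tensor, Tensor]:
    """One synchronous update; returns (messages, new states)."""
    # sum of states of edges arriving at each atom, then subtract the reverse
    # edge's state to realize the sum over N(p) \ {q}
    arriving = segment_sum(c, batch.edge_dst, batch.n_atoms)
    msg = arriving.take_rows(batch.edge_src) - c.take_rows(batch.rev_index)
    new_c = (c0 + msg @ params.W_msg.T).relu()
    return msg, new_c


def _readout_t(batch: GraphBatch, c: Tensor, params: DMPNNParams) -> Tensor:
    incoming = segment_sum(c, batch.edge_dst, batch.n_atoms)  # i_p over edges into p
    atom = Tensor(batch.atom_features)
    h = (concat([atom, incoming], axis=1) @ params.W_atom.T).relu()
    return segment_sum(h, batch.atom_mol, batch.n_mols)


def encode_batch(batch: GraphBatch, params: DMPNNParams) -> Tensor:
    """Differentiable encoding of a packed batch; (n_mols, hidden_dim)."""
    c0 = _init_edge_states_t(batch, params)
    c = c0
    for _ in range(params.depth):
        _, c = _message_step_t(batch, c0, c, params)
    return _readout_t(batch, c, params)


# -- single-graph public API -----------------------------------------------

@dataclass
class DirectedInfoVector:
    """The sum-pooled molecular representation (length ``hidden_dim``)."""

    values: np.ndarray


def init_edge_states(graph: MolecularGraph, params: DMPNNParams) -> EdgeStates:
    """Initial edge states c0_pq = ReLU(W_in . cat(a_p, b_pq))."""
    batch = pack_graphs([graph])
    c0 = _init_edge_states_t(batch, params).data
    return EdgeStates(c0=c0, c=c0.copy())


def message_step(graph: MolecularGraph, states: EdgeStates, params: DMPNNParams) -> EdgeStates:
    """One synchronous message-passing step over all directed edges."""
    batch = pack_graphs([graph])
    msg, new_c = _message_step_t(batch, Tensor(states.c0), Tensor(states.c), params)
    return EdgeStates(c0=states.c0, c=new_c.data, i=msg.data)

def readout(graph: MolecularGraph, states: EdgeStates, params: DMPNNParams) -> DirectedInfoVector:
    """Aggregate edge states into atoms, then sum-pool atoms into one vector."""
    batch = pack_graphs([graph])
    out = _readout_t(batch, Tensor(states.c), params)
    return DirectedInfoVector(values=out.data[0])


def encode(graph: MolecularGraph, params: DMPNNParams) -> DirectedInfoVector:
    """init -> depth x message_step -> readout, composed."""
    states = init_edge_states(graph, params)
    for _ in range(params.depth):
        states = message_step(graph, states, params)
    return readout(graph, states, params)
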