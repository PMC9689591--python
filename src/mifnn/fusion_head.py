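"""Feature fusion, FC head, and end-to-end training of the neural extractor.

The two branch features are fused by concatenation (directed-information
branch first), passed through a fully connected ReLU layer with dropout, and
— during training only — read by an auxiliary sigmoid head trained with
binary cross-entropy.  Training is two-stage: the whole extractor (D-MPNN +
both branches + FC) is optimized jointly against the auxiliary head, then the
head is discarded and the frozen FC output becomes the feature each molecule
presents to the downstream PSO-SVM.  The SVM itself is not differentiable, so
it never participates in backpropagation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import chem_io, dmpnn
from .autodiff import Adam, Tensor, concat, no_grad
from .chem_io import MoleculeRecord
from .extractors import (
    ExtractorConfig,
    MDIFENParams,
    MFFENParams,
    init_mdifen_params,
    init_mffen_params,
    mdifen_forward_batch,
    mffen_forward_batch,
)

logger = logging.getLogger(__name__)


class SingleClassDataset(ValueError):
    """Training requires at least one sample of each class."""


class NonFiniteLoss(RuntimeError):
    """The training loss became NaN or infinite."""


@dataclass
class FusedFeature:
    """Concatenation of the two branch features (directed branch first)."""

    values: np.ndarray


def fuse(f1, f2) -> FusedFeature:
    """Concatenate two branch features; order fixed (MDIFEN first)."""
    v1 = np.asarray(f1.values if hasattr(f1, "values") else f1, dtype=np.float64)
    v2 = np.asarray(f2.values if hasattr(f2, "values") else f2, dtype=np.float64)
    return FusedFeature(values=np.concatenate([v1, v2]))


def fc_forward(f, weights, bias, activation="relu") -> np.ndarray:
    """Fully connected layer a = act(w . f + b) on a plain feature vector."""
    v = np.asarray(f.values if hasattr(f, "values") else f, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    b = np.asarray(bias, dtype=np.float64)
    if w.shape[1] != v.shape[-1]:
        raise ValueError(f"weight shape {w.shape} incompatible with feature dim {v.shape[-1]}")
    a = v @ w.T + b
    if activation == "relu":
        return np.maximum(a, 0.0)
    if activation in (None, "linear"):
        return a
    raise ValueError(f"unknown activation {activation!r}")


@dataclass
class ModelConfig:
    """Architecture of the full extractor."""

    dmpnn_hidden: int = dmpnn.HIDDEN_DIM
    dmpnn_depth: int = dmpnn.DEFAULT_DEPTH
    extractor: ExtractorConfig = field(default_factory=ExtractorConfig)
    fc_dim: int = 64
    morgan_radius: int = 2
    fp_nbits: int = 2048
    use_mdifen: bool = True
    use_mffen: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["extractor"]["mffen_channels"] = list(d["extractor"]["mffen_channels"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        ext = dict(d.pop("extractor"))
        ext["mffen_channels"] = tuple(ext["mffen_channels"])
        return cls(extractor=ExtractorConfig(**ext), **d)


@dataclass
class TrainConfig:
    """Optimization settings for the extractor."""

    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class PreparedMolecule:
    """Cached arrays for fast re-batching during training."""

    record: MoleculeRecord
    atom_features: np.ndarray
    edge_bond_features: np.ndarray
    edge_src: np.ndarray
    edge_dst: np.ndarray
    fp_matrix: np.ndarray  # (32, 64) float


def prepare_molecules(
    records: list[MoleculeRecord], config: ModelConfig
) -> tuple[list[PreparedMolecule], int]:
    """Featurize records once; returns (prepared list, n dropped as invalid)."""
    prepared: list[PreparedMolecule] = []
    dropped = 0
    for rec in records:
        try:
            graph = chem_io.featurize(chem_io.parse_smiles(rec.smiles))
        except (chem_io.InvalidSmiles, chem_io.EmptyMolecule):
            dropped += 1
            continue
        src, dst, bond = [], [], []
        for (p, q) in graph.directed_edges:
            src.append(p)
            dst.append(q)
            bond.append(graph.bond_features[(min(p, q), max(p, q))])
        fp = chem_io.morgan_fingerprint(rec.smiles, config.morgan_radius, config.fp_nbits)
        prepared.append(
            PreparedMolecule(
                record=rec,
                atom_features=graph.atom_features,
                edge_bond_features=(
                    np.vstack(bond) if bond else np.zeros((0, chem_io.BOND_FEATURE_DIM))
                ),
                edge_src=np.asarray(src, dtype=np.intp),
                edge_dst=np.asarray(dst, dtype=np.intp),
                fp_matrix=chem_io.reshape_fingerprint(fp).astype(np.float64),
            )
        )
    if dropped:
        logger.info("dropped %d molecules that failed to featurize", dropped)
    return prepared, dropped


def _pack_prepared(mols: list[PreparedMolecule]) -> dmpnn.GraphBatch:
    offsets = np.cumsum([0] + [m.atom_features.shape[0] for m in mols])
    src = np.concatenate([m.edge_src + off for m, off in zip(mols, offsets)])
    dst = np.concatenate([m.edge_dst + off for m, off in zip(mols, offsets)])
    atom_mol = np.concatenate(
        [np.full(m.atom_features.shape[0], i, dtype=np.intp) for i, m in enumerate(mols)]
    )
    return dmpnn.GraphBatch(
        atom_features=np.vstack([m.atom_features for m in mols]),
        edge_bond_features=np.vstack([m.edge_bond_features for m in mols]),
        edge_src=src.astype(np.intp),
        edge_dst=dst.astype(np.intp),
        rev_index=np.arange(len(src), dtype=np.intp) ^ 1,
        atom_mol=atom_mol,
        n_mols=len(mols),
    )


@dataclass
class ExtractorParams:
    """All trainable tensors of the extractor, addressable by name."""

    dmpnn: dmpnn.DMPNNParams
    mdifen: MDIFENParams
    mffen: MFFENParams
    fc_W: Tensor
    fc_b: Tensor
    head_w: Tensor
    head_b: Tensor

    def tensors(self) -> list[Tensor]:
        return (self.dmpnn.tensors() + self.mdifen.tensors() + self.mffen.tensors()
                + [self.fc_W, self.fc_b, self.head_w, self.head_b])

    def named_arrays(self) -> dict[str, np.ndarray]:
        names_d = ["dmpnn.W_in", "dmpnn.W_msg", "dmpnn.W_atom"]
        names_m = ["mdifen.embed_w", "mdifen.embed_b", "mdifen.conv_W", "mdifen.conv_b"]
        for pfx in ("mdifen.lstm_fwd", "mdifen.lstm_bwd"):
            for g in ("i", "m", "o", "f"):
                names_m += [f"{pfx}.W_{g}", f"{pfx}.U_{g}", f"{pfx}.b_{g}"]
        names_m += ["mdifen.att.W_w", "mdifen.att.b_w", "mdifen.att.eta_w",
                    "mdifen.proj_W", "mdifen.proj_b"]
        names_f = ["mffen.conv1_W", "mffen.conv1_b", "mffen.conv2_W", "mffen.conv2_b",
                   "mffen.proj_W", "mffen.proj_b"]
        names = names_d + names_m + names_f + ["fc_W", "fc_b", "head_w", "head_b"]
        tensors = self.tensors()
        assert len(names) == len(tensors)
        return {n: t.data for n, t in zip(names, tensors)}


def init_extractor_params(rng: np.random.Generator, config: ModelConfig) -> ExtractorParams:
    def u(shape, fan_in):
        bound = 1.0 / np.sqrt(max(fan_in, 1))
        return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)

    ext = config.extractor
    fused_dim = ext.branch_dim * (int(config.use_mdifen) + int(config.use_mffen))
    return ExtractorParams(
        dmpnn=dmpnn.init_params(rng, config.dmpnn_hidden, config.dmpnn_depth),
        mdifen=init_mdifen_params(rng, ext),
        mffen=init_mffen_params(rng, ext),
        fc_W=u((config.fc_dim, fused_dim), fused_dim),
        fc_b=Tensor(np.zeros(config.fc_dim), requires_grad=True),
        head_w=u((config.fc_dim,), config.fc_dim),
        head_b=Tensor(np.zeros(1), requires_grad=True),
    )


def _forward_batch(
    mols: list[PreparedMolecule],
    params: ExtractorParams,
    config: ModelConfig,
    mode: str,
    rng: np.random.Generator | None,
) -> tuple[Tensor, Tensor]:
    """Returns (post-FC features (B, fc_dim), auxiliary logits (B,))."""
    branches: list[Tensor] = []
    if config.use_mdifen:
        batch = _pack_prepared(mols)
        dpi = dmpnn.encode_batch(batch, params.dmpnn)
        branches.append(mdifen_forward_batch(dpi, params.mdifen, mode, rng))
    if config.use_mffen:
        fps = Tensor(np.stack([m.fp_matrix for m in mols]))
        branches.append(mffen_forward_batch(fps, params.mffen, mode, rng))
    fused = branches[0] if len(branches) == 1 else concat(branches, axis=1)
    feat = (fused @ params.fc_W.T + params.fc_b).relu()
    feat = feat.dropout(config.extractor.dropout, rng, mode == "train")
    logits = (feat @ params.head_w) + params.head_b
    return feat, logits.reshape(-1)


def _bce_with_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy from logits."""
    yt = Tensor(np.asarray(y, dtype=np.float64))
    absz = logits.relu() + (-logits).relu()
    softplus = ((-absz).exp() + 1.0).log() + logits.relu()
    return (softplus - yt * logits).mean()


@dataclass
class TrainedExtractor:
    params: ExtractorParams
    model_config: ModelConfig
    train_config: TrainConfig
    loss_trace: list[float]
    train_auc_trace: list[float] = field(default_factory=list)

    def checkpoint_hash(self) -> str:
        h = hashlib.sha256()
        h.update(json.dumps(self.model_config.to_dict(), sort_keys=True).encode())
        for name, arr in sorted(self.params.named_arrays().items()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        """Serialize all named parameter arrays plus the config to one file."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = json.dumps(
            {"model_config": self.model_config.to_dict(),
             "train_config": asdict(self.train_config),
             "loss_trace": self.loss_trace,
             "train_auc_trace": self.train_auc_trace}
        )
        arrays = {k.replace(".", "__"): v for k, v in self.params.named_arrays().items()}
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedExtractor":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model_config = ModelConfig.from_dict(meta["model_config"])
            params = init_extractor_params(np.random.default_rng(0), model_config)
            named = params.named_arrays()
            for name in named:
                arr = data[name.replace(".", "__")]
                if named[name].shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                named[name][...] = arr
        return cls(
            params=params,
            model_config=model_config,
            train_config=TrainConfig(**meta["train_config"]),
            loss_trace=list(meta["loss_trace"]),
            train_auc_trace=list(meta.get("train_auc_trace", [])),
        )


def train_extractor(
    dataset: list[MoleculeRecord],
    config: TrainConfig,
    model_config: ModelConfig | None = None,
) -> TrainedExtractor:
    """Jointly optimize the D-MPNN, both branches and the FC layer.

    Minimizes binary cross-entropy of the auxiliary sigmoid head with Adam
    (default learning rate 0.001).  Fully reproducible given ``config.seed``.
    """
    model_config = model_config or ModelConfig()
    labels = np.array([r.label for r in dataset], dtype=float)
    if len(np.unique(labels)) < 2:
        raise SingleClassDataset("training requires both classes present")
    prepared, _ = prepare_molecules(dataset, model_config)
    labels = np.array([m.record.label for m in prepared], dtype=float)
    if len(np.unique(labels)) < 2:
        raise SingleClassDataset("training requires both classes after featurization")

    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_shuffle, rng_drop = (np.random.default_rng(s) for s in ss.spawn(3))
    params = init_extractor_params(rng_init, model_config)
    opt = Adam(params.tensors(), lr=config.learning_rate)

    n = len(prepared)
    loss_trace: list[float] = []
    auc_trace: list[float] = []
    for epoch in range(config.epochs):
        order = rng_shuffle.permutation(n)
        epoch_loss = 0.0
        epoch_logits = np.empty(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            mols = [prepared[i] for i in idx]
            _, logits = _forward_batch(mols, params, model_config, "train", rng_drop)
            loss = _bce_with_logits(logits, labels[idx])
            if not np.isfinite(loss.data):
                raise NonFiniteLoss(
                    f"non-finite loss at epoch {epoch}, batch start {start}: {loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            epoch_logits[idx] = logits.data
            del loss, logits  # drop the batch graph before building the next
        loss_trace.append(epoch_loss / n)
        # train AUC from the logits already computed during the epoch
        # (each sample scored once, by the then-current parameters)
        order_pairs = np.argsort(epoch_logits)
        ranks = np.empty(n)
        ranks[order_pairs] = np.arange(1, n + 1)
        n_pos = labels.sum()
        auc_trace.append(
            float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                  / (n_pos * (n - n_pos)))
        )
    return TrainedExtractor(
        params=params,
        model_config=model_config,
        train_config=config,
        loss_trace=loss_trace,
        train_auc_trace=auc_trace,
    )


@dataclass
class FeatureTable:
    """One fused, post-FC feature row per molecule (evaluation mode)."""

    ids: list[str]
    values: np.ndarray  # (n, fc_dim)


def extract_features(
    dataset: list[MoleculeRecord] | list[PreparedMolecule],
    trained: TrainedExtractor,
    batch_size: int = 256,
) -> FeatureTable:
    """Evaluate the frozen extractor on every valid record (row order kept)."""
    if dataset and isinstance(dataset[0], PreparedMolecule):
        prepared = dataset
    else:
        prepared, _ = prepare_molecules(dataset, trained.model_config)
    rows, ids = [], []
    with no_grad():
        for start in range(0, len(prepared), batch_size):
            mols = prepared[start:start + batch_size]
            feat, _ = _forward_batch(mols, trained.params, trained.model_config, "eval", None)
            rows.append(feat.data)
            ids.extend(m.record.id for m in mols)
    values = np.vstack(rows) if rows else np.zeros((0, trained.model_config.fc_dim))
    return FeatureTable(ids=ids, values=values)


def predict_logits(
    prepared: list[PreparedMolecule],
    trained: TrainedExtractor,
    batch_size: int = 256,
) -> np.ndarray:
    """Auxiliary-head logits in evaluation mode (used by the FFN baselines)."""
    out = []
    with no_grad():
        for start in range(0, len(prepared), batch_size):
            mols = prepared[start:start + batch_size]
            _, logits = _forward_batch(mols, trained.params, trained.model_config, "eval", None)
            out.append(logits.data)
    return np.concatenate(out) if out else np.zeros(0)
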