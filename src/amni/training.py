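"""End-to-end seeded training of the two branches and the fusion head.

The default recipe is Adam with learning rate 1e-4, weight decay 0.0015,
100 epochs and mini-batches of 16; the objective is
``L = L_C + lambda * L_M`` with lambda = 0.01.

Variants
--------
``amni``        both branches, feature-level fusion, MMD adaptation on.
``amni_womdd``  same architecture with lambda forced to 0 (MMD recorded,
                not optimized).
``amni_s``      structural branch only, head FC 64 -> 64 -> 2.
``amni_f``      functional branch only, head FC 64 -> 64 -> 2.
``amni_lf``     two independent per-branch classifiers trained jointly with
                their own cross-entropies; decision-level fusion with weight
                ``lf_weight`` on the functional softmax at predict time.

Identical seeds give identical parameters, history and predictions: the seed
controls parameter initialization, batch shuffling and dropout masks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .cnn_branch import CNNBranch, CNNBranchConfig
from .connectome import GraphConfig, build_graph, normalize_adjacency, pearson_fcn
from .errors import ConfigError, ContractViolationError, DataError
from .fusion import FusionHead, LossConfig, cross_entropy_from_probs, mmd_loss_with_grad
from .gcn_branch import GCNBranch, GCNBranchConfig
from .nn import Adam, Param, softmax
from .types import MultimodalSubject, Prediction

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "AMNIModel",
    "train_model",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

_VARIANTS = ("amni", "amni_s", "amni_f", "amni_womdd", "amni_lf")


@dataclass
class TrainConfig:
    """Hyperparameters of one training run."""

    learning_rate: float = 1e-4
    weight_decay: float = 0.0015
    epochs: int = 100
    batch_size: int = 16
    optimizer: str = "adam"
    seed: int = 0
    variant: str = "amni"
    lf_weight: float = 0.5
    loss: LossConfig = field(default_factory=LossConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    gcn: GCNBranchConfig = field(default_factory=GCNBranchConfig)
    cnn: CNNBranchConfig = field(default_factory=CNNBranchConfig)
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ConfigError("learning rate must be > 0 and weight decay >= 0")
        if self.epochs < 0 or self.batch_size < 1:
            raise ConfigError("epochs must be >= 0 and batch size >= 1")
        if self.optimizer.lower() != "adam":
            raise ConfigError(f"unsupported optimizer {self.optimizer!r}")
        if self.variant not in _VARIANTS:
            raise ConfigError(
                f"variant must be one of {_VARIANTS}, got {self.variant!r}"
            )
        if self.variant == "amni_lf" and not 0.0 <= self.lf_weight <= 1.0:
            raise ConfigError("lf_weight must be in [0, 1]")

    @property
    def uses_functional(self) -> bool:
        return self.variant != "amni_s"

    @property
    def uses_structural(self) -> bool:
        return self.variant != "amni_f"

    @property
    def effective_lambda(self) -> float:
        if self.variant in ("amni_womdd", "amni_s", "amni_f", "amni_lf"):
            return 0.0
        return float(self.loss.lambda_)


@dataclass
class TrainHistory:
    """Per-epoch loss and accuracy records."""

    records: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.records.append(dict(kwargs))

    def __len__(self) -> int:
        return len(self.records)

    def final(self, key: str) -> float:
        if not self.records:
            raise ContractViolationError("empty training history")
        return float(self.records[-1][key])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.records).to_csv(path, sep="\t", index=False)


class AMNIModel:
    """The assembled two-branch classifier for one variant."""

    def __init__(
        self,
        cfg: TrainConfig,
        n_rois: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.cfg = cfg
        self.n_rois = n_rois
        dtype = np.dtype(cfg.dtype).type
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.gcn: GCNBranch | None = None
        self.cnn: CNNBranch | None = None
        if cfg.uses_functional:
            if n_rois is None:
                raise ConfigError("n_rois is required for variants with a GCN branch")
            self.gcn = GCNBranch(n_rois, cfg.gcn, rng, dtype)
        if cfg.uses_structural:
            self.cnn = CNNBranch(cfg.cnn, rng, dtype)
        f_width = cfg.gcn.head_width if self.gcn is not None else 0
        s_width = cfg.cnn.fc_widths[1] if self.cnn is not None else 0
        if cfg.variant == "amni_lf":
            self.head_f = FusionHead(f_width, 64, 2, rng, dtype, name="lf_head_f")
            self.head_s = FusionHead(s_width, 64, 2, rng, dtype, name="lf_head_s")
            self.fusion = None
        else:
            self.fusion = FusionHead(f_width + s_width, 64, 2, rng, dtype, name="fusion")
            self.head_f = self.head_s = None

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[Param]:
        out: list[Param] = []
        if self.gcn is not None:
            out.extend(self.gcn.params())
        if self.cnn is not None:
            out.extend(self.cnn.params())
        for head in (self.fusion, self.head_f, self.head_s):
            if head is not None:
                out.extend(head.params())
        return out

    def named_params(self) -> dict[str, Param]:
        return {p.name: p for p in self.params()}

    def buffers(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        if self.cnn is not None:
            for block in self.cnn.blocks:
                if block.bn is not None:
                    out[f"{block.bn.gamma.name}.running_mean"] = block.bn.running_mean
                    out[f"{block.bn.gamma.name}.running_var"] = block.bn.running_var
        return out

    # -- data preparation ---------------------------------------------------
    def prepare_inputs(self, subjects: list[MultimodalSubject]) -> dict:
        """Precompute the fixed per-subject tensors (graphs, z-scored volumes)."""
        cfg = self.cfg
        dtype = np.dtype(cfg.dtype).type
        out: dict = {"labels": np.array([s.label for s in subjects], dtype=int)}
        out["ids"] = [s.subject_id for s in subjects]
        if cfg.uses_functional:
            a_list, x_list = [], []
            for s in subjects:
                if s.time_series is None:
                    raise DataError(
                        f"subject {s.subject_id!r} is missing the functional "
                        f"modality required by variant {cfg.variant!r}"
                    )
                b = pearson_fcn(s.time_series)
                if b.n_rois != self.n_rois:
                    raise DataError(
                        f"subject {s.subject_id!r} has {b.n_rois} ROIs, model "
                        f"expects {self.n_rois}"
                    )
                g = build_graph(b, cfg.graph)
                a_list.append(normalize_adjacency(g).values.astype(dtype))
                x_list.append(g.node_features.astype(dtype))
            out["A"] = np.stack(a_list)
            out["X"] = np.stack(x_list)
        if cfg.uses_structural:
            vols = []
            for s in subjects:
                if s.volume is None:
                    raise DataError(
                        f"subject {s.subject_id!r} is missing the structural "
                        f"modality required by variant {cfg.variant!r}"
                    )
                v = s.volume.values.astype(dtype)
                if cfg.cnn.zscore_input:
                    sd = v.std()
                    v = (v - v.mean()) / (sd if sd > 0 else 1.0)
                vols.append(v[..., None])  # trailing channel axis
            out["V"] = np.stack(vols)
        return out

    # -- forward / training step -------------------------------------------
    def _embeddings(self, data: dict, idx: np.ndarray, mode: str):
        g_f = g_s = None
        if self.gcn is not None:
            g_f = self.gcn.forward(data["A"][idx], data["X"][idx], mode)
        if self.cnn is not None:
            g_s = self.cnn.forward(data["V"][idx], mode)
        return g_f, g_s

    def forward_probs(self, data: dict, idx: np.ndarray, mode: str = "eval") -> np.ndarray:
        g_f, g_s = self._embeddings(data, idx, mode)
        if self.cfg.variant == "amni_lf":
            p_f = softmax(self.head_f.forward(g_f, mode))
            p_s = softmax(self.head_s.forward(g_s, mode))
            w = self.cfg.lf_weight
            return w * p_f + (1.0 - w) * p_s
        feats = [f for f in (g_f, g_s) if f is not None]
        fused = np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0]
        return softmax(self.fusion.forward(fused, mode))

    def train_step(self, data: dict, idx: np.ndarray) -> dict:
        """One forward/backward pass on a mini-batch; returns the loss terms.

        Gradients are accumulated on the parameters; the caller steps the
        optimizer.
        """
        cfg = self.cfg
        labels = data["labels"][idx]
        onehot = np.zeros((len(idx), 2))
        onehot[np.arange(len(idx)), labels] = 1.0
        g_f, g_s = self._embeddings(data, idx, "train")

        l_m = float("nan")
        d_f = d_s = None
        if g_f is not None and g_s is not None:
            l_m, dmf, dms = mmd_loss_with_grad(g_f, g_s, cfg.loss)
            lam = cfg.effective_lambda
            d_f = lam * dmf
            d_s = lam * dms

        if cfg.variant == "amni_lf":
            logits_f = self.head_f.forward(g_f, "train")
            logits_s = self.head_s.forward(g_s, "train")
            p_f, p_s = softmax(logits_f), softmax(logits_s)
            l_c = cross_entropy_from_probs(p_f[:, 1], labels) + cross_entropy_from_probs(
                p_s[:, 1], labels
            )
            dgf = self.head_f.backward((p_f - onehot) / len(idx)) + d_f
            dgs = self.head_s.backward((p_s - onehot) / len(idx)) + d_s
            self.gcn.backward(dgf.astype(g_f.dtype))
            self.cnn.backward(dgs.astype(g_s.dtype))
            probs = cfg.lf_weight * p_f + (1.0 - cfg.lf_weight) * p_s
        else:
            feats = [f for f in (g_f, g_s) if f is not None]
            fused = np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0]
            logits = self.fusion.forward(fused, "train")
            probs = softmax(logits)
            l_c = cross_entropy_from_probs(probs[:, 1], labels)
            dfused = self.fusion.backward((probs - onehot) / len(idx))
            offset = 0
            if g_f is not None:
                dgf = dfused[:, offset : offset + g_f.shape[1]]
                if d_f is not None:
                    dgf = dgf + d_f
                self.gcn.backward(dgf.astype(g_f.dtype))
                offset += g_f.shape[1]
            if g_s is not None:
                dgs = dfused[:, offset : offset + g_s.shape[1]]
                if d_s is not None:
                    dgs = dgs + d_s
                self.cnn.backward(dgs.astype(g_s.dtype))

        correct = int((probs.argmax(axis=1) == labels).sum())
        lam = cfg.effective_lambda
        total = l_c + (lam * l_m if np.isfinite(l_m) else 0.0)
        return {
            "l_c": float(l_c),
            "l_m": float(l_m),
            "l_total": float(total),
            "correct": correct,
            "n": len(idx),
        }

    # -- prediction ---------------------------------------------------------
    def predict(self, subjects: list[MultimodalSubject], batch_size: int = 32) -> list[Prediction]:
        data = self.prepare_inputs(subjects)
        n = len(subjects)
        preds: list[Prediction] = []
        for start in range(0, n, batch_size):
            idx = np.arange(start, min(start + batch_size, n))
            probs = self.forward_probs(data, idx, "eval")
            for local, i in enumerate(idx):
                p = probs[local].astype(float)
                p = p / p.sum()  # exact renormalization after float32 math
                preds.append(
                    Prediction(
                        subject_id=subjects[i].subject_id,
                        probabilities=(float(p[0]), float(p[1])),
                        predicted_label=int(p.argmax()),
                        true_label=subjects[i].label,
                    )
                )
        return preds


def _batches(perm: np.ndarray, batch_size: int) -> list[np.ndarray]:
    chunks = [perm[i : i + batch_size] for i in range(0, len(perm), batch_size)]
    # keep the last incomplete batch, but merge a singleton into its
    # predecessor so train-mode batch statistics stay defined
    if len(chunks) > 1 and len(chunks[-1]) < 2:
        chunks[-2] = np.concatenate([chunks[-2], chunks[-1]])
        chunks.pop()
    return chunks


def train_model(
    cohort: list[MultimodalSubject], cfg: TrainConfig
) -> tuple[AMNIModel, TrainHistory]:
    """Train one model on the cohort; deterministic given ``cfg.seed``."""
    if not cohort:
        raise DataError("cohort is empty")
    seeds = np.random.SeedSequence(cfg.seed).spawn(2)
    init_rng = np.random.default_rng(seeds[0])
    shuffle_rng = np.random.default_rng(seeds[1])
    n_rois = None
    if cfg.uses_functional:
        first = next((s for s in cohort if s.time_series is not None), None)
        if first is None:
            raise DataError("no subject carries the functional modality")
        n_rois = first.time_series.n_rois
    model = AMNIModel(cfg, n_rois=n_rois, rng=init_rng)
    data = model.prepare_inputs(cohort)
    params = model.params()
    optimizer = Adam(
        params, learning_rate=cfg.learning_rate, weight_decay=cfg.weight_decay
    )
    history = TrainHistory()
    n = len(cohort)
    lam = cfg.effective_lambda
    for epoch in range(cfg.epochs):
        perm = shuffle_rng.permutation(n)
        sums = {"l_c": 0.0, "l_m": 0.0, "l_total": 0.0, "correct": 0, "n": 0}
        saw_mmd = False
        for idx in _batches(perm, cfg.batch_size):
            optimizer.zero_grad()
            stats = model.train_step(data, idx)
            optimizer.step()
            w = stats["n"]
            sums["l_c"] += stats["l_c"] * w
            if np.isfinite(stats["l_m"]):
                sums["l_m"] += stats["l_m"] * w
                saw_mmd = True
            sums["l_total"] += stats["l_total"] * w
            sums["correct"] += stats["correct"]
            sums["n"] += w
        history.append(
            epoch=epoch,
            l_c=sums["l_c"] / sums["n"],
            l_m=(sums["l_m"] / sums["n"]) if saw_mmd else float("nan"),
            l_total=sums["l_total"] / sums["n"],
            train_acc=sums["correct"] / sums["n"],
            **{"lambda": lam},
        )
    return model, history


def predict(model: AMNIModel, subjects: list[MultimodalSubject]) -> list[Prediction]:
    """Eval-mode predictions: dropout off, batch-norm running moments."""
    return model.predict(subjects)


# -- checkpointing ----------------------------------------------------------

def _config_to_dict(cfg: TrainConfig) -> dict:
    d = asdict(cfg)
    d["cnn"]["fc_widths"] = list(d["cnn"]["fc_widths"])
    return d


def _config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    d["loss"] = LossConfig(**d["loss"])
    d["graph"] = GraphConfig(**d["graph"])
    d["gcn"] = GCNBranchConfig(**d["gcn"])
    cnn = dict(d["cnn"])
    cnn["fc_widths"] = tuple(cnn["fc_widths"])
    d["cnn"] = CNNBranchConfig(**cnn)
    return TrainConfig(**d)


def save_checkpoint(model: AMNIModel, path) -> None:
    """Serialize parameters, batch-norm buffers and the embedded config."""
    meta = {"config": _config_to_dict(model.cfg), "n_rois": model.n_rois}
    arrays = {f"param::{k}": p.value for k, p in model.named_params().items()}
    arrays.update({f"buffer::{k}": v for k, v in model.buffers().items()})
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> AMNIModel:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        cfg = _config_from_dict(meta["config"])
        model = AMNIModel(cfg, n_rois=meta["n_rois"], rng=np.random.default_rng(cfg.seed))
        named = model.named_params()
        for key in archive.files:
            if key.startswith("param::"):
                name = key[len("param::") :]
                if name not in named:
                    raise ContractViolationError(f"unexpected parameter {name!r} in checkpoint")
                named[name].value = archive[key].copy()
        buffers = model.buffers()
        for key in archive.files:
            if key.startswith("buffer::"):
                name = key[len("buffer::") :]
                if name in buffers:
                    buffers[name][...] = archive[key]
    return model
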