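"""End-to-end pipeline: manifest -> graphs/volumes -> training -> evaluation.

``run_pipeline`` executes the repeated-holdout protocol described by a run
configuration file and writes, into ``<output_dir>/run-<config hash>/``:

* ``metrics.tsv``   one row per repeat plus ``mean``/``std`` summary rows
* ``history.tsv``   per-epoch losses of every repeat (repeat column first)
* ``probabilities.tsv`` per test occurrence class-1 probabilities
* ``checkpoint.npz`` the model trained in the final repeat
* ``run.log``       config hash, seed, library versions, stage progress

The config hash in the directory name guarantees that re-running with a
changed configuration never overwrites an older run silently.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .cnn_branch import CNNBranchConfig
from .connectome import GraphConfig
from .errors import AmniError
from .evaluation import METRIC_NAMES, HoldoutResult, repeated_holdout, roc_points
from .fusion import LossConfig
from .gcn_branch import GCNBranchConfig
from .io import RunConfig, config_hash, load_cohort, load_run_config
from .training import TrainConfig, save_checkpoint, train_model

__all__ = ["train_config_from_run", "run_pipeline"]

logger = logging.getLogger("amni")


def train_config_from_run(cfg: RunConfig, seed: int | None = None) -> TrainConfig:
    """Assemble a TrainConfig from the nested run-config sections."""
    return TrainConfig(
        learning_rate=cfg.train.learning_rate,
        weight_decay=cfg.train.weight_decay,
        epochs=cfg.train.epochs,
        batch_size=cfg.train.batch_size,
        seed=cfg.train.seed if seed is None else seed,
        variant=cfg.train.variant,
        lf_weight=cfg.train.lf_weight,
        loss=LossConfig(
            lambda_=cfg.loss.lambda_,
            mmd_kernel=cfg.loss.mmd_kernel,
            mmd_squared=cfg.loss.mmd_squared,
        ),
        graph=GraphConfig(
            strategy=cfg.connectome.strategy,
            k=cfg.connectome.k,
            q=cfg.connectome.q,
            absolute=cfg.connectome.absolute,
        ),
        gcn=GCNBranchConfig(
            layer_widths=list(cfg.gcn.layer_widths),
            head_width=cfg.gcn.head_width,
            dropout_rate=cfg.gcn.dropout_rate,
        ),
        cnn=CNNBranchConfig(
            conv_channels=list(cfg.cnn.conv_channels),
            kernel_size=cfg.cnn.kernel_size,
            fc_widths=tuple(cfg.cnn.fc_widths),
            dropout_rate=cfg.cnn.dropout_rate,
            batch_norm=cfg.cnn.batch_norm,
            zscore_input=cfg.cnn.zscore_input,
        ),
        dtype=cfg.train.dtype,
    )


def _setup_logging(log_path: Path, quiet: bool) -> None:
    handlers: list[logging.Handler] = [logging.FileHandler(log_path)]
    if not quiet:
        handlers.append(logging.StreamHandler(sys.stderr))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def run_pipeline(config_path, quiet: bool = False) -> Path:
    """Run the configured protocol; returns the run output directory."""
    cfg = load_run_config(config_path)
    digest = config_hash(cfg)
    out_dir = Path(cfg.output_dir) / f"run-{digest}"
    out_dir.mkdir(parents=True, exist_ok=True)
    incomplete = out_dir / "INCOMPLETE"
    incomplete.touch()
    _setup_logging(out_dir / "run.log", quiet)
    logger.info("config %s (hash %s)", Path(config_path).name, digest)
    logger.info(
        "versions: numpy %s pandas %s python %s",
        np.__version__, pd.__version__, sys.version.split()[0],
    )
    try:
        manifest_path = Path(config_path).parent / cfg.manifest
        if not manifest_path.exists():
            manifest_path = Path(cfg.manifest)
        cohort = load_cohort(manifest_path)
        logger.info("stage=manifest loaded %d subjects", len(cohort))

        histories: list = []
        last_model: list = [None]

        def train_fn(train_subjects, seed):
            tc = train_config_from_run(cfg, seed=seed)
            model, history = train_model(train_subjects, tc)
            histories.append((seed, history))
            last_model[0] = model
            logger.info("stage=train seed=%d epochs=%d done", seed, tc.epochs)
            return model

        result = repeated_holdout(
            cohort,
            train_fn,
            n_repeats=cfg.eval.n_repeats,
            test_fraction=cfg.eval.test_fraction,
            base_seed=cfg.eval.base_seed,
            stratify=cfg.eval.stratify,
        )
        _write_outputs(out_dir, digest, cfg, result, histories)
        save_checkpoint(last_model[0], out_dir / "checkpoint.npz")
        logger.info("stage=done outputs in %s", out_dir)
        incomplete.unlink(missing_ok=True)
        return out_dir
    except AmniError as exc:
        logger.error("aborted: %s", exc)
        raise


def _write_outputs(
    out_dir: Path, digest: str, cfg: RunConfig, result: HoldoutResult, histories
) -> None:
    rows = []
    for i, record in enumerate(result.records):
        row = {"repeat": str(i), "config_hash": digest}
        row.update(record.as_dict())
        rows.append(row)
    rows.append({"repeat": "mean", "config_hash": digest, **result.mean})
    rows.append({"repeat": "std", "config_hash": digest, **result.std})
    pd.DataFrame(rows, columns=["repeat", "config_hash", *METRIC_NAMES]).to_csv(
        out_dir / "metrics.tsv", sep="\t", index=False
    )
    hist_rows = []
    for seed, history in histories:
        for record in history.records:
            hist_rows.append({"repeat_seed": seed, "config_hash": digest, **record})
    pd.DataFrame(hist_rows).to_csv(out_dir / "history.tsv", sep="\t", index=False)
    prob_rows = []
    for repeat, preds in enumerate(result.predictions):
        for p in preds:
            prob_rows.append(
                {
                    "repeat": repeat,
                    "subject_id": p.subject_id,
                    "p1": p.p1,
                    "predicted_label": p.predicted_label,
                    "true_label": p.true_label,
                    "config_hash": digest,
                }
            )
    pd.DataFrame(prob_rows).to_csv(out_dir / "probabilities.tsv", sep="\t", index=False)
    pooled = [p for preds in result.predictions for p in preds]
    try:
        points = roc_points(pooled)
        pd.DataFrame(points, columns=["fpr", "tpr", "threshold"]).to_csv(
            out_dir / "roc.tsv", sep="\t", index=False
        )
    except Exception:  # noqa: BLE001 - ROC undefined (single-class pool)
        logger.warning("ROC export skipped: pooled test labels are single-class")
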