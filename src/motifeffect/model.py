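"""Ensemble multi-task sequence-activity model.

The predictor F: sequence -> per-class activity probability is
approximated by an ensemble of small convolutional networks that differ
in their second convolutional layer (filter count and width); the
ensemble prediction is the arithmetic mean of member probabilities.
First-layer filters can be initialized from a motif database as
log-odds against a uniform background, so the first layer starts out
scanning for known transcription-factor motifs.

Two interfaces are provided. The functional layer
(:func:`build_ensemble`, :func:`train`, :class:`ModelEnsemble`) mirrors
the pipeline stages; :class:`SequenceActivityModel` /
:class:`SequenceActivityResults` wrap them in the fit/results idiom:
build the model from a :class:`~motifeffect.genomic_io.DatasetSplit`,
call :meth:`~SequenceActivityModel.fit`, and use the returned results
object for prediction, evaluation and pattern-effect interpretation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from . import __version__
from .genomic_io import DatasetSplit, LabeledDataset, one_hot
from .motifs import PWM
from .nn import ConvNet, fit_member

#: second-layer (n_filters, filter_width) per ensemble member; stand-in
#: defaults, fully configurable through ModelConfig
DEFAULT_SECOND_LAYERS = [(8, 5), (16, 9), (32, 13), (64, 17), (128, 21)]


@dataclass
class ModelConfig:
    """Hyperparameters of the ensemble.

    All values are configurable; the defaults are a CPU-friendly
    configuration of the standard architecture (64 motif-width filters
    in the shared first layer, five members with graded second layers,
    5 training epochs with early stopping on validation loss).
    """

    window_length: int = 100
    n_classes: int = 2
    class_names: list[str] = field(default_factory=lambda: ["class0", "class1"])
    ensemble_size: int = 5
    first_layer: tuple[int, int] = (64, 17)
    first_layer_init: str = "random"  # "random" | "motif_db"
    member_second_layers: list[tuple[int, int]] = field(
        default_factory=lambda: list(DEFAULT_SECOND_LAYERS)
    )
    epochs: int = 5
    early_stopping_patience: int = 2
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ensemble_size != len(self.member_second_layers):
            raise ValueError("ensemble_size must equal len(member_second_layers)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        widths = [self.first_layer[1]] + [w for _, w in self.member_second_layers]
        if self.window_length < max(widths):
            raise ValueError("window_length must be >= every filter width")
        if len(self.class_names) != self.n_classes:
            raise ValueError("class_names must have n_classes entries")


def motif_log_odds(pwm: PWM, filter_width: int, pseudocount: float = 0.01) -> np.ndarray:
    """PWM -> first-layer filter: log2((p + pseudocount)/0.25), centered.

    Columns outside the motif are zero, so they neither reward nor
    penalize flanking sequence.
    """
    L = len(pwm)
    if L > filter_width:
        raise ValueError(f"motif {pwm.name} (L={L}) longer than filter width {filter_width}")
    filt = np.zeros((filter_width, 4))
    off = (filter_width - L) // 2
    filt[off : off + L] = np.log2((pwm.matrix + pseudocount) / 0.25)
    return filt


class ModelEnsemble:
    """A (possibly trained) ensemble of :class:`~motifeffect.nn.ConvNet` members."""

    def __init__(self, members: list[ConvNet], config: ModelConfig):
        self.members = members
        self.config = config
        self.class_names = list(config.class_names)
        self.training_log: list[list[dict]] = []

    # -- prediction ----------------------------------------------------

    def encode(self, sequences: list[str]) -> np.ndarray:
        L = self.config.window_length
        for i, s in enumerate(sequences):
            if len(s) != L:
                raise ValueError(f"sequence {i} has length {len(s)}, expected {L}")
        return np.stack([one_hot(s) for s in sequences])

    def predict(self, sequences: list[str] | np.ndarray) -> np.ndarray:
        """Mean member probability for each sequence and class, (M, C)."""
        x = sequences if isinstance(sequences, np.ndarray) else self.encode(sequences)
        return np.mean([m.predict(x) for m in self.members], axis=0)

    def input_gradient(self, x: np.ndarray, dlogits: np.ndarray) -> np.ndarray:
        """Member-averaged gradient of an objective with respect to the input."""
        return np.mean(
            [m.input_gradient(x, dlogits) for m in self.members], axis=0
        )

    # -- persistence ---------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        with open(d / "config.json", "w") as fh:
            json.dump(cfg, fh, indent=1)
        with open(d / "MANIFEST", "w") as fh:
            fh.write(f"package\tmotifeffect {__version__}\n")
            fh.write(f"format_version\t1\n")
            fh.write(f"seed\t{self.config.seed}\n")
            fh.write(f"ensemble_size\t{len(self.members)}\n")
        for i, m in enumerate(self.members):
            np.savez(
                d / f"member_{i}.npz",
                **{f"p{j}": p for j, p in enumerate(m.params)},
            )
        with open(d / "training_log.json", "w") as fh:
            json.dump(self.training_log, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "ModelEnsemble":
        d = Path(directory)
        if not (d / "config.json").exists():
            raise FileNotFoundError(f"{d}: no saved ensemble (config.json missing)")
        manifest = dict(
            line.rstrip("\n").split("\t", 1)
            for line in open(d / "MANIFEST")
            if "\t" in line
        )
        if manifest.get("format_version") != "1":
            raise ValueError(
                f"{d}: saved-model format version {manifest.get('format_version')!r} "
                "not supported by this package version"
            )
        with open(d / "config.json") as fh:
            cfg = json.load(fh)
        cfg["first_layer"] = tuple(cfg["first_layer"])
        cfg["member_second_layers"] = [tuple(t) for t in cfg["member_second_layers"]]
        config = ModelConfig(**cfg)
        # saved weights overwrite the init below, so build with random init
        # and restore the recorded init mode afterwards
        init_mode, config.first_layer_init = config.first_layer_init, "random"
        ens = build_ensemble(config)
        config.first_layer_init = init_mode
        for i, m in enumerate(ens.members):
            with np.load(d / f"member_{i}.npz") as npz:
                m.set_weights([npz[f"p{j}"] for j in range(len(m.params))])
        log_path = d / "training_log.json"
        if log_path.exists():
            with open(log_path) as fh:
                ens.training_log = json.load(fh)
        return ens


def build_ensemble(config: ModelConfig, motif_db: list[PWM] | None = None) -> ModelEnsemble:
    """Construct an untrained ensemble.

    With ``first_layer_init="motif_db"`` the first ``min(n_filters,
    len(motif_db))`` filters of each member are initialized from motif
    log-odds; remaining filters stay random.
    """
    if config.first_layer_init == "motif_db" and not motif_db:
        raise ValueError("first_layer_init='motif_db' requires a non-empty motif_db")
    members = []
    for i, second in enumerate(config.member_second_layers):
        rng = np.random.default_rng(config.seed + i)
        net = ConvNet(
            window_length=config.window_length,
            n_classes=config.n_classes,
            conv1_shape=config.first_layer,
            conv2_shape=second,
            rng=rng,
            learning_rate=config.learning_rate,
        )
        if config.first_layer_init == "motif_db":
            n_filters, width = config.first_layer
            for k, pwm in enumerate(motif_db[:n_filters]):
                net.W1[k] = motif_log_odds(pwm, width)
        members.append(net)
    return ModelEnsemble(members, config)


def train(ensemble: ModelEnsemble, split: DatasetSplit) -> ModelEnsemble:
    """Train each member independently on identical data.

    Member ``i`` derives its randomness from ``config.seed + i``; with a
    fixed seed and single-threaded numpy the training log is
    reproducible. Early stopping monitors validation loss and restores
    the best-epoch weights.
    """
    cfg = ensemble.config
    if len(split.train) == 0:
        raise ValueError("training set is empty")
    if split.train.labels.shape[1] != cfg.n_classes:
        raise ValueError("label width does not match n_classes")
    for ci, cname in enumerate(ensemble.class_names):
        if split.train.labels[:, ci].sum() == 0:
            warnings.warn(
                f"class {cname!r} has no positive training examples", stacklevel=2
            )
    tx = split.train.encoded()
    ty = split.train.labels.astype(float)
    vx = split.validation.encoded() if len(split.validation) else None
    vy = split.validation.labels.astype(float) if len(split.validation) else None
    ensemble.training_log = []
    for i, member in enumerate(ensemble.members):
        rng = np.random.default_rng(cfg.seed + i)
        log = fit_member(
            member, tx, ty, vx, vy,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            patience=cfg.early_stopping_patience,
            rng=rng,
        )
        ensemble.training_log.append(log)
    return ensemble


def evaluate(ensemble: ModelEnsemble, dataset: LabeledDataset) -> pd.DataFrame:
    """Per-class AUROC, average precision and accuracy at threshold 0.5.

    A class with only one label value gets NaN metrics rather than an
    exception; the final ``mean`` row averages over defined classes.
    """
    probs = ensemble.predict(dataset.sequences)
    rows = []
    for ci, cname in enumerate(ensemble.class_names):
        y = dataset.labels[:, ci]
        p = probs[:, ci]
        if len(np.unique(y)) < 2:
            auroc = auprc = np.nan
        else:
            auroc = roc_auc_score(y, p)
            auprc = average_precision_score(y, p)
        acc = float(((p >= 0.5).astype(int) == y).mean()) if len(y) else np.nan
        rows.append({"class": cname, "auroc": auroc, "auprc": auprc, "accuracy": acc})
    table = pd.DataFrame(rows)
    mean_row = table[["auroc", "auprc", "accuracy"]].mean()
    table.loc[len(table)] = {"class": "mean", **mean_row.to_dict()}
    return table


# ---------------------------------------------------------------------------
# fit/results facade
# ---------------------------------------------------------------------------


class SequenceActivityModel:
    """Multi-task sequence-activity model specification.

    Parameters
    ----------
    split : DatasetSplit or LabeledDataset
        Training data. A bare dataset is treated as train-only (no
        early stopping).
    config : ModelConfig, optional
        Architecture and training hyperparameters; class count and
        names are taken from the data.
    motif_db : list of PWM, optional
        When given, first-layer filters are motif-initialized.
    """

    def __init__(
        self,
        split: DatasetSplit | LabeledDataset,
        config: ModelConfig | None = None,
        motif_db: list[PWM] | None = None,
    ):
        if isinstance(split, LabeledDataset):
            empty = LabeledDataset(
                [], np.zeros((0, split.n_classes)), list(split.class_names),
                window_length=split.window_length,
            )
            split = DatasetSplit(train=split, validation=empty, test=empty)
        self.split = split
        data = split.train
        if config is None:
            config = ModelConfig(
                window_length=data.window_length,
                n_classes=data.n_classes,
                class_names=list(data.class_names),
            )
        else:
            config.window_length = data.window_length
            config.n_classes = data.n_classes
            config.class_names = list(data.class_names)
        if motif_db:
            config.first_layer_init = "motif_db"
        self.config = config
        self.motif_db = motif_db

    @classmethod
    def from_bed(
        cls,
        bed_paths: dict[str, str],
        genome_fasta,
        window_length: int = 100,
        validation_chroms: tuple[str, ...] = ("chr18",),
        test_chroms: tuple[str, ...] = ("chr19",),
        negative_ratio: float = 1.0,
        seed: int = 0,
        config: ModelConfig | None = None,
        motif_db: list[PWM] | None = None,
    ) -> "SequenceActivityModel":
        """Build from per-class BED files and a genome FASTA.

        The genome is tiled into fixed windows, windows are labeled by
        the >50% union-overlap rule, all-zero windows are subsampled to
        ``negative_ratio`` times the positive count, and the data are
        split by held-out chromosomes (chr18 validation, chr19 test by
        default).
        """
        from pyfaidx import Fasta

        from .genomic_io import (
            extract_sequences, label_windows, make_windows, read_bed,
            split_by_chromosome,
        )

        genome = Fasta(str(genome_fasta))
        sizes = {name: len(genome[name]) for name in genome.keys()}
        windows = make_windows(sizes, window_length)
        peak_sets = {cls_name: read_bed(p) for cls_name, p in bed_paths.items()}
        labels = label_windows(windows, peak_sets)
        pos = labels.any(axis=1)
        neg_idx = np.flatnonzero(~pos)
        n_keep = min(len(neg_idx), int(round(negative_ratio * int(pos.sum()))))
        rng = np.random.default_rng(seed)
        keep = np.sort(
            np.concatenate([np.flatnonzero(pos), rng.choice(neg_idx, n_keep, replace=False)])
        )
        windows = [windows[i] for i in keep]
        labels = labels[keep]
        seqs = extract_sequences(windows, genome_fasta)
        dataset = LabeledDataset(
            sequences=seqs, labels=labels, class_names=list(bed_paths),
            provenance=windows, window_length=window_length,
        )
        split = split_by_chromosome(dataset, list(validation_chroms), list(test_chroms))
        return cls(split, config=config, motif_db=motif_db)

    def fit(self) -> "SequenceActivityResults":
        ensemble = build_ensemble(self.config, self.motif_db)
        train(ensemble, self.split)
        metrics = (
            evaluate(ensemble, self.split.test) if len(self.split.test) else None
        )
        return SequenceActivityResults(self, ensemble, metrics)


class SequenceActivityResults:
    """Fitted model: trained ensemble, metrics, and interpretation methods.

    Pattern-effect interpretation (EPE, DEPE, screens, spacing scans,
    per-base differential importance) hangs off this object; see
    :mod:`motifeffect.pattern_effect` for the functional forms.
    """

    def __init__(self, model: SequenceActivityModel, ensemble: ModelEnsemble,
                 metrics: pd.DataFrame | None = None):
        self.model = model
        self.ensemble = ensemble
        self.metrics = metrics
        self.class_names = ensemble.class_names

    # -- prediction / evaluation ---------------------------------------

    def predict(self, sequences: list[str]) -> np.ndarray:
        return self.ensemble.predict(sequences)

    def evaluate(self, dataset: LabeledDataset) -> pd.DataFrame:
        return evaluate(self.ensemble, dataset)

    # -- interpretation -------------------------------------------------

    def epe(self, backgrounds, pattern, class_name: str, **kw):
        from .pattern_effect import epe
        return epe(self.ensemble, backgrounds, pattern, class_name, **kw)

    def depe(self, backgrounds, pattern, class1: str, class2: str, **kw):
        from .pattern_effect import depe
        return depe(self.ensemble, backgrounds, pattern, class1, class2, **kw)

    def gia_effect(self, backgrounds, pattern, class_name: str, **kw):
        from .pattern_effect import gia_effect
        return gia_effect(self.ensemble, backgrounds, pattern, class_name, **kw)

    def motif_screen(self, backgrounds, motif_db, classes=None, class_pairs=None, **kw):
        from .pattern_effect import motif_screen
        return motif_screen(
            self.ensemble, backgrounds, motif_db, classes=classes,
            class_pairs=class_pairs, **kw,
        )

    def spacing_scan(self, backgrounds, motif_a, motif_b, spacings, class_name: str, **kw):
        from .pattern_effect import spacing_scan
        return spacing_scan(
            self.ensemble, backgrounds, motif_a, motif_b, spacings, class_name, **kw
        )

    def differential_saliency(self, sequence: str, class1: str, class2: str) -> np.ndarray:
        from .pattern_effect import differential_saliency
        return differential_saliency(self.ensemble, sequence, class1, class2)

    # -- reporting ------------------------------------------------------

    def summary(self) -> str:
        cfg = self.ensemble.config
        lines = [
            "Sequence activity model (convolutional ensemble)",
            "=" * 48,
            f"classes:        {', '.join(self.class_names)}",
            f"window length:  {cfg.window_length} bp",
            f"ensemble:       {cfg.ensemble_size} members, "
            f"first layer {cfg.first_layer[0]}x{cfg.first_layer[1]} "
            f"({cfg.first_layer_init} init)",
            f"second layers:  {cfg.member_second_layers}",
            f"training:       <= {cfg.epochs} epochs, batch {cfg.batch_size}, "
            f"patience {cfg.early_stopping_patience}, seed {cfg.seed}",
            f"train/val/test: {len(self.model.split.train)}/"
            f"{len(self.model.split.validation)}/{len(self.model.split.test)}",
        ]
        if self.metrics is not None:
            lines += ["", "Test metrics", "-" * 48,
                      self.metrics.to_string(index=False, float_format="%.4f")]
        return "\n".join(lines)

    def save(self, directory) -> None:
        self.ensemble.save(directory)
        if self.metrics is not None:
            self.metrics.to_csv(Path(directory) / "metrics.tsv", sep="\t", index=False)
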