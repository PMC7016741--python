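"""The predictive model zoo: sequence CNNs (basic, attention, ResNet),
epigenomics CNNs (basic two/one-branch, ResNet with/without fc head), the
two-layer FNN, the combined model, and the gradient-boosting baseline.

Every builder is pure: the same arguments always produce the same
architecture graph and parameter count. The padding / pooling / bias /
normalization-accounting convention resolved for each architecture is
recorded in ``model.metadata`` (key ``conventions``), together with which
parameter-count convention (``"total"`` including normalization statistics,
or ``"trainable"``) the published summary of that architecture follows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier

from .nn import (AttentionGate, AvgPool1D, BatchNorm, BranchedModel,
                 ChannelMean, Conv1D, Dense, Dropout, Flatten,
                 GlobalAvgPool1D, MaxPool1D, ReLU, ResidualBlock, Sequential,
                 SigmoidOutput, SoftmaxOutput, VectorModel, count_parameters,
                 reported_parameter_count)


@dataclass
class TrainingConfig:
    """Per-model optimizer settings (batch size, Adam learning rate, L2
    weight decay on convolution kernels, dropout rates)."""

    batch_size: int = 200
    learning_rate: float = 1e-3
    conv_l2: float = 1e-5
    dropout1: float = 0.0
    dropout2: Optional[float] = None

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.learning_rate:
            raise ValueError("learning_rate must be positive")


#: Published training settings for each model family.
TRAINING_CONFIGS = {
    "sequence_basic": TrainingConfig(64, 1e-5, 1e-6, 0.2, 0.8),
    "sequence_attention": TrainingConfig(64, 1e-5, 2e-5, 0.2, None),
    "sequence_resnet": TrainingConfig(200, 1e-5, 2e-5, 0.5, None),
    "epi_basic": TrainingConfig(200, 1e-6, 1e-5, 0.3, 0.6),
    "epi_resnet": TrainingConfig(64, 1e-3, 1e-5, 0.3, 0.6),
    "fnn": TrainingConfig(200, 1e-6, 1e-5, 0.7, None),
    "combined": TrainingConfig(200, 1e-5, 1e-6, 0.3, 0.5),
}


# ---------------------------------------------------------------------------
# sequence models
# ---------------------------------------------------------------------------

def build_sequence_basic_cnn(filters: int = 300, kernel: int = 40,
                             pool: int = 20, dense_units: int = 800,
                             input_lengths: Tuple[int, int] = (3000, 2000),
                             dropout1: float = 0.2, dropout2: float = 0.8,
                             seed: int = 0) -> BranchedModel:
    """Two-branch simple CNN on full-length one-hot sequences.

    One same-padded convolution (no bias; batch-normalized) and max-pool
    per branch, flatten/concatenate, an unbiased dense layer with batch
    norm, and a two-unit softmax output.
    """
    rng = np.random.default_rng(seed)

    def branch():
        return Sequential([
            Conv1D(filters, kernel, padding="same", use_bias=False),
            BatchNorm(), ReLU(), MaxPool1D(pool),
        ])

    head = Sequential([
        Dropout(dropout1),
        Dense(dense_units, use_bias=False), BatchNorm(), ReLU(),
        Dropout(dropout2),
    ])
    model = BranchedModel(
        "sequence_basic", branch(), branch(), head, SoftmaxOutput(use_bias=True),
        input_shapes=((input_lengths[0], 4), (input_lengths[1], 4)),
        merge="flatten_concat",
        metadata={
            "count_convention": "trainable",
            "has_dense_penultimate": True,
            "conventions": "same-padded conv, valid pooling, unbiased "
                           "conv/dense, BN after conv and dense, "
                           "2-unit softmax output",
        })
    return model.build(rng)


def build_sequence_attention_cnn(filters: int = 256, kernel: int = 8,
                                 pool: int = 4,
                                 input_lengths: Tuple[int, int] = (600, 400),
                                 dropout1: float = 0.2,
                                 seed: int = 0) -> BranchedModel:
    """Attention CNN on centrally cropped sequences (600/400 bp).

    Valid convolution + pool per branch; the head alternates unbiased dense
    layers with same-width multiplicative attention gates, ending in a
    128-d dense layer and a two-unit softmax output.
    """
    if tuple(input_lengths) != (600, 400):
        raise ValueError("attention CNN expects centrally cropped inputs "
                         f"(600, 400); got {input_lengths}")
    rng = np.random.default_rng(seed)

    def branch():
        return Sequential([
            Conv1D(filters, kernel, padding="valid", use_bias=False),
            BatchNorm(), ReLU(), MaxPool1D(pool),
        ])

    head = Sequential([
        Dropout(dropout1),
        Dense(800, use_bias=False), BatchNorm(), ReLU(),
        AttentionGate(800, use_bias=False, batchnorm=True),
        Dense(256, use_bias=False), ReLU(),
        AttentionGate(256, use_bias=False, batchnorm=True),
        Dense(128, use_bias=False), BatchNorm(), ReLU(),
    ])
    model = BranchedModel(
        "sequence_attention", branch(), branch(), head,
        SoftmaxOutput(use_bias=True),
        input_shapes=((600, 4), (400, 4)),
        merge="flatten_concat",
        metadata={
            "count_convention": "trainable",
            "has_dense_penultimate": True,
            "conventions": "valid conv/pool, unbiased conv/dense/attention, "
                           "BN after conv, fc800, both gates and fc128 "
                           "(not fc256), 2-unit softmax output",
        })
    return model.build(rng)


def build_sequence_resnet(filters: int = 64, kernel: int = 8,
                          blocks_per_stage: int = 3,
                          input_lengths: Tuple[int, int] = (600, 400),
                          dropout1: float = 0.5, seed: int = 0) -> BranchedModel:
    """Sequence ResNet without a fully connected head.

    A single trunk over the length-concatenated central crops: a stem
    convolution with max-pool 10, then three stages of residual blocks
    (64 filters, kernel 8), the later two stages downsampling by stride 3
    through 1x1 projection shortcuts. The head averages the channel maps
    (an 11-long feature for the published geometry) into the sigmoid
    output. He-normal initialization throughout.
    """
    rng = np.random.default_rng(seed)
    trunk = [
        Conv1D(filters, kernel, padding="valid", use_bias=False, init="he_normal"),
        BatchNorm(), ReLU(), MaxPool1D(10),
    ]
    for stage, stride in enumerate((1, 3, 3)):
        for b in range(blocks_per_stage):
            shortcut = "projection" if (b == 0 and stride > 1) else "identity"
            trunk.append(ResidualBlock(filters, kernel,
                                       stride=stride if b == 0 else 1,
                                       shortcut=shortcut))
    trunk.append(ChannelMean())
    head = Sequential([Dropout(dropout1)])
    model = BranchedModel(
        "sequence_resnet", Sequential(trunk), None, head,
        SigmoidOutput(use_bias=True),
        input_shapes=((input_lengths[0], 4), (input_lengths[1], 4)),
        merge="length_concat",
        metadata={
            "count_convention": "total",
            "has_dense_penultimate": False,
            "conventions": "single trunk on length-concatenated crops, "
                           "3 stages x 3 blocks, stride-3 projection "
                           "downsampling, channel-mean head (11-d), "
                           "He-normal init",
        })
    return model.build(rng)


# ---------------------------------------------------------------------------
# epigenomics models
# ---------------------------------------------------------------------------

def build_epi_basic_cnn(two_branch: bool = True, filters: int = 256,
                        n_tracks: int = 22,
                        input_windows: Tuple[int, int] = (296, 196),
                        dense_units: int = 512, dropout1: float = 0.3,
                        dropout2: float = 0.6, seed: int = 0) -> BranchedModel:
    """Basic epigenomics CNN on CNN-format features.

    Two-branch: three valid convolution (kernel 16) + max-pool-2 stages per
    branch. One-branch: the enhancer and promoter windows are concatenated
    row-wise (296+196=492) and a single stack with a doubled receptive
    field (kernel 32, same padding, max-pool 3 stride 2) processes the
    result. Both end in a 512-d dense layer and sigmoid output.
    """
    rng = np.random.default_rng(seed)
    we, wp = input_windows
    if two_branch:
        def branch():
            layers = []
            for _ in range(3):
                layers += [Conv1D(filters, 16, padding="valid", use_bias=False),
                           BatchNorm(), ReLU(), MaxPool1D(2)]
            return Sequential(layers)

        head = Sequential([
            Dropout(dropout1),
            Dense(dense_units, use_bias=True), ReLU(),
            Dropout(dropout2),
        ])
        model = BranchedModel(
            "epi_basic_2branch", branch(), branch(), head,
            SigmoidOutput(use_bias=True),
            input_shapes=((we, n_tracks), (wp, n_tracks)),
            merge="flatten_concat",
            metadata={
                "count_convention": "total",
                "has_dense_penultimate": True,
                "conventions": "valid conv k16 / pool2, unbiased conv, BN "
                               "after conv only, biased dense, sigmoid",
            })
        return model.build(rng)

    layers = []
    for _ in range(3):
        layers += [Conv1D(filters, 32, padding="same", use_bias=False),
                   BatchNorm(), ReLU(), MaxPool1D(3, stride=2)]
    head = Sequential([
        Dropout(dropout1),
        Dense(dense_units, use_bias=False), BatchNorm(), ReLU(),
        Dropout(dropout2),
    ])
    model = BranchedModel(
        "epi_basic_1branch", Sequential(layers), None, head,
        SigmoidOutput(use_bias=True),
        input_shapes=((we, n_tracks), (wp, n_tracks)),
        merge="length_concat",
        metadata={
            "count_convention": "total",
            "has_dense_penultimate": True,
            "conventions": "row-concatenated 492-window input, same-padded "
                           "conv k32 / pool3 stride2, unbiased conv and "
                           "dense, BN after conv and dense, sigmoid",
        })
    return model.build(rng)


def _epi_stem(stride: int) -> list:
    return [Conv1D(64, 7, stride=stride, padding="valid", use_bias=False,
                   init="he_normal"),
            BatchNorm(), ReLU(), MaxPool1D(3, stride=3)]


def build_epi_resnet(with_fc_head: bool = True, n_tracks: int = 22,
                     input_windows: Tuple[int, int] = (296, 196),
                     dropout1: float = 0.3, dropout2: float = 0.6,
                     seed: int = 0) -> BranchedModel:
    """Epigenomics ResNet on CNN-format features.

    Both variants use per-branch stems (kernel 7; stride 2 for the enhancer
    and 1 for the promoter, equalizing temporal scale) with max-pool 3.
    The with-fc variant has two stages of two 256-filter blocks per branch
    (both stages downsampling via projection shortcuts), average-pool 2,
    a flattened concatenation into an 800-d dense layer and sigmoid. The
    without-fc variant has four stages of two 128-filter blocks per branch
    (zero-padding entry shortcut; two stride-2 projection stages without
    shortcut normalization), concatenates the branch maps along the length
    axis, and reduces by global average pooling straight to the sigmoid.
    """
    rng = np.random.default_rng(seed)
    we, wp = input_windows

    if with_fc_head:
        def branch(stem_stride):
            layers = list(_epi_stem(stem_stride))
            for stage in range(2):
                layers.append(ResidualBlock(256, 3, stride=2,
                                            shortcut="projection"))
                layers.append(ResidualBlock(256, 3, shortcut="identity"))
            layers.append(AvgPool1D(2))
            return Sequential(layers)

        head = Sequential([
            Dropout(dropout1),
            Dense(800, use_bias=True), ReLU(),
            Dropout(dropout2),
        ])
        model = BranchedModel(
            "epi_resnet_fc", branch(2), branch(1), head,
            SigmoidOutput(use_bias=True),
            input_shapes=((we, n_tracks), (wp, n_tracks)),
            merge="flatten_concat",
            metadata={
                "count_convention": "total",
                "has_dense_penultimate": True,
                "conventions": "valid k7 stems (stride 2/1), pool3 stride3, "
                               "2 stages x 2 blocks of 256 filters with "
                               "stride-2 projection shortcuts, avgpool2, "
                               "800-d fc, sigmoid",
            })
        return model.build(rng)

    def branch(stem_stride):
        layers = list(_epi_stem(stem_stride))
        layers.append(ResidualBlock(128, 3, shortcut="zeropad"))
        layers.append(ResidualBlock(128, 3, shortcut="identity"))
        layers.append(ResidualBlock(128, 3, shortcut="identity"))
        layers.append(ResidualBlock(128, 3, shortcut="identity"))
        for _ in range(2):
            layers.append(ResidualBlock(128, 3, stride=2,
                                        shortcut="projection",
                                        projection_bn=False))
            layers.append(ResidualBlock(128, 3, shortcut="identity"))
        return Sequential(layers)

    head = Sequential([GlobalAvgPool1D(), Dropout(dropout1)])
    model = BranchedModel(
        "epi_resnet_nofc", branch(2), branch(1), head,
        SigmoidOutput(use_bias=True),
        input_shapes=((we, n_tracks), (wp, n_tracks)),
        merge="branch_length_concat",
        metadata={
            "count_convention": "total",
            "has_dense_penultimate": False,
            "conventions": "valid k7 stems (stride 2/1), pool3 stride3, "
                           "4 stages x 2 blocks of 128 filters, zero-pad "
                           "entry shortcut, two unnormalized stride-2 "
                           "projection stages, length-concat + global "
                           "average pool, sigmoid",
        })
    return model.build(rng)


# ---------------------------------------------------------------------------
# FNN, combined model, gradient boosting
# ---------------------------------------------------------------------------

def build_fnn(input_dim: int = 44, hidden: Tuple[int, int] = (512, 256),
              dropout: float = 0.7, seed: int = 0) -> VectorModel:
    """Two-layer feed-forward network with batch normalization and one
    dropout, for TargetFinder-format (44-d) features."""
    if input_dim < 1:
        raise ValueError("input_dim must be positive")
    rng = np.random.default_rng(seed)
    body = Sequential([
        Dense(hidden[0]), BatchNorm(), ReLU(), Dropout(dropout),
        Dense(hidden[1]), BatchNorm(), ReLU(),
    ])
    model = VectorModel("fnn", body, SigmoidOutput(use_bias=True), input_dim,
                        metadata={"count_convention": "total",
                                  "has_dense_penultimate": True})
    return model.build(rng)


class CombinedModel:
    """Sequential combination scheme: high-level features from trained
    sequence and epigenomics feeder models are concatenated and passed
    through one or two trainable hidden layers into a sigmoid output. The
    feeder models are frozen; only the head is trained."""

    def __init__(self, seq_model, epi_model, n_hidden_layers: int = 1,
                 hidden: Tuple[int, int] = (256, 64),
                 dropout: float = 0.3, seed: int = 0):
        if n_hidden_layers not in (1, 2):
            raise ValueError("n_hidden_layers must be 1 or 2")
        for m in (seq_model, epi_model):
            if not m.metadata.get("has_dense_penultimate", False):
                raise ValueError(
                    f"feeder model {m.name!r} has no penultimate dense layer")
        self.seq_model = seq_model
        self.epi_model = epi_model
        self.seq_model.frozen = True
        self.epi_model.frozen = True
        seq_w = _penultimate_width(seq_model)
        epi_w = _penultimate_width(epi_model)
        self.input_dim = seq_w + epi_w
        layers = [Dense(hidden[0]), BatchNorm(), ReLU(), Dropout(dropout)]
        if n_hidden_layers == 2:
            layers += [Dense(hidden[1]), BatchNorm(), ReLU()]
        self.head = VectorModel(
            "combined_head", Sequential(layers), SigmoidOutput(), self.input_dim,
            metadata={"count_convention": "total",
                      "has_dense_penultimate": True})
        self.head.build(np.random.default_rng(seed))
        self.name = "combined"
        self.metadata = {"count_convention": "total"}

    def extract_features(self, seq_inputs, epi_inputs) -> np.ndarray:
        fs = self.seq_model.penultimate_features(*seq_inputs)
        fe = self.epi_model.penultimate_features(*epi_inputs)
        return np.concatenate([fs, fe], axis=1)

    def predict_proba(self, seq_inputs, epi_inputs) -> np.ndarray:
        return self.head.predict_proba(self.extract_features(seq_inputs,
                                                             epi_inputs))


def _penultimate_width(model) -> int:
    stack = model.head if hasattr(model, "head") else model.body
    for lyr in reversed(stack.layers):
        if isinstance(lyr, Dense):
            return lyr.units
    raise ValueError(f"model {model.name!r} head has no dense layer")


def build_combined_model(seq_model, epi_model, n_hidden_layers: int = 1,
                         seed: int = 0) -> CombinedModel:
    return CombinedModel(seq_model, epi_model, n_hidden_layers, seed=seed)


class GradientBoostingBaseline:
    """Gradient-boosted trees on TargetFinder-format features, with the
    number of trees chosen on the validation split by AUROC."""

    def __init__(self, n_trees_grid: Sequence[int] = (50, 100, 200, 500),
                 learning_rate: float = 0.1, max_depth: int = 5,
                 seed: int = 0):
        if len(n_trees_grid) == 0:
            raise ValueError("n_trees grid must be non-empty")
        self.n_trees_grid = tuple(sorted(n_trees_grid))
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.seed = seed
        self.selected_n_trees: Optional[int] = None
        self._clf: Optional[GradientBoostingClassifier] = None
        self.name = "gradient_boosting"
        self.metadata = {"count_convention": "total"}

    def fit(self, X_train, y_train, X_val=None, y_val=None):
        from sklearn.metrics import roc_auc_score
        clf = GradientBoostingClassifier(
            n_estimators=max(self.n_trees_grid),
            learning_rate=self.learning_rate, max_depth=self.max_depth,
            random_state=self.seed)
        clf.fit(X_train, y_train)
        if X_val is not None and len(np.unique(y_val)) == 2:
            best, best_auc = None, -np.inf
            scores = np.zeros(len(y_val))
            staged = clf.staged_decision_function(X_val)
            for i, s in enumerate(staged, start=1):
                if i in self.n_trees_grid:
                    auc = roc_auc_score(y_val, s.ravel())
                    if auc > best_auc:
                        best, best_auc = i, auc
            self.selected_n_trees = best
        else:
            self.selected_n_trees = max(self.n_trees_grid)
        clf.set_params(n_estimators=self.selected_n_trees)
        clf.fit(X_train, y_train)
        self._clf = clf
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self._clf is None:
            raise RuntimeError("fit() must be called first")
        return self._clf.predict_proba(X)[:, 1]


def build_gradient_boosting(n_trees_grid: Sequence[int] = (50, 100, 200, 500),
                            **kwargs) -> GradientBoostingBaseline:
    return GradientBoostingBaseline(n_trees_grid, **kwargs)


# ---------------------------------------------------------------------------
# registry / description
# ---------------------------------------------------------------------------

ZOO_BUILDERS = {
    "sequence_basic": build_sequence_basic_cnn,
    "sequence_attention": build_sequence_attention_cnn,
    "sequence_resnet": build_sequence_resnet,
    "epi_basic_2branch": lambda **kw: build_epi_basic_cnn(True, **kw),
    "epi_basic_1branch": lambda **kw: build_epi_basic_cnn(False, **kw),
    "epi_resnet_fc": lambda **kw: build_epi_resnet(True, **kw),
    "epi_resnet_nofc": lambda **kw: build_epi_resnet(False, **kw),
    "fnn": build_fnn,
}


def describe(name: str) -> str:
    """Layer table plus both parameter counts for a zoo model."""
    model = ZOO_BUILDERS[name]()
    pc = count_parameters(model)
    lines = [f"model: {name}",
             f"conventions: {model.metadata.get('conventions', '-')}",
             f"total params (incl. normalization statistics): {pc.total:,}",
             f"trainable params: {pc.trainable:,}",
             f"reported convention: {model.metadata['count_convention']} "
             f"-> {reported_parameter_count(model):,}"]
    return "\n".join(lines)
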