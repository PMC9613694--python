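"""The LLT feature-space transform: law bank fitting and test-set projection.

Fitting computes the linear law of every (training instance, channel) series,
giving ``tau * m`` unit eigenvectors.  Per channel ``j`` they are collected as
columns of a bank matrix ``V^j`` (shape ``l x tau``), partitioned by the class
of the source instance.

Transforming a test instance computes its per-channel Gram matrices
``S^{te,j}`` and the products ``S^{te,j} V^j`` (shape ``l x tau``).  Columns
arising from laws of the instance's true class are near-annihilated (close to
the zero vector), so the selector ``f`` picks, per class, the column of
minimal variance — the best-annihilating law of that class.  Aggregating each
selected column by its mean (``g1``, absolute value by default) and variance
(``g2``) yields ``m * c`` scalar features per aggregator per test instance.

Only the test set is transformed; the training set's role is to supply the
bank.  Classifiers are then cross-validated on the transformed test features.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_laws import embed, gram, law_of_series
from .exceptions import ConfigurationError, DataError
from .panel import LabeledPanel

__all__ = [
    "LawBank",
    "SelectedColumns",
    "fit",
    "project",
    "select_min_variance",
    "aggregate",
    "transform",
    "save_bank",
    "load_bank",
    "feature_names",
]

_BANK_FORMAT_VERSION = 1


@dataclass
class LawBank:
    """Per-channel matrices of training laws, partitioned by class.

    Attributes
    ----------
    order:
        Embedding order ``l`` the laws were extracted at.
    channel_banks:
        ``channel_banks[j]`` is the ``l x tau`` matrix ``V^j`` whose columns
        are the unit-norm laws of the ``tau`` training instances, channel
        ``j``; column order is training-instance order and is identical across
        channels.
    column_classes:
        Length-``tau`` integer array: class (``1..c``) of the training
        instance behind each column.
    residuals:
        ``tau x m`` array of the residual eigenvalues, kept for diagnostics.
    """

    order: int
    channel_banks: list[np.ndarray]
    column_classes: np.ndarray
    residuals: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        return len(self.channel_banks)

    @property
    def n_train(self) -> int:
        return int(self.column_classes.shape[0])

    @property
    def n_classes(self) -> int:
        return int(self.column_classes.max())

    def class_columns(self, cls: int) -> np.ndarray:
        """0-based column indices of the given class, ascending."""
        return np.flatnonzero(self.column_classes == cls)


@dataclass
class SelectedColumns:
    """Output of the selector ``f`` for one test instance.

    ``columns[j][cls]`` is the minimal-variance column (length ``l``) of
    ``S^{te,j} V^j`` among the columns of class ``cls``; ``variances`` holds
    the corresponding sample variances.
    """

    columns: list[dict[int, np.ndarray]]
    variances: list[dict[int, float]]


def fit(train: LabeledPanel, order: int) -> LawBank:
    """Fit a law bank: one linear law per (training instance, channel).

    Produces ``tau * m`` laws in total, grouped per channel into ``V^j``.
    Every training series must have length at least ``order + 1``.
    """
    tau, m = train.n_instances, train.n_channels
    for i in range(tau):
        for j in range(m):
            if train.series[i][j].shape[0] < order + 1:
                raise DataError(
                    f"training instance {train.instance_ids[i]}, channel "
                    f"{j + 1}: series length {train.series[i][j].shape[0]} "
                    f"is too short for embedding order {order}"
                )
    banks = [np.empty((order, tau)) for _ in range(m)]
    residuals = np.empty((tau, m))
    for i in range(tau):
        for j in range(m):
            law = law_of_series(train.series[i][j], order)
            banks[j][:, i] = law.coefficients
            residuals[i, j] = law.residual
    return LawBank(
        order=order,
        channel_banks=banks,
        column_classes=train.labels.copy(),
        residuals=residuals,
    )


def project(test_series, bank_channel: np.ndarray, order: int) -> np.ndarray:
    """Product ``S^{te,j} V^j`` probing one test channel against one bank.

    ``S^{te,j}`` is the Gram matrix of the test series at the bank's embedding
    order; the product inherits the ``l x tau`` shape of ``V^j``.
    """
    V = np.asarray(bank_channel, dtype=float)
    if V.ndim != 2:
        raise ConfigurationError(f"bank channel must be 2-D, got shape {V.shape}")
    if V.shape[0] != order:
        raise ConfigurationError(
            f"bank channel has {V.shape[0]} rows but embedding order is {order}"
        )
    S = gram(embed(test_series, order))
    return S @ V


def select_min_variance(product: np.ndarray, column_classes) -> SelectedColumns:
    """Selector ``f``: per class, the product column of minimal variance.

    Variance is the sample variance (denominator ``l - 1``) over the ``l``
    entries of the column; ties are broken by lowest column index.  Returns a
    single-channel :class:`SelectedColumns`.
    """
    product = np.asarray(product, dtype=float)
    column_classes = np.asarray(column_classes, dtype=int)
    if product.shape[1] != column_classes.shape[0]:
        raise ConfigurationError(
            f"product has {product.shape[1]} columns but class map has "
            f"{column_classes.shape[0]} entries"
        )
    cols: dict[int, np.ndarray] = {}
    variances: dict[int, float] = {}
    for cls in range(1, int(column_classes.max()) + 1):
        members = np.flatnonzero(column_classes == cls)
        if members.size == 0:
            raise ConfigurationError(f"class {cls} has no columns in the bank")
        v = product[:, members].var(axis=0, ddof=1)
        best = members[int(np.argmin(v))]  # argmin keeps the lowest index on ties
        cols[cls] = product[:, best].copy()
        variances[cls] = float(product[:, best].var(ddof=1))
    return SelectedColumns(columns=[cols], variances=[variances])


def aggregate(selected: SelectedColumns, mode: str, absolute_mean: bool = True) -> np.ndarray:
    """Aggregators ``g1``/``g2``: reduce each selected column to one scalar.

    ``mode="mean"`` returns the arithmetic mean of each column (its absolute
    value when ``absolute_mean`` is on, the default); ``mode="variance"``
    returns the sample variance.  Output is ordered channel-major then class:
    ``(j=1,c=1), (j=1,c=2), ..., (j=m,c=C)``.
    """
    if mode not in ("mean", "variance"):
        raise ConfigurationError(f"mode must be 'mean' or 'variance', got {mode!r}")
    out: list[float] = []
    for chan in selected.columns:
        for cls in sorted(chan):
            o = chan[cls]
            if mode == "mean":
                val = float(o.mean())
                if absolute_mean:
                    val = abs(val)
            else:
                val = float(o.var(ddof=1))
            out.append(val)
    return np.asarray(out)


def feature_names(m: int, c: int, prefix: str) -> list[str]:
    """Channel-major-then-class feature names, e.g. ``mean_ch1_cls1``."""
    return [f"{prefix}_ch{j}_cls{cls}" for j in range(1, m + 1) for cls in range(1, c + 1)]


def _select_instance(panel: LabeledPanel, i: int, bank: LawBank) -> SelectedColumns:
    cols: list[dict[int, np.ndarray]] = []
    variances: list[dict[int, float]] = []
    for j in range(bank.n_channels):
        prod = project(panel.series[i][j], bank.channel_banks[j], bank.order)
        sel = select_min_variance(prod, bank.column_classes)
        cols.append(sel.columns[0])
        variances.append(sel.variances[0])
    return SelectedColumns(columns=cols, variances=variances)


def transform(
    test: LabeledPanel,
    bank: LawBank,
    absolute_mean: bool = True,
    return_selected: bool = False,
):
    """LLT-transform a test panel against a fitted law bank.

    Returns ``(means, variances)``: two feature tables of shape
    ``(n - tau) x (m * c)``, indexed by test instance id, each carrying the
    true label in a trailing ``label`` column.  With ``return_selected`` a
    third, stacked raw table of shape ``((n - tau) * l) x (m * c)`` holding the
    selected columns themselves is appended.
    """
    if test.n_channels != bank.n_channels:
        raise ConfigurationError(
            f"test panel has {test.n_channels} channels but the bank was fitted "
            f"on {bank.n_channels}"
        )
    m, c, l = bank.n_channels, bank.n_classes, bank.order
    mean_rows, var_rows, raw_blocks = [], [], []
    for i in range(test.n_instances):
        sel = _select_instance(test, i, bank)
        mean_rows.append(aggregate(sel, "mean", absolute_mean=absolute_mean))
        var_rows.append(aggregate(sel, "variance"))
        if return_selected:
            block = np.column_stack(
                [sel.columns[j][cls] for j in range(m) for cls in range(1, c + 1)]
            )
            raw_blocks.append(block)

    idx = pd.Index(test.instance_ids, name="instance")
    means = pd.DataFrame(np.vstack(mean_rows), index=idx, columns=feature_names(m, c, "mean"))
    variances = pd.DataFrame(np.vstack(var_rows), index=idx, columns=feature_names(m, c, "var"))
    means["label"] = test.labels
    variances["label"] = test.labels
    if not return_selected:
        return means, variances
    raw_idx = pd.MultiIndex.from_product(
        [test.instance_ids, range(1, l + 1)], names=["instance", "row"]
    )
    raw = pd.DataFrame(np.vstack(raw_blocks), index=raw_idx, columns=feature_names(m, c, "o"))
    return means, variances, raw


# ---------------------------------------------------------------------------
# Law-bank serialization: one zip archive holding JSON metadata and the V^j
# arrays as .npy members.  Round-trips are bit-exact (float64 preserved).
# ---------------------------------------------------------------------------

def save_bank(bank: LawBank, path) -> None:
    """Write a law bank to a single archive (JSON metadata + arrays)."""
    meta = {
        "format_version": _BANK_FORMAT_VERSION,
        "order": bank.order,
        "n_channels": bank.n_channels,
        "n_classes": bank.n_classes,
        "n_train": bank.n_train,
        "column_classes": bank.column_classes.tolist(),
        "feature_ordering": "channel-major then class",
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=2))
        for j, V in enumerate(bank.channel_banks):
            buf = _io.BytesIO()
            np.save(buf, V, allow_pickle=False)
            zf.writestr(f"V_{j + 1}.npy", buf.getvalue())
        if bank.residuals is not None:
            buf = _io.BytesIO()
            np.save(buf, bank.residuals, allow_pickle=False)
            zf.writestr("residuals.npy", buf.getvalue())


def load_bank(path) -> LawBank:
    """Read a law bank written by :func:`save_bank`."""
    with zipfile.ZipFile(path, "r") as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta.get("format_version") != _BANK_FORMAT_VERSION:
            raise DataError(
                f"unsupported law-bank format version {meta.get('format_version')}"
            )
        banks = [
            np.load(_io.BytesIO(zf.read(f"V_{j + 1}.npy")), allow_pickle=False)
            for j in range(meta["n_channels"])
        ]
        residuals = None
        if "residuals.npy" in zf.namelist():
            residuals = np.load(_io.BytesIO(zf.read("residuals.npy")), allow_pickle=False)
    return LawBank(
        order=int(meta["order"]),
        channel_banks=banks,
        column_classes=np.asarray(meta["column_classes"], dtype=int),
        residuals=residuals,
    )
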