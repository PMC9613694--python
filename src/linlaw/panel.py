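"""Labelled multichannel panel container.

A panel holds ``n`` instances, each with the same number ``m`` of scalar
channels; instance ``i``, channel ``j`` is one time series.  Series lengths may
differ across instances (longitudinal scaling produces exactly that) but are
identical across the channels of one instance in all formats this package
writes.  Labels are integers ``1..c`` with every class nonempty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError

__all__ = ["LabeledPanel"]


@dataclass
class LabeledPanel:
    """Instances x channels collection of time series with class labels.

    Attributes
    ----------
    series:
        ``series[i][j]`` is the 1-D float array for instance ``i`` (0-based),
        channel ``j`` (0-based).
    labels:
        Integer array of length ``n`` with values in ``1..c``.
    instance_ids:
        Optional external identifiers, defaults to ``1..n``.
    """

    series: list[list[np.ndarray]]
    labels: np.ndarray
    instance_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.series)
        if n == 0:
            raise DataError("panel must contain at least one instance")
        if self.labels.shape != (n,):
            raise DataError(
                f"labels length {self.labels.shape} does not match {n} instances"
            )
        m = len(self.series[0])
        if m == 0:
            raise DataError("instances must have at least one channel")
        for i, chans in enumerate(self.series):
            if len(chans) != m:
                raise DataError(
                    f"instance {i + 1} has {len(chans)} channels, expected {m}"
                )
            self.series[i] = [np.asarray(s, dtype=float) for s in chans]
            for j, s in enumerate(self.series[i]):
                if s.ndim != 1 or s.shape[0] < 2:
                    raise DataError(
                        f"instance {i + 1}, channel {j + 1}: series must be 1-D "
                        f"with length >= 2"
                    )
                if not np.all(np.isfinite(s)):
                    raise DataError(
                        f"instance {i + 1}, channel {j + 1}: non-finite values"
                    )
        if self.labels.min() < 1:
            raise DataError("labels must be integers >= 1")
        c = int(self.labels.max())
        present = set(self.labels.tolist())
        missing = sorted(set(range(1, c + 1)) - present)
        if missing:
            raise DataError(f"classes {missing} are empty (labels must cover 1..c)")
        if not self.instance_ids:
            self.instance_ids = [str(i + 1) for i in range(n)]
        elif len(self.instance_ids) != n:
            raise DataError("instance_ids length does not match instance count")

    @property
    def n_instances(self) -> int:
        return len(self.series)

    @property
    def n_channels(self) -> int:
        return len(self.series[0])

    @property
    def n_classes(self) -> int:
        return int(self.labels.max())

    def subset(self, indices) -> "LabeledPanel":
        """Panel restricted to the given 0-based instance indices (in order)."""
        indices = list(indices)
        return LabeledPanel(
            series=[self.series[i] for i in indices],
            labels=self.labels[indices],
            instance_ids=[self.instance_ids[i] for i in indices],
        )

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))
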