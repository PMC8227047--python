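"""Binary network construction and group-consensus backbones.

A weighted streamline-count matrix W is reduced to a binary adjacency U by an
absolute threshold set to a fraction (default 0.1%, the DSI Studio default) of
the maximum streamline count in that matrix — discarding spurious,
noise-driven connections.  A group backbone U_B keeps an edge when it appears
in at least a consensus fraction (default 75%) of subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from strucnet.io import ValidationError, WeightedConnectome


@dataclass
class BinaryNetwork:
    """A 0/1 symmetric adjacency matrix with zero diagonal."""

    adjacency: np.ndarray
    node_labels: list[str]
    subject_id: str = ""
    scheme: str = ""
    scale: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError(f"adjacency must be square, got {a.shape}")
        if not np.isin(a, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0 or 1")
        if (a != a.T).any():
            raise ValidationError("adjacency must be symmetric")
        if a.size and np.diag(a).any():
            raise ValidationError("adjacency diagonal must be zero")
        self.adjacency = a.astype(np.int8)
        self.node_labels = list(self.node_labels)
        if len(self.node_labels) != a.shape[0]:
            raise ValidationError("node_labels length does not match adjacency")
        if self.scale == 0:
            self.scale = len(self.node_labels)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)


@dataclass
class BackboneNetwork(BinaryNetwork):
    """Group-consensus binary network with per-edge consensus fractions.

    ``adjacency(i, j) = 1`` iff ``consensus_fraction(i, j) >= consensus_threshold``.
    """

    consensus_fraction: np.ndarray = None
    n_subjects: int = 0
    consensus_threshold: float = 0.75

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.consensus_fraction is None:
            raise ValidationError("backbone requires a consensus_fraction matrix")
        f = np.asarray(self.consensus_fraction, dtype=float)
        if f.shape != self.adjacency.shape:
            raise ValidationError("consensus_fraction shape mismatch")
        if (f != f.T).any() or (f.size and np.diag(f).any()):
            raise ValidationError("consensus_fraction must be symmetric, zero diagonal")
        expected = (f >= self.consensus_threshold).astype(np.int8)
        np.fill_diagonal(expected, 0)
        if (expected != self.adjacency).any():
            raise ValidationError(
                "adjacency inconsistent with consensus_fraction and threshold"
            )
        self.consensus_fraction = f


def threshold_to_binary(
    conn: WeightedConnectome, fraction: float = 0.001
) -> BinaryNetwork:
    """Binarize a streamline-count matrix at ``fraction`` of its maximum count.

    The threshold is ``t = fraction * max(W)``; edge (i, j) is kept when
    ``w_ij >= t`` (an edge exactly at threshold survives, keeping the rule
    stable under integer counts).  Tags are propagated.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    w_max = conn.matrix.max() if conn.matrix.size else 0.0
    if w_max <= 0:
        raise ValidationError(
            "all-zero matrix: threshold relative to the maximum is undefined"
        )
    t = fraction * w_max
    adjacency = (conn.matrix >= t).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    return BinaryNetwork(
        adjacency,
        conn.node_labels,
        subject_id=conn.subject_id,
        scheme=conn.scheme,
        scale=conn.scale,
    )


def build_backbone(
    group: Sequence[BinaryNetwork], consensus: float = 0.75
) -> BackboneNetwork:
    """Build the group-consensus backbone from per-subject binary networks.

    ``consensus_fraction(i, j)`` is the share of subjects whose network
    contains edge (i, j); the backbone keeps edges with fraction >=
    ``consensus`` ("at least 75% of the subjects": 3 of 4 qualifies at 0.75).
    """
    group = list(group)
    if len(group) < 2:
        raise ValidationError("backbone requires at least 2 subject networks")
    if not 0 < consensus <= 1:
        raise ValueError(f"consensus must be in (0, 1], got {consensus}")
    labels = group[0].node_labels
    for net in group[1:]:
        if net.node_labels != labels:
            raise ValidationError(
                f"node labels of subject {net.subject_id!r} differ from the "
                f"group's; reorder before building a backbone"
            )
    stack = np.stack([net.adjacency for net in group])
    frac = stack.mean(axis=0)
    adjacency = (frac >= consensus).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    first = group[0]
    return BackboneNetwork(
        adjacency,
        labels,
        subject_id="group",
        scheme=first.scheme,
        scale=first.scale,
        consensus_fraction=frac,
        n_subjects=len(group),
        consensus_threshold=consensus,
    )
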