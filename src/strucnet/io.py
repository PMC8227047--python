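"""Reading and writing connectivity matrices, ensembles, and reports.

All interchange is plain delimited text (TSV) or JSON so that fixtures are
human-readable and diffable.  Node identity is carried by label strings, not
matrix position: loaders reorder rows and columns into a group's canonical
label order before any cross-subject operation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: absolute tolerance for symmetry of streamline-count matrices
SYMMETRY_ATOL = 1e-9


class ValidationError(ValueError):
    """A connectivity matrix violates a structural invariant."""


@dataclass
class WeightedConnectome:
    """A symmetric nonnegative streamline-count matrix with node labels.

    Parameters
    ----------
    matrix
        Square ``(N, N)`` array; entry ``w_ij`` is the number of reconstructed
        streamlines connecting parcels ``i`` and ``j``.  Symmetric within
        ``SYMMETRY_ATOL``, zero diagonal, all entries nonnegative.
    node_labels
        ``N`` unique parcel names.
    subject_id, scheme, scale
        Provenance tags: subject identifier, acquisition (sampling) scheme
        tag such as ``"b1000"``, and parcellation scale (number of parcels).
    """

    matrix: np.ndarray
    node_labels: list[str]
    subject_id: str = ""
    scheme: str = ""
    scale: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.node_labels = list(self.node_labels)
        if self.scale == 0:
            self.scale = len(self.node_labels)
        self.validate()

    def validate(self) -> None:
        m = self.matrix
        labels = self.node_labels
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError(f"matrix must be square, got shape {m.shape}")
        if len(labels) != m.shape[0]:
            raise ValidationError(
                f"{len(labels)} node labels for a {m.shape[0]}-node matrix"
            )
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate node labels: {dupes}")
        asym = np.abs(m - m.T)
        if asym.size and asym.max() > SYMMETRY_ATOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValidationError(
                f"matrix asymmetric at ({labels[i]}, {labels[j]}): "
                f"{m[i, j]} vs {m[j, i]}"
            )
        if m.size and m.min() < 0:
            i, j = np.unravel_index(np.argmin(m), m.shape)
            raise ValidationError(
                f"negative weight {m[i, j]} at ({labels[i]}, {labels[j]})"
            )
        if m.size and np.abs(np.diag(m)).max() > 0:
            i = int(np.argmax(np.abs(np.diag(m))))
            raise ValidationError(f"nonzero diagonal at node {labels[i]}")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def reordered(self, labels: Sequence[str]) -> "WeightedConnectome":
        """Return a copy with rows/columns permuted into ``labels`` order."""
        if set(labels) != set(self.node_labels):
            raise ValidationError("label sets differ; cannot reorder")
        idx = [self.node_labels.index(l) for l in labels]
        return WeightedConnectome(
            self.matrix[np.ix_(idx, idx)],
            list(labels),
            self.subject_id,
            self.scheme,
            self.scale,
        )


@dataclass
class EnsembleManifest:
    """Index of per-subject connectome files grouped by (scheme, scale)."""

    entries: list[dict] = field(default_factory=list)
    root: Path = Path(".")

    @classmethod
    def from_json(cls, path: str | Path) -> "EnsembleManifest":
        path = Path(path)
        with open(path) as fh:
            entries = json.load(fh)
        if not isinstance(entries, list):
            raise ValidationError("manifest must be a JSON array")
        for e in entries:
            missing = {"subject_id", "scheme", "scale", "path"} - set(e)
            if missing:
                raise ValidationError(f"manifest entry missing keys {missing}: {e}")
        return cls(entries=entries, root=path.parent)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.entries, fh, indent=1, sort_keys=True)
            fh.write("\n")


def read_matrix(
    path: str | Path,
    format: str = "matrix_tsv",
    node_labels: Sequence[str] | None = None,
    **tags,
) -> WeightedConnectome:
    """Read a connectome from a delimited text file.

    ``matrix_tsv``: header row of node labels, each following row a label plus
    N weights.  ``edge_list_tsv``: columns ``node_a, node_b, weight``, one row
    per unordered pair; the node set is ``node_labels`` if given, otherwise
    inferred from the listed endpoints (sorted); absent edges are weight 0.
    """
    path = Path(path)
    if format == "matrix_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = [str(c) for c in df.columns]
        row_labels = [str(r) for r in df.index]
        if row_labels != labels:
            raise ValidationError(
                f"{path}: row labels do not match column labels"
            )
        matrix = df.to_numpy(dtype=float)
    elif format == "edge_list_tsv":
        df = pd.read_csv(path, sep="\t")
        required = {"node_a", "node_b", "weight"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"{path}: edge list needs columns {sorted(required)}"
            )
        if node_labels is None:
            labels = sorted(
                set(df["node_a"].astype(str)) | set(df["node_b"].astype(str))
            )
        else:
            labels = [str(l) for l in node_labels]
        index = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        matrix = np.zeros((n, n))
        seen: dict[tuple[int, int], float] = {}
        for a, b, w in zip(
            df["node_a"].astype(str), df["node_b"].astype(str), df["weight"]
        ):
            if a not in index or b not in index:
                raise ValidationError(f"{path}: edge endpoint not in node set")
            i, j = index[a], index[b]
            key = (min(i, j), max(i, j))
            if key in seen and seen[key] != w:
                raise ValidationError(
                    f"{path}: conflicting weights for pair ({a}, {b})"
                )
            seen[key] = w
            matrix[i, j] = w
            matrix[j, i] = w
        np.fill_diagonal(matrix, 0.0)
    else:
        raise ValueError(f"unknown format {format!r}")
    return WeightedConnectome(matrix, labels, **tags)


def write_matrix(conn: WeightedConnectome, path: str | Path) -> None:
    """Write a connectome as matrix TSV (integer formatting where exact)."""
    m = conn.matrix
    as_int = np.allclose(m, np.round(m), atol=SYMMETRY_ATOL)
    df = pd.DataFrame(
        m.astype(np.int64) if as_int else m,
        index=conn.node_labels,
        columns=conn.node_labels,
    )
    df.to_csv(path, sep="\t", index_label="node")


def load_ensemble(
    manifest: EnsembleManifest,
) -> dict[tuple[str, int], list[WeightedConnectome]]:
    """Load every connectome in a manifest, grouped by (scheme, scale).

    Within a group all subjects must carry an identical node-label set; each
    matrix is reordered into the group's canonical (first subject's) order.
    """
    groups: dict[tuple[str, int], list[WeightedConnectome]] = {}
    if not manifest.entries:
        logger.warning("empty manifest: no connectomes loaded")
        return groups
    for entry in manifest.entries:
        p = Path(entry["path"])
        if not p.is_absolute():
            p = manifest.root / p
        if not p.exists():
            raise FileNotFoundError(
                f"manifest entry for subject {entry['subject_id']}: "
                f"missing file {p}"
            )
        conn = read_matrix(
            p,
            format=entry.get("format", "matrix_tsv"),
            subject_id=str(entry["subject_id"]),
            scheme=str(entry["scheme"]),
            scale=int(entry["scale"]),
        )
        key = (conn.scheme, conn.scale)
        if key in groups:
            canonical = groups[key][0].node_labels
            if set(conn.node_labels) != set(canonical):
                raise ValidationError(
                    f"group {key}: subject {conn.subject_id} node labels "
                    f"differ from the group's"
                )
            if conn.node_labels != canonical:
                conn = conn.reordered(canonical)
        groups.setdefault(key, []).append(conn)
    return groups


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return [None if (isinstance(x, float) and np.isnan(x)) else x
                for x in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_report(
    metric_records: pd.DataFrame,
    rich_club_results: dict,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the analysis report: metrics.tsv, richclub_summary.tsv, results.json.

    ``metric_records`` has one row per analyzed network (all MetricRecord
    fields plus tags).  ``rich_club_results`` maps ``(scheme, scale)`` to a
    :class:`~strucnet.richclub.RichClubResult`; the summary TSV mirrors the
    k-level / RC% / FC% / LC% layout, one row per group.  ``results.json``
    carries the full per-k curves.  A p-value of exactly zero is printed as
    ``<1/m`` in the summary (the permutation resolution limit).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "metrics": out_dir / "metrics.tsv",
        "richclub": out_dir / "richclub_summary.tsv",
        "json": out_dir / "results.json",
    }

    metric_records.to_csv(paths["metrics"], sep="\t", index=False)

    rows = []
    curves = {}
    for (scheme, scale), res in sorted(rich_club_results.items()):
        m = res.m
        range_p = (
            f"<{1 / m:g}" if res.range_p == 0 else f"{res.range_p:g}"
        )
        rc, fc, lc = res.proportions
        rows.append(
            {
                "scheme": scheme,
                "scale": scale,
                "k_level": res.k_level,
                "RC": round(rc, 4),
                "FC": round(fc, 4),
                "LC": round(lc, 4),
                "significant_k_min": res.significant_k_range[0]
                if res.significant_k_range
                else "",
                "significant_k_max": res.significant_k_range[1]
                if res.significant_k_range
                else "",
                "range_p": range_p,
            }
        )
        curves[f"{scheme}/{scale}"] = res.to_dict()
    pd.DataFrame(
        rows,
        columns=[
            "scheme", "scale", "k_level", "RC", "FC", "LC",
            "significant_k_min", "significant_k_max", "range_p",
        ],
    ).to_csv(paths["richclub"], sep="\t", index=False)

    with open(paths["json"], "w") as fh:
        json.dump(curves, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
    return paths
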