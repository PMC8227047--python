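"""Synthetic multi-subject, multi-scheme, multiscale connectome ensembles.

Emulates the statistical structure of streamline-count connectome cohorts —
sparse symmetric nonnegative-integer-weighted networks with planted hub
(rich-club) and modular organization, subject-to-subject edge noise, and a
series of nodal scales — so that every pipeline stage can be exercised and
validated against known ground truth without any imaging data.

The default ensemble mirrors a cohort of 35 subjects scanned under eight
sampling schemes (four single-shell, four multishell) at six parcellation
scales (68, 200, 400, 600, 800, 1000 nodes).  Scheme differences are
modeled minimally as a small probability bonus for long-range edges (large
ring distance in an index embedding), qualitatively emulating the longer
streamlines recovered by schemes that include high b-value shells; this is
a statistical stand-in, not a diffusion model.  Integer edge weights are
drawn from a negative binomial, an overdispersed count distribution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np

from strucnet.construct import BinaryNetwork
from strucnet.io import EnsembleManifest, WeightedConnectome, write_matrix

_MODELS = ("er", "watts_strogatz", "planted_richclub", "planted_modular")


@dataclass
class GeneratorSpec:
    """Parameters of one base-network generator.

    ``er``: Erdos-Renyi with expected average degree ``d``.
    ``watts_strogatz``: ring lattice with ``ws_neighbors`` neighbors, each
    edge rewired with probability ``ws_rewire``.
    ``planted_richclub``: the first ``ceil(hub_fraction * N)`` nodes are
    hubs; hub-hub pairs connect with ``p_rr``, hub-periphery with ``p_rf``,
    periphery-periphery with ``p_ll``.
    ``planted_modular``: ``n_modules`` equal blocks, within-block density
    ``p_in``, between-block ``p_out``.
    """

    n_nodes: int = 200
    model: str = "planted_richclub"
    d: float = 10.0
    ws_neighbors: int = 10
    ws_rewire: float = 0.1
    hub_fraction: float = 0.20
    p_rr: float = 0.9
    p_rf: float = 0.3
    p_ll: float = 0.1
    n_modules: int = 4
    p_in: float = 0.3
    p_out: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_nodes < 4:
            raise ValueError(f"need N >= 4 nodes, got {self.n_nodes}")
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {_MODELS}")
        for name in ("p_rr", "p_rf", "p_ll", "p_in", "p_out", "ws_rewire"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.hub_fraction < 1:
            raise ValueError(
                f"hub_fraction must be in (0, 1), got {self.hub_fraction}"
            )


def _labels(n: int) -> list[str]:
    return [f"n{i:04d}" for i in range(n)]


def _pair_bernoulli(prob: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Symmetric 0/1 matrix with upper-triangle pair probabilities ``prob``."""
    n = prob.shape[0]
    draw = rng.random((n, n))
    upper = np.triu(draw < prob, k=1)
    return (upper | upper.T).astype(np.int8)


def generate_network(spec: GeneratorSpec) -> BinaryNetwork:
    """Draw one base binary network; deterministic given ``spec.seed``."""
    spec.validate()
    n = spec.n_nodes
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    if spec.model == "er":
        p = spec.d / (n - 1)
        if not 0 <= p <= 1:
            raise ValueError(f"expected degree {spec.d} infeasible for N={n}")
        adj = _pair_bernoulli(np.full((n, n), p), rng)
    elif spec.model == "watts_strogatz":
        g = nx.watts_strogatz_graph(
            n, spec.ws_neighbors, spec.ws_rewire,
            seed=int(rng.integers(2**31)),
        )
        adj = nx.to_numpy_array(g, nodelist=range(n), dtype=np.int8)
    elif spec.model == "planted_richclub":
        n_hubs = math.ceil(spec.hub_fraction * n)
        is_hub = np.zeros(n, dtype=bool)
        is_hub[:n_hubs] = True
        prob = np.where(
            np.outer(is_hub, is_hub),
            spec.p_rr,
            np.where(np.outer(is_hub, is_hub) | np.outer(~is_hub, ~is_hub),
                     spec.p_ll, spec.p_rf),
        )
        adj = _pair_bernoulli(prob, rng)
    else:  # planted_modular
        membership = np.arange(n) % spec.n_modules
        prob = np.where(
            membership[:, None] == membership[None, :], spec.p_in, spec.p_out
        )
        adj = _pair_bernoulli(prob, rng)
    np.fill_diagonal(adj, 0)
    return BinaryNetwork(adj, _labels(n))


def planted_truth(spec: GeneratorSpec) -> dict:
    """Ground-truth structure implied by a generator spec (for validation)."""
    n = spec.n_nodes
    if spec.model == "planted_richclub":
        n_hubs = math.ceil(spec.hub_fraction * n)
        return {"hubs": _labels(n)[:n_hubs]}
    if spec.model == "planted_modular":
        return {"modules": (np.arange(n) % spec.n_modules).tolist()}
    return {}


@dataclass
class SchemeEffect:
    """Acquisition-scheme modifier: extra probability of long-range edges."""

    tag: str
    long_range_p: float = 0.0


def default_schemes() -> list[SchemeEffect]:
    """Eight scheme tags, four single-shell and four multishell, with a
    long-range edge bonus growing with the highest b-value included."""
    return [
        SchemeEffect("b1000", 0.000),
        SchemeEffect("b3000", 0.002),
        SchemeEffect("b5000", 0.004),
        SchemeEffect("b10000", 0.006),
        SchemeEffect("b1000_3000", 0.003),
        SchemeEffect("b1000_3000_5000", 0.005),
        SchemeEffect("b3000_5000_10000", 0.008),
        SchemeEffect("b1000_3000_5000_10000", 0.010),
    ]


@dataclass
class EnsembleSpec:
    """A full synthetic cohort: base model x subjects x schemes x scales.

    ``edge_noise`` is the per-subject probability of flipping each base dyad
    (edge <-> non-edge).  Present edges receive integer streamline counts
    ``1 + NegativeBinomial`` with mean ``weight_mean`` and size parameter
    ``weight_dispersion`` (variance mu + mu^2/size).  The base network is
    regenerated at each scale with the same structural proportions.
    """

    base: GeneratorSpec = field(default_factory=GeneratorSpec)
    n_subjects: int = 35
    edge_noise: float = 0.05
    weight_mean: float = 50.0
    weight_dispersion: float = 0.5
    schemes: list[SchemeEffect] = field(default_factory=default_schemes)
    scales: list[int] = field(
        default_factory=lambda: [68, 200, 400, 600, 800, 1000]
    )
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.edge_noise < 0.5:
            raise ValueError(f"edge_noise must be in [0, 0.5), got {self.edge_noise}")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.weight_mean < 1:
            raise ValueError("weight_mean must be >= 1")
        if not self.schemes or not self.scales:
            raise ValueError("need at least one scheme and one scale")
        tags = [s.tag for s in self.schemes]
        if len(set(tags)) != len(tags):
            raise ValueError("scheme tags must be unique")


@dataclass
class EnsembleData:
    """In-memory synthetic cohort plus ground truth (and manifest if written)."""

    groups: dict[tuple[str, int], list[WeightedConnectome]]
    truth: dict
    manifest: EnsembleManifest | None = None


def _subject_rng(seed: int, scale: int, scheme_idx: int, subject: int):
    ss = np.random.SeedSequence([seed, scale, scheme_idx, subject])
    return np.random.Generator(np.random.PCG64(ss))


def generate_ensemble(
    spec: EnsembleSpec, out_dir: str | Path | None = None
) -> EnsembleData:
    """Generate the cohort; optionally write matrix TSVs, manifest, truth.json.

    Per (scale): one base network from the generator spec.  Per (subject,
    scheme): flip each dyad with ``edge_noise``, add long-range edges (ring
    distance > N/4) with the scheme's bonus probability, then draw integer
    weights for the present edges.  Each (subject, scheme, scale) cell has
    its own keyed random substream, so generating a subset of the design
    reproduces exactly the matrices of the full design.
    """
    spec.validate()
    groups: dict[tuple[str, int], list[WeightedConnectome]] = {}
    truth: dict = {"scales": {}}
    entries = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for scale in spec.scales:
        base_spec = replace(spec.base, n_nodes=scale, seed=spec.seed + scale)
        base = generate_network(base_spec)
        truth["scales"][str(scale)] = {
            "base_edges": int(base.n_edges),
            **planted_truth(base_spec),
        }
        n = scale
        idx = np.arange(n)
        ring_dist = np.abs(idx[:, None] - idx[None, :])
        ring_dist = np.minimum(ring_dist, n - ring_dist)
        long_range = ring_dist > n / 4
        for scheme_idx, scheme in enumerate(spec.schemes):
            group: list[WeightedConnectome] = []
            for subject in range(spec.n_subjects):
                rng = _subject_rng(spec.seed, scale, scheme_idx, subject)
                flip = _pair_bernoulli(
                    np.full((n, n), spec.edge_noise), rng
                ).astype(bool)
                adj = np.where(flip, 1 - base.adjacency, base.adjacency)
                extra = _pair_bernoulli(
                    np.where(long_range, scheme.long_range_p, 0.0), rng
                )
                adj = np.maximum(adj, extra)
                np.fill_diagonal(adj, 0)
                ei, ej = np.nonzero(np.triu(adj, k=1))
                mu = spec.weight_mean - 1.0
                size = spec.weight_dispersion
                counts = 1 + rng.negative_binomial(
                    size, size / (size + mu), len(ei)
                )
                w = np.zeros((n, n))
                w[ei, ej] = counts
                w += w.T
                subject_id = f"sub{subject:03d}"
                conn = WeightedConnectome(
                    w, base.node_labels,
                    subject_id=subject_id, scheme=scheme.tag, scale=scale,
                )
                group.append(conn)
                if out_path is not None:
                    fname = f"{subject_id}_{scheme.tag}_scale{scale}.tsv"
                    write_matrix(conn, out_path / fname)
                    entries.append(
                        {
                            "subject_id": subject_id,
                            "scheme": scheme.tag,
                            "scale": scale,
                            "path": fname,
                        }
                    )
            groups[(scheme.tag, scale)] = group
    manifest = None
    if out_path is not None:
        manifest = EnsembleManifest(entries=entries, root=out_path)
        manifest.to_json(out_path / "manifest.json")
        with open(out_path / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return EnsembleData(groups=groups, truth=truth, manifest=manifest)


def coarsen_scale(
    conn: WeightedConnectome, grouping: dict[str, str]
) -> tuple[WeightedConnectome, float]:
    """Merge nodes into supernodes, summing inter-group streamline counts.

    ``grouping`` maps every node label to a supernode label.  Intra-group
    counts fall on the (zeroed) diagonal and are dropped; the dropped total
    is returned so callers can account for it.
    """
    missing = set(conn.node_labels) - set(grouping)
    if missing:
        raise ValueError(f"grouping does not cover nodes: {sorted(missing)}")
    super_labels: list[str] = []
    for label in conn.node_labels:
        g = grouping[label]
        if g not in super_labels:
            super_labels.append(g)
    s = len(super_labels)
    assign = np.zeros((len(conn.node_labels), s))
    for i, label in enumerate(conn.node_labels):
        assign[i, super_labels.index(grouping[label])] = 1.0
    merged = assign.T @ conn.matrix @ assign
    dropped = float(np.trace(merged)) / 2.0
    np.fill_diagonal(merged, 0.0)
    return (
        WeightedConnectome(
            merged, super_labels,
            subject_id=conn.subject_id, scheme=conn.scheme, scale=s,
        ),
        dropped,
    )
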