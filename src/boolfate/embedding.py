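"""2-D t-SNE embedding of attractor states from their binary vectors.

Cycles contribute one row per state, so the map reflects the raw 0/1
expression patterns.  Exact duplicate rows are collapsed before the t-SNE
run (the algorithm cannot separate identical points and small perplexities
are unstable under duplicates) and re-expanded afterwards with a small
seeded jitter of radius :data:`JITTER_RADIUS` so coincident groups stay
visually coincident.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .attractors import AttractorSet
from .phenotype import PhenotypeScheme, annotate_set

__all__ = ["StateMatrix", "EmbeddingResult", "state_matrix", "embed_2d",
           "JITTER_RADIUS"]

#: Maximum displacement applied when re-expanding duplicate rows.
JITTER_RADIUS = 0.01


@dataclass(frozen=True)
class StateMatrix:
    """Binary state vectors (rows) plus per-row attractor metadata."""

    matrix: np.ndarray       # shape (rows, n_nodes), dtype uint8
    meta: pd.DataFrame       # attractor, state_index, period, class, name,
                             # state_name, duplicate_group

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]


def state_matrix(attr_set: AttractorSet, scheme: PhenotypeScheme,
                 aggregate: str = "state") -> StateMatrix:
    """One row per attractor state, in canonical attractor/state order.

    ``aggregate="attractor_mean"`` instead averages each cycle into a single
    fractional row (one row per attractor).
    """
    if aggregate not in ("state", "attractor_mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    if not len(attr_set):
        raise ValueError("empty attractor set")
    annotations = annotate_set(attr_set, scheme)
    rows = []
    meta = []
    for ai, ann in enumerate(annotations):
        if aggregate == "attractor_mean":
            rows.append(np.mean(ann.attractor.states, axis=0))
            meta.append({
                "attractor": ai, "state_index": 0, "period": ann.period,
                "class": ann.attractor_class, "name": ann.name,
                "state_name": ann.name,
            })
            continue
        for si, state in enumerate(ann.attractor.states):
            rows.append(state)
            meta.append({
                "attractor": ai,
                "state_index": si,
                "period": ann.period,
                "class": ann.attractor_class,
                "name": ann.name,
                "state_name": ann.state_names[si],
            })
    dtype = np.float64 if aggregate == "attractor_mean" else np.uint8
    matrix = np.asarray(rows, dtype=dtype)
    frame = pd.DataFrame(meta)
    # identical bit vectors share a duplicate-group id (first occurrence)
    groups: dict = {}
    group_ids = []
    for i in range(matrix.shape[0]):
        key = matrix[i].tobytes()
        group_ids.append(groups.setdefault(key, i))
    frame["duplicate_group"] = group_ids
    return StateMatrix(matrix=matrix, meta=frame)


@dataclass(frozen=True)
class EmbeddingResult:
    coords: np.ndarray       # shape (rows, 2)
    meta: pd.DataFrame
    perplexity: float
    seed: int
    n_iter: int

    def to_frame(self) -> pd.DataFrame:
        frame = self.meta.copy()
        frame["x"] = self.coords[:, 0]
        frame["y"] = self.coords[:, 1]
        return frame


def embed_2d(m: StateMatrix, seed: int, perplexity: Optional[float] = None,
             n_iter: int = 1000) -> EmbeddingResult:
    """Deterministic t-SNE of the state matrix for a fixed seed.

    Duplicate rows are embedded once and re-expanded with seeded jitter
    within :data:`JITTER_RADIUS`.  Perplexity defaults to
    ``min(5, distinct_rows - 1)`` and is shrunk (with a warning) whenever it
    is not below the number of distinct rows.
    """
    if m.n_rows < 3:
        raise ValueError(
            "need at least 3 rows to embed; plot the states directly instead")
    unique, inverse = np.unique(m.matrix, axis=0, return_inverse=True)
    n_distinct = unique.shape[0]
    if n_distinct < 3:
        raise ValueError(
            f"only {n_distinct} distinct state vectors; embedding needs >= 3 "
            "-- plot the states directly instead")
    if perplexity is None:
        perplexity = min(5, n_distinct - 1)
    if perplexity >= n_distinct:
        shrunk = max(1.0, float(n_distinct - 1))
        warnings.warn(
            f"perplexity {perplexity} >= {n_distinct} distinct rows; "
            f"shrinking to {shrunk}", stacklevel=2)
        perplexity = shrunk
    tsne = TSNE(n_components=2, perplexity=float(perplexity),
                random_state=seed, init="pca", max_iter=n_iter,
                learning_rate="auto")
    base = tsne.fit_transform(unique.astype(np.float64))
    coords = base[inverse].astype(np.float64)
    # jitter duplicates (beyond the first of each group) inside the radius
    rng = np.random.default_rng(seed)
    seen: dict = {}
    for i in range(m.n_rows):
        g = int(inverse[i])
        rank = seen.get(g, 0)
        seen[g] = rank + 1
        if rank == 0:
            continue
        angle = rng.uniform(0.0, 2.0 * np.pi)
        radius = rng.uniform(0.0, JITTER_RADIUS)
        coords[i, 0] += radius * np.cos(angle)
        coords[i, 1] += radius * np.sin(angle)
    return EmbeddingResult(coords=coords, meta=m.meta, perplexity=float(perplexity),
                           seed=seed, n_iter=n_iter)


def plot_embedding(result: EmbeddingResult, path, dpi: int = 150) -> None:
    """Scatter the embedding colored by attractor class (PNG/SVG by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = result.to_frame()
    fig, ax = plt.subplots(figsize=(6, 5))
    for cls, sub in frame.groupby("class", sort=True):
        ax.scatter(sub["x"], sub["y"], label=cls, s=30, alpha=0.8)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(str(path), dpi=dpi)
    plt.close(fig)
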