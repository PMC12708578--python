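"""p-stable random-projection LSH: ensembles, bucketing, index, ranking.

The hash of an item x under one table is the integer vector

    h(x) = floor((W·x + b) / r)

with W a t×d matrix of i.i.d. standard-normal entries (2-stable, so per-row
collision probability decreases with Euclidean distance), b a vector of t
offsets uniform on [0, r), and r the bucket width.  An ensemble holds L
independent tables; a query's candidates are the union of exact bucket-key
matches across tables, topped up by a nearest-bucket scan when the union is
too small to honour ``num_results``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .blinding import FeatureMatrix, ProjectionTable
from .errors import InvalidConfigError, ProtocolError

__all__ = [
    "ProjectionEnsemble",
    "BucketTable",
    "FederatedIndex",
    "QueryResult",
    "sample_ensemble",
    "project",
    "bucketize",
    "build_index",
    "lookup_candidates",
    "rank_candidates",
]

METRICS = ("euclidean", "cosine", "l1")


@dataclass
class ProjectionEnsemble:
    """L independent LSH tables sharing hash size t, dimension d and bucket width.

    ``num_hash`` is accepted as a config alias for ``bucket_width`` (the
    name some pipelines use for the quantizer's divisor).
    """

    tables: list[dict]  # each {"W": (t, d) array, "offsets": (t,) array}
    t: int
    d: int
    L: int
    bucket_width: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.bucket_width <= 0:
            raise InvalidConfigError("bucket_width must be positive")
        for tab in self.tables:
            if tab["W"].shape != (self.t, self.d):
                raise InvalidConfigError("all tables must share shape (t, d)")
            off = tab["offsets"]
            if off.shape != (self.t,) or np.any(off < 0) or np.any(off >= self.bucket_width):
                raise InvalidConfigError("offsets must lie in [0, bucket_width)")


@dataclass
class BucketTable:
    """Integer quantization of a projection table; one column per item."""

    values: np.ndarray  # (t, m) integers
    column_ids: list[str]
    table_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise InvalidConfigError("bucket table must be integer-valued")
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_ids):
            raise InvalidConfigError("bucket table shape must be (t, len(column_ids))")


@dataclass
class QueryResult:
    query_id: str
    candidate_ids: list[str]
    distances: list[float]
    metric: str
    num_results: int


@dataclass
class FederatedIndex:
    """Data-server structure: per-table bucket maps plus stored ranking vectors.

    Holds only hash values (integer buckets, and optionally the real-valued
    projections when projection-ranking is enabled) — never raw features.
    """

    t: int
    L: int
    buckets: list[dict[tuple, set[str]]] = field(default_factory=list)
    item_vectors: dict[str, np.ndarray] = field(default_factory=dict)  # (L*t,)
    item_client: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.buckets:
            self.buckets = [dict() for _ in range(self.L)]

    def __len__(self) -> int:
        return len(self.item_vectors)

    @property
    def item_ids(self) -> list[str]:
        return list(self.item_vectors)

    def _stacked(self) -> tuple[list[str], np.ndarray]:
        """Item ids and their vectors as one matrix, cached between queries."""
        cached = getattr(self, "_stack_cache", None)
        if cached is None or len(cached[0]) != len(self.item_vectors):
            ids = self.item_ids
            mat = np.stack([self.item_vectors[i] for i in ids]) if ids else np.empty((0, self.L * self.t))
            cached = (ids, mat)
            object.__setattr__(self, "_stack_cache", cached)
        return cached


def sample_ensemble(
    t: int,
    d: int,
    L: int,
    bucket_width: float,
    rng: np.random.Generator,
    seed: int | None = None,
) -> ProjectionEnsemble:
    """Draw L tables of i.i.d. N(0,1) projections and uniform offsets."""
    if t < 1 or d < 1 or L < 1 or bucket_width <= 0:
        raise InvalidConfigError(
            f"need t, d, L >= 1 and bucket_width > 0, got t={t} d={d} L={L} width={bucket_width}"
        )
    tables = [
        {
            "W": rng.standard_normal((t, d)),
            "offsets": rng.uniform(0.0, bucket_width, size=t),
        }
        for _ in range(L)
    ]
    return ProjectionEnsemble(tables=tables, t=t, d=d, L=L, bucket_width=bucket_width, seed=seed)


def project(W: np.ndarray, X: FeatureMatrix) -> ProjectionTable:
    """The plaintext projection table W·Xᵀ (t×m)."""
    W = np.asarray(W, dtype=float)
    if W.shape[1] != X.d:
        raise InvalidConfigError(f"W has {W.shape[1]} columns, data has d={X.d}")
    return ProjectionTable(values=W @ X.values.T, column_ids=list(X.row_ids))


def bucketize(
    H: ProjectionTable,
    offsets: np.ndarray,
    bucket_width: float,
    table_index: int = 0,
) -> BucketTable:
    """floor((H + b) / r), floor toward −∞ — the standard p-stable quantizer."""
    if bucket_width <= 0:
        raise InvalidConfigError("bucket_width must be positive")
    offsets = np.asarray(offsets, dtype=float)
    if offsets.shape != (H.values.shape[0],):
        raise InvalidConfigError("offsets length must equal the hash size t")
    vals = np.floor((H.values + offsets[:, None]) / bucket_width).astype(np.int64)
    return BucketTable(values=vals, column_ids=list(H.column_ids), table_index=table_index)


def build_index(
    bucket_tables: Sequence[Sequence[BucketTable]],
    client_ids: Sequence[str] | None = None,
) -> FederatedIndex:
    """Aggregate per-client bucket tables (one per LSH table) into one index.

    ``bucket_tables[c][tab]`` is client c's table for ensemble member ``tab``.
    Items already present (same id, e.g. a content UUID submitted by two
    clients) are skipped so the index holds each unique item once.
    """
    clients = [list(tabs) for tabs in bucket_tables]
    if not clients:
        return FederatedIndex(t=0, L=0)
    L = len(clients[0])
    t = clients[0][0].values.shape[0]
    for tabs in clients:
        if len(tabs) != L or any(bt.values.shape[0] != t for bt in tabs):
            raise ProtocolError("clients submitted inconsistent (t, L) bucket tables")
    if client_ids is None:
        client_ids = [f"client-{c}" for c in range(len(clients))]

    index = FederatedIndex(t=t, L=L)
    for cid, tabs in zip(client_ids, clients):
        ids = tabs[0].column_ids
        for bt in tabs:
            if bt.column_ids != ids:
                raise ProtocolError("bucket tables within a client disagree on item ids")
        for col, item in enumerate(ids):
            if item in index.item_vectors:  # duplicate UUID → skip
                continue
            vec = np.concatenate([tabs[tab].values[:, col] for tab in range(L)])
            index.item_vectors[item] = vec
            index.item_client[item] = cid
            for tab in range(L):
                key = tuple(int(v) for v in tabs[tab].values[:, col])
                index.buckets[tab].setdefault(key, set()).add(item)
    return index


def lookup_candidates(
    index: FederatedIndex,
    query_buckets: Sequence[np.ndarray],
    num_results: int,
) -> set[str]:
    """Exact bucket-key matches across tables, topped up by nearest buckets.

    When the union of exact matches is smaller than ``num_results``, the
    remaining slots are filled by scanning all indexed items and adding those
    with the smallest mean per-table L1 distance between integer bucket
    vectors (ties broken by item id).
    """
    if len(query_buckets) != index.L:
        raise ProtocolError(f"query has {len(query_buckets)} tables, index has {index.L}")
    candidates: set[str] = set()
    for tab, qb in enumerate(query_buckets):
        key = tuple(int(v) for v in np.asarray(qb).ravel())
        candidates |= index.buckets[tab].get(key, set())

    if len(candidates) < num_results and len(index) > len(candidates):
        qvec = np.concatenate([np.asarray(qb).ravel() for qb in query_buckets])
        ids, mat = index._stacked()
        dists = np.abs(mat - qvec).sum(axis=1) / index.L
        order = sorted(range(len(ids)), key=lambda k: (dists[k], ids[k]))
        for k in order:
            if len(candidates) >= num_results:
                break
            candidates.add(ids[k])
    return candidates


def rank_candidates(
    query_vector: np.ndarray,
    candidates: Mapping[str, np.ndarray],
    metric: str,
    num_results: int,
    query_id: str = "query",
) -> QueryResult:
    """Rank candidate vectors by distance to the query vector.

    Cosine ranks by 1 − cosine similarity (zero vectors get similarity 0);
    ties are broken by lexicographic item id.
    """
    if metric not in METRICS:
        raise InvalidConfigError(f"unknown metric {metric!r}; choose from {METRICS}")
    q = np.asarray(query_vector, dtype=float).ravel()
    scored: list[tuple[float, str]] = []
    for item, vec in candidates.items():
        v = np.asarray(vec, dtype=float).ravel()
        if v.shape != q.shape:
            raise InvalidConfigError(
                f"candidate {item!r} vector length {v.size} != query length {q.size}"
            )
        if metric == "euclidean":
            dist = float(np.linalg.norm(q - v))
        elif metric == "l1":
            dist = float(np.abs(q - v).sum())
        else:
            denom = np.linalg.norm(q) * np.linalg.norm(v)
            sim = float(q @ v / denom) if denom > 0 else 0.0
            dist = 1.0 - sim
        scored.append((dist, item))
    scored.sort(key=lambda pair: (pair[0], pair[1]))
    top = scored[:num_results]
    return QueryResult(
        query_id=query_id,
        candidate_ids=[item for _, item in top],
        distances=[dist for dist, _ in top],
        metric=metric,
        num_results=num_results,
    )
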