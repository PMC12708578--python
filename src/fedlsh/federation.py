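"""Three-role federated protocol: Client, Cloud Server, Data Server.

Roles
-----
* **Client** — owns a private feature matrix and a blinding key.  It blinds
  its data, outsources the projection product to the cloud, verifies and
  recovers the result, quantizes it into integer buckets and submits those
  to the data server.  Raw data and keys never leave the client object.
* **Cloud Server** — samples the global projection ensemble, broadcasts it,
  and computes blinded products.  It is keyless and stateless per request.
* **Data Server** — aggregates bucket tables from all clients into one
  federated index and answers k-candidate similarity queries.  It holds
  hash values only (integer buckets by default).

Transport is in-process message passing with serializable payloads; every
outbound message is recorded in an audit log so tests can assert that no
raw data or key material ever leaves a client.

Queries run in one of three modes that differ only in *where* the query's
projection table W·Xᵀ is computed — at the data server from raw vectors
("raw", for data that needs no protection), locally at the client
("local-hash"), or via the blinded cloud round-trip ("cloud-assisted",
for large batches).  All three return identical rankings.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import _ops, blinding, lsh
from .blinding import BlindingKey, EncryptedHashTable, EncryptedMatrix, FeatureMatrix
from .errors import InvalidConfigError, ProtocolError, VerificationFailedError
from .lsh import BucketTable, FederatedIndex, ProjectionEnsemble, QueryResult

__all__ = [
    "RunConfig",
    "ProtocolMessage",
    "Client",
    "CloudServer",
    "DataServer",
    "FederatedRun",
    "orchestrate",
    "QUERY_MODES",
]

QUERY_MODES = ("raw", "local-hash", "cloud-assisted")


@dataclass
class RunConfig:
    """Topology and protocol parameters for one federated run."""

    n_clients: int = 2
    items_per_client: int = 100
    d: int = 64
    t: int = 40
    L: int = 3
    bucket_width: float = 4.0
    l: int = 8  # Givens rotations per side of the blinding key
    num_results: int = 4
    metric: str = "euclidean"
    mode: str = "cloud-assisted"
    ranking: Literal["buckets", "projections"] = "buckets"
    server_side_bucketize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "n_clients": self.n_clients,
            "items_per_client": self.items_per_client,
            "d": self.d,
            "t": self.t,
            "L": self.L,
            "l": self.l,
            "num_results": self.num_results,
        }
        for name, val in positive.items():
            if val < 1:
                raise InvalidConfigError(f"{name} must be >= 1, got {val}")
        if self.bucket_width <= 0:
            raise InvalidConfigError("bucket_width must be positive")
        if self.mode not in QUERY_MODES:
            raise InvalidConfigError(f"mode must be one of {QUERY_MODES}, got {self.mode!r}")
        if self.metric not in lsh.METRICS:
            raise InvalidConfigError(f"metric must be one of {lsh.METRICS}")


@dataclass
class ProtocolMessage:
    """One hop of the protocol, with a payload the audit log can inspect."""

    sender: str
    receiver: str
    kind: Literal[
        "projection-ensemble",
        "encrypted-pair",
        "encrypted-hashtable",
        "hashtable",
        "bucket-table",
        "query",
        "result",
    ]
    payload: dict
    round_id: int = 0


def _payload_arrays(payload) -> list[np.ndarray]:
    out = []
    if isinstance(payload, np.ndarray):
        out.append(payload)
    elif isinstance(payload, dict):
        for v in payload.values():
            out.extend(_payload_arrays(v))
    elif isinstance(payload, (list, tuple)):
        for v in payload:
            out.extend(_payload_arrays(v))
    elif isinstance(payload, (EncryptedMatrix, EncryptedHashTable)):
        out.append(payload.values)
    elif isinstance(payload, BucketTable):
        out.append(payload.values)
    elif isinstance(payload, lsh.ProjectionTable):
        out.append(payload.values)
    return out


class Client:
    """Data owner: blinds, outsources, verifies, recovers, submits."""

    def __init__(self, client_id: str, data: FeatureMatrix, rng: np.random.Generator):
        self.client_id = client_id
        self._data = data  # private; never serialized into a message
        self._rng = rng
        self._key: BlindingKey | None = None
        self.ensemble: ProjectionEnsemble | None = None
        self.recovered: list[lsh.ProjectionTable] = []

    @property
    def n_items(self) -> int:
        return self._data.m

    def receive_ensemble(self, msg: ProtocolMessage) -> None:
        if msg.kind != "projection-ensemble":
            raise ProtocolError(f"expected projection-ensemble, got {msg.kind}")
        self.ensemble = msg.payload["ensemble"]

    def outsource(self, l: int, round_id: int = 0) -> ProtocolMessage:
        """Encrypt X once and every table's W, and address the pair to the cloud."""
        if self.ensemble is None:
            raise ProtocolError(f"{self.client_id}: no ensemble received before outsourcing")
        if self._data.m < 2 or self._data.d < 2:
            raise ProtocolError("blinding requires at least 2 items and 2 features")
        self._key = blinding.keygen(self._data.m, self._data.d, l, self._rng)
        with _ops.phase("encryption"):
            Xp = blinding.encrypt_data(self._data, self._key)
            Wps = [
                blinding.encrypt_projection(tab["W"], self._key)
                for tab in self.ensemble.tables
            ]
        return ProtocolMessage(
            sender=self.client_id,
            receiver="cloud",
            kind="encrypted-pair",
            payload={"X": Xp, "W": Wps, "client_id": self.client_id},
            round_id=round_id,
        )

    def finalize(self, msg: ProtocolMessage) -> list[lsh.ProjectionTable]:
        """Verify every returned table, then recover the plaintext projections.

        A failed verification discards everything from this round: a poisoned
        table must never reach the data server.
        """
        if msg.kind != "encrypted-hashtable":
            raise ProtocolError(f"expected encrypted-hashtable, got {msg.kind}")
        if self._key is None:
            raise ProtocolError("finalize before outsource")
        Xp: EncryptedMatrix = msg.payload["X"]
        tables: list[EncryptedHashTable] = msg.payload["tables"]
        Wps: list[EncryptedMatrix] = msg.payload["W"]
        with _ops.phase("verification"):
            for k, (Hp, Wp) in enumerate(zip(tables, Wps)):
                if not blinding.verify_product(Hp, Wp, Xp, self._rng):
                    raise VerificationFailedError(
                        f"{self.client_id}: cloud product for table {k} failed verification"
                    )
        with _ops.phase("recovery"):
            recovered = [blinding.recover(Hp, self._key) for Hp in tables]
        for table in recovered:
            table.column_ids = list(self._data.row_ids)
        self.recovered = recovered
        return recovered

    def local_projections(self) -> list[lsh.ProjectionTable]:
        """The no-cloud path: compute W·Xᵀ directly for every table."""
        if self.ensemble is None:
            raise ProtocolError("no ensemble received")
        return [lsh.project(tab["W"], self._data) for tab in self.ensemble.tables]

    def submit(self, tables: Sequence[lsh.ProjectionTable], cfg: RunConfig) -> ProtocolMessage:
        """Bucketize client-side (default) and address the result to the data server."""
        if self.ensemble is None:
            raise ProtocolError("no ensemble received")
        if cfg.server_side_bucketize:
            payload: dict = {
                "hashtables": [
                    lsh.ProjectionTable(values=tb.values.copy(), column_ids=list(tb.column_ids))
                    for tb in tables
                ],
                "client_id": self.client_id,
            }
            kind = "hashtable"
        else:
            buckets = [
                lsh.bucketize(tb, tab["offsets"], self.ensemble.bucket_width, k)
                for k, (tb, tab) in enumerate(zip(tables, self.ensemble.tables))
            ]
            payload = {"buckets": buckets, "client_id": self.client_id}
            if cfg.ranking == "projections":
                payload["projections"] = [tb.values.copy() for tb in tables]
            kind = "bucket-table"
        return ProtocolMessage(sender=self.client_id, receiver="dataserver", kind=kind, payload=payload)


class CloudServer:
    """Keyless outsourced compute: ensemble generation and blinded products."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng

    def make_ensemble(self, cfg: RunConfig) -> ProjectionEnsemble:
        return lsh.sample_ensemble(
            cfg.t, cfg.d, cfg.L, cfg.bucket_width, self._rng, seed=cfg.seed
        )

    def broadcast(self, ensemble: ProjectionEnsemble, receiver: str) -> ProtocolMessage:
        return ProtocolMessage(
            sender="cloud",
            receiver=receiver,
            kind="projection-ensemble",
            payload={"ensemble": ensemble},
        )

    def serve(self, msg: ProtocolMessage) -> ProtocolMessage:
        if msg.kind != "encrypted-pair":
            raise ProtocolError(f"cloud expected encrypted-pair, got {msg.kind}")
        Xp: EncryptedMatrix = msg.payload["X"]
        Wps: list[EncryptedMatrix] = msg.payload["W"]
        with _ops.phase("cloud"):
            tables = [blinding.encrypted_product(Wp, Xp) for Wp in Wps]
        return ProtocolMessage(
            sender="cloud",
            receiver=msg.sender,
            kind="encrypted-hashtable",
            payload={"tables": tables, "X": Xp, "W": Wps},
            round_id=msg.round_id,
        )


class DataServer:
    """Index holder: aggregates bucket tables, answers k-candidate queries."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.ensemble: ProjectionEnsemble | None = None
        self._submissions: list[tuple[str, list[BucketTable], list[np.ndarray] | None]] = []
        self.index: FederatedIndex | None = None

    def receive_ensemble(self, msg: ProtocolMessage) -> None:
        self.ensemble = msg.payload["ensemble"]

    def ingest(self, msg: ProtocolMessage) -> None:
        if msg.kind == "hashtable":
            if self.ensemble is None:
                raise ProtocolError("data server has no ensemble to bucketize with")
            buckets = [
                lsh.bucketize(tb, tab["offsets"], self.ensemble.bucket_width, k)
                for k, (tb, tab) in enumerate(
                    zip(msg.payload["hashtables"], self.ensemble.tables)
                )
            ]
            projections = (
                [tb.values for tb in msg.payload["hashtables"]]
                if self.cfg.ranking == "projections"
                else None
            )
        elif msg.kind == "bucket-table":
            buckets = msg.payload["buckets"]
            projections = msg.payload.get("projections")
        else:
            raise ProtocolError(f"data server expected a table submission, got {msg.kind}")
        self._submissions.append((msg.payload["client_id"], buckets, projections))
        self.index = None  # rebuilt lazily

    def build(self) -> FederatedIndex:
        index = lsh.build_index(
            [buckets for _, buckets, _ in self._submissions],
            client_ids=[cid for cid, _, _ in self._submissions],
        )
        if self.cfg.ranking == "projections":
            for cid, buckets, projections in self._submissions:
                if projections is None:
                    raise ProtocolError(f"{cid}: projection ranking requested but not submitted")
                ids = buckets[0].column_ids
                for col, item in enumerate(ids):
                    if index.item_client.get(item) == cid:
                        index.item_vectors[item] = np.concatenate(
                            [proj[:, col] for proj in projections]
                        )
        self.index = index
        return index

    def answer(
        self,
        query_tables: Sequence[lsh.ProjectionTable],
        num_results: int,
        metric: str,
        exclude_self: bool = False,
    ) -> list[QueryResult]:
        """Bucketize the query projections and rank candidates per query."""
        if self.ensemble is None:
            raise ProtocolError("data server has no ensemble")
        if self.index is None:
            self.build()
        index = self.index
        buckets = [
            lsh.bucketize(qt, tab["offsets"], self.ensemble.bucket_width, k)
            for k, (qt, tab) in enumerate(zip(query_tables, self.ensemble.tables))
        ]
        query_ids = query_tables[0].column_ids
        results = []
        for col, qid in enumerate(query_ids):
            per_table = [bt.values[:, col] for bt in buckets]
            want = num_results + (1 if exclude_self and qid in index.item_vectors else 0)
            cand_ids = lsh.lookup_candidates(index, per_table, want)
            if exclude_self:
                cand_ids.discard(qid)
            if self.cfg.ranking == "projections":
                qvec = np.concatenate([qt.values[:, col] for qt in query_tables])
            else:
                qvec = np.concatenate(per_table)
            results.append(
                lsh.rank_candidates(
                    qvec,
                    {cid: index.item_vectors[cid] for cid in cand_ids},
                    metric,
                    num_results,
                    query_id=qid,
                )
            )
        return results


@dataclass
class FederatedRun:
    """Handle to a completed run: index holder, roles, audit log and report."""

    config: RunConfig
    clients: list[Client]
    cloud: CloudServer
    dataserver: DataServer
    audit_log: list[ProtocolMessage]
    report: dict
    _query_rng: np.random.Generator = field(repr=False, default=None)

    @property
    def index(self) -> FederatedIndex:
        if self.dataserver.index is None:
            self.dataserver.build()
        return self.dataserver.index

    def query(
        self,
        Q: FeatureMatrix,
        mode: str | None = None,
        num_results: int | None = None,
        metric: str | None = None,
        exclude_self: bool = False,
    ) -> list[QueryResult]:
        """Answer a batch of queries through one of the three protocol paths."""
        cfg = self.config
        mode = mode or cfg.mode
        num_results = num_results or cfg.num_results
        metric = metric or cfg.metric
        if mode not in QUERY_MODES:
            raise InvalidConfigError(f"mode must be one of {QUERY_MODES}, got {mode!r}")
        ensemble = self.dataserver.ensemble
        if mode == "raw":
            msg = ProtocolMessage(
                sender="querier",
                receiver="dataserver",
                kind="query",
                payload={"raw": Q.values, "ids": list(Q.row_ids)},
            )
            self.audit_log.append(msg)
            tables = [lsh.project(tab["W"], Q) for tab in ensemble.tables]
        elif mode == "local-hash":
            tables = [lsh.project(tab["W"], Q) for tab in ensemble.tables]
            self.audit_log.append(
                ProtocolMessage(
                    sender="querier",
                    receiver="dataserver",
                    kind="query",
                    payload={"hashtables": tables, "ids": list(Q.row_ids)},
                )
            )
        else:  # cloud-assisted batch
            querier = Client("querier", Q, self._query_rng)
            querier.ensemble = ensemble
            out = querier.outsource(cfg.l)
            self.audit_log.append(out)
            back = self.cloud.serve(out)
            self.audit_log.append(back)
            tables = querier.finalize(back)
            self.audit_log.append(
                ProtocolMessage(
                    sender="querier",
                    receiver="dataserver",
                    kind="query",
                    payload={"hashtables": tables, "ids": list(Q.row_ids)},
                )
            )
        return self.dataserver.answer(tables, num_results, metric, exclude_self=exclude_self)


def orchestrate(
    config: RunConfig,
    data_per_client: Sequence[FeatureMatrix],
    counter: _ops.OpCounter | None = None,
) -> FederatedRun:
    """Run the full protocol: broadcast → outsource → cloud → verify/recover →
    submit → index.  Deterministic given ``config.seed``.

    In "raw" and "local-hash" modes the clients' own tables are computed
    locally; "cloud-assisted" routes them through the blinded cloud product
    with verification.
    """
    if len(data_per_client) != config.n_clients:
        raise InvalidConfigError(
            f"expected {config.n_clients} client datasets, got {len(data_per_client)}"
        )
    for X in data_per_client:
        if X.d != config.d:
            raise InvalidConfigError(f"client data has d={X.d}, config says d={config.d}")

    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=config.n_clients + 2)
    cloud = CloudServer(np.random.default_rng(int(seeds[0])))
    dataserver = DataServer(config)
    clients = [
        Client(f"client-{k}", X, np.random.default_rng(int(seeds[k + 1])))
        for k, X in enumerate(data_per_client)
    ]
    audit: list[ProtocolMessage] = []
    counter = counter if counter is not None else _ops.OpCounter()
    timings: dict[str, float] = {}

    with _ops.counting(counter):
        tic = time.perf_counter()
        ensemble = cloud.make_ensemble(config)
        for client in clients:
            client.receive_ensemble(cloud.broadcast(ensemble, client.client_id))
        dataserver.receive_ensemble(cloud.broadcast(ensemble, "dataserver"))
        timings["broadcast"] = time.perf_counter() - tic

        tic = time.perf_counter()
        for client in clients:
            if config.mode == "cloud-assisted":
                out = client.outsource(config.l)
                audit.append(out)
                back = cloud.serve(out)
                audit.append(back)
                tables = client.finalize(back)
            else:
                tables = client.local_projections()
                client.recovered = tables
            submission = client.submit(tables, config)
            audit.append(submission)
            dataserver.ingest(submission)
        timings["hash-tables"] = time.perf_counter() - tic

        tic = time.perf_counter()
        index = dataserver.build()
        timings["index-build"] = time.perf_counter() - tic

    report = {
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "n_indexed": len(index),
        "sm_counts": counter.as_dict(),
        "timings_s": timings,
    }
    return FederatedRun(
        config=config,
        clients=clients,
        cloud=cloud,
        dataserver=dataserver,
        audit_log=audit,
        report=report,
        _query_rng=np.random.default_rng(int(seeds[-1])),
    )


def audit_privacy(run: FederatedRun, tol: float = 1e-6) -> list[str]:
    """Scan the audit log for any payload that leaks a client's raw matrix.

    Returns a list of violation descriptions (empty when the run is clean).
    A payload counts as a leak when it has a client's data shape and is
    within Frobenius distance *tol* of the raw matrix.  Key material never
    appears in payloads by construction; this re-checks it.
    """
    violations = []
    raw = {c.client_id: c._data.values for c in run.clients}
    for n, msg in enumerate(run.audit_log):
        if msg.receiver not in ("cloud", "dataserver"):
            continue
        for arr in _payload_arrays(msg.payload):
            for cid, X in raw.items():
                if arr.shape == X.shape and np.linalg.norm(arr - X) < tol:
                    violations.append(f"message {n} ({msg.kind}) leaks raw data of {cid}")
        for val in msg.payload.values():
            if isinstance(val, BlindingKey):
                violations.append(f"message {n} ({msg.kind}) carries a blinding key")
    return violations
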