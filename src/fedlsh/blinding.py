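"""Givens-rotation blinding for outsourced hash-table computation.

A client holding a private feature matrix ``X`` (m items × d features) wants
an untrusted cloud to compute the projection table ``W·Xᵀ`` without seeing
either ``X`` or ``W``.  The client blinds both with a secret key

    SK = {α, P₁…P_l, Q₁…Q_l}

where α is a nonzero scalar and the P's and Q's are random Givens (elementary
rotation) matrices acting on the item and feature dimensions respectively:

    X′ = P₁P₂⋯P_l (αX) Q₁Q₂⋯Q_l          (data encryption)
    W′ = (αW) Q₁Q₂⋯Q_l                    (projection encryption)

The cloud returns ``H′ = W′·X′ᵀ``.  Because the rotations are orthogonal,

    (1/α²) · H′ · P₁P₂⋯P_l  =  W·Xᵀ       (exact recovery)

and a Freivalds-style random-vector contraction checks the cloud's work
without recomputing the full product:  V1 = (rW′)X′ᵀ must equal V2 = r·H′.

Rotations are stored as (i, j, θ) parameter triples and applied as sparse
two-row / two-column updates (4 scalar multiplications per affected vector
element), never as dense matrices — this is what makes the blinding cheap
relative to the t·d·m cost of the product itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from . import _ops
from .errors import (
    InvalidConfigError,
    InvalidDimensionError,
    InvalidKeyError,
    ProtocolError,
)

__all__ = [
    "GivensRotation",
    "BlindingKey",
    "FeatureMatrix",
    "EncryptedMatrix",
    "EncryptedHashTable",
    "ProjectionTable",
    "sample_givens",
    "rotation_as_dense",
    "apply_left_rotations",
    "apply_right_rotations",
    "keygen",
    "encrypt_data",
    "encrypt_projection",
    "encrypted_product",
    "verify_product",
    "recover",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GivensRotation:
    """One elementary rotation: angle ``theta`` in the (i, j) coordinate plane.

    The dense form is the identity with entries (i,i) = (j,j) = cos θ,
    (i,j) = sin θ and (j,i) = −sin θ.
    """

    i: int
    j: int
    theta: float

    def __post_init__(self) -> None:
        if not (0 <= self.i < self.j):
            raise InvalidDimensionError(
                f"rotation indices must satisfy 0 <= i < j, got ({self.i}, {self.j})"
            )
        if not (0.0 < self.theta < 2.0 * np.pi):
            raise InvalidConfigError(f"theta must lie in (0, 2*pi), got {self.theta}")


@dataclass(frozen=True)
class BlindingKey:
    """The client's secret key SK = {α, P₁…P_l, Q₁…Q_l}.

    Left rotations act on the item dimension (m), right rotations on the
    feature dimension (d).  Stored as parameter triples, never as dense
    matrices, so keys stay O(l) regardless of m and d.
    """

    alpha: float
    left_rotations: tuple[GivensRotation, ...]
    right_rotations: tuple[GivensRotation, ...]
    m: int
    d: int

    def __post_init__(self) -> None:
        if self.alpha == 0.0:
            raise InvalidKeyError("alpha must be nonzero")
        if len(self.left_rotations) != len(self.right_rotations):
            raise InvalidKeyError("left and right rotation lists must have equal length")
        if not self.left_rotations:
            raise InvalidKeyError("at least one rotation per side is required")
        for rot in self.left_rotations:
            if rot.j >= self.m:
                raise InvalidKeyError(f"left rotation {rot} out of range for m={self.m}")
        for rot in self.right_rotations:
            if rot.j >= self.d:
                raise InvalidKeyError(f"right rotation {rot} out of range for d={self.d}")

    @property
    def l(self) -> int:  # noqa: E743 - the protocol's own symbol
        return len(self.left_rotations)

    # -- key-file serialization (local use only; never enters the protocol) --

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "m": self.m,
            "d": self.d,
            "l": self.l,
            "left_rotations": [[r.i, r.j, r.theta] for r in self.left_rotations],
            "right_rotations": [[r.i, r.j, r.theta] for r in self.right_rotations],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "BlindingKey":
        return cls(
            alpha=float(payload["alpha"]),
            left_rotations=tuple(
                GivensRotation(int(i), int(j), float(t))
                for i, j, t in payload["left_rotations"]
            ),
            right_rotations=tuple(
                GivensRotation(int(i), int(j), float(t))
                for i, j, t in payload["right_rotations"]
            ),
            m=int(payload["m"]),
            d=int(payload["d"]),
        )

    def save(self, path: str | Path, seed: int | None = None) -> None:
        payload = self.to_dict()
        if seed is not None:
            payload["seed"] = int(seed)
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "BlindingKey":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class FeatureMatrix:
    """An m×d real matrix with per-row item identifiers."""

    values: np.ndarray
    row_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise InvalidDimensionError("feature matrix must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise InvalidDimensionError("feature matrix entries must be finite")
        if len(self.row_ids) != self.values.shape[0]:
            raise InvalidDimensionError("row_ids length must match row count")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class EncryptedMatrix:
    """A blinded matrix: ``kind`` says whether it plays the X′ or W′ role."""

    values: np.ndarray
    kind: Literal["data", "projection"]


@dataclass
class EncryptedHashTable:
    """The cloud's claimed blinded product H′ = W′·X′ᵀ (t×m)."""

    values: np.ndarray


@dataclass
class ProjectionTable:
    """The real-valued t×m table W·Xᵀ; columns follow ``column_ids``."""

    values: np.ndarray
    column_ids: list[str]


# ---------------------------------------------------------------------------
# rotation primitives
# ---------------------------------------------------------------------------


def sample_givens(dim: int, rng: np.random.Generator) -> GivensRotation:
    """Draw a uniform index pair i < j below *dim* and a uniform angle in (0, 2π)."""
    if dim < 2:
        raise InvalidDimensionError(f"need dim >= 2 to rotate, got {dim}")
    i, j = sorted(rng.choice(dim, size=2, replace=False).tolist())
    theta = float(rng.uniform(0.0, 2.0 * np.pi))
    while theta == 0.0:  # open interval; measure-zero but keep the contract exact
        theta = float(rng.uniform(0.0, 2.0 * np.pi))
    return GivensRotation(i=int(i), j=int(j), theta=theta)


def rotation_as_dense(rot: GivensRotation, dim: int) -> np.ndarray:
    """Materialize the dim×dim rotation matrix (test/debug aid, not a hot path)."""
    if rot.j >= dim:
        raise InvalidDimensionError(f"rotation {rot} out of range for dim {dim}")
    g = np.eye(dim)
    c, s = np.cos(rot.theta), np.sin(rot.theta)
    g[rot.i, rot.i] = c
    g[rot.j, rot.j] = c
    g[rot.i, rot.j] = s
    g[rot.j, rot.i] = -s
    return g


def apply_left_rotations(
    M: np.ndarray, rotations: Sequence[GivensRotation]
) -> np.ndarray:
    """Compute P₁P₂⋯P_l·M applying the rightmost factor first.

    Each rotation touches only rows i and j: 4·ncols scalar multiplications.
    """
    out = np.array(M, dtype=float, copy=True)
    nrows, ncols = out.shape
    for rot in reversed(rotations):
        if rot.j >= nrows:
            raise InvalidKeyError(f"rotation {rot} out of range for {nrows} rows")
        c, s = np.cos(rot.theta), np.sin(rot.theta)
        ri = out[rot.i].copy()
        rj = out[rot.j]
        out[rot.i] = c * ri + s * rj
        out[rot.j] = -s * ri + c * rj
        _ops.record(4 * ncols)
    return out


def apply_right_rotations(
    M: np.ndarray, rotations: Sequence[GivensRotation]
) -> np.ndarray:
    """Compute M·Q₁Q₂⋯Q_l applying the leftmost factor first.

    Each rotation touches only columns i and j: 4·nrows scalar multiplications.
    """
    out = np.array(M, dtype=float, copy=True)
    nrows, ncols = out.shape
    for rot in rotations:
        if rot.j >= ncols:
            raise InvalidKeyError(f"rotation {rot} out of range for {ncols} columns")
        c, s = np.cos(rot.theta), np.sin(rot.theta)
        ci = out[:, rot.i].copy()
        cj = out[:, rot.j]
        # right-multiplying by G mixes columns with G's columns: new_i = c·ci − s·cj
        out[:, rot.i] = c * ci - s * cj
        out[:, rot.j] = s * ci + c * cj
        _ops.record(4 * nrows)
    return out


# ---------------------------------------------------------------------------
# the protocol operations
# ---------------------------------------------------------------------------


def keygen(m: int, d: int, l: int, rng: np.random.Generator) -> BlindingKey:
    """Generate a fresh secret key for an m×d data matrix with l rotations per side.

    α is drawn log-uniform on [0.5, 2]: bounded away from 0 and ∞ so the 1/α²
    recovery never amplifies floating-point error catastrophically.
    """
    if m < 2 or d < 2:
        raise InvalidDimensionError(f"need m, d >= 2, got m={m}, d={d}")
    if l < 1:
        raise InvalidConfigError(f"need at least one rotation per side, got l={l}")
    alpha = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
    left = tuple(sample_givens(m, rng) for _ in range(l))
    right = tuple(sample_givens(d, rng) for _ in range(l))
    return BlindingKey(alpha=alpha, left_rotations=left, right_rotations=right, m=m, d=d)


def encrypt_data(X: FeatureMatrix, key: BlindingKey) -> EncryptedMatrix:
    """X′ = P₁P₂⋯P_l (αX) Q₁Q₂⋯Q_l."""
    if (X.m, X.d) != (key.m, key.d):
        raise InvalidKeyError(
            f"data shape {(X.m, X.d)} does not match key shape {(key.m, key.d)}"
        )
    scaled = key.alpha * X.values
    _ops.record(X.m * X.d)
    out = apply_left_rotations(scaled, key.left_rotations)
    out = apply_right_rotations(out, key.right_rotations)
    return EncryptedMatrix(values=out, kind="data")


def encrypt_projection(W: np.ndarray, key: BlindingKey) -> EncryptedMatrix:
    """W′ = (αW) Q₁Q₂⋯Q_l."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[1] != key.d:
        raise InvalidKeyError(
            f"projection must have {key.d} columns, got shape {W.shape}"
        )
    scaled = key.alpha * W
    _ops.record(W.shape[0] * W.shape[1])
    out = apply_right_rotations(scaled, key.right_rotations)
    return EncryptedMatrix(values=out, kind="projection")


def encrypted_product(Wp: EncryptedMatrix, Xp: EncryptedMatrix) -> EncryptedHashTable:
    """The cloud's job: H′ = W′·X′ᵀ.  Keyless and stateless.

    Cost is the full dense product: t·d·m scalar multiplications.
    """
    W, X = Wp.values, Xp.values
    if W.shape[1] != X.shape[1]:
        raise ProtocolError(
            f"inner dimensions disagree: W' is {W.shape}, X' is {X.shape}"
        )
    t, d = W.shape
    m = X.shape[0]
    _ops.record(t * d * m)
    return EncryptedHashTable(values=W @ X.T)


def verify_product(
    Hp: EncryptedHashTable,
    Wp: EncryptedMatrix,
    Xp: EncryptedMatrix,
    rng: np.random.Generator,
    rel_tol: float = 1e-6,
    n_checks: int = 1,
) -> bool:
    """Freivalds-style check of the cloud's claimed product.

    Draws a random sign vector r (i.i.d. ±1) and accepts iff

        ‖(rW′)X′ᵀ − r·H′‖∞  ≤  rel_tol · (1 + ‖V1‖∞)

    for every one of ``n_checks`` independent draws.  With ±1 entries a
    single-entry perturbation δ of H′ shifts one coordinate of V2 by exactly
    ±δ, so any such tamper above the floating-point tolerance is caught with
    certainty; a general (multi-entry) tamper slips past one draw with
    probability at most 1/2, so callers wanting protection against adversarial
    cancellation can raise ``n_checks``.

    Cost per draw: t·d + d·m + t·m scalar multiplications.
    """
    W, X, H = Wp.values, Xp.values, Hp.values
    t, d = W.shape
    m = X.shape[0]
    if H.shape != (t, m):
        raise ProtocolError(f"hash table shape {H.shape} does not match ({t}, {m})")
    for _ in range(max(1, n_checks)):
        r = rng.choice([-1.0, 1.0], size=t)
        _ops.record(t * d)  # r·W′  -> 1×d
        rW = r @ W
        _ops.record(d * m)  # (rW′)·X′ᵀ -> 1×m
        v1 = rW @ X.T
        _ops.record(t * m)  # r·H′ -> 1×m
        v2 = r @ H
        if np.max(np.abs(v1 - v2)) > rel_tol * (1.0 + np.max(np.abs(v1))):
            return False
    return True


def recover(Hp: EncryptedHashTable, key: BlindingKey) -> ProjectionTable:
    """HashTable = (1/α²) · H′ · P₁P₂⋯P_l  — undoes the blinding exactly.

    The right product by P un-rotates the item dimension; the α² divides out
    the two scalar blinds picked up by W′ and X′.
    """
    H = Hp.values
    if H.ndim != 2 or H.shape[1] != key.m:
        raise InvalidKeyError(
            f"hash table has {H.shape[1] if H.ndim == 2 else '?'} columns, key expects {key.m}"
        )
    out = apply_right_rotations(H, key.left_rotations)
    out /= key.alpha**2
    _ops.record(H.shape[0] * H.shape[1])
    return ProjectionTable(values=out, column_ids=[str(i) for i in range(key.m)])
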