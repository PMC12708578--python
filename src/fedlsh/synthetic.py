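"""Synthetic benchmark data: labeled Gaussian clusters and mutated genomes.

Two generators emulate the two benchmark settings the pipeline is evaluated
on, with ground truth emitted alongside so retrieval quality can be scored
without external labels:

* ``gen_clusters`` — a labeled point cloud: class centers i.i.d.
  N(0, center_scale²·I) in d dimensions, points = center + N(0, noise_sd²·I).
  The default spec (10 classes × 500 points, d=64, center_scale=1.0,
  noise_sd=1.8) is calibrated so plain 1-nearest-neighbor accuracy is ≈ 0.9 —
  a retrieval task that is clearly solvable but not trivial.

* ``gen_genomes`` — variable-length DNA records with planted near-duplicates:
  base sequences uniform over ACGT, plus variant copies carrying i.i.d.
  per-base substitutions.  Substitution-only (no indels), so a variant's
  k-th slice aligns with its base's k-th slice and planted-pair ground truth
  survives windowing.

Both are fully deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blinding import FeatureMatrix
from .errors import InvalidConfigError
from .genomics import GenomeRecord

__all__ = ["ClusterSpec", "GenomeSimSpec", "gen_clusters", "gen_genomes", "shard_clients"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ClusterSpec:
    """Gaussian mixture benchmark: 10 balanced classes by default."""

    n_classes: int = 10
    points_per_class: int = 500
    d: int = 64
    center_scale: float = 1.0
    noise_sd: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_classes, self.points_per_class, self.d) < 1:
            raise InvalidConfigError("n_classes, points_per_class and d must be >= 1")
        if self.center_scale <= 0 or self.noise_sd < 0:
            raise InvalidConfigError("center_scale must be > 0 and noise_sd >= 0")


@dataclass(frozen=True)
class GenomeSimSpec:
    """Synthetic genome set with planted near-duplicate variants."""

    n_base_sequences: int = 50
    length_min: int = 3000
    length_max: int = 12000
    mutation_rate: float = 0.01
    variants_per_base: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_base_sequences < 1 or self.length_min < 1:
            raise InvalidConfigError("need >= 1 base sequence of length >= 1")
        if self.length_max < self.length_min:
            raise InvalidConfigError("length_max must be >= length_min")
        if not (0.0 <= self.mutation_rate < 1.0):
            raise InvalidConfigError("mutation_rate must lie in [0, 1)")
        if self.variants_per_base < 0:
            raise InvalidConfigError("variants_per_base must be >= 0")


def gen_clusters(spec: ClusterSpec) -> tuple[FeatureMatrix, np.ndarray]:
    """Draw the labeled point cloud; returns (features, integer labels)."""
    rng = np.random.default_rng(spec.seed)
    centers = rng.normal(0.0, spec.center_scale, size=(spec.n_classes, spec.d))
    labels = np.repeat(np.arange(spec.n_classes), spec.points_per_class)
    points = centers[labels] + rng.normal(0.0, spec.noise_sd, size=(labels.size, spec.d))
    ids = [f"pt-{k:05d}" for k in range(labels.size)]
    return FeatureMatrix(values=points, row_ids=ids), labels


def gen_genomes(spec: GenomeSimSpec) -> tuple[list[GenomeRecord], dict[str, str]]:
    """Draw base sequences and mutated variants.

    Returns the records plus a provenance map: record id → base-sequence id
    (a base maps to itself), the ground truth for hit-rate evaluation.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[GenomeRecord] = []
    provenance: dict[str, str] = {}
    for b in range(spec.n_base_sequences):
        length = int(rng.integers(spec.length_min, spec.length_max + 1))
        base = rng.integers(0, 4, size=length)
        base_id = f"base-{b:04d}"
        records.append(GenomeRecord(id=base_id, sequence="".join(_BASES[base])))
        provenance[base_id] = base_id
        for v in range(spec.variants_per_base):
            seq = base.copy()
            hit = rng.random(length) < spec.mutation_rate
            # substitute with one of the three *other* bases
            seq[hit] = (seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
            var_id = f"base-{b:04d}.var-{v}"
            records.append(GenomeRecord(id=var_id, sequence="".join(_BASES[seq])))
            provenance[var_id] = base_id
    return records, provenance


def shard_clients(items: list, n_clients: int, seed: int) -> list[list]:
    """Seed-shuffled balanced partition: shard sizes differ by at most one."""
    if n_clients < 1:
        raise InvalidConfigError("need at least one client")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    shards: list[list] = [[] for _ in range(n_clients)]
    for pos, idx in enumerate(order):
        shards[pos % n_clients].append(items[idx])
    return shards
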