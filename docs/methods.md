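# Methods

## Problem setting

Institutions holding private genomic (or other high-dimensional) data want to
find, across all institutions, the items most similar to a query — without
sharing raw data. `fedlsh` implements a three-role protocol: each **client**
owns a private feature matrix `X ∈ ℝ^{m×d}`; an untrusted **cloud server**
performs the heavy projection products on blinded inputs; a **data server**
aggregates integer hash tables from all clients and answers k-candidate
queries. The data server never sees features, the cloud never sees plaintext,
and keys never leave the client.

## Blinding scheme

The client's secret key is `SK = {α, P₁…P_l, Q₁…Q_l}`: a nonzero scalar and
`2l` random Givens (elementary rotation) matrices, the `P`s acting on the
item dimension `m`, the `Q`s on the feature dimension `d`. Encryption and
recovery:

    X′ = P₁P₂⋯P_l (αX) Q₁Q₂⋯Q_l
    W′ = (αW) Q₁Q₂⋯Q_l
    H′ = W′·X′ᵀ                       (computed by the cloud)
    W·Xᵀ = (1/α²) · H′ · P₁P₂⋯P_l     (recovered by the client)

Correctness is an orthogonality identity: `X′ᵀ = QᵀXᵀPᵀ·α`, so
`H′ = α²·W·Xᵀ·Pᵀ` and right-multiplying by `P` cancels `Pᵀ` exactly.

Implementation choices:

* **Rotations are never materialized.** A rotation `(i, j, θ)` is applied as
  a two-row (or two-column) update costing 4·(row length) scalar
  multiplications; keys are stored and serialized as `(i, j, θ)` triples.
  Keys therefore stay `O(l)` in size and encryption stays
  `O(l·(m + d))` regardless of how large `X` is.
* **θ** is a real angle uniform on the open interval (0, 2π). Index pairs
  `i < j` are uniform over all pairs, drawn independently per rotation;
  repeats are allowed (the product stays orthogonal).
* **α** is log-uniform on [0.5, 2]. Any nonzero real works algebraically,
  but bounding `α` away from 0 and ∞ keeps the `1/α²` recovery step from
  amplifying floating-point error.
* **Factor order** is fixed: the left product applies `P_l` first and `P₁`
  last; the right product applies `Q₁` first; recovery right-multiplies by
  `P₁` first. Any consistent convention satisfies the recovery identity;
  this one matches the written factor order above.

## Verification

The client checks the cloud's claimed `H′` with a Freivalds-style
random-vector contraction: draw `r ∈ {−1, +1}^t`, compare
`V1 = (rW′)X′ᵀ` against `V2 = r·H′`, and accept iff

    ‖V1 − V2‖∞ ≤ rel_tol · (1 + ‖V1‖∞),     rel_tol = 1e−6 by default.

Exact equality is the correctness identity in real arithmetic; the relative
tolerance absorbs floating-point round-off. The Rademacher (±1) sign vector
is chosen deliberately over a continuous one: for a single tampered entry of
magnitude δ, the discrepancy `|V1 − V2|` at the affected column is *exactly*
δ, so any tamper above the tolerance floor is rejected with certainty. A
Gaussian `r` would scale the discrepancy by `|r_a|`, which falls below the
tolerance with probability on the order of a few percent at realistic table
scales — too weak for the soundness this package promises. A general
(multi-entry, adversarially crafted) tamper evades one ±1 draw with
probability at most 1/2; `verify_product(..., n_checks=k)` runs `k`
independent draws for `2^{−k}` evasion probability. One draw costs
`t·d + d·m + t·m` multiplications — far cheaper than the `t·d·m` product
being checked. Verification always runs before recovery; a failure aborts
that client's round and nothing is submitted downstream.

## LSH index

Hashing is standard 2-stable random-projection LSH: `L` independent tables,
each with a `t×d` projection `W` of i.i.d. N(0,1) entries, per-row offsets
`b` uniform on `[0, r)`, and bucket width `r`:

    h(x) = floor((W·x + b) / r)     (one integer per hash row)

Gaussian projections make the per-row collision probability a strictly
decreasing function of Euclidean distance, which is what justifies offering
Euclidean (also cosine and L1) ranking over hash vectors. The bucket width
`r` defaults to 4.0, the conventional choice for roughly unit-variance
data; it is exposed as config (alias `num_hash` accepted for continuity
with the pipeline's original parameter name).

**Candidate generation.** A query's bucket key per table is its full
t-tuple. Candidates are the union of exact key matches across the L tables.
Exact t-row collisions become rare as `t` grows, so when the union is
smaller than `num_results` the lookup falls back to scanning all indexed
items by mean per-table L1 distance between integer bucket vectors and
taking the nearest until `num_results` is reached. This keeps the data
server's working set hash-valued while guaranteeing a full candidate list
whenever the index is large enough.

**Ranking.** Candidates are ranked by the chosen metric on the concatenated
`L·t` integer bucket vectors (default), or on real-valued projection vectors
when `ranking="projections"` is configured — a strictly more informative but
less conservative option, since the data server then stores real
projections rather than quantized hashes. Ties break lexicographically by
item id so results are reproducible.

## Federation protocol

One run is: the cloud samples the global ensemble and broadcasts it to every
client and to the data server → each client blinds `(X, W₁…W_L)` (one `X′`
reused across the L tables, same key) → cloud returns the L blinded
products → client verifies all L, recovers, quantizes to integer buckets
client-side, and submits `(bucket tables, item ids)` → the data server
aggregates, skipping ids it has already indexed (content-UUID dedup).
Transport is in-process message passing with serializable payloads; every
outbound message is recorded in an audit log, and `audit_privacy` re-checks
after the fact that no cloud- or server-bound payload matches any client's
raw matrix and that no key object was ever serialized.

Bucketization happens client-side by default so the data server holds
integers only; a `server_side_bucketize` flag moves the quantizer to the
data server (which then receives real-valued tables) — the two placements
produce identical indexes, and a test asserts it.

Queries run in three modes differing only in where `W·Xᵀ` is computed:
`raw` (query vectors go to the data server — only for data needing no
protection), `local-hash` (client projects locally, sends hash values), and
`cloud-assisted` (the blinded round-trip, for large batches). Because all
three produce the same projection table up to floating-point round-off,
their rankings are identical; this equivalence is asserted end-to-end in the
tests. Floating-point equality of the quantized buckets is not formally
guaranteed — an entry landing within ~1e−12 of a bucket boundary could
round differently across modes — but the probability is negligible and has
never been observed in the seeded suites.

## Genome front-end

Variable-length nucleotide records are made indexable by numericization and
overlapped windowing:

* `A→0, T→1, C→2, G→3`; every other symbol (N, IUPAC ambiguity codes, gaps)
  maps to the same −1 sentinel used for padding. The value set thus stays
  `{−1, 0, 1, 2, 3}`; a distinct sentinel for ambiguity is available via
  `other_code` if separating "unknown base" from "past end of sequence"
  matters.
* Windows of `sequence_length` bases (default 3072) start every
  `sequence_length − overlap` positions (default overlap 100), so
  consecutive windows share `overlap` bases; the final short window is
  right-padded with −1. `n_chunks = max(1, ceil((len − overlap) / step))`.
  Concatenating windows while dropping each subsequent window's first
  `overlap` positions reproduces the input exactly — the primary test
  oracle for the slicer.
* Each slice gets a deterministic name-based UUID computed from its vector
  bytes, so identical fragments held by different clients collide on id and
  the index keeps one copy without any coordination.

The ordinal codes feed the projections directly as a `d = sequence_length`
vector. This imposes an artificial metric on base substitutions (A↔T is
distance 1, A↔G distance 3) — a deliberate reproduction of the pipeline's
encoding, documented as a caveat: substitution-heavy similarity is ranked,
but the geometry among unequal bases is arbitrary. One-hot encoding would
remove the artifact at 4× the dimension; it is out of scope here.

## Synthetic benchmarks

Real benchmark corpora (labeled image sets; public gene databases) need
external downloads, so the test and acceptance suites run on two generators
whose ground truth is emitted alongside the data:

* **Clusters** — class centers i.i.d. N(0, center_scale²·I), points =
  center + N(0, noise_sd²·I). Defaults: 10 classes × 500 points, d=64,
  center_scale=1.0, noise_sd=1.8, calibrated once so plain 1-nearest-
  neighbor accuracy is ≈ 0.90 — solvable but not saturated, which is the
  regime where retrieval quality is informative.
* **Genomes** — base sequences uniform over ACGT with lengths uniform on
  [3,000, 12,000], plus variant copies carrying i.i.d. substitutions at
  rate 0.01. Substitution-only by design: indels would shift slice frames
  and destroy planted-pair ground truth after windowing. This is a known
  limitation — real structural variation is not emulated, and neither are
  base-composition biases, repeats, or sequencing error profiles. Passing
  on these generators demonstrates the pipeline's mechanics and the LSH
  collision law, not performance on any real corpus.

Sharding distributes items over clients in a seed-shuffled balanced
partition (sizes differ by at most one).

## Evaluation

* **Hit rate @ k** — a query hits if at least one of its top-k candidates
  shares the query's ground-truth label (clusters) or base sequence
  (genomes). The query item is excluded from its own candidates; otherwise
  any indexed query trivially hits at rank 1. Repeated seeded runs give the
  reported mean ± sd (sd across run-level means).
* **Permutation null** — the chance level is estimated by permuting item
  labels and recomputing the hit rate; for a balanced C-class set at k
  candidates it sits near `1 − (1 − 1/C)^k` (≈ 0.344 at C=10, k=4).
* **SM accounting** — the cost unit is one scalar multiplication. The
  instrumented counter measures actual per-phase counts. Verification
  (`td + dm + tm` per draw) and the cloud product (`tdm`) are exact and
  asserted. The closed forms printed for encryption (`md+td+2ml+4dl`) and
  recovery (`tm+2ml`) do not match the true cost of sparse Givens updates
  (a left rotation on an m×d matrix costs 4d, not a multiple of `ml`;
  recovery's rotations on a t×m table cost 4t each): the tabulation reports
  those formulas verbatim next to measured counts without asserting
  equality, and the implementation's own provable encryption bound
  `md + td + 4l(m + d + t)` (single-table) is what tests enforce.

## Problem sizes and numerical choices

Default suite sizes: 100 random instances for the blinding round-trip
(m, t ≤ 64, d ≤ 128, l ≤ 16; worst relative error observed ~1e−15 against
a tolerance of 1e−9); 1,000 trials each for verification completeness and
soundness; 2,000 controlled pairs across three decades of distance for the
collision profile; the 10×500 cluster benchmark with t=40, L=3 and 250
self-queries for hit-rate checks; and a full-scale genomic run of 10
clients × 1,000 slices of d=3072 (t=40, L=3) with 100 queries at
num_results=4, for which timings are reported but never asserted, since
they are hardware-dependent.

Degenerate inputs: empty rotation lists are identities; zero matrices
encrypt, verify and recover to zero; an index smaller than `num_results`
returns everything it has; `overlap ≥ sequence_length`, non-positive bucket
widths, unknown metrics and unknown query modes are rejected before any
computation.

## Known limitations

* The blinding hides values, not shapes: `m`, `d`, `t` and the Frobenius
  norm up to `|α|` are visible to the cloud. No formal hardening beyond the
  rotation-product scheme is attempted (no homomorphic encryption,
  differential privacy, or secure multiparty computation).
* A single ±1 verification draw bounds adversarial (multi-entry,
  crafted) tampering only by 1/2; raise `n_checks` where an actively
  malicious cloud is in the threat model.
* Bucket-vector ranking is a proxy for true distance; its fidelity degrades
  as `bucket_width` grows relative to the data scale.
* The ordinal DNA encoding's substitution geometry is arbitrary (see above).
* In-process transport only: no networking, authentication, or
  malicious-client modeling.
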