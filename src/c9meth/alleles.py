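"""Wild-type vs expanded allele assignment by k-means on k-mer counts.

Each carrier has two alleles at the locus: a short wild-type tract and a long
expansion. On-target reads are split into the two groups by 2-means
clustering of overlapping k-mer counts of the tract-containing segment; raw
counts (not frequencies) are used on purpose, so tract length dominates the
feature space — that is the separating signal. The cluster with the larger
mean count of the repeat motif k-mer is labelled ``expanded`` (ties broken by
mean read length, since expansion implies length).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .records import EXPANDED, REPEAT_MOTIF, WILD_TYPE
from .simulate import default_anchors

_BASE_CODE = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def kmer_counts(sequence: str, k: int = 6) -> dict[str, int]:
    """Counts of all overlapping k-mers of ``sequence``.

    The counts sum to ``max(len(sequence) - k + 1, 0)``. Characters outside
    A/C/G/T raise ``ValueError``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ids = _encode_kmers(sequence, k)
    uniq, counts = np.unique(ids, return_counts=True)
    return {_decode_kmer(int(u), k): int(c) for u, c in zip(uniq, counts)}


def _encode_kmers(sequence: str, k: int) -> np.ndarray:
    """Base-4 integer ids of all overlapping k-mers (vectorised)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _BASE_CODE[arr]
    if (codes == 255).any():
        bad = sequence[int(np.argmax(codes == 255))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    if arr.size < k:
        return np.empty(0, dtype=np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), k)
    return windows @ weights


def _decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def _tract_segment(sequence: str, left_anchor: str, right_anchor: str) -> str:
    """Segment between the flank anchors (the locus region of interest).

    Falls back to the whole read when an anchor is absent, so the function
    also works on reads whose span flags were set by alignment coordinates.
    """
    i = sequence.find(left_anchor)
    start = i + len(left_anchor) if i != -1 else 0
    j = sequence.find(right_anchor, start)
    end = j if j != -1 else len(sequence)
    return sequence[start:end] if end > start else sequence


def assign_alleles(
    reads: pd.DataFrame,
    k: int = 6,
    seed: int = 0,
    left_anchor: str | None = None,
    right_anchor: str | None = None,
) -> pd.DataFrame:
    """Two-cluster k-means assignment of reads to wild-type/expanded.

    Returns a table with ``read_id``, ``label``, ``cluster_distance`` (the
    Euclidean distance to the assigned centroid) and ``feature_vector_norm``.
    Raises on fewer than two reads or on a degenerate cohort in which every
    read has an identical feature vector (single-allele input).
    """
    if len(reads) < 2:
        raise ValueError("allele assignment needs at least 2 reads")
    if left_anchor is None or right_anchor is None:
        la, ra = default_anchors()
        left_anchor = left_anchor or la
        right_anchor = right_anchor or ra

    segs = [
        _tract_segment(s, left_anchor, right_anchor) for s in reads["sequence"]
    ]
    encoded = [_encode_kmers(s, k) for s in segs]
    all_ids = np.unique(np.concatenate([e for e in encoded if e.size] or [np.empty(0, dtype=np.int64)]))
    col = {int(kid): j for j, kid in enumerate(all_ids)}
    X = np.zeros((len(reads), len(col)), dtype=float)
    for i, ids in enumerate(encoded):
        uniq, counts = np.unique(ids, return_counts=True)
        for u, c in zip(uniq, counts):
            X[i, col[int(u)]] = c

    if np.allclose(X, X[0]):
        raise ValueError(
            "all reads have identical k-mer profiles; clustering is degenerate "
            "(single-allele input?) — run in single-allele mode instead"
        )

    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    assignment = km.fit_predict(X)

    # Which cluster is the expansion: larger mean repeat-motif count wins;
    # ties (motif absent or balanced) fall back to mean read length.
    motif_id = _encode_kmers(REPEAT_MOTIF, k)[0] if len(REPEAT_MOTIF) >= k else None
    if motif_id is not None and int(motif_id) in col:
        motif_col = X[:, col[int(motif_id)]]
    else:
        motif_col = np.zeros(len(reads))
    means = [motif_col[assignment == c].mean() for c in (0, 1)]
    if means[0] != means[1]:
        expanded_cluster = int(np.argmax(means))
    else:
        lengths = reads["sequence"].str.len().to_numpy()
        expanded_cluster = int(
            np.argmax([lengths[assignment == c].mean() for c in (0, 1)])
        )

    dist = np.linalg.norm(X - km.cluster_centers_[assignment], axis=1)
    return pd.DataFrame(
        {
            "read_id": reads["read_id"].to_numpy(),
            "label": np.where(assignment == expanded_cluster, EXPANDED, WILD_TYPE),
            "cluster_distance": dist,
            "feature_vector_norm": np.linalg.norm(X, axis=1),
        }
    )


def assign_alleles_per_sample(
    reads: pd.DataFrame, k: int = 6, seed: int = 0,
    left_anchor: str | None = None, right_anchor: str | None = None,
) -> pd.DataFrame:
    """Run :func:`assign_alleles` independently within each sample.

    Each individual carries exactly two alleles, so clustering within a
    sample is the well-posed unit; pooling individuals with very different
    expansion sizes can otherwise split the expanded reads instead of the
    alleles. Samples whose reads are degenerate (e.g. a single spanning read)
    are labelled by motif count against the cohort-wide wild-type bound.
    """
    out = []
    for sample_id, grp in reads.groupby("sample_id", sort=True):
        try:
            calls = assign_alleles(grp, k=k, seed=seed,
                                   left_anchor=left_anchor, right_anchor=right_anchor)
        except ValueError:
            # fallback: motif-count threshold at the wild-type upper bound
            n_motif = grp["sequence"].str.count(REPEAT_MOTIF)
            calls = pd.DataFrame(
                {
                    "read_id": grp["read_id"].to_numpy(),
                    "label": np.where(n_motif > 30, EXPANDED, WILD_TYPE),
                    "cluster_distance": np.zeros(len(grp)),
                    "feature_vector_norm": np.zeros(len(grp)),
                }
            )
        out.append(calls)
    return pd.concat(out, ignore_index=True)
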