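"""Tetranucleotide composition signatures.

A genome's 4-mer usage deviates from what its shorter-mer usage predicts in a
way that is characteristic of the organism, which makes tetranucleotide
statistics a taxonomic signal for binning assembled contigs.  The statistic
used here is the z-score of each observed tetramer count against its
expectation under the maximal-order Markov model fitted from the same
sequence: for tetramer ``abcd``,

    E[N(abcd)] = N(abc) * N(bcd) / N(bc)
    Var[N(abcd)] = E[N(abcd)] * (N(bc) - N(abc)) * (N(bc) - N(bcd)) / N(bc)^2
    z(abcd) = (N(abcd) - E[N(abcd)]) / sqrt(Var[N(abcd)])

with z defined as 0 wherever the variance vanishes (absent trimer context),
so every signature is a comparable length-256 vector.

Counting pools all contigs of a collection (a SAG, a bin, or a single contig)
and, by default, both strands; windows containing ambiguous bases are skipped
entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._util import encode_seq, revcomp

TETRAMERS: list[str] = ["".join(p) for p in product("ACGT", repeat=4)]
Z_COLUMNS: list[str] = [f"z_{t}" for t in TETRAMERS]

_STRAND_MODES = ("given", "both")


def _as_seq_list(contigs) -> list[str]:
    """Accept a single string, an iterable of strings, or an id->seq mapping."""
    if isinstance(contigs, str):
        return [contigs]
    if isinstance(contigs, Mapping):
        return [contigs[k] for k in contigs]
    return list(contigs)


@dataclass
class KmerCounts:
    """Pooled k-mer counts for one sequence collection."""

    k: int
    counts: np.ndarray  # length 4**k
    n_windows: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4**self.k,):
            raise ValueError(f"counts must have length 4**{self.k}")
        if int(self.counts.sum()) != self.n_windows:
            raise ValueError("sum of counts must equal n_windows")


@dataclass
class TetraSignature:
    """Observed/expected tetramer counts and z-scores for one collection."""

    observed: np.ndarray
    expected: np.ndarray
    variance: np.ndarray
    z: np.ndarray
    source_ids: list[str] = field(default_factory=list)


def count_kmers(contigs, k: int, strand_mode: str = "both") -> KmerCounts:
    """Count k-mers pooled over all contigs of a collection.

    Windows containing any non-ACGT symbol are skipped.  With
    ``strand_mode="both"`` each contig and its reverse complement are counted,
    which makes the result invariant to contig orientation.
    """
    if k not in (2, 3, 4):
        raise ValueError("k must be 2, 3 or 4")
    if strand_mode not in _STRAND_MODES:
        raise ValueError(f"strand_mode must be one of {_STRAND_MODES}")
    seqs = _as_seq_list(contigs)
    if not seqs:
        raise ValueError("empty sequence collection")

    counts = np.zeros(4**k, dtype=np.int64)
    for seq in seqs:
        strands = (seq,) if strand_mode == "given" else (seq, revcomp(seq))
        for s in strands:
            counts += _count_one(s, k)
    return KmerCounts(k=k, counts=counts, n_windows=int(counts.sum()))


def _count_one(seq: str, k: int) -> np.ndarray:
    codes = encode_seq(seq)
    n = codes.size - k + 1
    if n <= 0:
        return np.zeros(4**k, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    idx = np.zeros(n, dtype=np.int64)
    for j in range(k):
        cj = codes[j : j + n]
        valid &= cj >= 0
        idx = idx * 4 + np.where(cj < 0, 0, cj)
    return np.bincount(idx[valid], minlength=4**k).astype(np.int64)


def expected_and_variance(
    c4: KmerCounts, c3: KmerCounts, c2: KmerCounts
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tetramer expectation and variance under the maximal-order Markov
    model implied by the trimer and dimer counts of the same collection.

    Both are set to 0 for tetramers whose central dimer context is absent.
    """
    if (c4.k, c3.k, c2.k) != (4, 3, 2):
        raise ValueError("expected k=4, k=3 and k=2 count vectors in that order")
    n3 = c3.counts.astype(float)
    n2 = c2.counts.astype(float)

    t = np.arange(256)
    abc = t // 4          # leading trimer a b c
    bcd = t % 64          # trailing trimer b c d
    bc = (t % 64) // 4    # central dimer b c

    n_bc = n2[bc]
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = np.where(n_bc > 0, n3[abc] * n3[bcd] / n_bc, 0.0)
        variance = np.where(
            n_bc > 0,
            expected * (n_bc - n3[abc]) * (n_bc - n3[bcd]) / n_bc**2,
            0.0,
        )
    # guard against tiny negative values from cancellation
    variance = np.maximum(variance, 0.0)
    return expected, variance


def zscores(observed, expected, variance) -> np.ndarray:
    """Elementwise (observed - expected) / sqrt(variance); 0 where variance=0."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    variance = np.asarray(variance, dtype=float)
    if observed.shape != (256,) or expected.shape != (256,) or variance.shape != (256,):
        raise ValueError("observed, expected and variance must have length 256")
    if np.any(variance < 0):
        raise ValueError("variance must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(variance > 0, (observed - expected) / np.sqrt(variance), 0.0)
    return z


def tetra_signature(
    contigs, strand_mode: str = "both", source_ids: Sequence[str] | None = None
) -> TetraSignature:
    """Full tetranucleotide signature (counts, expectation, variance, z) for a
    sequence collection."""
    c4 = count_kmers(contigs, 4, strand_mode)
    c3 = count_kmers(contigs, 3, strand_mode)
    c2 = count_kmers(contigs, 2, strand_mode)
    expected, variance = expected_and_variance(c4, c3, c2)
    z = zscores(c4.counts, expected, variance)
    if source_ids is None:
        source_ids = list(contigs.keys()) if isinstance(contigs, Mapping) else []
    return TetraSignature(
        observed=c4.counts.copy(),
        expected=expected,
        variance=variance,
        z=z,
        source_ids=list(source_ids),
    )


def signature_matrix(
    collections: Mapping[str, Mapping[str, str]],
    min_len: int = 5000,
    strand_mode: str = "both",
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Signature z-score matrix for several collections.

    Contigs shorter than ``min_len`` are dropped before counting; the second
    return value reports the dropped contig ids per collection.  A collection
    emptied by the filter raises a ``ValueError`` naming it.
    """
    rows = []
    dropped: dict[str, list[str]] = {}
    for name, contigs in collections.items():
        kept = {cid: s for cid, s in contigs.items() if len(s) >= min_len}
        dropped[name] = [cid for cid in contigs if cid not in kept]
        if not kept:
            raise ValueError(
                f"collection {name!r} has no contigs >= {min_len} bp after filtering"
            )
        sig = tetra_signature(kept, strand_mode=strand_mode)
        rows.append(sig.z)
    return (
        pd.DataFrame(rows, index=list(collections.keys()), columns=Z_COLUMNS),
        dropped,
    )


class TetraZScoreTransformer(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer from sequence collections to z-vectors.

    ``X`` is a sequence of collections, each either a raw nucleotide string or
    a contig-id -> sequence mapping; ``transform`` returns an (n, 256) array
    of tetranucleotide z-scores.  Stateless: ``fit`` only records dimensions.
    """

    def __init__(self, min_len: int = 0, strand_mode: str = "both"):
        self.min_len = min_len
        self.strand_mode = strand_mode

    def fit(self, X, y=None):
        if self.strand_mode not in _STRAND_MODES:
            raise ValueError(f"strand_mode must be one of {_STRAND_MODES}")
        self.n_features_in_ = 256
        return self

    def transform(self, X) -> np.ndarray:
        rows = np.empty((len(X), 256), dtype=float)
        for i, coll in enumerate(X):
            if isinstance(coll, str):
                kept: Mapping[str, str] | list[str] = (
                    [coll] if len(coll) >= self.min_len else []
                )
            else:
                kept = {c: s for c, s in coll.items() if len(s) >= self.min_len}
            if not kept:
                raise ValueError(f"collection at position {i} empty after min_len filter")
            rows[i] = tetra_signature(kept, strand_mode=self.strand_mode).z
        return rows

    def get_feature_names_out(self, input_features=None):
        return np.asarray(Z_COLUMNS, dtype=object)
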