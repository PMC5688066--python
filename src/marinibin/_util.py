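"""Shared helpers: deterministic seed splitting, checksums, sequence codes."""

from __future__ import annotations

import hashlib
import zlib

import numpy as np

# ACGT -> 0..3, everything else (N, IUPAC ambiguity, lowercase is upper-cased
# at I/O boundaries) -> -1
BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    BASE_CODE[ord(_b)] = _i

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode_seq(seq: str) -> np.ndarray:
    """Map a nucleotide string to int8 codes (A=0, C=1, G=2, T=3, other=-1)."""
    return BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def split_seed(seed: int, *labels) -> np.random.Generator:
    """Derive an independent Generator from a root seed and a label path.

    Every random draw in the package flows from one integer seed through this
    function; the label path (e.g. ``("genome", clade_id, sag_index)``) keys a
    CRC-derived child of the root SeedSequence, so adding or reordering stages
    never perturbs the streams of other stages.
    """
    key = zlib.crc32("/".join(str(x) for x in labels).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
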