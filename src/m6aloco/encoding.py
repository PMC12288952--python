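"""Sequence feature encodings: k-mer composition vectors and one-hot matrices.

Two representations feed the model family:

* **k-mer composition** — a 4^k vector counting every length-k subsequence
  in a step-1 sliding window (1024 dimensions for the default k=5).  Entries
  are indexed lexicographically over the alphabet order (A, C, G, T), i.e.
  AAAAA is index 0 and TTTTT is index 4^k - 1.  Windows containing an N
  contribute to no entry.
* **one-hot** — an L x 4 binary matrix, column order (A, C, G, T); an N
  position is an all-zero row.  The positions-by-channels orientation is the
  transpose of the channels-by-positions description sometimes used for the
  same encoding; no information differs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Dataset

BASE_ORDER = "ACGT"
_BASE_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate(BASE_ORDER):
    _BASE_CODE[ord(_b)] = _i


class EncodingError(ValueError):
    pass


@dataclass
class KmerVector:
    """4^k counts (or frequencies) of k-mers, lexicographic over (A,C,G,T)."""

    counts: np.ndarray
    k: int
    normalized: bool = False

    def kmer_index(self, kmer: str) -> int:
        if len(kmer) != self.k:
            raise EncodingError(f"k-mer {kmer!r} has length {len(kmer)}, expected {self.k}")
        idx = 0
        for c in kmer:
            code = _BASE_CODE[ord(c)] if ord(c) < 128 else -1
            if code < 0:
                raise EncodingError(f"k-mer {kmer!r} contains non-ACGT character {c!r}")
            idx = idx * 4 + code
        return int(idx)

    def __getitem__(self, kmer: str) -> float:
        return float(self.counts[self.kmer_index(kmer)])


def kmer_name(index: int, k: int) -> str:
    """Inverse of the lexicographic index: 0 -> 'A'*k, 4^k-1 -> 'T'*k."""
    if not 0 <= index < 4**k:
        raise EncodingError(f"index {index} out of range for k={k}")
    out = []
    for _ in range(k):
        out.append(BASE_ORDER[index % 4])
        index //= 4
    return "".join(reversed(out))


def _codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[arr]


def encode_kmer(seq: str, k: int = 5, normalized: bool = False) -> KmerVector:
    """Count every k-mer of ``seq`` with a step-1 sliding window.

    For an N-free sequence of length L the counts sum to L - k + 1.
    Windows overlapping an N (or any character mapped to N upstream) are
    skipped entirely.  With ``normalized=True`` counts are divided by the
    number of valid windows (when any exist).
    """
    if k <= 0:
        raise EncodingError(f"k must be positive, got {k}")
    if len(seq) < k:
        raise EncodingError(f"sequence length {len(seq)} < k={k}")
    codes = _codes(seq)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    counts = np.zeros(4**k, dtype=np.float64)
    if valid.any():
        idx = windows[valid] @ powers
        np.add.at(counts, idx, 1.0)
    if normalized:
        total = counts.sum()
        if total > 0:
            counts /= total
    return KmerVector(counts, k, normalized)


def encode_onehot(seq: str) -> np.ndarray:
    """L x 4 binary matrix, columns (A, C, G, T); N rows are all-zero."""
    if not seq:
        raise EncodingError("cannot one-hot encode an empty sequence")
    codes = _codes(seq)
    mat = np.zeros((len(seq), 4), dtype=np.float32)
    ok = codes >= 0
    mat[np.nonzero(ok)[0], codes[ok]] = 1.0
    return mat


@dataclass
class FeatureBundle:
    """Per-record feature arrays aligned with a dataset's record order."""

    ids: list[str]
    labels: np.ndarray
    kmer: np.ndarray | None = None  # (n, 4^k)
    onehot: np.ndarray | None = None  # (n, L, 4)
    k: int | None = None

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, indices: np.ndarray) -> "FeatureBundle":
        return FeatureBundle(
            ids=[self.ids[i] for i in indices],
            labels=self.labels[indices],
            kmer=None if self.kmer is None else self.kmer[indices],
            onehot=None if self.onehot is None else self.onehot[indices],
            k=self.k,
        )

    def subset_ids(self, ids) -> "FeatureBundle":
        pos = {rid: i for i, rid in enumerate(self.ids)}
        return self.subset(np.asarray([pos[r] for r in ids], dtype=np.int64))


def encode_dataset(
    ds: Dataset, scheme: str = "both", k: int = 5, normalized_kmer: bool = False
) -> FeatureBundle:
    """Encode every record of ``ds`` under ``scheme`` in {kmer, onehot, both}."""
    if scheme not in {"kmer", "onehot", "both"}:
        raise EncodingError(f"unknown scheme {scheme!r}")
    labels = np.asarray(ds.labels, dtype=np.float32)
    bundle = FeatureBundle(ids=[r.id for r in ds], labels=labels, k=k)
    errors: list[str] = []
    if scheme in {"kmer", "both"}:
        rows = []
        for r in ds:
            try:
                rows.append(encode_kmer(r.sequence, k, normalized_kmer).counts)
            except EncodingError as e:
                errors.append(f"record {r.id!r}: {e}")
        if not errors:
            bundle.kmer = np.asarray(rows, dtype=np.float32)
    if scheme in {"onehot", "both"}:
        rows = []
        for r in ds:
            try:
                rows.append(encode_onehot(r.sequence))
            except EncodingError as e:
                errors.append(f"record {r.id!r}: {e}")
        if not errors:
            bundle.onehot = np.stack(rows)
    if errors:
        raise EncodingError("encoding failed for records:\n  " + "\n  ".join(errors[:20]))
    return bundle


def export_kmer_table(bundle: FeatureBundle, path) -> None:
    """Write the k-mer array as CSV with one named column per k-mer."""
    import pandas as pd

    if bundle.kmer is None:
        raise EncodingError("bundle carries no k-mer features")
    header = [kmer_name(i, bundle.k) for i in range(4**bundle.k)]
    df = pd.DataFrame(bundle.kmer, columns=header, index=bundle.ids)
    df.insert(0, "label", bundle.labels.astype(int))
    df.to_csv(path, index_label="id")
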