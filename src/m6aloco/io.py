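"""Reading and writing labeled sequence-window datasets.

A dataset is an ordered collection of fixed-length nucleotide windows, each
carrying a record id, a chromosome label, and a binary m6A label (1 =
methylated adenosine at the window center, 0 = unmethylated control).
Two on-disk formats are supported:

* tabular (CSV/TSV) with columns ``id, chrom, sequence, label``;
* FASTA plus a BED-like three-column sidecar ``id <TAB> chrom <TAB> label``.

Sequences are normalized at the boundary: uppercased, RNA ``U`` mapped to
``T`` (the internal alphabet is DNA letters), and any other non-ACGTN
character mapped to ``N`` with a logged warning.  Wrong-length sequences are
rejected by default; a pad policy may instead center-crop or N-pad.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")
DEFAULT_COLUMNS = {"id": "id", "chrom": "chrom", "sequence": "sequence", "label": "label"}

_NORMALIZE = str.maketrans({"U": "T"})


class DatasetError(ValueError):
    """Raised for schema, domain, or consistency violations at the I/O boundary."""

    def __init__(self, message: str, record_errors: Sequence[str] = ()):
        self.record_errors = list(record_errors)
        if self.record_errors:
            message = message + "\n  " + "\n  ".join(self.record_errors)
        super().__init__(message)


@dataclass(frozen=True)
class SequenceRecord:
    """One labeled window: id, chromosome, sequence, binary label."""

    id: str
    chromosome: str
    sequence: str
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise DatasetError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")
        if not self.chromosome:
            raise DatasetError(f"record {self.id!r}: chromosome label is empty")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise DatasetError(f"record {self.id!r}: invalid characters {sorted(bad)}")


@dataclass
class Dataset:
    """Ordered collection of equal-length :class:`SequenceRecord`."""

    records: list[SequenceRecord]
    L: int
    provenance: str = ""

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dups = {i for i in ids if i in seen or seen.add(i)}
            raise DatasetError(f"duplicate record ids: {sorted(dups)[:10]}")
        bad = [r.id for r in self.records if len(r.sequence) != self.L]
        if bad:
            raise DatasetError(
                f"{len(bad)} records violate declared length L={self.L}",
                [f"record {i!r}" for i in bad[:20]],
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> list[int]:
        return [r.label for r in self.records]

    @property
    def chromosomes(self) -> list[str]:
        return [r.chromosome for r in self.records]

    def subset(self, ids: Iterable[str]) -> "Dataset":
        keep = set(ids)
        recs = [r for r in self.records if r.id in keep]
        missing = keep - {r.id for r in recs}
        if missing:
            raise DatasetError(f"unknown record ids: {sorted(missing)[:10]}")
        return Dataset(recs, self.L, self.provenance)


def normalize_sequence(seq: str, record_id: str = "?") -> str:
    """Uppercase, map U->T, and map other non-ACGTN characters to N (warned)."""
    s = seq.upper().translate(_NORMALIZE)
    bad = set(s) - VALID_ALPHABET
    if bad:
        logger.warning(
            "record %s: mapping non-ACGTN characters %s to N", record_id, sorted(bad)
        )
        s = "".join(c if c in VALID_ALPHABET else "N" for c in s)
    return s


def _apply_pad_policy(seq: str, L: int, policy: str | None, record_id: str) -> str:
    if len(seq) == L or policy is None:
        return seq
    if policy == "center-crop" and len(seq) > L:
        off = (len(seq) - L) // 2
        return seq[off : off + L]
    if policy == "n-pad" and len(seq) < L:
        pad = L - len(seq)
        left = pad // 2
        return "N" * left + seq + "N" * (pad - left)
    return seq  # still wrong length -> caught by length check


def _build_dataset(
    rows: Iterable[tuple[str, str, str, object]],
    L: int | None,
    provenance: str,
    pad_policy: str | None,
) -> Dataset:
    records: list[SequenceRecord] = []
    errors: list[str] = []
    for rid, chrom, seq, label in rows:
        try:
            lab = int(label)
        except (TypeError, ValueError):
            errors.append(f"record {rid!r}: label {label!r} is not an integer")
            continue
        if lab not in (0, 1):
            errors.append(f"record {rid!r}: label {lab} outside {{0,1}}")
            continue
        seq = normalize_sequence(str(seq), rid)
        records.append(SequenceRecord(str(rid), str(chrom), seq, lab))
    if errors:
        raise DatasetError("invalid records", errors)
    if not records:
        raise DatasetError("empty dataset: no records parsed")
    if L is None:
        L = len(records[0].sequence)
    if pad_policy is not None:
        records = [replace(r, sequence=_apply_pad_policy(r.sequence, L, pad_policy, r.id)) for r in records]
    wrong = [r.id for r in records if len(r.sequence) != L]
    if wrong:
        raise DatasetError(
            f"{len(wrong)} sequences do not match declared length L={L} "
            f"(use pad_policy='center-crop' or 'n-pad' to coerce)",
            [f"record {i!r}" for i in wrong[:20]],
        )
    return Dataset(records, L, provenance)


def read_tabular(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    L: int | None = None,
    delimiter: str | None = None,
    pad_policy: str | None = None,
) -> Dataset:
    """Load a dataset from a delimited text file with a header row.

    Parameters
    ----------
    path
        CSV or TSV file; the delimiter is sniffed from the extension/content
        unless given explicitly.
    column_map
        Maps the canonical roles ``id, chrom, sequence, label`` to the file's
        column names; defaults to those exact names.
    L
        Declared window length; inferred from the first record when omitted.
    pad_policy
        ``None`` (reject wrong lengths), ``"center-crop"`` or ``"n-pad"``.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab", ".bed"} else ","
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str)
    except pd.errors.EmptyDataError:
        raise DatasetError(f"empty dataset: {path} has no rows") from None
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise DatasetError(f"schema error: missing column(s) {missing} in {path}")
    if df.empty:
        raise DatasetError(f"empty dataset: {path} has a header but no rows")
    rows = zip(df[cols["id"]], df[cols["chrom"]], df[cols["sequence"]], df[cols["label"]])
    return _build_dataset(rows, L, f"tabular:{path.name}", pad_policy)


def read_fasta_with_labels(
    fasta: str | Path,
    labels: str | Path,
    *,
    L: int | None = None,
    pad_policy: str | None = None,
) -> Dataset:
    """Load a dataset from a FASTA file joined by id to a BED-like sidecar.

    The sidecar is a headerless, tab- or comma-separated file whose columns
    are ``id, chromosome, label``.  Every id must appear in both files.
    """
    fasta, labels = Path(fasta), Path(labels)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta), "fasta"):
        seqs[rec.id] = str(rec.seq)
    meta = pd.read_csv(labels, sep=None, engine="python", header=None, dtype=str)
    if meta.shape[1] < 3:
        raise DatasetError(f"label sidecar {labels} needs 3 columns (id, chrom, label)")
    meta_map = {str(r[0]): (str(r[1]), r[2]) for r in meta.itertuples(index=False)}
    orphans_fa = sorted(set(seqs) - set(meta_map))
    orphans_lab = sorted(set(meta_map) - set(seqs))
    if orphans_fa or orphans_lab:
        raise DatasetError(
            "join error between FASTA and label sidecar",
            [f"id only in FASTA: {i!r}" for i in orphans_fa[:10]]
            + [f"id only in labels: {i!r}" for i in orphans_lab[:10]],
        )
    rows = [(rid, meta_map[rid][0], seq, meta_map[rid][1]) for rid, seq in seqs.items()]
    return _build_dataset(rows, L, f"fasta:{fasta.name}", pad_policy)


def write_dataset(ds: Dataset, path: str | Path, fmt: str = "tabular") -> Path:
    """Write a dataset as ``tabular`` (CSV/TSV by extension) or ``fasta``.

    FASTA output is accompanied by a ``<path>.labels.tsv`` sidecar so the
    round-trip through :func:`read_fasta_with_labels` is exact.
    """
    if not ds.records:
        raise DatasetError("refusing to write an empty dataset")
    path = Path(path)
    if fmt == "tabular":
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        df = pd.DataFrame(
            {
                "id": [r.id for r in ds],
                "chrom": [r.chromosome for r in ds],
                "sequence": [r.sequence for r in ds],
                "label": [r.label for r in ds],
            }
        )
        df.to_csv(path, sep=sep, index=False)
    elif fmt == "fasta":
        bio = [BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in ds]
        SeqIO.write(bio, str(path), "fasta")
        sidecar = path.with_suffix(path.suffix + ".labels.tsv")
        with open(sidecar, "w") as fh:
            for r in ds:
                fh.write(f"{r.id}\t{r.chromosome}\t{r.label}\n")
    else:
        raise DatasetError(f"unknown format {fmt!r}; use 'tabular' or 'fasta'")
    return path
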