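"""Initial read quality control.

The first pipeline stage: discard reads containing any ``N``, collapse the
redundant (R) read list into a non-redundant (NR) sequence -> multiplicity
view, and compute two library diagnostics — the NR:R complexity ratio and
the per-base nucleotide composition matrix.

No quality trimming is performed; FASTQ quality strings are parsed and then
ignored. Variable-length reads are tolerated (composition is normalized per
position by the number of reads covering it) although the intended input is
fixed-length short reads.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ParameterError

BASES = ("A", "C", "G", "T", "N")


@dataclass
class ReadSet:
    """An ordered multiset of reads with a non-redundant view.

    ``reads`` is the redundant (R) list in input order; ``ids`` optionally
    carries one identifier per read (kept aligned through filtering).
    The NR view maps each distinct sequence to its multiplicity.
    """

    reads: list[str]
    ids: list[str] | None = None
    _nr: Counter | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.ids is not None and len(self.ids) != len(self.reads):
            raise ParameterError("ids must align one-to-one with reads")

    @property
    def nr_view(self) -> Counter:
        if self._nr is None:
            self._nr = Counter(self.reads)
        return self._nr

    @property
    def n_redundant(self) -> int:
        return len(self.reads)

    @property
    def n_nonredundant(self) -> int:
        return len(self.nr_view)

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "ReadSet":
        reads: list[str] = []
        for seq, k in counts.items():
            if k < 0:
                raise ParameterError(f"negative multiplicity for {seq!r}")
            reads.extend([seq] * int(k))
        rs = cls(reads)
        rs._nr = Counter({s: int(k) for s, k in counts.items() if k > 0})
        return rs

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class QcReport:
    input_reads: int
    accepted_reads: int
    discarded_n_reads: int
    complexity: float | None
    composition: pd.DataFrame
    composition_prefilter: pd.DataFrame

    def to_json(self, path: str | Path) -> None:
        payload = {
            "input_reads": self.input_reads,
            "accepted_reads": self.accepted_reads,
            "discarded_n_reads": self.discarded_n_reads,
            "complexity": self.complexity,
            "composition": self.composition.to_dict(orient="list"),
            "composition_prefilter": self.composition_prefilter.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _composition(reads: Sequence[str]) -> pd.DataFrame:
    """Position x base frequency matrix, normalized by coverage per position."""
    if not reads:
        return pd.DataFrame(columns=list(BASES))
    max_len = max(len(r) for r in reads)
    counts = np.zeros((max_len, len(BASES)), dtype=float)
    coverage = np.zeros(max_len, dtype=float)
    idx = {b: i for i, b in enumerate(BASES)}
    for r in reads:
        for p, b in enumerate(r):
            counts[p, idx.get(b, idx["N"])] += 1
        coverage[: len(r)] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / coverage[:, None]
    return pd.DataFrame(freq, columns=list(BASES))


def filter_reads(
    raw: Iterable[str] | Iterable[tuple[str, str]] | ReadSet,
) -> tuple[ReadSet, QcReport]:
    """Discard reads containing any N; report counts and diagnostics.

    Accepts plain sequences, ``(id, sequence)`` pairs, or a :class:`ReadSet`.
    Order of surviving reads is preserved. Empty input yields an empty
    ReadSet and an all-zero report rather than an error.
    """
    if isinstance(raw, ReadSet):
        items = list(zip(raw.ids or [None] * len(raw.reads), raw.reads))
    else:
        raw = list(raw)
        if raw and isinstance(raw[0], tuple):
            items = [(i, s) for i, s in raw]
        else:
            items = [(None, s) for s in raw]

    seqs = [s.upper() for _, s in items]
    if seqs and len({len(s) for s in seqs}) > 1:
        warnings.warn("reads have unequal lengths; composition sized to the longest")

    kept_ids: list[str] = []
    kept: list[str] = []
    for (rid, _), s in zip(items, seqs):
        if "N" not in s:
            kept.append(s)
            kept_ids.append(rid)
    have_ids = any(i is not None for i, _ in items)
    rs = ReadSet(kept, ids=kept_ids if have_ids else None)
    comp_post = _composition(kept)
    report = QcReport(
        input_reads=len(seqs),
        accepted_reads=len(kept),
        discarded_n_reads=len(seqs) - len(kept),
        complexity=complexity(rs) if kept else None,
        composition=comp_post,
        composition_prefilter=_composition(seqs),
    )
    return rs, report


def collapse(reads: Iterable[str] | ReadSet) -> Counter:
    """Collapse a redundant read list into the NR sequence -> multiplicity map."""
    if isinstance(reads, ReadSet):
        return Counter(reads.nr_view)
    return Counter(reads)


def complexity(readset: ReadSet | Iterable[str]) -> float:
    """NR:R ratio, a library-diversity diagnostic in (0, 1]."""
    if not isinstance(readset, ReadSet):
        readset = ReadSet(list(readset))
    if readset.n_redundant == 0:
        raise ParameterError("complexity undefined on an empty read set")
    return readset.n_nonredundant / readset.n_redundant


def base_composition(readset: ReadSet | Iterable[str]) -> pd.DataFrame:
    """Fraction of reads carrying each base at each position."""
    reads = readset.reads if isinstance(readset, ReadSet) else list(readset)
    return _composition(reads)


# ---------------------------------------------------------------------------
# File I/O


def read_sequences(path: str | Path, fmt: str | None = None) -> ReadSet:
    """Load reads from FASTQ or FASTA (extension-sniffed unless ``fmt`` given)."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), fmt):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return ReadSet(seqs, ids=ids or None)


def write_fasta(readset: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(readset.reads):
            rid = readset.ids[i] if readset.ids else f"read_{i + 1}"
            fh.write(f">{rid}\n{seq}\n")


def write_collapsed_fasta(nr_view: Mapping[str, int], path: str | Path) -> None:
    """Write the NR view with multiplicity encoded in headers (>seq_<i>_x<count>)."""
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(nr_view.items(), start=1):
            fh.write(f">seq_{i}_x{count}\n{seq}\n")


def read_collapsed_fasta(path: str | Path) -> Counter:
    """Inverse of :func:`write_collapsed_fasta`; multiplicity parsed from headers."""
    nr: Counter = Counter()
    for rec in SeqIO.parse(str(path), "fasta"):
        count = 1
        if "_x" in rec.id:
            try:
                count = int(rec.id.rsplit("_x", 1)[1])
            except ValueError:
                count = 1
        nr[str(rec.seq).upper()] += count
    return nr
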