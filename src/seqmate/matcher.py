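"""Deterministic ungapped short-read matching with at most one mismatch.

Implements the mapping contract of the expression pipeline: a read matches a
transcript window iff the full-length, ungapped Hamming distance is <= 1.
Matching is exhaustive — every qualifying (target, offset, strand) is
reported — via half-read pigeonhole seeding: any window within Hamming
distance 1 of the read contains at least one of the read's two halves
exactly, so an exact-lookup table over target substrings can never miss a
hit. No heuristics, no scoring.

Coordinates are 0-based on the target forward strand internally; exported
text formats use 1-based offsets and say so in their headers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .errors import ParameterError
from .read_qc import ReadSet

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Hit:
    """One full-length ungapped match of a read to a target window."""

    read_id: str
    target_id: str
    offset: int  # 0-based on the target forward strand
    strand: str  # '+' or '-'
    mismatches: int


@dataclass
class MatchIndex:
    """Exact-lookup seed tables over all target substrings of the two half lengths."""

    targets: dict[str, str]
    read_length: int
    seed_len_a: int = field(init=False)
    seed_len_b: int = field(init=False)
    _seeds_a: dict = field(init=False, repr=False)
    _seeds_b: dict = field(init=False, repr=False)

    def __post_init__(self):
        L = self.read_length
        self.seed_len_a = (L + 1) // 2
        self.seed_len_b = L - self.seed_len_a
        self._seeds_a = self._build_table(self.seed_len_a)
        self._seeds_b = (
            self._seeds_a
            if self.seed_len_b == self.seed_len_a
            else self._build_table(self.seed_len_b)
        )

    def _build_table(self, k: int) -> dict[str, list[tuple[str, int]]]:
        table: dict[str, list[tuple[str, int]]] = {}
        for tid, seq in self.targets.items():
            for pos in range(len(seq) - k + 1):
                table.setdefault(seq[pos : pos + k], []).append((tid, pos))
        return table

    def lookup_a(self, seed: str) -> list[tuple[str, int]]:
        return self._seeds_a.get(seed, [])

    def lookup_b(self, seed: str) -> list[tuple[str, int]]:
        return self._seeds_b.get(seed, [])


def build_index(
    targets: Mapping[str, str] | Iterable[tuple[str, str]], read_length: int
) -> MatchIndex:
    """Index targets for exact half-seed lookup at the given read length.

    Targets shorter than ``read_length`` cannot host a full-length hit and
    are excluded with a warning.
    """
    if read_length < 2:
        raise ParameterError("read_length must be >= 2")
    items = dict(targets.items() if isinstance(targets, Mapping) else targets)
    usable, short = {}, []
    for tid, seq in items.items():
        seq = seq.upper()
        if len(seq) < read_length:
            short.append(tid)
        else:
            usable[tid] = seq
    if short:
        warnings.warn(
            f"{len(short)} target(s) shorter than read_length excluded: {short[:5]}"
        )
    return MatchIndex(usable, read_length)


def _hamming_le(a: str, b: str, limit: int) -> int:
    """Hamming distance if <= limit, else limit + 1 (early exit)."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def _candidate_windows(read: str, index: MatchIndex) -> set[tuple[str, int]]:
    la = index.seed_len_a
    cands: set[tuple[str, int]] = set()
    for tid, pos in index.lookup_a(read[:la]):
        cands.add((tid, pos))
    for tid, pos in index.lookup_b(read[la:]):
        cands.add((tid, pos - la))
    return cands


def match_read(
    read: str,
    index: MatchIndex,
    read_id: str = "read",
    max_mismatch: int = 1,
    strands: str = "both",
) -> list[Hit]:
    """All (target, offset, strand) windows within ``max_mismatch`` of the read.

    Output is sorted by (target_id, offset, strand) with no duplicates.
    ``strands`` is ``"both"`` (default; the reverse complement of the read is
    also searched) or ``"forward"``.
    """
    read = read.upper()
    if len(read) != index.read_length:
        raise ParameterError(
            f"read length {len(read)} != index read_length {index.read_length}"
        )
    if "N" in read:
        raise ParameterError("reads must be N-free before matching")
    if max_mismatch not in (0, 1):
        raise ParameterError(
            "half-seed index guarantees completeness only for max_mismatch <= 1"
        )
    if strands not in ("both", "forward"):
        raise ParameterError("strands must be 'both' or 'forward'")

    L = index.read_length
    queries = [(read, "+")]
    if strands == "both":
        queries.append((revcomp(read), "-"))

    hits: list[Hit] = []
    for query, strand in queries:
        for tid, start in _candidate_windows(query, index):
            tseq = index.targets[tid]
            if start < 0 or start + L > len(tseq):
                continue
            d = _hamming_le(query, tseq[start : start + L], max_mismatch)
            if d <= max_mismatch:
                hits.append(Hit(read_id, tid, start, strand, d))
    return sorted(set(hits), key=lambda h: (h.target_id, h.offset, h.strand))


def exclude_rrna(
    readset: ReadSet, rrna_index: MatchIndex, max_mismatch: int = 1
) -> tuple[ReadSet, ReadSet]:
    """Partition reads into (retained, excluded-as-rRNA) multisets.

    A read is excluded iff it has at least one hit to any rRNA target under
    the standard contract. The two outputs partition the input exactly.
    """
    verdict: dict[str, bool] = {}
    for seq in readset.nr_view:
        verdict[seq] = bool(match_read(seq, rrna_index, max_mismatch=max_mismatch))
    keep_reads, keep_ids, drop_reads, drop_ids = [], [], [], []
    for i, seq in enumerate(readset.reads):
        rid = readset.ids[i] if readset.ids else None
        if verdict[seq]:
            drop_reads.append(seq)
            drop_ids.append(rid)
        else:
            keep_reads.append(seq)
            keep_ids.append(rid)
    has_ids = readset.ids is not None
    return (
        ReadSet(keep_reads, ids=keep_ids if has_ids else None),
        ReadSet(drop_reads, ids=drop_ids if has_ids else None),
    )


# ---------------------------------------------------------------------------
# File I/O


def read_fasta_targets(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_hits_tsv(hits: Iterable[Hit], path: str | Path) -> None:
    """TSV export; offsets are 1-based here (stated in the header)."""
    with open(path, "w") as fh:
        fh.write("read_id\ttarget_id\toffset_1based\tstrand\tmismatches\n")
        for h in hits:
            fh.write(f"{h.read_id}\t{h.target_id}\t{h.offset + 1}\t{h.strand}\t{h.mismatches}\n")


def write_hits_sam(
    hits: Iterable[Hit], targets: Mapping[str, str], reads: Mapping[str, str],
    path: str | Path,
) -> None:
    """Minimal unsorted SAM (flags 0/16, NM tag); for interoperability only."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for tid, seq in targets.items():
            fh.write(f"@SQ\tSN:{tid}\tLN:{len(seq)}\n")
        for h in hits:
            seq = reads[h.read_id]
            flag = 0 if h.strand == "+" else 16
            out_seq = seq if h.strand == "+" else revcomp(seq)
            fh.write(
                f"{h.read_id}\t{flag}\t{h.target_id}\t{h.offset + 1}\t255\t"
                f"{len(seq)}M\t*\t0\t0\t{out_seq}\t*\tNM:i:{h.mismatches}\n"
            )
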