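"""Synthetic inputs with known ground truth for every pipeline stage.

Generates (i) a toy transcriptome with a flagged rRNA contaminant subset,
(ii) 50-nt single-end reads sampled from it with per-base substitution
errors and N dropouts, (iii) overdispersed negative-binomial count matrices
for a two-tissue, two-regime, replicated design with a known DE fraction
and fold change, and (iv) multiple-choice mating trials driven by a known
pairing-propensity matrix with sequential removal of mated individuals.

Every generator takes an explicit seed and is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .mating import MatingTable
from .normalization import ExpressionMatrix
from .read_qc import ReadSet

_BASES = np.array(list("ACGT"))


@dataclass
class ToyTranscriptome:
    """A small reference transcript set; a subset of ids is flagged as rRNA."""

    records: list[tuple[str, str]]
    rrna_ids: frozenset[str]

    def __post_init__(self):
        ids = [i for i, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ParameterError("transcript ids must be unique")
        if any(not s for _, s in self.records):
            raise ParameterError("sequences must be non-empty")
        if not self.rrna_ids <= set(ids):
            raise ParameterError("rrna_ids must be a subset of record ids")

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def as_dict(self) -> dict[str, str]:
        return dict(self.records)

    def mrna_records(self) -> dict[str, str]:
        return {i: s for i, s in self.records if i not in self.rrna_ids}

    def rrna_records(self) -> dict[str, str]:
        return {i: s for i, s in self.records if i in self.rrna_ids}

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tid, seq in self.records:
                tag = " rRNA" if tid in self.rrna_ids else ""
                fh.write(f">{tid}{tag}\n{seq}\n")


@dataclass
class CountTruth:
    """Ground truth behind a simulated count matrix."""

    de_labels: np.ndarray  # bool per gene
    true_log2_fc: np.ndarray  # signed; 0 for non-DE genes
    group_means: pd.DataFrame  # gene x regime expected counts at lib_size
    dispersion: float


def make_transcriptome(
    n_transcripts: int,
    length_range: tuple[int, int],
    rrna_fraction: float,
    seed: int,
) -> ToyTranscriptome:
    """Random transcript set; round(n * rrna_fraction) records flagged rRNA."""
    if n_transcripts < 1:
        raise ParameterError("n_transcripts must be positive")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ParameterError(f"invalid length range {length_range}")
    if not 0 <= rrna_fraction < 1:
        raise ParameterError("rrna_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_BASES, size=length))
        records.append((f"tx_{i + 1:04d}", seq))
    n_rrna = round(n_transcripts * rrna_fraction)
    rrna = rng.choice(n_transcripts, size=n_rrna, replace=False)
    rrna_ids = frozenset(records[int(k)][0] for k in rrna)
    return ToyTranscriptome(records, rrna_ids)


def make_reads(
    tx: ToyTranscriptome,
    abundances: Mapping[str, float] | Sequence[float],
    n_reads: int,
    read_length: int = 50,
    mismatch_rate: float = 0.0,
    n_rate: float = 0.0,
    seed: int = 0,
) -> tuple[ReadSet, pd.DataFrame]:
    """Sample reads from transcripts with effective-length weighting.

    A read starts uniformly within its source transcript; source transcripts
    are drawn with probability proportional to abundance * (length - L + 1).
    Substitution errors (to a *different* base) are applied per base at
    ``mismatch_rate``, then N replacement at ``n_rate`` — an N never counts
    as a substitution in the truth table. Truth rows (read_id, source_id,
    offset, n_mismatches, has_n) align one-to-one with the returned reads.
    """
    if n_reads < 1:
        raise ParameterError("n_reads must be positive")
    ids = tx.ids
    seqs = tx.as_dict()
    if not isinstance(abundances, Mapping):
        if len(abundances) != len(ids):
            raise ParameterError("abundance vector length must match transcript count")
        abundances = dict(zip(ids, abundances))
    ab = np.array([float(abundances.get(t, 0.0)) for t in ids])
    if (ab < 0).any():
        raise ParameterError("abundances must be non-negative")
    lengths = np.array([len(seqs[t]) for t in ids])
    if (lengths < read_length).any():
        short = [t for t, L in zip(ids, lengths) if L < read_length]
        raise ParameterError(
            f"read_length {read_length} exceeds transcript(s) {short[:5]}"
        )
    weights = ab * (lengths - read_length + 1)
    if weights.sum() == 0:
        raise ParameterError("abundance weights are all zero")

    rng = np.random.default_rng(seed)
    sources = rng.choice(len(ids), size=n_reads, p=weights / weights.sum())
    reads, rows = [], []
    for r, src in enumerate(sources):
        tid = ids[int(src)]
        offset = int(rng.integers(0, lengths[int(src)] - read_length + 1))
        base = np.array(list(seqs[tid][offset : offset + read_length]))
        n_mm = 0
        if mismatch_rate > 0:
            flip = rng.random(read_length) < mismatch_rate
            for p in np.flatnonzero(flip):
                choices = _BASES[_BASES != base[p]]
                base[p] = rng.choice(choices)
            n_mm = int(flip.sum())
        has_n = False
        if n_rate > 0:
            dropn = rng.random(read_length) < n_rate
            base[dropn] = "N"
            has_n = bool(dropn.any())
        rid = f"read_{r + 1:06d}"
        reads.append("".join(base))
        rows.append(
            {"read_id": rid, "source_id": tid, "offset": offset,
             "n_mismatches": n_mm, "has_n": has_n}
        )
    truth = pd.DataFrame(rows)
    return ReadSet(reads, ids=[r["read_id"] for r in rows]), truth


def make_counts(
    n_genes: int,
    design: Sequence[tuple[str, str, int]],
    lib_size: int,
    dispersion: float,
    de_fraction: float,
    lfc: float,
    seed: int,
    base_mean_sigma: float = 1.0,
) -> tuple[ExpressionMatrix, CountTruth]:
    """Negative-binomial count matrix with a planted DE fraction.

    ``design`` lists (tissue, regime, replicate) per sample; at least two
    regimes are required. Exactly round(n_genes * de_fraction) genes get a
    true |log2 fold change| of ``lfc`` between regimes with random sign;
    the rest are null. The NB parameterization is
    variance = mean + dispersion * mean^2 (dispersion -> 0 is Poisson).
    Per-sample expected counts are the per-regime relative abundances
    scaled to ``lib_size``; the returned matrix carries state
    ``subsampled`` (all samples share one nominal depth).
    """
    if not design:
        raise ParameterError("design must be non-empty")
    if not 0 <= de_fraction <= 1:
        raise ParameterError("de_fraction must be in [0, 1]")
    if dispersion < 0:
        raise ParameterError("dispersion must be non-negative")
    regimes = sorted({r for _, r, _ in design})
    if len(regimes) < 2:
        raise ParameterError("design needs at least two regimes")

    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=base_mean_sigma, size=n_genes)
    n_de = round(n_genes * de_fraction)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    de_labels = np.zeros(n_genes, dtype=bool)
    de_labels[de_idx] = True
    signs = rng.choice([-1.0, 1.0], size=n_genes)
    true_lfc = np.where(de_labels, signs * lfc, 0.0)

    # split the fold change symmetrically around the base mean between the
    # first two regimes; extra regimes (if any) sit at the base level
    means = {}
    for r in regimes:
        means[r] = base.copy()
    means[regimes[0]] = base * np.exp2(true_lfc / 2.0)
    means[regimes[1]] = base * np.exp2(-true_lfc / 2.0)
    group_means = pd.DataFrame(
        {r: lib_size * means[r] / means[r].sum() for r in regimes},
        index=[f"g_{i + 1:05d}" for i in range(n_genes)],
    )

    sample_ids, meta_rows, cols = [], [], {}
    for tissue, regime, rep in design:
        sid = f"{tissue}_{regime}_{rep}"
        if sid in cols:
            raise ParameterError(f"duplicate design row {sid}")
        mu = group_means[regime].to_numpy()
        if dispersion == 0:
            counts = rng.poisson(mu)
        else:
            size = 1.0 / dispersion
            p = size / (size + mu)
            counts = rng.negative_binomial(size, p)
        cols[sid] = counts.astype(float)
        sample_ids.append(sid)
        meta_rows.append({"tissue": tissue, "regime": regime, "replicate": rep})
    values = pd.DataFrame(cols, index=group_means.index)
    meta = pd.DataFrame(meta_rows, index=sample_ids)
    em = ExpressionMatrix(values, meta, state="subsampled")
    truth = CountTruth(de_labels, true_lfc, group_means, dispersion)
    return em, truth


def make_mating_experiment(
    avail_females: Sequence[int],
    avail_males: Sequence[int],
    alpha: np.ndarray,
    types: Sequence[str] = ("A", "S"),
    max_pairs: int = 25,
    seed: int = 0,
) -> tuple[MatingTable, np.ndarray]:
    """Sequential multiple-choice mating trial under a propensity matrix.

    At each step a pair (female type i, male type j) forms with probability
    proportional to remaining_females_i * remaining_males_j * alpha[i, j];
    both individuals are removed. Sampling stops after ``max_pairs`` pairs,
    or earlier (with ``stopped_early`` flagged on the table) if every
    propensity-weighted product is zero. ``alpha`` all-ones is random
    mating. Returns the table plus the true alpha.
    """
    alpha = np.asarray(alpha, dtype=float)
    K = len(types)
    fem = np.asarray(avail_females, dtype=np.int64).copy()
    mal = np.asarray(avail_males, dtype=np.int64).copy()
    if alpha.shape != (K, K):
        raise ParameterError("alpha must be K x K for K types")
    if (alpha < 0).any() or not (alpha > 0).any():
        raise ParameterError("alpha must be non-negative with at least one positive entry")
    if max_pairs < 0:
        raise ParameterError("max_pairs must be non-negative")
    if max_pairs > min(fem.sum(), mal.sum()):
        raise ParameterError("max_pairs exceeds the available individuals")

    rng = np.random.default_rng(seed)
    pairs = np.zeros((K, K), dtype=np.int64)
    stopped_early = False
    for _ in range(max_pairs):
        w = fem[:, None] * mal[None, :] * alpha
        total = w.sum()
        if total == 0:
            stopped_early = True
            break
        flat = rng.choice(K * K, p=(w / total).ravel())
        i, j = divmod(int(flat), K)
        pairs[i, j] += 1
        fem[i] -= 1
        mal[j] -= 1
    table = MatingTable(
        types=list(types),
        avail_females=np.asarray(avail_females, dtype=np.int64),
        avail_males=np.asarray(avail_males, dtype=np.int64),
        pairs=pairs,
        stopped_early=stopped_early,
    )
    return table, alpha


# ---------------------------------------------------------------------------
# Writers for file-based entry points


def write_fastq(readset: ReadSet, path: str | Path, quality_char: str = "I") -> None:
    """Constant-quality FASTQ (no quality simulation by design)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(readset.reads):
            rid = readset.ids[i] if readset.ids else f"read_{i + 1}"
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_truth_json(truth: pd.DataFrame | CountTruth, path: str | Path) -> None:
    import json

    if isinstance(truth, CountTruth):
        payload = {
            "de_labels": truth.de_labels.tolist(),
            "true_log2_fc": truth.true_log2_fc.tolist(),
            "group_means": truth.group_means.to_dict(orient="list"),
            "dispersion": truth.dispersion,
        }
    else:
        payload = truth.to_dict(orient="records")
    Path(path).write_text(json.dumps(payload))
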