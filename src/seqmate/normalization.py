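"""Subsampling normalization, incidence-sum quantification, quantile normalization.

The expression half of the pipeline normalizes by *depth*, not by scaling:
each sample's filtered reads are subsampled without replacement down to a
common fixed total (the minimum post-filter depth across samples), so
per-transcript abundances are directly comparable counts. Per-transcript
abundance is the algebraic sum of the multiplicities of all distinct reads
incident to the transcript; a multi-mapping read contributes its full
multiplicity to every transcript it hits. Residual distributional
differences between samples are then removed by quantile normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DepthError, IntegrityError, ParameterError
from .matcher import Hit
from .read_qc import ReadSet

_STATE_ORDER = {"raw": 0, "subsampled": 1, "quantile_normalized": 2}


@dataclass
class ExpressionMatrix:
    """Transcripts x samples abundance matrix with sample metadata.

    ``values`` is indexed by transcript id with one column per sample;
    ``sample_meta`` is indexed by sample id with columns ``tissue``,
    ``regime`` and ``replicate``. ``state`` records the normalization stage
    and may only move forward (raw -> subsampled -> quantile_normalized).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    state: str = "raw"

    def __post_init__(self):
        if self.state not in _STATE_ORDER:
            raise ParameterError(f"unknown state {self.state!r}")
        if (self.values.values < 0).any():
            raise IntegrityError("expression values must be non-negative")
        if self.values.index.has_duplicates:
            raise IntegrityError("transcript ids must be unique")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise IntegrityError(f"samples missing from metadata: {sorted(missing)}")

    def advance_state(self, new_state: str) -> None:
        if _STATE_ORDER[new_state] < _STATE_ORDER[self.state]:
            raise IntegrityError(
                f"state may only move forward ({self.state} -> {new_state})"
            )
        self.state = new_state

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(samples)].copy(),
            self.sample_meta.loc[list(samples)].copy(),
            state=self.state,
        )

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, counts_path: str | Path, meta_path: str | Path | None = None) -> None:
        out = self.values.copy()
        out.index.name = "transcript_id"
        out.to_csv(counts_path, sep="\t")
        if meta_path is not None:
            meta = self.sample_meta.copy()
            meta.index.name = "sample_id"
            meta.to_csv(meta_path, sep="\t")

    @classmethod
    def from_tsv(
        cls, counts_path: str | Path, meta_path: str | Path, state: str = "raw"
    ) -> "ExpressionMatrix":
        values = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(values, meta, state=state)


def subsample_reads(readset: ReadSet, target_total: int, seed: int) -> ReadSet:
    """Subsample without replacement down to exactly ``target_total`` reads.

    Implemented as a single multivariate hypergeometric draw over the NR
    view — statistically identical to shuffling the redundant list and
    truncating, without materializing it.
    """
    if target_total < 0:
        raise ParameterError("target_total must be non-negative")
    if target_total > readset.n_redundant:
        raise DepthError(
            f"target_total {target_total} exceeds available depth "
            f"{readset.n_redundant}"
        )
    rng = np.random.default_rng(seed)
    seqs = list(readset.nr_view.keys())
    counts = np.array([readset.nr_view[s] for s in seqs], dtype=np.int64)
    if target_total == readset.n_redundant:
        drawn = counts
    elif len(counts) == 0:
        drawn = counts
    else:
        drawn = rng.multivariate_hypergeometric(counts, target_total)
    return ReadSet.from_counts({s: int(k) for s, k in zip(seqs, drawn) if k > 0})


def quantify(
    hits: Iterable[Hit],
    nr_view: Mapping[str, int],
    transcript_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Per-transcript abundance: sum of multiplicities of incident distinct reads.

    ``nr_view`` maps read identifiers (as used in the hits) to multiplicity.
    A read hitting a transcript at several offsets counts once for that
    transcript; a read hitting k transcripts contributes its full
    multiplicity to each. Transcripts with no hits get 0.
    """
    incident: dict[str, set[str]] = {}
    for h in hits:
        if h.read_id not in nr_view:
            raise IntegrityError(f"hit references unknown read {h.read_id!r}")
        incident.setdefault(h.target_id, set()).add(h.read_id)
    abundance = {
        t: float(sum(nr_view[r] for r in reads)) for t, reads in incident.items()
    }
    if transcript_ids is None:
        transcript_ids = sorted(abundance)
    return pd.Series(
        [abundance.get(t, 0.0) for t in transcript_ids],
        index=list(transcript_ids),
        name="abundance",
        dtype=float,
    )


def quantify_matrix(
    per_sample_hits: Mapping[str, Iterable[Hit]],
    per_sample_nr: Mapping[str, Mapping[str, int]],
    transcript_ids: Sequence[str],
    sample_meta: pd.DataFrame,
    state: str = "subsampled",
) -> ExpressionMatrix:
    """Assemble an ExpressionMatrix from per-sample hits and NR views."""
    cols = {
        s: quantify(per_sample_hits[s], per_sample_nr[s], transcript_ids)
        for s in sample_meta.index
    }
    values = pd.DataFrame(cols, index=list(transcript_ids))
    return ExpressionMatrix(values, sample_meta, state=state)


def quantile_normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common per-rank mean distribution.

    After the transform the sorted value vector of every sample equals the
    per-rank mean of the input's sorted columns. Ties within a sample
    receive the mean of the normalized values across their tied ranks, so
    within-sample rank order (with ties) is preserved.
    """
    arr = df.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        return df.copy()
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = ref
        # average over tied blocks so equal inputs stay equal
        ties = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = ties.to_numpy()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize an expression matrix, advancing its state."""
    if matrix.values.shape[1] < 2:
        import warnings

        warnings.warn("single sample: quantile normalization is a no-op")
        result = ExpressionMatrix(
            matrix.values.copy(), matrix.sample_meta.copy(), state=matrix.state
        )
        result.advance_state("quantile_normalized")
        return result
    normed = quantile_normalize_frame(matrix.values)
    result = ExpressionMatrix(normed, matrix.sample_meta.copy(), state=matrix.state)
    result.advance_state("quantile_normalized")
    return result


def write_normalization_log(
    path: str | Path,
    depths: Mapping[str, int],
    target: int,
    seed: int,
) -> None:
    Path(path).write_text(
        json.dumps({"depths": dict(depths), "target": target, "seed": seed}, indent=2)
    )
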