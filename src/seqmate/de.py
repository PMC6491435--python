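"""Offset-fold-change differential expression calling.

DE between two treatment groups is threshold-based, not p-value-based. The
effect size is the log2 offset fold change OFC(a, b) = log2((a + c)/(b + c))
with a small additive offset c (default 20) that damps ratios between
low-abundance values. Per-group replicate abundances are summarized as
maximal intervals (the min-max envelope); a transcript is called DE iff the
two group intervals are disjoint AND the OFC computed between the two
nearest interval bounds exceeds the threshold in magnitude. This
conservative-bound call is deliberately stricter than comparing group
means; the mean-based OFC is reported alongside as a point estimate.

A hierarchical variant first splits samples by tissue, applies the noise
floor and the DE call within each tissue, and labels each transcript as
tissue-specific or shared depending on where it clears the floor.

No multiple-testing correction is applied anywhere: the procedure has no
p-values to correct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, ParameterError
from .normalization import ExpressionMatrix, _STATE_ORDER


@dataclass
class DEConfig:
    """Tunable thresholds of the DE procedure (all in abundance or log2 units)."""

    offset: float = 20.0
    ofc_threshold: float = 1.0  # log2 units; 1 == 2-fold
    noise_floor: float = 100.0
    refgene_abundance_min: float = 500_000.0
    refgene_de_tol: float = 0.0001  # log2 units

    def __post_init__(self):
        for name in ("offset", "ofc_threshold", "noise_floor", "refgene_abundance_min"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.refgene_de_tol < 0:
            raise ParameterError("refgene_de_tol must be non-negative")


@dataclass
class DEResult:
    transcript_id: str
    tissue: str | None
    conservative_log2_ofc: float
    point_log2_ofc: float
    direction: str  # 'up_in_<group>' or 'none'
    intervals: dict[str, tuple[float, float]]
    de_call: bool
    expression_class: str | None = None  # 'tissue_specific' | 'shared'


def offset_fold_change(a: float, b: float, offset: float = 20.0) -> float:
    """log2((a + offset) / (b + offset)); antisymmetric in (a, b)."""
    if offset <= 0:
        raise ParameterError("offset must be positive")
    return float(np.log2((a + offset) / (b + offset)))


def noise_filter(
    matrix: ExpressionMatrix, noise_floor: float = 100.0
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop transcripts below the floor in *every* sample.

    A transcript expressed above the floor in even one sample is kept, so
    genes restricted to one condition or tissue survive.
    """
    if _STATE_ORDER[matrix.state] < _STATE_ORDER["subsampled"]:
        raise ParameterError("noise filtering requires a depth-normalized matrix")
    below_everywhere = (matrix.values < noise_floor).all(axis=1)
    dropped = list(matrix.values.index[below_everywhere])
    kept = ExpressionMatrix(
        matrix.values.loc[~below_everywhere].copy(),
        matrix.sample_meta.copy(),
        state=matrix.state,
    )
    return kept, dropped


def group_interval(values: Sequence[float]) -> tuple[float, float]:
    """Min-max envelope over biological replicates."""
    vals = list(values)
    if not vals:
        raise ParameterError("group_interval requires at least one replicate")
    return (float(min(vals)), float(max(vals)))


def call_de(
    matrix: ExpressionMatrix,
    grouping: Mapping[str, str] | pd.Series | None = None,
    config: DEConfig | None = None,
    tissue: str | None = None,
) -> list[DEResult]:
    """Two-group DE call on replicate min-max intervals.

    ``grouping`` maps sample id -> group label; defaults to the ``regime``
    column of the sample metadata. Exactly two groups are required, each
    with at least one replicate.
    """
    config = config or DEConfig()
    if grouping is None:
        grouping = matrix.sample_meta["regime"]
    grouping = pd.Series(grouping)
    groups = sorted(grouping.unique())
    if len(groups) != 2:
        raise DesignError(f"exactly 2 groups required, got {groups}")
    g1, g2 = groups
    cols1 = [s for s in matrix.values.columns if grouping[s] == g1]
    cols2 = [s for s in matrix.values.columns if grouping[s] == g2]
    if not cols1 or not cols2:
        raise DesignError("each group needs at least one replicate")

    v1 = matrix.values[cols1].to_numpy(dtype=float)
    v2 = matrix.values[cols2].to_numpy(dtype=float)
    lo1, hi1 = v1.min(axis=1), v1.max(axis=1)
    lo2, hi2 = v2.min(axis=1), v2.max(axis=1)
    m1, m2 = v1.mean(axis=1), v2.mean(axis=1)

    c = config.offset
    # conservative OFC between the two nearest interval bounds:
    # if group 1 sits higher, its low bound vs group 2's high bound, else
    # the mirror image (sign then comes out negative).
    g1_higher = m1 >= m2
    conservative = np.where(
        g1_higher,
        np.log2((lo1 + c) / (hi2 + c)),
        np.log2((hi1 + c) / (lo2 + c)),
    )
    point = np.log2((m1 + c) / (m2 + c))
    disjoint = (lo1 > hi2) | (lo2 > hi1)
    de = disjoint & (np.abs(conservative) > config.ofc_threshold)

    results = []
    for i, tid in enumerate(matrix.values.index):
        if de[i]:
            direction = f"up_in_{g1}" if conservative[i] > 0 else f"up_in_{g2}"
        else:
            direction = "none"
        results.append(
            DEResult(
                transcript_id=tid,
                tissue=tissue,
                conservative_log2_ofc=float(conservative[i]),
                point_log2_ofc=float(point[i]),
                direction=direction,
                intervals={
                    g1: (float(lo1[i]), float(hi1[i])),
                    g2: (float(lo2[i]), float(hi2[i])),
                },
                de_call=bool(de[i]),
            )
        )
    return results


def hierarchical_de(
    matrix: ExpressionMatrix, config: DEConfig | None = None
) -> dict[str, list[DEResult]]:
    """Tissue-then-treatment DE: noise filter and two-group call per tissue.

    ``expression_class`` is ``shared`` iff the transcript clears the noise
    floor in every tissue, else ``tissue_specific``.
    """
    config = config or DEConfig()
    meta = matrix.sample_meta
    for col in ("tissue", "regime"):
        if col not in meta.columns:
            raise DesignError(f"sample metadata lacks {col!r}")
    tissues = sorted(meta["tissue"].unique())

    kept_ids: dict[str, set[str]] = {}
    filtered: dict[str, ExpressionMatrix] = {}
    for t in tissues:
        samples = list(meta.index[meta["tissue"] == t])
        sub = matrix.subset_samples(samples)
        regimes = sub.sample_meta["regime"].unique()
        if len(regimes) < 2:
            raise DesignError(f"tissue {t!r} lacks both regimes")
        kept, _ = noise_filter(sub, config.noise_floor)
        filtered[t] = kept
        kept_ids[t] = set(kept.values.index)

    shared = set.intersection(*kept_ids.values()) if kept_ids else set()
    out: dict[str, list[DEResult]] = {}
    for t in tissues:
        results = call_de(filtered[t], config=config, tissue=t)
        for r in results:
            r.expression_class = (
                "shared" if r.transcript_id in shared else "tissue_specific"
            )
        out[t] = results
    return out


def select_reference_genes(
    matrix: ExpressionMatrix, config: DEConfig | None = None
) -> list[str]:
    """Screen for constitutively, highly expressed reference transcripts.

    A transcript qualifies iff its abundance exceeds the reference floor in
    every sample of every tissue AND its mean-based OFC is within tolerance
    both between regimes (within each tissue) and between tissues.
    """
    config = config or DEConfig()
    meta = matrix.sample_meta
    tissues = sorted(meta["tissue"].unique())
    if len(tissues) < 2:
        raise DesignError("reference-gene screen requires both tissues")

    high = (matrix.values > config.refgene_abundance_min).all(axis=1)
    candidates = matrix.values.index[high]
    selected = []
    for tid in candidates:
        row = matrix.values.loc[tid]
        ok = True
        for t in tissues:
            tsamples = meta.index[meta["tissue"] == t]
            regimes = sorted(meta.loc[tsamples, "regime"].unique())
            means = [
                row[meta.index[(meta["tissue"] == t) & (meta["regime"] == r)]].mean()
                for r in regimes
            ]
            for i in range(len(means)):
                for j in range(i + 1, len(means)):
                    if abs(offset_fold_change(means[i], means[j], config.offset)) > config.refgene_de_tol:
                        ok = False
        tissue_means = [row[meta.index[meta["tissue"] == t]].mean() for t in tissues]
        for i in range(len(tissue_means)):
            for j in range(i + 1, len(tissue_means)):
                if abs(offset_fold_change(tissue_means[i], tissue_means[j], config.offset)) > config.refgene_de_tol:
                    ok = False
        if ok:
            selected.append(tid)
    return selected


def results_to_frame(results: Sequence[DEResult] | Mapping[str, Sequence[DEResult]]) -> pd.DataFrame:
    """Flatten DE results (optionally per-tissue) into one tidy table."""
    if isinstance(results, Mapping):
        flat = [r for rs in results.values() for r in rs]
    else:
        flat = list(results)
    rows = []
    for r in flat:
        row = {
            "transcript_id": r.transcript_id,
            "tissue": r.tissue,
            "conservative_log2_ofc": r.conservative_log2_ofc,
            "point_log2_ofc": r.point_log2_ofc,
            "direction": r.direction,
            "de_call": r.de_call,
            "expression_class": r.expression_class,
        }
        for g, (lo, hi) in r.intervals.items():
            row[f"{g}_lo"], row[f"{g}_hi"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)
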