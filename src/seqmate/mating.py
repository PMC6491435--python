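"""Cross-product mate-choice statistics with bootstrap significance.

A multiple-choice mating trial records, for each (female type, male type)
cell, the number of mated pairs observed, together with the numbers of
available individuals per type and sex. From the K x K pair-count matrix
``n`` (rows = female type, columns = male type; total T) three expected
matrices are derived:

* ``e``  — expected pairs under fully random mating from the available
  pools: e_ij = T * (f_i / sum f) * (m_j / sum m);
* ``s``  — expected pairs under random pairing given the *mated* marginals:
  s_ij = rowsum_i * colsum_j / T.

The per-cell cross-product coefficients partition total deviation from
random mating (PTI = n/e) into sexual isolation (PSI = n/s) and sexual
selection (PSS = s/e); PTI = PSI * PSS wherever defined. For two types the
joint isolation index I_PSI = (PSI_11 + PSI_22 - PSI_12 - PSI_21) / sum(PSI)
lies in [-1, 1] (+1 total assortative, 0 random, -1 total disassortative);
IA_PSI is the ratio of the two heterotypic PSI cells (1 = no asymmetry);
W is the per-type mating rate normalized to the fittest type.

Significance is a two-tail bootstrap: T pairs are resampled multinomially
from the observed pair frequencies (availability margins fixed), the
statistic recomputed per resample, and the p-value is the doubled smaller
tail around the null (0 for I_PSI, 1 for everything else), values at the
null counting in both tails. Replicate p-values are combined with Fisher's
sum of logs, -2 * sum(ln p) ~ chi-square with 2k degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    IntegrityError,
    ParameterError,
    UndefinedStatisticError,
    UnstableStatisticError,
)

__all__ = [
    "MatingTable",
    "CellCoefficients",
    "BootstrapResult",
    "IsolationSummary",
    "FisherResult",
    "cell_coefficients",
    "i_psi",
    "ia_psi",
    "w_fitness",
    "bootstrap_p",
    "pool_replicates",
    "fisher_combine",
    "summarize_table",
    "read_mating_csv",
    "write_mating_csv",
]


@dataclass
class MatingTable:
    """Availability counts and the observed pair-count matrix for one trial.

    ``pairs[i, j]`` counts mated pairs of female type ``types[i]`` with male
    type ``types[j]``. Storage is always female-row x male-column; pair-type
    letter codes are never inferred.
    """

    types: list[str]
    avail_females: np.ndarray
    avail_males: np.ndarray
    pairs: np.ndarray
    stopped_early: bool = False

    def __post_init__(self):
        self.avail_females = np.asarray(self.avail_females, dtype=np.int64)
        self.avail_males = np.asarray(self.avail_males, dtype=np.int64)
        self.pairs = np.asarray(self.pairs, dtype=np.int64)
        K = len(self.types)
        if K < 2:
            raise ParameterError("at least two types required")
        if len(set(self.types)) != K:
            raise ParameterError("type labels must be unique")
        if self.avail_females.shape != (K,) or self.avail_males.shape != (K,):
            raise ParameterError("availability vectors must have one entry per type")
        if self.pairs.shape != (K, K):
            raise ParameterError("pairs must be a K x K matrix")
        if (self.pairs < 0).any() or (self.avail_females < 0).any() or (self.avail_males < 0).any():
            raise ParameterError("counts must be non-negative")
        if (self.pairs.sum(axis=1) > self.avail_females).any():
            raise IntegrityError("row sums of pairs exceed female availability")
        if (self.pairs.sum(axis=0) > self.avail_males).any():
            raise IntegrityError("column sums of pairs exceed male availability")

    @property
    def K(self) -> int:
        return len(self.types)

    @property
    def T(self) -> int:
        return int(self.pairs.sum())


@dataclass
class CellCoefficients:
    """Per-cell expected matrices and cross-product coefficients (NaN = undefined)."""

    types: list[str]
    e: np.ndarray
    s: np.ndarray
    PTI: np.ndarray
    PSI: np.ndarray
    PSS: np.ndarray


@dataclass
class BootstrapResult:
    statistic: str
    observed: float
    null: float
    p: float
    n_boot: int
    n_discarded: int
    seed: int


@dataclass
class IsolationSummary:
    types: list[str]
    i_psi: float
    ia_psi: float
    w_females: np.ndarray
    w_males: np.ndarray
    p_values: dict[str, float]
    n_boot: int
    seed: int


@dataclass
class FisherResult:
    chi_square: float
    df: int
    p: float
    n_combined: int = 0


# ---------------------------------------------------------------------------
# Vectorized coefficient kernels over stacked (B, K, K) pair arrays


def _coeff_arrays(n: np.ndarray, f: np.ndarray, m: np.ndarray):
    """e, s, PTI, PSI, PSS for a stack of pair matrices (undefined -> NaN)."""
    n = np.asarray(n, dtype=float)
    squeeze = n.ndim == 2
    if squeeze:
        n = n[None, :, :]
    T = n.sum(axis=(1, 2), keepdims=True)
    f = np.asarray(f, dtype=float)
    m = np.asarray(m, dtype=float)
    e = T * (f / f.sum())[None, :, None] * (m / m.sum())[None, None, :]
    row = n.sum(axis=2, keepdims=True)
    col = n.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = row * col / T
        PTI = np.where(e > 0, n / e, np.nan)
        PSI = np.where(s > 0, n / s, np.nan)
        PSS = np.where(e > 0, s / e, np.nan)
    if squeeze:
        return e[0], s[0], PTI[0], PSI[0], PSS[0]
    return e, s, PTI, PSI, PSS


def cell_coefficients(table: MatingTable) -> CellCoefficients:
    """Expected matrices and PTI/PSI/PSS for one table.

    Cells whose denominator is zero are NaN (undefined), never zero.
    """
    if table.T == 0:
        raise ParameterError("empty table: no mated pairs")
    if table.avail_females.sum() == 0 or table.avail_males.sum() == 0:
        raise ParameterError("availability must be positive for at least one type per sex")
    e, s, PTI, PSI, PSS = _coeff_arrays(table.pairs, table.avail_females, table.avail_males)
    return CellCoefficients(list(table.types), e, s, PTI, PSI, PSS)


def _i_psi_from_psi(PSI: np.ndarray) -> np.ndarray:
    """I_PSI over a stacked (B, 2, 2) PSI array; NaN where any cell undefined."""
    num = PSI[..., 0, 0] + PSI[..., 1, 1] - PSI[..., 0, 1] - PSI[..., 1, 0]
    den = PSI[..., 0, 0] + PSI[..., 1, 1] + PSI[..., 0, 1] + PSI[..., 1, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def i_psi(table: MatingTable) -> float:
    """Joint isolation index for two types; requires all four PSI cells defined."""
    if table.K != 2:
        raise ParameterError("I_PSI is defined for exactly two types")
    coeffs = cell_coefficients(table)
    if np.isnan(coeffs.PSI).any():
        cell = tuple(int(x) for x in np.argwhere(np.isnan(coeffs.PSI))[0])
        raise UndefinedStatisticError(
            f"PSI undefined for cell {cell} (zero mated marginal)", cell=cell
        )
    return float(_i_psi_from_psi(coeffs.PSI))


def _resolve_het_order(
    table: MatingTable, heterotypic_order: Sequence[tuple[str, str]] | None
) -> tuple[tuple[int, int], tuple[int, int]]:
    if heterotypic_order is None:
        heterotypic_order = (
            (table.types[0], table.types[1]),
            (table.types[1], table.types[0]),
        )
    (f1, m1), (f2, m2) = heterotypic_order
    idx = {t: i for i, t in enumerate(table.types)}
    c1, c2 = (idx[f1], idx[m1]), (idx[f2], idx[m2])
    if c1[0] == c1[1] or c2[0] == c2[1] or c1 == c2:
        raise ParameterError("heterotypic_order must name the two off-diagonal cells")
    return c1, c2


def ia_psi(
    table: MatingTable,
    heterotypic_order: Sequence[tuple[str, str]] | None = None,
) -> float:
    """Mating-asymmetry index: PSI of the second heterotypic cell over the first.

    ``heterotypic_order`` is a pair of (female_type, male_type) cells;
    default is ((types[0], types[1]), (types[1], types[0])). Values below
    one mean asymmetry towards the first pair type; swapping the order
    inverts the value.
    """
    if table.K != 2:
        raise ParameterError("IA_PSI is defined for exactly two types")
    c1, c2 = _resolve_het_order(table, heterotypic_order)
    coeffs = cell_coefficients(table)
    psi1, psi2 = coeffs.PSI[c1], coeffs.PSI[c2]
    if np.isnan(psi1) or np.isnan(psi2) or psi1 == 0:
        bad = c1 if (np.isnan(psi1) or psi1 == 0) else c2
        raise UndefinedStatisticError(
            f"heterotypic PSI undefined or zero at cell {bad}", cell=bad
        )
    return float(psi2 / psi1)


def w_fitness(table: MatingTable, sex: str) -> np.ndarray:
    """Cross-product sexual-selection estimator per type, relative to the fittest.

    ``raw_i`` is the mated fraction of type i among available individuals of
    the chosen sex; W_i = raw_i / max_j raw_j, so max(W) = 1.
    """
    if sex not in ("female", "male"):
        raise ParameterError("sex must be 'female' or 'male'")
    avail = table.avail_females if sex == "female" else table.avail_males
    mated = table.pairs.sum(axis=1) if sex == "female" else table.pairs.sum(axis=0)
    if (avail <= 0).any():
        raise ParameterError(f"availability must be positive for every {sex} type")
    raw = mated / avail
    if raw.max() == 0:
        raise UndefinedStatisticError(f"no matings for any {sex} type; W undefined")
    return raw / raw.max()


# ---------------------------------------------------------------------------
# Bootstrap


def _stat_kernel(
    table: MatingTable,
    statistic: str,
    cell: tuple[int, int] | None,
    sex: str | None,
    type_index: int | None,
    heterotypic_order: Sequence[tuple[str, str]] | None,
) -> tuple[Callable[[np.ndarray], np.ndarray], float]:
    """(vectorized stack -> values kernel, null value) for a named statistic."""
    f, m = table.avail_females, table.avail_males

    if statistic in ("PSI", "PSS", "PTI"):
        if cell is None:
            raise ParameterError(f"{statistic} needs a cell=(i, j)")
        i, j = cell
        which = {"PTI": 2, "PSI": 3, "PSS": 4}[statistic]

        def kernel(stack: np.ndarray) -> np.ndarray:
            return _coeff_arrays(stack, f, m)[which][..., i, j]

        return kernel, 1.0

    if statistic == "I_PSI":
        if table.K != 2:
            raise ParameterError("I_PSI requires two types")

        def kernel(stack: np.ndarray) -> np.ndarray:
            PSI = _coeff_arrays(stack, f, m)[3]
            return _i_psi_from_psi(PSI)

        return kernel, 0.0

    if statistic == "IA_PSI":
        c1, c2 = _resolve_het_order(table, heterotypic_order)

        def kernel(stack: np.ndarray) -> np.ndarray:
            PSI = _coeff_arrays(stack, f, m)[3]
            p1, p2 = PSI[..., c1[0], c1[1]], PSI[..., c2[0], c2[1]]
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(p1 > 0, p2 / p1, np.nan)

        return kernel, 1.0

    if statistic == "W":
        if sex not in ("female", "male") or type_index is None:
            raise ParameterError("W needs sex and type_index")
        avail = f if sex == "female" else m
        axis = 2 if sex == "female" else 1

        def kernel(stack: np.ndarray) -> np.ndarray:
            raw = stack.sum(axis=axis) / avail
            mx = raw.max(axis=-1)
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(mx > 0, raw[..., type_index] / mx, np.nan)

        return kernel, 1.0

    raise ParameterError(f"unknown statistic {statistic!r}")


def bootstrap_p(
    table: MatingTable,
    statistic: str,
    n_boot: int = 10_000,
    seed: int = 0,
    cell: tuple[int, int] | None = None,
    sex: str | None = None,
    type_index: int | None = None,
    heterotypic_order: Sequence[tuple[str, str]] | None = None,
) -> BootstrapResult:
    """Two-tail bootstrap p for one statistic under multinomial pair resampling.

    T pairs are redrawn from the observed pair frequencies ``n_boot`` times;
    resamples on which the statistic is undefined are discarded and counted.
    p = min(1, 2 * min(frac <= null, frac >= null)) over defined resamples,
    with the null at 0 for I_PSI and 1 for all other statistics. Raises
    :class:`UnstableStatisticError` if more than half the resamples are
    undefined.
    """
    if n_boot < 1:
        raise ParameterError("n_boot must be positive")
    kernel, null = _stat_kernel(table, statistic, cell, sex, type_index, heterotypic_order)
    observed = float(kernel(table.pairs.astype(float)[None])[0])
    if np.isnan(observed):
        raise UndefinedStatisticError(f"{statistic} undefined on the observed table")

    T = table.T
    if T == 0:
        raise ParameterError("empty table: no mated pairs")
    rng = np.random.default_rng(seed)
    probs = (table.pairs / T).ravel()
    draws = rng.multinomial(T, probs, size=n_boot).reshape(n_boot, table.K, table.K)
    values = kernel(draws.astype(float))
    defined = values[~np.isnan(values)]
    n_discarded = int(n_boot - defined.size)
    if n_discarded > n_boot / 2:
        raise UnstableStatisticError(
            f"{n_discarded}/{n_boot} resamples undefined for {statistic}"
        )
    lo = float(np.mean(defined <= null))
    hi = float(np.mean(defined >= null))
    p = min(1.0, 2.0 * min(lo, hi))
    return BootstrapResult(
        statistic=statistic,
        observed=observed,
        null=null,
        p=p,
        n_boot=n_boot,
        n_discarded=n_discarded,
        seed=seed,
    )


def pool_replicates(tables: Sequence[MatingTable]) -> MatingTable:
    """Elementwise sum of pair counts and availabilities across replicates."""
    if not tables:
        raise ParameterError("no tables to pool")
    types = tables[0].types
    for t in tables[1:]:
        if t.types != types:
            raise IntegrityError(f"type sets differ: {t.types} vs {types}")
    return MatingTable(
        types=list(types),
        avail_females=np.sum([t.avail_females for t in tables], axis=0),
        avail_males=np.sum([t.avail_males for t in tables], axis=0),
        pairs=np.sum([t.pairs for t in tables], axis=0),
    )


def fisher_combine(
    p_values: Sequence[float], zero_clamp: float = 1.0 / 20_000
) -> FisherResult:
    """Fisher's sum of logs: chi2 = -2 * sum(ln p) ~ chi-square(2k).

    Bootstrap p-values of exactly 0 are clamped to ``zero_clamp`` (default
    1/(2 * 10,000), the resolution of a 10,000-iteration bootstrap) with a
    warning so the logarithm stays finite.
    """
    ps = list(p_values)
    if not ps:
        raise ParameterError("fisher_combine requires at least one p-value")
    clean = []
    for p in ps:
        if p < 0 or p > 1:
            raise ParameterError(f"p-value out of range: {p}")
        if p == 0:
            warnings.warn(f"p-value 0 clamped to {zero_clamp}")
            p = zero_clamp
        clean.append(p)
    chi2 = float(-2.0 * np.sum(np.log(clean)))
    df = 2 * len(clean)
    return FisherResult(
        chi_square=chi2, df=df, p=float(stats.chi2.sf(chi2, df)), n_combined=len(clean)
    )


def summarize_table(
    table: MatingTable,
    n_boot: int = 10_000,
    seed: int = 0,
    heterotypic_order: Sequence[tuple[str, str]] | None = None,
) -> IsolationSummary:
    """All scalar indices plus their bootstrap p-values for one (pooled) table.

    Indices that are undefined on this table (for example IA_PSI when a
    heterotypic cell is empty) are reported as NaN and get no p-value,
    rather than aborting the summary.
    """

    def _try(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (UndefinedStatisticError, UnstableStatisticError):
            return None

    ip_val = _try(i_psi, table)
    ia_val = _try(ia_psi, table, heterotypic_order)
    wf = _try(w_fitness, table, "female")
    wm = _try(w_fitness, table, "male")
    ip = float("nan") if ip_val is None else ip_val
    ia = float("nan") if ia_val is None else ia_val
    nan_w = np.full(table.K, np.nan)
    p_values: dict[str, float] = {}
    if ip_val is not None:
        b = _try(bootstrap_p, table, "I_PSI", n_boot=n_boot, seed=seed)
        if b is not None:
            p_values["I_PSI"] = b.p
    if ia_val is not None:
        b = _try(
            bootstrap_p, table, "IA_PSI", n_boot=n_boot, seed=seed + 1,
            heterotypic_order=heterotypic_order,
        )
        if b is not None:
            p_values["IA_PSI"] = b.p
    for k, t in enumerate(table.types):
        if wf is not None:
            b = _try(
                bootstrap_p, table, "W", n_boot=n_boot, seed=seed + 2 + k,
                sex="female", type_index=k,
            )
            if b is not None:
                p_values[f"W_female_{t}"] = b.p
        if wm is not None:
            b = _try(
                bootstrap_p, table, "W", n_boot=n_boot, seed=seed + 2 + table.K + k,
                sex="male", type_index=k,
            )
            if b is not None:
                p_values[f"W_male_{t}"] = b.p
    return IsolationSummary(
        types=list(table.types),
        i_psi=ip,
        ia_psi=ia,
        w_females=nan_w if wf is None else wf,
        w_males=nan_w if wm is None else wm,
        p_values=p_values,
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# CSV I/O — long-format pairs plus an availability table, explicit
# female_type/male_type columns throughout (letter codes are never parsed).


def write_mating_csv(
    tables: dict[str, MatingTable], pairs_path: str | Path, avail_path: str | Path,
    groups: dict[str, str] | None = None,
) -> None:
    pair_rows, avail_rows = [], []
    for trial_id, t in tables.items():
        group = (groups or {}).get(trial_id, "")
        for i, ft in enumerate(t.types):
            for j, mt in enumerate(t.types):
                pair_rows.append(
                    {"trial_id": trial_id, "group": group, "female_type": ft,
                     "male_type": mt, "pairs": int(t.pairs[i, j])}
                )
            avail_rows.append(
                {"trial_id": trial_id, "sex": "female", "type": ft,
                 "available": int(t.avail_females[i])}
            )
            avail_rows.append(
                {"trial_id": trial_id, "sex": "male", "type": ft,
                 "available": int(t.avail_males[i])}
            )
    pd.DataFrame(pair_rows).to_csv(pairs_path, index=False)
    pd.DataFrame(avail_rows).to_csv(avail_path, index=False)


def read_mating_csv(
    pairs_path: str | Path, avail_path: str | Path
) -> tuple[dict[str, MatingTable], dict[str, str]]:
    """Load trials; returns (trial_id -> table, trial_id -> group label)."""
    pairs = pd.read_csv(pairs_path, dtype={"trial_id": str})
    avail = pd.read_csv(avail_path, dtype={"trial_id": str})
    for col in ("trial_id", "female_type", "male_type", "pairs"):
        if col not in pairs.columns:
            raise IntegrityError(f"pairs CSV lacks column {col!r}")
    for col in ("trial_id", "sex", "type", "available"):
        if col not in avail.columns:
            raise IntegrityError(f"availability CSV lacks column {col!r}")
    tables, groups = {}, {}
    for trial_id, block in pairs.groupby("trial_id", sort=True):
        types = sorted(set(block["female_type"]) | set(block["male_type"]))
        idx = {t: i for i, t in enumerate(types)}
        mat = np.zeros((len(types), len(types)), dtype=np.int64)
        for _, row in block.iterrows():
            mat[idx[row["female_type"]], idx[row["male_type"]]] += int(row["pairs"])
        ab = avail[avail["trial_id"] == trial_id]
        if ab.empty:
            raise IntegrityError(f"no availability rows for trial {trial_id!r}")
        af = np.zeros(len(types), dtype=np.int64)
        am = np.zeros(len(types), dtype=np.int64)
        for _, row in ab.iterrows():
            if row["type"] not in idx:
                raise IntegrityError(
                    f"availability names unknown type {row['type']!r} in trial {trial_id!r}"
                )
            if row["sex"] == "female":
                af[idx[row["type"]]] = int(row["available"])
            elif row["sex"] == "male":
                am[idx[row["type"]]] = int(row["available"])
            else:
                raise IntegrityError(f"bad sex {row['sex']!r} in trial {trial_id!r}")
        tables[trial_id] = MatingTable(types, af, am, mat)
        if "group" in block.columns:
            g = block["group"].iloc[0]
            groups[trial_id] = "" if pd.isna(g) else str(g)
        else:
            groups[trial_id] = ""
    return tables, groups
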