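"""Workflow orchestration: the expression and mating pipelines end to end.

The expression workflow chains QC -> rRNA exclusion -> subsampling to the
minimum post-filter depth -> matching -> incidence-sum quantification ->
quantile normalization -> hierarchical DE. The mating workflow chains
per-replicate pooling -> coefficients and indices -> bootstrap p-values ->
Fisher combination across replicates. Both record a JSON provenance log
(seed, config hash, per-stage counts) so every conservation invariant is
checkable from logs alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import matcher, mating, normalization, read_qc
from .de import DEConfig, hierarchical_de, results_to_frame
from .errors import ParameterError
from .normalization import ExpressionMatrix
from .read_qc import ReadSet
from .synthetic import ToyTranscriptome


@dataclass
class RunConfig:
    """Parameters for a full run; YAML-loadable, flags win over file values."""

    workflow: str = "expression"
    seed: int = 0
    read_length: int = 50
    max_mismatch: int = 1
    strands: str = "both"
    subsample_target: int | None = None  # None -> minimum post-filter depth
    quantile_within_tissue: bool = False
    de: DEConfig = field(default_factory=DEConfig)
    n_boot: int = 10_000

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        de_raw = raw.pop("de", {})
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        if de_raw:
            cfg.de = DEConfig(**de_raw)
        return cfg

    def digest(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def run_expression_workflow(
    reads_per_sample: Mapping[str, ReadSet],
    transcriptome: ToyTranscriptome,
    sample_meta: pd.DataFrame,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Full expression pipeline on in-memory inputs.

    Returns a summary dict with the DE results, the normalized matrix and
    the provenance log. If ``out_dir`` is given, every intermediate artifact
    is written there (TSV/JSON).
    """
    config = config or RunConfig()
    log: dict = {"workflow": "expression", "seed": config.seed,
                 "config_hash": config.digest(), "samples": {}}

    # stage 1: QC per sample
    filtered: dict[str, ReadSet] = {}
    for sid, rs in reads_per_sample.items():
        kept, report = read_qc.filter_reads(rs)
        filtered[sid] = kept
        log["samples"][sid] = {
            "input_reads": report.input_reads,
            "accepted_reads": report.accepted_reads,
            "discarded_n_reads": report.discarded_n_reads,
            "complexity": report.complexity,
        }

    # stage 2: rRNA exclusion
    rrna = transcriptome.rrna_records()
    if rrna:
        rrna_index = matcher.build_index(rrna, config.read_length)
        for sid in filtered:
            retained, excluded = matcher.exclude_rrna(
                filtered[sid], rrna_index, config.max_mismatch
            )
            log["samples"][sid]["rrna_excluded"] = excluded.n_redundant
            log["samples"][sid]["post_rrna_reads"] = retained.n_redundant
            filtered[sid] = retained
    else:
        for sid in filtered:
            log["samples"][sid]["rrna_excluded"] = 0
            log["samples"][sid]["post_rrna_reads"] = filtered[sid].n_redundant

    # stage 3: subsample every sample to the common depth
    depths = {sid: rs.n_redundant for sid, rs in filtered.items()}
    target = config.subsample_target or min(depths.values())
    if target > min(depths.values()):
        raise ParameterError(
            f"subsample target {target} exceeds the minimum depth {min(depths.values())}"
        )
    subsampled = {
        sid: normalization.subsample_reads(rs, target, seed=config.seed + k)
        for k, (sid, rs) in enumerate(sorted(filtered.items()))
    }
    log["subsample"] = {"target": target, "depths": depths}

    # stage 4: match + quantify
    mrna = transcriptome.mrna_records()
    index = matcher.build_index(mrna, config.read_length)
    per_sample_hits, per_sample_nr = {}, {}
    for sid, rs in subsampled.items():
        nr = rs.nr_view
        hits = []
        for seq in nr:
            hits.extend(
                matcher.match_read(
                    seq, index, read_id=seq,
                    max_mismatch=config.max_mismatch, strands=config.strands,
                )
            )
        per_sample_hits[sid] = hits
        per_sample_nr[sid] = nr
        log["samples"][sid]["matched_nr_reads"] = len({h.read_id for h in hits})
    em = normalization.quantify_matrix(
        per_sample_hits, per_sample_nr, list(mrna.keys()), sample_meta
    )

    # stage 5: quantile normalization (joint by default)
    if config.quantile_within_tissue:
        parts = []
        for t in sorted(sample_meta["tissue"].unique()):
            samples = list(sample_meta.index[sample_meta["tissue"] == t])
            parts.append(normalization.quantile_normalize(em.subset_samples(samples)))
        values = pd.concat([p.values for p in parts], axis=1)[list(sample_meta.index)]
        norm = ExpressionMatrix(values, sample_meta, state="raw")
        norm.advance_state("quantile_normalized")
    else:
        norm = normalization.quantile_normalize(em)

    # stage 6: hierarchical DE
    de_results = hierarchical_de(norm, config.de)
    de_frame = results_to_frame(de_results)
    tallies = {}
    for t, results in de_results.items():
        calls = [r for r in results if r.de_call]
        tallies[t] = {
            "tested": len(results),
            "de_total": len(calls),
            "per_direction": pd.Series(
                [r.direction for r in calls], dtype=str
            ).value_counts().to_dict(),
        }
    log["de"] = tallies

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        em.to_tsv(out / "abundance_raw.tsv", out / "sample_meta.tsv")
        norm.to_tsv(out / "abundance_normalized.tsv")
        de_frame.to_csv(out / "de_results.tsv", sep="\t", index=False)
        (out / "run_log.json").write_text(json.dumps(log, indent=2))

    return {"matrix": norm, "de_results": de_results, "de_frame": de_frame, "log": log}


def run_expression_from_counts(
    em: ExpressionMatrix, config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Count-matrix entry point: skips the read stages, quantile-normalizes
    (unless already normalized) and runs hierarchical DE."""
    config = config or RunConfig()
    if em.state == "quantile_normalized":
        norm = em
    else:
        norm = normalization.quantile_normalize(em)
    de_results = hierarchical_de(norm, config.de)
    de_frame = results_to_frame(de_results)
    log = {"workflow": "expression", "entry": "counts", "seed": config.seed,
           "config_hash": config.digest()}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        de_frame.to_csv(out / "de_results.tsv", sep="\t", index=False)
        (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return {"matrix": norm, "de_results": de_results, "de_frame": de_frame, "log": log}


def run_mating_workflow(
    tables: Mapping[str, mating.MatingTable],
    groups: Mapping[str, str] | None = None,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Per-replicate isolation analysis with Fisher combination across groups.

    ``groups`` maps trial_id -> line-replicate label; trials sharing a label
    are pooled before analysis. An empty/missing grouping pools everything
    into a single analysis.
    """
    config = config or RunConfig(workflow="mating")
    groups = dict(groups or {})
    by_group: dict[str, list[mating.MatingTable]] = {}
    for trial_id, table in tables.items():
        g = groups.get(trial_id, "") or "all"
        by_group.setdefault(g, []).append(table)

    summaries: dict[str, mating.IsolationSummary] = {}
    rows = []
    for k, (g, ts) in enumerate(sorted(by_group.items())):
        pooled = mating.pool_replicates(ts)
        summary = mating.summarize_table(
            pooled, n_boot=config.n_boot, seed=config.seed + 1000 * k
        )
        summaries[g] = summary
        row = {"group": g, "n_trials": len(ts), "T": pooled.T,
               "I_PSI": summary.i_psi, "IA_PSI": summary.ia_psi}
        for t, wf, wm in zip(summary.types, summary.w_females, summary.w_males):
            row[f"W_female_{t}"], row[f"W_male_{t}"] = float(wf), float(wm)
        for name, p in summary.p_values.items():
            row[f"p_{name}"] = p
        rows.append(row)
    per_group = pd.DataFrame(rows)

    combined = {}
    stat_names: list[str] = []
    for s in summaries.values():
        for name in s.p_values:
            if name not in stat_names:
                stat_names.append(name)
    for name in stat_names:
        ps = [s.p_values[name] for s in summaries.values() if name in s.p_values]
        fr = mating.fisher_combine(ps, zero_clamp=1.0 / (2 * config.n_boot))
        combined[name] = {"chi_square": fr.chi_square, "df": fr.df, "p": fr.p,
                          "n_combined": fr.n_combined}

    log = {"workflow": "mating", "seed": config.seed, "config_hash": config.digest(),
           "n_boot": config.n_boot, "groups": {g: len(ts) for g, ts in by_group.items()}}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_group.to_csv(out / "isolation_per_group.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"statistic": k, **v} for k, v in combined.items()]
        ).to_csv(out / "fisher_combined.tsv", sep="\t", index=False)
        (out / "run_log.json").write_text(json.dumps(log, indent=2))

    return {"per_group": per_group, "summaries": summaries, "combined": combined,
            "log": log}
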