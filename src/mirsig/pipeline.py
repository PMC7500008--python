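"""One-command orchestration of the full analysis.

Stages: normalize -> CPM filter -> dual-test differential expression ->
consensus calls -> signature scoring and G x N enrichment -> correlation
structure -> phenotype correlations -> normalization comparison -> report.
Every number in the report is recomputable from the persisted TSV
intermediates.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexp import N0_MIR, N1_MIR, DERecord, run_differential_expression
from .errors import GroupSizeError, PipelineConfigError
from .io import Dataset, bind_dataset, read_annotations, read_counts, write_results
from .normalization import (
    ExpressionMatrix,
    compare_normalizations,
    cpm,
    factors_by_method,
    filter_by_cpm,
)
from .signature import (
    SignatureResult,
    correlation_structure,
    evaluate_signature,
    phenotype_correlations,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    counts_path: str
    annotations_path: str
    outdir: str = "mirsig_out"
    normalization: str = "TMM"
    min_cpm: float = 1.0
    min_fraction: float = 0.5
    alpha: float = 0.05
    min_fold: float = 1.5
    pseudocount: float = 0.5
    mw_mode: str = "auto"
    prior_df: float = 10.0
    shrink_df: float = 20.0
    highlow_fold: float = 1.5
    n1_set: tuple[str, ...] | None = None  # explicit signature sets; default: consensus calls
    n0_set: tuple[str, ...] | None = None
    tie_policy: str = "G0"
    compare_norm: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.normalization.upper() not in ("TMM", "RLE", "UQ", "TC"):
            raise PipelineConfigError(f"unknown normalization {self.normalization!r}")
        if not 0 < self.alpha < 1:
            raise PipelineConfigError("alpha must lie in (0, 1)")
        if self.min_fold < 1:
            raise PipelineConfigError("min_fold must be >= 1")
        if self.tie_policy not in ("G0", "G1", "drop"):
            raise PipelineConfigError(f"unknown tie policy {self.tie_policy!r}")
        if self.mw_mode not in ("auto", "exact", "normal"):
            raise PipelineConfigError(f"unknown MW mode {self.mw_mode!r}")


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected; overrides win."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("n1_set", "n0_set"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise PipelineConfigError(str(exc)) from exc


@dataclass
class RunReport:
    """Stage counts and headline statistics of one run."""

    version: str
    config: dict
    n_mirnas_input: int = 0
    n_samples: int = 0
    n_N0: int = 0
    n_N1: int = 0
    n_mirnas_filtered: int = 0
    n_called_N1: int = 0
    n_called_N0: int = 0
    n_not_significant: int = 0
    signature_contingency: list | None = None
    fisher_p: float = float("nan")
    avg_within_N1: float = float("nan")
    avg_within_N0: float = float("nan")
    avg_cross: float = float("nan")
    gleason_vs_node_r: float = float("nan")
    gleason_vs_node_p: float = float("nan")
    norm_comparison: list | None = None
    signature_skipped_reason: str = ""

    def to_text(self) -> str:
        lines = [
            f"mirsig {self.version} run report",
            f"samples: {self.n_samples} (N0={self.n_N0}, N1={self.n_N1})",
            f"miRNAs: {self.n_mirnas_input} input, {self.n_mirnas_filtered} pass CPM filter",
            f"consensus calls: {self.n_called_N1} N1-miRs, {self.n_called_N0} N0-miRs, "
            f"{self.n_not_significant} not significant",
        ]
        if self.signature_contingency is not None:
            lines += [
                f"signature contingency (rows G0,G1 x cols N0,N1): {self.signature_contingency}",
                f"Fisher exact p (G x N): {self.fisher_p:.4g}",
                f"avg Spearman r: within-N1 {self.avg_within_N1:.3f}, "
                f"within-N0 {self.avg_within_N0:.3f}, cross {self.avg_cross:.3f}",
            ]
        elif self.signature_skipped_reason:
            lines.append(f"signature stage skipped: {self.signature_skipped_reason}")
        if np.isfinite(self.gleason_vs_node_r):
            lines.append(
                f"Gleason vs node: r = {self.gleason_vs_node_r:.3f}, p = {self.gleason_vs_node_p:.4g}"
            )
        return "\n".join(lines) + "\n"

    def to_frame(self) -> pd.DataFrame:
        flat = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if k not in ("config", "signature_contingency", "norm_comparison")
        }
        return pd.DataFrame([flat])


def run_pipeline(
    config: PipelineConfig, dataset: Dataset | None = None
) -> tuple[RunReport, list[DERecord], SignatureResult | None]:
    """Execute all stages and persist every intermediate under ``outdir``.

    ``dataset`` may be passed directly (e.g. from the generator); otherwise
    the count and annotation paths in the config are read.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if dataset is None:
        counts = read_counts(config.counts_path)
        annotations = read_annotations(config.annotations_path)
        dataset = bind_dataset(counts, annotations)
    counts = dataset.counts
    node = dataset.node_status
    report = RunReport(
        version=__version__,
        config=dataclasses.asdict(config),
        n_mirnas_input=counts.shape[0],
        n_samples=counts.shape[1],
        n_N0=int((node == "N0").sum()),
        n_N1=int((node == "N1").sum()),
    )

    factors = factors_by_method(counts, config.normalization)
    factors.to_series().to_csv(outdir / "norm_factors.tsv", sep="\t", index_label="sample_id")
    expr = cpm(counts, factors)
    keep = filter_by_cpm(expr, config.min_cpm, config.min_fraction)
    report.n_mirnas_filtered = len(keep)
    logger.info("%d/%d miRNAs pass the CPM filter", len(keep), counts.shape[0])
    expr_f = expr.subset_mirnas(keep)
    expr_f.values.to_csv(outdir / "cpm_filtered.tsv", sep="\t", index_label="mirna_id",
                         float_format="%.6g")

    records = run_differential_expression(
        counts,
        expr_f,
        factors,
        node,
        alpha=config.alpha,
        min_fold=config.min_fold,
        pseudocount=config.pseudocount,
        mw_mode=config.mw_mode,
        prior_df=config.prior_df,
        shrink_df=config.shrink_df,
        highlow_fold=config.highlow_fold,
    )
    write_results(records, outdir / "de_results.tsv")
    report.n_called_N1 = sum(r.call == N1_MIR for r in records)
    report.n_called_N0 = sum(r.call == N0_MIR for r in records)
    report.n_not_significant = len(records) - report.n_called_N1 - report.n_called_N0

    n1_set = list(config.n1_set) if config.n1_set else [r.mirna_id for r in records if r.call == N1_MIR]
    n0_set = list(config.n0_set) if config.n0_set else [r.mirna_id for r in records if r.call == N0_MIR]

    sig_result: SignatureResult | None = None
    if n1_set and n0_set:
        sig_result = evaluate_signature(
            expr_f, node, n1_set, n0_set, pseudocount=config.pseudocount, tie=config.tie_policy
        )
        sig_result.to_frame(node).to_csv(outdir / "signature_samples.tsv", sep="\t",
                                         index=False, float_format="%.6g")
        pd.DataFrame(
            sig_result.contingency, index=["G0", "G1"], columns=["N0", "N1"]
        ).to_csv(outdir / "signature_contingency.tsv", sep="\t", index_label="group")
        report.signature_contingency = sig_result.contingency.tolist()
        report.fisher_p = sig_result.fisher_p
        try:
            pair_r, a1, a0, ax = correlation_structure(expr_f, n1_set, n0_set)
            pair_r.to_csv(outdir / "signature_correlations.tsv", sep="\t",
                          index_label="mirna_id", float_format="%.6g")
            report.avg_within_N1, report.avg_within_N0, report.avg_cross = a1, a0, ax
        except GroupSizeError as exc:
            logger.warning("correlation structure skipped: %s", exc)
        pheno = phenotype_correlations(
            expr_f, node, dataset.gleason, mirna_ids=n1_set + n0_set
        )
        pheno_df = pd.DataFrame({"node_r": pheno.node_r, "node_p": pheno.node_p})
        if pheno.gleason_r is not None:
            pheno_df["gleason_r"] = pheno.gleason_r
            pheno_df["gleason_p"] = pheno.gleason_p
            report.gleason_vs_node_r = pheno.gleason_vs_node_r
            report.gleason_vs_node_p = pheno.gleason_vs_node_p
        pheno_df.to_csv(outdir / "phenotype_correlations.tsv", sep="\t",
                        index_label="mirna_id", float_format="%.6g")
    else:
        report.signature_skipped_reason = (
            "no consensus N1-miRs and/or N0-miRs and no explicit sets supplied"
        )
        logger.warning(report.signature_skipped_reason)

    if config.compare_norm:
        comparison = compare_normalizations(counts)
        comparison.to_frame().to_csv(outdir / "norm_comparison.tsv", sep="\t",
                                     index=False, float_format="%.6g")
        report.norm_comparison = comparison.to_frame().to_dict(orient="records")

    (outdir / "report.txt").write_text(report.to_text())
    report.to_frame().to_csv(outdir / "report.tsv", sep="\t", index=False, float_format="%.6g")
    with open(outdir / "config_used.yaml", "w") as fh:
        yaml.safe_dump(report.config, fh, sort_keys=False)
    return report, records, sig_result


def plot_signature_heatmap(
    expr: ExpressionMatrix | pd.DataFrame,
    sig_result: SignatureResult,
    n1_set: Sequence[str],
    n0_set: Sequence[str],
    path: str | Path,
    pseudocount: float = 0.5,
) -> None:
    """Simple centered-log2 heatmap of the signature miRNAs, samples ordered by score."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .signature import centered_log_expression

    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    cl = centered_log_expression(df, pseudocount=pseudocount)
    order = np.argsort(sig_result.scores)
    members = list(n1_set) + list(n0_set)
    mat = cl.loc[members].to_numpy()[:, order]
    fig, ax = plt.subplots(figsize=(10, 0.35 * len(members) + 2))
    vmax = np.nanmax(np.abs(mat)) or 1.0
    im = ax.imshow(mat, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_yticks(range(len(members)), members, fontsize=7)
    ax.set_xticks(range(mat.shape[1]),
                  [df.columns[i] for i in order], rotation=90, fontsize=6)
    ax.axhline(len(n1_set) - 0.5, color="black", lw=0.8)
    fig.colorbar(im, ax=ax, label="centered log2 CPM")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
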