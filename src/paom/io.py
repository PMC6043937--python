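"""Expression-panel I/O, run configuration, and the end-to-end pipeline.

Expression panels are tab-separated text: first header row = sample IDs,
first column = gene IDs, remaining cells strictly numeric.  Missing or
non-numeric values are hard errors — silent coercion hides upstream
problems in small-sample designs where every cell matters.

Every output file carries a short hash of the resolved configuration in a
leading comment line, so a result can always be traced to the exact
settings that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .compare import RelationTable, comparison_values, select_relations
from .core import ExpressionMatrix, align_panels
from .errors import ConfigurationError, ParseError
from .seqfilter import apply_filter, load_predictions
from .solver import FitOptions, FitResult, fit_rowwise
from .summary import FrequencyReport, mirna_frequency, render_frequency_plot

__all__ = ["read_expression", "write_expression", "RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


def read_expression(path: str | Path, condition: str = "", species: str = "") -> ExpressionMatrix:
    """Parse a TSV expression panel with strict validation."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty expression file")
    header = lines[0].split("\t")
    sample_ids = [s.strip() for s in header[1:]]
    if not sample_ids:
        raise ParseError(f"{path}: header row has no sample IDs")
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(sample_ids) + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {len(sample_ids) + 1} columns, got {len(fields)}"
            )
        gid = fields[0].strip()
        if gid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene ID {gid!r}")
        seen.add(gid)
        vals = []
        for col, cell in enumerate(fields[1:], start=2):
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} in column {col} "
                    f"(gene {gid!r}, sample {sample_ids[col - 2]!r})"
                ) from None
            if not np.isfinite(v):
                raise ParseError(f"{path}:{lineno}: non-finite value for gene {gid!r}")
            vals.append(v)
        gene_ids.append(gid)
        rows.append(vals)
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows), condition, species)


def write_expression(panel: ExpressionMatrix, path: str | Path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class RunConfig:
    """Full pipeline configuration (serializable to/from YAML)."""

    mirna_normal: str
    mirna_cancer: str
    mrna_normal: str
    mrna_cancer: str
    predictions: list[str] = field(default_factory=list)
    prediction_source: str = "predictions"
    fit: FitOptions = field(default_factory=FitOptions)
    eps: float = 1e-12
    include_cutoff: float = 0.5
    report_cutoff: float = 5.0
    require_negative_cancer: bool = True
    use_absolute: bool = False
    filter_mode: str = "any"
    drop_unsupported: bool = False
    log2_transform: bool = False
    frequency_cutoff: float = 5.0
    outdir: str = "paom_out"
    log_level: str = "INFO"

    def validate(self) -> None:
        for p in [self.mirna_normal, self.mirna_cancer, self.mrna_normal,
                  self.mrna_cancer, *self.predictions]:
            if not Path(p).exists():
                raise ConfigurationError(f"input path does not exist: {p}")
        for name in ("eps", "include_cutoff", "report_cutoff", "frequency_cutoff"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fit"] = self.fit.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("fit"), dict):
            d["fit"] = FitOptions.from_dict(d["fit"])
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    relations: RelationTable
    frequency: FrequencyReport
    diagnostics: dict
    fit_normal: FitResult
    fit_cancer: FitResult


def _fit_condition(
    config: RunConfig, x_path: str, y_path: str, condition: str
) -> tuple[FitResult, ExpressionMatrix]:
    X = read_expression(x_path, condition=condition, species="miRNA")
    Y = read_expression(y_path, condition=condition, species="mRNA")
    if config.log2_transform:
        X, Y = X.log2_transform(), Y.log2_transform()
    X, Y = align_panels(X, Y)
    result = fit_rowwise(X, Y, config.fit)
    if not result.converged:
        logger.warning("%s fit did not converge (final error %.3g)", condition, result.final_error)
    return result, X


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute fit(normal) -> fit(cancer) -> compare -> select -> filter -> summarize.

    Writes the relation table, frequency report, frequency plot, fit
    diagnostics, and the resolved configuration to ``config.outdir``.
    Non-convergence of a fit is recorded in the diagnostics, never raised.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[stage: {name}] {exc}") from exc

    fit_n, X_n = _stage(
        "fit normal", _fit_condition, config, config.mirna_normal, config.mrna_normal, "normal"
    )
    fit_c, X_c = _stage(
        "fit cancer", _fit_condition, config, config.mirna_cancer, config.mrna_cancer, "cancer"
    )
    comp = _stage("compare", comparison_values, fit_n.A_hat, fit_c.A_hat, config.eps)
    relations = _stage(
        "select", select_relations, comp,
        include_cutoff=config.include_cutoff,
        report_cutoff=config.report_cutoff,
        require_negative_cancer=config.require_negative_cancer,
        use_absolute=config.use_absolute,
    )
    if config.predictions:
        psets = []
        for p in config.predictions:
            psets.extend(load_predictions(p, config.prediction_source))
        relations = _stage(
            "filter", apply_filter, relations, psets,
            mode=config.filter_mode, drop=config.drop_unsupported,
        )
    frequency = _stage(
        "summarize", mirna_frequency, relations,
        cutoff=config.frequency_cutoff,
        filtered_only=bool(config.predictions),
        all_mirna_ids=X_n.gene_ids,
        condition_pair="normal_vs_cancer",
    )

    n_rows, m_cols = fit_n.A_hat.shape
    # per-row samples < unknowns means many exact solutions (coefficient
    # identification is ambiguous even when the data are reproduced exactly)
    underdetermined = {
        "normal": X_n.n_samples < m_cols,
        "cancer": X_c.n_samples < m_cols,
    }
    diagnostics = {
        "config_hash": chash,
        "n_mrnas": n_rows,
        "n_mirnas": m_cols,
        "cv_entries": comp.n_entries,
        "cv_unstable_entries": comp.n_unstable,
        "final_error_normal": fit_n.final_error,
        "final_error_cancer": fit_c.final_error,
        "converged_normal": fit_n.converged,
        "converged_cancer": fit_c.converged,
        "iterations_normal": fit_n.iterations,
        "iterations_cancer": fit_c.iterations,
        "underdetermined": underdetermined,
        "n_relations": len(relations),
        "n_passed_filter": int(relations.df["passed_filter"].sum()) if len(relations) else 0,
    }

    header = f"config_hash={chash}"
    relations.write_tsv(outdir / "relations.tsv", header_comment=header)
    relations.write_json(outdir / "relations.json")
    frequency.write_tsv(outdir / "frequency.tsv", header_comment=header)
    frequency.write_json(outdir / "frequency.json")
    render_frequency_plot(frequency, outdir / "frequency.png")
    (outdir / "diagnostics.json").write_text(json.dumps(diagnostics, indent=1))
    (outdir / "config.resolved.yaml").write_text(
        f"# config_hash={chash}\n" + yaml.safe_dump(config.to_dict(), sort_keys=True)
    )
    return PipelineResult(relations, frequency, diagnostics, fit_n, fit_c)
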