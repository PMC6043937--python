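"""Differential comparison of condition-specific interaction matrices.

The comparison value (CV, reported as the PAOM score) for a coefficient is
its relative change from normal to cancer::

    CV[i, j] = (P_normal[i, j] - P_cancer[i, j]) / |P_normal[i, j]|

Large CVs flag relations whose strength shifts between conditions — the
typical signature of interest is a weakly inhibitory coefficient in normal
tissue becoming strongly negative in cancer, which yields a large positive
CV.  Entries whose normal coefficient is numerically zero cannot support a
relative change and are flagged unstable rather than reported as huge
scores.

Selection applies two thresholds: an inclusion cutoff (0.5, the screening
rule) and a reporting cutoff (5.0, the score used for headline tables and
frequency figures), plus an optional requirement that the cancer
coefficient be negative (inhibitory).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import InteractionMatrix
from .errors import AlignmentError, ConfigurationError

__all__ = ["ComparisonResult", "RelationTable", "comparison_values", "select_relations"]

RELATION_COLUMNS = [
    "mrna_id",
    "mirna_id",
    "cv",
    "a_normal",
    "a_cancer",
    "negative_in_cancer",
    "reportable",
    "sources",
    "passed_filter",
]


@dataclass
class ComparisonResult:
    """CV matrix with provenance: both coefficient matrices and an unstable mask."""

    mrna_ids: list[str]
    mirna_ids: list[str]
    cv: np.ndarray
    a_normal: np.ndarray
    a_cancer: np.ndarray
    unstable: np.ndarray  # boolean; |a_normal| <= eps while a_normal != a_cancer
    eps: float

    @property
    def n_entries(self) -> int:
        return int(self.cv.size)

    @property
    def n_unstable(self) -> int:
        return int(self.unstable.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cv, index=self.mrna_ids, columns=self.mirna_ids)


@dataclass
class RelationTable:
    """Scored (mRNA, miRNA) candidate relations.

    Wraps a DataFrame with one row per unique pair, sorted by descending CV.
    ``sources`` holds the sequence-prediction resources supporting the pair
    (empty until a filter is applied); ``passed_filter`` records the filter
    outcome.
    """

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=RELATION_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in RELATION_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"relation table missing columns: {missing}")
        self.df = self.df[RELATION_COLUMNS].reset_index(drop=True)
        pairs = list(zip(self.df["mrna_id"], self.df["mirna_id"]))
        if len(set(pairs)) != len(pairs):
            raise ConfigurationError("duplicate (mRNA, miRNA) pairs in relation table")
        if len(self.df) and not np.all(np.isfinite(self.df["cv"].to_numpy(dtype=float))):
            raise ConfigurationError("non-finite CV in relation table")

    def __len__(self) -> int:
        return len(self.df)

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.df["mrna_id"], self.df["mirna_id"]))

    def write_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        out = self.df.copy()
        out["sources"] = [",".join(sorted(s)) for s in out["sources"]]
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            out.to_csv(fh, sep="\t", index=False)

    def write_json(self, path: str | Path) -> None:
        records = self.df.copy()
        records["sources"] = [sorted(s) for s in records["sources"]]
        Path(path).write_text(json.dumps(records.to_dict(orient="records"), indent=1))


def comparison_values(
    P_normal: InteractionMatrix, P_cancer: InteractionMatrix, eps: float = 1e-12
) -> ComparisonResult:
    """Relative change of every coefficient between the two condition fits.

    ``CV = (P_normal - P_cancer) / max(|P_normal|, eps)`` elementwise; the
    ``eps`` floor guards division by zero.  Entries with ``|P_normal| <=
    eps`` but differing coefficients are marked unstable (the relative
    change is undefined at a zero baseline).
    """
    if eps < 0 or not np.isfinite(eps):
        raise ConfigurationError(f"eps must be a nonnegative finite real, got {eps}")
    if P_normal.mrna_ids != P_cancer.mrna_ids or P_normal.mirna_ids != P_cancer.mirna_ids:
        raise AlignmentError("normal and cancer interaction matrices have different ID orderings")
    Pn, Pc = P_normal.values, P_cancer.values
    denom = np.maximum(np.abs(Pn), eps if eps > 0 else np.finfo(float).tiny)
    cv = (Pn - Pc) / denom
    unstable = (np.abs(Pn) <= eps) & (Pn != Pc)
    return ComparisonResult(
        mrna_ids=list(P_normal.mrna_ids),
        mirna_ids=list(P_normal.mirna_ids),
        cv=cv,
        a_normal=Pn.copy(),
        a_cancer=Pc.copy(),
        unstable=unstable,
        eps=eps,
    )


def select_relations(
    comparison: ComparisonResult,
    include_cutoff: float = 0.5,
    report_cutoff: float = 5.0,
    require_negative_cancer: bool = True,
    use_absolute: bool = False,
) -> RelationTable:
    """Threshold the CV matrix into a candidate relation table.

    Pairs with CV above ``include_cutoff`` are retained; those at or above
    ``report_cutoff`` are additionally marked reportable.  With
    ``require_negative_cancer`` (default) only pairs whose cancer
    coefficient is negative — i.e. read as inhibition in the tumor fit —
    survive.  ``use_absolute`` thresholds |CV| instead of the signed value
    (sensitivity analysis).  Unstable entries are never selected.  Rows are
    sorted by descending CV, ties broken by (mRNA ID, miRNA ID).
    """
    for name, c in (("include_cutoff", include_cutoff), ("report_cutoff", report_cutoff)):
        if not np.isfinite(c):
            raise ConfigurationError(f"{name} must be finite, got {c}")
    score = np.abs(comparison.cv) if use_absolute else comparison.cv
    keep = (score > include_cutoff) & ~comparison.unstable
    if require_negative_cancer:
        keep &= comparison.a_cancer < 0
    rows = []
    for i, j in np.argwhere(keep):
        rows.append(
            {
                "mrna_id": comparison.mrna_ids[i],
                "mirna_id": comparison.mirna_ids[j],
                "cv": float(comparison.cv[i, j]),
                "a_normal": float(comparison.a_normal[i, j]),
                "a_cancer": float(comparison.a_cancer[i, j]),
                "negative_in_cancer": bool(comparison.a_cancer[i, j] < 0),
                "reportable": bool(score[i, j] >= report_cutoff),
                "sources": frozenset(),
                "passed_filter": False,
            }
        )
    df = pd.DataFrame(rows, columns=RELATION_COLUMNS)
    if len(df):
        order = sorted(
            range(len(df)),
            key=lambda r: (-df["cv"].iloc[r], df["mrna_id"].iloc[r], df["mirna_id"].iloc[r]),
        )
        df = df.iloc[order].reset_index(drop=True)
    return RelationTable(df)
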