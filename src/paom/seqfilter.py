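"""Filtering candidate relations against sequence-based target predictions.

PicTar- and miRanda-style resources predict miRNA targets from sequence
alone (3' UTR alignment scanning; complementarity with position-specific
rules) and carry no information about cancer.  Intersecting the
optimization-derived candidates with such pair lists keeps only relations
that are also plausible at the sequence level.

Prediction files are plain delimited text: miRNA ID, mRNA ID, and an
optional third column naming the source.  miRNA naming in the wild is
inconsistent ("miR-98" vs "miR-98a", "let-7a" with varying case), so
matching is case-insensitive with an optional alias map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .compare import RelationTable
from .errors import ConfigurationError, ParseError

__all__ = ["PredictionSet", "load_predictions", "apply_filter", "normalize_id"]

logger = logging.getLogger(__name__)


def normalize_id(identifier: str, aliases: dict[str, str] | None = None) -> str:
    """Canonical form for matching: lowercase, stripped, alias-mapped."""
    key = identifier.strip().lower()
    if aliases:
        key = {a.strip().lower(): b.strip().lower() for a, b in aliases.items()}.get(key, key)
    return key


@dataclass
class PredictionSet:
    """Deduplicated (miRNA, mRNA) pairs from one prediction resource."""

    source: str
    pairs: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.source:
            raise ConfigurationError("prediction source tag must be non-empty")
        for mirna, mrna in self.pairs:
            if not mirna or not mrna:
                raise ConfigurationError(f"empty ID in prediction pair {(mirna, mrna)!r}")

    def __len__(self) -> int:
        return len(self.pairs)

    def contains(
        self, mirna_id: str, mrna_id: str, aliases: dict[str, str] | None = None
    ) -> bool:
        want = (normalize_id(mirna_id, aliases), normalize_id(mrna_id, aliases))
        return want in {
            (normalize_id(a, aliases), normalize_id(b, aliases)) for a, b in self.pairs
        }

    def normalized(self, aliases: dict[str, str] | None = None) -> frozenset[tuple[str, str]]:
        return frozenset(
            (normalize_id(a, aliases), normalize_id(b, aliases)) for a, b in self.pairs
        )


def load_predictions(
    path: str | Path, source_tag: str, delimiter: str = "\t"
) -> list[PredictionSet]:
    """Read a prediction pair list; returns one set per source found.

    Each line holds ``miRNA_ID<tab>mRNA_ID[<tab>source]``; a third column
    overrides ``source_tag``, so a concatenated multi-resource file is
    partitioned by source.  Duplicates are dropped (and counted in the log);
    an empty file yields one empty set with a warning.
    """
    by_source: dict[str, set[tuple[str, str]]] = {}
    n_dupes = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ParseError(
                    f"{path}:{lineno}: expected at least 2 non-empty columns "
                    f"(miRNA ID, mRNA ID), got {line!r}"
                )
            mirna, mrna = fields[0].strip(), fields[1].strip()
            src = fields[2].strip() if len(fields) > 2 and fields[2].strip() else source_tag
            bucket = by_source.setdefault(src, set())
            if (mirna, mrna) in bucket:
                n_dupes += 1
            bucket.add((mirna, mrna))
    if n_dupes:
        logger.info("dropped %d duplicate prediction pairs in %s", n_dupes, path)
    if not by_source:
        logger.warning("prediction file %s is empty", path)
        return [PredictionSet(source=source_tag, pairs=frozenset())]
    return [
        PredictionSet(source=src, pairs=frozenset(pairs))
        for src, pairs in sorted(by_source.items())
    ]


def write_predictions(predictions: list[PredictionSet], path: str | Path) -> None:
    """Write pair lists as TSV (miRNA, mRNA, source), sorted for determinism."""
    with open(path, "w") as fh:
        for pset in predictions:
            for mirna, mrna in sorted(pset.pairs):
                fh.write(f"{mirna}\t{mrna}\t{pset.source}\n")


def apply_filter(
    relations: RelationTable,
    predictions: list[PredictionSet],
    mode: str = "any",
    drop: bool = False,
    aliases: dict[str, str] | None = None,
) -> RelationTable:
    """Annotate each relation with its sequence-prediction support.

    A pair passes with ``mode="any"`` (default) when at least one resource
    predicts it, or with ``mode="all"`` when every resource does.  CV values
    and row order are untouched; failing rows are kept with
    ``passed_filter=False`` unless ``drop=True``.
    """
    if mode not in ("any", "all"):
        raise ConfigurationError(f"unknown filter mode {mode!r} (any or all)")
    if not predictions:
        raise ConfigurationError("at least one PredictionSet is required")
    normalized = {p.source: p.normalized(aliases) for p in predictions}
    df = relations.df.copy()
    sources_col, passed_col = [], []
    for _, row in df.iterrows():
        pair = (normalize_id(row["mirna_id"], aliases), normalize_id(row["mrna_id"], aliases))
        hits = frozenset(src for src, pairs in normalized.items() if pair in pairs)
        sources_col.append(hits)
        passed_col.append(len(hits) >= (1 if mode == "any" else len(normalized)))
    df["sources"] = sources_col
    df["passed_filter"] = passed_col
    if drop:
        df = df[df["passed_filter"]].reset_index(drop=True)
    return RelationTable(df)
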