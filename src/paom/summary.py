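"""Per-miRNA target-frequency summaries and bar-chart rendering.

Counting how many mRNAs each miRNA targets above a score cutoff highlights
hub regulators: miRNAs whose influence on many transcripts changes between
normal and tumor tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .compare import RelationTable
from .errors import ConfigurationError

__all__ = ["FrequencyReport", "mirna_frequency", "render_frequency_plot"]


@dataclass
class FrequencyReport:
    """Number of retained target mRNAs per miRNA at a given score cutoff."""

    counts: dict[str, int]
    cutoff_used: float
    condition_pair: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def write_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("mirna_id\tcount\n")
            for mirna in sorted(self.counts):
                fh.write(f"{mirna}\t{self.counts[mirna]}\n")

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "cutoff_used": self.cutoff_used,
                    "condition_pair": self.condition_pair,
                    "counts": dict(sorted(self.counts.items())),
                },
                indent=1,
            )
        )


def mirna_frequency(
    relations: RelationTable,
    cutoff: float = 5.0,
    filtered_only: bool = False,
    all_mirna_ids: list[str] | None = None,
    condition_pair: str = "",
) -> FrequencyReport:
    """Count retained target mRNAs per miRNA.

    A relation is retained when its CV is at or above ``cutoff`` (and, with
    ``filtered_only``, when it passed the sequence filter).  Panel miRNAs
    with no retained targets appear with count 0 when ``all_mirna_ids`` is
    given.
    """
    if not np.isfinite(cutoff):
        raise ConfigurationError(f"cutoff must be finite, got {cutoff}")
    counts: dict[str, int] = {m: 0 for m in (all_mirna_ids or [])}
    df = relations.df
    mask = df["cv"].to_numpy(dtype=float) >= cutoff if len(df) else np.zeros(0, bool)
    if filtered_only and len(df):
        mask &= df["passed_filter"].to_numpy(dtype=bool)
    for mirna in df.loc[mask, "mirna_id"]:
        counts[mirna] = counts.get(mirna, 0) + 1
    return FrequencyReport(counts=counts, cutoff_used=float(cutoff), condition_pair=condition_pair)


def render_frequency_plot(report: FrequencyReport, path: str | Path) -> Path:
    """Write a bar chart of the report (PNG/SVG by extension).

    Bars are sorted by descending count, ties broken alphabetically by
    miRNA ID so output is deterministic.  An all-zero report still renders
    (empty-looking axes), which keeps pipelines robust on null results.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = sorted(report.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    labels = [k for k, _ in order]
    heights = [v for _, v in order]
    fig, ax = plt.subplots(figsize=(max(4, 0.35 * len(labels) + 1), 4))
    ax.bar(range(len(labels)), heights, color="#4878a8")
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel(f"targets with score >= {report.cutoff_used:g}")
    ax.set_xlabel("miRNA")
    if report.condition_pair:
        ax.set_title(report.condition_pair)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
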