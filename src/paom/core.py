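"""Linear miRNA -> mRNA influence model and its forward (direct) solver.

The model is ``Y = A X``: the expression of each mRNA is a weighted sum of
the expression of all miRNAs on the panel, with the coefficient ``a_ij``
quantifying the influence of miRNA *j* on mRNA *i*.  Negative coefficients
are read as inhibition (translational repression / transcript degradation),
which is the biologically expected sign for miRNA regulation.

All containers carry explicit ID lists so coefficients are always addressed
by (mRNA ID, miRNA ID), never by bare index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ShapeError

__all__ = ["ExpressionMatrix", "InteractionMatrix", "forward", "align_panels"]


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(g) for g in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ShapeError(f"duplicate {what}: {dupes}")
    return ids


@dataclass
class ExpressionMatrix:
    """One condition's gene x sample expression panel.

    Parameters
    ----------
    gene_ids : ordered gene identifiers (rows).
    sample_ids : ordered sample identifiers (columns).
    values : real matrix, shape ``(len(gene_ids), len(sample_ids))``.
    condition : free-text condition label (e.g. ``"normal"``, ``"cancer"``).
    species : ``"miRNA"`` or ``"mRNA"``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    condition: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene IDs")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError(f"expression values must be 2-D, got {self.values.ndim}-D")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ShapeError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ShapeError(
                f"non-finite expression value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def log2_transform(self) -> "ExpressionMatrix":
        """Return a log2(x+1)-transformed copy (optional pre-transform)."""
        return replace(self, values=np.log2(self.values + 1.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, condition: str = "", species: str = ""
    ) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(frame.index),
            sample_ids=list(frame.columns),
            values=frame.to_numpy(dtype=float),
            condition=condition,
            species=species,
        )


@dataclass
class InteractionMatrix:
    """n x m matrix of influence coefficients a_ij (mRNA rows, miRNA columns)."""

    mrna_ids: list[str]
    mirna_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.mrna_ids = _check_ids(self.mrna_ids, "mRNA IDs")
        self.mirna_ids = _check_ids(self.mirna_ids, "miRNA IDs")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mrna_ids), len(self.mirna_ids)):
            raise ShapeError(
                f"interaction matrix shape {self.values.shape} does not match "
                f"{len(self.mrna_ids)} mRNAs x {len(self.mirna_ids)} miRNAs"
            )
        if not np.all(np.isfinite(self.values)):
            raise ShapeError("interaction matrix contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.mrna_ids, columns=self.mirna_ids)

    @classmethod
    def zeros(cls, mrna_ids: Sequence[str], mirna_ids: Sequence[str]) -> "InteractionMatrix":
        return cls(list(mrna_ids), list(mirna_ids), np.zeros((len(mrna_ids), len(mirna_ids))))


def forward(A: InteractionMatrix, X: ExpressionMatrix) -> ExpressionMatrix:
    """Direct solver: predict mRNA expression ``Y = A X``.

    ``A``'s miRNA columns must match ``X``'s gene rows, in the same order.
    Returns an mRNA panel with ``Y[i, k] = sum_j a_ij * X[j, k]``.
    """
    if A.mirna_ids != X.gene_ids:
        raise ShapeError(
            f"interaction matrix columns ({len(A.mirna_ids)} miRNAs) do not match "
            f"miRNA panel rows ({len(X.gene_ids)} genes) or their ordering differs"
        )
    return ExpressionMatrix(
        gene_ids=list(A.mrna_ids),
        sample_ids=list(X.sample_ids),
        values=A.values @ X.values,
        condition=X.condition,
        species="mRNA",
    )


def align_panels(
    X: ExpressionMatrix, Y: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two panels to their shared samples, in X's sample order.

    Gene order is preserved in both panels.  Identical sample lists are
    returned unchanged.
    """
    if X.sample_ids == Y.sample_ids:
        return X, Y
    shared = [s for s in X.sample_ids if s in set(Y.sample_ids)]
    if not shared:
        raise AlignmentError(
            f"no shared samples between panels ({X.sample_ids} vs {Y.sample_ids})"
        )

    def _restrict(panel: ExpressionMatrix) -> ExpressionMatrix:
        cols = [panel.sample_ids.index(s) for s in shared]
        return replace(panel, sample_ids=list(shared), values=panel.values[:, cols])

    return _restrict(X), _restrict(Y)
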