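"""Ground-truthed paired normal/cancer dataset generation.

Emulates the data regime of small paired tumor-profiling panels: a couple
of dozen miRNAs and mRNAs measured over a handful of tissue samples per
condition (defaults: 26 x 26 genes, 4 normal and 7 cancer samples), a
sparse inhibitory (all-negative) influence matrix, and a seeded subset of
edges whose strength changes in the cancer condition.  mRNA panels are
produced by the forward linear model, optionally plus Gaussian noise, so
noiseless datasets are exactly consistent by construction.

Also generates synthetic sequence-prediction pair lists (stand-ins for
PicTar/miRanda exports) by sampling true edges at a chosen true-positive
rate and non-edges at a false-positive rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import ExpressionMatrix, InteractionMatrix
from .errors import ConfigurationError
from .seqfilter import PredictionSet, write_predictions

__all__ = ["SyntheticDataset", "generate", "generate_prediction_sets", "write_dataset"]


@dataclass
class SyntheticDataset:
    """Paired panels + ground truth produced by :func:`generate`."""

    X_normal: ExpressionMatrix
    X_cancer: ExpressionMatrix
    Y_normal: ExpressionMatrix
    Y_cancer: ExpressionMatrix
    A_normal: InteractionMatrix
    A_cancer: InteractionMatrix
    changed_edges: frozenset[tuple[str, str]]  # (mRNA ID, miRNA ID)
    seed: int
    noise_sd: float
    params: dict | None = None

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.X_normal.gene_ids)

    @property
    def mrna_ids(self) -> list[str]:
        return list(self.Y_normal.gene_ids)


def generate(
    n: int = 26,
    m: int = 26,
    k_normal: int = 4,
    k_cancer: int = 7,
    edge_density: float = 0.15,
    change_fraction: float = 0.25,
    effect_multiplier: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    change_mode: str = "scale",
    sign_mode: str = "negative",
) -> SyntheticDataset:
    """Generate a paired normal/cancer dataset with known interactions.

    Parameters
    ----------
    n, m : number of mRNAs (rows of A) and miRNAs (columns).
    k_normal, k_cancer : samples per condition.
    edge_density : fraction of the n*m coefficients that are nonzero.
    change_fraction : fraction of the nonzero edges altered in cancer.
    effect_multiplier : factor (>= 1) applied to changed edges (``change_mode
        ="scale"``); with ``change_mode="zero"`` changed edges are removed
        in cancer instead.
    noise_sd : standard deviation of additive Gaussian noise on the mRNA
        panels (0 gives exactly consistent systems).
    seed : RNG seed; datasets are bit-reproducible from it.
    change_mode : "scale" or "zero".
    sign_mode : "negative" (inhibitory-only coefficients, uniform on
        [-2, -0.2]) or "mixed" (random signs, for stress testing).

    Notes
    -----
    miRNA expression is positive lognormal (log-scale mean 0, sd 1).  With
    the default panel shape the per-row systems are underdetermined
    (samples < miRNAs), reproducing the estimation regime where exact data
    reconstruction coexists with ambiguous coefficient identification.
    """
    if n < 1 or m < 1 or k_normal < 1 or k_cancer < 1:
        raise ConfigurationError("n, m and sample counts must all be >= 1")
    if not (0 <= edge_density <= 1 and 0 <= change_fraction <= 1):
        raise ConfigurationError("edge_density and change_fraction must lie in [0, 1]")
    if effect_multiplier < 1:
        raise ConfigurationError(f"effect_multiplier must be >= 1, got {effect_multiplier}")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be nonnegative")
    if change_mode not in ("scale", "zero"):
        raise ConfigurationError(f"unknown change_mode {change_mode!r}")
    if sign_mode not in ("negative", "mixed"):
        raise ConfigurationError(f"unknown sign_mode {sign_mode!r}")
    n_edges = int(round(edge_density * n * m))
    if n_edges < 1 and change_fraction > 0:
        raise ConfigurationError(
            f"edge_density {edge_density} yields no edges on a {n}x{m} panel "
            "but change_fraction > 0"
        )

    rng = np.random.default_rng(seed)
    mirna_ids = [f"miR-{j + 1:03d}" for j in range(m)]
    mrna_ids = [f"GENE{i + 1:03d}" for i in range(n)]

    A_n = np.zeros((n, m))
    flat = rng.choice(n * m, size=n_edges, replace=False)
    coeffs = rng.uniform(0.2, 2.0, size=n_edges)
    if sign_mode == "negative":
        coeffs = -coeffs
    else:
        coeffs *= rng.choice([-1.0, 1.0], size=n_edges)
    A_n.flat[flat] = coeffs

    n_changed = int(round(change_fraction * n_edges))
    changed_flat = rng.choice(flat, size=n_changed, replace=False) if n_changed else np.array([], int)
    A_c = A_n.copy()
    if change_mode == "scale":
        A_c.flat[changed_flat] *= effect_multiplier
    else:
        A_c.flat[changed_flat] = 0.0
    # defined by actual inequality so the invariant holds even when the
    # multiplier is exactly 1 (a scale by 1 changes nothing)
    changed = frozenset(
        (mrna_ids[i], mirna_ids[j]) for i, j in np.argwhere(A_n != A_c)
    )

    def _panels(K: int, condition: str) -> tuple[ExpressionMatrix, ExpressionMatrix]:
        samples = [f"{condition}_{k + 1}" for k in range(K)]
        Xv = rng.lognormal(mean=0.0, sigma=1.0, size=(m, K))
        A = A_n if condition == "normal" else A_c
        Yv = A @ Xv
        if noise_sd > 0:
            Yv = Yv + rng.normal(0.0, noise_sd, size=Yv.shape)
        X = ExpressionMatrix(mirna_ids, samples, Xv, condition=condition, species="miRNA")
        Y = ExpressionMatrix(mrna_ids, samples, Yv, condition=condition, species="mRNA")
        return X, Y

    X_n, Y_n = _panels(k_normal, "normal")
    X_c, Y_c = _panels(k_cancer, "cancer")
    params = {
        "n": n, "m": m, "k_normal": k_normal, "k_cancer": k_cancer,
        "edge_density": edge_density, "change_fraction": change_fraction,
        "effect_multiplier": effect_multiplier, "noise_sd": noise_sd,
        "seed": seed, "change_mode": change_mode, "sign_mode": sign_mode,
    }
    return SyntheticDataset(
        X_normal=X_n, X_cancer=X_c, Y_normal=Y_n, Y_cancer=Y_c,
        A_normal=InteractionMatrix(mrna_ids, mirna_ids, A_n),
        A_cancer=InteractionMatrix(mrna_ids, mirna_ids, A_c),
        changed_edges=changed, seed=seed, noise_sd=noise_sd, params=params,
    )


def true_edges(dataset: SyntheticDataset) -> frozenset[tuple[str, str]]:
    """(miRNA ID, mRNA ID) pairs with a nonzero coefficient in either condition."""
    nz = (dataset.A_normal.values != 0) | (dataset.A_cancer.values != 0)
    return frozenset(
        (dataset.mirna_ids[j], dataset.mrna_ids[i]) for i, j in np.argwhere(nz)
    )


def generate_prediction_sets(
    dataset: SyntheticDataset,
    true_positive_rate: float = 0.8,
    false_positive_rate: float = 0.05,
    seed: int = 0,
) -> list[PredictionSet]:
    """Two synthetic sequence-prediction pair lists for the dataset.

    Each resource independently includes every true edge with probability
    ``true_positive_rate`` and every non-edge with probability
    ``false_positive_rate`` — sequence predictors see real binding sites but
    also miss some and hallucinate others, independent of condition.
    """
    if not (0 <= true_positive_rate <= 1 and 0 <= false_positive_rate <= 1):
        raise ConfigurationError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = true_edges(dataset)
    sets = []
    for source in ("miranda", "pictar"):
        pairs = set()
        for mrna in dataset.mrna_ids:
            for mirna in dataset.mirna_ids:
                rate = true_positive_rate if (mirna, mrna) in truth else false_positive_rate
                if rng.random() < rate:
                    pairs.add((mirna, mrna))
        sets.append(PredictionSet(source=source, pairs=frozenset(pairs)))
    return sets


def _write_expression_tsv(panel: ExpressionMatrix, path: Path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def write_dataset(
    dataset: SyntheticDataset,
    outdir: str | Path,
    predictions: list[PredictionSet] | None = None,
) -> dict[str, Path]:
    """Write the dataset in the same TSV formats the pipeline reads.

    Emits four expression panels, a truth edge list with both condition
    coefficients, a manifest (all generator parameters + seed), and
    optionally prediction pair lists.  Returns the paths keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for key, panel in (
        ("mirna_normal", dataset.X_normal), ("mirna_cancer", dataset.X_cancer),
        ("mrna_normal", dataset.Y_normal), ("mrna_cancer", dataset.Y_cancer),
    ):
        p = outdir / f"{key}.tsv"
        _write_expression_tsv(panel, p)
        paths[key] = p

    truth = outdir / "truth_edges.tsv"
    with open(truth, "w") as fh:
        fh.write("mrna_id\tmirna_id\ta_normal\ta_cancer\tchanged\n")
        nz = (dataset.A_normal.values != 0) | (dataset.A_cancer.values != 0)
        for i, j in np.argwhere(nz):
            mrna, mirna = dataset.mrna_ids[i], dataset.mirna_ids[j]
            fh.write(
                f"{mrna}\t{mirna}\t{dataset.A_normal.values[i, j]!r}\t"
                f"{dataset.A_cancer.values[i, j]!r}\t"
                f"{int((mrna, mirna) in dataset.changed_edges)}\n"
            )
    paths["truth"] = truth

    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps(dataset.params or {}, indent=1))
    paths["manifest"] = manifest

    if predictions is not None:
        pred = outdir / "predictions.tsv"
        write_predictions(predictions, pred)
        paths["predictions"] = pred
    return paths
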