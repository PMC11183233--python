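"""Differential-expression signatures and connectivity ranking.

Quality-controlled annotations feed a standardized differential-expression
step: counts are library-size normalized (counts per million) and
log2(x+1) transformed, microarray intensities are taken as already on log
scale, and each gene gets a Welch t-statistic (perturbation minus
control).  The signed per-gene vector is the perturbation's *signature*.

Two signatures are compared by Spearman correlation over the union of
their strongest genes; a positive correlation means a similar
transcriptomic pattern, a negative one an opposing pattern — the candidate
logic of repurposing screens, where a compound opposing a disease
signature is a lead.  Significance comes from a seeded gene-label
permutation test, with Benjamini–Hochberg control across a library.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metadata_model import AnnotationRecord

__all__ = [
    "Scale",
    "ExpressionMatrix",
    "Signature",
    "Direction",
    "ConnectivityResult",
    "compute_signature",
    "connectivity",
    "rank_repurposing",
]


class Scale(str, enum.Enum):
    log_intensity = "log_intensity"
    counts = "counts"


class Direction(str, enum.Enum):
    similar = "similar"
    opposing = "opposing"


@dataclass
class ExpressionMatrix:
    """Genes × samples expression grid with an explicit scale."""

    values: pd.DataFrame  # index: genes, columns: samples
    scale: Scale = Scale.log_intensity

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if self.scale == Scale.counts:
            arr = self.values.to_numpy()
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be non-negative integers")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path, scale: Scale = Scale.log_intensity) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        return cls(values=df, scale=scale)

    def to_mtx(self, prefix: str | Path) -> None:
        """Write MatrixMarket triplet plus gene/sample index sidecars."""
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        prefix = Path(prefix)
        mmwrite(str(prefix) + ".mtx", csr_matrix(self.values.to_numpy()))
        Path(str(prefix) + "_genes.txt").write_text("\n".join(self.genes) + "\n")
        Path(str(prefix) + "_samples.txt").write_text("\n".join(self.samples) + "\n")

    @classmethod
    def from_mtx(cls, prefix: str | Path, scale: Scale = Scale.log_intensity) -> "ExpressionMatrix":
        from scipy.io import mmread

        prefix = Path(prefix)
        mat = mmread(str(prefix) + ".mtx").toarray()
        genes = Path(str(prefix) + "_genes.txt").read_text().splitlines()
        samples = Path(str(prefix) + "_samples.txt").read_text().splitlines()
        return cls(values=pd.DataFrame(mat, index=genes, columns=samples), scale=scale)


@dataclass
class Signature:
    """Signed per-gene statistics summarizing one perturbation's effect."""

    label: str
    stats: pd.Series  # index: genes, values: Welch t statistics
    n_ctrl: int
    n_pert: int

    def to_tsv(self, path: str | Path) -> None:
        self.stats.rename("statistic").to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path, label: str = "", n_ctrl: int = 0, n_pert: int = 0) -> "Signature":
        s = pd.read_csv(path, sep="\t", index_col=0)["statistic"]
        return cls(label=label or str(path), stats=s, n_ctrl=n_ctrl, n_pert=n_pert)


@dataclass
class ConnectivityResult:
    query: str
    target: str
    correlation: float
    p_value: float
    q_value: float
    direction: Direction
    n_genes: int

    @staticmethod
    def table(results: Sequence["ConnectivityResult"]) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "query": r.query,
                    "target": r.target,
                    "correlation": r.correlation,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                    "direction": r.direction.value,
                    "n_genes": r.n_genes,
                }
                for r in results
            ]
        )


def _to_log(matrix: ExpressionMatrix) -> pd.DataFrame:
    if matrix.scale == Scale.log_intensity:
        return matrix.values
    counts = matrix.values.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    lib[lib == 0] = 1.0
    cpm = counts / lib * 1e6
    return pd.DataFrame(np.log2(cpm + 1.0), index=matrix.values.index, columns=matrix.values.columns)


def compute_signature(matrix: ExpressionMatrix, annotation: AnnotationRecord) -> Signature:
    """Welch t signature of perturbation vs control groups on log scale.

    Counts are CPM-normalized and log2(x+1) transformed first, so one
    standardized procedure covers both microarray and RNA-seq inputs.
    Genes with zero variance in both groups are dropped.  Each group needs
    at least two samples present in the matrix.
    """
    cols = set(matrix.samples)
    ctrl = sorted(annotation.ctrl_ids & cols)
    pert = sorted(annotation.pert_ids & cols)
    if len(ctrl) < 2 or len(pert) < 2:
        raise ValueError(
            f"insufficient replicates: {len(ctrl)} control / {len(pert)} perturbation samples in matrix"
        )
    log = _to_log(matrix)
    c = log[ctrl].to_numpy()
    p = log[pert].to_numpy()
    keep = ~((c.var(axis=1) == 0) & (p.var(axis=1) == 0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # lone zero-variance groups
        t = stats.ttest_ind(p[keep], c[keep], axis=1, equal_var=False).statistic
    genes = log.index[keep]
    return Signature(
        label=f"{annotation.pert_name}@{annotation.series_id}",
        stats=pd.Series(t, index=genes),
        n_ctrl=len(ctrl),
        n_pert=len(pert),
    )


def _top_union(query: Signature, target: Signature, n_top: int) -> pd.Index:
    shared = query.stats.index.intersection(target.stats.index)
    top_q = query.stats.loc[shared].abs().sort_values(ascending=False, kind="stable").index[:n_top]
    top_t = target.stats.loc[shared].abs().sort_values(ascending=False, kind="stable").index[:n_top]
    return shared[shared.isin(set(top_q) | set(top_t))]


def connectivity(
    query: Signature,
    target: Signature,
    n_top: int = 250,
    n_perm: int = 10_000,
    seed: int = 0,
    q_value: float = float("nan"),
) -> ConnectivityResult:
    """Spearman connectivity between two signatures with a permutation p.

    The correlation is computed over the union of each signature's
    ``n_top`` strongest-|statistic| genes, restricted to shared genes
    (at least 10 required).  The two-sided p-value permutes the gene
    labels of the target signature ``n_perm`` times with a fixed seed.
    """
    genes = _top_union(query, target, n_top)
    if len(genes) < 10:
        raise ValueError(f"only {len(genes)} shared genes (>= 10 required)")
    x = query.stats.loc[genes].to_numpy()
    y = target.stats.loc[genes].to_numpy()
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    # perfect rank (anti-)agreement is reported exactly
    if np.array_equal(rx, ry):
        rho = 1.0
    elif np.array_equal(rx + ry, np.full_like(rx, rx.min() + rx.max())):
        rho = -1.0
    else:
        rho = _pearson(rx, ry)
    rng = np.random.default_rng(seed)
    n = len(genes)
    perm_idx = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    rho_perm = _pearson_rows(rx, ry[perm_idx])
    p = (1 + np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12)) / (n_perm + 1)
    return ConnectivityResult(
        query=query.label,
        target=target.label,
        correlation=float(rho),
        p_value=float(p),
        q_value=q_value,
        direction=Direction.similar if rho > 0 else Direction.opposing,
        n_genes=n,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    return float(xc @ yc / denom) if denom else 0.0


def _pearson_rows(x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    yc = ys - ys.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=1))
    denom[denom == 0] = np.inf
    return yc @ xc / denom


def rank_repurposing(
    query: Signature,
    library: Sequence[Signature],
    n_top: int = 250,
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[ConnectivityResult]:
    """Connectivity of the query against a signature library, BH-corrected.

    Library members with too little gene overlap are skipped with a
    warning.  Results carry Benjamini–Hochberg q-values across the library
    and are sorted by correlation (most similar first, strongest opposing
    last — the repurposing candidates).
    """
    if not library:
        raise ValueError("signature library is empty")
    results: list[ConnectivityResult] = []
    for i, target in enumerate(library):
        try:
            results.append(connectivity(query, target, n_top=n_top, n_perm=n_perm, seed=seed + i))
        except ValueError as exc:
            warnings.warn(f"skipping {target.label}: {exc}", stacklevel=2)
    if results:
        _, q, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        results = [
            ConnectivityResult(
                r.query, r.target, r.correlation, r.p_value, float(qi), r.direction, r.n_genes
            )
            for r, qi in zip(results, q)
        ]
    return sorted(results, key=lambda r: -r.correlation)
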