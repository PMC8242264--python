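"""Stage-1 candidate selection: thresholding, window de-duplication,
Kruskal-Wallis scanning, per-chromosome LARS and (iterative) sure
independence screening.

All screening is deterministic: ties are broken by p-value, then position,
then marker index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lars_path

from .data_io import GenotypeDataset
from .mlm import ScanResult

__all__ = [
    "CandidateSet",
    "select_by_pvalue",
    "dedup_by_radius",
    "kw_scan",
    "lars_select_per_chromosome",
    "sis_screen",
]


@dataclass
class CandidateSet:
    """Indices of stage-1 candidate markers plus their provenance statistic."""

    indices: np.ndarray  # sorted, unique marker indices
    method: str
    statistics: dict[int, float] = field(default_factory=dict)
    pvalues: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("candidate indices must be unique")
        self.indices = np.sort(idx)

    def __len__(self) -> int:
        return len(self.indices)

    def table(self, info: pd.DataFrame) -> pd.DataFrame:
        rows = info.iloc[self.indices]
        return pd.DataFrame(
            {
                "marker": rows["name"].to_numpy(),
                "chromosome": rows["chrom"].to_numpy(),
                "position": rows["pos"].to_numpy(),
                "statistic": [self.statistics.get(i, np.nan) for i in self.indices],
                "p_value": [self.pvalues.get(i, np.nan) for i in self.indices],
            }
        )


def select_by_pvalue(scan: ScanResult, alpha_screen: float = 0.005) -> CandidateSet:
    """Keep markers whose stage-1 p-value is at most ``alpha_screen``."""
    if not 0 < alpha_screen <= 1:
        raise ValueError("alpha_screen must lie in (0, 1]")
    idx = np.flatnonzero(scan.pvalues <= alpha_screen)
    return CandidateSet(
        idx,
        method=scan.method,
        statistics={int(i): float(scan.statistics[i]) for i in idx},
        pvalues={int(i): float(scan.pvalues[i]) for i in idx},
    )


def dedup_by_radius(
    cands: CandidateSet, info: pd.DataFrame, radius_kb: float
) -> CandidateSet:
    """Greedy per-chromosome sweep in ascending p-value order.

    A candidate is accepted iff no already-accepted candidate on the same
    chromosome lies within ``radius_kb`` kilobases; ties in p break by
    position, then marker name.
    """
    if len(cands) == 0:
        return cands
    radius_bp = radius_kb * 1000.0
    idx = cands.indices
    chrom = info["chrom"].to_numpy()[idx]
    pos = info["pos"].to_numpy()[idx]
    name = info["name"].to_numpy()[idx]
    pval = np.array([cands.pvalues.get(int(i), np.nan) for i in idx])
    order = sorted(
        range(len(idx)), key=lambda r: (pval[r], pos[r], str(name[r]))
    )
    accepted_pos: dict[str, list[float]] = {}
    keep = []
    for r in order:
        taken = accepted_pos.setdefault(chrom[r], [])
        if all(abs(pos[r] - q) > radius_bp for q in taken):
            taken.append(float(pos[r]))
            keep.append(idx[r])
    keep = np.array(sorted(keep), dtype=int)
    return CandidateSet(
        keep,
        method=cands.method,
        statistics={int(i): cands.statistics.get(int(i), np.nan) for i in keep},
        pvalues={int(i): cands.pvalues.get(int(i), np.nan) for i in keep},
    )


def kw_scan(y: np.ndarray, genotype: GenotypeDataset, trait: str = "") -> ScanResult:
    """Kruskal-Wallis rank scan over the genotype classes of each marker.

    ``y`` should already be covariate-adjusted (ordinary least-squares
    residual).  The H statistic uses the standard tie correction; the
    p-value comes from the chi-square distribution with (classes - 1)
    degrees of freedom.  Markers with a single genotype class, or a
    phenotype with all values tied, report p = 1.
    """
    y = np.asarray(y, float)
    n = len(y)
    X = genotype.codes
    ranks = stats.rankdata(y)
    # tie correction over the phenotype's tie groups
    _, counts = np.unique(y, return_counts=True)
    tie_num = float(np.sum(counts**3 - counts))
    C = 1.0 - tie_num / (n**3 - n) if n > 1 else 0.0

    m = X.shape[1]
    S = np.zeros(m)  # sum of R_g^2 / n_g over non-empty classes
    classes = np.zeros(m, dtype=int)
    for a in (-1.0, 0.0, 1.0):
        M = (X == a).astype(float)
        ng = M.sum(axis=0)
        Rg = ranks @ M
        nz = ng > 0
        S[nz] += Rg[nz] ** 2 / ng[nz]
        classes += nz.astype(int)
    H = 12.0 / (n * (n + 1)) * S - 3.0 * (n + 1)
    df = classes - 1
    valid = (df >= 1) & (C > 0)
    H = np.where(valid, H / np.where(C > 0, C, 1.0), 0.0)
    H = np.maximum(H, 0.0)
    pvals = np.ones(m)
    pvals[valid] = stats.chi2.sf(H[valid], df[valid])
    return ScanResult(np.zeros(m), H, pvals, method="kw_scan", trait=trait)


def lars_select_per_chromosome(
    y_w: np.ndarray,
    genotype: GenotypeDataset,
    max_per_chrom: int = 50,
    Z: np.ndarray | None = None,
) -> CandidateSet:
    """Least-angle-regression entry-order selection, per chromosome.

    For each chromosome the first ``min(max_per_chrom, m_chrom, n - 1)``
    markers to enter the LAR path against ``y_w`` are kept, in entry order.
    Markers are standardized to unit variance within the run; ``Z`` (e.g.
    whitened codes) replaces the raw codes when given.
    """
    if max_per_chrom < 1:
        raise ValueError("max_per_chrom must be >= 1")
    G = Z if Z is not None else genotype.codes
    y_w = np.asarray(y_w, float)
    n = len(y_w)
    chrom = genotype.info["chrom"].to_numpy()
    indices: list[int] = []
    stats_out: dict[int, float] = {}
    for c in pd.unique(chrom):
        cols = np.flatnonzero(chrom == c)
        Xc = G[:, cols]
        sd = Xc.std(axis=0)
        poly = sd > 1e-12
        if not poly.any():
            continue
        cols = cols[poly]
        Xs = (Xc[:, poly] - Xc[:, poly].mean(axis=0)) / sd[poly]
        k = min(max_per_chrom, len(cols), n - 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, active, _ = lars_path(
                Xs, y_w - y_w.mean(), method="lar", max_iter=k, return_path=False
            )
        chosen = [int(cols[a]) for a in active[:k]]
        for rank, j in enumerate(chosen):
            stats_out[j] = float(rank + 1)  # entry order, 1-based
        indices.extend(chosen)
    return CandidateSet(
        np.array(indices, dtype=int), method="pLARmEB", statistics=stats_out
    )


def sis_screen(
    y_w: np.ndarray,
    genotype: GenotypeDataset,
    d: int | None = None,
    iterations: int = 2,
    Z: np.ndarray | None = None,
    ridge: float = 1e-6,
) -> CandidateSet:
    """(Iterative) sure independence screening at the genome level.

    Iteration 1 keeps the ``d`` markers with the largest absolute correlation
    with ``y_w``; later iterations regress ``y_w`` on the kept markers (ridge
    with a small penalty) and rank the rest by absolute correlation with the
    residual.  The default dimension is ``floor(n / log n)``.  Exact ties
    break toward the lower marker index.
    """
    G = Z if Z is not None else genotype.codes
    y_w = np.asarray(y_w, float)
    n = len(y_w)
    m = G.shape[1]
    if d is None:
        d = max(1, int(np.floor(n / np.log(n))))
    if d < 1:
        raise ValueError("d must be >= 1")
    if d >= m:
        warnings.warn(f"screening dimension d={d} >= m={m}; keeping all markers")
        return CandidateSet(np.arange(m), method="ISIS EM-BLASSO")

    Gc = G - G.mean(axis=0)
    sd = Gc.std(axis=0)
    usable = sd > 1e-12
    Gs = np.where(usable, Gc / np.where(usable, sd, 1.0), 0.0)

    def top_d(resid: np.ndarray, excluded: set[int]) -> list[int]:
        score = np.abs(Gs.T @ (resid - resid.mean())) / n
        score[~usable] = -np.inf
        if excluded:
            score[list(excluded)] = -np.inf
        # stable sort on -score => ties keep the lower index first
        order = np.argsort(-score, kind="stable")
        return [int(j) for j in order[:d] if np.isfinite(score[j])]

    kept: list[int] = top_d(y_w, set())
    scores: dict[int, float] = {}
    resid = y_w
    for it in range(1, iterations):
        Zk = Gc[:, kept]
        A = Zk.T @ Zk + ridge * np.trace(Zk.T @ Zk) / max(len(kept), 1) * np.eye(len(kept))
        beta = np.linalg.solve(A, Zk.T @ (y_w - y_w.mean()))
        resid = y_w - y_w.mean() - Zk @ beta
        kept.extend(top_d(resid, set(kept)))
    corr0 = np.abs(Gs.T @ (y_w - y_w.mean())) / n
    for j in kept:
        scores[j] = float(corr0[j])
    return CandidateSet(
        np.array(kept, dtype=int), method="ISIS EM-BLASSO", statistics=scores
    )
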