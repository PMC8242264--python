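"""Genetic relationship (kinship) matrices from coded genotypes.

Two estimators are provided:

* ``marker_scaled`` — the centered cross-product ``W W' / c`` with
  ``c = sum_k 2 p_k (1 - p_k)`` over polymorphic markers, i.e. the genomic
  relationship matrix normalized by total expected heterozygosity.
* ``ibs`` — identity-by-state allele sharing,
  ``K[i,j] = 1 - sum_k |x_ik - x_jk| / (2 m)`` under the {-1, 0, +1} coding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import GenotypeDataset

__all__ = ["KinshipMatrix", "kinship_marker_scaled", "kinship_ibs"]

_PSD_TOL = -1e-8


@dataclass
class KinshipMatrix:
    values: np.ndarray
    method: str  # "marker_scaled" | "ibs"

    def __post_init__(self) -> None:
        K = self.values
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kinship must be square")
        if np.max(np.abs(K - K.T)) > 1e-10:
            raise ValueError("kinship must be symmetric to 1e-10")
        if self.method == "marker_scaled":
            w = np.linalg.eigvalsh(K)
            if w.min() < _PSD_TOL * max(1.0, w.max()):
                raise ValueError(
                    f"kinship not positive semi-definite (min eigenvalue {w.min():.3g})"
                )
        elif self.method == "ibs":
            if K.min() < -1e-10 or K.max() > 1 + 1e-10:
                raise ValueError("IBS kinship entries must lie in [0, 1]")
        elif self.method != "external":
            raise ValueError(f"unknown kinship method {self.method!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _require_imputed(genotype: GenotypeDataset) -> None:
    if not genotype.is_imputed:
        raise ValueError("genotypes must be imputed before kinship estimation")


def kinship_marker_scaled(
    genotype: GenotypeDataset, normalize_diag: bool = False
) -> KinshipMatrix:
    """Scaled cross-product kinship ``W W' / c``.

    ``W`` is the column-centered code matrix restricted to polymorphic
    markers and ``c = sum_k 2 p_k (1 - p_k)`` (p_k = minor-allele frequency).
    ``normalize_diag=True`` additionally rescales so the diagonal mean is 1.
    """
    _require_imputed(genotype)
    maf = genotype.maf
    poly = maf > 0
    if not poly.any():
        raise ValueError("all markers are monomorphic; kinship undefined")
    X = genotype.codes[:, poly]
    W = X - X.mean(axis=0)
    p = maf[poly]
    c = float(np.sum(2.0 * p * (1.0 - p)))
    K = (W @ W.T) / c
    K = (K + K.T) / 2.0
    if normalize_diag:
        K = K / np.mean(np.diag(K))
    return KinshipMatrix(K, "marker_scaled")


def kinship_ibs(genotype: GenotypeDataset) -> KinshipMatrix:
    """Identity-by-state allele-sharing kinship."""
    _require_imputed(genotype)
    if genotype.m == 0:
        raise ValueError("no markers")
    X = genotype.codes
    # sum_k |x_i - x_j| expands over the three code values without an n^2 m loop
    D = np.zeros((genotype.n, genotype.n))
    for a in (-1.0, 0.0, 1.0):
        A = (X == a).astype(float)
        for b in (-1.0, 0.0, 1.0):
            if abs(a - b) == 0:
                continue
            B = (X == b).astype(float)
            D += abs(a - b) * (A @ B.T)
    K = 1.0 - D / (2.0 * genotype.m)
    K = (K + K.T) / 2.0
    return KinshipMatrix(np.clip(K, 0.0, 1.0), "ibs")
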