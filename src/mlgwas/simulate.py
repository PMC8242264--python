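"""Synthetic GWAS data: biallelic SNP genotypes with block LD, sparse QTN
effects, a polygenic background and Gaussian residual noise.

The generator emulates the inputs a multi-locus association run consumes and
doubles as the fixture factory for the file readers (it can emit all three
genotype dialects).  Genotypes are drawn under Hardy-Weinberg equilibrium
with a per-marker minor-allele frequency sampled uniformly from a range;
local linkage disequilibrium is induced by a neighbor-copy rule (with
probability ``ld_rho`` a marker duplicates its left neighbor's codes).
Marker positions are spaced 10 kb apart.  Everything is reproducible from
the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import GenotypeDataset, PhenotypeTable, write_genotype
from .kinship import kinship_marker_scaled

__all__ = [
    "SimSpec",
    "QTNSpec",
    "TruthRecord",
    "simulate_genotypes",
    "simulate_phenotype",
    "score_detection",
    "write_dialect_fixtures",
]

MARKER_SPACING_BP = 10_000
_ALLELES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class QTNSpec:
    """One causal marker: either a target r2 share of var(y) or a fixed effect."""

    index: int
    r2: float | None = None
    effect: float | None = None

    def __post_init__(self) -> None:
        if (self.r2 is None) == (self.effect is None):
            raise ValueError("give exactly one of r2 or effect")


@dataclass
class SimSpec:
    n: int = 200
    m: int = 2000
    chromosomes: int = 5
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.5
    qtns: list[QTNSpec] = field(default_factory=list)
    h2_poly: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must sit inside (0, 0.5]")
        idx = [q.index for q in self.qtns]
        if len(set(idx)) != len(idx):
            raise ValueError("QTN indices must be distinct")
        if any(i < 0 or i >= self.m for i in idx):
            raise ValueError("QTN index out of range")
        r2_total = sum(q.r2 for q in self.qtns if q.r2 is not None)
        if r2_total + self.h2_poly >= 1.0:
            raise ValueError(
                f"variance budget infeasible: sum r2 ({r2_total}) + h2_poly "
                f"({self.h2_poly}) must stay below 1"
            )


@dataclass
class TruthRecord:
    """Ground truth for scoring: causal markers, effects and positions."""

    indices: np.ndarray
    effects: np.ndarray
    positions: np.ndarray
    chromosomes: np.ndarray
    target_r2: np.ndarray
    h2_poly: float
    var_y: float


def simulate_genotypes(spec: SimSpec) -> GenotypeDataset:
    """Draw the genotype matrix and marker map for ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n, spec.m
    lo, hi = spec.maf_range
    maf_t = rng.uniform(lo, hi, size=m)
    # Hardy-Weinberg genotype draws for the minor allele count 0/1/2
    u = rng.random((n, m))
    p = maf_t[None, :]
    hom_minor = u < p**2
    het = (u >= p**2) & (u < p**2 + 2 * p * (1 - p))
    codes = np.where(hom_minor, -1.0, np.where(het, 0.0, 1.0))
    # neighbor-copy LD, never across a chromosome boundary
    per_chrom = np.array_split(np.arange(m), spec.chromosomes)
    copy = rng.random(m) < spec.ld_rho
    for block in per_chrom:
        for j in block[1:]:
            if copy[j]:
                codes[:, j] = codes[:, j - 1]

    names = [f"snp{j + 1}" for j in range(m)]
    chroms: list[str] = []
    poss: list[int] = []
    for ci, block in enumerate(per_chrom, start=1):
        chroms.extend([str(ci)] * len(block))
        poss.extend((np.arange(len(block)) + 1) * MARKER_SPACING_BP)
    allele_pairs = [
        tuple(rng.choice(len(_ALLELES), size=2, replace=False)) for _ in range(m)
    ]
    major = [_ALLELES[a] for a, _ in allele_pairs]
    minor = [_ALLELES[b] for _, b in allele_pairs]
    # realized minor-allele frequency from the drawn codes
    p_minor = (np.sum(codes == -1, axis=0) + 0.5 * np.sum(codes == 0, axis=0)) / n
    maf = np.minimum(p_minor, 1.0 - p_minor)
    # keep the stored major/minor consistent with realized frequencies and the
    # lexicographic tie rule, so dialect round-trips are exact
    for j in range(m):
        flip = p_minor[j] > 0.5 or (p_minor[j] == 0.5 and minor[j] < major[j])
        if flip:
            major[j], minor[j] = minor[j], major[j]
            codes[:, j] = -codes[:, j]
    info = pd.DataFrame(
        {
            "name": names,
            "chrom": chroms,
            "pos": np.asarray(poss, dtype=np.int64),
            "major": major,
            "minor": minor,
            "maf": maf,
        }
    )
    return GenotypeDataset(
        individuals=[f"ind{i + 1}" for i in range(n)],
        info=info,
        codes=codes,
        missing=np.zeros((n, m), dtype=bool),
    )


def simulate_phenotype(
    genotype: GenotypeDataset, spec: SimSpec, trait_name: str = "trait1"
) -> tuple[PhenotypeTable, TruthRecord]:
    """Build ``y = sum_j effect_j x_j + polygenic + noise`` with unit target
    variance.

    Effects given as target r2 are solved via
    ``effect = sqrt(r2 * var_y / (2 p (1 - p)))`` with p the realized MAF.
    The polygenic term is multivariate normal with covariance
    ``h2_poly * K`` (marker-scaled kinship); the residual picks up the
    remaining variance share.
    """
    rng = np.random.default_rng(spec.seed + 1_000_003)
    n = genotype.n
    var_y = 1.0
    maf = genotype.maf
    effects = np.zeros(len(spec.qtns))
    target_r2 = np.zeros(len(spec.qtns))
    genetic = np.zeros(n)
    for i, q in enumerate(spec.qtns):
        p = maf[q.index]
        if q.r2 is not None:
            if p <= 0:
                raise ValueError(f"QTN at monomorphic marker index {q.index}")
            effects[i] = np.sqrt(q.r2 * var_y / (2.0 * p * (1.0 - p)))
            target_r2[i] = q.r2
        else:
            effects[i] = q.effect
            target_r2[i] = 2.0 * p * (1.0 - p) * q.effect**2 / var_y
        genetic += effects[i] * genotype.codes[:, q.index]
    r2_total = float(np.sum(target_r2))
    if r2_total + spec.h2_poly >= 1.0:
        raise ValueError("variance budget infeasible")
    if spec.h2_poly > 0:
        K = kinship_marker_scaled(genotype).values
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        poly = np.sqrt(spec.h2_poly * var_y) * (L @ rng.standard_normal(n))
        poly /= max(np.sqrt(np.mean(np.diag(K))), 1e-12)
    else:
        poly = np.zeros(n)
    sigma_e = np.sqrt((1.0 - r2_total - spec.h2_poly) * var_y)
    y = genetic + poly + sigma_e * rng.standard_normal(n)
    table = PhenotypeTable(
        individuals=list(genotype.individuals),
        traits=[trait_name],
        values=y[:, None],
    )
    idx = np.array([q.index for q in spec.qtns], dtype=int)
    truth = TruthRecord(
        indices=idx,
        effects=effects,
        positions=genotype.info["pos"].to_numpy()[idx] if len(idx) else np.array([], int),
        chromosomes=genotype.info["chrom"].to_numpy()[idx] if len(idx) else np.array([], str),
        target_r2=target_r2,
        h2_poly=spec.h2_poly,
        var_y=float(np.var(y)),
    )
    return table, truth


def score_detection(qtns, truth: TruthRecord, window_kb: float = 20.0) -> dict:
    """Power / false-positive summary of a call list against the truth.

    A true QTN counts as detected when any call on its chromosome lies
    within ``window_kb``; calls matching no true QTN are false positives.
    An empty call list reports power 0 and FDR 0 with ``fdr_defined=False``.
    """
    window_bp = window_kb * 1000.0
    calls = [(str(q.chromosome), float(q.position)) for q in qtns]
    n_true = len(truth.indices)
    detected = np.zeros(n_true, dtype=bool)
    matched_call = np.zeros(len(calls), dtype=bool)
    for t in range(n_true):
        tc, tp = str(truth.chromosomes[t]), float(truth.positions[t])
        for ci, (cc, cp) in enumerate(calls):
            if cc == tc and abs(cp - tp) <= window_bp:
                detected[t] = True
                matched_call[ci] = True
    false_pos = int(np.sum(~matched_call))
    power = float(np.mean(detected)) if n_true else 0.0
    fdr_defined = len(calls) > 0
    fdr = false_pos / len(calls) if fdr_defined else 0.0
    return {
        "power": power,
        "detected": detected,
        "false_positives": false_pos,
        "fdr": fdr,
        "fdr_defined": fdr_defined,
        "n_calls": len(calls),
    }


def write_dialect_fixtures(
    genotype: GenotypeDataset, phenotype: PhenotypeTable, outdir: str
) -> dict[str, str]:
    """Emit the generated data in all three genotype dialects + phenotype CSV."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for fmt in ("Num", "Cha", "Hmp"):
        path = os.path.join(outdir, f"genotype_{fmt.lower()}.csv")
        write_genotype(genotype, path, fmt)
        paths[fmt] = path
    phe_path = os.path.join(outdir, "phenotype.csv")
    pd.DataFrame(
        {"id": phenotype.individuals}
        | {t: phenotype.values[:, i] for i, t in enumerate(phenotype.traits)}
    ).to_csv(phe_path, index=False)
    paths["phenotype"] = phe_path
    return paths
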