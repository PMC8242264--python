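"""Model / results objects for a multi-locus genome-wide association fit.

:class:`MultiLocusGWAS` wraps one trait vector, an imputed genotype matrix,
optional fixed covariates and a kinship matrix.  ``fit(method=...)`` runs one
of the six named two-stage pipelines and returns a
:class:`GWASResults` carrying the stage-1 scan, the screened candidate set,
the empirical-Bayes fit, the called QTNs and a ``summary()`` table.

All six methods share the same architecture: a genome-wide screening stage
nominates candidate markers, then a multi-locus empirical-Bayes stage
jointly shrinks candidate effects and calls QTNs by likelihood-ratio LOD.

======================  =====================================================
method                  stage 1
======================  =====================================================
mrMLM                   random-effect scan -> p <= alpha -> window dedup
FASTmrMLM               fixed-effect (GLS) scan -> p <= alpha -> window dedup
FASTmrEMMA              whiten, random-effect scan on whitened data
pLARmEB                 whiten, per-chromosome LARS entry order
pKWmEB                  Kruskal-Wallis rank scan -> p <= alpha (rank scale)
ISIS EM-BLASSO          whiten, iterative sure independence screening
======================  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ebayes, mlm, screening
from .data_io import AlignedBundle, GenotypeDataset
from .kinship import KinshipMatrix, kinship_marker_scaled
from .mlm import ScanResult, SpectralBasis, VarianceComponents

__all__ = ["METHODS", "MultiLocusGWAS", "GWASResults"]

METHODS = (
    "mrMLM",
    "FASTmrMLM",
    "FASTmrEMMA",
    "pLARmEB",
    "pKWmEB",
    "ISIS EM-BLASSO",
)


@dataclass
class GWASResults:
    """Result of one (trait, method) multi-locus association fit."""

    method: str
    trait: str
    vc: VarianceComponents
    scan: ScanResult | None
    candidates: screening.CandidateSet
    ebfit: ebayes.EBFit | None
    lrt_table: pd.DataFrame
    qtns: list[ebayes.QTNRecord]
    params: dict = field(default_factory=dict)
    info: pd.DataFrame | None = None

    @property
    def qtn_frame(self) -> pd.DataFrame:
        return ebayes.qtn_table(self.qtns)

    @property
    def candidate_frame(self) -> pd.DataFrame:
        if self.info is None or len(self.candidates) == 0:
            return pd.DataFrame(
                columns=["marker", "chromosome", "position", "statistic", "p_value"]
            )
        return self.candidates.table(self.info)

    def summary(self) -> str:
        lines = [
            "Multi-locus GWAS results",
            "=" * 64,
            f"method:          {self.method}",
            f"trait:           {self.trait}",
            f"criterion:       {self.vc.criterion}",
            f"sigma_g^2:       {self.vc.sigma_g2:.6g}",
            f"sigma_e^2:       {self.vc.sigma_e2:.6g}",
            f"lambda:          {self.vc.lam:.6g}",
            f"stage-1 candidates: {len(self.candidates)}",
            f"QTNs called (LOD >= {self.params.get('crilod', 3.0)}): {len(self.qtns)}",
            "-" * 64,
        ]
        if self.qtns:
            lines.append(self.qtn_frame.to_string(index=False))
        else:
            lines.append("(no QTN cleared the LOD threshold)")
        return "\n".join(lines)


class MultiLocusGWAS:
    """One trait, one genotype matrix, one kinship: the fit target.

    Parameters
    ----------
    y : array (n,)
        Phenotype values (no missing entries; drop them before building).
    genotype : GenotypeDataset
        Imputed coded genotypes aligned to ``y``.
    covariates : array (n, c), optional
        Fixed covariates (population structure and/or continuous covariates);
        an intercept is always added internally.
    kinship : KinshipMatrix or array, optional
        Defaults to the marker-scaled kinship of ``genotype``.
    likelihood : {"REML", "ML"}
        Criterion for the null variance-component fit.
    """

    def __init__(
        self,
        y: np.ndarray,
        genotype: GenotypeDataset,
        covariates: np.ndarray | None = None,
        kinship: KinshipMatrix | np.ndarray | None = None,
        trait_name: str = "trait",
        likelihood: str = "REML",
    ) -> None:
        self.y = np.asarray(y, float)
        if np.any(~np.isfinite(self.y)):
            raise ValueError("phenotype contains missing values; drop them first")
        if not genotype.is_imputed:
            raise ValueError("genotype must be imputed")
        if genotype.n != len(self.y):
            raise ValueError("phenotype and genotype sample counts differ")
        self.genotype = genotype
        n = len(self.y)
        cols = [np.ones(n)]
        if covariates is not None:
            C = np.atleast_2d(np.asarray(covariates, float))
            if C.shape[0] != n:
                C = C.T
            cols.append(C)
        self.X = np.column_stack(cols)
        if kinship is None:
            kinship = kinship_marker_scaled(genotype)
        self.K = kinship if isinstance(kinship, KinshipMatrix) else KinshipMatrix(
            np.asarray(kinship, float), "external"
        )
        self.trait_name = trait_name
        self.likelihood = likelihood
        self._vc: VarianceComponents | None = None
        self._basis: SpectralBasis | None = None

    @classmethod
    def from_bundle(
        cls,
        bundle: AlignedBundle,
        trait: int = 0,
        likelihood: str = "REML",
        kinship: KinshipMatrix | np.ndarray | None = None,
    ) -> "MultiLocusGWAS":
        """Build from an aligned I/O bundle, dropping individuals with a
        missing phenotype for the chosen trait (case-wise per trait)."""
        values, observed = bundle.phenotype.trait_vector(trait)
        keep = np.flatnonzero(observed)
        geno = bundle.genotype
        if len(keep) < geno.n:
            geno = GenotypeDataset(
                individuals=[geno.individuals[i] for i in keep],
                info=geno.info,
                codes=geno.codes[keep],
                missing=geno.missing[keep],
            )
        cov = None
        if bundle.blocks:
            cov = np.column_stack([b.values for b in bundle.blocks])[keep]
        if kinship is None and bundle.kinship is not None:
            kinship = bundle.kinship[np.ix_(keep, keep)]
        elif isinstance(kinship, KinshipMatrix) and len(keep) < kinship.n:
            kinship = kinship.values[np.ix_(keep, keep)]
        elif isinstance(kinship, np.ndarray) and len(keep) < kinship.shape[0]:
            kinship = kinship[np.ix_(keep, keep)]
        return cls(
            values[keep],
            geno,
            covariates=cov,
            kinship=kinship,
            trait_name=bundle.phenotype.traits[trait],
            likelihood=likelihood,
        )

    # -- shared stages ------------------------------------------------------

    def null_model(self) -> tuple[VarianceComponents, SpectralBasis]:
        """Null variance components + spectral basis (computed once, cached)."""
        if self._vc is None:
            self._vc, self._basis = mlm.fit_null(
                self.y, self.X, self.K, criterion=self.likelihood
            )
        return self._vc, self._basis

    def _whitened(self):
        if getattr(self, "_white_cache", None) is None:
            vc, basis = self.null_model()
            self._white_cache = mlm.whiten(
                self.y, self.X, self.genotype.codes, vc, basis
            )
        return self._white_cache

    def _ols_residual(self) -> np.ndarray:
        coef, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        return self.y - self.X @ coef

    # -- the six pipelines --------------------------------------------------

    def fit(
        self,
        method: str = "FASTmrMLM",
        crilod: float = 3.0,
        search_radius: float = 20.0,
        select_variable: int = 50,
        alpha_screen: float = 0.005,
        kw_alpha: float = 0.05,
        tau: float = 0.0,
        omega: float = 0.0,
    ) -> GWASResults:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; valid: {', '.join(METHODS)}")
        vc, basis = self.null_model()
        info = self.genotype.info
        scan: ScanResult | None = None

        if method == "mrMLM":
            scan = mlm.random_scan(self.y, self.X, self.genotype, vc, basis, self.trait_name)
            cands = screening.select_by_pvalue(scan, alpha_screen)
            cands = screening.dedup_by_radius(cands, info, search_radius)
        elif method == "FASTmrMLM":
            scan = mlm.fixed_scan(self.y, self.X, self.genotype, vc, basis, self.trait_name)
            cands = screening.select_by_pvalue(scan, alpha_screen)
            cands = screening.dedup_by_radius(cands, info, search_radius)
        elif method == "FASTmrEMMA":
            # whiten once, then scan under residual-only covariance
            y_w, Gw = self._whitened()
            ident = SpectralBasis(np.zeros(len(y_w)), np.eye(len(y_w)))
            vc0 = VarianceComponents(
                sigma_g2=0.0, sigma_e2=vc.sigma_e2, lam=0.0,
                loglik=vc.loglik, criterion=vc.criterion,
            )
            scan = mlm.random_scan(
                y_w, np.ones((len(y_w), 1)), Gw, vc0, ident, self.trait_name
            )
            scan.method = "random_scan_whitened"
            cands = screening.select_by_pvalue(scan, alpha_screen)
        elif method == "pKWmEB":
            scan = screening.kw_scan(self._ols_residual(), self.genotype, self.trait_name)
            cands = screening.select_by_pvalue(scan, kw_alpha)
            cands.method = "pKWmEB"
        elif method == "pLARmEB":
            y_w, Gw = self._whitened()
            cands = screening.lars_select_per_chromosome(
                y_w, self.genotype, max_per_chrom=select_variable, Z=Gw
            )
        else:  # ISIS EM-BLASSO
            y_w, Gw = self._whitened()
            cands = screening.sis_screen(y_w, self.genotype, Z=Gw)

        y_w, Gw = self._whitened()
        ebfit = None
        lrt_table = pd.DataFrame(
            columns=["design_pos", "marker_index", "effect", "lr", "lod", "p_value"]
        )
        qtns: list[ebayes.QTNRecord] = []
        if len(cands) > 0:
            Zcand = Gw[:, cands.indices]
            nonzero = np.einsum("ij,ij->j", Zcand, Zcand) > 1e-12
            idx = cands.indices[nonzero]
            if len(idx) > 0:
                ebfit = ebayes.eb_fit(
                    y_w, Gw[:, idx], candidate_indices=idx, tau=tau, omega=omega
                )
                lrt_table = ebayes.lrt_lod(ebfit, y_w)
                qtns = ebayes.finalize_qtns(lrt_table, info, self.y, crilod=crilod)
        return GWASResults(
            method=method,
            trait=self.trait_name,
            vc=vc,
            scan=scan,
            candidates=cands,
            ebfit=ebfit,
            lrt_table=lrt_table,
            qtns=qtns,
            params={
                "crilod": crilod,
                "search_radius": search_radius,
                "select_variable": select_variable,
                "alpha_screen": alpha_screen,
                "kw_alpha": kw_alpha,
            },
            info=info,
        )
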