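"""Run orchestration: the 17-parameter run configuration, method assembly,
and the (trait x method) execution loop with a deterministic parallel
contract.

The seventeen user parameters mirror the named-argument invocation style of
multi-locus GWAS tooling: fileGen, filePhe, fileKin, filePS, PopStrType,
fileCov, Genformat, Method, Likelihood, Trait, SearchRadius, CriLOD,
SelectVariable, Bootstrap, DrawPlot, Plotformat, dir.  Of these, fileGen,
filePhe, Genformat, Method, Trait, CriLOD and dir must be set by the user;
Likelihood, SearchRadius and SelectVariable are consulted only by the
methods they parameterize.  Work is distributed over at most 10 workers;
outputs are bit-identical for any worker count because every stage is a
pure function of its inputs.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, asdict

import numpy as np

from . import data_io, plots
from .kinship import KinshipMatrix, kinship_marker_scaled
from .model import METHODS, GWASResults, MultiLocusGWAS

__all__ = ["RunConfig", "ResultBundle", "validate_config", "build_method", "run_all"]

MAX_WORKERS = 10

REQUIRED_KEYS = ("fileGen", "filePhe", "Genformat", "Method", "Trait", "CriLOD", "dir")

DEFAULTS = {
    "fileKin": None,
    "filePS": None,
    "PopStrType": None,
    "fileCov": None,
    "Likelihood": "REML",
    "SearchRadius": 20.0,
    "SelectVariable": 50,
    "Bootstrap": False,
    "DrawPlot": False,
    "Plotformat": "jpeg",
}

_STAGE_CHAINS = {
    "mrMLM": ("random_scan", "select_by_pvalue", "dedup_by_radius", "eb_fit", "lrt"),
    "FASTmrMLM": ("fixed_scan", "select_by_pvalue", "dedup_by_radius", "eb_fit", "lrt"),
    "FASTmrEMMA": ("whiten", "random_scan", "select_by_pvalue", "eb_fit", "lrt"),
    "pLARmEB": ("whiten", "lars_select_per_chromosome", "eb_fit", "lrt"),
    "pKWmEB": ("kw_scan", "select_by_pvalue", "eb_fit", "lrt"),
    "ISIS EM-BLASSO": ("whiten", "sis_screen", "eb_fit", "lrt"),
}

_STAGE_PARAMS = {
    "mrMLM": ("SearchRadius",),
    "FASTmrMLM": ("SearchRadius",),
    "FASTmrEMMA": ("Likelihood",),
    "pLARmEB": ("SelectVariable",),
    "pKWmEB": (),
    "ISIS EM-BLASSO": (),
}


@dataclass
class RunConfig:
    fileGen: str
    filePhe: str
    Genformat: str
    Method: list[str]
    Trait: list[int]
    CriLOD: float
    dir: str
    fileKin: str | None = None
    filePS: str | None = None
    PopStrType: str | None = None
    fileCov: str | None = None
    Likelihood: str = "REML"
    SearchRadius: float = 20.0
    SelectVariable: int = 50
    Bootstrap: bool = False
    DrawPlot: bool = False
    Plotformat: str = "jpeg"


@dataclass
class ResultBundle:
    """Everything a run produced, one slot per requested (trait, method)."""

    results: dict = field(default_factory=dict)   # (trait, method) -> GWASResults
    failures: dict = field(default_factory=dict)  # (trait, method) -> error string
    paths: dict = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def validate_config(raw: dict) -> RunConfig:
    """Check required keys, inject defaults, reject unknown keys."""
    known = set(REQUIRED_KEYS) | set(DEFAULTS)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
    for key in REQUIRED_KEYS:
        if key not in raw or raw[key] in (None, ""):
            raise ValueError(f"{key} must be set")
    merged = {**DEFAULTS, **raw}
    if merged["Genformat"] not in ("Num", "Cha", "Hmp"):
        raise ValueError(f"Genformat must be Num, Cha or Hmp, got {merged['Genformat']!r}")
    methods = merged["Method"]
    if isinstance(methods, str):
        methods = [methods]
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; valid: {', '.join(METHODS)}")
    merged["Method"] = list(methods)
    traits = merged["Trait"]
    if isinstance(traits, int):
        traits = [traits]
    if not traits or any((not isinstance(t, (int, np.integer))) or t < 1 for t in traits):
        raise ValueError("Trait must be a non-empty list of 1-based indices")
    merged["Trait"] = [int(t) for t in traits]
    if merged["Likelihood"] not in ("REML", "ML"):
        raise ValueError("Likelihood must be REML or ML")
    if merged["Plotformat"] not in ("png", "tiff", "jpeg", "pdf"):
        raise ValueError("Plotformat must be png, tiff, jpeg or pdf")
    if merged["Bootstrap"]:
        warnings.warn("Bootstrap is accepted but not executed", stacklevel=2)
    merged["CriLOD"] = float(merged["CriLOD"])
    merged["SearchRadius"] = float(merged["SearchRadius"])
    merged["SelectVariable"] = int(merged["SelectVariable"])
    return RunConfig(**merged)


def build_method(name: str) -> dict:
    """Describe the stage chain of one named method pipeline."""
    if name not in METHODS:
        raise ValueError(f"unknown method {name!r}; valid: {', '.join(METHODS)}")
    return {
        "name": name,
        "stages": _STAGE_CHAINS[name],
        "consumes": _STAGE_PARAMS[name],
    }


def _fit_pair(model: MultiLocusGWAS, method: str, cfg: RunConfig) -> GWASResults:
    return model.fit(
        method=method,
        crilod=cfg.CriLOD,
        search_radius=cfg.SearchRadius,
        select_variable=cfg.SelectVariable,
    )


def _pair_task(args):
    model, method, cfg = args
    return _fit_pair(model, method, cfg)


def run_all(config: RunConfig, workers: int = 1) -> ResultBundle:
    """Execute every requested (trait, method) pair and write the outputs.

    The kinship matrix and its spectral basis are computed once per trait and
    shared across methods.  Stage errors are recorded per pair and never
    abort sibling pairs.  Results are identical for any ``workers`` in 1..10.
    """
    if workers > MAX_WORKERS:
        warnings.warn(f"workers={workers} clamped to {MAX_WORKERS}")
        workers = MAX_WORKERS
    workers = max(1, workers)
    bundle = ResultBundle()
    bundle.log.append(f"config: {asdict(config)}")
    data_io.check_writable(config.dir)

    genotype = data_io.read_genotype(config.fileGen, config.Genformat)
    genotype = data_io.impute_missing(genotype)
    phenotype = data_io.read_phenotype(config.filePhe, config.Trait)
    blocks = []
    if config.filePS:
        blocks.append(
            data_io.read_square_matrix(config.filePS, "structure", config.PopStrType)
        )
    if config.fileCov:
        blocks.append(data_io.read_square_matrix(config.fileCov, "covariate"))
    kin = data_io.read_square_matrix(config.fileKin, "kinship") if config.fileKin else None
    aligned = data_io.align_samples(genotype, phenotype, blocks, kin)
    if aligned.kinship is None:
        kinship = kinship_marker_scaled(aligned.genotype)
    else:
        kinship = KinshipMatrix(aligned.kinship, "external")

    tasks = []
    for ti in range(len(config.Trait)):
        model = MultiLocusGWAS.from_bundle(
            aligned, trait=ti, likelihood=config.Likelihood, kinship=kinship
        )
        model.null_model()  # one spectral decomposition per trait, shared
        for method in config.Method:
            tasks.append(((ti, method), model))

    keyed = {}
    if workers == 1 or len(tasks) == 1:
        for (key, model) in tasks:
            keyed[key] = (model, None)
            try:
                keyed[key] = (model, _fit_pair(model, key[1], config))
            except Exception as exc:  # failure isolation per pair
                bundle.failures[key] = f"{type(exc).__name__}: {exc}"
                bundle.log.append(f"FAILED {key}: {exc}")
    else:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            futures = [
                (key, model, pool.submit(_pair_task, (model, key[1], config)))
                for key, model in tasks
            ]
            for key, model, fut in futures:
                try:
                    keyed[key] = (model, fut.result())
                except Exception as exc:
                    bundle.failures[key] = f"{type(exc).__name__}: {exc}"
                    bundle.log.append(f"FAILED {key}: {exc}")

    to_write = {}
    for (ti, method), payload in keyed.items():
        model, res = payload
        if res is None:
            continue
        trait_name = phenotype.traits[ti]
        bundle.results[(trait_name, method)] = res
        to_write[(trait_name, method)] = {
            "qtns": res.qtn_frame,
            "candidates": res.candidate_frame,
        }
        bundle.log.append(
            f"{trait_name} x {method}: {len(res.candidates)} candidates, "
            f"{len(res.qtns)} QTNs"
        )
    bundle.paths = data_io.write_results(to_write, config.dir)

    if config.DrawPlot:
        for (trait_name, method), res in bundle.results.items():
            if res.scan is None:
                continue
            stem = f"{data_io._safe(trait_name)}_{data_io._safe(method)}"
            spec = plots.PlotSpec(format=config.Plotformat, threshold=config.CriLOD)
            plots.manhattan_plot(
                res.scan, res.qtns, res.info, spec,
                f"{config.dir}/{stem}_manhattan.{config.Plotformat}",
            )
            plots.qq_plot(
                res.scan.pvalues, spec, f"{config.dir}/{stem}_qq.{config.Plotformat}"
            )
    return bundle
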