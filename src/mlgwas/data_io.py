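"""Reading, validating and writing the tabular inputs of a multi-locus GWAS run.

Three genotype dialects are supported:

``Num``
    Rows are markers; the first three columns are marker name, chromosome and
    base-pair position; every further column is one individual, coded
    +1 (major-allele homozygote), 0 (heterozygote), -1 (minor-allele
    homozygote).  The header row carries the individual IDs.
``Cha``
    Same layout as ``Num`` but genotypes are two-letter diploid tokens such as
    ``AA``/``AG``; ``NN`` is missing.
``Hmp``
    Standard Hapmap: eleven fixed header columns (rs#, alleles, chrom, pos,
    strand, assembly#, center, protLSID, assayLSID, panelLSID, QCcode)
    followed by one column per individual holding two-letter diploid tokens.

Character and Hapmap genotypes are converted to the {-1, 0, +1} coding by
determining the major/minor allele per marker from the data itself; frequency
ties are broken by lexicographic allele order (the lexicographically smaller
symbol becomes the major allele), so the coding never depends on how a file
happens to list its alleles.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeParseError",
    "MarkerInfo",
    "GenotypeDataset",
    "PhenotypeTable",
    "CovariateBlock",
    "AlignedBundle",
    "read_genotype",
    "write_genotype",
    "read_phenotype",
    "read_square_matrix",
    "align_samples",
    "impute_missing",
    "write_results",
]

HAPMAP_COLUMNS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


class GenotypeParseError(ValueError):
    """A genotype file violates its declared dialect."""


@dataclass(frozen=True)
class MarkerInfo:
    """Per-marker map entry."""

    name: str
    chromosome: str
    position: int
    alleles: tuple[str, str]  # (major, minor)
    maf: float

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"marker {self.name}: negative position {self.position}")
        if not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValueError(f"marker {self.name}: maf {self.maf} outside [0, 0.5]")


@dataclass
class GenotypeDataset:
    """Individuals x markers coded genotype matrix plus its marker map.

    ``codes`` holds entries in {-1, 0, +1}; ``missing`` is a boolean mask of
    the same shape (all-False once imputed).  The marker map is a DataFrame
    with columns ``name, chrom, pos, major, minor, maf`` sorted by position
    within each chromosome.
    """

    individuals: list[str]
    info: pd.DataFrame
    codes: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.missing is None:
            self.missing = np.zeros(self.codes.shape, dtype=bool)
        if len(set(self.individuals)) != len(self.individuals):
            dup = pd.Series(self.individuals).duplicated()
            raise ValueError(
                f"duplicated sample IDs: {sorted(set(pd.Series(self.individuals)[dup]))}"
            )
        if self.codes.shape != (len(self.individuals), len(self.info)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.info)} markers"
            )

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def m(self) -> int:
        return len(self.info)

    @property
    def maf(self) -> np.ndarray:
        return self.info["maf"].to_numpy(float)

    @property
    def is_imputed(self) -> bool:
        return not self.missing.any()

    def marker_info(self, j: int) -> MarkerInfo:
        row = self.info.iloc[j]
        return MarkerInfo(
            name=str(row["name"]), chromosome=str(row["chrom"]),
            position=int(row["pos"]), alleles=(str(row["major"]), str(row["minor"])),
            maf=float(row["maf"]),
        )


@dataclass
class PhenotypeTable:
    """Individuals x traits phenotype matrix with a missing mask."""

    individuals: list[str]
    traits: list[str]
    values: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)

    def trait_vector(self, t: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (values, observed-mask) for trait column ``t`` (0-based)."""
        obs = ~self.missing[:, t]
        return self.values[:, t], obs


@dataclass
class CovariateBlock:
    """A block of fixed-effect covariates (population structure or user table)."""

    source: str  # "population-structure" | "user-covariate"
    individuals: list[str]
    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != len(self.individuals):
            raise ValueError("covariate block rows must align to individuals")
        if self.values.shape[1]:
            rank = np.linalg.matrix_rank(self.values - self.values.mean(axis=0))
            if rank < min(self.values.shape[1], self.values.shape[0] - 1):
                warnings.warn(
                    f"{self.source} block is column-rank deficient", stacklevel=2
                )


@dataclass
class AlignedBundle:
    """All inputs restricted to a common sample set in one canonical order."""

    genotype: GenotypeDataset
    phenotype: PhenotypeTable
    blocks: list[CovariateBlock]
    kinship: np.ndarray | None = None


# ---------------------------------------------------------------------------
# reading


def _read_table(path: str) -> pd.DataFrame:
    # comma or tab delimited; sniff on the first line
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    ncol = df.shape[1]
    if any(len(r) != ncol for r in df.itertuples(index=False)):
        raise GenotypeParseError(f"{path}: inconsistent column counts")
    return df


def _codes_from_tokens(tokens: np.ndarray, name: str, col_ids: list[str]):
    """Convert two-letter diploid tokens of one marker to {-1,0,+1} codes.

    Returns (codes, missing, major, minor, maf).  Major/minor alleles come
    from the observed allele counts; ties break lexicographically.
    """
    counts: dict[str, int] = {}
    for tok in tokens:
        if tok == "NN" or tok == "" or tok == "NA":
            continue
        if len(tok) != 2 or not tok.isalpha():
            j = int(np.argmax([t == tok for t in tokens]))
            raise GenotypeParseError(
                f"marker {name}, individual {col_ids[j]}: unknown genotype token {tok!r}"
            )
        for a in tok:
            counts[a] = counts.get(a, 0) + 1
    alleles = sorted(counts, key=lambda a: (-counts[a], a))
    if len(alleles) > 2:
        raise GenotypeParseError(f"marker {name}: more than two alleles {alleles}")
    if not alleles:
        major, minor = "N", "N"
    elif len(alleles) == 1:
        major, minor = alleles[0], "N"
    else:
        major, minor = alleles
    total = sum(counts.values())
    maf = counts.get(minor, 0) / total if total else 0.0
    codes = np.zeros(len(tokens))
    missing = np.zeros(len(tokens), dtype=bool)
    for i, tok in enumerate(tokens):
        if tok in ("NN", "", "NA"):
            missing[i] = True
        elif tok[0] == tok[1]:
            codes[i] = 1.0 if tok[0] == major else -1.0
        else:
            codes[i] = 0.0
    return codes, missing, major, minor, maf


def _finalize_dataset(individuals, names, chroms, poss, per_marker, path):
    if pd.Series(names).duplicated().any():
        dup = sorted(set(pd.Series(names)[pd.Series(names).duplicated()]))
        raise GenotypeParseError(f"{path}: duplicate marker names {dup}")
    codes = np.column_stack([c for c, *_ in per_marker])
    missing = np.column_stack([mis for _, mis, *_ in per_marker])
    info = pd.DataFrame(
        {
            "name": names,
            "chrom": chroms,
            "pos": np.asarray(poss, dtype=np.int64),
            "major": [maj for *_, maj, _, _ in per_marker],
            "minor": [mnr for *_, mnr, _ in per_marker],
            "maf": [maf for *_, maf in per_marker],
        }
    )
    # sort by position within chromosome, chromosomes in file order
    chrom_order = {c: i for i, c in enumerate(pd.unique(info["chrom"]))}
    order = np.lexsort((info["pos"].to_numpy(), info["chrom"].map(chrom_order).to_numpy()))
    info = info.iloc[order].reset_index(drop=True)
    return GenotypeDataset(
        individuals=list(individuals),
        info=info,
        codes=codes[:, order],
        missing=missing[:, order],
    )


def read_genotype(path: str, format: str) -> GenotypeDataset:
    """Read a genotype file in the ``Num``, ``Cha`` or ``Hmp`` dialect."""
    if format not in ("Num", "Cha", "Hmp"):
        raise ValueError(f"unknown genotype format {format!r}; expected Num, Cha or Hmp")
    df = _read_table(path)
    if format == "Hmp":
        if df.shape[1] < 12:
            raise GenotypeParseError(f"{path}: Hapmap needs 11 header columns + individuals")
        individuals = list(df.columns[11:])
        names = df.iloc[:, 0].tolist()
        chroms = df.iloc[:, 2].astype(str).tolist()
        poss = pd.to_numeric(df.iloc[:, 3]).tolist()
        gmat = df.iloc[:, 11:].to_numpy(str)
    else:
        if df.shape[1] < 4:
            raise GenotypeParseError(f"{path}: need name/chrom/pos + individual columns")
        individuals = list(df.columns[3:])
        names = df.iloc[:, 0].tolist()
        chroms = df.iloc[:, 1].astype(str).tolist()
        poss = pd.to_numeric(df.iloc[:, 2]).tolist()
        gmat = df.iloc[:, 3:].to_numpy(str)

    per_marker = []
    if format == "Num":
        for k, name in enumerate(names):
            row = gmat[k]
            codes = np.zeros(len(row))
            missing = np.zeros(len(row), dtype=bool)
            for i, tok in enumerate(row):
                t = tok.strip()
                if t in ("", "NA", "NaN", "nan"):
                    missing[i] = True
                elif t in ("1", "+1", "1.0"):
                    codes[i] = 1.0
                elif t in ("-1", "-1.0"):
                    codes[i] = -1.0
                elif t in ("0", "0.0"):
                    codes[i] = 0.0
                else:
                    raise GenotypeParseError(
                        f"marker {name}, individual {individuals[i]}: "
                        f"unknown genotype token {t!r}"
                    )
            obs = codes[~missing]
            # observed allele frequency of the +1-coded allele
            p_plus = (np.sum(obs == 1) + 0.5 * np.sum(obs == 0)) / len(obs) if len(obs) else 0.0
            maf = min(p_plus, 1.0 - p_plus)
            per_marker.append((codes, missing, "A", "B", maf))
    else:
        for k, name in enumerate(names):
            per_marker.append(_codes_from_tokens(gmat[k], name, individuals))
    return _finalize_dataset(individuals, names, chroms, poss, per_marker, path)


def write_genotype(dataset: GenotypeDataset, path: str, format: str) -> None:
    """Write a dataset back out in any of the three dialects."""
    if format not in ("Num", "Cha", "Hmp"):
        raise ValueError(f"unknown genotype format {format!r}")
    info = dataset.info
    n, m = dataset.codes.shape
    if format == "Num":
        body = np.where(dataset.missing.T, "NA", dataset.codes.T.astype(int).astype(str))
        out = pd.DataFrame(
            {"rs#": info["name"], "chrom": info["chrom"], "pos": info["pos"]}
        )
        out = pd.concat([out, pd.DataFrame(body, columns=dataset.individuals)], axis=1)
        out.to_csv(path, index=False)
        return
    tokens = np.empty((m, n), dtype=object)
    for j in range(m):
        maj, mnr = info["major"].iat[j], info["minor"].iat[j]
        het = "".join(sorted((maj, mnr)))
        col = np.where(
            dataset.missing[:, j], "NN",
            np.where(dataset.codes[:, j] == 1, maj * 2,
                     np.where(dataset.codes[:, j] == -1, mnr * 2, het)),
        )
        tokens[j] = col
    if format == "Cha":
        out = pd.DataFrame(
            {"rs#": info["name"], "chrom": info["chrom"], "pos": info["pos"]}
        )
    else:
        out = pd.DataFrame(
            {
                "rs#": info["name"],
                "alleles": info["major"].str.cat(info["minor"], sep="/"),
                "chrom": info["chrom"],
                "pos": info["pos"],
                "strand": "+",
                "assembly#": "NA",
                "center": "NA",
                "protLSID": "NA",
                "assayLSID": "NA",
                "panelLSID": "NA",
                "QCcode": "NA",
            }
        )
    out = pd.concat([out, pd.DataFrame(tokens, columns=dataset.individuals)], axis=1)
    out.to_csv(path, index=False)


def read_phenotype(path: str, trait_selector: list[int] | None = None) -> PhenotypeTable:
    """Read the phenotype table; ``trait_selector`` holds 1-based column indices."""
    df = _read_table(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    traits_all = list(df.columns[1:])
    if trait_selector is None:
        trait_selector = list(range(1, len(traits_all) + 1))
    if not trait_selector:
        raise ValueError("empty trait selection")
    for t in trait_selector:
        if not 1 <= t <= len(traits_all):
            raise ValueError(
                f"trait index {t} out of range 1..{len(traits_all)}"
            )
    raw = df.iloc[:, [t for t in trait_selector]]
    values = np.full(raw.shape, np.nan)
    for cj, col in enumerate(raw.columns):
        for ri, cell in enumerate(raw[col]):
            s = str(cell).strip()
            if s in ("", "NA", "NaN", "nan"):
                continue
            try:
                values[ri, cj] = float(s)
            except ValueError:
                raise ValueError(
                    f"non-numeric phenotype at row {ri + 2}, column {col!r}: {s!r}"
                ) from None
    return PhenotypeTable(
        individuals=ids,
        traits=[traits_all[t - 1] for t in trait_selector],
        values=values,
    )


def read_square_matrix(path: str, kind: str, pop_str_type: str | None = None):
    """Read a kinship / population-structure / covariate file.

    Kinship files must carry an ID first column and be symmetric; the return
    is ``(ids, matrix)``.  Structure and covariate files (one row per
    individual, ID first column) return a :class:`CovariateBlock`; a Q matrix
    whose rows sum to one loses its last column so the block stays full rank
    next to an intercept.
    """
    if kind not in ("kinship", "structure", "covariate"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    df = _read_table(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    vals = df.iloc[:, 1:].apply(pd.to_numeric).to_numpy(float)
    if kind == "kinship":
        if vals.shape[0] != vals.shape[1]:
            raise ValueError(
                f"kinship must be square; got {vals.shape[0]} x {vals.shape[1]}"
            )
        if np.max(np.abs(vals - vals.T)) > 1e-8:
            raise ValueError("kinship matrix is not symmetric (tolerance 1e-8)")
        return ids, vals
    labels = list(df.columns[1:])
    if kind == "structure":
        rowsum = vals.sum(axis=1)
        if vals.shape[1] > 1 and np.allclose(rowsum, 1.0, atol=1e-6):
            vals = vals[:, :-1]  # membership proportions: drop one for identifiability
            labels = labels[:-1]
        return CovariateBlock("population-structure", ids, vals, labels)
    return CovariateBlock("user-covariate", ids, vals, labels)


# ---------------------------------------------------------------------------
# alignment / imputation


def align_samples(
    genotype: GenotypeDataset,
    phenotype: PhenotypeTable,
    blocks: list[CovariateBlock] | None = None,
    kinship: tuple[list[str], np.ndarray] | None = None,
) -> AlignedBundle:
    """Restrict all inputs to the common sample IDs, in genotype-file order."""
    blocks = blocks or []
    common = set(genotype.individuals) & set(phenotype.individuals)
    for b in blocks:
        common &= set(b.individuals)
    if kinship is not None:
        common &= set(kinship[0])
    if not common:
        raise ValueError(
            "no common sample IDs; e.g. genotype has "
            f"{genotype.individuals[:3]}, phenotype has {phenotype.individuals[:3]}"
        )
    order = [i for i in genotype.individuals if i in common]
    gidx = [genotype.individuals.index(i) for i in order]
    geno = GenotypeDataset(
        individuals=order,
        info=genotype.info,
        codes=genotype.codes[gidx],
        missing=genotype.missing[gidx],
    )
    pmap = {s: i for i, s in enumerate(phenotype.individuals)}
    pidx = [pmap[i] for i in order]
    phe = PhenotypeTable(
        individuals=order,
        traits=list(phenotype.traits),
        values=phenotype.values[pidx],
        missing=phenotype.missing[pidx],
    )
    new_blocks = []
    for b in blocks:
        bmap = {s: i for i, s in enumerate(b.individuals)}
        bidx = [bmap[i] for i in order]
        new_blocks.append(
            CovariateBlock(b.source, order, b.values[bidx], list(b.labels))
        )
    kin = None
    if kinship is not None:
        kmap = {s: i for i, s in enumerate(kinship[0])}
        kidx = [kmap[i] for i in order]
        kin = kinship[1][np.ix_(kidx, kidx)]
    return AlignedBundle(geno, phe, new_blocks, kin)


def impute_missing(genotype: GenotypeDataset) -> GenotypeDataset:
    """Replace each missing code by the marker mean snapped to {-1, 0, +1}.

    A mean exactly halfway between two codes rounds toward 0.
    """
    if genotype.is_imputed:
        return genotype
    codes = genotype.codes.copy()
    miss = genotype.missing
    fully_missing = miss.all(axis=0)
    if fully_missing.any():
        bad = genotype.info["name"][fully_missing].tolist()
        raise ValueError(f"markers with all genotypes missing: {bad}")
    masked = np.where(miss, np.nan, codes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(masked, axis=0)
    snapped = np.where(means > 0.5, 1.0, np.where(means < -0.5, -1.0, 0.0))
    codes[miss] = np.broadcast_to(snapped, codes.shape)[miss]
    return replace(
        genotype, codes=codes, missing=np.zeros_like(miss)
    )


# ---------------------------------------------------------------------------
# result output

FINAL_COLUMNS = [
    "marker", "chromosome", "position", "effect", "lod", "p_value",
    "r2_percent", "maf",
]


def _safe(s: str) -> str:
    return "".join(c if c.isalnum() or c in "-." else "_" for c in str(s))


def check_writable(outdir: str) -> None:
    """Fail fast if the output directory cannot be written to."""
    os.makedirs(outdir, exist_ok=True)
    probe = os.path.join(outdir, ".mlgwas_write_probe")
    try:
        with open(probe, "w") as fh:
            fh.write("ok")
        os.remove(probe)
    except OSError as exc:
        raise OSError(f"output directory {outdir!r} is not writable: {exc}") from exc


def write_results(results: dict, outdir: str) -> dict:
    """Write final QTN and intermediate candidate tables, one pair per
    (trait, method).

    ``results`` maps ``(trait, method)`` to a dict with keys ``qtns`` and
    ``candidates`` (DataFrames).  Existing files are overwritten.  Returns a
    map of written paths.
    """
    check_writable(outdir)
    paths = {}
    for (trait, method), res in results.items():
        stem = f"{_safe(trait)}_{_safe(method)}"
        final_path = os.path.join(outdir, f"{stem}_final.csv")
        inter_path = os.path.join(outdir, f"{stem}_intermediate.csv")
        qtns = res["qtns"]
        if qtns is None or len(qtns) == 0:
            qtns = pd.DataFrame(columns=FINAL_COLUMNS)
        qtns.to_csv(final_path, index=False, float_format="%.6g")
        cands = res.get("candidates")
        if cands is None or len(cands) == 0:
            cands = pd.DataFrame(
                columns=["marker", "chromosome", "position", "statistic", "p_value"]
            )
        cands.to_csv(inter_path, index=False, float_format="%.6g")
        paths[(trait, method)] = {"final": final_path, "intermediate": inter_path}
    return paths
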