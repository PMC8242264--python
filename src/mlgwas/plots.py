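"""Manhattan and QQ plots for genome-scan results.

Output formats: png, tiff, jpeg, pdf.  The Manhattan y-axis shows the
stage-1 -log10(p) for every marker (so the whole genome is plottable), with
called QTNs overplotted and a horizontal line at the p-value equivalent of
the LOD threshold; an alternate mode plots LOD for the called set only.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402
from scipy import stats  # noqa: E402

__all__ = ["PlotSpec", "manhattan_plot", "qq_plot"]

ALLOWED_FORMATS = ("png", "tiff", "jpeg", "pdf")


@dataclass
class PlotSpec:
    format: str = "png"
    dpi: int = 150
    threshold: float = 3.0  # LOD threshold to translate into the p scale
    width: float = 9.0
    height: float = 3.5

    def __post_init__(self) -> None:
        if self.format not in ALLOWED_FORMATS:
            raise ValueError(
                f"unknown plot format {self.format!r}; allowed: {ALLOWED_FORMATS}"
            )


def _threshold_logp(crilod: float) -> float:
    # p-value matching LOD = crilod under the chi2_1 reference
    lr = crilod * 2.0 * np.log(10.0)
    return -np.log10(max(stats.chi2.sf(lr, df=1), 1e-300))


def _clamp_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, float)
    if (p <= 0).any():
        import warnings

        warnings.warn("p = 0 clamped to machine minimum for plotting")
        p = np.maximum(p, np.finfo(float).tiny)
    return p


def manhattan_plot(scan, qtns, info: pd.DataFrame, spec: PlotSpec, path: str) -> str:
    """Genome-wide -log10(p) by cumulative position with QTN overlay."""
    if len(scan.pvalues) == 0:
        raise ValueError("empty scan")
    p = _clamp_p(scan.pvalues)
    chrom = info["chrom"].to_numpy()
    pos = info["pos"].to_numpy(float)
    offset = 0.0
    xs = np.empty(len(pos))
    bands = []
    chrom_offsets = {}
    for c in pd.unique(chrom):
        sel = chrom == c
        chrom_offsets[c] = offset - pos[sel].min()
        xs[sel] = pos[sel] + chrom_offsets[c]
        bands.append((c, xs[sel].min(), xs[sel].max()))
        offset = xs[sel].max() + 1.0
    fig, ax = plt.subplots(figsize=(spec.width, spec.height), dpi=spec.dpi)
    for i, (c, lo, hi) in enumerate(bands):
        if i % 2:
            ax.axvspan(lo, hi, color="0.92", zorder=0)
        sel = chrom == c
        ax.scatter(xs[sel], -np.log10(p[sel]), s=4,
                   color="tab:blue" if i % 2 == 0 else "tab:cyan", zorder=2)
    for q in qtns:
        x = q.position + chrom_offsets.get(str(q.chromosome), 0.0)
        ax.scatter([x], [-np.log10(max(q.p_value, np.finfo(float).tiny))],
                   s=40, marker="D", color="tab:red", zorder=3)
    ax.axhline(_threshold_logp(spec.threshold), ls="--", color="0.3", lw=1)
    ax.set_xlabel("genome position")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.set_xticks([(lo + hi) / 2 for _, lo, hi in bands])
    ax.set_xticklabels([c for c, *_ in bands])
    fig.tight_layout()
    fig.savefig(path, format=spec.format, dpi=spec.dpi)
    plt.close(fig)
    return path


def qq_plot(pvalues, spec: PlotSpec, path: str) -> str:
    """Observed vs expected -log10(p) with the identity line."""
    pvalues = np.asarray(pvalues, float)
    if len(pvalues) == 0:
        raise ValueError("empty p-value list")
    p = np.sort(_clamp_p(pvalues))
    m = len(p)
    expected = -np.log10((np.arange(1, m + 1)) / (m + 1))[::-1]
    observed = -np.log10(p)[::-1]
    fig, ax = plt.subplots(figsize=(spec.height, spec.height), dpi=spec.dpi)
    lim = max(expected.max(), observed.max()) * 1.05 + 1e-9
    ax.plot([0, lim], [0, lim], color="0.5", lw=1)
    ax.scatter(expected, observed, s=6, color="tab:blue")
    ax.set_xlabel(r"expected $-\log_{10}(p)$")
    ax.set_ylabel(r"observed $-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(path, format=spec.format, dpi=spec.dpi)
    plt.close(fig)
    return path
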