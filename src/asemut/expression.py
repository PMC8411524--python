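"""Gene expression quantification: FPKM, zFPKM, and active-gene calls.

The zFPKM transform locates the active-expression peak of the log2 FPKM
distribution with a kernel density estimate and rescales relative to it:
``mu`` is the density mode, ``sigma`` is a half-Gaussian fitted to the right
flank (sigma = mean(x[x > mu] - mu) * sqrt(pi/2)), and

    zFPKM = (log2 FPKM - mu) / sigma.

Genes with zFPKM <= -3 are treated as background (non-expressed).  Fitting
is per sample; genes with FPKM = 0 are excluded from the density and map to
zFPKM = -inf.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ZfpkmFit

#: Genes at or below this zFPKM are considered non-expressed.
ZFPKM_SILENT_THRESHOLD = -3.0

#: Minimum number of FPKM > 0 genes required for a stable density fit.
MIN_GENES_FOR_FIT = 100

_GRIDSIZE = 512
_CUT_BANDWIDTHS = 3.0


def compute_fpkm(
    counts: pd.DataFrame,
    gene_length_kb: pd.Series,
    mapped_read_total: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads, per gene and sample.

    Parameters
    ----------
    counts
        Raw read counts, genes x samples.
    gene_length_kb
        Transcript length in kilobases, indexed by gene; must cover every
        gene in *counts* and be strictly positive.
    mapped_read_total
        Per-sample mapped-read totals; defaults to the column sums.
    """
    lengths = gene_length_kb.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:5].tolist()
        raise ValueError(f"gene lengths missing for {missing} ...")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if mapped_read_total is None:
        mapped_read_total = counts.sum(axis=0)
    totals = pd.Series(mapped_read_total).reindex(counts.columns)
    if (totals <= 0).any() or totals.isna().any():
        raise ValueError("mapped-read totals must be > 0 for every sample")
    return counts.div(lengths, axis=0).div(totals / 1e6, axis=1)


def fit_zfpkm(fpkm: np.ndarray | pd.Series) -> ZfpkmFit:
    """Fit the zFPKM transform parameters on one sample's FPKM vector.

    Kernel density (Gaussian, Silverman bandwidth, 512-point grid spanning
    the data range plus 3 bandwidths on each side) of log2 FPKM over genes
    with FPKM > 0; ``mu`` is the grid argmax, ``sigma`` the half-Gaussian
    scale of the right flank.
    """
    from statsmodels.nonparametric.kde import KDEUnivariate

    values = np.asarray(fpkm, dtype=float)
    x = np.log2(values[values > 0])
    if x.size < MIN_GENES_FOR_FIT:
        raise ValueError(f"need >= {MIN_GENES_FOR_FIT} genes with FPKM > 0, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all log2 FPKM values equal")
    kde = KDEUnivariate(x)
    kde.fit(kernel="gau", bw="silverman", fft=True, gridsize=_GRIDSIZE, cut=_CUT_BANDWIDTHS)
    mu = float(kde.support[np.argmax(kde.density)])
    right = x[x > mu]
    if right.size == 0:
        raise ValueError("no genes above the density mode; cannot fit right flank")
    sigma = float((right.mean() - mu) * math.sqrt(math.pi / 2.0))
    if sigma <= 0:
        raise ValueError("non-positive sigma from right-flank fit")
    return ZfpkmFit(mu=mu, sigma=sigma, bandwidth=float(kde.bw), n_genes=int(x.size))


def zfpkm_transform(fpkm: np.ndarray | pd.Series, fit: ZfpkmFit) -> np.ndarray:
    """Apply a fitted transform; FPKM = 0 maps to zFPKM = -inf."""
    values = np.asarray(fpkm, dtype=float)
    with np.errstate(divide="ignore"):
        return (np.log2(values) - fit.mu) / fit.sigma


def classify_active(zfpkm, threshold: float = ZFPKM_SILENT_THRESHOLD):
    """True for active genes, False for silent; silent iff zFPKM <= threshold."""
    return np.asarray(zfpkm, dtype=float) > threshold


class ExpressionData:
    """Genes x samples raw-count matrix with FPKM and zFPKM layers.

    Lazily computes and caches the derived layers; per-sample ``ZfpkmFit``
    objects are kept in :attr:`fits`.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        gene_length_kb: pd.Series,
        mapped_read_total: pd.Series | None = None,
    ):
        self.counts = counts
        self.gene_length_kb = gene_length_kb
        self.mapped_read_total = (
            counts.sum(axis=0) if mapped_read_total is None else mapped_read_total
        )
        self._fpkm: pd.DataFrame | None = None
        self._zfpkm: pd.DataFrame | None = None
        self.fits: dict[str, ZfpkmFit] = {}

    @property
    def fpkm(self) -> pd.DataFrame:
        if self._fpkm is None:
            self._fpkm = compute_fpkm(self.counts, self.gene_length_kb, self.mapped_read_total)
        return self._fpkm

    @property
    def zfpkm(self) -> pd.DataFrame:
        if self._zfpkm is None:
            z = {}
            for sample in self.fpkm.columns:
                fit = fit_zfpkm(self.fpkm[sample].to_numpy())
                self.fits[sample] = fit
                z[sample] = zfpkm_transform(self.fpkm[sample].to_numpy(), fit)
            self._zfpkm = pd.DataFrame(z, index=self.fpkm.index)
        return self._zfpkm

    def gene_zfpkm(self, gene: str, sample: str) -> float | None:
        """zFPKM of *gene* in *sample*; None when the gene is not in the matrix."""
        if gene not in self.zfpkm.index or sample not in self.zfpkm.columns:
            return None
        return float(self.zfpkm.at[gene, sample])


def read_expression(
    counts_path: str | Path,
    gene_lengths_path: str | Path,
    totals_path: str | Path | None = None,
) -> ExpressionData:
    """Read raw counts, gene lengths (kb) and optional mapped-read totals."""
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene", comment="#")
    lengths = pd.read_csv(
        gene_lengths_path, sep="\t", index_col="gene", comment="#"
    )["length_kb"]
    totals = None
    if totals_path is not None:
        totals = pd.read_csv(
            totals_path, sep="\t", index_col="sample_id", comment="#"
        )["mapped_reads"]
    return ExpressionData(counts, lengths, totals)


def write_expression(data: ExpressionData, counts_path: str | Path,
                     gene_lengths_path: str | Path) -> None:
    data.counts.to_csv(counts_path, sep="\t", index_label="gene")
    data.gene_length_kb.rename("length_kb").to_csv(
        gene_lengths_path, sep="\t", index_label="gene"
    )
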