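"""Shared domain containers for the growth-curve analysis pipeline.

The central objects are:

* :class:`GrowthCurve` — an OD600 time series for one culture.
* :class:`SampleMeta` / :class:`ExpressionMatrix` — a genes x samples table of
  log10 expression ratios against a common reference, with an aligned matrix
  of lambda significance statistics and per-sample metadata (strain, culture
  replicate, dye orientation, OD600 at harvest).
* :class:`GenomeAnnotation` — gene -> replicon map used for enrichment tests.

Missing values are represented as ``numpy.nan`` everywhere; they are never
silently encoded as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "REPLICONS",
    "GrowthCurve",
    "SampleMeta",
    "ExpressionMatrix",
    "GenomeAnnotation",
]

#: Replicons of Halobacterium salinarum NRC-1: the main chromosome and the
#: two large plasmids.
REPLICONS = ("Chromosome", "pNRC100", "pNRC200")


@dataclass(frozen=True)
class GrowthCurve:
    """OD600 trajectory of a single batch culture.

    Parameters
    ----------
    strain, replicate:
        Identifiers of the strain and of the culture replicate.
    time_h:
        Sampling times in hours, strictly increasing.
    od600:
        Optical density at 600 nm at each sampling time; strictly positive.
    """

    strain: str
    replicate: str
    time_h: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "od600", od)
        if t.ndim != 1 or od.ndim != 1 or t.shape != od.shape:
            raise ValueError("time_h and od600 must be 1-D arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("time_h must be strictly increasing")
        if np.any(~np.isfinite(od)) or np.any(od <= 0):
            raise ValueError("all OD600 values must be finite and > 0")

    def __len__(self) -> int:
        return self.time_h.size


@dataclass(frozen=True, order=True)
class SampleMeta:
    """Metadata of one hybridized sample (one array column).

    ``sample_index`` is the position of the harvest along the growth curve
    (0-based); ``dye_flip`` records whether the labeling dyes were reversed
    for this hybridization.  The stored expression ratios are always
    orientation-corrected (test over reference) regardless of ``dye_flip``.
    """

    strain: str
    replicate: str
    sample_index: int
    dye_flip: bool
    od600: float

    @property
    def sample_id(self) -> str:
        flip = ".f" if self.dye_flip else ""
        return f"{self.strain}.{self.replicate}.s{self.sample_index}{flip}"

    def sort_key(self) -> tuple:
        # Samples are ordered within a strain by increasing OD600; ties are
        # broken by replicate id then dye orientation.
        return (self.strain, self.od600, self.replicate, self.dye_flip)


class ExpressionMatrix:
    """Genes x samples matrix of log10 ratios plus aligned lambda values.

    Parameters
    ----------
    gene_ids:
        Unique gene identifiers, one per row.
    samples:
        Ordered sample metadata, one per column.  On construction samples are
        sorted by ``(strain, od600, replicate, dye_flip)`` and the data
        columns are permuted accordingly, so that within each strain columns
        appear in order of increasing optical density.
    log10_ratio:
        ``(n_genes, n_samples)`` array of log10(test/reference) ratios; NaN
        marks missing measurements.
    lam:
        Optional aligned array of lambda significance statistics
        (non-negative or NaN).
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        samples: Sequence[SampleMeta],
        log10_ratio: np.ndarray,
        lam: np.ndarray | None = None,
    ) -> None:
        gene_ids = list(gene_ids)
        seen: set[str] = set()
        for g in gene_ids:
            if g in seen:
                raise ValueError(f"duplicate gene id {g!r}")
            seen.add(g)
        samples = list(samples)
        keys = {(s.strain, s.replicate, s.sample_index, s.dye_flip) for s in samples}
        if len(keys) != len(samples):
            raise ValueError("sample metadata (strain, replicate, index, flip) not unique")
        ratio = np.asarray(log10_ratio, dtype=float)
        if ratio.shape != (len(gene_ids), len(samples)):
            raise ValueError(
                f"log10_ratio shape {ratio.shape} does not match "
                f"{len(gene_ids)} genes x {len(samples)} samples"
            )
        if lam is not None:
            lam = np.asarray(lam, dtype=float)
            if lam.shape != ratio.shape:
                raise ValueError("lambda matrix shape must match log10_ratio")
            if np.any(lam[np.isfinite(lam)] < 0):
                raise ValueError("lambda values must be >= 0 or missing")

        order = sorted(range(len(samples)), key=lambda j: samples[j].sort_key())
        self.gene_ids = gene_ids
        self.samples = [samples[j] for j in order]
        self.log10_ratio = ratio[:, order]
        self.lam = None if lam is None else lam[:, order]
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_genes, self.n_samples)

    def gene_row(self, gene_id: str) -> np.ndarray:
        try:
            return self.log10_ratio[self._gene_index[gene_id]]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def strains(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.strain not in out:
                out.append(s.strain)
        return out

    def columns_for_strain(self, strain: str) -> list[int]:
        return [j for j, s in enumerate(self.samples) if s.strain == strain]

    def subset_strain(self, strain: str) -> "ExpressionMatrix":
        cols = self.columns_for_strain(strain)
        if not cols:
            raise KeyError(f"no samples for strain {strain!r}")
        return ExpressionMatrix(
            self.gene_ids,
            [self.samples[j] for j in cols],
            self.log10_ratio[:, cols],
            None if self.lam is None else self.lam[:, cols],
        )

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        rows = [self._gene_index[g] for g in gene_ids]
        return ExpressionMatrix(
            gene_ids,
            self.samples,
            self.log10_ratio[rows],
            None if self.lam is None else self.lam[rows],
        )

    def with_lambda(self, lam: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(self.gene_ids, self.samples, self.log10_ratio, lam)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        if self.gene_ids != other.gene_ids or self.samples != other.samples:
            return False
        if not np.array_equal(self.log10_ratio, other.log10_ratio, equal_nan=True):
            return False
        if (self.lam is None) != (other.lam is None):
            return False
        if self.lam is not None and not np.array_equal(self.lam, other.lam, equal_nan=True):
            return False
        return True

    def __repr__(self) -> str:
        return (
            f"<ExpressionMatrix {self.n_genes} genes x {self.n_samples} samples, "
            f"strains={self.strains()}, lambda={'yes' if self.lam is not None else 'no'}>"
        )


@dataclass
class GenomeAnnotation:
    """Gene -> replicon map for the whole genome.

    ``total_genes`` is the size of the gene universe N used as the
    denominator in enrichment tests; it defaults to the number of mapped
    genes but may be set larger when the map covers only part of the genome.
    """

    replicon_of: dict[str, str]
    total_genes: int | None = None

    def __post_init__(self) -> None:
        for g, r in self.replicon_of.items():
            if r not in REPLICONS:
                raise ValueError(f"gene {g!r} has unknown replicon {r!r}; expected one of {REPLICONS}")
        if self.total_genes is None:
            self.total_genes = len(self.replicon_of)
        elif self.total_genes < len(self.replicon_of):
            raise ValueError("total_genes smaller than number of mapped genes")

    def genes_on(self, *replicons: str) -> set[str]:
        for r in replicons:
            if r not in REPLICONS:
                raise ValueError(f"unknown replicon {r!r}")
        return {g for g, r in self.replicon_of.items() if r in replicons}

    def plasmid_genes(self) -> set[str]:
        return self.genes_on("pNRC100", "pNRC200")

    def require_genes(self, gene_ids: Iterable[str]) -> None:
        missing = [g for g in gene_ids if g not in self.replicon_of]
        if missing:
            raise KeyError(f"genes missing from annotation: {missing[:5]}" + ("..." if len(missing) > 5 else ""))
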