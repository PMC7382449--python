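"""Pairwise relatedness: Yang's unadjusted A_jk and shared homozygosity.

Two complementary views of how related each pair of sequenced individuals
is, both computed from the cohort's own genotypes:

* **A_jk** — the SNP-dosage estimator of the genomic relationship between
  individuals *j* and *k*.  With dosage ``x_ij`` of individual *j* at site
  *i* and allele frequency ``p_i``,

  .. math::

      A_{jk} = \\frac{1}{n}\\sum_i
          \\frac{(x_{ij}-2p_i)(x_{ik}-2p_i)}{2 p_i (1-p_i)},\\qquad j \\ne k

      A_{jj} = 1 + \\frac{1}{n}\\sum_i
          \\frac{x_{ij}^2-(1+2p_i)x_{ij}+2p_i^2}{2 p_i (1-p_i)}

  Expected values: 1 on the diagonal, ~0.5 for parent–offspring or full
  sibs, ~0 for unrelateds.  "Unadjusted" means allele frequencies are the
  plug-in cohort estimates (supplied external frequencies are accepted).

* **shared homozygosity** — restrict to common sites (MAF above a floor),
  collect per sample the set of sites homozygous for the alternate
  allele, and report the pairwise overlap after normalization:
  ``S_jk = |H_j ∩ H_k| / N(H_j, H_k)`` with N the smaller set size
  (default), the mean size, or the union size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import GenotypeTable

__all__ = [
    "GenotypeMatrix",
    "RelatednessMatrix",
    "ajk",
    "shared_homozygosity",
]


@dataclass
class GenotypeMatrix:
    """Samples × sites dosage matrix {0,1,2,NaN} with per-site allele freqs.

    ``allele_freq`` may be omitted; it is then estimated per site as the
    mean dosage / 2 over non-missing samples.
    """

    dosage: pd.DataFrame  # rows = samples, columns = sites
    allele_freq: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        vals = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if self.allele_freq is not None:
            self.allele_freq = np.asarray(self.allele_freq, dtype=float)
            if self.allele_freq.shape != (self.dosage.shape[1],):
                raise ValueError("allele_freq length must equal number of sites")

    @classmethod
    def from_table(cls, table: GenotypeTable) -> "GenotypeMatrix":
        return cls(dosage=table.dosage_matrix())

    def estimated_freqs(self) -> np.ndarray:
        if self.allele_freq is not None:
            return self.allele_freq
        return np.nanmean(self.dosage.to_numpy(dtype=float), axis=0) / 2.0

    @property
    def samples(self) -> list[str]:
        return list(self.dosage.index)


@dataclass
class RelatednessMatrix:
    values: pd.DataFrame  # symmetric samples × samples
    method: str  # "ajk" | "shared_homozygosity"
    n_sites_used: pd.DataFrame = field(default_factory=pd.DataFrame)

    def pair(self, a: str, b: str) -> float:
        return float(self.values.at[a, b])

    def to_long(self) -> pd.DataFrame:
        """Long format (sample_a, sample_b, method, value, n_sites), upper
        triangle including the diagonal."""
        samples = list(self.values.index)
        rows = []
        for i, a in enumerate(samples):
            for b in samples[i:]:
                rows.append(
                    {
                        "sample_a": a,
                        "sample_b": b,
                        "method": self.method,
                        "value": self.values.at[a, b],
                        "n_sites": self.n_sites_used.at[a, b]
                        if not self.n_sites_used.empty
                        else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def ajk(m: GenotypeMatrix) -> RelatednessMatrix:
    """Yang's unadjusted A_jk over all sample pairs.

    Monomorphic sites are excluded (the statistic is undefined there).
    Missing dosages are handled by pairwise deletion per site; a pair with
    no jointly observed polymorphic site gets NaN.
    """
    x = m.dosage.to_numpy(dtype=float)
    p = m.estimated_freqs()
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all sites are monomorphic; A_jk undefined")
    x = x[:, poly]
    p = p[poly]

    n_samples = x.shape[0]
    denom = 2.0 * p * (1.0 - p)
    centered = x - 2.0 * p  # broadcasts over samples
    obs = ~np.isnan(x)
    z = np.where(obs, centered / np.sqrt(denom), 0.0)

    # off-diagonals: mean over jointly observed sites of z_j * z_k
    num = z @ z.T
    counts = obs.astype(float) @ obs.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = num / counts

    # diagonal: 1 + mean of (x^2 - (1+2p)x + 2p^2) / (2p(1-p))
    diag_terms = np.where(obs, (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / denom, 0.0)
    diag_counts = obs.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        diag = 1.0 + diag_terms.sum(axis=1) / diag_counts
    vals[np.diag_indices(n_samples)] = diag
    counts[np.diag_indices(n_samples)] = diag_counts

    samples = m.samples
    values = pd.DataFrame(vals, index=samples, columns=samples)
    nsites = pd.DataFrame(counts.astype(int), index=samples, columns=samples)
    return RelatednessMatrix(values=values, method="ajk", n_sites_used=nsites)


def shared_homozygosity(
    m: GenotypeMatrix,
    maf_min: float = 0.01,
    normalizer: str = "min",
) -> RelatednessMatrix:
    """Pairwise overlap of alternate-homozygous sites at common variants.

    Sites are restricted to MAF > ``maf_min`` first.  ``normalizer``
    chooses N in S_jk = |H_j ∩ H_k| / N: "min" (smaller set), "mean"
    (average size) or "union" (|H_j ∪ H_k|).  A sample with an empty H
    yields NaN for its pairs under the "min" normalizer.
    """
    if normalizer not in ("min", "mean", "union"):
        raise ValueError(f"unknown normalizer {normalizer!r}")
    p = m.estimated_freqs()
    maf = np.minimum(p, 1.0 - p)
    common = maf > maf_min
    x = m.dosage.to_numpy(dtype=float)[:, common]

    hom = (x == 2.0)  # NaN-safe: NaN != 2
    sizes = hom.sum(axis=1).astype(float)
    inter = hom.astype(float) @ hom.astype(float).T

    n = x.shape[0]
    size_i = np.repeat(sizes[:, None], n, axis=1)
    size_j = np.repeat(sizes[None, :], n, axis=0)
    if normalizer == "min":
        norm = np.minimum(size_i, size_j)
    elif normalizer == "mean":
        norm = (size_i + size_j) / 2.0
    else:
        norm = size_i + size_j - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(norm > 0, inter / norm, np.nan)

    samples = m.samples
    values = pd.DataFrame(vals, index=samples, columns=samples)
    nsites = pd.DataFrame(
        np.full((n, n), int(common.sum())), index=samples, columns=samples
    )
    return RelatednessMatrix(
        values=values, method="shared_homozygosity", n_sites_used=nsites
    )
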