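"""Genotype QC for a single biallelic SNP: allele frequencies, Hardy-Weinberg
equilibrium testing, and additive / dummy design coding.

The instrument throughout is a biallelic variant coded as the count of effect
(C) alleles, 0/1/2, with TT the reference genotype. The HWE test is the 1-df
goodness-of-fit chi-squared against N*(p^2, 2pq, q^2) with the allele frequency
estimated from the sample, and no continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class EmptyCohortError(ValueError):
    """Raised when an operation needs at least one genotyped subject."""


class GenotypeValidationError(ValueError):
    """Raised when a genotype value is outside {0, 1, 2} / {TT, TC, CC}."""


class MonomorphicWarning(UserWarning):
    """Emitted when the HWE test is degenerate because one allele is absent."""


_STRING_TO_COUNT = {"TT": 0, "TC": 1, "CT": 1, "CC": 2}


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype tallies (n_TT, n_TC, n_CC) for one cohort."""

    n_TT: int
    n_TC: int
    n_CC: int

    def __post_init__(self) -> None:
        for field in ("n_TT", "n_TC", "n_CC"):
            v = getattr(self, field)
            if v < 0 or int(v) != v:
                raise GenotypeValidationError(f"{field} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return int(self.n_TT + self.n_TC + self.n_CC)

    @classmethod
    def from_genotypes(cls, genotypes: pd.Series | np.ndarray) -> "GenotypeCounts":
        """Tally a column of allele counts (0/1/2) or genotype strings (TT/TC/CC).

        Missing values are dropped.
        """
        g = coerce_allele_counts(genotypes)
        g = g[~np.isnan(g)]
        return cls(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))


@dataclass(frozen=True)
class HweResult:
    """Result of the Hardy-Weinberg goodness-of-fit test."""

    chi2: float
    df: int
    p: float
    expected_counts: tuple[float, float, float]


def coerce_allele_counts(genotypes: pd.Series | np.ndarray) -> np.ndarray:
    """Return a float array of C-allele counts with NaN for missing.

    Accepts numeric allele counts or two-letter genotype strings; anything
    outside {0, 1, 2} / {TT, TC, CT, CC} raises GenotypeValidationError.
    """
    s = pd.Series(genotypes)
    if s.dtype == object or pd.api.types.is_string_dtype(s):
        def _map(v):
            if pd.isna(v):
                return np.nan
            if isinstance(v, str):
                key = v.strip().upper()
                if key in _STRING_TO_COUNT:
                    return float(_STRING_TO_COUNT[key])
                raise GenotypeValidationError(f"unrecognised genotype string {v!r}")
            return float(v)

        out = s.map(_map).to_numpy(dtype=float)
    else:
        out = s.to_numpy(dtype=float)
    valid = np.isnan(out) | np.isin(out, (0.0, 1.0, 2.0))
    if not valid.all():
        bad = out[~valid][0]
        raise GenotypeValidationError(f"genotype values must be in {{0,1,2}}, got {bad!r}")
    return out


def allele_frequencies(counts: GenotypeCounts) -> tuple[float, float]:
    """(freq_T, freq_C) from genotype counts; freq_C = (2*n_CC + n_TC) / 2N."""
    n = counts.total
    if n == 0:
        raise EmptyCohortError("cannot compute allele frequencies for an empty cohort")
    freq_c = (2 * counts.n_CC + counts.n_TC) / (2 * n)
    return 1.0 - freq_c, freq_c


def hwe_test(counts: GenotypeCounts) -> HweResult:
    """1-df chi-squared goodness-of-fit test of Hardy-Weinberg proportions.

    Expected counts are N*(p^2, 2pq, q^2) with p estimated from the sample;
    no continuity correction. A monomorphic sample fits HWE trivially, so the
    test degenerates: chi2=0, p=1, with a MonomorphicWarning.
    """
    n = counts.total
    if n == 0:
        raise EmptyCohortError("cannot run the HWE test on an empty cohort")
    _, q = allele_frequencies(counts)
    p = 1.0 - q
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    if q == 0.0 or q == 1.0:
        warnings.warn(
            "monomorphic genotype data: HWE test is degenerate (p reported as 1)",
            MonomorphicWarning,
            stacklevel=2,
        )
        return HweResult(chi2=0.0, df=1, p=1.0, expected_counts=expected)
    observed = (counts.n_TT, counts.n_TC, counts.n_CC)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return HweResult(chi2=float(chi2), df=1, p=float(stats.chi2.sf(chi2, 1)), expected_counts=expected)


def code_genotype(genotypes: pd.Series | np.ndarray, scheme: str = "additive") -> pd.DataFrame:
    """Design columns for the genotype.

    additive -> one column ``g_additive`` of C-allele counts;
    dummy    -> two indicators ``g_TC`` (TC vs TT) and ``g_CC`` (CC vs TT).
    Missing genotypes propagate as NaN in every column.
    """
    g = coerce_allele_counts(genotypes)
    index = genotypes.index if isinstance(genotypes, pd.Series) else None
    if scheme == "additive":
        return pd.DataFrame({"g_additive": g}, index=index)
    if scheme == "dummy":
        tc = np.where(np.isnan(g), np.nan, (g == 1).astype(float))
        cc = np.where(np.isnan(g), np.nan, (g == 2).astype(float))
        return pd.DataFrame({"g_TC": tc, "g_CC": cc}, index=index)
    raise ValueError(f"unknown coding scheme {scheme!r}; use 'additive' or 'dummy'")


def qc_report(cohort: pd.DataFrame, genotype_col: str = "genotype") -> pd.DataFrame:
    """One-row QC summary: genotype counts, allele frequencies, HWE chi2/p."""
    counts = GenotypeCounts.from_genotypes(cohort[genotype_col])
    freq_t, freq_c = allele_frequencies(counts)
    hwe = hwe_test(counts)
    return pd.DataFrame(
        [
            {
                "n_TT": counts.n_TT,
                "n_TC": counts.n_TC,
                "n_CC": counts.n_CC,
                "n_total": counts.total,
                "n_missing": int(cohort[genotype_col].isna().sum()),
                "freq_T": freq_t,
                "freq_C": freq_c,
                "hwe_chi2": hwe.chi2,
                "hwe_p": hwe.p,
            }
        ]
    )
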