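"""Two-step median-anchored normalization of label-free protein abundances.

Run-to-run variation in label-free LC-MS experiments is corrected in two
steps:

1. **Protein scaling** — each protein's abundances are divided by
   ``f_i = mean_i / median_over_proteins(mean_i)``, where ``mean_i`` is the
   protein's average abundance across the experiment.  Afterwards every
   protein's mean equals the original median of protein means.
2. **Sample scaling** — each sample's (already adjusted) abundances are
   divided by ``g_j = median_within_sample_j / overall_median``, where the
   overall median is taken over all present values.  Afterwards every
   sample's median equals the pre-step overall median.

Means and medians are computed over *present* values only: missing entries
(NaN) are skipped, never imputed, and the missingness pattern is preserved.
Zeros, by contrast, are ordinary values and do enter the statistics; a
protein or sample that is entirely missing, or whose mean/median is not
strictly positive, is rejected with its identifier rather than silently
dropped.  The median of an even-length set is the midpoint of the two
central values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationFactors",
    "step1_protein_scaling",
    "step2_sample_scaling",
    "normalize_two_step",
]


@dataclass
class NormalizationFactors:
    """Scaling factors produced by the two normalization steps."""

    protein_factor: pd.Series | None = None
    sample_factor: pd.Series | None = None
    grand_median_of_protein_means: float | None = None
    overall_median_after_step1: float | None = None


def _check_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise ValueError("duplicate protein or sample identifiers")
    if (matrix < 0).any().any():
        raise ValueError("abundances must be nonnegative")


def step1_protein_scaling(matrix: pd.DataFrame) -> tuple[pd.DataFrame, NormalizationFactors]:
    """Divide each protein by its mean over the grand median of protein means."""
    _check_matrix(matrix)
    means = matrix.mean(axis=1, skipna=True)
    bad = means.index[~(means > 0)].tolist()  # catches all-NaN (mean=NaN) and zero means
    if bad:
        raise ValueError(f"proteins with undefined or nonpositive mean abundance: {bad}")
    grand_median = float(means.median())
    factors = means / grand_median
    out = matrix.div(factors, axis=0)
    return out, NormalizationFactors(
        protein_factor=factors.rename("protein_factor"),
        grand_median_of_protein_means=grand_median,
    )


def step2_sample_scaling(matrix: pd.DataFrame) -> tuple[pd.DataFrame, NormalizationFactors]:
    """Divide each sample by its median over the overall median abundance."""
    _check_matrix(matrix)
    medians = matrix.median(axis=0, skipna=True)
    bad = medians.index[~(medians > 0)].tolist()
    if bad:
        raise ValueError(f"samples with undefined or nonpositive median abundance: {bad}")
    overall = float(np.nanmedian(matrix.to_numpy()))
    factors = medians / overall
    out = matrix.div(factors, axis=1)
    return out, NormalizationFactors(
        sample_factor=factors.rename("sample_factor"),
        overall_median_after_step1=overall,
    )


def normalize_two_step(matrix: pd.DataFrame) -> tuple[pd.DataFrame, NormalizationFactors]:
    """Protein scaling followed by sample scaling; records both factor sets."""
    step1, f1 = step1_protein_scaling(matrix)
    step2, f2 = step2_sample_scaling(step1)
    return step2, NormalizationFactors(
        protein_factor=f1.protein_factor,
        sample_factor=f2.sample_factor,
        grand_median_of_protein_means=f1.grand_median_of_protein_means,
        overall_median_after_step1=f2.overall_median_after_step1,
    )
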