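"""Label-free proteomics statistics.

Protein intensity matrices (log2 scale, NaN = missing) are filtered on
peptide support and missingness, normalized with a robust z-score
transformation rescaled back to intensity-like units, and tested per
protein with a pooled-variance t-test.  Proteins observed in only one
condition get a pseudo fold change against the mean of the lowest-decile
intensities of the all-missing condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stability import bh_fdr

MAD_SCALE = 1.4826  # consistency factor: MAD of a normal -> sigma


@dataclass
class ProteinIntensityMatrix:
    """log2 intensities (proteins x samples, NaN missing) with peptide counts
    and per-sample group labels."""

    intensities: pd.DataFrame
    peptide_counts: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        self.peptide_counts = pd.Series(
            self.peptide_counts, index=self.intensities.index
        )
        self.groups = pd.Series(self.groups, index=self.intensities.columns)
        if (self.peptide_counts < 1).any():
            raise ValueError("peptide counts must be >= 1")


def filter_proteins(
    matrix: ProteinIntensityMatrix, min_peptides: int = 2, max_missing: int = 4
) -> ProteinIntensityMatrix:
    """Keep proteins with >= min_peptides peptides and <= max_missing missing cells."""
    missing = matrix.intensities.isna().sum(axis=1)
    keep = (matrix.peptide_counts >= min_peptides) & (missing <= max_missing)
    return ProteinIntensityMatrix(
        matrix.intensities.loc[keep],
        matrix.peptide_counts.loc[keep],
        matrix.groups,
    )


def robust_z_normalize(intensities: pd.DataFrame) -> pd.DataFrame:
    """Per-sample robust z-transformation rescaled to the grand location/scale.

    Each sample is centred at its median and scaled by 1.4826 x its MAD,
    then multiplied by the median of the per-sample scaled MADs and shifted
    by the median of the per-sample medians, so values stay in log2-intensity
    units and every sample's median equals the grand median afterwards.
    Missing values stay missing.
    """
    med = intensities.median(axis=0)
    mad = (intensities - med).abs().median(axis=0)
    if (mad == 0).any() or mad.isna().any():
        raise ValueError("sample with zero or undefined MAD")
    z = (intensities - med) / (MAD_SCALE * mad)
    grand_scale = (MAD_SCALE * mad).median()
    grand_loc = med.median()
    return z * grand_scale + grand_loc


def pooled_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided t-test with pooled variance; returns (log2 FC = mean(b)-mean(a), p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two present values per group")
    _, p = stats.ttest_ind(b, a, equal_var=True)
    return float(b.mean() - a.mean()), float(p)


def pseudo_fold_change(
    matrix: ProteinIntensityMatrix, protein: str, q: float = 0.10
) -> float:
    """Fold change for a protein entirely missing in one condition.

    The missing condition's group average is replaced by the mean of the
    lowest-``q`` fraction (at least one value) of all protein intensities
    observed in that condition; the FC is mean(group 2) - mean(group 1)
    on the log2 scale, as for observed proteins.
    """
    levels = list(pd.unique(matrix.groups))
    if len(levels) != 2:
        raise ValueError("exactly two conditions required")
    row = matrix.intensities.loc[protein]
    means: dict[str, float] = {}
    missing_groups = []
    for lv in levels:
        vals = row[matrix.groups[matrix.groups == lv].index].dropna()
        if vals.empty:
            missing_groups.append(lv)
        else:
            means[lv] = float(vals.mean())
    if len(missing_groups) == 0:
        raise ValueError(f"protein {protein!r} observed in both conditions")
    if len(missing_groups) == 2:
        raise ValueError(f"protein {protein!r} missing in both conditions")
    lv = missing_groups[0]
    cond = matrix.intensities[matrix.groups[matrix.groups == lv].index]
    observed = np.sort(cond.to_numpy().ravel())
    observed = observed[~np.isnan(observed)]
    if observed.size == 0:
        raise ValueError(f"no observed intensities in condition {lv!r}")
    n_low = max(1, int(np.floor(q * observed.size)))
    means[lv] = float(observed[:n_low].mean())
    return means[levels[1]] - means[levels[0]]


def differential_abundance(
    matrix: ProteinIntensityMatrix,
    min_peptides: int = 2,
    max_missing: int = 4,
    pseudo_q: float = 0.10,
    normalize: bool = True,
) -> pd.DataFrame:
    """Filter, normalize and test every protein; BH-FDR over the tested ones.

    Output columns: log2FC, p (NaN for pseudo-FC proteins), q, flag in
    {tested, pseudo, skipped}.
    """
    filtered = filter_proteins(matrix, min_peptides, max_missing)
    intens = (
        robust_z_normalize(filtered.intensities) if normalize else filtered.intensities
    )
    normed = ProteinIntensityMatrix(intens, filtered.peptide_counts, filtered.groups)
    levels = list(pd.unique(normed.groups))
    cols = {lv: normed.groups[normed.groups == lv].index for lv in levels}
    rows = []
    for prot, row in intens.iterrows():
        a = row[cols[levels[0]]].to_numpy(dtype=float)
        b = row[cols[levels[1]]].to_numpy(dtype=float)
        n_a = np.sum(~np.isnan(a))
        n_b = np.sum(~np.isnan(b))
        if n_a >= 2 and n_b >= 2:
            fc, p = pooled_t_test(a, b)
            rows.append((prot, fc, p, "tested"))
        elif (n_a == 0) != (n_b == 0):
            fc = pseudo_fold_change(normed, prot, q=pseudo_q)
            rows.append((prot, fc, np.nan, "pseudo"))
        else:
            rows.append((prot, np.nan, np.nan, "skipped"))
    out = pd.DataFrame(rows, columns=["protein", "log2FC", "p", "flag"]).set_index(
        "protein"
    )
    out["q"] = np.nan
    tested = out["flag"] == "tested"
    if tested.any():
        out.loc[tested, "q"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    return out
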