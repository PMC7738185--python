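"""Collagen-assay quantification and the proteomics differential-expression filter.

Two unrelated bench assays share this module because both reduce to simple,
auditable arithmetic over tabular inputs:

* a colorimetric total-collagen assay read at 560 nm, interpolated from a
  collagen type I standard linear-fit curve and scaled through the wet-mass
  dilution chain to micrograms of collagen per milligram of wet tissue; and
* a label-free proteomics filter chain — replicate presence filter,
  per-sample total-protein normalization, fold-change threshold of two, and
  a Wilcoxon rank-sum test per protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StandardCurve",
    "CollagenSample",
    "CollagenResult",
    "IntensityMatrix",
    "fit_standard_curve",
    "quantify_collagen",
    "de_filter",
]


# --------------------------------------------------------------------------
# collagen assay
# --------------------------------------------------------------------------

@dataclass
class StandardCurve:
    """OLS line absorbance = slope * mass + intercept from known standards."""

    masses_ug: np.ndarray
    absorbances: np.ndarray
    slope: float
    intercept: float
    r_squared: float

    def mass_from_absorbance(self, absorbance: float) -> float:
        return (absorbance - self.intercept) / self.slope

    @property
    def valid(self) -> bool:
        return self.slope > 0


@dataclass
class CollagenSample:
    """One wet-tissue sample pushed through the homogenization/hydrolysis chain.

    The default dilution chain: 100 uL water per 10 mg wet mass for
    homogenization; 100 uL homogenate hydrolyzed in 100 uL NaOH then
    neutralized with 100 uL HCl (3x dilution); 10 uL of hydrolysate plated
    per well, in triplicate.
    """

    wet_mass_mg: float
    triplicate_absorbances: np.ndarray
    region: str = ""
    homog_ul_per_mg: float = 10.0  # 100 uL per 10 mg
    hydrolysate_dilution: float = 3.0  # 100 uL homogenate -> 300 uL hydrolysate
    plated_ul: float = 10.0

    def __post_init__(self) -> None:
        if self.wet_mass_mg <= 0:
            raise ValueError("wet mass must be positive")
        self.triplicate_absorbances = np.asarray(self.triplicate_absorbances, float)

    @property
    def triplicate_cv(self) -> float:
        m = float(np.mean(self.triplicate_absorbances))
        if m == 0:
            return np.nan
        return float(np.std(self.triplicate_absorbances, ddof=1) / m)

    def well_mass_from_content(self, content_ug_per_mg: float) -> float:
        """Forward dilution model: expected collagen mass (ug) in one well."""
        conc_homog = content_ug_per_mg / self.homog_ul_per_mg  # ug/uL homogenate
        return conc_homog / self.hydrolysate_dilution * self.plated_ul


@dataclass
class CollagenResult:
    content_ug_per_mg: float
    well_mass_ug: float
    mean_absorbance: float
    triplicate_cv: float
    flags: list[str] = field(default_factory=list)


def fit_standard_curve(masses_ug, absorbances) -> StandardCurve:
    """Fit the linear standard curve by ordinary least squares."""
    m = np.asarray(masses_ug, float)
    a = np.asarray(absorbances, float)
    if m.size < 3:
        raise ValueError("need at least 3 standards")
    res = sps.linregress(m, a)
    return StandardCurve(
        masses_ug=m,
        absorbances=a,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
    )


def quantify_collagen(sample: CollagenSample, curve: StandardCurve) -> CollagenResult:
    """Mean triplicate absorbance -> well mass via the curve -> ug per mg wet tissue.

    Inverts the dilution chain: the well received ``plated_ul`` of
    hydrolysate, the hydrolysate diluted the homogenate by
    ``hydrolysate_dilution``, and the homogenate carried
    ``homog_ul_per_mg`` uL per mg of wet tissue, so

        content = well_mass * hydrolysate_dilution / plated_ul * homog_ul_per_mg
    """
    if not curve.valid:
        raise ValueError("standard curve has non-positive slope")
    flags: list[str] = []
    mean_abs = float(np.mean(sample.triplicate_absorbances))
    lo, hi = float(np.min(curve.absorbances)), float(np.max(curve.absorbances))
    if not lo <= mean_abs <= hi:
        flags.append("extrapolated_beyond_standards")
    well_mass = curve.mass_from_absorbance(mean_abs)
    if well_mass < 0:
        flags.append("negative_interpolated_mass_floored")
        well_mass = 0.0
    content = well_mass * sample.hydrolysate_dilution / sample.plated_ul * sample.homog_ul_per_mg
    return CollagenResult(
        content_ug_per_mg=float(content),
        well_mass_ug=float(well_mass),
        mean_absorbance=mean_abs,
        triplicate_cv=sample.triplicate_cv,
        flags=flags,
    )


# --------------------------------------------------------------------------
# proteomics DE filter
# --------------------------------------------------------------------------

@dataclass
class IntensityMatrix:
    """Protein x sample intensity table with two-group labels.

    ``intensities`` rows are proteins, columns samples; missing measurements
    are NaN.  ``groups`` maps each sample id to its group label; exactly two
    group labels must be present.
    """

    intensities: pd.DataFrame
    groups: pd.Series  # index = sample ids, values = group labels

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        if set(self.intensities.columns) != set(self.groups.index):
            raise ValueError("group labels must cover exactly the sample columns")
        if self.groups.nunique() != 2:
            raise ValueError("exactly two groups required")

    def group_columns(self, label: str) -> list:
        return list(self.groups.index[self.groups == label])

    @property
    def group_labels(self) -> tuple[str, str]:
        # stable order: CTL-like (reference) first if present, else sorted
        labels = sorted(self.groups.unique())
        if "CTL" in labels:
            labels = ["CTL"] + [g for g in labels if g != "CTL"]
        return tuple(labels)  # type: ignore[return-value]

    def to_tsv(self, path) -> None:
        self.intensities.to_csv(path, sep="\t")


def de_filter(
    matrix: IntensityMatrix,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    min_replicates: int = 2,
    test_mode: str = "two_sided_exact",
    group_summary: str = "mean",
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Run the differential-expression filter chain on an intensity matrix.

    Steps, in order:

    1. keep proteins with at least ``min_replicates`` non-missing intensity
       values in *every* group;
    2. divide each sample's intensities by that sample's total intensity
       (total-protein normalization);
    3. fold change = ratio of group summaries (mean by default) of the
       normalized intensities, treatment over reference;
    4. Wilcoxon rank-sum test per protein on the normalized values;
    5. flag as differentially expressed when |log2 fold change| >=
       log2(``fc_threshold``) and — except in ``fold_change_only`` mode —
       the test p-value is below ``alpha``.

    ``test_mode``: "two_sided_exact" (default), "one_sided" (direction taken
    from the observed fold change), or "fold_change_only" (no p gate; at
    n = 3 per group a two-sided exact rank-sum test cannot fall below 0.1,
    so the p gate is optional by design).

    Returns a DataFrame indexed by protein id with columns
    ``fold_change, log2fc, test_p, passes_replicate_filter, is_de``.
    """
    if group_summary not in ("mean", "median"):
        raise ValueError("group_summary must be 'mean' or 'median'")
    ref, treat = matrix.group_labels
    if reference_group is not None:
        labels = list(matrix.group_labels)
        if reference_group not in labels:
            raise ValueError(f"unknown reference group {reference_group!r}")
        ref = reference_group
        treat = next(g for g in labels if g != ref)

    X = matrix.intensities
    cols_ref = matrix.group_columns(ref)
    cols_treat = matrix.group_columns(treat)

    n_ref = X[cols_ref].notna().sum(axis=1)
    n_treat = X[cols_treat].notna().sum(axis=1)
    passes = (n_ref >= min_replicates) & (n_treat >= min_replicates)

    # total-protein normalization: per-sample totals over observed values
    totals = X.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        raise ValueError("every sample needs positive total intensity")
    N = X.divide(totals, axis=1)

    summarize = np.nanmean if group_summary == "mean" else np.nanmedian
    out = pd.DataFrame(index=X.index)
    out["passes_replicate_filter"] = passes

    fc = np.full(len(X), np.nan)
    pvals = np.full(len(X), np.nan)
    log2fc = np.full(len(X), np.nan)
    for i, (pid, row) in enumerate(N.iterrows()):
        if not passes.loc[pid]:
            continue
        a = row[cols_treat].dropna().to_numpy(float)
        b = row[cols_ref].dropna().to_numpy(float)
        sa, sb = summarize(a), summarize(b)
        if sb > 0:
            fc[i] = sa / sb
            log2fc[i] = np.log2(fc[i])
        if test_mode == "fold_change_only":
            continue
        if test_mode == "one_sided":
            alternative = "greater" if sa >= sb else "less"
        else:
            alternative = "two-sided"
        method = "exact" if (a.size + b.size) <= 20 else "asymptotic"
        try:
            pvals[i] = sps.mannwhitneyu(a, b, alternative=alternative, method=method).pvalue
        except ValueError:  # e.g. all values tied under exact method
            pvals[i] = sps.mannwhitneyu(a, b, alternative=alternative, method="asymptotic").pvalue

    out["fold_change"] = fc
    out["log2fc"] = log2fc
    out["test_p"] = pvals
    fc_pass = np.abs(out["log2fc"]) >= np.log2(fc_threshold)
    if test_mode == "fold_change_only":
        out["is_de"] = passes & fc_pass.fillna(False)
    else:
        out["is_de"] = passes & fc_pass.fillna(False) & (out["test_p"] < alpha).fillna(False)
    return out
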