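"""Associations between per-sample signature loads and clinical covariates.

All group comparisons default to two-sided Welch t-tests on relative loads
(pooled-variance and raw-load variants are flags). Degenerate zero-variance
comparisons return p = 1 with a flag instead of erroring; missing-covariate
exclusions are always tallied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConstantInputError, InsufficientDataError, ValidationError
from .nmf import ExposureMatrix

SMOKING_CATEGORIES = ("heavy", "light", "never", "unknown")
MSI_CATEGORIES = ("MSS", "MSI-L", "MSI-H", "unknown")


@dataclass
class AssociationResult:
    test: str
    groups: tuple[str, str] | None
    group_sizes: tuple[int, int] | None
    effect: float  # mean difference or correlation coefficient
    statistic: float
    p_value: float
    n_excluded: int = 0
    degenerate: bool = False
    tail: str = "two-sided"

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("test", "groups", "group_sizes", "effect", "statistic",
                 "p_value", "n_excluded", "degenerate", "tail")}


def read_covariates_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: covariate table needs a sample_id column")
    return df


def _aligned_loads(
    exposures: ExposureMatrix, signature_id: str, covariates: pd.DataFrame,
    use_relative: bool,
) -> pd.Series:
    if signature_id not in exposures.signature_ids:
        raise ValidationError(f"unknown signature {signature_id!r}")
    loads = pd.Series(
        exposures.row(signature_id, relative=use_relative), index=exposures.sample_ids
    )
    known = [s for s in covariates["sample_id"] if s in loads.index]
    return loads.loc[known]


def _welch(x: np.ndarray, y: np.ndarray, equal_var: bool = False) -> tuple[float, float, bool]:
    """(statistic, two-sided p, degenerate flag) with zero-variance handling."""
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        equal_means = np.isclose(x.mean(), y.mean())
        return 0.0 if equal_means else np.inf, 1.0 if equal_means else 0.0, True
    stat, p = stats.ttest_ind(x, y, equal_var=equal_var)
    if not np.isfinite(p):
        return float(stat), 1.0, True
    return float(stat), float(p), False


def compare_loads_by_group(
    exposures: ExposureMatrix,
    signature_id: str,
    covariates: pd.DataFrame,
    grouping: str,
    groups: tuple,
    use_relative: bool = True,
    equal_var: bool = False,
) -> AssociationResult:
    """Two-sided t-test on one signature's loads between two covariate groups.

    Each element of ``groups`` may be a single category or a collection of
    categories to merge (e.g. ``("heavy", "light")`` as smokers). Samples
    with missing/unknown covariate values or absent from the exposure matrix
    are excluded and tallied.
    """
    if grouping not in covariates.columns:
        raise ValidationError(f"covariate table has no column {grouping!r}")
    loads = _aligned_loads(exposures, signature_id, covariates, use_relative)
    cov = covariates.set_index("sample_id").loc[loads.index, grouping]

    def values_for(spec) -> np.ndarray:
        members = (spec,) if isinstance(spec, str) else tuple(spec)
        mask = cov.isin(members) & cov.notna()
        return loads[mask.values].to_numpy()

    x, y = values_for(groups[0]), values_for(groups[1])
    n_excluded = len(covariates) - len(x) - len(y)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError(
            f"need >= 2 samples per group, got {len(x)} and {len(y)}"
        )
    stat, p, degenerate = _welch(x, y, equal_var=equal_var)
    label = lambda spec: spec if isinstance(spec, str) else "+".join(spec)
    return AssociationResult(
        test="welch-t" if not equal_var else "pooled-t",
        groups=(label(groups[0]), label(groups[1])),
        group_sizes=(len(x), len(y)),
        effect=float(x.mean() - y.mean()),
        statistic=stat,
        p_value=p,
        n_excluded=n_excluded,
        degenerate=degenerate,
    )


def load_rank_halves_test(
    exposures: ExposureMatrix,
    signature_id: str,
    covariates: pd.DataFrame,
    covariate: str = "packs_per_year",
    use_relative: bool = True,
    equal_var: bool = False,
) -> AssociationResult:
    """Split samples at the median load (ties go to the heavy half) and
    t-test the numeric covariate between the heavy and light halves."""
    if covariate not in covariates.columns:
        raise ValidationError(f"covariate table has no column {covariate!r}")
    loads = _aligned_loads(exposures, signature_id, covariates, use_relative)
    cov = pd.to_numeric(covariates.set_index("sample_id").loc[loads.index, covariate],
                        errors="coerce")
    keep = cov.notna()
    n_excluded = len(covariates) - int(keep.sum())
    loads, cov = loads[keep.values], cov[keep]
    if len(loads) < 4:
        raise InsufficientDataError(f"need >= 4 samples with numeric {covariate}, got {len(loads)}")
    median = float(np.median(loads))
    heavy = loads.to_numpy() >= median
    if heavy.sum() < 2 or (~heavy).sum() < 2:
        raise InsufficientDataError("median split degenerate: a half has < 2 samples")
    x, y = cov.to_numpy()[heavy], cov.to_numpy()[~heavy]
    stat, p, degenerate = _welch(x, y, equal_var=equal_var)
    return AssociationResult(
        test="welch-t" if not equal_var else "pooled-t",
        groups=("heavy-load", "light-load"),
        group_sizes=(len(x), len(y)),
        effect=float(x.mean() - y.mean()),
        statistic=stat,
        p_value=p,
        n_excluded=n_excluded,
        degenerate=degenerate,
    )


def correlate_load_expression(
    exposures: ExposureMatrix,
    signature_id: str,
    covariates: pd.DataFrame,
    gene: str,
    method: str = "spearman",
    use_relative: bool = True,
) -> AssociationResult:
    """Correlation between one signature's loads and a gene's expression."""
    if method not in ("spearman", "pearson"):
        raise ValidationError(f"unknown correlation method {method!r}")
    column = gene if gene in covariates.columns else f"expr_{gene}"
    if column not in covariates.columns:
        raise ValidationError(f"covariate table has no expression column for {gene!r}")
    loads = _aligned_loads(exposures, signature_id, covariates, use_relative)
    expr = pd.to_numeric(covariates.set_index("sample_id").loc[loads.index, column],
                         errors="coerce")
    keep = expr.notna()
    n_excluded = len(covariates) - int(keep.sum())
    x, y = loads[keep.values].to_numpy(), expr[keep].to_numpy()
    if len(x) < 3:
        raise InsufficientDataError(f"need >= 3 paired observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    else:
        rho, p = stats.pearsonr(x, y)
    return AssociationResult(
        test=method,
        groups=None,
        group_sizes=None,
        effect=float(rho),
        statistic=float(rho),
        p_value=float(p),
        n_excluded=n_excluded,
    )


def expression_ordered_summary(
    exposures: ExposureMatrix,
    signature_ids: Sequence[str],
    covariates: pd.DataFrame,
    gene: str,
    housekeeping: str,
    use_relative: bool = True,
    log2_ratio: bool = False,
) -> pd.DataFrame:
    """Samples sorted by gene/housekeeping expression ratio with the loads of
    two signatures attached (and MSI status when available).

    Samples with a zero or missing housekeeping value are flagged and sorted
    last. One output row per input sample.
    """
    if len(signature_ids) != 2:
        raise ValidationError("expression_ordered_summary expects exactly two signature ids")
    for sig in signature_ids:
        if sig not in exposures.signature_ids:
            raise ValidationError(f"unknown signature {sig!r}")
    cols = {}
    for g in (gene, housekeeping):
        column = g if g in covariates.columns else f"expr_{g}"
        if column not in covariates.columns:
            raise ValidationError(f"covariate table has no expression column for {g!r}")
        cols[g] = column

    df = covariates.set_index("sample_id")
    samples = [s for s in df.index if s in exposures.sample_ids]
    num = pd.to_numeric(df.loc[samples, cols[gene]], errors="coerce")
    den = pd.to_numeric(df.loc[samples, cols[housekeeping]], errors="coerce")
    flagged = den.isna() | (den == 0) | num.isna()
    ratio = num / den.where(~flagged)
    if log2_ratio:
        ratio = np.log2(ratio)

    out = pd.DataFrame({"sample_id": samples, "expression_ratio": ratio.to_numpy(),
                        "flagged": flagged.to_numpy()})
    for sig in signature_ids:
        loads = pd.Series(exposures.row(sig, relative=use_relative), index=exposures.sample_ids)
        out[f"load_{sig}"] = loads.loc[samples].to_numpy()
    if "msi_status" in covariates.columns:
        out["msi_status"] = df.loc[samples, "msi_status"].to_numpy()
    out = out.sort_values(
        by=["flagged", "expression_ratio"], ascending=[True, True], kind="stable"
    ).reset_index(drop=True)
    return out
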