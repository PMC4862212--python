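"""Element-level statistics for ICP-MS ionomics tables.

The workflow mirrors routine practice for multi-element plant extracts:
a single-pass >3 SD outlier screen, one-way ANOVA per element with
two-tier significance flags, principal component analysis of the
correlation matrix (so that elements spanning seven orders of magnitude
in concentration contribute equally), box-plot summary statistics, and
the diagnostic cation/anion ratios (Na/K and Cl relative to Na+K) that
characterise salt accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from ._stats import fold_change, significance_flag, ttest_equal_var

#: the 27 major and trace elements measured in the extracts
ELEMENTS = (
    "Al", "As", "Ba", "B", "Br", "Cd", "Ca", "Cl", "Cr", "Co", "Cu", "Fe",
    "Pb", "Hg", "Mg", "Mn", "Mo", "Ni", "P", "K", "Se", "Si", "Ag", "Na",
    "S", "V", "Zn",
)

CONTROL = "control"
SALT = "salt"


def validate_table(table: pd.DataFrame, elements=ELEMENTS) -> None:
    if "condition" not in table.columns:
        raise ValueError("ionomics table needs a 'condition' column")
    missing = [e for e in elements if e not in table.columns]
    if missing:
        raise ValueError(f"ionomics table missing element column(s): {missing}")


# ---------------------------------------------------------------------------
# outlier screen
# ---------------------------------------------------------------------------

def remove_outliers(
    table: pd.DataFrame,
    sd_threshold: float = 3.0,
    elements=ELEMENTS,
    per_condition: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass removal of values more than ``sd_threshold`` SD from the mean.

    Mean and SD are computed over all samples of an element pooled across
    conditions (set ``per_condition`` to screen within conditions
    instead).  Flagged values become NaN; the returned log records
    (element, sample index, value, z-score).  The screen is strictly one
    pass: values that would only exceed the threshold after the first
    removal are retained.  Elements with zero SD are never flagged.
    """
    validate_table(table, elements)
    cleaned = table.copy()
    log_rows = []
    groups = [table.index] if not per_condition else [
        table.index[table["condition"] == c] for c in table["condition"].unique()
    ]
    for element in elements:
        for idx in groups:
            values = table.loc[idx, element].astype(float)
            mean, sd = values.mean(), values.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                continue
            z = (values - mean) / sd
            for sample, (val, zval) in zip(idx, zip(values, z)):
                if np.isfinite(zval) and abs(zval) > sd_threshold:
                    cleaned.loc[sample, element] = np.nan
                    log_rows.append(
                        {"element": element, "sample": sample, "value": val, "z": zval}
                    )
    log = pd.DataFrame(log_rows, columns=["element", "sample", "value", "z"])
    return cleaned, log


# ---------------------------------------------------------------------------
# per-element ANOVA
# ---------------------------------------------------------------------------

def box_stats(values: np.ndarray) -> dict:
    """Box-plot summary: median/mean, IQR, 5th/95th percentiles, extremes.

    Percentiles use linear interpolation so the summaries are exactly
    reproducible.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    q5, q25, q50, q75, q95 = np.percentile(v, [5, 25, 50, 75, 95], method="linear")
    return {
        "median": float(q50),
        "mean": float(v.mean()),
        "iqr_low": float(q25),
        "iqr_high": float(q75),
        "p5": float(q5),
        "p95": float(q95),
        "min": float(v.min()),
        "max": float(v.max()),
    }


def anova_per_element(
    table: pd.DataFrame,
    alpha_weak: float = 0.05,
    alpha_strong: float = 0.01,
    elements=ELEMENTS,
) -> pd.DataFrame:
    """One-way ANOVA (control vs salt) per element with flags and box stats.

    With two groups the ANOVA F-statistic equals the square of the
    equal-variance t statistic; the implementation cross-checks that
    identity and fails loudly if it is violated.  Elements reduced below
    two values in a condition (by the outlier screen) are reported with a
    missing p-value.
    """
    validate_table(table, elements)
    rows = []
    for element in elements:
        ctrl = table.loc[table["condition"] == CONTROL, element].dropna().to_numpy(float)
        salt = table.loc[table["condition"] == SALT, element].dropna().to_numpy(float)
        row: dict = {"element": element}
        row["mean_control"] = float(ctrl.mean()) if len(ctrl) else np.nan
        row["mean_salt"] = float(salt.mean()) if len(salt) else np.nan
        if len(ctrl) >= 2 and len(salt) >= 2:
            f_stat, p_anova = _sps.f_oneway(ctrl, salt)
            p_t = float(ttest_equal_var(ctrl, salt))
            if np.isfinite(p_anova) and abs(p_anova - p_t) > 1e-9:
                raise AssertionError(
                    f"{element}: two-group ANOVA p {p_anova} != t-test p {p_t}"
                )
            p = p_t if not np.isfinite(p_anova) else float(p_anova)
            row["F"] = float(f_stat) if np.isfinite(f_stat) else np.nan
            row["p_value"] = p
            row["flag"] = significance_flag(p, alpha_weak, alpha_strong)
            row["fold_change"] = fold_change(ctrl, salt)
        else:
            row.update({"F": np.nan, "p_value": np.nan, "flag": "NS", "fold_change": np.nan})
        for cond, vals in ((CONTROL, ctrl), (SALT, salt)):
            if len(vals):
                for key, val in box_stats(vals).items():
                    row[f"{cond}_{key}"] = val
        rows.append(row)
    return pd.DataFrame(rows).set_index("element")


# ---------------------------------------------------------------------------
# correlation-matrix PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame          # sample x component
    loadings: pd.DataFrame        # element x component
    variance_explained: pd.Series  # percent per component
    dropped_elements: list[str]    # zero-variance (or NaN-containing) columns


def pca_correlation(table: pd.DataFrame, elements=ELEMENTS) -> PCAResult:
    """PCA on the element correlation matrix.

    Each element is standardised to zero mean and unit variance over the
    samples, so high-concentration elements do not dominate.  Components
    are eigenvectors of the correlation matrix ordered by decreasing
    eigenvalue; each eigenvector's sign is fixed so its largest-magnitude
    loading is positive; scores are the standardised data projected onto
    the loadings.  Variance explained is eigenvalue / sum * 100.
    """
    validate_table(table, elements)
    if len(table) < 3:
        raise ValueError("PCA needs at least 3 samples")
    data = table[list(elements)].astype(float)
    usable, dropped = [], []
    for element in elements:
        col = data[element]
        if col.isna().any() or col.std(ddof=1) == 0:
            dropped.append(element)
        else:
            usable.append(element)
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable elements for PCA")
    x = data[usable].to_numpy()
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    corr = np.corrcoef(z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)
    for k in range(eigvecs.shape[1]):
        j = np.argmax(np.abs(eigvecs[:, k]))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    comps = [f"PC{i + 1}" for i in range(len(eigvals))]
    loadings = pd.DataFrame(eigvecs, index=usable, columns=comps)
    scores = pd.DataFrame(z @ eigvecs, index=table.index, columns=comps)
    var_exp = pd.Series(100.0 * eigvals / eigvals.sum(), index=comps)
    return PCAResult(scores, loadings, var_exp, dropped)


# ---------------------------------------------------------------------------
# diagnostic ratios
# ---------------------------------------------------------------------------

def element_ratios(means: pd.DataFrame) -> pd.DataFrame:
    """Na/K, Cl/(Na+K) and the Na+K total per condition.

    ``means`` is indexed by element with one column per condition (mg/L
    means), e.g. the ``mean_control``/``mean_salt`` columns of
    :func:`anova_per_element`.  A zero K mean leaves Na/K missing.
    """
    for el in ("Na", "K", "Cl"):
        if el not in means.index:
            raise ValueError(f"means table lacks element {el!r}")
    rows = {}
    for cond in means.columns:
        na, k, cl = (float(means.loc[el, cond]) for el in ("Na", "K", "Cl"))
        na_k = na / k if k else np.nan
        total = na + k
        cl_over = cl / total if total else np.nan
        rows[cond] = {"Na_K": na_k, "Na_plus_K": total, "Cl_over_NaK": cl_over}
    return pd.DataFrame(rows).T


@dataclass
class IonomicsConfig:
    alpha_weak: float = 0.05
    alpha_strong: float = 0.01
    outlier_sd: float = 3.0
    outlier_per_condition: bool = False


def ionomics_workflow(table: pd.DataFrame, config: IonomicsConfig | None = None) -> dict:
    """Outlier screen -> per-element ANOVA -> PCA -> ratio panel."""
    cfg = config or IonomicsConfig()
    validate_table(table)
    cleaned, outlier_log = remove_outliers(
        table, cfg.outlier_sd, per_condition=cfg.outlier_per_condition
    )
    stats = anova_per_element(cleaned, cfg.alpha_weak, cfg.alpha_strong)
    # elements left incomplete by the outlier screen are excluded from the
    # PCA (recorded in pca.dropped_elements) so the score matrix stays exact
    pca = pca_correlation(cleaned)
    means = stats[["mean_control", "mean_salt"]].rename(
        columns={"mean_control": CONTROL, "mean_salt": SALT}
    )
    ratios = element_ratios(means)
    return {
        "cleaned": cleaned,
        "outlier_log": outlier_log,
        "element_stats": stats,
        "pca": pca,
        "ratios": ratios,
    }
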