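"""Per-gene linear models on log2(RPKM+1): disease contrasts, age/sex adjustment, covariate scans.

Each gene is fit by ordinary least squares with disease status (NF as
reference level) and sex as categorical terms and age as a continuous,
cohort-mean-centered term. Fits are vectorized over genes via the normal
equations; per-coefficient two-sided p-values use the t distribution with
the residual degrees of freedom. "Adjusted" expression removes the
estimated age and sex effects around their cohort means — disease
structure is kept, and because the removed terms are mean-centered the
per-gene grand mean is preserved, so RPKM-difference thresholds remain
meaningful on the adjusted scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .deg import bh_adjust
from .io import ValidationError


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(value + 1); rejects negative input."""
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("log_transform requires nonnegative values")
    return pd.DataFrame(np.log2(values + 1.0), index=matrix.index, columns=matrix.columns)


def back_transform(logmatrix: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`log_transform`: 2**x - 1, clamped at 0."""
    return pd.DataFrame(
        np.maximum(np.exp2(logmatrix.to_numpy(dtype=float)) - 1.0, 0.0),
        index=logmatrix.index,
        columns=logmatrix.columns,
    )


def design_matrix(
    metadata: pd.DataFrame,
    terms: tuple[str, ...] = ("disease", "sex", "age"),
    extra: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Build the per-sample design matrix.

    Disease is dummy-coded with NF as the reference when present (otherwise
    the first level alphabetically); sex is a male indicator; age is
    centered at the cohort mean. ``extra`` appends one additional numeric
    column (used by the single-covariate scan).
    """
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(metadata))}
    info: dict = {"terms": list(terms), "n_samples": len(metadata)}
    if "disease" in terms:
        levels = sorted(metadata["phenotype"].unique())
        reference = "NF" if "NF" in levels else levels[0]
        info["reference"] = reference
        for level in levels:
            if level == reference:
                continue
            cols[f"disease[{level}]"] = (metadata["phenotype"] == level).to_numpy(float)
    if "sex" in terms:
        male = (metadata["sex"] == "male").to_numpy(float)
        cols["sex[male]"] = male
        info["sex_mean"] = float(male.mean())
    if "age" in terms:
        age = metadata["age"].to_numpy(float)
        if np.isnan(age).any():
            raise ValidationError("missing age values for included samples")
        info["age_mean"] = float(age.mean())
        cols["age"] = age - age.mean()
    if extra is not None:
        x = pd.to_numeric(extra, errors="raise").to_numpy(float)
        cols[str(extra.name)] = x
    X = pd.DataFrame(cols, index=metadata.index)
    _check_full_rank(X)
    return X, info


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the offending columns via the QR diagonal
        _, r = np.linalg.qr(arr)
        bad = [X.columns[i] for i in range(arr.shape[1]) if abs(r[i, i]) < 1e-10]
        raise ValidationError(
            f"design matrix is rank deficient (collinear columns: {bad or X.columns.tolist()})"
        )


@dataclass
class RegressionFit:
    """Vectorized per-gene OLS fit.

    All frames are genes x coefficients; ``sigma2`` is the per-gene residual
    variance (RSS / df) and ``df`` the shared residual degrees of freedom.
    """

    coefficients: pd.DataFrame
    stderr: pd.DataFrame
    pvalues: pd.DataFrame
    sigma2: pd.Series
    df: int
    design_info: dict

    def coefficient(self, term: str) -> pd.Series:
        return self.coefficients[term]


def fit_gene_models(
    logmatrix: pd.DataFrame,
    metadata: pd.DataFrame,
    terms: tuple[str, ...] = ("disease", "sex", "age"),
    extra: pd.Series | None = None,
) -> RegressionFit:
    """OLS fit of every gene on the shared design."""
    metadata = metadata.loc[logmatrix.columns]
    if "disease" in terms:
        counts = metadata["phenotype"].value_counts()
        if (counts < 2).any():
            raise ValidationError(f"need >= 2 samples per phenotype, have {counts.to_dict()}")
    X, info = design_matrix(metadata, terms, extra=extra)
    Xa = X.to_numpy(float)
    Y = logmatrix.to_numpy(float)  # genes x samples
    n, p = Xa.shape
    df = n - p
    if df <= 0:
        raise ValidationError(f"non-positive residual df: n={n}, p={p}")
    xtx_inv = np.linalg.inv(Xa.T @ Xa)
    beta = (xtx_inv @ Xa.T @ Y.T).T  # genes x p
    resid = Y - beta @ Xa.T
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / df
    # genes whose residuals vanish to rounding noise are exactly degenerate
    scale = np.einsum("ij,ij->i", Y, Y) / Y.shape[1] + 1.0
    tiny = sigma2 <= (np.finfo(float).eps * Y.shape[1]) ** 2 * scale
    sigma2[tiny] = 0.0
    beta[np.ix_(tiny, np.arange(p))] = np.where(
        np.abs(beta[tiny]) < 1e-8 * np.sqrt(scale[tiny])[:, None], 0.0, beta[tiny]
    )
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    # degenerate genes (zero residual variance): p=1 for null coefficients,
    # p=0 for nonzero ones
    degenerate = se == 0.0
    pvals[degenerate & (beta == 0.0)] = 1.0
    pvals[degenerate & (beta != 0.0)] = 0.0
    genes = logmatrix.index
    return RegressionFit(
        coefficients=pd.DataFrame(beta, index=genes, columns=X.columns),
        stderr=pd.DataFrame(se, index=genes, columns=X.columns),
        pvalues=pd.DataFrame(pvals, index=genes, columns=X.columns),
        sigma2=pd.Series(sigma2, index=genes, name="sigma2"),
        df=df,
        design_info=info,
    )


@dataclass
class AdjustedMatrix:
    """Expression with age/sex effects residualized out around their means.

    ``log2``: adjusted log2(RPKM+1); ``rpkm``: back-transform 2**x - 1
    clamped at 0; ``provenance`` records removed covariates, reference
    level and centering constants.
    """

    log2: pd.DataFrame
    rpkm: pd.DataFrame
    provenance: dict


def adjust_expression(
    logmatrix: pd.DataFrame,
    metadata: pd.DataFrame,
    remove: tuple[str, ...] = ("age", "sex"),
    fit: RegressionFit | None = None,
) -> AdjustedMatrix:
    """Remove age/sex effects (never disease) from a log2 matrix.

    adjusted = observed - b_age*(age - mean age) - b_sex*(male - mean male
    fraction). Mean-centering of the removed regressors preserves each
    gene's grand mean, and the disease contrasts of a refit on the adjusted
    data are unchanged.
    """
    allowed = {"age", "sex"}
    bad = set(remove) - allowed
    if bad:
        raise ValidationError(f"cannot remove terms {sorted(bad)}; only {sorted(allowed)}")
    metadata = metadata.loc[logmatrix.columns]
    if fit is None:
        fit = fit_gene_models(logmatrix, metadata)
    info = fit.design_info
    for term in remove:
        if term not in info["terms"]:
            raise ValidationError(f"term {term!r} absent from the fitted model")
    adjusted = logmatrix.to_numpy(float).copy()
    if "age" in remove:
        age_c = metadata["age"].to_numpy(float) - info["age_mean"]
        adjusted -= np.outer(fit.coefficients["age"].to_numpy(), age_c)
    if "sex" in remove:
        male_c = (metadata["sex"] == "male").to_numpy(float) - info["sex_mean"]
        adjusted -= np.outer(fit.coefficients["sex[male]"].to_numpy(), male_c)
    log2 = pd.DataFrame(adjusted, index=logmatrix.index, columns=logmatrix.columns)
    provenance = {
        "covariates_removed": list(remove),
        "reference_level": info.get("reference"),
        "age_mean": info.get("age_mean"),
        "sex_mean": info.get("sex_mean"),
    }
    return AdjustedMatrix(log2=log2, rpkm=back_transform(log2), provenance=provenance)


@dataclass
class CovariateScanResult:
    """Single-clinical-covariate association scan over DCM+ICM samples."""

    covariate: str
    table: pd.DataFrame  # per gene: coefficient, p, q
    n_significant: int
    fdr: float


def single_covariate_scan(
    logmatrix: pd.DataFrame,
    metadata: pd.DataFrame,
    covariate: str,
    fdr: float = 0.05,
) -> CovariateScanResult:
    """Per-gene OLS with terms {age, sex, covariate} on disease samples only.

    NF donors usually lack clinical records, so the scan is restricted to
    DCM+ICM subjects; the disease term is deliberately absent (including it
    alongside a disease-correlated covariate would be collinear).
    """
    meta = metadata.loc[metadata["phenotype"].isin(["DCM", "ICM"])]
    sub = logmatrix[meta.index.intersection(logmatrix.columns)]
    meta = meta.loc[sub.columns]
    if covariate not in meta.columns:
        raise ValidationError(f"covariate {covariate!r} absent from sample table")
    x = meta[covariate]
    if x.dtype == bool or set(pd.unique(x.dropna())) <= {0, 1, True, False}:
        x = x.astype(float)
    x = pd.to_numeric(x, errors="raise")
    if x.nunique() < 2:
        raise ValidationError(
            f"covariate {covariate!r} is constant in DCM+ICM (multicollinearity)"
        )
    fit = fit_gene_models(sub, meta, terms=("sex", "age"), extra=x.rename(covariate))
    p = fit.pvalues[covariate]
    q = pd.Series(bh_adjust(p.to_numpy()), index=p.index, name="q")
    table = pd.DataFrame(
        {"coefficient": fit.coefficients[covariate], "p": p, "q": q}
    ).sort_values("q")
    return CovariateScanResult(
        covariate=covariate,
        table=table,
        n_significant=int((q <= fdr).sum()),
        fdr=fdr,
    )
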