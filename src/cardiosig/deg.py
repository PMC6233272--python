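"""Two-group differential expression with the joint |ΔRPKM| >= 5 / BH-FDR <= 0.05 criterion.

Testing is done on the log2(RPKM+1) scale with a pooled-variance two-sample
t test (equivalent to a one-way linear-model F test), while the difference
threshold is applied to the RPKM-scale group means. BH adjustment runs
over the expressed (tested) genes only. DEG lists from two vs-NF
comparisons are partitioned into the HF-shared signature (intersection),
DCM-specific and ICM-specific sets (set differences), alongside the direct
ICM-vs-DCM list.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError
from .preprocess import expressed_genes

DIFF_RPKM = 5.0
FDR_LEVEL = 0.05


def test_two_groups(log_a: np.ndarray, log_b: np.ndarray) -> np.ndarray:
    """Two-sided pooled-variance t test per gene (rows) on log-scale values.

    Degenerate genes with zero residual variance get p = 1 when the group
    means are equal and p = 0 otherwise.
    """
    log_a = np.atleast_2d(np.asarray(log_a, float))
    log_b = np.atleast_2d(np.asarray(log_b, float))
    if log_a.shape[1] < 2 or log_b.shape[1] < 2:
        raise ValidationError("each group needs >= 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(log_a, log_b, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, float)
    var_a = log_a.var(axis=1, ddof=1)
    var_b = log_b.var(axis=1, ddof=1)
    degenerate = (var_a == 0.0) & (var_b == 0.0)
    if degenerate.any():
        equal_means = np.isclose(log_a.mean(axis=1), log_b.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    return p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, ties share q)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(mean1, mean2):
    """Signed expression ratio with magnitude >= 1.

    Positive when group 1 is higher (mean1/mean2), negative when lower
    (-mean2/mean1); no values inside (-1, 1). Requires positive means,
    which the expressed-gene filter guarantees.
    """
    m1 = np.asarray(mean1, float)
    m2 = np.asarray(mean2, float)
    if (m1 <= 0).any() or (m2 <= 0).any():
        raise ValidationError("fold change requires positive group means")
    fc = np.where(m1 >= m2, m1 / m2, -m2 / m1)
    return float(fc) if np.isscalar(mean1) and np.isscalar(mean2) else fc


def call_degs(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    comparison: tuple[str, str],
    expressed_threshold: float = 5.0,
    diff_threshold: float = DIFF_RPKM,
    fdr: float = FDR_LEVEL,
) -> pd.DataFrame:
    """Full two-group DEG call: expressed filter -> t test -> BH -> joint flag.

    ``matrix`` holds RPKM-scale values; testing happens on log2(RPKM+1).
    Returns a per-gene frame (sorted by q, untested genes last) with
    RPKM-scale group means, difference, signed fold change, p, q and the
    ``expressed`` / ``is_deg`` flags; the comparison label and group sizes
    are stored in ``.attrs``.
    """
    group1, group2 = comparison
    phen = metadata.loc[matrix.columns, "phenotype"]
    samples_1 = matrix.columns[(phen == group1).to_numpy()]
    samples_2 = matrix.columns[(phen == group2).to_numpy()]
    if len(samples_1) < 2 or len(samples_2) < 2:
        raise ValidationError(
            f"need >= 2 samples per group for {group1} vs {group2}; "
            f"have {len(samples_1)} and {len(samples_2)}"
        )
    mean1 = matrix[samples_1].mean(axis=1)
    mean2 = matrix[samples_2].mean(axis=1)
    expressed = expressed_genes(matrix, samples_1, samples_2, threshold=expressed_threshold)
    is_expressed = matrix.index.isin(expressed)

    log_values = np.log2(matrix.to_numpy(float) + 1.0)
    a = log_values[np.ix_(is_expressed, matrix.columns.get_indexer(samples_1))]
    b = log_values[np.ix_(is_expressed, matrix.columns.get_indexer(samples_2))]

    result = pd.DataFrame(
        {
            "mean_1": mean1,
            "mean_2": mean2,
            "diff": mean1 - mean2,
            "fold_change": np.nan,
            "p": np.nan,
            "q": np.nan,
            "expressed": is_expressed,
            "is_deg": False,
        },
        index=matrix.index,
    )
    if is_expressed.any():
        p = test_two_groups(a, b)
        q = bh_adjust(p)
        result.loc[is_expressed, "p"] = p
        result.loc[is_expressed, "q"] = q
        result.loc[is_expressed, "fold_change"] = fold_change(
            mean1[is_expressed].to_numpy(), mean2[is_expressed].to_numpy()
        )
        result["is_deg"] = (
            result["expressed"]
            & (result["diff"].abs() >= diff_threshold)
            & (result["q"] <= fdr)
        )
    result = result.sort_values("q", kind="stable", na_position="last")
    result.attrs["comparison"] = f"{group1}_vs_{group2}"
    result.attrs["groups"] = (group1, group2)
    result.attrs["n_samples"] = (len(samples_1), len(samples_2))
    result.attrs["fdr"] = fdr
    result.attrs["diff_threshold"] = diff_threshold
    return result


def _direction(result: pd.DataFrame, genes: pd.Index) -> pd.Series:
    return pd.Series(
        np.where(result.loc[genes, "diff"] > 0, "up", "down"), index=genes, name="direction"
    )


@dataclass
class SignatureSets:
    """Three-way DEG partition plus the direct disease-vs-disease list.

    ``hf`` (intersection of the two vs-NF DEG lists), ``dcm_specific`` and
    ``icm_specific`` (set differences) and ``direct`` (ICM vs DCM DEGs) are
    frames indexed by gene with a ``direction`` column (up/down relative to
    the first group of the source comparison; for ``hf`` the shared vs-NF
    direction, taken from DCM vs NF).
    """

    hf: pd.DataFrame
    dcm_specific: pd.DataFrame
    icm_specific: pd.DataFrame
    direct: pd.DataFrame

    def __post_init__(self) -> None:
        hf = set(self.hf.index)
        if hf & set(self.dcm_specific.index) or hf & set(self.icm_specific.index):
            raise ValidationError("HF signature overlaps a disease-specific set")

    @property
    def signature_genes(self) -> pd.Index:
        """Combined disease-specific signature used for sample classification."""
        return self.dcm_specific.index.union(self.icm_specific.index)

    def summary(self) -> dict:
        def updown(frame: pd.DataFrame) -> dict:
            return {
                "n": int(len(frame)),
                "up": int((frame["direction"] == "up").sum()),
                "down": int((frame["direction"] == "down").sum()),
            }

        return {
            "hf": updown(self.hf),
            "dcm_specific": updown(self.dcm_specific),
            "icm_specific": updown(self.icm_specific),
            "direct": updown(self.direct),
        }


def partition_signatures(
    dcm_vs_nf: pd.DataFrame,
    icm_vs_nf: pd.DataFrame,
    icm_vs_dcm: pd.DataFrame | None = None,
) -> SignatureSets:
    """Partition vs-NF DEG lists into HF-shared and disease-specific sets.

    The two vs-NF results must share a gene universe. Partition identities
    (hf ∪ specific = source DEG list, disjointness) hold by construction and
    are asserted.
    """
    if set(dcm_vs_nf.index) != set(icm_vs_nf.index):
        raise ValidationError("comparisons were not computed on the same gene universe")
    dcm_degs = dcm_vs_nf.index[dcm_vs_nf["is_deg"]]
    icm_degs = icm_vs_nf.index[icm_vs_nf["is_deg"]]
    hf = dcm_degs.intersection(icm_degs)
    dcm_only = dcm_degs.difference(hf)
    icm_only = icm_degs.difference(hf)
    if icm_vs_dcm is not None:
        direct_genes = icm_vs_dcm.index[icm_vs_dcm["is_deg"]]
        direct = _direction(icm_vs_dcm, direct_genes).to_frame()
    else:
        direct = pd.DataFrame({"direction": pd.Series(dtype=object)})
    sets = SignatureSets(
        hf=_direction(dcm_vs_nf, hf).to_frame(),
        dcm_specific=_direction(dcm_vs_nf, dcm_only).to_frame(),
        icm_specific=_direction(icm_vs_nf, icm_only).to_frame(),
        direct=direct,
    )
    assert len(sets.hf) + len(sets.dcm_specific) == len(dcm_degs)
    assert len(sets.hf) + len(sets.icm_specific) == len(icm_degs)
    return sets


def concordance_diagnostics(
    signatures: SignatureSets,
    dcm_vs_nf: pd.DataFrame,
    icm_vs_nf: pd.DataFrame,
) -> dict:
    """Direction concordance and log-mean R² over the HF-shared signature.

    ``direction_concordance``: fraction of HF genes whose RPKM difference has
    the same sign in both vs-NF comparisons. ``log_mean_r2``: coefficient of
    determination of log10 disease-group mean RPKM, DCM against ICM.
    """
    hf = signatures.hf.index
    if len(hf) == 0:
        raise ValidationError("HF signature is empty")
    d_dcm = dcm_vs_nf.loc[hf, "diff"]
    d_icm = icm_vs_nf.loc[hf, "diff"]
    concordance = float((np.sign(d_dcm) == np.sign(d_icm)).mean())
    log_dcm = np.log10(dcm_vs_nf.loc[hf, "mean_1"])
    log_icm = np.log10(icm_vs_nf.loc[hf, "mean_1"])
    r = np.corrcoef(log_dcm, log_icm)[0, 1]
    return {"direction_concordance": concordance, "log_mean_r2": float(r**2)}


# ---------------------------------------------------------------------------
# Supplementary-table style ingestion (gene id, comparison, means, diff,
# fold change, p, q, set label) so externally produced DEG lists can be fed
# through the same set algebra.

DEG_TABLE_COLUMNS = ["gene_id", "comparison", "mean_1", "mean_2", "diff", "fold_change", "p", "q", "is_deg"]


def write_deg_table(result: pd.DataFrame, path: str | Path) -> None:
    out = result.copy()
    out.insert(0, "comparison", result.attrs.get("comparison", ""))
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_deg_table(path: str | Path) -> pd.DataFrame:
    """Read a DEG table written by :func:`write_deg_table` (or the same layout)."""
    table = pd.read_csv(path, sep="\t", index_col="gene_id")
    missing = {"diff", "q", "is_deg"} - set(table.columns)
    if missing:
        raise ValidationError(f"DEG table missing columns: {sorted(missing)}")
    comparisons = table["comparison"].unique() if "comparison" in table.columns else []
    if len(comparisons) == 1:
        table.attrs["comparison"] = str(comparisons[0])
    return table


def deg_list_overlap(list_a: pd.Index, list_b: pd.Index) -> dict:
    """Shared-gene count and fraction (relative to the second list)."""
    shared = list_a.intersection(list_b)
    return {
        "n_shared": int(len(shared)),
        "fraction_of_b": float(len(shared) / len(list_b)) if len(list_b) else float("nan"),
    }
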