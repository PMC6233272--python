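"""Matrix filters: mitochondrial-gene exclusion, expressed-gene and most-variable-gene selection.

The pipeline works in RPKM units. A gene is "expressed" for a two-group
comparison when its arithmetic mean RPKM is at least 5 in *both* groups
(inclusive threshold). The PCA gene set keeps genes with overall mean
RPKM >= 5 whose pooled-disease (DCM+ICM) mean differs from the NF mean by
at least 5 RPKM. All filters are idempotent and monotone in their
thresholds.
"""

from __future__ import annotations

from collections.abc import Sequence

import pandas as pd

from .io import MITO_CHROMOSOMES, ValidationError

EXPRESSED_RPKM = 5.0
PCA_DIFF_RPKM = 5.0


def drop_mitochondrial(matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Remove genes annotated to the mitochondrial chromosome.

    ``annotation`` is indexed by gene_id with a ``chromosome`` column; every
    matrix gene must be annotated. Row order of the survivors is preserved.
    """
    missing = matrix.index.difference(annotation.index)
    if len(missing):
        raise ValidationError(f"genes missing from annotation: {missing.tolist()[:20]}")
    chrom = annotation.loc[matrix.index, "chromosome"].astype(str)
    keep = ~chrom.isin(MITO_CHROMOSOMES)
    return matrix.loc[keep.to_numpy()]


def expressed_genes(
    matrix: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    threshold: float = EXPRESSED_RPKM,
) -> pd.Index:
    """Genes with mean abundance >= ``threshold`` in both sample groups."""
    samples_a, samples_b = list(samples_a), list(samples_b)
    if not samples_a or not samples_b:
        raise ValidationError("both sample groups must be nonempty")
    if set(samples_a) & set(samples_b):
        raise ValidationError("sample groups must be disjoint")
    mean_a = matrix[samples_a].mean(axis=1)
    mean_b = matrix[samples_b].mean(axis=1)
    return matrix.index[(mean_a >= threshold) & (mean_b >= threshold)]


def variable_genes_for_pca(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    threshold: float = EXPRESSED_RPKM,
    diff_threshold: float = PCA_DIFF_RPKM,
    disease_mode: str = "pooled",
) -> pd.Index:
    """Most-variable gene set for PCA.

    Keeps genes with overall mean >= ``threshold`` and an absolute difference
    between the disease mean and the NF mean >= ``diff_threshold``.
    ``disease_mode='pooled'`` uses the pooled DCM+ICM mean; ``'per_disease'``
    uses the larger of the two per-disease absolute differences.
    """
    phen = metadata.loc[matrix.columns, "phenotype"]
    present = set(phen.unique())
    if not {"DCM", "ICM", "NF"} <= present:
        raise ValidationError(f"need all three phenotypes for PCA gene selection, have {sorted(present)}")
    overall = matrix.mean(axis=1)
    nf_mean = matrix.loc[:, phen == "NF"].mean(axis=1)
    if disease_mode == "pooled":
        dis_mean = matrix.loc[:, phen.isin(["DCM", "ICM"])].mean(axis=1)
        diff = (dis_mean - nf_mean).abs()
    elif disease_mode == "per_disease":
        d_dcm = (matrix.loc[:, phen == "DCM"].mean(axis=1) - nf_mean).abs()
        d_icm = (matrix.loc[:, phen == "ICM"].mean(axis=1) - nf_mean).abs()
        diff = pd.concat([d_dcm, d_icm], axis=1).max(axis=1)
    else:
        raise ValidationError(f"unknown disease_mode {disease_mode!r}")
    return matrix.index[(overall >= threshold) & (diff >= diff_threshold)]
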