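"""PCA, inter-sample Spearman correlation, UPGMA clustering and signature classification.

Samples are compared by Spearman rank correlation across a gene set and
clustered agglomeratively with average linkage (UPGMA) on the distance
1 - rho. Phenotype classification of an independent cohort extracts the
disease-specific signature genes, clusters the samples, cuts the tree at
k = number of phenotypes present and assigns each cluster its majority
phenotype; a sample is correctly segregated when its cluster's assigned
phenotype matches its label. Because Spearman distances depend only on
within-sample ranks, the procedure is invariant to strictly monotone
per-sample platform distortions (e.g. microarray intensity scales).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .deg import SignatureSets
from .io import ValidationError


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    variance_ratio: np.ndarray  # fraction of total variance per component
    gene_set: pd.Index


def pca(matrix: pd.DataFrame, gene_set) -> PCAResult:
    """SVD-based principal components of samples over a gene set.

    The gene submatrix is centered per gene; samples are the observations.
    Component signs are fixed by making each component's loading on the
    first gene nonnegative, so results are reproducible and invariant (up
    to that convention) to sample order.
    """
    gene_set = pd.Index(gene_set)
    if len(gene_set) == 0:
        raise ValidationError("empty gene set for PCA")
    missing = gene_set.difference(matrix.index)
    if len(missing):
        raise ValidationError(f"PCA gene set not in matrix: {missing.tolist()[:10]}")
    if matrix.shape[1] < 2:
        raise ValidationError("PCA needs >= 2 samples")
    sub = matrix.loc[gene_set]
    data = sub.to_numpy(float).T  # samples x genes
    data = data - data.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(data, full_matrices=False)
    # sign convention: loading of the first gene nonnegative
    flip = np.where(vt[:, 0] < 0, -1.0, 1.0)
    u = u * flip[None, :]
    scores = u * s[None, :]
    total = (s**2).sum()
    ratio = s**2 / total if total > 0 else np.zeros_like(s)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=cols),
        variance_ratio=ratio,
        gene_set=gene_set,
    )


def sample_correlation(matrix: pd.DataFrame, gene_set=None) -> pd.DataFrame:
    """Sample-by-sample Spearman correlation matrix (average ranks for ties)."""
    sub = matrix.loc[pd.Index(gene_set)] if gene_set is not None else matrix
    if len(sub) < 2:
        raise ValidationError("need >= 2 genes for sample correlation")
    constant = sub.nunique(axis=0) <= 1
    if constant.any():
        raise ValidationError(
            f"constant sample vectors (correlation undefined): {sub.columns[constant].tolist()}"
        )
    corr = sub.corr(method="spearman")
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr


@dataclass
class ClusterResult:
    """Average-linkage tree over samples at distance 1 - Spearman rho."""

    linkage: np.ndarray
    sample_ids: pd.Index
    labels: pd.Series | None  # flat clusters at requested k, 1-based
    leaf_order: list
    distance: str = "1 - spearman"

    def cut(self, k: int) -> pd.Series:
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.sample_ids, name="cluster")


def hierarchical_cluster(matrix: pd.DataFrame, gene_set=None, k: int | None = None) -> ClusterResult:
    """UPGMA clustering of samples; deterministic given input order.

    Ties in merge distances follow scipy's nearest-neighbor chain order,
    which is deterministic for a fixed sample ordering.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("need >= 2 samples to cluster")
    corr = sample_correlation(matrix, gene_set=gene_set)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce exact symmetry
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    result = ClusterResult(
        linkage=Z,
        sample_ids=matrix.columns,
        labels=None,
        leaf_order=[matrix.columns[i] for i in hierarchy.leaves_list(Z)],
    )
    if k is not None:
        result.labels = result.cut(k)
    return result


def collapse_probes(matrix: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Collapse probe-level rows to genes, keeping the max-mean-expression probe."""
    mapped = matrix.index.intersection(probe_map.index)
    sub = matrix.loc[mapped]
    genes = probe_map.loc[mapped]
    order = sub.mean(axis=1).groupby(genes.to_numpy()).idxmax()
    collapsed = sub.loc[order.to_numpy()]
    collapsed.index = pd.Index(order.index, name="gene_id")
    return collapsed


@dataclass
class SegregationReport:
    """Cluster-vs-phenotype segregation accuracy of a classified cohort."""

    per_phenotype: pd.DataFrame  # index phenotype, columns n_correct, n_total
    cluster_map: dict  # cluster id -> assigned phenotype
    accuracy: float
    cluster_labels: pd.Series
    n_signature_genes: int
    fraction_mapped: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_phenotype": {
                ph: {"n_correct": int(r["n_correct"]), "n_total": int(r["n_total"])}
                for ph, r in self.per_phenotype.iterrows()
            },
            "cluster_map": {int(k): v for k, v in self.cluster_map.items()},
            "n_signature_genes": self.n_signature_genes,
            "fraction_mapped": self.fraction_mapped,
        }


def classify_by_signature(
    external: pd.DataFrame,
    signatures: SignatureSets,
    labels: pd.DataFrame,
    probe_map: pd.Series | None = None,
    k: int | None = None,
    min_mappable: float = 0.2,
) -> SegregationReport:
    """Cluster an external cohort on the disease-specific signature and score it.

    Probes are collapsed to genes (max mean expression); the
    DCM-specific ∪ ICM-specific signature rows are extracted (at least
    ``min_mappable`` of the signature must map, else an error reports the
    mapping rate); samples are UPGMA-clustered on 1 - Spearman rho and the
    tree is cut at k = number of phenotypes present (overridable). Each
    cluster is assigned its majority phenotype, ties broken toward the
    larger phenotype then lexicographically.
    """
    gene_matrix = collapse_probes(external, probe_map) if probe_map is not None else external
    signature = signatures.signature_genes
    if len(signature) == 0:
        raise ValidationError("empty disease-specific signature")
    mapped = signature.intersection(gene_matrix.index)
    fraction = len(mapped) / len(signature)
    if fraction < min_mappable:
        raise ValidationError(
            f"only {len(mapped)}/{len(signature)} signature genes "
            f"({fraction:.1%}) mappable into the external matrix"
        )
    phen = labels.loc[gene_matrix.columns, "phenotype"]
    phenotypes = sorted(phen.unique())
    n_clusters = k if k is not None else len(phenotypes)
    tree = hierarchical_cluster(gene_matrix, gene_set=mapped, k=n_clusters)
    clusters = tree.labels
    totals = phen.value_counts()
    cluster_map: dict[int, str] = {}
    for cid in sorted(clusters.unique()):
        members = phen[clusters == cid]
        counts = members.value_counts()
        best = sorted(
            counts.index, key=lambda ph: (-counts[ph], -totals[ph], ph)
        )[0]
        cluster_map[int(cid)] = best
    predicted = clusters.map(cluster_map)
    correct = predicted == phen
    per_phenotype = pd.DataFrame(
        {
            "n_correct": correct.groupby(phen).sum().astype(int),
            "n_total": phen.groupby(phen).size().astype(int),
        }
    )
    per_phenotype.index.name = "phenotype"
    return SegregationReport(
        per_phenotype=per_phenotype,
        cluster_map=cluster_map,
        accuracy=float(correct.mean()),
        cluster_labels=clusters,
        n_signature_genes=int(len(signature)),
        fraction_mapped=float(fraction),
    )
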