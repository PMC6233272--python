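"""Label-permutation empirical null for DEG counts.

Sample labels for one two-group comparison are randomly reassigned
(preserving the original group sizes), the full DEG criterion is re-run,
and the resulting null distribution of DEG counts is summarized. Following
the study design this module validates, the observed count is compared to
the null by a one-sample t test of the null counts against the observed
value; the empirical rank of the observed count is reported as a
diagnostic only. Replicates are sampled independently (a split may repeat)
and the observed labeling is not excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .deg import call_degs
from .io import ValidationError

#: double-precision reporting floor used for vanishing p-values
P_FLOOR = 2.2e-16


def permute_labels(
    metadata: pd.DataFrame,
    comparison: tuple[str, str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Uniformly random relabeling of the pooled comparison samples.

    Returns a copy of ``metadata`` whose phenotype column carries shuffled
    group labels of the original sizes for the two comparison groups.
    """
    group1, group2 = comparison
    pool = metadata.index[metadata["phenotype"].isin([group1, group2])]
    n1 = int((metadata["phenotype"] == group1).sum())
    n2 = int((metadata["phenotype"] == group2).sum())
    if n1 == 0 or n2 == 0:
        raise ValidationError(f"both groups must be nonempty: {group1}={n1}, {group2}={n2}")
    if n1 + n2 > len(metadata):
        raise ValidationError("requested group sizes exceed the sample pool")
    shuffled = pool.to_numpy()[rng.permutation(len(pool))]
    permuted = metadata.copy()
    permuted.loc[shuffled[:n1], "phenotype"] = group1
    permuted.loc[shuffled[n1:], "phenotype"] = group2
    return permuted


@dataclass
class PermutationDistribution:
    """Null DEG counts under shuffled labels plus the observed count."""

    comparison: str
    counts: np.ndarray
    observed: int
    seed: int
    n_reps: int = field(default=0)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, int)
        self.n_reps = len(self.counts)

    @property
    def mean(self) -> float:
        return float(self.counts.mean())

    @property
    def sd(self) -> float:
        return float(self.counts.std(ddof=1)) if self.n_reps > 1 else 0.0

    @property
    def max_count(self) -> int:
        return int(self.counts.max())

    def fraction_le(self, k: int = 5) -> float:
        return float((self.counts <= k).mean())

    def empirical_rank(self) -> float:
        """Fraction of null counts >= the observed count (diagnostic only)."""
        return float((self.counts >= self.observed).mean())

    def summary(self) -> dict:
        t, p = permutation_test(self)
        return {
            "comparison": self.comparison,
            "n_reps": self.n_reps,
            "observed": self.observed,
            "mean": self.mean,
            "sd": self.sd,
            "max": self.max_count,
            "fraction_le_5": self.fraction_le(5),
            "t": t,
            "p": p,
            "p_report": format_p(p),
            "empirical_rank": self.empirical_rank(),
            "seed": self.seed,
        }


def permutation_null(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    comparison: tuple[str, str],
    n_reps: int = 1000,
    seed: int = 0,
    **deg_kwargs,
) -> PermutationDistribution:
    """Re-run the full DEG criterion under ``n_reps`` random relabelings."""
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    metadata = metadata.loc[matrix.columns]
    observed = int(call_degs(matrix, metadata, comparison, **deg_kwargs)["is_deg"].sum())
    rng = np.random.default_rng(seed)
    counts = np.empty(n_reps, dtype=int)
    for i in range(n_reps):
        permuted = permute_labels(metadata, comparison, rng)
        counts[i] = int(call_degs(matrix, permuted, comparison, **deg_kwargs)["is_deg"].sum())
    label = f"{comparison[0]}_vs_{comparison[1]}"
    return PermutationDistribution(comparison=label, counts=counts, observed=observed, seed=seed)


def one_sample_t(mean: float, sd: float, n: int, observed: float) -> tuple[float, float]:
    """One-sample t of a null distribution (summary form) against an observed value.

    t = (mean - observed) / (sd / sqrt(n)); two-sided p with n - 1 df.
    With sd = 0 the test is degenerate: p = 1 if observed equals the mean,
    else p = 0 (t = ±inf).
    """
    if sd == 0.0:
        if observed == mean:
            return 0.0, 1.0
        return float(np.sign(mean - observed)) * float("inf"), 0.0
    t = (mean - observed) / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), float(p)


def permutation_test(dist: PermutationDistribution) -> tuple[float, float]:
    """One-sample t test of the null counts against the observed count."""
    return one_sample_t(dist.mean, dist.sd, dist.n_reps, dist.observed)


def format_p(p: float) -> str:
    """Report a p-value, flooring at the double-precision limit (< 2.2e-16)."""
    if p < P_FLOOR:
        return "< 2.2e-16"
    return f"{p:.3g}"


def histogram_counts(dist: PermutationDistribution, offset: float = 0.1) -> pd.DataFrame:
    """Plot-ready (count + offset, frequency) pairs for log-scale display.

    Zero counts plot at ``offset`` (default 0.1); total frequency mass
    equals ``n_reps``.
    """
    values, freqs = np.unique(dist.counts, return_counts=True)
    return pd.DataFrame(
        {"count": values, "plotted": values + offset, "frequency": freqs}
    )


def plot_null_histogram(dist: PermutationDistribution, path: str | Path, offset: float = 0.1) -> None:
    """Log-log histogram of the null DEG counts with the observed count marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist = histogram_counts(dist, offset=offset)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(hist["plotted"], hist["frequency"], width=0.1 * hist["plotted"], color="steelblue")
    ax.axvline(dist.observed + offset, color="red", linestyle="--", label=f"observed = {dist.observed}")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(f"DEG count + {offset}")
    ax.set_ylabel("frequency")
    ax.set_title(dist.comparison)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def write_distribution(dist: PermutationDistribution, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    pd.DataFrame(
        {"replicate": np.arange(1, dist.n_reps + 1), "deg_count": dist.counts}
    ).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(dist.summary(), indent=2))
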