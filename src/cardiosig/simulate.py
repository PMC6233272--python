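"""Synthetic heart-failure cohort generator with known gene-level ground truth.

The generator emulates the statistical structure of a three-cohort bulk
RNA-seq study of end-stage heart failure: dilated cardiomyopathy (DCM),
ischemic cardiomyopathy (ICM) and non-failing donor hearts (NF), default
sizes 37/13/14. Expression is log2-additive:

    log2(RPKM + 1) = baseline_g + disease effect + sex effect * male
                     + age effect * standardized age + N(0, noise_sd)

back-transformed as 2**x - 1 and clamped at zero, mirroring the pipeline's
log2(RPKM+1) working scale so planted effects are exactly recoverable by
the covariate model. Gene classes: null, HF-shared (same-sign shift in both
diseases), DCM-specific, ICM-specific, sex-linked and age-linked
confounder genes. Down-shifted genes have their baseline raised by the
effect size so that both group means stay in the expressed (>= 5 RPKM)
regime, making the planted RPKM difference symmetric to the up case.

Demographics are phenotype-confounded on purpose (disease cohorts are
older and more male than NF), so sex-/age-linked genes masquerade as
disease genes until the covariate adjustment removes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import ValidationError, validate_expression

GENE_CLASSES = (
    "null",
    "hf_shared_up",
    "hf_shared_down",
    "dcm_specific",
    "icm_specific",
    "sex_linked",
    "age_linked",
)


@dataclass
class SimConfig:
    """Study conditions for a synthetic three-cohort experiment.

    Defaults give a 37/13/14 cohort of 5000 genes with 300 HF-shared,
    100 DCM-specific, 200 ICM-specific, 50 sex-linked and 50 age-linked
    genes. The baseline puts the NF mean near 10 RPKM so a +1 log2 shift
    produces a ~11 RPKM group difference (2**(log2(11)+1) - 1 = 21).
    """

    n_dcm: int = 37
    n_icm: int = 13
    n_nf: int = 14
    n_genes: int = 5000
    frac_null: float = 0.86
    frac_hf_shared_up: float = 0.03
    frac_hf_shared_down: float = 0.03
    frac_dcm_specific: float = 0.02
    frac_icm_specific: float = 0.04
    frac_sex_linked: float = 0.01
    frac_age_linked: float = 0.01
    effect_size_log2: float = 1.0
    sex_effect_log2: float = 2.0
    age_effect_log2: float = 1.0
    noise_sd_log2: float = 0.25
    baseline_log2_mean: float = float(np.log2(11.0))
    baseline_log2_sd: float = 0.4
    age_range_years: dict = field(
        default_factory=lambda: {"DCM": (36.0, 62.0), "ICM": (52.0, 60.0), "NF": (30.0, 50.0)}
    )
    sex_ratio: dict = field(
        default_factory=lambda: {"DCM": 0.81, "ICM": 0.77, "NF": 0.36}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_dcm", "n_icm", "n_nf", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        fracs = self.class_fractions()
        for cls, f in fracs.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"fraction for {cls} out of [0, 1]: {f}")
        total = sum(fracs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class fractions sum to {total!r}, not 1")
        if self.noise_sd_log2 <= 0:
            raise ValidationError("noise_sd_log2 must be > 0")

    def class_fractions(self) -> dict[str, float]:
        return {cls: getattr(self, f"frac_{cls}") for cls in GENE_CLASSES}

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["age_range_years"] = {k: list(v) for k, v in data["age_range_years"].items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "age_range_years" in data:
            data["age_range_years"] = {k: tuple(v) for k, v in data["age_range_years"].items()}
        return cls(**data)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort.

    ``gene_truth``: per-gene class, baseline_log2 and realized log2 effects
    (effect_dcm, effect_icm, sex_effect, age_effect; null genes are exactly
    zero everywhere). ``sample_truth``: per-sample phenotype, age, sex.
    """

    gene_truth: pd.DataFrame
    sample_truth: pd.DataFrame
    config: SimConfig

    def genes_of_class(self, *classes: str) -> pd.Index:
        unknown = set(classes) - set(GENE_CLASSES)
        if unknown:
            raise ValidationError(f"unknown gene classes: {sorted(unknown)}")
        mask = self.gene_truth["class"].isin(classes)
        return self.gene_truth.index[mask]


def largest_remainder_counts(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Apportion ``n`` items to classes by largest-remainder rounding (exact total)."""
    quotas = {cls: n * f for cls, f in fractions.items()}
    counts = {cls: int(np.floor(q)) for cls, q in quotas.items()}
    shortfall = n - sum(counts.values())
    remainders = sorted(
        quotas, key=lambda cls: (quotas[cls] - counts[cls], cls), reverse=True
    )
    for cls in remainders[:shortfall]:
        counts[cls] += 1
    return counts


def _draw_samples(config: SimConfig, rng: np.random.Generator, suffix: str = "",
                  sizes: dict[str, int] | None = None) -> pd.DataFrame:
    sizes = sizes or {"DCM": config.n_dcm, "ICM": config.n_icm, "NF": config.n_nf}
    rows = []
    # demographics realize the configured ratios exactly: sex counts by
    # rounding, ages on a quantile grid over the cohort range; both shuffled.
    # The stated composition is a study condition, not a sampling target.
    for phen in ("DCM", "ICM", "NF"):
        n = sizes[phen]
        lo, hi = config.age_range_years[phen]
        ages = lo + (hi - lo) * (np.arange(n) + 0.5) / n
        ages = ages[rng.permutation(n)]
        n_male = int(round(config.sex_ratio[phen] * n))
        sexes = np.array(["male"] * n_male + ["female"] * (n - n_male))
        sexes = sexes[rng.permutation(n)]
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{phen}{suffix}{i + 1:03d}",
                    "phenotype": phen,
                    "age": float(ages[i]),
                    "sex": str(sexes[i]),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def _assign_gene_classes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    counts = largest_remainder_counts(config.n_genes, config.class_fractions())
    labels = np.repeat(
        [cls for cls in GENE_CLASSES for _ in range(1)],
        [counts[cls] for cls in GENE_CLASSES],
    )
    labels = labels[rng.permutation(config.n_genes)]
    e = config.effect_size_log2
    gene_ids = [f"G{i + 1:06d}" for i in range(config.n_genes)]
    truth = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    truth["class"] = labels
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    eff_dcm = np.zeros(config.n_genes)
    eff_icm = np.zeros(config.n_genes)
    sex_eff = np.zeros(config.n_genes)
    age_eff = np.zeros(config.n_genes)

    up = labels == "hf_shared_up"
    eff_dcm[up] = e
    eff_icm[up] = e
    down = labels == "hf_shared_down"
    eff_dcm[down] = -e
    eff_icm[down] = -e
    baseline[down] += e  # keep the depleted group near baseline, NF above it
    for cls, eff in (("dcm_specific", eff_dcm), ("icm_specific", eff_icm)):
        mask = labels == cls
        signs = rng.choice([1.0, -1.0], size=int(mask.sum()))
        eff[mask] = signs * e
        idx = np.flatnonzero(mask)
        baseline[idx[signs < 0]] += e
    sex_eff[labels == "sex_linked"] = config.sex_effect_log2
    age_mask = labels == "age_linked"
    age_eff[age_mask] = config.age_effect_log2
    # the youngest cohort sits ~1 SD below the mean standardized age; raise the
    # baseline one age-effect unit so these genes stay in the expressed regime
    baseline[age_mask] += config.age_effect_log2

    truth["baseline_log2"] = baseline
    truth["effect_dcm"] = eff_dcm
    truth["effect_icm"] = eff_icm
    truth["sex_effect"] = sex_eff
    truth["age_effect"] = age_eff
    return truth


def _render_matrix(
    gene_truth: pd.DataFrame,
    samples: pd.DataFrame,
    noise_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    male = (samples["sex"] == "male").to_numpy(float)
    age = samples["age"].to_numpy(float)
    zage = (age - age.mean()) / age.std()
    disease_effect = np.zeros((len(gene_truth), len(samples)))
    phen = samples["phenotype"].to_numpy()
    disease_effect[:, phen == "DCM"] = gene_truth["effect_dcm"].to_numpy()[:, None]
    disease_effect[:, phen == "ICM"] = gene_truth["effect_icm"].to_numpy()[:, None]
    log2m = (
        gene_truth["baseline_log2"].to_numpy()[:, None]
        + disease_effect
        + gene_truth["sex_effect"].to_numpy()[:, None] * male[None, :]
        + gene_truth["age_effect"].to_numpy()[:, None] * zage[None, :]
        + rng.normal(0.0, noise_sd, (len(gene_truth), len(samples)))
    )
    rpkm = np.maximum(np.exp2(log2m) - 1.0, 0.0)
    return pd.DataFrame(rpkm, index=gene_truth.index, columns=samples.index)


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (expression matrix, sample table, truth) for one cohort.

    Deterministic given ``config.seed``: identical configs give bit-identical
    matrices.
    """
    rng = np.random.default_rng(config.seed)
    samples = _draw_samples(config, rng)
    gene_truth = _assign_gene_classes(config, rng)
    matrix = _render_matrix(gene_truth, samples, config.noise_sd_log2, rng)
    validate_expression(matrix)
    return matrix, samples, SyntheticTruth(gene_truth, samples, config)


def generate_external_dataset(
    truth: SyntheticTruth,
    platform: str = "rnaseq",
    distortion_seed: int = 0,
    n_dcm: int = 13,
    n_icm: int = 13,
    n_nf: int = 10,
    probe_fraction: float = 0.3,
    gamma_range: tuple[float, float] = (0.8, 1.3),
    scale_sigma: float = 0.3,
    affinity_sigma: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Replication cohort drawn from the same gene-class model.

    ``platform='rnaseq'`` returns undistorted RPKM-scale values.
    ``platform='microarray'`` applies a strictly monotone per-sample
    transform (``scale * x**gamma``) and expands ``probe_fraction`` of genes
    into two probes with probe-specific affinities.

    Returns ``(matrix, sample_table, probe_map)`` where ``probe_map`` maps
    each matrix row id to its parent gene id (identity for rnaseq).
    """
    if platform not in ("rnaseq", "microarray"):
        raise ValidationError(f"unknown platform {platform!r}")
    config = truth.config
    rng = np.random.default_rng(distortion_seed)
    samples = _draw_samples(
        config, rng, suffix="X", sizes={"DCM": n_dcm, "ICM": n_icm, "NF": n_nf}
    )
    matrix = _render_matrix(truth.gene_truth, samples, config.noise_sd_log2, rng)
    if platform == "rnaseq":
        probe_map = pd.Series(matrix.index, index=matrix.index, name="gene_id")
        return matrix, samples, probe_map

    gammas = rng.uniform(*gamma_range, size=matrix.shape[1])
    scales = np.exp(rng.normal(0.0, scale_sigma, size=matrix.shape[1]))
    distorted = scales[None, :] * np.power(matrix.to_numpy(), gammas[None, :])
    matrix = pd.DataFrame(distorted, index=matrix.index, columns=matrix.columns)

    n_multi = int(round(probe_fraction * len(matrix)))
    multi = pd.Index(rng.choice(matrix.index.to_numpy(), size=n_multi, replace=False))
    rows, probe_ids, parents = [], [], []
    for gene in matrix.index:
        n_probes = 2 if gene in set(multi) else 1
        for j in range(n_probes):
            affinity = float(np.exp(rng.normal(0.0, affinity_sigma))) if n_probes > 1 else 1.0
            rows.append(matrix.loc[gene].to_numpy() * affinity)
            probe_ids.append(f"{gene}_p{j + 1}")
            parents.append(gene)
    probe_matrix = pd.DataFrame(
        np.vstack(rows), index=pd.Index(probe_ids, name="probe_id"), columns=matrix.columns
    )
    probe_map = pd.Series(parents, index=probe_matrix.index, name="gene_id")
    return probe_matrix, samples, probe_map


#: per-phenotype comorbidity rates; DCM/ICM rates follow the study cohort's
#: clinical characteristics table (statins 27%/92%, CAD 11%/100%,
#: diabetes 16%/62%, hyperlipidemia 22%/69%); NF donors lack clinical records
#: so their rates default to 0.
DEFAULT_COMORBIDITY_RATES: dict[str, dict[str, float]] = {
    "statins": {"DCM": 0.27, "ICM": 0.92, "NF": 0.0},
    "coronary_artery_disease": {"DCM": 0.11, "ICM": 1.0, "NF": 0.0},
    "diabetes": {"DCM": 0.16, "ICM": 0.62, "NF": 0.0},
    "hyperlipidemia": {"DCM": 0.22, "ICM": 0.69, "NF": 0.0},
}


def generate_clinical_table(
    config: SimConfig,
    comorbidity_rates: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Sample table with binary clinical fields drawn per phenotype at stated rates."""
    rates = comorbidity_rates if comorbidity_rates is not None else DEFAULT_COMORBIDITY_RATES
    for field_name, per_phen in rates.items():
        for phen, r in per_phen.items():
            if not 0.0 <= r <= 1.0:
                raise ValidationError(f"rate for {field_name}/{phen} out of [0, 1]: {r}")
    rng = np.random.default_rng(config.seed)
    samples = _draw_samples(config, rng)
    for field_name, per_phen in rates.items():
        p = samples["phenotype"].map(lambda ph: per_phen.get(ph, 0.0)).to_numpy(float)
        samples[field_name] = rng.random(len(samples)) < p
    return samples


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    truth.gene_truth.to_csv(path, sep="\t", index_label="gene_id")
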