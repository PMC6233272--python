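"""Cohort-characteristics statistics and run-level summary reports.

Binary clinical characteristics are compared between groups with Fisher's
exact test on the 2x2 table; ordinal/continuous characteristics with a
two-sided Mann-Whitney U test (exact when the combined sample is small and
tie-free, normal approximation with tie and continuity correction
otherwise). Missing values are excluded per characteristic and counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

SCHEMA_VERSION = 1
#: combined-n cutoff below which the Mann-Whitney p is computed exactly
EXACT_MWU_MAX_N = 20


def _is_binary(values: pd.Series) -> bool:
    if values.dtype == bool:
        return True
    uniq = set(pd.unique(values.dropna()))
    return uniq <= {0, 1, True, False} and len(uniq) > 0


@dataclass
class CohortComparison:
    """Per-characteristic two-group comparison (test, statistic, p, summaries)."""

    table: pd.DataFrame
    groups: tuple[str, str]


def compare_cohorts(
    table: pd.DataFrame,
    characteristics: list[str],
    groups: tuple[str, str] = ("DCM", "ICM"),
) -> CohortComparison:
    """Reproduce a clinical-characteristics comparison between two cohorts."""
    g1, g2 = groups
    phen = table["phenotype"]
    present = set(phen.unique())
    if not {g1, g2} <= present:
        raise ValidationError(f"groups {groups} not both present (have {sorted(present)})")
    rows = []
    for char in characteristics:
        if char not in table.columns:
            raise ValidationError(f"characteristic {char!r} absent from sample table")
        values = table[char]
        a = values[phen == g1].dropna()
        b = values[phen == g2].dropna()
        n_missing = int(values[phen.isin(groups)].isna().sum())
        row: dict = {
            "characteristic": char,
            f"n_{g1}": len(a),
            f"n_{g2}": len(b),
            "n_missing": n_missing,
        }
        if _is_binary(values):
            a_yes, b_yes = int(a.astype(bool).sum()), int(b.astype(bool).sum())
            ct = [[a_yes, len(a) - a_yes], [b_yes, len(b) - b_yes]]
            odds, p = stats.fisher_exact(ct, alternative="two-sided")
            row.update(
                test="fisher_exact",
                statistic=float(odds),
                p=float(p),
                **{
                    f"summary_{g1}": f"{a_yes} ({100 * a_yes / len(a):.0f}%)" if len(a) else "0",
                    f"summary_{g2}": f"{b_yes} ({100 * b_yes / len(b):.0f}%)" if len(b) else "0",
                },
            )
        else:
            a_num = pd.to_numeric(a, errors="raise")
            b_num = pd.to_numeric(b, errors="raise")
            pooled = np.concatenate([a_num, b_num])
            no_ties = len(np.unique(pooled)) == len(pooled)
            method = "exact" if (len(pooled) <= EXACT_MWU_MAX_N and no_ties) else "asymptotic"
            u, p = stats.mannwhitneyu(
                a_num, b_num, alternative="two-sided", method=method, use_continuity=True
            )
            row.update(
                test="mann_whitney",
                statistic=float(u),
                p=float(p),
                **{
                    f"summary_{g1}": f"{a_num.mean():.1f} ± {a_num.std(ddof=1):.1f}",
                    f"summary_{g2}": f"{b_num.mean():.1f} ± {b_num.std(ddof=1):.1f}",
                },
            )
        rows.append(row)
    return CohortComparison(table=pd.DataFrame(rows).set_index("characteristic"), groups=groups)


def run_report(
    deg_results: dict[str, pd.DataFrame] | None = None,
    signatures=None,
    concordance: dict | None = None,
    permutations: dict | None = None,
    segregation: dict | None = None,
    cohort_comparison: CohortComparison | None = None,
) -> dict:
    """Collate stage outputs into a schema-versioned summary dictionary.

    Optional stages that were not run appear as null. When both DEG results
    and signatures are given, the partition identities
    |vs-NF DEGs| = |HF| + |disease-specific| are asserted.
    """
    report: dict = {"schema_version": SCHEMA_VERSION}
    if deg_results is not None:
        report["deg_counts"] = {
            label: int(res["is_deg"].sum()) for label, res in deg_results.items()
        }
    else:
        report["deg_counts"] = None
    if signatures is not None:
        summary = signatures.summary()
        report["signatures"] = summary
        if deg_results is not None:
            for label, specific in (("DCM_vs_NF", "dcm_specific"), ("ICM_vs_NF", "icm_specific")):
                if label in report["deg_counts"]:
                    expected = summary["hf"]["n"] + summary[specific]["n"]
                    if report["deg_counts"][label] != expected:
                        raise ValidationError(
                            f"partition identity violated for {label}: "
                            f"{report['deg_counts'][label]} != {expected}"
                        )
    else:
        report["signatures"] = None
    report["concordance"] = concordance
    report["permutations"] = (
        {label: dist.summary() for label, dist in permutations.items()}
        if permutations is not None
        else None
    )
    report["segregation"] = (
        {name: rep.to_dict() for name, rep in segregation.items()}
        if segregation is not None
        else None
    )
    report["cohort_comparison"] = (
        cohort_comparison.table.reset_index().to_dict(orient="records")
        if cohort_comparison is not None
        else None
    )
    return report


def report_to_markdown(report: dict) -> str:
    lines = ["# Run summary", ""]
    if report.get("deg_counts"):
        lines.append("## DEG counts")
        for label, n in report["deg_counts"].items():
            lines.append(f"- {label}: {n}")
        lines.append("")
    if report.get("signatures"):
        lines.append("## Signature partition")
        for name, s in report["signatures"].items():
            lines.append(f"- {name}: {s['n']} ({s['up']} up, {s['down']} down)")
        lines.append("")
    if report.get("concordance"):
        c = report["concordance"]
        lines.append("## HF signature concordance")
        lines.append(f"- direction concordance: {c['direction_concordance']:.3f}")
        lines.append(f"- log-mean R²: {c['log_mean_r2']:.3f}")
        lines.append("")
    if report.get("permutations"):
        lines.append("## Permutation null")
        for label, s in report["permutations"].items():
            lines.append(
                f"- {label}: observed {s['observed']} vs null M={s['mean']:.2f}, "
                f"SD={s['sd']:.2f}, max={s['max']}, p {s['p_report']}"
            )
        lines.append("")
    if report.get("segregation"):
        lines.append("## Signature classification")
        for name, s in report["segregation"].items():
            per = ", ".join(
                f"{ph} {v['n_correct']}/{v['n_total']}" for ph, v in s["per_phenotype"].items()
            )
            lines.append(f"- {name}: accuracy {s['accuracy']:.2f} ({per})")
        lines.append("")
    return "\n".join(lines)


def write_report(report: dict, json_path: str | Path, markdown_path: str | Path | None = None) -> None:
    Path(json_path).write_text(json.dumps(report, indent=2, default=str))
    if markdown_path is not None:
        Path(markdown_path).write_text(report_to_markdown(report))
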