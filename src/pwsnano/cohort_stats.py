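"""Patient-level aggregation and two-group cohort comparison of L_d.

The statistical unit is the patient: nucleus-level disorder strengths are
averaged per patient, and diagnostic groups are contrasted by

    effect size = |mean_A - mean_B| / s,

where s is, by default, the sample SD of the *combined* patient values (the
"cumulative SD" convention); the classical pooled within-group SD (Cohen's d
denominator) is available as an alternative.  Significance comes from a
two-sided Welch t-test by default, Mann-Whitney U as an option.  Effect sizes
are stored as fractions and rendered as percentages in reports, so 1.04 is
printed as 104.  Because effect sizes are invariant under common affine
rescaling of all values, arbitrary-unit L_d suffices for every cohort claim.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PatientSummary",
    "GroupComparison",
    "effect_size",
    "compare_groups",
    "correlate_compartments",
    "cohort_report",
    "summaries_to_frame",
    "frame_to_summaries",
]


@dataclass(frozen=True)
class PatientSummary:
    """Per-patient aggregate over segmented nuclei."""

    patient_id: str
    group: str
    mean_nuclear_ld: float
    mean_cellular_ld: float | None = None
    n_nuclei: int = 1

    def __post_init__(self) -> None:
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if not np.isfinite(self.mean_nuclear_ld):
            raise ValueError("mean_nuclear_ld must be finite")


@dataclass(frozen=True)
class GroupComparison:
    """Result of one two-group contrast on patient-level means."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    effect_size_fraction: float
    sd_convention: str
    p_value: float
    test: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")
        if self.effect_size_fraction < 0:
            raise ValueError("effect size is reported as an absolute value")


def effect_size(a, b, sd_convention: str = "cumulative") -> float:
    """|mean(a) - mean(b)| divided by the chosen SD.

    ``cumulative`` (default): sample SD (ddof=1) of the concatenated values.
    ``pooled_within``: classical pooled within-group SD.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if sd_convention == "cumulative":
        s = float(np.std(np.concatenate([a, b]), ddof=1))
    elif sd_convention == "pooled_within":
        s = float(
            np.sqrt(
                ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1))
                / (a.size + b.size - 2)
            )
        )
    else:
        raise ValueError(f"unknown sd_convention {sd_convention!r}")
    if s == 0.0:
        raise ValueError("zero SD: effect size undefined for identical values")
    return float(abs(a.mean() - b.mean()) / s)


def compare_groups(
    summaries: list[PatientSummary],
    group_a: str,
    group_b: str,
    test: str = "welch_t",
    sd_convention: str = "cumulative",
) -> GroupComparison:
    """Contrast two diagnostic groups on patient-level mean nuclear L_d."""
    by_group: dict[str, list[float]] = {}
    for s in summaries:
        by_group.setdefault(s.group, []).append(s.mean_nuclear_ld)
    for g in (group_a, group_b):
        if g not in by_group:
            raise ValueError(f"unknown group {g!r}; available groups: {sorted(by_group)}")
        if len(by_group[g]) < 2:
            raise ValueError(f"group {g!r} has {len(by_group[g])} patient(s); need >= 2")
    a = np.asarray(by_group[group_a])
    b = np.asarray(by_group[group_b])
    es = effect_size(a, b, sd_convention)
    if test == "welch_t":
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    elif test == "mann_whitney":
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=int(a.size),
        n_b=int(b.size),
        effect_size_fraction=es,
        sd_convention=sd_convention,
        p_value=p,
        test=test,
    )


def correlate_compartments(summaries: list[PatientSummary]) -> float:
    """Pearson correlation of nuclear vs cellular patient means."""
    pairs = [
        (s.mean_nuclear_ld, s.mean_cellular_ld)
        for s in summaries
        if s.mean_cellular_ld is not None and np.isfinite(s.mean_cellular_ld)
    ]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 patients with both compartment means, got {len(pairs)}")
    nuc, cell = np.asarray(pairs).T
    return float(stats.pearsonr(nuc, cell).statistic)


def _fmt_pct(fraction: float) -> str:
    return f"{fraction * 100:.6g}"


def cohort_report(comparisons: list[GroupComparison], out_path) -> Path:
    """Write a summary-table CSV: one row per contrast, effect size in percent."""
    if not comparisons:
        raise ValueError("no comparisons to report")
    rows = [
        {
            "contrast": f"{c.group_a} vs {c.group_b}",
            "effect_size_pct": _fmt_pct(c.effect_size_fraction),
            "p_value": c.p_value,
            "n_patients": c.n_a + c.n_b,
            "n_a": c.n_a,
            "n_b": c.n_b,
            "test": c.test,
            "sd_convention": c.sd_convention,
        }
        for c in comparisons
    ]
    out_path = Path(out_path)
    pd.DataFrame(rows).to_csv(out_path, index=False)
    return out_path


def summaries_to_frame(summaries: list[PatientSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in summaries],
            "group": [s.group for s in summaries],
            "mean_nuclear_ld": [s.mean_nuclear_ld for s in summaries],
            "mean_cellular_ld": [s.mean_cellular_ld for s in summaries],
            "n_nuclei": [s.n_nuclei for s in summaries],
        }
    )


def frame_to_summaries(df: pd.DataFrame) -> list[PatientSummary]:
    out = []
    for row in df.itertuples(index=False):
        cell = getattr(row, "mean_cellular_ld", None)
        if cell is not None and not np.isfinite(cell):
            cell = None
        out.append(
            PatientSummary(
                patient_id=str(row.patient_id),
                group=str(row.group),
                mean_nuclear_ld=float(row.mean_nuclear_ld),
                mean_cellular_ld=None if cell is None else float(cell),
                n_nuclei=int(getattr(row, "n_nuclei", 1)),
            )
        )
    return out
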