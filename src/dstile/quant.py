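"""Relative-expression quantification and knockdown statistics.

Implements 2^-ddCt relative expression against a reference gene and a
calibrator group, amplification-efficiency estimation from standard-curve
slopes, an efficiency-corrected (Pfaffl-style) fold mode, and
normality-gated two-group comparison (Shapiro-Wilk, then unpaired t-test
or Mann-Whitney U).

Fold summaries are computed on the cycle (log2) scale: the reported
``mean_fold`` is 2 to the minus mean ddCt, i.e. the geometric mean of the
per-replicate folds.  This makes the calibrator group's mean fold exactly
1 by construction and keeps the estimator unbiased on the log scale; the
arithmetic mean of the per-replicate folds is reported alongside.  CI95 is
Student-t on the ddCt scale, transformed back (asymmetric around the mean
in general, but always containing it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence as TSequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CqRecord",
    "StandardCurve",
    "ExpressionResult",
    "GroupComparison",
    "read_cq_table",
    "write_cq_table",
    "fit_standard_curve",
    "delta_delta_ct",
    "compare_groups",
]

CQ_COLUMNS = ("sample", "group", "gene", "replicate", "cq")


@dataclass(frozen=True)
class CqRecord:
    """One quantification-cycle measurement."""

    sample_id: str
    group: str
    gene: str
    replicate: int
    cq: float

    def __post_init__(self) -> None:
        if self.cq <= 0:
            raise ValueError(
                f"cq must be positive (sample {self.sample_id!r}, gene {self.gene!r})"
            )


@dataclass(frozen=True)
class StandardCurve:
    """Dilution-series fit: cq regressed on log10 template amount."""

    gene: str
    slope: float
    intercept: float
    r2: float
    efficiency: float
    n_points: int
    valid: bool


@dataclass(frozen=True)
class ExpressionResult:
    """Relative expression of one gene in one group vs a calibrator group."""

    gene: str
    group: str
    calibrator_group: str
    per_replicate_folds: tuple[float, ...]
    mean_fold: float
    arith_mean_fold: float
    sem: float
    ci95: tuple[float, float]
    percent_of_control: float
    percent_of_control_ratio: float
    n: int
    efficiency_corrected: bool = False


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of a normality-gated two-group test."""

    n_a: int
    n_b: int
    normality_p_a: float
    normality_p_b: float
    test_used: str  # "t_test" | "mann_whitney"
    statistic: float
    p_value: float
    significant: bool
    degenerate: bool = False
    alpha: float = 0.05


def read_cq_table(path) -> list[CqRecord]:
    """Read a delimited Cq table with header sample,group,gene,replicate,cq.

    Comma- and tab-separated files are both accepted.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in CQ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    records = [
        CqRecord(
            sample_id=str(row["sample"]),
            group=str(row["group"]),
            gene=str(row["gene"]),
            replicate=int(row["replicate"]),
            cq=float(row["cq"]),
        )
        for row in df.to_dict("records")
    ]
    seen = set()
    for r in records:
        key = (r.sample_id, r.gene, r.replicate)
        if key in seen:
            raise ValueError(f"{path}: duplicate (sample, gene, replicate) {key}")
        seen.add(key)
    return records


def write_cq_table(records: Iterable[CqRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(CQ_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.sample_id},{r.group},{r.gene},{r.replicate},{r.cq:.6f}\n"
            )


def fit_standard_curve(
    points: TSequence[tuple[float, float]], gene: str = ""
) -> StandardCurve:
    """Least-squares fit of cq on log10 template amount; E = 10^(-1/slope).

    Requires at least 3 points over at least 2 distinct dilutions.  A zero
    slope leaves the efficiency undefined and is an error; a positive
    slope or an efficiency outside (1, 2.5] is flagged invalid rather than
    rejected.
    """
    if len(points) < 3:
        raise ValueError("standard curve needs at least 3 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("standard curve needs at least 2 distinct dilutions")
    fit = stats.linregress(x, y)
    if fit.slope == 0:
        raise ValueError("invalid standard curve: zero slope")
    efficiency = 10.0 ** (-1.0 / fit.slope)
    valid = fit.slope < 0 and 1.0 < efficiency <= 2.5
    return StandardCurve(
        gene=gene,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        efficiency=float(efficiency),
        n_points=len(points),
        valid=valid,
    )


def _cq_by_sample(records: Iterable[CqRecord], group: str, gene: str) -> dict[str, float]:
    """Mean cq per sample for one (group, gene); technical replicates
    (repeated rows for the same sample and gene) are averaged."""
    acc: dict[str, list[float]] = {}
    for r in records:
        if r.group == group and r.gene == gene:
            acc.setdefault(r.sample_id, []).append(r.cq)
    return {s: float(np.mean(v)) for s, v in acc.items()}


def delta_delta_ct(
    records: TSequence[CqRecord],
    gene: str,
    reference_gene: str,
    group: str,
    calibrator_group: str,
    efficiencies: Optional[Mapping[str, float]] = None,
) -> ExpressionResult:
    """Relative expression of ``gene`` in ``group`` vs ``calibrator_group``.

    Per replicate sample, dCt = Cq_gene - Cq_reference; ddCt subtracts the
    calibrator group's mean dCt; fold = 2^-ddCt.  When ``efficiencies``
    maps both genes to amplification factors, the efficiency-corrected
    (Pfaffl) ratio E_gene^dCt_gene / E_ref^dCt_ref is used instead, with
    each gene's dCt taken against the calibrator-group mean Cq of that
    gene.  Both coincide when every efficiency is exactly 2.
    """
    out: dict[str, dict[str, dict[str, float]]] = {}
    for grp in (group, calibrator_group):
        grp_data = {}
        for g in (gene, reference_gene):
            grp_data[g] = _cq_by_sample(records, grp, g)
        samples = sorted(grp_data[gene])
        if not samples:
            raise ValueError(f"no cq records for gene {gene!r} in group {grp!r}")
        for s in samples:
            if s not in grp_data[reference_gene]:
                raise ValueError(
                    f"sample {s!r} (group {grp!r}) has no cq for reference "
                    f"gene {reference_gene!r}"
                )
        out[grp] = grp_data

    def dcts(grp: str) -> np.ndarray:
        data = out[grp]
        return np.array(
            [data[gene][s] - data[reference_gene][s] for s in sorted(data[gene])]
        )

    cal_dct = dcts(calibrator_group)
    grp_dct = dcts(group)

    if efficiencies is not None:
        try:
            e_g = float(efficiencies[gene])
            e_r = float(efficiencies[reference_gene])
        except KeyError as exc:
            raise ValueError(f"no efficiency supplied for gene {exc.args[0]!r}")
        if e_g <= 1 or e_r <= 1:
            raise ValueError("efficiencies must be > 1")
        cal = out[calibrator_group]
        cal_mean_g = float(np.mean([cal[gene][s] for s in sorted(cal[gene])]))
        cal_mean_r = float(
            np.mean([cal[reference_gene][s] for s in sorted(cal[reference_gene])])
        )
        data = out[group]
        samples = sorted(data[gene])
        folds = np.array(
            [
                e_g ** (cal_mean_g - data[gene][s])
                / e_r ** (cal_mean_r - data[reference_gene][s])
                for s in samples
            ]
        )
        log2_folds = np.log2(folds)
        corrected = True
    else:
        ddct = grp_dct - float(np.mean(cal_dct))
        folds = 2.0 ** (-ddct)
        log2_folds = -ddct
        corrected = False

    n = folds.size
    mean_log2 = float(np.mean(log2_folds))
    mean_fold = float(2.0**mean_log2)
    arith_mean = float(np.mean(folds))
    if n >= 2:
        sem = float(np.std(folds, ddof=1) / math.sqrt(n))
        sem_log2 = float(np.std(log2_folds, ddof=1) / math.sqrt(n))
        tcrit = float(stats.t.ppf(0.975, n - 1))
        ci95 = (
            float(2.0 ** (mean_log2 - tcrit * sem_log2)),
            float(2.0 ** (mean_log2 + tcrit * sem_log2)),
        )
    else:
        sem = float("nan")
        ci95 = (float("nan"), float("nan"))

    # ratio of group mean linear quantities (secondary summary)
    rel_grp = np.mean(2.0 ** (-grp_dct))
    rel_cal = np.mean(2.0 ** (-cal_dct))
    ratio_pct = float(rel_grp / rel_cal * 100.0)

    return ExpressionResult(
        gene=gene,
        group=group,
        calibrator_group=calibrator_group,
        per_replicate_folds=tuple(float(f) for f in folds),
        mean_fold=mean_fold,
        arith_mean_fold=arith_mean,
        sem=sem,
        ci95=ci95,
        percent_of_control=mean_fold * 100.0,
        percent_of_control_ratio=ratio_pct,
        n=int(n),
        efficiency_corrected=corrected,
    )


def compare_groups(
    folds_a: TSequence[float],
    folds_b: TSequence[float],
    alpha: float = 0.05,
) -> GroupComparison:
    """Normality-gated two-group comparison.

    Shapiro-Wilk is run on each group; when both retain normality at
    ``alpha`` the unpaired two-sided Student's t-test (equal variances) is
    used, otherwise the two-sided Mann-Whitney U test.  A constant-valued
    group leaves Shapiro-Wilk undefined; the comparison falls back to
    Mann-Whitney and is flagged degenerate.
    """
    a = np.asarray(folds_a, dtype=float)
    b = np.asarray(folds_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")

    degenerate = bool(np.ptp(a) == 0 or np.ptp(b) == 0)
    if degenerate:
        p_a = p_b = float("nan")
    else:
        p_a = float(stats.shapiro(a).pvalue)
        p_b = float(stats.shapiro(b).pvalue)

    if not degenerate and p_a >= alpha and p_b >= alpha:
        test_used = "t_test"
        res = stats.ttest_ind(a, b, equal_var=True)
        statistic, p_value = float(res.statistic), float(res.pvalue)
    else:
        test_used = "mann_whitney"
        if np.ptp(np.concatenate([a, b])) == 0:
            # all observations identical: no evidence of difference
            statistic, p_value = float(a.size * b.size / 2.0), 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            statistic, p_value = float(res.statistic), float(res.pvalue)

    return GroupComparison(
        n_a=int(a.size),
        n_b=int(b.size),
        normality_p_a=p_a,
        normality_p_b=p_b,
        test_used=test_used,
        statistic=statistic,
        p_value=p_value,
        significant=bool(p_value < alpha),
        degenerate=degenerate,
        alpha=alpha,
    )
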