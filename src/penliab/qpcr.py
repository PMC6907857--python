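"""Comparative-Ct (2^-ddCt) qPCR quantification with standard-curve QC.

Relative expression follows the comparative-Ct method: technical replicates
are averaged per (sample, gene); dCt = target Ct - reference Ct per
biological sample; ddCt = mean dCt(comparison) - mean dCt(calibrator); and
the fold change is 2^-ddCt.  Primer pairs are accepted only when their
standard-curve slope falls inside the configured window (default -3.3 +/- 0.3
Ct per decade, i.e. near-perfect doubling).  Group tests operate on the
per-sample dCt values (the log scale), with pairwise t-tests and Tukey's
honestly-significant-difference adjustment across the declared group family.
Efficiency is reported for QC but never used to correct folds.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CtTable
from .errors import DesignError, PowerError, ValidationError

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "FoldChange",
    "compute_relative_expression",
    "compare_expression_groups",
]


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of mean Ct on log10 template quantity for one primer pair."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    accepted: bool
    points: tuple[tuple[float, float], ...]  # (log10 quantity, mean Ct)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "r_squared": self.r_squared,
                    "efficiency": self.efficiency,
                    "accepted": self.accepted,
                }
            ]
        )


def fit_standard_curve(
    dilution_series: Sequence[tuple[float, Sequence[float]]],
    window: tuple[float, float] = (-3.3, 0.3),
) -> StandardCurve:
    """Fit a standard curve to a dilution series.

    ``dilution_series`` is a list of (relative quantity, replicate Cts);
    replicates are averaged per point before the ordinary least-squares fit
    of mean Ct on log10(quantity).  Amplification efficiency is
    10^(-1/slope) - 1 (1.0 = perfect doubling) and the curve is accepted iff
    |slope - center| <= half-width.
    """
    center, halfwidth = window
    if halfwidth <= 0:
        raise ValidationError(f"window half-width must be positive, got {halfwidth}")
    quantities = [q for q, _ in dilution_series]
    if any(q <= 0 for q in quantities):
        raise ValidationError(f"quantities must be positive: {quantities}")
    distinct = sorted(set(quantities))
    if len(distinct) < 3:
        raise DesignError(
            f"need >= 3 distinct quantities for a standard curve, got {len(distinct)}"
        )
    if distinct[-1] / distinct[0] < 10:
        warnings.warn(
            "dilution series spans less than one decade; the slope estimate "
            "may be unstable",
            stacklevel=2,
        )
    logq = np.log10(np.asarray(quantities, dtype=float))
    mean_ct = np.asarray([np.mean(cts) for _, cts in dilution_series], dtype=float)
    fit = stats.linregress(logq, mean_ct)
    slope = float(fit.slope)
    efficiency = float(10.0 ** (-1.0 / slope) - 1.0)
    return StandardCurve(
        slope=slope,
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency=efficiency,
        accepted=abs(slope - center) <= halfwidth,
        points=tuple(zip(logq.tolist(), mean_ct.tolist())),
    )


@dataclass(frozen=True)
class FoldChange:
    """Relative expression of one gene in a comparison group vs a calibrator."""

    gene: str
    comparison_group: str
    calibrator_group: str
    delta_ct: dict[str, dict[str, float]]  # group -> sample -> dCt
    ddct: float
    fold: float
    dispersion: float  # SD of per-sample folds in the comparison group
    n_comparison: int
    n_calibrator: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": self.gene,
                    "group": self.comparison_group,
                    "calibrator": self.calibrator_group,
                    "ddct": self.ddct,
                    "fold": self.fold,
                    "sd": self.dispersion,
                    "n": self.n_comparison,
                }
            ]
        )


def _delta_ct_by_sample(ct: CtTable, gene: str, reference: str, group: str) -> dict[str, float]:
    """Per-sample dCt (gene mean Ct - reference mean Ct) within one group."""
    means = ct.replicate_means()
    sub = means[means["group"] == group]
    if sub.empty:
        raise ValidationError(f"group {group!r} has no rows")
    out: dict[str, float] = {}
    for sample, block in sub.groupby("sample_id"):
        genes = dict(zip(block["gene"], block["ct"]))
        if gene not in genes:
            continue
        if reference not in genes:
            raise ValidationError(
                f"sample {sample!r} lacks reference gene {reference!r}"
            )
        out[str(sample)] = float(genes[gene] - genes[reference])
    if not out:
        raise ValidationError(f"group {group!r} has no sample with gene {gene!r}")
    return out


def compute_relative_expression(
    ct: CtTable,
    gene: str,
    reference: str,
    calibrator_group: str,
    comparison_group: str,
) -> FoldChange:
    """Comparative-Ct fold change of ``gene`` in the comparison group.

    Technical replicates are averaged before dCt; the biological unit is the
    (pooled) sample.  Dispersion is the SD of per-sample folds
    2^-(dCt - mean calibrator dCt) in the comparison group.
    """
    dct_cal = _delta_ct_by_sample(ct, gene, reference, calibrator_group)
    dct_cmp = _delta_ct_by_sample(ct, gene, reference, comparison_group)
    mean_cal = float(np.mean(list(dct_cal.values())))
    mean_cmp = float(np.mean(list(dct_cmp.values())))
    ddct = mean_cmp - mean_cal
    per_sample_folds = [2.0 ** -(v - mean_cal) for v in dct_cmp.values()]
    return FoldChange(
        gene=gene,
        comparison_group=comparison_group,
        calibrator_group=calibrator_group,
        delta_ct={calibrator_group: dct_cal, comparison_group: dct_cmp},
        ddct=float(ddct),
        fold=float(2.0**-ddct),
        dispersion=float(np.std(per_sample_folds, ddof=1)) if len(per_sample_folds) > 1 else 0.0,
        n_comparison=len(dct_cmp),
        n_calibrator=len(dct_cal),
    )


def compare_expression_groups(
    ct: CtTable,
    genes: Sequence[str],
    groups: Sequence[str],
    alpha: float = 0.05,
    *,
    reference: str = "rps18",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Pairwise two-sample t-tests on per-sample dCt with Tukey HSD adjustment.

    For each gene, every pair of declared groups is compared by a two-sided
    t-test on dCt (pooled variance by default; ``equal_var=False`` for
    Welch), and the Tukey honestly-significant-difference procedure across
    the whole group family provides the multiplicity-adjusted p.  Returns one
    row per (gene, group pair).
    """
    if len(groups) < 2:
        raise DesignError("need at least two groups to compare")
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rows = []
    for gene in genes:
        dct = {g: _delta_ct_by_sample(ct, gene, reference, g) for g in groups}
        for g, vals in dct.items():
            if len(vals) < 2:
                raise PowerError(
                    f"group {g!r} has {len(vals)} sample(s) for gene {gene!r}; "
                    "need >= 2"
                )
        values = np.concatenate([np.fromiter(dct[g].values(), float) for g in groups])
        labels = np.concatenate([[g] * len(dct[g]) for g in groups])
        if np.allclose(values, values[0]):
            # degenerate family: no variation at all, nothing to test
            tukey_p = {pair: 1.0 for pair in itertools.combinations(groups, 2)}
        else:
            hsd = pairwise_tukeyhsd(values, labels, alpha=alpha)
            tukey_p = {}
            for (g1, g2), p in zip(
                itertools.combinations(hsd.groupsunique.tolist(), 2), hsd.pvalues
            ):
                tukey_p[(g1, g2)] = float(p)
        for g1, g2 in itertools.combinations(groups, 2):
            x = np.fromiter(dct[g1].values(), float)
            y = np.fromiter(dct[g2].values(), float)
            if np.allclose(x, x[0]) and np.allclose(y, y[0]) and np.isclose(x[0], y[0]):
                t_stat, p_raw = 0.0, 1.0
            else:
                t_stat, p_raw = stats.ttest_ind(x, y, equal_var=equal_var)
            key = (g1, g2) if (g1, g2) in tukey_p else (g2, g1)
            p_tukey = tukey_p[key]
            rows.append(
                {
                    "gene": gene,
                    "group_1": g1,
                    "group_2": g2,
                    "t": float(t_stat),
                    "p_raw": float(p_raw),
                    "p_tukey": p_tukey,
                    "significant": p_tukey <= alpha,
                }
            )
    return pd.DataFrame(rows)
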