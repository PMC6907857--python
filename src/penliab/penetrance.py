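"""Penetrance estimation and group comparison.

Penetrance is the proportion of scored animals of a given genotype that
display a phenotype (binary presence/absence; expressivity and severity are
out of scope).  Groups are compared phenotype-by-phenotype with the
two-sided Fisher's exact test, and the family of p-values across phenotypes
is adjusted for multiplicity (Benjamini-Hochberg FDR or Hochberg step-up).
"""

from __future__ import annotations

import warnings
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .datatypes import AnalysisConfig, GenotypeCall, ScoringTable
from .errors import EstimationError, ValidationError

__all__ = [
    "Selector",
    "select_mask",
    "PenetranceEstimate",
    "estimate_penetrance",
    "ContingencyTable2x2",
    "fisher_exact_2x2",
    "PValueSet",
    "adjust_pvalues",
    "compare_penetrance_groups",
]

#: A group selector: either a boolean-mask callable over the table's
#: DataFrame, or a mapping such as
#: ``{"strain": "low", "generation": 8, "genotype": {"mef2ca": "mut"}}``.
Selector = Callable[[pd.DataFrame], pd.Series] | Mapping[str, object]

_METHOD_CODES = {"benjamini-hochberg": "fdr_bh", "hochberg": "simes-hochberg"}


def select_mask(table: ScoringTable, group: Selector) -> pd.Series:
    """Resolve a selector into a boolean row mask over ``table.data``."""
    df = table.data
    if callable(group):
        mask = pd.Series(np.asarray(group(df), dtype=bool), index=df.index)
        return mask
    mask = pd.Series(True, index=df.index)
    for key, value in group.items():
        if key == "genotype":
            for locus, call in value.items():  # type: ignore[union-attr]
                call = GenotypeCall(call).value
                mask &= df[locus] == call
        elif key in df.columns:
            if isinstance(value, (list, tuple, set)):
                mask &= df[key].isin(list(value))
            else:
                mask &= df[key] == value
        else:
            raise ValidationError(f"selector key {key!r} not in table")
    return mask


@dataclass(frozen=True)
class PenetranceEstimate:
    phenotype: str
    group: str
    affected: int
    scored: int
    proportion: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def estimate_penetrance(
    table: ScoringTable,
    phenotype: str,
    group: Selector,
    alpha: float = 0.05,
    *,
    label: str = "group",
    ci_method: str = "clopper-pearson",
) -> PenetranceEstimate:
    """Penetrance of ``phenotype`` among scored animals selected by ``group``.

    Unscored animals count in neither numerator nor denominator.  The
    confidence interval is the exact Clopper-Pearson interval at 1 - alpha
    by default (``ci_method`` accepts any :func:`proportion_confint` method).
    """
    if phenotype not in table.phenotypes:
        raise ValidationError(f"unknown phenotype {phenotype!r}")
    mask = select_mask(table, group)
    flags = table.data.loc[mask, phenotype]
    scored = flags.dropna()
    n = int(len(scored))
    if n == 0:
        raise EstimationError(
            f"no scored animals for {phenotype!r} in group {label!r}"
        )
    k = int(scored.sum())
    method = "beta" if ci_method == "clopper-pearson" else ci_method
    lo, hi = proportion_confint(k, n, alpha=alpha, method=method)
    return PenetranceEstimate(
        phenotype=phenotype,
        group=label,
        affected=k,
        scored=n,
        proportion=k / n,
        ci_low=float(lo),
        ci_high=float(hi),
        alpha=alpha,
    )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (affected, unaffected) x (group 1, group 2): rows a,b / c,d."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValidationError(f"counts must be non-negative integers: {cells}")
        if sum(cells) == 0:
            raise ValidationError("all four counts are zero")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def has_zero_margin(self) -> bool:
        return 0 in self.margins


def fisher_exact_2x2(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p-value under the probability-mass rule.

    All tables with the observed margins whose hypergeometric probability is
    at most that of the observed table (to within a 1e-7 relative tolerance)
    contribute to p.  A table with an all-zero margin carries no information;
    it returns p = 1.0 with a warning rather than an error.
    """
    if t.has_zero_margin():
        warnings.warn(
            "degenerate 2x2 table (zero margin); returning p = 1.0", stacklevel=2
        )
        return 1.0
    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return float(min(p, 1.0))


@dataclass
class PValueSet:
    labels: list[str]
    raw: np.ndarray
    method: str
    adjusted: np.ndarray | None = None
    alpha: float = 0.05
    significant: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if ((self.raw < 0) | (self.raw > 1)).any() or np.isnan(self.raw).any():
            raise ValidationError("raw p-values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "p_raw": self.raw,
                "p_adjusted": self.adjusted,
                "method": self.method,
                "significant": self.significant,
            }
        )


def adjust_pvalues(pset: PValueSet, method: str | None = None) -> PValueSet:
    """Apply the configured step-up adjustment across one family of tests.

    ``benjamini-hochberg``: adjusted_(i) = min_{j>=i} p_(j) * m / j, clipped
    at 1.  ``hochberg``: adjusted_(i) = min_{j>=i} p_(j) * (m - j + 1),
    clipped at 1.  ``none`` passes raw p-values through.  The original order
    of the family is preserved.
    """
    method = method or pset.method
    raw = pset.raw
    if method == "none":
        adjusted = raw.copy()
    elif method in _METHOD_CODES:
        _, adjusted, _, _ = multipletests(raw, alpha=pset.alpha, method=_METHOD_CODES[method])
    else:
        raise ValidationError(f"unknown adjustment method {method!r}")
    return PValueSet(
        labels=list(pset.labels),
        raw=raw.copy(),
        method=method,
        adjusted=np.asarray(adjusted, dtype=float),
        alpha=pset.alpha,
        significant=np.asarray(adjusted) <= pset.alpha,
    )


def compare_penetrance_groups(
    table: ScoringTable,
    phenotypes: Sequence[str],
    group_a: Selector,
    group_b: Selector,
    config: AnalysisConfig,
    *,
    label_a: str = "group_a",
    label_b: str = "group_b",
) -> pd.DataFrame:
    """Fisher's exact comparison of two groups across a family of phenotypes.

    Returns one row per retained phenotype with counts, proportions, the raw
    p, the family-adjusted p under ``config.multiplicity`` and the
    significance call at ``config.alpha``.  Phenotypes with zero scored
    animals in either group are dropped with a warning; overlapping group
    selectors are an error because each animal must contribute to one margin
    only.
    """
    mask_a = select_mask(table, group_a)
    mask_b = select_mask(table, group_b)
    overlap = mask_a & mask_b
    if overlap.any():
        ids = table.data.loc[overlap, "animal_id"].tolist()
        raise ValidationError(f"groups overlap on animals: {ids[:5]}")

    rows = []
    for phen in phenotypes:
        counts = {}
        skip = False
        for label, mask in ((label_a, mask_a), (label_b, mask_b)):
            flags = table.data.loc[mask, phen].dropna()
            if len(flags) == 0:
                warnings.warn(
                    f"phenotype {phen!r} has no scored animals in {label!r}; dropped",
                    stacklevel=2,
                )
                skip = True
                break
            counts[label] = (int(flags.sum()), int(len(flags)))
        if skip:
            continue
        (ka, na), (kb, nb) = counts[label_a], counts[label_b]
        ct = ContingencyTable2x2(a=ka, b=na - ka, c=kb, d=nb - kb)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = fisher_exact_2x2(ct)
        rows.append(
            {
                "phenotype": phen,
                "group_a_affected": ka,
                "group_a_scored": na,
                "group_a_proportion": ka / na,
                "group_b_affected": kb,
                "group_b_scored": nb,
                "group_b_proportion": kb / nb,
                "p_raw": p,
            }
        )
    if not rows:
        raise EstimationError("no phenotype retained for comparison")
    result = pd.DataFrame(rows)
    pset = adjust_pvalues(
        PValueSet(
            labels=result["phenotype"].tolist(),
            raw=result["p_raw"].to_numpy(),
            method=config.multiplicity,
            alpha=config.alpha,
        )
    )
    result["p_adjusted"] = pset.adjusted
    result["method"] = config.multiplicity
    result["significant"] = pset.significant
    return result
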