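"""Liability-scale transforms and the multiple-threshold model.

Under the liability-threshold model a binary phenotype reflects an unobserved
normally distributed liability: an animal is affected when its liability
exceeds a phenotype-specific threshold.  The observable incidence p of a
population therefore pins down the distance x between the population's mean
liability and the threshold via the probit transform,

    x = Phi^-1(1 - p),

in standard deviations of liability.  Because x is measured from a shared
threshold, the difference in x between two populations equals the difference
of their mean liabilities.  The *multiple-threshold* extension places one
liability distribution per strain against several phenotype thresholds on a
common scale, so a single selection regime shifts every phenotype's
penetrance, each to an extent set by its own threshold.

Incidences of exactly 0 or 1 have an infinite probit; they are replaced by a
finite saturation cap (default 4 SD) and flagged, never silently mixed into
downstream fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import IdentifiabilityError, SaturationError, ValidationError

__all__ = [
    "LiabilityValue",
    "incidence_to_liability",
    "liability_to_incidence",
    "strain_liability_difference",
    "ThresholdModel",
    "fit_multiple_threshold",
    "LiabilityTrajectory",
    "liability_trajectory",
]

DEFAULT_CAP = 4.0


@dataclass(frozen=True)
class LiabilityValue:
    """Distance x from a population's mean liability to a threshold (SD units).

    ``capped`` marks values substituted for the infinite probit of an
    incidence of exactly 0 or 1; for those, |x| equals ``cap`` and x is a
    bound on the distance, not an estimate of it.
    """

    x: float
    incidence: float
    capped: bool = False
    cap: float = DEFAULT_CAP


def incidence_to_liability(
    p: float, cap: float = DEFAULT_CAP, *, continuity: tuple[int, int] | None = None
) -> LiabilityValue:
    """Probit-transform an incidence into a liability distance.

    For p in (0, 1), x = Phi^-1(1 - p).  p = 0 maps to +cap and p = 1 to
    -cap, both flagged as capped.  ``continuity`` optionally supplies the
    raw counts (k, n) to apply the (k + 0.5) / (n + 1) correction before
    transforming (off by default).
    """
    if continuity is not None:
        k, n = continuity
        p = (k + 0.5) / (n + 1)
    if not 0 <= p <= 1 or not np.isfinite(p):
        raise ValidationError(f"incidence must lie in [0, 1], got {p}")
    if cap <= 0:
        raise ValidationError(f"cap must be positive, got {cap}")
    if p == 0.0:
        return LiabilityValue(x=+cap, incidence=0.0, capped=True, cap=cap)
    if p == 1.0:
        return LiabilityValue(x=-cap, incidence=1.0, capped=True, cap=cap)
    return LiabilityValue(x=float(norm.isf(p)), incidence=float(p), capped=False, cap=cap)


def liability_to_incidence(x: float) -> float:
    """Inverse transform: the incidence of a population whose mean liability
    lies ``x`` SD below the threshold is 1 - Phi(x)."""
    if not np.isfinite(x):
        raise ValidationError(f"liability distance must be finite, got {x}")
    return float(norm.sf(x))


def strain_liability_difference(
    x_a: LiabilityValue, x_b: LiabilityValue, *, allow_capped: bool = False
) -> float:
    """Difference of population mean liabilities for a shared threshold.

    Returns x_a.x - x_b.x; positive when population a's mean lies below
    population b's (a is less affected).  Capped inputs are bounds, not
    estimates, so they raise unless explicitly overridden.
    """
    if (x_a.capped or x_b.capped) and not allow_capped:
        raise SaturationError(
            "capped liability value: the distance is a bound, not an estimate; "
            "pass allow_capped=True to compare bounds anyway"
        )
    return float(x_a.x - x_b.x)


@dataclass
class ThresholdModel:
    """Least-squares multiple-threshold fit on one common liability scale.

    Each included cell (strain s, phenotype k) contributes the observation
    x_obs = T_k - mu_s; one strain mean (the anchor) is fixed at 0 because
    only differences of means are identifiable.
    """

    strain_means: dict[str, float]
    thresholds: dict[str, float]
    residuals: pd.DataFrame
    anchor: str
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def predicted(self, strain: str, phenotype: str) -> float:
        return self.thresholds[phenotype] - self.strain_means[strain]

    def mean_separation(self, strain_a: str, strain_b: str) -> float:
        """mu_a - mu_b on the fitted liability scale."""
        return self.strain_means[strain_a] - self.strain_means[strain_b]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"parameter": f"mean[{s}]", "value": v} for s, v in self.strain_means.items()
        ] + [
            {"parameter": f"threshold[{k}]", "value": v}
            for k, v in self.thresholds.items()
        ]
        return pd.DataFrame(rows)


def _connected(cells: Sequence[tuple[str, str]]) -> list[set[str]]:
    """Connected components of the bipartite strain/phenotype design graph.

    Strains are tagged ``s:`` and phenotypes ``k:`` so the two name spaces
    cannot collide.
    """
    adj: dict[str, set[str]] = {}
    for s, k in cells:
        a, b = f"s:{s}", f"k:{k}"
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen: set[str] = set()
    components = []
    for node in adj:
        if node in seen:
            continue
        stack, comp = [node], set()
        while stack:
            cur = stack.pop()
            if cur in comp:
                continue
            comp.add(cur)
            stack.extend(adj[cur] - comp)
        seen |= comp
        components.append(comp)
    return components


def fit_multiple_threshold(
    x_matrix: Mapping[tuple[str, str], LiabilityValue],
    anchor: str,
    include_capped: bool = False,
) -> ThresholdModel:
    """Fit strain means and phenotype thresholds to observed liability distances.

    ``x_matrix`` maps (strain, phenotype) to the observed
    :class:`LiabilityValue`.  Capped cells are excluded by default (and
    reported in ``excluded``); include them only to obtain a deliberately
    conservative bound-contaminated fit.  Raises
    :class:`IdentifiabilityError` when the included design graph is
    disconnected, because strain means in separate components share no
    threshold and cannot be placed on one scale.
    """
    included = {
        cell: lv
        for cell, lv in x_matrix.items()
        if include_capped or not lv.capped
    }
    excluded = [cell for cell, lv in x_matrix.items() if cell not in included]
    if not included:
        raise ValidationError("no cells left to fit after exclusions")
    strains = sorted({s for s, _ in included})
    phenotypes = sorted({k for _, k in included})
    if anchor not in strains:
        raise ValidationError(f"anchor strain {anchor!r} has no included cell")
    if len({s for s, _ in x_matrix}) < 2 or len(phenotypes) < 1:
        raise ValidationError("need >= 2 strains and >= 1 phenotype")

    components = _connected(list(included))
    if len(components) > 1:
        pretty = [sorted(c) for c in components]
        raise IdentifiabilityError(
            f"design disconnected after exclusions; components: {pretty}"
        )

    free_strains = [s for s in strains if s != anchor]
    params = free_strains + phenotypes  # mu_s ... then T_k ...
    index = {name: i for i, name in enumerate(params)}
    rows = []
    y = []
    for (s, k), lv in included.items():
        row = np.zeros(len(params))
        row[index[k]] = 1.0  # + T_k
        if s != anchor:
            row[index[s]] = -1.0  # - mu_s
        rows.append(row)
        y.append(lv.x)
    a = np.vstack(rows)
    beta, *_ = np.linalg.lstsq(a, np.asarray(y), rcond=None)

    strain_means = {anchor: 0.0}
    strain_means.update({s: float(beta[index[s]]) for s in free_strains})
    thresholds = {k: float(beta[index[k]]) for k in phenotypes}
    resid_rows = [
        {
            "strain": s,
            "phenotype": k,
            "observed": lv.x,
            "predicted": thresholds[k] - strain_means[s],
            "residual": lv.x - (thresholds[k] - strain_means[s]),
        }
        for (s, k), lv in included.items()
    ]
    return ThresholdModel(
        strain_means=strain_means,
        thresholds=thresholds,
        residuals=pd.DataFrame(resid_rows),
        anchor=anchor,
        excluded=excluded,
    )


@dataclass
class LiabilityTrajectory:
    """Per-generation liability of a selected line.

    ``delta_x`` is the per-generation response x_t - x_{t-1}; steps touching
    a capped generation are excluded from the cumulative response, which is
    then a bound rather than an estimate (``cumulative_is_bound``).
    """

    table: pd.DataFrame
    cumulative_response: float
    cumulative_is_bound: bool

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def liability_trajectory(
    incidences: Sequence[tuple[int, float]], cap: float = DEFAULT_CAP
) -> LiabilityTrajectory:
    """Probit-transform a per-generation incidence series.

    ``incidences`` is an ordered list of (generation, incidence).  Each
    generation's x comes from :func:`incidence_to_liability`; capped
    generations are flagged and the deltas adjacent to them are excluded
    from the cumulative response.
    """
    if len(incidences) < 2:
        raise ValidationError("need at least 2 generations for a trajectory")
    rows = []
    for gen, p in incidences:
        lv = incidence_to_liability(p, cap=cap)
        rows.append(
            {"generation": int(gen), "incidence": lv.incidence, "x": lv.x, "capped": lv.capped}
        )
    df = pd.DataFrame(rows)
    deltas = [np.nan]
    for i in range(1, len(df)):
        if df.loc[i, "capped"] or df.loc[i - 1, "capped"]:
            deltas.append(np.nan)
        else:
            deltas.append(float(df.loc[i, "x"] - df.loc[i - 1, "x"]))
    df["delta_x"] = deltas
    cumulative = float(np.nansum(deltas))
    is_bound = bool(df["capped"].any())
    df["cumulative_response"] = np.nancumsum([0.0] + deltas[1:])
    return LiabilityTrajectory(
        table=df, cumulative_response=cumulative, cumulative_is_bound=is_bound
    )
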