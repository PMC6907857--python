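"""Core domain types: scoring tables, Ct tables, and the analysis configuration.

A *scoring table* holds one row per animal with genotype calls at up to three
loci and binary presence/absence flags for named skeletal phenotypes.  It is
the unit on which every penetrance statistic operates.  A *Ct table* holds
replicate qPCR threshold-cycle measurements in long format.  Both are thin,
validated wrappers around :class:`pandas.DataFrame` so that downstream code
can use ordinary pandas selection.
"""

from __future__ import annotations

import dataclasses
import enum
from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "GenotypeCall",
    "PhenotypeState",
    "GENOTYPE_TOKENS",
    "TOKEN_FOR_CALL",
    "DEFAULT_PHENOTYPES",
    "DEFAULT_LOCI",
    "CORE_COLUMNS",
    "ScoringTable",
    "CtTable",
    "AnalysisConfig",
]


class GenotypeCall(str, enum.Enum):
    """Genotype call at one locus of a het-by-het intercross offspring."""

    WT = "wt"
    HET = "het"
    MUT = "mut"
    UNKNOWN = "unknown"


class PhenotypeState(str, enum.Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNSCORED = "unscored"


#: Fixed token dialect used in scoring files.
GENOTYPE_TOKENS: dict[str, GenotypeCall] = {
    "+/+": GenotypeCall.WT,
    "+/-": GenotypeCall.HET,
    "-/-": GenotypeCall.MUT,
    "NA": GenotypeCall.UNKNOWN,
}
TOKEN_FOR_CALL: dict[GenotypeCall, str] = {v: k for k, v in GENOTYPE_TOKENS.items()}

#: Built-in vocabulary of scored craniofacial phenotypes. Users may declare more.
DEFAULT_PHENOTYPES: tuple[str, ...] = (
    "ectopic-bone",
    "interhyal-joint-fusion",
    "jaw-joint-fusion",
    "dysmorphic-ceratohyal",
    "reduced-meckels",
    "short-symplectic",
)

DEFAULT_LOCI: tuple[str, ...] = ("mef2ca", "dlx5a", "jag1b")

CORE_COLUMNS: tuple[str, ...] = ("animal_id", "strain", "generation", "family_id")


@dataclass
class ScoringTable:
    """Per-animal genotype and phenotype scores.

    ``data`` columns: the four core columns, one column per locus holding
    :class:`GenotypeCall` values (as their string values), and one nullable
    boolean column per phenotype where ``pd.NA`` means *unscored*.  Unscored
    animals never enter penetrance numerators or denominators.
    """

    data: pd.DataFrame
    loci: tuple[str, ...] = DEFAULT_LOCI
    phenotypes: tuple[str, ...] = DEFAULT_PHENOTYPES
    provenance: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.loci = tuple(self.loci)
        self.phenotypes = tuple(self.phenotypes)
        df = self.data
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"scoring table lacks core columns: {missing}")
        if df["animal_id"].duplicated().any():
            dups = df.loc[df["animal_id"].duplicated(), "animal_id"].tolist()
            raise ValidationError(f"duplicate animal_id values: {dups[:5]}")
        valid_calls = {c.value for c in GenotypeCall}
        for locus in self.loci:
            if locus not in df.columns:
                raise ValidationError(f"declared locus column missing: {locus!r}")
            bad = set(df[locus].dropna().unique()) - valid_calls
            if bad:
                raise ValidationError(f"invalid genotype calls in {locus!r}: {sorted(bad)}")
        for phen in self.phenotypes:
            if phen not in df.columns:
                raise ValidationError(f"declared phenotype column missing: {phen!r}")
            if str(df[phen].dtype) != "boolean":
                # accept plain bool / object-with-NA and normalise
                self.data[phen] = df[phen].astype("boolean")

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoringTable):
            return NotImplemented
        if (self.loci, self.phenotypes) != (other.loci, other.phenotypes):
            return False
        cols = list(CORE_COLUMNS) + list(self.loci) + list(self.phenotypes)
        a = self.data[cols].reset_index(drop=True)
        b = other.data[cols].reset_index(drop=True)
        return a.equals(b)


@dataclass
class CtTable:
    """Replicate qPCR Ct measurements, one biological sample per ``sample_id``.

    Long format: one row per (sample, gene, replicate).  Technical replicates
    of the same (sample, gene) are identified simply by sharing those keys.
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "gene", "group", "ct")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"Ct table lacks columns: {missing}")
        ct = pd.to_numeric(df["ct"], errors="coerce")
        if ct.isna().any() or not np.isfinite(ct).all() or not (ct > 0).all():
            raise ValidationError("Ct values must be finite and positive")
        self.data = df.assign(ct=ct.astype(float))

    def require_reference(self, reference: str) -> None:
        """Every biological sample must carry rows for the reference gene."""
        by_sample = self.data.groupby("sample_id")["gene"].apply(set)
        lacking = [s for s, genes in by_sample.items() if reference not in genes]
        if lacking:
            raise ValidationError(
                f"samples lacking reference gene {reference!r}: {lacking}"
            )

    def replicate_means(self) -> pd.DataFrame:
        """Mean Ct per (sample, gene), carrying the group label along."""
        return (
            self.data.groupby(["sample_id", "gene", "group"], as_index=False)["ct"]
            .mean()
        )

    def __len__(self) -> int:
        return len(self.data)


def _positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValidationError(f"{name} must be positive, got {value}")


@dataclass
class AnalysisConfig:
    """Knobs shared by the statistical stages.

    ``multiplicity`` selects the family-wise adjustment applied across the
    phenotypes of one comparison; ``liability_cap`` bounds the probit of an
    incidence of exactly 0 or 1; the standard-curve window encodes which
    primer efficiencies are acceptable (slope −3.3 ± 0.3 by default).
    """

    phenotypes: tuple[str, ...] = DEFAULT_PHENOTYPES
    loci: tuple[str, ...] = DEFAULT_LOCI
    multiplicity: str = "benjamini-hochberg"  # benjamini-hochberg | hochberg | none
    alpha: float = 0.05
    liability_cap: float = 4.0
    reference_gene: str = "rps18"
    curve_slope_center: float = -3.3
    curve_slope_halfwidth: float = 0.3
    ci_method: str = "clopper-pearson"
    continuity_correction: bool = False
    undetermined_ct_ceiling: float | None = None
    report_precision: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must lie in (0,1), got {self.alpha}")
        _positive("liability_cap", self.liability_cap)
        _positive("curve_slope_halfwidth", self.curve_slope_halfwidth)
        if self.multiplicity not in ("benjamini-hochberg", "hochberg", "none"):
            raise ValidationError(f"unknown multiplicity method {self.multiplicity!r}")
        self.phenotypes = tuple(self.phenotypes)
        self.loci = tuple(self.loci)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["phenotypes"] = list(self.phenotypes)
        d["loci"] = list(self.loci)
        return d
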