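"""Health phenotype scorecards.

A scorecard turns per-sample metadata (experimental factors such as age,
genotype, treatment) into a per-sample *health phenotype score*: the young
untreated wildtype sample scores 1, samples from old individuals score 0,
and every health-improving (-reducing) treatment adds (subtracts) a signed
increment, 0.2 by default.  Knock-downs, knock-outs, gene transfers and
natural genetic variants are treated like any other treatment.  Scores are
only comparable *within* one experiment; they are never related across
experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

from .errors import ScoreCardError

DEFAULT_INCREMENT = 0.2


@dataclass(frozen=True)
class TreatmentRule:
    """One signed increment: applies when ``metadata[column] == value``."""

    column: str
    value: str
    delta: float = DEFAULT_INCREMENT
    note: str = ""

    def __post_init__(self):
        if not pd.notna(self.delta) or abs(self.delta) == float("inf"):
            raise ScoreCardError(f"non-finite increment for rule {self.column}={self.value}")


@dataclass
class ScoreCard:
    """Declarative per-experiment scoring rules.

    Parameters
    ----------
    base_scores
        Age category -> base score (e.g. ``{"young": 1.0, "old": 0.0}``).
    age_column
        Metadata column holding the age category.
    treatment_rules
        Signed increments applied on top of the base score.
    formula
        Optional escape hatch: a pandas-eval arithmetic expression over
        factor columns.  When present it *replaces* base + increments.
    note
        Free-text provenance for the card as a whole.
    """

    base_scores: dict[str, float] = field(default_factory=lambda: {"young": 1.0, "old": 0.0})
    age_column: str = "age"
    treatment_rules: list[TreatmentRule] = field(default_factory=list)
    formula: Optional[str] = None
    note: str = ""

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreCard":
        rules = [TreatmentRule(**r) for r in d.get("treatment_rules", [])]
        return cls(
            base_scores={str(k): float(v) for k, v in d.get("base_scores", {"young": 1.0, "old": 0.0}).items()},
            age_column=d.get("age_column", "age"),
            treatment_rules=rules,
            formula=d.get("formula"),
            note=d.get("note", ""),
        )

    @classmethod
    def from_yaml(cls, path) -> "ScoreCard":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PhenotypeVector:
    """Per-sample health phenotype score (unitless, within-experiment only)."""

    scores: pd.Series  # index: sample IDs
    constant: bool = False  # warning flag carried to module selection

    def __post_init__(self):
        self.scores = self.scores.astype(float)
        self.constant = bool(self.scores.nunique() <= 1)

    def to_tsv(self, path) -> None:
        self.scores.rename("health_score").to_csv(path, sep="\t", header=True, index_label="sample")


@dataclass
class ValidationReport:
    """Report-only result of checking a card against a metadata table."""

    missing_columns: list[str] = field(default_factory=list)
    unused_rules: list[TreatmentRule] = field(default_factory=list)
    uncovered_samples: list[str] = field(default_factory=list)
    constant_scores: bool = False

    @property
    def issues(self) -> list[str]:
        out = [f"missing factor column: {c}" for c in self.missing_columns]
        out += [f"unused rule: {r.column}={r.value}" for r in self.unused_rules]
        out += [f"uncovered sample: {s}" for s in self.uncovered_samples]
        if self.constant_scores:
            out.append("all samples receive the same score")
        return out


def _required_columns(card: ScoreCard) -> list[str]:
    cols = [] if card.formula is not None else [card.age_column]
    cols += [r.column for r in card.treatment_rules]
    # preserve order, drop duplicates
    return list(dict.fromkeys(cols))


def score_samples(metadata: pd.DataFrame, card: ScoreCard) -> PhenotypeVector:
    """Apply a scorecard to a sample-metadata table.

    score = base(age) + sum of applicable signed treatment increments,
    or the card's custom formula when one is configured.

    Raises
    ------
    ScoreCardError
        If a rule references a factor column absent from the metadata.
    """
    missing = [c for c in _required_columns(card) if c not in metadata.columns]
    if missing:
        raise ScoreCardError(f"metadata lacks factor column(s): {', '.join(missing)}")

    if card.formula is not None:
        scores = pd.Series(metadata.eval(card.formula), index=metadata.index, dtype=float)
    else:
        base = metadata[card.age_column].map(card.base_scores)
        if base.isna().any():
            bad = sorted(set(metadata.loc[base.isna(), card.age_column].astype(str)))
            raise ScoreCardError(f"no base score for age categor{'ies' if len(bad) > 1 else 'y'}: {', '.join(bad)}")
        scores = base.astype(float)
        for rule in card.treatment_rules:
            hit = metadata[rule.column].astype(str) == str(rule.value)
            scores = scores + hit.astype(float) * rule.delta
    return PhenotypeVector(scores=scores)


def validate_scorecard(card: ScoreCard, metadata: pd.DataFrame) -> ValidationReport:
    """Check a card against a metadata table without failing.

    Lists rules that never fire, samples not covered by any base score,
    factor columns the card names but the table lacks, and flags a
    constant score vector (which would make the downstream eigengene
    correlation undefined).
    """
    rep = ValidationReport()
    rep.missing_columns = [c for c in _required_columns(card) if c not in metadata.columns]
    if card.formula is None and card.age_column in metadata.columns:
        covered = metadata[card.age_column].isin(card.base_scores)
        rep.uncovered_samples = [str(s) for s in metadata.index[~covered]]
    for rule in card.treatment_rules:
        if rule.column in metadata.columns:
            if not (metadata[rule.column].astype(str) == str(rule.value)).any():
                rep.unused_rules.append(rule)
        # a missing column is already reported above; the rule is also unused
    if not rep.missing_columns:
        try:
            rep.constant_scores = score_samples(metadata, card).constant
        except ScoreCardError:
            pass
    return rep
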