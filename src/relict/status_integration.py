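"""Rule-based multi-evidence functional-status classifier.

Integrates lesion evidence, liver expression (TPM) and plasma enzyme
activity into a per-species Pon1 status: present (1), absent (0), or
excluded. Rule precedence, in order:

1. any coding lesion or critical-site substitution            -> absent (0)
2. any plasma activity > 0, or mean TPM >= tpm_present        -> present (1)
3. plasma activity measured as 0, or mean TPM <= tpm_absent   -> absent (0)
4. otherwise (incl. lesion-free DNA-only species)             -> excluded

Lesion evidence outranks expression and activity because it is the only
irreversible evidence class. The present threshold is inclusive (>=) so a
species sitting exactly at the boundary expression level counts as
functional; TPM strictly between the two thresholds with no other evidence
is excluded rather than guessed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

EXCLUDED = "excluded"


@dataclass(frozen=True)
class StatusThresholds:
    """TPM decision levels; defaults are the observed expression of the
    lowest clearly functional species (61.76) and the highest clearly
    nonfunctional one (41.3)."""

    tpm_present: float = 61.76
    tpm_absent: float = 41.3

    def __post_init__(self) -> None:
        if not self.tpm_absent < self.tpm_present:
            raise ValueError("tpm_absent must be below tpm_present")


@dataclass(frozen=True)
class EvidenceRecord:
    """Per-species evidence bundle. ``None`` marks missing evidence;
    ``plasma_activity`` of 0.0 is a measured zero (evidence of absence)."""

    species: str
    any_lesion: bool | None = None
    any_critical_sub: bool | None = None
    mean_tpm: float | None = None
    plasma_activity: float | None = None

    def has_any_evidence(self) -> bool:
        return any(
            v is not None
            for v in (self.any_lesion, self.any_critical_sub, self.mean_tpm,
                      self.plasma_activity)
        )


@dataclass(frozen=True)
class StatusCall:
    species: str
    status: int | str  # 1, 0, or "excluded"
    rationale: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rationale:
            raise ValueError("rationale must be nonempty")


def classify_pon1_status(
    evidence: EvidenceRecord,
    thresholds: StatusThresholds = StatusThresholds(),
) -> StatusCall:
    """Apply the precedence rules to one species' evidence."""
    if not evidence.has_any_evidence():
        raise ValueError(f"{evidence.species}: all evidence fields missing")
    fired: list[str] = []
    if evidence.any_lesion or evidence.any_critical_sub:
        kind = "coding lesion" if evidence.any_lesion else "critical-site substitution"
        fired.append(f"rule1: {kind} present -> absent")
        return StatusCall(evidence.species, 0, tuple(fired))
    if evidence.plasma_activity is not None and evidence.plasma_activity > 0:
        fired.append("rule2: plasma activity detected -> present")
        return StatusCall(evidence.species, 1, tuple(fired))
    if evidence.mean_tpm is not None and evidence.mean_tpm >= thresholds.tpm_present:
        fired.append(
            f"rule2: TPM {evidence.mean_tpm:g} >= {thresholds.tpm_present:g} -> present"
        )
        return StatusCall(evidence.species, 1, tuple(fired))
    if evidence.plasma_activity is not None and evidence.plasma_activity == 0:
        fired.append("rule3: plasma activity measured zero -> absent")
        return StatusCall(evidence.species, 0, tuple(fired))
    if evidence.mean_tpm is not None and evidence.mean_tpm <= thresholds.tpm_absent:
        fired.append(
            f"rule3: TPM {evidence.mean_tpm:g} <= {thresholds.tpm_absent:g} -> absent"
        )
        return StatusCall(evidence.species, 0, tuple(fired))
    fired.append("rule4: evidence insufficient under stringent criteria -> excluded")
    return StatusCall(evidence.species, EXCLUDED, tuple(fired))


def classify_all(
    records: Sequence[EvidenceRecord],
    thresholds: StatusThresholds = StatusThresholds(),
) -> list[StatusCall]:
    return [classify_pon1_status(r, thresholds) for r in records]


def build_trait_table(
    calls: Sequence[StatusCall],
    predictors: Mapping[str, Mapping[str, float]] | pd.DataFrame,
) -> pd.DataFrame:
    """One row per non-excluded species with binary status plus predictor
    columns; species with any missing predictor are dropped with a warning.

    ``predictors`` maps species -> {trait: value} (or an equivalent
    DataFrame indexed by species).
    """
    if isinstance(predictors, pd.DataFrame):
        pred = predictors
    else:
        pred = pd.DataFrame.from_dict(dict(predictors), orient="index")
    status = {
        c.species: c.status for c in sorted(calls, key=lambda c: c.species)
        if c.status != EXCLUDED
    }
    rows = []
    import warnings

    for sp in sorted(status):
        if sp not in pred.index or pred.loc[sp].isna().any():
            warnings.warn(f"{sp}: missing predictor value(s); dropped from trait table")
            continue
        row = {"species": sp, "status": int(status[sp])}
        row.update(pred.loc[sp].to_dict())
        rows.append(row)
    if not rows:
        raise ValueError("no usable rows: every species excluded or missing predictors")
    return pd.DataFrame(rows).set_index("species")


def write_status_tsv(calls: Sequence[StatusCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["species", "status", "fired_rules"])
        for c in sorted(calls, key=lambda c: c.species):
            w.writerow([c.species, c.status, "; ".join(c.rationale)])
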