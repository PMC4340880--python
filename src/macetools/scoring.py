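"""Scoring: from a 52-item response record to the full MACE score set.

Outputs per subscale the raw endorsement count, a 0-10 severity, and an
exposure flag (raw count >= the subscale threshold); across subscales
the Multiplicity (count of exposed types, 0-10, an ACE-like tally) and
the total Severity (sum of subscale severities, 0-100, a CTQ-like sum);
and, when age-of-exposure checkboxes are present, a chronology: the same
severity computed per year of age 1-18 from the items endorsed at that
age.

Reverse-scored items (42, 43, 52, 44, 45, 51 in the shipped instrument)
are flipped exactly once, here, driven by the instrument definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .instrument import SUBSCALE_ORDER, InstrumentDefinition, SubscaleDefinition

__all__ = ["SubscaleScore", "MaceScoreSet", "score_subscale", "score_person",
           "score_chronology"]


@dataclass
class SubscaleScore:
    name: str
    raw: int | None            # endorsed count after reverse-scoring
    severity: float            # 0-10; NaN when the subscale is fully missing
    exposed: bool | None       # None when not assessable (fully missing / no siblings)
    prorated: bool = False     # raw was scaled up from a partial item set
    n_observed: int = 0
    skipped_no_siblings: bool = False


@dataclass
class MaceScoreSet:
    person: object
    subscale_scores: dict      # name -> SubscaleScore
    multiplicity: int
    total_severity: float
    chronology: np.ndarray | None = None        # 18 x 10 per-year severities
    chronology_total: np.ndarray | None = None  # 18-vector of per-year totals
    flags: dict = field(default_factory=dict)

    def severity_row(self) -> dict:
        out = {}
        for name, s in self.subscale_scores.items():
            out[f"{name}_raw"] = s.raw
            out[f"{name}_severity"] = s.severity
            out[f"{name}_exposed"] = s.exposed
        out["multiplicity"] = self.multiplicity
        out["total_severity"] = self.total_severity
        return out


def _flipped(responses: dict, sub: SubscaleDefinition, already_flipped: bool):
    """Yield (item_id, 0/1/None) in construct coding (reverse items flipped)."""
    for item in sub.item_ids:
        v = responses.get(item)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            yield item, None
        else:
            v = int(v)
            if v not in (0, 1):
                raise ValueError(f"item {item}: response must be 0/1/missing, got {v}")
            if not already_flipped and item in sub.reverse_ids:
                v = 1 - v
            yield item, v


def score_subscale(responses: dict, sub: SubscaleDefinition,
                   already_flipped: bool = False) -> SubscaleScore:
    """Score one subscale from a mapping item_id -> 0/1/None.

    Reverse-scored items are flipped here (single point of truth) unless
    the caller passes construct-coded values with ``already_flipped``.
    Missing items: the observed count is prorated to the full item count
    (scaled by k/observed, floored — a conservative convention) and the
    result flagged; a fully missing subscale yields NaN severity and an
    unassessable exposure flag.
    """
    vals = dict(_flipped(responses, sub, already_flipped))
    observed = [v for v in vals.values() if v is not None]
    k = sub.n_items
    n_obs = len(observed)
    if n_obs == 0:
        return SubscaleScore(sub.name, None, math.nan, None, False, 0)
    r_obs = sum(observed)
    if n_obs < k:
        r = min(int(r_obs * k / n_obs), k)
        prorated = True
    else:
        r = int(r_obs)
        prorated = False
    return SubscaleScore(sub.name, r, sub.severity(r), r >= sub.threshold_raw,
                         prorated, n_obs)


def score_person(responses: dict, defn: InstrumentDefinition,
                 ages: dict | None = None, has_siblings: bool = True,
                 person=None) -> MaceScoreSet:
    """Full score set for one respondent.

    ``responses`` maps item id -> 0/1/None (raw, un-reversed);
    ``ages`` optionally maps item id -> set of endorsed ages (1..18).
    Sibling-conditional subscales are scored as missing for respondents
    without siblings and contribute 0 to the totals, flagged.
    """
    scores = {}
    flags = {"prorated": [], "missing": [], "skipped_no_siblings": []}
    for name, sub in defn.subscales.items():
        if not has_siblings and name in defn.sibling_conditional:
            scores[name] = SubscaleScore(name, None, math.nan, None,
                                         skipped_no_siblings=True)
            flags["skipped_no_siblings"].append(name)
            continue
        s = score_subscale(responses, sub)
        scores[name] = s
        if s.prorated:
            flags["prorated"].append(name)
        if s.raw is None:
            flags["missing"].append(name)

    multiplicity = sum(1 for s in scores.values() if s.exposed)
    total = sum(s.severity for s in scores.values() if not math.isnan(s.severity))

    chron = chron_total = None
    if ages is not None:
        chron, chron_total = score_chronology(responses, defn, ages,
                                              has_siblings=has_siblings)
    return MaceScoreSet(person, scores, multiplicity, round(float(total), 2),
                        chron, chron_total, flags)


def score_chronology(responses: dict, defn: InstrumentDefinition, ages: dict,
                     has_siblings: bool = True):
    """Per-year severities: an 18 x 10 matrix plus per-year totals.

    For each age a in 1..18 the binary indicator "item endorsed at age a"
    is scored with the same calibrated banks as the overall scale (a
    single instrument, no per-age recalibration). An item endorsed at any
    age must be endorsed overall; ages on non-endorsed items are invalid.
    """
    lo, hi = defn.age_range
    names = [n for n in SUBSCALE_ORDER if n in defn.subscales]
    for item, aset in ages.items():
        if not aset:
            continue
        if responses.get(item) != 1:
            raise ValueError(f"item {item}: ages recorded but item not endorsed")
        bad = [a for a in aset if a < lo or a > hi]
        if bad:
            raise ValueError(f"item {item}: ages {bad} outside {lo}..{hi}")

    n_ages = hi - lo + 1
    mat = np.zeros((n_ages, len(names)))
    for col, name in enumerate(names):
        sub = defn.subscales[name]
        if not has_siblings and name in defn.sibling_conditional:
            mat[:, col] = np.nan
            continue
        for row, age in enumerate(range(lo, hi + 1)):
            # construct-coded endorsement at this age: a directly worded
            # item counts where one of its checked ages matches; a reverse
            # item's deficit (raw 0) carries no age information and is
            # taken to apply across all of childhood
            at_age = {}
            for item in sub.item_ids:
                v = responses.get(item)
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    at_age[item] = None  # keep missing as missing per year
                elif item in sub.reverse_ids:
                    at_age[item] = 1 - int(v)
                else:
                    at_age[item] = 1 if (int(v) == 1 and age in ages.get(item, ())) else 0
            s = score_subscale(at_age, sub, already_flipped=True)
            mat[row, col] = s.severity
    totals = np.nansum(mat, axis=1)
    return mat, totals
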