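"""The concrete MACE instrument definition.

52 yes/no items partitioned into ten maltreatment subscales, with the
published Rasch calibrations (item difficulties and standard errors),
extreme-score anchors, and exposure thresholds, shipped as a versioned
JSON configuration. Subscales with five or more items are scored by
rescaling the ML person logit onto 0-10 using the anchors; the two
four-item subscales (parental verbal abuse, witnessing violence to
siblings) carry instead the fixed interpolation table
{0->0, 1->3, 2->5, 3->8, 4->10}, since four items provide too few
parameters for stable logit scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .rasch import ItemBank, estimate_person_theta

__all__ = [
    "SubscaleDefinition",
    "InstrumentDefinition",
    "load_instrument",
    "validate_instrument",
    "SUBSCALE_ORDER",
]

SUBSCALE_ORDER = ["EN", "NVEA", "PA", "PVA", "PeerE", "PeerP", "PN", "SA",
                  "WIPV", "WSibV"]

_ROUND_HALF_AWAY = lambda x: float(np.floor(np.abs(x) + 0.5) * np.sign(x))


@dataclass
class SubscaleDefinition:
    name: str
    full_name: str
    item_ids: list[int]
    reverse_ids: list[int]
    bank: ItemBank
    anchors: tuple | None  # (theta at r=0, theta at r=k); None for 4-item scales
    threshold_raw: int
    threshold_scaled: int
    threshold_logit: float | None = None
    interpolation: dict | None = None  # raw count -> severity, 4-item scales

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def calibrated_scoring(self) -> bool:
        return self.interpolation is None

    def severity(self, r: int) -> float:
        """0-10 severity at raw count ``r`` (continuous, 2-dp resolution)."""
        if r < 0 or r > self.n_items:
            raise ValueError(f"raw count {r} outside [0, {self.n_items}]")
        if self.interpolation is not None:
            return float(self.interpolation[int(r)])
        lo, hi = self.anchors
        theta = estimate_person_theta(int(r), self.bank).theta
        scaled = 10.0 * (theta - lo) / (hi - lo)
        return round(min(max(scaled, 0.0), 10.0), 2)

    def severity_rounded(self, r: int) -> int:
        """Integer severity (half away from zero), the report convention."""
        return int(_ROUND_HALF_AWAY(self.severity(r)))


@dataclass
class InstrumentDefinition:
    version: str
    subscales: dict  # name -> SubscaleDefinition, in canonical order
    age_range: tuple = (1, 18)
    sibling_conditional: tuple = ("WSibV",)
    source: str | None = None

    @property
    def all_item_ids(self) -> list[int]:
        out = []
        for sub in self.subscales.values():
            out.extend(sub.item_ids)
        return sorted(out)

    def subscale_of_item(self, item_id: int) -> str:
        for name, sub in self.subscales.items():
            if item_id in sub.item_ids:
                return name
        raise KeyError(item_id)

    def to_json_dict(self) -> dict:
        subs = []
        for sub in self.subscales.values():
            rec = {
                "name": sub.name,
                "full_name": sub.full_name,
                "items": [
                    {"id": i, "label": lab, "difficulty": float(d),
                     "se": float(s) if s is not None else None,
                     "reverse": i in sub.reverse_ids}
                    for i, lab, d, s in zip(
                        sub.item_ids,
                        sub.bank.meta.get("labels", [""] * sub.n_items),
                        sub.bank.difficulty,
                        (sub.bank.difficulty_se if sub.bank.difficulty_se is not None
                         else [None] * sub.n_items))
                ],
                "anchors": list(sub.anchors) if sub.anchors else None,
                "threshold_raw": sub.threshold_raw,
                "threshold_logit": sub.threshold_logit,
                "threshold_scaled": sub.threshold_scaled,
            }
            if sub.interpolation is not None:
                rec["interpolated"] = True
            subs.append(rec)
        return {
            "version": self.version,
            "age_min": self.age_range[0],
            "age_max": self.age_range[1],
            "sibling_conditional": list(self.sibling_conditional),
            "interpolation_table": {"0": 0, "1": 3, "2": 5, "3": 8, "4": 10},
            "subscales": subs,
        }


def _parse_subscale(rec: dict, interp_table: dict) -> SubscaleDefinition:
    items = rec["items"]
    ids = [int(it["id"]) for it in items]
    difficulty = [float(it["difficulty"]) for it in items]
    bank = ItemBank(
        item_ids=ids,
        difficulty=difficulty,
        difficulty_se=[float(it["se"]) if it.get("se") is not None else np.nan
                       for it in items],
        # off-center difficulties are loadable but flagged by the validator
        normalized=abs(sum(difficulty)) <= 0.02,
        anchor_low=rec["anchors"][0] if rec.get("anchors") else None,
        anchor_high=rec["anchors"][1] if rec.get("anchors") else None,
        meta={"labels": [it.get("label", "") for it in items]},
    )
    interpolation = None
    if rec.get("interpolated") or rec.get("anchors") is None:
        interpolation = {int(k): float(v) for k, v in interp_table.items()}
    return SubscaleDefinition(
        name=rec["name"],
        full_name=rec.get("full_name", rec["name"]),
        item_ids=ids,
        reverse_ids=[int(it["id"]) for it in items if it.get("reverse")],
        bank=bank,
        anchors=tuple(rec["anchors"]) if rec.get("anchors") else None,
        threshold_raw=int(rec["threshold_raw"]),
        threshold_scaled=int(rec["threshold_scaled"]),
        threshold_logit=rec.get("threshold_logit"),
        interpolation=interpolation,
    )


def load_instrument(path=None, strict: bool = True) -> InstrumentDefinition:
    """Load an instrument JSON; defaults to the bundled ``mace_v1``.

    With ``strict`` (default) any internal-consistency issue raises;
    otherwise issues are attached but loading proceeds.
    """
    if path is None:
        raw = resources.files("macetools.data").joinpath("mace_v1.json").read_text()
        source = "bundled:mace_v1.json"
    else:
        raw = Path(path).read_text()
        source = str(path)
    doc = json.loads(raw)
    for key in ("version", "subscales"):
        if key not in doc:
            raise ValueError(f"instrument JSON missing required key {key!r}")
    interp = doc.get("interpolation_table", {"0": 0, "1": 3, "2": 5, "3": 8, "4": 10})
    subs = {}
    for rec in doc["subscales"]:
        sub = _parse_subscale(rec, interp)
        subs[sub.name] = sub
    defn = InstrumentDefinition(
        version=doc["version"],
        subscales=subs,
        age_range=(int(doc.get("age_min", 1)), int(doc.get("age_max", 18))),
        sibling_conditional=tuple(doc.get("sibling_conditional", ())),
        source=source,
    )
    issues = validate_instrument(defn)
    fatal = [i for i in issues if not i.startswith("warning")]
    if strict and fatal:
        raise ValueError("instrument failed validation: " + "; ".join(fatal))
    return defn


def validate_instrument(defn: InstrumentDefinition) -> list[str]:
    """Internal consistency checks; returns named issues (empty = clean).

    Checks: the ten subscales partition items 1..52 exactly; calibrated
    (>=5-item) subscales carry anchors and four-item subscales the
    interpolation table; difficulties are mean-centered; and the linear
    rescale of each stated threshold logit with the anchors reproduces
    the stated scaled threshold after integer rounding.
    """
    issues = []
    seen = {}
    for name, sub in defn.subscales.items():
        for i in sub.item_ids:
            if i in seen:
                issues.append(f"overlapping membership: item {i} in {seen[i]} and {name}")
            seen[i] = name
    expected = set(range(1, 53))
    if set(seen) != expected:
        missing = sorted(expected - set(seen))
        extra = sorted(set(seen) - expected)
        issues.append(f"item coverage: missing {missing}, unexpected {extra}")

    for name, sub in defn.subscales.items():
        s = float(sub.bank.difficulty.sum())
        if abs(s) > 0.02:
            issues.append(f"warning: normalization: {name} difficulties sum to {s:+.3f}")
        if sub.n_items >= 5 and sub.anchors is None:
            issues.append(f"{name}: >=5 items but no anchors")
        if sub.n_items == 4 and sub.interpolation is None:
            issues.append(f"{name}: 4 items require an interpolation table")
        if not (0 < sub.threshold_raw <= sub.n_items):
            issues.append(f"{name}: threshold_raw {sub.threshold_raw} out of range")
        # load-time self-test: threshold logit -> scaled threshold
        if sub.calibrated_scoring and sub.threshold_logit is not None:
            lo, hi = sub.anchors
            scaled = 10.0 * (sub.threshold_logit - lo) / (hi - lo)
            if int(_ROUND_HALF_AWAY(scaled)) != sub.threshold_scaled:
                issues.append(
                    f"{name}: rescaled threshold logit gives {scaled:.2f} "
                    f"-> {int(_ROUND_HALF_AWAY(scaled))}, stated {sub.threshold_scaled}"
                )
        if sub.interpolation is not None:
            sev = sub.interpolation.get(sub.threshold_raw)
            if sev is not None and int(sev) != sub.threshold_scaled:
                issues.append(f"{name}: interpolation at threshold gives {sev}, "
                              f"stated {sub.threshold_scaled}")
    return issues
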