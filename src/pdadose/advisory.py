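"""Exposure-tiered mitigation advisories.

Maps an estimated cumulative dose over a rolling window to a risk tier and
a list of mitigation recommendations (diet, OTC supplements, prescription
options, referral), read from a configurable rules file.  The shipped
default tiers are illustrative — the dose thresholds that should trigger
each treatment are configuration, not inference — and every report carries
a fixed non-medical-advice disclaimer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

CATEGORIES = frozenset({"diet", "OTC supplement", "prescription", "referral"})

DISCLAIMER = (
    "Illustrative, not clinical guidance. Tier thresholds are configurable "
    "defaults, not medical advice; consult a qualified professional for "
    "diagnosis or treatment."
)


@dataclass(frozen=True)
class AdviceItem:
    category: str
    text: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown advice category {self.category!r}; "
                f"expected one of {sorted(CATEGORIES)}"
            )


@dataclass(frozen=True)
class AdvisoryRule:
    """One risk tier: a half-open dose interval [low, high) in ppm·h over
    the rule set's window, with its advice entries."""

    tier: int
    name: str
    dose_low: float
    dose_high: float  # may be inf
    advice: tuple[AdviceItem, ...]
    citations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.dose_low < self.dose_high:
            raise ValueError(
                f"tier {self.name!r}: interval [{self.dose_low}, "
                f"{self.dose_high}) is empty or negative"
            )

    def matches(self, dose: float) -> bool:
        return self.dose_low <= dose < self.dose_high


@dataclass(frozen=True)
class RuleSet:
    rules: tuple[AdvisoryRule, ...]
    window_days: int = 14

    def __post_init__(self) -> None:
        rules = sorted(self.rules, key=lambda r: r.dose_low)
        if not rules:
            raise ValueError("rule set is empty")
        if rules[0].dose_low != 0:
            raise ValueError(
                f"rules must cover doses from 0; first tier starts at "
                f"{rules[0].dose_low}"
            )
        for a, b in zip(rules, rules[1:]):
            if b.dose_low < a.dose_high:
                raise ValueError(
                    f"tiers {a.name!r} and {b.name!r} overlap at dose "
                    f"{b.dose_low}"
                )
            if b.dose_low > a.dose_high:
                raise ValueError(
                    f"gap between tiers {a.name!r} and {b.name!r}: doses in "
                    f"[{a.dose_high}, {b.dose_low}) match no tier"
                )
        if not math.isinf(rules[-1].dose_high):
            raise ValueError(
                f"rules must cover doses to infinity; last tier ends at "
                f"{rules[-1].dose_high}"
            )
        object.__setattr__(self, "rules", tuple(rules))

    def match(self, dose: float) -> AdvisoryRule:
        """The unique tier containing ``dose`` (total over [0, inf))."""
        if dose < 0:
            raise ValueError("dose must be non-negative")
        for rule in self.rules:
            if rule.matches(dose):
                return rule
        raise AssertionError("validated rule set failed to match")  # pragma: no cover


@dataclass(frozen=True)
class AdvisoryReport:
    tier: int
    tier_name: str
    dose_ppmh: float
    window_days: int
    advice: tuple[AdviceItem, ...]
    citations: tuple[str, ...]
    disclaimer: str = DISCLAIMER

    def to_dict(self) -> dict:
        return {
            "tier": self.tier,
            "tier_name": self.tier_name,
            "dose_ppmh": self.dose_ppmh,
            "window_days": self.window_days,
            "advice": [
                {"category": a.category, "text": a.text} for a in self.advice
            ],
            "citations": list(self.citations),
            "disclaimer": self.disclaimer,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    def to_text(self) -> str:
        lines = [
            f"Exposure tier {self.tier} ({self.tier_name}): "
            f"{self.dose_ppmh:.1f} ppm·h over {self.window_days} days",
        ]
        for a in self.advice:
            lines.append(f"  [{a.category}] {a.text}")
        lines.append(self.disclaimer)
        return "\n".join(lines)


def _parse_rules(doc: dict) -> RuleSet:
    try:
        tiers = doc["tiers"]
    except (KeyError, TypeError):
        raise ValueError("rules file must define a 'tiers' list") from None
    rules = []
    for t in tiers:
        rules.append(
            AdvisoryRule(
                tier=int(t["tier"]),
                name=str(t["name"]),
                dose_low=float(t["dose_low_ppmh"]),
                dose_high=float(t["dose_high_ppmh"]),
                advice=tuple(
                    AdviceItem(category=a["category"], text=a["text"].strip())
                    for a in t.get("advice", [])
                ),
                citations=tuple(t.get("citations", [])),
            )
        )
    return RuleSet(rules=tuple(rules), window_days=int(doc.get("window_days", 14)))


def load_rules(path: str | Path | None = None) -> RuleSet:
    """Load and validate an advisory rules file (YAML or JSON).

    With no path, the shipped default rules are used.  Overlapping or
    gapped tier intervals are rejected with the offending boundaries.
    """
    if path is None:
        text = (
            resources.files("pdadose").joinpath("data/advisory_rules.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    return _parse_rules(yaml.safe_load(text))


def advise(
    doses,
    rules: RuleSet | None = None,
) -> AdvisoryReport:
    """Map a dose history to its risk tier and recommendations.

    ``doses`` is a non-empty sequence of per-day (or per-photo incremental)
    dose estimates in ppm·h over the rule window, or a single cumulative
    dose.  The cumulative sum is matched to exactly one tier;
    the result is deterministic.
    """
    rules = rules if rules is not None else load_rules()
    if np_isscalar(doses):
        history = [float(doses)]
    else:
        history = [float(d) for d in doses]
    if not history:
        raise ValueError("dose history is empty")
    if any(d < 0 for d in history):
        raise ValueError("dose history contains a negative dose")
    total = sum(history)
    rule = rules.match(total)
    return AdvisoryReport(
        tier=rule.tier,
        tier_name=rule.name,
        dose_ppmh=total,
        window_days=rules.window_days,
        advice=rule.advice,
        citations=rule.citations,
    )


def np_isscalar(x) -> bool:
    try:
        iter(x)
        return False
    except TypeError:
        return True
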