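"""ACMG/AMP sequence-variant classification: combining evidence into tiers.

Evidence arrives as criterion codes (PVS1, PS1-4, PM1-6, PP1-5 on the
pathogenic side; BA1, BS1-4, BP1-7 on the benign side). The 2015 categorical
combining rules are applied to yield one of five tiers: Pathogenic, Likely
pathogenic, Uncertain significance, Likely benign, Benign. When combining
rules fire on both sides the verdict is Uncertain significance with a
conflict flag; stray opposing codes that satisfy no rule on their own side do
not force a conflict (a single PM next to two BS still classifies Benign).
Codes are taken as given — deciding which codes apply is the caller's job.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

CATEGORIES = ("PVS", "PS", "PM", "PP", "BA", "BS", "BP")
_CODE_RE = re.compile(r"^(PVS|PS|PM|PP|BA|BS|BP)(\d+)$")

TIERS = ("Benign", "Likely benign", "Uncertain significance",
         "Likely pathogenic", "Pathogenic")


class EvidenceError(ValueError):
    """Malformed ACMG criterion code."""


@dataclass
class AcmgEvidenceSet:
    """A set of unique ACMG criterion codes, with optional strength overrides.

    ``overrides`` maps a code to the category at which it should be weighed
    (e.g. {"PVS1": "PS"} to downgrade PVS1 to strong).
    """

    codes: frozenset[str]
    overrides: dict[str, str] = field(default_factory=dict)

    @classmethod
    def parse(cls, text: str | list[str] | set[str]) -> "AcmgEvidenceSet":
        if isinstance(text, str):
            items = [c.strip() for c in text.split(",") if c.strip()]
        else:
            items = list(text)
        for code in items:
            if not _CODE_RE.match(code):
                raise EvidenceError(f"malformed ACMG code {code!r}")
        return cls(codes=frozenset(items))

    def category_of(self, code: str) -> str:
        if code in self.overrides:
            cat = self.overrides[code]
            if cat not in CATEGORIES:
                raise EvidenceError(f"bad override category {cat!r} for {code}")
            return cat
        m = _CODE_RE.match(code)
        if not m:
            raise EvidenceError(f"malformed ACMG code {code!r}")
        return m.group(1)

    def counts(self) -> dict[str, int]:
        c = {cat: 0 for cat in CATEGORIES}
        for code in self.codes:
            c[self.category_of(code)] += 1
        return c

    def has_pvs1(self) -> bool:
        return any(self.category_of(c) == "PVS" for c in self.codes)

    def has_ba1(self) -> bool:
        return any(self.category_of(c) == "BA" for c in self.codes)


@dataclass
class Classification:
    tier: str
    fired_rules: list[str]
    conflict: bool = False


#: (rule id, readable form, predicate over category counts)
_PATHOGENIC_RULES = [
    ("P1", "1 Very strong + (>=1 Strong | >=2 Moderate | 1 Moderate + 1 Supporting | >=2 Supporting)",
     lambda c: c["PVS"] >= 1 and (c["PS"] >= 1 or c["PM"] >= 2
                                  or (c["PM"] >= 1 and c["PP"] >= 1) or c["PP"] >= 2)),
    ("P2", ">=2 Strong", lambda c: c["PS"] >= 2),
    ("P3", "1 Strong + (>=3 Moderate | 2 Moderate + >=2 Supporting | 1 Moderate + >=4 Supporting)",
     lambda c: c["PS"] >= 1 and (c["PM"] >= 3 or (c["PM"] >= 2 and c["PP"] >= 2)
                                 or (c["PM"] >= 1 and c["PP"] >= 4))),
]

_LIKELY_PATHOGENIC_RULES = [
    ("LP1", "1 Very strong + 1 Moderate", lambda c: c["PVS"] >= 1 and c["PM"] >= 1),
    ("LP2", "1 Strong + 1-2 Moderate", lambda c: c["PS"] >= 1 and 1 <= c["PM"] <= 2),
    ("LP3", "1 Strong + >=2 Supporting", lambda c: c["PS"] >= 1 and c["PP"] >= 2),
    ("LP4", ">=3 Moderate", lambda c: c["PM"] >= 3),
    ("LP5", "2 Moderate + >=2 Supporting", lambda c: c["PM"] >= 2 and c["PP"] >= 2),
    ("LP6", "1 Moderate + >=4 Supporting", lambda c: c["PM"] >= 1 and c["PP"] >= 4),
]

_BENIGN_RULES = [
    ("B1", "1 Stand-alone (BA1)", lambda c: c["BA"] >= 1),
    ("B2", ">=2 Strong benign", lambda c: c["BS"] >= 2),
]

_LIKELY_BENIGN_RULES = [
    ("LB1", "1 Strong benign + 1 Supporting benign", lambda c: c["BS"] >= 1 and c["BP"] >= 1),
    ("LB2", ">=2 Supporting benign", lambda c: c["BP"] >= 2),
]


def classify(evidence: AcmgEvidenceSet) -> Classification:
    """Apply the categorical combining rules to an evidence set."""
    counts = evidence.counts()
    fired: list[str] = []
    path_tier = None
    for rule_id, _, pred in _PATHOGENIC_RULES:
        if pred(counts):
            fired.append(rule_id)
            path_tier = path_tier or "Pathogenic"
    for rule_id, _, pred in _LIKELY_PATHOGENIC_RULES:
        if pred(counts):
            fired.append(rule_id)
            path_tier = path_tier or "Likely pathogenic"
    benign_tier = None
    for rule_id, _, pred in _BENIGN_RULES:
        if pred(counts):
            fired.append(rule_id)
            benign_tier = benign_tier or "Benign"
    for rule_id, _, pred in _LIKELY_BENIGN_RULES:
        if pred(counts):
            fired.append(rule_id)
            benign_tier = benign_tier or "Likely benign"

    if path_tier and benign_tier:
        return Classification("Uncertain significance", fired, conflict=True)
    if path_tier:
        return Classification(path_tier, fired)
    if benign_tier:
        return Classification(benign_tier, fired)
    return Classification("Uncertain significance", fired)


def explain(evidence: AcmgEvidenceSet) -> str:
    """Readable rationale: every satisfied combination and the winning tier."""
    counts = evidence.counts()
    result = classify(evidence)
    lines = [f"evidence: {', '.join(sorted(evidence.codes)) or '(none)'}"]
    lines.append(
        "category counts: "
        + ", ".join(f"{cat}={counts[cat]}" for cat in CATEGORIES if counts[cat])
        or "category counts: none"
    )
    all_rules = (_PATHOGENIC_RULES + _LIKELY_PATHOGENIC_RULES
                 + _BENIGN_RULES + _LIKELY_BENIGN_RULES)
    for rule_id, text, _ in all_rules:
        if rule_id in result.fired_rules:
            lines.append(f"rule {rule_id} fired: {text}")
    if result.conflict:
        lines.append("conflict: rules fired on both the pathogenic and benign side")
    if not result.fired_rules:
        lines.append("no combining rule fired -> Uncertain significance")
    lines.append(f"tier: {result.tier}")
    return "\n".join(lines)
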