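"""Rule-based ordinal scoring of MRI features predictive of extraprostatic extension.

The mEPE-score condenses the PI-RADS v2.1 imaging features suggestive of
extraprostatic extension (EPE) of prostate cancer into a single 1-5 ordinal
grade per index lesion:

1. no EPE feature at all;
2. capsular abutment;
3. irregular or spiculated margin;
4. exactly one of {bulging prostatic contour, neurovascular-bundle
   asymmetry, tumor-capsule interface > 10 mm};
5. two or more of those three, or measurable extraprostatic disease
   (obliteration of the recto-prostatic angle, or frank capsular breach /
   bladder-wall invasion).

Rules form a ladder: the highest satisfied level wins.  A lesion is called
EPE-positive when its score strictly exceeds the rule set's positivity
threshold (``> 3`` for the mEPE-score).

Three comparator scoring systems (ESUR-score, mEPE-grade,
early-and-late-EPE) are encoded as data-driven :class:`ScoreRuleSet` tables
with the same evaluation semantics.  Their built-in definitions are
provisional reconstructions from published summaries, not transcriptions of
the original systems, and can be overridden through a YAML config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import yaml

__all__ = [
    "LesionFeatures",
    "ScoreRuleSet",
    "ScoreAssignment",
    "compute_mepe_score",
    "compute_score",
    "score_cohort",
    "get_ruleset",
    "builtin_rulesets",
    "load_rulesets_config",
    "BASE_FEATURES",
    "DERIVED_FLAGS",
]

#: Binary feature columns as they appear in cohort CSVs (minus interface_mm).
BASE_FEATURES = (
    "abutment",
    "irregular_margin",
    "bulging",
    "nvb_asymmetry",
    "angle_obliteration",
    "capsule_breach",
)

#: Flags derivable from a LesionFeatures record, usable in rule predicates.
DERIVED_FLAGS = (
    "abutment",
    "irregular_margin",
    "bulging",
    "nvb_asymmetry",
    "angle_obliteration",
    "capsule_breach",
    "interface_gt10",
    "interface_ge15",
    "measurable_disease",
    "any_feature",
)


@dataclass(frozen=True)
class LesionFeatures:
    """EPE-predictive MRI features of one index lesion.

    All flags are independent observations; in particular capsular abutment
    is not inferred from a positive interface length.  ``interface_length``
    is the tumor-capsule contact length in millimetres.
    """

    capsular_abutment: bool = False
    interface_length: float = 0.0
    irregular_margin: bool = False
    bulging_contour: bool = False
    nvb_asymmetry: bool = False
    angle_obliteration: bool = False
    capsule_breach: bool = False

    def __post_init__(self) -> None:
        if self.interface_length < 0:
            raise ValueError(
                f"interface_length must be >= 0 mm, got {self.interface_length}"
            )

    @property
    def interface_gt10(self) -> bool:
        """Tumor-capsule interface strictly greater than 10 mm (PI-RADS criterion)."""
        return self.interface_length > 10.0

    @property
    def interface_ge15(self) -> bool:
        """Interface of at least 15 mm (the mEPE-grade contact criterion)."""
        return self.interface_length >= 15.0

    @property
    def measurable_disease(self) -> bool:
        """Measurable extraprostatic disease: angle obliteration or capsular breach."""
        return self.angle_obliteration or self.capsule_breach

    @property
    def any_feature(self) -> bool:
        """Any EPE-predictive finding at all (including interface > 10 mm)."""
        return (
            self.capsular_abutment
            or self.irregular_margin
            or self.bulging_contour
            or self.nvb_asymmetry
            or self.angle_obliteration
            or self.capsule_breach
            or self.interface_gt10
        )

    def flag(self, name: str) -> bool:
        """Value of a base or derived boolean flag by its cohort-CSV name."""
        mapping = {
            "abutment": self.capsular_abutment,
            "irregular_margin": self.irregular_margin,
            "bulging": self.bulging_contour,
            "nvb_asymmetry": self.nvb_asymmetry,
            "angle_obliteration": self.angle_obliteration,
            "capsule_breach": self.capsule_breach,
            "interface_gt10": self.interface_gt10,
            "interface_ge15": self.interface_ge15,
            "measurable_disease": self.measurable_disease,
            "any_feature": self.any_feature,
        }
        try:
            return mapping[name]
        except KeyError:
            raise KeyError(
                f"unknown feature flag {name!r}; known flags: {', '.join(mapping)}"
            ) from None


@dataclass(frozen=True)
class ScoreAssignment:
    """One lesion's score under one rule set, with its dichotomous call."""

    score: int
    positive_call: bool
    ruleset_name: str


# --- declarative rule predicates -------------------------------------------------
#
# Conditions are plain dicts so rule sets can round-trip through YAML:
#   {"flag": "irregular_margin"}
#   {"none": true}                      -> no feature at all
#   {"count_at_least": {"flags": [...], "n": 2}}
#   {"all": [...]} / {"any": [...]} / {"not": {...}}

Condition = Mapping


def evaluate_condition(cond: Condition, features: LesionFeatures) -> bool:
    """Evaluate a declarative rule condition against a lesion."""
    if not isinstance(cond, Mapping) or len(cond) != 1:
        raise ValueError(f"malformed rule condition: {cond!r}")
    (kind, arg), = cond.items()
    if kind == "flag":
        return features.flag(arg)
    if kind == "none":
        return not features.any_feature
    if kind == "count_at_least":
        flags = arg["flags"]
        return sum(features.flag(f) for f in flags) >= int(arg["n"])
    if kind == "all":
        return all(evaluate_condition(c, features) for c in arg)
    if kind == "any":
        return any(evaluate_condition(c, features) for c in arg)
    if kind == "not":
        return not evaluate_condition(arg, features)
    raise ValueError(f"unknown rule condition kind {kind!r}")


@dataclass(frozen=True)
class ScoreRuleSet:
    """An ordered ladder of (level, condition) rules over lesion features.

    ``base_level`` is assigned when no rule fires; otherwise the highest
    level among satisfied rules wins.  ``positivity_threshold`` dichotomizes
    with the strict convention ``positive <=> score > threshold``.
    """

    name: str
    base_level: int
    level_rules: tuple[tuple[int, Condition], ...]
    score_range: tuple[int, int]
    positivity_threshold: int
    provisional: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.score_range
        levels = {self.base_level} | {lvl for lvl, _ in self.level_rules}
        bad = sorted(l for l in levels if not lo <= l <= hi)
        if bad:
            raise ValueError(
                f"ruleset {self.name!r}: levels {bad} outside score range {lo}..{hi}"
            )

    def score(self, features: LesionFeatures) -> int:
        level = self.base_level
        for lvl, cond in self.level_rules:
            if lvl > level and evaluate_condition(cond, features):
                level = lvl
        return level

    def assign(self, features: LesionFeatures) -> ScoreAssignment:
        s = self.score(features)
        return ScoreAssignment(
            score=s,
            positive_call=s > self.positivity_threshold,
            ruleset_name=self.name,
        )


def _severe_trio(n: int) -> Condition:
    return {
        "count_at_least": {
            "flags": ["bulging", "nvb_asymmetry", "interface_gt10"],
            "n": n,
        }
    }


MEPE_SCORE = ScoreRuleSet(
    name="mEPE-score",
    base_level=1,
    level_rules=(
        (2, {"flag": "abutment"}),
        (3, {"flag": "irregular_margin"}),
        (4, _severe_trio(1)),
        (5, _severe_trio(2)),
        (5, {"flag": "measurable_disease"}),
    ),
    score_range=(1, 5),
    positivity_threshold=3,
    description=(
        "Comprehensive 1-5 grade over all PI-RADS v2.1 EPE features; "
        "positive when score > 3."
    ),
)

ESUR_SCORE = ScoreRuleSet(
    name="ESUR-score",
    base_level=1,
    level_rules=(
        (2, {"flag": "abutment"}),
        (3, {"any": [{"flag": "irregular_margin"}, {"flag": "bulging"}]}),
        (4, {"flag": "nvb_asymmetry"}),
        (5, {"flag": "measurable_disease"}),
    ),
    score_range=(1, 5),
    positivity_threshold=3,
    provisional=True,
    description=(
        "Qualitative 1-5 EPE-likelihood ladder excluding interface length; "
        "provisional reconstruction, positive when score > 3."
    ),
)

MEPE_GRADE = ScoreRuleSet(
    name="mEPE-grade",
    base_level=0,
    level_rules=(
        (1, {"any": [{"flag": "interface_ge15"},
                     {"flag": "irregular_margin"},
                     {"flag": "bulging"}]}),
        (2, {"all": [{"flag": "interface_ge15"},
                     {"any": [{"flag": "irregular_margin"},
                              {"flag": "bulging"}]}]}),
        (3, {"flag": "measurable_disease"}),
    ),
    score_range=(0, 3),
    positivity_threshold=1,
    provisional=True,
    description=(
        "0-3 grade using a 15-mm contact criterion and contour signs, "
        "omitting abutment and neurovascular-bundle asymmetry; provisional "
        "reconstruction, positive when grade > 1."
    ),
)

EARLY_LATE_EPE = ScoreRuleSet(
    name="early-and-late-EPE",
    base_level=1,
    level_rules=(
        (2, {"any": [{"flag": "abutment"},
                     {"flag": "irregular_margin"},
                     {"flag": "bulging"},
                     {"flag": "nvb_asymmetry"},
                     {"flag": "interface_gt10"}]}),
        (3, {"flag": "measurable_disease"}),
    ),
    score_range=(1, 3),
    positivity_threshold=1,
    provisional=True,
    description=(
        "1 none / 2 early capsule-contact signs / 3 late measurable disease; "
        "provisional reconstruction, positive when score > 1."
    ),
)

_BUILTINS = {
    rs.name: rs for rs in (MEPE_SCORE, ESUR_SCORE, MEPE_GRADE, EARLY_LATE_EPE)
}


def builtin_rulesets() -> dict[str, ScoreRuleSet]:
    """The four built-in rule sets, keyed by name."""
    return dict(_BUILTINS)


def get_ruleset(name: str) -> ScoreRuleSet:
    try:
        return _BUILTINS[name]
    except KeyError:
        raise KeyError(
            f"unknown ruleset {name!r}; built-ins: {', '.join(_BUILTINS)}"
        ) from None


def load_rulesets_config(path_or_stream) -> dict[str, ScoreRuleSet]:
    """Load user rule sets from a YAML config with a top-level ``rulesets:`` map.

    Each entry::

        rulesets:
          my-score:
            base_level: 1
            score_range: [1, 5]
            positivity_threshold: 3
            rules:
              - {level: 2, when: {flag: abutment}}
              ...
    """
    doc = yaml.safe_load(
        path_or_stream.read() if hasattr(path_or_stream, "read")
        else open(path_or_stream).read()
    )
    if not isinstance(doc, Mapping) or "rulesets" not in doc:
        raise ValueError("config must contain a top-level 'rulesets:' mapping")
    out: dict[str, ScoreRuleSet] = {}
    for name, body in doc["rulesets"].items():
        rules = tuple(
            (int(r["level"]), r["when"]) for r in body.get("rules", ())
        )
        out[name] = ScoreRuleSet(
            name=name,
            base_level=int(body["base_level"]),
            level_rules=rules,
            score_range=tuple(int(v) for v in body["score_range"]),
            positivity_threshold=int(body["positivity_threshold"]),
            provisional=bool(body.get("provisional", True)),
            description=str(body.get("description", "")),
        )
    return out


def compute_mepe_score(features: LesionFeatures) -> ScoreAssignment:
    """Assign the mEPE-score (1-5) and its positive call (score > 3).

    The rule ladder, highest satisfied level winning:

    =====  ==========================================================
    score  condition
    =====  ==========================================================
    1      no EPE feature (and interface <= 10 mm)
    2      capsular abutment
    3      irregular or spiculated margin
    4      one of bulging contour / NVB asymmetry / interface > 10 mm
    5      >= 2 of those three, or measurable extraprostatic disease
    =====  ==========================================================
    """
    severe = (
        features.bulging_contour
        + features.nvb_asymmetry
        + features.interface_gt10
    )
    if features.measurable_disease or severe >= 2:
        score = 5
    elif severe == 1:
        score = 4
    elif features.irregular_margin:
        score = 3
    elif features.capsular_abutment:
        score = 2
    else:
        score = 1
    return ScoreAssignment(score=score, positive_call=score > 3,
                           ruleset_name=MEPE_SCORE.name)


def compute_score(features: LesionFeatures, ruleset: ScoreRuleSet | str) -> ScoreAssignment:
    """Score one lesion under an arbitrary rule set (built-in name or table)."""
    rs = get_ruleset(ruleset) if isinstance(ruleset, str) else ruleset
    return rs.assign(features)


def score_cohort(
    records: Sequence[LesionFeatures], ruleset: ScoreRuleSet | str
) -> list[ScoreAssignment]:
    """Element-wise scoring of a cohort; order preserved, [] maps to []."""
    rs = get_ruleset(ruleset) if isinstance(ruleset, str) else ruleset
    return [rs.assign(f) for f in records]
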