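"""Fundamental movement skill (FMS) scoring for an adapted TGMD-2 battery.

Twelve skills, each scored on two trials against process criteria; the
adapted battery replaces the underhand roll with skipping.  Per-trial
maxima are 4 for most skills and 3 for leap, skip and bounce.  Skill
totals (two trials summed) roll up into locomotor, object-control and
total motor-competence scores; inter-rater checks use exact percent
agreement on per-trial scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

__all__ = [
    "SkillDefinition",
    "ADAPTED_TGMD2_SKILLS",
    "UNMODIFIED_TGMD2_SKILLS",
    "FmsScoreSheet",
    "SubsetScores",
    "skill_total",
    "subset_scores",
    "percent_agreement",
    "sheets_from_frame",
    "max_subset_scores",
]

LOCOMOTOR = "locomotor"
OBJECT_CONTROL = "object_control"


@dataclass(frozen=True)
class SkillDefinition:
    name: str
    subset: str
    max_per_trial: int

    def __post_init__(self):
        if self.subset not in (LOCOMOTOR, OBJECT_CONTROL):
            raise ValueError("subset must be locomotor or object_control")
        if self.max_per_trial not in (3, 4):
            raise ValueError("per-trial maxima are 3 or 4")


def _battery(defs: Iterable[tuple[str, str, int]]) -> tuple[SkillDefinition, ...]:
    return tuple(SkillDefinition(*d) for d in defs)


#: Default battery: skip added, underhand roll removed.
ADAPTED_TGMD2_SKILLS = _battery(
    [
        ("run", LOCOMOTOR, 4),
        ("gallop", LOCOMOTOR, 4),
        ("hop", LOCOMOTOR, 4),
        ("leap", LOCOMOTOR, 3),
        ("horizontal_jump", LOCOMOTOR, 4),
        ("skip", LOCOMOTOR, 3),
        ("slide", LOCOMOTOR, 4),
        ("strike", OBJECT_CONTROL, 4),
        ("bounce", OBJECT_CONTROL, 3),
        ("catch", OBJECT_CONTROL, 4),
        ("kick", OBJECT_CONTROL, 4),
        ("throw", OBJECT_CONTROL, 4),
    ]
)

#: The unmodified battery (no skip; underhand roll restored), for reuse.
UNMODIFIED_TGMD2_SKILLS = _battery(
    [
        ("run", LOCOMOTOR, 4),
        ("gallop", LOCOMOTOR, 4),
        ("hop", LOCOMOTOR, 4),
        ("leap", LOCOMOTOR, 3),
        ("horizontal_jump", LOCOMOTOR, 4),
        ("slide", LOCOMOTOR, 4),
        ("strike", OBJECT_CONTROL, 4),
        ("bounce", OBJECT_CONTROL, 3),
        ("catch", OBJECT_CONTROL, 4),
        ("kick", OBJECT_CONTROL, 4),
        ("throw", OBJECT_CONTROL, 4),
        ("underhand_roll", OBJECT_CONTROL, 4),
    ]
)


class SubsetScores(NamedTuple):
    locomotor: int
    object_control: int
    total: int


@dataclass(frozen=True)
class FmsScoreSheet:
    """Two-trial scores for one participant, keyed by skill name."""

    participant_id: str
    scores: Mapping[str, tuple[int, int]]
    battery: tuple[SkillDefinition, ...] = ADAPTED_TGMD2_SKILLS

    def skill(self, name: str) -> SkillDefinition:
        for s in self.battery:
            if s.name == name:
                return s
        raise KeyError(f"unknown skill {name!r}")


def skill_total(sheet: FmsScoreSheet, skill: str) -> int:
    """Sum of the two trial scores for one skill, validated against its maximum."""
    definition = sheet.skill(skill)
    if skill not in sheet.scores:
        raise ValueError(f"skill {skill!r} not scored for {sheet.participant_id}")
    t1, t2 = sheet.scores[skill]
    for trial, score in enumerate((t1, t2), start=1):
        if not float(score).is_integer() or score < 0 or score > definition.max_per_trial:
            raise ValueError(
                f"{skill!r} trial {trial} score {score} outside 0..{definition.max_per_trial}"
            )
    return int(t1) + int(t2)


def subset_scores(sheet: FmsScoreSheet) -> SubsetScores:
    """Locomotor, object-control and total motor-competence scores."""
    sums = {LOCOMOTOR: 0, OBJECT_CONTROL: 0}
    for definition in sheet.battery:
        if definition.name not in sheet.scores:
            raise ValueError(f"missing skill {definition.name!r} for {sheet.participant_id}")
        sums[definition.subset] += skill_total(sheet, definition.name)
    return SubsetScores(sums[LOCOMOTOR], sums[OBJECT_CONTROL], sums[LOCOMOTOR] + sums[OBJECT_CONTROL])


def max_subset_scores(battery: tuple[SkillDefinition, ...] = ADAPTED_TGMD2_SKILLS) -> SubsetScores:
    """Score ceilings implied by the battery (two trials per skill)."""
    loco = sum(2 * s.max_per_trial for s in battery if s.subset == LOCOMOTOR)
    obj = sum(2 * s.max_per_trial for s in battery if s.subset == OBJECT_CONTROL)
    return SubsetScores(loco, obj, loco + obj)


def percent_agreement(rater_a, rater_b):
    """Exact agreement between two raters' per-trial scores.

    Both arguments are iterables of :class:`FmsScoreSheet` covering the
    same participants and skills.  Returns ``(overall_pct, per_skill)``
    where ``per_skill`` maps skill name to its own percentage; each item
    is a per-trial score that either matches exactly or does not.
    """
    a_by_id = {s.participant_id: s for s in rater_a}
    b_by_id = {s.participant_id: s for s in rater_b}
    if set(a_by_id) != set(b_by_id):
        raise ValueError("raters scored different participant sets")
    if not a_by_id:
        raise ValueError("no sheets to compare")
    matches: dict[str, int] = {}
    counts: dict[str, int] = {}
    for pid, sa in a_by_id.items():
        sb = b_by_id[pid]
        if set(sa.scores) != set(sb.scores):
            raise ValueError(f"raters scored different skills for {pid}")
        for skill, pair_a in sa.scores.items():
            pair_b = sb.scores[skill]
            for ta, tb in zip(pair_a, pair_b):
                counts[skill] = counts.get(skill, 0) + 1
                matches[skill] = matches.get(skill, 0) + (ta == tb)
    per_skill = {k: 100.0 * matches[k] / counts[k] for k in sorted(counts)}
    overall = 100.0 * sum(matches.values()) / sum(counts.values())
    return overall, per_skill


def sheets_from_frame(
    frame: pd.DataFrame, battery: tuple[SkillDefinition, ...] = ADAPTED_TGMD2_SKILLS
) -> list[FmsScoreSheet]:
    """Read long-format score sheets (participant_id, skill, trial, score)."""
    needed = {"participant_id", "skill", "trial", "score"}
    if missing := needed - set(frame.columns):
        raise ValueError(f"score-sheet frame missing columns: {sorted(missing)}")
    sheets = []
    for pid, grp in frame.groupby("participant_id", sort=True):
        scores = {}
        for skill, g in grp.groupby("skill"):
            trials = g.set_index("trial")["score"]
            if set(trials.index) != {1, 2}:
                raise ValueError(f"{pid}/{skill}: need exactly trials 1 and 2")
            scores[skill] = (int(trials.loc[1]), int(trials.loc[2]))
        sheets.append(FmsScoreSheet(str(pid), scores, battery))
    return sheets
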