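"""Scoring engines for two parent-report developmental screeners.

The first instrument is a 20-item binary (yes/no) autism-specific checklist
with a structured follow-up stage. The count of at-risk answers on the
initial items maps to a risk tier (low 0-2, medium 3-7, high 8-20); the
follow-up confirms or clears each flagged item, and a final score of 2 or
more confirmed items is screen-positive. Two administration semantics are
supported:

* :func:`administer_interspersed` — the follow-up question for an item is
  asked immediately after a flagged answer, before the total is tallied, so
  every flagged item receives follow-up regardless of the eventual tier.
* :func:`administer_two_stage` — the standard procedure: follow-up only for
  medium-tier children; high tier is screen-positive outright; low tier is
  screen-negative outright.

The second instrument is a broad developmental questionnaire: 5 domains x 6
items each scored 0/5/10, with per-domain sums compared against age-normed
cutoffs ("refer" below the -2 SD equivalent, "monitor" between -2 and -1 SD).

Item content is never rendered here: items are abstract Q1..Q20 and domain
names; risk directions, labels and cutoffs come from config files
(:meth:`MChatKey.from_yaml`, :meth:`AsqCutoffs.from_yaml`).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import yaml

__all__ = [
    "ASQ_DOMAINS",
    "OUTCOME_NAMES",
    "N_MCHAT_ITEMS",
    "InputValidationError",
    "MChatKey",
    "MChatRecord",
    "TwoStageResult",
    "AsqCutoffs",
    "AsqRecord",
    "score_mchat_initial",
    "tier_for_count",
    "administer_interspersed",
    "administer_two_stage",
    "score_asq",
    "derive_outcomes",
]

N_MCHAT_ITEMS = 20

#: Domain order used everywhere (matches the questionnaire's published order).
ASQ_DOMAINS = (
    "gross_motor",
    "fine_motor",
    "personal_social",
    "problem_solving",
    "communication",
)

#: The six binary risk outcomes a predictor can target.
OUTCOME_NAMES = (
    "ASQ_GLOBAL",
    "MCHAT_R",
    "MCHAT_RF",
    "ASQ_PS",
    "ASQ_COMM",
    "ASQ_PS_OR_COMM",
)


class InputValidationError(ValueError):
    """Raised when an instrument record fails schema validation."""


def _data_path(name: str):
    return importlib.resources.files("askone.data").joinpath(name)


# ---------------------------------------------------------------------------
# 20-item checklist
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MChatKey:
    """Per-item risk directions for the 20-item checklist.

    ``risk_if_yes[i]`` is True when a "yes" answer to item ``i`` (0-based)
    indicates risk, False when "no" does.
    """

    risk_if_yes: tuple[bool, ...]
    labels: tuple[str, ...] = tuple(f"Q{i + 1}" for i in range(N_MCHAT_ITEMS))

    def __post_init__(self) -> None:
        if len(self.risk_if_yes) != N_MCHAT_ITEMS:
            raise InputValidationError(
                f"key must define {N_MCHAT_ITEMS} risk directions, "
                f"got {len(self.risk_if_yes)}"
            )
        if len(self.labels) != N_MCHAT_ITEMS:
            raise InputValidationError("key must define 20 item labels")

    @classmethod
    def default(cls) -> "MChatKey":
        """The bundled key following the published scoring convention."""
        with importlib.resources.as_file(_data_path("mchat_key.yaml")) as p:
            return cls.from_yaml(p)

    @classmethod
    def from_yaml(cls, path) -> "MChatKey":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        riy = raw["risk_if_yes"]
        directions = tuple(bool(riy[f"Q{i + 1}"]) for i in range(N_MCHAT_ITEMS))
        labels_raw = raw.get("labels", {})
        labels = tuple(
            str(labels_raw.get(f"Q{i + 1}", f"Q{i + 1}")) for i in range(N_MCHAT_ITEMS)
        )
        return cls(directions, labels)

    def risk_flags(self, responses: Sequence[int]) -> tuple[bool, ...]:
        """Map yes(1)/no(0) answers to per-item at-risk flags."""
        _validate_responses(responses)
        return tuple(
            bool(r) == self.risk_if_yes[i] for i, r in enumerate(responses)
        )


def _validate_responses(responses: Sequence[int]) -> None:
    if len(responses) != N_MCHAT_ITEMS:
        raise InputValidationError(
            f"expected {N_MCHAT_ITEMS} item responses, got {len(responses)}"
        )
    for i, r in enumerate(responses):
        if r is None or r not in (0, 1, True, False):
            raise InputValidationError(
                f"item {i + 1}: response must be binary (0/1), got {r!r}"
            )


def tier_for_count(count: int) -> str:
    """Risk tier from the initial at-risk count: low 0-2, medium 3-7, high 8-20."""
    if not 0 <= count <= N_MCHAT_ITEMS:
        raise InputValidationError(f"count must be in 0..{N_MCHAT_ITEMS}, got {count}")
    if count <= 2:
        return "low"
    if count <= 7:
        return "medium"
    return "high"


def score_mchat_initial(
    responses: Sequence[int], key: MChatKey
) -> tuple[int, str]:
    """Score the initial 20 items: (at-risk count, tier)."""
    flags = key.risk_flags(responses)
    count = sum(flags)
    return count, tier_for_count(count)


@dataclass(frozen=True)
class MChatRecord:
    """A fully scored checklist under interspersed follow-up administration."""

    responses: tuple[int, ...]
    initial_count: int
    tier: str
    followup_confirmed: Mapping[int, bool]  # keyed by 0-based flagged item index
    final_score: int
    at_risk_rf: bool


def _resolve_followup(
    followup: Mapping[int, bool] | Callable[[int], bool], item: int
) -> bool:
    if callable(followup):
        return bool(followup(item))
    try:
        return bool(followup[item])
    except KeyError:
        raise InputValidationError(
            f"follow-up response missing for flagged item {item + 1}"
        ) from None


def administer_interspersed(
    responses: Sequence[int],
    key: MChatKey,
    followup: Mapping[int, bool] | Callable[[int], bool],
) -> MChatRecord:
    """Interspersed administration: follow-up immediately after each flagged item.

    Every flagged item receives its follow-up before any tier is tallied, so
    even low- and high-tier children have follow-up data. ``final_score`` is
    the number of flagged items whose follow-up confirms risk;
    ``at_risk_rf`` is ``final_score >= 2``.
    """
    flags = key.risk_flags(responses)
    confirmed: dict[int, bool] = {}
    for i, flagged in enumerate(flags):
        if flagged:
            confirmed[i] = _resolve_followup(followup, i)
    initial_count = sum(flags)
    final_score = sum(confirmed.values())
    return MChatRecord(
        responses=tuple(int(bool(r)) for r in responses),
        initial_count=initial_count,
        tier=tier_for_count(initial_count),
        followup_confirmed=confirmed,
        final_score=final_score,
        at_risk_rf=final_score >= 2,
    )


@dataclass(frozen=True)
class TwoStageResult:
    """Standard two-stage administration outcome.

    ``final_score`` is defined only for medium-tier children (None otherwise):
    low tier is screen-negative and high tier screen-positive without
    follow-up.
    """

    initial_count: int
    tier: str
    final_score: int | None
    at_risk: bool


def administer_two_stage(
    responses: Sequence[int],
    key: MChatKey,
    followup: Mapping[int, bool] | Callable[[int], bool],
) -> TwoStageResult:
    flags = key.risk_flags(responses)
    initial_count = sum(flags)
    tier = tier_for_count(initial_count)
    if tier == "low":
        return TwoStageResult(initial_count, tier, None, False)
    if tier == "high":
        return TwoStageResult(initial_count, tier, None, True)
    final = sum(
        _resolve_followup(followup, i) for i, flagged in enumerate(flags) if flagged
    )
    return TwoStageResult(initial_count, tier, final, final >= 2)


# ---------------------------------------------------------------------------
# 5-domain developmental questionnaire
# ---------------------------------------------------------------------------

_VALID_ITEM_SCORES = (0, 5, 10)


@dataclass(frozen=True)
class AsqCutoffs:
    """Per-domain (refer, monitor) cutoffs for one age version.

    ``refer`` is the score equivalent of -2 SD, ``monitor`` of -1 SD;
    0 <= refer < monitor <= 60 for each of the 5 domains.
    """

    cutoffs: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        missing = set(ASQ_DOMAINS) - set(self.cutoffs)
        if missing:
            raise InputValidationError(f"cutoffs missing domains: {sorted(missing)}")
        for dom in ASQ_DOMAINS:
            refer, monitor = self.cutoffs[dom]
            if not (0 <= refer < monitor <= 60):
                raise InputValidationError(
                    f"domain {dom}: require 0 <= refer < monitor <= 60, "
                    f"got ({refer}, {monitor})"
                )

    @classmethod
    def default(cls) -> "AsqCutoffs":
        with importlib.resources.as_file(
            _data_path("asq_cutoffs_default.yaml")
        ) as p:
            return cls.from_yaml(p)

    @classmethod
    def from_yaml(cls, path) -> "AsqCutoffs":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        table = {
            dom: (float(v["refer"]), float(v["monitor"]))
            for dom, v in raw["cutoffs"].items()
        }
        return cls(table)


@dataclass(frozen=True)
class AsqRecord:
    items: Mapping[str, tuple[int, ...]]
    domain_sums: Mapping[str, int]
    domain_class: Mapping[str, str]  # refer / monitor / ok
    global_risk: bool


def score_asq(
    items: Mapping[str, Sequence[int]], cutoffs: AsqCutoffs
) -> AsqRecord:
    """Score the 5x6-item questionnaire against per-domain cutoffs.

    ``items`` maps each domain name to its 6 item scores in {0, 5, 10}.
    A domain is classified "refer" when its sum falls below the refer cutoff,
    "monitor" between the two cutoffs, "ok" otherwise; ``global_risk`` is
    True iff at least one domain is "refer".
    """
    missing = set(ASQ_DOMAINS) - set(items)
    if missing:
        raise InputValidationError(f"items missing domains: {sorted(missing)}")
    sums: dict[str, int] = {}
    classes: dict[str, str] = {}
    clean: dict[str, tuple[int, ...]] = {}
    for dom in ASQ_DOMAINS:
        scores = tuple(items[dom])
        if len(scores) != 6:
            raise InputValidationError(
                f"domain {dom}: expected 6 item scores, got {len(scores)}"
            )
        for k, s in enumerate(scores):
            if s not in _VALID_ITEM_SCORES:
                raise InputValidationError(
                    f"domain {dom}, item {k + 1}: score must be one of "
                    f"{_VALID_ITEM_SCORES}, got {s!r}"
                )
        total = int(sum(scores))
        refer, monitor = cutoffs.cutoffs[dom]
        if total < refer:
            cls_ = "refer"
        elif total < monitor:
            cls_ = "monitor"
        else:
            cls_ = "ok"
        clean[dom] = scores
        sums[dom] = total
        classes[dom] = cls_
    return AsqRecord(
        items=clean,
        domain_sums=sums,
        domain_class=classes,
        global_risk=any(c == "refer" for c in classes.values()),
    )


# ---------------------------------------------------------------------------
# Risk outcomes
# ---------------------------------------------------------------------------


def derive_outcomes(mchat: MChatRecord, asq: AsqRecord) -> dict[str, int]:
    """Derive the six binary risk outcomes from scored records.

    * ``ASQ_GLOBAL`` — refer in at least one domain.
    * ``MCHAT_R`` — initial tier medium or high.
    * ``MCHAT_RF`` — follow-up final score >= 2.
    * ``ASQ_PS`` / ``ASQ_COMM`` — refer on personal-social / communication.
    * ``ASQ_PS_OR_COMM`` — logical OR of the previous two.
    """
    ps = int(asq.domain_class["personal_social"] == "refer")
    comm = int(asq.domain_class["communication"] == "refer")
    return {
        "ASQ_GLOBAL": int(asq.global_risk),
        "MCHAT_R": int(mchat.tier in ("medium", "high")),
        "MCHAT_RF": int(mchat.at_risk_rf),
        "ASQ_PS": ps,
        "ASQ_COMM": comm,
        "ASQ_PS_OR_COMM": int(bool(ps or comm)),
    }
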