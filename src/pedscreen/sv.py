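"""Structural-variant recurrence screen.

"Recurrence" (rec) of an event in a phenotype group is the number of group
members carrying it. An event is retained when every required group meets
its recurrence threshold (>=) and, by default, no member of an excluded
group (the unaffected control) carries it. Retained events are flagged by
region class rather than silently dropped when exonic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .pedigree import Pedigree, Phenotype
from .variants import sv_member_columns


class SvRuleError(ValueError):
    """Raised for invalid recurrence-rule configuration."""


@dataclass
class RecurrenceRule:
    """Per-group recurrence thresholds with control exclusion.

    Defaults require the event in >= 5 cancer (MPLC) members and >= 9
    nodule members, and absent from every unaffected member.
    """

    min_rec: dict[Phenotype, int] = field(
        default_factory=lambda: {Phenotype.MPLC: 5, Phenotype.NODULE: 9}
    )
    exclude_groups: frozenset = frozenset({Phenotype.UNAFFECTED})
    require_absent_in_excluded: bool = True

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.min_rec.values()):
            raise SvRuleError("min_rec counts must be >= 0")
        for grp in list(self.min_rec) + list(self.exclude_groups):
            if not isinstance(grp, Phenotype):
                raise SvRuleError(f"unknown group label {grp!r}")


def recurrence_counts(events: pd.DataFrame, pedigree: Pedigree) -> pd.DataFrame:
    """Per-event carrier counts within each phenotype group.

    Returns a frame indexed by event id with one ``rec_<CLASS>`` column per
    phenotype class present in the pedigree.
    """
    member_cols = sv_member_columns(events)
    if set(member_cols) != set(pedigree.member_ids):
        raise ValueError("SV presence columns do not match pedigree members")
    out = pd.DataFrame(index=events["id"])
    for cls in Phenotype:
        group = pedigree.members_in_class(cls)
        if group:
            out[f"rec_{cls.value}"] = events[group].sum(axis=1).to_numpy()
    return out


def screen_sv(
    events: pd.DataFrame, pedigree: Pedigree, rule: RecurrenceRule | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the recurrence screen; returns (retained events, verdict trail).

    The verdict trail has one row per input event with its group counts and
    pass/fail per criterion; the screen is invariant to event and member
    order.
    """
    rule = rule or RecurrenceRule()
    counts = recurrence_counts(events, pedigree)
    trail = counts.copy()
    passed = pd.Series(True, index=counts.index)
    for cls, need in rule.min_rec.items():
        col = f"rec_{cls.value}"
        if col not in counts.columns:
            raise SvRuleError(f"pedigree has no members in required group {cls.value}")
        ok = counts[col] >= need
        trail[f"meets_min_{cls.value}"] = ok.to_numpy()
        passed &= ok
    if rule.require_absent_in_excluded:
        for cls in rule.exclude_groups:
            col = f"rec_{cls.value}"
            if col in counts.columns:
                ok = counts[col] == 0
                trail[f"absent_in_{cls.value}"] = ok.to_numpy()
                passed &= ok
    trail["passed"] = passed.to_numpy()
    retained = events[passed.reindex(events["id"]).to_numpy()].reset_index(drop=True)
    return retained, trail.reset_index()


def region_flag(events: pd.DataFrame) -> pd.DataFrame:
    """Annotate events as exonic / non_exonic / unknown (pass-through flag).

    Downstream reports separate exonic from non-exonic candidates rather
    than dropping either; an absent region class becomes "unknown".
    """
    flagged = events.copy()
    flagged["region_flag"] = [
        "unknown" if pd.isna(rc) or rc == "" else str(rc) for rc in events["region_class"]
    ]
    return flagged
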