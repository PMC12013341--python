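"""Scoring of the shortened self-report scales administered pre/mid/post.

Five abbreviated instruments: SUDS (5 items, 1-7, subjective distress),
PSS (5 items, 0-4, perceived stress), SMS (6 items, 1-5, state
mindfulness), ASC (9 items, 0-100 slider, altered states of
consciousness), and SCS (4 items, 1-6, social connectedness). A scale
total is the sum of its item responses after optional reverse-coding;
change scores are post minus pre; internal consistency is Cronbach's
alpha.

Reverse-coding is off by default: with the shortened instruments it is
not documented which items were reverse-keyed, and raw sums mirror the
reported direction-of-change results. ``scale_definitions(reverse_coded=
True)`` enables the standard sets (PSS item 5, which is positively worded,
and all four SCS items, which are negatively worded).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ScaleDefinition",
    "SCALES",
    "scale_definitions",
    "score_scale",
    "score_survey",
    "diff_scores",
    "cronbach_alpha",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """One instrument: item count, response range, and reverse-keyed items.

    ``reverse_items`` holds 1-based item indices; a reversed response x
    becomes ``minimum + maximum - x``.
    """

    name: str
    n_items: int
    minimum: float
    maximum: float
    reverse_items: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.n_items < 1 or self.minimum >= self.maximum:
            raise ValueError("invalid scale definition")
        if not all(1 <= i <= self.n_items for i in self.reverse_items):
            raise ValueError("reverse item index out of range")

    @property
    def total_range(self) -> tuple[float, float]:
        return self.n_items * self.minimum, self.n_items * self.maximum


#: Default (no reverse-coding) definitions of the shortened instruments.
SCALES: dict[str, ScaleDefinition] = {
    "suds": ScaleDefinition("suds", 5, 1, 7),
    "pss": ScaleDefinition("pss", 5, 0, 4),
    "sms": ScaleDefinition("sms", 6, 1, 5),
    "asc": ScaleDefinition("asc", 9, 0, 100),
    "scs": ScaleDefinition("scs", 4, 1, 6),
}

#: Standard reverse-keyed sets, applied when reverse coding is enabled.
_REVERSE_SETS = {"pss": frozenset({5}), "scs": frozenset({1, 2, 3, 4})}


def scale_definitions(reverse_coded: bool = False) -> dict[str, ScaleDefinition]:
    """The five shortened scales, optionally with standard reverse-keying."""
    if not reverse_coded:
        return dict(SCALES)
    return {
        name: replace(sc, reverse_items=_REVERSE_SETS.get(name, frozenset()))
        for name, sc in SCALES.items()
    }


def score_scale(responses, scale: ScaleDefinition) -> float:
    """Sum of item values after reverse-coding; no silent imputation.

    Raises on a missing item, a wrong item count, or an out-of-range value.
    """
    vals = np.asarray(responses, dtype=float)
    if vals.shape != (scale.n_items,):
        raise ValueError(
            f"{scale.name}: expected {scale.n_items} item responses, got {vals.shape}"
        )
    if np.isnan(vals).any():
        raise ValueError(f"{scale.name}: missing item response")
    if vals.min() < scale.minimum or vals.max() > scale.maximum:
        raise ValueError(
            f"{scale.name}: response outside [{scale.minimum}, {scale.maximum}]"
        )
    for i in scale.reverse_items:
        vals[i - 1] = scale.minimum + scale.maximum - vals[i - 1]
    return float(vals.sum())


def score_survey(
    responses: pd.DataFrame, scales: dict[str, ScaleDefinition] | None = None
) -> pd.DataFrame:
    """Score a tidy item table into totals per participant x timepoint x scale.

    Expects columns participant, timepoint, scale, item, value (the dialect
    the synthetic generator writes).
    """
    scales = scales or SCALES
    rows = []
    for (pid, tp, name), grp in responses.groupby(["participant", "timepoint", "scale"]):
        sc = scales[name]
        vals = grp.sort_values("item")["value"].to_numpy()
        rows.append(
            {
                "participant": pid,
                "timepoint": tp,
                "scale": name,
                "total": score_scale(vals, sc),
            }
        )
    return pd.DataFrame(rows)


def diff_scores(scored: pd.DataFrame) -> pd.DataFrame:
    """Post-minus-pre change per participant and scale.

    Raises if any participant x scale cell lacks a matched pre or post total.
    """
    wide = scored.pivot_table(
        index=["participant", "scale"], columns="timepoint", values="total", aggfunc="first"
    )
    for col in ("pre", "post"):
        if col not in wide.columns or wide[col].isna().any():
            bad = wide.index[wide[col].isna()].tolist() if col in wide.columns else "all"
            raise ValueError(f"unmatched {col} timepoint for {bad}")
    out = wide.reset_index()[["participant", "scale"]]
    out["diff"] = (wide["post"] - wide["pre"]).to_numpy()
    return out


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances)/variance(totals)).

    ``items`` is respondents x items. Sample variances (N-1). Returns NaN
    when the total score has zero variance (alpha is undefined).
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 respondents and >= 2 items")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1 - item_var.sum() / total_var))
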