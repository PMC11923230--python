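"""Pollinator-preference statistics for two-morph bee choice trials.

Naive bumblebee workers forage in a flight cage holding equal numbers of
yellow- and red-morph flowers of one species; every intentional corolla
contact is a visit, corolla-tube entries are probes, and handling time is
recorded per visit. Preference is tested by a chi-square goodness-of-fit of
pooled counts against the 50:50 null (no continuity correction, matching
the convention under which a 59:30 split gives chi^2 = 9.45), plus a
first-choice test over each bee's earliest visit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd
from scipy import stats

MORPHS = ("yellow", "red")

Metric = Literal["visits", "probes", "handling_time", "first_choice"]


@dataclass(frozen=True)
class ChoiceEvent:
    morph: str
    probed: bool = False
    handling_seconds: float = 0.0

    def __post_init__(self) -> None:
        if self.morph not in MORPHS:
            raise ValueError(f"morph must be one of {MORPHS}, got {self.morph!r}")
        if not self.handling_seconds >= 0:
            raise ValueError("handling_seconds must be finite and >= 0")


@dataclass(frozen=True)
class ChoiceTrial:
    """Ordered visit events for one bee in one species-pair trial.

    A trial with no events records a bee that failed to forage; it is kept
    in the log but excluded from successful-trial statistics.
    """

    bee_id: str
    species_pair: str
    events: tuple[ChoiceEvent, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "events",
            tuple(e if isinstance(e, ChoiceEvent) else ChoiceEvent(*e) for e in self.events),
        )

    @property
    def successful(self) -> bool:
        return len(self.events) > 0


@dataclass(frozen=True)
class PreferenceResult:
    n_yellow: float
    n_red: float
    chi_square: float
    df: int
    p: float

    @property
    def proportion_yellow(self) -> float:
        return self.n_yellow / (self.n_yellow + self.n_red)


def successful_trials(trials: Iterable[ChoiceTrial]) -> list[ChoiceTrial]:
    return [t for t in trials if t.successful]


def pool_counts(trials: Sequence[ChoiceTrial], metric: Metric = "visits") -> dict[str, float]:
    """Pool a choice metric across the successful trials of one species pair.

    visits: event counts; probes: events with the probed flag;
    handling_time: summed handling seconds rounded to whole seconds;
    first_choice: one count per bee, from its earliest event.
    """
    trials = successful_trials(trials)
    if not trials:
        raise ValueError("no successful trials to pool")
    pairs = {t.species_pair for t in trials}
    if len(pairs) > 1:
        raise ValueError(f"trials span multiple species pairs: {sorted(pairs)}")
    counts = {m: 0.0 for m in MORPHS}
    for t in trials:
        if metric == "first_choice":
            counts[t.events[0].morph] += 1
            continue
        for e in t.events:
            if metric == "visits":
                counts[e.morph] += 1
            elif metric == "probes":
                counts[e.morph] += int(e.probed)
            elif metric == "handling_time":
                counts[e.morph] += e.handling_seconds
            else:
                raise ValueError(f"unknown metric {metric!r}")
    if metric == "handling_time":
        counts = {m: round(v) for m, v in counts.items()}
    return counts


def chisq_gof(n_yellow: float, n_red: float) -> PreferenceResult:
    """Chi-square goodness of fit against the 50:50 no-preference null.

    E = (n_yellow + n_red)/2; chi^2 = sum (O - E)^2 / E on 1 df; p is the
    upper tail of chi^2_1. No Yates continuity correction.
    """
    if n_yellow < 0 or n_red < 0:
        raise ValueError("counts must be >= 0")
    total = n_yellow + n_red
    if total < 1:
        raise ValueError("need at least one observation")
    expected = total / 2.0
    chi2 = (n_yellow - expected) ** 2 / expected + (n_red - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    return PreferenceResult(n_yellow=n_yellow, n_red=n_red, chi_square=float(chi2), df=1, p=p)


def preference_test(trials: Sequence[ChoiceTrial], metric: Metric = "visits") -> PreferenceResult:
    counts = pool_counts(trials, metric)
    return chisq_gof(counts["yellow"], counts["red"])


def first_choice_test(trials: Sequence[ChoiceTrial]) -> PreferenceResult:
    """Goodness-of-fit test of each bee's first (naive) choice."""
    return preference_test(trials, metric="first_choice")


def per_bee_summary(trials: Sequence[ChoiceTrial]) -> pd.DataFrame:
    """One row per bee: visit/probe counts and handling totals per morph,
    plus the proportion of visits to yellow. Pooled margins equal
    :func:`pool_counts` output."""
    rows = []
    for t in trials:
        row = {"bee_id": t.bee_id, "species_pair": t.species_pair, "successful": t.successful}
        for m in MORPHS:
            ev = [e for e in t.events if e.morph == m]
            row[f"visits_{m}"] = len(ev)
            row[f"probes_{m}"] = sum(e.probed for e in ev)
            row[f"handling_{m}"] = sum(e.handling_seconds for e in ev)
        n = len(t.events)
        row["proportion_yellow"] = row["visits_yellow"] / n if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_trials(path) -> list[ChoiceTrial]:
    """Read an event-log CSV (bee_id, species_pair, event_order, morph,
    probed, handling_seconds) into trials; bees present in the log with no
    events (empty morph) become unsuccessful trials."""
    df = pd.read_csv(path, dtype={"bee_id": str, "species_pair": str}, keep_default_na=False)
    trials = []
    for (bee, pair), sub in df.groupby(["bee_id", "species_pair"], sort=False):
        sub = sub.sort_values("event_order")
        events = tuple(
            ChoiceEvent(r.morph, bool(int(r.probed)), float(r.handling_seconds))
            for r in sub.itertuples()
            if str(r.morph) in MORPHS
        )
        trials.append(ChoiceTrial(bee_id=bee, species_pair=pair, events=events))
    return trials
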