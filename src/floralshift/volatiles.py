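"""GC-MS floral volatile processing.

Headspace volatile samples arrive as vendor-integrated peak tables: one row
per detected peak with a retention time, an area under the curve, and the
three top-ranked tentative library identifications. Sensitive default
integration settings detect far more peaks than are biologically real, so a
filter cascade removes (1) tiny peaks, (2) late-eluting heavy compounds
unlikely to be airborne attractants, (3) peaks explained by the paired
ambient blank, and (4) peaks whose every library hit is a known instrument
contaminant (siloxanes from the column, phthalates from plasticware).
Surviving peaks are assigned Kovats retention indices against an n-alkane
ladder, quantified to ng per flower per hour through per-compound standard
curves, and summarised as per-sample totals and between-group fold changes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("floralshift.volatiles")

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakRecord:
    """One detected GC-MS peak.

    Parameters
    ----------
    sample_id : str
        Identifier of the sample (or blank) run the peak was detected in.
    retention_time : float
        Elution time in minutes; finite and non-negative.
    area : float
        Integrated area under the curve in detector counts; non-negative.
    library_hits : tuple of 3 str
        Top three tentative library identifications, ordered by match rank.
        Empty strings mark absent hits.
    is_blank : bool
        True when the peak comes from an ambient blank run.
    """

    sample_id: str
    retention_time: float
    area: float
    library_hits: tuple[str, str, str]
    is_blank: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.retention_time) or self.retention_time < 0:
            raise ValueError(
                f"retention_time must be finite and >= 0, got {self.retention_time!r}"
            )
        if not math.isfinite(self.area) or self.area < 0:
            raise ValueError(f"area must be finite and >= 0, got {self.area!r}")
        hits = tuple(self.library_hits)
        if len(hits) != 3:
            raise ValueError(f"library_hits must have exactly 3 entries, got {len(hits)}")
        object.__setattr__(self, "library_hits", hits)

    @property
    def top_hit(self) -> str:
        return self.library_hits[0]


@dataclass(frozen=True)
class AlkaneLadder:
    """Retention times of a co-run n-alkane ladder.

    ``rungs`` is a sequence of (carbon_number, retention_time_minutes) pairs,
    strictly increasing in both fields, with at least two rungs.
    """

    rungs: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        rungs = tuple((int(c), float(t)) for c, t in self.rungs)
        if len(rungs) < 2:
            raise ValueError("alkane ladder needs at least 2 rungs")
        carbons = [c for c, _ in rungs]
        times = [t for _, t in rungs]
        if any(c < 5 for c in carbons):
            raise ValueError("carbon numbers below C5 are not supported")
        if any(b <= a for a, b in zip(carbons, carbons[1:])):
            raise ValueError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("retention times must be strictly increasing")
        object.__setattr__(self, "rungs", rungs)

    @property
    def span(self) -> tuple[float, float]:
        return self.rungs[0][1], self.rungs[-1][1]


@dataclass(frozen=True)
class StandardCurve:
    """Linear response curve area = slope * ng + intercept for one compound."""

    compound: str
    slope: float  # area counts per ng, > 0
    intercept: float = 0.0
    source: str = "authentic standard"  # or "structural surrogate"

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"slope must be > 0, got {self.slope!r}")


@dataclass(frozen=True)
class EmissionRecord:
    """Quantified emission of one compound in one sample (ng/flower/hour)."""

    sample_id: str
    compound: str
    emission: float
    kovats_ri: float | None = None

    def __post_init__(self) -> None:
        if not self.emission >= 0:
            raise ValueError(f"emission must be >= 0, got {self.emission!r}")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the peak-filter cascade.

    Thresholds stated as "under X" / "after Y" are applied strictly, so a
    peak exactly at a boundary is retained.
    """

    min_area: float = 1e5
    max_retention: float = 30.0  # minutes
    blank_rt_window: float = 0.1  # minutes
    blank_fold: float = 5.0
    contaminant_terms: tuple[str, ...] = ("silox", "silic", "phthal")
    # blank matching compares the top-ranked hit by default; "any" matches on
    # any of the three hits.
    blank_match: str = "top"
    # optional spectral-similarity stage (OFF by default): when set, peaks
    # whose similarity score to the nearest blank peak exceeds the threshold
    # are removed in filter_spectral_similarity.
    spectral_similarity_threshold: float | None = None

    def __post_init__(self) -> None:
        for name in ("min_area", "max_retention", "blank_rt_window", "blank_fold"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.blank_match not in ("top", "any"):
            raise ValueError("blank_match must be 'top' or 'any'")


def _validate_peaks(peaks: Iterable[PeakRecord]) -> list[PeakRecord]:
    out = list(peaks)
    for p in out:
        if not isinstance(p, PeakRecord):
            raise TypeError(f"expected PeakRecord, got {type(p).__name__}")
    return out


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------


def filter_area(peaks: Sequence[PeakRecord], config: FilterConfig = FilterConfig()) -> list[PeakRecord]:
    """Drop peaks with area strictly under ``config.min_area``.

    Order is preserved and the input is not modified. A peak with area
    exactly at the threshold is retained.
    """
    peaks = _validate_peaks(peaks)
    kept = [p for p in peaks if p.area >= config.min_area]
    for p in peaks:
        if p.area < config.min_area:
            logger.info("area filter removed %s rt=%.3f area=%.3g", p.sample_id, p.retention_time, p.area)
    return kept


def filter_retention(peaks: Sequence[PeakRecord], config: FilterConfig = FilterConfig()) -> list[PeakRecord]:
    """Drop peaks eluting strictly after ``config.max_retention`` minutes."""
    peaks = _validate_peaks(peaks)
    kept = [p for p in peaks if p.retention_time <= config.max_retention]
    for p in peaks:
        if p.retention_time > config.max_retention:
            logger.info("retention filter removed %s rt=%.3f", p.sample_id, p.retention_time)
    return kept


def _blank_hit_match(sample: PeakRecord, blank: PeakRecord, config: FilterConfig) -> bool:
    if config.blank_match == "top":
        return sample.top_hit == blank.top_hit and sample.top_hit != ""
    sample_hits = {h for h in sample.library_hits if h}
    blank_hits = {h for h in blank.library_hits if h}
    return bool(sample_hits & blank_hits)


def filter_blank_matched(
    peaks: Sequence[PeakRecord],
    blank_peaks: Sequence[PeakRecord],
    config: FilterConfig = FilterConfig(),
) -> tuple[list[PeakRecord], list[tuple[PeakRecord, PeakRecord]]]:
    """Remove sample peaks explained by the paired ambient blank.

    A sample peak is removed iff some blank peak shares its top-ranked
    library identification, elutes within ``blank_rt_window`` minutes, and
    the sample area is less than ``blank_fold`` times the blank area.

    Returns
    -------
    retained : list of PeakRecord
    removed : list of (sample peak, triggering blank peak)
    """
    peaks = _validate_peaks(peaks)
    blank_peaks = _validate_peaks(blank_peaks)
    if not blank_peaks:
        warnings.warn("empty blank peak set: all sample peaks retained", stacklevel=2)
        return list(peaks), []
    retained: list[PeakRecord] = []
    removed: list[tuple[PeakRecord, PeakRecord]] = []
    for p in peaks:
        trigger = None
        for b in blank_peaks:
            if (
                _blank_hit_match(p, b, config)
                and abs(p.retention_time - b.retention_time) <= config.blank_rt_window
                and p.area < config.blank_fold * b.area
            ):
                trigger = b
                break
        if trigger is None:
            retained.append(p)
        else:
            removed.append((p, trigger))
            logger.info(
                "blank filter removed %s '%s' rt=%.3f (blank rt=%.3f area ratio %.2f)",
                p.sample_id, p.top_hit, p.retention_time, trigger.retention_time,
                p.area / trigger.area if trigger.area else float("inf"),
            )
    return retained, removed


def filter_contaminants(
    peaks: Sequence[PeakRecord], config: FilterConfig = FilterConfig()
) -> list[PeakRecord]:
    """Drop peaks whose ALL THREE library hits contain a contaminant term.

    Matching is case-insensitive substring; a single clean hit retains the
    peak.
    """
    peaks = _validate_peaks(peaks)
    terms = tuple(t.lower() for t in config.contaminant_terms)

    def contaminated(hit: str) -> bool:
        h = hit.lower()
        return any(t in h for t in terms)

    kept = []
    for p in peaks:
        if all(contaminated(h) for h in p.library_hits):
            logger.info("contaminant filter removed %s hits=%s", p.sample_id, p.library_hits)
        else:
            kept.append(p)
    return kept


def filter_spectral_similarity(
    peaks: Sequence[PeakRecord],
    similarity: Mapping[int, float],
    config: FilterConfig = FilterConfig(),
) -> list[PeakRecord]:
    """Optional stage replacing manual visual comparison of uncertain spectra.

    ``similarity`` maps the index of a peak (in ``peaks``) to a spectral
    similarity score against its nearest blank peak. Peaks whose score is at
    or above ``config.spectral_similarity_threshold`` are removed. When the
    threshold is None (default) the stage is a no-op.
    """
    peaks = _validate_peaks(peaks)
    if config.spectral_similarity_threshold is None:
        return list(peaks)
    thr = config.spectral_similarity_threshold
    return [p for i, p in enumerate(peaks) if similarity.get(i, 0.0) < thr]


def filter_cascade(
    peaks: Sequence[PeakRecord],
    blank_peaks: Sequence[PeakRecord],
    config: FilterConfig = FilterConfig(),
) -> list[PeakRecord]:
    """Full cascade: area -> retention -> blank match -> contaminants.

    Each predicate depends only on the individual peak and the fixed blank
    table, so the retained set equals the conjunction of the four predicates
    regardless of stage order.
    """
    out = filter_area(peaks, config)
    out = filter_retention(out, config)
    out, _ = filter_blank_matched(out, blank_peaks, config)
    out = filter_contaminants(out, config)
    return out


# ---------------------------------------------------------------------------
# Kovats retention index
# ---------------------------------------------------------------------------


def kovats_index(rt: float, ladder: AlkaneLadder) -> float:
    """Kovats retention index under the linear temperature-programmed
    (van den Dool & Kratz) convention.

    For rt bracketed by the rungs of carbon numbers n and n+? the index is
    ``100*n + 100*(rt - t_n) / (t_next - t_n) * (n_next - n)``; with a ladder
    of consecutive alkanes this reduces to the familiar
    ``100*n + 100*(rt - t_n)/(t_{n+1} - t_n)``. Piecewise linear, continuous,
    strictly increasing inside the ladder span, and exactly ``100*n`` at
    every rung.
    """
    lo, hi = ladder.span
    if not (lo <= rt <= hi):
        raise ValueError(
            f"retention time {rt:.4f} min outside ladder span [{lo:.4f}, {hi:.4f}] min"
        )
    rungs = ladder.rungs
    for (c0, t0), (c1, t1) in zip(rungs, rungs[1:]):
        if t0 <= rt <= t1:
            return 100.0 * c0 + 100.0 * (c1 - c0) * (rt - t0) / (t1 - t0)
    raise AssertionError("unreachable: rt inside span must be bracketed")


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------


def emission_scaling(flowers: int = 2, hours: float = 24.0, calibration: float = 1.0) -> float:
    """Per-sample divisor converting back-calculated ng to ng/flower/hour.

    The default sampling design encloses 2 flowers for 24 h; ``calibration``
    absorbs elution volume, aliquot concentration and injection volume into
    a single per-run factor (default 1).
    """
    if flowers <= 0 or hours <= 0 or calibration <= 0:
        raise ValueError("flowers, hours and calibration must all be > 0")
    return flowers * hours * calibration


def quantify(
    peak: PeakRecord,
    curve: StandardCurve,
    scaling: float = 48.0,
    kovats_ri: float | None = None,
) -> EmissionRecord:
    """Convert a peak area to an emission rate through a standard curve.

    mass_ng = max(0, (area - intercept) / slope); emission = mass_ng / scaling.
    A negative back-calculated mass clips to zero with a warning.
    """
    if scaling <= 0:
        raise ValueError("scaling must be > 0")
    mass_ng = (peak.area - curve.intercept) / curve.slope
    if mass_ng < 0:
        warnings.warn(
            f"negative back-calculated mass for {curve.compound!r} in "
            f"{peak.sample_id!r}; clipping to 0",
            stacklevel=2,
        )
        mass_ng = 0.0
    return EmissionRecord(
        sample_id=peak.sample_id,
        compound=curve.compound,
        emission=mass_ng / scaling,
        kovats_ri=kovats_ri,
    )


def quantify_peaks(
    peaks: Sequence[PeakRecord],
    curves: Mapping[str, StandardCurve],
    surrogates: Mapping[str, str] | None = None,
    scaling: float = 48.0,
    ladder: AlkaneLadder | None = None,
) -> list[EmissionRecord]:
    """Quantify each peak by its top library hit.

    Compounds without an authentic standard curve are quantified through the
    named structural surrogate in ``surrogates`` (compound -> surrogate
    compound). A compound with neither raises an error naming it.
    """
    surrogates = surrogates or {}
    records = []
    for p in peaks:
        name = p.top_hit
        curve = curves.get(name)
        if curve is None:
            surrogate = surrogates.get(name)
            if surrogate is None or surrogate not in curves:
                raise KeyError(
                    f"no standard curve or surrogate configured for compound {name!r}"
                )
            curve = replace(curves[surrogate], compound=name, source="structural surrogate")
        ri = None
        if ladder is not None:
            lo, hi = ladder.span
            if lo <= p.retention_time <= hi:
                ri = kovats_index(p.retention_time, ladder)
        records.append(quantify(p, curve, scaling=scaling, kovats_ri=ri))
    return records


def total_emission(records: Sequence[EmissionRecord]) -> float:
    """Sum emissions across compounds for one sample (ng/flower/hour)."""
    records = list(records)
    if not records:
        warnings.warn("empty emission record set: total is 0", stacklevel=2)
        return 0.0
    sample_ids = {r.sample_id for r in records}
    if len(sample_ids) > 1:
        raise ValueError(f"records span multiple samples: {sorted(sample_ids)}")
    return float(sum(r.emission for r in records))


def fold_change(group_a_totals: Sequence[float], group_b_totals: Sequence[float]) -> float:
    """Ratio of group mean total emissions, mean(a)/mean(b)."""
    a = np.asarray(group_a_totals, dtype=float)
    b = np.asarray(group_b_totals, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    mb = b.mean()
    if mb == 0:
        raise ZeroDivisionError("denominator group mean is zero")
    return float(a.mean() / mb)


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t test (unequal variances), two-sided.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("both groups have zero variance and unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    ex, ey = vx / x.size, vy / y.size
    df = (ex + ey) ** 2 / (ex**2 / (x.size - 1) + ey**2 / (y.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

PEAK_COLUMNS = ["sample_id", "rt_min", "area", "hit1", "hit2", "hit3"]


def read_peaks(path, is_blank: bool = False) -> list[PeakRecord]:
    """Read a peak table CSV (sample_id, rt_min, area, hit1, hit2, hit3)."""
    df = pd.read_csv(path, dtype={"sample_id": str}, keep_default_na=False)
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table {path} missing columns: {sorted(missing)}")
    return [
        PeakRecord(
            sample_id=row.sample_id,
            retention_time=float(row.rt_min),
            area=float(row.area),
            library_hits=(str(row.hit1), str(row.hit2), str(row.hit3)),
            is_blank=is_blank,
        )
        for row in df.itertuples()
    ]


def write_peaks(peaks: Sequence[PeakRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "rt_min": p.retention_time,
                "area": p.area,
                "hit1": p.library_hits[0],
                "hit2": p.library_hits[1],
                "hit3": p.library_hits[2],
            }
            for p in peaks
        ],
        columns=PEAK_COLUMNS,
    ).to_csv(path, index=False)


def read_ladder(path) -> AlkaneLadder:
    """Read an alkane ladder CSV (carbon_number, rt_min)."""
    df = pd.read_csv(path)
    return AlkaneLadder(tuple(zip(df["carbon_number"].astype(int), df["rt_min"].astype(float))))


def read_curves(path) -> dict[str, StandardCurve]:
    """Read standard curves CSV (compound, slope, intercept, source)."""
    df = pd.read_csv(path)
    curves = {}
    for row in df.itertuples():
        curves[row.compound] = StandardCurve(
            compound=row.compound,
            slope=float(row.slope),
            intercept=float(getattr(row, "intercept", 0.0)),
            source=str(getattr(row, "source", "authentic standard")),
        )
    return curves


def emissions_to_frame(records: Sequence[EmissionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "compound": r.compound,
                "emission_ng_per_flower_per_hour": r.emission,
                "kovats_ri": r.kovats_ri,
            }
            for r in records
        ],
        columns=["sample_id", "compound", "emission_ng_per_flower_per_hour", "kovats_ri"],
    )
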