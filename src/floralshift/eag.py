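"""Electroantennogram (EAG) normalization.

Antennae fatigue over a recording session, so raw response amplitudes drift
downward. The assay interleaves a positive-control odorant (phenylacetaldehyde,
PAA) as the first, middle and final stimulus blocks; the control responses
anchor a piecewise-linear drift baseline, every response is divided by the
baseline at its presentation index ("corrected"), and corrected values are
scaled to the initial control response. The first presentation of each test
stimulus is removed beforehand: solvent blow-off inflates it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("floralshift.eag")

DEFAULT_CONTROL_LABEL = "PAA"


@dataclass(frozen=True)
class Presentation:
    index: int
    stimulus: str
    amplitude: float  # mV, > 0

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("presentation index must be >= 1")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be > 0 mV")


@dataclass(frozen=True)
class EAGSeries:
    """Ordered stimulus presentations recorded from one antenna."""

    antenna_id: str
    presentations: tuple[Presentation, ...]
    control_label: str = DEFAULT_CONTROL_LABEL

    def __post_init__(self) -> None:
        pres = tuple(
            p if isinstance(p, Presentation) else Presentation(*p)
            for p in self.presentations
        )
        idx = [p.index for p in pres]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("presentation indices must be strictly increasing")
        controls = [p for p in pres if p.stimulus == self.control_label]
        if len(controls) < 2:
            raise ValueError("series needs >= 2 control presentations")
        if pres and pres[0].stimulus != self.control_label:
            raise ValueError("the control must be the first presentation of the series")
        object.__setattr__(self, "presentations", pres)

    def controls(self) -> tuple[Presentation, ...]:
        return tuple(p for p in self.presentations if p.stimulus == self.control_label)


@dataclass(frozen=True)
class NormalizedResponse:
    antenna_id: str
    stimulus: str
    index: int
    corrected_amplitude: float  # fraction of the local control baseline
    scaled_amplitude: float  # relative to the initial control response


def drop_first_responses(series: EAGSeries) -> EAGSeries:
    """Remove the earliest presentation of every distinct test stimulus.

    Control presentations are retained. A test stimulus presented only once
    disappears entirely (with a warning).
    """
    first_index: dict[str, int] = {}
    counts: dict[str, int] = {}
    for p in series.presentations:
        if p.stimulus == series.control_label:
            continue
        counts[p.stimulus] = counts.get(p.stimulus, 0) + 1
        if p.stimulus not in first_index:
            first_index[p.stimulus] = p.index
    for stim, n in counts.items():
        if n == 1:
            warnings.warn(
                f"stimulus {stim!r} has a single presentation; removed entirely",
                stacklevel=2,
            )
    kept = tuple(
        p
        for p in series.presentations
        if p.stimulus == series.control_label or p.index != first_index[p.stimulus]
    )
    return replace(series, presentations=kept)


def _control_anchors(series: EAGSeries) -> np.ndarray:
    """Anchor points (mean index, mean amplitude) of each contiguous control
    block, in presentation order."""
    anchors = []
    block: list[Presentation] = []
    prev_was_control = False
    for p in series.presentations:
        is_control = p.stimulus == series.control_label
        if is_control:
            if not prev_was_control and block:
                anchors.append(block)
                block = []
            block.append(p)
        prev_was_control = is_control
    if block:
        anchors.append(block)
    return np.array(
        [
            (np.mean([p.index for p in b]), np.mean([p.amplitude for p in b]))
            for b in anchors
        ]
    )


def control_baseline(series: EAGSeries):
    """Expected control amplitude as a function of presentation index.

    Contiguous runs of control presentations form anchor blocks; each block
    contributes the point (mean index, mean amplitude). Between anchors the
    baseline interpolates linearly; before the first and after the last it
    extends as a constant.
    """
    anchors = _control_anchors(series)
    if len(anchors) < 2:
        raise ValueError("baseline needs >= 2 control anchor blocks")
    xs, ys = anchors[:, 0], anchors[:, 1]

    def baseline(index):
        return np.interp(np.asarray(index, dtype=float), xs, ys)

    baseline.anchors = anchors
    return baseline


def normalize(series: EAGSeries, initial_control: float | None = None) -> list[NormalizedResponse]:
    """Drift-correct and scale every presentation of a series.

    corrected = amplitude / baseline(index). scaled multiplies corrected by
    baseline(first anchor index) / initial_control; by default the initial
    control response IS the first anchor block's mean (robust to
    single-presentation noise), so scaled == corrected. Pass the very first
    raw control amplitude as ``initial_control`` to scale to it instead.

    Apply :func:`drop_first_responses` beforehand.
    """
    baseline = control_baseline(series)
    first_anchor_amp = float(baseline.anchors[0, 1])
    if initial_control is None:
        initial_control = first_anchor_amp
    if initial_control <= 0:
        raise ValueError("initial control amplitude must be > 0")
    scale = first_anchor_amp / initial_control
    out = []
    for p in series.presentations:
        b = float(baseline(p.index))
        if b <= 0:
            raise ValueError(f"baseline <= 0 at index {p.index}")
        corrected = p.amplitude / b
        out.append(
            NormalizedResponse(
                antenna_id=series.antenna_id,
                stimulus=p.stimulus,
                index=p.index,
                corrected_amplitude=corrected,
                scaled_amplitude=corrected * scale,
            )
        )
    return out


def normalize_series(series: EAGSeries, **kwargs) -> list[NormalizedResponse]:
    """Convenience: drop first test-stimulus responses, then normalize."""
    return normalize(drop_first_responses(series), **kwargs)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_series(path, control_label: str = DEFAULT_CONTROL_LABEL) -> list[EAGSeries]:
    """Read EAG CSV (antenna_id, presentation_index, stimulus, amplitude_mV)
    into one series per antenna."""
    df = pd.read_csv(path, dtype={"antenna_id": str, "stimulus": str})
    series = []
    for antenna_id, sub in df.groupby("antenna_id"):
        sub = sub.sort_values("presentation_index")
        series.append(
            EAGSeries(
                antenna_id=antenna_id,
                presentations=tuple(
                    Presentation(int(r.presentation_index), r.stimulus, float(r.amplitude_mV))
                    for r in sub.itertuples()
                ),
                control_label=control_label,
            )
        )
    return series


def responses_to_frame(responses) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "antenna_id": r.antenna_id,
                "stimulus": r.stimulus,
                "presentation_index": r.index,
                "corrected_amplitude": r.corrected_amplitude,
                "scaled_amplitude": r.scaled_amplitude,
            }
            for r in responses
        ]
    )
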