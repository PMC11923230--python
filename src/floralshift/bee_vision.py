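"""Trichromatic bee colour-space model for floral reflectance.

Reflectance spectra (300-700 nm) are averaged hierarchically (technical
replicate -> flower -> line), converted to receptor quantum catches for the
honeybee UV, blue and green photoreceptors, von Kries-adapted to a green
vegetative background, transduced to receptor excitations E = q/(q+1), and
projected into the colour hexagon. Distance of a stimulus from the hexagon
centre approximates its chromatic contrast against the adapting background:
the background itself maps to the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# Standard honeybee receptor peak sensitivities (nm).
DEFAULT_LAMBDA_MAX = (344.0, 436.0, 544.0)  # UV, blue, green

DEFAULT_GRID = np.arange(300.0, 701.0, 1.0)


@dataclass(frozen=True)
class HexagonPoint:
    """A stimulus located in the colour hexagon."""

    x: float
    y: float

    @property
    def contrast(self) -> float:
        """Euclidean distance from the achromatic centre (hexagon units)."""
        return float(np.hypot(self.x, self.y))


# ---------------------------------------------------------------------------
# Spectra handling
# ---------------------------------------------------------------------------


def _check_grid(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
        raise ValueError("wavelength grid must be 1-D and strictly increasing")
    return wl


def regrid(wavelengths, reflectance, grid=DEFAULT_GRID) -> np.ndarray:
    """Linearly interpolate a spectrum onto the common 1-nm grid."""
    wl = _check_grid(wavelengths)
    r = np.asarray(reflectance, dtype=float)
    if grid[0] < wl[0] or grid[-1] > wl[-1]:
        raise ValueError(
            f"spectrum covers [{wl[0]}, {wl[-1]}] nm, cannot regrid onto "
            f"[{grid[0]}, {grid[-1]}] nm"
        )
    return np.interp(grid, wl, r)


def average_replicates(
    spectra: pd.DataFrame,
    by: tuple[str, ...] = ("line", "plant_id", "flower_id"),
) -> pd.DataFrame:
    """Hierarchical pointwise mean of long-format reflectance spectra.

    ``spectra`` is long format with columns including ``wavelength_nm``,
    ``reflectance`` and the grouping labels in ``by``. Averaging proceeds
    level by level from the innermost grouping (technical replicates within
    a flower) outward (flowers within a plant, plants within a line), so
    every flower and every plant carries equal weight regardless of its
    replicate count. Returns a long-format frame grouped by ``by[0]``.

    All spectra must share an identical wavelength grid.
    """
    required = {"wavelength_nm", "reflectance", *by}
    missing = required - set(spectra.columns)
    if missing:
        raise ValueError(f"spectra frame missing columns: {sorted(missing)}")
    grids = spectra.groupby(list(by), observed=True)["wavelength_nm"].apply(
        lambda s: tuple(np.sort(np.unique(s)))
    )
    if len(set(grids)) > 1:
        raise ValueError("spectra to be combined are on mismatched wavelength grids")
    df = spectra
    # innermost level first: mean over technical replicates, then collapse
    # one grouping level per step.
    levels = list(by)
    df = (
        df.groupby(levels + ["wavelength_nm"], observed=True)["reflectance"]
        .mean()
        .reset_index()
    )
    while len(levels) > 1:
        levels = levels[:-1]
        df = (
            df.groupby(levels + ["wavelength_nm"], observed=True)["reflectance"]
            .mean()
            .reset_index()
        )
    return df


# ---------------------------------------------------------------------------
# Receptor templates
# ---------------------------------------------------------------------------


def receptor_template(lambda_max: float, grid=DEFAULT_GRID) -> np.ndarray:
    """A1 visual-pigment absorbance template, peak-normalized to 1.

    Uses the Govardovskii-family rhodopsin nomogram: an alpha band that is a
    function of x = lambda_max / lambda plus a Gaussian beta band whose
    position and width scale with lambda_max.
    """
    if not 300.0 <= lambda_max <= 700.0:
        raise ValueError("lambda_max must lie in [300, 700] nm")
    wl = _check_grid(grid)
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lam_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((wl - lam_beta) / b_beta) ** 2))
    s = alpha + beta
    return s / s.max()


def default_receptors(grid=DEFAULT_GRID) -> dict[str, np.ndarray]:
    """UV/blue/green honeybee sensitivity curves on ``grid``."""
    names = ("uv", "blue", "green")
    return {n: receptor_template(lm, grid) for n, lm in zip(names, DEFAULT_LAMBDA_MAX)}


def flat_illuminant(grid=DEFAULT_GRID) -> np.ndarray:
    """Equal-energy illuminant (the default; a D65-like option exists)."""
    return np.ones(len(grid))


def d65_like_illuminant(grid=DEFAULT_GRID) -> np.ndarray:
    """Smooth daylight-like illuminant: rising through the UV, flat-topped
    in the visible. A coarse analytic stand-in for standard daylight,
    normalized to 1 at 560 nm."""
    wl = np.asarray(grid, dtype=float)
    s = 1.0 / (1.0 + np.exp(-(wl - 330.0) / 25.0))
    return s / np.interp(560.0, wl, s)


def green_leaf_background(grid=DEFAULT_GRID) -> np.ndarray:
    """Synthetic green-leaf reflectance: low in the UV and blue, a chlorophyll
    bump near 550 nm, and the start of the red-edge rise toward 700 nm."""
    wl = np.asarray(grid, dtype=float)
    bump = 0.12 * np.exp(-(((wl - 550.0) / 40.0) ** 2))
    red_edge = 0.35 / (1.0 + np.exp(-(wl - 705.0) / 12.0))
    return 0.04 + bump + red_edge


# ---------------------------------------------------------------------------
# Quantum catch and the hexagon
# ---------------------------------------------------------------------------


def quantum_catch(
    reflectance: np.ndarray,
    sensitivity: np.ndarray,
    illuminant: np.ndarray,
    background: np.ndarray,
    grid=DEFAULT_GRID,
) -> tuple[float, float]:
    """von Kries-adapted catch and excitation for one receptor.

    Raw catch Q = sum R(l) S(l) I(l) dl; the adapted catch q = Q/Q_bg
    normalizes by the same receptor's catch of the adapting background, and
    the excitation E = q/(q+1) is the hexagon transduction, in (0, 1).
    """
    wl = _check_grid(grid)
    arrays = [np.asarray(a, dtype=float) for a in (reflectance, sensitivity, illuminant, background)]
    if any(a.shape != wl.shape for a in arrays):
        raise ValueError("reflectance, sensitivity, illuminant and background must share the grid")
    r, s, i, bg = arrays
    dl = np.gradient(wl)
    q_raw = float(np.sum(r * s * i * dl))
    q_bg = float(np.sum(bg * s * i * dl))
    if q_bg <= 0:
        raise ValueError("background quantum catch must be > 0")
    q = q_raw / q_bg
    return q, q / (q + 1.0)


def hexagon_coords(e_uv: float, e_blue: float, e_green: float) -> HexagonPoint:
    """Project receptor excitations into the colour hexagon.

    x = (sqrt(3)/2) (E_green - E_uv); y = E_blue - (E_uv + E_green)/2.
    The adapting background (E = 0.5 for every receptor) maps to the origin.
    """
    x = (np.sqrt(3.0) / 2.0) * (e_green - e_uv)
    y = e_blue - (e_uv + e_green) / 2.0
    return HexagonPoint(float(x), float(y))


def spectrum_to_hexagon(
    reflectance: np.ndarray,
    background: np.ndarray,
    illuminant: np.ndarray | None = None,
    receptors: dict[str, np.ndarray] | None = None,
    grid=DEFAULT_GRID,
) -> HexagonPoint:
    """Full pipeline for one spectrum: catches for all three receptors, then
    hexagon coordinates."""
    if illuminant is None:
        illuminant = flat_illuminant(grid)
    if receptors is None:
        receptors = default_receptors(grid)
    e = {
        name: quantum_catch(reflectance, sens, illuminant, background, grid)[1]
        for name, sens in receptors.items()
    }
    return hexagon_coords(e["uv"], e["blue"], e["green"])


def lines_to_hexagon(
    spectra: pd.DataFrame,
    background: np.ndarray,
    grid=DEFAULT_GRID,
    **kwargs,
) -> pd.DataFrame:
    """Average long-format spectra per line and place each line in the hexagon.

    Returns a frame (line, x, y, contrast).
    """
    per_line = average_replicates(spectra)
    rows = []
    for line, sub in per_line.groupby("line", observed=True):
        sub = sub.sort_values("wavelength_nm")
        refl = regrid(sub["wavelength_nm"].to_numpy(), sub["reflectance"].to_numpy(), grid)
        pt = spectrum_to_hexagon(refl, background, grid=grid, **kwargs)
        rows.append({"line": line, "x": pt.x, "y": pt.y, "contrast": pt.contrast})
    return pd.DataFrame(rows, columns=["line", "x", "y", "contrast"])
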