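"""Synthetic study inputs with known ground truth.

Every stage of the pipeline gets a generator that emulates the shape and
statistical structure of its real input — vendor-style GC-MS peak tables
with paired blanks, reflectance spectra of red-like and yellow-like morphs,
EAG presentation series under exponential antennal fatigue, bee choice-trial
event logs, pigment/corolla-mass tables, and mock VCFs with spatially
heterogeneous variant density. Ground-truth parameters (emission fold
change, stimulus response ratios, choice probability, per-window Poisson
intensities) are embedded so the analysis stages can be tested for
parameter recovery. All generators are deterministic under a fixed seed.

Defaults mirror the study conditions: a ~2.3-fold total-emission difference
between yellow and red morphs, a 2:1 yellow choice preference with ten bees
per comparison, control-anchored EAG schedules with three control rounds,
and piecewise-constant variant intensity along mock chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import volatiles as vol
from .bee_vision import DEFAULT_GRID
from .choice import ChoiceEvent, ChoiceTrial
from .eag import EAGSeries, Presentation

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GcmsConfig:
    """Two morph groups emitting the same compounds at a known fold change.

    Areas are log-normal around the group mean; junk peaks (sub-threshold,
    late-eluting, contaminant-hit, blank-shared) exercise the filter
    cascade. ``fold`` multiplies every compound's emission in group A.
    """

    compounds: tuple[tuple[str, float, float], ...] = (
        # (name, retention minutes, base emission ng/flower/hour in group B)
        ("alpha-pinene", 9.3, 120.0),
        ("sabinene", 9.7, 50.0),
        ("beta-phellandrene", 10.2, 12.0),
        ("lavender lactone", 10.4, 1.2),
        ("valencene", 14.8, 0.5),
    )
    n_per_group: int = 15
    fold: float = 2.3
    rt_sd: float = 0.02  # minutes
    area_log_sd: float = 0.4  # log-normal sigma on emissions
    curve_slope: float = 2e4  # area counts per ng
    curve_intercept: float = 1e4
    scaling: float = 48.0  # 2 flowers x 24 h
    n_junk_small: int = 4  # per sample, area below the 1e5 threshold
    n_junk_late: int = 2  # per sample, elutes after 30 min
    n_contaminant: int = 3  # per sample, all-contaminant hit triplets
    n_blank_shared: int = 3  # per sample, matched in the blank at < 5-fold


@dataclass(frozen=True)
class SpectraConfig:
    """Red-like and yellow-like corolla reflectance plus a leaf background.

    Red-like: low reflectance below 600 nm with a sharp long-wavelength
    shoulder. Yellow-like: a high plateau above ~520 nm and a small UV bump
    (the subtle bullseye). Gaussian noise, clipped to [0, 1].
    """

    n_flowers: int = 4
    n_technical: int = 3
    noise_sd: float = 0.01
    yellow_plateau: float = 0.6
    yellow_uv_bump: float = 0.05
    red_base: float = 0.05
    red_shoulder: float = 0.5


@dataclass(frozen=True)
class EagConfig:
    """Control-anchored presentation schedule under exponential fatigue.

    amplitude(i) = base * exp(-decay * i) * rho_stimulus * (1 + noise); the
    first presentation of each test stimulus is inflated by
    ``first_inflation`` to emulate solvent blow-off.
    """

    n_antennae: int = 9
    base_amplitude: float = 4.0  # mV
    decay: float = 0.02  # per presentation
    stimulus_ratios: tuple[tuple[str, float], ...] = (
        ("MvY", 0.60),
        ("MvR", 0.55),
        ("McY", 0.65),
        ("McR", 0.58),
        ("solvent", 0.40),
        ("air", 0.25),
    )
    exposures_per_stimulus: int = 6
    control_label: str = "PAA"
    control_rounds: int = 3
    control_exposures: int = 4
    noise_sd: float = 0.05
    first_inflation: float = 1.5


@dataclass(frozen=True)
class ChoiceConfig:
    """Bernoulli visits at a known yellow probability."""

    p_yellow: float = 2.0 / 3.0
    n_bees: int = 10
    visits_lambda: float = 9.0  # Poisson mean visits per bee
    probe_prob: float = 0.5
    handling_shape: float = 2.0  # Gamma
    handling_scale: float = 5.0  # seconds
    species_pair: str = "MvY-vs-MvR"


@dataclass(frozen=True)
class VariantsConfig:
    """Inhomogeneous Poisson variant positions on mock chromosomes.

    Each chromosome is a tuple (name, length, segment intensities), the
    intensities being per-bp rates over equal-length segments.
    """

    chromosomes: tuple[tuple[str, int, tuple[float, ...]], ...] = (
        ("chr1", 2_000_000, (2e-3, 6e-3, 1e-3, 4e-3)),
        ("chr2", 1_500_000, (5e-3, 1e-3, 3e-3)),
    )


@dataclass(frozen=True)
class PigmentsConfig:
    """Group absorbance means/SDs and line corolla masses."""

    lines: tuple[tuple[str, float, float, float], ...] = (
        # (line, anthocyanin mean AU, carotenoid mean AU, corolla mass g)
        ("red", 0.90, 0.20, 0.060),
        ("yellow", 0.05, 0.55, 0.075),
    )
    n_per_line: int = 5
    absorbance_sd: float = 0.05


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    gcms: GcmsConfig = field(default_factory=GcmsConfig)
    spectra: SpectraConfig = field(default_factory=SpectraConfig)
    eag: EagConfig = field(default_factory=EagConfig)
    choice: ChoiceConfig = field(default_factory=ChoiceConfig)
    variants: VariantsConfig = field(default_factory=VariantsConfig)
    pigments: PigmentsConfig = field(default_factory=PigmentsConfig)


CONTAMINANT_TRIPLES = (
    ("hexamethylcyclotrisiloxane", "octamethylcyclotetrasiloxane", "silicic acid ester"),
    ("dibutyl phthalate", "diethyl phthalate", "bis(2-ethylhexyl) phthalate"),
    ("siloxane derivative", "decamethylpentasiloxane", "silicic acid, diethyl ester"),
)

CLEAN_VOCAB = ("beta-myrcene", "limonene", "linalool", "ocimene", "benzaldehyde")


# ---------------------------------------------------------------------------
# GC-MS
# ---------------------------------------------------------------------------


def gen_gcms(config: GcmsConfig = GcmsConfig(), seed: int = 0):
    """Sample and blank peak tables with embedded ground-truth emissions.

    Returns a dict with sample peaks, blank peaks, the alkane ladder,
    standard curves, per-sample group labels and the true per-sample total
    emissions (before noise-free filtering they are exactly recoverable by
    the cascade + quantification).
    """
    rng = np.random.default_rng(seed)
    ladder = vol.AlkaneLadder(tuple((c, 1.0 + (c - 7) * 1.9) for c in range(7, 21)))
    curves = {
        name: vol.StandardCurve(name, slope=config.curve_slope, intercept=config.curve_intercept)
        for name, _, _ in config.compounds
    }
    sample_peaks: list[vol.PeakRecord] = []
    blank_peaks: list[vol.PeakRecord] = []
    groups: dict[str, str] = {}
    true_totals: dict[str, float] = {}

    for group, mult in (("A", config.fold), ("B", 1.0)):
        for k in range(config.n_per_group):
            sid = f"{group}{k:02d}"
            groups[sid] = group
            total = 0.0
            for name, rt_mean, base in config.compounds:
                emission = mult * base * rng.lognormal(0.0, config.area_log_sd)
                total += emission
                area = config.curve_intercept + config.curve_slope * emission * config.scaling
                rt = max(0.0, rng.normal(rt_mean, config.rt_sd))
                hits = (name, *rng.choice(CLEAN_VOCAB, size=2, replace=False))
                sample_peaks.append(vol.PeakRecord(sid, rt, area, tuple(hits)))
            true_totals[sid] = total
            # junk below the area threshold
            for _ in range(config.n_junk_small):
                sample_peaks.append(
                    vol.PeakRecord(
                        sid,
                        float(rng.uniform(2, 28)),
                        float(rng.uniform(1e3, 9.9e4)),
                        tuple(rng.choice(CLEAN_VOCAB, size=3, replace=False)),
                    )
                )
            # heavy late-eluting junk
            for _ in range(config.n_junk_late):
                sample_peaks.append(
                    vol.PeakRecord(
                        sid,
                        float(rng.uniform(30.05, 40)),
                        float(rng.uniform(2e5, 1e6)),
                        tuple(rng.choice(CLEAN_VOCAB, size=3, replace=False)),
                    )
                )
            # instrument contaminants: all three hits contaminated
            for _ in range(config.n_contaminant):
                triple = CONTAMINANT_TRIPLES[rng.integers(len(CONTAMINANT_TRIPLES))]
                sample_peaks.append(
                    vol.PeakRecord(sid, float(rng.uniform(2, 28)), float(rng.uniform(2e5, 8e5)), triple)
                )
            # blank-shared peaks: same top hit within 0.1 min, sample area
            # under 5-fold the blank area
            for j in range(config.n_blank_shared):
                name = f"ambient-{sid}-{j}"
                rt = float(rng.uniform(3, 25))
                blank_area = float(rng.uniform(2e5, 6e5))
                sample_area = blank_area * float(rng.uniform(1.2, 4.5))
                jitter = float(rng.uniform(-0.08, 0.08))
                hits = (name, *rng.choice(CLEAN_VOCAB, size=2, replace=False))
                sample_peaks.append(vol.PeakRecord(sid, rt + jitter, sample_area, tuple(hits)))
                blank_peaks.append(
                    vol.PeakRecord(f"blank-{sid}", rt, blank_area, tuple(hits), is_blank=True)
                )
    return {
        "sample_peaks": sample_peaks,
        "blank_peaks": blank_peaks,
        "ladder": ladder,
        "curves": curves,
        "groups": groups,
        "true_totals": true_totals,
        "true_fold": config.fold,
        "scaling": config.scaling,
    }


def recover_fold_change(data, filter_config: vol.FilterConfig = vol.FilterConfig()) -> float:
    """Run the full volatiles pipeline on a generated dataset and return the
    estimated group A / group B total-emission fold change."""
    kept = vol.filter_cascade(data["sample_peaks"], data["blank_peaks"], filter_config)
    by_sample: dict[str, list[vol.PeakRecord]] = {}
    for p in kept:
        by_sample.setdefault(p.sample_id, []).append(p)
    totals = {"A": [], "B": []}
    for sid, peaks in by_sample.items():
        records = vol.quantify_peaks(peaks, data["curves"], scaling=data["scaling"])
        totals[data["groups"][sid]].append(vol.total_emission(records))
    return vol.fold_change(totals["A"], totals["B"])


# ---------------------------------------------------------------------------
# Reflectance spectra
# ---------------------------------------------------------------------------


def _red_like(wl: np.ndarray, config: SpectraConfig) -> np.ndarray:
    shoulder = config.red_shoulder / (1.0 + np.exp(-(wl - 620.0) / 8.0))
    return config.red_base + shoulder


def _yellow_like(wl: np.ndarray, config: SpectraConfig) -> np.ndarray:
    plateau = config.yellow_plateau / (1.0 + np.exp(-(wl - 510.0) / 10.0))
    uv_bump = config.yellow_uv_bump * np.exp(-(((wl - 350.0) / 25.0) ** 2))
    return 0.05 + plateau + uv_bump


def gen_spectra(config: SpectraConfig = SpectraConfig(), seed: int = 0, grid=DEFAULT_GRID) -> pd.DataFrame:
    """Long-format reflectance table for red-like and yellow-like lines.

    Columns: line, plant_id, flower_id, tissue, wavelength_nm, reflectance.
    One plant per flower here; three technical replicates per flower.
    """
    rng = np.random.default_rng(seed)
    wl = np.asarray(grid, dtype=float)
    rows = []
    for line, shape_fn in (("red-like", _red_like), ("yellow-like", _yellow_like)):
        base = shape_fn(wl, config)
        for f in range(config.n_flowers):
            for t in range(config.n_technical):
                refl = np.clip(base + rng.normal(0.0, config.noise_sd, wl.size), 0.0, 1.0)
                rows.append(
                    pd.DataFrame(
                        {
                            "line": line,
                            "plant_id": f"{line}-p{f}",
                            "flower_id": f"{line}-p{f}-f{f}",
                            "tissue": "petal lobe",
                            "replicate": t,
                            "wavelength_nm": wl,
                            "reflectance": refl,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# EAG
# ---------------------------------------------------------------------------


def gen_eag(config: EagConfig = EagConfig(), seed: int = 0) -> list[EAGSeries]:
    """EAG series with control anchors at the first, middle and final blocks.

    Ground truth: response ratio rho per stimulus relative to the control,
    multiplicative fatigue exp(-decay*i), iid multiplicative noise.
    """
    rng = np.random.default_rng(seed)
    ratios = dict(config.stimulus_ratios)
    series = []
    for a in range(config.n_antennae):
        # schedule: control block, half the test stimuli, control block,
        # the other half, control block — test order randomized per antenna
        stimuli = list(ratios)
        rng.shuffle(stimuli)
        mid = len(stimuli) // 2
        schedule: list[str] = []
        schedule += [config.control_label] * config.control_exposures
        for s in stimuli[:mid]:
            schedule += [s] * config.exposures_per_stimulus
        schedule += [config.control_label] * config.control_exposures
        for s in stimuli[mid:]:
            schedule += [s] * config.exposures_per_stimulus
        schedule += [config.control_label] * config.control_exposures
        seen: set[str] = set()
        presentations = []
        for i, stim in enumerate(schedule, start=1):
            rho = 1.0 if stim == config.control_label else ratios[stim]
            amp = config.base_amplitude * np.exp(-config.decay * i) * rho
            amp *= 1.0 + rng.normal(0.0, config.noise_sd)
            if stim != config.control_label and stim not in seen:
                amp *= config.first_inflation
                seen.add(stim)
            presentations.append(Presentation(i, stim, float(max(amp, 1e-6))))
        series.append(
            EAGSeries(
                antenna_id=f"antenna-{a}",
                presentations=tuple(presentations),
                control_label=config.control_label,
            )
        )
    return series


# ---------------------------------------------------------------------------
# Choice trials
# ---------------------------------------------------------------------------


def gen_choice(config: ChoiceConfig = ChoiceConfig(), seed: int = 0) -> list[ChoiceTrial]:
    """Choice-trial logs with iid Bernoulli(p_yellow) visit morphs."""
    rng = np.random.default_rng(seed)
    trials = []
    for b in range(config.n_bees):
        n_visits = max(1, int(rng.poisson(config.visits_lambda)))
        events = tuple(
            ChoiceEvent(
                morph="yellow" if rng.random() < config.p_yellow else "red",
                probed=bool(rng.random() < config.probe_prob),
                handling_seconds=float(rng.gamma(config.handling_shape, config.handling_scale)),
            )
            for _ in range(n_visits)
        )
        trials.append(ChoiceTrial(bee_id=f"bee-{b:02d}", species_pair=config.species_pair, events=events))
    return trials


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


def gen_variants(config: VariantsConfig = VariantsConfig(), seed: int = 0):
    """Variant positions from an inhomogeneous Poisson process.

    Returns (positions per chromosome, chromosome lengths, expected count
    per bp as a piecewise-constant array per chromosome).
    """
    rng = np.random.default_rng(seed)
    positions: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    intensities: dict[str, np.ndarray] = {}
    for name, length, rates in config.chromosomes:
        lengths[name] = length
        seg_len = length / len(rates)
        pos: list[int] = []
        rate_track = np.empty(length)
        for s, rate in enumerate(rates):
            lo = int(round(s * seg_len))
            hi = int(round((s + 1) * seg_len))
            rate_track[lo:hi] = rate
            n = rng.poisson(rate * (hi - lo))
            if n:
                pos.extend(rng.integers(lo + 1, hi + 1, size=n))  # 1-based
        positions[name] = np.sort(np.asarray(pos, dtype=np.int64))
        intensities[name] = rate_track
    return positions, lengths, intensities


def write_vcf(positions: dict[str, np.ndarray], lengths: dict[str, int], path) -> None:
    """Write positions as a minimal, standard-conforming VCF (sites only)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=floralshift-synthdata\n")
        for chrom, length in lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        bases = "ACGT"
        for chrom in lengths:
            for i, pos in enumerate(positions.get(chrom, [])):
                ref = bases[pos % 4]
                alt = bases[(pos + 1) % 4]
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t50\tPASS\t.\n")


def write_fai(lengths: dict[str, int], path) -> None:
    """Chromosome-length table in FASTA-index layout."""
    with Path(path).open("w") as fh:
        offset = 0
        for chrom, length in lengths.items():
            fh.write(f"{chrom}\t{length}\t{offset}\t60\t61\n")
            offset += length + length // 60 + 1


# ---------------------------------------------------------------------------
# Pigments
# ---------------------------------------------------------------------------


def gen_pigments(config: PigmentsConfig = PigmentsConfig(), seed: int = 0) -> pd.DataFrame:
    """Per-plant absorbance readings with line corolla masses."""
    rng = np.random.default_rng(seed)
    rows = []
    for line, antho, caro, mass in config.lines:
        for i in range(config.n_per_line):
            for pclass, mean in (("anthocyanin", antho), ("carotenoid", caro)):
                rows.append(
                    {
                        "line": line,
                        "plant_id": f"{line}-{i}",
                        "pigment_class": pclass,
                        "absorbance": float(max(0.0, rng.normal(mean, config.absorbance_sd))),
                        "dilution_factor": 1.0,
                        "mean_corolla_mass": mass,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-dataset driver
# ---------------------------------------------------------------------------


def generate_all(config: SynthConfig = SynthConfig(), outdir=None) -> dict:
    """Generate every stage's inputs from one master seed.

    Stage seeds are derived deterministically from ``config.seed``. When
    ``outdir`` is given, writes the CSV/VCF fixtures each stage's reader
    consumes.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    gcms = gen_gcms(config.gcms, seeds[0])
    spectra = gen_spectra(config.spectra, seeds[1])
    eag_series = gen_eag(config.eag, seeds[2])
    trials = gen_choice(config.choice, seeds[3])
    positions, lengths, intensities = gen_variants(config.variants, seeds[4])
    pigments = gen_pigments(config.pigments, seeds[5])
    data = {
        "gcms": gcms,
        "spectra": spectra,
        "eag": eag_series,
        "choice": trials,
        "variants": (positions, lengths, intensities),
        "pigments": pigments,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        vol.write_peaks(gcms["sample_peaks"], outdir / "peaks.csv")
        vol.write_peaks(gcms["blank_peaks"], outdir / "blanks.csv")
        pd.DataFrame(gcms["ladder"].rungs, columns=["carbon_number", "rt_min"]).to_csv(
            outdir / "ladder.csv", index=False
        )
        pd.DataFrame(
            [
                {"compound": c.compound, "slope": c.slope, "intercept": c.intercept, "source": c.source}
                for c in gcms["curves"].values()
            ]
        ).to_csv(outdir / "curves.csv", index=False)
        spectra.to_csv(outdir / "spectra.csv", index=False)
        pd.DataFrame(
            [
                {
                    "antenna_id": s.antenna_id,
                    "presentation_index": p.index,
                    "stimulus": p.stimulus,
                    "amplitude_mV": p.amplitude,
                }
                for s in eag_series
                for p in s.presentations
            ]
        ).to_csv(outdir / "eag.csv", index=False)
        pd.DataFrame(
            [
                {
                    "bee_id": t.bee_id,
                    "species_pair": t.species_pair,
                    "event_order": i,
                    "morph": e.morph,
                    "probed": int(e.probed),
                    "handling_seconds": e.handling_seconds,
                }
                for t in trials
                for i, e in enumerate(t.events)
            ]
        ).to_csv(outdir / "events.csv", index=False)
        write_vcf(positions, lengths, outdir / "calls.vcf")
        write_fai(lengths, outdir / "genome.fa.fai")
        pigments.to_csv(outdir / "pigments.csv", index=False)
    return data
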