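"""Synthetic-data generators with planted ground truth.

Every pipeline input can be generated here so that all stages are testable
end to end without external data: 11-plex TMT PSM tables with label biases
and a global-mix reference channel, FRET dose-response screens, subcellular
fraction time courses with planted translocations, two-condition correlated
replicate panels, enzyme-kinetics plates, FRAP traces and two-channel cell
images.  Each generator is a pure function of its parameters and a seed;
in the no-noise limit each satisfies its stated closed form exactly.

Default parameter values are chosen to emulate the desk-scale study design:
a 15-point time course split over three 5-pair series (A/B/C) per fraction,
three biological replicates, reporter-level log2 noise around 0.25, and
channel label biases around 0.3 log2 units.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_FRACTIONS,
    N_CHANNELS,
    SERIES_TIME_POINTS_S,
    AbundanceCube,
    ChannelAssignment,
    ImageFrame,
    PlexDesign,
    PsmRecord,
)

__all__ = [
    "TmtSimTruth", "ScreenSimTruth", "CubeSimTruth",
    "simulate_tmt_experiment", "simulate_dose_response_screen",
    "simulate_fraction_timecourse", "simulate_network_perturbation",
    "simulate_kinetics_plate", "simulate_frap_series",
    "simulate_apoptosis_images", "stage_rng",
]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """One RNG stream per generator, independent of call order."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# TMT experiment
# ---------------------------------------------------------------------------

@dataclass
class TmtSimTruth:
    """Ground truth of a simulated TMT experiment.

    ``effects`` maps (protein, time_s) -> true log2 treated-minus-control
    effect; ``label_bias`` maps (plex_id, channel 1-based) -> true log2 label
    bias; ``noise_sd`` maps protein -> reporter-level log2 noise sd.
    """

    effects: dict = field(default_factory=dict)
    changers: list = field(default_factory=list)
    label_bias: dict = field(default_factory=dict)
    noise_sd: dict = field(default_factory=dict)
    time_points_s: tuple = ()

    def effects_frame(self) -> pd.DataFrame:
        rows = [{"protein": p, "time_s": t, "effect": v}
                for (p, t), v in self.effects.items()]
        return pd.DataFrame(rows, columns=["protein", "time_s", "effect"])


def _effect_ramp(t_s: np.ndarray, tau_s: float = 6 * 3600.0) -> np.ndarray:
    """Saturating onset of a planted effect: 0 at t=0, ->1 for t >> tau."""
    return 1.0 - np.exp2(-np.asarray(t_s, dtype=float) / tau_s)


def simulate_tmt_experiment(
    n_proteins: int = 300,
    peptides_per_protein_mean: float = 3.0,
    n_bio_replicates: int = 3,
    changer_fraction: float = 0.25,
    effect_sd: float = 1.0,
    label_bias_sd: float = 0.3,
    noise_sd: float = 0.25,
    missing_series_prob: float = 0.1,
    seed: int = 20220624,
    fractions: tuple = DEFAULT_FRACTIONS,
    effect_magnitude: float | None = None,
    effect_tau_s: float = 6 * 3600.0,
) -> tuple[list[PsmRecord], list[PlexDesign], TmtSimTruth]:
    """Simulate an 11-plex TMT time-series experiment with planted effects.

    For each fraction x series x biological replicate one plex is generated:
    five treated channels, five matched control channels and one global-mix
    channel whose (pre-noise) intensity is the mean of the ten non-mix true
    intensities.  A ``changer_fraction`` of proteins receives a saturating
    treated-minus-control effect over time; if ``effect_magnitude`` is given
    the asymptotic |effect| is fixed at that value (random sign), otherwise
    it is drawn Normal(0, effect_sd^2).  Peptide counts are 1 + Poisson;
    whole-series dropout occurs per (protein, fraction, series) with
    probability ``missing_series_prob``.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    for name, v in [("changer_fraction", changer_fraction),
                    ("missing_series_prob", missing_series_prob)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if effect_sd <= 0 or label_bias_sd < 0 or noise_sd < 0:
        raise ValueError("sds must be positive (label/noise sds non-negative)")

    rng = stage_rng(seed, "tmt")
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    all_times = tuple(sorted(t for ts in SERIES_TIME_POINTS_S.values() for t in ts))

    is_changer = rng.random(n_proteins) < changer_fraction
    if effect_magnitude is None:
        max_effect = rng.normal(0.0, effect_sd, n_proteins)
    else:
        max_effect = float(effect_magnitude) * rng.choice([-1.0, 1.0], n_proteins)
    max_effect = np.where(is_changer, max_effect, 0.0)
    ramp = _effect_ramp(np.array(all_times), effect_tau_s)
    effect_by_time = np.outer(max_effect, ramp)  # n_proteins x 15

    truth = TmtSimTruth(time_points_s=all_times)
    truth.changers = [p for p, c in zip(proteins, is_changer) if c]
    for i, p in enumerate(proteins):
        truth.noise_sd[p] = noise_sd
        for j, t in enumerate(all_times):
            truth.effects[(p, t)] = float(effect_by_time[i, j])
    time_index = {t: j for j, t in enumerate(all_times)}

    n_peptides = 1 + rng.poisson(max(peptides_per_protein_mean - 1.0, 0.0), n_proteins)
    base_log2 = rng.normal(20.0, 1.0, (n_proteins, len(fractions)))

    designs: list[PlexDesign] = []
    records: list[PsmRecord] = []
    psm_counter = 0
    for fi, fraction in enumerate(fractions):
        for series, times in SERIES_TIME_POINTS_S.items():
            missing = rng.random(n_proteins) < missing_series_prob
            for rep in range(1, n_bio_replicates + 1):
                plex_id = f"{fraction[:3]}_{series}_r{rep}"
                channel_map = []
                for t in times:
                    channel_map.append(ChannelAssignment(time_s=t, condition="treated"))
                    channel_map.append(ChannelAssignment(time_s=t, condition="control"))
                channel_map.append(ChannelAssignment(time_s=times[0], condition="global_mix"))
                design = PlexDesign(plex_id=plex_id, series=series, fraction=fraction,
                                    bio_replicate=rep, tech_replicate=1,
                                    channel_map=tuple(channel_map))
                designs.append(design)

                bias = rng.normal(0.0, label_bias_sd, N_CHANNELS)
                for ch in range(N_CHANNELS):
                    truth.label_bias[(plex_id, ch + 1)] = float(bias[ch])

                for i in np.flatnonzero(~missing):
                    base = 2.0 ** base_log2[i, fi]
                    true_intensity = np.empty(N_CHANNELS)
                    for ch, assign in enumerate(channel_map[:-1]):
                        if assign.condition == "treated":
                            eff = effect_by_time[i, time_index[assign.time_s]]
                            true_intensity[ch] = base * 2.0 ** eff
                        else:
                            true_intensity[ch] = base
                    true_intensity[N_CHANNELS - 1] = true_intensity[:N_CHANNELS - 1].mean()
                    for pep in range(n_peptides[i]):
                        # per-channel reporter noise; the pooled mix channel is
                        # effectively noise-free (it aggregates all time points)
                        eps = rng.normal(0.0, noise_sd, N_CHANNELS) if noise_sd > 0 \
                            else np.zeros(N_CHANNELS)
                        eps[N_CHANNELS - 1] = 0.0
                        observed = true_intensity * 2.0 ** (bias + eps)
                        records.append(PsmRecord(
                            psm_id=f"psm{psm_counter:07d}",
                            peptide_sequence=f"PEP_{proteins[i]}_{pep}",
                            protein_ids=(proteins[i],),
                            plex_id=plex_id,
                            intensities=tuple(observed),
                        ))
                        psm_counter += 1
    return records, designs, truth


# ---------------------------------------------------------------------------
# FRET dose-response screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimTruth:
    """Ground truth for one simulated FRET sensor."""

    sensor: str
    ec50_um: float
    k: float
    onset_s: float
    amplitude: float
    baseline: float = 1.0
    in_dose_range: bool = True


# 12-point geometric dose series spanning the screen's 0.343-100 uM range
DEFAULT_DOSES_UM = tuple(0.343 * (100.0 / 0.343) ** (i / 11.0) for i in range(12))


def default_sensor_panel(n_in_range: int = 40, n_out_of_range: int = 10,
                         seed: int = 20220624) -> list[ScreenSimTruth]:
    """A realistic biosensor panel for the simulated screen.

    In-range sensors have EC50 log-uniform in 4-15 uM (well inside the
    0.343-100 uM dose series so the rescaled response covers the full
    sigmoid), slopes k in 4-6 per log10 unit (Hill coefficients ~1.7-2.6,
    typical of biosensors reading amplified signalling cascades), response
    amplitude equal to the baseline ratio and a sub-hour onset.
    Out-of-range sensors sit at 300 uM, where only the foot of the sigmoid
    is sampled.
    """
    rng = stage_rng(seed, "sensor_panel")
    sensors = []
    for i in range(n_in_range):
        sensors.append(ScreenSimTruth(
            sensor=f"S{i:03d}",
            ec50_um=float(10.0 ** rng.uniform(np.log10(4.0), np.log10(15.0))),
            k=float(rng.uniform(4.0, 6.0)), onset_s=1800.0,
            amplitude=1.0, baseline=1.0, in_dose_range=True))
    for i in range(n_out_of_range):
        sensors.append(ScreenSimTruth(
            sensor=f"X{i:03d}", ec50_um=300.0, k=float(rng.uniform(4.0, 6.0)),
            onset_s=1800.0, amplitude=1.0, baseline=1.0, in_dose_range=False))
    return sensors


def simulate_dose_response_screen(
    sensors: list[ScreenSimTruth],
    doses_um=DEFAULT_DOSES_UM,
    times_s=(3600.0, 7200.0, 14400.0),
    n_replicates: int = 6,
    noise_cv: float = 0.05,
    seed: int = 20220624,
) -> pd.DataFrame:
    """Simulate sensor ratios on a logistic dose response developing in time.

    ratio = baseline + amplitude * logistic(log10 dose; EC50, k) * onset(t)
    with onset(t) = min(1, t / onset_s) and multiplicative noise of the given
    coefficient of variation.  Doses span the screen's geometric series from
    0.343 to 100 uM by default.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    doses = np.asarray(sorted(doses_um), dtype=float)
    if len(doses) < 4:
        raise ValueError("need >= 4 doses")
    if doses.max() / doses.min() < 100:
        raise ValueError("doses must span >= 2 orders of magnitude")
    rng = stage_rng(seed, "screen")
    rows = []
    for s in sensors:
        for t in times_s:
            onset = 1.0 if s.onset_s <= 0 else min(1.0, float(t) / s.onset_s)
            for dose in doses:
                x = np.log10(dose)
                response = 1.0 / (1.0 + np.exp(-s.k * (x - np.log10(s.ec50_um))))
                clean = s.baseline + s.amplitude * response * onset
                for rep in range(1, n_replicates + 1):
                    noise = np.exp(rng.normal(0.0, noise_cv)) if noise_cv > 0 else 1.0
                    rows.append({"sensor": s.sensor, "dose_um": float(dose),
                                 "time_s": float(t), "replicate": rep,
                                 "ratio": clean * noise})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Subcellular fraction time course with planted translocations
# ---------------------------------------------------------------------------

@dataclass
class CubeSimTruth:
    """Planted translocators (protein, fraction_from, fraction_to), temporal
    changers, and per-entity noise sd for a fraction time course."""

    translocators: list = field(default_factory=list)
    changers: list = field(default_factory=list)
    noise_sd: float = 0.0


def simulate_fraction_timecourse(
    n_proteins: int = 200,
    fractions: tuple = DEFAULT_FRACTIONS,
    time_points_s: tuple | None = None,
    n_replicates: int = 3,
    n_translocators: int = 20,
    n_changers: int = 20,
    noise_sd: float = 0.1,
    seed: int = 20220624,
    amplitude: float = 1.0,
) -> tuple[AbundanceCube, CubeSimTruth]:
    """Simulate a protein x fraction x time x replicate abundance cube.

    Translocators get a smooth monotone (logistic-in-time) ramp of the given
    amplitude in ``fraction_from`` and its exact negation in ``fraction_to``
    (pre-noise Pearson r = -1); changers get a single-bump temporal profile in
    one random fraction; everything else is flat zero.  Gaussian noise is
    added independently per replicate.
    """
    if n_translocators + n_changers > n_proteins:
        raise ValueError("n_translocators + n_changers must not exceed n_proteins")
    rng = stage_rng(seed, "cube")
    if time_points_s is None:
        time_points_s = tuple(sorted(t for ts in SERIES_TIME_POINTS_S.values() for t in ts))
    times = np.asarray(time_points_s, dtype=float)
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    replicates = [f"rep{r}" for r in range(1, n_replicates + 1)]
    values = np.zeros((n_proteins, len(fractions), len(times), n_replicates))

    # logistic ramp in log1p(time), centered mid-course
    z = np.log1p(times)
    ramp = 1.0 / (1.0 + np.exp(-(z - z.mean()) / (0.25 * (z.max() - z.min() + 1e-12))))
    bump = np.sin(np.pi * np.arange(len(times)) / max(len(times) - 1, 1))

    chosen = rng.permutation(n_proteins)[: n_translocators + n_changers]
    truth = CubeSimTruth(noise_sd=noise_sd)
    for i in chosen[:n_translocators]:
        f_from, f_to = rng.choice(len(fractions), size=2, replace=False)
        values[i, f_from, :, :] = -amplitude * ramp[:, None]
        values[i, f_to, :, :] = amplitude * ramp[:, None]
        truth.translocators.append((proteins[i], fractions[f_from], fractions[f_to]))
    for i in chosen[n_translocators:]:
        f = rng.integers(len(fractions))
        a = rng.normal(0.0, amplitude)
        values[i, f, :, :] = (a * bump)[:, None]
        truth.changers.append(proteins[i])
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, values.shape)
    cube = AbundanceCube(proteins, list(fractions), times, replicates, values)
    return cube, truth


# ---------------------------------------------------------------------------
# Two-condition correlation-perturbation panel
# ---------------------------------------------------------------------------

def simulate_network_perturbation(
    n_proteins: int = 50,
    n_timepoints: int = 15,
    n_replicates_per_condition: int = 3,
    perturbed_pairs: list | None = None,
    base_correlation: float = 0.9,
    seed: int = 20220624,
) -> tuple[AbundanceCube, AbundanceCube, list]:
    """Simulate vehicle and treated replicate panels with flipped-edge pairs.

    Vehicle samples are multivariate normal with correlation
    ``base_correlation`` inside each listed pair and zero elsewhere; the
    treated condition is identical except the listed pairs' correlations are
    flipped in sign.  A non-positive-semidefinite correlation matrix raises
    (no silent projection).
    """
    if not -1.0 < base_correlation < 1.0:
        raise ValueError("base_correlation must be in (-1, 1)")
    rng = stage_rng(seed, "network")
    if perturbed_pairs is None:
        perturbed_pairs = [(2 * i, 2 * i + 1) for i in range(min(20, n_proteins // 2))]
    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    pairs_ix = []
    for u, v in perturbed_pairs:
        iu = u if isinstance(u, (int, np.integer)) else proteins.index(u)
        iv = v if isinstance(v, (int, np.integer)) else proteins.index(v)
        pairs_ix.append((iu, iv))

    def build_sigma(sign: float) -> np.ndarray:
        sigma = np.eye(n_proteins)
        for iu, iv in pairs_ix:
            sigma[iu, iv] = sigma[iv, iu] = sign * base_correlation
        eig = np.linalg.eigvalsh(sigma)
        if eig.min() < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite")
        return sigma

    times = np.arange(n_timepoints, dtype=float) * 3600.0
    replicates = [f"rep{r}" for r in range(1, n_replicates_per_condition + 1)]
    cubes = []
    for sign in (1.0, -1.0):
        sigma = build_sigma(sign)
        chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(n_proteins))
        values = np.empty((n_proteins, 1, n_timepoints, n_replicates_per_condition))
        for r in range(n_replicates_per_condition):
            draws = rng.standard_normal((n_timepoints, n_proteins)) @ chol.T
            values[:, 0, :, r] = draws.T
        cubes.append(AbundanceCube(proteins, ["whole"], times, replicates, values))
    named_pairs = [(proteins[iu], proteins[iv]) for iu, iv in pairs_ix]
    return cubes[0], cubes[1], named_pairs


# ---------------------------------------------------------------------------
# Enzyme-kinetics plate
# ---------------------------------------------------------------------------

def simulate_kinetics_plate(
    wells: list[tuple[float, float]],
    frame_interval_s: float = 600.0,
    horizon_s: float = 5 * 3600.0,
    image_shape: tuple = (64, 64),
    noise_sd: float = 0.0,
    seed: int = 20220624,
    fmax_factor: float = 100.0,
) -> list[ImageFrame]:
    """Simulate per-well fluorescence image time series of product formation.

    The summed well intensity follows F(t) = Fmax*(1 - exp(-rate*t/Fmax))
    with ``rate`` in intensity per hour and Fmax = fmax_factor * rate * 1 h,
    which keeps the trace linear to well under 1% for t <= 1 h.  Intensity is
    distributed uniformly over pixels plus optional Gaussian noise.
    """
    rng = stage_rng(seed, "kinetics")
    n_frames = int(round(horizon_s / frame_interval_s)) + 1
    n_px = image_shape[0] * image_shape[1]
    frames = []
    for w, (dose, rate) in enumerate(wells):
        well = f"W{w:03d}"
        fmax = fmax_factor * rate if rate > 0 else 1.0
        for j in range(n_frames):
            t = j * frame_interval_s
            total = fmax * (1.0 - np.exp(-rate * (t / 3600.0) / fmax)) if rate > 0 else 0.0
            pixels = np.full(image_shape, total / n_px)
            if noise_sd > 0:
                pixels = np.clip(pixels + rng.normal(0.0, noise_sd, image_shape), 0, None)
            frames.append(ImageFrame(pixels=pixels, channel="TRITC", time_s=t, well=well))
    return frames


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

def simulate_frap_series(
    mobile_fraction: float = 0.6,
    tau_s: float = 5.0,
    photofade_rate: float = 0.0,
    n_frames: int = 120,
    frame_interval_s: float = 0.25,
    n_prebleach: int = 8,
    bleach_floor: float = 0.2,
    noise_sd: float = 0.0,
    seed: int = 20220624,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Simulate bleach-ROI and remote-ROI traces with shared photofading.

    Post-bleach the bleach ROI follows fade(t) * [c + m*(1 - exp(-(t-t0)/tau))]
    with prebleach baseline 1, c = ``bleach_floor`` and recovery amplitude
    m = mobile_fraction * (1 - c); the remote ROI is fade(t) with
    fade(t) = exp(-photofade_rate * t).  Returns (times, bleach, remote, truth).
    """
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile_fraction must be in [0, 1]")
    if photofade_rate < 0:
        raise ValueError("photofade_rate must be >= 0")
    rng = stage_rng(seed, "frap")
    times = np.arange(n_frames) * frame_interval_s
    t0 = n_prebleach * frame_interval_s
    fade = np.exp(-photofade_rate * times)
    m = mobile_fraction * (1.0 - bleach_floor)
    bleach = np.where(
        times < t0, 1.0,
        bleach_floor + m * (1.0 - np.exp(-(times - t0) / tau_s)),
    ) * fade
    remote = fade.copy()
    if noise_sd > 0:
        bleach = bleach + rng.normal(0.0, noise_sd, n_frames)
        remote = remote + rng.normal(0.0, noise_sd, n_frames)
    truth = {"mobile_fraction": mobile_fraction, "tau_s": tau_s,
             "bleach_floor": bleach_floor, "amplitude": m, "t_bleach_s": t0}
    return times, bleach, remote, truth


# ---------------------------------------------------------------------------
# Apoptosis imaging
# ---------------------------------------------------------------------------

def simulate_apoptosis_images(
    n_cells: int = 50,
    apoptotic_fraction: float = 0.25,
    cell_radius_px: int = 4,
    image_shape: tuple = (128, 128),
    background_gradient: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 20220624,
    cell_amplitude: float = 1000.0,
    background_level: float = 50.0,
) -> tuple[ImageFrame, ImageFrame, dict]:
    """Simulate a DAPI (all nuclei) and FITC (apoptotic) image pair.

    Cells are uniform discs; an ``apoptotic_fraction`` subset also appears in
    the FITC channel.  A smooth multiplicative gradient of relative strength
    ``background_gradient`` emulates uneven illumination (flat-field
    recoverable).  Truth records the exact union mask pixel counts.
    """
    if not 0.0 <= apoptotic_fraction <= 1.0:
        raise ValueError("apoptotic_fraction must be in [0, 1]")
    rng = stage_rng(seed, "apoptosis")
    h, w = image_shape
    margin = cell_radius_px + 1
    centers = np.column_stack([
        rng.integers(margin, h - margin, n_cells),
        rng.integers(margin, w - margin, n_cells),
    ])
    n_apo = int(round(apoptotic_fraction * n_cells))
    apoptotic = np.zeros(n_cells, dtype=bool)
    apoptotic[rng.permutation(n_cells)[:n_apo]] = True

    yy, xx = np.mgrid[0:h, 0:w]
    dapi_mask = np.zeros((h, w), dtype=bool)
    fitc_mask = np.zeros((h, w), dtype=bool)
    for (cy, cx), apo in zip(centers, apoptotic):
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= cell_radius_px ** 2
        dapi_mask |= disc
        if apo:
            fitc_mask |= disc

    gradient = 1.0 + background_gradient * (xx / max(w - 1, 1) - 0.5)

    def render(mask: np.ndarray) -> np.ndarray:
        img = background_level + cell_amplitude * mask.astype(float)
        img = img * gradient
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        return np.clip(img, 0.0, None)

    truth = {"dapi_pixels": int(dapi_mask.sum()), "fitc_pixels": int(fitc_mask.sum()),
             "dapi_mask": dapi_mask, "fitc_mask": fitc_mask,
             "n_apoptotic": n_apo, "gradient": gradient}
    dapi = ImageFrame(pixels=render(dapi_mask), channel="DAPI")
    fitc = ImageFrame(pixels=render(fitc_mask), channel="FITC")
    return dapi, fitc, truth
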