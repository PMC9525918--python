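"""Shared domain types for the perturbation-analysis pipeline.

The pipeline's atomic observations are peptide-spectrum matches (PSMs) carrying
11 isobaric (TMT) reporter-ion intensities, arranged in plexes whose channels
map to (time point, condition) pairs with one pooled *global mix* reference
channel per plex.  Downstream stages exchange protein x fraction x time x
replicate abundance cubes and single-channel grayscale image frames.

All times are stored in seconds internally; human-readable strings such as
``"40 min"`` are accepted at parse time.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

N_CHANNELS = 11

SERIES_TIME_POINTS_S: dict[str, tuple[float, ...]] = {
    # 15-point time course split into three interleaved 5-point series
    "A": (0.0, 40 * 60.0, 3 * 3600.0, 12 * 3600.0, 24 * 3600.0),
    "B": (10 * 60.0, 80 * 60.0, 6 * 3600.0, 15 * 3600.0, 48 * 3600.0),
    "C": (20 * 60.0, 2 * 3600.0, 9 * 3600.0, 18 * 3600.0, 72 * 3600.0),
}

DEFAULT_FRACTIONS = ("cytosolic", "membrane", "nuclear")

_TIME_UNITS = {
    "s": 1.0, "sec": 1.0, "second": 1.0, "seconds": 1.0,
    "min": 60.0, "minute": 60.0, "minutes": 60.0, "m": 60.0,
    "h": 3600.0, "hr": 3600.0, "hour": 3600.0, "hours": 3600.0,
    "d": 86400.0, "day": 86400.0, "days": 86400.0,
}


class ValidationError(ValueError):
    """A domain-type invariant was violated."""


def parse_time(value) -> float:
    """Return a duration in seconds from a number or string like ``'40 min'``."""
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    text = str(value).strip()
    m = re.fullmatch(r"([-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)\s*([a-zA-Z]*)", text)
    if not m:
        raise ValidationError(f"cannot parse time value {value!r}")
    number, unit = m.groups()
    factor = _TIME_UNITS.get(unit.lower() or "s")
    if factor is None:
        raise ValidationError(f"unknown time unit {unit!r} in {value!r}")
    return float(number) * factor


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match with its 11 reporter-ion intensities."""

    psm_id: str
    peptide_sequence: str
    protein_ids: tuple[str, ...]
    plex_id: str
    intensities: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "protein_ids", tuple(self.protein_ids))
        object.__setattr__(self, "intensities", tuple(float(v) for v in self.intensities))
        if len(self.intensities) != N_CHANNELS:
            raise ValidationError(
                f"PSM {self.psm_id}: expected {N_CHANNELS} intensities, got {len(self.intensities)}"
            )
        if not all(math.isfinite(v) for v in self.intensities):
            raise ValidationError(f"PSM {self.psm_id}: non-finite intensity")
        if any(v < 0 for v in self.intensities):
            raise ValidationError(f"PSM {self.psm_id}: negative intensity")
        if len(self.protein_ids) < 1:
            raise ValidationError(f"PSM {self.psm_id}: no protein ids")


@dataclass(frozen=True)
class ChannelAssignment:
    """Role of one TMT channel: its time point and condition."""

    time_s: float
    condition: str  # treated | control | global_mix

    def __post_init__(self):
        if self.condition not in ("treated", "control", "global_mix"):
            raise ValidationError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class PlexDesign:
    """Design of one 11-plex: channel -> (time, condition), plus series metadata.

    Invariants: exactly one global-mix channel; every treated time point has a
    matched control channel at the same time point.
    """

    plex_id: str
    series: str
    fraction: str
    bio_replicate: int
    tech_replicate: int
    channel_map: tuple[ChannelAssignment, ...]

    def __post_init__(self):
        object.__setattr__(self, "channel_map", tuple(self.channel_map))
        if self.series not in ("A", "B", "C"):
            raise ValidationError(f"plex {self.plex_id}: series must be A/B/C, got {self.series!r}")
        if len(self.channel_map) != N_CHANNELS:
            raise ValidationError(
                f"plex {self.plex_id}: expected {N_CHANNELS} channels, got {len(self.channel_map)}"
            )
        if self.bio_replicate < 1 or self.tech_replicate < 1:
            raise ValidationError(f"plex {self.plex_id}: replicate indices must be >= 1")
        n_mix = sum(1 for c in self.channel_map if c.condition == "global_mix")
        if n_mix != 1:
            raise ValidationError(
                f"plex {self.plex_id}: exactly one global_mix channel required, found {n_mix}"
            )
        treated = {c.time_s for c in self.channel_map if c.condition == "treated"}
        control = {c.time_s for c in self.channel_map if c.condition == "control"}
        if treated != control:
            raise ValidationError(
                f"plex {self.plex_id}: treated/control time points are not matched pairs"
            )

    @property
    def mix_channel(self) -> int:
        """0-based index of the global-mix channel."""
        return next(i for i, c in enumerate(self.channel_map) if c.condition == "global_mix")

    @property
    def time_points_s(self) -> tuple[float, ...]:
        return tuple(sorted({c.time_s for c in self.channel_map if c.condition == "treated"}))


@dataclass
class AbundanceCube:
    """entity x fraction x time x replicate array of log2 differential abundance.

    Missing entries are NaN.  Time points strictly increasing (seconds).
    """

    entity_ids: list[str]
    fractions: list[str]
    time_points_s: np.ndarray
    replicates: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.time_points_s = np.asarray(self.time_points_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.entity_ids), len(self.fractions),
                    len(self.time_points_s), len(self.replicates))
        if self.values.shape != expected:
            raise ValidationError(
                f"cube shape {self.values.shape} does not match axes {expected}"
            )
        if np.any(np.diff(self.time_points_s) <= 0):
            raise ValidationError("time points must be strictly increasing")

    def restrict_entities(self, ids: Sequence[str]) -> "AbundanceCube":
        index = {e: i for i, e in enumerate(self.entity_ids)}
        rows = [index[e] for e in ids]
        return AbundanceCube(list(ids), list(self.fractions), self.time_points_s.copy(),
                             list(self.replicates), self.values[rows])

    def replicate_mean(self) -> np.ndarray:
        """entity x fraction x time mean over replicates, ignoring NaN."""
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.values, axis=3)


@dataclass
class ImageFrame:
    """One single-channel grayscale frame with acquisition metadata."""

    pixels: np.ndarray
    channel: str = ""
    time_s: float = 0.0
    well: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError("pixels must be a 2-D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValidationError("pixels must be non-negative")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 20220624,
    "tmt": {
        "n_chains": 5,
        "n_steps": 2000,
        "burn_in": 0.25,
        "nu": None,             # None -> nu^2 sampled under InvGamma(2, 0.5)
        "tau": None,            # None -> estimated with half-Normal(0, 0.5) hyperprior
        "sigma2_prior_shape": 2.0,
        "sigma2_prior_scale": 0.5,
        "sd_floor": 1e-3,
        "rhat_threshold": 1.05,
        "alpha": 0.05,
        "power": 0.8,
        "d_thresholds_by_n": {6: 1.50, 5: 1.75, 4: 2.25, 3: 3.38},
    },
    "fret": {
        "x_transform": "log10",
        "r2_threshold": 0.75,
        "mask_k_sigma": 3.0,
    },
    "network": {
        "retain_neg_log10_p": 2.0,
        "fisher_z": False,
        "welch": False,
        "drop_isolated": True,
        "sbm_b_max": 6,
        "sbm_restarts": 5,
    },
    "timecourse": {
        "spline_df": 3,
        "n_permutations": 1000,
        "r_threshold": -0.8,
        "variance_target": 0.9,
    },
    "merge": {
        "protein_edge_q_max": 0.01,
        "rna_edge_q_max": 0.01,
        "rna_min_abs_log2fc": 0.5,
        "de_gene_q_max": 0.05,
        "de_gene_min_abs_log2fc": 1.0,
        "dispensability_max": 0.1,
        "term_q_max": 0.05,
    },
    "imaging": {
        "k_sigma": 3.0,
        "background": "percentile",
        "background_percentile": 5.0,
        "rate_window_s": [0.0, 3600.0],
    },
}

_RANGES = {
    ("tmt", "burn_in"): (0.0, 1.0),
    ("tmt", "alpha"): (0.0, 1.0),
    ("tmt", "power"): (0.0, 1.0),
    ("fret", "r2_threshold"): (-math.inf, 1.0),
    ("timecourse", "r_threshold"): (-1.0, 1.0),
    ("timecourse", "variance_target"): (0.0, 1.0),
    ("merge", "protein_edge_q_max"): (0.0, 1.0),
    ("merge", "rna_edge_q_max"): (0.0, 1.0),
    ("merge", "de_gene_q_max"): (0.0, 1.0),
    ("merge", "dispensability_max"): (0.0, 1.0),
    ("merge", "term_q_max"): (0.0, 1.0),
}


def _deep_merge(base: dict, override: dict, path=()) -> dict:
    out = dict(base)
    for key, value in override.items():
        if key in base and isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(base[key], value, path + (key,))
        else:
            out[key] = value
    return out


@dataclass
class PipelineConfig:
    """Validated per-stage parameter blocks with documented defaults."""

    params: dict = field(default_factory=lambda: _deep_merge(DEFAULT_CONFIG, {}))

    @classmethod
    def from_dict(cls, overrides: dict | None) -> "PipelineConfig":
        cfg = cls(_deep_merge(DEFAULT_CONFIG, overrides or {}))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not isinstance(self.params.get("seed"), int):
            raise ValidationError("seed must be an integer")
        for (stage, key), (lo, hi) in _RANGES.items():
            value = self.params.get(stage, {}).get(key)
            if value is None:
                continue
            if not (lo <= float(value) <= hi):
                raise ValidationError(
                    f"{stage}.{key} = {value} outside legal range [{lo}, {hi}]"
                )
        if self.params["tmt"]["n_chains"] < 2:
            raise ValidationError("tmt.n_chains must be >= 2 for convergence diagnostics")

    def __getitem__(self, key):
        return self.params[key]
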