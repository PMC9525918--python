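"""Readers and writers for the pipeline's tabular, image and config formats.

Tabular files are tab-separated UTF-8 with a mandatory header row, ``.``
decimal separator and empty fields for missing values.  Images are
single-channel grayscale TIFF.  Schemas are documented in ``docs/schemas.md``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datamodel import (
    N_CHANNELS,
    AbundanceCube,
    ChannelAssignment,
    ImageFrame,
    PipelineConfig,
    PlexDesign,
    PsmRecord,
    ValidationError,
    parse_time,
)

PSM_COLUMNS = ["psm_id", "peptide", "proteins", "plex_id"] + [
    f"intensity_{i}" for i in range(1, N_CHANNELS + 1)
]
DESIGN_COLUMNS = ["plex_id", "series", "fraction", "bio_replicate",
                  "tech_replicate", "channel", "time", "condition"]
CUBE_COLUMNS = ["entity", "fraction", "time_s", "replicate", "value"]


class SchemaError(ValueError):
    """A table is missing a required column or has a malformed row."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {', '.join(missing)}")


# ---------------------------------------------------------------------------
# PSM + design tables
# ---------------------------------------------------------------------------

def read_design_table(path) -> list[PlexDesign]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, DESIGN_COLUMNS, "design table")
    designs = []
    for plex_id, rows in df.groupby("plex_id", sort=True):
        rows = rows.copy()
        rows["channel"] = rows["channel"].astype(int)
        rows = rows.sort_values("channel")
        if list(rows["channel"]) != list(range(1, N_CHANNELS + 1)):
            raise ValidationError(f"plex {plex_id}: channels must be 1..{N_CHANNELS}")
        channel_map = tuple(
            ChannelAssignment(time_s=parse_time(t), condition=c)
            for t, c in zip(rows["time"], rows["condition"])
        )
        head = rows.iloc[0]
        designs.append(PlexDesign(
            plex_id=str(plex_id),
            series=str(head["series"]),
            fraction=str(head["fraction"]),
            bio_replicate=int(head["bio_replicate"]),
            tech_replicate=int(head["tech_replicate"]),
            channel_map=channel_map,
        ))
    return designs


def read_psm_table(path, design_path) -> tuple[list[PsmRecord], list[PlexDesign]]:
    """Read PSM and design TSVs; validate records against the design."""
    designs = read_design_table(design_path)
    known_plexes = {d.plex_id for d in designs}
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, PSM_COLUMNS, "psm table")
    intensity_cols = [f"intensity_{i}" for i in range(1, N_CHANNELS + 1)]
    records = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            intensities = tuple(float(row[c]) for c in intensity_cols)
        except (TypeError, ValueError):
            raise SchemaError(f"psm table row {row_number}: non-numeric intensity")
        if any(not np.isfinite(v) for v in intensities):
            raise SchemaError(f"psm table row {row_number}: non-finite intensity")
        if row["plex_id"] not in known_plexes:
            raise ValidationError(
                f"psm table row {row_number}: unknown plex_id {row['plex_id']!r}"
            )
        records.append(PsmRecord(
            psm_id=str(row["psm_id"]),
            peptide_sequence=str(row["peptide"]),
            protein_ids=tuple(str(row["proteins"]).split(";")),
            plex_id=str(row["plex_id"]),
            intensities=intensities,
        ))
    return records, designs


def write_psm_table(records: list[PsmRecord], path) -> None:
    rows = []
    for r in records:
        row = {"psm_id": r.psm_id, "peptide": r.peptide_sequence,
               "proteins": ";".join(r.protein_ids), "plex_id": r.plex_id}
        for i, v in enumerate(r.intensities, start=1):
            row[f"intensity_{i}"] = repr(v)
        rows.append(row)
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, sep="\t", index=False)


def write_design_table(designs: list[PlexDesign], path) -> None:
    rows = []
    for d in designs:
        for channel, assign in enumerate(d.channel_map, start=1):
            rows.append({
                "plex_id": d.plex_id, "series": d.series, "fraction": d.fraction,
                "bio_replicate": d.bio_replicate, "tech_replicate": d.tech_replicate,
                "channel": channel, "time": repr(assign.time_s),
                "condition": assign.condition,
            })
    pd.DataFrame(rows, columns=DESIGN_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Abundance cubes (long format)
# ---------------------------------------------------------------------------

def write_cube(cube: AbundanceCube, path) -> None:
    rows = []
    for i, e in enumerate(cube.entity_ids):
        for j, f in enumerate(cube.fractions):
            for k, t in enumerate(cube.time_points_s):
                for l, r in enumerate(cube.replicates):
                    v = cube.values[i, j, k, l]
                    rows.append({"entity": e, "fraction": f, "time_s": repr(float(t)),
                                 "replicate": r,
                                 "value": "" if np.isnan(v) else repr(float(v))})
    pd.DataFrame(rows, columns=CUBE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cube(path) -> AbundanceCube:
    df = pd.read_csv(path, sep="\t", dtype={"entity": str, "fraction": str,
                                            "replicate": str})
    _require_columns(df, CUBE_COLUMNS, "abundance cube")
    entities = sorted(df["entity"].unique())
    fractions = sorted(df["fraction"].unique())
    times = np.array(sorted(df["time_s"].astype(float).unique()))
    replicates = sorted(df["replicate"].astype(str).unique())
    e_ix = {e: i for i, e in enumerate(entities)}
    f_ix = {f: i for i, f in enumerate(fractions)}
    t_ix = {t: i for i, t in enumerate(times)}
    r_ix = {r: i for i, r in enumerate(replicates)}
    values = np.full((len(entities), len(fractions), len(times), len(replicates)), np.nan)
    vv = pd.to_numeric(df["value"], errors="coerce").to_numpy()
    for row, v in zip(df.itertuples(index=False), vv):
        values[e_ix[row.entity], f_ix[row.fraction],
               t_ix[float(row.time_s)], r_ix[str(row.replicate)]] = v
    return AbundanceCube(entities, fractions, times, replicates, values)


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def write_image(frame: ImageFrame, path, dtype=np.float32) -> None:
    tifffile.imwrite(os.fspath(path), frame.pixels.astype(dtype))


def read_image_stack(paths, metadata: pd.DataFrame) -> list[ImageFrame]:
    """Load TIFF frames and sort them by (well, channel, time).

    ``metadata`` maps file name to (well, channel, time); frames of one well
    must share a shape.
    """
    _require_columns(metadata, ["file", "well", "channel", "time"], "image metadata")
    by_name = {Path(p).name: Path(p) for p in paths}
    frames = []
    for row in metadata.itertuples(index=False):
        path = by_name.get(Path(row.file).name, Path(row.file))
        if not Path(path).exists():
            raise IOError(f"image file not found: {row.file}")
        pixels = tifffile.imread(os.fspath(path))
        frames.append(ImageFrame(pixels=np.asarray(pixels, dtype=float),
                                 channel=str(row.channel),
                                 time_s=parse_time(row.time), well=str(row.well)))
    frames.sort(key=lambda fr: (fr.well, fr.channel, fr.time_s))
    shapes: dict[str, tuple] = {}
    for fr in frames:
        prior = shapes.setdefault(fr.well, fr.pixels.shape)
        if fr.pixels.shape != prior:
            raise ValidationError(f"well {fr.well}: frame shape mismatch "
                                  f"{fr.pixels.shape} vs {prior}")
    return frames


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path=None) -> PipelineConfig:
    """Load a YAML config, filling defaults for absent keys."""
    overrides = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            overrides = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(overrides)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.params, fh, sort_keys=True)
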