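# File formats

All tabular files are tab-separated UTF-8 with a mandatory header row, `.` as
the decimal separator, and missing values written as empty fields. Times are
stored in seconds; readers also accept human-readable durations such as
`"40 min"` or `"3 h"`. Writers are bit-stable for fixed inputs.

## PSM table (`psms.tsv`)

One row per peptide-spectrum match.

| column | content |
| --- | --- |
| `psm_id` | unique identifier |
| `peptide` | peptide sequence |
| `proteins` | `;`-separated protein ids (>= 1) |
| `plex_id` | id of the 11-plex the PSM was measured in |
| `intensity_1` .. `intensity_11` | reporter-ion intensities, non-negative |

## Design table (`design.tsv`)

One row per (plex, channel); channels 1..11 must all be present per plex.

| column | content |
| --- | --- |
| `plex_id` | plex identifier |
| `series` | `A`, `B` or `C` |
| `fraction` | subcellular fraction label |
| `bio_replicate` | biological replicate index (>= 1) |
| `tech_replicate` | technical replicate index (>= 1) |
| `channel` | 1..11 |
| `time` | channel time point (seconds or duration string) |
| `condition` | `treated`, `control` or `global_mix` (exactly one per plex) |

Every treated time point must have a matched control channel at the same
time point.

## Abundance cube (long format)

| column | content |
| --- | --- |
| `entity` | protein/gene id |
| `fraction` | fraction label |
| `time_s` | time point in seconds |
| `replicate` | replicate label |
| `value` | log2 differential abundance; empty if missing |

## Dose-response measurements

| column | content |
| --- | --- |
| `sensor` | biosensor identifier |
| `dose_um` | dose in micromolar (0 allowed; excluded from log fits) |
| `time_s` | measurement time |
| `replicate` | replicate index |
| `ratio` | FRET/CFP ratio (> 0) |

## Images

Single-channel grayscale TIFF (16-bit integer or 32-bit float), row-major,
origin top-left. Image stacks are described by a metadata table with columns
`file`, `well`, `channel`, `time`.

## Configuration

YAML with per-stage blocks (`tmt`, `fret`, `network`, `timecourse`, `merge`,
`imaging`) plus a top-level integer `seed`. Absent keys fall back to
documented defaults; out-of-range values are rejected at load time.
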