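"""Domain types, container I/O and stimulus-set bookkeeping.

The pipeline's inputs are (a) a multichannel voltage recording with channel
metadata, stored in an HDF5 container, (b) a trial table (stimulus id, onset
sample, 1-back repeat flag) and (c) a stimulus table (category, vocal/speech
flags, duration), both as tab-separated text.  This module defines those
types, validates their invariants, and implements the stimulus-set
construction rules of the two experimental tasks:

* **VL** (voice localizer): 550 ms clips, vocal and nonvocal classes balanced
  by keeping only the first ``n_vocal`` nonvocal sounds in their canonical
  order.
* **NatS** (natural sounds): 165 two-second sounds in 11 categories, grouped
  into superordinate vocal / nonvocal classes, with a small set of
  crowd-generated or voiceless human sounds reclassified from vocal to
  nonvocal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd


class VoicegateError(Exception):
    """Base class for pipeline errors."""


class FormatError(VoicegateError):
    """A container or table is missing required fields."""


class ConsistencyError(VoicegateError):
    """Fields are present but mutually inconsistent."""


class DegenerateDataError(VoicegateError):
    """Data are valid but degenerate (e.g. a constant channel)."""


# ---------------------------------------------------------------------------
# channels and recordings
# ---------------------------------------------------------------------------

ROI_LABELS = ("HG", "PT", "STG", "STS", "other")
#: super-ROI grouping: supratemporal plane vs. lateral temporal cortex
SUPER_ROI = {"HG": "STP", "PT": "STP", "STG": "STG/STS", "STS": "STG/STS", "other": "other"}
HEMISPHERES = ("left", "right")


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one sEEG contact.

    ``roi`` is an anatomical label consumed as input (localization itself is
    out of scope); ``other`` channels are carried through preprocessing but
    excluded from ROI contrasts.
    """

    channel_id: str
    roi: str = "other"
    hemisphere: str = "left"
    dist_to_cortex_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.roi not in ROI_LABELS:
            raise ValueError(f"roi must be one of {ROI_LABELS}, got {self.roi!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}")
        if not np.isfinite(self.dist_to_cortex_mm) or self.dist_to_cortex_mm < 0:
            raise ValueError("dist_to_cortex_mm must be a nonnegative real")

    @property
    def super_roi(self) -> str:
        return SUPER_ROI[self.roi]


@dataclass
class Recording:
    """Raw multichannel voltage (µV), channels × samples."""

    sample_rate_hz: float
    voltage: np.ndarray
    channels: list[ChannelInfo]

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.voltage.ndim != 2:
            raise ConsistencyError("voltage must be a 2-D channels × samples array")
        if self.voltage.shape[0] != len(self.channels):
            raise ConsistencyError(
                f"voltage has {self.voltage.shape[0]} rows but {len(self.channels)} "
                "channel metadata entries"
            )

    @property
    def n_channels(self) -> int:
        return self.voltage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltage.shape[1]


def write_recording(path: str | Path, rec: Recording) -> None:
    """Write a recording to an HDF5 container (voltage + rate + channel table)."""
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("voltage", data=rec.voltage)
        dset.attrs["units"] = "uV"
        f.attrs["sample_rate_hz"] = float(rec.sample_rate_hz)
        grp = f.create_group("channels")
        enc = h5py.string_dtype(encoding="utf-8")
        grp.create_dataset("channel_id", data=[c.channel_id for c in rec.channels], dtype=enc)
        grp.create_dataset("roi", data=[c.roi for c in rec.channels], dtype=enc)
        grp.create_dataset("hemisphere", data=[c.hemisphere for c in rec.channels], dtype=enc)
        grp.create_dataset(
            "dist_to_cortex_mm", data=[c.dist_to_cortex_mm for c in rec.channels]
        )


def read_recording(path: str | Path) -> Recording:
    """Read a recording container written by :func:`write_recording`.

    Raises
    ------
    FormatError
        if the container lacks the voltage array, sample rate or channel table.
    ConsistencyError
        if the channel table length does not match the voltage row count.
    """
    with h5py.File(path, "r") as f:
        if "voltage" not in f:
            raise FormatError(f"{path}: missing 'voltage' dataset")
        if "sample_rate_hz" not in f.attrs:
            raise FormatError(f"{path}: missing 'sample_rate_hz' attribute")
        if "channels" not in f:
            raise ConsistencyError(f"{path}: missing channel table")
        grp = f["channels"]
        for key in ("channel_id", "roi", "hemisphere", "dist_to_cortex_mm"):
            if key not in grp:
                raise FormatError(f"{path}: channel table missing '{key}'")
        channels = [
            ChannelInfo(
                channel_id=cid.decode() if isinstance(cid, bytes) else str(cid),
                roi=roi.decode() if isinstance(roi, bytes) else str(roi),
                hemisphere=hemi.decode() if isinstance(hemi, bytes) else str(hemi),
                dist_to_cortex_mm=float(d),
            )
            for cid, roi, hemi, d in zip(
                grp["channel_id"][()],
                grp["roi"][()],
                grp["hemisphere"][()],
                grp["dist_to_cortex_mm"][()],
            )
        ]
        return Recording(
            sample_rate_hz=float(f.attrs["sample_rate_hz"]),
            voltage=f["voltage"][()],
            channels=channels,
        )


# ---------------------------------------------------------------------------
# stimulus and trial tables
# ---------------------------------------------------------------------------

STIMULUS_COLUMNS = [
    "stimulus_id",
    "task",
    "category",
    "vocal",
    "speech",
    "duration_ms",
    "excluded_from_encoding",
]
TRIAL_COLUMNS = ["trial_id", "stimulus_id", "onset_sample", "is_repeat"]


def validate_stimulus_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in STIMULUS_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"stimulus table missing columns {missing}")
    if table["stimulus_id"].duplicated().any():
        raise ConsistencyError("duplicate stimulus ids")
    if (table["speech"] & ~table["vocal"]).any():
        raise ConsistencyError("speech stimuli must be vocal")
    for task, grp in table.groupby("task"):
        if grp["duration_ms"].nunique() != 1:
            raise ConsistencyError(f"duration must be constant within task {task!r}")
    if (table["duration_ms"] <= 0).any():
        raise ConsistencyError("durations must be positive")
    return table


def validate_trial_table(trials: pd.DataFrame, stimuli: pd.DataFrame,
                         min_isi_ms: float | None = None,
                         sample_rate_hz: float = 1000.0) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise FormatError(f"trial table missing columns {missing}")
    onsets = trials["onset_sample"].to_numpy()
    if not np.all(np.diff(onsets) > 0):
        raise ConsistencyError("trial onsets must be strictly increasing")
    unknown = set(trials["stimulus_id"]) - set(stimuli["stimulus_id"])
    if unknown:
        raise ConsistencyError(f"trials reference unknown stimuli: {sorted(unknown)[:5]}")
    if min_isi_ms is not None and len(trials) > 1:
        dur = stimuli.set_index("stimulus_id")["duration_ms"]
        dur_samples = dur.loc[trials["stimulus_id"].iloc[:-1]].to_numpy() * sample_rate_hz / 1000.0
        min_gap = dur_samples + min_isi_ms * sample_rate_hz / 1000.0
        if np.any(np.diff(onsets) < np.floor(min_gap)):
            raise ConsistencyError("inter-onset gap below stimulus duration + minimum ISI")
    return trials


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# stimulus-set construction rules
# ---------------------------------------------------------------------------

#: NatS categories with per-category counts (total 165; vocal superordinate
#: class = speech + human nonspeech vocalizations + lyrical music, 41 sounds
#: before reclassification).  Category names and counts are representative of
#: a natural-sound inventory; the class structure is what downstream analyses
#: consume.
NATS_CATEGORIES: dict[str, tuple[int, bool, bool]] = {
    # category: (count, vocal, speech)
    "english_speech": (10, True, True),
    "foreign_speech": (10, True, True),
    "lyrical_music": (10, True, True),
    "human_nonspeech_vocal": (11, True, False),
    "animal_vocalization": (18, False, False),
    "instrumental_music": (20, False, False),
    "nature": (18, False, False),
    "mechanical": (18, False, False),
    "tools": (18, False, False),
    "environmental": (16, False, False),
    "animal_nonvocal": (16, False, False),
}

#: named human nonspeech vocalizations; the first four are crowd-generated or
#: lack vocal-fold vibration and are reclassified to the nonvocal class.
_HUMAN_NONSPEECH_SOUNDS = [
    "cheering", "crowd_laughter", "breathing", "whistling",
    "laughter", "crying", "coughing", "sneezing", "yawning", "humming", "sighing",
]

DEFAULT_NATS_RECLASSIFY = [f"human_nonspeech_vocal_{name}" for name in _HUMAN_NONSPEECH_SOUNDS[:4]]


def make_nats_stimulus_table(reclassify: Sequence[str] | None = DEFAULT_NATS_RECLASSIFY,
                             ) -> pd.DataFrame:
    """Build the 165-sound NatS stimulus table (2,000 ms sounds, 11 categories).

    By default the four crowd/voiceless human sounds are reclassified to the
    nonvocal class, yielding 37 vocal and 128 nonvocal stimuli.
    """
    rows = []
    for category, (count, vocal, speech) in NATS_CATEGORIES.items():
        if category == "human_nonspeech_vocal":
            names = _HUMAN_NONSPEECH_SOUNDS
        else:
            names = [f"{i:02d}" for i in range(count)]
        for name in names[:count]:
            rows.append(
                {
                    "stimulus_id": f"{category}_{name}",
                    "task": "NatS",
                    "category": category,
                    "vocal": vocal,
                    "speech": speech,
                    "duration_ms": 2000.0,
                    "excluded_from_encoding": False,
                }
            )
    table = pd.DataFrame(rows, columns=STIMULUS_COLUMNS)
    if reclassify:
        table = reclassify_nats_vocal(table, list(reclassify))
    return validate_stimulus_table(table)


def make_vl_stimulus_table(n_vocal: int = 72, n_nonvocal: int = 80) -> pd.DataFrame:
    """Build the VL stimulus table (550 ms clips), balanced to equal classes.

    The segmentation step of the original localizer yields more nonvocal than
    vocal clips; only the first ``n_vocal`` nonvocal clips (canonical order)
    are kept.
    """
    rows = []
    for i in range(n_vocal):
        rows.append(
            {
                "stimulus_id": f"vl_vocal_{i:02d}",
                "task": "VL",
                "category": "vocal",
                "vocal": True,
                "speech": False,
                "duration_ms": 550.0,
                "excluded_from_encoding": False,
            }
        )
    nonvocal_ids = [f"vl_nonvocal_{i:02d}" for i in range(n_nonvocal)]
    keep = balance_vl_classes(n_nonvocal, n_vocal, nonvocal_ids)
    for sid in keep:
        rows.append(
            {
                "stimulus_id": sid,
                "task": "VL",
                "category": "nonvocal",
                "vocal": False,
                "speech": False,
                "duration_ms": 550.0,
                "excluded_from_encoding": False,
            }
        )
    return validate_stimulus_table(pd.DataFrame(rows, columns=STIMULUS_COLUMNS))


def balance_vl_classes(n_nonvocal: int, n_vocal: int, order: Sequence[str]) -> list[str]:
    """Class-balancing rule for the VL set.

    Keeps the first ``min(n_nonvocal, n_vocal)`` nonvocal stimuli in their
    canonical ``order``; the vocal set is left unchanged by the caller.
    Returns the retained nonvocal stimulus ids.
    """
    if n_nonvocal < 0 or n_vocal < 0:
        raise ValueError("stimulus counts must be nonnegative")
    if len(order) < n_nonvocal:
        raise ValueError(
            f"order lists {len(order)} nonvocal stimuli but n_nonvocal={n_nonvocal}"
        )
    keep = min(n_nonvocal, n_vocal)
    return list(order[:keep])


def reclassify_nats_vocal(table: pd.DataFrame, reclassify_ids: Sequence[str]) -> pd.DataFrame:
    """Move the listed stimuli from the vocal to the nonvocal class.

    Every id must exist in the table and currently be vocal; all other rows
    (and the total row count) are unchanged.
    """
    out = table.copy()
    idx = out.set_index("stimulus_id")
    for sid in reclassify_ids:
        if sid not in idx.index:
            raise ValueError(f"stimulus id {sid!r} not in table")
        if not bool(idx.loc[sid, "vocal"]):
            raise ValueError(f"stimulus {sid!r} is already nonvocal")
    mask = out["stimulus_id"].isin(set(reclassify_ids))
    out.loc[mask, "vocal"] = False
    out.loc[mask, "speech"] = False
    return out


# ---------------------------------------------------------------------------
# cohort bookkeeping
# ---------------------------------------------------------------------------

#: auditory-responsive / total contact counts per patient (P1..P8) from the
#: published cohort; the first three patients also performed the VL task.
COHORT_CHANNEL_COUNTS: list[tuple[int, int]] = [
    (72, 256), (70, 226), (32, 120), (37, 127), (28, 104), (55, 117), (58, 117), (47, 52),
]
VL_PATIENTS = slice(0, 3)


def summarize_channel_counts(per_patient: Iterable[tuple[int, int]]) -> dict[str, int]:
    """Sum and extrema of auditory-responsive channel counts across patients.

    Each element is ``(responsive, total)`` with ``responsive <= total``.
    """
    per_patient = list(per_patient)
    if not per_patient:
        raise ValueError("per_patient must be non-empty")
    responsive = []
    for resp, total in per_patient:
        if resp > total:
            raise ConsistencyError(f"responsive count {resp} exceeds total {total}")
        if resp < 0 or total < 0:
            raise ValueError("counts must be nonnegative")
        responsive.append(int(resp))
    return {
        "sum_responsive": int(sum(responsive)),
        "min": int(min(responsive)),
        "max": int(max(responsive)),
    }
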