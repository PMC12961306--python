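"""Reading and writing recordings, metadata, and results.

Signals travel as EDF (16-bit European Data Format); metadata and
results as UTF-8 tab-separated tables following BIDS-iEEG naming
conventions (``*_channels.tsv``, ``*_electrodes.tsv``, ``*_events.tsv``)
without claiming full BIDS validation. A JSON manifest records every
tunable that affects results, so a run is reproducible from its outputs.

EDF writing is implemented here directly (fixed physical range, fixed
start date so identical inputs give byte-identical files); reading goes
through :func:`mne.io.read_raw_edf`, which also serves as an independent
check on the writer.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Documented ROI vocabulary; anything else maps to "other".
ROI_VOCABULARY = ("HG", "STG", "MTG", "ITG", "IFG", "other")

#: Default EDF physical range in microvolts (symmetric). With 16-bit
#: digitization the quantization step is 200/65535 ~= 0.003 uV, far below
#: the unit-SD synthetic signals, so round-trips are phase-faithful.
EDF_PHYS_RANGE_UV = 100.0

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


class IOFormatError(ValueError):
    """Raised on malformed files or metadata contract violations."""


@dataclass
class ContactRecord:
    """One electrode contact with its anatomical metadata."""

    contact_id: str
    subject_id: str
    hemisphere: str  # L | R
    roi_label: str  # from ROI_VOCABULARY
    mni_xyz: tuple[float, float, float]
    sampling_rate: float | None = None


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise IOFormatError(f"EDF field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    data: np.ndarray,
    sfreq: float,
    ch_names: list[str],
    phys_range: float = EDF_PHYS_RANGE_UV,
) -> Path:
    """Write a channels x samples array as a 16-bit EDF file.

    The record duration is 1 s; the final partial record is zero-padded.
    The start date/time is fixed so rewriting identical data yields a
    byte-identical file. Samples outside ``+/-phys_range`` are clipped.
    """
    path = Path(path)
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise IOFormatError("EDF data must be 2-D (channels x samples)")
    n_ch, n_samp = data.shape
    if len(ch_names) != n_ch:
        raise IOFormatError(f"{len(ch_names)} names for {n_ch} channels")
    spr = int(round(sfreq))  # samples per 1-s record
    if abs(spr - sfreq) > 1e-9:
        raise IOFormatError(f"non-integer sampling rate {sfreq} not supported")
    n_rec = int(np.ceil(n_samp / spr))

    pmin, pmax = -phys_range, phys_range
    cal = (pmax - pmin) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    offset = pmin - _EDF_DIG_MIN * cal
    dig = np.round((np.clip(data, pmin, pmax) - offset) / cal)
    dig = np.clip(dig, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")
    if n_rec * spr > n_samp:
        pad = np.full((n_ch, n_rec * spr - n_samp),
                      int(round(-offset / cal)), dtype="<i2")
        dig = np.concatenate([dig, pad], axis=1)

    header = b"".join([
        _ascii("0", 8),
        _ascii("X X X X", 80),
        _ascii("Startdate 01-JAN-2000 X X X", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (n_ch + 1), 8),
        _ascii("", 44),
        _ascii(n_rec, 8),
        _ascii(1, 8),
        _ascii(n_ch, 4),
    ])
    fields = [
        [_ascii(name[:16], 16) for name in ch_names],
        [_ascii("sEEG depth contact", 80)] * n_ch,
        [_ascii("uV", 8)] * n_ch,
        [_ascii(f"{pmin:g}", 8)] * n_ch,
        [_ascii(f"{pmax:g}", 8)] * n_ch,
        [_ascii(_EDF_DIG_MIN, 8)] * n_ch,
        [_ascii(_EDF_DIG_MAX, 8)] * n_ch,
        [_ascii("", 80)] * n_ch,
        [_ascii(spr, 8)] * n_ch,
        [_ascii("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.write(b"".join(group))
        # record-interleaved samples: record r holds each channel's block
        for r in range(n_rec):
            fh.write(dig[:, r * spr:(r + 1) * spr].tobytes())
    return path


def load_recording(
    edf_path: str | Path, channels_tsv: str | Path | None = None
) -> tuple[np.ndarray, float, list[str]]:
    """Load a continuous EDF recording.

    Returns ``(data, sfreq, ch_names)`` with ``data`` in microvolts
    (channels x samples). If a channels sidecar is given, its channel
    set must match the EDF exactly; mismatches are reported by name.
    """
    import mne

    edf_path = Path(edf_path)
    if not edf_path.exists():
        raise IOFormatError(f"recording not found: {edf_path}")
    try:
        raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - delegated parser
        raise IOFormatError(f"unreadable EDF file {edf_path}: {exc}") from exc
    ch_names = list(raw.ch_names)
    if channels_tsv is not None:
        side = read_tsv(channels_tsv)
        if "name" not in side.columns:
            raise IOFormatError(f"channels sidecar {channels_tsv} lacks 'name'")
        side_names = list(side["name"].astype(str))
        missing = sorted(set(side_names) - set(ch_names))
        extra = sorted(set(ch_names) - set(side_names))
        if missing or extra:
            raise IOFormatError(
                f"channel/sidecar mismatch for {edf_path.name}: "
                f"missing from EDF {missing}, missing from sidecar {extra}"
            )
    data = raw.get_data() * 1e6  # MNE returns volts; sidecar units are uV
    return data, float(raw.info["sfreq"]), ch_names


def read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"table not found: {path}")
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    """Deterministic TSV writer (UTF-8, header row, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def load_contacts(tsv_path: str | Path) -> list[ContactRecord]:
    """Load and validate an electrodes table.

    Expected columns: name, subject_id, hemisphere, roi, x, y, z (MNI
    millimeters). Unknown ROI labels map to "other" with a warning;
    duplicate contact ids, bad hemispheres, or malformed coordinates
    are errors.
    """
    df = read_tsv(tsv_path)
    required = {"name", "subject_id", "hemisphere", "roi", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise IOFormatError(f"electrodes table missing columns {sorted(missing)}")
    dupes = df["name"][df["name"].duplicated()].tolist()
    if dupes:
        raise IOFormatError(f"duplicate contact ids: {sorted(set(dupes))}")
    records = []
    for _, row in df.iterrows():
        hemi = str(row["hemisphere"])
        if hemi not in ("L", "R"):
            raise IOFormatError(
                f"contact {row['name']}: hemisphere must be L or R, got {hemi!r}"
            )
        roi = str(row["roi"])
        if roi not in ROI_VOCABULARY:
            logger.warning("contact %s: unknown ROI %r mapped to 'other'",
                           row["name"], roi)
            roi = "other"
        try:
            xyz = (float(row["x"]), float(row["y"]), float(row["z"]))
        except (TypeError, ValueError) as exc:
            raise IOFormatError(
                f"contact {row['name']}: malformed MNI coordinates"
            ) from exc
        if not all(np.isfinite(xyz)):
            raise IOFormatError(f"contact {row['name']}: non-finite coordinates")
        records.append(ContactRecord(
            contact_id=str(row["name"]),
            subject_id=str(row["subject_id"]),
            hemisphere=hemi,
            roi_label=roi,
            mni_xyz=xyz,
            sampling_rate=float(row["sampling_rate"])
            if "sampling_rate" in df.columns else None,
        ))
    return records


def load_events(tsv_path: str | Path) -> pd.DataFrame:
    """Load a trial event table (trial_id, condition, onset, duration)."""
    df = read_tsv(tsv_path)
    required = {"trial_id", "condition", "onset", "duration"}
    missing = required - set(df.columns)
    if missing:
        raise IOFormatError(f"events table missing columns {sorted(missing)}")
    onsets = df["onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise IOFormatError("event onsets must be strictly increasing")
    if np.any(df["duration"].to_numpy(dtype=float) <= 0):
        raise IOFormatError("event durations must be positive")
    return df


def spectra_to_frame(zspectra) -> pd.DataFrame:
    """Long-format table of Z spectra (one row per frequency bin).

    Frequencies are rounded to 2 decimals at this presentation layer
    only; the in-memory axis stays exact.
    """
    rows = []
    for zs in zspectra:
        for f, itpc, z in zip(zs.freqs, zs.itpc, zs.z):
            rows.append({
                "contact_id": zs.contact_id,
                "condition": zs.condition,
                "spectrum_kind": zs.kind,
                "frequency": round(float(f), 2),
                "itpc": round(float(itpc), 6),
                "z": round(float(z), 6),
            })
    return pd.DataFrame(
        rows, columns=["contact_id", "condition", "spectrum_kind",
                       "frequency", "itpc", "z"],
    )


def write_results(
    out_dir: str | Path,
    zspectra=None,
    flags: pd.DataFrame | None = None,
    roi_summary: pd.DataFrame | None = None,
    selectivity: pd.DataFrame | None = None,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Write result tables and the run manifest to ``out_dir``.

    Empty tables are written with their header row; rewriting identical
    inputs yields byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if zspectra is not None:
        frame = zspectra if isinstance(zspectra, pd.DataFrame) \
            else spectra_to_frame(zspectra)
        written["spectra"] = write_tsv(frame, out_dir / "spectra.tsv")
    if flags is not None:
        written["flags"] = write_tsv(flags, out_dir / "flags.tsv")
    if roi_summary is not None:
        written["roi_summary"] = write_tsv(roi_summary, out_dir / "roi_summary.tsv")
    if selectivity is not None:
        written["selectivity"] = write_tsv(selectivity, out_dir / "selectivity.tsv")
    if manifest is not None:
        p = out_dir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written["manifest"] = p
    return written


# ---------------------------------------------------------------------------
# truth-table serialization

_TAG_COLS = [("locked", "locked_tags"), ("hg", "hg_modulated_tags")]


def truth_to_frame(truth_list) -> pd.DataFrame:
    """Serialize ContactTruth records to a flat table.

    Tag sets are comma-joined per condition (e.g. ``2,4``); empty string
    means no locked tags in that condition.
    """
    rows = []
    for t in truth_list:
        row = {
            "contact_id": t.contact_id,
            "subject_id": t.subject_id,
            "roi": t.roi,
            "hemisphere": t.hemisphere,
        }
        for prefix, attr in _TAG_COLS:
            tags = getattr(t, attr)
            for cond in ("syllable", "phrase", "sentence"):
                row[f"{prefix}_{cond}"] = ",".join(
                    f"{tag:g}" for tag in sorted(tags.get(cond, ()))
                )
        row.update({
            "locking_strength": t.locking_strength,
            "hg_depth": t.hg_depth,
            "hg_scale": t.hg_scale,
            "noise_exponent": t.noise_exponent,
            "x": t.mni_xyz[0], "y": t.mni_xyz[1], "z": t.mni_xyz[2],
            "seed": t.seed,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_truth(df: pd.DataFrame):
    """Inverse of :func:`truth_to_frame`."""
    from .simulate import ContactTruth

    def _parse(cell) -> tuple[float, ...]:
        if pd.isna(cell) or str(cell).strip() == "":
            return ()
        return tuple(float(x) for x in str(cell).split(","))

    out = []
    for _, row in df.iterrows():
        kw = {}
        for prefix, attr in _TAG_COLS:
            d = {}
            for cond in ("syllable", "phrase", "sentence"):
                tags = _parse(row.get(f"{prefix}_{cond}", ""))
                if tags:
                    d[cond] = tags
            kw[attr] = d
        out.append(ContactTruth(
            contact_id=str(row["contact_id"]),
            subject_id=str(row["subject_id"]),
            roi=str(row["roi"]),
            hemisphere=str(row["hemisphere"]),
            locking_strength=float(row["locking_strength"]),
            hg_depth=float(row["hg_depth"]),
            hg_scale=float(row["hg_scale"]),
            noise_exponent=float(row["noise_exponent"]),
            mni_xyz=(float(row["x"]), float(row["y"]), float(row["z"])),
            seed=int(row["seed"]),
            **kw,
        ))
    return out
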