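"""Reading and writing sessions as plain CSV files.

Layout written by :func:`write_session` (and accepted by :func:`read_session`):

* ``<participant_id>.csv`` — columns ``time_s, posture_deg, hr_bpm``; missing
  samples are empty cells.
* ``proximity.csv`` — ``id_a, id_b, mean_distance_m``, one row per
  within-group unordered pair (cross-group pairs are out of radio range and
  simply absent).
* ``metadata.csv`` — ``id, role, group, row, col`` (grid cell empty for the
  imam).
* ``config.json`` — the generator configuration, when the session came from
  the simulator.

All files are UTF-8, comma-separated, with a header row and ``.`` decimals.
"""

from __future__ import annotations

import json
import logging
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataIntegrityError
from .series import TimeSeries
from .synthetic import ParticipantRecord, RitualConfig, SessionData

logger = logging.getLogger(__name__)


def write_session(session: SessionData, directory) -> list:
    """Write a session to ``directory``; returns the list of paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        for p in session.participants:
            df = pd.DataFrame(
                {
                    "time_s": np.arange(len(p.posture)) / p.posture.sample_hz,
                    "posture_deg": np.where(p.posture.missing_mask, np.nan, p.posture.values),
                    "hr_bpm": np.where(p.hr.missing_mask, np.nan, p.hr.values),
                }
            )
            path = directory / f"{p.id}.csv"
            df.to_csv(path, index=False)
            written.append(path)

        rows = []
        ids = session.ids
        for a, b in combinations(ids, 2):
            d = session.proximity.loc[a, b]
            if pd.notna(d):
                rows.append({"id_a": a, "id_b": b, "mean_distance_m": float(d)})
        prox_path = directory / "proximity.csv"
        pd.DataFrame(rows, columns=["id_a", "id_b", "mean_distance_m"]).to_csv(
            prox_path, index=False
        )
        written.append(prox_path)

        meta_path = directory / "metadata.csv"
        session.metadata.reset_index().to_csv(meta_path, index=False)
        written.append(meta_path)

        if session.config_used is not None:
            cfg_path = directory / "config.json"
            cfg_path.write_text(json.dumps(session.config_used.to_dict(), indent=1))
            written.append(cfg_path)
    except OSError as exc:
        raise OSError(f"failed writing session under {directory}: {exc}") from exc
    logger.info("wrote session (%d files) to %s", len(written), directory)
    return written


def _read_series_file(path: Path, sample_hz: float) -> tuple:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise DataIntegrityError(f"{path}: unreadable series file: {exc}") from exc
    for col in ("time_s", "posture_deg", "hr_bpm"):
        if col not in df.columns:
            raise DataIntegrityError(f"{path}: missing column {col!r}")
    bad = df.index[df["time_s"].isna()]
    if len(bad):
        raise DataIntegrityError(f"{path}: malformed time_s at data rows {list(bad + 2)}")
    df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
    return df["posture_deg"].to_numpy(float), df["hr_bpm"].to_numpy(float)


def read_session(directory, sample_hz: float = 1.0, trim: tuple | None = None) -> SessionData:
    """Load a session directory written by :func:`write_session`.

    Empty cells become masked samples. ``trim=(start_s, end_s)`` keeps only
    the samples inside the analysis window (e.g. the prayer interval) before
    anything downstream sees the data.
    """
    directory = Path(directory)
    meta_path = directory / "metadata.csv"
    if not meta_path.exists():
        raise DataIntegrityError(f"{meta_path} not found")
    meta = pd.read_csv(meta_path)
    if meta["id"].duplicated().any():
        dupes = meta.loc[meta["id"].duplicated(), "id"].tolist()
        raise DataIntegrityError(f"duplicate participant ids in metadata: {dupes}")

    participants = []
    lengths = set()
    for rec in meta.to_dict("records"):
        pid = str(rec["id"])
        post, hr = _read_series_file(directory / f"{pid}.csv", sample_hz)
        if trim is not None:
            lo = int(round(trim[0] * sample_hz))
            hi = int(round(trim[1] * sample_hz))
            post, hr = post[lo:hi], hr[lo:hi]
        lengths.add(post.size)
        grid = None
        if not (pd.isna(rec.get("row")) or pd.isna(rec.get("col"))):
            grid = (int(rec["row"]), int(rec["col"]))
        participants.append(
            ParticipantRecord(
                id=pid,
                role=str(rec["role"]),
                group=str(rec["group"]),
                grid_position=grid,
                posture=TimeSeries(post, sample_hz, label=f"{pid}:posture"),
                hr=TimeSeries(hr, sample_hz, label=f"{pid}:hr"),
            )
        )
    if len(lengths) > 1:
        raise DataIntegrityError(f"series length mismatch across participants: {sorted(lengths)}")

    ids = [p.id for p in participants]
    prox = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    np.fill_diagonal(prox.values, 0.0)
    prox_path = directory / "proximity.csv"
    if prox_path.exists():
        for i, row in pd.read_csv(prox_path).iterrows():
            a, b = str(row["id_a"]), str(row["id_b"])
            if a not in prox.index or b not in prox.index:
                raise DataIntegrityError(f"{prox_path} line {i + 2}: unknown id in pair ({a}, {b})")
            prox.loc[a, b] = prox.loc[b, a] = float(row["mean_distance_m"])

    config = None
    cfg_path = directory / "config.json"
    if cfg_path.exists():
        config = RitualConfig.from_dict(json.loads(cfg_path.read_text()))

    return SessionData(participants=participants, proximity=prox, config_used=config)
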