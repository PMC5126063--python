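"""EDF and table I/O.

EDF export uses a minimal in-package writer (EDF 16-bit, one-second data
records, microvolt physical dimension); reading goes through MNE's EDF
reader.  Montages travel as TSV (label, x, y, z, role).
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import EEGRecording


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write the recording as a 16-bit EDF file (one-second data records).

    A trailing partial second is truncated; the sampling rate must be an
    integer for the one-second record layout.
    """
    path = Path(path)
    fs = rec.sfreq
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))                       # samples per record per signal
    n_records = rec.n_samples // spr
    if n_records == 0:
        raise ValueError("recording shorter than one EDF record (1 s)")
    data = rec.data[:, : n_records * spr]
    n_sig = rec.n_channels

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-9
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    # widen slightly, then round through the 8-char ASCII header format and
    # scale against the *stored* values so reader and writer agree exactly
    span = pmax - pmin
    smin = [f"{v:.6g}"[:8] for v in pmin - 1e-3 * span]
    smax = [f"{v:.6g}"[:8] for v in pmax + 1e-3 * span]
    pmin = np.array([float(s) for s in smin])
    pmax = np.array([float(s) for s in smax])
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((data - pmin[:, None]) * scale[:, None] + dmin).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate X X X X", 80),
        _pad(now.strftime("%d.%m.%y"), 8),
        _pad(now.strftime("%H.%M.%S"), 8),
        _pad(str(256 * (1 + n_sig)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(n_sig), 4),
    ])
    fields = [
        [_pad(f"EEG {l}", 16) for l in rec.labels],
        [_pad("AgAgCl electrode", 80)] * n_sig,
        [_pad("uV", 8)] * n_sig,
        [_pad(s, 8) for s in smin],
        [_pad(s, 8) for s in smax],
        [_pad(str(dmin), 8)] * n_sig,
        [_pad(str(dmax), 8)] * n_sig,
        [_pad("", 80)] * n_sig,
        [_pad(str(spr), 8)] * n_sig,
        [_pad("", 32)] * n_sig,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for block in fields:
            fh.write(b"".join(block))
        for r in range(n_records):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())
    return path


def read_edf(
    path: str | Path,
    montage: pd.DataFrame,
    reference_label: str = "Cz",
) -> EEGRecording:
    """Read an EDF file back into an :class:`EEGRecording`.

    ``montage`` supplies positions and roles (columns label, x, y, z, role),
    since EDF itself carries neither.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = [ch.removeprefix("EEG ").strip() for ch in raw.ch_names]
    data = raw.get_data() * 1e6                # Volts -> microvolts
    m = montage.set_index("label").loc[labels]
    return EEGRecording(
        data=data,
        sfreq=float(raw.info["sfreq"]),
        labels=labels,
        positions=m[["x", "y", "z"]].to_numpy(float),
        roles=m["role"].tolist(),
        reference_label=reference_label,
    )


def montage_table(rec: EEGRecording) -> pd.DataFrame:
    return pd.DataFrame({
        "label": rec.labels,
        "x": rec.positions[:, 0],
        "y": rec.positions[:, 1],
        "z": rec.positions[:, 2],
        "role": rec.roles,
    })


def write_montage(rec: EEGRecording, path: str | Path) -> Path:
    path = Path(path)
    montage_table(rec).to_csv(path, sep="\t", index=False)
    return path


def read_montage(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
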