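"""Readers and writers for the segment store, labels, predictions and reports.

Canonical segment store: one directory holding a ``manifest.csv``
(segment_id, file, fs_hz, label) plus either one delimited-text file per
segment (one mV value per row, full precision) or a single ``segments.npy``
array container.  Write-then-read round-trips values exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .evaluate import EvalReport
from .segment import ECGSegment, QualityLabel

__all__ = [
    "write_segments",
    "read_segments",
    "write_labels",
    "read_labels",
    "write_predictions",
    "read_predictions",
    "write_report",
    "ParseError",
]

MANIFEST = "manifest.csv"
ARRAY_FILE = "segments.npy"


class ParseError(ValueError):
    """A file failed to parse; the message names the offending file/line."""


def write_segments(
    segments: Sequence[ECGSegment], out_dir, fmt: str = "txt"
) -> Path:
    """Write a segment store; *fmt* is ``txt`` (one file per segment) or ``npy``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    if fmt not in ("txt", "npy"):
        raise ValueError(f"fmt must be 'txt' or 'npy', got {fmt!r}")
    arrays = []
    for i, seg in enumerate(segments):
        sid = seg.segment_id or f"seg{i:05d}"
        fname = f"{sid}.txt" if fmt == "txt" else ARRAY_FILE
        rows.append(
            {
                "segment_id": sid,
                "file": fname,
                "fs_hz": seg.fs_hz,
                "label": seg.label.value if seg.label else "",
            }
        )
        if fmt == "txt":
            np.savetxt(out / fname, seg.values, fmt="%.17g")
        else:
            arrays.append(seg.values)
    if fmt == "npy":
        np.save(out / ARRAY_FILE, np.stack(arrays) if arrays else np.empty((0, 0)))
    pd.DataFrame(rows, columns=["segment_id", "file", "fs_hz", "label"]).to_csv(
        out / MANIFEST, index=False
    )
    return out


def read_segments(path, expected_length: Optional[int] = None) -> List[ECGSegment]:
    """Read a segment store directory (or a single per-segment text file)."""
    p = Path(path)
    if p.is_file():
        return [_read_one_txt(p, p.stem, fs_hz=250, label=None,
                              expected_length=expected_length)]
    manifest = p / MANIFEST
    if not manifest.exists():
        raise ParseError(f"{p}: no {MANIFEST} found")
    df = pd.read_csv(manifest, dtype={"segment_id": str, "file": str, "label": str},
                     keep_default_na=False)
    segments: List[ECGSegment] = []
    npy_cache = {}
    for pos, row in df.iterrows():
        label = QualityLabel.from_string(row["label"]) if row["label"] else None
        fs = int(row["fs_hz"])
        if row["file"].endswith(".npy"):
            fpath = p / row["file"]
            if fpath not in npy_cache:
                npy_cache[fpath] = np.load(fpath)
            values = npy_cache[fpath][pos]
            seg = ECGSegment(values=values, fs_hz=fs, label=label,
                             segment_id=row["segment_id"])
            _check_length(seg, expected_length, str(fpath))
            segments.append(seg)
        else:
            segments.append(
                _read_one_txt(p / row["file"], row["segment_id"], fs, label,
                              expected_length)
            )
    return segments


def _read_one_txt(fpath: Path, sid: str, fs_hz: int,
                  label: Optional[QualityLabel],
                  expected_length: Optional[int]) -> ECGSegment:
    values = []
    with open(fpath) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            try:
                values.append(float(s))
            except ValueError:
                raise ParseError(
                    f"{fpath}:{lineno}: non-numeric value {s!r}"
                ) from None
    seg = ECGSegment(values=np.array(values), fs_hz=fs_hz, label=label, segment_id=sid)
    _check_length(seg, expected_length, str(fpath))
    return seg


def _check_length(seg: ECGSegment, expected: Optional[int], where: str) -> None:
    if expected is not None and seg.n_samples != expected:
        raise ParseError(
            f"{where}: segment {seg.segment_id} has {seg.n_samples} samples, "
            f"expected {expected}"
        )


# ---------------------------------------------------------------------------
# labels, predictions, reports


def write_labels(path, ids: Sequence[str], labels: Sequence) -> None:
    lab = [lbl.value if isinstance(lbl, QualityLabel) else str(lbl) for lbl in labels]
    pd.DataFrame({"segment_id": ids, "label": lab}).to_csv(path, index=False)


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"segment_id": str, "label": str})
    if not {"segment_id", "label"} <= set(df.columns):
        raise ParseError(f"{path}: labels file needs segment_id and label columns")
    for pos, value in df["label"].items():
        QualityLabel.from_string(value)  # raises on unknown class strings
    return df


def write_predictions(path, ids: Sequence[str], labels: Sequence[str],
                      proba: np.ndarray) -> None:
    pd.DataFrame(
        {
            "segment_id": ids,
            "predicted_label": labels,
            "p_acceptable": proba[:, 0],
            "p_unacceptable": proba[:, 1],
            "p_uncertain": proba[:, 2],
        }
    ).to_csv(path, index=False)


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"segment_id": str, "predicted_label": str})


def write_report(path, report: EvalReport) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
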