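"""File formats: 16-bit PNG pulse images, CSV sequences and heartbeat
traces, JSON model serialisation.

Round-trip guarantees: sequences are exact; images reproduce to the 16-bit
quantisation step (1/65535); model probability tables survive JSON to full
float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .classification import TemplateClassifier
from .errors import ParseError
from .predictor import Posture, PostureSequence, TransitionModel

__all__ = [
    "read_image", "write_image",
    "read_sequence_csv", "write_sequence_csv",
    "read_heartbeat_csv", "write_heartbeat_csv", "pivot_heartbeat",
    "model_to_json", "model_from_json",
    "classifier_to_json", "classifier_from_json",
]

_TEXT_SUFFIXES = {".txt", ".csv", ".tsv", ".dat"}


def read_image(path: str | Path) -> np.ndarray:
    """Read a pulse image from 16-bit PNG or delimited numeric text.

    PNG intensities are scaled to [0, 1] on read (by the dtype's full
    range); text files hold one row per line, comma or whitespace
    separated, and are returned as-is.
    """
    path = Path(path)
    if path.suffix.lower() in _TEXT_SUFFIXES:
        delimiter = "," if "," in path.read_text().splitlines()[0] else None
        arr = np.loadtxt(path, delimiter=delimiter, ndmin=2)
        return arr.astype(float)
    arr = iio.imread(path)
    if arr.ndim == 3:                       # collapse any colour channels
        arr = arr.mean(axis=2)
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    return arr.astype(float)


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a [0, 1] image as 16-bit grayscale PNG."""
    img = np.asarray(img, dtype=float)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image values must lie in [0, 1] for 16-bit export")
    iio.imwrite(Path(path), np.round(img * 65535.0).astype(np.uint16))


def read_sequence_csv(path: str | Path, epoch_seconds: float = 30.0) -> PostureSequence:
    """Read an ``epoch,label`` CSV into a posture sequence."""
    df = pd.read_csv(path)
    required = {"epoch", "label"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    labels = []
    for i, token in enumerate(df["label"]):
        try:
            labels.append(Posture(str(token).strip().upper()))
        except ValueError:
            raise ParseError(f"{path}: unknown posture label {token!r} "
                             f"on line {i + 2}") from None
    order = np.argsort(df["epoch"].to_numpy())
    return PostureSequence(labels=[labels[i] for i in order],
                           epoch_seconds=epoch_seconds)


def write_sequence_csv(path: str | Path, seq: PostureSequence) -> None:
    pd.DataFrame({"epoch": range(len(seq)),
                  "label": [l.value for l in seq.labels]}).to_csv(path, index=False)


def write_heartbeat_csv(path: str | Path, bpm: np.ndarray,
                        epoch_seconds: float = 30.0,
                        sites: list[str] | None = None) -> None:
    """Write a (rows, samples) bpm matrix as a ``time_s,bpm,site`` CSV.

    Each row becomes one site's trace; samples are spaced evenly over the
    epoch duration.
    """
    bpm = np.atleast_2d(np.asarray(bpm, dtype=float))
    n_rows, n_samp = bpm.shape
    sites = sites or [f"site{r}" for r in range(n_rows)]
    dt = epoch_seconds / n_samp
    rows = [{"time_s": s * dt, "bpm": bpm[r, s], "site": sites[r]}
            for r in range(n_rows) for s in range(n_samp)]
    pd.DataFrame(rows, columns=["time_s", "bpm", "site"]).to_csv(path, index=False)


def read_heartbeat_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"time_s", "bpm", "site"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    return df


def pivot_heartbeat(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Pivot a long heartbeat table to a (site x time) signal matrix."""
    wide = df.pivot_table(index="site", columns="time_s", values="bpm")
    wide = wide.sort_index()
    return wide.to_numpy(), list(wide.index)


def model_to_json(model: TransitionModel) -> str:
    return json.dumps({
        "order": model.order,
        "alpha": model.alpha,
        "labels": [l.value for l in model.labels],
        "mask": model.mask.astype(int).tolist(),
        "probs": model.probs.tolist(),
    }, indent=2)


def model_from_json(text: str) -> TransitionModel:
    d = json.loads(text)
    return TransitionModel(
        order=int(d["order"]),
        labels=tuple(Posture(l) for l in d["labels"]),
        probs=np.asarray(d["probs"], dtype=float),
        mask=np.asarray(d["mask"], dtype=bool),
        alpha=float(d["alpha"]),
    )


def classifier_to_json(clf: TemplateClassifier) -> str:
    return json.dumps({
        "labels": [l.value for l in clf.labels],
        "centroids": clf.centroids.tolist(),
        "temperature": clf.temperature,
    }, indent=2)


def classifier_from_json(text: str) -> TemplateClassifier:
    d = json.loads(text)
    return TemplateClassifier(
        labels=tuple(Posture(l) for l in d["labels"]),
        centroids=np.asarray(d["centroids"], dtype=float),
        temperature=float(d["temperature"]),
    )
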