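"""Serialization: discrete models as JSON, traces as CSV, images as PNG/PGM.

Matrices are stored dense, row-major, with explicit shape headers; the state
indexing convention (velocity as the fast axis for grid models) is recorded
in the header so files are self-describing.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image as PILImage

from actinf.discrete import DiscreteModel, EpisodeTrace
from actinf.saccade import Image


def model_to_json(model: DiscreteModel, path: str | Path) -> None:
    """Write a :class:`DiscreteModel` as a documented JSON file."""
    payload = {
        "format": "actinf-discrete-model",
        "version": 1,
        "indexing": "row-major, velocity fastest for grid models",
        "shapes": {
            "A": list(model.A.shape),
            "B": [list(Bk.shape) for Bk in model.B],
            "c": [len(model.c)],
            "d": [len(model.d)],
        },
        "T": model.T,
        "A": model.A.ravel().tolist(),
        "B": [Bk.ravel().tolist() for Bk in model.B],
        "c": model.c.tolist(),
        "d": model.d.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def model_from_json(path: str | Path) -> DiscreteModel:
    data = json.loads(Path(path).read_text())
    if data.get("format") != "actinf-discrete-model":
        raise ValueError("not an actinf discrete-model file")
    shapes = data["shapes"]
    A = np.array(data["A"]).reshape(shapes["A"])
    B = [np.array(b).reshape(s) for b, s in zip(data["B"], shapes["B"])]
    return DiscreteModel(A=A, B=B, c=np.array(data["c"]), d=np.array(data["d"]), T=data["T"])


def episode_to_csv(
    trace: EpisodeTrace,
    path: str | Path,
    coords: np.ndarray | None = None,
) -> pd.DataFrame:
    """Export an episode as CSV with one row per time point.

    ``coords`` (n_states, 2) maps state indices to (position, velocity); when
    omitted those columns are NaN.  The action/free-energy columns are NaN on
    the final row (no action is taken at the horizon).
    """
    n = len(trace.states)
    rows = []
    for t in range(n):
        s = trace.states[t]
        pos, vel = (coords[s] if coords is not None else (np.nan, np.nan))
        rows.append(
            {
                "time": t,
                "state_index": s,
                "position": pos,
                "velocity": vel,
                "observation": trace.observations[t],
                "action": trace.actions[t] if t < len(trace.actions) else np.nan,
                "free_energy": trace.free_energy[t]
                if t < len(trace.free_energy)
                else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def beliefs_to_csv(trace: EpisodeTrace, directory: str | Path) -> None:
    """Write each recorded belief snapshot as a CSV matrix (times x states)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, b in enumerate(trace.beliefs_history):
        np.savetxt(directory / f"alpha_step{k:02d}.csv", b.alpha, delimiter=",")
        np.savetxt(directory / f"beta_step{k:02d}.csv", b.beta, delimiter=",")


def write_image(img: Image | np.ndarray, path: str | Path) -> None:
    """Write a grayscale image (values scaled to [0, 255]) as PNG or PGM."""
    arr = img.values if isinstance(img, Image) else np.asarray(img, float)
    lo, hi = float(arr.min()), float(arr.max())
    scaled = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    PILImage.fromarray((scaled * 255).astype(np.uint8)).save(str(path))


def read_image(path: str | Path) -> Image:
    """Read a PNG/PGM grayscale image into [0, 1]."""
    arr = np.asarray(PILImage.open(str(path)).convert("L"), dtype=float) / 255.0
    return Image(arr)


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir: str | Path, extra: dict | None = None) -> Path:
    """Record every artifact in ``out_dir`` with its SHA-256 hash."""
    out_dir = Path(out_dir)
    files = sorted(p for p in out_dir.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "artifacts": {str(p.relative_to(out_dir)): file_sha256(p) for p in files},
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
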