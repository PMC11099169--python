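"""File formats: multi-page TIFF movies, HDF5 ground truth / traces, CSV tables."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile


def write_movie(path, movie: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(movie, dtype=np.float32))


def read_movie(path) -> np.ndarray:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    if np.any(data < 0):
        raise ValueError("movie contains negative intensities")
    return data


def write_masks(path, masks: np.ndarray) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("masks", data=np.asarray(masks, dtype=np.float32), compression="gzip")


def read_masks(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["masks"][...]


def write_ground_truth(path, gt) -> None:
    """Ground truth as HDF5 datasets (masks, traces, motion, z, offsets)."""
    with h5py.File(path, "w") as f:
        for name, arr in (
            ("masks", gt.masks),
            ("traces", gt.true_traces),
            ("motion", gt.motion_true),
            ("z", gt.z_true),
            ("odor_labels", gt.odor_labels),
        ):
            if arr is not None:
                f.create_dataset(name, data=np.asarray(arr))


def write_traces(path, traces: np.ndarray, f0: np.ndarray | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=np.asarray(traces))
        if f0 is not None:
            f.create_dataset("f0", data=np.asarray(f0))


def read_traces(path) -> tuple[np.ndarray, np.ndarray | None]:
    with h5py.File(path, "r") as f:
        traces = f["traces"][...]
        f0 = f["f0"][...] if "f0" in f else None
    return traces, f0


def traces_to_tidy_csv(path, F: np.ndarray, F0: np.ndarray, dff: np.ndarray) -> None:
    n_cells, n_frames = F.shape
    cell, frame = np.meshgrid(np.arange(n_cells), np.arange(n_frames), indexing="ij")
    pd.DataFrame(
        {
            "cell_id": cell.ravel(),
            "frame": frame.ravel(),
            "F": F.ravel(),
            "F0": F0.ravel(),
            "dff": dff.ravel(),
        }
    ).to_csv(path, index=False)


def write_motion_summary(path, per_frame: np.ndarray, z_um: np.ndarray | None = None) -> None:
    """Summary CSV with columns frame, dx_px, dy_px[, z_um]."""
    per_frame = np.asarray(per_frame)
    df = pd.DataFrame(
        {
            "frame": np.arange(per_frame.shape[0]),
            "dx_px": per_frame[:, 1],
            "dy_px": per_frame[:, 0],
        }
    )
    if z_um is not None:
        df["z_um"] = z_um
    df.to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"trial_id", "t_start_s", "odor_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
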