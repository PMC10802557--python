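import numpy as np
import pandas as pd
import pytest

from baitswitch.data_model import ArenaSpec, MouseInfo, Recording


def poses_from_positions(positions, theta=None, a=3.0, b=1.5, nose_frac=0.8):
    """Build a dense pose table from per-mouse center trajectories.

    ``positions`` maps mouse_id -> (n_frames, 2) arrays.  Headings default
    to the velocity direction (held through stationary frames); ``theta``
    may override per-mouse heading arrays.
    """
    rows = []
    for mouse, xy in positions.items():
        xy = np.asarray(xy, dtype=float)
        n = len(xy)
        if theta and mouse in theta:
            ang = np.asarray(theta[mouse], dtype=float)
        else:
            v = np.diff(xy, axis=0, prepend=xy[:1])
            norm = np.hypot(v[:, 0], v[:, 1])
            ang = np.where(norm > 1e-9, np.arctan2(v[:, 1], v[:, 0]), np.nan)
            ang = pd.Series(ang).ffill().fillna(0.0).to_numpy()
        rows.append(pd.DataFrame({
            "frame": np.arange(n),
            "mouse_id": mouse,
            "x_cm": xy[:, 0],
            "y_cm": xy[:, 1],
            "theta_rad": np.angle(np.exp(1j * ang)),
            "a_cm": a,
            "b_cm": b,
            "nose_x_cm": xy[:, 0] + nose_frac * a * np.cos(ang),
            "nose_y_cm": xy[:, 1] + nose_frac * a * np.sin(ang),
        }))
    df = pd.concat(rows, ignore_index=True)
    return df.sort_values(["frame", "mouse_id"]).reset_index(drop=True)


def make_recording(positions, events=(), theta=None, fps=30.0, side=76.2, mice=None):
    if mice is None:
        mice = [
            MouseInfo(m, "F" if m.startswith("F") else "M") for m in sorted(positions)
        ]
    arena = ArenaSpec(shape="rectangle", width_cm=side, height_cm=side, fps=fps)
    return Recording(
        arena=arena,
        mice=mice,
        poses=poses_from_positions(positions, theta=theta),
        events=list(events),
    )


@pytest.fixture(scope="session")
def default_recording():
    """One default-parameter synthetic recording, shared across tests."""
    from baitswitch.synthetic import GeneratorParams, generate_recording

    rec, truth = generate_recording(GeneratorParams(seed=1))
    return rec, truth


@pytest.fixture(scope="session")
def default_interactions(default_recording):
    from baitswitch.interactions import detect_interactions

    rec, _ = default_recording
    return detect_interactions(rec, "opposite_sex")
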