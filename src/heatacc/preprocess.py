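"""Count centering, orientation harmonisation, and the yz-plane magnitude.

Raw 12-bit counts span 0–4095 with 2048 corresponding to zero acceleration,
so centering subtracts 2048.  Collars can be mounted with the x (surge) and
y (sway) axes reversed between deployments; the orientation decision
compares per-axis means between the labelled training deployment and each
inference individual and flips x and/or y when the signs disagree.  Collar
rotation about the neck axis mixes y and z, so downstream features use the
per-sample yz magnitude ``ayz = sqrt(y^2 + z^2)``, which is invariant to
that rotation.

All downstream features operate on centered counts; :func:`counts_to_g`
(8 G per 4096 counts) is provided for reporting in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import AccBurst

CENTER_OFFSET = 2048
G_PER_COUNT = 8.0 / 4096.0  # full scale −4..+4 G over 4096 counts

#: Minimum |mean| (centered counts, ~0.2 G) for an orientation flip decision.
DEFAULT_ORIENTATION_FLOOR = 100.0


@dataclass(frozen=True)
class CenteredBurst:
    """A burst after centering, with the per-sample yz-plane magnitude."""

    individual_id: str
    timestamp: pd.Timestamp
    fs: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def ayz(self) -> np.ndarray:
        """Rotation-invariant yz-plane magnitude, per sample."""
        return np.sqrt(self.y.astype(float) ** 2 + self.z.astype(float) ** 2)


def center(burst: AccBurst) -> CenteredBurst:
    """Shift each axis by −2048 counts (exact integer arithmetic)."""
    return CenteredBurst(
        individual_id=burst.individual_id,
        timestamp=burst.timestamp,
        fs=burst.fs,
        x=burst.x_raw - CENTER_OFFSET,
        y=burst.y_raw - CENTER_OFFSET,
        z=burst.z_raw - CENTER_OFFSET,
    )


def counts_to_g(centered):
    """Map centered counts to acceleration in G (linear, 8 G / 4096 counts)."""
    return np.asarray(centered, dtype=float) * G_PER_COUNT


@dataclass(frozen=True)
class OrientationDecision:
    """Whether to reverse the x and/or y axis for one inference individual.

    Flips apply only to surge (x) and sway (y); the heave (z) axis keeps
    its sign.  The four means that drove the decision are retained for
    audit.
    """

    individual_id: str
    flip_x: bool
    flip_y: bool
    train_mean_x: float
    train_mean_y: float
    infer_mean_x: float
    infer_mean_y: float


def _pooled_mean(bursts, axis: str) -> float:
    total = 0.0
    count = 0
    for b in bursts:
        arr = getattr(b, axis)
        total += float(arr.sum())
        count += arr.size
    if count == 0:
        raise ValueError("cannot decide orientation from an empty burst set")
    return total / count


def decide_orientation(
    train_bursts,
    infer_bursts,
    individual_id: str,
    floor: float = DEFAULT_ORIENTATION_FLOOR,
) -> OrientationDecision:
    """Compare per-axis means between training and inference deployments.

    An axis is flipped iff the means disagree in sign *and* both exceed
    ``floor`` in magnitude — near-zero means carry no orientation signal
    and must not trigger spurious flips.  Decided once per individual over
    its whole inference dataset.
    """
    train_bursts, infer_bursts = list(train_bursts), list(infer_bursts)
    if not train_bursts or not infer_bursts:
        raise ValueError("both burst sets must be non-empty")
    tx, ty = _pooled_mean(train_bursts, "x"), _pooled_mean(train_bursts, "y")
    ix, iy = _pooled_mean(infer_bursts, "x"), _pooled_mean(infer_bursts, "y")

    def _flip(t: float, i: float) -> bool:
        return (np.sign(t) != np.sign(i)) and abs(t) > floor and abs(i) > floor

    return OrientationDecision(
        individual_id=individual_id,
        flip_x=_flip(tx, ix),
        flip_y=_flip(ty, iy),
        train_mean_x=tx,
        train_mean_y=ty,
        infer_mean_x=ix,
        infer_mean_y=iy,
    )


def apply_orientation(decision: OrientationDecision, burst: CenteredBurst) -> CenteredBurst:
    """Negate the flipped axes elementwise (an involution)."""
    return replace(
        burst,
        x=-burst.x if decision.flip_x else burst.x,
        y=-burst.y if decision.flip_y else burst.y,
    )


def write_orientation_decisions(decisions, path) -> None:
    """Serialize orientation decisions to a small delimited-text audit file."""
    pd.DataFrame(
        [
            {
                "individual_id": d.individual_id,
                "flip_x": d.flip_x,
                "flip_y": d.flip_y,
                "train_mean_x": d.train_mean_x,
                "train_mean_y": d.train_mean_y,
                "infer_mean_x": d.infer_mean_x,
                "infer_mean_y": d.infer_mean_y,
            }
            for d in decisions
        ]
    ).to_csv(path, index=False)
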