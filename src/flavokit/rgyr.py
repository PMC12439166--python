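"""Radius-of-gyration trajectory metrics and variance-heterogeneity testing.

The radius of gyration (RGYR) is the mass-weighted root-mean-square distance
of a set of atoms from their centre of mass — a scalar compactness measure.
Self-assembly of solute molecules into a compact aggregate lowers the
ensemble RGYR, so the time series and its late-window variance carry the
signal of interest.  Variance heterogeneity between conditions (e.g. solvent
control vs. solute-laden simulations) is assessed with Levene's test, with
the Brown–Forsythe median-centred variant available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FlavokitError, InsufficientDataError

GROUPS = ("protein", "flavonoid_core", "glycoside", "other")


@dataclass
class Trajectory:
    """Frames of tagged point masses.

    coordinates : (n_frames, n_atoms, 3) array, nm
    masses      : (n_atoms,) array, amu, strictly positive
    frame_times : (n_frames,) array, ns, strictly increasing
    atom_tags   : DataFrame with columns ``molecule_id`` and ``group``
                  (group in {protein, flavonoid_core, glycoside, other})
    """

    coordinates: np.ndarray
    masses: np.ndarray
    frame_times: np.ndarray
    atom_tags: pd.DataFrame

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.masses.shape != (self.coordinates.shape[1],):
            raise ValueError("masses must have one entry per atom")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.frame_times.shape != (self.coordinates.shape[0],):
            raise ValueError("frame_times must have one entry per frame")
        if self.frame_times.size > 1 and np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if len(self.atom_tags) != self.coordinates.shape[1]:
            raise ValueError("atom_tags must have one row per atom")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class RgyrSeries:
    """A per-frame RGYR time series (nm) for a given atom selection."""

    times: np.ndarray
    values: np.ndarray
    selection: str = "all"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must be the same length")
        if np.any(self.values < -1e-12):
            raise ValueError("RGYR values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "rgyr_nm": self.values})


@dataclass
class VarianceComparison:
    group_labels: tuple
    levene_W: float
    p_value: float
    center: str
    n_per_group: tuple

    def to_dict(self) -> dict:
        return {
            "group_labels": list(self.group_labels),
            "levene_W": self.levene_W,
            "p_value": self.p_value,
            "center": self.center,
            "n_per_group": list(self.n_per_group),
        }


def _resolve_selection(traj: Trajectory, selection) -> tuple[np.ndarray, str]:
    if selection is None:
        return np.arange(traj.n_atoms), "all"
    if isinstance(selection, str):
        mask = (traj.atom_tags["group"] == selection).to_numpy()
        return np.flatnonzero(mask), selection
    if callable(selection):
        mask = np.asarray([bool(selection(row)) for _, row in traj.atom_tags.iterrows()])
        return np.flatnonzero(mask), "callable"
    arr = np.asarray(selection)
    if arr.dtype == bool:
        return np.flatnonzero(arr), "mask"
    return arr.astype(int), "indices"


def radius_of_gyration(
    traj: Trajectory,
    selection=None,
    mass_weighted: bool = True,
) -> RgyrSeries:
    """Per-frame radius of gyration over an atom selection.

    RGYR(t) = sqrt( sum_k m_k |r_k(t) - rbar(t)|^2 / sum_k m_k ) with
    rbar the (mass-weighted) centroid; the unweighted variant sets m_k = 1.

    ``selection`` is ``None`` (all atoms), a group name from the atom tags,
    a boolean mask, or an integer index array.  Empty selections are an error.
    """
    idx, label = _resolve_selection(traj, selection)
    if idx.size == 0:
        raise FlavokitError(f"selection {label!r} matches no atoms")
    coords = traj.coordinates[:, idx, :]
    m = traj.masses[idx] if mass_weighted else np.ones(idx.size)
    w = m / m.sum()
    com = np.einsum("k,fkd->fd", w, coords)
    delta = coords - com[:, None, :]
    rg2 = np.einsum("k,fk->f", w, np.einsum("fkd,fkd->fk", delta, delta))
    # tiny negative values from cancellation are clipped before the sqrt
    values = np.sqrt(np.clip(rg2, 0.0, None))
    return RgyrSeries(times=traj.frame_times.copy(), values=values, selection=label)


def pool_replicates(samples: Sequence[np.ndarray]) -> np.ndarray:
    """Concatenate duplicate-run RGYR samples of one condition into one pool."""
    return np.concatenate([np.asarray(s, dtype=float).ravel() for s in samples])


def variance_comparison(
    groups: dict[str, np.ndarray] | Sequence[np.ndarray],
    center: str = "mean",
) -> VarianceComparison:
    """Levene (center='mean') or Brown–Forsythe (center='median') test.

    Each group must hold at least two pooled RGYR values.  The statistic W
    follows an F(k-1, N-k) distribution under variance homogeneity.
    """
    if isinstance(groups, dict):
        labels = tuple(groups.keys())
        arrays = [np.asarray(groups[k], dtype=float).ravel() for k in labels]
    else:
        arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
        labels = tuple(f"group{i}" for i in range(len(arrays)))
    if len(arrays) < 2:
        raise InsufficientDataError("need at least two groups")
    for lab, arr in zip(labels, arrays):
        if arr.size < 2:
            raise InsufficientDataError(f"group {lab!r} has fewer than 2 values")
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    W, p = stats.levene(*arrays, center=center)
    return VarianceComparison(
        group_labels=labels,
        levene_W=float(W),
        p_value=float(p),
        center=center,
        n_per_group=tuple(a.size for a in arrays),
    )


def distribution_summary(series: RgyrSeries, window: tuple[float, float]) -> dict:
    """Quartiles, extrema and count of RGYR values inside a time window.

    Bounds are inclusive on both ends; times in ns.  Mirrors the quartile
    annotations of violin-plot summaries over a late equilibrated window.
    """
    t0, t1 = window
    mask = (series.times >= t0) & (series.times <= t1)
    if not mask.any():
        raise FlavokitError(f"window [{t0}, {t1}] ns contains no frames")
    v = series.values[mask]
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "min": float(v.min()),
        "max": float(v.max()),
        "n": int(v.size),
    }
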