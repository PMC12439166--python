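"""Weighted-ensemble engine with a variation-maximising (REVO-style) resampler.

The weighted-ensemble (WE) scheme runs ``n_walkers`` trajectories in
parallel, each carrying a statistical weight; every cycle the walkers are
propagated for ``steps_per_cycle`` dynamics steps and then resampled by
cloning and merging so that total probability weight is conserved exactly.
The resampler maximises the ensemble "variation"

    V = sum_ij (d_ij / d0)^alpha

over a pluggable pairwise distance ``d`` (here, by default, the absolute
difference of radii of gyration — compact and extended configurations are
kept apart).  Each greedy iteration proposes cloning the walker with the
largest marginal contribution to V while merging the closest eligible pair
(pair distance <= merge_dist, combined weight <= pmax; clone half-weights
must stay >= pmin), keeping the walker count constant; proposals are
accepted while V strictly increases.  Merge survivors are drawn
weight-proportionally; clone ties break to the lowest walker index, so runs
are fully reproducible from the seed.

Pooling the per-cycle walker values and weights gives a normalised
probability distribution p over a progress coordinate; F = -ln(p) is a
free-energy-like profile in kT units up to an additive constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import FlavokitError, IntegrityError, SpecValidationError


@dataclass
class Walker:
    state: object
    weight: float

    def __post_init__(self) -> None:
        if not (self.weight > 0):
            raise SpecValidationError("weight", "must be > 0")


@dataclass
class REVOParams:
    """Resampler and run parameters (defaults follow the study's WE setup)."""

    n_walkers: int = 50
    merge_dist: float = 0.25
    char_dist: float = 0.1
    dist_exp: float = 4.0
    pmax: float = 0.5
    pmin: float = 1e-12
    steps_per_cycle: int = 100
    n_cycles: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.pmin < self.pmax <= 1):
            raise SpecValidationError("pmin", "need 0 < pmin < pmax <= 1")
        if self.dist_exp <= 0:
            raise SpecValidationError("dist_exp", "must be > 0")
        if self.char_dist <= 0:
            raise SpecValidationError("char_dist", "must be > 0")
        if self.merge_dist <= 0:
            raise SpecValidationError("merge_dist", "must be > 0")
        if self.n_walkers < 2:
            raise SpecValidationError("n_walkers", "must be >= 2")
        if self.n_cycles < 0 or self.steps_per_cycle < 0:
            raise SpecValidationError("n_cycles", "must be >= 0")


@dataclass
class ResamplingRecord:
    """Clone/merge bookkeeping for one cycle.

    ``parent_idx[k]`` is the pre-resampling slot whose state walker ``k``
    carries afterwards (identity when nothing happened to slot k).
    """

    cycle: int
    parent_idx: np.ndarray
    clones: dict  # parent slot -> [child slots]
    merges: list  # (absorbed slot, survivor slot)

    @property
    def empty(self) -> bool:
        return not self.clones and not self.merges


def scalar_distance(a, b) -> float:
    return abs(float(a) - float(b))


def rgyr_of_state(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration of one configuration (n_atoms, 3)."""
    coords = np.asarray(coords, dtype=float)
    m = np.ones(len(coords)) if masses is None else np.asarray(masses, dtype=float)
    w = m / m.sum()
    com = w @ coords
    return float(np.sqrt(w @ np.sum((coords - com) ** 2, axis=1)))


def make_rgyr_distance(masses: np.ndarray | None = None) -> Callable:
    """Distance |RGYR(a) - RGYR(b)| between coordinate states; scalar states
    fall back to plain absolute difference."""

    def dist(a, b) -> float:
        ra = float(a) if np.ndim(a) == 0 else rgyr_of_state(a, masses)
        rb = float(b) if np.ndim(b) == 0 else rgyr_of_state(b, masses)
        return abs(ra - rb)

    return dist


def _distance_matrix(states: Sequence, distance_fn: Callable) -> np.ndarray:
    arr = np.asarray(states, dtype=object)
    if distance_fn is scalar_distance:
        x = np.asarray(states, dtype=float)
        return np.abs(x[:, None] - x[None, :])
    n = len(states)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = float(distance_fn(states[i], states[j]))
    return D


def resample_revo(
    states: list,
    weights: np.ndarray,
    params: REVOParams,
    rng: np.random.Generator,
    distance_fn: Callable = scalar_distance,
    cycle: int = 0,
) -> tuple[list, np.ndarray, ResamplingRecord]:
    """One greedy variation-maximising resampling pass.

    Returns new states/weights of the same length and the record.  Total
    weight is conserved exactly (the merged weight is the float sum of the
    pair); after resampling all weights lie in [pmin, pmax] provided they
    did on entry.
    """
    n = len(states)
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise FlavokitError(f"walker weights must sum to 1, got {weights.sum()!r}")
    if n < 2:
        raise FlavokitError("need at least 2 walkers")

    states = list(states)
    weights = weights.copy()
    D = _distance_matrix(states, distance_fn)
    M = (D / params.char_dist) ** params.dist_exp
    np.fill_diagonal(M, 0.0)
    clones: dict[int, list[int]] = {}
    merges: list[tuple[int, int]] = []
    parent = np.arange(n)  # post-slot -> cycle-entry slot

    for _ in range(10 * n):  # safety bound; V strictly increases each pass
        row = M.sum(axis=1)
        # closest eligible merge pair (tie: lowest indices via argmin order)
        eligible = (D <= params.merge_dist) & (
            weights[:, None] + weights[None, :] <= params.pmax
        )
        eligible &= np.triu(np.ones((n, n), dtype=bool), k=1)
        if not eligible.any():
            break
        D_ok = np.where(eligible, D, np.inf)
        i_m, j_m = map(int, np.unravel_index(np.argmin(D_ok), D_ok.shape))
        # clone candidate: largest marginal contribution to V, half-weight
        # must stay above pmin; cannot be a member of the merge pair
        cand = [
            k
            for k in range(n)
            if k not in (i_m, j_m) and weights[k] / 2.0 >= params.pmin
        ]
        if not cand:
            break
        c = max(cand, key=lambda k: (row[k], -k))
        # the freed slot adopts a copy of walker c, so V changes only through
        # replacing the absorbed slot's state with c's state (the survivor
        # keeps its own state); pick the better of the two absorbed choices
        best = None
        for absorbed, survivor in ((i_m, j_m), (j_m, i_m)):
            dV = -2.0 * M[absorbed].sum() + 2.0 * (M[c].sum() - M[c, absorbed])
            if best is None or dV > best[0]:
                best = (dV, absorbed, survivor)
        dV, absorbed, survivor = best
        if dV <= 1e-12:
            break

        # survivor state of the merge drawn proportionally to weight
        pick = int(
            rng.choice(
                [absorbed, survivor],
                p=np.array([weights[absorbed], weights[survivor]])
                / (weights[absorbed] + weights[survivor]),
            )
        )
        ancestor_survivor = int(parent[pick])
        ancestor_clone = int(parent[c])
        states[survivor] = states[pick]
        weights[survivor] = weights[absorbed] + weights[survivor]
        merges.append((absorbed, survivor))
        # clone c into slots c and the freed absorbed slot
        half = weights[c] / 2.0
        weights[c] = half
        weights[absorbed] = half
        states[absorbed] = states[c]
        clones.setdefault(c, [c]).append(absorbed)
        parent[survivor] = ancestor_survivor
        parent[absorbed] = ancestor_clone

        # refresh distances for the slots whose state changed
        for k in {absorbed, survivor}:
            for j in range(n):
                d = 0.0 if j == k else float(distance_fn(states[k], states[j]))
                D[k, j] = D[j, k] = d
                M[k, j] = M[j, k] = (d / params.char_dist) ** params.dist_exp

    record = ResamplingRecord(cycle=cycle, parent_idx=parent, clones=clones, merges=merges)
    return states, weights, record


@dataclass
class WEResult:
    """Per-cycle snapshots of a weighted-ensemble run.

    ``values``/``weights`` have shape (n_cycles + 1, n_walkers); row 0 is
    the initial ensemble, row c+1 the post-resampling ensemble of cycle c.
    """

    values: np.ndarray
    weights: np.ndarray
    records: list
    params: REVOParams
    seed: int
    final_states: list

    @property
    def n_cycles(self) -> int:
        return self.values.shape[0] - 1

    def aggregate_time(self, per_walker_time: float) -> dict:
        """Total simulated time two ways: summed over walkers vs per walker."""
        return {
            "per_walker": per_walker_time * self.n_cycles,
            "aggregate": per_walker_time * self.n_cycles * self.values.shape[1],
        }


def run_weighted_ensemble(
    propagator: Callable,
    init_states,
    params: REVOParams,
    seed: int = 0,
    distance_fn: Callable = scalar_distance,
    value_fn: Callable | None = None,
) -> WEResult:
    """Run n_cycles of (propagate, resample) from equally weighted walkers.

    ``propagator(states_array, n_steps, rng) -> states_array`` supplies the
    dynamics; ``value_fn`` maps a state to the scalar progress coordinate
    recorded in the snapshots (identity for scalar states).  Fully
    reproducible from the seed.
    """
    rng = np.random.default_rng(seed)
    states = list(np.atleast_1d(np.asarray(init_states, dtype=float)))
    if len(states) != params.n_walkers:
        raise SpecValidationError(
            "n_walkers", f"got {len(states)} initial states for {params.n_walkers} walkers"
        )
    weights = np.full(params.n_walkers, 1.0 / params.n_walkers)
    if value_fn is None:
        value_fn = float

    values = np.empty((params.n_cycles + 1, params.n_walkers))
    whist = np.empty_like(values)
    values[0] = [value_fn(s) for s in states]
    whist[0] = weights
    records: list[ResamplingRecord] = []

    for cycle in range(params.n_cycles):
        arr = propagator(np.asarray(states, dtype=float), params.steps_per_cycle, rng)
        states = list(np.atleast_1d(arr))
        states, weights, rec = resample_revo(
            states, weights, params, rng, distance_fn, cycle=cycle
        )
        records.append(rec)
        values[cycle + 1] = [value_fn(s) for s in states]
        whist[cycle + 1] = weights

    return WEResult(
        values=values,
        weights=whist,
        records=records,
        params=params,
        seed=seed,
        final_states=states,
    )


@dataclass
class FreeEnergyProfile:
    bin_edges: np.ndarray
    p: np.ndarray  # per bin, zeros for unoccupied
    f: np.ndarray  # -ln p, NaN for unoccupied bins

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def occupied(self) -> np.ndarray:
        return self.p > 0


def free_energy_profile(
    values: np.ndarray,
    weights: np.ndarray,
    bins: int | np.ndarray = 50,
    burn_in_frac: float = 0.2,
    bin_range: tuple[float, float] | None = None,
) -> FreeEnergyProfile:
    """-ln of the normalised weighted distribution of a progress coordinate.

    ``values``/``weights`` are (n_snapshots, n_walkers) arrays (or flat);
    the first ``burn_in_frac`` of snapshots is discarded.  p_b sums the
    weights falling in bin b divided by the total retained weight; F_b =
    -ln p_b on occupied bins (NaN elsewhere), in kT units up to a constant.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.ndim == 2:
        start = int(np.floor(burn_in_frac * values.shape[0]))
        if start >= values.shape[0]:
            start = values.shape[0] - 1
        values = values[start:].ravel()
        weights = weights[start:].ravel()
    if values.size == 0:
        raise FlavokitError("no samples after burn-in")
    hist, edges = np.histogram(values, bins=bins, range=bin_range, weights=weights)
    total = hist.sum()
    if total <= 0:
        raise FlavokitError("all samples fall outside the bin range")
    p = hist / total
    with np.errstate(divide="ignore"):
        f = np.where(p > 0, -np.log(np.where(p > 0, p, 1.0)), np.nan)
    return FreeEnergyProfile(bin_edges=edges, p=p, f=f)


def trace_lineage(result: WEResult, walker_index: int) -> dict:
    """Walk parent pointers from a final walker back to cycle 0.

    Returns the continuous per-cycle value and weight series along the
    lineage plus the slot path (length n_cycles + 1).
    """
    n = result.values.shape[1]
    if not (0 <= walker_index < n):
        raise IntegrityError(f"walker index {walker_index} out of range [0, {n})")
    slots = [walker_index]
    slot = walker_index
    for rec in reversed(result.records):
        pi = rec.parent_idx
        if pi.shape != (n,):
            raise IntegrityError(f"cycle {rec.cycle}: malformed parent record")
        slot = int(pi[slot])
        if not (0 <= slot < n):
            raise IntegrityError(f"cycle {rec.cycle}: parent slot {slot} out of range")
        slots.append(slot)
    slots.reverse()
    cyc = np.arange(len(slots))
    return {
        "cycles": cyc,
        "slots": np.array(slots),
        "values": result.values[cyc, slots],
        "weights": result.weights[cyc, slots],
    }
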