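"""Synthetic generators for every input the analysis pipeline consumes.

Four generators emulate, at desk scale, the data the downstream stages were
designed for:

* an enzyme-inhibition screening panel (four-parameter-logistic responses
  with Gaussian assay noise) matching the study design of 58 compounds x
  7 enzymes, 10 concentrations from 5 nM to 100 uM, two technical
  replicates;
* a self-assembly "collapse" trajectory in which rigid molecules drift
  toward their common centroid, driving the ensemble radius of gyration
  down as aggregation proceeds;
* an ideal stacked-ring fiber (planar hexagons with given rise and twist,
  optional perpendicular branch sub-stacks and glycoside-like appendages)
  for exercising the pi-stacking detector;
* an overdamped-Langevin propagator on a double-well potential — a toy
  one-dimensional stand-in for solvated dynamics, used to drive the
  weighted-ensemble engine.

Determinism: each generator takes a single seed; all stochastic draws come
from one ``numpy.random.default_rng(seed)`` stream in the documented order,
so fixed seeds give bit-identical output across calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import dose_response as dr
from .errors import PlacementError, SpecValidationError
from .rgyr import Trajectory
from .stacking import RingSpec

#: study design: 10 assay concentrations, log-spaced from 5 nM to 100 uM
DEFAULT_CONCENTRATIONS: tuple = tuple(np.geomspace(5e-9, 1e-4, 10))


# ---------------------------------------------------------------------------
# inhibition panel
# ---------------------------------------------------------------------------


@dataclass
class SyntheticPanelSpec:
    """True dose-response parameters for a compound x enzyme panel.

    ``true_ic50`` is a compounds-by-enzymes DataFrame in molar; NaN marks an
    "absent" entry (no true inhibition — responses are baseline noise).
    ``noise_sd`` is the Gaussian assay noise in percent-inhibition units;
    responses are deliberately NOT clipped to [0, 100].
    """

    true_ic50: pd.DataFrame
    hill: float = 1.0
    noise_sd: float = 5.0
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size == 0 or np.any(conc <= 0):
            raise SpecValidationError("concentrations", "must all be > 0")
        if np.any(np.diff(conc) <= 0):
            raise SpecValidationError("concentrations", "must be strictly increasing")
        if self.n_replicates < 1:
            raise SpecValidationError("n_replicates", "must be >= 1")
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd", "must be >= 0")
        if self.hill <= 0:
            raise SpecValidationError("hill", "must be > 0")
        vals = self.true_ic50.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise SpecValidationError("true_ic50", "finite entries must be > 0 (molar)")


def gen_inhibition_panel(spec: SyntheticPanelSpec) -> pd.DataFrame:
    """Tidy inhibition table: one row per compound x enzyme x concentration
    x replicate.

    The noise-free response is the four-parameter logistic with bottom 0 %,
    top 100 %, the spec's Hill slope and the true IC50; absent entries give
    a flat 0 % baseline.  Gaussian noise of sd ``noise_sd`` is added to
    every record (single rng draw, C-order over compound, enzyme,
    concentration, replicate).
    """
    rng = np.random.default_rng(spec.seed)
    conc = np.asarray(spec.concentrations, dtype=float)
    logc = np.log10(conc)
    compounds = list(spec.true_ic50.index)
    enzymes = list(spec.true_ic50.columns)
    ic50 = spec.true_ic50.to_numpy(dtype=float)  # (nC, nE)

    with np.errstate(invalid="ignore"):
        log_ic50 = np.log10(ic50)
    clean = dr.logistic4(
        logc[None, None, :], 0.0, 100.0, spec.hill, log_ic50[:, :, None]
    )  # (nC, nE, nconc)
    clean = np.where(np.isfinite(ic50)[:, :, None], clean, 0.0)

    shape = (len(compounds), len(enzymes), conc.size, spec.n_replicates)
    noise = rng.normal(0.0, spec.noise_sd, size=shape) if spec.noise_sd > 0 else np.zeros(shape)
    resp = clean[:, :, :, None] + noise

    idx = pd.MultiIndex.from_product(
        [compounds, enzymes, conc, range(1, spec.n_replicates + 1)],
        names=["compound_id", "enzyme_id", "concentration_m", "replicate"],
    )
    table = pd.DataFrame({"percent_inhibition": resp.ravel()}, index=idx).reset_index()
    return table


def study_panel_spec(
    seed: int = 0,
    n_compounds: int = 58,
    n_enzymes: int = 7,
    noise_sd: float = 5.0,
    n_in_range: int = 106,
    n_extrapolated: int = 49,
) -> tuple[SyntheticPanelSpec, pd.DataFrame]:
    """Panel spec emulating the screen's composition, plus ground truth.

    Of the ``n_compounds * n_enzymes`` compound-enzyme pairs, ``n_in_range``
    get a true IC50 log-uniform in [10 nM, 10 uM] (well inside the assay
    window), ``n_extrapolated`` get one log-uniform in [150, 250] uM (the
    50 % crossing sits above the top assay concentration while partial
    inhibition remains visible in-window), and the remainder are absent
    (baseline).  The default counts 106/49/251 of 406 realise an
    in-range / extrapolated / baseline composition of 26 / 12 / 62 % to the
    nearest percent.  Returns ``(spec, truth)`` where ``truth`` has one row
    per pair with the true IC50 and true category.
    """
    rng = np.random.default_rng(seed)
    n_pairs = n_compounds * n_enzymes
    if n_in_range + n_extrapolated > n_pairs:
        raise SpecValidationError("n_in_range", "category counts exceed panel size")
    compounds = [f"C{i:03d}" for i in range(1, n_compounds + 1)]
    enzymes = [f"E{i}" for i in range(1, n_enzymes + 1)]

    # rng order: (1) pair permutation, (2) in-range log-IC50s, (3) extrapolated
    order = rng.permutation(n_pairs)
    log_in = rng.uniform(-8.0, -5.0, size=n_in_range)
    log_ext = rng.uniform(np.log10(1.5e-4), np.log10(2.5e-4), size=n_extrapolated)

    flat = np.full(n_pairs, np.nan)
    flat[order[:n_in_range]] = 10.0 ** log_in
    flat[order[n_in_range : n_in_range + n_extrapolated]] = 10.0 ** log_ext
    category = np.full(n_pairs, dr.BASELINE, dtype=object)
    category[order[:n_in_range]] = dr.IN_RANGE
    category[order[n_in_range : n_in_range + n_extrapolated]] = dr.EXTRAPOLATED

    true_ic50 = pd.DataFrame(
        flat.reshape(n_compounds, n_enzymes), index=compounds, columns=enzymes
    )
    truth = pd.DataFrame(
        {
            "compound_id": np.repeat(compounds, n_enzymes),
            "enzyme_id": np.tile(enzymes, n_compounds),
            "true_ic50_m": flat,
            "true_category": category,
        }
    )
    spec = SyntheticPanelSpec(true_ic50=true_ic50, noise_sd=noise_sd, seed=seed)
    return spec, truth


# ---------------------------------------------------------------------------
# collapse trajectory
# ---------------------------------------------------------------------------


@dataclass
class CollapseTrajSpec:
    """Rigid molecules drifting toward their common centroid.

    Defaults emulate a ten-molecule self-assembly box (~4 nm, matching a
    pre-assembly ensemble RGYR around 1.5 nm) over 400 frames of 1 ns.
    ``collapse_rate`` is the fractional drift toward the centroid per ns;
    ``thermal_sd`` the per-frame Gaussian jitter of molecule centres (nm).
    """

    n_molecules: int = 10
    atoms_per_molecule: int = 6
    box_edge: float = 4.0
    collapse_rate: float = 0.01
    n_frames: int = 400
    dt: float = 1.0
    thermal_sd: float = 0.05
    min_separation: float = 0.4
    max_retries: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.box_edge <= 0:
            raise SpecValidationError("box_edge", "must be > 0")
        if self.collapse_rate < 0:
            raise SpecValidationError("collapse_rate", "must be >= 0")
        if self.n_frames < 2:
            raise SpecValidationError("n_frames", "must be >= 2")
        if self.n_molecules < 1:
            raise SpecValidationError("n_molecules", "must be >= 1")
        if self.atoms_per_molecule < 1:
            raise SpecValidationError("atoms_per_molecule", "must be >= 1")
        if self.dt <= 0:
            raise SpecValidationError("dt", "must be > 0")
        if self.thermal_sd < 0:
            raise SpecValidationError("thermal_sd", "must be >= 0")


def _place_centers(rng: np.random.Generator, spec: CollapseTrajSpec) -> np.ndarray:
    """Uniform random non-overlapping centres (rejection sampling)."""
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < spec.n_molecules:
        cand = rng.uniform(0.0, spec.box_edge, size=3)
        if all(np.linalg.norm(cand - c) >= spec.min_separation for c in centers):
            centers.append(cand)
        else:
            tries += 1
            if tries > spec.max_retries:
                raise PlacementError(
                    f"could not place {spec.n_molecules} molecules with separation "
                    f">= {spec.min_separation} nm in a {spec.box_edge} nm box "
                    f"after {spec.max_retries} retries"
                )
    return np.array(centers)


def gen_collapse_trajectory(spec: CollapseTrajSpec) -> Trajectory:
    """Trajectory of rigid molecules drifting toward the ensemble centroid.

    rng order: (1) molecule centres (rejection sampling), (2) per-molecule
    rigid atom offsets, (3) per-frame thermal jitter.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _place_centers(rng, spec)
    offsets = rng.normal(0.0, 0.1, size=(spec.n_molecules, spec.atoms_per_molecule, 3))
    offsets -= offsets.mean(axis=1, keepdims=True)  # centre each rigid body

    # base centres drift deterministically toward the ensemble centroid;
    # thermal jitter is non-accumulating positional noise about the bases,
    # so a zero collapse rate yields a trend-free stationary series
    frames = np.empty((spec.n_frames, spec.n_molecules, spec.atoms_per_molecule, 3))
    base = centers.copy()
    for f in range(spec.n_frames):
        jitter = (
            rng.normal(0.0, spec.thermal_sd, size=base.shape)
            if spec.thermal_sd > 0
            else np.zeros_like(base)
        )
        frames[f] = (base + jitter)[:, None, :] + offsets
        centroid = base.mean(axis=0)
        base = base + spec.collapse_rate * spec.dt * (centroid - base)

    n_atoms = spec.n_molecules * spec.atoms_per_molecule
    coords = frames.reshape(spec.n_frames, n_atoms, 3)
    tags = pd.DataFrame(
        {
            "molecule_id": np.repeat(
                [f"M{i:03d}" for i in range(spec.n_molecules)], spec.atoms_per_molecule
            ),
            "group": "flavonoid_core",
        }
    )
    return Trajectory(
        coordinates=coords,
        masses=np.full(n_atoms, 12.0),
        frame_times=np.arange(spec.n_frames) * spec.dt,
        atom_tags=tags,
    )


# ---------------------------------------------------------------------------
# stacked-ring fiber
# ---------------------------------------------------------------------------


@dataclass
class Structure:
    """A single-frame collection of atoms (Angstrom) with ring definitions."""

    coordinates: np.ndarray
    masses: np.ndarray
    atom_tags: pd.DataFrame
    rings: list

    @property
    def molecule_ids(self) -> list:
        return list(dict.fromkeys(self.atom_tags["molecule_id"]))


@dataclass
class FiberSpec:
    """An ideal pi-stacked fiber of planar hexagonal rings.

    ``rise`` is the Angstrom spacing between consecutive ring centroids,
    ``twist`` the rotation (degrees) added per unit.  ``branch_points`` is a
    list of ``(unit_index, branch_length)`` pairs (1-based unit index); each
    spawns a sub-stack growing perpendicular to the main axis, emulating
    secondary fiber structure.  ``with_glycoside`` attaches a small off-ring
    atom cluster per unit, positioned radially outward like a sugar group.
    """

    n_units: int = 5
    rise: float = 3.5
    twist: float = 0.0
    branch_points: tuple = ()
    with_glycoside: bool = False

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise SpecValidationError("n_units", "must be >= 1")
        if self.rise <= 0:
            raise SpecValidationError("rise", "must be > 0")
        self.branch_points = tuple((int(u), int(l)) for u, l in self.branch_points)
        if len(self.branch_points) > 4:
            raise SpecValidationError(
                "branch_points", "at most 4 branches (one per lateral direction)"
            )
        for u, l in self.branch_points:
            if not (1 <= u <= self.n_units):
                raise SpecValidationError(
                    "branch_points", f"unit index {u} outside [1, {self.n_units}]"
                )
            if l < 1:
                raise SpecValidationError("branch_points", "branch length must be >= 1")


_RING_RADIUS = 1.39  # Angstrom, aromatic C-C ring circumradius
_BRANCH_DIRS = (
    np.array([1.0, 0.0, 0.0]),
    np.array([0.0, 1.0, 0.0]),
    np.array([-1.0, 0.0, 0.0]),
    np.array([0.0, -1.0, 0.0]),
)


def _hexagon(center: np.ndarray, normal: np.ndarray, phase_deg: float) -> np.ndarray:
    """Six atoms of an ideal planar hexagon in the plane through ``center``
    perpendicular to ``normal``."""
    normal = normal / np.linalg.norm(normal)
    # build an orthonormal in-plane basis
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    ang = np.radians(phase_deg) + np.arange(6) * (np.pi / 3)
    return center + _RING_RADIUS * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))


def gen_ring_fiber(spec: FiberSpec) -> Structure:
    """Construct the fiber; each ring is one molecule of six unit-mass atoms.

    Main-stack ring u sits at z = u * rise with normal +z and in-plane phase
    u * twist.  A branch at unit k grows along an axis perpendicular to the
    main stack (directions cycle +x, +y, -x, -y per branch), with branch
    ring normals along that axis so the sub-stack is itself face-to-face
    stacked; the joint between the branch and the main ring is an ideal
    edge-to-face (T-shaped, 90 degree) contact at distance ``rise``.
    """
    coords: list[np.ndarray] = []
    rings: list[RingSpec] = []
    mol_ids: list[str] = []
    groups: list[str] = []

    def add_ring(mol_id: str, center: np.ndarray, normal: np.ndarray, phase: float) -> None:
        start = len(mol_ids)
        pts = _hexagon(center, normal, phase)
        coords.append(pts)
        mol_ids.extend([mol_id] * 6)
        groups.extend(["flavonoid_core"] * 6)
        rings.append(RingSpec(molecule_id=mol_id, atom_indices=range(start, start + 6)))
        if spec.with_glycoside:
            # small 4-atom cluster radially outward, clear of the stack axis
            direction = _hexagon(center, normal, phase)[0] - center
            direction /= np.linalg.norm(direction)
            base = center + 3.5 * direction
            cluster = base + 0.5 * np.array(
                [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
            )
            coords.append(cluster)
            mol_ids.extend([mol_id] * 4)
            groups.extend(["glycoside"] * 4)

    z = np.array([0.0, 0.0, 1.0])
    main_centers = []
    for u in range(spec.n_units):
        c = np.array([0.0, 0.0, u * spec.rise])
        main_centers.append(c)
        add_ring(f"U{u + 1:03d}", c, z, u * spec.twist)

    for b, (unit, blen) in enumerate(spec.branch_points):
        direction = _BRANCH_DIRS[b % len(_BRANCH_DIRS)]
        origin = main_centers[unit - 1]
        for k in range(1, blen + 1):
            add_ring(f"B{b + 1}_{k:03d}", origin + k * spec.rise * direction, direction, 0.0)

    all_coords = np.vstack(coords)
    tags = pd.DataFrame({"molecule_id": mol_ids, "group": groups})
    return Structure(
        coordinates=all_coords,
        masses=np.ones(len(mol_ids)),
        atom_tags=tags,
        rings=rings,
    )


def expected_fiber_topology(spec: FiberSpec) -> dict:
    """Ground truth for detector-recovery tests: component size and class.

    A branch rooted at an end unit merely extends the path (all degrees
    stay <= 2), so SECONDARY requires some unit to carry degree >= 3:
    its main-stack neighbours plus the branches rooted there.
    """
    size = spec.n_units + sum(l for _, l in spec.branch_points)
    if size == 1:
        return {"size": 1, "topology": "SINGLETON"}
    branched = False
    for u in range(1, spec.n_units + 1):
        main_deg = int(u > 1) + int(u < spec.n_units)
        n_branches = sum(1 for bu, _ in spec.branch_points if bu == u)
        if main_deg + n_branches >= 3:
            branched = True
    return {"size": size, "topology": "SECONDARY" if branched else "PRIMARY"}


# ---------------------------------------------------------------------------
# double-well toy dynamics
# ---------------------------------------------------------------------------


@dataclass
class DoubleWellSpec:
    """Overdamped Langevin dynamics on U(x) = barrier * ((x/a)^2 - 1)^2.

    ``well_half_separation`` a sets the minima at +/- a; ``barrier`` is the
    central barrier height in kT units (with kT the energy scale below).
    The propagator uses the Euler-Maruyama update
    x += (D/kT) * F(x) * dt + sqrt(2 D dt) * xi.
    """

    barrier: float = 5.0
    well_half_separation: float = 1.0
    diffusion: float = 1.0
    dt: float = 1e-3
    kT: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.barrier < 0:
            raise SpecValidationError("barrier", "must be >= 0")
        if self.dt <= 0:
            raise SpecValidationError("dt", "must be > 0")
        if self.diffusion <= 0:
            raise SpecValidationError("diffusion", "must be > 0")
        if self.well_half_separation <= 0:
            raise SpecValidationError("well_half_separation", "must be > 0")
        if self.kT <= 0:
            raise SpecValidationError("kT", "must be > 0")


def double_well_potential(x: np.ndarray, spec: DoubleWellSpec) -> np.ndarray:
    a = spec.well_half_separation
    return spec.barrier * ((np.asarray(x, dtype=float) / a) ** 2 - 1.0) ** 2


def _double_well_force(x: np.ndarray, spec: DoubleWellSpec) -> np.ndarray:
    a = spec.well_half_separation
    return -4.0 * spec.barrier * x * ((x / a) ** 2 - 1.0) / a**2


def make_overdamped_propagator(
    force: Callable[[np.ndarray], np.ndarray],
    diffusion: float,
    dt: float,
    kT: float = 1.0,
) -> Callable:
    """Euler-Maruyama propagator for overdamped Langevin dynamics under an
    arbitrary force field; the returned callable has the contract
    ``(state, n_steps, rng) -> state`` and is vectorised over state arrays."""
    drift_c = diffusion * dt / kT
    noise_c = float(np.sqrt(2.0 * diffusion * dt))

    def propagate(state, n_steps: int, rng: np.random.Generator):
        x = np.array(state, dtype=float, copy=True)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        for _ in range(int(n_steps)):
            x += drift_c * force(x) + noise_c * rng.standard_normal(x.shape)
        return float(x[0]) if scalar else x

    return propagate


def make_double_well_propagator(spec: DoubleWellSpec) -> Callable:
    """Propagator on the spec's double well (see :class:`DoubleWellSpec`)."""
    return make_overdamped_propagator(
        lambda x: _double_well_force(x, spec), spec.diffusion, spec.dt, spec.kT
    )


def make_harmonic_propagator(
    k: float, diffusion: float = 1.0, dt: float = 1e-3, kT: float = 1.0
) -> Callable:
    """Propagator on U(x) = k x^2 / 2 — the analytically solvable reference
    (Boltzmann density N(0, kT/k)) used to validate free-energy profiles."""
    return make_overdamped_propagator(lambda x: -k * x, diffusion, dt, kT)
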