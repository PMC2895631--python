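"""Synthetic inputs with known ground truth.

Everything the analysis pipeline consumes can be generated here: sphere-
filling atom clusters (whose exclusion measures have closed forms), two-state
open/closed toy ensembles with a controlled size gap between the states, and
umbrella-window samples drawn exactly from a specified PMF (inverse-CDF
sampling, so recovery tests are free of MCMC convergence artifacts).

The toy protein is two overlapping atom lobes; opening rigidly separates the
lobes, so the open state has larger radius of gyration and SASA — the same
size asymmetry that makes crowding favour closed conformations of real
proteins. Defaults mirror the study conditions the package targets: 100
conformations per state, and the 32-window umbrella layout (centres 11.5 to
20.8 Å in 0.3 Å steps).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .structure import (
    ATOMIC_MASSES,
    BONDI_RADII,
    AtomisticStructure,
    ConformationalEnsemble,
)
from .surface import fibonacci_sphere
from .wham import UmbrellaWindow

__all__ = [
    "TwoStateToySpec",
    "GroundTruthPMF",
    "default_umbrella_centers",
    "double_well_pmf",
    "make_sphere_cluster",
    "make_two_state_ensembles",
    "sample_umbrella_windows",
    "crowding_weights_from_truth",
]

#: Umbrella layout used throughout: 32 centres, 11.5–20.8 Å, 0.3 Å increment.
def default_umbrella_centers() -> np.ndarray:
    return 11.5 + 0.3 * np.arange(32)


@dataclass(frozen=True)
class TwoStateToySpec:
    """Parameters of the two-lobe open/closed toy ensembles.

    ``closed_radius`` is the radius of each lobe; in the closed state the two
    lobe centres sit one lobe radius apart (a compact, strongly overlapping
    dumbbell) and opening displaces them by a further
    ``opening_displacement``. ``jitter_sd`` is the per-conformation Gaussian
    positional noise applied to every atom.
    """

    n_atoms: int = 200
    closed_radius: float = 7.0
    opening_displacement: float = 10.0
    jitter_sd: float = 0.5
    n_conformations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.opening_displacement < 0:
            raise ValueError("opening_displacement must be >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.jitter_sd > 0.2 * self.closed_radius:
            raise ValueError("jitter_sd must be small relative to the lobe size")
        if self.n_atoms < 2 or self.n_conformations < 1:
            raise ValueError("need at least 2 atoms and 1 conformation")


@dataclass(frozen=True)
class GroundTruthPMF:
    """An analytic PMF W*(x) in k_BT on [x_min, x_max], with an optional
    crowding chemical potential βΔμ*(x) used to fabricate per-sample weights."""

    w: Callable[[np.ndarray], np.ndarray]
    x_min: float
    x_max: float
    beta_dmu: Callable[[np.ndarray], np.ndarray] | None = None

    def grid(self, n: int = 4001) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, n)


def double_well_pmf(
    minimum_a: float = 12.5,
    minimum_b: float = 20.0,
    barrier: float = 3.0,
    tilt: float = 0.0,
    x_min: float = 10.5,
    x_max: float = 21.8,
) -> GroundTruthPMF:
    """Quartic double well with minima near ``minimum_a``/``minimum_b`` and a
    barrier of ``barrier`` k_BT at the midpoint; ``tilt`` (k_BT) linearly
    biases state b relative to state a."""
    c = 0.5 * (minimum_a + minimum_b)
    a = 0.5 * (minimum_b - minimum_a)

    def w(x: np.ndarray) -> np.ndarray:
        u = (np.asarray(x, float) - c) / a
        return barrier * (u**2 - 1.0) ** 2 + 0.5 * tilt * u

    return GroundTruthPMF(w=w, x_min=x_min, x_max=x_max)


def make_sphere_cluster(
    target_radius: float,
    n_atoms: int = 300,
    atom_radius: float = 1.9,
    seed: int = 0,
    element: str = "C",
    shell_fraction: float = 0.5,
) -> AtomisticStructure:
    """Atom cluster filling a ball of ``target_radius`` so that its exclusion
    measures approximate the analytic sphere measures.

    A fraction ``shell_fraction`` of the atoms tiles the shell at radius
    target − atom_radius (Fibonacci lattice, so the union's outer envelope
    tracks the target sphere); the rest fill the interior quasi-uniformly.
    The probe surface sags between shell atoms by roughly d²/2 × (1/r_shell
    + 1/(atom_radius + R_c)) for inter-atom spacing d, so a denser shell
    (larger n_atoms or shell_fraction) tracks the sphere more closely.
    """
    if not 0.0 < shell_fraction <= 1.0:
        raise ValueError("shell_fraction must lie in (0, 1]")
    if target_radius <= atom_radius:
        raise ValueError("target_radius must exceed atom_radius")
    v_atoms = n_atoms * (4.0 / 3.0) * math.pi * atom_radius**3
    v_target = (4.0 / 3.0) * math.pi * target_radius**3
    if v_atoms < 0.8 * v_target:
        raise ValueError(
            f"{n_atoms} atoms of radius {atom_radius} Å cannot plausibly fill "
            f"a {target_radius} Å sphere (volume ratio {v_atoms / v_target:.2f})"
        )
    rng = np.random.default_rng(seed)
    n_shell = max(1, int(round(shell_fraction * n_atoms)))
    shell = (target_radius - atom_radius) * fibonacci_sphere(n_shell)
    # random rigid rotation + tiny jitter: seeds differ without denting the shell
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, xq, yq, zq = q
    rot = np.array(
        [
            [1 - 2 * (yq**2 + zq**2), 2 * (xq * yq - w * zq), 2 * (xq * zq + w * yq)],
            [2 * (xq * yq + w * zq), 1 - 2 * (xq**2 + zq**2), 2 * (yq * zq - w * xq)],
            [2 * (xq * zq - w * yq), 2 * (yq * zq + w * xq), 1 - 2 * (xq**2 + yq**2)],
        ]
    )
    shell = shell @ rot.T
    shell += rng.normal(scale=0.01 * atom_radius, size=shell.shape)
    n_core = n_atoms - n_shell
    u = rng.uniform(size=n_core) ** (1.0 / 3.0)
    dirs = rng.normal(size=(n_core, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    core = (target_radius - atom_radius) * u[:, None] * dirs
    coords = np.vstack([shell, core])
    n = len(coords)
    return AtomisticStructure(
        elements=np.array([element] * n, dtype=object),
        coords=coords,
        radii=np.full(n, atom_radius),
        masses=np.full(n, ATOMIC_MASSES[element]),
        chain_ids=np.array(["A"] * n, dtype=object),
        res_ids=1 + np.arange(n) // 5,
        res_names=np.array(["CLU"] * n, dtype=object),
        atom_names=np.array([f"C{i % 5 + 1}" for i in range(n)], dtype=object),
        label="sphere_cluster",
    )


def _toy_base(spec: TwoStateToySpec, open_state: bool) -> AtomisticStructure:
    n_a = spec.n_atoms // 2
    n_b = spec.n_atoms - n_a
    lobe_a = make_sphere_cluster(
        spec.closed_radius, n_a, seed=spec.seed + 1,
    )
    lobe_b = make_sphere_cluster(
        spec.closed_radius, n_b, seed=spec.seed + 2,
    )
    sep = spec.closed_radius + (spec.opening_displacement if open_state else 0.0)
    coords = np.vstack(
        [lobe_a.coords - [sep / 2.0, 0, 0], lobe_b.coords + [sep / 2.0, 0, 0]]
    )
    n = spec.n_atoms
    label = "open" if open_state else "closed"
    return AtomisticStructure(
        elements=np.array(["C"] * n, dtype=object),
        coords=coords,
        radii=np.full(n, BONDI_RADII["C"]),
        masses=np.full(n, ATOMIC_MASSES["C"]),
        chain_ids=np.array(["A"] * n_a + ["B"] * n_b, dtype=object),
        res_ids=np.concatenate([1 + np.arange(n_a) // 5, 1 + np.arange(n_b) // 5]),
        res_names=np.array(["TOY"] * n, dtype=object),
        atom_names=np.array([f"C{i % 5 + 1}" for i in range(n)], dtype=object),
        label=label,
    )


def make_two_state_ensembles(
    spec: TwoStateToySpec,
) -> tuple[ConformationalEnsemble, ConformationalEnsemble]:
    """Open and closed toy ensembles (open first).

    Both states share atom identities and ordering; per-conformation jitter
    is the only within-state variation, so ensemble SASA/R_g spreads are
    tight (sub-percent for the default jitter), mimicking snapshots of a
    stable MD state.
    """
    rng = np.random.default_rng(spec.seed)
    ensembles = []
    for open_state in (True, False):
        base = _toy_base(spec, open_state)
        confs = []
        for i in range(spec.n_conformations):
            noise = rng.normal(scale=spec.jitter_sd, size=base.coords.shape)
            confs.append(
                base.with_coords(base.coords + noise, label=f"{base.label}[{i}]")
            )
        ensembles.append(
            ConformationalEnsemble(confs, state_label=base.label)
        )
    return ensembles[0], ensembles[1]


def sample_umbrella_windows(
    truth: GroundTruthPMF,
    centers: Sequence[float] | None = None,
    force_constants: Sequence[float] | float = 5.0,
    n_per_window: int = 1500,
    seed: int = 0,
    temperature: float = 300.0,
    grid_points: int = 4001,
) -> list[UmbrellaWindow]:
    """Draw window samples exactly from the biased Boltzmann densities
    p_i(x) ∝ exp(−W*(x) − ½k_i(x−x₀,i)²) by inverse-CDF on a fine grid.

    ``force_constants`` are in kcal/mol/Å² (one value or one per window);
    defaults follow the standard layout: 32 windows, 0.3 Å apart, 5
    kcal/mol/Å². Emits a warning when adjacent biased densities share less
    than 1% of their mass (WHAM would be poorly conditioned there).
    """
    from .thermo import kt_in_kcal_per_mol

    centers = default_umbrella_centers() if centers is None else np.asarray(centers, float)
    if np.isscalar(force_constants):
        force_constants = np.full(len(centers), float(force_constants))
    else:
        force_constants = np.asarray(force_constants, dtype=float)
        if len(force_constants) != len(centers):
            raise ValueError("need one force constant per window")
    kt = kt_in_kcal_per_mol(temperature)
    x = truth.grid(grid_points)
    w_vals = truth.w(x)
    rng = np.random.default_rng(seed)
    windows = []
    densities = []
    for x0, k in zip(centers, force_constants):
        energy = w_vals + 0.5 * (k / kt) * (x - x0) ** 2
        p = np.exp(-(energy - energy.min()))
        norm = np.trapezoid(p, x)
        if not norm > 0:
            raise ValueError(f"biased density at centre {x0} is not integrable")
        p /= norm
        densities.append(p)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(x))])
        cdf /= cdf[-1]
        u = rng.uniform(size=n_per_window)
        samples = np.interp(u, cdf, x)
        windows.append(UmbrellaWindow(center=float(x0), force_constant=float(k), samples=samples))
    for i in range(len(densities) - 1):
        overlap = np.trapezoid(np.minimum(densities[i], densities[i + 1]), x)
        if overlap < 0.01:
            warnings.warn(
                f"windows {i} and {i + 1} overlap by only {overlap:.2%}; "
                "WHAM may be ill-conditioned between them",
                stacklevel=2,
            )
    return windows


def crowding_weights_from_truth(
    windows: list[UmbrellaWindow],
    beta_dmu_of_x: Callable[[np.ndarray], np.ndarray],
) -> list[UmbrellaWindow]:
    """Attach fabricated crowding weights f = exp(−βΔμ*(x)) to every sample."""
    out = []
    for w in windows:
        dmu = np.asarray(beta_dmu_of_x(w.samples), dtype=float)
        if np.any(~np.isfinite(dmu)):
            raise ValueError("βΔμ*(x) must be finite on all samples")
        out.append(w.with_samples(w.samples, np.exp(-dmu)))
    return out
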