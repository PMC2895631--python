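"""Hard-sphere crowder models: the two routes to the crowding chemical potential.

A crowded solution is modelled as a fluid of hard spheres (radius ``R_c``,
volume fraction ``phi``). The chemical-potential change βΔμ of transferring a
rigid protein conformation from dilute to crowded solution is, for hard-core
protein–crowder repulsion, −ln f where f is the probability that the
conformation can be placed at a random position and orientation without
overlapping any crowder.

Two estimators are provided:

* :func:`insertion_probability` — direct particle-insertion Monte Carlo into
  equilibrated periodic crowder boxes (the oracle; fails to converge when f
  is astronomically small).
* :func:`gfmt_delta_mu` — the generalized fundamental-measure prediction,
  linear in the exclusion-surface measures (v_p, s_p, l_p), with coefficients
  pinned so that it reduces exactly to the scaled-particle-theory formula
  :func:`spt_delta_mu_sphere` for a spherical solute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import AtomisticStructure
from .surface import GeometricMeasures

__all__ = [
    "CrowderModel",
    "CrowderBox",
    "InsertionEstimate",
    "build_crowder_box",
    "insertion_probability",
    "spt_delta_mu_sphere",
    "gfmt_delta_mu",
    "save_crowder_box",
    "load_crowder_box",
]


@dataclass(frozen=True)
class CrowderModel:
    """Spherical crowder species: radius R_c (Å) and volume fraction phi."""

    R_c: float
    phi: float

    def __post_init__(self) -> None:
        if self.R_c <= 0:
            raise ValueError("R_c must be positive")
        if not 0.0 <= self.phi < 1.0:
            raise ValueError("phi must lie in [0, 1)")

    @property
    def sphere_volume(self) -> float:
        return 4.0 * math.pi / 3.0 * self.R_c**3

    @property
    def rho(self) -> float:
        """Number density (Å⁻³), phi / ((4π/3) R_c³)."""
        return self.phi / self.sphere_volume


@dataclass
class CrowderBox:
    """Periodic cubic box of non-overlapping crowder spheres."""

    box_length: float
    centers: np.ndarray  # (N, 3)
    R_c: float
    periodic: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        if self.box_length <= 0:
            raise ValueError("box_length must be positive")
        if len(self.centers) > 1:
            d = _min_image_pair_distances(self.centers, self.box_length)
            if d.min() < 2.0 * self.R_c - 1e-9:
                raise ValueError("crowder spheres overlap under minimum image")

    @property
    def n_crowders(self) -> int:
        return len(self.centers)

    @property
    def realized_phi(self) -> float:
        v = 4.0 * math.pi / 3.0 * self.R_c**3
        return self.n_crowders * v / self.box_length**3


@dataclass(frozen=True)
class InsertionEstimate:
    """Pooled insertion-MC result.

    ``stderr_f`` is the larger of the binomial standard error and the
    between-box standard error of per-box success fractions (trials within a
    box share that box's configuration, so the binomial term alone is
    anti-conservative when few crowders are present per box).

    When no trial succeeds, ``beta_delta_mu`` carries a one-sided lower
    bound, −ln(f_upper) with f_upper the 97.5% Wilson upper bound, and
    ``is_lower_bound`` is set.
    """

    trials: int
    successes: int
    f: float
    stderr_f: float
    beta_delta_mu: float
    is_lower_bound: bool = False

    @property
    def stderr_beta_delta_mu(self) -> float:
        if self.successes == 0:
            return math.inf
        return self.stderr_f / self.f


def _min_image_pair_distances(centers: np.ndarray, L: float) -> np.ndarray:
    diff = centers[:, None, :] - centers[None, :, :]
    diff -= L * np.round(diff / L)
    d = np.sqrt((diff**2).sum(axis=2))
    iu = np.triu_indices(len(centers), k=1)
    return d[iu]


def build_crowder_box(
    model: CrowderModel,
    box_length: float,
    n_sweeps: int = 500,
    seed: int = 0,
    max_step: float | None = None,
) -> CrowderBox:
    """Generate an equilibrated periodic box of hard-sphere crowders.

    N = round(phi L³ / ((4π/3) R_c³)) spheres are placed by random sequential
    insertion (simple-cubic lattice start above phi = 0.3, where RSA stalls)
    and relaxed by ``n_sweeps`` Metropolis single-sphere displacement sweeps
    (every non-overlapping move is accepted — hard-sphere Metropolis).
    """
    R, phi, L = model.R_c, model.phi, float(box_length)
    if phi >= 0.55:
        raise ValueError(
            "phi >= 0.55 is beyond reliable equilibration for this sampler"
        )
    if L < 6.0 * R:
        raise ValueError("box_length must be at least 6 R_c")
    n = int(round(phi * L**3 / model.sphere_volume))
    rng = np.random.default_rng(seed)
    if n == 0:
        return CrowderBox(L, np.empty((0, 3)), R, seed=seed)
    if n * (4.0 * math.pi / 3.0) * R**3 / L**3 > 0.55:
        raise ValueError("requested packing is geometrically impracticable here")

    if phi <= 0.30:
        centers = _rsa_fill(n, R, L, rng)
    else:
        centers = _lattice_fill(n, R, L, rng)
    step = 0.3 * R if max_step is None else max_step
    _metropolis_sweeps(centers, R, L, n_sweeps, step, rng)
    return CrowderBox(L, centers, R, seed=seed)


def _rsa_fill(n: int, R: float, L: float, rng: np.random.Generator) -> np.ndarray:
    centers = np.empty((0, 3))
    attempts = 0
    max_attempts = 20000 * n
    while len(centers) < n:
        if attempts > max_attempts:
            raise RuntimeError(
                f"random sequential insertion stalled at {len(centers)}/{n} spheres"
            )
        trial = rng.uniform(0.0, L, size=3)
        if len(centers):
            diff = centers - trial
            diff -= L * np.round(diff / L)
            if np.min((diff**2).sum(axis=1)) < (2.0 * R) ** 2:
                attempts += 1
                continue
        centers = np.vstack([centers, trial])
        attempts += 1
    return centers


def _lattice_fill(n: int, R: float, L: float, rng: np.random.Generator) -> np.ndarray:
    m = int(math.ceil(n ** (1.0 / 3.0)))
    while True:
        a = L / m
        if a < 2.0 * R:
            raise ValueError(
                "requested volume fraction cannot be reached from a cubic lattice"
            )
        if m**3 >= n:
            break
        m += 1
    idx = np.stack(np.meshgrid(*[np.arange(m)] * 3, indexing="ij"), -1).reshape(-1, 3)
    pick = rng.choice(len(idx), size=n, replace=False)
    return (idx[pick] + 0.5) * (L / m)


def _metropolis_sweeps(
    centers: np.ndarray, R: float, L: float, n_sweeps: int, step: float,
    rng: np.random.Generator,
) -> None:
    n = len(centers)
    if n <= 1:
        centers %= L
        return
    four_r2 = (2.0 * R) ** 2
    for _ in range(n_sweeps):
        moves = rng.uniform(-step, step, size=(n, 3))
        order = rng.permutation(n)
        for i in order:
            trial = (centers[i] + moves[i]) % L
            diff = centers - trial
            diff -= L * np.round(diff / L)
            d2 = (diff**2).sum(axis=1)
            d2[i] = np.inf
            if d2.min() >= four_r2:
                centers[i] = trial
    centers %= L


def _random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrices via unit quaternions, shape (n, 3, 3)."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - w * z)
    R[:, 0, 2] = 2 * (x * z + w * y)
    R[:, 1, 0] = 2 * (x * y + w * z)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - w * x)
    R[:, 2, 0] = 2 * (x * z - w * y)
    R[:, 2, 1] = 2 * (y * z + w * x)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def _wilson_upper(successes: int, trials: int, z: float = 1.959964) -> float:
    n = trials
    p = successes / n
    denom = 1.0 + z**2 / n
    centre = p + z**2 / (2 * n)
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
    return (centre + half) / denom


def insertion_probability(
    structure: AtomisticStructure,
    boxes: list[CrowderBox],
    n_trials: int = 10_000,
    seed: int = 0,
    chunk: int = 4096,
) -> InsertionEstimate:
    """Particle-insertion Monte Carlo estimate of f and βΔμ = −ln f.

    For each of ``n_trials`` trials *per box*, the structure is placed at a
    uniform random position with a uniform random orientation; the trial
    succeeds iff every atom clears every crowder centre by its hard-core
    radius plus R_c (minimum-image convention). Results are pooled over boxes.
    """
    if not boxes:
        raise ValueError("at least one crowder box is required")
    if n_trials < 1_000:
        raise ValueError("n_trials must be >= 1000")
    if not structure.has_radii:
        raise ValueError("assign radii before insertion")
    coords0 = structure.coords - structure.coords.mean(axis=0)
    radii = structure.radii
    bounding = np.linalg.norm(coords0, axis=1).max() + radii.max()
    rng = np.random.default_rng(seed)
    per_box_f = []
    total_succ = 0
    for box in boxes:
        L = box.box_length
        if 2.0 * bounding + 2.0 * box.R_c > L:
            raise ValueError(
                "structure (plus crowder radius) does not fit in the box"
            )
        if box.n_crowders == 0:
            per_box_f.append(1.0)
            total_succ += n_trials
            continue
        tree = cKDTree(box.centers % L, boxsize=L)
        clearance = radii + box.R_c
        succ = 0
        done = 0
        while done < n_trials:
            m = min(chunk, n_trials - done)
            rot = _random_rotations(m, rng)
            pos = rng.uniform(0.0, L, size=(m, 3))
            pts = np.einsum("nij,aj->nai", rot, coords0) + pos[:, None, :]
            d, _ = tree.query((pts % L).reshape(-1, 3), k=1, workers=-1)
            ok = (d.reshape(m, -1) >= clearance[None, :]).all(axis=1)
            succ += int(ok.sum())
            done += m
        per_box_f.append(succ / n_trials)
        total_succ += succ
    trials = n_trials * len(boxes)
    f = total_succ / trials
    se_binom = math.sqrt(max(f * (1.0 - f), 0.0) / trials)
    if len(boxes) > 1:
        se_boxes = float(np.std(per_box_f, ddof=1) / math.sqrt(len(boxes)))
    else:
        se_boxes = 0.0
    stderr = max(se_binom, se_boxes)
    if total_succ > 0:
        return InsertionEstimate(trials, total_succ, f, stderr, -math.log(f))
    f_up = _wilson_upper(0, trials)
    return InsertionEstimate(
        trials, 0, 0.0, stderr, -math.log(f_up), is_lower_bound=True
    )


def spt_delta_mu_sphere(r: float, model: CrowderModel) -> float:
    """Scaled-particle-theory insertion free energy (k_BT) of a hard sphere
    of radius ``r`` into the hard-sphere crowder fluid.

    With q = φ/(1−φ) and x = r/R_c:
    βΔμ = −ln(1−φ) + 3qx + (3q + 4.5q²)x² + φ(1+φ+φ²)/(1−φ)³ x³.
    """
    if r < 0:
        raise ValueError("solute radius must be >= 0")
    phi = model.phi
    if phi == 0.0:
        return 0.0
    q = phi / (1.0 - phi)
    x = r / model.R_c
    cubic = phi * (1.0 + phi + phi**2) / (1.0 - phi) ** 3
    return (
        -math.log(1.0 - phi)
        + 3.0 * q * x
        + (3.0 * q + 4.5 * q**2) * x**2
        + cubic * x**3
    )


def gfmt_delta_mu(measures: GeometricMeasures, model: CrowderModel) -> float:
    """Generalized fundamental-measure prediction of βΔμ (k_BT).

    Linear in the exclusion-surface measures, with coefficients fixed by the
    crowder fluid's scaled-particle equation of state:

    βΔμ = −ln(1−φ) + 3q (l_p/R_c) + (3q + 4.5q²) (s_p/4πR_c²)
          + ρ(1+φ+φ²)/(1−φ)³ · v_p

    For sphere measures this reduces exactly to :func:`spt_delta_mu_sphere`.
    The measures must have been computed at probe radius R_c.
    """
    if (
        measures.probe_radius is not None
        and abs(measures.probe_radius - model.R_c) > 1e-9
    ):
        raise ValueError(
            f"measures were computed at probe radius {measures.probe_radius} Å, "
            f"but the crowder radius is {model.R_c} Å"
        )
    phi = model.phi
    if phi == 0.0:
        return 0.0
    q = phi / (1.0 - phi)
    R = model.R_c
    return (
        -math.log(1.0 - phi)
        + 3.0 * q * (measures.l_p / R)
        + (3.0 * q + 4.5 * q**2) * (measures.s_p / (4.0 * math.pi * R**2))
        + model.rho * (1.0 + phi + phi**2) / (1.0 - phi) ** 3 * measures.v_p
    )


def save_crowder_box(box: CrowderBox, path: str) -> None:
    """Write a box as whitespace-delimited text (header: L, R_c, N, seed)."""
    with open(path, "w") as fh:
        fh.write(
            f"# crowder_box L={box.box_length:.6f} R_c={box.R_c:.6f} "
            f"N={box.n_crowders} seed={box.seed}\n"
        )
        for c in box.centers:
            fh.write(f"{c[0]:.6f} {c[1]:.6f} {c[2]:.6f}\n")


def load_crowder_box(path: str) -> CrowderBox:
    with open(path) as fh:
        header = fh.readline()
        fields = dict(
            kv.split("=") for kv in header.replace("#", "").split() if "=" in kv
        )
        centers = np.loadtxt(fh, ndmin=2) if fields.get("N") != "0" else np.empty((0, 3))
    seed = fields.get("seed")
    return CrowderBox(
        box_length=float(fields["L"]),
        centers=centers,
        R_c=float(fields["R_c"]),
        seed=None if seed in (None, "None") else int(seed),
    )
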