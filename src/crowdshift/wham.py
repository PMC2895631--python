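"""Umbrella-sampling analysis: WHAM, crowding-weighted WHAM, bootstrap, barriers.

The potential of mean force W(x) along a reaction coordinate x is recovered
from harmonically biased windows by iterating the WHAM equations

    P(x_j) = Σ_i n_i(x_j) / Σ_i N_i C_i⁻¹ exp(−U_i(x_j)/k_BT)
    C_i    = Σ_j exp(−U_i(x_j)/k_BT) P(x_j)

to self-consistency. Crowding enters by reweighting: each sampled
conformation carries a statistical weight f (its insertion probability into
the crowded solution); N_i and n_i(x_j) become sums of f instead of counts.
If f depends on x only, the crowded profile is the dilute one shifted by
βΔμ(x) up to a constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .thermo import kt_in_kcal_per_mol

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "WHAMConvergenceError",
    "solve_wham",
    "crowded_pmf",
    "bootstrap_pmf",
    "barrier_shift",
    "write_window",
    "read_window",
    "write_pmf",
]


class WHAMConvergenceError(RuntimeError):
    """WHAM iteration did not reach tolerance within max_iter."""


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic bias ½k(x − x₀)² and its samples.

    ``force_constant`` is in kcal/mol/Å² (converted to k_BT/Å² at solve
    time); ``weights``, if present, are per-sample crowding weights f > 0.
    """

    center: float
    force_constant: float
    samples: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size == 0:
            raise ValueError("window has no samples")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float).ravel()
            if self.weights.shape != self.samples.shape:
                raise ValueError("weights must match samples in length")
            if np.any(~np.isfinite(self.weights)) or np.any(self.weights <= 0):
                raise ValueError("weights must be positive and finite")

    def with_samples(
        self, samples: np.ndarray, weights: np.ndarray | None = None
    ) -> "UmbrellaWindow":
        return UmbrellaWindow(self.center, self.force_constant, samples, weights)


@dataclass
class PMFProfile:
    """Binned PMF: W(x_j) in k_BT (min-shifted to 0) and normalized P(x_j).

    Bins never visited are gaps: W and P are NaN there. ``errors`` holds
    per-bin bootstrap standard deviations when computed.
    """

    bin_centers: np.ndarray
    w: np.ndarray
    p: np.ndarray
    bin_width: float
    errors: np.ndarray | None = None
    condition_label: str = "dilute"

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.w)


def _default_bins(windows: list[UmbrellaWindow], bin_width: float = 0.1) -> np.ndarray:
    lo = min(w.center for w in windows) - 1.0
    hi = max(w.center for w in windows) + 1.0
    n = int(round((hi - lo) / bin_width))
    return lo + bin_width * np.arange(n + 1)


def solve_wham(
    windows: list[UmbrellaWindow],
    bins: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    temperature: float = 300.0,
    condition_label: str = "dilute",
) -> PMFProfile:
    """Iterate the WHAM equations to convergence and return the PMF.

    ``bins`` are edges (half-open [lo, hi) bins); default 0.1 Å bins over
    [min window centre − 1 Å, max + 1 Å]. Convergence is max_j |Δ ln P(x_j)|
    < tol over occupied bins. Per-sample weights, when present on the
    windows, replace unit counts in N_i and n_i(x_j).
    """
    if not windows:
        raise ValueError("need at least one window")
    edges = _default_bins(windows) if bins is None else np.asarray(bins, float)
    if edges.size < 2:
        raise ValueError("bin grid must contain at least one bin")
    width = float(edges[1] - edges[0])
    centers = 0.5 * (edges[:-1] + edges[1:])
    kt = kt_in_kcal_per_mol(temperature)

    n_win, n_bin = len(windows), centers.size
    counts = np.zeros((n_win, n_bin))
    N = np.zeros(n_win)
    for i, w in enumerate(windows):
        wts = np.ones_like(w.samples) if w.weights is None else w.weights
        idx = np.floor((w.samples - edges[0]) / width).astype(int)
        ok = (idx >= 0) & (idx < n_bin)
        np.add.at(counts[i], idx[ok], wts[ok])
        N[i] = wts.sum()
    numerator = counts.sum(axis=0)
    occupied = numerator > 0
    if not np.any(occupied):
        raise ValueError("no samples fall inside the bin range")

    k_kt = np.array([w.force_constant for w in windows]) / kt  # k_BT/Å²
    x0 = np.array([w.center for w in windows])
    bias = 0.5 * k_kt[:, None] * (centers[None, :] - x0[:, None]) ** 2
    boltz = np.exp(-bias)  # (n_win, n_bin)

    p = np.where(occupied, numerator, 0.0)
    p /= p.sum()
    ln_p_prev = np.log(np.where(occupied, p, np.nan))
    for _ in range(max_iter):
        C = boltz[:, occupied] @ p[occupied]
        denom = (N / C) @ boltz
        p = np.where(occupied & (denom > 0), numerator / np.where(denom > 0, denom, 1.0), 0.0)
        p /= p.sum()
        ln_p = np.log(np.where(occupied, p, np.nan))
        resid = np.nanmax(np.abs(ln_p - ln_p_prev))
        ln_p_prev = ln_p
        if resid < tol:
            break
    else:
        raise WHAMConvergenceError(
            f"WHAM did not converge in {max_iter} iterations (residual {resid:.2e})"
        )
    p_density = np.where(occupied, p / (p.sum() * width), np.nan)
    w_vals = -np.log(p_density)
    w_vals -= np.nanmin(w_vals)
    return PMFProfile(
        bin_centers=centers,
        w=w_vals,
        p=p_density,
        bin_width=width,
        condition_label=condition_label,
    )


def crowded_pmf(
    windows: list[UmbrellaWindow],
    f_of_sample: list[np.ndarray] | None = None,
    bins: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    temperature: float = 300.0,
    condition_label: str = "crowded",
) -> PMFProfile:
    """Crowding-reweighted PMF: per-sample insertion probabilities f replace
    unit counts in the WHAM sums.

    ``f_of_sample`` supplies one positive weight array per window; if omitted
    the windows must already carry weights.
    """
    weighted = []
    for i, w in enumerate(windows):
        if f_of_sample is not None:
            wts = np.asarray(f_of_sample[i], dtype=float)
        elif w.weights is not None:
            wts = w.weights
        else:
            raise ValueError(f"window {i} has no crowding weights")
        if np.any(~np.isfinite(wts)) or np.any(wts <= 0):
            raise ValueError("crowding weights must be positive and finite")
        weighted.append(w.with_samples(w.samples, wts))
    return solve_wham(
        weighted, bins=bins, tol=tol, max_iter=max_iter,
        temperature=temperature, condition_label=condition_label,
    )


def bootstrap_pmf(
    windows: list[UmbrellaWindow],
    bins: np.ndarray | None = None,
    n_boot: int = 50,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    temperature: float = 300.0,
) -> np.ndarray:
    """Per-bin bootstrap SD of W: resample each window's samples with
    replacement, re-solve, and take the SD over replicas (NaN-aware)."""
    if n_boot < 20:
        raise ValueError("n_boot must be >= 20")
    for w in windows:
        if w.samples.size < 2:
            raise ValueError("each window needs at least 2 samples to bootstrap")
    edges = _default_bins(windows) if bins is None else np.asarray(bins, float)
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        resampled = []
        for w in windows:
            idx = rng.integers(0, w.samples.size, size=w.samples.size)
            wts = None if w.weights is None else w.weights[idx]
            resampled.append(w.with_samples(w.samples[idx], wts))
        prof = solve_wham(
            resampled, bins=edges, tol=tol, max_iter=max_iter,
            temperature=temperature,
        )
        reps.append(prof.w)
    reps = np.asarray(reps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN gap bins
        return np.nanstd(reps, axis=0, ddof=1)


def _basin_min(profile: PMFProfile, lo: float, hi: float) -> int:
    sel = (profile.bin_centers >= lo) & (profile.bin_centers <= hi) & profile.occupied
    if not np.any(sel):
        raise ValueError(f"basin [{lo}, {hi}] contains no occupied bins")
    idx = np.flatnonzero(sel)
    return int(idx[np.argmin(profile.w[idx])])


def barrier_shift(
    dilute: PMFProfile,
    crowded: PMFProfile,
    basin_a: tuple[float, float],
    basin_b: tuple[float, float],
) -> tuple[float, float]:
    """Crowding-induced changes of the two barrier heights (k_BT).

    For each profile the barrier is the maximum of W between the two basin
    minima minus the departing basin's minimum; returns (Δbarrier a→b,
    Δbarrier b→a) = crowded − dilute.
    """
    if dilute.bin_centers.shape != crowded.bin_centers.shape or not np.allclose(
        dilute.bin_centers, crowded.bin_centers
    ):
        raise ValueError("profiles must share the same bins")

    def barriers(profile: PMFProfile) -> tuple[float, float]:
        ia = _basin_min(profile, *basin_a)
        ib = _basin_min(profile, *basin_b)
        lo, hi = sorted((ia, ib))
        if hi - lo < 2:
            raise ValueError("no interior bins between the basin minima")
        interior = profile.w[lo + 1 : hi]
        if np.all(np.isnan(interior)):
            raise ValueError("no occupied interior bins between the basins")
        top = np.nanmax(interior)
        if top <= max(profile.w[ia], profile.w[ib]):
            raise ValueError("no interior maximum between the basin minima")
        return top - profile.w[ia], top - profile.w[ib]

    d_ab, d_ba = barriers(dilute)
    c_ab, c_ba = barriers(crowded)
    return c_ab - d_ab, c_ba - d_ba


def write_window(window: UmbrellaWindow, path: str) -> None:
    """One file per window: header with centre and force constant, then one
    sample per line (optional second column: crowding weight)."""
    with open(path, "w") as fh:
        fh.write(
            f"# center={window.center:.6f} force_constant={window.force_constant:.6f}\n"
        )
        if window.weights is None:
            for x in window.samples:
                fh.write(f"{x:.6f}\n")
        else:
            for x, w in zip(window.samples, window.weights):
                fh.write(f"{x:.6f} {w:.8e}\n")


def read_window(path: str) -> UmbrellaWindow:
    with open(path) as fh:
        header = fh.readline()
        fields = dict(
            kv.split("=") for kv in header.replace("#", "").split() if "=" in kv
        )
        data = np.loadtxt(fh, ndmin=2)
    weights = data[:, 1] if data.shape[1] > 1 else None
    return UmbrellaWindow(
        center=float(fields["center"]),
        force_constant=float(fields["force_constant"]),
        samples=data[:, 0],
        weights=weights,
    )


def write_pmf(profile: PMFProfile, path: str) -> None:
    """Delimited text: bin centre, W (k_BT), bootstrap SD (NaN if absent)."""
    err = (
        profile.errors
        if profile.errors is not None
        else np.full_like(profile.w, np.nan)
    )
    with open(path, "w") as fh:
        fh.write(f"# condition={profile.condition_label}\n")
        fh.write("# x\tW_kT\tsd_kT\n")
        for x, w, e in zip(profile.bin_centers, profile.w, err):
            fh.write(f"{x:.4f}\t{w:.6f}\t{e:.6f}\n")
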