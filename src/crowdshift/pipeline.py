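"""End-to-end analyses: the equilibrium crowding scan and the PMF reweighting.

``run_equilibrium`` takes open and closed conformational ensembles, computes
the crowder-exclusion measures of every conformation at each crowder radius,
predicts per-conformation βΔμ (fundamental-measure route, optionally
cross-checked by insertion MC), Boltzmann-averages within each state, and
reports βΔΔG and κ on the full (R_c, φ) grid. Measures depend on R_c only,
so the φ grid is free once the surfaces are built.

``run_pmf`` solves the dilute and crowding-reweighted PMFs on common bins,
extracts the barrier changes between two configured basins, and attaches
bootstrap errors.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crowders, surface, thermo, wham
from .structure import (
    ConformationalEnsemble,
    assign_radii,
    common_residue_filter,
    radius_of_gyration,
    read_ensemble,
)
from .synthetic import (
    TwoStateToySpec,
    crowding_weights_from_truth,
    make_two_state_ensembles,
)

__all__ = [
    "RunConfig",
    "run_equilibrium",
    "run_pmf",
    "ensemble_measure_table",
]

logger = logging.getLogger("crowdshift")

DEFAULT_RC_GRID = (15.0, 20.0, 30.0, 50.0)
DEFAULT_PHI_GRID = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35)


@dataclass
class RunConfig:
    """Resolved configuration of one analysis run.

    Ensembles come either from multi-model PDB files (``open_pdb`` /
    ``closed_pdb``) or from the synthetic two-state generator
    (``synthetic``). The crowding grid defaults to crowder radii
    15–50 Å and volume fractions 5–35%.
    """

    open_pdb: str | None = None
    closed_pdb: str | None = None
    synthetic: TwoStateToySpec | None = None
    r_c_grid: tuple[float, ...] = DEFAULT_RC_GRID
    phi_grid: tuple[float, ...] = DEFAULT_PHI_GRID
    method: str = "gfmt"  # gfmt | insertion | both
    grid_spacing: float = 0.5
    insertion_boxes: int = 10
    insertion_trials: int = 20_000
    insertion_box_factor: float = 8.0  # box length in units of R_c
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.method not in ("gfmt", "insertion", "both"):
            raise ValueError("method must be gfmt, insertion or both")
        if not self.r_c_grid or not self.phi_grid:
            raise ValueError("crowding grid must be non-empty")
        has_pdb = self.open_pdb is not None and self.closed_pdb is not None
        if not has_pdb and self.synthetic is None:
            raise ValueError("provide open/closed PDB paths or a synthetic spec")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = TwoStateToySpec(**raw["synthetic"])
        for key in ("r_c_grid", "phi_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=True)


def _load_ensembles(
    config: RunConfig,
) -> tuple[ConformationalEnsemble, ConformationalEnsemble]:
    if config.synthetic is not None:
        return make_two_state_ensembles(config.synthetic)
    open_text = Path(config.open_pdb).read_text()
    closed_text = Path(config.closed_pdb).read_text()
    open_ens = read_ensemble(open_text, state_label="open")
    closed_ens = read_ensemble(closed_text, state_label="closed")
    open_ens = ConformationalEnsemble(
        [assign_radii(c) for c in open_ens], state_label="open"
    )
    closed_ens = ConformationalEnsemble(
        [assign_radii(c) for c in closed_ens], state_label="closed"
    )
    return open_ens, closed_ens


def _harmonized(
    open_ens: ConformationalEnsemble, closed_ens: ConformationalEnsemble
) -> tuple[ConformationalEnsemble, ConformationalEnsemble]:
    o0, c0 = common_residue_filter(open_ens.conformations[0], closed_ens.conformations[0])
    if o0.n_atoms == open_ens.conformations[0].n_atoms and c0.n_atoms == closed_ens.conformations[0].n_atoms:
        return open_ens, closed_ens
    new_open, new_closed = [], []
    for oc in open_ens:
        fo, _ = common_residue_filter(oc, closed_ens.conformations[0])
        new_open.append(fo)
    for cc in closed_ens:
        _, fc = common_residue_filter(open_ens.conformations[0], cc)
        new_closed.append(fc)
    return (
        ConformationalEnsemble(new_open, state_label=open_ens.state_label),
        ConformationalEnsemble(new_closed, state_label=closed_ens.state_label),
    )


def ensemble_measure_table(
    ensemble: ConformationalEnsemble,
    r_c_values,
    grid_spacing: float = 0.5,
    sasa_probe: float = 1.4,
) -> pd.DataFrame:
    """Per-conformation geometric report: v_p, s_p, l_p per R_c, plus SASA
    and R_g (one row per conformation and crowder radius)."""
    rows = []
    for i, conf in enumerate(ensemble):
        area = surface.sasa(conf, probe_radius=sasa_probe)
        rg = radius_of_gyration(conf)
        for r_c in r_c_values:
            m = surface.exclusion_measures(conf, r_c, grid_spacing=grid_spacing)
            rows.append(
                {
                    "state": ensemble.state_label,
                    "conformation": i,
                    "R_c": r_c,
                    "v_p": m.v_p,
                    "s_p": m.s_p,
                    "l_p": m.l_p,
                    "sasa": area,
                    "R_g": rg,
                }
            )
    return pd.DataFrame(rows)


def _per_state_mu(
    ensemble: ConformationalEnsemble,
    model: crowders.CrowderModel,
    measure_cache: dict[tuple[str, int, float], surface.GeometricMeasures],
    grid_spacing: float,
) -> thermo.StateChemicalPotential:
    vals = []
    for i, conf in enumerate(ensemble):
        key = (ensemble.state_label, i, model.R_c)
        if key not in measure_cache:
            measure_cache[key] = surface.exclusion_measures(
                conf, model.R_c, grid_spacing=grid_spacing
            )
        vals.append(crowders.gfmt_delta_mu(measure_cache[key], model))
    return thermo.state_chemical_potential(vals, state_label=ensemble.state_label)


def run_equilibrium(config: RunConfig) -> pd.DataFrame:
    """Equilibrium crowding scan; one row per (R_c, φ) grid point.

    Columns: method, R_c, phi, beta_dmu_open, beta_dmu_closed, beta_ddg,
    kappa, fold_change, percent_reduction (plus MC columns when the
    insertion cross-check runs). Deterministic for a fixed config and seed.
    """
    open_ens, closed_ens = _load_ensembles(config)
    open_ens, closed_ens = _harmonized(open_ens, closed_ens)
    if open_ens.conformations[0].n_atoms == 0:
        raise ValueError("no atoms left after residue harmonization")
    logger.info(
        "equilibrium scan: %d open / %d closed conformations, %d grid points",
        len(open_ens), len(closed_ens), len(config.r_c_grid) * len(config.phi_grid),
    )
    cache: dict[tuple[str, int, float], surface.GeometricMeasures] = {}
    rows = []
    rng_seed = np.random.SeedSequence(config.seed)
    for r_c in config.r_c_grid:
        for phi in config.phi_grid:
            model = crowders.CrowderModel(R_c=r_c, phi=phi)
            if config.method in ("gfmt", "both"):
                mu_o = _per_state_mu(open_ens, model, cache, config.grid_spacing)
                mu_c = _per_state_mu(closed_ens, model, cache, config.grid_spacing)
                ddg = thermo.delta_delta_g(mu_o.beta_delta_mu, mu_c.beta_delta_mu)
                eff = thermo.population_ratio_change(ddg)
                rows.append(
                    {
                        "method": "gfmt",
                        "R_c": r_c,
                        "phi": phi,
                        "beta_dmu_open": mu_o.beta_delta_mu,
                        "beta_dmu_closed": mu_c.beta_delta_mu,
                        "beta_ddg": ddg,
                        "kappa": eff.kappa,
                        "fold_change": eff.fold_change,
                        "percent_reduction": eff.percent_reduction,
                    }
                )
            if config.method in ("insertion", "both"):
                rows.append(
                    _insertion_row(open_ens, closed_ens, model, config, rng_seed)
                )
    report = pd.DataFrame(rows)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "equilibrium.tsv", sep="\t", index=False)
        (out / "config.yaml").write_text(config.to_yaml())
    return report


def _insertion_row(
    open_ens: ConformationalEnsemble,
    closed_ens: ConformationalEnsemble,
    model: crowders.CrowderModel,
    config: RunConfig,
    seed_seq: np.random.SeedSequence,
) -> dict:
    box_len = config.insertion_box_factor * model.R_c
    child = seed_seq.spawn(1)[0]
    seeds = child.generate_state(2 * config.insertion_boxes + 2) % (2**31)
    boxes = [
        crowders.build_crowder_box(model, box_len, seed=int(seeds[k]))
        for k in range(config.insertion_boxes)
    ]

    def state_estimate(ens: ConformationalEnsemble, offset: int):
        # pool per-conformation f values (equal conformation weights)
        fs, errs = [], []
        for i, conf in enumerate(ens):
            est = crowders.insertion_probability(
                conf, boxes, n_trials=config.insertion_trials,
                seed=int(seeds[config.insertion_boxes + offset] + i),
            )
            fs.append(est.f)
            errs.append(est.stderr_f)
        f_mean = float(np.mean(fs))
        err = float(np.sqrt(np.sum(np.square(errs))) / len(fs))
        return f_mean, err

    f_o, se_o = state_estimate(open_ens, 0)
    f_c, se_c = state_estimate(closed_ens, 1)
    row = {"method": "insertion", "R_c": model.R_c, "phi": model.phi,
           "f_open": f_o, "f_open_se": se_o, "f_closed": f_c, "f_closed_se": se_c}
    if f_o > 0 and f_c > 0:
        ddg = -np.log(f_o) + np.log(f_c)
        eff = thermo.population_ratio_change(ddg)
        # first-order error propagation through kappa = f_o/f_c - 1
        ratio = f_o / f_c
        kappa_se = ratio * np.sqrt((se_o / f_o) ** 2 + (se_c / f_c) ** 2)
        row.update(
            beta_dmu_open=-np.log(f_o), beta_dmu_closed=-np.log(f_c),
            beta_ddg=ddg, kappa=eff.kappa, kappa_se=float(kappa_se),
            fold_change=eff.fold_change, percent_reduction=eff.percent_reduction,
        )
    return row


def run_pmf(
    windows: list[wham.UmbrellaWindow],
    beta_dmu_of_x=None,
    weights: list[np.ndarray] | None = None,
    bins: np.ndarray | None = None,
    basin_a: tuple[float, float] = (11.5, 14.5),
    basin_b: tuple[float, float] = (18.0, 21.0),
    n_boot: int = 50,
    seed: int = 0,
    temperature: float = 300.0,
    output_dir: str | None = None,
) -> dict:
    """Dilute + crowded PMFs on common bins, barrier shifts, bootstrap errors.

    Crowding weights come either from ``weights`` (one positive array per
    window, e.g. precomputed insertion probabilities) or from a βΔμ(x)
    function applied to every sample. Returns a dict with keys ``dilute``,
    ``crowded``, ``barrier_shift_ab``, ``barrier_shift_ba``.
    """
    if bins is None:
        bins = wham._default_bins(windows)
    dilute = wham.solve_wham(windows, bins=bins, temperature=temperature)
    dilute.errors = wham.bootstrap_pmf(
        windows, bins=bins, n_boot=n_boot, seed=seed, temperature=temperature
    )
    if weights is None:
        if beta_dmu_of_x is None:
            raise ValueError("crowded PMF requested without weights or βΔμ(x)")
        wted = crowding_weights_from_truth(windows, beta_dmu_of_x)
    else:
        wted = [w.with_samples(w.samples, np.asarray(f)) for w, f in zip(windows, weights)]
    crowded = wham.crowded_pmf(wted, bins=bins, temperature=temperature)
    crowded.errors = wham.bootstrap_pmf(
        wted, bins=bins, n_boot=n_boot, seed=seed + 1, temperature=temperature
    )
    shift_ab, shift_ba = wham.barrier_shift(dilute, crowded, basin_a, basin_b)
    result = {
        "dilute": dilute,
        "crowded": crowded,
        "barrier_shift_ab": shift_ab,
        "barrier_shift_ba": shift_ba,
    }
    if output_dir:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        wham.write_pmf(dilute, str(out / "pmf_dilute.tsv"))
        wham.write_pmf(crowded, str(out / "pmf_crowded.tsv"))
        (out / "barrier_shifts.tsv").write_text(
            "direction\tdelta_barrier_kT\n"
            f"a_to_b\t{shift_ab:.6f}\nb_to_a\t{shift_ba:.6f}\n"
        )
    return result
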