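"""Seed-reproducible synthetic otolith growth datasets with known truth.

The generator emulates the statistical structure the back-calculation and
growth analyses assume:

* a per-species power-law proportionality between body length and otolith
  radius, ``L = L_0p - b R_0p^c + b R^c``, anchored at the hatching point
  (``L_0p``, ``R_0p``);
* individual von Bertalanffy growth trajectories whose parameters scatter
  around population values (``L_inf`` normal, ``K`` lognormal), with the
  hatch constraint ``L(0) = L_0p`` fixing each fish's ``t_0``;
* integer ages at capture, Gaussian observation noise on the measured capture
  length, and missing-at-random hatch radii.

Because the otolith-length coupling is generated exactly under the
proportional model, back-calculating with the generative parameters must
reproduce the true lengths-at-age — the closure oracle used throughout the
test suite.  The full ground truth (per-fish growth parameters, true lengths
and radii at every age, masked hatch radii) is retained alongside the emitted
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from .data_model import RESULT_COLUMNS, GrowthDataset, IndividualSample

_MAX_REDRAWS = 100


class SimulationConfig(BaseModel, frozen=True):
    """Study conditions for one synthetic dataset.

    Defaults describe a typical mid-sized reef-fish species: hatch length of a
    few millimetres, hatch otolith radius of a few hundredths of a millimetre,
    asymptotic length 400 mm, growth coefficient 0.4 / yr, moderate
    among-individual heterogeneity, 5 mm measurement noise on capture length
    and 30% unreadable hatch radii.
    """

    n_species: int = 2
    n_individuals_per_species: int = 20
    true_b: float = 200.0        # mm · mm^-c
    true_c: float = 1.0
    length_0p: float = 2.5       # mm
    r0p_mean: float = 0.05       # mm
    r0p_sd: float = 0.012        # mm
    pop_linf: float = 400.0      # mm
    pop_k: float = 0.4           # 1 / yr
    sd_linf: float = 30.0        # mm, among-individual sd of L_inf
    sd_logk: float = 0.15        # among-individual sd of log K
    sigma_length: float = 5.0    # mm, observation noise on capture length
    missing_r0p_rate: float = 0.3
    max_age: int = 12            # yr
    radius_noise_cv: float = 0.0  # optional multiplicative noise on radii
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.true_b <= 0 or self.true_c <= 0:
            raise ValueError("true_b and true_c must be positive")
        if not 0 <= self.missing_r0p_rate < 1:
            raise ValueError("missing_r0p_rate must lie in [0, 1)")
        if self.pop_linf <= self.length_0p:
            raise ValueError("pop_linf must exceed length_0p")
        if self.max_age < 3:
            raise ValueError("max_age must be at least 3")
        return self


@dataclass
class IndividualTruth:
    individual_id: str
    linf: float
    k: float
    t0: float
    r0p: float                     # true hatch radius, even when masked
    ages: np.ndarray               # 0..age_cpt
    true_lengths: np.ndarray       # mm, noise-free
    true_radii: np.ndarray         # mm, noise-free
    r0p_masked: bool = False


@dataclass
class SimulationTruth:
    """Ground truth aligned one-to-one with the emitted dataset."""

    true_b: float
    true_c: float
    individuals: dict[str, IndividualTruth] = field(default_factory=dict)

    def masked_ids(self) -> list[str]:
        return sorted(i for i, t in self.individuals.items() if t.r0p_masked)

    def frame(self) -> pd.DataFrame:
        rows = []
        for t in self.individuals.values():
            for age, L, R in zip(t.ages, t.true_lengths, t.true_radii):
                rows.append(
                    dict(
                        ID=t.individual_id, Age_i=int(age), true_L=L, true_R=R,
                        linf=t.linf, k=t.k, t0=t.t0, r0p=t.r0p,
                        r0p_masked=t.r0p_masked, true_b=self.true_b,
                        true_c=self.true_c,
                    )
                )
        return pd.DataFrame(rows)


def vb_length_scalar(t, linf, k, t0):
    return linf * (1.0 - np.exp(-k * (t - t0)))


def radius_from_length(L, length_0p, b, c, r0p):
    """Invert the proportional model for the otolith radius at body length L."""
    return ((L - length_0p) / b + r0p**c) ** (1.0 / c)


def simulate_individual(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    *,
    individual_id: str,
    species: tuple[str, str, str],
    location: str = "Alona",
) -> tuple[IndividualSample, pd.DataFrame, IndividualTruth]:
    """Draw one fish: growth parameters, trajectory, otolith radii, capture obs.

    ``t_0`` is set from the hatch constraint ``L(0) = length_0p``, i.e.
    ``t0 = ln(1 - length_0p / linf) / k`` (slightly negative).
    """
    family, genus, sp = species
    for _ in range(_MAX_REDRAWS):
        linf = rng.normal(cfg.pop_linf, cfg.sd_linf)
        if linf > max(2.0 * cfg.length_0p, 0.05 * cfg.pop_linf):
            break
    else:
        raise RuntimeError("could not draw L_inf above the hatch length")
    k = cfg.pop_k * np.exp(rng.normal(0.0, cfg.sd_logk))
    t0 = np.log(1.0 - cfg.length_0p / linf) / k

    for _ in range(_MAX_REDRAWS):
        r0p = rng.normal(cfg.r0p_mean, cfg.r0p_sd)
        if r0p > 0:
            break
    else:
        raise RuntimeError("could not draw a positive hatch radius")

    age_cpt = int(rng.integers(2, cfg.max_age + 1))
    ages = np.arange(age_cpt + 1)
    true_L = vb_length_scalar(ages, linf, k, t0)
    true_R = radius_from_length(true_L, cfg.length_0p, cfg.true_b, cfg.true_c, r0p)
    radii = true_R.copy()
    if cfg.radius_noise_cv > 0:
        noise = np.exp(rng.normal(0.0, cfg.radius_noise_cv, size=len(radii) - 2))
        radii[1:-1] = radii[1:-1] * noise  # keep hatch and capture anchors exact
        radii = np.maximum.accumulate(radii)  # preserve monotonicity

    length_cpt = true_L[-1] + rng.normal(0.0, cfg.sigma_length)
    length_cpt = max(length_cpt, cfg.length_0p * 1.01)

    sample = IndividualSample(
        individual_id=individual_id,
        family=family,
        genus=genus,
        species=sp,
        location=location,
        age_cpt=age_cpt,
        radius_cpt=float(radii[-1]),
        length_cpt=float(length_cpt),
        length_0p=cfg.length_0p,
        radius_0p=float(radii[0]),
        weight=None,
        observer="sim",
    )
    inc = pd.DataFrame({"ID": individual_id, "Age_i": ages, "R_i": radii})
    truth = IndividualTruth(
        individual_id=individual_id, linf=float(linf), k=float(k), t0=float(t0),
        r0p=float(radii[0]), ages=ages, true_lengths=true_L, true_radii=true_R,
    )
    return sample, inc, truth


_FAMILIES = ["Acanthuridae", "Scaridae", "Serranidae", "Lethrinidae", "Mullidae"]
_GENERA = ["Ctenochaetus", "Chlorurus", "Epinephelus", "Lethrinus", "Mulloidichthys"]


def simulate_dataset(cfg: SimulationConfig) -> tuple[GrowthDataset, SimulationTruth]:
    """Generate a full dataset of ``n_species x n_individuals_per_species`` fish.

    The output passes dataset validation with an empty report and is
    byte-identical across runs with the same config (the seed is part of the
    config).  Hatch-radius missingness is applied at ``missing_r0p_rate``
    subject to every species keeping at least two known hatch radii.
    """
    rng = np.random.default_rng(cfg.seed)
    ind_rows: list[dict] = []
    inc_frames: list[pd.DataFrame] = []
    truth = SimulationTruth(true_b=cfg.true_b, true_c=cfg.true_c)

    for s in range(cfg.n_species):
        family = _FAMILIES[s % len(_FAMILIES)]
        genus = _GENERA[s % len(_GENERA)]
        spname = f"simulatus{s + 1}"
        for j in range(cfg.n_individuals_per_species):
            iid = f"S{s + 1:02d}F{j + 1:03d}"
            sample, inc, tr = simulate_individual(
                cfg, rng, individual_id=iid, species=(family, genus, spname)
            )
            ind_rows.append(
                dict(
                    ID=iid, Family=sample.family, Genus=sample.genus,
                    Species=sample.species, Age_cpt=sample.age_cpt,
                    R_cpt=sample.radius_cpt, L_cpt=sample.length_cpt,
                    L_0p=sample.length_0p, R_0p=sample.radius_0p,
                    Weight=np.nan, Location=sample.location, Observer="sim",
                )
            )
            inc_frames.append(inc)
            truth.individuals[iid] = tr

    individuals = pd.DataFrame(ind_rows).set_index("ID").sort_index()
    increments = pd.concat(inc_frames, ignore_index=True)
    for col in RESULT_COLUMNS:
        increments[col] = np.nan
    increments = increments.sort_values(["ID", "Age_i"], kind="mergesort").reset_index(
        drop=True
    )
    ds = GrowthDataset(individuals, increments, provenance=f"synthetic seed={cfg.seed}")

    if cfg.missing_r0p_rate > 0:
        ds = apply_missingness(ds, cfg.missing_r0p_rate, rng)
        for iid in ds.individuals.index[ds.individuals["R_0p"].isna()]:
            truth.individuals[str(iid)].r0p_masked = True
    return ds, truth


def apply_missingness(
    ds: GrowthDataset, rate: float, rng: np.random.Generator
) -> GrowthDataset:
    """Mask hatch radii completely at random, keeping >= 2 known per species.

    Masks both ``R_0p`` and the age-0 ``R_i`` of selected fish (they are the
    same measurement).  Raises if the requested rate is incompatible with a
    species keeping two known hatch radii.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0:
        return ds
    out = ds.copy()
    key = out.individuals["Genus"].astype(str) + " " + out.individuals["Species"].astype(str)
    for group in sorted(key.unique()):
        ids = out.individuals.index[key == group]
        known = [i for i in ids if not pd.isna(out.individuals.at[i, "R_0p"])]
        n_known = len(known)
        if n_known < 2:
            raise ValueError(
                f"group {group!r} has {n_known} known hatch radii; cannot keep two"
            )
        # Bernoulli masking per fish, then unmask at random until two known remain
        mask = rng.random(n_known) < rate
        while n_known - int(mask.sum()) < 2:
            masked_idx = np.flatnonzero(mask)
            mask[rng.choice(masked_idx)] = False
        chosen = [iid for iid, m in zip(known, mask) if m]
        for iid in chosen:
            out.individuals.at[iid, "R_0p"] = np.nan
            sel = (out.increments["ID"] == iid) & (out.increments["Age_i"] == 0)
            out.increments.loc[sel, "R_i"] = np.nan
    return out
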