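"""Synthetic reciprocal-transplant common-garden datasets with known truth.

The generator emulates the study design this package analyzes: three
common gardens (MN, IL, OK) each planting the same three source
populations, 20 open-pollinated maternal families per population and 10
individuals per family per garden — 600 trees per garden, 1800 total.

Three layers are simulated:

* **Traits** (generative twin of the variance-partition model): for each
  trait, trait = mu(pop, garden) + block + u_family + e, with family
  effects u ~ N(0, V_g) drawn once per family and shared across gardens
  (the same genotypes are planted everywhere) and e ~ N(0, V_e) per
  individual. Defaults V_g = 0.3, V_e = 0.7 put broad-sense heritability
  at 0.3, in the range typical of field trials.
* **Fitness**: survival ~ Bernoulli(logit^-1(a_g + b.z + s_h x)) and, for
  survivors, final height = c_g + d.z + q.z^2 + h_h x + N(0, sigma),
  where z are the standardized genetic + environmental trait deviations
  and x the standardized initial height. Garden-dependent intercepts a_g
  reproduce the mortality gradient of the field study (hot southern
  garden with the heaviest mortality). The implied Lande-Arnold linear
  gradient of this surface is available analytically via
  :func:`implied_selection_gradients` (1-D Gauss-Hermite reduction).
* **Spectra**: phenomenological leaf reflectance on a 1-nm grid from 340
  to 2500 nm — a sigmoidal red-edge baseline minus Gaussian absorption
  features whose depths are driven by the pigment (531/645 nm), water
  (970/1400/1900 nm) and LMA (broadband NIR) trait values, plus optional
  population-specific offsets (for classifier testing), an optional
  sensor-overlap step at 990 nm (for splice testing), and white noise.
  The model is deliberately non-physical: it exercises splicing, index
  extraction and classification, not radiative transfer.

A single master seed drives everything; per-stage child generators are
derived with :class:`numpy.random.SeedSequence` so stages are individually
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumSet

__all__ = [
    "SimConfig",
    "SimBundle",
    "simulate_families",
    "simulate_fitness",
    "simulate_spectra",
    "simulate_experiment",
    "implied_selection_gradients",
]

GARDENS = ("MN", "IL", "OK")
POPULATIONS = ("MN", "IL", "OK")
DEFAULT_TRAITS = ("ANT", "CCI", "WBI", "R700", "RGR", "LMA", "thickness")


@dataclass
class SimConfig:
    """Generator settings; defaults mirror the field design."""

    gardens: tuple = GARDENS
    populations: tuple = POPULATIONS
    n_families: int = 20            # maternal families per population
    n_per_family: int = 10          # individuals per family per garden
    n_blocks: int = 6
    block_sd: float = 0.1

    traits: tuple = DEFAULT_TRAITS
    V_g: dict = field(default_factory=lambda: {})     # per trait; default 0.3
    V_e: dict = field(default_factory=lambda: {})     # per trait; default 0.7
    pop_trait_offsets: dict = field(default_factory=dict)  # (pop, trait) -> shift

    # fitness surface (coefficients per standardized trait deviation)
    survival_intercept: dict = field(
        default_factory=lambda: {"MN": 1.8, "IL": 2.2, "OK": 0.4}
    )
    survival_beta: dict = field(default_factory=dict)   # trait -> logit/SD
    height_intercept: dict = field(
        default_factory=lambda: {"MN": 60.0, "IL": 80.0, "OK": 70.0}
    )
    height_beta: dict = field(default_factory=lambda: {"RGR": 2.0})  # cm/SD
    height_gamma: dict = field(default_factory=dict)    # cm/SD^2 (quadratic)
    height_resid_sd: float = 10.0
    init_height_mean: float = 30.0
    init_height_sd: float = 5.0
    survival_init_coef: float = 0.3   # logit per SD of initial height
    height_init_coef: float = 2.0     # cm per SD of initial height
    surv_block_sd: float = 0.0
    height_block_sd: float = 0.0

    # spectra
    wl_start: float = 340.0
    wl_stop: float = 2500.0
    wl_step: float = 1.0
    spectral_noise_sd: float = 0.002
    spectral_trait_coupling: float = 1.0  # scales trait-driven feature depths
    sensor_step: float = 0.0          # additive offset for bands >= 990 nm
    pop_spectral_offsets: dict = field(default_factory=dict)
    # pop -> list of (center nm, width nm, amplitude)

    seed: int = 0

    def vg(self, trait: str) -> float:
        return float(self.V_g.get(trait, 0.3))

    def ve(self, trait: str) -> float:
        return float(self.V_e.get(trait, 0.7))


@dataclass
class SimBundle:
    table: pd.DataFrame
    spectra: SpectrumSet | None
    truth: dict


def _child_rngs(seed: int, n: int):
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_families(cfg: SimConfig, rng=None) -> pd.DataFrame:
    """Family-structured trait table across all gardens.

    Family effects are drawn once per (population, family, trait) and reused
    in every garden; blocks are assigned cyclically within garden and add a
    shared N(0, block_sd^2) shift to every trait. The standardized
    genetic+environmental deviation of each trait is kept in hidden
    ``_z_<trait>`` columns so the fitness stage and the implied-gradient
    oracle see exactly the deviations the surface acts on.
    """
    if rng is None:
        rng = _child_rngs(cfg.seed, 3)[0]
    fam_effects = {
        (pop, f, t): rng.normal(0.0, np.sqrt(cfg.vg(t)))
        for pop in cfg.populations
        for f in range(cfg.n_families)
        for t in cfg.traits
    }
    rows = []
    for garden in cfg.gardens:
        block_shift = rng.normal(0.0, cfg.block_sd, size=cfg.n_blocks)
        counter = 0
        for pop in cfg.populations:
            for f in range(cfg.n_families):
                for k in range(cfg.n_per_family):
                    block = counter % cfg.n_blocks
                    counter += 1
                    row = {
                        "id": f"{garden}_{pop}_F{f:02d}_{k:02d}",
                        "garden": garden,
                        "population": pop,
                        "family": f"{pop}_F{f:02d}",
                        "block": f"B{block}",
                        "height_init": rng.normal(cfg.init_height_mean,
                                                  cfg.init_height_sd),
                    }
                    for t in cfg.traits:
                        u = fam_effects[(pop, f, t)]
                        e = rng.normal(0.0, np.sqrt(cfg.ve(t)))
                        z = (u + e) / np.sqrt(cfg.vg(t) + cfg.ve(t))
                        mu = cfg.pop_trait_offsets.get((pop, t), 0.0)
                        row[t] = mu + block_shift[block] + u + e
                        row[f"_z_{t}"] = z
                    rows.append(row)
    return pd.DataFrame(rows)


def simulate_fitness(table: pd.DataFrame, cfg: SimConfig,
                     rng=None) -> pd.DataFrame:
    """Attach survival and final height drawn from the fitness surface."""
    if rng is None:
        rng = _child_rngs(cfg.seed, 3)[1]
    out = table.reset_index(drop=True).copy()
    n = len(out)
    x = ((out["height_init"] - cfg.init_height_mean)
         / cfg.init_height_sd).to_numpy()
    surv = np.empty(n)
    height = np.full(n, np.nan)
    for garden, idx in out.groupby("garden").groups.items():
        idx = np.asarray(idx)
        a = cfg.survival_intercept.get(garden, 1.5)
        c = cfg.height_intercept.get(garden, 70.0)
        eta = np.full(idx.size, a) + cfg.survival_init_coef * x[idx]
        mu = np.full(idx.size, c) + cfg.height_init_coef * x[idx]
        for t, b in cfg.survival_beta.items():
            eta += b * out.loc[idx, f"_z_{t}"].to_numpy()
        for t, d in cfg.height_beta.items():
            mu += d * out.loc[idx, f"_z_{t}"].to_numpy()
        for t, q in cfg.height_gamma.items():
            mu += q * out.loc[idx, f"_z_{t}"].to_numpy() ** 2
        if cfg.surv_block_sd > 0 or cfg.height_block_sd > 0:
            blocks = out.loc[idx, "block"].to_numpy()
            for lv in np.unique(blocks):
                m = blocks == lv
                eta[m] += rng.normal(0.0, cfg.surv_block_sd) \
                    if cfg.surv_block_sd > 0 else 0.0
                mu[m] += rng.normal(0.0, cfg.height_block_sd) \
                    if cfg.height_block_sd > 0 else 0.0
        p = 1.0 / (1.0 + np.exp(-eta))
        s = rng.random(idx.size) < p
        h = mu + rng.normal(0.0, cfg.height_resid_sd, size=idx.size)
        surv[idx] = s.astype(float)
        height[idx] = np.where(s, h, np.nan)
    out["survival"] = surv.astype(int)
    out["height_final"] = height
    out["fitness_obs"] = np.where(out["survival"] == 1,
                                  out["height_final"], 0.0)
    return out


def implied_selection_gradients(cfg: SimConfig, garden: str,
                                n_quad: int = 201) -> dict:
    """Implied linear selection gradients of the generating surface.

    For independent standard-normal inputs v (trait deviations and initial
    height) with survival logit a + ws.v and conditional height mean
    c + wh.v, expected fitness is W(v) = sigmoid(a + ws.v) (c + wh.v), and
    the regression coefficient of relative fitness on v_j is
    beta_j = E[W v_j] / E[W]. Both expectations reduce to one-dimensional
    Gauss-Hermite integrals over u = a + ws.v (conditioning v on u).
    Requires a purely linear surface (no quadratic height terms).
    """
    if any(q != 0 for q in cfg.height_gamma.values()):
        raise ValueError(
            "implied gradients available only for linear surfaces"
        )
    names = list(cfg.traits) + ["height_init"]
    ws = np.array([cfg.survival_beta.get(t, 0.0) for t in cfg.traits]
                  + [cfg.survival_init_coef])
    wh = np.array([cfg.height_beta.get(t, 0.0) for t in cfg.traits]
                  + [cfg.height_init_coef])
    a = cfg.survival_intercept.get(garden, 1.5)
    c = cfg.height_intercept.get(garden, 70.0)
    s2 = float(ws @ ws)
    if s2 == 0.0:
        p = 1.0 / (1.0 + np.exp(-a))
        EW = p * c
        EWv = p * wh
    else:
        nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
        u = a + np.sqrt(s2) * nodes        # u ~ N(a, s2)
        sig = 1.0 / (1.0 + np.exp(-u))
        wq = weights / weights.sum()
        m = np.outer((u - a) / s2, ws)     # E[v | u], nodes x dims
        cond_mean_h = c + m @ wh
        EW = float(wq @ (sig * cond_mean_h))
        # E[(c + wh.v) v_j | u] = c m_j + (Sigma_c wh)_j + (wh.m) m_j
        sigma_c_wh = wh - ws * (ws @ wh) / s2
        inner = (c * m + sigma_c_wh[None, :]
                 + (m @ wh)[:, None] * m)
        EWv = (wq * sig) @ inner
    beta = EWv / EW
    return {"E_W": EW, "beta": dict(zip(names, beta))}


def _red_edge_baseline(wl: np.ndarray) -> np.ndarray:
    vis = 0.08
    nir = 0.50
    base = vis + (nir - vis) / (1.0 + np.exp(-(wl - 715.0) / 18.0))
    # gentle decline into the SWIR
    base -= 0.15 / (1.0 + np.exp(-(wl - 1650.0) / 180.0))
    return base


def _gauss(wl, center, width):
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def simulate_spectra(table: pd.DataFrame, cfg: SimConfig,
                     rng=None) -> SpectrumSet:
    """Phenomenological leaf spectra driven by the trait columns.

    Trait deviations modulate Gaussian absorption depths: the pigment
    traits (CCI, ANT) at 531 and 645 nm, the water trait (WBI) at 970,
    1400 and 1900 nm (more water -> deeper absorption -> lower WBI as
    measured from the spectrum), and LMA the broadband NIR level.
    """
    if rng is None:
        rng = _child_rngs(cfg.seed, 3)[2]
    wl = np.arange(cfg.wl_start, cfg.wl_stop + cfg.wl_step / 2, cfg.wl_step)
    base = _red_edge_baseline(wl)
    f531 = _gauss(wl, 531.0, 25.0)
    f645 = _gauss(wl, 645.0, 30.0)
    f970 = _gauss(wl, 970.0, 45.0)
    f1400 = _gauss(wl, 1400.0, 60.0)
    f1900 = _gauss(wl, 1900.0, 80.0)
    nir = 1.0 / (1.0 + np.exp(-(wl - 750.0) / 30.0))

    def zcol(t):
        col = f"_z_{t}"
        if col in table.columns:
            return table[col].to_numpy(float)
        if t in table.columns:
            v = table[t].to_numpy(float)
            sd = v.std() or 1.0
            return (v - v.mean()) / sd
        return np.zeros(len(table))

    cpl = cfg.spectral_trait_coupling
    z_cci = cpl * zcol("CCI")
    z_ant = cpl * zcol("ANT")
    z_wbi = cpl * zcol("WBI")
    z_lma = cpl * zcol("LMA")

    spectra = []
    for i, (_, row) in enumerate(table.iterrows()):
        r = base.copy()
        r -= (0.030 + 0.006 * z_cci[i]) * f645      # chlorophyll well
        r -= (0.020 - 0.004 * z_cci[i] + 0.004 * z_ant[i]) * f531
        water_depth = 0.040 - 0.008 * z_wbi[i]       # higher WBI = less water
        r -= water_depth * f970
        r -= 2.0 * water_depth * f1400
        r -= 2.5 * water_depth * f1900
        r += 0.010 * z_lma[i] * nir
        for center, width, amp in cfg.pop_spectral_offsets.get(
            row["population"], ()
        ):
            r += amp * _gauss(wl, center, width)
        if cfg.sensor_step != 0.0:
            r = r + cfg.sensor_step * (wl >= 990.0)
        if cfg.spectral_noise_sd > 0:
            r = r + rng.normal(0.0, cfg.spectral_noise_sd, size=wl.size)
        if r.min() < 0.0 or r.max() > 1.0:
            raise ValueError(
                "spectral forward model left [0, 1]; reduce offsets/noise"
            )
        spectra.append(
            Spectrum(wl, r, {
                "id": row["id"], "garden": row["garden"],
                "population": row["population"], "family": row["family"],
                "block": row["block"],
            })
        )
    return SpectrumSet(spectra)


def simulate_experiment(cfg: SimConfig | None = None,
                        with_spectra: bool = True) -> SimBundle:
    """Full synthetic experiment: traits + fitness (+ spectra) + truth record."""
    if cfg is None:
        cfg = SimConfig()
    rng_fam, rng_fit, rng_spec = _child_rngs(cfg.seed, 3)
    table = simulate_families(cfg, rng_fam)
    table = simulate_fitness(table, cfg, rng_fit)
    spectra = simulate_spectra(table, cfg, rng_spec) if with_spectra else None
    truth: dict = {
        "V_g": {t: cfg.vg(t) for t in cfg.traits},
        "V_e": {t: cfg.ve(t) for t in cfg.traits},
        "H2": {t: cfg.vg(t) / (cfg.vg(t) + cfg.ve(t)) for t in cfg.traits},
        "block_sd": cfg.block_sd,
        "survival_beta": dict(cfg.survival_beta),
        "height_beta": dict(cfg.height_beta),
        "height_gamma": dict(cfg.height_gamma),
        "seed": cfg.seed,
    }
    if not any(q != 0 for q in cfg.height_gamma.values()):
        truth["implied_beta"] = {
            g: implied_selection_gradients(cfg, g)["beta"]
            for g in cfg.gardens
        }
    return SimBundle(table=table, spectra=spectra, truth=truth)
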