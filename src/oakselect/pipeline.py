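"""End-to-end orchestration: spectra -> traits -> quantgen -> fitness ->
selection -> response, with validation, logging and CSV report output.

Every output table is long-format and carries garden / population / level
keys so downstream joins are unambiguous. The pipeline is a pure function
of (inputs, config, seed): rerunning with the same configuration
reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import fitness as fit_mod
from . import plsda as plsda_mod
from . import quantgen, selection
from .simulate import SimConfig, simulate_experiment
from .spectra import (SpectrumSet, band, cci, qc_reflectance, read_spectra,
                      resample, splice_sensors, wbi, write_spectra)

__all__ = ["PipelineConfig", "validate_inputs", "run_pipeline"]

DEFAULT_TRAIT_GROUPS = {
    "physiological": ["ANT", "CCI", "WBI"],
    "spectral": ["R700", "R900", "R1400"],
    "morphological": ["RGR", "LMA", "thickness"],
}


@dataclass
class PipelineConfig:
    """Configuration for a full analysis run."""

    traits_csv: str | None = None
    spectra_csv: str | None = None
    simulate: bool = False
    out_dir: str = "oakselect_out"
    traits: list = field(default_factory=lambda: list(SimConfig().traits))
    trait_groups: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_GROUPS))
    splice_points: list = field(default_factory=lambda: [990.0, 1100.0])
    interp_widths: list = field(default_factory=lambda: [5.0, 1.0])
    resample_start: float = 400.0
    resample_stop: float = 2400.0
    resample_step: float = 10.0
    spectral_bands: list = field(default_factory=lambda: [700.0, 900.0, 1400.0])
    vif_threshold: float = 5.0
    plsda_max_comp: int = 6
    plsda_n_boot: int = 25
    block_alpha: float = 0.05
    seed: int = 0
    sim_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def validate_inputs(table: pd.DataFrame,
                    spectra: SpectrumSet | None = None) -> dict:
    """Schema and consistency checks; returns a report, never raises."""
    problems, warnings_ = [], []
    required = {"id", "garden", "population", "family", "block", "survival"}
    missing = required - set(table.columns)
    if missing:
        problems.append(f"missing trait-table columns: {sorted(missing)}")
    if "id" in table.columns and table["id"].duplicated().any():
        problems.append("duplicate individual ids in trait table")
    if spectra is not None and "id" in table.columns:
        tab_ids = set(table["id"].astype(str))
        spec_ids = {s.id for s in spectra}
        for sid in sorted(spec_ids - tab_ids)[:10]:
            warnings_.append(f"spectrum id {sid!r} absent from trait table")
    counts = {}
    if not problems:
        counts = (table.groupby(["garden", "population"])["id"]
                  .count().to_dict())
        fam_sizes = table.groupby(["garden", "population", "family"]).size()
        for key, size in fam_sizes.items():
            if size < 2:
                warnings_.append(
                    f"family {key} has {size} individual(s); excluded from "
                    "variance estimation")
        if "survival" in table.columns:
            counts["overall_survival"] = float(table["survival"].mean())
    return {
        "problems": problems,
        "warnings": warnings_,
        "counts": {str(k): v for k, v in counts.items()},
        "ok": not problems,
    }


def _preprocess_spectra(spectra: SpectrumSet, cfg: PipelineConfig):
    clean, qc = qc_reflectance(spectra)
    if clean is None:
        raise ValueError("all spectra failed reflectance QC")
    grid = np.arange(cfg.resample_start,
                     cfg.resample_stop + cfg.resample_step / 2,
                     cfg.resample_step)
    processed = clean.map(
        lambda s: resample(
            splice_sensors(s, cfg.splice_points, cfg.interp_widths), grid
        )
    )
    return processed, qc


def _spectral_traits(processed: SpectrumSet, cfg: PipelineConfig):
    rows = []
    for s in processed:
        row = {"id": s.id, "CCI": cci(s), "WBI": wbi(s)}
        for b in cfg.spectral_bands:
            row[f"R{int(b)}"] = band(s, b)
        rows.append(row)
    return pd.DataFrame(rows)


def _plsda_report(processed: SpectrumSet, table: pd.DataFrame,
                  cfg: PipelineConfig):
    meta = table.set_index("id")
    rows, top_rows = [], []
    X_all = processed.to_matrix()
    ids = [s.id for s in processed]
    labels = np.array([meta.loc[i, "population"] for i in ids])
    gardens = np.array([meta.loc[i, "garden"] for i in ids])
    for garden in np.unique(gardens):
        m = gardens == garden
        X, y = X_all[m], labels[m]
        ncomp = plsda_mod.select_ncomp(
            X, y, max_comp=cfg.plsda_max_comp, n_boot=cfg.plsda_n_boot,
            seed=cfg.seed,
        )
        ks = plsda_mod.bootstrap_kappa(X, y, ncomp, cfg.plsda_n_boot,
                                       seed=cfg.seed + 7)
        model = plsda_mod.fit_simpls(X, y, ncomp, bands=processed.grid)
        top = plsda_mod.top_loading_bands(model, k=10)
        rows.append({"garden": garden, "ncomp": ncomp,
                     "oob_kappa_mean": float(ks.mean()),
                     "oob_kappa_sd": float(ks.std(ddof=1))})
        top = top.copy()
        top["garden"] = garden
        top_rows.append(top)
    return pd.DataFrame(rows), pd.concat(top_rows, ignore_index=True)


def _fitness_stage(table: pd.DataFrame, cfg: PipelineConfig):
    out = table.copy()
    out["fitness_hat"] = np.nan
    block_rows = []
    for garden, sub in table.groupby("garden"):
        # family fixed effects can alias (families with no survivors) or
        # separate on small data; fall back to the family-free model then
        include_family = True
        try:
            stat, df, p = fit_mod.block_omnibus_test(sub)
        except ValueError:
            include_family = False
            stat, df, p = fit_mod.block_omnibus_test(sub,
                                                     include_family=False)
        if not include_family:
            import warnings

            warnings.warn(
                f"garden {garden}: family fixed effects dropped from the "
                "fitness model (aliasing or separation)", stacklevel=2)
        include_block = p < cfg.block_alpha
        model = fit_mod.fit_fitness_model(sub, include_family=include_family,
                                          include_block=include_block)
        out.loc[sub.index, "fitness_hat"] = fit_mod.predict_fitness(model, sub)
        block_rows.append({"garden": garden, "block_lrt": stat,
                           "block_df": df, "block_p": p,
                           "block_included": bool(include_block),
                           "family_included": include_family})
    return out, pd.DataFrame(block_rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis; writes artifacts under cfg.out_dir.

    Produces the V_g/H^2 table, the garden- and population-level selection
    tables, the response-to-selection table (R = H^2 * S), the PLSDA report
    and a JSON run log. Returns the artifacts in memory as a dict.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": cfg.seed, "config": asdict(cfg), "stages": []}

    # --- inputs
    if cfg.simulate:
        sim_cfg = SimConfig(seed=cfg.seed, **cfg.sim_overrides)
        bundle = simulate_experiment(sim_cfg)
        table, spectra = bundle.table, bundle.spectra
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(bundle.truth, fh, indent=1, default=str)
        log["stages"].append("simulate")
    else:
        if cfg.traits_csv is None:
            raise ValueError("traits_csv required when simulate is false")
        table = pd.read_csv(cfg.traits_csv)
        spectra = (read_spectra(cfg.spectra_csv)
                   if cfg.spectra_csv else None)
        log["stages"].append("load")

    report = validate_inputs(table, spectra)
    log["validation"] = report
    if not report["ok"]:
        raise ValueError(f"input validation failed: {report['problems']}")

    traits = list(cfg.traits)
    for t in traits:
        if t not in table.columns:
            raise ValueError(f"trait column {t!r} missing from trait table")

    artifacts: dict = {"validation": report}

    # --- spectra
    if spectra is not None:
        processed, qc = _preprocess_spectra(spectra, cfg)
        spec_traits = _spectral_traits(processed, cfg)
        spec_traits.to_csv(out_dir / "spectral_traits.csv", index=False)
        plsda_summary, plsda_top = _plsda_report(processed, table, cfg)
        plsda_summary.to_csv(out_dir / "plsda_report.csv", index=False)
        plsda_top.to_csv(out_dir / "plsda_top_bands.csv", index=False)
        artifacts["plsda"] = plsda_summary
        artifacts["plsda_top_bands"] = plsda_top
        artifacts["spectral_traits"] = spec_traits
        log["stages"].append("spectra+plsda")

    # --- variance components / heritability
    vg_table = quantgen.run_quantgen(table, traits)
    vg_table.to_csv(out_dir / "variance_components.csv", index=False)
    artifacts["variance_components"] = vg_table
    log["stages"].append("quantgen")

    # --- fitness
    table_fit, block_report = _fitness_stage(table, cfg)
    block_report.to_csv(out_dir / "fitness_block_tests.csv", index=False)
    table_fit[["id", "garden", "fitness_hat"]].to_csv(
        out_dir / "fitness_hat.csv", index=False)
    artifacts["fitness_block_tests"] = block_report
    log["stages"].append("fitness")

    # --- selection (garden and population level)
    sel_garden = selection.analyze_selection(
        table_fit, traits, level="garden", vif_threshold=cfg.vif_threshold)
    sel_pop = selection.analyze_selection(
        table_fit, traits, level="population",
        vif_threshold=cfg.vif_threshold)
    sel = pd.concat([sel_garden, sel_pop], ignore_index=True)
    sel.to_csv(out_dir / "selection_table.csv", index=False)
    artifacts["selection"] = sel
    log["retained_traits"] = sel_garden.attrs.get("retained_traits")
    log["stages"].append("selection")

    # --- response to selection: R = H2 * S at population x garden level
    s_pop = sel_pop[sel_pop["parameter"] == "S"][
        ["garden", "population", "trait", "estimate"]
    ].rename(columns={"estimate": "S"})
    h2 = vg_table[vg_table.get("estimable", True) == True][  # noqa: E712
        ["garden", "population", "trait", "H2"]
    ]
    resp = s_pop.merge(h2, on=["garden", "population", "trait"], how="inner")
    resp["R"] = selection.response_to_selection(resp["H2"], resp["S"])
    resp.to_csv(out_dir / "response_to_selection.csv", index=False)
    artifacts["response"] = resp
    log["stages"].append("response")

    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, default=str)
    artifacts["log"] = log
    return artifacts
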