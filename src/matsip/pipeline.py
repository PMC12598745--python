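"""End-to-end orchestration: read the tabular inputs, run each analysis
stage in dependency order, and write the result tables plus a markdown
summary report.

Stages
------
rates      bulk IRMS time series → assimilation rates and areal gross
           productivity (``rates.tsv``)
urea       GC–MS injections → urea quantification (``urea_quant.tsv``),
           urea consumption rates and the ambient lake urea concentration
community  protein spectral counts → MAG abundance and correlation tables
sip        peptide isotopologue patterns → peptide/MAG/sample isotope
           ratios and exact-quantile-test significance flags

All inputs and outputs are headered TSV. The configuration is a single
nested mapping (YAML on disk); unknown keys are rejected.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bulk_rates as br
from . import community as cm
from . import sip
from . import urea_gcms as ug
from .errors import ConfigError, InsufficientDataError
from .isotope import delta_to_ratio, ratio_to_delta

__all__ = ["DEFAULT_CONFIG", "load_config", "run", "write_report",
           "control_summary"]

DEFAULT_CONFIG: dict = {
    "out_dir": "matsip_out",
    "stages": {"rates": True, "urea": True, "community": True, "sip": True},
    "inputs": {
        "irms": "irms_bulk.tsv",
        "gcms": "gcms_injections.tsv",
        "proteins": "proteins.tsv",
        "patterns": "peptide_patterns.tsv",
    },
    "rates": {
        "c_pool_excess": 0.02,       # 13C-DIC spike above natural abundance
        "n_label_purity": 0.98,      # atom fraction of 15N substrates
        "areal_dry_density": 500.0,  # g dry biomass per m^2
        "inorganic_c_fraction": 0.0,  # optional carbonate correction, off
    },
    "urea": {
        "window_h": 2.0,
        "volume_ml": 100.0,
        "wet_mass_g": 25.0,
        "dry_wet_ratio": 0.1,
        "istd_amount_umol": 0.05,
        "sample_volume_ml": 0.200,
        "use_three_ion": False,
        "area_floor": 0.0,
    },
    "community": {"min_abundance": 0.001},
    "sip": {"element": "C", "q": 0.5, "alpha": 0.05, "pairs": None,
            "shared_only": True},
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        if key not in defaults:
            raise ConfigError(f"unknown configuration key {path + key!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict) \
                and key not in ("stages", "inputs"):
            out[key] = _merge(defaults[key], value, path + key + ".")
        else:
            out[key] = value
    return out


def load_config(source: str | Path | dict | None = None) -> dict:
    """Merge a user configuration (YAML path or mapping) over the defaults,
    rejecting unknown keys."""
    if source is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, source)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"input file not found: {path}")
    return pd.read_csv(path, sep="\t")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _ratio_column(irms: pd.DataFrame) -> pd.DataFrame:
    out = irms.copy()
    if "value_type" in out.columns:
        is_delta = out["value_type"] == "delta"
        ratios = out["value"].to_numpy(dtype=float).copy()
        if is_delta.any():
            for el in out.loc[is_delta, "element"].unique():
                m = is_delta & (out["element"] == el)
                ratios[m.to_numpy()] = delta_to_ratio(
                    out.loc[m, "value"].to_numpy(), el)
        out["ratio"] = ratios
    elif "ratio" not in out.columns:
        out["ratio"] = out["value"]
    return out


def control_summary(irms: pd.DataFrame) -> pd.DataFrame:
    """Natural-abundance baseline per element, reporting both the δ of the
    mean ratio and the mean of per-observation δ values (they differ
    slightly; both are labelled)."""
    irms = _ratio_column(irms)
    ctl = irms[irms["treatment"] == "control"]
    rows = []
    for el, grp in ctl.groupby("element"):
        r = grp["ratio"].to_numpy(dtype=float)
        rows.append({
            "element": el, "n": len(r), "mean_ratio": r.mean(),
            "sd_ratio": r.std(ddof=1) if len(r) > 1 else 0.0,
            "delta_of_mean_ratio_permil": ratio_to_delta(float(r.mean()), el),
            "mean_of_delta_permil": float(np.mean(ratio_to_delta(r, el))),
        })
    return pd.DataFrame(rows)


def _base_substrate(name: str) -> str:
    return str(name).split("_with")[0]


def _rates_stage(irms: pd.DataFrame, cfg: dict) -> pd.DataFrame:
    irms = _ratio_column(irms)
    if "series_id" not in irms.columns:
        irms["series_id"] = (irms["substrate"].astype(str) + "_"
                             + irms["light_phase"].astype(str))
    rows = []
    for series_id, grp in irms.groupby("series_id"):
        element = grp["element"].iloc[0]
        substrate = grp["substrate"].iloc[0] if "substrate" in grp.columns else ""
        phase = grp["light_phase"].iloc[0]
        comp = br.BiomassComposition(
            c_wt_pct=float(grp["c_wt_pct"].iloc[0]),
            n_wt_pct=float(grp["n_wt_pct"].iloc[0]),
            areal_dry_density=cfg["areal_dry_density"],
        )
        if element == "N":
            pool = br.SubstratePool.n_label(_base_substrate(substrate),
                                            cfg["n_label_purity"])
            est = br.n_assimilation_rate(grp, comp, pool)
            rows.append({"substrate": substrate, "light_phase": phase,
                         "rate": est.value, "stderr": est.stderr,
                         "units": est.units, "n_obs": est.n_obs,
                         "method": est.method})
        else:
            pool = br.SubstratePool.dic_spike(cfg["c_pool_excess"])
            hourly = br.c_fixation_rate(grp, comp, pool)
            if cfg["inorganic_c_fraction"]:
                corr = 1.0 / (1.0 - cfg["inorganic_c_fraction"])
                hourly = br.RateEstimate(hourly.value * corr,
                                         hourly.stderr * corr, hourly.units,
                                         hourly.n_obs, hourly.method)
            daily, per12 = br.areal_gross_productivity(grp, comp, pool)
            for est in (hourly, daily, per12):
                rows.append({"substrate": substrate, "light_phase": phase,
                             "rate": est.value, "stderr": est.stderr,
                             "units": est.units, "n_obs": est.n_obs,
                             "method": est.method})
    return pd.DataFrame(rows)


def _urea_stage(gcms: pd.DataFrame, cfg: dict) -> tuple[pd.DataFrame,
                                                        pd.DataFrame, float]:
    istd = ug.InternalStandard(cfg["istd_amount_umol"], cfg["sample_volume_ml"])
    quant = ug.quantify_injections(gcms, istd, cfg["use_three_ion"],
                                   cfg["area_floor"])
    setup = br.IncubationSetup(cfg["volume_ml"], cfg["wet_mass_g"],
                               cfg["dry_wet_ratio"])
    samples = quant[quant["role"] == "sample"].dropna(subset=["conc_15N_mM"])
    rate_rows = []
    for phase, grp in samples.groupby("light_phase"):
        try:
            est = br.urea_consumption_rate(grp["time_h"].to_numpy(),
                                           grp["conc_15N_mM"].to_numpy(),
                                           setup, cfg["window_h"])
        except InsufficientDataError:
            continue
        rate_rows.append({"substrate": "urea_consumption", "light_phase": phase,
                          "rate": est.value, "stderr": est.stderr,
                          "units": est.units, "n_obs": est.n_obs,
                          "method": est.method})
    # ambient lake urea from unspiked time-zero injections, against the
    # high-enrichment calibration series (role 'ambient_standard') when
    # present; the 15N-urea reference concentration comes from the spiked
    # time-zero samples
    lake_uM = float("nan")
    ambient = gcms[gcms["role"] == "ambient"]
    t0 = samples[samples["time_h"] <= samples["time_h"].min() + 1e-9]
    if len(ambient) and len(t0):
        astd_rows = gcms[gcms["role"] == "ambient_standard"]
        curve = quant.attrs["calibration"]
        if len(astd_rows):
            astds = [
                ug.CalibrationStandard(
                    float(row["known_15n_fraction"]),
                    ug.GcmsInjection(str(row["injection_id"]),
                                     float(row["s153"]), float(row["s155"])))
                for _, row in astd_rows.iterrows()
            ]
            curve = ug.fit_calibration(astds, cfg["use_three_ion"])
        c15_ref = float(t0["conc_15N_mM"].mean())
        vals = []
        for _, row in ambient.iterrows():
            inj = ug.GcmsInjection(str(row["injection_id"]),
                                   float(row["s153"]), float(row["s155"]))
            pct, _ = ug.calibrated_15n_percent(inj, curve,
                                               cfg["use_three_ion"])
            if pct < 100.0:
                vals.append(ug.conc_14n_urea_ambient(100.0 - pct, c15_ref))
        if vals:
            lake_uM = float(np.mean(vals)) * 1000.0
    return quant, pd.DataFrame(rate_rows), lake_uM


def _community_stage(proteins: pd.DataFrame, cfg: dict) -> dict:
    filtered = cm.filter_records(proteins)
    matrix = cm.abundance_matrix(filtered, prefiltered=True)
    mask = cm.abundance_threshold_mask(matrix, cfg["min_abundance"])
    corr = (cm.abundance_correlation(matrix)
            if matrix.shape[1] >= 3 else pd.DataFrame())
    long = matrix.reset_index(names="mag_id").melt(
        id_vars="mag_id", var_name="sample_id", value_name="abundance")
    return {"matrix": matrix, "long": long, "mask": mask, "correlation": corr,
            "removals": filtered.attrs["removals"]}


def _sip_stage(patterns: pd.DataFrame, cfg: dict) -> dict:
    ratios = sip.peptide_ratio_table(patterns, cfg["element"])
    pairs = cfg["pairs"]
    if pairs is None:
        labels = sorted(s for s in ratios["sample_id"].unique()
                        if str(s).endswith("_label"))
        pairs = [(s, s[: -len("label")] + "ctrl") for s in labels
                 if (s[: -len("label")] + "ctrl") in set(ratios["sample_id"])]
    pairs = [tuple(p) for p in pairs]
    tests = sip.run_quantile_tests(ratios, pairs, cfg["q"], cfg["alpha"],
                                   cfg["shared_only"])
    return {"peptide_ratios": ratios,
            "mag_ratios": sip.mag_ratio_table(ratios),
            "sample_ratios": sip.sample_ratio_table(ratios),
            "tests": tests, "pairs": pairs}


def run(config: dict | str | Path | None = None,
        base_dir: str | Path = ".") -> dict:
    """Execute the enabled stages and write all outputs under
    ``config['out_dir']``. Returns the in-memory results keyed by stage."""
    cfg = load_config(config)
    base = Path(base_dir)
    out_dir = Path(cfg["out_dir"])
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {"out_dir": out_dir}
    rate_frames = []

    def _input(name: str) -> pd.DataFrame:
        path = Path(cfg["inputs"][name])
        if not path.is_absolute():
            path = base / path
        try:
            return _read_tsv(path)
        except ConfigError as exc:
            raise ConfigError(f"stage input missing ({name}): {exc}") from exc

    if cfg["stages"]["rates"]:
        irms = _input("irms")
        rates = _rates_stage(irms, cfg["rates"])
        rate_frames.append(rates)
        results["rates"] = rates
        results["controls"] = control_summary(irms)
        _write_tsv(results["controls"], out_dir / "control_summary.tsv")
    if cfg["stages"]["urea"]:
        quant, urates, lake = _urea_stage(_input("gcms"), cfg["urea"])
        _write_tsv(quant.drop(columns=["clamped"], errors="ignore"),
                   out_dir / "urea_quant.tsv")
        rate_frames.append(urates)
        results["urea_quant"] = quant
        results["lake_urea_uM"] = lake
    if rate_frames:
        all_rates = pd.concat(rate_frames, ignore_index=True)
        _write_tsv(all_rates, out_dir / "rates.tsv")
        results["all_rates"] = all_rates
    if cfg["stages"]["community"]:
        comm = _community_stage(_input("proteins"), cfg["community"])
        _write_tsv(comm["long"], out_dir / "mag_abundance.tsv")
        if len(comm["correlation"]):
            comm["correlation"].to_csv(out_dir / "mag_correlation.tsv", sep="\t",
                                       float_format="%.10g")
        results["community"] = comm
    if cfg["stages"]["sip"]:
        sips = _sip_stage(_input("patterns"), cfg["sip"])
        _write_tsv(sips["peptide_ratios"], out_dir / "peptide_ratios.tsv")
        _write_tsv(sips["mag_ratios"], out_dir / "mag_ratios.tsv")
        _write_tsv(sips["sample_ratios"], out_dir / "sample_ratios.tsv")
        _write_tsv(sips["tests"], out_dir / "sip_tests.tsv")
        results["sip"] = sips
    write_report(results, out_dir / "report.md")
    return results


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.4g}") -> list[str]:
    if df.empty:
        return ["(empty)"]
    df = df.copy()
    for c in df.columns:
        if pd.api.types.is_float_dtype(df[c]):
            df[c] = df[c].map(lambda v: floatfmt.format(v))
    header = "| " + " | ".join(map(str, df.columns)) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    body = ["| " + " | ".join(map(str, row)) + " |"
            for row in df.itertuples(index=False)]
    return [header, sep, *body]


def write_report(results: dict, path: Path) -> None:
    """Summarize the stage outputs as a markdown report; every number comes
    from a table that was also written as TSV."""
    lines = ["# matsip analysis report", ""]
    if "all_rates" in results:
        lines += ["## Assimilation and consumption rates", ""]
        lines += _md_table(results["all_rates"])
        lines.append("")
    if "controls" in results:
        lines += ["## Natural-abundance baseline (controls)", ""]
        lines += _md_table(results["controls"], "{:.6g}")
        lines.append("")
    if "lake_urea_uM" in results and np.isfinite(results["lake_urea_uM"]):
        lines += [f"Ambient dissolved urea: {results['lake_urea_uM']:.2f} uM", ""]
    if "community" in results:
        comm = results["community"]
        lines += ["## Proteome community profile", "",
                  f"MAGs above display threshold in all samples: "
                  f"{', '.join(comm['mask']) or 'none'}",
                  f"QC removals: {comm['removals']}", ""]
        lines += _md_table(comm["long"].pivot(index="mag_id",
                                              columns="sample_id",
                                              values="abundance")
                           .reset_index(), "{:.4f}")
        lines.append("")
        if len(comm["correlation"]):
            lines += ["### Abundance correlations", ""]
            lines += _md_table(comm["correlation"].reset_index(names="mag_id"),
                               "{:.2f}")
            lines.append("")
    if "sip" in results:
        lines += ["## Protein-SIP enrichment tests", ""]
        lines += _md_table(results["sip"]["tests"])
        lines.append("")
    Path(path).write_text("\n".join(lines))
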