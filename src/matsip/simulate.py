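"""Synthetic stable-isotope-probing experiments with known ground truth.

The generator runs the same mass balances as the inference modules, but
forward: true assimilation rates produce bulk isotope-ratio time
courses, a true urea consumption rate produces a dissolved-urea
depletion curve and the GC–MS peak areas that would measure it, a
planted community composition produces spectral-count tables, and
planted per-MAG label trajectories produce peptide isotopologue
patterns. Every planted parameter is recorded in a ground-truth
manifest so any estimator output can be scored without re-reading the
configuration.

The default scenario mirrors a diurnal soda-lake mat labelling design:
0.5 mM 15N substrate supplements at 98 atom% purity incubated up to 8 h
in separate day and night series, a ~2% 13C-bicarbonate spike followed
over 48 h, a 1:10 dry-to-wet mat mass ratio, and a two-cyanobacteria
community whose dominant pair is forced to be anticorrelated across
samples. Noise parameters default to instrument-scale errors
(isotope-ratio sd 2e-5, 2% multiplicative GC–MS area noise, 1%
isotopologue pattern noise, overdispersed spectral counts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidValueError
from .isotope import atom_fraction_to_ratio, natural_atom_fraction
from .sip import ElementalComposition, labeled_pattern

__all__ = [
    "NoiseModel",
    "ExperimentConfig",
    "simulate_labeling_timecourse",
    "simulate_urea_depletion",
    "simulate_proteome",
    "simulate_peptide_patterns",
    "generate_experiment",
    "paper_like_config",
]


@dataclass(frozen=True)
class NoiseModel:
    irms_ratio_sd: float = 2e-5     # sd of heavy/light ratio measurements
    gcms_area_cv: float = 0.02      # multiplicative sd on SIM peak areas
    pattern_cv: float = 0.01        # multiplicative sd on isotopologue bins
    psm_dispersion: float = 5.0     # negative-binomial size for PSM counts
    conc_cv: float = 0.02           # multiplicative sd on reported concentrations

    def __post_init__(self) -> None:
        vals = (self.irms_ratio_sd, self.gcms_area_cv, self.pattern_cv,
                self.psm_dispersion, self.conc_cv)
        if any(v < 0 for v in vals):
            raise InvalidValueError("noise parameters must be non-negative")


def _default_rates() -> dict[tuple[str, str], float]:
    # μmol N/g dry/h per (substrate series, light phase)
    return {
        ("urea", "day"): 5.5,
        ("ammonium", "day"): 1.8,
        ("ammonium_with_nitrate", "day"): 2.5,
        ("nitrate_with_ammonium", "day"): 0.91,
        ("urea", "night"): 0.98,
        ("ammonium", "night"): 2.5,
        ("nitrate_with_ammonium", "night"): 0.39,
    }


def _default_urea_consumption() -> dict[str, float]:
    # μmol urea-N/g dry/h per light phase
    return {"day": 6.5, "night": 5.5}


def _default_mag_abundance() -> dict[str, float]:
    # base community composition; C* cyanobacteria, G8 purple sulfur
    # heterotroph analogue, A1 alphaproteobacterium, plus unbinned signal
    return {
        "C1": 0.18, "C2": 0.07, "C3": 0.07, "C4": 0.05,
        "C5": 0.21, "C6": 0.11, "G8": 0.19, "A1": 0.03,
        "unbinned": 0.09,
    }


def _default_label_trajectory() -> dict[str, dict[str, float]]:
    # 13C atom fraction of each labelled MAG per SIP time point;
    # C5 steps up toward the 2% DIC spike at late time points
    return {"C5": {"T1": 0.0115, "T2": 0.0130, "T3": 0.0160, "T4": 0.0200}}


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to generate one complete synthetic experiment."""

    seed: int = 0
    # bulk labelling design
    true_rates: dict[tuple[str, str], float] = field(default_factory=_default_rates)
    true_productivity: float = 24.0        # g C/m^2/day
    areal_dry_density: float = 500.0       # g dry biomass/m^2
    c_wt_pct: float = 40.0
    n_wt_pct: float = 7.0
    c_pool_excess: float = 0.02            # 13C-DIC spike above natural
    n_label_purity: float = 0.98           # 15N substrate atom fraction
    substrate_conc_mM: float = 0.5
    n_timepoints_h: tuple = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0)
    c_timepoints_h: tuple = (0.0, 6.0, 12.0, 24.0, 36.0, 48.0)
    n_replicates: int = 3
    # urea depletion / GC-MS design
    urea_consumption: dict[str, float] = field(
        default_factory=_default_urea_consumption)
    urea_c0_mM: float = 0.5
    lake_urea_uM: float = 3.9
    urea_timepoints_h: tuple = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0)
    urea_window_h: float = 2.0
    depletion_kinetics: str = "first_order"  # or "zero_order"
    technical_injections: int = 2  # GC vials per liquid sample
    volume_ml: float = 100.0
    wet_mass_g: float = 25.0  # dense homogenized-mat slurry
    dry_wet_ratio: float = 0.1
    istd_amount_umol: float = 0.05
    istd_volume_ml: float = 0.200
    calibration_fractions: tuple = (1.0, 0.9, 0.8, 0.0)  # 14N:15N 0:1,1:9,1:4,1:0
    # second standard series for ambient-urea work, urea:15N-urea ratios
    # 1:1 ... 1:5000 expressed as 15N fractions k/(k+1)
    ambient_calibration_ratios: tuple = (1, 9, 100, 500, 1000, 5000)
    calibration_replicates: int = 2
    # proteome design
    n_samples: int = 8
    mag_abundance: dict[str, float] = field(default_factory=_default_mag_abundance)
    anticorrelated_pair: tuple = ("C1", "C5", -0.9)
    proteins_per_mag: int = 30
    psm_depth: int = 20000
    planted_failures: dict[str, int] = field(default_factory=lambda: {
        "peptide_fdr": 2, "protein_fdr": 2, "no_unique_peptide": 2,
        "multi_mag": 2})
    # peptide-pattern design
    sip_mags: tuple = ("C1", "C5", "G8")
    labeled_mags: dict[str, dict[str, float]] = field(
        default_factory=_default_label_trajectory)
    sip_timepoints: tuple = ("T1", "T2", "T3", "T4")
    peptides_per_mag: int = 40
    pattern_length: int = 8
    peptide_p_jitter: float = 3e-4
    dropout_peptides: int = 4   # per MAG, missing from one sample (filter fodder)
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if self.n_samples < 4 and self.anticorrelated_pair is not None:
            raise ConfigError(
                "anticorrelated pair needs at least 4 samples to hit a target r")
        x_nat_c = natural_atom_fraction("C")
        for mag, traj in self.labeled_mags.items():
            for tp, p in traj.items():
                if not (x_nat_c <= p <= 0.5):
                    raise ConfigError(
                        f"label trajectory for {mag}/{tp} outside [x_nat, 0.5]")


def paper_like_config(seed: int = 0) -> ExperimentConfig:
    """The packaged scenario whose true parameters equal the headline rate
    table of the field study the defaults emulate."""
    return ExperimentConfig(seed=seed)


def _rngs(config: ExperimentConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(4)
    names = ("irms", "urea", "proteome", "patterns")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# bulk IRMS time courses


def simulate_labeling_timecourse(config: ExperimentConfig,
                                 rng: np.random.Generator | None = None,
                                 ) -> tuple[pd.DataFrame, dict]:
    """Forward-simulate bulk isotope-ratio series for every substrate/phase
    plus the 13C-bicarbonate series, with matching controls at natural
    abundance. Returns (table, truth)."""
    rng = rng if rng is not None else _rngs(config)["irms"]
    x_nat_n = natural_atom_fraction("N")
    x_nat_c = natural_atom_fraction("C")
    n_pool = config.n_wt_pct / 100.0 / 14.007 * 1e6  # μmol N/g dry
    n_excess = config.n_label_purity - x_nat_n
    rows = []

    def emit(series_id, substrate, element, phase, times, slope, x_nat):
        for treatment in ("labeled", "control"):
            for rep in range(1, config.n_replicates + 1):
                for t in times:
                    x = x_nat + (slope * t if treatment == "labeled" else 0.0)
                    ratio = atom_fraction_to_ratio(x)
                    ratio += rng.normal(0.0, config.noise.irms_ratio_sd)
                    rows.append({
                        "sample_id": f"{series_id}_{treatment}_r{rep}_t{t:g}",
                        "replicate": rep, "time_h": t, "element": element,
                        "value": max(ratio, 1e-9), "value_type": "ratio",
                        "treatment": treatment, "light_phase": phase,
                        "substrate": substrate, "series_id": series_id,
                        "c_wt_pct": config.c_wt_pct, "n_wt_pct": config.n_wt_pct,
                    })

    truth: dict = {"n_rates": {}, "productivity_daily": config.true_productivity}
    for (substrate, phase), rate in config.true_rates.items():
        slope = rate * n_excess / n_pool  # atom fraction per hour
        series_id = f"{substrate}_{phase}"
        emit(series_id, substrate, "N", phase, config.n_timepoints_h,
             slope, x_nat_n)
        truth["n_rates"][series_id] = rate

    hourly_c = config.true_productivity / (config.areal_dry_density * 24.0)
    slope_c = hourly_c * config.c_pool_excess / (config.c_wt_pct / 100.0)
    emit("bicarbonate_day", "bicarbonate", "C", "day", config.c_timepoints_h,
         slope_c, x_nat_c)
    truth["c_hourly_rate"] = hourly_c
    truth["c_excess_slope"] = slope_c
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# urea depletion + GC-MS injections


def _true_conc(config: ExperimentConfig, phase: str, t: float) -> float:
    rate = config.urea_consumption[phase]  # μmol urea-N/g dry/h
    slope0 = (rate / 2.0) * (config.wet_mass_g * config.dry_wet_ratio
                             ) / config.volume_ml  # mmol/l/h
    c0 = config.urea_c0_mM
    if config.depletion_kinetics == "zero_order":
        return max(c0 - slope0 * t, 0.0)
    k = slope0 / c0
    return c0 * float(np.exp(-k * t))


def simulate_urea_depletion(config: ExperimentConfig,
                            rng: np.random.Generator | None = None,
                            ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate the dissolved-urea concentration series and the GC–MS SIM
    injection table (samples + external calibration standards + ambient
    lake-water injections). Returns (urea_conc, injections, truth)."""
    rng = rng if rng is not None else _rngs(config)["urea"]
    conc_rows, inj_rows = [], []
    truth: dict = {"urea_consumption": dict(config.urea_consumption),
                   "true_conc": {}, "lake_urea_uM": config.lake_urea_uM}
    area_scale = 1e6
    cv = config.noise.gcms_area_cv

    def areas(frac15: float) -> tuple[float, float]:
        total = area_scale * float(rng.lognormal(0.0, 0.3))
        s155 = total * frac15 * float(rng.lognormal(0.0, cv))
        s153 = total * (1.0 - frac15) * float(rng.lognormal(0.0, cv))
        return s153, s155

    for i, frac in enumerate(config.calibration_fractions):
        for rep in range(1, config.calibration_replicates + 1):
            s153, s155 = areas(frac)
            inj_rows.append({
                "injection_id": f"std{i}_r{rep}", "role": "standard",
                "known_15n_fraction": frac, "s153": s153, "s154": 0.0,
                "s155": s155, "s168": s153 * 0.1, "s170": s155 * 0.1,
                "time_h": np.nan, "replicate": rep, "light_phase": "",
            })

    for i, k in enumerate(config.ambient_calibration_ratios):
        frac = k / (k + 1.0)
        for rep in range(1, config.calibration_replicates + 1):
            s153, s155 = areas(frac)
            inj_rows.append({
                "injection_id": f"astd{i}_r{rep}", "role": "ambient_standard",
                "known_15n_fraction": frac, "s153": s153, "s154": 0.0,
                "s155": s155, "s168": s153 * 0.1, "s170": s155 * 0.1,
                "time_h": np.nan, "replicate": rep, "light_phase": "",
            })

    istd_umol = config.istd_amount_umol
    vol_ml = config.istd_volume_ml
    lake_c14 = config.lake_urea_uM / 1000.0  # mM
    for phase in config.urea_consumption:
        for rep in range(1, config.n_replicates + 1):
            for t in config.urea_timepoints_h:
                c15 = _true_conc(config, phase, t)
                truth["true_conc"][f"{phase}_r{rep}_t{t:g}"] = c15
                conc_rows.append({
                    "time_h": t, "replicate": rep, "light_phase": phase,
                    "conc_mM": c15 * float(rng.lognormal(0.0, config.noise.conc_cv)),
                })
                n15_umol = c15 * vol_ml
                n14_umol = istd_umol + lake_c14 * vol_ml
                frac15 = n15_umol / (n15_umol + n14_umol)
                for tech in range(1, config.technical_injections + 1):
                    s153, s155 = areas(frac15)
                    inj_rows.append({
                        "injection_id": f"{phase}_r{rep}_t{t:g}_v{tech}",
                        "role": "sample",
                        "known_15n_fraction": np.nan, "s153": s153, "s154": 0.0,
                        "s155": s155, "s168": s153 * 0.1, "s170": s155 * 0.1,
                        "time_h": t, "replicate": rep, "light_phase": phase,
                    })
    # window-average consumption rate a first-2-h regression measures on
    # the noiseless depletion curve (the forward-simulation oracle)
    window = [t for t in config.urea_timepoints_h if t <= config.urea_window_h]
    truth["urea_consumption_window"] = {}
    for phase in config.urea_consumption:
        tw = np.asarray(window)
        cw = np.array([_true_conc(config, phase, t) for t in window])
        slope = float(np.polyfit(tw, cw, 1)[0])
        truth["urea_consumption_window"][phase] = (
            -slope * config.volume_ml
            / (config.wet_mass_g * config.dry_wet_ratio) * 2.0)
    # ambient lake-water injections: time-zero, no internal standard
    for rep in range(1, config.n_replicates + 1):
        c15 = config.urea_c0_mM
        frac15 = c15 / (c15 + lake_c14)
        s153, s155 = areas(frac15)
        inj_rows.append({
            "injection_id": f"ambient_r{rep}", "role": "ambient",
            "known_15n_fraction": np.nan, "s153": s153, "s154": 0.0,
            "s155": s155, "s168": s153 * 0.1, "s170": s155 * 0.1,
            "time_h": 0.0, "replicate": rep, "light_phase": "",
        })
    return pd.DataFrame(conc_rows), pd.DataFrame(inj_rows), truth


# ---------------------------------------------------------------------------
# proteome spectral counts


def simulate_proteome(config: ExperimentConfig,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[pd.DataFrame, dict]:
    """Generate a multi-sample protein spectral-count table with a planted
    community composition, an enforced anticorrelated MAG pair (checked
    post hoc against the target ± 0.1, redrawing if needed) and planted
    quality-control failures."""
    if len(config.mag_abundance) < 2:
        raise ConfigError("need at least 2 MAGs")
    rng = rng if rng is not None else _rngs(config)["proteome"]
    samples = [f"S{i + 1}" for i in range(config.n_samples)]
    mags = list(config.mag_abundance)
    pair = config.anticorrelated_pair
    target_r = pair[2] if pair else None

    planted = None
    for _ in range(200):
        base = np.array([config.mag_abundance[m] for m in mags])
        mat = np.empty((len(mags), len(samples)))
        u = rng.permutation(np.linspace(0.25, 0.75, len(samples)))
        for j in range(len(samples)):
            a = base * rng.lognormal(0.0, 0.25, size=len(mags))
            if pair:
                i1, i2 = mags.index(pair[0]), mags.index(pair[1])
                a[i1] = base[i1] * 2.0 * u[j] * rng.lognormal(0.0, 0.08)
                a[i2] = base[i2] * 2.0 * (1.0 - u[j]) * rng.lognormal(0.0, 0.08)
            mat[:, j] = a / a.sum()
        if pair is None:
            planted = mat
            break
        i1, i2 = mags.index(pair[0]), mags.index(pair[1])
        r = float(np.corrcoef(mat[i1], mat[i2])[0, 1])
        if abs(r - target_r) <= 0.1:
            planted = mat
            break
    if planted is None:
        raise ConfigError(
            f"could not realize pair correlation {target_r} ± 0.1; "
            "loosen the target or add samples")

    abund = pd.DataFrame(planted, index=mags, columns=samples)
    aa_len = {
        (m, k): int(rng.integers(150, 600))
        for m in mags for k in range(config.proteins_per_mag)
    }
    rows = []
    disp = config.noise.psm_dispersion
    for j, s in enumerate(samples):
        for m in mags:
            share = planted[mags.index(m), j] / config.proteins_per_mag
            for k in range(config.proteins_per_mag):
                length = aa_len[(m, k)]
                mu = max(config.psm_depth * share * (length / 375.0), 0.05)
                psms = int(rng.negative_binomial(disp, disp / (disp + mu)))
                if psms == 0:
                    continue
                rows.append({
                    "sample_id": s, "protein_id": f"{m}_p{k}", "mag_id": m,
                    "psms": psms, "aa_len": length, "has_unique_peptide": True,
                    "peptide_fdr": round(float(rng.uniform(0.0, 0.04)), 4),
                    "protein_fdr": round(float(rng.uniform(0.0, 0.04)), 4),
                    "multi_mag": False,
                })
        # planted failures, one batch per sample
        fail = config.planted_failures
        for n, kind in [(fail.get("peptide_fdr", 0), "peptide_fdr"),
                        (fail.get("protein_fdr", 0), "protein_fdr"),
                        (fail.get("no_unique_peptide", 0), "no_unique"),
                        (fail.get("multi_mag", 0), "multi_mag")]:
            for k in range(n):
                rec = {
                    "sample_id": s, "protein_id": f"fail_{kind}_{k}",
                    "mag_id": mags[k % len(mags)],
                    "psms": int(rng.integers(1, 20)),
                    "aa_len": int(rng.integers(150, 600)),
                    "has_unique_peptide": kind != "no_unique",
                    "peptide_fdr": 0.2 if kind == "peptide_fdr" else 0.01,
                    "protein_fdr": 0.2 if kind == "protein_fdr" else 0.01,
                    "multi_mag": kind == "multi_mag",
                }
                rows.append(rec)
    pair_r = (float(np.corrcoef(planted[mags.index(pair[0])],
                                planted[mags.index(pair[1])])[0, 1])
              if pair else None)
    truth = {
        "abundance": {m: {s: float(abund.loc[m, s]) for s in samples}
                      for m in mags},
        "pair": list(pair) if pair else None,
        "pair_realized_r": pair_r,
        "planted_failures_per_sample": dict(config.planted_failures),
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# peptide isotopologue patterns


def _random_composition(rng: np.random.Generator) -> ElementalComposition:
    n_c = int(rng.integers(20, 121))
    return ElementalComposition(
        n_c=n_c,
        n_h=int(round(1.58 * n_c)),
        n_n=int(round(0.27 * n_c)),
        n_o=int(round(0.30 * n_c)),
        n_s=int(rng.integers(0, 2)),
    )


def simulate_peptide_patterns(config: ExperimentConfig,
                              rng: np.random.Generator | None = None,
                              ) -> tuple[pd.DataFrame, dict]:
    """Generate per-peptide isotopologue patterns for paired labelled and
    control samples at each SIP time point. Labelled MAGs follow their
    configured 13C trajectory in treatment samples only; everything else
    sits at natural abundance. A few peptides per MAG are dropped from
    one sample to exercise the shared-peptide filter."""
    rng = rng if rng is not None else _rngs(config)["patterns"]
    x_nat = natural_atom_fraction("C")
    samples = [f"{tp}_{arm}" for tp in config.sip_timepoints
               for arm in ("label", "ctrl")]
    peptides = {
        m: [(f"{m}_pep{k}", _random_composition(rng))
            for k in range(config.peptides_per_mag)]
        for m in config.sip_mags
    }
    # peptides deliberately missing from one (randomly chosen) sample
    dropout: set[tuple[str, str]] = set()
    for m in config.sip_mags:
        for k in range(min(config.dropout_peptides, config.peptides_per_mag)):
            dropout.add((f"{m}_pep{k}", samples[int(rng.integers(len(samples)))]))

    rows = []
    truth_p: dict[str, dict[str, float]] = {}
    icols = [f"i{j}" for j in range(config.pattern_length)]
    for sample in samples:
        tp, arm = sample.rsplit("_", 1)
        for m in config.sip_mags:
            p_mag = x_nat
            if arm == "label" and m in config.labeled_mags:
                p_mag = config.labeled_mags[m].get(tp, x_nat)
            truth_p.setdefault(m, {})[sample] = p_mag
            for pep_id, comp in peptides[m]:
                if (pep_id, sample) in dropout:
                    continue
                p_pep = max(1e-4, float(rng.normal(p_mag, config.peptide_p_jitter)))
                pattern = labeled_pattern(comp, p_pep, config.pattern_length)
                total = float(rng.lognormal(np.log(5e5), 1.0))
                intens = pattern * total * rng.lognormal(
                    0.0, config.noise.pattern_cv, size=config.pattern_length)
                row = {
                    "sample_id": sample, "peptide_id": pep_id, "mag_id": m,
                    "n_c": comp.n_c, "n_h": comp.n_h, "n_n": comp.n_n,
                    "n_o": comp.n_o, "n_s": comp.n_s,
                    "summed_intensity": total,
                }
                row.update({c: float(v) for c, v in zip(icols, intens)})
                rows.append(row)
    truth = {"label_fraction": truth_p,
             "pairs": [[f"{tp}_label", f"{tp}_ctrl"]
                       for tp in config.sip_timepoints],
             "n_dropout": len(dropout)}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# full experiment


def generate_experiment(config: ExperimentConfig,
                        out_dir: str | Path | None = None) -> dict:
    """Generate every table of a synthetic experiment plus the ground-truth
    manifest; optionally write them (TSV + JSON) to ``out_dir``.

    Returns a dict with keys ``irms``, ``urea_conc``, ``gcms``,
    ``proteins``, ``patterns`` (DataFrames) and ``manifest`` (dict).
    """
    rngs = _rngs(config)
    irms, truth_irms = simulate_labeling_timecourse(config, rngs["irms"])
    urea_conc, gcms, truth_urea = simulate_urea_depletion(config, rngs["urea"])
    proteins, truth_prot = simulate_proteome(config, rngs["proteome"])
    patterns, truth_pat = simulate_peptide_patterns(config, rngs["patterns"])
    manifest = {
        "seed": config.seed,
        "bulk": truth_irms,
        "urea": truth_urea,
        "proteome": truth_prot,
        "patterns": truth_pat,
        "config": {
            "areal_dry_density": config.areal_dry_density,
            "c_wt_pct": config.c_wt_pct, "n_wt_pct": config.n_wt_pct,
            "c_pool_excess": config.c_pool_excess,
            "n_label_purity": config.n_label_purity,
            "volume_ml": config.volume_ml, "wet_mass_g": config.wet_mass_g,
            "dry_wet_ratio": config.dry_wet_ratio,
            "istd_amount_umol": config.istd_amount_umol,
            "istd_volume_ml": config.istd_volume_ml,
        },
    }
    out = {"irms": irms, "urea_conc": urea_conc, "gcms": gcms,
           "proteins": proteins, "patterns": patterns, "manifest": manifest}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        files = {"irms": "irms_bulk.tsv", "urea_conc": "urea_conc.tsv",
                 "gcms": "gcms_injections.tsv", "proteins": "proteins.tsv",
                 "patterns": "peptide_patterns.tsv"}
        for key, name in files.items():
            out[key].to_csv(out_dir / name, sep="\t", index=False,
                            float_format="%.10g")
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        (out_dir / "SCENARIO.md").write_text(_scenario_readme(config))
    return out


def _scenario_readme(config: ExperimentConfig) -> str:
    lines = [
        "# Synthetic SIP scenario",
        "",
        f"- seed: {config.seed}",
        f"- true N assimilation rates (umol N/g dry/h): "
        + ", ".join(f"{k[0]}/{k[1]}={v}" for k, v in config.true_rates.items()),
        f"- true gross productivity: {config.true_productivity} g C/m^2/day",
        f"- urea consumption (umol urea-N/g dry/h): {config.urea_consumption}",
        f"- lake urea: {config.lake_urea_uM} uM",
        f"- anticorrelated MAG pair: {config.anticorrelated_pair}",
        f"- labelled MAG trajectories (13C atom fraction): {config.labeled_mags}",
        "",
        "Generated files: irms_bulk.tsv, urea_conc.tsv, gcms_injections.tsv, "
        "proteins.tsv, peptide_patterns.tsv, ground_truth.json",
    ]
    return "\n".join(lines) + "\n"
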