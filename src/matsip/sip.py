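"""Protein stable-isotope probing: isotopologue modeling, label-fraction
estimation, and exact quantile testing of taxon-level enrichment.

A peptide's isotopologue pattern — the relative intensities of its +0,
+1, +2, … unit-mass peaks — is the convolution of per-element binomial
heavy-isotope distributions. Assimilation of a 13C- (or 15N-) labelled
substrate shifts the carbon (nitrogen) heavy-atom probability above
natural abundance; inverting the forward model by least squares on the
observed pattern yields the peptide's heavy-atom fraction p̂ and isotope
ratio p̂/(1−p̂).

Peptide ratios aggregate to a MAG as the weighted median (weights are
MS summed intensity expressed in counts of 100 000) and to a sample as
the intensity-weighted mean over MAGs plus the unbinned fraction.
Treatment-vs-control enrichment of a MAG is tested with the exact
two-sample quantile test: of the ``r`` pooled observations lying
strictly above the pooled ``q``-quantile, the number ``k`` contributed
by the treatment group is hypergeometric under the null, and the
one-sided p-value is its upper tail. Benjamini–Hochberg correction
controls the false discovery rate across the many MAG × time-point
comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    InsufficientDataError,
    InvalidValueError,
    NonIdentifiableError,
    SchemaError,
)
from .isotope import natural_atom_fraction

__all__ = [
    "ElementalComposition",
    "NATURAL_HEAVY_ABUNDANCE",
    "QuantileTestResult",
    "natural_pattern",
    "labeled_pattern",
    "estimate_label_fraction",
    "weight_count",
    "mag_ratio",
    "sample_ratio",
    "shared_peptide_filter",
    "exact_quantile_test",
    "bh_adjust",
    "significance_report",
    "peptide_ratio_table",
    "mag_ratio_table",
    "sample_ratio_table",
    "run_quantile_tests",
]

#: natural heavy-isotope abundance per element; C and N derive from the
#: international standards, the rest are IUPAC representative values.
#: O and S are treated as +2 contributors on the unit-mass axis.
NATURAL_HEAVY_ABUNDANCE = {
    "C": natural_atom_fraction("C"),  # 0.0110566
    "H": 0.000115,
    "N": natural_atom_fraction("N"),  # 0.0036630
    "O": 0.00205,
    "S": 0.0429,
}

#: mass shift (in unit-mass bins) contributed by one heavy atom
_MASS_SHIFT = {"C": 1, "H": 1, "N": 1, "O": 2, "S": 2}

WEIGHT_DIVISOR = 100_000.0


@dataclass(frozen=True)
class ElementalComposition:
    """Atom counts of a peptide (side chains + backbone, no charge)."""

    n_c: int
    n_h: int = 0
    n_n: int = 0
    n_o: int = 0
    n_s: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_c, self.n_h, self.n_n, self.n_o, self.n_s)
        if any(c < 0 for c in counts):
            raise InvalidValueError("atom counts must be non-negative")
        if self.n_c >= 1 and self.n_n > self.n_c:
            raise InvalidValueError("peptide composition requires n_c >= n_n")

    def count(self, element: str) -> int:
        return {"C": self.n_c, "H": self.n_h, "N": self.n_n,
                "O": self.n_o, "S": self.n_s}[element]


def _binom_head(n: int, p: float, kmax: int) -> np.ndarray:
    """First ``kmax + 1`` terms of Binomial(n, p) via the ratio recurrence
    pmf(k+1) = pmf(k)·(n−k)/(k+1)·p/(1−p); far cheaper than evaluating the
    full pmf when only the low-mass isotopologue bins are needed."""
    q = 1.0 - p
    pmf = np.zeros(kmax + 1)
    pmf[0] = q ** n
    for k in range(min(kmax, n)):
        pmf[k + 1] = pmf[k] * (n - k) / (k + 1) * (p / q)
    return pmf


def _convolve_pattern(comp: ElementalComposition, heavy_prob: dict[str, float],
                      length: int) -> np.ndarray:
    dist = np.array([1.0])
    for elem in ("C", "H", "N", "O", "S"):
        n = comp.count(elem)
        p = heavy_prob[elem]
        if n == 0 or p == 0.0:
            continue
        # only the first `length` bins matter; cap the binomial support
        shift = _MASS_SHIFT[elem]
        kmax = min(n, (length - 1) // shift + 1)
        pmf = _binom_head(n, p, kmax)
        if shift > 1:
            expanded = np.zeros(shift * kmax + 1)
            expanded[::shift] = pmf
            pmf = expanded
        dist = np.convolve(dist, pmf)[:length]
    out = np.zeros(length)
    out[: len(dist)] = dist
    total = out.sum()
    if total <= 0:
        raise InvalidValueError("degenerate isotopologue pattern")
    return out / total


def natural_pattern(comp: ElementalComposition, length: int = 8,
                    abundances: dict[str, float] | None = None) -> np.ndarray:
    """Isotopologue pattern at natural abundance, truncated to ``length``
    unit-mass bins and renormalized to sum 1."""
    if length < 2:
        raise InvalidValueError("pattern length must be at least 2")
    ab = dict(NATURAL_HEAVY_ABUNDANCE)
    if abundances:
        ab.update(abundances)
    return _convolve_pattern(comp, ab, length)


def labeled_pattern(comp: ElementalComposition, p_heavy: float,
                    length: int = 8, element: str = "C") -> np.ndarray:
    """Forward model of a labelled peptide's pattern: natural abundances
    for all elements except ``element``, whose heavy-atom probability is
    ``p_heavy``. Reduces to :func:`natural_pattern` at natural abundance."""
    if not (0.0 <= p_heavy < 1.0):
        raise InvalidValueError("heavy-atom fraction must lie in [0, 1)")
    return natural_pattern(comp, length, abundances={element: p_heavy})


def estimate_label_fraction(intensities, comp: ElementalComposition,
                            element: str = "C",
                            p_max: float = 0.5) -> tuple[float, float]:
    """Estimate the heavy-atom fraction of ``element`` from an observed
    isotopologue pattern by bounded least squares against the forward
    model.

    Returns ``(p_hat, ratio)`` with ``ratio = p_hat / (1 − p_hat)``.
    A noiseless forward pattern is inverted to its generating fraction
    to better than 1e-6 (coarse grid bracketing plus bounded scalar
    minimization).
    """
    obs = np.asarray(intensities, dtype=float)
    if obs.ndim != 1 or len(obs) < 3:
        raise InvalidValueError("pattern needs at least 3 isotopologue intensities")
    if np.any(obs < 0) or obs.sum() <= 0:
        raise InvalidValueError("intensities must be non-negative, not all zero")
    obs = obs / obs.sum()
    if np.ptp(obs) < 1e-9:
        raise NonIdentifiableError("flat isotopologue pattern carries no signal")
    length = len(obs)

    def objective(p: float) -> float:
        model = labeled_pattern(comp, p, length, element)
        return float(np.sum((obs - model) ** 2))

    grid = np.linspace(0.0, p_max, 201)
    values = [objective(p) for p in grid]
    i = int(np.argmin(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-12})
    p_hat = float(res.x)
    return p_hat, p_hat / (1.0 - p_hat)


def weight_count(summed_intensity: float) -> int:
    """Observation multiplicity of a peptide: its MS summed intensity in
    units of 100 000, floored, with a minimum of 1 so every detected
    peptide counts at least once."""
    if summed_intensity < 0:
        raise InvalidValueError("summed intensity must be non-negative")
    return max(1, int(math.floor(summed_intensity / WEIGHT_DIVISOR)))


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Median of the dataset in which ``values[i]`` appears ``weights[i]``
    times (equals ``np.median(np.repeat(values, weights))``)."""
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=np.int64)[order]
    cw = np.cumsum(w)
    total = int(cw[-1])
    lower_k = (total + 1) // 2
    upper_k = total // 2 + 1
    lo = v[np.searchsorted(cw, lower_k)]
    hi = v[np.searchsorted(cw, upper_k)]
    return float((lo + hi) / 2.0)


def mag_ratio(ratios, weights=None) -> float:
    """MAG-level isotope ratio: the weighted median of its peptides'
    ratios, weights acting as observation multiplicities."""
    ratios = np.asarray(ratios, dtype=float)
    if len(ratios) == 0:
        raise InsufficientDataError("no peptide ratios for MAG")
    if weights is None:
        weights = np.ones(len(ratios), dtype=np.int64)
    weights = np.asarray(weights, dtype=np.int64)
    if np.any(weights < 1):
        raise InvalidValueError("weights must be positive integers")
    return _weighted_median(ratios, weights)


def sample_ratio(group_ratios, group_weights) -> float:
    """Sample-level isotope ratio: the weighted mean over MAGs plus the
    unbinned fraction, weighted by each group's MS summed intensity."""
    r = np.asarray(group_ratios, dtype=float)
    w = np.asarray(group_weights, dtype=float)
    if len(r) == 0:
        raise InsufficientDataError("no groups to average")
    if w.sum() <= 0:
        raise InvalidValueError("group weights sum to zero")
    return float(np.sum(w * r) / np.sum(w))


def shared_peptide_filter(patterns: pd.DataFrame,
                          sample_ids=None) -> pd.DataFrame:
    """Keep only peptides observed in every sample of the comparison set
    (damps mat-heterogeneity noise in cross-sample tests)."""
    if sample_ids is None:
        sample_ids = patterns["sample_id"].unique()
    sample_ids = list(sample_ids)
    if len(sample_ids) < 2:
        raise InsufficientDataError("shared-peptide filter needs >=2 samples")
    sub = patterns[patterns["sample_id"].isin(sample_ids)]
    counts = sub.groupby("peptide_id")["sample_id"].nunique()
    shared = counts.index[counts == len(sample_ids)]
    return sub[sub["peptide_id"].isin(shared)].copy()


@dataclass(frozen=True)
class QuantileTestResult:
    mag_id: str
    treatment_sample: str
    control_sample: str
    k: int
    r: int
    p_raw: float
    p_adjusted: float = float("nan")
    direction: str = "greater"
    n_treatment: int = 0
    n_control: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.r):
            raise InvalidValueError("need 0 <= k <= r")


def exact_quantile_test(treatment, control, q: float = 0.5,
                        treatment_weights=None, control_weights=None,
                        mag_id: str = "", treatment_sample: str = "",
                        control_sample: str = "") -> QuantileTestResult:
    """Exact two-sample quantile test (one-sided, treatment enriched).

    Both groups are expanded by their integer weights and pooled (size
    ``N``). With ``c`` the pooled order statistic at rank ``ceil(q·N)``,
    ``r`` counts pooled values strictly above ``c`` and ``k`` those from
    the treatment group; under the null of exchangeability ``k`` is
    hypergeometric and ``p = P(K ≥ k)``. Ties with the cutoff count as
    not-above. ``r = 0`` gives p = 1.
    """
    if not (0.0 < q < 1.0):
        raise InvalidValueError("quantile q must lie in (0, 1)")
    t = np.asarray(treatment, dtype=float)
    ctl = np.asarray(control, dtype=float)
    if treatment_weights is not None:
        t = np.repeat(t, np.asarray(treatment_weights, dtype=np.int64))
    if control_weights is not None:
        ctl = np.repeat(ctl, np.asarray(control_weights, dtype=np.int64))
    n_t, n_c = len(t), len(ctl)
    if n_t == 0 or n_c == 0:
        raise InsufficientDataError("both groups must be non-empty")
    pooled = np.concatenate([t, ctl])
    big_n = n_t + n_c
    cutoff = np.sort(pooled)[int(math.ceil(q * big_n)) - 1]
    r = int(np.sum(pooled > cutoff))
    k = int(np.sum(t > cutoff))
    p = 1.0 if r == 0 else float(stats.hypergeom.sf(k - 1, big_n, n_t, r))
    return QuantileTestResult(mag_id, treatment_sample, control_sample,
                              k, r, min(p, 1.0),
                              n_treatment=n_t, n_control=n_c)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significance_report(results: list[QuantileTestResult],
                        alpha: float = 0.05) -> pd.DataFrame:
    """BH-adjust a batch of quantile-test results and flag adjusted
    p < alpha (strict inequality)."""
    if not results:
        return pd.DataFrame(columns=[
            "mag_id", "treatment_sample", "control_sample", "k", "r",
            "p_raw", "p_adj", "significant"])
    p_adj = bh_adjust([res.p_raw for res in results])
    rows = [
        {"mag_id": res.mag_id, "treatment_sample": res.treatment_sample,
         "control_sample": res.control_sample, "k": res.k, "r": res.r,
         "n_treatment": res.n_treatment, "n_control": res.n_control,
         "p_raw": res.p_raw, "p_adj": float(adj),
         "significant": bool(adj < alpha)}
        for res, adj in zip(results, p_adj)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# table-level workflow


_PATTERN_META = ["sample_id", "peptide_id", "mag_id", "n_c", "n_h", "n_n",
                 "n_o", "n_s", "summed_intensity"]


def _intensity_columns(patterns: pd.DataFrame) -> list[str]:
    cols = [c for c in patterns.columns if c.startswith("i") and c[1:].isdigit()]
    if len(cols) < 3:
        raise SchemaError("pattern table needs intensity columns i0, i1, ...")
    return sorted(cols, key=lambda c: int(c[1:]))


def peptide_ratio_table(patterns: pd.DataFrame, element: str = "C",
                        ) -> pd.DataFrame:
    """Estimate per-peptide label fractions and ratios for a pattern table.

    Expects columns ``sample_id, peptide_id, mag_id, n_c, n_h, n_n, n_o,
    n_s, summed_intensity, i0..iK``. Non-identifiable patterns are
    dropped with a count in ``attrs['n_failed']``.
    """
    missing = set(_PATTERN_META) - set(patterns.columns)
    if missing:
        raise SchemaError(f"pattern table missing columns {sorted(missing)}")
    icols = _intensity_columns(patterns)
    rows, n_failed = [], 0
    for row in patterns.itertuples(index=False):
        comp = ElementalComposition(
            int(row.n_c), int(row.n_h), int(row.n_n), int(row.n_o), int(row.n_s))
        intens = np.array([getattr(row, c) for c in icols], dtype=float)
        try:
            p_hat, ratio = estimate_label_fraction(intens, comp, element)
        except (NonIdentifiableError, InvalidValueError):
            n_failed += 1
            continue
        rows.append({
            "sample_id": row.sample_id, "peptide_id": row.peptide_id,
            "mag_id": row.mag_id, "element": element,
            "label_fraction": p_hat, "ratio": ratio,
            "summed_intensity": row.summed_intensity,
            "weight_count": weight_count(float(row.summed_intensity)),
        })
    out = pd.DataFrame(rows)
    out.attrs["n_failed"] = n_failed
    return out


def mag_ratio_table(peptide_ratios: pd.DataFrame) -> pd.DataFrame:
    """Weighted-median ratio and boxplot statistics (q1/median/q3 of the
    weight-expanded peptide ratios) per MAG and sample."""
    rows = []
    for (mag, sample), grp in peptide_ratios.groupby(["mag_id", "sample_id"]):
        expanded = np.repeat(grp["ratio"].to_numpy(),
                             grp["weight_count"].to_numpy(dtype=np.int64))
        rows.append({
            "mag_id": mag, "sample_id": sample,
            "ratio": mag_ratio(grp["ratio"].to_numpy(),
                               grp["weight_count"].to_numpy()),
            "q1": float(np.percentile(expanded, 25)),
            "median": float(np.median(expanded)),
            "q3": float(np.percentile(expanded, 75)),
            "n_peptides": len(grp),
            "summed_intensity": float(grp["summed_intensity"].sum()),
        })
    return pd.DataFrame(rows)


def sample_ratio_table(peptide_ratios: pd.DataFrame) -> pd.DataFrame:
    """Per-sample isotope ratio: intensity-weighted average of the MAG
    medians (unbinned peptides forming their own group)."""
    mags = mag_ratio_table(peptide_ratios)
    rows = []
    for sample, grp in mags.groupby("sample_id"):
        rows.append({
            "sample_id": sample,
            "ratio": sample_ratio(grp["ratio"].to_numpy(),
                                  grp["summed_intensity"].to_numpy()),
            "n_groups": len(grp),
        })
    return pd.DataFrame(rows)


def run_quantile_tests(peptide_ratios: pd.DataFrame,
                       pairs: list[tuple[str, str]],
                       q: float = 0.5, alpha: float = 0.05,
                       shared_only: bool = True) -> pd.DataFrame:
    """Exact quantile tests per MAG for every (treatment, control) sample
    pair, BH-corrected across the whole batch.

    ``pairs`` lists comparisons as (treatment sample, control sample).
    With ``shared_only`` the test for each pair is restricted to
    peptides observed in both samples of the pair and in every other
    sample of the table (the shared-peptide rule).
    """
    table = peptide_ratios
    if shared_only:
        table = shared_peptide_filter(peptide_ratios)
    results = []
    for treat_s, ctrl_s in pairs:
        for mag in sorted(table["mag_id"].unique()):
            t = table[(table["sample_id"] == treat_s) & (table["mag_id"] == mag)]
            c = table[(table["sample_id"] == ctrl_s) & (table["mag_id"] == mag)]
            if len(t) == 0 or len(c) == 0:
                continue
            results.append(exact_quantile_test(
                t["ratio"].to_numpy(), c["ratio"].to_numpy(), q,
                t["weight_count"].to_numpy(), c["weight_count"].to_numpy(),
                mag_id=mag, treatment_sample=treat_s, control_sample=ctrl_s))
    return significance_report(results, alpha)
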