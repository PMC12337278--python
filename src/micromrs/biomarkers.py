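"""The 14-biomarker panel, QC estimators, and two-cohort statistics.

Each biomarker is a (region, statistic) pair computed on a referenced,
baseline-corrected spectrum. Intensities are trapezoidal integrals of the
clipped (non-negative) lineshape over a region; skewness and kurtosis treat
the clipped lineshape as an unnormalized density over chemical shift, so they
describe the peak's *shape* (kurtosis rises as lines sharpen); Saturate-Ampl
and Saturate-Width come from a single-Lorentzian-plus-offset least-squares fit
in the Saturate window. Kurtosis is the Pearson (non-excess) convention, so a
flat profile gives 9/5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .spectra import (
    DEFAULT_REGIONS,
    NOISE_WINDOW,
    RegionSet,
    Spectrum,
    baseline_correct,
    reference_to_water,
)

__all__ = [
    "BiomarkerDef",
    "BiomarkerRegistry",
    "DEFAULT_REGISTRY",
    "CohortComparison",
    "region_intensity",
    "region_moment_stat",
    "lorentzian_fit",
    "snr",
    "extract_biomarkers",
    "build_feature_table",
    "compare_cohorts",
    "mannwhitney_exact",
    "lilliefors_mc",
]

STAT_KINDS = ("Int", "Skew", "Kurt", "LorentzAmpl", "LorentzWidth")


@dataclass(frozen=True)
class BiomarkerDef:
    name: str
    region: str
    kind: str

    def __post_init__(self):
        if self.kind not in STAT_KINDS:
            raise ValueError(f"unknown statistic kind {self.kind!r}")


class BiomarkerRegistry:
    """Ordered biomarker definitions over a :class:`RegionSet`."""

    def __init__(self, defs: Sequence[BiomarkerDef], regions: RegionSet = DEFAULT_REGIONS):
        for d in defs:
            if d.region not in regions:
                raise KeyError(f"biomarker {d.name!r} references unknown region {d.region!r}")
        self.defs = tuple(defs)
        self.regions = regions

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.defs]

    def __len__(self):
        return len(self.defs)

    def __iter__(self):
        return iter(self.defs)


DEFAULT_REGISTRY = BiomarkerRegistry(
    [
        BiomarkerDef("PLC-Int", "PLC", "Int"),
        BiomarkerDef("Saturate-Int", "Saturate", "Int"),
        BiomarkerDef("S1-Int", "S1", "Int"),
        BiomarkerDef("S3-Int", "S3", "Int"),
        BiomarkerDef("SaturateL-Int", "SaturateL", "Int"),
        BiomarkerDef("SaturateR-Int", "SaturateR", "Int"),
        BiomarkerDef("PLC-Skew", "PLC", "Skew"),
        BiomarkerDef("Saturate-Skew", "Saturate", "Skew"),
        BiomarkerDef("SaturateR-Skew", "SaturateR", "Skew"),
        BiomarkerDef("PLC-Kurt", "PLC", "Kurt"),
        BiomarkerDef("Saturate-Kurt", "Saturate", "Kurt"),
        BiomarkerDef("SaturateR-Kurt", "SaturateR", "Kurt"),
        BiomarkerDef("Saturate-Ampl", "Saturate", "LorentzAmpl"),
        BiomarkerDef("Saturate-Width", "Saturate", "LorentzWidth"),
    ]
)


# ---------------------------------------------------------------------------
# per-region statistics


def _region_slice(spec: Spectrum, region: tuple[float, float], min_bins: int = 4):
    mask = spec.region_mask(*region)
    if mask.sum() < min_bins:
        raise ValueError(
            f"region [{region[0]}, {region[1]}] ppm covers only {int(mask.sum())} "
            f"bins (< {min_bins}); axis resolution too coarse"
        )
    return spec.ppm[mask], spec.intensity[mask]


def region_intensity(spec: Spectrum, region: tuple[float, float]) -> float:
    """Trapezoidal integral of the clipped intensity over a closed region."""
    x, y = _region_slice(spec, region)
    return float(np.trapezoid(np.clip(y, 0.0, None), x))


def region_moment_stat(spec: Spectrum, region: tuple[float, float], kind: str) -> float:
    """Intensity-weighted skewness or Pearson kurtosis of chemical shift.

    The clipped lineshape w(d) = max(I(d), 0) acts as an unnormalized density
    on the region; returns m3/m2^1.5 (Skew) or m4/m2^2 (Kurt).
    """
    if kind not in ("Skew", "Kurt"):
        raise ValueError("kind must be 'Skew' or 'Kurt'")
    x, y = _region_slice(spec, region)
    w = np.clip(y, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero intensities in region; moment statistic undefined")
    mu = float(np.sum(w * x) / total)
    dx = x - mu
    m2 = float(np.sum(w * dx**2) / total)
    if m2 <= 0:
        raise ValueError("zero variance in region; moment statistic undefined")
    if kind == "Skew":
        m3 = float(np.sum(w * dx**3) / total)
        return m3 / m2**1.5
    m4 = float(np.sum(w * dx**4) / total)
    return m4 / m2**2


def lorentzian_fit(
    spec: Spectrum, region: tuple[float, float], max_nfev: int = 2000
) -> tuple[float, float, float, float, bool]:
    """Fit I(d) = A*g^2/((d-d0)^2+g^2) + c over a region by least squares.

    Returns ``(amplitude, fwhm_ppm, center_ppm, offset, converged)``; on
    failure the numeric fields are NaN and ``converged`` is False.
    """
    x, y = _region_slice(spec, region, min_bins=8)

    def model(d, amp, gamma, d0, c):
        return amp * gamma**2 / ((d - d0) ** 2 + gamma**2) + c

    i0 = int(np.argmax(y))
    d0 = float(x[i0])
    c0 = float(np.median(y))
    a0 = float(y[i0] - c0)
    if a0 <= 0:
        return (np.nan, np.nan, np.nan, np.nan, False)
    half = c0 + a0 / 2.0
    above = y >= half
    g0 = max((x[above][-1] - x[above][0]) / 2.0, (x[1] - x[0])) if above.any() else 0.05
    span = float(x[-1] - x[0])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                model, x, y, p0=[a0, g0, d0, c0],
                bounds=([0.0, 1e-4, x[0] - span, -np.inf],
                        [np.inf, 5.0 * span, x[-1] + span, np.inf]),
                maxfev=max_nfev,
            )
    except (RuntimeError, ValueError):
        return (np.nan, np.nan, np.nan, np.nan, False)
    amp, gamma, d0_fit, c = (float(v) for v in popt)
    at_bound = gamma <= 1.1e-4 or gamma >= 4.99 * span
    return (amp, 2.0 * gamma, d0_fit, c, not at_bound)


def snr(spec: Spectrum, noise_window: tuple[float, float] = NOISE_WINDOW,
        signal_region: tuple[float, float] | None = None) -> float:
    """Saturate-region peak maximum divided by noise SD in a signal-free window."""
    if signal_region is None:
        signal_region = DEFAULT_REGIONS["Saturate"]
    _, y_sig = _region_slice(spec, signal_region)
    mask = spec.region_mask(*noise_window)
    if not mask.any():
        raise ValueError(f"noise window {noise_window} outside the ppm axis")
    peak = float(y_sig.max())
    if peak <= 0:
        raise ValueError("no positive signal in the saturate region; SNR undefined")
    sd = float(np.std(spec.intensity[mask], ddof=1))
    if sd == 0:
        warnings.warn("zero noise SD; reporting infinite SNR", stacklevel=2)
        return float("inf")
    return peak / sd


# ---------------------------------------------------------------------------
# feature extraction


def _preprocess(spec: Spectrum) -> Spectrum:
    if not spec.referenced:
        spec = reference_to_water(spec)
    if "baseline_offset" not in spec.metadata:
        spec = baseline_correct(spec)
    return spec


#: ppm window integrated for the optional water normalization
WATER_REGION = (4.4, 5.0)


def extract_biomarkers(
    spec: Spectrum, registry: BiomarkerRegistry = DEFAULT_REGISTRY,
    preprocess: bool = True, normalize: str | None = None,
) -> dict:
    """Compute the full biomarker vector plus SNR / linewidth QC fields.

    Undefined statistics and non-converged fits propagate as NaN (flagged in
    ``_missing``), never as silent zeros. ``normalize="water"`` divides the
    scale-carrying values (intensities and the Lorentzian amplitude) by the
    water-region integral; the default reports raw integrals, since water is
    used only as a frequency reference and the between-sample intensity
    spread is itself informative.
    """
    if normalize not in (None, "water"):
        raise ValueError("normalize must be None or 'water'")
    if preprocess:
        spec = _preprocess(spec)
    norm = 1.0
    if normalize == "water":
        norm = region_intensity(spec, WATER_REGION)
        if norm <= 0:
            raise ValueError("water-region integral is non-positive; "
                             "cannot normalize")
    values: dict[str, float] = {}
    missing: list[str] = []
    fit_cache: dict[str, tuple] = {}
    for d in registry:
        region = registry.regions[d.region]
        try:
            if d.kind == "Int":
                values[d.name] = region_intensity(spec, region) / norm
            elif d.kind in ("Skew", "Kurt"):
                values[d.name] = region_moment_stat(spec, region, d.kind)
            else:
                if d.region not in fit_cache:
                    fit_cache[d.region] = lorentzian_fit(spec, region)
                amp, fwhm, _, _, ok = fit_cache[d.region]
                values[d.name] = amp / norm if d.kind == "LorentzAmpl" else fwhm
                if not ok:
                    missing.append(d.name)
        except ValueError:
            values[d.name] = float("nan")
            missing.append(d.name)
        if not np.isfinite(values[d.name]) and d.name not in missing:
            missing.append(d.name)
    out = dict(values)
    try:
        out["snr"] = snr(spec)
    except ValueError:
        out["snr"] = float("nan")
        missing.append("snr")
    sat_fit = fit_cache.get("Saturate") or lorentzian_fit(
        spec, registry.regions["Saturate"])
    out["linewidth_ppm"] = sat_fit[1]
    out["sample_id"] = spec.metadata.get("sample_id", "")
    out["_missing"] = tuple(missing)
    return out


def build_feature_table(
    spectra: Iterable[Spectrum],
    labels: Sequence[str] | None = None,
    registry: BiomarkerRegistry = DEFAULT_REGISTRY,
    preprocess: bool = True,
    normalize: str | None = None,
) -> pd.DataFrame:
    """One row per sample: sample_id, 14 biomarkers, snr, linewidth_ppm, label."""
    rows = []
    spectra = list(spectra)
    if labels is None:
        labels = [s.metadata.get("cohort_label") for s in spectra]
    if len(labels) != len(spectra):
        raise ValueError("labels length must match number of spectra")
    for spec, lbl in zip(spectra, labels):
        rec = extract_biomarkers(spec, registry, preprocess=preprocess,
                                 normalize=normalize)
        rec.pop("_missing")
        rec["label"] = lbl
        rows.append(rec)
    cols = ["sample_id"] + registry.names + ["snr", "linewidth_ppm", "label"]
    return pd.DataFrame(rows)[cols]


# ---------------------------------------------------------------------------
# two-cohort statistics


def lilliefors_mc(x: np.ndarray, n_reps: int = 5000, seed: int = 0) -> float:
    """Lilliefors normality test: KS distance to the fitted normal, with a
    seeded Monte-Carlo null (parameters re-estimated in every replicate)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("Lilliefors test needs n >= 4")
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0  # degenerate: certainly not a nondegenerate normal
    d_obs = stats.kstest((x - x.mean()) / sd, "norm").statistic
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_reps, n))
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
    z.sort(axis=1)
    grid = np.arange(1, n + 1)
    cdf = stats.norm.cdf(z)
    d_null = np.maximum(grid / n - cdf, cdf - (grid - 1) / n).max(axis=1)
    return float((1 + np.sum(d_null >= d_obs)) / (1 + n_reps))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x against y via midranks (tie-aware)."""
    nx = x.size
    allv = np.concatenate([x, y])
    ranks = stats.rankdata(allv)
    return float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)


def mannwhitney_exact(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact Mann-Whitney p-value by enumerating all rank splits.

    Tie-aware: the null distribution of U is built over all C(n+m, n)
    assignments of the pooled (midranked) values, so it is exact under the
    permutation null even with ties. Intended for min(n, m) <= 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    u_obs = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    total = comb(nx + ny, nx)
    mean_u = nx * ny / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = 0
    base = nx * (nx + 1) / 2.0
    for idx in combinations(range(nx + ny), nx):
        u = ranks[list(idx)].sum() - base
        if abs(u - mean_u) >= dev_obs - 1e-12:
            count += 1
    return count / total


@dataclass
class CohortComparison:
    biomarker: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    normality_p_a: float
    normality_p_b: float
    test_used: str  # "Welch-t" or "Mann-Whitney-U"
    p_value: float


def compare_cohorts(
    table: pd.DataFrame, biomarker: str, label_col: str = "label",
    alpha_normality: float = 0.05, seed: int = 0,
    exact_max_n: int = 10,
) -> CohortComparison:
    """Welch t-test if both groups pass Lilliefors normality, else Mann-Whitney U.

    The U test is the exact tie-aware enumeration when both groups have
    n <= ``exact_max_n``, otherwise scipy's tie-corrected normal approximation.
    """
    groups = sorted(table[label_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two cohorts, found {groups}")
    a, b = groups
    xa = table.loc[table[label_col] == a, biomarker].dropna().to_numpy(float)
    xb = table.loc[table[label_col] == b, biomarker].dropna().to_numpy(float)
    if xa.size < 3 or xb.size < 3:
        raise ValueError("each cohort needs n >= 3 for a comparison")
    pa = lilliefors_mc(xa, seed=seed) if xa.size >= 4 else 0.0
    pb = lilliefors_mc(xb, seed=seed + 1) if xb.size >= 4 else 0.0
    both_normal = pa > alpha_normality and pb > alpha_normality
    if both_normal:
        test_used = "Welch-t"
        p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
    else:
        test_used = "Mann-Whitney-U"
        if max(xa.size, xb.size) <= exact_max_n:
            p = mannwhitney_exact(xa, xb)
        else:
            p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                         method="asymptotic").pvalue)
    return CohortComparison(
        biomarker=biomarker, group_a=a, group_b=b, n_a=xa.size, n_b=xb.size,
        mean_a=float(xa.mean()), mean_b=float(xb.mean()),
        sd_a=float(xa.std(ddof=1)), sd_b=float(xb.std(ddof=1)),
        normality_p_a=pa, normality_p_b=pb, test_used=test_used, p_value=p,
    )
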